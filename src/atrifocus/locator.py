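"""Torso-quadrant scoring and the atrial focus location algorithm.

The torso is split into eight quadrants — four anterior, four posterior —
by a vertical and a lateral midline on each face. Every electrode's
polarity label is scored (negative = 2, biphasic/flat = 1, positive = 0)
and averaged per quadrant into Sp. The quadrant holding the largest mean,
Sp_max, points at the atrial quadrant containing the ectopic focus via a
torso-to-atria correlation table; ties between quadrants are resolved by
comparing neighbouring quadrants' Sp values (two-way, three-way/corner,
and four-or-more rules). An optional refinement step places the focus in
one of four sub-quadrants of the winner by checking whether each in-face
neighbour's Sp lies within a threshold (0.1 by default) of Sp_max.

Quadrant ids follow a fixed convention (configurable via the correlation
table): Qt1 anterior superior-right, Qt2 anterior superior-left, Qt3
anterior inferior-right, Qt4 anterior inferior-left, Qt5-Qt8 the posterior
counterparts in the same order; Qa_i matches Qt_i for the default atrial
orientation. "Right"/"left" are the patient's own sides.

All score comparisons use exact rational arithmetic (integer score sums
over integer lead counts), so ties are exact and float round-off cannot
fabricate or destroy one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

from .errors import (
    AssignmentMismatchError,
    DegenerateLayoutError,
    InvalidWinnerError,
    MissingVariantError,
    UnresolvableTieError,
)
from .pwave import PolarityLabel, PolarityMap, polarity_score

# ---------------------------------------------------------------------------
# Quadrant geometry and adjacency


@dataclass(frozen=True)
class TorsoQuadrant:
    """One of the eight torso quadrants."""

    id: str
    face: str  # anterior | posterior
    vertical: str  # superior | inferior
    lateral: str  # right | left


_QT_DEFS = [
    ("Qt1", "anterior", "superior", "right"),
    ("Qt2", "anterior", "superior", "left"),
    ("Qt3", "anterior", "inferior", "right"),
    ("Qt4", "anterior", "inferior", "left"),
    ("Qt5", "posterior", "superior", "right"),
    ("Qt6", "posterior", "superior", "left"),
    ("Qt7", "posterior", "inferior", "right"),
    ("Qt8", "posterior", "inferior", "left"),
]

TORSO_QUADRANTS: dict[str, TorsoQuadrant] = {
    qid: TorsoQuadrant(qid, f, v, l) for qid, f, v, l in _QT_DEFS
}
QT_IDS: tuple[str, ...] = tuple(TORSO_QUADRANTS)
QA_IDS: tuple[str, ...] = tuple(f"Qa{i}" for i in range(1, 9))


def quadrant_id(face: str, vertical: str, lateral: str) -> str:
    for qid, f, v, l in _QT_DEFS:
        if (f, v, l) == (face, vertical, lateral):
            return qid
    raise ValueError(f"no quadrant ({face}, {vertical}, {lateral})")


@dataclass(frozen=True)
class AdjacencyGraph:
    """In-face edge-sharing neighbours plus the front/back counterpart.

    Each quadrant has exactly two in-face neighbours (the quadrant across
    its vertical midline and the one across its horizontal midline — never
    the diagonal) and one counterpart on the opposite face.
    """

    in_face: Mapping[str, tuple[str, str]]
    counterpart: Mapping[str, str]

    def in_face_neighbors(self, qid: str) -> tuple[str, str]:
        return self.in_face[qid]

    def all_neighbors(self, qid: str) -> tuple[str, ...]:
        return self.in_face[qid] + (self.counterpart[qid],)

    def lateral_neighbor(self, qid: str) -> str:
        """In-face neighbour across the vertical midline (left/right flip)."""
        q = TORSO_QUADRANTS[qid]
        other = "left" if q.lateral == "right" else "right"
        return quadrant_id(q.face, q.vertical, other)

    def vertical_neighbor(self, qid: str) -> str:
        """In-face neighbour across the horizontal midline (sup/inf flip)."""
        q = TORSO_QUADRANTS[qid]
        other = "inferior" if q.vertical == "superior" else "superior"
        return quadrant_id(q.face, other, q.lateral)


def default_adjacency() -> AdjacencyGraph:
    in_face: dict[str, tuple[str, str]] = {}
    counterpart: dict[str, str] = {}
    for qid, q in TORSO_QUADRANTS.items():
        lat = "left" if q.lateral == "right" else "right"
        ver = "inferior" if q.vertical == "superior" else "superior"
        in_face[qid] = (
            quadrant_id(q.face, q.vertical, lat),
            quadrant_id(q.face, ver, q.lateral),
        )
        other_face = "posterior" if q.face == "anterior" else "anterior"
        counterpart[qid] = quadrant_id(other_face, q.vertical, q.lateral)
    return AdjacencyGraph(in_face=in_face, counterpart=counterpart)


# ---------------------------------------------------------------------------
# Electrode -> quadrant assignment


@dataclass(frozen=True)
class QuadrantAssignment:
    """Assignment of every layout lead to exactly one torso quadrant."""

    lead_to_quadrant: Mapping[str, str]

    @property
    def counts(self) -> dict[str, int]:
        c = {qid: 0 for qid in QT_IDS}
        for q in self.lead_to_quadrant.values():
            c[q] += 1
        return c

    def leads_in(self, qid: str) -> list[str]:
        return [l for l, q in self.lead_to_quadrant.items() if q == qid]


def assign_leads_to_quadrants(
    coords: Mapping[str, tuple[str, float, float]],
    midlines: tuple[float, float] = (0.0, 0.0),
) -> QuadrantAssignment:
    """Assign electrodes to torso quadrants by face and midline sign.

    ``coords`` maps lead id to ``(face, u, z)`` where ``u`` is the lateral
    torso-surface coordinate (mm, positive toward the patient's left) and
    ``z`` the vertical coordinate (mm, positive superior). ``midlines`` is
    ``(lateral_midline, vertical_midline)``. An electrode exactly on a
    midline goes to the right/superior side.
    """
    lat_mid, ver_mid = midlines
    mapping: dict[str, str] = {}
    for lead, (face, u, z) in coords.items():
        if face not in ("anterior", "posterior"):
            raise DegenerateLayoutError(f"lead {lead}: unknown face {face!r}")
        lateral = "left" if u > lat_mid else "right"
        vertical = "superior" if z >= ver_mid else "inferior"
        mapping[lead] = quadrant_id(face, vertical, lateral)
    assignment = QuadrantAssignment(lead_to_quadrant=mapping)
    empty = [qid for qid, n in assignment.counts.items() if n == 0]
    if empty:
        raise DegenerateLayoutError(
            f"empty torso quadrants {empty}: the location algorithm is "
            "undefined on this layout/midline combination"
        )
    return assignment


# ---------------------------------------------------------------------------
# Quadrant scores (Sp)


@dataclass(frozen=True)
class QuadrantScores:
    """Exact per-quadrant mean polarity scores.

    ``sp`` holds one Fraction per quadrant; ``sp_max`` and ``argmax_set``
    are derived under exact comparison.
    """

    sp: Mapping[str, Fraction]

    @property
    def sp_max(self) -> Fraction:
        return max(self.sp.values())

    @property
    def argmax_set(self) -> tuple[str, ...]:
        m = self.sp_max
        return tuple(q for q in QT_IDS if self.sp[q] == m)

    @property
    def sp_float(self) -> dict[str, float]:
        return {q: float(v) for q, v in self.sp.items()}


def quadrant_scores(
    pmap: PolarityMap,
    assignment: QuadrantAssignment,
    flat_policy: str = "score",
) -> QuadrantScores:
    """Average the per-lead polarity scores within each torso quadrant.

    ``flat_policy`` — ``"score"`` counts flat leads with the biphasic value
    of 1 (default); ``"exclude"`` drops them from the quadrant mean, and a
    quadrant left with no leads falls back to the neutral value 1.
    """
    if flat_policy not in ("score", "exclude"):
        raise ValueError(f"unknown flat_policy {flat_policy!r}")
    sums = {qid: 0 for qid in QT_IDS}
    counts = {qid: 0 for qid in QT_IDS}
    for lead, label in pmap.entries.items():
        qid = assignment.lead_to_quadrant.get(lead)
        if qid is None:
            raise AssignmentMismatchError(f"lead {lead} has no quadrant assignment")
        if flat_policy == "exclude" and label is PolarityLabel.FLAT:
            continue
        sums[qid] += polarity_score(label)
        counts[qid] += 1
    sp = {
        qid: (Fraction(sums[qid], counts[qid]) if counts[qid] else Fraction(1))
        for qid in QT_IDS
    }
    return QuadrantScores(sp=sp)


# ---------------------------------------------------------------------------
# Focus location (decision rules)


def _neighbor_mean(scores: QuadrantScores, adjacency: AdjacencyGraph,
                   qid: str, exclude: set[str]) -> Fraction | None:
    vals = [scores.sp[n] for n in adjacency.all_neighbors(qid) if n not in exclude]
    if not vals:
        return None
    return sum(vals, Fraction(0)) / len(vals)


def _fallback_among(scores: QuadrantScores, adjacency: AdjacencyGraph,
                    tied: Sequence[str]) -> str:
    """Generic tie fallback: largest mean Sp over non-tied neighbours."""
    tie_set = set(tied)
    means = {q: _neighbor_mean(scores, adjacency, q, tie_set) for q in tied}
    if all(m is None for m in means.values()):
        raise UnresolvableTieError(
            f"tied quadrants {sorted(tied)} have no non-tied neighbours"
        )
    best = max(m for m in means.values() if m is not None)
    winners = [q for q in tied if means[q] == best]
    if len(winners) != 1:
        raise UnresolvableTieError(
            f"tied quadrants {sorted(winners)} remain indistinguishable by "
            "their neighbours' scores"
        )
    return winners[0]


def locate_focus(
    scores: QuadrantScores, adjacency: AdjacencyGraph | None = None
) -> tuple[str, str]:
    """Pick the torso quadrant of the focus from the Sp scores.

    Returns ``(quadrant_id, tie_rule_used)`` with ``tie_rule_used`` one of
    ``none`` / ``two_way`` / ``three_way`` / ``four_plus``.

    Decision rules, applied to the set of quadrants attaining Sp_max:

    * one quadrant — it wins outright;
    * two tied, sharing an in-face edge — each tied quadrant's remaining
      in-face neighbour is examined, and the tied quadrant whose neighbour
      carries the larger Sp wins;
    * three tied — the corner quadrant, i.e. the one adjacent to both
      others, wins;
    * four or more tied — the largest Sp among non-tied quadrants is found
      and the tied quadrant adjacent to it (counting the front/back
      counterpart as adjacent) wins.

    Two-way ties between non-adjacent quadrants, or secondary comparisons
    that are themselves tied, fall back to comparing the mean Sp of each
    tied quadrant's non-tied neighbours; if that also ties, an
    :class:`~atrifocus.errors.UnresolvableTieError` is raised rather than
    guessing.
    """
    adjacency = adjacency or default_adjacency()
    tied = scores.argmax_set
    if len(tied) == 1:
        return tied[0], "none"

    if len(tied) == 2:
        q1, q2 = tied
        if q2 in adjacency.in_face_neighbors(q1):
            # remaining in-face neighbour of each tied quadrant
            (n1,) = [n for n in adjacency.in_face_neighbors(q1) if n != q2]
            (n2,) = [n for n in adjacency.in_face_neighbors(q2) if n != q1]
            if scores.sp[n1] > scores.sp[n2]:
                return q1, "two_way"
            if scores.sp[n2] > scores.sp[n1]:
                return q2, "two_way"
        return _fallback_among(scores, adjacency, tied), "two_way"

    if len(tied) == 3:
        corners = [
            q
            for q in tied
            if all(
                o in adjacency.in_face_neighbors(q) for o in tied if o != q
            )
        ]
        if len(corners) != 1:
            # tie not an L-shape within one face; allow counterpart edges
            corners = [
                q
                for q in tied
                if all(o in adjacency.all_neighbors(q) for o in tied if o != q)
            ]
        if len(corners) == 1:
            return corners[0], "three_way"
        return _fallback_among(scores, adjacency, tied), "three_way"

    # four or more tied
    tie_set = set(tied)
    others = [q for q in QT_IDS if q not in tie_set]
    if not others:
        raise UnresolvableTieError(
            "all eight quadrants share Sp_max; no discriminating neighbour"
        )
    sub_max = max(scores.sp[q] for q in others)
    reference = [q for q in others if scores.sp[q] == sub_max]
    candidates = [
        q for q in tied if any(r in adjacency.all_neighbors(q) for r in reference)
    ]
    if not candidates:
        return _fallback_among(scores, adjacency, tied), "four_plus"
    if len(candidates) > 1:
        # deterministic: most reference neighbours, then lowest quadrant index
        def key(q: str) -> tuple[int, int]:
            hits = sum(r in adjacency.all_neighbors(q) for r in reference)
            return (-hits, QT_IDS.index(q))

        candidates.sort(key=key)
        best = key(candidates[0])
        if key(candidates[1]) == best:
            return _fallback_among(scores, adjacency, tied), "four_plus"
    return candidates[0], "four_plus"


# ---------------------------------------------------------------------------
# Torso -> atria correlation table (defaults ship with the package)


@dataclass(frozen=True)
class CorrelationTable:
    """Torso-quadrant to atrial-quadrant correspondence plus anatomy.

    ``variants`` maps an atrial-position variant name to the per-Qa list
    of anatomical regions; ``qt_to_qa`` gives the torso-to-atria quadrant
    correspondence (identity by default, overridable for patient-specific
    orientations).
    """

    variants: Mapping[str, Mapping[str, tuple[str, ...]]]
    qt_to_qa: Mapping[str, str] = field(
        default_factory=lambda: {f"Qt{i}": f"Qa{i}" for i in range(1, 9)}
    )

    def regions(self, qa: str, variant: str) -> tuple[str, ...]:
        if variant not in self.variants:
            raise MissingVariantError(
                f"variant {variant!r} not in table; have {sorted(self.variants)}"
            )
        return tuple(self.variants[variant][qa])

    def to_dict(self) -> dict:
        return {
            "variants": {
                v: {qa: list(r) for qa, r in d.items()}
                for v, d in self.variants.items()
            },
            "qt_to_qa": dict(self.qt_to_qa),
        }


@dataclass(frozen=True)
class SubQuadrant:
    """Near/far tag along each in-face axis of the winning quadrant."""

    lateral: str  # near | far (relative to the in-face lateral boundary)
    vertical: str  # near | far (relative to the in-face vertical boundary)

    @property
    def tag(self) -> str:
        return f"lateral={self.lateral},vertical={self.vertical}"


@dataclass(frozen=True)
class FocusEstimate:
    """Predicted origin of the atrial ectopic focus."""

    torso_quadrant: str
    atrial_quadrant: str
    regions: tuple[str, ...]
    tie_rule_used: str = "none"
    sub_quadrant: SubQuadrant | None = None

    def to_dict(self) -> dict:
        d = {
            "torso_quadrant": self.torso_quadrant,
            "atrial_quadrant": self.atrial_quadrant,
            "regions": list(self.regions),
            "tie_rule_used": self.tie_rule_used,
        }
        if self.sub_quadrant is not None:
            d["sub_quadrant"] = {
                "lateral": self.sub_quadrant.lateral,
                "vertical": self.sub_quadrant.vertical,
            }
        return d


def map_to_atrial_quadrant(
    qt: str,
    table: CorrelationTable,
    variant: str,
    tie_rule_used: str = "none",
    sub_quadrant: SubQuadrant | None = None,
) -> FocusEstimate:
    """Pure lookup of the atrial quadrant and anatomy behind a torso quadrant."""
    qa = table.qt_to_qa[qt]
    return FocusEstimate(
        torso_quadrant=qt,
        atrial_quadrant=qa,
        regions=table.regions(qa, variant),
        tie_rule_used=tie_rule_used,
        sub_quadrant=sub_quadrant,
    )


#: Sp-difference threshold below which the focus is placed near the shared
#: quadrant boundary.
DEFAULT_REFINE_THRESHOLD = 0.1


def refine_subquadrant(
    scores: QuadrantScores,
    winner: str,
    threshold: float = DEFAULT_REFINE_THRESHOLD,
    adjacency: AdjacencyGraph | None = None,
) -> SubQuadrant:
    """Place the focus in one of the winner's four sub-quadrants.

    For each in-face neighbour of the winning quadrant: if its Sp lies
    within ``threshold`` of Sp_max the focus is near the shared boundary,
    otherwise far from it. The two axes combine into a 2x2 sub-quadrant
    tag.
    """
    adjacency = adjacency or default_adjacency()
    if winner not in scores.argmax_set:
        raise InvalidWinnerError(f"{winner} does not attain Sp_max")
    thr = Fraction(str(threshold))
    sp_max = scores.sp[winner]

    def side(neighbor: str) -> str:
        return "near" if (sp_max - scores.sp[neighbor]) <= thr else "far"

    return SubQuadrant(
        lateral=side(adjacency.lateral_neighbor(winner)),
        vertical=side(adjacency.vertical_neighbor(winner)),
    )
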