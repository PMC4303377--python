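"""Reference implementation of the quadrant decision rules.

A direct, self-contained transcription of the prose rules (single
maximum; two-way tie compared through the remaining in-face neighbours;
three-way corner; four-or-more via the best non-tied neighbour, counting
the front/back counterpart) used only to cross-check the packaged
implementation. It shares no code with it: quadrant geometry is rebuilt
here from index arithmetic.

Quadrant index layout (1-based): 1 anterior superior-right, 2 anterior
superior-left, 3 anterior inferior-right, 4 anterior inferior-left,
5-8 the posterior counterparts in the same order.
"""

from fractions import Fraction


class OracleUnresolvable(Exception):
    pass


def _pos(i):  # 0 sup-right, 1 sup-left, 2 inf-right, 3 inf-left
    return (i - 1) % 4


def _face_base(i):  # 1 for anterior, 5 for posterior
    return 1 if i <= 4 else 5


def in_face_neighbors(i):
    base, p = _face_base(i), _pos(i)
    return (base + (p ^ 1), base + (p ^ 2))  # lateral flip, vertical flip


def counterpart(i):
    return i + 4 if i <= 4 else i - 4


def all_neighbors(i):
    return in_face_neighbors(i) + (counterpart(i),)


def _fallback(sp, tied):
    tie_set = set(tied)
    means = {}
    for q in tied:
        vals = [sp[n] for n in all_neighbors(q) if n not in tie_set]
        means[q] = sum(vals, Fraction(0)) / len(vals) if vals else None
    usable = [m for m in means.values() if m is not None]
    if not usable:
        raise OracleUnresolvable("no non-tied neighbours")
    best = max(usable)
    winners = [q for q in tied if means[q] == best]
    if len(winners) != 1:
        raise OracleUnresolvable("neighbour means tied")
    return winners[0]


def oracle_locate(sp):
    """sp: dict {1..8: Fraction}; returns (winner_index, rule)."""
    sp = {q: Fraction(v) for q, v in sp.items()}
    m = max(sp.values())
    tied = [q for q in range(1, 9) if sp[q] == m]

    if len(tied) == 1:
        return tied[0], "none"

    if len(tied) == 2:
        q1, q2 = tied
        if q2 in in_face_neighbors(q1):
            (n1,) = [n for n in in_face_neighbors(q1) if n != q2]
            (n2,) = [n for n in in_face_neighbors(q2) if n != q1]
            if sp[n1] > sp[n2]:
                return q1, "two_way"
            if sp[n2] > sp[n1]:
                return q2, "two_way"
        return _fallback(sp, tied), "two_way"

    if len(tied) == 3:
        corners = [
            q for q in tied
            if all(o in in_face_neighbors(q) for o in tied if o != q)
        ]
        if len(corners) != 1:
            corners = [
                q for q in tied
                if all(o in all_neighbors(q) for o in tied if o != q)
            ]
        if len(corners) == 1:
            return corners[0], "three_way"
        return _fallback(sp, tied), "three_way"

    others = [q for q in range(1, 9) if q not in tied]
    if not others:
        raise OracleUnresolvable("all eight tied")
    sub_max = max(sp[q] for q in others)
    reference = [q for q in others if sp[q] == sub_max]
    candidates = [
        q for q in tied if any(r in all_neighbors(q) for r in reference)
    ]
    if not candidates:
        return _fallback(sp, tied), "four_plus"
    if len(candidates) > 1:
        def key(q):
            return (-sum(r in all_neighbors(q) for r in reference), q)

        candidates.sort(key=key)
        if key(candidates[0]) == key(candidates[1]):
            return _fallback(sp, tied), "four_plus"
    return candidates[0], "four_plus"
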