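"""P-wave segmentation, peak measurement and polarity classification.

A P-wave is classified per lead from its two extremal deflections relative
to the pre-P isoelectric baseline:

* ``positive``  — positive peak amplitude strictly greater than twice the
  negative peak amplitude;
* ``negative``  — the mirror-image rule;
* ``biphasic``  — the secondary deflection is at least half the primary one
  (the complement of the two rules above, including the exact boundary);
* ``flat``      — both deflections fall below a smallness threshold
  ``flat_eps``; by default 5% of the largest absolute peak seen across all
  leads of the same recording, so the criterion is unit-free.

Bifid (notched) sub-peaks are deliberately ignored: only the global extrema
of the segment enter the classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    EmptyTraceError,
    InvalidMeasurementError,
    InvalidWindowError,
    MissingLeadError,
)

#: Relative flat threshold: fraction of the recording-wide max |peak|.
DEFAULT_FLAT_FRACTION = 0.05

#: Minimum number of samples required inside a baseline window.
MIN_BASELINE_SAMPLES = 5


class PolarityLabel(str, Enum):
    """Polarity class of a single lead's P-wave."""

    POSITIVE = "positive"
    NEGATIVE = "negative"
    BIPHASIC = "biphasic"
    FLAT = "flat"


#: Numeric score entering the per-quadrant mean Sp.
#: Flat leads score like biphasic ones: a flat wave sits in the transition
#: band between the positive and negative regions of the torso.
POLARITY_SCORES: dict[PolarityLabel, int] = {
    PolarityLabel.NEGATIVE: 2,
    PolarityLabel.BIPHASIC: 1,
    PolarityLabel.FLAT: 1,
    PolarityLabel.POSITIVE: 0,
}


@dataclass(frozen=True)
class PWaveTrace:
    """One lead's P-wave segment (time in ms, potential in mV)."""

    lead_id: str
    t: np.ndarray
    v: np.ndarray
    baseline_window: tuple[float, float] | None = None

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        v = np.asarray(self.v, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "v", v)
        if t.ndim != 1 or v.ndim != 1 or len(t) != len(v):
            raise ValueError("t and v must be 1-D arrays of equal length")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("time samples must be strictly increasing")


@dataclass(frozen=True)
class PeakMeasurement:
    """Extremal deflections of a baseline-corrected P-wave.

    Amplitudes are non-negative magnitudes; a monophasic or flat wave has
    one (or both) amplitude equal to zero, with the peak time reported at
    the corresponding extremum sample regardless.
    """

    pos_amp: float
    neg_amp: float
    pos_time: float
    neg_time: float


def baseline_correct(
    trace: PWaveTrace, baseline_window: tuple[float, float] | None = None
) -> PWaveTrace:
    """Subtract the mean potential over ``baseline_window`` from the trace.

    The window is a closed time interval ``(t_start, t_end)`` in ms that
    must contain at least :data:`MIN_BASELINE_SAMPLES` samples of the trace.
    Only a constant offset is removed; the waveform shape is untouched.
    """
    window = baseline_window if baseline_window is not None else trace.baseline_window
    if window is None:
        raise InvalidWindowError("no baseline window given")
    t_start, t_end = float(window[0]), float(window[1])
    if t_end < t_start:
        raise InvalidWindowError(f"empty window ({t_start}, {t_end})")
    mask = (trace.t >= t_start) & (trace.t <= t_end)
    n_in = int(mask.sum())
    if n_in < MIN_BASELINE_SAMPLES:
        raise InvalidWindowError(
            f"baseline window ({t_start}, {t_end}) contains {n_in} samples; "
            f"at least {MIN_BASELINE_SAMPLES} required"
        )
    offset = float(trace.v[mask].mean())
    return PWaveTrace(
        lead_id=trace.lead_id,
        t=trace.t,
        v=trace.v - offset,
        baseline_window=(t_start, t_end),
    )


def measure_peaks(pwave: PWaveTrace) -> PeakMeasurement:
    """Measure the positive and negative extrema of a baseline-corrected trace.

    Ties are broken toward the earliest sample.
    """
    if len(pwave.v) == 0:
        raise EmptyTraceError(f"lead {pwave.lead_id}: empty trace")
    v = pwave.v
    i_pos = int(np.argmax(v))  # argmax returns the first maximum
    i_neg = int(np.argmin(v))
    return PeakMeasurement(
        pos_amp=float(max(v[i_pos], 0.0)),
        neg_amp=float(max(-v[i_neg], 0.0)),
        pos_time=float(pwave.t[i_pos]),
        neg_time=float(pwave.t[i_neg]),
    )


def classify_polarity(peaks: PeakMeasurement, flat_eps: float) -> PolarityLabel:
    """Classify a P-wave from its peak measurement.

    ``positive`` requires ``pos_amp > 2 * neg_amp`` (strict), ``negative``
    the mirror image; everything else non-flat is ``biphasic``, so the exact
    boundary (secondary peak equal to half the primary) is biphasic. The
    three rules partition all non-flat amplitude pairs.
    """
    if peaks.pos_amp < 0 or peaks.neg_amp < 0:
        raise InvalidMeasurementError("peak amplitudes must be non-negative")
    if flat_eps < 0:
        raise InvalidMeasurementError("flat_eps must be non-negative")
    if max(peaks.pos_amp, peaks.neg_amp) < flat_eps:
        return PolarityLabel.FLAT
    if peaks.pos_amp > 2.0 * peaks.neg_amp:
        return PolarityLabel.POSITIVE
    if peaks.neg_amp > 2.0 * peaks.pos_amp:
        return PolarityLabel.NEGATIVE
    return PolarityLabel.BIPHASIC


def polarity_score(label: PolarityLabel) -> int:
    """Numeric value a lead contributes to its quadrant mean Sp."""
    return POLARITY_SCORES[PolarityLabel(label)]


@dataclass(frozen=True)
class PolarityMap:
    """Per-lead polarity labels over one electrode layout."""

    entries: Mapping[str, PolarityLabel]
    layout_ref: str = "default"
    excluded: tuple[str, ...] = field(default_factory=tuple)

    def __getitem__(self, lead_id: str) -> PolarityLabel:
        return self.entries[lead_id]

    @property
    def lead_ids(self) -> list[str]:
        return list(self.entries)

    def to_dict(self) -> dict:
        return {
            "layout_ref": self.layout_ref,
            "entries": {k: v.value for k, v in self.entries.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PolarityMap":
        return cls(
            entries={k: PolarityLabel(v) for k, v in d["entries"].items()},
            layout_ref=d.get("layout_ref", "default"),
        )


def default_flat_eps(peak_list: Iterable[PeakMeasurement]) -> float:
    """Recording-relative flat threshold: 5% of the largest |peak| anywhere."""
    biggest = max(
        (max(p.pos_amp, p.neg_amp) for p in peak_list),
        default=0.0,
    )
    return DEFAULT_FLAT_FRACTION * biggest


def build_polarity_map(
    traces: Sequence[PWaveTrace],
    flat_eps: float | None = None,
    layout_leads: Sequence[str] | None = None,
    layout_ref: str = "default",
) -> PolarityMap:
    """Classify every lead of one recording into a :class:`PolarityMap`.

    ``flat_eps`` may be an absolute threshold in mV; when omitted it
    defaults to 5% of the largest absolute peak across all leads of the
    recording. When ``layout_leads`` is given, the trace set must cover it
    exactly, otherwise a :class:`~atrifocus.errors.MissingLeadError` lists
    the offending ids.
    """
    seen = [tr.lead_id for tr in traces]
    if len(set(seen)) != len(seen):
        dupes = sorted({x for x in seen if seen.count(x) > 1})
        raise MissingLeadError([], extra=dupes)
    if layout_leads is not None:
        missing = set(layout_leads) - set(seen)
        extra = set(seen) - set(layout_leads)
        if missing or extra:
            raise MissingLeadError(missing, extra)
    peaks = {tr.lead_id: measure_peaks(tr) for tr in traces}
    eps = flat_eps if flat_eps is not None else default_flat_eps(peaks.values())
    entries = {lead: classify_polarity(pk, eps) for lead, pk in peaks.items()}
    return PolarityMap(entries=entries, layout_ref=layout_ref)
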