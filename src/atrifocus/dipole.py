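"""Body-surface dipole tracking.

At every time step the body-surface potential field has a maximum
(positive pole) and a minimum (negative pole); their electrode locations
and amplitudes traced over the P-wave describe the evolution of the atrial
dipole as seen on the torso. Poles are resolved at electrode resolution —
no spatial interpolation between electrodes — and exact amplitude ties go
to the lowest lead index for determinism.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import LayoutMismatchError


@dataclass(frozen=True)
class BSPFrame:
    """Body-surface potentials over all layout leads at one instant."""

    t: float
    potentials: Mapping[str, float]


@dataclass(frozen=True)
class DipoleSample:
    """Positive and negative pole of one frame."""

    t: float
    pos_lead: str
    pos_amp: float
    neg_lead: str
    neg_amp: float
    degenerate: bool = False  # all-zero frame: poles carry no information


@dataclass(frozen=True)
class DipoleTrack:
    samples: tuple[DipoleSample, ...]

    def __post_init__(self):
        times = [s.t for s in self.samples]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("sample times must be strictly increasing")


def track_dipole(frames: Sequence[BSPFrame]) -> DipoleTrack:
    """Extract the positive/negative pole from each frame.

    All frames must share one lead set (the layout); the pole lead is the
    argmax/argmin of the frame potentials, lowest lead index on exact ties.
    A frame whose potentials are all zero is flagged degenerate.
    """
    if not frames:
        raise ValueError("need at least one frame")
    lead_order = list(frames[0].potentials)
    lead_set = set(lead_order)
    samples = []
    for fr in frames:
        if set(fr.potentials) != lead_set:
            raise LayoutMismatchError(
                f"frame at t={fr.t} has a different lead set"
            )
        vals = np.array([fr.potentials[l] for l in lead_order], dtype=float)
        i_pos = int(np.argmax(vals))
        i_neg = int(np.argmin(vals))
        samples.append(
            DipoleSample(
                t=fr.t,
                pos_lead=lead_order[i_pos],
                pos_amp=float(vals[i_pos]),
                neg_lead=lead_order[i_neg],
                neg_amp=float(vals[i_neg]),
                degenerate=bool(np.all(vals == 0.0)),
            )
        )
    return DipoleTrack(samples=tuple(samples))


@dataclass(frozen=True)
class DipoleTrajectory:
    """Pole positions (torso-surface coordinates) and amplitudes vs time."""

    t: np.ndarray
    pos_uv: np.ndarray  # (n, 2) lateral/vertical surface coordinates, mm
    neg_uv: np.ndarray
    pos_amp: np.ndarray
    neg_amp: np.ndarray
    pos_leads: tuple[str, ...]
    neg_leads: tuple[str, ...]


def dipole_trajectory_summary(track: DipoleTrack, layout) -> DipoleTrajectory:
    """Project each pole's electrode onto 2-D torso-surface coordinates.

    ``layout`` is an :class:`~atrifocus.simulate.ElectrodeLayout` (anything
    exposing ``surface_coords()``); unknown pole leads raise a
    :class:`~atrifocus.errors.LayoutMismatchError`.
    """
    coords = layout.surface_coords()
    for s in track.samples:
        for lead in (s.pos_lead, s.neg_lead):
            if lead not in coords:
                raise LayoutMismatchError(f"pole lead {lead} not in layout")
    t = np.array([s.t for s in track.samples])
    pos_uv = np.array([coords[s.pos_lead][1:] for s in track.samples], dtype=float)
    neg_uv = np.array([coords[s.neg_lead][1:] for s in track.samples], dtype=float)
    return DipoleTrajectory(
        t=t,
        pos_uv=pos_uv,
        neg_uv=neg_uv,
        pos_amp=np.array([s.pos_amp for s in track.samples]),
        neg_amp=np.array([s.neg_amp for s in track.samples]),
        pos_leads=tuple(s.pos_lead for s in track.samples),
        neg_leads=tuple(s.neg_lead for s in track.samples),
    )


def track_to_dict(track: DipoleTrack) -> dict:
    return {
        "samples": [
            {
                "t": s.t,
                "pos_lead": s.pos_lead,
                "pos_amp": s.pos_amp,
                "neg_lead": s.neg_lead,
                "neg_amp": s.neg_amp,
                "degenerate": s.degenerate,
            }
            for s in track.samples
        ]
    }
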