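"""Simplified atria-torso forward model for synthetic 64-lead P-waves.

The generator replaces a biophysically detailed monodomain-plus-boundary-
element chain with a transparent equivalent-source model whose polarity
patterns — the only feature the location algorithm consumes — behave like
the full problem:

1. the atrial surface is a watertight triangulated ellipsoid partitioned
   into eight anatomical octants (Qa1-Qa8);
2. focal activation spreads from the stimulus site at a uniform conduction
   velocity; activation times are on-surface geodesic distances (shortest
   paths over the mesh edge graph) divided by that velocity;
3. each triangle emits a current dipole directed along the local
   propagation direction, scaled by its area, with a raised-cosine
   time-course triggered at its activation time;
4. body-surface potentials are the superposition of those dipole
   potentials in an infinite homogeneous conductor,
   ``phi = m . r / (4 pi sigma |r|^3)`` — torso inhomogeneities change
   P-wave amplitudes, not polarity patterns, so a homogeneous medium
   preserves what the algorithm reads;
5. 64 unipolar leads are derived against Wilson's Central Terminal (the
   mean potential of three limb electrodes), and a three-stimulus pacing
   train at a chosen cycle length yields the analysed final-beat P-wave.

Body coordinates: x toward the patient's left, y anterior, z superior,
origin at the atrial centroid; distances mm, times ms, potentials mV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial.transform import Rotation

from .dipole import BSPFrame
from .errors import (
    ConfigurationError,
    InvalidGeometryError,
    SingularGeometryError,
    UnreachableVertexError,
)
from .pwave import PWaveTrace, baseline_correct

# --------------------------------------------------------------------------
# Defaults (the study conditions of the synthetic experiments)

#: Atrial ellipsoid semi-axes, mm (lateral, antero-posterior, vertical).
DEFAULT_SEMI_AXES = (45.0, 35.0, 40.0)
#: Icosphere refinement level (3 -> 642 vertices, 1280 triangles).
DEFAULT_SUBDIVISIONS = 3
#: Conduction velocity, mm/ms.
DEFAULT_CV = 0.7
#: Fractional CV reduction at fast pacing (cycle length < 500 ms).
DEFAULT_FAST_CV_SCALE = 0.9
#: Torso conductivity (model units).
DEFAULT_SIGMA = 0.2
#: Source time-course duration, ms (order of the atrial upstroke).
DEFAULT_WAVE_DURATION = 20.0
#: Dipole moment surface density scale; calibrated once so that peak
#: unipolar lead amplitudes land near 0.1 mV, a physiological P-wave.
DEFAULT_SOURCE_STRENGTH = 3.0
#: Torso cylinder radius for the default electrode grids, mm.
DEFAULT_TORSO_RADIUS = 140.0
#: Sampling step of synthetic traces, ms.
DEFAULT_DT = 1.0

# Fixed generic-position rotation applied to the unit icosphere before
# scaling: no mesh vertex then lies exactly on an octant boundary plane.
_GENERIC_ROTATION = Rotation.from_rotvec(
    0.31 * np.array([1.0, 2.0, 3.0]) / np.sqrt(14.0)
).as_matrix()


def _octant_ids(local_xyz: np.ndarray) -> np.ndarray:
    """Qa octant of each point from the signs of its local coordinates.

    Qa1 anterior superior-right, Qa2 anterior superior-left, Qa3 anterior
    inferior-right, Qa4 anterior inferior-left; Qa5-Qa8 posterior in the
    same order. Points exactly on a boundary go to the anterior / superior
    / right side.
    """
    x, y, z = local_xyz[:, 0], local_xyz[:, 1], local_xyz[:, 2]
    idx = (
        1
        + (x > 0).astype(int)  # left adds 1
        + 2 * (z < 0).astype(int)  # inferior adds 2
        + 4 * (y < 0).astype(int)  # posterior adds 4
    )
    return np.array([f"Qa{i}" for i in idx])


@dataclass(frozen=True)
class AtrialSurface:
    """Triangulated closed atrial surface with its octant partition.

    ``vertices`` are world coordinates (after the position-variant
    transform); ``local_vertices`` are body-frame coordinates in which the
    octant partition is defined, so the partition rotates rigidly with the
    anatomy.
    """

    vertices: np.ndarray  # (n, 3) mm, world frame
    faces: np.ndarray  # (m, 3) int
    local_vertices: np.ndarray  # (n, 3) mm, pre-transform frame
    octant: np.ndarray  # (n,) Qa ids per vertex
    transform: np.ndarray  # (3, 3) rotation, local -> world

    @property
    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    @property
    def mesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )

    def octant_vertices(self, qa: str) -> np.ndarray:
        return np.flatnonzero(self.octant == qa)

    def octant_centroid_vertex(self, qa: str) -> int:
        """Vertex closest to the mean position of its octant's vertices."""
        idx = self.octant_vertices(qa)
        if len(idx) == 0:
            raise InvalidGeometryError(f"octant {qa} is empty")
        center = self.local_vertices[idx].mean(axis=0)
        d = np.linalg.norm(self.local_vertices[idx] - center, axis=1)
        return int(idx[np.argmin(d)])

    def nearest_vertex(self, point: Sequence[float]) -> int:
        d = np.linalg.norm(self.vertices - np.asarray(point, float), axis=1)
        return int(np.argmin(d))


def build_atrial_surface(
    semi_axes: Sequence[float] = DEFAULT_SEMI_AXES,
    subdivisions: int = DEFAULT_SUBDIVISIONS,
    transform: np.ndarray | None = None,
) -> AtrialSurface:
    """Build the ellipsoidal atrial stand-in surface.

    ``transform`` is an optional 3x3 rotation (the atrial position
    variant) applied after scaling; the octant partition is defined in the
    pre-transform frame and therefore rotates with the mesh.
    """
    semi_axes = np.asarray(semi_axes, dtype=float)
    if semi_axes.shape != (3,) or np.any(semi_axes <= 0):
        raise InvalidGeometryError(f"semi-axes must be 3 positive values, got {semi_axes}")
    base = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    if len(base.faces) < 200:
        raise InvalidGeometryError(
            f"mesh density too low ({len(base.faces)} triangles; need >= 200)"
        )
    unit = base.vertices @ _GENERIC_ROTATION.T
    local = unit * semi_axes[None, :]
    R = np.eye(3) if transform is None else np.asarray(transform, dtype=float)
    if R.shape != (3, 3):
        raise InvalidGeometryError("transform must be a 3x3 rotation matrix")
    world = local @ R.T
    return AtrialSurface(
        vertices=world,
        faces=np.asarray(base.faces),
        local_vertices=local,
        octant=_octant_ids(local),
        transform=R,
    )


def position_variant_rotation(angle_deg: float = 30.0) -> np.ndarray:
    """Rigid rotation emulating an alternative atrial orientation.

    Rotation about the body x-axis (patient's left-right axis), the main
    axis along which reported atrial orientations differ between the
    textbook position and segmented anatomies.
    """
    return Rotation.from_euler("x", angle_deg, degrees=True).as_matrix()


# --------------------------------------------------------------------------
# Activation


@dataclass(frozen=True)
class ActivationMap:
    """Per-vertex activation time (ms) of a single beat; 0 at the focus."""

    times: np.ndarray
    focus_vertex: int
    cv: float


def _unfolded_diagonals(mesh: trimesh.Trimesh) -> tuple[np.ndarray, np.ndarray]:
    """Extra graph edges across each pair of adjacent triangles.

    For every interior mesh edge the two opposite triangle vertices are
    connected with the straight-line length measured after unfolding the
    two triangles into a common plane, provided that straight segment
    actually crosses the shared edge. This shrinks the metric distortion
    of plain edge-graph shortest paths well below the mesh edge length.
    """
    V = mesh.vertices
    shared = mesh.face_adjacency_edges  # (k, 2) vertex ids of shared edges
    opposite = mesh.face_adjacency_unshared  # (k, 2) opposite vertex ids
    u, v = V[shared[:, 0]], V[shared[:, 1]]
    w1, w2 = V[opposite[:, 0]], V[opposite[:, 1]]
    L = np.linalg.norm(v - u, axis=1)
    ok = L > 1e-12

    def planar(w):
        a2 = np.einsum("ij,ij->i", w - u, w - u)
        b2 = np.einsum("ij,ij->i", w - v, w - v)
        x = (a2 - b2 + L**2) / (2.0 * np.where(ok, L, 1.0))
        y = np.sqrt(np.maximum(a2 - x**2, 0.0))
        return x, y

    x1, y1 = planar(w1)
    x2, y2 = planar(w2)
    # w2 unfolds to the other side of the shared edge: y -> -y2
    lengths = np.hypot(x1 - x2, y1 + y2)
    denom = y1 + y2
    cross = x1 + y1 * (x2 - x1) / np.where(denom > 1e-12, denom, 1.0)
    valid = ok & (denom > 1e-12) & (cross >= 0.0) & (cross <= L)
    return opposite[valid], lengths[valid]


def compute_activation(
    surface: AtrialSurface, focus_vertex: int, cv: float = DEFAULT_CV
) -> ActivationMap:
    """Geodesic activation: graph shortest-path distance / velocity.

    The graph holds the mesh edges plus unfolded-diagonal shortcuts across
    adjacent triangle pairs, keeping the discrete geodesics within a few
    percent of the smooth-surface ones at the default mesh density.
    """
    if cv <= 0:
        raise InvalidGeometryError(f"conduction velocity must be > 0, got {cv}")
    n = len(surface.vertices)
    if not (0 <= focus_vertex < n):
        raise InvalidGeometryError(f"focus vertex {focus_vertex} out of range")
    mesh = surface.mesh
    edges = mesh.edges_unique
    lengths = np.linalg.norm(
        surface.vertices[edges[:, 0]] - surface.vertices[edges[:, 1]], axis=1
    )
    diag_edges, diag_lengths = _unfolded_diagonals(mesh)
    if len(diag_edges):
        edges = np.vstack([edges, diag_edges])
        lengths = np.concatenate([lengths, diag_lengths])
    rows = np.concatenate([edges[:, 0], edges[:, 1]])
    cols = np.concatenate([edges[:, 1], edges[:, 0]])
    data = np.concatenate([lengths, lengths])
    graph = coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    dist = dijkstra(graph, directed=False, indices=focus_vertex)
    if not np.all(np.isfinite(dist)):
        raise UnreachableVertexError(
            f"{int(np.sum(~np.isfinite(dist)))} vertices unreachable from focus"
        )
    return ActivationMap(times=dist / cv, focus_vertex=focus_vertex, cv=cv)


# --------------------------------------------------------------------------
# Equivalent dipole sources


def raised_cosine(duration: float = DEFAULT_WAVE_DURATION) -> Callable:
    """Unit raised-cosine pulse supported on [0, duration] ms."""
    if duration <= 0:
        raise InvalidGeometryError("waveform duration must be > 0")

    def w(tau):
        tau = np.asarray(tau, dtype=float)
        inside = (tau >= 0) & (tau <= duration)
        out = np.zeros_like(tau)
        out[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * tau[inside] / duration))
        return out

    w.duration = duration
    return w


@dataclass(frozen=True)
class DipoleSourceField:
    """Per-triangle dipole sources of one activation sequence."""

    positions: np.ndarray  # (m, 3) triangle centroids, mm
    directions: np.ndarray  # (m, 3) unit propagation directions
    areas: np.ndarray  # (m,) mm^2
    t_act: np.ndarray  # (m,) activation times, ms
    waveform: Callable  # unit time-course, supported on [0, duration]
    strength: float = DEFAULT_SOURCE_STRENGTH

    def moments(self, times: np.ndarray, offsets: Sequence[float] = (0.0,)) -> np.ndarray:
        """Scalar moment magnitude per (triangle, time), summed over beats."""
        times = np.asarray(times, dtype=float)
        w_sum = np.zeros((len(self.t_act), len(times)))
        for off in offsets:
            w_sum += self.waveform(times[None, :] - self.t_act[:, None] - off)
        return (self.strength * self.areas)[:, None] * w_sum


def assemble_sources(
    surface: AtrialSurface,
    activation: ActivationMap,
    waveform: Callable | None = None,
    strength: float = DEFAULT_SOURCE_STRENGTH,
) -> DipoleSourceField:
    """Per-triangle dipoles along the activation-time gradient.

    Each triangle carries a dipole of magnitude ``area * waveform(t -
    t_act)`` pointing along the in-plane gradient of the activation time
    (the propagation direction). Triangles with zero area or an
    ill-defined gradient (at the focus or at symmetric collision points)
    are emitted with zero moment and a warning for the former.
    """
    waveform = waveform or raised_cosine()
    V, F = surface.vertices, surface.faces
    p0, p1, p2 = V[F[:, 0]], V[F[:, 1]], V[F[:, 2]]
    e1, e2 = p1 - p0, p2 - p0
    cross = np.cross(e1, e2)
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    zero_area = areas <= 1e-12
    if np.any(zero_area):
        warnings.warn(
            f"skipping {int(zero_area.sum())} zero-area triangles", stacklevel=2
        )
    u = activation.times
    d1 = u[F[:, 1]] - u[F[:, 0]]
    d2 = u[F[:, 2]] - u[F[:, 0]]
    a = np.einsum("ij,ij->i", e1, e1)
    b = np.einsum("ij,ij->i", e1, e2)
    c = np.einsum("ij,ij->i", e2, e2)
    det = a * c - b * b
    safe = (~zero_area) & (det > 1e-12)
    coef1 = np.where(safe, (d1 * c - d2 * b) / np.where(safe, det, 1.0), 0.0)
    coef2 = np.where(safe, (d2 * a - d1 * b) / np.where(safe, det, 1.0), 0.0)
    grad = coef1[:, None] * e1 + coef2[:, None] * e2
    norm = np.linalg.norm(grad, axis=1)
    ok = norm > 1e-9
    directions = np.zeros_like(grad)
    directions[ok] = grad[ok] / norm[ok, None]
    t_act = u[F].mean(axis=1)
    return DipoleSourceField(
        positions=(p0 + p1 + p2) / 3.0,
        directions=directions,
        areas=np.where(zero_area, 0.0, areas),
        t_act=t_act,
        waveform=waveform,
        strength=strength,
    )


# --------------------------------------------------------------------------
# Electrode layout


@dataclass(frozen=True)
class ElectrodeLayout:
    """Torso electrode positions, face tags and the WCT limb electrodes."""

    positions: Mapping[str, np.ndarray]  # lead -> (3,) mm
    faces: Mapping[str, str]  # lead -> anterior | posterior
    wct_positions: np.ndarray  # (3, 3) mm
    name: str = "default"

    def __post_init__(self):
        wct = np.asarray(self.wct_positions, dtype=float)
        object.__setattr__(self, "wct_positions", wct)
        if wct.shape != (3, 3):
            raise ConfigurationError("exactly 3 WCT limb positions required")
        for lead in self.positions:
            if self.faces.get(lead) not in ("anterior", "posterior"):
                raise ConfigurationError(f"lead {lead}: missing/invalid face tag")

    @property
    def lead_ids(self) -> list[str]:
        return list(self.positions)

    def position_array(self, leads: Sequence[str] | None = None) -> np.ndarray:
        leads = leads if leads is not None else self.lead_ids
        return np.array([self.positions[l] for l in leads], dtype=float)

    def surface_coords(self) -> dict[str, tuple[str, float, float]]:
        """Per-lead (face, lateral, vertical) torso-surface coordinates.

        The lateral coordinate is the body x-coordinate (mm, positive
        toward the patient's left) and the vertical one the z-coordinate;
        with the face tag this identifies the electrode's quadrant.
        """
        return {
            l: (self.faces[l], float(p[0]), float(p[2]))
            for l, p in self.positions.items()
        }


def default_layout(
    radius: float = DEFAULT_TORSO_RADIUS,
    n_cols: int = 8,
    n_rows: int = 4,
    z_extent: float = 105.0,
    max_angle_deg: float = 70.0,
) -> ElectrodeLayout:
    """Two n_rows x n_cols unipolar grids on a cylindrical torso.

    32 anterior (A01-A32) and 32 posterior (P01-P32) electrodes by
    default, vertically centred on the atrial centroid, plus three distant
    limb electrodes for Wilson's Central Terminal. Columns run from the
    patient's right to left, rows from superior to inferior.
    """
    angles = np.deg2rad(np.linspace(-max_angle_deg, max_angle_deg, n_cols))
    zs = np.linspace(z_extent, -z_extent, n_rows)
    positions: dict[str, np.ndarray] = {}
    faces: dict[str, str] = {}
    for face, prefix, ysign in (("anterior", "A", 1.0), ("posterior", "P", -1.0)):
        k = 0
        for z in zs:
            for th in angles:
                k += 1
                lead = f"{prefix}{k:02d}"
                positions[lead] = np.array(
                    [radius * np.sin(th), ysign * radius * np.cos(th), z]
                )
                faces[lead] = face
    wct = np.array(
        [
            [-250.0, 0.0, 250.0],  # right arm
            [250.0, 0.0, 250.0],  # left arm
            [100.0, 0.0, -700.0],  # left leg
        ]
    )
    return ElectrodeLayout(positions=positions, faces=faces, wct_positions=wct)


# --------------------------------------------------------------------------
# Potentials and unipolar leads

#: Reserved channel ids carrying the WCT limb-electrode potentials.
WCT_CHANNELS = ("WCT1", "WCT2", "WCT3")


def compute_potentials(
    sources: DipoleSourceField,
    points: np.ndarray,
    sigma: float,
    times: np.ndarray,
    beat_offsets: Sequence[float] = (0.0,),
) -> np.ndarray:
    """Infinite homogeneous-medium dipole potentials at arbitrary points.

    ``phi[e, t] = sum_i m_i(t) d_i . (r_e - r_i) / (4 pi sigma |r_e - r_i|^3)``.
    """
    if sigma <= 0:
        raise ConfigurationError(f"sigma must be > 0, got {sigma}")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    diff = points[:, None, :] - sources.positions[None, :, :]  # (e, i, 3)
    dist = np.linalg.norm(diff, axis=2)
    if np.any(dist < 1e-9):
        raise SingularGeometryError("electrode coincides with a source position")
    geom = np.einsum("eij,ij->ei", diff, sources.directions) / (
        4.0 * np.pi * sigma * dist**3
    )
    return geom @ sources.moments(times, beat_offsets)


def compute_bsp(
    sources: DipoleSourceField,
    layout: ElectrodeLayout,
    sigma: float = DEFAULT_SIGMA,
    times: np.ndarray | None = None,
    beat_offsets: Sequence[float] = (0.0,),
    include_wct: bool = True,
) -> list[BSPFrame]:
    """Body-surface potential frames at the layout electrodes.

    When ``include_wct`` is set (default) the frames carry three extra
    channels, :data:`WCT_CHANNELS`, holding the limb-electrode potentials
    needed to derive unipolar leads.
    """
    if times is None:
        t_end = sources.t_act.max() + sources.waveform.duration
        times = np.arange(0.0, t_end + DEFAULT_DT, DEFAULT_DT)
    leads = layout.lead_ids
    pts = layout.position_array(leads)
    if include_wct:
        pts = np.vstack([pts, layout.wct_positions])
    phi = compute_potentials(sources, pts, sigma, times, beat_offsets)
    channels = leads + (list(WCT_CHANNELS) if include_wct else [])
    return [
        BSPFrame(t=float(t), potentials=dict(zip(channels, phi[:, j])))
        for j, t in enumerate(times)
    ]


def derive_unipolar_leads(
    frames: Sequence[BSPFrame], layout: ElectrodeLayout
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Reference every electrode against Wilson's Central Terminal.

    ``lead(t) = phi_electrode(t) - mean(phi at the three limb electrodes)``.
    Returns the time axis and one referenced trace per layout lead. The
    frames must carry the :data:`WCT_CHANNELS` potentials.
    """
    if not frames:
        raise ConfigurationError("no frames given")
    if any(ch not in frames[0].potentials for ch in WCT_CHANNELS):
        raise ConfigurationError(
            "frames lack the WCT limb-electrode channels; re-run compute_bsp "
            "with include_wct=True"
        )
    times = np.array([fr.t for fr in frames])
    wct = np.array(
        [[fr.potentials[ch] for ch in WCT_CHANNELS] for fr in frames]
    ).mean(axis=1)
    traces = {
        lead: np.array([fr.potentials[lead] for fr in frames]) - wct
        for lead in layout.lead_ids
    }
    return times, traces


def unipolar_frames(
    times: np.ndarray, traces: Mapping[str, np.ndarray]
) -> list[BSPFrame]:
    """Re-package unipolar lead traces as per-instant frames."""
    leads = list(traces)
    return [
        BSPFrame(t=float(t), potentials={l: float(traces[l][j]) for l in leads})
        for j, t in enumerate(times)
    ]


# --------------------------------------------------------------------------
# Pacing protocol


@dataclass(frozen=True)
class FocusSpec:
    """Ectopic stimulus site and pacing protocol."""

    focus_vertex: int
    cycle_length: float  # ms
    n_stimuli: int = 3
    true_quadrant: str | None = None  # Qa octant of the focus

    def __post_init__(self):
        if self.cycle_length <= 0:
            raise ConfigurationError("cycle_length must be > 0")
        if self.n_stimuli < 1:
            raise ConfigurationError("n_stimuli must be >= 1")


@dataclass(frozen=True)
class SimulationResult:
    """Synthetic final-beat P-wave of one paced ectopic focus."""

    times: np.ndarray  # ms, window around the final beat
    traces: dict[str, np.ndarray]  # unipolar leads, mV (noise included)
    frames: list  # unipolar BSPFrames of the same window
    focus: FocusSpec
    focus_position: np.ndarray  # world mm
    baseline_window: tuple[float, float]
    seed: int | None
    noise_sd: float  # absolute sd actually applied, mV
    config: dict = field(default_factory=dict)

    def pwave_traces(self) -> list[PWaveTrace]:
        """Baseline-corrected per-lead P-wave segments."""
        return [
            baseline_correct(
                PWaveTrace(
                    lead_id=lead,
                    t=self.times,
                    v=v,
                    baseline_window=self.baseline_window,
                )
            )
            for lead, v in self.traces.items()
        ]


def effective_cv(
    cv: float,
    cycle_length: float,
    fast_cv_scale: float = DEFAULT_FAST_CV_SCALE,
    fast_threshold: float = 500.0,
) -> float:
    """Conduction velocity with rate-dependent slowing at short cycle lengths."""
    return cv * fast_cv_scale if cycle_length < fast_threshold else cv


def simulate_pacing(
    surface: AtrialSurface,
    focus: FocusSpec,
    layout: ElectrodeLayout,
    cv: float = DEFAULT_CV,
    sigma: float = DEFAULT_SIGMA,
    noise_sd: float = 0.0,
    seed: int | None = None,
    wave_duration: float = DEFAULT_WAVE_DURATION,
    strength: float = DEFAULT_SOURCE_STRENGTH,
    dt: float = DEFAULT_DT,
    fast_cv_scale: float = DEFAULT_FAST_CV_SCALE,
    baseline_ms: float = 20.0,
) -> SimulationResult:
    """Run a pacing train and return the final beat's unipolar P-waves.

    ``noise_sd`` is the additive white Gaussian noise standard deviation
    expressed as a fraction of the recording's clean peak amplitude; it is
    reproducible from ``seed``. The final of ``n_stimuli`` beats is
    returned, preceded by ``baseline_ms`` of pre-P baseline.
    """
    cv_eff = effective_cv(cv, focus.cycle_length, fast_cv_scale)
    activation = compute_activation(surface, focus.focus_vertex, cv_eff)
    waveform = raised_cosine(wave_duration)
    sources = assemble_sources(surface, activation, waveform, strength)

    t_act_max = float(activation.times.max())
    if focus.cycle_length < t_act_max + wave_duration:
        warnings.warn(
            "cycle length shorter than the beat duration: successive beats "
            "superpose",
            stacklevel=2,
        )
    beat_offsets = [k * focus.cycle_length for k in range(focus.n_stimuli)]
    final = beat_offsets[-1]
    times = np.arange(
        final - baseline_ms, final + t_act_max + wave_duration + 10.0 + dt / 2, dt
    )
    frames = compute_bsp(sources, layout, sigma, times, beat_offsets)
    t_axis, traces = derive_unipolar_leads(frames, layout)

    peak = max(np.abs(v).max() for v in traces.values())
    sd_abs = noise_sd * peak
    if sd_abs > 0:
        rng = np.random.default_rng(seed)
        for lead in traces:
            traces[lead] = traces[lead] + rng.normal(0.0, sd_abs, size=len(t_axis))

    true_q = focus.true_quadrant or str(surface.octant[focus.focus_vertex])
    focus_full = FocusSpec(
        focus_vertex=focus.focus_vertex,
        cycle_length=focus.cycle_length,
        n_stimuli=focus.n_stimuli,
        true_quadrant=true_q,
    )
    return SimulationResult(
        times=t_axis,
        traces=traces,
        frames=unipolar_frames(t_axis, traces),
        focus=focus_full,
        focus_position=surface.vertices[focus.focus_vertex].copy(),
        baseline_window=(float(times[0]), float(final - dt)),
        seed=seed,
        noise_sd=sd_abs,
        config={
            "cv": cv,
            "cv_effective": cv_eff,
            "sigma": sigma,
            "noise_sd_fraction": noise_sd,
            "wave_duration": wave_duration,
            "strength": strength,
            "dt": dt,
            "cycle_length": focus.cycle_length,
            "n_stimuli": focus.n_stimuli,
        },
    )
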