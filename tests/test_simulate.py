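import warnings

import numpy as np
import pytest

from atrifocus import (
    BSPFrame,
    DipoleSourceField,
    FocusSpec,
    assemble_sources,
    build_atrial_surface,
    compute_activation,
    compute_bsp,
    derive_unipolar_leads,
    position_variant_rotation,
    raised_cosine,
    simulate_pacing,
)
from atrifocus.errors import (
    ConfigurationError,
    InvalidGeometryError,
    SingularGeometryError,
)
from atrifocus.simulate import AtrialSurface, WCT_CHANNELS, compute_potentials


def unit_dipole(direction=(1.0, 0.0, 0.0), t_act=0.0):
    return DipoleSourceField(
        positions=np.zeros((1, 3)),
        directions=np.array([direction], dtype=float),
        areas=np.ones(1),
        t_act=np.array([t_act]),
        waveform=raised_cosine(20.0),
        strength=1.0,
    )


class TestSurface:
    def test_sphere_octants_are_balanced(self):
        surf = build_atrial_surface(semi_axes=(30.0, 30.0, 30.0))
        counts = np.array(
            [len(surf.octant_vertices(f"Qa{i}")) for i in range(1, 9)]
        )
        mean = len(surf.vertices) / 8
        assert np.all(np.abs(counts - mean) <= 0.05 * mean)

    def test_watertight(self, surface):
        assert surface.mesh.is_watertight

    def test_variant_rotation_moves_vertices_with_octants(self, surface):
        R = position_variant_rotation(30.0)
        rotated = build_atrial_surface(transform=R)
        # octant labels are anatomical: they rotate rigidly with the mesh
        assert np.array_equal(rotated.octant, surface.octant)
        assert np.allclose(rotated.vertices, surface.vertices @ R.T)

    def test_zero_semi_axis_rejected(self):
        with pytest.raises(InvalidGeometryError):
            build_atrial_surface(semi_axes=(0.0, 30.0, 30.0))


class TestActivation:
    def test_focus_activates_at_time_zero(self, surface):
        act = compute_activation(surface, 5, cv=0.7)
        assert act.times[5] == 0.0
        assert np.all(act.times >= 0.0)

    def test_sphere_antipode_matches_great_circle(self):
        surf = build_atrial_surface(semi_axes=(30.0, 30.0, 30.0))
        act = compute_activation(surf, 0, cv=0.7)
        anti = surf.nearest_vertex(-surf.vertices[0])
        expect = np.pi * 30.0 / 0.7
        assert abs(act.times[anti] - expect) <= 0.05 * expect

    def test_doubling_cv_halves_times(self, surface):
        a = compute_activation(surface, 0, cv=0.7)
        b = compute_activation(surface, 0, cv=1.4)
        assert np.allclose(b.times, a.times / 2.0)

    def test_invalid_cv_rejected(self, surface):
        with pytest.raises(InvalidGeometryError):
            compute_activation(surface, 0, cv=0.0)


class TestSources:
    def test_silent_before_earliest_activation(self, surface):
        act = compute_activation(surface, 0)
        sources = assemble_sources(surface, act)
        m = sources.moments(np.array([-1.0, -0.01]))
        assert np.all(m == 0.0)

    def test_time_translation_equivariance(self, surface):
        act = compute_activation(surface, 0)
        s0 = assemble_sources(surface, act)
        shifted = type(act)(times=act.times + 40.0, focus_vertex=0, cv=act.cv)
        s1 = assemble_sources(surface, shifted)
        t = np.linspace(0.0, 300.0, 61)
        assert np.allclose(s1.moments(t + 40.0), s0.moments(t))

    def test_planar_wavefront_gives_parallel_moments(self):
        # flat strip in the xy-plane, activation sweeping along +x
        xs, ys = np.meshgrid(np.arange(5.0), np.arange(3.0))
        verts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(xs.size)])
        faces = []
        for r in range(2):
            for c in range(4):
                a = r * 5 + c
                faces.append([a, a + 1, a + 5])
                faces.append([a + 1, a + 6, a + 5])
        surf = AtrialSurface(
            vertices=verts,
            faces=np.array(faces),
            local_vertices=verts,
            octant=np.array(["Qa1"] * len(verts)),
            transform=np.eye(3),
        )
        from atrifocus.simulate import ActivationMap

        act = ActivationMap(times=verts[:, 0] / 0.7, focus_vertex=0, cv=0.7)
        sources = assemble_sources(surf, act)
        assert np.allclose(sources.directions, [1.0, 0.0, 0.0], atol=1e-9)


class TestPotentials:
    def test_single_dipole_closed_form(self):
        # peak of the raised cosine: unit moment along +x
        phi = compute_potentials(
            unit_dipole(), np.array([[100.0, 0.0, 0.0]]), 0.2, np.array([10.0])
        )
        expect = 1.0 / (4.0 * np.pi * 0.2 * 100.0**2)
        assert phi[0, 0] == pytest.approx(expect, rel=1e-10)

    def test_equatorial_plane_is_silent(self):
        phi = compute_potentials(
            unit_dipole(), np.array([[0.0, 100.0, 0.0]]), 0.2, np.array([10.0])
        )
        assert phi[0, 0] == 0.0

    def test_linearity_in_moments(self, surface, layout):
        act = compute_activation(surface, 0)
        s1 = assemble_sources(surface, act, strength=1.0)
        s2 = assemble_sources(surface, act, strength=2.0)
        t = np.array([30.0, 60.0])
        pts = layout.position_array()[:5]
        assert np.allclose(
            compute_potentials(s2, pts, 0.2, t),
            2.0 * compute_potentials(s1, pts, 0.2, t),
        )

    def test_far_field_decays_as_inverse_square(self):
        dists = np.array([200.0, 400.0, 800.0])
        phis = [
            compute_potentials(
                unit_dipole(), np.array([[d, 0.0, 0.0]]), 0.2, np.array([10.0])
            )[0, 0]
            for d in dists
        ]
        assert phis[0] / phis[1] == pytest.approx(4.0, rel=1e-9)
        assert phis[1] / phis[2] == pytest.approx(4.0, rel=1e-9)

    def test_electrode_on_source_rejected(self):
        with pytest.raises(SingularGeometryError):
            compute_potentials(
                unit_dipole(), np.zeros((1, 3)), 0.2, np.array([10.0])
            )


class TestUnipolarLeads:
    def test_uniform_field_cancels(self, layout):
        channels = layout.lead_ids + list(WCT_CHANNELS)
        frames = [BSPFrame(t=0.0, potentials={c: 0.7 for c in channels})]
        _, traces = derive_unipolar_leads(frames, layout)
        assert all(np.allclose(v, 0.0) for v in traces.values())

    def test_reference_invariance_under_offsets(self, surface, layout):
        act = compute_activation(surface, 0)
        sources = assemble_sources(surface, act)
        t = np.arange(0.0, 120.0, 10.0)
        frames = compute_bsp(sources, layout, times=t)
        shifted = [
            BSPFrame(t=fr.t, potentials={k: v + 5.0 for k, v in fr.potentials.items()})
            for fr in frames
        ]
        _, a = derive_unipolar_leads(frames, layout)
        _, b = derive_unipolar_leads(shifted, layout)
        for lead in a:
            assert np.allclose(a[lead], b[lead])

    def test_two_frame_arithmetic(self, layout):
        lead0 = layout.lead_ids[0]
        channels = layout.lead_ids + list(WCT_CHANNELS)
        def mk(t, v_lead, wct):
            pots = {c: 0.0 for c in channels}
            pots[lead0] = v_lead
            for c, w in zip(WCT_CHANNELS, wct):
                pots[c] = w
            return BSPFrame(t=t, potentials=pots)
        frames = [mk(0.0, 1.0, (0.3, 0.6, 0.0)), mk(1.0, -0.5, (0.1, 0.1, 0.1))]
        _, traces = derive_unipolar_leads(frames, layout)
        assert traces[lead0] == pytest.approx([1.0 - 0.3, -0.5 - 0.1])

    def test_missing_wct_channels_rejected(self, layout):
        frames = [BSPFrame(t=0.0, potentials={l: 0.0 for l in layout.lead_ids})]
        with pytest.raises(ConfigurationError):
            derive_unipolar_leads(frames, layout)


class TestPacing:
    def test_zero_noise_is_seed_independent(self, surface, layout):
        spec = FocusSpec(focus_vertex=10, cycle_length=700.0)
        a = simulate_pacing(surface, spec, layout, seed=1)
        b = simulate_pacing(surface, spec, layout, seed=999)
        for lead in a.traces:
            assert np.array_equal(a.traces[lead], b.traces[lead])

    def test_noise_reproducible_from_seed(self, surface, layout):
        spec = FocusSpec(focus_vertex=10, cycle_length=700.0)
        a = simulate_pacing(surface, spec, layout, noise_sd=0.05, seed=42)
        b = simulate_pacing(surface, spec, layout, noise_sd=0.05, seed=42)
        c = simulate_pacing(surface, spec, layout, noise_sd=0.05, seed=43)
        assert all(np.array_equal(a.traces[l], b.traces[l]) for l in a.traces)
        assert any(not np.array_equal(a.traces[l], c.traces[l]) for l in a.traces)

    def test_ground_truth_quadrant_recorded(self, surface, layout):
        sim = simulate_pacing(
            surface, FocusSpec(focus_vertex=10, cycle_length=700.0), layout
        )
        assert sim.focus.true_quadrant == surface.octant[10]

    def test_short_cycle_length_warns_of_overlap(self, surface, layout):
        spec = FocusSpec(focus_vertex=10, cycle_length=50.0)
        with pytest.warns(UserWarning, match="superpose"):
            simulate_pacing(surface, spec, layout)

    def test_final_beat_window_covers_the_pwave(self, surface, layout):
        sim = simulate_pacing(
            surface, FocusSpec(focus_vertex=10, cycle_length=700.0), layout
        )
        assert sim.times[0] < 1400.0 <= sim.times[-1]
        peak = max(np.abs(v).max() for v in sim.traces.values())
        assert 0.01 < peak < 1.0  # physiological P-wave scale, mV
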