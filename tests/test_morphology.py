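import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cldend import (
    CANONICAL_SPINE,
    SpineGeometry,
    attach_spines,
    build_cylinder,
    implicit_spine_factors,
    make_stimulus,
    matched_diameter,
)


class TestBuildCylinder:
    def test_standard_discretization(self):
        m = build_cylinder(700.0, 1.0, 1.0)
        assert m.n == 700
        assert np.allclose(m.volumes(), math.pi / 4)
        assert m.shaft_length == pytest.approx(700.0)
        # chain topology, sealed ends: exactly n-1 edges
        assert len(m.edges) == 699
        m.validate()

    def test_single_compartment_degenerate(self):
        m = build_cylinder(700.0, 1.0, dx=700.0)
        assert m.n == 1
        assert m.total_volume == pytest.approx(math.pi / 4 * 700, rel=1e-12)

    def test_plasticity_cylinder(self):
        m = build_cylinder(200.0, 1.0, 1.0)
        assert m.n == 200
        assert m.shaft_length == pytest.approx(200.0)

    @pytest.mark.parametrize("bad", [(0, 1, 1), (700, -1, 1), (700, 1, 0), (10, 1, 20)])
    def test_parameter_errors(self, bad):
        with pytest.raises(ValueError):
            build_cylinder(*bad)

    def test_noninteger_length_ratio_keeps_total_length(self):
        m = build_cylinder(10.5, 1.0, 1.0)
        assert m.n == 11
        assert m.shaft_length == pytest.approx(10.5)


class TestAttachSpines:
    def test_zero_density_is_identity(self, small_cylinder):
        out = attach_spines(small_cylinder, 0.0, seed=0)
        assert out.n == small_cylinder.n
        assert len(out.edges) == len(small_cylinder.edges)
        assert not out.spines

    def test_count_and_volume_bookkeeping(self):
        m = build_cylinder(700.0, 1.0, 1.0)
        spiny = attach_spines(m, 2.0, CANONICAL_SPINE, seed=0)
        assert len(spiny.spines) == 1400
        v_spine = CANONICAL_SPINE.total_volume
        assert v_spine == pytest.approx(
            math.pi * (0.3**2 * 0.55 + 0.1**2 * 1.25), rel=1e-12
        )
        assert spiny.total_volume == pytest.approx(
            m.total_volume + 1400 * v_spine, rel=1e-12
        )
        spiny.validate()

    def test_shaft_geometry_untouched(self, small_cylinder):
        spiny = attach_spines(small_cylinder, 5.0, seed=3)
        for a, b in zip(small_cylinder.compartments, spiny.compartments):
            assert (a.kind, a.length, a.diameter, a.axial_position) == (
                b.kind, b.length, b.diameter, b.axial_position
            )

    def test_seed_determinism(self, small_cylinder):
        a = attach_spines(small_cylinder, 2.0, seed=42)
        b = attach_spines(small_cylinder, 2.0, seed=42)
        c = attach_spines(small_cylinder, 2.0, seed=43)
        assert [s[0] for s in a.spines] == [s[0] for s in b.spines]
        assert [s[0] for s in a.spines] != [s[0] for s in c.spines]
        assert a.to_json() == b.to_json()

    def test_region_restriction(self, small_cylinder):
        spiny = attach_spines(small_cylinder, 1.0, seed=0, region=(100.0, 150.0))
        assert len(spiny.spines) == 50
        pos = spiny.positions()
        for shaft_id, _, _ in spiny.spines:
            assert 99.0 <= pos[shaft_id] <= 151.0

    def test_negative_density_rejected(self, small_cylinder):
        with pytest.raises(ValueError):
            attach_spines(small_cylinder, -1.0)

    def test_neck_coupling_uses_neck_cross_section(self, small_cylinder):
        spiny = attach_spines(small_cylinder, 0.1, seed=0)
        shaft_id, neck_id, _ = spiny.spines[0]
        edge = next(e for e in spiny.edges if {e.i, e.j} == {shaft_id, neck_id})
        assert edge.area == pytest.approx(math.pi * 0.1**2, rel=1e-12)


class TestVolumeMatching:
    def test_no_spines_identity(self):
        assert matched_diameter(1.0, 0.0) == pytest.approx(1.0)

    def test_printed_control_diameters(self):
        # the 1.2 μm and 1.5 μm volume-matched smooth controls
        assert matched_diameter(1.0, 2.0) == pytest.approx(1.2, abs=0.03)
        assert matched_diameter(1.0, 5.0) == pytest.approx(1.5, abs=0.03)

    def test_inverse_of_volume_map(self, canonical):
        density = 3.7
        d = matched_diameter(1.0, density, canonical)
        smooth = build_cylinder(100.0, d, 1.0)
        spiny = attach_spines(build_cylinder(100.0, 1.0, 1.0), density, canonical, seed=0)
        per_um_smooth = smooth.total_volume / 100.0
        per_um_spiny = spiny.total_volume / 100.0
        assert per_um_smooth == pytest.approx(per_um_spiny, abs=1e-9)


class TestImplicitSpineFactors:
    def test_zero_density(self, small_cylinder):
        assert implicit_spine_factors(small_cylinder, 0.0) == pytest.approx(1.0)

    def test_lateral_area_arithmetic(self, small_cylinder, canonical):
        lateral = math.pi * (0.6 * 0.55 + 0.2 * 1.25)
        assert lateral == pytest.approx(1.822, abs=5e-3)
        f = implicit_spine_factors(small_cylinder, 2.0, canonical, include_head_cap=False)
        assert f == pytest.approx(1 + 2 * lateral / math.pi, rel=1e-12)
        # head-cap convention adds the distal end cap per spine
        f_cap = implicit_spine_factors(small_cylinder, 2.0, canonical)
        assert f_cap == pytest.approx(
            1 + 2 * (lateral + math.pi * 0.3**2) / math.pi, rel=1e-12
        )

    @given(st.floats(0.0, 20.0), st.floats(0.1, 20.0))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_density(self, d1, delta):
        m = build_cylinder(50.0, 1.0, 1.0)
        assert implicit_spine_factors(m, d1 + delta) > implicit_spine_factors(m, d1)


class TestSpineGeometry:
    def test_canonical_head_neck_ratio(self, canonical):
        assert canonical.head_diameter / canonical.neck_diameter == pytest.approx(3.0)

    def test_positive_fields_enforced(self):
        with pytest.raises(ValueError):
            SpineGeometry(head_diameter=0.0)

    def test_wide_neck_warns(self):
        with pytest.warns(UserWarning):
            SpineGeometry(head_diameter=0.2, neck_diameter=0.4)


class TestStimulus:
    def test_periodic_train(self):
        tr = make_stimulus("periodic", 10.0, n_events=30)
        assert tr.n_events == 30
        assert np.allclose(tr.times, np.arange(30) * 100.0)
        assert tr.times[-1] == pytest.approx(2900.0)  # activity spans 3 s

    def test_zero_rate_periodic_with_events_rejected(self):
        with pytest.raises(ValueError):
            make_stimulus("periodic", 0.0, n_events=5)

    def test_poisson_zero_rate_empty(self):
        assert make_stimulus("poisson", 0.0, duration=3000.0, seed=0).n_events == 0

    def test_poisson_mean_count(self):
        counts = [
            make_stimulus("poisson", 5.0, duration=3000.0, seed=s).n_events
            for s in range(1000)
        ]
        # expectation rate × duration = 15; SE of the mean ≈ 0.12
        assert np.mean(counts) == pytest.approx(15.0, abs=0.5)

    @given(st.integers(0, 10_000), st.floats(0.5, 50.0))
    @settings(max_examples=30, deadline=None)
    def test_poisson_trains_sorted_nonnegative(self, seed, rate):
        tr = make_stimulus("poisson", rate, duration=500.0, seed=seed)
        assert np.all(np.diff(tr.times) >= 0)
        assert np.all(tr.times >= 0) and np.all(tr.times < 500.0)
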