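import numpy as np
import pytest

from copolar import (CellParams, ConfigurationError, PeriodicDomain,
                     apply_cell_variability, build_junction_map,
                     init_state, junction_growth_fields, junction_rate_fields,
                     neutralize_if_depleted, stimulus_rate_profile)
from copolar.junctions import (ActinRegulation, RateRegulation, StimulusSpec,
                               crosstalk_actin, motif_regulations,
                               pushpull_actin, regulation_arrays)
from copolar.kernels import SLOT_KON_RAC, SLOT_KON_RHO


@pytest.fixture(scope="module")
def jmap():
    return build_junction_map("doublet")


class TestJunctionMap:
    def test_doublet_arc_spans_quarter_perimeter(self, jmap):
        j = jmap.junctions[0]
        assert len(j.sites_a) == round(0.25 * jmap.domain.n_grid)
        thetas = jmap.domain.theta_deg(jmap.domain.site_centers[j.sites_a])
        # arc centered on the facing point (0 deg), spanning 90 degrees
        centered = (thetas + 180.0) % 360.0 - 180.0
        assert centered.min() > -45.0 and centered.max() < 45.0
        assert abs(np.degrees(np.angle(np.exp(1j * np.radians(thetas)).sum()))) < 1e-9

    @pytest.mark.parametrize("layout", ["doublet", "chain4", "square4"])
    def test_mirror_is_an_involution(self, layout):
        jm = build_junction_map(layout)
        mc, mi = jm.mirror_arrays()
        for c in range(jm.n_cells):
            for g in np.nonzero(mc[c] >= 0)[0]:
                c2, g2 = mc[c, g], mi[c, g]
                assert mc[c2, g2] == c and mi[c2, g2] == g

    def test_chain_interior_cells_have_two_disjoint_arcs(self):
        jm = build_junction_map("chain4")
        for cell, expected in ((0, 1), (1, 2), (2, 2), (3, 1)):
            arcs = [j for j in jm.junctions if cell in (j.cell_a, j.cell_b)]
            assert len(arcs) == expected
        mc, _ = jm.mirror_arrays()
        # interior cell arcs must not overlap
        sites1 = np.concatenate([
            (j.sites_a if j.cell_a == 1 else j.sites_b)
            for j in jm.junctions if 1 in (j.cell_a, j.cell_b)])
        assert len(sites1) == len(set(sites1.tolist()))

    def test_square_has_four_lateral_junctions(self):
        jm = build_junction_map("square4")
        assert len(jm.junctions) == 4
        pairs = {frozenset((j.cell_a, j.cell_b)) for j in jm.junctions}
        assert frozenset((0, 2)) not in pairs  # no diagonal contact
        assert frozenset((1, 3)) not in pairs

    def test_unknown_layout_rejected(self):
        with pytest.raises(ConfigurationError):
            build_junction_map("triplet")


class TestRateFields:
    def test_empty_regulation_is_identity(self, jmap):
        f = junction_rate_fields([], jmap, [CellParams()] * 2)
        assert np.all(f == 1.0)

    def test_gamma_applies_only_on_target_cell_junction(self, jmap):
        regs = [RateRegulation(0, "rac", "on", 1000.0)]
        f = junction_rate_fields(regs, jmap, [CellParams()] * 2)
        j = jmap.junctions[0]
        assert np.all(f[0, SLOT_KON_RAC, j.sites_a] == 1000.0)
        off = np.setdiff1d(np.arange(jmap.domain.n_grid), j.sites_a)
        assert np.all(f[0, SLOT_KON_RAC, off] == 1.0)
        assert np.all(f[1] == 1.0)

    def test_gamma_below_one_rejected(self):
        with pytest.raises(ConfigurationError):
            RateRegulation(0, "rac", "on", 0.5)

    def test_conc_dependent_zero_neighbor_reduces_to_baseline(self, jmap):
        regs = [RateRegulation(0, "rac", "on", 1000.0, conc_dependent=True,
                               source_species="rho")]
        n = jmap.domain.n_grid
        counts = {0: (np.zeros(n), np.zeros(n)), 1: (np.zeros(n), np.zeros(n))}
        f = junction_rate_fields(regs, jmap, [CellParams()] * 2, counts)
        assert np.all(f == 1.0)
        counts[1] = (np.zeros(n), np.full(n, 3.0))
        f = junction_rate_fields(regs, jmap, [CellParams()] * 2, counts)
        assert np.all(f[0, SLOT_KON_RAC, jmap.junctions[0].sites_a] == 3000.0)

    def test_conc_dependent_requires_source(self):
        with pytest.raises(ConfigurationError):
            RateRegulation(0, "rac", "on", 10.0, conc_dependent=True)


class TestGrowthFields:
    def test_all_zero_coefficients_give_zero_fields(self, jmap):
        ea, eb = junction_growth_fields([], jmap, [CellParams()] * 2)
        assert np.all(ea == 0) and np.all(eb == 0)

    def test_pushpull_motif_layout(self, jmap):
        regs = pushpull_actin(jmap, 1.0)
        ea, eb = junction_growth_fields(regs, jmap, [CellParams()] * 2)
        j = jmap.junctions[0]
        # bundled up in cell 0 at its junction, branched up in cell 1
        assert np.all(eb[0, j.sites_a] == 1.0) and np.all(ea[0] == 0.0)
        assert np.all(ea[1, j.sites_b] == 1.0) and np.all(eb[1] == 0.0)

    def test_dependent_mode_with_zero_neighbor_fields(self, jmap):
        regs = crosstalk_actin(jmap, 1.0)
        n = jmap.domain.n_grid
        fields = {c: (np.zeros(n), np.zeros(n)) for c in (0, 1)}
        ea, eb = junction_growth_fields(regs, jmap, [CellParams()] * 2, fields)
        assert np.all(ea == 0) and np.all(eb == 0)

    def test_dependent_mode_reads_mirror_point(self, jmap):
        regs = [ActinRegulation(0, eps_ab=2.0)]
        n = jmap.domain.n_grid
        b_nb = np.arange(n, dtype=float)
        fields = {0: (np.zeros(n), np.zeros(n)), 1: (np.zeros(n), b_nb)}
        ea, _ = junction_growth_fields(regs, jmap, [CellParams()] * 2, fields)
        j = jmap.junctions[0]
        assert np.allclose(ea[0, j.sites_a], 2.0 * b_nb[j.sites_b])


class TestStimulus:
    def test_zero_amplitude_gives_uniform_baseline(self, jmap):
        spec = StimulusSpec(0, 90.0, amplitude=0.0)
        kr, ko = stimulus_rate_profile(spec, jmap.domain, 2.0)
        assert np.allclose(kr, 2.0) and np.allclose(ko, 2.0)

    def test_rac_peaks_and_rho_dips_at_center(self, jmap):
        spec = StimulusSpec(1, 275.0, amplitude=4.0)
        kr, ko = stimulus_rate_profile(spec, jmap.domain, 1.0)
        thetas = jmap.domain.theta_deg(jmap.domain.site_centers)
        peak = thetas[np.argmax(kr)]
        assert abs((peak - 275.0 + 180) % 360 - 180) <= 360 / jmap.domain.n_grid
        assert np.argmin(ko) == np.argmax(kr)

    def test_sum_of_rates_is_constant(self, jmap):
        spec = StimulusSpec(0, 33.0, amplitude=4.0, half_width_deg=70.0)
        kr, ko = stimulus_rate_profile(spec, jmap.domain, 1.5)
        total = kr + ko
        assert np.max(np.abs(total - total[0])) == 0.0

    def test_inactive_window_returns_baseline(self, jmap):
        spec = StimulusSpec(0, 0.0, amplitude=4.0, t_on=5.0, t_off=10.0)
        kr, ko = stimulus_rate_profile(spec, jmap.domain, 1.0, t=20.0)
        assert np.allclose(kr, 1.0) and np.allclose(ko, 1.0)


class TestNeutralization:
    def test_noop_when_species_bound(self, params, domain, rng):
        st_ = init_state(params, domain, rng=1)
        before = st_.gtpase.rac.copy()
        neutralize_if_depleted(st_, rng)
        assert np.array_equal(st_.gtpase.rac, before)

    def test_rebinds_ten_percent_when_depleted(self, params, domain, rng):
        st_ = init_state(params, domain, rng=1)
        st_.gtpase.set_positions("rac", np.array([]))
        neutralize_if_depleted(st_, rng)
        assert st_.gtpase.bound_count("rac") == 10
        assert (st_.gtpase.bound_count("rac")
                + st_.gtpase.inactive_count("rac")) == params.n_rac


class TestCellVariability:
    def test_empty_overrides_identity(self, params):
        assert apply_cell_variability(params, {}) == params

    def test_tenfold_rac_binding(self, params):
        p2 = apply_cell_variability(params, {"kon_rac_factor": 10.0})
        assert p2.kon_rac_factor == 10.0 and p2.kon_rho_factor == 1.0

    def test_junction_gamma_composes_multiplicatively(self, jmap):
        p2 = apply_cell_variability(CellParams(), {"kon_rac_factor": 10.0})
        regs = [RateRegulation(0, "rac", "on", 100.0)]
        cf, _, _ = regulation_arrays(regs, jmap, [p2, CellParams()])
        j = jmap.junctions[0]
        assert np.all(cf[0, SLOT_KON_RAC, j.sites_a] == 1000.0)
        off = np.setdiff1d(np.arange(jmap.domain.n_grid), j.sites_a)
        assert np.all(cf[0, SLOT_KON_RAC, off] == 10.0)

    def test_unknown_or_negative_overrides_rejected(self, params):
        with pytest.raises(ConfigurationError):
            apply_cell_variability(params, {"bogus": 1.0})
        with pytest.raises(ConfigurationError):
            apply_cell_variability(params, {"kon_rac_factor": -2.0})


class TestMotifs:
    def test_motif_orientation_roles(self, jmap):
        regs = motif_regulations("asym_bind_complementary", jmap, 1000.0)
        by_cell = {r.cell: r for r in regs}
        assert by_cell[0].species == "rac" and by_cell[0].rate == "on"
        assert by_cell[1].species == "rho" and by_cell[1].rate == "on"

    def test_conc_dependent_source_is_partner_species(self, jmap):
        regs = motif_regulations("asym_bind_complementary", jmap, 1000.0,
                                 conc_dependent=True)
        by_cell = {r.cell: r for r in regs}
        assert by_cell[0].source_species == "rho"
        assert by_cell[1].source_species == "rac"

    def test_chain_motif_covers_every_junction(self):
        jm = build_junction_map("chain4")
        regs = motif_regulations("asym_bind_unbind_rac", jm, 1000.0)
        assert len(regs) == 6  # two entries per junction
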