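"""Scoring terms, precalculated tables, unit conversions, H-bonds."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pldock.conformation import identity_conformation, realize
from pldock.energetics import (
    DEFAULT_CUTOFF,
    DEFAULT_N_SAMPLES,
    IntraPairs,
    N_TYPE_PAIRS,
    ScoringWeights,
    ThermoConstants,
    consensus_score,
    detect_hbonds,
    flexibility_penalized_energy,
    intra_score,
    kcal_to_pkd,
    ligand_efficiency,
    lookup_score,
    pair_index,
    pair_score,
    pkd_to_kcal,
    precalculate_table,
    surface_distance,
    term_values,
)
from pldock.pdbqt import ATOM_TYPES, TYPE_CODES, parse_ligand, parse_receptor


def reference_pair_score(r, ta, tb, w=ScoringWeights(), cutoff=8.0):
    """Straight-line reimplementation used as the dual-route oracle."""
    if r >= cutoff:
        return 0.0
    d = r - ATOM_TYPES[ta].vdw_radius - ATOM_TYPES[tb].vdw_radius
    gauss1 = math.exp(-((d / 0.5) ** 2))
    gauss2 = math.exp(-(((d - 3.0) / 2.0) ** 2))
    repulsion = d * d if d < 0 else 0.0
    hydrophobic = min(max(1.5 - d, 0.0), 1.0)
    hbond = min(max(-d / 0.7, 0.0), 1.0)
    a, b = ATOM_TYPES[ta], ATOM_TYPES[tb]
    total = w.w_gauss1 * gauss1 + w.w_gauss2 * gauss2 \
        + w.w_repulsion * repulsion
    if a.is_hydrophobic and b.is_hydrophobic:
        total += w.w_hydrophobic * hydrophobic
    if (a.is_hbond_donor and b.is_hbond_acceptor) or \
            (a.is_hbond_acceptor and b.is_hbond_donor):
        total += w.w_hbond * hbond
    return total


class TestSurfaceDistance:
    def test_touching_surfaces(self):
        assert surface_distance(3.8, "C_H", "C_H") == pytest.approx(0.0)

    def test_zero_distance_full_overlap(self):
        assert surface_distance(0.0, "C_H", "C_P") == pytest.approx(-3.8)

    def test_carbon_nitrogen_arithmetic(self):
        assert surface_distance(4.0, "C_H", "N") == pytest.approx(0.3)


class TestTermValues:
    def test_gauss1_peaks_no_repulsion_at_contact(self):
        g1, _, rep, _, _ = term_values(0.0)
        assert g1 == pytest.approx(1.0)
        assert rep == pytest.approx(0.0)

    def test_ramps_vanish_beyond_support(self):
        _, _, _, hyd, hb = term_values(2.0)
        assert hyd == pytest.approx(0.0)
        assert hb == pytest.approx(0.0)

    def test_repulsion_quadratic_in_overlap(self):
        assert term_values(-1.0)[2] == pytest.approx(1.0)


class TestPairScore:
    @pytest.mark.parametrize("r", [8.0, 9.3])
    def test_zero_at_and_beyond_cutoff(self, r):
        assert pair_score(r, "C_H", "O_A") == 0.0

    def test_matches_reference_reimplementation(self, rng):
        for _ in range(300):
            ta, tb = rng.choice(TYPE_CODES, size=2)
            r = float(rng.uniform(0, 10))
            assert pair_score(r, ta, tb) == pytest.approx(
                reference_pair_score(r, ta, tb), abs=1e-12)


class TestPairPotentialTable:
    def test_default_dimensions(self, table):
        assert table.values.shape == (N_TYPE_PAIRS, DEFAULT_N_SAMPLES)
        assert (N_TYPE_PAIRS, DEFAULT_N_SAMPLES) == (120, 16384)
        assert table.r_cutoff == DEFAULT_CUTOFF == 8.0

    def test_all_pair_indices_distinct(self):
        seen = {pair_index(a, b) for i, a in enumerate(TYPE_CODES)
                for b in TYPE_CODES[i:]}
        assert seen == set(range(120))
        # unordered: index is symmetric
        assert pair_index("C_H", "Met") == pair_index("Met", "C_H")

    def test_degenerate_two_sample_table(self):
        t = precalculate_table(n_samples=2)
        assert t.values.shape[1] == 2
        assert np.all(t.values[:, -1] == 0.0)

    def test_cutoff_sample_is_zero(self, table):
        assert np.all(table.values[:, -1] == 0.0)

    def test_rejects_single_sample(self):
        with pytest.raises(ValueError):
            precalculate_table(n_samples=1)


class TestLookup:
    def test_on_grid_identity(self, table):
        # sample 1000: r exactly on a grid point
        r = 1000 * table.sample_spacing
        assert lookup_score(table, r, "C_H", "O_A") == pytest.approx(
            pair_score(r, "C_H", "O_A"), abs=1e-12)

    def test_zero_beyond_cutoff(self, table):
        assert lookup_score(table, 8.0, "C_H", "C_H") == 0.0
        assert lookup_score(table, 12.0, "C_H", "C_H") == 0.0

    def test_negative_distance_rejected(self, table):
        with pytest.raises(ValueError):
            lookup_score(table, -0.1, "C_H", "C_H")

    def test_error_bounded_by_lipschitz_times_bin(self, table, rng):
        """Nearest-sample error <= slope x half-bin, plus the cutoff jump.

        The score is truncated to zero at the cutoff, so within the last
        bin the error can reach the (small) analytic value just below it.
        """
        for _ in range(20):
            ta, tb = rng.choice(TYPE_CODES, size=2)
            p = pair_index(ta, tb)
            lipschitz = np.abs(table.derivatives[p]).max()
            jump = abs(float(pair_score(8.0 - 1e-9, ta, tb)))
            r = rng.uniform(0, 8, size=5000)
            err = np.abs(
                np.array([lookup_score(table, ri, ta, tb) for ri in r])
                - np.array([pair_score(ri, ta, tb) for ri in r]))
            bound = lipschitz * table.sample_spacing * 0.51 + jump + 1e-9
            assert err.max() <= bound

    def test_error_shrinks_as_samples_double(self, rng):
        """Sup-norm lookup error decreases monotonically with resolution."""
        r = rng.uniform(0, 8, size=4000)
        errs = []
        for n in (2**10, 2**12, 2**14):
            t = precalculate_table(n_samples=n)
            err = np.abs(lookup_score(t, r, "C_H", "O_A")
                         - pair_score(r, "C_H", "O_A"))
            errs.append(err.max())
        assert errs[0] > errs[1] > errs[2]


class TestIntraScore:
    def test_rigid_ligand_scores_zero(self, rigid_ligand_text, table):
        t = parse_ligand(rigid_ligand_text)
        assert intra_score(t, t.input_coords(), table) == 0.0

    def test_one_four_pairs_excluded(self, flexible_ligand_text, table):
        t = parse_ligand(flexible_ligand_text)
        pairs = IntraPairs(t)
        serials = {(t.atoms[i].serial, t.atoms[j].serial)
                   for i, j in zip(pairs.i, pairs.j)}
        for pair in serials:
            assert tuple(sorted(pair)) not in t.one_four_exclusions

    def test_matches_brute_force_enumeration(self, flexible_ligand_text,
                                             table, rng):
        t = parse_ligand(flexible_ligand_text)
        conf = identity_conformation(t)
        coords = realize(t, conf.__class__(
            position=conf.position, orientation=conf.orientation,
            torsions=rng.uniform(-np.pi, np.pi, t.n_active)))
        got = intra_score(t, coords, table)
        # brute force: every mobile heavy pair, 1-4 excluded
        from pldock.pdbqt import mobile_heavy_pairs
        expected = 0.0
        for i, j in mobile_heavy_pairs(t):
            r = float(np.linalg.norm(coords[i] - coords[j]))
            expected += float(lookup_score(
                table, r, t.atoms[i].type, t.atoms[j].type))
        assert got == pytest.approx(expected, abs=1e-12)


class TestFlexibilityPenalty:
    def test_penalty_off_and_rigid_reduce_to_difference(self):
        w0 = ScoringWeights(w_flex=0.0)
        assert flexibility_penalized_energy(-5.0, -1.0, 3, 2, w0) == \
            pytest.approx(-4.0)
        assert flexibility_penalized_energy(-5.0, -1.0, 0, 0) == \
            pytest.approx(-4.0)

    @given(st.lists(st.floats(-20, 5).map(lambda x: round(x, 3)),
                    min_size=2, max_size=8, unique=True))
    @settings(deadline=None)
    def test_ranking_preserved_within_one_ligand(self, scores):
        """The denominator is constant per ligand, so ordering by output
        equals ordering by the conformation-dependent score."""
        e1 = min(scores) * 0.3  # any fixed reference intra score
        out = [flexibility_penalized_energy(e, e1, 4, 2) for e in scores]
        assert np.argsort(out).tolist() == np.argsort(scores).tolist()

    def test_inactive_torsions_weigh_half(self):
        w = ScoringWeights()
        full = flexibility_penalized_energy(-6.0, 0.0, 2, 0, w)
        half = flexibility_penalized_energy(-6.0, 0.0, 1, 2, w)
        assert full == pytest.approx(half)


class TestUnitConversions:
    def test_zero_maps_to_zero(self):
        assert kcal_to_pkd(0.0) == 0.0

    def test_one_pkd_unit(self):
        c = ThermoConstants()
        dg = -c.gas_constant * c.temperature * math.log(10)
        assert dg == pytest.approx(-1.364, abs=2e-3)
        assert kcal_to_pkd(dg) == pytest.approx(1.0)

    def test_example_affinity(self):
        assert kcal_to_pkd(-6.82) == pytest.approx(5.0, abs=0.01)

    @given(st.floats(-30, 30))
    @settings(deadline=None)
    def test_linear_and_invertible(self, dg):
        assert pkd_to_kcal(kcal_to_pkd(dg)) == pytest.approx(dg, abs=1e-12)

    def test_consensus_is_symmetric_mean(self):
        assert consensus_score(5.0, 7.0) == 6.0
        assert consensus_score(4.2, 4.2) == 4.2
        assert consensus_score(1.0, 2.0) == consensus_score(2.0, 1.0)

    def test_ligand_efficiency(self):
        assert ligand_efficiency(-8.0, 20) == pytest.approx(-0.4)
        assert ligand_efficiency(-3.0, 1) == -3.0
        with pytest.raises(ValueError):
            ligand_efficiency(-8.0, 0)


class TestHbondDetection:
    def test_donor_acceptor_within_threshold(self, tiny_receptor_text):
        rec = parse_receptor(tiny_receptor_text)
        # ligand acceptor O 2.9 A from the receptor's donor nitrogen
        coords = np.array([[3.0 + 2.9, 0.0, 0.0]])
        found = detect_hbonds(rec, coords, ["O_A"])
        assert len(found) == 1
        assert found[0][2] == pytest.approx(2.9)

    def test_hydrophobic_pair_ignored(self, tiny_receptor_text):
        rec = parse_receptor(tiny_receptor_text)
        coords = np.array([[2.9, 0.0, 0.0]])
        assert detect_hbonds(rec, coords, ["C_H"]) == []

    def test_beyond_threshold_ignored(self, tiny_receptor_text):
        rec = parse_receptor(tiny_receptor_text)
        coords = np.array([[3.0 + 5.0, 0.0, 0.0]])
        assert detect_hbonds(rec, coords, ["O_A"]) == []
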