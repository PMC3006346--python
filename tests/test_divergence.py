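"""Divergence, heterozygosity, rate tests and calibration arithmetic."""

from __future__ import annotations

from itertools import product

import numpy as np
import pytest

import probmsc as pm
from conftest import make_table
from probmsc.divergence import CalibrationWindow, theta_to_diploid_n
from probmsc.simulate import expected_pairwise_divergence


def brute_force_mismatch(f_x: float, f_y: float) -> float:
    """Enumerate the four ordered single-chromosome draws for one site."""
    total = 0.0
    for ax, px in ((1, f_x), (0, 1 - f_x)):
        for ay, py in ((1, f_y), (0, 1 - f_y)):
            total += px * py * (ax != ay)
    return total


class TestPairwiseDivergence:
    @pytest.mark.parametrize("fx,fy", list(product([0.0, 0.5, 1.0], repeat=2)))
    def test_single_site_matches_draw_enumeration(self, fx, fy):
        table = make_table([{"F": 2 * fx, "S": 2 * fy}])
        got = pm.pairwise_divergence(table, "F", "S")
        assert got == pytest.approx(brute_force_mismatch(fx, fy))

    def test_symmetry(self, study_table):
        for x, y in [("F", "S"), ("A", "M"), ("F", "O")]:
            assert (pm.pairwise_divergence(study_table, x, y)
                    == pytest.approx(pm.pairwise_divergence(study_table, y, x)))

    def test_heterozygosity_counts_het_genotypes(self):
        table = make_table([{"F": 1.0}, {"F": 1.0}, {"F": 2.0}, {"S": 1.0}])
        assert pm.pairwise_divergence(table, "F", "F") == 2.0
        assert pm.pairwise_divergence(table, "S", "S") == 1.0

    def test_heterozygosity_invariant_under_allele_relabeling(self):
        table = make_table([{"F": 1.0, "S": 2.0}, {"F": 1.0}])
        flipped = make_table([{"F": 1.0, "S": 0.0}, {"F": 1.0, "S": 2.0,
                                                     "A": 2.0, "M": 2.0, "O": 1.0}],
                             polarized=False)
        assert (pm.pairwise_divergence(table, "F", "F")
                == pm.pairwise_divergence(pm.polarize(flipped), "F", "F"))

    def test_pooled_heterozygosity_from_two_individuals(self):
        """Four pooled chromosomes: expected mismatch 2f(1-f) * 4/3 per site.
        With 1 of 4 derived copies, a random pair differs with probability
        (1*3)/C(4,2) = 1/2; with 2 of 4, 4/6 = 2/3."""
        table = make_table([{"A": 1.0}, {"A": 2.0}, {"A": 0.0}])
        table.df["A2"] = [0.0, 0.0, np.nan]
        from probmsc.divergence import pooled_heterozygosity
        got = pooled_heterozygosity(table, "A")
        assert got == pytest.approx(0.5 + 2 / 3)

    def test_empty_table_rejected(self):
        table = make_table([{}]).subset(np.array([False]))
        with pytest.raises(ValueError, match="empty"):
            pm.pairwise_divergence(table, "F", "S")


class TestDivergenceMatrix:
    def test_normalizer_is_one_with_zero_se(self, study_table):
        mat = pm.divergence_matrix(study_table)
        key = (pm.Taxon.SAVANNA, pm.Taxon.ASIAN)
        assert mat.normalized[key] == pytest.approx(1.0)
        assert mat.se[key] == pytest.approx(0.0, abs=1e-12)

    def test_identical_sequences_within_taxa_zero_heterozygosity(self):
        table = make_table([{"F": 2.0, "S": 2.0}, {"A": 2.0}, {"S": 2.0, "A": 2.0}])
        mat = pm.divergence_matrix(table, with_uncertainty=False)
        for t in pm.ELEPHANTIDS:
            assert mat.values[(t, t)] == 0.0

    def test_normalized_ratios_track_coalescent_expectations(self, study_table, default_model):
        """On simulator output the normalized divergences must converge to
        ratios of closed-form expected coalescent path lengths."""
        mat = pm.divergence_matrix(study_table)
        t_sa = expected_pairwise_divergence(default_model, "S", "A")
        for x, y, in [("F", "S"), ("A", "M"), ("F", "A"), ("S", "M")]:
            expected = expected_pairwise_divergence(default_model, x, y) / t_sa
            se = max(mat.se[tuple(pm.Taxon(t) for t in (x, y))], 0.01)
            assert mat.get(x, y) == pytest.approx(expected, abs=3.5 * se)


class TestRelativeRateTest:
    def test_symmetric_counts_give_zero_statistic(self):
        rows = []
        for l in (1, 2, 3, 4):
            rows.append({"locus_id": f"L{l:03d}", "F": 2.0})
            rows.append({"locus_id": f"L{l:03d}", "S": 2.0})
        res = pm.relative_rate_test(make_table(rows), "F", "S")
        assert res.estimate == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_toy_counts_and_brute_force_jackknife(self):
        """n_x = 3 lineage-specific sites vs n_y = 1 gives statistic 0.5; the
        SE must match an explicit delete-one-locus enumeration."""
        rows = [
            {"locus_id": "L001", "F": 2.0}, {"locus_id": "L001", "F": 2.0},
            {"locus_id": "L002", "F": 2.0}, {"locus_id": "L002", "S": 2.0},
            {"locus_id": "L003", "A": 2.0}, {"locus_id": "L003", "M": 1.0},
        ]
        table = make_table(rows)
        res = pm.relative_rate_test(table, "F", "S")
        assert res.estimate == pytest.approx((3 - 1) / (3 + 1))

        def stat(t):
            f, s = t.frequencies("F"), t.frequencies("S")
            nx = float(np.sum(f * (1 - s)))
            ny = float(np.sum(s * (1 - f)))
            return (nx - ny) / (nx + ny)

        sizes = table.sites_per_locus()
        loo = [stat(table.drop_locus(l)) for l in sizes.index]
        _, se = pm.weighted_jackknife_values(res.estimate, loo, sizes.to_numpy(float))
        assert res.se == pytest.approx(se, rel=1e-12)

    def test_global_denominator_scales_statistic(self):
        rows = [
            {"locus_id": "L001", "F": 2.0}, {"locus_id": "L001", "F": 2.0},
            {"locus_id": "L002", "F": 2.0}, {"locus_id": "L002", "S": 2.0},
            {"locus_id": "L003", "A": 2.0}, {"locus_id": "L003", "M": 1.0},
        ]
        table = make_table(rows)
        res = pm.relative_rate_test(table, "F", "S", denominator="global")
        assert res.estimate == pytest.approx((3 - 1) / 6)

    def test_no_lineage_specific_sites_reported_undefined(self):
        table = make_table([{"F": 2.0, "S": 2.0}, {"A": 1.0}])
        with pytest.raises(ValueError, match="no lineage-specific"):
            pm.relative_rate_test(table, "F", "S")

    def test_clocklike_on_simulated_data(self, study_table):
        """Simulated data evolve clock-free of lineage effects, so no pair
        should show a wildly significant rate difference."""
        res = pm.relative_rate_test(study_table, "S", "F")
        assert abs(res.z) < 4.0


class TestCalibration:
    def test_fossil_window_lower_bound(self):
        lo, hi = pm.calibrate_absolute((0.45, 0.79))
        assert lo == pytest.approx(1.89, abs=0.005)
        assert hi == pytest.approx(7.11, abs=0.005)

    def test_unit_ratio_returns_window(self):
        assert pm.calibrate_absolute(1.0) == pytest.approx((4.2, 9.0))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            pm.calibrate_absolute(-0.5)
        with pytest.raises(ValueError):
            CalibrationWindow(t_lox_eur_mya=(9.0, 4.2))

    def test_theta_to_population_size(self):
        # theta = 4 N mu g  =>  N = theta / (4 mu g)
        n = theta_to_diploid_n(0.00238, mu_per_year=3.33e-10, generation_years=31.0)
        assert n == pytest.approx(0.00238 / (4 * 3.33e-10 * 31.0))
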