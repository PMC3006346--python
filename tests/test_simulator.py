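"""Structured-coalescent simulator against closed forms and msprime."""

from __future__ import annotations

import math

import msprime
import numpy as np
import pytest
from scipy import stats

import probmsc as pm
from probmsc.simulate import (GeneTree, LEAF_LABELS, _coalesce_interval,
                              drop_mutations, expected_pairwise_divergence,
                              simulate_gene_tree)

N_REPS = 10_000


@pytest.fixture(scope="module")
def tree_sample(default_model):
    rng = np.random.default_rng(42)
    return [simulate_gene_tree(default_model, rng) for _ in range(N_REPS)]


def mc_band(p: float, n: int) -> float:
    return 3.0 * math.sqrt(p * (1 - p) / n)


class TestGeneTrees:
    def test_ultrametric_and_complete(self, tree_sample):
        for tree in tree_sample[:200]:
            assert len(tree.time) == 2 * len(LEAF_LABELS) - 1
            for node, bl in tree.branches():
                assert bl >= 0.0
            assert tree.mask[tree.root] == (1 << len(LEAF_LABELS)) - 1

    def test_no_coalescence_fraction_matches_closed_form(self, tree_sample,
                                                         default_model):
        """P(F and S lineages fail to coalesce before the African-Eurasian
        split) = exp(-2 (tau_LoxEur - tau_FS) / theta_FS), by sampling
        consistency of the coalescent for the marginal pair (F1, S1)."""
        m = default_model
        expected = math.exp(-2 * (m.tau_loxeur - m.tau_fs) / m.theta_fs)
        deep = np.mean([t.pair_tmrca(0, 2) >= m.tau_loxeur for t in tree_sample])
        assert deep == pytest.approx(expected, abs=mc_band(expected, N_REPS))

    def test_triplet_discordance_matches_msc_formula(self, tree_sample,
                                                     default_model):
        """P(F1 or S1 joins A1 before joining each other) =
        (2/3) exp(-2 dtau / theta_FS), the standard three-taxon result."""
        m = default_model
        expected = (2 / 3) * math.exp(-2 * (m.tau_loxeur - m.tau_fs) / m.theta_fs)
        disc = 0
        for t in tree_sample:
            t_fs = t.pair_tmrca(0, 2)   # F1, S1
            t_fa = t.pair_tmrca(0, 4)   # F1, A1
            t_sa = t.pair_tmrca(2, 4)   # S1, A1
            if min(t_fa, t_sa) < t_fs:
                disc += 1
        disc /= len(tree_sample)
        assert disc == pytest.approx(expected, abs=mc_band(expected, N_REPS))

    def test_interval_waiting_times_are_exponential(self):
        """First coalescence among k lineages in one interval ~ Exp(k(k-1)/theta)
        (Kolmogorov-Smirnov at alpha = 0.01)."""
        rng = np.random.default_rng(9)
        theta = 0.002
        for k in (2, 4):
            times = []
            for _ in range(4000):
                tree = GeneTree(k)
                lineages = _coalesce_interval(list(range(k)), theta, 0.0,
                                              math.inf, tree, rng)
                times.append(tree.time[k])  # first added node
            scale = theta / (k * (k - 1))
            assert stats.kstest(times, "expon", args=(0, scale)).pvalue > 0.01

    def test_tiny_ancestral_theta_removes_discordance(self):
        model = pm.SpeciesTreeModel(theta_fs=1e-7, theta_am=1e-7)
        rng = np.random.default_rng(12)
        trees = [simulate_gene_tree(model, rng) for _ in range(800)]
        disc = np.mean([t.pair_tmrca(0, 2) >= model.tau_loxeur for t in trees])
        assert disc == 0.0

    def test_cross_validated_against_msprime(self, default_model):
        """Independent oracle: pairwise F1-S1 coalescence times from msprime
        under the matched demography (KS test at alpha = 0.01).  Times are
        expressed in mutation units by setting population size theta/4 and
        split times tau in msprime 'generations'."""
        m = default_model
        demography = msprime.Demography()
        for pop, theta in [("F", m.theta_f), ("S", m.theta_s), ("A", m.theta_a),
                           ("M", m.theta_m), ("FS", m.theta_fs), ("AM", m.theta_am),
                           ("LOX", m.theta_loxeur), ("ROOT", m.theta_root),
                           ("O", m.theta_root)]:
            demography.add_population(name=pop, initial_size=theta / 4)
        demography.add_population_split(time=m.tau_fs, derived=["F", "S"], ancestral="FS")
        demography.add_population_split(time=m.tau_am, derived=["A", "M"], ancestral="AM")
        demography.add_population_split(time=m.tau_loxeur, derived=["FS", "AM"],
                                        ancestral="LOX")
        demography.add_population_split(time=m.tau_root, derived=["LOX", "O"],
                                        ancestral="ROOT")
        demography.sort_events()
        reps = msprime.sim_ancestry(
            samples={"F": 1, "S": 1, "A": 1, "M": 1}, demography=demography,
            ploidy=2, num_replicates=3000, random_seed=77)
        ms_times = []
        for ts in reps:
            t = ts.first()
            ms_times.append(t.tmrca(0, 2))  # first F chromosome, first S chromosome
        rng = np.random.default_rng(13)
        ours = [simulate_gene_tree(m, rng).pair_tmrca(0, 2) for _ in range(3000)]
        assert stats.ks_2samp(ms_times, ours).pvalue > 0.01


class TestMutations:
    def test_zero_branch_lengths_give_identical_sequences(self):
        tree = GeneTree(3)
        tree.add_node(0.0, 0, 1)
        tree.add_node(0.0, 2, 3)
        rng = np.random.default_rng(0)
        aln, ledger = drop_mutations(tree, 40, "infinite_sites", rng)
        assert len(set(aln.sequences.values())) == 1
        assert len(ledger) == 0

    def test_infinite_sites_ledger_matches_polymorphic_columns(self, small_sim):
        for locus, tree in zip(small_sim.loci[:20], small_sim.gene_trees[:20]):
            seqs = list(locus.sequences.values())
            poly = sum(len({s[i] for s in seqs}) > 1 for i in range(locus.length))
            planted = len(small_sim.ledger[small_sim.ledger["locus_id"]
                                           == locus.locus_id])
            assert poly == planted

    def test_within_taxon_diversity_tracks_theta(self, default_model):
        """Mean F1-F2 mismatch per site approximates the closed-form
        expected heterozygosity (3 MC SE band over loci)."""
        sim = pm.simulate_dataset(n_loci=1500, seed=31, damage_rate=0.0)
        per_site = []
        for l in sim.loci:
            d = sum(a != b for a, b in zip(l.sequences["F1"], l.sequences["F2"]))
            per_site.append(d / l.length)
        expected = expected_pairwise_divergence(default_model, "F", "F")
        se = np.std(per_site, ddof=1) / math.sqrt(len(per_site))
        assert np.mean(per_site) == pytest.approx(expected, abs=3 * se)

    def test_jc69_allows_recurrent_hits(self):
        model = pm.SpeciesTreeModel()
        rng = np.random.default_rng(5)
        tree = simulate_gene_tree(model, rng)
        aln, ledger = drop_mutations(tree, 200, "jc69", rng)
        assert set(aln.sequences) == set(LEAF_LABELS)
        assert all(len(s) == 200 for s in aln.sequences.values())


class TestDamage:
    def test_rate_zero_is_identity(self, small_sim):
        rng = np.random.default_rng(1)
        for locus in small_sim.loci[:5]:
            assert pm.apply_damage(locus, 0.0, rng).sequences == locus.sequences

    def test_rate_one_strips_c_and_g_from_mastodon(self, small_sim):
        rng = np.random.default_rng(1)
        damaged = pm.apply_damage(small_sim.loci[0], 1.0, rng)
        assert not set(damaged.sequences["O"]) & {"C", "G"}
        assert damaged.sequences["F1"] == small_sim.loci[0].sequences["F1"]

    def test_damage_inflates_mastodon_column_not_polymorphic_calls(self):
        """Paired run: damage must inflate apparent mastodon-specific
        divergence strongly while leaving the elephantid-polymorphic site
        set almost untouched (the ancestral-allele role of the mastodon is
        robust; the calibration role is not)."""
        base = pm.simulate_dataset(n_loci=375, seed=17, damage_rate=0.0)
        rng = np.random.default_rng(18)
        damaged_loci = [pm.apply_damage(l, 0.05, rng) for l in base.loci]

        def polarized_table(loci):
            return pm.polarize(pm.call_divergent_sites(loci, max_poly_per_locus=10 ** 9))

        clean = polarized_table(base.loci)
        noisy = polarized_table(damaged_loci)

        def polymorphic_set(t):
            mask = t.polymorphic_mask()
            return set(zip(t.df.loc[mask, "locus_id"], t.df.loc[mask, "pos"]))

        clean_poly = polymorphic_set(clean)
        noisy_poly = polymorphic_set(noisy)
        overlap = len(clean_poly & noisy_poly) / len(clean_poly)
        assert overlap > 0.95

        def mastodon_specific(t):
            return int((t.derived_counts() == 8).sum())

        inflation = mastodon_specific(noisy) / mastodon_specific(clean)
        # calibrated so that ~62% of apparent mastodon-specific divergent
        # sites are damage artifacts: inflation factor ~ 1/0.38
        assert 1.8 < inflation < 3.8


class TestSimulateDataset:
    def test_fixed_seed_reproduces_bytes(self):
        a = pm.simulate_dataset(n_loci=12, seed=99)
        b = pm.simulate_dataset(n_loci=12, seed=99)
        for la, lb in zip(a.loci, b.loci):
            assert la.sequences == lb.sequences
        assert a.ledger.equals(b.ledger)

    def test_zero_loci_dataset_is_valid(self, tmp_path):
        sim = pm.simulate_dataset(n_loci=0, seed=1)
        assert sim.loci == [] and sim.total_bp == 0
        pm.write_phylip_multilocus(sim.loci, tmp_path / "empty.phy")

    def test_study_scale_counts(self, study_sim):
        """375 loci at the fitted parameters: total length and the count of
        elephantid-polymorphic sites must be on the study's scale."""
        assert 34_000 < study_sim.total_bp < 46_000
        table = pm.polarize(pm.call_divergent_sites(study_sim.loci))
        assert 300 < table.n_polymorphic < 900

    def test_length_distribution(self):
        sim = pm.simulate_dataset(n_loci=400, seed=55)
        lens = np.array([l.length for l in sim.loci])
        assert lens.min() >= 50
        assert abs(lens.mean() - 106) < 5
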