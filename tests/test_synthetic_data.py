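import dendropy
import numpy as np
import pytest
from scipy import stats

from dupdyn.family_size_evolution import BirthDeathModel, bd_transition_prob
from dupdyn.family_clustering import filter_hits
from dupdyn.synthetic_data import (
    TwoSpeciesConfig,
    evolve_cds,
    random_cds,
    simulate_codon_pair,
    simulate_counts,
    simulate_family_sizes,
    simulate_hits,
    simulate_positions,
    simulate_two_species_world,
)
from dupdyn.tandem_detection import call_tandem_arrays
from dupdyn.io_formats import ProteinRecord, translate_cds
from tests.test_codon_evolution import pair_estimate


@pytest.fixture
def small_tree():
    return dendropy.Tree.get(data="((A:0.5,B:0.5):0.5,C:1.0);", schema="newick")


class TestFamilySizes:
    def test_lambda_zero_keeps_root_sizes(self, small_tree):
        tips, truth = simulate_family_sizes(
            small_tree, 50, BirthDeathModel(lam={"global": 0.0}), seed=1
        )
        root_col = "A|B|C"
        for sp in "ABC":
            assert (tips[sp] == truth[root_col]).all()

    def test_equal_birth_death_is_martingale(self, small_tree):
        tips, truth = simulate_family_sizes(
            small_tree, 2000, BirthDeathModel(lam={"global": 0.3}), seed=2,
            root_size_mean=3.0,
        )
        root = truth["A|B|C"].to_numpy()
        for sp in "ABC":
            diff = tips[sp].to_numpy() - root
            se = diff.std(ddof=1) / np.sqrt(len(diff))
            assert abs(diff.mean()) < 4 * se

    def test_same_seed_reproducible(self, small_tree):
        a = simulate_family_sizes(small_tree, 30, BirthDeathModel(lam={"global": 0.2}), seed=9)
        b = simulate_family_sizes(small_tree, 30, BirthDeathModel(lam={"global": 0.2}), seed=9)
        assert a[1].equals(b[1])

    def test_single_branch_frequencies_match_transition_formula(self):
        """Empirical Gillespie transition frequencies from s=2 over lambda*t=0.3
        agree with the closed-form birth-death probabilities."""
        t = dendropy.Tree.get(data="(A:1.0,B:1.0);", schema="newick")
        lam = 0.3
        tips, truth = simulate_family_sizes(
            t, 4000, BirthDeathModel(lam={"global": lam}), seed=3,
            root_size_mean=2.0,
        )
        # restrict to families that start at size 2 on the root
        root = truth["A|B"]
        obs = tips.loc[root == 2, "A"]
        n = len(obs)
        assert n > 200
        for c in range(5):
            p_exp = bd_transition_prob(2, c, 1.0, lam)
            p_obs = (obs == c).mean()
            se = np.sqrt(p_exp * (1 - p_exp) / n)
            assert abs(p_obs - p_exp) < 4 * se + 1e-9


class TestSequences:
    def test_zero_intensity_identical(self, rng):
        cds = random_cds(60, rng)
        assert evolve_cds(cds, 5.0, 0.0, 1.0, rng) == cds
        a, b = simulate_codon_pair(60, 2.0, 0.0, 1.0, rng)
        assert a == b
        assert pair_estimate(a, b).dS == 0.0

    def test_omega_zero_gives_zero_dn(self, rng):
        for _ in range(5):
            a, b = simulate_codon_pair(100, 1.0, 0.15, 0.0, rng)
            est = pair_estimate(a, b)
            assert est.dN == 0.0

    def test_no_stop_codons_ever(self, rng):
        a, b = simulate_codon_pair(200, 3.0, 0.3, 1.0, rng)
        for seq in (a, b):
            assert "*" not in translate_cds(seq)

    def test_ds_tracks_divergence_time(self, rng):
        """Realised dS correlates strongly with simulated divergence time
        across 500 pairs (Spearman rho > 0.9)."""
        times = rng.uniform(0.1, 3.0, size=500)
        ds = []
        for t in times:
            a, b = simulate_codon_pair(120, float(t), 0.1, 0.3, rng)
            est = pair_estimate(a, b)
            ds.append(est.dS if np.isfinite(est.dS) else 3.0)
        rho = stats.spearmanr(times, ds).statistic
        assert rho > 0.9


class TestHits:
    def test_identical_sequences_full_identity_hit(self):
        prot = [
            ProteinRecord("SPA|g1", "SPA", "MKVLWAALLVTFLAGCQA" * 10),
            ProteinRecord("SPA|g2", "SPA", "MKVLWAALLVTFLAGCQA" * 10),
        ]
        hits = simulate_hits(prot)
        cross = [h for h in hits if not h.is_self]
        assert len(cross) == 2  # both directions
        assert cross[0].pct_identity == 100.0
        assert cross[0].evalue < 1e-50

    def test_unrelated_random_proteins_produce_no_passing_hit(self, rng):
        prots = [
            ProteinRecord(f"SPA|r{i}", "SPA", translate_cds(random_cds(300, rng)))
            for i in range(12)
        ]
        hits = simulate_hits(prots)
        lengths = {p.gene_id: len(p) for p in prots}
        assert filter_hits(hits, lengths) == []

    def test_deterministic_given_inputs(self, rng):
        a, b = simulate_codon_pair(150, 0.5, 0.1, 0.5, rng)
        prots = [
            ProteinRecord("SPA|g1", "SPA", translate_cds(a)),
            ProteinRecord("SPA|g2", "SPA", translate_cds(b)),
        ]
        assert simulate_hits(prots) == simulate_hits(prots)


class TestTwoSpeciesWorld:
    def test_truth_consistent_with_emitted_sequences(self):
        cfg = TwoSpeciesConfig(n_families=15)
        w = simulate_two_species_world(cfg, seed=4)
        gene_ids = {p.gene_id for p in w.proteins}
        assert set(w.coding) == gene_ids
        listed = {g for f in w.true_families for _, g in f.members}
        assert listed == gene_ids
        # every truth pair references emitted genes; orthologs split at speciation
        assert set(w.pair_truth["gene_a"]) <= gene_ids
        cross = w.pair_truth[w.pair_truth.species_a != w.pair_truth.species_b]
        assert (cross["divergence"] >= cfg.t_speciation - 1e-9).all()

    def test_same_seed_byte_identical(self):
        cfg = TwoSpeciesConfig(n_families=10)
        w1 = simulate_two_species_world(cfg, seed=8)
        w2 = simulate_two_species_world(cfg, seed=8)
        assert [p.sequence for p in w1.proteins] == [p.sequence for p in w2.proteins]
        assert w1.pair_truth.equals(w2.pair_truth)

    def test_pre_speciation_pairs_are_older(self):
        w = simulate_two_species_world(TwoSpeciesConfig(n_families=30), seed=6)
        within = w.pair_truth[w.pair_truth.species_a == w.pair_truth.species_b]
        old = within[within.pre_speciation]["divergence"]
        young = within[~within.pre_speciation]["divergence"]
        if len(old) and len(young):
            assert old.min() > young.max() - 1e-9


class TestPositions:
    def test_planted_arrays_recovered_exactly(self):
        w = simulate_two_species_world(TwoSpeciesConfig(n_families=25), seed=12)
        positions, planted = simulate_positions(w.true_families, "SPA", seed=13)
        called = call_tandem_arrays(positions, w.true_families)
        assert {t.members for t in called} == {m for _, m in planted}


class TestCounts:
    def test_null_recovery_at_fdr_level(self):
        from dupdyn.expression_filtering import bh_fdr, nb_mm_test

        counts, cond, true_de = simulate_counts(800, seed=21, de_fraction=0.0)
        assert true_de == set()
        res = nb_mm_test(counts, cond)
        assert bh_fdr(res["p"].to_numpy())["reject"].mean() < 0.02

    def test_planted_fold_change_recovered(self):
        from dupdyn.expression_filtering import de_call, nb_mm_test

        # means concentrated near 500 counts, the regime where a 4-fold
        # planted shift should be recovered almost completely
        counts, cond, true_de = simulate_counts(
            600, seed=22, de_fraction=0.10, log2_fc=2.0,
            mean_log_mu=6.2, sd_log_mu=0.3,
        )
        res = nb_mm_test(counts, cond)
        called = {c.gene for c in de_call(res) if c.is_de}
        recall = len(called & true_de) / len(true_de)
        assert recall >= 0.9

    def test_enriched_category_odds(self):
        genes = [f"g{i + 1:05d}" for i in range(3000)]
        cat = set(genes[:600])
        _, _, true_de = simulate_counts(
            3000, seed=23, de_fraction=0.05, categories={"c": cat},
            enrichment_odds=4.0,
        )
        in_rate = len(true_de & cat) / len(cat)
        out_rate = len(true_de - cat) / (len(genes) - len(cat))
        assert in_rate > 2 * out_rate
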