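"""Relatedness estimators, dyad simulation oracle checks, group tests."""
import numpy as np
import pytest

from gentag import simulate as sim
from gentag.dataset import allele_frequencies
from gentag.relatedness import (
    TRUE_R,
    _coded_loci,
    _dyadml_probs,
    _em_simplex,
    _encode,
    compare_estimators,
    dyadml,
    estimate_dyads,
    group_permutation_test,
    individual_inbreeding,
    pairwise_relatedness,
    population_mean_relatedness,
    simulate_dyads,
)
from tests.conftest import make_dataset


@pytest.fixture(scope="module")
def freqs(field_survey_freqs):
    return field_survey_freqs


class TestMomentEstimators:
    def test_qg_identical_heterozygotes_equifrequent(self):
        # two identical fully heterozygous genotypes, 4 equifrequent alleles:
        # per locus numerator = denominator = 1 - p_a - p_b, so r = 1
        g = np.array(
            [[[1, 2], [3, 4]], [[1, 2], [3, 4]], [[1, 3], [2, 4]], [[2, 4], [1, 3]],
             [[1, 4], [2, 3]], [[2, 3], [1, 4]], [[3, 4], [1, 2]], [[1, 2], [3, 4]]],
            np.int32,
        )
        ds = make_dataset(g)
        est = pairwise_relatedness(ds, "QG", pairs=[("s1", "s2")])
        assert est[0].r == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("estimator", ["QG", "LynchRD", "Wang"])
    @pytest.mark.parametrize("category", ["unrelated", "half_sib", "full_sib", "parent_offspring"])
    def test_mean_recovers_true_r(self, freqs, estimator, category):
        dyads = simulate_dyads(freqs, category, n_pairs=2000, seed=42)
        r = estimate_dyads(dyads, freqs, estimator)
        r = r[np.isfinite(r)]
        se = r.std(ddof=1) / np.sqrt(r.size)
        assert abs(r.mean() - TRUE_R[category]) < 3 * se + 1e-3

    def test_symmetric_in_pair_order(self, field_survey):
        sub = field_survey.subset(field_survey.sample_ids[:10])
        fwd = pairwise_relatedness(sub, "QG", pairs=[("s1" if False else sub.sample_ids[0], sub.sample_ids[1])])
        rev = pairwise_relatedness(sub, "QG", pairs=[(sub.sample_ids[1], sub.sample_ids[0])])
        assert fwd[0].r == pytest.approx(rev[0].r, abs=1e-12)


class TestDyadML:
    def test_clone_pair_r_near_one(self, field_survey):
        ds = field_survey.subset(field_survey.sample_ids[:2])
        g = ds.genotypes.copy()
        g[1] = g[0]
        from gentag.dataset import GenotypeDataset

        clone = GenotypeDataset(ds.loci, ds.samples, g)
        est = dyadml(clone, tuple(clone.sample_ids))
        assert est.r > 0.95

    def test_rare_shared_allele_parent_offspring_signal(self):
        # pair sharing exactly one rare allele per locus: ML lands near k1=1
        g = [[[1, 2], [1, 3]], [[1, 6], [1, 7]]]
        extra = [[[4, 4], [4, 4]]] * 96  # make alleles 1..3, 6, 7 rare
        ds = make_dataset(np.sort(np.array(g + extra, np.int32), axis=2))
        est = dyadml(ds, ("s1", "s2"))
        assert est.ibd[1] > 0.9  # k1
        assert est.r == pytest.approx(0.5, abs=0.06)

    def test_range_constraint(self, freqs):
        dyads = simulate_dyads(freqs, "unrelated", n_pairs=50, seed=3)
        r = estimate_dyads(dyads, freqs, "DyadML")
        assert np.all(r >= 0) and np.all(r <= 1)

    def test_em_matches_grid_search_likelihood(self, freqs):
        dyads = simulate_dyads(freqs, "half_sib", n_pairs=25, seed=9)
        coded = _coded_loci(dyads.locus_names, [dyads.genotypes_x, dyads.genotypes_y], freqs)
        gx = _encode(dyads.genotypes_x, coded)
        gy = _encode(dyads.genotypes_y, coded)
        grid = []
        step = 0.01
        for k2 in np.arange(0, 1 + 1e-9, step):
            for k1 in np.arange(0, 1 - k2 + 1e-9, step):
                grid.append((1 - k1 - k2, k1, k2))
        grid = np.clip(np.array(grid), 0.0, None)
        for i in range(gx.shape[0]):
            probs = _dyadml_probs(gx[i], gy[i], coded, False)
            w = _em_simplex(probs)
            ll_em = float(np.sum(np.log(probs @ w)))
            ll_grid = float(np.max(np.sum(np.log(grid @ probs.T + 1e-300), axis=1)))
            assert ll_em >= ll_grid - 1e-6

    def test_inbreeding_variant_valid_simplex(self, freqs):
        dyads = simulate_dyads(freqs, "full_sib", n_pairs=10, seed=5)
        r = estimate_dyads(dyads, freqs, "DyadML_F")
        assert np.all((r >= 0) & (r <= 1))


class TestSimulateDyads:
    def test_parent_offspring_share_allele_everywhere(self, freqs):
        dyads = simulate_dyads(freqs, "parent_offspring", n_pairs=200, seed=1)
        for i in range(200):
            for j in range(len(dyads.locus_names)):
                x = set(dyads.genotypes_x[i, j])
                y = set(dyads.genotypes_y[i, j])
                assert x & y, "parent and offspring must share an allele"

    def test_full_sib_ibd_class_frequencies(self, freqs):
        # verify Mendelian machinery via a perfectly informative marker set:
        # unique parental alleles let IBD state be read off the genotypes
        from gentag.dataset import AlleleFrequencyTable, POOLED

        table = AlleleFrequencyTable()
        table.freqs[(POOLED, "L1")] = {a: 0.25 for a in (1, 2, 3, 4)}
        table.n_genes[(POOLED, "L1")] = 4000
        rng_counts = np.zeros(3)
        dyads = simulate_dyads(table, "full_sib", n_pairs=20_000, seed=2)
        gx, gy = dyads.genotypes_x[:, 0], dyads.genotypes_y[:, 0]
        shared = (gx[:, 0] == gy[:, 0]).astype(int) + (gx[:, 1] == gy[:, 1]).astype(int)
        # with 4 equifrequent alleles some sharing is by state, not descent,
        # so compare against the analytic expectation instead of (.25,.5,.25)
        counts = np.bincount(shared, minlength=3) / shared.size
        # expected P(identical genotype) for FS at 4 equifrequent alleles
        # derived by enumeration over IBD classes:
        # P2=1; P1=a2=0.25; P0=2*a2^2-a4 = 0.109375
        p_identical = 0.25 * 1 + 0.5 * 0.25 + 0.25 * (2 * 0.25**2 - 4 * 0.25**4)
        assert counts[2] == pytest.approx(p_identical, abs=0.01)

    def test_seed_reproducibility(self, freqs):
        d1 = simulate_dyads(freqs, "full_sib", 50, seed=7)
        d2 = simulate_dyads(freqs, "full_sib", 50, seed=7)
        assert np.array_equal(d1.genotypes_x, d2.genotypes_x)
        assert np.array_equal(d1.genotypes_y, d2.genotypes_y)


class TestCompareEstimators:
    def test_many_loci_high_correlation_and_determinism(self):
        rng = np.random.default_rng(0)
        loci, labels, anc = sim.ancestral_frequencies(rng, n_loci=400, alpha=1.0)
        from gentag.dataset import AlleleFrequencyTable, POOLED

        table = AlleleFrequencyTable()
        for l, lab, f in zip(loci, labels, anc):
            table.freqs[(POOLED, l.name)] = dict(zip(lab.astype(int), f))
            table.n_genes[(POOLED, l.name)] = 10_000
        rep = compare_estimators(table, n_pairs=40, seed=5)
        rep2 = compare_estimators(table, n_pairs=40, seed=5)
        assert rep == rep2
        for est, info in rep["estimators"].items():
            assert info["pearson_r"] > 0.95, est

    def test_single_diallelic_locus_degrades(self):
        from gentag.dataset import AlleleFrequencyTable, POOLED

        table = AlleleFrequencyTable()
        table.freqs[(POOLED, "L1")] = {1: 0.5, 2: 0.5}
        table.n_genes[(POOLED, "L1")] = 1000
        rep = compare_estimators(table, n_pairs=100, seed=1, estimators=("QG",))
        assert rep["estimators"]["QG"]["pearson_r"] < 0.6


class TestGroupPermutationTest:
    def test_clone_dataset_p_one(self, field_survey, freqs):
        # every individual identical: observed equals every null value, so
        # shuffling is a no-op and p = 1 (reference frequencies from the
        # wider sample, since a pure-clone panel defines no internal ones)
        from gentag.dataset import GenotypeDataset, SampleMetadata

        g = np.tile(field_survey.genotypes[:1], (12, 1, 1))
        samples = [SampleMetadata(sample_id=f"c{i}") for i in range(12)]
        ds = GenotypeDataset(field_survey.loci, samples, g)
        groups = {"g1": ds.sample_ids[:4], "g2": ds.sample_ids[4:8], "g3": ds.sample_ids[8:]}
        res = group_permutation_test(ds, groups, "QG", iterations=50, seed=0, freqs=freqs)
        assert res.p_overall == pytest.approx(1.0)

    def test_sib_groups_detected(self, freqs):
        ds, _ = sim.simulate_kin_groups(freqs, [("full_sib", 4)] * 8, background_n=0, seed=3)
        groups = {}
        for s in ds.samples:
            groups.setdefault(s.group_id, []).append(s.sample_id)
        res = group_permutation_test(ds, groups, "LynchRD", iterations=200, seed=4)
        assert res.p_overall == pytest.approx(1 / 201)
        assert res.observed_overall > res.expected_overall + 0.2

    def test_invariant_to_group_relabeling(self, freqs):
        ds, _ = sim.simulate_kin_groups(freqs, [("unrelated", 3)] * 6, seed=5)
        groups = {}
        for s in ds.samples:
            groups.setdefault(s.group_id, []).append(s.sample_id)
        res1 = group_permutation_test(ds, groups, "QG", iterations=100, seed=6)
        renamed = {f"x_{k}": v for k, v in groups.items()}
        res2 = group_permutation_test(ds, renamed, "QG", iterations=100, seed=6)
        assert res1.p_overall == res2.p_overall
        assert res1.observed_overall == pytest.approx(res2.observed_overall)

    def test_singleton_group_excluded_with_warning(self, freqs):
        ds, _ = sim.simulate_kin_groups(freqs, [("unrelated", 3)] * 3, seed=7)
        groups = {}
        for s in ds.samples:
            groups.setdefault(s.group_id, []).append(s.sample_id)
        groups["lonely"] = [ds.sample_ids[0]]
        del groups["G001"]
        ds2 = ds.drop(set(ds.sample_ids) - {m for v in groups.values() for m in v})
        with pytest.warns(UserWarning, match="size < 2"):
            res = group_permutation_test(ds2, groups, "QG", iterations=20, seed=1)
        assert "lonely" in res.excluded_groups

    def test_null_distribution_length(self, freqs):
        ds, _ = sim.simulate_kin_groups(freqs, [("unrelated", 3)] * 4, seed=8)
        groups = {}
        for s in ds.samples:
            groups.setdefault(s.group_id, []).append(s.sample_id)
        res = group_permutation_test(ds, groups, "QG", iterations=77, seed=2)
        assert res.null_distribution.shape == (77,)


class TestIndividualInbreeding:
    def test_all_heterozygous_f_zero(self, field_survey):
        sub = field_survey.subset(field_survey.sample_ids[:5])
        g = sub.genotypes.copy()
        # make first individual heterozygous everywhere
        for j in range(sub.n_loci):
            a = g[:, j].ravel()
            vals = np.unique(a[a > 0])[:2]
            g[0, j] = vals if len(vals) == 2 else [vals[0], vals[0] + 2]
        from gentag.dataset import GenotypeDataset

        ds = GenotypeDataset(sub.loci, sub.samples, np.sort(g, axis=2))
        out = individual_inbreeding(ds)
        assert out["individual_F"][ds.sample_ids[0]] == pytest.approx(0.0, abs=1e-6)

    def test_selfed_offspring_recovery(self, freqs):
        # selfing one parent gives offspring with true F = 0.5
        rng = np.random.default_rng(10)
        loci = freqs.loci()
        n = 200
        g = np.zeros((n, len(loci), 2), np.int32)
        from gentag.dataset import POOLED

        for j, locus in enumerate(loci):
            d = freqs.frequencies(POOLED, locus)
            lab = np.array(sorted(d))
            p = np.array([d[int(a)] for a in lab])
            p = p / p.sum()
            parents = np.stack(
                [rng.choice(lab, n, p=p), rng.choice(lab, n, p=p)], axis=1
            )
            picks = rng.integers(0, 2, size=(n, 2))
            g[:, j, 0] = parents[np.arange(n), picks[:, 0]]
            g[:, j, 1] = parents[np.arange(n), picks[:, 1]]
        from gentag.dataset import Locus

        ds = make_dataset(np.sort(g, axis=2), loci=[Locus(n_) for n_ in loci])
        out = individual_inbreeding(ds, freqs)
        mean_f = np.mean(list(out["individual_F"].values()))
        assert mean_f == pytest.approx(0.5, abs=0.1)

    def test_degenerate_group_correlation_flagged(self, freqs):
        g = np.tile(np.array([[100, 104]], np.int32), (6, 1, 1))
        ds = make_dataset(g)
        groups = {"g1": ds.sample_ids[:3], "g2": ds.sample_ids[3:]}
        out = individual_inbreeding(ds, groups=groups)
        assert np.isnan(out["r_vs_F"]["spearman_rho"])


class TestPopulationMeanRelatedness:
    def test_single_population_envelope_undefined(self, freqs):
        ds, _ = sim.simulate_kin_groups(freqs, [("unrelated", 5)], seed=2)
        out = population_mean_relatedness(ds, n_bootstrap=50, n_permutations=10, seed=0)
        info = out["NEA"]
        assert np.isnan(info["null_95"]) and not info["significant"]
        assert info["ci"][0] <= info["mean_r"] <= info["ci"][1]

    def test_sib_population_flagged(self, freqs):
        ds, _ = sim.simulate_kin_groups(freqs, [("full_sib", 10)], background_n=30, seed=4)
        # relabel: sib family = popA, background = popB
        for s in ds.samples:
            s.population = "popA" if s.group_id else "popB"
        from gentag.dataset import GenotypeDataset

        ds = GenotypeDataset(ds.loci, ds.samples, ds.genotypes)
        out = population_mean_relatedness(ds, n_bootstrap=100, n_permutations=99, seed=1)
        assert out["popA"]["significant"]
        assert out["popA"]["mean_r"] > out["popB"]["mean_r"]
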