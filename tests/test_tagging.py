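"""Probability of identity, genotype matching, dedup and re-encounters."""
import datetime

import numpy as np
import pytest

from gentag import simulate as sim
from gentag.dataset import (
    MISSING,
    POOLED,
    GenotypeDataset,
    Locus,
    SampleMetadata,
    allele_frequencies,
)
from gentag.tagging import (
    ErrorRateReport,
    classify_reencounters,
    count_mismatches,
    deduplicate,
    find_matches,
    genotyping_error_rate,
    haversine_km,
    pid,
)
from tests.conftest import make_dataset


def _freqs_for(genotypes):
    return allele_frequencies(make_dataset(genotypes))


class TestPid:
    def test_two_equifrequent_alleles_enumeration(self):
        # p = q = 0.5: genotype probs (0.25, 0.5, 0.25); sum of squares 0.375
        freqs = _freqs_for([[[1, 1]], [[2, 2]], [[1, 2]], [[1, 2]]])
        res = pid(freqs)
        assert res.pid_biased["L1"] == pytest.approx(0.375)
        assert res.pid_sibs["L1"] == pytest.approx(0.59375)

    def test_monomorphic_locus_is_one(self):
        freqs = _freqs_for([[[7, 7]]] * 5)
        res = pid(freqs)
        assert res.pid_biased["L1"] == pytest.approx(1.0)
        assert res.pid_sibs["L1"] == pytest.approx(1.0)

    def test_multilocus_is_product(self):
        freqs = _freqs_for(
            [[[1, 1], [1, 1]], [[2, 2], [2, 2]], [[1, 2], [1, 2]], [[1, 2], [1, 2]]]
        )
        res = pid(freqs)
        assert res.multilocus_sibs == pytest.approx(0.59375**2)

    def test_unbiased_converges_to_biased(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            p = rng.dirichlet(np.ones(6))
            from gentag.tagging import _pid_locus

            biased, unbiased, _ = _pid_locus(p, 10_000)
            assert unbiased == pytest.approx(biased, rel=0.01)

    def test_sibs_at_least_unbiased(self, field_survey_freqs):
        res = pid(field_survey_freqs)
        assert res.multilocus_sibs >= res.multilocus_unbiased
        for locus in res.loci:
            assert res.pid_sibs[locus] >= res.pid_unbiased[locus]

    def test_tiny_sample_excluded_with_warning(self):
        freqs = _freqs_for([[[1, 2]]])
        with pytest.warns(UserWarning, match="excluded"):
            res = pid(freqs)
        assert res.excluded_loci == ["L1"]


class TestCountMismatches:
    def test_identical_panels(self):
        g = np.tile([100, 104], (19, 1))
        assert count_mismatches(g, g) == (19, 0)

    def test_two_mismatching_loci(self):
        g1 = np.tile([100, 104], (19, 1))
        g2 = g1.copy()
        g2[3] = [100, 100]
        g2[7] = [96, 98]
        assert count_mismatches(g1, g2) == (19, 2)

    def test_missing_loci_excluded(self):
        g1 = np.tile([100, 104], (5, 1))
        g2 = g1.copy()
        g2[0] = [MISSING, MISSING]
        assert count_mismatches(g1, g2) == (4, 0)

    def test_allele_order_irrelevant(self):
        g1 = np.array([[104, 100]])
        g2 = np.array([[100, 104]])
        assert count_mismatches(g1, g2) == (1, 0)


class TestFindMatches:
    def test_injected_duplicate_found_exactly_once(self, field_survey):
        base = field_survey.subset(field_survey.sample_ids[:80])
        merged, truth = sim.inject_recaptures(base, 1, seed=0)
        matches = find_matches(merged)
        assert len(matches) == 1
        assert {matches[0].sample_id_1, matches[0].sample_id_2} == set(truth[0])
        assert matches[0].classification == "exact"

    def test_dropout_duplicate_near_match_with_loci_listed(self, field_survey):
        base = field_survey.subset(field_survey.sample_ids[:50])
        copy = base.subset([base.sample_ids[0]])
        g = copy.genotypes.copy()
        # force dropout at the first two heterozygous loci
        hets = np.nonzero(g[0, :, 0] != g[0, :, 1])[0][:2]
        for j in hets:
            g[0, j] = [g[0, j, 0], g[0, j, 0]]
        dup = GenotypeDataset(
            base.loci, [SampleMetadata(sample_id="dup")], np.sort(g, axis=2)
        )
        merged = GenotypeDataset(
            base.loci,
            base.samples + dup.samples,
            np.concatenate([base.genotypes, dup.genotypes]),
        )
        matches = find_matches(merged)
        rec = [m for m in matches if "dup" in (m.sample_id_1, m.sample_id_2)]
        assert len(rec) == 1
        assert rec[0].classification == "near_match"
        assert set(rec[0].mismatch_loci) == {base.locus_names[j] for j in hets}
        assert rec[0].mismatch_kinds == ["false_homozygote"] * 2

    def test_beyond_threshold_not_reported(self):
        g1 = np.tile([100, 104], (19, 1))
        g2 = g1.copy()
        g2[:4] = [90, 92]
        ds = make_dataset(np.stack([g1, g2]).reshape(2, 19, 2))
        assert find_matches(ds, max_mismatch=3) == []

    def test_symmetric_and_order_invariant(self, field_survey):
        base = field_survey.subset(field_survey.sample_ids[:60])
        merged, _ = sim.inject_recaptures(base, 5, seed=1)
        fwd = find_matches(merged)
        rev = find_matches(merged.subset(list(reversed(merged.sample_ids))))
        pairs_f = {frozenset((m.sample_id_1, m.sample_id_2)) for m in fwd}
        pairs_r = {frozenset((m.sample_id_1, m.sample_id_2)) for m in rev}
        assert pairs_f == pairs_r


class TestDeduplicate:
    def _pair(self, missing_in_second=3, dates=(None, None)):
        g1 = np.tile([100, 104], (10, 1))[None]
        g2 = g1.copy()
        g2[0, :missing_in_second] = MISSING
        samples = [
            SampleMetadata(sample_id="a", date=dates[0]),
            SampleMetadata(sample_id="b", date=dates[1]),
        ]
        return GenotypeDataset(
            [Locus(f"L{j}") for j in range(10)], samples, np.concatenate([g1, g2])
        )

    def test_more_complete_genotype_retained(self):
        ds = self._pair(missing_in_second=3)
        out, removed = deduplicate(ds, find_matches(ds))
        assert removed == ["b"] and out.sample_ids == ["a"]

    def test_tie_broken_by_earlier_date(self):
        ds = self._pair(
            missing_in_second=0,
            dates=(datetime.date(2010, 6, 1), datetime.date(2009, 6, 1)),
        )
        out, removed = deduplicate(ds, find_matches(ds))
        assert out.sample_ids == ["b"]

    def test_no_matches_leaves_dataset(self, field_survey):
        sub = field_survey.subset(field_survey.sample_ids[:30])
        out, removed = deduplicate(sub, find_matches(sub))
        assert out.equals(sub) and removed == []

    def test_non_clique_component_warns_but_resolves(self):
        g = np.tile([100, 104], (8, 1))
        ga, gb, gc = g.copy(), g.copy(), g.copy()
        gb[:2] = [100, 100]  # B ~2 mismatches from A
        gc[2:6] = [90, 90]  # C far from A but...
        gc[:2] = [100, 100]  # near B? construct A-B near, B-C near, A-C far
        gb[2:4] = [90, 90]
        ds = make_dataset(np.stack([ga, gb, gc]), ids=["A", "B", "C"])
        matches = find_matches(ds, max_mismatch=4)
        if len({frozenset((m.sample_id_1, m.sample_id_2)) for m in matches}) < 3:
            with pytest.warns(UserWarning, match="clique"):
                out, _ = deduplicate(ds, matches)
            assert out.n_samples == 1


class TestReencounters:
    def _two(self, d1, d2, coords=None, sites=("S", "S")):
        c1 = coords[0] if coords else (None, None)
        c2 = coords[1] if coords else (None, None)
        samples = [
            SampleMetadata(sample_id="a", date=d1, latitude=c1[0], longitude=c1[1], site=sites[0]),
            SampleMetadata(sample_id="b", date=d2, latitude=c2[0], longitude=c2[1], site=sites[1]),
        ]
        g = np.tile([100, 104], (19, 1))
        ds = GenotypeDataset(
            [Locus(f"L{j}") for j in range(19)], samples, np.stack([g, g])
        )
        return classify_reencounters(find_matches(ds), ds)

    @pytest.mark.parametrize(
        "d1,d2,expected_days",
        [
            ("07.08.2009", "26.06.2010", 323),
            ("09.08.2009", "04.06.2013", 1395),
            ("26.06.2010", "09.08.2012", 775),
            ("08.08.2012", "18.07.2013", 344),
        ],
    )
    def test_field_date_intervals(self, d1, d2, expected_days):
        from gentag.dataset import parse_date

        recs = self._two(parse_date(d1), parse_date(d2))
        assert recs[0].interval_days == expected_days
        assert recs[0].category == "inter_annual_same_site"

    def test_same_day_same_site(self):
        d = datetime.date(2012, 7, 1)
        recs = self._two(d, d)
        assert recs[0].interval_days == 0
        assert recs[0].category == "within_season_same_site"

    def test_distance_drives_site_assignment(self):
        recs = self._two(
            datetime.date(2010, 6, 1),
            datetime.date(2011, 6, 1),
            coords=[(54.0, -4.5), (57.5, -6.2)],  # Irish Sea vs West Scotland
        )
        assert recs[0].distance_km > 100
        assert recs[0].category == "inter_annual_different_site"

    def test_missing_date_unknown_category(self):
        recs = self._two(None, datetime.date(2011, 6, 1))
        assert recs[0].category == "unknown"

    def test_haversine_known_distance(self):
        # one degree of latitude ~ 111.2 km
        assert haversine_km(54.0, -4.5, 55.0, -4.5) == pytest.approx(111.19, abs=0.1)


class TestGenotypingErrorRate:
    def test_field_scale_counts(self):
        # 1635 replicated single-locus genotypes with 16 mismatches
        rng = np.random.default_rng(0)
        n_ind, n_loci = 87, 19
        g = np.sort(rng.choice([1, 2, 3, 4], size=(n_ind, n_loci, 2)), axis=2).astype(np.int32)
        original = make_dataset(g)
        rep = g.copy()
        flat = [(i, j) for i in range(n_ind) for j in range(n_loci)]
        keep = rng.choice(len(flat), size=1635, replace=False)
        mask = np.ones((n_ind, n_loci), bool)
        for k in keep:
            mask[flat[k]] = False
        rep_missing = rep.copy()
        rep_missing[mask] = MISSING
        wrong = rng.choice(keep, size=16, replace=False)
        for k in wrong:
            i, j = flat[k]
            rep_missing[i, j] = [9, 9]
        replicate = make_dataset(np.sort(rep_missing, axis=2))
        report = genotyping_error_rate(original, replicate)
        assert report.n_replicated == 1635
        assert report.n_mismatching == 16
        assert report.mean_rate == pytest.approx(16 / 1635)
        # printed to 4 d.p. (truncated) this is the familiar 0.0097
        assert int(report.mean_rate * 10_000) == 97

    def test_identical_replicates_zero(self, field_survey):
        sub = field_survey.subset(field_survey.sample_ids[:20])
        report = genotyping_error_rate(sub, sub)
        assert report.mean_rate == 0.0
        assert all(v == 0.0 for v in report.per_locus_rate.values())

    def test_per_locus_arithmetic(self):
        g = np.tile([1, 2], (100, 1))[:, None, :]
        original = make_dataset(g)
        rep = g.copy()
        rep[:2, 0] = [1, 1]
        replicate = make_dataset(rep)
        report = genotyping_error_rate(original, replicate)
        assert report.per_locus_rate["L1"] == pytest.approx(0.02)
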