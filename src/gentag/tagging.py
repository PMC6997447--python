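"""Genetic tagging: probability of identity, genotype matching and
re-encounter classification.

A multilocus microsatellite genotype serves as a permanent individual tag.
Two samples whose genotypes match exactly, or nearly (a small number of
mismatching loci attributable to genotyping error), are inferred to be the
same individual re-encountered. Probability-of-identity statistics bound the
chance that two *different* individuals share a genotype: P_ID for random
pairs (optimistic) and P_ID(sibs) for full siblings (conservative).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .dataset import MISSING, POOLED, AlleleFrequencyTable, GenotypeDataset

EARTH_RADIUS_KM = 6371.0088  # mean Earth radius


# -- probability of identity ----------------------------------------------

@dataclass
class PidResult:
    """Per-locus and multilocus probability-of-identity statistics."""

    loci: list[str]
    pid_biased: dict[str, float]
    pid_unbiased: dict[str, float]
    pid_sibs: dict[str, float]
    excluded_loci: list[str] = field(default_factory=list)

    @property
    def multilocus_unbiased(self) -> float:
        return float(np.prod([self.pid_unbiased[l] for l in self.loci]))

    @property
    def multilocus_sibs(self) -> float:
        return float(np.prod([self.pid_sibs[l] for l in self.loci]))


def _pid_locus(p: np.ndarray, n_genes: int) -> tuple[float, float, float]:
    a2 = float(np.sum(p**2))
    a3 = float(np.sum(p**3))
    a4 = float(np.sum(p**4))
    biased = 2.0 * a2**2 - a4  # sum over genotypes of P(genotype)^2
    n = n_genes
    # small-sample unbiased estimator (Kendall-Stuart moments, as used for
    # P_ID(unbiased) in standard microsatellite toolkits)
    unbiased = (
        n**3 * (2 * a2**2 - a4)
        - 2 * n**2 * (a3 + 2 * a2)
        + n * (9 * a2 + 2)
        - 6
    ) / ((n - 1.0) * (n - 2.0) * (n - 3.0))
    sibs = 0.25 + 0.5 * a2 + 0.5 * a2**2 - 0.25 * a4
    return biased, unbiased, sibs


def pid(freqs: AlleleFrequencyTable, population: str = POOLED) -> PidResult:
    """Probability of identity per locus and multilocus (product over loci).

    Loci with fewer than 4 typed genes are excluded (the unbiased estimator
    divides by n(n-1)(n-2)(n-3)) with a warning.
    """
    result = PidResult(loci=[], pid_biased={}, pid_unbiased={}, pid_sibs={})
    for locus in freqs.loci():
        d = freqs.frequencies(population, locus)
        n = freqs.genes(population, locus)
        if not d:
            continue
        if n < 4:
            warnings.warn(f"locus {locus}: n_genes={n} < 4, excluded from P_ID")
            result.excluded_loci.append(locus)
            continue
        p = np.array(list(d.values()))
        b, u, s = _pid_locus(p, n)
        result.loci.append(locus)
        result.pid_biased[locus] = b
        result.pid_unbiased[locus] = u
        result.pid_sibs[locus] = s
    return result


# -- matching --------------------------------------------------------------

@dataclass
class MatchRecord:
    sample_id_1: str
    sample_id_2: str
    loci_compared: int
    loci_mismatching: int
    classification: str  # exact | near_match | non_match
    mismatch_loci: list[str] = field(default_factory=list)
    mismatch_kinds: list[str] = field(default_factory=list)  # per mismatching locus


def count_mismatches(
    calls_1: np.ndarray, calls_2: np.ndarray
) -> tuple[int, int]:
    """Compare two canonical call vectors of shape (n_loci, 2).

    Loci missing in either sample are excluded from the comparison; a locus
    mismatches iff the unordered allele pairs differ (one- and two-allele
    differences both count as one mismatching locus).
    """
    c1 = np.sort(np.asarray(calls_1), axis=-1)
    c2 = np.sort(np.asarray(calls_2), axis=-1)
    if c1.shape != c2.shape:
        raise ValueError("call vectors must cover the same locus panel")
    typed = (c1[:, 0] != MISSING) & (c2[:, 0] != MISSING)
    if not typed.any():
        return 0, 0
    diff = (c1[:, 0] != c2[:, 0]) | (c1[:, 1] != c2[:, 1])
    return int(typed.sum()), int((diff & typed).sum())


def _mismatch_kind(a: tuple[int, int], b: tuple[int, int]) -> str:
    """Classify a mismatching locus for dropout/null-allele review.

    ``false_homozygote``: one call homozygous for an allele carried by the
    other (classic allelic-dropout signature); otherwise ``different_alleles``.
    """
    ha, hb = a[0] == a[1], b[0] == b[1]
    if ha and not hb and a[0] in b:
        return "false_homozygote"
    if hb and not ha and b[0] in a:
        return "false_homozygote"
    return "different_alleles"


def find_matches(
    dataset: GenotypeDataset, max_mismatch: int = 3, min_loci_compared: int = 1
) -> list[MatchRecord]:
    """Evaluate all unordered sample pairs; return exact and near matches.

    exact = 0 mismatching loci; near_match = 1..max_mismatch. Non-matching
    pairs are not returned (there are O(n^2) of them). Near matches are
    annotated with the mismatching loci and a dropout-forensics kind.
    """
    g = dataset.genotypes
    n, L, _ = g.shape
    typed = g[:, :, 0] != MISSING
    ids = dataset.sample_ids
    records: list[MatchRecord] = []
    for i in range(n - 1):
        both = typed[i] & typed[i + 1 :]
        diff = (g[i, :, 0] != g[i + 1 :, :, 0]) | (g[i, :, 1] != g[i + 1 :, :, 1])
        mism = (diff & both).sum(axis=1)
        compared = both.sum(axis=1)
        hits = np.nonzero((mism <= max_mismatch) & (compared >= min_loci_compared))[0]
        for h in hits:
            k = i + 1 + int(h)
            m = int(mism[h])
            rec = MatchRecord(
                sample_id_1=ids[i],
                sample_id_2=ids[k],
                loci_compared=int(compared[h]),
                loci_mismatching=m,
                classification="exact" if m == 0 else "near_match",
            )
            if m:
                where = np.nonzero(diff[h] & both[h])[0]
                rec.mismatch_loci = [dataset.locus_names[j] for j in where]
                rec.mismatch_kinds = [
                    _mismatch_kind(tuple(g[i, j]), tuple(g[k, j])) for j in where
                ]
            records.append(rec)
    return records


def deduplicate(
    dataset: GenotypeDataset, matches: list[MatchRecord]
) -> tuple[GenotypeDataset, list[str]]:
    """Keep one member of each matched component; return (dataset, removal log).

    The retained member is the least degraded genotype (fewest missing loci);
    ties break to the earlier sampling date, then lexicographic id. A
    contradictory match graph (A~B, B~C but A vs C beyond threshold) keeps
    the component with a warning and still retains its best member.
    """
    graph = nx.Graph()
    matched = [m for m in matches if m.classification in ("exact", "near_match")]
    graph.add_edges_from((m.sample_id_1, m.sample_id_2) for m in matched)
    edge = {
        frozenset((m.sample_id_1, m.sample_id_2)): m.loci_mismatching for m in matched
    }
    miss = dict(zip(dataset.sample_ids, dataset.missing_per_sample()))
    removed: list[str] = []
    for comp in nx.connected_components(graph):
        members = sorted(comp)
        for a in members:
            for b in members:
                if a < b and frozenset((a, b)) not in edge:
                    warnings.warn(
                        f"match component {members} is not a clique "
                        f"({a} vs {b} beyond threshold); keeping best member"
                    )
        def sort_key(sid: str):
            meta = dataset.metadata(sid)
            date = meta.date.toordinal() if meta.date else np.inf
            return (miss[sid], date, sid)
        keep = min(members, key=sort_key)
        removed.extend(s for s in members if s != keep)
    removed = [s for s in dataset.sample_ids if s in set(removed)]
    return (dataset.drop(removed) if removed else dataset), removed


# -- re-encounters ---------------------------------------------------------

@dataclass
class ReencounterRecord:
    sample_id_1: str
    sample_id_2: str
    interval_days: int | None
    distance_km: float | None
    category: str  # within_season_same_site | inter_annual_same_site |
    #               inter_annual_different_site | unknown


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km (mean Earth radius)."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


def equirectangular_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Planar (euclidean-on-projection) approximation, for reproduction only."""
    phi = math.radians((lat1 + lat2) / 2)
    x = math.radians(lon2 - lon1) * math.cos(phi)
    y = math.radians(lat2 - lat1)
    return EARTH_RADIUS_KM * math.hypot(x, y)


def classify_reencounters(
    matches: list[MatchRecord],
    dataset: GenotypeDataset,
    site_radius_km: float = 20.0,
    distance: str = "haversine",
) -> list[ReencounterRecord]:
    """Classify confirmed matches into site-fidelity categories.

    within_season = same calendar year; inter_annual = different years;
    same site = sampling points within ``site_radius_km`` (or identical
    site labels when coordinates are unavailable).
    """
    dist_fn = haversine_km if distance == "haversine" else equirectangular_km
    out: list[ReencounterRecord] = []
    for m in matches:
        if m.classification not in ("exact", "near_match"):
            continue
        m1 = dataset.metadata(m.sample_id_1)
        m2 = dataset.metadata(m.sample_id_2)
        d_km: float | None = None
        if None not in (m1.latitude, m1.longitude, m2.latitude, m2.longitude):
            d_km = dist_fn(m1.latitude, m1.longitude, m2.latitude, m2.longitude)
        if m1.date is None or m2.date is None:
            out.append(ReencounterRecord(m.sample_id_1, m.sample_id_2, None, d_km, "unknown"))
            continue
        interval = abs((m2.date - m1.date).days)
        if d_km is not None:
            same_site = d_km <= site_radius_km
        else:
            same_site = (m1.site is not None) and (m1.site == m2.site)
        if m1.date.year == m2.date.year:
            category = "within_season_same_site" if same_site else "inter_annual_different_site"
            if not same_site:
                category = "within_season_different_site"
        else:
            category = "inter_annual_same_site" if same_site else "inter_annual_different_site"
        out.append(
            ReencounterRecord(m.sample_id_1, m.sample_id_2, interval, d_km, category)
        )
    return out


# -- replicate-based genotyping error rate ---------------------------------

@dataclass
class ErrorRateReport:
    per_locus_rate: dict[str, float]
    per_locus_counts: dict[str, tuple[int, int]]  # (mismatching, replicated)
    mean_rate: float
    n_mismatching: int
    n_replicated: int


def genotyping_error_rate(
    original: GenotypeDataset, replicate: GenotypeDataset
) -> ErrorRateReport:
    """Error rate from re-amplified samples.

    A single-locus genotype is *replicated* iff typed in both runs; it
    *mismatches* iff the unordered allele pairs differ (at least one allelic
    mismatch). The mean rate is total mismatching / total replicated.
    """
    shared = [s for s in replicate.sample_ids if s in set(original.sample_ids)]
    if not shared:
        raise ValueError("replicate dataset shares no samples with the original")
    loci = [l for l in replicate.locus_names if l in set(original.locus_names)]
    if not loci:
        raise ValueError("replicate dataset shares no loci with the original")
    oi = [original.index_of(s) for s in shared]
    ri = [replicate.index_of(s) for s in shared]
    oj = [original.locus_names.index(l) for l in loci]
    rj = [replicate.locus_names.index(l) for l in loci]
    g1 = original.genotypes[np.ix_(oi, oj)]
    g2 = replicate.genotypes[np.ix_(ri, rj)]
    both = (g1[:, :, 0] != MISSING) & (g2[:, :, 0] != MISSING)
    if not both.any():
        raise ValueError("no overlapping typed single-locus genotypes")
    diff = ((g1[:, :, 0] != g2[:, :, 0]) | (g1[:, :, 1] != g2[:, :, 1])) & both
    per_rate: dict[str, float] = {}
    per_counts: dict[str, tuple[int, int]] = {}
    for j, locus in enumerate(loci):
        n_rep = int(both[:, j].sum())
        n_mis = int(diff[:, j].sum())
        per_counts[locus] = (n_mis, n_rep)
        if n_rep:
            per_rate[locus] = n_mis / n_rep
    n_mis_total = int(diff.sum())
    n_rep_total = int(both.sum())
    return ErrorRateReport(
        per_locus_rate=per_rate,
        per_locus_counts=per_counts,
        mean_rate=n_mis_total / n_rep_total,
        n_mismatching=n_mis_total,
        n_replicated=n_rep_total,
    )
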