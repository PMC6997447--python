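"""Diversity statistics, exact Hardy-Weinberg and linkage-disequilibrium
tests, null-allele screening and multiple-testing adjustment.

Conventions follow the common microsatellite toolchain: unbiased expected
heterozygosity H_E = (2n/(2n-1))(1 - sum p^2); F_IS = (H_E - H_O)/H_E per
locus averaged over loci; allelic richness by rarefaction to a common number
of sampled genes.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .dataset import (
    MISSING,
    POOLED,
    AlleleFrequencyTable,
    GenotypeDataset,
    allele_frequencies,
)


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_permutations_or_iterations: int = 0
    se: float | None = None
    applicable: bool = True
    note: str = ""


# -- diversity -------------------------------------------------------------

@dataclass
class DiversitySummary:
    """Per-(population, locus) diversity table plus per-population means/SEs.

    ``per_locus[pop]`` is a dict locus -> dict of statistics; ``means[pop]``
    and ``se[pop]`` aggregate across loci (SE = sd / sqrt(n_loci_defined)).
    """

    per_locus: dict[str, dict[str, dict[str, float]]]
    means: dict[str, dict[str, float]]
    se: dict[str, dict[str, float]]

    def table(self):
        import pandas as pd

        rows = []
        for pop, stats in self.means.items():
            row = {"population": pop}
            row.update(stats)
            rows.append(row)
        return pd.DataFrame(rows)


def _locus_stats(geno: np.ndarray) -> dict[str, float] | None:
    """Stats for one population x locus block of canonical calls (n, 2)."""
    typed = geno[:, 0] != MISSING
    g = geno[typed]
    n = g.shape[0]
    if n == 0:
        return None
    alleles, counts = np.unique(g.ravel(), return_counts=True)
    p = counts / counts.sum()
    h_o = float(np.mean(g[:, 0] != g[:, 1]))
    sum_p2 = float(np.sum(p**2))
    h_e_raw = 1.0 - sum_p2
    stats = {
        "N": float(n),
        "N_dA": float(len(alleles)),
        "N_E": 1.0 / sum_p2,
        "H_O": h_o,
    }
    if n >= 2:
        h_e = (2 * n / (2 * n - 1)) * h_e_raw
        stats["H_E"] = h_e
        stats["F_IS"] = (h_e - h_o) / h_e if h_e > 0 else np.nan
    return stats


def diversity_summary(
    dataset: GenotypeDataset, grouping: str = "population", g_genes: int = 14
) -> DiversitySummary:
    """Table-style diversity summary per population.

    Includes N, N_dA (different alleles), N_E (effective alleles), H_O,
    unbiased H_E, F_IS, private alleles P_A (defined only with >=2
    populations) and allelic richness A_R rarefied to ``g_genes`` genes.
    """
    pops = dataset.populations if grouping == "population" else [POOLED]
    labels = dataset.population_labels()
    richness = allelic_richness(dataset, g_genes=g_genes) if grouping == "population" else {}

    # which alleles occur in which populations (for private alleles)
    occurrence: dict[str, dict[int, set[str]]] = {l: {} for l in dataset.locus_names}
    if len(pops) > 1:
        for pop in pops:
            sub = dataset.genotypes[labels == pop]
            for j, locus in enumerate(dataset.locus_names):
                a = sub[:, j, :].ravel()
                for al in np.unique(a[a != MISSING]):
                    occurrence[locus].setdefault(int(al), set()).add(pop)

    per_locus: dict[str, dict[str, dict[str, float]]] = {}
    means: dict[str, dict[str, float]] = {}
    ses: dict[str, dict[str, float]] = {}
    for pop in pops:
        mask = labels == pop if pop != POOLED else np.ones(dataset.n_samples, bool)
        sub = dataset.genotypes[mask]
        per_locus[pop] = {}
        for j, locus in enumerate(dataset.locus_names):
            stats = _locus_stats(sub[:, j])
            if stats is None:
                continue
            if len(pops) > 1:
                a = sub[:, j, :].ravel()
                present = np.unique(a[a != MISSING])
                stats["P_A"] = float(
                    sum(1 for al in present if occurrence[locus][int(al)] == {pop})
                )
            ar = richness.get((pop, locus))
            if ar is not None:
                stats["A_R"] = ar
            per_locus[pop][locus] = stats
        keys = sorted({k for s in per_locus[pop].values() for k in s})
        means[pop] = {}
        ses[pop] = {}
        for key in keys:
            vals = np.array(
                [s[key] for s in per_locus[pop].values() if key in s and np.isfinite(s[key])]
            )
            if vals.size:
                means[pop][key] = float(vals.mean())
                ses[pop][key] = float(vals.std(ddof=1) / math.sqrt(vals.size)) if vals.size > 1 else 0.0
        # mean alleles per locus is the mean of N_dA; keep an explicit alias
        if "N_dA" in means[pop]:
            means[pop]["N_A"] = means[pop]["N_dA"]
    return DiversitySummary(per_locus=per_locus, means=means, se=ses)


def allelic_richness(
    dataset: GenotypeDataset, g_genes: int = 14
) -> dict[tuple[str, str], float]:
    """Rarefied allele counts per (population, locus).

    A_R = sum over alleles of [1 - C(N - N_a, g)/C(N, g)], the expected
    number of distinct alleles in a random subsample of ``g_genes`` genes.
    Populations with fewer than ``g_genes`` typed genes at a locus are
    omitted (not applicable, as in small-sample table entries).
    """
    if g_genes < 2:
        raise ValueError("g_genes must be >= 2")
    out: dict[tuple[str, str], float] = {}
    labels = dataset.population_labels()
    for pop in dataset.populations:
        sub = dataset.genotypes[labels == pop]
        for j, locus in enumerate(dataset.locus_names):
            a = sub[:, j, :].ravel()
            a = a[a != MISSING]
            n = a.size
            if n < g_genes:
                continue
            _, counts = np.unique(a, return_counts=True)
            # 1 - C(n - c, g)/C(n, g), via log-gammas for stability
            log_cn = _log_comb(n, g_genes)
            terms = []
            for c in counts:
                if n - c < g_genes:
                    terms.append(1.0)
                else:
                    terms.append(1.0 - math.exp(_log_comb(n - c, g_genes) - log_cn))
            out[(pop, locus)] = float(sum(terms))
    return out


def _log_comb(n: int, k: int) -> float:
    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


# -- exact HWE test --------------------------------------------------------

def _table_log_prob(table: np.ndarray, log_const: float) -> float:
    """Log of Levene's conditional probability of a genotype-count table.

    ``table`` is a symmetric-storage lower-triangular (k x k) count matrix
    with heterozygote counts at [i, j], i > j, homozygotes on the diagonal.
    log_const collects the terms that depend only on n and allele counts.
    """
    het = int(table.sum() - np.trace(table))
    return log_const + het * math.log(2.0) - float(gammaln(table + 1).sum())


def _log_const(n: int, allele_counts: np.ndarray) -> float:
    # log [ n! * prod(n_a!) / (2n)! ]
    return float(gammaln(n + 1) + gammaln(allele_counts + 1).sum() - gammaln(2 * n + 1))


def _genotype_table(geno: np.ndarray, alleles: np.ndarray) -> np.ndarray:
    idx = {int(a): i for i, a in enumerate(alleles)}
    k = len(alleles)
    table = np.zeros((k, k), dtype=np.int64)
    for a, b in geno:
        i, j = idx[int(a)], idx[int(b)]
        table[max(i, j), min(i, j)] += 1
    return table


def _enumerate_two_allele(n1: int, n: int):
    """All genotype tables for 2 alleles given allele-1 count n1 of 2n genes."""
    n2 = 2 * n - n1
    for het in range(n1 % 2, min(n1, n2) + 1, 2):
        hom1 = (n1 - het) // 2
        hom2 = (n2 - het) // 2
        yield np.array([[hom1, 0], [het, hom2]], dtype=np.int64)


def hwe_exact_test(
    dataset: GenotypeDataset,
    population: str,
    locus: str,
    iterations: int = 10_000,
    burn_in: int = 1_000,
    seed: int | None = None,
    enumeration_max_alleles: int = 2,
) -> TestResult:
    """Fisher-style exact test of Hardy-Weinberg equilibrium.

    The p-value is the probability, under Levene's conditional distribution
    of genotype tables given allele counts, of tables no more probable than
    the observed one. With up to ``enumeration_max_alleles`` alleles the
    table space is enumerated completely; otherwise a Guo-Thompson-style
    switch MCMC on the underlying gene pairing is run for ``iterations``
    recorded sweeps, and the p-value carries a batch-means Monte-Carlo SE.
    """
    labels = dataset.population_labels()
    j = dataset.locus_names.index(locus)
    geno = dataset.genotypes[labels == population, j]
    geno = geno[geno[:, 0] != MISSING]
    n = geno.shape[0]
    alleles, counts = np.unique(geno.ravel(), return_counts=True)
    if len(alleles) < 2:
        return TestResult(np.nan, np.nan, "hwe_exact", 0, applicable=False,
                          note="monomorphic locus: test inapplicable")
    if n < 3:
        return TestResult(np.nan, np.nan, "hwe_exact", 0, applicable=False,
                          note="fewer than 3 typed individuals")
    log_const = _log_const(n, counts)
    observed = _genotype_table(geno, alleles)
    lp_obs = _table_log_prob(observed, log_const)
    tol = 1e-9

    if len(alleles) <= enumeration_max_alleles:
        p = 0.0
        for table in _enumerate_two_allele(int(counts[0]), n):
            lp = _table_log_prob(table, log_const)
            if lp <= lp_obs + tol:
                p += math.exp(lp)
        return TestResult(lp_obs, min(p, 1.0), "hwe_exact_enumeration", 0)

    # switch MCMC on the gene pairing: swap one allele between two random
    # individuals each step; the uniform distribution over pairings is
    # invariant and induces Levene's distribution on tables.
    rng = np.random.default_rng(seed)
    pairs = geno.copy()
    idx = {int(a): i for i, a in enumerate(alleles)}
    coded = np.array([[idx[int(a)], idx[int(b)]] for a, b in pairs])
    table = observed.copy().astype(np.int64)
    lp = lp_obs
    hits = np.empty(iterations, dtype=np.float64)
    total = burn_in + iterations
    u_ind = rng.integers(0, n, size=(total, 2))
    u_slot = rng.integers(0, 2, size=(total, 2))
    for t in range(total):
        i1, i2 = u_ind[t]
        if i1 != i2:
            s1, s2 = u_slot[t]
            a1, b1 = coded[i1]
            a2, b2 = coded[i2]
            # remove old table entries
            table[max(a1, b1), min(a1, b1)] -= 1
            table[max(a2, b2), min(a2, b2)] -= 1
            x1 = [a1, b1]
            x2 = [a2, b2]
            x1[s1], x2[s2] = x2[s2], x1[s1]
            coded[i1] = x1
            coded[i2] = x2
            table[max(x1[0], x1[1]), min(x1[0], x1[1])] += 1
            table[max(x2[0], x2[1]), min(x2[0], x2[1])] += 1
            lp = _table_log_prob(table, log_const)
        if t >= burn_in:
            hits[t - burn_in] = 1.0 if lp <= lp_obs + tol else 0.0
    p = float(hits.mean())
    n_batches = 50
    if iterations >= n_batches:
        batches = hits[: (iterations // n_batches) * n_batches].reshape(n_batches, -1).mean(axis=1)
        se = float(batches.std(ddof=1) / math.sqrt(n_batches))
    else:
        se = float(hits.std(ddof=1) / math.sqrt(iterations))
    return TestResult(lp_obs, p, "hwe_guo_thompson_mcmc", iterations, se=se)


# -- genotypic LD test -----------------------------------------------------

def _g_statistic(codes1: np.ndarray, codes2: np.ndarray, k1: int, k2: int) -> float:
    table = np.bincount(codes1 * k2 + codes2, minlength=k1 * k2).reshape(k1, k2)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    total = table.sum()
    expected = row * col / total
    mask = table > 0
    return float(2.0 * np.sum(table[mask] * np.log(table[mask] / expected[mask])))


def ld_pair_test(
    dataset: GenotypeDataset,
    population: str,
    locus1: str,
    locus2: str,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> TestResult:
    """Permutation test of genotypic linkage disequilibrium.

    Statistic: log-likelihood-ratio G between the two-locus genotype
    contingency table and independence; null distribution by shuffling
    single-locus genotypes of the second locus among individuals. p uses
    (count >= observed + 1)/(n_permutations + 1).
    """
    labels = dataset.population_labels()
    j1 = dataset.locus_names.index(locus1)
    j2 = dataset.locus_names.index(locus2)
    sub = dataset.genotypes[labels == population]
    typed = (sub[:, j1, 0] != MISSING) & (sub[:, j2, 0] != MISSING)
    g1 = sub[typed, j1]
    g2 = sub[typed, j2]
    n = g1.shape[0]

    def codes(g: np.ndarray) -> tuple[np.ndarray, int]:
        _, inv = np.unique(g, axis=0, return_inverse=True)
        return inv.astype(np.int64), int(inv.max()) + 1 if inv.size else 0

    c1, k1 = codes(g1)
    c2, k2 = codes(g2)
    if n == 0 or k1 < 2 or k2 < 2:
        return TestResult(np.nan, np.nan, "ld_permutation", 0, applicable=False,
                          note="a locus is monomorphic (genotypically) in this population")
    note = "fewer than 5 jointly typed individuals: underpowered" if n < 5 else ""
    rng = np.random.default_rng(seed)
    g_obs = _g_statistic(c1, c2, k1, k2)
    count = 0
    c2p = c2.copy()
    for _ in range(n_permutations):
        rng.shuffle(c2p)
        if _g_statistic(c1, c2p, k1, k2) >= g_obs - 1e-12:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return TestResult(g_obs, p, "ld_permutation", n_permutations, note=note)


# -- null alleles ----------------------------------------------------------

def null_allele_estimates(
    dataset: GenotypeDataset, population: str, locus: str
) -> dict[str, float]:
    """Simple heterozygote-deficit null-allele frequency estimators.

    chakraborty = (H_E - H_O)/(H_E + H_O); brookfield1 = (H_E - H_O)/(1 + H_E).
    Raw values are returned alongside versions clipped at zero for reporting.
    """
    labels = dataset.population_labels()
    j = dataset.locus_names.index(locus)
    stats = _locus_stats(dataset.genotypes[labels == population, j])
    if stats is None or "H_E" not in stats:
        raise ValueError("H_E undefined: too few typed individuals")
    h_e, h_o = stats["H_E"], stats["H_O"]
    if h_e == 0 and h_o == 0:
        raise ValueError("H_E = H_O = 0: null-allele estimate undefined")
    chak = (h_e - h_o) / (h_e + h_o)
    brook = (h_e - h_o) / (1.0 + h_e)
    return {
        "chakraborty": max(chak, 0.0),
        "brookfield1": max(brook, 0.0),
        "chakraborty_raw": chak,
        "brookfield1_raw": brook,
    }


# -- multiple testing ------------------------------------------------------

def adjust_pvalues(p_values, method: str = "fdr_bh") -> np.ndarray:
    """Benjamini-Hochberg step-up or Holm (sequential Bonferroni) step-down."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"fdr_bh": "fdr_bh", "holm_sequential_bonferroni": "holm"}[method]
    return multipletests(p, method=key)[1]
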