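"""Pairwise population differentiation with bootstrap confidence intervals,
Nei's standard genetic distance, and principal coordinate ordination.

Statistics reported side by side per population pair: Weir-Cockerham theta
(F_ST), Nei-Chesser bias-corrected G_ST, Hedrick's standardized G''_ST and
Jost's D_est. Multilocus values combine variance/heterozygosity components
across loci before taking ratios (ratio of averages).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .dataset import MISSING, GenotypeDataset

STATISTICS = ("fst_wc", "gst_nei", "gst_hedrick", "jost_d")


# -- per-locus building blocks ---------------------------------------------

def _wc_locus(genotypes_by_pop: list[np.ndarray]) -> tuple[float, float, float] | None:
    """WC (a, b, c) summed over alleles for one locus.

    ``genotypes_by_pop``: list of (n_k, 2) typed canonical call arrays.
    Returns None when fewer than 2 populations have >= 2 typed individuals
    or the locus is monomorphic across the populations.
    """
    pops = [g for g in genotypes_by_pop if g.shape[0] >= 2]
    r = len(pops)
    if r < 2:
        return None
    ns = np.array([g.shape[0] for g in pops], dtype=float)
    alleles = sorted({int(a) for g in pops for a in g.ravel()})
    if len(alleles) < 2:
        return None
    nbar = ns.mean()
    nc = (r * nbar - np.sum(ns**2) / (r * nbar)) / (r - 1)
    a_sum = b_sum = c_sum = 0.0
    for al in alleles:
        p_i = np.array([np.mean(g.ravel() == al) for g in pops])
        h_i = np.array([np.mean((g[:, 0] == al) ^ (g[:, 1] == al)) for g in pops])
        pbar = float(np.sum(ns * p_i) / (r * nbar))
        s2 = float(np.sum(ns * (p_i - pbar) ** 2) / ((r - 1) * nbar))
        hbar = float(np.sum(ns * h_i) / (r * nbar))
        a = (nbar / nc) * (
            s2 - (1.0 / (nbar - 1.0)) * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum, b_sum, c_sum


def _nei_chesser_locus(genotypes_by_pop: list[np.ndarray]) -> tuple[float, float, float] | None:
    """Bias-corrected (H_S, H_T, H_O) for one locus (Nei & Chesser 1983)."""
    pops = [g for g in genotypes_by_pop if g.shape[0] >= 2]
    s = len(pops)
    if s < 2:
        return None
    ns = np.array([g.shape[0] for g in pops], dtype=float)
    n_harm = s / np.sum(1.0 / ns)
    alleles = sorted({int(a) for g in pops for a in g.ravel()})
    if len(alleles) < 2:
        return None
    p = np.array([[np.mean(g.ravel() == al) for al in alleles] for g in pops])
    h_o = float(np.mean([np.mean(g[:, 0] != g[:, 1]) for g in pops]))
    hs_tilde = 1.0 - float(np.mean(np.sum(p**2, axis=1)))
    pbar = p.mean(axis=0)
    ht_tilde = 1.0 - float(np.sum(pbar**2))
    hs = (n_harm / (n_harm - 1.0)) * (hs_tilde - h_o / (2.0 * n_harm))
    ht = ht_tilde + hs / (n_harm * s) - h_o / (2.0 * n_harm * s)
    return hs, ht, h_o


@dataclass
class PairwiseDifferentiation:
    pop1: str
    pop2: str
    fst_wc: float
    gst_nei: float
    gst_hedrick: float
    jost_d: float
    n_loci_used: int
    ci: dict | None = None  # statistic -> (low, high)
    significant: dict | None = None


def _point_estimates(dataset: GenotypeDataset, pop_pair: tuple[str, str]) -> PairwiseDifferentiation:
    labels = dataset.population_labels()
    p1, p2 = pop_pair
    a_tot = b_tot = c_tot = 0.0
    hs_list, ht_list = [], []
    used = 0
    for j in range(dataset.n_loci):
        by_pop = []
        for pop in pop_pair:
            g = dataset.genotypes[labels == pop, j]
            by_pop.append(g[g[:, 0] != MISSING])
        wc = _wc_locus(by_pop)
        nc = _nei_chesser_locus(by_pop)
        if wc is None or nc is None:
            continue
        used += 1
        a_tot += wc[0]
        b_tot += wc[1]
        c_tot += wc[2]
        hs_list.append(nc[0])
        ht_list.append(nc[1])
    if used == 0:
        return PairwiseDifferentiation(p1, p2, np.nan, np.nan, np.nan, np.nan, 0)
    denom = a_tot + b_tot + c_tot
    fst = a_tot / denom if denom != 0 else np.nan
    hs = float(np.mean(hs_list))
    ht = float(np.mean(ht_list))
    k = 2.0
    gst = (ht - hs) / ht if ht > 0 else np.nan
    if ht > 0 and hs < 1.0:
        gst_max_den = (k * ht - hs) * (1.0 - hs)
        gpp = k * (ht - hs) / gst_max_den if gst_max_den != 0 else np.nan
    else:
        gpp = np.nan
    d = (k / (k - 1.0)) * (ht - hs) / (1.0 - hs) if hs < 1.0 else np.nan
    return PairwiseDifferentiation(p1, p2, float(fst), float(gst), float(gpp), float(d), used)


def pairwise_differentiation(
    dataset: GenotypeDataset,
    pop_pair: tuple[str, str] | None = None,
) -> PairwiseDifferentiation | list[PairwiseDifferentiation]:
    """Point estimates for one population pair, or all pairs when omitted.

    Loci monomorphic across both populations, or with < 2 typed individuals
    in either, are excluded; with no usable loci all statistics are NaN.
    """
    if pop_pair is not None:
        return _point_estimates(dataset, pop_pair)
    pops = dataset.populations
    return [
        _point_estimates(dataset, (pops[i], pops[j]))
        for i in range(len(pops))
        for j in range(i + 1, len(pops))
    ]


def bootstrap_ci(
    dataset: GenotypeDataset,
    pop_pair: tuple[str, str],
    statistic: str = "gst_nei",
    n_boot: int = 1000,
    seed: int | None = None,
) -> tuple[float, float, bool]:
    """Bias-corrected (BC) percentile bootstrap CI for one statistic.

    Individuals are resampled with replacement within each population.
    ``significant`` means the interval excludes zero from below (ci_low > 0).
    """
    if statistic not in STATISTICS:
        raise ValueError(f"statistic must be one of {STATISTICS}")
    labels = dataset.population_labels()
    for pop in pop_pair:
        if int(np.sum(labels == pop)) < 3:
            raise ValueError(f"population {pop} has fewer than 3 individuals")
    rng = np.random.default_rng(seed)
    observed = getattr(_point_estimates(dataset, pop_pair), statistic)
    idx1 = np.nonzero(labels == pop_pair[0])[0]
    idx2 = np.nonzero(labels == pop_pair[1])[0]
    g = dataset.genotypes
    boots = np.empty(n_boot)
    for t in range(n_boot):
        sel1 = rng.choice(idx1, size=idx1.size, replace=True)
        sel2 = rng.choice(idx2, size=idx2.size, replace=True)
        a_tot = b_tot = c_tot = 0.0
        hs_list, ht_list = [], []
        for j in range(dataset.n_loci):
            g1 = g[sel1, j]
            g2 = g[sel2, j]
            by_pop = [g1[g1[:, 0] != MISSING], g2[g2[:, 0] != MISSING]]
            if statistic == "fst_wc":
                wc = _wc_locus(by_pop)
                if wc is None:
                    continue
                a_tot += wc[0]
                b_tot += wc[1]
                c_tot += wc[2]
            else:
                nc = _nei_chesser_locus(by_pop)
                if nc is None:
                    continue
                hs_list.append(nc[0])
                ht_list.append(nc[1])
        if statistic == "fst_wc":
            denom = a_tot + b_tot + c_tot
            boots[t] = a_tot / denom if denom != 0 else np.nan
        else:
            if not hs_list:
                boots[t] = np.nan
                continue
            hs, ht = float(np.mean(hs_list)), float(np.mean(ht_list))
            if statistic == "gst_nei":
                boots[t] = (ht - hs) / ht if ht > 0 else np.nan
            elif statistic == "gst_hedrick":
                den = (2 * ht - hs) * (1 - hs)
                boots[t] = 2 * (ht - hs) / den if den != 0 else np.nan
            else:
                boots[t] = 2 * (ht - hs) / (1 - hs) if hs < 1 else np.nan
    boots = boots[np.isfinite(boots)]
    if boots.size == 0:
        return np.nan, np.nan, False
    if np.allclose(boots, boots[0]):
        return float(boots[0]), float(boots[0]), bool(boots[0] > 0)
    frac = np.mean(boots < observed)
    frac = min(max(float(frac), 1.0 / (boots.size + 1)), 1.0 - 1.0 / (boots.size + 1))
    z0 = norm.ppf(frac)
    lo_q = norm.cdf(2 * z0 - 1.959963984540054)
    hi_q = norm.cdf(2 * z0 + 1.959963984540054)
    lo = float(np.percentile(boots, 100 * lo_q))
    hi = float(np.percentile(boots, 100 * hi_q))
    return lo, hi, bool(lo > 0)


# -- Nei distance & ordination ---------------------------------------------

def nei_distance(dataset: GenotypeDataset) -> tuple[list[str], np.ndarray]:
    """Nei (1972) standard genetic distance matrix between populations.

    D = -ln( J_XY / sqrt(J_X J_Y) ), with the J identity terms averaged over
    loci. Populations sharing no alleles anywhere (J_XY = 0) get +inf.
    """
    labels = dataset.population_labels()
    pops = dataset.populations
    # per pop, per locus allele-frequency dicts
    freqs: dict[str, list[dict[int, float]]] = {}
    for pop in pops:
        sub = dataset.genotypes[labels == pop]
        per = []
        for j in range(dataset.n_loci):
            a = sub[:, j, :].ravel()
            a = a[a != MISSING]
            if a.size == 0:
                per.append({})
                continue
            al, ct = np.unique(a, return_counts=True)
            per.append({int(x): c / a.size for x, c in zip(al, ct)})
        freqs[pop] = per
    n = len(pops)
    d = np.zeros((n, n))
    for i in range(n):
        for k in range(i + 1, n):
            jx = jy = jxy = 0.0
            used = 0
            for fx, fy in zip(freqs[pops[i]], freqs[pops[k]]):
                if not fx or not fy:
                    continue
                used += 1
                jx += sum(p**2 for p in fx.values())
                jy += sum(p**2 for p in fy.values())
                jxy += sum(fx[a] * fy.get(a, 0.0) for a in fx)
            if used == 0:
                d[i, k] = d[k, i] = np.nan
                continue
            jx, jy, jxy = jx / used, jy / used, jxy / used
            if jxy <= 0:
                d[i, k] = d[k, i] = np.inf
            else:
                d[i, k] = d[k, i] = -np.log(jxy / np.sqrt(jx * jy))
    return pops, d


@dataclass
class Ordination:
    labels: list[str]
    coordinates: np.ndarray  # populations x axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (may be negative)
    percent_variance: np.ndarray  # positive eigenvalues / sum of positives


def pcoa(distance_matrix: np.ndarray, labels: list[str] | None = None) -> Ordination:
    """Classical metric multidimensional scaling (principal coordinates).

    Double-centres the squared-distance (Gower) matrix and eigendecomposes.
    Axes with positive eigenvalues carry coordinates; negative eigenvalues
    are reported but excluded from the percent-variance denominator.
    """
    d = np.asarray(distance_matrix, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    n = d.shape[0]
    a = -0.5 * d**2
    centering = np.eye(n) - np.ones((n, n)) / n
    b = centering @ a @ centering
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    pos = eigval > 1e-10
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    percent = 100.0 * eigval[pos] / eigval[pos].sum() if pos.any() else np.array([])
    return Ordination(
        labels=list(labels) if labels is not None else [str(i) for i in range(n)],
        coordinates=coords,
        eigenvalues=eigval,
        percent_variance=percent,
    )
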