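"""Pairwise relatedness estimators, dyad simulation, and the group-shuffling
Monte-Carlo test of within-group kin structure.

Estimators
----------
QG        Queller & Goodnight (1989) moment estimator, both-directions averaged.
LynchRD   Lynch & Ritland (1999) moment estimator, locus-weighted, averaged.
Wang      similarity-class moment estimator in the style of Wang (2002):
          the exactly-unbiased weighted-least-squares solution of the
          class-probability moment equations (see docs/methods.md).
DyadML    dyadic maximum likelihood over IBD coefficients (k0, k1, k2), or
          over the nine condensed Jacquard coefficients when inbreeding is
          allowed; constrained to r in [0, 1].

All estimators take reference allele frequencies; by default these are
computed from the full sample (the pair included), matching common toolchain
behaviour. Loci missing in either member of a pair are excluded pairwise.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import spearmanr

from .dataset import (
    MISSING,
    POOLED,
    AlleleFrequencyTable,
    GenotypeDataset,
    allele_frequencies,
)

MOMENT_ESTIMATORS = ("QG", "LynchRD", "Wang")
ESTIMATORS = MOMENT_ESTIMATORS + ("DyadML", "DyadML_F")

_FREQ_FLOOR = 1e-6


# -- encoding --------------------------------------------------------------

@dataclass
class CodedLoci:
    """Per-locus allele-frequency vectors and genotype index coding."""

    locus_names: list[str]
    freqs: list[np.ndarray]  # per locus, frequencies (floored, renormalized)
    labels: list[np.ndarray]  # per locus, allele labels matching ``freqs``

    def index_maps(self) -> list[dict[int, int]]:
        return [{int(a): i for i, a in enumerate(lab)} for lab in self.labels]


def _coded_loci(
    locus_names: Sequence[str],
    genotype_arrays: Sequence[np.ndarray],
    freq_table: AlleleFrequencyTable,
    population: str = POOLED,
) -> CodedLoci:
    """Build per-locus frequency vectors covering every observed allele.

    Alleles observed in the genotypes but absent from the frequency table
    get the floor frequency 1e-6; each vector is renormalized.
    """
    freqs: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    for j, name in enumerate(locus_names):
        table = dict(freq_table.frequencies(population, name))
        observed: set[int] = set()
        for g in genotype_arrays:
            a = g[:, j, :].ravel()
            observed.update(int(x) for x in a[a != MISSING])
        for al in observed:
            table.setdefault(al, 0.0)
        lab = np.array(sorted(table), dtype=np.int64)
        f = np.array([table[int(a)] for a in lab], dtype=float)
        f = np.maximum(f, _FREQ_FLOOR)
        f = f / f.sum()
        labels.append(lab)
        freqs.append(f)
    return CodedLoci(list(locus_names), freqs, labels)


def _encode(genotypes: np.ndarray, coded: CodedLoci) -> np.ndarray:
    """Map canonical allele labels to per-locus indices; -1 = missing."""
    n, L, _ = genotypes.shape
    out = np.full((n, L, 2), -1, dtype=np.int64)
    maps = coded.index_maps()
    for j in range(L):
        m = maps[j]
        for slot in (0, 1):
            col = genotypes[:, j, slot]
            out[:, j, slot] = [m[int(a)] if a != MISSING else -1 for a in col]
    return out


# -- moment estimators (vectorized over pairs) -----------------------------

def _moment_r(
    gx: np.ndarray, gy: np.ndarray, coded: CodedLoci, estimator: str
) -> np.ndarray:
    """r for pair arrays gx, gy of allele-index codes, shape (p, L, 2)."""
    p_pairs, L, _ = gx.shape
    if estimator == "Wang":
        return _wang_r(gx, gy, coded)
    num1 = np.zeros(p_pairs)
    den1 = np.zeros(p_pairs)
    num2 = np.zeros(p_pairs)
    den2 = np.zeros(p_pairs)
    for j in range(L):
        f = coded.freqs[j]
        ia, ib = gx[:, j, 0], gx[:, j, 1]
        ic, idd = gy[:, j, 0], gy[:, j, 1]
        typed = (ia >= 0) & (ic >= 0)
        pa = f[np.clip(ia, 0, None)]
        pb = f[np.clip(ib, 0, None)]
        pc = f[np.clip(ic, 0, None)]
        pd = f[np.clip(idd, 0, None)]
        dac = (ia == ic).astype(float)
        dad = (ia == idd).astype(float)
        dbc = (ib == ic).astype(float)
        dbd = (ib == idd).astype(float)
        dab = (ia == ib).astype(float)
        dcd = (ic == idd).astype(float)
        if estimator == "QG":
            n1 = 0.5 * (dac + dad + dbc + dbd) - pa - pb
            d1 = 1.0 + dab - pa - pb
            n2 = 0.5 * (dac + dad + dbc + dbd) - pc - pd
            d2 = 1.0 + dcd - pc - pd
            ok1 = typed & (np.abs(d1) > 1e-12)
            ok2 = typed & (np.abs(d2) > 1e-12)
        elif estimator == "LynchRD":
            # direction 1: x = (a,b) is the reference individual
            n1 = pa * (dbc + dbd) + pb * (dac + dad) - 4.0 * pa * pb
            d1 = (1.0 + dab) * (pa + pb) - 4.0 * pa * pb
            w1 = 2.0 * pa * pb
            n2 = pc * (dad + dbd) + pd * (dac + dbc) - 4.0 * pc * pd
            d2 = (1.0 + dcd) * (pc + pd) - 4.0 * pc * pd
            w2 = 2.0 * pc * pd
            ok1 = typed & (np.abs(d1) > 1e-12)
            ok2 = typed & (np.abs(d2) > 1e-12)
            n1, d1 = n1 / w1, d1 / w1
            n2, d2 = n2 / w2, d2 / w2
        else:
            raise ValueError(f"unknown moment estimator {estimator!r}")
        num1 += np.where(ok1, n1, 0.0)
        den1 += np.where(ok1, d1, 0.0)
        num2 += np.where(ok2, n2, 0.0)
        den2 += np.where(ok2, d2, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r1 = np.where(np.abs(den1) > 1e-12, num1 / den1, np.nan)
        r2 = np.where(np.abs(den2) > 1e-12, num2 / den2, np.nan)
    both = np.stack([r1, r2])
    with np.errstate(invalid="ignore"):
        return np.nanmean(both, axis=0)


def _wang_locus_design(f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Similarity-class probabilities given IBD state, for one locus.

    Returns (P, A): P is the 3 x 3 matrix of [P(class c | state)] for classes
    c in {identical, hom-het-sharing, het-het-share-one} and states
    {2 IBD pairs, 1 IBD pair, 0 IBD}; A = P[:, :2] - P[:, 2:3] is the design
    for the moment equations E[y - P0] = A @ (k2, k1).
    """
    a2 = float(np.sum(f**2))
    a3 = float(np.sum(f**3))
    a4 = float(np.sum(f**4))
    p2 = np.array([1.0, 0.0, 0.0])
    p1 = np.array([a2, 2.0 * (a2 - a3), 1.0 - 3.0 * a2 + 2.0 * a3])
    p0 = np.array(
        [
            2.0 * a2**2 - a4,
            4.0 * (a3 - a4),
            4.0 * (a2 - 2.0 * a3 + 2.0 * a4 - a2**2),
        ]
    )
    P = np.column_stack([p2, p1, p0])
    A = P[:, :2] - P[:, 2:3]
    return P, A


def _wang_r(gx: np.ndarray, gy: np.ndarray, coded: CodedLoci) -> np.ndarray:
    p_pairs, L, _ = gx.shape
    M = np.zeros((p_pairs, 2, 2))
    v = np.zeros((p_pairs, 2))
    any_locus = np.zeros(p_pairs, dtype=bool)
    for j in range(L):
        P, A = _wang_locus_design(coded.freqs[j])
        P0 = P[:, 2]
        AT = A.T  # (2, 3)
        ATA = AT @ A
        ATP0 = AT @ P0
        ia, ib = gx[:, j, 0], gx[:, j, 1]
        ic, idd = gy[:, j, 0], gy[:, j, 1]
        typed = (ia >= 0) & (ic >= 0)
        eq = (ia == ic) & (ib == idd)
        homx = ia == ib
        homy = ic == idd
        shares = (ia == ic) | (ia == idd) | (ib == ic) | (ib == idd)
        cat = np.full(p_pairs, 3, dtype=np.int64)  # class 4 (no shared)
        cat[shares & ~homx & ~homy & ~eq] = 2
        cat[shares & (homx ^ homy)] = 1
        cat[eq] = 0
        # v += AT[:, cat] for classes 0..2; class 3 contributes nothing to A^T y
        ATx = np.column_stack([AT, np.zeros(2)])  # (2, 4)
        contrib = ATx[:, cat].T  # (p, 2)
        v += np.where(typed[:, None], contrib - ATP0[None, :], 0.0)
        M += np.where(typed[:, None, None], ATA[None, :, :], 0.0)
        any_locus |= typed
    # solve 2x2 systems: k = M^-1 v
    det = M[:, 0, 0] * M[:, 1, 1] - M[:, 0, 1] * M[:, 1, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        k2 = (M[:, 1, 1] * v[:, 0] - M[:, 0, 1] * v[:, 1]) / det
        k1 = (M[:, 0, 0] * v[:, 1] - M[:, 1, 0] * v[:, 0]) / det
    r = k2 + 0.5 * k1
    r[~any_locus | ~np.isfinite(r)] = np.nan
    return r


# -- dyadic likelihood -----------------------------------------------------

def _hwe_prob(i: int, j: int, f: np.ndarray) -> float:
    return float(f[i] * f[j] * (2.0 if i != j else 1.0))


def _t_coeff(i: int, j: int, s: int, f: np.ndarray) -> float:
    """P(one further random allele completes genotype {i,j} given one copy s)."""
    if s == i == j:
        return float(f[i])
    if i != j:
        if s == i:
            return float(f[j])
        if s == j:
            return float(f[i])
    return 0.0


def _k_state_probs(gx, gy, f) -> np.ndarray:
    """(P0, P1, P2): genotype-pair probability given 0/1/2 IBD pairs."""
    a, b = gx
    c, d = gy
    p0 = _hwe_prob(a, b, f) * _hwe_prob(c, d, f)
    shared = {a, b} & {c, d}
    p1 = sum(f[s] * _t_coeff(a, b, s, f) * _t_coeff(c, d, s, f) for s in shared)
    p2 = _hwe_prob(a, b, f) if (a, b) == (c, d) else 0.0
    return np.array([p0, p1, p2])


def _jacquard_probs(gx, gy, f) -> np.ndarray:
    """Genotype-pair probability under each condensed Jacquard state D1..D9."""
    a, b = gx
    c, d = gy
    hx = _hwe_prob(a, b, f)
    hy = _hwe_prob(c, d, f)
    homx = a == b
    homy = c == d
    out = np.zeros(9)
    out[0] = f[a] if (homx and homy and a == c) else 0.0  # D1
    out[1] = f[a] * f[c] if (homx and homy) else 0.0  # D2
    if homx:  # D3: x's pair IBD with one allele of y
        if c == a:
            out[2] = f[a] * f[d]
        elif d == a:
            out[2] = f[a] * f[c]
    out[3] = f[a] * hy if homx else 0.0  # D4
    if homy:  # D5 (mirror of D3)
        if a == c:
            out[4] = f[c] * f[b]
        elif b == c:
            out[4] = f[c] * f[a]
    out[5] = f[c] * hx if homy else 0.0  # D6
    out[6] = hx if (a, b) == (c, d) else 0.0  # D7
    shared = {a, b} & {c, d}
    out[7] = sum(f[s] * _t_coeff(a, b, s, f) * _t_coeff(c, d, s, f) for s in shared)  # D8
    out[8] = hx * hy  # D9
    return out


def _em_simplex(probs: np.ndarray, tol: float = 1e-10, max_iter: int = 5000) -> np.ndarray:
    """Maximize sum_l log(sum_s w_s probs[l, s]) over the simplex by EM.

    The log-likelihood is concave in w, so EM from the barycentre reaches
    the global optimum; iteration stops when the log-likelihood improves by
    less than ``tol``.
    """
    L, S = probs.shape
    w = np.full(S, 1.0 / S)
    last = -np.inf
    for _ in range(max_iter):
        mix = probs @ w  # (L,)
        ll = float(np.sum(np.log(mix)))
        if ll - last < tol:
            break
        last = ll
        resp = probs * w[None, :] / mix[:, None]
        w = resp.mean(axis=0)
    return w


@dataclass
class RelatednessEstimate:
    sample_id_1: str
    sample_id_2: str
    estimator: str
    r: float
    ibd: np.ndarray | None = None  # (k0,k1,k2) or Jacquard D1..D9


def _dyadml_probs(gx_codes, gy_codes, coded: CodedLoci, allow_inbreeding: bool) -> np.ndarray:
    """Per-locus state-probability matrix for a single coded genotype pair."""
    rows = []
    for j in range(len(coded.locus_names)):
        a, b = int(gx_codes[j, 0]), int(gx_codes[j, 1])
        c, d = int(gy_codes[j, 0]), int(gy_codes[j, 1])
        if a < 0 or c < 0:
            continue
        f = coded.freqs[j]
        if allow_inbreeding:
            rows.append(_jacquard_probs((a, b), (c, d), f))
        else:
            rows.append(_k_state_probs((a, b), (c, d), f))
    if not rows:
        raise ValueError("pair has no jointly typed loci")
    return np.array(rows)


def _dyadml_r(weights: np.ndarray, allow_inbreeding: bool) -> float:
    if allow_inbreeding:
        d = weights
        return float(d[0] + 0.5 * (d[2] + d[4] + d[6]) + 0.25 * d[7])
    k0, k1, k2 = weights
    return float(k2 + 0.5 * k1)


def dyadml(
    dataset: GenotypeDataset,
    pair: tuple[str, str],
    freqs: AlleleFrequencyTable | None = None,
    allow_inbreeding: bool = False,
    population: str = POOLED,
) -> RelatednessEstimate:
    """Maximum-likelihood relatedness for one pair (DyadML / DyadML_F)."""
    if freqs is None:
        freqs = allele_frequencies(dataset, grouping="pooled")
    coded = _coded_loci(dataset.locus_names, [dataset.genotypes], freqs, population)
    gidx = _encode(dataset.genotypes, coded)
    i = dataset.index_of(pair[0])
    k = dataset.index_of(pair[1])
    probs = _dyadml_probs(gidx[i], gidx[k], coded, allow_inbreeding)
    w = _em_simplex(probs)
    return RelatednessEstimate(
        pair[0],
        pair[1],
        "DyadML_F" if allow_inbreeding else "DyadML",
        _dyadml_r(w, allow_inbreeding),
        ibd=w,
    )


def pairwise_relatedness(
    dataset: GenotypeDataset,
    estimator: str = "QG",
    freqs: AlleleFrequencyTable | None = None,
    pairs: Sequence[tuple[str, str]] | None = None,
    population: str = POOLED,
    allow_inbreeding: bool = False,
) -> list[RelatednessEstimate]:
    """Relatedness for the given pairs (default: all unordered pairs)."""
    if estimator not in ESTIMATORS:
        raise ValueError(f"estimator must be one of {ESTIMATORS}")
    if freqs is None:
        freqs = allele_frequencies(dataset, grouping="pooled")
    coded = _coded_loci(dataset.locus_names, [dataset.genotypes], freqs, population)
    gidx = _encode(dataset.genotypes, coded)
    ids = dataset.sample_ids
    if pairs is None:
        pairs = [(ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))]
    I = np.array([dataset.index_of(a) for a, _ in pairs])
    J = np.array([dataset.index_of(b) for _, b in pairs])
    out: list[RelatednessEstimate] = []
    if estimator in MOMENT_ESTIMATORS:
        r = _moment_r(gidx[I], gidx[J], coded, estimator)
        for (a, b), val in zip(pairs, r):
            out.append(RelatednessEstimate(a, b, estimator, float(val)))
    else:
        inbreeding = allow_inbreeding or estimator == "DyadML_F"
        for (a, b), i, j in zip(pairs, I, J):
            probs = _dyadml_probs(gidx[i], gidx[j], coded, inbreeding)
            w = _em_simplex(probs)
            out.append(
                RelatednessEstimate(a, b, estimator, _dyadml_r(w, inbreeding), ibd=w)
            )
    return out


# -- dyad simulation -------------------------------------------------------

TRUE_K = {
    "unrelated": (1.0, 0.0, 0.0),
    "parent_offspring": (0.0, 1.0, 0.0),
    "half_sib": (0.5, 0.5, 0.0),
    "full_sib": (0.25, 0.5, 0.25),
}
TRUE_R = {c: k[2] + 0.5 * k[1] for c, k in TRUE_K.items()}


@dataclass
class DyadSet:
    """Simulated genotype pairs with known pedigree relationship."""

    locus_names: list[str]
    genotypes_x: np.ndarray  # (n_pairs, L, 2) canonical allele labels
    genotypes_y: np.ndarray
    category: str
    true_k: tuple[float, float, float]

    @property
    def true_r(self) -> float:
        return self.true_k[2] + 0.5 * self.true_k[1]


def simulate_dyads(
    freqs: AlleleFrequencyTable,
    category: str,
    n_pairs: int = 200,
    seed: int | None = None,
    population: str = POOLED,
) -> DyadSet:
    """Simulate genotype pairs of a given pedigree relationship.

    Parents are drawn under HWE from the frequency table; offspring receive
    alleles by Mendelian segregation according to the category's pedigree
    (no mutation or genotyping error).
    """
    if category not in TRUE_K:
        raise ValueError(f"category must be one of {sorted(TRUE_K)}")
    rng = np.random.default_rng(seed)
    loci = freqs.loci()
    L = len(loci)
    gx = np.zeros((n_pairs, L, 2), dtype=np.int32)
    gy = np.zeros((n_pairs, L, 2), dtype=np.int32)
    for j, locus in enumerate(loci):
        d = freqs.frequencies(population, locus)
        labels = np.array(sorted(d), dtype=np.int32)
        probs = np.array([d[int(a)] for a in labels], dtype=float)
        probs = probs / probs.sum()

        def draw(n):
            return np.stack(
                [rng.choice(labels, size=n, p=probs), rng.choice(labels, size=n, p=probs)],
                axis=1,
            )

        def segregate(parents):  # one gamete per parent genotype row
            pick = rng.integers(0, 2, size=parents.shape[0])
            return parents[np.arange(parents.shape[0]), pick]

        if category == "unrelated":
            x, y = draw(n_pairs), draw(n_pairs)
        elif category == "parent_offspring":
            x = draw(n_pairs)
            other = rng.choice(labels, size=n_pairs, p=probs)
            y = np.stack([segregate(x), other], axis=1)
        elif category == "full_sib":
            p1, p2 = draw(n_pairs), draw(n_pairs)
            x = np.stack([segregate(p1), segregate(p2)], axis=1)
            y = np.stack([segregate(p1), segregate(p2)], axis=1)
        else:  # half_sib
            shared, m1, m2 = draw(n_pairs), draw(n_pairs), draw(n_pairs)
            x = np.stack([segregate(shared), segregate(m1)], axis=1)
            y = np.stack([segregate(shared), segregate(m2)], axis=1)
        gx[:, j, :] = np.sort(x, axis=1)
        gy[:, j, :] = np.sort(y, axis=1)
    return DyadSet(loci, gx, gy, category, TRUE_K[category])


def estimate_dyads(
    dyads: DyadSet,
    freqs: AlleleFrequencyTable,
    estimator: str,
    population: str = POOLED,
) -> np.ndarray:
    """Relatedness estimates for every simulated pair (vector)."""
    coded = _coded_loci(
        dyads.locus_names, [dyads.genotypes_x, dyads.genotypes_y], freqs, population
    )
    gx = _encode(dyads.genotypes_x, coded)
    gy = _encode(dyads.genotypes_y, coded)
    if estimator in MOMENT_ESTIMATORS:
        return _moment_r(gx, gy, coded, estimator)
    inbreeding = estimator == "DyadML_F"
    out = np.empty(gx.shape[0])
    for i in range(gx.shape[0]):
        probs = _dyadml_probs(gx[i], gy[i], coded, inbreeding)
        out[i] = _dyadml_r(_em_simplex(probs), inbreeding)
    return out


def compare_estimators(
    freqs: AlleleFrequencyTable,
    n_pairs: int = 200,
    seed: int | None = None,
    estimators: Sequence[str] = ("QG", "LynchRD", "Wang", "DyadML"),
) -> dict:
    """Simulate dyads of each relationship and score every estimator.

    Returns per-estimator pooled Pearson correlation with true r plus
    per-category means and variances, and a correlation-ranked summary.
    """
    rng = np.random.default_rng(seed)
    categories = ("unrelated", "half_sib", "parent_offspring", "full_sib")
    sims = {
        c: simulate_dyads(freqs, c, n_pairs, seed=int(rng.integers(2**31)))
        for c in categories
    }
    result: dict = {"n_pairs": n_pairs, "estimators": {}}
    for est in estimators:
        per_cat = {}
        pooled_est = []
        pooled_truth = []
        for c in categories:
            r = estimate_dyads(sims[c], freqs, est)
            r = r[np.isfinite(r)]
            per_cat[c] = {"mean": float(r.mean()), "var": float(r.var(ddof=1)),
                          "true_r": TRUE_R[c]}
            pooled_est.append(r)
            pooled_truth.append(np.full(r.size, TRUE_R[c]))
        e = np.concatenate(pooled_est)
        t = np.concatenate(pooled_truth)
        corr = float(np.corrcoef(e, t)[0, 1])
        result["estimators"][est] = {"pearson_r": corr, "categories": per_cat}
    result["ranking"] = sorted(
        result["estimators"], key=lambda k: -result["estimators"][k]["pearson_r"]
    )
    return result


# -- group permutation test ------------------------------------------------

@dataclass
class GroupRelatednessResult:
    estimator: str
    iterations: int
    observed_per_group: dict[str, float]
    observed_overall: float
    expected_overall: float
    null_distribution: np.ndarray
    p_overall: float
    per_group_p: dict[str, float]
    excluded_groups: list[str] = field(default_factory=list)


def relatedness_matrix(
    dataset: GenotypeDataset,
    estimator: str = "QG",
    freqs: AlleleFrequencyTable | None = None,
    population: str = POOLED,
) -> np.ndarray:
    """Symmetric matrix of pairwise r over all samples (nan diagonal)."""
    n = dataset.n_samples
    ids = dataset.sample_ids
    pairs = [(ids[i], ids[j]) for i in range(n) for j in range(i + 1, n)]
    ests = pairwise_relatedness(dataset, estimator, freqs, pairs, population)
    mat = np.full((n, n), np.nan)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = ests[k].r
            k += 1
    return mat


def group_permutation_test(
    dataset: GenotypeDataset,
    groups: Mapping[str, Sequence[str]],
    estimator: str = "LynchRD",
    iterations: int = 1000,
    seed: int | None = None,
    freqs: AlleleFrequencyTable | None = None,
) -> GroupRelatednessResult:
    """Test whether individuals within groups are more related than chance.

    Observed per-group R is the mean of all within-group pairwise estimates;
    the overall statistic averages group means with equal weight. The null
    distribution shuffles individuals among groups, preserving every group
    size, and recomputes the overall mean each iteration.
    p_overall = (#null >= observed + 1)/(iterations + 1). Per-group p values
    compare each group's R against the null group-means pooled across
    permuted groups of the same size.
    """
    groups = {g: list(m) for g, m in groups.items()}
    excluded = [g for g, m in groups.items() if len(m) < 2]
    if excluded:
        import warnings

        warnings.warn(f"groups of size < 2 excluded: {sorted(excluded)}")
        groups = {g: m for g, m in groups.items() if len(m) >= 2}
    if not groups:
        raise ValueError("no groups of size >= 2")
    members = [m for g in groups.values() for m in g]
    if len(set(members)) != len(members):
        raise ValueError("groups must not share members")
    sub = dataset.subset(members)
    if freqs is None:
        freqs = allele_frequencies(dataset, grouping="pooled")
    mat = relatedness_matrix(sub, estimator, freqs)
    index = {s: i for i, s in enumerate(sub.sample_ids)}

    def group_mean(idx: np.ndarray) -> float:
        block = mat[np.ix_(idx, idx)]
        vals = block[np.triu_indices(len(idx), 1)]
        vals = vals[np.isfinite(vals)]
        return float(vals.mean()) if vals.size else np.nan

    names = list(groups)
    obs = {g: group_mean(np.array([index[s] for s in groups[g]])) for g in names}
    observed_overall = float(np.nanmean(list(obs.values())))

    rng = np.random.default_rng(seed)
    sizes = [len(groups[g]) for g in names]
    pool = np.array([index[s] for g in names for s in groups[g]])
    null = np.empty(iterations)
    by_size: dict[int, list[float]] = {s: [] for s in set(sizes)}
    for t in range(iterations):
        perm = rng.permutation(pool)
        means = []
        start = 0
        for s in sizes:
            m = group_mean(perm[start : start + s])
            means.append(m)
            by_size[s].append(m)
            start += s
        null[t] = np.nanmean(means)
    p_overall = (float(np.sum(null >= observed_overall - 1e-12)) + 1.0) / (iterations + 1.0)
    per_group_p = {}
    for g, s in zip(names, sizes):
        ref = np.array(by_size[s])
        ref = ref[np.isfinite(ref)]
        per_group_p[g] = (float(np.sum(ref >= obs[g] - 1e-12)) + 1.0) / (ref.size + 1.0)
    return GroupRelatednessResult(
        estimator=estimator,
        iterations=iterations,
        observed_per_group=obs,
        observed_overall=observed_overall,
        expected_overall=float(null.mean()),
        null_distribution=null,
        p_overall=p_overall,
        per_group_p=per_group_p,
        excluded_groups=excluded,
    )


# -- inbreeding ------------------------------------------------------------

def individual_inbreeding(
    dataset: GenotypeDataset,
    freqs: AlleleFrequencyTable | None = None,
    groups: Mapping[str, Sequence[str]] | None = None,
    population: str = POOLED,
    estimator_for_groups: str = "LynchRD",
    n_permutations: int = 999,
    seed: int | None = None,
) -> dict:
    """Per-individual ML inbreeding coefficient F-hat, constrained to [0, 1].

    Per locus, P(hom_i | F) = F p_i + (1-F) p_i^2 and
    P(het_ij | F) = (1-F) 2 p_i p_j; the product over typed loci is maximized
    in F. If ``groups`` is given, also returns per-group mean F and the
    Spearman rank correlation of group mean R vs group mean F with a
    permutation p-value.
    """
    if freqs is None:
        freqs = allele_frequencies(dataset, grouping="pooled")
    coded = _coded_loci(dataset.locus_names, [dataset.genotypes], freqs, population)
    gidx = _encode(dataset.genotypes, coded)
    f_hat: dict[str, float] = {}
    for i, sid in enumerate(dataset.sample_ids):
        hom_p = []
        het_p = []
        for j in range(dataset.n_loci):
            a, b = gidx[i, j]
            if a < 0:
                continue
            f = coded.freqs[j]
            if a == b:
                hom_p.append(float(f[a]))
            else:
                het_p.append(float(2 * f[a] * f[b]))
        if not hom_p and not het_p:
            f_hat[sid] = np.nan
            continue
        hp = np.array(hom_p)
        tp = np.array(het_p)

        def neg_ll(F):
            ll = float(np.sum(np.log(F * hp + (1 - F) * hp**2))) if hp.size else 0.0
            if tp.size:
                ll += float(np.sum(np.log((1 - F) * tp)))
            return -ll

        if tp.size and not hp.size:
            f_hat[sid] = 0.0  # all-heterozygous: likelihood decreasing in F
        else:
            res = minimize_scalar(neg_ll, bounds=(0.0, 1.0 - 1e-9), method="bounded")
            f_hat[sid] = float(res.x)
    out: dict = {"individual_F": f_hat}
    if groups:
        group_f = {
            g: float(np.nanmean([f_hat[s] for s in m])) for g, m in groups.items()
        }
        out["group_F"] = group_f
        res = group_permutation_test(
            dataset, groups, estimator=estimator_for_groups, iterations=1, seed=seed
        )
        group_r = res.observed_per_group
        names = [g for g in groups if np.isfinite(group_f[g]) and np.isfinite(group_r[g])]
        rvals = np.array([group_r[g] for g in names])
        fvals = np.array([group_f[g] for g in names])
        if len(names) >= 3 and np.std(rvals) > 0 and np.std(fvals) > 0:
            rho = float(spearmanr(rvals, fvals).statistic)
            rng = np.random.default_rng(seed)
            count = 0
            for _ in range(n_permutations):
                perm = rng.permutation(fvals)
                if abs(float(spearmanr(rvals, perm).statistic)) >= abs(rho) - 1e-12:
                    count += 1
            out["r_vs_F"] = {
                "spearman_rho": rho,
                "p_value": (count + 1) / (n_permutations + 1),
            }
        else:
            out["r_vs_F"] = {"spearman_rho": np.nan, "p_value": np.nan,
                             "note": "degenerate: too few groups or zero variance"}
    return out


# -- population-level mean relatedness -------------------------------------

def population_mean_relatedness(
    dataset: GenotypeDataset,
    estimator: str = "QG",
    n_bootstrap: int = 1000,
    n_permutations: int = 999,
    seed: int | None = None,
    freqs: AlleleFrequencyTable | None = None,
) -> dict:
    """Mean within-population pairwise r with bootstrap CI and null envelope.

    The CI resamples within-population pairs with replacement; the null
    envelope permutes population labels ``n_permutations`` times. A
    population is flagged when its observed mean exceeds the 95th percentile
    of its size-matched null distribution.
    """
    if freqs is None:
        freqs = allele_frequencies(dataset, grouping="pooled")
    mat = relatedness_matrix(dataset, estimator, freqs)
    labels = dataset.population_labels()
    rng = np.random.default_rng(seed)
    pops = dataset.populations
    result: dict = {}

    def pop_mean(idx: np.ndarray) -> tuple[float, np.ndarray]:
        block = mat[np.ix_(idx, idx)]
        vals = block[np.triu_indices(len(idx), 1)]
        vals = vals[np.isfinite(vals)]
        return (float(vals.mean()) if vals.size else np.nan), vals

    observed: dict[str, float] = {}
    pair_values: dict[str, np.ndarray] = {}
    for pop in pops:
        idx = np.nonzero(labels == pop)[0]
        if idx.size < 2:
            observed[pop] = np.nan
            pair_values[pop] = np.array([])
            continue
        observed[pop], pair_values[pop] = pop_mean(idx)

    null_by_pop: dict[str, list[float]] = {p: [] for p in pops}
    if len(pops) > 1:
        sizes = {p: int(np.sum(labels == p)) for p in pops}
        all_idx = np.arange(dataset.n_samples)
        order = list(pops)
        for _ in range(n_permutations):
            perm = rng.permutation(all_idx)
            start = 0
            for p in order:
                m, _ = pop_mean(perm[start : start + sizes[p]])
                null_by_pop[p].append(m)
                start += sizes[p]

    for pop in pops:
        vals = pair_values[pop]
        if vals.size:
            boots = np.array(
                [vals[rng.integers(0, vals.size, vals.size)].mean() for _ in range(n_bootstrap)]
            )
            ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
        else:
            ci = (np.nan, np.nan)
        null = np.array(null_by_pop[pop]) if null_by_pop[pop] else np.array([])
        if null.size:
            upper = float(np.nanpercentile(null, 95))
            significant = bool(observed[pop] > upper)
        else:
            upper, significant = np.nan, False
        result[pop] = {
            "mean_r": observed[pop],
            "ci": ci,
            "null_95": upper,
            "significant": significant,
        }
    return result
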