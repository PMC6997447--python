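"""Synthetic microsatellite genotype generators.

These emulate the statistical structure the analyses assume — a few hundred
diploid individuals typed at ~19 loci carrying 3-18 alleles each, mean
expected heterozygosity around 0.66, weak spatial structure (G_ST ~ 0.01),
kin-structured surface groups, injected recaptures, and a genotyping-error
model (allelic dropout, null alleles, mis-scoring, missingness). Every
generator is a pure function of (config, seed).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .dataset import (
    MISSING,
    POOLED,
    AlleleFrequencyTable,
    GenotypeDataset,
    Locus,
    SampleMetadata,
)

#: Symmetric Dirichlet concentration for ancestral allele frequencies;
#: with allele counts uniform on [3, 18] this yields mean H_E ~ 0.66.
DEFAULT_DIRICHLET_ALPHA = 0.35


@dataclass
class ErrorModelConfig:
    """Per-single-locus-genotype error probabilities."""

    dropout_rate: float = 0.0
    misscore_rate: float = 0.0
    missing_rate: float = 0.0
    larger_allele_bias: bool = True  # dropout preferentially loses the larger allele
    null_alleles: Mapping[str, int] = field(default_factory=dict)  # locus -> allele

    def __post_init__(self):
        for rate in (self.dropout_rate, self.misscore_rate, self.missing_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("error rates must lie in [0, 1]")


@dataclass
class SimulationConfig:
    seed: int = 0
    n_loci: int = 19
    alleles_min: int = 3
    alleles_max: int = 18
    motif_length: int = 2
    n_populations: int = 4
    deme_size: int = 200
    migration_rate: float = 0.1
    generations: int = 50
    target_fst: float | None = None  # Balding-Nichols mode when set
    dirichlet_alpha: float = DEFAULT_DIRICHLET_ALPHA


def ancestral_frequencies(
    rng: np.random.Generator,
    n_loci: int = 19,
    alleles_min: int = 3,
    alleles_max: int = 18,
    motif_length: int = 2,
    alpha: float = DEFAULT_DIRICHLET_ALPHA,
) -> tuple[list[Locus], list[np.ndarray], list[np.ndarray]]:
    """Draw per-locus allele labels and Dirichlet ancestral frequencies.

    Allele labels are fragment sizes on a motif-spaced ladder starting from
    a locus-specific offset, so mis-scoring errors stay on the ladder.
    """
    loci = []
    labels = []
    freqs = []
    for j in range(n_loci):
        k = int(rng.integers(alleles_min, alleles_max + 1))
        start = int(rng.integers(80, 300))
        loci.append(Locus(name=f"Cmax{j + 1:02d}", motif_length=motif_length))
        labels.append(start + motif_length * np.arange(k, dtype=np.int64))
        freqs.append(rng.dirichlet(np.full(k, alpha)))
    return loci, labels, freqs


def _sample_hwe(rng, labels: np.ndarray, probs: np.ndarray, n: int) -> np.ndarray:
    a = rng.choice(labels, size=n, p=probs)
    b = rng.choice(labels, size=n, p=probs)
    return np.sort(np.stack([a, b], axis=1), axis=1)


def _dataset_from_freqs(
    rng,
    loci: list[Locus],
    labels: list[np.ndarray],
    pop_freqs: Mapping[str, list[np.ndarray]],
    pop_sizes: Mapping[str, int],
    id_prefix: str = "ind",
) -> GenotypeDataset:
    samples = []
    rows = []
    counter = 0
    for pop, size in pop_sizes.items():
        for _ in range(size):
            counter += 1
            samples.append(SampleMetadata(sample_id=f"{id_prefix}{counter:04d}", population=pop))
    genotypes = np.zeros((len(samples), len(loci), 2), dtype=np.int32)
    offset = 0
    for pop, size in pop_sizes.items():
        for j in range(len(loci)):
            f = pop_freqs[pop][j]
            genotypes[offset : offset + size, j, :] = _sample_hwe(rng, labels[j], f, size)
        offset += size
    return GenotypeDataset(loci, samples, genotypes)


# -- island model ----------------------------------------------------------

def simulate_island_model(config: SimulationConfig, sample_sizes: Mapping[str, int] | None = None):
    """Finite-island Wright-Fisher drift with symmetric migration.

    Deme allele frequencies start at a shared Dirichlet ancestral draw and
    evolve for ``generations`` rounds of migration (toward the pooled mean
    at rate m) followed by binomial drift in 2N genes. Individuals are
    sampled under HWE within their deme. Returns (dataset, truth) where
    truth holds realized deme frequencies and the equilibrium expectation
    F_ST ~ 1/(4Nm + 1).
    """
    if config.deme_size < 2:
        raise ValueError("deme_size must be >= 2")
    rng = np.random.default_rng(config.seed)
    loci, labels, anc = ancestral_frequencies(
        rng, config.n_loci, config.alleles_min, config.alleles_max,
        config.motif_length, config.dirichlet_alpha,
    )
    K = config.n_populations
    m = config.migration_rate
    two_n = 2 * config.deme_size
    deme_freqs = [[anc[j].copy() for j in range(config.n_loci)] for _ in range(K)]
    for _ in range(config.generations):
        for j in range(config.n_loci):
            mat = np.stack([deme_freqs[k][j] for k in range(K)])
            pooled = mat.mean(axis=0)
            post = (1 - m) * mat + m * pooled[None, :]
            for k in range(K):
                counts = rng.multinomial(two_n, post[k])
                deme_freqs[k][j] = counts / two_n
    pops = [f"pop{k + 1}" for k in range(K)]
    if sample_sizes is None:
        sample_sizes = {p: 50 for p in pops}
    pop_freqs = {}
    for k, p in enumerate(pops):
        per = []
        for j in range(config.n_loci):
            f = deme_freqs[k][j]
            total = f.sum()
            per.append(f / total if total > 0 else np.full_like(f, 1.0 / f.size))
        pop_freqs[p] = per
    dataset = _dataset_from_freqs(rng, loci, labels, pop_freqs, sample_sizes)
    truth = {
        "deme_frequencies": pop_freqs,
        "expected_fst": 1.0 / (4.0 * config.deme_size * m + 1.0) if m > 0 else np.nan,
    }
    return dataset, truth


def simulate_balding_nichols(
    n_pops: int,
    target_fst: float,
    n: int | Mapping[str, int],
    seed: int,
    n_loci: int = 19,
    alleles_min: int = 3,
    alleles_max: int = 18,
    dirichlet_alpha: float = DEFAULT_DIRICHLET_ALPHA,
):
    """Balding-Nichols demes: deme frequencies ~ Dirichlet(p (1-F)/F).

    The marginal of each allele is Beta(p(1-F)/F, (1-p)(1-F)/F), the
    standard correlated-allele-frequency model at divergence F.
    """
    if not 0.0 < target_fst < 1.0:
        raise ValueError("target_fst must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    loci, labels, anc = ancestral_frequencies(
        rng, n_loci, alleles_min, alleles_max, alpha=dirichlet_alpha
    )
    scale = (1.0 - target_fst) / target_fst
    pops = [f"pop{k + 1}" for k in range(n_pops)]
    sizes = {p: n for p in pops} if isinstance(n, int) else dict(n)
    pop_freqs = {}
    for p in pops:
        per = []
        for j in range(n_loci):
            alpha = np.maximum(anc[j] * scale, 1e-9)
            per.append(rng.dirichlet(alpha))
        pop_freqs[p] = per
    dataset = _dataset_from_freqs(rng, loci, labels, pop_freqs, sizes)
    truth = {"ancestral_frequencies": anc, "target_fst": target_fst,
             "deme_frequencies": pop_freqs}
    return dataset, truth


# -- kin groups ------------------------------------------------------------

def simulate_kin_groups(
    freqs: AlleleFrequencyTable,
    group_spec: Sequence[tuple[str, int]],
    background_n: int = 0,
    seed: int | None = None,
    population: str = POOLED,
):
    """Surface groups with known kin structure in an unrelated background.

    ``group_spec`` is a sequence of (kind, size) with kind in
    {"full_sib", "half_sib", "unrelated"}; each group's members get a
    shared ``group_id``. Returns (dataset, truth) where truth maps group_id
    to its kind and expected mean pairwise r (0.5 full sibs, 0.25 half
    sibs, 0 unrelated).
    """
    rng = np.random.default_rng(seed)
    loci_names = freqs.loci()
    L = len(loci_names)
    per_locus = []
    for name in loci_names:
        d = freqs.frequencies(population, name)
        lab = np.array(sorted(d), dtype=np.int64)
        f = np.array([d[int(a)] for a in lab])
        per_locus.append((lab, f / f.sum()))

    def hwe(n):
        g = np.zeros((n, L, 2), dtype=np.int32)
        for j, (lab, f) in enumerate(per_locus):
            g[:, j, :] = _sample_hwe(rng, lab, f, n)
        return g

    def offspring(parents_a, parents_b):
        n = parents_a.shape[0]
        out = np.zeros_like(parents_a)
        pick_a = rng.integers(0, 2, size=(n, L))
        pick_b = rng.integers(0, 2, size=(n, L))
        rows = np.arange(n)[:, None]
        cols = np.arange(L)[None, :]
        out[:, :, 0] = parents_a[rows, cols, pick_a]
        out[:, :, 1] = parents_b[rows, cols, pick_b]
        return np.sort(out, axis=2)

    expected_r = {"full_sib": 0.5, "half_sib": 0.25, "unrelated": 0.0}
    blocks = []
    samples = []
    truth = {}
    counter = 0
    for gi, (kind, size) in enumerate(group_spec, start=1):
        if size < 2:
            raise ValueError("group sizes must be >= 2")
        if kind == "full_sib":
            p1 = np.repeat(hwe(1), size, axis=0)
            p2 = np.repeat(hwe(1), size, axis=0)
            g = offspring(p1, p2)
        elif kind == "half_sib":
            shared = np.repeat(hwe(1), size, axis=0)
            g = offspring(shared, hwe(size))
        elif kind == "unrelated":
            g = hwe(size)
        else:
            raise ValueError(f"unknown kin kind {kind!r}")
        gid = f"G{gi:03d}"
        truth[gid] = {"kind": kind, "expected_r": expected_r[kind], "size": size}
        for _ in range(size):
            counter += 1
            samples.append(
                SampleMetadata(sample_id=f"grp{counter:04d}", population="NEA", group_id=gid)
            )
        blocks.append(g)
    if background_n:
        blocks.append(hwe(background_n))
        for _ in range(background_n):
            counter += 1
            samples.append(SampleMetadata(sample_id=f"bg{counter:04d}", population="NEA"))
    genotypes = np.concatenate(blocks, axis=0)
    dataset = GenotypeDataset([Locus(n) for n in loci_names], samples, genotypes)
    return dataset, truth


# -- genotyping-error model ------------------------------------------------

@dataclass
class ErrorEvent:
    sample_id: str
    locus: str
    kind: str  # dropout | null_allele | misscore | missing
    original: tuple[int, int]
    corrupted: tuple[int, int]


def apply_error_model(
    dataset: GenotypeDataset,
    config: ErrorModelConfig,
    seed: int | None = None,
) -> tuple[GenotypeDataset, list[ErrorEvent]]:
    """Corrupt single-locus genotypes per the error model; log every change.

    Order per call: null-allele masking (carriers of a designated null
    allele appear homozygous for their other allele; null homozygotes drop
    to missing), then allelic dropout of heterozygotes (losing the larger
    allele when ``larger_allele_bias``), then mis-scoring (one allele moves
    +/- one motif length), then whole-call missingness. The truth log
    replays to reconstruct the original dataset exactly.
    """
    rng = np.random.default_rng(seed)
    out = dataset.copy()
    g = out.genotypes
    events: list[ErrorEvent] = []
    motif = {l.name: l.motif_length for l in dataset.loci}
    for j, locus in enumerate(dataset.locus_names):
        null = config.null_alleles.get(locus)
        for i, sid in enumerate(dataset.sample_ids):
            a, b = int(g[i, j, 0]), int(g[i, j, 1])
            if a == MISSING:
                continue
            orig = (a, b)
            if null is not None and null in (a, b):
                if a == b:
                    a = b = MISSING
                else:
                    keep = b if a == null else a
                    a = b = keep
                events.append(ErrorEvent(sid, locus, "null_allele", orig, (a, b)))
                if a == MISSING:
                    g[i, j] = (MISSING, MISSING)
                    continue
            cur = (a, b)
            if a != b and rng.random() < config.dropout_rate:
                if config.larger_allele_bias:
                    a = b = min(a, b)
                else:
                    a = b = int(rng.choice([a, b]))
                events.append(ErrorEvent(sid, locus, "dropout", cur, (a, b)))
                cur = (a, b)
            if rng.random() < config.misscore_rate:
                slot = int(rng.integers(0, 2))
                shift = int(rng.choice([-1, 1])) * motif[locus]
                pair = [a, b]
                pair[slot] = max(pair[slot] + shift, 1)
                a, b = min(pair), max(pair)
                events.append(ErrorEvent(sid, locus, "misscore", cur, (a, b)))
                cur = (a, b)
            if rng.random() < config.missing_rate:
                events.append(ErrorEvent(sid, locus, "missing", cur, (MISSING, MISSING)))
                a = b = MISSING
            g[i, j] = (min(a, b), max(a, b)) if a != MISSING else (MISSING, MISSING)
    return out, events


def replay_errors(corrupted: GenotypeDataset, events: list[ErrorEvent]) -> GenotypeDataset:
    """Invert the error log, restoring the original dataset."""
    out = corrupted.copy()
    for ev in reversed(events):
        i = out.index_of(ev.sample_id)
        j = out.locus_names.index(ev.locus)
        out.genotypes[i, j] = ev.original
    out.genotypes = np.sort(out.genotypes, axis=2)
    return out


# -- recapture injection ---------------------------------------------------

def inject_recaptures(
    dataset: GenotypeDataset,
    n_recaptures: int,
    error_config: ErrorModelConfig | None = None,
    seed: int | None = None,
) -> tuple[GenotypeDataset, list[tuple[str, str]]]:
    """Duplicate individuals as simulated re-encounters.

    Chosen individuals are copied under a new sample id (suffix ``_r``),
    optionally corrupted by the error model; returns the augmented dataset
    and the truth list of (original_id, recapture_id) pairs.
    """
    if n_recaptures > dataset.n_samples:
        raise ValueError("n_recaptures exceeds the number of individuals")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(dataset.n_samples, size=n_recaptures, replace=False)
    copies = dataset.subset([dataset.sample_ids[i] for i in chosen])
    for s in copies.samples:
        s.sample_id = s.sample_id + "_r"
    copies = GenotypeDataset(copies.loci, copies.samples, copies.genotypes)
    if error_config is not None:
        copies, _ = apply_error_model(copies, error_config, seed=seed)
    merged = GenotypeDataset(
        dataset.loci,
        [replace(s) for s in dataset.samples] + [replace(s) for s in copies.samples],
        np.concatenate([dataset.genotypes, copies.genotypes], axis=0),
    )
    truth = [
        (dataset.sample_ids[i], dataset.sample_ids[i] + "_r") for i in chosen
    ]
    return merged, truth


# -- single closed Wright-Fisher population --------------------------------

def simulate_wright_fisher(
    true_ne: int,
    sample_s: int,
    n_loci: int = 20,
    alleles_per_locus: int = 10,
    generations: int = 20,
    seed: int | None = None,
    dirichlet_alpha: float = 1.0,
) -> GenotypeDataset:
    """Individual-based Wright-Fisher population of ``true_ne`` diploids.

    Discrete generations, random union of gametes (parents drawn uniformly
    with replacement), unlinked loci inherited jointly from each parent —
    the finite parent pool is what generates the between-locus linkage
    disequilibrium that the LD-Ne method measures. Returns a sample of
    ``sample_s`` diploids drawn without replacement.
    """
    if true_ne < 2:
        raise ValueError("true_ne must be >= 2")
    if sample_s > true_ne:
        raise ValueError("sample_s cannot exceed true_ne")
    rng = np.random.default_rng(seed)
    loci, labels, freqs = ancestral_frequencies(
        rng, n_loci, alleles_per_locus, alleles_per_locus, alpha=dirichlet_alpha
    )
    N = true_ne
    pop = np.zeros((N, n_loci, 2), dtype=np.int32)
    for j in range(n_loci):
        pop[:, j, :] = _sample_hwe(rng, labels[j], freqs[j], N)
    rows = np.arange(N)[:, None]
    cols = np.arange(n_loci)[None, :]
    for _ in range(generations):
        mothers = rng.integers(0, N, size=N)
        fathers = rng.integers(0, N, size=N)
        pick_m = rng.integers(0, 2, size=(N, n_loci))
        pick_f = rng.integers(0, 2, size=(N, n_loci))
        child = np.zeros_like(pop)
        child[:, :, 0] = pop[mothers[:, None], cols, pick_m]
        child[:, :, 1] = pop[fathers[:, None], cols, pick_f]
        pop = child
    pop = np.sort(pop, axis=2)
    chosen = rng.choice(N, size=sample_s, replace=False)
    samples = [SampleMetadata(sample_id=f"wf{i:04d}", population="wf") for i in range(sample_s)]
    return GenotypeDataset(loci, samples, pop[chosen])


# -- field-survey preset -----------------------------------------------------

FIELD_SURVEY_POP_SIZES = {"IoM": 97, "IRE": 89, "IRE_12": 88, "SCO": 133}  # sums to 407


def field_survey_dataset(seed: int = 0, target_gst: float = 0.01) -> GenotypeDataset:
    """A 407-individual, 19-locus, 4-population dataset with weak structure.

    Allele counts uniform on [3, 18], expected heterozygosity ~ 0.66 and
    between-population differentiation near ``target_gst`` via the
    Balding-Nichols model.
    """
    dataset, _ = simulate_balding_nichols(
        n_pops=4,
        target_fst=target_gst,
        n={f"pop{k + 1}": s for k, s in enumerate(FIELD_SURVEY_POP_SIZES.values())},
        seed=seed,
    )
    names = list(FIELD_SURVEY_POP_SIZES)
    for s in dataset.samples:
        s.population = names[int(s.population.removeprefix("pop")) - 1]
    return GenotypeDataset(dataset.loci, dataset.samples, dataset.genotypes)
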