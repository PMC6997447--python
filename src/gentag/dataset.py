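"""Core data model: diploid microsatellite genotypes with sample metadata.

Allele labels are positive integers (fragment sizes in base pairs). Genotype
calls are stored unordered in canonical form (smaller label first); phase is
unknowable for microsatellites. A call is either fully typed or fully missing.
"""
from __future__ import annotations

import datetime
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

#: Sentinel allele label for a missing call (both slots 0).
MISSING = 0

POOLED = "__pooled__"


@dataclass(frozen=True)
class Locus:
    """A microsatellite locus. ``motif_length`` is metadata (bp per repeat)."""

    name: str
    motif_length: int = 2

    def __post_init__(self) -> None:
        if self.motif_length < 1:
            raise ValueError(f"motif_length must be >= 1, got {self.motif_length}")


@dataclass
class SampleMetadata:
    """Per-sample metadata: identity, location, date, sex, group membership."""

    sample_id: str
    population: str = "pop1"
    site: str | None = None
    date: datetime.date | None = None
    latitude: float | None = None
    longitude: float | None = None
    sex: str = "unknown"
    length_m: float | None = None
    group_id: str | None = None

    def __post_init__(self) -> None:
        if self.latitude is not None and not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude out of range: {self.latitude}")
        if self.longitude is not None and not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude out of range: {self.longitude}")
        if self.sex not in ("female", "male", "unknown"):
            raise ValueError(f"sex must be female/male/unknown, got {self.sex!r}")
        if self.length_m is not None and self.length_m < 0:
            raise ValueError("length_m must be >= 0")


def canonicalize(genotypes: np.ndarray) -> np.ndarray:
    """Return calls sorted (min, max) per pair; half-missing calls are an error."""
    g = np.asarray(genotypes, dtype=np.int32)
    if g.ndim != 3 or g.shape[2] != 2:
        raise ValueError("genotype array must have shape (n_samples, n_loci, 2)")
    if g.size == 0:
        return g
    if g.min() < 0:
        raise ValueError("allele labels must be positive (0 = missing)")
    half = (g[..., 0] == MISSING) != (g[..., 1] == MISSING)
    if half.any():
        i, j = np.argwhere(half)[0]
        raise ValueError(
            f"half-missing call at sample index {i}, locus index {j}: "
            "both alleles must be present or both missing"
        )
    return np.sort(g, axis=2)


class GenotypeDataset:
    """Individuals x loci matrix of unordered diploid calls plus metadata.

    ``genotypes`` has shape (n_samples, n_loci, 2), dtype int32, canonical
    order, with ``(0, 0)`` meaning missing.
    """

    def __init__(
        self,
        loci: Sequence[Locus],
        samples: Sequence[SampleMetadata],
        genotypes: np.ndarray,
    ):
        names = [l.name for l in loci]
        if len(set(names)) != len(names):
            raise ValueError("locus names must be unique")
        ids = [s.sample_id for s in samples]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate sample_id(s): {sorted(dupes)}")
        g = canonicalize(genotypes)
        if g.shape[:2] != (len(samples), len(loci)):
            raise ValueError(
                f"genotype array shape {g.shape[:2]} does not match "
                f"({len(samples)} samples, {len(loci)} loci)"
            )
        self.loci = list(loci)
        self.samples = list(samples)
        self.genotypes = g
        self._index = {s.sample_id: k for k, s in enumerate(self.samples)}

    # -- basic accessors ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.loci]

    @property
    def populations(self) -> list[str]:
        """Distinct population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.population, None)
        return list(seen)

    def population_labels(self) -> np.ndarray:
        return np.array([s.population for s in self.samples])

    def index_of(self, sample_id: str) -> int:
        return self._index[sample_id]

    def metadata(self, sample_id: str) -> SampleMetadata:
        return self.samples[self._index[sample_id]]

    def call(self, sample_id: str, locus: str) -> tuple[int, int]:
        j = self.locus_names.index(locus)
        a, b = self.genotypes[self._index[sample_id], j]
        return int(a), int(b)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_samples, n_loci): True where the call is missing."""
        return self.genotypes[..., 0] == MISSING

    def missing_per_sample(self) -> np.ndarray:
        return self.missing_mask().sum(axis=1)

    def proportion_typed(self) -> float:
        """Mean proportion of (sample, locus) cells with a typed call."""
        return float(1.0 - self.missing_mask().mean())

    # -- transforms --------------------------------------------------------
    def subset(self, sample_ids: Iterable[str]) -> "GenotypeDataset":
        idx = [self._index[s] for s in sample_ids]
        return GenotypeDataset(
            self.loci,
            [replace(self.samples[i]) for i in idx],
            self.genotypes[idx].copy(),
        )

    def drop(self, sample_ids: Iterable[str]) -> "GenotypeDataset":
        omit = set(sample_ids)
        keep = [s.sample_id for s in self.samples if s.sample_id not in omit]
        return GenotypeDataset(
            self.loci,
            [replace(self.metadata(s)) for s in keep],
            self.genotypes[[self._index[s] for s in keep]].copy(),
        )

    def copy(self) -> "GenotypeDataset":
        return GenotypeDataset(
            self.loci, [replace(s) for s in self.samples], self.genotypes.copy()
        )

    def equals(self, other: "GenotypeDataset") -> bool:
        return (
            self.loci == other.loci
            and self.samples == other.samples
            and np.array_equal(self.genotypes, other.genotypes)
        )

    def __repr__(self) -> str:
        return (
            f"GenotypeDataset({self.n_samples} samples, {self.n_loci} loci, "
            f"{len(self.populations)} population(s))"
        )


@dataclass
class AlleleFrequencyTable:
    """Allele frequencies per (population, locus).

    ``freqs[(pop, locus)]`` maps allele label -> frequency; ``n_genes`` counts
    2 x (individuals typed). A pooled view (all samples as one population) is
    stored under the population key :data:`POOLED`.
    """

    freqs: dict[tuple[str, str], dict[int, float]] = field(default_factory=dict)
    n_genes: dict[tuple[str, str], int] = field(default_factory=dict)

    def frequencies(self, population: str, locus: str) -> dict[int, float]:
        return self.freqs[(population, locus)]

    def genes(self, population: str, locus: str) -> int:
        return self.n_genes[(population, locus)]

    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for pop, _ in self.freqs:
            seen.setdefault(pop, None)
        return list(seen)

    def loci(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, loc in self.freqs:
            seen.setdefault(loc, None)
        return list(seen)

    def freq_vectors(self, population: str) -> dict[str, np.ndarray]:
        """Per-locus frequency arrays (alleles sorted by label)."""
        out = {}
        for loc in self.loci():
            d = self.freqs.get((population, loc))
            if d:
                out[loc] = np.array([d[a] for a in sorted(d)])
        return out


def allele_frequencies(
    dataset: GenotypeDataset, grouping: str = "population"
) -> AlleleFrequencyTable:
    """Estimate allele frequencies by direct counting, missing calls excluded.

    grouping="population" computes per-population tables plus a pooled table;
    grouping="pooled" computes the pooled table only. A (population, locus)
    with zero typed individuals is flagged empty: present with an empty
    mapping and n_genes = 0.
    """
    if grouping not in ("population", "pooled"):
        raise ValueError("grouping must be 'population' or 'pooled'")
    table = AlleleFrequencyTable()
    groups: list[tuple[str, np.ndarray]] = []
    if grouping == "population":
        labels = dataset.population_labels()
        groups.extend((p, labels == p) for p in dataset.populations)
    groups.append((POOLED, np.ones(dataset.n_samples, dtype=bool)))
    for pop, mask in groups:
        sub = dataset.genotypes[mask]
        for j, locus in enumerate(dataset.locus_names):
            alleles = sub[:, j, :].ravel()
            alleles = alleles[alleles != MISSING]
            key = (pop, locus)
            if alleles.size == 0:
                table.freqs[key] = {}
                table.n_genes[key] = 0
                continue
            labels_u, counts = np.unique(alleles, return_counts=True)
            total = counts.sum()
            table.freqs[key] = {
                int(a): float(c) / total for a, c in zip(labels_u, counts)
            }
            table.n_genes[key] = int(total)
    return table


def filter_by_missing(
    dataset: GenotypeDataset, max_missing_loci: int = 6
) -> tuple[GenotypeDataset, list[str]]:
    """Drop individuals that failed to amplify at more than ``max_missing_loci``.

    Returns the filtered dataset and the removal log (ids removed, in input
    order). Individuals missing exactly ``max_missing_loci`` are retained.
    """
    miss = dataset.missing_per_sample()
    removed = [s.sample_id for s, m in zip(dataset.samples, miss) if m > max_missing_loci]
    if not removed:
        return dataset, []
    return dataset.drop(removed), removed


def parse_date(text: str) -> datetime.date:
    """Parse DD.MM.YYYY (field convention) or ISO-8601 YYYY-MM-DD."""
    text = text.strip()
    for fmt in ("%d.%m.%Y", "%Y-%m-%d"):
        try:
            return datetime.datetime.strptime(text, fmt).date()
        except ValueError:
            continue
    raise ValueError(f"unparseable date: {text!r} (expected DD.MM.YYYY or YYYY-MM-DD)")
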