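"""Readers and writers: wide CSV, GenePop (2/3-digit) and Structure formats.

The wide CSV dialect has a header of metadata columns (``sample_id`` required;
``population``, ``site``, ``date``, ``latitude``, ``longitude``, ``sex``,
``length_m``, ``group_id`` optional) followed by two columns per locus named
``<locus>.a1`` and ``<locus>.a2``. Cells of ``0`` or blank are missing.
Writers are deterministic byte-for-byte for a given dataset.
"""
from __future__ import annotations

import re
from pathlib import Path

import pandas as pd

from .dataset import (
    MISSING,
    GenotypeDataset,
    Locus,
    SampleMetadata,
    parse_date,
)

import numpy as np

_METADATA_COLS = (
    "sample_id",
    "population",
    "site",
    "date",
    "latitude",
    "longitude",
    "sex",
    "length_m",
    "group_id",
)


class FormatError(ValueError):
    """Raised for malformed genotype files."""


def _parse_allele(cell, row: int, col: str) -> int:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return MISSING
    text = str(cell).strip()
    if text in ("", "0", "0.0"):
        return MISSING
    try:
        value = int(float(text))
    except ValueError:
        raise FormatError(f"row {row}: non-integer allele {cell!r} in column {col}")
    if value < 0:
        raise FormatError(f"row {row}: negative allele {value} in column {col}")
    return value


def read_genotype_table(path: str | Path) -> GenotypeDataset:
    """Read the wide CSV dialect into a :class:`GenotypeDataset`."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = list(df.columns)
    if "sample_id" not in cols:
        raise FormatError("header must include a sample_id column")
    allele_cols = [c for c in cols if re.search(r"\.a[12]$", c)]
    if len(allele_cols) % 2 != 0:
        raise FormatError(f"odd number of allele columns ({len(allele_cols)})")
    locus_names: list[str] = []
    for c in allele_cols:
        name = c[: c.rfind(".")]
        if name not in locus_names:
            locus_names.append(name)
    for name in locus_names:
        if f"{name}.a1" not in cols or f"{name}.a2" not in cols:
            raise FormatError(f"locus {name!r} must have both .a1 and .a2 columns")

    samples: list[SampleMetadata] = []
    seen: set[str] = set()
    rows = []
    for i, row in df.iterrows():
        rownum = int(i) + 2  # 1-based with header line
        sid = row["sample_id"].strip()
        if not sid:
            raise FormatError(f"row {rownum}: empty sample_id")
        if sid in seen:
            raise FormatError(f"duplicate sample_id {sid!r}")
        seen.add(sid)
        kwargs: dict = {"sample_id": sid}
        for key in _METADATA_COLS[1:]:
            if key not in cols:
                continue
            text = str(row[key]).strip()
            if not text:
                continue
            if key == "date":
                try:
                    kwargs["date"] = parse_date(text)
                except ValueError as exc:
                    raise FormatError(f"row {rownum}: {exc}") from exc
            elif key in ("latitude", "longitude", "length_m"):
                kwargs[key] = float(text)
            else:
                kwargs[key] = text
        samples.append(SampleMetadata(**kwargs))
        calls = []
        for name in locus_names:
            a = _parse_allele(row[f"{name}.a1"], rownum, f"{name}.a1")
            b = _parse_allele(row[f"{name}.a2"], rownum, f"{name}.a2")
            if (a == MISSING) != (b == MISSING):
                a = b = MISSING  # half-called genotypes are unusable
            calls.append((a, b))
        rows.append(calls)

    genotypes = np.array(rows, dtype=np.int32).reshape(len(samples), len(locus_names), 2)
    return GenotypeDataset([Locus(n) for n in locus_names], samples, genotypes)


def write_genotype_table(dataset: GenotypeDataset, path: str | Path) -> None:
    """Write the wide CSV dialect (ISO dates; missing alleles as 0)."""
    records = []
    for k, s in enumerate(dataset.samples):
        rec: dict = {
            "sample_id": s.sample_id,
            "population": s.population,
            "site": s.site or "",
            "date": s.date.isoformat() if s.date else "",
            "latitude": "" if s.latitude is None else repr(s.latitude),
            "longitude": "" if s.longitude is None else repr(s.longitude),
            "sex": s.sex,
            "length_m": "" if s.length_m is None else repr(s.length_m),
            "group_id": s.group_id or "",
        }
        for j, name in enumerate(dataset.locus_names):
            a, b = dataset.genotypes[k, j]
            rec[f"{name}.a1"] = int(a)
            rec[f"{name}.a2"] = int(b)
        records.append(rec)
    pd.DataFrame.from_records(records).to_csv(path, index=False)


# -- GenePop ---------------------------------------------------------------

def read_genepop(path: str | Path) -> GenotypeDataset:
    """Read a GenePop file; auto-detects 2- vs 3-digit allele coding per file.

    Populations are named pop1, pop2, ... from POP blocks; "00"/"000" codes
    become missing calls.
    """
    lines = Path(path).read_text().splitlines()
    if len(lines) < 2:
        raise FormatError("GenePop file too short")
    body = lines[1:]
    # locus list: one per line, or comma-separated on one line, up to first POP
    locus_names: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().upper() != "POP":
        part = body[i].strip()
        if part:
            locus_names.extend(x.strip() for x in part.split(",") if x.strip())
        i += 1
    if i == len(body):
        raise FormatError("no POP line found")

    digits: int | None = None
    samples: list[SampleMetadata] = []
    rows: list[list[tuple[int, int]]] = []
    pop = 0
    for lineno, line in enumerate(body[i:], start=i + 2):
        text = line.strip()
        if not text:
            continue
        if text.upper() == "POP":
            pop += 1
            continue
        if "," not in text:
            raise FormatError(f"line {lineno}: expected 'id , genotypes'")
        sid, geno_text = text.split(",", 1)
        fields = geno_text.split()
        if len(fields) != len(locus_names):
            raise FormatError(
                f"line {lineno}: {len(fields)} genotypes for {len(locus_names)} loci"
            )
        calls = []
        for field, name in zip(fields, locus_names):
            if len(field) not in (4, 6) or not field.isdigit():
                raise FormatError(
                    f"line {lineno}: truncated or invalid genotype {field!r} at {name}"
                )
            d = len(field) // 2
            if digits is None:
                digits = d
            elif digits != d:
                raise FormatError(
                    f"line {lineno}: mixed {2 * digits}- and {2 * d}-character "
                    "genotype codes in one file"
                )
            a, b = int(field[:d]), int(field[d:])
            if a == 0 or b == 0:
                a = b = MISSING
            calls.append((a, b))
        samples.append(SampleMetadata(sample_id=sid.strip(), population=f"pop{pop}"))
        rows.append(calls)

    genotypes = np.array(rows, dtype=np.int32).reshape(len(samples), len(locus_names), 2)
    return GenotypeDataset([Locus(n) for n in locus_names], samples, genotypes)


def write_genepop(dataset: GenotypeDataset, path: str | Path, title: str = "gentag export") -> None:
    """Write 3-digit GenePop; allele labels must be <= 999."""
    if dataset.n_samples and int(dataset.genotypes.max(initial=0)) > 999:
        raise FormatError(
            "allele label > 999 cannot be written as 3-digit GenePop; "
            "recode alleles (e.g. subtract a locus-wise offset) first"
        )
    out = [title]
    out.extend(dataset.locus_names)
    for pop in dataset.populations:
        out.append("POP")
        for k, s in enumerate(dataset.samples):
            if s.population != pop:
                continue
            parts = [
                f"{int(a):03d}{int(b):03d}" for a, b in dataset.genotypes[k]
            ]
            out.append(f"{s.sample_id} , " + " ".join(parts))
    Path(path).write_text("\n".join(out) + "\n")


def write_structure(dataset: GenotypeDataset, path: str | Path) -> None:
    """Write a two-row-per-individual Structure file.

    Alleles are recoded to consecutive integers per locus (sorted by label);
    missing is -9. Header row lists locus names; each data row is
    ``sample_id pop_index allele...``.
    """
    recode: list[dict[int, int]] = []
    for j in range(dataset.n_loci):
        alleles = dataset.genotypes[:, j, :].ravel()
        alleles = sorted(set(int(a) for a in alleles if a != MISSING))
        recode.append({a: i + 1 for i, a in enumerate(alleles)})
    pops = {p: i + 1 for i, p in enumerate(dataset.populations)}
    out = ["\t".join(dataset.locus_names)]
    for k, s in enumerate(dataset.samples):
        for slot in (0, 1):
            row = [s.sample_id, str(pops[s.population])]
            for j in range(dataset.n_loci):
                a = int(dataset.genotypes[k, j, slot])
                row.append("-9" if a == MISSING else str(recode[j][a]))
            out.append("\t".join(row))
    Path(path).write_text("\n".join(out) + "\n")
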