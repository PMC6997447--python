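"""End-to-end orchestration of the genetic-tagging workflow.

Stage order: read -> missing-data filter -> replicate error rate (optional)
-> matching -> re-encounter classification -> deduplication -> diversity +
HWE/LD screens -> probability of identity -> pairwise differentiation with
bootstrap CIs and multiple-testing adjustment -> Nei distance + PCoA ->
relatedness (pairwise, groups, permutation test) -> LD-Ne -> age-structure
adjustment -> census inference. Outputs are deterministic given (inputs,
config, seed).
"""
from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import differentiation as diff
from . import effective_size as es
from . import io as gio
from . import popstats, relatedness, tagging
from .dataset import GenotypeDataset, allele_frequencies, filter_by_missing

log = logging.getLogger("gentag.pipeline")


@dataclass
class PipelineConfig:
    input_path: str | None = None
    replicate_path: str | None = None
    max_mismatch: int = 3
    max_missing_loci: int = 6
    site_radius_km: float = 20.0
    estimators: tuple[str, ...] = ("LynchRD", "DyadML")
    iterations: int = 1000
    n_bootstrap: int = 1000
    n_permutations: int = 999
    pcrit: float = 0.02
    age_ratio_low: float = 0.74
    age_ratio_high: float = 0.86
    ne_n_ratio: float = 0.6
    ne_population: str | None = None
    seed: int = 0
    output_dir: str = "gentag_out"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a declarative config file; keyword arguments override it."""
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update(overrides)
        if "estimators" in data:
            data["estimators"] = tuple(data["estimators"])
        return cls(**data)


def _json_default(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        v = float(x)
        return v if math.isfinite(v) else str(v)
    if isinstance(x, float) and not math.isfinite(x):
        return str(x)
    if dataclasses.is_dataclass(x):
        return dataclasses.asdict(x)
    raise TypeError(f"not serializable: {type(x)}")


def run_pipeline(
    config: PipelineConfig, dataset: GenotypeDataset | None = None
) -> dict:
    """Run the full workflow; write reports under ``config.output_dir``.

    ``dataset`` may be passed directly (e.g. a synthetic dataset); otherwise
    ``config.input_path`` is read (GenePop if the suffix is .gen/.genepop,
    wide CSV otherwise). Returns the report bundle as a dict.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": dataclasses.asdict(config)}
    rng_seed = config.seed

    if dataset is None:
        if config.input_path is None:
            raise ValueError("either dataset or config.input_path is required")
        path = Path(config.input_path)
        reader = gio.read_genepop if path.suffix in (".gen", ".genepop") else gio.read_genotype_table
        dataset = reader(path)
    log.info("input: %s", dataset)
    report["n_input"] = dataset.n_samples

    stage = "filter_by_missing"
    try:
        dataset, removed = filter_by_missing(dataset, config.max_missing_loci)
        report["removed_missing"] = removed
        log.info("%s: removed %d", stage, len(removed))

        if config.replicate_path:
            stage = "genotyping_error_rate"
            rep = gio.read_genotype_table(config.replicate_path)
            err = tagging.genotyping_error_rate(dataset, rep)
            report["error_rate"] = {
                "mean_rate": err.mean_rate,
                "n_mismatching": err.n_mismatching,
                "n_replicated": err.n_replicated,
                "per_locus": err.per_locus_rate,
            }

        stage = "find_matches"
        matches = tagging.find_matches(dataset, config.max_mismatch)
        report["n_matches"] = len(matches)

        stage = "classify_reencounters"
        reencounters = tagging.classify_reencounters(
            matches, dataset, config.site_radius_km
        )
        pd.DataFrame(
            [dataclasses.asdict(r) for r in reencounters]
        ).to_csv(out_dir / "reencounters.tsv", sep="\t", index=False)
        report["n_reencounters"] = len(reencounters)

        stage = "deduplicate"
        dataset, dropped = tagging.deduplicate(dataset, matches)
        report["removed_duplicates"] = dropped
        report["n_unique"] = dataset.n_samples

        stage = "diversity"
        summary = popstats.diversity_summary(dataset)
        summary.table().to_csv(out_dir / "diversity.tsv", sep="\t", index=False)
        report["diversity_means"] = summary.means

        stage = "hwe_ld_screen"
        hwe_results = {}
        for pop in dataset.populations:
            for locus in dataset.locus_names:
                res = popstats.hwe_exact_test(
                    dataset, pop, locus, seed=rng_seed
                )
                if res.applicable:
                    hwe_results[f"{pop}:{locus}"] = res.p_value
        if hwe_results:
            adjusted = popstats.adjust_pvalues(list(hwe_results.values()), "fdr_bh")
            report["hwe"] = {
                k: {"p": p, "p_fdr": float(q)}
                for (k, p), q in zip(hwe_results.items(), adjusted)
            }

        stage = "pid"
        freqs = allele_frequencies(dataset)
        pid_res = tagging.pid(freqs)
        report["pid"] = {
            "multilocus_unbiased": pid_res.multilocus_unbiased,
            "multilocus_sibs": pid_res.multilocus_sibs,
        }

        stage = "differentiation"
        pairs = diff.pairwise_differentiation(dataset)
        diff_rows = []
        for pd_pair in pairs if isinstance(pairs, list) else [pairs]:
            row = dataclasses.asdict(pd_pair)
            if min(np.sum(dataset.population_labels() == p) for p in (pd_pair.pop1, pd_pair.pop2)) >= 3:
                lo, hi, sig = diff.bootstrap_ci(
                    dataset, (pd_pair.pop1, pd_pair.pop2), "gst_nei",
                    n_boot=config.n_bootstrap, seed=rng_seed,
                )
                row["gst_ci"] = (lo, hi)
                row["gst_significant"] = sig
            diff_rows.append(row)
        report["differentiation"] = diff_rows

        stage = "ordination"
        pops, dist = diff.nei_distance(dataset)
        if len(pops) >= 3 and np.all(np.isfinite(dist)):
            ord_res = diff.pcoa(dist, labels=pops)
            report["pcoa_percent_variance"] = ord_res.percent_variance[:2].tolist()

        stage = "relatedness"
        groups: dict[str, list[str]] = {}
        for s in dataset.samples:
            if s.group_id:
                groups.setdefault(s.group_id, []).append(s.sample_id)
        groups = {g: m for g, m in groups.items() if len(m) >= 2}
        if groups:
            grp = relatedness.group_permutation_test(
                dataset, groups, estimator=config.estimators[0],
                iterations=config.iterations, seed=rng_seed,
            )
            report["group_relatedness"] = {
                "estimator": grp.estimator,
                "observed_overall": grp.observed_overall,
                "expected_overall": grp.expected_overall,
                "p_overall": grp.p_overall,
            }

        stage = "effective_size"
        try:
            ne = es.ld_ne(dataset, config.ne_population, pcrit=config.pcrit)
            adj_low = es.adjust_ne_age_structure(ne.ne_point, config.age_ratio_low)
            census = es.census_from_ne(adj_low.ne_adjusted, config.ne_n_ratio)
            report["ne"] = {
                "pcrit": ne.pcrit,
                "mean_r2": ne.mean_r2,
                "ne_point": ne.ne_point,
                "ci": ne.ci_parametric,
                "ne_adjusted": adj_low.ne_adjusted,
                "census_estimate": census,
            }
        except ValueError as exc:
            report["ne"] = {"error": str(exc)}
    except Exception:
        log.exception("pipeline failed at stage %s", stage)
        report["failed_stage"] = stage
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=2, default=_json_default)
        )
        raise

    (out_dir / "report.json").write_text(
        json.dumps(report, indent=2, default=_json_default)
    )
    return report
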