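"""Configuration-driven orchestration of the full methylome analysis.

Stages run in a fixed order — probe filtering, per-age-group DML calling,
region-category enrichment, bivalent / dynamic / EDR enrichment, and the
developmental delay report — writing TSV outputs plus a machine-readable
``summary.json``.  A single seed fans out to per-stage child seeds by
stable hashing of the stage name, so the randomness of one stage never
depends on which other stages exist.  Reruns with the same config and
seed are bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, dml, edr, io, regions, trajectory
from .simulate import DEFAULT_STAGE_BINS, SimulationConfig, simulate_dataset, write_dataset

SUMMARY_KEYS = ("filter", "dml", "region_enrichment", "bivalent", "dynamic", "edr", "delay")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def child_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31."""
    return (int(seed) ^ zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclasses.dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    simulate: dict | None = None
    paths: dict | None = None
    alpha: float = 0.05
    delta_beta: float = 0.10
    n_perm: int = 999
    stage_bins: tuple = DEFAULT_STAGE_BINS
    dynamic_range_threshold: float = 0.1
    delay_early_stages: int = 2

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.paths is None):
            raise ValueError("config needs exactly one of 'simulate' or 'paths'")
        if self.alpha <= 0 or self.delta_beta <= 0 or self.n_perm <= 0:
            raise ValueError("cutoffs must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, outdir: str | None = None, seed: int | None = None):
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "stage_bins" in raw:
            raw["stage_bins"] = tuple(tuple(b) for b in raw["stage_bins"])
        if outdir is not None:
            raw["outdir"] = outdir
        if seed is not None:
            raw["seed"] = seed
        return cls(**raw)


def _log(lines: list, message: str) -> None:
    lines.append(message)


def _load_inputs(config: PipelineConfig, outdir: Path, log: list):
    if config.simulate is not None:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("stage_bins", config.stage_bins)
        sim_kwargs["seed"] = child_seed(config.seed, "simulate")
        sim = SimulationConfig(**sim_kwargs)
        _log(log, f"simulate: seed={sim.seed} n_probes={sim.n_probes}")
        data = simulate_dataset(sim)
        write_dataset(data, outdir / "simulated")
        dynamic_input = None
        return (
            data.manifest,
            data.betas,
            data.samples,
            data.mark_a,
            data.mark_b,
            data.fetal,
            dynamic_input,
        )
    paths = config.paths
    manifest = io.read_manifest(paths["manifest"])
    betas = io.read_beta_matrix(paths["betas"])
    samples = io.read_sample_sheet(paths["samples"])
    mark_a = io.read_bed(paths["bed_a"])
    mark_b = io.read_bed(paths["bed_b"])
    fetal_betas = io.read_beta_matrix(paths["fetal_betas"])
    fetal_samples = pd.read_csv(paths["fetal_samples"], sep="\t", dtype={"sample_id": str})
    fetal = dataclasses.make_dataclass("F", ["betas", "samples"])(fetal_betas, fetal_samples)
    dynamic_input = None
    if paths.get("dynamic_probes"):
        dynamic_input = set(
            pd.read_csv(paths["dynamic_probes"], sep="\t", header=None)[0].astype(str)
        )
    return manifest, betas, samples, mark_a, mark_b, fetal, dynamic_input


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage, write outputs under ``config.outdir`` and
    return the summary dict (also written as summary.json)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    summary: dict = {
        "seed": config.seed,
        "cutoffs": {
            "alpha": config.alpha,
            "delta_beta": config.delta_beta,
            "n_perm": config.n_perm,
        },
        "versions": {
            "methyldelay": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    _log(log, f"pipeline seed={config.seed} alpha={config.alpha} "
              f"delta_beta={config.delta_beta} n_perm={config.n_perm}")

    stage = "inputs"
    try:
        manifest, betas, samples, mark_a, mark_b, fetal, dynamic_input = _load_inputs(
            config, outdir, log
        )

        stage = "filter"
        filtered, report = io.filter_probes(betas, manifest)
        io.write_filter_report(report, outdir / "filter_report.json")
        summary["filter"] = report.to_dict()
        _log(log, f"filter: retained {report.n_retained}/{report.n_input}")
        background = manifest[manifest["probe_id"].isin(filtered.index)]
        bg_ids = set(background["probe_id"])

        stage = "dml"
        dml_sets = []
        dml_summary = {}
        annot = manifest.set_index("probe_id")[
            ["chromosome", "position", "gene_symbol", "region_category"]
        ]
        for spec in dml.comparisons_from_sample_sheet(samples):
            called = dml.run_comparison(
                filtered,
                spec,
                alpha=config.alpha,
                delta=config.delta_beta,
                n_perm=config.n_perm,
                seed=child_seed(config.seed, f"dml:{spec.label}"),
            )
            out = called.table.join(annot).sort_index()
            out.to_csv(outdir / f"dml_{spec.label}.tsv", sep="\t", index_label="probe_id")
            dml_sets.append(called)
            dml_summary[spec.label] = len(called.table)
            _log(log, f"dml[{spec.label}]: {len(called.table)} loci "
                      f"(seed={child_seed(config.seed, f'dml:{spec.label}')})")
        union = edr.dml_union(dml_sets)
        dml_summary["union"] = len(union)
        summary["dml"] = dml_summary

        stage = "region_enrichment"
        region_rows = []
        for called in dml_sets:
            if len(called.table) == 0:
                continue
            counts = regions.categorize(called.probe_ids, background)
            tbl = regions.category_enrichment(counts)
            tbl.insert(0, "age_group", called.label)
            region_rows.append(tbl)
        region_table = (
            pd.concat(region_rows, ignore_index=True)
            if region_rows
            else pd.DataFrame()
        )
        region_table.to_csv(outdir / "region_enrichment.tsv", sep="\t", index=False)
        summary["region_enrichment"] = {
            row["age_group"] + "/" + row["category"]: round(float(row["fold"]), 4)
            for _, row in region_table.iterrows()
        } if len(region_table) else {}

        stage = "bivalent"
        bivalent_track = regions.intersect_tracks(mark_a, mark_b)
        io.write_bed(bivalent_track, outdir / "bivalent.bed")
        bivalent_ids, _, bg_pct = regions.probes_in_peaks(background, bivalent_track)
        bivalent_summary = {"background_percent": bg_pct, "n_peaks": len(bivalent_track)}
        for called in dml_sets:
            if len(called.table) == 0:
                continue
            subset = background[background["probe_id"].isin(called.probe_ids)]
            hits, count, pct = regions.probes_in_peaks(subset, bivalent_track)
            enr = regions.fold_enrichment(
                count, len(subset), len(bivalent_ids), len(background)
            )
            bivalent_summary[called.label] = {
                "n_in_bivalent": count,
                "n_dml": len(subset),
                "percent": pct,
                "fold": round(enr.fold, 4),
                "p": enr.p,
            }
        summary["bivalent"] = bivalent_summary
        _log(log, f"bivalent: {len(bivalent_track)} intersection peaks")

        stage = "dynamic"
        fetal_stages = trajectory.stage_bin_means(
            fetal.betas, fetal.samples, config.stage_bins
        )
        if dynamic_input is not None:
            dynamic_ids = dynamic_input & bg_ids
        else:
            span = fetal_stages.means.max(axis=1) - fetal_stages.means.min(axis=1)
            dynamic_ids = set(span.index[span >= config.dynamic_range_threshold]) & bg_ids
        pd.Series(sorted(dynamic_ids)).to_csv(
            outdir / "dynamic_probes.tsv", sep="\t", index=False, header=False
        )
        dyn_enr = (
            edr.dynamic_overlap(union, dynamic_ids, bg_ids)
            if union and dynamic_ids
            else None
        )
        summary["dynamic"] = {
            "n_dynamic": len(dynamic_ids),
            "fold": round(dyn_enr.fold, 4) if dyn_enr else None,
            "p": dyn_enr.p if dyn_enr else None,
        }

        stage = "edr"
        bivalent_bg = bivalent_ids & bg_ids
        edr_set = edr.define_edr(
            bivalent_bg, dynamic_ids, bivalent_source="mark intersection",
            dynamic_source="fetal stage-mean range",
        )
        pd.Series(sorted(edr_set.probe_ids)).to_csv(
            outdir / "edr_probes.tsv", sep="\t", index=False, header=False
        )
        edr_enr = (
            edr.edr_enrichment(union, edr_set, bg_ids)
            if union and len(edr_set)
            else None
        )
        summary["edr"] = {
            "n_edr": len(edr_set),
            "n_dml_in_edr": edr_enr.n_in_subset if edr_enr else 0,
            "fold": round(edr_enr.fold, 4) if edr_enr else None,
            "p": edr_enr.p if edr_enr else None,
        }
        _log(log, f"edr: {len(edr_set)} probes")

        stage = "delay"
        # the trajectory matrix is computed over the case-associated DML that
        # fall in EDRs; if too few are present, fall back to the full EDR set
        delay_summary = {}
        subset = sorted(set(edr_set.probe_ids) & union & set(filtered.index))
        subset_kind = "dml_in_edr"
        if len(subset) < 3:
            subset = sorted(set(edr_set.probe_ids) & set(filtered.index))
            subset_kind = "edr"
        if len(subset) >= 3:
            reports = {}
            for pooled in (False, True):
                profiles = trajectory.group_profiles(
                    filtered, samples, subset, pool_age_groups=pooled
                )
                rep = trajectory.correlate_profiles(profiles, fetal_stages, subset)
                reports["pooled" if pooled else "per_group"] = trajectory.delay_score(
                    rep, n_early_stages=config.delay_early_stages
                )
            report = reports["per_group"]
            report.r.to_csv(outdir / "delay_correlations.tsv", sep="\t")
            report.delay_scores.to_csv(outdir / "delay_scores.tsv", sep="\t")
            reports["pooled"].r.to_csv(outdir / "delay_correlations_pooled.tsv", sep="\t")
            delay_summary = {
                "subset": subset_kind,
                "n_cpgs": len(subset),
                "r": {
                    f"{diag}:{grp}": {s: round(float(v), 4) for s, v in row.items()}
                    for (diag, grp), row in report.r.iterrows()
                },
                "delay_scores": {
                    grp: {s: round(float(v), 4) for s, v in row.items()}
                    for grp, row in report.delay_scores.iterrows()
                },
                "delay_scores_pooled": {
                    grp: {s: round(float(v), 4) for s, v in row.items()}
                    for grp, row in reports["pooled"].delay_scores.iterrows()
                },
            }
        summary["delay"] = delay_summary

    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        (outdir / "run.log").write_text("\n".join(log + [f"FAILED at {stage}: {exc}"]) + "\n")
        raise PipelineError(stage, exc) from exc

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    (outdir / "run.log").write_text("\n".join(log) + "\n")
    return summary
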