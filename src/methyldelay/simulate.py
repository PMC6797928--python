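"""Synthetic methylome cohorts with planted ground truth.

Emulates the data shapes of a 450k-style case/control brain methylation
study: a probe manifest with genomic annotation, two histone-mark peak
tracks whose intersection defines bivalent domains, a staged fetal-brain
reference series with monotone developmental trajectories at dynamic CpGs,
and a postnatal case/control cohort in which differentially methylated loci
(DML) are planted with a known signed effect and a configurable subset of
bivalent-and-dynamic CpGs is "delayed": the case group mean is set to an
earlier fetal stage's value while controls sit at the final stage.

Every generator is deterministic given ``SimulationConfig.seed``; child
random streams are derived per stage so adding a stage never perturbs the
randomness of earlier ones.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    REGION_CATEGORIES,
    write_bed,
    write_beta_matrix,
    write_manifest,
    write_sample_sheet,
)

DEFAULT_STAGE_BINS = (
    ("s1", 23, 76),
    ("s2", 77, 89),
    ("s3", 90, 108),
    ("s4", 109, 184),
)

_AGE_RANGES = {"young": (2.0, 16.0), "middle": (17.0, 40.0), "old": (41.0, 80.0)}

# probes sit on this coordinate grid so peak margins can never leak onto a
# neighbouring probe
_GRID = 16


class ConfigurationError(ValueError):
    pass


class CapacityError(ValueError):
    pass


@dataclasses.dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults mirror the emulated design
    (three age groups, six samples per arm, a 0.15 planted effect against a
    0.10 call cutoff, four prenatal stage bins)."""

    n_probes: int = 10_000
    chrom_layout: tuple = (("chr1", 50_000_000), ("chr2", 30_000_000))
    n_per_group: int = 6
    age_groups: tuple = ("young", "middle", "old")
    dml_fraction: float = 0.05
    dml_delta: float = 0.15
    noise_sd: float = 0.02
    bivalent_probe_fraction: float = 0.10
    dynamic_fraction: float = 0.08
    delayed_fraction: float = 0.18
    edr_dml_fold: float = 4.0
    dynamic_dml_fold: float = 3.0
    region_proportions: tuple = ((0.30, 0.35, 0.05, 0.30))
    snp_fraction: float = 0.02
    cpg_island_fraction: float = 0.30
    stage_bins: tuple = DEFAULT_STAGE_BINS
    n_fetal_per_stage: int = 25
    delay_to_stage: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = {
            "dml_fraction": self.dml_fraction,
            "bivalent_probe_fraction": self.bivalent_probe_fraction,
            "dynamic_fraction": self.dynamic_fraction,
            "delayed_fraction": self.delayed_fraction,
            "snp_fraction": self.snp_fraction,
            "cpg_island_fraction": self.cpg_island_fraction,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name}={value} outside [0, 1]")
        if abs(sum(self.region_proportions) - 1.0) > 1e-9:
            raise ConfigurationError("region_proportions must sum to 1")
        if self.n_per_group < 2:
            raise ConfigurationError("n_per_group must be >= 2")
        bins = list(self.stage_bins)
        for (_, lo, hi) in bins:
            if lo > hi:
                raise ConfigurationError(f"stage bin [{lo}, {hi}] inverted")
        for (_, _, hi_prev), (_, lo_next, _) in zip(bins, bins[1:]):
            if lo_next <= hi_prev:
                raise ConfigurationError("stage bins overlap or are unordered")
        if not 0 <= self.delay_to_stage < len(bins):
            raise ConfigurationError("delay_to_stage outside stage bins")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stage]))


@dataclasses.dataclass
class GroundTruth:
    """Planted truth: which probes carry effects and of what size."""

    dml_probe_ids: dict = dataclasses.field(default_factory=dict)
    bivalent_probe_ids: set = dataclasses.field(default_factory=set)
    dynamic_probe_ids: set = dataclasses.field(default_factory=set)
    delayed_probe_ids: set = dataclasses.field(default_factory=set)
    planted_deltas: dict = dataclasses.field(default_factory=dict)
    fetal_stage_means: pd.DataFrame | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "dml_probe_ids": {g: sorted(s) for g, s in self.dml_probe_ids.items()},
            "bivalent_probe_ids": sorted(self.bivalent_probe_ids),
            "dynamic_probe_ids": sorted(self.dynamic_probe_ids),
            "delayed_probe_ids": sorted(self.delayed_probe_ids),
            "planted_deltas": self.planted_deltas,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")


@dataclasses.dataclass
class FetalSeries:
    betas: pd.DataFrame  # probes x fetal samples
    samples: pd.DataFrame  # sample_id, stage, dpc


@dataclasses.dataclass
class SimulatedDataset:
    manifest: pd.DataFrame
    mark_a: pd.DataFrame
    mark_b: pd.DataFrame
    fetal: FetalSeries
    betas: pd.DataFrame
    samples: pd.DataFrame
    truth: GroundTruth


# ---------------------------------------------------------------------------
# manifest


def generate_manifest(config: SimulationConfig) -> pd.DataFrame:
    if not config.chrom_layout:
        raise ConfigurationError("chrom_layout must be non-empty")
    rng = config.rng(1)
    slots = {chrom: max((length - 1) // _GRID - 1, 0) for chrom, length in config.chrom_layout}
    capacity = sum(slots.values())
    if config.n_probes > capacity:
        raise CapacityError(
            f"{config.n_probes} probes requested but only {capacity} positions available"
        )
    # apportion probes to chromosomes by capacity
    chroms = [c for c, _ in config.chrom_layout]
    weights = np.array([slots[c] for c in chroms], dtype=float)
    counts = np.zeros(len(chroms), dtype=int)
    if config.n_probes > 0 and capacity > 0:
        raw = weights / weights.sum() * config.n_probes
        counts = np.floor(raw).astype(int)
        # hand out the remainder to the largest fractional parts
        for i in np.argsort(-(raw - counts))[: config.n_probes - counts.sum()]:
            counts[i] += 1
        # respect per-chromosome capacity
        for i, c in enumerate(chroms):
            if counts[i] > slots[c]:
                counts[i] = slots[c]
        deficit = config.n_probes - counts.sum()
        i = 0
        while deficit > 0:
            if counts[i] < slots[chroms[i]]:
                counts[i] += 1
                deficit -= 1
            else:
                i += 1

    rows = []
    probe_no = 0
    for chrom, k in zip(chroms, counts):
        idx = np.sort(rng.choice(slots[chrom], size=k, replace=False))
        positions = (idx + 1) * _GRID
        for pos in positions:
            probe_no += 1
            rows.append((f"cg{probe_no:08d}", chrom, int(pos)))
    n = len(rows)
    mf = pd.DataFrame(rows, columns=["probe_id", "chromosome", "position"])
    mf["strand"] = rng.choice(["+", "-"], size=n)
    mf["region_category"] = rng.choice(
        list(REGION_CATEGORIES), size=n, p=list(config.region_proportions)
    )
    gene_idx = (mf["position"] // 100_000).astype(int)
    symbols = "GENE_" + mf["chromosome"].astype(str) + "_" + gene_idx.astype(str)
    mf["gene_symbol"] = np.where(mf["region_category"] == "intergenic", "", symbols)
    mf["cpg_island"] = rng.random(n) < config.cpg_island_fraction
    mf["snp_flag"] = rng.random(n) < config.snp_fraction
    mf["transcript_count"] = 1 + rng.poisson(2.0, size=n)
    return mf


# ---------------------------------------------------------------------------
# peak tracks


def _clean_probe_ids(manifest: pd.DataFrame) -> pd.Index:
    return pd.Index(manifest.loc[~manifest["snp_flag"].astype(bool), "probe_id"])


def generate_peak_tracks(
    manifest: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Two mark tracks whose intersection covers exactly the planted
    bivalent probe set.

    Bivalent probes get a core interval in both tracks (with asymmetric
    margins); the remaining probes are covered by at most one track so the
    intersection never touches them.
    """
    if manifest.empty:
        raise ConfigurationError("manifest is empty")
    rng = config.rng(2)
    n = len(manifest)
    k = int(round(config.bivalent_probe_fraction * n))
    pool = _clean_probe_ids(manifest)
    if k > len(pool):  # fall back to flagged probes if the target demands it
        pool = pd.Index(manifest["probe_id"])
    selected = set(rng.choice(pool.to_numpy(), size=min(k, len(pool)), replace=False))

    a_rows, b_rows = [], []
    for chrom, sub in manifest.groupby("chromosome", sort=True):
        sub = sub.sort_values("position")
        pos = sub["position"].to_numpy()
        sel = sub["probe_id"].isin(selected).to_numpy()
        u = rng.random(len(sub))
        a_only = ~sel & (u < 0.30)
        b_only = ~sel & (u >= 0.30) & (u < 0.60)
        a_rows += [(chrom, p - 4, p + 4) for p in pos[sel]]
        b_rows += [(chrom, p - 7, p + 7) for p in pos[sel]]
        a_rows += [(chrom, p - 5, p + 5) for p in pos[a_only]]
        b_rows += [(chrom, p - 5, p + 5) for p in pos[b_only]]
        # a few probe-free decoy peaks per chromosome for realism
        gaps = np.flatnonzero(np.diff(pos) > 600)
        for j, gi in enumerate(gaps[::50]):
            mid = int((pos[gi] + pos[gi + 1]) // 2)
            target = a_rows if j % 2 == 0 else b_rows
            target.append((chrom, mid - 20, mid + 20))

    mark_a = pd.DataFrame(a_rows, columns=["chrom", "start", "end"])
    mark_b = pd.DataFrame(b_rows, columns=["chrom", "start", "end"])
    mark_a = mark_a.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    mark_b = mark_b.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    truth = GroundTruth(bivalent_probe_ids=selected)
    return mark_a, mark_b, truth


# ---------------------------------------------------------------------------
# fetal series


def generate_fetal_series(
    manifest: pd.DataFrame, config: SimulationConfig
) -> tuple[FetalSeries, GroundTruth]:
    """Staged fetal reference methylomes.

    Dynamic probes follow a strictly monotone trajectory across the four
    stage-bin means with a total change of at least 0.2 beta units and a
    random direction; static probes are flat up to noise.
    """
    if config.n_fetal_per_stage < 1:
        raise ConfigurationError("n_fetal_per_stage must be >= 1")
    rng = config.rng(3)
    probe_ids = manifest["probe_id"].to_numpy()
    n = len(probe_ids)
    n_stages = len(config.stage_bins)

    pool = _clean_probe_ids(manifest)
    k = int(round(config.dynamic_fraction * n))
    k = min(k, len(pool))
    dynamic = set(rng.choice(pool.to_numpy(), size=k, replace=False))
    is_dyn = np.isin(probe_ids, list(dynamic))

    means = np.empty((n, n_stages))
    base = rng.uniform(0.05, 0.95, size=n)
    means[:] = base[:, None]

    n_dyn = int(is_dyn.sum())
    if n_dyn:
        total = rng.uniform(0.2, 0.5, size=n_dyn)
        sign = rng.choice([-1.0, 1.0], size=n_dyn)
        lo = np.where(sign > 0, 0.02, 0.02 + total)
        hi = np.where(sign > 0, 0.98 - total, 0.98)
        start = rng.uniform(lo, hi)
        incr = rng.uniform(0.2, 1.0, size=(n_dyn, n_stages - 1))
        cum = np.concatenate(
            [np.zeros((n_dyn, 1)), np.cumsum(incr, axis=1)], axis=1
        )
        cum /= cum[:, -1:]
        means[is_dyn] = start[:, None] + (sign * total)[:, None] * cum

    stage_labels = [label for label, _, _ in config.stage_bins]
    stage_means = pd.DataFrame(means, index=probe_ids, columns=stage_labels)

    sample_rows, columns = [], []
    for si, (label, lo, hi) in enumerate(config.stage_bins):
        dpcs = rng.integers(lo, hi + 1, size=config.n_fetal_per_stage)
        for j, dpc in enumerate(sorted(dpcs.tolist())):
            sid = f"fetal_{label}_{j + 1:02d}"
            sample_rows.append((sid, label, int(dpc)))
            noise = rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd else 0.0
            columns.append(np.clip(means[:, si] + noise, 0.0, 1.0))
    samples = pd.DataFrame(sample_rows, columns=["sample_id", "stage", "dpc"])
    betas = pd.DataFrame(
        np.column_stack(columns), index=probe_ids, columns=samples["sample_id"]
    )
    truth = GroundTruth(dynamic_probe_ids=dynamic, fetal_stage_means=stage_means)
    return FetalSeries(betas=betas, samples=samples), truth


# ---------------------------------------------------------------------------
# cohort


def _merge_truth(*parts: GroundTruth) -> GroundTruth:
    out = GroundTruth()
    for p in parts:
        out.dml_probe_ids.update(p.dml_probe_ids)
        out.bivalent_probe_ids |= p.bivalent_probe_ids
        out.dynamic_probe_ids |= p.dynamic_probe_ids
        out.delayed_probe_ids |= p.delayed_probe_ids
        for g, d in p.planted_deltas.items():
            out.planted_deltas.setdefault(g, {}).update(d)
        if p.fetal_stage_means is not None:
            out.fetal_stage_means = p.fetal_stage_means
    return out


def generate_cohort(
    manifest: pd.DataFrame,
    fetal_truth: GroundTruth,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Case/control cohort over the manifest.

    Controls sit at the final fetal stage mean.  Per age group, planted DML
    shift the case mean by a signed ``dml_delta``; delayed probes (a subset
    of bivalent-and-dynamic CpGs, shared by all age groups) take the value
    of an earlier fetal stage instead.  DML are apportioned so that the
    planted rate inside the bivalent-and-dynamic set exceeds the outside
    rate by ``edr_dml_fold``.
    """
    if fetal_truth.fetal_stage_means is None:
        raise ConfigurationError("fetal ground truth (stage means) required")
    rng = config.rng(4)
    stage_means = fetal_truth.fetal_stage_means
    probe_ids = manifest["probe_id"].to_numpy()
    control_mean = stage_means.iloc[:, -1].reindex(probe_ids).to_numpy()
    delay_mean = stage_means.iloc[:, config.delay_to_stage].reindex(probe_ids).to_numpy()

    clean = set(_clean_probe_ids(manifest))
    dynamic = fetal_truth.dynamic_probe_ids & clean
    edr = (fetal_truth.bivalent_probe_ids & dynamic)
    dyn_only = dynamic - edr
    other = clean - dynamic
    n_bg = len(clean)
    n_edr, n_dyn = len(edr), len(dynamic)

    n_delayed = int(round(config.delayed_fraction * n_edr))
    delayed = set(
        rng.choice(sorted(edr), size=n_delayed, replace=False)
    ) if n_delayed else set()

    # stratum quotas so that the realised DML rate is edr_dml_fold-times the
    # background rate inside EDRs and dynamic_dml_fold-times among dynamic
    # CpGs overall
    total_dml = min(int(round(config.dml_fraction * n_bg)), n_bg)
    k_edr = int(round(config.edr_dml_fold * total_dml * n_edr / n_bg)) if n_bg else 0
    k_edr = min(max(k_edr, n_delayed), n_edr, total_dml)
    k_dyn_total = (
        int(round(config.dynamic_dml_fold * total_dml * n_dyn / n_bg)) if n_bg else 0
    )
    k_dyn_only = int(np.clip(k_dyn_total - k_edr, 0, min(len(dyn_only), total_dml - k_edr)))
    k_other = int(np.clip(total_dml - k_edr - k_dyn_only, 0, len(other)))

    reg_edr = (
        set(rng.choice(sorted(edr - delayed), size=k_edr - n_delayed, replace=False))
        if k_edr > n_delayed
        else set()
    )
    reg_dyn = (
        set(rng.choice(sorted(dyn_only), size=k_dyn_only, replace=False))
        if k_dyn_only
        else set()
    )
    reg_out = (
        set(rng.choice(sorted(other), size=k_other, replace=False)) if k_other else set()
    )

    # distinct regular DML per age group (the delayed set is in every group)
    regular = np.array(sorted(reg_edr | reg_dyn | reg_out))
    rng.shuffle(regular)
    parts = np.array_split(regular, len(config.age_groups))
    dml_ids = {
        g: set(part.tolist()) | delayed for g, part in zip(config.age_groups, parts)
    }

    pos = {pid: i for i, pid in enumerate(probe_ids)}
    planted_deltas: dict[str, dict[str, float]] = {}
    group_means: dict[str, np.ndarray] = {}
    for g in config.age_groups:
        asd = control_mean.copy()
        deltas = {}
        for pid in sorted(dml_ids[g]):
            i = pos[pid]
            if pid in delayed:
                asd[i] = delay_mean[i]
            else:
                sign = 1.0 if rng.random() < 0.5 else -1.0
                target = control_mean[i] + sign * config.dml_delta
                if not 0.01 <= target <= 0.99:
                    target = control_mean[i] - sign * config.dml_delta
                target = float(np.clip(target, 0.01, 0.99))
                asd[i] = target
            deltas[pid] = float(asd[i] - control_mean[i])
        planted_deltas[g] = deltas
        group_means[g] = asd

    sample_rows, columns = [], []
    for g in config.age_groups:
        lo, hi = _AGE_RANGES.get(g, (1.0, 80.0))
        for diag, mean in (("control", control_mean), ("autism", group_means[g])):
            prefix = "ctl" if diag == "control" else "asd"
            for j in range(config.n_per_group):
                sid = f"{prefix}_{g}_{j + 1:02d}"
                age = float(np.round(rng.uniform(lo, hi), 1))
                pmi = float(np.round(rng.uniform(8.0, 30.0), 1))
                sample_rows.append((sid, diag, g, age, pmi))
                noise = (
                    rng.normal(0.0, config.noise_sd, size=len(probe_ids))
                    if config.noise_sd
                    else 0.0
                )
                columns.append(np.clip(mean + noise, 0.0, 1.0))

    samples = pd.DataFrame(
        sample_rows,
        columns=["sample_id", "diagnosis", "age_group", "age_years", "pmi_hours"],
    )
    betas = pd.DataFrame(
        np.column_stack(columns), index=probe_ids, columns=samples["sample_id"]
    )
    truth = _merge_truth(
        fetal_truth,
        GroundTruth(
            dml_probe_ids=dml_ids,
            delayed_probe_ids=delayed,
            planted_deltas=planted_deltas,
        ),
    )
    return betas, samples, truth


# ---------------------------------------------------------------------------
# one-call convenience


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    manifest = generate_manifest(config)
    mark_a, mark_b, peak_truth = generate_peak_tracks(manifest, config)
    fetal, fetal_truth = generate_fetal_series(manifest, config)
    combined = _merge_truth(peak_truth, fetal_truth)
    betas, samples, truth = generate_cohort(manifest, combined, config)
    return SimulatedDataset(
        manifest=manifest,
        mark_a=mark_a,
        mark_b=mark_b,
        fetal=fetal,
        betas=betas,
        samples=samples,
        truth=truth,
    )


def write_dataset(data: SimulatedDataset, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_manifest(data.manifest, outdir / "manifest.tsv")
    write_bed(data.mark_a, outdir / "mark_a.bed")
    write_bed(data.mark_b, outdir / "mark_b.bed")
    write_beta_matrix(data.betas, outdir / "betas.tsv")
    write_sample_sheet(data.samples, outdir / "samples.tsv")
    write_beta_matrix(data.fetal.betas, outdir / "fetal_betas.tsv")
    data.fetal.samples.to_csv(outdir / "fetal_samples.tsv", sep="\t", index=False)
    if data.truth.fetal_stage_means is not None:
        data.truth.fetal_stage_means.to_csv(
            outdir / "fetal_stage_means.tsv", sep="\t", index_label="probe_id"
        )
    data.truth.to_json(outdir / "ground_truth.json")
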