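"""Developmental-trajectory correlation and epigenetic-delay scoring.

Staged fetal reference methylomes are reduced to per-CpG stage-bin means;
postnatal case/control groups are reduced to per-CpG means (with SEM);
each (group, stage) pair gets a Pearson correlation over a CpG subset
(typically the EDR CpGs).  The delay score for an age group at an early
prenatal stage is r_case - r_control: a positive score means the case
profile resembles the earlier fetal methylome more than the matched
control profile does.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats


@dataclasses.dataclass
class FetalStageDataset:
    stage_bins: tuple  # (label, dpc_min, dpc_max) x 4
    means: pd.DataFrame  # probes x stage labels
    n_per_bin: dict  # label -> sample count

    @property
    def stage_labels(self) -> list:
        return list(self.means.columns)


@dataclasses.dataclass
class GroupProfile:
    diagnosis: str
    age_group: str
    mean: pd.Series  # per-CpG mean beta
    sem: pd.Series  # per-CpG sd/sqrt(n)
    n: int

    @property
    def key(self) -> tuple:
        return (self.diagnosis, self.age_group)


@dataclasses.dataclass
class DelayReport:
    r: pd.DataFrame  # (diagnosis, age_group) x stage
    p: pd.DataFrame
    delay_scores: pd.DataFrame | None = None  # age_group x early stages
    case_higher: pd.DataFrame | None = None  # age_group x all stages (bool)


def stage_bin_means(
    fetal_betas: pd.DataFrame,
    fetal_samples: pd.DataFrame,
    stage_bins,
) -> FetalStageDataset:
    """Arithmetic per-CpG mean beta per stage bin.

    Every sample's days-post-conception must fall in exactly one bin and
    no bin may be empty.
    """
    bins = tuple(stage_bins)
    dpc = fetal_samples.set_index("sample_id")["dpc"]
    missing = [s for s in fetal_betas.columns if s not in dpc.index]
    if missing:
        raise ValueError(f"samples without dpc: {missing[:5]}")
    assignment: dict[str, str] = {}
    unbinned = []
    for sid in fetal_betas.columns:
        d = dpc[sid]
        labels = [label for label, lo, hi in bins if lo <= d <= hi]
        if len(labels) != 1:
            unbinned.append(sid)
        else:
            assignment[sid] = labels[0]
    if unbinned:
        raise ValueError(f"samples outside all stage bins: {unbinned}")
    means = {}
    n_per_bin = {}
    for label, _, _ in bins:
        cols = [s for s, b in assignment.items() if b == label]
        if not cols:
            raise ValueError(f"stage bin {label!r} has no samples")
        means[label] = fetal_betas[cols].mean(axis=1)
        n_per_bin[label] = len(cols)
    return FetalStageDataset(
        stage_bins=bins, means=pd.DataFrame(means), n_per_bin=n_per_bin
    )


def group_profiles(
    betas: pd.DataFrame,
    samples: pd.DataFrame,
    probe_subset=None,
    pool_age_groups: bool = False,
) -> list[GroupProfile]:
    """Per-CpG mean and SEM for every (diagnosis, age group) cell.

    With ``pool_age_groups`` the age groups collapse and one profile per
    diagnosis is returned (age_group label "all").
    """
    if probe_subset is not None:
        subset = pd.Index(sorted(set(probe_subset)))
        absent = subset.difference(betas.index)
        if len(absent):
            raise ValueError(f"probes absent from beta matrix: {list(absent[:5])}")
        betas = betas.loc[subset]
    keys = ["diagnosis"] if pool_age_groups else ["diagnosis", "age_group"]
    profiles = []
    for key, sub in samples.groupby(keys, sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        diagnosis = key[0]
        age_group = "all" if pool_age_groups else key[1]
        cols = [c for c in sub["sample_id"] if c in betas.columns]
        if len(cols) < 2:
            raise ValueError(f"group {key} has fewer than 2 samples in the matrix")
        vals = betas[cols]
        profiles.append(
            GroupProfile(
                diagnosis=diagnosis,
                age_group=age_group,
                mean=vals.mean(axis=1),
                sem=vals.std(axis=1, ddof=1) / np.sqrt(len(cols)),
                n=len(cols),
            )
        )
    return profiles


def correlate_profiles(
    profiles: list[GroupProfile],
    fetal: FetalStageDataset,
    probe_subset=None,
) -> DelayReport:
    """Pearson r (and two-sided p) of every group-mean profile against
    every fetal stage-mean vector over the shared CpG subset."""
    if probe_subset is None:
        shared = fetal.means.index
        for prof in profiles:
            shared = shared.intersection(prof.mean.index)
    else:
        shared = pd.Index(sorted(set(probe_subset)))
    if len(shared) < 3:
        raise ValueError("need >= 3 shared CpGs for correlation")
    index = pd.MultiIndex.from_tuples(
        [p.key for p in profiles], names=["diagnosis", "age_group"]
    )
    r = pd.DataFrame(index=index, columns=fetal.stage_labels, dtype=float)
    pmat = pd.DataFrame(index=index, columns=fetal.stage_labels, dtype=float)
    for prof in profiles:
        x = prof.mean.reindex(shared).to_numpy(dtype=float)
        if np.std(x) == 0:
            raise ValueError(f"constant profile for group {prof.key}")
        for stage in fetal.stage_labels:
            y = fetal.means.loc[shared, stage].to_numpy(dtype=float)
            if np.std(y) == 0:
                raise ValueError(f"constant fetal stage vector {stage!r}")
            res = stats.pearsonr(x, y)
            r.loc[prof.key, stage] = float(res.statistic)
            pmat.loc[prof.key, stage] = float(res.pvalue)
    return DelayReport(r=r, p=pmat)


def delay_score(
    report: DelayReport,
    case_diagnosis: str = "autism",
    control_diagnosis: str = "control",
    n_early_stages: int = 2,
) -> DelayReport:
    """Fill in delay scores: r_case - r_control at the earliest prenatal
    stages, per age group, plus case-higher flags for every stage."""
    r = report.r
    diagnoses = r.index.get_level_values("diagnosis")
    for diag in (case_diagnosis, control_diagnosis):
        if diag not in set(diagnoses):
            raise ValueError(f"diagnosis arm {diag!r} missing from report")
    case_r = r.xs(case_diagnosis, level="diagnosis")
    ctrl_r = r.xs(control_diagnosis, level="diagnosis")
    groups = case_r.index.intersection(ctrl_r.index)
    if len(groups) == 0:
        raise ValueError("no age group has both diagnosis arms")
    early = list(r.columns[:n_early_stages])
    scores = (case_r.loc[groups, early] - ctrl_r.loc[groups, early]).astype(float)
    flags = (case_r.loc[groups] > ctrl_r.loc[groups]).astype(bool)
    return DelayReport(r=report.r, p=report.p, delay_scores=scores, case_higher=flags)


def locus_report(
    probe_id: str,
    profiles: list[GroupProfile],
    fetal: FetalStageDataset,
) -> pd.DataFrame:
    """Single-CpG trajectory table: one row per fetal stage, then one per
    postnatal group (mean, SEM) — the data behind a locus trajectory plot."""
    if probe_id not in fetal.means.index:
        raise KeyError(f"probe {probe_id!r} absent from fetal dataset")
    rows = []
    for stage in fetal.stage_labels:
        rows.append(("fetal", stage, float(fetal.means.loc[probe_id, stage]), np.nan, fetal.n_per_bin[stage]))
    for prof in profiles:
        if probe_id not in prof.mean.index:
            raise KeyError(f"probe {probe_id!r} absent from group {prof.key}")
        rows.append(
            (
                "postnatal",
                f"{prof.diagnosis}:{prof.age_group}",
                float(prof.mean[probe_id]),
                float(prof.sem[probe_id]),
                prof.n,
            )
        )
    return pd.DataFrame(rows, columns=["kind", "label", "mean", "sem", "n"])
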