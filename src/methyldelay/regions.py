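"""Genomic-interval engine and region enrichment statistics.

Peak sets are (chrom, start, end) frames in 0-based half-open coordinates.
``intersect_tracks`` emits one fragment per overlapping pair of intervals
(bedtools-style intersect semantics); ``merge_peaks`` collapses a track to
disjoint runs.  A CpG probe at 1-based position p occupies the interval
[p-1, p+1) — the dinucleotide — and overlaps a peak when they share at
least one base.

Enrichment of a probe subset in a genomic annotation is summarised by the
fold ratio of subset vs background hit fractions with a 1-df chi-square
goodness-of-fit test; category distributions use the k-1-df chi-square
against background proportions.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .io import REGION_CATEGORIES, probe_interval, sort_peaks


@dataclasses.dataclass
class CategoryCounts:
    observed: dict  # category -> count
    total: int
    expected_prop: dict  # category -> background proportion

    def __post_init__(self) -> None:
        if sum(self.observed.values()) != self.total:
            raise ValueError("category counts do not sum to total")
        if abs(sum(self.expected_prop.values()) - 1.0) > 1e-9:
            raise ValueError("expected proportions do not sum to 1")


@dataclasses.dataclass
class EnrichmentResult:
    n_in_subset: int
    n_subset: int
    n_in_background: int
    n_background: int
    fold: float
    chi2: float
    p: float

    @property
    def subset_fraction(self) -> float:
        return self.n_in_subset / self.n_subset

    @property
    def background_fraction(self) -> float:
        return self.n_in_background / self.n_background


# ---------------------------------------------------------------------------
# interval engine


def intersect_tracks(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Pairwise intersection: one output fragment per overlapping (a, b)
    interval pair, clipped to their shared coordinates."""
    rows = []
    a = sort_peaks(a)
    b = sort_peaks(b)
    for chrom in sorted(set(a["chrom"]) & set(b["chrom"])):
        asub = a[a["chrom"] == chrom]
        bsub = b[b["chrom"] == chrom]
        astart = asub["start"].to_numpy()
        aend = asub["end"].to_numpy()
        bstart = bsub["start"].to_numpy()
        bend = bsub["end"].to_numpy()
        # raw tracks may contain mutually overlapping intervals, so a plain
        # two-pointer sweep can miss pairs; bound the backward scan with the
        # running maximum of b ends instead
        bend_cummax = np.maximum.accumulate(bend)
        for s, e in zip(astart, aend):
            hi = int(np.searchsorted(bstart, e, side="left"))
            k = hi - 1
            while k >= 0 and bend_cummax[k] > s:
                if bend[k] > s:  # overlap guaranteed: bstart[k] < e already
                    rows.append((chrom, int(max(s, bstart[k])), int(min(e, bend[k]))))
                k -= 1
    out = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return sort_peaks(out)


def merge_peaks(peaks: pd.DataFrame) -> pd.DataFrame:
    """Collapse a track into disjoint maximal runs (book-ended intervals
    merge)."""
    rows = []
    for chrom, sub in sort_peaks(peaks).groupby("chrom", sort=True):
        cur_start = cur_end = None
        for start, end in zip(sub["start"], sub["end"]):
            if cur_start is None:
                cur_start, cur_end = start, end
            elif start <= cur_end:
                cur_end = max(cur_end, end)
            else:
                rows.append((chrom, int(cur_start), int(cur_end)))
                cur_start, cur_end = start, end
        if cur_start is not None:
            rows.append((chrom, int(cur_start), int(cur_end)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def probes_in_peaks(
    probes: pd.DataFrame, peaks: pd.DataFrame
) -> tuple[set, int, float]:
    """Which probes of a manifest subset overlap a peak set by >= 1 bp.

    Returns (probe id set, count, percent of subset rounded half-even to
    one decimal).  The subset must be non-empty (the percent is undefined
    otherwise).
    """
    if len(probes) == 0:
        raise ValueError("empty probe subset: percent undefined")
    merged = merge_peaks(peaks)
    hits: set = set()
    for chrom, sub in probes.groupby("chromosome", sort=False):
        msub = merged[merged["chrom"] == chrom]
        if msub.empty:
            continue
        starts = msub["start"].to_numpy()
        ends = msub["end"].to_numpy()
        pos = sub["position"].to_numpy(dtype=int)
        pstart = pos - 1
        pend = pos + 1
        # candidate: last merged interval starting at or before probe end - 1
        idx = np.searchsorted(starts, pend - 1, side="right") - 1
        ok = (idx >= 0) & (np.where(idx >= 0, ends[np.maximum(idx, 0)], 0) > pstart)
        hits.update(sub.loc[ok, "probe_id"])
    count = len(hits)
    return hits, count, overlap_percent(count, len(probes))


def overlap_percent(count: int, total: int) -> float:
    """Percent of a subset, rounded half-even to one decimal."""
    if total <= 0:
        raise ValueError("percent undefined for empty subset")
    return round(100.0 * count / total, 1)


# ---------------------------------------------------------------------------
# enrichment statistics


def categorize(dml_probe_ids, manifest: pd.DataFrame) -> CategoryCounts:
    """Genomic-region category counts for a probe set, with expected
    proportions from the full (post-filter) manifest background."""
    mf = manifest.set_index("probe_id")
    ids = pd.Index(sorted(set(dml_probe_ids)))
    absent = ids.difference(mf.index)
    if len(absent):
        raise ValueError(f"probes absent from manifest: {list(absent[:5])}")
    unknown = set(mf["region_category"]) - set(REGION_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown region categories: {sorted(unknown)}")
    obs_counts = mf.loc[ids, "region_category"].value_counts()
    bg_counts = mf["region_category"].value_counts()
    observed = {c: int(obs_counts.get(c, 0)) for c in REGION_CATEGORIES}
    expected = {c: float(bg_counts.get(c, 0)) / len(mf) for c in REGION_CATEGORIES}
    return CategoryCounts(observed=observed, total=len(ids), expected_prop=expected)


def chisq_gof(observed, expected_prop) -> tuple[float, int, float]:
    """Chi-square goodness of fit: chi2 = sum (O-E)^2/E, df = k-1,
    upper-tail p.  Accepts dicts (aligned on keys) or sequences."""
    if isinstance(observed, dict):
        keys = list(observed)
        obs = np.array([observed[k] for k in keys], dtype=float)
        exp_p = np.array([expected_prop[k] for k in keys], dtype=float)
    else:
        obs = np.asarray(observed, dtype=float)
        exp_p = np.asarray(expected_prop, dtype=float)
    if obs.size < 2:
        raise ValueError("need >= 2 categories")
    total = obs.sum()
    expected = exp_p * total
    if np.any(expected <= 0):
        raise ValueError("expected count of 0 in some category")
    chi2 = float(np.sum((obs - expected) ** 2 / expected))
    df = obs.size - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def fold_enrichment(
    n_in_subset: int, n_subset: int, n_in_background: int, n_background: int
) -> EnrichmentResult:
    """Fold = (subset hit fraction) / (background hit fraction), with a
    1-df goodness-of-fit chi-square of the observed subset hit count
    against its background-rate expectation."""
    if n_subset <= 0 or n_background <= 0:
        raise ValueError("subset and background must be non-empty")
    bg_frac = n_in_background / n_background
    if bg_frac == 0:
        raise ValueError("background fraction is 0: fold undefined")
    fold = (n_in_subset / n_subset) / bg_frac
    expected = np.array([n_subset * bg_frac, n_subset * (1.0 - bg_frac)])
    observed = np.array([n_in_subset, n_subset - n_in_subset], dtype=float)
    if expected[1] == 0:  # background fraction 1: everything is a hit
        chi2, p = 0.0, 1.0
    else:
        chi2 = float(np.sum((observed - expected) ** 2 / expected))
        p = float(stats.chi2.sf(chi2, 1))
    return EnrichmentResult(
        n_in_subset=int(n_in_subset),
        n_subset=int(n_subset),
        n_in_background=int(n_in_background),
        n_background=int(n_background),
        fold=float(fold),
        chi2=chi2,
        p=p,
    )


def category_enrichment(counts: CategoryCounts) -> pd.DataFrame:
    """Per-category fold (observed vs expected share) plus the overall
    goodness-of-fit test, as one tidy row per category.  An empty probe
    set yields zero counts and no test (NaN chi2/p)."""
    if counts.total == 0:
        chi2, df, p = np.nan, len(counts.observed) - 1, np.nan
    else:
        chi2, df, p = chisq_gof(counts.observed, counts.expected_prop)
    rows = []
    for cat in counts.observed:
        obs = counts.observed[cat]
        exp_frac = counts.expected_prop[cat]
        fold = (obs / counts.total) / exp_frac if counts.total and exp_frac else np.nan
        rows.append((cat, obs, counts.total, exp_frac, fold, chi2, df, p))
    return pd.DataFrame(
        rows,
        columns=[
            "category",
            "observed",
            "total",
            "expected_prop",
            "fold",
            "chi2_overall",
            "df",
            "p_overall",
        ],
    )


def bivalent_overlap(
    dml_probe_ids,
    manifest: pd.DataFrame,
    mark_a: pd.DataFrame,
    mark_b: pd.DataFrame,
) -> tuple[EnrichmentResult, set]:
    """DML overlap with the two-mark intersection vs the array background."""
    bivalent = intersect_tracks(mark_a, mark_b)
    mf = manifest
    subset = mf[mf["probe_id"].isin(set(dml_probe_ids))]
    bg_hits, n_bg_in, _ = probes_in_peaks(mf, bivalent)
    sub_hits, n_sub_in, _ = probes_in_peaks(subset, bivalent)
    result = fold_enrichment(n_sub_in, len(subset), n_bg_in, len(mf))
    return result, sub_hits
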