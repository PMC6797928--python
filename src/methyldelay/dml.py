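"""Differential-methylation calling with a moderated statistic and a
label-permutation null.

The per-probe pooled variance is shrunk toward a common prior variance
estimated across probes (empirical Bayes): s2_post = (d0*s0^2 + d*s2)/(d0+d)
with (d0, s0^2) fit by method of moments on the log sample variances, and
the moderated t is delta_beta / sqrt(s2_post*(1/n1+1/n2)).  Significance
comes from permuting the case/control labels and recomputing the moderated
statistic — including the shrinkage step — for every relabelling: exact
enumeration of all balanced assignments when their number is small, else
Monte-Carlo with the add-one estimator.

A probe is a DML when p_perm < alpha and |delta_beta| >= delta (default
0.05 / 0.10).  No multiple-testing correction is applied: the raw-p plus
effect-size gate is deliberate and should be kept in mind when
interpreting calls.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
import warnings

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_array, check_is_fitted

_TOL = 1e-12


@dataclasses.dataclass
class ComparisonSpec:
    """A planned case-vs-control comparison within one age group."""

    case_sample_ids: tuple
    control_sample_ids: tuple
    label: str = ""

    def __post_init__(self) -> None:
        case = tuple(self.case_sample_ids)
        control = tuple(self.control_sample_ids)
        if set(case) & set(control):
            raise ValueError("case and control sample sets overlap")
        if len(case) < 2 or len(control) < 2:
            raise ValueError("each arm needs at least 2 samples")
        object.__setattr__(self, "case_sample_ids", case)
        object.__setattr__(self, "control_sample_ids", control)


@dataclasses.dataclass
class DMLSet:
    label: str
    table: pd.DataFrame  # passing probes with stats
    alpha: float
    delta: float

    @property
    def probe_ids(self) -> set:
        return set(self.table.index)


def comparisons_from_sample_sheet(samples: pd.DataFrame) -> list[ComparisonSpec]:
    """One comparison per age group: autism vs control."""
    specs = []
    for group, sub in samples.groupby("age_group", sort=False):
        specs.append(
            ComparisonSpec(
                case_sample_ids=tuple(sub.loc[sub["diagnosis"] == "autism", "sample_id"]),
                control_sample_ids=tuple(
                    sub.loc[sub["diagnosis"] == "control", "sample_id"]
                ),
                label=str(group),
            )
        )
    return specs


# ---------------------------------------------------------------------------
# empirical-Bayes variance shrinkage


def trigamma_inverse(y: np.ndarray) -> np.ndarray:
    """Solve trigamma(x) = y elementwise (Newton iteration)."""
    y = np.atleast_1d(np.asarray(y, dtype=float))
    x = np.empty_like(y)
    small = y < 1e-6  # trigamma(x) ~ 1/x for large x
    large = y > 1e7  # trigamma(x) ~ 1/x^2 + ... for small x
    x[small] = 1.0 / y[small]
    x[large] = 1.0 / np.sqrt(y[large])
    mid = ~(small | large)
    z = 0.5 + 1.0 / y[mid]
    for _ in range(50):
        tri = special.polygamma(1, z)
        step = tri * (1.0 - tri / y[mid]) / special.polygamma(2, z)
        z = z + step
        if z.size == 0 or np.max(np.abs(step) / np.maximum(z, 1e-12)) < 1e-10:
            break
    x[mid] = z
    return x


def squeeze_variances(s2: np.ndarray, d: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shrink per-probe variances toward a common prior.

    ``s2`` is (n_probes,) or (n_probes, B) — moments are computed per
    column so each permutation re-estimates its own prior.  Returns
    (s2_post, d0, s0_sq) with d0/s0_sq per column.  Columns where the
    prior cannot be estimated (fewer than two positive variances) fall
    back to the unmoderated variances with d0 = 0.
    """
    s2 = np.asarray(s2, dtype=float)
    squeeze_1d = s2.ndim == 1
    if squeeze_1d:
        s2 = s2[:, None]
    n_probes, n_cols = s2.shape

    with np.errstate(divide="ignore"):
        z = np.where(s2 > 0, np.log(np.maximum(s2, 1e-300)), np.nan)
    e = z - special.polygamma(0, d / 2.0) + math.log(d / 2.0)
    n_ok = np.sum(~np.isnan(e), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        e_mean = np.nanmean(e, axis=0)
        e_var = np.nanvar(e, axis=0, ddof=1)

    d0 = np.zeros(n_cols)
    s0_sq = np.ones(n_cols)
    estimable = n_ok >= 2
    excess = e_var - special.polygamma(1, d / 2.0)
    finite_prior = estimable & (excess > 0)
    if np.any(finite_prior):
        half_d0 = trigamma_inverse(excess[finite_prior])
        d0[finite_prior] = 2.0 * half_d0
        s0_sq[finite_prior] = np.exp(
            e_mean[finite_prior]
            + special.polygamma(0, half_d0)
            - np.log(half_d0)
        )
    # no excess dispersion beyond sampling noise: the variances are
    # homogeneous and the common value is their geometric mean, so
    # shrinking identical variances is a no-op
    infinite_prior = estimable & ~(excess > 0)
    d0[infinite_prior] = np.inf
    s0_sq[infinite_prior] = np.exp(
        e_mean[infinite_prior] + special.polygamma(0, d / 2.0) - math.log(d / 2.0)
    )

    s2_post = np.empty_like(s2)
    for j in range(n_cols):
        if not estimable[j]:
            if n_cols == 1:
                warnings.warn(
                    "prior variance not estimable; falling back to unmoderated t",
                    RuntimeWarning,
                    stacklevel=2,
                )
            s2_post[:, j] = s2[:, j]
        elif np.isinf(d0[j]):
            s2_post[:, j] = s0_sq[j]
        else:
            s2_post[:, j] = (d0[j] * s0_sq[j] + d * s2[:, j]) / (d0[j] + d)

    if squeeze_1d:
        return s2_post[:, 0], d0[0], s0_sq[0]
    return s2_post, d0, s0_sq


def _stats_for_masks(X: np.ndarray, masks: np.ndarray, n1: int, n2: int):
    """Group means, pooled variance and moderated t for each case mask.

    ``X`` is probes x samples, ``masks`` is B x samples (True = case);
    returns arrays of shape (n_probes, B).
    """
    M = masks.T.astype(float)  # samples x B
    tot = X.sum(axis=1, keepdims=True)
    tot2 = (X * X).sum(axis=1, keepdims=True)
    s1 = X @ M
    q1 = (X * X) @ M
    m1 = s1 / n1
    m2 = (tot - s1) / n2
    v1 = np.maximum(q1 - n1 * m1 * m1, 0.0) / (n1 - 1)
    v2 = np.maximum((tot2 - q1) - n2 * m2 * m2, 0.0) / (n2 - 1)
    d = n1 + n2 - 2
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / d
    delta = m1 - m2
    s2_post, d0, s0_sq = squeeze_variances(s2, d)
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / se
    t[(se == 0) & (delta == 0)] = 0.0
    t[(se == 0) & (delta > 0)] = np.inf
    t[(se == 0) & (delta < 0)] = -np.inf
    return m1, m2, delta, s2, s2_post, t, d0, s0_sq


def _exhaustive_masks(n: int, n1: int) -> np.ndarray:
    combos = itertools.combinations(range(n), n1)
    masks = np.zeros((math.comb(n, n1), n), dtype=bool)
    for i, combo in enumerate(combos):
        masks[i, list(combo)] = True
    return masks


# ---------------------------------------------------------------------------
# estimator


class DMLDetector(SelectorMixin, BaseEstimator):
    """Permutation empirical-Bayes differential-methylation caller.

    A scikit-learn selector: ``fit(X, y)`` with ``X`` of shape
    (n_samples, n_probes) (beta values) and binary ``y`` (``case_label``
    marks cases) computes per-probe group means, delta beta, moderated t
    and a permutation p-value; ``transform`` keeps the called DML columns.

    Parameters
    ----------
    alpha, delta : the significance and effect-size gates (p_perm < alpha
        and |delta_beta| >= delta).
    n_perm : Monte-Carlo permutation count when exhaustive enumeration is
        not engaged.
    mode : "auto" switches to exhaustive enumeration of all balanced label
        assignments when their number is <= ``exhaustive_limit``;
        "exhaustive" / "montecarlo" force either.
    random_state : seed for Monte-Carlo resampling.

    Attributes
    ----------
    mean_case_, mean_control_, delta_beta_, t_mod_, p_perm_ : per-probe
        arrays; ``d0_``, ``s0_sq_`` the fitted prior; ``support_`` the DML
        mask; ``n_assignments_`` the permutation count actually used.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        delta: float = 0.10,
        n_perm: int = 999,
        mode: str = "auto",
        exhaustive_limit: int = 2000,
        case_label=1,
        random_state=None,
    ):
        self.alpha = alpha
        self.delta = delta
        self.n_perm = n_perm
        self.mode = mode
        self.exhaustive_limit = exhaustive_limit
        self.case_label = case_label
        self.random_state = random_state

    def fit(self, X, y):
        X = check_array(X, dtype=float)
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y have inconsistent lengths")
        case = y == self.case_label
        n1, n2 = int(case.sum()), int((~case).sum())
        if n1 < 2 or n2 < 2:
            raise ValueError("need >= 2 samples per arm")
        if self.mode not in ("auto", "exhaustive", "montecarlo"):
            raise ValueError(f"unknown mode {self.mode!r}")

        # probes x samples, cases first so the identity mask is row 0
        order = np.concatenate([np.flatnonzero(case), np.flatnonzero(~case)])
        Xt = X.T[:, order]
        n = n1 + n2
        obs_mask = np.zeros((1, n), dtype=bool)
        obs_mask[0, :n1] = True
        m1, m2, delta, s2, s2_post, t, d0, s0 = _stats_for_masks(Xt, obs_mask, n1, n2)
        self.mean_case_ = m1[:, 0]
        self.mean_control_ = m2[:, 0]
        self.delta_beta_ = delta[:, 0]
        self.t_mod_ = t[:, 0]
        self.s2_pooled_ = s2[:, 0]
        self.s2_post_ = s2_post[:, 0]
        self.d0_ = float(np.atleast_1d(d0)[0])
        self.s0_sq_ = float(np.atleast_1d(s0)[0])

        n_total = math.comb(n, n1)
        exhaustive = self.mode == "exhaustive" or (
            self.mode == "auto" and n_total <= self.exhaustive_limit
        )
        abs_obs = np.abs(self.t_mod_)[:, None]
        if exhaustive:
            masks = _exhaustive_masks(n, n1)
            count = np.zeros(Xt.shape[0], dtype=int)
            for start in range(0, len(masks), 256):
                chunk = masks[start : start + 256]
                t_perm = _stats_for_masks(Xt, chunk, n1, n2)[5]
                count += (np.abs(t_perm) >= abs_obs - _TOL).sum(axis=1)
            self.p_perm_ = count / float(n_total)
            self.n_assignments_ = n_total
            self.mode_used_ = "exhaustive"
        else:
            if self.n_perm <= 0:
                raise ValueError("n_perm must be positive in Monte-Carlo mode")
            if self.n_perm < 100:
                warnings.warn(
                    f"n_perm={self.n_perm} is small for Monte-Carlo p-values",
                    RuntimeWarning,
                    stacklevel=2,
                )
            rng = np.random.default_rng(self.random_state)
            count = np.zeros(Xt.shape[0], dtype=int)
            remaining = self.n_perm
            while remaining > 0:
                b = min(remaining, 256)
                keys = rng.random((b, n))
                chunk = np.argsort(keys, axis=1) < n1
                t_perm = _stats_for_masks(Xt, chunk, n1, n2)[5]
                count += (np.abs(t_perm) >= abs_obs - _TOL).sum(axis=1)
                remaining -= b
            self.p_perm_ = (1.0 + count) / (self.n_perm + 1.0)
            self.n_assignments_ = self.n_perm
            self.mode_used_ = "montecarlo"

        self.support_ = (self.p_perm_ < self.alpha) & (
            np.abs(self.delta_beta_) >= self.delta - _TOL
        )
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


# ---------------------------------------------------------------------------
# functional wrappers over the estimator (BetaMatrix = probes x samples frame)


def _fit_detector(
    betas: pd.DataFrame, spec: ComparisonSpec, **kwargs
) -> DMLDetector:
    sample_ids = list(spec.case_sample_ids) + list(spec.control_sample_ids)
    missing = [s for s in sample_ids if s not in betas.columns]
    if missing:
        raise ValueError(f"samples absent from beta matrix: {missing}")
    X = betas[sample_ids].to_numpy(dtype=float).T
    if np.isnan(X).any():
        raise ValueError("beta matrix contains missing values; filter first")
    y = np.array([1] * len(spec.case_sample_ids) + [0] * len(spec.control_sample_ids))
    det = DMLDetector(case_label=1, **kwargs)
    det.fit(X, y)
    return det


def probe_stats(betas: pd.DataFrame, spec: ComparisonSpec) -> pd.DataFrame:
    """Per-probe group means, delta beta and moderated t (no p-values)."""
    sample_ids = list(spec.case_sample_ids) + list(spec.control_sample_ids)
    missing = [s for s in sample_ids if s not in betas.columns]
    if missing:
        raise ValueError(f"samples absent from beta matrix: {missing}")
    X = betas[sample_ids].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("beta matrix contains missing values; filter first")
    n1, n2 = len(spec.case_sample_ids), len(spec.control_sample_ids)
    obs = np.zeros((1, n1 + n2), dtype=bool)
    obs[0, :n1] = True
    m1, m2, delta, _, _, t, d0, s0 = _stats_for_masks(X, obs, n1, n2)
    table = pd.DataFrame(
        {
            "mean_case": m1[:, 0],
            "mean_control": m2[:, 0],
            "delta_beta": delta[:, 0],
            "t_mod": t[:, 0],
        },
        index=betas.index,
    )
    table.attrs["d0"] = float(np.atleast_1d(d0)[0])
    table.attrs["s0_sq"] = float(np.atleast_1d(s0)[0])
    return table


def permutation_pvalues(
    betas: pd.DataFrame,
    spec: ComparisonSpec,
    n_perm: int = 999,
    seed: int | None = None,
    mode: str = "auto",
    exhaustive_limit: int = 2000,
) -> pd.Series:
    det = _fit_detector(
        betas,
        spec,
        n_perm=n_perm,
        mode=mode,
        exhaustive_limit=exhaustive_limit,
        random_state=seed,
    )
    out = pd.Series(det.p_perm_, index=betas.index, name="p_perm")
    out.attrs["mode"] = det.mode_used_
    out.attrs["n_assignments"] = det.n_assignments_
    return out


def call_dml(
    stats_table: pd.DataFrame,
    pvals: pd.Series,
    alpha: float = 0.05,
    delta: float = 0.10,
    label: str = "",
) -> DMLSet:
    """Gate probes on p_perm < alpha and |delta_beta| >= delta."""
    if not stats_table.index.equals(pvals.index):
        pvals = pvals.reindex(stats_table.index)
        if pvals.isna().any():
            raise ValueError("stats and p-values are not aligned on probe ids")
    table = stats_table.copy()
    table["p_perm"] = pvals
    passing = table[
        (table["p_perm"] < alpha) & (table["delta_beta"].abs() >= delta - _TOL)
    ]
    passing = passing.sort_index()
    return DMLSet(label=label, table=passing, alpha=alpha, delta=delta)


def run_comparison(
    betas: pd.DataFrame,
    spec: ComparisonSpec,
    alpha: float = 0.05,
    delta: float = 0.10,
    n_perm: int = 999,
    seed: int | None = None,
    mode: str = "auto",
) -> DMLSet:
    """Fit one comparison end-to-end and return the called DML set."""
    det = _fit_detector(
        betas, spec, n_perm=n_perm, mode=mode, random_state=seed,
        alpha=alpha, delta=delta,
    )
    table = pd.DataFrame(
        {
            "mean_case": det.mean_case_,
            "mean_control": det.mean_control_,
            "delta_beta": det.delta_beta_,
            "t_mod": det.t_mod_,
            "p_perm": det.p_perm_,
        },
        index=betas.index,
    )
    return call_dml(table, table["p_perm"], alpha=alpha, delta=delta, label=spec.label)


# ---------------------------------------------------------------------------
# clustering and distribution tests


def cluster_samples(betas: pd.DataFrame):
    """Complete-linkage clustering of samples, Manhattan distance on beta
    vectors; samples are ordered lexicographically first so ties break
    deterministically.

    Returns (linkage matrix, leaf-order sample ids).
    """
    cols = sorted(betas.columns)
    X = betas[cols].to_numpy(dtype=float).T
    if len(cols) < 2:
        return np.empty((0, 4)), list(cols)
    Z = hierarchy.linkage(pdist(X, metric="cityblock"), method="complete")
    order = [cols[i] for i in hierarchy.leaves_list(Z)]
    return Z, order


def cut_clusters(Z: np.ndarray, leaf_ids: list, k: int) -> dict:
    """Cut a dendrogram into k flat clusters; returns sample -> cluster."""
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    # fcluster indexes leaves in original (lexicographic) order
    return {sid: int(c) for sid, c in zip(sorted(leaf_ids), labels)}


def ks_two_sample(a, b) -> tuple[float, float]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("KS test needs non-empty samples")
    res = stats.ks_2samp(a, b, method="auto")
    return float(res.statistic), float(res.pvalue)


def ttest_two_sample(a, b) -> tuple[float, float]:
    """Welch two-sided t-test; degenerate equal-constant input gives (0, 1)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("t-test needs >= 2 observations per sample")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        return math.copysign(math.inf, np.mean(a) - np.mean(b)), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)
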