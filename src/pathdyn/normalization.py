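"""Internal-standard normalization of expression arrays.

Three steps, each anchored to an internal standard built from the data
itself:

1. ``identify_background_cohort`` finds the low-intensity mode of genes whose
   signals are indistinguishable from technological noise (iterative
   upper-tail trimming until the mode passes a Kolmogorov-Smirnov normality
   test).
2. ``identify_equally_expressed_cohort`` finds above-background genes whose
   intensity rank is stable across arrays; this cohort anchors the robust
   per-array regression in ``normalize_arrays``.
3. ``compute_residuals`` subtracts the averaged control profile at the
   matching timepoint, yielding the log-scale residuals that every
   downstream statistic operates on.

All logs are base 2; zero intensities are floored at half the smallest
positive value before logging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .datasets import ExpressionDataset

log = logging.getLogger(__name__)


class NormalizationError(ValueError):
    pass


def log2_intensities(values: pd.DataFrame) -> pd.DataFrame:
    """Log2 with zero-flooring at half the smallest positive intensity."""
    arr = values.to_numpy(dtype=float)
    pos = arr[arr > 0]
    if pos.size == 0:
        raise NormalizationError("matrix contains no positive intensities")
    floor = 0.5 * pos.min()
    return pd.DataFrame(
        np.log2(np.maximum(arr, floor)), index=values.index, columns=values.columns
    )


@dataclass
class BackgroundModel:
    """The technological-noise internal standard."""

    member_genes: list
    mu_bg: float
    sigma_bg: float
    ks_p: float

    @property
    def threshold_3sd(self) -> float:
        return self.mu_bg + 3.0 * self.sigma_bg


@dataclass
class NormalizedMatrix:
    """Log2 expressions after per-array affine correction."""

    values: pd.DataFrame  # genes x arrays, log2 scale
    meta: pd.DataFrame
    scaling: pd.DataFrame  # per array: slope, intercept

    @property
    def gene_ids(self):
        return list(self.values.index)


@dataclass
class ResidualMatrix:
    """Deviations from the averaged control profile (log2 scale)."""

    values: pd.DataFrame
    meta: pd.DataFrame
    ks_p_global: float

    @property
    def gene_ids(self):
        return list(self.values.index)

    def columns_for(self, group=None, duplicate=None, timepoint=None) -> list:
        m = self.meta.loc[list(self.values.columns)]
        mask = pd.Series(True, index=m.index)
        if group is not None:
            mask &= m["group"] == group
        if duplicate is not None:
            mask &= m["duplicate_idx"] == duplicate
        if timepoint is not None:
            mask &= m["timepoint_h"] == timepoint
        return list(m.index[mask])


def _ks_normal(x: np.ndarray) -> float:
    """Two-sided KS p-value of standardized values against N(0, 1)."""
    sd = x.std(ddof=1)
    if sd <= 0:
        return 0.0
    z = (x - x.mean()) / sd
    return float(stats.kstest(z, "norm").pvalue)


def identify_background_cohort(
    ds: ExpressionDataset,
    *,
    alpha: float = 0.05,
    min_members: int = 20,
    trim_frac: float = 0.01,
) -> BackgroundModel:
    """Largest low-intensity gene set passing a KS normality test.

    Per-gene median log2 intensities are sorted; genes are trimmed from the
    upper tail until the remaining set is compatible with a single normal
    mode (KS p > ``alpha``).
    """
    if ds.n_genes < 50:
        raise NormalizationError("need at least 50 genes to fit a background mode")
    med = log2_intensities(ds.values).median(axis=1).sort_values()
    k = len(med)
    vals = med.to_numpy()
    while k >= min_members:
        p = _ks_normal(vals[:k])
        if p > alpha:
            sub = vals[:k]
            return BackgroundModel(
                member_genes=list(med.index[:k]),
                mu_bg=float(sub.mean()),
                sigma_bg=float(sub.std(ddof=1)),
                ks_p=p,
            )
        k -= max(1, int(trim_frac * k))
    raise NormalizationError("no background mode: no low-intensity subset is normal")


def identify_equally_expressed_cohort(
    ds: ExpressionDataset,
    bg: BackgroundModel,
    *,
    min_members: int = 30,
    target_size: int = 600,
    max_rank_cv: float = 0.10,
    max_swing: float = 1.0,
) -> list:
    """Above-background genes equally expressed across arrays.

    Two stability criteria must both hold: (a) the SD of the gene's
    within-array rank (computed among above-background genes, divided by the
    cohort size) stays under an adaptive cutoff -- the cutoff shrinks so the
    cohort reaches ``target_size`` members when that many rank-stable genes
    exist, and never exceeds ``max_rank_cv``; (b) the gene's temporal swing
    (range of its per-timepoint mean log2 expression) stays below
    ``max_swing``, excluding strongly dynamic genes whatever their rank.
    """
    logv = log2_intensities(ds.values)
    med = logv.median(axis=1)
    above = med.index[med > bg.threshold_3sd]
    if len(above) < min_members:
        raise NormalizationError("fewer than 30 genes above background")
    sub = logv.loc[above]
    tps = ds.meta.loc[list(sub.columns), "timepoint_h"]
    tp_means = sub.T.groupby(tps.values).mean().T
    swing = tp_means.max(axis=1) - tp_means.min(axis=1)
    ranks = sub.rank(axis=0)
    rank_var = ranks.std(axis=1) / len(above)
    eligible = rank_var.index[swing <= max_swing]
    if len(eligible) < min_members:
        raise NormalizationError(
            f"only {len(eligible)} rank-stable genes; no equally expressed cohort"
        )
    sorted_var = rank_var.loc[eligible].sort_values()
    adaptive = sorted_var.iloc[min(target_size, len(sorted_var)) - 1]
    cutoff = min(float(adaptive), max_rank_cv)
    cohort = list(sorted_var.index[sorted_var <= cutoff])
    if len(cohort) < min_members:
        raise NormalizationError(
            f"only {len(cohort)} rank-stable genes; no equally expressed cohort"
        )
    return cohort


def normalize_arrays(
    ds: ExpressionDataset, cohort, *, max_iter: int = 50
) -> NormalizedMatrix:
    """Robust per-array affine correction anchored on the stable cohort.

    Each array's log2 cohort intensities are regressed (iteratively
    re-weighted least squares, bisquare weights) on the cohort's median log2
    profile across arrays; the inverse affine map is applied to all genes of
    that array.

    An affine normalization is only identified up to one global affine
    gauge, and the regression against a noisy median profile carries a small
    attenuation common to every array.  Each pass therefore fixes the gauge
    by anchoring the ensemble (geometric mean of the slopes 1, mean
    intercept 0), and passes repeat against the re-computed median profile
    until the corrections are the identity.  The converged procedure is a
    true fixed point: re-normalizing its output changes nothing (within
    1e-8).
    """
    cohort = list(cohort)
    if not cohort:
        raise NormalizationError("empty normalization cohort")
    logv = log2_intensities(ds.values)
    values = logv.copy()
    total = {aid: (1.0, 0.0) for aid in ds.array_ids}
    for _ in range(30):
        ref = values.loc[cohort].median(axis=1).to_numpy()
        if ref.std(ddof=0) <= 1e-12:
            raise NormalizationError("degenerate regression: cohort has zero variance")
        X = sm.add_constant(ref)
        fits = {}
        for aid in ds.array_ids:
            y = values.loc[cohort, aid].to_numpy()
            fit = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight()).fit(maxiter=max_iter)
            intercept, slope = fit.params
            if slope <= 0:
                raise NormalizationError(f"non-positive slope for array {aid!r}")
            fits[aid] = (slope, intercept)
        gauge_scale = float(
            np.exp(np.mean(np.log([a for a, _ in fits.values()])))
        )
        gauge_shift = float(np.mean([b * gauge_scale / a for a, b in fits.values()]))
        out, delta = {}, 0.0
        for aid in ds.array_ids:
            a, b = fits[aid]
            s, i = a / gauge_scale, b - gauge_shift * a / gauge_scale
            out[aid] = (values[aid] - i) / s
            a0, b0 = total[aid]
            total[aid] = (a0 * s, b0 + a0 * i)
            delta = max(delta, abs(s - 1.0), abs(i))
        values = pd.DataFrame(out, index=logv.index)[ds.array_ids]
        if delta < 1e-10:
            break
    scaling = pd.DataFrame(
        [
            {"array_id": aid, "slope": a, "intercept": b}
            for aid, (a, b) in total.items()
        ]
    ).set_index("array_id")
    return NormalizedMatrix(values=values, meta=ds.meta.copy(), scaling=scaling)


def compute_residuals(
    nm: NormalizedMatrix, *, ks_subsample: int = 2000
) -> ResidualMatrix:
    """Subtract the averaged control profile at the matching timepoint.

    The pooled standardized residuals are checked for normality with a KS
    test; to keep the test informative rather than rejecting on trivial
    deviations at huge sample sizes, at most ``ks_subsample`` residuals
    (deterministic subsample) enter the test.
    """
    meta = nm.meta.loc[list(nm.values.columns)]
    timepoints = sorted(meta["timepoint_h"].unique())
    ctrl_mean = {}
    for t in timepoints:
        cols = meta.index[(meta["group"] == "control") & (meta["timepoint_h"] == t)]
        if len(cols) == 0:
            raise NormalizationError(f"no control array at timepoint {t}")
        ctrl_mean[t] = nm.values[list(cols)].mean(axis=1)
    resid = {}
    for aid in nm.values.columns:
        t = meta.loc[aid, "timepoint_h"]
        resid[aid] = nm.values[aid] - ctrl_mean[t]
    values = pd.DataFrame(resid, index=nm.values.index)[list(nm.values.columns)]
    # Subtracting a mean of m control arrays leaves variance (1 - 1/m) sigma^2
    # on control residuals and (1 + 1/m) sigma^2 on the other group's; the KS
    # check standardizes each column by that design factor so the pooled test
    # sees a homoscedastic sample.
    n_ctrl = {
        t: len(meta.index[(meta["group"] == "control") & (meta["timepoint_h"] == t)])
        for t in timepoints
    }
    scaled = {}
    for aid in values.columns:
        t, grp = meta.loc[aid, "timepoint_h"], meta.loc[aid, "group"]
        m = n_ctrl[t]
        factor = np.sqrt(1.0 - 1.0 / m) if grp == "control" else np.sqrt(1.0 + 1.0 / m)
        scaled[aid] = values[aid] / factor if factor > 0 else values[aid] * np.nan
    flat = pd.DataFrame(scaled).to_numpy().ravel()
    flat = flat[np.isfinite(flat)]
    if flat.size > ks_subsample:
        idx = np.random.default_rng(0).choice(flat.size, ks_subsample, replace=False)
        flat = flat[idx]
    ks_p = _ks_normal(flat)
    if ks_p <= 0.01:
        log.info("pooled residuals deviate from normality (KS p=%.3g)", ks_p)
    return ResidualMatrix(values=values, meta=nm.meta.copy(), ks_p_global=ks_p)
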