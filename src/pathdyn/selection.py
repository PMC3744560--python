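"""Gene-selection statistics built on the low-variability reference group.

The reference group (the "biologically stable genes") is the third internal
standard: above-background genes whose residual variability is
indistinguishable from technological variation by an F-test.  Its pooled
residual distribution -- thousands of values -- is the null against which
individual genes are scored:

* hypervariable (HVE) genes: residual variance exceeds the pooled reference
  variance with P < 1/N, N the number of above-background genes;
* differentially expressed genes: a Student t-test between the two groups'
  replicates (p < 0.05) AND an associative t-test of the gene's replicated
  residuals against the reference pool at a Bonferroni-corrected threshold;
* jackknife reproducibility: the DE selection repeated over all n x m
  leave-one-out-per-group subsets;
* profile reproducibility: Pearson correlation >= cc_min between duplicated
  time profiles in at least one phenotype group.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .normalization import BackgroundModel, NormalizedMatrix, ResidualMatrix

log = logging.getLogger(__name__)


class SelectionError(ValueError):
    pass


@dataclass
class ReferenceGroup:
    """Above-background genes with technological-level variability."""

    member_genes: list
    pooled_residuals: np.ndarray
    pooled_variance: float
    df: int


def _gene_variances(values: pd.DataFrame) -> tuple[pd.Series, int]:
    """Per-gene variance of residuals about the gene mean; df = n - 1."""
    n = values.shape[1]
    if n < 2:
        raise SelectionError("need at least 2 arrays to estimate variances")
    return values.var(axis=1, ddof=1), n - 1


def build_reference_group(
    rm: ResidualMatrix,
    above_bg,
    *,
    alpha: float = 0.05,
    min_members: int = 20,
    max_iter: int = 50,
    trim_frac: float = 0.20,
) -> ReferenceGroup:
    """Iteratively exclude genes more variable than the pool (F-test p < alpha).

    The pooled (technological) variance is estimated from the lowest
    ``1 - trim_frac`` fraction of per-gene variances with an exact
    chi-square truncation correction (the conditional mean of a chi-square
    below the trim quantile is divided out).  The fixed upper trim makes the
    estimate robust to hypervariable contamination while staying unbiased --
    and the downstream F-tests calibrated -- under the null, which a naively
    trimmed pool would not be.
    """
    values = rm.values if hasattr(rm, "values") and not isinstance(rm, pd.DataFrame) else rm
    above_bg = [g for g in above_bg if g in values.index]
    if len(above_bg) < 30:
        raise SelectionError("need at least 30 above-background genes")
    sub = values.loc[above_bg]
    s2, df_g = _gene_variances(sub)
    k = int(np.ceil((1.0 - trim_frac) * len(above_bg)))
    c = stats.chi2.ppf(1.0 - trim_frac, df_g)
    g_factor = stats.chi2.cdf(c, df_g + 2) / (1.0 - trim_frac)  # E[X | X<=c] / df
    pooled = float(np.sort(s2.to_numpy())[:k].mean()) / g_factor
    if pooled <= 0:
        raise SelectionError("zero pooled variance in reference group")
    members = list(above_bg)
    for _ in range(max_iter):
        df_pool = df_g * len(members)
        p = stats.f.sf(s2 / pooled, df_g, df_pool)
        new_members = list(s2.index[p >= alpha])
        if len(new_members) < min_members:
            raise SelectionError("reference group collapsed below 20 genes")
        if set(new_members) == set(members):
            members = new_members
            break
        members = new_members
    centered = sub.loc[members].sub(sub.loc[members].mean(axis=1), axis=0)
    return ReferenceGroup(
        member_genes=members,
        pooled_residuals=centered.to_numpy().ravel(),
        pooled_variance=pooled,
        df=df_g * len(members),
    )


def select_above_background(
    nm: NormalizedMatrix,
    bg: BackgroundModel,
    *,
    sd_mult: float = 3.0,
    alpha: float = 0.05,
    per_group: bool = False,
):
    """Genes expressed above background in at least one (group, timepoint).

    A gene qualifies when its mean log2 expression over the group's lines
    exceeds mu_bg + 3 sigma_bg at some timepoint AND an associative test of
    its standardized replicates against the background distribution (N(0,1)
    after standardization) rejects at the Bonferroni-corrected threshold
    alpha / n_genes.

    Returns ``(gene ids, N)``; with ``per_group=True`` also a dict
    group -> above-background gene set (used for the A3/A4 DE classes).
    """
    meta = nm.meta.loc[list(nm.values.columns)]
    n_genes = nm.values.shape[0]
    corrected = alpha / n_genes
    pool_n = 5000  # effective size of the standardized background pool
    threshold = bg.mu_bg + sd_mult * bg.sigma_bg
    by_group: dict[str, set] = {}
    for grp in sorted(meta["group"].unique()):
        sel = pd.Series(False, index=nm.values.index)
        for t in sorted(meta["timepoint_h"].unique()):
            cols = list(meta.index[(meta["group"] == grp) & (meta["timepoint_h"] == t)])
            if not cols:
                continue
            vals = nm.values[cols]
            z = (vals - bg.mu_bg) / bg.sigma_bg
            mean_ok = vals.mean(axis=1) > threshold
            m1 = z.mean(axis=1)
            s1 = z.std(axis=1, ddof=1).fillna(0.0)
            n1 = len(cols)
            if n1 < 2:
                s1 = pd.Series(0.0, index=z.index)
            _, p = stats.ttest_ind_from_stats(
                m1, s1, n1, 0.0, 1.0, pool_n, equal_var=True
            )
            sel |= mean_ok & (pd.Series(p, index=z.index) < corrected)
        by_group[grp] = set(sel.index[sel])
    union = sorted(set().union(*by_group.values())) if by_group else []
    if per_group:
        return union, len(union), by_group
    return union, len(union)


def select_hve(
    rm,
    ref: ReferenceGroup,
    N: int,
    *,
    columns=None,
    genes=None,
) -> pd.DataFrame:
    """F-test of each gene's variability among samples against the reference.

    ``rm`` is a residual/normalized matrix object (anything with ``values``
    and gene-indexed rows) or a plain DataFrame; the variance is computed
    across the selected columns about the gene's own mean, so passing one
    experiment's arrays measures the gene's temporal variability within that
    experiment.  Selection threshold is P < 1/N -- on average one false
    positive per dataset under the null.  Returns a DataFrame (index gene)
    with columns ``F``, ``p``, ``selected``.
    """
    if N < 1:
        raise SelectionError("N must be >= 1")
    if ref.pooled_variance <= 0:
        raise SelectionError("zero pooled variance in reference group")
    values = rm.values if hasattr(rm, "values") and not isinstance(rm, pd.DataFrame) else rm
    if columns is not None:
        values = values[list(columns)]
    if genes is not None:
        values = values.loc[[g for g in genes if g in values.index]]
    s2, df_g = _gene_variances(values)
    F = s2 / ref.pooled_variance
    p = pd.Series(stats.f.sf(F, df_g, ref.df), index=F.index)
    return pd.DataFrame({"F": F, "p": p, "selected": p < 1.0 / N})


def _student_test(case: np.ndarray, control: np.ndarray, fallback_var: float):
    """Two-sample t; with a single replicate or zero variance in both groups,
    fall back to the reference pooled variance."""
    n, m = case.shape[-1], control.shape[-1]
    diff = case.mean(axis=-1) - control.mean(axis=-1)
    if n >= 2 and m >= 2:
        t, p = stats.ttest_ind(case, control, axis=-1)
        bad = ~np.isfinite(p)
        if np.any(bad):
            se = np.sqrt(fallback_var * (1.0 / n + 1.0 / m))
            z = diff / se
            p = np.where(bad, 2.0 * stats.norm.sf(np.abs(z)), p)
        return p
    se = np.sqrt(fallback_var * (1.0 / n + 1.0 / m))
    z = diff / se
    return 2.0 * stats.norm.sf(np.abs(z))


def associative_de_test(
    case: pd.DataFrame,
    control: pd.DataFrame,
    ref: ReferenceGroup,
    N: int,
    *,
    alpha: float = 0.05,
    case_above=None,
    control_above=None,
    case_expression: pd.Series | None = None,
    control_expression: pd.Series | None = None,
    min_expression: float = 20.0,
    fold_cutoff: float = 2.0,
) -> pd.DataFrame:
    """Student + associative DE test on replicated residuals.

    ``case`` / ``control`` are genes x replicates residual matrices.  A gene
    is DE when the Student t-test between groups gives p < ``alpha`` AND the
    associative t-test of the case replicates against the reference pool
    gives p < ``alpha`` / N.  Classes: A1 overexpressed in case, A2 in
    control; A3/A4 expressed in only one group (other group below background
    or under the minimum-expression floor on the linear scale).
    """
    if N < 1:
        raise SelectionError("N must be >= 1")
    genes = case.index
    if not genes.equals(control.index):
        raise SelectionError("case and control matrices must share gene ids")
    pool = ref.pooled_residuals
    pm, ps, pn = float(pool.mean()), float(pool.std(ddof=1)), len(pool)
    ca, co = case.to_numpy(dtype=float), control.to_numpy(dtype=float)
    student_p = _student_test(ca, co, ref.pooled_variance)
    m1 = ca.mean(axis=1)
    n1 = ca.shape[1]
    s1 = ca.std(axis=1, ddof=1) if n1 >= 2 else np.zeros_like(m1)
    s1 = np.nan_to_num(s1)
    _, assoc_p = stats.ttest_ind_from_stats(m1, s1, n1, pm, ps, pn, equal_var=True)
    corrected = alpha / N
    mean_case, mean_control = m1, co.mean(axis=1)
    ratio = np.exp2(mean_case - mean_control)
    de = (student_p < alpha) & (assoc_p < corrected)
    cls = np.where(de & (mean_case > mean_control), "A1", "")
    cls = np.where(de & (mean_case < mean_control), "A2", cls)
    if case_above is not None and control_above is not None:
        in_case = genes.isin(set(case_above))
        in_ctrl = genes.isin(set(control_above))
        if case_expression is not None:
            in_case &= case_expression.reindex(genes).to_numpy() > min_expression
        if control_expression is not None:
            in_ctrl &= control_expression.reindex(genes).to_numpy() > min_expression
        cls = np.where(de & in_case & ~in_ctrl, "A3", cls)
        cls = np.where(de & in_ctrl & ~in_case, "A4", cls)
    return pd.DataFrame(
        {
            "mean_case": mean_case,
            "mean_control": mean_control,
            "sd_case": s1,
            "sd_control": np.nan_to_num(co.std(axis=1, ddof=1)) if co.shape[1] >= 2 else 0.0,
            "student_p": student_p,
            "associative_p": assoc_p,
            "ratio": ratio,
            "de": de,
            "class": cls,
            "passes_fold": np.abs(np.log2(ratio)) >= np.log2(fold_cutoff),
        },
        index=genes,
    )


def jackknife_reproducibility(
    case: pd.DataFrame, control: pd.DataFrame, test
) -> pd.Series:
    """Percentage of n x m leave-one-out-per-group subsets selecting each gene.

    ``test(case_subset, control_subset)`` must return a boolean per-gene
    Series.  With n and m replicates, n x m comparisons are run; a gene
    selected every time scores 100%.
    """
    n, m = case.shape[1], control.shape[1]
    if n < 2 or m < 2:
        raise SelectionError("jackknife needs >= 2 replicates per group")
    counts = pd.Series(0, index=case.index, dtype=int)
    for i, j in itertools.product(range(n), range(m)):
        sub_case = case.drop(columns=case.columns[i])
        sub_ctrl = control.drop(columns=control.columns[j])
        selected = test(sub_case, sub_ctrl)
        counts += selected.reindex(case.index).fillna(False).astype(int)
    return 100.0 * counts / (n * m)


def make_de_selector(ref: ReferenceGroup, N: int, **kwargs):
    """DE-procedure adapter for the jackknife: returns a boolean Series."""

    def _select(case: pd.DataFrame, control: pd.DataFrame) -> pd.Series:
        rec = associative_de_test(case, control, ref, N, **kwargs)
        return rec["de"]

    return _select


def profile_correlations(p1: pd.DataFrame, p2: pd.DataFrame) -> pd.Series:
    """Per-gene Pearson correlation between duplicate time profiles."""
    if list(p1.columns) != list(p2.columns):
        raise SelectionError("duplicate profiles must cover identical timepoints")
    a = p1.to_numpy(dtype=float)
    b = p2.loc[p1.index].to_numpy(dtype=float)
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    denom = np.sqrt((a**2).sum(axis=1) * (b**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a * b).sum(axis=1) / denom
    return pd.Series(r, index=p1.index)


def profile_reproducibility_filter(profile_pairs, cc_min: float = 0.8) -> list:
    """Keep genes whose duplicate profiles correlate >= cc_min in >= 1 group.

    ``profile_pairs`` is either a single ``(profiles_dup1, profiles_dup2)``
    tuple or a dict group -> tuple.  Genes with a constant profile (undefined
    correlation) are excluded and logged.
    """
    if isinstance(profile_pairs, tuple):
        profile_pairs = {"all": profile_pairs}
    keep: set = set()
    genes = None
    for grp, (p1, p2) in profile_pairs.items():
        r = profile_correlations(p1, p2)
        genes = r.index if genes is None else genes
        constant = r.index[~np.isfinite(r)]
        if len(constant):
            log.info(
                "group %s: %d constant profiles excluded from reproducibility "
                "filter", grp, len(constant)
            )
        keep |= set(r.index[r.fillna(-np.inf) >= cc_min])
    return [g for g in genes if g in keep]
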