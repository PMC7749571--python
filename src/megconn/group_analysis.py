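"""Group-level statistics: normality screening, score and metric group
comparisons, score-metric correlations, and rank-indexed FDR control.

Test routing follows common neurophysiology practice: each variable is
screened for normality per group with a one-sample Kolmogorov-Smirnov test
against a normal with the sample's own mean and SD; variables normal in both
groups are compared with the pooled-variance two-sample t test, all others
with the Mann-Whitney U test.  Correlations are Pearson for normal pairs and
Spearman otherwise.

Multiple-comparison control uses the rank-indexed false-discovery-rate rule:
sort the family's p-values ascending, give the k-th smallest the rank index
i = k (tied p-values all receive the average of their ranks), compare each p
against its rank-wise threshold alpha * i / N, and apply the step-up
decision — the largest p at or below its threshold becomes the realized
cutoff p*, and every p <= p* is declared significant.  With distinct
p-values this is exactly the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import CohortTable, ParameterError, SCORE_NAMES

METRIC_NAMES = ("SA", "DA", "LA", "CA")


@dataclass
class StatResult:
    """One comparison or correlation, with its FDR bookkeeping.

    ``fdr_threshold`` is the realized step-up cutoff p* for the family (so
    ``significant == (p <= fdr_threshold)`` always holds);
    ``rank_threshold`` is this comparison's own rank-wise bound alpha*i/N.
    """

    comparison: str
    test: str
    statistic: float
    p: float
    band: Optional[str] = None
    rank_i: Optional[float] = None
    rank_threshold: Optional[float] = None
    fdr_threshold: Optional[float] = None
    significant: Optional[bool] = None
    note: str = ""


# ---------------------------------------------------------------------------
# elementary tests
# ---------------------------------------------------------------------------

def ks_normality(x: Sequence[float]) -> StatResult:
    """One-sample KS test against N(mean(x), sd(x)).

    Used only as a routing screen (parametric vs rank test).  A constant
    sample is returned as decisively non-normal with a warning.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 5:
        raise ParameterError(f"need n >= 5 for the normality screen, got {x.size}")
    sd = x.std(ddof=1)
    if sd == 0:
        warnings.warn("constant sample in normality screen; treating as non-normal")
        return StatResult(comparison="ks", test="KS", statistic=1.0, p=0.0,
                          note="constant sample")
    stat, p = stats.kstest(x, "norm", args=(x.mean(), sd))
    return StatResult(comparison="ks", test="KS", statistic=float(stat), p=float(p))


def t_from_summary(m1: float, s1: float, n1: int,
                   m2: float, s2: float, n2: int) -> StatResult:
    """Pooled-variance two-sample t from summary statistics (means, SDs, n).

    The same formula :func:`independent_t` applies to raw samples, so the two
    agree to machine precision; this form lets published group summaries act
    as fixtures.
    """
    if n1 < 2 or n2 < 2:
        raise ParameterError("need n >= 2 per group")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
    diff = m1 - m2
    if sp2 == 0:
        t = 0.0 if diff == 0 else float(np.sign(diff) * np.inf)
    else:
        t = diff / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = float(2.0 * stats.t.sf(abs(t), df=df)) if np.isfinite(t) else 0.0
    return StatResult(comparison="t", test="t", statistic=float(t), p=p)


def independent_t(a: Sequence[float], b: Sequence[float]) -> StatResult:
    """Pooled-variance two-sample t on raw samples."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    return t_from_summary(a.mean(), a.std(ddof=1), a.size,
                          b.mean(), b.std(ddof=1), b.size)


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> StatResult:
    """Two-sided Mann-Whitney U: exact enumeration for n_a + n_b <= 12 (and
    no ties), tie-corrected normal approximation otherwise."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ParameterError("need n >= 2 per group")
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size + b.size <= 12 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return StatResult(comparison="U", test="MWU",
                      statistic=float(res.statistic), p=float(res.pvalue),
                      note=method)


def correlate(x: Sequence[float], y: Sequence[float],
              method: str = "pearson") -> StatResult:
    """Pearson or Spearman correlation with two-sided p."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.size < 4:
        raise ParameterError("need two equal-length 1-D samples with n >= 4")
    if x.std() == 0 or y.std() == 0:
        raise ParameterError("zero-variance input: correlation undefined")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ParameterError(f"unknown correlation method {method!r}")
    return StatResult(comparison="corr", test=method,
                      statistic=float(r), p=float(p))


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

def fdr_correct(pvals: Sequence[float], alpha: float = 0.05):
    """Rank-indexed FDR with tie-averaged ranks and the step-up decision.

    Returns ``(significant, ranks, rank_thresholds, cutoff)`` where
    ``cutoff`` is the realized p* (0 when nothing is significant).  An empty
    input yields empty arrays.
    """
    p = np.asarray(pvals, dtype=np.float64)
    if p.size == 0:
        return (np.zeros(0, dtype=bool), np.zeros(0), np.zeros(0), 0.0)
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("p-values must lie in [0, 1]")
    n = p.size
    ranks = stats.rankdata(p, method="average")
    thresholds = alpha * ranks / n
    passing = p <= thresholds
    if passing.any():
        cutoff = float(p[passing].max())
        significant = p <= cutoff
    else:
        cutoff = 0.0
        significant = np.zeros(n, dtype=bool)
    return significant, ranks, thresholds, cutoff


def _apply_fdr(results: list[StatResult], alpha: float) -> None:
    sig, ranks, thr, cutoff = fdr_correct([r.p for r in results], alpha)
    for r, s, i, t in zip(results, sig, ranks, thr):
        r.significant = bool(s)
        r.rank_i = float(i)
        r.rank_threshold = float(t)
        r.fdr_threshold = cutoff


# ---------------------------------------------------------------------------
# cohort-level drivers
# ---------------------------------------------------------------------------

def _route(a: np.ndarray, b: np.ndarray, normality_alpha: float,
           force_nonparametric: Optional[bool]) -> StatResult:
    if force_nonparametric is True:
        return mann_whitney(a, b)
    if force_nonparametric is False:
        return independent_t(a, b)
    if min(a.size, b.size) < 5:
        # too small to screen for normality; default to the rank test
        return mann_whitney(a, b)
    normal = (ks_normality(a).p > normality_alpha
              and ks_normality(b).p > normality_alpha)
    return independent_t(a, b) if normal else mann_whitney(a, b)


def run_group_comparison(
    cohort: CohortTable,
    score_vars: Sequence[str] = SCORE_NAMES,
    metric_vars: Sequence[str] = METRIC_NAMES,
    bands: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
    normality_alpha: float = 0.05,
    force_nonparametric: Optional[bool] = None,
) -> pd.DataFrame:
    """Patient-vs-control comparison of cognitive scores and graph metrics.

    FDR families: the score comparisons form one family; each metric's
    comparisons across bands form one family per metric.  Rows are emitted in
    a fixed (variable, band) order regardless of p-values.
    """
    cohort.require_two_groups()
    subj = cohort.subjects
    pat = subj[subj["group"] == "patient"]
    ctl = subj[subj["group"] == "control"]
    out: list[StatResult] = []

    family: list[StatResult] = []
    for var in score_vars:
        r = _route(pat[var].to_numpy(), ctl[var].to_numpy(),
                   normality_alpha, force_nonparametric)
        r.comparison = var
        family.append(r)
    _apply_fdr(family, alpha)
    out.extend(family)

    if cohort.metrics is not None and metric_vars:
        m = cohort.metrics
        if bands is None:
            bands = list(dict.fromkeys(m["band"]))
        pat_ids = set(cohort.group_ids("patient"))
        ctl_ids = set(cohort.group_ids("control"))
        for var in metric_vars:
            family = []
            for band in bands:
                sel = m[m["band"] == band]
                a = sel[sel["subject_id"].isin(pat_ids)][var].to_numpy()
                b = sel[sel["subject_id"].isin(ctl_ids)][var].to_numpy()
                a = a[np.isfinite(a)]
                b = b[np.isfinite(b)]
                if a.size < 2 or b.size < 2:
                    raise ParameterError(
                        f"metric {var}/{band}: fewer than 2 subjects per group"
                    )
                r = _route(a, b, normality_alpha, force_nonparametric)
                r.comparison = var
                r.band = band
                family.append(r)
            _apply_fdr(family, alpha)
            out.extend(family)

    return results_frame(out)


def score_metric_correlations(
    cohort: CohortTable,
    group: str = "patient",
    score_vars: Sequence[str] = SCORE_NAMES,
    metric_vars: Sequence[str] = METRIC_NAMES,
    bands: Optional[Sequence[str]] = None,
    method: str = "spearman",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Correlate each cognitive score against each (metric, band) within one
    group; FDR per score family."""
    if cohort.metrics is None:
        raise ParameterError("cohort has no metrics table")
    ids = cohort.group_ids(group)
    if len(ids) < 4:
        raise ParameterError(f"need >= 4 subjects in group {group!r}")
    subj = cohort.subjects.set_index("subject_id").loc[ids]
    m = cohort.metrics[cohort.metrics["subject_id"].isin(ids)]
    if bands is None:
        bands = list(dict.fromkeys(m["band"]))
    out: list[StatResult] = []
    for score in score_vars:
        family = []
        for var in metric_vars:
            for band in bands:
                sel = m[m["band"] == band].set_index("subject_id")
                common = [i for i in ids if i in sel.index]
                x = subj.loc[common, score].to_numpy(dtype=float)
                y = sel.loc[common, var].to_numpy(dtype=float)
                ok = np.isfinite(x) & np.isfinite(y)
                if ok.sum() < 4 or x[ok].std() == 0 or y[ok].std() == 0:
                    continue
                r = correlate(x[ok], y[ok], method=method)
                r.comparison = f"{score}~{var}"
                r.band = band
                family.append(r)
        _apply_fdr(family, alpha)
        out.extend(family)
    return results_frame(out)


def results_frame(results: Sequence[StatResult]) -> pd.DataFrame:
    """Flatten StatResults to the stats-report table."""
    return pd.DataFrame(
        [
            {
                "comparison": r.comparison,
                "band": r.band if r.band is not None else "",
                "test": r.test,
                "statistic": r.statistic,
                "p": r.p,
                "rank_i": r.rank_i,
                "rank_threshold": r.rank_threshold,
                "fdr_threshold": r.fdr_threshold,
                "significant": r.significant,
                "note": r.note,
            }
            for r in results
        ]
    )
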