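"""Negative-binomial enrichment statistics between sorting rounds.

The model follows the classic count-based differential-abundance recipe for
sequencing data:

* per-column size factors by the median-of-ratios method — the median, over
  rows with no zero, of the count divided by the row's geometric mean;
* per-row dispersions by method of moments on normalized counts, with a
  mean-dispersion trend ``alpha(mu) = a0 + a1/mu`` fitted across rows and the
  final dispersion taken as the maximum of the per-row estimate and the trend
  (conservative sharing);
* an exact conditional test: given the total count of a row, the probability
  under the null of equal per-condition means of all splits as or less likely
  than the observed one, with each condition's sum modelled as a negative
  binomial whose variance matches the sum of its columns.  With dispersion 0
  this reduces to the exact binomial split test.

Sites that disappear between rounds ("cleared") or appear from nothing get a
sentinel log2 fold change of -/+ ``cap_value`` instead of an estimate;
p-values are Benjamini-Hochberg adjusted across all tested sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.special import logsumexp
from scipy.stats import nbinom, poisson
from statsmodels.stats.multitest import multipletests

from .counting import CountTable, filter_productive, sum_ends


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-site enrichment between an initial and a final library."""

    site: tuple
    base_mean: float
    log2fc: float
    pvalue: float
    padj: float
    cap: Literal["none", "appeared", "cleared"]
    significant: bool


# ---------------------------------------------------------------------------
# Normalization


def estimate_size_factors(
    counts: pd.DataFrame | np.ndarray, pseudocount: float = 0.0
) -> np.ndarray:
    """Median-of-ratios size factors, one per column.

    Only rows with no zero cell enter the median.  When no such row exists,
    pass ``pseudocount > 0`` to stabilize, or fail with a diagnostic.
    """
    k = np.asarray(counts, dtype=float)
    if k.ndim != 2 or k.shape[1] < 1:
        raise ValueError("counts must be a 2-D table")
    if pseudocount:
        k = k + pseudocount
    nonzero = (k > 0).all(axis=1)
    if not nonzero.any():
        raise ValueError(
            "no row with all-nonzero counts; rerun with a pseudocount "
            "(e.g. pseudocount=0.5) to estimate size factors"
        )
    kk = k[nonzero]
    log_geo = np.log(kk).mean(axis=1, keepdims=True)
    return np.exp(np.median(np.log(kk) - log_geo, axis=0))


def estimate_dispersions(
    counts: pd.DataFrame | np.ndarray,
    size_factors: np.ndarray,
    conditions: Optional[Sequence] = None,
    mode: Literal["per-condition", "pooled"] = "per-condition",
) -> np.ndarray:
    """Per-row dispersion (alpha of variance = mu + alpha*mu^2).

    Method of moments on normalized counts with the sampling-noise bias
    removed, then shared through a fitted ``a0 + a1/mu`` trend; the final
    value is max(raw estimate, trend) per row.  ``mode='pooled'`` treats all
    columns as replicates (required when conditions lack replication).
    """
    k = np.asarray(counts, dtype=float)
    s = np.asarray(size_factors, dtype=float)
    if k.shape[1] < 2:
        raise ValueError("need at least two columns to estimate dispersions")
    if mode == "per-condition":
        if conditions is None:
            raise ValueError("per-condition mode needs a conditions vector")
        conds = np.asarray(conditions)
        groups = [np.flatnonzero(conds == c) for c in pd.unique(conds)]
        if all(len(g) < 2 for g in groups):
            raise ValueError(
                "no condition has replicate columns; use mode='pooled'"
            )
        groups = [g for g in groups if len(g) >= 2]
    else:
        groups = [np.arange(k.shape[1])]

    q = k / s  # normalized counts
    mu = q.mean(axis=1)

    # pooled within-condition variance and the matching sampling-noise term
    ss = np.zeros(k.shape[0])
    dof = 0
    inv_s = []
    for g in groups:
        qg = q[:, g]
        ss += ((qg - qg.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        dof += len(g) - 1
        inv_s.extend(1.0 / s[g])
    w = ss / dof
    xi = float(np.mean(inv_s))
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(mu > 0, (w - mu * xi) / mu**2, 0.0)

    a0, a1 = _fit_dispersion_trend(mu, raw)
    with np.errstate(divide="ignore"):
        trend = np.where(mu > 0, a0 + a1 / mu, a0)
    return np.maximum(np.maximum(raw, trend), 0.0)


def _fit_dispersion_trend(mu: np.ndarray, raw: np.ndarray) -> tuple[float, float]:
    """Median (L1) regression fit of raw dispersions to a0 + a1/mu.

    All rows enter the fit, negative raw estimates included: with few
    replicates the raw method-of-moments estimates are strongly right-skewed,
    and a mean-based fit (or one restricted to the positive half) would bias
    the trend — and hence every shared dispersion — upward, making the test
    conservative.  Median regression tracks the center of the estimates;
    coefficients are clamped at zero.
    """
    ok = (mu > 0) & np.isfinite(raw)
    if ok.sum() < 3:
        return 0.0, 0.0
    import warnings

    import statsmodels.api as sm

    A = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coef = sm.QuantReg(raw[ok], A).fit(q=0.5).params
    except Exception:
        coef, _ = nnls(A, raw[ok])
    return float(max(coef[0], 0.0)), float(max(coef[1], 0.0))


# ---------------------------------------------------------------------------
# Per-row exact conditional test


def _sum_logpmf(x: np.ndarray, mean: float, var: float) -> np.ndarray:
    """log pmf of a condition's count sum: NB matching (mean, var), Poisson
    in the var <= mean limit."""
    if mean <= 0:
        # degenerate: all mass at 0
        return np.where(x == 0, 0.0, -np.inf)
    if var <= mean * (1 + 1e-12):
        return poisson.logpmf(x, mean)
    r = mean**2 / (var - mean)
    p = r / (r + mean)
    return nbinom.logpmf(x, r, p)


def nb_test(
    counts_initial: np.ndarray,
    counts_final: np.ndarray,
    sf_initial: np.ndarray,
    sf_final: np.ndarray,
    alpha: float,
) -> float:
    """Exact conditional test of equal means between two conditions.

    Conditions on the row total N = kA + kB and sums, over all splits
    (a, N-a) with joint probability no greater than the observed split's, the
    joint NB probabilities; the result is normalized by the total over all
    splits.  With ``alpha = 0`` and equal size-factor sums this is the
    two-sided exact binomial test with p = 1/2.
    """
    kA = int(np.sum(counts_initial))
    kB = int(np.sum(counts_final))
    N = kA + kB
    if N == 0:
        return 1.0
    if N > 5_000_000:
        raise ValueError("row total too large for exact enumeration")
    sA = np.asarray(sf_initial, dtype=float)
    sB = np.asarray(sf_final, dtype=float)
    SA, SB = sA.sum(), sB.sum()
    qhat = N / (SA + SB)
    mean_a, var_a = qhat * SA, qhat * SA + alpha * qhat**2 * np.sum(sA**2)
    mean_b, var_b = qhat * SB, qhat * SB + alpha * qhat**2 * np.sum(sB**2)
    a = np.arange(N + 1)
    logp = _sum_logpmf(a, mean_a, var_a) + _sum_logpmf(N - a, mean_b, var_b)
    obs = logp[kA]
    if not np.isfinite(obs):
        return 1.0
    keep = logp <= obs + 1e-10
    num = logsumexp(logp[keep])
    den = logsumexp(logp)
    return float(min(1.0, math.exp(num - den)))


def log2_fold_change(
    counts_initial: np.ndarray,
    counts_final: np.ndarray,
    sf_initial: np.ndarray,
    sf_final: np.ndarray,
    pseudocount: float = 0.5,
) -> float:
    """log2 of (mean normalized final + pc) / (mean normalized initial + pc).

    The pseudocount keeps near-zero rows finite for display; it never enters
    the significance test.
    """
    mi = float(np.mean(np.asarray(counts_initial) / np.asarray(sf_initial)))
    mf = float(np.mean(np.asarray(counts_final) / np.asarray(sf_final)))
    if pseudocount == 0 and (mi == 0 or mf == 0):
        return float("nan")
    return math.log2((mf + pseudocount) / (mi + pseudocount))


def bh_adjust(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order kept)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Orchestration


def compute_enrichment(
    table: CountTable,
    initial_samples: Sequence[str],
    final_samples: Sequence[str],
    cap_value: float = 6.0,
    alpha: float = 0.1,
    productive_only: bool = False,
    use_raw_p: bool = False,
    collapse_ends: bool = False,
    pseudocount: float = 0.5,
    sf_pseudocount: Optional[float] = None,
) -> list[EnrichmentResult]:
    """Full enrichment pipeline between two sets of samples.

    The N/C junction-end columns of each sample act as technical replicates
    within their condition (or are pre-summed with ``collapse_ends``).  With
    ``productive_only`` the table is restricted to forward in-frame rows
    *before* normalization, so size factors are recomputed relative to
    productive insertions only.  Rows absent from the final condition are
    capped at ``-cap_value`` ("cleared"); rows absent from the initial one at
    ``+cap_value`` ("appeared").  ``significant`` compares the BH-adjusted
    p-value (or the raw one with ``use_raw_p``) to ``alpha``.
    """
    initial_samples = list(initial_samples)
    final_samples = list(final_samples)
    if set(initial_samples) & set(final_samples):
        raise ValueError("initial and final sample sets overlap")
    if cap_value <= 0:
        raise ValueError("cap_value must be positive")

    work = filter_productive(table) if productive_only else table
    if collapse_ends:
        work = sum_ends(work)
    df = work.df
    samples = df.columns.get_level_values("sample")
    missing = (set(initial_samples) | set(final_samples)) - set(samples)
    if missing:
        raise ValueError(f"samples not in table: {sorted(missing)}")
    cols_i = [c for c in df.columns if c[0] in initial_samples]
    cols_f = [c for c in df.columns if c[0] in final_samples]
    sub = df.loc[:, cols_i + cols_f]
    sub = sub.loc[sub.sum(axis=1) > 0]
    if sub.empty:
        return []

    k = sub.to_numpy(dtype=float)
    sf = estimate_size_factors(k, pseudocount=sf_pseudocount or 0.0)
    ni = len(cols_i)
    conds = np.array(["initial"] * ni + ["final"] * (k.shape[1] - ni))
    groups_replicated = any(
        np.sum(conds == c) >= 2 for c in ("initial", "final")
    )
    disp_mode = "per-condition" if groups_replicated else "pooled"
    alphas = estimate_dispersions(k, sf, conditions=conds, mode=disp_mode)

    base_mean = (k / sf).mean(axis=1)
    ki, kf = k[:, :ni], k[:, ni:]
    si, sfin = sf[:ni], sf[ni:]

    pvals = np.empty(len(sub))
    l2fc = np.empty(len(sub))
    caps = []
    for i in range(len(sub)):
        pvals[i] = nb_test(ki[i], kf[i], si, sfin, float(alphas[i]))
        ti, tf = ki[i].sum(), kf[i].sum()
        if tf == 0 and ti > 0:
            caps.append("cleared")
            l2fc[i] = -cap_value
        elif ti == 0 and tf > 0:
            caps.append("appeared")
            l2fc[i] = +cap_value
        else:
            caps.append("none")
            l2fc[i] = log2_fold_change(ki[i], kf[i], si, sfin, pseudocount)

    padj = bh_adjust(pvals)
    crit = pvals if use_raw_p else padj
    return [
        EnrichmentResult(
            site=tuple(sub.index[i]),
            base_mean=float(base_mean[i]),
            log2fc=float(l2fc[i]),
            pvalue=float(pvals[i]),
            padj=float(padj[i]),
            cap=caps[i],
            significant=bool(crit[i] < alpha),
        )
        for i in range(len(sub))
    ]


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Enrichment results as a DataFrame (TSV-ready)."""
    return pd.DataFrame(
        {
            "kind": [r.site[0] for r in results],
            "pos": [r.site[1] for r in results],
            "orientation": [r.site[2] for r in results],
            "phase": [r.site[3] for r in results],
            "base_mean": [r.base_mean for r in results],
            "log2fc": [r.log2fc for r in results],
            "pvalue": [r.pvalue for r in results],
            "padj": [r.padj for r in results],
            "cap": [r.cap for r in results],
            "significant": [r.significant for r in results],
        }
    )
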