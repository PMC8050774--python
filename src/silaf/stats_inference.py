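"""Empirical-Bayes moderated t-statistics and Benjamini-Hochberg FDR.

One-sample design on per-replicate log2 H/L values (each replicate of a
two-channel mixing design is self-paired, so the null is mean log2 ratio =
0).  Per-feature sample variances ``s2`` with ``d = n - 1`` degrees of
freedom are shrunk toward a prior variance ``s0^2`` with prior degrees of
freedom ``d0`` estimated across all features by method of moments on
``log s2`` (digamma/trigamma inversion, closed form):

    s2_post = (d0 * s0^2 + d * s2) / (d0 + d)
    t_mod   = mean / sqrt(s2_post / n),  with  d0 + d  degrees of freedom.

With ``d0 = 0`` this is the ordinary one-sample t-test; ``d0 = inf`` gives
complete shrinkage to the common prior variance.  Adjusted p-values use the
Benjamini-Hochberg step-up procedure, implemented here once and shared by
every module that corrects across multiple tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats


# ---------------------------------------------------------------------------
# Hyperparameter estimation
# ---------------------------------------------------------------------------


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        raise ValueError("trigamma inverse requires a positive argument")
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        step = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += step
        if abs(step) / y < 1e-10:
            break
    return y


def estimate_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse-chi-square prior.

    Matches the classic empirical-Bayes moment equations on ``z = log s2``:
    ``e = z - digamma(d/2) + log(d/2)`` has mean ``log s0^2 + digamma(d0/2)
    - log(d0/2)`` and excess variance ``trigamma(d0/2)``.  Returns
    ``(d0, s0_sq)``.  When the moment equation has no positive root the
    prior degrees of freedom fall back to 0 (no moderation) with a warning.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    if np.all(s2 <= 0):
        raise ValueError(
            "all features have zero variance; add a noise floor to the inputs")
    z = np.log(np.maximum(s2, 1e-300))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(np.mean(special.polygamma(1, df / 2.0)))
    if evar <= 0:
        warnings.warn("moment equation for the prior df has no positive root; "
                      "falling back to d0 = 0 (no moderation)")
        return 0.0, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


# ---------------------------------------------------------------------------
# Moderated one-sample t-test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModerationPrior:
    d0: float
    s0_sq: float


def moderated_t_test(
    values: pd.DataFrame,
    prior_df: float | None = None,
    min_n: int = 2,
) -> pd.DataFrame:
    """Moderated one-sample t-test of mean log2 ratio != 0 per feature.

    ``values`` holds one row per feature and one column per biological
    replicate (NaN = missing).  Features with fewer than ``min_n`` finite
    values are reported untested (NaN statistic and p).  ``prior_df``
    overrides the estimated prior degrees of freedom (0 = ordinary t-test,
    ``inf`` = complete shrinkage to the prior variance).

    Returns a DataFrame with ``mean_log2fc, n, s2, s2_post, d0, s0_sq,
    t_mod, p, p_adj`` (BH adjustment across the tested features).
    """
    arr = values.to_numpy(dtype=float)
    n = np.sum(np.isfinite(arr), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(np.where(np.isfinite(arr), arr, np.nan), axis=1)
        s2 = np.nanvar(np.where(np.isfinite(arr), arr, np.nan), axis=1, ddof=1)
    tested = n >= max(2, min_n)
    if not tested.any():
        raise ValueError("no feature has enough replicates to test")
    df = (n - 1).astype(float)

    if prior_df is None:
        d0, s0_sq = estimate_prior(s2[tested], df[tested])
    else:
        d0 = float(prior_df)
        _, s0_sq = estimate_prior(s2[tested], df[tested]) if not np.isfinite(d0) or d0 > 0 \
            else (0.0, float(np.nan))
        if d0 == 0.0:
            s0_sq = float(np.nan)

    s2_post = np.full_like(s2, np.nan)
    if np.isinf(d0):
        s2_post[tested] = s0_sq
        df_total = np.full_like(df, np.inf)
    else:
        s2_post[tested] = (d0 * (s0_sq if d0 > 0 else 0.0) + df[tested] * s2[tested]) \
            / (d0 + df[tested])
        df_total = d0 + df
    with np.errstate(invalid="ignore", divide="ignore"):
        t_mod = mean / np.sqrt(s2_post / n)
    p = np.full_like(t_mod, np.nan)
    ok = tested & np.isfinite(t_mod)
    p[ok] = 2.0 * stats.t.sf(np.abs(t_mod[ok]), df_total[ok])
    p[ok] = np.minimum(p[ok], 1.0)

    out = pd.DataFrame({
        "mean_log2fc": mean, "n": n, "s2": s2, "s2_post": s2_post,
        "d0": d0, "s0_sq": s0_sq, "t_mod": t_mod, "p": p,
    }, index=values.index)
    out["p_adj"] = np.nan
    out.loc[ok, "p_adj"] = bh_adjust(p[ok])
    return out


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------


def bh_adjust(p: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving.

    Input p-values must lie in (0, 1].  Monotonicity is enforced by the
    cumulative minimum from the largest p downwards; output position i
    corresponds to input position i.
    """
    arr = np.asarray(list(p), dtype=float)
    bad = np.where(~((arr > 0) & (arr <= 1)))[0]
    if bad.size:
        raise ValueError(f"p-value out of (0, 1] at index {int(bad[0])}: {arr[bad[0]]!r}")
    m = arr.size
    if m == 0:
        return arr
    order = np.argsort(arr, kind="mergesort")
    ranked = arr[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# Significance calls
# ---------------------------------------------------------------------------


def significance_table(results: pd.DataFrame, threshold: float = 0.01
                       ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Volcano-ready significance calls at an adjusted-p threshold.

    Adds ``significant`` and ``direction`` (sign of the mean log2 fold
    change) columns and returns the counts of up/down-regulated features.
    Conventional thresholds: 0.01 for proteome-wide fold changes, 0.05 for
    phospho-occupancy changes.
    """
    out = results.copy()
    sig = out["p_adj"] < threshold
    out["significant"] = sig.fillna(False)
    out["direction"] = np.where(out["mean_log2fc"] > 0, "up", "down")
    out.loc[out["mean_log2fc"] == 0, "direction"] = "none"
    counts = {
        "up": int((out["significant"] & (out["direction"] == "up")).sum()),
        "down": int((out["significant"] & (out["direction"] == "down")).sum()),
        "n_tested": int(out["p_adj"].notna().sum()),
        "threshold": threshold,
    }
    return out, counts
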