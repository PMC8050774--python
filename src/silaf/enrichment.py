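"""Functional-category enrichment: hypergeometric ORA and permutation GSEA.

Overrepresentation analysis tests each gene set with the one-sided
hypergeometric upper tail against a user-supplied background.  Gene-set
enrichment analysis ranks features by log2 fold change and computes the
weighted Kolmogorov-Smirnov-like running-sum enrichment score (weight
``|log2fc|**w``, w = 1 by default); significance comes from gene-label
permutation with a p-value floor of ``1 / (n_perm + 1)``, and scores are
normalized by the permutation mean of matching sign.  Gene sets must be
supplied in the same identifier space as the results; identifier mapping is
out of scope.  All across-set corrections use the shared Benjamini-Hochberg
implementation.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .stats_inference import bh_adjust
from .tables_io import CategoryAnnotation, GeneSet


# ---------------------------------------------------------------------------
# Overrepresentation analysis
# ---------------------------------------------------------------------------


def hypergeom_upper_tail(n_hits: int, n_background: int, n_set: int,
                         n_foreground: int) -> float:
    """P(X >= n_hits) for X ~ Hypergeom(background, set, foreground draws)."""
    return float(stats.hypergeom.sf(n_hits - 1, n_background, n_set, n_foreground))


def ora(
    foreground: set[str] | Sequence[str],
    background: set[str] | Sequence[str],
    sets: Sequence[GeneSet],
    min_overlap: int = 3,
) -> pd.DataFrame:
    """Hypergeometric overrepresentation of each gene set in the foreground.

    Sets are intersected with the background before testing; sets with fewer
    than ``min_overlap`` foreground hits are reported untested (NaN p).
    Returns one row per set with ``n_set`` (within background), ``n_hits``,
    ``fold_enrichment``, ``p`` and ``p_adj`` (BH across tested sets).
    """
    fg = set(foreground)
    bg = set(background)
    if not fg or not bg:
        raise ValueError("foreground and background must be non-empty")
    if not fg <= bg:
        raise ValueError("foreground must be a subset of the background")
    records = []
    for s in sets:
        members = s.members & bg
        hits = members & fg
        tested = len(hits) >= min_overlap and len(members) > 0
        if tested:
            p = hypergeom_upper_tail(len(hits), len(bg), len(members), len(fg))
            fold = (len(hits) / len(fg)) / (len(members) / len(bg))
        else:
            p, fold = np.nan, np.nan
        records.append({"set_id": s.set_id, "n_set": len(members),
                        "n_hits": len(hits), "fold_enrichment": fold,
                        "p": p, "tested": tested})
    out = pd.DataFrame.from_records(records).set_index("set_id")
    out["p_adj"] = np.nan
    mask = out["tested"]
    if mask.any():
        out.loc[mask, "p_adj"] = bh_adjust(out.loc[mask, "p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# GSEA
# ---------------------------------------------------------------------------


def _es_from_positions(positions: np.ndarray, weights: np.ndarray, n: int) -> float:
    """Enrichment score from the sorted 0-based hit positions only.

    The running sum rises by the normalized weight at each hit and falls by
    1/(N - m) at each miss; its extrema occur immediately after a hit
    (maximum candidates) or immediately before one (minimum candidates), so
    only O(m) evaluations are needed.
    """
    m = positions.size
    if m == 0:
        return 0.0
    wsum = float(weights.sum())
    if wsum <= 0:
        # all-zero weights: fall back to equal weights (unweighted statistic)
        weights = np.ones(m)
        wsum = float(m)
    miss_denom = n - m
    cum = np.cumsum(weights) / wsum
    j = np.arange(1, m + 1)
    if miss_denom > 0:
        after = cum - (positions + 1 - j) / miss_denom
        before = np.concatenate(([0.0], cum[:-1])) - (positions - (j - 1)) / miss_denom
    else:
        after = cum
        before = np.concatenate(([0.0], cum[:-1]))
    candidates = np.concatenate((after, before))
    idx = int(np.argmax(np.abs(candidates)))
    return float(candidates[idx])


def enrichment_score(ranked_ids: Sequence[str], weights: np.ndarray,
                     members: set[str]) -> tuple[float, list[str]]:
    """Observed ES and leading edge of a set against a ranked list."""
    hit_mask = np.fromiter((g in members for g in ranked_ids), dtype=bool,
                           count=len(ranked_ids))
    positions = np.where(hit_mask)[0]
    es = _es_from_positions(positions, weights[positions], len(ranked_ids))
    # leading edge: hits up to the running-sum extremum
    m = positions.size
    if m == 0:
        return 0.0, []
    w = weights[positions]
    wsum = float(w.sum()) or float(m)
    cum = np.cumsum(w if w.sum() > 0 else np.ones(m)) / wsum
    j = np.arange(1, m + 1)
    miss_denom = len(ranked_ids) - m
    after = cum - (positions + 1 - j) / miss_denom if miss_denom else cum
    if es >= 0:
        cut = int(np.argmax(after))
        lead = positions[: cut + 1]
    else:
        before = (np.concatenate(([0.0], cum[:-1]))
                  - (positions - (j - 1)) / miss_denom if miss_denom
                  else np.concatenate(([0.0], cum[:-1])))
        cut = int(np.argmin(before))
        lead = positions[cut:]
    return es, [ranked_ids[i] for i in lead]


def gsea(
    ranked: Sequence[tuple[str, float]] | Mapping[str, float],
    sets: Sequence[GeneSet],
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
    min_size: int = 5,
) -> pd.DataFrame:
    """Permutation gene-set enrichment over a ranked log2-fold-change list.

    ``ranked`` maps unique identifiers to log2 fold changes (an unsorted
    mapping or pair list; ranking is by decreasing fold change).  For each
    set of at least ``min_size`` members within the ranking, the observed
    weighted running-sum score is compared with ``n_perm`` gene-label
    permutations (random same-size sets).  Returns per set: ``es``, ``nes``
    (ES over the mean of same-sign permutation scores), ``p`` (floored at
    ``1/(n_perm+1)``), ``p_adj``, ``direction`` and the leading edge.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    items = list(ranked.items()) if isinstance(ranked, Mapping) else list(ranked)
    ids = [g for g, _ in items]
    dupes = {g for g in ids if ids.count(g) > 1} if len(set(ids)) != len(ids) else set()
    if dupes:
        raise ValueError(f"duplicate identifiers in ranking: {sorted(dupes)}")
    items.sort(key=lambda kv: (-kv[1], kv[0]))
    ranked_ids = [g for g, _ in items]
    fc = np.array([v for _, v in items], dtype=float)
    weights = np.abs(fc) ** weight_exponent
    n = len(ranked_ids)
    rng = np.random.default_rng(seed)
    records = []
    for s in sets:
        members = s.members & set(ranked_ids)
        if len(members) < min_size:
            records.append({"set_id": s.set_id, "n_set": len(members),
                            "es": np.nan, "nes": np.nan, "p": np.nan,
                            "direction": "", "leading_edge": "", "tested": False})
            continue
        es, lead = enrichment_score(ranked_ids, weights, members)
        m = len(members)
        perm_es = np.empty(n_perm)
        for i in range(n_perm):
            pos = np.sort(rng.choice(n, size=m, replace=False))
            perm_es[i] = _es_from_positions(pos, weights[pos], n)
        if es >= 0:
            same = perm_es[perm_es >= 0]
            extreme = int(np.sum(perm_es >= es))
        else:
            same = perm_es[perm_es < 0]
            extreme = int(np.sum(perm_es <= es))
        denom = max(len(same), 1)
        p = max((extreme) / denom if denom else 1.0, 1.0 / (n_perm + 1))
        p = min(p, 1.0)
        mean_same = float(np.mean(np.abs(same))) if len(same) else np.nan
        nes = es / mean_same if mean_same and np.isfinite(mean_same) else np.nan
        records.append({"set_id": s.set_id, "n_set": m, "es": es, "nes": nes,
                        "p": p, "direction": "down" if es < 0 else "up",
                        "leading_edge": ";".join(lead), "tested": True})
    out = pd.DataFrame.from_records(records).set_index("set_id")
    out["p_adj"] = np.nan
    mask = out["tested"]
    if mask.any():
        out.loc[mask, "p_adj"] = bh_adjust(out.loc[mask, "p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Category box-plot summaries with rank-sum tests
# ---------------------------------------------------------------------------


def category_boxplot_summary(
    values: Mapping[str, float] | pd.Series,
    annotation: CategoryAnnotation,
) -> pd.DataFrame:
    """Per-category distribution summary with a median-shift test.

    For each annotated category: median, quartiles, and Tukey whisker bounds
    (most extreme data within 1.5 x IQR of the box), plus a two-sided
    Wilcoxon rank-sum test of the category's values against all other
    proteins, BH-adjusted across categories.
    """
    ser = pd.Series(dict(values), dtype=float).dropna()
    cats = pd.Series({p: annotation.category(p) for p in ser.index})
    records = []
    for cat in sorted(cats.unique()):
        vals = ser[cats == cat]
        rest = ser[cats != cat]
        q25, med, q75 = np.percentile(vals, [25, 50, 75])
        iqr = q75 - q25
        in_lo = vals[vals >= q25 - 1.5 * iqr]
        in_hi = vals[vals <= q75 + 1.5 * iqr]
        if len(rest) and len(vals):
            p = float(stats.mannwhitneyu(vals, rest, alternative="two-sided").pvalue)
        else:
            p = np.nan
        records.append({"category": cat, "n": len(vals), "median": med,
                        "q25": q25, "q75": q75,
                        "whisker_low": float(in_lo.min()) if len(in_lo) else np.nan,
                        "whisker_high": float(in_hi.max()) if len(in_hi) else np.nan,
                        "p": p})
    out = pd.DataFrame.from_records(records).set_index("category")
    tested = out["p"].notna()
    out["p_adj"] = np.nan
    if tested.any():
        out.loc[tested, "p_adj"] = bh_adjust(out.loc[tested, "p"].to_numpy())
    return out
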