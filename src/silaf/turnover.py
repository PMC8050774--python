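"""Protein turnover estimation from pulse-labeling time courses.

The labeling fraction of a protein turning over at rate ``k`` follows the
single-pool first-order model ``f(t) = 1 - exp(-k t)`` with ``f(0) = 0``
(animals arrive unlabeled at transfer to heavy food) and asymptote 1.  The
rate is estimated per protein by unweighted least squares on the fraction
scale over a bounded interval, and the half-life is ``ln 2 / k``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .tables_io import CategoryAnnotation

K_BOUNDS = (1e-6, 10.0)

#: labeling-fraction bins of the final timepoint used for quartile ORA input;
#: closed at 0, right-closed elsewhere: [0-0.25], (0.25-0.5], (0.5-0.75], (0.75-1]
QUARTILE_LABELS = ("[0-25]", "(25-50]", "(50-75]", "(75-100]")


@dataclass(frozen=True)
class TurnoverFit:
    """Least-squares fit of the first-order labeling model for one protein."""

    protein_id: str
    k_hat: float
    half_life: float
    rss: float
    n_timepoints: int
    converged: bool


def fit_turnover(
    timepoints: Sequence[tuple[float, float]],
    protein_id: str = "",
    rss_threshold: float = math.inf,
) -> TurnoverFit:
    """Fit ``f(t) = 1 - exp(-k t)`` to (days, fraction) observations.

    Requires at least three distinct timepoints.  ``k`` is optimized over
    ``(1e-6, 10]`` per day by bounded scalar minimization of the residual
    sum of squares; ``converged`` is False when the optimum sits at a bound
    or the residual exceeds ``rss_threshold`` (all-zero fractions land on
    the lower bound and are reported non-converged, not raised).
    """
    pts = [(float(t), float(f)) for t, f in timepoints]
    if len({t for t, _ in pts}) < 3:
        raise ValueError("need >= 3 distinct timepoints to fit a turnover rate")
    t = np.array([p[0] for p in pts])
    f = np.array([p[1] for p in pts])
    if np.any(t < 0):
        raise ValueError("timepoints must be non-negative")
    if np.any((f < 0) | (f > 1)):
        raise ValueError("fractions must lie in [0, 1]")

    def rss(k: float) -> float:
        return float(np.sum((f - (-np.expm1(-k * t))) ** 2))

    res = optimize.minimize_scalar(rss, bounds=K_BOUNDS, method="bounded",
                                   options={"xatol": 1e-10})
    k_hat = float(res.x)
    at_bound = k_hat <= K_BOUNDS[0] * 1.01 or k_hat >= K_BOUNDS[1] * 0.999
    value = float(res.fun)
    converged = bool(res.success) and not at_bound and value <= rss_threshold
    return TurnoverFit(protein_id=protein_id, k_hat=k_hat,
                       half_life=math.log(2.0) / k_hat, rss=value,
                       n_timepoints=len({tt for tt, _ in pts}),
                       converged=converged)


def fit_all_proteins(timecourse: pd.DataFrame,
                     rss_threshold: float = math.inf) -> pd.DataFrame:
    """Fit every protein in an incorporation time-course table.

    Expects the long table from ``incorporation_timecourse`` (columns
    ``protein_group_id``, ``timepoint``, ``fraction``; replicate rows are
    passed to the fit as repeated observations).  Proteins with fewer than
    three distinct timepoints are skipped.
    """
    records = []
    for pid, grp in timecourse.groupby("protein_group_id"):
        pts = list(zip(grp["timepoint"], grp["fraction"]))
        if len({t for t, _ in pts}) < 3:
            continue
        fit = fit_turnover(pts, protein_id=pid, rss_threshold=rss_threshold)
        records.append({"protein_id": fit.protein_id, "k_hat": fit.k_hat,
                        "half_life": fit.half_life, "rss": fit.rss,
                        "n_timepoints": fit.n_timepoints,
                        "converged": fit.converged})
    return pd.DataFrame.from_records(records).set_index("protein_id") \
        if records else pd.DataFrame(columns=["k_hat", "half_life", "rss",
                                              "n_timepoints", "converged"])


def labeling_quartile(fraction: float) -> str:
    """Assign a final-timepoint labeling fraction to its quartile bin."""
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    if fraction <= 0.25:
        return QUARTILE_LABELS[0]
    if fraction <= 0.5:
        return QUARTILE_LABELS[1]
    if fraction <= 0.75:
        return QUARTILE_LABELS[2]
    return QUARTILE_LABELS[3]


def category_labeling_summary(
    fractions: dict[str, float] | pd.Series,
    annotation: CategoryAnnotation,
) -> pd.DataFrame:
    """Per-category median and quartiles of labeling fractions.

    Proteins not covered by the annotation are grouped as ``"unannotated"``.
    Also assigns each protein's labeling quartile bin; the per-category table
    and the per-protein bins feed overrepresentation analysis downstream.
    """
    ser = pd.Series(dict(fractions), name="fraction", dtype=float)
    cats = pd.Series({p: annotation.category(p) for p in ser.index}, name="category")
    df = pd.concat([ser, cats], axis=1)
    g = df.groupby("category")["fraction"]
    summary = pd.DataFrame({"median": g.median(), "q25": g.quantile(0.25),
                            "q75": g.quantile(0.75), "n": g.size()})
    summary["quartile_bin_of_median"] = [labeling_quartile(m) for m in summary["median"]]
    return summary


def quartile_partition(fractions: dict[str, float] | pd.Series) -> dict[str, list[str]]:
    """Partition proteins into the four labeling-quartile bins (disjoint, total)."""
    bins: dict[str, list[str]] = {lab: [] for lab in QUARTILE_LABELS}
    for pid, f in dict(fractions).items():
        bins[labeling_quartile(f)].append(pid)
    return bins
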