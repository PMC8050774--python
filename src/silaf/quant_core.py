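"""Core H/L quantification: filtering, normalization, aggregation.

Implements the standard two-channel workflow: protein groups flagged as
decoy ("reverse"), potential contaminant, or "only identified by site" are
excluded; peptide H/L ratios are median-centered on the log2 scale within
each run; protein-level log2 ratios are the median over peptide ratios per
replicate, technical replicates are averaged before any biological
statistics; label incorporation is computed from raw (not normalized)
intensities as H / (H + L).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .runlog import RunLog
from .tables_io import CategoryAnnotation, EvidenceRow, ProteinGroupRow


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


def filter_protein_groups(
    rows: Sequence[ProteinGroupRow], log: RunLog | None = None
) -> list[ProteinGroupRow]:
    """Drop protein groups carrying any of the three quality flags.

    A row flagged both contaminant and reverse is removed once but counted
    under both flags in the log.
    """
    kept = [r for r in rows
            if not (r.flag_reverse or r.flag_contaminant or r.flag_only_by_site)]
    if log is not None:
        log.log(
            "filter_protein_groups",
            n_input=len(rows), n_kept=len(kept),
            n_reverse=sum(r.flag_reverse for r in rows),
            n_contaminant=sum(r.flag_contaminant for r in rows),
            n_only_by_site=sum(r.flag_only_by_site for r in rows),
        )
    return kept


# ---------------------------------------------------------------------------
# Elementary quantities
# ---------------------------------------------------------------------------


def incorporation_rate(intensity_heavy, intensity_light):
    """Label incorporation H / (H + L) from raw intensities.

    Accepts scalars or arrays; absent (None/NaN) channels count as zero
    signal, and an observation with no signal in either channel is undefined
    and returned as NaN (missing), never as 0.
    """
    h = np.asarray(np.nan_to_num(np.array(intensity_heavy, dtype=float), nan=0.0))
    light = np.asarray(np.nan_to_num(np.array(intensity_light, dtype=float), nan=0.0))
    if np.any(h < 0) or np.any(light < 0):
        raise ValueError("intensities must be non-negative")
    total = h + light
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, h / np.where(total > 0, total, 1.0), np.nan)
    if frac.ndim == 0:
        return float(frac)
    return frac


def normalize_ratios(ratios: Iterable[float], log: RunLog | None = None,
                     run: str = "") -> np.ndarray:
    """Median-center H/L ratios on the log2 scale within one run.

    Returns the ratios divided by ``2 ** median(log2 ratios)`` so the
    within-run median log2 ratio becomes 0.  Non-finite / non-positive
    entries are ignored for the shift and propagated as NaN.
    """
    arr = np.asarray(list(ratios), dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        log2r = np.where(arr > 0, np.log2(np.where(arr > 0, arr, 1.0)), np.nan)
    finite = np.isfinite(log2r)
    if not finite.any():
        raise ValueError(f"no finite ratios to normalize in run {run!r}")
    shift = float(np.median(log2r[finite]))
    if log is not None:
        log.log("normalize_ratios", run=run, shift_log2=shift, n_ratios=int(finite.sum()))
    return arr / 2.0 ** shift


# ---------------------------------------------------------------------------
# Evidence -> DataFrame
# ---------------------------------------------------------------------------


def evidence_frame(evidence: Sequence[EvidenceRow]) -> pd.DataFrame:
    """Tabulate evidence rows (absent intensities become NaN, never 0)."""
    return pd.DataFrame({
        "peptide": [e.peptide_sequence for e in evidence],
        "protein_group_id": [e.protein_group_id for e in evidence],
        "raw_file": [e.raw_file for e in evidence],
        "bio": [e.replicate_bio for e in evidence],
        "tech": [e.replicate_tech for e in evidence],
        "timepoint": [np.nan if e.timepoint_days is None else e.timepoint_days
                      for e in evidence],
        "intensity_h": [np.nan if e.intensity_heavy is None else e.intensity_heavy
                        for e in evidence],
        "intensity_l": [np.nan if e.intensity_light is None else e.intensity_light
                        for e in evidence],
    })


# ---------------------------------------------------------------------------
# Comparison-mode protein quantification
# ---------------------------------------------------------------------------


@dataclass
class ProteinQuantTable:
    """Protein-level quantification at three aggregation stages.

    ``per_rep``  — log2 normalized H/L per (protein x ``b{bio}_t{tech}``);
    ``per_bio``  — technical replicates averaged, per (protein x ``bio``);
    ``summary``  — ``mean_log2fc`` over biological replicates plus
    ``n_peptide_ratios``, ``n_bio_used`` and ``category``.
    """

    per_rep: pd.DataFrame
    per_bio: pd.DataFrame
    summary: pd.DataFrame


def quantify_comparison(
    evidence: Sequence[EvidenceRow],
    protein_groups: Sequence[ProteinGroupRow],
    min_peptide_ratios: int = 1,
    annotation: CategoryAnnotation | None = None,
    log: RunLog | None = None,
) -> ProteinQuantTable:
    """Protein log2 fold changes from peptide H/L ratios.

    Pipeline: flag-filter protein groups -> peptide ratios (rows with signal
    in both channels; one-channel-only rows are excluded from ratio
    statistics) -> per-run median centering on log2 scale -> per replicate,
    protein ratio = median of its peptides' log2 ratios -> technical
    replicates averaged -> mean over biological replicates.
    """
    kept_ids = {g.protein_group_id for g in filter_protein_groups(protein_groups, log)}
    df = evidence_frame(evidence)
    df = df[df["protein_group_id"].isin(kept_ids)].copy()
    usable = (df["intensity_h"] > 0) & (df["intensity_l"] > 0)
    if log is not None:
        log.log("peptide_ratios", n_evidence=len(df), n_with_ratio=int(usable.sum()))
    df = df[usable].copy()
    if df.empty:
        raise ValueError("no usable peptide ratios after filtering")
    df["log2_ratio"] = np.log2(df["intensity_h"] / df["intensity_l"])
    # per-run median centering
    shifts = df.groupby("raw_file")["log2_ratio"].median()
    if log is not None:
        for run, shift in shifts.items():
            log.log("normalize_ratios", run=run, shift_log2=float(shift),
                    n_ratios=int((df["raw_file"] == run).sum()))
    df["log2_norm"] = df["log2_ratio"] - df["raw_file"].map(shifts)

    per_rep_long = (df.groupby(["protein_group_id", "bio", "tech"])["log2_norm"]
                      .median().rename("log2_ratio").reset_index())
    per_rep = per_rep_long.pivot_table(
        index="protein_group_id",
        columns=per_rep_long["bio"].astype(str).radd("b") + "_" +
                per_rep_long["tech"].astype(str).radd("t"),
        values="log2_ratio", aggfunc="first")
    per_rep.columns.name = None

    per_bio_long = (per_rep_long.groupby(["protein_group_id", "bio"])["log2_ratio"]
                    .mean().reset_index())
    per_bio = per_bio_long.pivot_table(
        index="protein_group_id",
        columns=per_bio_long["bio"].astype(str).radd("bio"),
        values="log2_ratio", aggfunc="first")
    per_bio.columns.name = None

    n_ratios = df.groupby("protein_group_id").size().rename("n_peptide_ratios")
    summary = pd.DataFrame({
        "mean_log2fc": per_bio.mean(axis=1),
        "n_bio_used": per_bio.notna().sum(axis=1),
    }).join(n_ratios)
    summary = summary[summary["n_peptide_ratios"] >= min_peptide_ratios]
    dropped = per_bio.index.difference(summary.index)
    if log is not None and len(dropped):
        log.log("proteins_dropped_min_ratios", n=len(dropped))
    if annotation is not None:
        summary["category"] = [annotation.category(pid) for pid in summary.index]
    per_rep = per_rep.loc[summary.index]
    per_bio = per_bio.loc[summary.index]
    return ProteinQuantTable(per_rep=per_rep, per_bio=per_bio, summary=summary)


# ---------------------------------------------------------------------------
# Time-course incorporation
# ---------------------------------------------------------------------------


def incorporation_timecourse(
    evidence: Sequence[EvidenceRow],
    protein_groups: Sequence[ProteinGroupRow] | None = None,
    pool_replicates: str = "after",
    log: RunLog | None = None,
) -> pd.DataFrame:
    """Per-protein label incorporation per timepoint from raw intensities.

    The per-protein fraction is ``incorporation_rate`` applied to the summed
    (not normalized) heavy and light intensities of its peptides within one
    timepoint.  With ``pool_replicates="after"`` (default) a fraction is
    computed per biological replicate and the pooled distribution keeps one
    value per (protein, timepoint, replicate); ``"before"`` sums intensities
    across replicates first.
    """
    if pool_replicates not in ("after", "before"):
        raise ValueError("pool_replicates must be 'after' or 'before'")
    if protein_groups is not None:
        kept = {g.protein_group_id for g in filter_protein_groups(protein_groups, log)}
    else:
        kept = None
    df = evidence_frame(evidence)
    df = df[df["timepoint"].notna()]
    if kept is not None:
        df = df[df["protein_group_id"].isin(kept)]
    if df.empty:
        raise ValueError("no time-course evidence (timepoint_days absent everywhere)")
    keys = ["protein_group_id", "timepoint"]
    if pool_replicates == "after":
        keys = keys + ["bio"]
    sums = (df.groupby(keys)[["intensity_h", "intensity_l"]]
              .sum(min_count=1).reset_index())
    sums["fraction"] = incorporation_rate(sums["intensity_h"], sums["intensity_l"])
    sums = sums.dropna(subset=["fraction"])
    if log is not None:
        log.log("incorporation_timecourse", n_points=len(sums),
                pool_replicates=pool_replicates,
                timepoints=sorted(df["timepoint"].unique().tolist()))
    return sums[keys + ["fraction"]]


def pooled_incorporation_by_timepoint(timecourse: pd.DataFrame) -> pd.DataFrame:
    """Median and quartiles of the pooled per-protein fractions per timepoint."""
    g = timecourse.groupby("timepoint")["fraction"]
    return pd.DataFrame({"median": g.median(),
                         "q25": g.quantile(0.25),
                         "q75": g.quantile(0.75),
                         "n": g.size()})


def category_median_incorporation(
    timecourse: pd.DataFrame, annotation: CategoryAnnotation
) -> pd.DataFrame:
    """Median labeling fraction per functional category and timepoint."""
    df = timecourse.copy()
    df["category"] = [annotation.category(p) for p in df["protein_group_id"]]
    g = df.groupby(["category", "timepoint"])["fraction"]
    return g.median().rename("median_fraction").reset_index()
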