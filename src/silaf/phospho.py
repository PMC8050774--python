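"""Phosphosite filtering and occupancy-change quantification.

Sites are retained only with localization probability strictly above 0.75.
The occupancy change of a site between conditions is its log2 H/L ratio
minus the matched protein's log2 H/L ratio in the same replicate
(protein-normalized site ratio), so a pure protein-abundance change yields
an occupancy change of 0.  Occupancy changes are computed within replicate,
technical replicates are averaged, and biological replicates feed the
moderated statistics.  Sites on strongly changed proteins are flagged as
potentially confounded but never silently dropped.
"""

from __future__ import annotations

import re
from typing import Sequence

import numpy as np
import pandas as pd

from .quant_core import ProteinQuantTable
from .runlog import RunLog
from .tables_io import SiteRow

LOCALIZATION_THRESHOLD = 0.75

_REP_KEY = re.compile(r"^b(\d+)_t(\d+)$")


def filter_sites(sites: Sequence[SiteRow], threshold: float = LOCALIZATION_THRESHOLD,
                 log: RunLog | None = None) -> list[SiteRow]:
    """Keep sites with localization probability strictly above ``threshold``.

    A site at exactly the threshold is removed.  Logs the retained count and
    the residue composition of what survives (phosphoproteomes are
    serine-dominated; the summary makes that visible).
    """
    kept = [s for s in sites if s.localization_probability > threshold]
    if log is not None:
        comp = {res: sum(1 for s in kept if s.residue == res) for res in "STY"}
        log.log("filter_sites", threshold=threshold, n_input=len(sites),
                n_kept=len(kept), residue_composition=comp)
    return kept


def occupancy_change(site_log2_ratio: float, protein_log2_ratio: float) -> float:
    """Protein-normalized site change: log2 site H/L minus log2 protein H/L."""
    if not (np.isfinite(site_log2_ratio) and np.isfinite(protein_log2_ratio)):
        raise ValueError("both site and protein log2 ratios must be finite")
    return float(site_log2_ratio - protein_log2_ratio)


def flag_protein_confound(occupancy_table: pd.DataFrame,
                          protein_mean_log2fc: pd.Series,
                          threshold: float = 2.0) -> pd.DataFrame:
    """Annotate sites whose protein changes more than ``2**threshold``-fold.

    A site on a protein with |log2 fold change| strictly above the threshold
    (default 2, i.e. fourfold) gets ``confounded=True``: its apparent
    occupancy change may be skewed by the protein-level change.  The flag is
    carried into reports; rows are never dropped on its account.
    """
    out = occupancy_table.copy()
    pfc = out["protein_group_id"].map(protein_mean_log2fc)
    out["protein_mean_log2fc"] = pfc
    out["confounded"] = pfc.abs() > threshold
    out.loc[pfc.isna(), "confounded"] = False
    return out


def quantify_occupancy(
    sites: Sequence[SiteRow],
    quant: ProteinQuantTable,
    localization_threshold: float = LOCALIZATION_THRESHOLD,
    confound_threshold: float = 2.0,
    log: RunLog | None = None,
) -> pd.DataFrame:
    """Site-level occupancy changes against matched protein quantification.

    Returns one row per localization-filtered site with per-biological-
    replicate occupancy changes (``occ_bio{i}`` columns; technical replicates
    averaged within each biological replicate), ``mean_log2_occupancy_change``,
    the number of replicates used, the matched/unmatched status, and the
    protein-confound flag.  Sites whose protein group is absent from the
    filtered protein table are reported unmatched and excluded from the
    occupancy statistics (``matched=False``, NaN changes).
    """
    kept = filter_sites(sites, localization_threshold, log)
    per_rep = quant.per_rep
    records = []
    n_unmatched = 0
    for s in kept:
        matched = s.protein_group_id in per_rep.index
        by_bio: dict[int, list[float]] = {}
        if matched:
            prot = per_rep.loc[s.protein_group_id]
            for key, ratio in s.ratio_hl_per_replicate.items():
                m = _REP_KEY.match(key)
                if m is None or key not in per_rep.columns:
                    continue
                p_log2 = prot[key]
                if pd.isna(p_log2):
                    continue
                by_bio.setdefault(int(m.group(1)), []).append(
                    occupancy_change(float(np.log2(ratio)), float(p_log2)))
        else:
            n_unmatched += 1
        rec = {
            "site_id": s.site_id,
            "protein_group_id": s.protein_group_id,
            "position": s.position_in_protein,
            "residue": s.residue,
            "localization_probability": s.localization_probability,
            "matched": matched,
            "n_bio_used": len(by_bio),
        }
        for b, vals in sorted(by_bio.items()):
            rec[f"occ_bio{b}"] = float(np.mean(vals))
        occs = [rec[k] for k in rec if str(k).startswith("occ_bio")]
        rec["mean_log2_occupancy_change"] = float(np.mean(occs)) if occs else np.nan
        records.append(rec)
    table = pd.DataFrame.from_records(records)
    if table.empty:
        return table
    occ_cols = sorted(c for c in table.columns if c.startswith("occ_bio"))
    ordered = ["site_id", "protein_group_id", "position", "residue",
               "localization_probability", "matched", "n_bio_used",
               *occ_cols, "mean_log2_occupancy_change"]
    table = table[ordered]
    table = flag_protein_confound(table, quant.summary["mean_log2fc"],
                                  confound_threshold)
    if log is not None:
        log.log("quantify_occupancy", n_sites=len(kept),
                n_unmatched=n_unmatched,
                n_quantified=int(table["mean_log2_occupancy_change"].notna().sum()))
    return table.set_index("site_id")
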