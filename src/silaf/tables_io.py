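"""Readers and writers for search-engine result tables and gene-set files.

The pipeline consumes tab-separated tables in the dialect emitted by common
search engines (MaxQuant-style headers such as ``Intensity H``,
``Ratio H/L normalized``, ``Reverse``, ``Potential contaminant``), GMT
gene-set collections, and a small protein -> functional-category annotation
map.  All column names are configurable through :class:`TableDialect`; the
defaults follow the upstream convention.

Missing-value discipline: an empty intensity or ratio cell is parsed as
*absent* (``None``), never as numeric zero, and writers emit absent values
as empty cells, so a write/read round trip preserves both values and the
pattern of missingness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .runlog import RunLog

#: The 20 standard amino acids.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

PHOSPHO_RESIDUES = frozenset("STY")


class TableFormatError(ValueError):
    """A table does not conform to the expected dialect (e.g. missing column)."""


class RowParseError(ValueError):
    """A single data line could not be parsed; carries the 1-based line number."""

    def __init__(self, path: str | Path, line: int, message: str) -> None:
        super().__init__(f"{path}:{line}: {message}")
        self.path = str(path)
        self.line = line


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EvidenceRow:
    """One quantified peptide observation — the atom of all quantification.

    ``intensity_heavy`` / ``intensity_light`` are raw (not normalized) MS
    intensities in arbitrary units; either may be absent (``None``) but not
    both.  ``timepoint_days`` is set only in pulse-labeling experiments.
    Modification positions are 1-based within ``peptide_sequence``.
    """

    peptide_sequence: str
    charge: int
    intensity_heavy: float | None
    intensity_light: float | None
    protein_group_id: str
    raw_file: str
    fraction: int = 0
    replicate_bio: int = 1
    replicate_tech: int = 1
    timepoint_days: float | None = None
    modifications: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.peptide_sequence:
            raise ValueError("peptide_sequence must be non-empty")
        bad = set(self.peptide_sequence) - AMINO_ACIDS
        if bad:
            raise ValueError(
                f"peptide_sequence contains non-standard residues: {sorted(bad)}"
            )
        if self.charge < 1:
            raise ValueError("charge must be a positive integer")
        if self.intensity_heavy is None and self.intensity_light is None:
            raise ValueError("at least one of heavy/light intensity must be present")
        for name, val in (
            ("intensity_heavy", self.intensity_heavy),
            ("intensity_light", self.intensity_light),
        ):
            if val is not None and val < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.fraction < 0:
            raise ValueError("fraction must be >= 0")
        if self.replicate_bio < 1 or self.replicate_tech < 1:
            raise ValueError("replicate indices are 1-based")
        if self.timepoint_days is not None and self.timepoint_days < 0:
            raise ValueError("timepoint_days must be non-negative")
        for pos, _name in self.modifications:
            if not 1 <= pos <= len(self.peptide_sequence):
                raise ValueError(
                    f"modification position {pos} outside peptide of length "
                    f"{len(self.peptide_sequence)}"
                )


@dataclass(frozen=True)
class ProteinGroupRow:
    """One protein group with its quality flags and summary quantification."""

    protein_group_id: str
    member_protein_ids: tuple[str, ...]
    ratio_hl_normalized: float | None = None
    intensity_heavy: float | None = None
    intensity_light: float | None = None
    flag_reverse: bool = False
    flag_contaminant: bool = False
    flag_only_by_site: bool = False

    def __post_init__(self) -> None:
        if not self.member_protein_ids:
            raise ValueError("member_protein_ids must be non-empty")
        if self.ratio_hl_normalized is not None and self.ratio_hl_normalized <= 0:
            raise ValueError("ratio_hl_normalized must be positive when present")


@dataclass(frozen=True)
class SiteRow:
    """One phosphorylation site (S/T/Y) with per-replicate H/L ratios.

    ``ratio_hl_per_replicate`` maps replicate keys (e.g. ``"b1_t2"`` for
    biological replicate 1, technical replicate 2) to positive H/L ratios;
    replicates without a quantified ratio are simply absent from the map.
    """

    protein_group_id: str
    position_in_protein: int
    residue: str
    localization_probability: float
    ratio_hl_per_replicate: Mapping[str, float] = field(default_factory=dict)
    intensity_heavy: float | None = None
    intensity_light: float | None = None

    def __post_init__(self) -> None:
        if self.residue not in PHOSPHO_RESIDUES:
            raise ValueError(f"residue must be one of S/T/Y, got {self.residue!r}")
        if self.position_in_protein < 1:
            raise ValueError("position_in_protein is 1-based")
        if not 0.0 <= self.localization_probability <= 1.0:
            raise ValueError("localization_probability must lie in [0, 1]")
        for key, val in self.ratio_hl_per_replicate.items():
            if val <= 0:
                raise ValueError(f"ratio for replicate {key!r} must be positive")

    @property
    def site_id(self) -> str:
        return f"{self.protein_group_id}_{self.residue}{self.position_in_protein}"


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene/protein identifiers (one GMT line)."""

    set_id: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.set_id!r} has no members")


@dataclass
class CategoryAnnotation:
    """Protein -> (is_mitochondrial, functional category) map.

    Each protein maps to at most one category label; proteins absent from the
    map are reported as ``"unannotated"`` downstream.
    """

    mapping: dict[str, tuple[bool, str]] = field(default_factory=dict)

    def category(self, protein_id: str) -> str:
        entry = self.mapping.get(protein_id)
        return entry[1] if entry is not None else "unannotated"

    def is_mitochondrial(self, protein_id: str) -> bool:
        entry = self.mapping.get(protein_id)
        return bool(entry[0]) if entry is not None else False

    def categories(self) -> list[str]:
        return sorted({cat for _mito, cat in self.mapping.values()})

    def __len__(self) -> int:
        return len(self.mapping)


# ---------------------------------------------------------------------------
# Dialect
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TableDialect:
    """Column-name map for the tab-separated input dialect.

    Defaults follow the MaxQuant-style convention.  Flag columns use ``"+"``
    for flagged and an empty cell for not flagged.  Per-replicate site ratio
    columns are discovered by prefix: every column starting with
    ``site_ratio_prefix`` contributes one replicate keyed by the suffix.
    """

    # evidence table
    sequence: str = "Sequence"
    charge: str = "Charge"
    intensity_heavy: str = "Intensity H"
    intensity_light: str = "Intensity L"
    proteins: str = "Proteins"
    raw_file: str = "Raw file"
    fraction: str = "Fraction"
    replicate_bio: str = "Bio replicate"
    replicate_tech: str = "Tech replicate"
    timepoint: str = "Time [days]"
    modifications: str = "Modifications"
    # protein groups table
    protein_group_id: str = "Protein group ID"
    member_ids: str = "Protein IDs"
    ratio_hl_normalized: str = "Ratio H/L normalized"
    reverse: str = "Reverse"
    contaminant: str = "Potential contaminant"
    only_by_site: str = "Only identified by site"
    # sites table
    site_position: str = "Position"
    site_residue: str = "Amino acid"
    localization_prob: str = "Localization prob"
    site_ratio_prefix: str = "Ratio H/L normalized "
    # conventions
    flag_true: str = "+"
    member_separator: str = ";"


DEFAULT_DIALECT = TableDialect()


# ---------------------------------------------------------------------------
# Low-level parsing helpers
# ---------------------------------------------------------------------------


def _load_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise TableFormatError(f"input table not found: {path}")
    try:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error passthrough
        raise TableFormatError(f"could not read table {path}: {exc}") from exc


def _require_columns(df: pd.DataFrame, names: Iterable[str], path: str | Path) -> None:
    missing = [n for n in names if n not in df.columns]
    if missing:
        raise TableFormatError(
            f"{path}: missing mandatory column(s): {', '.join(missing)}"
        )


def _opt_float(cell: str, path: str | Path, line: int, column: str) -> float | None:
    """Parse an optional numeric cell; empty string means absent (never 0)."""
    if cell == "":
        return None
    try:
        return float(cell)
    except ValueError:
        raise RowParseError(path, line, f"unparsable number {cell!r} in column {column!r}")


def _req_int(cell: str, path: str | Path, line: int, column: str, default: int | None = None) -> int:
    if cell == "":
        if default is not None:
            return default
        raise RowParseError(path, line, f"empty cell in mandatory column {column!r}")
    try:
        return int(float(cell))
    except ValueError:
        raise RowParseError(path, line, f"unparsable integer {cell!r} in column {column!r}")


def _fmt(value: float | int | str | None) -> str:
    """Serialize a cell.  ``repr`` of a float is the shortest exactly
    round-tripping decimal, so write/read is lossless."""
    if value is None:
        return ""
    if isinstance(value, (float, np.floating)):
        return repr(float(value))
    if isinstance(value, np.integer):
        return str(int(value))
    return str(value)


def _parse_modifications(cell: str, path: str | Path, line: int) -> tuple[tuple[int, str], ...]:
    if cell == "":
        return ()
    mods = []
    for item in cell.split(";"):
        pos_str, _, name = item.partition(":")
        try:
            pos = int(pos_str)
        except ValueError:
            raise RowParseError(path, line, f"bad modification entry {item!r}")
        mods.append((pos, name))
    return tuple(mods)


def _fmt_modifications(mods: Sequence[tuple[int, str]]) -> str:
    return ";".join(f"{pos}:{name}" for pos, name in mods)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_evidence(
    path: str | Path,
    dialect: TableDialect = DEFAULT_DIALECT,
    log: RunLog | None = None,
) -> list[EvidenceRow]:
    """Read an evidence-level peptide table into :class:`EvidenceRow` records."""
    d = dialect
    df = _load_tsv(path)
    _require_columns(
        df,
        [d.sequence, d.charge, d.intensity_heavy, d.intensity_light, d.proteins, d.raw_file],
        path,
    )
    rows: list[EvidenceRow] = []
    for i, rec in enumerate(df.itertuples(index=False)):
        line = i + 2  # 1-based, after the header
        cells = dict(zip(df.columns, rec))
        try:
            row = EvidenceRow(
                peptide_sequence=cells[d.sequence],
                charge=_req_int(cells[d.charge], path, line, d.charge),
                intensity_heavy=_opt_float(cells[d.intensity_heavy], path, line, d.intensity_heavy),
                intensity_light=_opt_float(cells[d.intensity_light], path, line, d.intensity_light),
                protein_group_id=cells[d.proteins],
                raw_file=cells[d.raw_file],
                fraction=_req_int(cells.get(d.fraction, ""), path, line, d.fraction, default=0),
                replicate_bio=_req_int(cells.get(d.replicate_bio, ""), path, line, d.replicate_bio, default=1),
                replicate_tech=_req_int(cells.get(d.replicate_tech, ""), path, line, d.replicate_tech, default=1),
                timepoint_days=_opt_float(cells.get(d.timepoint, ""), path, line, d.timepoint),
                modifications=_parse_modifications(cells.get(d.modifications, ""), path, line),
            )
        except RowParseError:
            raise
        except ValueError as exc:
            raise RowParseError(path, line, str(exc))
        rows.append(row)
    if log is not None:
        log.log("read_evidence", path=str(path), n_rows=len(rows),
                column_map={k: getattr(d, k) for k in (
                    "sequence", "charge", "intensity_heavy", "intensity_light",
                    "proteins", "raw_file")})
    return rows


def read_protein_groups(
    path: str | Path,
    dialect: TableDialect = DEFAULT_DIALECT,
    log: RunLog | None = None,
) -> list[ProteinGroupRow]:
    """Read a protein-groups table; ``"+"`` flag cells become booleans."""
    d = dialect
    df = _load_tsv(path)
    _require_columns(df, [d.protein_group_id, d.member_ids], path)
    rows: list[ProteinGroupRow] = []
    for i, rec in enumerate(df.itertuples(index=False)):
        line = i + 2
        cells = dict(zip(df.columns, rec))
        members = tuple(m for m in cells[d.member_ids].split(d.member_separator) if m)
        try:
            rows.append(
                ProteinGroupRow(
                    protein_group_id=cells[d.protein_group_id],
                    member_protein_ids=members,
                    ratio_hl_normalized=_opt_float(
                        cells.get(d.ratio_hl_normalized, ""), path, line, d.ratio_hl_normalized),
                    intensity_heavy=_opt_float(cells.get(d.intensity_heavy, ""), path, line, d.intensity_heavy),
                    intensity_light=_opt_float(cells.get(d.intensity_light, ""), path, line, d.intensity_light),
                    flag_reverse=cells.get(d.reverse, "") == d.flag_true,
                    flag_contaminant=cells.get(d.contaminant, "") == d.flag_true,
                    flag_only_by_site=cells.get(d.only_by_site, "") == d.flag_true,
                )
            )
        except RowParseError:
            raise
        except ValueError as exc:
            raise RowParseError(path, line, str(exc))
    if log is not None:
        log.log("read_protein_groups", path=str(path), n_rows=len(rows))
    return rows


def read_sites(
    path: str | Path,
    dialect: TableDialect = DEFAULT_DIALECT,
    log: RunLog | None = None,
) -> list[SiteRow]:
    """Read a phospho(STY)-sites table.

    Per-replicate ratio columns are discovered by the configured prefix; the
    remainder of each such column name is the replicate key.
    """
    d = dialect
    df = _load_tsv(path)
    _require_columns(df, [d.protein_group_id, d.site_position, d.site_residue, d.localization_prob], path)
    ratio_cols = [c for c in df.columns if c.startswith(d.site_ratio_prefix)
                  and c != d.ratio_hl_normalized]
    rep_keys = [c[len(d.site_ratio_prefix):] for c in ratio_cols]
    rows: list[SiteRow] = []
    for i, rec in enumerate(df.itertuples(index=False)):
        line = i + 2
        cells = dict(zip(df.columns, rec))
        ratios: dict[str, float] = {}
        for col, key in zip(ratio_cols, rep_keys):
            val = _opt_float(cells[col], path, line, col)
            if val is not None:
                ratios[key] = val
        try:
            loc = _opt_float(cells[d.localization_prob], path, line, d.localization_prob)
            if loc is None:
                raise ValueError("localization probability is mandatory")
            rows.append(
                SiteRow(
                    protein_group_id=cells[d.protein_group_id],
                    position_in_protein=_req_int(cells[d.site_position], path, line, d.site_position),
                    residue=cells[d.site_residue],
                    localization_probability=loc,
                    ratio_hl_per_replicate=ratios,
                    intensity_heavy=_opt_float(cells.get(d.intensity_heavy, ""), path, line, d.intensity_heavy),
                    intensity_light=_opt_float(cells.get(d.intensity_light, ""), path, line, d.intensity_light),
                )
            )
        except RowParseError:
            raise
        except ValueError as exc:
            raise RowParseError(path, line, str(exc))
    if log is not None:
        log.log("read_sites", path=str(path), n_rows=len(rows), replicate_keys=rep_keys)
    return rows


def read_gmt(path: str | Path, log: RunLog | None = None) -> list[GeneSet]:
    """Read a GMT gene-set collection (set_id TAB description TAB member...)."""
    path = Path(path)
    if not path.exists():
        raise TableFormatError(f"GMT file not found: {path}")
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for i, raw in enumerate(fh):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise RowParseError(path, i + 1, "GMT line needs set_id, description and >= 1 member")
            set_id, desc, *members = parts
            members = [m for m in members if m]
            if not members:
                raise RowParseError(path, i + 1, f"gene set {set_id!r} has no members")
            if set_id in seen:
                raise RowParseError(path, i + 1, f"duplicate set_id {set_id!r}")
            seen.add(set_id)
            sets.append(GeneSet(set_id=set_id, description=desc, members=frozenset(members)))
    if log is not None:
        log.log("read_gmt", path=str(path), n_sets=len(sets))
    return sets


def read_annotation(path: str | Path, log: RunLog | None = None) -> CategoryAnnotation:
    """Read a protein -> category map (protein TAB category [TAB mito-flag])."""
    path = Path(path)
    if not path.exists():
        raise TableFormatError(f"annotation file not found: {path}")
    mapping: dict[str, tuple[bool, str]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("protein_id\t"):
            raise TableFormatError(f"{path}: expected header starting with 'protein_id'")
        for i, raw in enumerate(fh):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise RowParseError(path, i + 2, "annotation line needs protein_id and category")
            pid, category = parts[0], parts[1]
            mito = len(parts) > 2 and parts[2] == "+"
            if pid in mapping and mapping[pid][1] != category:
                raise RowParseError(path, i + 2, f"protein {pid!r} maps to more than one category")
            mapping[pid] = (mito, category)
    if log is not None:
        log.log("read_annotation", path=str(path), n_proteins=len(mapping))
    return CategoryAnnotation(mapping)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_evidence(rows: Sequence[EvidenceRow], path: str | Path,
                   dialect: TableDialect = DEFAULT_DIALECT) -> None:
    d = dialect
    cols = [d.sequence, d.charge, d.intensity_heavy, d.intensity_light, d.proteins,
            d.raw_file, d.fraction, d.replicate_bio, d.replicate_tech, d.timepoint,
            d.modifications]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            fh.write("\t".join([
                r.peptide_sequence, _fmt(r.charge), _fmt(r.intensity_heavy),
                _fmt(r.intensity_light), r.protein_group_id, r.raw_file,
                _fmt(r.fraction), _fmt(r.replicate_bio), _fmt(r.replicate_tech),
                _fmt(r.timepoint_days), _fmt_modifications(r.modifications),
            ]) + "\n")


def write_protein_groups(rows: Sequence[ProteinGroupRow], path: str | Path,
                         dialect: TableDialect = DEFAULT_DIALECT) -> None:
    d = dialect
    cols = [d.protein_group_id, d.member_ids, d.ratio_hl_normalized,
            d.intensity_heavy, d.intensity_light, d.reverse, d.contaminant,
            d.only_by_site]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            fh.write("\t".join([
                r.protein_group_id, d.member_separator.join(r.member_protein_ids),
                _fmt(r.ratio_hl_normalized), _fmt(r.intensity_heavy),
                _fmt(r.intensity_light),
                d.flag_true if r.flag_reverse else "",
                d.flag_true if r.flag_contaminant else "",
                d.flag_true if r.flag_only_by_site else "",
            ]) + "\n")


def write_sites(rows: Sequence[SiteRow], path: str | Path,
                dialect: TableDialect = DEFAULT_DIALECT) -> None:
    d = dialect
    rep_keys = sorted({k for r in rows for k in r.ratio_hl_per_replicate})
    cols = [d.protein_group_id, d.site_position, d.site_residue, d.localization_prob,
            d.intensity_heavy, d.intensity_light]
    cols += [d.site_ratio_prefix + k for k in rep_keys]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            cells = [r.protein_group_id, _fmt(r.position_in_protein), r.residue,
                     _fmt(r.localization_probability), _fmt(r.intensity_heavy),
                     _fmt(r.intensity_light)]
            cells += [_fmt(r.ratio_hl_per_replicate.get(k)) for k in rep_keys]
            fh.write("\t".join(cells) + "\n")


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.set_id, s.description, *sorted(s.members)]) + "\n")


def write_annotation(annotation: CategoryAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tfunctional_category\tis_mitochondrial\n")
        for pid in sorted(annotation.mapping):
            mito, category = annotation.mapping[pid]
            fh.write(f"{pid}\t{category}\t{'+' if mito else ''}\n")


def write_results(records: Sequence, path: str | Path,
                  dialect: TableDialect = DEFAULT_DIALECT) -> None:
    """Write a homogeneous list of domain records, dispatching on type.

    The write/read round trip is lossless: identifiers are reproduced
    bit-exactly and reals via shortest round-tripping decimals.
    """
    if len(records) == 0:
        raise ValueError("write_results needs at least one record to infer the type")
    first = records[0]
    if isinstance(first, EvidenceRow):
        write_evidence(records, path, dialect)
    elif isinstance(first, ProteinGroupRow):
        write_protein_groups(records, path, dialect)
    elif isinstance(first, SiteRow):
        write_sites(records, path, dialect)
    elif isinstance(first, GeneSet):
        write_gmt(records, path)
    else:
        raise TypeError(f"cannot serialize records of type {type(first).__name__}")


def write_dataframe(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    """Write a results DataFrame as TSV with a stable column order."""
    df.to_csv(path, sep="\t", index=index)
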