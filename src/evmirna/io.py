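"""Reading and writing of qPCR array well tables, sample sheets and results.

Well-level exports from TaqMan-style array cards arrive as long tables with
one row per well (sample, card A/B, well position, miRNA assay, Cq plus the
amplification-quality scores AmpScore and CqConf). Column names vary between
software versions, so reading goes through a configurable *dialect*: a map
from the canonical field names used throughout this package to the header
names present in the file.

The in-memory currency is pandas: well collections and sample sheets are
validated DataFrames with canonical column names, and the pooled Cq grid is
a :class:`CqMatrix` (assays x samples) with a parallel provenance grid that
records, per cell, whether a value was observed, censored by the instrument
("Undetermined"), removed by a QC rule, or simply has no well.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    DuplicateRecordError,
    FormatError,
    OrphanSampleError,
    PairingError,
)

#: canonical field -> default export header (ExpressionSuite-style)
DEFAULT_DIALECT: dict[str, str] = {
    "sample_id": "Sample Name",
    "card": "Card",
    "well": "Well",
    "assay_id": "Target Name",
    "cq": "Cq",
    "amp_score": "Amp Score",
    "cq_conf": "Cq Conf",
}

#: strings read as a missing Cq (censored / failed amplification)
MISSING_SENTINELS = {"Undetermined", "UNDETERMINED", "undetermined", "NA", ""}

WELL_COLUMNS = ["sample_id", "card", "well", "assay_id", "cq", "amp_score", "cq_conf"]
SHEET_COLUMNS = ["sample_id", "receptor", "group", "pair_id", "batch"]
GROUPS = ("MEDIA_CONTROL", "VEHICLE_CONTROL", "TREATED")

#: instrument cycle ceiling; Cq beyond this is physically impossible
CQ_MAX_VALID = 45.0


def _read_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a CSV/TSV file, inferring the delimiter from the extension."""
    sep = "," if str(path).lower().endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def _parse_numeric(series: pd.Series, name: str) -> pd.Series:
    """Parse a string column to float, mapping sentinels to NaN.

    Non-sentinel strings that fail to parse raise a FormatError rather than
    silently becoming missing.
    """
    cleaned = series.str.strip()
    is_sentinel = cleaned.isin(MISSING_SENTINELS)
    out = pd.to_numeric(cleaned.mask(is_sentinel), errors="coerce")
    bad = out.isna() & ~is_sentinel
    if bad.any():
        offender = cleaned[bad].iloc[0]
        raise FormatError(f"column {name!r}: unparseable value {offender!r}")
    return out.astype(float)


def read_well_table(
    path: str | os.PathLike, dialect: dict[str, str] | None = None
) -> pd.DataFrame:
    """Read a long-format well table into a validated wells DataFrame.

    Parameters
    ----------
    path
        CSV or TSV file with one row per well.
    dialect
        Map from canonical field names (``sample_id``, ``card``, ``well``,
        ``assay_id``, ``cq``, ``amp_score``, ``cq_conf``) to the file's
        header names. Defaults to :data:`DEFAULT_DIALECT`. Partial maps
        override the default field-wise.

    Returns
    -------
    DataFrame with columns :data:`WELL_COLUMNS`; ``cq``, ``amp_score`` and
    ``cq_conf`` are floats with NaN for missing.
    """
    colmap = dict(DEFAULT_DIALECT)
    if dialect:
        colmap.update(dialect)
    raw = _read_table(path)
    missing = [colmap[f] for f in WELL_COLUMNS if colmap[f] not in raw.columns]
    if missing and not dialect and all(f in raw.columns for f in WELL_COLUMNS):
        # already in canonical layout (e.g. written by the simulator)
        colmap = {f: f for f in WELL_COLUMNS}
        missing = []
    if missing:
        raise FormatError(f"well table {path}: missing mandatory column(s) {missing}")
    wells = pd.DataFrame(
        {f: raw[colmap[f]] for f in WELL_COLUMNS},
    )
    return validate_wells(wells, source=str(path))


def validate_wells(wells: pd.DataFrame, source: str = "<memory>") -> pd.DataFrame:
    """Validate and coerce a wells DataFrame in canonical column layout."""
    wells = wells.copy()
    for col in ("cq", "amp_score", "cq_conf"):
        if wells[col].dtype == object:
            wells[col] = _parse_numeric(wells[col].astype(str), col)
        wells[col] = wells[col].astype(float)
    for col in ("sample_id", "card", "well", "assay_id"):
        wells[col] = wells[col].astype(str).str.strip()
    if (wells["assay_id"] == "").any():
        raise FormatError(f"{source}: empty assay_id")
    bad_card = ~wells["card"].isin(["A", "B"])
    if bad_card.any():
        raise FormatError(
            f"{source}: card must be 'A' or 'B', got {sorted(wells.loc[bad_card, 'card'].unique())}"
        )
    cq = wells["cq"]
    out_of_range = cq.notna() & ((cq < 0) | (cq > CQ_MAX_VALID))
    if out_of_range.any():
        raise FormatError(
            f"{source}: Cq outside [0, {CQ_MAX_VALID}]: {cq[out_of_range].tolist()[:5]}"
        )
    conf = wells["cq_conf"]
    bad_conf = conf.notna() & ((conf < 0) | (conf > 1))
    if bad_conf.any():
        raise FormatError(f"{source}: cq_conf outside [0, 1]")
    dup = wells.duplicated(subset=["sample_id", "card", "assay_id"], keep=False)
    if dup.any():
        offenders = (
            wells.loc[dup, ["sample_id", "card", "assay_id"]]
            .drop_duplicates()
            .to_records(index=False)
            .tolist()
        )
        raise DuplicateRecordError(
            f"{source}: duplicate (sample, card, assay) records: {offenders[:10]}"
        )
    return wells.reset_index(drop=True)


def read_sample_sheet(path: str | os.PathLike) -> pd.DataFrame:
    """Read and validate a sample sheet (sample_id, receptor, group, pair_id, batch)."""
    raw = _read_table(path)
    missing = [c for c in SHEET_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"sample sheet {path}: missing column(s) {missing}")
    return validate_sample_sheet(raw[SHEET_COLUMNS], source=str(path))


def validate_sample_sheet(sheet: pd.DataFrame, source: str = "<memory>") -> pd.DataFrame:
    """Validate group vocabulary and treated/vehicle pairing constraints."""
    sheet = sheet.copy()
    for col in ("sample_id", "receptor", "group", "batch"):
        sheet[col] = sheet[col].astype(str).str.strip()
    bad = ~sheet["group"].isin(GROUPS)
    if bad.any():
        raise FormatError(
            f"{source}: unknown group label(s) {sorted(sheet.loc[bad, 'group'].unique())}; "
            f"expected one of {GROUPS}"
        )
    if sheet["sample_id"].duplicated().any():
        raise FormatError(f"{source}: duplicated sample_id")
    pair = sheet["pair_id"]
    if pair.dtype == object:
        pair = pair.astype(str).str.strip().replace({"": None, "NA": None, "nan": None})
    sheet["pair_id"] = pd.array(
        [int(float(v)) if v is not None and not pd.isna(v) else None for v in pair],
        dtype="Int64",
    )
    mc_with_pair = (sheet["group"] == "MEDIA_CONTROL") & sheet["pair_id"].notna()
    if mc_with_pair.any():
        raise PairingError(f"{source}: media-control samples must not carry a pair_id")
    for grp in ("TREATED", "VEHICLE_CONTROL"):
        sub = sheet[(sheet["group"] == grp) & sheet["pair_id"].notna()]
        dup = sub["pair_id"][sub["pair_id"].duplicated()]
        if len(dup):
            raise PairingError(
                f"{source}: pair_id {sorted(set(dup.tolist()))} used by multiple {grp} samples"
            )
    return sheet.reset_index(drop=True)


@dataclass
class CqMatrix:
    """Assays x samples Cq grid pooled from both cards.

    Attributes
    ----------
    values
        float DataFrame (index: assay_id sorted, columns: sample_id sorted);
        NaN marks a missing cycle value.
    provenance
        str DataFrame of the same shape; one of ``observed``, ``absent``
        (no well), or ``filtered:<reason>``.
    card
        Series mapping assay_id -> card letter.
    """

    values: pd.DataFrame
    provenance: pd.DataFrame
    card: pd.Series = field(repr=False)

    @property
    def assays(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def copy(self) -> "CqMatrix":
        return CqMatrix(self.values.copy(), self.provenance.copy(), self.card.copy())

    def subset_assays(self, assays) -> "CqMatrix":
        keep = [a for a in self.assays if a in set(assays)]
        return CqMatrix(
            self.values.loc[keep], self.provenance.loc[keep], self.card.loc[keep]
        )


def build_cq_matrix(wells: pd.DataFrame, annotations: pd.DataFrame) -> CqMatrix:
    """Pool A- and B-card wells into one assays x samples Cq grid.

    Every well's sample must appear in the sample sheet; an assay may live on
    only one card. Cells without a well are flagged ``absent``; wells present
    but censored ("Undetermined") are flagged ``filtered:undetermined``.
    Ordering of both axes is lexicographic, so repeated runs are reproducible
    byte for byte.
    """
    known = set(annotations["sample_id"])
    orphan = sorted(set(wells["sample_id"]) - known)
    if orphan:
        raise OrphanSampleError(f"wells reference unannotated sample(s): {orphan}")
    cards = wells.groupby("assay_id")["card"].nunique()
    both = cards[cards > 1]
    if len(both):
        raise FormatError(
            f"assay(s) present on both cards (must be disjoint): {sorted(both.index)[:10]}"
        )
    assays = sorted(wells["assay_id"].unique())
    samples = sorted(annotations["sample_id"].unique())
    values = wells.pivot(index="assay_id", columns="sample_id", values="cq").reindex(
        index=assays, columns=samples
    )
    has_well = (
        wells.assign(present=True)
        .pivot(index="assay_id", columns="sample_id", values="present")
        .reindex(index=assays, columns=samples)
        .notna()
    )
    provenance = pd.DataFrame("absent", index=assays, columns=samples)
    provenance = provenance.mask(has_well & values.isna(), "filtered:undetermined")
    provenance = provenance.mask(values.notna(), "observed")
    card = wells.groupby("assay_id")["card"].first().reindex(assays)
    values.index.name = values.columns.name = None
    provenance.index.name = provenance.columns.name = None
    return CqMatrix(values.astype(float), provenance, card)


def quality_grids(
    wells: pd.DataFrame, matrix: CqMatrix
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pivot amp_score and cq_conf onto the matrix's assay x sample layout."""
    amp = wells.pivot(index="assay_id", columns="sample_id", values="amp_score")
    conf = wells.pivot(index="assay_id", columns="sample_id", values="cq_conf")
    shape = dict(index=matrix.values.index, columns=matrix.values.columns)
    return amp.reindex(**shape), conf.reindex(**shape)


def write_results_table(records, path: str | os.PathLike) -> None:
    """Write any result collection as TSV: floats at 6 significant digits, NA for missing.

    ``records`` may be a DataFrame or an iterable of dataclass-like objects
    with ``__dict__``. An empty collection with known columns produces a
    header-only file.
    """
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        rows = [getattr(r, "__dict__", r) for r in records]
        frame = pd.DataFrame(rows)
    frame.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def write_matrix(matrix: CqMatrix, path: str | os.PathLike) -> None:
    """Write a CqMatrix values grid (plus card column) as TSV, NA for missing."""
    out = matrix.values.copy()
    out.insert(0, "card", matrix.card)
    out.index.name = "assay_id"
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.6g")


def read_matrix(path: str | os.PathLike) -> CqMatrix:
    """Read a matrix written by :func:`write_matrix`."""
    frame = pd.read_csv(path, sep="\t", index_col="assay_id", na_values=["NA"])
    card = frame.pop("card")
    frame.index.name = None
    prov = pd.DataFrame(
        np.where(frame.notna(), "observed", "absent"),
        index=frame.index,
        columns=frame.columns,
    )
    return CqMatrix(frame.astype(float), prov, card)


def melt_wide_export(
    frame: pd.DataFrame,
    assay_col: str,
    sample_cols: dict[str, str],
    card: str | None = None,
    card_col: str | None = None,
    default_amp_score: float = np.nan,
    default_cq_conf: float = np.nan,
) -> pd.DataFrame:
    """Rewrite a wide (assay x sample) supplementary matrix into the long well format.

    Adapter for repository-deposited series tables whose layout is one column
    per sample. The mapping is user-supplied: ``sample_cols`` maps file column
    name -> sample_id; ``card`` fixes one card letter for the whole table, or
    ``card_col`` names a per-row card column. Quality-score columns rarely
    survive deposition, so constant defaults may be supplied (missing scores
    are treated as QC failures downstream unless defaults are given).
    """
    if (card is None) == (card_col is None):
        raise FormatError("exactly one of card / card_col must be given")
    rows = []
    for file_col, sample_id in sample_cols.items():
        part = pd.DataFrame(
            {
                "sample_id": sample_id,
                "card": frame[card_col] if card_col else card,
                "well": [f"W{i}" for i in range(len(frame))],
                "assay_id": frame[assay_col],
                "cq": frame[file_col],
                "amp_score": default_amp_score,
                "cq_conf": default_cq_conf,
            }
        )
        rows.append(part)
    return validate_wells(pd.concat(rows, ignore_index=True), source="<wide export>")
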