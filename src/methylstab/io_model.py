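"""Domain types and tabular I/O for methylation stability analyses.

The pipeline works on four tabular artifacts: a probes x samples beta-value
matrix (methylation fractions in [0, 1]), a sample sheet describing the
paired cohort (two time points per subject), a manifest-style probe
annotation, and optional variant / CpG-set / gene-set inputs.  Everything is
backed by pandas; the wrapper classes only add validation and a stable
column vocabulary.

Coordinates are 1-based inclusive throughout, following the Illumina
manifest convention.  BED-like variant input (0-based half-open) is
converted on read when requested.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("methylstab")

TIMEPOINTS = ("T1", "T2")
SEX_LABELS = ("F", "M")
SMOKING_LABELS = ("active", "non-smoker")
DISEASE_LABELS = ("CD", "UC")

SAMPLE_SHEET_REQUIRED = ("sample_id", "subject_id", "timepoint")
SAMPLE_SHEET_OPTIONAL = (
    "age_years",
    "sex",
    "smoking",
    "disease",
    "crp_mg_per_l",
    "leukocytes_e9_per_l",
)
ANNOTATION_REQUIRED = ("probe_id", "chrom", "pos")
ANNOTATION_OPTIONAL = ("gene", "gene_region", "is_qc_gv", "annotated_gv", "dbsnp_id")
VARIANT_REQUIRED = ("variant_id", "chrom", "pos", "phenotype")


class FormatError(ValueError):
    """Raised when an input file violates the documented contract."""


def _detect_delimiter(path: str | Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    suffix = Path(path).suffix.lower()
    return "," if suffix == ".csv" else "\t"


def _normalize_columns(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df.columns = [str(c).strip().lower() for c in df.columns]
    return df


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing required column(s) {missing}")


@dataclass
class BetaMatrix:
    """Probes x samples matrix of methylation fractions.

    ``data`` is a float DataFrame indexed by probe id with sample ids as
    columns; missing measurements are NaN, every finite value lies in
    [0, 1].
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise FormatError(f"duplicate probe id: {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        values = self.data.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = (values < 0.0) | (values > 1.0)
        if np.any(bad):
            i, j = map(int, np.argwhere(bad)[0])
            raise FormatError(
                "value out of range [0, 1] at probe "
                f"{self.data.index[i]!r}, sample {self.data.columns[j]!r}: "
                f"{values[i, j]!r}"
            )
        self.data = self.data.astype(float)

    @property
    def probe_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class SampleSheet:
    """Cohort description: one row per sample, two time points per subject."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        _require_columns(df, SAMPLE_SHEET_REQUIRED, "sample sheet")
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        bad_tp = set(df["timepoint"].dropna().unique()) - set(TIMEPOINTS)
        if bad_tp:
            raise FormatError(f"timepoint labels must be in {TIMEPOINTS}, got {sorted(bad_tp)}")
        for col, allowed in (("sex", SEX_LABELS), ("smoking", SMOKING_LABELS), ("disease", DISEASE_LABELS)):
            if col in df.columns:
                bad = set(df[col].dropna().unique()) - set(allowed)
                if bad:
                    raise FormatError(f"{col} labels must be in {allowed}, got {sorted(bad)}")

    def check_paired(self) -> None:
        """Hard check that every subject has exactly one sample per time point."""
        counts = self.data.groupby(["subject_id", "timepoint"]).size()
        bad = counts[counts > 1]
        if len(bad):
            subj, tp = bad.index[0]
            raise FormatError(
                f"subject {subj!r} has {bad.iloc[0]} samples at {tp}; expected exactly one"
            )

    @property
    def subjects(self) -> np.ndarray:
        return np.sort(self.data["subject_id"].unique())

    def sample_for(self, subject: str, timepoint: str) -> str | None:
        rows = self.data[
            (self.data["subject_id"] == subject) & (self.data["timepoint"] == timepoint)
        ]
        return None if rows.empty else rows["sample_id"].iloc[0]


@dataclass
class ProbeAnnotation:
    """Manifest-style per-probe genomic context and probe-class flags."""

    data: pd.DataFrame
    genome_build: str = "hg19"

    def __post_init__(self) -> None:
        df = self.data
        _require_columns(df, ANNOTATION_REQUIRED, "probe annotation")
        if df["probe_id"].duplicated().any():
            dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise FormatError(f"duplicate probe id in annotation: {dup!r}")
        if (df["pos"].dropna() < 1).any():
            raise FormatError("annotation positions are 1-based; found pos < 1")
        for flag in ("is_qc_gv", "annotated_gv"):
            if flag not in df.columns:
                df[flag] = False
            df[flag] = df[flag].fillna(False).astype(bool)
        self.data = df.set_index("probe_id", drop=False)


@dataclass
class VariantTable:
    """Known variants with 1-based positions and a phenotype label."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _require_columns(self.data, VARIANT_REQUIRED, "variant table")
        if (self.data["pos"] < 1).any():
            raise FormatError("variant positions are 1-based; found pos < 1")


@dataclass(frozen=True)
class CpGSet:
    """Named set of CpG probe ids (e.g. an epigenetic-clock CpG list)."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise FormatError(f"set {self.name!r} has duplicate members")


@dataclass(frozen=True)
class GeneSet:
    """Named set of gene symbols."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise FormatError(f"set {self.name!r} has duplicate members")


@dataclass
class PairedView:
    """Per-probe (subjects x 2) view of a beta matrix.

    Subjects are sorted by id; ``t1``/``t2`` are probes x subjects arrays
    aligned to ``probe_ids`` and ``subject_ids``.  Subjects missing either
    time point are listed in ``excluded``.
    """

    probe_ids: pd.Index
    subject_ids: np.ndarray
    t1: np.ndarray
    t2: np.ndarray
    excluded: list[str] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.subject_ids)

    def pairs_for(self, probe_id: str) -> np.ndarray:
        """(n_subjects, 2) array for one probe, NaN where missing."""
        i = self.probe_ids.get_loc(probe_id)
        return np.column_stack([self.t1[i], self.t2[i]])


# ---------------------------------------------------------------------------
# readers / writers


def read_beta_matrix(path: str | Path, delimiter: str | None = None) -> BetaMatrix:
    sep = _detect_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for j, col in enumerate(df.columns):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise FormatError(
                f"non-numeric value at row {df.index[i]!r}, column {col!r}: {df[col].iloc[i]!r}"
            )
        df[col] = coerced
    return BetaMatrix(df)


def write_beta_matrix(
    beta: BetaMatrix, path: str | Path, delimiter: str | None = None, float_format: str = "%.10g"
) -> None:
    sep = _detect_delimiter(path, delimiter)
    beta.data.to_csv(path, sep=sep, index_label="probe_id", float_format=float_format)


def read_sample_sheet(path: str | Path, delimiter: str | None = None, paired: bool = True) -> SampleSheet:
    sep = _detect_delimiter(path, delimiter)
    df = _normalize_columns(pd.read_csv(path, sep=sep))
    _require_columns(df, SAMPLE_SHEET_REQUIRED, "sample sheet")
    df["sample_id"] = df["sample_id"].astype(str)
    df["subject_id"] = df["subject_id"].astype(str)
    sheet = SampleSheet(df)
    if paired:
        sheet.check_paired()
    return sheet


def write_sample_sheet(sheet: SampleSheet, path: str | Path, delimiter: str | None = None) -> None:
    sep = _detect_delimiter(path, delimiter)
    sheet.data.to_csv(path, sep=sep, index=False)


def read_probe_annotation(path: str | Path, delimiter: str | None = None) -> ProbeAnnotation:
    sep = _detect_delimiter(path, delimiter)
    df = _normalize_columns(pd.read_csv(path, sep=sep))
    _require_columns(df, ANNOTATION_REQUIRED, "probe annotation")
    df["probe_id"] = df["probe_id"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    df["pos"] = pd.to_numeric(df["pos"], errors="raise").astype(int)
    return ProbeAnnotation(df)


def write_probe_annotation(ann: ProbeAnnotation, path: str | Path, delimiter: str | None = None) -> None:
    sep = _detect_delimiter(path, delimiter)
    ann.data.to_csv(path, sep=sep, index=False)


def read_variant_table(
    path: str | Path, delimiter: str | None = None, bed_coords: bool = False
) -> VariantTable:
    """Read a variant table.

    With ``bed_coords=True`` the file is a 4-column BED-like TSV
    (chrom, start, end, name[:phenotype]) in 0-based half-open coordinates;
    start is converted to the 1-based position of the variant.
    """
    sep = _detect_delimiter(path, delimiter)
    if bed_coords:
        raw = pd.read_csv(path, sep=sep, header=None, comment="#")
        if raw.shape[1] < 4:
            raise FormatError("BED-like variant input needs 4 columns: chrom,start,end,name")
        name = raw.iloc[:, 3].astype(str)
        pheno = name.str.split(":").str[-1].where(name.str.contains(":"), "NA")
        df = pd.DataFrame(
            {
                "variant_id": name.str.split(":").str[0],
                "chrom": raw.iloc[:, 0].astype(str),
                "pos": raw.iloc[:, 1].astype(int) + 1,  # 0-based start -> 1-based
                "phenotype": pheno,
            }
        )
    else:
        df = _normalize_columns(pd.read_csv(path, sep=sep))
        _require_columns(df, VARIANT_REQUIRED, "variant table")
        df["pos"] = pd.to_numeric(df["pos"], errors="raise").astype(int)
    return VariantTable(df)


def read_sets(path: str | Path, kind: str = "cpg", delimiter: str | None = None) -> list:
    """Read CpG or gene sets from two-column long format or GMT.

    Long format: header ``set_name,member``.  GMT: one set per line,
    ``name<TAB>description<TAB>member...``; detected by '.gmt' extension.
    """
    cls = CpGSet if kind == "cpg" else GeneSet
    if Path(path).suffix.lower() == ".gmt":
        sets = []
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                members = tuple(dict.fromkeys(m for m in parts[2:] if m))
                sets.append(cls(parts[0], members))
        return sets
    sep = _detect_delimiter(path, delimiter)
    df = _normalize_columns(pd.read_csv(path, sep=sep))
    _require_columns(df, ("set_name", "member"), "set file")
    return [
        cls(str(name), tuple(dict.fromkeys(grp["member"].astype(str))))
        for name, grp in df.groupby("set_name", sort=True)
    ]


def write_sets(sets: Sequence, path: str | Path, delimiter: str | None = None) -> None:
    sep = _detect_delimiter(path, delimiter)
    rows = [(s.name, m) for s in sets for m in s.members]
    pd.DataFrame(rows, columns=["set_name", "member"]).to_csv(path, sep=sep, index=False)


def align_pairs(beta: BetaMatrix, sheet: SampleSheet) -> PairedView:
    """Arrange the beta matrix as (subjects x 2) per probe.

    Subjects with both time points present as beta columns are kept in
    sorted subject-id order; incomplete subjects are dropped with a warning
    and listed in ``excluded``.  Raises when no complete pair remains.
    """
    sheet.check_paired()
    have = set(map(str, beta.sample_ids))
    kept, excluded = [], []
    for subj in sheet.subjects:
        s1 = sheet.sample_for(subj, "T1")
        s2 = sheet.sample_for(subj, "T2")
        if s1 in have and s2 in have:
            kept.append((subj, s1, s2))
        else:
            excluded.append(str(subj))
    if not kept:
        raise FormatError("no subject has both time points present in the beta matrix")
    if excluded:
        warnings.warn(
            f"dropping {len(excluded)} subject(s) missing a time point: {excluded}",
            stacklevel=2,
        )
        logger.warning("align_pairs: excluded subjects %s", excluded)
    subjects = np.array([k[0] for k in kept])
    t1 = beta.data[[k[1] for k in kept]].to_numpy()
    t2 = beta.data[[k[2] for k in kept]].to_numpy()
    return PairedView(beta.probe_ids, subjects, t1, t2, excluded)
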