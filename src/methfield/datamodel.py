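"""Core domain types and TSV/BED readers for the methylation pipeline.

Conventions
-----------
* Beta matrices are probe x sample tables of methylation fractions in [0, 1];
  missing values (masked probes) are NaN and propagate pairwise-complete
  through downstream statistics.
* Manifest CpG positions are 1-based (Illumina convention).
* BED segments are 0-based half-open (BED standard).  The two coordinate
  systems meet in exactly one place, :func:`methfield.enrichment.assign_cpgs_to_segments`;
  nothing else converts coordinates.
* Strand is ignored throughout: CpGs are point queries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TISSUE_CLASSES = ("cancer", "normal_adjacent", "normal_distant")
ISLAND_RELATIONS = ("island", "shore", "shelf", "open_sea")
EAU_RISK_LEVELS = ("intermediate", "high")

#: Accepted manifest spellings for CpG island relation, normalized to the
#: four-level vocabulary used throughout.
_ISLAND_ALIASES = {
    "island": "island",
    "n_shore": "shore",
    "s_shore": "shore",
    "shore": "shore",
    "n_shelf": "shelf",
    "s_shelf": "shelf",
    "shelf": "shelf",
    "opensea": "open_sea",
    "open_sea": "open_sea",
    "none": "open_sea",
}


class DataModelError(ValueError):
    """Raised for malformed or inconsistent input tables."""


@dataclass
class BetaMatrix:
    """A CpG x sample matrix of methylation beta values.

    Parameters
    ----------
    df
        DataFrame indexed by probe id with one column per sample id.
        Values must lie in [0, 1] or be NaN (masked).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.df.shape[0] == 0:
            raise DataModelError("no probes in beta matrix")
        if self.df.index.duplicated().any():
            dups = self.df.index[self.df.index.duplicated()].tolist()[:5]
            raise DataModelError(f"duplicate probe ids: {dups}")
        if self.df.columns.duplicated().any():
            dups = self.df.columns[self.df.columns.duplicated()].tolist()[:5]
            raise DataModelError(f"duplicate sample ids: {dups}")
        vals = self.df.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = np.nansum((vals < 0) | (vals > 1))
        if bad:
            raise DataModelError(f"{int(bad)} beta values outside [0, 1]")
        self.df = self.df.astype(float)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.df.shape

    def subset_probes(self, probe_ids) -> "BetaMatrix":
        return BetaMatrix(self.df.loc[list(probe_ids)])

    def subset_samples(self, sample_ids) -> "BetaMatrix":
        return BetaMatrix(self.df[list(sample_ids)])

    def write_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index_label="probe_id", float_format="%.10g")

    @classmethod
    def read_tsv(cls, path) -> "BetaMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.shape[0] == 0:
            raise DataModelError(f"no probes in beta file {path}")
        return cls(df)


def validate_sample_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample sheet (sample_id, patient_id, tissue_class, cancer_area_pct)."""
    required = {"sample_id", "patient_id", "tissue_class"}
    missing = required - set(df.columns)
    if missing:
        raise DataModelError(f"sample sheet missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise DataModelError("duplicate sample ids in sample sheet")
    bad = sorted(set(df["tissue_class"]) - set(TISSUE_CLASSES))
    if bad:
        raise DataModelError(
            f"unknown tissue_class value(s) {bad}; allowed: {list(TISSUE_CLASSES)}"
        )
    df = df.copy()
    if "cancer_area_pct" not in df.columns:
        df["cancer_area_pct"] = np.where(df["tissue_class"] == "cancer", np.nan, 0.0)
    pct = df["cancer_area_pct"].astype(float)
    if ((pct < 0) | (pct > 100)).any():
        raise DataModelError("cancer_area_pct outside [0, 100]")
    nonzero_normal = (df["tissue_class"] != "cancer") & (pct.fillna(0) > 0)
    if nonzero_normal.any():
        raise DataModelError("normal samples must have cancer_area_pct 0")
    return df.reset_index(drop=True)


def validate_patient_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate patient-level outcomes.

    Enforces that metastasis implies recurrence and that a recurrence-free
    interval is present iff the patient recurred.
    """
    required = {"patient_id", "recurrence", "metastasis", "followup_years"}
    missing = required - set(df.columns)
    if missing:
        raise DataModelError(f"patient table missing columns: {sorted(missing)}")
    if df["patient_id"].duplicated().any():
        raise DataModelError("duplicate patient ids")
    df = df.copy()
    for col in ("recurrence", "metastasis"):
        df[col] = df[col].astype(bool)
    if (df["metastasis"] & ~df["recurrence"]).any():
        raise DataModelError("metastasis without recurrence is inconsistent")
    if "recurrence_free_interval_months" in df.columns:
        rfi = df["recurrence_free_interval_months"].astype(float)
        if (df["recurrence"] & rfi.isna()).any():
            raise DataModelError("recurrence patients need a recurrence-free interval")
        if (~df["recurrence"] & rfi.notna()).any():
            raise DataModelError("non-recurrence patients must not have an interval")
        if (rfi.dropna() < 0).any():
            raise DataModelError("negative recurrence-free interval")
    if "eau_risk" in df.columns:
        bad = sorted(set(df["eau_risk"].dropna()) - set(EAU_RISK_LEVELS))
        if bad:
            raise DataModelError(f"unknown eau_risk level(s) {bad}")
    return df.reset_index(drop=True)


def read_dataset(beta_path, sample_sheet_path, patient_table_path):
    """Read and cross-reference the beta matrix, sample sheet and patient table.

    Returns
    -------
    (BetaMatrix, sample table DataFrame, patient table DataFrame)
        Samples are guaranteed to map to exactly one known patient and to be
        present in the beta matrix.
    """
    beta = BetaMatrix.read_tsv(beta_path)
    samples = validate_sample_table(pd.read_csv(sample_sheet_path, sep="\t"))
    patients = validate_patient_table(pd.read_csv(patient_table_path, sep="\t"))
    missing = sorted(set(samples["sample_id"]) - set(beta.sample_ids))
    if missing:
        raise DataModelError(f"samples in sheet absent from beta matrix: {missing}")
    unknown = sorted(set(samples["patient_id"]) - set(patients["patient_id"]))
    if unknown:
        raise DataModelError(f"samples reference unknown patients: {unknown}")
    return beta, samples, patients


def normalize_island_relation(raw: str) -> str:
    key = str(raw).strip().lower()
    if key not in _ISLAND_ALIASES:
        raise DataModelError(
            f"unknown island relation {raw!r}; expected one of {list(ISLAND_RELATIONS)}"
        )
    return _ISLAND_ALIASES[key]


def read_manifest(path) -> pd.DataFrame:
    """Read a per-probe manifest TSV into an annotation table.

    Expected columns: probe_id, chrom, pos (1-based), gene_symbols
    (';'-separated, possibly empty), island_relation, bead_count,
    detection_p, snp_distance_bp.  Row order is preserved.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return validate_manifest(df)


def validate_manifest(df: pd.DataFrame) -> pd.DataFrame:
    required = {"probe_id", "chrom", "pos", "island_relation"}
    missing = required - set(df.columns)
    if missing:
        raise DataModelError(f"manifest missing columns: {sorted(missing)}")
    df = df.copy()
    pos = pd.to_numeric(df["pos"], errors="coerce")
    if pos.isna().any():
        bad = df.loc[pos.isna(), "probe_id"].tolist()[:5]
        raise DataModelError(f"non-numeric position for probes {bad}")
    if (pos < 1).any():
        bad = df.loc[pos < 1, "probe_id"].tolist()[:5]
        raise DataModelError(f"positions must be 1-based (>= 1); offending probes {bad}")
    df["pos"] = pos.astype(int)
    df["island_relation"] = [normalize_island_relation(v) for v in df["island_relation"]]
    if "gene_symbols" not in df.columns:
        df["gene_symbols"] = ""
    df["gene_symbols"] = df["gene_symbols"].fillna("")
    if "detection_p" in df.columns:
        p = df["detection_p"].astype(float)
        if ((p < 0) | (p > 1)).any():
            raise DataModelError("detection_p outside [0, 1]")
    if "snp_distance_bp" in df.columns:
        # infinity encodes "no SNP anywhere near the probe"
        d = df["snp_distance_bp"].astype(float)
        if (d.dropna() < 0).any():
            raise DataModelError("negative snp_distance_bp")
    return df.reset_index(drop=True)


def read_bed(path, label_column: int = 3) -> pd.DataFrame:
    """Read a BED3+ file into a segment table (chrom, start, end, label).

    Coordinates are parsed verbatim: 0-based half-open, never shifted.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] <= label_column:
        raise DataModelError(
            f"BED file has {df.shape[1]} columns; label column {label_column} missing"
        )
    out = df.iloc[:, [0, 1, 2, label_column]].copy()
    out.columns = ["chrom", "start", "end", "label"]
    out["start"] = out["start"].astype(int)
    out["end"] = out["end"].astype(int)
    return validate_track(out, require_tiling=False)


def validate_track(df: pd.DataFrame, require_tiling: bool = False) -> pd.DataFrame:
    if (df["start"] < 0).any():
        raise DataModelError("negative segment start")
    empty = df["start"] >= df["end"]
    if empty.any():
        row = df[empty].iloc[0]
        raise DataModelError(
            f"empty segment {row['chrom']}:[{row['start']},{row['end']})"
        )
    if require_tiling:
        for chrom, grp in df.groupby("chrom", sort=False):
            g = grp.sort_values("start")
            if (g["start"].to_numpy()[1:] != g["end"].to_numpy()[:-1]).any():
                raise DataModelError(f"track does not tile chromosome {chrom}")
    return df.reset_index(drop=True)


def write_bed(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end", "label"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def validate_survival(df: pd.DataFrame) -> pd.DataFrame:
    """Validate survival records (unit_id, time_months, event)."""
    required = {"unit_id", "time_months", "event"}
    missing = required - set(df.columns)
    if missing:
        raise DataModelError(f"survival table missing columns: {sorted(missing)}")
    df = df.copy()
    df["time_months"] = df["time_months"].astype(float)
    df["event"] = df["event"].astype(bool)
    if (df["time_months"] <= 0).any():
        raise DataModelError("non-positive survival time")
    return df.reset_index(drop=True)


@dataclass
class Cohort:
    """A fully cross-referenced cohort bundle (convenience container)."""

    beta: BetaMatrix
    samples: pd.DataFrame
    patients: pd.DataFrame
    annotation: pd.DataFrame = field(default=None)

    def sample_patients(self) -> pd.Series:
        """sample_id -> patient_id, ordered like the beta matrix columns."""
        mapping = self.samples.set_index("sample_id")["patient_id"]
        return mapping.loc[self.beta.sample_ids]
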