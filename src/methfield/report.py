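"""Cohort summary table and heatmap-ready matrix construction."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .datamodel import BetaMatrix

_NUMERIC_VARS = ("age_years", "psa_ng_ml", "recurrence_free_interval_months")
_CATEGORICAL_VARS = ("eau_risk", "isup_grade", "pt_stage", "metastasis")
_GROUPS = ("non_recurrence", "recurrence", "total")


@dataclass
class CohortSummary:
    """Patient characteristics split by recurrence status.

    ``numeric`` holds median and IQR (25th/75th percentile, linear
    interpolation) per variable and group; ``categorical`` holds counts and
    percentages per level, computed on non-missing denominators and rounded
    to one decimal; ``missing`` counts excluded records.
    """

    numeric: pd.DataFrame  # variable, stat, group, value
    categorical: pd.DataFrame  # variable, level, group, count, percent
    missing: pd.DataFrame  # variable, group, n_missing
    n_patients: dict

    def percent(self, variable: str, level, group: str) -> float:
        m = (
            (self.categorical["variable"] == variable)
            & (self.categorical["level"].astype(str) == str(level))
            & (self.categorical["group"] == group)
        )
        if not m.any():
            return 0.0
        return float(self.categorical.loc[m, "percent"].iloc[0])


def cohort_summary(patients: pd.DataFrame) -> CohortSummary:
    """Summarize patient characteristics by recurrence group.

    Percentages use non-missing denominators within each group; numeric
    variables report median and IQR.
    """
    if len(patients) == 0:
        raise ValueError("empty patient table")
    groups = {
        "non_recurrence": patients[~patients["recurrence"].astype(bool)],
        "recurrence": patients[patients["recurrence"].astype(bool)],
        "total": patients,
    }
    num_rows, cat_rows, miss_rows = [], [], []
    for var in _NUMERIC_VARS:
        if var not in patients.columns:
            continue
        for gname, g in groups.items():
            vals = g[var].dropna().astype(float)
            miss_rows.append((var, gname, int(g[var].isna().sum())))
            if len(vals) == 0:
                continue
            q25, med, q75 = np.percentile(vals, [25, 50, 75])
            num_rows += [
                (var, "median", gname, float(med)),
                (var, "q25", gname, float(q25)),
                (var, "q75", gname, float(q75)),
            ]
    for var in _CATEGORICAL_VARS:
        if var not in patients.columns:
            continue
        levels = sorted(patients[var].dropna().unique(), key=str)
        for gname, g in groups.items():
            nonmiss = g[var].dropna()
            miss_rows.append((var, gname, int(g[var].isna().sum())))
            denom = len(nonmiss)
            for level in levels:
                count = int((nonmiss == level).sum())
                pct = round(100.0 * count / denom, 1) if denom else 0.0
                cat_rows.append((var, level, gname, count, pct))
    return CohortSummary(
        numeric=pd.DataFrame(num_rows, columns=["variable", "stat", "group", "value"]),
        categorical=pd.DataFrame(
            cat_rows, columns=["variable", "level", "group", "count", "percent"]
        ),
        missing=pd.DataFrame(miss_rows, columns=["variable", "group", "n_missing"]),
        n_patients={g: len(df) for g, df in groups.items()},
    )


def heatmap_matrix(
    beta: BetaMatrix,
    samples: pd.DataFrame,
    patients: pd.DataFrame,
    cpg_set,
    row_order: str = "cluster",
    col_order: str = "cluster",
):
    """Ordered DMC x sample matrix plus sample annotations, heatmap-ready.

    ``row_order``/``col_order`` are 'cluster' (average-linkage hierarchical
    clustering on Euclidean distance) or 'given' (input order preserved).
    Returns (ordered DataFrame, annotation DataFrame with tissue class and
    outcome labels per sample, in matrix column order).
    """
    cpg_set = list(cpg_set)
    if not cpg_set:
        raise ValueError("empty CpG set")
    mat = beta.df.loc[cpg_set]

    def order(df, axis):
        data = df.to_numpy() if axis == 0 else df.to_numpy().T
        if data.shape[0] < 3:
            return np.arange(data.shape[0])
        return leaves_list(linkage(pdist(data, metric="euclidean"), method="average"))

    if row_order == "cluster":
        mat = mat.iloc[order(mat, 0)]
    elif row_order != "given":
        raise ValueError("row_order must be 'cluster' or 'given'")
    if col_order == "cluster":
        mat = mat.iloc[:, order(mat, 1)]
    elif col_order != "given":
        raise ValueError("col_order must be 'cluster' or 'given'")

    info = samples.set_index("sample_id").loc[mat.columns]
    pat = patients.set_index("patient_id")
    ann = pd.DataFrame(
        {
            "sample_id": mat.columns,
            "patient_id": info["patient_id"].to_numpy(),
            "tissue_class": info["tissue_class"].to_numpy(),
            "recurrence": pat.loc[info["patient_id"], "recurrence"].to_numpy(),
            "metastasis": pat.loc[info["patient_id"], "metastasis"].to_numpy(),
        }
    )
    return mat, ann


def plot_heatmap(mat: pd.DataFrame, ann: pd.DataFrame, path) -> None:
    """Basic clustered-heatmap PNG with outcome/tissue annotation bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax_ann, ax) = plt.subplots(
        2, 1, figsize=(max(6, mat.shape[1] * 0.18), max(4, mat.shape[0] * 0.12 + 1)),
        gridspec_kw={"height_ratios": [1, 10]}, sharex=True,
    )
    rec = ann["recurrence"].astype(int).to_numpy()[None, :]
    tis = ann["tissue_class"].map(
        {"cancer": 2, "normal_adjacent": 1, "normal_distant": 0}
    ).to_numpy()[None, :]
    ax_ann.imshow(np.vstack([rec, tis]), aspect="auto", cmap="coolwarm")
    ax_ann.set_yticks([0, 1], ["recurrence", "tissue"])
    ax_ann.set_xticks([])
    im = ax.imshow(mat.to_numpy(), aspect="auto", cmap="RdYlBu_r", vmin=0, vmax=1)
    ax.set_xlabel("samples")
    ax.set_ylabel(f"{mat.shape[0]} CpGs")
    fig.colorbar(im, ax=ax, label="beta value", shrink=0.6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
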