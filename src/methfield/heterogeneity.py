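"""Intra- and interpatient methylation heterogeneity.

Two complementary views of tissue heterogeneity across multi-sample
patients:

* variability — the coefficient of variation (CV), computed between
  patients (one random sample per patient, averaged over resampling
  iterations) and within patients (all samples of each patient);
* similarity — Spearman correlation of methylation profiles within tissue
  types of one patient, and between a patient's mean cancer and mean
  normal profiles.

Each quantity computed for a CpG set of interest (e.g. the DMCs) has a
size-matched null built from random CpG draws over the filtered array,
averaged per position over iterations.  Distributions are compared with
the two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import BetaMatrix
from .stats import spearman_rho, wilcoxon_rank_sum

_NORMAL_CLASSES = ("normal_adjacent", "normal_distant")


def _patient_columns(samples: pd.DataFrame, sample_ids) -> dict[str, list[str]]:
    info = samples.set_index("sample_id").loc[list(sample_ids)]
    return {p: list(g.index) for p, g in info.groupby("patient_id", sort=True)}


def _cv_rows(values: np.ndarray) -> np.ndarray:
    """Row-wise sample CV (n-1 denominator); NaN-aware, NaN when mean is 0."""
    mean = np.nanmean(values, axis=1)
    sd = np.nanstd(values, axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(mean == 0, np.nan, sd / mean)


def interpatient_cv(
    beta: BetaMatrix, samples: pd.DataFrame, cpg_set, n_iter: int = 10, seed: int = 0
) -> pd.Series:
    """Between-patient CV per CpG, averaged over resampling iterations.

    Each iteration draws one sample per patient uniformly at random (all
    tissue classes eligible) and computes one CV per CpG across the drawn
    values; the mean over ``n_iter`` iterations is returned.
    """
    cpg_set = list(cpg_set)
    if not cpg_set:
        raise ValueError("empty CpG set")
    rng = np.random.default_rng(seed)
    by_patient = _patient_columns(samples, beta.sample_ids)
    sub = beta.df.loc[cpg_set]
    acc = np.zeros(len(cpg_set))
    for _ in range(n_iter):
        chosen = [cols[rng.integers(len(cols))] for cols in by_patient.values()]
        acc += _cv_rows(sub[chosen].to_numpy())
    return pd.Series(acc / n_iter, index=cpg_set, name="interpatient_cv")


def intrapatient_cv(beta: BetaMatrix, samples: pd.DataFrame, cpg_set) -> pd.DataFrame:
    """Within-patient CV per (patient, CpG), using all of a patient's samples.

    Patients with a single sample cannot contribute and are listed in
    ``result.attrs['skipped']``.  Returns a CpG x patient table.
    """
    cpg_set = list(cpg_set)
    if not cpg_set:
        raise ValueError("empty CpG set")
    by_patient = _patient_columns(samples, beta.sample_ids)
    sub = beta.df.loc[cpg_set]
    out = {}
    skipped = []
    for pid, cols in by_patient.items():
        if len(cols) < 2:
            skipped.append(pid)
            continue
        out[pid] = _cv_rows(sub[cols].to_numpy())
    res = pd.DataFrame(out, index=cpg_set)
    res.attrs["skipped"] = skipped
    return res


def matched_null_cv(
    beta: BetaMatrix, samples: pd.DataFrame, set_size: int, n_iter: int = 10, seed: int = 0
) -> dict:
    """Size-matched random-CpG null for the inter- and intrapatient CV.

    Per iteration a sorted draw of ``set_size`` CpGs (uniform, without
    replacement) is scored exactly like a DMC set; values are averaged
    per position over iterations.  Returns ``{"inter": Series,
    "intra": DataFrame, "n_iter": int}`` with positional indices.
    """
    probes = beta.probe_ids
    if set_size > len(probes):
        raise ValueError(f"set_size {set_size} exceeds universe {len(probes)}")
    rng = np.random.default_rng(seed)
    inter_acc = np.zeros(set_size)
    intra_acc = None
    patients = None
    for _ in range(n_iter):
        idx = np.sort(rng.choice(len(probes), size=set_size, replace=False))
        chosen = [probes[i] for i in idx]
        inter_acc += interpatient_cv(
            beta, samples, chosen, n_iter=1, seed=int(rng.integers(2**31))
        ).to_numpy()
        intra = intrapatient_cv(beta, samples, chosen)
        if intra_acc is None:
            intra_acc = intra.to_numpy()
            patients = list(intra.columns)
        else:
            intra_acc += intra.to_numpy()
    inter = pd.Series(inter_acc / n_iter, index=pd.RangeIndex(set_size), name="null_interpatient_cv")
    intra = pd.DataFrame(intra_acc / n_iter, columns=patients, index=pd.RangeIndex(set_size))
    return {"inter": inter, "intra": intra, "n_iter": n_iter}


def compare_cv(dmc_cvs, null_cvs) -> float:
    """Two-sided Wilcoxon rank-sum p comparing two CV distributions."""
    a = np.asarray(dmc_cvs, dtype=float).ravel()
    b = np.asarray(null_cvs, dtype=float).ravel()
    _, p = wilcoxon_rank_sum(a[~np.isnan(a)], b[~np.isnan(b)])
    return p


@dataclass
class CVReport:
    """All CV distributions for one DMC set plus its matched null."""

    dmc_inter: pd.Series
    dmc_intra: pd.DataFrame
    null_inter: pd.Series
    null_intra: pd.DataFrame
    p_inter_vs_null: float
    p_intra_vs_null: float
    p_intra_vs_inter: float
    medians: dict
    n_iter: int


def cv_report(
    beta: BetaMatrix, samples: pd.DataFrame, cpg_set, n_iter: int = 10, seed: int = 0
) -> CVReport:
    """Full CV heterogeneity analysis of a CpG set against a matched null."""
    cpg_set = list(cpg_set)
    dmc_inter = interpatient_cv(beta, samples, cpg_set, n_iter=n_iter, seed=seed)
    dmc_intra = intrapatient_cv(beta, samples, cpg_set)
    null = matched_null_cv(beta, samples, set_size=len(cpg_set), n_iter=n_iter, seed=seed + 1)
    medians = {
        "dmc_inter": float(dmc_inter.median()),
        "dmc_intra": float(np.nanmedian(dmc_intra.to_numpy())),
        "null_inter": float(null["inter"].median()),
        "null_intra": float(np.nanmedian(null["intra"].to_numpy())),
    }
    return CVReport(
        dmc_inter=dmc_inter,
        dmc_intra=dmc_intra,
        null_inter=null["inter"],
        null_intra=null["intra"],
        p_inter_vs_null=compare_cv(dmc_inter, null["inter"]),
        p_intra_vs_null=compare_cv(dmc_intra.to_numpy(), null["intra"].to_numpy()),
        p_intra_vs_inter=compare_cv(dmc_intra.to_numpy(), dmc_inter),
        medians=medians,
        n_iter=n_iter,
    )


# ---------------------------------------------------------------------------
# similarity (correlation)
# ---------------------------------------------------------------------------

def _choose_pairs(samples: pd.DataFrame, sample_ids, rng, pool_normal: bool = True):
    """Per patient and tissue type, the (up to) two samples used for the
    within-type correlation: both if exactly two, a seeded uniform draw of
    two if more, None if fewer."""
    info = samples.set_index("sample_id").loc[list(sample_ids)]
    types = {"cancer": ("cancer",)}
    if pool_normal:
        types["normal"] = _NORMAL_CLASSES
    else:
        types["normal_adjacent"] = ("normal_adjacent",)
        types["normal_distant"] = ("normal_distant",)
    pairs = {}
    for pid, grp in info.groupby("patient_id", sort=True):
        entry = {}
        for tname, classes in types.items():
            ids = list(grp.index[grp["tissue_class"].isin(classes)])
            if len(ids) < 2:
                entry[tname] = None
            elif len(ids) == 2:
                entry[tname] = tuple(ids)
            else:
                pick = rng.choice(len(ids), size=2, replace=False)
                entry[tname] = (ids[pick[0]], ids[pick[1]])
        # all samples per class, for the mean cancer-vs-normal profile
        entry["_cancer_all"] = list(grp.index[grp["tissue_class"] == "cancer"])
        entry["_normal_all"] = list(grp.index[grp["tissue_class"].isin(_NORMAL_CLASSES)])
        pairs[pid] = entry
    return pairs


def _correlations_for_set(beta: BetaMatrix, pairs: dict, cpg_set) -> pd.DataFrame:
    sub = beta.df.loc[list(cpg_set)]
    rows = []
    for pid, entry in pairs.items():
        row = {"patient_id": pid}
        for tname, pair in entry.items():
            if tname.startswith("_"):
                continue
            if pair is None:
                row[f"rho_{tname}"] = np.nan
            else:
                row[f"rho_{tname}"] = spearman_rho(
                    sub[pair[0]].to_numpy(), sub[pair[1]].to_numpy()
                )
        ca, na = entry["_cancer_all"], entry["_normal_all"]
        if ca and na:
            row["rho_cancer_vs_normal"] = spearman_rho(
                sub[ca].mean(axis=1).to_numpy(), sub[na].mean(axis=1).to_numpy()
            )
        else:
            row["rho_cancer_vs_normal"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("patient_id")


def intrapatient_correlation(
    beta: BetaMatrix, samples: pd.DataFrame, cpg_set, seed: int = 0,
    pool_normal: bool = True,
) -> pd.DataFrame:
    """Within-patient profile similarity over a CpG set.

    Per patient: Spearman rho between two samples of each tissue type
    (cancer; normal = adjacent + distant pooled unless ``pool_normal`` is
    False), NaN with fewer than two samples of the type, a seeded uniform
    two-sample draw with more; plus rho between the patient's mean cancer
    and mean normal profiles.
    """
    cpg_set = list(cpg_set)
    if len(cpg_set) < 3:
        raise ValueError("need at least 3 CpGs for profile correlation")
    rng = np.random.default_rng(seed)
    pairs = _choose_pairs(samples, beta.sample_ids, rng, pool_normal=pool_normal)
    return _correlations_for_set(beta, pairs, cpg_set)


def matched_null_correlation(
    beta: BetaMatrix, samples: pd.DataFrame, set_size: int = 37, n_iter: int = 100,
    seed: int = 0, pool_normal: bool = True,
) -> pd.DataFrame:
    """Per-patient mean correlation over random size-matched CpG sets.

    The two samples used per patient and tissue type are drawn once per run
    (seeded) and held fixed across the ``n_iter`` random CpG draws.
    """
    probes = beta.probe_ids
    if set_size > len(probes):
        raise ValueError(f"set_size {set_size} exceeds universe {len(probes)}")
    rng = np.random.default_rng(seed)
    pairs = _choose_pairs(samples, beta.sample_ids, rng, pool_normal=pool_normal)
    acc = None
    for _ in range(n_iter):
        idx = np.sort(rng.choice(len(probes), size=set_size, replace=False))
        res = _correlations_for_set(beta, pairs, [probes[i] for i in idx])
        acc = res if acc is None else acc + res
    return acc / n_iter
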