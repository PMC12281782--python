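"""Patient-aware differential methylation and expression testing.

The group test follows the array-world consensus-correlation scheme: a
single within-patient (compound-symmetry) correlation is estimated by
pooling per-feature moment estimates on the variance-stabilized atanh
scale, and each feature is then tested by generalized least squares with a
block compound-symmetry covariance and a Wald test on the group
coefficient.  With one sample per patient and consensus correlation zero
this reduces exactly to the ordinary two-sample linear-model t-test.
Per-feature maximum-likelihood mixed models would be unstable with 5-11
patients per group, which is why the consensus approximation is the
default in this setting.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datamodel import BetaMatrix
from .stats import benjamini_hochberg


def _logit(p, eps=1e-6):
    p = np.clip(p, eps, 1 - eps)
    return np.log(p / (1.0 - p))


def _impute_row_mean(Y: np.ndarray) -> np.ndarray:
    """Replace masked values by the probe's own mean (test design matrices
    cannot carry per-feature missingness patterns in the vectorized GLS)."""
    if not np.isnan(Y).any():
        return Y
    Y = Y.copy()
    row_mean = np.nanmean(Y, axis=1)
    rows, cols = np.nonzero(np.isnan(Y))
    Y[rows, cols] = row_mean[rows]
    return Y


def consensus_correlation(Y: np.ndarray, X: np.ndarray, patient: np.ndarray) -> float:
    """Pooled within-patient correlation of model residuals.

    Per feature (row of ``Y``), residuals from the OLS fit on ``X`` are
    decomposed by one-way ANOVA over patients into between- and
    within-patient mean squares; the method-of-moments intraclass
    correlation is pooled across features via mean atanh.
    Patients contribute only with two or more samples.
    """
    n = Y.shape[1]
    H = X @ np.linalg.solve(X.T @ X, X.T)
    R = Y - Y @ H.T  # residuals, features x samples
    pats, counts = np.unique(patient, return_counts=True)
    keep = counts >= 2
    if not keep.any() or len(pats[keep]) < 2:
        return 0.0
    pats, counts = pats[keep], counts[keep]
    G = np.stack([(patient == p).astype(float) for p in pats], axis=1)  # n x npat
    mask = G.sum(axis=1) > 0
    Rk = R[:, mask]
    Gk = G[mask]
    nk = Gk.sum(axis=0)
    N = Rk.shape[1]
    means = (Rk @ Gk) / nk  # features x npat
    grand = Rk.mean(axis=1, keepdims=True)
    ssb = (nk * (means - grand) ** 2).sum(axis=1)
    ssw = (Rk**2).sum(axis=1) - (nk * means**2).sum(axis=1)
    df_b = len(pats) - 1
    df_w = N - len(pats)
    if df_w <= 0:
        return 0.0
    msb = ssb / df_b
    msw = np.maximum(ssw / df_w, 1e-12)
    k0 = (N - (nk**2).sum() / N) / df_b
    icc = (msb - msw) / (msb + (k0 - 1) * msw)
    icc = np.clip(icc, -0.95, 0.95)
    return float(np.tanh(np.arctanh(icc).mean()))


def _cs_whiten(patient: np.ndarray, rho: float) -> np.ndarray:
    """Whitening matrix W with W Sigma W' = I for block compound symmetry.

    Within a patient block of size k the transform is
    (y - theta * mean(y)) / sqrt(1 - rho) with
    theta = 1 - sqrt((1 - rho) / (1 + (k - 1) rho)).
    """
    n = patient.size
    W = np.zeros((n, n))
    for p in np.unique(patient):
        idx = np.flatnonzero(patient == p)
        k = idx.size
        theta = 1.0 - math.sqrt((1.0 - rho) / (1.0 + (k - 1) * rho))
        block = (np.eye(k) - theta / k * np.ones((k, k))) / math.sqrt(1.0 - rho)
        W[np.ix_(idx, idx)] = block
    return W


def _gls_group_test(Y: np.ndarray, group: np.ndarray, patient: np.ndarray):
    """Per-feature GLS Wald test of a binary group effect with a consensus
    compound-symmetry within-patient correlation.

    Returns (effect, p, rho, df).  Features with zero residual variance get
    NaN p (undefined), flagged rather than dropped.
    """
    n = Y.shape[1]
    X = np.column_stack([np.ones(n), group.astype(float)])
    rho = consensus_correlation(Y, X, patient)
    rho = max(min(rho, 0.99), -0.49)  # keep the block covariance positive definite
    W = _cs_whiten(patient, rho)
    Xw = W @ X
    Yw = Y @ W.T
    XtX_inv = np.linalg.inv(Xw.T @ Xw)
    B = Yw @ Xw @ XtX_inv  # features x 2
    resid = Yw - B @ Xw.T
    df = n - 2
    s2 = (resid**2).sum(axis=1) / df
    se = np.sqrt(s2 * XtX_inv[1, 1])
    effect = B[:, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, effect / se, np.nan)
    p = 2.0 * sps.t.sf(np.abs(t), df)
    return effect, p, rho, df


def _prepare_outcome(samples: pd.DataFrame, patients: pd.DataFrame, outcome: str,
                     sample_ids) -> tuple[np.ndarray, np.ndarray]:
    if outcome not in ("recurrence", "metastasis"):
        raise ValueError("outcome must be 'recurrence' or 'metastasis'")
    info = samples.set_index("sample_id").loc[list(sample_ids)]
    pat_outcome = patients.set_index("patient_id")[outcome]
    missing = set(info["patient_id"]) - set(pat_outcome.index)
    if missing:
        raise ValueError(f"samples reference patients without outcome: {sorted(missing)}")
    group = pat_outcome.loc[info["patient_id"]].to_numpy().astype(bool)
    patient = info["patient_id"].to_numpy()
    # outcome is patient-level: a patient may not straddle both groups
    for pid in np.unique(patient):
        if np.unique(group[patient == pid]).size > 1:
            raise ValueError(f"patient {pid} has samples in both outcome groups")
    n_pat_per_group = pd.Series(group, index=patient).groupby(level=0).first().value_counts()
    if (n_pat_per_group < 2).any() or n_pat_per_group.size < 2:
        raise ValueError("need at least 2 patients per outcome group")
    return group, patient


def _assoc_table(feature_ids, effect, p) -> pd.DataFrame:
    q = benjamini_hochberg(p)
    out = pd.DataFrame({"feature_id": list(feature_ids), "effect": effect, "p": p, "q": q})
    order = np.argsort(np.where(np.isnan(p), np.inf, p), kind="mergesort")
    rank = np.empty(len(out), dtype=int)
    rank[order] = np.arange(1, len(out) + 1)
    out["rank"] = rank
    return out


def mixed_group_test(
    beta: BetaMatrix,
    samples: pd.DataFrame,
    patients: pd.DataFrame,
    outcome: str = "recurrence",
    use_m_values: bool = False,
) -> pd.DataFrame:
    """Patient-aware two-group differential methylation test.

    Tests every CpG for a difference between all samples of outcome-positive
    patients and all samples of outcome-negative patients, accounting for
    within-patient correlation (consensus compound-symmetry GLS).  The
    reported effect is always the modeled group difference on the beta
    scale; ``use_m_values`` switches the *test* to the logit (M-value)
    scale.  Returns a table with feature_id, effect, p, q (BH) and rank.
    """
    group, patient = _prepare_outcome(samples, patients, outcome, beta.sample_ids)
    Y = _impute_row_mean(beta.values)
    Y_test = _logit(Y) if use_m_values else Y
    effect_scale, p, rho, df = _gls_group_test(Y_test, group, patient)
    if use_m_values:
        effect_beta, _, _, _ = _gls_group_test(Y, group, patient)
    else:
        effect_beta = effect_scale
    out = _assoc_table(beta.probe_ids, effect_beta, p)
    out.attrs["consensus_correlation"] = rho
    out.attrs["df"] = df
    out.attrs["scale"] = "m_value" if use_m_values else "beta"
    return out


def rank_overlap(stats_a: pd.DataFrame, stats_b: pd.DataFrame, top_fraction: float):
    """Overlap of the top-ranked features of two result lists.

    Takes the floor(top_fraction * n) best-ranked features from each list
    over a shared feature universe; returns (overlap count, overlap
    fraction of the top-list size).
    """
    if not (0 < top_fraction <= 1):
        raise ValueError("top_fraction must be in (0, 1]")
    ua = set(stats_a["feature_id"])
    ub = set(stats_b["feature_id"])
    if ua != ub:
        raise ValueError("result lists cover different feature universes")
    k = int(math.floor(len(ua) * top_fraction + 1e-9))
    top_a = set(stats_a.nsmallest(k, "rank")["feature_id"])
    top_b = set(stats_b.nsmallest(k, "rank")["feature_id"])
    overlap = len(top_a & top_b)
    return overlap, overlap / k if k else float("nan")


def log_cpm(counts: pd.DataFrame, prior_count: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million with a prior count."""
    libsize = counts.sum(axis=0).astype(float)
    if (libsize == 0).any():
        bad = list(libsize.index[libsize == 0])[:5]
        raise ValueError(f"library size 0 for sample(s) {bad}")
    return np.log2((counts + prior_count).div(libsize + 2 * prior_count, axis=1) * 1e6)


def de_mixed_test(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    patients: pd.DataFrame,
    grouping: str = "outcome",
    outcome: str = "recurrence",
) -> pd.DataFrame:
    """Patient-aware differential expression on log-CPM.

    ``grouping='outcome'`` contrasts samples by patient outcome;
    ``grouping='tissue'`` contrasts cancer samples against pooled normal
    samples (a within-patient contrast; the patient random effect is
    retained through the same consensus-correlation GLS).
    Counts must be raw nonnegative integers.
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    Y = log_cpm(counts).to_numpy()
    info = samples.set_index("sample_id").loc[list(counts.columns)]
    if grouping == "outcome":
        group, patient = _prepare_outcome(samples, patients, outcome, counts.columns)
    elif grouping == "tissue":
        group = (info["tissue_class"] == "cancer").to_numpy()
        patient = info["patient_id"].to_numpy()
    else:
        raise ValueError("grouping must be 'outcome' or 'tissue'")
    effect, p, rho, df = _gls_group_test(Y, group, patient)
    out = _assoc_table(counts.index, effect, p)
    out.attrs["consensus_correlation"] = rho
    out.attrs["df"] = df
    out.attrs["scale"] = "log2_cpm"
    return out


def meth_expr_correlation(
    beta: BetaMatrix,
    counts: pd.DataFrame,
    annotation: pd.DataFrame,
    samples: pd.DataFrame = None,
) -> pd.DataFrame:
    """Pearson correlation between each probe's betas and its gene's log-CPM.

    Probes without a gene annotation or whose gene is absent from the count
    matrix are skipped.  Pairs with fewer than 3 matched samples get NaN.
    Returns a table (probe_id, gene, r, n_samples).
    """
    shared = [s for s in beta.sample_ids if s in counts.columns]
    expr = log_cpm(counts[shared])
    rows = []
    ann = annotation.set_index("probe_id")["gene_symbols"]
    for pid in beta.probe_ids:
        gene = ann.get(pid, "")
        if not gene or gene not in expr.index:
            continue
        x = beta.df.loc[pid, shared].to_numpy(dtype=float)
        y = expr.loc[gene].to_numpy(dtype=float)
        keep = ~(np.isnan(x) | np.isnan(y))
        if keep.sum() < 3:
            rows.append((pid, gene, np.nan, int(keep.sum())))
            continue
        xs, ys = x[keep], y[keep]
        if xs.std() == 0 or ys.std() == 0:
            rows.append((pid, gene, np.nan, int(keep.sum())))
            continue
        r = float(np.corrcoef(xs, ys)[0, 1])
        rows.append((pid, gene, r, int(keep.sum())))
    return pd.DataFrame(rows, columns=["probe_id", "gene", "r", "n_samples"])
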