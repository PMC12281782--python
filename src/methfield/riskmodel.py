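"""Leave-one-out Cox-LASSO stability selection and risk stratification.

The procedure: train an elastic-net Cox model (mixing 0.1, i.e. mostly
ridge — chosen to keep most candidate CpGs in the model) on all units but
one, with penalty strength chosen by inner k-fold cross-validated
partial-likelihood deviance, and repeat for every unit.  The final model
keeps the candidates with a nonzero coefficient in strictly more than 50%
of iterations, assigns each the mean of its nonzero per-iteration
coefficients, and splits units into high-/low-risk groups at the median
training risk score (ties go to high-risk).  Group separation is assessed
by Kaplan-Meier curves and the two-group log-rank test.

Units are samples by default (each held-out unit is one tissue sample);
``group_by_patient`` leaves out whole patients instead, because same-patient
samples in train and test leak outcome information.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .stats import (
    LogrankResult,
    cox_path_fit,
    cv_choose_lambda,
    logrank_test,
)

_NONZERO = 1e-10


@dataclass
class RiskModel:
    """Stability-selected Cox risk model."""

    probes: list
    coefficients: pd.Series  # mean of nonzero per-iteration coefficients
    cutoff: float  # median training risk score
    selection_frequency: pd.Series  # per candidate, over non-skipped iterations

    def risk_scores(self, X: pd.DataFrame) -> pd.Series:
        missing = [p for p in self.probes if p not in X.columns]
        if missing:
            raise ValueError(f"X lacks model probes: {missing[:5]}")
        return X[self.probes] @ self.coefficients.loc[self.probes]

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "probes": list(self.probes),
                    "coefficients": {p: float(c) for p, c in self.coefficients.items()},
                    "cutoff": float(self.cutoff),
                    "selection_frequency": {
                        p: float(f) for p, f in self.selection_frequency.items()
                    },
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path) -> "RiskModel":
        d = json.loads(Path(path).read_text())
        return cls(
            probes=d["probes"],
            coefficients=pd.Series(d["coefficients"]),
            cutoff=d["cutoff"],
            selection_frequency=pd.Series(d["selection_frequency"]),
        )


def _check_survival(X: pd.DataFrame, survival: pd.DataFrame) -> pd.DataFrame:
    surv = survival.set_index("unit_id").loc[X.index]
    if surv["event"].sum() < 2:
        raise ValueError("need at least 2 events")
    return surv


def loocv_selection(
    X: pd.DataFrame,
    survival: pd.DataFrame,
    l1_ratio: float = 0.1,
    inner_cv_folds: int = 5,
    seed: int = 0,
    group_by_patient: pd.Series = None,
    n_lambdas: int = 12,
) -> dict:
    """Leave-one-out stability selection for a penalized Cox model.

    ``X`` is a unit x candidate-CpG beta matrix; ``survival`` has columns
    unit_id, time_months, event.  Each iteration leaves one unit (or one
    patient's units, with ``group_by_patient``) out, picks the penalty
    strength by inner CV on the training units, fits, and records the
    coefficient vector and the held-out linear-predictor risk score(s).

    Returns a dict with 'coefficients' (iteration x candidate DataFrame),
    'heldout_scores' (Series per unit), and 'skipped' (list of units whose
    iteration failed to converge).  More than 20% skips is an error.
    """
    if X.shape[0] < 5:
        raise ValueError("need at least 5 units")
    if X.isna().any().any():
        raise ValueError("X contains missing values")
    surv = _check_survival(X, survival)
    time = surv["time_months"].to_numpy()
    event = surv["event"].to_numpy()
    rng = np.random.default_rng(seed)

    if group_by_patient is not None:
        groups = pd.Series(group_by_patient).loc[X.index]
        folds = [list(X.index[groups == g]) for g in groups.unique()]
    else:
        folds = [[u] for u in X.index]

    coef_rows, heldout, skipped = [], {}, []
    for held in folds:
        tr = ~X.index.isin(held)
        if event[tr].sum() < 2:
            skipped.extend(held)
            continue
        Xtr = X.loc[tr].to_numpy()
        try:
            lam, lambdas = cv_choose_lambda(
                Xtr,
                time[tr],
                event[tr],
                l1_ratio=l1_ratio,
                n_folds=inner_cv_folds,
                rng=rng,
                n_lambdas=n_lambdas,
            )
            # refit on the full training set, warm-started down the path
            path = lambdas[lambdas >= lam]
            beta = cox_path_fit(
                Xtr, time[tr], event[tr], l1_ratio=l1_ratio, lambdas=path
            )[-1]
        except RuntimeError:
            skipped.extend(held)
            continue
        coef_rows.append(pd.Series(beta, index=X.columns, name=tuple(held)))
        for u in held:
            heldout[u] = float(X.loc[u].to_numpy() @ beta)
    if len(skipped) > 0.2 * X.shape[0]:
        raise RuntimeError(
            f"{len(skipped)} of {X.shape[0]} leave-one-out iterations failed to converge"
        )
    return {
        "coefficients": pd.DataFrame(coef_rows),
        "heldout_scores": pd.Series(heldout, name="risk_score"),
        "skipped": skipped,
    }


def build_final_model(
    coefficients: pd.DataFrame,
    X: pd.DataFrame,
    survival: pd.DataFrame,
    frequency_threshold: float = 0.5,
) -> RiskModel:
    """Build the stability-selected final model from per-iteration coefficients.

    Keeps candidates nonzero in strictly more than ``frequency_threshold``
    of iterations; each kept coefficient is the mean over the iterations
    where it was nonzero; the cutoff is the median risk score of all
    training units under the final coefficients.
    """
    nonzero = coefficients.abs() > _NONZERO
    freq = nonzero.mean(axis=0)
    kept = freq.index[freq > frequency_threshold]
    if len(kept) == 0:
        raise ValueError(
            "empty model: no candidate was selected in more than "
            f"{frequency_threshold:.0%} of iterations"
        )
    coefs = pd.Series(
        {p: coefficients.loc[nonzero[p], p].mean() for p in kept}, name="coefficient"
    )
    model = RiskModel(
        probes=list(kept),
        coefficients=coefs,
        cutoff=float("nan"),
        selection_frequency=freq,
    )
    model.cutoff = float(np.median(model.risk_scores(X)))
    return model


def kaplan_meier(time, event) -> pd.DataFrame:
    """Kaplan-Meier step function: (time, n_at_risk, n_events, survival)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    out = [(0.0, time.size, 0, 1.0)]
    surv = 1.0
    for t in np.unique(time[event]):
        at_risk = int((time >= t).sum())
        d = int((event & (time == t)).sum())
        surv *= 1.0 - d / at_risk
        out.append((float(t), at_risk, d, surv))
    return pd.DataFrame(out, columns=["time", "n_at_risk", "n_events", "survival"])


def stratify_and_test(
    model: RiskModel, X: pd.DataFrame, survival: pd.DataFrame
) -> tuple[pd.Series, dict, LogrankResult]:
    """Median-cutoff risk stratification with Kaplan-Meier and log-rank.

    High-risk iff risk score >= cutoff (scores equal to the cutoff go to
    high-risk).  Returns (group labels, KM curves per group, log-rank
    result).
    """
    scores = model.risk_scores(X)
    labels = pd.Series(
        np.where(scores >= model.cutoff, "high", "low"), index=X.index, name="risk_group"
    )
    surv = survival.set_index("unit_id").loc[X.index]
    curves = {}
    for g in ("high", "low"):
        m = labels == g
        if m.any():
            curves[g] = kaplan_meier(surv.loc[m.to_numpy(), "time_months"], surv.loc[m.to_numpy(), "event"])
    if labels.nunique() < 2:
        raise ValueError(
            "risk stratification produced a single group "
            f"(all scores {'>= ' if (labels == 'high').all() else '< '}cutoff {model.cutoff:.4g})"
        )
    res = logrank_test(
        surv["time_months"].to_numpy(), surv["event"].to_numpy(), labels.to_numpy()
    )
    return labels, curves, res
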