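"""Synthetic-benchmark experiments for the whole pipeline.

Each function generates a cohort with known ground truth under the default
study conditions, runs one analysis stage, and returns recovery or
calibration metrics.  They back the acceptance checks in the test suite
and the reproduction script, and are handy for sanity-checking parameter
changes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import dmc as dmc_mod
from . import enrichment as enr
from . import heterogeneity as het
from . import riskmodel as rm
from .heterogeneity import cv_report
from .preprocess import filter_probes
from .simulate import (
    SimulationConfig,
    generate_cohort,
    generate_survival,
    generate_tracks,
    prognostic_risk_link,
)


def reference_cohort_table() -> pd.DataFrame:
    """A 16-patient table reproducing the study cohort's printed group
    counts (synthetic reconstruction; identities are arbitrary).

    5 non-recurrence / 11 recurrence patients; 5 metastasis (all within the
    recurrence group); EAU risk 2 high + 3 intermediate vs 3 high + 8
    intermediate; post-surgery ISUP grades 4x2 + 1x3 vs 4x2 + 5x3 + 2x5;
    pT stage T2c x4 (+1 missing) vs T2c x4 + T3a x3 + T3b x4.
    """
    rec = [False] * 5 + [True] * 11
    met = [False] * 5 + [True] * 5 + [False] * 6
    isup = [2, 2, 2, 2, 3] + [3, 3, 3, 3, 3, 2, 2, 2, 2, 5, 5]
    eau = (["high"] * 2 + ["intermediate"] * 3
           + ["high"] * 3 + ["intermediate"] * 8)
    pt = (["T2c"] * 4 + [None]
          + ["T2c"] * 4 + ["T3a"] * 3 + ["T3b"] * 4)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:02d}" for i in range(16)],
            "recurrence": rec,
            "metastasis": met,
            "isup_grade": isup,
            "eau_risk": eau,
            "pt_stage": pt,
            "followup_years": 10.0,
            "age_years": 63.0,
            "psa_ng_ml": 10.0,
            "recurrence_free_interval_months": [np.nan] * 5 + [37.0] * 11,
        }
    )


def null_calibration_experiment(seed: int = 0, n_probes: int = 2000) -> dict:
    """Rejection rate of the patient-aware group test on a null cohort
    (no spiked group effect)."""
    cfg = SimulationConfig(seed=seed, delta_beta=0.0, n_probes=n_probes,
                           n_filter_fail=0)
    beta, samples, patients, annotation, _ = generate_cohort(cfg)
    res = dmc_mod.mixed_group_test(beta, samples, patients, outcome="recurrence")
    n = len(res)
    rate = float((res["q"] < 0.05).mean())
    return {
        "rate_q05": rate,
        "limit": 0.05 + 3 * float(np.sqrt(0.05 * 0.95 / n)),
        "n_probes": n,
    }


def dmc_recovery_experiment(seed: int = 0, n_probes: int = 10_000,
                            delta_beta: float = 0.2) -> dict:
    """Sensitivity and empirical FDR of DMC detection on a spiked cohort
    (37 recurrence DMCs; metastasis spikes disabled so that every non-spiked
    probe is a true null for the recurrence contrast)."""
    cfg = SimulationConfig(seed=seed, n_probes=n_probes, delta_beta=delta_beta,
                           n_metastasis_dmcs=0, dmc_overlap_fraction=0.0)
    beta, samples, patients, annotation, truth = generate_cohort(cfg)
    beta_f, _ = filter_probes(beta, annotation)
    res = dmc_mod.mixed_group_test(beta_f, samples, patients, outcome="recurrence")
    hits = set(res.loc[res["q"] < 0.05, "feature_id"])
    true = set(truth.loc[truth["spike_recurrence"], "probe_id"])
    tp = len(hits & true)
    return {
        "sensitivity": tp / len(true),
        "n_hits": len(hits),
        "n_true": len(true),
        "false_positives": len(hits - true),
        "fdr": (len(hits) - tp) / max(len(hits), 1),
    }


def heterogeneity_experiment(seed: int = 0, n_probes: int = 10_000) -> dict:
    """CV structure of the spiked (prognostic) CpG set against its matched
    random-CpG null on a default cohort."""
    cfg = SimulationConfig(seed=seed, n_probes=n_probes)
    beta, samples, patients, annotation, truth = generate_cohort(cfg)
    beta_f, _ = filter_probes(beta, annotation)
    spiked = [p for p in truth.loc[truth["spike_recurrence"], "probe_id"]
              if p in set(beta_f.probe_ids)]
    rep = cv_report(beta_f, samples, spiked, n_iter=10, seed=seed)
    return {
        **rep.medians,
        "p_inter_vs_null": rep.p_inter_vs_null,
        "p_intra_vs_inter": rep.p_intra_vs_inter,
    }


def enrichment_recovery_experiment(seed: int = 0, n_probes: int = 10_000,
                                   promoter_enrichment_factor: float = 3.0,
                                   n_tfs: int = 50, n_true_tfs: int = 5) -> dict:
    """Promoter-state and planted-TF recovery on synthetic tracks."""
    cfg = SimulationConfig(seed=seed, n_probes=n_probes)
    beta, samples, patients, annotation, truth = generate_cohort(cfg)
    beta_f, _ = filter_probes(beta, annotation)
    tracks, tfbs, tf_truth = generate_tracks(
        annotation, truth, promoter_enrichment_factor=promoter_enrichment_factor,
        n_tfs=n_tfs, n_true_tfs=n_true_tfs, seed=seed,
    )
    background = beta_f.probe_ids
    query = [p for p in truth.loc[truth["spike_recurrence"], "probe_id"]
             if p in set(background)]
    out = {}
    for cell, track in tracks.items():
        res = enr.state_enrichment(query, background, annotation, track)
        prom = res[res["category"] == "promoter"].iloc[0]
        out[cell] = {"fold": float(prom["fold"]), "q": float(prom["q"])}
    tf_res = enr.tf_enrichment(query, background, annotation, enr.build_tfbr(tfbs))
    top = list(tf_res["category"].iloc[:n_true_tfs])
    out["tf"] = {
        "n_tfs_tested": len(tf_res),
        "planted_in_top": len(set(top) & set(tf_truth["true_tfs"])),
        "n_planted": n_true_tfs,
    }
    return out


def risk_model_experiment(seed: int = 0, n_prognostic: int = 5,
                          hr_per_sd: float = 2.0) -> dict:
    """LOOCV Cox-LASSO stability selection on a cohort whose survival is
    driven by a subset of the spiked CpGs (the candidate list is the full
    spiked set, mirroring a DMC panel)."""
    cfg = SimulationConfig(seed=seed)
    beta, samples, patients, annotation, truth = generate_cohort(cfg)
    candidates = list(truth.loc[truth["spike_recurrence"], "probe_id"])
    prognostic = candidates[:n_prognostic]
    link = prognostic_risk_link(beta, samples, prognostic, hr_per_sd=hr_per_sd)
    surv_pat = generate_survival(patients, link, seed=seed)
    pat_of = samples.set_index("sample_id")["patient_id"]
    X = beta.df.loc[candidates].T
    sp = surv_pat.set_index("unit_id")
    surv = pd.DataFrame(
        {
            "unit_id": X.index,
            "time_months": sp.loc[pat_of.loc[X.index], "time_months"].to_numpy(),
            "event": sp.loc[pat_of.loc[X.index], "event"].to_numpy(),
        }
    )
    sel = rm.loocv_selection(X, surv, seed=seed)
    model = rm.build_final_model(sel["coefficients"], X, surv)
    _, _, lr = rm.stratify_and_test(model, X, surv)
    return {
        "n_true_selected": sum(p in model.probes for p in prognostic),
        "n_prognostic": n_prognostic,
        "n_selected": len(model.probes),
        "n_candidates": len(candidates),
        "logrank_p": lr.p,
        "n_skipped": len(sel["skipped"]),
    }
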