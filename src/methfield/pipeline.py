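"""End-to-end pipeline orchestration.

A single run config (YAML or dict) names either a ``simulate`` block or a
``paths`` block plus per-stage parameters; :func:`run_pipeline` executes
probe filtering -> differential methylation -> heterogeneity -> enrichment
-> risk model -> report, writing every artifact into the run directory.
Outputs are stamped with the config hash and seed, and a run log records
each stage's input/output sizes.  All randomness derives from the single
``seed``, so a rerun with the same config is numerically identical.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dmc as dmc_mod
from . import enrichment as enr
from . import heterogeneity as het
from . import riskmodel as rm
from .datamodel import BetaMatrix, read_bed, read_dataset, read_manifest
from .preprocess import filter_probes
from .report import cohort_summary, heatmap_matrix, plot_heatmap
from .simulate import (
    SimulationConfig,
    generate_cohort,
    generate_survival,
    generate_tracks,
    prognostic_risk_link,
)

_FLOAT_FMT = "%.8g"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(path_or_dict)
    if "seed" not in cfg:
        raise ValueError("config missing required field 'seed'")
    if "simulate" not in cfg and "paths" not in cfg:
        raise ValueError("config needs either a 'simulate' or a 'paths' block")
    if "paths" in cfg:
        for key in ("beta", "samples", "patients", "manifest"):
            if key not in cfg["paths"]:
                raise ValueError(f"config paths block missing required field {key!r}")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config, out_dir=None) -> Path:
    """Execute every stage on the configured cohort; returns the run directory."""
    cfg = load_config(config)
    seed = int(cfg["seed"])
    out = Path(out_dir or cfg.get("out_dir", "methfield_run"))
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"config_hash={config_hash(cfg)}", f"seed={seed}"]
    t0 = _time.time()

    def log(msg):
        log_lines.append(f"[{_time.time() - t0:7.1f}s] {msg}")

    stage = "load"
    try:
        if "simulate" in cfg:
            sim = SimulationConfig(**{**(cfg.get("simulate") or {}), "seed": seed})
            beta, samples, patients, annotation, truth = generate_cohort(sim)
            tracks, tfbs, tf_truth = generate_tracks(
                annotation,
                truth,
                promoter_enrichment_factor=float(cfg.get("promoter_enrichment_factor", 3.0)),
                seed=seed,
            )
            log(
                f"simulated cohort: {beta.shape[0]} probes x {beta.shape[1]} samples, "
                f"{len(patients)} patients"
            )
        else:
            paths = cfg["paths"]
            beta, samples, patients = read_dataset(
                paths["beta"], paths["samples"], paths["patients"]
            )
            annotation = read_manifest(paths["manifest"])
            truth = None
            tracks = {
                Path(p).stem: read_bed(p) for p in paths.get("chromatin", [])
            }
            tfbs = read_bed(paths["tfbs"]) if "tfbs" in paths else None
            tf_truth = None
            log(f"loaded cohort: {beta.shape[0]} probes x {beta.shape[1]} samples")

        stage = "filter"
        beta_f, removal = filter_probes(beta, annotation)
        removal.to_csv(out / "probe_removal_report.tsv", sep="\t", index=False)
        log(f"probe filters: {beta.shape[0]} -> {beta_f.shape[0]} probes "
            f"({len(removal['probe_id'].unique())} removed)")

        stage = "dmc"
        dmc_cfg = cfg.get("dmc") or {}
        fdr = float(dmc_cfg.get("fdr", 0.05))
        res_rec = dmc_mod.mixed_group_test(
            beta_f, samples, patients, outcome="recurrence",
            use_m_values=bool(dmc_cfg.get("use_m_values", False)),
        )
        res_met = dmc_mod.mixed_group_test(
            beta_f, samples, patients, outcome="metastasis",
            use_m_values=bool(dmc_cfg.get("use_m_values", False)),
        )
        for name, res in (("recurrence", res_rec), ("metastasis", res_met)):
            res.to_csv(out / f"dmc_{name}.tsv", sep="\t", index=False,
                       float_format=_FLOAT_FMT)
        dmcs_rec = list(res_rec.loc[res_rec["q"] < fdr, "feature_id"])
        dmcs_met = list(res_met.loc[res_met["q"] < fdr, "feature_id"])
        n10, f10 = dmc_mod.rank_overlap(res_rec, res_met, 0.10)
        n01, f01 = dmc_mod.rank_overlap(res_rec, res_met, 0.01)
        _write_json(
            {"top10pct": {"count": n10, "fraction": f10},
             "top1pct": {"count": n01, "fraction": f01}},
            out / "rank_overlap.json",
        )
        log(f"DMCs at q<{fdr}: recurrence {len(dmcs_rec)}, metastasis {len(dmcs_met)}; "
            f"top-10% overlap {f10:.3f}")
        # downstream stages need a non-trivial CpG set: fall back to the
        # best-ranked sites when too few reach significance
        set_rec = dmcs_rec if len(dmcs_rec) >= 3 else list(
            res_rec.nsmallest(int(dmc_cfg.get("fallback_top_n", 37)), "rank")["feature_id"]
        )
        set_met = dmcs_met if len(dmcs_met) >= 3 else list(
            res_met.nsmallest(int(dmc_cfg.get("fallback_top_n_met", 20)), "rank")["feature_id"]
        )

        stage = "heterogeneity"
        het_cfg = cfg.get("heterogeneity") or {}
        n_iter = int(het_cfg.get("n_iter", 10))
        corr_iter = int(het_cfg.get("corr_iter", 100))
        medians = {}
        for name, cset in (("recurrence", set_rec), ("metastasis", set_met)):
            rep = het.cv_report(beta_f, samples, cset, n_iter=n_iter, seed=seed)
            medians[name] = {
                **rep.medians,
                "p_inter_vs_null": rep.p_inter_vs_null,
                "p_intra_vs_null": rep.p_intra_vs_null,
                "p_intra_vs_inter": rep.p_intra_vs_inter,
            }
            rep.dmc_inter.to_csv(out / f"cv_interpatient_{name}.tsv", sep="\t",
                                 float_format=_FLOAT_FMT)
            rep.dmc_intra.to_csv(out / f"cv_intrapatient_{name}.tsv", sep="\t",
                                 float_format=_FLOAT_FMT)
            corr = het.intrapatient_correlation(beta_f, samples, cset, seed=seed)
            corr.to_csv(out / f"correlation_{name}.tsv", sep="\t", float_format=_FLOAT_FMT)
        null_corr = het.matched_null_correlation(
            beta_f, samples, set_size=len(set_rec), n_iter=corr_iter, seed=seed
        )
        null_corr.to_csv(out / "correlation_null.tsv", sep="\t", float_format=_FLOAT_FMT)
        _write_json(medians, out / "heterogeneity_summary.json")
        log(f"heterogeneity: recurrence medians {medians['recurrence']}")

        stage = "enrichment"
        background = beta_f.probe_ids
        for cell, track in tracks.items():
            res = enr.state_enrichment(set_rec, background, annotation, track)
            res.to_csv(out / f"enrichment_states_{cell}.tsv", sep="\t", index=False,
                       float_format=_FLOAT_FMT)
            top = res.iloc[0] if len(res) else None
            if top is not None:
                log(f"state enrichment [{cell}]: top {top['category']} "
                    f"fold={top['fold']:.2f} q={top['q']:.2g}")
        if tfbs is not None:
            tfbr = enr.build_tfbr(tfbs, pad=int(cfg.get("tfbr_pad", 150)))
            res_tf = enr.tf_enrichment(set_rec, background, annotation, tfbr)
            res_tf.to_csv(out / "enrichment_tfs.tsv", sep="\t", index=False,
                          float_format=_FLOAT_FMT)
            log(f"TF enrichment: {int((res_tf['q'] < 0.05).sum())} of {len(res_tf)} "
                "TFs at q<0.05")

        stage = "riskmodel"
        rm_cfg = cfg.get("riskmodel") or {}
        if "simulate" in cfg:
            n_prog = int(rm_cfg.get("n_prognostic", 5))
            prog = list(truth.loc[truth["spike_recurrence"], "probe_id"])[:n_prog]
            link = prognostic_risk_link(
                beta_f, samples, prog, hr_per_sd=float(rm_cfg.get("hr_per_sd", 2.0))
            )
            surv_pat = generate_survival(patients, link, seed=seed)
        else:
            surv_pat = pd.DataFrame(
                {
                    "unit_id": patients["patient_id"],
                    "time_months": np.where(
                        patients["recurrence"],
                        patients["recurrence_free_interval_months"],
                        patients["followup_years"] * 12.0,
                    ),
                    "event": patients["recurrence"].astype(bool),
                }
            )
        pat_of = samples.set_index("sample_id")["patient_id"]
        surv = pd.DataFrame(
            {
                "unit_id": beta_f.sample_ids,
                "time_months": surv_pat.set_index("unit_id")
                .loc[pat_of.loc[beta_f.sample_ids], "time_months"].to_numpy(),
                "event": surv_pat.set_index("unit_id")
                .loc[pat_of.loc[beta_f.sample_ids], "event"].to_numpy(),
            }
        )
        candidates = set_rec
        X = beta_f.df.loc[candidates].T
        sel = rm.loocv_selection(
            X,
            surv,
            l1_ratio=float(rm_cfg.get("l1_ratio", 0.1)),
            inner_cv_folds=int(rm_cfg.get("inner_cv_folds", 5)),
            seed=seed,
            n_lambdas=int(rm_cfg.get("n_lambdas", 15)),
        )
        model = rm.build_final_model(sel["coefficients"], X, surv)
        model.to_json(out / "risk_model.json")
        labels, curves, lr = rm.stratify_and_test(model, X, surv)
        labels.to_frame().assign(risk_score=model.risk_scores(X)).to_csv(
            out / "risk_groups.tsv", sep="\t", float_format=_FLOAT_FMT
        )
        pd.concat(
            [c.assign(group=g) for g, c in curves.items()], ignore_index=True
        ).to_csv(out / "km_curves.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
        _write_json(
            {"chi_square": lr.statistic, "p": lr.p, "n_events": lr.n_events,
             "n_selected": len(model.probes), "cutoff": model.cutoff},
            out / "logrank.json",
        )
        log(f"risk model: {len(model.probes)} probes selected, log-rank p={lr.p:.3g}")

        stage = "report"
        summ = cohort_summary(patients)
        summ.numeric.to_csv(out / "cohort_numeric.tsv", sep="\t", index=False,
                            float_format=_FLOAT_FMT)
        summ.categorical.to_csv(out / "cohort_categorical.tsv", sep="\t", index=False,
                                float_format=_FLOAT_FMT)
        mat, ann = heatmap_matrix(beta_f, samples, patients, set_rec)
        mat.to_csv(out / "heatmap_recurrence.tsv", sep="\t", float_format=_FLOAT_FMT)
        ann.to_csv(out / "heatmap_annotation.tsv", sep="\t", index=False)
        if cfg.get("plots", False):
            plot_heatmap(mat, ann, out / "heatmap_recurrence.png")
        log("report written")
    except PipelineError:
        raise
    except Exception as err:  # noqa: BLE001 - attach the failing stage
        raise PipelineError(stage, err) from err

    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    if "simulate" in cfg:
        cfg_used = {**cfg, "simulate": asdict(sim)}
    else:
        cfg_used = cfg
    with open(out / "config_used.yaml", "w") as fh:
        yaml.safe_dump({**cfg_used, "config_hash": config_hash(cfg)}, fh)
    return out
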