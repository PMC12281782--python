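"""Synthetic EPIC-like cohort generator.

Emulates the statistical structure of a multi-sample-per-patient prostate
methylation study: 16 patients (11 with biochemical recurrence, 5 of whom
developed metastasis), 3-5 samples each across cancer / normal-adjacent /
normal-distant tissue, ~10,000 probes, and a small set of spiked prognostic
CpGs whose methylation differs between outcome groups at the *patient*
level with high between-patient and low within-patient variation.

Beta values are generated on the logit scale and back-transformed:

    logit(beta_ijs) = mu_j + shift_j * outcome_i + b_ij + e_ijs

with per-CpG baseline ``mu_j``, patient random effect ``b_ij`` and sample
noise ``e_ijs``.  The logistic back-transform keeps every value in (0, 1)
for any effect size.  Companion generators produce tiling chromatin-state
tracks with a controllable promoter enrichment of the spiked CpGs, a TFBS
track with factors planted near spiked CpGs, recurrence-free survival
linked to methylation, and a tissue-driven expression count matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    BetaMatrix,
    validate_patient_table,
    validate_sample_table,
    validate_track,
    write_bed,
)
from .enrichment import CHROMHMM_STATES, STATE_GROUPS

_CHROMS = ("chr1", "chr2", "chr3", "chr4")
_CHROM_LEN = 30_000_000

#: Background sampling weights over the 17 chromatin states for the probe
#: universe.  Methylation-array probes are deliberately concentrated at
#: promoters and CpG islands, so the promoter-group fraction (~20%) is far
#: above its genome-wide share, while quiescent chromatin still dominates
#: the remainder.
_STATE_WEIGHTS = {
    "TssA": 0.060, "TssBiv": 0.030, "TssFlnk": 0.050, "TssFlnkD": 0.030,
    "TssFlnkU": 0.030, "EnhA1": 0.025, "EnhA2": 0.025, "EnhBiv": 0.010,
    "EnhG1": 0.015, "EnhG2": 0.015, "EnhWk": 0.050, "ReprPC": 0.030,
    "ReprPCWk": 0.050, "Tx": 0.060, "TxWk": 0.120, "Het": 0.050, "Quies": 0.350,
}


def _logit(p):
    return np.log(p / (1.0 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Noise scales are on the logit scale.  Spiked (prognostic) CpGs get a
    patient random effect ``sigma_inter`` with much smaller sample noise
    ``sigma_intra`` (low within-patient heterogeneity); background CpGs get
    comparable between- and within-patient noise, as random array CpGs show.
    """

    n_patients: int = 16
    n_recurrence: int = 11
    n_metastasis: int = 5
    samples_per_patient: tuple[int, int] = (3, 5)
    n_probes: int = 10_000
    n_recurrence_dmcs: int = 37
    n_metastasis_dmcs: int = 20
    dmc_overlap_fraction: float = 0.1
    delta_beta: float = 0.2
    sigma_inter: float = 0.30
    sigma_intra: float = 0.03
    sigma_inter_bg: float = 0.20
    sigma_intra_bg: float = 0.15
    metastasis_loss_fraction: float = 0.8
    n_filter_fail: int = 100
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        if not (self.n_metastasis <= self.n_recurrence <= self.n_patients):
            raise ValueError("need n_metastasis <= n_recurrence <= n_patients")
        if not (self.sigma_intra < self.sigma_inter):
            raise ValueError("spiked CpGs need sigma_intra < sigma_inter")
        lo, hi = self.samples_per_patient
        if not (1 <= lo <= hi):
            raise ValueError("invalid samples_per_patient range")
        if not (0 <= self.delta_beta < 1):
            raise ValueError("delta_beta must be in [0, 1)")
        n_spiked = self.n_recurrence_dmcs + self.n_metastasis_dmcs
        if n_spiked + self.n_filter_fail > self.n_probes:
            raise ValueError("too few probes for spiked + filter-failing sets")
        return self


def _tissue_plan(k: int) -> list[str]:
    """Tissue classes for a patient with k samples (two tumour samples when
    possible, one normal adjacent, one normal distant, extras to cancer)."""
    base = ["cancer", "normal_adjacent", "normal_distant"]
    return base + ["cancer"] * (k - 3)


def generate_cohort(config: SimulationConfig):
    """Generate (BetaMatrix, samples, patients, annotation, truth).

    ``truth`` records per probe whether it is spiked for recurrence and/or
    metastasis, the shift direction, and any designed QC failure.
    """
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed)

    # --- patients -----------------------------------------------------------
    pids = [f"P{i + 1:02d}" for i in range(cfg.n_patients)]
    rec_ids = list(rng.choice(pids, size=cfg.n_recurrence, replace=False))
    met_ids = list(rng.choice(rec_ids, size=cfg.n_metastasis, replace=False))
    recurrence = np.array([p in rec_ids for p in pids])
    metastasis = np.array([p in met_ids for p in pids])
    followup = rng.uniform(8.0, 16.0, cfg.n_patients).round(1)
    rfi = np.where(
        recurrence,
        np.clip(rng.lognormal(np.log(30.0), 1.0, cfg.n_patients), 1.0, followup * 12.0 - 1.0).round(1),
        np.nan,
    )
    patients = pd.DataFrame(
        {
            "patient_id": pids,
            "recurrence": recurrence,
            "metastasis": metastasis,
            "recurrence_free_interval_months": rfi,
            "followup_years": followup,
            "age_years": np.clip(rng.normal(62.5, 4.5, cfg.n_patients).round(), 45, 78).astype(int),
            "psa_ng_ml": np.clip(rng.lognormal(np.log(10.0), 0.35, cfg.n_patients), 2, 40).round(1),
            "isup_grade": rng.choice([2, 3, 5], size=cfg.n_patients, p=[0.5, 0.37, 0.13]),
            "eau_risk": rng.choice(["intermediate", "high"], size=cfg.n_patients, p=[0.69, 0.31]),
            "pt_stage": rng.choice(["T2c", "T3a", "T3b"], size=cfg.n_patients, p=[0.53, 0.2, 0.27]),
        }
    )
    patients = validate_patient_table(patients)

    # --- samples ------------------------------------------------------------
    lo, hi = cfg.samples_per_patient
    rows = []
    for pid in pids:
        k = int(rng.integers(lo, hi + 1))
        for s, tissue in enumerate(_tissue_plan(k), start=1):
            pct = float(np.clip(rng.normal(85, 15), 10, 100).round()) if tissue == "cancer" else 0.0
            rows.append((f"{pid}_S{s}", pid, tissue, pct))
    samples = validate_sample_table(
        pd.DataFrame(rows, columns=["sample_id", "patient_id", "tissue_class", "cancer_area_pct"])
    )
    n_samples = len(samples)

    # --- probe annotation ---------------------------------------------------
    probe_ids = np.array([f"cg{i:08d}" for i in range(cfg.n_probes)])
    chroms = np.array(_CHROMS)[np.arange(cfg.n_probes) % len(_CHROMS)]
    pos = np.empty(cfg.n_probes, dtype=int)
    for c in _CHROMS:
        m = chroms == c
        k = int(m.sum())
        draw = np.unique(rng.integers(1000, _CHROM_LEN, size=2 * k + 16))
        pos[m] = np.sort(rng.choice(draw, size=k, replace=False))
    island = rng.choice(
        ["island", "shore", "shelf", "open_sea"], size=cfg.n_probes, p=[0.30, 0.20, 0.10, 0.40]
    )
    genes = np.array([f"GENE{i // 5:05d}" if i % 2 == 0 else "" for i in range(cfg.n_probes)])

    # --- spiked sets --------------------------------------------------------
    n_overlap = int(round(cfg.dmc_overlap_fraction * cfg.n_metastasis_dmcs))
    n_spike_total = cfg.n_recurrence_dmcs + cfg.n_metastasis_dmcs - n_overlap
    spike_idx = rng.choice(cfg.n_probes, size=n_spike_total, replace=False)
    rec_idx = spike_idx[: cfg.n_recurrence_dmcs]
    met_idx = np.concatenate(
        [rec_idx[: n_overlap], spike_idx[cfg.n_recurrence_dmcs :]]
    )
    is_rec = np.zeros(cfg.n_probes, dtype=bool)
    is_rec[rec_idx] = True
    is_met = np.zeros(cfg.n_probes, dtype=bool)
    is_met[met_idx] = True
    spiked = is_rec | is_met

    # --- QC fields with designed failures (never on spiked probes) ----------
    bead_count = rng.integers(6, 18, cfg.n_probes)
    detection_p = rng.uniform(0.0, 0.01, cfg.n_probes)
    snp_distance = np.full(cfg.n_probes, np.inf)
    eligible = np.flatnonzero(~spiked)
    fail_idx = rng.choice(eligible, size=cfg.n_filter_fail, replace=False)
    fail_rule = rng.choice(["beads", "detection_p", "snp"], size=cfg.n_filter_fail)
    bead_count[fail_idx[fail_rule == "beads"]] = rng.integers(
        0, 3, (fail_rule == "beads").sum()
    )
    detection_p[fail_idx[fail_rule == "detection_p"]] = rng.uniform(
        0.051, 0.5, (fail_rule == "detection_p").sum()
    )
    snp_distance[fail_idx[fail_rule == "snp"]] = rng.integers(
        0, 5, (fail_rule == "snp").sum()
    )

    annotation = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chrom": chroms,
            "pos": pos,
            "gene_symbols": genes,
            "island_relation": island,
            "bead_count": bead_count,
            "detection_p": detection_p,
            "snp_distance_bp": snp_distance,
        }
    )

    # --- beta values on the logit scale -------------------------------------
    comp = rng.choice(3, size=cfg.n_probes, p=[0.4, 0.4, 0.2])
    mu = np.where(
        comp == 0,
        rng.normal(-2.0, 0.5, cfg.n_probes),
        np.where(comp == 1, rng.normal(2.0, 0.5, cfg.n_probes), rng.normal(0.0, 1.0, cfg.n_probes)),
    )
    # prognostic CpGs sit at intermediate methylation where a delta_beta shift
    # is well inside (0, 1)
    mu[spiked] = rng.normal(_logit(0.30), 0.30, spiked.sum())

    def shift_logit(idx, sign):
        base = _expit(mu[idx])
        target = np.clip(base + sign * cfg.delta_beta, 0.02, 0.98)
        return _logit(target) - mu[idx]

    rec_sign = rng.choice([-1.0, 1.0], size=cfg.n_recurrence_dmcs)
    # metastasis-linked differential methylation is predominantly a LOSS of
    # methylation in the metastasis group
    met_sign = np.where(
        rng.random(len(met_idx)) < cfg.metastasis_loss_fraction, -1.0, 1.0
    )
    rec_shift = np.zeros(cfg.n_probes)
    rec_shift[rec_idx] = shift_logit(rec_idx, rec_sign)
    met_shift = np.zeros(cfg.n_probes)
    met_shift[met_idx] = shift_logit(met_idx, met_sign)

    sig_inter = np.where(spiked, cfg.sigma_inter, cfg.sigma_inter_bg)
    sig_intra = np.where(spiked, cfg.sigma_intra, cfg.sigma_intra_bg)

    b_pat = rng.normal(0.0, 1.0, (cfg.n_probes, cfg.n_patients)) * sig_inter[:, None]
    pat_logit = (
        mu[:, None]
        + rec_shift[:, None] * recurrence[None, :]
        + met_shift[:, None] * metastasis[None, :]
        + b_pat
    )
    pat_index = {p: i for i, p in enumerate(pids)}
    col_pat = np.array([pat_index[p] for p in samples["patient_id"]])
    noise = rng.normal(0.0, 1.0, (cfg.n_probes, n_samples)) * sig_intra[:, None]
    betas = _expit(pat_logit[:, col_pat] + noise)
    beta = BetaMatrix(pd.DataFrame(betas, index=probe_ids, columns=samples["sample_id"].to_numpy()))

    fail_map = pd.Series("", index=probe_ids, dtype=object)
    fail_map.iloc[fail_idx] = fail_rule
    truth = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "spike_recurrence": is_rec,
            "spike_metastasis": is_met,
            "recurrence_sign": np.where(is_rec, np.sign(rec_shift), 0.0),
            "metastasis_sign": np.where(is_met, np.sign(met_shift), 0.0),
            "filter_fail": fail_map.to_numpy(),
        }
    )
    return beta, samples, patients, annotation, truth


# ---------------------------------------------------------------------------
# genomic tracks
# ---------------------------------------------------------------------------

def generate_tracks(
    annotation: pd.DataFrame,
    truth: pd.DataFrame,
    promoter_enrichment_factor: float = 3.0,
    n_tfs: int = 50,
    n_true_tfs: int = 5,
    sites_per_tf: int = 300,
    seed: int = 0,
):
    """Generate two tiling chromatin-state tracks and one TFBS track.

    Each track partitions every chromosome at the midpoints between
    consecutive CpGs, so every CpG is covered by exactly one segment whose
    state is drawn per CpG.  Recurrence-spiked CpGs draw promoter-group
    states at a probability elevated by ``promoter_enrichment_factor``.
    ``n_true_tfs`` factors additionally get binding sites planted within
    150 bp of each recurrence-spiked CpG.

    Returns (dict of cell-line name -> chromatin track, TFBS track,
    track truth dict with the planted TF names).
    """
    if promoter_enrichment_factor < 1:
        raise ValueError("promoter_enrichment_factor must be >= 1")
    rng = np.random.default_rng(seed)
    states = np.array(CHROMHMM_STATES)
    base_w = np.array([_STATE_WEIGHTS[s] for s in states])
    base_w = base_w / base_w.sum()
    prom = np.array([STATE_GROUPS[s] == "promoter" for s in states])
    p_prom = base_w[prom].sum()
    p_prom_dmc = min(promoter_enrichment_factor * p_prom, 0.9)
    dmc_w = base_w.copy()
    dmc_w[prom] *= p_prom_dmc / p_prom
    dmc_w[~prom] *= (1 - p_prom_dmc) / (1 - p_prom)

    is_rec = truth.set_index("probe_id")["spike_recurrence"].reindex(
        annotation["probe_id"]
    ).to_numpy()

    tracks = {}
    for cell_line in ("PC3_like", "LNCaP_like"):
        labels = np.where(
            is_rec,
            rng.choice(states, size=len(annotation), p=dmc_w),
            rng.choice(states, size=len(annotation), p=base_w),
        )
        rows = []
        all_chrom = annotation["chrom"].to_numpy()
        all_pos = annotation["pos"].to_numpy()
        for chrom in annotation["chrom"].unique():
            idx = np.flatnonzero(all_chrom == chrom)
            idx = idx[np.argsort(all_pos[idx])]
            pos0 = all_pos[idx] - 1
            mids = (pos0[:-1] + pos0[1:]) // 2 + 1
            starts = np.concatenate([[0], mids])
            ends = np.concatenate([mids, [pos0[-1] + 1000]])
            rows.append(
                pd.DataFrame({"chrom": chrom, "start": starts, "end": ends, "label": labels[idx]})
            )
        tracks[cell_line] = validate_track(pd.concat(rows, ignore_index=True), require_tiling=True)

    # --- TFBS track ---------------------------------------------------------
    tf_names = [f"TF{i + 1:03d}" for i in range(n_tfs)]
    true_tfs = [str(t) for t in rng.choice(tf_names, size=n_true_tfs, replace=False)]
    rec_ann = annotation[is_rec]
    rows = []
    for tf in tf_names:
        chrom_pick = rng.choice(_CHROMS, size=sites_per_tf)
        starts = rng.integers(0, _CHROM_LEN - 20, size=sites_per_tf)
        widths = rng.integers(8, 21, size=sites_per_tf)
        rows.append(
            pd.DataFrame(
                {"chrom": chrom_pick, "start": starts, "end": starts + widths, "label": tf}
            )
        )
        if tf in true_tfs:
            offs = rng.integers(-100, 101, size=len(rec_ann))
            s = np.maximum(rec_ann["pos"].to_numpy() - 1 + offs, 0)
            rows.append(
                pd.DataFrame(
                    {"chrom": rec_ann["chrom"].to_numpy(), "start": s, "end": s + 10, "label": tf}
                )
            )
    tfbs = validate_track(pd.concat(rows, ignore_index=True), require_tiling=False)
    return tracks, tfbs, {"true_tfs": true_tfs}


# ---------------------------------------------------------------------------
# survival and expression
# ---------------------------------------------------------------------------

def generate_survival(
    patient_table: pd.DataFrame,
    risk_link,
    seed: int = 0,
    baseline_median_months: float = 120.0,
    followup_months: tuple[float, float] = (96.0, 192.0),
) -> pd.DataFrame:
    """Exponential event times with patient-specific hazard, censored at a
    simulated follow-up drawn uniformly from ``followup_months``
    (emulating clinical follow-up 8-16 years after surgery).

    ``risk_link`` maps patient_id -> log-hazard (e.g. built from spiked CpG
    betas via :func:`prognostic_risk_link`); zero link gives the baseline
    hazard with median event time ``baseline_median_months``.
    """
    rng = np.random.default_rng(seed)
    link = pd.Series(risk_link)
    pids = patient_table["patient_id"].to_numpy()
    lam0 = np.log(2.0) / baseline_median_months
    rows = []
    for pid in pids:
        rate = lam0 * np.exp(float(link.get(pid, 0.0)))
        t_event = rng.exponential(1.0 / rate)
        censor = rng.uniform(*followup_months)
        event = t_event <= censor
        rows.append((pid, min(t_event, censor), bool(event)))
    return pd.DataFrame(rows, columns=["unit_id", "time_months", "event"])


def prognostic_risk_link(
    beta: BetaMatrix, samples: pd.DataFrame, probe_ids, hr_per_sd: float = 2.0
) -> pd.Series:
    """Patient log-hazard from mean methylation of prognostic CpGs.

    Each probe contributes ``log(hr_per_sd)`` per standard deviation of its
    patient-mean beta value.
    """
    pat = samples.set_index("sample_id")["patient_id"].loc[beta.sample_ids]
    sub = beta.df.loc[list(probe_ids)]
    pat_mean = sub.T.groupby(pat.to_numpy()).mean()  # patient x probe
    z = (pat_mean - pat_mean.mean()) / pat_mean.std(ddof=0).replace(0, 1.0)
    return np.log(hr_per_sd) * z.sum(axis=1)


def generate_expression(
    annotation: pd.DataFrame,
    samples: pd.DataFrame,
    truth: pd.DataFrame,
    tissue_log2fc: float = 1.0,
    frac_tissue_de: float = 0.1,
    seed: int = 0,
):
    """Gene-count matrix with expression differing by tissue but not outcome.

    Genes annotated to spiked CpGs plus a random ``frac_tissue_de`` of the
    rest receive a cancer-vs-normal log2 fold change of ``tissue_log2fc``
    (random sign); no gene depends on recurrence or metastasis status.
    Returns (counts DataFrame gene x sample, truth DataFrame per gene).
    """
    rng = np.random.default_rng(seed)
    genes = sorted(g for g in annotation["gene_symbols"].unique() if g)
    spiked_genes = set(
        annotation.loc[
            annotation["probe_id"].isin(
                truth.loc[truth["spike_recurrence"] | truth["spike_metastasis"], "probe_id"]
            ),
            "gene_symbols",
        ]
    ) - {""}
    n_genes = len(genes)
    de = np.array([g in spiked_genes for g in genes])
    de |= rng.random(n_genes) < frac_tissue_de
    sign = rng.choice([-1.0, 1.0], size=n_genes)
    log2fc = np.where(de, sign * tissue_log2fc, 0.0)

    base = rng.normal(5.0, 1.5, n_genes)  # log2 relative abundance
    pat_ids = samples["patient_id"].unique()
    pat_eff = {p: rng.normal(0.0, 0.1, n_genes) for p in pat_ids}
    is_cancer = (samples["tissue_class"] == "cancer").to_numpy()
    cols = {}
    for j, (_, row) in enumerate(samples.iterrows()):
        log2_expr = (
            base
            + log2fc * (1.0 if is_cancer[j] else 0.0)
            + pat_eff[row["patient_id"]]
            + rng.normal(0.0, 0.25, n_genes)
        )
        rel = 2.0**log2_expr
        libsize = rng.uniform(0.8e6, 1.2e6)
        cols[row["sample_id"]] = rng.poisson(rel / rel.sum() * libsize)
    counts = pd.DataFrame(cols, index=genes)
    gene_truth = pd.DataFrame({"gene": genes, "tissue_de": de, "log2fc": log2fc})
    return counts, gene_truth


# ---------------------------------------------------------------------------
# on-disk cohort
# ---------------------------------------------------------------------------

def write_cohort(out_dir, config: SimulationConfig, with_tracks: bool = True) -> dict:
    """Generate a cohort and write every artifact as TSV/BED; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    beta, samples, patients, annotation, truth = generate_cohort(config)
    paths = {
        "beta": out / "beta.tsv",
        "samples": out / "samples.tsv",
        "patients": out / "patients.tsv",
        "manifest": out / "manifest.tsv",
        "truth": out / "truth.tsv",
    }
    beta.write_tsv(paths["beta"])
    samples.to_csv(paths["samples"], sep="\t", index=False)
    patients.to_csv(paths["patients"], sep="\t", index=False)
    annotation.to_csv(paths["manifest"], sep="\t", index=False)
    truth.to_csv(paths["truth"], sep="\t", index=False)
    if with_tracks:
        tracks, tfbs, tf_truth = generate_tracks(annotation, truth, seed=config.seed)
        for name, track in tracks.items():
            paths[f"chromatin_{name}"] = out / f"chromatin_{name}.bed"
            write_bed(track, paths[f"chromatin_{name}"])
        paths["tfbs"] = out / "tfbs.bed"
        write_bed(tfbs, paths["tfbs"])
        (out / "true_tfs.txt").write_text("\n".join(tf_truth["true_tfs"]) + "\n")
        paths["true_tfs"] = out / "true_tfs.txt"
    return paths
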