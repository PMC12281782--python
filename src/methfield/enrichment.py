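"""Enrichment of CpG sets in chromatin states and TF binding regions.

Chromatin segmentations use the 17-label ChromHMM vocabulary collapsed into
six functional groups (promoter, enhancer, PRC, transcribed,
heterochromatin, quiescent).  Transcription-factor binding sites are padded
by +/-150 bp into binding regions (TFBRs) and merged per factor.  Both
analyses score a query CpG set against the full array background with a
one-sided hypergeometric test and Benjamini-Hochberg correction within the
natural family (the six state groups of one track; the TF set of one run).

This module is the single place where 1-based CpG positions meet 0-based
half-open segments: a CpG at 1-based position p lies in [start, end) iff
start <= p - 1 < end.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import benjamini_hochberg, hypergeometric_upper_tail

#: The 17 ChromHMM state labels and their collapsed functional groups.
STATE_GROUPS: dict[str, str] = {
    "TssA": "promoter",
    "TssBiv": "promoter",
    "TssFlnk": "promoter",
    "TssFlnkD": "promoter",
    "TssFlnkU": "promoter",
    "EnhA1": "enhancer",
    "EnhA2": "enhancer",
    "EnhBiv": "enhancer",
    "EnhG1": "enhancer",
    "EnhG2": "enhancer",
    "EnhWk": "enhancer",
    "ReprPC": "PRC",
    "ReprPCWk": "PRC",
    "Tx": "transcribed",
    "TxWk": "transcribed",
    "Het": "heterochromatin",
    "Quies": "quiescent",
}

CHROMHMM_STATES = tuple(STATE_GROUPS)
STATE_GROUP_NAMES = (
    "promoter",
    "enhancer",
    "PRC",
    "transcribed",
    "heterochromatin",
    "quiescent",
)


def collapse_state(raw_label: str) -> str:
    """Map one of the 17 ChromHMM labels to its functional group."""
    try:
        return STATE_GROUPS[raw_label]
    except KeyError:
        raise ValueError(
            f"unknown chromatin state {raw_label!r}; valid labels: {list(CHROMHMM_STATES)}"
        ) from None


def assign_cpgs_to_segments(cpgs: pd.DataFrame, track: pd.DataFrame) -> pd.Series:
    """Label each CpG with the segment it falls in, or NaN if uncovered.

    ``cpgs`` needs columns probe_id, chrom, pos (1-based); ``track`` is a
    segment table (chrom, start, end, label) non-overlapping per chromosome.
    """
    out = pd.Series(np.nan, index=cpgs["probe_id"].to_numpy(), dtype=object)
    for chrom, seg in track.groupby("chrom", sort=False):
        seg = seg.sort_values("start")
        starts = seg["start"].to_numpy()
        ends = seg["end"].to_numpy()
        labels = seg["label"].to_numpy()
        sub = cpgs[cpgs["chrom"] == chrom]
        if sub.empty:
            continue
        pos0 = sub["pos"].to_numpy() - 1  # the one coordinate conversion
        idx = np.searchsorted(starts, pos0, side="right") - 1
        inside = (idx >= 0) & (pos0 < ends[np.clip(idx, 0, len(ends) - 1)])
        probe_ids = sub["probe_id"].to_numpy()
        out.loc[probe_ids[inside]] = labels[idx[inside]]
    return out


def _enrichment_table(categories: pd.Series, query_ids, background_ids) -> pd.DataFrame:
    """Per-category hypergeometric enrichment of query vs background CpGs.

    ``categories`` maps probe_id -> category label (NaN = uncovered; stays
    in the population but counts toward no category).
    """
    query_ids = list(query_ids)
    background_ids = list(background_ids)
    missing = set(query_ids) - set(background_ids)
    if missing:
        raise ValueError(
            f"query CpGs absent from background: {sorted(missing)[:5]} "
            f"({len(missing)} total)"
        )
    fg_total = len(query_ids)
    bg_total = len(background_ids)
    cats_bg = categories.reindex(background_ids)
    cats_fg = categories.reindex(query_ids)
    rows = []
    dropped = []
    for cat in pd.unique(cats_bg.dropna()):
        bg_in = int((cats_bg == cat).sum())
        fg_in = int((cats_fg == cat).sum())
        if bg_in == 0:  # pragma: no cover - unreachable given the loop source
            dropped.append(cat)
            continue
        fold = (fg_in / fg_total) / (bg_in / bg_total)
        p = hypergeometric_upper_tail(bg_total, bg_in, fg_total, fg_in)
        rows.append((cat, fg_in, fg_total, bg_in, bg_total, fold, p))
    out = pd.DataFrame(
        rows, columns=["category", "fg_in", "fg_total", "bg_in", "bg_total", "fold", "p"]
    )
    if len(out):
        out["q"] = benjamini_hochberg(out["p"].to_numpy())
        out = out.sort_values("p", kind="mergesort").reset_index(drop=True)
    else:
        out["q"] = []
    out.attrs["dropped"] = dropped
    return out


def state_enrichment(
    query_cpgs, background_cpgs, annotation: pd.DataFrame, track: pd.DataFrame
) -> pd.DataFrame:
    """Enrichment of a CpG set in the six collapsed chromatin-state groups.

    One call per segmentation track (cell line); BH is applied across the
    six groups of that track.
    """
    ann = annotation.set_index("probe_id", drop=False)
    raw = assign_cpgs_to_segments(ann.loc[list(background_cpgs)], track)
    groups = raw.map(lambda s: collapse_state(s) if isinstance(s, str) else np.nan)
    return _enrichment_table(groups, query_cpgs, background_cpgs)


def build_tfbr(tfbs_track: pd.DataFrame, pad: int = 150) -> pd.DataFrame:
    """Extend TF binding sites by ``pad`` bp on both sides and merge per TF.

    Overlapping or touching padded intervals of one TF on one chromosome are
    merged into maximal disjoint intervals; starts clamp at 0.
    """
    if pad < 0:
        raise ValueError("pad must be non-negative")
    rows = []
    for (tf, chrom), grp in tfbs_track.groupby(["label", "chrom"], sort=False):
        starts = np.maximum(grp["start"].to_numpy() - pad, 0)
        ends = grp["end"].to_numpy() + pad
        order = np.argsort(starts, kind="mergesort")
        starts, ends = starts[order], ends[order]
        cur_s, cur_e = int(starts[0]), int(ends[0])
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:  # overlap or touch: half-open adjacency has no gap
                cur_e = max(cur_e, int(e))
            else:
                rows.append((chrom, cur_s, cur_e, tf))
                cur_s, cur_e = int(s), int(e)
        rows.append((chrom, cur_s, cur_e, tf))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "label"]).sort_values(
        ["label", "chrom", "start"], kind="mergesort"
    ).reset_index(drop=True)


def _cpgs_in_regions(cpgs: pd.DataFrame, regions: pd.DataFrame) -> pd.Series:
    """Boolean membership of each CpG in any region of a disjoint interval set."""
    hit = assign_cpgs_to_segments(cpgs, regions)
    return hit.notna()


def tf_enrichment(
    query_cpgs, background_cpgs, annotation: pd.DataFrame, tfbr: pd.DataFrame
) -> pd.DataFrame:
    """Per-TF hypergeometric enrichment of a CpG set in merged TFBRs.

    A CpG inside regions of several TFs contributes to each TF's test.  TFs
    whose regions contain no background CpG are dropped (fold undefined) and
    listed in ``result.attrs['dropped']``.
    """
    query_cpgs = list(query_cpgs)
    background_cpgs = list(background_cpgs)
    missing = set(query_cpgs) - set(background_cpgs)
    if missing:
        raise ValueError(f"query CpGs absent from background: {sorted(missing)[:5]}")
    ann = annotation.set_index("probe_id", drop=False)
    bg_ann = ann.loc[background_cpgs]
    fg_ann = ann.loc[query_cpgs]
    fg_total, bg_total = len(query_cpgs), len(background_cpgs)
    rows, dropped = [], []
    for tf, regions in tfbr.groupby("label", sort=False):
        bg_in = int(_cpgs_in_regions(bg_ann, regions).sum())
        if bg_in == 0:
            dropped.append(tf)
            continue
        fg_in = int(_cpgs_in_regions(fg_ann, regions).sum())
        fold = (fg_in / fg_total) / (bg_in / bg_total)
        p = hypergeometric_upper_tail(bg_total, bg_in, fg_total, fg_in)
        rows.append((tf, fg_in, fg_total, bg_in, bg_total, fold, p))
    out = pd.DataFrame(
        rows, columns=["category", "fg_in", "fg_total", "bg_in", "bg_total", "fold", "p"]
    )
    if len(out):
        out["q"] = benjamini_hochberg(out["p"].to_numpy())
        out = out.sort_values("p", kind="mergesort").reset_index(drop=True)
    else:
        out["q"] = []
    out.attrs["dropped"] = dropped
    return out
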