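"""Probe-level quality and SNP filters.

Removes probes with fewer than 3 beads, a detection p-value above 0.05, or
a SNP closer than 5 bp to the interrogated CpG.  All three boundaries are
read strictly: bead_count == 3, detection_p == 0.05 and snp_distance == 5
are retained.  QC fields are per-probe scalars (the worst case across
samples); input beta values are assumed already normalized.
"""

from __future__ import annotations

import pandas as pd

from .datamodel import BetaMatrix


def filter_probes(beta: BetaMatrix, annotation: pd.DataFrame):
    """Apply the probe QC filters to a beta matrix.

    Returns
    -------
    (BetaMatrix, DataFrame)
        The filtered matrix (survivors in input order) and a removal report
        with one row per removed probe per triggered rule
        (columns: probe_id, rule, value).
    """
    ann = annotation.set_index("probe_id")
    missing = [p for p in beta.probe_ids if p not in ann.index]
    if missing:
        raise ValueError(
            f"probe(s) missing annotation: {missing[:5]}" +
            (f" (+{len(missing) - 5} more)" if len(missing) > 5 else "")
        )
    ann = ann.loc[beta.probe_ids]

    report_rows = []
    removed = set()
    if "bead_count" in ann.columns:
        for pid, v in ann.loc[ann["bead_count"] < 3, "bead_count"].items():
            report_rows.append((pid, "beads", float(v)))
            removed.add(pid)
    if "detection_p" in ann.columns:
        for pid, v in ann.loc[ann["detection_p"] > 0.05, "detection_p"].items():
            report_rows.append((pid, "detection_p", float(v)))
            removed.add(pid)
    if "snp_distance_bp" in ann.columns:
        snp = ann["snp_distance_bp"].astype(float)
        for pid, v in snp[snp < 5].items():
            report_rows.append((pid, "snp", float(v)))
            removed.add(pid)

    report = pd.DataFrame(report_rows, columns=["probe_id", "rule", "value"])
    survivors = [p for p in beta.probe_ids if p not in removed]
    if not survivors:
        raise ValueError("all probes removed by QC filters")
    return beta.subset_probes(survivors), report
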