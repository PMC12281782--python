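"""Generate a synthetic EPIC-like prostate cohort and inspect its structure.

The generator emulates a 16-patient study (11 biochemical recurrence, 5
metastasis) with 3-5 samples per patient across cancer / normal-adjacent /
normal-distant tissue, and spikes 37 recurrence-linked and 20
metastasis-linked CpGs at the patient level.
"""

from methfield.simulate import SimulationConfig, generate_cohort

beta, samples, patients, annotation, truth = generate_cohort(
    SimulationConfig(n_probes=2000, seed=7)
)

print(f"beta matrix: {beta.shape[0]} probes x {beta.shape[1]} samples")
print(f"tissue classes: {samples['tissue_class'].value_counts().to_dict()}")
print(f"recurrence patients: {patients['recurrence'].sum()} of {len(patients)}")
print(f"spiked recurrence CpGs: {truth['spike_recurrence'].sum()}, "
      f"metastasis CpGs: {truth['spike_metastasis'].sum()}")
print(f"designed QC failures: {(truth['filter_fail'] != '').sum()} probes")
# Spiked CpGs carry the group signal at the patient level, so their
# between-patient spread is large while same-patient samples stay similar.
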