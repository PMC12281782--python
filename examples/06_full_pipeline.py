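"""Run the entire pipeline from one config and list its artifacts.

Equivalent to `methfield run --config config.yaml`; everything derives
from the single seed, so a rerun is numerically identical.
"""

from methfield.pipeline import run_pipeline

config = {
    "seed": 42,
    "simulate": {"n_probes": 3000},
    "heterogeneity": {"n_iter": 10, "corr_iter": 25},
    "riskmodel": {"l1_ratio": 0.1, "inner_cv_folds": 5},
}
out = run_pipeline(config, out_dir="scratch/example_run")
print(f"artifacts in {out}:")
for f in sorted(out.iterdir()):
    print("  ", f.name)
print("\nrun log:")
print((out / "run_log.txt").read_text())
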