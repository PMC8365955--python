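"""Step-wise training end to end on a small synthetic dataset.

Five base models train on the base partition; their probabilities on the
meta partitions feed 31 stacking models (one per base-feature subset); the
subset improving the most metrics over the best single model is selected.
Epoch counts here are small so the example runs in about a minute.
"""

from hergstack import PipelineConfig, run_stepwise_training
from hergstack.pipeline import combination_grid_frame
from hergstack.synthetic import SyntheticSpec, generate_synthetic_dataset

ds = generate_synthetic_dataset(SyntheticSpec(n=400, seed=1))
config = PipelineConfig(seed=1, base_epochs=3, meta_epochs=300)
manifest = run_stepwise_training(ds, config)

print("base-model validation AUC:")
for name, tm in manifest.base_models.items():
    print(f"  {name:5s} {tm.valid_report.auc:.3f}")
print(f"combinations evaluated: {len(manifest.combination_results)}")
print(f"selected: {manifest.selected.combination_id} {manifest.selected.members}")
print(f"selected meta-valid metrics: {manifest.selected.report.formatted()}")
print(f"role isolation audit passed: {manifest.audit_isolation()}")

grid = combination_grid_frame(manifest)
print(grid.head(8).to_string(index=False))
# On noise-free planted-rule data every base model approaches AUC 1.0, so
# stacking mostly competes on threshold calibration: with only ~40
# meta-training molecules some subsets stay uncalibrated (SPE 0 rows), and
# the selection picks the subset improving the most metrics over the best
# single model, breaking ties by MCC then subset size.
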