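"""Simulate a two-condition breast-cancer-like cohort and inspect its truth.

Builds the default cohort (4 patients per condition, 5 lineages, two
malignant clones with planted copy-number segments), writes it to disk in
10x-style text formats, and prints the planted composition.
"""

from pathlib import Path

from clonescope import simulate as sim

cfg = sim.default_config(seed=1)
adata, truth = sim.simulate_cohort(cfg)

print(f"cohort: {adata.n_obs} cells x {adata.n_vars} genes, "
      f"{truth.cells['patient'].nunique()} patients")
print("\ncells per condition and lineage:")
print(truth.cells.groupby(["condition", "cell_type"], observed=True).size().unstack())
print(f"\nmalignant cells: {int(truth.cells['is_malignant'].sum())}")
print("clone prevalence by condition:")
print(truth.cells[truth.cells.is_malignant]
      .groupby(["condition", "clone_id"], observed=True).size().unstack(fill_value=0))
print(f"\nplanted differential regions (clone segments whose prevalence "
      f"differs between conditions): {len(truth.differential_regions)}")

out = Path("scratch/example_cohort")
paths = sim.write_cohort(adata, truth, cfg, out)
print(f"\nwrote {len(paths)} files to {out}/ (matrix.mtx, features.tsv, ...)")
# The clone-prevalence table is the planted ground truth that the CNV and
# region-test examples try to recover from expression alone.
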