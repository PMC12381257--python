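"""Cell-type proportion testing between conditions.

A cohort is planted with a myeloid drop from 4% (primary) to 0.5%
(metastatic, true log2FC = 3); the permutation test recovers the shift and
applies the joint rule p < 0.05 AND |log2FC| > 2.
"""

from clonescope import presets
from clonescope import simulate as sim
from clonescope.composition import proportion_test

adata, _ = sim.simulate_cohort(presets.composition_shift_config(seed=1))
table = proportion_test(
    adata.obs["cell_type"],
    adata.obs["condition"],
    n_perm=2000,
    n_boot=1000,
    alpha=0.05,
    fc_threshold=2.0,
    seed=0,
    conditions=("primary", "metastatic"),
)
cols = ["cell_type", "prop_primary", "prop_metastatic", "log2fc",
        "p_value", "ci_low", "ci_high", "significant"]
print(table[cols].round(4).to_string(index=False))
print("\nplanted: myeloid 4% (primary) vs 0.5% (metastatic), true log2FC = 3.")
hits = table.loc[table["significant"], "cell_type"].tolist()
print(f"types passing the joint rule (p < 0.05 and |log2FC| > 2): {hits}")
print("The compensating lineage shifts reach small p-values but stay below "
      "the magnitude threshold, so the rule singles out the planted change.")
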