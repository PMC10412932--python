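"""Simulate a pulse-chase reporter cohort and look at its structure.

Generates the default study design: 61 mice treated with a 5-day tamoxifen
pulse at t = 0, one mouse sacrificed per timepoint across days 4-66, with
thymic mSP and pooled spleen+LN naive T cell measurements per lineage.
"""

from tchase import default_design, default_truth, generate_cohort
from tchase.preprocess import derive_observables

design = default_design()
truth = default_truth("ki67")  # full Ki67-stratified ground truth
cohort = generate_cohort(truth, design, seed=1)
obs = derive_observables(cohort)

print(f"cohort table: {len(cohort)} records from {design.n_mice} mice")
print(cohort.head(3).to_string(index=False))

cd4 = obs[obs.lineage == "CD4"]
print(f"\nCD4 pooled observables ({len(cd4)} mice):")
print(cd4[["t", "N", "L", "l", "lplus", "Y", "Kplus"]].describe().loc[["mean", "std"]])
print(
    "\nN is the pooled naive pool (steady ~2e7 cells); l and lplus are the "
    "YFP+ fraction\nand the Ki67+ fraction within YFP+ cells - the two "
    "observables the Ki67 model fits."
)
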