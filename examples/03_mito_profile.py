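"""Nuclear/mitochondrial read partition and mitochondrial gene expression change.

The design places 4.5% of reads on the mitochondrial chromosome in 'con' and
11.2% in 'ldl'.  The compartment profile recovers those percentages per sample;
the gene-change table shows every mitochondrial unit up with positive log2 fold
change (CPM surrogate with t-test + Benjamini-Hochberg, not a negative-binomial
Wald test).
"""

from mitosplice.pipeline import mito_profile, simulate_in_memory
from mitosplice.synthetic import SimConfig

exp = simulate_in_memory(SimConfig(seed=42, reads_per_sample=100_000))
profile, changes = mito_profile(exp, order=("con", "ldl"))
print(profile.to_string(index=False))
print()
print(changes.to_string(index=False))
print(
    "\nmito_pct tracks the designed fractions within sampling noise; the ~2.5x "
    "fraction increase appears as l2fc ~ +1.3 for every mitochondrial gene "
    "(the nuclear share shrinks, inflating mito CPM slightly above log2(2.5))."
)
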