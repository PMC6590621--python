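"""Gene-normalized splice-site usage (GNSSR) and the reciprocal junction shift.

Simulates the default design in memory (isoform mixture 0.8/0.2 vs 0.5/0.5),
computes GNSSR per junction and sample, splits the nuclear gene's junctions at
the anchor exon, and compares the per-sample group means between conditions.
"""

from mitosplice.pipeline import junction_shift_analysis, simulate_in_memory
from mitosplice.synthetic import SimConfig

exp = simulate_in_memory(SimConfig(seed=42))
result = junction_shift_analysis(exp, order=("con", "ldl"))
print(result.to_string(index=False))
print(
    "\nThe upstream group (junctions only the full-length isoform uses) loses "
    "usage under 'ldl' while the downstream group gains it — the reciprocal "
    "signature of a shift toward a 3'-only transcript isoform. p-values are "
    "from an unpaired Student's t-test on per-sample group means (4 vs 4)."
)
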