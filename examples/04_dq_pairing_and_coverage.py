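"""HLA-DQ analytics without any training: cis/trans classification,
pseudo-sequence distance, prevalent-molecule enumeration and coverage.

These operations depend only on allele names, the haplotype pairing table,
BLOSUM50 and peptide-count tables, so they run instantly.
"""

import pandas as pd

from mhc2deconv import (
    classify_pairing,
    coverage,
    enumerate_prevalent,
    extended_coverage,
    pseudo_distance,
    weighted_frequency,
)

# cis = observed as a haplotype (two-digit groups); everything else trans-only
for dqa, dqb in [("DQA1*01:01", "DQB1*05:01"), ("DQA1*01:01", "DQB1*03:01"),
                 ("DQA1*03:03", "DQB1*05:01"), ("DQA1*05:01", "DQB1*02:01")]:
    print(f"{dqa} + {dqb}: {classify_pairing(dqa, dqb)}")

# worldwide frequency: population-size-weighted mean, sizes capped at 1000
freq = weighted_frequency([(0.1, 500), (0.3, 4000)])
print(f"\nweighted frequency of (0.1, n=500) and (0.3, n=4000->1000): {freq:.4f}")

# enumerate prevalent molecules: rule-allowed pairs with combined freq > 5e-5
prevalent = enumerate_prevalent(
    {"DQA1*01:01": 0.15, "DQA1*03:03": 0.08},
    {"DQB1*05:01": 0.12, "DQB1*03:01": 0.10, "DQB1*02:01": 0.0003},
)
print("\nprevalent molecules (combined frequency > 0.00005):")
print(prevalent.to_string(index=False))

# coverage: per-cell-line counts enter only at >= 5% of the line's DQ total;
# covered at >= 100 accumulated peptides
ann = pd.DataFrame(
    [("CL1", "DQA10101-DQB10501", False, 1.0)] * 60
    + [("CL2", "DQA10101-DQB10501", False, 1.0)] * 50
    + [("CL2", "DQA10303-DQB10301", False, 1.0)] * 30,
    columns=["sample_id", "molecule", "is_trash", "target"],
)
cov = coverage(ann)
print("\n" + cov.to_string(index=False))

# extended coverage: within pseudo-distance 0.025 of a covered molecule
pseudos = {
    "DQA10101-DQB10501": "A" * 34,
    "DQA10303-DQB10301": "A" * 30 + "CCCC",
}
ext = extended_coverage(cov, pseudos)
print("\n" + ext.to_string(index=False))
print(f"\npseudo-distance between the two molecules: "
      f"{pseudo_distance(pseudos['DQA10101-DQB10501'], pseudos['DQA10303-DQB10301']):.4f}")

# The first molecule accumulates 110 peptides (covered); the second stays at 30
# (not covered) and is too far in pseudo-sequence space to inherit coverage.
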