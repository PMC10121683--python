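"""Percentile-rank calibration: anchoring raw scores to random natural peptides.

Raw network outputs are not comparable between molecules (each molecule has its
own score distribution), so scores are reported as the percentage of random
natural peptides scoring higher.  A planted binder should sit at a very low
rank; a random peptide should scatter uniformly over [0, 100].
"""

import numpy as np

from mhc2deconv import RankCalibration, percentile_rank

# hand-built calibration: 9 reference scores 0.1 ... 0.9
cal = RankCalibration(scores=np.arange(0.1, 1.0, 0.1))
for query in (0.95, 0.65, 0.05):
    print(f"score {query:.2f} -> percentile rank {percentile_rank(query, cal):6.2f}")

# ranks of the calibration's own scores are uniform on {0, 100/N, ...}
own = sorted(percentile_rank(s, cal) for s in cal.scores)
print("ranks of the calibration's own scores:", [round(r, 1) for r in own])

# strictly-greater counting means ties rank favorably
tied = RankCalibration(scores=np.full(10, 0.5))
print("rank of 0.5 against ten tied 0.5 references:", percentile_rank(0.5, tied))

# A peptide at rank 1 outscores 99% of random natural peptides for that
# molecule; rank > 20 marks a peptide no expressed molecule explains (trash).
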