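"""Apply the dock / design / prediction filter cascade to a table of
binder-design metrics.

The metrics come from upstream design tools; this package applies the
threshold cascade with strict comparisons and reports per-stage survivor
counts.
"""

import numpy as np

from cyclopept import cascade
from cyclopept.fixtures import synthetic_metrics_table

rng = np.random.default_rng(7)
table = synthetic_metrics_table(rng, 400)

survivors, counts = cascade(table)
print("stage        survivors")
for stage, n in counts.items():
    print(f"{stage:12s} {n}")
print("\nfirst survivors:")
print(survivors.head(3).to_string(index=False))

# Each stage only ever removes rows: dock thresholds (interface area > 900
# A^2, SC > 0.7, ddG < -40, CMS > 480, contact patch > 440), then the
# post-design thresholds (including >= 3 ligand hydrogen bonds and zero
# buried unsatisfied donors), then the structure-prediction confidence
# thresholds (pLDDT > 90, RMSD < 1.1 A, pTM > 0.8).
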