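"""Conditional tissue-enrichment iteration.

A panel of correlated tissue Z-scores (cardiac tissues share signal) is
conditioned on its top tissue repeatedly until the maximum Z drops below
2.585 (the lowest Z with FDR < 0.05 in the upstream enrichment engine).
Tissues whose signal survives conditioning are independently enriched.
"""

import numpy as np

from cardiomr.enrichment import TissueZPanel, iterate_conditioning

labels = ["heart", "atrium", "ventricle", "artery", "liver", "lung"]
z = np.array([8.2, 7.5, 7.1, 3.4, 1.0, 0.4])
corr = np.array([
    [1.00, 0.85, 0.80, 0.40, 0.10, 0.05],
    [0.85, 1.00, 0.75, 0.35, 0.08, 0.04],
    [0.80, 0.75, 1.00, 0.30, 0.06, 0.03],
    [0.40, 0.35, 0.30, 1.00, 0.20, 0.10],
    [0.10, 0.08, 0.06, 0.20, 1.00, 0.30],
    [0.05, 0.04, 0.03, 0.10, 0.30, 1.00],
])

trace = iterate_conditioning(TissueZPanel(labels, z, corr), z_stop=2.585)
print(trace.summary().to_string(index=False))
print(f"\ntissues conditioned on: {[s.tissue for s in trace.steps]}")
print(f"remaining maximum Z: {trace.final.z.max(initial=float('-inf')):.2f} "
      f"(< 2.585: no further independent enrichment)")
# the shared cardiac signal collapses after conditioning on 'heart';
# only tissues with independent signal trigger further iterations
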