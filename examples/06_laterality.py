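"""Ipsilateral/contralateral signature analysis on a planted lineage.

Simulates a course in which ~5% of early cells carry an ipsilateral module
(mutually exclusive with the contralateral module, fading after the second
age), calls I-/C-cells by the 1.5-SD rule, propagates the I-cells through
the composed transport maps, and reports where their mass lands.
"""

import warnings

warnings.filterwarnings("ignore")

import numpy as np

from rgcfate import benchmarks

truth, res, frac = benchmarks.run_laterality_scenario(seed=0, n_cells_per_age=400)
calls = res["laterality"]["calls"]
print(f"called I-cells at the first age: {calls.i_mask.mean() * 100:.1f}% "
      f"(planted ~5%); C-cells: {calls.c_mask.mean() * 100:.1f}%")
r = np.corrcoef(calls.ipsi_score, calls.contra_score)[0, 1]
print(f"ipsi vs contra score correlation: {r:.2f} (mutually exclusive modules)")

de = res["laterality"]["de"]
print(f"I-vs-rest DE at the first age: {int(de['significant'].sum())} significant genes")
print(f"planted ipsi lineage: terminal types {truth.ipsi_types}")
print(f"share of propagated I-cell mass landing on those types: {frac:.2f}")
print(
    "\nThe calls recover the planted fraction and the signature genes; the"
    "\npropagated mass concentrates on, but also diffuses beyond, the planted"
    "\nlineage - entropic transport chains leak a few percent per step."
)
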