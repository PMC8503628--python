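"""Condition-specific weighted correlation networks and rewiring.

Builds unsigned weighted networks (adjacency |r|^beta, topological
overlap, connectivity) separately for cases and controls on a cohort
with a planted oxidized-phospholipid-like block whose within-condition
correlation is 0.8 in cases but only 0.3 in controls, then recovers the
rewiring through module density and the differential-connectivity rule
(|delta k| > 5).
"""

import numpy as np

from lipidflow import network as nm
from lipidflow.simulate import ModuleSpec, SimConfig, simulate_cohort

cfg = SimConfig(n_lipids=200, modules=[ModuleSpec(30, 0.8, 0.3)],
                effect_lipids=[], causal_chain=[], causal_coefficients=[],
                missing_rate=0, seed=5)
matrix, clinical, truth = simulate_cohort(cfg)
logm = matrix.with_values(np.log2(matrix.values), scale_state="log")

beta = 4
nets = {}
for name, flag in (("case", 1), ("control", 0)):
    sub = logm.subset_samples(clinical.index[clinical.status == flag])
    net = nm.build_network(sub, beta)
    nm.detect_modules(net, sub)
    nets[name] = net
    labels = [l for l in net.modules.unique() if l != "grey"]
    dens = {l: round(nm.module_density(net, l), 2) for l in labels}
    print(f"{name:8s} network (beta={beta}): modules {dens} "
          "(density = mean within-module topological overlap)")

increased, decreased, dk = nm.connectivity_diff(nets["case"],
                                                nets["control"], delta=5.0)
block = {l for l, t in truth.true_modules.items()
         if t == truth.rewired_module}
print(f"\nlipids with connectivity increased by >5 in cases: {len(increased)}")
print(f"  of which in the planted rewired block: "
      f"{len(block & set(increased))}/{len(block)}")
print(f"lipids with decreased connectivity: {len(decreased)}")
print("\nThe rewired block is densely connected only in cases, so its"
      " members gain connectivity there — the same signature the method"
      " reports for oxidized phospholipids in preeclampsia.")
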