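"""Wild-type development: one noisy ensemble diversifies into four cell types.

Simulates 100 progenitor cells (Hnf6 and Pdx1 high, everything else off)
with the default noise magnitude, classifies terminal states by the four
lineage markers, and reports the attractor census and the three lineage
branchings.  The four patterns are exocrine (Ptf1a), alpha (Brn4),
beta (MafA) and delta (DeltaGene); the counts are the stochastic lineage
proportions, which the model does not attempt to predict quantitatively.
"""

from collections import Counter

import panfate as pf

network = pf.build_master_network()
params = pf.ParameterSet()

ens = pf.simulate_ensemble(100, network, params, master_seed=1)
thr = pf.marker_thresholds(network, params)

counts = Counter(c.label for c in pf.classify_ensemble(ens, thr))
print("terminal cell types:", dict(counts))

n, patterns = pf.count_attractors(ens, thr)
print(f"{n} distinct marker patterns:", sorted(patterns))

for r in pf.detect_branchings(ens, thr):
    print(f"switch {r.switch_pair}: split={r.split_detected} "
          f"sizes={r.subpopulation_sizes} first seen t={r.detection_time}")
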