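"""In-silico knockouts: deleting one toggle gene removes its lineages.

Pax4 deletion leaves only exocrine and alpha cells (no beta/delta);
Arx deletion leaves exocrine, beta and delta (no alpha).  A noisy Pdx1
knockout (expression zero on average, fluctuations boosted) still reaches
all four marker-high fates, plus abnormal cells co-expressing several
markers -- the "hidden attractors" that survive loss of the master gene.
"""

from collections import Counter

import panfate as pf

network = pf.build_master_network()
params = pf.ParameterSet()
thr = pf.marker_thresholds(network, params)

for name in ("pax4_ko", "arx_ko", "pdx1_noisy_ko"):
    ens = pf.simulate_ensemble(100, network, params, pf.preset(name), master_seed=1)
    counts = Counter(c.label for c in pf.classify_ensemble(ens, thr))
    print(f"{name:15s} ->", dict(counts))
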