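"""Noise stability of the attractors and parameter robustness.

The noise scan parks cohorts at each attractor and raises the noise
magnitude D until cells spontaneously change type: attractors are stable at
the default D=0.05 and destabilize as D grows.  The parameter scan draws
log-uniform multipliers for the production rate a, degradation rate k and
weakening coefficient eta across two orders of magnitude and reports the
fraction of parameter sets that still produce all four cell types.
"""

import panfate as pf

network = pf.build_master_network()
params = pf.ParameterSet()

res = pf.noise_threshold_scan(n_cells=10, network=network, params=params,
                              master_seed=0)
print("switches per noise level:", res["switch_counts"])
print("smallest destabilizing D:", res["D_star"])

scan = pf.parameter_robustness_scan(n_samples=30, n_cells=20,
                                    network=network, params=params,
                                    master_seed=0)
print(f"robustness: {scan.success.sum()}/{len(scan.success)} parameter sets "
      f"produce all four cell types (fraction {scan.success_fraction:.2f})")
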