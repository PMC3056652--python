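# Methods

## The model

`panfate` describes pancreas lineage commitment as motion of a noisy
dynamical system whose stable fixed points are cell types.  The state is
an 11-vector: ten transcription factors (Hnf6, Pdx1, Ptf1a, Ngn3, Pax4,
Arx, MafA, a δ-cell placeholder factor "DeltaGene", Pax6, Brn4) and a
bookkeeping variable "maturation".  The backbone of the circuit is three
cross-inhibition toggle switches arranged hierarchically — Ptf1a↔Ngn3,
Pax4↔Arx, MafA↔DeltaGene — connected by documented activations: Hnf6
activates Pdx1, Ngn3 and Ptf1a; Ngn3 activates Pax6, Pax4 and Arx; Pax4
activates MafA and DeltaGene; Arx activates Brn4; MafA and Pax6 feed back
onto Pdx1; Pdx1 activates Pax4, Arx and MafA.  MafA, DeltaGene, Ptf1a,
Pax6 and Brn4 carry self-activation; Ngn3, Pax4 and Arx do not, which is
what makes them transient: they collapse once their upstream drive
disappears.  An "alternative" variant adds direct inhibition of Ptf1a and
Ngn3 by Pdx1.

Gene lumping follows the source literature (NeuroD/Isl1 read through Ngn3,
Mist1 through Ptf1a); it is documentation only — there are no extra nodes.

Every TF evolves as

    dx_i = [ a_i S_i(x) − k x_i ] dt + √(2D) dW_i ,

with reflection at zero implemented by clipping after each Euler–Maruyama
step.  The noise convention is ⟨ξ_i(t)ξ_j(t′)⟩ = 2D δ_ij δ(t−t′), so a
pure-decay gene has stationary variance D/k (this is pinned by a unit
test).  Noise acts on the ten TFs only; maturation is deterministic.

## The transfer function and its calibration

Production is a rational sigmoid

    S_i = N_i / (1 + N_i + I_i)

whose activator terms are η_i (x_j/χ_e)^m and whose inhibitor terms are
(x_j/χ_e)^4, plus a self-activation latch (x_i/x₀)^{m_s} for autoregulated
genes.  The printed kinetic constants are used unchanged: a = 2.2 for
Pdx1 and Hnf6, 6 for Pax4 and Arx, 4 otherwise; k = 1; η = 0.25 for
single-input genes and 0.125 for multi-input genes; regulatory Hill
exponent m = 4; maturity rate λ = 0.01.  The free elements of the rule —
the per-edge input scales χ_e, the latch shape, and the Hnf6 gate — were
calibrated once so that the circuit actually performs the decision
cascade.  Each choice answers a specific failure mode of the naive
uniform-scale form, observed in simulation:

* **Chain activations run saturated (χ = 1).**  With the source at its
  "on" level (≈ 3–6) the term η x⁴ is ≫ 1, so S sits on the flat top of
  the sigmoid and input fluctuations are strongly attenuated.  Operating
  these couplings near half-saturation instead amplifies noise ~4× per
  level and lets committed switches flip spontaneously.
* **Switch→marker couplings are high-threshold (χ = 2.9 on Pax4→MafA,
  Pax4→DeltaGene, Arx→Brn4).**  During a toggle race both members
  transiently reach ≈ 2–3 before mutual exclusion resolves; the marker
  latches must hear only the settled winner (≈ 4–6), not the race
  transient, or losers' bumps permanently ignite markers of the wrong
  lineage.
* **Pdx1's outgoing activations are high-threshold (χ = 3).**  At its
  physiological level (≈ 2) Pdx1 then has almost no influence on the
  decision circuits — consistent with its documented permissive role —
  while virus-level over-expression (> 4) transmits.  This also protects
  α cells: their Pax6-sustained Pdx1 would otherwise ignite MafA.
* **Within-pair inhibitions are unweighted with χ = 1.2.**  The toggle
  backbone must dominate: an established winner (≈ 4–6) pins the loser
  essentially to zero, while loser-side noise spikes (≲ 1) do not dent
  the winner (a smaller χ makes the switch hair-triggered, a larger one
  lets both members co-express).
* **Self-activation is a steep latch, (x/2.0)^10.**  Markers must ignite
  only above x ≈ 2 (protecting the off state against race transients and
  noise bursts) yet hold a deep on-state basin.  With production bounded
  by a = 4 and k = 1 the off- and on-basin depths trade off against each
  other; exponent 10 with half-engagement 2.0 approximately maximises the
  smaller of the two while remaining breakable — a sustained competing
  inhibition (e.g. Ngn3 ≈ 4 against Ptf1a during reprogramming) can still
  destroy the latched state, which a steeper latch cannot.
* **The Hnf6→Ptf1a trigger is sharp (exponent 8, χ = 1.55).**  Ptf1a owns
  a self-latch, so a soft drive biases the first race heavily toward the
  exocrine side; a sharp threshold just below the Hnf6 plateau (2.2)
  arms the trigger during the progenitor phase and disarms it early in
  the Hnf6 decay, preventing late Ptf1a re-ignition inside committed
  endocrine cells.
* **Hnf6 is a pure maturation gate, S = 1/(1+(x₁₁/0.7)^8).**  A basal
  term inside the shared denominator would cap Hnf6 at a/2 = 1.1, too low
  to drive the first switch; the gate holds the plateau at 2.2 and then
  shuts production sharply.  An extra-degradation alternative
  (−x₁₁·Hnf6) is available via `ParameterSet(hnf6_mode="degradation")`.

Maturation accumulates the saturating readout of the four terminal
markers, dx₁₁/dt = λ Σ_m x_m⁴/(1+x_m⁴) (bounded by 4λ, zero when all
markers are off, never decaying), and only Hnf6 listens to it.

Other functional forms with equivalent qualitative structure behave the
same; what matters is which couplings are saturated, which are
thresholded, and that the latches are steep.  None of the printed
constants were altered.

## Simulation defaults

dt = 0.01, save interval 0.5, ensemble size 100, D = 0.05, master seed 1.
The horizon is t_end = 400 model-time units: maturation (λ = 0.01) needs
roughly 250 units after the first markers appear to push x₁₁ past the
Hnf6 gate, and 400 units leaves Hnf6 below 10 % of its initial value with
all three branchings and the terminal patterns long settled.  Initial
condition: Hnf6 = Pdx1 = 2.2 (their uninhibited steady levels), all other
genes and maturation at zero.  Per-cell RNG streams are spawned from the
master seed (`numpy` SeedSequence), so ensembles are reproducible and
order-independent.

Deterministic attractors are located by relaxing archetype states (marker
high plus lineage support genes) with D = 0 until max |drift| < 10⁻⁶,
with the maturation clock frozen; non-convergence within 10·t_end is
flagged, not raised.  Classification thresholds are 50 % of each gene's
wild-type attractor level (≈ 2.0 for the markers), falling back to 1.0
for genes that are off in every attractor.  A cell is exocrine/α/β/δ if
exactly its lineage marker is on, progenitor if none is, abnormal if two
or more are.

## Perturbation protocols

Knockout clamps a gene to zero for the whole run.  The noisy knockout
removes a gene's production (zero mean, fluctuations remain) and raises
the global noise magnitude (default D_high = 0.2); a per-gene-only noise
boost is available.  Over-expression adds a constant gain inside a time
window; inhibition adds −d·x.  Defaults: window [0, 40], inhibition
d = 5, generic gain g = 5.  The reprogramming presets use per-gene doses:
Ngn3 4.0 (the conversion driver — its sustained inhibition is what breaks
the Ptf1a latch), Pdx1 0.5, Pax4 4.0, and a sub-latch boost of 0.3 for
self-latching marker genes.  Marker genes cannot be dosed above their
ignition threshold (≈ 2) without latching permanently in *every* cell,
which would erase the α by-product of the Pdx1+Ngn3+MafA recipe; the
small MafA boost instead tilts the MafA–δ switch toward β, which is also
why MafA-first staggering outperforms Pdx1-first.  Staggered protocols
open the gain windows at multiples of a 10-unit delay and close them
together.

## What the simulations do and do not show

All inputs are generated by the model itself; there is no external data.
The ensemble generator emulates a clonal population of identical,
non-interacting cells with intrinsic expression noise.  Real pancreas
development involves cell–cell signalling, proliferation and tissue
geometry, none of which is modelled — consequently the *proportions* of
cell types are stochastic artifacts of the noise realisation and are not
predictions; only the identity, stability and reachability of the
terminal patterns, the order and existence of the branchings, and the
qualitative responses to perturbations are meaningful.  Temporal profiles
are in arbitrary model time; only their shapes (transience of Ngn3/Pax4,
the Pdx1 dip-and-recovery, the gradual Hnf6 decay) are interpretable.

## Noise-stability threshold

The noise scan parks 25-cell cohorts at each of the four attractors,
simulates one additional developmental duration (t_end) at each D on the
grid {0.05, 0.1, 0.15, 0.2, 0.25, 0.3, 0.4}, and reports the smallest D
at which any cell changes its classified type.  Under the 2D·δ noise
convention the model's attractors are fully stable at D ≤ 0.1, show first
rare transitions at D = 0.15, and switch freely by D = 0.25–0.3.  The
basin-depth analysis above explains why the first-transition point cannot
be pushed much higher in this model family: with a = 4 and k = 1 the
marker latch's off- and on-basin depths sum to a bounded value, and the
measured optimum places the extreme-value threshold of a 100-cell,
400-unit exposure near D ≈ 0.15–0.2.  Note that the reported threshold
doubles if noise increments are read as √(D dt) rather than √(2D dt) —
the value is convention-bound, the qualitative picture (stability at the
operating point D = 0.05, order-of-magnitude 0.1–0.3 ceiling) is not.

## Parameter robustness

The scan multiplies all production rates, the degradation rate, and both
weakening coefficients by independent log-uniform factors spanning two
orders of magnitude (±1 decade), runs a reduced 30-cell ensemble per
sample, and flags success when all four cell types appear.  Because the
calibrated input scales χ are absolute, success requires the expression
scale a/k (and the η-compensated input strengths) to remain near the
design point, so the success region is a ridge around the default set
rather than the full cube; the default parameter set itself is always
included as sample 0.

## Known limitations

* Cell–cell interactions, proliferation and lineage proportions are out
  of scope.
* Rate constants are not fitted to experimental time courses; time is in
  arbitrary units.
* The δ-determining factor is a symmetry placeholder, not an identified
  gene.
* The exocrine attractor tolerates a latched Pax6 in a minority of cells
  whose first-switch resolution was slow (Pax6 is not a classification
  marker and has no downstream effect there beyond sustaining Pdx1, whose
  outputs are high-threshold).
* The alternative (Pdx1⊣Ptf1a/Ngn3) variant is calibrated only to run and
  to produce the four cell types; the published smoother temporal
  profiles of that variant are not reproduced quantitatively.
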