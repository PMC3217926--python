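# Methods

## The model

Integrin activation is modeled as a rule-based reaction system over six
molecule types — extracellular ligand (L), integrin (INT), talin (TAL),
Dok1 (DOK), Src kinase (SRC) and type-I PIP kinase (PIPKI) — in three
compartments: extracellular space (EC), plasma membrane (PM) and cytoplasm
(CP). Each molecule is a site-graph node: named binding sites, optional
internal states (phosphorylation `U/P`, conformation `O/C`, talin activity
`I/A`), and at most one bond per site. A species is a connected complex in a
single compartment; the rule set (`src/integrinsim/model/integrin.bngl`)
expands from the free-molecule seeds into a finite reaction network which is
compiled into mass-action ODEs.

The biological content of the rules:

* **Conformational equilibrium (R1).** Integrin flickers between a closed
  and an open conformation; closing requires a free ligand site and an
  NPxY motif not occupied by talin — ligand and talin, but not Dok1,
  stabilize the open state. Dok1-bound integrin closes with Dok1 aboard.
* **Ligand binding (R2)** to the open conformation only. With the default
  constants the ligand-held open fraction is deliberately small
  (`K1·L/KD2 ≈ 0.1`): ligand alone produces only weak sustained activation,
  so durable activation is talin-dependent, while ligand-bound integrins
  drive Src activation (R7a) and hence the downstream program.
* **NPxY engagement (R3/R4).** Talin (active, membrane-localized, not
  PIPKI-bound) and Dok1 compete for the single NPxY site of open integrin.
  Phosphorylation of the motif weakens talin binding 5-fold and strengthens
  Dok1 binding 400-fold. Binding requires the open conformation;
  dissociation is conformation-independent.
* **Src (R5–R9).** Src binds integrin tails and PIPKI through one SH
  module, only in its open conformation, and cannot close while bound.
  Ligand-bound integrins license Src trans-autophosphorylation (R7a); the
  inside-out protocol switches on ligand-independent cross-talk activation
  (R7b). Active Src phosphorylates PIPKI in Src:PIPKI complexes (R8) and
  the NPxY motif of the *open* integrin it rides on (R9) — a closed
  integrin's clamped tail and any bound talin/Dok1 shield the motif.
* **Talin/PIPKI scaffolding (R10).** PIPKI is a dimeric scaffold with two
  equivalent talin arms. Src and talin engage the same PIPKI tail region,
  so Src-bound PIPKI cannot scaffold talin (this is what lets high Src
  sequester PIPKI away from recruitment). Src phosphorylation of PIPKI
  enhances talin binding: the unphosphorylated scaffold binds `m10 = 20`
  fold more weakly, so PIPKI cycles through Src before being locked into
  talin complexes.
* **Talin activation (R11/R12).** Membrane talin in complex with
  phosphorylated PIPKI activates quickly; a small PIPKI-independent leak
  (~2% active at rest) exists; inactive talin cannot hold integrin, and
  integrin-bound talin cannot re-autoinhibit.
* **Dephosphorylation (R13–R15)** is first-order; bound Dok1 protects the
  phosphorylated motif (R15 needs a free site).
* **Membrane shuttling (R16/R17).** Monomeric talin, Dok1, monomeric PIPKI
  and the TAL:PIPKI 1:1 dimer partition weakly to the membrane; the
  TAL:PIPKI:TAL trimer partitions strongly (`K17b = 30`) — PIPKI
  multimerizes talin and thereby raises its effective membrane affinity.
  Complexes translocate as a unit; a Src-anchored complex cannot leave.

Expanding these rules yields **87 species and 363 reactions**. The study
this model reconstructs reports 108 species and 456/454 fluxes (the source
contradicts itself on the latter); the exact supplementary rule definitions
are not recoverable, and no semantically defensible variant of the recovered
rule set reproduces 108 exactly — the reachable state space changes in
multiples of the molecular state-space factors, and the variants that come
numerically closest violate the paper's described biology (see "Design
choices" below). The package reports its own counts.

## Compartment volume correction

State variables are species amounts on the cytoplasmic concentration scale
(V_CP = 1). Unimolecular reactions and translocations act on amounts, so
mass is conserved exactly; a bimolecular encounter is scaled by the inverse
of the collision volume — the membrane shell (V_PM = 0.01 by default) for a
PM-confined pair, the larger bulk phase for mixed encounters. Membrane
confinement therefore makes in-situ affinities V_PM-fold tighter than the
bulk KDs in the parameter table, which is the mechanism by which membrane
recruitment concentrates the signaling machinery.

## Parameters and uncertainty

`src/integrinsim/model/parameters.tsv` holds 38 entries; 33 are sampled
log-uniformly within ±2-, ±5- or ±10-fold of their base value (so values
below and above the base are equally likely), the rest are fixed. Reversible
bindings are parameterized by (KD, off-rate) with on = off/KD; conformational
and shuttling pairs by (equilibrium ratio, reverse rate).

The printed kinetic values of the original table are not recoverable from
the available text, so every kinetic base value is a documented
reconstruction (`provenance: reconstructed`). They were chosen so the model
reproduces the study's reported qualitative phenomenology — these are
calibration targets of the reconstruction, not test-fitting:

* ligand-driven opening on the second-to-minute scale, membrane recruitment
  and talin engagement on the minute-to-hour scale;
* only transient activation without talin (knockout phenotypes of both
  signaling modes);
* anticorrelated Dok1- vs talin-complex formation and positively correlated
  outside-in/inside-out capacity across the sampled ensemble;
* sustained (non-adapting) open-integrin responses in all samples;
* bell-shaped dependence of activation and talin recruitment on total
  PIPKI, with the activation optimum at lower PIPKI than the recruitment
  optimum.

The totals rows map the published values onto molecules as INT = 15 µM and
SRC = 40 µM (fixed), DOK = TAL = 1 µM, PIPKI = 0.5 µM and L = 25 µM
(each sampled 10-fold). The anchors for this assignment: group-level shifts
in relative talin abundance require talin's total to be a *sampled*
parameter; the activation fraction rises to near-maximal at 10 µM talin
(top of the sampled decade); the Dok/talin switching point sits at ratio ≈ 1,
i.e. equal base values; Src is scanned rather than sampled and must be
abundant enough to sequester PIPKI at the membrane. The mapping lives in the
parameter file and can be corrected without code changes.

## Protocols and criteria

The ground state (GS) is the steady state without ligand or cross-talk
activation, found by step-doubling stiff integration until
‖dy/dt‖∞ < 1e-9·max(y) (100 h cap). Outside-in (OI) adds a ligand bolus to
the GS; inside-out (IO) enables rule R7b instead. Trajectories are recorded
on a 200-point log grid from 1 s to 10 h and the final state is refined to
steady state. LSODA with an analytic Jacobian integrates the system
(~10–30 ms per run); a pure-python fallback exists if numba is absent.

Eight criteria summarize one parameter set (all fractions of the relevant
total, evaluated at steady state; the printed formulas in the source are
corrupted and these reconstructions follow the verbal definitions): Dok1-
and talin-complex formation (c1, c2), PIPKI-dependent talin recruitment and
talin-dependent PIPKI recruitment via knockout differences (c3, c4), PIPKI
and integrin phosphorylation (c5, c6), and open-integrin fractions under OI
and IO (c7, c8). Five runs feed them: GS, OI, IO, and OI after talin/PIPKI
knockout (each knockout from its own ground state).

Transient responses are characterized by sensitivity
`S = |X_peak − X_GS| / max(X_GS, ε)` (peak within 1 h of stimulation) and
precision `P = |X_peak − X_GS| / max(|X_ss − X_GS|, ε)` with ε = 1e-6 and a
cap of 1e6 for perfect adaptation. A *transient* response has high S and
high P; *sustained* responses have P near 1; low-S samples are unresponsive,
and their P is uninformative (the sustained-activation check therefore
considers samples with S > 1).

## Ensemble, groups and ranking

Parameters are drawn independently per sample (`numpy` PCG64, explicit
seed); the battery runs per row and failures are flagged, never fabricated.
Convergence of ensemble means uses a blocking procedure (equal blocks,
coefficient of variation of block means per time point, threshold 1%
by default); time-course spreads are summarized by pointwise
2.5/25/50/75/97.5 percentiles. The default analysis size is 2,000 samples
(~8 minutes on one CPU); the production-scale 1e5 run of the original study
is reproducible through the CLI by raising `--n`.

Groups are the top 2% of valid samples by c2 (group 1) and by c1 (group 2),
with deterministic tie-breaking. For every sampled parameter three
Kolmogorov–Smirnov distances are computed — each group against the *analytic*
log-uniform sampling CDF (the law is known exactly, removing one layer of
noise; an ECDF-vs-ECDF mode exists behind a flag) and group 1 against
group 2 — and parameters are ranked by the maximum of the three.
Characteristic group parameter sets are geometric means (the centroid on
the sampling's log scale; arithmetic mean available by flag).

## Design choices on genuinely open points

* **Competition context.** Talin's integrin (ptb) and PIPKI (pipk)
  engagements are mutually exclusive, as are Src's and talin's engagement
  of PIPKI. Without the first, network expansion diverges combinatorially
  (≈800 species); without the second, Src-anchored talin:PIPKI complexes
  pin talin at the membrane and the recruitment bell curve cannot exist.
* **Dissociation contexts are minimal.** Off-rules carry only the bond.
  Requiring the open conformation for Dok1 release (the naive reversal of
  the binding rule) turns Dok1-bound closed integrin into an absorbing sink
  and makes Dok1-complex formation a trivial function of Dok1 abundance.
* **R9 requires the open conformation**: tail separation exposes the NPxY
  motif; this is what makes talin shielding (and hence the phosphorylation
  switch) effective.
* **Rule R7b** is enabled only in the inside-out protocol (its rate is 0
  otherwise), implementing cross-talk Src activation without ligand.
* **Thermodynamic closure**: ligand binds only the open conformation and
  blocks closing; the resulting ligand-held pool is equilibrium-limited
  (≈ K1·L/KD2), which plays the role of a weak-affinity cycle without
  enlarging the state space.
* **Numerics.** rtol 1e-8 / atol 1e-10; steady-state residual tolerance
  1e-9·max(y); trajectories clipped at zero with a warning beyond solver
  tolerance; mass conservation asserted per run at 1e-6 relative; integrator
  failures retry with larger step budgets and an internally estimated
  Jacobian before flagging the sample invalid.

## What the generator emulates — and what it does not

The sampler reproduces the study's uncertainty treatment exactly (fold
classes, log-uniform marginals, independence). It does not emulate real
biological variation beyond that: no correlation between parameters, no
cell-to-cell variability structure, no measurement noise on observables.
Tests passing on this ensemble show that the *model* behaves as described
across its documented uncertainty range, not that real cells do.

## Known limitations

* Kinetic base values are reconstructions; quantitative magnitudes
  (e.g. exact criterion values, scatter geometry) are not comparable to the
  original figures — only signs, orderings and qualitative shapes are.
* The ensemble-wide anticorrelation between Dok1- and talin-complex
  formation is weak (Spearman ≈ −0.1 at the shipped defaults); its sign is
  stable at n = 2000 but the magnitude depends on unrecoverable kinetics.
* The two signaling modes reach steady activation within about a factor of
  two of each other under group-1 parameters, short of the "similar extent"
  being a 20% match; the ratio depends strongly on the sampled kinetics of
  the characteristic set.
* Spatial PIP2 diffusion, protein turnover, integrin clustering geometry,
  kindlin and Rap1/RIAM recruitment are outside the model's scope, as in
  the source study; stochastic (SSA) simulation is not implemented.
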