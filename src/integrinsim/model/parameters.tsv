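# Parameter table for the integrin activation model.
# role: equilibrium-constant | off-rate | first-order-rate | total-concentration
# fold: sampling half-range on the log scale ("fixed" = never perturbed);
#       sampled values lie in [value/fold, value*fold], log-uniformly.
# evidence: *** measured, ** inferred from data, * plausible background value.
# provenance: "reconstructed" marks base values that are this package's
# documented reconstructions, chosen so that the model reproduces the
# qualitative behaviors the study reports: ligand-driven opening on the
# second-to-minute scale with only transient activation in the absence of
# talin, talin recruitment/engagement on the minute-to-hour scale, a
# phosphorylation switch in which talin shields and Dok1 locks the NPxY
# motif (400-fold affinity gain on phosphorylation, 5-fold talin loss), and
# PIPKI-dependent talin activation with sequestration at high PIPKI.
# "assigned" marks the totals mapping of the published concentration values
# onto molecules (see docs/methods.md for the anchors used).
# Equilibrium constants for conformational/shuttling pairs are dimensionless
# ratios (forward rate = K * reverse rate); binding KDs are in uM on the
# bulk scale (on-rate = off-rate / KD; membrane confinement makes the
# effective in-situ affinity V_PM-fold tighter).
symbol	role	value	fold	evidence	provenance	rule_ids	description
K1	equilibrium-constant	0.015	2	**	reconstructed	R1	open/closed equilibrium of unliganded integrin (basal open fraction ~1.5%)
k1c	off-rate	10.0	10	*	reconstructed	R1	integrin closing rate [1/s]
KD2	equilibrium-constant	5.0	fixed	***	reconstructed	R2	integrin/ligand KD [uM]
koff2	off-rate	1.0	10	*	reconstructed	R2	ligand off-rate [1/s]
KD3a	equilibrium-constant	0.5	2	**	reconstructed	R3a	integrin/talin KD, unphosphorylated NPxY [uM]
koff3a	off-rate	0.1	10	*	reconstructed	R3a,R4a	talin off-rate [1/s]
KD3b	equilibrium-constant	120.0	2	**	reconstructed	R3b	integrin/Dok1 KD, unphosphorylated NPxY [uM]
koff3b	off-rate	0.1	10	*	reconstructed	R3b,R4b	Dok1 off-rate [1/s]
KD4a	equilibrium-constant	2.5	2	**	reconstructed	R4a	integrin/talin KD, phospho-NPxY (5x weaker than KD3a) [uM]
KD4b	equilibrium-constant	0.3	2	**	reconstructed	R4b	integrin/Dok1 KD, phospho-NPxY (400x tighter than KD3b) [uM]
K5	equilibrium-constant	0.5	fixed	***	reconstructed	R5	open/closed equilibrium of Src
k5c	off-rate	1.0	10	*	reconstructed	R5	Src closing rate [1/s]
KD6	equilibrium-constant	1.0	5	**	reconstructed	R6a,R6b	Src SH-domain KD for integrin tails and PIPKI [uM]
koff6	off-rate	1.0	10	*	reconstructed	R6a,R6b	Src off-rate [1/s]
k7	first-order-rate	1.0	5	**	reconstructed	R7a,R7b	Src trans-autophosphorylation rate [1/s]
k8	first-order-rate	0.5	5	**	reconstructed	R8	PIPKI phosphorylation rate by bound Src [1/s]
k9	first-order-rate	1.0	5	**	reconstructed	R9	integrin NPxY phosphorylation rate by bound Src [1/s]
KD10	equilibrium-constant	0.1	2	**	reconstructed	R10	talin/PIPKI KD, phosphorylated PIPKI [uM]
koff10	off-rate	0.05	10	*	reconstructed	R10	talin/PIPKI off-rate [1/s]
m10	equilibrium-constant	20.0	fixed	*	reconstructed	R10	fold weakening of talin/PIPKI binding for unphosphorylated PIPKI
k11a	first-order-rate	1.0	5	*	reconstructed	R11a	PIPKI-dependent talin activation rate [1/s]
k11b	first-order-rate	0.0002	5	*	reconstructed	R11b	PIPKI-independent talin activation leak [1/s]
k12	first-order-rate	0.01	2	***	reconstructed	R12	talin deactivation (autoinhibition re-engagement) [1/s]
k13	first-order-rate	0.02	5	*	reconstructed	R13	Src dephosphorylation rate [1/s]
k14	first-order-rate	0.01	5	*	reconstructed	R14	PIPKI dephosphorylation rate [1/s]
k15	first-order-rate	0.003	5	*	reconstructed	R15	integrin NPxY dephosphorylation rate [1/s]
K16	equilibrium-constant	0.5	2	**	reconstructed	R16a,R16b,R16c	membrane/cytoplasm partition of talin and Dok1
k16off	off-rate	0.01	10	*	reconstructed	R16a,R16b,R16c	talin/Dok1 membrane detachment rate [1/s]
K17a	equilibrium-constant	0.3	5	**	reconstructed	R17a	membrane/cytoplasm partition of monomeric PIPKI
k17aoff	off-rate	0.01	10	*	reconstructed	R17a	PIPKI membrane detachment rate [1/s]
K17b	equilibrium-constant	30.0	5	**	reconstructed	R17b	membrane/cytoplasm partition of the TAL:PIPKI:TAL trimer
k17boff	off-rate	0.01	10	*	reconstructed	R17b	trimer membrane detachment rate [1/s]
INT_tot	total-concentration	15.0	fixed	***	assigned	-	total integrin [uM]
SRC_tot	total-concentration	40.0	fixed	***	assigned	-	total Src [uM]
DOK_tot	total-concentration	1.0	10	*	assigned	-	total Dok1 [uM]
TAL_tot	total-concentration	1.0	10	*	assigned	-	total talin [uM]
PIPKI_tot	total-concentration	0.5	10	*	assigned	-	total PIPKI [uM]
L_tot	total-concentration	25.0	10	*	assigned	-	ligand amount applied in outside-in runs [uM]
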