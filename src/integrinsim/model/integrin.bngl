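# Rule-based model of integrin activation: ligand (L), integrin (INT),
# talin (TAL), Dok1 (DOK), Src kinase (SRC) and PIP kinase type I (PIPKI)
# across extracellular (EC), plasma-membrane (PM) and cytoplasmic (CP)
# compartments.  Rates are expressions over the symbols defined in
# parameters.tsv; reversible bindings use on = off/KD.
#
# Context conventions encoded below (see docs/methods.md for rationale):
#  - ligand and talin, but not Dok1, stabilize the open integrin
#    conformation: closing (R1c*) requires a free lig site and an npxy site
#    that is not talin-bound; Dok1 stays bound when the integrin closes.
#  - talin's integrin (ptb) and PIPKI (pipk) engagements are competitive:
#    R3a/R4a require a free pipk site, R10 requires a free ptb site.
#  - Src binds via its SH domain only in the open conformation and cannot
#    close while bound; catalytic rules require an open, phosphorylated Src.
#  - bound talin cannot deactivate (R12 requires a free ptb site).
#  - membrane shuttling moves whole complexes and requires a free PIPKI sh
#    site (a Src-anchored complex cannot leave the membrane).

begin compartments
  EC 1.0
  PM 0.01
  CP 1.0
end compartments

begin molecule types
  L(int) @EC
  INT(lig,npxy~U~P,src,conf~O~C) @PM
  TAL(ptb,pipk,act~I~A) @CP,PM
  DOK(ptb) @CP,PM
  SRC(sh,phos~U~P,conf~O~C) @PM
  PIPKI(tal1,tal2,sh,phos~U~P) @CP,PM symmetric{tal1,tal2}
end molecule types

begin seed species
  L(int)@EC                        L_tot
  INT(lig,npxy~U,src,conf~C)@PM    INT_tot
  TAL(ptb,pipk,act~I)@CP           TAL_tot
  DOK(ptb)@CP                      DOK_tot
  SRC(sh,phos~U,conf~C)@PM         SRC_tot
  PIPKI(tal1,tal2,sh,phos~U)@CP    PIPKI_tot
end seed species

begin observables
  openINT    INT(conf~O)
  INT_P      INT(npxy~P)
  INT_L      INT(lig!+)
  INT_DOK    INT(npxy!1).DOK(ptb!1)
  INT_TAL    INT(npxy!1).TAL(ptb!1)
  TAL_PM     TAL()@PM
  PIPKI_PM   PIPKI()@PM
  PIPKI_P    PIPKI(phos~P)
  SRC_P      SRC(phos~P)
end observables

begin reaction rules
  # integrin conformation (R1): opening unconditional; closing requires a
  # ligand-free and talin-free integrin (Dok1-bound closing is allowed)
  R1o:   INT(conf~C) -> INT(conf~O)                                K1*k1c
  R1c:   INT(lig,npxy,conf~O) -> INT(lig,npxy,conf~C)              k1c
  R1cd:  INT(lig,npxy!1,conf~O).DOK(ptb!1) -> INT(lig,npxy!1,conf~C).DOK(ptb!1)  k1c

  # ligand binding (R2): open conformation only
  R2:    L(int) + INT(lig,conf~O) <-> L(int!1).INT(lig!1,conf~O)   koff2/KD2, koff2

  # talin / Dok1 binding to the unphosphorylated NPxY motif (R3); binding
  # requires the open conformation, dissociation is conformation-independent
  # (a closed integrin releases Dok1 at the same off-rate), so the reverse
  # rules carry only the bond.  Off-rates are shared between the U- and
  # P-motif (the KD difference lives in the on-rates).
  R3a:   TAL(ptb,pipk,act~A)@PM + INT(npxy~U,conf~O) -> TAL(ptb!1,pipk,act~A).INT(npxy~U!1,conf~O)  koff3a/KD3a
  R3b:   DOK(ptb)@PM + INT(npxy~U,conf~O) -> DOK(ptb!1).INT(npxy~U!1,conf~O)                        koff3b/KD3b
  R3a_r: TAL(ptb!1).INT(npxy!1) -> TAL(ptb) + INT(npxy)   koff3a
  R3b_r: DOK(ptb!1).INT(npxy!1) -> DOK(ptb) + INT(npxy)   koff3b

  # talin / Dok1 binding to the phosphorylated NPxY motif (R4); released by
  # the shared R3a_r/R3b_r off-rules
  R4a:   TAL(ptb,pipk,act~A)@PM + INT(npxy~P,conf~O) -> TAL(ptb!1,pipk,act~A).INT(npxy~P!1,conf~O)  koff3a/KD4a
  R4b:   DOK(ptb)@PM + INT(npxy~P,conf~O) -> DOK(ptb!1).INT(npxy~P!1,conf~O)                        koff3b/KD4b

  # Src conformation (R5): closing requires a free SH domain
  R5o:   SRC(conf~C) -> SRC(conf~O)                                K5*k5c
  R5c:   SRC(sh,conf~O) -> SRC(sh,conf~C)                          k5c

  # Src binding to integrin tails / PIPKI (R6); open Src only
  R6a:   SRC(sh,conf~O) + INT(src) <-> SRC(sh!1,conf~O).INT(src!1)         koff6/KD6, koff6
  # Src engages the PIPKI tail region that talin also binds: Src-bound
  # PIPKI cannot scaffold talin and vice versa (Src sequestration of PIPKI
  # attenuates its talin-recruiting role)
  R6b:   SRC(sh,conf~O) + PIPKI(sh,tal1,tal2)@PM <-> SRC(sh!1,conf~O).PIPKI(sh!1,tal1,tal2)    koff6/KD6, koff6

  # Src activation (R7): ligand-bound integrins proxy juxta-position (7a);
  # cross-talk activation (7b) is switched on only for inside-out runs
  R7a:   SRC(phos~U,conf~O,sh!1).INT(src!1,lig!2).L(int!2) -> SRC(phos~P,conf~O,sh!1).INT(src!1,lig!2).L(int!2)  k7
  R7b:   SRC(phos~U,conf~O) -> SRC(phos~P,conf~O)                  k7b

  # Src-mediated phosphorylation of PIPKI (R8) and integrin tails (R9);
  # a bound NPxY motif is shielded from phosphorylation
  R8:    PIPKI(phos~U,sh!1).SRC(sh!1,phos~P,conf~O) -> PIPKI(phos~P,sh!1).SRC(sh!1,phos~P,conf~O)    k8
  # NPxY phosphorylation needs the open conformation (separated tails expose
  # the motif) and a free npxy site (talin/Dok1 binding shields it)
  R9:    INT(npxy~U,src!1,conf~O).SRC(sh!1,phos~P,conf~O) -> INT(npxy~P,src!1,conf~O).SRC(sh!1,phos~P,conf~O)  k9

  # talin/PIPKI scaffolding (R10): either arm of the dimeric scaffold;
  # integrin-bound talin is not available (competitive ptb engagement)
  # Src phosphorylation of the PIPKI tail enhances talin binding: the
  # unphosphorylated scaffold binds m10-fold more weakly, so PIPKI cycles
  # through Src before it is locked into talin complexes
  R10u:  TAL(ptb,pipk) + PIPKI(tal1,sh,phos~U) <-> TAL(ptb,pipk!1).PIPKI(tal1!1,sh,phos~U)     koff10/(KD10*m10), koff10
  R10p:  TAL(ptb,pipk) + PIPKI(tal1,sh,phos~P) <-> TAL(ptb,pipk!1).PIPKI(tal1!1,sh,phos~P)     koff10/KD10, koff10

  # talin activation (R11): PIPKI-dependent (active, membrane PIPKI) and a
  # small PIPKI-independent leak; deactivation (R12) only off integrin
  R11a:  TAL(act~I,pipk!1).PIPKI(tal1!1,phos~P)@PM -> TAL(act~A,pipk!1).PIPKI(tal1!1,phos~P)@PM  k11a
  R11b:  TAL(act~I)@PM -> TAL(act~A)@PM                            k11b
  R12:   TAL(ptb,act~A) -> TAL(ptb,act~I)                          k12

  # dephosphorylation (R13-R15); bound Dok1 protects phospho-NPxY
  R13:   SRC(phos~P) -> SRC(phos~U)                                k13
  R14:   PIPKI(phos~P) -> PIPKI(phos~U)                            k14
  R15:   INT(npxy~P) -> INT(npxy~U)                                k15

  # membrane shuttling (R16/R17): monomeric talin and Dok1, the talin:PIPKI
  # heterodimer (same rates), monomeric PIPKI, and the TAL:PIPKI:TAL trimer
  # with its own (multimerization-enhanced) rate pair
  R16a:  TAL(ptb,pipk)@CP <-> TAL(ptb,pipk)@PM                     K16*k16off, k16off
  R16b:  TAL(ptb,pipk!1).PIPKI(tal1!1,tal2,sh)@CP <-> TAL(ptb,pipk!1).PIPKI(tal1!1,tal2,sh)@PM  K16*k16off, k16off
  R16c:  DOK(ptb)@CP <-> DOK(ptb)@PM                               K16*k16off, k16off
  R17a:  PIPKI(tal1,tal2,sh)@CP <-> PIPKI(tal1,tal2,sh)@PM         K17a*k17aoff, k17aoff
  R17b:  TAL(ptb,pipk!1).PIPKI(tal1!1,tal2!2,sh).TAL(ptb,pipk!2)@CP <-> TAL(ptb,pipk!1).PIPKI(tal1!1,tal2!2,sh).TAL(ptb,pipk!2)@PM  K17b*k17boff, k17boff
end reaction rules
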