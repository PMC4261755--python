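# synthetic_egfr — a synthetic reconstruction of the classic EGFR signaling
# rule-based model (egf / egfr / Grb2 / Shc / Sos with receptor dimerization,
# transphosphorylation, and adaptor recruitment).  Written for this package's
# test suite: 24 reaction rules that compress to a contact map with 5 molecule
# nodes, 6 binding edges, and 3 modifiable components.
begin model
begin parameters
  egf_tot   1.2e6
  egfr_tot  1.8e5
  kp1 1.667e-06
  km1 0.06
  kp2 5.556e-06
  km2 0.1
  kp3 0.5
  km3 4.505
  kp4 8.333e-07
  km4 0.05
  kp5 5.556e-06
  km5 0.06
  kp6 4.167e-07
  km6 0.3
  kp7 3.0
  km7 0.03
  kp8 8.333e-07
  km8 0.05
  kp9 5.556e-06
  km9 0.0214
  km10 0.1
end parameters
begin molecule types
  egf(r)
  egfr(l,r,Y1068~U~P,Y1148~U~P)
  Grb2(SH2,SH3)
  Shc(PTB,Y317~U~pY)
  Sos(dom)
end molecule types
begin seed species
  egf(r)                          egf_tot
  egfr(l,r,Y1068~U,Y1148~U)       egfr_tot
  Grb2(SH2,SH3)                   1.0e5
  Shc(PTB,Y317~U)                 2.7e5
  Sos(dom)                        1.3e5
end seed species
begin observables
  Molecules  Dimers      egfr(r!1).egfr(r!1)
  Molecules  RP          egfr(Y1068~P), egfr(Y1148~P)
  Molecules  ShcP        Shc(Y317~pY)
  Molecules  Sos_act     Grb2(SH3!1).Sos(dom!1)
end observables
begin reaction rules
  # ligand binding and receptor dimerization
  egf(r) + egfr(l,r) <-> egf(r!1).egfr(l!1,r)                                    kp1, km1
  egfr(l!+,r) + egfr(l!+,r) <-> egfr(l!+,r!1).egfr(l!+,r!1)                      kp2, km2
  # transphosphorylation within a dimer, dephosphorylation off it
  egfr(r!+,Y1068~U) -> egfr(r!+,Y1068~P)                                         kp3
  egfr(r!+,Y1148~U) -> egfr(r!+,Y1148~P)                                         kp3
  egfr(r,Y1068~P) -> egfr(r,Y1068~U)                                             km3
  egfr(r,Y1148~P) -> egfr(r,Y1148~U)                                             km3
  # Grb2 recruitment to phosphorylated Y1068, with or without Sos in tow
  egfr(Y1068~P) + Grb2(SH2,SH3) <-> egfr(Y1068~P!1).Grb2(SH2!1,SH3)              kp4, km4
  egfr(Y1068~P) + Grb2(SH2,SH3!+) <-> egfr(Y1068~P!1).Grb2(SH2!1,SH3!+)          kp4, km4
  # Grb2-Sos association, cytosolic and membrane-recruited
  Grb2(SH2,SH3) + Sos(dom) <-> Grb2(SH2,SH3!1).Sos(dom!1)                        kp5, km5
  Grb2(SH2!+,SH3) + Sos(dom) <-> Grb2(SH2!+,SH3!1).Sos(dom!1)                    kp5, km5
  # Shc recruitment to phosphorylated Y1148 in either phosphoform
  egfr(Y1148~P) + Shc(PTB,Y317~U) <-> egfr(Y1148~P!1).Shc(PTB!1,Y317~U)          kp6, km6
  egfr(Y1148~P) + Shc(PTB,Y317~pY) <-> egfr(Y1148~P!1).Shc(PTB!1,Y317~pY)        kp6, km6
  # Shc phosphorylation cycle
  Shc(PTB!+,Y317~U) -> Shc(PTB!+,Y317~pY)                                        kp7
  Shc(PTB,Y317~pY) -> Shc(PTB,Y317~U)                                            km7
  # Grb2 binding phosphorylated Shc, free or receptor-bound
  Shc(Y317~pY) + Grb2(SH2,SH3) <-> Shc(Y317~pY!1).Grb2(SH2!1,SH3)                kp8, km8
  Shc(Y317~pY) + Grb2(SH2,SH3!+) <-> Shc(Y317~pY!1).Grb2(SH2!1,SH3!+)            kp8, km8
  Shc(PTB!+,Y317~pY) + Grb2(SH2,SH3) <-> Shc(PTB!+,Y317~pY!1).Grb2(SH2!1,SH3)    kp8, km8
  Shc(PTB!+,Y317~pY) + Grb2(SH2,SH3!+) <-> Shc(PTB!+,Y317~pY!2).Grb2(SH2!2,SH3!+) kp8, km8
  # Sos binding Shc-anchored Grb2
  Shc(Y317~pY!1).Grb2(SH2!1,SH3) + Sos(dom) <-> Shc(Y317~pY!1).Grb2(SH2!1,SH3!2).Sos(dom!2) kp9, km9
  # receptor-bound Shc dephosphorylation
  egfr(r!+,Y1148~P!1).Shc(PTB!1,Y317~pY) -> egfr(r!+,Y1148~P!1).Shc(PTB!1,Y317~U) km7
  # adaptor release coupled to dephosphorylation
  egfr(Y1068~P!1).Grb2(SH2!1) -> egfr(Y1068~U) + Grb2(SH2)                       km10
  egfr(Y1148~P!1).Shc(PTB!1) -> egfr(Y1148~U) + Shc(PTB)                         km10
  # ligand release from monomeric receptor, dimer dissociation
  egf(r!1).egfr(l!1,r) -> egf(r) + egfr(l,r)                                     km1
  egfr(r!1,Y1068~U,Y1148~U).egfr(r!1,Y1068~U,Y1148~U) -> egfr(r,Y1068~U,Y1148~U) + egfr(r,Y1068~U,Y1148~U) km2
end reaction rules
end model
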