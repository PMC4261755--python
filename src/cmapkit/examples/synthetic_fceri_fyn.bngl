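# synthetic_fceri_fyn — synthetic_fceri_base plus the Fyn kinase docking
# on the phosphorylated receptor beta chain.
# Derived from a synthetic reconstruction in the style of the
# classic FceRI (high-affinity IgE receptor) rule-based model: a bivalent
# ligand aggregating receptors, Lyn kinase docking on the receptor beta
# chain, and Syk recruitment to the phosphorylated gamma chain.
begin model
begin parameters
  kp1 1.3e-7
  km1 0.01
  kp2 2.5e-1
  km2 0.01
  kpL 5.0e-2
  kmL 20.0
  kpLs 3.0e-2
  kmLs 0.25
  kpS 6.0e-2
  kmS 0.13
  pLb 30.0
  pLg 1.0
  pS  100.0
  dm  20.0
  dS  0.1
end parameters
begin molecule types
  Lig(l,l)
  Fyn(SH2)
  Lyn(U,SH2)
  Rec(a,b~Y~pY,g~Y~pY)
  Syk(tSH2,a~Y~pY)
end molecule types
begin seed species
  Lig(l,l)           6.0e3
  Fyn(SH2)           2.0e4
  Lyn(U,SH2)         2.8e4
  Rec(a,b~Y,g~Y)     4.0e2
  Syk(tSH2,a~Y)      4.0e2
end seed species
begin observables
  Molecules  RecPbeta   Rec(b~pY)
  Molecules  RecPgamma  Rec(g~pY)
  Molecules  RecSyk     Rec(g~pY!1).Syk(tSH2!1)
  Molecules  RecSykPS   Rec(g~pY!1).Syk(tSH2!1,a~pY)
end observables
begin reaction rules
  # ligand capture and receptor cross-linking through the same arm site
  Lig(l,l) + Rec(a) <-> Lig(l!1,l).Rec(a!1)            kp1, km1
  Lig(l,l!+) + Rec(a) <-> Lig(l!1,l!+).Rec(a!1)        kp2, km2
  # Lyn constitutive docking on unphosphorylated beta
  Rec(b~Y) + Lyn(U,SH2) <-> Rec(b~Y!1).Lyn(U!1,SH2)    kpL, kmL
  # transphosphorylation in aggregates, dephosphorylation
  Rec(a!+,b~Y) -> Rec(a!+,b~pY)                        pLb
  Rec(a!+,g~Y) -> Rec(a!+,g~pY)                        pLg
  Rec(b~pY) -> Rec(b~Y)                                dm
  Rec(g~pY) -> Rec(g~Y)                                dm
  # Lyn SH2 docking on phosphorylated beta
  Rec(b~pY) + Lyn(U,SH2) <-> Rec(b~pY!1).Lyn(U,SH2!1)  kpLs, kmLs
  # Fyn SH2 docking on phosphorylated beta
  Rec(b~pY) + Fyn(SH2) <-> Rec(b~pY!1).Fyn(SH2!1)      kpLs, kmLs
  # Syk recruitment to phosphorylated gamma and its activation cycle
  Rec(g~pY) + Syk(tSH2) <-> Rec(g~pY!1).Syk(tSH2!1)    kpS, kmS
  Syk(tSH2!+,a~Y) -> Syk(tSH2!+,a~pY)                  pS
  Syk(a~pY) -> Syk(a~Y)                                dS
end reaction rules
end model
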