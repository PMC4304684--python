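# Salt screen: final concentrations after 1:1 mixing with protein+dye.
# A1-A3 are water blanks used as the reference.
# C7 '5 mM GuHCl' and 'Na2NO3' are transcribed verbatim from the
# source table (possible typos there; not silently corrected).
well,component,concentration,unit,ph25,dpka_per_degc,role
A1,,,,,,reference
A2,,,,,,reference
A3,,,,,,reference
A4,SDS,5,mM,,,sample
A5,urea,4.5,M,,,sample
A6,urea,0.5,M,,,sample
A7,ammonium sulfate,1.5,M,,,sample
A8,ammonium sulfate,1.0,M,,,sample
A9,ammonium sulfate,0.8,M,,,sample
A10,ammonium sulfate,0.6,M,,,sample
A11,ammonium sulfate,0.4,M,,,sample
A12,ammonium sulfate,0.2,M,,,sample
B1,NaCl,1.5,M,,,sample
B2,NaCl,1.0,M,,,sample
B3,NaCl,0.8,M,,,sample
B4,NaCl,0.6,M,,,sample
B5,NaCl,0.4,M,,,sample
B6,NaCl,0.2,M,,,sample
B7,NH4Cl,1.5,M,,,sample
B8,NH4Cl,1.0,M,,,sample
B9,NH4Cl,0.8,M,,,sample
B10,NH4Cl,0.6,M,,,sample
B11,NH4Cl,0.4,M,,,sample
B12,NH4Cl,0.2,M,,,sample
C1,malonate,1.5,M,,,sample
C2,malonate,1.0,M,,,sample
C3,malonate,0.8,M,,,sample
C4,malonate,0.6,M,,,sample
C5,malonate,0.4,M,,,sample
C6,malonate,0.2,M,,,sample
C7,GuHCl,5,mM,,,sample
C8,GuHCl,1.0,M,,,sample
C9,GuHCl,0.8,M,,,sample
C10,GuHCl,0.6,M,,,sample
C11,GuHCl,0.4,M,,,sample
C12,GuHCl,0.2,M,,,sample
D1,MgSO4,1.0,M,,,sample
D2,MgSO4,0.8,M,,,sample
D3,MgSO4,0.6,M,,,sample
D4,MgSO4,0.4,M,,,sample
D5,MgSO4,0.2,M,,,sample
D6,Na2SO4,1.0,M,,,sample
D7,Na2SO4,0.8,M,,,sample
D8,Na2SO4,0.6,M,,,sample
D9,Na2SO4,0.4,M,,,sample
D10,Na2SO4,0.2,M,,,sample
D11,KCl,0.5,M,,,sample
D12,KCl,0.2,M,,,sample
E1,LiCl,0.5,M,,,sample
E2,LiCl,0.2,M,,,sample
E3,RbCl,0.5,M,,,sample
E4,RbCl,0.2,M,,,sample
E5,CsCl,0.5,M,,,sample
E6,CsCl,0.2,M,,,sample
E7,NaF,0.4,M,,,sample
E8,NaF,0.1,M,,,sample
E9,NaBr,0.4,M,,,sample
E10,NaBr,0.1,M,,,sample
E11,NaI,0.4,M,,,sample
E12,NaI,0.1,M,,,sample
F1,sodium formate,0.5,M,,,sample
F2,sodium formate,0.2,M,,,sample
F3,sodium malate,0.5,M,,,sample
F4,sodium malate,0.2,M,,,sample
F5,Na2NO3,0.5,M,,,sample
F6,Na2NO3,0.2,M,,,sample
F7,sodium citrate,0.5,M,,,sample
F8,sodium citrate,0.2,M,,,sample
F9,sodium lactate,0.5,M,,,sample
F10,sodium lactate,0.2,M,,,sample
F11,sodium acetate,0.5,M,,,sample
F12,sodium acetate,0.2,M,,,sample
G1,MgCl2,0.4,M,,,sample
G2,MgCl2,5,mM,,,sample
G3,CaCl2,5,mM,,,sample
G4,SrCl2,5,mM,,,sample
G5,ZnCl2,1,mM,,,sample
G6,NiCl2,1,mM,,,sample
G7,CoCl2,1,mM,,,sample
G8,CuSO4,1,mM,,,sample
G9,MgCl2,1,mM,,,sample
G9,CaCl2,1,mM,,,sample
G9,ZnCl2,1,mM,,,sample
G10,MnCl2,5,mM,,,sample
G11,EDTA,5,mM,8.0,,sample
G12,EGTA,5,mM,8.9,,sample
H1,Na2HPO4,5,mM,,,sample
H2,Na3VO4,5,mM,,,sample
H3,Na2WO4,5,mM,,,sample
H4,Na2MoO4,5,mM,,,sample
H5,glycine,20,%,,,sample
H6,glycine,10,%,,,sample
H7,arginine,1,M,7.0,,sample
H8,TMAO,1,M,,,sample
H9,TMAO,0.5,M,,,sample
H10,trehalose,0.5,M,,,sample
H11,TMG,1,M,,,sample
H12,TMG,0.5,M,,,sample
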