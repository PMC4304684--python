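# pH screen: final concentrations after 1:1 mixing with protein+dye.
# Buffers A/B/C are universal three-component buffers used at 0.2 M.
# A1 is the reference well; row F holds water blanks.
well,component,concentration,unit,ph25,dpka_per_degc,role
A1,,,,,,reference
A2,boric acid,0.1,M,9.2,,sample
A3,glycine,0.1,M,9.6,,sample
A4,urea,4.5,M,,,sample
A5,succinic acid,0.1,M,4.2,,sample
A6,acetic acid,0.1,M,4.8,,sample
A7,citric acid,0.1,M,4.8,,sample
A8,succinic acid,0.1,M,5.6,,sample
A9,MES,0.1,M,6.3,,sample
A10,citric acid,0.1,M,6.4,,sample
A11,ADA,0.1,M,6.6,,sample
A12,bis-tris,0.1,M,6.75,,sample
B1,bis-tris propane,0.1,M,6.8,,sample
B2,imidazole,0.1,M,6.95,,sample
B3,MOPS,0.1,M,7.1,,sample
B4,phosphate,0.1,M,7.2,,sample
B5,HEPES,0.1,M,7.5,,sample
B6,tricine,0.1,M,8.0,,sample
B7,TrisHCl,0.1,M,8.1,,sample
B8,bicine,0.1,M,8.5,,sample
B9,bis-tris propane,0.1,M,9.0,,sample
B10,CHES,0.1,M,9.5,,sample
B11,CAPS,0.1,M,10.3,,sample
B12,phosphate,0.1,M,12.3,,sample
C1,buffer A,0.2,M,4.0,,sample
C2,buffer A,0.2,M,4.4,,sample
C3,buffer A,0.2,M,4.7,,sample
C4,buffer A,0.2,M,5.0,,sample
C5,buffer A,0.2,M,5.4,,sample
C6,buffer A,0.2,M,5.6,,sample
C7,buffer A,0.2,M,6.0,,sample
C8,buffer A,0.2,M,6.4,,sample
C9,buffer A,0.2,M,6.9,,sample
C10,buffer A,0.2,M,7.6,,sample
C11,buffer A,0.2,M,9.2,,sample
C12,buffer A,0.2,M,10.0,,sample
D1,buffer B,0.2,M,4.0,,sample
D2,buffer B,0.2,M,4.5,,sample
D3,buffer B,0.2,M,4.9,,sample
D4,buffer B,0.2,M,5.4,,sample
D5,buffer B,0.2,M,5.9,,sample
D6,buffer B,0.2,M,6.1,,sample
D7,buffer B,0.2,M,6.6,,sample
D8,buffer B,0.2,M,7.4,,sample
D9,buffer B,0.2,M,7.5,,sample
D10,buffer B,0.2,M,8.3,,sample
D11,buffer B,0.2,M,9.1,,sample
D12,buffer B,0.2,M,10.0,,sample
E1,buffer C,0.2,M,4.0,,sample
E2,buffer C,0.2,M,5.0,,sample
E3,buffer C,0.2,M,5.6,,sample
E4,buffer C,0.2,M,5.8,,sample
E5,buffer C,0.2,M,6.3,,sample
E6,buffer C,0.2,M,6.8,,sample
E7,buffer C,0.2,M,7.4,,sample
E8,buffer C,0.2,M,7.8,,sample
E9,buffer C,0.2,M,8.0,,sample
E10,buffer C,0.2,M,8.5,,sample
E11,buffer C,0.2,M,9.2,,sample
E12,buffer C,0.2,M,10.0,,sample
F1,,,,,,blank
F2,,,,,,blank
F3,,,,,,blank
F4,,,,,,blank
F5,,,,,,blank
F6,,,,,,blank
F7,,,,,,blank
F8,,,,,,blank
F9,,,,,,blank
F10,,,,,,blank
F11,,,,,,blank
F12,,,,,,blank
G1,buffer B,0.2,M,5,,sample
G1,malonate,0.8,M,5,,sample
G2,buffer B,0.2,M,7,,sample
G2,malonate,0.8,M,7,,sample
G3,buffer B,0.2,M,9,,sample
G3,malonate,0.8,M,9,,sample
G4,buffer B,0.2,M,5,,sample
G4,malonate,0.4,M,5,,sample
G5,buffer B,0.2,M,7,,sample
G5,malonate,0.4,M,7,,sample
G6,buffer B,0.2,M,9,,sample
G6,malonate,0.4,M,9,,sample
G7,buffer B,0.2,M,5,,sample
G7,NaCl,0.8,M,5,,sample
G8,buffer B,0.2,M,7,,sample
G8,NaCl,0.8,M,7,,sample
G9,buffer B,0.2,M,9,,sample
G9,NaCl,0.8,M,9,,sample
G10,buffer B,0.2,M,5,,sample
G10,NaCl,0.4,M,5,,sample
G11,buffer B,0.2,M,7,,sample
G11,NaCl,0.4,M,7,,sample
G12,buffer B,0.2,M,9,,sample
G12,NaCl,0.4,M,9,,sample
H1,buffer C,0.2,M,5,,sample
H1,malonate,0.8,M,5,,sample
H2,buffer C,0.2,M,7,,sample
H2,malonate,0.8,M,7,,sample
H3,buffer C,0.2,M,9,,sample
H3,malonate,0.8,M,9,,sample
H4,buffer C,0.2,M,5,,sample
H4,malonate,0.4,M,5,,sample
H5,buffer C,0.2,M,7,,sample
H5,malonate,0.4,M,7,,sample
H6,buffer C,0.2,M,9,,sample
H6,malonate,0.4,M,9,,sample
H7,buffer C,0.2,M,5,,sample
H7,NaCl,0.8,M,5,,sample
H8,buffer C,0.2,M,7,,sample
H8,NaCl,0.8,M,7,,sample
H9,buffer C,0.2,M,9,,sample
H9,NaCl,0.8,M,9,,sample
H10,buffer C,0.2,M,5,,sample
H10,NaCl,0.4,M,5,,sample
H11,buffer C,0.2,M,7,,sample
H11,NaCl,0.4,M,7,,sample
H12,buffer C,0.2,M,9,,sample
H12,NaCl,0.4,M,9,,sample
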