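enzyme	median_tpm_bmp	median_tpm_nbmp	reaction
ARSA	34.61	30.21	H2O + N-acyl-1-beta-D-(3-O-sulfo)-galactosyl-sphing-4-enine → a beta-D-galactosyl-(1<->1')-N-acylsphing-4-enine + H^+^ + sulfate
CANT1	41.95	37.17	a ribonucleoside 5'-diphosphate + H2O → a ribonucleoside 5'-phosphate + H^+^ + phosphate
CASK	12.34	8.89	ATP + L-seryl-[protein] → ADP + H^+^ + O-phospho-L-seryl-[protein]
CERK	25.48	19.19	an N-acylsphing-4-enine + ATP → ADP + an N-acylsphing-4-enine 1-phosphate + H^+^
EPHA4	3.89	1.74	ATP + L-tyrosyl-[protein] → ADP + H^+^ + O-phospho-L-tyrosyl-[protein]
EZH2	14.61	8.53	L-lysyl27-[histone H3] + 3 S-adenosyl-L-methionine → 3 H^+^ + N6,N6,N6-trimethyl-L-lysyl27-[histone H3] + 3 S-adenosyl-L-homocysteine
FYN	11.32	9.37	ATP + L-tyrosyl-[protein] → ADP + H^+^ + O-phospho-L-tyrosyl-[protein]
GLYATL2	0.15	0.06	an acyl-CoA + glycine → an N-acylglycine + CoA + H^+^
MYO3A	0.10	0.04	ATP + L-seryl-[protein] → ADP + H^+^ + O-phospho-L-seryl-[protein]
NMNAT2	1.62	0.97	diphosphate + NAD+ → H^+^ + ATP + beta-nicotinamide D-ribonucleotide
PDE11A	0.17	0.13	3',5'-cyclic GMP + H2O → GMP + H^+^
PDE3A	4.35	1.94	a nucleoside 3',5'-cyclic phosphate + H2O → a nucleoside 5'-phosphate + H^+^
PGLS	40.61	36.71	6-phospho-D-glucono-1,5-lactone + H2O → 6-phospho-D-gluconate + H^+^
ULK1	19.70	17.45	ATP + L-seryl-[protein] → ADP + H^+^ + O-phospho-L-seryl-[protein]
XDH	0.79	0.58	H2O + NAD+ + xanthine → H^+^ + NADH + urate
YARS1	29.19	23.15	ATP + L-tyrosine + tRNATyr → AMP + diphosphate + H^+^ + L-tyrosyl-tRNATyr
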