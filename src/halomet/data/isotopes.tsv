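# halomet element isotope table, version 1
# columns: element, isotope mass (Da), relative abundance (fraction)
# Masses: AME2020 / IUPAC 2021. Chlorine abundances pinned to 75.77/24.23
# (classic IUPAC representative values) so simulated Cl envelopes match the
# printed diagnostic M+2 ratio exactly.
H	1.0078250319	0.999885
H	2.0141017781	0.000115
C	12.0000000000	0.9893
C	13.0033548351	0.0107
N	14.0030740044	0.99636
N	15.0001088989	0.00364
O	15.9949146196	0.99757
O	16.9991317565	0.00038
O	17.9991596129	0.00205
P	30.9737619984	1.0
S	31.9720711744	0.9499
S	32.9714589098	0.0075
S	33.9678670070	0.0425
S	35.9670807120	0.0001
Cl	34.9688526900	0.7577
Cl	36.9659026000	0.2423
Br	78.9183376000	0.5069
Br	80.9162897000	0.4931
I	126.9044719000	1.0
Na	22.9897692820	1.0
K	38.9637064864	0.932581
K	39.9639981660	0.000117
K	40.9618252579	0.067302
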