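# halomet reference compound library, version 1
# Entries without a formula are name-only annotations and are excluded from
# exact-mass matching.
# columns: number, name, formula, family, halogens, note
1	ilicicolinal (LL-Z1272alpha)	C23H31ClO3	ilicicolin	Cl	ilicicolin pathway product
2	ilicicolinic acid A	C23H31ClO4	ilicicolin	Cl	ilicicolin pathway product
3	ilicicolinic acid C		ilicicolin	Cl	name-only annotation
4	sclerotiorin	C21H23ClO5	azaphilone	Cl	azaphilone pathway product
5	sclerotioramine		azaphilone	Cl	name-only annotation
6	5-chloroisorotiorin		azaphilone	Cl	name-only annotation
7	orsellinic acid		ilicicolin		predicted PKS product, name-only
8	grifolic acid	C23H32O4	ilicicolin		prenylated intermediate
9	ilicicolin B (LL-Z1272beta)	C23H32O3	ilicicolin		reduced intermediate
10	azaphilone precursor 10	C19H24O4	azaphilone		cyclized polyketide intermediate
11	azaphilone precursor 11	C19H24O5	azaphilone		oxygenated intermediate
12	azaphilone scaffold 12	C19H22O4	azaphilone		minimal azaphilone scaffold
13	acylated intermediate 13	C21H24O5	azaphilone		acyl transfer product
14	intermediate 14 (not detected)		azaphilone		postulated, not detected
15	condensation product 15	C23H24O5	azaphilone		Knoevenagel condensation product
16	hydrogenated intermediate 16	C23H26O5	azaphilone		lactone hydrogenation product
17	isochromophilone I		azaphilone	Cl	name-only annotation
18	intermediate 18		azaphilone		name-only annotation
19	intermediate 19	C21H28O5	azaphilone		reduced/acylated intermediate
20	chlorinated azaphilone 20	C21H27ClO5	azaphilone	Cl	chlorination product of 19
21	chlorinated scaffold 21	C19H21ClO4	azaphilone	Cl	chlorinated analog of 12
22	5-bromoisorotiorin	C23H23BrO5	azaphilone	Br	new brominated azaphilone
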