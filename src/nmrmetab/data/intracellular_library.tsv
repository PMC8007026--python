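# Intracellular metabolite assignment table (1H NMR, 400 MHz, cell extracts).
# Columns: name<TAB>compound_id<TAB>multiplets
# Multiplets are encoded as "<shift ppm>(<code>)" tokens separated by ";".
# Codes: s singlet, d doublet, t triplet, q quartet, dd doublet of doublets,
# m multiplet. Tokens "td"/"dq" occurring below are parsed as generic
# multiplets (m). Compound ids are synthetic package-local slugs, not real
# database accessions.
# NOTE: the 5-Methoxytryptophol entries at 0 and 3 ppm are transcribed as
# printed in the source assignment list; the 0 ppm doublet collides with the
# TSP reference region and is excluded from integration windows downstream.
name	compound_id	multiplets
Acetate	cpd:acetate	1.91(s); 1.92(s)
5-Hydroxytryptophan	cpd:5-hydroxytryptophan	3.23(dd); 3.41(dd); 4.02(dd); 6.87(d); 6.88(d); 7.14(s); 7.28(s); 7.41(d)
5-Methoxytryptophol	cpd:5-methoxytryptophol	0(d); 3(t); 3.88(t); 3.9(s); 7.23(s); 7.26(s); 7.44(d)
Acetyl carnitine	cpd:acetyl-carnitine	2.14(s); 2.51(dd); 2.65(dd); 3.19(s); 3.61(d); 3.85(dd)
Alanine	cpd:alanine	1.48(d); 3.79(q)
Alpha-aminoisobutyrate	cpd:alpha-aminoisobutyrate	1.5(s)
Alpha-epsilon-diaminopimelate	cpd:alpha-epsilon-diaminopimelate	1.49(m); 1.92(m); 3.76(m)
Beta-hydroxybutyrate	cpd:beta-hydroxybutyrate	1.2(d); 2.31(dd); 2.41(dd); 4.16(d)
Carnitine	cpd:carnitine	2.44(dd); 3.23(s); 3.43(m)
Citrate	cpd:citrate	2.54(d); 2.66(d)
Creatine	cpd:creatine	3.04(s); 3.93(s)
Cysteate	cpd:cysteate	3.29(dd); 3.55(dd); 4.1(dd)
Cysteine	cpd:cysteine	3.03(dd); 3.1(dd); 3.97(t)
Formate	cpd:formate	8.46(s)
Glutamate	cpd:glutamate	2.1(m); 2.36(d); 3.77(t)
Glutamine	cpd:glutamine	2.14(m); 2.46(m); 3.77(t)
Homoserine	cpd:homoserine	2.03(m); 2.16(m); 3.79(m)
Indole-3-lactate	cpd:indole-3-lactate	3.08(dd); 3.26(d); 4.34(m); 7.17(t); 7.27(t); 7.27(s); 7.51(d); 7.76(d)
Inosine	cpd:inosine	3.85(dd); 3.92(dd); 4.28(q); 4.44(t); 6.1(d); 8.24(s); 8.34(s)
Isoleucine	cpd:isoleucine	0.94(t); 1.01(d); 1.26(m); 1.48(m); 1.98(m); 3.68(d)
Kynurenine	cpd:kynurenine	3.72(d); 4.16(t); 6.82(t); 6.89(d); 7.43(t); 7.89(d)
Lactate	cpd:lactate	1.33(d); 4.11(q)
L-Homocysteic acid	cpd:l-homocysteic-acid	2.32(m); 3.06(m); 3.96(t)
N-epsilon-methyllysine	cpd:n-epsilon-methyllysine	2.71(s); 3.06(t); 3.76(t)
o-Hydroxyphenylacetate	cpd:o-hydroxyphenylacetate	3.54(s); 6.93(d); 6.95(t); 7.19(dd); 7.22(td)
p-Hydroxybenzoate	cpd:p-hydroxybenzoate	6.92(d); 7.81(d)
Picolinate	cpd:picolinate	7.54(t); 7.92(d); 7.96(t); 8.57(s)
Quinolinate	cpd:quinolinate	7.45(q); 7.9(d); 8.02(d)
Succinate	cpd:succinate	2.41(s)
Tryptamine	cpd:tryptamine	3.18(t); 3.35(t); 7.21(t); 7.29(t); 7.34(s); 7.56(d); 7.71(d)
Tryptophan	cpd:tryptophan	3.31(dd); 3.49(dd); 4.06(dd); 7.21(t); 7.29(t); 7.33(s); 7.55(d); 7.74(d)
Uracil	cpd:uracil	5.81(d); 7.54(d)
Valine	cpd:valine	0.99(d); 1.04(d); 2.28(dd); 3.62(d)
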