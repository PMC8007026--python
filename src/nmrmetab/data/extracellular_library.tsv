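# Extracellular (conditioned medium) metabolite assignment table (1H NMR,
# 400 MHz). Same format as intracellular_library.tsv.
# NOTE: the Glucose 8.78(s) entry is chemically implausible for glucose but is
# transcribed as printed in the source assignment list.
name	compound_id	multiplets
Acetate	cpd:acetate	1.91(s); 1.92(s)
5-Hydroxytryptamine	cpd:5-hydroxytryptamine	3.12(t); 3.31(t); 7.1(s); 7.3(s); 7.42(d)
Alanine	cpd:alanine	1.48(d); 3.79(q)
Alpha-aminoisobutyrate	cpd:alpha-aminoisobutyrate	1.5(s)
Choline	cpd:choline	3.21(s); 3.52(m); 4.07(m)
Carnitine	cpd:carnitine	2.44(dd); 3.23(s); 3.43(m)
Cysteate	cpd:cysteate	3.29(dd); 3.55(dd); 4.1(dd)
Cysteine	cpd:cysteine	3.03(dd); 3.1(dd); 3.97(t)
Formate	cpd:formate	8.46(s)
Glutamate	cpd:glutamate	2.1(m); 2.36(d); 3.77(t)
Glutamine	cpd:glutamine	2.14(m); 2.46(m); 3.77(t)
Homoserine	cpd:homoserine	2.03(m); 2.16(m); 3.79(m)
Isoleucine	cpd:isoleucine	0.94(t); 1.01(d); 1.26(m); 1.48(m); 1.98(m); 3.68(d)
Kynurenine	cpd:kynurenine	3.72(d); 4.16(t); 6.82(t); 6.89(d); 7.43(t); 7.89(d)
Lactate	cpd:lactate	1.33(d); 4.11(q)
Methionine	cpd:methionine	2.14(s); 2.16(m); 2.65(t); 3.86(t)
N-Acetylhistamine	cpd:n-acetylhistamine	2.84(t); 3.45(m); 7.03(s); 7.95(s)
Lysine	cpd:lysine	1.48(m); 1.73(q); 1.91(m); 3.03(t); 3.76(t)
Pyruvate	cpd:pyruvate	2.38(s)
Alpha-hydroxybutyrate	cpd:alpha-hydroxybutyrate	0.9(t); 1.7(m); 4.0(dd)
p-Hydroxypheny-lacetate	cpd:p-hydroxyphenylacetate	3.45(s); 6.87(d); 7.17(d)
Threonine	cpd:threonine	1.33(d); 3.59(d); 4.26(dq)
Tryptamine	cpd:tryptamine	3.18(t); 3.35(t); 7.21(t); 7.29(t); 7.34(s); 7.56(d); 7.71(d)
Glucose	cpd:glucose	3.69(m); 3.82(m); 8.78(s)
Valine	cpd:valine	0.99(d); 1.04(d); 2.28(dd); 3.62(d)
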