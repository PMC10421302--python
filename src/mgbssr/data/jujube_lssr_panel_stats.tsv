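# Published population characteristics of the 12-marker jujube LSSR panel
# (249 accessions): Na = observed alleles, Ne = effective alleles,
# Ho/He = observed/expected heterozygosity, PIC = polymorphism information content.
marker	na	ne	ho	he	pic
LSSR-4	5	2.0396	0.485	0.511	0.431
LSSR-6	5	2.922	0.845	0.659	0.598
LSSR-8	11	6.1057	0.732	0.839	0.818
LSSR-10	10	2.994	0.576	0.68	0.624
LSSR-17	9	2.919	0.604	0.663	0.633
LSSR-22	15	6.198	0.551	0.841	0.823
LSSR-23	9	5.2615	0.752	0.812	0.783
LSSR-25	6	2.2674	0.461	0.56	0.461
LSSR-26	15	7.8924	0.853	0.875	0.861
LSSR-27	9	4.3823	0.506	0.786	0.751
LSSR-28	6	2.1094	0.444	0.527	0.426
LSSR-29	6	2.7283	0.646	0.635	0.564
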