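# Synthetic 18-taxon primate-like reference phylogeny (not inferred from data).
# Branch lengths in expected amino-acid substitutions per site; total tree length ~1.
(((((((Homo_sapiens:0.01139,(Pan_troglodytes:0.006834,Pan_paniscus:0.006834):0.004556):0.006834,Gorilla_gorilla:0.018223):0.013667,Pongo_abelii:0.031891):0.006834,Nomascus_leucogenys:0.038724):0.018223,(((Macaca_mulatta:0.009112,Macaca_fascicularis:0.009112):0.013667,(Papio_anubis:0.015945,Cercocebus_atys:0.015945):0.006834):0.004556,Chlorocebus_sabaeus:0.027335):0.029613):0.022779,((Callithrix_jacchus:0.027335,Aotus_nancymaae:0.027335):0.009112,Saimiri_boliviensis:0.036446):0.04328):0.056948,(Carlito_syrichta:0.136674,((Microcebus_murinus:0.068337,Propithecus_coquereli:0.068337):0.034169,Otolemur_garnettii:0.102506):0.052392):0.018223);
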