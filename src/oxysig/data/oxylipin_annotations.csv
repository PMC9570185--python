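# Static annotation of plasma oxylipins: precursor PUFA, dominant
# biosynthetic pathway, literature-curated cardiometabolic functions
# (pipe-separated labels among: inflammation, vascular tone,
# blood clotting, endothelial integrity, glucose homeostasis,
# adipogenesis) and default analytical-robustness flags.  All columns
# are editable configuration; the robustness flags are conservative
# defaults, not measurements.
analyte,precursor,pathway,functions,storage_stable,interlab_ok
9-HODE,LA,LOX/free-radical,inflammation|endothelial integrity|blood clotting,True,True
10-HODE,LA,free-radical,glucose homeostasis,True,True
12-HODE,LA,free-radical,glucose homeostasis,True,True
13-HODE,LA,LOX/free-radical,inflammation|endothelial integrity|blood clotting,True,True
15-HODE,LA,CYP,,True,True
9-oxo-ODE,LA,LOX/free-radical,inflammation,True,True
13-oxo-ODE,LA,LOX/free-radical,inflammation,True,True
9(10)-EpOME,LA,CYP,glucose homeostasis,True,True
12(13)-EpOME,LA,CYP,,True,True
"9,10-DiHOME",LA,sEH,vascular tone|glucose homeostasis,True,True
"12,13-DiHOME",LA,sEH,,True,True
9(10)-EpODE,ALA,CYP,,True,True
12(13)-EpODE,ALA,CYP,,True,True
15(16)-EpODE,ALA,CYP,,True,True
"9,10-DiHODE",ALA,sEH,,True,True
"12,13-DiHODE",ALA,sEH,,True,True
"15,16-DiHODE",ALA,sEH,,True,True
9-HOTrE,ALA,LOX/free-radical,,True,True
13-HOTrE,ALA,LOX/free-radical,,True,True
5-HETrE,DGLA,5-LOX,inflammation,True,True
8-HETrE,DGLA,LOX/free-radical,,True,True
12-HETrE,DGLA,12-LOX/CYP,blood clotting,True,True
15-HETrE,DGLA,15-LOX,inflammation,True,True
5-HETE,AA,5-LOX,inflammation|vascular tone,True,True
8-HETE,AA,free-radical,,True,True
9-HETE,AA,free-radical,,False,True
11-HETE,AA,free-radical,,True,True
12-HETE,AA,12-LOX,blood clotting|inflammation,False,True
15-HETE,AA,15-LOX,inflammation,True,True
16-HETE,AA,CYP,inflammation|blood clotting,True,True
18-HETE,AA,CYP,,True,True
20-HETE,AA,CYP,vascular tone,True,True
5-oxo-ETE,AA,5-LOX,inflammation,True,True
8(9)-EpETrE,AA,CYP,,True,True
11(12)-EpETrE,AA,CYP,glucose homeostasis|vascular tone|endothelial integrity|blood clotting|adipogenesis,True,True
14(15)-EpETrE,AA,CYP,vascular tone,True,True
"5,6-DiHETrE",AA,sEH,inflammation|vascular tone|glucose homeostasis,True,True
"8,9-DiHETrE",AA,sEH,,True,True
"11,12-DiHETrE",AA,sEH,,True,True
"14,15-DiHETrE",AA,sEH,inflammation|vascular tone|glucose homeostasis,True,True
14(15)-EpEDE,EDA,CYP,,True,True
"14,15-DiHEDE",EDA,sEH,,True,True
5-HEPE,EPA,5-LOX,inflammation|vascular tone,True,True
8-HEPE,EPA,free-radical,adipogenesis,True,True
9-HEPE,EPA,free-radical,,True,True
12-HEPE,EPA,12-LOX,,True,True
15-HEPE,EPA,15-LOX,,True,True
18-HEPE,EPA,CYP/free-radical,inflammation,True,True
11(12)-EpETE,EPA,CYP,blood clotting|vascular tone,True,True
14(15)-EpETE,EPA,CYP,,True,True
17(18)-EpETE,EPA,CYP,,True,True
"14,15-DiHETE",EPA,sEH,,True,True
"17,18-DiHETE",EPA,sEH,,True,True
4-HDHA,DHA,5-LOX,endothelial integrity,True,True
7-HDHA,DHA,5-LOX,,True,True
10-HDHA,DHA,LOX/free-radical,,True,True
11-HDHA,DHA,free-radical,,True,True
13-HDHA,DHA,LOX/free-radical,,True,True
14-HDHA,DHA,12-LOX,,True,True
16-HDHA,DHA,LOX/free-radical,,True,True
17-HDHA,DHA,15-LOX,inflammation,True,True
20-HDHA,DHA,LOX/free-radical,,True,True
"7,8-DiHDPE",DHA,sEH,,True,True
"10,11-DiHDPE",DHA,sEH,,True,True
"16,17-DiHDPE",DHA,sEH,,True,True
"19,20-DiHDPE",DHA,sEH,,True,True
19(20)-EpDPE,DHA,CYP,,True,True
9(10)-epoxy-stearic acid,stearic acid,CYP,glucose homeostasis,True,True
"9,10-dihydroxy-stearic acid",stearic acid,sEH,,True,True
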