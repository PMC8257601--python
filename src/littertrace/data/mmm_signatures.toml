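# Molecular-mixing-model signature matrix.
#
# Each class entry lists the fraction of that compound class's 13C NMR
# intensity falling in the seven chemical-shift regions, in the order
# given by `regions` (ppm bounds: 0-45, 45-60, 60-95, 95-110, 110-145,
# 145-165, 165-215). Values follow the terrestrial molecular-mixing-
# model literature (Nelson & Baldock lineage) and are data, not code:
# edit or replace this file to use a different calibration. Columns are
# renormalised to sum to exactly 1 on load.

regions = ["r0_45", "r45_60", "r60_95", "r95_110", "r110_145", "r145_165", "r165_215"]

[classes]
# cellulose-like: C2-C6 in 60-95, anomeric C1 in 95-110
carbohydrate = [0.000, 0.000, 0.833, 0.167, 0.000, 0.000, 0.000]
# side chains alkyl, alpha-C 45-60, amide carbonyl 165-215
protein      = [0.398, 0.240, 0.020, 0.010, 0.100, 0.022, 0.210]
# methoxyl 45-60, aryl 110-145, O-aryl 145-165
lignin       = [0.060, 0.130, 0.120, 0.080, 0.370, 0.200, 0.040]
# long-chain alkyl dominated, ester carbonyl
lipid        = [0.760, 0.040, 0.050, 0.000, 0.040, 0.010, 0.100]
# carboxyl/amide-only pseudo-component
carbonyl     = [0.000, 0.000, 0.000, 0.000, 0.000, 0.000, 1.000]
# condensed aromatic (pyrogenic) C
char         = [0.000, 0.000, 0.000, 0.080, 0.720, 0.140, 0.060]
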