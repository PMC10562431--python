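# Synthetic 10-SNP responder score table.
#
# The panel lists the ten loci used for a priori fat-/carbohydrate-responder
# classification. The trial's actual per-genotype point values and thresholds
# were published only in non-public supplementary material, so the point
# values below are SYNTHETIC stand-ins constructed for this package: four
# loci load on the fat axis, three on the carbohydrate axis, and three load
# antagonistically on both (the negative correlation between axes required to
# reproduce the observed ~41%/20%/39% fat/carb/ineligible screening split).
# The scoring engine is table-agnostic: replace this file to use real
# criteria.
version_tag: UPDATED_10SNP
fat_threshold: 6.0
carb_threshold: 5.0
panel:
  - {rsid: rs838147,   chromosome: "19", alleles: [C, A]}   # FGF21
  - {rsid: rs662799,   chromosome: "11", alleles: [G, A]}   # APOA5
  - {rsid: rs894160,   chromosome: "15", alleles: [T, C]}   # PLIN1
  - {rsid: rs5082,     chromosome: "1",  alleles: [G, A]}   # APOA2
  - {rsid: rs12255372, chromosome: "10", alleles: [T, G]}   # TCF7L2
  - {rsid: rs2943641,  chromosome: "2",  alleles: [C, T]}   # IRS1
  - {rsid: rs10423928, chromosome: "19", alleles: [A, T]}   # GIPR (strand-ambiguous)
  - {rsid: rs9939609,  chromosome: "16", alleles: [A, T]}   # FTO (strand-ambiguous)
  - {rsid: rs1801282,  chromosome: "3",  alleles: [G, C]}   # PPARG (strand-ambiguous)
  - {rsid: rs1478290,  chromosome: "12", alleles: [C, A]}   # GYS2
entries:
  # fat-axis loci: effect-allele homozygote 2, heterozygote 1, other 0
  rs838147:
    CC: {fat: 2.0, carb: 0.0}
    AC: {fat: 1.0, carb: 0.0}
    AA: {fat: 0.0, carb: 0.0}
  rs662799:
    GG: {fat: 2.0, carb: 0.0}
    AG: {fat: 1.0, carb: 0.0}
    AA: {fat: 0.0, carb: 0.0}
  rs894160:
    TT: {fat: 2.0, carb: 0.0}
    CT: {fat: 1.0, carb: 0.0}
    CC: {fat: 0.0, carb: 0.0}
  rs5082:
    GG: {fat: 2.0, carb: 0.0}
    AG: {fat: 1.0, carb: 0.0}
    AA: {fat: 0.0, carb: 0.0}
  # carbohydrate-axis loci
  rs12255372:
    TT: {fat: 0.0, carb: 2.0}
    GT: {fat: 0.0, carb: 1.0}
    GG: {fat: 0.0, carb: 0.0}
  rs2943641:
    CC: {fat: 0.0, carb: 2.0}
    CT: {fat: 0.0, carb: 1.0}
    TT: {fat: 0.0, carb: 0.0}
  rs10423928:
    AA: {fat: 0.0, carb: 2.0}
    AT: {fat: 0.0, carb: 1.0}
    TT: {fat: 0.0, carb: 0.0}
  # antagonistic loci: one allele favours fat response, the other carb response
  rs9939609:
    AA: {fat: 2.0, carb: 0.0}
    AT: {fat: 1.0, carb: 1.0}
    TT: {fat: 0.0, carb: 2.0}
  rs1801282:
    GG: {fat: 2.0, carb: 0.0}
    CG: {fat: 1.0, carb: 1.0}
    CC: {fat: 0.0, carb: 2.0}
  rs1478290:
    CC: {fat: 2.0, carb: 0.0}
    AC: {fat: 1.0, carb: 1.0}
    AA: {fat: 0.0, carb: 2.0}
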