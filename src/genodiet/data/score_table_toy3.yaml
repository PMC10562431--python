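# Toy 3-SNP score table used in tests and worked examples.
# Each locus gives 1 fat point for the effect-allele homozygote, 0.5 for the
# heterozygote, 0 otherwise; the carb axis mirrors it on the other homozygote.
version_tag: UPDATED_10SNP
fat_threshold: 2.0
carb_threshold: 2.0
panel:
  - {rsid: rs0000001, chromosome: "1", alleles: [A, G]}
  - {rsid: rs0000002, chromosome: "2", alleles: [C, T]}
  - {rsid: rs0000003, chromosome: "3", alleles: [A, C]}
entries:
  rs0000001:
    AA: {fat: 1.0, carb: 0.0}
    AG: {fat: 0.5, carb: 0.5}
    GG: {fat: 0.0, carb: 1.0}
  rs0000002:
    CC: {fat: 1.0, carb: 0.0}
    CT: {fat: 0.5, carb: 0.5}
    TT: {fat: 0.0, carb: 1.0}
  rs0000003:
    AA: {fat: 1.0, carb: 0.0}
    AC: {fat: 0.5, carb: 0.5}
    CC: {fat: 0.0, carb: 1.0}
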