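# Declarative pipeline config for the packaged worked example.
# "fixtures:tableN" resolves to the shipped tables; any entry may instead
# point at a VCF / PED / TSV path in the documented dialects.
inputs:
  genotypes: fixtures:table1
  candidates: fixtures:table2
  cohort_table: fixtures:table3

# the exome-sequenced affected trio
discovery_ids: [Co-441, Co-666, Co-771]

# obligate carriers in ledger-attribution order: the trio, then the two
# Sanger-typed rectal cancer cases
carriers: [Co-441, Co-666, Co-771, Co-634, Co-667]

# cumulative carrier assumptions from polyp findings, strongest first
scenarios:
  - label: tubulovillous-adenomas
    add: [Co-652]
    rationale: three large tubulovillous adenomas
  - label: tubular-adenomas
    add: [Co-692]
    rationale: four small tubular adenomas, 8 hyperplastic polyps
  - label: hyperplastic-polyps
    add: [Co-657]
    rationale: five large hyperplastic polyps

cascade:
  maf_threshold: 0.20
  background_max_carriers: 1

strict_genotypes: true
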