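# Default HLA screening panel: surrogate tag-SNV and allele-specific TaqMan
# assays for HLA-A*31:01, HLA-B*15:02, HLA-B*57:01 and HLA-B*58:01.
#
# Tag-allele orientation (which nucleotide counts as "positive") is
# configuration, recorded here per assay from the published assay
# descriptions and dbSNP orientation; the inference engine never hard-codes
# it.  Assays with clinical: false were evaluated and rejected for clinical
# carrier inference (kept for re-evaluation); they carry no rule.
schema_version: "1"
assays:
  - id: C__16222070_10
    mode: snv_tag
    rsid: rs2395029
    tag_allele: G
    other_allele: T
    associated_target: "B*57:01"
    metadata: {gene_context: HCP5}
  - id: ANEP7CD
    mode: snv_tag
    rsid: rs10484555
    tag_allele: T
    other_allele: C
    associated_target: "B*15:02"
  - id: AN33NRP
    mode: snv_tag
    rsid: rs144012689
    tag_allele: T
    other_allele: C
    associated_target: "B*15:02"
    metadata: {note: first of two designs covering a nearby variant}
  - id: AN49HCM
    mode: snv_tag
    rsid: rs144012689
    tag_allele: T
    other_allele: C
    associated_target: "B*15:02"
    metadata: {note: second of two designs covering a nearby variant}
  - id: C__33415939_10
    mode: snv_tag
    rsid: rs17179220
    tag_allele: G
    other_allele: A
    associated_target: "A*31:01"
  - id: ANKCPPX
    mode: snv_tag
    rsid: rs1061235
    tag_allele: T
    other_allele: A
    associated_target: "A*31:01"
  - id: C__29757466_10
    mode: snv_tag
    rsid: rs9262570
    tag_allele: G
    other_allele: A
    associated_target: "B*58:01"
    clinical: false
  - id: ANDKDRF
    mode: snv_tag
    rsid: rs9263726
    tag_allele: A
    other_allele: G
    associated_target: "B*58:01"
    clinical: false
  - id: C_30505354_31
    mode: snv_tag
    rsid: rs9469003
    tag_allele: C
    other_allele: T
    associated_target: "B*58:01"
    clinical: false
  - id: "5801A"
    mode: allele_specific
    reference_channel: "ß-Globin"
    associated_target: "B*58:01"
    metadata:
      target_channel: VIC
      reference_dye: FAM
      oligos:
        - {name: ß-Globin-F, sequence: AGTCAGGGCAGAGCCATCTA, concentration_20x: 10.8 µM}
        - {name: ß-Globin-R, sequence: TTAGGGTTGCCCATAACAGC, concentration_20x: 10.8 µM}
        - {name: ß-Globin probe, sequence: 6FAM-AGTCTGCCGTTACTGCCCTGTGG-MGB, concentration_20x: 2.4 µM}
        - {name: 5801-AS-F, sequence: GGGCCGGAGTATTGGGATG, concentration_20x: 18 µM}
        - {name: 5801-AS-R, sequence: GCCATACATCCTCTGGATGA, concentration_20x: 18 µM}
        - {name: 5801-A probe, sequence: VIC-ACCGAGAGAACCTGCGGATCGCGCTCC-QSY, concentration_20x: 4 µM}
  - id: "5801B"
    mode: allele_specific
    reference_channel: "ß-Globin"
    associated_target: "B*58:01"
    metadata:
      target_channel: VIC
      reference_dye: FAM
      oligos:
        - {name: ß-Globin-F, sequence: AGTCAGGGCAGAGCCATCTA, concentration_20x: 10.8 µM}
        - {name: ß-Globin-R, sequence: TTAGGGTTGCCCATAACAGC, concentration_20x: 10.8 µM}
        - {name: ß-Globin probe, sequence: 6FAM-AGTCTGCCGTTACTGCCCTGTGG-MGB, concentration_20x: 2.4 µM}
        - {name: 5801-AS-F, sequence: GGGCCGGAGTATTGGGATG, concentration_20x: 18 µM}
        - {name: 5801-AS-R, sequence: GCCATACATCCTCTGGATGA, concentration_20x: 18 µM}
        - {name: 5801-B probe, sequence: VIC-TCCGAGATCCGCCTCCCTGAGGCC-QSY, concentration_20x: 4 µM}
rules:
  - target: "A*31:01"
    combinator: ALL
    members: [[ANKCPPX], [C__33415939_10]]
    notes: >
      Carrier only when positive for both rs1061235 and rs17179220; either
      SNV alone over-calls (false positives), the conjunction removes them.
  - target: "B*15:02"
    combinator: ANY
    members: [[ANEP7CD], [AN33NRP, AN49HCM]]
    notes: >
      rs10484555 and rs144012689 are each valid markers on their own and are
      reported separately; a sample positive for either of the two
      rs144012689 assay designs counts as rs144012689-positive.  The ANY
      combination is a screening convenience, not a validated composite
      verdict; discrepancies between the two SNVs should be reviewed.
  - target: "B*57:01"
    combinator: SINGLE
    members: [[C__16222070_10]]
    notes: rs2395029 (HCP5) G allele; rare false positives are possible.
  - target: "B*58:01"
    combinator: ANY
    members: [["5801A"], ["5801B"]]
    notes: >
      Two allele-specific assays read as genotyping assays against a
      ß-Globin reference channel; positive on either is a carrier call and
      discordance between the two is flagged for review.
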