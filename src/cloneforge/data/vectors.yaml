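# Synthetic example cloning-vector definitions.
#
# This file documents the vector-config schema. The single vector below is a
# SYNTHETIC example assembled for demonstration and testing: its backbone is
# generated sequence and its adapters are illustrative. Real vector
# definitions (e.g. an in-house LIC series) are user data and follow the
# same schema.
#
# Schema (per entry under `vectors:`):
#   name             unique vector name
#   overhang_fw      5' extension added to every forward primer (IUPAC ok,
#                    lower/upper case preserved for display)
#   overhang_rv      5' extension added to every reverse primer
#   tag_protein      N-terminal fusion tag encoded by the backbone, as
#                    protein one-letter codes (optional)
#   cleavage_offset  number of C-terminal tag residues left on the insert
#                    after protease digestion (optional; requires tag_protein)
#   c_term_tag       C-terminal tag residues appended after the insert
#                    (optional)
#   backbone         full backbone sequence, strict DNA (whitespace ignored)
#   placeholder      [start, end] 1-based inclusive span of the backbone
#                    that the construct DNA replaces
#   features         backbone annotations; spans are 1-based inclusive and
#                    may not overlap the placeholder
vectors:
  - name: synLIC1
    overhang_fw: cagggacccggt
    overhang_rv: cgaggagaagcccggtta
    tag_protein: MHHHHHHSSGENLYFQG   # His6 + linker + TEV site, synthetic demo tag
    cleavage_offset: 1               # TEV leaves the G of ENLYFQ/G on the insert
    backbone: >-
      TGGTGAAATCAATGCGCCACCTTTCGTGGGGCTTGAGAGCGAGGTTGGAATTCCCTCATG
      ACAAAACCCCGCTAACGTAGACCACTGTATTTAAGAAGCCCATAGAATACCATCCTGCTA
      GCGGCCGGAAGTCCTCCTGAAGATTTCCATGTCAATCATACTAGTCCACGGCTTTGGCGC
      AGCGAGACCTACAAGCCTATATGCACCACCACCACCACCACAGCAGCGGCGAAAACCTGT
      ATTTTCAGGGCTGTCAAGTAAGAGATAAGCCCCAACTCGCGGCAACGCAGGTTGATAAAA
      ACTTAGGTCCGAATAAACGAAACGACCCACCGGTGTAAACCCGGGGTCTGTAAATCAATC
      TCCTCCCCGGTGATGCGACTAAGCGGTGACTCTACCTGGGCCGGCGCCAAAACGAATACT
      CCCGGCCAGGTGCATACTTGGACGTAGGACGCCAGTCATGGGCACGCCCCTAACAAGAGA
      CGAGATCCGAAAACACTGTGGAACTAACGCATTTCGAACAGGTCACGTGTCAACGGTTGA
      CAGCGAATTACCACCTACCCGAGACGCATTAACGGCTAGCATAGAGTCTAGGAAGTCAAT
      TAATAGCTAAGCTAAAGCGGGGCCGCATCTGCAAAAACGTCAGCCAGTCGACGACCCATT
      GCTTCTAACATAAGACGTTCGGGGAGTATTTCAAAAGGACCTATCATCTTGTGGCGCTTT
      CGAGCCCCTATACTTGACGCGAAGCAACTCCCCGGCTAGCTCCCCTTGGTCTGCGATTGG
      ATGATATGTAGCTAGTATCCGATCGCTGCTGACATAGGTCATTTACGTCGCTCTATAGGA
      TTGCCTGGACCGCTCACTGGCAAACATTAGTAAAGATTCTGACTTTAACGGTTAAAGTTC
    placeholder: [252, 275]
    features:
      - name: demo promoter
        span: [150, 200]
        type: promoter
      - name: His6-TEV tag
        span: [201, 251]
        type: misc_feature
      - name: TEV protease site
        span: [231, 251]
        type: protein_bind
      - name: demo terminator
        span: [400, 450]
        type: terminator
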