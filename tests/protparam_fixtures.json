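[
 {
  "peptide": "EAKIIFEVDWQCADHITYAVHVQIRWKAGQMKFHMEDPENNYKCRVEPDV",
  "mw": 6019.7804,
  "pi": 5.4227,
  "eps280_reduced": 13980,
  "eps280_cystine": 14105
 },
 {
  "peptide": "YNWHDCILDIEPKRNGNNHKDYGVIGRPKVIMCICMPKD",
  "mw": 4587.3126,
  "pi": 7.9373,
  "eps280_reduced": 8480,
  "eps280_cystine": 8605
 },
 {
  "peptide": "WMHSPRFKFIVVKWQWPNIFTSDCEFGQYDPPYRTK",
  "mw": 4536.1546,
  "pi": 9.0458,
  "eps280_reduced": 19480,
  "eps280_cystine": 19480
 },
 {
  "peptide": "AEVKMELQGRAKTGTELTYHFNGVTAYMSAENLICIWDDSDVFFSVG",
  "mw": 5245.8264,
  "pi": 4.4342,
  "eps280_reduced": 8480,
  "eps280_cystine": 8480
 },
 {
  "peptide": "TYQHVHLPNRTREIIDMAWVIWIADCIDCMDTIKSHVF",
  "mw": 4572.2731,
  "pi": 5.7213,
  "eps280_reduced": 12490,
  "eps280_cystine": 12615
 },
 {
  "peptide": "WSISQHEEQNQQRCECPMEIHHVRFQGKRIDRVECVADIGQSSHPCGP",
  "mw": 5587.1715,
  "pi": 6.03,
  "eps280_reduced": 5500,
  "eps280_cystine": 5750
 },
 {
  "peptide": "PKRLQVSFHLHCWVCMCCWSTTGCTDGDYD",
  "mw": 3492.9819,
  "pi": 6.0265,
  "eps280_reduced": 12490,
  "eps280_cystine": 12740
 },
 {
  "peptide": "PEWIWYCYDQWWTMKHMIKPFLRMDARYWEDVHTKFN",
  "mw": 4952.6717,
  "pi": 7.2655,
  "eps280_reduced": 31970,
  "eps280_cystine": 31970
 },
 {
  "peptide": "INLGRVLYTAVLEFKEEVFKLYHMHKTSKCDQ",
  "mw": 3841.4582,
  "pi": 8.1372,
  "eps280_reduced": 2980,
  "eps280_cystine": 2980
 },
 {
  "peptide": "CAMFKGRVQVAEDFVCNWVFQFCLNCNHIENVQYFIGG",
  "mw": 4431.0832,
  "pi": 5.4442,
  "eps280_reduced": 6990,
  "eps280_cystine": 7240
 }
]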