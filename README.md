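# cloneforge

Designing truncation constructs is the unglamorous bottleneck of most protein
expression and structural-biology projects: given a protein of interest (POI),
one must find the coding DNA that actually encodes the chosen isoform, decide
where domains start and end, and then order PCR primers that amplify exactly
the chosen residue span with the right cloning adapters — for every candidate
boundary combination, with bookkeeping for the tagged and protease-cleaved
products. `cloneforge` is a library + CLI that automates the mechanical part
of this workflow:

* **Isoform ↔ ORF matching** — candidate coding sequences (CDS features from
  GenBank/EMBL records, or ORFs scanned from raw/multicistronic/genomic DNA up
  to 1 Mb) are translated and matched to protein isoforms at the protein
  level. Imperfect matches of up to **three single amino-acid substitutions**
  are reported with the differing positions, and only when no perfect match
  exists for that isoform. Silent SNPs are deliberately ignored — they cannot
  change the primers' product.
* **Primer design** — a start residue *s* maps to CDS bases `3s−2..3s`, so a
  forward primer anneals from base `3s−2`; a stop residue *t* gives a reverse
  primer whose annealing region is the reverse complement of the segment
  ending at base `3t` (the clicked residue is always inside the construct).
  The annealing region grows one base at a time until its melting temperature
  reaches the target (default **65 °C**; nearest-neighbor model, unified
  SantaLucia 1998 parameters, 50 mM Na⁺, 500 nM primer), giving the minimal
  primer that meets the target. Overhangs — vector adapters, `spacer +
  recognition-site` for restriction cloning, or arbitrary custom sequence with
  degenerate IUPAC codes — are prepended without affecting the Tm, and
  in-frame start/stop codons inside them are flagged. Primers are named
  `prefix_Fw_<start>` / `prefix_Rv_<stop>`, serialized with the overhang in
  lower case and the annealing region in upper case.
* **Construct analysis** — all start×stop combinations (s ≤ t) are enumerated,
  and each construct (bare, tag-fused, and protease-cleaved) is characterised
  with the ProtParam conventions: average molecular weight
  `MW = Σ residue masses + H₂O`, isoelectric point by bisection of the net
  Henderson–Hasselbalch charge with the Bjellqvist pKa set, and
  `ε₂₈₀ = 5500·nTrp + 1490·nTyr (+125 per cystine)` (Gill & von Hippel).
* **Annotation filters** — homology hits (BLAST outfmt-6 TSV) are filtered for
  display at E ≤ 0.001 and **query coverage ≥ 75 %**; up to **five** hits with
  identity **> 95 %** are selected as alignment-mapping stand-ins; hits against
  solved structures are binned into similarity tiers **PDB_95 (≥ 95 %),
  PDB50_to_95 [50, 95), PDB30_to_50 [30, 50)** with deposited-construct
  boundaries marked `>`/`<`. Per-residue tracks (PTM letter codes, domain
  spans, external predictor output) are merged into a fixed-width report
  aligned under the query sequence.
* **Plasmid maps** — vector definitions (overhangs, tag, cleavage offset,
  backbone with an insertion placeholder) come from a YAML config; the insert
  replaces the placeholder, downstream features are re-coordinated, and the
  result is written as a circular GenBank flat file.

## Worked example

Make a synthetic 100-codon CDS and design primers for start positions 1 and
48 and stop positions 48 and 58, with the overhangs of the shipped example
vector `synLIC1`:

```bash
python -c "from cloneforge import generate_fixture;
cds = generate_fixture('orf', {'n_codons': 100}, seed=1);
open('poi_cds.fasta','w').write(f'>poi\n{cds.bases}\n')"
cloneforge primers --cds poi_cds.fasta --start 1 --start 48 \
    --stop 48 --stop 58 --prefix RBX5 --vector synLIC1
```

```
name,direction,boundary,sequence,length,tm_annealing,notices
RBX5_Fw_1,Fw,1,cagggacccggtATGAGAGCCTGGTCGTATACACACACTGAATATCTCC,49,65.91,
RBX5_Fw_48,Fw,48,cagggacccggtATCCTAGTTAACGAGATTTATCTCGAAGCAATTCCTATTGTAATTTATCTGCA,65,65.09,
RBX5_Rv_48,Rv,48,cgaggagaagcccggttaGATTACGCGTAATTTATCCCCGTTGTTGTTGGGG,52,66.09,stop-codon-in-overhang
RBX5_Rv_58,Rv,58,cgaggagaagcccggttaAATTGCTTCGAGATAAATCTCGTTAACTAGGATTACGCGTAATTTATCC,67,65.21,stop-codon-in-overhang
```

Every annealing region (upper case) is the shortest CDS-anchored oligo whose
nearest-neighbor Tm reaches 65 °C; the reverse overhang supplies an in-frame
stop codon, which is why the design flags `stop-codon-in-overhang` — a notice,
not an error. The four boundary combinations give four constructs:

```bash
cloneforge constructs --cds poi_cds.fasta --start 1 --start 48 \
    --stop 48 --stop 58 --vector synLIC1
```

```
name,start,stop,length,mw,pi,eps280_reduced
poi_cds_1-48,1,48,48,5578.41,9.51,9970
poi_cds_1-58,1,58,58,6736.77,7.91,11460
poi_cds_48-48,48,48,1,131.17,5.53,0
poi_cds_48-58,48,58,11,1289.53,3.79,1490
```

(the full table also carries ε₂₈₀ for the all-cystine form and, because a
vector was given, the MW/pI/ε₂₈₀ columns of the His₆-TEV-tagged and
TEV-cleaved products). Finally, the annotated plasmid map:

```bash
cloneforge map --cds poi_cds.fasta --vector synLIC1 --construct 1-48 -o poi_1-48.gb
# wrote poi_1-48.gb (1020 bp, circular)
```

The record is 900 (backbone) − 24 (placeholder) + 144 (insert) = 1020 bp, with
the insert CDS annotated at the placeholder position and downstream backbone
features shifted accordingly.

## Notes

* The shipped vector config (`src/cloneforge/data/vectors.yaml`) is a
  documented **synthetic** example of the schema; real vector definitions are
  user data.
* `cloneforge.fetch` is optional, untested convenience plumbing for
  downloading UniProt/ENA records; the rest of the package is strictly
  offline and file-based.
* External predictor output (disorder, secondary structure, domains, coiled
  coils) is ingested from a simple span table: tab-separated columns
  `track`, `start`, `end`, `symbol` with 1-based inclusive residue spans.
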