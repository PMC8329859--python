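# Methods

This note documents the models, conventions and design choices behind
`cloneforge`, in the spirit of a methods section: what is computed, under
which assumptions, and where the defaults come from.

## Coordinates and sequence contracts

All user-visible coordinates are 1-based inclusive: residue *i* of a protein
occupies CDS bases `3i−2..3i`, and feature spans in vector configs and
GenBank output follow the same convention. Internally Biopython's 0-based
half-open locations are used where its parsers/writers require them; the
conversion never leaks through an interface.

Annealing and translation templates are strict DNA (`ACGT` only); degenerate
IUPAC codes are legal exclusively in primer overhangs, where synthesized
oligos may genuinely carry them. `translate` tolerates exactly one trailing
stop codon (CDS records commonly include it) and reports it via a flag;
internal stops are errors, because a template with an internal stop cannot
encode the isoform being matched.

## ORF scanning

`find_orfs` reports, per reading frame and strand, every maximal segment from
the first start codon after the previous in-frame stop to the next in-frame
stop, keeping segments of at least `min_codons` sense codons. ORFs without a
terminating stop codon (running off the sequence end) are not reported. The
reported span covers the start codon through the last sense codon — the stop
codon is excluded — so that `len(cds) == 3 × len(translation)` holds for every
candidate. Coordinates are always given on the forward strand
(`start_base ≤ end_base`); for minus-strand ORFs the start codon is at
`end_base`.

Defaults: start codons `{ATG, GTG, TTG}` (bacterial initiation, the context
in which multicistronic parsing matters), `min_codons = 50`, both strands
scanned, input capped at 1 Mb of sequence. The cap is enforced on base count
— a deterministic, offline proxy for record size. GTG/TTG-initiated ORFs are
translated literally (Val/Leu first residue) rather than as fMet, keeping
`translate(orf.cds)` an exact round trip; isoform matching tolerates the
resulting first-residue difference via the substitution allowance.

## Isoform matching

Matching is substitution-only and at the protein level: a candidate
translation of equal length with Hamming distance 1–3 is an *imperfect*
match, distance 0 a *perfect* match, anything else no match. Indels are
deliberately out of scope — allowing them would change the semantics of the
three-substitution threshold. Imperfect matches are shown only for isoforms
with no perfect match; when several perfect matches exist all are reported,
sorted by source id for deterministic output. Raw-DNA comparison (silent
SNPs) is never attempted: it cannot affect the protein product or the
primers, whose annealing regions come from the user-chosen CDS itself.

## Melting temperature and primer extension

The paper trail for primer Tm models is thin across tools, so the method is
explicit and configurable:

* **nearest-neighbor** (default): unified SantaLucia (1998) ΔH/ΔS parameter
  set with the monovalent-salt entropy correction
  `ΔS += 0.368·(N−1)·ln[Na⁺]`, at 50 mM Na⁺ and 500 nM single-strand
  concentration. Computed via Biopython's `MeltingTemp.Tm_NN` (table
  `DNA_NN3`); the test suite checks it against an independently hand-rolled
  implementation of the same published table to 0.1 °C.
* **wallace**: `Tm = 2(A+T) + 4(G+C)` — the bench rule of thumb; exact
  closed-form values make it useful for tests.
* **gc-fraction**: GC-content formula, for completeness.

In Tm mode the annealing region starts at the boundary codon edge with
`min_len = 15` bases and grows one base at a time until Tm ≥ target (default
65 °C) or `max_len = 60` is reached (then a `tm-unreachable` notice is set,
and the max-length primer is returned). Growth-by-one guarantees minimality
*by construction*: the previous length was tested and fell short, so dropping
the last base always violates the target. The 15/60 bounds are practical PCR
limits. In fixed-length mode the primer is exactly the requested length and
no target is enforced.

Overhang start/stop-codon notices are frame-aware: the overhang is read on
the *coding* strand (reverse-primer overhangs are reverse-complemented
first), and only triplets in the insert's reading frame — anchored at the
overhang/annealing junction, shifted by the overhang's `frame_offset` — are
scanned. A plain substring scan would flag codons the ribosome never reads.

## Construct properties

Computed with the ProtParam conventions so that numbers match what the
community expects from the Expasy service:

* **MW**: sum of average (not monoisotopic) residue masses plus one water.
* **pI**: bisection of the net Henderson–Hasselbalch charge on pH 0–14 with
  the Bjellqvist pKa set (termini + D, E, C, Y, H, K, R), including the
  residue-specific N/C-terminal pKa refinements. Bisection runs until the pH
  bracket is below 1e−6 (≤ 100 iterations). Converging on the bracket rather
  than on |charge| matters: acidic/basic plateaus make the charge curve
  nearly flat, and a charge-based stop can halt several tenths of a pH unit
  from the root.
* **ε₂₈₀**: Gill & von Hippel, `5500·nTrp + 1490·nTyr`, reported for the
  reduced form and for the all-cystine form (+125 per `⌊nCys/2⌋` disulfide
  pair). Both values are always reported; which applies is a property of the
  folded protein, not of the sequence.

Tag fusion models an N-terminal tag (and optionally a C-terminal one):
`tagged = tag + insert`, and after protease digestion `cleaved` keeps the
last `cleavage_offset` tag residues (e.g. the glycine of an ENLYFQ↓G TEV
site). A vector without a protease simply has no cleaved form.

## Homolog filters and PDB tiers

Display filtering keeps hits with **E ≤ 0.001** and per-hit query coverage
**≥ 75 %** (`(qend − qstart + 1)/query_length`; overlapping hits are not
merged — the filter asks whether each hit on its own looks like an
orthologue). The significance direction is worth a remark: the threshold is
implemented as a *maximum* E-value, the only reading consistent with the
filter's purpose of retaining true orthologues; it is a parameter
(`max_evalue`) for users who want a different cutoff.

Alignment-mapping candidates are the hits with identity strictly above 95 %,
sorted by identity (ties: E-value, then subject id), capped at five.

PDB similarity tiers partition identity half-open downward: `PDB_95` ≥ 95,
`PDB50_to_95` [50, 95), `PDB30_to_50` [30, 50), nothing below 30. Tier
tracks mark covered residues with `=`; top-tier hits additionally mark the
deposited construct's boundaries with `>`/`<` and attach the structure
id+chain as hover metadata — those boundaries are experimentally validated
truncation points.

## Merged report

Tracks are fixed-width rows of one symbol per residue, rendered in 60-column
blocks under the query with a residue ruler, `label | symbols` per row so the
report re-parses losslessly. PTM letters follow the shipped legend
(A acetylation, U ubiquitination, P phosphorylation, N glycosylation,
M methylation, ^ disulfide), with `+` for residues carrying more than one
modification type. PTM tracks are disabled (returned blank, flagged) when a
non-canonical isoform is selected, since database PTM positions refer to the
canonical sequence.

## Vectors and GenBank output

Vector definitions live in YAML: overhangs, tag protein, cleavage offset,
a strict-DNA backbone with a `[start, end]` insertion placeholder, and
feature annotations that may not overlap the placeholder. The shipped config
is a fully documented synthetic example — real adapter/tag sequences are
user data, not package constants. Plasmid maps replace the placeholder with
the insert, shift downstream features by the length difference, add a CDS
feature carrying the construct name and translation, and are written as
circular GenBank flat files (fixed date stamp for reproducible output).
Conformance is defined operationally: an independent parser (biotite) must
recover the identical sequence and feature spans.

## Synthetic data

The fixture generator (`generate_fixture`) produces the study conditions for
the tests and the acceptance script, deterministic per seed:

* `orf` — ATG + random non-stop codons + stop; bodies avoid internal ATG so
  nested starts stay rare.
* `isoform-set` — a canonical random protein plus variants with exact counts
  of substitutions/insertions/deletions.
* `genomic` — ORFs embedded at known coordinates in stop-codon-rich
  background (which keeps spurious long ORFs unlikely), optionally on the
  minus strand; ground-truth candidates are returned alongside.
* `vector` — a schema-complete synthetic vector with random backbone.
* `hits` — outfmt-6 rows with prescribed coverages/identities/E-values
  spanning the filter thresholds.

What the synthetic data does *not* emulate: codon-usage bias, real splice
structures, sequencing errors, paralog structure in hit tables, or realistic
E-value/identity correlations. Passing tests therefore demonstrate the
correctness of the decision logic and coordinate arithmetic, not performance
on any particular genome or proteome.

## Problem sizes

The test suite and acceptance script use 60–150-codon CDSs, 100–140-residue
queries, 0.5 %-step identity sweeps, 200 primer round-trip triples and five
plasmid maps of 0.5–5 kb — sizes chosen so every check exercises the full
code path while the whole suite stays interactive-fast.

## Known limitations

* Substitution-only isoform matching; exotic genetic codes are parameterised
  but only the standard table is exercised.
* No primer specificity/hairpin/dimer screening and no codon optimization —
  out of scope by design.
* In-silico PCR (`amplify`) requires the two annealing sites to be
  non-overlapping on the template; single-residue constructs are still
  enumerated and characterised, but their "amplicon" is degenerate.
* Backbone features that would wrap the circular origin are not supported;
  choose the insertion point accordingly.
* The GenBank writer targets the NCBI sample-record layout; exotic dialects
  (multi-line qualifiers beyond Biopython's conventions) are not emitted.
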