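"""Sequence primitives for expression-construct design.

Alphabet validation, translation, reverse complement, codon-level
coordinate mapping, ORF scanning on (multicistronic/genomic) DNA, and a
deterministic synthetic-fixture generator used by the test suite and the
``fixtures`` CLI subcommand.

Coordinate convention: every coordinate visible at a public interface is
1-based inclusive, matching how residues and bases are numbered in lab
notebooks and primer names.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from Bio.Data import CodonTable
from Bio.Seq import Seq

__all__ = [
    "SequenceError",
    "DnaSequence",
    "ProteinSequence",
    "OrfCandidate",
    "STRICT_DNA",
    "IUPAC_DNA",
    "PROTEIN_ALPHABET",
    "DEFAULT_START_CODONS",
    "MAX_GENOMIC_BASES",
    "validate_sequence",
    "translate",
    "reverse_complement",
    "residue_to_codon_span",
    "find_orfs",
    "generate_fixture",
]

STRICT_DNA = frozenset("ACGT")
IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Start codons used by the multicistronic/genomic ORF scanner. Bacterial
#: genes initiate predominantly at ATG but also at GTG and TTG.
DEFAULT_START_CODONS = frozenset({"ATG", "GTG", "TTG"})

#: Input cap for genomic scans (bases). Large records must be split upstream.
MAX_GENOMIC_BASES = 1_000_000

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_ALPHABETS = {
    "strict-dna": STRICT_DNA,
    "iupac-dna": IUPAC_DNA,
    "protein": PROTEIN_ALPHABET,
}


class SequenceError(ValueError):
    """Raised for alphabet violations and sequence contract breaches."""


@dataclass(frozen=True)
class DnaSequence:
    """A named DNA sequence over the IUPAC nucleotide alphabet.

    Templates used for annealing or translation must be *strict* (ACGT
    only); degenerate codes are legal only in primer overhangs.
    """

    bases: str
    name: str = ""

    def __post_init__(self) -> None:
        bad = set(self.bases) - IUPAC_DNA
        if bad:
            raise SequenceError(
                f"non-IUPAC character(s) {sorted(bad)} in DNA sequence {self.name!r}"
            )

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def is_strict(self) -> bool:
        return set(self.bases) <= STRICT_DNA

    def require_strict(self, context: str = "template") -> None:
        for i, b in enumerate(self.bases, start=1):
            if b not in STRICT_DNA:
                raise SequenceError(
                    f"degenerate base {b!r} at position {i} not allowed in {context}"
                )


@dataclass(frozen=True)
class ProteinSequence:
    """A named protein sequence over the 20 standard one-letter codes."""

    residues: str
    name: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError(f"protein sequence {self.name!r} is empty")
        bad = set(self.residues) - PROTEIN_ALPHABET
        if bad:
            raise SequenceError(
                f"illegal residue(s) {sorted(bad)} in protein {self.name!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class OrfCandidate:
    """An open reading frame located on a source DNA sequence.

    ``start_base``/``end_base`` are 1-based inclusive coordinates on the
    *forward* strand of the source (``start_base <= end_base`` always; for
    minus-strand ORFs the start codon sits at ``end_base``). The span
    covers the start codon through the last sense codon: the terminating
    stop codon is excluded, so ``len(cds) == 3 * len(translation)``.
    """

    source_id: str
    strand: str  # "+" or "-"
    start_base: int
    end_base: int
    cds: DnaSequence
    translation: ProteinSequence

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise SequenceError(f"strand must be '+' or '-', got {self.strand!r}")
        span = self.end_base - self.start_base + 1
        if span % 3 != 0:
            raise SequenceError(f"ORF span {span} not divisible by 3")
        if len(self.translation) * 3 != len(self.cds):
            raise SequenceError("translation length inconsistent with CDS length")


# ---------------------------------------------------------------------------
# validation / normalisation
# ---------------------------------------------------------------------------

def validate_sequence(raw: str, alphabet: str = "strict-dna") -> str:
    """Normalise pasted sequence text and enforce an alphabet.

    FASTA header lines are dropped, whitespace and digits (sequence rulers)
    are removed and the result is upper-cased. ``alphabet`` is one of
    ``strict-dna``, ``iupac-dna`` or ``protein``.

    Raises
    ------
    SequenceError
        If a character outside the alphabet remains; the message names the
        offending character and its 1-based position in the cleaned
        sequence.
    """
    try:
        allowed = _ALPHABETS[alphabet]
    except KeyError:
        raise SequenceError(
            f"unknown alphabet {alphabet!r}; choose from {sorted(_ALPHABETS)}"
        ) from None
    lines = [ln for ln in raw.splitlines() if not ln.lstrip().startswith((">", ";"))]
    cleaned = "".join(
        ch for ln in lines for ch in ln if not ch.isspace() and not ch.isdigit()
    ).upper()
    for i, ch in enumerate(cleaned, start=1):
        if ch not in allowed:
            raise SequenceError(
                f"illegal character {ch!r} at position {i} for alphabet {alphabet}"
            )
    return cleaned


# ---------------------------------------------------------------------------
# translation / complement / coordinates
# ---------------------------------------------------------------------------

def translate(cds: DnaSequence | str, table: int | str = 1) -> tuple[ProteinSequence, bool]:
    """Translate a strict-DNA CDS; returns (protein, stop_flag).

    A single trailing stop codon is tolerated: it sets ``stop_flag`` and is
    excluded from the returned protein. An internal stop codon is an error,
    as is a length not divisible by 3.
    """
    seq = cds if isinstance(cds, DnaSequence) else DnaSequence(bases=cds)
    seq.require_strict("translation template")
    if len(seq) == 0:
        raise SequenceError("cannot translate an empty sequence")
    if len(seq) % 3 != 0:
        raise SequenceError(f"CDS length {len(seq)} is not divisible by 3")
    aa = str(Seq(seq.bases).translate(table=table))
    stop_flag = aa.endswith("*")
    core = aa[:-1] if stop_flag else aa
    if "*" in core:
        pos = core.index("*") + 1
        raise SequenceError(f"internal stop codon at codon {pos}")
    return ProteinSequence(residues=core, name=seq.name), stop_flag


def reverse_complement(seq: DnaSequence | str) -> DnaSequence:
    """IUPAC-aware reverse complement (an involution)."""
    s = seq if isinstance(seq, DnaSequence) else DnaSequence(bases=seq)
    return DnaSequence(bases=str(Seq(s.bases).reverse_complement()), name=s.name)


def residue_to_codon_span(residue_index: int) -> tuple[int, int]:
    """Map residue *i* (1-based) to its codon's base span on the CDS.

    Returns the 1-based inclusive pair ``(3i - 2, 3i)`` relative to the
    first base of the coding sequence.
    """
    if residue_index < 1:
        raise SequenceError(f"residue index must be >= 1, got {residue_index}")
    return 3 * residue_index - 2, 3 * residue_index


# ---------------------------------------------------------------------------
# ORF scanning
# ---------------------------------------------------------------------------

def _scan_strand(bases: str, min_codons: int, start_codons: frozenset[str]):
    """Yield (start0, end0_exclusive_of_stop) maximal ORFs on one strand.

    For each reading frame, an ORF runs from the first start codon after
    the previous in-frame stop to the next in-frame stop (which must
    exist). Length is counted in sense codons, stop excluded.
    """
    n = len(bases)
    for frame in range(3):
        start: int | None = None
        for pos in range(frame, n - 2, 3):
            codon = bases[pos : pos + 3]
            if codon in STOP_CODONS:
                if start is not None:
                    n_codons = (pos - start) // 3
                    if n_codons >= min_codons:
                        yield start, pos
                    start = None
            elif start is None and codon in start_codons:
                start = pos


def find_orfs(
    genomic: DnaSequence | str,
    min_codons: int = 50,
    start_codons: frozenset[str] | set[str] = DEFAULT_START_CODONS,
    both_strands: bool = True,
    max_bases: int = MAX_GENOMIC_BASES,
) -> list[OrfCandidate]:
    """Scan a (multicistronic or genomic) sequence for open reading frames.

    Every maximal start-codon -> in-frame-stop segment with at least
    ``min_codons`` sense codons is returned, sorted by forward-strand start
    coordinate. ORFs must terminate at a stop codon; ORFs running off the
    sequence end are not reported.
    """
    src = genomic if isinstance(genomic, DnaSequence) else DnaSequence(bases=genomic)
    src.require_strict("ORF scan template")
    if len(src) > max_bases:
        raise SequenceError(
            f"input of {len(src)} bases exceeds the {max_bases} base limit; "
            "split the record before scanning"
        )
    start_codons = frozenset(c.upper() for c in start_codons)
    out: list[OrfCandidate] = []
    strands = [("+", src.bases)]
    if both_strands:
        strands.append(("-", reverse_complement(src).bases))
    for strand, bases in strands:
        for s0, e0 in _scan_strand(bases, min_codons, start_codons):
            cds = DnaSequence(bases=bases[s0:e0], name=src.name)
            if strand == "+":
                start_base, end_base = s0 + 1, e0
            else:  # map back onto the forward strand
                start_base = len(src) - e0 + 1
                end_base = len(src) - s0
            # GTG/TTG starts are translated as fMet in vivo; keep the
            # literal codon translation here so translate(cds) round-trips.
            protein, _ = translate(cds)
            out.append(
                OrfCandidate(
                    source_id=src.name or "sequence",
                    strand=strand,
                    start_base=start_base,
                    end_base=end_base,
                    cds=cds,
                    translation=protein,
                )
            )
    out.sort(key=lambda o: (o.start_base, o.end_base, o.strand))
    return out


# ---------------------------------------------------------------------------
# synthetic fixtures
# ---------------------------------------------------------------------------

_SENSE_CODONS = sorted(
    {
        f"{a}{b}{c}"
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
    }
    - STOP_CODONS
    - {"ATG"}  # avoided inside fixture ORF bodies to keep nested starts rare
)

_AA = sorted(PROTEIN_ALPHABET)


def _random_cds(rng: random.Random, n_codons: int) -> str:
    body = "".join(rng.choice(_SENSE_CODONS) for _ in range(n_codons - 1))
    return "ATG" + body + rng.choice(sorted(STOP_CODONS))


def _fixture_orf(rng: random.Random, params: dict):
    n = int(params.get("n_codons", 100))
    if n < 1:
        raise SequenceError("n_codons must be >= 1")
    return DnaSequence(bases=_random_cds(rng, n), name=params.get("name", "fix_orf"))


def _fixture_isoform_set(rng: random.Random, params: dict):
    """A canonical protein plus variants differing by point edits.

    ``variants`` is a list of dicts: {"substitutions": k} and/or
    {"insertions": k, "deletions": k}. Deterministic per seed.
    """
    length = int(params.get("length", 120))
    canonical = "".join(rng.choice(_AA) for _ in range(length))
    isoforms = [ProteinSequence(residues=canonical, name="iso1")]
    for vi, spec in enumerate(params.get("variants", []), start=2):
        res = list(canonical)
        positions = rng.sample(range(length), k=int(spec.get("substitutions", 0)))
        for p in positions:
            res[p] = rng.choice([a for a in _AA if a != res[p]])
        for _ in range(int(spec.get("deletions", 0))):
            del res[rng.randrange(len(res))]
        for _ in range(int(spec.get("insertions", 0))):
            res.insert(rng.randrange(len(res) + 1), rng.choice(_AA))
        isoforms.append(ProteinSequence(residues="".join(res), name=f"iso{vi}"))
    return isoforms


def _fixture_genomic(rng: random.Random, params: dict):
    """Background DNA with ORFs embedded at known coordinates.

    Returns (DnaSequence, list[OrfCandidate]) where the candidates are the
    embedded ground truth (stop codon excluded from the span, matching
    ``find_orfs``).
    """
    n_orfs = int(params.get("n_orfs", 2))
    orf_codons = int(params.get("orf_codons", 60))
    spacer = int(params.get("spacer", 50))
    minus = bool(params.get("minus_strand", False))
    name = params.get("name", "fix_genomic")

    def background(n: int) -> str:
        # stop-codon-rich background: keeps spurious long ORFs unlikely
        out = []
        while len("".join(out)) < n:
            out.append(rng.choice(["TAA", "TGA", "TAG", rng.choice("ACGT")]))
        return "".join(out)[:n]

    pieces: list[str] = [background(spacer)]
    truth: list[dict] = []
    for i in range(n_orfs):
        cds_with_stop = _random_cds(rng, orf_codons)
        strand = "-" if (minus and i % 2 == 1) else "+"
        offset = sum(len(p) for p in pieces)
        embedded = cds_with_stop if strand == "+" else str(
            Seq(cds_with_stop).reverse_complement()
        )
        pieces.append(embedded)
        pieces.append(background(spacer))
        cds = cds_with_stop[:-3]
        if strand == "+":
            start_base, end_base = offset + 1, offset + len(cds)
        else:
            start_base = offset + 4  # skip the (reverse-complemented) stop codon
            end_base = offset + len(cds_with_stop)
        truth.append(
            dict(strand=strand, start_base=start_base, end_base=end_base, cds=cds)
        )
    genomic = DnaSequence(bases="".join(pieces), name=name)
    candidates = [
        OrfCandidate(
            source_id=name,
            strand=t["strand"],
            start_base=t["start_base"],
            end_base=t["end_base"],
            cds=DnaSequence(bases=t["cds"], name=name),
            translation=translate(t["cds"])[0],
        )
        for t in truth
    ]
    return genomic, candidates


def _fixture_vector(rng: random.Random, params: dict):
    """A small synthetic cloning-vector definition (dict, YAML-serialisable)."""
    backbone_len = int(params.get("backbone_len", 600))
    placeholder_len = int(params.get("placeholder_len", 24))
    tag = params.get("tag_protein", "MHHHHHHENLYFQG")
    bases = "".join(rng.choice("ACGT") for _ in range(backbone_len))
    ph_start = backbone_len // 2
    placeholder = ph_start + 1, ph_start + placeholder_len
    return {
        "name": params.get("name", f"synvec{rng.randrange(1000)}"),
        "overhang_fw": "cagggacccggt",
        "overhang_rv": "cgaggagaagcccggtta",
        "tag_protein": tag,
        "cleavage_offset": 1,
        "backbone": bases,
        "placeholder": list(placeholder),
        "features": [
            {"name": "promoter", "span": [10, 40], "type": "promoter"},
            {"name": "terminator", "span": [backbone_len - 60, backbone_len - 20],
             "type": "terminator"},
        ],
    }


def _fixture_hits(rng: random.Random, params: dict):
    """Tabular homology hits (12-column BLAST outfmt-6 rows, as dicts)."""
    query_length = int(params.get("query_length", 100))
    coverages = params.get("coverages", list(range(60, 100, 5)))
    identities = params.get("identities")
    evalues = params.get("evalues")
    rows = []
    for i, cov in enumerate(coverages):
        span = max(1, round(query_length * cov / 100))
        qstart = 1 + rng.randrange(max(1, query_length - span + 1))
        qend = qstart + span - 1
        ident = identities[i] if identities else round(rng.uniform(30, 100), 1)
        ev = evalues[i] if evalues else 10 ** rng.uniform(-30, -4)
        rows.append(
            {
                "qseqid": params.get("query_id", "query"),
                "sseqid": f"subj{i + 1:02d}_A",
                "pident": float(ident),
                "length": span,
                "mismatch": 0,
                "gapopen": 0,
                "qstart": qstart,
                "qend": qend,
                "sstart": 1,
                "send": span,
                "evalue": float(ev),
                "bitscore": round(2.0 * span, 1),
            }
        )
    return rows


_FIXTURE_KINDS = {
    "orf": _fixture_orf,
    "isoform-set": _fixture_isoform_set,
    "genomic": _fixture_genomic,
    "vector": _fixture_vector,
    "hits": _fixture_hits,
}


def generate_fixture(kind: str, params: dict | None = None, seed: int = 0):
    """Deterministic synthetic records for tests and demos.

    ``kind`` is one of ``orf``, ``isoform-set``, ``genomic``, ``vector``,
    ``hits``. The same (kind, params, seed) triple always yields identical
    output.
    """
    try:
        maker = _FIXTURE_KINDS[kind]
    except KeyError:
        raise SequenceError(
            f"unknown fixture kind {kind!r}; choose from {sorted(_FIXTURE_KINDS)}"
        ) from None
    return maker(random.Random(seed), dict(params or {}))
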