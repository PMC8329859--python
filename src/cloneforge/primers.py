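"""Tm-targeted PCR primer design with cloning overhangs.

Chosen truncation boundaries on the protein are mapped to codon edges on
the coding DNA: a start residue yields a forward primer whose annealing
region begins at the first base of that residue's codon, a stop residue a
reverse primer whose annealing region ends at the last base of its codon,
so the clicked residue is always included in the amplified construct.

In melting-temperature mode the annealing region grows one base at a time
from ``min_len`` until its Tm reaches the target (default 65 °C) — the
returned primer is therefore minimal: dropping its last template base
would fall below the target. Overhangs (vector adapters, restriction
sites, custom sequence — degenerate IUPAC codes allowed) are prepended 5'
of the annealing region and never enter the Tm computation.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, replace

import pandas as pd
from Bio.SeqUtils import MeltingTemp as _mt

from .seqcore import (
    IUPAC_DNA,
    DnaSequence,
    SequenceError,
    reverse_complement,
    residue_to_codon_span,
)

__all__ = [
    "Overhang",
    "Primer",
    "DEFAULT_TARGET_TM",
    "DEFAULT_MIN_LEN",
    "DEFAULT_MAX_LEN",
    "TM_PARAMS",
    "melting_temperature",
    "design_forward_primer",
    "design_reverse_primer",
    "design_primer_set",
    "attach_overhang",
    "restriction_overhang",
    "load_enzyme_table",
    "primer_table",
    "amplify",
]

DEFAULT_TARGET_TM = 65.0  # °C
DEFAULT_MIN_LEN = 15
DEFAULT_MAX_LEN = 60

#: Nearest-neighbor conditions: unified SantaLucia (1998) parameter set,
#: 50 mM monovalent salt, 500 nM primer, salt correction applied to dS.
TM_PARAMS = dict(Na=50.0, dnac1=500.0, dnac2=0.0, saltcorr=5)

STOP_TRIPLETS = ("TAA", "TAG", "TGA")

NOTICE_START = "start-codon-in-overhang"
NOTICE_STOP = "stop-codon-in-overhang"
NOTICE_TM = "tm-unreachable"


@dataclass(frozen=True)
class Overhang:
    """A 5' primer extension that does not anneal to the template.

    ``frame_offset`` (0-2) is the offset of the insert's first codon
    relative to the overhang's 3' end: 0 means the insert reading frame
    starts immediately after the overhang. Degenerate IUPAC codes are
    permitted here (and only here); letter case is preserved for display.
    """

    sequence: str
    origin: str = "custom"  # vector | restriction | custom
    frame_offset: int = 0

    def __post_init__(self) -> None:
        bad = set(self.sequence.upper()) - IUPAC_DNA
        if bad:
            raise SequenceError(
                f"overhang contains non-IUPAC character(s) {sorted(bad)}"
            )
        if self.origin not in ("vector", "restriction", "custom"):
            raise SequenceError(f"unknown overhang origin {self.origin!r}")
        if not 0 <= self.frame_offset <= 2:
            raise SequenceError("frame_offset must be 0, 1 or 2")

    def __len__(self) -> int:
        return len(self.sequence)


EMPTY_OVERHANG = Overhang(sequence="", origin="custom")


@dataclass(frozen=True)
class Primer:
    """A designed PCR primer: optional overhang + strict annealing region."""

    name: str
    direction: str  # "Fw" | "Rv"
    boundary_residue: int
    annealing: DnaSequence
    overhang: Overhang = EMPTY_OVERHANG
    tm_annealing: float = float("nan")
    notices: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.direction not in ("Fw", "Rv"):
            raise SequenceError("direction must be 'Fw' or 'Rv'")
        self.annealing.require_strict("primer annealing region")

    @property
    def full_sequence(self) -> str:
        """Display form: overhang lower-case, annealing upper-case."""
        return self.overhang.sequence.lower() + self.annealing.bases.upper()

    def __len__(self) -> int:
        return len(self.overhang) + len(self.annealing)


# ---------------------------------------------------------------------------
# melting temperature
# ---------------------------------------------------------------------------

def melting_temperature(seq: DnaSequence | str, method: str = "nearest-neighbor",
                        **params) -> float:
    """Tm (°C) of a strict-DNA oligo.

    Methods: ``nearest-neighbor`` (unified SantaLucia 1998 table with
    monovalent-salt entropy correction; conditions in :data:`TM_PARAMS`,
    overridable per call), ``wallace`` (2(A+T) + 4(G+C)) and
    ``gc-fraction``. Degenerate bases have no defined Tm and are rejected.
    """
    s = seq if isinstance(seq, DnaSequence) else DnaSequence(bases=seq.upper())
    if len(s) == 0:
        raise SequenceError("cannot compute Tm of an empty sequence")
    s.require_strict("Tm computation")
    if method == "nearest-neighbor":
        kw = {**TM_PARAMS, **params}
        return float(_mt.Tm_NN(s.bases, nn_table=_mt.DNA_NN3, **kw))
    if method == "wallace":
        return float(_mt.Tm_Wallace(s.bases))
    if method == "gc-fraction":
        return float(_mt.Tm_GC(s.bases, **params))
    raise SequenceError(
        f"unknown Tm method {method!r}; choose nearest-neighbor, wallace or gc-fraction"
    )


# ---------------------------------------------------------------------------
# primer design
# ---------------------------------------------------------------------------

def _grow_annealing(segment_of, available: int, target_tm, fixed_length,
                    min_len, max_len, tm_method):
    """Shared extension loop. ``segment_of(L)`` returns the candidate oligo."""
    notices: list[str] = []
    if fixed_length is not None:
        if fixed_length < 1:
            raise SequenceError("fixed primer length must be >= 1")
        if fixed_length > available:
            raise SequenceError(
                f"annealing region of {fixed_length} bases would run past the CDS end "
                f"(only {available} bases available)"
            )
        oligo = segment_of(fixed_length)
        return oligo, melting_temperature(oligo, tm_method), notices
    if available < min_len:
        raise SequenceError(
            f"annealing region would run past the CDS end: {available} bases "
            f"available, minimum primer length is {min_len}"
        )
    cap = min(max_len, available)
    for length in range(min_len, cap + 1):
        oligo = segment_of(length)
        tm = melting_temperature(oligo, tm_method)
        if tm >= target_tm:
            return oligo, tm, notices
    notices.append(NOTICE_TM)
    return oligo, tm, notices


def _protein_length(cds: DnaSequence) -> int:
    if len(cds) % 3 != 0:
        raise SequenceError(f"CDS length {len(cds)} is not divisible by 3")
    return len(cds) // 3


def design_forward_primer(
    cds: DnaSequence | str,
    start_residue: int,
    target_tm: float = DEFAULT_TARGET_TM,
    fixed_length: int | None = None,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    tm_method: str = "nearest-neighbor",
    prefix: str = "primer",
) -> Primer:
    """Forward primer for a construct starting at ``start_residue``.

    The annealing region is a CDS substring beginning exactly at base
    ``3*start - 2`` (the residue's first codon base).
    """
    template = cds if isinstance(cds, DnaSequence) else DnaSequence(bases=cds)
    template.require_strict("PCR template")
    n_res = _protein_length(template)
    if not 1 <= start_residue <= n_res:
        raise SequenceError(
            f"start residue {start_residue} outside protein range 1..{n_res}"
        )
    first, _ = residue_to_codon_span(start_residue)
    offset = first - 1
    available = len(template) - offset
    annealing, tm, notices = _grow_annealing(
        lambda L: template.bases[offset : offset + L],
        available, target_tm, fixed_length, min_len, max_len, tm_method,
    )
    return Primer(
        name=f"{prefix}_Fw_{start_residue}",
        direction="Fw",
        boundary_residue=start_residue,
        annealing=DnaSequence(bases=annealing),
        tm_annealing=tm,
        notices=tuple(notices),
    )


def design_reverse_primer(
    cds: DnaSequence | str,
    stop_residue: int,
    target_tm: float = DEFAULT_TARGET_TM,
    fixed_length: int | None = None,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    tm_method: str = "nearest-neighbor",
    prefix: str = "primer",
) -> Primer:
    """Reverse primer for a construct ending at ``stop_residue``.

    The annealing region is the reverse complement of the CDS segment
    ending at base ``3*stop``, grown toward the CDS 5' end.
    """
    template = cds if isinstance(cds, DnaSequence) else DnaSequence(bases=cds)
    template.require_strict("PCR template")
    n_res = _protein_length(template)
    if not 1 <= stop_residue <= n_res:
        raise SequenceError(
            f"stop residue {stop_residue} outside protein range 1..{n_res}"
        )
    _, last = residue_to_codon_span(stop_residue)
    available = last
    annealing, tm, notices = _grow_annealing(
        lambda L: reverse_complement(template.bases[last - L : last]).bases,
        available, target_tm, fixed_length, min_len, max_len, tm_method,
    )
    return Primer(
        name=f"{prefix}_Rv_{stop_residue}",
        direction="Rv",
        boundary_residue=stop_residue,
        annealing=DnaSequence(bases=annealing),
        tm_annealing=tm,
        notices=tuple(notices),
    )


def design_primer_set(cds, starts, stops, overhang_fw: Overhang = EMPTY_OVERHANG,
                      overhang_rv: Overhang = EMPTY_OVERHANG, prefix: str = "primer",
                      **opts) -> list[Primer]:
    """One forward primer per start and one reverse per stop, with overhangs."""
    primers = [
        attach_overhang(design_forward_primer(cds, s, prefix=prefix, **opts), overhang_fw)
        for s in sorted(set(starts))
    ]
    primers += [
        attach_overhang(design_reverse_primer(cds, t, prefix=prefix, **opts), overhang_rv)
        for t in sorted(set(stops))
    ]
    return primers


# ---------------------------------------------------------------------------
# overhangs
# ---------------------------------------------------------------------------

def _inframe_triplets(ext: str, frame_offset: int, anchored_at_end: bool):
    """Triplets of ``ext`` that sit in the insert's reading frame.

    ``anchored_at_end=True``: the frame is anchored at the 3' end of
    ``ext`` (coding sequence continues right after it, shifted by
    ``frame_offset``); otherwise it is anchored at the 5' end.
    """
    n = len(ext)
    for i in range(n - 2):
        in_frame = ((n + frame_offset - i) % 3 == 0) if anchored_at_end \
            else ((i - frame_offset) % 3 == 0)
        if in_frame:
            yield ext[i : i + 3].upper()


def attach_overhang(primer: Primer, overhang: Overhang) -> Primer:
    """Prepend an overhang and flag in-frame start/stop codons inside it.

    The scan is frame-aware on the *coding* strand: a forward primer's
    overhang is read directly; a reverse primer's overhang is reverse
    complemented first (that is how it appears on the coding strand of the
    PCR product). The annealing Tm is untouched — overhangs never anneal.
    """
    primer.annealing.require_strict("primer annealing region")
    if len(overhang) == 0:
        return primer
    if primer.direction == "Fw":
        coding_ext = overhang.sequence.upper()
        anchored_at_end = True
    else:
        coding_ext = str(reverse_complement(
            DnaSequence(bases=overhang.sequence.upper())).bases)
        anchored_at_end = False
    notices = list(primer.notices)
    triplets = list(_inframe_triplets(coding_ext, overhang.frame_offset, anchored_at_end))
    if "ATG" in triplets and NOTICE_START not in notices:
        notices.append(NOTICE_START)
    if any(t in STOP_TRIPLETS for t in triplets) and NOTICE_STOP not in notices:
        notices.append(NOTICE_STOP)
    return replace(primer, overhang=overhang, notices=tuple(notices))


@functools.cache
def load_enzyme_table() -> dict[str, str]:
    """Restriction enzymes shipped with the package (name -> recognition site)."""
    from importlib.resources import files

    text = files("cloneforge.data").joinpath("enzymes.tsv").read_text()
    table = {}
    for line in text.strip().splitlines()[1:]:
        name, site = line.split("\t")
        table[name] = site
    return table


def restriction_overhang(enzyme: str, spacer: str = "",
                         frame_offset: int = 0) -> Overhang:
    """Overhang for conventional restriction cloning: spacer + recognition site."""
    table = load_enzyme_table()
    if enzyme not in table:
        raise SequenceError(
            f"unknown enzyme {enzyme!r}; available: {', '.join(sorted(table))}"
        )
    return Overhang(
        sequence=spacer + table[enzyme], origin="restriction",
        frame_offset=frame_offset,
    )


# ---------------------------------------------------------------------------
# export / in-silico PCR
# ---------------------------------------------------------------------------

def primer_table(primers: list[Primer], prefix: str) -> pd.DataFrame:
    """Spreadsheet-ready primer table.

    Primers are named ``prefix_Fw_<start>`` / ``prefix_Rv_<stop>``; the
    serialized sequence shows the overhang in lower case and the annealing
    region in upper case. Name collisions are errors.
    """
    if not prefix:
        raise SequenceError("primer name prefix must be non-empty")
    rows = []
    seen: set[str] = set()
    for p in primers:
        name = f"{prefix}_{p.direction}_{p.boundary_residue}"
        if name in seen:
            raise SequenceError(f"duplicate primer name {name!r}")
        seen.add(name)
        rows.append(
            dict(
                name=name,
                direction=p.direction,
                boundary=p.boundary_residue,
                sequence=p.full_sequence,
                length=len(p),
                tm_annealing=round(p.tm_annealing, 2),
                notices=";".join(p.notices),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["name", "direction", "boundary", "sequence", "length",
                 "tm_annealing", "notices"],
    )


def amplify(template: DnaSequence | str, forward: Primer, reverse: Primer) -> str:
    """In-silico PCR: anneal both primers on the template and extend.

    Returns the top strand of the product: forward overhang + amplified
    template region + reverse complement of the reverse overhang. The
    template region runs from the forward annealing site through the site
    the reverse primer anneals to.
    """
    bases = template.bases if isinstance(template, DnaSequence) else template
    fw_site = forward.annealing.bases
    rv_site = reverse_complement(reverse.annealing).bases
    i = bases.find(fw_site)
    if i < 0:
        raise SequenceError("forward primer does not anneal to the template")
    j = bases.find(rv_site, i)
    if j < 0:
        raise SequenceError(
            "reverse primer does not anneal downstream of the forward primer"
        )
    core = bases[i : j + len(rv_site)]
    rv_oh_rc = str(reverse_complement(
        DnaSequence(bases=reverse.overhang.sequence.upper())).bases) \
        if len(reverse.overhang) else ""
    return forward.overhang.sequence.lower() + core + rv_oh_rc.lower()
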