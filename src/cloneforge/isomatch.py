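"""Match candidate coding sequences to protein isoforms.

Coding DNA gathered for a protein of interest rarely comes annotated per
isoform: the same gene cross-references several nucleotide records. This
module translates candidate CDSs and matches them to isoforms at the
protein level. Matching is substitution-only: a candidate of equal length
with up to three single amino-acid substitutions is reported as an
*imperfect* match (with the differing positions listed), anything else is
no match. No comparison of the raw DNA is attempted — silent SNPs never
affect the designed primers' protein product.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .seqcore import (
    DnaSequence,
    OrfCandidate,
    ProteinSequence,
    SequenceError,
    find_orfs,
    translate,
    validate_sequence,
)

__all__ = [
    "MAX_SUBSTITUTIONS",
    "MatchResult",
    "IsoformReport",
    "match_orf_to_isoform",
    "parse_cds_candidates",
    "build_isoform_reports",
    "report_table",
]

#: Maximum number of single amino-acid substitutions tolerated for an
#: imperfect isoform/ORF match.
MAX_SUBSTITUTIONS = 3


@dataclass(frozen=True)
class MatchResult:
    """Outcome of comparing one ORF translation to one isoform.

    ``differences`` lists ``(residue_index, isoform_aa, orf_aa)`` tuples,
    1-based. Empty iff the match is perfect; 1-3 entries iff imperfect.
    """

    isoform_id: str
    orf: OrfCandidate
    status: str  # "perfect" | "imperfect" | "none"
    differences: tuple[tuple[int, str, str], ...] = ()

    def notice(self) -> str:
        """Human-readable description of the sequence differences."""
        if self.status == "perfect":
            return "exact protein-level match"
        if self.status == "none":
            return "no protein-level match"
        diffs = ", ".join(
            f"{iso_aa}{pos}{orf_aa}" for pos, iso_aa, orf_aa in self.differences
        )
        return (
            f"imperfect match with {len(self.differences)} substitution(s): {diffs}"
        )


@dataclass(frozen=True)
class IsoformReport:
    isoform_id: str
    matches: tuple[MatchResult, ...]
    cross_refs: tuple[str, ...]
    no_match: bool = False


def match_orf_to_isoform(orf: OrfCandidate, isoform: ProteinSequence) -> MatchResult:
    """Classify an ORF against one isoform (perfect / imperfect / none)."""
    a, b = isoform.residues, orf.translation.residues
    iso_id = isoform.name or "isoform"
    if a == b:
        return MatchResult(isoform_id=iso_id, orf=orf, status="perfect")
    if len(a) != len(b):
        return MatchResult(isoform_id=iso_id, orf=orf, status="none")
    diffs = tuple(
        (i, x, y) for i, (x, y) in enumerate(zip(a, b), start=1) if x != y
    )
    if len(diffs) <= MAX_SUBSTITUTIONS:
        return MatchResult(
            isoform_id=iso_id, orf=orf, status="imperfect", differences=diffs
        )
    return MatchResult(isoform_id=iso_id, orf=orf, status="none")


def _candidate_from_cds_feature(record, feature, index: int) -> OrfCandidate:
    seq = feature.location.extract(record.seq)
    cds = str(seq).upper()
    if len(cds) % 3 != 0:
        raise SequenceError(
            f"CDS feature {index} of record {record.id!r} has length {len(cds)} "
            "not divisible by 3"
        )
    protein, stop_flag = translate(cds)
    if stop_flag:
        cds = cds[:-3]
    strand = "-" if feature.location.strand == -1 else "+"
    return OrfCandidate(
        source_id=record.id,
        strand=strand,
        start_base=int(feature.location.start) + 1,
        end_base=int(feature.location.end),
        cds=DnaSequence(bases=cds, name=record.id),
        translation=protein,
    )


def parse_cds_candidates(path, fmt: str | None = None, **orf_kwargs) -> list[OrfCandidate]:
    """Extract coding-sequence candidates from a nucleotide record file.

    GenBank/EMBL records contribute one candidate per CDS feature (exons
    joined in feature order, complement strand honoured). Records without
    CDS features — plain FASTA in particular — fall back to an ORF scan of
    the raw sequence (``orf_kwargs`` forwarded to :func:`find_orfs`).
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = {
            ".gb": "genbank", ".gbk": "genbank", ".genbank": "genbank",
            ".embl": "embl",
            ".fa": "fasta", ".fasta": "fasta", ".fna": "fasta",
        }.get(suffix, "genbank")
    try:
        records = list(SeqIO.parse(str(path), fmt))
    except Exception as exc:
        raise SequenceError(f"cannot parse {path.name!r} as {fmt}: {exc}") from exc
    if not records:
        raise SequenceError(f"no records found in {path.name!r} (format {fmt})")
    candidates: list[OrfCandidate] = []
    for record in records:
        cds_features = [f for f in getattr(record, "features", []) if f.type == "CDS"]
        if cds_features:
            for i, feat in enumerate(cds_features, start=1):
                candidates.append(_candidate_from_cds_feature(record, feat, i))
        else:
            raw = validate_sequence(str(record.seq), "strict-dna")
            candidates.extend(
                find_orfs(DnaSequence(bases=raw, name=record.id), **orf_kwargs)
            )
    return candidates


def build_isoform_reports(
    isoforms: list[ProteinSequence], candidates: list[OrfCandidate]
) -> list[IsoformReport]:
    """Pair every isoform with its matching coding sequences.

    All perfect matches are reported (sorted by source id). Imperfect
    matches are shown only when an isoform has *no* perfect match; they are
    then sorted by substitution count, ties by source id. Isoforms with no
    match at all get an empty list and the ``no_match`` flag.
    """
    if not isoforms:
        raise SequenceError("at least one isoform is required")
    reports = []
    for iso in isoforms:
        results = [match_orf_to_isoform(orf, iso) for orf in candidates]
        perfect = sorted(
            (m for m in results if m.status == "perfect"),
            key=lambda m: m.orf.source_id,
        )
        if perfect:
            kept = perfect
        else:
            kept = sorted(
                (m for m in results if m.status == "imperfect"),
                key=lambda m: (len(m.differences), m.orf.source_id),
            )
        reports.append(
            IsoformReport(
                isoform_id=iso.name or "isoform",
                matches=tuple(kept),
                cross_refs=tuple(sorted({m.orf.source_id for m in kept})),
                no_match=not kept,
            )
        )
    return reports


def report_table(reports: list[IsoformReport]):
    """Flatten reports to a DataFrame (TSV-ready); one row per match."""
    import pandas as pd

    rows = []
    for rep in reports:
        if rep.no_match:
            rows.append(
                dict(isoform=rep.isoform_id, source="", status="no-match",
                     substitutions=0, notice="no matching coding sequence found")
            )
        for m in rep.matches:
            rows.append(
                dict(
                    isoform=rep.isoform_id,
                    source=m.orf.source_id,
                    status=m.status,
                    substitutions=len(m.differences),
                    notice=m.notice(),
                )
            )
    return pd.DataFrame(
        rows, columns=["isoform", "source", "status", "substitutions", "notice"]
    )
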