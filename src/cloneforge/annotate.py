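"""Homolog-selection filters, PDB similarity tiers and per-residue tracks.

This module re-creates, on plain files, the decision logic that guides
construct-boundary choices: which homology-search hits are worth showing
(significance and ≥75% query-coverage filters), which near-identical hits
can stand in for the query when mapping to precomputed alignments (up to
five at >95% identity), how PDB hits are binned into similarity tiers
(PDB_95 / PDB50_to_95 / PDB30_to_50) with deposited-construct boundary
markers, human-readable identifier renaming, single-letter PTM tracks and
the fixed-width merged report that vertically aligns every track under
the query sequence.

Hits are read from 12-column tabular output (BLAST ``-outfmt 6``); the
predictions themselves (secondary structure, disorder, domains, ...) are
produced by external tools and ingested from simple tabular files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .seqcore import ProteinSequence, SequenceError

__all__ = [
    "SearchHit",
    "AnnotationTrack",
    "OUTFMT6_COLUMNS",
    "DEFAULT_MAX_EVALUE",
    "DEFAULT_MIN_COVERAGE",
    "MAPPING_MIN_IDENTITY",
    "MAPPING_MAX_HITS",
    "PDB_TIERS",
    "PTM_LEGEND",
    "read_hits_tsv",
    "hits_from_records",
    "filter_homolog_hits",
    "select_mapping_candidates",
    "pdb_tier_of",
    "classify_pdb_tiers",
    "rename_identifier",
    "ptm_track",
    "span_track",
    "read_span_tracks_tsv",
    "merge_tracks",
    "parse_report",
]

OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

#: Display filters for homology hits shown as an ad-hoc orthologue set.
DEFAULT_MAX_EVALUE = 0.001
DEFAULT_MIN_COVERAGE = 0.75

#: Near-identity hits usable as stand-ins for alignment mapping.
MAPPING_MIN_IDENTITY = 95.0  # strict >
MAPPING_MAX_HITS = 5

#: Similarity tiers for hits against solved structures: name -> [low, high).
#: The top tier is closed above (identity 100 included).
PDB_TIERS = {
    "PDB_95": (95.0, 100.000001),
    "PDB50_to_95": (50.0, 95.0),
    "PDB30_to_50": (30.0, 50.0),
}

PTM_LEGEND = {
    "acetylation": "A",
    "ubiquitination": "U",
    "phosphorylation": "P",
    "glycosylation": "N",
    "methylation": "M",
    "disulfide": "^",
}
PTM_MULTIPLE = "+"


@dataclass(frozen=True)
class SearchHit:
    """One tabular homology hit against the query protein."""

    query_id: str
    subject_id: str
    percent_identity: float
    evalue: float
    query_start: int
    query_end: int
    subject_start: int = 0
    subject_end: int = 0
    bitscore: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.percent_identity <= 100:
            raise SequenceError(
                f"identity {self.percent_identity} outside 0..100"
            )
        if self.evalue < 0:
            raise SequenceError("E-value must be >= 0")
        if not 1 <= self.query_start <= self.query_end:
            raise SequenceError(
                f"invalid query span {self.query_start}..{self.query_end}"
            )

    @property
    def structure_id(self) -> str:
        """PDB id + chain convention: subject ids like ``1ABC_A``."""
        return self.subject_id

    def coverage(self, query_length: int) -> float:
        return (self.query_end - self.query_start + 1) / query_length


@dataclass(frozen=True)
class AnnotationTrack:
    """A per-residue symbol row displayed under the query sequence."""

    name: str
    symbols: str
    legend: tuple[tuple[str, str], ...] = ()
    metadata: tuple[tuple[int, str], ...] = ()  # (residue, hover text)
    disabled: bool = False

    def __len__(self) -> int:
        return len(self.symbols)


def _track(name, symbols: list[str], legend: dict[str, str],
           metadata: list[tuple[int, str]] = (), disabled=False) -> AnnotationTrack:
    return AnnotationTrack(
        name=name, symbols="".join(symbols),
        legend=tuple(sorted(legend.items())),
        metadata=tuple(metadata), disabled=disabled,
    )


# ---------------------------------------------------------------------------
# hit ingestion
# ---------------------------------------------------------------------------

def hits_from_records(records) -> list[SearchHit]:
    """Build hits from dict rows (e.g. the synthetic-fixture generator)."""
    return [
        SearchHit(
            query_id=r["qseqid"], subject_id=r["sseqid"],
            percent_identity=float(r["pident"]), evalue=float(r["evalue"]),
            query_start=int(r["qstart"]), query_end=int(r["qend"]),
            subject_start=int(r.get("sstart", 0)), subject_end=int(r.get("send", 0)),
            bitscore=float(r.get("bitscore", 0.0)),
        )
        for r in records
    ]


def read_hits_tsv(path) -> list[SearchHit]:
    """Read 12-column BLAST ``-outfmt 6`` tabular hits (no header line)."""
    df = pd.read_csv(path, sep="\t", names=OUTFMT6_COLUMNS, header=None)
    return hits_from_records(df.to_dict("records"))


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def filter_homolog_hits(
    hits: list[SearchHit],
    query_length: int,
    max_evalue: float = DEFAULT_MAX_EVALUE,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> list[SearchHit]:
    """Keep hits that are significant and cover most of the query.

    A hit is kept when its E-value is at most ``max_evalue`` and its query
    span covers at least ``min_coverage`` of the query length. The high
    coverage requirement favours true orthologues over proteins sharing a
    single domain with the query. Coverage is per hit; overlapping hits
    are not merged.
    """
    if query_length < 1:
        raise SequenceError("query length must be >= 1")
    return [
        h for h in hits
        if h.evalue <= max_evalue and h.coverage(query_length) >= min_coverage
    ]


def select_mapping_candidates(
    hits: list[SearchHit],
    min_identity: float = MAPPING_MIN_IDENTITY,
    max_hits: int = MAPPING_MAX_HITS,
) -> list[SearchHit]:
    """Up to ``max_hits`` hits strictly above ``min_identity`` % identity.

    Sorted by identity descending, ties broken by E-value ascending then
    subject id; identity exactly at the threshold is excluded.
    """
    eligible = [h for h in hits if h.percent_identity > min_identity]
    eligible.sort(key=lambda h: (-h.percent_identity, h.evalue, h.subject_id))
    return eligible[:max_hits]


# ---------------------------------------------------------------------------
# PDB similarity tiers
# ---------------------------------------------------------------------------

def pdb_tier_of(identity: float) -> str | None:
    """Tier name for a percent identity, or None below the lowest bound.

    Bands are half-open downward: ≥95 is PDB_95, [50, 95) PDB50_to_95,
    [30, 50) PDB30_to_50.
    """
    for name, (lo, hi) in PDB_TIERS.items():
        if lo <= identity < hi:
            return name
    return None


def classify_pdb_tiers(hits: list[SearchHit], query_length: int
                       ) -> dict[str, AnnotationTrack]:
    """Per-residue tier tracks plus deposited-construct boundary markers.

    Each hit falls in exactly one tier (or none). Residues covered by a
    tier's hits are marked '='; for the top tier the deposited construct
    boundaries are additionally marked '>' (start) and '<' (stop), with
    the structure id and chain attached as hover metadata.
    """
    rows = {name: [" "] * query_length for name in PDB_TIERS}
    markers: list[tuple[int, str]] = []
    for h in hits:
        tier = pdb_tier_of(h.percent_identity)
        if tier is None:
            continue
        if h.query_end > query_length:
            raise SequenceError(
                f"hit {h.subject_id} span exceeds query length {query_length}"
            )
        row = rows[tier]
        for i in range(h.query_start - 1, h.query_end):
            if row[i] == " ":
                row[i] = "="
        if tier == "PDB_95":
            row[h.query_start - 1] = ">"
            row[h.query_end - 1] = "<"
            markers.append((h.query_start, f"start of {h.structure_id}"))
            markers.append((h.query_end, f"stop of {h.structure_id}"))
    legend = {"=": "covered by a hit in this tier",
              ">": "start of a deposited construct",
              "<": "stop of a deposited construct"}
    return {
        name: _track(name, rows[name],
                     legend if name == "PDB_95" else {"=": legend["="]},
                     markers if name == "PDB_95" else ())
        for name in PDB_TIERS
    }


# ---------------------------------------------------------------------------
# identifier renaming
# ---------------------------------------------------------------------------

def rename_identifier(raw_id: str, species: str | None = None,
                      gene: str | None = None,
                      accession: str | None = None) -> str:
    """Readable display name: ``G.species_gene_(ACCESSION)``.

    The genus is abbreviated to its initial. Missing fields are dropped;
    with no metadata at all the raw identifier is returned unchanged.
    """
    if not (species or gene or accession):
        return raw_id
    parts = []
    if species:
        words = species.split()
        abbrev = f"{words[0][0]}.{''.join(words[1:])}" if len(words) > 1 else words[0]
        parts.append(abbrev)
    if gene:
        parts.append(gene)
    name = "_".join(parts)
    if accession:
        name = f"{name}_({accession})" if name else f"({accession})"
    return name or raw_id


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------

def ptm_track(modifications: list[tuple[int, str]], query_length: int,
              canonical: bool = True, name: str = "PTM") -> AnnotationTrack:
    """Single-letter post-translational-modification track.

    ``modifications`` is a list of (residue, type) with types from
    :data:`PTM_LEGEND`. A residue carrying more than one modification type
    shows '+'. PTM annotations refer to the canonical isoform: for an
    alternative splicing variant (``canonical=False``) the track is
    returned disabled (all blank) to avoid residue-numbering discrepancy.
    """
    legend = {v: k for k, v in PTM_LEGEND.items()}
    legend[PTM_MULTIPLE] = "multiple known modifications"
    if not canonical:
        return _track(name, [" "] * query_length, legend, disabled=True)
    per_residue: dict[int, set[str]] = {}
    for residue, kind in modifications:
        if not 1 <= residue <= query_length:
            raise SequenceError(
                f"modified residue {residue} outside query 1..{query_length}"
            )
        if kind not in PTM_LEGEND:
            raise SequenceError(
                f"unknown modification type {kind!r}; known: {sorted(PTM_LEGEND)}"
            )
        per_residue.setdefault(residue, set()).add(kind)
    row = [" "] * query_length
    for residue, kinds in per_residue.items():
        row[residue - 1] = PTM_LEGEND[next(iter(kinds))] if len(kinds) == 1 \
            else PTM_MULTIPLE
    return _track(name, row, legend)


def span_track(name: str, spans: list[tuple[int, int]], symbol: str,
               query_length: int, legend_text: str = "") -> AnnotationTrack:
    """Mark 1-based inclusive spans with a single symbol (domains etc.)."""
    if len(symbol) != 1:
        raise SequenceError("span symbol must be a single character")
    row = [" "] * query_length
    for start, end in spans:
        if not 1 <= start <= end <= query_length:
            raise SequenceError(f"span {start}..{end} outside query 1..{query_length}")
        for i in range(start - 1, end):
            row[i] = symbol
    return _track(name, row, {symbol: legend_text or name})


def read_span_tracks_tsv(path, query_length: int) -> list[AnnotationTrack]:
    """Ingest externally produced predictions from a span table.

    Expected columns (tab-separated, with header): ``track``, ``start``,
    ``end``, ``symbol`` — e.g. rows from disorder, globularity, coiled-coil
    or domain predictors. One track is built per distinct track name, in
    file order.
    """
    df = pd.read_csv(path, sep="\t")
    missing = {"track", "start", "end", "symbol"} - set(df.columns)
    if missing:
        raise SequenceError(f"span table missing column(s) {sorted(missing)}")
    tracks = []
    for name in df["track"].unique():
        sub = df[df["track"] == name]
        symbol = str(sub["symbol"].iloc[0])
        spans = [(int(r.start), int(r.end)) for r in sub.itertuples()]
        tracks.append(span_track(str(name), spans, symbol, query_length))
    return tracks


# ---------------------------------------------------------------------------
# merged report
# ---------------------------------------------------------------------------

BLOCK_WIDTH = 60
QUERY_LABEL = "POI"


def merge_tracks(tracks: list[AnnotationTrack], query: ProteinSequence,
                 block_width: int = BLOCK_WIDTH) -> str:
    """Fixed-width report: query sequence with all tracks aligned under it.

    The sequence is chunked into ``block_width`` columns; each block shows
    a residue ruler, the query row and one row per track, vertically
    aligned so any symbol maps straight onto its residue. Label and symbol
    fields are separated by ``| `` so the report re-parses exactly. A
    legend follows the blocks.
    """
    n = len(query)
    for t in tracks:
        if len(t) != n:
            raise SequenceError(
                f"track {t.name!r} length {len(t)} != query length {n}"
            )
    label_w = max([len(QUERY_LABEL)] + [len(t.name) for t in tracks]) + 1
    lines: list[str] = []
    for lo in range(1, n + 1, block_width):
        hi = min(lo + block_width - 1, n)
        ruler = [" "] * (hi - lo + 1)
        for pos in range(lo, hi + 1):
            if pos % 10 == 0 or pos == lo:
                text = str(pos)
                col = pos - lo
                begin = max(0, col - len(text) + 1)
                ruler[begin : col + 1] = list(text[-(col - begin + 1):])
        lines.append(" " * label_w + "| " + "".join(ruler))
        lines.append(QUERY_LABEL.ljust(label_w) + "| " + query.residues[lo - 1 : hi])
        for t in tracks:
            lines.append(t.name.ljust(label_w) + "| " + t.symbols[lo - 1 : hi])
        lines.append("")
    lines.append("# legend")
    for t in tracks:
        entries = ", ".join(f"{sym}={meaning}" for sym, meaning in t.legend)
        suffix = " [disabled: non-canonical isoform selected]" if t.disabled else ""
        lines.append(f"#   {t.name}: {entries}{suffix}")
        for residue, text in t.metadata:
            lines.append(f"#   {t.name} @{residue}: {text}")
    return "\n".join(lines) + "\n"


def parse_report(text: str) -> dict[str, str]:
    """Re-read a merged report into {row label -> full symbol string}.

    The query row appears under the key ``POI``. Ruler lines (empty label)
    and legend lines are ignored.
    """
    rows: dict[str, list[str]] = {}
    block_rows: dict[str, str] = {}
    width = 0

    def flush():
        nonlocal block_rows, width
        for label, seg in block_rows.items():
            rows.setdefault(label, []).append(seg.ljust(width))
        block_rows, width = {}, 0

    for line in text.splitlines():
        if line.startswith("#"):
            continue
        if not line.strip():
            flush()
            continue
        if "| " not in line:
            continue
        label, seg = line.split("| ", 1)
        label = label.strip()
        if not label:  # ruler
            continue
        block_rows[label] = seg
        width = max(width, len(seg))
    flush()
    return {label: "".join(segs).rstrip() for label, segs in rows.items()}
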