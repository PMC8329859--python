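"""Cloning-vector definitions and annotated plasmid maps.

Vectors are described in a YAML config: cloning overhangs for the two
primers, the fusion tag (with an optional protease-cleavage offset), a
backbone sequence with a marked insertion placeholder span, and backbone
feature annotations. Building a plasmid map replaces the placeholder with
the construct's amplified DNA, recalculates downstream feature
coordinates and writes a circular GenBank flat file that any standard
DNA-manipulation program can open.

The shipped sample config (``data/vectors.yaml``) is a documented
*synthetic* example — real vector definitions are user data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib.resources import files
from pathlib import Path

import yaml
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .primers import Overhang
from .seqcore import DnaSequence, ProteinSequence, SequenceError, translate, validate_sequence

__all__ = [
    "Feature",
    "VectorSpec",
    "PlasmidRecord",
    "load_vector_config",
    "sample_vector_config_path",
    "build_plasmid_map",
    "write_genbank",
]


@dataclass(frozen=True)
class Feature:
    """An annotated span: GenBank feature key, 1-based inclusive span."""

    key: str
    start: int
    end: int
    qualifiers: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise SequenceError(
                f"feature {self.key!r}: invalid span {self.start}..{self.end}"
            )


@dataclass(frozen=True)
class VectorSpec:
    """A cloning vector: overhangs, tag, backbone and insertion placeholder."""

    name: str
    overhang_fw: Overhang
    overhang_rv: Overhang
    tag_protein: ProteinSequence | None
    cleavage_offset: int | None
    backbone: DnaSequence
    placeholder: tuple[int, int]  # 1-based inclusive span replaced by the insert
    c_term_tag: ProteinSequence | None = None
    features: tuple[Feature, ...] = ()


@dataclass(frozen=True)
class PlasmidRecord:
    """A circular plasmid sequence with 1-based inclusive feature spans."""

    name: str
    sequence: DnaSequence
    features: tuple[Feature, ...]
    circular: bool = True


class ConfigError(SequenceError):
    """Vector-config schema violation; message carries the field path."""


def _require(cond: bool, path: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"{path}: {msg}")


def _parse_vector(entry: dict, idx: int) -> VectorSpec:
    path = f"vectors[{idx}]"
    _require(isinstance(entry, dict), path, "must be a mapping")
    name = entry.get("name")
    _require(bool(name), f"{path}.name", "vector name is required")
    backbone_raw = entry.get("backbone", "")
    _require(bool(backbone_raw), f"{path}.backbone", "backbone sequence is required")
    backbone = DnaSequence(
        bases=validate_sequence(backbone_raw, "strict-dna"), name=name
    )
    ph = entry.get("placeholder")
    _require(
        isinstance(ph, (list, tuple)) and len(ph) == 2,
        f"{path}.placeholder", "must be a [start, end] pair",
    )
    ph = (int(ph[0]), int(ph[1]))
    _require(
        1 <= ph[0] <= ph[1] <= len(backbone),
        f"{path}.placeholder",
        f"span {ph[0]}..{ph[1]} outside backbone 1..{len(backbone)}",
    )
    tag_raw = entry.get("tag_protein")
    tag = ProteinSequence(residues=tag_raw, name=f"{name}_tag") if tag_raw else None
    offset = entry.get("cleavage_offset")
    if offset is not None:
        offset = int(offset)
        _require(tag is not None, f"{path}.cleavage_offset", "requires tag_protein")
        _require(
            0 <= offset <= len(tag),
            f"{path}.cleavage_offset",
            f"must be within 0..{len(tag)} (tag length)",
        )
    c_term_raw = entry.get("c_term_tag")
    c_term = (
        ProteinSequence(residues=c_term_raw, name=f"{name}_cterm")
        if c_term_raw else None
    )
    feats = []
    for fi, f in enumerate(entry.get("features", [])):
        fpath = f"{path}.features[{fi}]"
        _require(isinstance(f, dict), fpath, "must be a mapping")
        span = f.get("span")
        _require(
            isinstance(span, (list, tuple)) and len(span) == 2,
            f"{fpath}.span", "must be a [start, end] pair",
        )
        start, end = int(span[0]), int(span[1])
        _require(
            1 <= start <= end <= len(backbone),
            f"{fpath}.span", "span outside backbone",
        )
        _require(
            end < ph[0] or start > ph[1],
            f"{fpath}.span", "feature may not overlap the insertion placeholder",
        )
        feats.append(
            Feature(
                key=f.get("type", "misc_feature"),
                start=start,
                end=end,
                qualifiers=(("label", f.get("name", f"feature{fi}")),),
            )
        )
    return VectorSpec(
        name=name,
        overhang_fw=Overhang(entry.get("overhang_fw", ""), origin="vector"),
        overhang_rv=Overhang(entry.get("overhang_rv", ""), origin="vector"),
        tag_protein=tag,
        cleavage_offset=offset,
        backbone=backbone,
        placeholder=ph,
        c_term_tag=c_term,
        features=tuple(feats),
    )


def load_vector_config(path) -> list[VectorSpec]:
    """Load and validate vector definitions from a YAML config file."""
    raw = yaml.safe_load(Path(path).read_text())
    _require(isinstance(raw, dict) and "vectors" in raw, "vectors",
             "top-level 'vectors' list is required")
    entries = raw["vectors"]
    _require(isinstance(entries, list) and entries, "vectors",
             "must be a non-empty list")
    specs = [_parse_vector(e, i) for i, e in enumerate(entries)]
    names = [s.name for s in specs]
    dupes = {n for n in names if names.count(n) > 1}
    _require(not dupes, "vectors", f"duplicate vector name(s): {sorted(dupes)}")
    return specs


def sample_vector_config_path() -> Path:
    """Path to the shipped synthetic example vector config."""
    return Path(str(files("cloneforge.data").joinpath("vectors.yaml")))


# ---------------------------------------------------------------------------
# plasmid maps
# ---------------------------------------------------------------------------

def build_plasmid_map(vector: VectorSpec, insert: DnaSequence,
                      construct_name: str) -> PlasmidRecord:
    """Insert a construct's DNA into the vector backbone.

    The insert replaces the placeholder span; backbone features downstream
    of the placeholder shift by (insert length − placeholder length). An
    ``CDS`` feature with the construct name and translation is added over
    the insert span.
    """
    insert.require_strict("plasmid insert")
    if len(insert) == 0:
        raise SequenceError("insert must be non-empty")
    if len(insert) % 3 != 0:
        raise SequenceError(f"insert length {len(insert)} is not divisible by 3")
    ph_start, ph_end = vector.placeholder
    delta = len(insert) - (ph_end - ph_start + 1)
    bases = (
        vector.backbone.bases[: ph_start - 1]
        + insert.bases
        + vector.backbone.bases[ph_end:]
    )
    feats: list[Feature] = []
    for f in vector.features:
        if f.end < ph_start:
            feats.append(f)
        else:  # entirely downstream (overlap excluded at load time)
            feats.append(Feature(f.key, f.start + delta, f.end + delta, f.qualifiers))
    protein, _ = translate(insert)
    feats.append(
        Feature(
            key="CDS",
            start=ph_start,
            end=ph_start + len(insert) - 1,
            qualifiers=(
                ("label", construct_name),
                ("translation", protein.residues),
            ),
        )
    )
    feats.sort(key=lambda f: (f.start, f.end))
    return PlasmidRecord(
        name=construct_name,
        sequence=DnaSequence(bases=bases, name=construct_name),
        features=tuple(feats),
    )


def write_genbank(record: PlasmidRecord, path) -> Path:
    """Write a plasmid map as a circular GenBank flat file.

    The layout follows the NCBI sample record: LOCUS with length and
    topology, FEATURES with 1-based inclusive locations, ORIGIN with 60
    bases per line in 10-base groups. Output is independent-parser safe
    and sequence round-trips byte-identically.
    """
    for f in record.features:
        if f.end > len(record.sequence):
            raise SequenceError(
                f"feature {f.key!r} span {f.start}..{f.end} exceeds sequence "
                f"length {len(record.sequence)}"
            )
    seqrec = SeqRecord(
        Seq(record.sequence.bases),
        id=record.name[:16] or "plasmid",
        name=(record.name or "plasmid").replace(" ", "_")[:16],
        description=f"{record.name} expression construct map",
        annotations={
            "molecule_type": "ds-DNA",
            "topology": "circular" if record.circular else "linear",
            "data_file_division": "SYN",
            "date": "01-JAN-2024",
        },
    )
    for f in record.features:
        seqrec.features.append(
            SeqFeature(
                FeatureLocation(f.start - 1, f.end, strand=1),
                type=f.key,
                qualifiers={k: [v] for k, v in f.qualifiers},
            )
        )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        SeqIO.write([seqrec], fh, "genbank")
    return path
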