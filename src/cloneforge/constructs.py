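"""Construct enumeration and physicochemical characterisation.

Every ordered (start, stop) boundary pair defines a truncation construct:
its amplified DNA (codons start..stop), its protein sequence, and the
numbers a protein-production lab wants on the tube label — average
molecular weight, isoelectric point and the 280 nm molar extinction
coefficient — computed with the ProtParam conventions (Bjellqvist pKa set
for pI; Gill & von Hippel coefficients for ε280; average residue masses).
When a cloning vector is set, the tag-fused and protease-cleaved forms of
every construct are characterised too.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .seqcore import DnaSequence, ProteinSequence, SequenceError, translate

__all__ = [
    "PropertySet",
    "Construct",
    "molecular_weight",
    "isoelectric_point",
    "extinction_280",
    "property_set",
    "enumerate_constructs",
    "fuse_and_cleave",
    "construct_table",
    "construct_dna_table",
]

#: Average residue masses (Da): amino-acid mass minus one water, the
#: values used by the ProtParam service.
AVERAGE_RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MASS = 18.0153

#: Bjellqvist pKa values (as used by ProtParam): positively charged groups.
PKA_POSITIVE = {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98}
#: Negatively charged groups.
PKA_NEGATIVE = {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
#: Terminal pKa depends on the terminal residue (Bjellqvist refinement).
PKA_NTERM_BY_RESIDUE = {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82,
                        "V": 7.44, "E": 7.7}
PKA_CTERM_BY_RESIDUE = {"D": 4.55, "E": 4.75}

#: Gill & von Hippel molar extinction coefficients at 280 nm (M^-1 cm^-1).
EPS_TRP = 5500
EPS_TYR = 1490
EPS_CYSTINE = 125


@dataclass(frozen=True)
class PropertySet:
    """MW (Da, average masses), pI, and ε280 for reduced / all-cystine forms."""

    mw: float
    pi: float
    eps280_reduced: int
    eps280_cystine: int


@dataclass(frozen=True)
class Construct:
    """A truncation construct with its DNA, protein and derived forms."""

    start: int
    stop: int
    dna: DnaSequence
    protein: ProteinSequence
    properties: PropertySet
    tagged_protein: ProteinSequence | None = None
    tagged_properties: PropertySet | None = None
    cleaved_protein: ProteinSequence | None = None
    cleaved_properties: PropertySet | None = None

    @property
    def name(self) -> str:
        return f"{self.protein.name or 'construct'}_{self.start}-{self.stop}"


def _residues(protein: ProteinSequence | str) -> str:
    return protein.residues if isinstance(protein, ProteinSequence) else protein


def molecular_weight(protein: ProteinSequence | str) -> float:
    """Average molecular weight in Da: residue masses plus one water."""
    res = _residues(protein)
    if not res:
        raise SequenceError("cannot compute MW of an empty protein")
    try:
        return sum(AVERAGE_RESIDUE_MASS[a] for a in res) + WATER_MASS
    except KeyError as exc:
        raise SequenceError(f"unknown residue {exc.args[0]!r}") from None


def _net_charge(res: str, ph: float) -> float:
    def pos(pka: float) -> float:
        return 1.0 / (1.0 + 10 ** (ph - pka))

    def neg(pka: float) -> float:
        return 1.0 / (1.0 + 10 ** (pka - ph))

    nterm_pka = PKA_NTERM_BY_RESIDUE.get(res[0], PKA_POSITIVE["Nterm"])
    cterm_pka = PKA_CTERM_BY_RESIDUE.get(res[-1], PKA_NEGATIVE["Cterm"])
    charge = pos(nterm_pka) - neg(cterm_pka)
    for aa, pka in PKA_POSITIVE.items():
        if aa != "Nterm":
            charge += res.count(aa) * pos(pka)
    for aa, pka in PKA_NEGATIVE.items():
        if aa != "Cterm":
            charge -= res.count(aa) * neg(pka)
    return charge


def isoelectric_point(protein: ProteinSequence | str, ph_tol: float = 1e-6,
                      max_iter: int = 100) -> float:
    """pI by bisection of the Henderson–Hasselbalch net charge on pH 0–14.

    Charged groups: termini plus D, E, C, Y, H, K, R with the Bjellqvist
    pKa set, including the residue-specific terminal pKa refinements. Net
    charge decreases monotonically with pH, so bisection on the bracket
    always converges; it runs until the bracket is narrower than ``ph_tol``
    (the charge curve can be nearly flat around the root, so converging on
    the pH bracket — not on |charge| — is what reproduces the reference
    ProtParam values).
    """
    res = _residues(protein)
    if not res:
        raise SequenceError("cannot compute pI of an empty protein")
    lo, hi = 0.0, 14.0
    ph = 7.0
    for _ in range(max_iter):
        ph = (lo + hi) / 2.0
        q = _net_charge(res, ph)
        if hi - lo < ph_tol:
            break
        if q > 0:
            lo = ph
        else:
            hi = ph
    return ph


def extinction_280(protein: ProteinSequence | str) -> tuple[int, int]:
    """ε280 (M⁻¹ cm⁻¹) for the reduced protein and the all-cystine form.

    reduced = 5500·nTrp + 1490·nTyr; the cystine value adds 125 per
    disulfide pair, assuming all ⌊nCys/2⌋ pairs are formed.
    """
    res = _residues(protein)
    if not res:
        raise SequenceError("cannot compute ε280 of an empty protein")
    reduced = EPS_TRP * res.count("W") + EPS_TYR * res.count("Y")
    return reduced, reduced + EPS_CYSTINE * (res.count("C") // 2)


def property_set(protein: ProteinSequence | str) -> PropertySet:
    eps_red, eps_cys = extinction_280(protein)
    return PropertySet(
        mw=molecular_weight(protein),
        pi=isoelectric_point(protein),
        eps280_reduced=eps_red,
        eps280_cystine=eps_cys,
    )


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------

def enumerate_constructs(
    starts: set[int] | list[int],
    stops: set[int] | list[int],
    protein: ProteinSequence,
    cds: DnaSequence,
) -> list[Construct]:
    """All constructs from ordered boundary combinations.

    One construct per (start, stop) pair with start <= stop, sorted by
    (start, stop); inverted pairs are silently excluded. A residue marked
    both start and stop yields the single-residue construct.
    """
    starts, stops = sorted(set(starts)), sorted(set(stops))
    if not starts or not stops:
        raise SequenceError("need at least one start and one stop boundary")
    n = len(protein)
    if len(cds) < 3 * n:
        raise SequenceError("CDS shorter than 3x protein length")
    for b in (*starts, *stops):
        if not 1 <= b <= n:
            raise SequenceError(f"boundary {b} outside protein range 1..{n}")
    out = []
    for s in starts:
        for t in stops:
            if s > t:
                continue
            dna = DnaSequence(bases=cds.bases[3 * s - 3 : 3 * t], name=cds.name)
            prot = ProteinSequence(
                residues=protein.residues[s - 1 : t], name=protein.name
            )
            assert translate(dna)[0].residues == prot.residues
            out.append(
                Construct(start=s, stop=t, dna=dna, protein=prot,
                          properties=property_set(prot))
            )
    return out


def fuse_and_cleave(construct: Construct, vector) -> Construct:
    """Attach the vector's tag(s) and model protease cleavage.

    tagged = tag + insert (+ optional C-terminal tag). If the vector
    defines a protease site, ``cleavage_offset`` residues of the tag stay
    on the insert after digestion; without a protease the cleaved form is
    simply absent. Both derived forms get full property sets.
    """
    name = construct.protein.name
    c_term = getattr(vector, "c_term_tag", None)
    c_res = c_term.residues if c_term else ""
    tag = vector.tag_protein.residues if vector.tag_protein else ""
    tagged = ProteinSequence(
        residues=tag + construct.protein.residues + c_res, name=name
    ) if (tag or c_res) else None
    cleaved = None
    offset = getattr(vector, "cleavage_offset", None)
    if offset is not None and tag:
        retained = tag[len(tag) - offset :] if offset > 0 else ""
        cleaved = ProteinSequence(
            residues=retained + construct.protein.residues + c_res, name=name
        )
    from dataclasses import replace

    return replace(
        construct,
        tagged_protein=tagged,
        tagged_properties=property_set(tagged) if tagged else None,
        cleaved_protein=cleaved,
        cleaved_properties=property_set(cleaved) if cleaved else None,
    )


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def _props_cols(prefix: str, props: PropertySet | None) -> dict:
    if props is None:
        return {}
    return {
        f"{prefix}mw": round(props.mw, 2),
        f"{prefix}pi": round(props.pi, 2),
        f"{prefix}eps280_reduced": props.eps280_reduced,
        f"{prefix}eps280_cystine": props.eps280_cystine,
    }


def construct_table(constructs: list[Construct]) -> pd.DataFrame:
    """Bookkeeping table: one row per construct, spreadsheet-compatible.

    Bare-protein columns always present; tagged/cleaved columns appear
    when a vector has been applied via :func:`fuse_and_cleave`.
    """
    rows = []
    for c in constructs:
        row = dict(
            name=c.name, start=c.start, stop=c.stop, length=len(c.protein),
            dna=c.dna.bases, protein=c.protein.residues,
            **_props_cols("", c.properties),
        )
        if c.tagged_protein is not None:
            row["tagged_protein"] = c.tagged_protein.residues
            row.update(_props_cols("tagged_", c.tagged_properties))
        if c.cleaved_protein is not None:
            row["cleaved_protein"] = c.cleaved_protein.residues
            row.update(_props_cols("cleaved_", c.cleaved_properties))
        rows.append(row)
    return pd.DataFrame(rows)


def construct_dna_table(constructs: list[Construct]) -> pd.DataFrame:
    """The "save construct DNA" export: name, boundaries and amplified DNA."""
    return pd.DataFrame(
        [dict(name=c.name, start=c.start, stop=c.stop, dna=c.dna.bases)
         for c in constructs],
        columns=["name", "start", "stop", "dna"],
    )
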