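"""Primer design: Tm models, extension minimality, overhangs, tables, PCR."""

import math
import random

import pytest

from cloneforge import (
    DnaSequence,
    Overhang,
    SequenceError,
    amplify,
    attach_overhang,
    design_forward_primer,
    design_reverse_primer,
    design_primer_set,
    melting_temperature,
    primer_table,
    restriction_overhang,
    reverse_complement,
    translate,
)
from cloneforge.primers import DEFAULT_TARGET_TM, NOTICE_START, NOTICE_STOP, NOTICE_TM

# ---------------------------------------------------------------------------
# independent nearest-neighbor oracle: unified SantaLucia (1998) parameters,
# 50 mM monovalent salt entropy correction, 500 nM single strand
# ---------------------------------------------------------------------------

NN = {  # dinucleotide (5'->3' top strand) -> (dH kcal/mol, dS cal/mol/K)
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
INIT_AT = (2.3, 4.1)
INIT_GC = (0.1, -2.8)
R_GAS = 1.987  # cal / (mol K)


def oracle_tm_nn(seq: str, na_molar: float = 0.05, strand_nM: float = 500.0) -> float:
    dh, ds = 0.0, 0.0
    for end in (seq[0], seq[-1]):
        h, s = INIT_AT if end in "AT" else INIT_GC
        dh += h
        ds += s
    for i in range(len(seq) - 1):
        h, s = NN[seq[i : i + 2]]
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(na_molar)
    k = strand_nM * 1e-9
    return 1000.0 * dh / (ds + R_GAS * math.log(k)) - 273.15


@pytest.mark.parametrize(
    "seq, expected",
    [("AAAAAAAAAAAAAAA", 30.0), ("GCGCGCGCGC", 40.0), ("ATGC", 12.0)],
)
def test_wallace_rule(seq, expected):
    assert melting_temperature(seq, "wallace") == pytest.approx(expected)


def test_nearest_neighbor_matches_independent_oracle():
    rng = random.Random(13)
    for _ in range(40):
        seq = "".join(rng.choice("ACGT") for _ in range(20))
        assert melting_temperature(seq) == pytest.approx(oracle_tm_nn(seq), abs=0.1)


def test_tm_rejects_degenerate_and_unknown_method():
    with pytest.raises(SequenceError, match="degenerate"):
        melting_temperature("ATGN")
    with pytest.raises(SequenceError, match="unknown Tm method"):
        melting_temperature("ATGC", "salting-out")


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

def assert_minimal(primer, target=DEFAULT_TARGET_TM, min_len=15):
    """Exhaustive-extension oracle: Tm reached and one base fewer fails."""
    annealing = primer.annealing.bases
    if NOTICE_TM in primer.notices:
        assert melting_temperature(annealing) < target
        return
    assert melting_temperature(annealing) >= target
    if len(annealing) > min_len:
        assert melting_temperature(annealing[:-1]) < target


def test_forward_starts_at_codon_edge_and_is_minimal(cds):
    p = design_forward_primer(cds, 1)
    assert cds.bases.startswith(p.annealing.bases)
    assert_minimal(p)
    p48 = design_forward_primer(cds, 48)
    assert cds.bases[141:].startswith(p48.annealing.bases)
    assert_minimal(p48)


def test_forward_fixed_length(cds):
    p = design_forward_primer(cds, 1, fixed_length=20)
    assert p.annealing.bases == cds.bases[:20]


def test_forward_out_of_range(cds):
    with pytest.raises(SequenceError, match="outside protein range"):
        design_forward_primer(cds, 101)
    with pytest.raises(SequenceError, match="run past the CDS end"):
        design_forward_primer(cds, 99)  # 6 bases left < min_len


def test_reverse_at_final_codon(cds):
    p = design_reverse_primer(cds, 100)
    assert reverse_complement(p.annealing).bases == cds.bases[-len(p.annealing):]
    assert_minimal(p)


def test_reverse_segment_ends_at_stop_codon_base(cds):
    p = design_reverse_primer(cds, 58)
    segment = reverse_complement(p.annealing).bases
    assert cds.bases[174 - len(segment) : 174] == segment
    assert_minimal(p)


def test_reverse_near_5prime_end_errors(cds):
    with pytest.raises(SequenceError, match="run past the CDS end"):
        design_reverse_primer(cds, 2)  # only 6 template bases upstream


def test_unreachable_tm_notice():
    at_rich = DnaSequence(bases="AT" * 30)
    p = design_forward_primer(at_rich, 1, target_tm=80.0, max_len=20)
    assert NOTICE_TM in p.notices and len(p.annealing) == 20


# ---------------------------------------------------------------------------
# overhangs
# ---------------------------------------------------------------------------

def test_inframe_atg_in_forward_overhang_is_flagged(cds):
    p = design_forward_primer(cds, 2)
    flagged = attach_overhang(p, Overhang("caccATG", frame_offset=0))
    assert NOTICE_START in flagged.notices
    # same triplet out of frame: no notice
    clean = attach_overhang(p, Overhang("ATGca", frame_offset=0))
    assert NOTICE_START not in clean.notices


def test_inframe_stop_in_reverse_overhang_is_flagged(cds):
    p = design_reverse_primer(cds, 58)
    # overhang whose reverse complement carries an in-frame TAA
    flagged = attach_overhang(p, Overhang("GCTTAGCA".lower(), frame_offset=0))
    # coding strand reads ...| TGCTAAGC: TGC TAA -> stop in frame 0? offset by 0:
    # revcomp("gcttagca") = "tgctaagc"; triplets at 0,3: TGC, TAA -> stop
    assert NOTICE_STOP in flagged.notices


def test_degenerate_overhang_accepted(cds):
    p = design_forward_primer(cds, 1)
    oh = Overhang("caccB", origin="custom")
    assert oh.origin == "custom"
    full = attach_overhang(p, oh)
    assert full.full_sequence.startswith("caccb")


def test_empty_overhang_is_identity(cds):
    p = design_forward_primer(cds, 1)
    assert attach_overhang(p, Overhang("")) == p


def test_tm_invariant_under_overhang(cds):
    p = design_forward_primer(cds, 1)
    full = attach_overhang(p, Overhang("cagggacccggt", origin="vector"))
    assert full.tm_annealing == p.tm_annealing
    assert melting_temperature(full.annealing) == melting_temperature(p.annealing)


@pytest.mark.parametrize(
    "enzyme, spacer, expected",
    [("BamHI", "aaa", "aaaGGATCC"), ("BamHI", "", "GGATCC")],
)
def test_restriction_overhang(enzyme, spacer, expected):
    oh = restriction_overhang(enzyme, spacer)
    assert oh.sequence == expected and oh.origin == "restriction"


def test_unknown_enzyme_lists_available():
    with pytest.raises(SequenceError, match="BamHI"):
        restriction_overhang("XyzI")


# ---------------------------------------------------------------------------
# table + in-silico PCR
# ---------------------------------------------------------------------------

def test_primer_table_naming_and_case(cds):
    primers = design_primer_set(
        cds, starts=[1, 48], stops=[48, 58],
        overhang_fw=Overhang("cagg", origin="vector"),
        overhang_rv=Overhang("cgag", origin="vector"),
    )
    table = primer_table(primers, "RBX5")
    assert len(table) == 4
    assert set(table.name) == {"RBX5_Fw_1", "RBX5_Fw_48", "RBX5_Rv_48", "RBX5_Rv_58"}
    row = table[table.name == "RBX5_Fw_1"].iloc[0]
    assert row.sequence.startswith("cagg")
    tail = row.sequence[4:]
    assert tail == tail.upper() and row.sequence[:4] == "cagg"
    assert row.length == len(row.sequence)


def test_primer_table_duplicate_names_error(cds):
    p = design_forward_primer(cds, 1)
    with pytest.raises(SequenceError, match="duplicate primer name"):
        primer_table([p, p], "X")
    with pytest.raises(SequenceError, match="prefix"):
        primer_table([p], "")


@pytest.mark.parametrize("seed", range(25))
def test_pcr_round_trip_and_minimality(seed):
    """Designed pairs amplify exactly protein[start..stop]; Tm growth minimal."""
    rng = random.Random(seed)
    n_codons = rng.randint(60, 150)
    from cloneforge import generate_fixture

    cds = DnaSequence(
        bases=generate_fixture("orf", {"n_codons": n_codons}, seed=seed).bases[:-3]
    )
    protein, _ = translate(cds)
    # keep the two annealing sites non-overlapping on the template
    start = rng.randint(1, n_codons - 25)
    stop = rng.randint(start + 20, n_codons)
    fw = attach_overhang(design_forward_primer(cds, start),
                         Overhang("cagg", origin="vector"))
    rv = attach_overhang(design_reverse_primer(cds, stop),
                         Overhang("cgagct", origin="vector"))
    product = amplify(cds, fw, rv)
    assert product.startswith("cagg") and product.endswith(
        reverse_complement("CGAGCT").bases.lower()
    )
    core = product[len(fw.overhang) : len(product) - len(rv.overhang)]
    assert len(core) == 3 * (stop - start + 1)
    translated, _ = translate(core)
    assert translated.residues == protein.residues[start - 1 : stop]
    assert_minimal(fw)
    assert_minimal(rv)
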