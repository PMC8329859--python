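"""Homolog filters, PDB tiers, renaming, PTM tracks and the merged report."""

import pandas as pd
import pytest

from cloneforge import (
    ProteinSequence,
    SequenceError,
    classify_pdb_tiers,
    filter_homolog_hits,
    generate_fixture,
    merge_tracks,
    ptm_track,
    read_hits_tsv,
    rename_identifier,
    select_mapping_candidates,
    span_track,
)
from cloneforge.annotate import (
    OUTFMT6_COLUMNS,
    SearchHit,
    hits_from_records,
    parse_report,
    pdb_tier_of,
    read_span_tracks_tsv,
)


def make_hit(identity=90.0, evalue=1e-20, qstart=1, qend=100, subject="1ABC_A"):
    return SearchHit(
        query_id="q", subject_id=subject, percent_identity=identity,
        evalue=evalue, query_start=qstart, query_end=qend,
    )


# ---------------------------------------------------------------------------
# ingestion
# ---------------------------------------------------------------------------

def test_outfmt6_tsv_roundtrip(tmp_path):
    rows = generate_fixture("hits", {"coverages": [60, 75, 90]}, seed=1)
    path = tmp_path / "hits.tsv"
    pd.DataFrame(rows)[OUTFMT6_COLUMNS].to_csv(
        path, sep="\t", header=False, index=False
    )
    hits = read_hits_tsv(path)
    assert len(hits) == 3
    assert [h.subject_id for h in hits] == [r["sseqid"] for r in rows]
    assert [h.percent_identity for h in hits] == [r["pident"] for r in rows]


# ---------------------------------------------------------------------------
# homolog display filter
# ---------------------------------------------------------------------------

class TestHomologFilter:
    def test_coverage_threshold_is_75_percent(self):
        # spans of 74 and 75 residues on a 100-residue query
        low = make_hit(qstart=1, qend=74)
        edge = make_hit(qstart=11, qend=85)
        kept = filter_homolog_hits([low, edge], query_length=100)
        assert kept == [edge]

    def test_evalue_rule(self):
        good = make_hit(evalue=0.001)
        bad = make_hit(evalue=0.0011)
        assert filter_homolog_hits([good, bad], 100) == [good]

    def test_empty_input(self):
        assert filter_homolog_hits([], 100) == []

    def test_monotone_in_coverage(self):
        # raising a kept hit's coverage never removes it
        for span in range(75, 101):
            hit = make_hit(qstart=1, qend=span)
            assert filter_homolog_hits([hit], 100) == [hit]


class TestMappingCandidates:
    def test_cap_at_five(self):
        hits = [make_hit(identity=96 + 0.3 * i, subject=f"s{i}") for i in range(10)]
        picked = select_mapping_candidates(hits)
        assert len(picked) == 5
        idents = [h.percent_identity for h in picked]
        assert idents == sorted(idents, reverse=True)

    def test_exactly_95_excluded(self):
        assert select_mapping_candidates([make_hit(identity=95.0)]) == []
        assert len(select_mapping_candidates([make_hit(identity=95.1)])) == 1

    def test_none_above_threshold(self):
        assert select_mapping_candidates([make_hit(identity=80)]) == []


# ---------------------------------------------------------------------------
# PDB tiers
# ---------------------------------------------------------------------------

class TestPdbTiers:
    @pytest.mark.parametrize(
        "identity, tier",
        [(96, "PDB_95"), (95, "PDB_95"), (70, "PDB50_to_95"), (50, "PDB50_to_95"),
         (40, "PDB30_to_50"), (30, "PDB30_to_50"), (29, None), (100, "PDB_95")],
    )
    def test_tier_assignment(self, identity, tier):
        assert pdb_tier_of(identity) == tier

    def test_partition_over_identity_sweep(self):
        for step in range(0, 201):
            identity = step / 2.0
            tiers = [t for t in ("PDB_95", "PDB50_to_95", "PDB30_to_50")
                     if pdb_tier_of(identity) == t]
            assert len(tiers) <= 1
            assert (pdb_tier_of(identity) is None) == (identity < 30)

    def test_tracks_and_boundary_markers(self):
        hits = [
            make_hit(identity=96, qstart=10, qend=40, subject="2XYZ_B"),
            make_hit(identity=70, qstart=20, qend=60),
            make_hit(identity=40, qstart=50, qend=90),
        ]
        tracks = classify_pdb_tiers(hits, query_length=100)
        top = tracks["PDB_95"]
        assert top.symbols[9] == ">" and top.symbols[39] == "<"
        assert set(top.symbols[10:39]) == {"="}
        assert ("start of 2XYZ_B" in dict((r, t) for r, t in top.metadata).values()
                or any("2XYZ_B" in t for _, t in top.metadata))
        mid = tracks["PDB50_to_95"]
        assert set(mid.symbols[19:60]) == {"="} and mid.symbols[18] == " "
        low = tracks["PDB30_to_50"]
        assert set(low.symbols[49:90]) == {"="}
        for t in tracks.values():
            assert len(t) == 100


# ---------------------------------------------------------------------------
# renaming + PTM tracks
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "args, expected",
    [
        (("ENSMUSG00000006715", "Mus musculus", "gmnn", "H3BLK4_MOUSE"),
         "M.musculus_gmnn_(H3BLK4_MOUSE)"),
        (("ENSMUSG00000006715", "Mus musculus", None, "H3BLK4_MOUSE"),
         "M.musculus_(H3BLK4_MOUSE)"),
        (("ENSMUSG00000006715", None, None, None), "ENSMUSG00000006715"),
    ],
)
def test_rename_identifier(args, expected):
    assert rename_identifier(*args) == expected


class TestPtmTrack:
    def test_single_modification_letter(self):
        track = ptm_track([(12, "acetylation")], 20)
        assert track.symbols[11] == "A" and track.symbols.count("A") == 1

    def test_multiple_types_collapse_to_plus(self):
        track = ptm_track([(12, "acetylation"), (12, "ubiquitination")], 20)
        assert track.symbols[11] == "+"

    def test_disabled_for_noncanonical_isoform(self):
        track = ptm_track([(12, "acetylation")], 20, canonical=False)
        assert track.disabled and set(track.symbols) == {" "}

    def test_out_of_range_and_unknown_type(self):
        with pytest.raises(SequenceError, match="outside query"):
            ptm_track([(30, "acetylation")], 20)
        with pytest.raises(SequenceError, match="unknown modification"):
            ptm_track([(1, "sumoylation?")], 20)


# ---------------------------------------------------------------------------
# merged report
# ---------------------------------------------------------------------------

@pytest.fixture()
def query140():
    iso = generate_fixture("isoform-set", {"length": 140}, seed=12)[0]
    return ProteinSequence(residues=iso.residues, name="poi")


def test_domain_span_marks_all_positions(query140):
    track = span_track("ZnF_A20", [(10, 60)], "*", len(query140))
    assert set(track.symbols[9:60]) == {"*"}
    assert track.symbols[8] == " " and track.symbols[60] == " "


def test_all_rows_have_query_length(query140):
    tracks = [
        span_track("domain", [(10, 60)], "*", 140),
        ptm_track([(5, "acetylation"), (70, "ubiquitination")], 140),
    ]
    report = merge_tracks(tracks, query140)
    parsed = parse_report(report)
    for label, symbols in parsed.items():
        assert len(symbols.rstrip()) <= 140
        assert len(symbols.ljust(140)) == 140


def test_report_roundtrip_preserves_symbol_matrix(query140):
    tracks = [
        span_track("domain", [(10, 60)], "*", 140),
        span_track("coil", [(100, 130)], "@", 140),
        ptm_track([(5, "acetylation"), (70, "ubiquitination"),
                   (70, "acetylation")], 140),
    ]
    report = merge_tracks(tracks, query140)
    parsed = parse_report(report)
    assert parsed["POI"] == query140.residues
    for t in tracks:
        assert parsed[t.name].ljust(140) == t.symbols


def test_track_length_mismatch_rejected(query140):
    with pytest.raises(SequenceError, match="length"):
        merge_tracks([span_track("x", [(1, 5)], "*", 20)], query140)


def test_span_tracks_tsv_ingestion(tmp_path, query140):
    path = tmp_path / "tracks.tsv"
    path.write_text(
        "track\tstart\tend\tsymbol\n"
        "disorder\t1\t15\td\n"
        "disorder\t120\t140\td\n"
        "globular\t20\t110\tG\n"
    )
    tracks = read_span_tracks_tsv(path, 140)
    assert [t.name for t in tracks] == ["disorder", "globular"]
    disorder = tracks[0]
    assert set(disorder.symbols[0:15]) == {"d"}
    assert set(disorder.symbols[119:140]) == {"d"}
    assert disorder.symbols[15] == " "
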