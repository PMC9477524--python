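"""Alignment ingestion, quality filters, pileup construction and TSV I/O."""

from __future__ import annotations

import os

import numpy as np
import pysam
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonesift.pileup_io import (
    BASES,
    PileupFormatError,
    build_pileup,
    pileup_from_alignments,
    pooled_counts,
    read_alignments,
    read_pileup,
    write_pileup,
)
from clonesift.sim import export_sam, simulate_population
from conftest import make_pileup

HEADER = {
    "HD": {"VN": "1.6", "SO": "unsorted"},
    "SQ": [{"SN": "chr1", "LN": 10_000}],
}


def _write_sam(path, records):
    """records: (qname, flag, pos0, mapq, seq, quals, tags)"""
    with pysam.AlignmentFile(os.fspath(path), "wh", header=HEADER) as out:
        for qname, flag, pos, mapq, seq, quals, tags in records:
            a = pysam.AlignedSegment()
            a.query_name = qname
            a.flag = flag
            a.reference_id = 0
            a.reference_start = pos
            a.mapping_quality = mapq
            a.cigartuples = [(0, len(seq))]
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in quals)
            )
            for tag, value in tags.items():
                a.set_tag(tag, value)
            out.write(a)


class TestReadAlignments:
    def test_quality_filters(self, tmp_path):
        path = tmp_path / "in.sam"
        _write_sam(
            path,
            [
                # MAPQ 29: whole read dropped
                ("r1", 0, 100, 29, "ACGT", [37] * 4, {"CB": "X"}),
                # MAPQ 60 but one base below 30: only that base dropped
                ("r2", 0, 200, 60, "ACGT", [37, 29, 37, 37], {"CB": "X"}),
                # duplicate flag: dropped
                ("r3", 0x400, 300, 60, "ACGT", [37] * 4, {"CB": "X"}),
                # secondary: dropped
                ("r4", 0x100, 400, 60, "ACGT", [37] * 4, {"CB": "X"}),
            ],
        )
        obs = list(read_alignments(path, require_proper_pair=False))
        positions = sorted(p for _, _, _, p, _, _ in obs)
        assert positions == [200, 202, 203]

    def test_missing_barcode_raises(self, tmp_path):
        path = tmp_path / "in.sam"
        _write_sam(path, [("r1", 0, 100, 60, "ACGT", [37] * 4, {})])
        with pytest.raises(PileupFormatError, match="CB"):
            list(read_alignments(path, require_proper_pair=False))

    def test_empty_sam_gives_empty_stream(self, tmp_path):
        path = tmp_path / "in.sam"
        _write_sam(path, [])
        assert list(read_alignments(path)) == []

    def test_mates_share_fragment_id(self, tmp_path):
        path = tmp_path / "in.sam"
        _write_sam(
            path,
            [
                ("frag", 0x1 | 0x2 | 0x40, 100, 60, "AAAA", [37] * 4, {"CB": "X"}),
                ("frag", 0x1 | 0x2 | 0x80, 500, 60, "CCCC", [37] * 4, {"CB": "X"}),
                ("other", 0x1 | 0x2 | 0x40, 900, 60, "GGGG", [37] * 4, {"CB": "X"}),
            ],
        )
        obs = list(read_alignments(path))
        frag_of = {}
        for cell, frag, _, pos, _, _ in obs:
            frag_of.setdefault(pos // 100, frag)
        assert frag_of[1] == frag_of[5]
        assert frag_of[9] != frag_of[1]

    @pytest.mark.parametrize("base_q,map_q", [(0, 0), (30, 30), (37, 60), (40, 61)])
    def test_surviving_bases_monotone_in_cutoffs(self, tmp_path, base_q, map_q):
        path = tmp_path / "in.sam"
        rng = np.random.default_rng(0)
        records = []
        for i in range(30):
            quals = rng.integers(20, 42, size=8).tolist()
            records.append(
                (f"r{i}", 0, 10 * i, int(rng.integers(20, 61)),
                 "ACGTACGT", quals, {"CB": f"c{i % 3}"})
            )
        _write_sam(path, records)
        loose = len(list(read_alignments(path, min_base_qual=0, min_map_qual=0,
                                         require_proper_pair=False)))
        n = len(list(read_alignments(path, min_base_qual=base_q,
                                     min_map_qual=map_q,
                                     require_proper_pair=False)))
        assert n <= loose

    def test_per_cell_directory_mode(self, tmp_path):
        d = tmp_path / "cells"
        d.mkdir()
        _write_sam(d / "cellA.sam", [("r", 0, 10, 60, "AAAA", [37] * 4, {})])
        _write_sam(d / "cellB.sam", [("r", 0, 20, 60, "CCCC", [37] * 4, {})])
        cell_index: dict[str, int] = {}
        obs = list(read_alignments(d, require_proper_pair=False,
                                   cell_index=cell_index))
        assert cell_index == {"cellA": 0, "cellB": 1}
        assert {c for c, *_ in obs} == {0, 1}


class TestBuildPileup:
    def test_monomorphic_locus_removed(self):
        rows = [(5, c, 0, "A", 37) for c in range(10)]
        rows += [(6, 0, 0, "A", 37), (6, 1, 0, "C", 37)]
        p = make_pileup(rows, n_cells=10)
        assert p.n_loci == 1
        assert int(p.locus_pos[0]) == 6

    def test_mixed_locus_counts(self):
        rows = [(5, c, 0, "A", 37) for c in range(9)] + [(5, 9, 0, "C", 37)]
        p = make_pileup(rows, n_cells=10)
        bc = pooled_counts(p.get_locus(0))
        assert bc.counts == (9, 1, 0, 0)
        assert bc.c == 10

    def test_duplicate_fragment_hit_resolved_to_higher_quality(self):
        # overlapping mates of one fragment disagree at one locus
        rows = [
            (7, 0, 0, "A", 35),
            (7, 0, 0, "C", 32),
            (7, 1, 0, "G", 37),  # second cell so the locus is polymorphic
        ]
        p = make_pileup(rows, n_cells=2)
        loc = p.get_locus(0)
        rec = [r for r in loc.records if r[0] == 0]
        assert rec == [(0, 0, "A", 35)]

    def test_pooled_counts_tie_break_order(self):
        rows = [(3, c, 0, b, 37) for c, b in enumerate("ACGT")]
        p = make_pileup(rows, n_cells=4)
        bc = pooled_counts(p.get_locus(0))
        assert bc.counts == (1, 1, 1, 1)
        assert bc.bases == "ACGT"

    def test_count_conservation_random(self):
        rng = np.random.default_rng(1)
        rows = [
            (int(rng.integers(0, 50)), int(c), 0,
             "ACGT"[rng.integers(4)], 37)
            for c in range(1000)
        ]
        p = make_pileup(rows, n_cells=1000)
        total = sum(pooled_counts(p.get_locus(i)).c for i in range(p.n_loci))
        assert total == p.n_records

    def test_empty_observations(self):
        p = build_pileup([], chrom_names=["chr1"], chrom_lengths=[100], n_cells=1)
        assert p.n_loci == 0 and p.n_records == 0


class TestTsvRoundTrip:
    def test_round_trip_identity(self, tmp_path, small_two_clone):
        _, _, pileup = small_two_clone
        path = os.fspath(tmp_path / "pileup.tsv")
        write_pileup(pileup, path)
        back = read_pileup(path)
        for attr in ("pos", "cell", "frag", "base", "qual", "locus_start",
                     "cell_depths"):
            assert np.array_equal(getattr(pileup, attr), getattr(back, attr)), attr
        assert back.genome_length == pileup.genome_length
        assert back.chrom_names == pileup.chrom_names

    def test_positions_one_based_on_disk(self, tmp_path):
        p = make_pileup([(0, 0, 0, "A", 37), (0, 1, 0, "C", 37)], n_cells=2)
        path = os.fspath(tmp_path / "p.tsv")
        write_pileup(p, path)
        data_rows = [
            line for line in open(path)
            if not line.startswith("#") and not line.startswith("chrom")
        ]
        assert data_rows[0].split("\t")[1] == "1"  # in-memory 0 -> file 1
        assert int(read_pileup(path).locus_pos[0]) == 0

    def test_malformed_line_names_line_number(self, tmp_path):
        p = make_pileup([(0, 0, 0, "A", 37), (0, 1, 0, "C", 37)], n_cells=2)
        path = os.fspath(tmp_path / "p.tsv")
        write_pileup(p, path)
        lines = open(path).readlines()
        lines[5] = "chr1\tnotanumber\t0\t0\tA\t37\n"
        with open(path, "w") as fh:
            fh.writelines(lines)
        with pytest.raises(PileupFormatError, match="line 6"):
            read_pileup(path)


class TestSimOracleEquivalence:
    def test_sam_ingestion_reproduces_direct_pileup(self, tmp_path,
                                                    small_two_clone):
        """Pileup built from exported SAM equals the simulator's own pileup."""
        _, result, direct = small_two_clone
        path = os.fspath(tmp_path / "reads.sam")
        export_sam(result, path)
        via_sam, cell_index = pileup_from_alignments(path)
        assert len(cell_index) == result.truth.n_cells
        for attr in ("pos", "cell", "frag", "base", "qual", "locus_start",
                     "cell_depths"):
            assert np.array_equal(getattr(direct, attr),
                                  getattr(via_sam, attr)), attr


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(
            st.integers(0, 20),  # pos
            st.integers(0, 4),  # cell
            st.integers(0, 2),  # frag
            st.sampled_from("ACGT"),
            st.integers(0, 45),  # qual
        ),
        max_size=60,
    )
)
def test_pileup_invariants_random_observations(rows):
    """Rows sorted by position; every locus polymorphic; (cell,frag) unique."""
    p = make_pileup([(g, c, f, b, q) for g, c, f, b, q in rows], n_cells=5)
    assert np.all(np.diff(p.pos) >= 0)
    for i in range(p.n_loci):
        loc = p.get_locus(i)
        bases = {r[2] for r in loc.records}
        assert len(bases) >= 2
        keys = [(r[0], r[1]) for r in loc.records]
        assert len(keys) == len(set(keys))
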