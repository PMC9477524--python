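"""Barcoded-alignment ingestion and the per-locus observation store.

The central container is :class:`Pileup`, a column-oriented table of
(position, cell, fragment, base, quality) records sorted by genomic
position.  Positions are 0-based, half-open in memory and 1-based in the
TSV dialect.  All chromosomes are mapped onto a single global coordinate
axis (concatenated blocks); chromosome name / local position are
recovered on serialization.

Quality control mirrors standard ultra-low-coverage scDNA-seq practice:
bases below a Phred cutoff and reads below a mapping-quality cutoff are
discarded, and loci where every surviving base is identical carry no
clustering signal and are pruned.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

BASES = "ACGT"
BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}

DEFAULT_MIN_BASE_QUAL = 30
DEFAULT_MIN_MAP_QUAL = 30


@dataclass(frozen=True)
class BaseCounts:
    """Pooled per-locus base counts, sorted descending (c1 >= c2 >= c3 >= c4).

    ``bases`` gives the base identity for each count; ties broken by
    alphabetical base order A < C < G < T.
    """

    counts: tuple[int, int, int, int]
    bases: str

    @property
    def c1(self) -> int:
        return self.counts[0]

    @property
    def c2(self) -> int:
        return self.counts[1]

    @property
    def c3(self) -> int:
        return self.counts[2]

    @property
    def c4(self) -> int:
        return self.counts[3]

    @property
    def c(self) -> int:
        return sum(self.counts)


@dataclass
class LocusObservations:
    """All surviving observations at one genomic locus."""

    chrom: str
    pos: int  # 0-based within chrom
    records: list[tuple[int, int, str, int]]  # (cell_id, fragment_id, base, qual)


@dataclass
class Pileup:
    """Sorted column store of per-base observations across all loci.

    Rows are sorted by (global position, cell, fragment).  ``locus_start``
    holds row offsets delimiting each locus (length n_loci + 1).
    ``cell_depths`` counts every quality-passing base per cell *before*
    the all-identical-locus pruning, so pooled-coverage estimates are not
    biased by the pruning.
    """

    chrom_names: list[str]
    chrom_lengths: np.ndarray  # int64, per chromosome
    pos: np.ndarray  # int64 global 0-based, sorted
    cell: np.ndarray  # int32
    frag: np.ndarray  # int32, scoped per cell
    base: np.ndarray  # uint8 codes into BASES
    qual: np.ndarray  # uint8 Phred
    locus_start: np.ndarray  # int64 offsets, len n_loci + 1
    n_cells: int
    cell_depths: np.ndarray  # int64 per cell
    genome_length: int

    @property
    def n_loci(self) -> int:
        return len(self.locus_start) - 1

    @property
    def n_records(self) -> int:
        return len(self.pos)

    @property
    def chrom_offsets(self) -> np.ndarray:
        return np.concatenate([[0], np.cumsum(self.chrom_lengths)])

    @property
    def locus_pos(self) -> np.ndarray:
        """Global 0-based position of each locus."""
        return self.pos[self.locus_start[:-1]]

    def locus_sizes(self) -> np.ndarray:
        return np.diff(self.locus_start)

    def row_locus_index(self) -> np.ndarray:
        """Locus ordinal for every row."""
        return np.repeat(np.arange(self.n_loci), self.locus_sizes())

    def split_global_pos(self, gpos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Global position -> (chromosome index, local 0-based position)."""
        offsets = self.chrom_offsets
        ci = np.searchsorted(offsets, np.asarray(gpos), side="right") - 1
        return ci, np.asarray(gpos) - offsets[ci]

    def get_locus(self, i: int) -> LocusObservations:
        lo, hi = self.locus_start[i], self.locus_start[i + 1]
        ci, local = self.split_global_pos(self.pos[lo : lo + 1])
        records = [
            (int(self.cell[r]), int(self.frag[r]), BASES[self.base[r]], int(self.qual[r]))
            for r in range(lo, hi)
        ]
        return LocusObservations(self.chrom_names[ci[0]], int(local[0]), records)

    def iter_loci(self) -> Iterator[LocusObservations]:
        for i in range(self.n_loci):
            yield self.get_locus(i)

    def subset_cells(self, cells: Sequence[int]) -> "Pileup":
        """Restrict to a cell subset, re-pruning loci that lose all variation.

        Cell ids keep their global meaning; ``cell_depths`` is zeroed for
        cells outside the subset.
        """
        member = np.zeros(self.n_cells, dtype=bool)
        member[np.asarray(list(cells), dtype=np.int64)] = True
        keep = member[self.cell]
        depths = np.where(member, self.cell_depths, 0)
        return _assemble_pileup(
            self.pos[keep],
            self.cell[keep],
            self.frag[keep],
            self.base[keep],
            self.qual[keep],
            chrom_names=self.chrom_names,
            chrom_lengths=self.chrom_lengths,
            n_cells=self.n_cells,
            cell_depths=depths,
            genome_length=self.genome_length,
            presorted=True,
        )

    def mean_pooled_coverage(self, cells: Optional[Sequence[int]] = None) -> float:
        """Mean pooled per-locus depth over the genome for a cell group."""
        if cells is None:
            total = int(self.cell_depths.sum())
        else:
            total = int(self.cell_depths[np.asarray(list(cells), dtype=np.int64)].sum())
        return total / float(self.genome_length)


def pooled_counts(locus: LocusObservations) -> BaseCounts:
    """Sorted pooled base counts for one locus (ties broken A < C < G < T)."""
    counts = [0, 0, 0, 0]
    for _, _, b, _ in locus.records:
        counts[BASE_TO_CODE[b]] += 1
    order = sorted(range(4), key=lambda k: (-counts[k], k))
    return BaseCounts(
        tuple(counts[k] for k in order),  # type: ignore[arg-type]
        "".join(BASES[k] for k in order),
    )


def locus_base_counts(pileup: Pileup) -> np.ndarray:
    """(n_loci, 4) matrix of per-locus base counts in A,C,G,T order."""
    counts = np.zeros((pileup.n_loci, 4), dtype=np.int64)
    np.add.at(counts, (pileup.row_locus_index(), pileup.base), 1)
    return counts


def sorted_locus_counts(counts4: np.ndarray) -> np.ndarray:
    """Row-wise descending sort of ACGT count rows -> (c1, c2, c3, c4)."""
    return -np.sort(-np.asarray(counts4), axis=-1)


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------


def _assemble_pileup(
    gpos: np.ndarray,
    cell: np.ndarray,
    frag: np.ndarray,
    base: np.ndarray,
    qual: np.ndarray,
    *,
    chrom_names: Sequence[str],
    chrom_lengths: np.ndarray,
    n_cells: int,
    cell_depths: np.ndarray,
    genome_length: int,
    presorted: bool = False,
) -> Pileup:
    """Sort, deduplicate and prune raw observation columns into a Pileup.

    Duplicate (cell, fragment) hits at one locus (overlapping mates) are
    resolved to the highest-quality base; remaining ties break toward the
    alphabetically smaller base so results are order-independent.  Loci
    whose surviving bases are all identical are dropped.
    """
    cols = {
        "gpos": gpos,
        "cell": cell,
        "frag": frag,
        "base": np.asarray(base, dtype=np.uint8),
        "qual": np.asarray(qual, dtype=np.uint8),
    }
    return _assemble_pileup_consuming(
        cols,
        chrom_names=chrom_names,
        chrom_lengths=chrom_lengths,
        n_cells=n_cells,
        cell_depths=cell_depths,
        genome_length=genome_length,
        presorted=presorted,
    )


def _assemble_pileup_consuming(
    cols: dict[str, np.ndarray],
    *,
    chrom_names: Sequence[str],
    chrom_lengths: np.ndarray,
    n_cells: int,
    cell_depths: np.ndarray,
    genome_length: int,
    presorted: bool = False,
) -> Pileup:
    """Core builder; pops arrays out of ``cols`` so callers that hand over
    ownership (the simulator's streaming path, with ~1e8 rows) avoid
    holding duplicate copies alive during the sort."""
    base = np.asarray(cols.pop("base"), dtype=np.uint8)
    qual = np.asarray(cols.pop("qual"), dtype=np.uint8)
    gpos = cols.pop("gpos")
    cell = cols.pop("cell")
    frag = cols.pop("frag")

    if len(gpos) and not presorted:
        # Sort by (pos, cell, frag, qual desc, base) through one composite
        # int64 key built in place -- the observation table can run to 1e8
        # rows, so per-key lexsort copies are avoided whenever the key fits.
        max_frag = int(np.max(frag)) + 1
        span = (int(np.max(gpos)) + 1) * (int(n_cells) + 1) * max_frag * 64 * 4
        if span < 2**63:
            key = np.asarray(gpos).astype(np.int64)
            key *= n_cells + 1
            key += cell
            key *= max_frag
            key += frag
            key *= 64
            key += 63 - np.minimum(qual, 63)
            key *= 4
            key += base
            order = np.argsort(key, kind="stable")
            del key
        else:
            order = np.lexsort(
                (base, 255 - qual.astype(np.int16), frag, cell, gpos)
            )
        tmp = np.asarray(gpos)[order]
        del gpos
        gpos = tmp.astype(np.int64) if tmp.dtype != np.int64 else tmp
        tmp = np.asarray(cell)[order]
        del cell
        cell = tmp.astype(np.int32) if tmp.dtype != np.int32 else tmp
        tmp = np.asarray(frag)[order]
        del frag
        frag = tmp.astype(np.int32) if tmp.dtype != np.int32 else tmp
        base = base[order]
        qual = qual[order]
        del order, tmp

    gpos = np.asarray(gpos, dtype=np.int64)
    cell = np.asarray(cell, dtype=np.int32)
    frag = np.asarray(frag, dtype=np.int32)

    if len(gpos):
        # keep first row of each (pos, cell, frag) group = highest qual
        new = np.empty(len(gpos), dtype=bool)
        new[0] = True
        new[1:] = (
            (gpos[1:] != gpos[:-1]) | (cell[1:] != cell[:-1]) | (frag[1:] != frag[:-1])
        )
        gpos, cell, frag, base, qual = (
            gpos[new],
            cell[new],
            frag[new],
            base[new],
            qual[new],
        )

    if len(gpos):
        starts_mask = np.empty(len(gpos), dtype=bool)
        starts_mask[0] = True
        starts_mask[1:] = gpos[1:] != gpos[:-1]
        starts = np.flatnonzero(starts_mask)
        varied = np.maximum.reduceat(base, starts) != np.minimum.reduceat(base, starts)
        sizes = np.diff(np.concatenate([starts, [len(gpos)]]))
        row_keep = np.repeat(varied, sizes)
        gpos, cell, frag, base, qual = (
            gpos[row_keep],
            cell[row_keep],
            frag[row_keep],
            base[row_keep],
            qual[row_keep],
        )

    if len(gpos):
        starts_mask = np.empty(len(gpos), dtype=bool)
        starts_mask[0] = True
        starts_mask[1:] = gpos[1:] != gpos[:-1]
        locus_start = np.concatenate([np.flatnonzero(starts_mask), [len(gpos)]]).astype(
            np.int64
        )
    else:
        locus_start = np.zeros(1, dtype=np.int64)

    return Pileup(
        chrom_names=list(chrom_names),
        chrom_lengths=np.asarray(chrom_lengths, dtype=np.int64),
        pos=gpos,
        cell=cell,
        frag=frag,
        base=base,
        qual=qual,
        locus_start=locus_start,
        n_cells=int(n_cells),
        cell_depths=np.asarray(cell_depths, dtype=np.int64),
        genome_length=int(genome_length),
    )


def build_pileup_from_arrays(
    gpos: np.ndarray,
    cell: np.ndarray,
    frag: np.ndarray,
    base: np.ndarray,
    qual: np.ndarray,
    *,
    chrom_names: Sequence[str],
    chrom_lengths: Sequence[int],
    n_cells: int,
    genome_length: Optional[int] = None,
    min_base_qual: int = DEFAULT_MIN_BASE_QUAL,
) -> Pileup:
    """Vectorized pileup construction from raw observation columns."""
    qual = np.asarray(qual, dtype=np.uint8)
    keep = qual >= min_base_qual
    cell = np.asarray(cell, dtype=np.int32)
    depths = np.bincount(cell[keep], minlength=n_cells).astype(np.int64)
    chrom_lengths = np.asarray(chrom_lengths, dtype=np.int64)
    if genome_length is None:
        genome_length = int(chrom_lengths.sum())
    return _assemble_pileup(
        np.asarray(gpos, dtype=np.int64)[keep],
        cell[keep],
        np.asarray(frag, dtype=np.int32)[keep],
        np.asarray(base, dtype=np.uint8)[keep],
        qual[keep],
        chrom_names=chrom_names,
        chrom_lengths=chrom_lengths,
        n_cells=n_cells,
        cell_depths=depths,
        genome_length=genome_length,
    )


def build_pileup(
    observations: Iterable[tuple[int, int, str, int, str, int]],
    *,
    chrom_names: Sequence[str],
    chrom_lengths: Sequence[int],
    n_cells: int,
) -> Pileup:
    """Build a pileup from (cell, fragment, chrom, pos, base, qual) tuples.

    Observations are assumed to be pre-filtered (e.g. the output of
    :func:`read_alignments`); no further quality filtering is applied.
    """
    chrom_lengths = np.asarray(chrom_lengths, dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(chrom_lengths)])
    chrom_index = {name: i for i, name in enumerate(chrom_names)}
    cols: tuple[list, list, list, list, list] = ([], [], [], [], [])
    for cell_id, frag_id, chrom, p, b, q in observations:
        cols[0].append(offsets[chrom_index[chrom]] + p)
        cols[1].append(cell_id)
        cols[2].append(frag_id)
        cols[3].append(BASE_TO_CODE[b])
        cols[4].append(q)
    return build_pileup_from_arrays(
        np.array(cols[0], dtype=np.int64),
        np.array(cols[1], dtype=np.int32),
        np.array(cols[2], dtype=np.int32),
        np.array(cols[3], dtype=np.uint8),
        np.array(cols[4], dtype=np.uint8),
        chrom_names=chrom_names,
        chrom_lengths=chrom_lengths,
        n_cells=n_cells,
        min_base_qual=0,
    )


# ---------------------------------------------------------------------------
# Alignment ingestion
# ---------------------------------------------------------------------------


class PileupFormatError(ValueError):
    pass


def read_alignments(
    path: str | os.PathLike,
    *,
    min_base_qual: int = DEFAULT_MIN_BASE_QUAL,
    min_map_qual: int = DEFAULT_MIN_MAP_QUAL,
    require_proper_pair: bool = True,
    drop_duplicates: bool = True,
    primary_only: bool = True,
    cell_tag: str = "CB",
    cell_index: Optional[dict[str, int]] = None,
) -> Iterator[tuple[int, int, str, int, str, int]]:
    """Stream quality-filtered per-base observations from SAM/BAM input.

    ``path`` may be a single barcoded file (cell identity from ``cell_tag``)
    or a directory of per-cell files (cell identity from the file name).
    Barcodes map to dense integer ids in first-seen order; pass a dict as
    ``cell_index`` to capture (or pre-seed) the mapping.  Mates sharing a
    query name share a fragment id, so a fragment is one phased unit.

    Yields (cell_id, fragment_id, chrom, pos0, base, qual) tuples.
    """
    if cell_index is None:
        cell_index = {}
    path = os.fspath(path)
    if os.path.isdir(path):
        files = sorted(
            os.path.join(path, f)
            for f in os.listdir(path)
            if f.endswith((".sam", ".bam"))
        )
        sources: list[tuple[str, Optional[str]]] = [
            (f, os.path.splitext(os.path.basename(f))[0]) for f in files
        ]
    else:
        sources = [(path, None)]

    for fname, fixed_barcode in sources:
        # fragment ids are dense per cell, in first-seen order
        frag_index: dict[int, dict[str, int]] = {}
        with pysam.AlignmentFile(fname, check_sq=False) as af:
            for read in af:
                if read.is_unmapped:
                    continue
                if primary_only and (read.is_secondary or read.is_supplementary):
                    continue
                if drop_duplicates and read.is_duplicate:
                    continue
                if require_proper_pair and read.is_paired and not read.is_proper_pair:
                    continue
                if (read.mapping_quality or 0) < min_map_qual:
                    continue
                if fixed_barcode is not None:
                    barcode = fixed_barcode
                else:
                    try:
                        barcode = read.get_tag(cell_tag)
                    except KeyError:
                        raise PileupFormatError(
                            f"record {read.query_name!r} in {fname} lacks the "
                            f"{cell_tag} cell barcode tag"
                        ) from None
                cell_id = cell_index.setdefault(barcode, len(cell_index))
                cell_frags = frag_index.setdefault(cell_id, {})
                frag_id = cell_frags.setdefault(read.query_name, len(cell_frags))
                seq = read.query_sequence
                quals = read.query_qualities
                if seq is None or quals is None:
                    continue
                chrom = read.reference_name
                for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                    b = seq[qpos]
                    if b not in BASE_TO_CODE:
                        continue
                    q = quals[qpos]
                    if q < min_base_qual:
                        continue
                    yield (cell_id, frag_id, chrom, rpos, b, q)


def pileup_from_alignments(
    path: str | os.PathLike, **kwargs
) -> tuple[Pileup, dict[str, int]]:
    """Read alignments and build the pileup in one pass.

    Chromosome names/lengths come from the SAM header (first file in
    directory mode).
    """
    p = os.fspath(path)
    first = p
    if os.path.isdir(p):
        cand = sorted(f for f in os.listdir(p) if f.endswith((".sam", ".bam")))
        if not cand:
            raise PileupFormatError(f"no SAM/BAM files in directory {p}")
        first = os.path.join(p, cand[0])
    with pysam.AlignmentFile(first, check_sq=False) as af:
        chrom_names = list(af.references)
        chrom_lengths = list(af.lengths)
    cell_index: dict[str, int] = dict(kwargs.pop("cell_index", {}))
    obs = list(read_alignments(path, cell_index=cell_index, **kwargs))
    n_cells = max(len(cell_index), 1)
    pileup = build_pileup(
        obs, chrom_names=chrom_names, chrom_lengths=chrom_lengths, n_cells=n_cells
    )
    return pileup, cell_index


# ---------------------------------------------------------------------------
# TSV serialization (1-based positions on disk)
# ---------------------------------------------------------------------------

_HEADER_SQ = "#SQ"
_HEADER_META = "#META"
_COLUMNS = ["chrom", "pos", "cell_id", "fragment_id", "base", "qual"]


def write_pileup(pileup: Pileup, path: str | os.PathLike) -> None:
    """Write the pileup as TSV: chrom, pos (1-based), cell, fragment, base, qual."""
    ci, local = pileup.split_global_pos(pileup.pos)
    df = pd.DataFrame(
        {
            "chrom": np.array(pileup.chrom_names, dtype=object)[ci],
            "pos": local + 1,
            "cell_id": pileup.cell,
            "fragment_id": pileup.frag,
            "base": np.array(list(BASES))[pileup.base],
            "qual": pileup.qual,
        }
    )
    with open(path, "w") as fh:
        for name, length in zip(pileup.chrom_names, pileup.chrom_lengths):
            fh.write(f"{_HEADER_SQ}\t{name}\t{int(length)}\n")
        fh.write(f"{_HEADER_META}\tn_cells\t{pileup.n_cells}\n")
        fh.write(f"{_HEADER_META}\tgenome_length\t{pileup.genome_length}\n")
        fh.write(
            f"{_HEADER_META}\tcell_depths\t"
            + ",".join(str(int(d)) for d in pileup.cell_depths)
            + "\n"
        )
        fh.write("\t".join(_COLUMNS) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_pileup(path: str | os.PathLike) -> Pileup:
    """Read a pileup TSV written by :func:`write_pileup` (loss-free)."""
    chrom_names: list[str] = []
    chrom_lengths: list[int] = []
    meta: dict[str, str] = {}
    cols: tuple[list, list, list, list, list] = ([], [], [], [], [])
    chrom_index: dict[str, int] = {}
    offsets: Optional[np.ndarray] = None
    saw_columns = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if parts[0] == _HEADER_SQ:
                chrom_index[parts[1]] = len(chrom_names)
                chrom_names.append(parts[1])
                chrom_lengths.append(int(parts[2]))
                continue
            if parts[0] == _HEADER_META:
                meta[parts[1]] = parts[2]
                continue
            if not saw_columns:
                if parts != _COLUMNS:
                    raise PileupFormatError(
                        f"{path}: line {lineno}: expected column header "
                        f"{_COLUMNS}, got {parts}"
                    )
                saw_columns = True
                offsets = np.concatenate(
                    [[0], np.cumsum(np.array(chrom_lengths, dtype=np.int64))]
                )
                continue
            try:
                chrom, pos_s, cell_s, frag_s, b, qual_s = parts
                gpos = offsets[chrom_index[chrom]] + int(pos_s) - 1
                cols[0].append(gpos)
                cols[1].append(int(cell_s))
                cols[2].append(int(frag_s))
                cols[3].append(BASE_TO_CODE[b])
                cols[4].append(int(qual_s))
            except (ValueError, KeyError, TypeError) as exc:
                raise PileupFormatError(
                    f"{path}: line {lineno}: malformed pileup row: {line!r}"
                ) from exc
    n_cells = int(meta.get("n_cells", 0)) or (max(cols[1]) + 1 if cols[1] else 1)
    genome_length = int(meta.get("genome_length", sum(chrom_lengths)))
    if "cell_depths" in meta and meta["cell_depths"]:
        cell_depths = np.array(
            [int(x) for x in meta["cell_depths"].split(",")], dtype=np.int64
        )
    else:
        cell_depths = np.bincount(
            np.array(cols[1], dtype=np.int64), minlength=n_cells
        ).astype(np.int64)
    return _assemble_pileup(
        np.array(cols[0], dtype=np.int64),
        np.array(cols[1], dtype=np.int32),
        np.array(cols[2], dtype=np.int32),
        np.array(cols[3], dtype=np.uint8),
        np.array(cols[4], dtype=np.uint8),
        chrom_names=chrom_names,
        chrom_lengths=np.array(chrom_lengths, dtype=np.int64),
        n_cells=n_cells,
        cell_depths=cell_depths,
        genome_length=genome_length,
    )


def write_cell_index(cell_index: dict[str, int], path: str | os.PathLike) -> None:
    """Write the barcode -> dense id mapping as TSV."""
    with open(path, "w") as fh:
        fh.write("barcode\tcell_id\n")
        for barcode, idx in sorted(cell_index.items(), key=lambda kv: kv[1]):
            fh.write(f"{barcode}\t{idx}\n")
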