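"""Synthetic ultra-low-coverage single-cell DNA-seq with known clonal truth.

Emulates the regime of amplification-free droplet scDNA-seq: a diploid
genome carrying germline heterozygous sites (~1e-3 per bp), a clone tree
whose branches add private somatic SNVs (half gaining heterozygosity,
AA->AB, and half losing it, AB->AA), cells assigned to clones, and
per-cell fragments at 0.005-0.1x coverage with unbiased substitution
errors.  Fragments are placed uniformly (no GC or mappability bias) on a
single coordinate axis partitioned into contiguous chromosome blocks,
and each fragment - including both mates of a pair - samples exactly one
haplotype, so phase is preserved within a fragment.

Randomness: one master seed; each cell draws from an independent child
generator seeded as ``default_rng([seed, _CELL_STREAM, cell_index])``, so
per-cell data is reproducible in isolation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pysam

from .pileup_io import (
    BASES,
    DEFAULT_MIN_BASE_QUAL,
    Pileup,
    _assemble_pileup_consuming,
    build_pileup_from_arrays,
)

_CELL_STREAM = 7919  # stream tag separating per-cell generators from the master
_GERMLINE_ID = "__germline__"

GAIN_HET = "gain_het"  # AA -> AB: a homozygous site becomes heterozygous
LOSS_HET = "loss_het"  # AB -> AA: a germline het site loses its alternate allele


class SimConfigError(ValueError):
    pass


@dataclass(frozen=True)
class CloneSpec:
    clone_id: str
    parent_id: Optional[str]
    n_cells: int
    n_private_snvs: int


@dataclass
class SimConfig:
    genome_length_bp: int
    clone_specs: list[CloneSpec]
    n_chromosomes: int = 1
    germline_het_rate: float = 1e-3
    per_cell_coverage: float = 0.05
    read_length_bp: int = 100
    paired: bool = True
    fragment_span_bp: int = 500
    seq_error_rate: float = 0.01
    low_qual_fraction: float = 0.01
    low_qual_phred: int = 10
    base_qual_phred: int = 37
    seed: int = 0

    def validate(self) -> None:
        if self.genome_length_bp <= 0 or self.n_chromosomes <= 0:
            raise SimConfigError("genome_length_bp and n_chromosomes must be positive")
        if not 0.0 <= self.germline_het_rate <= 1.0:
            raise SimConfigError("germline_het_rate must be a probability")
        if self.per_cell_coverage <= 0:
            raise SimConfigError("per_cell_coverage must be positive")
        if not 0.0 <= self.seq_error_rate < 1.0:
            raise SimConfigError("seq_error_rate must be in [0, 1)")
        if self.paired and self.fragment_span_bp < 2 * self.read_length_bp:
            raise SimConfigError(
                "fragment_span_bp must fit two non-overlapping mates when paired"
            )
        if self.fragment_span_bp < self.read_length_bp:
            raise SimConfigError("fragment_span_bp must be >= read_length_bp")
        self._validated_tree()
        if sum(s.n_cells for s in self.clone_specs) <= 0:
            raise SimConfigError("total number of cells must be positive")

    def _validated_tree(self) -> list[CloneSpec]:
        """Return clone specs in root-to-leaf (topological) order."""
        ids = [s.clone_id for s in self.clone_specs]
        if len(set(ids)) != len(ids):
            raise SimConfigError("clone_ids must be unique")
        roots = [s for s in self.clone_specs if s.parent_id is None]
        if len(roots) != 1:
            raise SimConfigError("exactly one root clone (parent_id=None) required")
        by_id = {s.clone_id: s for s in self.clone_specs}
        order: list[CloneSpec] = []
        seen: set[str] = set()
        frontier = [roots[0]]
        while frontier:
            node = frontier.pop()
            if node.clone_id in seen:
                raise SimConfigError("clone tree contains a cycle")
            seen.add(node.clone_id)
            order.append(node)
            frontier.extend(
                s for s in self.clone_specs if s.parent_id == node.clone_id
            )
        if len(order) != len(self.clone_specs):
            raise SimConfigError(
                "clone parent graph is not a tree rooted at the root clone"
            )
        for s in self.clone_specs:
            if s.parent_id is not None and s.parent_id not in by_id:
                raise SimConfigError(f"unknown parent_id {s.parent_id!r}")
        return order

    @property
    def chrom_lengths(self) -> np.ndarray:
        base = self.genome_length_bp // self.n_chromosomes
        lengths = np.full(self.n_chromosomes, base, dtype=np.int64)
        lengths[: self.genome_length_bp % self.n_chromosomes] += 1
        return lengths

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]


@dataclass
class CloneTruth:
    """Ground truth: cell assignments and cumulative per-clone SNV sets.

    ``clone_snvs[cid]`` holds every somatic SNV on the path from the root
    to clone ``cid`` as (position, ref_base, alt_base, direction) with
    global 0-based positions.  ``germline_hets`` are the positions
    heterozygous in the root genome.
    """

    cell_to_clone: dict[int, str]
    clone_snvs: dict[str, set[tuple[int, str, str, str]]]
    germline_hets: set[int]

    @property
    def n_cells(self) -> int:
        return len(self.cell_to_clone)

    def clone_cells(self, clone_id: str) -> list[int]:
        return sorted(c for c, k in self.cell_to_clone.items() if k == clone_id)

    def labels(self) -> np.ndarray:
        """Dense integer clone label per cell, in clone-id sorted order."""
        clones = sorted(self.clone_snvs)
        index = {k: i for i, k in enumerate(clones)}
        out = np.empty(self.n_cells, dtype=np.int64)
        for cell, k in self.cell_to_clone.items():
            out[cell] = index[k]
        return out


@dataclass
class SimResult:
    """Simulation output: truth, raw observations and read layout.

    ``observations`` are per-base records in generation order (fragment-
    major within each cell); ``reads`` maps each emitted read onto its
    observation rows so a SAM export reproduces the exact same bases.
    """

    config: SimConfig
    truth: CloneTruth
    reference: np.ndarray  # uint8 base codes, full genome
    obs_pos: np.ndarray  # int64 global
    obs_cell: np.ndarray  # int32
    obs_frag: np.ndarray  # int32
    obs_base: np.ndarray  # uint8
    obs_qual: np.ndarray  # uint8
    read_cell: np.ndarray  # int32
    read_frag: np.ndarray  # int32
    read_start: np.ndarray  # int64 global
    read_len: np.ndarray  # int32
    read_is_mate2: np.ndarray  # bool
    read_obs_offset: np.ndarray  # int64 row offset into observations

    def pileup(self, min_base_qual: int = DEFAULT_MIN_BASE_QUAL) -> Pileup:
        return build_pileup_from_arrays(
            self.obs_pos,
            self.obs_cell,
            self.obs_frag,
            self.obs_base,
            self.obs_qual,
            chrom_names=self.config.chrom_names,
            chrom_lengths=self.config.chrom_lengths,
            n_cells=self.truth.n_cells,
            genome_length=self.config.genome_length_bp,
            min_base_qual=min_base_qual,
        )


# ---------------------------------------------------------------------------
# Genome and clone construction
# ---------------------------------------------------------------------------


class _HaplotypePair:
    """Sparse diploid genome: reference plus per-haplotype overrides."""

    def __init__(self) -> None:
        self.overrides: tuple[dict[int, int], dict[int, int]] = ({}, {})
        self._arrays: Optional[list[tuple[np.ndarray, np.ndarray]]] = None

    def copy(self) -> "_HaplotypePair":
        new = _HaplotypePair()
        new.overrides = (dict(self.overrides[0]), dict(self.overrides[1]))
        return new

    def finalize(self) -> None:
        arrays = []
        for h in (0, 1):
            pos = np.array(sorted(self.overrides[h]), dtype=np.int64)
            base = np.array(
                [self.overrides[h][p] for p in pos], dtype=np.uint8
            )
            arrays.append((pos, base))
        self._arrays = arrays

    def gather(self, reference: np.ndarray, gpos: np.ndarray, hap: int) -> np.ndarray:
        assert self._arrays is not None, "finalize() before gather()"
        out = reference[gpos].copy()
        vpos, vbase = self._arrays[hap]
        if len(vpos):
            idx = np.searchsorted(vpos, gpos)
            idx_clip = np.minimum(idx, len(vpos) - 1)
            hit = vpos[idx_clip] == gpos
            out[hit] = vbase[idx_clip[hit]]
        return out


def _build_clone_genomes(
    config: SimConfig, rng: np.random.Generator, reference: np.ndarray
) -> tuple[CloneTruth, dict[str, _HaplotypePair], np.ndarray]:
    L = config.genome_length_bp
    het_mask = rng.random(L) < config.germline_het_rate
    het_pos = np.flatnonzero(het_mask).astype(np.int64)
    het_hap = rng.integers(0, 2, size=len(het_pos))
    het_alt = (reference[het_pos] + rng.integers(1, 4, size=len(het_pos))) % 4
    het_info = {
        int(p): (int(h), int(a)) for p, h, a in zip(het_pos, het_hap, het_alt)
    }

    root_genome = _HaplotypePair()
    for p, (h, a) in het_info.items():
        root_genome.overrides[h][p] = a

    order = config._validated_tree()
    genomes: dict[str, _HaplotypePair] = {}
    snvs: dict[str, set[tuple[int, str, str, str]]] = {}
    # positions already touched by a somatic event anywhere in the tree,
    # so events never collide across branches
    used: set[int] = set()
    het_available: dict[str, set[int]] = {}
    germline_set = set(int(p) for p in het_pos)

    for spec in order:
        if spec.parent_id is None:
            genome = root_genome.copy()
            inherited: set[tuple[int, str, str, str]] = set()
            avail = set(germline_set)
        else:
            genome = genomes[spec.parent_id].copy()
            inherited = set(snvs[spec.parent_id])
            avail = set(het_available[spec.parent_id])
        private: set[tuple[int, str, str, str]] = set()
        for _ in range(spec.n_private_snvs):
            want_loss = rng.random() < 0.5
            if want_loss and avail:
                p = int(rng.choice(np.fromiter(avail, dtype=np.int64)))
                avail.discard(p)
                used.add(p)
                h, a = het_info[p]
                del genome.overrides[h][p]  # haplotype reverts to reference
                private.add((p, BASES[reference[p]], BASES[a], LOSS_HET))
            else:
                while True:
                    p = int(rng.integers(0, L))
                    if p not in germline_set and p not in used:
                        break
                used.add(p)
                h = int(rng.integers(0, 2))
                alt = int((reference[p] + rng.integers(1, 4)) % 4)
                genome.overrides[h][p] = alt
                private.add((p, BASES[reference[p]], BASES[alt], GAIN_HET))
        genome.finalize()
        genomes[spec.clone_id] = genome
        snvs[spec.clone_id] = inherited | private
        het_available[spec.clone_id] = avail

    cell_to_clone: dict[int, str] = {}
    cell = 0
    clone_of_cell: list[str] = []
    for spec in config.clone_specs:
        for _ in range(spec.n_cells):
            cell_to_clone[cell] = spec.clone_id
            clone_of_cell.append(spec.clone_id)
            cell += 1
    truth = CloneTruth(
        cell_to_clone=cell_to_clone,
        clone_snvs=snvs,
        germline_hets=germline_set,
    )
    return truth, genomes, np.array(clone_of_cell, dtype=object)


# ---------------------------------------------------------------------------
# Fragment sampling
# ---------------------------------------------------------------------------


def _prepare_simulation(config: SimConfig):
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    L = config.genome_length_bp
    reference = rng.integers(0, 4, size=L, dtype=np.uint8)
    truth, genomes, clone_of_cell = _build_clone_genomes(config, rng, reference)

    rl = config.read_length_bp
    span = config.fragment_span_bp if config.paired else rl
    bases_per_frag = 2 * rl if config.paired else rl
    lam = config.per_cell_coverage * L / bases_per_frag

    chrom_lengths = config.chrom_lengths
    chrom_offsets = np.concatenate([[0], np.cumsum(chrom_lengths)])
    placeable = np.maximum(chrom_lengths - span + 1, 0).astype(np.float64)
    if placeable.sum() <= 0:
        raise SimConfigError("no chromosome is long enough for one fragment")
    chrom_prob = placeable / placeable.sum()
    return reference, truth, genomes, clone_of_cell, rl, span, lam, (
        chrom_offsets, placeable, chrom_prob
    )


def _cell_chunk(
    config: SimConfig,
    cell: int,
    genome: _HaplotypePair,
    reference: np.ndarray,
    rl: int,
    span: int,
    lam: float,
    placement,
):
    """Generate one cell's reads; returns (obs dict, reads dict) or None.

    Observations are emitted fragment-major (frag0-mate1, frag0-mate2,
    frag1-mate1, ...) so each read occupies one contiguous row range.
    """
    chrom_offsets, placeable, chrom_prob = placement
    crng = np.random.default_rng([config.seed, _CELL_STREAM, cell])
    n_frag = int(crng.poisson(lam))
    if n_frag == 0:
        return None
    ci = crng.choice(config.n_chromosomes, size=n_frag, p=chrom_prob)
    within = (crng.random(n_frag) * placeable[ci]).astype(np.int64)
    start = chrom_offsets[ci] + within
    hap = crng.integers(0, 2, size=n_frag)

    if config.paired:
        starts = np.repeat(start, 2)
        starts[1::2] += span - rl
        frag_ids = np.repeat(np.arange(n_frag), 2)
        haps = np.repeat(hap, 2)
        mate2 = np.zeros(2 * n_frag, dtype=bool)
        mate2[1::2] = True
    else:
        starts = start
        frag_ids = np.arange(n_frag)
        haps = hap
        mate2 = np.zeros(n_frag, dtype=bool)

    n_reads = len(starts)
    gpos = (starts[:, None] + np.arange(rl)[None, :]).reshape(-1)
    bases = np.empty(len(gpos), dtype=np.uint8)
    hap_rows = np.repeat(haps, rl)
    for h in (0, 1):
        m = hap_rows == h
        if m.any():
            bases[m] = genome.gather(reference, gpos[m], h)
    if config.seq_error_rate > 0:
        err = crng.random(len(gpos)) < config.seq_error_rate
        n_err = int(err.sum())
        if n_err:
            bases[err] = (bases[err] + crng.integers(1, 4, size=n_err)) % 4
    quals = np.full(len(gpos), config.base_qual_phred, dtype=np.uint8)
    if config.low_qual_fraction > 0:
        low = crng.random(len(gpos)) < config.low_qual_fraction
        quals[low] = config.low_qual_phred

    obs = {
        "gpos": gpos,
        "frag": np.repeat(frag_ids.astype(np.int32), rl),
        "base": bases,
        "qual": quals,
    }
    reads = {
        "frag": frag_ids.astype(np.int32),
        "start": starts.astype(np.int64),
        "mate2": mate2,
        "row": np.arange(n_reads, dtype=np.int64) * rl,
    }
    return obs, reads


def simulate_population(config: SimConfig) -> SimResult:
    """Simulate the full cell population; see the module docstring.

    The expected number of sequenced bases per cell equals
    ``per_cell_coverage * genome_length_bp`` (fragment counts are Poisson).
    Keeps every raw observation and the read layout (for SAM export); for
    large runs where only the pileup is needed use :func:`simulate_pileup`.
    """
    reference, truth, genomes, clone_of_cell, rl, span, lam, placement = (
        _prepare_simulation(config)
    )
    obs_cols: dict[str, list[np.ndarray]] = {
        k: [] for k in ("gpos", "cell", "frag", "base", "qual")
    }
    read_cols: dict[str, list[np.ndarray]] = {
        k: [] for k in ("cell", "frag", "start", "mate2", "row")
    }
    obs_total = 0
    for cell in range(truth.n_cells):
        chunk = _cell_chunk(
            config, cell, genomes[clone_of_cell[cell]], reference, rl, span,
            lam, placement,
        )
        if chunk is None:
            continue
        obs, reads = chunk
        n = len(obs["gpos"])
        obs_cols["gpos"].append(obs["gpos"])
        obs_cols["cell"].append(np.full(n, cell, dtype=np.int32))
        obs_cols["frag"].append(obs["frag"])
        obs_cols["base"].append(obs["base"])
        obs_cols["qual"].append(obs["qual"])
        read_cols["cell"].append(np.full(len(reads["frag"]), cell, dtype=np.int32))
        read_cols["frag"].append(reads["frag"])
        read_cols["start"].append(reads["start"])
        read_cols["mate2"].append(reads["mate2"])
        read_cols["row"].append(reads["row"] + obs_total)
        obs_total += n

    def _cat(chunks: list[np.ndarray], dtype) -> np.ndarray:
        if not chunks:
            return np.empty(0, dtype=dtype)
        return np.concatenate(chunks)

    n_reads = sum(len(c) for c in read_cols["cell"])
    return SimResult(
        config=config,
        truth=truth,
        reference=reference,
        obs_pos=_cat(obs_cols["gpos"], np.int64),
        obs_cell=_cat(obs_cols["cell"], np.int32),
        obs_frag=_cat(obs_cols["frag"], np.int32),
        obs_base=_cat(obs_cols["base"], np.uint8),
        obs_qual=_cat(obs_cols["qual"], np.uint8),
        read_cell=_cat(read_cols["cell"], np.int32),
        read_frag=_cat(read_cols["frag"], np.int32),
        read_start=_cat(read_cols["start"], np.int64),
        read_len=np.full(n_reads, config.read_length_bp, dtype=np.int32),
        read_is_mate2=_cat(read_cols["mate2"], bool),
        read_obs_offset=_cat(read_cols["row"], np.int64),
    )


def simulate_pileup(
    config: SimConfig, min_base_qual: int = DEFAULT_MIN_BASE_QUAL
) -> tuple[CloneTruth, Pileup, np.ndarray]:
    """Simulate and build the quality-filtered pileup without retaining reads.

    Memory-lean path for large populations (~1e8 observations): base
    observations are quality-filtered per cell, stored with compact
    dtypes and handed to the pileup builder by ownership transfer.
    Produces exactly the same pileup as
    ``simulate_population(config).pileup(min_base_qual)``.

    Returns (truth, pileup, reference-base-code array).
    """
    reference, truth, genomes, clone_of_cell, rl, span, lam, placement = (
        _prepare_simulation(config)
    )
    L = config.genome_length_bp
    pos_dtype = np.int32 if L < 2**31 else np.int64
    frag_dtype = np.int16 if lam * 4 + 64 < 2**15 else np.int32
    chunks: dict[str, list[np.ndarray]] = {
        k: [] for k in ("gpos", "frag", "base", "qual")
    }
    counts: list[int] = []
    depths = np.zeros(truth.n_cells, dtype=np.int64)
    for cell in range(truth.n_cells):
        chunk = _cell_chunk(
            config, cell, genomes[clone_of_cell[cell]], reference, rl, span,
            lam, placement,
        )
        if chunk is None:
            counts.append(0)
            continue
        obs, _ = chunk
        keep = obs["qual"] >= min_base_qual
        depths[cell] = int(keep.sum())
        counts.append(int(keep.sum()))
        chunks["gpos"].append(obs["gpos"][keep].astype(pos_dtype))
        chunks["frag"].append(obs["frag"][keep].astype(frag_dtype))
        chunks["base"].append(obs["base"][keep])
        chunks["qual"].append(obs["qual"][keep])

    cols: dict[str, np.ndarray] = {}
    for name, dtype in (
        ("gpos", pos_dtype),
        ("frag", frag_dtype),
        ("base", np.uint8),
        ("qual", np.uint8),
    ):
        lst = chunks.pop(name)
        cols[name] = (
            np.concatenate(lst) if lst else np.empty(0, dtype=dtype)
        )
        lst.clear()
    cols["cell"] = np.repeat(
        np.arange(truth.n_cells, dtype=np.int32), np.array(counts, dtype=np.int64)
    )
    pileup = _assemble_pileup_consuming(
        cols,
        chrom_names=config.chrom_names,
        chrom_lengths=config.chrom_lengths,
        n_cells=truth.n_cells,
        cell_depths=depths,
        genome_length=L,
    )
    return truth, pileup, reference


# ---------------------------------------------------------------------------
# Truth serialization
# ---------------------------------------------------------------------------


def write_truth(truth: CloneTruth, prefix: str | os.PathLike) -> None:
    """Write truth tables: <prefix>.cells.tsv and <prefix>.snvs.tsv.

    Positions on disk are global and 1-based.  Germline heterozygous
    positions appear in the SNV table under the reserved clone id
    ``__germline__``.  Output is deterministically sorted.
    """
    prefix = os.fspath(prefix)
    with open(prefix + ".cells.tsv", "w") as fh:
        fh.write("cell_id\tclone_id\n")
        for cell in sorted(truth.cell_to_clone):
            fh.write(f"{cell}\t{truth.cell_to_clone[cell]}\n")
    with open(prefix + ".snvs.tsv", "w") as fh:
        fh.write("clone_id\tpos\tref\talt\tdirection\n")
        for clone in sorted(truth.clone_snvs):
            for pos, ref, alt, direction in sorted(truth.clone_snvs[clone]):
                fh.write(f"{clone}\t{pos + 1}\t{ref}\t{alt}\t{direction}\n")
        for pos in sorted(truth.germline_hets):
            fh.write(f"{_GERMLINE_ID}\t{pos + 1}\t.\t.\thet\n")


def read_truth(prefix: str | os.PathLike) -> CloneTruth:
    prefix = os.fspath(prefix)
    cell_to_clone: dict[int, str] = {}
    with open(prefix + ".cells.tsv") as fh:
        next(fh)
        for line in fh:
            cell_s, clone = line.rstrip("\n").split("\t")
            cell_to_clone[int(cell_s)] = clone
    clone_snvs: dict[str, set[tuple[int, str, str, str]]] = {}
    germline: set[int] = set()
    with open(prefix + ".snvs.tsv") as fh:
        next(fh)
        for line in fh:
            clone, pos_s, ref, alt, direction = line.rstrip("\n").split("\t")
            if clone == _GERMLINE_ID:
                germline.add(int(pos_s) - 1)
            else:
                clone_snvs.setdefault(clone, set()).add(
                    (int(pos_s) - 1, ref, alt, direction)
                )
    for clone in set(cell_to_clone.values()):
        clone_snvs.setdefault(clone, set())
    return CloneTruth(cell_to_clone, clone_snvs, germline)


# ---------------------------------------------------------------------------
# SAM export
# ---------------------------------------------------------------------------


def export_sam(result: SimResult, path: str | os.PathLike) -> None:
    """Write the simulated reads as a valid barcoded SAM file.

    One read group; every record carries the cell barcode in the CB tag.
    Bases and qualities are the exact simulated observations, so building
    a pileup from this file (under the same quality filters) reproduces
    ``result.pileup()``.
    """
    config = result.config
    chrom_lengths = config.chrom_lengths
    offsets = np.concatenate([[0], np.cumsum(chrom_lengths)])
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": name, "LN": int(ln)}
            for name, ln in zip(config.chrom_names, chrom_lengths)
        ],
        "RG": [{"ID": "sim", "SM": "synthetic"}],
    }
    span = config.fragment_span_bp
    rl = config.read_length_bp
    with pysam.AlignmentFile(os.fspath(path), "wh", header=header) as out:
        for r in range(len(result.read_cell)):
            cell = int(result.read_cell[r])
            frag = int(result.read_frag[r])
            gstart = int(result.read_start[r])
            ci = int(np.searchsorted(offsets, gstart, side="right") - 1)
            local = gstart - int(offsets[ci])
            off = int(result.read_obs_offset[r])
            seq = "".join(BASES[b] for b in result.obs_base[off : off + rl])
            qual = result.obs_qual[off : off + rl]
            a = pysam.AlignedSegment()
            a.query_name = f"c{cell}-f{frag}"
            a.reference_id = ci
            a.reference_start = local
            a.mapping_quality = 60
            a.cigartuples = [(0, rl)]
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in qual)
            )
            if config.paired:
                mate2 = bool(result.read_is_mate2[r])
                a.flag = 147 if mate2 else 99
                a.next_reference_id = ci
                if mate2:
                    a.next_reference_start = local - (span - rl)
                    a.template_length = -span
                else:
                    a.next_reference_start = local + span - rl
                    a.template_length = span
            else:
                a.flag = 0
            a.set_tag("CB", f"BC{cell:06d}")
            a.set_tag("RG", "sim")
            out.write(a)


def snv_prevalence(n_snvs: int, genome_length_bp: float) -> float:
    """Genome-wide prevalence of subclonal SNVs (events per bp)."""
    return n_snvs / float(genome_length_bp)


def two_clone_study_config(seed: int = 1) -> SimConfig:
    """The package's standard two-subclone benchmark configuration.

    Two equal clones of 500 cells on a 2 Mb genome: germline het rate
    1e-3, 600 clone-private somatic SNVs, per-cell coverage 0.05x
    (pooled ~50x), sequencing error 1%, paired 100 bp reads.  This is
    the regime in which the coverage/SNV feasibility sweep predicts a
    successful 2-way split at >90% precision and recall.
    """
    return SimConfig(
        genome_length_bp=2_000_000,
        clone_specs=[
            CloneSpec("healthy", None, 500, 0),
            CloneSpec("tumor", "healthy", 500, 600),
        ],
        germline_het_rate=1e-3,
        per_cell_coverage=0.05,
        seq_error_rate=0.01,
        paired=True,
        seed=seed,
    )
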