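"""Pseudo-bulk genotyping of cell clusters and VCF output.

Reads from all cells of one cluster are pooled into per-locus base
counts and the maximum-posterior diploid genotype is chosen among the
10 unordered base pairs under a MAQ-style multinomial model: a
homozygote gg emits g with probability 1 - theta and each other base
with theta/3; a heterozygote g1g2 emits each of g1, g2 with probability
1/2 - theta/3 and each other base with theta/3.  The genotype prior is
uniform and calls below a minimum pooled depth are suppressed — the
depth floor defaults to 9, the lowest pooled coverage sufficient for a
reliable call.  Call confidence is reported as a Phred-scaled posterior,
GQ = -10 log10(1 - posterior), capped at 255.

This caller is a reconstruction of the published approach from its
stated ingredients; its exact quality model may differ from the original.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from itertools import combinations_with_replacement
from typing import Iterable, Optional, Sequence

import numpy as np
import pysam
from scipy.special import logsumexp

from .pileup_io import BASES, BASE_TO_CODE, Pileup, locus_base_counts

#: the 10 unordered diploid genotypes as base-code pairs, lexicographic
GENOTYPES: tuple[tuple[int, int], ...] = tuple(
    combinations_with_replacement(range(4), 2)
)


@dataclass
class CallerParams:
    theta_call: float = 0.01  # post base-quality-filter error rate
    min_call_depth: int = 9
    gq_cap: int = 255


@dataclass(frozen=True)
class GenotypeCall:
    chrom: str
    pos: int  # 0-based
    ref_base: str
    genotype: tuple[str, str]  # unordered pair, alphabetical
    phred_quality: int
    depth: int

    @property
    def is_variant(self) -> bool:
        return self.genotype != (self.ref_base, self.ref_base)


def _genotype_log_emissions(theta: float) -> np.ndarray:
    """(10, 4) matrix of log per-base emission probabilities."""
    out = np.empty((len(GENOTYPES), 4))
    for gi, (a, b) in enumerate(GENOTYPES):
        probs = np.full(4, theta / 3.0)
        if a == b:
            probs[a] = 1.0 - theta
        else:
            probs[a] = 0.5 - theta / 3.0
            probs[b] = 0.5 - theta / 3.0
        out[gi] = np.log(probs)
    return out


def pool_cluster_counts(
    pileup: Pileup, cell_set: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """(positions, (n_loci, 4) ACGT counts) pooled over the cluster's cells.

    Counts are additive over disjoint cell sets: summing the children of
    a node reproduces the node's counts at every locus.
    """
    cell_set = np.asarray(sorted(set(int(c) for c in cell_set)), dtype=np.int64)
    if len(cell_set) == 0:
        raise ValueError("cell_set must be non-empty")
    member = np.zeros(pileup.n_cells, dtype=bool)
    member[cell_set] = True
    keep = member[pileup.cell]
    counts = np.zeros((pileup.n_loci, 4), dtype=np.int64)
    np.add.at(counts, (pileup.row_locus_index()[keep], pileup.base[keep]), 1)
    return pileup.locus_pos, counts


def call_genotype(
    counts_acgt: Sequence[int] | np.ndarray,
    ref_base: str,
    params: Optional[CallerParams] = None,
) -> Optional[GenotypeCall]:
    """Maximum-posterior diploid genotype from pooled ACGT counts.

    Returns ``None`` below the minimum call depth.  ``chrom``/``pos`` of
    the returned call are placeholders ("", 0); use
    :func:`call_cluster_variants` for positioned calls.
    """
    if params is None:
        params = CallerParams()
    if ref_base not in BASE_TO_CODE:
        raise ValueError(f"reference base must be one of {BASES}, got {ref_base!r}")
    counts = np.asarray(counts_acgt, dtype=np.float64)
    depth = int(counts.sum())
    if depth < params.min_call_depth:
        return None
    loglik = _genotype_log_emissions(params.theta_call) @ counts
    post = np.exp(loglik - logsumexp(loglik))
    gi = int(np.argmax(post))
    a, b = GENOTYPES[gi]
    gq = _phred_from_posterior(post[gi], params.gq_cap)
    return GenotypeCall(
        chrom="",
        pos=0,
        ref_base=ref_base,
        genotype=(BASES[a], BASES[b]),
        phred_quality=gq,
        depth=depth,
    )


def _phred_from_posterior(p: float, cap: int) -> int:
    if p >= 1.0:
        return cap
    return int(min(cap, round(-10.0 * np.log10(max(1.0 - p, 1e-300)))))


def call_cluster_variants(
    pileup: Pileup,
    cell_set: Sequence[int],
    reference: np.ndarray,
    params: Optional[CallerParams] = None,
) -> list[GenotypeCall]:
    """Variant calls (genotype != ref/ref) over all pileup loci of a cluster.

    ``reference`` is the base-code array over global coordinates.  Calls
    are made at every pileup locus, not only filter-passing ones — the
    locus filter is tuned for clustering, not calling.
    """
    if params is None:
        params = CallerParams()
    positions, counts = pool_cluster_counts(pileup, cell_set)
    depth = counts.sum(axis=1)
    callable_mask = depth >= params.min_call_depth
    if not callable_mask.any():
        return []
    emis = _genotype_log_emissions(params.theta_call)
    loglik = counts[callable_mask].astype(np.float64) @ emis.T
    post = np.exp(loglik - logsumexp(loglik, axis=1, keepdims=True))
    best = np.argmax(post, axis=1)
    pos_sel = positions[callable_mask]
    depth_sel = depth[callable_mask]
    ref_codes = reference[pos_sel]
    ci, local = pileup.split_global_pos(pos_sel)

    calls: list[GenotypeCall] = []
    for r in range(len(pos_sel)):
        a, b = GENOTYPES[best[r]]
        ref = int(ref_codes[r])
        if (a, b) == (ref, ref):
            continue
        calls.append(
            GenotypeCall(
                chrom=pileup.chrom_names[ci[r]],
                pos=int(local[r]),
                ref_base=BASES[ref],
                genotype=(BASES[a], BASES[b]),
                phred_quality=_phred_from_posterior(float(post[r, best[r]]),
                                                    params.gq_cap),
                depth=int(depth_sel[r]),
            )
        )
    return calls


def write_vcf(
    calls: Sequence[GenotypeCall],
    chrom_names: Sequence[str],
    chrom_lengths: Sequence[int],
    sample_name: str,
    path: str | os.PathLike,
    germline_mask: Optional[Iterable[tuple[str, int]]] = None,
) -> None:
    """Write one cluster's calls as VCF 4.2 (uncompressed, one sample).

    ``germline_mask`` is a set of (chrom, 0-based pos) to omit — e.g.
    known germline heterozygous sites.  Input must be sorted by
    (chrom order, pos); positions become 1-based in the file.
    """
    mask = set(germline_mask) if germline_mask is not None else set()
    order = {name: i for i, name in enumerate(chrom_names)}
    keys = [(order[c.chrom], c.pos) for c in calls]
    if keys != sorted(keys):
        raise ValueError("calls must be sorted by (chrom, pos)")

    header = pysam.VariantHeader()
    header.add_line('##fileformat=VCFv4.2')
    for name, length in zip(chrom_names, chrom_lengths):
        header.contigs.add(name, length=int(length))
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Pooled read depth")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    header.add_sample(sample_name)

    with pysam.VariantFile(os.fspath(path), "w", header=header) as out:
        for call in calls:
            if (call.chrom, call.pos) in mask:
                continue
            alts = sorted({b for b in call.genotype if b != call.ref_base})
            alleles = [call.ref_base] + alts
            idx = {b: i for i, b in enumerate(alleles)}
            rec = out.new_record(
                contig=call.chrom,
                start=call.pos,
                stop=call.pos + 1,
                alleles=tuple(alleles),
            )
            rec.samples[sample_name]["GT"] = tuple(idx[b] for b in call.genotype)
            rec.samples[sample_name]["DP"] = call.depth
            rec.samples[sample_name]["GQ"] = call.phred_quality
            out.write(rec)


def snv_recall(
    calls: Sequence[GenotypeCall],
    truth_positions: set[int],
    pileup: Pileup,
) -> float:
    """Fraction of true SNV positions recovered by variant calls."""
    if not truth_positions:
        return float("nan")
    offsets = pileup.chrom_offsets
    name_to_idx = {n: i for i, n in enumerate(pileup.chrom_names)}
    called = {
        int(offsets[name_to_idx[c.chrom]] + c.pos) for c in calls if c.is_variant
    }
    return len(called & truth_positions) / len(truth_positions)
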