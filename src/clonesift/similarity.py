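"""Phasing-aware cell-to-cell log-odds similarity from read overlaps.

The similarity s(i, j) of two cells is the log-odds of the two cells
having the same versus different genotypes, decomposed over *overlaps*:
pairs of fragments, one from each cell, sharing at least one informative
locus.  An overlap is summarized by (x_s, x_d) = (#matching bases,
#mismatching bases) across the shared informative loci.

The two overlap likelihoods model every informative position as
heterozygous, homozygous-identical or (in the different-genotype case)
subclonally mutated, with base-pair sequencing kernels

    P_ss = (1-theta)^2 + theta^2/3        same underlying base read as same
    P_sd = 1 - P_ss
    P_ds = 2(1-theta)theta/3 + 2theta^2/9 different bases read as same
    P_dd = 1 - P_ds

Because a fragment is a contiguous sample of one haplotype, the
haplotype choice couples *all* heterozygous positions of an overlap: the
factor (1/2)(P_ss^k P_sd^l + P_ds^k P_dd^l) sums over the two phase
configurations jointly rather than per position.  This is what makes a
long all-mismatch overlap weak evidence for "different genotypes" (it
may just be opposite phase) while mixed match/mismatch overlaps are the
strongest such evidence.

For fixed overlap length L = x_s + x_d each likelihood is a probability
distribution over {(x_s, x_d)}; both are evaluated exactly in log space
with precomputed log-binomials and cached per (x_s, x_d).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .locus_filter import InformativeLoci
from .pileup_io import Pileup

#: floor used when a configuration has probability zero in a degenerate
#: parameter limit (e.g. theta -> 0 with h = 1): log-probabilities are
#: clamped here rather than returning -inf so downstream sums stay finite.
LOG_FLOOR = -745.0  # ~ log of the smallest positive double


@dataclass
class SimilarityParams:
    """Overlap-model parameters.

    theta: sequencing error probability on informative positions (higher
        than the raw platform error rate because the informative set is
        enriched for positions carrying errors).
    h: fraction of homozygous loci among informative positions.
    epsilon: fraction of subclonally mutated loci among informative
        positions.
    max_overlap: overlaps up to this length are cached in a lookup table;
        longer ones are computed on demand.
    """

    theta: float = 0.05
    h: float = 0.5
    epsilon: float = 0.01
    max_overlap: int = 64

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta < 1.0:
            raise ValueError("theta must be in [0, 1)")
        if self.h < 0 or self.epsilon < 0 or self.h + self.epsilon > 1.0:
            raise ValueError("need h >= 0, epsilon >= 0 and h + epsilon <= 1")


@dataclass(frozen=True)
class PairKernels:
    p_ss: float
    p_sd: float
    p_ds: float
    p_dd: float


def pair_kernels(theta: float) -> PairKernels:
    """Closed-form base-pair sequencing kernels for error rate theta."""
    p_ss = (1.0 - theta) ** 2 + theta**2 / 3.0
    p_ds = 2.0 * (1.0 - theta) * theta / 3.0 + 2.0 * theta**2 / 9.0
    return PairKernels(p_ss=p_ss, p_sd=1.0 - p_ss, p_ds=p_ds, p_dd=1.0 - p_ds)


def _safe_log(x: float) -> float:
    return float(np.log(x)) if x > 0.0 else LOG_FLOOR


def _log_binom(n: int, k: np.ndarray | int) -> np.ndarray:
    return gammaln(n + 1) - gammaln(np.asarray(k) + 1) - gammaln(n - np.asarray(k) + 1)


def log_prob_same(xs: int, xd: int, params: SimilarityParams) -> float:
    """Log probability of an (xs, xd) overlap given equal genotypes.

    Double sum over k heterozygous matches and l heterozygous mismatches;
    the remaining positions are homozygous-identical.  Returns 0.0 for
    the empty overlap.
    """
    if xs < 0 or xd < 0:
        raise ValueError("overlap counts must be non-negative")
    if xs + xd == 0:
        return 0.0
    K = pair_kernels(params.theta)
    l_ss, l_sd = _safe_log(K.p_ss), _safe_log(K.p_sd)
    l_ds, l_dd = _safe_log(K.p_ds), _safe_log(K.p_dd)
    l_hom_w = _safe_log(params.h + params.epsilon / 2.0)
    l_het_w = _safe_log(1.0 - params.h - params.epsilon / 2.0)

    k = np.arange(xs + 1)[:, None]
    l = np.arange(xd + 1)[None, :]
    # phase-coupled heterozygous factor, combined with the hom kernels:
    # same-phase branch contributes Pss^k Psd^l, i.e. hom+het together give
    # Pss^xs Psd^xd; opposite phase swaps the het part to Pds^k Pdd^l.
    branch_same = float(xs * l_ss + xd * l_sd)
    branch_diff = (xs - k) * l_ss + (xd - l) * l_sd + k * l_ds + l * l_dd
    coupled = np.logaddexp(branch_same, branch_diff) - np.log(2.0)
    # k = l = 0: no heterozygous position, no phase ambiguity
    coupled = np.where((k + l) == 0, branch_same, coupled)
    terms = (
        _log_binom(xs, k)
        + _log_binom(xd, l)
        + (k + l) * l_het_w
        + (xs + xd - k - l) * l_hom_w
        + coupled
    )
    return float(logsumexp(terms) + _log_binom(xs + xd, xs))


def log_prob_diff(xs: int, xd: int, params: SimilarityParams) -> float:
    """Log probability of an (xs, xd) overlap given different genotypes.

    Quadruple sum: k/l heterozygous matches/mismatches (phase-coupled as
    in :func:`log_prob_same`), p/q homozygous-identical matches /
    mismatches, and the remainder subclonally mutated positions with
    mixed kernels (P_ss + P_ds)/2-style weights folded into epsilon/2.
    """
    if xs < 0 or xd < 0:
        raise ValueError("overlap counts must be non-negative")
    if xs + xd == 0:
        return 0.0
    K = pair_kernels(params.theta)
    l_ss, l_sd = _safe_log(K.p_ss), _safe_log(K.p_sd)
    l_ds, l_dd = _safe_log(K.p_ds), _safe_log(K.p_dd)
    l_het_w = _safe_log(1.0 - params.h - params.epsilon)
    l_hom_w = _safe_log(params.h)
    l_mut_w = _safe_log(params.epsilon / 2.0)
    l_mut_s = _safe_log(K.p_ss + K.p_ds)  # mutated position, bases read equal
    l_mut_d = _safe_log(K.p_dd + K.p_sd)  # mutated position, bases read different

    parts = []
    lg = gammaln(np.arange(max(xs, xd) + 2))
    for k in range(xs + 1):
        for l in range(xd + 1):
            p = np.arange(xs - k + 1)[:, None]
            q = np.arange(xd - l + 1)[None, :]
            multi = (
                lg[xs + 1] - lg[k + 1] - lg[p + 1] - lg[xs - k - p + 1]
                + lg[xd + 1] - lg[l + 1] - lg[q + 1] - lg[xd - l - q + 1]
            )
            if k + l == 0:
                coupled = 0.0
            else:
                coupled = float(
                    np.logaddexp(k * l_ss + l * l_sd, k * l_ds + l * l_dd)
                    - np.log(2.0)
                )
            terms = (
                multi
                + (k + l) * l_het_w
                + coupled
                + (xs + xd - k - l - p - q) * l_mut_w
                + (xs - k - p) * l_mut_s
                + (xd - l - q) * l_mut_d
                + (p + q) * l_hom_w
                + p * l_ss
                + q * l_sd
            )
            parts.append(logsumexp(terms))
    return float(logsumexp(parts) + _log_binom(xs + xd, xs))


class LogOddsTable:
    """Cached per-(xs, xd) overlap log-odds for one parameter set."""

    def __init__(self, params: SimilarityParams) -> None:
        self.params = params
        self._cache: dict[tuple[int, int], float] = {(0, 0): 0.0}

    def __call__(self, xs: int, xd: int) -> float:
        key = (int(xs), int(xd))
        val = self._cache.get(key)
        if val is None:
            val = log_prob_same(*key, self.params) - log_prob_diff(*key, self.params)
            self._cache[key] = val
        return val


def pair_log_odds(xs: int, xd: int, params: SimilarityParams) -> float:
    """Per-overlap contribution to s(i, j): log P_same - log P_diff."""
    return log_prob_same(xs, xd, params) - log_prob_diff(xs, xd, params)


def overlap_counts(
    frag_i: dict[int, int] | Sequence[tuple[int, int]],
    frag_j: dict[int, int] | Sequence[tuple[int, int]],
    informative_loci: Optional[set[int]] = None,
) -> Optional[tuple[int, int]]:
    """(x_s, x_d) over the informative loci two fragments share, or None.

    Fragments are given as {locus: base_code} maps (or (locus, base)
    pairs); loci outside ``informative_loci`` (when provided) are
    ignored.
    """
    di = dict(frag_i)
    dj = dict(frag_j)
    shared = set(di) & set(dj)
    if informative_loci is not None:
        shared &= informative_loci
    if not shared:
        return None
    xs = sum(1 for p in shared if di[p] == dj[p])
    return xs, len(shared) - xs


@dataclass
class SimilarityMatrix:
    """Symmetric dense matrix of pairwise cell log-odds, zero diagonal."""

    cells: np.ndarray  # global cell ids, sorted; row/col order
    matrix: np.ndarray  # (n, n) float64

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def build_similarity_matrix(
    pileup: Pileup,
    informative: InformativeLoci,
    params: SimilarityParams,
    cells: Optional[Sequence[int]] = None,
) -> SimilarityMatrix:
    """Accumulate per-overlap log-odds into the cell-to-cell matrix.

    Every pair of fragments from two *different* cells that shares at
    least one informative locus contributes pair_log_odds(xs, xd) to
    s(i, j); cell pairs with no overlapping fragments stay exactly 0.
    The accumulation order is fixed (loci in genomic order, fragments in
    sorted id order) so results are bit-reproducible.
    """
    if cells is None:
        cells_arr = np.arange(pileup.n_cells, dtype=np.int64)
    else:
        cells_arr = np.asarray(sorted(cells), dtype=np.int64)
        if len(cells_arr) and cells_arr[-1] >= pileup.n_cells:
            raise ValueError("cell id outside the pileup's cell universe")
    n = len(cells_arr)
    local = -np.ones(pileup.n_cells, dtype=np.int64)
    local[cells_arr] = np.arange(n)

    S = np.zeros((n, n), dtype=np.float64)
    if len(informative) == 0 or n == 0:
        return SimilarityMatrix(cells_arr, S)

    # rows at informative loci, restricted to the cell subset
    sizes = pileup.locus_sizes()
    sel = informative.locus_index
    row_idx = np.concatenate(
        [np.arange(pileup.locus_start[i], pileup.locus_start[i + 1]) for i in sel]
    ) if len(sel) else np.empty(0, dtype=np.int64)
    locus_of_row = np.repeat(np.arange(len(sel)), sizes[sel])
    cell_r = pileup.cell[row_idx]
    keep = local[cell_r] >= 0
    row_idx, locus_of_row, cell_r = row_idx[keep], locus_of_row[keep], cell_r[keep]
    frag_r = pileup.frag[row_idx]
    base_r = pileup.base[row_idx]

    if len(row_idx) == 0:
        return SimilarityMatrix(cells_arr, S)

    # dense fragment ids across (cell, frag)
    gid_key = cell_r.astype(np.int64) << 32 | frag_r.astype(np.int64)
    uniq, gid = np.unique(gid_key, return_inverse=True)
    frag_cell_local = local[(uniq >> 32).astype(np.int64)]

    # enumerate fragment pairs per informative locus
    order = np.lexsort((gid, locus_of_row))
    locus_of_row, gid, base_r = locus_of_row[order], gid[order], base_r[order]
    boundaries = np.flatnonzero(
        np.concatenate([[True], locus_of_row[1:] != locus_of_row[:-1], [True]])
    )
    pa_chunks, pb_chunks, match_chunks = [], [], []
    for s, e in zip(boundaries[:-1], boundaries[1:]):
        m = e - s
        if m < 2:
            continue
        ii, jj = np.triu_indices(m, 1)
        a, b = gid[s + ii], gid[s + jj]
        diff_cell = frag_cell_local[a] != frag_cell_local[b]
        if not diff_cell.any():
            continue
        a, b = a[diff_cell], b[diff_cell]
        pa_chunks.append(a)
        pb_chunks.append(b)
        match_chunks.append(base_r[s + ii][diff_cell] == base_r[s + jj][diff_cell])
    if not pa_chunks:
        return SimilarityMatrix(cells_arr, S)
    pa = np.concatenate(pa_chunks)
    pb = np.concatenate(pb_chunks)
    match = np.concatenate(match_chunks)

    # aggregate (xs, xd) per fragment pair
    lo = np.minimum(pa, pb).astype(np.int64)
    hi = np.maximum(pa, pb).astype(np.int64)
    pair_key = lo * len(uniq) + hi
    upairs, pidx = np.unique(pair_key, return_inverse=True)
    xs = np.bincount(pidx, weights=match.astype(np.float64)).astype(np.int64)
    tot = np.bincount(pidx).astype(np.int64)
    xd = tot - xs

    table = LogOddsTable(params)
    combo_key = xs * (int(tot.max()) + 1) + xd
    ucombo, cidx = np.unique(combo_key, return_inverse=True)
    combo_val = np.array(
        [
            table(int(k // (int(tot.max()) + 1)), int(k % (int(tot.max()) + 1)))
            for k in ucombo
        ]
    )
    weights = combo_val[cidx]

    ca = frag_cell_local[(upairs // len(uniq)).astype(np.int64)]
    cb = frag_cell_local[(upairs % len(uniq)).astype(np.int64)]
    np.add.at(S, (ca, cb), weights)
    np.add.at(S, (cb, ca), weights)
    np.fill_diagonal(S, 0.0)
    return SimilarityMatrix(cells_arr, S)


def write_similarity(sim: SimilarityMatrix, path: str) -> None:
    """Dense TSV with a cell-id header row."""
    with open(path, "w") as fh:
        fh.write("\t".join(str(int(c)) for c in sim.cells) + "\n")
        np.savetxt(fh, sim.matrix, fmt="%.10g", delimiter="\t")


def read_similarity(path: str) -> SimilarityMatrix:
    with open(path) as fh:
        cells = np.array([int(x) for x in fh.readline().split("\t")], dtype=np.int64)
        matrix = np.loadtxt(fh, delimiter="\t", ndmin=2)
    return SimilarityMatrix(cells, matrix)
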