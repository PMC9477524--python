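"""Bayesian selection of informative loci from pooled base counts.

A locus is informative for clonal deconvolution when the pooled counts
are unlikely under the hypothesis that every cell shares one homozygous
genotype.  Writing M = 1 for that hypothesis, the posterior

    P(M=1 | c1..c4) = P(c1..c4 | M=1) P(M=1) / P(c1..c4)

is computed with the likelihood approximated by its dominant homozygous
genotype (a multinomial with event probabilities (1-theta, theta/3,
theta/3, theta/3)) and the evidence approximated by a four-term sum over
locus classes: homozygous, heterozygous, homozygous+mutated and
heterozygous+mutated, weighted by the class priors p_hom, p_het, p_mut.
A single multinomial coefficient is shared by all four evidence terms,
and the uniform genotype-prior factor cancels between the numerator and
the evidence, so the posterior approaches 1 for unambiguous homozygous
loci.  Loci pass when the posterior falls at or below a threshold K.

Two auxiliary filters follow the same rationale: a fast heterozygous
heuristic keeps a locus only when c1 > 1.5 * c2 (a shared germline het
would show c1 ~ c2) with minimum support c1+c2+c3 >= 5, and count /
coverage filters drop loci with fewer than 5 non-major bases or with
pooled coverage more than two standard deviations from the pileup mean
(a signature of mapping artifacts).  All likelihood arithmetic is in
log space with lgamma factorials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import gammaln, logsumexp

from .pileup_io import BaseCounts, Pileup, locus_base_counts, sorted_locus_counts

#: order in which rejection reasons are attributed (first failing rule wins)
REJECTION_ORDER = ("coverage_outlier", "min_top3", "het_ratio", "min_nonref", "posterior")


@dataclass
class FilterParams:
    """Locus-filter knobs.

    Priors follow the conservative literature-derived choices: both the
    heterozygous-site rate and somatic-SNV prevalence are taken at 1e-3
    per bp, giving prior_same_hom = 1 - 2e-3 = 0.998.  theta is the
    error-enriched sequencing error rate used throughout clustering.
    """

    theta: float = 0.05
    K: float = 0.05
    p_het: float = 1e-3
    p_mut: float = 1e-3
    prior_same_hom: Optional[float] = None  # default: 1 - p_het - p_mut
    het_ratio: float = 1.5
    min_top3: int = 5
    min_nonref: int = 5
    coverage_sd_limit: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 < self.theta < 1.0:
            raise ValueError("theta must be in (0, 1)")
        if not 0.0 < self.K <= 1.0:
            raise ValueError("K must be in (0, 1]")
        if self.prior_same_hom is None:
            self.prior_same_hom = 1.0 - self.p_het - self.p_mut
        if not 0.0 <= self.prior_same_hom <= 1.0:
            raise ValueError("prior_same_hom must be a probability")

    @property
    def p_hom(self) -> float:
        return 1.0 - self.p_het - self.p_mut


@dataclass
class FilterReport:
    n_input_loci: int
    n_passed: int
    rejections: dict[str, int] = field(default_factory=dict)

    def check(self) -> None:
        assert self.n_input_loci == self.n_passed + sum(self.rejections.values())


@dataclass
class InformativeLoci:
    """Filter output: the selected loci with their statistics."""

    locus_index: np.ndarray  # indices into the source pileup's loci
    positions: np.ndarray  # global 0-based
    counts_acgt: np.ndarray  # (n, 4) in A,C,G,T order
    posteriors: np.ndarray

    def __len__(self) -> int:
        return len(self.locus_index)


def _as_sorted_counts(counts: BaseCounts | np.ndarray | tuple) -> np.ndarray:
    if isinstance(counts, BaseCounts):
        arr = np.asarray(counts.counts, dtype=np.float64)
    else:
        arr = -np.sort(-np.asarray(counts, dtype=np.float64), axis=-1)
    return arr


def _log_alpha_max(sorted_counts: np.ndarray, theta: float) -> np.ndarray:
    """log of the largest multinomial term max_g alpha_g (coefficient included).

    The maximizing genotype is always the homozygote of the most frequent
    base: alpha_g = coef * (1-theta)^{c_i} (theta/3)^{c-c_i} is increasing
    in c_i since 1-theta > theta/3 for theta < 3/4.
    """
    c = sorted_counts.sum(axis=-1)
    c1 = sorted_counts[..., 0]
    coef = gammaln(c + 1) - gammaln(sorted_counts + 1).sum(axis=-1)
    return coef + c1 * np.log1p(-theta) + (c - c1) * np.log(theta / 3.0)


def hom_likelihood(counts: BaseCounts | np.ndarray, theta: float) -> float:
    """P(c1..c4 | all cells share one homozygous genotype), dominant-term form.

    Evaluates max_g alpha_g * P(g) with a uniform genotype prior
    P(g) = 1/4.  Raises on zero coverage.
    """
    sc = _as_sorted_counts(counts)
    if sc.sum() <= 0:
        raise ValueError("hom_likelihood undefined at zero coverage")
    return float(np.exp(_log_alpha_max(sc, theta) + np.log(0.25)))


def _log_evidence(sorted_counts: np.ndarray, params: FilterParams) -> np.ndarray:
    """Four-term evidence approximation, log space, shared multinomial coefficient."""
    th = params.theta
    sc = sorted_counts
    c1, c2, c3, c4 = (sc[..., k] for k in range(4))
    c = sc.sum(axis=-1)
    coef = gammaln(c + 1) - gammaln(sc + 1).sum(axis=-1)
    log_err = np.log(th / 3.0)
    log_half = np.log(0.5 - th / 3.0)
    terms = np.stack(
        [
            np.log(params.p_hom) + c1 * np.log1p(-th) + (c2 + c3 + c4) * log_err,
            np.log(params.p_het) + (c1 + c2) * log_half + (c3 + c4) * log_err,
            np.log(params.p_hom)
            + np.log(params.p_mut)
            + c1 * np.log(0.75 - 2.0 * th / 3.0)
            + c2 * np.log(0.25)
            + (c3 + c4) * log_err,
            np.log(params.p_het)
            + np.log(params.p_mut)
            + c1 * log_half
            + (c2 + c3) * np.log(0.25)
            + c4 * log_err,
        ],
        axis=-1,
    )
    return coef + logsumexp(terms, axis=-1)


def evidence(counts: BaseCounts | np.ndarray, params: FilterParams) -> float:
    """Approximate marginal probability of the pooled counts, P(c1..c4)."""
    sc = _as_sorted_counts(counts)
    if sc.sum() <= 0:
        raise ValueError("evidence undefined at zero coverage")
    return float(np.exp(_log_evidence(sc, params)))


def evidence_terms(counts: BaseCounts | np.ndarray, params: FilterParams) -> np.ndarray:
    """The four evidence components (hom, het, hom+mut, het+mut), linear scale.

    Exposed for diagnostics; each term includes the shared multinomial
    coefficient so the values sum to :func:`evidence`.
    """
    sc = _as_sorted_counts(counts)
    th = params.theta
    c1, c2, c3, c4 = sc
    c = sc.sum()
    coef = float(gammaln(c + 1) - gammaln(sc + 1).sum())
    log_err = np.log(th / 3.0)
    log_half = np.log(0.5 - th / 3.0)
    logs = np.array(
        [
            np.log(params.p_hom) + c1 * np.log1p(-th) + (c2 + c3 + c4) * log_err,
            np.log(params.p_het) + (c1 + c2) * log_half + (c3 + c4) * log_err,
            np.log(params.p_hom) + np.log(params.p_mut)
            + c1 * np.log(0.75 - 2 * th / 3) + c2 * np.log(0.25) + (c3 + c4) * log_err,
            np.log(params.p_het) + np.log(params.p_mut)
            + c1 * log_half + (c2 + c3) * np.log(0.25) + c4 * log_err,
        ]
    )
    return np.exp(coef + logs)


def log_posterior_same_homozygous(
    sorted_counts: np.ndarray, params: FilterParams
) -> np.ndarray:
    """Vectorized log posterior for rows of descending-sorted counts."""
    la = _log_alpha_max(sorted_counts, params.theta)
    le = _log_evidence(sorted_counts, params)
    if params.prior_same_hom == 0.0:
        return np.full(np.shape(la), -np.inf)
    lp = la + np.log(params.prior_same_hom) - le
    return np.minimum(lp, 0.0)


def posterior_same_homozygous(
    counts: BaseCounts | np.ndarray, params: FilterParams
) -> float:
    """P(all cells share one homozygous genotype | pooled counts), in [0, 1].

    The uniform genotype-prior factor cancels between the dominant-term
    likelihood and the evidence's homozygous term, so it is omitted from
    both; the result is an approximation clipped to [0, 1].
    """
    sc = _as_sorted_counts(counts)
    if sc.sum() <= 0:
        raise ValueError("posterior undefined at zero coverage")
    return float(np.exp(log_posterior_same_homozygous(sc, params)))


def het_informative(counts: BaseCounts | np.ndarray, params: FilterParams) -> bool:
    """Fast heterozygous-locus heuristic: c1 > het_ratio*c2 and c1+c2+c3 >= min_top3."""
    sc = _as_sorted_counts(counts)
    c1, c2, c3 = sc[..., 0], sc[..., 1], sc[..., 2]
    return bool((c1 > params.het_ratio * c2) & (c1 + c2 + c3 >= params.min_top3))


def select_informative_loci(
    pileup: Pileup, params: FilterParams
) -> tuple[InformativeLoci, FilterReport]:
    """Apply all filters to every pileup locus.

    A locus passes iff the posterior is <= K, the heterozygous heuristic
    holds, at least ``min_nonref`` bases disagree with the majority base,
    and pooled coverage lies within ``coverage_sd_limit`` standard
    deviations of the pileup-wide mean (mean/sd over the loci present in
    this pileup).  Every rejection is attributed to the first failing
    rule in :data:`REJECTION_ORDER`.
    """
    counts4 = locus_base_counts(pileup)
    n = len(counts4)
    report = FilterReport(n_input_loci=n, n_passed=0,
                          rejections={r: 0 for r in REJECTION_ORDER})
    if n == 0:
        return (
            InformativeLoci(
                np.empty(0, dtype=np.int64),
                np.empty(0, dtype=np.int64),
                np.empty((0, 4), dtype=np.int64),
                np.empty(0),
            ),
            report,
        )
    sc = sorted_locus_counts(counts4).astype(np.float64)
    c = sc.sum(axis=1)
    c1, c2, c3 = sc[:, 0], sc[:, 1], sc[:, 2]

    mean_cov = float(c.mean())
    sd_cov = float(c.std())
    fail_cov = np.abs(c - mean_cov) > params.coverage_sd_limit * sd_cov
    fail_top3 = c1 + c2 + c3 < params.min_top3
    fail_ratio = c1 <= params.het_ratio * c2
    fail_nonref = c - c1 < params.min_nonref

    posterior = np.exp(log_posterior_same_homozygous(sc, params))
    fail_post = posterior > params.K

    fails = np.stack([fail_cov, fail_top3, fail_ratio, fail_nonref, fail_post])
    any_fail = fails.any(axis=0)
    first = np.argmax(fails, axis=0)
    for k, reason in enumerate(REJECTION_ORDER):
        report.rejections[reason] = int(np.sum(any_fail & (first == k)))
    passed = ~any_fail
    report.n_passed = int(passed.sum())
    report.check()

    idx = np.flatnonzero(passed)
    info = InformativeLoci(
        locus_index=idx.astype(np.int64),
        positions=pileup.locus_pos[idx],
        counts_acgt=counts4[idx],
        posteriors=posterior[idx],
    )
    return info, report


def calibrate_posterior_threshold(
    pileup: Pileup, params: FilterParams, target_pass_rate: float = 1e-4
) -> float:
    """Choose K on a null pileup so ~``target_pass_rate`` of its loci pass.

    ``pileup`` should come from data without subclonal structure (e.g. a
    single-clone simulation).  Among loci passing every non-posterior
    rule, K is set to the posterior quantile that lets approximately
    ``target_pass_rate`` of all input loci through; the returned value
    can be fed back into :class:`FilterParams`.  Returns the current K
    when no locus passes the other rules.
    """
    counts4 = locus_base_counts(pileup)
    if len(counts4) == 0:
        return params.K
    sc = sorted_locus_counts(counts4).astype(np.float64)
    c = sc.sum(axis=1)
    c1, c2, c3 = sc[:, 0], sc[:, 1], sc[:, 2]
    mean_cov, sd_cov = float(c.mean()), float(c.std())
    others_ok = (
        (np.abs(c - mean_cov) <= params.coverage_sd_limit * sd_cov)
        & (c1 + c2 + c3 >= params.min_top3)
        & (c1 > params.het_ratio * c2)
        & (c - c1 >= params.min_nonref)
    )
    if not others_ok.any():
        return params.K
    posteriors = np.sort(
        np.exp(log_posterior_same_homozygous(sc[others_ok], params))
    )
    n_target = int(np.floor(target_pass_rate * len(counts4)))
    if n_target < 1:
        # even the single smallest posterior exceeds the target rate;
        # place K just below it so nothing passes
        return float(max(posteriors[0] / 2.0, 0.0))
    k = posteriors[min(n_target, len(posteriors)) - 1]
    return float(k)


def write_informative_loci(
    info: InformativeLoci, pileup: Pileup, path: str
) -> None:
    """TSV: chrom, pos (1-based), c1..c4 (descending), posterior."""
    ci, local = pileup.split_global_pos(info.positions)
    sc = sorted_locus_counts(info.counts_acgt)
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tc1\tc2\tc3\tc4\tposterior\n")
        for k in range(len(info)):
            fh.write(
                f"{pileup.chrom_names[ci[k]]}\t{local[k] + 1}\t"
                + "\t".join(str(int(x)) for x in sc[k])
                + f"\t{info.posteriors[k]:.6g}\n"
            )


def write_filter_report(report: FilterReport, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("metric\tcount\n")
        fh.write(f"n_input_loci\t{report.n_input_loci}\n")
        fh.write(f"n_passed\t{report.n_passed}\n")
        for reason in REJECTION_ORDER:
            fh.write(f"rejected_{reason}\t{report.rejections.get(reason, 0)}\n")
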