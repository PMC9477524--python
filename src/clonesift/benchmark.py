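"""Reproducible end-to-end benchmark on the standard two-subclone study.

Runs the whole pipeline (simulate -> pileup -> filter -> similarity ->
recursive spectral clustering -> pseudo-bulk calling) on the two-clone
configuration of :func:`clonesift.sim.two_clone_study_config` and scores
the result against the simulated truth.  Used by the acceptance script
and the integration tests; every quantity reported is computed from the
run itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .clustering import ClusterNode, ClusterParams, partition_scores, recursive_cluster
from .locus_filter import FilterParams, FilterReport, select_informative_loci
from .pileup_io import Pileup
from .sim import GAIN_HET, CloneTruth, simulate_pileup, two_clone_study_config
from .similarity import SimilarityParams
from .variant_caller import CallerParams, call_cluster_variants, snv_recall


@dataclass
class StudyResult:
    truth: CloneTruth
    pileup: Pileup
    reference: np.ndarray
    tree: ClusterNode
    filter_report: FilterReport
    n_informative: int
    snv_loci_covered: int
    snv_loci_passed: int
    precision: float
    recall: float
    clustered_snv_recall: float
    unclustered_snv_recall: float

    @property
    def n_leaves(self) -> int:
        return len(self.tree.leaves())


def run_two_clone_study(
    seed: int = 1,
    min_cluster_cells: int = 100,
    filter_params: Optional[FilterParams] = None,
    similarity_params: Optional[SimilarityParams] = None,
    caller_params: Optional[CallerParams] = None,
) -> StudyResult:
    """Full pipeline on the standard two-clone fixture, scored against truth.

    ``seed`` drives the simulation; the clustering uses ``seed + 1`` so
    the two randomness sources stay distinct.  Precision/recall are the
    optimally-matched partition scores of the leaf partition versus the
    true clone assignment.  SNV recall is measured on the
    heterozygosity-gaining clone-private SNVs (the losses revert a
    germline het site to reference in the tumor, so a germline-masked
    caller cannot surface them) by calling once per true clone
    ("clustered") and once on all cells pooled ("unclustered").
    """
    fp = filter_params or FilterParams()
    sp = similarity_params or SimilarityParams()
    cp = CallerParams() if caller_params is None else caller_params

    config = two_clone_study_config(seed)
    truth, pileup, reference = simulate_pileup(config)

    info, report = select_informative_loci(pileup, fp)
    snv_pos = {s[0] for s in truth.clone_snvs["tumor"]}
    covered = set(int(p) for p in pileup.locus_pos) & snv_pos
    passed = set(int(p) for p in info.positions) & snv_pos

    cluster_params = ClusterParams(
        min_cluster_cells=min_cluster_cells, seed=seed + 1
    )
    tree = recursive_cluster(pileup, fp, sp, cluster_params)
    labels_true = truth.labels()
    labels_pred = tree.leaf_labels(pileup.n_cells)
    precision, recall = partition_scores(labels_true, labels_pred)

    gains = {
        s[0] for s in truth.clone_snvs["tumor"] if s[3] == GAIN_HET
    }
    tumor_cells = truth.clone_cells("tumor")
    healthy_cells = truth.clone_cells("healthy")
    clustered_calls = call_cluster_variants(pileup, tumor_cells, reference, cp)
    clustered_calls += call_cluster_variants(pileup, healthy_cells, reference, cp)
    unclustered_calls = call_cluster_variants(
        pileup, list(range(pileup.n_cells)), reference, cp
    )
    mask = truth.germline_hets
    clustered_rec = snv_recall(
        [c for c in clustered_calls
         if _gpos(c, pileup) not in mask],
        gains, pileup,
    )
    unclustered_rec = snv_recall(
        [c for c in unclustered_calls
         if _gpos(c, pileup) not in mask],
        gains, pileup,
    )

    return StudyResult(
        truth=truth,
        pileup=pileup,
        reference=reference,
        tree=tree,
        filter_report=report,
        n_informative=len(info),
        snv_loci_covered=len(covered),
        snv_loci_passed=len(passed),
        precision=precision,
        recall=recall,
        clustered_snv_recall=clustered_rec,
        unclustered_snv_recall=unclustered_rec,
    )


def _gpos(call, pileup: Pileup) -> int:
    offsets = pileup.chrom_offsets
    idx = pileup.chrom_names.index(call.chrom)
    return int(offsets[idx] + call.pos)
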