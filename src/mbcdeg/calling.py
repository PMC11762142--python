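"""Turning a fitted cluster model into a differential-expression call.

The non-DEG cluster is the one whose zero-sum center has the smallest
Euclidean (L2) norm: a center near the origin means no systematic
between-group difference for genes in that cluster. Genes are then ranked
by their posterior probability of belonging to that cluster — lower
posterior, stronger evidence of differential expression. The remaining
clusters are labeled by the group in which their center is highest
("DEG1" = up in the first group, "DEG2" = up in the second, ...).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .counts_io import CountMatrix, GroupDesign
from .nbmix import ClusterModel, em_fit
from .scaling import offsets_for_variant

__all__ = [
    "DEGResult",
    "NonDEGIdentificationWarning",
    "l2_norm",
    "find_nondeg_cluster",
    "label_patterns",
    "rank_genes",
    "run_mbcdeg",
]


class NonDEGIdentificationWarning(UserWarning):
    """The two smallest center norms are close: the non-DEG cluster call is ambiguous.

    This is the known failure mode at extreme DEG proportions, where a
    cluster of genuinely differential genes can present the smallest norm.
    """


@dataclass(frozen=True)
class DEGResult:
    """Ranked differential-expression call for every gene.

    ``scores`` are the posterior probabilities in the non-DEG cluster
    (lower = more DE); ``ranks`` is the permutation of 1..G induced by
    ascending score with stable ties; ``cluster_assignment`` holds 1-based
    argmax-posterior cluster indices (for reporting only — the ranking
    statistic is always the non-DEG posterior, never 1 - max posterior).
    """

    nondeg_index: int
    scores: np.ndarray
    ranks: np.ndarray
    patterns: tuple
    cluster_assignment: np.ndarray
    gene_ids: tuple = ()


def l2_norm(center) -> float:
    """Euclidean norm of a cluster center across groups."""
    return float(np.linalg.norm(np.asarray(center, dtype=float)))


def find_nondeg_cluster(model: ClusterModel, warn: bool = True) -> int:
    """1-based index of the minimal-norm center; ties go to the smaller index.

    Emits :class:`NonDEGIdentificationWarning` when the smallest norm
    exceeds half the second smallest, i.e. when the two candidates are
    within 50% of each other and misidentification is plausible.
    """
    norms = np.array([l2_norm(c) for c in model.centers])
    k = int(np.argmin(norms))
    if warn and model.K >= 2:
        ordered = np.sort(norms)
        if ordered[0] > 0.5 * ordered[1]:
            warnings.warn(
                "the two smallest cluster-center norms "
                f"({ordered[0]:.3g} and {ordered[1]:.3g}) are within 50% of each other; "
                "the non-DEG cluster may be misidentified",
                NonDEGIdentificationWarning,
                stacklevel=2,
            )
    return k + 1


def label_patterns(model: ClusterModel, nondeg_index: int) -> tuple:
    """Per-cluster pattern names: the non-DEG cluster, else "DEG<i>".

    ``i`` is the 1-based group in which the center is highest; several
    clusters may share a pattern name.
    """
    labels = []
    for k in range(model.K):
        if k + 1 == nondeg_index:
            labels.append("non-DEG")
        else:
            labels.append(f"DEG{int(np.argmax(model.centers[k])) + 1}")
    return tuple(labels)


def rank_genes(model: ClusterModel, gene_ids=()) -> DEGResult:
    """Rank genes by posterior probability in the non-DEG cluster.

    Rank 1 = most differentially expressed (smallest non-DEG posterior);
    ties resolve in input gene order (stable sort).
    """
    k_star = find_nondeg_cluster(model)
    scores = model.posteriors[:, k_star - 1].copy()
    order = np.argsort(scores, kind="stable")
    ranks = np.empty(scores.size, dtype=np.int64)
    ranks[order] = np.arange(1, scores.size + 1)
    cluster_assignment = model.posteriors.argmax(axis=1) + 1
    cluster_labels = label_patterns(model, k_star)
    patterns = tuple(cluster_labels[c - 1] for c in cluster_assignment)
    return DEGResult(
        nondeg_index=k_star,
        scores=scores,
        ranks=ranks,
        patterns=patterns,
        cluster_assignment=cluster_assignment,
        gene_ids=tuple(gene_ids),
    )


def run_mbcdeg(
    cm: CountMatrix,
    design: GroupDesign,
    variant: int,
    K: int = 3,
    seed: int = 0,
):
    """Run one MBCdeg variant end to end.

    Computes the variant's log scaling offsets, fits the K-component NB
    mixture, identifies the non-DEG cluster and ranks genes. Fully
    deterministic given ``seed``. Returns ``(DEGResult, ClusterModel)``.
    """
    offsets = offsets_for_variant(cm, design, variant)
    model = em_fit(cm, design, offsets, K=K, seed=seed)
    result = rank_genes(model, gene_ids=cm.gene_ids)
    return result, model
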