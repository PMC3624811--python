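"""Candidate-regulator restriction via time-lagged CLR relevance scores.

Before model selection, each gene's candidate regulators are limited to the
union of the top-k (default 10) TFs by a background-corrected relevance score
and every TF with a prior edge onto that gene.  Prior TFs are never filtered
out, so the structure prior can always be weighed by the regression stage.

Relevance uses the Gaussian mutual-information approximation
``r = -0.5 * ln(1 - rho^2)`` between a TF's time-lagged design column and the
gene's response, background-corrected CLR-style: z-scores of r against the
TF's distribution over all genes and against the gene's distribution over all
TFs, negatives clipped to zero, combined in quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import PriorMatrix
from .design import DesignResponseSet

__all__ = ["PredictorScores", "tlclr_scores", "candidate_set"]

DEFAULT_MAX_PREDICTORS = 10


@dataclass
class PredictorScores:
    """Background-corrected relevance scores, TF x gene."""

    scores: np.ndarray       # (n_tfs, n_genes) CLR z-scores
    correlations: np.ndarray  # (n_tfs, n_genes) lagged Pearson rho (tie-break)
    tf_ids: list[str]
    gene_ids: list[str]


def _zscore(r: np.ndarray, axis: int) -> np.ndarray:
    mu = r.mean(axis=axis, keepdims=True)
    sd = r.std(axis=axis, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (r - mu) / sd, 0.0)
    return np.clip(z, 0.0, None)


def tlclr_scores(drset: DesignResponseSet) -> PredictorScores:
    """Time-lagged CLR relevance of every (TF, gene) pair."""
    D = drset.design          # R x n_tfs, scaled
    Y = drset.response        # n_genes x R, scaled
    R = drset.n_obs
    denom = max(R - 1, 1)
    rho = (D.T @ Y.T) / denom          # n_tfs x n_genes
    rho = np.clip(rho, -1.0, 1.0)

    tf_ids = drset.dataset.tf_ids
    gene_ids = drset.dataset.gene_ids
    self_tf = np.asarray([tf_ids.index(g) for g in gene_ids if g in tf_ids])
    self_gene = np.asarray([i for i, g in enumerate(gene_ids) if g in tf_ids])
    if self_tf.size:
        rho[self_tf, self_gene] = 0.0

    rho2 = np.minimum(rho**2, 1.0 - 1e-12)
    relevance = -0.5 * np.log1p(-rho2)

    z_tf = _zscore(relevance, axis=1)    # background over the TF's targets
    z_gene = _zscore(relevance, axis=0)  # background over the gene's regulators
    scores = np.sqrt(z_tf**2 + z_gene**2)
    if self_tf.size:
        scores[self_tf, self_gene] = 0.0
    return PredictorScores(scores=scores, correlations=rho,
                           tf_ids=list(tf_ids), gene_ids=list(gene_ids))


def candidate_set(scores: PredictorScores, priors: PriorMatrix | None, gene_id: str,
                  max_k: int = DEFAULT_MAX_PREDICTORS) -> list[str]:
    """Candidate regulators of a gene: top-``max_k`` by score, union prior TFs.

    Self-regulation is excluded.  Ties at the score cut-off are broken by larger
    absolute lagged correlation, then lexicographic TF id.  The returned list is
    ordered by dataset TF order (stable downstream indexing).
    """
    gi = scores.gene_ids.index(gene_id)
    eligible = [j for j, t in enumerate(scores.tf_ids) if t != gene_id]

    def sort_key(j: int):
        return (-scores.scores[j, gi], -abs(scores.correlations[j, gi]), scores.tf_ids[j])

    top = sorted(eligible, key=sort_key)[:max_k]
    chosen = set(top)
    if priors is not None:
        prior_col = priors.entries[:, priors.gene_ids.index(gene_id)]
        for j, t in enumerate(scores.tf_ids):
            if t == gene_id:
                continue
            if prior_col[priors.tf_ids.index(t)]:
                chosen.add(j)
    return [scores.tf_ids[j] for j in sorted(chosen)]
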