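"""Confidence scoring, bootstrap ensemble, and rank combination.

A selected coefficient's magnitude is a poor confidence measure across genes,
so each edge is re-scored by how much of the target's variance the predictor
explains within its selected model:

    S_ij = 1 - sigma2_full / sigma2_without_j

where both residual variances come from OLS refits of the selected support
(with and without predictor j), clipped to [0, 1].  The whole pipeline
(candidate filtering -> model selection -> scoring) is run on 20 bootstrap
resamples of the design/response rows, and the per-bootstrap S matrices are
rank-combined (mean rank across bootstraps, average ranks on ties) into the
final ranked edge list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .bbsr import GPriorSpec, bbsr_fit
from .datasets import ExpressionDataset, PriorMatrix
from .design import DesignResponse, DesignResponseSet, build_design_response
from .filtering import DEFAULT_MAX_PREDICTORS, candidate_set, tlclr_scores
from .men import MenConfig, men_fit
from .regression import RegressionResult

__all__ = [
    "ConfidenceMatrix",
    "confidence_scores",
    "bootstrap_ensemble",
    "rank_combine",
    "run_inference",
    "RankedNetwork",
]

log = logging.getLogger(__name__)

DEFAULT_N_BOOTSTRAPS = 20


@dataclass
class ConfidenceMatrix:
    """TF x gene confidence scores S from one model-selection run."""

    scores: np.ndarray
    tf_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.tf_ids), len(self.gene_ids)):
            raise ValueError("score matrix shape does not match axes")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("non-finite confidence scores")


def _ols_ssr(X: np.ndarray, y: np.ndarray) -> float:
    if X.shape[1] == 0:
        return float(y @ y)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def confidence_scores(results: dict[str, RegressionResult],
                      drset: DesignResponseSet) -> ConfidenceMatrix:
    """Variance-ratio confidence S_ij for every selected edge of every gene."""
    ds = drset.dataset
    S = np.zeros((ds.n_tfs, ds.n_genes))
    tf_pos = {t: j for j, t in enumerate(ds.tf_ids)}
    for i, gene in enumerate(ds.gene_ids):
        res = results.get(gene)
        if res is None or not res.selected:
            continue
        dr = drset.for_gene(gene, predictor_ids=res.selected)
        X, y = dr.design, dr.response
        support = dr.predictor_ids
        ssr_full = _ols_ssr(X, y)
        for pos, tf in enumerate(support):
            cols = [c for c in range(len(support)) if c != pos]
            ssr_minus = _ols_ssr(X[:, cols], y)
            if ssr_minus <= 0:
                if ssr_full <= 0:
                    log.debug("gene %s, tf %s: no evidence either way", gene, tf)
                continue  # S stays 0
            S[tf_pos[tf], i] = float(np.clip(1.0 - ssr_full / ssr_minus, 0.0, 1.0))
    return ConfidenceMatrix(scores=S, tf_ids=list(ds.tf_ids), gene_ids=list(ds.gene_ids))


def _prior_sets(priors: PriorMatrix | None, dataset: ExpressionDataset) -> dict[str, set[str]]:
    if priors is None:
        return {g: set() for g in dataset.gene_ids}
    col = {g: i for i, g in enumerate(priors.gene_ids)}
    out = {}
    for g in dataset.gene_ids:
        tf_hits = np.nonzero(priors.entries[:, col[g]])[0]
        out[g] = {priors.tf_ids[j] for j in tf_hits if priors.tf_ids[j] != g}
    return out


def _fit_all(drset: DesignResponseSet, priors: PriorMatrix | None, method: str,
             gprior: GPriorSpec | None, men_config: MenConfig | None,
             max_predictors: int, rng: np.random.Generator,
             use_prior_weights: bool = True) -> dict[str, RegressionResult]:
    ds = drset.dataset
    scores = tlclr_scores(drset)
    prior_sets = _prior_sets(priors, ds)
    results: dict[str, RegressionResult] = {}
    for gene in ds.gene_ids:
        cands = candidate_set(scores, priors, gene, max_k=max_predictors)
        dr = drset.for_gene(gene, predictor_ids=cands)
        prior_tfs = prior_sets[gene] if use_prior_weights else set()
        if method == "bbsr":
            results[gene] = bbsr_fit(dr, prior_tfs, gprior)
        elif method == "men":
            results[gene] = men_fit(dr, prior_tfs, men_config, rng)
        else:
            raise ValueError(f"unknown method {method!r}")
    return results


def bootstrap_ensemble(dataset: ExpressionDataset, priors: PriorMatrix | None = None,
                       method: str = "bbsr", *, gprior: GPriorSpec | None = None,
                       men_config: MenConfig | None = None,
                       half_life: float | None = None,
                       max_predictors: int = DEFAULT_MAX_PREDICTORS,
                       n_boot: int = DEFAULT_N_BOOTSTRAPS,
                       seed: int | None = None,
                       no_resample: bool = False) -> list[ConfidenceMatrix]:
    """Run the full pipeline on ``n_boot`` bootstrap resamples.

    Each replicate resamples the constructed design/response row pairs with
    replacement (sample size equal to the original), preserving the time-lag
    pairing, then re-scales and runs filtering, model selection and scoring.
    ``no_resample=True`` runs every replicate on the original rows (testing
    hook).  All randomness derives deterministically from ``seed``.
    """
    kwargs = {} if half_life is None else {"half_life": half_life}
    drset = build_design_response(dataset, **kwargs)
    R = drset.n_obs
    ss = np.random.SeedSequence(seed)
    matrices = []
    for child in ss.spawn(n_boot):
        rng = np.random.default_rng(child)
        if no_resample:
            boot = drset
        else:
            rows = rng.integers(0, R, size=R)
            boot = drset.resample(rows)
        results = _fit_all(boot, priors, method, gprior, men_config,
                           max_predictors, rng)
        matrices.append(confidence_scores(results, boot))
    return matrices


@dataclass
class RankedNetwork:
    """Final rank-combined edge list, best edge first."""

    edges: pd.DataFrame  # columns: tf, target, combined_score, mean_rank, sign

    def ranked_pairs(self) -> list[tuple[str, str]]:
        return list(zip(self.edges["tf"], self.edges["target"]))

    def scores(self) -> np.ndarray:
        return self.edges["combined_score"].to_numpy()

    def write(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)


def rank_combine(matrices: list[ConfidenceMatrix],
                 signs: dict[tuple[str, str], int] | None = None) -> RankedNetwork:
    """Combine per-bootstrap S matrices into one ranked list by mean rank.

    Within each bootstrap, edges are ranked by descending S with average ranks
    on ties; the final order is ascending mean rank.  Self-pairs are excluded.
    ``combined_score`` rescales the mean rank to [0, 1] (1 = best) so that
    larger remains more confident downstream.
    """
    if not matrices:
        raise ValueError("need at least one confidence matrix")
    first = matrices[0]
    for m in matrices[1:]:
        if m.tf_ids != first.tf_ids or m.gene_ids != first.gene_ids:
            raise ValueError("confidence matrices have mismatched axes")

    tf_idx, gene_idx = np.meshgrid(np.arange(len(first.tf_ids)),
                                   np.arange(len(first.gene_ids)), indexing="ij")
    tf_names = np.asarray(first.tf_ids)[tf_idx.ravel()]
    gene_names = np.asarray(first.gene_ids)[gene_idx.ravel()]
    keep = tf_names != gene_names
    tf_names, gene_names = tf_names[keep], gene_names[keep]

    ranks = np.zeros(keep.sum())
    for m in matrices:
        flat = m.scores.ravel()[keep]
        ranks += rankdata(-flat, method="average")
    mean_rank = ranks / len(matrices)

    M = len(mean_rank)
    combined = 1.0 - (mean_rank - 1.0) / max(M - 1, 1)
    order = np.argsort(mean_rank, kind="stable")
    df = pd.DataFrame({
        "tf": tf_names[order],
        "target": gene_names[order],
        "combined_score": combined[order],
        "mean_rank": mean_rank[order],
        "sign": [0] * M if signs is None else
                [signs.get((t, g), 0) for t, g in zip(tf_names[order], gene_names[order])],
    })
    return RankedNetwork(edges=df)


def run_inference(dataset: ExpressionDataset, priors: PriorMatrix | None = None,
                  method: str = "bbsr", *, gprior: GPriorSpec | None = None,
                  men_config: MenConfig | None = None,
                  half_life: float | None = None,
                  max_predictors: int = DEFAULT_MAX_PREDICTORS,
                  n_boot: int = DEFAULT_N_BOOTSTRAPS,
                  seed: int | None = None,
                  no_resample: bool = False) -> RankedNetwork:
    """End-to-end inference: bootstrap ensemble plus a full-data fit for signs."""
    matrices = bootstrap_ensemble(
        dataset, priors, method, gprior=gprior, men_config=men_config,
        half_life=half_life, max_predictors=max_predictors, n_boot=n_boot,
        seed=seed, no_resample=no_resample,
    )
    kwargs = {} if half_life is None else {"half_life": half_life}
    drset = build_design_response(dataset, **kwargs)
    full = _fit_all(drset, priors, method, gprior, men_config, max_predictors,
                    np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0]))
    signs = {}
    for gene, res in full.items():
        for tf, beta in zip(res.selected, res.betas):
            signs[(tf, gene)] = int(np.sign(beta))
    return rank_combine(matrices, signs=signs)
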