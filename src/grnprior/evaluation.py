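"""Precision-recall evaluation and prior-robustness experiment machinery.

Ranked edge lists are scored against a gold standard by area under the
precision-recall curve (AUPR), evaluated only over the universe of (TF, gene)
pairs where both endpoints take part in at least one gold edge (self-pairs
excluded).  Also provided: leave-out-set evaluation (gold edges withheld from
the prior), the prior-corruption generator (true prior interactions, TPIs,
mixed with random false prior interactions, FPIs), a naive priors-first
ranking baseline, and random prior subsampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import EdgeMatrix, GoldStandard, PriorMatrix

__all__ = [
    "PRResult",
    "evaluation_universe",
    "aupr",
    "leave_out_eval",
    "corrupt_priors",
    "naive_prior_ranking",
    "subsample_priors",
]

Edge = tuple[str, str]


@dataclass
class PRResult:
    """Precision-recall curve and its area for one ranked list."""

    precision: np.ndarray
    recall: np.ndarray
    aupr: float
    n_gold: int
    n_eval: int


def evaluation_universe(gold: EdgeMatrix) -> set[Edge]:
    """All (TF, gene) pairs whose TF and gene each touch >= 1 gold edge."""
    has_out = gold.entries.sum(axis=1) > 0
    has_in = gold.entries.sum(axis=0) > 0
    tfs = [t for j, t in enumerate(gold.tf_ids) if has_out[j]]
    genes = [g for i, g in enumerate(gold.gene_ids) if has_in[i]]
    return {(t, g) for t in tfs for g in genes if t != g}


def _walk_curve(ordered: list[Edge], positives: set[Edge]) -> PRResult:
    n_gold = len(positives)
    tp = 0
    precision, recall = [], []
    for k, e in enumerate(ordered, start=1):
        if e in positives:
            tp += 1
        precision.append(tp / k)
        recall.append(tp / n_gold)
    precision = np.asarray(precision)
    recall = np.asarray(recall)
    prev = np.concatenate([[0.0], recall[:-1]])
    area = float(np.sum((recall - prev) * precision))
    return PRResult(precision=precision, recall=recall, aupr=area,
                    n_gold=n_gold, n_eval=len(ordered))


def _order_edges(ranked: list[Edge], scores: np.ndarray | None,
                 universe: set[Edge], rng: np.random.Generator) -> list[Edge]:
    """Restrict a ranking to the universe, permute ties, append unranked pairs."""
    in_universe = [(e, i) for i, e in enumerate(ranked) if e in universe]
    if scores is not None:
        # permute within tie groups so equal scores carry no hidden order
        groups: dict[float, list[Edge]] = {}
        for e, i in in_universe:
            groups.setdefault(float(scores[i]), []).append(e)
        ordered = []
        for s in sorted(groups, reverse=True):
            block = groups[s]
            ordered.extend([block[j] for j in rng.permutation(len(block))])
    else:
        ordered = [e for e, _ in in_universe]
    seen = set(ordered)
    rest = sorted(universe - seen)
    if rest:
        ordered.extend([rest[j] for j in rng.permutation(len(rest))])
    return ordered


def aupr(ranked: list[Edge], gold: EdgeMatrix, scores: np.ndarray | None = None,
         seed: int | None = None, universe: set[Edge] | None = None,
         positives: set[Edge] | None = None) -> PRResult:
    """Step-wise AUPR of a ranked edge list against a gold standard.

    ``ranked`` is best-first; ``scores`` (same length, descending) enables
    seeded tie permutation.  Edges outside the evaluation universe are dropped;
    universe pairs missing from the ranking are appended in seeded random
    order, so recall always reaches 1.
    """
    if universe is None:
        universe = evaluation_universe(gold)
    if positives is None:
        positives = set(gold.edge_list()) & universe
    if not positives:
        raise ValueError("gold standard contains no positives in the universe")
    rng = np.random.default_rng(seed)
    ordered = _order_edges(ranked, scores, universe, rng)
    return _walk_curve(ordered, positives)


def leave_out_eval(ranked: list[Edge], gold: EdgeMatrix, pki: EdgeMatrix,
                   scores: np.ndarray | None = None,
                   seed: int | None = None) -> PRResult:
    """AUPR over the leave-out set: gold edges *not* supplied as priors.

    Prior pairs are removed from the evaluation universe entirely, so the
    score reflects only the ability to discover novel interactions.
    """
    universe = evaluation_universe(gold)
    pki_set = set(pki.edge_list())
    positives = (set(gold.edge_list()) - pki_set) & universe
    if not positives:
        raise ValueError("leave-out set is empty (all gold edges were priors)")
    universe = universe - pki_set
    rng = np.random.default_rng(seed)
    ordered = _order_edges(ranked, scores, universe, rng)
    return _walk_curve(ordered, positives)


def corrupt_priors(gold: GoldStandard, tpi_fraction: float = 0.5,
                   fpi_ratio: int = 0, seed: int | None = None
                   ) -> tuple[PriorMatrix, set[Edge], set[Edge]]:
    """Build a corrupted prior: a TPI sample of the gold plus random FPIs.

    ``tpi_fraction`` of the gold edges are kept as true prior interactions;
    ``fpi_ratio`` false prior interactions per TPI are drawn uniformly from the
    non-gold, non-self (TF, gene) pairs.  Returns the prior matrix plus the
    TPI and FPI sets for bookkeeping.
    """
    rng = np.random.default_rng(seed)
    gold_edges = sorted(gold.edge_list())
    n_tpi = int(round(tpi_fraction * len(gold_edges)))
    tpi_idx = rng.choice(len(gold_edges), size=n_tpi, replace=False)
    tpis = {gold_edges[i] for i in tpi_idx}

    all_pairs = [(t, g) for t in gold.tf_ids for g in gold.gene_ids if t != g]
    non_gold = sorted(set(all_pairs) - set(gold_edges))
    n_fpi = fpi_ratio * n_tpi
    if n_fpi > len(non_gold):
        raise ValueError(
            f"cannot draw {n_fpi} false priors from {len(non_gold)} non-gold pairs")
    fpi_idx = rng.choice(len(non_gold), size=n_fpi, replace=False)
    fpis = {non_gold[i] for i in fpi_idx}

    entries = np.zeros_like(gold.entries)
    tf_pos = {t: j for j, t in enumerate(gold.tf_ids)}
    gene_pos = {g: i for i, g in enumerate(gold.gene_ids)}
    for t, g in tpis | fpis:
        entries[tf_pos[t], gene_pos[g]] = 1
    prior = PriorMatrix(entries=entries, tf_ids=list(gold.tf_ids),
                        gene_ids=list(gold.gene_ids))
    return prior, tpis, fpis


def naive_prior_ranking(priors: EdgeMatrix, universe: set[Edge],
                        seed: int | None = None) -> list[Edge]:
    """Baseline ranking: all prior pairs first, then the rest, both shuffled."""
    rng = np.random.default_rng(seed)
    prior_set = set(priors.edge_list()) & universe
    first = sorted(prior_set)
    rest = sorted(universe - prior_set)
    return ([first[i] for i in rng.permutation(len(first))]
            + [rest[i] for i in rng.permutation(len(rest))])


def subsample_priors(gold: GoldStandard, fraction: float, rep: int = 0,
                     seed: int | None = None) -> PriorMatrix:
    """Uniform without-replacement sample of the gold edges as a prior set.

    Repetition ``rep`` under the same ``seed`` is reproducible and independent
    of other repetitions.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed or 0, rep)))
    edges = sorted(gold.edge_list())
    n = int(round(fraction * len(edges)))
    idx = rng.choice(len(edges), size=n, replace=False)
    entries = np.zeros_like(gold.entries)
    tf_pos = {t: j for j, t in enumerate(gold.tf_ids)}
    gene_pos = {g: i for i, g in enumerate(gold.gene_ids)}
    for i in idx:
        t, g = edges[i]
        entries[tf_pos[t], gene_pos[g]] = 1
    return PriorMatrix(entries=entries, tf_ids=list(gold.tf_ids),
                       gene_ids=list(gold.gene_ids))
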