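"""Combinatorial gene-set optimization and robustness controls.

Every search evaluates candidate feature-gene lists through the seeded
reconstruction experiment (success rate + total variance) and ranks by
success rate descending with total variance ascending as tie-break.
Evaluations are cached by the sorted feature-gene tuple, so distinct set
combinations with identical gene unions are computed once.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import ReconstructionReport, run_trials
from .expression import ExpressionMatrix, log_transform
from .genesets import GeneSetCollection, enumerate_combinations, feature_union
from .som import SOMConfig

__all__ = [
    "SearchRecord",
    "records_to_frame",
    "scan_single_sets",
    "scan_anchored_combinations",
    "prune_genes",
    "gene_influence",
    "forward_gene_search",
    "noise_robustness",
]


@dataclass(frozen=True)
class SearchRecord:
    """One evaluated candidate: its identity, score and compactness."""

    feature: tuple[str, ...]  # set ids, removed genes, or the gene list itself
    genes: tuple[str, ...]
    success_rate: float
    total_variance: float
    reached_target: bool = True

    @property
    def n_genes(self) -> int:
        return len(self.genes)


def records_to_frame(records: list[SearchRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature": [";".join(r.feature) for r in records],
            "n_genes": [r.n_genes for r in records],
            "success_rate": [r.success_rate for r in records],
            "total_variance": [r.total_variance for r in records],
        }
    )


def _rank_key(r: SearchRecord) -> tuple:
    return (-r.success_rate, r.total_variance, r.feature)


class Evaluator:
    """Caching bridge from gene lists to reconstruction scores."""

    def __init__(
        self,
        data: ExpressionMatrix,
        annot: pd.DataFrame,
        cfg: SOMConfig | None = None,
        n_trials: int = 100,
        seed_start: int = 0,
    ):
        self.data = data
        self.annot = annot
        self.cfg = cfg or SOMConfig()
        self.n_trials = n_trials
        self.seed_start = seed_start
        self._cache: dict[tuple[str, ...], ReconstructionReport] = {}

    def report(self, genes: list[str]) -> ReconstructionReport:
        key = tuple(sorted(genes))
        if key not in self._cache:
            self._cache[key] = run_trials(
                self.data,
                list(key),
                self.annot,
                self.cfg,
                n_trials=self.n_trials,
                seed_start=self.seed_start,
            )
        return self._cache[key]

    def record(
        self, feature: tuple[str, ...], genes: list[str], reached: bool = True
    ) -> SearchRecord:
        rep = self.report(genes)
        return SearchRecord(
            feature=feature,
            genes=tuple(sorted(genes)),
            success_rate=rep.success_rate,
            total_variance=rep.total_variance,
            reached_target=reached,
        )


def scan_single_sets(
    collection: GeneSetCollection,
    data: ExpressionMatrix,
    annot: pd.DataFrame,
    cfg: SOMConfig | None = None,
    n_trials: int = 100,
    seed_start: int = 0,
) -> list[SearchRecord]:
    """Evaluate every gene set on its own; ranked best-first."""
    if len(collection) == 0:
        raise ValueError("empty collection")
    measured = set(data.gene_ids)
    ev = Evaluator(data, annot, cfg, n_trials, seed_start)
    records = []
    for gs in collection:
        genes = feature_union(collection, [gs.set_id], measured)
        records.append(ev.record((gs.set_id,), genes))
    return sorted(records, key=_rank_key)


def scan_anchored_combinations(
    collection: GeneSetCollection,
    anchor: str,
    pool: list[str],
    k: int,
    data: ExpressionMatrix,
    annot: pd.DataFrame,
    cfg: SOMConfig | None = None,
    n_trials: int = 100,
    seed_start: int = 0,
) -> list[SearchRecord]:
    """Evaluate the union of the anchor set with every k-combination of the pool."""
    measured = set(data.gene_ids)
    ev = Evaluator(data, annot, cfg, n_trials, seed_start)
    records = []
    for ids in enumerate_combinations(anchor, pool, k):
        genes = feature_union(collection, list(ids), measured)
        records.append(ev.record(ids, genes))
    return sorted(records, key=_rank_key)


def prune_genes(
    gene_list: list[str],
    data: ExpressionMatrix,
    annot: pd.DataFrame,
    cfg: SOMConfig | None = None,
    max_remove: int = 2,
    n_trials: int = 100,
    seed_start: int = 0,
) -> SearchRecord:
    """Best record over removing every subset of up to ``max_remove`` genes.

    Ties resolve to fewer removals, then lower total variance, then
    lexicographically on the removed genes.  The record's ``feature`` names
    the removed genes (empty tuple = no pruning).
    """
    if len(gene_list) <= max_remove:
        raise ValueError("gene_list must be longer than max_remove")
    ev = Evaluator(data, annot, cfg, n_trials, seed_start)
    candidates = [ev.record((), list(gene_list))]
    for j in range(1, max_remove + 1):
        for removed in itertools.combinations(sorted(gene_list), j):
            kept = [g for g in gene_list if g not in removed]
            candidates.append(ev.record(removed, kept))
    return min(
        candidates,
        key=lambda r: (-r.success_rate, len(r.feature), r.total_variance, r.feature),
    )


def gene_influence(
    gene_list: list[str],
    data: ExpressionMatrix,
    annot: pd.DataFrame,
    cfg: SOMConfig | None = None,
    pairs_with: str | None = None,
    n_trials: int = 100,
    seed_start: int = 0,
) -> list[SearchRecord]:
    """Leave-one-out (or leave-pair-out anchored at ``pairs_with``) influence.

    Returns one record per removed gene, sorted ascending by success rate so
    the most influential gene comes first.  The ``feature`` field names the
    removed gene(s).
    """
    if len(gene_list) < 2:
        raise ValueError("need at least two genes")
    if pairs_with is not None and pairs_with not in gene_list:
        raise ValueError(f"{pairs_with!r} not in gene_list")
    ev = Evaluator(data, annot, cfg, n_trials, seed_start)
    records = []
    for g in gene_list:
        removed = {g} if pairs_with is None else {g, pairs_with}
        if pairs_with is not None and g == pairs_with:
            continue
        kept = [x for x in gene_list if x not in removed]
        records.append(ev.record(tuple(sorted(removed)), kept))
    return sorted(records, key=lambda r: (r.success_rate, r.total_variance, r.feature))


def forward_gene_search(
    data: ExpressionMatrix,
    annot: pd.DataFrame,
    cfg: SOMConfig | None = None,
    candidate_genes: list[str] | None = None,
    target: float = 1.0,
    beam_width: int | None = None,
    max_depth: int = 6,
    n_trials: int = 100,
    seed_start: int = 0,
) -> list[SearchRecord]:
    """Greedy beam search growing gene sets until the target success rate.

    All singletons are evaluated first; the leaders (all ties for the best
    score, or the top ``beam_width``) are each extended by every remaining
    candidate, and so on.  Returns every record reaching ``target`` at the
    first depth where one does; if the depth cap is hit the best-so-far
    records are returned with ``reached_target=False``.
    """
    candidates = list(candidate_genes) if candidate_genes else list(data.gene_ids)
    if not candidates:
        raise ValueError("candidate_genes must be non-empty")
    ev = Evaluator(data, annot, cfg, n_trials, seed_start)
    beam = [ev.record((g,), [g]) for g in sorted(candidates)]
    beam.sort(key=_rank_key)
    for depth in range(1, max_depth + 1):
        winners = [r for r in beam if r.success_rate >= target]
        if winners:
            return winners
        if beam_width is None:
            best = beam[0].success_rate
            leaders = [r for r in beam if r.success_rate == best]
        else:
            leaders = beam[:beam_width]
        if depth == max_depth:
            break
        extended: dict[tuple[str, ...], SearchRecord] = {}
        for leader in leaders:
            for g in candidates:
                if g in leader.genes:
                    continue
                genes = sorted((*leader.genes, g))
                key = tuple(genes)
                if key not in extended:
                    extended[key] = ev.record(key, genes)
        if not extended:
            break
        beam = sorted(extended.values(), key=_rank_key)
    best = beam[0].success_rate
    return [
        SearchRecord(r.feature, r.genes, r.success_rate, r.total_variance, False)
        for r in beam
        if r.success_rate == best
    ]


def noise_robustness(
    data: ExpressionMatrix,
    gene_list: list[str],
    annot: pd.DataFrame,
    cfg: SOMConfig | None = None,
    levels: list[float] = (0.01, 0.02, 0.05, 0.10),
    seed: int = 0,
    n_trials: int = 100,
    seed_start: int = 0,
    sd_mode: str = "global",
) -> list[SearchRecord]:
    """Success rate under additive Gaussian noise at each level.

    Noise SD is ``level`` times the SD of all log-expression values of the
    feature submatrix (``sd_mode='global'``), or per gene
    (``sd_mode='per_gene'``).  Level 0 reproduces the noiseless record.
    """
    if any(lv < 0 for lv in levels):
        raise ValueError("noise levels must be >= 0")
    if sd_mode not in ("global", "per_gene"):
        raise ValueError(f"unknown sd_mode {sd_mode!r}")
    sub = data.subset_genes(list(gene_list))
    if not sub.transformed:
        sub = log_transform(sub)
    rng = np.random.default_rng(seed)
    records = []
    for lv in levels:
        if lv == 0:
            noisy = sub
        else:
            if sd_mode == "global":
                sd = float(sub.values.std()) * lv
                noise = rng.normal(0.0, sd, size=sub.frame.shape)
            else:
                sd = sub.values.std(axis=1, ddof=0) * lv
                noise = rng.normal(0.0, 1.0, size=sub.frame.shape) * sd[:, None]
            noisy = ExpressionMatrix(sub.frame + noise, transformed=True)
        rep = run_trials(
            noisy, None, annot, cfg, n_trials=n_trials, seed_start=seed_start
        )
        records.append(
            SearchRecord(
                feature=(f"noise={lv:g}",),
                genes=tuple(sorted(gene_list)),
                success_rate=rep.success_rate,
                total_variance=rep.total_variance,
            )
        )
    return records
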