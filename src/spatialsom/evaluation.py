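"""Scoring of 3D reconstructions against the four-domain embryo topology.

A reconstruction is judged on where the four expression domains
(D1 anterior, D2 lateral-distal, D3 lateral-proximal, D4 posterior) land on
the 2x2x2 lattice.  Per seeded trial, each domain's gravity center is the
mean of its samples' BMU coordinates; the trial scores s = 1 iff, after
rounding the centers to the lattice (half rounds up), all six pairwise
relations hold:

  * D1 and D4 sit diagonally on the xy-plane (differ in both x and y);
  * D2 and D3 are stacked along z (same x and y, different z);
  * each of D1/D4 is xy-adjacent to each of D2/D3 (rounded xy coordinates
    differ in exactly one of x, y) -- four relations.

Success rate is the mean of s over trials; total variance is the
trial-averaged mean of the 3 x D per-domain per-axis unbiased variances of
sample lattice coordinates, a compactness measure that separates gene sets
with equal success rates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EvaluationError
from .expression import DOMAINS, ExpressionMatrix, log_transform
from .som import Lattice, SOMConfig, SOMResults, StochasticSOM

__all__ = [
    "gravity_centers",
    "round_half_up",
    "topology_checks",
    "topology_score",
    "domain_variances",
    "total_variance",
    "domain_correlation",
    "TrialResult",
    "ReconstructionReport",
    "TissueReconstruction",
    "run_trials",
]


def _domain_samples(annot: pd.DataFrame, sample_ids: list[str]) -> dict[str, np.ndarray]:
    """Map each domain label to the integer positions of its samples."""
    domains = annot.loc[sample_ids, "domain"].to_numpy()
    out: dict[str, np.ndarray] = {}
    for d in DOMAINS:
        idx = np.flatnonzero(domains == d)
        if idx.size == 0:
            raise EvaluationError(f"domain {d} has no samples")
        out[d] = idx
    return out


def gravity_centers(results: SOMResults, annot: pd.DataFrame) -> dict[str, np.ndarray]:
    """Per-domain mean of the samples' BMU lattice coordinates."""
    coords = results.sample_coords
    groups = _domain_samples(annot, results.sample_ids)
    return {d: coords[idx].mean(axis=0) for d, idx in groups.items()}


def round_half_up(x: np.ndarray) -> np.ndarray:
    """Round to the nearest lattice level with ties (0.5) rounding up."""
    return np.floor(np.asarray(x, dtype=float) + 0.5)


def topology_checks(centers: dict[str, np.ndarray]) -> dict[str, bool]:
    """The six pairwise topology predicates on rounded gravity centers."""
    r = {d: round_half_up(c) for d, c in centers.items()}
    checks: dict[str, bool] = {}
    d1, d2, d3, d4 = (r[d] for d in DOMAINS)
    checks["D1-D4 xy-diagonal"] = bool(d1[0] != d4[0] and d1[1] != d4[1])
    checks["D2-D3 z-stacked"] = bool(
        d2[0] == d3[0] and d2[1] == d3[1] and d2[2] != d3[2]
    )
    for a, b in (("D1", "D2"), ("D1", "D3"), ("D4", "D2"), ("D4", "D3")):
        ra, rb = r[a], r[b]
        n_diff = int(ra[0] != rb[0]) + int(ra[1] != rb[1])
        checks[f"{a}-{b} xy-adjacent"] = n_diff == 1
    return checks


def topology_score(centers: dict[str, np.ndarray]) -> int:
    """1 iff all six (= C(4,2)) pairwise relations hold, else 0."""
    for c in centers.values():
        c = np.asarray(c, dtype=float)
        if not np.isfinite(c).all():
            raise EvaluationError("gravity centers must be finite")
    s_prime = sum(topology_checks(centers).values())
    return 1 if s_prime == 6 else 0


def domain_variances(
    results: SOMResults, annot: pd.DataFrame, warn_singleton: bool = True
) -> dict[str, np.ndarray]:
    """Per-domain, per-axis unbiased (n-1) variances of BMU coordinates.

    A single-sample domain has no unbiased variance; it is reported as 0
    with a warning.
    """
    coords = results.sample_coords
    groups = _domain_samples(annot, results.sample_ids)
    out: dict[str, np.ndarray] = {}
    for d, idx in groups.items():
        if idx.size < 2:
            if warn_singleton:
                warnings.warn(
                    f"domain {d} has a single sample; unbiased variance set to 0",
                    stacklevel=2,
                )
            out[d] = np.zeros(3)
        else:
            out[d] = coords[idx].var(axis=0, ddof=1)
    return out


@dataclass
class TrialResult:
    """One seeded reconstruction trial: centers, topology score, spread."""

    trial: int
    seed: int
    gravity_centers: dict[str, np.ndarray]
    s: int
    variances: dict[str, np.ndarray]  # domain -> (var_x, var_y, var_z)

    def variance_sum(self) -> float:
        return float(sum(v.sum() for v in self.variances.values()))


def total_variance(trials: list[TrialResult], n_domains: int = 4) -> float:
    """Trial-averaged mean of the 3*D per-domain per-axis variances.

    Every trial contributes regardless of its topology score.
    """
    if not trials:
        raise ValueError("no trials")
    per_trial = [t.variance_sum() / (3.0 * n_domains) for t in trials]
    return float(np.mean(per_trial))


def domain_correlation(
    data: ExpressionMatrix,
    feature_genes: list[str],
    annot: pd.DataFrame,
) -> pd.DataFrame:
    """Pearson correlation of per-domain mean log-expression vectors.

    Symmetric with unit diagonal; a domain whose mean vector has zero
    variance yields NaN against every other domain.
    """
    sub = data.subset_genes(list(feature_genes))
    if not sub.transformed:
        sub = log_transform(sub)
    groups = _domain_samples(annot, sub.sample_ids)
    means = np.column_stack([sub.values[:, idx].mean(axis=1) for idx in groups.values()])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(means, rowvar=False)
    corr = pd.DataFrame(corr, index=list(groups), columns=list(groups))
    np.fill_diagonal(corr.values, 1.0)
    return corr


@dataclass
class ReconstructionReport:
    """Aggregate of seeded reconstruction trials for one feature gene set."""

    feature_genes: list[str]
    trials: list[TrialResult]
    success_rate: float
    total_variance: float
    domain_correlation: pd.DataFrame | None = None
    config: SOMConfig | None = None

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def trial_table(self) -> pd.DataFrame:
        rows = []
        for tr in self.trials:
            row: dict[str, object] = {"trial": tr.trial, "seed": tr.seed, "s": tr.s}
            for d, v in tr.variances.items():
                row[f"var_{d}"] = float(v.sum())
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "3D reconstruction report",
            "========================",
            f"feature genes:  {len(self.feature_genes)}",
            f"trials:         {self.n_trials}",
            f"success rate:   {self.success_rate:.2%}",
            f"total variance: {self.total_variance:.4f}",
        ]
        if self.domain_correlation is not None:
            lines.append("domain correlation:")
            lines.append(self.domain_correlation.round(3).to_string())
        return "\n".join(lines)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_genes": self.feature_genes,
            "n_trials": self.n_trials,
            "success_rate": self.success_rate,
            "total_variance": self.total_variance,
            "domain_correlation": (
                None
                if self.domain_correlation is None
                else self.domain_correlation.to_dict()
            ),
            "trials": [
                {
                    "trial": tr.trial,
                    "seed": tr.seed,
                    "s": tr.s,
                    "gravity_centers": {d: c.tolist() for d, c in tr.gravity_centers.items()},
                    "variances": {d: v.tolist() for d, v in tr.variances.items()},
                }
                for tr in self.trials
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    def trials_to_tsv(self, path: str | Path) -> None:
        self.trial_table().to_csv(path, sep="\t", index=False)


class TissueReconstruction:
    """Reconstruction experiment: repeated seeded SOM fits scored on topology.

    Parameters
    ----------
    data : ExpressionMatrix
    annot : pandas.DataFrame
        Sample annotation indexed by sample id with a ``domain`` column;
        ground truth used only for scoring, never by the SOM itself.
    feature_genes : list of str, optional
    config : SOMConfig, optional

    Examples
    --------
    >>> model = TissueReconstruction(data, annot, feature_genes=genes)
    >>> report = model.fit(n_trials=100, seed_start=0)
    >>> report.success_rate, report.total_variance
    """

    def __init__(
        self,
        data: ExpressionMatrix,
        annot: pd.DataFrame,
        feature_genes: list[str] | None = None,
        config: SOMConfig | None = None,
        lattice: Lattice | None = None,
    ):
        self.config = config or SOMConfig()
        self.som = StochasticSOM(data, feature_genes, self.config, lattice)
        self.data = data
        self.annot = annot
        self.feature_genes = self.som.feature_genes
        missing = set(self.som.data.sample_ids) - set(annot.index)
        if missing:
            raise EvaluationError(f"samples without annotation: {sorted(missing)[:5]}")

    def fit(
        self,
        n_trials: int = 100,
        seed_start: int = 0,
        with_correlation: bool = True,
        warn_singleton: bool = True,
    ) -> ReconstructionReport:
        """Run ``n_trials`` fits with seeds ``seed_start .. seed_start+n-1``."""
        if n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        trials: list[TrialResult] = []
        for t in range(n_trials):
            seed = seed_start + t
            res = self.som.fit(seed=seed)
            centers = gravity_centers(res, self.annot)
            variances = domain_variances(
                res, self.annot, warn_singleton=warn_singleton and t == 0
            )
            trials.append(
                TrialResult(
                    trial=t,
                    seed=seed,
                    gravity_centers=centers,
                    s=topology_score(centers),
                    variances=variances,
                )
            )
        corr = (
            domain_correlation(self.som.data, self.feature_genes, self.annot)
            if with_correlation
            else None
        )
        return ReconstructionReport(
            feature_genes=list(self.feature_genes),
            trials=trials,
            success_rate=float(np.mean([tr.s for tr in trials])),
            total_variance=total_variance(trials, n_domains=len(DOMAINS)),
            domain_correlation=corr,
            config=self.config,
        )


def run_trials(
    data: ExpressionMatrix,
    feature_genes: list[str] | None,
    annot: pd.DataFrame,
    cfg: SOMConfig | None = None,
    n_trials: int = 100,
    seed_start: int = 0,
    with_correlation: bool = False,
) -> ReconstructionReport:
    """Functional wrapper over :class:`TissueReconstruction`."""
    model = TissueReconstruction(data, annot, feature_genes, cfg)
    return model.fit(
        n_trials=n_trials,
        seed_start=seed_start,
        with_correlation=with_correlation,
        warn_singleton=False,
    )
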