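"""Stochastic batch-learning self-organizing map on a 2x2x2 cubic lattice.

The output layer is a cube of eight units, two per axis, standing in for the
four body-wall quadrants (anterior/posterior/left/right on the xy-plane) and
the proximal/distal halves (z-axis) of a mid-gastrula embryo.  Learning is
the batch SOM update

    c_j(t) = argmin_i || x_j - m_i(t) ||
    m_i(t+1) = sum_j h_{c_j(t) i}(t) x_j / sum_j h_{c_j(t) i}(t)

with a Gaussian lattice neighborhood whose squared distance is multiplied by
a fresh uniform draw in [0.5, 1) per (BMU, unit) pair per step:

    h_ci(t) = alpha(t) * exp( - u * ||r_c - r_i||^2 / (2 sigma(t)^2) ),
    u ~ U[0.5, 1).

The stochastic factor slows and roughens convergence -- the cooling role a
temperature schedule plays in simulated annealing -- which matters because
eight units give the map very few degrees of freedom and plain batch
learning freezes into local minima within a few steps.  Two hard
constraints reflect the embryo's geometry: units diagonal on the xy-plane
are never updated from each other (the embryo is hollow in the middle, so
diagonal quadrants are not tissue-connected), and the learning rate
alpha(t) cancels between numerator and denominator of the batch update, so
it only matters for the scalar neighborhood values, not for the fit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import StateError
from .expression import ExpressionMatrix, log_transform

__all__ = ["Lattice", "SOMConfig", "SOMResults", "StochasticSOM", "load_config"]


@dataclass(frozen=True)
class Lattice:
    """A cubic output lattice with ``side`` units per axis (contract: side=2).

    Unit ``i`` sits at integer coordinates ``(x, y, z)`` with x varying
    fastest.  ``xy_diagonal_pairs`` holds the (symmetric) unit pairs whose
    x and y offsets are both +-1 -- the pairs excluded from neighborhood
    updates.
    """

    side: int = 2

    @property
    def n_units(self) -> int:
        return self.side**3

    @property
    def unit_coords(self) -> np.ndarray:
        s = self.side
        coords = np.array(
            [(i % s, (i // s) % s, i // (s * s)) for i in range(s**3)], dtype=float
        )
        return coords

    @property
    def xy_diagonal_pairs(self) -> frozenset[tuple[int, int]]:
        coords = self.unit_coords
        pairs = set()
        for c in range(self.n_units):
            for i in range(self.n_units):
                dx = abs(coords[c, 0] - coords[i, 0])
                dy = abs(coords[c, 1] - coords[i, 1])
                if dx == 1 and dy == 1:
                    pairs.add((c, i))
        return frozenset(pairs)

    def squared_distances(self) -> np.ndarray:
        """n_units x n_units matrix of squared lattice distances."""
        coords = self.unit_coords
        diff = coords[:, None, :] - coords[None, :, :]
        return (diff**2).sum(axis=2)


@dataclass(frozen=True)
class SOMConfig:
    """Hyper-parameters of the stochastic batch SOM.

    sigma0, alpha0
        Initial neighborhood radius and learning rate (0.6 and 1.0 by
        default).  alpha(t) is held constant: it cancels in the batch
        update.
    n_steps
        Number of batch learning steps T (default 100).
    sigma_min
        Floor of the radius schedule.
    schedule
        'linear': sigma(t) = max(sigma0 * (1 - t/T), sigma_min);
        'exponential': sigma0 * (sigma_min/sigma0)**(t/T).
    stochastic
        If False the uniform factor is fixed at 1 (classic batch SOM).
    use_log
        Cluster on log10(FPKM + 1) values (default) rather than raw FPKM.
    """

    sigma0: float = 0.6
    alpha0: float = 1.0
    n_steps: int = 100
    sigma_min: float = 0.01
    seed: int = 0
    schedule: str = "linear"
    stochastic: bool = True
    use_log: bool = True

    def __post_init__(self) -> None:
        if self.sigma0 <= 0:
            raise ValueError("sigma0 must be > 0")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if not 0 < self.sigma_min <= self.sigma0:
            raise ValueError("require 0 < sigma_min <= sigma0")
        if self.schedule not in ("linear", "exponential"):
            raise ValueError(f"unknown schedule {self.schedule!r}")

    def sigma(self, t: int) -> float:
        frac = t / self.n_steps
        if self.schedule == "linear":
            return max(self.sigma0 * (1.0 - frac), self.sigma_min)
        return max(self.sigma0 * (self.sigma_min / self.sigma0) ** frac, self.sigma_min)

    def alpha(self, t: int) -> float:
        return self.alpha0

    def with_seed(self, seed: int) -> "SOMConfig":
        return replace(self, seed=seed)


def load_config(path: str | Path) -> SOMConfig:
    """Build a :class:`SOMConfig` from a YAML mapping of field names."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return SOMConfig(**raw)


# ---------------------------------------------------------------------------
# low-level operations (exposed for testing and composition)
# ---------------------------------------------------------------------------


def init_weights(
    X: np.ndarray, lattice: Lattice, rng: np.random.Generator
) -> np.ndarray:
    """Initial unit weights: per gene, uniform over that gene's data range.

    For a constant gene (min == max) every unit receives that constant.
    """
    if X.shape[1] == 0:
        raise ValueError("cannot initialize weights with zero feature genes")
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    return rng.uniform(lo, hi, size=(lattice.n_units, X.shape[1]))


def best_matching_unit(x: np.ndarray, weights: np.ndarray) -> int:
    """Index of the unit with minimal Euclidean distance; ties -> lowest index."""
    if np.isnan(x).any():
        raise ValueError("sample vector contains NaN")
    d2 = ((weights - x[None, :]) ** 2).sum(axis=1)
    return int(np.argmin(d2))


def _bmu_all(X: np.ndarray, weights: np.ndarray) -> np.ndarray:
    d2 = ((X[:, None, :] - weights[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)


def _draw_order(lattice: Lattice) -> list[tuple[int, int]]:
    """Fixed (BMU, unit) order in which stochastic draws are consumed.

    Pairs with zero lattice distance (i == c) and xy-diagonal pairs consume
    no draw: their neighborhood value is alpha(t) and 0 respectively.
    """
    diag = lattice.xy_diagonal_pairs
    return [
        (c, i)
        for c in range(lattice.n_units)
        for i in range(lattice.n_units)
        if c != i and (c, i) not in diag
    ]


def neighborhood_matrix(
    t: int, cfg: SOMConfig, lattice: Lattice, rng: np.random.Generator
) -> np.ndarray:
    """The full h_ci(t) table (BMU c by unit i) for one learning step.

    Stochastic draws are consumed in a fixed (c, i) order so the table --
    and hence the batch update -- does not depend on sample order.
    """
    n = lattice.n_units
    d2 = lattice.squared_distances()
    sigma = cfg.sigma(t)
    alpha = cfg.alpha(t)
    H = np.zeros((n, n))
    np.fill_diagonal(H, alpha)
    pairs = _draw_order(lattice)
    if cfg.stochastic:
        u = rng.uniform(0.5, 1.0, size=len(pairs))
    else:
        u = np.ones(len(pairs))
    for (c, i), ui in zip(pairs, u):
        H[c, i] = alpha * np.exp(-ui * d2[c, i] / (2.0 * sigma**2))
    return H


def neighborhood_weight(
    c: int, i: int, t: int, cfg: SOMConfig, lattice: Lattice, rng: np.random.Generator
) -> float:
    """Scalar h_ci(t); consumes one uniform draw iff (c, i) is a drawn pair."""
    if (c, i) in lattice.xy_diagonal_pairs:
        return 0.0
    if c == i:
        return cfg.alpha(t)
    u = rng.uniform(0.5, 1.0) if cfg.stochastic else 1.0
    d2 = lattice.squared_distances()[c, i]
    return cfg.alpha(t) * np.exp(-u * d2 / (2.0 * cfg.sigma(t) ** 2))


def batch_step(
    weights: np.ndarray,
    X: np.ndarray,
    t: int,
    cfg: SOMConfig,
    lattice: Lattice,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One batch learning step: recompute BMUs, then the h-weighted means.

    Returns (new_weights, bmu).  A unit receiving zero total neighborhood
    mass keeps its previous weight.
    """
    bmu = _bmu_all(X, weights)
    H = neighborhood_matrix(t, cfg, lattice, rng)
    Hs = H[bmu]  # n_samples x n_units
    den = Hs.sum(axis=0)
    num = Hs.T @ X
    new = weights.copy()
    active = den > 0
    new[active] = num[active] / den[active, None]
    return new, bmu


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------


class StochasticSOM:
    """Stochastic batch SOM model over an expression matrix.

    Parameters
    ----------
    data : ExpressionMatrix
        Genes x samples matrix.  If ``config.use_log`` and the matrix is
        raw, values are log10(FPKM + 1)-transformed internally.
    feature_genes : list of str, optional
        Restrict clustering to these genes (order preserved); all must be
        present.  Default: every gene in ``data``.
    config : SOMConfig, optional
    lattice : Lattice, optional

    Examples
    --------
    >>> model = StochasticSOM(data, feature_genes=["Id2", "Nrp2"])
    >>> res = model.fit(seed=0)
    >>> res.sample_coords  # (n_samples, 3) lattice positions
    """

    def __init__(
        self,
        data: ExpressionMatrix,
        feature_genes: list[str] | None = None,
        config: SOMConfig | None = None,
        lattice: Lattice | None = None,
    ):
        self.config = config or SOMConfig()
        self.lattice = lattice or Lattice()
        if feature_genes is not None:
            data = data.subset_genes(list(feature_genes))
        if self.config.use_log and not data.transformed:
            data = log_transform(data)
        self.data = data
        self.feature_genes = list(data.gene_ids)
        if not self.feature_genes:
            raise ValueError("no feature genes to cluster on")
        # samples x genes design matrix
        self.exog = data.values.T.copy()

    def fit(self, seed: int | None = None) -> "SOMResults":
        """Run T batch steps from seeded uniform initial weights."""
        cfg = self.config if seed is None else self.config.with_seed(seed)
        rng = np.random.default_rng(cfg.seed)
        X = self.exog
        weights = init_weights(X, self.lattice, rng)
        prev_bmu = _bmu_all(X, weights)
        bmu_changes = []
        for t in range(cfg.n_steps):
            weights, bmu = batch_step(weights, X, t, cfg, self.lattice, rng)
            bmu_changes.append(int((bmu != prev_bmu).sum()))
            prev_bmu = bmu
        final_bmu = _bmu_all(X, weights)
        return SOMResults(
            model=self,
            config=cfg,
            weights=weights,
            bmu=final_bmu,
            bmu_changes=np.asarray(bmu_changes),
        )


@dataclass
class SOMResults:
    """Fitted SOM: unit weights, per-sample best matching units, diagnostics."""

    model: StochasticSOM
    config: SOMConfig
    weights: np.ndarray
    bmu: np.ndarray
    bmu_changes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def lattice(self) -> Lattice:
        return self.model.lattice

    @property
    def sample_ids(self) -> list[str]:
        return self.model.data.sample_ids

    @property
    def sample_coords(self) -> np.ndarray:
        """(n_samples, 3) lattice coordinates of each sample's BMU."""
        return self.lattice.unit_coords[self.bmu]

    def similarity(self) -> np.ndarray:
        """Euclidean norm between each sample vector and its BMU weight."""
        diff = self.model.exog - self.weights[self.bmu]
        return np.linalg.norm(diff, axis=1)

    def summary(self) -> str:
        lines = [
            "Stochastic SOM fit",
            "==================",
            f"samples:        {len(self.bmu)}",
            f"feature genes:  {len(self.model.feature_genes)}",
            f"lattice:        {self.lattice.side}x{self.lattice.side}x{self.lattice.side}",
            f"steps:          {self.config.n_steps}",
            f"sigma0/min:     {self.config.sigma0}/{self.config.sigma_min}",
            f"stochastic:     {self.config.stochastic}",
            f"seed:           {self.config.seed}",
            f"occupied units: {len(np.unique(self.bmu))}/{self.lattice.n_units}",
        ]
        if self.bmu_changes.size:
            lines.append(f"BMU changes (last 5 steps): {self.bmu_changes[-5:].tolist()}")
        return "\n".join(lines)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "unit_coords": self.lattice.unit_coords.tolist(),
            "weights": self.weights.tolist(),
            "sample_ids": self.sample_ids,
            "bmu": self.bmu.tolist(),
            "config": {
                "sigma0": self.config.sigma0,
                "alpha0": self.config.alpha0,
                "n_steps": self.config.n_steps,
                "sigma_min": self.config.sigma_min,
                "seed": self.config.seed,
                "schedule": self.config.schedule,
                "stochastic": self.config.stochastic,
                "use_log": self.config.use_log,
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
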