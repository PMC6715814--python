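"""Synthetic mid-gastrula-like expression data with known spatial ground truth.

The generator emulates the cryosection design of the real study: eleven
sections along the proximal-distal axis, each cut into anterior (A),
posterior (P), left (L) and right (R) quadrants; the most distal section
has no left/right samples and one designated low-expression sample is
dropped, leaving 41 samples split 9/11/10/11 over the four domains
(D1 anterior, D2 lateral-distal, D3 lateral-proximal, D4 posterior).

Expression is built on the log10(FPKM + 1) scale as

    log-expression = baseline + discriminator contribution + N(0, noise_sd)

and exponentiated back to an FPKM-like scale.  Discriminator genes carry
the positional signal: a 'domain' gene is a graded indicator of one target
domain -- full amplitude inside the target, decaying with the spatial
distance between domain territories (the lateral pair D2/D3 is mutually
close, the anterior/posterior poles D1/D4 are maximally apart), which is
what makes the embryo's topology recoverable; an 'AP' gene is signed by
region (+amplitude/2 anterior, -amplitude/2 posterior); a 'PD' gene
increases with section index (linear by default, sigmoidal optionally).
Noise genes are pure baseline noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DesignError
from .expression import ExpressionMatrix

__all__ = [
    "Discriminator",
    "SyntheticDesign",
    "generate_embryo",
    "add_noise",
    "DOMAIN_POSITIONS",
    "domain_proximity",
]

# ground-truth territory centers on the unit cube: D1/D4 at opposite
# xy-diagonal columns, D2/D3 stacked along z in a shared lateral column
DOMAIN_POSITIONS: dict[str, tuple[float, float, float]] = {
    "D1": (0.0, 0.0, 0.5),
    "D2": (0.0, 1.0, 0.0),
    "D3": (0.0, 1.0, 1.0),
    "D4": (1.0, 1.0, 0.5),
}


def domain_proximity(a: str, b: str) -> float:
    """Spatial proximity of two domain territories, scaled to [0, 1].

    1 for the same domain, 0 for the most distant pair (D1 vs D4).
    """
    pa = np.asarray(DOMAIN_POSITIONS[a])
    pb = np.asarray(DOMAIN_POSITIONS[b])
    d = float(np.linalg.norm(pa - pb))
    d_max = float(
        np.linalg.norm(
            np.asarray(DOMAIN_POSITIONS["D1"]) - np.asarray(DOMAIN_POSITIONS["D4"])
        )
    )
    return 1.0 - d / d_max


@dataclass(frozen=True)
class Discriminator:
    """A planted spatial discriminator gene.

    kind: 'domain' (graded indicator of ``target`` domain), 'AP'
    (anterior-posterior gradient) or 'PD' (proximal-distal gradient along
    sections).
    amplitude: peak contribution on the log10 scale; must be > 0.
    """

    gene_id: str
    kind: str = "domain"
    target: str | None = None
    amplitude: float = 2.0

    def __post_init__(self) -> None:
        if self.kind not in ("domain", "AP", "PD"):
            raise DesignError(f"unknown discriminator kind {self.kind!r}")
        if self.kind == "domain" and self.target is None:
            raise DesignError(f"domain discriminator {self.gene_id!r} needs a target")
        if self.amplitude < 0:
            raise DesignError("discriminator amplitude must be >= 0")


def default_discriminators(amplitude: float = 2.0) -> tuple[Discriminator, ...]:
    """One indicator gene per domain (the default study condition)."""
    return tuple(
        Discriminator(f"disc_{d}", kind="domain", target=d, amplitude=amplitude)
        for d in ("D1", "D2", "D3", "D4")
    )


@dataclass(frozen=True)
class SyntheticDesign:
    """Design of the synthetic embryo.

    Defaults reproduce the 41-sample, four-domain layout with four
    domain-indicator genes at amplitude 2.0 over noise_sd 0.4 (a 5:1
    signal-to-noise ratio on the log scale) plus 46 uninformative genes.
    """

    n_sections: int = 11
    discriminators: tuple[Discriminator, ...] = field(
        default_factory=default_discriminators
    )
    n_noise_genes: int = 46
    baseline: float = 1.0
    noise_sd: float = 0.4
    gradient_shape: str = "linear"  # for AP/PD kinds: 'linear' or 'sigmoid'
    drop_sample: str = "R6"  # the designated low-expression sample
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sections < 2:
            raise DesignError("need at least two sections")
        if self.noise_sd < 0:
            raise DesignError("noise_sd must be >= 0")
        if self.gradient_shape not in ("linear", "sigmoid"):
            raise DesignError(f"unknown gradient shape {self.gradient_shape!r}")
        ids = [d.gene_id for d in self.discriminators]
        if len(set(ids)) != len(ids):
            raise DesignError("duplicate discriminator gene ids")

    def layout(self) -> pd.DataFrame:
        """Sample annotation table implied by the design.

        Sections run 1 (most distal) to ``n_sections`` (most proximal); the
        most distal section has anterior/posterior samples only.  Domains
        for the default 11-section design: D1 = anterior sections 3-11,
        D4 = posterior throughout, D2 = distal tips plus distal laterals,
        D3 = proximal laterals minus the dropped sample.
        """
        n = self.n_sections
        rows = []
        for section in range(1, n + 1):
            regions = ("A", "P") if section == 1 else ("A", "P", "L", "R")
            for region in regions:
                rows.append((f"{region}{section}", section, region))
        annot = pd.DataFrame(rows, columns=["sample_id", "section", "region"])
        annot = annot[annot["sample_id"] != self.drop_sample].reset_index(drop=True)

        # boundaries scale with the section count; defaults give 9/11/10/11
        a_cut = max(1, n - 9)  # anterior samples above this section are D1
        lat_cut = (n + 1) // 2  # lateral D2/D3 boundary

        def assign(section: int, region: str) -> str:
            if region == "P":
                return "D4"
            if region == "A":
                return "D1" if section > a_cut else "D2"
            if region == "L":
                return "D2" if section <= lat_cut else "D3"
            return "D2" if section <= lat_cut - 1 else "D3"

        annot["domain"] = [
            assign(s, r) for s, r in zip(annot["section"], annot["region"])
        ]
        return annot.set_index("sample_id")

    def with_amplitude(self, amplitude: float) -> "SyntheticDesign":
        """Copy of the design with every discriminator rescaled.

        ``amplitude=0`` removes the spatial signal entirely (the
        discriminator genes keep their ids but become plain noise genes),
        which is the null condition for calibrating the topology score.
        """
        return replace(
            self,
            discriminators=tuple(
                replace(d, amplitude=amplitude) for d in self.discriminators
            ),
        )


def _gradient(x: np.ndarray, shape: str) -> np.ndarray:
    """Map a normalized coordinate in [0, 1] to a gradient value in [0, 1]."""
    if shape == "linear":
        return x
    return 1.0 / (1.0 + np.exp(-10.0 * (x - 0.5)))


def generate_embryo(design: SyntheticDesign) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Generate (expression matrix on the raw FPKM-like scale, annotation)."""
    annot = design.layout()
    counts = annot["domain"].value_counts()
    if (counts < 1).any() or len(counts) != 4:
        raise DesignError("every domain needs at least one sample")
    sample_ids = list(annot.index)
    n_samples = len(sample_ids)
    sections = annot["section"].to_numpy()
    regions = annot["region"].to_numpy()
    domains = annot["domain"].to_numpy()

    rng = np.random.default_rng(design.seed)
    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    for disc in design.discriminators:
        if disc.kind == "domain":
            prox = np.array([domain_proximity(d, disc.target) for d in domains])
            signal = disc.amplitude * prox
        elif disc.kind == "AP":
            signed = np.where(regions == "A", 0.5, np.where(regions == "P", -0.5, 0.0))
            signal = disc.amplitude * signed
        else:  # PD
            frac = (sections - 1) / (design.n_sections - 1)
            signal = disc.amplitude * _gradient(frac, design.gradient_shape)
        gene_ids.append(disc.gene_id)
        rows.append(design.baseline + signal)
    for i in range(design.n_noise_genes):
        gene_ids.append(f"noise_{i:03d}")
        rows.append(np.full(n_samples, design.baseline))

    log_expr = np.vstack(rows) if rows else np.empty((0, n_samples))
    log_expr = log_expr + rng.normal(0.0, design.noise_sd, size=log_expr.shape)
    fpkm = np.clip(10.0**log_expr - 1.0, 0.0, None)
    frame = pd.DataFrame(fpkm, index=gene_ids, columns=sample_ids)
    return ExpressionMatrix(frame, transformed=False), annot


def add_noise(m: ExpressionMatrix, level: float, seed: int = 0) -> ExpressionMatrix:
    """Add N(0, (level * global SD)^2) noise to a log-transformed matrix.

    The anchor SD is that of the whole matrix (all cells pooled).  Level 0
    returns a bit-identical copy.
    """
    if not m.transformed:
        raise ValueError("add_noise expects a log-transformed matrix")
    if level < 0:
        raise ValueError("noise level must be >= 0")
    if level == 0:
        return ExpressionMatrix(m.frame.copy(), transformed=True)
    rng = np.random.default_rng(seed)
    sd = float(m.values.std())
    noisy = m.frame + rng.normal(0.0, level * sd, size=m.frame.shape)
    return ExpressionMatrix(noisy, transformed=True)
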