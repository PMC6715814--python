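"""Similarity-based paraboloid projection and report export.

The eight lattice units are anchored on a cup-shaped paraboloid echoing the
embryo's shape: unit r = (u, v, w) sits at

    ( u - 1/2,  v - 1/2,  curvature * ((u-1/2)^2 + (v-1/2)^2) + w/2 )

and each sample is displaced from its BMU anchor radially (away from the
paraboloid axis in the xy-plane) by ``spread`` times its normalized
similarity, where similarity is the Euclidean norm between the sample
vector and the BMU weight.  The geometry is presentation-only: no statistic
depends on it.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import StateError
from .evaluation import ReconstructionReport
from .som import SOMResults

__all__ = ["paraboloid_projection", "unit_anchors", "export_report"]

_COLUMNS = ["sample_id", "x", "y", "z", "domain", "bmu", "similarity"]


def unit_anchors(results: SOMResults, curvature: float = 1.0) -> np.ndarray:
    """Paraboloid anchor positions of the lattice units (n_units x 3)."""
    uvw = results.lattice.unit_coords - np.array([0.5, 0.5, 0.0])
    z = curvature * (uvw[:, 0] ** 2 + uvw[:, 1] ** 2) + 0.5 * uvw[:, 2]
    return np.column_stack([uvw[:, 0], uvw[:, 1], z])


def paraboloid_projection(
    results: SOMResults,
    annot: pd.DataFrame | None = None,
    curvature: float = 1.0,
    spread: float = 0.25,
) -> pd.DataFrame:
    """Project each sample near its unit anchor; similarity sets the offset.

    Returns a DataFrame with columns sample_id, x, y, z, domain, bmu,
    similarity.  A sample identical to its BMU weight sits exactly at the
    anchor; the most dissimilar sample sits ``spread`` away from it.
    """
    if results.weights is None or results.bmu is None:
        raise StateError("model is not fitted")
    anchors = unit_anchors(results, curvature)
    sims = results.similarity()
    max_sim = sims.max()
    scale = sims / max_sim if max_sim > 0 else np.zeros_like(sims)
    coords = results.lattice.unit_coords
    rows = []
    for j, sid in enumerate(results.sample_ids):
        b = int(results.bmu[j])
        anchor = anchors[b]
        radial = np.array([coords[b, 0] - 0.5, coords[b, 1] - 0.5, 0.0])
        norm = np.linalg.norm(radial)
        direction = radial / norm if norm > 0 else np.zeros(3)
        pos = anchor + spread * scale[j] * direction
        domain = (
            str(annot.loc[sid, "domain"]) if annot is not None and sid in annot.index else ""
        )
        rows.append((sid, *pos, domain, b, float(sims[j])))
    return pd.DataFrame(rows, columns=_COLUMNS)


def _atomic_write(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name)
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def export_report(
    report: ReconstructionReport,
    projections: pd.DataFrame | None,
    out_dir: str | Path,
    image: bool = False,
) -> dict[str, Path]:
    """Write coordinates, correlation matrix, trial table and JSON summary.

    Re-running overwrites atomically.  With ``image=True`` a static 3D
    scatter (matplotlib) is also written.  Returns the paths written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    coords_path = out_dir / "coordinates.tsv"
    proj = (
        projections
        if projections is not None
        else pd.DataFrame(columns=_COLUMNS)
    )
    _atomic_write(coords_path, proj.to_csv(sep="\t", index=False))
    written["coordinates"] = coords_path

    if report.domain_correlation is not None:
        corr_path = out_dir / "domain_correlation.tsv"
        _atomic_write(
            corr_path,
            report.domain_correlation.to_csv(sep="\t", index=True, index_label="domain"),
        )
        written["correlation"] = corr_path

    trials_path = out_dir / "trials.tsv"
    _atomic_write(trials_path, report.trial_table().to_csv(sep="\t", index=False))
    written["trials"] = trials_path

    summary_path = out_dir / "summary.json"
    _atomic_write(
        summary_path,
        json.dumps(
            {
                "n_feature_genes": len(report.feature_genes),
                "feature_genes": report.feature_genes,
                "n_trials": report.n_trials,
                "success_rate": report.success_rate,
                "total_variance": report.total_variance,
            },
            indent=1,
        ),
    )
    written["summary"] = summary_path

    if image and len(proj):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig = plt.figure(figsize=(5, 5))
        ax = fig.add_subplot(projection="3d")
        for domain, grp in proj.groupby("domain"):
            ax.scatter(grp["x"], grp["y"], grp["z"], label=str(domain), s=25)
        ax.legend()
        img_path = out_dir / "reconstruction.png"
        fig.savefig(img_path, dpi=120)
        plt.close(fig)
        written["image"] = img_path
    return written
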