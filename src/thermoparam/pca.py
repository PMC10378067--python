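"""Principal-component features of thermogram curves.

The full 451-point thermogram is compressed into a handful of orthogonal
modes by PCA of the sample × temperature matrix: column-mean centering, no
scaling (all readings share the cal/°C·g unit).  Scores for PC1–PC4 join
the 19 summary metrics as statistical parameters; k defaults to 5 for the
scree report.

Sign convention: each loading is flipped so that its largest-magnitude
element is positive, making score signs reproducible across runs and
platforms (the eigenvector sign is otherwise arbitrary).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import TemperatureMesh, ThermogramCurve

__all__ = ["PCADecomposition", "fit_pca", "project"]


@dataclass
class PCADecomposition:
    """Fitted thermogram PCA basis."""

    mesh: TemperatureMesh
    mean_curve: np.ndarray              # per-temperature mean, length 451
    loadings: np.ndarray                # (n_temperatures, k) orthonormal columns
    explained_fraction: np.ndarray      # k fractions of total variance
    explained_fraction_full: np.ndarray # all min(n-1, p) fractions (sums to 1)
    scores: pd.DataFrame                # samples × k, columns PC1..PCk

    @property
    def k(self) -> int:
        return self.loadings.shape[1]

    def save(self, directory: str | Path, stem: str = "pca") -> None:
        """Persist as a CSV pair (loadings, scores) plus a JSON sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        cols = [f"PC{i+1}" for i in range(self.k)]
        pd.DataFrame(
            np.column_stack([self.mesh.values, self.mean_curve, self.loadings]),
            columns=["Temperature", "mean_cp"] + cols,
        ).to_csv(directory / f"{stem}_loadings.csv", index=False)
        self.scores.to_csv(directory / f"{stem}_scores.csv")
        sidecar = {
            "explained_fraction": self.explained_fraction.tolist(),
            "explained_fraction_full": self.explained_fraction_full.tolist(),
            "mesh": {"start": self.mesh.start, "stop": self.mesh.stop, "step": self.mesh.step},
            "sign_convention": "largest-magnitude loading element positive",
            "centering": "column mean", "scaling": "none",
        }
        (directory / f"{stem}_meta.json").write_text(json.dumps(sidecar, indent=2))


def _stack(curves: Sequence[ThermogramCurve]) -> tuple[TemperatureMesh, np.ndarray, list[str]]:
    mesh = curves[0].mesh
    for c in curves[1:]:
        if not c.mesh.matches(mesh):
            raise ValueError(f"sample {c.sample_id!r} is on a different mesh")
    X = np.vstack([c.cp for c in curves])
    return mesh, X, [c.sample_id for c in curves]


def fit_pca(curves: Sequence[ThermogramCurve], k: int = 5) -> PCADecomposition:
    """Mean-centered, unscaled PCA of n thermograms (n >= 2) via SVD.

    Scores are the centered data projected on the loadings; explained
    fractions are eigenvalue shares of the total variance.
    """
    if len(curves) < 2:
        raise ValueError("PCA needs at least two curves")
    mesh, X, ids = _stack(curves)
    mean_curve = X.mean(axis=0)
    Xc = X - mean_curve
    # economy SVD: Xc = U S Vt, eigenvalues of covariance = S^2/(n-1)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = S**2
    total = eig.sum()
    if total <= 0:
        raise ValueError("zero total variance: all curves identical")
    frac_full = eig / total
    k = min(k, Vt.shape[0])
    loadings = Vt[:k].T.copy()
    # deterministic sign: largest-|.| element of each loading positive
    for j in range(k):
        col = loadings[:, j]
        if col[int(np.argmax(np.abs(col)))] < 0:
            loadings[:, j] = -col
    scores = Xc @ loadings
    return PCADecomposition(
        mesh=mesh,
        mean_curve=mean_curve,
        loadings=loadings,
        explained_fraction=frac_full[:k],
        explained_fraction_full=frac_full,
        scores=pd.DataFrame(
            scores, index=pd.Index(ids, name="sample_id"),
            columns=[f"PC{i+1}" for i in range(k)],
        ),
    )


def project(
    curves: Sequence[ThermogramCurve], decomposition: PCADecomposition
) -> pd.DataFrame:
    """Project curves onto a fitted basis: (cp − mean_curve) · loadings."""
    mesh, X, ids = _stack(curves)
    if not mesh.matches(decomposition.mesh):
        raise ValueError("curves are not on the decomposition's mesh")
    scores = (X - decomposition.mean_curve) @ decomposition.loadings
    return pd.DataFrame(
        scores, index=pd.Index(ids, name="sample_id"),
        columns=[f"PC{i+1}" for i in range(decomposition.k)],
    )
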