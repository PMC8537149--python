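"""Grid-ESP descriptor vectors and their PCA reduction.

Each aligned molecule is represented by the electrostatic potential sampled
at every node of the common descriptor grid (0.212 Å spacing by default),
flattened with x varying fastest into a K-vector.  PCA, fitted on the
training fold only, projects these K-vectors to the low-dimensional
descriptors fed to the regression model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .chem_io import Molecule
from .espgrid import ChargeModel, GridBox, density_field, solve_poisson


@dataclass(frozen=True)
class PcaModel:
    """Centered PCA: mean (K,), orthonormal components (p, K) sorted by
    decreasing variance, and explained-variance ratios (p,).

    Sign convention: each component's largest-magnitude loading is positive,
    making projections reproducible across runs and libraries.
    """

    mean: np.ndarray
    components: np.ndarray
    explained_variance_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def to_json(self) -> str:
        return json.dumps({
            "mean": self.mean.tolist(),
            "components": self.components.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
        })

    @classmethod
    def from_json(cls, text: str) -> "PcaModel":
        d = json.loads(text)
        return cls(
            np.array(d["mean"]),
            np.array(d["components"]),
            np.array(d["explained_variance_ratio"]),
        )


@dataclass
class DescriptorMatrix:
    ids: list[str]
    raw: np.ndarray        # n_mol × K ESP values
    projected: np.ndarray  # n_mol × p
    pca: PcaModel


def esp_vector(
    mol_aligned: Molecule,
    box: GridBox,
    model: ChargeModel,
    poisson_mode: str = "freespace",
) -> np.ndarray:
    """ESP at every descriptor grid point, flattened x-fastest (units e/Å)."""
    rho = density_field(mol_aligned, box, model)
    phi = solve_poisson(rho, mode=poisson_mode)
    return phi.flatten()


def fit_pca(
    raw: np.ndarray,
    n_components: int | None = None,
    variance_target: float = 0.95,
) -> PcaModel:
    """Centered PCA of the raw descriptor matrix.

    If ``n_components`` is not given, the smallest p explaining at least
    ``variance_target`` of the training variance is retained, capped at
    n_train − 1.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[0] < 2:
        raise ValueError("need an n×K matrix with n >= 2")
    cap = min(raw.shape[0] - 1, raw.shape[1])
    if n_components is not None:
        if not 1 <= n_components <= cap:
            raise ValueError(
                f"n_components must be in [1, {cap}] for this matrix")
        p = n_components
    else:
        probe = PCA(n_components=cap, svd_solver="full").fit(raw)
        cum = np.cumsum(probe.explained_variance_ratio_)
        p = int(np.searchsorted(cum, variance_target) + 1)
        p = min(p, cap)
    fitted = PCA(n_components=p, svd_solver="full").fit(raw)
    components = fitted.components_.copy()
    for row in components:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    return PcaModel(
        mean=fitted.mean_.copy(),
        components=components,
        explained_variance_ratio=fitted.explained_variance_ratio_.copy(),
    )


def project(pca: PcaModel, raw_rows: np.ndarray) -> np.ndarray:
    """Out-of-sample projection using the training mean and components only."""
    rows = np.atleast_2d(np.asarray(raw_rows, dtype=float))
    if rows.shape[1] != pca.mean.shape[0]:
        raise ValueError(
            f"row length {rows.shape[1]} != descriptor length {pca.mean.shape[0]}")
    return (rows - pca.mean) @ pca.components.T


def reconstruct(pca: PcaModel, projected_rows: np.ndarray) -> np.ndarray:
    rows = np.atleast_2d(np.asarray(projected_rows, dtype=float))
    return rows @ pca.components + pca.mean


def descriptor_matrix(
    mols_aligned: list[Molecule],
    box: GridBox,
    model: ChargeModel,
    n_components: int | None = None,
    variance_target: float = 0.95,
    poisson_mode: str = "freespace",
) -> DescriptorMatrix:
    """Raw ESP vectors for a set of aligned molecules plus their fitted PCA."""
    raw = np.array([
        esp_vector(m, box, model, poisson_mode=poisson_mode)
        for m in mols_aligned
    ])
    pca = fit_pca(raw, n_components=n_components, variance_target=variance_target)
    return DescriptorMatrix(
        [m.id for m in mols_aligned], raw, project(pca, raw), pca
    )
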