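"""Template (representative molecule) selection by betweenness centrality.

Molecules of a subset are vertices of a complete weighted graph whose edge
weights are alignment-based distances

    d_ij = ½(E_ii + E_jj) − E_ij ≥ 0,

half the Coulomb self-energy of the difference density at the optimal
alignment (zero exactly when the aligned fields coincide).  The betweenness
centrality of vertex i is the fraction of all-pairs weighted shortest paths
on which i lies as an interior vertex; the most central molecule becomes the
structural template of the subset.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import dijkstra

from .align3d import RotamerSet, align_pair, self_correlation
from .chem_io import Molecule
from .espgrid import ChargeModel, GridBox, density_field, solve_poisson


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray  # e²/Å, symmetric, zero diagonal

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0.0):
            raise ValueError("distance matrix diagonal must be zero")

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id"] + self.ids)
            for mol_id, row in zip(self.ids, self.d):
                writer.writerow([mol_id] + [f"{v:.10g}" for v in row])


@dataclass
class CentralityResult:
    c: dict[str, float]
    n_paths: int
    template_id: str
    method: str

    def to_json(self) -> str:
        return json.dumps(
            {"centrality": self.c, "n_paths": self.n_paths,
             "template_id": self.template_id, "method": self.method}
        )


def distance_matrix(
    mols: list[Molecule],
    box: GridBox,
    rotamers: RotamerSet,
    model: ChargeModel,
    poisson_mode: str = "freespace",
) -> DistanceMatrix:
    """Alignment-based pairwise distances for one subset.

    E_ij is computed in both orderings (i as template, j as target, and the
    reverse) and the two resulting distances averaged; discretization makes
    E_ij and E_ji agree only approximately.  Tiny negative values from grid
    error (within 1e-9 of the self-correlation scale) are clamped to zero.
    """
    if len(mols) < 2:
        raise ValueError("need at least two molecules")
    centered = [m.translated(box.center - m.centroid()) for m in mols]
    fields = []
    for m in centered:
        rho = density_field(m, box, model)
        phi = solve_poisson(rho, mode=poisson_mode)
        fields.append((rho, phi))
    e_self = np.array([
        float(np.sum(phi.values * rho.values) * box.voxel_volume)
        for rho, phi in fields
    ])
    n = len(mols)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            try:
                res = align_pair(
                    centered[i], centered[j], box, rotamers, model,
                    template_phi=fields[i][1], poisson_mode=poisson_mode,
                )
            except ValueError as exc:
                raise ValueError(
                    f"alignment failed for pair "
                    f"({mols[i].id!r}, {mols[j].id!r}): {exc}"
                ) from exc
            d[i, j] = 0.5 * (e_self[i] + e_self[j]) - res.e_ij
    d = 0.5 * (d + d.T)
    tol = 1e-9 * float(np.max(e_self))
    d[(d < 0) & (d > -tol)] = 0.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix([m.id for m in mols], d)


def _interior_counts(dm: DistanceMatrix, pairs) -> np.ndarray:
    """For each vertex, the number of the given (A, B) pairs whose weighted
    shortest path contains it as an interior vertex.

    One deterministic shortest path per pair (Dijkstra predecessor chain).
    """
    n = len(dm.ids)
    # Mask the diagonal only: off-diagonal zeros are genuine zero-weight
    # edges (duplicate molecules), which scipy's dense-path convention would
    # otherwise drop.
    graph = np.ma.masked_array(dm.d, mask=np.eye(n, dtype=bool))
    _, predecessors = dijkstra(graph, return_predecessors=True)
    counts = np.zeros(n)
    for a, b in pairs:
        v = int(predecessors[a, b])
        while v != a and v >= 0:
            counts[v] += 1
            v = int(predecessors[a, v])
    return counts


def _argmax_id(ids, values) -> str:
    top = max(values)
    return min(ids[i] for i in range(len(ids)) if values[i] == top)


def betweenness_exact(dm: DistanceMatrix) -> CentralityResult:
    """Exact betweenness: C_i = (number of all-pairs shortest paths with i
    interior) / (number of unordered vertex pairs)."""
    if np.any(dm.d < 0):
        raise ValueError("distances must be non-negative")
    n = len(dm.ids)
    pairs = [(a, b) for a in range(n) for b in range(a + 1, n)]
    counts = _interior_counts(dm, pairs)
    n_paths = len(pairs)
    c = counts / n_paths if n_paths else counts
    cmap = dict(zip(dm.ids, c.tolist()))
    return CentralityResult(cmap, n_paths, _argmax_id(dm.ids, c), "exact")


def betweenness_mc(
    dm: DistanceMatrix, n_walks: int, seed: int
) -> CentralityResult:
    """Monte Carlo betweenness estimate: sample vertex pairs uniformly at
    random (with restart) and average the interior-vertex indicator.

    When ``n_walks`` covers all pairs the estimator switches to exhaustive
    enumeration and equals :func:`betweenness_exact`.
    """
    if n_walks < 1:
        raise ValueError("n_walks must be at least 1")
    if np.any(dm.d < 0):
        raise ValueError("distances must be non-negative")
    n = len(dm.ids)
    all_pairs = [(a, b) for a in range(n) for b in range(a + 1, n)]
    if n_walks >= len(all_pairs):
        pairs = all_pairs
        denom = len(all_pairs)
    else:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, len(all_pairs), size=n_walks)
        pairs = [all_pairs[i] for i in idx]
        denom = n_walks
    counts = _interior_counts(dm, pairs)
    c = counts / denom
    cmap = dict(zip(dm.ids, c.tolist()))
    return CentralityResult(
        cmap, denom, _argmax_id(dm.ids, c), f"mc(seed={seed}, walks={n_walks})"
    )


def select_template(cr: CentralityResult) -> str:
    """Most central molecule; ties go to the lexicographically smallest id."""
    if not cr.c:
        raise ValueError("empty centrality result")
    top = max(cr.c.values())
    return min(k for k, v in cr.c.items() if v == top)
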