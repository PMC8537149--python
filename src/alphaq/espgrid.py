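"""Grid boxes, Gaussian charge-density fields and Poisson ESP solvers.

The molecular charge distribution is modelled as a sum of isotropic
normalized Gaussians centred on the atoms.  Two weightings are provided:

* ``promolecule`` — weights are electron counts, giving an everywhere
  positive density that mimics an electron density (used for alignment);
* ``partial_charge`` — weights are signed partial charges (used for the
  ESP descriptor).

The electrostatic potential solves the Poisson equation in Gaussian-style
units (charge in e, length in Å):  ∇²φ = −4πρ, so a unit point charge gives
φ = 1/r.  The default free-space solver convolves ρ with the 1/r Green
function on a doubled (zero-padded) grid via FFT; a periodic spectral solve
is retained for speed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft
from scipy.special import erf

from .chem_io import Molecule
from .constants import BOHR_TO_ANGSTROM


@dataclass(frozen=True)
class GridBox:
    """Axis-aligned node-centred voxel lattice: point (i, j, k) sits at
    ``origin + spacing * (i, j, k)``, indices 0-based."""

    origin: tuple[float, float, float]
    spacing: float
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if any(d < 1 for d in self.dims):
            raise ValueError("dims must be positive")
        object.__setattr__(self, "origin", tuple(float(x) for x in self.origin))
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    @property
    def voxel_volume(self) -> float:
        return self.spacing**3

    @property
    def upper(self) -> np.ndarray:
        return np.asarray(self.origin) + self.spacing * (np.array(self.dims) - 1)

    @property
    def center(self) -> np.ndarray:
        return 0.5 * (np.asarray(self.origin) + self.upper)

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        o = self.origin
        return tuple(
            o[a] + self.spacing * np.arange(self.dims[a]) for a in range(3)
        )

    def contains_points(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(points)
        lo = np.asarray(self.origin)
        return np.all((points >= lo - 1e-9) & (points <= self.upper + 1e-9),
                      axis=1)


@dataclass
class ScalarField:
    """A scalar quantity sampled on a GridBox.

    ``kind`` is one of ``density`` (e/Å³), ``esp`` (e/Å) or ``score``
    (e²/Å, cross-correlation maps indexed by grid shift).
    """

    box: GridBox
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.box.dims:
            raise ValueError(
                f"values shape {self.values.shape} != box dims {self.box.dims}"
            )
        if self.kind not in {"density", "esp", "score"}:
            raise ValueError(f"unknown field kind {self.kind!r}")

    def flatten(self) -> np.ndarray:
        """Flatten with x varying fastest."""
        return self.values.ravel(order="F")


@dataclass(frozen=True)
class ChargeModel:
    """Gaussian atom-centred charge model.

    ``sigma`` is the Gaussian width in Å, either one global value or a
    per-element mapping (missing elements fall back to ``default_sigma``).
    """

    mode: str = "promolecule"
    sigma: float | dict = 0.4
    default_sigma: float = 0.4

    def __post_init__(self) -> None:
        if self.mode not in {"promolecule", "partial_charge"}:
            raise ValueError(f"unknown charge model mode {self.mode!r}")
        sigmas = (
            self.sigma.values() if isinstance(self.sigma, dict) else [self.sigma]
        )
        if any(s <= 0 for s in sigmas) or self.default_sigma <= 0:
            raise ValueError("sigma must be positive")

    def sigma_for(self, element: str) -> float:
        if isinstance(self.sigma, dict):
            return float(self.sigma.get(element, self.default_sigma))
        return float(self.sigma)

    def weights(self, mol: Molecule) -> np.ndarray:
        if self.mode == "promolecule":
            return np.array([float(a.electron_count) for a in mol.atoms])
        return np.array([a.partial_charge for a in mol.atoms])


def build_common_box(
    mols: list[Molecule], spacing: float, margin: float = 2.7
) -> GridBox:
    """Smallest grid box covering the union of van der Waals extents of all
    molecules, plus ``margin`` added to each dimension.

    dims = ceil(extent / spacing) + 1 per axis; the grid is centred on the
    union bounding box.
    """
    if not mols:
        raise ValueError("need at least one molecule to build a box")
    lows = np.min(
        [np.min(m.positions - m.vdw_radii[:, None], axis=0) for m in mols],
        axis=0,
    )
    highs = np.max(
        [np.max(m.positions + m.vdw_radii[:, None], axis=0) for m in mols],
        axis=0,
    )
    extent = highs - lows + margin
    dims = tuple(int(np.ceil(e / spacing - 1e-9)) + 1 for e in extent)
    length = spacing * (np.array(dims) - 1)
    origin = 0.5 * (lows + highs) - 0.5 * length
    return GridBox(tuple(origin), spacing, dims)


def density_field(mol: Molecule, box: GridBox, model: ChargeModel) -> ScalarField:
    """Charge density ρ(r) = Σ_a w_a G(r − r_a; σ_a) on the grid, with G a
    normalized isotropic Gaussian; the voxel sum times voxel volume
    approximates Σ w_a."""
    inside = box.contains_points(mol.positions)
    if not np.all(inside):
        bad = list(np.nonzero(~inside)[0])
        raise ValueError(f"atoms {bad} of molecule {mol.id!r} outside box")
    weights = model.weights(mol)
    values = np.zeros(box.dims)
    xs, ys, zs = box.axes()
    for atom, w in zip(mol.atoms, weights):
        if w == 0.0:
            continue
        sigma = model.sigma_for(atom.element)
        cutoff = 6.0 * sigma
        i0, i1 = _window(xs, atom.position[0], cutoff)
        j0, j1 = _window(ys, atom.position[1], cutoff)
        k0, k1 = _window(zs, atom.position[2], cutoff)
        dx = xs[i0:i1] - atom.position[0]
        dy = ys[j0:j1] - atom.position[1]
        dz = zs[k0:k1] - atom.position[2]
        r2 = (
            dx[:, None, None] ** 2
            + dy[None, :, None] ** 2
            + dz[None, None, :] ** 2
        )
        norm = (2.0 * np.pi * sigma**2) ** -1.5
        values[i0:i1, j0:j1, k0:k1] += w * norm * np.exp(-r2 / (2 * sigma**2))
    return ScalarField(box, values, "density")


def _window(axis: np.ndarray, center: float, cutoff: float) -> tuple[int, int]:
    i0 = int(np.searchsorted(axis, center - cutoff))
    i1 = int(np.searchsorted(axis, center + cutoff, side="right"))
    return i0, i1


def _self_cell_kernel(spacing: float, n_sub: int = 32) -> float:
    """Average of 1/r over one voxel centred at the origin (the r=0 entry of
    the discretized Green function), by midpoint quadrature."""
    t = (np.arange(n_sub) + 0.5) / n_sub - 0.5
    x = spacing * t
    r = np.sqrt(
        x[:, None, None] ** 2 + x[None, :, None] ** 2 + x[None, None, :] ** 2
    )
    return float(np.mean(1.0 / r))


def solve_poisson(rho: ScalarField, mode: str = "freespace") -> ScalarField:
    """Electrostatic potential from ∇²φ = −4πρ (units: e, Å).

    ``freespace`` (default): convolution of ρ with the 1/r Green function on
    a domain-doubled grid (zero-padded FFT), so boundaries are open.
    ``periodic``: spectral solve φ_k = 4πρ_k/k² under periodic boundaries
    with zero-mean gauge.
    """
    if rho.kind != "density":
        raise ValueError("solve_poisson expects a density field")
    vmax = np.max(np.abs(rho.values))
    if vmax > 0:
        boundary = np.concatenate([
            np.abs(rho.values[[0, -1], :, :]).ravel(),
            np.abs(rho.values[:, [0, -1], :]).ravel(),
            np.abs(rho.values[:, :, [0, -1]]).ravel(),
        ])
        if boundary.max() > 1e-6 * vmax:
            warnings.warn(
                "density is not negligible at the box boundary; "
                "the potential may be inaccurate", stacklevel=2)
    h = rho.box.spacing
    if mode == "freespace":
        nx, ny, nz = rho.box.dims
        shape = (2 * nx, 2 * ny, 2 * nz)
        dist_1d = [
            np.minimum(np.arange(n2), n2 - np.arange(n2)) * h for n2 in shape
        ]
        r = np.sqrt(
            dist_1d[0][:, None, None] ** 2
            + dist_1d[1][None, :, None] ** 2
            + dist_1d[2][None, None, :] ** 2
        )
        with np.errstate(divide="ignore"):
            green = 1.0 / r
        green[0, 0, 0] = _self_cell_kernel(h)
        pad = np.zeros(shape)
        pad[:nx, :ny, :nz] = rho.values
        phi_full = sfft.irfftn(
            sfft.rfftn(pad) * sfft.rfftn(green), s=shape
        )
        phi = phi_full[:nx, :ny, :nz] * rho.box.voxel_volume
    elif mode == "periodic":
        k = [2.0 * np.pi * sfft.fftfreq(n, d=h) for n in rho.box.dims]
        k2 = (
            k[0][:, None, None] ** 2
            + k[1][None, :, None] ** 2
            + k[2][None, None, :] ** 2
        )
        rho_k = sfft.fftn(rho.values)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi_k = 4.0 * np.pi * rho_k / k2
        phi_k[0, 0, 0] = 0.0  # zero-mean gauge
        phi = np.real(sfft.ifftn(phi_k))
    else:
        raise ValueError(f"unknown Poisson mode {mode!r}")
    return ScalarField(rho.box, phi, "esp")


def coulomb_direct(
    mol: Molecule, points: np.ndarray, model: ChargeModel
) -> np.ndarray:
    """Gaussian-smeared Coulomb sum φ(p) = Σ_a w_a erf(|p−r_a|/(σ√2))/|p−r_a|.

    Exact (to summation order) potential of the Gaussian charge model;
    serves as the independent oracle for :func:`solve_poisson`.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if not np.all(np.isfinite(points)):
        raise ValueError("probe points must be finite")
    weights = model.weights(mol)
    phi = np.zeros(len(points))
    for atom, w in zip(mol.atoms, weights):
        if w == 0.0:
            continue
        sigma = model.sigma_for(atom.element)
        d = np.linalg.norm(points - atom.position, axis=1)
        if sigma == 0.0:
            if np.any(d == 0.0):
                raise ZeroDivisionError(
                    "probe point coincides with a point charge (sigma=0)")
            phi += w / d
        else:
            # erf(x)/x -> 2/sqrt(pi) * 1/(sigma*sqrt(2)) as d -> 0
            small = d < 1e-12
            safe = np.where(small, 1.0, d)
            vals = erf(safe / (sigma * np.sqrt(2.0))) / safe
            vals = np.where(small, np.sqrt(2.0 / np.pi) / sigma, vals)
            phi += w * vals
    return phi


def write_cube(field: ScalarField, path, atoms: Molecule | None = None) -> None:
    """Write a Gaussian cube file (lengths converted Å → Bohr)."""
    box = field.box
    b = 1.0 / BOHR_TO_ANGSTROM
    lines = ["alphaq scalar field", f"kind: {field.kind}"]
    natoms = len(atoms.atoms) if atoms is not None else 0
    o = np.asarray(box.origin) * b
    lines.append(f"{natoms:5d} {o[0]:12.6f} {o[1]:12.6f} {o[2]:12.6f}")
    for ax in range(3):
        v = [0.0, 0.0, 0.0]
        v[ax] = box.spacing * b
        lines.append(
            f"{box.dims[ax]:5d} {v[0]:12.6f} {v[1]:12.6f} {v[2]:12.6f}")
    if atoms is not None:
        from .constants import ATOMIC_NUMBERS

        for a in atoms.atoms:
            p = a.position * b
            lines.append(
                f"{ATOMIC_NUMBERS[a.element]:5d} {0.0:12.6f} "
                f"{p[0]:12.6f} {p[1]:12.6f} {p[2]:12.6f}")
    flat = field.values.ravel(order="C")  # z fastest, cube convention
    for start in range(0, flat.size, 6):
        chunk = flat[start:start + 6]
        lines.append(" ".join(f"{v: .6E}" for v in chunk))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_cube(path) -> ScalarField:
    """Read a Gaussian cube file into a ScalarField (Bohr → Å).

    Only orthogonal, axis-aligned, uniformly spaced cubes are supported.
    """
    with open(path) as fh:
        tokens_by_line = [line.split() for line in fh]
    kind = "density"
    if len(tokens_by_line) > 1 and tokens_by_line[1][:1] == ["kind:"]:
        kind = tokens_by_line[1][1]
    try:
        header = tokens_by_line[2]
        natoms = int(header[0])
        origin = np.array([float(x) for x in header[1:4]]) * BOHR_TO_ANGSTROM
        dims = []
        spacings = []
        for ax in range(3):
            row = tokens_by_line[3 + ax]
            n = int(row[0])
            vec = np.array([float(x) for x in row[1:4]])
            off_axis = np.delete(vec, ax)
            if np.any(off_axis != 0.0):
                raise NotImplementedError(
                    "non-orthogonal cube axes are unsupported")
            dims.append(n)
            spacings.append(vec[ax] * BOHR_TO_ANGSTROM)
        if not np.allclose(spacings, spacings[0], rtol=1e-9):
            raise NotImplementedError(
                "anisotropic cube spacing is unsupported")
        data_start = 6 + abs(natoms)
        flat = np.array(
            [float(t) for row in tokens_by_line[data_start:] for t in row]
        )
        nx, ny, nz = dims
        if flat.size != nx * ny * nz:
            raise ValueError("truncated cube data section")
        values = flat.reshape((nx, ny, nz), order="C")
    except NotImplementedError:
        raise
    except Exception as exc:
        raise ValueError(f"malformed cube file {path}: {exc}") from exc
    box = GridBox(tuple(origin), float(spacings[0]), (nx, ny, nz))
    return ScalarField(box, values, kind)
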