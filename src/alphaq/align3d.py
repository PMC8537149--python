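"""Field-based rigid alignment of a target molecule onto a template.

The alignment objective is the cross-correlation

    E_ij = ∭ φ_i(r) ρ_j(r − t) dV

between the template's electrostatic potential φ_i and the target's charge
density ρ_j, maximized jointly over a fixed set of rotations (near-uniform
SO(3) samples built from Hopf-fibration coordinates, 2000 by default) and
over all integer grid translations t (searched exhaustively with a
zero-padded FFT cross-correlation).

The target's density is computed exactly once for its initial pose; rotamer
densities are obtained by trilinear re-interpolation of that field, with
analytic re-evaluation (rotate the atoms, rebuild the field) available as an
accuracy oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal
from scipy.spatial.transform import Rotation

from .chem_io import Atom, Molecule
from .espgrid import ChargeModel, GridBox, ScalarField, density_field, solve_poisson


@dataclass(frozen=True)
class RotamerSet:
    """An ordered set of unit quaternions (w, x, y, z)."""

    quaternions: np.ndarray
    generator: str = "hopf"

    def __post_init__(self) -> None:
        q = np.atleast_2d(np.asarray(self.quaternions, dtype=float))
        norms = np.linalg.norm(q, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-12):
            raise ValueError("rotamer quaternions must be unit-norm")
        object.__setattr__(self, "quaternions", q)

    def __len__(self) -> int:
        return len(self.quaternions)


@dataclass(frozen=True)
class AlignmentResult:
    """Optimal rigid placement of a target against a template."""

    rotamer_index: int
    quaternion: np.ndarray
    translation: np.ndarray  # Å, snapped to the grid
    e_ij: float  # e²/Å
    e_map_max_location: tuple[int, int, int]


def hopf_rotations(n: int) -> RotamerSet:
    """Deterministic near-uniform SO(3) sample of size ``n``.

    Rotations are generated on a product grid in Hopf coordinates: a uniform
    grid on the fiber circle ψ ∈ [0, 2π) crossed with a spherical Fibonacci
    grid on the base S² (θ, φ).  The unit quaternion is

        q = (cos(θ/2)cos(ψ/2), cos(θ/2)sin(ψ/2),
             sin(θ/2)cos(φ+ψ/2), sin(θ/2)sin(φ+ψ/2)).

    The first element is always the identity rotation.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    quats = [np.array([1.0, 0.0, 0.0, 0.0])]
    if n > 1:
        # Match circle and sphere resolutions: n1 ≈ (π n)^(1/3).
        n1 = max(1, int(round((np.pi * n) ** (1.0 / 3.0))))
        n2 = int(np.ceil((n - 1) / n1)) + 1
        golden = np.pi * (3.0 - np.sqrt(5.0))
        k = np.arange(n2)
        cos_theta = 1.0 - 2.0 * (k + 0.5) / n2
        theta = np.arccos(np.clip(cos_theta, -1.0, 1.0))
        phi = np.mod(golden * k, 2.0 * np.pi)
        psi = 2.0 * np.pi * np.arange(n1) / n1
        for kk in range(n2):
            for p in psi:
                th, ph = theta[kk], phi[kk]
                quats.append(np.array([
                    np.cos(th / 2) * np.cos(p / 2),
                    np.cos(th / 2) * np.sin(p / 2),
                    np.sin(th / 2) * np.cos(ph + p / 2),
                    np.sin(th / 2) * np.sin(ph + p / 2),
                ]))
                if len(quats) == n:
                    break
            if len(quats) == n:
                break
    return RotamerSet(np.array(quats[:n]), generator="hopf")


def random_rotations(n: int, seed: int) -> RotamerSet:
    """Uniform random SO(3) sample (Marsaglia method), for comparison."""
    rng = np.random.default_rng(seed)
    q = rng.standard_normal((n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    return RotamerSet(q, generator=f"random({seed})")


def quaternion_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix of a unit quaternion given as (w, x, y, z)."""
    q = np.asarray(q, dtype=float)
    if abs(np.linalg.norm(q) - 1.0) > 1e-9:
        raise ValueError("quaternion must be unit-norm")
    return Rotation.from_quat(np.r_[q[1:], q[0]]).as_matrix()


def rotate_molecule(mol: Molecule, q: np.ndarray, center: np.ndarray) -> Molecule:
    """Rotate atom positions rigidly about ``center``."""
    R = quaternion_matrix(q)
    center = np.asarray(center, dtype=float)
    atoms = [
        Atom(a.element, R @ (a.position - center) + center,
             a.partial_charge, a.electron_count, a.vdw_radius)
        for a in mol.atoms
    ]
    return Molecule(mol.id, atoms, mol.logbb)


def rotate_field(field: ScalarField, q: np.ndarray) -> ScalarField:
    """Trilinear re-interpolation of the field rotated about the box center;
    lookups falling outside the box read as zero."""
    R = quaternion_matrix(q)
    box = field.box
    center_idx = (box.center - np.asarray(box.origin)) / box.spacing
    idx = np.indices(box.dims, dtype=float)
    rel = idx.reshape(3, -1) - center_idx[:, None]
    src = R.T @ rel + center_idx[:, None]
    values = ndimage.map_coordinates(
        field.values, src, order=1, mode="constant", cval=0.0
    ).reshape(box.dims)
    return ScalarField(box, values, field.kind)


def cross_correlation_map(
    phi_template: ScalarField, rho_target: ScalarField
) -> ScalarField:
    """score(t) = Σ_r φ(r) ρ(r − t) ΔV for every integer grid shift t,
    via zero-padded (linear) FFT cross-correlation.

    The returned field is indexed by shift: entry (i, j, k) corresponds to
    t = (i, j, k) − (n − 1), i.e. its box origin is −(n−1)·spacing.
    """
    if phi_template.box != rho_target.box:
        raise ValueError("template and target fields must share one GridBox")
    box = phi_template.box
    corr = signal.correlate(
        phi_template.values, rho_target.values, mode="full", method="fft"
    ) * box.voxel_volume
    n = np.array(box.dims)
    score_box = GridBox(
        tuple(-(n - 1) * box.spacing), box.spacing, tuple(2 * n - 1)
    )
    return ScalarField(score_box, corr, "score")


def self_correlation(
    mol: Molecule, box: GridBox, model: ChargeModel,
    poisson_mode: str = "freespace",
) -> float:
    """E_ii = Σ φ_i ρ_i ΔV at zero shift."""
    rho = density_field(mol, box, model)
    phi = solve_poisson(rho, mode=poisson_mode)
    return float(np.sum(phi.values * rho.values) * box.voxel_volume)


def _centered(mol: Molecule, box: GridBox) -> Molecule:
    """Place the molecule's centroid at the box center."""
    return mol.translated(box.center - mol.centroid())


def _valid_shift_range(
    positions: np.ndarray, radii: np.ndarray, box: GridBox
) -> list[tuple[int, int]] | None:
    """Inclusive integer shift bounds per axis keeping the vdW envelope of
    the (already rotated) target inside the box, or None if impossible."""
    lo = np.asarray(box.origin)
    hi = box.upper
    ranges = []
    for ax in range(3):
        pmin = float(np.min(positions[:, ax] - radii))
        pmax = float(np.max(positions[:, ax] + radii))
        t_lo = int(np.ceil((lo[ax] - pmin) / box.spacing - 1e-9))
        t_hi = int(np.floor((hi[ax] - pmax) / box.spacing + 1e-9))
        if t_hi < t_lo:
            return None
        ranges.append((t_lo, t_hi))
    return ranges


def align_pair(
    template: Molecule,
    target: Molecule,
    box: GridBox,
    rotamers: RotamerSet,
    model: ChargeModel,
    template_phi: ScalarField | None = None,
    poisson_mode: str = "freespace",
) -> AlignmentResult:
    """Maximize E_ij over (rotamer, grid shift) for one template-target pair.

    The template stays fixed; the target is first re-centred so its centroid
    sits at the box center (the translation search absorbs the choice).
    Ties break to the lowest rotamer index, then the lexicographically
    smallest shift.  Shifts that push the target's van der Waals envelope
    out of the box are excluded.
    """
    if template_phi is None:
        rho_t = density_field(template, box, model)
        template_phi = solve_poisson(rho_t, mode=poisson_mode)
    centered = _centered(target, box)
    rho0 = density_field(centered, box, model)
    n = np.array(box.dims)

    best = None  # (e_ij, rot_idx, (i, j, k) in the full map)
    for rot_idx, q in enumerate(rotamers.quaternions):
        if rot_idx == 0 or np.allclose(q, [1, 0, 0, 0]):
            rho_r = rho0 if np.allclose(q, [1, 0, 0, 0]) else rotate_field(rho0, q)
        else:
            rho_r = rotate_field(rho0, q)
        rotated = rotate_molecule(centered, q, box.center)
        ranges = _valid_shift_range(rotated.positions, rotated.vdw_radii, box)
        if ranges is None:
            continue
        score = cross_correlation_map(template_phi, rho_r)
        sl = tuple(
            slice(r[0] + n[ax] - 1, r[1] + n[ax]) for ax, r in enumerate(ranges)
        )
        window = score.values[sl]
        flat = int(np.argmax(window))
        loc = np.unravel_index(flat, window.shape)
        value = float(window[loc])
        full_loc = tuple(int(loc[ax] + sl[ax].start) for ax in range(3))
        if best is None or value > best[0]:
            best = (value, rot_idx, full_loc)
    if best is None:
        raise ValueError(
            "box too small: no shift keeps the target inside for any rotamer")
    e_ij, rot_idx, full_loc = best
    grid_shift = (np.array(full_loc) - (n - 1)) * box.spacing
    # Total translation applied after rotating about the target's centroid:
    # the re-centring move plus the grid-search shift, so a target
    # pre-displaced by an exact grid vector d reports translation -d.
    translation = (box.center - target.centroid()) + grid_shift
    return AlignmentResult(
        rotamer_index=rot_idx,
        quaternion=np.array(rotamers.quaternions[rot_idx]),
        translation=translation,
        e_ij=e_ij,
        e_map_max_location=full_loc,
    )


def apply_alignment(
    target: Molecule, box: GridBox, result: AlignmentResult
) -> Molecule:
    """Atom coordinates of the target in its optimal pose (analytic, not
    interpolated): rotate about the centroid, then apply the reported
    translation."""
    rotated = rotate_molecule(target, result.quaternion, target.centroid())
    return rotated.translated(result.translation)
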