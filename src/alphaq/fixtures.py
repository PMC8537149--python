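"""Deterministic synthetic molecules, labels and packaged reference rows.

Real LogBB datasets are literature compilations that cannot be bundled, so
every pipeline stage is exercised on synthetic molecules: small neutral sets
of Gaussian charge centres (dumbbells, rings, random clusters) whose LogBB
labels come from a known teacher model applied to their own grid-ESP
descriptors.  Because the teacher is known, recovery can be measured
exactly; zero-noise labels should be learnable nearly perfectly.

Fixture grids are deliberately coarse (0.4-0.8 Å) and molecules small
(≤ 12 atoms) so the full pipeline runs in seconds; production defaults stay
at the fine 0.106/0.212 Å spacings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annmodel import sigmoid
from .chem_io import Atom, Molecule
from .descriptors import esp_vector, fit_pca, project
from .espgrid import ChargeModel, build_common_box

# Experimental LogBB span of the modelling dataset.
LOGBB_SPAN = (-2.69, 1.64)

_ELEMENTS = ("C", "N", "O", "H")


@dataclass(frozen=True)
class SyntheticSpec:
    n_molecules: int = 20
    atoms_per_mol: tuple[int, int] = (4, 10)
    scaffold: str = "random-cluster"  # dumbbell | ring | random-cluster
    sigma: float = 0.4
    label_model: str = "teacher_ann"  # teacher_ann | linear
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scaffold not in {"dumbbell", "ring", "random-cluster"}:
            raise ValueError(f"unknown scaffold {self.scaffold!r}")
        if self.label_model not in {"teacher_ann", "linear"}:
            raise ValueError(f"unknown label model {self.label_model!r}")


def _neutral_charges(rng: np.random.Generator, k: int) -> np.ndarray:
    q = rng.uniform(-0.4, 0.4, size=k)
    return q - q.mean()


def _one_molecule(rng: np.random.Generator, spec: SyntheticSpec,
                  index: int) -> Molecule:
    lo, hi = spec.atoms_per_mol
    if spec.scaffold == "dumbbell":
        k = 2
        sep = rng.uniform(1.2, 2.0)
        positions = np.array([[-sep / 2, 0, 0], [sep / 2, 0, 0]])
    elif spec.scaffold == "ring":
        k = int(rng.integers(max(lo, 3), hi + 1))
        angles = 2 * np.pi * np.arange(k) / k
        radius = rng.uniform(1.0, 1.6)
        positions = np.c_[radius * np.cos(angles),
                          radius * np.sin(angles),
                          np.zeros(k)]
    else:
        k = int(rng.integers(lo, hi + 1))
        positions = rng.normal(scale=1.2, size=(k, 3))
        positions -= positions.mean(axis=0)
    elements = rng.choice(_ELEMENTS, size=k)
    charges = _neutral_charges(rng, k)
    atoms = [
        Atom(el, pos, q)
        for el, pos, q in zip(elements, positions, charges)
    ]
    return Molecule(f"syn{index:03d}", atoms)


def make_molecules(spec: SyntheticSpec) -> list[Molecule]:
    """Seeded family of neutral Gaussian-atom molecules."""
    rng = np.random.default_rng(spec.seed)
    return [_one_molecule(rng, spec, i) for i in range(spec.n_molecules)]


def make_rotated_copies(base: Molecule, n_copies: int, seed: int):
    """Rotated/translated copies of a base scaffold with the ground-truth
    rigid motions recorded, for alignment recovery tests.

    Returns (copies, ground_truth) where ground_truth[i] = (quaternion,
    translation) applied to the base about its centroid.
    """
    from .align3d import random_rotations, rotate_molecule

    rots = random_rotations(n_copies, seed)
    rng = np.random.default_rng(seed + 1)
    copies, truth = [], []
    for i, q in enumerate(rots.quaternions):
        t = rng.uniform(-0.5, 0.5, size=3)
        moved = rotate_molecule(base, q, base.centroid()).translated(t)
        moved = Molecule(f"{base.id}_copy{i}", moved.atoms, base.logbb)
        copies.append(moved)
        truth.append((q, t))
    return copies, truth


@dataclass
class LabelSet:
    labels: np.ndarray
    teacher: dict
    raw_descriptors: np.ndarray
    projections: np.ndarray


def make_labels(
    mols: list[Molecule],
    spec: SyntheticSpec,
    raw_descriptors: np.ndarray | None = None,
    spacing: float = 0.5,
    n_components: int = 5,
) -> LabelSet:
    """LogBB-like labels from a known teacher acting on the molecules' own
    grid-ESP descriptors, scaled to the dataset-like span (−2.69, 1.64),
    plus optional Gaussian noise.

    The teacher (its weights, the PCA projection it used and the affine
    output scaling) is returned so recovery tests can compare against it.
    """
    model = ChargeModel(mode="partial_charge", sigma=spec.sigma)
    if raw_descriptors is None:
        box = build_common_box(mols, spacing=spacing, margin=2.7)
        centered = [m.translated(box.center - m.centroid()) for m in mols]
        raw_descriptors = np.array(
            [esp_vector(m, box, model) for m in centered])
    p = min(n_components, len(mols) - 1, raw_descriptors.shape[1])
    pca = fit_pca(raw_descriptors, n_components=p)
    proj = project(pca, raw_descriptors)
    span = proj.max(axis=0) - proj.min(axis=0)
    span[span == 0] = 1.0
    z = (proj - proj.min(axis=0)) / span

    rng = np.random.default_rng(spec.seed + 1000)
    if spec.label_model == "teacher_ann":
        w_in = rng.uniform(-2.0, 2.0, size=(p, 3))
        w_out = rng.uniform(-2.0, 2.0, size=3)
        out = sigmoid(sigmoid(z @ w_in) @ w_out)
        teacher = {"kind": "teacher_ann", "w_in": w_in, "w_out": w_out}
    else:
        coef = rng.uniform(-1.0, 1.0, size=p)
        out = z @ coef
        teacher = {"kind": "linear", "coef": coef}
    lo, hi = LOGBB_SPAN
    omin, omax = float(out.min()), float(out.max())
    scale = (hi - lo) / (omax - omin) if omax > omin else 1.0
    labels = lo + (out - omin) * scale
    teacher["output_scale"] = (omin, omax, lo, hi)
    noise = rng.normal(scale=spec.noise_sd, size=len(labels)) \
        if spec.noise_sd > 0 else 0.0
    return LabelSet(labels + noise, teacher, raw_descriptors, proj)


def make_teacher_dataset(
    seed: int, n: int = 40, p: int = 10, saturation: float = 7.0
):
    """Inputs and LogBB-like labels from a random 3-hidden teacher network
    of the same architecture as the regression model (no biases).

    The teacher's output layer is rescaled so its pre-sigmoid outputs span
    at least ±``saturation`` on the sampled inputs.  Its sigmoid outputs
    then cover nearly the whole unit interval, so the min-max normalization
    applied at training time is close to the identity and a near-zero-loss
    solution exists inside the model class — the property teacher-student
    recovery tests rely on.

    Returns (X, y, teacher_dict).
    """
    rng = np.random.default_rng(seed)
    X = rng.uniform(0.0, 1.0, size=(n, p))
    w_in = v = z = None
    for _ in range(200):
        w_in = rng.uniform(-4.0, 4.0, size=(p, 3))
        v = rng.uniform(-1.0, 1.0, size=3)
        z = sigmoid(X @ w_in) @ v
        if z.min() < 0.0 < z.max() and 0.4 < -z.min() / z.max() < 2.5:
            break
    c = saturation / min(-z.min(), z.max())
    w_out = c * v
    out = sigmoid(c * z)
    lo, hi = LOGBB_SPAN
    y = lo + (out - out.min()) / (out.max() - out.min()) * (hi - lo)
    teacher = {
        "w_in": w_in, "w_out": w_out,
        "output_scale": (float(out.min()), float(out.max()), lo, hi),
    }
    return X, y, teacher


def table3_fixture() -> pd.DataFrame:
    """The printed characteristics of the experimentally assayed molecules:
    thirteen rows of (name, Hill formula, MW/amu, calculated LogBB,
    experimental LogBB).  Rows "3".."12" are the ten drug candidates; "1",
    "2" and carbamazepine are the printed comparison compounds."""
    rows = [
        ("1", "C15H10Cl2N2O2", 321.2, -0.16, 0.44),
        ("2", "C10H12N4O3", 236.2, -0.77, -1.30),
        ("carbamazepine", "C15H12N2O", 236.3, -0.04, -0.14),
        ("3", "C17H17ClN8O", 384.8, -0.02, -0.25),
        ("4", "C22H25ClN6O3", 456.9, -0.67, -0.39),
        ("5", "C23H27ClN6O3", 471.0, -0.24, -0.44),
        ("6", "C25H32ClN7O2", 498.0, 0.26, -0.09),
        ("7", "C19H21F4N5O3", 443.4, -0.21, -0.07),
        ("8", "C25H26F3N5O3", 501.5, -0.74, -0.21),
        ("9", "C24H20F3N5O3", 483.5, -2.07, -1.70),
        ("10", "C28H31N7O3", 513.6, -0.25, -0.38),
        ("11", "C17H23N5O2", 329.4, 0.46, 0.54),
        ("12", "C24H31N3O2", 393.5, -0.73, -0.38),
    ]
    return pd.DataFrame(
        rows, columns=["name", "formula", "mw", "logbb_calc", "logbb_exp"]
    )


def subset_table_fixture() -> pd.DataFrame:
    """Printed per-subset dataset sizes: MW range and train/test counts of
    the eight molecular-weight subsets."""
    rows = [
        (1, 200.0, 250.0, 57, 14),
        (2, 251.0, 275.0, 39, 9),
        (3, 276.0, 301.0, 40, 10),
        (4, 302.0, 323.0, 40, 10),
        (5, 324.0, 360.0, 40, 10),
        (6, 361.0, 398.0, 40, 10),
        (7, 399.0, 453.0, 40, 9),
        (8, 454.0, 600.0, 32, 6),
    ]
    return pd.DataFrame(
        rows, columns=["subset", "mw_low", "mw_high", "n_train", "n_test"]
    )
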