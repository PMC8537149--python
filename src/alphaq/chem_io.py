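"""Molecule ingestion, molecular weight arithmetic, MW subsetting and folds.

The modelling protocol partitions a LogBB dataset into eight molecular-weight
subsets (one below 250 amu, six equal-population quantile bins over
(250, 453] amu, one above 453 amu) and, within each subset, draws five
independent random 80-85% train / 15-20% test resamples ("fivefold external
cross-validation").
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import (
    ATOMIC_NUMBERS,
    ATOMIC_WEIGHTS,
    DEFAULT_VDW_RADIUS,
    VDW_RADII,
)


class ParseError(ValueError):
    """Raised when a structure file cannot be parsed."""


@dataclass
class Atom:
    """One atom: element symbol, position (Å), signed partial charge (e),
    electron count (atomic number by default) and van der Waals radius (Å)."""

    element: str
    position: np.ndarray
    partial_charge: float = 0.0
    electron_count: int | None = None
    vdw_radius: float | None = None

    def __post_init__(self) -> None:
        if self.element not in ATOMIC_WEIGHTS:
            raise ValueError(f"unrecognized element symbol: {self.element!r}")
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("atom position must be a 3-vector")
        if self.electron_count is None:
            self.electron_count = ATOMIC_NUMBERS[self.element]
        if self.electron_count < 0:
            raise ValueError("electron_count must be non-negative")
        if self.vdw_radius is None:
            self.vdw_radius = VDW_RADII.get(self.element, DEFAULT_VDW_RADIUS)
        if self.vdw_radius <= 0:
            raise ValueError("vdw_radius must be positive")


@dataclass
class Molecule:
    """A molecule with 3D coordinates, per-atom metadata and an optional
    experimental LogBB label.

    Molecules are assumed electrically neutral; a nonzero net partial charge
    triggers a warning, not an error.
    """

    id: str
    atoms: list[Atom]
    logbb: float | None = None

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"molecule {self.id!r} has no atoms")
        if abs(self.net_charge) > 1e-6:
            warnings.warn(
                f"molecule {self.id!r} has net charge "
                f"{self.net_charge:.4f} e (expected neutral)",
                stacklevel=2,
            )

    @property
    def mw(self) -> float:
        """Molecular weight: sum of standard atomic weights, amu."""
        return float(sum(ATOMIC_WEIGHTS[a.element] for a in self.atoms))

    @property
    def net_charge(self) -> float:
        return float(sum(a.partial_charge for a in self.atoms))

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    @property
    def vdw_radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms])

    def centroid(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    def translated(self, shift: np.ndarray) -> "Molecule":
        shift = np.asarray(shift, dtype=float)
        atoms = [
            Atom(a.element, a.position + shift, a.partial_charge,
                 a.electron_count, a.vdw_radius)
            for a in self.atoms
        ]
        return Molecule(self.id, atoms, self.logbb)


@dataclass(frozen=True)
class SubsetSpec:
    """One MW bin. Membership is mw in (mw_low, mw_high]; the lowest bin is
    additionally closed at its lower edge."""

    index: int
    mw_low: float
    mw_high: float

    def __post_init__(self) -> None:
        if self.mw_high <= self.mw_low:
            raise ValueError("mw_high must exceed mw_low")


@dataclass(frozen=True)
class FoldSplit:
    fold: int
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test ids overlap")

    def to_json(self) -> str:
        return json.dumps(
            {"fold": self.fold, "seed": self.seed,
             "train_ids": list(self.train_ids),
             "test_ids": list(self.test_ids)}
        )


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def mw_from_formula(formula: str) -> float:
    """Molecular weight (amu, 1 decimal) from a Hill-notation formula.

    >>> mw_from_formula("C15H12N2O")
    236.3
    """
    pos = 0
    total = 0.0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula at {formula[pos:]!r}")
        pos = match.end()
        symbol, count = match.group(1), match.group(2)
        if symbol not in ATOMIC_WEIGHTS:
            raise ValueError(f"unknown element symbol {symbol!r} in {formula!r}")
        n = int(count) if count else 1
        if n <= 0:
            raise ValueError(f"non-positive count for {symbol} in {formula!r}")
        total += n * ATOMIC_WEIGHTS[symbol]
    if pos != len(formula) or pos == 0:
        raise ValueError(f"cannot parse formula {formula!r}")
    return round(total, 1)


def read_molecules(path, logbb_table=None) -> list[Molecule]:
    """Read molecules from an SDF/MOL V2000 file.

    Partial charges come from a ``PARTIAL_CHARGES`` SD property
    (space-separated, one value per atom) when present, otherwise from
    Gasteiger charges when the molecule sanitizes, otherwise zero.
    ``logbb_table`` is a CSV with header columns ``id,logbb``; labels are
    joined on the molecule id (SDF title or ``_Name``).
    """
    from rdkit import Chem
    from rdkit.Chem import AllChem

    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    molecules: list[Molecule] = []
    for idx, rdmol in enumerate(supplier):
        if rdmol is None:
            raise ParseError(f"malformed SDF record at index {idx} in {path}")
        if rdmol.GetNumConformers() == 0:
            raise ParseError(f"record {idx} in {path} has no coordinates")
        conf = rdmol.GetConformer()
        name = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else ""
        mol_id = name.strip() or f"mol{idx}"

        charges = None
        if rdmol.HasProp("PARTIAL_CHARGES"):
            charges = [float(v) for v in rdmol.GetProp("PARTIAL_CHARGES").split()]
            if len(charges) != rdmol.GetNumAtoms():
                raise ParseError(
                    f"record {idx}: PARTIAL_CHARGES length mismatch")
        else:
            try:
                clean = Chem.Mol(rdmol)
                Chem.SanitizeMol(clean)
                AllChem.ComputeGasteigerCharges(clean)
                charges = [
                    float(a.GetProp("_GasteigerCharge"))
                    for a in clean.GetAtoms()
                ]
                if not all(np.isfinite(charges)):
                    charges = None
            except Exception:
                charges = None

        atoms = []
        for i, a in enumerate(rdmol.GetAtoms()):
            p = conf.GetAtomPosition(i)
            atoms.append(
                Atom(
                    element=a.GetSymbol(),
                    position=np.array([p.x, p.y, p.z]),
                    partial_charge=charges[i] if charges else 0.0,
                )
            )
        molecules.append(Molecule(mol_id, atoms))

    if logbb_table is not None:
        table = pd.read_csv(logbb_table)
        if not {"id", "logbb"} <= set(table.columns):
            raise ValueError("LogBB CSV needs 'id' and 'logbb' columns")
        labels = dict(zip(table["id"].astype(str), table["logbb"].astype(float)))
        by_id = {m.id: m for m in molecules}
        for mol_id, value in labels.items():
            if mol_id in by_id:
                by_id[mol_id].logbb = value
            else:
                warnings.warn(f"LogBB id {mol_id!r} not found in SDF",
                              stacklevel=2)
    return molecules


def write_sdf(molecules: list[Molecule], path) -> None:
    """Write molecules to an SDF (V2000, no bonds) carrying partial charges
    in a ``PARTIAL_CHARGES`` property so a round trip is lossless."""
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    with Chem.SDWriter(str(path)) as writer:
        writer.SetKekulize(False)
        for mol in molecules:
            rw = Chem.RWMol()
            for atom in mol.atoms:
                rd_atom = Chem.Atom(atom.element)
                rd_atom.SetNoImplicit(True)
                rw.AddAtom(rd_atom)
            conf = Chem.Conformer(len(mol.atoms))
            for i, atom in enumerate(mol.atoms):
                conf.SetAtomPosition(i, Point3D(*atom.position))
            rw.AddConformer(conf)
            out = rw.GetMol()
            out.SetProp("_Name", mol.id)
            out.SetProp(
                "PARTIAL_CHARGES",
                " ".join(f"{a.partial_charge:.8f}" for a in mol.atoms),
            )
            out.UpdatePropertyCache(strict=False)
            writer.write(out)


def make_equal_population_bins(
    mws,
    inner_low: float = 250.0,
    inner_high: float = 453.0,
    n_inner: int = 6,
    outer_low: float = 200.0,
    outer_high: float = 600.0,
) -> list[SubsetSpec]:
    """Quantile MW bins: one bin below ``inner_low``, ``n_inner``
    equal-population bins over ``(inner_low, inner_high]`` and one bin above.

    Inner bin edges are population quantiles of the MWs falling inside the
    inner range, so inner bin populations differ by at most one.
    """
    mws = np.asarray(list(mws), dtype=float)
    inner = np.sort(mws[(mws > inner_low) & (mws <= inner_high)])
    if inner.size < n_inner:
        raise ValueError(
            f"need at least {n_inner} molecules in ({inner_low}, {inner_high}]"
        )
    if inner[0] == inner[-1]:
        raise ValueError("degenerate quantiles: all inner MWs are equal")
    # Edge between bins b and b+1 sits midway between the flanking order
    # statistics, guaranteeing populations split as evenly as possible.
    edges = [inner_low]
    for b in range(1, n_inner):
        cut = int(round(b * inner.size / n_inner))
        cut = min(max(cut, 1), inner.size - 1)
        edges.append(0.5 * (inner[cut - 1] + inner[cut]))
    edges.append(inner_high)
    if len(set(edges)) != len(edges) or sorted(edges) != edges:
        raise ValueError("degenerate quantiles: duplicate bin edges")
    specs = [SubsetSpec(1, outer_low, inner_low)]
    for b in range(n_inner):
        specs.append(SubsetSpec(b + 2, edges[b], edges[b + 1]))
    specs.append(SubsetSpec(n_inner + 2, inner_high, outer_high))
    return specs


def assign_subset(mol: Molecule, specs: list[SubsetSpec]) -> int:
    """Subset index for a molecule; bins are (low, high], the first bin is
    closed at its lower edge. MW outside total coverage raises."""
    mw = mol.mw
    lowest = min(specs, key=lambda s: s.mw_low)
    for spec in specs:
        if spec.mw_low < mw <= spec.mw_high:
            return spec.index
        if spec is lowest and mw == spec.mw_low:
            return spec.index
    raise ValueError(
        f"molecular weight {mw:.1f} amu outside subset coverage "
        f"[{lowest.mw_low}, {max(s.mw_high for s in specs)}]"
    )


def make_folds(
    ids,
    n_folds: int = 5,
    train_frac: float = 0.80,
    seed: int = 0,
) -> list[FoldSplit]:
    """Five independent seeded random train/test resamples of one subset.

    Each fold draws its own random split at ``train_frac``; folds are
    independent resamples, not a disjoint partition.
    """
    ids = list(ids)
    if len(ids) < 5:
        raise ValueError("need at least 5 molecule ids")
    if not 0.80 <= train_frac <= 0.85:
        raise ValueError("train_frac must lie in [0.80, 0.85]")
    n_train = int(round(train_frac * len(ids)))
    folds = []
    for fold in range(1, n_folds + 1):
        rng = np.random.default_rng((seed, fold))
        perm = rng.permutation(len(ids))
        train = tuple(ids[i] for i in sorted(perm[:n_train]))
        test = tuple(ids[i] for i in sorted(perm[n_train:]))
        folds.append(FoldSplit(fold, train, test, seed))
    return folds
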