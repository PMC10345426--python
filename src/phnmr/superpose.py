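"""Rigid-body superposition, cross-structure region RMSD, ensemble precision.

The Kabsch algorithm gives the closed-form least-squares rotation that
superimposes one corresponded point set onto another; reflections are
rejected by flipping the sign of the smallest singular direction when the
determinant would be negative. Cross-structure RMSD is computed over an
explicit residue correspondence after superposition; ensemble precision is
the average pairwise RMSD of each model to the converged mean structure,
as reported in NMR structure statistics tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from phnmr.exceptions import (
    ConditioningError,
    CoverageError,
    DimensionError,
    PrecisionUndefinedError,
)
from phnmr.structure_io import (
    BACKBONE_ATOMS,
    Selection,
    StructureEnsemble,
    extract_coordinates,
    resolve_selection,
)


@dataclass(frozen=True)
class Superposition:
    """A proper rigid transform x -> rotation @ x + translation, with the
    RMSD it achieves between the superimposed sets."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass(frozen=True)
class RegionCorrespondence:
    """One-to-one residue pairing between two structures.

    ``pairs`` is an ordered list of (residue_number_a, residue_number_b);
    no residue may repeat on either side.
    """

    pairs: tuple
    label: str = ""

    def __post_init__(self):
        pairs = tuple((int(a), int(b)) for a, b in self.pairs)
        object.__setattr__(self, "pairs", pairs)
        a_side = [a for a, _ in pairs]
        b_side = [b for _, b in pairs]
        if len(set(a_side)) != len(a_side) or len(set(b_side)) != len(b_side):
            raise ValueError("correspondence is not one-to-one: repeated residue")

    def __len__(self):
        return len(self.pairs)

    def swapped(self) -> "RegionCorrespondence":
        return RegionCorrespondence(tuple((b, a) for a, b in self.pairs), self.label)


@dataclass(frozen=True)
class EnsemblePrecision:
    """Average pairwise r.m.s. deviation of models from the mean structure."""

    mean_rmsd: float
    sd_rmsd: float
    selection: Selection
    per_model_rmsd: tuple

    def __post_init__(self):
        per = np.asarray(self.per_model_rmsd, dtype=float)
        assert abs(per.mean() - self.mean_rmsd) < 1e-9


def kabsch(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    weights: np.ndarray | None = None,
) -> Superposition:
    """Least-squares rigid superposition of ``coords_a`` onto ``coords_b``.

    Returns the proper rotation and translation minimizing the (weighted)
    RMSD, together with that RMSD. Requires n >= 3 non-collinear points.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise DimensionError(f"shape mismatch: {a.shape} vs {b.shape}")
    n = a.shape[0]
    if n < 3:
        raise DimensionError("superposition requires at least 3 points")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,):
            raise DimensionError("weights must have one entry per point")
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()
    cent_a = w @ a
    cent_b = w @ b
    a0 = a - cent_a
    b0 = b - cent_b
    # collinearity check on the reference set
    gyr = (a0 * w[:, None]).T @ a0
    eigvals = np.linalg.eigvalsh(gyr)
    if eigvals[1] <= 1e-12 * max(eigvals[2], 1.0):
        raise ConditioningError("points are (near-)collinear; rotation ill-determined")
    h = (a0 * w[:, None]).T @ b0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = cent_b - rot @ cent_a
    diff = (a0 @ rot.T) - b0
    rmsd = float(np.sqrt(np.sum(w[:, None] * diff**2)))
    return Superposition(rot, trans, rmsd)


def _region_coords(
    ens: StructureEnsemble,
    residues,
    atom_names: tuple,
    representative,
    chain: str = "A",
) -> np.ndarray:
    """Stack representative coordinates for given residues in pair order."""
    rows = []
    missing = []
    if representative == "mean":
        coords = ens.coords.mean(axis=0)
    else:
        m = int(representative)
        if not 1 <= m <= ens.n_models:
            raise CoverageError(f"model {m} out of range 1..{ens.n_models}")
        coords = ens.coords[m - 1]
    for resnum in residues:
        for atom in atom_names:
            i = ens._index.get((chain, resnum, atom))
            if i is None:
                missing.append((resnum, atom))
            else:
                rows.append(coords[i])
    if missing:
        raise CoverageError(f"correspondence not covered; missing atoms: {missing}")
    return np.asarray(rows)


def region_rmsd(
    ens_a: StructureEnsemble,
    ens_b: StructureEnsemble,
    corr: RegionCorrespondence,
    atom_class: str = "backbone",
    representative: int | str = "mean",
) -> float:
    """RMSD between two structures over a residue correspondence.

    Coordinates of the corresponded residues (backbone {N, CA, C, O} or all
    heavy atoms; for ``heavy`` both structures must share side-chain atom
    names per pair) are superimposed by :func:`kabsch` and the achieved
    RMSD returned. Symmetric in its two structures.
    """
    if atom_class == "backbone":
        atoms = BACKBONE_ATOMS
        coords_a = _region_coords(ens_a, [a for a, _ in corr.pairs], atoms, representative)
        coords_b = _region_coords(ens_b, [b for _, b in corr.pairs], atoms, representative)
    elif atom_class == "heavy":
        # heavy-atom correspondence: intersection of heavy atom names per residue pair
        if representative == "mean":
            ca, cb = ens_a.coords.mean(axis=0), ens_b.coords.mean(axis=0)
        else:
            m = int(representative)
            ca, cb = ens_a.coords[m - 1], ens_b.coords[m - 1]
        rows_a, rows_b = [], []
        for ra, rb in corr.pairs:
            names_a = {
                an
                for i, (c, rn, _r, an) in enumerate(ens_a.roster)
                if c == "A" and rn == ra and not ens_a.is_hydrogen(i)
            }
            names_b = {
                an
                for i, (c, rn, _r, an) in enumerate(ens_b.roster)
                if c == "A" and rn == rb and not ens_b.is_hydrogen(i)
            }
            shared = sorted(names_a & names_b)
            if not shared:
                raise CoverageError(f"no shared heavy atoms for pair ({ra}, {rb})")
            for an in shared:
                rows_a.append(ca[ens_a._index[("A", ra, an)]])
                rows_b.append(cb[ens_b._index[("A", rb, an)]])
        coords_a, coords_b = np.asarray(rows_a), np.asarray(rows_b)
    else:
        raise ValueError(f"atom_class must be 'backbone' or 'heavy', got {atom_class!r}")
    return kabsch(coords_a, coords_b).rmsd


def mean_structure(ens: StructureEnsemble, selection: Selection, tol: float = 1e-6,
                   max_iter: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Iteratively superimpose models and recompute the mean until converged.

    Returns (mean_coords, superimposed_model_coords) over the selection.
    Convergence: the mean moves < ``tol`` Å (max per-coordinate change).
    """
    idx = resolve_selection(ens, selection)
    models = ens.coords[:, idx, :].copy()
    mean = models.mean(axis=0)
    for _ in range(max_iter):
        fitted = np.empty_like(models)
        for m in range(models.shape[0]):
            sup = kabsch(models[m], mean)
            fitted[m] = sup.apply(models[m])
        new_mean = fitted.mean(axis=0)
        shift = np.max(np.abs(new_mean - mean))
        models = fitted
        mean = new_mean
        if shift < tol:
            break
    return mean, models


def ensemble_precision(ens: StructureEnsemble, selection: Selection) -> EnsemblePrecision:
    """Coordinate precision: per-model RMSD to the converged mean structure.

    Reported as mean ± sample (n−1) standard deviation over models, the
    convention of NMR ensemble statistics tables.
    """
    if ens.n_models < 2:
        raise PrecisionUndefinedError("ensemble precision requires >= 2 models")
    mean, models = mean_structure(ens, selection)
    per_model = []
    for m in range(models.shape[0]):
        sup = kabsch(models[m], mean)
        per_model.append(sup.rmsd)
    per = np.asarray(per_model)
    return EnsemblePrecision(
        mean_rmsd=float(per.mean()),
        sd_rmsd=float(per.std(ddof=1)),
        selection=selection,
        per_model_rmsd=tuple(float(x) for x in per),
    )
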