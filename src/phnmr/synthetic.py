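"""Seeded synthetic-data generators for every analysis input.

Each generator emulates one experimental data class with known ground
truth: multi-model coordinate ensembles as a rigid template plus per-atom
Gaussian jitter, fast-exchange HSQC titration trajectories driven by a
true Kd, one-site ITC thermograms with Gaussian heat noise, NOE restraint
lists with planted separation-class counts, and hetNOE profiles with
planted mobile segments. All generators draw from their own
``numpy.random.Generator`` seeded explicitly; identical arguments give
bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from phnmr.csp import Peak, TitrationSeries
from phnmr.hetnoe import HetNoeRecord, make_record
from phnmr.itc import BindingParams, ITCExperiment, simulate_isotherm
from phnmr.restraints import (
    DEFAULT_SCHEME,
    SEPARATION_CLASSES,
    RestraintRecord,
    make_restraint,
)
from phnmr.structure_io import StructureEnsemble

# ---------------------------------------------------------------------------
# idealized backbone template (NeRF chain extension)

_BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231}
_ANGLE = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7, "CA-C-O": 120.8}
_HELIX = (-57.0, -47.0)
_STRAND = (-139.0, 135.0)


def _place(a, b, c, bond, angle_deg, torsion_deg):
    """Place atom d given three predecessors and internal coordinates."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(torsion),
        bond * math.sin(angle) * math.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def ideal_backbone(n_residues: int = 30, pattern: str | None = None) -> np.ndarray:
    """Poly-alanine backbone (N, CA, C, O per residue) with standard geometry.

    ``pattern`` is a per-residue string of 'H' (alpha helix) and 'E'
    (extended strand); the default is a mixed alpha/beta arrangement of two
    strands flanking a central helix, echoing a small globular fold.
    Returns coordinates of shape (4 * n_residues, 3) in roster order
    N, CA, C, O per residue.
    """
    if pattern is None:
        third = max(n_residues // 3, 1)
        pattern = "E" * third + "H" * (n_residues - 2 * third) + "E" * third
    if len(pattern) != n_residues:
        raise ValueError("pattern length must equal n_residues")
    phi_psi = [(_HELIX if ss == "H" else _STRAND) for ss in pattern]
    # seed atoms for residue 1
    coords = {}
    n1 = np.array([0.0, 0.0, 0.0])
    ca1 = n1 + np.array([_BOND["N-CA"], 0.0, 0.0])
    ang = math.radians(_ANGLE["N-CA-C"])
    c1 = ca1 + _BOND["CA-C"] * np.array([-math.cos(ang), math.sin(ang), 0.0])
    coords[(1, "N")], coords[(1, "CA")], coords[(1, "C")] = n1, ca1, c1
    for i in range(2, n_residues + 1):
        phi_prev, psi_prev = phi_psi[i - 2]
        n_i = _place(coords[(i - 1, "N")], coords[(i - 1, "CA")],
                     coords[(i - 1, "C")], _BOND["C-N"], _ANGLE["CA-C-N"], psi_prev)
        ca_i = _place(coords[(i - 1, "CA")], coords[(i - 1, "C")], n_i,
                      _BOND["N-CA"], _ANGLE["C-N-CA"], 180.0)  # omega trans
        phi_i, _ = phi_psi[i - 1]
        c_i = _place(coords[(i - 1, "C")], n_i, ca_i,
                     _BOND["CA-C"], _ANGLE["N-CA-C"], phi_i)
        coords[(i, "N")], coords[(i, "CA")], coords[(i, "C")] = n_i, ca_i, c_i
    # carbonyl oxygens: N-CA-C-O torsion = psi + 180 (next N when available)
    for i in range(1, n_residues + 1):
        _, psi = phi_psi[i - 1]
        coords[(i, "O")] = _place(coords[(i, "N")], coords[(i, "CA")],
                                  coords[(i, "C")], _BOND["C-O"],
                                  _ANGLE["CA-C-O"], psi + 180.0)
    out = []
    for i in range(1, n_residues + 1):
        for atom in ("N", "CA", "C", "O"):
            out.append(coords[(i, atom)])
    return np.asarray(out)


def make_ensemble(
    n_residues: int = 30,
    n_models: int = 20,
    sigma: float = 0.5,
    seed: int = 0,
    pattern: str | None = None,
) -> tuple[StructureEnsemble, np.ndarray]:
    """Jittered ensemble around an idealized backbone template.

    Each model is the template plus iid Gaussian noise (sd ``sigma`` Å per
    coordinate). Returns (ensemble, template coordinates); the template is
    the ground truth the ensemble scatters around.
    """
    if sigma < 0 or n_models < 1:
        raise ValueError("sigma must be >= 0 and n_models >= 1")
    rng = np.random.default_rng(seed)
    template = ideal_backbone(n_residues, pattern)
    roster = [
        ("A", i, "ALA", atom)
        for i in range(1, n_residues + 1)
        for atom in ("N", "CA", "C", "O")
    ]
    noise = rng.normal(0.0, sigma, size=(n_models, len(roster), 3)) if sigma > 0 \
        else np.zeros((n_models, len(roster), 3))
    coords = template[None, :, :] + noise
    return StructureEnsemble(roster, coords), template


# ---------------------------------------------------------------------------
# fast-exchange HSQC titration


def fraction_bound(protein_uM: float, ligand_uM: float, kd_nM: float) -> float:
    """Bound fraction of protein from the exact binding quadratic."""
    p = protein_uM * 1e-6
    l = ligand_uM * 1e-6
    kd = kd_nM * 1e-9
    if l == 0:
        return 0.0
    s = p + l + kd
    return (s - math.sqrt(s * s - 4.0 * p * l)) / (2.0 * p)


@dataclass(frozen=True)
class TitrationTruth:
    """Ground truth of a synthetic titration."""

    site_residues: dict        # residue -> ddmax (ppm, combined scale)
    kd_nM: float
    fraction_bound: tuple      # per ratio


def make_titration(
    protein_conc_uM: float = 100.0,
    ratios: tuple = (0.0, 0.25, 0.5, 1.0),
    kd_nM: float = 50.0,
    site_residues: dict | None = None,
    background_sigma: float = 0.01,
    n_residues: int = 100,
    seed: int = 0,
    lost_residues: tuple = (),
) -> tuple[TitrationSeries, TitrationTruth]:
    """Fast-exchange titration peak lists with a planted binding site.

    ``site_residues`` maps residue -> Δδ_max (combined ppm) reached at full
    saturation (default: five residues at 0.3 ppm). Observed shift of a
    site residue is free shift + f_bound * Δδ_max along a fixed random
    direction in the scaled plane; other residues get iid Gaussian jitter
    (sd ``background_sigma`` ppm per scaled dimension). Residues listed in
    ``lost_residues`` vanish (exchange broadening) at the final ratio.
    Only the reference (ratio 0) peaks carry assignments.
    """
    if site_residues is None:
        site_residues = {r: 0.3 for r in (12, 13, 45, 47, 59)}
    rng = np.random.default_rng(seed)
    unknown = set(site_residues) - set(range(1, n_residues + 1))
    if unknown:
        raise ValueError(f"site residues outside 1..{n_residues}: {sorted(unknown)}")
    # free-state peak positions: dispersed amide region
    free_h = rng.uniform(6.8, 9.8, size=n_residues)
    free_n = rng.uniform(104.0, 130.0, size=n_residues)
    # fixed random direction per site residue in the scaled plane
    directions = {}
    for res in site_residues:
        ang = rng.uniform(0.0, 2.0 * math.pi)
        directions[res] = (math.cos(ang), math.sin(ang))
    fb = tuple(
        fraction_bound(protein_conc_uM, protein_conc_uM * r, kd_nM) for r in ratios
    )
    peaklists = []
    for k, _ratio in enumerate(ratios):
        peaks = []
        for idx in range(n_residues):
            res = idx + 1
            dh, dn = free_h[idx], free_n[idx]
            if res in site_residues:
                step = fb[k] * site_residues[res]
                dh = dh + step * directions[res][0]
                dn = dn + step * directions[res][1] * 5.0  # undo nitrogen scaling
            elif k > 0:
                dh = dh + rng.normal(0.0, background_sigma)
                dn = dn + rng.normal(0.0, background_sigma * 5.0)
            if k == len(ratios) - 1 and res in lost_residues:
                continue  # peak broadened beyond detection
            peaks.append(Peak(res if k == 0 else None, dh, dn, 1.0))
        peaklists.append(tuple(peaks))
    series = TitrationSeries(tuple(ratios), tuple(peaklists))
    return series, TitrationTruth(dict(site_residues), kd_nM, fb)


# ---------------------------------------------------------------------------
# ITC thermograms


def make_itc(
    exp: ITCExperiment | None = None,
    params: BindingParams | None = None,
    noise_sigma_ucal: float | None = None,
    noise_fraction: float = 0.02,
    seed: int = 0,
) -> tuple[ITCExperiment, np.ndarray]:
    """One-site thermogram with iid Gaussian heat noise.

    The default design titrates 300 µM peptide in the syringe titrated
    into 2 ml of 30 µM protein, 25 x 20 µl injections at 20 C. When
    ``noise_sigma_ucal`` is None it defaults to ``noise_fraction`` of the
    largest noiseless |heat|. Returns (experiment with noisy heats,
    noiseless heats).
    """
    if exp is None:
        exp = ITCExperiment()
    if params is None:
        params = BindingParams(n=1.0, ka=1e7, dh=-10.0)
    rng = np.random.default_rng(seed)
    clean = simulate_isotherm(exp, params)
    if noise_sigma_ucal is None:
        noise_sigma_ucal = noise_fraction * float(np.max(np.abs(clean)))
    noisy = clean + rng.normal(0.0, noise_sigma_ucal, size=clean.shape) \
        if noise_sigma_ucal > 0 else clean.copy()
    return exp.with_heats(noisy), clean


# ---------------------------------------------------------------------------
# restraint lists


_SEP_RANGES = {
    "intraresidue": (0, 0),
    "sequential": (1, 1),
    "medium": (2, 4),
    "long": (5, 40),
}
_ATOMS = ("H", "HA", "HB", "HG", "HD")
_CLASSES = ("strong", "medium", "weak", "very_weak")


def make_restraints(
    class_counts: dict | None = None,
    n_residues: int = 108,
    seed: int = 0,
) -> tuple[list[RestraintRecord], dict]:
    """Restraint list with planted per-separation-class counts.

    ``class_counts`` maps separation class to the number of restraints to
    generate (default mirrors a realistic NOE partition). Returns
    (restraints, ground-truth counts).
    """
    if class_counts is None:
        class_counts = {"intraresidue": 40, "sequential": 60,
                        "medium": 45, "long": 55}
    unknown = set(class_counts) - set(SEPARATION_CLASSES)
    if unknown:
        raise ValueError(f"unknown separation classes: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    out = []
    for cls in SEPARATION_CLASSES:
        count = int(class_counts.get(cls, 0))
        lo, hi = _SEP_RANGES[cls]
        for _ in range(count):
            sep = int(rng.integers(lo, hi + 1))
            i = int(rng.integers(1, n_residues - sep + 1))
            j = i + sep
            atom_i = _ATOMS[rng.integers(0, len(_ATOMS))]
            atom_j = _ATOMS[rng.integers(0, len(_ATOMS))]
            if cls == "intraresidue" and atom_i == atom_j:
                atom_j = "HA" if atom_i != "HA" else "HB"
            intensity = _CLASSES[rng.integers(0, len(_CLASSES))]
            out.append(make_restraint(i, atom_i, j, atom_j, intensity,
                                      scheme=DEFAULT_SCHEME))
    rng.shuffle(out)
    return out, dict(class_counts)


# ---------------------------------------------------------------------------
# hetNOE profiles


def make_hetnoe(
    n_residues: int = 108,
    mobile_segments: tuple = ((1, 4), (64, 68), (104, 108)),
    rigid_level: float = 0.80,
    mobile_level: float = 0.30,
    level_sd: float = 0.04,
    noise_sd: float = 0.01,
    missing_residues: tuple = (),
    seed: int = 0,
) -> tuple[list, set]:
    """hetNOE intensity pairs with planted mobile segments.

    Rigid residues scatter around ``rigid_level`` and mobile ones around
    ``mobile_level``; scatter is clipped away from the 0.5 decision line
    (rigid >= 0.55, mobile <= 0.45) so the planted truth is recoverable.
    Residues in ``missing_residues`` (prolines, overlapped peaks) are
    emitted as (residue, None). Returns (records, planted mobile set).
    """
    rng = np.random.default_rng(seed)
    mobile_set = set()
    for start, end in mobile_segments:
        mobile_set.update(range(start, end + 1))
    mobile_set &= set(range(1, n_residues + 1))
    records = []
    for res in range(1, n_residues + 1):
        if res in missing_residues:
            records.append((res, None))
            continue
        if res in mobile_set:
            level = float(np.clip(rng.normal(mobile_level, level_sd), 0.02, 0.45))
        else:
            level = float(np.clip(rng.normal(rigid_level, level_sd), 0.55, 1.0))
        i_ref = rng.normal(100.0, 5.0)
        i_sat = level * i_ref
        sigma = noise_sd * abs(i_ref)
        records.append(make_record(res, i_sat, i_ref, sigma, sigma))
    mobile_set -= set(missing_residues)
    return records, mobile_set
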