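"""NOE distance-restraint binning, classification and summary statistics.

NOESY cross-peak intensities are conventionally grouped into strong,
medium, weak and very-weak bins, each mapped to an interproton distance
range with a fixed 1.8 Å lower bound; upper bounds are relaxed for NOEs
involving amide (HN) protons and incremented by pseudo-atom corrections
for methyl, aromatic-ring and non-stereospecifically assigned methylene
groups. Restraints are further classified by residue separation
(intraresidue / sequential / medium-range / long-range), the partition
used in structure-statistics tables.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from phnmr.exceptions import SchemeError

SEPARATION_CLASSES = ("intraresidue", "sequential", "medium", "long")

#: Default pseudo-atom upper-bound corrections in Å.
PSEUDO_CORRECTIONS = {
    "methyl": 1.0,
    "methylene": 0.7,  # non-stereospecifically assigned
    "aromatic": 2.0,
    "none": 0.0,
}


@dataclass(frozen=True)
class BinningScheme:
    """Intensity class -> (lower, upper) distance range in Å.

    ``hn_upper`` overrides the upper bound when the restraint involves an
    HN proton (only classes that define an adjustment appear there).
    """

    bounds: dict = field(default_factory=lambda: {
        "strong": (1.8, 2.7),
        "medium": (1.8, 3.3),
        "weak": (1.8, 5.0),
        "very_weak": (1.8, 6.0),
    })
    hn_upper: dict = field(default_factory=lambda: {
        "strong": 2.9,
        "medium": 3.5,
    })
    pseudo_corrections: dict = field(
        default_factory=lambda: dict(PSEUDO_CORRECTIONS)
    )


DEFAULT_SCHEME = BinningScheme()


@dataclass(frozen=True)
class RestraintRecord:
    """One NOE-derived interproton distance bound."""

    residue_i: int
    atom_i: str
    residue_j: int
    atom_j: str
    intensity_class: str
    lower: float
    upper: float
    involves_hn: bool = False
    pseudo_correction: float = 0.0

    def __post_init__(self):
        if not (1.8 <= self.lower <= self.upper):
            raise ValueError(
                f"bounds must satisfy 1.8 <= lower <= upper, got "
                f"({self.lower}, {self.upper})"
            )
        if self.pseudo_correction < 0:
            raise ValueError("pseudo_correction must be >= 0")

    @property
    def separation_class(self) -> str:
        return classify_separation(self.residue_i, self.residue_j)


@dataclass(frozen=True)
class RestraintSummary:
    """Structure-statistics style restraint counts."""

    counts: dict
    total: int
    dihedral_counts: dict
    hbond_count: int

    @property
    def hbond_distance_restraints(self) -> int:
        # two distances per hydrogen bond: H–acceptor and donor-heavy–acceptor
        return 2 * self.hbond_count


def classify_separation(residue_i: int, residue_j: int) -> str:
    """Classify a restraint by |i−j|: 0 intraresidue, 1 sequential,
    2–4 medium-range, >=5 long-range. Total and symmetric."""
    if residue_i < 1 or residue_j < 1:
        raise ValueError("residue numbers must be >= 1")
    sep = abs(residue_i - residue_j)
    if sep == 0:
        return "intraresidue"
    if sep == 1:
        return "sequential"
    if sep < 5:
        return "medium"
    return "long"


def assign_bounds(
    intensity_class: str,
    involves_hn: bool = False,
    pseudo_correction: float = 0.0,
    scheme: BinningScheme = DEFAULT_SCHEME,
) -> tuple[float, float]:
    """Distance bounds for an intensity class.

    Upper bound = class upper (HN-adjusted where the class defines an
    adjustment) + pseudo-atom correction; the lower bound is always 1.8 Å.
    """
    if intensity_class not in scheme.bounds:
        raise SchemeError(
            f"unknown intensity class {intensity_class!r}; "
            f"known: {sorted(scheme.bounds)}"
        )
    lower, upper = scheme.bounds[intensity_class]
    if involves_hn and intensity_class in scheme.hn_upper:
        upper = scheme.hn_upper[intensity_class]
    return (lower, upper + pseudo_correction)


def make_restraint(
    residue_i: int,
    atom_i: str,
    residue_j: int,
    atom_j: str,
    intensity_class: str,
    pseudo_group: str = "none",
    scheme: BinningScheme = DEFAULT_SCHEME,
) -> RestraintRecord:
    """Build a RestraintRecord, deriving HN involvement and bounds."""
    involves_hn = atom_i in ("H", "HN") or atom_j in ("H", "HN")
    corr = scheme.pseudo_corrections[pseudo_group]
    lower, upper = assign_bounds(intensity_class, involves_hn, corr, scheme)
    return RestraintRecord(
        residue_i, atom_i, residue_j, atom_j, intensity_class,
        lower, upper, involves_hn, corr,
    )


def summarize(
    restraints: Sequence[RestraintRecord],
    dihedrals: dict | None = None,
    hbonds: int = 0,
) -> RestraintSummary:
    """Count restraints by sequence-separation class.

    The four classes partition the list exactly, so the per-class counts
    always sum to the total. ``dihedrals`` maps angle type (phi, psi,
    chi1, chi2) to a count; ``hbonds`` is the number of hydrogen bonds
    (each contributing two distance restraints).
    """
    counts = {cls: 0 for cls in SEPARATION_CLASSES}
    for r in restraints:
        counts[r.separation_class] += 1
    return RestraintSummary(
        counts=counts,
        total=len(restraints),
        dihedral_counts=dict(dihedrals or {}),
        hbond_count=int(hbonds),
    )


def dihedral_restraint(angle: str, center: float, halfwidth: float = 30.0) -> tuple:
    """A dihedral restraint as (angle, lower, upper) = center ± halfwidth.

    Side-chain rotamers (chi1/chi2) default to ±30°; backbone phi/psi
    halfwidths come from chemical-shift analysis tables and must be given.
    """
    return (angle, center - halfwidth, center + halfwidth)


# ---------------------------------------------------------------------------
# native TSV dialect


_TSV_FIELDS = ["residue_i", "atom_i", "residue_j", "atom_j", "intensity_class",
               "lower", "upper", "involves_hn", "pseudo_correction"]


def write_restraints_tsv(restraints: Iterable[RestraintRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(_TSV_FIELDS)
        for r in restraints:
            writer.writerow([
                r.residue_i, r.atom_i, r.residue_j, r.atom_j, r.intensity_class,
                f"{r.lower:.2f}", f"{r.upper:.2f}", int(r.involves_hn),
                f"{r.pseudo_correction:.2f}",
            ])


def read_restraints_tsv(path) -> list[RestraintRecord]:
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.append(RestraintRecord(
                residue_i=int(row["residue_i"]),
                atom_i=row["atom_i"],
                residue_j=int(row["residue_j"]),
                atom_j=row["atom_j"],
                intensity_class=row["intensity_class"],
                lower=float(row["lower"]),
                upper=float(row["upper"]),
                involves_hn=bool(int(row["involves_hn"])),
                pseudo_correction=float(row["pseudo_correction"]),
            ))
    return out
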