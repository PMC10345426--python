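"""Chemical-shift-perturbation analysis of HSQC titrations.

A ligand titrated into a ¹⁵N-labelled protein moves backbone amide peaks
in the ¹H-¹⁵N HSQC; in fast exchange each peak slides continuously toward
its bound position. Peaks are tracked across titration points by global
minimum-cost one-to-one matching in the scaled (δH, δN/5) plane, the
combined shift change Δδ = √(ΔδH² + (ΔδN/5)²) is computed per residue,
and residues with Δδ above a mapping threshold (strictly greater than
0.100 ppm by default) are called as the perturbed surface.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from phnmr.exceptions import PhnmrError

#: ¹⁵N shift changes are down-weighted by this factor in the combined shift,
#: reflecting the ~5x wider nitrogen shift dispersion. Fixed, not configurable.
NITROGEN_SCALE = 5.0

DEFAULT_THRESHOLD = 0.100  # ppm, strict >
DEFAULT_MAX_STEP = 0.25    # ppm in scaled space, per titration step

#: Bin edges for coloring perturbed residues by Δδ magnitude (ppm).
MAGNITUDE_BINS = (0.100, 0.200, 0.300)


@dataclass(frozen=True)
class Peak:
    """One amide cross-peak: residue assignment (or None), shifts, intensity."""

    residue: int | None
    delta_h: float
    delta_n: float
    intensity: float = 1.0

    def __post_init__(self):
        if not (math.isfinite(self.delta_h) and math.isfinite(self.delta_n)):
            raise ValueError("peak shifts must be finite")
        if self.intensity < 0:
            raise ValueError("intensity must be >= 0")

    @property
    def scaled(self) -> tuple[float, float]:
        return (self.delta_h, self.delta_n / NITROGEN_SCALE)


@dataclass(frozen=True)
class TitrationSeries:
    """Per-ratio peak lists; ratios are ligand:protein, increasing from 0."""

    ratios: tuple
    peaklists: tuple  # one tuple of Peaks per ratio

    def __post_init__(self):
        ratios = tuple(float(r) for r in self.ratios)
        object.__setattr__(self, "ratios", ratios)
        object.__setattr__(
            self, "peaklists", tuple(tuple(pl) for pl in self.peaklists)
        )
        if len(ratios) != len(self.peaklists):
            raise ValueError("one peak list required per ratio")
        if not ratios or ratios[0] != 0.0:
            raise ValueError("first molar ratio must be 0")
        if any(b <= a for a, b in zip(ratios, ratios[1:])):
            raise ValueError("ratios must be strictly increasing")


@dataclass(frozen=True)
class CspTable:
    """Per-residue Δδ at each titration ratio; None marks a lost peak."""

    ratios: tuple
    deltas: dict  # residue -> tuple of Δδ (or None) per ratio

    def final_deltas(self) -> dict:
        """Residue -> Δδ at the final ratio (None if the peak was lost)."""
        return {res: traj[-1] for res, traj in self.deltas.items()}


def delta_delta(dh: float, dn: float) -> float:
    """Combined amide shift change Δδ = √(ΔδH² + (ΔδN/5)²), in ppm."""
    if not (math.isfinite(dh) and math.isfinite(dn)):
        raise ValueError("shift changes must be finite")
    return math.hypot(dh, dn / NITROGEN_SCALE)


def _match_step(
    prev_positions: dict, peaks: tuple, max_step: float
) -> dict:
    """One titration step: assign previous peak positions to new peaks.

    Global minimum-cost one-to-one assignment on Euclidean distance in the
    scaled plane; assignments whose cost exceeds ``max_step`` are voided
    (the peak is flagged lost). Returns residue -> Peak or None.
    """
    residues = sorted(prev_positions)
    if not peaks:
        return {res: None for res in residues}
    prev = np.array([prev_positions[res] for res in residues])
    cur = np.array([p.scaled for p in peaks])
    cost = np.linalg.norm(prev[:, None, :] - cur[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(cost)
    out = {res: None for res in residues}
    for r, c in zip(rows, cols):
        if cost[r, c] <= max_step:
            out[residues[r]] = peaks[c]
    return out


def track_peaks(
    series: TitrationSeries, max_step: float = DEFAULT_MAX_STEP
) -> CspTable:
    """Track assigned reference peaks across a titration and compute Δδ.

    The reference (ratio 0) peaks must carry residue assignments; each is
    linked across consecutive ratios by minimum-cost one-to-one matching in
    (δH, δN/5) space. A link longer than ``max_step`` (exchange broadening,
    peak disappearance) leaves the residue unmatched from that point on and
    its Δδ is reported as missing (None), never as zero.
    """
    reference = series.peaklists[0]
    seen = set()
    for p in reference:
        if p.residue is None:
            raise PhnmrError("reference peaks must carry residue assignments")
        if p.residue in seen:
            raise PhnmrError(f"duplicate residue assignment {p.residue} at reference")
        seen.add(p.residue)
    ref_pos = {p.residue: p.scaled for p in reference}
    positions = dict(ref_pos)  # current scaled position per live residue
    deltas = {p.residue: [0.0] for p in reference}
    lost: set = set()
    for peaks in series.peaklists[1:]:
        live = {res: pos for res, pos in positions.items() if res not in lost}
        matched = _match_step(live, peaks, max_step)
        for res in deltas:
            if res in lost:
                deltas[res].append(None)
                continue
            peak = matched.get(res)
            if peak is None:
                lost.add(res)
                deltas[res].append(None)
            else:
                positions[res] = peak.scaled
                dh = peak.delta_h - (ref_pos[res][0])
                dn_scaled = peak.scaled[1] - ref_pos[res][1]
                deltas[res].append(math.hypot(dh, dn_scaled))
    return CspTable(
        ratios=series.ratios,
        deltas={res: tuple(v) for res, v in deltas.items()},
    )


def call_perturbed(
    table: CspTable, threshold: float = DEFAULT_THRESHOLD
) -> tuple[set, dict]:
    """Residues whose final-ratio Δδ strictly exceeds the threshold.

    Returns (perturbed residue set, residue -> magnitude bin index) where
    bin k means Δδ lies in (MAGNITUDE_BINS[k-1], MAGNITUDE_BINS[k]] style
    grading used for structure coloring (0 = below lowest edge).
    """
    finals = {res: d for res, d in table.final_deltas().items() if d is not None}
    if not finals:
        raise PhnmrError("no final-ratio delta available for any residue")
    perturbed = {res for res, d in finals.items() if d > threshold}
    bins = {}
    for res, d in finals.items():
        k = 0
        for edge in MAGNITUDE_BINS:
            if d > edge:
                k += 1
        bins[res] = k
    return perturbed, bins


# ---------------------------------------------------------------------------
# TSV peak-list I/O: residue (or '-'), delta_h, delta_n, intensity


def write_peaklist_tsv(peaks, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["residue", "delta_h", "delta_n", "intensity"])
        for p in peaks:
            writer.writerow([
                p.residue if p.residue is not None else "-",
                f"{p.delta_h:.4f}", f"{p.delta_n:.4f}", f"{p.intensity:.4f}",
            ])


def read_peaklist_tsv(path) -> list[Peak]:
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            res = None if row["residue"] in ("-", "", None) else int(row["residue"])
            out.append(Peak(res, float(row["delta_h"]), float(row["delta_n"]),
                            float(row.get("intensity") or 1.0)))
    return out


def write_csp_tsv(table: CspTable, path, threshold: float = DEFAULT_THRESHOLD) -> None:
    """Per-residue Δδ per ratio plus the final-point perturbed flag."""
    perturbed, _bins = call_perturbed(table, threshold)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        header = ["residue"] + [f"dd_ratio_{r:g}" for r in table.ratios] + ["perturbed"]
        writer.writerow(header)
        for res in sorted(table.deltas):
            traj = table.deltas[res]
            row = [res] + [("NA" if d is None else f"{d:.4f}") for d in traj]
            row.append(int(res in perturbed))
            writer.writerow(row)
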