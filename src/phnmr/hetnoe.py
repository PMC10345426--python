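"""Steady-state ¹⁵N-{¹H} heteronuclear NOE analysis.

The hetNOE of a backbone amide is the ratio of its peak intensity with
and without proton presaturation; values near 0.8 indicate a rigid
backbone on the ps-ns timescale while values below ~0.5 mark fast local
mobility (flexible termini and loops). Uncertainties are propagated to
first order from the spectral noise standard deviations.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass

from phnmr.exceptions import UndefinedRatioError

MOBILE_THRESHOLD = 0.5  # strict <


@dataclass(frozen=True)
class HetNoeRecord:
    residue: int
    i_sat: float
    i_ref: float
    noe: float
    sigma_noe: float
    mobile: bool


def compute_noe(
    i_sat: float,
    i_ref: float,
    sigma_sat: float = 0.0,
    sigma_ref: float | None = None,
) -> tuple[float, float]:
    """NOE = I_sat/I_ref with first-order (quadrature) error propagation.

    sigma_noe = |noe| * sqrt((sigma_sat/i_sat)^2 + (sigma_ref/i_ref)^2).
    If only one noise sd is supplied it is used for both spectra. Scale
    invariant: multiplying intensities and noise by c > 0 changes nothing.
    """
    if i_ref <= 0:
        raise UndefinedRatioError(f"reference intensity must be > 0, got {i_ref}")
    if sigma_ref is None:
        sigma_ref = sigma_sat
    if sigma_sat < 0 or sigma_ref < 0:
        raise ValueError("noise standard deviations must be >= 0")
    noe = i_sat / i_ref
    if i_sat == 0:
        # the saturated term's relative error is undefined; propagate the
        # reference-only contribution, which is 0 when noe = 0
        sigma_noe = sigma_sat / i_ref
    else:
        sigma_noe = abs(noe) * math.sqrt(
            (sigma_sat / i_sat) ** 2 + (sigma_ref / i_ref) ** 2
        )
    return (noe, sigma_noe)


def make_record(
    residue: int,
    i_sat: float,
    i_ref: float,
    sigma_sat: float = 0.0,
    sigma_ref: float | None = None,
    threshold: float = MOBILE_THRESHOLD,
) -> HetNoeRecord:
    noe, sigma = compute_noe(i_sat, i_ref, sigma_sat, sigma_ref)
    return HetNoeRecord(residue, i_sat, i_ref, noe, sigma, noe < threshold)


def flag_mobile(records, threshold: float = MOBILE_THRESHOLD) -> set:
    """Residues with NOE strictly below the threshold.

    Records may be HetNoeRecords or (residue, noe) pairs; entries whose NOE
    is None (overlapped/unreliable peaks, prolines) are never flagged.
    """
    mobile = set()
    for rec in records:
        if isinstance(rec, HetNoeRecord):
            residue, noe = rec.residue, rec.noe
        else:
            residue, noe = rec
        if noe is None:
            continue
        if noe < threshold:
            mobile.add(residue)
    return mobile


# ---------------------------------------------------------------------------
# TSV I/O: residue, i_sat, i_ref[, sigma_sat, sigma_ref]; 'NA' rows are
# carried through as missing (e.g. prolines, overlapped peaks).


def read_hetnoe_tsv(path) -> list:
    """Returns a list of HetNoeRecord or (residue, None) for missing rows."""
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            residue = int(row["residue"])
            if row["i_sat"] in ("NA", "", None):
                out.append((residue, None))
                continue
            sigma_sat = float(row.get("sigma_sat") or 0.0)
            sigma_ref_raw = row.get("sigma_ref")
            sigma_ref = float(sigma_ref_raw) if sigma_ref_raw else None
            out.append(make_record(
                residue, float(row["i_sat"]), float(row["i_ref"]),
                sigma_sat, sigma_ref,
            ))
    return out


def write_hetnoe_tsv(records, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["residue", "noe", "sigma_noe", "mobile"])
        for rec in records:
            if isinstance(rec, HetNoeRecord):
                writer.writerow([
                    rec.residue, f"{rec.noe:.4f}", f"{rec.sigma_noe:.4f}",
                    int(rec.mobile),
                ])
            else:
                residue, _ = rec
                writer.writerow([residue, "NA", "NA", 0])
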