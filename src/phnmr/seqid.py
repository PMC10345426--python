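"""Pairwise global alignment and region-restricted percent identity.

Global alignment uses the Gotoh affine-gap dynamic program with a pinned
deterministic tie-break (diagonal, then gap-in-B, then gap-in-A) so that
alignments are bit-reproducible. Identity is reported over aligned
(non-gap) pairs only; for region comparisons a structural residue
correspondence can stand in for an alignment, which is how identity over
a superimposed core region is computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from phnmr.exceptions import AlphabetError, UndefinedIdentityError
from phnmr.superpose import RegionCorrespondence

AMINO_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class SeqRecord:
    """A protein sequence with an identifier and a residue-numbering offset.

    Position ``i`` (1-based) of ``residues`` corresponds to residue number
    ``i + offset`` in the parent structure's numbering.
    """

    identifier: str
    residues: str
    offset: int = 0

    def __post_init__(self):
        bad = set(self.residues.upper()) - AMINO_ALPHABET
        if bad:
            raise AlphabetError(
                f"{self.identifier}: invalid characters {sorted(bad)}"
            )
        object.__setattr__(self, "residues", self.residues.upper())

    def __len__(self):
        return len(self.residues)

    def letter_at_residue(self, residue_number: int) -> str:
        return self.residues[residue_number - self.offset - 1]


@dataclass(frozen=True)
class AlignmentMap:
    """Ordered aligned position pairs; ``None`` marks a gap on that side.

    Positions are 1-based indices into each sequence and strictly increase
    along each side.
    """

    pairs: tuple
    score: float = 0.0

    def __post_init__(self):
        last_a = last_b = 0
        for pa, pb in self.pairs:
            if pa is not None:
                if pa <= last_a:
                    raise ValueError("positions must strictly increase on side A")
                last_a = pa
            if pb is not None:
                if pb <= last_b:
                    raise ValueError("positions must strictly increase on side B")
                last_b = pb

    @property
    def aligned_pairs(self) -> list[tuple[int, int]]:
        return [(pa, pb) for pa, pb in self.pairs if pa is not None and pb is not None]


def read_fasta(path) -> list[SeqRecord]:
    """Read FASTA into SeqRecords (offset 0)."""
    records = []
    ident, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if ident is not None:
                    records.append(SeqRecord(ident, "".join(chunks)))
                ident, chunks = line[1:].split()[0], []
            else:
                chunks.append(line)
    if ident is not None:
        records.append(SeqRecord(ident, "".join(chunks)))
    return records


def global_align(
    a: SeqRecord,
    b: SeqRecord,
    match_score: float = 1.0,
    mismatch_score: float = 0.0,
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> AlignmentMap:
    """Optimal global (Needleman–Wunsch/Gotoh) alignment with affine gaps.

    A gap of length L scores ``gap_open + (L - 1) * gap_extend``. Ties are
    broken deterministically: match/mismatch first, then a gap in B
    (consuming A), then a gap in A.
    """
    sa, sb = a.residues, b.residues
    if not sa or not sb:
        raise ValueError("sequences must be non-empty")
    n, m = len(sa), len(sb)
    neg = -np.inf
    M = np.full((n + 1, m + 1), neg)   # ends in aligned pair
    X = np.full((n + 1, m + 1), neg)   # ends in gap in B (A consumed)
    Y = np.full((n + 1, m + 1), neg)   # ends in gap in A (B consumed)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match_score if sa[i - 1] == sb[j - 1] else mismatch_score
            M[i, j] = s + max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend,
                          Y[i - 1, j] + gap_open)
            Y[i, j] = max(M[i, j - 1] + gap_open, X[i, j - 1] + gap_open,
                          Y[i, j - 1] + gap_extend)
    # traceback from the best final state; ties prefer M, then X, then Y
    finals = (("M", M[n, m]), ("X", X[n, m]), ("Y", Y[n, m]))
    best = max(v for _k, v in finals)
    state = next(k for k, v in finals if v == best)
    i, j = n, m
    pairs = []
    eps = 1e-9
    while i > 0 or j > 0:
        if state == "M":
            s = match_score if sa[i - 1] == sb[j - 1] else mismatch_score
            target = M[i, j] - s
            pairs.append((i, j))
            state = next(
                prev
                for prev, val in (("M", M[i - 1, j - 1]), ("X", X[i - 1, j - 1]),
                                  ("Y", Y[i - 1, j - 1]))
                if np.isfinite(val) and abs(val - target) < eps
            )
            i, j = i - 1, j - 1
        elif state == "X":
            pairs.append((i, None))
            state = next(
                prev
                for prev, val, cost in (("M", M[i - 1, j], gap_open),
                                        ("X", X[i - 1, j], gap_extend),
                                        ("Y", Y[i - 1, j], gap_open))
                if np.isfinite(val) and abs(val + cost - X[i, j]) < eps
            )
            i -= 1
        else:  # Y
            pairs.append((None, j))
            state = next(
                prev
                for prev, val, cost in (("M", M[i, j - 1], gap_open),
                                        ("X", X[i, j - 1], gap_open),
                                        ("Y", Y[i, j - 1], gap_extend))
                if np.isfinite(val) and abs(val + cost - Y[i, j]) < eps
            )
            j -= 1
    pairs.reverse()
    return AlignmentMap(tuple(pairs), score=float(best))


def percent_identity(
    map_or_corr: AlignmentMap | RegionCorrespondence,
    a: SeqRecord,
    b: SeqRecord,
    region: set | None = None,
) -> float:
    """Percent identity over aligned pairs, rounded half-up to one decimal.

    ``region`` (optional) restricts to pairs whose A-side residue number is
    in the set; gap columns are never counted in the denominator. For a
    :class:`RegionCorrespondence` the pairs are residue numbers in each
    structure's own numbering, translated through each record's offset.
    """
    if isinstance(map_or_corr, RegionCorrespondence):
        aligned = [(ra, rb) for ra, rb in map_or_corr.pairs]
        get_a = a.letter_at_residue
        get_b = b.letter_at_residue
    else:
        aligned = map_or_corr.aligned_pairs
        get_a = lambda p: a.residues[p - 1]
        get_b = lambda p: b.residues[p - 1]
    if region is not None:
        aligned = [(pa, pb) for pa, pb in aligned if pa in region]
    if not aligned:
        raise UndefinedIdentityError("no aligned pairs in region")
    same = sum(1 for pa, pb in aligned if get_a(pa) == get_b(pb))
    pct = Decimal(100 * same) / Decimal(len(aligned))
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
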