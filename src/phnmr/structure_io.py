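"""Multi-model PDB input/output and atom selection.

An NMR deposition is an ensemble of models (MODEL/ENDMDL blocks) that all
share one (chain, residue, atom) roster. This module reads such files into
a :class:`StructureEnsemble`, validates roster consistency, resolves
residue/atom selections into deterministic coordinate matrices, and writes
ensembles back out. Parsing and serialization are delegated to gemmi;
validation, ordering and selection semantics live here.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gemmi
import numpy as np

from phnmr.exceptions import ParseError, RosterError, SelectionError

#: Backbone atom class as used for all backbone RMSD statistics.
BACKBONE_ATOMS = ("N", "CA", "C", "O")

# Canonical within-residue atom ordering: backbone first, then side chain
# alphabetically.  Makes extracted coordinate matrices independent of the
# atom order in the source file.
_BB_RANK = {name: i for i, name in enumerate(BACKBONE_ATOMS)}


def _atom_rank(name: str) -> tuple:
    return (0, _BB_RANK[name]) if name in _BB_RANK else (1, name)


@dataclass(frozen=True)
class AtomRecord:
    """One atom in one model of an ensemble.

    ``residue_number`` is taken verbatim from the file (1-based, as in
    'residues 1-108'); no renumbering is ever applied.
    """

    model_index: int
    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    position: np.ndarray

    def __post_init__(self):
        if not np.all(np.isfinite(self.position)):
            raise ValueError(
                f"non-finite position for {self.chain_id}{self.residue_number}:{self.atom_name}"
            )


@dataclass(frozen=True)
class Selection:
    """A set of residues and an atom class.

    ``residues``: iterable of (chain_id, residue_number) pairs, or plain
    residue numbers (implying chain 'A'), or None for all residues.
    ``atom_names``: explicit set of atom names, or the symbolic classes
    ``"backbone"`` ({N, CA, C, O}) and ``"heavy"`` (all non-hydrogens).
    """

    residues: frozenset | None = None
    atom_names: frozenset | str = "backbone"

    @staticmethod
    def of(residues=None, atom_names="backbone") -> "Selection":
        if residues is not None:
            norm = frozenset(
                (r if isinstance(r, tuple) else ("A", int(r))) for r in residues
            )
        else:
            norm = None
        if not isinstance(atom_names, str):
            atom_names = frozenset(atom_names)
        return Selection(norm, atom_names)


class StructureEnsemble:
    """Multi-model coordinates over a single shared atom roster.

    Parameters
    ----------
    roster : list of (chain_id, residue_number, residue_name, atom_name)
        Shared atom identities, in canonical order.
    coords : ndarray, shape (n_models, n_atoms, 3)
        Coordinates in Å, one row of atoms per model.
    """

    def __init__(self, roster: Sequence[tuple], coords: np.ndarray):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_models, n_atoms, 3)")
        if coords.shape[0] < 1:
            raise ValueError("ensemble needs at least one model")
        if coords.shape[1] != len(roster):
            raise ValueError("coords second axis must match roster length")
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")
        order = sorted(
            range(len(roster)),
            key=lambda i: (roster[i][0], roster[i][1], _atom_rank(roster[i][3])),
        )
        self.roster = [tuple(roster[i]) for i in order]
        self.coords = coords[:, order, :]
        self._index = {
            (c, rn, an): i for i, (c, rn, _rname, an) in enumerate(self.roster)
        }

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def sequence(self) -> dict:
        """Map (chain_id, residue_number) -> 3-letter residue name."""
        seq = {}
        for chain, resnum, resname, _atom in self.roster:
            seq[(chain, resnum)] = resname
        return seq

    def residue_numbers(self, chain: str = "A") -> list[int]:
        return sorted({rn for c, rn in self.sequence if c == chain})

    def one_letter_sequence(self, chain: str = "A") -> str:
        letters = []
        for (c, _rn), resname in sorted(self.sequence.items()):
            if c != chain:
                continue
            info = gemmi.find_tabulated_residue(resname)
            letters.append(info.one_letter_code.upper() if info else "X")
        return "".join(letters)

    def atoms(self, model_index: int = 1) -> Iterable[AtomRecord]:
        m = model_index - 1
        for i, (chain, resnum, resname, atom) in enumerate(self.roster):
            yield AtomRecord(model_index, chain, resnum, resname, atom, self.coords[m, i])

    def is_hydrogen(self, i: int) -> bool:
        name = self.roster[i][3]
        # PDB v3 hydrogen names start with H or a digit followed by H (1HB2...)
        stripped = name.lstrip("0123456789")
        return stripped.startswith("H") or stripped.startswith("D")


def _collect_model(model: gemmi.Model, model_index: int):
    """Extract (roster, coords) from one gemmi model, resolving altlocs."""
    best: dict[tuple, tuple] = {}
    for chain in model:
        chain_id = chain.name.strip() or "A"
        for residue in chain:
            resnum = residue.seqid.num
            for atom in residue:
                key = (chain_id, resnum, atom.name)
                occ = atom.occ
                alt = atom.altloc or ""
                prev = best.get(key)
                # keep highest occupancy; ties broken by altloc letter
                if prev is None or (-occ, alt) < (-prev[0], prev[1]):
                    best[key] = (
                        occ,
                        alt,
                        residue.name,
                        np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    )
    roster = []
    coords = []
    for (chain_id, resnum, atom_name), (_occ, _alt, resname, pos) in sorted(
        best.items(), key=lambda kv: (kv[0][0], kv[0][1], _atom_rank(kv[0][2]))
    ):
        roster.append((chain_id, resnum, resname, atom_name))
        coords.append(pos)
    return roster, np.asarray(coords, dtype=float)


def read_ensemble(path: str | os.PathLike, format: str = "pdb") -> StructureEnsemble:
    """Read a (possibly multi-model) PDB file into a StructureEnsemble.

    Every model must carry the identical atom roster; a mismatch raises
    :class:`RosterError` listing the offending atoms.
    """
    if format != "pdb":
        raise ValueError(f"unsupported format {format!r}; only 'pdb' is supported")
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_pdb(path, split_chain_on_ter=False)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{path}: no models found")
    rosters, per_model = [], []
    for i, model in enumerate(st):
        roster, coords = _collect_model(model, i + 1)
        if not roster:
            raise ParseError(f"{path}: model {i + 1} contains no atoms")
        rosters.append(roster)
        per_model.append(coords)
    ref = rosters[0]
    ref_keys = [(c, rn, an) for c, rn, _r, an in ref]
    for i, roster in enumerate(rosters[1:], start=2):
        keys = [(c, rn, an) for c, rn, _r, an in roster]
        if keys != ref_keys:
            missing = sorted(set(ref_keys) - set(keys))
            extra = sorted(set(keys) - set(ref_keys))
            parts = []
            if missing:
                parts.append(f"missing {missing}")
            if extra:
                parts.append(f"extra {extra}")
            raise RosterError(
                f"{path}: model {i} roster differs from model 1: " + "; ".join(parts)
            )
    return StructureEnsemble(ref, np.stack(per_model))


def write_ensemble(ensemble: StructureEnsemble, path: str | os.PathLike) -> None:
    """Write an ensemble as a multi-model PDB file (MODEL/ENDMDL blocks)."""
    st = gemmi.Structure()
    st.name = "phnmr"
    for m in range(ensemble.n_models):
        model = gemmi.Model(m + 1)
        chains: dict[str, gemmi.Chain] = {}
        residues: dict[tuple, gemmi.Residue] = {}
        for i, (chain_id, resnum, resname, atom_name) in enumerate(ensemble.roster):
            if chain_id not in chains:
                chains[chain_id] = gemmi.Chain(chain_id)
            rkey = (chain_id, resnum)
            if rkey not in residues:
                res = gemmi.Residue()
                res.name = resname
                res.seqid = gemmi.SeqId(resnum, " ")
                residues[rkey] = res
            atom = gemmi.Atom()
            atom.name = atom_name
            x, y, z = ensemble.coords[m, i]
            atom.pos = gemmi.Position(x, y, z)
            atom.occ = 1.0
            stripped = atom_name.lstrip("0123456789")
            element = "H" if stripped[:1] in ("H", "D") else stripped[:1]
            atom.element = gemmi.Element(element)
            residues[rkey].add_atom(atom)
        for (chain_id, _rn), res in sorted(residues.items()):
            chains[chain_id].add_residue(res)
        for chain in chains.values():
            model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    st.write_pdb(os.fspath(path))


def write_fasta(ensemble: StructureEnsemble, path: str | os.PathLike, identifier: str = "roster") -> None:
    """Export the roster sequence of each chain as FASTA."""
    with open(path, "w") as fh:
        chains = sorted({c for c, _rn in ensemble.sequence})
        for chain in chains:
            fh.write(f">{identifier}_{chain}\n")
            seq = ensemble.one_letter_sequence(chain)
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def resolve_selection(ensemble: StructureEnsemble, selection: Selection) -> list[int]:
    """Resolve a Selection to roster indices in canonical order."""
    if isinstance(selection.atom_names, str):
        if selection.atom_names == "backbone":
            allowed = set(BACKBONE_ATOMS)
            symbolic = True
        elif selection.atom_names == "heavy":
            allowed = None  # all non-hydrogens
            symbolic = True
        else:
            raise SelectionError(f"unknown atom class {selection.atom_names!r}")
    else:
        allowed = set(selection.atom_names)
        symbolic = False
        roster_names = {an for _c, _rn, _r, an in ensemble.roster}
        unknown = allowed - roster_names
        if unknown:
            raise SelectionError(f"atom names not in roster: {sorted(unknown)}")
    idx = []
    for i, (chain, resnum, _resname, atom) in enumerate(ensemble.roster):
        if selection.residues is not None and (chain, resnum) not in selection.residues:
            continue
        if allowed is None:
            if ensemble.is_hydrogen(i):
                continue
        elif atom not in allowed:
            continue
        idx.append(i)
    if not idx:
        raise SelectionError("selection resolves to no atoms")
    if symbolic is False and selection.residues is not None:
        pass  # explicit names already validated against roster
    return idx


def extract_coordinates(
    ensemble: StructureEnsemble,
    selection: Selection,
    model_index: int | str = 1,
) -> np.ndarray:
    """Extract an (n_atoms, 3) Å coordinate matrix for a selection.

    ``model_index`` is 1-based; the string ``"mean"`` returns the unweighted
    per-atom average over all models. Atom order is canonical (ascending
    chain, residue number, then backbone-first atom-name order), so the
    result is independent of the atom order in the source file.
    """
    idx = resolve_selection(ensemble, selection)
    if model_index == "mean":
        return ensemble.coords[:, idx, :].mean(axis=0)
    m = int(model_index)
    if not 1 <= m <= ensemble.n_models:
        raise SelectionError(
            f"model_index {m} out of range 1..{ensemble.n_models}"
        )
    return ensemble.coords[m - 1, idx, :].copy()
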