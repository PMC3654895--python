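"""Contact-site extraction from peptide-HLA class I complex structures.

An HLA residue and a peptide residue are considered to interact when the
minimum distance over all their heavy-atom pairs is strictly below a
cutoff (default 4.0 A).  Contacts are aggregated over many complexes of
the same locus into a grid of (HLA residue index, peptide position 1-9)
cells with occurrence counts; rarely occurring cells (fewer than
``min_count`` complexes, default 5) are discarded.  The retained grid is
the pan-allele "pseudo-sequence" mask used by the encoder.

The bundled default grids (59 cells for HLA-A, 75 for HLA-B) are
reconstructed from canonical class I binding-pocket assignments, not
computed from a structure set; regenerate from your own complexes with
:func:`aggregate_contacts` for production use.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import numpy as np

from .matrices import NONSTANDARD_PARENT

logger = logging.getLogger(__name__)

PEPTIDE_LENGTH = 9


class ChainNotFoundError(KeyError):
    """Requested chain absent from the structure; lists available chains."""


class PeptideLengthError(ValueError):
    """Peptide chain does not have the expected 9 residues."""


@dataclass
class ResidueAtomSet:
    """One residue with its heavy-atom coordinates (author numbering)."""

    chain_id: str
    residue_index: int
    amino_acid: str  # 1-letter code; "X" flags unmapped nonstandard
    atoms: list[tuple[str, float, float, float]]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(
                f"residue {self.chain_id}:{self.residue_index} has no atoms")

    @property
    def coords(self) -> np.ndarray:
        return np.array([a[1:] for a in self.atoms], dtype=float)


@dataclass
class ComplexStructure:
    complex_id: str
    hla_chain: list[ResidueAtomSet]
    peptide_chain: list[ResidueAtomSet]
    locus: str = "A"


@dataclass
class ContactGrid:
    """Filtered (HLA residue index, peptide position) contact cells."""

    locus: str
    cells: dict[tuple[int, int], int] = field(default_factory=dict)
    n_complexes: int = 0
    min_count: int = 5
    cutoff_angstrom: float = 4.0

    def sorted_cells(self) -> list[tuple[int, int]]:
        """Cells in the canonical (hla_index, peptide_position) order used
        for feature layout."""
        return sorted(self.cells)

    def hla_indices(self) -> list[int]:
        return sorted({h for h, _ in self.cells})

    def __len__(self) -> int:
        return len(self.cells)

    # -- serialization ----------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "locus": self.locus,
            "cutoff_angstrom": self.cutoff_angstrom,
            "min_count": self.min_count,
            "n_complexes": self.n_complexes,
            "cells": [[h, p, c] for (h, p), c in sorted(self.cells.items())],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "ContactGrid":
        with open(path) as fh:
            payload = json.load(fh)
        return cls._from_payload(payload)

    @classmethod
    def _from_payload(cls, payload: dict) -> "ContactGrid":
        cells = {(int(h), int(p)): int(c) for h, p, c in payload["cells"]}
        for (h, p), c in cells.items():
            if not 1 <= p <= PEPTIDE_LENGTH:
                raise ValueError(f"peptide position {p} outside 1..9")
        return cls(
            locus=payload["locus"],
            cells=cells,
            n_complexes=int(payload.get("n_complexes", 0)),
            min_count=int(payload.get("min_count", 5)),
            cutoff_angstrom=float(payload.get("cutoff_angstrom", 4.0)),
        )

    def to_tsv(self, path) -> None:
        """Grid as TSV: rows = peptide positions 1-9, columns = HLA residue
        indices, cell = occurrence count (0 when not retained)."""
        cols = self.hla_indices()
        with open(path, "w") as fh:
            fh.write("pos\t" + "\t".join(map(str, cols)) + "\n")
            for p in range(1, PEPTIDE_LENGTH + 1):
                row = [str(self.cells.get((h, p), 0)) for h in cols]
                fh.write(f"{p}\t" + "\t".join(row) + "\n")


def load_default_grid(locus: str) -> ContactGrid:
    """Bundled reconstructed default grid: 59 cells (A) or 75 cells (B)."""
    if locus not in ("A", "B"):
        raise ValueError(f"locus must be 'A' or 'B', got {locus!r}")
    text = (resources.files("annbm.data")
            / f"contact_grid_{locus}.synthetic.json").read_text()
    return ContactGrid._from_payload(json.loads(text))


# ---------------------------------------------------------------------------
# parsing

def _residues_from_chain(chain, chain_id: str) -> list[ResidueAtomSet]:
    from Bio.SeqUtils import seq1

    out = []
    for res in chain:
        hetflag, resseq, _icode = res.id
        resname = res.get_resname().strip()
        if hetflag != " ":
            if resname in ("HOH", "WAT"):
                continue
            if resname in NONSTANDARD_PARENT:
                aa = NONSTANDARD_PARENT[resname]
            else:
                logger.warning("skipping unmapped hetero residue %s %s:%d",
                               resname, chain_id, resseq)
                continue
        else:
            aa = seq1(resname)
            if aa == "X" and resname in NONSTANDARD_PARENT:
                aa = NONSTANDARD_PARENT[resname]
            if aa == "X":
                logger.warning("nonstandard residue %s at %s:%d kept as 'X'",
                               resname, chain_id, resseq)
        atoms = [(atom.element or atom.get_name()[0],
                  *map(float, atom.coord))
                 for atom in res.get_atoms()
                 if (atom.element or atom.get_name()[0]).upper() not in ("H", "D")]
        if atoms:
            out.append(ResidueAtomSet(chain_id, int(resseq), aa, atoms))
    return out


def parse_complex(structure_file, hla_chain_id: str, peptide_chain_id: str,
                  locus: str = "A",
                  allow_any_peptide_length: bool = False) -> ComplexStructure:
    """Parse one peptide-HLA complex from a PDB file.

    Only model 1 is read; waters and unmapped hetero groups are dropped;
    hydrogens are excluded.  Raises :class:`ChainNotFoundError` naming the
    available chains when a requested chain is absent, and
    :class:`PeptideLengthError` when the peptide chain is not a 9-mer
    (override with ``allow_any_peptide_length``).
    """
    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure("complex",
                                                        str(structure_file))
    model = next(iter(structure))  # model 1 only
    chains = {c.id: c for c in model}
    for cid in (hla_chain_id, peptide_chain_id):
        if cid not in chains:
            raise ChainNotFoundError(
                f"chain {cid!r} not found; available chains: "
                f"{sorted(chains)}")
    hla = _residues_from_chain(chains[hla_chain_id], hla_chain_id)
    pep = _residues_from_chain(chains[peptide_chain_id], peptide_chain_id)
    if len(pep) != PEPTIDE_LENGTH and not allow_any_peptide_length:
        raise PeptideLengthError(
            f"peptide chain {peptide_chain_id!r} has {len(pep)} residues, "
            f"expected {PEPTIDE_LENGTH}")
    return ComplexStructure(complex_id=str(structure_file),
                            hla_chain=hla, peptide_chain=pep, locus=locus)


# ---------------------------------------------------------------------------
# contact detection

def find_contacts(complex_: ComplexStructure,
                  cutoff: float = 4.0) -> set[tuple[int, int]]:
    """Interacting (HLA residue index, peptide position) pairs.

    A pair interacts when the minimum heavy-atom distance is strictly
    below ``cutoff``.  Peptide position is the 1-based rank of the residue
    in the peptide chain (not its author number).
    """
    if not complex_.hla_chain or not complex_.peptide_chain:
        raise ValueError("complex has an empty chain")
    pep_coords = [r.coords for r in complex_.peptide_chain]
    contacts = set()
    for hres in complex_.hla_chain:
        hc = hres.coords
        for pos, pc in enumerate(pep_coords, start=1):
            d2 = np.sum((hc[:, None, :] - pc[None, :, :]) ** 2, axis=-1)
            if d2.min() < cutoff ** 2:
                contacts.add((hres.residue_index, pos))
    return contacts


def aggregate_contacts(complexes: Iterable[ComplexStructure],
                       cutoff: float = 4.0, min_count: int = 5,
                       filter_level: str = "cell") -> ContactGrid:
    """Count contact cells over complexes and filter rare ones.

    ``filter_level="cell"`` (default) discards individual grid cells seen
    in fewer than ``min_count`` complexes; ``"residue"`` discards whole
    HLA residues whose contact occurrences (complexes in which the residue
    touches the peptide anywhere) fall below ``min_count``.
    """
    complexes = list(complexes)
    if not complexes:
        raise ValueError("no complexes given")
    loci = {c.locus for c in complexes}
    if len(loci) != 1:
        raise ValueError(f"complexes mix loci {sorted(loci)}; aggregate one "
                         "locus at a time")
    if filter_level not in ("cell", "residue"):
        raise ValueError(f"unknown filter_level {filter_level!r}")

    cell_counts: dict[tuple[int, int], int] = {}
    residue_counts: dict[int, int] = {}
    for cx in complexes:
        cset = find_contacts(cx, cutoff=cutoff)
        for cell in cset:
            cell_counts[cell] = cell_counts.get(cell, 0) + 1
        for h in {h for h, _ in cset}:
            residue_counts[h] = residue_counts.get(h, 0) + 1

    if filter_level == "cell":
        kept = {c: n for c, n in cell_counts.items() if n >= min_count}
    else:
        ok = {h for h, n in residue_counts.items() if n >= min_count}
        kept = {(h, p): n for (h, p), n in cell_counts.items() if h in ok}
    return ContactGrid(locus=loci.pop(), cells=kept,
                       n_complexes=len(complexes), min_count=min_count,
                       cutoff_angstrom=cutoff)
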