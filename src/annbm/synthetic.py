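"""Synthetic fixtures: toy complex structures and motif-driven binding data.

Two generators make the whole pipeline testable without any downloads.

``gen_toy_complex`` builds a miniature peptide-HLA complex with contact
pairs planted at controlled distances: the 9 peptide residues sit on a
line 12 A apart, each planted HLA residue is dropped at its target
minimum heavy-atom distance from the paired peptide residue, and all
other HLA residues are parked far (> 8 A) from every peptide atom.  The
complexes serialize to PDB text and round-trip through the parser.

``gen_binding_data`` draws random 9-mers and assigns log-IC50 values from
a linear model in exactly the feature families the encoder uses —
per-position peptide motif weights plus a coupling term summing the
contact energies B(allele residue, peptide residue) over the grid cells —
plus Gaussian noise, clipped to [1, 50000] nM.  Alleles generated
together share a supertype: correlated motif weights and sequences
differing at a few contact positions, so leave-one-allele-out is
learnable by design.  This linearity is deliberate: recovery failures
then indicate pipeline defects, not model mismatch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contacts import ComplexStructure, ContactGrid, ResidueAtomSet
from .encoding import AlleleSequence, transform_affinity
from .matrices import AA_INDEX, AA_ORDER, load_b_matrix

PEPTIDE_SPACING = 12.0  # A between consecutive toy peptide residues


# ---------------------------------------------------------------------------
# toy complexes

@dataclass
class ToyComplexSpec:
    """Blueprint for one synthetic complex.

    ``planted``: (hla_residue_index, peptide_position 1-9, target min
    distance in A) triples; each HLA residue index may appear once.
    ``jitter_sd`` perturbs the achieved distance (Gaussian, A).
    """

    n_hla_residues: int = 10
    planted: list[tuple[int, int, float]] = field(default_factory=list)
    jitter_sd: float = 0.0
    seed: int = 0
    locus: str = "A"

    def __post_init__(self) -> None:
        idxs = [h for h, _, _ in self.planted]
        if len(idxs) != len(set(idxs)):
            raise ValueError("infeasible geometry: an HLA residue cannot be "
                             "planted at two peptide positions")
        for h, p, d in self.planted:
            if d <= 0:
                raise ValueError(f"target distance must be positive, got {d}")
            if not 1 <= p <= 9:
                raise ValueError(f"peptide position {p} outside 1..9")


def _residue(chain_id: str, index: int, aa: str, base: np.ndarray,
             away: np.ndarray) -> ResidueAtomSet:
    # CA at `base`; CB/CG stacked 1.5 A apart on the `away` side so the
    # CA-CA pair always realises the residue pair's minimum distance.
    atoms = [("C", *map(float, base + k * 1.5 * away)) for k in range(3)]
    return ResidueAtomSet(chain_id=chain_id, residue_index=index,
                          amino_acid=aa, atoms=atoms)


def gen_toy_complex(spec: ToyComplexSpec, hla_chain_id: str = "A",
                    peptide_chain_id: str = "C") -> ComplexStructure:
    """Deterministic toy complex realising the planted contact distances."""
    rng = np.random.default_rng(spec.seed)
    pep_aas = rng.choice(list(AA_ORDER), size=9)
    peptide = [_residue(peptide_chain_id, p,
                        pep_aas[p - 1],
                        np.array([PEPTIDE_SPACING * (p - 1), 0.0, 0.0]),
                        np.array([0.0, -1.0, 0.0]))
               for p in range(1, 10)]

    planted_idx = {h for h, _, _ in spec.planted}
    n_extra = spec.n_hla_residues - len(planted_idx)
    if n_extra < 0:
        raise ValueError("more planted pairs than HLA residues")
    hla_aas = rng.choice(list(AA_ORDER), size=spec.n_hla_residues)
    hla: list[ResidueAtomSet] = []
    used = sorted(planted_idx)
    for k, (h, p, d) in enumerate(sorted(spec.planted)):
        dist = d + (rng.normal(0.0, spec.jitter_sd) if spec.jitter_sd else 0.0)
        dist = max(dist, 0.1)
        base = np.array([PEPTIDE_SPACING * (p - 1), dist, 0.0])
        hla.append(_residue(hla_chain_id, h, hla_aas[k],
                            base, np.array([0.0, 1.0, 0.0])))
    # spectators parked far below the peptide line
    spare = [i for i in range(1, spec.n_hla_residues + len(used) + 1)
             if i not in planted_idx][:n_extra]
    for j, idx in enumerate(spare):
        base = np.array([10.0 * j, -30.0, 15.0])
        hla.append(_residue(hla_chain_id, idx, hla_aas[len(used) + j],
                            base, np.array([0.0, -1.0, 0.0])))
    hla.sort(key=lambda r: r.residue_index)
    return ComplexStructure(complex_id=f"toy-{spec.seed}", hla_chain=hla,
                            peptide_chain=peptide, locus=spec.locus)


_AA_3LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}
_ATOM_NAMES = ["CA", "CB", "CG", "CD", "CE"]


def write_pdb(complex_: ComplexStructure, path) -> None:
    """Write the complex as minimal PDB ATOM records (deterministic)."""
    serial = 0
    lines = []
    for chain in (complex_.hla_chain, complex_.peptide_chain):
        for res in chain:
            resname = _AA_3LETTER.get(res.amino_acid, "UNK")
            for a_i, (elem, x, y, z) in enumerate(res.atoms):
                serial += 1
                name = _ATOM_NAMES[a_i % len(_ATOM_NAMES)]
                lines.append(
                    f"ATOM  {serial:5d}  {name:<3s}{resname:>4s} "
                    f"{res.chain_id}{res.residue_index:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                    f"          {elem:>2s}")
        lines.append("TER")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# motif-driven binding data

@dataclass
class MotifModel:
    """Per-position peptide preference of one allele on the log-IC50 scale.

    ``weights[p-1, AA_INDEX[aa]]`` is added to log-IC50 when ``aa`` sits
    at peptide position ``p``; negative weights favour binding.
    """

    allele_name: str
    weights: np.ndarray  # (9, 20)
    noise_sd: float = 0.3

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (9, 20):
            raise ValueError("motif weights must be 9x20")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("motif weights must be finite")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def make_supertype_motifs(allele_names: list[str], seed: int = 0,
                          anchor_positions: tuple[int, ...] = (2, 9),
                          anchor_sd: float = 1.5, other_sd: float = 0.3,
                          within_jitter: float = 0.2,
                          noise_sd: float = 0.3) -> list[MotifModel]:
    """Correlated motifs for alleles of one synthetic supertype: a shared
    base motif (strong weights at anchor positions) plus small per-allele
    jitter."""
    rng = np.random.default_rng(seed)
    sds = np.array([anchor_sd if p in anchor_positions else other_sd
                    for p in range(1, 10)])
    base = rng.normal(0.0, 1.0, (9, 20)) * sds[:, None]
    return [MotifModel(allele_name=name,
                       weights=base + rng.normal(0.0, within_jitter, (9, 20)),
                       noise_sd=noise_sd)
            for name in allele_names]


def make_allele_sequences(allele_names: list[str], grid: ContactGrid,
                          seed: int = 0, n_mutations: int = 6
                          ) -> dict[str, AlleleSequence]:
    """Synthetic heavy-chain sequences covering all grid positions.

    Alleles share a random base sequence and differ by ``n_mutations``
    substitutions drawn among the grid's contact positions, mimicking the
    sequence similarity of a supertype."""
    rng = np.random.default_rng(seed)
    length = max(grid.hla_indices())
    base = rng.choice(list(AA_ORDER), size=length)
    contact_pos = np.array(grid.hla_indices()) - 1
    out = {}
    for name in allele_names:
        seq = base.copy()
        mutate = rng.choice(contact_pos,
                            size=min(n_mutations, len(contact_pos)),
                            replace=False)
        for pos in mutate:
            seq[pos] = rng.choice(list(AA_ORDER))
        out[name] = AlleleSequence(allele_name=name, sequence="".join(seq),
                                   locus=grid.locus)
    return out


def _scaled_b() -> np.ndarray:
    b = load_b_matrix().values
    return 2.0 * (b - b.min()) / (b.max() - b.min()) - 1.0


def gen_binding_data(motifs: list[MotifModel],
                     alleles: dict[str, AlleleSequence],
                     grid: ContactGrid, n_per_allele: int = 300,
                     coupling: float = 0.2, seed: int = 0) -> pd.DataFrame:
    """Motif + contact-energy binding table.

    log IC50 = base + sum_p W(p, pep[p]) + coupling * sum_cells
    B(allele[h], pep[p]) + N(0, noise_sd), IC50 clipped to [1, 50000] nM.
    The coupling term uses the same min-max-scaled B matrix as the
    encoder, so the allele-specific signal is exactly representable by
    the contact features; it is centred by its expectation over uniform
    random peptides so the base level stays mid-range (balanced binder /
    non-binder classes) at any coupling strength.
    """
    rng = np.random.default_rng(seed)
    b = _scaled_b()
    cells = grid.sorted_cells()
    base_level = math.log(50000.0) / 2.0
    rows = []
    for motif in motifs:
        allele = alleles[motif.allele_name]
        h_idx = np.array([AA_INDEX[allele.residue(h)] for h, _ in cells])
        cell_pos = np.array([p - 1 for _, p in cells])
        contact_offset = float(b[h_idx].mean(axis=1).sum())
        for _ in range(n_per_allele):
            pep = rng.choice(20, size=9)
            y = base_level + float(motif.weights[np.arange(9), pep].sum())
            if coupling:
                y += coupling * (float(b[h_idx, pep[cell_pos]].sum())
                                 - contact_offset)
            if motif.noise_sd:
                y += rng.normal(0.0, motif.noise_sd)
            ic50 = float(np.clip(math.exp(y), 1.0, 50000.0))
            rows.append({"peptide": "".join(AA_ORDER[a] for a in pep),
                         "allele": motif.allele_name, "ic50_nM": ic50})
    df = pd.DataFrame(rows)
    df["affinity"] = [transform_affinity(x) for x in df["ic50_nM"]]
    df["binder"] = df["ic50_nM"] < 500.0
    return df


def supertype_preset(n_alleles: int = 5, n_per_allele: int = 300,
                     noise_sd: float = 0.3, coupling: float = 0.2,
                     seed: int = 0, grid: ContactGrid | None = None,
                     supertype: str = "A2"):
    """One synthetic supertype ready for leave-one-allele-out experiments.

    Returns ``(binding_df, alleles, supertype_map)``.
    """
    from .contacts import load_default_grid
    from .evaluation import SupertypeMap

    if grid is None:
        grid = load_default_grid("A")
    names = [f"{grid.locus}*SYN{k:02d}" for k in range(1, n_alleles + 1)]
    motifs = make_supertype_motifs(names, seed=seed, noise_sd=noise_sd)
    alleles = make_allele_sequences(names, grid, seed=seed + 1)
    df = gen_binding_data(motifs, alleles, grid,
                          n_per_allele=n_per_allele, coupling=coupling,
                          seed=seed + 2)
    return df, alleles, SupertypeMap({n: supertype for n in names})
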