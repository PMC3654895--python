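"""Feature encoding for (9-mer peptide, HLA allele) pairs and the IC50
affinity transform.

The network consumes a fixed-layout feature vector: a peptide block of
9 x 20 = 180 BLOSUM row entries, followed by one contact-energy value per
retained contact-grid cell (h, p) in sorted order, namely
``B(allele_residue_h, peptide_residue_p)``.  With the default grids this
gives 180 + 59 = 239 inputs for HLA-A pairs and 180 + 75 = 255 for HLA-B.
Because only grid positions of the allele sequence enter the encoding,
the model is pan-allele: any allele with a sequence is encodable.

Measured IC50 (nM) maps to the training target via

    affinity = 1 - log(IC50) / log(50000)

so 1 nM -> 1.0 and 50 000 nM -> 0.0; values outside [1, 50000] nM are
clipped into [0, 1] with a warning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contacts import ContactGrid
from .matrices import (AA_ORDER, ContactEnergyMatrix, SubstitutionMatrix,
                       load_b_matrix, load_blosum)

logger = logging.getLogger(__name__)

IC50_MAX_NM = 50000.0
_LOG_MAX = math.log(IC50_MAX_NM)


# ---------------------------------------------------------------------------
# affinity transform

def transform_affinity(ic50_nM: float) -> float:
    """1 - log(IC50)/log(50000), clipped to [0, 1]."""
    if ic50_nM <= 0:
        raise ValueError(f"IC50 must be positive, got {ic50_nM}")
    a = 1.0 - math.log(ic50_nM) / _LOG_MAX
    if not 0.0 <= a <= 1.0:
        logger.warning("IC50 %.4g nM outside [1, 50000]; affinity clipped",
                       ic50_nM)
        a = min(1.0, max(0.0, a))
    return a


def inverse_transform(affinity: float) -> float:
    """Affinity back to IC50 in nM: 50000**(1 - affinity)."""
    if not 0.0 <= affinity <= 1.0:
        raise ValueError(f"affinity must be in [0, 1], got {affinity}")
    return IC50_MAX_NM ** (1.0 - affinity)


# ---------------------------------------------------------------------------
# domain records

@dataclass(frozen=True)
class AlleleSequence:
    """Mature-protein HLA heavy-chain sequence, 1-based indexing."""

    allele_name: str
    sequence: str
    locus: str = ""

    def __post_init__(self) -> None:
        if not self.locus:
            object.__setattr__(self, "locus", self.allele_name[:1])

    def residue(self, index: int) -> str:
        """Amino acid at 1-based position ``index``."""
        if not 1 <= index <= len(self.sequence):
            raise IndexError(
                f"allele {self.allele_name} sequence (length "
                f"{len(self.sequence)}) does not cover residue {index}")
        return self.sequence[index - 1]


@dataclass(frozen=True)
class BindingRecord:
    peptide: str
    allele_name: str
    ic50_nM: float
    affinity: float = field(init=False)
    binder: bool = field(init=False)

    def __post_init__(self) -> None:
        if len(self.peptide) != 9:
            raise ValueError(f"peptide {self.peptide!r} is not a 9-mer")
        object.__setattr__(self, "affinity", transform_affinity(self.ic50_nM))
        object.__setattr__(self, "binder", self.ic50_nM < 500.0)


# ---------------------------------------------------------------------------
# file I/O

def read_alleles_fasta(path) -> dict[str, AlleleSequence]:
    """FASTA of allele heavy-chain sequences; record id = allele name."""
    from Bio import SeqIO

    alleles = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        alleles[rec.id] = AlleleSequence(allele_name=rec.id,
                                         sequence=str(rec.seq).upper())
    if not alleles:
        raise ValueError(f"no FASTA records in {path}")
    return alleles


def write_alleles_fasta(alleles: dict[str, AlleleSequence], path) -> None:
    with open(path, "w") as fh:
        for a in alleles.values():
            fh.write(f">{a.allele_name}\n{a.sequence}\n")


def read_binding_tsv(path) -> pd.DataFrame:
    """Binding table TSV with columns peptide, allele, ic50_nM (header
    required); adds derived ``affinity`` and ``binder`` columns."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"peptide", "allele", "ic50_nM"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: binding TSV needs columns {sorted(required)},"
                         f" found {list(df.columns)}")
    bad = df.index[df["peptide"].str.len() != 9]
    if len(bad):
        raise ValueError(f"{path}: non-9-mer peptides at rows {list(bad[:5])}")
    df["affinity"] = [transform_affinity(x) for x in df["ic50_nM"]]
    df["binder"] = df["ic50_nM"] < 500.0
    return df


def write_binding_tsv(df: pd.DataFrame, path, provenance: dict | None = None
                      ) -> None:
    with open(path, "w") as fh:
        if provenance:
            fh.write("# annbm " + " ".join(f"{k}={v}" for k, v in
                                           sorted(provenance.items())) + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# encoder

@dataclass
class PairEncoder:
    """Encode (peptide, allele) pairs against a fixed contact grid.

    Parameters
    ----------
    grid:
        Retained contact cells; determines the contact-block layout.
    blosum, b_matrix:
        Score matrices (defaults: BLOSUM62 and the bundled threonine-
        referenced contact-energy matrix).
    blosum_scale:
        Multiplier applied to raw BLOSUM integers (default 0.1), keeping
        sigmoid inputs in a trainable range.
    b_scaling:
        "minmax" (default) maps contact energies linearly onto [-1, 1]
        using the matrix extremes; "none" passes raw energies.
    contact_mode:
        "cell" (default) emits B(allele residue, peptide residue) per grid
        cell; "row_mean" substitutes the allele residue's mean contact
        energy, ignoring the paired peptide residue.
    """

    grid: ContactGrid
    blosum: SubstitutionMatrix = None
    b_matrix: ContactEnergyMatrix = None
    blosum_scale: float = 0.1
    b_scaling: str = "minmax"
    contact_mode: str = "cell"

    def __post_init__(self) -> None:
        if self.blosum is None:
            self.blosum = load_blosum("BLOSUM62")
        if self.b_matrix is None:
            self.b_matrix = load_b_matrix()
        if self.b_scaling not in ("minmax", "none"):
            raise ValueError(f"unknown b_scaling {self.b_scaling!r}")
        if self.contact_mode not in ("cell", "row_mean"):
            raise ValueError(f"unknown contact_mode {self.contact_mode!r}")
        self._cells = self.grid.sorted_cells()
        v = self.b_matrix.values
        if self.b_scaling == "minmax":
            lo, hi = v.min(), v.max()
            self._b_scaled = 2.0 * (v - lo) / (hi - lo) - 1.0
        else:
            self._b_scaled = v

    @property
    def n_features(self) -> int:
        return 180 + len(self._cells)

    def encode_peptide(self, peptide: str) -> np.ndarray:
        """180-dim peptide block: scaled BLOSUM row per position."""
        if len(peptide) != 9:
            raise ValueError(f"peptide {peptide!r} is not a 9-mer")
        blocks = []
        for pos, aa in enumerate(peptide, start=1):
            if aa not in AA_ORDER:
                raise ValueError(
                    f"nonstandard residue {aa!r} at peptide position {pos}")
            blocks.append(self.blosum.row(aa) * self.blosum_scale)
        return np.concatenate(blocks)

    def encode_contact_energy(self, peptide: str,
                              allele: AlleleSequence) -> np.ndarray:
        """One contact-energy value per retained grid cell, sorted order."""
        if len(peptide) != 9:
            raise ValueError(f"peptide {peptide!r} is not a 9-mer")
        from .matrices import AA_INDEX

        out = np.empty(len(self._cells))
        for k, (h, p) in enumerate(self._cells):
            h_aa = allele.residue(h)
            if h_aa not in AA_INDEX:
                raise ValueError(f"allele {allele.allele_name} has "
                                 f"nonstandard residue {h_aa!r} at {h}")
            p_aa = peptide[p - 1]
            if p_aa not in AA_INDEX:
                raise ValueError(
                    f"nonstandard residue {p_aa!r} at peptide position {p}")
            if self.contact_mode == "cell":
                out[k] = self._b_scaled[AA_INDEX[h_aa], AA_INDEX[p_aa]]
            else:
                out[k] = self._b_scaled[AA_INDEX[h_aa]].mean()
        return out

    def encode_pair(self, peptide: str, allele: AlleleSequence) -> np.ndarray:
        """Full feature vector: peptide block then contact block."""
        return np.concatenate([self.encode_peptide(peptide),
                               self.encode_contact_energy(peptide, allele)])

    def encode_frame(self, df: pd.DataFrame,
                     alleles: dict[str, AlleleSequence]) -> np.ndarray:
        """Feature matrix for a binding table (rows in order)."""
        rows = []
        for pep, al in zip(df["peptide"], df["allele"]):
            if al not in alleles:
                raise KeyError(f"allele {al!r} missing from FASTA")
            rows.append(self.encode_pair(pep, alleles[al]))
        return np.array(rows)

    def config_dict(self) -> dict:
        return {
            "blosum": self.blosum.name,
            "b_matrix": self.b_matrix.name,
            "blosum_scale": self.blosum_scale,
            "b_scaling": self.b_scaling,
            "contact_mode": self.contact_mode,
            "n_features": self.n_features,
        }
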