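"""Amino-acid scoring matrices: BLOSUM substitution scores and residue
contact energies.

Two 20x20 symmetric matrices drive the feature encoding:

* a BLOSUM substitution matrix (default BLOSUM62) encoding each peptide
  residue by its 20-entry score row, and
* a contact-energy matrix ("B matrix") derived from a Miyazawa-Jernigan
  style inter-residue potential by re-referencing every pair energy to
  threonine, so that the energy of any residue paired with threonine is
  exactly zero.  The re-referencing removes the solvent reference state of
  the raw potential, which over-weights nonpolar interactions.

The bundled potential table (``data/mj_contact_energies.txt``) is a
transcription of the widely reproduced 20x20 contact-energy table; a user
matrix in the same plain-text grammar can be supplied by path.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

#: Fixed amino-acid column order used throughout the package.
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

#: Common nonstandard residue codes mapped to their parent amino acid.
NONSTANDARD_PARENT = {
    "MSE": "M",  # selenomethionine
    "SEC": "C",  # selenocysteine (one-letter U)
    "PYL": "K",
    "SEP": "S",
    "TPO": "T",
    "PTR": "Y",
    "CSO": "C",
    "HYP": "P",
    "MLY": "K",
}


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Symmetric 20x20 residue-pair score matrix in :data:`AA_ORDER`."""

    name: str
    values: np.ndarray  # (20, 20) float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (20, 20):
            raise ValueError(f"expected a 20x20 matrix, got {v.shape}")
        if not np.allclose(v, v.T):
            raise ValueError(f"matrix {self.name!r} is not symmetric")
        object.__setattr__(self, "values", v)

    def score(self, aa1: str, aa2: str) -> float:
        return float(self.values[AA_INDEX[aa1], AA_INDEX[aa2]])

    def row(self, aa: str) -> np.ndarray:
        """20-entry row for ``aa``, columns in :data:`AA_ORDER`."""
        return self.values[AA_INDEX[aa]]


class ContactEnergyMatrix(SubstitutionMatrix):
    """Residue-pair contact energies (dimensionless, threonine-referenced)."""


def parse_matrix_text(text: str, name: str = "custom") -> SubstitutionMatrix:
    """Parse the plain-text 20x20 matrix grammar.

    Grammar: ``#`` comment lines; a header line of 20 one-letter codes; 20
    data lines ``<code> <20 floats>``.  Row/column order in the file is
    free; values are reindexed into :data:`AA_ORDER`.
    """
    lines = [ln.split() for ln in text.splitlines()
             if ln.strip() and not ln.lstrip().startswith("#")]
    header = lines[0]
    if len(header) != 20 or sorted(header) != sorted(AA_ORDER):
        raise ValueError("header must list the 20 standard one-letter codes")
    raw = np.zeros((20, 20))
    seen = set()
    for row in lines[1:]:
        aa, vals = row[0], row[1:]
        if len(vals) != 20:
            raise ValueError(f"row {aa!r} has {len(vals)} values, expected 20")
        seen.add(aa)
        for col_aa, v in zip(header, vals):
            raw[AA_INDEX[aa], AA_INDEX[col_aa]] = float(v)
    if seen != set(AA_ORDER):
        raise ValueError(f"missing rows for {set(AA_ORDER) - seen}")
    return SubstitutionMatrix(name=name, values=raw)


def load_matrix_file(path, name: str | None = None) -> SubstitutionMatrix:
    with open(path) as fh:
        return parse_matrix_text(fh.read(), name=name or str(path))


def load_blosum(name: str = "BLOSUM62") -> SubstitutionMatrix:
    """Load a named BLOSUM substitution matrix."""
    from Bio.Align import substitution_matrices

    m = substitution_matrices.load(name)
    values = np.array([[m[a, b] for b in AA_ORDER] for a in AA_ORDER],
                      dtype=float)
    return SubstitutionMatrix(name=name, values=values)


def threonine_referenced(raw: SubstitutionMatrix) -> ContactEnergyMatrix:
    """Re-reference a raw contact potential e(i,j) to threonine:

    ``B(i,j) = e(i,j) - e(i,T) - e(T,j) + e(T,T)``

    so B is symmetric and B(T, x) = 0 for every residue x.
    """
    e = raw.values
    t = AA_INDEX["T"]
    b = e - e[:, [t]] - e[[t], :] + e[t, t]
    return ContactEnergyMatrix(name="B matrix", values=b)


def load_b_matrix(path=None) -> ContactEnergyMatrix:
    """Load the contact-energy B matrix.

    Without ``path`` the bundled potential table is used; a custom raw
    potential file is threonine-referenced the same way.
    """
    if path is None:
        text = (resources.files("annbm.data") / "mj_contact_energies.txt"
                ).read_text()
        raw = parse_matrix_text(text, name="MJ contact energies")
    else:
        raw = load_matrix_file(path)
    return threonine_referenced(raw)
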