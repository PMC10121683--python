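"""BLOSUM50 substitution scores and amino-acid alphabet helpers.

The 20 standard residues are kept in the fixed order ``ACDEFGHIKLMNPQRSTVWY``;
all encodings and position-specific matrices in this package index residues in
that order.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Scale applied to BLOSUM scores before they enter the network input layer,
#: keeping encoded values roughly in [-1, 3].
BLOSUM_INPUT_SCALE = 5.0


def _load_blosum50() -> np.ndarray:
    full = substitution_matrices.load("BLOSUM50")
    mat = np.empty((20, 20), dtype=np.float64)
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            mat[i, j] = full[a, b]
    return mat


#: Raw BLOSUM50 scores restricted to the 20 standard residues (20x20, symmetric).
BLOSUM50: np.ndarray = _load_blosum50()

#: BLOSUM50 divided by BLOSUM_INPUT_SCALE; rows are the per-residue input encoding.
BLOSUM50_SCALED: np.ndarray = BLOSUM50 / BLOSUM_INPUT_SCALE


def seq_to_indices(seq: str) -> np.ndarray:
    """Map a peptide/pseudo-sequence to residue indices; raises on non-standard letters."""
    try:
        return np.fromiter((AA_INDEX[a] for a in seq), dtype=np.int64, count=len(seq))
    except KeyError as exc:
        raise ValueError(f"non-standard amino acid {exc.args[0]!r} in sequence {seq!r}") from None


def is_standard(seq: str) -> bool:
    return all(a in AA_INDEX for a in seq)
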