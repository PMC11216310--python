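"""Protein substitution scoring shared by the seeding and validation aligners.

The matrix is BLOSUM62 restricted to the 20 standard residues plus ``X``
(unknown) and ``*`` (stop).  ``X`` and ``*`` score 0 against everything,
including themselves: an unknown residue carries no evidence for or against
homology, and a stop is never treated as similar to anything.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

#: Residue alphabet used internally; index into :data:`SCORE`.
ALPHABET = "ARNDCQEGHILKMFPSTWYVX*"

_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

# Karlin-Altschul parameters for ungapped BLOSUM62 local alignment.
KA_LAMBDA = 0.3176
KA_K = 0.134
_LN2 = float(np.log(2.0))


def _build_score_matrix() -> np.ndarray:
    blosum = substitution_matrices.load("BLOSUM62")
    n = len(ALPHABET)
    mat = np.zeros((n, n), dtype=np.int32)
    for i, a in enumerate(ALPHABET[:20]):
        for j, b in enumerate(ALPHABET[:20]):
            mat[i, j] = int(blosum[a][b])
    # X and * rows/columns stay 0.
    return mat


#: 22x22 integer substitution matrix indexed by :data:`ALPHABET` positions.
SCORE = _build_score_matrix()


def encode(seq: str) -> np.ndarray:
    """Encode an amino-acid string as indices into :data:`SCORE`.

    Raises ``KeyError`` for residues outside the internal alphabet.
    """
    try:
        return np.fromiter((_INDEX[c] for c in seq), dtype=np.int64, count=len(seq))
    except KeyError as exc:
        raise KeyError(f"residue {exc.args[0]!r} not in scoring alphabet") from None


def pair_scores(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-position substitution scores of two equal-length encoded sequences."""
    return SCORE[a, b]


def bit_score(raw: float) -> float:
    """Normalized bit score of an ungapped raw BLOSUM62 alignment score."""
    return (KA_LAMBDA * raw - np.log(KA_K)) / _LN2
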