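"""Position weight matrices.

A PWM is a ``(w, 4)`` matrix of per-position probabilities over the bases
A, C, G, T (columns in that fixed order).  It is the unit of motif
discovery, comparison and scanning throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
#: complement of base code i is ``3 - i`` under the A,C,G,T encoding
COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.int64)

_COL_TOL = 1e-9


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as int codes (A=0, C=1, G=2, T=3, N/other=4)."""
    table = np.full(256, 4, dtype=np.int8)
    for b, i in BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].astype(np.int64)


def decode(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)


def reverse_complement(seq: str) -> str:
    comp = str.maketrans("ACGTNacgtn", "TGCANtgcan")
    return seq.translate(comp)[::-1]


@dataclass
class PWM:
    """Per-position nucleotide probability matrix.

    Parameters
    ----------
    matrix
        ``(w, 4)`` array; every row must sum to 1 (within 1e-9).
    motif_id
        Optional identifier carried through comparison and scanning.
    """

    matrix: np.ndarray
    motif_id: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must have shape (w, 4)")
        sums = self.matrix.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("PWM columns must each sum to 1")
        # renormalise away rounding noise so invariants hold to 1e-9
        self.matrix = self.matrix / sums[:, None]
        if np.any(self.matrix < 0):
            raise ValueError("PWM probabilities must be non-negative")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def from_counts(
        cls,
        counts: np.ndarray,
        pseudocount: float | np.ndarray = 0.0,
        motif_id: str = "",
    ) -> "PWM":
        """Build a PWM from a ``(w, 4)`` count matrix.

        ``pseudocount`` may be a scalar (added to every cell) or a length-4
        vector (e.g. background-proportional pseudocounts).
        """
        counts = np.asarray(counts, dtype=float)
        counts = counts + np.asarray(pseudocount, dtype=float)
        totals = counts.sum(axis=1, keepdims=True)
        if np.any(totals <= 0):
            raise ValueError("PWM count column does not sum to a positive total")
        return cls(counts / totals, motif_id=motif_id)

    def reverse_complement(self) -> "PWM":
        return PWM(self.matrix[::-1, ::-1].copy(), motif_id=self.motif_id)

    def log_matrix(self, floor: float = 1e-6) -> np.ndarray:
        return np.log(np.maximum(self.matrix, floor))

    def information_content(self) -> float:
        """Total information content in bits: sum over positions of
        ``2 + sum_b p log2 p``."""
        p = np.maximum(self.matrix, 1e-12)
        return float(np.sum(2.0 + np.sum(self.matrix * np.log2(p), axis=1)))

    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.matrix, axis=1))

    def sample_site(self, rng: np.random.Generator) -> str:
        """Draw one site string from the per-position distributions."""
        return "".join(
            BASES[rng.choice(4, p=row / row.sum())] for row in self.matrix
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PWM):
            return NotImplemented
        return self.width == other.width and np.allclose(
            self.matrix, other.matrix, atol=1e-12
        )
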