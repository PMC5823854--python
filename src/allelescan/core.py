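"""Shared domain types for allele-specific motif-disruption analysis.

Coordinate conventions used throughout the package:

* Intervals (BED-like) are 0-based, half-open ``[start, end)``.
* Variant positions are 1-based in tables and files (VCF-like) and are
  converted to 0-based indices only at the point of sequence indexing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Fixed column order of every PWM matrix in this package.
ALPHABET = "ACGT"

_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over the ACGTN alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def base_index(base: str) -> int:
    """Map a base to its column index in a PWM matrix (A=0..T=3)."""
    return _BASE_INDEX[base]


@dataclass(frozen=True)
class GenomeSeq:
    """A named contig sequence over the alphabet {A, C, G, T, N}."""

    contig_name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for contig {self.contig_name!r}")
        if set(self.sequence) - set("ACGTN"):
            bad = sorted(set(self.sequence) - set("ACGTN"))
            raise ValueError(f"non-ACGTN characters in {self.contig_name!r}: {bad}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open genomic interval with an optional strand."""

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "Interval") -> bool:
        return (
            self.contig == other.contig
            and self.start <= other.start
            and other.end <= self.end
        )

    def contains_pos(self, pos0: int) -> bool:
        """Whether a 0-based position falls inside the interval."""
        return self.start <= pos0 < self.end

    def gap_to(self, other: "Interval") -> int:
        """Edge-to-edge distance in bp; 0 when the intervals overlap or abut."""
        if self.contig != other.contig:
            raise ValueError("intervals on different contigs have no distance")
        return max(0, max(self.start, other.start) - min(self.end, other.end))


@dataclass
class PWM:
    """Position weight matrix: per-position base probabilities.

    ``matrix`` has shape (length, 4) with columns ordered A, C, G, T;
    every position (row) sums to 1 after pseudocount regularization.
    Log-odds scores are taken base 2 against a uniform 0.25 background,
    so scores are in bits.
    """

    motif_id: str
    tf_name: str = ""
    family: str = ""
    matrix: np.ndarray = field(default_factory=lambda: np.full((4, 4), 0.25))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must have shape (length, 4)")
        if len(self.matrix) < 1:
            raise ValueError("PWM must have at least one position")
        if np.any(self.matrix <= 0):
            raise ValueError("PWM probabilities must be strictly positive "
                             "(apply a pseudocount first)")
        sums = self.matrix.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("PWM rows must sum to 1 after regularization")

    def __len__(self) -> int:
        return len(self.matrix)

    @property
    def log_odds(self) -> np.ndarray:
        """log2(p / 0.25) per position per base."""
        return np.log2(self.matrix / 0.25)

    def reverse_complement(self) -> "PWM":
        return PWM(
            motif_id=self.motif_id,
            tf_name=self.tf_name,
            family=self.family,
            matrix=self.matrix[::-1, ::-1].copy(),
        )

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=1))

    def information_content(self) -> np.ndarray:
        """Per-position information content in bits (2 + sum p log2 p)."""
        return 2.0 + (self.matrix * np.log2(self.matrix)).sum(axis=1)

    @classmethod
    def from_probabilities(
        cls,
        motif_id: str,
        matrix,
        tf_name: str = "",
        family: str = "",
        pseudocount: float = 1e-3,
    ) -> "PWM":
        """Build a PWM from raw probabilities, applying the standard
        pseudocount regularization (p + c) / (1 + 4c)."""
        m = np.asarray(matrix, dtype=float)
        m = (m + pseudocount) / (1.0 + 4.0 * pseudocount)
        m = m / m.sum(axis=1, keepdims=True)
        return cls(motif_id=motif_id, tf_name=tf_name, family=family, matrix=m)

    @classmethod
    def from_consensus(
        cls,
        motif_id: str,
        consensus: str,
        p_major: float = 0.97,
        tf_name: str = "",
        family: str = "",
    ) -> "PWM":
        """Near-deterministic PWM for a consensus string (IUPAC W/R/Y/S/K/M
        split their probability mass over the allowed bases)."""
        iupac = {
            "A": "A", "C": "C", "G": "G", "T": "T",
            "W": "AT", "R": "AG", "Y": "CT", "S": "CG", "K": "GT", "M": "AC",
            "N": "ACGT",
        }
        rows = []
        for ch in consensus.upper():
            allowed = iupac[ch]
            row = np.full(4, (1.0 - p_major) / (4 - len(allowed))
                          if len(allowed) < 4 else 0.25)
            for b in allowed:
                row[_BASE_INDEX[b]] = p_major / len(allowed)
            rows.append(row / row.sum())
        return cls.from_probabilities(motif_id, np.array(rows),
                                      tf_name=tf_name, family=family)


def encode_sequence(seq: str) -> np.ndarray:
    """Encode ACGTN as integers 0..3, with N (and anything else) as 4."""
    out = np.full(len(seq), 4, dtype=np.int8)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out
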