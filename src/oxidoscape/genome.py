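"""Reference-sequence container and small sequence utilities.

Coordinates are 0-based half-open everywhere inside the package; conversion
to/from 1-based formats (VCF, SAM) happens only at file boundaries.

Bases are encoded A=0, C=1, G=2, T=3; anything else (N, lower-case handled by
upper-casing first) encodes as 4 and is treated as unresolvable context.
"""

from __future__ import annotations

import numpy as np
import pyfaidx

BASES = "ACGT"
A, C, G, T = 0, 1, 2, 3
N_CODE = 4

_ENCODE = np.full(256, N_CODE, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_COMP_CODE = np.array([T, G, C, A, N_CODE], dtype=np.uint8)

#: the 64 trinucleotides in lexicographic (AAA..TTT) order
TRINUCLEOTIDES = [a + b + c for a in BASES for b in BASES for c in BASES]
TRINUC_INDEX = {t: i for i, t in enumerate(TRINUCLEOTIDES)}


def encode(seq: str) -> np.ndarray:
    """Encode a sequence string as a uint8 code array."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def complement(base: str) -> str:
    return _COMPLEMENT[base.upper()]


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))


class Genome:
    """A set of named contigs held in memory.

    Wraps plain uppercase strings plus cached numeric code arrays and
    per-position trinucleotide codes used by the profiling machinery.
    """

    def __init__(self, sequences: dict[str, str]):
        self._seqs = {name: s.upper() for name, s in sequences.items()}
        self._codes: dict[str, np.ndarray] = {}
        self._tricodes: dict[str, np.ndarray] = {}

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def to_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self._seqs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    @property
    def names(self) -> list[str]:
        return list(self._seqs)

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def __getitem__(self, name: str) -> str:
        return self._seqs[name]

    def length(self, name: str) -> int:
        return len(self._seqs[name])

    def codes(self, name: str) -> np.ndarray:
        if name not in self._codes:
            self._codes[name] = encode(self._seqs[name])
        return self._codes[name]

    def tricodes(self, name: str) -> np.ndarray:
        """Per-position top-strand trinucleotide code (center at the index).

        Positions whose 3-mer is incomplete (contig edges) or contains an
        ambiguous base carry code 64.
        """
        if name not in self._tricodes:
            c = self.codes(name).astype(np.int16)
            out = np.full(len(c), 64, dtype=np.int16)
            if len(c) >= 3:
                left, mid, right = c[:-2], c[1:-1], c[2:]
                ok = (left < 4) & (mid < 4) & (right < 4)
                vals = 16 * left + 4 * mid + right
                out[1:-1][ok] = vals[ok]
            self._tricodes[name] = out
        return self._tricodes[name]

    def base(self, name: str, pos: int) -> str:
        return self._seqs[name][pos]

    def fetch(self, name: str, start: int, end: int) -> str:
        """Slice [start, end); clipped at contig bounds."""
        return self._seqs[name][max(start, 0) : end]

    def trinucleotide(self, name: str, pos: int) -> str | None:
        """Top-strand trinucleotide centered at pos, or None at edges/N."""
        if pos < 1 or pos > len(self._seqs[name]) - 2:
            return None
        tri = self._seqs[name][pos - 1 : pos + 2]
        return tri if all(b in BASES for b in tri) else None

    def trinucleotide_counts(self) -> np.ndarray:
        """Genome-wide top-strand counts of the 64 trinucleotides."""
        counts = np.zeros(64, dtype=np.int64)
        for name in self.names:
            tc = self.tricodes(name)
            counts += np.bincount(tc[tc < 64], minlength=64)
        return counts
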