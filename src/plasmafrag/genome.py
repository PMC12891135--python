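"""Reference-sequence containers and k-mer encoding.

Sequences are plain upper-case strings over ``{A, C, G, T, N}``.  For the
vectorised feature extractors each chromosome is lazily encoded as a
``uint8`` array (A=0, C=1, G=2, T=3, N=4) from which sliding k-mer codes
in ``[0, 4**k)`` are derived; windows touching an ``N`` get code ``-1``.
"""

from __future__ import annotations

from collections.abc import Iterator, Mapping
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

ALPHABET = "ACGT"

_BYTE_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BYTE_TO_CODE[_b] = _i
    _BYTE_TO_CODE[_b + 32] = _i  # lower case
_BYTE_TO_CODE[ord("N")] = 4
_BYTE_TO_CODE[ord("n")] = 4

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeSequence:
    """One chromosome: a named sequence over {A,C,G,T,N}."""

    name: str
    sequence: str
    _codes: np.ndarray | None = field(default=None, repr=False, compare=False)
    _kmers: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) == 0:
            raise ValueError(f"chromosome {self.name!r} has empty sequence")
        codes = _BYTE_TO_CODE[np.frombuffer(self.sequence.encode("ascii"), dtype=np.uint8)]
        if (codes == 255).any():
            bad = self.sequence[int(np.argmax(codes == 255))]
            raise ValueError(f"chromosome {self.name!r}: invalid base {bad!r}")
        self._codes = codes

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def codes(self) -> np.ndarray:
        """uint8 base codes, A=0 C=1 G=2 T=3 N=4."""
        return self._codes

    def kmer_codes(self, k: int) -> np.ndarray:
        """Sliding k-mer codes at every start position (length L-k+1).

        Windows containing N are -1.  Cached per k.
        """
        if k not in self._kmers:
            self._kmers[k] = kmer_code_array(self._codes, k)
        return self._kmers[k]

    def gc_fraction(self, start: int = 0, end: int | None = None) -> float:
        """GC fraction of [start, end), ignoring N; nan if all N."""
        sub = self._codes[start:end]
        n_acgt = int((sub < 4).sum())
        if n_acgt == 0:
            return float("nan")
        gc = int(((sub == 1) | (sub == 2)).sum())
        return gc / n_acgt


class Genome(Mapping):
    """Ordered mapping of chromosome name -> :class:`GenomeSequence`."""

    def __init__(self, chroms) -> None:
        self._chroms: dict[str, GenomeSequence] = {}
        for c in chroms:
            if c.name in self._chroms:
                raise ValueError(f"duplicate chromosome name {c.name!r}")
            self._chroms[c.name] = c

    def __getitem__(self, name: str) -> GenomeSequence:
        return self._chroms[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._chroms)

    def __len__(self) -> int:
        return len(self._chroms)

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self._chroms.values())

    def reverse_complemented(self) -> "Genome":
        """A copy with every chromosome reverse complemented (test utility)."""
        return Genome(GenomeSequence(c.name, revcomp(c.sequence)) for c in self._chroms.values())


def kmer_code_array(codes: np.ndarray, k: int) -> np.ndarray:
    """Vector of k-mer codes for every window start; -1 where a window has N."""
    if k < 1:
        raise ValueError("k must be >= 1")
    L = len(codes)
    n = L - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    valid = codes < 4
    out = np.zeros(n, dtype=np.int64)
    ok = np.ones(n, dtype=bool)
    c64 = codes.astype(np.int64)
    for j in range(k):
        out = out * 4 + c64[j : j + n]
        ok &= valid[j : j + n]
    out[~ok] = -1
    return out


@lru_cache(maxsize=8)
def revcomp_code_table(k: int) -> np.ndarray:
    """Lookup table mapping each k-mer code to its reverse-complement code."""
    codes = np.arange(4**k, dtype=np.int64)
    rc = np.zeros_like(codes)
    tmp = codes.copy()
    for _ in range(k):
        rc = rc * 4 + (3 - (tmp % 4))
        tmp //= 4
    return rc


def motif_string(code: int, k: int) -> str:
    """Decode an integer k-mer code (big-endian base-4) to its string."""
    if code < 0:
        raise ValueError("negative motif code (window contained N)")
    out = []
    for _ in range(k):
        out.append(ALPHABET[code % 4])
        code //= 4
    return "".join(reversed(out))


def motif_code(motif: str) -> int:
    """Encode an A/C/G/T string to its integer code."""
    code = 0
    for ch in motif.upper():
        idx = ALPHABET.find(ch)
        if idx < 0:
            raise ValueError(f"invalid motif base {ch!r}")
        code = code * 4 + idx
    return code


@lru_cache(maxsize=8)
def all_motifs(k: int) -> tuple[str, ...]:
    """All 4**k motifs in code (lexicographic) order."""
    return tuple(motif_string(c, k) for c in range(4**k))
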