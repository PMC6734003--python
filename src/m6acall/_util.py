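"""Small shared helpers: alphabet handling, reverse complement, stable hashing."""

from __future__ import annotations

import zlib

import numpy as np

DNA = "ACGT"
COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def normalize_sequence(seq: str) -> str:
    """Uppercase and convert RNA (U) to DNA sense (T)."""
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def stable_hash(*parts) -> int:
    """Deterministic 31-bit hash of the string representation of ``parts``.

    Used to derive sub-seeds and per-k-mer factors that must be identical
    across runs, platforms and Python processes (unlike builtin ``hash``).
    """
    key = ":".join(str(p) for p in parts)
    return zlib.crc32(key.encode()) & 0x7FFFFFFF


def kmer_rng(kmer: str, salt: str) -> np.random.Generator:
    """A generator seeded deterministically by (kmer, salt)."""
    return np.random.default_rng(stable_hash(salt, kmer))
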