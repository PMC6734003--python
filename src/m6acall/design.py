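"""Design of k-mer-complete synthetic RNA sequences ("curlcakes").

Synthetic in vitro transcribed constructs used to profile modification
error signatures must present every possible 5-mer to the pore while
folding as little as possible, so that each k-mer's base-calling behaviour
can be measured in both the modified and the unmodified condition.

The generator builds a randomized Eulerian circuit on the (k-1)-mer
de Bruijn multigraph (each k-mer edge can be given a multiplicity, so a
single design can present each k-mer many times), scores a pool of
candidate superstrings with a reverse-complement stem-count penalty as a
fast proxy for secondary structure, keeps the least-structured candidate,
and splits it into a few synthesis-sized parts whose junctions duplicate
k-1 letters so that no k-mer is lost to a split.

With the default configuration (k=5, multiplicity 10, 4 parts) the design
totals ~10.3 kb, contains all 1024 5-mers with a median occurrence of 10,
and is split into four parts of near-equal length.
"""

from __future__ import annotations

from bisect import bisect_right
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import DNA, revcomp, stable_hash

#: refuse to enumerate k-mer spaces larger than this
MAX_KMER_SPACE = 4**10


@dataclass(frozen=True)
class DesignConfig:
    """Parameters of a curlcake-style design run.

    Attributes
    ----------
    k
        Motif length covered exhaustively (default 5).
    alphabet
        Ordered nucleotide letters; U is normalized to T upstream.
    n_parts
        Number of synthesis parts the superstring is split into.
    kmer_copies
        Multiplicity of each k-mer edge in the de Bruijn multigraph.  The
        default of 10 yields ~10 kb of sequence in which each 5-mer occurs
        10 times (median occurrence 10).
    part_length_tolerance
        Maximum allowed relative spread (max-min)/mean of part lengths.
    min_stem_len, min_loop_len
        Structure-penalty parameters: minimum perfect reverse-complement
        stem counted, and minimum unpaired loop separating the stem halves.
    n_candidates
        Number of candidate superstrings generated and scored per design.
    seed
        RNG seed; the whole design is a deterministic function of it.
    """

    k: int = 5
    alphabet: tuple[str, ...] = ("A", "C", "G", "T")
    n_parts: int = 4
    kmer_copies: int = 10
    part_length_tolerance: float = 0.10
    min_stem_len: int = 6
    min_loop_len: int = 3
    n_candidates: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.n_parts < 1:
            raise ValueError("n_parts must be >= 1")
        if self.min_stem_len < 2:
            raise ValueError("min_stem_len must be >= 2")
        if len(set(self.alphabet)) != 4:
            raise ValueError("alphabet must contain 4 distinct letters")
        if self.kmer_copies < 1:
            raise ValueError("kmer_copies must be >= 1")


@dataclass
class SequenceSet:
    """Named sequences plus the provenance of the design that produced them."""

    records: list[tuple[str, str]]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [n for n, _ in self.records]
        if len(set(names)) != len(names):
            raise ValueError("sequence names must be unique")
        if any(not s for _, s in self.records):
            raise ValueError("sequences must be non-empty")

    @property
    def sequences(self) -> list[str]:
        return [s for _, s in self.records]


def build_kmer_superstring(
    k: int,
    alphabet: Sequence[str] = DNA,
    seed: int = 0,
    copies: int = 1,
    max_kmer_space: int = MAX_KMER_SPACE,
) -> str:
    """Return a sequence containing every k-mer over ``alphabet``.

    The sequence is an Eulerian circuit of the (k-1)-mer de Bruijn
    multigraph in which every k-mer edge appears ``copies`` times, so each
    k-mer occurs exactly ``copies`` times as a sliding window.  Edge order
    is shuffled by the seeded RNG (randomized Hierholzer traversal), so
    different seeds give different superstrings and the same seed
    reproduces the output bit-identically.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    alphabet = tuple(alphabet)
    n_kmers = len(alphabet) ** k
    if n_kmers > max_kmer_space:
        raise ValueError(
            f"k={k} would enumerate {n_kmers} k-mers, above the cap of "
            f"{max_kmer_space}; raise max_kmer_space explicitly if intended"
        )
    rng = np.random.default_rng(seed)

    if k == 1:
        letters = list(alphabet) * copies
        order = rng.permutation(len(letters))
        return "".join(letters[i] for i in order)

    # adjacency: (k-1)-mer node -> shuffled successor list (multiplicities kept)
    nodes = [""]
    for _ in range(k - 1):
        nodes = [n + a for n in nodes for a in alphabet]
    adj: dict[str, list[str]] = {}
    for node in nodes:
        succ = [node[1:] + a for a in alphabet] * copies
        idx = rng.permutation(len(succ))
        adj[node] = [succ[i] for i in idx]

    # Hierholzer's algorithm; the full de Bruijn multigraph is connected and
    # every node has equal in/out degree, so an Eulerian circuit exists.
    start = alphabet[0] * (k - 1)
    stack = [start]
    circuit: list[str] = []
    while stack:
        v = stack[-1]
        if adj[v]:
            stack.append(adj[v].pop())
        else:
            circuit.append(stack.pop())
    circuit.reverse()
    return circuit[0] + "".join(node[-1] for node in circuit[1:])


def structure_penalty(
    sequence: str, min_stem_len: int = 6, min_loop_len: int = 3
) -> int:
    """Count potential self-complementary stems in ``sequence``.

    The score is the number of ordered position pairs (i, j) with
    j - i > min_loop_len + min_stem_len at which the ``min_stem_len``-long
    words starting at i and j are perfect reverse complements of each
    other, i.e. could base-pair as a hairpin stem with a loop of at least
    ``min_loop_len`` unpaired bases.  A cheap, deterministic proxy for a
    thermodynamic folding prediction: fewer pairable stems, less structure.
    """
    if min_stem_len < 2:
        raise ValueError("min_stem_len must be >= 2")
    if min_loop_len < 0:
        raise ValueError("min_loop_len must be >= 0")
    m = min_stem_len
    n = len(sequence)
    if n < 2 * m:
        return 0
    occ: dict[str, list[int]] = {}
    for j in range(n - m + 1):
        occ.setdefault(sequence[j : j + m], []).append(j)
    gap = min_loop_len + min_stem_len
    score = 0
    for i in range(n - m + 1):
        partners = occ.get(revcomp(sequence[i : i + m]))
        if partners:
            score += len(partners) - bisect_right(partners, i + gap)
    return score


def design_curlcakes(config: DesignConfig = DesignConfig()) -> SequenceSet:
    """Design a k-mer-complete sequence set split into synthesis parts.

    ``n_candidates`` superstrings are generated from seeds derived from
    ``config.seed``; the candidate with the lowest :func:`structure_penalty`
    wins (first generated wins ties).  The winner is cut into ``n_parts``
    contiguous parts; each non-final part is extended by k-1 letters past
    its cut point, so every k-mer of the superstring lies wholly inside at
    least one part.
    """
    best_seq = None
    best_penalty = None
    candidate_penalties = []
    for i in range(config.n_candidates):
        sub_seed = stable_hash("design-candidate", config.seed, i)
        cand = build_kmer_superstring(
            config.k, config.alphabet, seed=sub_seed, copies=config.kmer_copies
        )
        pen = structure_penalty(cand, config.min_stem_len, config.min_loop_len)
        candidate_penalties.append(pen)
        if best_penalty is None or pen < best_penalty:
            best_seq, best_penalty = cand, pen

    assert best_seq is not None
    parts = _split_superstring(best_seq, config.n_parts, config.k)
    lengths = [len(p) for p in parts]
    spread = (max(lengths) - min(lengths)) / (sum(lengths) / len(lengths))
    if spread > config.part_length_tolerance:
        raise ValueError(
            f"part length spread {spread:.3f} exceeds tolerance "
            f"{config.part_length_tolerance} (lengths {lengths}); "
            "increase part_length_tolerance or reduce n_parts"
        )
    records = [(f"curlcake_{i + 1}", p) for i, p in enumerate(parts)]
    provenance = {
        "config": config,
        "selected_penalty": best_penalty,
        "candidate_penalties": candidate_penalties,
        "superstring": best_seq,
    }
    return SequenceSet(records=records, provenance=provenance)


def _split_superstring(seq: str, n_parts: int, k: int) -> list[str]:
    """Cut ``seq`` into n contiguous parts, duplicating k-1 boundary letters.

    Cut points are placed so the *emitted* part lengths (including the k-1
    letters each non-final part duplicates past its cut) are as equal as
    possible.
    """
    n = len(seq)
    if n_parts > n:
        raise ValueError(f"cannot split length-{n} sequence into {n_parts} parts")
    total = n + (n_parts - 1) * (k - 1)  # sum of emitted part lengths
    bounds = [round(i * total / n_parts) for i in range(n_parts + 1)]
    cuts = [0]
    for i in range(n_parts - 1):
        emitted = bounds[i + 1] - bounds[i]
        cuts.append(min(cuts[-1] + emitted - (k - 1), n))
    cuts.append(n)
    parts = []
    for i in range(n_parts):
        end = cuts[i + 1] + (k - 1 if i < n_parts - 1 else 0)
        parts.append(seq[cuts[i] : min(end, n)])
    return parts


def kmer_occurrence_table(
    sequences: Sequence[str], k: int
) -> tuple[pd.DataFrame, dict]:
    """Sliding-window k-mer counts over a set of sequences.

    Returns a (kmer, count) table over the k-mers present, sorted by k-mer,
    and a summary dict with min/median/max occurrence over present k-mers
    and the count of distinct k-mers.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: Counter[str] = Counter()
    for seq in sequences:
        for i in range(len(seq) - k + 1):
            counts[seq[i : i + k]] += 1
    table = pd.DataFrame(
        sorted(counts.items()), columns=["kmer", "count"]
    )
    if len(table):
        summary = {
            "n_distinct": int(len(table)),
            "min": int(table["count"].min()),
            "median": float(table["count"].median()),
            "max": int(table["count"].max()),
        }
    else:
        summary = {"n_distinct": 0, "min": None, "median": None, "max": None}
    return table, summary
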