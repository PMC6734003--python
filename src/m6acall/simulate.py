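"""Simulation of nanopore direct-RNA alignments with modification signatures.

Base-callers trained on unmodified RNA systematically mis-handle modified
bases: at (and around) an m6A site, base quality drops and mismatch and
deletion frequencies rise, while insertions behave irreproducibly and the
pore current in 5-mer windows containing the modified base shifts.  This
module generates per-base alignment tables and per-window current ("event")
tables that reproduce those signatures with configurable effect sizes, so
that the whole feature-extraction / classification / site-calling pipeline
can be exercised and validated without any sequencing data.

Realism choices (see docs/methods.md for rationale and defaults):

* baseline error rates, base quality and current level all carry a
  deterministic k-mer-dependent component (hash-derived lognormal/normal
  factors), emulating pore k-mer current levels and base-caller context
  dependence;
* modification effect sizes are likewise k-mer-modulated, so replicates of
  the same condition share an error *pattern* across sites that a
  modification-free control does not;
* insertion rates have zero modification delta by default, making
  insertion frequency condition-independent (uninformative);
* the number of modified reads is deterministic, round(coverage*fraction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._util import DNA, kmer_rng, normalize_sequence, stable_hash

PERBASE_COLUMNS = ["read_id", "ref", "pos", "ref_base", "call", "qual", "ins"]
EVENT_COLUMNS = ["read_id", "ref", "window_start", "mean_pA", "sd_pA"]

QUAL_MIN, QUAL_MAX = 1, 40


@dataclass(frozen=True)
class ErrorModel:
    """Generative parameters for modified vs unmodified read behaviour.

    Probabilities are per base; quality in Phred units; currents in pA.
    ``*_delta`` values are added at modified positions of modified reads;
    ``neighbor_bleed`` applies the stated fractions of each delta at
    positions +/-1 and +/-2 from a modified base.  ``kmer_*_spread``
    parameters control deterministic k-mer-dependent variation of the
    baselines and of the modification effect sizes (0 disables them).
    """

    base_quality_mean: float = 12.0
    base_quality_sd: float = 3.0
    p_mismatch: float = 0.03
    p_deletion: float = 0.02
    p_insertion: float = 0.01
    quality_shift: float = -3.0
    mismatch_delta: float = 0.10
    deletion_delta: float = 0.05
    insertion_delta: float = 0.0
    substitution_profile: tuple[float, float, float] | None = None
    current_mean_baseline: float = 100.0
    current_sd: float = 2.0
    current_shift: float = 3.0
    neighbor_bleed: tuple[float, float] = (0.25, 0.1)
    kmer_current_spread: float = 8.0
    kmer_quality_spread: float = 1.0
    kmer_error_spread: float = 0.3
    kmer_delta_spread: float = 0.4

    def __post_init__(self) -> None:
        for name in ("p_mismatch", "p_deletion", "p_insertion"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {p}")
        if self.substitution_profile is not None:
            prof = np.asarray(self.substitution_profile, dtype=float)
            if prof.shape != (3,) or prof.min() < 0 or not math.isclose(prof.sum(), 1.0):
                raise ValueError("substitution_profile must be 3 probabilities summing to 1")


def _kmer_factor_arrays(seq: str, model: ErrorModel) -> dict[str, np.ndarray]:
    """Per-position deterministic k-mer factors (centred 5-mers).

    Lognormal multiplicative factors for error baselines and deltas, and
    additive normal offsets for quality and current level.  Positions too
    close to the reference ends to have a full 5-mer get neutral factors.
    """
    L = len(seq)
    out = {
        "q_off": np.zeros(L),
        "curr_off": np.zeros(L),
        "mis_mult": np.ones(L),
        "del_mult": np.ones(L),
        "mis_delta_mult": np.ones(L),
        "del_delta_mult": np.ones(L),
        "q_delta_mult": np.ones(L),
    }
    cache: dict[str, tuple] = {}
    for p in range(2, L - 2):
        kmer = seq[p - 2 : p + 3]
        if kmer not in cache:
            cache[kmer] = (
                kmer_rng(kmer, "qual").normal(0.0, 1.0),
                kmer_rng(kmer, "curr").normal(0.0, 1.0),
                kmer_rng(kmer, "mis").normal(0.0, 1.0),
                kmer_rng(kmer, "del").normal(0.0, 1.0),
                kmer_rng(kmer, "dmis").normal(0.0, 1.0),
                kmer_rng(kmer, "ddel").normal(0.0, 1.0),
                kmer_rng(kmer, "dq").normal(0.0, 1.0),
            )
        zq, zc, zm, zd, zdm, zdd, zdq = cache[kmer]
        out["q_off"][p] = model.kmer_quality_spread * zq
        out["curr_off"][p] = model.kmer_current_spread * zc
        out["mis_mult"][p] = math.exp(model.kmer_error_spread * zm)
        out["del_mult"][p] = math.exp(model.kmer_error_spread * zd)
        out["mis_delta_mult"][p] = math.exp(model.kmer_delta_spread * zdm)
        out["del_delta_mult"][p] = math.exp(model.kmer_delta_spread * zdd)
        out["q_delta_mult"][p] = math.exp(model.kmer_delta_spread * zdq)
    return out


def _mod_weight(L: int, modified_idx: np.ndarray, bleed: tuple[float, float]) -> np.ndarray:
    """Per-position fraction of the modification delta applied (<=1)."""
    w = np.zeros(L)
    for off, frac in ((0, 1.0), (1, bleed[0]), (-1, bleed[0]), (2, bleed[1]), (-2, bleed[1])):
        idx = modified_idx + off
        idx = idx[(idx >= 0) & (idx < L)]
        np.maximum.at(w, idx, frac)
    return w


def _empty_tables() -> tuple[pd.DataFrame, pd.DataFrame]:
    perbase = pd.DataFrame(
        {
            "read_id": pd.Series(dtype=str),
            "ref": pd.Series(dtype=str),
            "pos": pd.Series(dtype=np.int64),
            "ref_base": pd.Series(dtype=str),
            "call": pd.Series(dtype=str),
            "qual": pd.Series(dtype=float),
            "ins": pd.Series(dtype=str),
        }
    )
    events = pd.DataFrame(
        {
            "read_id": pd.Series(dtype=str),
            "ref": pd.Series(dtype=str),
            "window_start": pd.Series(dtype=np.int64),
            "mean_pA": pd.Series(dtype=float),
            "sd_pA": pd.Series(dtype=float),
        }
    )
    return perbase, events


def simulate_reads(
    reference: str,
    coverage: int,
    modified_positions: Iterable[int] = (),
    mod_fraction: float = 0.0,
    model: ErrorModel = ErrorModel(),
    seed: int = 0,
    ref_name: str = "ref",
    read_prefix: str = "read",
    emit_events: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate ``coverage`` full-length reads over ``reference``.

    Exactly ``round(coverage * mod_fraction)`` reads (chosen by the seeded
    RNG) carry the modified error model at ``modified_positions`` (1-based,
    must be A).  Returns the per-base alignment table and the per-window
    event table (empty when ``emit_events`` is false).  Output is a
    deterministic function of the arguments.
    """
    seq = normalize_sequence(reference)
    L = len(seq)
    mod_pos = np.asarray(sorted(set(modified_positions)), dtype=int)
    if mod_pos.size:
        if mod_pos.min() < 1 or mod_pos.max() > L:
            raise ValueError("modified positions must lie within the reference")
        bad = [int(p) for p in mod_pos if seq[p - 1] != "A"]
        if bad:
            raise ValueError(
                f"modified positions must be A (m6A replaces adenine only): {bad}"
            )
    if not 0.0 <= mod_fraction <= 1.0:
        raise ValueError("mod_fraction must be in [0,1]")
    if coverage < 0:
        raise ValueError("coverage must be >= 0")
    if coverage == 0 or L == 0:
        return _empty_tables()

    rng = np.random.default_rng(seed)
    N = coverage
    n_mod = round(N * mod_fraction)
    mod_reads = np.zeros(N, dtype=bool)
    mod_reads[rng.choice(N, size=n_mod, replace=False)] = True

    factors = _kmer_factor_arrays(seq, model)
    w = _mod_weight(L, mod_pos - 1, model.neighbor_bleed)

    # per-(read,pos) probabilities; modified rows add the (bled) deltas
    mod_col = mod_reads[:, None].astype(float)
    p_del = np.clip(
        model.p_deletion * factors["del_mult"][None, :]
        + mod_col * w[None, :] * model.deletion_delta * factors["del_delta_mult"][None, :],
        0.0,
        1.0,
    )
    p_mis = np.clip(
        model.p_mismatch * factors["mis_mult"][None, :]
        + mod_col * w[None, :] * model.mismatch_delta * factors["mis_delta_mult"][None, :],
        0.0,
        1.0,
    )
    p_mis = np.minimum(p_mis, 1.0 - p_del)  # mutually exclusive outcomes
    p_ins = np.clip(
        model.p_insertion + mod_col * w[None, :] * model.insertion_delta, 0.0, 1.0
    )
    q_mean = (
        model.base_quality_mean
        + factors["q_off"][None, :]
        + mod_col * w[None, :] * model.quality_shift * factors["q_delta_mult"][None, :]
    )

    # one uniform draw splits {deletion, mismatch, match} exactly
    u = rng.random((N, L))
    del_mask = u < p_del
    mis_mask = ~del_mask & (u < p_del + p_mis)

    ref_idx = np.frombuffer(seq.encode(), dtype=np.uint8)
    ref_idx = np.searchsorted(np.frombuffer(b"ACGT", dtype=np.uint8), ref_idx)
    letters = np.array(list(DNA))
    # the 3 alternatives to each reference base, in alphabetical order
    alt = np.array([[j for j in range(4) if j != i] for i in range(4)])

    # dtype wide enough for the "DEL" marker, not just single letters
    calls = np.broadcast_to(letters[ref_idx], (N, L)).astype("<U3")
    n_mis = int(mis_mask.sum())
    if n_mis:
        if model.substitution_profile is None:
            which = rng.integers(0, 3, size=n_mis)
        else:
            which = rng.choice(3, size=n_mis, p=model.substitution_profile)
        calls[mis_mask] = letters[alt[np.broadcast_to(ref_idx, (N, L))[mis_mask], which]]
    calls[del_mask] = "DEL"

    quals = np.rint(rng.normal(q_mean, model.base_quality_sd)).clip(QUAL_MIN, QUAL_MAX)
    quals = quals.astype(float)
    quals[del_mask] = np.nan

    ins_mask = rng.random((N, L)) < p_ins
    ins = np.full((N, L), "", dtype=object)
    n_ins = int(ins_mask.sum())
    if n_ins:
        ins[ins_mask] = letters[rng.integers(0, 4, size=n_ins)]

    read_ids = np.array([f"{read_prefix}{i}" for i in range(N)], dtype=object)
    perbase = pd.DataFrame(
        {
            "read_id": np.repeat(read_ids, L),
            "ref": ref_name,
            "pos": np.tile(np.arange(1, L + 1), N),
            "ref_base": np.tile(letters[ref_idx], N),
            "call": calls.ravel(),
            "qual": quals.ravel(),
            "ins": ins.ravel(),
        }
    )

    if emit_events and L >= 5:
        W = L - 4
        # does window [s, s+4] of a modified read cover a modified position?
        mod_ind = np.zeros(L)
        if mod_pos.size:
            mod_ind[mod_pos - 1] = 1.0
        win_has_mod = (
            np.convolve(mod_ind, np.ones(5), mode="valid") > 0
        ).astype(float)
        mu = (
            model.current_mean_baseline
            + factors["curr_off"][2 : L - 2][None, :]
            + mod_col * win_has_mod[None, :] * model.current_shift
        )
        means = rng.normal(mu, model.current_sd)
        sds = np.abs(rng.normal(model.current_sd, model.current_sd / 5, size=(N, W)))
        events = pd.DataFrame(
            {
                "read_id": np.repeat(read_ids, W),
                "ref": ref_name,
                "window_start": np.tile(np.arange(1, W + 1), N),
                "mean_pA": means.ravel(),
                "sd_pA": sds.ravel(),
            }
        )
    else:
        events = _empty_tables()[1]
    return perbase, events


def mix_read_sets(
    modified_table: pd.DataFrame,
    unmodified_table: pd.DataFrame,
    fraction: float,
    n_reads: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample a read mixture at a given methylation ratio.

    Takes floor(n_reads * fraction) whole reads (sampled without
    replacement) from the modified set and the remainder from the
    unmodified set; read identities are preserved.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0,1]")
    n_mod = math.floor(n_reads * fraction)
    n_unm = n_reads - n_mod
    rng = np.random.default_rng(seed)
    parts = []
    for table, need, label in (
        (modified_table, n_mod, "modified"),
        (unmodified_table, n_unm, "unmodified"),
    ):
        ids = table["read_id"].unique()
        if need > len(ids):
            raise ValueError(
                f"requested {need} {label} reads but only {len(ids)} available "
                f"(shortfall {need - len(ids)})"
            )
        if need:
            take = rng.choice(ids, size=need, replace=False)
            parts.append(table[table["read_id"].isin(take)])
    if not parts:
        return modified_table.iloc[0:0].copy()
    return pd.concat(parts, ignore_index=True)


def simulate_replicates(
    reference: str,
    design: Mapping[str, float],
    n_replicates: int = 3,
    coverage: int = 100,
    modified_positions: Iterable[int] = (),
    model: ErrorModel = ErrorModel(),
    seed: int = 0,
    emit_events: bool = False,
) -> dict[tuple[str, int], tuple[pd.DataFrame, pd.DataFrame]]:
    """Simulate independent replicates per condition.

    ``design`` maps condition name -> mod_fraction (e.g. {"wt": 0.5,
    "ko": 0.0}).  Each (condition, replicate) dataset uses a sub-seed
    derived deterministically from (seed, condition, replicate).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    out = {}
    for cond, frac in design.items():
        for rep in range(1, n_replicates + 1):
            sub = stable_hash("replicate", seed, cond, rep)
            out[(cond, rep)] = simulate_reads(
                reference,
                coverage,
                modified_positions,
                frac,
                model,
                seed=sub,
                read_prefix=f"{cond}_rep{rep}_read",
                emit_events=emit_events,
            )
    return out


def motif_array_reference(
    n_sites: int,
    spacer_len: int = 20,
    motifs: tuple[str, ...] = ("GGACC", "GGACT"),
    seed: int = 0,
) -> tuple[str, list[int]]:
    """Synthetic reference densely planted with single-A RRACH motifs.

    Random sequence contains very few RRACH 5-mers with a single A (only
    GGACC/GGACT qualify once multi-A 5-mers are excluded), so pipeline
    simulations use this dense array instead: ``n_sites`` motifs drawn
    from ``motifs`` separated by A-free spacers (letters C/G/T), so every
    adenine in the reference is a planted motif centre and motif scanning
    recovers exactly the planted sites.  Returns the sequence and the
    1-based positions of the motif-centre A's.
    """
    for m in motifs:
        if len(m) != 5 or m.count("A") != 1 or m[2] != "A":
            raise ValueError(f"motif {m!r} must be a 5-mer with its only A at centre")
    rng = np.random.default_rng(seed)
    spacer_letters = np.array(list("CGT"))
    chunks = []
    centers = []
    pos = 0
    for i in range(n_sites):
        spacer = "".join(rng.choice(spacer_letters, size=spacer_len))
        motif = motifs[int(rng.integers(0, len(motifs)))]
        chunks.append(spacer + motif)
        pos += spacer_len + 5
        centers.append(pos - 2)  # centre A of the 5-mer, 1-based
    chunks.append("".join(rng.choice(spacer_letters, size=spacer_len)))
    return "".join(chunks), centers
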