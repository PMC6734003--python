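"""Shared fixtures: simulated study datasets reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from m6acall import (
    ErrorModel,
    ModelSpec,
    motif_array_reference,
    per_site_features,
    simulate_reads,
    train_svm,
    window_features,
)


@pytest.fixture(scope="session")
def motif_study():
    """A dense RRACH motif-array reference with designated modified sites."""
    ref, centers = motif_array_reference(150, seed=3)
    modified = centers[::2]
    unmodified = [c for c in centers if c not in set(modified)]
    return {"ref": ref, "centers": centers, "modified": modified, "unmodified": unmodified}


def labeled_windows(ref, positions, mod_fraction, coverage, seed, label,
                    with_current=False):
    """Window features at ``positions`` from one simulated condition."""
    from m6acall import current_window_stats

    perbase, events = simulate_reads(
        ref, coverage, positions if mod_fraction > 0 else [], mod_fraction,
        seed=seed, read_prefix=f"{label}{seed}_", emit_events=with_current,
    )
    current = current_window_stats(events) if with_current else None
    w = window_features(per_site_features(perbase, reference=ref), current)
    w = w[w["center_pos"].isin(positions)].copy()
    w["label"] = label
    return w


@pytest.fixture(scope="session")
def trained_combined3(motif_study):
    """SVM trained on stoichiometry-matched (0.5 vs 0) simulated windows."""
    ref, modified = motif_study["ref"], motif_study["modified"]
    windows = pd.concat(
        [
            labeled_windows(ref, modified, 0.5, 100, 11, "modified"),
            labeled_windows(ref, modified, 0.0, 100, 12, "unmodified"),
        ],
        ignore_index=True,
    )
    return train_svm(windows, ModelSpec(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)


def random_perbase_table(rng, n_reads=20, ref_len=15, ref_name="ref"):
    """A small random per-base table (with deletions and insertions)."""
    letters = np.array(list("ACGT"))
    seq = "".join(rng.choice(letters, size=ref_len))
    rows = []
    for r in range(n_reads):
        for p in range(1, ref_len + 1):
            ref_base = seq[p - 1]
            roll = rng.random()
            if roll < 0.1:
                call, qual = "DEL", np.nan
            elif roll < 0.3:
                call = str(rng.choice([b for b in "ACGT" if b != ref_base]))
                qual = float(rng.integers(1, 41))
            else:
                call, qual = ref_base, float(rng.integers(1, 41))
            ins = str(rng.choice(letters)) if rng.random() < 0.1 else ""
            rows.append(
                {
                    "read_id": f"r{r}",
                    "ref": ref_name,
                    "pos": p,
                    "ref_base": ref_base,
                    "call": call,
                    "qual": qual,
                    "ins": ins,
                }
            )
    return pd.DataFrame(rows), seq


@pytest.fixture()
def calm_model():
    """Error model with every k-mer-dependent spread disabled."""
    return ErrorModel(
        p_mismatch=0.01,
        p_deletion=0.005,
        p_insertion=0.01,
        kmer_error_spread=0.0,
        kmer_quality_spread=0.0,
        kmer_delta_spread=0.0,
        kmer_current_spread=0.0,
        neighbor_bleed=(0.0, 0.0),
    )
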