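"""Per-site base-called features and 5-mer window feature vectors.

From a per-base alignment table this module computes, for every reference
position, the spanning coverage, mean Phred quality of the aligned (non
deleted) calls, and mismatch / insertion / deletion frequencies; and from
a per-read event table the across-read mean and standard deviation of the
5-mer window current.  Site rows are then assembled into 5-mer-centred
window vectors (quality, mismatch frequency and deletion frequency at
positions -2..+2, 15 numbers) — the input representation for the SVM.

Conventions: coordinates are 1-based; the denominator of every frequency
is the spanning coverage (reads calling the position or deleting it);
insertions are left-anchored to the reference position they follow and
are extracted but, being irreproducible, excluded from default model
feature sets.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from ._util import normalize_sequence

POSITION_TAGS = ("-2", "-1", "0", "+1", "+2")
WINDOW_FEATURE_COLUMNS = [
    f"{f}{t}" for f in ("q", "mis", "del") for t in POSITION_TAGS
]

SITE_COLUMNS = [
    "ref",
    "pos",
    "ref_base",
    "coverage",
    "mean_quality",
    "mismatch_freq",
    "insertion_freq",
    "deletion_freq",
]


def per_site_features(
    perbase: pd.DataFrame,
    reference: str | Mapping[str, str] | None = None,
    ref_name: str | None = None,
) -> pd.DataFrame:
    """Aggregate a per-base alignment table into per-site features.

    When ``reference`` is given (a sequence, or a mapping name ->
    sequence), every reference position is emitted; positions no read
    spans get coverage 0 and missing (NaN) frequencies rather than being
    dropped.  Without a reference, only covered positions are emitted and
    ref_base is taken from the table.
    """
    refs: dict[str, str] = {}
    if reference is not None:
        if isinstance(reference, str):
            if ref_name is None:
                present = perbase["ref"].unique()
                if len(present) > 1:
                    raise ValueError("ref_name required: table covers several references")
                ref_name = str(present[0]) if len(present) else "ref"
            refs = {ref_name: normalize_sequence(reference)}
        else:
            refs = {n: normalize_sequence(s) for n, s in reference.items()}

    df = perbase
    if len(df):
        is_del = (df["call"] == "DEL").to_numpy()
        is_mis = (~is_del) & (df["call"].to_numpy() != df["ref_base"].to_numpy())
        has_ins = df["ins"].fillna("").astype(str).str.len().to_numpy() > 0
        qual = df["qual"].to_numpy(dtype=float)
        work = pd.DataFrame(
            {
                "ref": df["ref"].to_numpy(),
                "pos": df["pos"].to_numpy(),
                "ref_base": df["ref_base"].to_numpy(),
                "is_del": is_del,
                "is_mis": is_mis,
                "has_ins": has_ins,
                "qsum": np.where(is_del, 0.0, np.nan_to_num(qual)),
                "qn": ~is_del,
            }
        )
        g = work.groupby(["ref", "pos", "ref_base"], sort=True).agg(
            coverage=("is_del", "size"),
            n_del=("is_del", "sum"),
            n_mis=("is_mis", "sum"),
            n_ins=("has_ins", "sum"),
            qsum=("qsum", "sum"),
            qn=("qn", "sum"),
        )
        g = g.reset_index()
        cov = g["coverage"].to_numpy(dtype=float)
        g["mismatch_freq"] = g["n_mis"] / cov
        g["deletion_freq"] = g["n_del"] / cov
        g["insertion_freq"] = g["n_ins"] / cov
        with np.errstate(invalid="ignore", divide="ignore"):
            g["mean_quality"] = np.where(
                g["qn"] > 0, g["qsum"] / g["qn"].to_numpy(dtype=float), np.nan
            )
        sites = g[SITE_COLUMNS].copy()
    else:
        sites = pd.DataFrame(columns=SITE_COLUMNS)

    if refs:
        frames = []
        for name, seq in refs.items():
            full = pd.DataFrame(
                {
                    "ref": name,
                    "pos": np.arange(1, len(seq) + 1),
                    "ref_base": list(seq),
                }
            )
            have = sites[sites["ref"] == name].drop(columns=["ref_base"])
            merged = full.merge(have, on=["ref", "pos"], how="left")
            merged["coverage"] = merged["coverage"].fillna(0).astype(int)
            frames.append(merged[SITE_COLUMNS])
        sites = pd.concat(frames, ignore_index=True)
    else:
        sites["coverage"] = sites["coverage"].astype(int)
    sites["pos"] = sites["pos"].astype(int)
    return sites.reset_index(drop=True)


def current_window_stats(events: pd.DataFrame) -> pd.DataFrame:
    """Across-read current statistics per (ref, window_start).

    ``curr_mean`` is the mean of the per-read window means; ``curr_sd``
    their sample standard deviation (ddof=1; 0 when a single read spans
    the window).
    """
    if not len(events):
        return pd.DataFrame(columns=["ref", "window_start", "curr_mean", "curr_sd", "n_reads"])
    g = events.groupby(["ref", "window_start"], sort=True)["mean_pA"].agg(
        curr_mean="mean", curr_sd=lambda x: x.std(ddof=1), n_reads="size"
    )
    g = g.reset_index()
    g.loc[g["n_reads"] == 1, "curr_sd"] = 0.0
    return g


def window_features(
    sites: pd.DataFrame,
    current: pd.DataFrame | None = None,
    k: int = 5,
) -> pd.DataFrame:
    """Assemble k-mer-centred window vectors from contiguous site rows.

    One row per centre position having full +/-(k//2) context inside the
    reference: the k-mer, quality / mismatch / deletion at each window
    offset, optional across-read current statistics for the window, the
    minimum coverage over the window, a ``has_missing`` flag (any missing
    positional feature, e.g. a zero-coverage position), and a ``label``
    column initialised to "unknown".
    """
    if k % 2 != 1:
        raise ValueError("k must be odd")
    half = k // 2
    out_frames = []
    for ref, grp in sites.groupby("ref", sort=True):
        grp = grp.sort_values("pos").reset_index(drop=True)
        pos = grp["pos"].to_numpy()
        if len(pos) and not np.array_equal(pos, np.arange(pos[0], pos[0] + len(pos))):
            raise ValueError(f"site table for {ref!r} is not contiguous")
        L = len(grp)
        if L < k:
            continue
        base = grp["ref_base"].astype(str).to_numpy()
        q = grp["mean_quality"].to_numpy(dtype=float)
        mis = grp["mismatch_freq"].to_numpy(dtype=float)
        dele = grp["deletion_freq"].to_numpy(dtype=float)
        cov = grp["coverage"].to_numpy(dtype=float)
        centers = np.arange(half, L - half)
        cols: dict[str, np.ndarray] = {
            "ref": np.full(len(centers), ref, dtype=object),
            "center_pos": pos[centers],
            "kmer": np.array(
                ["".join(base[c - half : c + half + 1]) for c in centers], dtype=object
            ),
        }
        for arr, fname in ((q, "q"), (mis, "mis"), (dele, "del")):
            for off, tag in zip(range(-half, half + 1), POSITION_TAGS):
                cols[f"{fname}{tag}"] = arr[centers + off]
        cols["cov_min"] = np.min(
            np.stack([cov[centers + off] for off in range(-half, half + 1)]), axis=0
        )
        frame = pd.DataFrame(cols)
        out_frames.append(frame)
    if not out_frames:
        return pd.DataFrame(
            columns=["ref", "center_pos", "kmer", *WINDOW_FEATURE_COLUMNS,
                     "cov_min", "curr_mean", "curr_sd", "has_missing", "label"]
        )
    out = pd.concat(out_frames, ignore_index=True)
    if current is not None and len(current):
        cur = current.copy()
        cur["center_pos"] = cur["window_start"] + (k // 2)
        out = out.merge(
            cur[["ref", "center_pos", "curr_mean", "curr_sd"]],
            on=["ref", "center_pos"],
            how="left",
        )
    else:
        out["curr_mean"] = np.nan
        out["curr_sd"] = np.nan
    out["has_missing"] = out[WINDOW_FEATURE_COLUMNS].isna().any(axis=1)
    out["label"] = "unknown"
    return out
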