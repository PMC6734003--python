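"""Transcriptome-style m6A site calling.

Candidate sites are the central A's of RRACH 5-mers (R = A/G, H = A/C/T);
5-mers with more than one A are excluded by default because an in vitro
fully modified training set methylates every A of such k-mers, an
arrangement that does not occur in vivo.  Sites must reach a minimum
coverage in every sample.  Per-replicate SVM probabilities are merged
into a modification score M (1 if every replicate is >= 0.5, else their
mean), and a site is called modified when M_wt / M_ko > 1.5 and
M_wt > 0.5, with the knockout (modification-free) strain serving as the
false-positive control.  Stoichiometry is estimated by interpolating the
observed mismatch frequency between 0%- and 100%-modified calibration
levels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import normalize_sequence
from .model import PerformanceReport

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class CallingConfig:
    motif: str = "RRACH"
    min_coverage: int = 5
    score_threshold: float = 0.5
    ratio_threshold: float = 1.5
    exclude_multi_A: bool = True
    n_replicates: int = 3
    #: ratio recorded when M_ko == 0 (site then callable whenever M_wt qualifies)
    zero_denominator_ratio: float = math.inf

    def __post_init__(self) -> None:
        if self.score_threshold <= 0 or self.ratio_threshold <= 0:
            raise ValueError("thresholds must be > 0")
        if self.min_coverage < 0:
            raise ValueError("min_coverage must be >= 0")


@dataclass
class SiteCall:
    ref: str
    pos: int
    m_wt: float
    m_ko: float
    ratio: float
    status: str
    kmer: str = ""


def scan_motif(
    reference: str | Mapping[str, str],
    motif: str = "RRACH",
    exclude_multi_A: bool = True,
) -> pd.DataFrame:
    """Candidate modification sites: centres of motif-matching 5-mers.

    Returns one row per match with ``ref``, ``pos`` (1-based centre of the
    5-mer, the methylatable A for RRACH), ``kmer``, and ``multi_A`` (more
    than one A in the 5-mer).  Multi-A matches are flagged, and dropped
    when ``exclude_multi_A``.
    """
    motif = motif.upper()
    if len(motif) != 5:
        raise ValueError("motif must be a 5-mer (windows are 5-mers)")
    try:
        allowed = [set(IUPAC[c]) for c in motif]
    except KeyError as exc:
        raise ValueError(f"motif contains a non-IUPAC code: {exc}") from exc
    refs = {"ref": reference} if isinstance(reference, str) else dict(reference)
    rows = []
    for name, seq in refs.items():
        seq = normalize_sequence(seq)
        for i in range(len(seq) - 4):
            window = seq[i : i + 5]
            if all(b in a for b, a in zip(window, allowed)):
                rows.append(
                    {
                        "ref": name,
                        "pos": i + 3,  # centre, 1-based
                        "kmer": window,
                        "multi_A": window.count("A") > 1,
                    }
                )
    out = pd.DataFrame(rows, columns=["ref", "pos", "kmer", "multi_A"])
    if exclude_multi_A and len(out):
        out = out[~out["multi_A"]].reset_index(drop=True)
    return out


def coverage_filter(
    site_tables: Sequence[pd.DataFrame], min_coverage: int = 5
) -> pd.DataFrame:
    """Sites reaching ``min_coverage`` in *every* sample.

    ``site_tables`` are per-sample per-site feature tables (needing only
    ``ref``, ``pos``, ``coverage``).  Returns the retained (ref, pos) pairs.
    """
    if not site_tables:
        return pd.DataFrame(columns=["ref", "pos"])
    kept: set | None = None
    for table in site_tables:
        ok = table.loc[table["coverage"] >= min_coverage, ["ref", "pos"]]
        pairs = set(map(tuple, ok.to_numpy()))
        kept = pairs if kept is None else kept & pairs
    out = pd.DataFrame(sorted(kept), columns=["ref", "pos"]) if kept else pd.DataFrame(
        columns=["ref", "pos"]
    )
    return out


def merge_replicate_scores(
    scores: Sequence[float],
    score_threshold: float = 0.5,
    n_replicates: int = 3,
) -> float:
    """Merge per-replicate probabilities into a modification score M.

    M = 1 when every replicate probability is >= ``score_threshold``
    (boundary inclusive), otherwise the arithmetic mean.
    """
    scores = [float(s) for s in scores]
    if len(scores) != n_replicates:
        raise ValueError(
            f"expected {n_replicates} replicate scores, got {len(scores)}"
        )
    if any(not 0.0 <= s <= 1.0 for s in scores):
        raise ValueError("replicate scores must be in [0,1]")
    if all(s >= score_threshold for s in scores):
        return 1.0
    return sum(scores) / len(scores)


def call_modification(
    m_wt: float,
    m_ko: float,
    config: CallingConfig = CallingConfig(),
    ref: str = "",
    pos: int = 0,
    kmer: str = "",
) -> SiteCall:
    """Differential wt/ko call for one site.

    Modified iff M_wt / M_ko > ratio_threshold (strict) and
    M_wt > score_threshold (strict); M_ko = 0 yields the configured
    zero-denominator ratio (+inf by default).
    """
    for name, m in (("m_wt", m_wt), ("m_ko", m_ko)):
        if not 0.0 <= m <= 1.0:
            raise ValueError(f"{name} must be in [0,1], got {m}")
    ratio = m_wt / m_ko if m_ko > 0 else config.zero_denominator_ratio
    modified = ratio > config.ratio_threshold and m_wt > config.score_threshold
    return SiteCall(
        ref=ref,
        pos=pos,
        kmer=kmer,
        m_wt=m_wt,
        m_ko=m_ko,
        ratio=ratio,
        status="modified" if modified else "unmodified",
    )


def call_sites(
    wt_probs: Sequence[pd.DataFrame],
    ko_probs: Sequence[pd.DataFrame],
    config: CallingConfig = CallingConfig(),
) -> pd.DataFrame:
    """Merge per-replicate probability tables and call every shared site.

    Each table needs columns ``ref``, ``pos``, ``prob`` (and optionally
    ``kmer``).  Only sites present in every replicate of both conditions
    are called.  Returns a calls table (ref, pos, kmer, m_wt, m_ko,
    ratio, status).
    """
    if len(wt_probs) != config.n_replicates or len(ko_probs) != config.n_replicates:
        raise ValueError(
            f"expected {config.n_replicates} replicate tables per condition"
        )

    def stack(tables: Sequence[pd.DataFrame], cond: str) -> pd.DataFrame:
        frames = []
        for i, t in enumerate(tables, start=1):
            f = t[["ref", "pos", "prob"]].copy()
            f["rep"] = i
            frames.append(f)
        df = pd.concat(frames, ignore_index=True)
        wide = df.pivot_table(index=["ref", "pos"], columns="rep", values="prob")
        wide.columns = [f"{cond}_s{c}" for c in wide.columns]
        return wide

    wt = stack(wt_probs, "wt")
    ko = stack(ko_probs, "ko")
    both = wt.join(ko, how="inner").dropna()
    kmers = {}
    for t in list(wt_probs) + list(ko_probs):
        if "kmer" in t.columns:
            kmers.update(
                {(r, p): k for r, p, k in t[["ref", "pos", "kmer"]].to_numpy()}
            )
    rows = []
    for (ref, pos), rec in both.iterrows():
        m_wt = merge_replicate_scores(
            [rec[f"wt_s{i}"] for i in range(1, config.n_replicates + 1)],
            config.score_threshold,
            config.n_replicates,
        )
        m_ko = merge_replicate_scores(
            [rec[f"ko_s{i}"] for i in range(1, config.n_replicates + 1)],
            config.score_threshold,
            config.n_replicates,
        )
        call = call_modification(
            m_wt, m_ko, config, ref=ref, pos=int(pos), kmer=kmers.get((ref, pos), "")
        )
        rows.append(
            {
                "ref": call.ref,
                "pos": call.pos,
                "kmer": call.kmer,
                "m_wt": call.m_wt,
                "m_ko": call.m_ko,
                "ratio": call.ratio,
                "status": call.status,
            }
        )
    return pd.DataFrame(
        rows, columns=["ref", "pos", "kmer", "m_wt", "m_ko", "ratio", "status"]
    )


def performance_vs_known(
    calls: pd.DataFrame, known_sites: Iterable[tuple[str, int]]
) -> PerformanceReport:
    """Confusion counts of a calls table against a known-site list.

    Known sites must all have been analyzed (be present in ``calls``).
    TP: known sites called modified; FN: known sites called unmodified;
    FP/TN: the remaining analyzed sites.  ``report.recovery`` is
    TP / len(known); with an empty known list it is None (undefined).
    """
    known = set((str(r), int(p)) for r, p in known_sites)
    analyzed = set(zip(calls["ref"].astype(str), calls["pos"].astype(int)))
    outside = known - analyzed
    if outside:
        raise ValueError(
            f"{len(outside)} known sites absent from the analyzed set, e.g. "
            f"{sorted(outside)[:3]}"
        )
    is_known = np.array(
        [(r, p) in known for r, p in zip(calls["ref"].astype(str), calls["pos"].astype(int))]
    )
    is_mod = (calls["status"] == "modified").to_numpy()
    return PerformanceReport(
        tp=int(np.sum(is_known & is_mod)),
        fn=int(np.sum(is_known & ~is_mod)),
        fp=int(np.sum(~is_known & is_mod)),
        tn=int(np.sum(~is_known & ~is_mod)),
    )


def estimate_stoichiometry(
    observed_mismatch,
    unmodified_mismatch,
    fully_modified_mismatch,
):
    """Methylation fraction by linear interpolation of mismatch frequency.

    (observed - unmodified) / (fully_modified - unmodified), clipped to
    [0,1].  Accepts scalars or arrays (broadcast elementwise).
    """
    obs = np.asarray(observed_mismatch, dtype=float)
    unm = np.asarray(unmodified_mismatch, dtype=float)
    full = np.asarray(fully_modified_mismatch, dtype=float)
    if np.any(full <= unm):
        raise ValueError(
            "degenerate calibration: fully modified mismatch level must exceed "
            "the unmodified level"
        )
    frac = np.clip((obs - unm) / (full - unm), 0.0, 1.0)
    return float(frac) if frac.ndim == 0 else frac
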