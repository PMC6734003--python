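"""Readers and writers for the formats the pipeline touches.

Per-base alignment tables and event tables are plain TSV (the per-base
dialect is equivalent to a sam2tsv conversion of a BAM); site and window
features are headered CSV; designs are 60-column-wrapped FASTA; modified
sites can be exported as BED6.  BAM/SAM alignments are converted to
per-base records by expanding the CIGAR (M/=/X to calls, D to DEL rows,
I to an insertion string left-anchored on the preceding reference
position; soft clips and reference skips are passed over).  Mismatch
determination prefers a supplied reference sequence and falls back to the
MD tag.

Coordinates are 1-based inclusive everywhere except BED output (0-based,
half-open).  Phred encoding on serialization is Phred+33.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import pysam
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import normalize_sequence
from .design import SequenceSet
from .features import SITE_COLUMNS, WINDOW_FEATURE_COLUMNS
from .simulate import EVENT_COLUMNS, PERBASE_COLUMNS

FREQ_DECIMALS = 6


# ---------------------------------------------------------------- FASTA

def write_fasta(path, sequences: SequenceSet | Mapping[str, str]) -> None:
    records = (
        sequences.records
        if isinstance(sequences, SequenceSet)
        else list(sequences.items())
    )
    bio = [SeqRecord(Seq(s), id=n, description="") for n, s in records]
    with open(path, "w") as fh:
        SeqIO.write(bio, fh, "fasta")  # Biopython wraps at 60 columns


def read_fasta(path) -> dict[str, str]:
    return {
        rec.id: normalize_sequence(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    }


# ------------------------------------------------------------- TSV / CSV

def write_perbase_tsv(path, table: pd.DataFrame) -> None:
    out = table[PERBASE_COLUMNS].copy()
    out["qual"] = out["qual"].map(lambda q: "" if pd.isna(q) else str(int(q)))
    out["ins"] = out["ins"].fillna("")
    out.to_csv(path, sep="\t", index=False)

def read_perbase_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"read_id": str, "ref": str, "ref_base": str, "call": str},
        keep_default_na=False,
        na_values=[],
    )
    df["pos"] = df["pos"].astype(int)
    df["qual"] = pd.to_numeric(df["qual"].replace("", np.nan))
    df["ins"] = df["ins"].astype(str)
    return df[PERBASE_COLUMNS]


def write_event_tsv(path, events: pd.DataFrame) -> None:
    events[EVENT_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.4f")

def read_event_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "ref": str})
    df["window_start"] = df["window_start"].astype(int)
    return df[EVENT_COLUMNS]


def write_site_csv(path, sites: pd.DataFrame) -> None:
    sites[SITE_COLUMNS].to_csv(path, index=False, float_format=f"%.{FREQ_DECIMALS}f")

def read_site_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"ref": str, "ref_base": str})
    df["pos"] = df["pos"].astype(int)
    df["coverage"] = df["coverage"].astype(int)
    return df[SITE_COLUMNS]


def write_window_csv(path, windows: pd.DataFrame) -> None:
    cols = ["ref", "center_pos", "kmer", *WINDOW_FEATURE_COLUMNS,
            "curr_mean", "curr_sd", "cov_min", "has_missing", "label"]
    windows[cols].to_csv(path, index=False, float_format=f"%.{FREQ_DECIMALS}f")

def read_window_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"ref": str, "kmer": str, "label": str})
    df["center_pos"] = df["center_pos"].astype(int)
    df["has_missing"] = df["has_missing"].astype(bool)
    return df


def write_probs_csv(path, windows: pd.DataFrame, probs: pd.Series) -> None:
    out = windows.loc[probs.index, ["ref", "center_pos", "kmer"]].copy()
    out = out.rename(columns={"center_pos": "pos"})
    out["prob"] = probs
    out.to_csv(path, index=False, float_format=f"%.{FREQ_DECIMALS}f")

def read_probs_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"ref": str, "kmer": str})
    df["pos"] = df["pos"].astype(int)
    return df


def write_calls_csv(path, calls: pd.DataFrame) -> None:
    calls.to_csv(path, index=False, float_format=f"%.{FREQ_DECIMALS}f")


def write_bed(path, calls: pd.DataFrame, name_prefix: str = "m6A") -> None:
    """BED6 of modified sites; score = round(1000 * M_wt)."""
    mod = calls[calls["status"] == "modified"]
    with open(path, "w") as fh:
        for _, row in mod.iterrows():
            start = int(row["pos"]) - 1  # 1-based -> 0-based half-open
            fh.write(
                f"{row['ref']}\t{start}\t{start + 1}\t{name_prefix}_{row['kmer']}"
                f"\t{round(1000 * row['m_wt'])}\t+\n"
            )


def read_known_sites(path) -> list[tuple[str, int]]:
    """Known modified sites from 1-based TSV (ref, pos) or 0-based BED."""
    path = Path(path)
    sites = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if path.suffix.lower() == ".bed":
                sites.append((fields[0], int(fields[1]) + 1))
            else:
                if fields[1].isdigit():
                    sites.append((fields[0], int(fields[1])))
    return sites


# ------------------------------------------------------------- alignments

def load_alignment(
    path, reference: str | Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Canonical per-base records from BAM/SAM or the per-base TSV dialect."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tsv", ".txt"):
        return read_perbase_tsv(path)
    if suffix in (".bam", ".sam", ".cram"):
        refs = None
        if reference is not None:
            refs = (
                {None: normalize_sequence(reference)}
                if isinstance(reference, str)
                else {n: normalize_sequence(s) for n, s in reference.items()}
            )
        return _perbase_from_bam(path, refs)
    raise ValueError(
        f"unsupported alignment format {suffix!r}: expected .bam/.sam or the "
        "per-base .tsv dialect"
    )


def _perbase_from_bam(path: Path, refs: dict | None) -> pd.DataFrame:
    mode = "rb" if path.suffix.lower() == ".bam" else "r"
    rows = []
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as bam:
        for read in bam:
            if read.is_unmapped or read.query_sequence is None:
                continue
            ref_name = read.reference_name
            if refs is not None:
                ref_seq = refs.get(ref_name, refs.get(None))
                if ref_seq is None:
                    raise ValueError(f"no reference sequence supplied for {ref_name!r}")
            else:
                try:
                    ref_seq_aln = read.get_reference_sequence().upper()
                except ValueError as exc:
                    raise ValueError(
                        "alignment lacks an MD tag; supply the reference FASTA "
                        "to determine mismatches"
                    ) from exc
                ref_seq = None
            query = read.query_sequence.upper()
            quals = read.query_qualities
            qpos = 0
            rpos = read.reference_start  # 0-based
            aln_off = 0  # offset into MD-derived reference segment
            last_row = None
            for op, length in read.cigartuples:
                if op in (0, 7, 8):  # M/=/X
                    for i in range(length):
                        base = (
                            ref_seq[rpos + i]
                            if ref_seq is not None
                            else ref_seq_aln[aln_off + i]
                        )
                        last_row = {
                            "read_id": read.query_name,
                            "ref": ref_name,
                            "pos": rpos + i + 1,
                            "ref_base": base,
                            "call": query[qpos + i],
                            "qual": float(quals[qpos + i]) if quals is not None else np.nan,
                            "ins": "",
                        }
                        rows.append(last_row)
                    qpos += length
                    rpos += length
                    aln_off += length
                elif op == 1:  # I: attach to preceding reference position
                    if last_row is not None:
                        last_row["ins"] += query[qpos : qpos + length]
                    qpos += length
                elif op == 2:  # D
                    for i in range(length):
                        base = (
                            ref_seq[rpos + i]
                            if ref_seq is not None
                            else ref_seq_aln[aln_off + i]
                        )
                        last_row = {
                            "read_id": read.query_name,
                            "ref": ref_name,
                            "pos": rpos + i + 1,
                            "ref_base": base,
                            "call": "DEL",
                            "qual": np.nan,
                            "ins": "",
                        }
                        rows.append(last_row)
                    rpos += length
                    aln_off += length
                elif op == 3:  # N: spliced gap, positions not covered
                    rpos += length
                    aln_off += length
                    last_row = None
                elif op == 4:  # S
                    qpos += length
                # H/P consume nothing we track
    return pd.DataFrame(rows, columns=PERBASE_COLUMNS) if rows else pd.DataFrame(
        columns=PERBASE_COLUMNS
    )


# ------------------------------------------------------------ config/json

def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def write_json(path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
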