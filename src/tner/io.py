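"""Readers and writers for the package's tab-separated formats.

Pileup tables are the entry point of the whole pipeline: per-position
read depth and per-allele read counts for one sample, optionally split
by strand.  The dialect is deliberately simple — a header line and
tab-separated columns — so tables can be produced by any upstream
consensus/dedup pipeline.

Pileup TSV columns
    chrom  pos  ref  depth  A  C  G  T
    [A_fwd A_rev C_fwd C_rev G_fwd G_rev T_fwd T_rev]

``pos`` is 1-based.  Allele counts must not exceed ``depth`` (their sum
may be below it: gaps and deletions absorb the difference).  When strand
columns are present, fwd+rev must equal the total per allele.

Background profiles are serialized with a version tag so that model
building and polishing can run as separate CLI steps.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .contexts import BASES, Panel

PILEUP_COLUMNS = ["chrom", "pos", "ref", "depth", "A", "C", "G", "T"]
STRAND_COLUMNS = [f"{b}_{s}" for b in BASES for s in ("fwd", "rev")]

PROFILE_MAGIC = "# tner-background-profile v1"
PROFILE_COLUMNS = [
    "chrom", "pos", "ref", "alt", "tnc",
    "pi_hat", "sd_hat", "mean_depth", "n_obs", "flags",
]


def validate_pileup(df: pd.DataFrame) -> pd.DataFrame:
    """Check pileup invariants; return the (unmodified) frame.

    Raises ``ValueError`` on missing columns, allele counts exceeding
    depth, or strand counts that do not add up.
    """
    missing = [c for c in PILEUP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"pileup table missing columns {missing}")
    counts = df[list(BASES)].to_numpy()
    depth = df["depth"].to_numpy()
    if (counts < 0).any() or (depth < 0).any():
        raise ValueError("negative counts in pileup table")
    if (counts.sum(axis=1) > depth).any():
        bad = df.loc[counts.sum(axis=1) > depth, ["chrom", "pos"]].iloc[0]
        raise ValueError(
            f"allele counts exceed depth at {bad['chrom']}:{bad['pos']} (corrupt input)"
        )
    if all(c in df.columns for c in STRAND_COLUMNS):
        for b in BASES:
            total = df[f"{b}_fwd"].to_numpy() + df[f"{b}_rev"].to_numpy()
            if not np.array_equal(total, df[b].to_numpy()):
                raise ValueError(f"strand counts for allele {b} do not sum to total")
    return df


def read_pileup(path: str | Path) -> pd.DataFrame:
    """Read and validate a pileup TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str})
    df["pos"] = df["pos"].astype(int)
    return validate_pileup(df)


def write_pileup(df: pd.DataFrame, path: str | Path) -> None:
    validate_pileup(df)
    df.to_csv(path, sep="\t", index=False)


def align_pileup(df: pd.DataFrame, panel: Panel) -> tuple[np.ndarray, np.ndarray]:
    """Align a pileup to a panel; return (depth, counts[n_positions, 4]).

    The pileup must cover every panel position exactly once.  Count
    columns follow the fixed allele order A, C, G, T.
    """
    validate_pileup(df)
    keyed = df.set_index(["chrom", "pos"])
    if keyed.index.has_duplicates:
        raise ValueError("pileup table has duplicate positions")
    panel_index = pd.MultiIndex.from_frame(panel.positions[["chrom", "pos"]])
    try:
        aligned = keyed.loc[panel_index]
    except KeyError as exc:
        raise ValueError(f"pileup does not cover the panel: {exc}") from exc
    depth = aligned["depth"].to_numpy(dtype=float)
    counts = aligned[list(BASES)].to_numpy(dtype=float)
    return depth, counts


def write_profile(profile: pd.DataFrame, path: str | Path) -> None:
    """Write a background profile TSV with its version tag."""
    with open(path, "w") as fh:
        fh.write(PROFILE_MAGIC + "\n")
        profile[PROFILE_COLUMNS].to_csv(fh, sep="\t", index=False)


def read_profile(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline().strip()
        if first != PROFILE_MAGIC:
            raise ValueError(
                f"{path}: not a background profile (expected {PROFILE_MAGIC!r})"
            )
        df = pd.read_csv(fh, sep="\t", dtype={"chrom": str}, keep_default_na=False)
    df["pos"] = df["pos"].astype(int)
    for col in ("pi_hat", "sd_hat", "mean_depth"):
        df[col] = df[col].astype(float)
    df["n_obs"] = df["n_obs"].astype(int)
    df["flags"] = df["flags"].astype(str)
    return df


def write_vcf(decisions: pd.DataFrame, path: str | Path, sample_depth: bool = True) -> None:
    """Emit retained variants as a minimal VCF 4.2 (AF and DP in INFO)."""
    retained = decisions[decisions["decision"] == "retained"]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Allele fraction">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in retained.itertuples():
            dp = int(round(row.depth)) if "depth" in retained.columns else 0
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t"
                f"AF={row.observed_rate:.6g};DP={dp}\n"
            )
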