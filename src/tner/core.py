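"""Decision engine: shrinkage estimators, Clopper–Pearson thresholds, polishing.

The per-position background error rate estimated from a handful of
healthy controls is noisy.  The estimator used here pulls it toward the
mean rate of its tri-nucleotide context:

    pi~_ij = w_ij * mu^_i + (1 - w_ij) * pi^_ij

Two weights are available.  The default "modified" weight

    w_ij = mu^_i / (mu^_i + pi^_ij)

shrinks less when the position-specific rate is large, so genuinely
noisy positions keep their elevated background.  The "analytic" weight
is the conjugate beta-binomial posterior weight w = nu / (nu + n).

The detection threshold is the upper 1 - alpha/2 Clopper–Pearson bound
for a binomial proportion at the shrunk background rate pi~ and the
healthy-cohort mean depth N:

    B = BetaQuantile(1 - alpha/2; N*pi~ + 1, N*(1 - pi~))

An observed alternate-allele fraction below B is classified as
background and polished to the reference allele; a fraction at or above
B is retained as a candidate mutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ShrinkageEstimate",
    "shrink",
    "shrink_analytic",
    "detection_threshold",
    "PolishResult",
]


@dataclass(frozen=True)
class ShrinkageEstimate:
    """Weight and shrunk background rate; works element-wise on arrays."""

    w: np.ndarray | float
    pi_tilde: np.ndarray | float
    mode: str = "modified"


def shrink(mu_hat, pi_hat) -> ShrinkageEstimate:
    """Modified-weight shrinkage of a position rate toward its TNC mean.

    ``w = mu/(mu + pi)``; the degenerate case mu = pi = 0 is defined as
    w = 1, pi~ = 0.  Accepts scalars or broadcastable arrays.
    """
    mu = np.asarray(mu_hat, dtype=float)
    pi = np.asarray(pi_hat, dtype=float)
    denom = mu + pi
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(denom > 0, mu / np.where(denom > 0, denom, 1.0), 1.0)
    pi_tilde = w * mu + (1.0 - w) * pi
    if np.ndim(mu_hat) == 0 and np.ndim(pi_hat) == 0:
        return ShrinkageEstimate(float(w), float(pi_tilde), "modified")
    return ShrinkageEstimate(w, pi_tilde, "modified")


def shrink_analytic(mu_hat, nu_hat, x, n) -> ShrinkageEstimate:
    """Conjugate beta-binomial posterior mean with weight nu/(nu + n).

    ``x`` error reads out of ``n`` total; n = 0 returns the prior.
    """
    mu = np.asarray(mu_hat, dtype=float)
    nu = np.asarray(nu_hat, dtype=float)
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(nu <= 0):
        raise ValueError("prior concentration nu_hat must be positive")
    safe_n = np.where(n > 0, n, 0.0)
    w = nu / (nu + safe_n)
    pi_tilde = np.where(n > 0, (mu * nu + x) / (nu + safe_n), mu)
    if all(np.ndim(v) == 0 for v in (mu_hat, nu_hat, x, n)):
        return ShrinkageEstimate(float(w), float(pi_tilde), "analytic")
    return ShrinkageEstimate(w, pi_tilde, "analytic")


def detection_threshold(pi_tilde, depth, alpha: float):
    """Upper 1 - alpha/2 Clopper–Pearson bound used as detection threshold.

    ``B = BetaQuantile(1 - alpha/2; depth*pi~ + 1, depth*(1 - pi~))``,
    with the beta shape parameters kept as real numbers (no rounding).
    ``depth`` is normally the healthy-cohort mean depth.  Entries with
    depth <= 0 yield NaN (unmodeled).  Accepts scalars or arrays.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    pi = np.asarray(pi_tilde, dtype=float)
    n = np.asarray(depth, dtype=float)
    if np.any((pi < 0) | (pi >= 1)):
        raise ValueError("pi_tilde must lie in [0, 1)")
    ok = n > 0
    a = n * pi + 1.0
    b = n * (1.0 - pi)
    with np.errstate(invalid="ignore"):
        thr = np.where(ok, stats.beta.ppf(1.0 - alpha / 2.0, a, np.where(ok, b, 1.0)), np.nan)
    if np.ndim(pi_tilde) == 0 and np.ndim(depth) == 0:
        return float(thr)
    return thr


DECISION_COLUMNS = [
    "chrom", "pos", "ref", "alt", "tnc", "depth", "observed_rate",
    "pi_hat", "mu_hat", "w", "pi_tilde", "threshold", "decision", "flags",
    "method",
]


@dataclass
class PolishResult:
    """Outcome of polishing one sample against a background model.

    ``decisions`` has one row per (position, alternate allele) including
    unmodeled entries (decision ``unmodeled``); ``polished`` is the
    sample pileup with polished alternate reads reassigned to the
    reference allele.
    """

    decisions: pd.DataFrame
    polished: pd.DataFrame
    alpha: float
    method: str

    @property
    def n_polished(self) -> int:
        return int((self.decisions["decision"] == "polished").sum())

    @property
    def n_retained(self) -> int:
        return int((self.decisions["decision"] == "retained").sum())

    @property
    def n_unmodeled(self) -> int:
        return int((self.decisions["decision"] == "unmodeled").sum())

    def retained_variants(self) -> pd.DataFrame:
        return self.decisions[self.decisions["decision"] == "retained"].copy()

    def panel_metrics(self, panel=None, snp_threshold: float = 0.05):
        from .evaluate import panel_metrics

        return panel_metrics(self.polished, snp_threshold=snp_threshold)

    def to_vcf(self, path: str | Path) -> None:
        from .io import write_vcf

        write_vcf(self.decisions, path)

    def write_decisions(self, path: str | Path) -> None:
        self.decisions.to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        lines = [
            f"Polish summary (method={self.method}, alpha={self.alpha})",
            f"  entries:   {len(self.decisions)}",
            f"  polished:  {self.n_polished}",
            f"  retained:  {self.n_retained}",
            f"  unmodeled: {self.n_unmodeled}",
        ]
        return "\n".join(lines)


def apply_decisions(sample: pd.DataFrame, decisions: pd.DataFrame) -> pd.DataFrame:
    """Return a polished copy of ``sample``: polished alt reads move to ref.

    Strand columns, when present, are zeroed for polished alternates and
    credited to the reference allele so totals stay consistent.
    """
    from .contexts import BASES
    from .io import STRAND_COLUMNS

    polished = sample.copy()
    has_strands = all(c in sample.columns for c in STRAND_COLUMNS)
    to_zero = decisions[decisions["decision"] == "polished"]
    if to_zero.empty:
        return polished

    row_of = {
        key: i for i, key in enumerate(zip(polished["chrom"], polished["pos"]))
    }
    rows = np.array(
        [row_of[key] for key in zip(to_zero["chrom"], to_zero["pos"])], dtype=int
    )
    base_idx = {b: i for i, b in enumerate(BASES)}
    alt_idx = to_zero["alt"].map(base_idx).to_numpy()
    ref_idx = to_zero["ref"].map(base_idx).to_numpy()

    def _move(matrix: np.ndarray) -> None:
        moved = matrix[rows, alt_idx].copy()
        matrix[rows, alt_idx] = 0
        np.add.at(matrix, (rows, ref_idx), moved)

    counts = polished[list(BASES)].to_numpy().copy()
    _move(counts)
    polished[list(BASES)] = counts
    if has_strands:
        for strand in ("fwd", "rev"):
            cols = [f"{b}_{strand}" for b in BASES]
            mat = polished[cols].to_numpy().copy()
            _move(mat)
            polished[cols] = mat
    return polished
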