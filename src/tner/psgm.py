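"""Position-specific Gaussian model (PSGM) — the comparator baseline.

Before context-sharing error models, background polishing for deep
targeted panels typically modeled each position's error rate with a
Gaussian fitted across healthy subjects and retained observations that
were outliers relative to that per-position distribution.  This module
is a simplified reimplementation of that idea, used as the benchmark
the tri-nucleotide model is compared against; it makes no claim of
bit-compatibility with any published polishing software.

The decision rule is a one-sided upper test: an observed alternate
fraction is retained iff

    observed >= mean + z(1 - alpha/2) * max(sd, sd_floor)

where mean and sd are the across-subject sample moments of the
(germline-masked) per-entry rates.  The ``sd_floor`` (default 1e-5, one
read in 100,000) is required because ultra-deep count data frequently
yields zero across-subject variance, which would otherwise retain any
nonzero observation regardless of alpha.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import core
from .background import (
    DEFAULT_SNP_THRESHOLD,
    TNERBackgroundResults,
    _join_flags,
    _unmodeled_rows,
    compute_profile,
)
from .contexts import BASES, Panel
from .io import align_pileup, read_profile

DEFAULT_SD_FLOOR = 1e-5


def fit_gaussian(profile: pd.DataFrame) -> pd.DataFrame:
    """Per-entry Gaussian background (mean, sd) from a background profile.

    ``mean`` is the germline-masked across-subject mean rate and ``sd``
    the unbiased (n-1) sample standard deviation; entries observed in
    fewer than two subjects carry sd = 0 and the ``sd_undefined`` flag.
    """
    cols = ["pos_index", "chrom", "pos", "ref", "alt", "tnc"]
    cols = [c for c in cols if c in profile.columns]
    out = profile[cols].copy()
    out["mean"] = profile["pi_hat"].to_numpy(dtype=float)
    out["sd"] = profile["sd_hat"].to_numpy(dtype=float)
    out["mean_depth"] = profile["mean_depth"].to_numpy(dtype=float)
    out["n_obs"] = profile["n_obs"].to_numpy()
    out["flags"] = profile["flags"].to_numpy()
    return out


def psgm_decision(observed_rate, mean, sd, alpha: float, sd_floor: float = DEFAULT_SD_FLOOR):
    """Vectorized retain/polish call: retained iff obs >= mean + z*max(sd, floor)."""
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    threshold = np.asarray(mean, dtype=float) + z * np.maximum(
        np.asarray(sd, dtype=float), sd_floor
    )
    retained = np.asarray(observed_rate, dtype=float) >= threshold
    if np.ndim(observed_rate) == 0 and np.ndim(mean) == 0 and np.ndim(sd) == 0:
        return "retained" if bool(retained) else "polished"
    return np.where(retained, "retained", "polished")


class PositionSpecificGaussian:
    """Gaussian per-position background model fitted to a healthy cohort."""

    def __init__(
        self,
        cohort: Sequence[pd.DataFrame],
        panel: Panel,
        snp_threshold: float = DEFAULT_SNP_THRESHOLD,
        sd_floor: float = DEFAULT_SD_FLOOR,
    ) -> None:
        if len(cohort) == 0:
            raise ValueError("cohort must contain at least one subject")
        self.cohort = list(cohort)
        self.panel = panel
        self.snp_threshold = snp_threshold
        self.sd_floor = sd_floor

    def fit(self) -> "PSGMResults":
        profile = compute_profile(self.cohort, self.panel, self.snp_threshold)
        return PSGMResults(
            background=fit_gaussian(profile),
            panel=self.panel,
            n_subjects=len(self.cohort),
            snp_threshold=self.snp_threshold,
            sd_floor=self.sd_floor,
        )


@dataclass
class PSGMResults:
    """Fitted per-position Gaussian background with a polish method."""

    background: pd.DataFrame
    panel: Panel
    n_subjects: int | None = None
    snp_threshold: float = DEFAULT_SNP_THRESHOLD
    sd_floor: float = DEFAULT_SD_FLOOR

    @classmethod
    def from_background_results(
        cls, results: TNERBackgroundResults, sd_floor: float = DEFAULT_SD_FLOOR
    ) -> "PSGMResults":
        """Reuse the per-subject moments already aggregated in a TNER fit."""
        return cls(
            background=fit_gaussian(results.profile),
            panel=results.panel,
            n_subjects=results.n_subjects,
            snp_threshold=results.snp_threshold,
            sd_floor=sd_floor,
        )

    @classmethod
    def load(cls, path: str | Path, panel: Panel, **kwargs) -> "PSGMResults":
        results = TNERBackgroundResults.from_profile(read_profile(path), panel)
        return cls.from_background_results(results, **kwargs)

    def polish(
        self,
        sample: pd.DataFrame,
        alpha: float = 0.01,
        build_polished: bool = True,
    ) -> core.PolishResult:
        """Polish one sample with the per-position Gaussian outlier rule."""
        depth, counts = align_pileup(sample, self.panel)
        bg = self.background
        p = bg["pos_index"].to_numpy()
        a = bg["alt"].map({b: i for i, b in enumerate(BASES)}).to_numpy()
        obs_depth = depth[p]
        with np.errstate(invalid="ignore", divide="ignore"):
            observed = np.where(
                obs_depth > 0,
                counts[p, a] / np.where(obs_depth > 0, obs_depth, 1.0),
                np.nan,
            )
        mean = bg["mean"].to_numpy(dtype=float)
        sd = bg["sd"].to_numpy(dtype=float)
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        threshold = mean + z * np.maximum(sd, self.sd_floor)

        unmodeled = np.isnan(observed)
        snp_like = ~unmodeled & (observed >= self.snp_threshold)
        retained = ~unmodeled & (observed >= threshold)
        decision = np.where(
            unmodeled, "unmodeled", np.where(retained | snp_like, "retained", "polished")
        )
        decisions = pd.DataFrame(
            {
                "chrom": bg["chrom"].to_numpy(),
                "pos": bg["pos"].to_numpy(),
                "ref": bg["ref"].to_numpy(),
                "alt": bg["alt"].to_numpy(),
                "tnc": bg["tnc"].to_numpy(),
                "depth": obs_depth,
                "observed_rate": observed,
                "pi_hat": mean,
                "mu_hat": np.nan,
                "w": np.nan,
                "pi_tilde": mean,
                "threshold": threshold,
                "decision": decision,
                "flags": _join_flags(
                    ("probable_snp", snp_like),
                    ("no_sample_coverage", unmodeled),
                ),
                "method": "psgm",
            }
        )
        extra = _unmodeled_rows(self.panel, depth, counts, "psgm")
        if len(extra):
            decisions = pd.concat([decisions, extra], ignore_index=True)
        polished = core.apply_decisions(sample, decisions) if build_polished else sample
        return core.PolishResult(decisions, polished, alpha, "psgm")

    def summary(self) -> str:
        bg = self.background
        return "\n".join(
            [
                "Position-specific Gaussian background",
                "=" * 54,
                f"(position, alt) pairs  {len(bg):>10d}",
                f"subjects               {str(self.n_subjects or 'n/a'):>10s}",
                f"mean rate              {bg['mean'].mean():>10.3e}",
                f"sd floor               {self.sd_floor:>10.1e}",
            ]
        )
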