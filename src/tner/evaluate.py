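"""Evaluation harness: panel metrics, leave-one-out, ROC comparison.

Two families of metrics mirror how polishing methods are benchmarked on
deep targeted panels.  On healthy data, the number of *error-free
positions* (positions with exclusively reference-allele reads after
suppression) and the *panel-wide error rate* (nonreference reads at
sub-5%-frequency alleles over total reads) summarize residual noise;
these are computed per held-out subject in a leave-one-out scheme.  On
simulated data with a known truth set, sensitivity (retained true
signals) and specificity (polished non-signal entries) are swept over a
grid of detection levels alpha to form ROC curves and their trapezoid
AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .background import TNERBackground, TNERBackgroundResults
from .contexts import BASES, Panel
from .io import validate_pileup
from .psgm import PositionSpecificGaussian, PSGMResults

#: Default detection-level grid for ROC sweeps (log-spaced).
DEFAULT_ALPHA_GRID = np.geomspace(1e-6, 0.5, 25)


@dataclass(frozen=True)
class PanelMetrics:
    """Residual-noise summary of one (polished or raw) pileup table."""

    n_positions: int
    error_free_count: int
    error_rate: float

    @property
    def error_free_fraction(self) -> float:
        return self.error_free_count / self.n_positions if self.n_positions else 0.0


def panel_metrics(pileup: pd.DataFrame, snp_threshold: float = 0.05) -> PanelMetrics:
    """Error-free positions and panel-wide error rate of a pileup table.

    A position is error-free when all nonreference allele counts are
    zero.  The error rate sums nonreference reads whose per-allele
    frequency is below ``snp_threshold`` (probable germline variants are
    excluded from the numerator) and divides by total reads.
    """
    validate_pileup(pileup)
    counts = pileup[list(BASES)].to_numpy(dtype=float)
    depth = pileup["depth"].to_numpy(dtype=float)
    ref_idx = pileup["ref"].map({b: i for i, b in enumerate(BASES)})
    alt_counts = counts.copy()
    rows = np.flatnonzero(ref_idx.notna().to_numpy())
    alt_counts[rows, ref_idx[ref_idx.notna()].astype(int).to_numpy()] = 0.0

    error_free = int((alt_counts.sum(axis=1) == 0).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(depth[:, None] > 0, alt_counts / np.where(depth[:, None] > 0, depth[:, None], 1.0), 0.0)
    numerator = float(alt_counts[freq < snp_threshold].sum())
    total = float(depth.sum())
    rate = numerator / total if total > 0 else 0.0
    return PanelMetrics(len(pileup), error_free, rate)


def leave_one_out(
    cohort: Sequence[pd.DataFrame],
    panel: Panel,
    alpha: float = 0.01,
    method: str = "tner",
    snp_threshold: float = 0.05,
    **polish_kwargs,
) -> pd.DataFrame:
    """Polish each subject against a background built from the others.

    Returns one row per held-out subject with its post-polish panel
    metrics.  Requires at least two subjects.
    """
    if len(cohort) < 2:
        raise ValueError("leave-one-out requires a cohort of at least 2 subjects")
    if method not in ("tner", "psgm"):
        raise ValueError("method must be 'tner' or 'psgm'")
    rows = []
    for i, held_out in enumerate(cohort):
        rest = [c for j, c in enumerate(cohort) if j != i]
        if method == "tner":
            results = TNERBackground(rest, panel, snp_threshold=snp_threshold).fit()
        else:
            results = PositionSpecificGaussian(rest, panel, snp_threshold=snp_threshold).fit()
        polished = results.polish(held_out, alpha=alpha, **polish_kwargs)
        m = panel_metrics(polished.polished, snp_threshold=snp_threshold)
        rows.append(
            (i, method, alpha, m.n_positions, m.error_free_count,
             m.error_free_fraction, m.error_rate)
        )
    return pd.DataFrame(
        rows,
        columns=["subject", "method", "alpha", "n_positions",
                 "error_free_count", "error_free_fraction", "error_rate"],
    )


@dataclass
class RocCurve:
    """Sensitivity/specificity across a detection-level grid."""

    method: str
    table: pd.DataFrame  # columns: alpha, sensitivity, specificity
    descriptor: dict = field(default_factory=dict)

    @property
    def auc(self) -> float:
        """Trapezoid area under (1 - specificity, sensitivity).

        Anchored at (0, 0) and (1, 1): polishing curves never reach the
        top-right corner on their own because zero-observation entries
        are polished at every alpha.
        """
        x = 1.0 - self.table["specificity"].to_numpy()
        y = self.table["sensitivity"].to_numpy()
        order = np.argsort(x, kind="stable")
        x = np.concatenate([[0.0], x[order], [1.0]])
        y = np.concatenate([[0.0], y[order], [1.0]])
        return float(np.trapezoid(y, x))


def _truth_mask(decisions: pd.DataFrame, truth: pd.DataFrame) -> np.ndarray:
    keys = set(zip(truth["chrom"], truth["pos"], truth["alt"]))
    return np.fromiter(
        (k in keys for k in zip(decisions["chrom"], decisions["pos"], decisions["alt"])),
        dtype=bool,
        count=len(decisions),
    )


def roc_curve(
    results: TNERBackgroundResults | PSGMResults,
    sample: pd.DataFrame,
    truth: pd.DataFrame,
    alpha_grid: np.ndarray | None = None,
    descriptor: dict | None = None,
) -> RocCurve:
    """Sweep alpha and score decisions against a known truth set.

    sensitivity = retained truth entries / |truth|; specificity =
    polished modeled non-truth entries / all modeled non-truth entries.
    """
    if len(truth) == 0:
        raise ValueError("truth set is empty")
    alphas = np.sort(np.asarray(alpha_grid if alpha_grid is not None else DEFAULT_ALPHA_GRID))
    if np.any((alphas <= 0) | (alphas >= 1)):
        raise ValueError("alpha grid must lie in (0, 1)")
    rows = []
    mask = None
    method = None
    for alpha in alphas:
        result = results.polish(sample, alpha=float(alpha), build_polished=False)
        dec = result.decisions
        if mask is None:
            modeled = (dec["decision"] != "unmodeled").to_numpy()
            mask = _truth_mask(dec, truth)
            if mask.sum() < len(truth):
                raise ValueError("truth entries missing from modeled panel decisions")
            method = result.method
        retained = (dec["decision"] == "retained").to_numpy()
        sens = retained[mask].sum() / mask.sum()
        neg = modeled & ~mask
        spec = (~retained[neg]).sum() / neg.sum()
        rows.append((float(alpha), float(sens), float(spec)))
    table = pd.DataFrame(rows, columns=["alpha", "sensitivity", "specificity"])
    return RocCurve(method, table, descriptor or {})


def roc_compare(
    backgrounds: Mapping[str, TNERBackgroundResults | PSGMResults],
    sample: pd.DataFrame,
    truth: pd.DataFrame,
    alpha_grid: np.ndarray | None = None,
    descriptor: dict | None = None,
) -> dict[str, RocCurve]:
    """ROC curves for several fitted backgrounds on the same spiked sample."""
    return {
        name: roc_curve(res, sample, truth, alpha_grid, descriptor)
        for name, res in backgrounds.items()
    }


def spike_in_sensitivity(
    results: TNERBackgroundResults | PSGMResults,
    sample: pd.DataFrame,
    truth: pd.DataFrame,
    alpha: float = 0.01,
) -> int:
    """Number of truth entries retained when polishing at level ``alpha``."""
    result = results.polish(sample, alpha=alpha, build_polished=False)
    mask = _truth_mask(result.decisions, truth)
    retained = (result.decisions["decision"] == "retained").to_numpy()
    return int((retained & mask).sum())


def dilution_spike_in(
    seed: int,
    n_variants: int = 10,
    allele_fraction: float = 0.001,
    depth: int = 10000,
    context_mean: float = 1e-5,
    alpha: float = 0.01,
    panel_size: int = 3000,
) -> int:
    """Deterministic analog of the private-SNP dilution experiment.

    A carrier's unique heterozygous SNPs diluted 1:500 give an expected
    allele fraction of 0.1%.  Here: a random panel, a background profile
    with zero position-specific error at ``n_variants`` randomly chosen
    positions and a flat rate of ``context_mean`` elsewhere (so every
    context prior mean is ~``context_mean``), and a test sample with
    exactly ``allele_fraction * depth`` alternate reads at each chosen
    position.  Returns how many of the variants are retained.
    """
    from . import simulate
    from .background import TNERBackgroundResults

    rng = np.random.default_rng(seed)
    panel = simulate.random_panel(panel_size, seed=int(rng.integers(2**31)))
    pos_df = panel.positions
    rows = rng.choice(
        np.flatnonzero(pos_df["modeled"].to_numpy()), size=n_variants, replace=False
    )
    truth = pd.DataFrame(
        [
            (
                pos_df.at[r, "chrom"],
                pos_df.at[r, "pos"],
                pos_df.at[r, "ref"],
                next(b for b in "ACTG" if b != pos_df.at[r, "ref"]),
            )
            for r in rows
        ],
        columns=["chrom", "pos", "ref", "alt"],
    )

    profile = panel.alt_table().copy()
    profile["pi_hat"] = context_mean
    keys = set(zip(truth["chrom"], truth["pos"], truth["alt"]))
    hit = [k in keys for k in zip(profile["chrom"], profile["pos"], profile["alt"])]
    profile.loc[hit, "pi_hat"] = 0.0
    profile["sd_hat"] = 0.0
    profile["mean_depth"] = float(depth)
    profile["n_obs"] = 14
    profile["flags"] = ""
    results = TNERBackgroundResults.from_profile(profile, panel, n_subjects=14)

    sample = pos_df[["chrom", "pos", "ref"]].copy()
    sample["depth"] = depth
    for b in BASES:
        sample[b] = 0
    for i, ref in enumerate(sample["ref"]):
        if ref in BASES:
            sample.iloc[i, sample.columns.get_loc(ref)] = depth
    indexed = sample.set_index(["chrom", "pos"])
    n_alt = int(round(allele_fraction * depth))
    for row in truth.itertuples():
        indexed.at[(row.chrom, row.pos), row.alt] += n_alt
        indexed.at[(row.chrom, row.pos), row.ref] -= n_alt
    sample = indexed.reset_index()
    return spike_in_sensitivity(results, sample, truth, alpha=alpha)


def simulation_study(
    seed: int,
    n_positions: int = 20000,
    n_signals: int = 150,
    signal_af: float = 0.00075,
    coverage: int = 10000,
    cohort_coverage: int = 12000,
    n_subjects: Sequence[int] = (14,),
    read_model: str = "binomial",
    alpha_grid: np.ndarray | None = None,
) -> dict[str, RocCurve]:
    """One full in-silico benchmark replicate; returns ROC curves per arm.

    Protocol: draw a random panel and a synthetic healthy cohort (size
    ``max(n_subjects)`` at ``cohort_coverage``); take the cohort-average
    error-rate matrix as the simulation BMER; spike ``n_signals`` rows
    with ``signal_af``; draw one test sample at ``coverage``; fit the
    context model and the Gaussian baseline on the first ``n`` cohort
    subjects for each ``n`` in ``n_subjects``; sweep alpha.  Keys are
    ``"tner_n{n}"`` / ``"psgm_n{n}"``.
    """
    from . import simulate
    from .background import TNERBackground

    rng = np.random.default_rng(seed)
    panel = simulate.random_panel(n_positions, seed=int(rng.integers(2**31)))
    cohort, _ = simulate.synth_cohort(
        panel, n_subjects=max(n_subjects), coverage=cohort_coverage,
        seed=int(rng.integers(2**31)),
    )
    results_full = TNERBackground(cohort, panel).fit()
    bmer = results_full.to_bmer()
    spiked, truth = simulate.spike_signals(
        bmer, n_signals, signal_af, seed=int(rng.integers(2**31))
    )
    sample = simulate.simulate_counts(
        spiked, coverage, model=read_model, seed=int(rng.integers(2**31))
    )
    curves: dict[str, RocCurve] = {}
    for n in sorted(n_subjects, reverse=True):
        if n == len(cohort):
            res = results_full
        else:
            res = TNERBackground(cohort[:n], panel).fit()
        desc = {
            "seed": seed, "n_positions": n_positions, "n_signals": n_signals,
            "signal_af": signal_af, "coverage": coverage,
            "read_model": read_model, "n_subjects": n,
        }
        curves[f"tner_n{n}"] = roc_curve(res, sample, truth, alpha_grid, desc)
        curves[f"psgm_n{n}"] = roc_curve(
            PSGMResults.from_background_results(res), sample, truth, alpha_grid, desc
        )
    return curves


def plot_roc(curves: Mapping[str, RocCurve], path=None):
    """Plot ROC curves (one line per method); optionally save to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, curve in curves.items():
        ax.plot(
            1.0 - curve.table["specificity"],
            curve.table["sensitivity"],
            marker="o", markersize=3,
            label=f"{name} (AUC={curve.auc:.3f})",
        )
    ax.plot([0, 1], [0, 1], ls=":", c="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig


def plot_loo(metrics: pd.DataFrame, path=None):
    """Bar plot of per-subject error-free fractions from leave-one-out."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for method, grp in metrics.groupby("method"):
        ax.bar(
            grp["subject"] + (0.0 if method == "tner" else 0.35),
            grp["error_free_fraction"] * 100,
            width=0.35, label=method,
        )
    ax.set_xlabel("held-out subject")
    ax.set_ylabel("error-free positions (%)")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
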