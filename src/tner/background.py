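"""Healthy-cohort background model with tri-nucleotide-context priors.

Errors at panel position j are modeled as X_ij ~ Binomial(N_j, pi_ij)
with a position- and substitution-specific background error rate pi_ij.
With a dozen healthy controls the per-position estimate pi^_ij (mean
alternate-allele fraction across subjects, germline SNPs masked) is
imprecise, so pi_ij is given a conjugate beta prior shared by all
positions in the same tri-nucleotide context i:

    pi ~ Beta(mu * nu, (1 - mu) * nu)

The prior mean mu_i and concentration nu_i are estimated per context by
the method of moments from the across-position spread of pi^ within the
context: mu^ = mean, nu^ = mu^(1 - mu^)/var - 1.

:class:`TNERBackground` is the model object (cohort + panel + options);
:meth:`TNERBackground.fit` returns a :class:`TNERBackgroundResults`
carrying the per-entry profile, the 96 context priors, and the
:meth:`~TNERBackgroundResults.polish` decision method.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import core
from .contexts import BASES, Panel, enumerate_contexts
from .io import align_pileup, read_profile, write_profile

logger = logging.getLogger(__name__)

DEFAULT_SNP_THRESHOLD = 0.05
DEFAULT_NU_CAP = 1e6


def _join_flags(*flag_arrays: np.ndarray) -> np.ndarray:
    """Combine boolean flag arrays (name, mask) pairs into ';'-joined strings."""
    n = len(flag_arrays[0][1])
    out = np.full(n, "", dtype=object)
    for name, mask in flag_arrays:
        hit = np.asarray(mask)
        out[hit] = np.where(out[hit] == "", name, out[hit] + ";" + name)
    return out


def subject_error_rates(
    pileup: pd.DataFrame,
    panel: Panel,
    snp_threshold: float = DEFAULT_SNP_THRESHOLD,
) -> pd.DataFrame:
    """Per-(position, alternate) error rates for one subject.

    Returns the panel alt table with columns ``rate`` (NaN when masked),
    ``masked_snp`` (alternate fraction >= ``snp_threshold``, treated as a
    germline variant of this subject) and ``no_coverage`` (depth 0).
    """
    depth, counts = align_pileup(pileup, panel)
    alts = panel.alt_table().copy()
    p = alts["pos_index"].to_numpy()
    a = alts["alt"].map({b: i for i, b in enumerate(BASES)}).to_numpy()
    d = depth[p]
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(d > 0, counts[p, a] / np.where(d > 0, d, 1.0), np.nan)
    snp = np.nan_to_num(rate, nan=0.0) >= snp_threshold
    no_cov = d <= 0
    alts["rate"] = np.where(snp | no_cov, np.nan, rate)
    alts["masked_snp"] = snp & ~no_cov
    alts["no_coverage"] = no_cov
    return alts


def compute_profile(
    cohort: Sequence[pd.DataFrame],
    panel: Panel,
    snp_threshold: float = DEFAULT_SNP_THRESHOLD,
    depth_weighted: bool = False,
) -> pd.DataFrame:
    """Aggregate a healthy cohort into the per-entry background profile.

    One row per (modeled position, alternate allele) with the mean error
    rate ``pi_hat`` across subjects (germline-masked, unweighted by
    default), the across-subject sample sd ``sd_hat``, the cohort mean
    depth and the number of contributing observations.
    """
    if len(cohort) == 0:
        raise ValueError("cohort must contain at least one subject")
    alts = panel.alt_table()
    p = alts["pos_index"].to_numpy()
    a = alts["alt"].map({b: i for i, b in enumerate(BASES)}).to_numpy()

    n_subjects = len(cohort)
    depths = np.empty((n_subjects, panel.n_positions))
    rates = np.empty((n_subjects, len(alts)))
    counts_e = np.empty((n_subjects, len(alts)))
    for s, pileup in enumerate(cohort):
        depth, counts = align_pileup(pileup, panel)
        depths[s] = depth
        d = depth[p]
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(d > 0, counts[p, a] / np.where(d > 0, d, 1.0), np.nan)
        r[np.nan_to_num(r, nan=0.0) >= snp_threshold] = np.nan  # germline mask
        rates[s] = r
        counts_e[s] = counts[p, a]

    obs = ~np.isnan(rates)
    n_obs = obs.sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if depth_weighted:
            dsub = depths[:, p]
            num = np.where(obs, counts_e, 0.0).sum(axis=0)
            den = np.where(obs, dsub, 0.0).sum(axis=0)
            pi_hat = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
        else:
            pi_hat = np.nanmean(rates, axis=0)
        sd_hat = np.nanstd(rates, axis=0, ddof=1)
    pi_hat = np.where(n_obs == 0, 0.0, pi_hat)
    sd_hat = np.where(n_obs >= 2, sd_hat, 0.0)

    profile = alts.copy()
    profile["pi_hat"] = pi_hat
    profile["sd_hat"] = sd_hat
    profile["mean_depth"] = depths.mean(axis=0)[p]
    profile["n_obs"] = n_obs
    profile["flags"] = _join_flags(
        ("no_obs", n_obs == 0), ("sd_undefined", n_obs < 2)
    )
    return profile


def fit_beta_moments(rates: np.ndarray, nu_cap: float = DEFAULT_NU_CAP) -> tuple[float, float]:
    """Method-of-moments beta parameters (mu, nu) from a sample of rates.

    Inverts var = mu(1 - mu)/(nu + 1); degenerate samples (fewer than two
    values, zero variance, or an inversion yielding nu <= 0) return the
    near-point-mass cap for nu.
    """
    rates = np.asarray(rates, dtype=float)
    rates = rates[~np.isnan(rates)]
    if rates.size == 0:
        raise ValueError("no rates to estimate from")
    mu = float(rates.mean())
    if rates.size < 2:
        return mu, nu_cap
    var = float(rates.var(ddof=1))
    if var <= 0:
        return mu, nu_cap
    nu = mu * (1.0 - mu) / var - 1.0
    if nu <= 0:
        return mu, nu_cap
    return mu, min(nu, nu_cap)


def estimate_priors(
    profile: pd.DataFrame,
    nu_cap: float = DEFAULT_NU_CAP,
) -> pd.DataFrame:
    """Per-TNC beta priors by the method of moments.

    Returns one row per canonical context label (all 96, in enumeration
    order): ``mu_hat`` (mean of member-entry pi_hat), ``nu_hat``,
    ``var_hat`` (across-position sample variance), ``n_positions`` and
    ``defined``.  Contexts with no member positions fall back to the
    pooled panel-wide mean (flagged, logged).
    """
    pooled = float(profile["pi_hat"].mean()) if len(profile) else 0.0
    rows = {}
    for tnc, grp in profile.groupby("tnc"):
        vals = grp["pi_hat"].to_numpy(dtype=float)
        mu, nu = fit_beta_moments(vals, nu_cap=nu_cap)
        var = float(vals.var(ddof=1)) if vals.size >= 2 else np.nan
        rows[tnc] = (mu, nu, var, vals.size, True)
    records = []
    undefined = []
    for key in enumerate_contexts():
        if key.label in rows:
            records.append((key.label, *rows[key.label]))
        else:
            undefined.append(key.label)
            records.append((key.label, pooled, nu_cap, np.nan, 0, False))
    if undefined:
        logger.warning(
            "%d TNCs have no panel positions (e.g. %s); their priors fall back "
            "to the pooled panel mean %.3g",
            len(undefined), ", ".join(undefined[:4]), pooled,
        )
    return pd.DataFrame(
        records, columns=["tnc", "mu_hat", "nu_hat", "var_hat", "n_positions", "defined"]
    ).set_index("tnc")


class TNERBackground:
    """Tri-nucleotide-context background error model for a healthy cohort.

    Parameters
    ----------
    cohort
        Pileup tables (one per healthy subject), all covering ``panel``.
    panel
        Annotated target panel.
    snp_threshold
        Alternate-allele fraction at or above which an observation is
        masked as a germline variant of that subject (default 0.05).
    depth_weighted
        Weight the cohort average by per-subject depth instead of the
        default unweighted mean of rates.
    nu_cap
        Upper bound for the prior concentration; also the value used for
        degenerate (zero-variance) contexts.
    """

    def __init__(
        self,
        cohort: Sequence[pd.DataFrame],
        panel: Panel,
        snp_threshold: float = DEFAULT_SNP_THRESHOLD,
        depth_weighted: bool = False,
        nu_cap: float = DEFAULT_NU_CAP,
    ) -> None:
        if len(cohort) == 0:
            raise ValueError("cohort must contain at least one subject")
        self.cohort = list(cohort)
        self.panel = panel
        self.snp_threshold = snp_threshold
        self.depth_weighted = depth_weighted
        self.nu_cap = nu_cap

    def fit(self) -> "TNERBackgroundResults":
        profile = compute_profile(
            self.cohort, self.panel, self.snp_threshold, self.depth_weighted
        )
        priors = estimate_priors(profile, nu_cap=self.nu_cap)
        return TNERBackgroundResults(
            profile=profile,
            priors=priors,
            panel=self.panel,
            n_subjects=len(self.cohort),
            snp_threshold=self.snp_threshold,
        )


@dataclass
class TNERBackgroundResults:
    """Fitted background: per-entry profile, context priors, polishing.

    ``profile`` has one row per (modeled position, alternate allele);
    ``priors`` one row per canonical TNC.  Obtain it from
    :meth:`TNERBackground.fit`, :meth:`from_profile`, or :meth:`load`.
    """

    profile: pd.DataFrame
    priors: pd.DataFrame
    panel: Panel
    n_subjects: int | None = None
    snp_threshold: float = DEFAULT_SNP_THRESHOLD

    # -- construction / persistence -----------------------------------

    @classmethod
    def from_profile(
        cls,
        profile: pd.DataFrame,
        panel: Panel,
        n_subjects: int | None = None,
        snp_threshold: float = DEFAULT_SNP_THRESHOLD,
        nu_cap: float = DEFAULT_NU_CAP,
    ) -> "TNERBackgroundResults":
        """Rebuild results from a (possibly deserialized) profile table."""
        if "pos_index" not in profile.columns:
            profile = panel.alt_table().merge(
                profile.drop(columns=["ref", "tnc"], errors="ignore"),
                on=["chrom", "pos", "alt"],
                how="left",
                validate="one_to_one",
            )
            if profile["pi_hat"].isna().any():
                missing = int(profile["pi_hat"].isna().sum())
                logger.warning("%d panel entries absent from profile", missing)
                profile["flags"] = profile["flags"].fillna("absent_from_profile")
                profile["pi_hat"] = profile["pi_hat"].fillna(0.0)
                profile["sd_hat"] = profile["sd_hat"].fillna(0.0)
                profile["mean_depth"] = profile["mean_depth"].fillna(0.0)
                profile["n_obs"] = profile["n_obs"].fillna(0).astype(int)
        priors = estimate_priors(profile, nu_cap=nu_cap)
        return cls(profile, priors, panel, n_subjects, snp_threshold)

    def save(self, path: str | Path) -> None:
        write_profile(self.profile, path)

    @classmethod
    def load(cls, path: str | Path, panel: Panel, **kwargs) -> "TNERBackgroundResults":
        return cls.from_profile(read_profile(path), panel, **kwargs)

    # -- polishing -----------------------------------------------------

    def polish(
        self,
        sample: pd.DataFrame,
        alpha: float = 0.01,
        mode: str = "modified",
        threshold_depth: str = "cohort",
        build_polished: bool = True,
    ) -> core.PolishResult:
        """Polish one sample against this background.

        Per (position, alternate): the background rate is shrunk toward
        its context mean (``mode='modified'`` uses w = mu/(mu + pi);
        ``mode='analytic'`` the conjugate posterior weight), the
        Clopper–Pearson upper bound at level 1 - ``alpha``/2 becomes the
        detection threshold, and the observed alternate fraction is
        retained when at or above it, polished otherwise.  Alternate
        fractions at or above ``snp_threshold`` pass through retained,
        flagged as probable germline SNPs.  ``threshold_depth`` selects
        the depth entering the bound: ``'cohort'`` (healthy-cohort mean,
        the default) or ``'sample'``.
        """
        if mode not in ("modified", "analytic"):
            raise ValueError("mode must be 'modified' or 'analytic'")
        if threshold_depth not in ("cohort", "sample"):
            raise ValueError("threshold_depth must be 'cohort' or 'sample'")
        depth, counts = align_pileup(sample, self.panel)
        prof = self.profile
        p = prof["pos_index"].to_numpy()
        a = prof["alt"].map({b: i for i, b in enumerate(BASES)}).to_numpy()
        obs_depth = depth[p]
        obs_count = counts[p, a]
        with np.errstate(invalid="ignore", divide="ignore"):
            observed = np.where(
                obs_depth > 0, obs_count / np.where(obs_depth > 0, obs_depth, 1.0), np.nan
            )

        pi_hat = prof["pi_hat"].to_numpy(dtype=float)
        mu = self.priors["mu_hat"].reindex(prof["tnc"]).to_numpy(dtype=float)
        prior_defined = self.priors["defined"].reindex(prof["tnc"]).to_numpy(dtype=bool)
        if mode == "modified":
            est = core.shrink(mu, pi_hat)
        else:
            nu = self.priors["nu_hat"].reindex(prof["tnc"]).to_numpy(dtype=float)
            n_prior = prof["mean_depth"].to_numpy(dtype=float)
            est = core.shrink_analytic(mu, nu, pi_hat * n_prior, n_prior)

        if threshold_depth == "cohort":
            thr_depth = prof["mean_depth"].to_numpy(dtype=float)
        else:
            thr_depth = obs_depth
        threshold = core.detection_threshold(est.pi_tilde, thr_depth, alpha)

        unmodeled = np.isnan(observed) | np.isnan(threshold)
        snp_like = ~unmodeled & (observed >= self.snp_threshold)
        retained = ~unmodeled & (observed >= threshold)
        decision = np.where(
            unmodeled, "unmodeled", np.where(retained | snp_like, "retained", "polished")
        )

        decisions = pd.DataFrame(
            {
                "chrom": prof["chrom"].to_numpy(),
                "pos": prof["pos"].to_numpy(),
                "ref": prof["ref"].to_numpy(),
                "alt": prof["alt"].to_numpy(),
                "tnc": prof["tnc"].to_numpy(),
                "depth": obs_depth,
                "observed_rate": observed,
                "pi_hat": pi_hat,
                "mu_hat": mu,
                "w": est.w,
                "pi_tilde": est.pi_tilde,
                "threshold": threshold,
                "decision": decision,
                "flags": _join_flags(
                    ("probable_snp", snp_like),
                    ("no_sample_coverage", np.isnan(observed)),
                    ("prior_fallback", ~prior_defined),
                ),
                "method": "tner",
            }
        )
        extra = _unmodeled_rows(self.panel, depth, counts, "tner")
        if len(extra):
            decisions = pd.concat([decisions, extra], ignore_index=True)
        polished = core.apply_decisions(sample, decisions) if build_polished else sample
        return core.PolishResult(decisions, polished, alpha, "tner")

    def to_bmer(self):
        """Empirical cohort-average error rates as a BMER matrix.

        This is the simulation substrate of the in-silico benchmark: the
        per-(position, alternate) mean error rate across the healthy
        cohort, zero where nothing was observed.
        """
        from .simulate import BmerMatrix

        matrix = np.zeros((self.panel.n_positions, 4))
        a = self.profile["alt"].map({b: i for i, b in enumerate(BASES)}).to_numpy()
        matrix[self.profile["pos_index"].to_numpy(), a] = self.profile[
            "pi_hat"
        ].to_numpy(dtype=float)
        return BmerMatrix(self.panel, matrix)

    # -- reporting -----------------------------------------------------

    def summary(self) -> str:
        """Human-readable fit summary in the spirit of statsmodels."""
        prof, priors = self.profile, self.priors
        defined = priors[priors["defined"]]
        lines = [
            "TNER background model",
            "=" * 54,
            f"panel positions        {self.panel.n_positions:>10d}",
            f"  modeled              {self.panel.n_modeled:>10d}",
            f"(position, alt) pairs  {len(prof):>10d}",
            f"subjects               {str(self.n_subjects or 'n/a'):>10s}",
            f"mean background rate   {prof['pi_hat'].mean():>10.3e}",
            f"mean cohort depth      {prof['mean_depth'].mean():>10.1f}",
            "",
            "TNC priors (method of moments)",
            "-" * 54,
            f"defined contexts       {len(defined):>10d} / 96",
            f"mu_hat  min/median/max {defined['mu_hat'].min():.3e} / "
            f"{defined['mu_hat'].median():.3e} / {defined['mu_hat'].max():.3e}",
            f"nu_hat  min/median/max {defined['nu_hat'].min():.3e} / "
            f"{defined['nu_hat'].median():.3e} / {defined['nu_hat'].max():.3e}",
        ]
        return "\n".join(lines)


def _unmodeled_rows(
    panel: Panel, depth: np.ndarray, counts: np.ndarray, method: str
) -> pd.DataFrame:
    """Decision rows for panel positions without a TNC (edge / N context)."""
    pos_df = panel.positions
    un = pos_df[~pos_df["modeled"]]
    if un.empty:
        return pd.DataFrame(columns=core.DECISION_COLUMNS)
    rows = []
    for idx, chrom, pos, ref, reason in zip(
        un.index, un["chrom"], un["pos"], un["ref"], un["reason"]
    ):
        alts = [b for b in BASES if b != ref] if ref in BASES else list(BASES)
        d = depth[idx]
        for alt in alts:
            c = counts[idx, BASES.index(alt)]
            rate = c / d if d > 0 else np.nan
            rows.append(
                (chrom, pos, ref, alt, "", d, rate, np.nan, np.nan, np.nan,
                 np.nan, np.nan, "unmodeled", reason, method)
            )
    return pd.DataFrame(rows, columns=core.DECISION_COLUMNS)
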