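"""Synthetic data generation: BMER matrices, spiked signals, read counts.

Two jobs live here.  First, the in-silico benchmark protocol used to
compare polishing methods: start from a background-mutation-error-rate
(BMER) matrix (panel positions x 4 nucleotides, reference column zero),
add a fixed allele-fraction "signal" to one nonreference column of a
random subset of rows, draw read counts at a fixed total coverage under
a binomial (or, alternatively, normal) model, and split counts into
strands.  The spiked rows form the truth set for sensitivity /
specificity bookkeeping.

Second, a healthy-cohort generator with the statistical structure the
error model assumes: each (position, alternate) entry draws its true
rate from the beta prior of its tri-nucleotide context, and each
subject's counts are binomial at that rate.  The built-in 96-context
prior preset emulates the error spectrum of ultra-deep hybrid-capture
cfDNA panels: transitions (C>T, T>C) dominate transversions, C>T in a
CpG-like context is highest, and rates span roughly 1e-5 to 1e-3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .contexts import BASES, Panel, enumerate_contexts

logger = logging.getLogger(__name__)

#: Allele order used for the spike-target fallback and tie-breaking.
SPIKE_ALLELE_ORDER = "ACTG"

#: Per-substitution base rates of the default prior preset (fractions).
#: Scaled to barcoded-consensus cfDNA data: panel-wide error ~2e-5, most
#: entries effectively error-free, transitions dominant, CpG C>T hottest.
_PRESET_BASE_MU = {
    "C>A": 5e-6,
    "C>G": 3e-6,
    "C>T": 2e-5,
    "T>A": 2e-6,
    "T>C": 1e-5,
    "T>G": 2e-6,
}
_PRESET_NU = 1000.0
_CPG_FACTOR = 3.0  # C>T with a 3' G (CpG deamination analog)
_FLANK_FACTOR = {"A": 0.8, "C": 0.9, "G": 1.1, "T": 1.2}  # 5' flank modulation


def default_priors() -> pd.DataFrame:
    """Built-in 96-context prior preset (columns mu, nu; index tnc label)."""
    records = []
    for key in enumerate_contexts():
        sub = f"{key.ref}>{key.alt}"
        mu = _PRESET_BASE_MU[sub] * _FLANK_FACTOR[key.trinucleotide[0]]
        if sub == "C>T" and key.trinucleotide[2] == "G":
            mu *= _CPG_FACTOR
        records.append((key.label, mu, _PRESET_NU))
    return pd.DataFrame(records, columns=["tnc", "mu", "nu"]).set_index("tnc")


@dataclass
class BmerMatrix:
    """Per-position, per-nucleotide background error rates on a panel.

    ``rates`` is (n_positions, 4) in allele order A, C, G, T; the
    reference-nucleotide column of each row is structurally zero, and
    unmodeled positions are all-zero rows.
    """

    panel: Panel
    rates: np.ndarray

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.shape != (self.panel.n_positions, 4):
            raise ValueError(
                f"rates shape {self.rates.shape} does not match panel "
                f"({self.panel.n_positions} positions x 4)"
            )
        if (self.rates < 0).any() or (self.rates >= 1).any():
            raise ValueError("BMER entries must lie in [0, 1)")
        ref_idx = self.panel.positions["ref"].map(
            {b: i for i, b in enumerate(BASES)}
        )
        valid = ref_idx.notna()
        if valid.any():
            rows = np.flatnonzero(valid.to_numpy())
            cols = ref_idx[valid].astype(int).to_numpy()
            if (self.rates[rows, cols] != 0).any():
                raise ValueError("reference-nucleotide column must be zero")

    def to_frame(self) -> pd.DataFrame:
        df = self.panel.positions[["chrom", "pos", "ref"]].copy()
        for i, b in enumerate(BASES):
            df[b] = self.rates[:, i]
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, panel: Panel) -> "BmerMatrix":
        merged = panel.positions[["chrom", "pos"]].merge(
            df, on=["chrom", "pos"], how="left", validate="one_to_one"
        )
        return cls(panel, merged[list(BASES)].fillna(0.0).to_numpy())


def random_panel(
    n_positions: int, seed: int | None = None, chrom: str = "panel1"
) -> Panel:
    """Random-sequence single-contig panel with ``n_positions`` modeled bases.

    The contig carries one extra flanking base on each side so no target
    position sits at a contig edge.
    """
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list(BASES), size=n_positions + 2))
    return Panel.from_sequences({chrom: seq}, [(chrom, 1, n_positions + 1)])


def bmer_from_priors(
    panel: Panel,
    priors: pd.DataFrame | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> BmerMatrix:
    """Draw a true BMER matrix: one beta draw per (position, alternate).

    ``priors`` needs columns ``mu`` and ``nu`` indexed by TNC label
    (default: the built-in preset).  A context mean of exactly zero
    yields rate zero.
    """
    if priors is None:
        priors = default_priors()
    rng = rng if rng is not None else np.random.default_rng(seed)
    alts = panel.alt_table()
    mu = priors["mu"].reindex(alts["tnc"]).to_numpy(dtype=float)
    nu = priors["nu"].reindex(alts["tnc"]).to_numpy(dtype=float)
    if np.isnan(mu).any():
        missing = sorted(set(alts["tnc"]) - set(priors.index))
        raise KeyError(f"priors missing contexts {missing[:5]}...")
    rates_e = np.zeros(len(alts))
    pos_mask = mu > 0
    rates_e[pos_mask] = rng.beta(
        mu[pos_mask] * nu[pos_mask], (1.0 - mu[pos_mask]) * nu[pos_mask]
    )
    matrix = np.zeros((panel.n_positions, 4))
    a = alts["alt"].map({b: i for i, b in enumerate(BASES)}).to_numpy()
    matrix[alts["pos_index"].to_numpy(), a] = rates_e
    return BmerMatrix(panel, matrix)


def spike_signals(
    bmer: BmerMatrix,
    n_signals: int,
    signal_af: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[BmerMatrix, pd.DataFrame]:
    """Add a fixed allele fraction to one nonreference column of random rows.

    Rows are chosen uniformly without replacement among modeled panel
    positions.  Within a row the target column is the nonreference
    nucleotide with the largest BMER; all-zero rows (and ties) resolve
    to the first nonreference letter in A-C-T-G order.  Returns the
    updated matrix and the truth table (chrom, pos, ref, alt, af).
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    modeled_rows = np.flatnonzero(bmer.panel.positions["modeled"].to_numpy())
    if n_signals > modeled_rows.size:
        raise ValueError(
            f"cannot place {n_signals} signals on {modeled_rows.size} modeled positions"
        )
    if signal_af <= 0:
        raise ValueError("signal_af must be positive")
    if signal_af + bmer.rates.max() >= 1:
        raise ValueError("signal_af plus maximal BMER must stay below 1")
    chosen = np.sort(rng.choice(modeled_rows, size=n_signals, replace=False))
    rates = bmer.rates.copy()
    pos_df = bmer.panel.positions
    records = []
    for row in chosen:
        ref = pos_df.at[row, "ref"]
        candidates = [b for b in SPIKE_ALLELE_ORDER if b != ref]
        values = [rates[row, BASES.index(b)] for b in candidates]
        target = candidates[int(np.argmax(values))]  # argmax keeps first on ties
        rates[row, BASES.index(target)] += signal_af
        records.append((pos_df.at[row, "chrom"], pos_df.at[row, "pos"], ref, target, signal_af))
    truth = pd.DataFrame(records, columns=["chrom", "pos", "ref", "alt", "af"])
    return BmerMatrix(bmer.panel, rates), truth


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def simulate_counts(
    bmer: BmerMatrix,
    coverage: int,
    model: str = "binomial",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    sd_mode: str = "sqrt_over_100",
) -> pd.DataFrame:
    """Draw a pileup table from a BMER matrix at fixed total coverage.

    ``model='binomial'``: each nonreference count ~ Binomial(coverage,
    rate).  ``model='normal'``: the allele fraction is drawn normal with
    the BMER as mean and, under the default ``sd_mode='sqrt_over_100'``,
    sqrt(BMER)/100 as standard deviation (``'sqrt_of_ratio'`` uses
    sqrt(BMER/100)); negative draws truncate to zero and counts round
    half-away-from-zero.  The reference count is the remainder so counts
    always sum to the coverage.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = rng if rng is not None else np.random.default_rng(seed)
    rates = bmer.rates
    if model == "binomial":
        counts = rng.binomial(coverage, rates).astype(np.int64)
    elif model == "normal":
        if sd_mode == "sqrt_over_100":
            sd = np.sqrt(rates) / 100.0
        elif sd_mode == "sqrt_of_ratio":
            sd = np.sqrt(rates / 100.0)
        else:
            raise ValueError("sd_mode must be 'sqrt_over_100' or 'sqrt_of_ratio'")
        af = rng.normal(rates, sd)
        af[rates == 0] = 0.0  # degenerate sd: keep structural zeros exact
        af = np.clip(af, 0.0, None)
        counts = _round_half_away(af * coverage).astype(np.int64)
    else:
        raise ValueError("model must be 'binomial' or 'normal'")

    pos_df = bmer.panel.positions
    ref_idx = pos_df["ref"].map({b: i for i, b in enumerate(BASES)})
    rows = np.flatnonzero(ref_idx.notna().to_numpy())
    counts[rows, ref_idx[ref_idx.notna()].astype(int).to_numpy()] = 0

    total_alt = counts.sum(axis=1)
    over = total_alt > coverage
    if over.any():  # pathological draw; cap proportionally
        logger.warning("capping alternate counts exceeding coverage at %d positions",
                       int(over.sum()))
        scale = coverage / total_alt[over]
        counts[over] = np.floor(counts[over] * scale[:, None]).astype(np.int64)
        total_alt = counts.sum(axis=1)
    ref_counts = coverage - total_alt
    counts[rows, ref_idx[ref_idx.notna()].astype(int).to_numpy()] = ref_counts[rows]

    out = pos_df[["chrom", "pos", "ref"]].copy()
    out["depth"] = coverage
    for i, b in enumerate(BASES):
        out[b] = counts[:, i]
    return out


def split_strands(
    pileup: pd.DataFrame,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    concentration: float = 50.0,
) -> pd.DataFrame:
    """Split allele counts into forward/reverse strands.

    Per position a forward-strand fraction f ~ Beta(c, c) (centered at
    0.5, i.e. a fwd:rev ratio of about 1) is drawn and each allele count
    splits Binomial(count, f) / remainder.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    out = pileup.copy()
    f = rng.beta(concentration, concentration, size=len(out))
    for b in BASES:
        total = out[b].to_numpy(dtype=np.int64)
        fwd = rng.binomial(total, f)
        out[f"{b}_fwd"] = fwd
        out[f"{b}_rev"] = total - fwd
    return out


def synth_cohort(
    panel: Panel,
    priors: pd.DataFrame | None = None,
    n_subjects: int = 14,
    coverage: int = 12000,
    seed: int | None = None,
) -> tuple[list[pd.DataFrame], BmerMatrix]:
    """Generate a healthy cohort with beta-within-context true rates.

    Draws one true BMER matrix from the context priors, then per subject
    binomial counts at ``coverage``.  Defaults follow the study design
    the model targets: 14 healthy subjects at ~12,000x mean coverage.
    Returns the cohort and the true BMER for parameter-recovery checks.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    bmer = bmer_from_priors(panel, priors, rng=rng)
    cohort = [
        simulate_counts(bmer, coverage, model="binomial", rng=rng)
        for _ in range(n_subjects)
    ]
    return cohort, bmer
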