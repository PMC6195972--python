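"""Synthetic-data generator: BMER matrices, spiking, counts, strands."""

import numpy as np
import pandas as pd
import pytest

from tner.contexts import BASES, Panel
from tner.simulate import (
    BmerMatrix,
    bmer_from_priors,
    default_priors,
    random_panel,
    simulate_counts,
    spike_signals,
    split_strands,
    synth_cohort,
)


def zero_bmer(panel: Panel) -> BmerMatrix:
    return BmerMatrix(panel, np.zeros((panel.n_positions, 4)))


def first_nonref_column(rates: np.ndarray, panel: Panel, value: float) -> np.ndarray:
    """Write ``value`` into the first non-reference column of each row."""
    out = rates.copy()
    for i, ref in enumerate(panel.positions["ref"]):
        for b in BASES:
            if b != ref:
                out[i, BASES.index(b)] = value
                break
    return out


class TestBmerMatrix:
    def test_reference_column_must_be_zero(self):
        panel = random_panel(10, seed=0)
        rates = np.full((10, 4), 1e-4)
        with pytest.raises(ValueError, match="reference"):
            BmerMatrix(panel, rates)

    def test_default_priors_cover_all_96_contexts(self):
        priors = default_priors()
        assert len(priors) == 96
        assert (priors["mu"] > 0).all() and (priors["mu"] < 1e-3).all()
        # CpG-context deamination analog: A[C>T]G hotter than A[C>T]A
        assert priors.at["A[C>T]G", "mu"] > priors.at["A[C>T]A", "mu"]
        # transitions dominate transversions at matched flanks
        assert priors.at["A[C>T]A", "mu"] > priors.at["A[C>A]A", "mu"]

    def test_frame_roundtrip(self):
        panel = random_panel(20, seed=1)
        bmer = bmer_from_priors(panel, seed=2)
        back = BmerMatrix.from_frame(bmer.to_frame(), panel)
        np.testing.assert_allclose(back.rates, bmer.rates)


class TestSpikeSignals:
    def test_largest_background_column_receives_signal(self):
        panel = Panel.from_sequences({"c": "GATCAG"}, [("c", 1, 2)])  # one A position
        rates = np.zeros((1, 4))
        rates[0, BASES.index("C")] = 1e-4
        rates[0, BASES.index("G")] = 3e-4
        rates[0, BASES.index("T")] = 1e-5
        spiked, truth = spike_signals(BmerMatrix(panel, rates), 1, 7.5e-4, seed=0)
        assert truth.iloc[0]["alt"] == "G"
        assert spiked.rates[0, BASES.index("G")] == pytest.approx(1.05e-3)

    def test_all_zero_row_uses_first_nonreference_in_ACTG_order(self):
        panel = Panel.from_sequences({"c": "GACAG"}, [("c", 2, 3)])  # one C position
        spiked, truth = spike_signals(zero_bmer(panel), 1, 1e-3, seed=0)
        assert truth.iloc[0]["alt"] == "A"
        assert spiked.rates[0, BASES.index("A")] == pytest.approx(1e-3)

    def test_truth_size_and_distinct_positions(self):
        panel = random_panel(500, seed=3)
        _, truth = spike_signals(bmer_from_priors(panel, seed=4), 100, 7.5e-4, seed=5)
        assert len(truth) == 100
        assert not truth.duplicated(["chrom", "pos"]).any()

    def test_too_many_signals_rejected(self):
        panel = random_panel(10, seed=0)
        with pytest.raises(ValueError, match="signals"):
            spike_signals(zero_bmer(panel), 11, 1e-3, seed=0)


class TestSimulateCounts:
    def test_zero_rate_never_yields_reads(self):
        panel = random_panel(200, seed=6)
        table = simulate_counts(zero_bmer(panel), 1000, seed=7)
        alts = table[list(BASES)].to_numpy().sum() - table["depth"].sum()
        assert alts == 0  # all reads on the reference allele

    def test_count_conservation(self):
        panel = random_panel(300, seed=8)
        table = simulate_counts(bmer_from_priors(panel, seed=9), 5000, seed=10)
        assert (table[list(BASES)].sum(axis=1) == 5000).all()

    def test_binomial_mean_matches_rate(self):
        panel = random_panel(10000, seed=11)
        rates = first_nonref_column(np.zeros((10000, 4)), panel, 1e-3)
        table = simulate_counts(BmerMatrix(panel, rates), 10000, seed=12)
        counts = table[list(BASES)].to_numpy()
        target = rates > 0
        mean_alt = counts[target].mean()
        assert 9.5 < mean_alt < 10.5  # binomial mean 10, SE of the mean ~ 0.03

    def test_normal_model_dispersion_follows_stated_formula(self):
        rate = 0.01  # sd = sqrt(rate)/100 = 1e-3, far from the truncation at 0
        panel = random_panel(20000, seed=13)
        rates = first_nonref_column(np.zeros((20000, 4)), panel, rate)
        table = simulate_counts(BmerMatrix(panel, rates), 10000, model="normal", seed=14)
        af = table[list(BASES)].to_numpy()[rates > 0] / 10000.0
        assert af.std() == pytest.approx(np.sqrt(rate) / 100, rel=0.05)
        # the alternative parsing sqrt(rate/100) would give sd 1e-2 (10x);
        # its draws truncate heavily at zero, so only check the separation
        table2 = simulate_counts(
            BmerMatrix(panel, rates), 10000, model="normal", seed=14,
            sd_mode="sqrt_of_ratio",
        )
        af2 = table2[list(BASES)].to_numpy()[rates > 0] / 10000.0
        assert af2.std() > 4 * af.std()

    def test_seed_reproducibility(self):
        panel = random_panel(100, seed=15)
        bmer = bmer_from_priors(panel, seed=16)
        a = simulate_counts(bmer, 2000, seed=17)
        b = simulate_counts(bmer, 2000, seed=17)
        c = simulate_counts(bmer, 2000, seed=18)
        pd.testing.assert_frame_equal(a, b)
        assert not a.equals(c)


class TestSplitStrands:
    def test_strands_conserve_totals(self):
        panel = random_panel(200, seed=19)
        table = simulate_counts(bmer_from_priors(panel, seed=20), 3000, seed=21)
        split = split_strands(table, seed=22)
        for b in BASES:
            assert (split[f"{b}_fwd"] + split[f"{b}_rev"] == split[b]).all()

    def test_zero_count_splits_to_zero(self):
        panel = random_panel(50, seed=23)
        split = split_strands(simulate_counts(zero_bmer(panel), 100, seed=24), seed=25)
        alt_cols = [
            f"{b}_{s}" for b in BASES for s in ("fwd", "rev")
        ]
        ref_reads = sum(
            split.loc[split["ref"] == b, [f"{b}_fwd", f"{b}_rev"]].to_numpy().sum()
            for b in BASES
        )
        assert split[alt_cols].to_numpy().sum() == ref_reads  # only ref reads exist

    def test_strand_fraction_centered_at_half(self):
        panel = random_panel(10000, seed=26)
        split = split_strands(simulate_counts(zero_bmer(panel), 10000, seed=27), seed=28)
        ref = split["ref"].to_numpy()
        fwd = np.array([split[f"{b}_fwd"].to_numpy() for b in BASES]).T
        idx = pd.Series(list(BASES)).reset_index().set_index(0)["index"]
        f = fwd[np.arange(len(split)), idx[ref].to_numpy()] / 10000.0
        assert abs(f.mean() - 0.5) < 0.02


class TestSynthCohort:
    def test_cohort_shape_and_coverage(self):
        panel = random_panel(100, seed=29)
        cohort, bmer = synth_cohort(panel, n_subjects=14, coverage=12000, seed=30)
        assert len(cohort) == 14
        for table in cohort:
            assert len(table) == panel.n_positions
            assert (table["depth"] == 12000).all()
        assert bmer.rates.shape == (100, 4)

    def test_zero_mean_priors_give_clean_cohort(self):
        panel = random_panel(50, seed=31)
        priors = default_priors().assign(mu=0.0)
        cohort, bmer = synth_cohort(panel, priors=priors, n_subjects=2, coverage=1000, seed=32)
        assert bmer.rates.sum() == 0
        for table in cohort:
            assert (table[list(BASES)].sum(axis=1) == table["depth"]).all()
            alt = table[list(BASES)].to_numpy().sum() - table["depth"].sum()
            assert alt == 0

    def test_degenerate_prior_concentrates_on_context_mean(self):
        panel = random_panel(300, seed=33)
        priors = default_priors().assign(nu=1e12)
        _, bmer = synth_cohort(panel, priors=priors, n_subjects=1, coverage=10, seed=34)
        alts = panel.alt_table()
        mu = default_priors()["mu"].reindex(alts["tnc"]).to_numpy()
        drawn = bmer.rates[
            alts["pos_index"].to_numpy(),
            alts["alt"].map({b: i for i, b in enumerate(BASES)}).to_numpy(),
        ]
        # beta sd at nu = 1e12 is ~mu/1000; allow a few of those
        np.testing.assert_allclose(drawn, mu, rtol=1e-2)

    def test_seed_determinism_end_to_end(self):
        panel = random_panel(60, seed=35)
        a, _ = synth_cohort(panel, n_subjects=3, coverage=500, seed=36)
        b, _ = synth_cohort(panel, n_subjects=3, coverage=500, seed=36)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)
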