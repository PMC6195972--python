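"""Shrinkage estimators, Clopper–Pearson thresholds and polish decisions."""

import numpy as np
import pytest

from tner.background import TNERBackground, TNERBackgroundResults
from tner.contexts import Panel
from tner.core import detection_threshold, shrink, shrink_analytic
from tner.evaluate import panel_metrics

from conftest import make_pileup


class TestModifiedShrinkage:
    @pytest.mark.parametrize(
        "mu,pi,w_expected,pi_tilde_expected",
        [
            (0.001, 0.0, 1.0, 0.001),        # zero position rate: full prior
            (0.001, 0.003, 0.25, 0.0025),    # worked arithmetic
            (0.002, 0.002, 0.5, 0.002),      # symmetry
            (0.0, 0.0, 1.0, 0.0),            # degenerate case is defined
        ],
    )
    def test_worked_examples(self, mu, pi, w_expected, pi_tilde_expected):
        est = shrink(mu, pi)
        assert est.w == pytest.approx(w_expected, rel=1e-12)
        assert est.pi_tilde == pytest.approx(pi_tilde_expected, rel=1e-12)

    def test_estimate_bounded_by_inputs_everywhere(self):
        """pi~ always lies between the context mean and the position rate,
        and the weight in [0, 1] (10^6 random pairs)."""
        rng = np.random.default_rng(11)
        mu = rng.uniform(0, 0.999, size=1_000_000)
        pi = rng.uniform(0, 0.999, size=1_000_000)
        est = shrink(mu, pi)
        assert np.all((est.w >= 0) & (est.w <= 1))
        lo, hi = np.minimum(mu, pi), np.maximum(mu, pi)
        assert np.all(est.pi_tilde >= lo - 1e-15)
        assert np.all(est.pi_tilde <= hi + 1e-15)


class TestAnalyticShrinkage:
    def test_posterior_mean_arithmetic(self):
        est = shrink_analytic(0.002, 1000.0, 0, 1000)
        assert est.pi_tilde == pytest.approx(0.001)
        assert est.w == pytest.approx(0.5)

    def test_prior_mean_is_fixed_point(self):
        for nu in (10.0, 1e3, 1e6):
            est = shrink_analytic(0.004, nu, 40, 10000)  # x/n == mu
            assert est.pi_tilde == pytest.approx(0.004, rel=1e-12)

    def test_large_concentration_returns_prior(self):
        est = shrink_analytic(0.002, 1e12, 500, 10000)
        assert est.pi_tilde == pytest.approx(0.002, rel=1e-6)

    def test_zero_reads_returns_prior(self):
        est = shrink_analytic(0.002, 100.0, 0, 0)
        assert est.w == 1.0 and est.pi_tilde == 0.002

    def test_agrees_with_modified_weight_at_prior_mean(self):
        m = 3e-4
        assert shrink(m, m).pi_tilde == pytest.approx(
            shrink_analytic(m, 500.0, m * 10000, 10000).pi_tilde, rel=1e-12
        )

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError):
            shrink_analytic(0.002, 0.0, 1, 100)


class TestDetectionThreshold:
    @pytest.mark.parametrize("n", [100, 1000, 10000, 100000])
    @pytest.mark.parametrize("alpha", [0.01, 0.05])
    def test_zero_background_closed_form(self, n, alpha):
        """At pi~ = 0 the bound has the closed form 1 - (alpha/2)^(1/N):
        the Beta(1, N) distribution function is 1 - (1 - x)^N."""
        expected = 1.0 - (alpha / 2.0) ** (1.0 / n)
        assert detection_threshold(0.0, n, alpha) == pytest.approx(expected, rel=1e-10)

    def test_worked_values(self):
        assert detection_threshold(0.0, 10000, 0.01) == pytest.approx(5.298e-4, rel=1e-3)
        assert detection_threshold(0.0, 1000, 0.05) == pytest.approx(3.682e-3, rel=1e-3)

    def test_nondecreasing_in_background_rate(self):
        grid = np.linspace(0, 5e-3, 40)
        b = detection_threshold(grid, 10000.0, 0.01)
        assert np.all(np.diff(b) >= 0)

    def test_nonincreasing_in_depth_at_zero_background(self):
        depths = np.geomspace(100, 1e6, 40)
        b = detection_threshold(0.0, depths, 0.01)
        assert np.all(np.diff(b) <= 0)

    def test_zero_depth_is_unmodeled(self):
        assert np.isnan(detection_threshold(1e-4, 0.0, 0.01))

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            detection_threshold(0.0, 100, 1.5)


def results_with_flat_context_mean(panel: Panel, mu: float, depth: float = 10000.0):
    """Background whose every entry has pi_hat 0 but TNC mean ~mu, built by
    assigning rate mu to every entry and zeroing a target subset is not
    needed here: a uniform profile at mu gives mu_hat == mu in every context."""
    profile = panel.alt_table().copy()
    profile["pi_hat"] = mu
    profile["sd_hat"] = 0.0
    profile["mean_depth"] = depth
    profile["n_obs"] = 14
    profile["flags"] = ""
    return TNERBackgroundResults.from_profile(profile, panel, n_subjects=14)


class TestPolish:
    def test_decision_examples(self, tiny_panel):
        res = results_with_flat_context_mean(tiny_panel, mu=0.0)
        # with pi~ = 0 and N = 10000, B ~ 5.3e-4
        sample = make_pileup(
            tiny_panel, depth=10000,
            alt_counts={("chr1", 3, "T"): 10, ("chr1", 5, "A"): 2},
        )
        out = res.polish(sample, alpha=0.01)
        dec = out.decisions.set_index(["pos", "alt"])
        assert dec.at[(3, "T"), "decision"] == "retained"   # 1e-3 above bound
        assert dec.at[(5, "A"), "decision"] == "polished"   # 2e-4 below bound
        zero_entries = dec[dec["observed_rate"] == 0]
        assert (zero_entries["decision"] == "polished").all()

    def test_polished_reads_move_to_reference(self, tiny_panel):
        res = results_with_flat_context_mean(tiny_panel, mu=0.0)
        sample = make_pileup(tiny_panel, depth=10000, alt_counts={("chr1", 5, "A"): 2})
        out = res.polish(sample, alpha=0.01)
        row = out.polished.set_index("pos").loc[5]
        assert row["A"] == 0
        assert row[row["ref"]] == 10000
        m = panel_metrics(out.polished)
        assert m.error_free_count == tiny_panel.n_positions

    def test_retained_counts_preserved(self, tiny_panel):
        res = results_with_flat_context_mean(tiny_panel, mu=0.0)
        sample = make_pileup(tiny_panel, depth=10000, alt_counts={("chr1", 3, "T"): 50})
        out = res.polish(sample, alpha=0.01)
        assert out.polished.set_index("pos").at[3, "T"] == 50

    def test_germline_fraction_passes_through_flagged(self, tiny_panel):
        res = results_with_flat_context_mean(tiny_panel, mu=1e-5)
        sample = make_pileup(tiny_panel, depth=10000, alt_counts={("chr1", 3, "T"): 4800})
        dec = res.polish(sample, alpha=0.01).decisions.set_index(["pos", "alt"])
        row = dec.at[(3, "T"), "decision"], dec.at[(3, "T"), "flags"]
        assert row[0] == "retained" and "probable_snp" in row[1]

    def test_unmodeled_positions_reported_not_dropped(self):
        panel = Panel.from_sequences({"c": "ACGNTACGTACGA"})
        cohort = [make_pileup(panel, depth=1000)] * 2
        res = TNERBackground(cohort, panel).fit()
        out = res.polish(make_pileup(panel, depth=1000))
        un = out.decisions[out.decisions["decision"] == "unmodeled"]
        assert set(un["pos"]) == {1, 3, 4, 5, 13}  # edges, N and N-context
        covered = set(zip(out.decisions["pos"], out.decisions["alt"]))
        assert all((p, a) in covered
                   for p in panel.positions["pos"]
                   for a in "ACGT"
                   if a != panel.positions.set_index("pos").at[p, "ref"])

    def test_zero_sample_depth_is_unmodeled(self, tiny_panel):
        res = results_with_flat_context_mean(tiny_panel, mu=0.0)
        sample = make_pileup(tiny_panel, depth=1000)
        sample.loc[sample["pos"] == 3, ["depth", "A", "C", "G", "T"]] = 0
        dec = res.polish(sample).decisions.set_index(["pos", "alt"])
        assert dec.at[(3, "T"), "decision"] == "unmodeled"

    def test_sample_depth_threshold_mode(self, tiny_panel):
        res = results_with_flat_context_mean(tiny_panel, mu=0.0, depth=10000.0)
        # 4 alt reads at depth 4000: rate 1e-3 exceeds the cohort-depth bound
        # (5.3e-4) but not the shallower sample-depth bound (1.32e-3)
        sample = make_pileup(tiny_panel, depth=4000, alt_counts={("chr1", 3, "T"): 4})
        by_cohort = res.polish(sample, alpha=0.01).decisions.set_index(["pos", "alt"])
        by_sample = res.polish(sample, alpha=0.01, threshold_depth="sample").decisions.set_index(["pos", "alt"])
        assert by_cohort.at[(3, "T"), "decision"] == "retained"
        assert by_sample.at[(3, "T"), "decision"] == "polished"

    def test_analytic_mode_runs_and_agrees_at_prior_mean(self, tiny_panel):
        res = results_with_flat_context_mean(tiny_panel, mu=2e-4)
        sample = make_pileup(tiny_panel, depth=10000)
        mod = res.polish(sample, mode="modified").decisions
        ana = res.polish(sample, mode="analytic").decisions
        # every pi_hat equals the context mean, so both modes shrink to it
        np.testing.assert_allclose(
            mod["pi_tilde"].to_numpy(dtype=float),
            ana["pi_tilde"].to_numpy(dtype=float),
            rtol=1e-9,
        )
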