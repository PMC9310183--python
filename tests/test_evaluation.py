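"""Interaction tables, bootstrap CIs, model comparison, and anchored ML."""

import math

import numpy as np
import pytest
from scipy.stats import binom

from apecomm import (
    AFFILIATIVE,
    AVOIDANT,
    CombinationFrequencies,
    DomainError,
    IdentifiabilityError,
    InsufficientDataError,
    InteractionRecord,
    ParseError,
    UndefinedCorrelationError,
    bootstrap_ci,
    compare_models,
    correlate,
    default_frequencies,
    fit_parameters,
    generate_records,
    negative_log_likelihood,
    prediction_grid,
    read_records,
    reduced_parameters,
    summarize_reactions,
    write_records,
)
from apecomm.evaluation import CombinationSummary

ANCHORS = {
    "facial.neutral": 0.5,
    "context.positive": 0.3,
    "dominance.dominant_sender": 0.25,
}


def rec(g="stretched_arm", f="neutral", c="negative", s="subordinate_sender",
        reaction=AVOIDANT):
    return InteractionRecord(g, f, c, s, reaction)


def summary(combo, n, k):
    return CombinationSummary(combination=combo, n=n, n_avoidant=k,
                              ci_low=0.0, ci_high=1.0)


class TestRecordIO:
    def test_round_trip(self, tmp_path):
        records = [rec(), rec(reaction=AFFILIATIVE), rec(g="bent_arm", f="funneled_lip")]
        path = tmp_path / "records.csv"
        write_records(records, path)
        assert read_records(path) == records

    def test_header_only_file_is_empty(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("gesture,facial,context,dominance,reaction\n")
        assert read_records(path) == []

    @pytest.mark.parametrize(
        "row,field",
        [
            ("Stretched-Arm,neutral,negative,subordinate_sender,avoidant", "gesture"),
            ("stretched_arm,smile,negative,subordinate_sender,avoidant", "facial"),
            ("stretched_arm,neutral,negative,subordinate_sender,", "reaction"),
            ("stretched_arm,neutral,negative,subordinate_sender,AVOIDANT", "reaction"),
        ],
    )
    def test_strict_labels_name_row_and_field(self, tmp_path, row, field):
        path = tmp_path / "bad.csv"
        path.write_text("gesture,facial,context,dominance,reaction\n" + row + "\n")
        with pytest.raises(ParseError, match="2"):
            read_records(path)

    def test_wrong_header_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("gesture,facial,reaction\nstretched_arm,neutral,avoidant\n")
        with pytest.raises(ParseError, match="header"):
            read_records(path)


class TestSummarize:
    def test_minimum_count_filter(self):
        records = [rec(reaction=AVOIDANT)] * 3 + [rec(reaction=AFFILIATIVE)] * 2
        records += [rec(g="bent_arm")]  # singleton combination, dropped
        out = summarize_reactions(records, min_n=5, B=100, seed=0)
        assert len(out) == 1
        (s,) = out
        assert (s.n, s.n_avoidant) == (5, 3)
        assert s.proportion_avoidant == pytest.approx(0.6)
        assert s.ci_low <= s.proportion_avoidant <= s.ci_high

    def test_min_n_one_keeps_everything(self):
        records = [rec(reaction=AVOIDANT), rec(reaction=AVOIDANT)]
        (s,) = summarize_reactions(records, min_n=1, B=100, seed=0)
        assert s.proportion_avoidant == 1.0

    def test_empty_input(self):
        assert summarize_reactions([], min_n=5) == []

    def test_retained_counts_bounded_by_total(self):
        records = [rec()] * 7 + [rec(c="positive")] * 4 + [rec(g="bent_arm")] * 5
        out = summarize_reactions(records, min_n=5, B=100, seed=0)
        assert all(s.n >= 5 for s in out)
        assert sum(s.n for s in out) <= len(records)


class TestBootstrap:
    def test_degenerate_all_avoidant(self):
        assert bootstrap_ci(8, 8, B=1000, seed=0) == (1.0, 1.0)

    def test_matches_exact_binomial_quantiles(self):
        """Percentile interval == exact quantile of Binomial(n, k/n)/n."""
        for n, k in [(10, 5), (12, 3), (7, 1), (9, 8)]:
            lo, hi = bootstrap_ci(n, k, B=100_000, seed=123)
            assert lo == pytest.approx(binom.ppf(0.025, n, k / n) / n, abs=1e-12)
            assert hi == pytest.approx(binom.ppf(0.975, n, k / n) / n, abs=1e-12)

    def test_seed_reproducibility(self):
        assert bootstrap_ci(20, 9, B=5000, seed=42) == bootstrap_ci(20, 9, B=5000, seed=42)

    def test_invalid_inputs(self):
        with pytest.raises(DomainError):
            bootstrap_ci(0, 0)
        with pytest.raises(DomainError):
            bootstrap_ci(5, 6)


class TestCorrelate:
    def grid_for(self, preds):
        import pandas as pd

        combos = [("stretched_arm", "neutral", "negative", "subordinate_sender"),
                  ("stretched_arm", "bared_teeth", "negative", "subordinate_sender"),
                  ("bent_arm", "neutral", "negative", "subordinate_sender")]
        return (
            pd.DataFrame(combos, columns=["gesture", "facial", "context", "dominance"])
            .assign(p_avoidant=preds),
            combos,
        )

    def test_perfect_agreement(self):
        grid, combos = self.grid_for([0.2, 0.5, 0.8])
        sums = [summary(c, 10, round(10 * p)) for c, p in zip(combos, [0.2, 0.5, 0.8])]
        assert correlate(grid, sums) == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_pearson(self):
        grid, combos = self.grid_for([0.2, 0.5, 0.8])
        sums = [summary(c, 10, round(10 * p)) for c, p in zip(combos, [0.1, 0.6, 0.8])]
        assert correlate(grid, sums) == pytest.approx(0.9707253433941508, abs=1e-9)

    def test_weighted_equals_unweighted_for_equal_counts(self):
        grid, combos = self.grid_for([0.2, 0.5, 0.8])
        sums = [summary(c, 10, k) for c, k in zip(combos, [1, 6, 8])]
        assert correlate(grid, sums, weighted=True) == pytest.approx(
            correlate(grid, sums, weighted=False), abs=1e-12
        )

    def test_weighted_downweights_small_cells(self):
        grid, combos = self.grid_for([0.2, 0.5, 0.8])
        # outlier cell has few observations; weighting must pull r upward
        sums = [summary(combos[0], 100, 20), summary(combos[1], 100, 50),
                summary(combos[2], 4, 0)]
        assert correlate(grid, sums, weighted=True) > correlate(grid, sums)

    def test_constant_predictions_undefined(self):
        grid, combos = self.grid_for([0.7, 0.7, 0.7])
        sums = [summary(c, 10, k) for c, k in zip(combos, [2, 5, 8])]
        with pytest.raises(UndefinedCorrelationError, match="predictions"):
            correlate(grid, sums)

    def test_constant_observations_undefined(self):
        grid, combos = self.grid_for([0.2, 0.5, 0.8])
        sums = [summary(c, 10, 5) for c in combos]
        with pytest.raises(UndefinedCorrelationError, match="observations"):
            correlate(grid, sums)

    def test_fewer_than_three_combos(self):
        grid, combos = self.grid_for([0.2, 0.5, 0.8])
        with pytest.raises(InsufficientDataError):
            correlate(grid, [summary(combos[0], 10, 5), summary(combos[1], 10, 5)])


class TestCompareModels:
    def test_full_model_dominates_on_its_own_data(self, params):
        """Data simulated from the full model: the full model's correlation
        must exceed every single-component reduction's."""
        records = generate_records(params, n=50_000, seed=11)
        report = compare_models(records, params, min_n=5, B=200, seed=0)
        full = report.results["full"].correlation
        assert full is not None and full > 0.97
        for name, res in report.results.items():
            if name == "full":
                continue
            assert (not res.defined) or res.correlation < full

    def test_structureless_data_no_correlation_structure(self, params, registry):
        """Reactions independent of cues: correlations scatter around zero,
        so the per-model average over independent replicates is small."""
        combos = list(registry.combinations())
        sums: dict[str, list[float]] = {}
        for seed in range(10):
            rng = np.random.default_rng(seed)
            records = [
                InteractionRecord(
                    *combos[rng.integers(len(combos))],
                    reaction=AVOIDANT if rng.random() < 0.5 else AFFILIATIVE,
                )
                for _ in range(5_000)
            ]
            report = compare_models(records, params, min_n=5, B=50, seed=0)
            for name, res in report.results.items():
                if res.defined:
                    sums.setdefault(name, []).append(res.correlation)
        assert "full" in sums
        for name, values in sums.items():
            assert abs(np.mean(values)) < 0.25, name

    def test_single_combination_insufficient(self, params):
        records = [rec()] * 10
        with pytest.raises(InsufficientDataError):
            compare_models(records, params)

    def test_negative_context_only_context_model_undefined(self, params):
        """All evaluable combinations in one context: the context-only
        reduction predicts a constant and its correlation is undefined."""
        freqs = default_frequencies(params.registry, negative_share=1.0)
        records = generate_records(params, freqs, n=5_000, seed=13)
        report = compare_models(records, params, min_n=5, B=200, seed=0)
        ctx = report.results["context_only"]
        assert not ctx.defined
        assert "constant predictions" in ctx.undefined_reason
        assert report.results["full"].defined


class TestNegativeLogLikelihood:
    def test_single_record_value(self, params):
        # posterior avoidant for this cell is 0.8876 under reference weights
        got = negative_log_likelihood(params, [rec()])
        assert got == pytest.approx(-math.log(0.8875598086124402), abs=1e-9)

    def test_neutral_model_is_n_log_two(self, neutral_params):
        records = [rec(), rec(reaction=AFFILIATIVE), rec(g="bent_arm")]
        assert negative_log_likelihood(neutral_params, records) == pytest.approx(
            3 * math.log(2), abs=1e-12
        )

    def test_additivity(self, params):
        r = rec(f="funneled_lip")
        one = negative_log_likelihood(params, [r])
        assert negative_log_likelihood(params, [r, r]) == pytest.approx(2 * one, abs=1e-9)

    def test_zero_probability_observation_rejected(self, params):
        hard = params.replace(facial={"neutral": 0.5, "bared_teeth": 0.6,
                                      "funneled_lip": 1.0})
        with pytest.raises(DomainError):
            negative_log_likelihood(hard, [rec(f="funneled_lip",
                                               reaction=AFFILIATIVE)])


class TestFitParameters:
    def uniform_freqs(self, registry):
        combos = list(registry.combinations())
        return CombinationFrequencies({c: 1 / len(combos) for c in combos})

    def test_log_odds_shift_invariance(self, params):
        """Adding δ to all gesture log-odds and subtracting it from all
        facial log-odds changes no posterior and no NLL — the reason
        anchoring is mandatory."""
        from scipy.special import expit, logit

        delta = 0.4
        shifted = params.replace(
            gesture={k: float(expit(logit(v) + delta))
                     for k, v in params.component("gesture").items()},
            facial={k: float(expit(logit(v) - delta))
                    for k, v in params.component("facial").items()},
        )
        records = generate_records(params, n=500, seed=3)
        g0 = prediction_grid(params)["p_avoidant"].to_numpy()
        g1 = prediction_grid(shifted)["p_avoidant"].to_numpy()
        assert np.allclose(g0, g1, atol=1e-12)
        assert negative_log_likelihood(shifted, records) == pytest.approx(
            negative_log_likelihood(params, records), abs=1e-9
        )

    def test_unanchored_fit_rejected(self, params):
        records = generate_records(params, n=100, seed=0)
        with pytest.raises(IdentifiabilityError):
            fit_parameters(records, anchors={}, seed=0)
        with pytest.raises(IdentifiabilityError):
            fit_parameters(records, anchors={"facial.neutral": 0.5,
                                             "context.positive": 0.3}, seed=0)

    def test_recovers_generating_grid(self, params, registry):
        """2,000 records per cell from the reference weights: the fitted
        24-cell grid matches the generating grid within 0.03."""
        records = generate_records(params, self.uniform_freqs(registry),
                                   n=2_000 * 24, seed=21)
        result = fit_parameters(records, anchors=ANCHORS, seed=2)
        fitted = prediction_grid(result.params)["p_avoidant"].to_numpy()
        truth = prediction_grid(params)["p_avoidant"].to_numpy()
        assert np.max(np.abs(fitted - truth)) < 0.03
        assert result.nll <= negative_log_likelihood(params, records) + 1e-6

    def test_null_recovery(self, neutral_params, registry):
        """Data from all-neutral truth with neutral anchors: every fitted
        weight returns to 0.5."""
        anchors = {"facial.neutral": 0.5, "context.positive": 0.5,
                   "dominance.dominant_sender": 0.5}
        records = generate_records(neutral_params, self.uniform_freqs(registry),
                                   n=20_000, seed=9)
        result = fit_parameters(records, anchors=anchors, seed=1)
        for value in result.params.to_flat_dict().values():
            assert value == pytest.approx(0.5, abs=0.03)

    def test_unobserved_labels_flagged_sparse(self, params):
        records = [rec(reaction=AVOIDANT)] * 6 + [rec(reaction=AFFILIATIVE)] * 3 \
            + [rec(g="bent_arm")] * 5 + [rec(f="bared_teeth")] * 5
        result = fit_parameters(records, anchors=ANCHORS, seed=0)
        assert "facial.funneled_lip" in result.sparse_parameters
        assert result.params.weight("facial", "funneled_lip") == 0.5

    def test_deterministic_given_seed(self, params):
        records = generate_records(params, n=2_000, seed=4)
        a = fit_parameters(records, anchors=ANCHORS, seed=7)
        b = fit_parameters(records, anchors=ANCHORS, seed=7)
        assert a.params == b.params and a.nll == b.nll

    def test_empty_records_rejected(self):
        with pytest.raises(DomainError):
            fit_parameters([], anchors=ANCHORS, seed=0)
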