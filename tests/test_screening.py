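import itertools

import numpy as np
import pytest

from antioxkit.exceptions import DomainError
from antioxkit.screening import (
    ScreenOutcome,
    binary_roc_auc,
    enrichment_factor,
    hit_rate,
)
from antioxkit.simulate import simulate_screen


def _rank_auc_oracle(o: ScreenOutcome) -> float:
    """Concordant-pair AUC with binary calls as scores, ties counted half."""
    actives = [1] * o.tp + [0] * o.fn
    inactives = [1] * o.fp + [0] * o.tn
    total = 0.0
    for a in actives:
        for i in inactives:
            total += 1.0 if a > i else (0.5 if a == i else 0.0)
    return total / (len(actives) * len(inactives))


class TestRocAuc:
    def test_reference_screen_outcome(self):
        o = ScreenOutcome(tp=9, fn=0, fp=1, tn=8)
        auc = binary_roc_auc(o)
        assert auc == pytest.approx(17.0 / 18.0)
        assert round(auc, 2) == 0.94

    def test_perfect_classifier(self):
        assert binary_roc_auc(ScreenOutcome(tp=9, fn=0, fp=0, tn=9)) == 1.0

    def test_coin_flip_marginal(self):
        # tp/n_active == fp/n_inactive
        assert binary_roc_auc(ScreenOutcome(tp=3, fn=6, fp=3, tn=6)) == 0.5

    def test_matches_rank_pair_oracle_for_all_nine_by_nine_matrices(self):
        for tp, fp in itertools.product(range(10), range(10)):
            o = ScreenOutcome(tp=tp, fn=9 - tp, fp=fp, tn=9 - fp)
            assert binary_roc_auc(o) == pytest.approx(_rank_auc_oracle(o), abs=1e-12)

    def test_empty_class_rejected(self):
        with pytest.raises(DomainError):
            binary_roc_auc(ScreenOutcome(tp=0, fn=0, fp=1, tn=8))


class TestEnrichmentFactor:
    def test_reference_screen_outcome(self):
        assert enrichment_factor(ScreenOutcome(tp=9, fn=0, fp=1, tn=8)) == pytest.approx(1.8)

    def test_random_selection_at_prevalence(self):
        assert enrichment_factor(ScreenOutcome(tp=3, fn=6, fp=3, tn=6)) == pytest.approx(1.0)

    def test_pure_active_selection_at_half_prevalence(self):
        assert enrichment_factor(ScreenOutcome(tp=5, fn=4, fp=0, tn=9)) == pytest.approx(2.0)

    def test_invariant_to_scaling_all_counts(self):
        o1 = ScreenOutcome(tp=9, fn=0, fp=1, tn=8)
        o3 = ScreenOutcome(tp=27, fn=0, fp=3, tn=24)
        assert enrichment_factor(o1) == pytest.approx(enrichment_factor(o3))
        assert binary_roc_auc(o1) == pytest.approx(binary_roc_auc(o3))

    def test_empty_selection_rejected(self):
        with pytest.raises(DomainError):
            enrichment_factor(ScreenOutcome(tp=0, fn=9, fp=0, tn=9))


class TestHitRate:
    @pytest.mark.parametrize(
        "hits, tested, percent, display",
        [(10, 21, 47.619047619047619, "48%"), (0, 21, 0.0, "0%"), (21, 21, 100.0, "100%")],
    )
    def test_values_and_display(self, hits, tested, percent, display):
        hr = hit_rate(hits, tested)
        assert hr.percent == pytest.approx(percent)
        assert hr.display == display

    def test_preconditions(self):
        with pytest.raises(DomainError):
            hit_rate(5, 0)
        with pytest.raises(DomainError):
            hit_rate(22, 21)


class TestSimulatedScreens:
    def test_perfect_sensitivity_and_specificity(self):
        o = simulate_screen(9, 9, sens=1.0, spec_=1.0, seed=0)
        assert (o.tp, o.fp, o.tn, o.fn) == (9, 0, 9, 0)

    def test_seed_determinism(self):
        o1 = simulate_screen(9, 9, sens=0.8, spec_=0.7, seed=42)
        o2 = simulate_screen(9, 9, sens=0.8, spec_=0.7, seed=42)
        assert o1 == o2

    def test_mean_enrichment_approaches_analytic_value(self):
        """Law of large numbers over many simulated screens."""
        sens, spec_ = 1.0, 8.0 / 9.0
        efs = []
        for seed in range(1000):
            o = simulate_screen(9, 9, sens, spec_, seed)
            if o.tp + o.fp > 0:
                efs.append(enrichment_factor(o))
        expected = np.mean(efs)
        # analytic EF for expected counts tp=9, fp=1
        assert expected == pytest.approx(1.8, abs=0.05)
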