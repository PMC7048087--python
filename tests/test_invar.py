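"""UMI consensus rules, background error estimation, the exact
binomial-tail oracle, aggregate likelihood, gmAF and the IR gate."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ctdnakit as ck
from ctdnakit import invar

LOCUS = ck.TargetLocus("chr1", 100, "C", "T", "ACA", tissue_maf=0.4)
LOCUS2 = ck.TargetLocus("chr1", 200, "G", "A", "TGC", tissue_maf=0.2)


def reads(entries):
    """entries: list of (umi, base) at locus 0."""
    return pd.DataFrame(
        {
            "locus_id": [0] * len(entries),
            "umi": [u for u, _ in entries],
            "base": [b for _, b in entries],
        }
    )


def model(rate=0.0, rates=None):
    return invar.BackgroundErrorModel(
        rates=rates or {}, counts={}, global_rate=rate
    )


class TestCollapseUMI:
    def test_singleton_family_dropped(self):
        piles = invar.collapse_umi(reads([("u1", "T")]), [LOCUS])
        assert piles[0].depth == 0

    def test_two_thirds_majority_discarded(self):
        """{A, A, C} reaches only 66.7% majority < 90%."""
        piles = invar.collapse_umi(
            reads([("u1", "T"), ("u1", "T"), ("u1", "C")]), [LOCUS]
        )
        assert piles[0].depth == 0

    def test_exact_ninety_percent_majority_kept(self):
        """{alt x9, other x1}: 90% exactly, inclusive, consensus = alt."""
        entries = [("u1", "T")] * 9 + [("u1", "C")]
        piles = invar.collapse_umi(reads(entries), [LOCUS])
        assert piles[0].depth == 1 and piles[0].mutant == 1

    def test_unanimous_pair_kept(self):
        piles = invar.collapse_umi(reads([("u1", "C"), ("u1", "C")]), [LOCUS])
        assert piles[0].depth == 1 and piles[0].mutant == 0

    def test_families_counted_per_locus(self):
        df = pd.DataFrame(
            {
                "locus_id": [0, 0, 1, 1],
                "umi": ["a", "a", "b", "b"],
                "base": ["C", "C", "A", "A"],
            }
        )
        piles = invar.collapse_umi(df, [LOCUS, LOCUS2])
        assert piles[0].depth == 1 and piles[1].depth == 1
        assert piles[1].mutant == 1  # locus2 alt is A


class TestBackgroundModel:
    def test_rate_is_pooled_ratio(self):
        piles = [
            invar.LocusPileup(LOCUS, depth=60_000, mutant=1),
            invar.LocusPileup(LOCUS, depth=40_000, mutant=1),
        ]
        bg = invar.estimate_background(piles)
        assert bg.rates["ACA>T"] == pytest.approx(2e-5)

    def test_thin_class_falls_back_to_global(self):
        piles = [
            invar.LocusPileup(LOCUS, depth=100_000, mutant=2),
            invar.LocusPileup(LOCUS2, depth=100, mutant=0),
        ]
        bg = invar.estimate_background(piles)
        assert "TGC>A" in bg.fallback_classes
        assert bg.rate_for("TGC>A") == bg.global_rate

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError):
            invar.estimate_background([invar.LocusPileup(LOCUS, 0, 0)])

    def test_simulator_rates_recovered(self):
        loci = (LOCUS,) * 1  # one class
        cfg = ck.SimulationConfig(
            seed=2, tumor_fraction=0.0, default_error_rate=5e-4, read_error_rate=0.0,
            umi_family_size_distribution=((3, 1.0),),
        )
        rds = ck.simulate_targeted_reads(cfg, loci, mean_depth=50_000, seed=3)
        piles = invar.collapse_umi(rds, loci)
        bg = invar.estimate_background(piles)
        d = piles[0].depth
        se = np.sqrt(5e-4 / d)
        assert abs(bg.rates["ACA>T"] - 5e-4) < 2 * se


def binom_tail_oracle(m, d, e):
    """Independent exact tail by direct summation of the pmf."""
    return sum(
        math.comb(d, k) * e**k * (1 - e) ** (d - k) for k in range(m, d + 1)
    )


class TestLocusSignificance:
    def test_zero_mutants_gives_one(self):
        p = invar.locus_significance(invar.LocusPileup(LOCUS, 100, 0), model(1e-4))
        assert p == 1.0

    def test_zero_error_rate_with_signal_gives_zero(self):
        p = invar.locus_significance(invar.LocusPileup(LOCUS, 100, 1), model(0.0))
        assert p == 0.0

    def test_deep_locus_tail_value(self):
        """d=10^4, e=1e-4, m=10: tail ~ 1.1e-7 (Poisson regime)."""
        p = invar.locus_significance(
            invar.LocusPileup(LOCUS, 10_000, 10), model(1e-4)
        )
        oracle = sum(
            math.exp(-1) / math.factorial(k) for k in range(10, 40)
        )  # Poisson(1) cross-check
        assert p == pytest.approx(1.14e-7, rel=0.05)
        assert p == pytest.approx(oracle, rel=0.05)

    @settings(deadline=None, max_examples=200)
    @given(
        d=st.integers(min_value=1, max_value=50),
        m_frac=st.floats(min_value=0, max_value=1),
        e=st.floats(min_value=1e-6, max_value=0.2),
    )
    def test_matches_enumeration_oracle(self, d, m_frac, e):
        m = int(round(m_frac * d))
        p = invar.locus_significance(invar.LocusPileup(LOCUS, d, m), model(e))
        assert p == pytest.approx(binom_tail_oracle(m, d, e), rel=1e-9, abs=1e-300)


class TestAggregateLikelihood:
    def test_all_zero_mutants_null_maximizer(self):
        piles = [invar.LocusPileup(LOCUS, 1000, 0), invar.LocusPileup(LOCUS2, 1000, 0)]
        score, f_hat = invar.aggregate_likelihood(piles, model(1e-4))
        assert f_hat == 0.0 and score == 0.0

    def test_single_locus_profile_fit(self):
        """d=10^4, e=1e-4, m=10: f_hat lands near m/d - e ~ 9e-4 and the
        likelihood-ratio score is positive."""
        piles = [invar.LocusPileup(LOCUS, 10_000, 10)]
        score, f_hat = invar.aggregate_likelihood(piles, model(1e-4))
        assert score > 0
        assert 5e-4 < f_hat < 1.5e-3

    def test_doubling_evidence_increases_score(self):
        bg = model(1e-4)
        s1, _ = invar.aggregate_likelihood([invar.LocusPileup(LOCUS, 10_000, 10)], bg)
        s2, _ = invar.aggregate_likelihood([invar.LocusPileup(LOCUS, 20_000, 20)], bg)
        assert s2 > s1

    def test_zero_depth_loci_excluded(self):
        piles = [invar.LocusPileup(LOCUS, 0, 0), invar.LocusPileup(LOCUS2, 1000, 3)]
        score, _ = invar.aggregate_likelihood(piles, model(1e-4))
        only = invar.aggregate_likelihood([piles[1]], model(1e-4))[0]
        # LOCUS2 weight changes (mean-1 normalization) but the signal is the same locus
        assert score > 0 and only > 0

    def test_all_zero_depth_rejected(self):
        with pytest.raises(ValueError):
            invar.aggregate_likelihood([invar.LocusPileup(LOCUS, 0, 0)], model(1e-4))


class TestThresholdGmafIR:
    def test_controls_all_zero_any_positive_detected(self):
        thr = invar.roc_threshold([0.0] * 20)
        assert thr == 0.0 and (0.5 > thr)

    def test_target_specificity_one_is_max(self):
        scores = [0.1, 0.9, 0.4, 0.2]
        assert invar.roc_threshold(scores, 1.0) == 0.9

    def test_quantile_threshold(self):
        scores = list(np.arange(100) / 100.0)
        thr = invar.roc_threshold(scores, 0.99)
        assert thr == pytest.approx(0.98)

    def test_gmaf_formulas(self):
        piles = [
            invar.LocusPileup(LOCUS, 1000, 10),
            invar.LocusPileup(LOCUS2, 1000, 0),
        ]
        assert invar.compute_gmaf(piles, model(0.0)) == pytest.approx(5.0e-3)
        assert invar.compute_gmaf(piles, model(1e-3)) == pytest.approx(4.0e-3)

    def test_gmaf_floored_at_zero(self):
        piles = [invar.LocusPileup(LOCUS, 1000, 1)]
        assert invar.compute_gmaf(piles, model(0.5)) == 0.0

    def test_ir_gate_boundaries(self):
        piles_ok = [invar.LocusPileup(LOCUS, 100, 0) for _ in range(200)]
        ir, fail = invar.informative_reads(piles_ok)
        assert ir == 20_000 and not fail
        piles_ok[0] = invar.LocusPileup(LOCUS, 99, 0)
        ir, fail = invar.informative_reads(piles_ok)
        assert ir == 19_999 and fail

    def test_few_loci_warning(self):
        with pytest.warns(UserWarning, match="99"):
            invar.informative_reads([invar.LocusPileup(LOCUS, 300, 0)] * 99)


class TestRunInvar:
    def test_technical_fail_never_detected(self):
        piles = [invar.LocusPileup(LOCUS, 100, 50)]  # strong signal, IR=100
        res = invar.run_invar(piles, model(1e-4), threshold=0.0)
        assert res.technical_fail and res.detected is False

    def test_signal_sample_detected_above_threshold(self):
        piles = [invar.LocusPileup(LOCUS, 200, 2) for _ in range(150)]
        res = invar.run_invar(piles, model(1e-4), threshold=5.0)
        assert not res.technical_fail and res.detected
        assert res.gmaf == pytest.approx(2 / 200 - 1e-4, rel=0.01)
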