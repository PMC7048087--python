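"""Size selection, length features (with the analytic comb oracle), and
the random-forest triage model."""

import numpy as np
import pandas as pd
import pytest

import ctdnakit as ck
from ctdnakit import fragmentomics as fx
from ctdnakit.lengths import LENGTH_MAX, LENGTH_MIN


def frags_with_lengths(lengths):
    lengths = np.asarray(lengths)
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.zeros(len(lengths), dtype=np.int64),
            "end": lengths.astype(np.int64),
            "length": lengths.astype(np.int64),
            "source": "normal",
            "umi": "",
            "locus_alleles": "",
        }
    )


class TestSizeSelect:
    def test_inclusive_boundaries(self):
        df = frags_with_lengths([89, 90, 150, 151])
        out = fx.size_select(df)
        assert sorted(out["length"]) == [90, 150]

    def test_empty_input(self):
        assert len(fx.size_select(frags_with_lengths([]))) == 0

    def test_idempotent(self, tiny_genome):
        df = ck.simulate_sample(ck.SimulationConfig(seed=1, n_fragments=20_000), tiny_genome)
        once = fx.size_select(df)
        twice = fx.size_select(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_enriches_tumor_fragments(self, tiny_genome):
        cfg = ck.SimulationConfig(seed=2, tumor_fraction=0.1, n_fragments=100_000)
        df = ck.simulate_sample(cfg, tiny_genome)
        before = (df["source"] == "tumor").mean()
        after = (fx.size_select(df)["source"] == "tumor").mean()
        assert after > before


class TestProportions:
    def test_all_in_range(self):
        hist = fx.LengthHistogram.from_fragments(frags_with_lengths([100] * 100))
        assert fx.proportion_in_range(hist, 20, 150) == 1.0

    def test_half_split(self):
        hist = fx.LengthHistogram.from_fragments(
            frags_with_lengths([100] * 50 + [200] * 50)
        )
        assert fx.proportion_in_range(hist, 20, 150) == 0.5

    def test_uniform_subrange_counting(self):
        hist = fx.LengthHistogram.from_fragments(
            frags_with_lengths(list(range(160, 181)))
        )
        assert fx.proportion_in_range(hist, 163, 169) == pytest.approx(7 / 21)

    def test_empty_histogram_errors(self):
        hist = fx.LengthHistogram(np.zeros(LENGTH_MAX - LENGTH_MIN + 1, dtype=int))
        with pytest.raises(ValueError):
            fx.proportion_in_range(hist, 20, 150)


class TestAmplitude10bp:
    def test_flat_comb_recovers_amplitude(self):
        """h(L) = c*(1 + 0.3*cos(2*pi*L/10)) on [76,150] reads ~0.3."""
        lengths = np.arange(LENGTH_MIN, LENGTH_MAX + 1)
        counts = np.zeros(len(lengths))
        sel = (lengths >= 76) & (lengths <= 150)
        counts[sel] = 1e6 * (1 + 0.3 * np.cos(2 * np.pi * lengths[sel] / 10))
        amp = fx.amplitude_10bp(fx.LengthHistogram(counts.round().astype(int)))
        assert amp == pytest.approx(0.3, rel=0.05)

    def test_smooth_density_near_zero(self):
        lengths = np.arange(LENGTH_MIN, LENGTH_MAX + 1)
        counts = (np.exp(-0.5 * ((lengths - 167) / 30.0) ** 2) * 1e7).astype(int)
        amp = fx.amplitude_10bp(fx.LengthHistogram(counts))
        assert amp < 0.01

    def test_monotone_in_simulator_periodicity(self, tiny_genome):
        amps = []
        for A in (0.0, 0.2):
            lm = ck.FragmentLengthModel(periodicity_amplitude=A)
            df = ck.simulate_sample(
                ck.SimulationConfig(seed=1, n_fragments=300_000, length_model=lm),
                tiny_genome,
            )
            amps.append(fx.amplitude_10bp(fx.LengthHistogram.from_fragments(df)))
        assert amps[1] > amps[0]


class TestFeatures:
    def test_ten_features_in_canonical_order(self, tiny_genome):
        df = ck.simulate_sample(ck.SimulationConfig(seed=1, n_fragments=5_000), tiny_genome)
        feats = fx.compute_features(df, 0.01)
        arr = feats.to_array()
        assert len(arr) == 10
        assert arr[0] == 0.01  # t_mad first
        assert fx.FEATURE_NAMES[0] == "t_mad"

    def test_deterministic(self, tiny_genome):
        df = ck.simulate_sample(ck.SimulationConfig(seed=1, n_fragments=5_000), tiny_genome)
        a = fx.compute_features(df, 0.01).to_array()
        b = fx.compute_features(df, 0.01).to_array()
        assert (a == b).all()

    def test_mononucleosome_peak_dominates_null_sample(self, tiny_genome):
        df = ck.simulate_sample(ck.SimulationConfig(seed=2, n_fragments=50_000), tiny_genome)
        f = fx.compute_features(df, 0.0)
        assert f.p_160_180 == max(f.p_160_180, f.p_20_150, f.p_100_150, f.p_180_220, f.p_250_320)

    def test_zero_denominator_sentinel(self):
        # all fragments short: P(160-180) = 0 while P(20-150) > 0
        df = frags_with_lengths([100] * 1000)
        feats = fx.compute_features(df, 0.0)
        assert feats.ratio_20_150_over_160_180 == fx.RATIO_SENTINEL
        assert "ratio_20_150_over_160_180" in feats.sentinel_flags

    def test_proportions_within_unit_interval(self, tiny_genome):
        df = ck.simulate_sample(ck.SimulationConfig(seed=3, n_fragments=5_000), tiny_genome)
        f = fx.compute_features(df, 0.0)
        for name in ("p_20_150", "p_160_180", "p_100_150", "p_180_220", "p_250_320"):
            assert 0.0 <= getattr(f, name) <= 1.0


def _feature_cohort(genome, n_per_class, seed0):
    """Synthetic triage cohort: controls vs tumor-shortened samples."""
    rows, labels = [], []
    for i in range(2 * n_per_class):
        cancer = i >= n_per_class
        tf = 0.15 if cancer else 0.0
        cfg = ck.SimulationConfig(
            seed=seed0 + i, tumor_fraction=tf, n_fragments=20_000
        )
        df = ck.simulate_sample(cfg, genome)
        feats = fx.compute_features(df, 0.02 if cancer else 0.002)
        rows.append(feats.to_array())
        labels.append(int(cancer))
    table = pd.DataFrame(rows, columns=fx.FEATURE_NAMES)
    return table, np.array(labels)


@pytest.fixture(scope="module")
def cohort(tiny_genome):
    return _feature_cohort(tiny_genome, 20, seed0=100)


class TestTriageModel:
    def test_separable_training_sample_scores_positive(self, cohort):
        table, labels = cohort
        model = fx.train_triage_model(table, labels, seed=0)
        feats_row = table.iloc[-1]
        feats = fx.FragmentomicsFeatures(**{n: feats_row[n] for n in fx.FEATURE_NAMES})
        res = fx.predict_triage(model, feats)
        assert res.probability_cancer > 0.5 and res.triaged_positive

    def test_fixed_seed_reproducible_predictions(self, cohort):
        table, labels = cohort
        m1 = fx.train_triage_model(table, labels, seed=7)
        m2 = fx.train_triage_model(table, labels, seed=7)
        p1 = m1.classifier.predict_proba(table[fx.FEATURE_NAMES].to_numpy())
        p2 = m2.classifier.predict_proba(table[fx.FEATURE_NAMES].to_numpy())
        assert (p1 == p2).all()

    def test_probability_exactly_half_not_triaged(self):
        class Stub:
            def predict_proba(self, X):
                return np.array([[0.5, 0.5]])

        model = fx.TriageModel(classifier=Stub(), seed=0)
        feats = fx.FragmentomicsFeatures(0, 0, 0, 0, 0, 0, 0, 0, 0, 0)
        res = fx.predict_triage(model, feats)
        assert res.probability_cancer == 0.5 and not res.triaged_positive

    def test_permuted_labels_near_chance(self, cohort, tiny_genome):
        table, labels = cohort
        rng = np.random.default_rng(5)
        perm = rng.permutation(labels)
        model = fx.train_triage_model(table.iloc[:30], perm[:30], seed=1, min_per_class=5)
        held = model.classifier.predict(table.iloc[30:][fx.FEATURE_NAMES].to_numpy())
        acc = (held == perm[30:]).mean()
        assert 0.2 <= acc <= 0.8

    def test_single_class_rejected(self, cohort):
        table, _ = cohort
        with pytest.raises(ValueError):
            fx.train_triage_model(table, np.zeros(len(table)), seed=0)


class TestSizeSelectedTMAD:
    def test_eligibility_gate_strictly_below_two_million(self, prepared_cna_controls):
        """1,999,999 post-selection fragments are ineligible; no score."""
        df = frags_with_lengths(np.full(1_999_999, 120))
        out = fx.size_selected_tmad(df, prepared_cna_controls)
        assert not out.eligible and out.result.tmad_score is None
        assert out.n_selected == 1_999_999

    def test_enrichment_above_one_for_short_tumor_fragments(
        self, genome2, rcc_like_scna, cna_controls, prepared_cna_controls
    ):
        from ctdnakit import cna

        prep_ss = cna.prepare_controls(
            [fx.size_select(c) for c in cna_controls],
            genome2, bin_bp=500_000, downsample_n=50_000, seed=2,
        )
        wins, ss_tumor, ss_null = 0, [], []
        for s in range(5):
            cfg = ck.SimulationConfig(
                seed=400 + s, tumor_fraction=0.1, n_fragments=400_000,
                scna_segments=rcc_like_scna, gc_bias_strength=0.3,
            )
            df = ck.simulate_sample(cfg, genome2)
            un = cna.score_sample(df, prepared_cna_controls, seed=5)
            ss = fx.size_selected_tmad(
                df, prep_ss, unselected_tmad=un.tmad_score,
                downsample_n=50_000, min_fragments=30_000, seed=6,
            )
            wins += ss.enrichment > 1
            ss_tumor.append(ss.result.tmad_score)
            cfg0 = ck.SimulationConfig(
                seed=500 + s, tumor_fraction=0.0, n_fragments=400_000,
                gc_bias_strength=0.3,
            )
            df0 = ck.simulate_sample(cfg0, genome2)
            ss0 = fx.size_selected_tmad(
                df0, prep_ss, downsample_n=50_000, min_fragments=30_000, seed=6,
            )
            ss_null.append(ss0.result.tmad_score)
        assert wins == 5
        # no mutant signal to enrich: null size-selected scores stay at
        # the noise floor, far below the tumor scores
        assert np.mean(ss_null) < np.mean(ss_tumor) / 5
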