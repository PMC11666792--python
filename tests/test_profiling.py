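"""Positional profiling: context tables, obs/exp oracle, smoothing, periods."""

import numpy as np
import pytest

from oxidoscape.genome import Genome, TRINUCLEOTIDES, TRINUC_INDEX
from oxidoscape.profiling import (
    NUCLEOSOME_CORE_HALFWIDTH,
    ROTATIONAL_BAND,
    TRANSLATIONAL_BAND,
    PositionalProfile,
    classify_rotational,
    estimate_period,
    event_context_frequency,
    fit_sinusoid,
    obs_exp_log2,
    savgol_smooth,
    tf_midpoint_profile,
    window_context_table,
)


class Ev:
    def __init__(self, contig, pos):
        self.contig, self.pos = contig, pos


def brute_force_profile(events, anchors, genome, W):
    """Independent enumeration oracle for O_j, E_j (pure python, O(n^2))."""
    offsets = list(range(-W, W + 1))
    # context occurrences per offset across windows
    n_c = {(c, j): 0 for c in TRINUCLEOTIDES for j in offsets}
    for contig, pos_list in anchors.items():
        for a in pos_list:
            for j in offsets:
                tri = genome.trinucleotide(contig, a + j)
                if tri is not None:
                    n_c[(tri, j)] += 1
    # genome-wide event context frequency
    genome_counts = {c: 0 for c in TRINUCLEOTIDES}
    for contig in genome.names:
        seq = genome[contig]
        for p in range(1, len(seq) - 1):
            tri = genome.trinucleotide(contig, p)
            if tri is not None:
                genome_counts[tri] += 1
    event_counts = {c: 0 for c in TRINUCLEOTIDES}
    for ev in events:
        tri = genome.trinucleotide(ev.contig, ev.pos)
        if tri is not None:
            event_counts[tri] += 1
    f = {c: (event_counts[c] / genome_counts[c] if genome_counts[c] else 0.0) for c in TRINUCLEOTIDES}
    O = {j: 0 for j in offsets}
    for ev in events:
        for a in anchors.get(ev.contig, []):
            j = ev.pos - a
            if -W <= j <= W:
                O[j] += 1
    E = {j: sum(f[c] * n_c[(c, j)] for c in TRINUCLEOTIDES) for j in offsets}
    return O, E


@pytest.fixture()
def tiny_genome():
    return Genome({"chrA": "ACGTGCATGGACCTGATCGATGCAGTCAGT", "chrB": "TTGACGTACGGTACGATCAA"})


class TestWindowContextTable:
    def test_single_interior_anchor_columns_sum_to_one(self, tiny_genome):
        mat = window_context_table({"chrA": np.array([10])}, tiny_genome, halfwidth=4)
        assert mat.shape == (64, 9)
        assert np.all(mat.sum(axis=0) == 1)

    def test_hand_enumeration_toy(self):
        g = Genome({"chrT": "ACGTACGTACGTACGTACGTA"})  # 21 bp
        mat = window_context_table({"chrT": np.array([10])}, g, halfwidth=3)
        for col, j in enumerate(range(-3, 4)):
            tri = g.trinucleotide("chrT", 10 + j)
            expect = np.zeros(64)
            expect[TRINUC_INDEX[tri]] = 1
            assert np.array_equal(mat[:, col], expect)

    def test_edge_clipping(self, tiny_genome):
        mat = window_context_table({"chrA": np.array([2])}, tiny_genome, halfwidth=5)
        sums = mat.sum(axis=0)
        # offsets -5..-2 map to positions < 1 (no full trinucleotide)
        assert list(sums[:4]) == [0, 0, 0, 0]
        assert np.all(sums[4:] == 1)

    def test_unknown_contig_skipped(self, tiny_genome):
        mat = window_context_table({"chrZ": np.array([5])}, tiny_genome, halfwidth=3)
        assert mat.sum() == 0


class TestEventContextFrequency:
    def test_frequency_arithmetic(self, tiny_genome):
        events = [Ev("chrA", 5)] * 3
        table = event_context_frequency(events, tiny_genome)
        tri = tiny_genome.trinucleotide("chrA", 5)
        idx = TRINUC_INDEX[tri]
        assert table.event_counts[idx] == 3
        assert table.frequency[idx] == pytest.approx(3 / table.genome_counts[idx])

    def test_conservation_identity(self, tiny_genome):
        events = [Ev("chrA", p) for p in (3, 5, 7, 11)] + [Ev("chrB", 4)]
        table = event_context_frequency(events, tiny_genome)
        assert np.sum(table.frequency * table.genome_counts) == pytest.approx(len(events))

    def test_no_events(self, tiny_genome):
        table = event_context_frequency([], tiny_genome)
        assert np.all(table.frequency == 0)


class TestObsExpOracle:
    def test_matches_brute_force_exactly(self, tiny_genome):
        anchors = {"chrA": np.array([8, 15]), "chrB": np.array([9])}
        events = [Ev("chrA", 6), Ev("chrA", 9), Ev("chrA", 16), Ev("chrB", 8), Ev("chrB", 11)]
        W = 5
        prof = obs_exp_log2(events, anchors, tiny_genome, W)
        O, E = brute_force_profile(events, anchors, tiny_genome, W)
        for col, j in enumerate(range(-W, W + 1)):
            assert prof.observed[col] == O[j]
            assert prof.expected[col] == pytest.approx(E[j], abs=1e-12)
            L = prof.log2_ratio[col]
            if O[j] > 0 and E[j] > 0:
                assert L == pytest.approx(np.log2(O[j] / E[j]), abs=1e-12)
            else:
                assert np.isnan(L)

    def test_observed_equals_expected_gives_zero(self):
        prof = PositionalProfile(np.arange(-3, 4), np.full(7, 4.0), np.full(7, 4.0))
        assert np.allclose(prof.log2_ratio, 0.0)

    def test_double_observed_gives_one(self):
        prof = PositionalProfile(np.arange(-1, 2), np.array([2.0, 4.0, 2.0]), np.full(3, 2.0))
        assert prof.log2_ratio[1] == pytest.approx(1.0)

    def test_no_anchors_is_error(self, tiny_genome):
        with pytest.raises(ValueError):
            obs_exp_log2([], {}, tiny_genome, 5)

    def test_accepts_one_shot_event_iterator(self, tiny_genome):
        anchors = {"chrA": np.array([8, 15])}
        events = [Ev("chrA", 6), Ev("chrA", 9), Ev("chrA", 16)]
        from_list = obs_exp_log2(events, anchors, tiny_genome, 5)
        from_iter = obs_exp_log2(iter(events), anchors, tiny_genome, 5)
        assert np.array_equal(from_list.observed, from_iter.observed)
        assert from_iter.observed.sum() > 0


class TestSavgol:
    def test_constant_preserved(self):
        out = savgol_smooth(np.full(300, 2.5))
        assert np.allclose(out, 2.5)

    def test_cubic_reproduced(self):
        x = np.arange(400, dtype=float)
        y = 1e-6 * x**3 - 2e-4 * x**2 + 0.05 * x - 1
        out = savgol_smooth(y)
        assert np.allclose(out, y, atol=1e-8)

    def test_interior_point_matches_direct_lsq_cubic(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=401)
        out = savgol_smooth(y, window=201, polyorder=3)
        j = 250
        xs = np.arange(j - 100, j + 101, dtype=float)
        coef = np.polyfit(xs, y[j - 100 : j + 101], 3)
        assert out[j] == pytest.approx(np.polyval(coef, j), abs=1e-9)

    def test_window_validation(self):
        with pytest.raises(ValueError):
            savgol_smooth(np.zeros(100), window=200)
        with pytest.raises(ValueError):
            savgol_smooth(np.zeros(100), window=201)


class TestEstimatePeriod:
    def test_pure_rotational_cosine(self):
        j = np.arange(-73, 74)
        vals = np.cos(2 * np.pi * j / 10.3)
        est = estimate_period((j, vals), ROTATIONAL_BAND, NUCLEOSOME_CORE_HALFWIDTH)
        assert est.period == pytest.approx(10.3, abs=0.05)
        assert est.significant

    def test_pure_translational_cosine(self):
        j = np.arange(-500, 501)
        vals = np.cos(2 * np.pi * j / 192.0)
        est = estimate_period((j, vals), TRANSLATIONAL_BAND)
        assert est.period == pytest.approx(192.0, abs=1.0)

    def test_constant_profile_not_significant(self):
        j = np.arange(-500, 501)
        est = estimate_period((j, np.full(len(j), 1.7)), TRANSLATIONAL_BAND)
        assert est.power <= 1e-12 and not est.significant

    def test_missing_offsets_tolerated(self):
        j = np.arange(-73, 74)
        vals = np.cos(2 * np.pi * j / 11.0)
        vals[::7] = np.nan
        est = estimate_period((j, vals), ROTATIONAL_BAND)
        assert est.period == pytest.approx(11.0, abs=0.05)

    def test_band_shorter_than_three_cycles_rejected(self):
        j = np.arange(-10, 11)
        with pytest.raises(ValueError):
            estimate_period((j, np.cos(j / 3)), TRANSLATIONAL_BAND)


class TestFitSinusoid:
    def test_noiseless_parameter_recovery(self):
        j = np.arange(-73, 74)
        vals = 0.1 + 0.5 * np.cos(2 * np.pi * j / 10.3)
        fit = fit_sinusoid((j, vals), period=10.3)
        assert fit.amplitude == pytest.approx(0.5, abs=1e-3)
        assert fit.offset == pytest.approx(0.1, abs=1e-3)
        assert abs(fit.phase) < 1e-3

    def test_free_period_recovery(self):
        j = np.arange(-73, 74)
        vals = 0.5 * np.cos(2 * np.pi * j / 10.3 + 0.7)
        fit = fit_sinusoid((j, vals), band=ROTATIONAL_BAND)
        assert fit.period == pytest.approx(10.3, abs=0.05)
        assert fit.phase == pytest.approx(0.7, abs=0.05)

    def test_flat_profile_zero_amplitude(self):
        j = np.arange(-73, 74)
        fit = fit_sinusoid((j, np.zeros(len(j))), period=10.3)
        assert fit.amplitude <= 1e-6

    def test_phase_shift_equivariance(self):
        j = np.arange(-73, 74)
        base = fit_sinusoid((j, np.cos(2 * np.pi * j / 10.3)), period=10.3)
        shift = fit_sinusoid((j, np.cos(2 * np.pi * (j - 2) / 10.3)), period=10.3)
        dphi = (shift.phase - base.phase) % (2 * np.pi)
        # rightward shift by d decreases the phase by 2*pi*d/P
        assert dphi == pytest.approx((-2 * np.pi * 2 / 10.3) % (2 * np.pi), abs=1e-6)


class TestClassifyRotational:
    def test_maxima_inward_minima_outward(self):
        j = np.arange(-73, 74)
        fit = fit_sinusoid((j, np.cos(2 * np.pi * j / 10.3)), period=10.3)
        labels = classify_rotational(np.array([0.0, 10.3 / 2]), fit)
        assert labels[0] == "inward" and labels[1] == "outward"

    def test_insignificant_fit_gives_intermediate(self):
        j = np.arange(-73, 74)
        fit = fit_sinusoid((j, np.zeros(len(j))), period=10.3)
        fit.significant = False
        assert set(classify_rotational(j, fit)) == {"intermediate"}

    def test_planted_phase_recovery(self):
        """Events planted with a rotational phase label >= 95% of true-phase
        inward offsets as inward."""
        from oxidoscape.synthetic import (
            SyntheticConfig,
            make_annotation_fixtures,
            make_reference,
            plant_events,
        )

        cfg = SyntheticConfig(
            seed=13, contig_lengths={"chrS1": 1_000_000},
            rotational_amplitude=0.6, n_events=30_000,
        )
        g = make_reference(cfg)
        tr = make_annotation_fixtures(cfg, g)
        truth = plant_events(cfg, g, tr)
        events = [Ev(c, p) for c, p in zip(truth.events.contig, truth.events.pos)]
        prof = obs_exp_log2(events, tr.dyads, g, 500)
        fit = fit_sinusoid(prof, band=ROTATIONAL_BAND, offsets_restriction=73)
        core = np.arange(-73, 74)
        labels = classify_rotational(core, fit)
        true_phase = np.cos(2 * np.pi * core / cfg.rotational_period)
        true_inward = core[true_phase > 0.2]  # clearly inward offsets
        recovered = labels[np.isin(core, true_inward)]
        assert np.mean(recovered == "inward") >= 0.95


class TestTfProfile:
    def test_zero_events_zero_profile(self, tiny_genome):
        df = tf_midpoint_profile([], {"chrA": np.array([10])}, halfwidth=5, smooth=False)
        assert df["count"].sum() == 0

    def test_conservation_under_nearest_assignment(self, tiny_genome):
        sites = {"chrA": np.array([8, 20])}
        events = [Ev("chrA", p) for p in (5, 9, 14, 14, 25, 29)]
        df = tf_midpoint_profile(events, sites, halfwidth=5, smooth=False)
        within = sum(1 for e in events if min(abs(e.pos - 8), abs(e.pos - 20)) <= 5)
        assert df["count"].sum() == within

    def test_tie_goes_to_leftmost(self, tiny_genome):
        sites = {"chrA": np.array([8, 12])}
        df = tf_midpoint_profile([Ev("chrA", 10)], sites, halfwidth=5, smooth=False)
        # offset recorded relative to the left midpoint: 10 - 8 = +2
        assert df.loc[df.offset == 2, "count"].iloc[0] == 1

    def test_uniform_events_flat_within_poisson_band(self, small_genome):
        rng = np.random.default_rng(17)
        L = small_genome.length("chrS1")
        # well-separated midpoints so every offset has full site coverage
        sites = {"chrS1": np.arange(1000, L - 1000, 2500)}
        events = [Ev("chrS1", int(p)) for p in rng.integers(500, L - 500, size=50_000)]
        df = tf_midpoint_profile(events, sites, halfwidth=500, smooth=False)
        counts = df["count"].to_numpy()
        mu = counts.mean()
        assert np.all(np.abs(counts - mu) <= 4 * np.sqrt(mu) + 1)

    def test_no_sites_is_error(self):
        with pytest.raises(ValueError):
            tf_midpoint_profile([], {}, halfwidth=5)
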