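"""Generator correctness: waveform anchors, Poisson noise model,
hierarchical populations, and NB count moments."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cardiotransit.params import (
    CONCORDANCE_PRESETS,
    IMAGING_PRESETS,
    AcquisitionParams,
    ConcordancePreset,
    CountSimParams,
    PopulationPreset,
    TransientParams,
    preset_without_noise,
)
from cardiotransit.simulate import (
    batch_sizes,
    draw_population_params,
    gen_cell_population,
    gen_counts,
    gen_de_tables,
    gen_linescan,
    gen_transient_waveform,
    poisson_rows,
)
from cardiotransit.transients import detect_baseline, measure_transient


DT = 1.0 / 1057.7


class TestWaveform:
    def test_amplitude_one_gives_constant_baseline(self):
        p = TransientParams(1.0, 150.0, 500.0, baseline_f0=40.0)
        w = gen_transient_waveform(p, DT, 4.0)
        assert np.all(w == 40.0)

    @pytest.mark.parametrize(
        "amp,rise,dec",
        [(2.8, 169.5, 603.5), (3.5, 199.0, 460.8), (1.5, 80.0, 200.0), (5.0, 400.0, 900.0)],
    )
    def test_analyzer_recovers_parameters_on_noiseless_waveform(self, amp, rise, dec):
        """The 15%-onset / peak / half-decay definitions invert the generator
        exactly (closed-form anchors), to within the sampling period."""
        p = TransientParams(amp, rise, dec)
        w = gen_transient_waveform(p, DT, 4.0)
        t = np.arange(w.size) * DT
        m = measure_transient(t, w, baseline=p.baseline_f0)
        assert m.amplitude / p.baseline_f0 == pytest.approx(amp, rel=1e-3)
        assert m.rise_time_ms == pytest.approx(rise, abs=DT * 1000)
        assert m.decay50_ms == pytest.approx(dec, abs=DT * 1000)

    def test_wt_preset_peak_ratio(self, wt_params):
        w = gen_transient_waveform(wt_params, DT, 4.0)
        # sampled maximum sits within dt of the true peak
        assert w.max() / wt_params.baseline_f0 == pytest.approx(2.8, abs=1e-4)

    def test_epoch_fit_invariant_rejected(self):
        with pytest.raises(ValueError, match="epoch"):
            TransientParams(2.0, 500.0, 2000.0, pacing_hz=0.25)

    def test_bad_sampling_arguments(self, wt_params):
        with pytest.raises(ValueError):
            gen_transient_waveform(wt_params, 0.0, 4.0)
        with pytest.raises(ValueError):
            gen_transient_waveform(wt_params, DT, 1.0)  # below one epoch


class TestLineScan:
    def test_noiseless_mean_equals_waveform(self, wt_params, small_acq):
        rec = gen_linescan(wt_params, small_acq, seed=0, noise=False)
        w = gen_transient_waveform(wt_params, small_acq.dt, small_acq.duration_s)
        assert np.allclose(rec.intensity.mean(axis=1), w, rtol=0, atol=1e-9)

    def test_poisson_variance_matches_mean(self, wt_params):
        """Per-pixel noise is Poisson: on resting lines (constant rate) the
        pooled sample variance equals the sample mean within 3 SE."""
        acq = AcquisitionParams(n_pixels=128, n_lines=4300)
        rec = gen_linescan(wt_params, acq, seed=7, noise=True)
        rest = rec.intensity[:800]  # pre-stimulus fifth of the first epoch
        x = rest.ravel()
        assert x.size >= 1e4
        lam = wt_params.baseline_f0
        # Var(s^2) for Poisson ~ (lam + 2 lam^2)/n
        se = np.sqrt((lam + 2 * lam**2) / x.size)
        assert abs(x.var(ddof=1) - x.mean()) < 3 * se

    def test_default_acquisition_shape(self, wt_params, full_acq):
        rec = gen_linescan(wt_params, full_acq, seed=0, noise=False)
        assert rec.intensity.shape == (20000, 512)

    def test_alias_sampler_matches_poisson_distribution(self, rng):
        lam = 77.3
        draws = poisson_rows(np.full(2000, lam), 512, rng).astype(int)
        vals, counts = np.unique(draws, return_counts=True)
        emp = counts / draws.size
        theory = sps.poisson.pmf(vals, lam)
        assert np.abs(emp - theory).max() < 5e-4
        assert draws.mean() == pytest.approx(lam, rel=0.01)

    def test_fixed_seed_reproducible(self, wt_params, small_acq):
        a = gen_linescan(wt_params, small_acq, seed=3).intensity
        b = gen_linescan(wt_params, small_acq, seed=3).intensity
        assert np.array_equal(a, b)

    def test_nonpositive_gain_rejected(self):
        with pytest.raises(ValueError):
            AcquisitionParams(photon_gain=0.0)


class TestPopulation:
    def test_degenerate_variance_reproduces_means(self):
        preset = preset_without_noise(IMAGING_PRESETS["WT"])
        cells = draw_population_params(preset, 9, seed=0)
        assert np.all(cells["amplitude_peak"] == 2.8)
        assert np.all(cells["rise_time_ms"] == 169.5)
        assert np.all(cells["decay50_ms"] == 603.5)

    def test_batch_split_near_even(self):
        assert batch_sizes(181, 3) == [61, 60, 60]
        cells = draw_population_params(IMAGING_PRESETS["WT"], 181, seed=0)
        assert cells["batch"].value_counts().sort_index().tolist() == [61, 60, 60]

    def test_population_mean_converges_to_preset(self):
        """CLT oracle: the sample mean of ground-truth amplitudes at n = 181
        lies within 2 SE of the preset mean (SE includes the batch level)."""
        preset = IMAGING_PRESETS["WT"]
        cells = draw_population_params(preset, 181, seed=11)
        mu = preset.metric_mean("amplitude_peak")
        se = np.sqrt(
            (preset.cv_between_cell["amplitude_peak"] * mu) ** 2 / 181
            + preset.sd_between_diff["amplitude_peak"] ** 2 / preset.n_diff
        )
        assert abs(cells["amplitude_peak"].mean() - mu) < 2 * se

    def test_streaming_population_carries_labels(self, small_acq):
        recs = list(
            gen_cell_population(IMAGING_PRESETS["KO"], 3, small_acq, seed=0, noise=False)
        )
        assert [r.metadata["batch"] for r in recs] == [0, 1, 2]
        assert all(r.metadata["group"] == "KO" for r in recs)
        assert all("ground_truth" in r.metadata for r in recs)

    def test_requires_at_least_one_cell_per_batch(self, small_acq):
        with pytest.raises(ValueError):
            draw_population_params(IMAGING_PRESETS["WT"], 2, seed=0)


def _count_params(n_genes=400, dispersion=0.05, effects=None, base_mean=None, sf=(1.0, 1.0)):
    design = {f"c{i}": "A" for i in range(4)} | {f"t{i}": "B" for i in range(4)}
    return CountSimParams(
        n_genes=n_genes,
        design=design,
        stages=("A", "B"),
        dispersion=dispersion,
        size_factor_range=sf,
        planted_effects=effects or {},
        base_mean=base_mean,
    )


class TestCounts:
    def test_null_poisson_group_means_agree(self):
        params = _count_params(dispersion=0.0, base_mean=500.0)
        cm = gen_counts(params, seed=0)
        a = cm.counts[[s for s in cm.counts if cm.groups[s] == "A"]].to_numpy().mean()
        b = cm.counts[[s for s in cm.counts if cm.groups[s] == "B"]].to_numpy().mean()
        assert a == pytest.approx(b, rel=0.01)
        x = cm.counts.to_numpy().ravel()
        assert x.var() / x.mean() == pytest.approx(1.0, rel=0.05)

    def test_planted_log2fc_two_gives_ratio_four(self):
        params = _count_params(
            n_genes=200, dispersion=0.01, base_mean=2000.0,
            effects={g: {"B": 2.0} for g in range(200)},
        )
        cm = gen_counts(params, seed=1)
        a = cm.counts[[s for s in cm.counts if cm.groups[s] == "A"]].to_numpy().mean()
        b = cm.counts[[s for s in cm.counts if cm.groups[s] == "B"]].to_numpy().mean()
        assert b / a == pytest.approx(4.0, rel=0.03)

    def test_nb_moments(self, rng):
        """Var/mean of NB draws ~ 1 + alpha*mu = 11 at mu=100, alpha=0.1."""
        mu, alpha = 100.0, 0.1
        r = 1 / alpha
        x = rng.negative_binomial(r, r / (r + mu), size=100_000)
        assert x.var() / x.mean() == pytest.approx(1 + alpha * mu, rel=0.10)
        # and through the generator itself
        params = _count_params(n_genes=12500, dispersion=alpha, base_mean=mu)
        cm = gen_counts(params, seed=2)
        y = cm.counts.to_numpy().ravel()
        assert y.var() / y.mean() == pytest.approx(1 + alpha * mu, rel=0.10)

    def test_counts_are_nonnegative_integers(self):
        cm = gen_counts(_count_params(), seed=3)
        arr = cm.counts.to_numpy()
        assert np.all(arr >= 0) and np.issubdtype(arr.dtype, np.integer)

    def test_empty_design_rejected(self):
        with pytest.raises(ValueError):
            CountSimParams(n_genes=5, design={}, stages=("A",))


@pytest.fixture(scope="module")
def small_tables():
    preset = ConcordancePreset(n_genes=1500, n_planted=8)
    return gen_de_tables(preset, seed=5)


class TestDeTables:
    def test_ortholog_map_is_bijection(self, small_tables):
        _, _, ortho, _ = small_tables
        assert ortho["human_id"].is_unique and ortho["mouse_id"].is_unique
        assert (ortho["mapping_type"] == "one2one").all()

    def test_planted_gene_effects_match_preset(self, small_tables):
        _, _, _, truth = small_tables
        assert truth.loc[0, "human_lfc_ch"] == 1.6
        assert truth.loc[0, "human_lfc_hf"] == 2.6
        assert truth.loc[0, "mouse_lfc_ch"] == 1.5
        assert truth.loc[0, "mouse_lfc_hf"] == 2.3

    def test_planted_flags_and_estimates(self, small_tables):
        human, mouse, _, _ = small_tables
        assert human["planted"].sum() == 8
        # planted CRISPLD1-like gene estimated near its true effect
        assert human.iloc[0]["log2fc_ch"] == pytest.approx(1.6, abs=0.5)
        assert human.iloc[0]["q_ch"] < 0.05

    def test_pure_null_preset_has_no_conserved_genes(self):
        from cardiotransit.concordance import conserved_set, join_orthologs

        human, mouse, ortho, _ = gen_de_tables(
            ConcordancePreset(n_genes=1500, n_planted=0), seed=9
        )
        cs = conserved_set(join_orthologs(human, mouse, ortho))
        assert len(cs) <= 1
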