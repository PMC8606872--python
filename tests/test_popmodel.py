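"""Neural binding model: encoding, decoding, simulation, likelihood."""

import numpy as np
import pytest

from vwmbind import popmodel, taskgen
from vwmbind.circstats import abs_error_correlation, circ_dist, circular_sd, v_test, wrap
from vwmbind.popmodel import (
    PopulationGrid,
    PopulationParams,
    conditional_density,
    mean_rates,
    ml_decode_item,
    response_log_likelihood,
    retrieval_plan,
    sample_spikes,
    simulate_reports,
)

PARAMS = PopulationParams(gamma=100.0, kappa_loc=8.0, kappa_col=4.0, kappa_ori=4.0)
DIMS = ("location", "color")


class TestMeanRates:
    @pytest.mark.parametrize("n_items", [1, 3, 6, 8])
    @pytest.mark.parametrize("m_side", [24, 32])
    def test_total_expected_count_is_gamma(self, n_items, m_side, rng):
        grid = PopulationGrid(m_side)
        total = 0.0
        for _ in range(n_items):
            item = rng.uniform(-np.pi, np.pi, 2)
            total += mean_rates(tuple(item), PARAMS, grid, n_items, DIMS).sum()
        assert total == pytest.approx(PARAMS.gamma, rel=1e-3)

    def test_flat_tuning_limit(self):
        p = PopulationParams(60.0, 1e-9, 1e-9, 1e-9)
        grid = PopulationGrid(16)
        r = mean_rates((0.3, -1.0), p, grid, 6, DIMS)
        assert np.allclose(r, 60.0 / (6 * grid.M), rtol=1e-6)

    def test_peak_at_nearest_lattice_point(self, rng):
        grid = PopulationGrid(32)
        p = PopulationParams(100.0, 5.0, 5.0, 5.0)
        for _ in range(10):
            item = rng.uniform(-np.pi, np.pi, 2)
            r = mean_rates(tuple(item), p, grid, 6, DIMS)
            pref = np.stack(grid.preferred(), axis=1)
            d = np.abs(wrap(pref - item)).max(axis=1)
            # argmax neuron is the lattice point nearest the item (chebyshev)
            assert d[np.argmax(r)] <= np.pi / 32 + 1e-12

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            PopulationParams(0.0, 1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            PopulationParams(1.0, -1.0, 1.0, 1.0)


class TestSampleSpikes:
    def test_zero_rate_zero_count(self, rng):
        assert np.all(sample_spikes(np.zeros(50), rng) == 0)

    def test_poisson_moments(self, rng):
        x = sample_spikes(np.full(100_000, 3.0), rng)
        assert x.mean() == pytest.approx(3.0, abs=0.05)
        assert x.var() == pytest.approx(3.0, abs=0.1)

    def test_negative_rate_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_spikes(np.array([-0.1]), rng)


class TestMLDecode:
    def test_single_spike_decodes_preferred(self, rng):
        grid = PopulationGrid(16)
        pref_psi, pref_theta = grid.preferred()
        counts = np.zeros(grid.M, int)
        counts[37] = 1
        psi, theta = ml_decode_item(counts, PARAMS, grid, DIMS, rng)
        assert psi == pytest.approx(pref_psi[37], abs=1e-9)
        assert theta == pytest.approx(pref_theta[37], abs=1e-9)

    def test_two_spikes_decode_midpoint(self, rng):
        # closed-form check: resultant direction of preferred 0.4 and 0.8
        grid = PopulationGrid(32)
        pref_psi, pref_theta = grid.preferred()
        counts = np.zeros(grid.M, int)
        i1 = np.argmin(np.abs(pref_psi - 0.4) + np.abs(pref_theta - 0.0))
        i2 = np.argmin(np.abs(pref_psi - 0.8) + np.abs(pref_theta - 0.0))
        counts[i1] = counts[i2] = 1
        psi, _ = ml_decode_item(counts, PARAMS, grid, DIMS, rng)
        mid = 0.5 * (pref_psi[i1] + pref_psi[i2])
        assert psi == pytest.approx(mid, abs=1e-9)

    def test_brute_force_grid_oracle(self, rng):
        # independent oracle: scan the decode objective
        # sum_i r_i * kappa * cos(psi - psi'_i) on a 1e-4 grid
        grid = PopulationGrid(16)
        pref_psi, _ = grid.preferred()
        scan = np.arange(-np.pi, np.pi, 1e-4)
        worst = 0.0
        for _ in range(20):
            counts = rng.poisson(0.05, grid.M)
            if counts.sum() == 0 or abs(np.sum(counts * np.exp(1j * pref_psi))) < 1e-9:
                continue
            psi, _ = ml_decode_item(counts, PARAMS, grid, DIMS, rng)
            obj = np.zeros_like(scan)
            for i in np.flatnonzero(counts):
                obj += counts[i] * np.cos(scan - pref_psi[i])
            worst = max(worst, abs(circ_dist(scan[np.argmax(obj)], psi)))
        assert worst < 2e-3

    def test_zero_spikes_uniform_guess(self):
        grid = PopulationGrid(8)
        rng = np.random.default_rng(5)
        psis = [
            ml_decode_item(np.zeros(grid.M, int), PARAMS, grid, DIMS, rng)[0]
            for _ in range(2000)
        ]
        _, p = v_test(psis, 0.0)
        assert p > 0.01


class TestSimulateReports:
    def test_noiseless_limit(self, rng):
        ds = taskgen.generate_experiment(
            taskgen.exp1_design(n_trials=252, trials_per_block=36), rng
        )
        sharp = PopulationParams(1e6, 50.0, 50.0, 50.0)
        resp = simulate_reports(ds, sharp, "spatial", rng)
        ds = ds.with_responses(resp)
        err = np.concatenate([ds.errors(0), ds.errors(1)])
        assert np.mean(np.abs(err) < 0.05) > 0.99

    def test_spatial_location_cue_errors_independent(self, rng):
        # direct retrieval from separate populations: conditional on the
        # trial, the two reports' errors are independent
        design = taskgen.exp1_design(n_trials=36)
        base = taskgen.generate_experiment(design, rng)
        big = base.subset(np.tile(np.arange(36), 600))  # same trials repeated
        resp = simulate_reports(big, PARAMS, "spatial", rng)
        big = big.with_responses(resp)
        # within fixed trials, abs-error correlation should vanish
        r = abs_error_correlation(big.errors(0), big.errors(1))
        assert abs(r) < 0.02

    def test_swap_mechanism_orientation_cue(self, rng):
        # spatial binding with an orientation cue retrieves color through
        # the decoded location: when the intermediary location selects a
        # nontarget, the color response clusters on that nontarget's color
        design = taskgen.exp2_design()
        ds = taskgen.generate_multi_participant(design, 8, rng)
        resp, details = simulate_reports(
            ds, PARAMS, "spatial", rng, return_details=True
        )
        ds = ds.with_responses(resp)
        sel = details["selected"]
        # stage 0 selects on orientation; its output is the location report
        swap = sel[:, 0] != ds.target_index
        assert 0.01 < swap.mean() < 0.5
        items = np.arange(ds.n_trials)
        col_of_selected = ds.colors[items, sel[:, 0]]
        dev = np.abs(circ_dist(ds.responses[:, 0], col_of_selected))
        mad_swap = float(np.mean(dev[swap]))
        err_col = np.abs(ds.errors(0))
        mad_target = float(np.mean(err_col[~swap]))
        assert mad_swap < np.pi / 2 - 0.1
        assert mad_swap == pytest.approx(mad_target, abs=0.1)

    def test_incompatible_variant_rejected(self, rng):
        ds = taskgen.generate_experiment(taskgen.exp1_design(n_trials=36), rng)
        with pytest.raises(ValueError):
            retrieval_plan("spatial", "color", ("location", "orientation"))
        with pytest.raises(ValueError):
            simulate_reports(ds, PARAMS, "no_such_variant", rng)


class TestConditionalDensity:
    def test_normalizes(self, rng):
        trial = taskgen.generate_array(taskgen.exp1_design(), rng)
        grid, dens = conditional_density(
            PARAMS, ("location", "color"), 0.5, trial, 128
        )
        total = np.trapezoid(np.append(dens, dens[0]), np.append(grid, np.pi))
        assert total == pytest.approx(1.0, abs=1e-3)

    def test_resolution_floor(self, rng):
        trial = taskgen.generate_array(taskgen.exp1_design(), rng)
        with pytest.raises(ValueError):
            conditional_density(PARAMS, ("location", "color"), 0.0, trial, 16)

    def test_uninformative_cue_mixes_all_items(self, rng):
        # kappa_cue -> 0: selection carries no information, so the density
        # approaches an equal mixture over the items' report features
        trial = taskgen.generate_array(taskgen.exp1_design(), rng)
        p = PopulationParams(100.0, 1e-2, 8.0, 8.0)
        grid, dens = conditional_density(p, ("location", "color"), 0.0, trial, 256)
        cols = trial.colors[0]
        peak_heights = [np.interp(c, grid, dens, period=2 * np.pi) for c in cols]
        # every item contributes a comparable peak
        assert min(peak_heights) > 0.3 * max(peak_heights)

    def test_matches_simulation_histogram(self, rng):
        # chain equivalence: simulated responses vs quadrature density
        trial = taskgen.generate_array(taskgen.exp2_design(), rng)
        big = trial.subset(np.zeros(30_000, int))
        resp = simulate_reports(big, PARAMS, "spatial", rng)
        grid, dens = conditional_density(
            PARAMS,
            ("orientation", "location"),
            float(trial.cue_values()[0]),
            trial,
            256,
        )
        hist, edges = np.histogram(
            resp[:, 1], bins=64, range=(-np.pi, np.pi), density=True
        )
        centers = 0.5 * (edges[:-1] + edges[1:])
        tv = 0.5 * np.sum(
            np.abs(hist - np.interp(centers, grid, dens, period=2 * np.pi))
        ) * (2 * np.pi / 64)
        assert tv < 0.05


class TestResponseLogLikelihood:
    def test_guessing_limit(self, rng):
        # gamma -> 0: every decode is a uniform guess, per-trial joint
        # density is (1/2pi)^2
        ds = taskgen.generate_experiment(taskgen.exp1_design(n_trials=36), rng)
        ds = ds.with_responses(rng.uniform(-np.pi, np.pi, (36, 2)))
        tiny = PopulationParams(1e-6, 4.0, 4.0, 4.0)
        ll = response_log_likelihood(ds, tiny, "spatial")
        assert ll / 36 == pytest.approx(2 * np.log(1.0 / (2 * np.pi)), abs=1e-3)

    def test_rotation_invariance(self, exp1_dataset):
        ll0 = response_log_likelihood(exp1_dataset, PARAMS, "spatial")
        shift = 1.1
        ds = exp1_dataset
        from vwmbind.dataset import Dataset

        rot = Dataset(
            locations=wrap(ds.locations + shift),
            colors=wrap(ds.colors + shift),
            orientations=wrap(ds.orientations + shift),
            cue_dim=ds.cue_dim,
            report_dims=ds.report_dims,
            target_index=ds.target_index,
            delay=ds.delay,
            responses=wrap(ds.responses + shift),
            participant=ds.participant,
            block=ds.block,
        )
        ll1 = response_log_likelihood(rot, PARAMS, "spatial")
        assert ll1 == pytest.approx(ll0, abs=0.1)

    def test_duplication_doubles_ll(self, exp1_dataset):
        ll = response_log_likelihood(exp1_dataset, PARAMS, "spatial")
        doubled = exp1_dataset.subset(np.tile(np.arange(216), 2))
        ll2 = response_log_likelihood(doubled, PARAMS, "spatial")
        assert ll2 == pytest.approx(2 * ll, rel=1e-6)

    def test_true_variant_attains_highest_ll(self, exp1_dataset):
        lls = {
            v: response_log_likelihood(exp1_dataset, PARAMS, v)
            for v in popmodel.VARIANTS
        }
        assert max(lls, key=lls.get) == "spatial"


class TestModelProperties:
    def test_decode_sd_shrinks_with_gamma(self, rng):
        # decoding consistency: more spikes, tighter decodes
        sds = []
        for gamma in (10.0, 100.0, 1000.0, 10_000.0):
            p = PopulationParams(gamma, 8.0, 8.0, 8.0)
            sds.append(popmodel.decoding_sd(p, "color", 6))
        assert all(a > b for a, b in zip(sds, sds[1:]))

    def test_swap_rate_grows_as_cue_kappa_falls(self, rng):
        design = taskgen.exp1_design(n_trials=2016, trials_per_block=36)
        ds = taskgen.generate_experiment(design, rng)
        rates = []
        for kl in (32.0, 8.0, 2.0):
            # moderate spike budget so that selection errors actually occur
            p = PopulationParams(50.0, kl, 4.0, 4.0)
            _, det = simulate_reports(
                ds, p, "spatial", np.random.default_rng(77), return_details=True
            )
            rates.append(np.mean(det["selected"][:, 0] != ds.target_index))
        assert rates[0] < rates[1] < rates[2]

    def test_joint_error_density_factorizes(self, rng):
        # Exp 1 spatial binding: joint error density = product of marginals
        design = taskgen.exp1_design(n_trials=36)
        base = taskgen.generate_experiment(design, rng)
        big = base.subset(np.tile(np.arange(36), 2800))
        resp = simulate_reports(big, PARAMS, "spatial", rng)
        big = big.with_responses(resp)
        e1, e2 = big.errors(0), big.errors(1)
        bins = 8
        h2, _, _ = np.histogram2d(
            e1, e2, bins=bins, range=[[-np.pi, np.pi]] * 2, density=True
        )
        h1a = np.histogram(e1, bins=bins, range=(-np.pi, np.pi), density=True)[0]
        h1b = np.histogram(e2, bins=bins, range=(-np.pi, np.pi), density=True)[0]
        outer = np.outer(h1a, h1b)
        cell = (2 * np.pi / bins) ** 2
        tv = 0.5 * np.sum(np.abs(h2 - outer)) * cell
        assert tv < 0.03
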