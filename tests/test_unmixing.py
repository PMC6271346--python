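"""Unmixing engine: NNLS abundances, bounded ratio optimization, protocols."""

import numpy as np
import pandas as pd
import pytest

import plfatax as px
from plfatax.profiles import REFERENCE_FA
from plfatax.unmixing import _row_normalize

from conftest import simplex_grid_argmin


def sample_from(R: px.TaxonRatioMatrix, weights: dict[str, float]) -> pd.Series:
    """Noise-free mixture of row-normalized taxon signatures."""
    Fn = _row_normalize(R.values)
    w = np.array([weights.get(t, 0.0) for t in R.taxa])
    return pd.Series(w @ Fn, index=R.fas)


class TestSolveAbundances:
    def test_pure_taxon_recovered_exactly(self, ratio_input):
        for taxon in ("Diatoms", "Proteobacteria"):
            s = sample_from(ratio_input, {taxon: 1.0})
            a, resid = px.solve_abundances(ratio_input, s)
            assert a[taxon] == pytest.approx(1.0, abs=1e-9)
            assert resid < 1e-12

    def test_green_diatom_even_mixture(self, ratio_input):
        """50:50 green algae / diatom mixture is recovered to 1e-6 and
        matches the exhaustive simplex grid oracle."""
        R2 = ratio_input.restrict(["Green algae", "Diatoms"])
        s = sample_from(R2, {"Green algae": 0.5, "Diatoms": 0.5})
        a, _ = px.solve_abundances(R2, s)
        assert a["Green algae"] == pytest.approx(0.5, abs=1e-6)
        assert a["Diatoms"] == pytest.approx(0.5, abs=1e-6)
        Fn = _row_normalize(R2.values)
        oracle = simplex_grid_argmin(Fn, s.to_numpy())
        assert np.abs(a.to_numpy() - oracle).max() <= 1e-4

    @pytest.mark.parametrize("n_taxa,n_fas", [(2, 5), (3, 6), (3, 8)])
    def test_matches_grid_oracle_on_random_instances(self, n_taxa, n_fas):
        """solve_abundances agrees with exhaustive simplex grid search (1e-4)."""
        fa_names = ["16:0", "18:0", "18:1ω9c", "18:2ω6c", "18:3ω3", "20:5ω3", "a-15:0", "cy17:0"]
        rng = np.random.default_rng(n_taxa * 100 + n_fas)
        for trial in range(20):
            R = rng.uniform(0.05, 2.0, size=(n_taxa, n_fas))
            # 16:0 referencing cancels in the row normalization, so a random
            # matrix wrapped as a ratio matrix exercises the same fit
            matrix = px.TaxonRatioMatrix(
                pd.DataFrame(R, index=[f"t{i}" for i in range(n_taxa)], columns=fa_names[:n_fas])
            )
            Fn = _row_normalize(R)
            a_true = rng.dirichlet(np.ones(n_taxa))
            noise = rng.normal(0, 0.01, size=n_fas)
            s = np.clip(a_true @ Fn + noise, 1e-6, None)
            s = s / s.sum()
            a, _ = px.solve_abundances(matrix, dict(zip(fa_names[:n_fas], s)))
            oracle = simplex_grid_argmin(Fn, s)
            assert np.abs(a.to_numpy() - oracle).max() <= 5e-4, f"trial {trial}"

    def test_too_few_shared_fas(self, ratio_input):
        with pytest.raises(ValueError, match="shared"):
            px.solve_abundances(ratio_input, {"16:0": 1.0, "18:0": 0.2})


class TestFit:
    def test_noise_free_data_is_global_optimum(self, ratio_input):
        sc = px.make_scenario(ratio_input, n_samples=10, seed=5, cv=0.0)
        S, truth = px.gen_pond_samples(sc)
        res = px.fit(S, ratio_input)
        assert res.rmse < 1e-10
        pd.testing.assert_frame_equal(res.ratio_out.data, ratio_input.data)
        assert np.abs(res.abundances.to_numpy() - truth.to_numpy()).max() < 1e-6

    def test_scaled_element_recovery_well_separated(self, small_matrix):
        """Noise-free data from a matrix with one element scaled x1.3:
        the bounded optimizer recovers the element and the abundances."""
        data = small_matrix.data.copy()
        data.loc["green-like", "18:3ω3"] *= 1.3
        R_true = px.TaxonRatioMatrix(data)
        sc = px.make_scenario(R_true, n_samples=12, seed=3, cv=0.0)
        S, truth = px.gen_pond_samples(sc)
        res = px.fit(S, small_matrix, px.UnmixingConfig(max_iter=2000, tol=1e-12))
        el = res.ratio_out.data.loc["green-like", "18:3ω3"]
        assert el == pytest.approx(data.loc["green-like", "18:3ω3"], rel=0.05)
        assert np.abs(res.abundances.to_numpy() - truth.to_numpy()).max() < 1e-3

    def test_bound_factor_one_freezes_ratio(self, ratio_input):
        sc = px.make_scenario(ratio_input, n_samples=8, seed=2, cv=0.1)
        S, _ = px.gen_pond_samples(sc)
        res = px.fit(S, ratio_input, px.UnmixingConfig(bound_factor=1.0))
        pd.testing.assert_frame_equal(res.ratio_out.data, ratio_input.data)
        for i, sid in enumerate(S.sample_ids):
            a, _ = px.solve_abundances(ratio_input, pd.Series(S.values[i], index=S.fas))
            assert np.abs(res.abundances.loc[sid].to_numpy() - a.to_numpy()).max() < 1e-9

    def test_invariants_bounds_zeros_and_simplex(self, ratio_input):
        sc = px.make_scenario(ratio_input, n_samples=15, seed=11, cv=0.1)
        S, _ = px.gen_pond_samples(sc)
        cfg = px.UnmixingConfig(bound_factor=1.5)
        res = px.fit(S, ratio_input, cfg)
        A = res.abundances.to_numpy()
        assert (A >= 0).all()
        assert np.abs(A.sum(axis=1) - 1.0).max() < 1e-9
        R0, R1 = ratio_input.values, res.ratio_out.values
        nz = R0 > 0
        ratio = R1[nz] / R0[nz]
        assert ratio.min() >= 1 / cfg.bound_factor - 1e-12
        assert ratio.max() <= cfg.bound_factor + 1e-12
        assert (R1[~nz] == 0).all()
        # 16:0 reference frozen at exactly 1
        assert (res.ratio_out.data[REFERENCE_FA] == 1.0).all()

    def test_rmse_trajectory_non_increasing(self, ratio_input):
        sc = px.make_scenario(ratio_input, n_samples=10, seed=4, cv=0.1)
        S, _ = px.gen_pond_samples(sc)
        res = px.fit(S, ratio_input)
        t = np.array(res.rmse_trajectory)
        assert (np.diff(t) <= 1e-12).all()

    def test_extra_sample_fas_warn_and_drop(self, ratio_input):
        sc = px.make_scenario(ratio_input, n_samples=4, seed=1, cv=0.0)
        S, _ = px.gen_pond_samples(sc)
        S2 = px.SampleMatrix(
            sample_ids=S.sample_ids,
            fas=S.fas + ["18:4ω3"],
            values=np.hstack([S.values, np.full((len(S.sample_ids), 1), 0.5)]),
        )
        with pytest.warns(UserWarning, match="18:4ω3"):
            res = px.fit(S2, ratio_input)
        assert res.rmse < 1e-8


class TestProtocols:
    def test_successive_runs_noise_free_stable(self, small_matrix):
        sc = px.make_scenario(small_matrix, n_samples=8, seed=6, cv=0.0)
        S, _ = px.gen_pond_samples(sc)
        cfg = px.UnmixingConfig(n_successive_runs=3)
        res = px.successive_runs(S, small_matrix, cfg)
        assert res.rmse < 1e-10
        pd.testing.assert_frame_equal(res.ratio_out.data, small_matrix.data)

    def test_single_run_equals_fit(self, small_matrix):
        sc = px.make_scenario(small_matrix, n_samples=8, seed=6, cv=0.1)
        S, _ = px.gen_pond_samples(sc)
        cfg = px.UnmixingConfig(n_successive_runs=1)
        r1 = px.successive_runs(S, small_matrix, cfg)
        r2 = px.fit(S, small_matrix, cfg)
        pd.testing.assert_frame_equal(r1.abundances, r2.abundances)
        assert r1.rmse == r2.rmse

    @pytest.mark.parametrize("seed", range(1, 21))
    def test_successive_runs_never_worse_than_first(self, small_matrix, seed):
        sc = px.make_scenario(small_matrix, n_samples=6, seed=seed, cv=0.1)
        S, _ = px.gen_pond_samples(sc)
        cfg = px.UnmixingConfig(n_successive_runs=3, max_iter=100)
        first = px.fit(S, small_matrix, cfg)
        best = px.successive_runs(S, small_matrix, cfg)
        assert best.rmse <= first.rmse + 1e-15

    def test_randomized_starts_deterministic(self, small_matrix):
        sc = px.make_scenario(small_matrix, n_samples=6, seed=9, cv=0.1)
        S, _ = px.gen_pond_samples(sc)
        cfg = px.UnmixingConfig(n_random_starts=6, seed=123, max_iter=100)
        r1 = px.randomized_starts(S, small_matrix, cfg)
        r2 = px.randomized_starts(S, small_matrix, cfg)
        assert (r1.abundances.to_numpy() == r2.abundances.to_numpy()).all()
        assert (r1.ratio_out.values == r2.ratio_out.values).all()

    def test_single_unperturbed_start_equals_fit(self, small_matrix):
        sc = px.make_scenario(small_matrix, n_samples=6, seed=9, cv=0.1)
        S, _ = px.gen_pond_samples(sc)
        cfg = px.UnmixingConfig(n_random_starts=1, start_jitter=0.0, seed=5, max_iter=100)
        r1 = px.randomized_starts(S, small_matrix, cfg)
        r2 = px.fit(S, small_matrix, cfg)
        assert r1.rmse == pytest.approx(r2.rmse, rel=1e-9)

    def test_best_fraction_beats_median_start(self, small_matrix):
        sc = px.make_scenario(small_matrix, n_samples=6, seed=2, cv=0.0)
        S, _ = px.gen_pond_samples(sc)
        cfg = px.UnmixingConfig(n_random_starts=20, best_fraction=0.25, seed=3, max_iter=60)
        res = px.randomized_starts(S, small_matrix, cfg)
        # each individual start fit is itself bounded below by the returned fit
        singles = []
        for k in range(10):
            c = px.UnmixingConfig(n_random_starts=1, seed=1000 + k, max_iter=60)
            singles.append(px.randomized_starts(S, small_matrix, c).rmse)
        assert res.rmse <= np.median(singles) + 1e-12

    def test_randomized_starts_respect_original_bounds(self, small_matrix):
        sc = px.make_scenario(small_matrix, n_samples=6, seed=13, cv=0.15)
        S, _ = px.gen_pond_samples(sc)
        cfg = px.UnmixingConfig(n_random_starts=8, seed=4, max_iter=80)
        res = px.randomized_starts(S, small_matrix, cfg)
        R0, R1 = small_matrix.values, res.ratio_out.values
        nz = R0 > 0
        ratio = R1[nz] / R0[nz]
        assert ratio.min() >= 1 / cfg.bound_factor - 1e-12
        assert ratio.max() <= cfg.bound_factor + 1e-12


class TestRunByLocation:
    def test_single_location_matches_fit(self, small_matrix):
        sc = px.make_scenario(small_matrix, n_samples=6, seed=8, cv=0.1)
        S, _ = px.gen_pond_samples(sc)
        S.location = {s: "pondA" for s in S.sample_ids}
        merged, results = px.run_by_location(
            S, small_matrix, {"pondA": small_matrix.taxa}
        )
        ref = px.fit(S, small_matrix)
        assert np.abs(merged.to_numpy() - ref.abundances.to_numpy()).max() < 1e-12
        assert set(results) == {"pondA"}

    def test_excluded_taxa_report_zero(self, small_matrix):
        sc = px.make_scenario(small_matrix, n_samples=6, seed=8, cv=0.1)
        S, _ = px.gen_pond_samples(sc)
        S.location = {
            s: ("pondA" if i < 3 else "pondB") for i, s in enumerate(S.sample_ids)
        }
        membership = {
            "pondA": ["diatom-like", "green-like"],
            "pondB": ["bacteria-like", "green-like"],
        }
        merged, _ = px.run_by_location(S, small_matrix, membership)
        a_ids = S.sample_ids[:3]
        b_ids = S.sample_ids[3:]
        assert (merged.loc[a_ids, "bacteria-like"] == 0).all()
        assert (merged.loc[b_ids, "diatom-like"] == 0).all()
        assert np.abs(merged.to_numpy().sum(axis=1) - 1.0).max() < 1e-9

    def test_restricted_fit_beats_pooled_on_mismatched_taxa(self, small_matrix):
        """When each location truly contains a taxon subset, per-location
        unmixing recovers abundances at least as well as a pooled run."""
        rng = np.random.default_rng(21)
        taxa = small_matrix.taxa
        rows = []
        for i in range(8):
            w = rng.dirichlet(np.ones(2))
            if i < 4:
                rows.append({"diatom-like": w[0], "green-like": w[1], "bacteria-like": 0.0})
            else:
                rows.append({"diatom-like": 0.0, "green-like": w[1], "bacteria-like": w[0]})
        truth = pd.DataFrame(rows, index=[f"s{i}" for i in range(8)])[taxa]
        sc = px.SyntheticScenario(
            ratio_matrix=small_matrix, true_abundances=truth, cv=0.08, seed=17
        )
        S, _ = px.gen_pond_samples(sc)
        S.location = {f"s{i}": ("A" if i < 4 else "B") for i in range(8)}
        membership = {"A": ["diatom-like", "green-like"], "B": ["green-like", "bacteria-like"]}
        merged, _ = px.run_by_location(S, small_matrix, membership)
        pooled = px.fit(S, small_matrix)
        err_loc = np.abs(merged.to_numpy() - truth.to_numpy()).mean()
        err_pool = np.abs(pooled.abundances.to_numpy() - truth.to_numpy()).mean()
        assert err_loc <= err_pool + 1e-9

    def test_missing_location_assignment_errors(self, small_matrix):
        sc = px.make_scenario(small_matrix, n_samples=4, seed=8, cv=0.1)
        S, _ = px.gen_pond_samples(sc)
        with pytest.raises(ValueError, match="without a location"):
            px.run_by_location(S, small_matrix, {"A": small_matrix.taxa})
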