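"""Tests of population composition, mean-RF comparison, RF diversity and the
non-negative nearest-neighbour decomposition."""

import numpy as np
import pandas as pd
import pytest

from onoffmap import rfmodel as rfm
from onoffmap import synthetic as syn
from onoffmap.datasets import study_datasets
from onoffmap.errors import ParameterError


class TestComposition:
    def test_bundled_volumes_pool_to_reference_counts(self):
        comp = rfm.population_composition(study_datasets())
        assert comp.n_dual == 4430
        assert (comp.pct_off, comp.pct_on, comp.pct_dual) == (55, 27, 18)

    def test_single_dataset_fractions(self):
        t = pd.DataFrame([dict(n_on=1, n_off=1, n_dual=2)])
        comp = rfm.population_composition(t)
        f = comp.fractions()
        assert (f["on"], f["off"], f["dual"]) == (0.25, 0.25, 0.5)

    def test_negative_counts_rejected(self):
        t = pd.DataFrame([dict(n_on=-1, n_off=1, n_dual=2)])
        with pytest.raises(ParameterError):
            rfm.population_composition(t)

    def test_empty_table_rejected(self):
        with pytest.raises(ParameterError):
            rfm.population_composition(pd.DataFrame(columns=["n_on"]))

    def test_composition_from_classified_cells(self):
        cells = pd.DataFrame(dict(cell_class=["ON", "OFF", "OFF", "SIMPLE",
                                              "COMPLEX", "NONE"]))
        comp = rfm.composition_from_cells(cells)
        assert (comp.n_on, comp.n_off, comp.n_dual) == (1, 2, 2)
        assert comp.n_simple == 1 and comp.n_complex == 1


def _blob(c1, c2, sigma=1.2):
    ii, jj = np.mgrid[0:8, 0:18].astype(float)
    return np.exp(-0.5 * (((jj - c1) / sigma) ** 2 + ((ii - c2) / sigma) ** 2))


class TestMeanRf:
    def test_exact_difference_gives_unit_correlation(self):
        on = _blob(5, 3)[None]
        off = _blob(11, 4)[None]
        simple = (on - off)
        res = rfm.mean_rf_comparison(on, off, simple, n_permutations=50,
                                     seed=0)
        assert res.r_mean == pytest.approx(1.0)

    def test_generative_population_consistency(self):
        """Simple cells built as sums of nearby mono components yield a mean
        RF positively and significantly correlated with mu_on - mu_off."""
        bias = syn.make_bias_field(amplitude=0.0, seed=5)
        ret = syn.default_retinotopy()
        pop = syn.sample_population(bias, ret, n_on=150, n_off=150,
                                    n_simple=200, n_complex=0, seed=6)
        tc = pop.cells.true_class.to_numpy()
        srf = pop.on_maps[tc == "SIMPLE"] - pop.off_maps[tc == "SIMPLE"]
        res = rfm.mean_rf_comparison(pop.on_maps[tc == "ON"],
                                     pop.off_maps[tc == "OFF"], srf,
                                     n_permutations=200, seed=1)
        assert res.r_mean > 0.3
        assert res.p_value < 0.01

    def test_shuffled_simple_maps_not_significant(self):
        """Spatially shuffling the simple-cell maps leaves the permutation p
        roughly uniform."""
        ps = []
        for s in range(20):
            rng = np.random.default_rng(s)
            on = np.stack([_blob(*rng.uniform(2, 14, 2)) for _ in range(20)])
            off = np.stack([_blob(*rng.uniform(2, 14, 2)) for _ in range(20)])
            simple = np.stack([
                m.ravel()[rng.permutation(m.size)].reshape(m.shape)
                for m in (on[:10] - off[:10])])
            res = rfm.mean_rf_comparison(on, off, simple, n_permutations=100,
                                         seed=s)
            ps.append(res.p_value)
        assert np.mean(np.asarray(ps) < 0.05) <= 0.25
        assert np.median(ps) > 0.1

    def test_empty_group_rejected(self):
        with pytest.raises(ParameterError):
            rfm.mean_rf_comparison(np.empty((0, 8, 18)), _blob(5, 3)[None],
                                   _blob(5, 3)[None])


class TestRfDiversity:
    def test_identical_cells_all_unit_correlation(self):
        mu = _blob(6, 3)
        res = rfm.rf_diversity(np.stack([mu, mu, mu]), mu)
        assert np.allclose(res.correlations, 1.0)

    def test_symmetric_population_has_zero_median(self):
        mu = _blob(6, 3) - _blob(10, 3)
        cells = np.stack([mu, -mu] * 5)
        res = rfm.rf_diversity(cells, mu)
        assert np.median(res.correlations) == pytest.approx(0.0)
        assert res.p_signrank > 0.05

    def test_constant_map_excluded(self):
        mu = _blob(6, 3)
        cells = np.stack([mu, np.zeros_like(mu), mu])
        res = rfm.rf_diversity(cells, mu)
        assert res.excluded == 1
        assert len(res.correlations) == 2


class TestKnn:
    @staticmethod
    def _mono(n, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(dict(
            cell_id=np.arange(n),
            cell_class=rng.choice(["ON", "OFF"], size=n),
            x1=rng.uniform(0, 900, n), x2=rng.uniform(0, 540, n),
            x3=rng.choice([150.0, 180.0, 210.0], n)))

    def test_single_neighbor(self):
        mono = pd.DataFrame(dict(cell_id=[0, 1],
                                 cell_class=["ON", "OFF"],
                                 x1=[10.0, 0.0], x2=[0.0, 5.0],
                                 x3=[150.0, 150.0]))
        nb = rfm.knn_neighbors(np.array([0.0, 0.0, 150.0]), mono, 1)
        assert nb["ON"][0].tolist() == [0]
        assert nb["ON"][1][0] == pytest.approx(10.0)

    def test_matches_exhaustive_sort(self):
        mono = self._mono(100, seed=3)
        t = np.array([450.0, 270.0, 180.0])
        nb = rfm.knn_neighbors(t, mono, 5)
        for pol in ("ON", "OFF"):
            pool = mono[mono.cell_class == pol]
            d = np.sqrt(((pool[["x1", "x2", "x3"]].to_numpy() - t) ** 2).sum(1))
            expected = pool.cell_id.to_numpy()[np.argsort(d, kind="stable")][:5]
            assert nb[pol][0].tolist() == expected.tolist()

    def test_tie_break_by_cell_id(self):
        # four ON cells on a symmetric ring around the target
        mono = pd.DataFrame(dict(
            cell_id=[7, 3, 9, 5, 0, 1],
            cell_class=["ON", "ON", "ON", "ON", "OFF", "OFF"],
            x1=[10.0, -10.0, 0.0, 0.0, 1.0, 2.0],
            x2=[0.0, 0.0, 10.0, -10.0, 0.0, 0.0],
            x3=[0.0] * 6))
        nb = rfm.knn_neighbors(np.zeros(3), mono, 2)
        assert nb["ON"][0].tolist() == [3, 5]

    def test_shortfall_raises(self):
        mono = self._mono(10, seed=4)
        with pytest.raises(ParameterError, match="available"):
            rfm.knn_neighbors(np.zeros(3), mono, 50)


class TestNnls:
    def test_exact_representation_recovers_weights(self):
        phi1 = np.zeros((8, 18)); phi1[2, 3] = 1.0
        phi2 = np.zeros((8, 18)); phi2[6, 12] = 1.0
        target = 0.7 * phi1 + 0.3 * phi2
        fit = rfm.nnls_fit(target, np.stack([phi1, phi2]),
                           np.empty((0, 8, 18)))
        assert np.max(np.abs(fit.weights["ON"] - [0.7, 0.3])) < 1e-8
        assert fit.fit_corr == pytest.approx(1.0)

    def test_orthogonal_target_gets_zero_weights(self):
        phi = np.zeros((8, 18)); phi[0, 0] = 1.0
        target = np.zeros((8, 18)); target[7, 17] = 1.0
        fit = rfm.nnls_fit(target, phi[None], np.empty((0, 8, 18)))
        assert np.all(fit.weights["ON"] == 0.0)

    def test_off_maps_enter_with_negative_sign(self):
        phi = _blob(9, 4)
        target = -0.5 * phi
        fit = rfm.nnls_fit(target, np.empty((0, 8, 18)), phi[None])
        assert fit.weights["OFF"][0] == pytest.approx(0.5, abs=1e-10)

    def test_matches_simplex_grid_search(self):
        """Dense (0.01-step) search over two weights agrees with the
        active-set solution within the grid resolution."""
        rng = np.random.default_rng(0)
        grid = np.arange(0.0, 1.5, 0.01)
        for trial in range(5):
            phi1 = _blob(rng.uniform(3, 14), rng.uniform(2, 6))
            phi2 = _blob(rng.uniform(3, 14), rng.uniform(2, 6))
            target = (rng.uniform(0, 1) * phi1 + rng.uniform(0, 1) * phi2
                      + rng.normal(scale=0.05, size=phi1.shape))
            fit = rfm.nnls_fit(target, np.stack([phi1, phi2]),
                               np.empty((0, 8, 18)))
            A = np.column_stack([phi1.ravel(), phi2.ravel()])
            t = target.ravel()
            # exhaustive search over the (w1, w2) grid
            resid = (t[:, None, None]
                     - A[:, 0][:, None, None] * grid[None, :, None]
                     - A[:, 1][:, None, None] * grid[None, None, :])
            sse = np.sum(resid ** 2, axis=0)
            i, j = np.unravel_index(np.argmin(sse), sse.shape)
            best = np.array([grid[i], grid[j]])
            assert np.max(np.abs(fit.weights["ON"] - best)) <= 0.011

    def test_all_zero_target(self):
        phi = _blob(5, 3)
        fit = rfm.nnls_fit(np.zeros((8, 18)), phi[None], np.empty((0, 8, 18)))
        assert np.all(fit.weights["ON"] == 0.0)
        assert np.isnan(fit.fit_corr)

    def test_kkt_condition_on_population_fits(self, classified):
        """For every zero weight the gradient of the objective is
        non-negative (the active-set solution satisfies the KKT conditions)."""
        pop, stim, cells, kset = classified
        mono = cells[cells.cell_class.isin(["ON", "OFF"])]
        simple = cells[cells.cell_class == "SIMPLE"]
        if len(simple) == 0:
            pytest.skip("no simple cells recovered in fixture")
        mono_maps = {int(r.cell_id): kset.stack(int(r.cell_id),
                                                r.cell_class).peak_map
                     for _, r in mono.iterrows()}
        from onoffmap.kernels import simple_rf
        srfs = {int(r.cell_id): simple_rf(kset.stack(int(r.cell_id), "ON"),
                                          kset.stack(int(r.cell_id), "OFF"))
                for _, r in simple.iterrows()}
        fits = rfm.fit_neighborhood_model(simple, srfs, mono, mono_maps, k=5)
        for f in fits:
            w = np.concatenate([f.weights["ON"], f.weights["OFF"]])
            on_ids, off_ids = f.neighbor_ids["ON"], f.neighbor_ids["OFF"]
            A = np.column_stack(
                [mono_maps[int(i)].ravel() for i in on_ids]
                + [-mono_maps[int(i)].ravel() for i in off_ids])
            g = A.T @ (A @ w - srfs[f.cell_id].ravel())
            assert np.all(g[w == 0] >= -1e-8 * np.abs(g).max())


class TestSweepK:
    def test_median_fit_corr_nondecreasing_in_k(self, small_population):
        pop = small_population
        cells = pop.cells
        mono = cells[cells.true_class.isin(["ON", "OFF"])].rename(
            columns={"true_class": "cell_class"})
        simple = cells[cells.true_class == "SIMPLE"]
        mono_maps = {int(r.cell_id):
                     pop.on_maps[int(r.cell_id)] if r.cell_class == "ON"
                     else pop.off_maps[int(r.cell_id)]
                     for _, r in mono.iterrows()}
        srfs = {int(r.cell_id): pop.signed_rf(int(r.cell_id))
                for _, r in simple.iterrows()}
        res = rfm.sweep_k(simple, srfs, mono, mono_maps, k_range=range(1, 7))
        med = res["summary"]["median"].to_numpy()
        assert np.all(np.diff(med) >= -1e-12)

    def test_pure_noise_targets_near_chance_level(self):
        """Random targets against random neighbour maps give a median fit
        correlation near the analytic chance level for the ~k active
        regressors the non-negativity constraint leaves in play."""
        rng = np.random.default_rng(1)
        m = 144
        k = 5
        fcs = []
        for _ in range(200):
            f = rfm.nnls_fit(rng.normal(size=m).reshape(8, 18),
                             rng.normal(size=(k, m)).reshape(k, 8, 18),
                             rng.normal(size=(k, m)).reshape(k, 8, 18))
            fcs.append(0.0 if np.isnan(f.fit_corr) else f.fit_corr)
        chance = np.sqrt(k / (m - 1))
        assert abs(np.median(fcs) - chance) < 0.08

    def test_empty_k_range_rejected(self, small_population):
        with pytest.raises(ParameterError):
            rfm.sweep_k(pd.DataFrame(), {}, pd.DataFrame(), {}, k_range=[])


class TestWeightSparsity:
    @staticmethod
    def _fit_with_weights(on_w, off_w):
        return rfm.NeighborhoodFit(
            cell_id=0, k=max(len(on_w), len(off_w)),
            neighbor_ids={"ON": np.arange(len(on_w)),
                          "OFF": np.arange(len(off_w))},
            distances={"ON": np.arange(len(on_w), dtype=float),
                       "OFF": np.arange(len(off_w), dtype=float)},
            weights={"ON": np.asarray(on_w, dtype=float),
                     "OFF": np.asarray(off_w, dtype=float)},
            fit_corr=1.0, model_rf=np.zeros((8, 18)))

    def test_single_nonzero_weight(self):
        f = self._fit_with_weights([0.0, 0.8, 0.0], [0.5, 0.0, 0.0])
        assert f.n90("ON") == 1
        res = rfm.weight_sparsity([f])
        assert res["ON"]["mean_cumulative"][0] == pytest.approx(1.0)

    def test_equal_weights_need_all_five(self):
        f = self._fit_with_weights([0.2] * 5, [0.2] * 5)
        assert f.n90("ON") == 5

    def test_zero_weight_fits_excluded(self):
        good = self._fit_with_weights([1.0], [1.0])
        bad = self._fit_with_weights([0.0], [0.0])
        res = rfm.weight_sparsity([good, bad])
        assert len(res["ON"]["n90"]) == 1

    def test_sparse_truth_recovers_low_n90(self, small_population):
        """With the generator's sparse Dirichlet weights, two or three
        same-polarity inputs carry 90% of the total weight."""
        pop = small_population
        cells = pop.cells
        mono = cells[cells.true_class.isin(["ON", "OFF"])].rename(
            columns={"true_class": "cell_class"})
        simple = cells[cells.true_class == "SIMPLE"]
        mono_maps = {int(r.cell_id):
                     pop.on_maps[int(r.cell_id)] if r.cell_class == "ON"
                     else pop.off_maps[int(r.cell_id)]
                     for _, r in mono.iterrows()}
        srfs = {int(r.cell_id): pop.signed_rf(int(r.cell_id))
                for _, r in simple.iterrows()}
        fits = rfm.fit_neighborhood_model(simple, srfs, mono, mono_maps, k=5)
        res = rfm.weight_sparsity(fits)
        assert np.mean(res["ON"]["n90"]) <= 3.0
        assert np.mean(res["OFF"]["n90"]) <= 3.0


class TestNeighborDistances:
    @staticmethod
    def _fits_from_distances(rng, n, shift=0.0):
        fits = []
        for i in range(n):
            d_on = rng.gamma(3.0, 10.0, size=5) + shift
            d_off = rng.gamma(3.0, 10.0, size=5)
            fits.append(rfm.NeighborhoodFit(
                cell_id=i, k=5,
                neighbor_ids={"ON": np.arange(5), "OFF": np.arange(5)},
                distances={"ON": d_on, "OFF": d_off},
                weights={"ON": np.ones(5), "OFF": np.ones(5)},
                fit_corr=1.0, model_rf=np.zeros((8, 18))))
        return fits

    def test_identical_distributions_rarely_significant(self):
        hits = 0
        for s in range(50):
            rng = np.random.default_rng(s)
            res = rfm.neighbor_distance_comparison(
                self._fits_from_distances(rng, 20))
            hits += res["p_value"] < 0.05
        assert hits <= 7

    def test_on_sparser_pool_gives_larger_distances(self):
        """With half the ON density, nearest ON neighbours sit farther than
        OFF ones and the rank-sum test detects it in most seeds."""
        hits = 0
        n_seeds = 30
        for s in range(n_seeds):
            rng = np.random.default_rng(s)
            mono = pd.DataFrame(dict(
                cell_id=np.arange(360),
                cell_class=["ON"] * 120 + ["OFF"] * 240,
                x1=rng.uniform(0, 900, 360), x2=rng.uniform(0, 540, 360),
                x3=rng.choice([150.0, 180.0], 360)))
            fits = []
            for i in range(200):
                t = np.array([rng.uniform(0, 900), rng.uniform(0, 540), 150.0])
                nb = rfm.knn_neighbors(t, mono, 5)
                fits.append(rfm.NeighborhoodFit(
                    cell_id=i, k=5,
                    neighbor_ids={"ON": nb["ON"][0], "OFF": nb["OFF"][0]},
                    distances={"ON": nb["ON"][1], "OFF": nb["OFF"][1]},
                    weights={"ON": np.ones(5), "OFF": np.ones(5)},
                    fit_corr=1.0, model_rf=np.zeros((8, 18))))
            res = rfm.neighbor_distance_comparison(fits)
            hits += (res["p_value"] < 0.05
                     and res["median_on"] > res["median_off"])
        assert hits >= int(0.8 * n_seeds)

    def test_colocated_cells_degenerate(self):
        fits = []
        for i in range(12):
            fits.append(rfm.NeighborhoodFit(
                cell_id=i, k=2,
                neighbor_ids={"ON": np.arange(2), "OFF": np.arange(2)},
                distances={"ON": np.zeros(2), "OFF": np.zeros(2)},
                weights={"ON": np.ones(2), "OFF": np.ones(2)},
                fit_corr=1.0, model_rf=np.zeros((8, 18))))
        res = rfm.neighbor_distance_comparison(fits)
        assert res["p_value"] == 1.0

    def test_too_few_fits_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ParameterError):
            rfm.neighbor_distance_comparison(self._fits_from_distances(rng, 3))
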