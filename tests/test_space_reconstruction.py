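"""Design matrices, least-squares recovery, permutation null, distances."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.stats import rankdata

from repspace import space_reconstruction as sr
from repspace import synthetic_data as sd
from repspace.dimensions import other_space_pairs
from repspace.errors import (
    EmptyDesignError,
    InvalidArgumentError,
    MissingImageError,
    UndefinedCorrelationError,
)

from conftest import SHARED_FULL


def _trials(rows):
    """Build a minimal encoding table from (first, second, dim_a, dim_b, ra, rb)."""
    return pd.DataFrame([
        {"participant_id": "s0", "block_condition": "conceptual",
         "dim_a": da, "dim_b": db, "image_first": f, "image_second": s,
         "rating_a": ra, "rating_b": rb, "rt_first": 1.0, "rt_second": 1.0}
        for f, s, da, db, ra, rb in rows
    ])


class TestDesignMatrix:
    def test_single_trial_row(self):
        trials = _trials([("A", "B", "size", "climate", 30.0, 5.0)])
        system = sr.build_design_matrix(trials, "size", image_index=["A", "B", "C"])
        assert system.M.shape == (1, 3)
        np.testing.assert_array_equal(system.M.toarray(), [[1.0, -1.0, 0.0]])
        np.testing.assert_array_equal(system.response, [30.0])
        system.validate()

    def test_unrated_dimension_is_empty_design(self):
        trials = _trials([("A", "B", "size", "climate", 30.0, 5.0)])
        with pytest.raises(EmptyDesignError):
            sr.build_design_matrix(trials, "color")

    def test_matches_naive_per_trial_constructor(self):
        rng = np.random.default_rng(3)
        images = ["A", "B", "C"]
        rows = []
        for _ in range(6):
            f, s = rng.choice(images, size=2, replace=False)
            rows.append((f, s, "size", "climate",
                         float(rng.uniform(-50, 50)), float(rng.uniform(-50, 50))))
        trials = _trials(rows)
        system = sr.build_design_matrix(trials, "size", image_index=images)
        naive = np.zeros((len(rows), len(images)))
        resp = np.zeros(len(rows))
        for t, (f, s, _, _, ra, _) in enumerate(rows):
            naive[t, images.index(f)] = 1.0
            naive[t, images.index(s)] = -1.0
            resp[t] = ra
        np.testing.assert_array_equal(system.M.toarray(), naive)
        np.testing.assert_array_equal(system.response, resp)

    def test_both_rating_slots_contribute(self):
        trials = _trials([("A", "B", "size", "climate", 30.0, 5.0),
                          ("B", "C", "climate", "size", 2.0, -7.0)])
        system = sr.build_design_matrix(trials, "size", image_index=["A", "B", "C"])
        assert system.M.shape[0] == 2
        assert set(system.response) == {30.0, -7.0}


class TestSolveDimension:
    def test_noiseless_three_image_closed_form(self):
        # latents (10, -20, 10): solve the normal equations by hand
        latents = {"A": 10.0, "B": -20.0, "C": 10.0}
        rows = [("A", "B", "size", "climate", latents["A"] - latents["B"], 0.0),
                ("B", "C", "size", "climate", latents["B"] - latents["C"], 0.0),
                ("A", "C", "size", "climate", latents["A"] - latents["C"], 0.0)]
        system = sr.build_design_matrix(_trials(rows), "size",
                                        image_index=["A", "B", "C"])
        sol = sr.solve_dimension(system)
        centered = np.array([latents[i] for i in ["A", "B", "C"]])
        centered -= centered.mean()
        np.testing.assert_allclose(sol.coords.to_numpy(), centered, atol=1e-8)
        assert sol.residual_norm < 1e-8
        assert sol.n_components == 1

    def test_all_zero_ratings(self):
        rows = [("A", "B", "size", "climate", 0.0, 0.0),
                ("B", "C", "size", "climate", 0.0, 0.0)]
        system = sr.build_design_matrix(_trials(rows), "size")
        sol = sr.solve_dimension(system)
        np.testing.assert_allclose(sol.coords.to_numpy(), 0.0, atol=1e-10)
        assert sol.residual_norm < 1e-10

    def test_disconnected_clusters_centered_independently(self):
        rows = [("A", "B", "size", "climate", 12.0, 0.0),
                ("C", "D", "size", "climate", -4.0, 0.0)]
        system = sr.build_design_matrix(_trials(rows), "size",
                                        image_index=["A", "B", "C", "D"])
        sol = sr.solve_dimension(system)
        assert sol.n_components == 2
        coords = sol.coords
        assert coords["A"] + coords["B"] == pytest.approx(0.0, abs=1e-10)
        assert coords["C"] + coords["D"] == pytest.approx(0.0, abs=1e-10)
        assert coords["A"] - coords["B"] == pytest.approx(12.0, abs=1e-8)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(8)
        images = [f"i{k}" for k in range(6)]
        rows = []
        for _ in range(15):
            f, s = rng.choice(images, size=2, replace=False)
            rows.append((f, s, "size", "climate", float(rng.normal(0, 10)), 0.0))
        trials = _trials(rows)
        shuffled = trials.sample(frac=1.0, random_state=1)
        a = sr.solve_dimension(sr.build_design_matrix(trials, "size", images))
        b = sr.solve_dimension(sr.build_design_matrix(shuffled, "size", images))
        np.testing.assert_allclose(a.coords.to_numpy(), b.coords.to_numpy(),
                                   atol=1e-8)

    def test_matches_pinv_oracle_with_noise(self):
        rng = np.random.default_rng(12)
        images = [f"i{k}" for k in range(8)]
        rows = []
        for _ in range(30):
            f, s = rng.choice(images, size=2, replace=False)
            rows.append((f, s, "size", "climate", float(rng.normal(0, 15)), 0.0))
        system = sr.build_design_matrix(_trials(rows), "size", images)
        sol = sr.solve_dimension(system)
        # minimum-norm least squares via pseudoinverse
        oracle = np.linalg.pinv(system.M.toarray()) @ system.response
        oracle -= oracle.mean()
        np.testing.assert_allclose(sol.coords.to_numpy(), oracle, atol=1e-6)


class TestSpaceAndDistances:
    def _sol(self, name, values, images):
        coords = pd.Series(values, index=pd.Index(images, name="image_id"),
                           name=name, dtype=float)
        return sr.DimensionSolution(coords, 0.0, 1, np.zeros(len(images), int), name)

    def test_three_four_five(self):
        sol_a = self._sol("size", [0.0, 3.0], ["A", "B"])
        sol_b = self._sol("climate", [0.0, 4.0], ["A", "B"])
        space = sr.make_space(sol_a, sol_b)
        assert space.pair_distance("A", "B") == pytest.approx(5.0)

    def test_zero_solutions(self):
        sol = self._sol("size", [0.0, 0.0, 0.0], ["A", "B", "C"])
        sol2 = self._sol("climate", [0.0, 0.0, 0.0], ["A", "B", "C"])
        assert not sr.make_space(sol, sol2).distance.to_numpy().any()

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(5)
        images = [f"i{k}" for k in range(10)]
        xa, xb = rng.normal(0, 10, 10), rng.normal(0, 10, 10)
        space = sr.make_space(self._sol("size", xa, images),
                              self._sol("climate", xb, images))
        for i in range(10):
            for j in range(10):
                expected = np.sqrt((xa[i] - xa[j]) ** 2 + (xb[i] - xb[j]) ** 2)
                assert space.distance.iat[i, j] == pytest.approx(expected)

    def test_mismatched_image_sets_rejected(self):
        with pytest.raises(InvalidArgumentError):
            sr.make_space(self._sol("size", [0, 1], ["A", "B"]),
                          self._sol("climate", [0, 1], ["A", "C"]))

    def test_distance_matrix_is_metric(self, small_config, noisy_encoding):
        space = sr.global_space(noisy_encoding, ("size", "climate"))
        d = space.distance.to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        n = len(d)
        rng = np.random.default_rng(0)
        for _ in range(200):
            i, j, k = rng.integers(0, n, 3)
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-9

    @pytest.mark.parametrize("ra,rb,expected", [
        (30.0, 40.0, 50.0),
        (0.0, 0.0, 0.0),
        (-50.0, 50.0, 70.7107),
    ])
    def test_trial_relevant_distance(self, ra, rb, expected):
        assert sr.trial_relevant_distance(ra, rb) == pytest.approx(expected,
                                                                   abs=1e-4)

    def test_trial_relevant_distance_sign_symmetric(self):
        assert sr.trial_relevant_distance(-30.0, 40.0) == \
            sr.trial_relevant_distance(30.0, -40.0)

    def test_trial_relevant_distance_range_checked(self):
        with pytest.raises(InvalidArgumentError):
            sr.trial_relevant_distance(60.0, 0.0)

    def test_irrelevant_distance_is_mean_over_spaces(self):
        spaces = []
        for k, d in enumerate([1.0, 2.0, 3.0, 4.0, 5.0]):
            sol_a = self._sol(f"d{k}a", [0.0, d], ["A", "B"])
            sol_b = self._sol(f"d{k}b", [0.0, 0.0], ["A", "B"])
            spaces.append(sr.make_space(sol_a, sol_b))
        assert sr.irrelevant_distance(("A", "B"), spaces) == pytest.approx(3.0)
        assert sr.irrelevant_distance(("A", "B"), spaces[:1]) == pytest.approx(1.0)

    def test_missing_image_names_space(self):
        sol_a = self._sol("size", [0.0, 1.0], ["A", "B"])
        sol_b = self._sol("climate", [0.0, 1.0], ["A", "B"])
        space = sr.make_space(sol_a, sol_b)
        with pytest.raises(MissingImageError, match="size"):
            sr.irrelevant_distance(("A", "Z"), [space])

    def test_five_other_spaces_enumeration(self):
        # The rated (climate, size) pair leaves exactly these five 2D spaces.
        others = other_space_pairs("climate", "size")
        assert len(others) == 5
        expected = {frozenset(p) for p in [("climate", "approach"),
                                           ("size", "approach"),
                                           ("color", "camouflage"),
                                           ("orientation", "camouflage"),
                                           ("orientation", "color")]}
        assert {frozenset(p) for p in others} == expected

    def test_trial_distances_never_use_own_ratings(self, noisy_encoding):
        table = sr.compute_trial_distances(noisy_encoding)
        assert table["irrelevant_distance"].notna().all()
        assert table["relevant_distance"].equals(
            pd.Series(np.hypot(table["rating_a"], table["rating_b"]),
                      name="relevant_distance"))
        # provenance: leave-one-out spaces exclude the probe participant
        pid = noisy_encoding["participant_id"].iloc[0]
        spaces = sr.leave_one_out_spaces(noisy_encoding, pid)
        for space in spaces.values():
            assert space.excluded_participant == pid
            assert pid not in space.provenance


class TestPermutation:
    def test_constant_response_gives_p_one(self):
        rows = [("A", "B", "size", "climate", 5.0, 0.0),
                ("B", "C", "size", "climate", 5.0, 0.0),
                ("C", "A", "size", "climate", 5.0, 0.0)]
        system = sr.build_design_matrix(_trials(rows), "size")
        res = sr.permutation_validate(system, n_perm=99, seed=1)
        assert res.p_value == pytest.approx(1.0)

    def test_noiseless_structure_beats_every_shuffle(self, small_config):
        enc = sd.simulate_encoding(small_config, 1, 80, 0.0, seed=31,
                                   shared_weight=SHARED_FULL)
        system = sr.build_design_matrix(enc, "size")
        res = sr.permutation_validate(system, n_perm=999, seed=2)
        assert res.empirical_error < 1e-4
        assert (res.null_errors > res.empirical_error).all()
        assert res.p_value == pytest.approx(1.0 / 1000.0)

    def test_projection_equals_explicit_refit(self):
        rng = np.random.default_rng(4)
        images = [f"i{k}" for k in range(7)]
        rows = []
        for _ in range(20):
            f, s = rng.choice(images, size=2, replace=False)
            rows.append((f, s, "size", "climate", float(rng.normal(0, 10)), 0.0))
        system = sr.build_design_matrix(_trials(rows), "size", images)
        res = sr.permutation_validate(system, n_perm=50, seed=3)
        # replay the same permutation stream and refit each shuffle with LSQR
        replay = np.random.default_rng(3)
        for k in range(50):
            shuffled = replay.permutation(system.response)
            x = sp.linalg.lsqr(system.M, shuffled, atol=1e-12, btol=1e-12)[0]
            explicit = np.linalg.norm(system.M @ x - shuffled)
            assert res.null_errors[k] == pytest.approx(explicit, abs=1e-6)

    def test_null_p_values_roughly_uniform(self):
        # pure-noise responses: the empirical system is itself a shuffle draw
        pvals = []
        for s in range(120):
            rng = np.random.default_rng(5000 + s)
            images = [f"i{k}" for k in range(12)]
            rows = []
            for _ in range(30):
                f, g = rng.choice(images, size=2, replace=False)
                rows.append((f, g, "size", "climate",
                             float(rng.normal(0, 10)), 0.0))
            system = sr.build_design_matrix(_trials(rows), "size", images)
            pvals.append(sr.permutation_validate(system, n_perm=99,
                                                 seed=6000 + s).p_value)
        assert 0.40 < np.mean(pvals) < 0.60


class TestGlobalAndSimilarity:
    def test_single_participant_pool_equals_individual(self, noisy_encoding):
        one = noisy_encoding[noisy_encoding["participant_id"] == "sub000"]
        pooled = sr.global_space(one, ("size", "climate"))
        images = list(pooled.distance.index)
        individual = sr.make_space(
            sr.solve_dimension(sr.build_design_matrix(one, "size", images)),
            sr.solve_dimension(sr.build_design_matrix(one, "climate", images)))
        np.testing.assert_allclose(pooled.distance.to_numpy(),
                                   individual.distance.to_numpy(), atol=1e-8)

    def test_pooled_noiseless_recovers_shared_latents(self, small_config):
        enc = sd.simulate_encoding(small_config, 3, 80, 0.0, seed=41,
                                   shared_weight=SHARED_FULL)
        space = sr.global_space(enc, ("size", "climate"))
        truth = small_config.coords.loc[space.coords2d.index, ["size", "climate"]]
        for dim in ("size", "climate"):
            expected = truth[dim] - truth[dim].mean()
            np.testing.assert_allclose(space.coords2d[dim].to_numpy(),
                                       expected.to_numpy(), atol=1e-7)

    def test_identical_spaces_rho_one(self, noisy_encoding):
        space = sr.global_space(noisy_encoding, ("size", "climate"))
        assert sr.individual_global_similarity(space, space) == pytest.approx(1.0)

    def test_rank_invariance_under_monotone_transform(self, noisy_encoding):
        space = sr.global_space(noisy_encoding, ("size", "climate"))
        squared = sr.Space2D(space.dim_a, space.dim_b, space.coords2d,
                             space.distance ** 2)
        assert sr.individual_global_similarity(space, squared) == pytest.approx(1.0)

    def test_matches_hand_rolled_rank_oracle(self):
        rng = np.random.default_rng(9)
        images = [f"i{k}" for k in range(5)]
        def random_space():
            xy = rng.normal(0, 10, size=(5, 2))
            d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
            frame = pd.DataFrame(d, index=images, columns=images)
            return sr.Space2D("a", "b", pd.DataFrame(xy, index=images), frame)
        s1, s2 = random_space(), random_space()
        rho = sr.individual_global_similarity(s1, s2)
        iu = np.triu_indices(5, k=1)
        va = rankdata(s1.distance.to_numpy()[iu])
        vb = rankdata(s2.distance.to_numpy()[iu])
        oracle = np.corrcoef(va, vb)[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_constant_distances_rejected(self):
        images = ["A", "B", "C"]
        d = pd.DataFrame(np.ones((3, 3)) - np.eye(3), index=images, columns=images)
        space = sr.Space2D("a", "b", pd.DataFrame(index=images), d)
        with pytest.raises(UndefinedCorrelationError):
            sr.individual_global_similarity(space, space)

    def test_idiosyncrasy_compare(self):
        rng = np.random.default_rng(10)
        rp = rng.normal(0.4, 0.1, 30)
        same = sr.idiosyncrasy_compare(rp, rp)
        assert same["t"] == 0.0 and same["p"] == 1.0
        shifted = sr.idiosyncrasy_compare(rp, rp + 0.3)
        assert shifted["t"] > 0
        with pytest.raises(Exception):
            sr.idiosyncrasy_compare([0.1], [0.2])

    def test_individual_global_gap_matches_design(self, small_config):
        # conceptual spaces are designed to track the shared structure better
        enc = sd.simulate_encoding(small_config, 14, 140, 6.0, seed=55)
        images = sorted(set(enc["image_first"]) | set(enc["image_second"]))
        rhos = {"perceptual": [], "conceptual": []}
        pair_of = {"perceptual": ("orientation", "color"),
                   "conceptual": ("size", "climate")}
        for condition, pair in pair_of.items():
            global_sp = sr.global_space(enc, pair, images)
            for pid in enc["participant_id"].unique():
                own = enc[enc["participant_id"] == pid]
                try:
                    ind = sr.global_space(own, pair, images)
                except Exception:
                    continue
                rhos[condition].append(
                    sr.individual_global_similarity(ind, global_sp))
        assert np.mean(rhos["conceptual"]) > np.mean(rhos["perceptual"])


class TestReconstructionDegradation:
    def test_quality_non_increasing_in_noise(self):
        from scipy.stats import spearmanr

        config = sd.generate_latent_configuration(12, 1, seed=60, coord_sd=10.0)
        truth = config.coords["size"]
        means = []
        for noise in (0.0, 8.0, 25.0):
            rhos = []
            for seed in range(12):
                enc = sd.simulate_encoding(config, 1, 60, noise, seed=70 + seed,
                                           shared_weight=SHARED_FULL)
                sol = sr.solve_dimension(sr.build_design_matrix(enc, "size"))
                est = sol.coords
                x = truth.loc[est.index].to_numpy()
                iu = np.triu_indices(len(x), k=1)
                true_d = np.abs(x[:, None] - x[None, :])[iu]
                e = est.to_numpy()
                est_d = np.abs(e[:, None] - e[None, :])[iu]
                rhos.append(spearmanr(true_d, est_d).statistic)
            means.append(np.mean(rhos))
        assert means[0] >= means[1] >= means[2]
        assert means[0] > 0.99
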