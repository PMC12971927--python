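"""Product-of-Gaussians inference: densities, fusion, heatmaps, prediction."""

import numpy as np
import pytest
from scipy import stats

from couinaudps import (
    ALL_LANDMARKS,
    COUINAUD_LANDMARKS,
    DisplacementModel,
    LabelVolume,
    LandmarkSet,
    build_cohort_matrix,
    conditional_log_density,
    fit_displacement_model,
    fuse,
    heatmap,
    landmark_index,
    predict_missing,
)

N = len(ALL_LANDMARKS)


def make_model(pairs):
    """DisplacementModel from {(u, k): (mu, sigma)} with mu = E[l_u - l_k]."""
    mu = np.full((N, N, 3), np.nan)
    sigma = np.full((N, N, 3, 3), np.nan)
    usable = np.zeros((N, N), bool)
    n = np.zeros((N, N), int)
    for (u, k), (m, s) in pairs.items():
        iu, ik = landmark_index(u), landmark_index(k)
        mu[iu, ik] = m
        sigma[iu, ik] = s
        usable[iu, ik] = True
        n[iu, ik] = 99
    return DisplacementModel(
        mu=mu, sigma=sigma, n_samples=n, usable=usable, regularization=0.0
    )


def random_spd(rng, scale=6.0):
    a = rng.normal(size=(3, 3))
    return a @ a.T + scale * np.eye(3)


class TestConditionalLogDensity:
    def test_standard_normal_peak_value(self):
        model = make_model({("UF", "IVCi"): (np.zeros(3), np.eye(3))})
        val = conditional_log_density("UF", "IVCi", [0, 0, 0], model, [0, 0, 0])
        assert val == pytest.approx(-1.5 * np.log(2 * np.pi), abs=1e-12)
        assert val == pytest.approx(-2.75682, abs=1e-5)

    def test_unit_variance_density_ratio(self):
        model = make_model({("UF", "IVCi"): (np.array([10.0, 0, 0]), np.eye(3))})
        at_mean = conditional_log_density("UF", "IVCi", [0, 0, 0], model, [10, 0, 0])
        off = conditional_log_density("UF", "IVCi", [0, 0, 0], model, [11, 0, 0])
        assert at_mean - off == pytest.approx(0.5, abs=1e-12)

    def test_matches_scipy_reference_density(self, rng):
        for _ in range(200):
            m = rng.normal(scale=30, size=3)
            s = random_spd(rng)
            lk = rng.normal(scale=50, size=3)
            v = rng.normal(scale=60, size=3)
            model = make_model({("UF", "IVCi"): (m, s)})
            ours = conditional_log_density("UF", "IVCi", lk, model, v)
            ref = stats.multivariate_normal(mean=lk + m, cov=s).logpdf(v)
            assert ours == pytest.approx(ref, abs=1e-10)

    def test_unusable_pair_identified_in_error(self):
        model = make_model({("UF", "IVCi"): (np.zeros(3), np.eye(3))})
        with pytest.raises(ValueError, match=r"\(UF, IVCs\)"):
            conditional_log_density("UF", "IVCs", [0, 0, 0], model, [0, 0, 0])


class TestFuse:
    def test_single_contributor_mean_is_shifted_position(self):
        model = make_model({("UF", "IVCi"): (np.array([3.0, -2, 7]), 4 * np.eye(3))})
        known = LandmarkSet.from_dict("s", {"IVCi": (10, 10, 10)})
        fused = fuse("UF", known, model)
        assert np.allclose(fused.mean, [13, 8, 17])

    def test_equal_isotropic_contributors_average(self):
        model = make_model({
            ("UF", "IVCi"): (np.array([10.0, 0, 0]), 2 * np.eye(3)),
            ("UF", "IVCs"): (np.array([-10.0, 0, 0]), 2 * np.eye(3)),
        })
        known = LandmarkSet.from_dict("s", {"IVCi": (0, 0, 0), "IVCs": (4, 0, 0)})
        fused = fuse("UF", known, model)
        # predictions are (10,0,0) and (-6,0,0) -> midpoint
        assert np.allclose(fused.mean, [2, 0, 0])

    def test_no_contributor_raises_unpredictable(self):
        model = make_model({("UF", "IVCi"): (np.zeros(3), np.eye(3))})
        known = LandmarkSet.from_dict("s", {"IVCs": (0, 0, 0)})
        with pytest.raises(ValueError, match="unpredictable"):
            fuse("UF", known, model)

    def test_fused_mode_matches_dense_grid_argmax(self, rng):
        """Closed form vs brute-force grid evaluation of the product density."""
        contributors = ["IVCi", "IVCs", "GBF", "LPV", "RPV", "MHV", "RHV", "GB_TOP"]
        for trial in range(10):
            k = int(rng.integers(2, 9))
            names = contributors[:k]
            pairs, known_pos = {}, {}
            for name in names:
                pairs[("UF", name)] = (rng.normal(scale=5, size=3), random_spd(rng))
                known_pos[name] = rng.normal(scale=8, size=3)
            model = make_model(pairs)
            known = LandmarkSet.from_dict("s", known_pos)
            fused = fuse("UF", known, model)
            # independent oracle: dense 0.5 mm grid of summed log densities
            spacing = 0.5
            half = 24
            axes = [fused.mean[i] + spacing * np.arange(-half, half + 1) for i in range(3)]
            grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
            total = np.zeros(grid.shape[:-1])
            for name in names:
                mean = known_pos[name] + pairs[("UF", name)][0]
                total += stats.multivariate_normal(
                    mean=mean, cov=pairs[("UF", name)][1]
                ).logpdf(grid.reshape(-1, 3)).reshape(total.shape)
            idx = np.unravel_index(np.argmax(total), total.shape)
            assert all(0 < i < 2 * half for i in idx), "argmax hit grid boundary"
            grid_mode = grid[idx]
            assert np.linalg.norm(grid_mode - fused.mean) <= spacing * np.sqrt(3)

    def test_additional_contributor_never_reduces_precision(self, rng):
        pairs = {
            ("UF", "IVCi"): (rng.normal(size=3), random_spd(rng)),
            ("UF", "IVCs"): (rng.normal(size=3), random_spd(rng)),
            ("UF", "GBF"): (rng.normal(size=3), random_spd(rng)),
        }
        model = make_model(pairs)
        pos = {"IVCi": (0, 0, 0), "IVCs": (0, 0, 80), "GBF": (35, 60, -45)}
        prev = 0.0
        for k in range(1, 4):
            known = LandmarkSet.from_dict("s", dict(list(pos.items())[:k]))
            lam_min = np.linalg.eigvalsh(fuse("UF", known, model).precision).min()
            assert lam_min >= prev - 1e-12
            prev = lam_min


class TestHeatmap:
    def _setup(self, rng, k=3):
        names = ["IVCi", "IVCs", "GBF"][:k]
        pairs = {("UF", n): (rng.normal(scale=5, size=3), random_spd(rng)) for n in names}
        known = LandmarkSet.from_dict(
            "s", {n: rng.normal(scale=10, size=3) for n in names}
        )
        model = make_model(pairs)
        fused = fuse("UF", known, model)
        affine = np.diag([1.0, 1.0, 1.0, 1.0])
        affine[:3, 3] = fused.mean - 15
        grid = LabelVolume(np.zeros((31, 31, 31), np.int16), affine)
        return model, known, grid, fused

    def test_combined_map_is_sum_of_contributor_maps(self, rng):
        model, known, grid, _ = self._setup(rng)
        combined, per = heatmap("UF", known, model, grid=grid)
        assert len(per) == 3
        assert np.allclose(
            combined.log_density, sum(p.log_density for p in per), atol=1e-9
        )

    def test_single_contributor_combined_equals_contributor(self, rng):
        model, known, grid, _ = self._setup(rng, k=1)
        combined, per = heatmap("UF", known, model, grid=grid)
        assert len(per) == 1
        assert np.array_equal(combined.log_density, per[0].log_density)

    def test_grid_argmax_agrees_with_closed_form(self, rng):
        for _ in range(10):
            model, known, grid, fused = self._setup(rng)
            combined, _ = heatmap("UF", known, model, grid=grid)
            assert np.linalg.norm(combined.argmax_world() - fused.mean) <= np.sqrt(3)


class TestPredictMissing:
    def test_noise_free_cohort_recovers_exact_positions(self, template):
        # identical subjects up to translation: displacement model is exact
        subjects = []
        for i, t in enumerate([(0, 0, 0), (5, 5, 5), (-8, 2, 1), (3, -9, 4), (1, 1, 1)]):
            moved = template.translated(t)
            subjects.append(LandmarkSet(f"s{i}", moved.coords, moved.present))
        model = fit_displacement_model(build_cohort_matrix(subjects))
        partial = template.subset(
            [n for n in ALL_LANDMARKS if n not in COUINAUD_LANDMARKS]
        )
        completed, provenance = predict_missing(partial, model, list(COUINAUD_LANDMARKS))
        for n in COUINAUD_LANDMARKS:
            assert provenance[n] == "predicted"
            assert np.linalg.norm(completed[n] - template[n]) < 1e-6

    def test_translation_equivariance_of_predictions(self, small_cohort):
        model = fit_displacement_model(build_cohort_matrix(small_cohort))
        partial = small_cohort[0].subset(
            [n for n in ALL_LANDMARKS if n not in COUINAUD_LANDMARKS]
        )
        a, _ = predict_missing(partial, model, list(COUINAUD_LANDMARKS))
        b, _ = predict_missing(
            partial.translated([17.0, -4.0, 9.0]), model, list(COUINAUD_LANDMARKS)
        )
        for n in COUINAUD_LANDMARKS:
            assert np.allclose(b[n], a[n] + [17.0, -4.0, 9.0], atol=1e-9)

    def test_present_target_rejected_and_unpredictable_flagged(self):
        model = make_model({("UF", "IVCi"): (np.zeros(3), np.eye(3))})
        known = LandmarkSet.from_dict("s", {"IVCi": (0, 0, 0)})
        with pytest.raises(ValueError, match="already present"):
            predict_missing(known, model, ["IVCi"])
        completed, provenance = predict_missing(known, model, ["UF", "RHV"])
        assert provenance["UF"] == "predicted"
        assert provenance["RHV"] == "unpredictable"
        assert not completed.is_present("RHV")
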