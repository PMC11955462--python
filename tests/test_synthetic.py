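"""Tests of the synthetic cohort generator against independent oracles."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage
from scipy.stats import spearmanr

from hemil.synthetic import (BASE_BLOB_DENSITY, PATCH_AREA, SyntheticCohortSpec,
                             generate_cohort, make_signature, render_tile,
                             simulate_survival, synthesize_expression)


def count_brown_blobs(img: np.ndarray) -> int:
    """Independent color-range detector + connected-component count."""
    r, g, b = img[..., 0].astype(int), img[..., 1].astype(int), img[..., 2].astype(int)
    brown = (r >= 80) & (r <= 150) & (g >= 50) & (g <= 110) & (b < 75) & (r > g) & (g > b)
    _, n = ndimage.label(brown)
    return n


class TestRenderTile:
    def test_zero_m2_matches_base_density_within_poisson_error(self):
        """At m2=0 the blob count should equal base_density x tissue area."""
        total, expected = 0, 0.0
        for seed in range(100):
            img, mask = render_tile(0.0, 5.0, 448, seed=seed, return_mask=True)
            total += count_brown_blobs(img)
            expected += BASE_BLOB_DENSITY * mask.sum() / PATCH_AREA
        # Poisson sd plus a small allowance for blob merging
        assert abs(total - expected) < 4 * np.sqrt(expected) + 0.05 * expected

    def test_high_m2_strictly_raises_blob_count(self):
        lo = sum(count_brown_blobs(render_tile(0.0, 5.0, 448, seed=s))
                 for s in range(100))
        hi = sum(count_brown_blobs(render_tile(1.0, 5.0, 448, seed=1000 + s))
                 for s in range(100))
        assert hi > lo

    def test_planted_monotonicity_rank_correlation(self):
        rng = np.random.default_rng(0)
        levels = rng.uniform(0, 1, 100)
        counts = [count_brown_blobs(render_tile(m, 5.0, 448, seed=i))
                  for i, m in enumerate(levels)]
        rho, p = spearmanr(levels, counts)
        assert rho > 0 and p < 0.01

    def test_no_tissue_gives_pure_white_tile_failing_filter(self):
        from hemil.patches import filter_background, tile_image
        img = render_tile(0.7, 5.0, 448, seed=0, tissue_coverage=0.0)
        assert (img == 255).all()
        assert filter_background(tile_image(img)) == []

    def test_background_near_white(self):
        img, mask = render_tile(0.5, 5.0, 448, seed=3, return_mask=True)
        assert (img[~mask] >= 240).all()

    def test_deterministic_given_seed(self):
        a = render_tile(0.4, 5.0, 224, seed=11)
        b = render_tile(0.4, 5.0, 224, seed=11)
        assert np.array_equal(a, b)

    def test_small_tile_rejected(self):
        with pytest.raises(ValueError):
            render_tile(0.5, 5.0, 223, seed=0)


class TestSynthesizeExpression:
    def test_noiseless_equals_linear_mixture(self):
        sig = make_signature(30, 4, seed=0)
        f = np.array([0.1, 0.2, 0.3, 0.4])
        assert np.allclose(synthesize_expression(f, sig, 0.0), sig.to_numpy() @ f)

    def test_unit_fraction_returns_signature_column(self):
        sig = make_signature(30, 4, seed=0)
        f = np.array([0.0, 1.0, 0.0, 0.0])
        assert np.allclose(synthesize_expression(f, sig, 0.0), sig.iloc[:, 1])

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            synthesize_expression(np.array([0.5, 0.5]), make_signature(30, 4), 0.0)

    def test_noise_truncated_at_zero_and_deterministic(self):
        sig = make_signature(30, 4, seed=0)
        f = np.array([0.25] * 4)
        a = synthesize_expression(f, sig, 0.5, seed=3)
        assert (a >= 0).all()
        assert np.array_equal(a, synthesize_expression(f, sig, 0.5, seed=3))


class TestSimulateSurvival:
    def test_no_censoring_means_all_events(self):
        df = simulate_survival(["high"] * 10 + ["low"] * 10, np.log(4), 0.02, 0.0, seed=0)
        assert (df["event"] == 1).all()

    def test_empty_labels_rejected(self):
        with pytest.raises(ValueError):
            simulate_survival([], 0.0, 0.02, 0.2)

    def test_censoring_rate_calibrated(self):
        df = simulate_survival(["high"] * 2000 + ["low"] * 2000, np.log(4),
                               0.02, 0.3, seed=1)
        assert abs((1 - df["event"].mean()) - 0.3) < 0.03

    def test_high_group_dies_faster_on_average(self):
        df = simulate_survival(["high"] * 500 + ["low"] * 500, np.log(4),
                               0.02, 0.0, seed=2)
        assert (df.loc[df.group == "high", "time_months"].mean()
                < df.loc[df.group == "low", "time_months"].mean())


class TestGenerateCohort:
    def test_two_patient_cohort_artifact_counts(self, tmp_path):
        spec = SyntheticCohortSpec(n_patients=2, tiles_per_patient=1, tile_size=224,
                                   zero_inflation_prob=0.0, seed=5)
        manifest = generate_cohort(spec, tmp_path)
        assert len(list((tmp_path / "tiles").glob("*.png"))) == 2
        assert len(pd.read_csv(tmp_path / "ground_truth.csv")) == 2
        assert len(pd.read_csv(tmp_path / "survival.csv")) == 2
        assert len(manifest["patients"]) == 2

    def test_same_spec_and_seed_reproduces_manifest_bytes(self, tmp_path):
        spec = SyntheticCohortSpec(n_patients=3, tiles_per_patient=1, tile_size=224, seed=7)
        generate_cohort(spec, tmp_path / "a")
        generate_cohort(spec, tmp_path / "b")
        assert ((tmp_path / "a/manifest.json").read_bytes()
                == (tmp_path / "b/manifest.json").read_bytes())
        assert ((tmp_path / "a/ground_truth.csv").read_bytes()
                == (tmp_path / "b/ground_truth.csv").read_bytes())

    def test_zero_inflation_reproduces_exclusion_pathway(self, tmp_path):
        """With the study-sized cohort, about a quarter of patients should
        have exactly zero M2 infiltration (binomial around 21 of 86)."""
        spec = SyntheticCohortSpec(n_patients=86, tiles_per_patient=1, tile_size=224,
                                   zero_inflation_prob=21 / 86, seed=9)
        manifest = generate_cohort(spec, tmp_path)
        sd = np.sqrt(86 * (21 / 86) * (1 - 21 / 86))
        assert abs(manifest["n_zero_m2"] - 21) < 4 * sd
        truth = pd.read_csv(tmp_path / "ground_truth.csv")
        zero = truth[truth["true_m2_fraction"] == 0]
        assert (zero["true_label"] == "low").all()

    def test_label_is_high_iff_fraction_above_cohort_mean(self, tmp_path):
        spec = SyntheticCohortSpec(n_patients=12, tiles_per_patient=1, tile_size=224, seed=3)
        generate_cohort(spec, tmp_path)
        truth = pd.read_csv(tmp_path / "ground_truth.csv")
        boundary = truth["true_m2_fraction"].mean()
        expect = np.where(truth["true_m2_fraction"] > boundary, "high", "low")
        assert (truth["true_label"] == expect).all()

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            SyntheticCohortSpec(n_patients=0)
        with pytest.raises(ValueError):
            SyntheticCohortSpec(tile_size=100)
        with pytest.raises(ValueError):
            SyntheticCohortSpec(censor_rate=1.5)
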