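"""Observer components: GDL oracle values, network mechanics, training
sanity, rule-based segmentation."""

import numpy as np
import pytest

from lvdose import phantom as ph
from lvdose.segmenter import (
    NetConfig,
    NetObserver,
    RuleBasedObserver,
    TrainRecipe,
    TrainingCase,
    generalized_dice_loss,
    noise_robust_recipe,
    rule_based_segment,
    standard_recipe,
    train_observer,
)
from lvdose.segmenter.loss import softmax_gdl_grad
from lvdose.segmenter.unet import ResUNet3D
from lvdose.volumes import Grid, ImageVolume


def brute_force_gdl(p, r, eps=1e-5):
    """Direct formula evaluation, independent loop-based arithmetic."""
    num = den = 0.0
    for l in range(p.shape[0]):
        w = 1.0 / (r[l].sum() + eps) ** 2
        num += w * float((r[l] * p[l]).sum())
        den += w * float((r[l] + p[l]).sum())
    return 1.0 - 2.0 * num / den


class TestGeneralizedDiceLoss:
    def test_perfect_prediction_is_zero(self):
        r = np.eye(3, dtype=float)[np.random.default_rng(0).integers(0, 3, (4, 4))]
        r = r.transpose(2, 0, 1)
        assert generalized_dice_loss(r, r) == pytest.approx(0.0, abs=1e-3)

    def test_totally_wrong_prediction_is_one(self):
        r = np.zeros((2, 4))
        r[0] = 1.0
        p = np.zeros((2, 4))
        p[1] = 1.0
        assert generalized_dice_loss(p, r) == pytest.approx(1.0, abs=1e-6)

    def test_four_voxel_toy_matches_brute_force(self):
        r = np.array([[1, 1, 0, 0], [0, 0, 1, 1]], dtype=float)
        p1 = np.array([0.8, 0.6, 0.3, 0.1])
        p = np.stack([p1, 1 - p1])
        assert generalized_dice_loss(p, r) == pytest.approx(brute_force_gdl(p, r), abs=1e-12)

    def test_voxel_permutation_invariance(self, rng):
        r = np.eye(3)[rng.integers(0, 3, 50)].T
        p = rng.dirichlet(np.ones(3), size=50).T
        perm = rng.permutation(50)
        assert generalized_dice_loss(p, r) == pytest.approx(
            generalized_dice_loss(p[:, perm], r[:, perm]))

    def test_loss_decreases_as_mass_moves_to_reference(self):
        r = np.array([[1.0, 0.0], [0.0, 1.0]])
        losses = []
        for a in (0.4, 0.6, 0.8, 0.99):
            p = np.array([[a, 1 - a], [1 - a, a]])
            losses.append(generalized_dice_loss(p, r))
        assert all(b < a for a, b in zip(losses, losses[1:]))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            generalized_dice_loss(np.ones((2, 3)) / 2, np.ones((2, 4)))

    def test_softmax_gradient_matches_finite_differences(self, rng):
        logits = rng.normal(size=(3, 2, 2, 2)).astype(np.float32)
        ref = np.eye(3, dtype=np.float32)[rng.integers(0, 3, (2, 2, 2))].transpose(3, 0, 1, 2)
        _, g = softmax_gdl_grad(logits, ref)
        eps = 1e-3
        for _ in range(5):
            idx = tuple(rng.integers(0, s) for s in logits.shape)
            lp = logits.copy(); lp[idx] += eps
            lm = logits.copy(); lm[idx] -= eps
            fd = (softmax_gdl_grad(lp, ref)[0] - softmax_gdl_grad(lm, ref)[0]) / (2 * eps)
            assert g[idx] == pytest.approx(fd, abs=1e-4)


@pytest.fixture(scope="module")
def tiny_cases(study_grid):
    """Four noise-free phantom phases at study resolution."""
    cases = []
    for i, spec in enumerate(ph.generate_cohort(2, seed=42)):
        for phase in ("ED", "ES"):
            lab, img = ph.voxelize_phase(spec, phase, study_grid)
            cases.append(TrainingCase(f"t{i}", 500.0, img, lab))
    return cases


TINY_NET = NetConfig(base_channels=2, patch_size=(16, 16, 16), n_levels=3,
                     residual_blocks_per_level=1)


class TestTraining:
    def test_loss_decreases_on_toy_run(self, tiny_cases):
        recipe = standard_recipe(500.0, epochs=16, batch_size=2, draws_per_epoch=8,
                                 learning_rate=2e-3, seed=0)
        obs = train_observer(TINY_NET, recipe, tiny_cases)
        # per-epoch losses are noisy (few random patches); compare the mean
        # of the last epochs against the first epochs
        assert np.mean(obs.loss_history[-4:]) < np.mean(obs.loss_history[:4])

    def test_training_reproducible_for_fixed_seed(self, tiny_cases):
        recipe = standard_recipe(500.0, epochs=2, batch_size=2, draws_per_epoch=4,
                                 learning_rate=2e-3, seed=7)
        a = train_observer(TINY_NET, recipe, tiny_cases)
        b = train_observer(TINY_NET, recipe, tiny_cases)
        assert a.loss_history == b.loss_history

    def test_recipes_audit_their_dose_levels(self, tiny_cases, study_grid):
        low = [TrainingCase(c.case_id, 25.0, c.image, c.labels) for c in tiny_cases]
        recipe = standard_recipe(500.0, epochs=1, draws_per_epoch=2, batch_size=1)
        obs_std = train_observer(TINY_NET, recipe, tiny_cases + low)
        assert {d for _, d in obs_std.dataset_audit} == {500.0}
        obs_nr = train_observer(
            TINY_NET, noise_robust_recipe(epochs=1, draws_per_epoch=2, batch_size=1),
            tiny_cases + low)
        assert {d for _, d in obs_nr.dataset_audit} == {500.0, 25.0}

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="no training cases"):
            train_observer(TINY_NET, standard_recipe(500.0), [])

    def test_patch_larger_than_volume_rejected(self, tiny_cases):
        big = NetConfig(base_channels=2, patch_size=(128, 128, 128), n_levels=3)
        with pytest.raises(ValueError, match="smaller than patch"):
            train_observer(big, standard_recipe(500.0), tiny_cases)


class TestInference:
    @pytest.fixture(scope="class")
    def trained(self, tiny_cases):
        recipe = standard_recipe(500.0, epochs=10, batch_size=2, draws_per_epoch=6,
                                 learning_rate=2e-3, seed=3)
        return train_observer(TINY_NET, recipe, tiny_cases)

    def test_untrained_observer_refuses_to_segment(self, coarse_phases):
        obs = NetObserver(TINY_NET)
        with pytest.raises(RuntimeError, match="not been trained"):
            obs.segment(coarse_phases["ED"][1])

    def test_output_grid_matches_input_and_is_deterministic(self, trained, coarse_phases):
        img = coarse_phases["ED"][1]
        a = trained.segment(img)
        b = trained.segment(img)
        assert a.grid == img.grid
        assert np.array_equal(a.array, b.array)
        assert set(np.unique(a.array)) <= {0, 1, 2}

    def test_checkpoint_roundtrip_preserves_predictions(self, trained, coarse_phases, tmp_path):
        prefix = str(tmp_path / "obs")
        trained.save(prefix)
        loaded = NetObserver.load(prefix)
        img = coarse_phases["ED"][1]
        assert np.array_equal(trained.segment(img).array, loaded.segment(img).array)


class TestRuleBased:
    def test_noise_free_phantom_interior_dice_is_one(self, coarse_phases):
        from scipy.ndimage import binary_erosion

        labels, image = coarse_phases["ED"]
        pred = rule_based_segment(image, smooth_sigma_vox=0.0)
        for class_id in (1, 2):
            # boundary voxels are ambiguous under smoothing-free thresholds;
            # interior agreement must be exact
            interior = binary_erosion(labels.array == class_id)
            assert np.all(pred.array[interior] == class_id)
        # and overall Dice is near-perfect
        from lvdose.metrics import dice
        assert dice(pred, labels, 1) > 0.99
        assert dice(pred, labels, 2) > 0.99

    def test_all_background_image_yields_all_background(self, study_grid):
        img = ImageVolume(array=np.full(study_grid.shape, 40.0, np.float32), grid=study_grid)
        pred = rule_based_segment(img)
        assert not pred.array.any()

    def test_inverted_thresholds_rejected(self, coarse_phases):
        with pytest.raises(ValueError, match="increasing"):
            rule_based_segment(coarse_phases["ED"][1], hu_thresholds=(225.0, 70.0))
        with pytest.raises(ValueError, match="increasing"):
            RuleBasedObserver(hu_thresholds=(225.0, 70.0))


class TestNetConfig:
    def test_patch_divisibility_enforced(self):
        with pytest.raises(ValueError, match="divisible"):
            NetConfig(patch_size=(30, 32, 32))

    def test_deterministic_initialization(self):
        a = ResUNet3D(TINY_NET, seed=4).state_dict()
        b = ResUNet3D(TINY_NET, seed=4).state_dict()
        assert all(np.array_equal(a[k], b[k]) for k in a)
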