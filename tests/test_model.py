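"""Architecture contracts, parameter accounting, training mechanics and
inference determinism of the landmark network."""

import numpy as np
import pytest

from softmark.model import (
    LandmarkCNN,
    TrainConfig,
    count_parameters,
    spec_for_schema,
    train_model,
)
from softmark.pipeline import resize_normalize, samples_to_arrays
from softmark.schemas import FRONTAL_SCHEMA, PROFILE_SCHEMA


def test_spatial_trace_and_flatten_width():
    spec = spec_for_schema(FRONTAL_SCHEMA)
    assert spec.spatial_trace() == [126, 63, 61, 30, 28, 14, 12, 6]
    assert spec.flatten_width() == 6 * 6 * 256 == 9216


def test_parameter_count_layer_formulas():
    spec = spec_for_schema(FRONTAL_SCHEMA)
    # first conv block: (3*3*3 + 1) * 32
    assert (3 * 3 * 3 + 1) * 32 == 896
    # dense 9216 -> 512
    assert (9216 + 1) * 512 == 4_719_104
    assert count_parameters(spec) == 5_130_092
    profile_spec = spec_for_schema(PROFILE_SCHEMA)
    assert count_parameters(profile_spec) == 5_130_092 - (512 + 1) * 14


def test_built_network_parameter_count_matches_formula():
    est = LandmarkCNN(view="frontal").initialize()
    built = sum(p.size for p in est.network_.params)
    assert built == count_parameters(est.spec_)


@pytest.mark.parametrize("view,width", [("frontal", 44), ("profile", 30)])
def test_output_widths_and_sigmoid_range(view, width, rng):
    est = LandmarkCNN(view=view).initialize()
    X = rng.random((2, 128, 128, 3)).astype(np.float32)
    out = est.predict(X)
    assert out.shape == (2, width)
    assert np.all((out > 0) & (out < 1))


def test_unknown_view_rejected():
    import softmark

    with pytest.raises(softmark.SchemaError):
        LandmarkCNN(view="oblique").initialize()


def test_empty_training_set_errors():
    with pytest.raises(ValueError):
        train_model([], None, "frontal")


def test_overfit_single_sample(rng):
    """Optimizer sanity oracle: with dropout off, the network memorizes
    one sample to near-zero training loss."""
    X = rng.random((1, 128, 128, 3)).astype(np.float32)
    y = rng.uniform(0.2, 0.8, (1, 44)).astype(np.float32)
    est = LandmarkCNN(view="frontal", learning_rate=1e-3, max_epochs=100,
                      early_stopping=False, batch_size=1, dropout_rate=0.0)
    est.fit(X, y)
    assert est.history_["train_loss"][-1] < 1e-4


def test_early_stopping_restores_best_weights(rng):
    """The returned weights belong to the best-validation epoch; the best
    monitored loss is never worse than the final epoch's."""
    X = rng.random((8, 128, 128, 3)).astype(np.float32)
    y = rng.uniform(0.2, 0.8, (8, 44)).astype(np.float32)
    Xv = rng.random((4, 128, 128, 3)).astype(np.float32)
    yv = rng.uniform(0.2, 0.8, (4, 44)).astype(np.float32)
    est = LandmarkCNN(view="frontal", learning_rate=1e-3, max_epochs=8,
                      patience=3)
    est.fit(X, y, Xv, yv)
    vals = est.history_["val_loss"]
    assert est.best_epoch_ == int(np.argmin(vals))
    assert est.best_val_loss_ <= vals[-1] + 1e-12
    # restored weights reproduce the recorded best validation loss
    assert est.network_.evaluate_loss(Xv, yv) == pytest.approx(
        est.best_val_loss_, rel=1e-6)


def test_prediction_bit_identical_across_calls(frontal_image):
    est = LandmarkCNN(view="frontal").initialize()
    a = est.predict_image(frontal_image)
    b = est.predict_image(frontal_image)
    assert [(p.x, p.y) for p in a] == [(p.x, p.y) for p in b]
    assert len(a) == 22
    # predictions always inside the image rectangle
    for p in a:
        assert 0 < p.x < frontal_image.width
        assert 0 < p.y < frontal_image.height


def test_view_mismatch_rejected(profile_image):
    est = LandmarkCNN(view="frontal").initialize()
    with pytest.raises(ValueError, match="view"):
        est.predict_image(profile_image)


def test_training_reduces_error_on_small_cohort(small_cohort):
    """Learning smoke test at reduced scale: a briefly trained model beats
    the untrained initialization on held-out subjects."""
    train_imgs = [im for im in small_cohort
                  if im.view == "frontal"][:6]
    test_imgs = [im for im in small_cohort if im.view == "frontal"][6:]
    cfg = TrainConfig(learning_rate=1e-3, max_epochs=4, patience=4,
                      batch_size=4)
    model = train_model([resize_normalize(im) for im in train_imgs],
                        None, "frontal", cfg)
    untrained = LandmarkCNN(view="frontal", init_seed=7).initialize()
    te = [resize_normalize(im) for im in test_imgs]
    X, y = samples_to_arrays(te)

    def mean_err(m):
        return float(np.abs(m.predict(X) - y).mean())

    assert mean_err(model) < mean_err(untrained)


def test_save_load_round_trip(tmp_path, rng):
    X = rng.random((4, 128, 128, 3)).astype(np.float32)
    y = rng.uniform(0.2, 0.8, (4, 30)).astype(np.float32)
    est = LandmarkCNN(view="profile", learning_rate=1e-3, max_epochs=2,
                      patience=2)
    est.fit(X, y)
    est.save(tmp_path / "m")
    back = LandmarkCNN.load(tmp_path / "m")
    np.testing.assert_array_equal(back.predict(X), est.predict(X))
    assert back.view == "profile"
    assert (tmp_path / "m" / "history.csv").exists()


def test_sklearn_get_set_params_clone():
    from sklearn.base import clone

    est = LandmarkCNN(view="profile", learning_rate=5e-4)
    params = est.get_params()
    assert params["view"] == "profile"
    cloned = clone(est)
    assert cloned.get_params() == params
    cloned.set_params(batch_size=8)
    assert cloned.batch_size == 8
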