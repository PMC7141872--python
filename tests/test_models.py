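"""Architecture construction, parameter counts and the training loop."""

import numpy as np
import pytest

from ensgrad.models import (
    ARCHITECTURES,
    ArchitectureSpec,
    TrainedModel,
    TrainingConfig,
    build_architecture,
    build_from_spec,
    build_multioutput,
    count_parameters,
    train_model,
)
from ensgrad.sequences import encode_batch

PRINTED_TOTALS = {
    "Seq_32_32": 13954,
    "Seq_32x1_16": 8402,
    "Seq_32x2_16": 18706,
    "Seq_64x1_16": 16754,
    "Seq_32x1_16_filt3": 7122,
    "Seq_embed_32x1_16": 13082,
}


@pytest.mark.parametrize("name,total", sorted(PRINTED_TOTALS.items()))
def test_parameter_counts_match_reference_totals(name, total):
    assert count_parameters(build_architecture(name)) == total


def test_parameter_count_by_independent_layer_arithmetic():
    # Seq_32x1_16: conv 5*20*32+32, dense (10*32)*16+16, head 16*2+2
    conv = 5 * 20 * 32 + 32
    dense = (10 * 32) * 16 + 16
    head = 16 * 2 + 2
    assert conv + dense + head == 8402
    assert count_parameters(build_architecture("Seq_32x1_16")) == conv + dense + head


def test_degenerate_dense_spec_closed_form():
    spec = ArchitectureSpec("tiny", (), (1,), n_outputs=1)
    model = build_from_spec(spec)
    assert count_parameters(model) == 400 * 1 + 1 + 1 * 1 + 1  # 403


def test_unknown_architecture_lists_valid_names():
    with pytest.raises(ValueError, match="Seq_32_32"):
        build_architecture("nope")


def test_multioutput_same_trunk_same_count():
    # two regression units replace the two-head output: count unchanged
    assert count_parameters(build_multioutput("Seq_32x1_16", 2)) == 8402
    with pytest.raises(ValueError, match="n_targets"):
        build_multioutput("Seq_32x1_16", 1)


def test_predict_deterministic_and_batch_invariant(small_model, campaign):
    x = campaign["x"][:8]
    a = small_model.predict(x)
    b = small_model.predict(x)
    assert np.array_equal(a, b)
    single = np.stack([small_model.predict(x[i])[0] for i in range(8)])
    assert np.allclose(a, single, atol=1e-10)


def test_predict_all_zero_input_is_finite(small_model):
    out = small_model.predict(np.zeros((1, 20, 20)))
    assert np.all(np.isfinite(out))


def test_predict_rejects_wrong_shape(small_model):
    with pytest.raises(ValueError, match="expected"):
        small_model.predict(np.zeros((1, 19, 20)))


def test_single_example_memorization():
    x = encode_batch(["ACDEFGHIKL"])
    y = np.array([0.7])
    lab = np.array([True])
    model = build_from_spec(
        ArchitectureSpec("memo", (), (32, 32), dropout_rate=0.0), seed=0
    )
    train_model(model, x, y, lab,
                TrainingConfig(max_epochs=400, patience=400, learning_rate=1e-2, seed=1))
    assert (model.predict_enrichment(x)[0] - 0.7) ** 2 < 1e-3


def test_training_is_seed_reproducible(campaign):
    x, y, lab = campaign["x"][:200], campaign["y"][:200], campaign["labels"][:200]
    preds = []
    for _ in range(2):
        m = build_architecture("Seq_32_32", seed=4)
        train_model(m, x, y, lab, TrainingConfig(max_epochs=5, seed=5))
        preds.append(m.predict_enrichment(x[:10]))
    assert np.array_equal(preds[0], preds[1])


def test_multioutput_loss_masks_missing_targets():
    # the loss-mask identity: a fully missing target contributes neither
    # loss nor gradient, so training reduces to the observed target
    from ensgrad.models import _loss_and_grad

    out = np.array([[0.5, -1.0], [0.2, 3.0]])
    y_full = np.array([[0.0, np.nan], [1.0, np.nan]])
    cfg = TrainingConfig()
    loss, dy = _loss_and_grad(out, y_full, None, cfg)
    expected = np.mean((out[:, 0] - np.array([0.0, 1.0])) ** 2)
    assert loss == pytest.approx(expected)
    assert np.all(dy[:, 1] == 0.0)

    # partial missingness: loss averages over observed entries only
    y_part = np.array([[0.0, 2.0], [1.0, np.nan]])
    loss_p, dy_p = _loss_and_grad(out, y_part, None, cfg)
    resid = [out[0, 0] - 0.0, out[0, 1] - 2.0, out[1, 0] - 1.0]
    assert loss_p == pytest.approx(np.mean(np.array(resid) ** 2))
    assert dy_p[1, 1] == 0.0


def test_multioutput_training_runs_with_nan_targets(campaign):
    x, y = campaign["x"][:300], campaign["y"][:300]
    y2 = np.stack([y, np.full_like(y, np.nan)], axis=1)
    m2 = build_multioutput("Seq_32_32", 2, seed=6)
    train_model(m2, x, y2, None, TrainingConfig(max_epochs=5, seed=7))
    assert np.all(np.isfinite(m2.predict(x[:20])))


def test_checkpoint_roundtrip(tmp_path, small_model, campaign):
    path = tmp_path / "model.npz"
    small_model.save(path)
    loaded = TrainedModel.load(path)
    x = campaign["x"][:5]
    assert np.allclose(loaded.predict(x), small_model.predict(x))
    assert loaded.spec.name == small_model.spec.name
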