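import numpy as np
import pytest

from resprop import (
    ModelConfig,
    ProteinRecord,
    build_model,
    build_transformer_variant,
    decode_angles,
    encode_angles,
    load_checkpoint,
    one_hot_encode,
    predict_bundle,
    rsa_to_asa,
    save_checkpoint,
)
from resprop.core import DEFAULT_MAX_ASA, ValidationError, max_asa_vector
from resprop.network import HEAD_WIDTHS, MultiTaskModel, heads_to_bundle


def run_model(model, rng, L=15, D=20, B=1):
    x = rng.normal(size=(B, L, D))
    mask = np.ones((B, L), dtype=bool)
    model.eval()
    return model(x, mask), x, mask


class TestArchitectureShapes:
    def test_full_config_feature_width_one_hot(self):
        model = build_model(ModelConfig(input_dim=20, fc_width=64,
                                        lstm_hidden=8, lstm_layers=1))
        assert model.feature_width == 20 + 32 + 32  # input + two conv branches

    def test_full_config_feature_width_lm(self):
        model = build_model(ModelConfig(input_dim=1280, fc_width=64,
                                        lstm_hidden=8, lstm_layers=1))
        assert model.feature_width == 1280 + 32 + 32

    def test_full_kernel_heads_preserve_length(self, rng):
        model = build_model(ModelConfig(input_dim=20, fc_width=32,
                                        lstm_hidden=8, lstm_layers=1))
        out, _, _ = run_model(model, rng, L=15)
        for task, width in HEAD_WIDTHS.items():
            assert out[task].shape == (1, 15, width)

    def test_reduced_config_head_shapes(self, tiny_config, rng):
        model = build_model(tiny_config)
        out, _, _ = run_model(model, rng, L=7)
        assert {t: v.shape[-1] for t, v in out.items()} == HEAD_WIDTHS

    @pytest.mark.parametrize("L", [1, 2, 50])
    def test_length_preservation(self, tiny_config, rng, L):
        model = build_model(tiny_config)
        out, _, _ = run_model(model, rng, L=L)
        assert all(v.shape[1] == L for v in out.values())

    def test_transformer_same_head_contract(self, tiny_transformer_config, rng):
        model = build_transformer_variant(tiny_transformer_config)
        out, _, _ = run_model(model, rng, L=15)
        assert {t: v.shape[-1] for t, v in out.items()} == HEAD_WIDTHS

    def test_non_finite_input_rejected(self, tiny_config):
        model = build_model(tiny_config)
        x = np.full((1, 5, 20), np.nan)
        with pytest.raises(ValidationError, match="non-finite"):
            model(x, np.ones((1, 5), dtype=bool))

    def test_builders_check_downstream_field(self, tiny_config, tiny_transformer_config):
        with pytest.raises(ValidationError):
            build_model(tiny_transformer_config)
        with pytest.raises(ValidationError):
            build_transformer_variant(tiny_config)


class TestForwardRanges:
    @pytest.mark.parametrize("variant", ["cnn_bilstm", "transformer"])
    def test_activation_ranges_and_determinism(self, variant, tiny_config,
                                               tiny_transformer_config, rng):
        cfg = tiny_config if variant == "cnn_bilstm" else tiny_transformer_config
        model = MultiTaskModel(cfg)
        out, x, mask = run_model(model, rng, L=20)
        assert out["rsa"].data.min() >= 0.0 and out["rsa"].data.max() <= 1.0
        for task in ("phi", "psi"):
            assert np.abs(out[task].data).max() <= 1.0
        # deterministic in eval mode
        again = model(x, mask)
        for task in out:
            np.testing.assert_array_equal(out[task].data, again[task].data)

    @pytest.mark.parametrize("variant", ["cnn_bilstm", "transformer"])
    def test_padding_non_interference(self, variant, tiny_config,
                                      tiny_transformer_config, rng):
        cfg = tiny_config if variant == "cnn_bilstm" else tiny_transformer_config
        model = MultiTaskModel(cfg)
        model.eval()
        L, pad = 12, 6
        x = rng.normal(size=(1, L, 20))
        out = model(x, np.ones((1, L), dtype=bool))
        xp = np.concatenate([x, rng.normal(size=(1, pad, 20))], axis=1)
        mask = np.zeros((1, L + pad), dtype=bool)
        mask[0, :L] = True
        padded = model(xp, mask)
        for task in out:
            np.testing.assert_allclose(
                padded[task].data[0, :L], out[task].data[0], atol=1e-4)

    def test_mask_must_be_trailing(self, tiny_config, rng):
        model = build_model(tiny_config)
        mask = np.ones((1, 6), dtype=bool)
        mask[0, 2] = False
        with pytest.raises(ValidationError, match="contiguous"):
            model(rng.normal(size=(1, 6, 20)), mask)


class TestAngleCodec:
    def test_axis_identities(self):
        assert decode_angles(np.array([[0.0, 1.0]]))[0] == 0.0
        assert decode_angles(np.array([[1.0, 0.0]]))[0] == 90.0
        assert decode_angles(np.array([[0.0, -1.0]]))[0] == 180.0
        assert decode_angles(np.array([[-1.0, 0.0]]))[0] == -90.0

    def test_round_trip_over_grid(self):
        grid = np.linspace(-179.9, 180.0, 721)
        decoded = decode_angles(encode_angles(grid))
        np.testing.assert_allclose(decoded, grid, atol=1e-6)

    def test_zero_row_raises_or_uses_sentinel(self):
        sc = np.zeros((1, 2))
        with pytest.raises(ValidationError, match="position 0"):
            decode_angles(sc)
        assert decode_angles(sc, zero_sentinel=0.0)[0] == 0.0


class TestAsa:
    def test_zero_rsa_gives_zero_asa(self):
        assert (rsa_to_asa(np.zeros(3), "ACD") == 0.0).all()

    def test_unit_rsa_recovers_table(self):
        seq = "AWP"
        np.testing.assert_array_equal(
            rsa_to_asa(np.ones(3), seq),
            [DEFAULT_MAX_ASA[c] for c in seq])

    def test_half_rsa_alanine(self):
        # alanine maximum is 129 Å²
        assert rsa_to_asa(np.array([0.5]), "A")[0] == 64.5

    def test_exact_product_in_bundle(self, tiny_config, rng):
        model = build_model(tiny_config)
        seq = "ACDEFGHIKLMNPQRSTVWYX"[:20]
        bundle = predict_bundle(model, one_hot_encode(ProteinRecord("p", seq)), seq)
        np.testing.assert_array_equal(
            bundle.asa, bundle.rsa * max_asa_vector(seq))


class TestBundlesAndWindows:
    def test_probability_rows_are_simplexes(self, tiny_config, rng):
        model = build_model(tiny_config)
        seq = "ACDEFGHIKLMNPQRSTVWY"
        bundle = predict_bundle(model, one_hot_encode(ProteinRecord("p", seq)), seq)
        for probs in (bundle.q8_probs, bundle.q3_probs, bundle.disorder_probs):
            np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)
            assert (probs >= 0).all()

    def test_windowed_prediction_agrees_with_plan(self, tiny_config, rng):
        """A long sequence is predicted window-by-window; rows inside a
        window's keep interval must equal a direct forward pass on that
        window."""
        model = build_model(tiny_config)
        L = 150
        seq = "".join(np.random.default_rng(3).choice(list("ACDEFGHIKL"), L))
        emb = one_hot_encode(ProteinRecord("p", seq))
        bundle = predict_bundle(model, emb, seq,
                                window_size=64, window_stride=48, window_trim=5)
        assert len(bundle) == L
        from resprop.encode import plan_windows
        plan = plan_windows(L, 64, 48, 5)
        w = plan.windows[1]
        direct = model(emb.values[None, w.start:w.end],
                       np.ones((1, w.end - w.start), dtype=bool))
        np.testing.assert_allclose(
            bundle.rsa[w.keep_start:w.keep_end],
            direct["rsa"].data[0, w.keep_start - w.start:w.keep_end - w.start, 0],
            atol=1e-12)

    def test_heads_to_bundle_angle_decoding(self):
        L = 4
        raw = {
            "q8": np.zeros((L, 8)), "q3": np.zeros((L, 3)),
            "disorder": np.zeros((L, 2)), "rsa": np.full((L, 1), 0.25),
            "phi": encode_angles(np.array([-120.0, 0.0, 90.0, 180.0])),
            "psi": encode_angles(np.array([45.0, -45.0, 135.0, -135.0])),
        }
        bundle = heads_to_bundle(raw, "ACDE")
        np.testing.assert_allclose(bundle.phi_deg, [-120.0, 0.0, 90.0, 180.0],
                                   atol=1e-10)
        np.testing.assert_allclose(bundle.psi_deg, [45.0, -45.0, 135.0, -135.0],
                                   atol=1e-10)


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tiny_config, rng, tmp_path):
        model = build_model(tiny_config)
        path = tmp_path / "model.npz"
        save_checkpoint(model, path)
        clone = load_checkpoint(path)
        x = rng.normal(size=(1, 9, 20))
        mask = np.ones((1, 9), dtype=bool)
        model.eval()
        clone.eval()
        a = model(x, mask)
        b = clone(x, mask)
        for task in a:
            np.testing.assert_array_equal(a[task].data, b[task].data)
        assert clone.config.to_dict() == model.config.to_dict()
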