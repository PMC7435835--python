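import numpy as np
import pytest

import apneakit as ak
from apneakit.model import ConfigurationError, architecture_descriptor


def reference_parameter_count():
    """Spreadsheet-style enumeration of the 10-layer architecture.

    conv1 (32*1+1)*45; conv2..10 (32*45+1)*45 each; BN 4*45 per feature
    layer; FC1 225*512+512; FC2..4 512*512+512 each; BN 4*512 per
    classification layer; head 512*2+2.
    """
    total = (32 * 1 + 1) * 45
    total += 9 * ((32 * 45 + 1) * 45)
    total += 10 * 4 * 45
    total += 225 * 512 + 512
    total += 3 * (512 * 512 + 512)
    total += 4 * 4 * 512
    total += 512 * 2 + 2
    return total


class TestPooledLength:
    @pytest.mark.parametrize("n,layers,expected", [
        (6000, 10, 5),
        (6000, 0, 6000),
        (375, 1, 187),
        (6000, 1, 3000),
        (11, 1, 5),
    ])
    def test_floor_halving(self, n, layers, expected):
        assert ak.pooled_length(n, layers) == expected

    def test_too_many_layers_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            ak.pooled_length(6000, 13)


class TestShapeTable:
    def test_reference_chain(self):
        """The 10-layer table: 6000→3000→…→11→5 with 45 channels."""
        rows = {r.layer_name: r for r in ak.shape_table(ak.ModelConfig())}
        assert rows["input"].shape == (6000, 1)
        expect = [6000, 3000, 1500, 750, 375, 187, 93, 46, 23, 11]
        for i, length in enumerate(expect, start=1):
            assert rows[f"conv_{i}"].shape == (length, 45)
            assert rows[f"batch_norm_{i}"].shape == (length, 45)
            assert rows[f"max_pool_{i}"].shape == (length // 2, 45)
        assert rows["max_pool_10"].shape == (5, 45)
        assert rows["flatten"].length == 225
        for j in range(1, 5):
            assert rows[f"fc_{j}"].length == 512
        assert rows["output"].length == 2

    def test_flatten_width_property(self):
        assert ak.ModelConfig().flatten_width == 225

    def test_single_layer_post_pool_shape(self):
        cfg = ak.ModelConfig(n_feature_layers=1)
        rows = {r.layer_name: r for r in ak.shape_table(cfg)}
        assert rows["max_pool_1"].shape == (3000, 45)

    def test_invalid_depth_rejected(self):
        with pytest.raises(ConfigurationError):
            ak.ModelConfig(n_feature_layers=13)


class TestCountParameters:
    def test_equals_independent_enumeration(self):
        assert ak.count_parameters(ak.ModelConfig()) == \
            reference_parameter_count()

    def test_rounds_to_one_and_a_half_million(self):
        millions = ak.count_parameters(ak.ModelConfig()) / 1e6
        assert round(millions, 1) == 1.5

    def test_trainable_subset_excludes_moving_statistics(self):
        cfg = ak.ModelConfig()
        diff = ak.count_parameters(cfg) - \
            ak.count_parameters(cfg, trainable_only=True)
        # 2 moving stats per BN channel: 10 conv BNs of 45 + 4 FC BNs of 512
        assert diff == 2 * (10 * 45 + 4 * 512)

    def test_degenerate_config_counts_head_only(self):
        cfg = ak.ModelConfig(n_feature_layers=0, n_class_layers=0)
        assert ak.count_parameters(cfg) == (6000 + 1) * 2


@pytest.fixture(scope="module")
def reduced():
    cfg = ak.ModelConfig.reduced(input_length=256)
    return cfg, ak.build_model(cfg, seed=3)


class TestBuildModel:
    def test_framework_count_matches_analytic(self, reduced):
        cfg, model = reduced
        assert model.n_parameters() == ak.count_parameters(cfg)
        assert model.n_parameters(trainable_only=True) == \
            ak.count_parameters(cfg, trainable_only=True)

    def test_softmax_output_is_probability_vector(self, reduced):
        cfg, model = reduced
        x = np.random.default_rng(0).standard_normal(
            (4, cfg.input_length, 1)).astype(np.float32)
        p = model.predict_proba(x)
        assert p.shape == (4, 2)
        assert np.all(p >= 0) and np.all(p <= 1)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_same_seed_gives_identical_weights(self):
        cfg = ak.ModelConfig.reduced(input_length=128)
        a = ak.build_model(cfg, seed=7).state_dict()
        b = ak.build_model(cfg, seed=7).state_dict()
        assert all(np.array_equal(a[k], b[k]) for k in a)
        c = ak.build_model(cfg, seed=8).state_dict()
        assert any(not np.array_equal(a[k], c[k]) for k in a)

    def test_inference_is_deterministic(self, reduced):
        cfg, model = reduced
        x = np.random.default_rng(1).standard_normal(
            (2, cfg.input_length, 1)).astype(np.float32)
        assert np.array_equal(model.predict_proba(x), model.predict_proba(x))

    def test_invalid_seed_rejected(self):
        with pytest.raises(ConfigurationError):
            ak.build_model(ak.ModelConfig.reduced(), seed="abc")


class TestCheckpointRoundTrip:
    def test_save_load_restores_weights_and_config(self, tmp_path):
        cfg = ak.ModelConfig.reduced(input_length=128)
        model = ak.build_model(cfg, seed=5)
        ak.save_checkpoint(tmp_path / "ckpt", cfg, model.state_dict())
        cfg2, state = ak.load_checkpoint(tmp_path / "ckpt")
        assert cfg2 == cfg
        model2 = ak.build_model(cfg2, seed=0)
        model2.load_state_dict(state)
        x = np.random.default_rng(2).standard_normal(
            (3, 128, 1)).astype(np.float32)
        assert np.array_equal(model.predict_proba(x),
                              model2.predict_proba(x))

    def test_descriptor_reports_counts(self):
        import json
        desc = json.loads(architecture_descriptor(ak.ModelConfig()))
        assert desc["n_parameters"] == reference_parameter_count()
        assert desc["shapes"][-1]["length"] == 2
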