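"""Architecture spec, shape inference, parameter counting, builder."""

import numpy as np
import pytest

from seizurekit.model import (
    LayerSpec,
    ModelSpec,
    build,
    count_parameters,
    default_spec,
    describe,
    infer_shapes,
    spec_from_json,
    spec_to_json,
)

REFERENCE_SHAPES = [
    (2050, 16), (2050, 16), (2050, 16),
    (1025, 32), (1025, 32), (1025, 32),
    (512, 64), (512, 64), (512, 64),
    (255, 64),
    (255, 128), (255, 128), (255, 128),
    (127, 128),
    (127, 256), (127, 256), (127, 256),
    (63, 256),
    (63, 512), (63, 512), (63, 512),
    (31, 512),
    (200,), (200,), (64,), (64,), (1,), (1,),
]

REFERENCE_COUNTS = [
    48, 64, 0, 1056, 128, 0, 4160, 256, 0, 0,
    8320, 512, 0, 0, 33024, 1024, 0, 0, 131584, 2048,
    0, 0, 570400, 0, 12864, 0, 65, 0,
]


class TestDefaultSpec:
    def test_28_layer_reference_architecture(self):
        spec = default_spec(4100, 2)
        assert len(spec.layers) == 28
        assert spec.layers[0].filters == 16 and spec.layers[0].kernel == 2
        assert [ls.kind for ls in spec.layers].count("conv1d") == 6
        assert [ls.kind for ls in spec.layers].count("maxpool1d") == 4
        assert [ls.kind for ls in spec.layers].count("lstm") == 1
        assert spec.layers[-1].activation == "sigmoid"

    def test_multiclass_head(self):
        spec = default_spec(4100, 8)
        assert spec.layers[-2].units == 8
        assert spec.layers[-1].activation == "softmax"

    def test_too_short_input_raises_shape_error(self):
        with pytest.raises(ValueError):
            default_spec(63, 2)


class TestInferShapes:
    def test_reference_shape_sequence(self):
        assert infer_shapes(default_spec(4100, 2)) == REFERENCE_SHAPES

    def test_pool3_stride2_on_255(self):
        spec = ModelSpec(
            input_length=255,
            layers=(LayerSpec("maxpool1d", pool=3, stride=2),),
            n_classes=2,
            input_channels=128,
        )
        assert infer_shapes(spec) == [(127, 128)]

    def test_kernel1_stride1_is_length_identity(self):
        for n in (17, 100, 4100):
            spec = ModelSpec(
                input_length=n,
                layers=(LayerSpec("conv1d", filters=4, kernel=1, stride=1),),
            )
            assert infer_shapes(spec)[0] == (n, 4)

    def test_monotone_in_input_length(self):
        """Longer inputs never shrink any intermediate length."""
        prev = None
        for n in (256, 300, 512, 1024, 4100):
            lengths = [s[0] for s in infer_shapes(default_spec(n, 2)) if len(s) == 2]
            if prev is not None:
                assert all(b >= a for a, b in zip(prev, lengths))
            prev = lengths


class TestCountParameters:
    def test_reference_per_layer_counts(self):
        counts, total = count_parameters(default_spec(4100, 2))
        assert counts == REFERENCE_COUNTS
        assert total == 765_553

    def test_lstm_count_formula(self):
        spec = ModelSpec(
            input_length=31,
            layers=(LayerSpec("lstm", units=200), LayerSpec("flatten")),
            input_channels=512,
        )
        counts, _ = count_parameters(spec)
        assert counts[0] == 570_400 == 4 * ((512 + 200) * 200 + 200)

    def test_relu_and_dropout_free(self):
        counts, _ = count_parameters(default_spec(4100, 2))
        kinds = [ls.kind for ls in default_spec(4100, 2).layers]
        for k, c in zip(kinds, counts):
            if k in ("relu", "dropout", "maxpool1d", "flatten", "activation"):
                assert c == 0


class TestBuild:
    def test_backend_count_matches_analytic(self):
        spec = default_spec(4100, 2)
        net = build(spec, seed=0)
        assert net.param_count() == count_parameters(spec)[1] == 765_553

    def test_softmax_rows_sum_to_one(self, rng):
        spec = default_spec(256, 3)
        net = build(spec, seed=1)
        p = net.forward(rng.standard_normal((4, 256, 1)))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert p.shape == (4, 3)

    def test_sigmoid_zero_weights_gives_half(self, rng):
        spec = default_spec(256, 2)
        net = build(spec, seed=2)
        for layer in net.layers:
            for k in layer.params:
                if k != "gamma":
                    layer.params[k][...] = 0.0
        p = net.forward(rng.standard_normal((3, 256, 1)))
        np.testing.assert_allclose(p, 0.5, atol=1e-12)

    def test_randomized_specs_backend_equals_oracle(self, rng):
        """Analytic shapes and parameter counts agree with the realized
        network over randomized conv/pool/LSTM stacks."""
        for trial in range(25):
            n = int(rng.integers(64, 400))
            layers = []
            length = n
            for _ in range(int(rng.integers(1, 4))):
                k = int(rng.integers(1, 4))
                s = int(rng.integers(1, 3))
                if (length - k) // s + 1 < 8:
                    break
                f = int(rng.integers(2, 9))
                layers.append(LayerSpec("conv1d", filters=f, kernel=k, stride=s))
                layers.append(LayerSpec("batchnorm"))
                layers.append(LayerSpec("relu"))
                length = (length - k) // s + 1
                if length >= 4 and rng.random() < 0.5:
                    layers.append(LayerSpec("maxpool1d", pool=2, stride=2))
                    length = (length - 2) // 2 + 1
            layers += [
                LayerSpec("lstm", units=int(rng.integers(2, 12))),
                LayerSpec("flatten"),
                LayerSpec("dense", units=int(rng.integers(2, 8)), activation="relu"),
                LayerSpec("dense", units=1),
                LayerSpec("activation", activation="sigmoid"),
            ]
            spec = ModelSpec(input_length=n, layers=tuple(layers))
            shapes = infer_shapes(spec)
            _, total = count_parameters(spec)
            net = build(spec, seed=trial)
            assert net.param_count() == total, f"trial {trial}"
            out = net.forward(np.zeros((2, n, 1)))
            assert out.shape == (2,) + shapes[-1], f"trial {trial}"


class TestSerialization:
    def test_json_round_trip(self, tmp_path):
        spec = default_spec(4100, 2)
        p = tmp_path / "spec.json"
        spec_to_json(spec, p)
        assert spec_from_json(p) == spec

    def test_describe_contains_total(self):
        assert "765,553" in describe(default_spec(4100, 2))
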