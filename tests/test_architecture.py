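"""Size algebra, design conditions, layer plans, weight counts, forward pass."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acns import (
    ImageGrid,
    NetworkSpec,
    build_layer_plan,
    conv_output_size,
    count_weights,
    deconv_output_size,
    enumerate_valid_specs,
    forward,
    parse_spec_string,
    reference_plan,
    validate_spec,
    xavier_init,
)
from acns.architecture import GeometryError, LayerPlan, LayerStage, _forward_batch


class TestSizeFormulas:
    @pytest.mark.parametrize(
        "args,expected",
        [((11, 5, 0, 1), 7), ((7, 3, 1, 1), 7), ((1, 1, 0, 1), 1), ((11, 5, 0, 2), 4)],
    )
    def test_conv_output_size(self, args, expected):
        assert conv_output_size(*args) == expected

    @pytest.mark.parametrize(
        "args,expected",
        [((7, 9, 5, 2), 11), ((7, 9, 5, 3), 17), ((7, 9, 5, 4), 23), ((1, 9, 0, 4), 9)],
    )
    def test_deconv_output_size(self, args, expected):
        # the three selected-network HR patch sizes and the single-pixel case
        assert deconv_output_size(*args) == expected

    def test_invalid_geometry_raises(self):
        with pytest.raises(GeometryError):
            conv_output_size(3, 5, 0, 1)
        with pytest.raises(GeometryError):
            deconv_output_size(2, 3, 4, 1)

    @given(
        in_size=st.integers(2, 64),
        kernel=st.integers(1, 9),
        padding=st.integers(0, 4),
        stride=st.integers(1, 4),
    )
    @settings(max_examples=60, deadline=None)
    def test_conv_then_deconv_round_trip_identity_stride(self, in_size, kernel, padding, stride):
        """With stride 1 and symmetric padding p=(k-1)/2 a conv/deconv pair
        preserves the size (the property the mapping stages rely on)."""
        if kernel % 2 == 0 or in_size + 2 * padding < kernel:
            return
        mid = conv_output_size(in_size, kernel, (kernel - 1) // 2, 1)
        assert mid == in_size
        out = deconv_output_size(mid, kernel, (kernel - 1) // 2, 1)
        assert out == in_size


class TestValidation:
    def test_selected_network_passes_all_scales(self):
        for f, hr in [(2, 11), (3, 17), (4, 23)]:
            report = validate_spec(parse_spec_string("ACNS(16,8,5,9,5,4)", scale=f), 11)
            assert report.passed
            assert report.hr_patch == hr

    def test_condition1_boundary(self):
        report = validate_spec(NetworkSpec(4, 2, 11, 9, 0, 1, scale=2), 11)
        assert not report.conditions[0].passed
        assert not report.passed
        assert report.hr_patch is None

    def test_condition3_boundary(self):
        report = validate_spec(NetworkSpec(4, 2, 1, 9, 9, 1, scale=2), 11)
        assert not report.conditions[2].passed

    def test_report_consistency(self):
        report = validate_spec(NetworkSpec(4, 2, 5, 9, 5, 1, scale=2), 11)
        assert report.passed == all(c.passed for c in report.conditions)

    def test_enumeration_contains_selected_and_only_valid(self):
        triples = enumerate_valid_specs(11, 2)
        assert (5, 9, 5) in triples
        assert triples == sorted(triples)
        for w1, w_out, p in triples:
            assert validate_spec(NetworkSpec(1, 1, w1, w_out, p, 1, scale=2), 11).passed

    def test_enumeration_empty_when_w1_too_large(self):
        assert enumerate_valid_specs(11, 2, w1_candidates=(11,)) == []

    def test_round_trip_implied_hr_patch(self):
        """Chaining the stage size formulas over the built plan reproduces
        the ValidationReport's implied HR patch size."""
        for f in (2, 3, 4):
            spec = parse_spec_string("ACNS(16,8,5,9,5,4)", scale=f)
            report = validate_spec(spec, 11)
            size = 11
            for st_ in build_layer_plan(spec).stages:
                if st_.role == "deconvolution":
                    size = deconv_output_size(size, st_.kernel, st_.padding, st_.stride)
                else:
                    size = conv_output_size(size, st_.kernel, st_.padding, st_.stride)
            assert size == report.hr_patch


class TestPlansAndCounts:
    def test_selected_plan_structure(self, selected_spec):
        plan = build_layer_plan(selected_spec)
        assert plan.channel_chain == (1, 16, 8, 8, 8, 8, 16, 1)
        assert len(plan) == 7
        assert plan.stages[-1].role == "deconvolution"
        assert sum(s.role == "deconvolution" for s in plan.stages) == 1

    def test_minimum_recursion_gives_four_stages(self):
        assert len(build_layer_plan(NetworkSpec(4, 2, 3, 3, 1, 1, scale=2))) == 4

    @pytest.mark.parametrize(
        "name,total",
        [("SRCNN", 8032), ("FSRCNN", 12464), ("DRCN", 1774080)],
    )
    def test_reference_plan_counts(self, name, total):
        assert count_weights(reference_plan(name)) == total

    def test_selected_network_count(self, selected_spec):
        assert count_weights(build_layer_plan(selected_spec)) == 5728

    def test_count_additive_and_order_invariant(self, selected_spec):
        plan = build_layer_plan(selected_spec)
        per_stage = [s.kernel_weights for s in plan.stages]
        assert count_weights(plan) == sum(per_stage)
        assert sum(per_stage) == sum(reversed(per_stage))

    def test_single_1x1_stage(self):
        plan = LayerPlan((LayerStage("feature_extraction", 1, 1, 1, 0, 1, "none"),))
        assert count_weights(plan) == 1

    def test_count_flags(self, selected_spec):
        plan = build_layer_plan(selected_spec)
        base = count_weights(plan)
        n_bias = sum(s.out_channels for s in plan.stages)
        n_prelu = sum(s.out_channels for s in plan.stages if s.activation == "prelu")
        assert count_weights(plan, include_bias=True) == base + n_bias
        assert count_weights(plan, include_bias=True, include_prelu=True) == base + n_bias + n_prelu

    def test_unknown_reference_raises(self):
        with pytest.raises(ValueError):
            reference_plan("EDSR")

    def test_broken_channel_chain_rejected(self):
        with pytest.raises(ValueError):
            LayerPlan(
                (
                    LayerStage("feature_extraction", 1, 4, 3, 0, 1, "none"),
                    LayerStage("mapping", 8, 4, 3, 1, 1, "none"),
                )
            )


class TestSpecParsing:
    def test_parse_and_format(self, selected_spec):
        assert str(selected_spec) == "ACNS(16,8,5,9,5,4)"
        assert parse_spec_string(str(selected_spec), scale=2) == selected_spec

    def test_dict_round_trip(self, selected_spec):
        assert NetworkSpec.from_dict(selected_spec.to_dict()) == selected_spec

    def test_unknown_keys_rejected(self):
        with pytest.raises(ValueError):
            NetworkSpec.from_dict({"n_feature": 1, "n_map": 1, "w1": 3, "w_out": 3,
                                   "p": 0, "n": 1, "bogus": 1})

    @pytest.mark.parametrize("bad", ["ACNS(16,8,5,9,5)", "SRCNN(1,2,3,4,5,6)", "ACNS()"])
    def test_bad_strings(self, bad):
        with pytest.raises(ValueError):
            parse_spec_string(bad)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            NetworkSpec(16, 8, 4, 9, 5, 4)  # even w1
        with pytest.raises(ValueError):
            NetworkSpec(0, 8, 5, 9, 5, 4)


class TestForward:
    def test_constant_propagation_with_zero_kernels(self, tiny_spec):
        """All-zero kernels: the output is the analytically propagated
        constant determined by biases and PReLU slopes alone."""
        params = xavier_init(build_layer_plan(tiny_spec), seed=0)
        biases = [0.3, -0.4, 0.5, -0.2]
        const = 0.0
        for sp, st_, b in zip(params.stages, params.plan.stages, biases):
            sp.kernel[:] = 0.0
            sp.bias[:] = b
            const = b  # zero kernels: pre-activation equals the bias
            if sp.alpha is not None:
                sp.alpha[:] = 0.25
                const = max(const, 0.0) + 0.25 * min(const, 0.0)
        out = forward(params, np.random.default_rng(0).random((8, 8)), border_mode="valid")
        assert np.allclose(out, const)

    def test_full_size_border_contract(self, selected_spec):
        params = xavier_init(build_layer_plan(selected_spec), seed=0)
        img = np.random.default_rng(2).random((20, 20))
        assert forward(params, img, border_mode="full-size").shape == (40, 40)

    def test_valid_mode_hr_patch_sizes(self):
        """An 11-pixel input through the selected network in valid mode yields
        exactly the published HR patch size for every scale factor."""
        for f, hr in [(2, 11), (3, 17), (4, 23)]:
            spec = parse_spec_string("ACNS(16,8,5,9,5,4)", scale=f)
            params = xavier_init(build_layer_plan(spec), seed=0)
            out = forward(params, np.zeros((11, 11)), border_mode="valid")
            assert out.shape == (hr, hr)

    def test_deterministic(self, selected_spec):
        params = xavier_init(build_layer_plan(selected_spec), seed=5)
        img = np.random.default_rng(3).random((16, 16))
        a = forward(params, img)
        b = forward(params, img)
        assert np.array_equal(a, b)

    def test_image_grid_in_grid_out(self, tiny_spec):
        params = xavier_init(build_layer_plan(tiny_spec), seed=0)
        grid = ImageGrid(np.random.default_rng(4).random((12, 12)) * 255)
        out = forward(params, grid)
        assert isinstance(out, ImageGrid)
        assert out.max_intensity == grid.max_intensity

    def test_matches_quadruple_loop_convolution_oracle(self):
        """The conv stages agree with a direct quadruple-loop convolution."""
        spec = NetworkSpec(3, 2, 3, 3, 1, 1, scale=2)
        params = xavier_init(build_layer_plan(spec), seed=9)
        x = np.random.default_rng(10).random((5, 5))

        def conv_prelu_oracle(img_stack, kernel, bias, alpha, pad):
            c_in, h, w = img_stack.shape
            o_ch = kernel.shape[0]
            k = kernel.shape[2]
            padded = np.zeros((c_in, h + 2 * pad, w + 2 * pad))
            padded[:, pad : pad + h, pad : pad + w] = img_stack
            oh = padded.shape[1] - k + 1
            out = np.zeros((o_ch, oh, oh))
            for o in range(o_ch):
                for y in range(oh):
                    for xx in range(oh):
                        acc = bias[o]
                        for c in range(c_in):
                            for i in range(k):
                                for j in range(k):
                                    acc += kernel[o, c, i, j] * padded[c, y + i, xx + j]
                        out[o, y, xx] = max(acc, 0.0) + alpha[o] * min(acc, 0.0)
            return out

        state = x[None]
        batch = x[None, :, :, None]
        for sp, st_ in zip(params.stages, params.plan.stages):
            if st_.role == "deconvolution":
                break
            state = conv_prelu_oracle(state, sp.kernel, sp.bias, sp.alpha, st_.padding)
        # run the real network up to (excluding) the deconvolution stage
        from acns._nn import conv2d_forward, prelu_forward

        for sp, st_ in zip(params.stages, params.plan.stages):
            if st_.role == "deconvolution":
                break
            batch, _ = conv2d_forward(batch, sp.kernel, sp.bias, st_.padding, st_.stride)
            batch, _ = prelu_forward(batch, sp.alpha)
        got = batch[0].transpose(2, 0, 1)
        assert np.max(np.abs(got - state)) <= 1e-10 * max(1.0, np.max(np.abs(state)))
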