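"""Architecture construction: shapes, channel arithmetic, parameter counts."""

import numpy as np
import pytest

from chronomid.models import (
    VARIANTS,
    ArchitectureSpec,
    ChainSpec,
    CrossConnectSpec,
    HyperParams,
    build_chain,
    build_model,
    build_xchain,
    chain_specs,
    count_parameters,
    inject_timestamp,
)


def closed_form_count(variant, h, w, n_classes=2, cross_filters=8, dense=(64, 32)):
    """Independent per-layer oracle: conv (k*k*cin+1)*cout, BN 4 per feature,
    dense (fan_in+1)*fan_out, summed over the declared architecture."""
    total = 0
    specs = chain_specs(variant)
    xcnn = variant.startswith("xcnn")
    in_i = in_d = 1
    for cs in specs:
        f1, f2 = cs.conv_filters
        streams = [(in_i, f1, f2), (in_d, f1, f2)] if xcnn else [(in_i, f1, f2)]
        for cin, c1, c2 in streams:
            total += (3 * 3 * cin + 1) * c1 + (3 * 3 * c1 + 1) * c2
            total += 4 * c2  # BN over the chain output
        if xcnn:
            total += 2 * ((1 * 1 * f2 + 1) * cross_filters)  # I->D and D->I
            in_i = in_d = f2 + cross_filters
        else:
            in_i = f2
        h, w = h // 2, w // 2
    flat = h * w * in_i * (2 if xcnn else 1)
    flat += 1 if variant.endswith("_ts") else 0
    d1, d2 = dense
    total += (flat + 1) * d1 + 4 * d1
    total += (d1 + 1) * d2 + 4 * d2
    total += (d2 + 1) * n_classes
    return total


class TestChainBlocks:
    def test_chain_halves_spatial_dims_and_sets_channels(self):
        rng = np.random.default_rng(0)
        blk = build_chain(chain_specs("cnn")[0], in_channels=1, rng=rng)
        out = blk.forward(np.zeros((2, 64, 64, 1)), training=False)
        assert out.shape == (2, 32, 32, 16)

    def test_five_poolings_on_full_size_input(self):
        spec = ArchitectureSpec(variant="cnn", input_height=501, input_width=763)
        m = build_model(spec)
        assert (m.final_h, m.final_w) == (15, 23)

    def test_chain5_has_no_dropout(self):
        specs = chain_specs("cnn")
        assert specs[4].dropout is False and specs[4].batch_norm is True
        blk = build_chain(specs[4], in_channels=32)
        assert all(type(l).__name__ != "Dropout" for l in blk.reg)

    def test_xchain_concatenation_arithmetic(self):
        rng = np.random.default_rng(0)
        blk = build_xchain(
            ChainSpec(conv_filters=(16, 16)), CrossConnectSpec(), 16, 16, rng=rng
        )
        oi, od = blk.forward(np.zeros((1, 16, 16, 16)), np.zeros((1, 16, 16, 16)))
        assert oi.shape[-1] == od.shape[-1] == 16 + 8

    def test_information_flows_across_streams(self):
        """Zeroing the D-stream input changes the I-stream output, so the
        cross-connections genuinely exchange features."""
        rng = np.random.default_rng(1)
        blk = build_xchain(
            ChainSpec(conv_filters=(8, 8)), CrossConnectSpec(), 1, 1, rng=rng
        )
        xi = np.abs(np.random.default_rng(2).normal(size=(1, 8, 8, 1)))
        xd = np.abs(np.random.default_rng(3).normal(size=(1, 8, 8, 1)))
        oi_full, _ = blk.forward(xi, xd)
        oi_zero, _ = blk.forward(xi, np.zeros_like(xd))
        assert not np.allclose(oi_full, oi_zero)

    def test_cross_conv_weight_count(self):
        blk = build_xchain(ChainSpec(conv_filters=(8, 8)), CrossConnectSpec(), 1, 1)
        assert blk.cross_parameter_count() == 2 * (1 * 1 * 8 + 1) * 8  # 144 total

    def test_stream_symmetry_with_tied_weights(self):
        """Equal inputs and mirrored weights give mirrored outputs."""
        blk = build_xchain(ChainSpec(conv_filters=(4, 4), dropout=False),
                           CrossConnectSpec(), 1, 1)
        for pi, pd in zip(blk.chain_i.params(), blk.chain_d.params()):
            pd.value[...] = pi.value
        for pa, pb in zip(blk.cross_i2d.params(), blk.cross_d2i.params()):
            pb.value[...] = pa.value
        x = np.abs(np.random.default_rng(0).normal(size=(2, 8, 8, 1)))
        oi, od = blk.forward(x, x.copy())
        assert np.allclose(oi, od)


class TestBuildModel:
    @pytest.mark.parametrize("variant", VARIANTS)
    @pytest.mark.parametrize("dims", [(64, 64), (501, 763)])
    def test_all_variants_build_at_both_scales(self, variant, dims):
        spec = ArchitectureSpec(variant=variant, input_height=dims[0], input_width=dims[1])
        model = build_model(spec)
        assert count_parameters(model) > 0

    def test_baseline_parameter_bound_full_size(self):
        spec = ArchitectureSpec(variant="cnn", input_height=501, input_width=763)
        assert count_parameters(build_model(spec)) < 900_000

    @pytest.mark.parametrize("variant", ["xcnn_abs", "xcnn_rel", "xcnn_abs_ts", "xcnn_rel_ts"])
    def test_xcnn_parameter_bound_full_size(self, variant):
        spec = ArchitectureSpec(variant=variant, input_height=501, input_width=763)
        assert count_parameters(build_model(spec)) > 1_500_000

    @pytest.mark.parametrize("variant", VARIANTS)
    def test_count_matches_closed_form_oracle(self, variant):
        spec = ArchitectureSpec(variant=variant, input_height=64, input_width=64)
        assert count_parameters(build_model(spec)) == closed_form_count(variant, 64, 64)

    def test_removing_cross_connections_removes_exactly_their_params(self):
        spec = ArchitectureSpec(variant="xcnn_abs", input_height=64, input_width=64)
        model = build_model(spec)
        cross_total = sum(blk.cross_parameter_count() for blk in model.blocks)
        without = sum(
            p.size
            for blk in model.blocks
            for p in blk.chain_i.params() + blk.chain_d.params()
        )
        with_cross = sum(p.size for blk in model.blocks for p in blk.params())
        assert with_cross - without == cross_total

    def test_timestamp_widens_first_dense_by_one(self):
        base = build_model(ArchitectureSpec(variant="cnn", input_height=64, input_width=64))
        ts = build_model(ArchitectureSpec(variant="cnn_ts", input_height=64, input_width=64))
        w_base = base.head[0].W.value.shape[0]
        w_ts = ts.head[0].W.value.shape[0]
        assert w_ts == w_base + 1

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError):
            build_model(ArchitectureSpec(variant="cnn", input_height=16, input_width=16))

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            ArchitectureSpec(variant="resnet", input_height=64, input_width=64)

    def test_cross_before_regularisation_also_builds_and_runs(self):
        spec = ArchitectureSpec(
            variant="xcnn_abs", input_height=64, input_width=64,
            cross_after_regularisation=False,
        )
        model = build_model(spec)
        imgs = np.random.default_rng(0).integers(0, 255, (2, 64, 64)).astype(float)
        diffs = np.zeros_like(imgs)
        logits = model.forward(imgs, diffs, training=False)
        assert logits.shape == (2, 2)


class TestTimestampInjection:
    def test_raw_week_value_enters_unnormalised(self):
        model = build_model(ArchitectureSpec(variant="cnn_ts", input_height=64, input_width=64))
        ts = inject_timestamp(model, [5, 0, 8])
        assert ts.tolist() == [[5.0], [0.0], [8.0]]

    def test_week_zero_valid(self):
        model = build_model(ArchitectureSpec(variant="cnn_ts", input_height=64, input_width=64))
        assert inject_timestamp(model, [0]).tolist() == [[0.0]]

    def test_non_ts_variant_rejects_timestamp(self):
        model = build_model(ArchitectureSpec(variant="cnn", input_height=64, input_width=64))
        with pytest.raises(ValueError):
            inject_timestamp(model, [3])
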