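import numpy as np
import pytest

from scatinception.errors import ConfigurationError
from scatinception.inception_blocks import (
    BlockSpec,
    block_forward,
    build_block,
    default_branch_channels,
)

from .conftest import jitter_params


def test_scat_a_has_five_branches(rng):
    block = build_block(BlockSpec("SCAT_A", in_channels=64), rng=rng)
    assert len(block.branches) == 5


@pytest.mark.parametrize("variant", ["SCAT_A", "SCAT_B", "C", "E"])
def test_same_padding_contract(variant, rng):
    block = build_block(BlockSpec(variant, in_channels=8), rng=rng)
    x = rng.normal(size=(1, 8, 32, 32)).astype(np.float32)
    y = block_forward(block, x)
    assert y.shape[2:] == (32, 32)
    assert not block.downsamples


def test_downsampling_halves_floor(rng):
    block = build_block(BlockSpec("D", in_channels=8), rng=rng)
    for size in (32, 15):
        x = rng.normal(size=(1, 8, size, size)).astype(np.float32)
        y = block_forward(block, x)
        assert y.shape[2:] == (size // 2, size // 2)


@pytest.mark.parametrize("variant", ["SCAT_A", "SCAT_B", "C", "D", "E"])
def test_channel_accounting(variant, rng):
    spec = BlockSpec(variant, in_channels=12)
    block = build_block(spec, rng=rng)
    x = rng.normal(size=(2, 12, 8, 8)).astype(np.float32)
    y = block_forward(block, x)
    assert y.shape[1] == spec.out_channels
    expected_extra = 12 if variant == "D" else 0
    assert spec.out_channels == sum(spec.branch_channels) + expected_extra


def test_five_branch_widths_concatenate(rng):
    spec = BlockSpec("SCAT_A", in_channels=16, branch_channels=[8, 8, 8, 8, 8])
    block = build_block(spec, rng=rng)
    x = rng.normal(size=(1, 16, 8, 8)).astype(np.float32)
    assert block_forward(block, x).shape[1] == 40


def test_scat_placement():
    for variant in ("SCAT_A", "SCAT_B"):
        assert BlockSpec(variant, 8).has_scat
        assert build_block(BlockSpec(variant, 8)).scat is not None
    for variant in ("C", "D", "E"):
        assert not BlockSpec(variant, 8).has_scat
        assert build_block(BlockSpec(variant, 8)).scat is None


def test_scat_ablation_changes_values_not_shapes(rng):
    spec = BlockSpec("SCAT_A", in_channels=8)
    block = build_block(spec, rng=np.random.default_rng(0))
    x = rng.normal(size=(1, 8, 8, 8)).astype(np.float32)
    y_scat = block_forward(block, x)
    block.scat = None  # identity ablation
    y_plain = block_forward(block, x)
    assert y_scat.shape == y_plain.shape
    assert not np.allclose(y_scat, y_plain)


def test_channel_mismatch_raises(rng):
    block = build_block(BlockSpec("C", in_channels=8), rng=rng)
    with pytest.raises(ConfigurationError):
        block_forward(block, rng.normal(size=(1, 4, 8, 8)).astype(np.float32))


def test_invalid_specs():
    with pytest.raises(ConfigurationError):
        BlockSpec("SCAT_A", 8, branch_channels=[4, 4])  # needs 5 branches
    with pytest.raises(ConfigurationError):
        BlockSpec("X", 8)
    with pytest.raises(ConfigurationError):
        BlockSpec("C", 8, branch_channels=[1, 1, 0, 1, 1])


def test_identity_1x1_kernel_tiles_input(rng):
    # A 1x1-branch block with identity kernels copies the input channels.
    spec = BlockSpec("SCAT_A", in_channels=2, branch_channels=[2, 1, 1, 1, 1])
    block = build_block(spec, rng=rng)
    b0_conv = block.branches[0].layers[0]
    b0_conv.weight.data[...] = 0.0
    b0_conv.weight.data[0, 0] = 1.0
    b0_conv.weight.data[1, 1] = 1.0
    b0_conv.bias.data[...] = 0.0
    block.scat = None
    x = np.abs(rng.normal(size=(1, 2, 4, 4))).astype(np.float32)  # positive: ReLU inert
    y = block_forward(block, x)
    np.testing.assert_allclose(y[:, :2], x, atol=1e-6)


def test_parameter_count_matches_hand_count():
    # Minimal SCAT_A spec, all branch widths 1, in_channels=1:
    #  b1: 1x1 conv 1->1                weights 1,  bias 1
    #  b2: 1x1 (1->1) + 3x3 (1->1)      weights 1+9, biases 2
    #  b3: 1x1 (1->1) + 5x5 (1->1)      weights 1+25, biases 2
    #  b4: 1x1 + 3x3 + 3x3 (all 1->1)   weights 1+9+9, biases 3
    #  b5: avgpool + 1x1 (1->1)         weights 1, bias 1
    #  SCAT on 5 channels: reduce 1x1 (5->1): 5+1; attn 1x1 (1->1): 1+1
    expected = (1 + 1) + (10 + 2) + (26 + 2) + (19 + 3) + (1 + 1) + (6 + 2)
    spec = BlockSpec("SCAT_A", in_channels=1, branch_channels=[1, 1, 1, 1, 1])
    assert build_block(spec).n_params() == expected


def test_block_forward_matches_direct_convolution_oracle(rng):
    # Fixed random weights on a 2x4x4 input; compare with a dependency-free
    # per-pixel convolution loop for each branch, then concatenation.
    spec = BlockSpec("SCAT_B", in_channels=2, branch_channels=[1, 1, 1, 1, 1])
    block = build_block(spec, rng=np.random.default_rng(9))
    block.scat = None
    x = rng.normal(size=(2, 4, 4)).astype(np.float32)

    def conv_direct(img, weight, bias):
        cin, h, w = img.shape
        cout, _, kh, kw = weight.shape
        ph, pw = (kh - 1) // 2, (kw - 1) // 2
        padded = np.zeros((cin, h + kh - 1, w + kw - 1))
        padded[:, ph : ph + h, pw : pw + w] = img
        out = np.zeros((cout, h, w))
        for co in range(cout):
            for i in range(h):
                for j in range(w):
                    acc = bias[co]
                    for ci in range(cin):
                        for a in range(kh):
                            for b in range(kw):
                                acc += weight[co, ci, a, b] * padded[ci, i + a, j + b]
                    out[co, i, j] = acc
        return out

    def avgpool3_direct(img):
        cin, h, w = img.shape
        out = np.zeros_like(img)
        for c in range(cin):
            for i in range(h):
                for j in range(w):
                    vals = [
                        img[c, a, b]
                        for a in range(max(0, i - 1), min(h, i + 2))
                        for b in range(max(0, j - 1), min(w, j + 2))
                    ]
                    # SAME padding averages over the full 3x3 window (zeros off-edge)
                    out[c, i, j] = sum(vals) / 9.0
        return out

    def branch_convs(branch):
        convs = []
        for sub in branch.layers:
            if hasattr(sub, "layers"):
                convs += [l for l in sub.layers if hasattr(l, "weight")]
            elif hasattr(sub, "weight"):
                convs.append(sub)
        return convs

    expected_parts = []
    for bi, branch in enumerate(block.branches):
        h = x.astype(np.float64)
        if bi == 4:
            h = avgpool3_direct(h)
        for conv in branch_convs(branch):
            h = conv_direct(h, conv.weight.data.astype(np.float64), conv.bias.data)
            h = np.maximum(h, 0.0)  # each conv is followed by ReLU
        expected_parts.append(h)
    expected = np.concatenate(expected_parts, axis=0)
    actual = block_forward(block, x)
    np.testing.assert_allclose(actual, expected, rtol=1e-4, atol=1e-5)


@pytest.mark.parametrize("variant", ["SCAT_A", "SCAT_B", "C", "D", "E"])
def test_block_backward_gradcheck(variant, rng):
    block = build_block(BlockSpec(variant, in_channels=3), rng=np.random.default_rng(7))
    jitter_params(block, rng)
    x = rng.normal(size=(1, 3, 6, 6))
    y = block.forward(x)
    w_out = rng.normal(size=y.shape)
    block.forward(x)
    dx = block.backward(w_out.copy())
    eps = 1e-6
    for idx in rng.integers(0, x.size, size=6):
        orig = x.flat[idx]
        x.flat[idx] = orig + eps
        lp = float((block.forward(x) * w_out).sum())
        x.flat[idx] = orig - eps
        lm = float((block.forward(x) * w_out).sum())
        x.flat[idx] = orig
        np.testing.assert_allclose(dx.flat[idx], (lp - lm) / (2 * eps), rtol=1e-3, atol=1e-6)


def test_default_branch_channels():
    assert default_branch_channels("SCAT_A", 16) == [4, 4, 4, 4, 4]
    assert len(default_branch_channels("D", 16)) == 2
    assert default_branch_channels("C", 2) == [1, 1, 1, 1, 1]
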