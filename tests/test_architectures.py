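"""Architecture construction, parameter accounting and width resolution."""

import numpy as np
import pytest

from monetseg.architectures import (
    CANONICAL_MONET,
    DOCUMENTED_SEARCH_SPACE,
    EXTENDED_SEARCH_SPACE,
    ConvBlockSpec,
    InvalidSpecError,
    MoNetConfig,
    RddcSpec,
    WidthSearchSpace,
    build_monet,
    build_unet,
    count_parameters,
    make_conv_block,
    make_rddc_block,
    monet_encoder_receptive_fields,
    monet_parameter_count,
    parameter_table,
    rddc_receptive_field,
    resolve_monet_widths,
)


# ---------------------------------------------------------------------------
# Independent layer-algebra oracle: walks the declared structure with closed
# forms, never touching the built networks.
# ---------------------------------------------------------------------------

def _oracle_conv(cin, cout, k=3, bias=True, norm=True):
    return k * k * cin * cout + (cout if bias else 0) + (4 * cout if norm
                                                         else 0)


def _oracle_rddc(c, projection=False):
    total = 4 * _oracle_conv(c, c)
    if projection:
        total += _oracle_conv(c, c, k=1, norm=False)
    return total


def _oracle_monet(cfg: MoNetConfig):
    f1, f2, f3 = cfg.widths
    proj = cfg.residual == "projection"
    k = cfg.up_kernel
    t = _oracle_conv(1, f1)
    if cfg.extra_stem:
        t += _oracle_conv(f1, f1)
    t += _oracle_rddc(f1, proj) + _oracle_conv(f1, f2)
    t += _oracle_rddc(f2, proj) + _oracle_conv(f2, f3)
    t += _oracle_rddc(f3, proj)
    t += _oracle_conv(f3, f2, k=k, norm=cfg.normalized_up)
    t += _oracle_conv(2 * f2, f2) + (_oracle_conv(f2, f2) if cfg.extra_fuse
                                     else 0)
    t += _oracle_rddc(f2, proj)
    t += _oracle_conv(f2, f1, k=k, norm=cfg.normalized_up)
    t += _oracle_conv(2 * f1, f1) + (_oracle_conv(f1, f1) if cfg.extra_fuse
                                     else 0)
    t += _oracle_rddc(f1, proj)
    return t + _oracle_conv(f1, 1, k=1, norm=False)


def _oracle_unet(f):
    widths = [f * 2 ** i for i in range(5)]
    t = _oracle_conv(1, widths[0]) + _oracle_conv(widths[0], widths[0])
    for a, b in zip(widths, widths[1:]):
        t += _oracle_conv(a, b) + _oracle_conv(b, b)
    for hi, lo in zip(widths[:0:-1], widths[-2::-1]):
        t += _oracle_conv(hi, lo, k=2, norm=False)        # up-conv
        t += _oracle_conv(2 * lo, lo) + _oracle_conv(lo, lo)
    return t + _oracle_conv(widths[0], 1, k=1, norm=False)


# ---------------------------------------------------------------------------
# Conv / RDDC blocks
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("spec,expected", [
    (ConvBlockSpec(1, 1, normalized=False), 10),
    (ConvBlockSpec(1, 16), 224),
    (ConvBlockSpec(16, 32, stride=2), 9 * 512 + 32 + 128),
])
def test_conv_block_parameter_count(spec, expected):
    block = make_conv_block(spec)
    assert count_parameters(block) == expected == spec.parameter_count


def test_conv_block_invalid_spec():
    with pytest.raises(InvalidSpecError):
        make_conv_block(ConvBlockSpec(0, 4))
    with pytest.raises(InvalidSpecError):
        ConvBlockSpec(1, 4, dilation=0).validate()
    with pytest.raises(InvalidSpecError):
        ConvBlockSpec(1, 4, stride=3).validate()


def test_rddc_block_counts_and_shape(rng):
    block = make_rddc_block(RddcSpec(16))
    assert count_parameters(block) == 9536 == _oracle_rddc(16)
    x = rng.normal(size=(2, 16, 32, 32)).astype(np.float32)
    assert block.forward(x).shape == x.shape


def test_rddc_rejects_noncanonical_dilations():
    with pytest.raises(InvalidSpecError):
        RddcSpec(8, dilation_schedule=(1, 2, 3, 4)).validate()
    # explicit override is allowed but must be flagged
    spec = RddcSpec(8, dilation_schedule=(2, 1), allow_noncanonical=True)
    assert spec.validate() is spec


def test_rddc_identity_residual_adds_input(rng):
    res = make_rddc_block(RddcSpec(4, dropout_rate=0.0))
    plain = make_rddc_block(RddcSpec(4, dropout_rate=0.0, residual="none"))
    for _, lay, attr in res.named_param_layers():
        setattr(lay, attr, np.random.default_rng(3).normal(
            scale=0.3, size=getattr(lay, attr).shape).astype(np.float32))
    plain.load_state_dict(res.state_dict())
    x = rng.normal(size=(1, 4, 12, 12)).astype(np.float32)
    np.testing.assert_allclose(res.forward(x), plain.forward(x) + x,
                               rtol=1e-5, atol=1e-6)


def test_rddc_receptive_field_is_21():
    assert rddc_receptive_field() == 21
    assert rddc_receptive_field(dilations=(1,)) == 3


def test_encoder_receptive_field_monotone():
    rfs = monet_encoder_receptive_fields()
    assert rfs == sorted(rfs)
    assert rfs[0] == 1 + 2 + 2 * (4 + 3 + 2 + 1)   # stem + stage-1 RDDC


# ---------------------------------------------------------------------------
# Full networks
# ---------------------------------------------------------------------------

def test_unet_counts_match_published_totals():
    assert count_parameters(build_unet(16)) == 1_946_705 == _oracle_unet(16)
    assert count_parameters(build_unet(64)) == 31_054_145 == _oracle_unet(64)


def test_monet_canonical_count_matches_oracle():
    net = build_monet()
    assert count_parameters(net) == _oracle_monet(CANONICAL_MONET) == 403_556


@pytest.mark.parametrize("cfg", [
    MoNetConfig(widths=(16, 32, 64), residual="identity"),
    MoNetConfig(widths=(12, 18, 36), up_kernel=2, extra_stem=True),
    MoNetConfig(widths=(8, 16, 24), extra_fuse=True, normalized_up=False),
])
def test_monet_count_matches_oracle_across_variants(cfg):
    assert count_parameters(build_monet(cfg)) == _oracle_monet(cfg)
    assert monet_parameter_count(cfg) == _oracle_monet(cfg)


def test_unet_parameter_scaling():
    """Doubling base filters roughly quadruples the count."""
    counts = {f: count_parameters(build_unet(f)) for f in (8, 16, 32)}
    for f in (8, 16):
        assert counts[2 * f] > 3.9 * counts[f]
        assert counts[2 * f] < 4.1 * counts[f]


def test_count_invariant_to_batch_and_weights(rng):
    net = build_monet(MoNetConfig(widths=(2, 4, 8)))
    n0 = count_parameters(net)
    net.forward(rng.normal(size=(1, 1, 16, 16)).astype(np.float32))
    net.forward(rng.normal(size=(3, 1, 16, 16)).astype(np.float32))
    for _, lay, attr in net.named_param_layers():
        setattr(lay, attr, rng.normal(
            size=getattr(lay, attr).shape).astype(np.float32))
    assert count_parameters(net) == n0
    assert sum(s for _, _, s, _ in parameter_table(net)) == n0


def test_forward_output_contract(rng):
    for net in (build_monet(MoNetConfig(widths=(3, 5, 7))), build_unet(2)):
        from monetseg.training import initialize_weights
        initialize_weights(net, seed=0)
        x = rng.normal(size=(2, 1, 64, 64)).astype(np.float32)
        y = net.forward(x)
        assert y.shape == (2, 1, 64, 64)
        assert float(y.min()) >= 0.0 and float(y.max()) <= 1.0


def test_monet_rejects_bad_input_shape(rng):
    net = build_monet(MoNetConfig(widths=(2, 3, 4)))
    with pytest.raises(ValueError):
        net.forward(rng.normal(size=(1, 1, 30, 30)).astype(np.float32))
    with pytest.raises(ValueError):
        net.forward(rng.normal(size=(1, 2, 32, 32)).astype(np.float32))


# ---------------------------------------------------------------------------
# Width resolution
# ---------------------------------------------------------------------------

def test_spec_example_nearest_miss_configuration():
    cfg = MoNetConfig(widths=(16, 32, 64), up_kernel=3, residual="identity")
    assert monet_parameter_count(cfg) == 313_137


def test_documented_space_has_no_exact_match_and_reports_nearest():
    res = resolve_monet_widths(403_556, DOCUMENTED_SEARCH_SPACE)
    assert not res.resolved
    assert len(res.nearest) == 5
    delta, count, cfg = res.nearest[0]
    assert delta == abs(count - 403_556) > 0
    assert monet_parameter_count(cfg) == count


def test_extended_space_resolves_canonical_config():
    res = resolve_monet_widths(403_556, EXTENDED_SEARCH_SPACE)
    assert res.resolved
    assert CANONICAL_MONET in res.exact
    for cfg in res.exact:
        f1, f2, f3 = cfg.widths
        assert f1 < f2 <= 2 * f1 and f2 < f3 <= 2 * f2


def test_unreachable_target_yields_no_solution_report():
    res = resolve_monet_widths(10, WidthSearchSpace(f1_range=(12, 14)))
    assert not res.resolved and res.nearest


def test_empty_search_space_raises():
    with pytest.raises(InvalidSpecError):
        resolve_monet_widths(403_556, WidthSearchSpace(f1_range=(5, 4)))
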