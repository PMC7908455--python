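"""Tests for the synthetic expert-judgment generator."""

import numpy as np
import pytest

from swotahp import (
    MatrixValidationError,
    SyntheticPanelSpec,
    UnsupportedOrderError,
    aggregate_judgments,
    consistency_check,
    generate_panel,
    generate_swot_config,
    geometric_mean_weights,
    make_consistent_matrix,
    perturb_matrix,
    run_full_analysis,
    snap_to_saaty,
    validate_comparison_matrix,
)


def test_consistent_matrix_ratios_and_consistency():
    m = make_consistent_matrix([0.5, 0.3, 0.2])
    assert m.values[0, 1] == pytest.approx(5 / 3)
    assert m.values[0, 2] == pytest.approx(2.5)
    assert m.values[1, 2] == pytest.approx(1.5)
    rep = consistency_check(m)
    assert rep.ci == pytest.approx(0.0, abs=1e-12)
    assert rep.cr == pytest.approx(0.0, abs=1e-12)


def test_uniform_weights_give_all_ones_matrix():
    m = make_consistent_matrix([0.25] * 4)
    assert m.values == pytest.approx(np.ones((4, 4)))


def test_make_consistent_rejects_nonpositive():
    with pytest.raises(MatrixValidationError):
        make_consistent_matrix([0.5, 0.5, 0.0])


def test_weight_recovery_is_identity_at_sigma_zero():
    rng = np.random.default_rng(11)
    for _ in range(10):
        w = rng.dirichlet(np.ones(int(rng.integers(2, 8))))
        back = geometric_mean_weights(make_consistent_matrix(w)).weights
        assert back == pytest.approx(w, abs=1e-12)


@pytest.mark.parametrize(
    "value, expected",
    [(1.6667, 2.0), (1.0, 1.0), (0.55, 0.5), (9.5, 9.0), (0.11, 1 / 9)],
)
def test_snap_to_saaty_nearest_in_log_space(value, expected):
    assert snap_to_saaty(value) == pytest.approx(expected)


def test_snap_ties_break_toward_one():
    # sqrt(2) is equidistant (in log space) between 1 and 2: prefer 1
    assert snap_to_saaty(2 ** 0.5) == 1.0


def test_perturb_no_noise_returns_input_unchanged():
    m = make_consistent_matrix([0.5, 0.3, 0.2])
    out = perturb_matrix(m, sigma=0.0, seed=3, quantize=False)
    assert out.values == pytest.approx(m.values, abs=0)


def test_perturb_quantize_snaps_entries():
    m = make_consistent_matrix([0.5, 0.3, 0.2])  # a_12 = 1.6667
    out = perturb_matrix(m, sigma=0.0, seed=0, quantize=True)
    assert out.values[0, 1] == 2.0
    assert out.values[1, 0] == 0.5
    again = perturb_matrix(out, sigma=0.0, seed=1, quantize=True)
    assert again.values == pytest.approx(out.values, abs=0)  # idempotent


def test_perturb_deterministic_and_validates():
    m = make_consistent_matrix([0.4, 0.3, 0.2, 0.1])
    a = perturb_matrix(m, sigma=0.5, seed=42)
    b = perturb_matrix(m, sigma=0.5, seed=42)
    assert np.array_equal(a.values, b.values)
    validate_comparison_matrix(a.values)  # reciprocity holds exactly


def test_perturb_rejects_negative_sigma():
    with pytest.raises(MatrixValidationError):
        perturb_matrix(make_consistent_matrix([0.5, 0.5]), sigma=-0.1)


def test_panel_sigma_zero_recovers_true_weights_exactly():
    spec = SyntheticPanelSpec(true_weights=(0.4, 0.35, 0.25), n_experts=5, sigma=0.0)
    panel = generate_panel(spec)
    assert len(panel) == 5
    w = geometric_mean_weights(aggregate_judgments(panel)).weights
    assert w == pytest.approx([0.4, 0.35, 0.25], abs=1e-12)


def test_large_panel_aggregation_recovers_weights():
    """Law of large numbers: geometric-mean aggregation of 200 noisy experts
    (sigma = 0.3) lands within L1 distance 0.05 of the true weights."""
    true_w = (0.4, 0.3, 0.2, 0.1)
    spec = SyntheticPanelSpec(true_weights=true_w, n_experts=200, sigma=0.3, seed=20210129)
    w = geometric_mean_weights(aggregate_judgments(generate_panel(spec))).weights
    assert np.abs(w - np.array(true_w)).sum() < 0.05


def test_mean_cr_nondecreasing_in_sigma():
    """More elicitation noise cannot make panels more consistent on average:
    mean CR over 100 common-random-number replicates is non-decreasing
    through sigma in {0, 0.1, 0.2, 0.4}."""
    base = make_consistent_matrix([0.4, 0.3, 0.2, 0.1])
    seeds = np.random.SeedSequence(987).spawn(100)
    means = []
    for sigma in (0.0, 0.1, 0.2, 0.4):
        crs = [
            consistency_check(perturb_matrix(base, sigma, np.random.default_rng(s))).cr
            for s in seeds
        ]
        means.append(float(np.mean(crs)))
    assert means == sorted(means)
    assert means[0] == pytest.approx(0.0, abs=1e-12)


def test_generate_swot_config_consistent_and_deterministic():
    cfg = generate_swot_config((4, 3, 3, 3), seed=5, sigma=0.0)
    result = run_full_analysis(cfg)
    for g in result.groups.values():
        assert g.consistency.cr == pytest.approx(0.0, abs=1e-9)
    cfg2 = generate_swot_config((4, 3, 3, 3), seed=5, sigma=0.0)
    for key in "SWOT":
        assert np.array_equal(
            cfg.groups[key].matrix.values, cfg2.groups[key].matrix.values
        )
        assert cfg.groups[key].factors == cfg2.groups[key].factors


def test_generate_swot_config_caps_group_size():
    with pytest.raises(UnsupportedOrderError):
        generate_swot_config((11, 3, 3, 3), seed=0)


def test_extreme_strengths_drive_rho_to_one():
    cfg = generate_swot_config((3, 3, 3, 3), seed=9, sigma=0.1, n_experts=3)
    forced = _with_strengths(cfg, {"S": 5, "O": 5, "W": 0, "T": 0})
    result = run_full_analysis(forced)
    assert result.vector.rho == 1.0
    assert result.call.quadrant_type == "SO"


def _with_strengths(cfg, by_group):
    from dataclasses import replace

    groups = {
        key: replace(
            g, factors=tuple(replace(f, strength=float(by_group[key])) for f in g.factors)
        )
        for key, g in cfg.groups.items()
    }
    return replace(cfg, groups=groups)
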