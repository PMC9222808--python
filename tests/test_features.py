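import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.regression.linear_model import burg as sm_burg
from statsmodels.regression.linear_model import yule_walker

from harpipe import (
    FeatureRecord,
    Window,
    apply_minmax,
    apply_scaling,
    assemble_feature_vector,
    extract_stream_features,
    fit_minmax,
)
from harpipe.features import (
    N_STREAM_FEATURES,
    angle_x_gravity,
    ar_coefficients,
    burg_ar,
    roll_angle_series,
    roll_features,
    signal_entropy,
    sma,
    tilt_angle,
    unscale,
)


def make_window(values, rate=50.0, label="Walk", subject="S01", **kw):
    return Window(values=np.asarray(values, dtype=float), label=label,
                  subject_id=subject, rate_hz=rate, **kw)


def simulate_ar4(coeffs, n, seed, burn=500):
    rng = np.random.default_rng(seed)
    x = np.zeros(n + burn)
    e = rng.normal(size=n + burn)
    for i in range(4, n + burn):
        x[i] = coeffs @ x[i - 4:i][::-1] + e[i]
    return x[burn:]


# ---------------------------------------------------------------------------
# AR coefficients (Burg)

def test_burg_matches_statsmodels():
    """The lattice recursion agrees with the reference Burg solver."""
    rng = np.random.default_rng(7)
    for _ in range(5):
        x = rng.normal(size=256) + rng.normal() * 3
        np.testing.assert_allclose(burg_ar(x, 4), sm_burg(x, 4)[0], atol=1e-10)


def test_burg_recovers_known_ar4_process():
    """Generate-and-refit: Burg and an independent Yule-Walker fit both
    recover the true AR(4) coefficients at slen 4096."""
    true = np.array([0.4, -0.3, 0.2, -0.15])
    x = simulate_ar4(true, n=4096, seed=42)
    est = burg_ar(x, 4)
    yw_est, _ = yule_walker(x, order=4, method="mle")
    np.testing.assert_allclose(est, true, atol=0.05)
    np.testing.assert_allclose(est, yw_est, atol=0.05)


def test_burg_white_noise_near_zero():
    rng = np.random.default_rng(1)
    est = burg_ar(rng.normal(size=4096), 4)
    np.testing.assert_allclose(est, 0.0, atol=0.1)


def test_ar_coefficients_layout_and_degenerate_axis():
    rng = np.random.default_rng(2)
    vals = np.column_stack([
        simulate_ar4(np.array([0.5, -0.2, 0.1, -0.05]), 128, seed=3),
        rng.normal(size=128),
        np.full(128, 2.0),  # constant axis
    ])
    window = make_window(vals)
    with pytest.warns(UserWarning, match="constant axis"):
        out = ar_coefficients(window, order=4)
    assert out.shape == (12,)
    np.testing.assert_allclose(out[0:4], burg_ar(vals[:, 0], 4))
    np.testing.assert_array_equal(out[8:12], 0.0)


def test_ar_window_too_short():
    with pytest.raises(ValueError, match="too short"):
        ar_coefficients(make_window(np.zeros((8, 3))), order=4)


# ---------------------------------------------------------------------------
# Scalar features

@pytest.mark.parametrize("values,expected", [
    (np.zeros((128, 3)), 0.0),
    ([[1.0, -2.0, 3.0], [0.0, 0.0, 0.0]], 6.0),
    (np.ones((128, 3)), 384.0),
])
def test_sma_hand_examples(values, expected):
    assert sma(make_window(values)) == pytest.approx(expected)


@pytest.mark.parametrize("mean,expected", [
    ((0, 0, 1), 0.0),
    ((1, 0, 0), np.pi / 2),
    ((0, 0, -1), np.pi),
])
def test_tilt_angle_reference_axis(mean, expected):
    window = make_window(np.tile(mean, (32, 1)).astype(float))
    assert tilt_angle(window) == pytest.approx(expected)


def test_tilt_angle_zero_mean_warns():
    with pytest.warns(UserWarning, match="zero-norm"):
        assert tilt_angle(make_window(np.zeros((32, 3)))) == 0.0


@pytest.mark.parametrize("bay,baz,expected", [
    (-1.0, 0.0, 0.0),
    (0.0, -1.0, np.pi / 2),
    (1.0, 0.0, np.pi),
])
def test_roll_angle_quadrants(bay, baz, expected):
    window = make_window(np.tile([0.0, bay, baz], (16, 1)))
    np.testing.assert_allclose(roll_angle_series(window), expected)


def test_roll_angle_degenerate_origin():
    window = make_window(np.zeros((16, 3)))
    np.testing.assert_array_equal(roll_angle_series(window), 0.0)


def test_roll_features_constant_series():
    # constant (BAy, BAz) => constant roll angle c => (c, 0, 0, c^2)
    window = make_window(np.tile([0.0, -1.0, -1.0], (64, 1)))
    c = np.arctan2(1.0, 1.0)
    np.testing.assert_allclose(roll_features(window),
                               [c, 0.0, 0.0, c**2], atol=1e-12)


def test_roll_features_alternating_signs():
    # roll alternates +-pi/4 equally => mean 0, power pi^2/16
    pattern = np.tile([[0.0, -1.0, -1.0], [0.0, -1.0, 1.0]], (32, 1))
    out = roll_features(make_window(pattern))
    assert out[0] == pytest.approx(0.0, abs=1e-12)
    assert out[3] == pytest.approx(np.pi**2 / 16)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_roll_power_identity(seed):
    """power = mean^2 + STD^2 (population convention) for the roll series."""
    rng = np.random.default_rng(seed)
    window = make_window(rng.normal(size=(64, 3)))
    mean, std, _, power = roll_features(window)
    assert power == pytest.approx(mean**2 + std**2, abs=1e-9)


@pytest.mark.parametrize("mx,gm,expected", [
    (1.0, (1.0, 0.0, 0.0), 0.0),            # parallel
    (1.0, (0.0, 0.0, 9.81), np.pi / 2),      # perpendicular
    (-1.0, (1.0, 0.0, 0.0), np.pi),          # antiparallel (sign retained)
])
def test_angle_x_gravity_geometry(mx, gm, expected):
    window = make_window(np.tile([mx, 0.0, 0.0], (16, 1)))
    assert angle_x_gravity(window, np.array(gm)) == pytest.approx(expected)


def test_angle_x_gravity_clamps_cosine():
    # cosine ratio numerically at 1 must clamp, never go complex/NaN
    window = make_window(np.tile([1e-8, 0.0, 0.0], (16, 1)))
    out = angle_x_gravity(window, np.array([1e8, 0.0, 0.0]))
    assert out == pytest.approx(0.0)


def test_angle_x_gravity_zero_norm_sentinel():
    window = make_window(np.zeros((16, 3)))
    with pytest.warns(UserWarning, match="zero-norm"):
        assert angle_x_gravity(window, np.array([0, 0, 9.81])) == 0.0


def test_entropy_hand_values():
    assert signal_entropy(np.full(100, 3.3)) == 0.0
    # 16 equally filled bins: maximum entropy ln 16
    series = np.repeat(np.arange(16), 10) + 0.5
    assert signal_entropy(series, n_bins=16) == pytest.approx(np.log(16))
    # two half-filled bins: ln 2
    two = np.array([0.0] * 50 + [1.0] * 50)
    assert signal_entropy(two, n_bins=2) == pytest.approx(np.log(2))


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_entropy_bounds(seed):
    rng = np.random.default_rng(seed)
    h = signal_entropy(rng.normal(size=rng.integers(2, 300)), n_bins=16)
    assert 0.0 <= h <= np.log(16) + 1e-12


# ---------------------------------------------------------------------------
# Full stream descriptor

def test_descriptor_length_and_determinism():
    rng = np.random.default_rng(5)
    window = make_window(rng.normal(size=(128, 3)))
    gm = np.array([0.0, 0.0, 9.81])
    a = extract_stream_features(window, gm)
    b = extract_stream_features(window, gm)
    assert a.values.shape == (N_STREAM_FEATURES,)
    np.testing.assert_array_equal(a.values, b.values)


def test_descriptor_zero_window_is_finite():
    out = extract_stream_features(make_window(np.zeros((128, 3))),
                                  np.array([0.0, 0.0, 9.81]))
    v = out.values
    assert np.all(np.isfinite(v))
    np.testing.assert_array_equal(v[0:12], 0.0)   # means/STDs of AS and JS
    assert v[24] == 0.0                           # SMA
    np.testing.assert_array_equal(v[31:37], 0.0)  # entropies and powers


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_descriptor_randomized_invariants(seed):
    """37 finite values; per-axis power = mean^2 + STD^2; angles in range."""
    rng = np.random.default_rng(seed)
    window = make_window(rng.normal(scale=2.0, size=(128, 3)) + rng.normal(size=3))
    v = extract_stream_features(window, np.array([0.1, 0.2, 9.8])).values
    assert v.shape == (N_STREAM_FEATURES,)
    assert np.all(np.isfinite(v))
    for axis in range(3):
        assert v[34 + axis] == pytest.approx(v[axis] ** 2 + v[3 + axis] ** 2,
                                             abs=1e-9)
    assert 0.0 <= v[25] <= np.pi      # tilt
    assert 0.0 <= v[30] <= np.pi      # x-gravity angle
    assert all(0.0 <= v[31 + i] <= np.log(16) + 1e-12 for i in range(3))


def test_descriptor_rejects_nan():
    vals = np.zeros((128, 3))
    vals[5, 1] = np.nan
    with pytest.raises(ValueError):
        make_window(vals)


# ---------------------------------------------------------------------------
# Assembly

def _aligned_windows(stream_names, seed=0):
    rng = np.random.default_rng(seed)
    out = {}
    for name in stream_names:
        device, kind = name.split(".")
        out[name] = make_window(rng.normal(size=(128, 3)) + [0, 0, 9.8],
                                device_position=device, sensor_kind=kind)
    return out


def test_assemble_shoaib_dim_222():
    names = ["pocket.body_accel", "pocket.gravity_accel", "pocket.gyroscope",
             "wrist.body_accel", "wrist.gravity_accel", "wrist.gyroscope"]
    rec = assemble_feature_vector(_aligned_windows(names), preset="shoaib")
    assert rec.dim == 222
    assert rec.feature_names[0] == "pocket.body_accel.F1"
    assert rec.feature_names[-1] == "wrist.gyroscope.F37"


def test_assemble_wisdm_dim_74():
    names = ["pocket.body_accel", "pocket.gravity_accel"]
    rec = assemble_feature_vector(_aligned_windows(names), preset="wisdm")
    assert rec.dim == 74


def test_assemble_custom_dim_multiple_of_37():
    names = ["pocket.body_accel", "pocket.gravity_accel",
             "pocket.gyroscope", "wrist.body_accel"]
    rec = assemble_feature_vector(_aligned_windows(names), preset="custom")
    assert rec.dim == 148


def test_assemble_misaligned_window_rejected():
    names = ["pocket.body_accel", "pocket.gravity_accel"]
    windows = _aligned_windows(names)
    windows["pocket.gravity_accel"].start_index = 64
    with pytest.raises(ValueError, match="not aligned"):
        assemble_feature_vector(windows, preset="wisdm")


def test_assemble_missing_stream_rejected():
    windows = _aligned_windows(["pocket.body_accel"])
    with pytest.raises(ValueError, match="requires streams"):
        assemble_feature_vector(windows, preset="wisdm")


# ---------------------------------------------------------------------------
# Scaling and normalization

def _record(dim=222, seed=0):
    rng = np.random.default_rng(seed)
    return FeatureRecord(vector=rng.normal(size=dim), label="Walk",
                         subject_id="S01")


def test_scaling_slen_one_is_identity():
    rec = _record()
    np.testing.assert_array_equal(apply_scaling(rec, 1).vector, rec.vector)


def test_scaling_sma_divided_by_slen_squared():
    vec = np.zeros(37)
    vec[24] = 384.0  # SMA slot
    rec = FeatureRecord(vector=vec, label="x", subject_id="s")
    scaled = apply_scaling(rec, 128)
    assert scaled.vector[24] == pytest.approx(384.0 / 128**2)
    assert scaled.vector[24] == pytest.approx(0.0234375)


def test_scaling_leaves_entropies_unchanged():
    rec = _record(dim=37, seed=3)
    scaled = apply_scaling(rec, 128)
    np.testing.assert_array_equal(scaled.vector[31:34], rec.vector[31:34])
    np.testing.assert_array_equal(scaled.vector[34:37], rec.vector[34:37])
    # the groups that must shrink
    np.testing.assert_allclose(scaled.vector[0:9], rec.vector[0:9] / 128)
    np.testing.assert_allclose(scaled.vector[12:24], rec.vector[12:24] / 128)
    assert scaled.vector[30] == pytest.approx(rec.vector[30] / 128)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1),
       st.integers(min_value=1, max_value=512))
def test_scaling_roundtrip(seed, slen):
    """Unscaling inverts scaling: bit-exact for power-of-two segment lengths
    (the defaults), to machine precision otherwise."""
    rec = _record(seed=seed)
    back = unscale(apply_scaling(rec, slen), slen)
    if slen & (slen - 1) == 0:
        np.testing.assert_array_equal(back.vector, rec.vector)
    else:
        np.testing.assert_allclose(back.vector, rec.vector, rtol=1e-15)


def test_minmax_training_in_unit_interval():
    rng = np.random.default_rng(8)
    records = [_record(dim=10, seed=i) for i in range(20)]
    params = fit_minmax(records)
    out = apply_minmax(records, params)
    mat = np.vstack([r.vector for r in out])
    assert mat.min() >= 0.0 and mat.max() <= 1.0


def test_minmax_constant_feature_maps_to_zero():
    records = [FeatureRecord(vector=np.array([1.0, i]), label="x", subject_id="s")
               for i in range(5)]
    out = apply_minmax(records, fit_minmax(records))
    assert all(r.vector[0] == 0.0 for r in out)


def test_minmax_test_values_not_clipped():
    train = [FeatureRecord(vector=np.array([float(i)]), label="x", subject_id="s")
             for i in range(5)]
    params = fit_minmax(train)
    (out,) = apply_minmax(
        [FeatureRecord(vector=np.array([8.0]), label="x", subject_id="s")], params
    )
    assert out.vector[0] == pytest.approx(2.0)  # above the training max


def test_minmax_requires_two_records():
    with pytest.raises(ValueError):
        fit_minmax([])
    with pytest.raises(ValueError):
        fit_minmax([_record()])
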