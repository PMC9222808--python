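"""The 37-feature window descriptor, scaling, and min-max normalization.

Every 3-axis stream window is summarized by an ordered 37-value descriptor:

====== ==========================================================
F1-6   per-axis mean then per-axis STD of the signal (AS)
F7-12  per-axis mean then per-axis STD of its jerk (JS)
F13-24 order-4 autoregressive coefficients per axis (Burg method)
F25    signal magnitude area (SMA), an unnormalized sum
F26    tilt angle (TA) between the window-mean vector and +z
F27-30 roll-angle series: mean, STD, entropy of its jerk, power
F31    angle between the x-projected mean and the mean gravity vector
F32-34 histogram entropy of each jerk axis
F35-37 per-axis power (mean of squares) of the signal
====== ==========================================================

Concatenating the descriptor over the streams of a recording gives the
per-window feature vector: 6 streams x 37 = 222 for two-device
accelerometer + gyroscope data, 2 streams x 37 = 74 for a single
accelerometer.  Large-magnitude features are then compressed by the segment
length ``slen`` (SMA by slen^2), and finally each feature is min-max
normalized to [0, 1] using training-set extrema only.

Statistics use the population (1/N) variance convention throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io_formats import FeatureRecord
from .preprocessing import Window, jerk_signal

__all__ = [
    "StreamFeatures",
    "NormalizationParams",
    "N_STREAM_FEATURES",
    "burg_ar",
    "ar_coefficients",
    "sma",
    "tilt_angle",
    "roll_angle_series",
    "roll_features",
    "angle_x_gravity",
    "signal_entropy",
    "extract_stream_features",
    "assemble_feature_vector",
    "scaling_factors",
    "apply_scaling",
    "unscale",
    "fit_minmax",
    "apply_minmax",
    "SHOAIB_STREAM_ORDER",
    "WISDM_STREAM_ORDER",
]

#: number of features per 3-axis stream
N_STREAM_FEATURES = 37

#: fixed stream concatenation order for the two-device preset (dim 222)
SHOAIB_STREAM_ORDER = (
    "pocket.body_accel",
    "pocket.gravity_accel",
    "pocket.gyroscope",
    "wrist.body_accel",
    "wrist.gravity_accel",
    "wrist.gyroscope",
)

#: stream order for the single-accelerometer preset (dim 74)
WISDM_STREAM_ORDER = ("pocket.body_accel", "pocket.gravity_accel")


@dataclass
class StreamFeatures:
    """Ordered 37-value descriptor of one stream window."""

    values: np.ndarray
    stream_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_STREAM_FEATURES,):
            raise ValueError(f"expected {N_STREAM_FEATURES} features")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature value")


def burg_ar(x: np.ndarray, order: int) -> np.ndarray:
    """Autoregressive coefficients of a 1-D series by Burg's method.

    Returns coefficients ``a`` in the prediction convention
    ``x[n] = sum_k a[k] x[n-k] + e[n]`` (after demeaning).  The lattice
    recursion minimizes the sum of forward and backward prediction error
    power at each order, which keeps all reflection coefficients in [-1, 1].
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n <= 2 * order:
        raise ValueError(f"need more than {2 * order} samples for order {order}")
    x = x - x.mean()
    # error-filter convention inside the recursion: A(z) = 1 + a1 z^-1 + ...
    a = np.zeros(0)
    f = x[1:].copy()   # forward prediction errors
    b = x[:-1].copy()  # backward prediction errors
    for _ in range(order):
        denom = f @ f + b @ b
        if denom <= 0:
            a = np.concatenate([a, np.zeros(order - len(a))])
            break
        k = -2.0 * (f @ b) / denom
        a = np.concatenate([a + k * a[::-1], [k]])
        f, b = (f + k * b)[1:], (b + k * f)[:-1]
    return -a  # flip to the prediction convention


def ar_coefficients(window: Window, order: int = 4) -> np.ndarray:
    """Per-axis Burg AR coefficients, axis-major (x1..x4, y1..y4, z1..z4).

    A constant axis has no spectral content; its coefficients are set to 0
    with a warning.
    """
    if window.slen <= 2 * order:
        raise ValueError(f"window too short for AR order {order}")
    out = np.empty(3 * order)
    for axis in range(3):
        x = window.values[:, axis]
        if np.ptp(x) == 0:
            warnings.warn(
                f"constant axis {axis}: AR coefficients set to 0", stacklevel=2
            )
            out[axis * order : (axis + 1) * order] = 0.0
        else:
            out[axis * order : (axis + 1) * order] = burg_ar(x, order)
    return out


def sma(window: Window) -> float:
    """Signal magnitude area: sum over samples of |x| + |y| + |z|.

    Deliberately an unnormalized sum (it grows linearly with slen), which is
    why the scaling stage divides it by slen^2.
    """
    return float(np.abs(window.values).sum())


def tilt_angle(window: Window) -> float:
    """Angle (radians, [0, pi]) between the window-mean vector and +z."""
    mean = window.values.mean(axis=0)
    norm = np.linalg.norm(mean)
    if norm == 0:
        warnings.warn("zero-norm window mean: tilt angle set to 0", stacklevel=2)
        return 0.0
    return float(np.arccos(np.clip(mean[2] / norm, -1.0, 1.0)))


def roll_angle_series(window: Window) -> np.ndarray:
    """Per-sample roll angle arctan2(-BAz, -BAy), in (-pi, pi].

    ``arctan2(0, 0)`` is defined as 0.
    """
    y = window.values[:, 1]
    z = window.values[:, 2]
    # add +0.0 so negating a (+0.0) sample cannot produce -0.0, which would
    # flip arctan2 results from +pi to -pi (and (0, 0) to -pi instead of 0)
    return np.arctan2(-z + 0.0, -y + 0.0)


def roll_features(window: Window, entropy_bins: int = 16) -> np.ndarray:
    """Mean, STD, jerk entropy, and power of the roll-angle series (F27-30)."""
    if window.slen < 3:
        raise ValueError("need at least 3 samples for roll features")
    roll = roll_angle_series(window)
    jerk = jerk_signal(roll[:, None], window.rate_hz)[:, 0]
    return np.array(
        [
            roll.mean(),
            roll.std(),
            signal_entropy(jerk, entropy_bins),
            np.mean(roll**2),
        ]
    )


def angle_x_gravity(window: Window, gravity_mean: np.ndarray) -> float:
    """Angle (radians, [0, pi]) between the x-projected window mean and gravity.

    The window's representative x-vector is ``Bx = (mean_x, 0, 0)`` with the
    sign of the x-mean retained, so the angle distinguishes forward from
    backward tilt; ``Gm`` is the mean gravity vector of the same device.  The
    cosine ratio is clamped to [-1, 1] so the result is always real.  A
    zero-norm input returns the sentinel 0 with a warning.
    """
    gravity_mean = np.asarray(gravity_mean, dtype=float)
    mean_x = window.values[:, 0].mean()
    bx = np.array([mean_x, 0.0, 0.0])
    nb = np.linalg.norm(bx)
    ng = np.linalg.norm(gravity_mean)
    if nb == 0 or ng == 0:
        warnings.warn("zero-norm vector in x-gravity angle: returning 0",
                      stacklevel=2)
        return 0.0
    cos = np.clip(bx @ gravity_mean / (nb * ng), -1.0, 1.0)
    return float(np.arccos(cos))


def signal_entropy(series: np.ndarray, n_bins: int = 16) -> float:
    """Shannon entropy (nats) of the equal-width histogram of a series.

    Bins span [min, max]; a constant series (degenerate range) has entropy 0.
    Bounded by ln(n_bins).
    """
    series = np.asarray(series, dtype=float).ravel()
    if series.size == 0:
        raise ValueError("empty series")
    lo, hi = series.min(), series.max()
    if lo == hi:
        return 0.0
    counts, _ = np.histogram(series, bins=n_bins, range=(lo, hi))
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def extract_stream_features(
    window: Window,
    gravity_mean: np.ndarray,
    ar_order: int = 4,
    entropy_bins: int = 16,
) -> StreamFeatures:
    """Compute the ordered 37-feature descriptor of one stream window.

    Deterministic and finite for every valid window; an all-zeros window
    yields zeros for every moment-based feature and no NaN anywhere.
    """
    if window.slen < 16:
        raise ValueError("window too short for feature extraction")
    vals = window.values
    jerk = jerk_signal(vals, window.rate_hz)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate windows fall back to 0s
        feats = np.concatenate(
            [
                vals.mean(axis=0),            # F1-3
                vals.std(axis=0),             # F4-6
                jerk.mean(axis=0),            # F7-9
                jerk.std(axis=0),             # F10-12
                ar_coefficients(window, ar_order),          # F13-24
                [sma(window)],                              # F25
                [tilt_angle(window)],                       # F26
                roll_features(window, entropy_bins),        # F27-30
                [angle_x_gravity(window, gravity_mean)],    # F31
                [signal_entropy(jerk[:, a], entropy_bins) for a in range(3)],  # F32-34
                np.mean(vals**2, axis=0),     # F35-37
            ]
        )
    name = f"{window.device_position}.{window.sensor_kind}"
    return StreamFeatures(values=feats, stream_name=name)


def _stream_order(preset: str, windows_by_stream: Mapping[str, Window]) -> tuple:
    if preset == "shoaib":
        return SHOAIB_STREAM_ORDER
    if preset == "wisdm":
        return WISDM_STREAM_ORDER
    if preset == "custom":
        return tuple(windows_by_stream.keys())
    raise ValueError(f"unknown preset {preset!r}")


def assemble_feature_vector(
    windows_by_stream: Mapping[str, Window],
    preset: str = "custom",
    ar_order: int = 4,
    entropy_bins: int = 16,
) -> FeatureRecord:
    """Concatenate per-stream descriptors into one per-window vector.

    ``windows_by_stream`` maps ``"<device>.<sensor_kind>"`` to aligned
    windows (same start index, subject, and label).  The mean gravity vector
    of each device is taken from that device's ``gravity_accel`` window; a
    stream on a device without one falls back to its own window mean.  The
    stream order is fixed by the preset (dim 222 for the two-device preset,
    74 for the single-accelerometer preset, 37 x k for custom).
    """
    order = _stream_order(preset, windows_by_stream)
    missing = [k for k in order if k not in windows_by_stream]
    if missing:
        raise ValueError(f"preset {preset!r} requires streams {missing}")

    ref = windows_by_stream[order[0]]
    for key in order:
        w = windows_by_stream[key]
        if (w.start_index, w.subject_id, w.label) != (
            ref.start_index,
            ref.subject_id,
            ref.label,
        ):
            raise ValueError(f"stream {key!r} window is not aligned")

    gravity_means = {
        key.split(".")[0]: windows_by_stream[key].values.mean(axis=0)
        for key in order
        if key.endswith(".gravity_accel")
    }

    parts, names = [], []
    for key in order:
        w = windows_by_stream[key]
        device = key.split(".")[0]
        gm = gravity_means.get(device, w.values.mean(axis=0))
        sf = extract_stream_features(w, gm, ar_order, entropy_bins)
        parts.append(sf.values)
        names.extend(f"{key}.F{i + 1}" for i in range(N_STREAM_FEATURES))
    return FeatureRecord(
        vector=np.concatenate(parts),
        label=ref.label,
        subject_id=ref.subject_id,
        feature_names=names,
    )


def scaling_factors(dim: int, slen: int) -> np.ndarray:
    """Per-feature divisors of the segment-length scaling, tiled per stream.

    Within each 37-block: AR coefficients, tilt angle, AS mean/STD, JS mean,
    roll mean and roll power, and the x-gravity angle are divided by slen;
    SMA by slen^2; everything else (JS STDs, roll STD, entropies, powers)
    is left unscaled.
    """
    if dim % N_STREAM_FEATURES:
        raise ValueError(f"dimension {dim} is not a multiple of {N_STREAM_FEATURES}")
    block = np.ones(N_STREAM_FEATURES)
    block[0:6] = slen        # F1-6 mean/STD of AS
    block[6:9] = slen        # F7-9 mean of JS
    block[12:24] = slen      # F13-24 AR
    block[24] = slen**2      # F25 SMA
    block[25] = slen         # F26 TA
    block[26] = slen         # F27 mean of RA
    block[29] = slen         # F30 power of RA
    block[30] = slen         # F31 angle of x-component
    return np.tile(block, dim // N_STREAM_FEATURES)


def apply_scaling(record: FeatureRecord, slen: int) -> FeatureRecord:
    """Divide the large-magnitude feature groups by the segment length."""
    if slen < 1:
        raise ValueError("slen must be >= 1")
    factors = scaling_factors(record.dim, slen)
    return FeatureRecord(
        vector=record.vector / factors,
        label=record.label,
        subject_id=record.subject_id,
        feature_names=record.feature_names,
    )


def unscale(record: FeatureRecord, slen: int) -> FeatureRecord:
    """Exact inverse of :func:`apply_scaling` (multiply the divisors back)."""
    factors = scaling_factors(record.dim, slen)
    return FeatureRecord(
        vector=record.vector * factors,
        label=record.label,
        subject_id=record.subject_id,
        feature_names=record.feature_names,
    )


@dataclass
class NormalizationParams:
    """Per-feature training-set extrema for min-max normalization."""

    minimum: np.ndarray
    maximum: np.ndarray

    def __post_init__(self) -> None:
        self.minimum = np.asarray(self.minimum, dtype=float)
        self.maximum = np.asarray(self.maximum, dtype=float)
        if np.any(self.minimum > self.maximum):
            raise ValueError("min > max")


def fit_minmax(records: Sequence[FeatureRecord]) -> NormalizationParams:
    """Learn per-feature (min, max) from training records only."""
    records = list(records)
    if len(records) < 2:
        raise ValueError("need at least 2 training records to fit normalization")
    mat = np.vstack([r.vector for r in records])
    return NormalizationParams(minimum=mat.min(axis=0), maximum=mat.max(axis=0))


def apply_minmax(
    records: Sequence[FeatureRecord], params: NormalizationParams
) -> list[FeatureRecord]:
    """Map each feature to (x - min) / (max - min).

    Constant training features map to 0; held-out values outside the training
    range are *not* clipped (they may fall outside [0, 1]).
    """
    span = params.maximum - params.minimum
    safe = np.where(span > 0, span, 1.0)
    out = []
    for r in records:
        if len(r.vector) != len(span):
            raise ValueError("record dimension does not match normalization params")
        x = (r.vector - params.minimum) / safe
        x[span == 0] = 0.0
        out.append(
            FeatureRecord(
                vector=x,
                label=r.label,
                subject_id=r.subject_id,
                feature_names=r.feature_names,
            )
        )
    return out
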