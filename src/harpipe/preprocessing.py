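"""Signal conditioning: denoising, gravity/body separation, jerk, windowing.

Accelerometer streams carry both device orientation (gravity, a near-DC
component) and limb motion (body acceleration).  The two are split with a
zero-phase low-pass Butterworth filter: the low-pass output is the gravity
estimate and the residual is body acceleration, so the two components always
sum back to the input exactly.

Defaults follow common smartphone HAR practice: a 4th-order filter, a 20 Hz
denoising corner at 50 Hz sampling, a 0.3 Hz gravity corner, and 2.56 s
windows (128 samples at 50 Hz) with 50% overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io_formats import SensorStream

__all__ = [
    "FilterSpec",
    "Window",
    "lowpass_filter",
    "separate_gravity_body",
    "jerk_signal",
    "segment_windows",
]


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth filter parameters.

    ``zero_phase=True`` applies the filter forward and backward
    (scipy ``filtfilt``), doubling attenuation in dB and removing group
    delay so windows need no lag compensation.
    """

    order: int = 4
    cutoff_hz: float = 20.0
    kind: str = "lowpass"
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("order must be a positive integer")
        if self.cutoff_hz <= 0:
            raise ValueError("cutoff_hz must be positive")
        if self.kind != "lowpass":
            raise ValueError("only lowpass filters are supported")


@dataclass
class Window:
    """A fixed-length segment of one stream.

    ``values`` is an (slen, 3) matrix; body-acceleration windows expose the
    per-sample components BAx, BAy, BAz as its columns.
    """

    values: np.ndarray
    label: str
    subject_id: str
    rate_hz: float
    device_position: str = "pocket"
    sensor_kind: str = "accelerometer"
    start_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 3:
            raise ValueError("window values must be (slen, 3)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("window contains NaN or Inf")

    @property
    def slen(self) -> int:
        return self.values.shape[0]

    @property
    def provenance(self) -> tuple[str, str]:
        return (self.device_position, self.sensor_kind)


def _apply_lowpass(values: np.ndarray, spec: FilterSpec, rate_hz: float) -> np.ndarray:
    nyquist = rate_hz / 2.0
    if spec.cutoff_hz >= nyquist:
        raise ValueError(
            f"cutoff {spec.cutoff_hz} Hz must be below Nyquist ({nyquist} Hz)"
        )
    sos = signal.butter(spec.order, spec.cutoff_hz, btype="low",
                        fs=rate_hz, output="sos")
    padlen = 3 * (2 * len(sos) + 1)  # sosfiltfilt default edge padding
    if len(values) <= padlen:
        raise ValueError(
            f"stream too short for zero-phase filtering: need > {padlen} samples"
        )
    if spec.zero_phase:
        return signal.sosfiltfilt(sos, values, axis=0)
    return signal.sosfilt(sos, values, axis=0)


def lowpass_filter(stream: SensorStream, spec: FilterSpec) -> SensorStream:
    """Apply a (zero-phase by default) Butterworth low-pass to each axis.

    Output has the same length and rate; the DC component is preserved
    (unit gain at 0 Hz).
    """
    filtered = _apply_lowpass(stream.samples, spec, stream.rate_hz)
    return stream.replace(samples=filtered)


def separate_gravity_body(
    accel: SensorStream,
    gravity_cutoff_hz: float = 0.3,
    order: int = 4,
) -> tuple[SensorStream, SensorStream]:
    """Split an accelerometer stream into body and gravity components.

    gravity = low-pass(accel, gravity_cutoff_hz); body = accel - gravity,
    so body + gravity reconstructs the input exactly by construction.

    Returns ``(body, gravity)`` with sensor kinds ``body_accel`` and
    ``gravity_accel``.
    """
    if accel.sensor_kind != "accelerometer":
        raise ValueError(
            f"expected an accelerometer stream, got {accel.sensor_kind!r}"
        )
    spec = FilterSpec(order=order, cutoff_hz=gravity_cutoff_hz)
    gravity_vals = _apply_lowpass(accel.samples, spec, accel.rate_hz)
    body_vals = accel.samples - gravity_vals
    gravity = accel.replace(samples=gravity_vals, sensor_kind="gravity_accel")
    body = accel.replace(samples=body_vals, sensor_kind="body_accel")
    return body, gravity


def jerk_signal(values: np.ndarray, rate_hz: float) -> np.ndarray:
    """First time derivative estimated by scaled first difference.

    ``jerk[n] = (x[n+1] - x[n]) * rate_hz`` per axis; output is one sample
    shorter than the input.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 samples to differentiate")
    return np.diff(values, axis=0) * rate_hz


def segment_windows(
    stream: SensorStream,
    slen: int,
    overlap_fraction: float = 0.5,
) -> list[Window]:
    """Cut a stream into fixed-length windows with fractional overlap.

    Step = round(slen * (1 - overlap)); windows start at 0, step, 2*step, ...
    A window's label is the majority per-sample label; windows where no label
    covers more than half the samples are discarded (only happens at activity
    transitions).  A stream shorter than ``slen`` yields an empty list.
    """
    if slen < 2:
        raise ValueError("slen must be >= 2")
    if not (0 <= overlap_fraction < 1):
        raise ValueError("overlap_fraction must be in [0, 1)")
    step = int(round(slen * (1 - overlap_fraction)))
    step = max(step, 1)
    n = len(stream)
    if n < slen:
        return []
    windows: list[Window] = []
    for start in range(0, n - slen + 1, step):
        chunk_labels = stream.labels[start : start + slen]
        labels, counts = np.unique(chunk_labels.astype(str), return_counts=True)
        best = int(np.argmax(counts))
        if counts[best] * 2 <= slen:
            continue  # no majority label
        windows.append(
            Window(
                values=stream.samples[start : start + slen],
                label=str(labels[best]),
                subject_id=stream.subject_id,
                rate_hz=stream.rate_hz,
                device_position=stream.device_position,
                sensor_kind=stream.sensor_kind,
                start_index=start,
            )
        )
    return windows
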