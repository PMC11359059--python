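"""Raw position trials -> frequency-domain features and trunk displacement.

The preprocessing chain is the standard movement-analysis one: zero-phase
Butterworth low-pass filtering of every channel/axis series, optional
differentiation to linear acceleration, magnitude spectra via the real DFT,
per-subject pooling over tasks and repetitions, and column z-scoring.
Trunk displacement — the severity proxy used for cluster labeling — is the
baseline-referenced sum of absolute x/y/z deviations of the trunk channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .errors import ConfigurationError, DataError, InputError
from .synthetic import MotionTrial

POSITION_SPECTRUM = "position-spectrum"
ACCELERATION_SPECTRUM = "acceleration-spectrum"
_KIND_ALIASES = {
    "position": POSITION_SPECTRUM,
    "acceleration": ACCELERATION_SPECTRUM,
    POSITION_SPECTRUM: POSITION_SPECTRUM,
    ACCELERATION_SPECTRUM: ACCELERATION_SPECTRUM,
}


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth filter parameters (default: 2nd order, 10 Hz)."""

    order: int = 2
    cutoff_hz: float = 10.0
    kind: str = "lowpass"

    def validate(self, sampling_rate_hz: float) -> None:
        if self.order < 1:
            raise ConfigurationError("filter order must be >= 1")
        if self.kind != "lowpass":
            raise ConfigurationError("only low-pass filtering is supported")
        if not 0.0 < self.cutoff_hz < sampling_rate_hz / 2.0:
            raise ConfigurationError(
                f"cutoff_hz must lie in (0, Nyquist={sampling_rate_hz / 2.0} Hz)"
            )


@dataclass(frozen=True)
class FeatureMatrix:
    """n subjects x d frequency-domain features, z-scored per column."""

    values: np.ndarray
    row_ids: tuple[str, ...]
    feature_names: tuple[str, ...]
    feature_kind: str

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.row_ids), columns=list(self.feature_names)
        )


@dataclass(frozen=True)
class TrunkDisplacementSummary:
    """Per-step trunk displacement (TD) series and its per-axis components.

    ``td`` is TD(s) = TD_x + TD_y + TD_z for every step past the baseline
    window; ``components`` holds the per-axis terms; ``mean_td`` is the
    per-trial summary used for severity ranking.  Multi-marker input is
    averaged across markers.
    """

    td: np.ndarray
    components: np.ndarray
    mean_td: float


def design_lowpass(spec: FilterSpec, sampling_rate_hz: float):
    """Return (b, a) coefficients of the specified Butterworth low-pass."""
    spec.validate(sampling_rate_hz)
    return signal.butter(spec.order, spec.cutoff_hz, btype="low", fs=sampling_rate_hz)


def lowpass_filter(
    series: np.ndarray, sampling_rate_hz: float, spec: FilterSpec = FilterSpec()
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass along axis 0.

    Forward-backward application squares the magnitude response, so the
    effective attenuation at the cutoff is -6 dB rather than -3 dB.
    """
    series = np.asarray(series, dtype=float)
    if series.shape[0] < 3 * spec.order:
        raise InputError(
            f"series length {series.shape[0]} < 3 x filter order {spec.order}"
        )
    b, a = design_lowpass(spec, sampling_rate_hz)
    return signal.filtfilt(b, a, series, axis=0)


def derive_acceleration(positions: np.ndarray, sampling_rate_hz: float) -> np.ndarray:
    """Linear acceleration from positions by second differencing.

    Interior points use the central second difference
    a_t = (p_{t+1} - 2 p_t + p_{t-1}) * fs^2 (exact for quadratics); the two
    endpoints reuse the one-sided second difference of their nearest
    interior triple so the output stays aligned with the input time base.
    """
    p = np.asarray(positions, dtype=float)
    if p.shape[0] < 3:
        raise InputError("need at least 3 samples to differentiate twice")
    fs2 = sampling_rate_hz**2
    a = np.empty_like(p)
    a[1:-1] = (p[2:] - 2.0 * p[1:-1] + p[:-2]) * fs2
    a[0] = (p[2] - 2.0 * p[1] + p[0]) * fs2
    a[-1] = (p[-1] - 2.0 * p[-2] + p[-3]) * fs2
    return a


def trunk_displacement(
    positions: np.ndarray, baseline_n: int = 10
) -> TrunkDisplacementSummary:
    """Baseline-referenced trunk displacement per step.

    ``positions`` is (time, 3) for a single trunk sensor or
    (time, markers, 3) for a multi-marker trunk (camera configuration); in
    the latter case TD is computed per marker and averaged.  The baseline is
    the per-axis mean of the first ``baseline_n`` samples; each later step
    contributes the absolute per-axis deviation from that baseline, summed
    over axes.  Absolute values make TD a nonnegative magnitude, so opposite
    lean directions cannot cancel.
    """
    p = np.asarray(positions, dtype=float)
    if p.ndim == 2:
        p = p[:, None, :]
    if p.ndim != 3 or p.shape[-1] != 3:
        raise InputError("positions must be (time, 3) or (time, markers, 3)")
    if p.shape[0] < baseline_n + 1:
        raise InputError(
            f"need at least baseline_n + 1 = {baseline_n + 1} samples, got {p.shape[0]}"
        )
    baseline = p[:baseline_n].mean(axis=0)
    dev = np.abs(p[baseline_n:] - baseline[None, :, :])
    components = dev.mean(axis=1)  # average across markers
    td = components.sum(axis=1)
    return TrunkDisplacementSummary(
        td=td, components=components, mean_td=float(td.mean())
    )


def subject_trunk_displacement(
    trials: list[MotionTrial], trunk_channel: str, baseline_n: int = 10
) -> pd.Series:
    """Per-subject mean trunk displacement, averaged over a subject's trials."""
    acc: dict[str, list[float]] = {}
    for tr in trials:
        summ = trunk_displacement(tr.channel(trunk_channel), baseline_n=baseline_n)
        acc.setdefault(tr.subject_id, []).append(summ.mean_td)
    index = sorted(acc)
    return pd.Series([float(np.mean(acc[s])) for s in index], index=index, name="td")


def to_frequency_features(
    trials: list[MotionTrial],
    filter_spec: FilterSpec = FilterSpec(),
    feature_kind: str = "position",
    n_bins: int = 8,
) -> FeatureMatrix:
    """Build the subject-level frequency-domain feature matrix.

    Per trial, each channel/axis series is low-pass filtered (and, for the
    acceleration kind, differentiated twice), transformed by the real DFT,
    and the first ``n_bins`` magnitude bins are kept.  Trial feature vectors
    are averaged per subject over tasks and repetitions, then every column
    is z-scored across subjects.  Rows are ordered by subject id; columns as
    ``<channel>_<axis>_bin<j>``.
    """
    if not trials:
        raise InputError("no trials supplied")
    kind = _KIND_ALIASES.get(feature_kind)
    if kind is None:
        raise ConfigurationError(f"unknown feature_kind {feature_kind!r}")
    fs = trials[0].sampling_rate_hz
    if any(tr.sampling_rate_hz != fs for tr in trials):
        raise InputError("all trials must share one sampling rate")
    n_samples = min(tr.n_samples for tr in trials)
    if n_bins > n_samples // 2 + 1:
        raise InputError(
            f"n_bins={n_bins} exceeds available spectrum length {n_samples // 2 + 1}"
        )

    channels = trials[0].channel_names
    names = tuple(
        f"{ch}_{axis}_bin{j}" for ch in channels for axis in "xyz" for j in range(n_bins)
    )
    ordered = sorted(trials, key=lambda t: (t.subject_id, t.task_id, t.repetition))
    per_subject: dict[str, list[np.ndarray]] = {}
    for tr in ordered:
        flat = tr.positions.reshape(tr.n_samples, -1)  # (T, C*3), axis-minor
        filt = lowpass_filter(flat, fs, filter_spec)
        if kind == ACCELERATION_SPECTRUM:
            filt = derive_acceleration(filt, fs)
        mags = np.abs(np.fft.rfft(filt, axis=0)) / filt.shape[0]
        vec = mags[:n_bins].T.reshape(-1)  # bins contiguous per channel-axis
        per_subject.setdefault(tr.subject_id, []).append(vec)

    row_ids = tuple(sorted(per_subject))
    values = np.vstack([np.mean(per_subject[s], axis=0) for s in row_ids])
    if not np.all(np.isfinite(values)):
        raise DataError("non-finite feature values after transformation")

    mu = values.mean(axis=0)
    sd = values.std(axis=0)
    centered = values - mu
    # zero-variance columns carry no information; left at 0 after centering
    nz = sd > 0
    centered[:, nz] /= sd[nz]
    return FeatureMatrix(
        values=centered, row_ids=row_ids, feature_names=names, feature_kind=kind
    )
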