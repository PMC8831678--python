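"""Channel-space preprocessing for fNIRS recordings.

Raw intensities are screened by coefficient of variation, cleaned of
superficial physiology using the average of the 0.7 cm proximity channels,
band-pass filtered in the slow hemodynamic band, converted to optical
density changes (log-ratio against a reference window) and block averaged
around task onsets.  A baseline window supplies the noise covariance used
by the inverse solvers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

__all__ = [
    "ChannelTimeSeries",
    "NoiseModel",
    "reject_by_cv",
    "to_delta_od",
    "regress_superficial",
    "bandpass",
    "block_average",
    "estimate_noise",
    "run_chain",
]


@dataclass
class ChannelTimeSeries:
    """Channels x time data with montage bookkeeping.

    ``values`` holds raw intensity (arbitrary units) or unitless optical
    density changes, depending on pipeline stage.  ``channel_ids`` index
    into the montage channel table.  ``events`` is a list of (onset_s,
    duration_s) task blocks; ``baseline_window`` is (t_start_s, t_end_s)
    relative to the recording start.
    """

    values: np.ndarray
    sampling_rate: float
    channel_ids: np.ndarray
    wavelength: float | None = None
    events: list = field(default_factory=list)
    baseline_window: tuple | None = None
    t0: float = 0.0     # time (s) of the first sample

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_times) / self.sampling_rate

    def copy_with(self, **kw) -> "ChannelTimeSeries":
        if "values" in kw:
            kw["values"] = np.asarray(kw["values"], dtype=float)
        return replace(self, **kw)

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite sample in time series")
        dur = self.n_times / self.sampling_rate
        for onset, duration in self.events:
            if onset - self.t0 < 0 or onset + duration - self.t0 > dur:
                raise ValueError("event outside the recording")


@dataclass
class NoiseModel:
    """Channel noise covariance and its inverse (precision)."""

    covariance: np.ndarray
    precision: np.ndarray
    estimation_window: tuple | None = None

    def validate(self, tol: float = 1e-6) -> None:
        c, p = self.covariance, self.precision
        if not np.allclose(c, c.T, atol=tol):
            raise ValueError("covariance not symmetric")
        eye = p @ c
        if not np.allclose(eye, np.eye(c.shape[0]), atol=1e-5 * max(1.0, np.abs(eye).max())):
            raise ValueError("precision is not the inverse of the covariance")


def reject_by_cv(raw: ChannelTimeSeries, cv_threshold: float = 0.08):
    """Reject channels whose std exceeds ``cv_threshold`` of the signal mean.

    Operates on raw (strictly positive) intensities.  Returns the kept
    series and the rejected channel ids.
    """
    v = raw.values
    if np.any(v <= 0):
        raise ValueError("coefficient-of-variation screening requires positive intensities")
    cv = v.std(axis=1) / v.mean(axis=1)
    keep = cv <= cv_threshold
    if not np.any(keep):
        raise ValueError("all channels rejected by the CV screen")
    kept = raw.copy_with(values=v[keep], channel_ids=raw.channel_ids[keep])
    return kept, raw.channel_ids[~keep]


def to_delta_od(raw: ChannelTimeSeries, reference_window: tuple | None = None) -> ChannelTimeSeries:
    """Convert intensity to optical-density change: dOD = -log(I / I_ref).

    ``I_ref`` is the per-channel mean over ``reference_window`` (defaults to
    the series' baseline window, else the whole recording).  Absorption
    increases (intensity drops) give positive dOD.
    """
    v = raw.values
    if np.any(v <= 0):
        bad = raw.channel_ids[np.any(v <= 0, axis=1)]
        raise ValueError(f"nonpositive intensity in channels {bad.tolist()}")
    win = reference_window or raw.baseline_window
    if win is None:
        ref = v.mean(axis=1)
    else:
        t = raw.times
        m = (t >= win[0]) & (t <= win[1])
        if not np.any(m):
            raise ValueError("reference window contains no samples")
        ref = v[:, m].mean(axis=1)
    od = -np.log(v / ref[:, None])
    return raw.copy_with(values=od)


def regress_superficial(data: ChannelTimeSeries, proximity_ids) -> ChannelTimeSeries:
    """Regress the proximity-channel average out of every long channel.

    The single regressor is the mean of all 0.7 cm proximity channels; each
    long channel has its OLS fit (regressor plus intercept) subtracted, with
    the channel mean added back so the DC level survives for later
    log-ratio conversion.  Proximity channels are passed through unchanged.
    """
    prox_ids = np.asarray(list(proximity_ids), dtype=int)
    mask = np.isin(data.channel_ids, prox_ids)
    if not np.any(mask):
        raise ValueError("no proximity channels present for superficial regression")
    g = data.values[mask].mean(axis=0)
    gc = g - g.mean()
    denom = float(gc @ gc)
    out = data.values.copy()
    for i in np.flatnonzero(~mask):
        y = data.values[i]
        mean = y.mean()
        if denom > 0:
            beta = float((y - mean) @ gc) / denom
            out[i] = y - beta * gc
    return data.copy_with(values=out)


def bandpass(
    data: ChannelTimeSeries,
    low_hz: float = 0.01,
    high_hz: float = 0.1,
    order: int = 3,
    preserve_mean: bool = False,
) -> ChannelTimeSeries:
    """Zero-phase (forward-backward) Butterworth band-pass; DC removed.

    With ``preserve_mean=True`` the channel mean is added back after
    filtering the fluctuation — used on raw intensities inside the chain so
    they stay positive for the later log-ratio step.
    """
    nyq = data.sampling_rate / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(f"band ({low_hz}, {high_hz}) Hz outside (0, {nyq}) Hz")
    b, a = signal.butter(order, [low_hz / nyq, high_hz / nyq], btype="band")
    mean = data.values.mean(axis=1, keepdims=True)
    filt = signal.filtfilt(b, a, data.values - mean, axis=1)
    return data.copy_with(values=filt + mean if preserve_mean else filt)


def block_average(data: ChannelTimeSeries, pre_s: float, post_s: float) -> ChannelTimeSeries:
    """Epoch around event onsets, baseline-correct, and average epochs.

    Each epoch spans [-pre_s, post_s] around an onset and is corrected by
    its own mean over [-pre_s, 0].  The returned series has ``t0 = -pre_s``
    and a single pseudo-event at time 0.
    """
    if not data.events:
        raise ValueError("no events to block average")
    fs = data.sampling_rate
    n_pre = int(round(pre_s * fs))
    n_post = int(round(post_s * fs))
    epochs = []
    for onset, _ in data.events:
        i0 = int(round((onset - data.t0) * fs))
        if i0 - n_pre < 0 or i0 + n_post + 1 > data.n_times:
            raise ValueError("event window outside the recording")
        seg = data.values[:, i0 - n_pre : i0 + n_post + 1]
        base = seg[:, : n_pre + 1].mean(axis=1, keepdims=True) if n_pre > 0 else 0.0
        epochs.append(seg - base)
    avg = np.mean(epochs, axis=0)
    return data.copy_with(
        values=avg,
        t0=-pre_s,
        events=[(0.0, 0.0)],
        baseline_window=(-pre_s, 0.0),
    )


def estimate_noise(
    data: ChannelTimeSeries,
    window: tuple | None = None,
    ridge: float = 0.05,
    diagonal_only: bool = True,
) -> NoiseModel:
    """Estimate the channel noise covariance from a baseline window.

    Default is the diagonal sample variance with ``ridge`` x mean-variance
    loading — robust for short baselines, and the depth weighting only uses
    the diagonal of A' Sigma_d A.  Set ``diagonal_only=False`` for the full
    sample covariance (requires a window of at least 2x channels samples
    unless ridge > 0).
    """
    win = window or data.baseline_window
    if win is None:
        seg = data.values
    else:
        t = data.times
        m = (t >= win[0]) & (t <= win[1])
        if not np.any(m):
            raise ValueError("noise window contains no samples")
        seg = data.values[:, m]
    n_ch, n_t = seg.shape
    if not diagonal_only and n_t < 2 * n_ch and ridge <= 0:
        raise ValueError("window too short for a full covariance without ridge loading")
    seg = seg - seg.mean(axis=1, keepdims=True)
    if diagonal_only:
        cov = np.diag(seg.var(axis=1, ddof=1) if n_t > 1 else np.zeros(n_ch))
    else:
        cov = seg @ seg.T / max(n_t - 1, 1)
    load = ridge * np.trace(cov) / n_ch if np.trace(cov) > 0 else ridge
    if load == 0 and np.all(np.diag(cov) == 0):
        load = 1.0      # zero-signal degenerate case: pure loading scale
    cov = cov + load * np.eye(n_ch)
    try:
        prec = np.linalg.inv(cov)
    except np.linalg.LinAlgError as err:
        raise ValueError("noise covariance singular after loading") from err
    model = NoiseModel(covariance=cov, precision=prec, estimation_window=win)
    model.validate()
    return model


def run_chain(
    raw: ChannelTimeSeries,
    proximity_ids,
    cv_threshold: float = 0.08,
    band=(0.01, 0.1),
    order: int = 3,
    pre_s: float = 10.0,
    post_s: float = 30.0,
    superficial_regression: bool = True,
):
    """Full preprocessing chain in the fixed order:

    CV rejection -> superficial regression -> band-pass -> dOD -> block
    average.  Returns ``(block_averaged_dod, rejected_ids)``.
    """
    kept, rejected = reject_by_cv(raw, cv_threshold)
    if superficial_regression:
        kept = regress_superficial(kept, proximity_ids)
    kept = bandpass(kept, band[0], band[1], order, preserve_mean=True)
    od = to_delta_od(kept)
    avg = block_average(od, pre_s, post_s)
    return avg, rejected
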