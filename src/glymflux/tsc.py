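"""Neck time-signal-curve pipeline.

Starts from per-structure curves already extracted from the neck DCE
images: percent change to baseline, normalization to the peak CSF
signal, trailing moving-average smoothing, and group drainage-strength
comparison (the cauterization model reduces deep-cervical-node drainage
by roughly 80% on this readout).
"""

from __future__ import annotations

import numpy as np

from .containers import Tsc

__all__ = [
    "percent_change",
    "normalize_to_peak_csf",
    "moving_average",
    "drainage_reduction",
]


def percent_change(
    series_values: np.ndarray,
    n_baseline: int,
    times: np.ndarray | None = None,
    label: str = "",
) -> Tsc:
    """Percent signal change to baseline.

    value_t = 100 * (S_t - mean(S_0..S_{n_baseline-1})) / mean(...).
    The acquisition protocol collects five baseline scans; any
    ``n_baseline >= 1`` with a positive baseline mean is accepted.
    """
    values = np.asarray(series_values, dtype=float)
    if n_baseline < 1:
        raise ValueError("n_baseline must be at least 1")
    if n_baseline > len(values):
        raise ValueError("n_baseline exceeds series length")
    s0 = float(values[:n_baseline].mean())
    if s0 <= 0:
        raise ValueError(f"baseline mean must be positive; got {s0}")
    if times is None:
        times = np.arange(len(values), dtype=float)
    return Tsc(
        times=times,
        values=100.0 * (values - s0) / s0,
        label=label,
        normalization="baseline",
    )


def normalize_to_peak_csf(tsc: Tsc, csf_tsc: Tsc) -> Tsc:
    """Express a curve as percent of the peak CSF signal.

    The CSF curve itself normalizes to a peak of exactly 100%; common
    rescaling of both curves leaves the result unchanged.
    """
    if len(tsc.times) != len(csf_tsc.times) or not np.allclose(
        tsc.times, csf_tsc.times
    ):
        raise ValueError("curve and CSF reference must share one time grid")
    peak = float(np.max(csf_tsc.values))
    if peak <= 0:
        raise ValueError(f"CSF peak must be positive; got {peak}")
    return Tsc(
        times=tsc.times.copy(),
        values=100.0 * tsc.values / peak,
        label=tsc.label,
        normalization="peak_csf",
    )


def moving_average(tsc: Tsc, window: int = 2) -> Tsc:
    """Trailing moving average over ``window`` consecutive points.

    Output length is ``len - window + 1``; output times are the
    trailing edge of each window, so monotone uptake curves stay
    monotone. ``window=1`` is the identity.
    """
    if window < 1:
        raise ValueError("window must be at least 1")
    n = len(tsc.values)
    if window > n:
        raise ValueError(f"window {window} exceeds curve length {n}")
    kernel = np.ones(window) / window
    values = np.convolve(tsc.values, kernel, mode="valid")
    return Tsc(
        times=tsc.times[window - 1 :].copy(),
        values=values,
        label=tsc.label,
        normalization=tsc.normalization,
    )


def _group_mean_curve(group: list[Tsc]) -> tuple[np.ndarray, np.ndarray]:
    times = group[0].times
    for t in group[1:]:
        if len(t.times) != len(times) or not np.allclose(t.times, times):
            raise ValueError("all curves in a group must share one time grid")
    return times, np.mean([t.values for t in group], axis=0)


def drainage_reduction(
    reference_group: list[Tsc],
    test_group: list[Tsc],
    metric: str = "auc",
) -> float:
    """Percent reduction of drainage strength in the test group.

    100 * (1 - M_test / M_ref) where M is, per ``metric``:
    "auc" (default) the trapezoidal area under the group-mean curve,
    "peak" its maximum, or "terminal" its final value. A test group at
    0.2x the reference amplitude therefore reads 80%.
    """
    if not reference_group or not test_group:
        raise ValueError("both groups must be non-empty")
    t_ref, ref = _group_mean_curve(reference_group)
    t_test, test = _group_mean_curve(test_group)
    if len(t_ref) != len(t_test) or not np.allclose(t_ref, t_test):
        raise ValueError("reference and test groups must share one time grid")
    if metric == "auc":
        m_ref = float(np.trapezoid(ref, t_ref))
        m_test = float(np.trapezoid(test, t_test))
    elif metric == "peak":
        m_ref, m_test = float(ref.max()), float(test.max())
    elif metric == "terminal":
        m_ref, m_test = float(ref[-1]), float(test[-1])
    else:
        raise ValueError(f"unknown metric {metric!r}; use auc, peak, or terminal")
    if m_ref <= 0:
        raise ValueError(f"reference {metric} must be positive; got {m_ref}")
    return 100.0 * (1.0 - m_test / m_ref)
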