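"""ICP waveform summaries and two-group inference.

Mean intracranial pressure is taken over the first stable 60-second
window of a recording (stability judged by rolling 5-s standard
deviations against the final minute of the trace). Group comparisons
use Welch's two-sample t test with the Welch-Satterthwaite degrees of
freedom and a confidence interval on the mean difference; families of
p-values are adjusted by the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import IcpRecording

__all__ = [
    "MeanIcpResult",
    "WelchResult",
    "mean_icp",
    "welch_test",
    "bh_fdr",
]


@dataclass
class MeanIcpResult:
    mean_mmhg: float
    window_start_s: float
    window_end_s: float


@dataclass
class WelchResult:
    mean_a: float
    mean_b: float
    mean_difference: float  # mean_a - mean_b, mmHg in the ICP use
    ci_low: float
    ci_high: float
    confidence: float
    t_statistic: float
    df: float
    p_value: float

    def __post_init__(self) -> None:
        if np.isfinite(self.ci_low) and not (
            self.ci_low - 1e-12 <= self.mean_difference <= self.ci_high + 1e-12
        ):
            raise ValueError("confidence interval does not bracket the difference")


def mean_icp(
    rec: IcpRecording,
    window_s: float = 60.0,
    block_s: float = 5.0,
    stability_factor: float = 2.0,
) -> MeanIcpResult:
    """Mean pressure over the first stable ``window_s`` seconds.

    The recording is cut into ``block_s`` blocks; the reference spread
    is the standard deviation of the final ``window_s`` of the trace
    (pulsatile by nature, so never near zero on real data). The window
    used is the first run of blocks spanning ``window_s`` whose every
    block SD is at most ``stability_factor`` times the reference -
    settling transients after catheter connection inflate early block
    SDs and are skipped.
    """
    if rec.duration < window_s:
        raise ValueError(
            f"recording lasts {rec.duration:.1f} s, shorter than the "
            f"{window_s:.0f} s analysis window"
        )
    nb = int(round(rec.fs * block_s))
    n_blocks = len(rec.samples) // nb
    blocks = rec.samples[: n_blocks * nb].reshape(n_blocks, nb)
    block_sd = blocks.std(axis=1)

    n_ref = int(round(rec.fs * window_s))
    ref_sd = float(rec.samples[-n_ref:].std())
    threshold = stability_factor * max(ref_sd, 1e-12)

    blocks_per_window = int(round(window_s / block_s))
    stable = block_sd <= threshold
    for start in range(n_blocks - blocks_per_window + 1):
        if stable[start : start + blocks_per_window].all():
            i0 = start * nb
            i1 = i0 + blocks_per_window * nb
            return MeanIcpResult(
                mean_mmhg=float(rec.samples[i0:i1].mean()),
                window_start_s=i0 / rec.fs,
                window_end_s=i1 / rec.fs,
            )
    raise ValueError(
        f"no stable {window_s:.0f} s window found: rolling {block_s:.0f} s SD "
        f"never stayed below {threshold:.3g} mmHg for a full window"
    )


def _summary(group) -> tuple[float, float, int]:
    if isinstance(group, tuple) and len(group) == 3:
        mean, sd, n = group
        if n < 2:
            raise ValueError("each group needs n >= 2")
        if sd < 0:
            raise ValueError("sd must be non-negative")
        return float(mean), float(sd), int(n)
    samples = np.asarray(group, dtype=float)
    if samples.ndim != 1 or len(samples) < 2:
        raise ValueError("each group needs at least 2 samples")
    return float(samples.mean()), float(samples.std(ddof=1)), len(samples)


def welch_test(group_a, group_b, confidence: float = 0.95) -> WelchResult:
    """Welch's two-sample t test with confidence interval.

    Groups may be raw sample arrays or ``(mean, sd, n)`` summary
    tuples; both routes agree to machine precision. The difference is
    ``mean_a - mean_b``; df follows Welch-Satterthwaite. With both
    spreads zero and equal means the t statistic is undefined and
    reported as NaN with p = 1.
    """
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    mean_a, sd_a, n_a = _summary(group_a)
    mean_b, sd_b, n_b = _summary(group_b)
    diff = mean_a - mean_b
    va, vb = sd_a**2 / n_a, sd_b**2 / n_b
    se = np.sqrt(va + vb)
    if se == 0:
        # degenerate: no variance in either group
        t_stat = np.nan if diff == 0 else np.inf * np.sign(diff)
        return WelchResult(
            mean_a=mean_a,
            mean_b=mean_b,
            mean_difference=diff,
            ci_low=diff,
            ci_high=diff,
            confidence=confidence,
            t_statistic=float(t_stat),
            df=float(n_a + n_b - 2),
            p_value=1.0 if diff == 0 else 0.0,
        )
    df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    t_stat = diff / se
    p = 2.0 * stats.t.sf(abs(t_stat), df)
    half = stats.t.ppf(1.0 - (1.0 - confidence) / 2.0, df) * se
    return WelchResult(
        mean_a=mean_a,
        mean_b=mean_b,
        mean_difference=diff,
        ci_low=diff - half,
        ci_high=diff + half,
        confidence=confidence,
        t_statistic=float(t_stat),
        df=float(df),
        p_value=float(p),
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    q_(i) = min over j >= i of p_(j) * m / j, capped at 1, returned in
    the input order. Idempotent and monotone in the input ranks.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1D")
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out
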