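"""Phase and amplitude resetting of bioluminescence circadian rhythms.

Cells carrying a PER2-promoter luciferase reporter are synchronized with
dexamethasone at staggered times, so plate wells oscillate at several distinct
circadian phases. A cold exposure (the recording gap, since plates leave the
readers) may reset the clock: after rewarming, previously staggered profiles
collapse onto a common phase. Resetting is quantified with

* phase shift, as a percentage of the period:
  ``[(peak_t + trough_t)_test - (peak_t + trough_t)_control] / (2 * period)``
  using the second peak after the anchor (start of the cold window for short
  exposures, end for day-long ones) and its subsequent trough;
* amplitude fold change: ``log2[(peak - trough)_test / (peak - trough)_ctrl]``;
* collapse of the spread of peak times, tested as a variance difference with
  the Brown-Forsythe (median-centered Levene) test, Holm-Bonferroni adjusted.

Signals are baseline-detrended with a centered 24 h moving average and scaled
to a genotype-matched control mean profile so pre-cold amplitudes agree.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal, stats

from ._stats import holm_adjust


@dataclass
class WellProfile:
    """One plate well's bioluminescence time course at fixed sampling.

    Samples inside ``cold_window`` are NaN (plates out of the reader), never
    zero. ``is_control`` marks wells that stayed at 37 C throughout.
    """

    well_id: str
    time_h: np.ndarray
    signal: np.ndarray
    genotype: str = "WT"
    phase_group: str = "a"
    cold_window: tuple[float, float] | None = None
    is_control: bool = False

    def __post_init__(self):
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time_h.size != self.signal.size:
            raise ValueError("time and signal must have equal length")
        if np.any(np.diff(self.time_h) <= 0):
            raise ValueError("time must be strictly increasing")

    @property
    def dt_h(self) -> float:
        return float(np.median(np.diff(self.time_h)))

    def masked(self) -> np.ndarray:
        return np.isnan(self.signal)


@dataclass(frozen=True)
class PeakTroughPair:
    peak_time_h: float
    trough_time_h: float
    peak_signal: float
    trough_signal: float

    def __post_init__(self):
        if self.trough_time_h <= self.peak_time_h:
            raise ValueError("trough must follow the peak")


def _moving_average_nan(x: np.ndarray, win: int) -> np.ndarray:
    """Centered moving average ignoring NaNs, edges padded by reflection."""
    half = win // 2
    xp = np.pad(x, half, mode="reflect")
    vals = np.where(np.isnan(xp), 0.0, xp)
    cnt = (~np.isnan(xp)).astype(float)
    kernel = np.ones(win)
    num = np.convolve(vals, kernel, mode="valid")
    den = np.convolve(cnt, kernel, mode="valid")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    return out[: x.size] if out.size > x.size else out


def detrend(profile: WellProfile, baseline_window_h: float = 24.0) -> WellProfile:
    """Subtract a centered 24 h moving-average baseline.

    Masked (cold-window) samples are bridged by linear interpolation before
    the moving average is taken, so the gap does not drag the neighbouring
    baseline; they are re-masked in the output.
    """
    span = profile.time_h[-1] - profile.time_h[0]
    if span < 2 * baseline_window_h:
        raise ValueError("need at least 48 h of recording to detrend")
    win = int(round(baseline_window_h / profile.dt_h))
    win += win % 2 == 0  # odd window keeps the average centered
    y = profile.signal
    gap = np.isnan(y)
    filled = y.copy()
    if gap.any():
        filled[gap] = np.interp(
            profile.time_h[gap], profile.time_h[~gap], y[~gap]
        )
    baseline = _moving_average_nan(filled, win)
    out = np.where(gap, np.nan, filled - baseline)
    return replace(profile, signal=out)


def _peak_to_trough(x: np.ndarray) -> float:
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("empty segment")
    return float(x.max() - x.min())


def scale_to_control(
    profile: WellProfile,
    control_mean: WellProfile,
    precold_end_h: float | None = None,
) -> tuple[WellProfile, float]:
    """Scale a profile so its pre-cold peak-to-trough amplitude matches control.

    ``precold_end_h`` defaults to the profile's cold-window start (controls
    must then pass it explicitly). Returns the scaled profile and the factor.
    """
    if precold_end_h is None:
        if profile.cold_window is None:
            raise ValueError("no cold window; pass precold_end_h explicitly")
        precold_end_h = profile.cold_window[0]
    if precold_end_h - profile.time_h[0] < 24.0:
        raise ValueError("pre-cold segment must span at least one period")
    pre = profile.time_h < precold_end_h
    pre_c = control_mean.time_h < precold_end_h
    amp = _peak_to_trough(profile.signal[pre])
    amp_ref = _peak_to_trough(control_mean.signal[pre_c])
    if amp == 0:
        raise ValueError("flat pre-cold profile cannot be scaled")
    factor = amp_ref / amp
    return replace(profile, signal=profile.signal * factor), factor


def _refine_extremum(
    t: np.ndarray, y: np.ndarray, i: int, finite: np.ndarray, half_width_h: float
) -> tuple[float, float]:
    """Sub-sample extremum location by a quadratic fit around sample i.

    Fitting the raw signal over about a quarter period averages the noise
    down; the vertex of the parabola gives time and height. Falls back to
    the discrete sample when the fit degenerates or runs out of the window.
    """
    win = finite & (np.abs(t - t[i]) <= half_width_h)
    if win.sum() < 5:
        return float(t[i]), float(y[i])
    c = np.polyfit(t[win] - t[i], y[win], 2)
    if c[0] == 0:
        return float(t[i]), float(y[i])
    dt = -c[1] / (2 * c[0])
    if abs(dt) > half_width_h:
        return float(t[i]), float(y[i])
    return float(t[i] + dt), float(c[2] - c[1] ** 2 / (4 * c[0]))


def find_peaks(
    profile: WellProfile,
    anchor_time_h: float,
    n_peaks: int = 2,
    prominence_frac: float = 0.2,
    smooth_samples: int = 5,
    refine_half_width_h: float = 6.0,
) -> list[PeakTroughPair]:
    """Locate ordered peak/subsequent-trough pairs after an anchor time.

    The detrended signal is lightly smoothed (moving average over
    ``smooth_samples``), peaks require a prominence of ``prominence_frac``
    times the pre-anchor peak-to-trough amplitude, and masked samples can
    never host a peak. Each detected extremum is refined to sub-sample
    precision by a local quadratic fit of the raw signal over
    ``+-refine_half_width_h`` (about a quarter period by default). Returns
    the first ``n_peaks`` peaks after the anchor, each paired with the first
    subsequent trough; ties go to the earliest sample. Raises if fewer than
    ``n_peaks`` peaks (with troughs) are found.
    """
    t, y = profile.time_h, profile.signal.copy()
    finite = ~np.isnan(y)
    ys = y.copy()
    if smooth_samples > 1:
        ys[finite] = _moving_average_nan(np.where(finite, y, np.nan), smooth_samples)[finite]
    pre = (t < anchor_time_h) & finite
    if pre.sum() >= 2:
        # robust pre-anchor amplitude: quantile span of the smoothed trace,
        # insensitive to single noise excursions
        lo, hi = np.quantile(ys[pre], [0.025, 0.975])
        ref_amp = hi - lo
    else:
        ref_amp = float(np.nanmax(np.abs(ys)))
    prom = prominence_frac * ref_amp

    # peaks can never sit in the masked gap: detect per contiguous segment
    pk_list, tr_list = [], []
    idx = np.flatnonzero(finite)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    for seg in np.split(idx, breaks + 1):
        if seg.size < 3:
            continue
        p, _ = signal.find_peaks(ys[seg], prominence=prom)
        q, _ = signal.find_peaks(-ys[seg], prominence=prom)
        pk_list.append(seg[p])
        tr_list.append(seg[q])
    pk = np.concatenate(pk_list) if pk_list else np.empty(0, int)
    tr = np.concatenate(tr_list) if tr_list else np.empty(0, int)
    pk = pk[t[pk] >= anchor_time_h]

    pairs: list[PeakTroughPair] = []
    for i in pk:
        later = tr[tr > i]
        if later.size == 0:
            continue
        j = later[0]
        pt, pv = _refine_extremum(t, y, i, finite, refine_half_width_h)
        tt, tv = _refine_extremum(t, y, j, finite, refine_half_width_h)
        if tt <= pt:  # refinement crossed over; keep discrete landmarks
            pt, pv, tt, tv = float(t[i]), float(y[i]), float(t[j]), float(y[j])
        pairs.append(PeakTroughPair(pt, tt, pv, tv))
        if len(pairs) == n_peaks:
            break
    if len(pairs) < n_peaks:
        raise ValueError(
            f"found only {len(pairs)} peak/trough pairs after t={anchor_time_h} h"
        )
    return pairs


def phase_shift(
    test: PeakTroughPair, control: PeakTroughPair, period_h: float
) -> float:
    """Signed phase shift as a percentage of the period (positive = delay).

    ``[(peak_t + trough_t)_test - (peak_t + trough_t)_ctrl] / (2 * period)``,
    wrapped into (-50%, +50%] because phase is circular.
    """
    raw = (
        (test.peak_time_h + test.trough_time_h)
        - (control.peak_time_h + control.trough_time_h)
    ) / (2.0 * period_h) * 100.0
    wrapped = (raw + 50.0) % 100.0 - 50.0
    return 50.0 if wrapped == -50.0 and raw > 0 else float(wrapped)


def amplitude_fc(test: PeakTroughPair, control: PeakTroughPair) -> float:
    """log2 of the peak-to-trough amplitude ratio, test over control."""
    num = test.peak_signal - test.trough_signal
    den = control.peak_signal - control.trough_signal
    if den <= 0:
        raise ValueError("control peak-to-trough amplitude must be positive")
    if num <= 0:
        raise ValueError("test peak-to-trough amplitude must be positive")
    return float(np.log2(num / den))


def variance_alignment_test(
    peak_times: dict[str, np.ndarray],
    comparisons: list[tuple[str, str]],
) -> pd.DataFrame:
    """Brown-Forsythe variance-equality tests over a family of comparisons.

    ``peak_times`` maps a condition label (e.g. 'WT:cold', 'KO:37C') to the
    per-well times of the landmark peak. Each requested pair is tested with
    the median-centered Levene statistic; p-values are Holm-Bonferroni
    adjusted across the whole family, matching how the well-spread boxplots
    are annotated.
    """
    rows = []
    for a, b in comparisons:
        xa, xb = np.asarray(peak_times[a]), np.asarray(peak_times[b])
        if xa.size < 3 or xb.size < 3:
            raise ValueError("each group needs >=3 wells")
        f, p = stats.levene(xa, xb, center="median")
        rows.append({"group_a": a, "group_b": b, "stat": float(f), "p": float(p)})
    out = pd.DataFrame(rows)
    out["p_adj"] = holm_adjust(out["p"].to_numpy())
    return out


def threshold_tests(
    values_by_group: dict[str, np.ndarray],
    threshold: float,
    two_directions: bool = True,
) -> pd.DataFrame:
    """One-sided one-sample t-tests for group means exceeding a threshold.

    Used for phase shifts against +-5% of the period and log2 amplitude fold
    changes against +-log2(1.4). The test direction follows the sign of each
    group's observed mean (strict exceedance: a mean sitting exactly at the
    threshold is not significant); the family of groups is Holm-Bonferroni
    adjusted.
    """
    rows = []
    for name, vals in values_by_group.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size < 3:
            raise ValueError("each group needs >=3 wells")
        mean = vals.mean()
        thr = float(np.sign(mean)) * threshold if two_directions else threshold
        alternative = "greater" if thr >= 0 else "less"
        res = stats.ttest_1samp(vals, thr, alternative=alternative)
        p = float(res.pvalue)
        rows.append(
            {
                "group": name,
                "mean": float(mean),
                "sd": float(vals.std(ddof=1)),
                "n": vals.size,
                "threshold": float(thr),
                "p": float(p),
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = holm_adjust(out["p"].to_numpy())
    out["significant"] = out["p_adj"] < 0.05
    return out


@dataclass
class PeriodAmplitude:
    period_h: float
    amplitude: float
    confidence: float  # autocorrelation at the period lag

    @property
    def reliable(self) -> bool:
        return self.confidence >= 0.2


def period_amplitude(
    profile: WellProfile,
    min_period_h: float = 16.0,
    max_period_h: float = 36.0,
    min_confidence: float = 0.2,
) -> PeriodAmplitude:
    """Estimate free-running period and amplitude of a detrended recording.

    Period comes from the lag of the first autocorrelation maximum in the
    plausible circadian band, refined by parabolic interpolation; amplitude
    is the mean peak-to-trough excursion divided by two. Arrhythmic input
    (autocorrelation below ``min_confidence`` at the candidate lag) raises.
    """
    y = profile.signal[~np.isnan(profile.signal)]
    dt = profile.dt_h
    if y.size * dt < 2 * min_period_h:
        raise ValueError("need at least two full cycles")
    yc = y - y.mean()
    ac = np.correlate(yc, yc, mode="full")[yc.size - 1 :]
    ac = ac / ac[0]
    lo = max(1, int(np.floor(min_period_h / dt)))
    hi = min(ac.size - 2, int(np.ceil(max_period_h / dt)))
    if hi <= lo:
        raise ValueError("recording too short for the circadian band")
    k = lo + int(np.argmax(ac[lo : hi + 1]))
    if ac[k] < min_confidence:
        raise ValueError(
            f"no confident rhythm: autocorrelation {ac[k]:.3f} at candidate period"
        )
    # parabolic refinement around the discrete argmax
    y0, y1, y2 = ac[k - 1], ac[k], ac[k + 1]
    denom = y0 - 2 * y1 + y2
    delta = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    period = (k + float(np.clip(delta, -1, 1))) * dt

    prom = 0.2 * _peak_to_trough(y)
    pk, _ = signal.find_peaks(y, prominence=prom)
    tr, _ = signal.find_peaks(-y, prominence=prom)
    if pk.size == 0 or tr.size == 0:
        raise ValueError("no peaks found for amplitude estimation")
    amp = float((y[pk].mean() - y[tr].mean()) / 2.0)
    return PeriodAmplitude(float(period), amp, float(ac[k]))


def welch_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Welch's t-test (unequal variances), for group comparisons."""
    t, p = stats.ttest_ind(np.asarray(a), np.asarray(b), equal_var=False)
    return float(t), float(p)
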