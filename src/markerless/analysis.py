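"""Outcome metrics and statistics for movement-dynamics studies.

Covers the clinical analysis battery: the between-limb symmetry index,
stance-phase detection and peak extraction, bodyweight normalization, EMG
envelope processing, waveform error analysis (delay + offset alignment),
ROC-based classification, and the paired-comparison machinery (Shapiro-Wilk
gate, paired t / Wilcoxon signed-rank, Benjamini-Hochberg correction,
post-hoc power).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.signal import butter, sosfiltfilt
from statsmodels.stats.multitest import multipletests

#: Between-limb symmetry index above which a functional deficit is predicted.
SYMMETRY_DEFICIT_THRESHOLD = 1.15

GRAVITY_MAG = 9.81  # m/s^2


# ---------------------------------------------------------------------------
# Symmetry and peaks
# ---------------------------------------------------------------------------

@dataclass
class SymmetryMeasurement:
    """Peak values of the involved (e.g. left) and uninvolved limb."""

    a_involved: float
    a_uninvolved: float

    def __post_init__(self):
        if self.a_uninvolved == 0:
            raise ValueError("uninvolved peak must be nonzero")


def symmetry_index(m: SymmetryMeasurement) -> float:
    """1 - (a_involved - a_uninvolved) / a_uninvolved.

    Exceeds one when the involved limb's peak is lower than the uninvolved
    limb's (the expected direction when the involved limb is unloaded).
    Scale-invariant: multiplying both peaks by c > 0 leaves it unchanged.
    """
    return 1.0 - (m.a_involved - m.a_uninvolved) / m.a_uninvolved


def detect_stance(grf_vertical: np.ndarray, frame_rate: float,
                  threshold: float = 0.05, bodyweight: float | None = None,
                  hysteresis: float = 0.8, min_duration: float = 0.05
                  ) -> list[tuple[int, int]]:
    """Stance intervals from a vertical GRF series.

    ``threshold`` is a fraction of bodyweight (default 5% BW); if
    ``bodyweight`` (N) is None the series is assumed already normalized to
    bodyweight fractions.  Hysteresis: stance ends only when the force drops
    below ``hysteresis * threshold``.  Intervals shorter than
    ``min_duration`` seconds are discarded.  Returns [(start, stop)) frame
    index pairs.
    """
    g = np.asarray(grf_vertical, dtype=float)
    if bodyweight is not None:
        g = g / bodyweight
    hi, lo = threshold, hysteresis * threshold
    intervals = []
    inside = False
    start = 0
    for i, v in enumerate(g):
        if not inside and v > hi:
            inside = True
            start = i
        elif inside and v < lo:
            inside = False
            intervals.append((start, i))
    if inside:
        intervals.append((start, len(g)))
    min_frames = int(round(min_duration * frame_rate))
    return [(a, b) for a, b in intervals if b - a >= min_frames]


def peak_in_window(signal: np.ndarray, interval: tuple[int, int],
                   portion: str = "first_half") -> tuple[float, int]:
    """Maximum of a signal over a portion of a stance interval.

    ``portion``: ``first_half`` | ``second_half`` | ``full``.  Ties break
    toward the earliest frame.  Returns (value, frame index).
    """
    a, b = interval
    if a < 0 or b > len(signal):
        raise ValueError("interval outside signal span")
    mid = a + (b - a) // 2
    lo, hi = {"first_half": (a, mid), "second_half": (mid, b), "full": (a, b)}[portion]
    hi = max(hi, lo + 1)
    seg = np.asarray(signal[lo:hi])
    k = int(np.argmax(seg))
    return float(seg[k]), lo + k


def normalize_outcomes(value: np.ndarray, mass: float, height: float | None = None
                       ) -> np.ndarray:
    """Express forces in %BW (height None) or moments in %BW*height."""
    denom = mass * GRAVITY_MAG * (height if height is not None else 1.0)
    return np.asarray(value) / denom * 100.0


# ---------------------------------------------------------------------------
# EMG processing
# ---------------------------------------------------------------------------

def emg_envelope(raw: np.ndarray, fs: float, channel_max: float,
                 band: tuple[float, float] = (30.0, 500.0),
                 lowpass: float = 6.0, order: int = 4) -> np.ndarray:
    """Standard EMG envelope: zero-lag band-pass (30-500 Hz), rectification,
    zero-lag low-pass (6 Hz), then normalization by a supplied channel
    maximum."""
    if fs <= 2 * band[1]:
        raise ValueError(f"sampling rate {fs} Hz too low for a {band[1]} Hz band edge")
    x = np.asarray(raw, dtype=float)
    sos_bp = butter(order, band, btype="bandpass", fs=fs, output="sos")
    x = sosfiltfilt(sos_bp, x)
    x = np.abs(x)
    sos_lp = butter(order, lowpass, fs=fs, output="sos")
    env = sosfiltfilt(sos_lp, x)
    return env / channel_max


# ---------------------------------------------------------------------------
# Waveform error analysis
# ---------------------------------------------------------------------------

@dataclass
class WaveformErrors:
    mae: float
    rmse: float
    mae_percent_range: float
    delay_frames: int
    offset: np.ndarray


def align_and_compare(series_a: np.ndarray, series_b: np.ndarray,
                      max_delay: int = 120) -> WaveformErrors:
    """Errors of b against a after delay + offset alignment.

    The integer delay minimizing the mean (Euclidean) difference is removed,
    the remaining constant offset is subtracted from b, and MAE / RMSE /
    MAE-as-%-of-range are computed on the overlap.  Series may be (T,) or
    (T, D) or (T, M, D) (markers); averaging runs over everything but time.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    a2 = a.reshape(len(a), -1)
    b2 = b.reshape(len(b), -1)
    best, best_d = np.inf, 0
    for d in range(-max_delay, max_delay + 1):
        if d >= 0:
            xa, xb = a2[d:], b2[:len(b2) - d] if d else b2
        else:
            xa, xb = a2[:len(a2) + d], b2[-d:]
        n = min(len(xa), len(xb))
        if n < 2:
            continue
        score = np.mean(np.linalg.norm(xa[:n] - xb[:n], axis=1))
        if score < best - 1e-15:
            best, best_d = score, d
    d = best_d
    if d >= 0:
        xa, xb = a2[d:], b2
    else:
        xa, xb = a2, b2[-d:]
    n = min(len(xa), len(xb))
    xa, xb = xa[:n], xb[:n]
    offset = np.mean(xb - xa, axis=0)
    diff = xb - offset - xa
    mae = float(np.mean(np.abs(diff)))
    rmse = float(np.sqrt(np.mean(diff ** 2)))
    rng = float(np.ptp(xa))
    return WaveformErrors(mae, rmse, 100.0 * mae / rng if rng > 0 else np.nan,
                          d, offset.reshape(a.shape[1:] if a.ndim > 1 else ()))


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

@dataclass
class ClassificationReport:
    auc: float
    threshold: float
    accuracy: float


def roc_analysis(scores: np.ndarray, labels: np.ndarray) -> ClassificationReport:
    """AUC by the rank (Mann-Whitney) statistic with tie correction, plus the
    threshold maximizing TPR - FPR (Youden) and the accuracy there.

    Higher scores are taken to indicate the positive class (label 1).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n1, n0 = int(labels.sum()), int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)  # midranks handle ties
    auc = (ranks[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    # sweep thresholds over the observed scores (predict positive if >= thr)
    cand = np.unique(scores)
    best_j, best_thr, best_acc = -np.inf, cand[0], 0.0
    for thr in cand:
        pred = scores >= thr
        tpr = (pred & labels).sum() / n1
        fpr = (pred & ~labels).sum() / n0
        j = tpr - fpr
        if j > best_j + 1e-12:
            best_j, best_thr = j, thr
            best_acc = float((pred == labels).mean())
    return ClassificationReport(float(auc), float(best_thr), best_acc)


# ---------------------------------------------------------------------------
# Paired comparisons
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    test: str  # 'paired_t' | 'wilcoxon' | 'degenerate'
    p_value: float
    effect_size: float  # Cohen's d_z (t) or rank-biserial r (Wilcoxon)
    shapiro_p: float
    power: float
    p_adjusted: float | None = None


def paired_comparison(x: np.ndarray, y: np.ndarray, alpha: float = 0.05
                      ) -> ComparisonResult:
    """Two-sided paired comparison with a normality gate.

    Differences are tested with Shapiro-Wilk; if p > .05 a paired t test is
    used, otherwise a Wilcoxon signed-rank test.  All-zero differences are a
    degenerate case reported with p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("paired samples of equal length >= 3 required")
    d = y - x
    if np.allclose(d, 0.0):
        return ComparisonResult("degenerate", 1.0, 0.0, 1.0, alpha)
    sh_p = float(stats.shapiro(d).pvalue)
    n = len(d)
    if sh_p > 0.05:
        t = stats.ttest_rel(y, x)
        d_z = float(np.mean(d) / np.std(d, ddof=1))
        power = posthoc_power(abs(d_z), n, alpha, test="paired_t")
        return ComparisonResult("paired_t", float(t.pvalue), d_z, sh_p, power)
    w = stats.wilcoxon(y, x)
    n_eff = np.sum(d != 0)
    r_rb = float(1.0 - 2.0 * w.statistic / (n_eff * (n_eff + 1) / 2))
    d_z = float(np.mean(d) / np.std(d, ddof=1))  # for the power approximation
    power = posthoc_power(abs(d_z), n, alpha, test="wilcoxon")
    return ComparisonResult("wilcoxon", float(w.pvalue), r_rb, sh_p, power)


def adjust_bh(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def compare_battery(pairs: dict[str, tuple[np.ndarray, np.ndarray]],
                    alpha: float = 0.05) -> dict[str, ComparisonResult]:
    """Run paired comparisons for a family of outcomes and BH-adjust the
    p-values across the family."""
    results = {k: paired_comparison(x, y, alpha) for k, (x, y) in pairs.items()}
    keys = list(results)
    adj = adjust_bh([results[k].p_value for k in keys])
    for k, pa in zip(keys, adj):
        results[k].p_adjusted = float(pa)
    return results


def posthoc_power(effect_size: float, n: int, alpha: float = 0.05,
                  test: str = "paired_t") -> float:
    """Post-hoc power of a two-sided one-sample/paired test.

    Paired t: exact, via the noncentral t distribution with noncentrality
    d_z * sqrt(n).  Wilcoxon signed-rank: normal approximation with the
    asymptotic relative efficiency 3/pi (documented as approximate).
    """
    if n < 2:
        raise ValueError("n >= 2 required")
    if test == "paired_t":
        df = n - 1
        nc = effect_size * np.sqrt(n)
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        return float(1 - stats.nct.cdf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))
    if test == "wilcoxon":
        are = 3.0 / np.pi
        nc = effect_size * np.sqrt(n * are)
        zcrit = stats.norm.ppf(1 - alpha / 2)
        return float(stats.norm.cdf(nc - zcrit) + stats.norm.cdf(-nc - zcrit))
    raise ValueError(f"unknown test {test!r}")
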