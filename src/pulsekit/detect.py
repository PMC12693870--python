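"""Derivative-based single-pass event detection.

The detector thresholds the first finite-difference derivative of the raw
trace.  Because a slow baseline varies little between adjacent samples, its
derivative is near zero: differentiation acts as a high-pass operator that
suppresses drift while emphasising the steep ingress/egress slopes of each
bipolar transit pulse.  A pulse appears in the derivative as a
positive-slope lobe followed by a negative-slope lobe (with an optional
trailing positive lobe); the zero crossings of the derivative between and
around the lobes are the raw-signal extrema and the event boundaries.

All stages are vectorised array passes; total work is linear in the trace
length.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigError, DegenerateThresholdError, TraceTooShortError
from .recon import EventFeatures
from .trace import SignalTrace

logger = logging.getLogger(__name__)

#: Scale factor turning a median absolute deviation into a Gaussian sd.
MAD_TO_SD = 0.6745


@dataclass
class DerivativeTrace:
    """First derivative s'[i] (V/s) on the same grid as the source trace."""

    values: np.ndarray
    fs_Sa_s: float
    t_start_s: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ConfigError("derivative values must be finite")


@dataclass(frozen=True)
class DetectorConfig:
    """Derivative-detector settings.

    Either ``threshold_V_s`` (absolute derivative threshold, V/s) or
    ``auto_k`` (multiplier on the robust MAD noise scale of s') must be set;
    an explicit threshold wins.  ``min_lobe_samples`` discards very short
    supra-threshold runs, ``max_gap_s`` bounds the spacing between the paired
    slope lobes of one event, and events closer than ``refractory_s`` are
    merged (keeping the larger peak-to-peak amplitude).
    """

    threshold_V_s: float | None = None
    auto_k: float | None = 5.0
    min_lobe_samples: int = 3
    max_gap_s: float = 2.0e-3
    refractory_s: float = 0.0

    def __post_init__(self) -> None:
        if self.threshold_V_s is None and self.auto_k is None:
            raise ConfigError("either threshold_V_s or auto_k must be set")
        if self.threshold_V_s is not None and not self.threshold_V_s > 0:
            raise ConfigError("threshold_V_s must be positive")
        if self.threshold_V_s is None and not self.auto_k > 0:
            raise ConfigError("auto_k must be positive")
        if self.min_lobe_samples < 1:
            raise ConfigError("min_lobe_samples must be >= 1")
        if not self.max_gap_s > 0:
            raise ConfigError("max_gap_s must be positive")
        if self.refractory_s < 0:
            raise ConfigError("refractory_s must be >= 0")

    @classmethod
    def from_kinematics(
        cls,
        delta_s: float,
        sigma_s: float,
        fs_Sa_s: float,
        threshold_V_s: float | None = None,
        auto_k: float | None = 5.0,
        refractory: bool = True,
    ) -> "DetectorConfig":
        """Scale the structural settings to the expected pulse timing:
        lobe-pair gap 1.5*delta, minimum lobe length sigma/4 (in samples) and
        a delta/2 refractory merge window (disable with ``refractory=False``
        to let broadened pulses over-detect, as unmerged multi-crossing
        detectors do)."""
        return cls(
            threshold_V_s=threshold_V_s,
            auto_k=auto_k,
            min_lobe_samples=max(2, int(round(sigma_s * fs_Sa_s / 4.0))),
            max_gap_s=1.5 * delta_s,
            refractory_s=delta_s / 2.0 if refractory else 0.0,
        )

    def with_(self, **kwargs) -> "DetectorConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class EventLandmarks:
    """Sample-index landmarks of one event.

    ``left_zc_idx``/``right_zc_idx`` are the outermost derivative zero
    crossings enclosing the slope lobes; ``pos_peak_idx``/``neg_peak_idx``
    are the raw-signal extrema (zero crossings between/after the lobes);
    ``deriv_extrema_idx`` holds the derivative's own extremum inside each
    paired lobe.
    """

    left_zc_idx: int
    right_zc_idx: int
    pos_peak_idx: int
    neg_peak_idx: int
    deriv_extrema_idx: tuple[int, int]

    def __post_init__(self) -> None:
        if not self.left_zc_idx < self.right_zc_idx:
            raise ConfigError("left_zc_idx must precede right_zc_idx")
        if not self.pos_peak_idx < self.neg_peak_idx:
            raise ConfigError("pos_peak_idx must precede neg_peak_idx")


@dataclass
class DetectedEvent:
    """One detected bipolar event with landmarks, peak values and features."""

    landmarks: EventLandmarks
    t_pos_s: float
    t_neg_s: float
    v_pos_V: float
    v_neg_V: float
    features: EventFeatures | None = None

    @property
    def t_center_s(self) -> float:
        return 0.5 * (self.t_pos_s + self.t_neg_s)

    def shifted(self, n_samples: int, dt_s: float) -> "DetectedEvent":
        """Return a copy with all indices/times shifted (chunked processing)."""
        lm = self.landmarks
        return DetectedEvent(
            landmarks=EventLandmarks(
                lm.left_zc_idx + n_samples,
                lm.right_zc_idx + n_samples,
                lm.pos_peak_idx + n_samples,
                lm.neg_peak_idx + n_samples,
                (lm.deriv_extrema_idx[0] + n_samples, lm.deriv_extrema_idx[1] + n_samples),
            ),
            t_pos_s=self.t_pos_s + dt_s,
            t_neg_s=self.t_neg_s + dt_s,
            v_pos_V=self.v_pos_V,
            v_neg_V=self.v_neg_V,
            features=self.features,
        )


def compute_derivative(trace: SignalTrace) -> DerivativeTrace:
    """First derivative by finite differences in one pass.

    Central differences at interior points, forward/backward differences at
    the two boundary samples; exact for linear signals everywhere.
    """
    s = trace.samples
    n = s.size
    if n < 3:
        raise TraceTooShortError("derivative needs at least 3 samples")
    fs = trace.fs_Sa_s
    d = np.empty(n)
    d[0] = (s[1] - s[0]) * fs
    d[-1] = (s[-1] - s[-2]) * fs
    d[1:-1] = (s[2:] - s[:-2]) * (fs / 2.0)
    return DerivativeTrace(d, fs, trace.t_start_s)


def auto_threshold(deriv: DerivativeTrace, k: float) -> float:
    """Robust automatic threshold: k times the MAD-based noise scale of s'.

    theta = k * MAD(s') / 0.6745, which estimates k noise standard
    deviations while staying insensitive to sparse large event slopes.
    """
    if not k > 0:
        raise ConfigError("k must be positive")
    v = deriv.values
    mad = float(np.median(np.abs(v - np.median(v))))
    theta = k * mad / MAD_TO_SD
    if theta == 0.0:
        raise DegenerateThresholdError(
            "derivative noise scale is zero (constant or noiseless trace); "
            "set an explicit threshold_V_s"
        )
    return theta


def _runs(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start (inclusive) / end (exclusive) indices of True runs."""
    m = mask.view(np.int8)
    d = np.diff(m)
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.concatenate(([0], starts))
    if mask[-1]:
        ends = np.concatenate((ends, [mask.size]))
    return starts, ends


def _merge_and_trim(centers, dvs, lefts, rights, pos, neg, refractory_s):
    """Single pass over center-sorted candidates.

    Candidates closer than the refractory window (or whose peaks interleave)
    are duplicates of one event: keep the one with the largest peak-to-peak
    amplitude.  Distinct neighbours whose windows merely overlap are both
    kept, with the shared boundary trimmed to the midpoint between the
    earlier event's negative peak and the later one's positive peak — window
    width depends on where the slope tails meet the noise floor, so merging
    on overlap alone would preferentially swallow neighbours of strong
    events.  Returns kept positional indices; ``lefts``/``rights`` are
    trimmed in place.
    """
    keep: list[int] = []
    for i in range(centers.size):
        if keep:
            j = keep[-1]
            duplicate = (centers[i] - centers[j] < refractory_s
                         or pos[i] <= neg[j] + 1)
            if duplicate:
                if dvs[i] > dvs[j]:
                    keep[-1] = i
                continue
            if lefts[i] <= rights[j]:  # distinct events, overlapping windows
                mid = (int(neg[j]) + int(pos[i])) // 2
                rights[j] = min(rights[j], max(mid, neg[j] + 1))
                lefts[i] = min(max(lefts[i], mid + 1), pos[i] - 1)
        keep.append(i)
    return keep


def detect_events(
    deriv: DerivativeTrace,
    raw: SignalTrace,
    cfg: DetectorConfig,
    threshold_V_s: float | None = None,
) -> list[DetectedEvent]:
    """Threshold |s'|, pair slope lobes, extract zero-crossing landmarks.

    Pipeline: (i) maximal runs with |s'| > theta of at least
    ``min_lobe_samples`` samples, each run carrying the sign of s';
    (ii) each adjacent (+, -) run pair within ``max_gap_s`` becomes a
    candidate event — a trailing positive lobe is never consumed, so it can
    serve as the next event's leading lobe or is simply left unpaired;
    (iii) zero crossings of s' locate the raw peaks (between the lobes and
    after the negative lobe); crossing times are linearly interpolated
    between the straddling samples and the nearer integer index is reported
    (ties toward the earlier sample); the event boundaries are the outermost
    zero crossings enclosing the lobes, searched within a ``max_gap_s``
    horizon (capped at the horizon when s' stays one-signed, e.g. under
    drift);
    (iv) events closer than ``refractory_s`` (or with interleaved peaks) are
    merged, keeping the largest peak-to-peak amplitude; distinct neighbours
    with overlapping windows are trimmed at the midpoint so the output
    windows never overlap.

    Events whose lobes or peak crossings touch the trace edges are dropped
    (counted in the log), as are inverted-polarity candidates.
    """
    if deriv.values.size != raw.n:
        raise ConfigError("derivative and raw trace must share the same grid")
    v = deriv.values
    fs = deriv.fs_Sa_s
    t_start = raw.t_start_s

    if threshold_V_s is not None:
        theta = threshold_V_s
    elif cfg.threshold_V_s is not None:
        theta = cfg.threshold_V_s
    else:
        theta = auto_threshold(deriv, cfg.auto_k)
    if not theta > 0:
        raise ConfigError("resolved threshold must be positive")

    mask = np.abs(v) > theta
    if not mask.any():
        return []
    starts, ends = _runs(mask)
    keep = (ends - starts) >= cfg.min_lobe_samples
    starts, ends = starts[keep], ends[keep]
    if starts.size < 2:
        return []
    signs = np.sign(v[starts])

    gap_ok = (starts[1:] - ends[:-1]) / fs <= cfg.max_gap_s
    pair = np.flatnonzero((signs[:-1] > 0) & (signs[1:] < 0) & gap_ok)
    if pair.size == 0:
        return []
    p_start, p_end = starts[pair], ends[pair]
    n_start, n_end = starts[pair + 1], ends[pair + 1]

    # All sign transitions of s' (zeros count as non-positive).
    pos = v > 0
    desc = np.flatnonzero(pos[:-1] & ~pos[1:]) + 1  # + -> <=0 at index j
    asc = np.flatnonzero(~pos[:-1] & pos[1:]) + 1   # <=0 -> + at index j

    n_pairs = pair.size

    # pos peak: first descending crossing at/after the + lobe's end
    i1 = np.searchsorted(desc, p_end, side="left")
    # neg peak: first ascending crossing at/after the - lobe's end
    i2 = np.searchsorted(asc, n_end, side="left")
    valid = (i1 < desc.size) & (i2 < asc.size)
    valid &= p_start > 0
    valid &= n_end < v.size
    if not valid.any():
        logger.info("detect: %d lobe pairs, all dropped at edges", n_pairs)
        return []
    dropped_edge = int(n_pairs - valid.sum())

    # compress all per-candidate arrays to the surviving candidates
    p_start, p_end = p_start[valid], p_end[valid]
    n_start, n_end = n_start[valid], n_end[valid]
    j_pos = desc[i1[valid]]
    j_neg = asc[i2[valid]]

    def cross(j):
        # interpolated crossing between samples j-1 and j; nearest index,
        # ties toward the earlier sample
        a = v[j - 1]
        b = v[j]
        frac = a / (a - b)
        t = t_start + (j - 1 + frac) / fs
        near = j - 1 + (frac > 0.5)
        return t, near

    t_posc, pos_idx = cross(j_pos)
    t_negc, neg_idx = cross(j_neg)

    # Event boundaries: the outermost zero crossings enclosing the lobes,
    # searched within a max_gap_s horizon.  Under baseline drift s' can stay
    # one-signed for long stretches, so an uncapped search would wander into
    # a neighbouring event; the horizon cap keeps windows local.
    gap_n = max(1, int(round(cfg.max_gap_s * fs)))
    left_cap = p_start - gap_n
    right_cap = n_end + gap_n
    i0 = np.searchsorted(asc, p_start, side="right") - 1
    have_l = i0 >= 0
    left_idx = np.where(have_l, np.maximum(asc[np.maximum(i0, 0)] - 1, left_cap),
                        left_cap)
    i3 = np.searchsorted(desc, j_neg + 1, side="left")
    have_r = i3 < desc.size
    right_idx = np.where(have_r,
                         np.minimum(desc[np.minimum(i3, desc.size - 1)], right_cap),
                         right_cap)
    left_idx = np.clip(np.minimum(left_idx, pos_idx - 1), 0, None)
    right_idx = np.clip(np.maximum(right_idx, neg_idx + 1), None, v.size - 1)

    v_pos = raw.samples[pos_idx]
    v_neg = raw.samples[neg_idx]
    polarity_ok = (pos_idx < neg_idx) & (v_pos > v_neg) & (left_idx < right_idx)
    n_inverted = int(polarity_ok.size - polarity_ok.sum())
    if not polarity_ok.any():
        return []
    arrays = (p_start, p_end, n_start, n_end, pos_idx, neg_idx, left_idx,
              right_idx, t_posc, t_negc, v_pos, v_neg)
    (p_start, p_end, n_start, n_end, pos_idx, neg_idx, left_idx, right_idx,
     t_posc, t_negc, v_pos, v_neg) = (a[polarity_ok] for a in arrays)

    centers = 0.5 * (t_posc + t_negc)
    order = np.argsort(centers, kind="stable")
    arrays = (p_start, p_end, n_start, n_end, pos_idx, neg_idx, left_idx,
              right_idx, t_posc, t_negc, v_pos, v_neg, centers)
    (p_start, p_end, n_start, n_end, pos_idx, neg_idx, left_idx, right_idx,
     t_posc, t_negc, v_pos, v_neg, centers) = (a[order] for a in arrays)

    kept = _merge_and_trim(centers, v_pos - v_neg, left_idx, right_idx,
                           pos_idx, neg_idx, cfg.refractory_s)
    n_merged = centers.size - len(kept)

    events: list[DetectedEvent] = []
    for k in kept:
        events.append(
            DetectedEvent(
                landmarks=EventLandmarks(
                    left_zc_idx=int(left_idx[k]),
                    right_zc_idx=int(right_idx[k]),
                    pos_peak_idx=int(pos_idx[k]),
                    neg_peak_idx=int(neg_idx[k]),
                    deriv_extrema_idx=(
                        int(p_start[k] + np.argmax(v[p_start[k]:p_end[k]])),
                        int(n_start[k] + np.argmin(v[n_start[k]:n_end[k]])),
                    ),
                ),
                t_pos_s=float(t_posc[k]),
                t_neg_s=float(t_negc[k]),
                v_pos_V=float(v_pos[k]),
                v_neg_V=float(v_neg[k]),
                features=EventFeatures(
                    dV_V=float(v_pos[k] - v_neg[k]),
                    dt_s=float(t_negc[k] - t_posc[k]),
                ),
            )
        )
    logger.info(
        "detect: theta=%.4g V/s, %d lobe pairs -> %d events "
        "(%d dropped at edges, %d inverted, %d merged)",
        theta, n_pairs, len(events), dropped_edge, n_inverted, n_merged,
    )
    return events


def run_pipeline(
    trace: SignalTrace,
    cfg: DetectorConfig,
) -> list[DetectedEvent]:
    """Full single-pass pipeline: derivative -> threshold -> events+features.

    At most three linear passes over the trace (differencing, threshold
    scale, run/landmark extraction); no step is super-linear in the trace
    length.
    """
    deriv = compute_derivative(trace)
    return detect_events(deriv, trace, cfg)
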