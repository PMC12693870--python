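"""Simple amplitude-thresholding comparator and balanced-threshold tuning.

The reference detector against which the derivative method is benchmarked:
a conventional multi-stage pipeline that (1) estimates and subtracts a slow
baseline with a moving median, (2) marks runs where the detrended signal
exceeds +theta or falls below -theta, and (3) pairs each positive excursion
with the following negative excursion to form one bipolar event.  Every
stage is toggleable so the sensitivity of any comparison to the comparator's
construction can be reported.

Both detectors emit the same :class:`~pulsekit.detect.DetectedEvent` schema,
so the evaluation code treats them symmetrically.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .detect import (
    DetectedEvent,
    DetectorConfig,
    EventLandmarks,
    MAD_TO_SD,
    _runs,
    compute_derivative,
    run_pipeline,
)
from .errors import ConfigError, DegenerateThresholdError
from .recon import EventFeatures
from .sim import SyntheticStream, derive_kinematics
from .trace import SignalTrace

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BaselineConfig:
    """Amplitude-thresholding detector settings.

    ``amp_threshold_V`` (two-sided raw-amplitude threshold) or ``auto_k``
    (multiplier on the MAD noise scale of the detrended trace) must be set.
    ``baseline_window_s`` sets the moving-median drift-estimation window;
    ``detrend=False`` skips drift estimation entirely (only the global median
    is removed), exposing the method's sensitivity to baseline drift.
    ``pairing=False`` switches stage 3 from bipolar run pairing to the
    structure-blind variant common in simple peak-finding pipelines: nearby
    supra-threshold excursions are merged into one event window whose
    extrema become the peaks, without requiring both polarities.
    """

    amp_threshold_V: float | None = None
    auto_k: float | None = 5.0
    baseline_window_s: float = 0.1
    detrend: bool = True
    pairing: bool = True
    min_event_samples: int = 3
    pair_gap_s: float = 2.0e-3

    def __post_init__(self) -> None:
        if self.amp_threshold_V is None and self.auto_k is None:
            raise ConfigError("either amp_threshold_V or auto_k must be set")
        if self.amp_threshold_V is not None and not self.amp_threshold_V > 0:
            raise ConfigError("amp_threshold_V must be positive")
        if self.amp_threshold_V is None and not self.auto_k > 0:
            raise ConfigError("auto_k must be positive")
        if not self.baseline_window_s > 0:
            raise ConfigError("baseline_window_s must be positive")
        if self.min_event_samples < 1:
            raise ConfigError("min_event_samples must be >= 1")
        if not self.pair_gap_s > 0:
            raise ConfigError("pair_gap_s must be positive")

    @classmethod
    def from_kinematics(
        cls,
        delta_s: float,
        sigma_s: float,
        fs_Sa_s: float,
        amp_threshold_V: float | None = None,
        auto_k: float | None = 5.0,
        detrend: bool = True,
        pairing: bool = True,
    ) -> "BaselineConfig":
        return cls(
            amp_threshold_V=amp_threshold_V,
            auto_k=auto_k,
            baseline_window_s=max(0.1, 20.0 * delta_s),
            detrend=detrend,
            pairing=pairing,
            min_event_samples=max(2, int(round(sigma_s * fs_Sa_s / 4.0))),
            pair_gap_s=1.5 * delta_s,
        )

    def with_(self, **kwargs) -> "BaselineConfig":
        return replace(self, **kwargs)


def moving_median(x: np.ndarray, window_samples: int) -> np.ndarray:
    """Decimated moving median: medians of half-window blocks, linearly
    interpolated back to the full grid.  O(N) and faithful for baselines that
    vary slowly relative to the window."""
    n = x.size
    if window_samples > n:
        raise ConfigError("baseline window is longer than the trace")
    block = max(1, window_samples // 2)
    nb = n // block
    if nb < 2:
        return np.full(n, np.median(x))
    med = np.median(x[: nb * block].reshape(nb, block), axis=1)
    centers = (np.arange(nb) + 0.5) * block
    return np.interp(np.arange(n), centers, med)


def baseline_detect(trace: SignalTrace, cfg: BaselineConfig,
                    amp_threshold_V: float | None = None) -> list[DetectedEvent]:
    """Multi-stage amplitude thresholding.

    Stage 1 subtracts the moving-median baseline (or the global median when
    detrending is off); stage 2 marks supra-threshold runs of the detrended
    signal above +theta and below -theta; stage 3 pairs each positive run
    with the adjacent following negative run within ``pair_gap_s``.  Peaks
    are the extremum samples of each run; peak values are read from the raw
    trace at those indices.
    """
    s = trace.samples
    fs = trace.fs_Sa_s
    if cfg.detrend:
        w = int(round(cfg.baseline_window_s * fs))
        base = moving_median(s, w)
    else:
        base = np.median(s)
    x = s - base

    if amp_threshold_V is not None:
        theta = amp_threshold_V
    elif cfg.amp_threshold_V is not None:
        theta = cfg.amp_threshold_V
    else:
        mad = float(np.median(np.abs(x - np.median(x))))
        theta = cfg.auto_k * mad / MAD_TO_SD
        if theta == 0.0:
            raise DegenerateThresholdError(
                "amplitude noise scale is zero; set an explicit amp_threshold_V"
            )
    if not theta > 0:
        raise ConfigError("resolved threshold must be positive")

    mask = (x > theta) | (x < -theta)
    if not mask.any():
        return []
    starts, ends = _runs(mask)
    keep = (ends - starts) >= cfg.min_event_samples
    starts, ends = starts[keep], ends[keep]

    windows: list[tuple[int, int, int, int]] = []  # (ps, pe, ns, ne)
    if cfg.pairing:
        if starts.size < 2:
            return []
        signs = np.sign(x[starts])
        gap_ok = (starts[1:] - ends[:-1]) / fs <= cfg.pair_gap_s
        pair = np.flatnonzero((signs[:-1] > 0) & (signs[1:] < 0) & gap_ok)
        for i in pair:
            windows.append((int(starts[i]), int(ends[i]),
                            int(starts[i + 1]), int(ends[i + 1])))
    else:
        # structure-blind: merge nearby excursions of either polarity into
        # one window; peaks are the window extrema
        if starts.size == 0:
            return []
        gap = (starts[1:] - ends[:-1]) / fs
        brk = np.flatnonzero(gap > cfg.pair_gap_s)
        w_lo = starts[np.concatenate(([0], brk + 1))]
        w_hi = ends[np.concatenate((brk, [starts.size - 1]))]
        for a, b in zip(w_lo, w_hi):
            windows.append((int(a), int(b), int(a), int(b)))

    events: list[DetectedEvent] = []
    for ps, pe, ns, ne in windows:
        if ps == 0 or ne == s.size:
            continue  # edge events are discarded, as in the derivative path
        pos_idx = ps + int(np.argmax(x[ps:pe]))
        neg_idx = ns + int(np.argmin(x[ns:ne]))
        if pos_idx >= neg_idx:
            if not cfg.pairing:
                # unpaired windows may have extrema in either order; keep the
                # window but report the extrema in time order
                pos_idx, neg_idx = min(pos_idx, neg_idx), max(pos_idx, neg_idx)
                if pos_idx == neg_idx:
                    continue
            else:
                continue
        t_pos = trace.t_start_s + pos_idx / fs
        t_neg = trace.t_start_s + neg_idx / fs
        v_pos = float(s[pos_idx])
        v_neg = float(s[neg_idx])
        dv = float(x[pos_idx] - x[neg_idx])  # detrended peak-to-peak
        feats = EventFeatures(dV_V=dv, dt_s=t_neg - t_pos) if dv > 0 else None
        events.append(
            DetectedEvent(
                landmarks=EventLandmarks(
                    left_zc_idx=ps, right_zc_idx=ne - 1,
                    pos_peak_idx=pos_idx, neg_peak_idx=neg_idx,
                    deriv_extrema_idx=(pos_idx, neg_idx),
                ),
                t_pos_s=t_pos, t_neg_s=t_neg,
                v_pos_V=v_pos, v_neg_V=v_neg, features=feats,
            )
        )
    logger.info("baseline: theta=%.4g V, %d events", theta, len(events))
    return events


# ---------------------------------------------------------------------------
# Method dispatch and balanced-threshold tuning
# ---------------------------------------------------------------------------

METHODS = ("derivative", "threshold")


def make_detector(method: str, stream_config, threshold: float | None = None,
                  detrend: bool = True, pairing: bool = True,
                  refractory: bool = True):
    """Build a ``trace -> events`` callable for a named method, with the
    structural settings scaled to the stream's expected pulse kinematics."""
    kin = derive_kinematics(stream_config)
    fs = stream_config.fs_Sa_s
    if method == "derivative":
        cfg = DetectorConfig.from_kinematics(
            kin.delta_s, kin.sigma_s, fs, threshold_V_s=threshold,
            refractory=refractory,
        )
        return lambda trace: run_pipeline(trace, cfg)
    if method == "threshold":
        cfg = BaselineConfig.from_kinematics(
            kin.delta_s, kin.sigma_s, fs, amp_threshold_V=threshold,
            detrend=detrend, pairing=pairing,
        )
        return lambda trace: baseline_detect(trace, cfg)
    raise ConfigError(f"unknown method {method!r}; expected one of {METHODS}")


def noise_scale(method: str, trace: SignalTrace, stream_config=None) -> float:
    """Robust (MAD-based) noise scale of the trace on which a method
    thresholds: s' for the derivative method, the detrended raw signal for
    amplitude thresholding."""
    if method == "derivative":
        v = compute_derivative(trace).values
    elif method == "threshold":
        w = int(round(0.1 * trace.fs_Sa_s))
        v = trace.samples - moving_median(trace.samples, min(w, trace.n))
    else:
        raise ConfigError(f"unknown method {method!r}")
    mad = float(np.median(np.abs(v - np.median(v))))
    return mad / MAD_TO_SD


def default_threshold_grid(scale: float, n: int = 30,
                           lo: float = 0.5, hi: float = 20.0) -> np.ndarray:
    """Log-spaced threshold grid spanning [lo, hi] x noise scale; the same
    relative grid is used for every method so comparisons stay fair."""
    if not scale > 0:
        raise ConfigError("noise scale must be positive")
    return scale * np.geomspace(lo, hi, n)


def tune_balanced_threshold(
    method: str,
    stream: SyntheticStream,
    grid: np.ndarray | None = None,
    tol_s: float | None = None,
    detrend: bool = True,
    pairing: bool = True,
) -> float:
    """Grid-search a method's threshold to balance precision and recall.

    Returns the grid value minimising |precision - recall| with F1 as the
    tie-breaker (and the larger threshold on exact ties).  Grid points that
    yield no detections or no matches are skipped; if every point does, the
    coarsest usable compromise (smallest grid value) is returned.
    Deterministic given the stream and grid.
    """
    from .evaluate import MatchConfig, compute_metrics, match_events

    kin = derive_kinematics(stream.config)
    if tol_s is None:
        tol_s = kin.delta_s / 2.0
    if grid is None:
        grid = default_threshold_grid(noise_scale(method, stream.trace))
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ConfigError("threshold grid is empty")

    mcfg = MatchConfig(tol_s=tol_s)
    best = None  # (|p-r|, -f1, -theta)
    best_theta = None
    for theta in grid:
        det = make_detector(method, stream.config, threshold=float(theta),
                            detrend=detrend, pairing=pairing)
        events = det(stream.trace)
        if not events:
            continue
        pairs, ud, ut = match_events(events, stream.truth, mcfg)
        m = compute_metrics(pairs, ud, ut)
        if np.isnan(m.precision) or np.isnan(m.recall):
            continue
        f1 = m.f1 if np.isfinite(m.f1) else 0.0
        key = (abs(m.precision - m.recall), -f1, -float(theta))
        if best is None or key < best:
            best = key
            best_theta = float(theta)
    if best_theta is None:
        logger.warning("tuning found no usable grid point; returning grid min")
        return float(grid.min())
    logger.info("tuned %s threshold: %.4g", method, best_theta)
    return best_theta
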