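"""Decision-tree particle-size classification from (dV, dt) features.

A CART tree with Gini-impurity splits on the two derivative-extracted
features — peak-to-peak amplitude and transit time — trained on synthetically
labelled streams.  Because amplitude scales with particle volume (d^3), the
two-feature space is nearly axis-separable and a shallow tree suffices.

The fitted tree is stored as plain arrays (split feature, threshold, children,
leaf posteriors), so models serialise to portable JSON and prediction does not
require scikit-learn at load time.  A feature exactly on a split threshold is
routed to the <= (left) branch.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split
from sklearn.tree import DecisionTreeClassifier

from .detect import DetectorConfig, run_pipeline
from .errors import ConfigError
from .recon import EventFeatures
from .trace import SignalTrace

logger = logging.getLogger(__name__)

FEATURE_NAMES = ("dV_V", "dt_s")


@dataclass
class LabeledFeatureSet:
    """Rows of (dV_V, dt_s, label) with provenance (stream ids / seeds)."""

    X: np.ndarray  # (n, 2): dV_V, dt_s
    y: np.ndarray  # (n,) string labels
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2 or self.X.shape[1] != 2:
            raise ConfigError("X must be an (n, 2) array of (dV_V, dt_s)")
        if self.y.shape[0] != self.X.shape[0]:
            raise ConfigError("X and y lengths differ")
        if not np.all(np.isfinite(self.X)) or not np.all(self.X > 0):
            raise ConfigError("features must be finite and positive")

    @property
    def n_classes(self) -> int:
        return np.unique(self.y).size

    @classmethod
    def from_events(cls, events, label: str, provenance: str = "") -> "LabeledFeatureSet":
        rows = [(e.features.dV_V, e.features.dt_s) for e in events
                if e.features is not None]
        X = np.array(rows, dtype=float).reshape(-1, 2)
        y = np.full(X.shape[0], label)
        return cls(X=X, y=y, provenance=[provenance] * X.shape[0])

    @staticmethod
    def concat(parts: list["LabeledFeatureSet"]) -> "LabeledFeatureSet":
        return LabeledFeatureSet(
            X=np.vstack([p.X for p in parts]),
            y=np.concatenate([p.y for p in parts]),
            provenance=[s for p in parts for s in p.provenance],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"dV_V": self.X[:, 0], "dt_s": self.X[:, 1], "label": self.y}
        )


@dataclass
class TreeModel:
    """Binary tree of axis-aligned splits stored as flat arrays.

    ``feature[i]`` is -1 at leaves; ``posterior[i]`` holds per-class
    probabilities at every node (used only at leaves).
    """

    feature: np.ndarray       # (n_nodes,) int: 0=dV_V, 1=dt_s, -1=leaf
    threshold: np.ndarray     # (n_nodes,) float
    left: np.ndarray          # (n_nodes,) int child index, -1 at leaf
    right: np.ndarray         # (n_nodes,) int
    posterior: np.ndarray     # (n_nodes, n_classes) float
    classes: list[str]
    max_depth: int
    min_leaf: int
    report: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return int(self.feature.size)

    def depth(self) -> int:
        d = np.zeros(self.n_nodes, dtype=int)
        for i in range(self.n_nodes):  # parents precede children in CART order
            for c in (self.left[i], self.right[i]):
                if c >= 0:
                    d[c] = d[i] + 1
        return int(d.max()) if self.n_nodes else 0

    def predict_one(self, features: EventFeatures) -> tuple[str, float]:
        """Deterministic leaf lookup; O(depth). Non-finite features are
        rejected with a ConfigError rather than assigned a class."""
        x = (features.dV_V, features.dt_s)
        if not all(np.isfinite(x)):
            raise ConfigError("non-finite features rejected")
        i = 0
        while self.feature[i] >= 0:
            i = int(self.left[i]) if x[self.feature[i]] <= self.threshold[i] \
                else int(self.right[i])
        p = self.posterior[i]
        k = int(np.argmax(p))
        return self.classes[k], float(p[k])

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorised prediction for an (n, 2) feature matrix."""
        X = np.asarray(X, dtype=float)
        if not np.all(np.isfinite(X)):
            raise ConfigError("non-finite features rejected")
        idx = np.zeros(X.shape[0], dtype=int)
        rows = np.flatnonzero(self.feature[idx] >= 0)
        while rows.size:
            node = idx[rows]
            f = self.feature[node]
            go_left = X[rows, f] <= self.threshold[node]
            idx[rows] = np.where(go_left, self.left[node], self.right[node])
            rows = rows[self.feature[idx[rows]] >= 0]
        post = self.posterior[idx]
        k = np.argmax(post, axis=1)
        labels = np.asarray(self.classes)[k]
        return labels, post[np.arange(post.shape[0]), k]

    def to_json(self) -> str:
        return json.dumps({
            "feature": self.feature.tolist(),
            "threshold": self.threshold.tolist(),
            "left": self.left.tolist(),
            "right": self.right.tolist(),
            "posterior": self.posterior.tolist(),
            "classes": list(self.classes),
            "max_depth": self.max_depth,
            "min_leaf": self.min_leaf,
            "report": self.report,
            "feature_names": list(FEATURE_NAMES),
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TreeModel":
        d = json.loads(text)
        return cls(
            feature=np.asarray(d["feature"], dtype=int),
            threshold=np.asarray(d["threshold"], dtype=float),
            left=np.asarray(d["left"], dtype=int),
            right=np.asarray(d["right"], dtype=int),
            posterior=np.asarray(d["posterior"], dtype=float),
            classes=list(d["classes"]),
            max_depth=int(d["max_depth"]),
            min_leaf=int(d["min_leaf"]),
            report=d.get("report", {}),
        )


def _extract(clf: DecisionTreeClassifier, classes: list[str],
             max_depth: int, min_leaf: int) -> TreeModel:
    t = clf.tree_
    counts = t.value[:, 0, :]
    post = counts / counts.sum(axis=1, keepdims=True)
    return TreeModel(
        feature=t.feature.copy(),
        threshold=t.threshold.copy(),
        left=t.children_left.copy(),
        right=t.children_right.copy(),
        posterior=post,
        classes=classes,
        max_depth=max_depth,
        min_leaf=min_leaf,
    )


def _per_class_pr(y_true: np.ndarray, y_pred: np.ndarray, classes) -> dict:
    out = {}
    for c in classes:
        tp = int(np.sum((y_pred == c) & (y_true == c)))
        fp = int(np.sum((y_pred == c) & (y_true != c)))
        fn = int(np.sum((y_pred != c) & (y_true == c)))
        out[str(c)] = {
            "precision": tp / (tp + fp) if tp + fp else float("nan"),
            "recall": tp / (tp + fn) if tp + fn else float("nan"),
            "support": tp + fn,
        }
    return out


def train_tree(
    data: LabeledFeatureSet,
    max_depth: int = 3,
    min_leaf: int = 5,
    seed: int = 0,
    holdout_frac: float = 0.3,
) -> TreeModel:
    """Greedy Gini-impurity CART training, deterministic given (data, seed).

    A stratified hold-out split (default 70/30) yields the per-class
    precision/recall training report; the returned model is refit on the full
    data.  Single-class data degenerates to one leaf with a warning.
    """
    if data.X.shape[0] == 0:
        raise ConfigError("empty training data")
    classes = sorted(np.unique(data.y).tolist())
    if len(classes) < 2:
        logger.warning("single-class training data; returning a one-leaf model")
        post = np.ones((1, 1))
        return TreeModel(
            feature=np.array([-1]), threshold=np.array([0.0]),
            left=np.array([-1]), right=np.array([-1]),
            posterior=post, classes=classes,
            max_depth=max_depth, min_leaf=min_leaf,
            report={"note": "degenerate single-class model"},
        )

    Xtr, Xho, ytr, yho = train_test_split(
        data.X, data.y, test_size=holdout_frac, stratify=data.y,
        random_state=seed,
    )
    probe = DecisionTreeClassifier(
        criterion="gini", max_depth=max_depth, min_samples_leaf=min_leaf,
        random_state=seed,
    ).fit(Xtr, ytr)
    yho_pred = probe.predict(Xho)
    report = {
        "holdout_frac": holdout_frac,
        "n_train": int(len(ytr)),
        "n_holdout": int(len(yho)),
        "holdout_accuracy": float(np.mean(yho_pred == yho)),
        "per_class": _per_class_pr(yho, yho_pred, probe.classes_),
    }

    clf = DecisionTreeClassifier(
        criterion="gini", max_depth=max_depth, min_samples_leaf=min_leaf,
        random_state=seed,
    ).fit(data.X, data.y)
    model = _extract(clf, [str(c) for c in clf.classes_], max_depth, min_leaf)
    model.report = report
    logger.info("trained tree: %d nodes, hold-out accuracy %.4f",
                model.n_nodes, report["holdout_accuracy"])
    return model


def predict(model: TreeModel, features: EventFeatures) -> tuple[str, float]:
    """Classify one event: (label, leaf posterior)."""
    return model.predict_one(features)


def stream_classify(
    trace: SignalTrace,
    model: TreeModel,
    cfg: DetectorConfig,
    chunk_s: float,
    overlap_s: float | None = None,
) -> pd.DataFrame:
    """Chunked detection + classification of a streaming trace.

    The trace is processed in chunks of ``chunk_s`` seconds, each padded with
    ``overlap_s`` of neighbouring signal so events straddling a chunk
    boundary are seen whole; an event is attributed to the chunk containing
    its centre.  The detection threshold is resolved once on the first chunk
    and then frozen, and the refractory merge is re-applied globally, so the
    output matches whole-trace processing away from the stream tail.

    Returns a tidy table with per-event times, features, label, posterior and
    the wall-clock processing time of each chunk.
    """
    fs = trace.fs_Sa_s
    chunk_n = int(round(chunk_s * fs))
    if chunk_n < 3:
        raise ConfigError("chunk must contain at least 3 samples")
    if overlap_s is None:
        overlap_s = max(5.0 * cfg.max_gap_s, 0.01)
    ov_n = int(round(overlap_s * fs))
    n = trace.n

    theta = cfg.threshold_V_s
    collected = []
    chunk_times = []
    for start in range(0, n, chunk_n):
        lo = max(0, start - ov_n)
        hi = min(n, start + chunk_n + ov_n)
        if hi - lo < 3:
            continue
        tic = time.perf_counter()
        sub = SignalTrace(trace.samples[lo:hi], fs,
                          trace.t_start_s + lo / fs)
        if theta is None:
            from .detect import auto_threshold, compute_derivative
            theta = auto_threshold(compute_derivative(sub), cfg.auto_k)
        events = run_pipeline(sub, cfg.with_(threshold_V_s=theta, auto_k=None))
        t_lo = trace.t_start_s + start / fs
        t_hi = trace.t_start_s + min(start + chunk_n, n) / fs
        for e in events:
            if t_lo <= e.t_center_s < t_hi:
                collected.append(e.shifted(lo, 0.0))
        chunk_times.append(time.perf_counter() - tic)

    collected.sort(key=lambda e: e.t_center_s)
    # re-apply the refractory merge across chunk boundaries
    from .detect import _merge_and_trim
    if collected:
        centers = np.array([e.t_center_s for e in collected])
        dvs = np.array([e.v_pos_V - e.v_neg_V for e in collected])
        lefts = np.array([e.landmarks.left_zc_idx for e in collected])
        rights = np.array([e.landmarks.right_zc_idx for e in collected])
        pos = np.array([e.landmarks.pos_peak_idx for e in collected])
        neg = np.array([e.landmarks.neg_peak_idx for e in collected])
        kept = _merge_and_trim(centers, dvs, lefts, rights, pos, neg,
                               cfg.refractory_s)
        from .detect import DetectedEvent, EventLandmarks
        rebuilt = []
        for i in kept:
            e = collected[i]
            lm = e.landmarks
            if (lm.left_zc_idx, lm.right_zc_idx) != (lefts[i], rights[i]):
                e = DetectedEvent(
                    landmarks=EventLandmarks(
                        int(lefts[i]), int(rights[i]),
                        lm.pos_peak_idx, lm.neg_peak_idx,
                        lm.deriv_extrema_idx),
                    t_pos_s=e.t_pos_s, t_neg_s=e.t_neg_s,
                    v_pos_V=e.v_pos_V, v_neg_V=e.v_neg_V,
                    features=e.features)
            rebuilt.append(e)
        collected = rebuilt

    rows = []
    for e in collected:
        label, post = model.predict_one(e.features)
        rows.append({
            "t_pos_s": e.t_pos_s, "t_neg_s": e.t_neg_s,
            "v_pos_V": e.v_pos_V, "v_neg_V": e.v_neg_V,
            "dV_V": e.features.dV_V, "dt_s": e.features.dt_s,
            "label": label, "posterior": post,
        })
    df = pd.DataFrame(rows, columns=["t_pos_s", "t_neg_s", "v_pos_V", "v_neg_V",
                                     "dV_V", "dt_s", "label", "posterior"])
    df.attrs["chunk_seconds"] = chunk_times
    df.attrs["threshold_V_s"] = theta
    logger.info("stream_classify: %d events over %d chunks "
                "(mean %.4g s processing per chunk)",
                len(df), len(chunk_times),
                float(np.mean(chunk_times)) if chunk_times else float("nan"))
    return df
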