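"""End-to-end study protocols: classification, benchmark, size trend, drift.

Each protocol wires the simulator, the detectors, the evaluation harness and
the classifier into one reproducible experiment driven by a single master
seed.  These are the analyses the package exists to run; the command-line
``benchmark`` subcommand and the acceptance script are thin wrappers over
them.

Seeding: a master seed fans out to per-stream seeds through
``numpy.random.SeedSequence`` so every stream is independent yet fully
reproducible.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import baseline as bl
from .classify import LabeledFeatureSet, train_tree
from .detect import DetectorConfig, run_pipeline
from .evaluate import STANDARD_CONDITIONS, benchmark_sweep, evaluate_stream
from .sim import DriftSpec, SimulationConfig, derive_kinematics, post_filter_noise_sd, synthesize_stream

logger = logging.getLogger(__name__)


def _child_seeds(master_seed: int, n: int, tag: int = 0) -> list[int]:
    ss = np.random.SeedSequence(entropy=(int(master_seed), int(tag)))
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def _default_detector(cfg: SimulationConfig, auto_k: float = 5.0) -> DetectorConfig:
    kin = derive_kinematics(cfg)
    return DetectorConfig.from_kinematics(kin.delta_s, kin.sigma_s,
                                          cfg.fs_Sa_s, auto_k=auto_k)


# ---------------------------------------------------------------------------
# Classification study (two bead sizes)
# ---------------------------------------------------------------------------

def classification_study(
    master_seed: int,
    classes: tuple[float, ...] = (4.0, 7.0),
    n_train_per_class: int = 15,
    n_eval_per_class: int = 5,
    base_config: SimulationConfig | None = None,
    max_depth: int = 3,
    min_leaf: int = 5,
) -> dict:
    """Train on labelled synthetic streams, evaluate on fresh ones.

    Streams are single-class, so every derivative-detected event inherits the
    stream's label.  The decision tree is trained on (dV, dt) from the
    training streams; per-class precision/recall are computed on the events
    of held-out evaluation streams against their stream labels.

    Returns the per-class metrics, their minimum, the trained model and
    event counts.
    """
    base = base_config or SimulationConfig()
    n_streams = (n_train_per_class + n_eval_per_class) * len(classes)
    seeds = _child_seeds(master_seed, n_streams, tag=1)
    seed_iter = iter(seeds)

    def run_streams(d_um: float, n: int) -> LabeledFeatureSet:
        cfg = base.with_(D_um=d_um)
        det = _default_detector(cfg)
        parts = []
        for _ in range(n):
            sd = next(seed_iter)
            stream = synthesize_stream(cfg, seed=sd, keep_components=False)
            events = run_pipeline(stream.trace, det)
            parts.append(LabeledFeatureSet.from_events(
                events, cfg.label, provenance=f"seed{sd}"))
        return LabeledFeatureSet.concat(parts)

    train_parts, eval_parts = [], []
    for d in classes:
        train_parts.append(run_streams(d, n_train_per_class))
        eval_parts.append(run_streams(d, n_eval_per_class))
    train_data = LabeledFeatureSet.concat(train_parts)
    eval_data = LabeledFeatureSet.concat(eval_parts)

    model = train_tree(train_data, max_depth=max_depth, min_leaf=min_leaf,
                       seed=master_seed)
    pred, _ = model.predict(eval_data.X)

    per_class = {}
    values = []
    for d in classes:
        label = f"{d:g}um"
        tp = int(np.sum((pred == label) & (eval_data.y == label)))
        fp = int(np.sum((pred == label) & (eval_data.y != label)))
        fn = int(np.sum((pred != label) & (eval_data.y == label)))
        prec = tp / (tp + fp) if tp + fp else float("nan")
        rec = tp / (tp + fn) if tp + fn else float("nan")
        per_class[label] = {"precision": prec, "recall": rec, "support": tp + fn}
        values += [prec, rec]
    out = {
        "per_class": per_class,
        "min_precision_recall": float(np.min(values)),
        "accuracy": float(np.mean(pred == eval_data.y)),
        "n_train_events": int(train_data.X.shape[0]),
        "n_eval_events": int(eval_data.X.shape[0]),
        "model": model,
    }
    logger.info("classification study: min per-class P/R = %.4f over %d eval events",
                out["min_precision_recall"], out["n_eval_events"])
    return out


# ---------------------------------------------------------------------------
# Benchmark study (derivative vs amplitude thresholding)
# ---------------------------------------------------------------------------

def benchmark_study(
    master_seed: int,
    n_seeds: int = 10,
    conditions=STANDARD_CONDITIONS,
    base_config: SimulationConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Paired sweep over (flow, bandwidth) plus a summary of paired
    method differences in percentage points."""
    base = base_config or SimulationConfig(D_um=2.0)
    df = benchmark_sweep(conditions=conditions, n_seeds=n_seeds,
                         base_config=base, master_seed=master_seed)
    summary = summarize_benchmark(df)
    return df, summary


def summarize_benchmark(df: pd.DataFrame) -> dict:
    """Paired per-(condition, seed) differences, averaged, in percentage
    points: derivative minus baseline for precision/recall, baseline minus
    derivative for FDR (a positive value = the derivative improves)."""
    ok = df[df["error"] == ""] if "error" in df.columns else df
    d = ok[ok.method == "derivative"].set_index(["Q_uL_min", "BW_Hz", "seed"])
    b = ok[ok.method == "threshold"].set_index(["Q_uL_min", "BW_Hz", "seed"])
    common = d.index.intersection(b.index)
    d, b = d.loc[common], b.loc[common]
    dp = (d["precision"] - b["precision"]) * 100.0
    dr = (d["recall"] - b["recall"]) * 100.0
    dfdr = (b["fdr"] - d["fdr"]) * 100.0
    per_condition = {}
    for (q, bw), grp in dp.groupby(level=[0, 1]):
        per_condition[f"Q{q:g}_BW{bw:g}"] = {
            "precision_gain_pp": float(grp.mean()),
            "recall_gain_pp": float(dr.loc[(q, bw)].mean()),
            "fdr_reduction_pp": float(dfdr.loc[(q, bw)].mean()),
        }
    return {
        "precision_gain_pp": float(dp.mean()),
        "recall_gain_pp": float(dr.mean()),
        "mean_pr_gain_pp": float((dp.mean() + dr.mean()) / 2.0),
        "fdr_reduction_pp": float(dfdr.mean()),
        "per_condition": per_condition,
        "n_pairs": int(len(common)),
    }


# ---------------------------------------------------------------------------
# Size trend study
# ---------------------------------------------------------------------------

def size_trend_study(
    master_seed: int,
    sizes: tuple[float, ...] = (2.0, 3.0, 4.0),
    n_seeds: int = 20,
    base_config: SimulationConfig | None = None,
) -> pd.DataFrame:
    """Derivative-method metrics vs particle size at standard settings.

    The detection threshold is tuned (balanced precision/recall) per size on
    one calibration stream, then applied to ``n_seeds`` fresh streams.
    Returns per-size mean metrics.
    """
    base = base_config or SimulationConfig()
    rows = []
    for si, d_um in enumerate(sizes):
        cfg = base.with_(D_um=d_um)
        kin = derive_kinematics(cfg)
        tol = kin.delta_s / 2.0
        seeds = _child_seeds(master_seed, n_seeds + 1, tag=100 + si)
        calib = synthesize_stream(cfg, seed=seeds[0])
        theta = bl.tune_balanced_threshold("derivative", calib, tol_s=tol)
        det = bl.make_detector("derivative", cfg, threshold=theta)
        for sd in seeds[1:]:
            stream = synthesize_stream(cfg, seed=sd, keep_components=False)
            m = evaluate_stream(det(stream.trace), stream.truth, tol_s=tol)
            rows.append({"D_um": d_um, "seed": sd, "threshold": theta,
                         **{k: v for k, v in m.as_dict().items() if k != "flags"}})
    df = pd.DataFrame(rows)
    return df


# ---------------------------------------------------------------------------
# Drift-suppression study
# ---------------------------------------------------------------------------

def drift_study(
    master_seed: int,
    n_seeds: int = 5,
    drift_amp_factor: float = 10.0,
    drift_freq_Hz: float = 2.0,
    base_config: SimulationConfig | None = None,
) -> dict:
    """Paired drift-free vs drifting streams for both detectors.

    The drift is a slow sinusoid with amplitude ``drift_amp_factor`` times
    the post-filter noise sd.  Thresholds are tuned on a drift-free
    calibration stream; the baseline runs without detrending so its raw
    sensitivity to drift is exposed, while differentiation suppresses the
    drift term by construction.  Events and noise are identical within each
    pair, so metric changes are attributable to the drift alone.
    """
    base = base_config or SimulationConfig(D_um=2.0)
    kin = derive_kinematics(base)
    tol = kin.delta_s / 2.0
    noise_sd = post_filter_noise_sd(base)
    drift = DriftSpec(kind="sine", amplitude_V=drift_amp_factor * noise_sd,
                      freq_Hz=drift_freq_Hz)
    drift_cfg = base.with_(drift=drift)

    seeds = _child_seeds(master_seed, n_seeds + 1, tag=200)
    calib = synthesize_stream(base, seed=seeds[0])
    thetas = {
        "derivative": bl.tune_balanced_threshold("derivative", calib, tol_s=tol),
        "threshold": bl.tune_balanced_threshold("threshold", calib, tol_s=tol,
                                                detrend=False),
    }
    detectors = {
        "derivative": {
            "clean": bl.make_detector("derivative", base,
                                      threshold=thetas["derivative"]),
            "drift": bl.make_detector("derivative", drift_cfg,
                                      threshold=thetas["derivative"]),
        },
        "threshold": {
            "clean": bl.make_detector("threshold", base,
                                      threshold=thetas["threshold"],
                                      detrend=False),
            "drift": bl.make_detector("threshold", drift_cfg,
                                      threshold=thetas["threshold"],
                                      detrend=False),
        },
    }

    acc: dict[str, dict[str, list]] = {
        m: {"clean_p": [], "clean_r": [], "drift_p": [], "drift_r": []}
        for m in detectors
    }
    for sd in seeds[1:]:
        clean = synthesize_stream(base, seed=sd, keep_components=False)
        drifty = synthesize_stream(drift_cfg, seed=sd, keep_components=False)
        for method, dets in detectors.items():
            mc = evaluate_stream(dets["clean"](clean.trace), clean.truth, tol_s=tol)
            md = evaluate_stream(dets["drift"](drifty.trace), drifty.truth, tol_s=tol)
            acc[method]["clean_p"].append(mc.precision)
            acc[method]["clean_r"].append(mc.recall)
            acc[method]["drift_p"].append(0.0 if np.isnan(md.precision) else md.precision)
            acc[method]["drift_r"].append(md.recall)

    out = {"drift_amplitude_V": drift.amplitude_V, "noise_sd_V": noise_sd}
    for method, a in acc.items():
        cp, cr = np.nanmean(a["clean_p"]), np.nanmean(a["clean_r"])
        dp, dr = np.nanmean(a["drift_p"]), np.nanmean(a["drift_r"])
        out[method] = {
            "clean_precision": float(cp), "clean_recall": float(cr),
            "drift_precision": float(dp), "drift_recall": float(dr),
            "precision_change_pp": float((dp - cp) * 100.0),
            "recall_change_pp": float((dr - cr) * 100.0),
        }
    return out
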