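"""End-to-end orchestration: simulate -> PLV/network + CSP -> PE;
recurrence image -> CNN -> RE; clinical screen -> clinical probability;
decision fusion; evaluation.

The default configuration is the desk-scale study: 150 recordings (50
per state, 4 channels, 1,000 samples at 128 Hz), 64 x 64 recurrence
images from one frontal channel, a 30-epoch CNN run, and stacked fusion
evaluated on a held-out 30% test split.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field

import numpy as np

from . import fusion as fu
from . import network as net
from . import phase as ph
from . import recurrence as rc
from . import rpnet as rp
from . import synthetic as syn
from .csp import OneVsRestCSP
from .recording import STATES

log = logging.getLogger("adeeg.pipeline")


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run (seeded, reproducible)."""

    n_per_state: int = 50
    n_channels: int = 4
    n_samples: int = 1000
    fs: float = 128.0
    band: tuple[float, float] = (8.0, 30.0)
    seed: int = 0
    # PE branch
    csp_m: int = 2
    csp_selector: str = "log_variance"
    betweenness_mode: str = "standard"
    # RE branch
    rp_channels: tuple[str, ...] = ("F3",)   # or ("all",) for every channel
    image_side: int = 64
    image_scaling: str = "global"
    epochs: int = 30
    batch: int = 16
    lr: float = 1e-3
    # splits and fusion
    test_fraction: float = 0.3
    meta_fraction: float = 0.25
    fusion_method: str = "stacked"
    fusion_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    alpha: float = 0.05

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        import tomllib
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        kwargs = {}
        for f_ in cls.__dataclass_fields__.values():
            if f_.name in raw:
                v = raw[f_.name]
                kwargs[f_.name] = tuple(v) if isinstance(v, list) else v
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)


@dataclass
class PipelineReport:
    """Everything one run produced: per-source and fused test accuracy,
    per-class confusion counts and AUCs, the screening table, learning
    curves, stage timings and all seeds."""

    config: dict
    screening: dict
    source_accuracy: dict[str, float]
    fused_accuracy: float
    per_class: dict[str, dict]
    train_report: dict
    timings: dict[str, float] = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(_jsonable(asdict(self)), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _stratified_indices(labels, fraction, rng):
    labels = np.asarray(labels)
    held, rest = [], []
    for cls in np.unique(labels):
        idx = rng.permutation(np.nonzero(labels == cls)[0])
        n_held = max(1, int(round(fraction * idx.size)))
        held.extend(idx[:n_held])
        rest.extend(idx[n_held:])
    return np.array(sorted(rest)), np.array(sorted(held))


def _recording_images(recordings, channels, side):
    """Unscaled block-reduced recurrence matrices, one list per recording."""
    per_rec = []
    for r in recordings:
        names = r.channel_labels if channels == ("all",) else channels
        mats = []
        for ch in names:
            img = rc.recurrence_image(r.channel(ch), rc.FULL_RESOLUTION,
                                      epsilon=0.0)
            mats.append(rc.block_reduce(img.unthresholded, side))
        per_rec.append(np.stack(mats))
    return per_rec


def run_pipeline(config: PipelineConfig | None = None) -> PipelineReport:
    """Execute the full analysis on synthetic data and evaluate it."""
    cfg = config or PipelineConfig()
    rng = np.random.default_rng(cfg.seed)
    timings: dict[str, float] = {}

    def stage(name):
        log.info("stage %s", name)
        timings[name] = time.perf_counter()
        return name

    def done(name):
        timings[name] = time.perf_counter() - timings[name]

    # ---- simulate -------------------------------------------------------
    s = stage("simulate")
    try:
        recordings = syn.generate_state_dataset(
            cfg.n_per_state, cfg.n_channels, cfg.n_samples, cfg.fs,
            seed=cfg.seed,
        )
        clinical = syn.generate_clinical_table(
            len(recordings), seed=cfg.seed + 1
        )
        for rec, cl in zip(recordings, clinical):
            cl.subject_id = rec.subject_id
            if cl.label != rec.state:
                raise RuntimeError("clinical labels out of sync")
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc
    done(s)

    labels = np.array([r.state for r in recordings])
    y = np.array([STATES.index(st) for st in labels])
    train_idx, test_idx = _stratified_indices(labels, cfg.test_fraction, rng)
    base_idx, meta_idx = _stratified_indices(
        labels[train_idx], cfg.meta_fraction, rng
    )
    base_idx, meta_idx = train_idx[base_idx], train_idx[meta_idx]

    # ---- PE branch: PLV network + CSP features --------------------------
    s = stage("pe_features")
    try:
        net_feats = []
        for r in recordings:
            plv = ph.plv_matrix(r, band=cfg.band)
            g = net.from_plv(plv)
            net_feats.append(
                net.network_feature_vector(
                    g, betweenness_mode=cfg.betweenness_mode
                )
            )
        net_feats = np.stack(net_feats)
        csp = OneVsRestCSP.fit(
            [recordings[i] for i in base_idx], m=cfg.csp_m,
            selector=cfg.csp_selector,
        )
        csp_feats = np.stack([csp.transform(r) for r in recordings])
        pe_features = np.concatenate([csp_feats, net_feats], axis=1)
        pe_clf = fu.PEClassifier(seed=cfg.seed).fit(
            pe_features[base_idx], y[base_idx]
        )
        pe_probs = pe_clf.predict_proba(pe_features)
    except Exception as exc:
        raise RuntimeError(f"stage 'pe_features' failed: {exc}") from exc
    done(s)

    # ---- RE branch: recurrence images + CNN -----------------------------
    s = stage("re_branch")
    try:
        per_rec = _recording_images(recordings, cfg.rp_channels,
                                    cfg.image_side)
        if cfg.image_scaling == "global":
            train_vals = np.concatenate(
                [per_rec[i].ravel() for i in base_idx]
            )
            scale = float(np.quantile(train_vals, 0.975))
            per_rec = [np.clip(m / scale, 0.0, 1.0) for m in per_rec]
        else:
            per_rec = [
                np.stack([
                    (mat - mat.min()) / (mat.max() - mat.min())
                    if mat.max() > mat.min() else np.zeros_like(mat)
                    for mat in m
                ])
                for m in per_rec
            ]
        flat_images = np.concatenate(per_rec, axis=0)
        flat_labels = np.concatenate(
            [np.full(m.shape[0], y[i]) for i, m in enumerate(per_rec)]
        )
        rec_of_image = np.concatenate(
            [np.full(m.shape[0], i) for i, m in enumerate(per_rec)]
        )
        base_mask = np.isin(rec_of_image, base_idx)
        meta_mask = np.isin(rec_of_image, meta_idx)
        model = rp.build_rpnet(rp.RPNetConfig(input_side=cfg.image_side,
                                              seed=cfg.seed))
        train_report = rp.train_rpnet(
            model,
            flat_images[base_mask], flat_labels[base_mask],
            epochs=cfg.epochs, batch=cfg.batch, lr=cfg.lr, seed=cfg.seed,
            val_images=flat_images[meta_mask],
            val_labels=flat_labels[meta_mask],
        )
        re_probs = np.stack([rp.predict_re(model, m) for m in per_rec])
    except Exception as exc:
        raise RuntimeError(f"stage 're_branch' failed: {exc}") from exc
    done(s)

    # ---- clinical branch ------------------------------------------------
    s = stage("clinical")
    try:
        train_records = [clinical[i] for i in np.concatenate([base_idx,
                                                              meta_idx])]
        screening = fu.screen_clinical(train_records, alpha=cfg.alpha)
        clin_model = fu.ClinicalModel(screening, seed=cfg.seed).fit(
            [clinical[i] for i in base_idx]
        )
        clin_probs = clin_model.predict_proba(clinical)
    except Exception as exc:
        raise RuntimeError(f"stage 'clinical' failed: {exc}") from exc
    done(s)

    # ---- fusion ---------------------------------------------------------
    s = stage("fusion")
    try:
        all_probs = [
            fu.ClassProbabilities(pe=pe_probs[i], re=re_probs[i],
                                  clinical=clin_probs[i])
            for i in range(len(recordings))
        ]
        meta = None
        if cfg.fusion_method == "stacked":
            meta = fu.fit_stacker([all_probs[i] for i in meta_idx],
                                  y[meta_idx], seed=cfg.seed)
        fused = np.stack([
            fu.fuse(p, method=cfg.fusion_method,
                    weights=(cfg.fusion_weights
                             if cfg.fusion_method == "weighted" else None),
                    meta_model=meta)
            for p in all_probs
        ])
        for i, p in enumerate(all_probs):
            p.fused = fused[i]
    except Exception as exc:
        raise RuntimeError(f"stage 'fusion' failed: {exc}") from exc
    done(s)

    # ---- evaluation -----------------------------------------------------
    s = stage("evaluate")
    yt = y[test_idx]
    source_acc = {
        "pe": fu.multiclass_accuracy(yt, pe_probs[test_idx].argmax(1)),
        "re": fu.multiclass_accuracy(yt, re_probs[test_idx].argmax(1)),
        "clinical": fu.multiclass_accuracy(yt, clin_probs[test_idx].argmax(1)),
    }
    fused_pred = fused[test_idx].argmax(1)
    fused_acc = fu.multiclass_accuracy(yt, fused_pred)
    per_class = {}
    for state in STATES:
        counts = fu.confusion_counts(yt, fused_pred, state)
        entry = {
            "TP": counts.TP, "FP": counts.FP,
            "TN": counts.TN, "FN": counts.FN,
            "accuracy": fu.accuracy(counts),
        }
        try:
            _, _, auc_val = fu.roc_curve(fused[test_idx], yt, state)
            entry["auc"] = auc_val
        except ValueError:
            entry["auc"] = float("nan")
        per_class[state] = entry
    done(s)

    return PipelineReport(
        config=asdict(cfg),
        screening={
            "selected": list(screening.selected),
            "p_values": dict(zip(screening.tests["feature"],
                                 screening.tests["p_value"])),
        },
        source_accuracy=source_acc,
        fused_accuracy=fused_acc,
        per_class=per_class,
        train_report={
            "train_loss": train_report.train_loss,
            "train_accuracy": train_report.train_accuracy,
            "val_loss": train_report.val_loss,
            "val_accuracy": train_report.val_accuracy,
            "seed": train_report.seed,
        },
        timings=timings,
    )
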