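"""End-to-end orchestration of the train -> features -> select -> evaluate
workflow, shared by the command-line interface and by tests.

One global seed fans out deterministically to per-stage seeds (model init,
train/val split + shuffling, NCA, fold plans), so each stage is independently
reproducible and a rerun of any command with the same config and inputs
produces identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .architecture import ArchitectureSpec, build_model, load_model, save_model
from .data import load_image_folder
from .errors import ConfigurationError, DataError
from .exemplar import build_feature_matrix, load_features, save_features
from .inca import (
    KNNOracleConfig,
    NCAConfig,
    apply_selection,
    iterative_selection,
    load_selection,
    nca_weights,
    rank_features,
    save_selection,
    standardize_apply,
    standardize_fit,
)
from .metrics import full_report, mcnemar
from .nn.optim import softmax
from .shallow import (
    ClassifierSpec,
    PredictionSet,
    knn_predict,
    lda_train_predict,
    svm_train_predict,
)
from .training import TrainConfig, train_model

ABLATIONS = ("full", "softmax_only", "full_image_only", "no_inca")

MODEL_FILE = "model.npz"
TRACE_FILE = "training_trace.csv"
SELECTION_FILE = "selection.txt"
LOG_FILE = "log.jsonl"


def derive_seed(master: int, stage: str) -> int:
    """Stable per-stage seed below 2**31 derived from the global seed."""
    return zlib.crc32(f"{master}:{stage}".encode()) % (2 ** 31)


@dataclass
class PipelineConfig:
    data_root: str = "."
    artifacts: str = "artifacts"
    architecture: ArchitectureSpec = field(default_factory=ArchitectureSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    patch_mode: str = "resize"
    iv: int = 100
    fv: int = 1000
    oracle_k: int = 1
    oracle_folds: int = 10
    standardize: bool = True
    ablation: str = "full"
    seed: int = 0

    def validate(self) -> None:
        self.architecture.validate()
        self.train.validate()
        if self.ablation not in ABLATIONS:
            raise ConfigurationError(
                f"ablation must be one of {ABLATIONS}, got {self.ablation!r}")
        if self.patch_mode not in ("resize", "native"):
            raise ConfigurationError(f"unknown patch_mode {self.patch_mode!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["architecture"]["filters"] = list(self.architecture.filters)
        d["architecture"]["repetitions"] = list(self.architecture.repetitions)
        d["train"]["train_val_ratio"] = list(self.train.train_val_ratio)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "architecture" in d:
            a = dict(d["architecture"])
            for key in ("filters", "repetitions"):
                if key in a:
                    a[key] = tuple(a[key])
            d["architecture"] = ArchitectureSpec(**a)
        if "train" in d:
            t = dict(d["train"])
            if "train_val_ratio" in t:
                t["train_val_ratio"] = tuple(t["train_val_ratio"])
            d["train"] = TrainConfig(**t)
        return cls(**d)

    @classmethod
    def from_json_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def config_hash(self) -> str:
        """Hash of the artifact-determining fields (evaluation-time switches
        like the ablation flag and the artifact path itself are excluded)."""
        d = self.to_dict()
        d.pop("ablation", None)
        d.pop("artifacts", None)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def _check_stale(cfg: PipelineConfig) -> None:
    """Refuse to mix artifacts produced under a different configuration."""
    marker = Path(cfg.artifacts) / "config_hash.txt"
    if marker.exists() and marker.read_text().strip() != cfg.config_hash():
        raise ConfigurationError(
            f"artifacts in {cfg.artifacts} were produced with config hash "
            f"{marker.read_text().strip()}, current config hashes to "
            f"{cfg.config_hash()}; use a fresh artifacts directory")


def _log(cfg: PipelineConfig, command: str, inputs: list[str],
         outputs: list[str]) -> None:
    art = Path(cfg.artifacts)
    art.mkdir(parents=True, exist_ok=True)
    (art / "config_hash.txt").write_text(cfg.config_hash() + "\n")
    entry = {
        "time": datetime.now(timezone.utc).isoformat(),
        "command": command,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "inputs": inputs,
        "outputs": outputs,
        "version": __version__,
    }
    with open(art / LOG_FILE, "a") as fh:
        fh.write(json.dumps(entry) + "\n")


def run_train(cfg: PipelineConfig) -> dict:
    """Stage 1: train the backbone on ``data_root/train`` and archive it."""
    cfg.validate()
    _check_stale(cfg)
    train_dir = Path(cfg.data_root) / "train"
    if not train_dir.is_dir():
        raise DataError(f"training folder {train_dir} does not exist")
    model = build_model(cfg.architecture, seed=derive_seed(cfg.seed, "init"))
    tcfg = TrainConfig(**{**asdict(cfg.train),
                          "train_val_ratio": cfg.train.train_val_ratio,
                          "seed": derive_seed(cfg.seed, "train")})
    model, trace = train_model(model, str(train_dir), tcfg)
    art = Path(cfg.artifacts)
    art.mkdir(parents=True, exist_ok=True)
    save_model(model, art / MODEL_FILE)
    pd.DataFrame(trace).to_csv(art / TRACE_FILE, index=False)
    _log(cfg, "train", [str(train_dir)], [str(art / MODEL_FILE), str(art / TRACE_FILE)])
    final = trace[-1] if trace else {}
    return {"model_path": str(art / MODEL_FILE), "trace": trace,
            "final_train_acc": final.get("train_acc"),
            "final_val_acc": final.get("val_acc")}


def features_path(cfg: PipelineConfig, split: str) -> Path:
    return Path(cfg.artifacts) / f"features_{split}.csv"


def run_features(cfg: PipelineConfig, split: str) -> dict:
    """Stage 2: exemplar feature matrix for one split, written as labeled CSV."""
    cfg.validate()
    _check_stale(cfg)
    if split not in ("train", "test"):
        raise ConfigurationError(f"split must be 'train' or 'test', got {split!r}")
    split_dir = Path(cfg.data_root) / split
    if not split_dir.is_dir():
        raise DataError(f"split folder {split_dir} does not exist")
    model = load_model(Path(cfg.artifacts) / MODEL_FILE)
    fm = build_feature_matrix(model, split_dir, patch_mode=cfg.patch_mode)
    out = features_path(cfg, split)
    save_features(fm, out)
    _log(cfg, f"features[{split}]", [str(split_dir)], [str(out)])
    return {"path": str(out), "shape": fm.X.shape}


def run_select(cfg: PipelineConfig, features_file=None) -> dict:
    """Stage 3: INCA selection on the *training* features only.

    ``features_file`` defaults to the artifact train-split matrix; a file whose
    name marks it as test-split features is refused (leakage guard).
    """
    cfg.validate()
    _check_stale(cfg)
    path = Path(features_file) if features_file else features_path(cfg, "train")
    if "test" in path.name:
        raise DataError(
            f"refusing to run feature selection on {path.name}: selection must "
            f"be fitted on training features only")
    fm = load_features(path)
    X = fm.X
    if cfg.standardize:
        X = standardize_apply(X, standardize_fit(X))
    weights = nca_weights(X, fm.y, NCAConfig(seed=derive_seed(cfg.seed, "nca")))
    ranking = rank_features(weights)
    fv = min(cfg.fv, X.shape[1])
    iv = min(cfg.iv, fv)
    result = iterative_selection(
        X, fm.y, ranking, iv=iv, fv=fv,
        oracle_config=KNNOracleConfig(k=cfg.oracle_k, n_folds=cfg.oracle_folds,
                                      seed=derive_seed(cfg.seed, "folds")))
    out = Path(cfg.artifacts) / SELECTION_FILE
    save_selection(result, out)
    _log(cfg, "select", [str(path)], [str(out)])
    return {"path": str(out), "candidates": fv - iv + 1,
            "best_size": result.best_size,
            "best_error": float(result.mcv.min())}


def _predict_all(train_X, train_y, test_X, test_y) -> dict:
    return {
        "knn": knn_predict(train_X, train_y, test_X,
                           ClassifierSpec("knn"), test_y=test_y),
        "svm": svm_train_predict(train_X, train_y, test_X,
                                 ClassifierSpec("svm"), test_y=test_y),
        "lda": lda_train_predict(train_X, train_y, test_X,
                                 ClassifierSpec("lda"), test_y=test_y),
    }


def run_evaluate(cfg: PipelineConfig) -> dict:
    """Stage 4: apply the ablation-selected feature route, fit the shallow
    classifiers on training features, predict the test split, and write
    metric reports plus a pairwise McNemar table."""
    cfg.validate()
    _check_stale(cfg)
    art = Path(cfg.artifacts)
    results: dict = {"ablation": cfg.ablation, "reports": {}}
    if cfg.ablation == "softmax_only":
        model = load_model(art / MODEL_FILE)
        test_dir = Path(cfg.data_root) / "test"
        if not test_dir.is_dir():
            raise DataError(f"test folder {test_dir} does not exist")
        X, y, class_names, _ = load_image_folder(test_dir, model.spec.input_side)
        probs = []
        for start in range(0, X.shape[0], 32):
            probs.append(softmax(model.logits_batch(X[start:start + 32]), axis=1))
        pred_idx = np.vstack(probs).argmax(axis=1)
        names = np.array(class_names, dtype=object)
        preds = {"softmax": PredictionSet(y_true=names[y], y_pred=names[pred_idx],
                                          source="softmax/test")}
    else:
        fm_train = load_features(features_path(cfg, "train"))
        fm_test = load_features(features_path(cfg, "test"))
        Xtr, Xte = fm_train.X, fm_test.X
        gap = len(fm_train.columns) // 10
        if cfg.ablation == "full_image_only":
            Xtr, Xte = Xtr[:, :gap], Xte[:, :gap]
        if cfg.standardize:
            stats = standardize_fit(Xtr)
            Xtr, Xte = standardize_apply(Xtr, stats), standardize_apply(Xte, stats)
        if cfg.ablation == "full":
            sel = load_selection(art / SELECTION_FILE)
            Xtr = apply_selection(Xtr, sel["selected"])
            Xte = apply_selection(Xte, sel["selected"])
        preds = _predict_all(Xtr, fm_train.y, Xte, fm_test.y)
    lines = [f"# ablation: {cfg.ablation}"]
    overall_rows = []
    for name, ps in preds.items():
        report = full_report(ps.y_true, ps.y_pred)
        results["reports"][name] = report
        lines += [f"\n== {name} ==", report.to_text()]
        pd.DataFrame({
            "true_label": ps.y_true, "predicted_label": ps.y_pred,
            "classifier": name, "mode": ps.source,
        }).to_csv(art / f"predictions_{name}_{cfg.ablation}.csv", index=False)
        overall_rows.append({
            "classifier": name, "accuracy": report.accuracy, "uar": report.uar,
            "uap": report.uap, "f1": report.f1, "ci_low": report.ci_low,
            "ci_high": report.ci_high, "n": report.n,
        })
        report.per_class.round(2).to_csv(
            art / f"per_class_{name}_{cfg.ablation}.csv")
    pd.DataFrame(overall_rows).round(2).to_csv(
        art / f"overall_{cfg.ablation}.csv", index=False)
    if len(preds) > 1:
        lines.append("\n== McNemar pairwise (continuity-corrected) ==")
        names = list(preds)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                r = mcnemar(preds[names[i]], preds[names[j]])
                lines.append(
                    f"{names[i]} vs {names[j]}: b={r.b} c={r.c} "
                    f"chi2={r.chi2:.4g} p={r.p:.4g}")
    report_path = art / f"report_{cfg.ablation}.txt"
    report_path.write_text("\n".join(lines) + "\n")
    _log(cfg, f"evaluate[{cfg.ablation}]", [str(art)], [str(report_path)])
    results["report_path"] = str(report_path)
    results["predictions"] = preds
    return results
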