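"""End-to-end training and evaluation.

Covers the full experimental harness: context-window preparation, Adam
training with early stopping, the accuracy / macro-F1 / Cohen's kappa
metric triple on confusion matrices, the eight-variant ablation table over
the (A = recurrent branch, B = domain attention, C = transitional-stage
estimator) switches, the attention-head-count sweep, and hypnogram export.

Splits are contiguous 70/15/15 blocks of the recording (attached by the
simulator); context windows are built over the whole recording with edge
epochs replicated, so a window near a split boundary may peek at a handful
of neighbouring epochs.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .channel_graph import ChannelGraph, build_knn_adjacency, default_montage
from .exceptions import ParameterError, TrainingError, ValidationError
from .features import zscore_features
from .model import AblationFlags, MganetModel, ModelConfig
from .stages import HYPNOGRAM_ORDER, N_STAGES, STAGES
from .synthetic_psg import LabeledRecording

__all__ = [
    "TrainingConfig",
    "EvaluationReport",
    "make_windows",
    "assemble_model",
    "train_model",
    "evaluate",
    "confusion_matrix",
    "report_from_predictions",
    "run_ablation",
    "head_sweep",
    "export_hypnogram",
    "export_predictions",
    "plot_hypnogram",
    "default_graph",
]

logger = logging.getLogger("mganet")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(name)s %(levelname)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization settings.

    Adam with learning rate 1e-3 and batch size 32, at most 100 passes
    over the training split, early-stopped when the validation loss has
    not improved for ``patience`` consecutive passes (the best-validation
    parameters are restored).  ``class_weights`` enables inverse-frequency
    cross-entropy weighting; it is off by default - the estimator head,
    not re-weighting, is the mechanism aimed at the minority stages.
    """

    epochs_max: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    optimizer_name: str = "adam"
    seed: int = 0
    patience: int = 10
    normalize: bool = True
    class_weights: bool = False
    ablation_flags: AblationFlags = field(default_factory=AblationFlags)

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ParameterError("learning_rate must be >= 0")
        if self.optimizer_name.lower() != "adam":
            raise ParameterError(f"unknown optimizer {self.optimizer_name!r}")
        if self.batch_size < 1 or self.epochs_max < 1:
            raise ParameterError("batch_size and epochs_max must be >= 1")


@dataclass(frozen=True)
class EvaluationReport:
    """Metric triple plus the confusion matrix it derives from."""

    accuracy: float
    mf1: float
    kappa: float
    confusion: np.ndarray = field(repr=False)
    per_class_f1: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "mf1": self.mf1,
            "kappa": self.kappa,
            "confusion": np.asarray(self.confusion).tolist(),
            "per_class_f1": np.asarray(self.per_class_f1).tolist(),
            "stages": list(STAGES),
        }


def default_graph(k: int = 3) -> ChannelGraph:
    """k-NN graph over the packaged 6-channel montage."""
    return build_knn_adjacency(default_montage(), k=k)


def make_windows(features: np.ndarray, context_len: int) -> np.ndarray:
    """Stack each epoch with its symmetric context into (E, T, n, F).

    Edge epochs replicate the first/last epoch to fill the window.
    """
    if context_len % 2 == 0 or context_len < 1:
        raise ParameterError("context_len must be a positive odd integer")
    features = np.asarray(features, dtype=float)
    n_epochs = features.shape[0]
    half = context_len // 2
    idx = np.arange(n_epochs)[:, None] + np.arange(-half, half + 1)[None, :]
    idx = np.clip(idx, 0, n_epochs - 1)
    return features[idx]


def assemble_model(
    graph: ChannelGraph,
    n_features: int,
    model_config: ModelConfig = ModelConfig(),
    flags: AblationFlags = AblationFlags(),
    seed: int = 0,
) -> MganetModel:
    """Instantiate the network for a given graph and ablation variant."""
    return MganetModel(
        graph=graph, n_features=n_features, config=model_config, flags=flags, seed=seed
    )


def _prepare(data: LabeledRecording, context_len: int, normalize: bool) -> np.ndarray:
    feats = zscore_features(data.features) if normalize else data.features
    return make_windows(feats, context_len)


def train_model(
    model: MganetModel,
    data: LabeledRecording,
    tc: TrainingConfig,
) -> tuple[MganetModel, dict[str, list[float]]]:
    """Train in place with Adam + early stopping; returns the model and the
    per-pass train/validation loss traces.

    Fully deterministic for a fixed ``tc.seed`` (initialisation is the
    model's; batching order is the trainer's).
    """
    windows = _prepare(data, model.config.context_len, tc.normalize)
    x_train, y_train = windows[data.train_idx], data.labels[data.train_idx]
    x_val, y_val = windows[data.val_idx], data.labels[data.val_idx]
    if x_train.shape[0] == 0 or x_val.shape[0] == 0:
        raise ValidationError("training requires non-empty train and val splits")

    weights = None
    if tc.class_weights:
        counts = np.bincount(y_train, minlength=N_STAGES).astype(float)
        counts[counts == 0] = 1.0
        weights = y_train.shape[0] / (N_STAGES * counts)

    rng = np.random.default_rng(tc.seed)
    names = sorted(model.params)
    m = {k: np.zeros_like(model.params[k].data) for k in names}
    v = {k: np.zeros_like(model.params[k].data) for k in names}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    trace: dict[str, list[float]] = {"train": [], "val": []}
    best_val = np.inf
    best_params: dict[str, np.ndarray] | None = None
    stall = 0

    for sweep in range(tc.epochs_max):
        order = rng.permutation(x_train.shape[0])
        batch_losses = []
        for lo in range(0, order.shape[0], tc.batch_size):
            sel = order[lo : lo + tc.batch_size]
            for t in model.params.values():
                t.zero_grad()
            sw = weights[y_train[sel]] if weights is not None else None
            loss = model.loss(x_train[sel], y_train[sel], sample_weight=sw)
            if not np.isfinite(loss.data):
                raise TrainingError(
                    f"non-finite loss at pass {sweep}, batch {lo // tc.batch_size}"
                )
            loss.backward()
            step += 1
            for k in names:
                p = model.params[k]
                g = p.grad if p.grad is not None else np.zeros_like(p.data)
                m[k] = beta1 * m[k] + (1 - beta1) * g
                v[k] = beta2 * v[k] + (1 - beta2) * g * g
                mhat = m[k] / (1 - beta1**step)
                vhat = v[k] / (1 - beta2**step)
                p.data = p.data - tc.learning_rate * mhat / (np.sqrt(vhat) + eps)
            batch_losses.append(float(loss.data))
        val_loss = float(model.loss(x_val, y_val).data)
        train_loss = float(np.mean(batch_losses))
        trace["train"].append(train_loss)
        trace["val"].append(val_loss)
        logger.info(
            "pass %d train_loss %.4f val_loss %.4f", sweep, train_loss, val_loss
        )
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_params = {k: model.params[k].data.copy() for k in names}
            stall = 0
        else:
            stall += 1
            if stall >= tc.patience:
                logger.info("early stop at pass %d (patience %d)", sweep, tc.patience)
                break
    if best_params is not None and tc.learning_rate > 0:
        for k in names:
            model.params[k].data = best_params[k]
    return model, trace


def confusion_matrix(labels_true: np.ndarray, labels_pred: np.ndarray) -> np.ndarray:
    """5x5 count matrix, rows = true stage, columns = predicted stage."""
    labels_true = np.asarray(labels_true, dtype=np.int64)
    labels_pred = np.asarray(labels_pred, dtype=np.int64)
    if labels_true.shape != labels_pred.shape:
        raise ValidationError("label arrays must have equal length")
    out = np.zeros((N_STAGES, N_STAGES), dtype=np.int64)
    np.add.at(out, (labels_true, labels_pred), 1)
    return out


def report_from_predictions(
    labels_true: np.ndarray, labels_pred: np.ndarray
) -> EvaluationReport:
    """Compute accuracy, macro-F1 and Cohen's kappa from label pairs.

    Macro-F1 averages per-class F1 over all five stages; a stage absent
    from both truth and prediction contributes F1 = 0.  Kappa uses the
    marginal-product chance agreement p_e; the degenerate case p_e = 1 is
    reported as kappa 0.
    """
    conf = confusion_matrix(labels_true, labels_pred)
    total = conf.sum()
    if total == 0:
        raise ValidationError("cannot evaluate an empty split")
    accuracy = float(np.trace(conf) / total)
    f1 = np.zeros(N_STAGES)
    for k in range(N_STAGES):
        tp = conf[k, k]
        denom = conf[k, :].sum() + conf[:, k].sum()  # 2 TP + FP + FN
        f1[k] = 2.0 * tp / denom if denom > 0 else 0.0
    p_o = accuracy
    p_e = float((conf.sum(axis=1) * conf.sum(axis=0)).sum() / total**2)
    kappa = 0.0 if np.isclose(p_e, 1.0) else float((p_o - p_e) / (1.0 - p_e))
    return EvaluationReport(
        accuracy=accuracy,
        mf1=float(f1.mean()),
        kappa=kappa,
        confusion=conf,
        per_class_f1=f1,
    )


def evaluate(
    model: MganetModel,
    data: LabeledRecording,
    split: str = "test",
    normalize: bool = True,
) -> EvaluationReport:
    """Evaluate a trained model on one of the recording's splits."""
    idx = {"train": data.train_idx, "val": data.val_idx, "test": data.test_idx}[split]
    if idx.shape[0] == 0:
        raise ValidationError(f"split {split!r} is empty")
    windows = _prepare(data, model.config.context_len, normalize)
    preds = model.predict(windows[idx])
    return report_from_predictions(data.labels[idx], preds)


def run_ablation(
    data: LabeledRecording,
    base_config: TrainingConfig,
    model_config: ModelConfig = ModelConfig(),
    graph: ChannelGraph | None = None,
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Train all eight ablation variants with the same seed and splits.

    Returns a table with columns (variant, use_rnn, use_st_attention,
    use_tse, accuracy, mf1, kappa) and a dict of per-variant confusion
    matrices.
    """
    graph = graph or default_graph()
    rows = []
    confusions: dict[str, np.ndarray] = {}
    for a in (False, True):
        for b in (False, True):
            for c in (False, True):
                flags = AblationFlags(use_rnn=a, use_st_attention=b, use_tse=c)
                tc = replace(base_config, ablation_flags=flags)
                model = assemble_model(
                    graph, data.features.shape[2], model_config, flags, seed=tc.seed
                )
                model, _ = train_model(model, data, tc)
                report = evaluate(model, data, "test", normalize=tc.normalize)
                name = flags.variant_name()
                logger.info(
                    "ablation %-12s acc %.3f mf1 %.3f kappa %.3f",
                    name, report.accuracy, report.mf1, report.kappa,
                )
                rows.append(
                    {
                        "variant": name,
                        "use_rnn": a,
                        "use_st_attention": b,
                        "use_tse": c,
                        "accuracy": report.accuracy,
                        "mf1": report.mf1,
                        "kappa": report.kappa,
                    }
                )
                confusions[name] = report.confusion
    return pd.DataFrame(rows), confusions


def head_sweep(
    data: LabeledRecording,
    heads_list: tuple[int, ...] = (2, 4, 8, 16, 20),
    base_config: TrainingConfig = TrainingConfig(),
    model_config: ModelConfig = ModelConfig(),
    graph: ChannelGraph | None = None,
) -> pd.DataFrame:
    """Accuracy/macro-F1 as a function of the attention head count."""
    graph = graph or default_graph()
    rows = []
    for h in heads_list:
        cfg = replace(model_config, n_heads=h)
        model = assemble_model(
            graph, data.features.shape[2], cfg, base_config.ablation_flags,
            seed=base_config.seed,
        )
        model, _ = train_model(model, data, base_config)
        report = evaluate(model, data, "test", normalize=base_config.normalize)
        logger.info("heads %2d acc %.3f mf1 %.3f", h, report.accuracy, report.mf1)
        rows.append({"heads": h, "accuracy": report.accuracy, "mf1": report.mf1})
    return pd.DataFrame(rows)


def export_hypnogram(
    labels_true: np.ndarray,
    labels_pred: np.ndarray,
    path: str | Path,
    plot_path: str | Path | None = None,
) -> None:
    """Write the true/predicted stage traces as TSV (and optionally plot).

    Columns: epoch_index, true_stage, pred_stage.
    """
    labels_true = np.asarray(labels_true, dtype=np.int64)
    labels_pred = np.asarray(labels_pred, dtype=np.int64)
    if labels_true.shape != labels_pred.shape:
        raise ValidationError("label arrays must have equal length")
    with open(path, "w") as fh:
        fh.write("epoch_index\ttrue_stage\tpred_stage\n")
        for i, (yt, yp) in enumerate(zip(labels_true, labels_pred)):
            fh.write(f"{i}\t{STAGES[yt]}\t{STAGES[yp]}\n")
    if plot_path is not None:
        plot_hypnogram(labels_true, labels_pred, plot_path)


def export_predictions(
    labels_pred: np.ndarray, probs: np.ndarray, path: str | Path
) -> None:
    """Write per-epoch stage probabilities as TSV.

    Columns: epoch_index, stage, p_W, p_N1, p_N2, p_N3, p_REM.
    """
    labels_pred = np.asarray(labels_pred, dtype=np.int64)
    probs = np.asarray(probs, dtype=float)
    with open(path, "w") as fh:
        fh.write("epoch_index\tstage\t" + "\t".join(f"p_{s}" for s in STAGES) + "\n")
        for i, (lab, row) in enumerate(zip(labels_pred, probs)):
            cells = "\t".join(f"{p:.6f}" for p in row)
            fh.write(f"{i}\t{STAGES[lab]}\t{cells}\n")


def plot_hypnogram(
    labels_true: np.ndarray, labels_pred: np.ndarray, path: str | Path
) -> None:
    """Stacked true/predicted hypnogram plot, stage axis W, REM, N1, N2, N3."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    display_rank = {STAGES.index(s): i for i, s in enumerate(HYPNOGRAM_ORDER)}
    fig, axes = plt.subplots(2, 1, figsize=(10, 4), sharex=True)
    for ax, labels, title in (
        (axes[0], labels_true, "reference"),
        (axes[1], labels_pred, "predicted"),
    ):
        ranks = [display_rank[int(l)] for l in labels]
        ax.step(np.arange(len(labels)), ranks, where="post", lw=0.8)
        ax.set_yticks(range(len(HYPNOGRAM_ORDER)))
        ax.set_yticklabels(HYPNOGRAM_ORDER)
        ax.invert_yaxis()
        ax.set_ylabel(title)
    axes[1].set_xlabel("epoch")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
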