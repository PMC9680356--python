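"""Two-stage training: (1) supervised pretraining on a source domain,
(2) fine-tuning the multi-exit student on the target domain under
frozen-teacher distillation plus self-distillation.

Both stages use momentum SGD with a piecewise-constant learning-rate
schedule (see :class:`~cytodistill.losses.DistillConfig` for the default
hyperparameters).  All randomness (batch order, augmentation) derives
from a single seed, and the numpy backend has no nondeterministic
kernels, so identical seeds reproduce final weights bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from . import nn
from .data import AugmentPolicy, LabeledImageSet, augment, compute_norm_stats, resize_image
from .losses import DistillConfig, cross_entropy, soften, total_loss
from .metrics import ensemble_predict, softmax
from .models import ExitBundle, MultiExitStudent

logger = logging.getLogger(__name__)

__all__ = [
    "pretrain", "transfer_load", "finetune_distill", "run_manifest",
    "dataset_fingerprint", "prepare_split_arrays",
]


def _normalize_chw(img: np.ndarray, mean, std) -> np.ndarray:
    """(H, W, 3) [0,1] -> normalized (3, H, W) float32."""
    return ((img - mean) / std).transpose(2, 0, 1).astype(np.float32)


def prepare_split_arrays(dataset: LabeledImageSet, split: str, image_size: int,
                         mean, std):
    """Resize-only preprocessing for validation/test: (N, 3, S, S), labels."""
    idx = dataset.indices(split)
    xs = np.stack([
        _normalize_chw(resize_image(dataset.load_array(i), image_size), mean, std)
        for i in idx])
    ys = dataset.labels[idx]
    return xs, ys


def _augmented_batch(raw_images, batch_idx, policy, mean, std, rng):
    xs = []
    for i in batch_idx:
        seed = int(rng.integers(0, 2 ** 31 - 1))
        xs.append(_normalize_chw(augment(raw_images[i], policy, seed), mean, std))
    return np.stack(xs)


def _eval_accuracy(model, x, y, batch_size=128):
    """Validation accuracy; for multi-exit models returns
    (per_exit_accuracies, ensemble_accuracy)."""
    model.eval()
    outs = None
    for s in range(0, x.shape[0], batch_size):
        res = model(x[s:s + batch_size])
        if isinstance(res, ExitBundle):
            parts = [z.data for z in res.logits_per_exit]
        else:
            parts = [res.data]
        if outs is None:
            outs = [[p] for p in parts]
        else:
            for acc, p in zip(outs, parts):
                acc.append(p)
    model.train()
    logits = [np.concatenate(a) for a in outs]
    accs = [float((z.argmax(axis=1) == y).mean()) for z in logits]
    if len(logits) > 1:
        ens = ensemble_predict([softmax(z) for z in logits])
        return accs, float((ens.argmax(axis=1) == y).mean())
    return accs, accs[0]


def _check_finite(value: float, what: str) -> float:
    if not np.isfinite(value):
        raise FloatingPointError(f"{what} became non-finite ({value})")
    return value


def pretrain(model, source_set: LabeledImageSet, cfg: DistillConfig,
             seed: int = 0, image_size: int = 64,
             augment_policy: AugmentPolicy | None = None) -> dict:
    """Stage 1: plain supervised (cross-entropy) training.

    For a plain classifier the loss is CE on its logits; for a multi-exit
    model every exit gets CE supervision (multi-head CE).  Returns the
    best-validation checkpoint: ``{"state_dict", "history",
    "best_val_accuracy", "norm_stats"}``.
    """
    if source_set.split_assignment is None:
        raise ValueError("source_set needs a train/val split (use split_dataset)")
    head_dim = _head_out_features(model)
    if head_dim != source_set.n_classes:
        raise ValueError(
            f"model head emits {head_dim} classes but the source set has "
            f"{source_set.n_classes}")
    policy = augment_policy or AugmentPolicy(output_size=image_size)
    rng = np.random.default_rng(seed)
    mean, std = compute_norm_stats(source_set, "train", image_size)
    train_idx = source_set.indices("train")
    raw = {i: source_set.load_array(i) for i in train_idx}
    labels = source_set.labels
    x_val, y_val = prepare_split_arrays(source_set, "val", image_size, mean, std)

    opt = nn.SGD(model.parameters(), cfg.lr, cfg.momentum, cfg.weight_decay)
    best = {"val_accuracy": -1.0, "state": None}
    history = []
    model.train()
    for epoch in range(cfg.epochs):
        opt.lr = nn.lr_at_epoch(epoch, cfg.lr, cfg.lr_milestones, cfg.lr_gamma)
        order = np.array(train_idx)
        rng.shuffle(order)
        losses = []
        for s in range(0, len(order), cfg.batch_size):
            bidx = order[s:s + cfg.batch_size]
            xb = _augmented_batch(raw, bidx, policy, mean, std, rng)
            yb = labels[bidx]
            out = model(xb)
            if isinstance(out, ExitBundle):
                loss = None
                for z in out.logits_per_exit:
                    term = cross_entropy(soften(z, 1.0), yb)
                    loss = term if loss is None else loss + term
            else:
                loss = cross_entropy(soften(out, 1.0), yb)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(_check_finite(loss.item(), "pretrain loss"))
        _, val_acc = _eval_accuracy(model, x_val, y_val)
        history.append({"epoch": epoch, "lr": opt.lr,
                        "train_loss": float(np.mean(losses)),
                        "val_accuracy": val_acc})
        if val_acc >= best["val_accuracy"]:
            best = {"val_accuracy": val_acc, "state": model.state_dict()}
    model.load_state_dict(best["state"])
    return {"state_dict": best["state"], "history": history,
            "best_val_accuracy": best["val_accuracy"],
            "norm_stats": (mean, std)}


def _head_out_features(model) -> int:
    if isinstance(model, MultiExitStudent):
        return model.config.num_classes
    return model.fc.weight.shape[1]


def transfer_load(student, checkpoint, num_target_classes: int,
                  reinit_heads: bool = True):
    """Copy backbone (stem + stages) weights from a checkpoint into a
    student; exit branches and classifier heads keep their fresh
    initialization for the target class count.

    ``checkpoint`` is a state dict or a path saved by
    :func:`~cytodistill.models.save_checkpoint`.  With
    ``reinit_heads=False`` every tensor with a matching name and shape is
    copied.  Returns ``(student, report)`` where the report lists
    transferred vs freshly initialized tensors.
    """
    from .models import load_checkpoint

    if isinstance(checkpoint, (str, Path)):
        state, _ = load_checkpoint(checkpoint)
    else:
        state = dict(checkpoint)
    own = dict(student.named_parameters())
    own.update(dict(student.named_buffers()))
    transferred, skipped = [], []
    for name, target in own.items():
        backbone = name.startswith(("stem.", "stages."))
        eligible = backbone or not reinit_heads
        src = state.get(name)
        if eligible and src is not None and tuple(src.shape) == tuple(target.shape if isinstance(target, np.ndarray) else target.data.shape):
            if isinstance(target, np.ndarray):
                target[...] = src
            else:
                target.data = np.array(src, dtype=np.float32)
            transferred.append(name)
        else:
            skipped.append(name)
    if not transferred:
        raise ValueError("no overlapping backbone tensors between checkpoint "
                         "and student")
    if _head_out_features(student) != num_target_classes:
        raise ValueError(
            f"student head emits {_head_out_features(student)} classes, "
            f"expected {num_target_classes}")
    report = {"transferred": transferred, "reinitialized": skipped}
    return student, report


def finetune_distill(student: MultiExitStudent, teacher, target_set: LabeledImageSet,
                     cfg: DistillConfig, seed: int = 0, image_size: int = 64,
                     augment_policy: AugmentPolicy | None = None,
                     log_file=None):
    """Stage 2: optimize the multi-exit student under the combined
    knowledge-distillation + self-distillation objective with a frozen
    teacher.

    ``teacher=None`` trains the multi-head cross-entropy baseline (per-exit
    CE supervision, no distillation terms).  Per-epoch history records each
    exit's validation accuracy and the ensemble accuracy; the returned
    student carries the best-ensemble-validation weights.  The teacher is
    verified frozen before training and hashed before/after.
    """
    if target_set.split_assignment is None:
        raise ValueError("target_set needs a train/val split (use split_dataset)")
    if teacher is not None and not teacher.frozen:
        raise ValueError("teacher has trainable parameters; freeze it before "
                         "distillation (teacher.freeze())")
    policy = augment_policy or AugmentPolicy(output_size=image_size)
    rng = np.random.default_rng(seed)
    mean, std = compute_norm_stats(target_set, "train", image_size)
    train_idx = target_set.indices("train")
    raw = {i: target_set.load_array(i) for i in train_idx}
    labels = target_set.labels
    x_val, y_val = prepare_split_arrays(target_set, "val", image_size, mean, std)
    teacher_hash_before = teacher.param_hash() if teacher is not None else None
    if teacher is not None:
        teacher.eval()

    opt = nn.SGD(student.parameters(), cfg.lr, cfg.momentum, cfg.weight_decay)
    best = {"ensemble_val_accuracy": -1.0, "state": None}
    history = []
    log_fh = open(log_file, "w") if log_file else None
    step = 0
    student.train()
    try:
        for epoch in range(cfg.epochs):
            opt.lr = nn.lr_at_epoch(epoch, cfg.lr, cfg.lr_milestones, cfg.lr_gamma)
            order = np.array(train_idx)
            rng.shuffle(order)
            losses = []
            for s in range(0, len(order), cfg.batch_size):
                bidx = order[s:s + cfg.batch_size]
                xb = _augmented_batch(raw, bidx, policy, mean, std, rng)
                yb = labels[bidx]
                t_logits = teacher(xb).data if teacher is not None else None
                bundle = student(xb)
                loss, breakdown = total_loss(bundle, t_logits, yb, cfg)
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(_check_finite(loss.item(), "distillation loss"))
                if log_fh:
                    log_fh.write(json.dumps(
                        {"epoch": epoch, "step": step, **breakdown}) + "\n")
                step += 1
            exit_accs, ens_acc = _eval_accuracy(student, x_val, y_val)
            history.append({"epoch": epoch, "lr": opt.lr,
                            "train_loss": float(np.mean(losses)),
                            "exit_val_accuracy": exit_accs,
                            "ensemble_val_accuracy": ens_acc})
            if ens_acc >= best["ensemble_val_accuracy"]:
                best = {"ensemble_val_accuracy": ens_acc,
                        "state": student.state_dict()}
    finally:
        if log_fh:
            log_fh.close()
    student.load_state_dict(best["state"])
    teacher_hash_after = teacher.param_hash() if teacher is not None else None
    if teacher is not None and teacher_hash_before != teacher_hash_after:
        raise RuntimeError("teacher parameters changed during distillation")
    result = {
        "history": history,
        "best_ensemble_val_accuracy": best["ensemble_val_accuracy"],
        "teacher_hash_before": teacher_hash_before,
        "teacher_hash_after": teacher_hash_after,
        "norm_stats": (mean, std),
    }
    return student, result


def dataset_fingerprint(dataset: LabeledImageSet) -> str:
    """Content hash of a dataset (pixel bytes + labels + class names)."""
    h = hashlib.sha256()
    for name in dataset.class_names:
        h.update(name.encode())
    for i in range(len(dataset)):
        arr = dataset.load_array(i)
        h.update(np.ascontiguousarray(arr, dtype=np.float32).tobytes())
        h.update(str(dataset.items[i][1]).encode())
    return h.hexdigest()


def run_manifest(cfg: DistillConfig, seeds: dict, dataset_fingerprints: dict,
                 path=None, extra: dict | None = None) -> dict:
    """Reproducibility record for a run: config echo, seeds, dataset
    content hashes, and library versions.  The body is a pure function of
    its inputs, so identical runs produce identical manifests."""
    import skimage

    manifest = {
        "config": cfg.to_dict(),
        "seeds": dict(seeds),
        "dataset_fingerprints": dict(dataset_fingerprints),
        "versions": {"numpy": np.__version__, "scikit-image": skimage.__version__},
    }
    if extra:
        manifest["extra"] = dict(extra)
    if path is not None:
        with open(path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
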