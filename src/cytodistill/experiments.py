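"""Desk-scale reference experiment: the full two-model pipeline run on
the synthetic 5-class cell fixture at sizes a single CPU handles in
minutes.

Conditions: 84 images per class at 64x64 (a stratified 3:1:1 split gives
250 train / 85 val / 85 test), a reduced-depth multi-exit student
(`resnet8`: one residual block per stage, 8-64 channels) distilled for
30 epochs from a wider frozen teacher (`resnet8w`) trained on the same
split.  The optimization schedule is the reference recipe rescaled to
this regime: batch 50, initial learning rate 0.03, tenfold decays at the
same relative positions (epochs 17 and 25 of 30), momentum 0.9, weight
decay 1e-4, tau=3, lam=0.03.
"""

from __future__ import annotations

from . import nn
from .data import split_dataset
from .losses import DistillConfig
from .models import ResNetClassifier, StudentConfig, build_student
from .synth import SyntheticSpec, generate_dataset
from .train import finetune_distill, pretrain

__all__ = [
    "desk_distill_config", "desk_student_config", "make_desk_dataset",
    "train_desk_teacher", "run_desk_distillation",
]

DESK_IMAGE_SIZE = 64
DESK_N_PER_CLASS = 84  # 420 images -> 250 train / 85 val / 85 test at 3:1:1


def desk_distill_config(epochs: int = 30, **overrides) -> DistillConfig:
    """Reference hyperparameters rescaled to the desk fixture."""
    milestones = (max(1, round(epochs * 100 / 180)), max(2, round(epochs * 150 / 180)))
    base = dict(epochs=epochs, batch_size=50, lr=0.03, lr_milestones=milestones)
    base.update(overrides)
    return DistillConfig(**base)


def desk_student_config(**overrides) -> StudentConfig:
    base = dict(backbone_id="resnet8", gc_reduction_ratio=4, num_classes=5)
    base.update(overrides)
    return StudentConfig(**base)


def make_desk_dataset(seed: int, n_per_class: int = DESK_N_PER_CLASS,
                      image_size: int = DESK_IMAGE_SIZE):
    """Synthetic 5-class dataset with a stratified 3:1:1 split."""
    spec = SyntheticSpec(image_size=image_size)
    ds = generate_dataset(spec, n_per_class, seed=seed)
    return split_dataset(ds, seed=seed)


def train_desk_teacher(dataset, seed: int, epochs: int = 10,
                       image_size: int = DESK_IMAGE_SIZE) -> ResNetClassifier:
    """Supervised teacher (wider reduced-depth net), frozen after training."""
    cfg = desk_distill_config(epochs=epochs)
    nn.seed_init(seed)
    teacher = ResNetClassifier("resnet8w", dataset.n_classes)
    pretrain(teacher, dataset, cfg, seed=seed, image_size=image_size)
    return teacher.freeze()


def run_desk_distillation(dataset, teacher, seed: int, epochs: int = 30,
                          baseline: bool = False,
                          image_size: int = DESK_IMAGE_SIZE):
    """One stage-2 run.  ``baseline=True`` trains the multi-head
    cross-entropy baseline instead (no teacher, no self-distillation).

    Returns ``(student, result)`` as from
    :func:`~cytodistill.train.finetune_distill`.
    """
    cfg = desk_distill_config(epochs=epochs,
                              use_self_distill=not baseline)
    student = build_student(desk_student_config(num_classes=dataset.n_classes),
                            init_seed=seed)
    return finetune_distill(student, None if baseline else teacher, dataset,
                            cfg, seed=seed, image_size=image_size)
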