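"""Loss functions for teacher–student distillation with a multi-exit,
self-distilling student.

The training objective combines, per exit branch m of an n-exit student:

* a knowledge-distillation term
  ``KD_m = tau^2 * KL(soften(S_m), t) + CE(softmax(S_m), y) + CE(softmax(S_n), y)``,
  where ``t`` is the frozen teacher's temperature-softened output and
  ``S_n`` the deepest exit's logits; and
* a self-distillation term (for m < n)
  ``SD_m = tau^2 * KL(soften(S_m), soften(S_n)) + lam * MSE(mu_m(F_m), F_n)``,
  in which the deepest exit acts as an internal teacher: its logits and
  features enter as constants (stop-gradient), so knowledge flows from
  deep to shallow only.

The total objective sums ``KD_m + SD_m`` over all exits.  Summed
literally, the deep-supervision term ``CE(softmax(S_n), y)`` recurs once
per exit; ``dedup_deep_ce=True`` counts it once overall instead (the two
conventions differ by exactly ``(n-1) * CE(softmax(S_n), y)``).

The KL direction is configurable: ``student_to_teacher`` places the
student's softened distribution in the log numerator (sum p_s log(p_s/p_t));
``teacher_to_student`` is the conventional distillation direction.

All functions accept either :class:`~cytodistill.nn.Tensor` or plain
numpy arrays and return a scalar Tensor (use ``.item()`` for the float).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
import numpy as np

from .nn import Tensor

logger = logging.getLogger(__name__)

#: probabilities are clamped to this floor before taking logs
LOG_EPS = 1e-12

_KL_DIRECTIONS = ("student_to_teacher", "teacher_to_student")


@dataclass
class DistillConfig:
    """Training hyperparameters.

    Defaults are the reference schedule for full-scale runs: 180 epochs of
    momentum SGD at batch 128, initial learning rate 0.1 decayed tenfold
    at epochs 100 and 150, weight decay 1e-4, momentum 0.9, distillation
    temperature tau=3 and feature-loss weight lam=0.03.
    """

    tau: float = 3.0
    lam: float = 0.03
    kl_direction: str = "student_to_teacher"
    dedup_deep_ce: bool = False
    use_self_distill: bool = True
    epochs: int = 180
    batch_size: int = 128
    lr: float = 0.1
    lr_milestones: tuple = (100, 150)
    lr_gamma: float = 0.1
    weight_decay: float = 1e-4
    momentum: float = 0.9

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if self.lam < 0:
            raise ValueError(f"lam must be >= 0, got {self.lam}")
        if self.kl_direction not in _KL_DIRECTIONS:
            raise ValueError(
                f"kl_direction must be one of {_KL_DIRECTIONS}, got {self.kl_direction!r}")
        self.lr_milestones = tuple(self.lr_milestones)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["lr_milestones"] = list(self.lr_milestones)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DistillConfig":
        return cls(**d)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def soften(logits, tau: float) -> Tensor:
    """Temperature-scaled softmax: t_k = exp(z_k/tau) / sum_j exp(z_j/tau).

    Stabilized by subtracting the row maximum (softmax is shift-invariant,
    so this changes nothing analytically).  tau=1 is the ordinary softmax;
    larger tau flattens the distribution toward uniform.
    """
    if tau <= 0:
        raise ValueError(f"temperature must be > 0, got {tau}")
    z = _as_tensor(logits)
    scaled = z * (1.0 / float(tau))
    shift = Tensor(scaled.data.max(axis=-1, keepdims=True))
    e = (scaled - shift).exp()
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(predicted_probs, true_labels) -> Tensor:
    """Mean cross-entropy -(1/n) sum_i log p_i[y_i] for probability rows.

    Rows must already be normalized (checked to 1e-4).  A zero probability
    at the true class is clamped at ``LOG_EPS`` and logged rather than
    producing an infinite loss.
    """
    p = _as_tensor(predicted_probs)
    y = np.asarray(true_labels)
    n, m = p.shape
    if y.min() < 0 or y.max() >= m:
        raise ValueError(f"labels must lie in [0, {m}), got range [{y.min()}, {y.max()}]")
    rowsums = p.data.sum(axis=-1)
    if not np.allclose(rowsums, 1.0, atol=1e-4):
        raise ValueError("predicted_probs rows must sum to 1")
    onehot = Tensor(np.eye(m, dtype=p.data.dtype)[y])
    picked = (p * onehot).sum(axis=-1)
    if np.any(picked.data <= LOG_EPS):
        logger.warning("cross_entropy: clamping %d zero probabilities at the true class",
                       int(np.sum(picked.data <= LOG_EPS)))
    return -(picked.clamp_min(LOG_EPS).log().mean())


def _kl_probs(p: Tensor, q: Tensor) -> Tensor:
    """Batch-mean KL(p || q) for probability rows, logs clamped at LOG_EPS."""
    log_ratio = p.clamp_min(LOG_EPS).log() - q.clamp_min(LOG_EPS).log()
    return (p * log_ratio).sum(axis=-1).mean()


def kl_distill(student_logits, teacher_logits, tau: float,
               direction: str = "student_to_teacher") -> Tensor:
    """Temperature-softened KL divergence between two logit sets.

    ``student_to_teacher`` returns mean_i KL(p_i || q_i) with p the
    student's softened rows (student distribution in the log numerator);
    ``teacher_to_student`` returns mean_i KL(q_i || p_i).
    """
    s = _as_tensor(student_logits)
    t = _as_tensor(teacher_logits)
    if s.shape != t.shape:
        raise ValueError(f"logit shapes differ: {s.shape} vs {t.shape}")
    if direction not in _KL_DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}")
    p = soften(s, tau)
    q = soften(t, tau)
    return _kl_probs(p, q) if direction == "student_to_teacher" else _kl_probs(q, p)


def exit_kd_loss(exit_logits, teacher_soft, labels, deepest_logits,
                 cfg: DistillConfig) -> Tensor:
    """Knowledge-distillation loss for one exit:
    tau^2 * KL(soften(S_m), t) + CE(softmax(S_m), y) + CE(softmax(S_n), y).

    ``teacher_soft`` must be the teacher's probabilities softened at
    ``cfg.tau``; tau^2 multiplies only the KL term, restoring the gradient
    magnitude that temperature scaling divides away.
    """
    s_m = _as_tensor(exit_logits)
    t = _as_tensor(teacher_soft).detach()
    s_n = _as_tensor(deepest_logits)
    p_m = soften(s_m, cfg.tau)
    if cfg.kl_direction == "student_to_teacher":
        kl = _kl_probs(p_m, t)
    else:
        kl = _kl_probs(t, p_m)
    ce_m = cross_entropy(soften(s_m, 1.0), labels)
    ce_n = cross_entropy(soften(s_n, 1.0), labels)
    return (cfg.tau ** 2) * kl + ce_m + ce_n


def self_distill_loss(exit_logits, deepest_logits, unified_features,
                      deepest_features, cfg: DistillConfig,
                      exit_index: int | None = None) -> Tensor:
    """Self-distillation loss for one shallow exit:
    tau^2 * KL(soften(S_m), soften(S_n)) + lam * MSE(mu_m(F_m), F_n).

    The deepest exit's logits and features are treated as constants
    (stop-gradient): the deep classifier teaches the shallow ones without
    being pulled toward them.  MSE is the mean over all feature elements,
    so ``lam`` is independent of feature-map resolution.
    """
    s_m = _as_tensor(exit_logits)
    s_n = _as_tensor(deepest_logits).detach()
    f_m = _as_tensor(unified_features)
    f_n = _as_tensor(deepest_features).detach()
    if f_m.shape != f_n.shape:
        where = f" at exit {exit_index}" if exit_index is not None else ""
        raise ValueError(
            f"unified feature shape {f_m.shape} does not match deepest "
            f"feature shape {f_n.shape}{where}")
    kl = kl_distill(s_m, s_n, cfg.tau, cfg.kl_direction)
    mse = ((f_m - f_n) ** 2.0).mean()
    return (cfg.tau ** 2) * kl + cfg.lam * mse


def total_loss(bundle, teacher_logits, labels, cfg: DistillConfig):
    """Total training objective over all exits, with a per-term breakdown.

    ``bundle`` is an ExitBundle (attributes ``logits_per_exit``,
    ``features_per_exit``, ``n``).  With ``teacher_logits=None`` the
    external-teacher KL and the deep-supervision CE are dropped, leaving
    per-exit CE supervision (the multi-head cross-entropy baseline);
    ``cfg.use_self_distill=False`` additionally drops the SD terms.

    Returns ``(loss, breakdown)`` where breakdown maps term names to
    floats for logging.
    """
    n = bundle.n
    if n < 2:
        raise ValueError("self-distillation requires at least 2 exits")
    logits = bundle.logits_per_exit
    feats = bundle.features_per_exit
    s_n = logits[-1]
    f_n = feats[-1]
    breakdown = {"exit_kd": [], "self_distill": []}
    total = Tensor(0.0)
    teacher_soft = None
    if teacher_logits is not None:
        teacher_soft = soften(_as_tensor(teacher_logits).detach(), cfg.tau)
    for m in range(n):
        if teacher_soft is not None:
            kd = exit_kd_loss(logits[m], teacher_soft, labels, s_n, cfg)
        else:
            kd = cross_entropy(soften(_as_tensor(logits[m]), 1.0), labels)
        breakdown["exit_kd"].append(kd.item())
        total = total + kd
        if cfg.use_self_distill and m < n - 1:
            sd = self_distill_loss(logits[m], s_n, feats[m], f_n, cfg, exit_index=m + 1)
            breakdown["self_distill"].append(sd.item())
            total = total + sd
        else:
            breakdown["self_distill"].append(0.0)
    if cfg.dedup_deep_ce and teacher_soft is not None:
        ce_n = cross_entropy(soften(_as_tensor(s_n), 1.0), labels)
        total = total - (n - 1) * ce_n
        breakdown["dedup_correction"] = -(n - 1) * ce_n.item()
    breakdown["total"] = total.item()
    return total, breakdown
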