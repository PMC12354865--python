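"""Training the MIL risk model on disease-free survival labels.

The objective is the negative Cox partial log-likelihood with Breslow tie
handling, computed over risk sets formed within each mini-batch of patients,
plus L1 and L2 penalties on the weight matrices. Each epoch re-samples up to
512 tiles per bag without replacement, so over many epochs the network sees
every tile. Model selection is by Harrell's concordance index on the
validation split, computed on full (unsampled) bags for determinism; early
stopping uses a patience counter on that metric. Patients are split
4:4:2 into train/validation/test at the patient level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from lifelines.utils import concordance_index as _lifelines_cindex

from .bags import FeatureBag
from .model import MILRiskModel, ModelConfig
from .nn import Tensor, concat

__all__ = ["TrainConfig", "SurvivalLabel", "TrainingLog", "split_patients",
           "sample_bag", "cox_loss", "concordance_index", "train", "score_bags"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    tiles_per_bag: int = 512
    batch_size: int = 64
    lr: float = 1e-4
    l1_weight: float = 0.001
    l2_weight: float = 0.001
    max_epochs: int = 50
    patience: int = 15
    split_ratio: tuple = (4, 4, 2)
    seed: int = 0

    def __post_init__(self):
        if min(self.tiles_per_bag, self.batch_size, self.max_epochs) < 1 or self.lr <= 0:
            raise ValueError("tiles_per_bag, batch_size, max_epochs must be >= 1; lr > 0")
        if self.l1_weight < 0 or self.l2_weight < 0:
            raise ValueError("regularization weights must be >= 0")
        if self.patience < 0 or self.patience > self.max_epochs:
            raise ValueError("need 0 <= patience <= max_epochs")
        if any(r < 0 for r in self.split_ratio) or sum(self.split_ratio) <= 0:
            raise ValueError("split_ratio parts must be >= 0 with positive sum")


@dataclass(frozen=True)
class SurvivalLabel:
    patient_id: str
    time_months: float
    event: int

    def __post_init__(self):
        if not np.isfinite(self.time_months) or self.time_months <= 0:
            raise ValueError(f"time must be finite and positive, got {self.time_months}")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


def split_patients(patients: list, ratio: tuple = (4, 4, 2), seed: int = 0):
    """Disjoint, exhaustive patient-level split by largest-remainder apportionment."""
    patients = list(patients)
    n = len(patients)
    nonzero_parts = sum(1 for r in ratio if r > 0)
    if n < nonzero_parts:
        raise ValueError(f"cannot split {n} patients into {nonzero_parts} nonempty parts")
    total = sum(ratio)
    quotas = [n * r / total for r in ratio]
    sizes = [int(np.floor(q)) for q in quotas]
    remainder = n - sum(sizes)
    # distribute by largest fractional part, ties broken by part order
    fracs = sorted(range(len(ratio)), key=lambda i: (-(quotas[i] - sizes[i]), i))
    for i in fracs[:remainder]:
        sizes[i] += 1
    perm = np.random.default_rng(seed).permutation(n)
    shuffled = [patients[i] for i in perm]
    out, start = [], 0
    for s in sizes:
        out.append(shuffled[start:start + s])
        start += s
    return tuple(out)


def sample_bag(bag: FeatureBag, k: int, rng: np.random.Generator) -> FeatureBag:
    """Sample up to k tiles without replacement; small bags pass through whole."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if bag.n_tiles <= k:
        return bag
    idx = rng.choice(bag.n_tiles, size=k, replace=False)
    return FeatureBag(slide_id=bag.slide_id, patient_id=bag.patient_id,
                      feats=bag.feats[idx], coords=bag.coords[idx],
                      slide_index=None if bag.slide_index is None else bag.slide_index[idx])


def cox_loss(scores: Tensor, times: np.ndarray, events: np.ndarray) -> Tensor:
    """Negative Cox partial log-likelihood, Breslow ties, risk sets in-batch.

    loss = -(1/D) * sum_{i: event} [ r_i - log sum_{j: t_j >= t_i} exp(r_j) ]
    with D the number of events. Requires at least one event.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    d = int(events.sum())
    if d < 1:
        raise ValueError("cox_loss needs at least one event in the batch")
    n = times.shape[0]
    if scores.shape != (n,):
        raise ValueError("scores must be a flat vector aligned with labels")
    risk_mask = (times[None, :] >= times[:, None]).astype(float)   # (i, j)
    m = float(np.max(scores.data))
    e = (scores - m).exp()
    denom = Tensor(risk_mask) @ e.reshape(n, 1)                    # (n, 1)
    log_denom = denom.reshape(n).log() + m
    contrib = (scores - log_denom) * Tensor(events.astype(float))
    return -contrib.sum() * (1.0 / d)


def concordance_index(scores, labels: list[SurvivalLabel]) -> float:
    """Harrell's C for risk scores (higher risk should fail earlier).

    Pairs (i, j) are comparable when t_i < t_j and patient i had an event;
    concordant when r_i > r_j; score ties count 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    times = np.array([l.time_months for l in labels])
    events = np.array([l.event for l in labels])
    comparable = (times[:, None] < times[None, :]) & (events[:, None] == 1)
    if not comparable.any():
        raise ValueError("no comparable pairs: concordance undefined")
    # lifelines' convention: higher prediction = longer survival
    return float(_lifelines_cindex(times, -scores, events))


@dataclass
class TrainingLog:
    epoch_losses: list = field(default_factory=list)
    epoch_val_cindex: list = field(default_factory=list)
    best_epoch: int = -1
    best_val_cindex: float = -np.inf
    stopped_early: bool = False


def score_bags(model: MILRiskModel, bags: list[FeatureBag]) -> np.ndarray:
    return np.array([model.forward(b.feats.astype(np.float64), b.patient_id).risk
                     for b in bags])


def _penalty(model: MILRiskModel, l1: float, l2: float) -> Tensor | float:
    if l1 == 0 and l2 == 0:
        return 0.0
    terms = []
    for name in model.regularizable():
        w = model.params[name]
        if l1 > 0:
            terms.append(((w * w + 1e-24) ** 0.5).sum() * l1)  # smooth |w|
        if l2 > 0:
            terms.append((w * w).sum() * l2)
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total


def train(bags: dict, labels: list[SurvivalLabel], model_cfg: ModelConfig,
          train_cfg: TrainConfig, splits=None, restore_best: bool = True):
    """Fit the MIL model; returns (model, TrainingLog).

    ``bags`` maps patient_id -> FeatureBag (one merged bag per patient).
    ``splits`` may pre-specify (train_ids, val_ids, test_ids); otherwise the
    patients are split by ``train_cfg.split_ratio``. By default the model is
    restored to the checkpoint with the best validation C-index; with
    ``restore_best=False`` the final-epoch weights are kept instead — useful
    when the downstream consumer needs tile-level resolution, which keeps
    improving after the bag-level selection metric saturates.
    """
    label_by_pid = {l.patient_id: l for l in labels}
    pids = [l.patient_id for l in labels if l.patient_id in bags]
    if splits is None:
        splits = split_patients(pids, train_cfg.split_ratio, train_cfg.seed)
    train_ids, val_ids, _test_ids = splits

    model = MILRiskModel(model_cfg)
    opt = model.make_optimizer(train_cfg.lr)
    rng = np.random.default_rng(train_cfg.seed + 1)
    tlog = TrainingLog()
    best_state = model.state_dict()
    val_bags = [bags[p] for p in val_ids]
    val_labels = [label_by_pid[p] for p in val_ids]
    no_improve = 0

    for epoch in range(train_cfg.max_epochs):
        order = rng.permutation(len(train_ids))
        losses = []
        for start in range(0, len(order), train_cfg.batch_size):
            chunk = [train_ids[i] for i in order[start:start + train_cfg.batch_size]]
            batch_labels = [label_by_pid[p] for p in chunk]
            events = np.array([l.event for l in batch_labels])
            if events.sum() == 0:
                log.warning("batch of %d patients has zero events; skipped", len(chunk))
                continue
            scores = concat([
                model.forward_tensor(
                    Tensor(sample_bag(bags[p], train_cfg.tiles_per_bag, rng)
                           .feats.astype(np.float64)),
                    training=True, rng=rng).reshape(1)
                for p in chunk])
            times = np.array([l.time_months for l in batch_labels])
            loss = cox_loss(scores, times, events)
            loss = loss + _penalty(model, train_cfg.l1_weight, train_cfg.l2_weight)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"training diverged: non-finite loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())

        val_scores = score_bags(model, val_bags)
        val_c = concordance_index(val_scores, val_labels)
        tlog.epoch_losses.append(float(np.mean(losses)) if losses else np.nan)
        tlog.epoch_val_cindex.append(val_c)
        if val_c > tlog.best_val_cindex:
            tlog.best_val_cindex = val_c
            tlog.best_epoch = epoch
            best_state = model.state_dict()
            no_improve = 0
        else:
            no_improve += 1
        if no_improve >= train_cfg.patience:
            tlog.stopped_early = epoch + 1 < train_cfg.max_epochs
            break

    if restore_best:
        model.load_state_dict(best_state)
    return model, tlog
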