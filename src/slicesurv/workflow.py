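"""Training and evaluation orchestration.

Tenfold patient-level cross-validation with an inner 90/10 train/validation
split, AdamW optimization of the combined likelihood + ranking loss, model
selection by validation time-dependent concordance (ties broken toward the
earliest epoch), fine-tuning from a pretrained state, and the attention
interpretability report (mean attention over relative slice positions, and
per-patient slices at or above the patient's median attention weight).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .imaging_io import AugmentConfig, augment_slice, preprocess_volume
from .metrics_stats import ModelPredictions, ctd_index
from .nn import AdamW, Module, Tensor, stack as nn_stack
from .representation import (
    EncoderConfig,
    SelfAttentionCTk,
    build_aggregator,
    build_backbone,
)
from .survival_head import (
    T_MAX,
    LossConfig,
    RiskNetConfig,
    RiskNetwork,
    SurvivalDistribution,
    SurvivalRecord,
    total_loss_tensor,
)
from .synthetic_cohort import CohortDataset

__all__ = [
    "CVConfig",
    "PatientData",
    "FoldResult",
    "AttentionProfile",
    "SliceFusionModel",
    "prepare_cohort",
    "train_fold",
    "train_single",
    "run_cv",
    "finetune",
    "attention_report",
    "predictions_frame",
    "attention_frame",
]


@dataclass(frozen=True)
class CVConfig:
    k_folds: int = 10
    inner_val_fraction: float = 0.1
    learning_rate: float = 1e-4
    weight_decay: float = 1e-2
    batch_size: int = 4
    epochs: int = 100
    seed: int = 0
    aggregator: str = "soft_attention"
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    risk: RiskNetConfig = field(default_factory=RiskNetConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    augment: AugmentConfig | None = field(default_factory=AugmentConfig)
    grad_clip: float | None = None  # off by default; not part of the reference recipe

    def __post_init__(self):
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if not 0.0 < self.inner_val_fraction < 1.0:
            raise ValueError("inner_val_fraction must be in (0, 1)")
        if min(self.learning_rate, self.weight_decay) < 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("hyperparameters must be positive")


@dataclass(frozen=True)
class PatientData:
    """Preprocessed, encoder-ready representation of one patient."""

    patient_id: str
    slices: np.ndarray  # (R, H, W) in [0, 1]
    relative_positions: np.ndarray
    source_indices: np.ndarray
    record: SurvivalRecord


@dataclass
class FoldResult:
    fold_id: int
    ctd: float
    flagged: bool
    predictions: ModelPredictions
    attention: dict[str, dict[str, np.ndarray]]  # patient -> positions/weights/sources
    best_epoch: int
    history: list[dict]
    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    test_ids: tuple[str, ...]

    def split_hash(self) -> str:
        payload = repr((sorted(self.train_ids), sorted(self.val_ids), sorted(self.test_ids)))
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class AttentionProfile:
    bin_edges: np.ndarray
    mean_weight: np.ndarray
    n_patients: int


class SliceFusionModel(Module):
    """Backbone encoder + slice aggregator + risk network."""

    def __init__(self, encoder_cfg: EncoderConfig | None = None,
                 aggregator: str = "soft_attention",
                 risk_cfg: RiskNetConfig | None = None, seed: int = 0):
        super().__init__()
        encoder_cfg = encoder_cfg or EncoderConfig()
        self.encoder_cfg = replace(encoder_cfg, seed=seed)
        self.aggregator_name = aggregator
        self.backbone = build_backbone(self.encoder_cfg)
        self.aggregator = build_aggregator(aggregator, self.encoder_cfg.d_e, seed=seed + 1)
        self.risk = RiskNetwork(self.encoder_cfg.d_e, risk_cfg,
                                np.random.default_rng(seed + 2))

    def trainable_parameters(self) -> list[Tensor]:
        return [p for p in self.parameters() if p.requires_grad]

    def embed_volume(self, slices: np.ndarray):
        """(R, H, W) array -> (volume embedding Tensor, attention weights array)."""
        emb = self.backbone(Tensor(np.asarray(slices)[:, None, :, :]))
        if isinstance(self.aggregator, SelfAttentionCTk):
            fused = self.aggregator(emb)
            weights = np.full(emb.shape[0], np.nan)  # not defined for this aggregator
        else:
            fused, w = self.aggregator(emb)
            weights = w.data.copy()
        return fused, weights

    def forward_batch(self, volumes: list[np.ndarray],
                      rng: np.random.Generator | None = None) -> Tensor:
        fused = [self.embed_volume(v)[0] for v in volumes]
        return self.risk(nn_stack(fused, axis=0), rng)

    def predict(self, items: list[PatientData]):
        """Evaluation-mode predictions and attention weights for a patient list."""
        was_training = self.training
        self.eval()
        try:
            dists, attention = [], {}
            for item in items:
                fused, weights = self.embed_volume(item.slices)
                logits = self.risk(fused.reshape(1, -1))
                dists.append(SurvivalDistribution(logits.softmax(axis=1).data[0]))
                attention[item.patient_id] = {
                    "relative_positions": item.relative_positions.copy(),
                    "source_indices": item.source_indices.copy(),
                    "weights": weights,
                }
        finally:
            self.train(was_training)
        preds = ModelPredictions(
            patient_ids=tuple(i.patient_id for i in items),
            distributions=tuple(dists),
            records=tuple(i.record for i in items),
        )
        return preds, attention


def prepare_cohort(cohort: CohortDataset, *, out_size: int = 32,
                   min_fraction: float = 0.02,
                   hu_window=(-1000.0, 400.0)) -> list[PatientData]:
    """Run every cohort phantom through the preprocessing pipeline."""
    items = []
    for patient in cohort.patients:
        vol, _, _ = patient.volume()
        stack, _ = preprocess_volume(vol, out_size=out_size, min_fraction=min_fraction,
                                     hu_window=hu_window,
                                     target_spacing=vol.spacing)
        items.append(PatientData(
            patient_id=patient.patient_id,
            slices=np.stack(stack.slices),
            relative_positions=stack.relative_positions,
            source_indices=stack.source_indices,
            record=patient.record,
        ))
    return items


def _augmented(item: PatientData, cfg: AugmentConfig | None,
               rng: np.random.Generator) -> np.ndarray:
    if cfg is None or cfg.apply_probability == 0.0:
        return item.slices
    return np.stack([augment_slice(s, cfg, rng) for s in item.slices])


def _safe_ctd(preds: ModelPredictions) -> float:
    try:
        return ctd_index(preds)
    except ValueError:
        return float("nan")


def train_fold(train_items: list[PatientData], val_items: list[PatientData],
               cfg: CVConfig, model: SliceFusionModel,
               rng: np.random.Generator) -> dict:
    """Optimize the model on the training split; select the epoch with the
    highest validation concordance (earliest on ties). Returns the best state,
    epoch index and per-epoch history; the model is left at the best state."""
    if not train_items or not val_items:
        raise ValueError("train and validation splits must be nonempty")
    opt = AdamW(model.trainable_parameters(), lr=cfg.learning_rate,
                weight_decay=cfg.weight_decay)
    best = {"ctd": -np.inf, "epoch": -1, "state": model.state_dict(), "loss": np.inf}
    history: list[dict] = []
    select_by_loss = np.isnan(_safe_ctd(model.predict(val_items)[0]))

    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(len(train_items))
        epoch_loss = 0.0
        for start in range(0, len(order), cfg.batch_size):
            batch = [train_items[i] for i in order[start : start + cfg.batch_size]]
            volumes = [_augmented(it, cfg.augment, rng) for it in batch]
            records = [it.record for it in batch]
            logits = model.forward_batch(volumes, rng)
            y = logits.softmax(axis=1)
            loss = total_loss_tensor(y, records, cfg.loss)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"divergent loss at epoch {epoch}: {loss.data}; "
                    f"check learning rate and inputs"
                )
            opt.zero_grad()
            loss.backward()
            if cfg.grad_clip is not None:
                opt.clip_grad_norm(cfg.grad_clip)
            opt.step()
            epoch_loss += loss.item()

        val_preds, _ = model.predict(val_items)
        val_ctd = _safe_ctd(val_preds)
        history.append({"epoch": epoch, "train_loss": epoch_loss / len(train_items),
                        "val_ctd": val_ctd})
        if select_by_loss:
            if epoch_loss < best["loss"]:
                best.update(loss=epoch_loss, epoch=epoch, state=model.state_dict())
        elif val_ctd > best["ctd"]:
            best.update(ctd=val_ctd, epoch=epoch, state=model.state_dict())

    model.load_state_dict(best["state"])
    return {"state": best["state"], "best_epoch": best["epoch"], "history": history,
            "selection": "train_loss" if select_by_loss else "val_ctd"}


def _partition(ids: list[str], k: int, rng: np.random.Generator) -> list[list[str]]:
    order = list(rng.permutation(ids))
    return [list(part) for part in np.array_split(order, k)]


def run_cv(items: list[PatientData], cfg: CVConfig,
           init_state: dict | None = None) -> list[FoldResult]:
    """Patient-level tenfold cross-validation. ``init_state`` warm-starts every
    fold from a pretrained model (the fine-tuning workflow)."""
    if len(items) < cfg.k_folds:
        raise ValueError("cohort smaller than the number of folds")
    by_id = {it.patient_id: it for it in items}
    rng = np.random.default_rng(cfg.seed)
    folds = _partition(sorted(by_id), cfg.k_folds, rng)

    results = []
    for fold_id, test_ids in enumerate(folds):
        rest = [pid for part in folds for pid in part if pid not in set(test_ids)]
        fold_rng = np.random.default_rng([cfg.seed, fold_id])
        rest = list(fold_rng.permutation(rest))
        n_val = max(1, int(round(cfg.inner_val_fraction * len(rest))))
        val_ids, train_ids = rest[:n_val], rest[n_val:]

        model = SliceFusionModel(cfg.encoder, cfg.aggregator, cfg.risk,
                                 seed=int(fold_rng.integers(2**31 - 1)))
        if init_state is not None:
            model.load_state_dict(init_state)
        fit = train_fold([by_id[p] for p in train_ids], [by_id[p] for p in val_ids],
                         cfg, model, fold_rng)
        preds, attention = model.predict([by_id[p] for p in test_ids])
        ctd = _safe_ctd(preds)
        results.append(FoldResult(
            fold_id=fold_id,
            ctd=ctd,
            flagged=bool(np.isnan(ctd)) or fit["selection"] != "val_ctd",
            predictions=preds,
            attention=attention,
            best_epoch=fit["best_epoch"],
            history=fit["history"],
            train_ids=tuple(train_ids),
            val_ids=tuple(val_ids),
            test_ids=tuple(test_ids),
        ))
    return results


def finetune(pretrained_state: dict, items: list[PatientData],
             cfg: CVConfig) -> list[FoldResult]:
    """Resume all weights from a pretrained model and re-train on a new cohort
    under the same selection rule."""
    return run_cv(items, cfg, init_state=pretrained_state)


def train_single(items: list[PatientData], cfg: CVConfig) -> tuple[SliceFusionModel, dict]:
    """Train one model on a simple 90/10 split (used to produce a pretraining
    checkpoint for the transfer-learning workflow)."""
    rng = np.random.default_rng(cfg.seed)
    ids = list(rng.permutation(sorted(it.patient_id for it in items)))
    n_val = max(1, int(round(cfg.inner_val_fraction * len(ids))))
    by_id = {it.patient_id: it for it in items}
    model = SliceFusionModel(cfg.encoder, cfg.aggregator, cfg.risk,
                             seed=int(rng.integers(2**31 - 1)))
    fit = train_fold([by_id[p] for p in ids[n_val:]], [by_id[p] for p in ids[:n_val]],
                     cfg, model, rng)
    return model, fit


def attention_report(fold_results: list[FoldResult], n_bins: int = 20
                     ) -> tuple[AttentionProfile, dict[str, np.ndarray]]:
    """Aggregate attention over relative slice positions across patients and
    folds, and flag, per patient, the slices whose weight is at or above the
    50th percentile of that patient's weight distribution."""
    positions, weights = [], []
    highlights: dict[str, np.ndarray] = {}
    n_patients = 0
    for fr in fold_results:
        for pid, att in fr.attention.items():
            w = np.asarray(att["weights"], dtype=float)
            if np.any(np.isnan(w)):
                continue
            positions.append(np.asarray(att["relative_positions"], dtype=float))
            weights.append(w)
            threshold = np.percentile(w, 50)
            highlights[pid] = np.asarray(att["source_indices"])[w >= threshold]
            n_patients += 1
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    means = np.full(n_bins, np.nan)
    if positions:
        pos = np.concatenate(positions)
        wts = np.concatenate(weights)
        which = np.clip(np.digitize(pos, edges) - 1, 0, n_bins - 1)
        for b in range(n_bins):
            sel = which == b
            if sel.any():
                means[b] = wts[sel].mean()
    return AttentionProfile(bin_edges=edges, mean_weight=means,
                            n_patients=n_patients), highlights


def predictions_frame(preds: ModelPredictions) -> pd.DataFrame:
    rows = {f"y_{m}": [d.y[m - 1] for d in preds.distributions] for m in range(1, T_MAX + 1)}
    return pd.DataFrame({"patient_id": list(preds.patient_ids), **rows})


def attention_frame(fold_results: list[FoldResult]) -> pd.DataFrame:
    rows = []
    for fr in fold_results:
        for pid, att in fr.attention.items():
            for src, pos, w in zip(att["source_indices"], att["relative_positions"],
                                   att["weights"]):
                rows.append({"patient_id": pid, "fold": fr.fold_id,
                             "source_index": int(src), "relative_position": float(pos),
                             "weight": float(w)})
    return pd.DataFrame(rows)
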