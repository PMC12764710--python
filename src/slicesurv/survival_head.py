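"""Discrete-time survival risk network with a censoring-aware two-term loss.

The network maps a fused volume embedding to a probability distribution over
monthly event-time bins (2-year horizon, 24 bins) through a shared trunk and a
cause-specific head that also receives the raw input features (residual input
connection), ending in a single softmax.

The loss combines the negative log-likelihood of the first hitting time under
censoring with an exponential ranking penalty on cumulative incidence values,
``alpha * L1 + beta * L2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .nn import Dropout, Linear, Module, Tensor, concat

T_MAX = 24

__all__ = [
    "T_MAX",
    "SurvivalRecord",
    "SurvivalDistribution",
    "RiskNetConfig",
    "LossConfig",
    "RiskNetwork",
    "forward_risk",
    "estimated_cif",
    "loss_l1",
    "loss_l2",
    "total_loss",
    "l1_loss_tensor",
    "l2_loss_tensor",
    "total_loss_tensor",
]


@dataclass(frozen=True)
class SurvivalRecord:
    """Observed follow-up: time ``s`` in months and event indicator ``k``
    (1 = death observed, 0 = censored/truncated)."""

    s: int
    k: int

    def __post_init__(self):
        if self.k not in (0, 1):
            raise ValueError(f"event indicator must be 0 or 1, got {self.k}")
        if not 1 <= self.s <= T_MAX:
            raise ValueError(f"time must be in 1..{T_MAX}, got {self.s}")

    @staticmethod
    def from_raw(time_months: float, event: int) -> "SurvivalRecord":
        """Clamp raw follow-up to the discrete horizon.

        Times beyond the horizon become censored at T_MAX; a time of 0 is
        remapped to bin 1 with a warning (a hit at month 0 is not representable
        in the first-hitting-time softmax).
        """
        s = int(round(time_months))
        k = int(event)
        if s <= 0:
            warnings.warn("survival time <= 0 remapped to month 1", stacklevel=2)
            s = 1
        if s > T_MAX:
            s, k = T_MAX, 0
        return SurvivalRecord(s=s, k=k)


@dataclass(frozen=True)
class SurvivalDistribution:
    """Predicted per-month event probabilities ``y[0] = P(s=1), ..., y[23] = P(s=24)``."""

    y: np.ndarray

    def __post_init__(self):
        y = np.asarray(self.y, dtype=np.float64)
        object.__setattr__(self, "y", y)
        if y.shape != (T_MAX,):
            raise ValueError(f"distribution must have {T_MAX} bins, got shape {y.shape}")
        if np.any(y < -1e-9) or abs(y.sum() - 1.0) > 1e-6:
            raise ValueError("distribution entries must be nonnegative and sum to 1")

    def cif(self) -> np.ndarray:
        """Cumulative incidence F(t) for t = 0..T_MAX (length 25, F(0) = 0)."""
        return np.concatenate([[0.0], np.cumsum(self.y)])


@dataclass(frozen=True)
class RiskNetConfig:
    n_hidden_layers: int = 5
    neurons_per_layer: int = 100
    dropout: float = 0.2

    def __post_init__(self):
        if self.n_hidden_layers < 1 or self.neurons_per_layer < 1:
            raise ValueError("layer counts must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


@dataclass(frozen=True)
class LossConfig:
    alpha: float = 0.5
    beta: float = 0.5
    sigma: float = 0.1
    theta: float = 1.0
    eps: float = 1e-7
    mean_normalize_l2: bool = True

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be nonnegative")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0 < self.eps <= 1e-4:
            raise ValueError("eps must be in (0, 1e-4]")


class _MLP(Module):
    def __init__(self, in_dim: int, cfg: RiskNetConfig, rng: np.random.Generator):
        super().__init__()
        dims = [in_dim] + [cfg.neurons_per_layer] * cfg.n_hidden_layers
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        for i, layer in enumerate(self.layers):
            self._modules[f"fc{i}"] = layer
        self.drop = Dropout(cfg.dropout)

    def forward(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        for layer in self.layers:
            x = self.drop(layer(x).relu(), rng)
        return x


class RiskNetwork(Module):
    """Shared trunk + single cause-specific head with residual input connection."""

    def __init__(self, in_dim: int, cfg: RiskNetConfig | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        cfg = cfg or RiskNetConfig()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.cfg = cfg
        self.in_dim = in_dim
        self.shared = _MLP(in_dim, cfg, rng)
        self.cause_specific = _MLP(cfg.neurons_per_layer + in_dim, cfg, rng)
        self.out = Linear(cfg.neurons_per_layer, T_MAX, rng)

    def forward(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        """Return unnormalized logits of shape (batch, T_MAX)."""
        if not np.all(np.isfinite(x.data)):
            raise ValueError("non-finite input to risk network")
        fs = self.shared(x, rng)
        z = concat([fs, x], axis=1)
        logits = self.out(self.cause_specific(z, rng))
        if not np.all(np.isfinite(logits.data)):
            raise ValueError("non-finite activations in risk network")
        return logits

    def predict(self, x: np.ndarray) -> list[SurvivalDistribution]:
        """Deterministic evaluation-mode prediction for a (batch, in_dim) array."""
        was_training = self.training
        self.eval()
        try:
            probs = self.forward(Tensor(np.atleast_2d(x))).softmax(axis=1).data
        finally:
            self.train(was_training)
        return [SurvivalDistribution(row) for row in probs]


def forward_risk(x: np.ndarray, net: RiskNetwork) -> SurvivalDistribution:
    """Single-volume convenience wrapper around :meth:`RiskNetwork.predict`."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.shape[0] != net.in_dim:
        raise ValueError(f"expected embedding of dimension {net.in_dim}, got shape {x.shape}")
    return net.predict(x[None, :])[0]


def estimated_cif(dist: SurvivalDistribution, t: int) -> float:
    """F(t) = sum of the per-month probabilities up to and including month t."""
    if not 0 <= t <= T_MAX:
        raise ValueError(f"t must be in 0..{T_MAX}, got {t}")
    return float(dist.cif()[t])


# ---------------------------------------------------------------------------
# Loss — tensor core (differentiable) and record-level wrappers.
# ---------------------------------------------------------------------------

def _floor(x: Tensor, eps: float) -> Tensor:
    # max(x, eps) expressed through relu so it stays differentiable
    return (x - eps).relu() + eps


def l1_loss_tensor(y: Tensor, records: list[SurvivalRecord], eps: float = 1e-7) -> Tensor:
    """Negative log-likelihood term on event-time probabilities y (batch, T_MAX).

    Uncensored patients contribute -log y_s; censored patients contribute
    -log(1 - F(s)). Logs are floored at ``eps``.
    """
    n = len(records)
    if y.shape != (n, T_MAX):
        raise ValueError(f"y must be ({n}, {T_MAX}), got {y.shape}")
    idx = np.arange(n)
    s = np.array([r.s for r in records])
    k = np.array([r.k for r in records])
    cif = y.cumsum(axis=1)
    event_p = y[idx, s - 1]
    surv_p = 1.0 - cif[idx, s - 1]
    terms = (
        Tensor(k.astype(float)) * _floor(event_p, eps).log()
        + Tensor((1 - k).astype(float)) * _floor(surv_p, eps).log()
    )
    return -terms.sum()


def l2_loss_tensor(y: Tensor, records: list[SurvivalRecord], sigma: float = 0.1,
                   theta: float = 1.0, mean_normalize: bool = True) -> Tensor:
    """Ranking term: exp(-(F_i(s_i) - F_j(s_i)) / sigma) over acceptable pairs
    (k_i = 1, s_i < s_j); mean over pairs by default, plain sum when
    ``mean_normalize`` is False. Zero when no pair is acceptable."""
    n = len(records)
    s = np.array([r.s for r in records])
    k = np.array([r.k for r in records])
    pair_i, pair_j = np.nonzero((k[:, None] == 1) & (s[:, None] < s[None, :]))
    if len(pair_i) == 0:
        return Tensor(0.0)
    cif = y.cumsum(axis=1)
    f_i = cif[pair_i, s[pair_i] - 1]
    f_j = cif[pair_j, s[pair_i] - 1]
    eta = ((f_j - f_i) * (1.0 / sigma)).exp()
    total = eta.sum() * theta
    if mean_normalize:
        total = total * (1.0 / len(pair_i))
    return total


def total_loss_tensor(y: Tensor, records: list[SurvivalRecord],
                      cfg: LossConfig | None = None) -> Tensor:
    cfg = cfg or LossConfig()
    return (
        l1_loss_tensor(y, records, cfg.eps) * cfg.alpha
        + l2_loss_tensor(y, records, cfg.sigma, cfg.theta, cfg.mean_normalize_l2) * cfg.beta
    )


def _batch_to_tensor(batch: list[tuple[SurvivalDistribution, SurvivalRecord]]):
    if not batch:
        raise ValueError("batch must be nonempty")
    y = Tensor(np.stack([d.y for d, _ in batch]))
    return y, [r for _, r in batch]


def loss_l1(batch: list[tuple[SurvivalDistribution, SurvivalRecord]],
            cfg: LossConfig | None = None) -> float:
    cfg = cfg or LossConfig()
    y, records = _batch_to_tensor(batch)
    return float(l1_loss_tensor(y, records, cfg.eps).item())


def loss_l2(batch: list[tuple[SurvivalDistribution, SurvivalRecord]],
            cfg: LossConfig | None = None) -> float:
    cfg = cfg or LossConfig()
    y, records = _batch_to_tensor(batch)
    return float(l2_loss_tensor(y, records, cfg.sigma, cfg.theta, cfg.mean_normalize_l2).item())


def total_loss(batch: list[tuple[SurvivalDistribution, SurvivalRecord]],
               cfg: LossConfig | None = None) -> float:
    cfg = cfg or LossConfig()
    return cfg.alpha * loss_l1(batch, cfg) + cfg.beta * loss_l2(batch, cfg)
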