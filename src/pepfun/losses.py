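"""Multi-label focal dice loss (MLFDL), its analytic gradient, and baselines.

For label ``m`` of sample ``n``, the sigmoid output ``p_nm`` is the
*foreground* probability and ``1 - p_nm`` the *background* probability.
Focal modulation rescales both before a two-term soft-dice loss::

    p1_nm = min(p_nm + eps1, 1) * p_nm          # foreground, eps1 in [0,1]
    p0_nm = (1 - max(p_nm - eps0, 0)) * (1-p_nm)  # background, eps0 in [0,1]

    L1_n = 1 - 2 sum_m p1 y   / (sum_m p1^2 + sum_m y^2     + delta)
    L0_n = 1 - 2 sum_m p0(1-y)/ (sum_m p0^2 + sum_m (1-y)^2 + delta)

    MLFDL = reduce_n [ omega * L1_n + (1 - omega) * L0_n ]

Because the dice denominators couple all labels of a sample, both the loss
and its gradient depend on every label's probability, not just the one being
differentiated — the property that distinguishes this loss from per-label
cross-entropy-style losses under class imbalance.

The analytic gradient is implemented independently of the autodiff tape and
serves as a verification oracle for the training path; both must agree.

Baselines: binary cross-entropy (``cel``), focal loss (``fl``), asymmetric
loss (``asl``) and plain two-term dice (``dl`` = MLFDL at eps1 = eps0 = 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from ._autodiff import Tensor

__all__ = [
    "FocalDiceConfig",
    "ModulatedProbabilities",
    "LossValue",
    "modulate_probabilities",
    "mlfdl",
    "mlfdl_gradient",
    "mlfdl_tensor",
    "baseline_loss",
    "make_loss",
    "BASELINE_LOSSES",
]

_CLIP = 1e-7


@dataclass(frozen=True)
class FocalDiceConfig:
    """Hyperparameters of the focal dice loss.

    epsilon1, epsilon0 : focal factors for foreground / background, in [0,1];
        at 1 the modulation collapses to the identity and the loss is the
        symmetric two-term dice loss.
    omega : balance between foreground and background terms, in [0,1].
    smoothing : small delta added to the dice denominators so that degenerate
        rows (e.g. all labels positive) stay finite.
    """

    epsilon1: float = 0.5
    epsilon0: float = 0.5
    omega: float = 0.5
    smoothing: float = 1e-8
    reduction: str = "mean"

    def __post_init__(self):
        for name in ("epsilon1", "epsilon0", "omega"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.smoothing < 0:
            raise ValueError("smoothing must be >= 0")
        if self.reduction not in ("mean", "sum"):
            raise ValueError("reduction must be 'mean' or 'sum'")


@dataclass
class ModulatedProbabilities:
    p1: np.ndarray
    p0: np.ndarray


@dataclass
class LossValue:
    value: float
    per_sample_fg: np.ndarray = field(default_factory=lambda: np.zeros(0))
    per_sample_bg: np.ndarray = field(default_factory=lambda: np.zeros(0))


def _check_probs(P: np.ndarray) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if ((P < 0) | (P > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    return P


def _check_labels(Y: np.ndarray, shape) -> np.ndarray:
    Y = np.asarray(Y)
    if Y.shape != shape:
        raise ValueError(f"label shape {Y.shape} does not match {shape}")
    if not np.isin(Y, (0, 1)).all():
        raise ValueError("labels must be binary")
    return Y.astype(float)


def modulate_probabilities(P, config: FocalDiceConfig) -> ModulatedProbabilities:
    """Apply the focal modulating factors elementwise."""
    P = _check_probs(P)
    p1 = np.minimum(P + config.epsilon1, 1.0) * P
    p0 = (1.0 - np.maximum(P - config.epsilon0, 0.0)) * (1.0 - P)
    return ModulatedProbabilities(p1=p1, p0=p0)


def _dice_terms(P, Y, config):
    mod = modulate_probabilities(P, config)
    d = config.smoothing
    L1 = 1.0 - 2.0 * (mod.p1 * Y).sum(1) / ((mod.p1 ** 2).sum(1) + (Y ** 2).sum(1) + d)
    L0 = 1.0 - 2.0 * (mod.p0 * (1 - Y)).sum(1) / (
        (mod.p0 ** 2).sum(1) + ((1 - Y) ** 2).sum(1) + d)
    return L1, L0


def mlfdl(P, Y, config: FocalDiceConfig = FocalDiceConfig()) -> LossValue:
    """Multi-label focal dice loss over an (N, M) probability matrix."""
    P = _check_probs(P)
    Y = _check_labels(Y, P.shape)
    L1, L0 = _dice_terms(P, Y, config)
    per = config.omega * L1 + (1 - config.omega) * L0
    value = per.mean() if config.reduction == "mean" else per.sum()
    return LossValue(value=float(value), per_sample_fg=L1, per_sample_bg=L0)


def mlfdl_gradient(P, Y, config: FocalDiceConfig = FocalDiceConfig()) -> np.ndarray:
    """Closed-form d MLFDL / d p_nm, independent of the autodiff tape.

    Piecewise chain factors: d p1/d p = 2p + eps1 where p < 1 - eps1, else 1;
    d p0/d p = 2p - 2 - eps0 where p > eps0, else -1 (the constant branch
    applies at the kink itself, which is flagged with a warning).
    """
    P = _check_probs(P)
    Y = _check_labels(Y, P.shape)
    e1, e0, w, d = config.epsilon1, config.epsilon0, config.omega, config.smoothing
    at_kink = np.isclose(P, 1 - e1, rtol=0, atol=0) | np.isclose(P, e0, rtol=0, atol=0)
    if at_kink.any():
        warnings.warn("gradient evaluated exactly at a modulation kink; "
                      "constant branch used", RuntimeWarning, stacklevel=2)
    mod = modulate_probabilities(P, config)
    D1 = (mod.p1 ** 2).sum(1, keepdims=True) + (Y ** 2).sum(1, keepdims=True) + d
    S1 = (mod.p1 * Y).sum(1, keepdims=True)
    dL1_dp1 = -2.0 * Y / D1 + 4.0 * mod.p1 * S1 / D1 ** 2

    D0 = (mod.p0 ** 2).sum(1, keepdims=True) + ((1 - Y) ** 2).sum(1, keepdims=True) + d
    S0 = (mod.p0 * (1 - Y)).sum(1, keepdims=True)
    dL0_dp0 = -2.0 * (1 - Y) / D0 + 4.0 * mod.p0 * S0 / D0 ** 2

    dp1_dp = np.where(P < 1 - e1, 2 * P + e1, 1.0)
    dp0_dp = np.where(P > e0, 2 * P - 2 - e0, -1.0)

    grad = w * dL1_dp1 * dp1_dp + (1 - w) * dL0_dp0 * dp0_dp
    if config.reduction == "mean":
        grad = grad / P.shape[0]
    return grad


def mlfdl_tensor(P: Tensor, Y, config: FocalDiceConfig = FocalDiceConfig()) -> Tensor:
    """The same loss on the autodiff tape — the path training differentiates."""
    Y = _check_labels(Y, P.shape).astype(P.data.dtype, copy=False)
    d = config.smoothing
    p1 = (P + config.epsilon1).minimum(1.0) * P
    p0 = (1.0 - (P - config.epsilon0).maximum(0.0)) * (1.0 - P)
    L1 = 1.0 - (p1 * Y).sum(axis=1) * 2.0 / (
        (p1 ** 2).sum(axis=1) + Tensor((Y ** 2).sum(1)) + d)
    L0 = 1.0 - (p0 * (1 - Y)).sum(axis=1) * 2.0 / (
        (p0 ** 2).sum(axis=1) + Tensor(((1 - Y) ** 2).sum(1)) + d)
    per = L1 * config.omega + L0 * (1 - config.omega)
    return per.mean() if config.reduction == "mean" else per.sum()


# ---------------------------------------------------------------------------
# baseline losses

BASELINE_LOSSES = ("cel", "fl", "asl", "dl")


def _bce_terms(P: Tensor, Y: np.ndarray) -> tuple[Tensor, Tensor, Tensor]:
    Pc = P.clip(_CLIP, 1 - _CLIP)
    return Pc, Pc.log(), (1.0 - Pc).log()


def _baseline_tensor(name: str, P: Tensor, Y: np.ndarray, *, gamma: float = 2.0,
                     gamma_pos: float = 0.0, gamma_neg: float = 4.0,
                     shift: float = 0.05,
                     dice: FocalDiceConfig | None = None) -> Tensor:
    name = name.lower()
    Y = np.asarray(Y).astype(P.data.dtype, copy=False)
    if name == "cel":
        Pc, logp, log1p = _bce_terms(P, Y)
        return -(logp * Y + log1p * (1 - Y)).mean()
    if name == "fl":
        Pc, logp, log1p = _bce_terms(P, Y)
        return -((1.0 - Pc) ** gamma * logp * Y + Pc ** gamma * log1p * (1 - Y)).mean()
    if name == "asl":
        Pc = P.clip(_CLIP, 1 - _CLIP)
        # probability shift on the negative term clamps easy negatives to zero loss
        Pm = (Pc - shift).maximum(0.0)
        pos = (1.0 - Pc) ** gamma_pos * Pc.log() * Y
        neg = Pm ** gamma_neg * (1.0 - Pm).clip(_CLIP, 1.0).log() * (1 - Y)
        return -(pos + neg).mean()
    if name == "dl":
        cfg = replace(dice or FocalDiceConfig(), epsilon1=1.0, epsilon0=1.0)
        return mlfdl_tensor(P, Y, cfg)
    raise ValueError(f"unknown loss {name!r}; expected one of {BASELINE_LOSSES}")


def baseline_loss(name: str, P, Y, **hyper) -> LossValue:
    """Evaluate a baseline loss on plain arrays (no gradient)."""
    P = _check_probs(P)
    Y = _check_labels(Y, P.shape)
    val = _baseline_tensor(name, Tensor(P), Y, **hyper)
    return LossValue(value=float(val.data))


def make_loss(name: str, config: FocalDiceConfig | None = None, **hyper):
    """Return ``loss_fn(P_tensor, Y) -> scalar Tensor`` for the named loss.

    ``mlfdl`` uses ``config``; ``dl`` is mlfdl at eps1 = eps0 = 1; the rest
    take their canonical hyperparameters via ``hyper``.
    """
    name = name.lower()
    if name == "mlfdl":
        cfg = config or FocalDiceConfig()
        return lambda P, Y: mlfdl_tensor(P, Y, cfg)
    if name in BASELINE_LOSSES:
        return lambda P, Y: _baseline_tensor(name, P, Y, dice=config, **hyper)
    raise ValueError(f"unknown loss {name!r}")
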