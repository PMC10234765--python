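"""Teacher-student knowledge distillation and attention-based attribution.

The fitted classifier is accurate but opaque: convolution and pooling mix
residue positions. To attribute predictions to residues, a small student
network that *preserves the length dimension* is trained to mimic the
teacher. The student is embedding + sinusoidal positions + padding-masked
self-attention, followed by per-class attention pooling: each class owns a
learned query vector whose normalized attention over positions is both the
class's evidence-pooling rule and its per-residue attribution profile.

Losses: the student loss SL is the focal dice loss on hard labels; the
distillation loss KDL is cross-entropy between the teacher's sigmoid
probabilities (soft labels) and the student's; the total is
``TL = SL + mu * KDL``. At ``mu = 0`` distillation reduces exactly to plain
student training.

Interpretation utilities: per-class attention profiles, fragment framing
around the max-attention residue, and the Pearson correlation matrix of the
per-class weight vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._autodiff import Tensor, embedding, no_grad
from .io import LabelSpace, PeptideRecord, encode_sequence
from .losses import FocalDiceConfig, mlfdl_tensor
from .metrics import MetricsReport, evaluate, threshold_predictions
from .network import positional_encoding, _xavier
from .training import ClassifierResults, _Adam, _records_to_arrays

__all__ = [
    "StudentConfig",
    "DistillConfig",
    "StudentNetwork",
    "Distillation",
    "StudentResults",
    "FramedFragment",
    "teacher_soft_labels",
    "soft_labels_from_scores",
    "kd_loss",
    "kd_loss_tensor",
    "total_loss",
    "student_loss",
    "frame_fragment",
    "class_weight_correlation",
    "train_student",
    "distill",
]

_CLIP = 1e-7


@dataclass
class StudentConfig:
    label_dim: int
    embed_dim: int = 32
    max_seq_len: int = 50
    vocab_size: int = 21
    n_heads: int = 4
    n_attention_layers: int = 1
    dropout: float = 0.0
    use_pos: bool = True
    dtype: str = "float32"

    def __post_init__(self):
        if self.embed_dim < 8:
            raise ValueError("embed_dim must be >= 8")
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")


@dataclass
class DistillConfig:
    mu: float = 1.0
    epochs: int = 20
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0
    loss_config: FocalDiceConfig = field(default_factory=FocalDiceConfig)
    threshold: float = 0.5

    def __post_init__(self):
        if self.mu < 0:
            raise ValueError("mu must be >= 0")


class StudentNetwork:
    """Length-preserving attention network with per-class query pooling."""

    def __init__(self, config: StudentConfig, seed: int = 0):
        self.config = config
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        c, d = config, config.embed_dim
        dt = np.dtype(config.dtype)
        self.params: dict[str, Tensor] = {}

        def add(name, arr):
            self.params[name] = Tensor(arr, requires_grad=True, name=name)

        add("emb", (rng.standard_normal((c.vocab_size, d)) / np.sqrt(d)).astype(dt))
        for l in range(c.n_attention_layers):
            for nm in ("wq", "wk", "wv", "wo"):
                add(f"attn{l}_{nm}", _xavier(rng, d, d, dt))
            add(f"attn{l}_bo", np.zeros(d, dtype=dt))
        add("queries", (rng.standard_normal((c.label_dim, d)) / np.sqrt(d)).astype(dt))
        add("out_w", _xavier(rng, c.label_dim, d, dt))
        add("out_b", np.zeros(c.label_dim, dtype=dt))
        self._pos = positional_encoding(c.max_seq_len, d).astype(dt)

    def zero_grad(self):
        for p in self.params.values():
            p.zero_grad()

    def forward(self, codes: np.ndarray, return_attention: bool = False):
        """Probabilities (N, M); optionally per-class position weights (N, M, n)."""
        c = self.config
        codes = np.asarray(codes)
        pad = (codes != 0)
        if (~pad).all(axis=1).any():
            raise ValueError("all-pad sequence")
        N, n = codes.shape
        d, h, dh = c.embed_dim, c.n_heads, c.embed_dim // c.n_heads
        x = embedding(self.params["emb"], codes)
        if c.use_pos:
            x = x + Tensor(self._pos[None, :n, :])
        neg = np.where(pad, 0.0, -1e9)
        for l in range(c.n_attention_layers):
            q = (x @ self.params[f"attn{l}_wq"]).reshape(N, n, h, dh).transpose(0, 2, 1, 3)
            k = (x @ self.params[f"attn{l}_wk"]).reshape(N, n, h, dh).transpose(0, 2, 1, 3)
            v = (x @ self.params[f"attn{l}_wv"]).reshape(N, n, h, dh).transpose(0, 2, 1, 3)
            s = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
            w = (s + Tensor(neg[:, None, None, :].astype(s.data.dtype))).softmax(axis=-1)
            x = (w @ v).transpose(0, 2, 1, 3).reshape(N, n, d)
            x = x @ self.params[f"attn{l}_wo"] + self.params[f"attn{l}_bo"]
        # per-class attention pooling over positions
        scores = (x @ self.params["queries"].transpose(1, 0)) * (1.0 / np.sqrt(d))
        scores = scores.transpose(0, 2, 1)  # (N, M, n)
        attn = (scores + Tensor(neg[:, None, :].astype(scores.data.dtype))).softmax(axis=-1)
        context = attn @ x  # (N, M, d)
        logits = (context * self.params["out_w"]).sum(axis=-1) + self.params["out_b"]
        probs = logits.sigmoid()
        if return_attention:
            return probs, attn
        return probs

    def save(self, path, label_names=None, extra=None) -> None:
        import json
        from dataclasses import asdict

        meta = {"config": asdict(self.config), "seed": self.seed,
                "label_names": label_names, "extra": extra or {}}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **{k: p.data for k, p in self.params.items()})

    @classmethod
    def load(cls, path):
        import json

        with np.load(path) as zf:
            meta = json.loads(bytes(zf["__meta__"].tobytes()).decode())
            net = cls(StudentConfig(**meta["config"]), seed=meta["seed"])
            for name in net.params:
                net.params[name] = Tensor(zf[name].copy(), requires_grad=True, name=name)
        return net, meta


# ---------------------------------------------------------------------------
# losses


def soft_labels_from_scores(scores) -> np.ndarray:
    """Sigmoid map from raw label scores to soft-label probabilities."""
    return 1.0 / (1.0 + np.exp(-np.asarray(scores, dtype=float)))


def teacher_soft_labels(teacher, codes: np.ndarray) -> np.ndarray:
    """The frozen teacher's sigmoid probabilities, computed once and cached.

    Accepts fitted results or a bare network with a ``forward`` method.
    """
    with no_grad():
        if isinstance(teacher, ClassifierResults):
            return teacher.predict_codes(codes)[0]
        return teacher.forward(codes).data.astype(np.float64)


def kd_loss_tensor(T: np.ndarray, S: Tensor, reduction: str = "mean") -> Tensor:
    """Cross-entropy from teacher soft labels T to student probabilities S.

    Reduction: mean over samples, sum over labels (config-exposed; ``sum``
    gives the plain double sum).
    """
    T = np.clip(np.asarray(T), _CLIP, 1 - _CLIP).astype(S.data.dtype, copy=False)
    if T.shape != S.shape:
        raise ValueError(f"shape mismatch: {T.shape} vs {S.shape}")
    Sc = S.clip(_CLIP, 1 - _CLIP)
    per = -(Sc.log() * T + (1.0 - Sc).log() * (1 - T)).sum(axis=1)
    return per.mean() if reduction == "mean" else per.sum()


def kd_loss(T, S, reduction: str = "mean") -> float:
    return float(kd_loss_tensor(T, Tensor(np.asarray(S, dtype=float)), reduction).data)


def student_loss(S, Y, config: FocalDiceConfig = FocalDiceConfig()):
    """Hard-label focal dice loss on the student's probabilities."""
    from .losses import mlfdl

    return mlfdl(S, Y, config)


def total_loss(sl: float, kdl: float, mu: float) -> float:
    """TL = SL + mu * KDL."""
    if mu < 0:
        raise ValueError("mu must be >= 0")
    return sl + mu * kdl


# ---------------------------------------------------------------------------
# fitting


class Distillation:
    """Fit a student to records, optionally mimicking a frozen teacher."""

    def __init__(self, teacher: ClassifierResults | None,
                 records: Sequence[PeptideRecord], label_space: LabelSpace,
                 student_config: StudentConfig | None = None,
                 distill_config: DistillConfig | None = None):
        self.teacher = teacher
        self.label_space = label_space
        self.records = list(records)
        self.student_config = student_config or StudentConfig(label_dim=label_space.size)
        if self.student_config.label_dim != label_space.size:
            raise ValueError("student label_dim must equal label-space size")
        if teacher is not None and tuple(teacher.label_space.names) != tuple(label_space.names):
            raise ValueError("teacher and records use different label spaces")
        self.distill_config = distill_config or DistillConfig()
        self.X, self.Y = _records_to_arrays(records, self.student_config.max_seq_len)

    def fit(self, verbose: bool = False) -> "StudentResults":
        cfg = self.distill_config
        student = StudentNetwork(self.student_config, seed=cfg.seed)
        opt = _Adam(student.params, cfg.learning_rate)
        order_rng = np.random.default_rng(cfg.seed + 1)
        use_kd = cfg.mu > 0 and self.teacher is not None
        T = teacher_soft_labels(self.teacher, self.X) if use_kd else None
        history = []
        for epoch in range(cfg.epochs):
            order = order_rng.permutation(len(self.X))
            losses = []
            for start in range(0, len(self.X), cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                student.zero_grad()
                S = student.forward(self.X[idx])
                loss = mlfdl_tensor(S, self.Y[idx], cfg.loss_config)
                if use_kd:
                    loss = loss + kd_loss_tensor(T[idx], S) * cfg.mu
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            history.append(float(np.mean(losses)))
            if verbose:
                print(f"epoch {epoch + 1}/{cfg.epochs}  loss {history[-1]:.4f}")
        return StudentResults(student=student, label_space=self.label_space,
                              distill_config=cfg, loss_history=history)


@dataclass(frozen=True)
class FramedFragment:
    start: int            # 0-based, inclusive
    end: int              # 0-based, exclusive
    fragment: str
    whole_sequence: bool  # window exceeded the sequence length


@dataclass
class StudentResults:
    student: StudentNetwork
    label_space: LabelSpace
    distill_config: DistillConfig
    loss_history: list[float]

    def predict_codes(self, codes, tau: float = 0.5):
        with no_grad():
            P = self.student.forward(codes).data.astype(np.float64)
        return P, threshold_predictions(P, tau)

    def evaluate(self, records: Sequence[PeptideRecord],
                 tau: float | None = None) -> MetricsReport:
        tau = self.distill_config.threshold if tau is None else tau
        X, Y = _records_to_arrays(records, self.student.config.max_seq_len)
        _, pred = self.predict_codes(X, tau)
        return evaluate(Y, pred)

    def extract_attention(self, sequence: str) -> np.ndarray:
        """Per-class position weights (M, L) over the real residues.

        Pad positions receive zero attention by construction, so restricting
        to the first L columns keeps each class row summing to 1.
        """
        codes = encode_sequence(sequence, self.student.config.max_seq_len)[None, :]
        with no_grad():
            _, attn = self.student.forward(codes, return_attention=True)
        return attn.data[0, :, :len(sequence)].astype(np.float64)

    def frame_fragment(self, sequence: str, class_index: int,
                       window: int = 3) -> FramedFragment:
        profile = self.extract_attention(sequence)[class_index]
        return frame_fragment(profile, sequence, window)

    def class_weight_correlation(self) -> np.ndarray:
        return class_weight_correlation(self.student)

    def summary(self) -> str:
        c = self.student.config
        n_params = sum(p.data.size for p in self.student.params.values())
        return "\n".join([
            "Distilled attention student",
            "=" * 42,
            f"labels (M):    {c.label_dim}",
            f"embed dim:     {c.embed_dim}   heads: {c.n_heads}",
            f"parameters:    {n_params}",
            f"mu:            {self.distill_config.mu}",
            f"epochs run:    {len(self.loss_history)}",
            f"final loss:    {self.loss_history[-1]:.4f}" if self.loss_history else "",
        ])

    def save(self, path) -> None:
        self.student.save(path, label_names=list(self.label_space.names),
                          extra={"mu": self.distill_config.mu,
                                 "loss_history": self.loss_history})


def frame_fragment(weights: np.ndarray, sequence: str,
                   window: int = 3) -> FramedFragment:
    """Window-length fragment centered on the arg-max attention position.

    Ties break toward the N-terminus; the window is clipped at the sequence
    ends; a window longer than the sequence returns the whole sequence with
    the ``whole_sequence`` flag set.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    weights = np.asarray(weights, dtype=float)
    L = len(sequence)
    if weights.shape != (L,):
        raise ValueError("weights length must equal sequence length")
    if window > L:
        return FramedFragment(0, L, sequence, whole_sequence=True)
    center = int(np.argmax(weights))  # first max wins ties
    half = window // 2
    start = max(0, center - half)
    end = min(L, center + half + 1)
    return FramedFragment(start, end, sequence[start:end], whole_sequence=False)


def class_weight_correlation(student: StudentNetwork) -> np.ndarray:
    """Pearson correlation between the per-class query vectors.

    Zero-variance vectors have undefined correlation; those entries are
    reported as 0 (the diagonal stays 1).
    """
    Q = student.params["queries"].data.astype(np.float64)
    M = Q.shape[0]
    centered = Q - Q.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    corr = np.zeros((M, M))
    for i in range(M):
        for j in range(M):
            if i == j:
                corr[i, j] = 1.0
            elif norms[i] > 0 and norms[j] > 0:
                corr[i, j] = centered[i] @ centered[j] / (norms[i] * norms[j])
    return corr


def train_student(records, label_space, student_config=None,
                  distill_config=None) -> StudentResults:
    """Plain student training on hard labels (no teacher, mu forced to 0)."""
    from dataclasses import replace

    cfg = distill_config or DistillConfig()
    cfg = replace(cfg, mu=0.0)
    return Distillation(None, records, label_space, student_config, cfg).fit()


def distill(teacher: ClassifierResults, records, label_space,
            student_config=None, distill_config=None) -> StudentResults:
    return Distillation(teacher, records, label_space,
                        student_config, distill_config).fit()
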