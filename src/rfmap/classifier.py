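"""Pilot / boosted patch classifiers and the repeated-training protocol.

The network follows the transfer-learning contract of the study design: a
frozen convolutional base acting as a generic feature extractor and two
trainable fully connected layers with dropout and a softmax output.  The
desk-scale default base ("tiny") is a fixed-filter two-block CNN whose
filters are drawn once from a seeded He-scaled Gaussian — the protocol, not
the pretrained weights, is the artifact, and the base is a pluggable
contract (any object with ``features`` / ``backward_features``).

Because the base is frozen, its per-image features are computed once and the
head is trained on them, which keeps a 50-run stability protocol cheap.  The
whole model is differentiable end to end, so the saliency module can ask for
exact class-score gradients with respect to the input pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import convolve2d, correlate2d

from .fusion import mann_whitney_auc
from .patches import CompositeInput

__all__ = ["TrainConfig", "DataSplit", "PatchNet", "RunEnsemble",
           "train_once", "stability_protocol", "TinyConvBase"]

_BASE_SEED = 7_654_321  # fixed: the frozen base is shared by every run


@dataclass(frozen=True)
class TrainConfig:
    backbone: str = "tiny"
    freeze_base: bool = True
    dropout: float = 0.25
    epochs: int = 200
    batch_size: int = 16
    lr: float = 0.01
    hidden: int = 24
    weight_decay: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class DataSplit:
    """Training and validation inputs with binary labels (1 = positive)."""

    train_X: np.ndarray
    train_y: np.ndarray
    val_X: np.ndarray
    val_y: np.ndarray


def _as_array(X) -> np.ndarray:
    if isinstance(X, np.ndarray):
        return X.astype(float)
    return np.stack([x.channels if isinstance(x, CompositeInput) else np.asarray(x, float)
                     for x in X])


def _avgpool(a: np.ndarray, k: int) -> np.ndarray:
    c, h, w = a.shape
    return a.reshape(c, h // k, k, w // k, k).mean(axis=(2, 4))


def _avgpool_back(g: np.ndarray, k: int) -> np.ndarray:
    return np.kron(g, np.ones((1, k, k))) / (k * k)


def _conv_symm(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """3x3 cross-correlation with symmetric (reflect-including-edge) padding.

    Zero padding would put the strongest responses on the artificial border
    contrast ring, which poisons both the features and the saliency maps.
    """
    return correlate2d(np.pad(x, 1, mode="symmetric"), w, mode="valid")


def _conv_symm_adjoint(g: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Exact adjoint of :func:`_conv_symm` (gradient w.r.t. its input)."""
    gp = convolve2d(g, w, mode="full")  # gradient w.r.t. the padded input
    gx = gp[1:-1, 1:-1].copy()
    gx[0, :] += gp[0, 1:-1]
    gx[-1, :] += gp[-1, 1:-1]
    gx[:, 0] += gp[1:-1, 0]
    gx[:, -1] += gp[1:-1, -1]
    gx[0, 0] += gp[0, 0]
    gx[0, -1] += gp[0, -1]
    gx[-1, 0] += gp[-1, 0]
    gx[-1, -1] += gp[-1, -1]
    return gx


class TinyConvBase:
    """Fixed-filter two-block convolutional feature extractor.

    Features are the spatial mean squares of both blocks' ReLU activations
    (8 + 16 = 24 values), i.e. per-filter response energies.  Second moments
    are used alone so the class-score gradient at each pixel is proportional
    to the local activation magnitude, which keeps saliency maps spatially
    localized on the structures the model actually responds to.
    """

    n_features = 24

    def __init__(self, seed: int = _BASE_SEED, pool0: int = 8):
        self.pool0 = pool0
        rng = np.random.default_rng(seed)
        self.W1 = rng.normal(0, np.sqrt(2 / (3 * 9)), size=(8, 3, 3, 3))
        self.W2 = rng.normal(0, np.sqrt(2 / (8 * 9)), size=(16, 8, 3, 3))

    def _forward(self, x: np.ndarray):
        xp = _avgpool(x, self.pool0)
        z1 = np.stack([
            sum(_conv_symm(xp[c], self.W1[f, c]) for c in range(3))
            for f in range(8)
        ])
        a1 = np.maximum(z1, 0)
        p1 = _avgpool(a1, 2)
        z2 = np.stack([
            sum(_conv_symm(p1[c], self.W2[f, c]) for c in range(8))
            for f in range(16)
        ])
        a2 = np.maximum(z2, 0)
        return xp, z1, a1, p1, z2, a2

    def features(self, x: np.ndarray) -> np.ndarray:
        _, _, a1, _, _, a2 = self._forward(x)
        return np.concatenate([
            (a1 ** 2).mean(axis=(1, 2)), (a2 ** 2).mean(axis=(1, 2)),
        ])

    def backward_features(self, x: np.ndarray, g_feat: np.ndarray) -> np.ndarray:
        """Gradient of ``g_feat . features(x)`` with respect to ``x``."""
        _, z1, a1, p1, z2, a2 = self._forward(x)
        n1 = a1[0].size
        n2 = a2[0].size
        g_a1 = 2 * a1 * g_feat[0:8, None, None] / n1
        g_a2 = 2 * a2 * g_feat[8:24, None, None] / n2
        g_z2 = g_a2 * (z2 > 0)
        g_p1 = np.stack([
            sum(_conv_symm_adjoint(g_z2[f], self.W2[f, c]) for f in range(16))
            for c in range(8)
        ])
        g_a1 = g_a1 + _avgpool_back(g_p1, 2)
        g_z1 = g_a1 * (z1 > 0)
        g_xp = np.stack([
            sum(_conv_symm_adjoint(g_z1[f], self.W1[f, c]) for f in range(8))
            for c in range(3)
        ])
        return _avgpool_back(g_xp, self.pool0)


def _make_base(cfg: TrainConfig):
    if cfg.backbone == "tiny":
        return TinyConvBase()
    raise ValueError(f"unknown backbone {cfg.backbone!r}; desk-scale build ships 'tiny'")


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class PatchNet:
    """Frozen base + two trainable FC layers (dropout between, softmax out)."""

    def __init__(self, base, cfg: TrainConfig):
        self.base = base
        self.cfg = cfg
        self.feat_mu: np.ndarray | None = None
        self.feat_sd: np.ndarray | None = None
        self.params: dict[str, np.ndarray] = {}

    # -- feature plumbing ---------------------------------------------------
    def base_features(self, X: np.ndarray) -> np.ndarray:
        return np.stack([self.base.features(x) for x in X])

    def _standardize(self, F: np.ndarray) -> np.ndarray:
        return (F - self.feat_mu) / self.feat_sd

    # -- head ---------------------------------------------------------------
    def _init_head(self, rng: np.random.Generator) -> None:
        nf, nh = self.base.n_features, self.cfg.hidden
        self.params = {
            "W1": rng.normal(0, np.sqrt(2 / nf), size=(nh, nf)),
            "b1": np.zeros(nh),
            "W2": rng.normal(0, np.sqrt(2 / nh), size=(2, nh)),
            "b2": np.zeros(2),
        }

    def _head_forward(self, S: np.ndarray, drop_mask: np.ndarray | None = None):
        p = self.params
        z1 = S @ p["W1"].T + p["b1"]
        h = np.maximum(z1, 0)
        if drop_mask is not None:
            h = h * drop_mask
        logits = h @ p["W2"].T + p["b2"]
        return z1, h, logits

    def fit_head(self, F_train: np.ndarray, y: np.ndarray,
                 rng: np.random.Generator) -> None:
        cfg = self.cfg
        self.feat_mu = F_train.mean(axis=0)
        # sd floored relative to the feature's own scale: near-constant
        # features carry no signal but an unfloored 1/sd would dominate the
        # input gradient (and hence the saliency map) with noise
        sd = F_train.std(axis=0)
        self.feat_sd = np.maximum(sd, 0.05 * np.abs(self.feat_mu) + 1e-8)
        S = self._standardize(F_train)
        n = len(y)
        self._init_head(rng)
        p = self.params
        m = {k: np.zeros_like(v) for k, v in p.items()}
        v = {k: np.zeros_like(vv) for k, vv in p.items()}
        b1, b2, eps = 0.9, 0.999, 1e-8
        t = 0
        keep = 1.0 - cfg.dropout
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                Sb, yb = S[idx], y[idx]
                mask = (rng.random((len(idx), cfg.hidden)) < keep) / keep if keep < 1 else None
                z1, h, logits = self._head_forward(Sb, mask)
                probs = _softmax(logits)
                g_logits = probs.copy()
                g_logits[np.arange(len(idx)), yb] -= 1.0
                g_logits /= len(idx)
                grads = {
                    "W2": g_logits.T @ h + cfg.weight_decay * p["W2"],
                    "b2": g_logits.sum(axis=0),
                }
                g_h = g_logits @ p["W2"]
                if mask is not None:
                    g_h = g_h * mask
                g_z1 = g_h * (z1 > 0)
                grads["W1"] = g_z1.T @ Sb + cfg.weight_decay * p["W1"]
                grads["b1"] = g_z1.sum(axis=0)
                t += 1
                for k in p:
                    m[k] = b1 * m[k] + (1 - b1) * grads[k]
                    v[k] = b2 * v[k] + (1 - b2) * grads[k] ** 2
                    mh = m[k] / (1 - b1 ** t)
                    vh = v[k] / (1 - b2 ** t)
                    p[k] -= cfg.lr * mh / (np.sqrt(vh) + eps)

    # -- inference ----------------------------------------------------------
    def predict_proba_features(self, F: np.ndarray) -> np.ndarray:
        _, _, logits = self._head_forward(self._standardize(F))
        return _softmax(logits)

    def predict_proba(self, X) -> np.ndarray:
        return self.predict_proba_features(self.base_features(_as_array(X)))

    def input_gradient(self, x: np.ndarray, class_index: int = 1) -> np.ndarray:
        """d(class logit)/d(input pixels), exact, dropout off."""
        x = np.asarray(x, dtype=float)
        f = self.base.features(x)
        s = (f - self.feat_mu) / self.feat_sd
        p = self.params
        z1 = p["W1"] @ s + p["b1"]
        h = np.maximum(z1, 0)
        g_h = p["W2"][class_index] * (z1 > 0)
        g_s = p["W1"].T @ g_h
        g_f = g_s / self.feat_sd
        return self.base.backward_features(x, g_f)


def train_once(train, val, cfg: TrainConfig | None = None):
    """Train one model and return it with its validation class-1 probabilities.

    ``train`` and ``val`` are ``(inputs, labels)`` pairs; inputs may be a
    stacked array or a list of :class:`CompositeInput`.  Deterministic given
    the config seed.
    """
    cfg = cfg or TrainConfig()
    Xt, yt = _as_array(train[0]), np.asarray(train[1], dtype=int)
    Xv, yv = _as_array(val[0]), np.asarray(val[1], dtype=int)
    if len(np.unique(yt)) < 2:
        raise ValueError("training set must contain both classes")
    model = PatchNet(_make_base(cfg), cfg)
    rng = np.random.default_rng(cfg.seed)
    model.fit_head(model.base_features(Xt), yt, rng)
    probs = model.predict_proba(Xv)[:, 1]
    return model, probs


@dataclass
class RunEnsemble:
    """Results of the repeated-training stability protocol.

    The selected run is the one whose validation AUC is closest to the
    ensemble mean (ties broken by lowest seed); its per-subject class-1
    probabilities are carried for downstream fusion.
    """

    aucs: np.ndarray
    seeds: tuple[int, ...]
    selected_index: int
    selected_model: PatchNet
    selected_probabilities: np.ndarray
    val_labels: np.ndarray

    @property
    def mean_auc(self) -> float:
        return float(self.aucs.mean())

    @property
    def sd_auc(self) -> float:
        return float(self.aucs.std(ddof=1)) if len(self.aucs) > 1 else 0.0

    def summary(self) -> str:
        lines = [
            "Repeated-training stability protocol",
            f"  runs:          {len(self.aucs)}",
            f"  mean AUC (SD): {self.mean_auc:.3f} ({self.sd_auc:.3f})",
            f"  selected run:  #{self.selected_index} "
            f"(seed {self.seeds[self.selected_index]}, "
            f"AUC {self.aucs[self.selected_index]:.3f})",
        ]
        return "\n".join(lines)


def stability_protocol(split: DataSplit, cfg: TrainConfig | None = None,
                       runs: int = 50) -> RunEnsemble:
    """Train ``runs`` models from distinct seeds and select the run whose
    validation AUC is closest to the mean.

    The frozen base's features are computed once and shared across runs; only
    the FC head is re-initialized and re-trained per run.
    """
    if runs < 2:
        raise ValueError("need at least two runs")
    cfg = cfg or TrainConfig()
    Xt, yt = _as_array(split.train_X), np.asarray(split.train_y, dtype=int)
    Xv, yv = _as_array(split.val_X), np.asarray(split.val_y, dtype=int)
    if len(np.unique(yt)) < 2:
        raise ValueError("training set must contain both classes")
    base = _make_base(cfg)
    ref = PatchNet(base, cfg)
    Ft = ref.base_features(Xt)
    Fv = ref.base_features(Xv)
    seeds = tuple(cfg.seed + i for i in range(runs))
    aucs = np.empty(runs)
    models, probs = [], []
    for i, s in enumerate(seeds):
        model = PatchNet(base, TrainConfig(**{**cfg.__dict__, "seed": s}))
        model.fit_head(Ft, yt, np.random.default_rng(s))
        p = model.predict_proba_features(Fv)[:, 1]
        aucs[i] = mann_whitney_auc(p, yv)
        models.append(model)
        probs.append(p)
    mean = aucs.mean()
    # closest to mean; ties -> lowest seed (stable argmin on distance)
    sel = int(np.argmin(np.abs(aucs - mean)))
    return RunEnsemble(aucs, seeds, sel, models[sel], probs[sel], yv)
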