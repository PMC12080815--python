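"""The OAOM vision-transformer classifier.

The Optimized Apple Orchard Model (OAOM) is a ViT-style classifier: the
image is cut into non-overlapping patches, each patch is flattened and
passed through one shared affine projection to width ``D``, a learned
positional-encoding vector is added per position, a learned CLS token is
prepended, and the token sequence runs through a stack of pre-norm
multi-head self-attention encoder blocks.  The final CLS state feeds an
MLP head with a softmax output.

The reference configuration (12 layers, hidden size 790, 12 heads,
feed-forward width 3092, 6x6 patches on a 70x70 image) and tiny test
configurations run the identical code path; every size is a config field.

``OAOMClassifier`` wraps the network in the scikit-learn estimator API
(``fit`` / ``predict`` / ``predict_proba``) with an Adam training loop,
so it composes with sklearn pipelines and model selection.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from PIL import Image
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from . import autodiff as ad
from .autodiff import Tensor
from .losses import LossParams, batched_loss

__all__ = [
    "OAOMConfig",
    "PatchSequence",
    "extract_patches",
    "reassemble_patches",
    "OAOMNetwork",
    "OAOMClassifier",
]


@dataclass
class OAOMConfig:
    """Architecture hyper-parameters.

    Notes
    -----
    ``head_dim`` defaults to ``floor(hidden_size / num_heads)``; the head
    concatenation is always projected back to ``hidden_size``, so the
    hidden size need not be divisible by the head count (the reference
    size 790 with 12 heads is not).

    ``boundary_policy`` handles images whose side is not a multiple of the
    patch side: ``"resize"`` rescales to the nearest multiple (70 -> 72,
    giving 144 patches of 6x6), ``"crop"`` drops the bottom/right
    remainder (70 -> 66, giving 121).
    """

    image_size: tuple[int, int] = (70, 70)
    patch_size: tuple[int, int] = (6, 6)
    stride: tuple[int, int] | None = None  # None => patch_size (non-overlap)
    hidden_size: int = 790
    num_layers: int = 12
    num_heads: int = 12
    head_dim: int | None = None
    mlp_size: int = 3092
    head_widths: tuple[int, ...] = (512,)
    num_classes: int = 2
    dropout_rate: float = 0.1
    boundary_policy: str = "resize"

    def __post_init__(self) -> None:
        self.image_size = tuple(int(v) for v in self.image_size)
        self.patch_size = tuple(int(v) for v in self.patch_size)
        self.head_widths = tuple(int(v) for v in self.head_widths)
        if self.stride is None:
            self.stride = self.patch_size
        else:
            self.stride = tuple(int(v) for v in self.stride)
        for name in ("hidden_size", "num_layers", "num_heads", "mlp_size", "num_classes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if min(self.image_size) < 1 or min(self.patch_size) < 1:
            raise ValueError("image and patch sizes must be positive")
        if self.stride != self.patch_size:
            raise ValueError("only non-overlapping patches (stride == patch_size) are supported")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.boundary_policy not in ("crop", "resize"):
            raise ValueError("boundary_policy must be 'crop' or 'resize'")
        if self.head_dim is None:
            self.head_dim = max(1, self.hidden_size // self.num_heads)

    # -- derived geometry -----------------------------------------------------

    @property
    def effective_image_size(self) -> tuple[int, int]:
        """Image dimensions after the boundary policy is applied."""
        out = []
        for dim, p in zip(self.image_size, self.patch_size):
            if dim < p:
                raise ValueError(f"image dimension {dim} smaller than patch {p}")
            if dim % p == 0:
                out.append(dim)
            elif self.boundary_policy == "crop":
                out.append((dim // p) * p)
            else:  # nearest multiple, at least one patch
                out.append(max(p, int(round(dim / p)) * p))
        return tuple(out)

    @property
    def grid_shape(self) -> tuple[int, int]:
        eh, ew = self.effective_image_size
        return eh // self.patch_size[0], ew // self.patch_size[1]

    @property
    def num_patches(self) -> int:
        gh, gw = self.grid_shape
        return gh * gw

    @property
    def patch_dim(self) -> int:
        return self.patch_size[0] * self.patch_size[1] * 3

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PatchSequence:
    """Row-major non-overlapping patches of one image."""

    patches: np.ndarray  # (N, Ph, Pw, 3)
    positions: np.ndarray  # (N,), 1-based
    grid_shape: tuple[int, int]


def _apply_boundary(image: np.ndarray, config: OAOMConfig) -> np.ndarray:
    h, w = image.shape[:2]
    ph, pw = config.patch_size
    if h < ph or w < pw:
        raise ValueError(f"image {h}x{w} smaller than one {ph}x{pw} patch")
    eh, ew = config.effective_image_size
    if (h, w) == tuple(config.image_size):
        target = (eh, ew)
    else:
        # geometry recomputed for the actual array, same policy
        tmp = OAOMConfig(
            image_size=(h, w), patch_size=config.patch_size,
            boundary_policy=config.boundary_policy, num_classes=config.num_classes,
        )
        target = tmp.effective_image_size
    if (h, w) == target:
        return image
    if config.boundary_policy == "crop":
        return image[: target[0], : target[1]]
    arr = np.clip(image, 0.0, 1.0)
    im = Image.fromarray((arr * 255.0 + 0.5).astype(np.uint8))
    im = im.resize((target[1], target[0]), Image.BILINEAR)
    return np.asarray(im, dtype=np.float64) / 255.0


def extract_patches(image: np.ndarray, config: OAOMConfig) -> PatchSequence:
    """Cut an ``H x W x 3`` image (values in [0, 1]) into row-major patches.

    ``N = floor(H'/Ph) * floor(W'/Pw)`` where ``H', W'`` are the
    dimensions after the boundary policy; with stride equal to the patch
    size the patches tile the image without overlap.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 2:
        image = np.repeat(image[..., None], 3, axis=-1)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an H x W x 3 image")
    image = _apply_boundary(image, config)
    ph, pw = config.patch_size
    gh, gw = image.shape[0] // ph, image.shape[1] // pw
    patches = (
        image[: gh * ph, : gw * pw]
        .reshape(gh, ph, gw, pw, 3)
        .transpose(0, 2, 1, 3, 4)
        .reshape(gh * gw, ph, pw, 3)
    )
    return PatchSequence(patches=patches, positions=np.arange(1, gh * gw + 1), grid_shape=(gh, gw))


def reassemble_patches(seq: PatchSequence) -> np.ndarray:
    """Inverse of :func:`extract_patches` (exact under the crop policy)."""
    gh, gw = seq.grid_shape
    n, ph, pw, c = seq.patches.shape
    return (
        seq.patches.reshape(gh, gw, ph, pw, c)
        .transpose(0, 2, 1, 3, 4)
        .reshape(gh * ph, gw * pw, c)
    )


# -- network ------------------------------------------------------------------


def _gelu(x: Tensor) -> Tensor:
    # tanh approximation of GELU
    c = math.sqrt(2.0 / math.pi)
    return 0.5 * x * (1.0 + ad.tanh(c * (x + 0.044715 * x**3)))


def _layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc / ad.sqrt(var + eps) * gamma + beta


class OAOMNetwork:
    """Parameter container + differentiable forward pass.

    All weights are :class:`Tensor` leaves in ``self.params``; the forward
    pass builds the autodiff graph so ``loss.backward()`` yields gradients
    for the Adam step.
    """

    def __init__(self, config: OAOMConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        std = 0.02
        c = config
        p: dict[str, Tensor] = {}

        def w(name, *shape):
            p[name] = Tensor(rng.normal(0.0, std, size=shape), requires_grad=True)

        def zeros(name, *shape):
            p[name] = Tensor(np.zeros(shape), requires_grad=True)

        def ones(name, *shape):
            p[name] = Tensor(np.ones(shape), requires_grad=True)

        w("proj_w", c.patch_dim, c.hidden_size)
        zeros("proj_b", c.hidden_size)
        w("pos", c.num_patches, c.hidden_size)
        w("cls", c.hidden_size)
        inner = c.num_heads * c.head_dim
        for l in range(c.num_layers):
            ones(f"ln1_g{l}", c.hidden_size)
            zeros(f"ln1_b{l}", c.hidden_size)
            for nm in ("q", "k", "v"):
                w(f"{nm}_w{l}", c.hidden_size, inner)
                zeros(f"{nm}_b{l}", inner)
            w(f"o_w{l}", inner, c.hidden_size)
            zeros(f"o_b{l}", c.hidden_size)
            ones(f"ln2_g{l}", c.hidden_size)
            zeros(f"ln2_b{l}", c.hidden_size)
            w(f"ff1_w{l}", c.hidden_size, c.mlp_size)
            zeros(f"ff1_b{l}", c.mlp_size)
            w(f"ff2_w{l}", c.mlp_size, c.hidden_size)
            zeros(f"ff2_b{l}", c.hidden_size)
        ones("lnf_g", c.hidden_size)
        zeros("lnf_b", c.hidden_size)
        prev = c.hidden_size
        for i, width in enumerate(c.head_widths):
            w(f"head_w{i}", prev, width)
            zeros(f"head_b{i}", width)
            prev = width
        w("out_w", prev, c.num_classes)
        zeros("out_b", c.num_classes)
        self.params = p

    # -- pieces ---------------------------------------------------------------

    def _dropout(self, x: Tensor, train: bool, rng) -> Tensor:
        rate = self.config.dropout_rate
        if not train or rate == 0.0:
            return x
        mask = (rng.random(x.shape) >= rate).astype(np.float64) / (1.0 - rate)
        return x * Tensor(mask)

    def embed(self, images: np.ndarray) -> Tensor:
        """Patchify + shared projection + positional encoding + CLS token.

        ``images``: (B, H, W, 3) floats in [0, 1].  Returns (B, N+1, D).
        """
        c = self.config
        flat = np.stack(
            [extract_patches(im, c).patches.reshape(c.num_patches, -1) for im in images]
        )  # (B, N, P)
        x = Tensor(flat) @ self.params["proj_w"] + self.params["proj_b"]
        x = x + self.params["pos"].reshape(1, c.num_patches, c.hidden_size)
        b = flat.shape[0]
        cls = self.params["cls"].reshape(1, 1, c.hidden_size) + Tensor(np.zeros((b, 1, 1)))
        return ad.concat([cls, x], axis=1)

    def attention(self, x: Tensor, layer: int) -> Tensor:
        """Multi-head scaled dot-product self-attention at one layer."""
        c = self.config
        b, t, _ = x.shape
        h, hd = c.num_heads, c.head_dim

        def split_heads(z):
            return z.reshape(b, t, h, hd).transpose(0, 2, 1, 3)  # (B, H, T, hd)

        q = split_heads(x @ self.params[f"q_w{layer}"] + self.params[f"q_b{layer}"])
        k = split_heads(x @ self.params[f"k_w{layer}"] + self.params[f"k_b{layer}"])
        v = split_heads(x @ self.params[f"v_w{layer}"] + self.params[f"v_b{layer}"])
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(hd))
        weights = ad.softmax(scores, axis=-1)
        ctx = (weights @ v).transpose(0, 2, 1, 3).reshape(b, t, h * hd)
        return ctx @ self.params[f"o_w{layer}"] + self.params[f"o_b{layer}"]

    def encoder_block(self, x: Tensor, layer: int, train: bool = False, rng=None) -> Tensor:
        """Pre-norm residual block: x + MHSA(LN(x)); y + FFN(LN(y))."""
        a = self.attention(_layer_norm(x, self.params[f"ln1_g{layer}"], self.params[f"ln1_b{layer}"]), layer)
        x = x + self._dropout(a, train, rng)
        hdn = _layer_norm(x, self.params[f"ln2_g{layer}"], self.params[f"ln2_b{layer}"])
        hdn = _gelu(hdn @ self.params[f"ff1_w{layer}"] + self.params[f"ff1_b{layer}"])
        hdn = hdn @ self.params[f"ff2_w{layer}"] + self.params[f"ff2_b{layer}"]
        return x + self._dropout(hdn, train, rng)

    def forward(self, images: np.ndarray, train: bool = False, rng=None) -> Tensor:
        """Full pass to class logits (B, num_classes)."""
        if train and rng is None:
            rng = np.random.default_rng(0)
        x = self.embed(np.asarray(images, dtype=np.float64))
        for l in range(self.config.num_layers):
            x = self.encoder_block(x, l, train=train, rng=rng)
        cls = _layer_norm(x, self.params["lnf_g"], self.params["lnf_b"])[:, 0, :]
        for i in range(len(self.config.head_widths)):
            cls = _gelu(cls @ self.params[f"head_w{i}"] + self.params[f"head_b{i}"])
            cls = self._dropout(cls, train, rng)
        return cls @ self.params["out_w"] + self.params["out_b"]

    def predict_proba(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Inference-mode class probabilities (dropout off)."""
        images = np.asarray(images, dtype=np.float64)
        out = []
        for i in range(0, len(images), batch_size):
            logits = self.forward(images[i : i + batch_size], train=False)
            out.append(ad.softmax(logits.data, axis=-1))
        return np.concatenate(out, axis=0)

    # -- persistence ----------------------------------------------------------

    def save(self, path) -> None:
        """Self-describing checkpoint: config JSON + weight arrays (.npz)."""
        arrays = {k: t.data for k, t in self.params.items()}
        np.savez(path, __config__=np.frombuffer(
            json.dumps(self.config.to_dict()).encode(), dtype=np.uint8
        ), **arrays)

    @classmethod
    def load(cls, path) -> "OAOMNetwork":
        with np.load(path) as z:
            cfg = json.loads(bytes(z["__config__"]).decode())
            cfg.pop("head_dim_", None)
            net = cls(OAOMConfig(**{k: tuple(v) if isinstance(v, list) else v for k, v in cfg.items()}), seed=0)
            for k in net.params:
                net.params[k] = Tensor(z[k], requires_grad=True)
        return net


class _Adam:
    """Adam optimizer over a dict of parameter Tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.v = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1.0 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1.0 - self.b2) * g**2
            p.data -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


class OAOMClassifier(ClassifierMixin, BaseEstimator):
    """Vision-transformer image classifier with the MFCE loss family.

    scikit-learn estimator over image arrays.  ``X`` is ``(n, H, W, 3)``
    (or flattened ``(n, H*W*3)``) with values in [0, 1]; ``y`` is any
    label array.  Training minimises the selected loss with Adam; all
    randomness (init, shuffling, dropout) derives from ``seed``.

    Parameters mirror :class:`OAOMConfig` plus the training options; the
    defaults are a tiny desk-scale configuration — pass the reference
    sizes (12 layers, hidden 790, 12 heads, mlp 3092) for the full model.
    """

    def __init__(
        self,
        image_size=(24, 24),
        patch_size=(6, 6),
        hidden_size=32,
        num_layers=2,
        num_heads=2,
        head_dim=None,
        mlp_size=64,
        head_widths=(32,),
        dropout_rate=0.0,
        boundary_policy="resize",
        loss_kind="mfce",
        gamma=2.0,
        dv=1.0,
        learning_rate=1e-3,
        batch_size=32,
        epochs=30,
        validation_fraction=0.0,
        seed=0,
    ):
        self.image_size = image_size
        self.patch_size = patch_size
        self.hidden_size = hidden_size
        self.num_layers = num_layers
        self.num_heads = num_heads
        self.head_dim = head_dim
        self.mlp_size = mlp_size
        self.head_widths = head_widths
        self.dropout_rate = dropout_rate
        self.boundary_policy = boundary_policy
        self.loss_kind = loss_kind
        self.gamma = gamma
        self.dv = dv
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.validation_fraction = validation_fraction
        self.seed = seed

    # -- helpers --------------------------------------------------------------

    def _as_images(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        h, w = self.image_size
        if X.ndim == 2:
            X = X.reshape(-1, h, w, 3)
        if X.ndim != 4 or X.shape[3] != 3:
            raise ValueError("X must be (n, H, W, 3) images or flattened rows")
        return X

    def _build_config(self, num_classes: int) -> OAOMConfig:
        return OAOMConfig(
            image_size=tuple(self.image_size),
            patch_size=tuple(self.patch_size),
            hidden_size=self.hidden_size,
            num_layers=self.num_layers,
            num_heads=self.num_heads,
            head_dim=self.head_dim,
            mlp_size=self.mlp_size,
            head_widths=tuple(self.head_widths),
            num_classes=num_classes,
            dropout_rate=self.dropout_rate,
            boundary_policy=self.boundary_policy,
        )

    def _loss_params(self) -> LossParams:
        return LossParams(gamma=self.gamma, dv=self.dv, reduction="mean")

    # -- estimator API --------------------------------------------------------

    def fit(self, X, y):
        X = self._as_images(X)
        y = np.asarray(y)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        config = self._build_config(len(self.classes_))
        self.config_ = config
        rng = np.random.default_rng(self.seed)
        self.network_ = OAOMNetwork(config, seed=int(rng.integers(2**31)))

        if self.validation_fraction > 0:
            X_tr, X_val, y_tr, y_val = train_test_split(
                X, y_idx, test_size=self.validation_fraction,
                stratify=y_idx, random_state=int(rng.integers(2**31)),
            )
        else:
            X_tr, y_tr, X_val, y_val = X, y_idx, None, None

        params = self._loss_params()
        opt = _Adam(self.network_.params, lr=self.learning_rate)
        n = len(X_tr)
        history = []
        best_val, best_state = -np.inf, None
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss, seen = 0.0, 0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                logits = self.network_.forward(X_tr[idx], train=True, rng=rng)
                probs = ad.softmax(logits, axis=-1)
                loss = batched_loss(self.loss_kind, y_tr[idx], probs, params)
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += loss.item() * len(idx)
                seen += len(idx)
            row = {"epoch": epoch + 1, "train_loss": epoch_loss / seen}
            proba_tr = self.network_.predict_proba(X_tr)
            row["train_acc"] = float(np.mean(proba_tr.argmax(axis=1) == y_tr))
            if X_val is not None:
                proba_val = self.network_.predict_proba(X_val)
                row["val_loss"] = batched_loss(self.loss_kind, y_val, proba_val, params)
                row["val_acc"] = float(np.mean(proba_val.argmax(axis=1) == y_val))
                if row["val_acc"] > best_val:  # strict: ties keep the earliest epoch
                    best_val = row["val_acc"]
                    best_state = {k: t.data.copy() for k, t in self.network_.params.items()}
            history.append(row)
        if best_state is not None:
            for k, t in self.network_.params.items():
                t.data = best_state[k]
        self.history_ = history
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "network_")
        return self.network_.predict_proba(self._as_images(X))

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def save(self, path) -> None:
        """Persist network weights + config + class labels."""
        check_is_fitted(self, "network_")
        self.network_.save(path)
        np.savez(str(path) + ".classes.npz", classes=self.classes_)

    @classmethod
    def load(cls, path) -> "OAOMClassifier":
        net = OAOMNetwork.load(path)
        est = cls()
        c = net.config
        est.set_params(
            image_size=c.image_size, patch_size=c.patch_size, hidden_size=c.hidden_size,
            num_layers=c.num_layers, num_heads=c.num_heads, head_dim=c.head_dim,
            mlp_size=c.mlp_size, head_widths=c.head_widths,
            dropout_rate=c.dropout_rate, boundary_policy=c.boundary_policy,
        )
        est.network_ = net
        est.config_ = c
        with np.load(str(path) + ".classes.npz", allow_pickle=True) as z:
            est.classes_ = z["classes"]
        est.history_ = []
        return est
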