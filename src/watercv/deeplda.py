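"""Deep-LDA collective variables.

The network maps the descriptor vector d to hidden features h; linear
discriminant analysis on h gives the projection s = w^T h, and the loss that
trains the network is the negative optimal Fisher ratio

    J* = (mu_B - mu_U)^T (S_w + lambda I)^{-1} (mu_B - mu_U)

computed on the batch's features. J* has a closed-form gradient in the
features themselves: with v = (S_w + lambda I)^{-1} (mu_B - mu_U),

    dJ*/dh_k =  2 v / n_B - 2 (v.(h_k - mu_B)) v / (n_B - 1)   (k in B)
    dJ*/dh_k = -2 v / n_U - 2 (v.(h_k - mu_U)) v / (n_U - 1)   (k in U)

which backpropagates through the network like any other loss. A classifier
this sharp compresses the two states into narrow peaks, so the biased CV is
the smoothed s_w = u + u^3, where u is s affinely rescaled so the training
projections span [-1, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .lda import ScatterStats, lda_direction, optimal_fisher_ratio, scatter_stats, split_by_label
from .network import MLP, Adam

DEFAULT_HIDDEN = (32, 16, 8)


def _batch_loss_grad(h_B: np.ndarray, h_U: np.ndarray, lambda_reg: float):
    """(J*, dJ*/dh_B, dJ*/dh_U) for one batch of hidden features."""
    stats = scatter_stats(h_B, h_U)
    dim = h_B.shape[1]
    m = stats.S_w + lambda_reg * np.eye(dim)
    v = np.linalg.solve(m, stats.mean_gap)
    j = float(stats.mean_gap @ v)
    nb, nu = len(h_B), len(h_U)
    g_B = 2.0 * v / nb - (2.0 / (nb - 1)) * ((h_B - stats.mu_B) @ v)[:, None] * v
    g_U = -2.0 * v / nu - (2.0 / (nu - 1)) * ((h_U - stats.mu_U) @ v)[:, None] * v
    return j, g_B, g_U


@dataclass
class DeepLDAModel:
    """Trained water-CV: network + LDA vector + cubic-transform rescale.

    ``project`` gives the raw discriminant s = w^T h(d); ``stretch`` rescales
    s with the training-set affine map and applies u + u^3. The sign of w is
    fixed so the bound class projects positive.
    """

    net: MLP
    w: np.ndarray  # unit norm, length n_hidden
    s_min: float  # training-set projection range, defines the rescale
    s_max: float
    input_mean: np.ndarray
    input_std: np.ndarray
    lambda_reg: float
    seed: int
    descriptor_names: list[str] = field(default_factory=list)
    config_hash: str = ""

    @property
    def n_descriptors(self) -> int:
        return self.net.n_inputs

    def _check_dim(self, d: np.ndarray) -> np.ndarray:
        d = np.atleast_2d(np.asarray(d, dtype=float))
        if d.shape[1] != self.n_descriptors:
            raise ValueError(
                f"descriptor vector has {d.shape[1]} entries, model expects "
                f"{self.n_descriptors}"
            )
        return d

    def hidden(self, d) -> np.ndarray:
        d = self._check_dim(d)
        return self.net.forward((d - self.input_mean) / self.input_std)

    def project(self, d) -> np.ndarray:
        """Raw Deep-LDA projection s = w^T h(d); batch in, batch out."""
        return self.hidden(d) @ self.w

    def rescale(self, s: np.ndarray) -> np.ndarray:
        """Affine map sending the training projections onto [-1, 1]."""
        return (2.0 * np.asarray(s) - (self.s_max + self.s_min)) / (self.s_max - self.s_min)

    def stretch(self, s) -> np.ndarray:
        """Cubic smoothing of the rescaled projection: u + u^3 (monotone)."""
        u = self.rescale(np.asarray(s, dtype=float))
        return u + u**3

    def cv_value(self, d) -> np.ndarray:
        """The biased CV s_w(d) = stretch(project(d))."""
        return self.stretch(self.project(d))

    def cv_gradient(self, d) -> np.ndarray:
        """d s_w / d d, shape (n, n_descriptors); chain rule through the
        rescale (slope 2/(s_max - s_min)) and the cubic (1 + 3 u^2)."""
        d = self._check_dim(d)
        x = (d - self.input_mean) / self.input_std
        g_s = self.net.input_gradient(x, self.w) / self.input_std
        u = self.rescale(self.project(d))
        scale = 2.0 / (self.s_max - self.s_min)
        return g_s * (scale * (1.0 + 3.0 * u**2))[:, None]

    # -- serialisation (plain JSON: text, byte-stable for a given model) --

    def to_json(self, path: str | Path) -> None:
        payload = {
            "sizes": self.net.sizes,
            "activation": self.net.activation,
            "weights": [w.tolist() for w in self.net.weights],
            "biases": [b.tolist() for b in self.net.biases],
            "w": self.w.tolist(),
            "s_min": self.s_min,
            "s_max": self.s_max,
            "input_mean": self.input_mean.tolist(),
            "input_std": self.input_std.tolist(),
            "lambda_reg": self.lambda_reg,
            "seed": self.seed,
            "descriptor_names": self.descriptor_names,
            "config_hash": self.config_hash,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "DeepLDAModel":
        p = json.loads(Path(path).read_text())
        net = MLP(p["sizes"], activation=p["activation"], seed=0)
        net.weights = [np.asarray(w, dtype=float) for w in p["weights"]]
        net.biases = [np.asarray(b, dtype=float) for b in p["biases"]]
        return cls(
            net=net,
            w=np.asarray(p["w"], dtype=float),
            s_min=p["s_min"],
            s_max=p["s_max"],
            input_mean=np.asarray(p["input_mean"], dtype=float),
            input_std=np.asarray(p["input_std"], dtype=float),
            lambda_reg=p["lambda_reg"],
            seed=p["seed"],
            descriptor_names=list(p.get("descriptor_names", [])),
            config_hash=p.get("config_hash", ""),
        )


def train_deep_lda(
    table: pd.DataFrame,
    hidden: tuple[int, ...] = DEFAULT_HIDDEN,
    activation: str = "elu",
    lambda_reg: float = 0.05,
    epochs: int = 1000,
    lr: float = 1e-3,
    seed: int = 0,
    val_fraction: float = 0.2,
    patience: int = 50,
    config_hash: str = "",
) -> DeepLDAModel:
    """Train a Deep-LDA CV on a labelled descriptor table.

    Full-batch Adam on -J*; 80/20 train/validation split (seeded); early
    stopping when validation J* has not improved for ``patience`` epochs, and
    the returned weights are those of the best validation epoch. The LDA
    vector w, the bound-positive sign, and the [-1, 1] rescale are all fixed
    on the training split of the best model.

    Raises on single-class input and aborts on a non-finite loss.
    """
    feature_cols = [c for c in table.columns if c not in ("label", "time")]
    xb, xu = split_by_label(table, feature_cols)
    if len(xb) < 4 or len(xu) < 4:
        raise ValueError("need at least 4 samples per class")
    rng = np.random.default_rng(seed)

    def _split(x):
        idx = rng.permutation(len(x))
        n_val = max(1, int(round(val_fraction * len(x))))
        return x[idx[n_val:]], x[idx[:n_val]]

    xb_tr, xb_val = _split(xb)
    xu_tr, xu_val = _split(xu)
    all_tr = np.vstack([xb_tr, xu_tr])
    mean = all_tr.mean(axis=0)
    std = all_tr.std(axis=0, ddof=0)
    std[std == 0] = 1.0
    zb_tr, zu_tr = (xb_tr - mean) / std, (xu_tr - mean) / std
    zb_val, zu_val = (xb_val - mean) / std, (xu_val - mean) / std

    net = MLP([len(feature_cols), *hidden], activation=activation, seed=seed)
    opt = Adam(net.get_params(), lr=lr)
    best_j, best_params, since_best = -np.inf, None, 0
    for epoch in range(epochs):
        h_b = net.forward(zb_tr, cache=False)
        h_u = net.forward(zu_tr, cache=False)
        j, g_b, g_u = _batch_loss_grad(h_b, h_u, lambda_reg)
        if not np.isfinite(j):
            raise RuntimeError(f"non-finite Fisher loss at epoch {epoch}; "
                               "reduce the learning rate")
        # maximise J* -> descend on -J*; one cached forward+backward per class
        net.forward(zb_tr, cache=True)
        gW_b, gb_b = net.backward(-g_b)
        net.forward(zu_tr, cache=True)
        gW_u, gb_u = net.backward(-g_u)
        grads = [a + b for a, b in zip(gW_b, gW_u)] + [
            a + b for a, b in zip(gb_b, gb_u)
        ]
        opt.step(net.get_params(), grads)
        j_val, _, _ = _batch_loss_grad(
            net.forward(zb_val), net.forward(zu_val), lambda_reg
        )
        if j_val > best_j:
            best_j = j_val
            best_params = [p.copy() for p in net.get_params()]
            since_best = 0
        else:
            since_best += 1
            if since_best >= patience:
                break
    net.set_params(best_params)

    h_b, h_u = net.forward(zb_tr), net.forward(zu_tr)
    stats = scatter_stats(h_b, h_u)
    w = lda_direction(stats, lambda_reg)
    s_tr = np.concatenate([h_b @ w, h_u @ w])
    s_min, s_max = float(s_tr.min()), float(s_tr.max())
    if s_max <= s_min:
        s_min, s_max = s_min - 0.5, s_min + 0.5  # degenerate: constant projection
    return DeepLDAModel(
        net=net,
        w=w,
        s_min=s_min,
        s_max=s_max,
        input_mean=mean,
        input_std=std,
        lambda_reg=lambda_reg,
        seed=seed,
        descriptor_names=feature_cols,
        config_hash=config_hash,
    )


def validation_fisher_ratio(model: DeepLDAModel, table: pd.DataFrame,
                            lambda_reg: float | None = None) -> float:
    """Optimal Fisher ratio of the model's hidden features on a labelled table."""
    xb, xu = split_by_label(table, model.descriptor_names or None)
    lam = model.lambda_reg if lambda_reg is None else lambda_reg
    return optimal_fisher_ratio(scatter_stats(model.hidden(xb), model.hidden(xu)), lam)


def export_cv_table(model: DeepLDAModel, grids: list[np.ndarray]) -> pd.DataFrame:
    """Tabulate s_w(d) on a mesh (1-D or 2-D descriptor spaces) for use by
    external bias engines."""
    if len(grids) != model.n_descriptors:
        raise ValueError("one grid per descriptor required")
    if len(grids) > 2:
        raise ValueError("table export supported for 1 or 2 descriptors")
    mesh = np.meshgrid(*grids, indexing="ij")
    pts = np.column_stack([m.ravel() for m in mesh])
    sw = model.cv_value(pts)
    cols = {f"d_{i + 1}": pts[:, i] for i in range(pts.shape[1])}
    cols["s_w"] = sw
    return pd.DataFrame(cols)
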