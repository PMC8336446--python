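"""Gated-attention multi-instance network over one-hot sequence instances.

Every instance of a bag passes through the same small convolutional encoder
(motif scanner -> max-pool -> dropout -> motif-combination layer -> global
max-pool) producing an embedding ``h_k``.  The bag probability comes from one
of four pooling heads:

* ``gated`` (feature merging): attention weights
  ``a_k = softmax_k( w^T ( tanh(V h_k) * sigmoid(U h_k) ) )`` over the real
  instances, bag embedding ``z = sum_k a_k h_k``, then a fully connected
  sigmoid classifier on ``z``.  The weights form a simplex, so the head is
  invariant to bag size, and the highest-weight instance localizes the
  modification-containing sub-region.
* ``max`` / ``avg`` / ``noisy_and`` (score merging): a shared per-instance
  sigmoid head scores every instance and the scores are pooled.  Noisy-and is
  a saturating function of the mean score with a learnable threshold.

The network is implemented directly in numpy with explicit reverse-mode
gradients — both for the parameters (training) and for the input one-hot
matrix (integrated-gradients attribution).  Forward passes are deterministic
in eval mode; dropout is active only in training mode.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

Pooling = Literal["gated", "max", "avg", "noisy_and"]

_EPS = 1e-7


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass(frozen=True)
class EncoderConfig:
    """Instance-encoder hyperparameters.

    Defaults are sized for 50-nt instances on a CPU: a 15-nt motif-scanning
    convolution, width-4 max-pool, dropout 0.2, a 5-unit second convolution
    capturing local motif dependencies, and a global max-pool to a 32-dim
    embedding.  ``attention_dim`` is the hidden width of the gated-attention
    scorer.
    """

    conv1_filters: int = 32
    conv1_width: int = 15
    pool_width: int = 4
    dropout_rate: float = 0.2
    conv2_filters: int = 32
    conv2_width: int = 5
    attention_dim: int = 64

    def __post_init__(self) -> None:
        for name in ("conv1_filters", "conv1_width", "pool_width", "conv2_filters", "conv2_width", "attention_dim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")

    @property
    def embedding_dim(self) -> int:
        return self.conv2_filters

    def min_window(self) -> int:
        """Smallest instance length the architecture accepts."""
        return self.conv1_width + self.pool_width * (self.conv2_width - 1)


@dataclass
class AttentionOutput:
    """Per-instance simplex weights ``a`` and the bag embedding ``z``."""

    weights: np.ndarray
    embedding: np.ndarray


def gated_attention(
    h: np.ndarray,
    V: np.ndarray,
    U: np.ndarray,
    w: np.ndarray,
    mask: np.ndarray | None = None,
) -> AttentionOutput:
    """Gated-attention pooling of K instance embeddings.

    ``a_k`` is the masked softmax of ``w^T(tanh(V h_k^T) * sigm(U h_k^T))``;
    padded instances are excluded from the softmax and receive weight 0.
    """
    h = np.asarray(h, dtype=np.float64)
    if h.ndim != 2:
        raise ValueError("h must be K x embedding_dim")
    K = h.shape[0]
    mask = np.ones(K) if mask is None else np.asarray(mask, dtype=np.float64)
    if mask.sum() == 0:
        raise ValueError("bag has no real (unmasked) instances")
    t = np.tanh(h @ V.T)
    g = _sigmoid(h @ U.T)
    e = (t * g) @ w
    e = np.where(mask > 0, e, -np.inf)
    e -= e[mask > 0].max()
    a = np.where(mask > 0, np.exp(e), 0.0)
    a /= a.sum()
    return AttentionOutput(weights=a, embedding=a @ h)


def noisy_and(mean_score: np.ndarray | float, threshold: float, slope: float = 10.0) -> np.ndarray | float:
    """Saturating pooled probability from a mean instance score.

    ``(sigm(a*(m - b)) - sigm(-a*b)) / (sigm(a*(1 - b)) - sigm(-a*b))`` with
    slope ``a`` and learnable threshold ``b`` in (0, 1); maps mean 0 -> 0 and
    mean 1 -> 1 and is monotone in between.
    """
    m = np.asarray(mean_score, dtype=np.float64)
    a, b = float(slope), float(threshold)
    lo = _sigmoid(np.asarray(-a * b))
    hi = _sigmoid(np.asarray(a * (1.0 - b)))
    return (_sigmoid(a * (m - b)) - lo) / (hi - lo)


def pool_baseline(
    scores: np.ndarray,
    method: str,
    mask: np.ndarray | None = None,
    threshold: float = 0.5,
    slope: float = 10.0,
) -> float:
    """Pool per-instance scores in [0, 1] into a bag score.

    ``max`` and ``avg`` over real instances; ``noisy_and`` applies the
    saturating threshold function to the mean.
    """
    scores = np.asarray(scores, dtype=np.float64)
    mask = np.ones_like(scores) if mask is None else np.asarray(mask, dtype=np.float64)
    if scores.size == 0 or mask.sum() == 0:
        raise ValueError("cannot pool an empty instance list")
    real = scores[mask > 0]
    if method == "max":
        return float(real.max())
    if method == "avg":
        return float(real.mean())
    if method == "noisy_and":
        return float(noisy_and(real.mean(), threshold, slope))
    raise ValueError(f"unknown pooling method {method!r}")


def _im2col(x: np.ndarray, width: int) -> np.ndarray:
    """(N, L, C) -> (N, L - width + 1, width * C) sliding windows."""
    win = np.lib.stride_tricks.sliding_window_view(x, width, axis=1)
    # win: (N, L-width+1, C, width) -> (N, Lout, width, C)
    win = win.transpose(0, 1, 3, 2)
    n, lout = win.shape[0], win.shape[1]
    return np.ascontiguousarray(win).reshape(n, lout, width * x.shape[2])


def _fold_cols(dcols: np.ndarray, width: int, channels: int, length: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`."""
    n, lout = dcols.shape[0], dcols.shape[1]
    d = dcols.reshape(n, lout, width, channels)
    out = np.zeros((n, length, channels), dtype=dcols.dtype)
    for j in range(width):
        out[:, j : j + lout, :] += d[:, :, j, :]
    return out


class MILModel:
    """Multi-instance bag classifier with a shared instance encoder.

    Parameters are plain numpy arrays initialized with fan-in-scaled normal
    noise from a recorded seed.  ``pooling`` selects the head; all parameter
    tensors exist regardless of the head so checkpoints are interchangeable.
    """

    SCHEMA_VERSION = 1

    def __init__(
        self,
        cfg: EncoderConfig | None = None,
        pooling: Pooling = "gated",
        seed: int = 0,
        noisy_and_slope: float = 10.0,
    ) -> None:
        self.cfg = cfg or EncoderConfig()
        if pooling not in ("gated", "max", "avg", "noisy_and"):
            raise ValueError(f"unknown pooling {pooling!r}")
        self.pooling = pooling
        self.seed = seed
        self.noisy_and_slope = noisy_and_slope
        c = self.cfg
        rng = np.random.default_rng(seed)

        def init(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        d, da = c.embedding_dim, c.attention_dim
        self.params: dict[str, np.ndarray] = {
            "W1": init((c.conv1_width * 4, c.conv1_filters), c.conv1_width * 4),
            "b1": np.zeros(c.conv1_filters),
            "W2": init((c.conv2_width * c.conv1_filters, c.conv2_filters), c.conv2_width * c.conv1_filters),
            "b2": np.zeros(c.conv2_filters),
            "V": init((da, d), d),
            "U": init((da, d), d),
            "w_att": init((da,), da),
            "Wc": init((d,), d),
            "bc": np.zeros(()),
            "Wi": init((d,), d),
            "bi": np.zeros(()),
            "beta": np.zeros(()),  # noisy-and threshold b = sigmoid(beta)
        }

    # ------------------------------------------------------------------
    # forward

    def _encode(self, x: np.ndarray, train: bool, rng: np.random.Generator | None):
        """Shared-weight encoder: (B, K, c, 4) -> embeddings (B, K, d)."""
        cfg, P = self.cfg, self.params
        B, K, c, _ = x.shape
        if c < cfg.min_window():
            raise ValueError(
                f"instance length {c} is below the architecture minimum "
                f"{cfg.min_window()} (conv widths and pooling)"
            )
        xr = x.reshape(B * K, c, 4).astype(np.float64)
        cols1 = _im2col(xr, cfg.conv1_width)
        z1 = cols1 @ P["W1"] + P["b1"]
        r1 = np.maximum(z1, 0.0)

        pw = cfg.pool_width
        l1 = r1.shape[1]
        l1p = l1 // pw
        blocks = r1[:, : l1p * pw, :].reshape(B * K, l1p, pw, -1)
        arg1 = blocks.argmax(axis=2)
        p1 = np.take_along_axis(blocks, arg1[:, :, None, :], axis=2)[:, :, 0, :]

        if train and cfg.dropout_rate > 0.0:
            if rng is None:
                raise ValueError("training-mode forward needs an rng for dropout")
            keep = (rng.random(p1.shape) >= cfg.dropout_rate) / (1.0 - cfg.dropout_rate)
        else:
            keep = None
        p1d = p1 if keep is None else p1 * keep

        cols2 = _im2col(p1d, cfg.conv2_width)
        z2 = cols2 @ P["W2"] + P["b2"]
        r2 = np.maximum(z2, 0.0)
        arg2 = r2.argmax(axis=1)
        h = np.take_along_axis(r2, arg2[:, None, :], axis=1)[:, 0, :]
        cache = dict(
            x=xr, cols1=cols1, z1=z1, arg1=arg1, p1=p1, keep=keep,
            cols2=cols2, z2=z2, arg2=arg2, l1=l1, l1p=l1p, shape=(B, K, c),
        )
        return h.reshape(B, K, -1), cache

    def forward(
        self,
        x: np.ndarray,
        mask: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ):
        """Bag probabilities and per-instance weights/scores.

        Returns ``(probs (B,), weights (B, K), cache)``; ``weights`` are
        attention weights for the gated head and instance scores for the
        score-merging heads.  Masked instances get weight/score 0.
        """
        x = np.asarray(x, dtype=np.float64)
        mask = np.asarray(mask, dtype=np.float64)
        if x.ndim != 4:
            raise ValueError("x must be (B, K, c, 4)")
        if (mask.sum(axis=1) == 0).any():
            raise ValueError("every bag needs at least one real instance")
        P = self.params
        h, enc_cache = self._encode(x, train, rng)
        B, K, d = h.shape
        cache: dict = dict(enc=enc_cache, h=h, mask=mask)

        if self.pooling == "gated":
            t = np.tanh(h @ P["V"].T)
            g = _sigmoid(h @ P["U"].T)
            e = (t * g) @ P["w_att"]
            e = np.where(mask > 0, e, -np.inf)
            e = e - np.max(np.where(mask > 0, e, -np.inf), axis=1, keepdims=True)
            expe = np.where(mask > 0, np.exp(e), 0.0)
            a = expe / expe.sum(axis=1, keepdims=True)
            z = np.einsum("bk,bkd->bd", a, h)
            logit = z @ P["Wc"] + P["bc"]
            prob = _sigmoid(logit)
            cache.update(t=t, g=g, a=a, z=z, logit=logit, prob=prob)
            return prob, a, cache

        li = h @ P["Wi"] + P["bi"]
        sc = _sigmoid(li) * (mask > 0)
        kreal = mask.sum(axis=1)
        if self.pooling == "max":
            li_masked = np.where(mask > 0, li, -np.inf)
            argk = li_masked.argmax(axis=1)
            prob = _sigmoid(li_masked[np.arange(B), argk])
            cache.update(li=li, sc=sc, argk=argk, prob=prob)
        elif self.pooling == "avg":
            prob = (sc * (mask > 0)).sum(axis=1) / kreal
            cache.update(li=li, sc=sc, kreal=kreal, prob=prob)
        else:  # noisy_and
            mean = (sc * (mask > 0)).sum(axis=1) / kreal
            b_t = float(_sigmoid(self.params["beta"]))
            prob = np.asarray(noisy_and(mean, b_t, self.noisy_and_slope))
            cache.update(li=li, sc=sc, kreal=kreal, mean=mean, b_t=b_t, prob=prob)
        return prob, sc, cache

    def encode_instances(
        self,
        instances: np.ndarray,
        mode: str = "eval",
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Embed a (K, c, 4) one-hot instance stack with the shared encoder.

        Identical weights are applied to every instance; ``mode='eval'`` is
        deterministic (dropout off).
        """
        x = np.asarray(instances, dtype=np.float64)
        if hasattr(instances, "instances"):
            x = np.asarray(instances.instances, dtype=np.float64)
        if mode not in ("train", "eval"):
            raise ValueError("mode must be 'train' or 'eval'")
        h, _ = self._encode(x[None], train=mode == "train", rng=rng)
        return h[0]

    def predict(self, x: np.ndarray, mask: np.ndarray):
        """Deterministic eval-mode probabilities and instance weights."""
        prob, weights, _ = self.forward(x, mask, train=False)
        return prob, weights

    # ------------------------------------------------------------------
    # backward

    def backward(self, cache: dict, dprob: np.ndarray):
        """Reverse-mode pass from dL/dprob.

        Returns ``(grads, dx)`` where ``grads`` maps parameter names to
        gradients and ``dx`` has the input's (B, K, c, 4) shape.
        """
        P, cfg = self.params, self.cfg
        h, mask = cache["h"], cache["mask"]
        B, K, d = h.shape
        grads = {k: np.zeros_like(v) for k, v in P.items()}
        dprob = np.asarray(dprob, dtype=np.float64)

        if self.pooling == "gated":
            a, z, t, g, prob = cache["a"], cache["z"], cache["t"], cache["g"], cache["prob"]
            dlogit = dprob * prob * (1.0 - prob)
            grads["Wc"] = dlogit @ z
            grads["bc"] = np.asarray(dlogit.sum())
            dz = dlogit[:, None] * P["Wc"][None, :]
            da = np.einsum("bd,bkd->bk", dz, h)
            dh = a[:, :, None] * dz[:, None, :]
            # masked-softmax backward (a is 0 on padding)
            de = a * (da - (a * da).sum(axis=1, keepdims=True))
            s_t = de[:, :, None] * P["w_att"] * g * (1.0 - t * t)
            s_g = de[:, :, None] * P["w_att"] * t * g * (1.0 - g)
            grads["V"] = np.einsum("bkd,bkf->df", s_t, h)
            grads["U"] = np.einsum("bkd,bkf->df", s_g, h)
            grads["w_att"] = np.einsum("bk,bkd->d", de, t * g)
            dh = dh + s_t @ P["V"] + s_g @ P["U"]
            dh *= mask[:, :, None]
        else:
            li, sc = cache["li"], cache["sc"]
            dli = np.zeros_like(li)
            if self.pooling == "max":
                argk, prob = cache["argk"], cache["prob"]
                dli[np.arange(B), argk] = dprob * prob * (1.0 - prob)
            elif self.pooling == "avg":
                dsc = dprob[:, None] * (mask > 0) / cache["kreal"][:, None]
                dli = dsc * sc * (1.0 - sc)
            else:
                mean, b_t = cache["mean"], cache["b_t"]
                A = self.noisy_and_slope
                lo = _sigmoid(np.asarray(-A * b_t))
                hi = _sigmoid(np.asarray(A * (1.0 - b_t)))
                den = hi - lo
                sm = _sigmoid(A * (mean - b_t))
                num = sm - lo
                dp_dmean = A * sm * (1.0 - sm) / den
                dnum_db = -A * sm * (1.0 - sm) + A * lo * (1.0 - lo)
                dden_db = -A * hi * (1.0 - hi) + A * lo * (1.0 - lo)
                dp_db = (dnum_db * den - num * dden_db) / (den * den)
                dmean = dprob * dp_dmean
                db = float((dprob * dp_db).sum())
                grads["beta"] = np.asarray(db * b_t * (1.0 - b_t))
                dsc = dmean[:, None] * (mask > 0) / cache["kreal"][:, None]
                dli = dsc * sc * (1.0 - sc)
            grads["Wi"] = np.einsum("bk,bkd->d", dli, h)
            grads["bi"] = np.asarray(dli.sum())
            dh = dli[:, :, None] * P["Wi"][None, None, :]
            dh *= mask[:, :, None]

        dx = self._encode_backward(cache["enc"], dh.reshape(B * K, d), grads)
        return grads, dx.reshape(B, K, cache["enc"]["shape"][2], 4)

    def _encode_backward(self, ec: dict, dh: np.ndarray, grads: dict) -> np.ndarray:
        cfg, P = self.cfg, self.params
        n = dh.shape[0]
        # global max-pool
        dr2 = np.zeros_like(ec["z2"])
        np.put_along_axis(dr2, ec["arg2"][:, None, :], dh[:, None, :], axis=1)
        dz2 = dr2 * (ec["z2"] > 0)
        grads["W2"] = ec["cols2"].reshape(-1, ec["cols2"].shape[2]).T @ dz2.reshape(-1, dz2.shape[2])
        grads["b2"] = dz2.sum(axis=(0, 1))
        dcols2 = dz2 @ P["W2"].T
        dp1d = _fold_cols(dcols2, cfg.conv2_width, cfg.conv1_filters, ec["l1p"])
        if ec["keep"] is not None:
            dp1 = dp1d * ec["keep"]
        else:
            dp1 = dp1d
        # max-pool within width-pw blocks
        pw = cfg.pool_width
        dblocks = np.zeros((n, ec["l1p"], pw, cfg.conv1_filters))
        np.put_along_axis(dblocks, ec["arg1"][:, :, None, :], dp1[:, :, None, :], axis=2)
        dr1 = np.zeros_like(ec["z1"])
        dr1[:, : ec["l1p"] * pw, :] = dblocks.reshape(n, ec["l1p"] * pw, -1)
        dz1 = dr1 * (ec["z1"] > 0)
        grads["W1"] = ec["cols1"].reshape(-1, ec["cols1"].shape[2]).T @ dz1.reshape(-1, dz1.shape[2])
        grads["b1"] = dz1.sum(axis=(0, 1))
        dcols1 = dz1 @ P["W1"].T
        return _fold_cols(dcols1, cfg.conv1_width, 4, ec["shape"][2])

    # ------------------------------------------------------------------

    def input_gradient(self, x: np.ndarray, mask: np.ndarray, wrt: str = "prob") -> np.ndarray:
        """d(output)/d(input) in eval mode; ``wrt`` is 'prob' or 'logit'.

        For score-merging heads 'logit' falls back to the probability since
        the pooled output is not a single sigmoid pre-activation.
        """
        prob, _, cache = self.forward(x, mask, train=False)
        if wrt == "logit" and self.pooling == "gated":
            dprob = 1.0 / np.maximum(prob * (1.0 - prob), _EPS)
        elif wrt in ("prob", "logit"):
            dprob = np.ones_like(prob)
        else:
            raise ValueError("wrt must be 'prob' or 'logit'")
        _, dx = self.backward(cache, dprob)
        return dx

    # ------------------------------------------------------------------
    # checkpoints

    def save(self, path: str | Path) -> None:
        """Serialize parameters (npz) with a JSON config sidecar."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.params)
        sidecar = {
            "schema_version": self.SCHEMA_VERSION,
            "encoder": asdict(self.cfg),
            "pooling": self.pooling,
            "seed": self.seed,
            "noisy_and_slope": self.noisy_and_slope,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "MILModel":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        if sidecar.get("schema_version") != cls.SCHEMA_VERSION:
            raise ValueError("unsupported checkpoint schema version")
        model = cls(
            EncoderConfig(**sidecar["encoder"]),
            pooling=sidecar["pooling"],
            seed=sidecar["seed"],
            noisy_and_slope=sidecar["noisy_and_slope"],
        )
        with np.load(path.with_suffix(".npz")) as data:
            model.params = {k: data[k].copy() for k in data.files}
        return model

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}
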