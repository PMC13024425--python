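"""The improved BiLSTM network with a dynamic vector-routing classifier.

Architecture, for an input epoch tensor (B, 1, C, T):

1. reshape to (B, T, C): the sequence runs along time, and the network sees
   the full C-channel snapshot at every step;
2. a single bidirectional LSTM layer encodes temporal context; forward and
   backward hidden states are concatenated to h_t in R^{2H} (no extra
   normalization or activation);
3. a time-shared affine map followed by the squash nonlinearity turns each
   h_t into a lower-level vector unit u_t in R^d with norm in [0, 1);
4. dynamic routing (r iterations) aggregates the T lower units into one
   output vector per class; the couplings of each class are softmax
   normalized over the lower units, so they sum to 1 across time;
5. the norm of each class vector is its confidence; a learnable positive
   scale maps norms to logits; training minimizes a margin loss on the
   norms and inference picks the class with the largest norm (ties go to
   the lower class index).

Ablation variants: ``routing_only`` feeds per-time-step channel snapshots
directly through the vectorizing affine map (no recurrent encoder);
``bilstm_only`` replaces routing with a mean-pooled hidden state and a dense
two-way readout whose sigmoid scores are trained with the same margin loss;
``bidirectional=False`` uses a single forward LSTM.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn

__all__ = [
    "ModelConfig", "RoutingState", "ForwardOutput", "BiLSTMRoutingClassifier",
    "squash", "bilstm_encode", "primary_vectorize", "dynamic_route", "margin_loss",
    "save_checkpoint", "load_checkpoint",
]

VARIANTS = ("full", "routing_only", "bilstm_only")


@dataclass(frozen=True)
class ModelConfig:
    hidden_size: int = 64
    vec_dim: int = 16
    out_vec_dim: int = 16
    n_classes: int = 2
    routing_iters: int = 3
    bidirectional: bool = True
    variant: str = "full"
    squash_variant: str = "paper_linear"
    m_plus: float = 0.9
    m_minus: float = 0.1
    lam: float = 0.5
    logit_scale_init: float = 1.0
    in_channels: int = 128
    seed: int = 0
    route_init_scale: float = 3.0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if not (0 < self.m_minus < self.m_plus < 1):
            raise ValueError("need 0 < m_minus < m_plus < 1")
        if self.routing_iters < 1:
            raise ValueError("routing_iters must be >= 1")
        if min(self.hidden_size, self.vec_dim, self.out_vec_dim) < 1:
            raise ValueError("hidden_size, vec_dim, out_vec_dim must be >= 1")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.logit_scale_init <= 0:
            raise ValueError("logit_scale_init must be positive")


@dataclass
class RoutingState:
    """Couplings and class vectors after the final routing iteration.

    Arrays carry a leading batch axis: b and a are (B, K, n1), v is (B, K, d').
    For every class j, a[:, j, :] sums to 1 over the n1 lower units.
    """

    b: np.ndarray
    a: np.ndarray
    v: np.ndarray
    iteration: int


@dataclass
class ForwardOutput:
    class_vectors: np.ndarray  # (B, K, d')
    class_norms: np.ndarray  # (B, K) in [0, 1)
    logits: np.ndarray  # (B, K) = scale * norms
    prediction: np.ndarray  # (B,) argmax of norms, ties -> lower index
    routing: RoutingState | None = None


# -- spec-level functional surface ------------------------------------------

def squash(s: np.ndarray, variant: str = "paper_linear") -> np.ndarray:
    """Squash vectors along the last axis; norm in [0, 1), direction kept."""
    v, _ = nn.squash_forward(s, variant)
    return v


def margin_loss(class_norms: np.ndarray, targets: np.ndarray,
                m_plus: float = 0.9, m_minus: float = 0.1, lam: float = 0.5) -> float:
    """Batch-averaged margin loss on class-vector norms."""
    loss, _ = nn.margin_loss_forward(class_norms, targets, m_plus, m_minus, lam)
    return loss


def dynamic_route(u: np.ndarray, W: np.ndarray, r: int,
                  squash_variant: str = "paper_linear") -> RoutingState:
    """Route lower units u (B, T, d) to class vectors via W (K, d', d)."""
    a, v, cache = nn.routing_forward(u, W, r, squash_variant)
    return RoutingState(b=cache["b_final"], a=a, v=v, iteration=r)


class BiLSTMRoutingClassifier:
    """NumPy implementation with explicit forward/backward passes."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.params = self._init_params(np.random.default_rng(config.seed))

    # -- parameters ---------------------------------------------------------

    def _init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        cfg = self.config
        p: dict[str, np.ndarray] = {}
        enc_out = cfg.in_channels
        if cfg.variant != "routing_only":
            for key in (("lstm_f",) if not cfg.bidirectional else ("lstm_f", "lstm_b")):
                for name, arr in nn.lstm_init(rng, cfg.in_channels, cfg.hidden_size).items():
                    p[f"{key}.{name}"] = arr
            enc_out = cfg.hidden_size * (2 if cfg.bidirectional else 1)
        if cfg.variant == "bilstm_only":
            k = 1.0 / np.sqrt(enc_out)
            p["dense.W"] = rng.uniform(-k, k, size=(enc_out, cfg.n_classes))
            p["dense.b"] = np.zeros(cfg.n_classes)
        else:
            k = 1.0 / np.sqrt(enc_out)
            p["prim.A"] = rng.uniform(-k, k, size=(enc_out, cfg.vec_dim))
            # unit-vector bias: gives the lower units a common base direction,
            # so amplitude differences between inputs also tilt their direction
            # instead of only rescaling a near-zero vector
            c = rng.standard_normal(cfg.vec_dim)
            p["prim.c"] = c / np.linalg.norm(c)
            # Glorot limit scaled up: the linear squash only has usable
            # gradient for pre-activation norms of order 1, so the routing
            # transform starts with class norms mid-range between the margins
            # instead of collapsed near zero
            limit = cfg.route_init_scale * np.sqrt(6.0 / (cfg.vec_dim + cfg.out_vec_dim))
            p["route.W"] = rng.uniform(
                -limit, limit, size=(cfg.n_classes, cfg.out_vec_dim, cfg.vec_dim))
        # positive logit scale parameterized through exp
        p["scale.rho"] = np.array(np.log(cfg.logit_scale_init))
        dt = np.dtype(cfg.dtype)
        return {k: np.asarray(v, dtype=dt) for k, v in p.items()}

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        self.params = {k: v.copy() for k, v in params.items()}

    # -- forward ------------------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        cfg = self.config
        if x.ndim != 4 or x.shape[1] != 1 or x.shape[2] != cfg.in_channels:
            raise ValueError(
                f"expected input (B, 1, {cfg.in_channels}, T), got {x.shape}")
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite values in model input")
        # (B, 1, C, T) -> (B, T, C)
        return np.ascontiguousarray(
            x[:, 0].transpose(0, 2, 1), dtype=np.dtype(cfg.dtype))

    def _encode(self, xs: np.ndarray) -> tuple[np.ndarray, dict]:
        p, cfg = self.params, self.config
        hf, cache_f = nn.lstm_forward(
            xs, {"Wx": p["lstm_f.Wx"], "Wh": p["lstm_f.Wh"], "b": p["lstm_f.b"]},
            validate=False)  # _check_input already validated
        if cfg.bidirectional:
            hb, cache_b = nn.lstm_forward(
                xs, {"Wx": p["lstm_b.Wx"], "Wh": p["lstm_b.Wh"], "b": p["lstm_b.b"]},
                reverse=True, validate=False)
            h = np.concatenate([hf, hb], axis=-1)
        else:
            hb = cache_b = None
            h = hf
        return h, {"f": cache_f, "b": cache_b}

    def forward(self, x: np.ndarray, with_cache: bool = False):
        """Run the network on (B, 1, C, T); returns a ForwardOutput.

        With ``with_cache=True`` returns (output, cache) for backward().
        """
        xs = self._check_input(x)
        p, cfg = self.params, self.config
        cache: dict = {"xs_shape": xs.shape}
        if cfg.variant == "bilstm_only":
            h, enc_cache = self._encode(xs)
            pooled = h.mean(axis=1)  # (B, 2H)
            scores = pooled @ p["dense.W"] + p["dense.b"]
            norms = nn.sigmoid(scores)  # (0,1) confidence per class
            vectors = norms[..., None]
            routing = None
            cache.update(enc=enc_cache, h=h, pooled=pooled, scores=scores, norms=norms)
        else:
            if cfg.variant == "routing_only":
                h = xs  # lower units come straight from channel snapshots
                enc_cache = None
            else:
                h, enc_cache = self._encode(xs)
            pre = h @ p["prim.A"] + p["prim.c"]
            u, _ = nn.squash_forward(pre, cfg.squash_variant)
            a, v, route_cache = nn.routing_forward(
                u, p["route.W"], cfg.routing_iters, cfg.squash_variant)
            norms = np.linalg.norm(v, axis=-1)
            vectors = v
            routing = RoutingState(b=route_cache["b_final"], a=a, v=v,
                                   iteration=cfg.routing_iters)
            cache.update(enc=enc_cache, h=h, pre=pre, u=u, route=route_cache,
                         v=v, norms=norms)
        scale = np.exp(p["scale.rho"])
        out = ForwardOutput(
            class_vectors=vectors,
            class_norms=norms,
            logits=scale * norms,
            prediction=np.argmax(norms, axis=1),
            routing=routing,
        )
        return (out, cache) if with_cache else out

    # -- backward -----------------------------------------------------------

    def backward(self, dnorms: np.ndarray, cache: dict,
                 want_input_grad: bool = False):
        """Backprop a gradient w.r.t. the class norms through the network.

        Returns (grads, dx) where dx is (B, T, C) or None.
        """
        p, cfg = self.params, self.config
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        if cfg.variant == "bilstm_only":
            norms = cache["norms"]
            dscores = dnorms * norms * (1.0 - norms)
            grads["dense.W"] = cache["pooled"].T @ dscores
            grads["dense.b"] = dscores.sum(axis=0)
            dpooled = dscores @ p["dense.W"].T
            T = cache["h"].shape[1]
            dh = np.repeat(dpooled[:, None, :] / T, T, axis=1)
            dx = self._encode_backward(dh, cache["enc"], grads, want_input_grad)
            return grads, dx
        # routing variants: norms -> v
        v = cache["v"]
        n = np.maximum(cache["norms"], nn.EPS)
        dv = dnorms[..., None] * v / n[..., None]
        du, dW = nn.routing_backward(dv, cache["route"])
        grads["route.W"] = dW
        dpre = nn.squash_backward(du, cache["pre"], cfg.squash_variant)
        h = cache["h"]
        grads["prim.A"] = h.reshape(-1, h.shape[-1]).T @ dpre.reshape(-1, dpre.shape[-1])
        grads["prim.c"] = dpre.sum(axis=(0, 1))
        dh = dpre @ p["prim.A"].T
        if cfg.variant == "routing_only":
            return grads, (dh if want_input_grad else None)
        dx = self._encode_backward(dh, cache["enc"], grads, want_input_grad)
        return grads, dx

    def _encode_backward(self, dh: np.ndarray, enc_cache: dict,
                         grads: dict, want_input_grad: bool):
        cfg = self.config
        H = cfg.hidden_size
        dx_f, g_f = nn.lstm_backward(dh[..., :H], enc_cache["f"],
                                     want_dx=want_input_grad)
        for name, g in g_f.items():
            grads[f"lstm_f.{name}"] = g
        dx = dx_f
        if cfg.bidirectional:
            dx_b, g_b = nn.lstm_backward(dh[..., H:], enc_cache["b"],
                                         want_dx=want_input_grad)
            for name, g in g_b.items():
                grads[f"lstm_b.{name}"] = g
            dx = dx + dx_b if want_input_grad else None
        return dx if want_input_grad else None

    # -- training-facing helpers --------------------------------------------

    def loss_and_grads(self, x: np.ndarray, targets: np.ndarray):
        out, cache = self.forward(x, with_cache=True)
        cfg = self.config
        loss, dnorms = nn.margin_loss_forward(
            out.class_norms, targets, cfg.m_plus, cfg.m_minus, cfg.lam)
        grads, _ = self.backward(dnorms, cache)
        return loss, grads, out

    def predict(self, x: np.ndarray, batch_size: int = 256) -> ForwardOutput:
        outs = [self.forward(x[i:i + batch_size]) for i in range(0, len(x), batch_size)]
        return ForwardOutput(
            class_vectors=np.concatenate([o.class_vectors for o in outs]),
            class_norms=np.concatenate([o.class_norms for o in outs]),
            logits=np.concatenate([o.logits for o in outs]),
            prediction=np.concatenate([o.prediction for o in outs]),
        )


# -- spec-level wrappers over a model instance ------------------------------

def bilstm_encode(model: BiLSTMRoutingClassifier, x: np.ndarray) -> np.ndarray:
    """Temporal encoding only: (B, T, C) -> (B, T, 2H) (or (B, T, H))."""
    h, _ = model._encode(x)
    return h


def primary_vectorize(model: BiLSTMRoutingClassifier, h: np.ndarray) -> np.ndarray:
    """Time-shared affine map + squash: (B, T, enc) -> (B, T, d)."""
    pre = h @ model.params["prim.A"] + model.params["prim.c"]
    return squash(pre, model.config.squash_variant)


# -- checkpointing ----------------------------------------------------------

def save_checkpoint(model: BiLSTMRoutingClassifier, path: str | Path) -> None:
    """Weights as npz next to a JSON config sidecar (.json suffix added)."""
    path = Path(path)
    np.savez_compressed(path, **model.params)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"config": asdict(model.config)}, indent=2))


def load_checkpoint(path: str | Path) -> BiLSTMRoutingClassifier:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    cfg = ModelConfig(**json.loads(sidecar.read_text())["config"])
    model = BiLSTMRoutingClassifier(cfg)
    with np.load(path) as data:
        model.params = {k: data[k].copy() for k in data.files}
    return model
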