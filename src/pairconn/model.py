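"""The pairwise-attention connectivity network.

Six stages map a parcellated scan x = (s_1 .. s_N), s_i in R^T, to l
logits:

1. region embedding        e_i = E(s_i), a six-layer 1-D CNN shared
                           across regions, linear head to R^d;
2. pairwise connectivity   k_ij = F([e_i, e_j]), an MLP with terminal
                           sigmoid, applied to every ordered pair,
                           giving K in [0,1]^{NxN};
3. attention weights       w_i = beta + (1-beta) * sum_{j != i} k_ij;
4. reweighting             e_i' = w_i * e_i;
5. updated connectivity    k_ij' = F([w_i e_i, w_j e_j]) with the SAME F;
6. classification          logits = C(flatten(K')), C an MLP whose first
                           hidden layer (width 100) provides the feature
                           vector used for the 2-D embedding analysis.

Ablation switches replace E by the identity, F by the sample Pearson
correlation (differentiable, so E still trains through it), or drop the
reweighting so that classification acts on K directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Parameter, Tensor
from .config import ModelConfig, POOL_AFTER
from .data import SubjectTimeSeries

__all__ = [
    "PairwiseAttentionNet",
    "ForwardResult",
    "attention_weights",
    "reweight_embeddings",
    "pearson_connectivity",
]


# ---------------------------------------------------------------------
# reference (numpy) forms of the closed-form stages
# ---------------------------------------------------------------------


def attention_weights(K: np.ndarray, beta: float) -> np.ndarray:
    """w_i = beta + (1-beta) * sum_{j != i} k_ij for a single N x N matrix."""
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta must be in [0,1], got {beta}")
    K = np.asarray(K, dtype=np.float64)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("K must be square")
    return beta + (1.0 - beta) * (K.sum(axis=1) - np.diagonal(K))


def reweight_embeddings(emb: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Scale embedding row i by its attention weight w_i."""
    emb = np.asarray(emb, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    if emb.shape[0] != w.shape[0]:
        raise ValueError("one weight per region required")
    return emb * w[:, None]


def pearson_connectivity(emb: np.ndarray) -> np.ndarray:
    """Sample Pearson correlation between all row pairs (closed form)."""
    z = emb - emb.mean(axis=1, keepdims=True)
    n = np.sqrt((z * z).sum(axis=1))
    n = np.maximum(n, 1e-12)
    return (z @ z.T) / np.outer(n, n)


def _row_correlation(emb: Tensor) -> Tensor:
    """Differentiable batched row-wise Pearson correlation (B,N,d)->(B,N,N)."""
    e = emb.data
    z = e - e.mean(axis=2, keepdims=True)
    nrm = np.sqrt((z * z).sum(axis=2))
    nrm = np.maximum(nrm, 1e-12)
    zn = z / nrm[:, :, None]
    R = np.einsum("bid,bjd->bij", zn, zn)
    out = ad._node(R, (emb,))

    def bwd(g):
        H = g + g.transpose(0, 2, 1)
        t1 = np.einsum("bij,bjd->bid", H, zn) / nrm[:, :, None]
        t2 = (H * R).sum(axis=2)[:, :, None] * z / (nrm ** 2)[:, :, None]
        gz = t1 - t2
        emb._accumulate(gz - gz.mean(axis=2, keepdims=True))

    out._backward = bwd
    return out


# ---------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------


@dataclass
class ForwardResult:
    """Numpy view of one forward pass (evaluation mode)."""

    K: np.ndarray                 # (n, N, N)
    K_prime: np.ndarray | None    # absent under the no-reweighting ablation
    logits: np.ndarray            # (n, l)
    embeddings: np.ndarray        # (n, N, d_eff)
    weights: np.ndarray | None    # (n, N) attention weights
    hidden_features: np.ndarray   # (n, 100) first classifier-layer activations


# He-normal fan-in scaling for ReLU-followed layers, Glorot for the
# linear output layers: keeps activation variance (and hence the spread
# of connectivity scores across subjects) from collapsing through the
# deep shared extractor, which plain fan-in-uniform init does not.


def _init_linear(rng, fan_in, fan_out, relu=False):
    if relu:
        w = Parameter(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_out, fan_in)))
    else:
        bound = np.sqrt(6.0 / (fan_in + fan_out))
        w = Parameter(rng.uniform(-bound, bound, size=(fan_out, fan_in)))
    b = Parameter(np.zeros(fan_out))
    return w, b


def _init_conv(rng, c_in, c_out, k):
    fan_in = c_in * k
    w = Parameter(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k)))
    b = Parameter(np.zeros(c_out))
    return w, b


class PairwiseAttentionNet:
    """Stages 1-6 with shared parameters across regions and pairs."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self.seed = int(seed)
        self.dtype = np.float32 if config.precision == "float32" else np.float64
        rng = np.random.default_rng(self.seed)
        self.params: dict[str, Parameter] = {}
        self.fitted = False
        cfg = config

        if not cfg.identity_E:
            c_in = 1
            for li, c_out in enumerate(cfg.conv_filters):
                w, b = _init_conv(rng, c_in, c_out, 3)
                self.params[f"E.conv{li}.w"] = w
                self.params[f"E.conv{li}.b"] = b
                c_in = c_out
            flat = cfg.conv_filters[-1] * cfg.conv_output_len()
            w, b = _init_linear(rng, flat, cfg.embed_dim)
            self.params["E.out.w"] = w
            self.params["E.out.b"] = b

        d_eff = cfg.effective_embed_dim()
        if not cfg.pearson_F:
            widths = [2 * d_eff, *cfg.similarity_hidden, 1]
            for li in range(len(widths) - 1):
                w, b = _init_linear(rng, widths[li], widths[li + 1],
                                    relu=li < len(widths) - 2)
                self.params[f"F.lin{li}.w"] = w
                self.params[f"F.lin{li}.b"] = b

        widths = [cfg.n_regions ** 2, *cfg.classifier_hidden, cfg.head_size]
        for li in range(len(widths) - 1):
            w, b = _init_linear(rng, widths[li], widths[li + 1],
                                relu=li < len(widths) - 2)
            self.params[f"C.lin{li}.w"] = w
            self.params[f"C.lin{li}.b"] = b

        if self.dtype is np.float32:
            for p in self.params.values():
                p.data = p.data.astype(np.float32)

    # -- stages --------------------------------------------------------

    def embed(self, x: Tensor) -> Tensor:
        """(B, N, T) -> (B, N, d_eff); E shared across regions."""
        cfg = self.config
        B, N, T = x.shape
        if cfg.identity_E:
            return x
        h = x.reshape(B * N, 1, T)
        for li in range(6):
            h = ad.conv1d(h, self.params[f"E.conv{li}.w"], self.params[f"E.conv{li}.b"], pad=1)
            h = h.relu()
            if POOL_AFTER[li]:
                h = ad.maxpool1d(h)
        h = h.reshape(B * N, -1)
        h = ad.linear(h, self.params["E.out.w"], self.params["E.out.b"])
        return h.reshape(B, N, cfg.embed_dim)

    def connectivity(self, emb: Tensor) -> Tensor:
        """(B, N, d) -> (B, N, N) via F on every ordered pair."""
        cfg = self.config
        if cfg.pearson_F:
            return _row_correlation(emb)
        B, N, d = emb.shape
        pairs = ad.pairwise_concat(emb).reshape(B * N * N, 2 * d)
        h = pairs
        n_layers = len(cfg.similarity_hidden) + 1
        for li in range(n_layers):
            h = ad.linear(h, self.params[f"F.lin{li}.w"], self.params[f"F.lin{li}.b"])
            if li < n_layers - 1:
                h = h.relu()
        return h.sigmoid().reshape(B, N, N)

    def attention(self, K: Tensor) -> Tensor:
        beta = self.config.beta
        return ad.offdiag_row_sum(K).affine(1.0 - beta, beta)

    def classify(self, K: Tensor, train: bool = False, rng=None) -> tuple[Tensor, Tensor]:
        """Flattened connectivity -> (logits, 100-dim hidden features)."""
        cfg = self.config
        B = K.shape[0]
        h = K.reshape(B, cfg.n_regions ** 2)
        hidden = None
        n_layers = len(cfg.classifier_hidden) + 1
        for li in range(n_layers):
            h = ad.linear(h, self.params[f"C.lin{li}.w"], self.params[f"C.lin{li}.b"])
            if li == 0:
                hidden = h
            if li < n_layers - 1:
                h = h.relu()
                if train and cfg.dropout > 0:
                    h = ad.dropout(h, cfg.dropout, rng)
        return h, hidden

    # -- composition ---------------------------------------------------

    def forward_graph(self, x: np.ndarray, train: bool = False, rng=None) -> dict:
        """Build the full autodiff graph for a batch (n, N, T).

        Returns tensors for K, K', both logit paths, attention weights,
        embeddings and hidden features.  In training mode the classifier
        is applied twice with shared parameters: once to K (the L1 path)
        and once to K' (the L2 path).
        """
        cfg = self.config
        xt = Tensor(np.asarray(x, dtype=self.dtype))
        emb = self.embed(xt)
        K = self.connectivity(emb)
        out = {"embeddings": emb, "K": K}
        if cfg.no_reweighting:
            logits, hidden = self.classify(K, train=train, rng=rng)
            out.update(K_prime=None, weights=None,
                       logits_K=logits, logits_Kprime=None,
                       logits=logits, hidden=hidden)
            return out
        w = self.attention(K)
        if not cfg.pearson_F:
            self._check_weight_bounds(w.data)
        emb2 = ad.scale_rows(emb, w)
        K_prime = self.connectivity(emb2)
        logits_Kp, hidden = self.classify(K_prime, train=train, rng=rng)
        out.update(K_prime=K_prime, weights=w, logits_Kprime=logits_Kp,
                   logits=logits_Kp, hidden=hidden)
        if train:
            logits_K, _ = self.classify(K, train=True, rng=rng)
            out["logits_K"] = logits_K
        else:
            out["logits_K"] = None
        return out

    def _check_weight_bounds(self, w: np.ndarray):
        beta, N = self.config.beta, self.config.n_regions
        lo, hi = beta, beta + (1.0 - beta) * (N - 1)
        eps = 1e-9
        if w.min() < lo - eps or w.max() > hi + eps:
            raise AssertionError(
                f"attention weights outside [{lo}, {hi}]: "
                f"range [{w.min()}, {w.max()}]"
            )

    def predict(self, subjects, batch_size: int = 32) -> ForwardResult:
        """Evaluation-mode forward over a list of SubjectTimeSeries (or array)."""
        if isinstance(subjects, np.ndarray):
            X = subjects
        else:
            X = np.stack([
                s.matrix if isinstance(s, SubjectTimeSeries) else np.asarray(s)
                for s in subjects
            ])
        Ks, Kps, logits, embs, ws, hids = [], [], [], [], [], []
        for lo in range(0, X.shape[0], batch_size):
            out = self.forward_graph(X[lo:lo + batch_size], train=False)
            Ks.append(out["K"].data)
            logits.append(out["logits"].data)
            embs.append(out["embeddings"].data)
            hids.append(out["hidden"].data)
            if out["K_prime"] is not None:
                Kps.append(out["K_prime"].data)
                ws.append(out["weights"].data)
        return ForwardResult(
            K=np.concatenate(Ks),
            K_prime=np.concatenate(Kps) if Kps else None,
            logits=np.concatenate(logits),
            embeddings=np.concatenate(embs),
            weights=np.concatenate(ws) if ws else None,
            hidden_features=np.concatenate(hids),
        )

    # -- persistence ---------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.params.items()}

    def load_state_dict(self, state: dict):
        for k, p in self.params.items():
            arr = np.asarray(state[k], dtype=self.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr
        self.fitted = True
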