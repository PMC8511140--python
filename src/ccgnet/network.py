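"""The cocrystal graph network (CCGNet) in NumPy.

Architecture, in the order a sample flows through it:

1. *Message passing*: a stack of CCGBlocks. Each block runs

   - a single-layer feedforward update of the global state
     ``u_out = sigma(u W + b)`` applied independently to each coformer's
     descriptor row,
   - a bond-type graph convolution over the node features,
     ``V_out = sigma(I V_in W0 + GConv(V_in, F) + b)`` where the filter for
     input channel c is ``H^(c) = sum_l h_l^(c) A_l`` (one scalar per
     bond-type slice and channel, stacked over F output filters), and
   - a broadcast concatenation that appends each coformer's updated global
     state to every atom of that coformer.

2. *Readout*: K parallel global-attention heads. Each head scores every
   node with a small MLP, softmaxes over the real (unmasked) nodes of the
   graph, and sums the attention-weighted node vectors; the K head outputs
   are concatenated, then the final global state of both coformers is
   concatenated on.

3. A sequential dense head ends in two logits ``[a, b]`` (negative,
   positive class). A pair is predicted to cocrystallize iff ``b > a``;
   ties classify as negative.

All arithmetic is float64. Gradients are hand-derived reverse-mode and are
verified against finite differences in the test suite. All randomness
(weight initialization) flows from one seed recorded in checkpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .featurize import (
    DESCRIPTOR_NAMES,
    DESCRIPTORS_2D,
    DESCRIPTORS_3D,
    NUM_ATOM_FEATURES,
)

__all__ = [
    "CCGNetConfig",
    "COMPACT_CONFIG",
    "GraphConvWeights",
    "CCGNet",
    "FEATURE_MODES",
    "graph_conv",
    "global_state_update",
    "broadcast_concat",
    "global_attention",
    "multihead_readout",
    "masked_softmax",
    "relu",
]

_MASK_NEG = -1e30  # additive logit for padded nodes

FEATURE_MODES = ("MG", "MG+2D", "MG+3D", "MG+2D+3D")


def descriptor_indices(mode: str) -> list[int]:
    """Global-state column subset used by an ablation mode."""
    if mode == "MG":
        return []
    if mode == "MG+2D":
        names = DESCRIPTORS_2D
    elif mode == "MG+3D":
        names = DESCRIPTORS_3D
    elif mode == "MG+2D+3D":
        names = DESCRIPTOR_NAMES
    else:
        raise ValueError(f"unknown feature mode {mode!r}; pick one of {FEATURE_MODES}")
    return [DESCRIPTOR_NAMES.index(n) for n in names]


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def masked_softmax(logits: np.ndarray, mask: np.ndarray, axis: int = -1) -> np.ndarray:
    """Softmax that assigns exactly zero weight to masked positions."""
    if not np.any(mask):
        raise ValueError("empty graph: all nodes are masked")
    z = np.where(mask > 0, logits, _MASK_NEG)
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z) * (mask > 0)
    return e / e.sum(axis=axis, keepdims=True)


# --- functional layer ops (single graph) --------------------------------------------

@dataclass
class GraphConvWeights:
    """Trainable parameters of one bond-type graph convolution."""

    h: np.ndarray    # L x C x F, one scalar per (bond slice, in channel, filter)
    W0: np.ndarray   # C x F self-loop weight
    b: np.ndarray    # F bias


def graph_conv(V_in, A, weights: GraphConvWeights, activation=relu) -> np.ndarray:
    """Bond-type graph convolution on a single graph.

    ``V_out = activation(V_in @ W0 + sum_l A_l V_in h_l + b)`` where ``h_l``
    maps input channels to F filters for bond-type slice l.
    """
    V_in = np.asarray(V_in, dtype=float)
    A = np.asarray(A, dtype=float)
    if V_in.shape[1] != weights.h.shape[1] or A.shape[2] != weights.h.shape[0]:
        raise ValueError("graph_conv shape mismatch between inputs and weights")
    M = np.einsum("pql,qc->plc", A, V_in)
    G = np.einsum("plc,lcf->pf", M, weights.h)
    return activation(V_in @ weights.W0 + G + weights.b)


def global_state_update(u, W, b, activation=relu) -> np.ndarray:
    """Single-layer feedforward update of the global state, per coformer row."""
    u = np.asarray(u, dtype=float)
    return activation(u @ W + b)


def broadcast_concat(V, u, coformer_slices) -> np.ndarray:
    """Append each coformer's global-state row to every atom of that coformer."""
    V = np.asarray(V, dtype=float)
    u = np.asarray(u, dtype=float)
    n = V.shape[0]
    covered = sorted(
        i for sl in coformer_slices for i in range(sl.start, sl.stop)
    )
    if covered != list(range(n)):
        raise ValueError("coformer slices do not partition the node set")
    R = np.zeros((n, u.shape[1]))
    for row, sl in enumerate(coformer_slices):
        R[sl] = u[row]
    return np.concatenate([V, R], axis=1)


def global_attention(V, phi, mask=None):
    """Attention-weighted sum of node vectors for one graph.

    ``phi`` maps the node matrix to one logit per node (callable or a
    ``(W1, b1, w2, b2)`` MLP parameter tuple). Returns ``(x_graph, alpha)``.
    """
    V = np.asarray(V, dtype=float)
    mask = np.ones(V.shape[0]) if mask is None else np.asarray(mask, dtype=float)
    if callable(phi):
        logits = np.asarray(phi(V), dtype=float).reshape(-1)
    else:
        W1, b1, w2, b2 = phi
        logits = relu(V @ W1 + b1) @ w2 + b2
    alpha = masked_softmax(logits, mask)
    return alpha @ V, alpha


def multihead_readout(V, heads, mask=None):
    """K-head global attention: concatenated per-head weighted sums.

    ``heads`` is a list of ``phi`` scorers; output width is K x node width.
    Returns ``(x_cat, alpha)`` with ``alpha`` of shape (N, K).
    """
    if len(heads) < 1:
        raise ValueError("need at least one attention head")
    outs, alphas = [], []
    for phi in heads:
        x, a = global_attention(V, phi, mask)
        outs.append(x)
        alphas.append(a)
    return np.concatenate(outs), np.stack(alphas, axis=1)


# --- full model ----------------------------------------------------------------------

@dataclass
class CCGNetConfig:
    """Architecture and featurization-mode configuration.

    Defaults follow the reference depth (four CCGBlocks) with documented,
    configurable widths; they are not claimed to be the original
    hyper-parameter-search optimum.
    """

    conv_widths: tuple = (64, 64, 128, 128)
    global_widths: tuple = (64, 64, 128, 128)
    attention_heads: int = 2
    attention_hidden: int = 32
    dense_head: tuple = (256, 128, 2)
    feature_mode: str = "MG+2D+3D"
    simple: bool = False  # skip per-block concatenation, keep readout concat
    num_bond_types: int = 4
    atom_features: int = NUM_ATOM_FEATURES
    seed: int = 0

    def __post_init__(self):
        if len(self.conv_widths) != len(self.global_widths):
            raise ValueError("conv_widths and global_widths must have equal depth")
        if self.dense_head[-1] != 2:
            raise ValueError("final dense width must be 2")
        if self.attention_heads < 1:
            raise ValueError("need K >= 1 attention heads")
        descriptor_indices(self.feature_mode)


# Desk-scale architecture used by the bundled experiments; same topology,
# smaller widths so CPU training stays fast.
COMPACT_CONFIG = dict(
    conv_widths=(16, 16, 32, 32),
    global_widths=(16, 16, 32, 32),
    attention_hidden=16,
    dense_head=(64, 32, 2),
)


def _glorot(rng, shape, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class CCGNet:
    """The full model: parameters, forward pass, and hand-derived gradients."""

    def __init__(self, config: CCGNetConfig | None = None):
        self.config = config or CCGNetConfig()
        cfg = self.config
        self.desc_idx = descriptor_indices(cfg.feature_mode)
        self.has_global = len(self.desc_idx) > 0
        rng = np.random.default_rng(cfg.seed)
        p: dict[str, np.ndarray] = {}

        dv = cfg.atom_features
        du = len(self.desc_idx)
        L = cfg.num_bond_types
        for i, (F, Dg) in enumerate(zip(cfg.conv_widths, cfg.global_widths)):
            p[f"block{i}.h"] = _glorot(rng, (L, dv, F), dv * L, F)
            p[f"block{i}.W0"] = _glorot(rng, (dv, F), dv, F)
            p[f"block{i}.b"] = np.zeros(F)
            if self.has_global:
                p[f"block{i}.Wu"] = _glorot(rng, (du, Dg), du, Dg)
                p[f"block{i}.bu"] = np.zeros(Dg)
                du = Dg
            dv = F + (Dg if self.has_global and not cfg.simple else 0)

        self.node_width = dv
        for k in range(cfg.attention_heads):
            H = cfg.attention_hidden
            p[f"head{k}.W1"] = _glorot(rng, (dv, H), dv, H)
            p[f"head{k}.b1"] = np.zeros(H)
            p[f"head{k}.w2"] = _glorot(rng, (H,), H, 1)
            p[f"head{k}.b2"] = np.zeros(1)

        width = cfg.attention_heads * dv
        if self.has_global:
            width += 2 * cfg.global_widths[-1]
        for j, out in enumerate(cfg.dense_head):
            p[f"dense{j}.W"] = _glorot(rng, (width, out), width, out)
            p[f"dense{j}.b"] = np.zeros(out)
            width = out

        self.params = p
        # input standardization (fit on training data, stored in checkpoints)
        self.v_center = np.zeros(cfg.atom_features)
        self.v_scale = np.ones(cfg.atom_features)
        self.u_center = np.zeros(len(self.desc_idx))
        self.u_scale = np.ones(len(self.desc_idx))

    # --- preprocessing ---------------------------------------------------------------

    def fit_scalers(self, batch: dict) -> None:
        """Fit per-column standardization of V (real nodes) and U on training data."""
        mask = batch["mask"].astype(bool)
        nodes = batch["V"][mask]
        self.v_center = nodes.mean(axis=0)
        self.v_scale = np.where(nodes.std(axis=0) > 1e-8, nodes.std(axis=0), 1.0)
        if self.has_global:
            u = batch["U"][:, :, self.desc_idx].reshape(-1, len(self.desc_idx))
            self.u_center = u.mean(axis=0)
            self.u_scale = np.where(u.std(axis=0) > 1e-8, u.std(axis=0), 1.0)

    def _prepare(self, batch: dict):
        mask = batch["mask"].astype(float)
        V = (batch["V"] - self.v_center) / self.v_scale * mask[..., None]
        U = None
        if self.has_global:
            U = (batch["U"][:, :, self.desc_idx] - self.u_center) / self.u_scale
        return V, batch["A"], U, mask, batch["comp"]

    # --- forward ---------------------------------------------------------------------

    def forward(self, batch: dict, return_cache: bool = False):
        cfg = self.config
        p = self.params
        V, A, U, mask, comp = self._prepare(batch)
        B, N = mask.shape
        # bond-type-major contiguous layout; slices are symmetric by construction
        A = np.ascontiguousarray(A.transpose(0, 3, 1, 2))
        # one-hot coformer membership restricted to real nodes
        P = np.zeros((B, N, 2))
        P[np.arange(B)[:, None], np.arange(N)[None, :], comp] = 1.0
        P *= mask[..., None]

        cache = {"A": A, "mask": mask, "P": P, "blocks": []}
        for i in range(len(cfg.conv_widths)):
            blk = {"V_in": V, "U_in": U}
            if self.has_global:
                Zu = U @ p[f"block{i}.Wu"] + p[f"block{i}.bu"]
                Uo = relu(Zu)
                blk["Zu"] = Zu
            else:
                Uo = None
            S0 = V @ p[f"block{i}.W0"]
            h = p[f"block{i}.h"]
            M = A @ V[:, None]                       # (B, L, N, C) neighbor sums per slice
            G = sum(M[:, l] @ h[l] for l in range(h.shape[0]))
            Z = S0 + G + p[f"block{i}.b"]
            Vc = relu(Z) * mask[..., None]
            blk["M"], blk["Z"] = M, Z
            if self.has_global and not cfg.simple:
                R = P @ Uo
                V = np.concatenate([Vc, R], axis=2)
            else:
                V = Vc
            U = Uo
            cache["blocks"].append(blk)

        cache["V_last"], cache["U_last"] = V, U

        # multi-head global attention readout
        heads = []
        alphas = []
        for k in range(cfg.attention_heads):
            H1z = V @ p[f"head{k}.W1"] + p[f"head{k}.b1"]
            H1 = relu(H1z)
            s = H1 @ p[f"head{k}.w2"] + p[f"head{k}.b2"]
            alpha = masked_softmax(s, mask)
            g = (alpha[:, None, :] @ V)[:, 0]
            heads.append({"H1z": H1z, "H1": H1, "alpha": alpha, "g": g})
            alphas.append(alpha)
        cache["heads"] = heads
        cache["alpha"] = np.stack(alphas, axis=2)  # (B, N, K)

        X = np.concatenate([h["g"] for h in heads], axis=1)
        if self.has_global:
            X = np.concatenate([X, U.reshape(B, -1)], axis=1)
        cache["X0"] = X

        dense = []
        for j in range(len(cfg.dense_head)):
            Zd = X @ p[f"dense{j}.W"] + p[f"dense{j}.b"]
            last = j == len(cfg.dense_head) - 1
            Xn = Zd if last else relu(Zd)
            dense.append({"X_in": X, "Zd": Zd})
            X = Xn
        cache["dense"] = dense

        logits = X
        return (logits, cache) if return_cache else logits

    # --- backward --------------------------------------------------------------------

    def backward(self, cache: dict, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        cfg = self.config
        p = self.params
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        mask = cache["mask"]
        B = mask.shape[0]

        dX = dlogits
        for j in reversed(range(len(cfg.dense_head))):
            d = cache["dense"][j]
            dZ = dX if j == len(cfg.dense_head) - 1 else dX * (d["Zd"] > 0)
            grads[f"dense{j}.W"] += d["X_in"].T @ dZ
            grads[f"dense{j}.b"] += dZ.sum(axis=0)
            dX = dZ @ p[f"dense{j}.W"].T

        V = cache["V_last"]
        D = V.shape[2]
        K = cfg.attention_heads
        dV = np.zeros_like(V)
        dU = None
        if self.has_global:
            dUflat = dX[:, K * D:]
            dU = dUflat.reshape(B, 2, -1)
            dX = dX[:, : K * D]

        for k in range(K):
            h = cache["heads"][k]
            dg = dX[:, k * D : (k + 1) * D]
            dalpha = (V @ dg[:, :, None])[:, :, 0]
            dV += h["alpha"][..., None] * dg[:, None, :]
            # masked-softmax backward (alpha is 0 on padded nodes)
            ds = h["alpha"] * (dalpha - (h["alpha"] * dalpha).sum(axis=1, keepdims=True))
            grads[f"head{k}.b2"] += np.array([ds.sum()])
            grads[f"head{k}.w2"] += (ds.reshape(1, -1) @ h["H1"].reshape(-1, h["H1"].shape[2]))[0]
            dH1 = ds[..., None] * p[f"head{k}.w2"][None, None, :]
            dZ1 = dH1 * (h["H1z"] > 0)
            grads[f"head{k}.W1"] += V.reshape(-1, D).T @ dZ1.reshape(-1, dZ1.shape[2])
            grads[f"head{k}.b1"] += dZ1.sum(axis=(0, 1))
            dV += dZ1 @ p[f"head{k}.W1"].T

        A, P = cache["A"], cache["P"]
        for i in reversed(range(len(cfg.conv_widths))):
            blk = cache["blocks"][i]
            F = cfg.conv_widths[i]
            if self.has_global and not cfg.simple:
                dVc = dV[..., :F]
                dR = dV[..., F:]
                dUo = P.transpose(0, 2, 1) @ dR
                if dU is not None:
                    dUo = dUo + dU
            else:
                dVc = dV
                dUo = dU
            dZ = dVc * mask[..., None] * (blk["Z"] > 0)
            h = p[f"block{i}.h"]
            M = blk["M"]
            L, Cw, F = h.shape
            dZf = dZ.reshape(-1, F)
            grads[f"block{i}.b"] += dZ.sum(axis=(0, 1))
            Cin = blk["V_in"].shape[2]
            grads[f"block{i}.W0"] += blk["V_in"].reshape(-1, Cin).T @ dZf
            dV_in = dZ @ p[f"block{i}.W0"].T
            for l in range(L):
                grads[f"block{i}.h"][l] += M[:, l].reshape(-1, Cw).T @ dZf
            # dV via A^T; A slices are symmetric so A itself is used
            dM = dZ[:, None] @ h.transpose(0, 2, 1)[None]   # (B, L, N, C)
            dV_in += (A @ dM).sum(axis=1)
            if self.has_global:
                dZu = dUo * (blk["Zu"] > 0)
                du_in = blk["U_in"].shape[2]
                grads[f"block{i}.Wu"] += blk["U_in"].reshape(-1, du_in).T @ dZu.reshape(-1, dZu.shape[2])
                grads[f"block{i}.bu"] += dZu.sum(axis=(0, 1))
                dU = dZu @ p[f"block{i}.Wu"].T
            dV = dV_in
        return grads

    # --- losses and predictions ------------------------------------------------------

    def loss_and_grads(self, batch: dict):
        """Mean softmax cross-entropy and parameter gradients."""
        logits, cache = self.forward(batch, return_cache=True)
        labels = batch["labels"]
        B = logits.shape[0]
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        probs = e / e.sum(axis=1, keepdims=True)
        loss = -np.mean(np.log(probs[np.arange(B), labels] + 1e-300))
        dlogits = probs.copy()
        dlogits[np.arange(B), labels] -= 1.0
        dlogits /= B
        return loss, self.backward(cache, dlogits)

    def loss(self, batch: dict) -> float:
        logits = self.forward(batch)
        labels = batch["labels"]
        z = logits - logits.max(axis=1, keepdims=True)
        probs = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
        return float(-np.mean(np.log(probs[np.arange(len(labels)), labels] + 1e-300)))

    def predict(self, batch: dict):
        """Class scores and hard labels.

        Returns ``(scores, labels)`` where ``scores[:, 1]`` is the positive
        class probability; a sample is positive iff logit ``b > a`` (ties
        break negative — conservative for screening).
        """
        logits = self.forward(batch)
        z = logits - logits.max(axis=1, keepdims=True)
        scores = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
        labels = (logits[:, 1] > logits[:, 0]).astype(int)
        return scores, labels

    def attention_map(self, batch: dict) -> list[np.ndarray]:
        """Per-sample attention weights aligned to input atom order.

        Returns one (n_atoms, K) array per sample; each head's weights over a
        graph's real atoms sum to 1.
        """
        _, cache = self.forward(batch, return_cache=True)
        alpha = cache["alpha"]
        out = []
        for i, n in enumerate(batch["n_nodes"]):
            out.append(alpha[i, : int(n), :].copy())
        return out

    # --- (de)serialization helpers ---------------------------------------------------

    def state(self) -> dict:
        arrays = dict(self.params)
        arrays["_v_center"], arrays["_v_scale"] = self.v_center, self.v_scale
        arrays["_u_center"], arrays["_u_scale"] = self.u_center, self.u_scale
        return {"config": asdict(self.config), "arrays": arrays}

    @classmethod
    def from_state(cls, state: dict) -> "CCGNet":
        cfg_dict = dict(state["config"])
        cfg_dict["conv_widths"] = tuple(cfg_dict["conv_widths"])
        cfg_dict["global_widths"] = tuple(cfg_dict["global_widths"])
        cfg_dict["dense_head"] = tuple(cfg_dict["dense_head"])
        model = cls(CCGNetConfig(**cfg_dict))
        arrays = state["arrays"]
        for k in model.params:
            # copy so clones never alias (and mutate) the source model's weights
            model.params[k] = np.array(arrays[k], dtype=float)
        model.v_center = np.array(arrays["_v_center"], dtype=float)
        model.v_scale = np.array(arrays["_v_scale"], dtype=float)
        model.u_center = np.array(arrays["_u_center"], dtype=float)
        model.u_scale = np.array(arrays["_u_scale"], dtype=float)
        return model
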