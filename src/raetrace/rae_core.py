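"""Recursive auto-encoder: parameters, tree construction, losses, training.

A single encoder/decoder pair is applied recursively over a binary merge
tree.  Two construction orders are supported: a right-to-left linear
cascade, and a greedy order that at every level merges the adjacent pair
with the smallest reconstruction error.  Training is mini-batch gradient
descent (Adam) with gradients backpropagated through the (fixed, per
example, per epoch) tree structure.  The per-node loss is either the
plain reconstruction MSE or its convex combination with a softmax
cross-entropy against the window's activity label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EPS_LOG = 1e-12  # cross-entropy clamp


@dataclass
class RAEParams:
    """Encoder/decoder (and optional label-softmax) weights.

    ``n`` is the shared child/parent dimension; the decoder activation is
    the identity by default (tanh optional).
    """

    W1: np.ndarray  # (n, 2n) encode
    b1: np.ndarray  # (n,)
    W2: np.ndarray  # (2n, n) decode
    b2: np.ndarray  # (2n,)
    Wlabel: np.ndarray | None = None  # (K, n), present iff semi-supervised
    decode_activation: str = "identity"  # "identity" | "tanh"

    def __post_init__(self) -> None:
        n = self.W1.shape[0]
        if self.W1.shape != (n, 2 * n):
            raise ValueError(f"W1 must be (n, 2n), got {self.W1.shape}")
        if self.b1.shape != (n,):
            raise ValueError(f"b1 must be (n,), got {self.b1.shape}")
        if self.W2.shape != (2 * n, n):
            raise ValueError(f"W2 must be (2n, n), got {self.W2.shape}")
        if self.b2.shape != (2 * n,):
            raise ValueError(f"b2 must be (2n,), got {self.b2.shape}")
        if self.Wlabel is not None and self.Wlabel.shape[1] != n:
            raise ValueError(f"Wlabel must be (K, n), got {self.Wlabel.shape}")
        if self.decode_activation not in ("identity", "tanh"):
            raise ValueError(f"unknown decode activation {self.decode_activation!r}")

    @property
    def n(self) -> int:
        return self.W1.shape[0]

    @property
    def n_labels(self) -> int | None:
        return None if self.Wlabel is None else self.Wlabel.shape[0]

    def copy(self) -> "RAEParams":
        return RAEParams(
            self.W1.copy(), self.b1.copy(), self.W2.copy(), self.b2.copy(),
            None if self.Wlabel is None else self.Wlabel.copy(),
            self.decode_activation,
        )

    def arrays(self) -> dict[str, np.ndarray]:
        out = {"W1": self.W1, "b1": self.b1, "W2": self.W2, "b2": self.b2}
        if self.Wlabel is not None:
            out["Wlabel"] = self.Wlabel
        return out


def init_params(
    n: int,
    n_labels: int | None = None,
    seed: int = 0,
    scale: float = 0.05,
    decode_activation: str = "identity",
) -> RAEParams:
    """Uniform(-scale, scale) initialisation from *seed*."""
    rng = np.random.default_rng(seed)
    Wlabel = None if n_labels is None else rng.uniform(-scale, scale, (n_labels, n))
    return RAEParams(
        W1=rng.uniform(-scale, scale, (n, 2 * n)),
        b1=rng.uniform(-scale, scale, n),
        W2=rng.uniform(-scale, scale, (2 * n, n)),
        b2=rng.uniform(-scale, scale, 2 * n),
        Wlabel=Wlabel,
        decode_activation=decode_activation,
    )


@dataclass
class TrainingConfig:
    mode: str = "unsupervised"  # "unsupervised" | "semisupervised"
    alpha: float = 0.2  # weight on the reconstruction term (semi-supervised)
    epochs: int = 10
    learning_rate: float = 0.01
    batch_size: int = 20
    seed: int = 0
    tree_style: str = "greedy"  # "linear" | "greedy"
    init_scale: float = 0.05
    decode_activation: str = "identity"

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.mode not in ("unsupervised", "semisupervised"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.tree_style not in ("linear", "greedy"):
            raise ValueError(f"unknown tree style {self.tree_style!r}")


# ---------------------------------------------------------------------------
# Encode / decode / elementary losses


def _decode_act(pre: np.ndarray, kind: str) -> np.ndarray:
    return np.tanh(pre) if kind == "tanh" else pre


def encode_pair(c1: np.ndarray, c2: np.ndarray, params: RAEParams) -> np.ndarray:
    """p = tanh(W1 [c1; c2] + b1)."""
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    if c1.shape != (params.n,) or c2.shape != (params.n,):
        raise ValueError(f"children must have shape ({params.n},)")
    return np.tanh(params.W1 @ np.concatenate([c1, c2]) + params.b1)


def decode_pair(p: np.ndarray, params: RAEParams) -> tuple[np.ndarray, np.ndarray]:
    """Reconstruct both children from a parent vector."""
    p = np.asarray(p, dtype=float)
    if p.shape != (params.n,):
        raise ValueError(f"parent must have shape ({params.n},)")
    rec = _decode_act(params.W2 @ p + params.b2, params.decode_activation)
    return rec[: params.n], rec[params.n :]


def reconstruction_error(x: np.ndarray, x_rec: np.ndarray) -> float:
    """Mean squared error between a vector and its reconstruction."""
    x = np.asarray(x, dtype=float)
    x_rec = np.asarray(x_rec, dtype=float)
    if x.shape != x_rec.shape:
        raise ValueError("dimension mismatch")
    return float(np.mean((x_rec - x) ** 2))


def softmax_label(p: np.ndarray, params: RAEParams) -> np.ndarray:
    """softmax(Wlabel p): label distribution at a parent node."""
    if params.Wlabel is None:
        raise ValueError("params carry no label weights")
    logits = params.Wlabel @ np.asarray(p, dtype=float)
    logits = logits - logits.max()
    e = np.exp(logits)
    return e / e.sum()


def supervised_error(d: np.ndarray, t: np.ndarray, eps: float = EPS_LOG) -> float:
    """Cross-entropy -sum t_k log d_k (probabilities clamped at eps)."""
    d = np.asarray(d, dtype=float)
    t = np.asarray(t, dtype=float)
    if d.shape != t.shape:
        raise ValueError("dimension mismatch")
    return float(-(t * np.log(np.clip(d, eps, None))).sum())


def combined_error(eu: float, es: float, alpha: float) -> float:
    """alpha * unsupervised + (1 - alpha) * supervised."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    return alpha * eu + (1.0 - alpha) * es


# ---------------------------------------------------------------------------
# Trees


@dataclass
class TreeNode:
    """Internal node; child refs < k point at leaves, refs >= k at nodes[ref-k]."""

    left: int
    right: int
    p: np.ndarray
    recon: np.ndarray  # (2n,) reconstructed [c1; c2]
    error: float

    def __post_init__(self) -> None:
        if self.error < 0:
            raise ValueError("node error must be >= 0")


@dataclass
class RAETree:
    """A binary merge tree over leaf vectors; nodes in construction order."""

    leaves: np.ndarray  # (k, n)
    nodes: list[TreeNode]
    tokens: list[int] | None = None  # optional sensor indices behind the leaves
    label: str | None = None

    def __post_init__(self) -> None:
        k = self.leaves.shape[0]
        if k >= 2 and len(self.nodes) != k - 1:
            raise ValueError(f"{k} leaves require {k - 1} internal nodes, got {len(self.nodes)}")

    @property
    def n_leaves(self) -> int:
        return int(self.leaves.shape[0])

    @property
    def is_degenerate(self) -> bool:
        return not self.nodes

    @property
    def root(self) -> TreeNode:
        if self.is_degenerate:
            raise ValueError("degenerate tree has no internal nodes")
        return self.nodes[-1]

    def root_vector(self) -> np.ndarray:
        """Fixed-length representation of the whole sequence."""
        return self.leaves[0] if self.is_degenerate else self.nodes[-1].p

    def node_errors(self) -> np.ndarray:
        return np.array([nd.error for nd in self.nodes])

    def structure(self) -> list[tuple[int, int]]:
        return [(nd.left, nd.right) for nd in self.nodes]

    def leaf_span(self, node_index: int) -> list[int]:
        """Left-to-right leaf indices under internal node *node_index*."""
        k = self.n_leaves

        def walk(ref: int) -> list[int]:
            if ref < k:
                return [ref]
            nd = self.nodes[ref - k]
            return walk(nd.left) + walk(nd.right)

        return walk(node_index + k)


def root_feature(tree: RAETree) -> np.ndarray:
    """The root's vector: a fixed 1 x n encoding of a variable-length input."""
    return tree.root_vector()


def _pair_forward(pairs: np.ndarray, params: RAEParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised encode/decode of (m, 2n) stacked child pairs."""
    P = np.tanh(pairs @ params.W1.T + params.b1)
    R = _decode_act(P @ params.W2.T + params.b2, params.decode_activation)
    errs = np.mean((R - pairs) ** 2, axis=1)
    return P, R, errs


def build_linear_tree(rows: np.ndarray, params: RAEParams, tokens: list[int] | None = None,
                      label: str | None = None) -> RAETree:
    """Right-to-left cascade: merge the rightmost pair, then fold leftwards."""
    rows = np.asarray(rows, dtype=float)
    if rows.ndim != 2 or rows.shape[0] < 2:
        raise ValueError("linear tree needs at least 2 rows")
    k = rows.shape[0]
    structure = [(k - 2, k - 1)]
    for i in range(k - 3, -1, -1):
        structure.append((i, k + len(structure) - 1))
    return forward_tree(rows, structure, params, tokens=tokens, label=label)


def build_greedy_tree(rows: np.ndarray, params: RAEParams, tokens: list[int] | None = None,
                      label: str | None = None) -> RAETree:
    """At each level merge the adjacent pair with least reconstruction error.

    Ties break to the leftmost minimal pair.  A single row yields a
    degenerate tree with no internal nodes.
    """
    rows = np.asarray(rows, dtype=float)
    if rows.ndim != 2 or rows.shape[0] < 1:
        raise ValueError("greedy tree needs at least 1 row")
    k = rows.shape[0]
    if k == 1:
        return RAETree(leaves=rows, nodes=[], tokens=tokens, label=label)
    vecs = rows.copy()
    refs = list(range(k))
    nodes: list[TreeNode] = []
    while len(refs) > 1:
        pairs = np.hstack([vecs[:-1], vecs[1:]])
        P, R, errs = _pair_forward(pairs, params)
        j = int(np.argmin(errs))  # argmin returns the leftmost minimum
        nodes.append(TreeNode(left=refs[j], right=refs[j + 1], p=P[j], recon=R[j],
                              error=float(errs[j])))
        refs[j : j + 2] = [k + len(nodes) - 1]
        vecs = np.vstack([vecs[:j], P[j][None, :], vecs[j + 2 :]])
    return RAETree(leaves=rows, nodes=nodes, tokens=tokens, label=label)


def forward_tree(rows: np.ndarray, structure: list[tuple[int, int]], params: RAEParams,
                 tokens: list[int] | None = None, label: str | None = None) -> RAETree:
    """Evaluate a fixed merge structure under *params*."""
    rows = np.asarray(rows, dtype=float)
    k = rows.shape[0]

    def vec(ref: int, nodes: list[TreeNode]) -> np.ndarray:
        return rows[ref] if ref < k else nodes[ref - k].p

    nodes: list[TreeNode] = []
    for left, right in structure:
        c = np.concatenate([vec(left, nodes), vec(right, nodes)])
        p = np.tanh(params.W1 @ c + params.b1)
        r = _decode_act(params.W2 @ p + params.b2, params.decode_activation)
        nodes.append(TreeNode(left=left, right=right, p=p, recon=r,
                              error=float(np.mean((r - c) ** 2))))
    return RAETree(leaves=rows, nodes=nodes, tokens=tokens, label=label)


# ---------------------------------------------------------------------------
# Loss and gradients over a fixed structure


def tree_loss(rows: np.ndarray, structure: list[tuple[int, int]], params: RAEParams,
              alpha: float = 1.0, label_index: int | None = None) -> float:
    """Mean per-node loss of a fixed structure.

    Unsupervised (``label_index is None``): the node reconstruction MSE.
    Semi-supervised: alpha * MSE + (1 - alpha) * cross-entropy of the
    node's softmax against the window label.
    """
    tree = forward_tree(rows, structure, params)
    losses = []
    for nd in tree.nodes:
        if label_index is None:
            losses.append(nd.error)
        else:
            d = softmax_label(nd.p, params)
            t = np.zeros_like(d)
            t[label_index] = 1.0
            losses.append(combined_error(nd.error, supervised_error(d, t), alpha))
    return float(np.mean(losses))


def tree_grad(rows: np.ndarray, structure: list[tuple[int, int]], params: RAEParams,
              alpha: float = 1.0, label_index: int | None = None,
              ) -> tuple[float, dict[str, np.ndarray]]:
    """Loss and analytic parameter gradients via backprop through structure."""
    rows = np.asarray(rows, dtype=float)
    k = rows.shape[0]
    n = params.n
    M = len(structure)
    if M == 0:
        raise ValueError("structure has no internal nodes")
    semi = label_index is not None
    if semi and params.Wlabel is None:
        raise ValueError("semi-supervised gradient requires Wlabel")

    # Forward, caching per-node values.
    P = np.zeros((M, n))
    C = np.zeros((M, 2 * n))
    R = np.zeros((M, 2 * n))
    D = np.zeros((M, params.n_labels)) if semi else None

    def vec(ref: int) -> np.ndarray:
        return rows[ref] if ref < k else P[ref - k]

    loss = 0.0
    alpha_rec = alpha if semi else 1.0
    for j, (left, right) in enumerate(structure):
        C[j] = np.concatenate([vec(left), vec(right)])
        P[j] = np.tanh(params.W1 @ C[j] + params.b1)
        R[j] = _decode_act(params.W2 @ P[j] + params.b2, params.decode_activation)
        e_rec = float(np.mean((R[j] - C[j]) ** 2))
        node_loss = alpha_rec * e_rec
        if semi:
            D[j] = softmax_label(P[j], params)
            node_loss += (1.0 - alpha) * float(-np.log(max(D[j][label_index], EPS_LOG)))
        loss += node_loss
    loss /= M

    grads = {
        "W1": np.zeros_like(params.W1),
        "b1": np.zeros_like(params.b1),
        "W2": np.zeros_like(params.W2),
        "b2": np.zeros_like(params.b2),
    }
    if params.Wlabel is not None:
        grads["Wlabel"] = np.zeros_like(params.Wlabel)

    gp = np.zeros((M, n))  # dL/dp accumulated from parents
    w = 1.0 / M
    for j in range(M - 1, -1, -1):
        # reconstruction branch
        delta_r = w * alpha_rec * (2.0 / (2 * n)) * (R[j] - C[j])
        if params.decode_activation == "tanh":
            delta_r = delta_r * (1.0 - R[j] ** 2)
        grads["W2"] += np.outer(delta_r, P[j])
        grads["b2"] += delta_r
        gp_j = params.W2.T @ delta_r + gp[j]
        delta_c = -w * alpha_rec * (2.0 / (2 * n)) * (R[j] - C[j])
        # label branch
        if semi:
            t = np.zeros(params.n_labels)
            t[label_index] = 1.0
            delta_logits = w * (1.0 - alpha) * (D[j] - t)
            grads["Wlabel"] += np.outer(delta_logits, P[j])
            gp_j = gp_j + params.Wlabel.T @ delta_logits
        # through the encoder
        delta_z = (1.0 - P[j] ** 2) * gp_j
        grads["W1"] += np.outer(delta_z, C[j])
        grads["b1"] += delta_z
        delta_c = delta_c + params.W1.T @ delta_z
        for half, ref in ((delta_c[:n], structure[j][0]), (delta_c[n:], structure[j][1])):
            if ref >= k:
                gp[ref - k] += half
    return loss, grads


# ---------------------------------------------------------------------------
# Training


@dataclass
class TrainingExample:
    """One window: leaf rows (k x n) plus an optional label index."""

    rows: np.ndarray
    label_index: int | None = None

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float)
        if self.rows.ndim != 2 or self.rows.shape[0] < 2:
            raise ValueError("training example needs at least 2 rows")


def _example_structure(ex: TrainingExample, params: RAEParams, style: str) -> list[tuple[int, int]]:
    if style == "linear":
        k = ex.rows.shape[0]
        structure = [(k - 2, k - 1)]
        for i in range(k - 3, -1, -1):
            structure.append((i, k + len(structure) - 1))
        return structure
    return build_greedy_tree(ex.rows, params).structure()


def corpus_loss(corpus: list[TrainingExample], params: RAEParams, config: TrainingConfig) -> float:
    """Mean per-tree loss of *corpus* under *params* (structures rebuilt)."""
    semi = config.mode == "semisupervised"
    total = 0.0
    for ex in corpus:
        structure = _example_structure(ex, params, config.tree_style)
        total += tree_loss(ex.rows, structure, params,
                           alpha=config.alpha if semi else 1.0,
                           label_index=ex.label_index if semi else None)
    return total / len(corpus)


def train(corpus: list[TrainingExample], config: TrainingConfig,
          n_labels: int | None = None) -> RAEParams:
    """Fit RAE parameters on *corpus*; deterministic per config seed.

    Greedy structures are rebuilt under the current parameters every
    epoch.  Returns the initial parameters untouched when epochs == 0.
    """
    if not corpus:
        raise ValueError("training corpus is empty")
    semi = config.mode == "semisupervised"
    if semi:
        if any(ex.label_index is None for ex in corpus):
            raise ValueError("semi-supervised training requires a label on every example")
        if n_labels is None:
            n_labels = max(ex.label_index for ex in corpus) + 1
    n = corpus[0].rows.shape[1]
    params = init_params(n, n_labels if semi else None, seed=config.seed,
                         scale=config.init_scale, decode_activation=config.decode_activation)
    if config.epochs == 0:
        return params

    rng = np.random.default_rng(config.seed + 1)
    m_state = {key: np.zeros_like(val) for key, val in params.arrays().items()}
    v_state = {key: np.zeros_like(val) for key, val in params.arrays().items()}
    beta1, beta2, adam_eps = 0.9, 0.999, 1e-8
    step = 0
    for _ in range(config.epochs):
        order = rng.permutation(len(corpus))
        for lo in range(0, len(corpus), config.batch_size):
            batch = [corpus[i] for i in order[lo : lo + config.batch_size]]
            acc = {key: np.zeros_like(val) for key, val in params.arrays().items()}
            for ex in batch:
                structure = _example_structure(ex, params, config.tree_style)
                _, grads = tree_grad(ex.rows, structure, params,
                                     alpha=config.alpha if semi else 1.0,
                                     label_index=ex.label_index if semi else None)
                for key in acc:
                    acc[key] += grads[key]
            step += 1
            arrays = params.arrays()
            for key in acc:
                g = acc[key] / len(batch)
                m_state[key] = beta1 * m_state[key] + (1 - beta1) * g
                v_state[key] = beta2 * v_state[key] + (1 - beta2) * g * g
                m_hat = m_state[key] / (1 - beta1**step)
                v_hat = v_state[key] / (1 - beta2**step)
                arrays[key] -= config.learning_rate * m_hat / (np.sqrt(v_hat) + adam_eps)
    return params
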