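"""Recurrent classifier cells: Elman RNN, GRU, and bidirectional LSTM.

Cell equations
--------------
Elman RNN (sigmoid hidden state, tanh output):

    h_t = σ(P_h h_{t−1} + P_x x_t + B_a)
    y_t = tanh(P_o h_t + B_o)

GRU (reset gate r, update gate z, ⊙ the Hadamard product):

    r_t = σ(W_r x_t + U_r h_{t−1} + b_r)
    z_t = σ(W_z x_t + U_z h_{t−1} + b_z)
    h_t = (1 − z_t) ⊙ h_{t−1} + z_t ⊙ tanh(W_h x_t + U_h (r_t ⊙ h_{t−1}) + b_h)

BiLSTM: a forward and a backward LSTM layer (standard input/forget/output
gates and a tanh cell candidate) run over the sequence in opposite
directions; their per-step outputs o_t and o′_t are combined as

    y_t = tanh(ω₄ o_t + ω₆ o′_t + b_y).

Classifiers wrap a cell with a softmax head and are trained by full
backpropagation through time with Adam; the analytic gradients are
verified against finite differences in the test suite.  Feature vectors
enter as sequences via ``featurize_sequence`` (reshape to
timesteps x (dim/timesteps), zero-padded when the dimension does not
divide evenly).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RecurrentCellSpec",
    "featurize_sequence",
    "rnn_step",
    "gru_step",
    "lstm_step",
    "bilstm_forward",
    "SequenceClassifier",
    "make_cell_spec",
]

CELL_KINDS = ("elman", "gru", "bilstm")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class RecurrentCellSpec:
    """Cell kind, sizes, and the named weight tensors of its equations."""

    cell_kind: str
    hidden_units: int
    input_dim: int
    weights: dict[str, np.ndarray]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cell_kind not in CELL_KINDS:
            raise ValueError(f"cell_kind must be one of {CELL_KINDS}")
        if self.hidden_units <= 0:
            raise ValueError("hidden_units must be positive")


def make_cell_spec(cell_kind: str, input_dim: int, hidden_units: int,
                   seed: int = 0, output_dim: int | None = None,
                   ) -> RecurrentCellSpec:
    """Seeded Glorot-style initialisation of a cell's weight tensors."""
    rng = np.random.default_rng(int(seed))
    H, d = hidden_units, input_dim
    O = output_dim or hidden_units

    def mat(rows, cols):
        return rng.standard_normal((rows, cols)) * np.sqrt(1.0 / cols)

    w: dict[str, np.ndarray] = {}
    if cell_kind == "elman":
        w = {"P_h": mat(H, H), "P_x": mat(H, d), "B_a": np.zeros(H),
             "P_o": mat(O, H), "B_o": np.zeros(O)}
    elif cell_kind == "gru":
        for g in ("r", "z", "h"):
            w[f"W_{g}"] = mat(H, d)
            w[f"U_{g}"] = mat(H, H)
            w[f"b_{g}"] = np.zeros(H)
    else:  # bilstm: two LSTM directions + the combination weights
        for pre in ("f", "b"):  # forward / backward direction
            for g in ("i", "f", "o", "g"):
                w[f"{pre}_W_{g}"] = mat(H, d)
                w[f"{pre}_U_{g}"] = mat(H, H)
                w[f"{pre}_b_{g}"] = np.zeros(H)
        w["w4"] = mat(O, H)
        w["w6"] = mat(O, H)
        w["b_y"] = np.zeros(O)
    return RecurrentCellSpec(cell_kind=cell_kind, hidden_units=H,
                             input_dim=d, weights=w, seed=int(seed))


def featurize_sequence(feature_vector: np.ndarray, timesteps: int,
                       ) -> tuple[np.ndarray, int]:
    """Reshape a feature vector into (timesteps, dim/timesteps) steps.

    Returns (sequence, n_padded): the vector is zero-padded up to the next
    multiple of ``timesteps`` and the pad length recorded; flattening the
    sequence and dropping the pad restores the input exactly.
    """
    v = np.asarray(feature_vector, dtype=float).ravel()
    if timesteps < 1:
        raise ValueError("timesteps must be at least 1")
    n_pad = (-len(v)) % timesteps
    if n_pad:
        v = np.concatenate([v, np.zeros(n_pad)])
    return v.reshape(timesteps, -1), n_pad


def rnn_step(x_t: np.ndarray, h_prev: np.ndarray, spec: RecurrentCellSpec,
             ) -> tuple[np.ndarray, np.ndarray]:
    """One Elman step: returns (h_t, y_t)."""
    w = spec.weights
    h_t = _sigmoid(w["P_h"] @ h_prev + w["P_x"] @ x_t + w["B_a"])
    y_t = np.tanh(w["P_o"] @ h_t + w["B_o"])
    return h_t, y_t


def gru_step(x_t: np.ndarray, h_prev: np.ndarray, spec: RecurrentCellSpec,
             ) -> np.ndarray:
    """One GRU step: returns h_t."""
    w = spec.weights
    r = _sigmoid(w["W_r"] @ x_t + w["U_r"] @ h_prev + w["b_r"])
    z = _sigmoid(w["W_z"] @ x_t + w["U_z"] @ h_prev + w["b_z"])
    cand = np.tanh(w["W_h"] @ x_t + w["U_h"] @ (r * h_prev) + w["b_h"])
    return (1.0 - z) * h_prev + z * cand


def lstm_step(x_t: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray,
              weights: dict[str, np.ndarray], prefix: str = "",
              ) -> tuple[np.ndarray, np.ndarray]:
    """One standard LSTM step: returns (h_t, c_t)."""
    def w(name):
        return weights[f"{prefix}{name}"]

    i = _sigmoid(w("W_i") @ x_t + w("U_i") @ h_prev + w("b_i"))
    f = _sigmoid(w("W_f") @ x_t + w("U_f") @ h_prev + w("b_f"))
    o = _sigmoid(w("W_o") @ x_t + w("U_o") @ h_prev + w("b_o"))
    g = np.tanh(w("W_g") @ x_t + w("U_g") @ h_prev + w("b_g"))
    c_t = f * c_prev + i * g
    h_t = o * np.tanh(c_t)
    return h_t, c_t


def bilstm_forward(sequence: np.ndarray, spec: RecurrentCellSpec,
                   ) -> np.ndarray:
    """Run both LSTM directions and combine per step.

    ``sequence`` is (T, d); the output is (T, output_dim) with
    y_t = tanh(ω₄ o_t + ω₆ o′_t + b_y), o the forward and o′ the backward
    hidden states.  Empty input yields an empty output.
    """
    seq = np.atleast_2d(np.asarray(sequence, dtype=float))
    if seq.size == 0:
        return np.empty((0, spec.weights["w4"].shape[0]))
    T = seq.shape[0]
    H = spec.hidden_units
    w = spec.weights
    hf = np.zeros(H)
    cf = np.zeros(H)
    fwd = np.empty((T, H))
    for t in range(T):
        hf, cf = lstm_step(seq[t], hf, cf, w, prefix="f_")
        fwd[t] = hf
    hb = np.zeros(H)
    cb = np.zeros(H)
    bwd = np.empty((T, H))
    for t in range(T - 1, -1, -1):
        hb, cb = lstm_step(seq[t], hb, cb, w, prefix="b_")
        bwd[t] = hb
    return np.tanh(fwd @ w["w4"].T + bwd @ w["w6"].T + w["b_y"])


# =====================================================================
# Trainable classifiers (batched forward + manual BPTT)
# =====================================================================


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class SequenceClassifier:
    """A recurrent cell + softmax head trained by BPTT.

    The softmax head reads the final hidden state for the Elman and GRU
    cells, and the time-average of the combined bidirectional outputs for
    the BiLSTM (its backward pass has seen the whole sequence only at the
    first step, so no single step summarises both directions).
    """

    cell_kind: str
    n_features: int
    n_classes: int
    hidden_units: int = 24
    timesteps: int = 8
    seed: int = 0
    learning_rate: float = 0.02
    epochs: int = 30
    batch_size: int = 16
    spec: RecurrentCellSpec = field(init=False)
    head: dict[str, np.ndarray] = field(init=False)

    def __post_init__(self) -> None:
        step_dim = -(-self.n_features // self.timesteps)
        self.spec = make_cell_spec(self.cell_kind, step_dim,
                                   self.hidden_units, seed=self.seed)
        rng = np.random.default_rng(self.seed + 1)
        out_dim = self.hidden_units
        self.head = {
            "W": rng.standard_normal((self.n_classes, out_dim))
            * np.sqrt(1.0 / out_dim),
            "b": np.zeros(self.n_classes),
        }
        self._mu = 0.0
        self._sd = 1.0

    # ------------------------------------------------------------ shaping

    def _sequences(self, X: np.ndarray) -> np.ndarray:
        X = (np.asarray(X, dtype=float) - self._mu) / self._sd
        n = len(X)
        n_pad = (-X.shape[1]) % self.timesteps
        if n_pad:
            X = np.concatenate([X, np.zeros((n, n_pad))], axis=1)
        return X.reshape(n, self.timesteps, -1)

    # ---------------------------------------------------- batched forward

    def _forward(self, seq: np.ndarray) -> tuple[np.ndarray, dict]:
        """Return (summary state fed to the head, cache for backprop)."""
        B, T, _ = seq.shape
        H = self.hidden_units
        w = self.spec.weights
        cache: dict = {"seq": seq}
        if self.cell_kind == "elman":
            h = np.zeros((B, H))
            hs = [h]
            for t in range(T):
                h = _sigmoid(h @ w["P_h"].T + seq[:, t] @ w["P_x"].T + w["B_a"])
                hs.append(h)
            cache["hs"] = hs
            return hs[-1], cache
        if self.cell_kind == "gru":
            h = np.zeros((B, H))
            hs, rs, zs, cs = [h], [], [], []
            for t in range(T):
                x = seq[:, t]
                r = _sigmoid(x @ w["W_r"].T + h @ w["U_r"].T + w["b_r"])
                z = _sigmoid(x @ w["W_z"].T + h @ w["U_z"].T + w["b_z"])
                cand = np.tanh(x @ w["W_h"].T + (r * h) @ w["U_h"].T + w["b_h"])
                h = (1 - z) * h + z * cand
                hs.append(h)
                rs.append(r)
                zs.append(z)
                cs.append(cand)
            cache.update(hs=hs, rs=rs, zs=zs, cs=cs)
            return hs[-1], cache
        # bilstm
        fwd, fcache = self._lstm_scan(seq, "f_", reverse=False)
        bwd, bcache = self._lstm_scan(seq, "b_", reverse=True)
        y = np.tanh(np.einsum("bth,oh->bto", fwd, w["w4"])
                    + np.einsum("bth,oh->bto", bwd, w["w6"]) + w["b_y"])
        cache.update(fwd=fwd, bwd=bwd, y=y, fcache=fcache, bcache=bcache)
        return y.mean(axis=1), cache

    def _lstm_scan(self, seq, prefix, reverse):
        B, T, _ = seq.shape
        H = self.hidden_units
        w = self.spec.weights
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        order = range(T - 1, -1, -1) if reverse else range(T)
        hs = np.empty((B, T, H))
        gates = {}
        hs_prev = np.empty((B, T, H))
        cs_prev = np.empty((B, T, H))
        for name in ("i", "f", "o", "g", "c", "tc"):
            gates[name] = np.empty((B, T, H))
        for t in order:
            x = seq[:, t]
            hs_prev[:, t] = h
            cs_prev[:, t] = c
            i = _sigmoid(x @ w[f"{prefix}W_i"].T + h @ w[f"{prefix}U_i"].T
                         + w[f"{prefix}b_i"])
            f = _sigmoid(x @ w[f"{prefix}W_f"].T + h @ w[f"{prefix}U_f"].T
                         + w[f"{prefix}b_f"])
            o = _sigmoid(x @ w[f"{prefix}W_o"].T + h @ w[f"{prefix}U_o"].T
                         + w[f"{prefix}b_o"])
            g = np.tanh(x @ w[f"{prefix}W_g"].T + h @ w[f"{prefix}U_g"].T
                        + w[f"{prefix}b_g"])
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            hs[:, t] = h
            for name, val in (("i", i), ("f", f), ("o", o), ("g", g),
                              ("c", c), ("tc", tc)):
                gates[name][:, t] = val
        return hs, {"gates": gates, "hs_prev": hs_prev, "cs_prev": cs_prev,
                    "order": list(order)}

    # --------------------------------------------------------- backward

    def _backward(self, cache: dict, d_summary: np.ndarray,
                  ) -> dict[str, np.ndarray]:
        w = self.spec.weights
        seq = cache["seq"]
        B, T, _ = seq.shape
        grads = {k: np.zeros_like(v) for k, v in w.items()}
        if self.cell_kind == "elman":
            hs = cache["hs"]
            dh = d_summary
            for t in range(T - 1, -1, -1):
                h_t, h_prev = hs[t + 1], hs[t]
                da = dh * h_t * (1 - h_t)
                grads["P_h"] += da.T @ h_prev
                grads["P_x"] += da.T @ seq[:, t]
                grads["B_a"] += da.sum(axis=0)
                dh = da @ w["P_h"]
            return grads
        if self.cell_kind == "gru":
            hs, rs, zs, cs = cache["hs"], cache["rs"], cache["zs"], cache["cs"]
            dh = d_summary
            for t in range(T - 1, -1, -1):
                h_prev = hs[t]
                r, z, cand = rs[t], zs[t], cs[t]
                x = seq[:, t]
                dz = dh * (cand - h_prev)
                dcand = dh * z
                dh_prev = dh * (1 - z)
                dac = dcand * (1 - cand**2)
                grads["W_h"] += dac.T @ x
                grads["U_h"] += dac.T @ (r * h_prev)
                grads["b_h"] += dac.sum(axis=0)
                drh = dac @ w["U_h"]
                dr = drh * h_prev
                dh_prev += drh * r
                dar = dr * r * (1 - r)
                grads["W_r"] += dar.T @ x
                grads["U_r"] += dar.T @ h_prev
                grads["b_r"] += dar.sum(axis=0)
                dh_prev += dar @ w["U_r"]
                daz = dz * z * (1 - z)
                grads["W_z"] += daz.T @ x
                grads["U_z"] += daz.T @ h_prev
                grads["b_z"] += daz.sum(axis=0)
                dh_prev += daz @ w["U_z"]
                dh = dh_prev
            return grads
        # bilstm: d_summary is d(mean_t y_t)
        fwd, bwd, y = cache["fwd"], cache["bwd"], cache["y"]
        dy = d_summary[:, None, :] / T * np.ones((1, T, 1))
        dpre = dy * (1 - y**2)
        grads["w4"] += np.einsum("bto,bth->oh", dpre, fwd)
        grads["w6"] += np.einsum("bto,bth->oh", dpre, bwd)
        grads["b_y"] += dpre.sum(axis=(0, 1))
        dfwd = np.einsum("bto,oh->bth", dpre, w["w4"])
        dbwd = np.einsum("bto,oh->bth", dpre, w["w6"])
        self._lstm_backward(seq, cache["fcache"], dfwd, "f_", grads)
        self._lstm_backward(seq, cache["bcache"], dbwd, "b_", grads)
        return grads

    def _lstm_backward(self, seq, lcache, dhs, prefix, grads):
        w = self.spec.weights
        g = lcache["gates"]
        order = lcache["order"]
        B, T, H = dhs.shape
        dh_carry = np.zeros((B, H))
        dc = np.zeros((B, H))
        for t in reversed(order):
            dh = dhs[:, t] + dh_carry
            i, f, o = g["i"][:, t], g["f"][:, t], g["o"][:, t]
            gg, tc = g["g"][:, t], g["tc"][:, t]
            c_prev = lcache["cs_prev"][:, t]
            h_prev = lcache["hs_prev"][:, t]
            x = seq[:, t]
            do = dh * tc
            dc = dc + dh * o * (1 - tc**2)
            di, dg, df = dc * gg, dc * i, dc * c_prev
            dc = dc * f
            dai = di * i * (1 - i)
            daf = df * f * (1 - f)
            dao = do * o * (1 - o)
            dag = dg * (1 - gg**2)
            dh_carry = np.zeros((B, H))
            for name, da in (("i", dai), ("f", daf), ("o", dao), ("g", dag)):
                grads[f"{prefix}W_{name}"] += da.T @ x
                grads[f"{prefix}U_{name}"] += da.T @ h_prev
                grads[f"{prefix}b_{name}"] += da.sum(axis=0)
                dh_carry += da @ w[f"{prefix}U_{name}"]

    # ---------------------------------------------------------- training

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray,
                       ) -> tuple[float, dict, dict]:
        """Cross-entropy loss and gradients for one batch (used by tests)."""
        seq = self._sequences(X)
        summary, cache = self._forward(seq)
        logits = summary @ self.head["W"].T + self.head["b"]
        proba = _softmax(logits)
        n = len(y)
        loss = -float(np.mean(np.log(proba[np.arange(n), y] + 1e-300)))
        dlogits = proba.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        head_grads = {"W": dlogits.T @ summary, "b": dlogits.sum(axis=0)}
        d_summary = dlogits @ self.head["W"]
        cell_grads = self._backward(cache, d_summary)
        return loss, cell_grads, head_grads

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SequenceClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain at least 2 classes")
        self._mu = X.mean(axis=0)
        self._sd = X.std(axis=0) + 1e-8
        rng = np.random.default_rng(self.seed + 2)
        opt_cell = _Adam(self.spec.weights, self.learning_rate)
        opt_head = _Adam(self.head, self.learning_rate)
        for _epoch in range(self.epochs):
            order = rng.permutation(len(X))
            for start in range(0, len(X), self.batch_size):
                sel = order[start:start + self.batch_size]
                loss, cg, hg = self.loss_and_grads(X[sel], y[sel])
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"{self.cell_kind} member diverged during training")
                opt_cell.step(self.spec.weights, cg)
                opt_head.step(self.head, hg)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        summary, _ = self._forward(self._sequences(np.asarray(X, dtype=float)))
        return _softmax(summary @ self.head["W"].T + self.head["b"])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)
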