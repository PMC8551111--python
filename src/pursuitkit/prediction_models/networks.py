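"""Minimal NumPy feedforward/recurrent network stack.

All model kinds share a three-weight-layer skeleton mapping the
6-component state input to a 5-component head output (dims 6 -> 64 ->
128 -> 5); "deep" kinds insert one extra 128-unit hidden layer of the
same type:

    LN     Linear - Linear - Linear
    NN     Linear+ReLU - Linear+ReLU - Linear
    RNN    Linear - tanh recurrent(64->128) - Linear
    LSTM   Linear - LSTM(64->128) - Linear
    DNN    Linear+ReLU x3 - Linear
    DRNN   Linear - recurrent x2 - Linear
    DLSTM  Linear - LSTM x2 - Linear

Layers expose ``forward``/``backward`` over a (T, n) array. For
stateless layers rows are independent (so a shuffled minibatch of
time-steps works); recurrent layers treat the rows as one ordered
sequence starting from a zero state and backpropagate through time.
``step`` runs a single frame with an explicit carried state, which is
what the closed-loop rollout uses.

Gradients of every layer are validated against central finite
differences in the test suite.
"""
from __future__ import annotations

import numpy as np

MODEL_KINDS = ("L", "C", "LN", "NN", "RNN", "LSTM", "DNN", "DRNN", "DLSTM")
NETWORK_KINDS = ("LN", "NN", "RNN", "LSTM", "DNN", "DRNN", "DLSTM")
RECURRENT_KINDS = ("RNN", "LSTM", "DRNN", "DLSTM")

INPUT_DIM = 6
HEAD_DIM = 5
HIDDEN_DIMS = (64, 128)


def _uniform_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Layer:
    """Interface: params/grads lists plus forward/backward/step."""

    stateful = False

    def __init__(self) -> None:
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def init_state(self):
        return None

    def step(self, x: np.ndarray, state):
        return self.forward(x[None, :])[0], None


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.W = _uniform_init(rng, (n_in, n_out), n_in)
        self.b = _uniform_init(rng, (n_out,), n_in)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, gout: np.ndarray) -> np.ndarray:
        self.grads[0] += self._x.T @ gout
        self.grads[1] += gout.sum(axis=0)
        return gout @ self.W.T


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, gout, 0.0)


class Recurrent(Layer):
    """Vanilla tanh recurrence: h_t = tanh(Wxh x_t + Whh h_{t-1} + b)."""

    stateful = True

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.Wxh = _uniform_init(rng, (n_in, n_out), n_in)
        self.Whh = _uniform_init(rng, (n_out, n_out), n_out)
        self.b = _uniform_init(rng, (n_out,), n_out)
        self.params = [self.Wxh, self.Whh, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]
        self.n_out = n_out

    def forward(self, x: np.ndarray) -> np.ndarray:
        T = x.shape[0]
        hs = np.zeros((T + 1, self.n_out))
        for t in range(T):
            hs[t + 1] = np.tanh(x[t] @ self.Wxh + hs[t] @ self.Whh + self.b)
        self._x = x
        self._hs = hs
        return hs[1:]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        x, hs = self._x, self._hs
        T = x.shape[0]
        gx = np.zeros_like(x)
        dh_next = np.zeros(self.n_out)
        dWxh, dWhh, db = self.grads
        for t in range(T - 1, -1, -1):
            dh = gout[t] + dh_next
            dpre = dh * (1.0 - hs[t + 1] ** 2)
            dWxh += np.outer(x[t], dpre)
            dWhh += np.outer(hs[t], dpre)
            db += dpre
            gx[t] = dpre @ self.Wxh.T
            dh_next = dpre @ self.Whh.T
        return gx

    def init_state(self) -> np.ndarray:
        return np.zeros(self.n_out)

    def step(self, x: np.ndarray, state: np.ndarray):
        h = np.tanh(x @ self.Wxh + state @ self.Whh + self.b)
        return h, h


class LSTM(Layer):
    """Standard LSTM layer with zero initial hidden and cell state."""

    stateful = True

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        # gate order: input, forget, output, candidate
        self.Wx = [_uniform_init(rng, (n_in, n_out), n_in) for _ in range(4)]
        self.Wh = [_uniform_init(rng, (n_out, n_out), n_out) for _ in range(4)]
        self.bs = [_uniform_init(rng, (n_out,), n_out) for _ in range(4)]
        self.params = [*self.Wx, *self.Wh, *self.bs]
        self.grads = [np.zeros_like(p) for p in self.params]
        self.n_out = n_out

    @staticmethod
    def _sigmoid(z: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-z))

    def forward(self, x: np.ndarray) -> np.ndarray:
        T = x.shape[0]
        n = self.n_out
        hs = np.zeros((T + 1, n))
        cs = np.zeros((T + 1, n))
        gates = np.zeros((T, 4, n))  # i, f, o, g
        tanh_c = np.zeros((T, n))
        Wxi, Wxf, Wxo, Wxc = self.Wx
        Whi, Whf, Who, Whc = self.Wh
        bi, bf, bo, bc = self.bs
        for t in range(T):
            h_prev, c_prev = hs[t], cs[t]
            i = self._sigmoid(x[t] @ Wxi + h_prev @ Whi + bi)
            f = self._sigmoid(x[t] @ Wxf + h_prev @ Whf + bf)
            o = self._sigmoid(x[t] @ Wxo + h_prev @ Who + bo)
            g = np.tanh(x[t] @ Wxc + h_prev @ Whc + bc)
            c = f * c_prev + i * g
            hs[t + 1] = o * np.tanh(c)
            cs[t + 1] = c
            gates[t] = (i, f, o, g)
            tanh_c[t] = np.tanh(c)
        self._cache = (x, hs, cs, gates, tanh_c)
        return hs[1:]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        x, hs, cs, gates, tanh_c = self._cache
        T = x.shape[0]
        gx = np.zeros_like(x)
        dh_next = np.zeros(self.n_out)
        dc_next = np.zeros(self.n_out)
        dWx = self.grads[0:4]
        dWh = self.grads[4:8]
        dbs = self.grads[8:12]
        for t in range(T - 1, -1, -1):
            i, f, o, g = gates[t]
            dh = gout[t] + dh_next
            do = dh * tanh_c[t]
            dc = dh * o * (1.0 - tanh_c[t] ** 2) + dc_next
            di = dc * g
            dg = dc * i
            df = dc * cs[t]
            dc_next = dc * f
            dzi = di * i * (1.0 - i)
            dzf = df * f * (1.0 - f)
            dzo = do * o * (1.0 - o)
            dzg = dg * (1.0 - g**2)
            dzs = (dzi, dzf, dzo, dzg)
            gx_t = np.zeros(x.shape[1])
            dh_prev = np.zeros(self.n_out)
            for k in range(4):
                dWx[k] += np.outer(x[t], dzs[k])
                dWh[k] += np.outer(hs[t], dzs[k])
                dbs[k] += dzs[k]
                gx_t += dzs[k] @ self.Wx[k].T
                dh_prev += dzs[k] @ self.Wh[k].T
            gx[t] = gx_t
            dh_next = dh_prev
        return gx

    def init_state(self) -> tuple[np.ndarray, np.ndarray]:
        return np.zeros(self.n_out), np.zeros(self.n_out)

    def step(self, x: np.ndarray, state: tuple[np.ndarray, np.ndarray]):
        h_prev, c_prev = state
        Wxi, Wxf, Wxo, Wxc = self.Wx
        Whi, Whf, Who, Whc = self.Wh
        bi, bf, bo, bc = self.bs
        i = self._sigmoid(x @ Wxi + h_prev @ Whi + bi)
        f = self._sigmoid(x @ Wxf + h_prev @ Whf + bf)
        o = self._sigmoid(x @ Wxo + h_prev @ Who + bo)
        g = np.tanh(x @ Wxc + h_prev @ Whc + bc)
        c = f * c_prev + i * g
        h = o * np.tanh(c)
        return h, (h, c)


class Network:
    """An ordered stack of layers with a 5-component head output."""

    def __init__(self, kind: str, layers: list[Layer]) -> None:
        self.kind = kind
        self.layers = layers

    @property
    def recurrent(self) -> bool:
        return any(layer.stateful for layer in self.layers)

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(T, 6) -> (T, 5). For recurrent nets rows form one sequence."""
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, gout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gout = layer.backward(gout)
        return gout

    def init_state(self) -> list:
        return [layer.init_state() for layer in self.layers]

    def step(self, x: np.ndarray, state: list) -> tuple[np.ndarray, list]:
        """Single-frame forward with explicit state (for rollouts)."""
        new_state = []
        for layer, st in zip(self.layers, state):
            x, st = layer.step(x, st)
            new_state.append(st)
        return x, new_state

    def set_parameters(self, values: list[np.ndarray]) -> None:
        for p, v in zip(self.parameters(), values):
            p[...] = v

    def copy_parameters(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]


def build_network(
    kind: str,
    rng: np.random.Generator,
    input_dim: int = INPUT_DIM,
    hidden_dims: tuple[int, int] = HIDDEN_DIMS,
    head_dim: int = HEAD_DIM,
) -> Network:
    if kind not in NETWORK_KINDS:
        raise ValueError(f"unknown network kind {kind!r}; choose from {NETWORK_KINDS}")
    h1, h2 = hidden_dims
    layers: list[Layer]
    if kind == "LN":
        layers = [Linear(input_dim, h1, rng), Linear(h1, h2, rng), Linear(h2, head_dim, rng)]
    elif kind == "NN":
        layers = [
            Linear(input_dim, h1, rng), ReLU(),
            Linear(h1, h2, rng), ReLU(),
            Linear(h2, head_dim, rng),
        ]
    elif kind == "DNN":
        layers = [
            Linear(input_dim, h1, rng), ReLU(),
            Linear(h1, h2, rng), ReLU(),
            Linear(h2, h2, rng), ReLU(),
            Linear(h2, head_dim, rng),
        ]
    elif kind == "RNN":
        layers = [Linear(input_dim, h1, rng), Recurrent(h1, h2, rng), Linear(h2, head_dim, rng)]
    elif kind == "DRNN":
        layers = [
            Linear(input_dim, h1, rng),
            Recurrent(h1, h2, rng),
            Recurrent(h2, h2, rng),
            Linear(h2, head_dim, rng),
        ]
    elif kind == "LSTM":
        layers = [Linear(input_dim, h1, rng), LSTM(h1, h2, rng), Linear(h2, head_dim, rng)]
    else:  # DLSTM
        layers = [
            Linear(input_dim, h1, rng),
            LSTM(h1, h2, rng),
            LSTM(h2, h2, rng),
            Linear(h2, head_dim, rng),
        ]
    return Network(kind, layers)


def parameter_count(net: Network) -> int:
    return int(sum(p.size for p in net.parameters()))
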