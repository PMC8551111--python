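"""Training loop (Adam + Gaussian NLL) and leave-one-participant-out CV.

Feedforward kinds are trained on shuffled minibatches of individual
time-steps; recurrent kinds on minibatches of whole trials with
full-sequence unrolling and a state reset per trial. The loss is the
mean NLL over the steps in a batch. A fixed seed makes initialization,
shuffling and therefore the whole training history reproducible.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ..trajectory_io import TrialSet
from .features import TrialFeatures, build_inputs, stack_features
from .gaussian import nll_and_grad_head, nll_from_head
from .networks import (
    HEAD_DIM,
    HIDDEN_DIMS,
    INPUT_DIM,
    NETWORK_KINDS,
    RECURRENT_KINDS,
    Network,
    build_network,
)

logger = logging.getLogger(__name__)


@dataclass
class ModelSpec:
    """Hyperparameters of one trainable model."""

    kind: str
    hidden_dims: tuple[int, int] = HIDDEN_DIMS
    learning_rate: float = 3e-4
    batch_size: int = 16
    epochs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in NETWORK_KINDS:
            raise ValueError(f"ModelSpec.kind must be one of {NETWORK_KINDS}")
        self.hidden_dims = tuple(self.hidden_dims)

    @property
    def recurrent(self) -> bool:
        return self.kind in RECURRENT_KINDS

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "hidden_dims": list(self.hidden_dims),
            "learning_rate": self.learning_rate,
            "batch_size": self.batch_size,
            "epochs": self.epochs,
            "seed": self.seed,
        }


@dataclass
class TrainedModel:
    spec: ModelSpec
    network: Network
    history: list[float] = field(default_factory=list)  # per-epoch mean NLL
    fold_id: str | None = None

    def save(self, path: str | Path) -> None:
        """Serialize to an .npz with the spec embedded as JSON."""
        meta = {
            "format_version": 1,
            "spec": self.spec.to_dict(),
            "fold_id": self.fold_id,
            "history": self.history,
        }
        arrays = {f"param_{i}": p for i, p in enumerate(self.network.parameters())}
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            spec = ModelSpec(**{**meta["spec"], "hidden_dims": tuple(meta["spec"]["hidden_dims"])})
            net = build_network(spec.kind, np.random.default_rng(spec.seed), hidden_dims=spec.hidden_dims)
            values = [data[f"param_{i}"] for i in range(len(net.parameters()))]
            net.set_parameters(values)
        return cls(spec=spec, network=net, history=list(meta["history"]), fold_id=meta["fold_id"])


class Adam:
    """Adam optimizer over a list of parameter arrays."""

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 3e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def train(
    spec: ModelSpec,
    train_data: TrialSet | list[TrialFeatures],
    fold_id: str | None = None,
) -> TrainedModel:
    """Train a network per its spec; returns the model with history.

    ``train_data`` may be a TrialSet (features are built at 20 Hz) or
    pre-built per-trial features. The parameters of the epoch with the
    lowest mean training NLL are retained.
    """
    if isinstance(train_data, TrialSet):
        features = build_inputs(train_data)
    else:
        features = list(train_data)
    if not features or sum(len(f) for f in features) == 0:
        raise ValueError("empty training set")

    rng = np.random.default_rng(spec.seed)
    net = build_network(spec.kind, rng, hidden_dims=spec.hidden_dims)
    opt = Adam(net.parameters(), lr=spec.learning_rate)
    history: list[float] = []

    if spec.recurrent:
        _train_recurrent(spec, net, opt, features, rng, history)
    else:
        _train_feedforward(spec, net, opt, features, rng, history)

    return TrainedModel(spec=spec, network=net, history=history, fold_id=fold_id)


def _train_feedforward(
    spec: ModelSpec,
    net: Network,
    opt: Adam,
    features: list[TrialFeatures],
    rng: np.random.Generator,
    history: list[float],
) -> None:
    X, Y = stack_features(features)
    n = len(X)
    best = (np.inf, None)
    for _epoch in range(spec.epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, spec.batch_size):
            idx = order[start : start + spec.batch_size]
            net.zero_grad()
            h = net.forward(X[idx])
            nll, gh = nll_and_grad_head(h, Y[idx])
            net.backward(gh / len(idx))
            opt.step(net.gradients())
            total += float(nll.sum())
        epoch_nll = total / n
        history.append(epoch_nll)
        if epoch_nll < best[0]:
            best = (epoch_nll, net.copy_parameters())
    if best[1] is not None:
        net.set_parameters(best[1])


def _train_recurrent(
    spec: ModelSpec,
    net: Network,
    opt: Adam,
    features: list[TrialFeatures],
    rng: np.random.Generator,
    history: list[float],
) -> None:
    n_trials = len(features)
    n_steps = sum(len(f) for f in features)
    best = (np.inf, None)
    for _epoch in range(spec.epochs):
        order = rng.permutation(n_trials)
        total = 0.0
        for start in range(0, n_trials, spec.batch_size):
            batch = [features[i] for i in order[start : start + spec.batch_size]]
            batch_steps = sum(len(f) for f in batch)
            if batch_steps == 0:
                continue
            net.zero_grad()
            for f in batch:
                h = net.forward(f.X)  # state resets inside forward
                nll, gh = nll_and_grad_head(h, f.Y)
                net.backward(gh / batch_steps)
                total += float(nll.sum())
            opt.step(net.gradients())
        epoch_nll = total / n_steps
        history.append(epoch_nll)
        if epoch_nll < best[0]:
            best = (epoch_nll, net.copy_parameters())
    if best[1] is not None:
        net.set_parameters(best[1])


def mean_nll(model: TrainedModel, features: list[TrialFeatures]) -> float:
    """Mean NLL of a trained model over per-trial feature blocks."""
    total = 0.0
    n = 0
    for f in features:
        h = model.network.forward(f.X)
        total += float(nll_from_head(h, f.Y).sum())
        n += len(f)
    return total / n if n else float("nan")


def loo_cv(
    spec: ModelSpec,
    ts: TrialSet,
    evaluate,
    min_participants: int = 2,
):
    """Leave-one-defender-participant-out cross-validation.

    ``evaluate(model, held_out_features)`` is called once per fold with
    the model trained on all other participants. Returns the list of
    its return values, one per fold, in participant order. Folds whose
    held-out participant has no usable trials are skipped with a
    warning.
    """
    participants = ts.defender_participants()
    if len(participants) < min_participants:
        raise ValueError("leave-one-out needs at least 2 defender participants")
    all_features = build_inputs(ts)
    results = []
    for p in participants:
        test_feats = [f for f in all_features if f.defender_participant == p]
        train_feats = [f for f in all_features if f.defender_participant != p]
        if not test_feats:
            logger.warning("fold %s skipped: no usable held-out trials", p)
            continue
        model = train(spec, train_feats, fold_id=p)
        logger.info(
            "fold %s: trained on %d trials / %d steps, testing on %d trials / %d steps",
            p,
            len(train_feats),
            sum(len(f) for f in train_feats),
            len(test_feats),
            sum(len(f) for f in test_feats),
        )
        results.append(evaluate(model, test_feats))
    return results
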