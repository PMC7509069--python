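"""Supervised self-organizing map (SSOM) used as the measurement model.

Three layers: an input layer with one node per item, a rectangular
competition grid, and an output layer with one node per mastery-pattern
class.  A presented response vector activates the competition neuron whose
input-weight column is nearest in Euclidean distance (the "winner"); the
winner's predicted class is the argmax of its output-weight row.

Training is sequential and supervised.  For every sample the winner g and
its grid neighborhood N_c(t) are found; when the winner's current predicted
class matches the sample's label, neighborhood weights move toward the
sample on both layers,

    W_in  <- W_in  + eta1(t) (x - W_in)
    W_out <- W_out + eta2(t) (y - W_out)

and when it mismatches the same moves are damped by the coefficient ``mu``
(default 0.5), so wrongly-predicted samples still organize the map but
reinforce their own class more weakly than confirmed ones.  A negative
``mu`` turns the mismatch branch into an LVQ2-style repulsion; that setting
is supported but destabilizes early training, when predictions are still
random, and is not the default.

Learning rates decay linearly over all presentation steps.  The Chebyshev
neighborhood radius shrinks linearly to zero over the first
``ordering_fraction`` of the steps (the ordering phase) and stays at zero
for the remainder (fine tuning), so prototypes converge exactly onto their
training inputs.

Classification restricts the competition to neurons that won at least one
sample in the final training pass — the rest never acquired a meaningful
prototype or label — and resolves distance ties toward the neuron with the
larger receptive field (more training wins), which favors a-priori frequent
patterns exactly where the response vector itself cannot decide.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np

from ._validate import ValidationError

__all__ = ["SSOMConfig", "SSOMNetwork", "find_winner", "predicted_label",
           "update_weights", "train", "classify", "select_iterations"]

# squared-distance slack for a "tie": distinct binary profiles differ by >= 1
_TIE_TOL = 0.25


@dataclass(frozen=True)
class SSOMConfig:
    """Hyperparameters of the supervised SOM.

    ``eta1``/``eta2`` are (start, end) learning-rate pairs for the
    input->competition and competition->output layers, interpolated linearly
    over all presentation steps; a constant rate uses start == end.
    ``radius_start`` is the initial Chebyshev neighborhood radius (``None``
    means half the larger grid side); it decays to zero over the first
    ``ordering_fraction`` of the steps.  ``mu`` scales updates on mismatched
    winners: 0 < mu < 1 damps them, mu < 0 repels.
    """

    grid_shape: tuple = (10, 10)
    eta1: tuple = (0.5, 0.01)
    eta2: tuple = (0.5, 0.01)
    mu: float = 0.5
    radius_start: float | None = None
    ordering_fraction: float = 0.5
    iterations: int = 2
    init_scale: float = 1.0
    out_init_scale: float = 0.1
    seed: int | None = None

    def __post_init__(self):
        rows, cols = self.grid_shape
        if rows < 1 or cols < 1:
            raise ValidationError("grid_shape must be positive")
        for name, (a, b) in (("eta1", self.eta1), ("eta2", self.eta2)):
            if not (0 < a <= 1 and 0 < b <= 1):
                raise ValidationError(f"{name} rates must lie in (0, 1]")
        if self.iterations < 1:
            raise ValidationError("iterations must be >= 1")
        if self.radius_start is not None and self.radius_start < 0:
            raise ValidationError("radius_start must be >= 0")
        if not 0 < self.ordering_fraction <= 1:
            raise ValidationError("ordering_fraction must lie in (0, 1]")
        if not -1 <= self.mu <= 1 or self.mu == 0:
            raise ValidationError("mu must lie in [-1, 1] and be nonzero")

    @property
    def n_neurons(self) -> int:
        return self.grid_shape[0] * self.grid_shape[1]

    def initial_radius(self) -> float:
        if self.radius_start is None:
            return max(self.grid_shape) / 2.0
        return float(self.radius_start)


@dataclass
class SSOMNetwork:
    """Weights and grid geometry of a (possibly trained) SSOM.

    ``w_in`` is n x m (items x neurons), ``w_out`` m x k (neurons x classes);
    ``grid`` holds each neuron's integer grid coordinates.  ``history`` is
    the per-pass training-set accuracy trace and ``wins`` the per-neuron win
    count of the final pass, both filled in by :func:`train`.
    """

    w_in: np.ndarray
    w_out: np.ndarray
    grid: np.ndarray
    config: SSOMConfig
    history: list = field(default_factory=list)
    wins: np.ndarray | None = None

    @property
    def n_inputs(self) -> int:
        return self.w_in.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.w_in.shape[1]

    @property
    def n_classes(self) -> int:
        return self.w_out.shape[1]

    def save(self, path) -> None:
        """Serialize weights, config and training trace to one ``.npz`` archive."""
        cfg = asdict(self.config)
        wins = np.zeros(self.n_neurons) if self.wins is None else self.wins
        np.savez(Path(path), w_in=self.w_in, w_out=self.w_out, grid=self.grid,
                 history=np.asarray(self.history, dtype=float), wins=wins,
                 config=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8),
                 schema=np.array([1]))

    @classmethod
    def load(cls, path) -> "SSOMNetwork":
        data = np.load(Path(path))
        cfg = json.loads(bytes(data["config"]).decode())
        for key in ("grid_shape", "eta1", "eta2"):
            cfg[key] = tuple(cfg[key])
        return cls(w_in=data["w_in"], w_out=data["w_out"], grid=data["grid"],
                   config=SSOMConfig(**cfg), history=list(data["history"]),
                   wins=data["wins"])


def _init_network(n_inputs: int, n_classes: int, config: SSOMConfig,
                  rng: np.random.Generator) -> SSOMNetwork:
    rows, cols = config.grid_shape
    if config.n_neurons < n_classes:
        raise ValidationError("competition grid must have >= n_classes neurons")
    grid = np.stack(np.meshgrid(np.arange(rows), np.arange(cols),
                                indexing="ij"), axis=-1).reshape(-1, 2)
    w_in = rng.uniform(0.0, config.init_scale, (n_inputs, config.n_neurons))
    w_out = rng.uniform(0.0, config.out_init_scale, (config.n_neurons, n_classes))
    return SSOMNetwork(w_in=w_in, w_out=w_out, grid=grid, config=config)


def find_winner(x, net: SSOMNetwork):
    """Winning neuron index and Euclidean distances to every neuron."""
    x = np.asarray(x, dtype=float)
    if x.shape != (net.n_inputs,):
        raise ValidationError(f"input length {x.shape} != {net.n_inputs}")
    if np.isnan(x).any() or np.isnan(net.w_in).any():
        raise ValidationError("NaN in input or weights")
    dist = np.sqrt(((net.w_in - x[:, None]) ** 2).sum(axis=0))
    return int(np.argmin(dist)), dist


def predicted_label(g: int, net: SSOMNetwork) -> int:
    """Class read off the winner's output weights; ties break to the lowest index."""
    if not 0 <= g < net.n_neurons:
        raise ValidationError(f"neuron index {g} out of range")
    return int(np.argmax(net.w_out[g]))


def _schedule(start: float, end: float, t: int, total: int) -> float:
    if total <= 1:
        return start
    frac = min(max(t / (total - 1), 0.0), 1.0)
    return start + (end - start) * frac


def _radius_at(config: SSOMConfig, t: int, total: int) -> float:
    t_order = max(int(config.ordering_fraction * total), 1)
    return config.initial_radius() * max(1.0 - t / t_order, 0.0)


def update_weights(net: SSOMNetwork, x, y_onehot, g: int, t: int,
                   total_steps: int | None = None) -> SSOMNetwork:
    """One supervised update around winner ``g`` at presentation step ``t``.

    Neurons within the Chebyshev neighborhood of ``g`` move toward the sample
    on both layers; the move is scaled by the mismatch coefficient ``mu``
    when the winner's current predicted class disagrees with the label.
    Modifies ``net`` in place and returns it.
    """
    cfg = net.config
    x = np.asarray(x, dtype=float)
    y = np.asarray(y_onehot, dtype=float)
    if total_steps is None:
        total_steps = max(t + 1, 1)
    eta1 = _schedule(*cfg.eta1, t, total_steps)
    eta2 = _schedule(*cfg.eta2, t, total_steps)
    radius = _radius_at(cfg, t, total_steps)
    cheb = np.abs(net.grid - net.grid[g]).max(axis=1)
    hood = cheb <= radius
    match = predicted_label(g, net) == int(np.argmax(y))
    factor = 1.0 if match else cfg.mu
    net.w_in[:, hood] += factor * eta1 * (x[:, None] - net.w_in[:, hood])
    net.w_out[hood, :] += factor * eta2 * (y[None, :] - net.w_out[hood, :])
    return net


def classify(responses, net: SSOMNetwork) -> np.ndarray:
    """Hard pattern classification of each response row (the HMM observation layer).

    Competition is restricted to neurons with a non-empty receptive field in
    the final training pass (all neurons when the network carries no win
    counts); squared-distance ties are resolved toward the neuron with the
    most training wins, then the lower class index.
    """
    from .design import ResponseMatrix
    if isinstance(responses, ResponseMatrix):
        responses = responses.scores
    x = np.asarray(responses, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] != net.n_inputs:
        raise ValidationError(
            f"response columns {x.shape[1]} != network inputs {net.n_inputs}")
    if net.wins is not None and (net.wins > 0).any():
        active = np.flatnonzero(net.wins > 0)
        wins = net.wins[active]
    else:
        active = np.arange(net.n_neurons)
        wins = np.ones(active.size)
    w = net.w_in[:, active]
    d2 = (x ** 2).sum(axis=1)[:, None] - 2.0 * x @ w + (w ** 2).sum(axis=0)[None, :]
    best = d2.min(axis=1, keepdims=True)
    tied = d2 <= best + _TIE_TOL
    pick = np.argmax(np.where(tied, wins[None, :], -1.0), axis=1)
    return np.argmax(net.w_out[active[pick]], axis=1).astype(np.int64)


def train(inputs, labels, config: SSOMConfig, n_classes: int | None = None,
          seed=None) -> SSOMNetwork:
    """Train an SSOM with shuffled sequential passes over the training set.

    ``seed`` overrides ``config.seed``; the same data, config and seed give
    bit-identical weights.  The returned network's ``history`` holds the
    training-set accuracy after each full pass and ``wins`` the final-pass
    win count per neuron.
    """
    x = np.asarray(inputs, dtype=float)
    y = np.asarray(labels, dtype=np.int64)
    if x.ndim != 2 or x.shape[0] == 0:
        raise ValidationError("training inputs must be a non-empty 2-D array")
    if y.shape != (x.shape[0],):
        raise ValidationError("labels must align with training rows")
    if n_classes is None:
        n_classes = int(y.max()) + 1
    if (y < 0).any() or (y >= n_classes).any():
        raise ValidationError("labels out of range")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    net = _init_network(x.shape[1], n_classes, config, rng)
    onehot = np.eye(n_classes)
    n = x.shape[0]
    total = config.iterations * n
    step = 0
    for _ in range(config.iterations):
        wins = np.zeros(net.n_neurons, dtype=np.int64)
        for i in rng.permutation(n):
            g, _ = find_winner(x[i], net)
            wins[g] += 1
            update_weights(net, x[i], onehot[y[i]], g, step, total)
            step += 1
        net.wins = wins
        net.history.append(float(np.mean(classify(x, net) == y)))
    return net


def select_iterations(inputs, labels, config: SSOMConfig, patience: int = 2,
                      tol: float = 5e-3, cap: int = 20, seed=None) -> int:
    """Smallest pass count after which training accuracy plateaus.

    Retrains from scratch with 1, 2, ... passes (schedules stretch with the
    pass count, mirroring how the pass number is tuned empirically) and
    returns the first count followed by ``patience`` consecutive accuracy
    changes below ``tol``.  Warns and returns ``cap`` if no plateau appears.
    """
    if patience < 1:
        raise ValidationError("patience must be >= 1")
    accs = []
    for count in range(1, cap + 1):
        net = train(inputs, labels, replace(config, iterations=count), seed=seed)
        accs.append(net.history[-1])
        start = count - patience
        if start >= 1:
            diffs = [abs(accs[i] - accs[i - 1]) for i in range(start, count)]
            if all(d < tol for d in diffs):
                return start
    warnings.warn(f"training accuracy did not stabilize within {cap} passes")
    return cap
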