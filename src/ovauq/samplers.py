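"""Stochastic reference predictors that produce ProbabilitySamples.

The predictors here are deliberately small, self-contained numpy models:

* :class:`DropoutMLP` — a feed-forward rectifier network with a logistic
  output unit and inverted dropout after every hidden layer, trained by
  mini-batch Adam on binary cross-entropy.  Keeping dropout active at
  inference and running T forward passes (:func:`mc_dropout_sample`) yields
  Monte Carlo dropout predictive samples.
* deep ensembles (:func:`ensemble_sample`) — one deterministic pass per
  independently initialized and trained member;
* ensemble MC dropout (:func:`emc_sample`) — the concatenation of each
  member's MC-dropout passes;
* :class:`BayesianMLP` — a mean-field Gaussian-weight network trained by
  stochastic variational inference (Bayes by backprop: per-batch weight
  draws, cross-entropy plus a KL penalty to a standard-normal prior
  weighted 1/n_batches), sampled by drawing a full weight realization per
  pass (:func:`bayes_sample`); ensembles of these (:func:`ebnn_sample`).

The default architecture has three hidden layers of 128, 64 and 32 units
with dropout rate 0.5, a 150-dimensional input and a single logistic
output — 29,697 trainable parameters.  All samplers are bit-reproducible
under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .uq_metrics import InvalidInputError, InvalidParameterError, ProbabilitySample


class InvalidSpecError(ValueError):
    """An architecture or ensemble specification is structurally invalid."""


class InvalidStateError(ValueError):
    """Model parameters are non-finite or otherwise unusable."""


@dataclass(frozen=True)
class ReferenceNetSpec:
    """Architecture of the reference feed-forward network."""

    input_dim: int = 150
    hidden: tuple[int, ...] = (128, 64, 32)
    dropout_rate: float = 0.5

    def __post_init__(self) -> None:
        if self.input_dim < 1 or any(w < 1 for w in self.hidden):
            raise InvalidSpecError("layer widths must be positive")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise InvalidSpecError("dropout rate must be in [0, 1)")

    @property
    def layer_widths(self) -> list[int]:
        return [self.input_dim, *self.hidden, 1]

    def layer_param_counts(self) -> list[int]:
        """(fan_in + 1) * fan_out for each dense layer (weights + biases)."""
        w = self.layer_widths
        return [(w[i] + 1) * w[i + 1] for i in range(len(w) - 1)]

    def param_count(self) -> int:
        return sum(self.layer_param_counts())


@dataclass(frozen=True)
class TrainConfig:
    """Mini-batch training configuration (Adam on binary cross-entropy)."""

    learning_rate: float = 1e-3
    epochs: int = 15
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 0:
            raise InvalidParameterError("learning rate, batch size and epochs must be positive")


@dataclass(frozen=True)
class EnsembleSpec:
    """Size and seeding of an ensemble of independently trained members."""

    n_members: int = 5
    passes_per_member: int = 10

    def __post_init__(self) -> None:
        if self.n_members < 1 or self.passes_per_member < 1:
            raise InvalidSpecError("ensemble needs >= 1 member and >= 1 pass per member")


def _check_training_inputs(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise InvalidInputError("features must be (n, d) aligned with labels")
    if not np.all(np.isfinite(X)):
        raise InvalidInputError("features must be finite")
    if not np.all((y == 0) | (y == 1)):
        raise InvalidInputError("labels must be binary 0/1")
    return X, y


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class _Adam:
    """Adam optimizer state over a flat list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class DropoutMLP:
    """Rectifier network with inverted dropout and a logistic output unit.

    Satisfies the stochastic-predictor contract: ``sample(X, T, seed)``
    returns a ProbabilitySample, ``param_count()`` the number of trainable
    parameters.  Dropout is applied after each hidden activation; at
    inference it is off unless a dropout generator is supplied.
    """

    def __init__(self, spec: ReferenceNetSpec = ReferenceNetSpec(), seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        widths = spec.layer_widths
        # variance-scaled (He) init for the rectifier layers
        self.W = [
            rng.normal(0.0, np.sqrt(2.0 / widths[i]), size=(widths[i], widths[i + 1]))
            for i in range(len(widths) - 1)
        ]
        self.b = [np.zeros(widths[i + 1]) for i in range(len(widths) - 1)]

    # -- structure ---------------------------------------------------------

    def param_count(self) -> int:
        return sum(w.size + b.size for w, b in zip(self.W, self.b))

    def layer_param_counts(self) -> list[int]:
        return [w.size + b.size for w, b in zip(self.W, self.b)]

    # -- forward -----------------------------------------------------------

    def _forward(self, X: np.ndarray, dropout_rng: np.random.Generator | None):
        """Forward pass; returns (probabilities, per-layer caches)."""
        keep = 1.0 - self.spec.dropout_rate
        a = X
        caches = []
        for i in range(len(self.W) - 1):
            z = a @ self.W[i] + self.b[i]
            h = np.maximum(z, 0.0)
            if dropout_rng is not None and keep < 1.0:
                mask = (dropout_rng.random(h.shape) < keep) / keep
            else:
                mask = None
            a_next = h * mask if mask is not None else h
            caches.append((a, z, mask))
            a = a_next
        z_out = a @ self.W[-1] + self.b[-1]
        caches.append((a, z_out, None))
        return _sigmoid(z_out).ravel(), caches

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Deterministic probabilities (dropout off)."""
        return self._forward(np.asarray(X, dtype=float), None)[0]

    def sample(self, X: np.ndarray, T: int, seed: int | np.random.Generator = 0) -> ProbabilitySample:
        return mc_dropout_sample(self, X, T, seed)

    # -- training ----------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray, cfg: TrainConfig = TrainConfig()) -> list[float]:
        """Mini-batch Adam on binary cross-entropy with dropout active.

        Returns the per-epoch mean training loss (length = cfg.epochs).
        """
        X, y = _check_training_inputs(X, y)
        rng = np.random.default_rng(cfg.seed)
        params = [*self.W, *self.b]
        opt = _Adam(params, cfg.learning_rate)
        history: list[float] = []
        n = X.shape[0]
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                Xb, yb = X[idx], y[idx]
                p, caches = self._forward(Xb, rng)
                eps = 1e-12
                losses.append(float(-np.mean(
                    yb * np.log(p + eps) + (1 - yb) * np.log(1 - p + eps))))
                grads = self._backward(p, yb, caches)
                opt.step(params, grads)
            history.append(float(np.mean(losses)))
        return history

    def _backward(self, p: np.ndarray, y: np.ndarray, caches) -> list[np.ndarray]:
        B = y.shape[0]
        gW = [np.empty(0)] * len(self.W)
        gb = [np.empty(0)] * len(self.b)
        delta = ((p - y) / B)[:, None]          # d loss / d z_out
        a_in, _, _ = caches[-1]
        gW[-1] = a_in.T @ delta
        gb[-1] = delta.sum(axis=0)
        da = delta @ self.W[-1].T
        for i in range(len(self.W) - 2, -1, -1):
            a_prev, z, mask = caches[i]
            if mask is not None:
                da = da * mask
            dz = da * (z > 0)
            gW[i] = a_prev.T @ dz
            gb[i] = dz.sum(axis=0)
            if i > 0:
                da = dz @ self.W[i].T
        return [*gW, *gb]


def build_reference_net(spec: ReferenceNetSpec = ReferenceNetSpec(), seed: int = 0) -> DropoutMLP:
    """Construct the reference dropout network for a one-vs-all task."""
    return DropoutMLP(spec, seed)


def train(predictor, X: np.ndarray, y: np.ndarray, cfg: TrainConfig = TrainConfig()) -> list[float]:
    """Train any predictor exposing ``fit``; returns the loss history."""
    return predictor.fit(X, y, cfg)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def mc_dropout_sample(
    model: DropoutMLP, X: np.ndarray, T: int, seed: int | np.random.Generator = 0
) -> ProbabilitySample:
    """T stochastic forward passes with dropout kept active at inference."""
    if T < 1:
        raise InvalidParameterError(f"T must be >= 1, got {T}")
    X = np.asarray(X, dtype=float)
    rng = _as_rng(seed)
    rows = [model._forward(X, rng if model.spec.dropout_rate > 0 else None)[0] for _ in range(T)]
    return ProbabilitySample(np.vstack(rows))


def ensemble_sample(members: Sequence, X: np.ndarray) -> ProbabilitySample:
    """One deterministic pass per member (dropout off); T = number of members."""
    if len(members) < 1:
        raise InvalidSpecError("ensemble must have at least one member")
    X = np.asarray(X, dtype=float)
    return ProbabilitySample(np.vstack([m.predict(X) for m in members]))


def emc_sample(
    members: Sequence[DropoutMLP], X: np.ndarray, T_per_member: int,
    seed: int | np.random.Generator = 0,
) -> ProbabilitySample:
    """Concatenated MC-dropout passes of every member; T = M * T_per_member.

    A single shared generator is threaded through the members in order, so
    an ensemble of one reproduces :func:`mc_dropout_sample` exactly.
    """
    if len(members) < 1:
        raise InvalidSpecError("ensemble must have at least one member")
    rng = _as_rng(seed)
    blocks = [mc_dropout_sample(m, X, T_per_member, rng).probs for m in members]
    return ProbabilitySample(np.vstack(blocks))


# ---------------------------------------------------------------------------
# mean-field Gaussian-weight network
# ---------------------------------------------------------------------------


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


class BayesianMLP:
    """Feed-forward network with independent Gaussian posteriors per weight.

    Each weight w has a variational posterior N(mu, sigma^2) with
    sigma = softplus(rho).  Training follows Bayes by backprop: for every
    mini-batch one weight realization is drawn by reparameterization
    (w = mu + sigma * eps), the binary cross-entropy is backpropagated to
    (mu, rho), and the KL divergence to the standard-normal prior is added
    with weight 1 / (n_batches * batch).  Prediction draws one full weight
    realization per stochastic pass; with all sigma = 0 the network is
    deterministic.
    """

    RHO_INIT = -5.0  # softplus(-5) ~ 6.7e-3: near-deterministic start

    def __init__(self, spec: ReferenceNetSpec = ReferenceNetSpec(dropout_rate=0.0), seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        widths = spec.layer_widths
        self.W_mu = [
            rng.normal(0.0, np.sqrt(2.0 / widths[i]), size=(widths[i], widths[i + 1]))
            for i in range(len(widths) - 1)
        ]
        self.b_mu = [np.zeros(widths[i + 1]) for i in range(len(widths) - 1)]
        self.W_rho = [np.full_like(w, self.RHO_INIT) for w in self.W_mu]
        self.b_rho = [np.full_like(b, self.RHO_INIT) for b in self.b_mu]

    def param_count(self) -> int:
        """Count of predictive weights (posterior means), matching the
        deterministic architecture; rho parameters shadow them 1:1."""
        return sum(w.size + b.size for w, b in zip(self.W_mu, self.b_mu))

    def scale_posterior_std(self, factor: float) -> None:
        """Multiply every posterior standard deviation by ``factor`` in place."""
        for i in range(len(self.W_rho)):
            for arr in (self.W_rho, self.b_rho):
                sigma = _softplus(arr[i]) * factor
                with np.errstate(divide="ignore"):
                    arr[i] = np.where(
                        sigma > 0, np.log(np.expm1(np.maximum(sigma, 1e-300))), -np.inf
                    )

    def set_zero_variance(self) -> None:
        for i in range(len(self.W_rho)):
            self.W_rho[i] = np.full_like(self.W_rho[i], -np.inf)
            self.b_rho[i] = np.full_like(self.b_rho[i], -np.inf)

    def _check_state(self) -> None:
        for arrs in (self.W_mu, self.b_mu):
            if any(not np.all(np.isfinite(a)) for a in arrs):
                raise InvalidStateError("posterior means must be finite")
        for arrs in (self.W_rho, self.b_rho):
            # -inf rho encodes exactly-zero variance and is allowed
            if any(np.any(np.isnan(a) | (a == np.inf)) for a in arrs):
                raise InvalidStateError("posterior scale parameters must not be NaN/+inf")

    def _draw_weights(self, rng: np.random.Generator):
        Ws, bs, eWs, ebs = [], [], [], []
        for Wm, Wr, bm, br in zip(self.W_mu, self.W_rho, self.b_mu, self.b_rho):
            eW = rng.standard_normal(Wm.shape)
            eb = rng.standard_normal(bm.shape)
            Ws.append(Wm + _softplus(Wr) * eW)
            bs.append(bm + _softplus(br) * eb)
            eWs.append(eW)
            ebs.append(eb)
        return Ws, bs, eWs, ebs

    @staticmethod
    def _forward_with(Ws, bs, X):
        a = X
        caches = []
        for i in range(len(Ws) - 1):
            z = a @ Ws[i] + bs[i]
            caches.append((a, z))
            a = np.maximum(z, 0.0)
        z_out = a @ Ws[-1] + bs[-1]
        caches.append((a, z_out))
        return _sigmoid(z_out).ravel(), caches

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Probabilities at the posterior means (no weight noise)."""
        return self._forward_with(self.W_mu, self.b_mu, np.asarray(X, dtype=float))[0]

    def sample(self, X: np.ndarray, T: int, seed: int | np.random.Generator = 0) -> ProbabilitySample:
        return bayes_sample(self, X, T, seed)

    def fit(self, X: np.ndarray, y: np.ndarray, cfg: TrainConfig = TrainConfig()) -> list[float]:
        """Stochastic variational training; returns per-epoch mean data loss."""
        X, y = _check_training_inputs(X, y)
        rng = np.random.default_rng(cfg.seed)
        params = [*self.W_mu, *self.b_mu, *self.W_rho, *self.b_rho]
        opt = _Adam(params, cfg.learning_rate)
        n = X.shape[0]
        n_batches = max(1, int(np.ceil(n / cfg.batch_size)))
        history: list[float] = []
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                Xb, yb = X[idx], y[idx]
                Ws, bs, eWs, ebs = self._draw_weights(rng)
                p, caches = self._forward_with(Ws, bs, Xb)
                eps = 1e-12
                losses.append(float(-np.mean(
                    yb * np.log(p + eps) + (1 - yb) * np.log(1 - p + eps))))
                gW, gb = self._backward_weights(Ws, p, yb, caches)
                kl_w = 1.0 / (n_batches * len(idx))
                grads = self._variational_grads(gW, gb, eWs, ebs, kl_w)
                opt.step(params, grads)
            history.append(float(np.mean(losses)))
        return history

    def _backward_weights(self, Ws, p, y, caches):
        B = y.shape[0]
        gW = [np.empty(0)] * len(Ws)
        gb = [np.empty(0)] * len(Ws)
        delta = ((p - y) / B)[:, None]
        a_in, _ = caches[-1]
        gW[-1] = a_in.T @ delta
        gb[-1] = delta.sum(axis=0)
        da = delta @ Ws[-1].T
        for i in range(len(Ws) - 2, -1, -1):
            a_prev, z = caches[i]
            dz = da * (z > 0)
            gW[i] = a_prev.T @ dz
            gb[i] = dz.sum(axis=0)
            if i > 0:
                da = dz @ Ws[i].T
        return gW, gb

    def _variational_grads(self, gW, gb, eWs, ebs, kl_w):
        """Map weight-space gradients to (mu, rho) gradients and add the KL term.

        KL(N(mu, s^2) || N(0, 1)) has d/dmu = mu and d/ds = s - 1/s; the
        1/s term is clipped to keep the near-zero-variance regime stable.
        """
        g_mu, g_rho = [], []
        for g, e, mu, rho in zip(
            gW + gb, eWs + ebs, self.W_mu + self.b_mu, self.W_rho + self.b_rho
        ):
            s = _softplus(rho)
            dsig = _sigmoid(rho)  # d softplus / d rho
            d_kl_s = s - np.minimum(1.0 / np.maximum(s, 1e-6), 1e4)
            g_mu.append(g + kl_w * mu)
            g_rho.append(g * e * dsig + kl_w * d_kl_s * dsig)
        return g_mu + g_rho


def bayes_sample(
    model: BayesianMLP, X: np.ndarray, T: int, seed: int | np.random.Generator = 0
) -> ProbabilitySample:
    """T passes, each under an independent full weight draw from the posterior."""
    if T < 1:
        raise InvalidParameterError(f"T must be >= 1, got {T}")
    model._check_state()
    X = np.asarray(X, dtype=float)
    rng = _as_rng(seed)
    rows = []
    for _ in range(T):
        Ws, bs, _, _ = model._draw_weights(rng)
        rows.append(model._forward_with(Ws, bs, X)[0])
    return ProbabilitySample(np.vstack(rows))


def ebnn_sample(
    members: Sequence[BayesianMLP], X: np.ndarray, T_per_member: int,
    seed: int | np.random.Generator = 0,
) -> ProbabilitySample:
    """Pooled posterior-weight passes of an ensemble of Bayesian networks."""
    if len(members) < 1:
        raise InvalidSpecError("ensemble must have at least one member")
    rng = _as_rng(seed)
    blocks = [bayes_sample(m, X, T_per_member, rng).probs for m in members]
    return ProbabilitySample(np.vstack(blocks))
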