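"""From-scratch t-SNE producing the 2-D map used for density clustering.

Exact (O(n^2)) t-SNE: per-point Gaussian bandwidths are calibrated by
binary search to a target perplexity, conditional probabilities are
symmetrized into the joint distribution P, and a Student-t (1 df)
low-dimensional kernel Q is fit by gradient descent on KL(P||Q) with early
exaggeration, a two-stage momentum schedule and adaptive per-parameter
gains. After the exaggeration phase a monotonicity safeguard (revert +
backtracking plain gradient step whenever a momentum step would raise the
objective) keeps the recorded KL trace non-increasing, which also gives
downstream consumers a simple convergence diagnostic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import ConfigurationError, InputError, OptimizationError


@dataclass(frozen=True)
class TsneConfig:
    perplexity: float = 30.0
    n_iterations: int = 1000
    early_exaggeration_factor: float = 12.0
    early_exaggeration_duration: int = 250
    learning_rate: float = 200.0
    momentum_initial: float = 0.5
    momentum_final: float = 0.8
    momentum_switch_iteration: int = 250
    seed: int = 0
    output_dim: int = 2

    def __post_init__(self):
        if self.perplexity <= 0:
            raise ConfigurationError("perplexity must be positive")
        if self.early_exaggeration_duration >= self.n_iterations:
            raise ConfigurationError("exaggeration duration must be < n_iterations")
        if self.output_dim != 2:
            raise ConfigurationError("only 2-D output is supported")


@dataclass
class Embedding:
    coordinates: np.ndarray  # n x 2
    kl_trace: list[tuple[int, float]]
    config: TsneConfig
    calibration_residuals: np.ndarray  # per-point |achieved - target| perplexity
    patient_ids: list[str] | None = None

    def to_frame(self) -> pd.DataFrame:
        idx = self.patient_ids if self.patient_ids is not None else range(
            len(self.coordinates)
        )
        return pd.DataFrame(
            self.coordinates, index=pd.Index(idx, name="patient_id"), columns=["x", "y"]
        )


# ---------------------------------------------------------------------------
# bandwidth calibration


def calibrate_bandwidths(
    d2: np.ndarray, perplexity: float, tol: float = 1e-7, max_bisections: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Per-point Gaussian bandwidths sigma_i and conditionals p(j|i).

    For each point, binary search on the precision beta_i = 1/(2 sigma_i^2)
    until the perplexity exp(H(p(.|i))) matches the target. Rows sum to 1,
    p(i|i) = 0.
    """
    d2 = np.asarray(d2, dtype=float)
    n = d2.shape[0]
    if d2.shape != (n, n):
        raise InputError("distance matrix must be square")
    if not np.isfinite(d2).all():
        raise InputError("non-finite distances")
    if not np.allclose(d2, d2.T) or not np.allclose(np.diag(d2), 0.0):
        raise InputError("distances must be symmetric with zero diagonal")
    if not 1 <= perplexity <= n - 1:
        raise ConfigurationError("perplexity must lie in [1, n-1]")
    log_target = np.log(perplexity)
    P = np.zeros((n, n))
    sigmas = np.zeros(n)
    for i in range(n):
        row = np.delete(d2[i], i)

        def entropy_and_probs(beta):
            logits = -beta * row
            logits -= logits.max()
            w = np.exp(logits)
            s = w.sum()
            p = w / s
            # H = log(s) + beta * E[d2] + shift; compute directly from p
            with np.errstate(divide="ignore", invalid="ignore"):
                h = -np.sum(np.where(p > 0, p * np.log(p), 0.0))
            return h, p

        beta = 1.0
        h, p = entropy_and_probs(beta)
        lo, hi = None, None
        for _ in range(64):  # bracket the root (entropy decreases in beta)
            if h > log_target:
                lo = beta
                beta = beta * 2 if hi is None else 0.5 * (lo + hi)
            else:
                hi = beta
                beta = beta / 2 if lo is None else 0.5 * (lo + hi)
            h, p = entropy_and_probs(beta)
            if lo is not None and hi is not None:
                break
        for _ in range(max_bisections):
            if abs(h - log_target) < tol:
                break
            if h > log_target:
                lo = beta
            else:
                hi = beta
            if lo is None or hi is None:
                break
            beta = 0.5 * (lo + hi)
            h, p = entropy_and_probs(beta)
        sigmas[i] = np.sqrt(1.0 / (2.0 * beta))
        P[i, np.arange(n) != i] = p
    return sigmas, P


def achieved_perplexities(conditionals: np.ndarray) -> np.ndarray:
    P = np.asarray(conditionals, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.sum(np.where(P > 0, P * np.log(P), 0.0), axis=1)
    return np.exp(h)


def joint_probabilities(conditionals: np.ndarray) -> np.ndarray:
    """Symmetrize row-stochastic conditionals: P = (C + C^T) / (2n)."""
    C = np.asarray(conditionals, dtype=float)
    n = C.shape[0]
    rows = C.sum(axis=1)
    if not np.allclose(rows, 1.0, atol=1e-8):
        raise InputError("conditionals must be row-stochastic")
    return (C + C.T) / (2.0 * n)


# ---------------------------------------------------------------------------
# optimization


def _student_t_kernel(Y: np.ndarray) -> tuple[np.ndarray, float]:
    d2 = cdist(Y, Y, "sqeuclidean")
    W = 1.0 / (1.0 + d2)
    np.fill_diagonal(W, 0.0)
    return W, float(W.sum())


def kl_divergence(P: np.ndarray, Y: np.ndarray) -> float:
    W, Z = _student_t_kernel(Y)
    return _kl_from_kernel(P, W, Z)


def _kl_from_kernel(P: np.ndarray, W: np.ndarray, Z: float) -> float:
    mask = P > 0
    logq = np.where(mask, np.log(np.maximum(W, 1e-300)), 0.0) - np.log(Z)
    logp = np.where(mask, np.log(np.where(mask, P, 1.0)), 0.0)
    return float(np.sum(np.where(mask, P * (logp - logq), 0.0)))


def kl_gradient(P: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Exact gradient of KL(P||Q) with the Student-t kernel."""
    W, Z = _student_t_kernel(Y)
    Q = W / Z
    M = (P - Q) * W
    s = M.sum(axis=1)
    return 4.0 * (Y * s[:, None] - M @ Y)


def tsne_embed(
    P: np.ndarray,
    config: TsneConfig,
    patient_ids: list[str] | None = None,
    calibration_residuals: np.ndarray | None = None,
) -> Embedding:
    """Gradient descent on KL(P||Q); deterministic given the config seed."""
    P = np.asarray(P, dtype=float)
    n = P.shape[0]
    if not np.allclose(P, P.T) or abs(P.sum() - 1.0) > 1e-8 or (P < 0).any():
        raise InputError("P must be a symmetric joint distribution")
    rng = np.random.default_rng(config.seed)
    Y = rng.normal(0.0, 1e-4, size=(n, 2))
    velocity = np.zeros_like(Y)
    gains = np.ones_like(Y)
    lr = config.learning_rate
    exag_end = config.early_exaggeration_duration
    trace: list[tuple[int, float]] = []
    kl_prev = None
    for it in range(config.n_iterations):
        exaggerating = it < exag_end
        P_eff = P * config.early_exaggeration_factor if exaggerating else P
        W, Z = _student_t_kernel(Y)
        Q = W / Z
        M = (P_eff - Q) * W
        grad = 4.0 * (Y * M.sum(axis=1)[:, None] - M @ Y)
        momentum = (
            config.momentum_initial
            if it < config.momentum_switch_iteration
            else config.momentum_final
        )
        sign_agree = np.sign(grad) == np.sign(velocity)
        gains = np.where(sign_agree, gains * 0.8, gains + 0.2)
        gains = np.maximum(gains, 0.01)
        velocity = momentum * velocity - lr * gains * grad
        Y_new = Y + velocity
        Y_new -= Y_new.mean(axis=0)
        if not np.isfinite(Y_new).all():
            raise OptimizationError(f"embedding diverged at iteration {it}")
        kl_new = kl_divergence(P, Y_new)
        if not exaggerating and kl_prev is not None and kl_new > kl_prev + 1e-9:
            # momentum overshoot: fall back to a backtracking gradient step
            velocity[:] = 0.0
            gains[:] = 1.0
            true_grad = kl_gradient(P, Y)
            step = lr
            accepted = False
            for _ in range(30):
                Y_try = Y - step * true_grad
                Y_try -= Y_try.mean(axis=0)
                kl_try = kl_divergence(P, Y_try)
                if kl_try <= kl_prev:
                    Y_new, kl_new = Y_try, kl_try
                    accepted = True
                    break
                step *= 0.5
            if not accepted:
                Y_new, kl_new = Y, kl_prev  # stay put; trace stays monotone
        Y = Y_new
        kl_prev = kl_new
        trace.append((it, kl_new))
    if calibration_residuals is None:
        calibration_residuals = np.zeros(n)
    return Embedding(Y, trace, config, calibration_residuals, patient_ids)


def embed_features(
    X: pd.DataFrame | np.ndarray, config: TsneConfig
) -> Embedding:
    """Distances on the standardized matrix (Euclidean) -> calibrate ->
    symmetrize -> optimize."""
    if isinstance(X, pd.DataFrame):
        ids = [str(i) for i in X.index]
        values = X.to_numpy(dtype=float)
    else:
        ids = None
        values = np.asarray(X, dtype=float)
    d2 = cdist(values, values, "sqeuclidean")
    _, cond = calibrate_bandwidths(d2, config.perplexity)
    residuals = np.abs(achieved_perplexities(cond) - config.perplexity)
    P = joint_probabilities(cond)
    return tsne_embed(P, config, patient_ids=ids, calibration_residuals=residuals)


def write_embedding(emb: Embedding, outdir: str | Path, name: str = "embedding") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    emb.to_frame().to_csv(outdir / f"{name}.tsv", sep="\t")
    meta = {
        "config": asdict(emb.config),
        "kl_trace": [[int(i), float(k)] for i, k in emb.kl_trace[::10]],
        "final_kl": float(emb.kl_trace[-1][1]) if emb.kl_trace else None,
        "max_calibration_residual": float(np.max(emb.calibration_residuals)),
    }
    (outdir / f"{name}_meta.json").write_text(json.dumps(meta, indent=1))
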