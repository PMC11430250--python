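"""Learnable type-2 fuzzy (FT2) activation unit.

The activation is a rectifier whose positive/negative slopes P and N are
modulated by a type-2-fuzzy membership factor k(σ; α):

    f(σ) = P · σ · k(σ)     for σ > 0
    f(σ) = N · σ · k(−σ)    for σ ≤ 0

    k(σ) = ½ [ 1 / (α + (1−α)σ)  +  (α−1) / (ασ − 1) ]

with fuzziness parameter α ∈ (0, 1).  k(1) = 1 for every α, so f(1) = P and
f(−1) = −N; with k ≡ 1 the unit degenerates exactly to Leaky-ReLU (exposed via
``as_leaky`` for regression testing).

All three parameters γ = [α, P, N] are learnable; gradients are the exact
derivatives of the forward map (validated against finite differences) and are
applied with a classical momentum update Δγ ← ρΔγ + ξ ∂L/∂γ, γ ← γ − Δγ.

k has a pole at σ = 1/α.  Denominators within ``eps`` of zero are clamped
(sign-preserving) and counted in ``FT2Params.guard_hits``; α is initialised at
0.5 and inputs are expected batch-standardised upstream so typical |σ| stays
below the pole.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np

EPS_GUARD = 1e-8
ALPHA_CLAMP = 1e-6


def _guard(d: np.ndarray, eps: float) -> np.ndarray:
    """Clamp near-zero denominators away from zero, preserving sign."""
    s = np.where(d >= 0, 1.0, -1.0)
    return np.where(np.abs(d) < eps, s * eps, d)


def k_func(sigma, alpha, eps: float = EPS_GUARD):
    """Membership factor k(σ; α) for σ ≥ 0 (elementwise).

    k(σ) = ½ [ 1/(α + σ − ασ) + (α−1)/(ασ − 1) ].  k(1) = 1 exactly.
    """
    sigma = np.asarray(sigma, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0) or np.any(alpha >= 1):
        raise ValueError("alpha must lie strictly in (0, 1)")
    A = _guard(alpha + (1.0 - alpha) * sigma, eps)
    B = _guard(alpha * sigma - 1.0, eps)
    return 0.5 * (1.0 / A + (alpha - 1.0) / B)


def _k_parts(sigma, alpha, eps):
    """k, dk/dσ and dk/dα together (σ ≥ 0), plus a guard-hit count."""
    A_raw = alpha + (1.0 - alpha) * sigma
    B_raw = alpha * sigma - 1.0
    hits = int(np.count_nonzero(np.abs(A_raw) < eps) +
               np.count_nonzero(np.abs(B_raw) < eps))
    A = _guard(A_raw, eps)
    B = _guard(B_raw, eps)
    k = 0.5 * (1.0 / A + (alpha - 1.0) / B)
    dk_ds = 0.5 * (-(1.0 - alpha) / A**2 - alpha * (alpha - 1.0) / B**2)
    dk_da = 0.5 * (sigma - 1.0) * (1.0 / A**2 + 1.0 / B**2)
    return k, dk_ds, dk_da, hits


@dataclass
class FT2Params:
    """Per-layer FT2 state: γ = [α, P, N] plus momentum accumulators.

    By default α is a per-layer scalar while P and N are per-unit vectors
    (so a layer with C units learns 2C + 1 activation parameters).  ``rho``
    and ``xi`` are the momentum coefficient and activation learning rate.
    """

    alpha: np.ndarray
    P: np.ndarray
    N: np.ndarray
    rho: float = 0.9
    xi: float = 1e-3
    eps: float = EPS_GUARD
    as_leaky: bool = False
    velocity: Dict[str, np.ndarray] = field(default_factory=dict)
    guard_hits: int = 0

    @staticmethod
    def init(n_units: int, alpha0: float = 0.5, p0: float = 1.0, n0: float = 0.01,
             rho: float = 0.9, xi: float = 1e-3, as_leaky: bool = False) -> "FT2Params":
        return FT2Params(
            alpha=np.asarray(alpha0, dtype=float),
            P=np.full(n_units, p0, dtype=float),
            N=np.full(n_units, n0, dtype=float),
            rho=rho, xi=xi, as_leaky=as_leaky,
        )

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        self.N = np.asarray(self.N, dtype=float)
        if np.any(self.alpha <= 0) or np.any(self.alpha >= 1):
            raise ValueError("alpha must lie strictly in (0, 1)")
        if not (np.all(np.isfinite(self.P)) and np.all(np.isfinite(self.N))):
            raise ValueError("P and N must be finite")
        for name, p in (("alpha", self.alpha), ("P", self.P), ("N", self.N)):
            self.velocity.setdefault(name, np.zeros_like(p))
            if self.velocity[name].shape != p.shape:
                raise ValueError(f"velocity shape mismatch for {name}")

    def copy(self) -> "FT2Params":
        return FT2Params(
            alpha=self.alpha.copy(), P=self.P.copy(), N=self.N.copy(),
            rho=self.rho, xi=self.xi, eps=self.eps, as_leaky=self.as_leaky,
            velocity={k: v.copy() for k, v in self.velocity.items()},
            guard_hits=self.guard_hits,
        )


def ft2_forward(sigma: np.ndarray, params: FT2Params) -> np.ndarray:
    """Activation f(σ) elementwise; P/N broadcast along the last axis."""
    sigma = np.asarray(sigma, dtype=float)
    if not np.all(np.isfinite(sigma)):
        raise ValueError("non-finite pre-activation input")
    pos = sigma > 0
    if params.as_leaky:
        k_pos = k_neg = 1.0
    else:
        s = np.where(pos, sigma, -sigma)  # |σ|, argument of k on both branches
        k_pos, _, _, hits = _k_parts(s, params.alpha, params.eps)
        k_neg = k_pos
        params.guard_hits += hits
    return np.where(pos, params.P * sigma * k_pos, params.N * sigma * k_neg)


def ft2_backward(sigma: np.ndarray, params: FT2Params):
    """Elementwise partials (∂f/∂σ, ∂f/∂α, ∂f/∂P, ∂f/∂N) of the forward map.

    Returned arrays have sigma's shape; reductions over batch axes (and over
    units, for the shared α) are the caller's job via the chain rule.
    """
    sigma = np.asarray(sigma, dtype=float)
    if not np.all(np.isfinite(sigma)):
        raise ValueError("non-finite pre-activation input")
    pos = sigma > 0
    if params.as_leaky:
        slope = np.where(pos, params.P * np.ones_like(sigma),
                         params.N * np.ones_like(sigma))
        z = np.zeros_like(sigma)
        return slope, z, np.where(pos, sigma, 0.0), np.where(pos, 0.0, sigma)

    s = np.where(pos, sigma, -sigma)
    k, dk_ds, dk_da, hits = _k_parts(s, params.alpha, params.eps)
    params.guard_hits += hits
    # σ>0: f = Pσk(σ)  → f′ = P(k + σ k′);  k, k′ evaluated at s = σ
    # σ≤0: f = Nσk(−σ) → f′ = N(k(−σ) − σ k′(−σ));  k, k′ evaluated at s = −σ
    df_ds = np.where(pos, params.P * (k + sigma * dk_ds),
                     params.N * (k - sigma * dk_ds))
    df_da = np.where(pos, params.P * sigma * dk_da, params.N * sigma * dk_da)
    df_dP = np.where(pos, sigma * k, 0.0)
    df_dN = np.where(pos, 0.0, sigma * k)
    return df_ds, df_da, df_dP, df_dN


def ft2_update(params: FT2Params, grads: Dict[str, np.ndarray]) -> FT2Params:
    """Momentum step Δγ ← ρΔγ + ξ·∂L/∂γ, γ ← γ − Δγ (in place; returns params).

    α is clamped back into (0, 1) after the step.
    """
    for name in ("alpha", "P", "N"):
        g = np.asarray(grads[name], dtype=float)
        if not np.all(np.isfinite(g)):
            raise ValueError(f"non-finite gradient for {name}")
        v = params.velocity[name]
        if g.shape != v.shape:
            # allow scalar-vs-array broadcast only when sizes agree
            g = np.broadcast_to(g, v.shape).copy()
        v *= params.rho
        v += params.xi * g
        cur = getattr(params, name)
        setattr(params, name, cur - v)
    params.alpha = np.clip(params.alpha, ALPHA_CLAMP, 1.0 - ALPHA_CLAMP)
    return params
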