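"""Spectral graph machinery: connectivity adjacency, Laplacian, graph Fourier
transform, exact spectral filtering and Chebyshev-polynomial convolution.

Nodes are EEG channels; edge weights are thresholded absolute Pearson
correlations between channel time series (functional connectivity).  The
combinatorial Laplacian L = D − W is used unnormalised, with its dense
eigendecomposition L = U Λ Uᵀ (N is tiny — 3 to a few dozen channels).

Chebyshev filtering operates on the rescaled Laplacian
L̃ = 2L/λ_max − I, whose spectrum lies in [−1, 1], via the recurrence
T₀ = I, T₁ = L̃, T_q = 2 L̃ T_{q−1} − T_{q−2}.  Exact spectral filtering
(``spectral_filter``) is kept as the oracle against which ``cheb_conv`` is
validated.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .core import EpochSet

_SYM_TOL = 1e-10

#: stability guard: Chebyshev orders beyond this are rejected
DEFAULT_Q_CAP = 25


def correlation_adjacency(epochs) -> np.ndarray:
    """Absolute Pearson correlation between channels, averaged over epochs.

    Accepts an :class:`EpochSet` or an array (n_epochs, n_channels, n_samples)
    / (n_channels, n_samples).  Diagonal is zeroed.  A zero-variance channel
    gets zero correlations and triggers a warning.
    """
    if isinstance(epochs, EpochSet):
        arr = epochs.epochs
    else:
        arr = np.asarray(epochs, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError("expected (epochs, channels, samples) array")
    if arr.shape[2] < 2:
        raise ValueError("need at least 2 samples per channel")
    n = arr.shape[1]
    acc = np.zeros((n, n))
    for ep in arr:
        sd = ep.std(axis=1)
        dead = sd == 0
        if dead.any():
            warnings.warn(
                f"zero-variance channel(s) {np.where(dead)[0].tolist()}; "
                "their correlations are set to 0",
                RuntimeWarning,
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.corrcoef(ep)
        c = np.nan_to_num(c, nan=0.0)
        acc += np.abs(c)
    C = acc / arr.shape[0]
    C = np.clip((C + C.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(C, 0.0)
    return C


def threshold_adjacency(C: np.ndarray, tau: float, binarize: bool = False) -> np.ndarray:
    """Keep entries >= tau (weighted retention by default; binary by flag)."""
    if not (0.0 <= tau <= 1.0):
        raise ValueError(f"tau must lie in [0, 1], got {tau}")
    C = np.asarray(C, dtype=float)
    if not np.allclose(C, C.T, atol=1e-12):
        raise ValueError("connectivity matrix must be symmetric")
    keep = C >= tau
    W = np.where(keep, 1.0 if binarize else C, 0.0)
    np.fill_diagonal(W, 0.0)
    return W


@dataclass
class SpectralGraph:
    """Adjacency, Laplacian and eigensystem of a channel graph."""

    W: np.ndarray
    D: np.ndarray
    L: np.ndarray
    U: np.ndarray
    lam: np.ndarray
    lambda_max: float
    L_scaled: np.ndarray
    node_labels: Sequence[str] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.W.shape[0]

    def to_json(self, path=None, tau: Optional[float] = None) -> str:
        payload = {
            "node_labels": list(self.node_labels),
            "W": self.W.tolist(),
            "tau": tau,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @staticmethod
    def from_json(source) -> "SpectralGraph":
        if hasattr(source, "read"):
            payload = json.load(source)
        elif isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        g = build_graph(np.asarray(payload["W"], dtype=float))
        g.node_labels = payload.get("node_labels", [])
        return g


def build_graph(W: np.ndarray, node_labels: Sequence[str] = ()) -> SpectralGraph:
    """Assemble degree matrix, Laplacian and eigensystem from an adjacency.

    Eigenvalues come out ascending; each eigenvector's sign is fixed by making
    its largest-magnitude entry positive, so serialised graphs reproduce.
    For the empty graph (λ_max = 0) the rescaled Laplacian is defined as −I so
    Chebyshev terms stay well defined.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be square")
    if not np.allclose(W, W.T, atol=_SYM_TOL):
        raise ValueError("W must be symmetric")
    if (W < -_SYM_TOL).any():
        raise ValueError("W must be nonnegative")
    if np.abs(np.diag(W)).max(initial=0.0) > _SYM_TOL:
        raise ValueError("W must have zero diagonal")
    W = (W + W.T) / 2.0

    deg = W.sum(axis=1)
    D = np.diag(deg)
    L = D - W
    lam, U = np.linalg.eigh(L)
    # deterministic sign convention
    for k in range(U.shape[1]):
        j = np.argmax(np.abs(U[:, k]))
        if U[j, k] < 0:
            U[:, k] = -U[:, k]
    lam = np.where(np.abs(lam) < 1e-12, 0.0, lam)
    lambda_max = float(lam[-1])
    n = W.shape[0]
    if lambda_max <= 0.0:
        L_scaled = -np.eye(n)
        lambda_max = 0.0
    else:
        L_scaled = 2.0 * L / lambda_max - np.eye(n)
    return SpectralGraph(
        W=W, D=D, L=L, U=U, lam=lam, lambda_max=lambda_max,
        L_scaled=L_scaled, node_labels=list(node_labels),
    )


def graph_from_epochs(
    epochs: EpochSet, tau: float = 0.5, binarize: bool = False
) -> SpectralGraph:
    """Connectivity graph straight from an epoch set (correlation + threshold)."""
    C = correlation_adjacency(epochs)
    W = threshold_adjacency(C, tau, binarize=binarize)
    return build_graph(W, node_labels=list(epochs.channel_names))


def _check_signal(q: np.ndarray, G: SpectralGraph) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if q.shape[0] != G.n_nodes:
        raise ValueError(f"signal length {q.shape[0]} != graph order {G.n_nodes}")
    return q


def graph_fourier(q: np.ndarray, G: SpectralGraph) -> np.ndarray:
    """Graph Fourier transform q̂ = Uᵀ q."""
    return G.U.T @ _check_signal(q, G)


def inverse_graph_fourier(q_hat: np.ndarray, G: SpectralGraph) -> np.ndarray:
    """Inverse transform q = U q̂."""
    return G.U @ _check_signal(q_hat, G)


def spectral_filter(
    x: np.ndarray, g_of_lambda: Callable[[np.ndarray], np.ndarray], G: SpectralGraph
) -> np.ndarray:
    """Exact filtering y = U g(Λ) Uᵀ x with g applied to the eigenvalues.

    Serves as the correctness oracle for :func:`cheb_conv`.
    """
    x = _check_signal(x, G)
    g = np.asarray(g_of_lambda(G.lam), dtype=float)
    if g.shape != G.lam.shape or not np.all(np.isfinite(g)):
        raise ValueError("g(lambda) must be finite and one value per eigenvalue")
    xh = G.U.T @ x
    if x.ndim == 1:
        return G.U @ (g * xh)
    return G.U @ (g[:, None] * xh)


def cheb_polynomial_values(coeffs: np.ndarray, lam: np.ndarray, lambda_max: float) -> np.ndarray:
    """Scalar filter response Σ_q θ_q T_q(2λ/λ_max − 1) — oracle helper."""
    coeffs = np.asarray(coeffs, dtype=float).ravel()
    if lambda_max <= 0:
        x = -np.ones_like(lam)
    else:
        x = 2.0 * np.asarray(lam) / lambda_max - 1.0
    t_prev, t = np.ones_like(x), x.copy()
    out = coeffs[0] * t_prev
    if len(coeffs) > 1:
        out = out + coeffs[1] * t
    for q in range(2, len(coeffs)):
        t_prev, t = t, 2.0 * x * t - t_prev
        out = out + coeffs[q] * t
    return out


def cheb_conv(
    X: np.ndarray,
    theta: np.ndarray,
    G: SpectralGraph,
    q_cap: int = DEFAULT_Q_CAP,
) -> np.ndarray:
    """Chebyshev graph convolution Y = Σ_q T_q(L̃) X θ_q.

    ``X`` is (N, F_in) or batched (B, N, F_in); ``theta`` is (Q, F_in, F_out).
    Orders above ``q_cap`` are rejected (high-order recurrences amplify
    rounding error with no practical benefit here).
    """
    theta = np.asarray(theta, dtype=float)
    if theta.ndim == 1:
        theta = theta[:, None, None]
    if theta.ndim != 3:
        raise ValueError("theta must have shape (Q, F_in, F_out)")
    Q = theta.shape[0]
    if Q < 1:
        raise ValueError("Chebyshev order Q must be >= 1")
    if Q > q_cap:
        raise ValueError(f"Chebyshev order {Q} exceeds cap {q_cap}")
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta must be finite")

    X = np.asarray(X, dtype=float)
    batched = X.ndim == 3
    if not batched:
        X = X[None]
    if X.shape[1] != G.n_nodes:
        raise ValueError(f"X node axis {X.shape[1]} != graph order {G.n_nodes}")
    if X.shape[2] != theta.shape[1]:
        raise ValueError(f"X feature axis {X.shape[2]} != theta F_in {theta.shape[1]}")

    Lt = G.L_scaled
    Z_prev = X                                  # T_0(L̃) X
    Y = Z_prev @ theta[0]
    if Q > 1:
        Z = np.einsum("nm,bmf->bnf", Lt, X)     # T_1(L̃) X
        Y = Y + Z @ theta[1]
        for q in range(2, Q):
            Z_prev, Z = Z, 2.0 * np.einsum("nm,bmf->bnf", Lt, Z) - Z_prev
            Y = Y + Z @ theta[q]
    return Y if batched else Y[0]
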