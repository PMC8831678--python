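"""Maximum Entropy on the Mean (MEM) reconstruction for surface DOT.

MEM selects, among all probability distributions on the source amplitudes
whose mean explains the data, the one closest (in relative entropy) to a
reference prior.  The reference factorizes over K cortical parcels; each
parcel is a Bernoulli-Gaussian mixture

    dnu_k = (1 - alpha_k) * delta(x_k) + alpha_k * N(mu_k, Sigma_k)

whose Dirac component can *switch off* an inactive parcel entirely — the
mechanism behind MEM's accurate recovery of spatial extent.  The convex
problem reduces to maximizing the concave channel-space dual

    D(lambda) = lambda' y  -  F_nu(A' lambda)  -  1/2 lambda' Sigma_noise lambda

where F_nu is the free energy (log-Laplace transform) of the reference, and
the estimate is the free-energy gradient at xi = A' lambda*.

Depth weighting enters twice: omega2 controls the depth-weighted MNE used
to scale the parcel covariances (locally normalized per time sample so the
prior carries spatial, not temporal, information), and omega1 scales each
parcel covariance by the depth-weighting diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .mne import DepthWeighting, depth_weights, solve_mne
from .parcellation import Parcellation, smoothness_operator
from .metrics import CorticalMap

__all__ = ["ParcelModel", "MemDual", "init_prior", "free_energy", "maximize_dual", "mem_estimate", "solve_mem"]


@dataclass
class ParcelModel:
    """Initialized MEM reference prior on a parcellation.

    Per parcel k: activation probability ``alpha[k]`` in (0, 1); Gaussian
    mean zero; covariance Sigma_k(t) = eta[k, t] * base[k] where ``base[k]``
    is the fixed depth-weighted smoothness kernel
    L_k^(1/2) W' W L_k^(1/2) and ``eta[k, t]`` is 5% of the parcel-mean
    squared locally-normalized depth-weighted MNE energy at time t.
    """

    parcellation: Parcellation
    alpha: np.ndarray                  # (K,)
    base: list                         # K dense (n_k, n_k) kernels
    eta: np.ndarray                    # (K, T)
    omega1: float
    omega2: float
    times: np.ndarray | None = None
    dmne: np.ndarray | None = None     # the initializing depth-weighted MNE map
    members: list | None = None        # cached per-parcel vertex index arrays

    @property
    def K(self) -> int:
        return self.parcellation.K

    def parcel_members(self, k: int) -> np.ndarray:
        if self.members is None:
            self.members = [self.parcellation.parcel_vertices(j) for j in range(self.K)]
        return self.members[k]


@dataclass
class MemDual:
    lambda_dual: np.ndarray
    converged: bool
    dual_value: float
    grad_norm: float
    n_iter: int = 0


def init_prior(
    Y,
    A,
    noise,
    parcels: Parcellation,
    omega1: float = 0.3,
    omega2: float = 0.5,
    eta_fraction: float = 0.05,
    sigma_smooth: float = 0.6,
    max_order: int = 3,
    alpha_scores: np.ndarray | None = None,
    alpha_clamp: tuple = (0.05, 0.95),
    mesh=None,
    lambda_grid=None,
    lambda_selector: str = "lcurve",
) -> ParcelModel:
    """Build the parcel-wise Bernoulli-Gaussian reference prior.

    Steps: (i) depth-weighted MNE with exponent ``omega2``; (ii) local
    normalization — each time sample of the MNE map is divided by its own
    spatial maximum, so the prior keeps only spatial structure and the
    temporal dynamics are estimated from the data; (iii) parcel energies
    eta_k(t) = ``eta_fraction`` x mean squared normalized MNE over the
    parcel; (iv) fixed kernels L_k^(1/2) W'W L_k^(1/2) with the
    ``omega1`` depth-weighting diagonal restricted to the parcel;
    (v) alpha_k from the parcel-mean MSP score, clamped into (0, 1).
    """
    a = A.matrix() if hasattr(A, "matrix") else np.asarray(A, dtype=float)
    y = Y.values if hasattr(Y, "values") else np.asarray(Y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    mesh = mesh or (A.mesh if hasattr(A, "mesh") else None)
    if mesh is None:
        raise ValueError("init_prior needs the cortical mesh (pass mesh=...)")

    w2 = depth_weights(a, noise, omega2)
    sol = solve_mne(y, a, noise, weighting=w2, lambda_grid=lambda_grid, selector=lambda_selector)
    x = sol.X_hat                                   # (q, T)
    T = x.shape[1]

    # local (per-time-sample) normalization by the spatial maximum
    xn = np.zeros_like(x)
    for t in range(T):
        m = np.max(np.abs(x[:, t]))
        if m > 0:
            xn[:, t] = x[:, t] / m

    w1 = depth_weights(a, noise, omega1)
    K = parcels.K
    eta = np.zeros((K, T))
    base = []
    for k in range(K):
        members = parcels.parcel_vertices(k)
        eta[k] = eta_fraction * np.mean(xn[members] ** 2, axis=0)
        W = smoothness_operator(mesh, members, sigma=sigma_smooth, max_order=max_order).matrix
        lam_half = np.sqrt(w1.scaling[members])
        base.append((W.T @ W) * np.outer(lam_half, lam_half))
    # floor so the free energy stays finite when a parcel's energy vanishes
    floor = 1e-12 * max(eta.max(), 1.0)
    eta = np.maximum(eta, floor)

    if alpha_scores is not None:
        alpha = np.array(
            [np.clip(np.mean(alpha_scores[parcels.parcel_vertices(k)]), *alpha_clamp) for k in range(K)]
        )
    else:
        alpha = np.full(K, 0.5)

    return ParcelModel(
        parcellation=parcels,
        alpha=alpha,
        base=base,
        eta=eta,
        omega1=float(omega1),
        omega2=float(omega2),
        times=getattr(Y, "times", None),
        dmne=x,
    )


def _parcel_terms(xi: np.ndarray, model: ParcelModel, t: int):
    """Per-parcel (g_k, Sigma_k xi_k) with g_k = 1/2 xi' Sigma xi (mu = 0)."""
    gs = np.empty(model.K)
    sx = []
    for k in range(model.K):
        members = model.parcel_members(k)
        xk = xi[members]
        s = model.eta[k, t] * (model.base[k] @ xk)
        gs[k] = 0.5 * float(xk @ s)
        sx.append(s)
    return gs, sx


def free_energy(xi: np.ndarray, model: ParcelModel, t: int = 0):
    """Free energy F_nu(xi) of the Bernoulli-Gaussian reference and gradient.

    F = sum_k log[(1-a_k) + a_k exp(g_k)], g_k = 1/2 xi_k' Sigma_k xi_k.
    Gradient on parcel k: gamma_k * Sigma_k xi_k with posterior activation
    gamma_k = sigmoid(g_k + logit(a_k)).  Evaluated in log space so large
    g_k cannot overflow.
    """
    xi = np.asarray(xi, dtype=float)
    gs, sx = _parcel_terms(xi, model, t)
    a = model.alpha
    log_a, log_1ma = np.log(a), np.log1p(-a)
    vals = np.logaddexp(log_1ma, log_a + gs)
    if not np.all(np.isfinite(vals)):
        raise FloatingPointError("non-finite free energy")
    gamma = expit(gs + log_a - log_1ma)
    grad = np.zeros_like(xi)
    for k in range(model.K):
        grad[model.parcel_members(k)] = gamma[k] * sx[k]
    return float(np.sum(vals)), grad


def maximize_dual(
    Y_t: np.ndarray,
    A,
    noise,
    model: ParcelModel,
    t: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    lambda0: np.ndarray | None = None,
) -> MemDual:
    """Maximize the concave dual D(lambda) by quasi-Newton ascent.

    D(lambda) = lambda'y - F_nu(A'lambda) - 1/2 lambda' Sigma_noise lambda.
    Convergence requires the gradient norm to fall below ``tol`` (scaled by
    max(1, |y|)); otherwise the best iterate is returned flagged.
    """
    a = A.matrix() if hasattr(A, "matrix") else np.asarray(A, dtype=float)
    cov = noise.covariance if hasattr(noise, "covariance") else np.asarray(noise, dtype=float)
    y = np.asarray(Y_t, dtype=float).ravel()

    # cache members/order once: parcel slicing dominates the gradient cost
    def neg_dual(lam):
        xi = a.T @ lam
        f, gf = free_energy(xi, model, t)
        val = float(lam @ y) - f - 0.5 * float(lam @ (cov @ lam))
        grad = y - a @ gf - cov @ lam
        return -val, -grad

    x0 = np.zeros(len(y)) if lambda0 is None else np.asarray(lambda0, dtype=float)
    scale = max(1.0, float(np.linalg.norm(y)))
    res = minimize(
        neg_dual,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": tol * scale * 1e-2, "ftol": 1e-14},
    )
    grad_norm = float(np.linalg.norm(res.jac))
    return MemDual(
        lambda_dual=res.x,
        converged=grad_norm <= tol * scale,
        dual_value=-float(res.fun),
        grad_norm=grad_norm,
        n_iter=int(res.nit),
    )


def mem_estimate(dual: MemDual, A, model: ParcelModel, t: int = 0, gamma_floor: float = 1e-12) -> np.ndarray:
    """MEM amplitudes: gradient of the free energy at xi = A' lambda*.

    Parcels whose posterior activation gamma_k is (numerically) zero are
    switched off exactly — their vertices return 0.
    """
    a = A.matrix() if hasattr(A, "matrix") else np.asarray(A, dtype=float)
    xi = a.T @ dual.lambda_dual
    gs, sx = _parcel_terms(xi, model, t)
    alpha = model.alpha
    gamma = expit(gs + np.log(alpha) - np.log1p(-alpha))
    x = np.zeros(a.shape[1])
    for k in range(model.K):
        if gamma[k] <= gamma_floor:
            continue
        x[model.parcel_members(k)] = gamma[k] * sx[k]
    return x


def solve_mem(
    Y,
    A,
    noise,
    parcels: Parcellation,
    omega1: float = 0.3,
    omega2: float = 0.5,
    mesh=None,
    alpha_scores=None,
    tol: float = 1e-6,
    max_iter: int = 500,
    eta_fraction: float = 0.05,
    sigma_smooth: float = 0.6,
    lambda_selector: str = "lcurve",
    require_convergence: bool = False,
) -> CorticalMap:
    """Full MEM solve: prior initialization then per-sample dual ascent.

    Successive time samples are independent problems; the dual maximizer of
    sample t warm-starts sample t+1.  The output map is tagged
    ``MEM(omega1,omega2)`` and carries per-sample convergence diagnostics in
    ``diagnostics``.
    """
    y = Y.values if hasattr(Y, "values") else np.asarray(Y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    a = A.matrix() if hasattr(A, "matrix") else np.asarray(A, dtype=float)
    mesh = mesh or (A.mesh if hasattr(A, "mesh") else None)
    model = init_prior(
        Y, A, noise, parcels,
        omega1=omega1, omega2=omega2,
        eta_fraction=eta_fraction, sigma_smooth=sigma_smooth,
        alpha_scores=alpha_scores, mesh=mesh,
        lambda_selector=lambda_selector,
    )
    T = y.shape[1]
    X = np.zeros((a.shape[1], T))
    diags = []
    lam_prev = None
    for t in range(T):
        dual = maximize_dual(y[:, t], a, noise, model, t=t, tol=tol, max_iter=max_iter, lambda0=lam_prev)
        if require_convergence and not dual.converged:
            raise RuntimeError(f"MEM dual did not converge at sample {t} (|grad|={dual.grad_norm:.2e})")
        X[:, t] = mem_estimate(dual, a, model, t=t)
        lam_prev = dual.lambda_dual
        diags.append({"t": t, "converged": bool(dual.converged), "grad_norm": dual.grad_norm, "n_iter": dual.n_iter})
    times = getattr(Y, "times", None)
    cmap = CorticalMap(
        amplitudes=X,
        times=np.asarray(times) if times is not None else np.arange(T, dtype=float),
        method_tag=f"MEM({omega1:g},{omega2:g})",
        mesh=mesh,
    )
    cmap.diagnostics = diags
    cmap.model = model
    return cmap
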