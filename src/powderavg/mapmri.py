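"""MAP-MRI in spherical coordinates: a 3D signal representation whose
isotropic part is a continuous powder average S_bar(b).

The signal is expanded as ``S(q, q_hat) = sum c_jlm Xi_jlm(u0, q, q_hat)``
with basis functions

    Xi_jlm = sqrt(4 pi) i^{-l} (2 pi^2 u0^2 q^2)^{l/2} exp(-2 pi^2 u0^2 q^2)
             * L_{j-1}^{l+1/2}(4 pi^2 u0^2 q^2) * Y_l^m(q_hat)

over even ``l`` (antipodal symmetry), ``j >= 1``, ``2j + l = N + 2`` for
``N = 0, 2, ..., n_max``.  For even ``l`` the phase ``i^{-l}`` is the
real sign ``(-1)^{l/2}``.  The wavevector magnitude maps to b-value via
``q = sqrt(b / tau) / (2 pi)`` with ``tau = Delta - delta/3``, chosen so
that ``exp(-2 pi^2 u0^2 q^2) = exp(-b MD)`` when ``u0^2 = 2 MD tau`` -
i.e. the single-term fit is exact for isotropic Gaussian diffusion, and
the data-driven scale ``u0`` absorbs the wavevector convention.

Three fit modes are supported: plain least squares (``ls``), propagator-
positivity-constrained quadratic programming (``constrained``, the
original MAP formulation) and Laplacian-regularized least squares with
generalized cross-validation for the penalty weight (``laplacian``,
known as MAPL).

The ensemble-average propagator (EAP) dual of the basis, needed for the
positivity constraints and for the Laplacian penalty, follows from the
harmonic-oscillator eigenfunction property of the basis under the 3D
Fourier transform:

    Psi_jlm(r) = (-1)^{j-1} (2 pi)^{-3/2} u0^{-3} sqrt(4 pi)
                 * t^{l/2} exp(-t) L_{j-1}^{l+1/2}(2 t) Y_l^m(r_hat),
    t = r^2 / (2 u0^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import eval_genlaguerre, gammaln

from ._sph import cart_to_sph, real_sph_harm
from .sampling import GradientScheme, lebedev_rule
from .simulate import SignalArray

__all__ = [
    "MAPBasisSpec",
    "MAPFit",
    "MapMriModel",
    "map_basis_matrix",
    "estimate_u0",
    "fit_map",
    "map_powder_average",
    "laplacian_matrix",
    "propagator_basis_matrix",
]

_SQRT4PI = np.sqrt(4.0 * np.pi)
_LAMBDA_GRID = np.logspace(-5.0, 1.0, 13)


def _index_list(n_max: int) -> list[tuple[int, int, int]]:
    """(j, l, m) triples with 2j + l = N + 2 over even N = 0..n_max."""
    out = []
    for N in range(0, n_max + 1, 2):
        for l in range(N, -1, -2):
            j = (N + 2 - l) // 2
            for m in range(-l, l + 1):
                out.append((j, l, m))
    return out


@dataclass(frozen=True)
class MAPBasisSpec:
    """Basis definition: truncation order ``n_max`` and scale ``u0`` (um)."""

    n_max: int = 8
    u0: float = 1.0

    def __post_init__(self):
        if self.n_max % 2 != 0 or self.n_max < 0:
            raise ValueError("n_max must be a nonnegative even integer")
        if not self.u0 > 0:
            raise ValueError("u0 must be positive")

    @property
    def index_list(self) -> list[tuple[int, int, int]]:
        return _index_list(self.n_max)

    @property
    def n_coeff(self) -> int:
        h = self.n_max // 2
        return (h + 1) * (h + 2) * (2 * self.n_max + 3) // 6


def _radial_xi(j: int, l: int, s: np.ndarray) -> np.ndarray:
    """Radial factor of Xi at s = 2 pi^2 u0^2 q^2 (includes sqrt(4pi) i^-l)."""
    sign = (-1.0) ** (l // 2)
    with np.errstate(invalid="ignore"):
        sl = np.where(s > 0, s ** (l / 2.0), 1.0 if l == 0 else 0.0)
    return sign * _SQRT4PI * sl * np.exp(-s) * eval_genlaguerre(j - 1, l + 0.5, 2.0 * s)


def _basis_matrix_from_q(q: np.ndarray, directions: np.ndarray,
                         spec: MAPBasisSpec) -> np.ndarray:
    s = 2.0 * np.pi**2 * spec.u0**2 * q**2
    theta, phi = cart_to_sph(directions)
    cols = []
    ycache: dict[tuple[int, int], np.ndarray] = {}
    for (j, l, m) in spec.index_list:
        if (l, m) not in ycache:
            ycache[(l, m)] = real_sph_harm(l, m, theta, phi)
        cols.append(_radial_xi(j, l, s) * ycache[(l, m)])
    return np.column_stack(cols)


def b_to_q(b, tau: float):
    """Wavevector magnitude for a b-value: ``q = sqrt(b / tau) / (2 pi)``."""
    return np.sqrt(np.asarray(b, dtype=float) / tau) / (2.0 * np.pi)


def map_basis_matrix(scheme: GradientScheme, spec: MAPBasisSpec) -> np.ndarray:
    """Design matrix Xi_jlm(u0, q_i, u_i), one row per scheme sample."""
    q = b_to_q(scheme.b_values, scheme.tau)
    return _basis_matrix_from_q(q, scheme.directions, spec)


def propagator_basis_matrix(r: np.ndarray, directions: np.ndarray,
                            spec: MAPBasisSpec) -> np.ndarray:
    """EAP dual-basis matrix Psi_jlm(u0, r_i, r_hat_i).

    ``r`` in um, one radius per row of ``directions``.
    """
    r = np.asarray(r, dtype=float)
    t = r**2 / (2.0 * spec.u0**2)
    theta, phi = cart_to_sph(directions)
    const = (2.0 * np.pi) ** (-1.5) * spec.u0 ** (-3) * _SQRT4PI
    cols = []
    ycache: dict[tuple[int, int], np.ndarray] = {}
    for (j, l, m) in spec.index_list:
        if (l, m) not in ycache:
            ycache[(l, m)] = real_sph_harm(l, m, theta, phi)
        with np.errstate(invalid="ignore"):
            tl = np.where(t > 0, t ** (l / 2.0), 1.0 if l == 0 else 0.0)
        rad = ((-1.0) ** (j - 1) * const * tl * np.exp(-t)
               * eval_genlaguerre(j - 1, l + 0.5, 2.0 * t))
        cols.append(rad * ycache[(l, m)])
    return np.column_stack(cols)


def isotropic_radial_norm(j: int, u0: float) -> float:
    """Analytic L2 norm of Xi_j00 under the measure 4 pi q^2 dq:
    ``||Xi_j00||^2 = Gamma(j + 1/2) / ((j-1)! 4 pi^2 u0^3)``."""
    return float(np.exp(gammaln(j + 0.5) - gammaln(j)) / (4.0 * np.pi**2 * u0**3))


def laplacian_matrix(spec: MAPBasisSpec, n_radial: int = 256) -> np.ndarray:
    """Gram matrix of the q-space Laplacian of the basis.

    ``R_ab = int (nabla^2 Xi_a)(nabla^2 Xi_b) d^3q``; by Plancherel this
    equals ``16 pi^4 int r^4 Psi_a Psi_b d^3r``, which is block-diagonal
    in (l, m) by the orthonormality of the real spherical harmonics and
    is evaluated here by Gauss-Legendre quadrature on the radial factor.
    """
    idx = spec.index_list
    n = len(idx)
    u0 = spec.u0
    # radial grid: the duals decay like exp(-r^2/(2 u0^2))
    r_max = 12.0 * u0
    x, wx = np.polynomial.legendre.leggauss(n_radial)
    r = 0.5 * r_max * (x + 1.0)
    w = 0.5 * r_max * wx
    t = r**2 / (2.0 * u0**2)
    const = (2.0 * np.pi) ** (-1.5) * u0 ** (-3) * _SQRT4PI
    # radial dual functions per (j, l) actually used
    rad = {}
    for (j, l, m) in idx:
        if (j, l) not in rad:
            with np.errstate(invalid="ignore"):
                tl = np.where(t > 0, t ** (l / 2.0), 1.0 if l == 0 else 0.0)
            rad[(j, l)] = ((-1.0) ** (j - 1) * const * tl * np.exp(-t)
                           * eval_genlaguerre(j - 1, l + 0.5, 2.0 * t))
    R = np.zeros((n, n))
    weight = 16.0 * np.pi**4 * w * r**6
    for a, (j, l, m) in enumerate(idx):
        for b in range(a, n):
            j2, l2, m2 = idx[b]
            if l2 != l or m2 != m:
                continue
            val = np.sum(weight * rad[(j, l)] * rad[(j2, l)])
            R[a, b] = R[b, a] = val
    return R


def estimate_u0(scheme: GradientScheme, signals: SignalArray | np.ndarray,
                b_cut: float = 3.0) -> float:
    """Basis scale from a log-linear tensor fit on the low-b data.

    Fits ``ln S = ln S0 - b u^T D u`` on samples with ``b <= b_cut``
    (ms/um^2) and returns ``u0 = sqrt(2 MD tau)`` with MD the mean
    diffusivity and ``tau = Delta - delta/3`` - the width of a Gaussian
    displacement distribution with that mean diffusivity.  The
    log-linear fit is signal-weighted (weights S_i, the first-order
    variance correction for log-transformed noisy magnitudes), which
    leaves exact data untouched but keeps the scale estimate stable at
    low SNR.
    """
    values = signals.values if isinstance(signals, SignalArray) else np.asarray(signals, dtype=float)
    mask = scheme.b_values <= b_cut
    b = scheme.b_values[mask]
    d = scheme.directions[mask]
    s = np.clip(values[mask], 1e-6, None)
    ux, uy, uz = d[:, 0], d[:, 1], d[:, 2]
    X = np.column_stack([
        np.ones_like(b),
        -b * ux**2, -b * uy**2, -b * uz**2,
        -2 * b * ux * uy, -2 * b * ux * uz, -2 * b * uy * uz,
    ])
    beta, *_ = np.linalg.lstsq(X * s[:, None], np.log(s) * s, rcond=None)
    md = float(np.mean(beta[1:4]))
    if md <= 0:
        raise ValueError(f"nonpositive mean diffusivity estimate ({md:.4g})")
    return float(np.sqrt(2.0 * md * scheme.tau))


@dataclass(frozen=True)
class MAPFit:
    """Fitted MAP-MRI coefficients and fit diagnostics."""

    coefficients: np.ndarray
    basis: MAPBasisSpec
    mode: str
    tau: float
    lambda_reg: float = 0.0
    residual_norm: float = 0.0
    scale: float = 1.0  # mean b=0 signal the data were normalized by
    gcv_lambda_rel: float | None = None

    @property
    def n_coeff(self) -> int:
        return len(self.coefficients)

    def powder_average(self, b_query) -> np.ndarray:
        """Isotropic part of the fitted signal at the given b-values."""
        return map_powder_average(self, b_query)

    def summary(self) -> str:
        """Plain-text summary of the fit."""
        lines = [
            "MAP-MRI fit",
            "=" * 46,
            f"{'mode':<22}{self.mode:>24}",
            f"{'n_max':<22}{self.basis.n_max:>24}",
            f"{'coefficients':<22}{self.n_coeff:>24}",
            f"{'u0 (um)':<22}{self.basis.u0:>24.4f}",
            f"{'lambda':<22}{self.lambda_reg:>24.4g}",
            f"{'residual norm':<22}{self.residual_norm:>24.4g}",
            f"{'b=0 scale':<22}{self.scale:>24.4f}",
            "=" * 46,
            "leading isotropic coefficients c_j00:",
        ]
        iso = [(j, c) for c, (j, l, m) in
               zip(self.coefficients, self.basis.index_list) if l == 0]
        for j, c in sorted(iso):
            lines.append(f"  j={j}: {c:+.6f}")
        return "\n".join(lines)


def default_constraint_grid(spec: MAPBasisSpec):
    """Displacement-space grid for the positivity constraints: radii
    ``(0.02, 0.04, ..., 1) * 5 u0`` crossed with the 43-pair Lebedev set."""
    radii = np.arange(1, 51) / 50.0 * 5.0 * spec.u0
    dirs = lebedev_rule(43).directions
    r = np.repeat(radii, len(dirs))
    d = np.tile(dirs, (len(radii), 1))
    return r, d


def _fit_constrained(A: np.ndarray, s: np.ndarray, K: np.ndarray,
                     margin_rel: float = 1e-7) -> np.ndarray:
    """min ||Ac - s||^2 subject to K c >= 0, solved in the dual.

    With Q = 2 A^T A positive definite, the Lagrange dual of the QP is a
    bound-constrained QP in the multipliers mu >= 0,

        min_mu 1/2 mu^T (K Q^-1 K^T) mu + mu^T K Q^-1 p,   p = 2 A^T s,

    solved by L-BFGS-B; the primal solution is c = Q^-1 (p + K^T mu).
    A small positive margin (relative to the constraint scale) keeps the
    recovered primal strictly feasible despite the finite duality gap.
    """
    Kn = K / np.linalg.norm(K, axis=1, keepdims=True)
    Q = 2.0 * (A.T @ A)
    p = 2.0 * (A.T @ s)
    Qinv_p = np.linalg.solve(Q, p)
    c_ls = Qinv_p
    viol0 = Kn @ c_ls
    scale = np.abs(viol0).max()
    if viol0.min() >= -1e-14 * scale:
        return c_ls  # unconstrained optimum already feasible
    margin = margin_rel * scale
    # working-set strategy: optimize the dual only over constraints that
    # are (or become) violated, growing the set until the primal is
    # feasible on the whole grid
    active = np.flatnonzero(viol0 < margin).tolist()
    mu_act = np.zeros(len(active))
    c = c_ls
    for _ in range(40):
        Ka = Kn[active]
        Z = np.linalg.solve(Q, Ka.T)  # (p, n_active)
        G = Ka @ Z
        h = Ka @ Qinv_p - margin

        def dual(mu, G=G, h=h):
            Gmu = G @ mu
            return float(0.5 * mu @ Gmu + mu @ h), Gmu + h

        res = minimize(dual, mu_act, jac=True, method="L-BFGS-B",
                       bounds=[(0.0, None)] * len(active),
                       options={"maxiter": 20000, "maxfun": 50000,
                                "ftol": 1e-18, "gtol": 1e-14})
        mu = res.x
        c = Qinv_p + Z @ mu
        viol = Kn @ c
        new = np.flatnonzero(viol < 0.0)
        new = [i for i in new if i not in set(active)]
        if not new:
            break
        active.extend(new)
        mu_act = np.concatenate([mu, np.zeros(len(new))])
    return c


class MapMriModel:
    """MAP-MRI model of a 3D diffusion-signal sampling.

    Parameters
    ----------
    signals
        Measured/simulated signal values (``SignalArray`` or array
        aligned with the scheme samples).
    scheme
        The gradient scheme the signals were sampled on.
    n_max
        Even basis truncation order (6 or 8 are typical).
    u0
        Basis scale in um; estimated from the low-b data via
        :func:`estimate_u0` when omitted.

    Examples
    --------
    >>> model = MapMriModel(signal_array, scheme, n_max=8)
    >>> res = model.fit(mode="laplacian")
    >>> res.powder_average([1.5, 3.0])
    """

    def __init__(self, signals, scheme: GradientScheme, n_max: int = 8,
                 u0: float | None = None):
        values = signals.values if isinstance(signals, SignalArray) else np.asarray(signals, dtype=float)
        if values.shape[0] != scheme.n_samples:
            raise ValueError("signal length does not match scheme")
        self.scheme = scheme
        self.scale = float(np.mean(values[scheme.b_values == 0])) if scheme.n_b0 > 0 else 1.0
        if self.scale <= 0:
            self.scale = 1.0
        self.values = values / self.scale
        if u0 is None:
            u0 = estimate_u0(scheme, self.values)
        self.spec = MAPBasisSpec(n_max=n_max, u0=float(u0))
        self._A = map_basis_matrix(scheme, self.spec)

    @property
    def design(self) -> np.ndarray:
        return self._A

    def fit(self, mode: str = "ls", lambda_reg: float | None = None,
            constraint_grid=None) -> "MAPFit":
        """Fit the coefficients.

        ``ls``: pseudoinverse least squares (requires at least as many
        samples as coefficients).  ``constrained``: least squares under
        propagator nonnegativity on a displacement-space grid.
        ``laplacian``: penalized least squares
        ``min ||Ac - s||^2 + lambda c^T R c`` with the analytic
        Laplacian-energy Gram matrix R; ``lambda_reg`` is chosen by
        generalized cross-validation over a logarithmic grid (relative
        to ``mean diag(A^T A) / mean diag(R)``) when not supplied.
        """
        A, s, spec = self._A, self.values, self.spec
        n, p = A.shape
        gcv_rel = None
        if mode == "ls":
            if n < p:
                raise ValueError(f"need >= {p} samples for an unregularized fit, got {n}")
            c = np.linalg.pinv(A, rcond=1e-10) @ s
            lam = 0.0
        elif mode == "laplacian":
            R = laplacian_matrix(spec)
            unit = float(np.mean(np.diag(A.T @ A)) / np.mean(np.diag(R)))
            if lambda_reg is None:
                lam_rel = _gcv_select(A, s, R, unit)
                gcv_rel = lam_rel
                lam = lam_rel * unit
            else:
                if lambda_reg < 0:
                    raise ValueError("lambda_reg must be >= 0")
                lam = float(lambda_reg)
            c = np.linalg.solve(A.T @ A + lam * R, A.T @ s)
        elif mode == "constrained":
            if constraint_grid is None:
                constraint_grid = default_constraint_grid(spec)
            r, dirs = constraint_grid
            K = propagator_basis_matrix(np.asarray(r, dtype=float), dirs, spec)
            c = _fit_constrained(A, s, K)
            lam = 0.0
        else:
            raise ValueError(f"unknown fit mode {mode!r}")
        resid = float(np.linalg.norm(A @ c - s))
        return MAPFit(c, spec, mode, self.scheme.tau, lam, resid, self.scale,
                      gcv_rel)


def _gcv_select(A: np.ndarray, s: np.ndarray, R: np.ndarray, unit: float) -> float:
    """Generalized cross-validation over the relative lambda grid."""
    n = len(s)
    AtA, Ats = A.T @ A, A.T @ s
    best, best_rel = np.inf, _LAMBDA_GRID[0]
    for rel in _LAMBDA_GRID:
        M = AtA + rel * unit * R
        try:
            X = np.linalg.solve(M, np.hstack([Ats[:, None], A.T]))
        except np.linalg.LinAlgError:
            continue
        c = X[:, 0]
        H_diag_sum = float(np.sum(A * X[:, 1:].T))
        resid = float(np.sum((A @ c - s) ** 2))
        denom = max(n - H_diag_sum, 1e-9)
        score = n * resid / denom**2
        if score < best:
            best, best_rel = score, rel
    return float(best_rel)


def map_powder_average(fit: MAPFit, b_query, tau: float | None = None) -> np.ndarray:
    """Isotropic part of the fitted signal at arbitrary b-values.

    ``S_bar(b) = sum_N c_{(1+N/2)00} Xi_{(1+N/2)00}(u0, q(b))`` - the
    l = 0 terms of the expansion; works off-shell, enabling
    interpolation between acquired b-values.
    """
    tau = fit.tau if tau is None else tau
    b = np.atleast_1d(np.asarray(b_query, dtype=float))
    if np.any(b < 0):
        raise ValueError("b must be >= 0")
    q = b_to_q(b, tau)
    s = 2.0 * np.pi**2 * fit.basis.u0**2 * q**2
    out = np.zeros_like(b)
    for c, (j, l, m) in zip(fit.coefficients, fit.basis.index_list):
        if l == 0:
            # Xi_j00 = radial * Y_0^0 = radial / sqrt(4 pi)
            out += c * _radial_xi(j, 0, s) / _SQRT4PI
    return out


def fit_map(scheme: GradientScheme, signals, spec: MAPBasisSpec | None = None,
            mode: str = "ls", lambda_reg: float | None = None,
            constraint_grid=None, n_max: int = 8) -> MAPFit:
    """Functional front-end to :class:`MapMriModel`."""
    u0 = spec.u0 if spec is not None else None
    if spec is not None:
        n_max = spec.n_max
    model = MapMriModel(signals, scheme, n_max=n_max, u0=u0)
    return model.fit(mode=mode, lambda_reg=lambda_reg, constraint_grid=constraint_grid)
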