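"""Gradient sampling schemes: Lebedev quadrature sets, electrostatic
repulsion direction sets, shelled and non-shelled multi-b schemes.

Units follow the in-memory convention of the package: b-values in
ms/um^2, diffusion time ``Delta`` and gradient duration ``delta`` in ms.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from ._sph import real_sh_basis

__all__ = [
    "QuadratureRule",
    "GradientScheme",
    "DirectionSet",
    "lebedev_rule",
    "repulsion_directions",
    "build_scheme",
    "perturb_b",
]

# Default acquisition parameters of the simulated multi-shell protocol.
DEFAULT_B_SHELLS = (1.5, 3.0, 4.5, 6.0, 7.5, 9.0, 10.5, 12.0)
DEFAULT_DELTA_BIG = 43.1  # ms
DEFAULT_DELTA_SMALL = 10.6  # ms


@dataclass(frozen=True)
class QuadratureRule:
    """Spherical quadrature nodes restricted to one antipodal representative
    per +/- pair, with pair weights folded together and normalized to 1.

    ``degree`` is the polynomial exactness of the underlying full-sphere
    rule: ``4*pi * sum_i w_i f(u_i)`` integrates every (antipodally
    symmetric) spherical polynomial of degree <= ``degree`` exactly.
    """

    directions: np.ndarray
    weights: np.ndarray
    degree: int

    def __post_init__(self):
        d = np.atleast_2d(np.asarray(self.directions, dtype=float))
        w = np.asarray(self.weights, dtype=float)
        norms = np.linalg.norm(d, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-12):
            raise ValueError("quadrature directions must be unit vectors")
        if np.any(w < 0):
            raise ValueError("quadrature weights must be nonnegative")
        object.__setattr__(self, "directions", d)
        object.__setattr__(self, "weights", w / w.sum())

    @property
    def n_pairs(self) -> int:
        return len(self.weights)

    def integrate(self, values: np.ndarray) -> float:
        """Normalized quadrature: mean of ``values`` over the sphere."""
        return float(self.weights @ np.asarray(values, dtype=float))


@dataclass(frozen=True)
class DirectionSet:
    """Electrostatic-repulsion-optimized unit vectors with final energy."""

    directions: np.ndarray
    energy: float

    def __post_init__(self):
        d = np.atleast_2d(np.asarray(self.directions, dtype=float))
        if not np.allclose(np.linalg.norm(d, axis=1), 1.0, atol=1e-12):
            raise ValueError("directions must be unit vectors")
        # no near-duplicate (parallel or antipodal) pairs
        dots = np.abs(d @ d.T)
        np.fill_diagonal(dots, 0.0)
        if dots.max() > np.cos(1e-6):
            raise ValueError("duplicate (anti)parallel directions in set")
        object.__setattr__(self, "directions", d)


@dataclass(frozen=True)
class GradientScheme:
    """A diffusion gradient table: unit directions, b-values and timing.

    ``shell_ids`` labels samples of equal b (None for non-shelled data);
    b=0 samples carry shell id -1 when shell ids are present.
    """

    directions: np.ndarray
    b_values: np.ndarray
    shell_ids: np.ndarray | None = None
    Delta: float = DEFAULT_DELTA_BIG
    delta: float = DEFAULT_DELTA_SMALL

    def __post_init__(self):
        d = np.atleast_2d(np.asarray(self.directions, dtype=float))
        b = np.asarray(self.b_values, dtype=float)
        if d.shape[0] != b.shape[0]:
            raise ValueError("directions and b_values length mismatch")
        if np.any(b < 0):
            raise ValueError("b-values must be >= 0")
        if not np.allclose(np.linalg.norm(d, axis=1), 1.0, atol=1e-12):
            raise ValueError("directions must be unit vectors")
        if not (self.Delta > self.delta / 3.0 > 0):
            raise ValueError("timing must satisfy Delta > delta/3 > 0")
        sid = self.shell_ids
        if sid is not None:
            sid = np.asarray(sid, dtype=int)
            if sid.shape[0] != b.shape[0]:
                raise ValueError("shell_ids length mismatch")
            for s in np.unique(sid[sid >= 0]):
                bs = b[sid == s]
                if not np.allclose(bs, bs[0], rtol=1e-12, atol=1e-12):
                    raise ValueError(f"shell {s} has unequal b-values")
        object.__setattr__(self, "directions", d)
        object.__setattr__(self, "b_values", b)
        object.__setattr__(self, "shell_ids", sid)

    @property
    def n_samples(self) -> int:
        return len(self.b_values)

    @property
    def n_b0(self) -> int:
        return int(np.sum(self.b_values == 0))

    @property
    def n_dwi(self) -> int:
        return int(np.sum(self.b_values > 0))

    @property
    def tau(self) -> float:
        """Effective diffusion time Delta - delta/3 in ms."""
        return self.Delta - self.delta / 3.0

    @property
    def is_shelled(self) -> bool:
        return self.shell_ids is not None

    def shells(self):
        """Yield (shell_id, b, sample index array) for nonzero-b shells."""
        if self.shell_ids is None:
            raise ValueError("scheme is not shelled")
        for s in sorted(np.unique(self.shell_ids[self.shell_ids >= 0])):
            idx = np.flatnonzero(self.shell_ids == s)
            yield int(s), float(self.b_values[idx[0]]), idx


# ---------------------------------------------------------------------------
# Lebedev quadrature
# ---------------------------------------------------------------------------
# Octahedrally symmetric grids are assembled from symmetry orbits:
#   a1: the 6 vertices (+-1, 0, 0)...
#   a3: the 8 cube diagonals (+-1, +-1, +-1)/sqrt(3)
#   b(a): 24 points, permutations of (a, a, m) with m = sqrt(1 - 2 a^2)
#   c(p): 24 points, permutations of (p, q, 0) with q = sqrt(1 - p^2)
# Orbit parameters and weights are refined at build time by Newton
# iteration on the defining exactness equations, starting from the
# tabulated values, so every constructed rule meets its design degree to
# near machine precision.

def _orbit_a1() -> np.ndarray:
    e = np.eye(3)
    return np.vstack([e, -e])


def _orbit_a3() -> np.ndarray:
    signs = np.array(np.meshgrid([1, -1], [1, -1], [1, -1])).T.reshape(-1, 3)
    return signs / np.sqrt(3.0)


def _orbit_b(a: float) -> np.ndarray:
    m = np.sqrt(max(1.0 - 2.0 * a * a, 0.0))
    base = [(a, a, m), (a, m, a), (m, a, a)]
    pts = []
    for v in base:
        for sx in (1, -1):
            for sy in (1, -1):
                for sz in (1, -1):
                    pts.append((sx * v[0], sy * v[1], sz * v[2]))
    return np.array(pts)


def _orbit_c(p: float) -> np.ndarray:
    q = np.sqrt(max(1.0 - p * p, 0.0))
    base = [(p, q, 0.0), (q, p, 0.0), (p, 0.0, q), (q, 0.0, p), (0.0, p, q), (0.0, q, p)]
    pts = []
    for v in base:
        for sx in (1, -1):
            for sy in (1, -1):
                x, y, z = sx * v[0], sy * v[1], v[2]
                for sz in (1, -1):
                    pts.append((x, y, sz * z))
    arr = np.array(pts)
    # orbit points with a zero coordinate are duplicated by the sign loop
    return np.unique(np.round(arr, 15), axis=0)


def _assemble(params: np.ndarray, layout: list[tuple[str, int]]):
    """Build (points, weights) from a flat parameter vector.

    ``layout`` lists orbit types in order; parameter vector holds one
    weight per orbit followed by one geometry parameter per b/c orbit.
    """
    n_orbits = len(layout)
    weights = params[:n_orbits]
    geom = list(params[n_orbits:])
    pts_list, w_list = [], []
    for (kind, _), w in zip(layout, weights):
        if kind == "a1":
            pts = _orbit_a1()
        elif kind == "a3":
            pts = _orbit_a3()
        elif kind == "b":
            pts = _orbit_b(geom.pop(0))
        elif kind == "c":
            pts = _orbit_c(geom.pop(0))
        else:  # pragma: no cover
            raise ValueError(kind)
        pts_list.append(pts)
        w_list.append(np.full(len(pts), w))
    return np.vstack(pts_list), np.concatenate(w_list)


def _exactness_residuals(params: np.ndarray, layout, degree: int) -> np.ndarray:
    pts, w = _assemble(params, layout)
    Y, idx = real_sh_basis(pts, degree if degree % 2 == 0 else degree - 1)
    res = w @ Y  # should be [1/sqrt(4pi) * sum(w), 0, 0, ...]
    res[0] -= np.sum(w) / np.sqrt(4.0 * np.pi)
    return np.concatenate([[np.sum(w) - 1.0], res[1:]])


# (layout, initial parameters, degree) for each supported grid.
_LEBEDEV_SPECS = {
    3: (  # 6-point octahedron, degree 3: exact by symmetry
        [("a1", 6)],
        np.array([1.0 / 6.0]),
        3,
    ),
    19: (  # 38-point grid, degree 9
        [("a1", 6), ("a3", 8), ("c", 24)],
        np.array([1.0 / 105.0, 9.0 / 280.0, 1.0 / 35.0, 0.4597008433809831]),
        9,
    ),
    43: (  # 86-point grid, degree 15
        [("a1", 6), ("a3", 8), ("b", 24), ("b", 24), ("c", 24)],
        np.array(
            [
                0.0115440115440678,
                0.0119439090858562,
                0.0111105557106034,
                0.0118765012945371,
                0.0118123037469044,
                0.3696028464541502,
                0.6943540066026664,
                0.3742902284035836,
            ]
        ),
        15,
    ),
}


@functools.lru_cache(maxsize=None)
def _full_lebedev(n_pairs: int):
    layout, x0, degree = _LEBEDEV_SPECS[n_pairs]
    if len(x0) > 1:
        sol = least_squares(
            _exactness_residuals, x0, args=(layout, degree), xtol=3e-16, ftol=3e-16, gtol=1e-15
        )
        x0 = sol.x
    pts, w = _assemble(x0, layout)
    return pts, w, degree


def _antipodal_half(points: np.ndarray, weights: np.ndarray):
    """Pick one representative per +/- pair; fold the pair weights."""
    keep, w_out = [], []
    used = np.zeros(len(points), dtype=bool)
    for i, p in enumerate(points):
        if used[i]:
            continue
        used[i] = True
        j = np.argmax(-(points @ p))
        if np.allclose(points[j], -p, atol=1e-12) and not used[j]:
            used[j] = True
            w_out.append(weights[i] + weights[j])
        else:  # pragma: no cover - tabulated grids are antipodal
            w_out.append(weights[i])
        # canonical hemisphere representative
        rep = p if (p[2] > 1e-12 or (abs(p[2]) <= 1e-12 and (p[1] > 1e-12 or (abs(p[1]) <= 1e-12 and p[0] > 0)))) else -p
        keep.append(rep)
    return np.array(keep), np.array(w_out)


def lebedev_rule(n_pairs: int) -> QuadratureRule:
    """Lebedev quadrature with ``n_pairs`` antipodal-pair representatives.

    Supported sizes: 3 (6-point, degree 3), 19 (38-point, degree 9) and
    43 (86-point, degree 15).  Pair weights are folded and normalized to
    sum to 1, which is valid for antipodally symmetric integrands such
    as SDE magnitude signals.
    """
    if n_pairs not in _LEBEDEV_SPECS:
        raise ValueError(
            f"unsupported Lebedev size {n_pairs}; supported n_pairs: "
            f"{sorted(_LEBEDEV_SPECS)}"
        )
    pts, w, degree = _full_lebedev(n_pairs)
    half_pts, half_w = _antipodal_half(pts, w)
    assert len(half_pts) == n_pairs
    return QuadratureRule(half_pts, half_w, degree)


# ---------------------------------------------------------------------------
# Electrostatic repulsion
# ---------------------------------------------------------------------------

def _pair_energy_grad(u: np.ndarray, radii: np.ndarray | None = None):
    """Antipodal Coulomb energy and gradient for unit vectors ``u``.

    With ``radii`` given, charges sit at ``r_i * u_i`` (3D q-space
    layout); otherwise on the unit sphere.  Each configuration also
    interacts with the mirrored set ``-r_j * u_j``.
    """
    x = u if radii is None else u * radii[:, None]
    diff = x[:, None, :] - x[None, :, :]
    summ = x[:, None, :] + x[None, :, :]
    dd = np.linalg.norm(diff, axis=2)
    ds = np.linalg.norm(summ, axis=2)
    n = len(x)
    iu = np.triu_indices(n, k=1)
    energy = np.sum(1.0 / dd[iu]) + np.sum(1.0 / ds[iu])
    np.fill_diagonal(dd, np.inf)
    np.fill_diagonal(ds, np.inf)
    g = -np.sum(diff / dd[:, :, None] ** 3, axis=1) - np.sum(summ / ds[:, :, None] ** 3, axis=1)
    if radii is not None:
        g = g * radii[:, None]
    return energy, g


def _project_tangent(u: np.ndarray, g: np.ndarray) -> np.ndarray:
    return g - (np.sum(g * u, axis=1, keepdims=True)) * u


def _repulsion_optimize(u0: np.ndarray, radii: np.ndarray | None = None,
                        max_iter: int = 2000, tol: float = 1e-10):
    """Projected gradient descent with step halving on the sphere."""
    u = u0 / np.linalg.norm(u0, axis=1, keepdims=True)
    energy, g = _pair_energy_grad(u, radii)
    step = 0.1 / len(u)
    for _ in range(max_iter):
        t = _project_tangent(u, g)
        moved = False
        while step > 1e-16:
            cand = u - step * t
            cand /= np.linalg.norm(cand, axis=1, keepdims=True)
            e_new, g_new = _pair_energy_grad(cand, radii)
            if e_new < energy:
                rel = (energy - e_new) / abs(energy)
                u, energy, g = cand, e_new, g_new
                step *= 1.5
                moved = True
                if rel < tol:
                    return u, energy
                break
            step *= 0.5
        if not moved:
            break
    return u, energy


@functools.lru_cache(maxsize=32)
def _cached_repulsion(n: int, seed: int):
    rng = np.random.default_rng(seed)
    u0 = rng.standard_normal((n, 3))
    u, energy = _repulsion_optimize(u0)
    return u, energy


def repulsion_directions(n: int, seed: int = 0) -> DirectionSet:
    """Locally minimize the antipodal Coulomb energy of ``n`` unit vectors.

    The cost is ``sum_{i<j} 1/|u_i - u_j| + 1/|u_i + u_j|``, the classic
    electrostatic-repulsion criterion for uniform gradient sampling with
    antipodal charge pairs.  Deterministic for a fixed seed.
    """
    if n < 2:
        raise ValueError("need at least 2 directions")
    u, energy = _cached_repulsion(int(n), int(seed))
    return DirectionSet(u.copy(), float(energy))


# ---------------------------------------------------------------------------
# Scheme builders
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=16)
def _cached_nonshelled(n: int, b_max: float, seed: int):
    """3D q-space layout: b uniform in (0, b_max]; angular positions from
    antipodal repulsion of charges at radius q ~ sqrt(b)."""
    b = b_max * np.arange(1, n + 1) / n
    radii = np.sqrt(b / b_max)
    rng = np.random.default_rng(seed)
    u0 = rng.standard_normal((n, 3))
    directions, _ = _repulsion_optimize(u0, radii=radii, max_iter=600)
    return directions, b


_SHELLED_KINDS = {"shelled_uniform", "shelled_lebedev", "shelled_random"}
_NONSHELLED_KINDS = {"nonshelled", "nonshelled_random"}


def _stack_scheme(directions: np.ndarray, b_shells, n_b0: int,
                  Delta: float, delta: float) -> GradientScheme:
    n_dir = len(directions)
    dirs = [directions[: max(n_b0, 0)] if n_b0 <= n_dir else
            np.vstack([directions] * -(-n_b0 // n_dir))[:n_b0]]
    bs = [np.zeros(n_b0)]
    sids = [np.full(n_b0, -1)]
    for s, b in enumerate(b_shells):
        dirs.append(directions)
        bs.append(np.full(n_dir, b))
        sids.append(np.full(n_dir, s))
    return GradientScheme(
        np.vstack(dirs), np.concatenate(bs), np.concatenate(sids), Delta, delta
    )


def build_scheme(
    kind: str,
    n: int,
    b_shells=DEFAULT_B_SHELLS,
    b_max: float | None = None,
    seed: int = 0,
    n_b0: int | None = None,
    Delta: float = DEFAULT_DELTA_BIG,
    delta: float = DEFAULT_DELTA_SMALL,
) -> GradientScheme:
    """Build one of the study's gradient sampling schemes.

    Parameters
    ----------
    kind
        ``shelled_uniform`` - one repulsion-optimized direction set
        replicated over every b-shell; ``shelled_lebedev`` - Lebedev
        nodes replicated over shells; ``shelled_random`` - ``n``
        directions drawn without replacement from a 102-point repulsion
        set, replicated over shells; ``nonshelled`` - ``n`` samples
        spread over the q-space ball up to ``b_max`` by 3D antipodal
        repulsion with b-values uniform in (0, b_max]; and
        ``nonshelled_random`` - uniformly random directions and b-values.
    n
        Directions per shell (shelled kinds) or total samples
        (non-shelled kinds).
    n_b0
        Number of b=0 samples; defaults to the per-shell direction count
        (shelled) or ``round(n / len(b_shells))`` (non-shelled).
    """
    if kind in _SHELLED_KINDS:
        b_shells = tuple(float(b) for b in b_shells)
        if len(b_shells) == 0:
            raise ValueError("shelled schemes need at least one b shell")
        if kind == "shelled_uniform":
            directions = repulsion_directions(n, seed).directions
        elif kind == "shelled_lebedev":
            directions = lebedev_rule(n).directions
        else:  # shelled_random
            pool = repulsion_directions(102, seed=12345).directions
            if n > len(pool):
                raise ValueError("cannot draw more than 102 random directions")
            rng = np.random.default_rng(seed)
            directions = pool[rng.choice(len(pool), size=n, replace=False)]
        if n_b0 is None:
            n_b0 = n
        return _stack_scheme(directions, b_shells, n_b0, Delta, delta)

    if kind in _NONSHELLED_KINDS:
        if b_max is None or b_max <= 0:
            raise ValueError("non-shelled schemes need b_max > 0")
        if n_b0 is None:
            n_b0 = int(round(n / max(len(b_shells), 1)))
        rng = np.random.default_rng(seed)
        if kind == "nonshelled_random":
            directions = rng.standard_normal((n, 3))
            directions /= np.linalg.norm(directions, axis=1, keepdims=True)
            b = rng.uniform(0.0, b_max, size=n)
            b = np.maximum(b, b_max * 1e-6)
        else:
            directions, b = _cached_nonshelled(int(n), float(b_max), int(seed))
        b0_dirs = directions[:n_b0] if n_b0 <= n else directions[
            np.arange(n_b0) % n
        ]
        all_dirs = np.vstack([b0_dirs, directions])
        all_b = np.concatenate([np.zeros(n_b0), b])
        return GradientScheme(all_dirs, all_b, None, Delta, delta)

    raise ValueError(
        f"unknown scheme kind {kind!r}; expected one of "
        f"{sorted(_SHELLED_KINDS | _NONSHELLED_KINDS)}"
    )


def perturb_b(scheme: GradientScheme, fraction: float, seed: int = 0) -> GradientScheme:
    """Multiply each nonzero b by (1 + delta), delta ~ U(-fraction, fraction).

    Emulates gradient-strength miscalibration: nominally shelled data
    end up slightly off their shells, so ``shell_ids`` are cleared.
    Directions are unchanged.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    if fraction == 0.0:
        return scheme
    rng = np.random.default_rng(seed)
    b = scheme.b_values.copy()
    nz = b > 0
    b[nz] = b[nz] * (1.0 + rng.uniform(-fraction, fraction, size=nz.sum()))
    return GradientScheme(scheme.directions, b, None, scheme.Delta, scheme.delta)
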