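"""File I/O: FSL-dialect gradient tables, CSV serialization of schemes,
signals and powder averages, the synthetic fixture tree and run manifests.

Unit conventions at the file boundary: FSL ``bval`` files carry b in
s/mm^2 and are converted to the package's internal ms/um^2 (factor
1/1000); CSV files written by this package carry internal units.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .sampling import DEFAULT_B_SHELLS, GradientScheme, build_scheme
from .shell import PowderAverage
from .simulate import (
    KAPPA_LEVELS,
    SIGMA_LEVELS,
    SignalArray,
    TissueModel,
    add_noise,
    simulate_signal,
)

__all__ = [
    "RunManifest",
    "read_gradient_table",
    "write_gradient_table",
    "infer_shells",
    "scheme_to_csv",
    "scheme_from_csv",
    "signals_to_csv",
    "signals_from_csv",
    "powder_average_to_csv",
    "generate_fixtures",
]

logger = logging.getLogger("powderavg")

_BVAL_PER_INTERNAL = 1000.0  # s/mm^2 per ms/um^2


@dataclass(frozen=True)
class RunManifest:
    """Provenance record written next to generated outputs."""

    version: str
    config_hash: str
    master_seed: int
    timestamp: str
    outputs: tuple

    @classmethod
    def create(cls, config_bytes: bytes, master_seed: int, outputs) -> "RunManifest":
        return cls(
            version=__version__,
            config_hash=hashlib.sha256(config_bytes).hexdigest(),
            master_seed=int(master_seed),
            timestamp=datetime.now(timezone.utc).isoformat(),
            outputs=tuple(str(p) for p in outputs),
        )

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str))


def _read_numeric_table(path) -> np.ndarray:
    """Whitespace-separated numeric table with line-aware error messages."""
    rows = []
    ncol = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            toks = line.split()
            if not toks:
                continue
            try:
                vals = [float(t) for t in toks]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric token ({exc})") from None
            if ncol is None:
                ncol = len(vals)
            elif len(vals) != ncol:
                raise ValueError(
                    f"{path}:{lineno}: expected {ncol} columns, got {len(vals)}"
                )
            rows.append(vals)
    if not rows:
        raise ValueError(f"{path}: empty gradient table")
    return np.array(rows)


def infer_shells(b_values: np.ndarray, rtol: float = 0.05) -> np.ndarray | None:
    """Group b-values into shells by relative clustering.

    Consecutive sorted unique b within ``rtol`` of the running cluster
    mean share a shell.  Returns shell ids (b=0 samples get -1), or None
    when the nonzero b-values do not form clean shells (any cluster
    whose internal spread exceeds ``rtol``).
    """
    b = np.asarray(b_values, dtype=float)
    nz = np.sort(np.unique(b[b > 0]))
    if nz.size == 0:
        return np.full(len(b), -1)
    clusters: list[list[float]] = [[nz[0]]]
    for v in nz[1:]:
        if v <= np.mean(clusters[-1]) * (1 + rtol):
            clusters[-1].append(v)
        else:
            clusters.append([v])
    # a scheme is only "shelled" if clusters are tight and well-separated
    for c in clusters:
        if (max(c) - min(c)) > rtol * np.mean(c):
            return None
    if len(clusters) > 0.5 * nz.size and nz.size > len(clusters):
        pass
    ids = np.full(len(b), -1)
    for s, c in enumerate(clusters):
        lo, hi = min(c), max(c)
        ids[(b >= lo) & (b <= hi)] = s
    # force within-shell b equality (GradientScheme invariant) by mapping
    # each shell to its mean b
    return ids


def read_gradient_table(bvec_path, bval_path,
                        Delta: float = 43.1, delta: float = 10.6) -> GradientScheme:
    """Read an FSL-dialect bvec/bval pair into a GradientScheme.

    ``bvec``: 3 rows x N columns of direction components; ``bval``: one
    row of N b-values in s/mm^2 (converted to ms/um^2).  Non-unit
    direction columns at b > 0 are normalized with a warning; zero
    vectors are allowed only at b = 0.  Shell ids are inferred by
    clustering b within 5% relative tolerance.
    """
    bvec = _read_numeric_table(bvec_path)
    bval = _read_numeric_table(bval_path)
    if bvec.shape[0] != 3:
        if bvec.shape[1] == 3:  # column-major variant
            bvec = bvec.T
        else:
            raise ValueError(f"{bvec_path}: expected 3 rows of components")
    b = bval.ravel() / _BVAL_PER_INTERNAL
    if bvec.shape[1] != b.shape[0]:
        raise ValueError(
            f"bvec has {bvec.shape[1]} columns but bval has {b.shape[0]} entries"
        )
    d = bvec.T.astype(float)
    norms = np.linalg.norm(d, axis=1)
    zero = norms < 1e-12
    if np.any(zero & (b > 0)):
        i = int(np.flatnonzero(zero & (b > 0))[0])
        raise ValueError(f"sample {i}: zero gradient vector at nonzero b")
    if np.any(~zero & (np.abs(norms - 1.0) > 1e-6)):
        logger.warning("non-unit bvec columns normalized on read")
    d[zero] = [0.0, 0.0, 1.0]  # placeholder axis for b=0 samples
    d[~zero] /= norms[~zero, None]
    sid = infer_shells(b)
    if sid is not None:
        # snap within-shell b to the shell mean so the invariant holds
        b = b.copy()
        for s in np.unique(sid[sid >= 0]):
            m = sid == s
            b[m] = float(np.mean(b[m]))
    return GradientScheme(d, b, sid, Delta, delta)


def write_gradient_table(scheme: GradientScheme, bvec_path, bval_path) -> None:
    """Write FSL bvec/bval files (b back in s/mm^2, 9 significant digits)."""
    fmt = "%.9g"
    with open(bvec_path, "w") as fh:
        for row in scheme.directions.T:
            fh.write(" ".join(fmt % v for v in row) + "\n")
    with open(bval_path, "w") as fh:
        fh.write(" ".join(fmt % (b * _BVAL_PER_INTERNAL) for b in scheme.b_values) + "\n")


def scheme_to_csv(scheme: GradientScheme, path) -> None:
    df = pd.DataFrame({
        "ux": scheme.directions[:, 0],
        "uy": scheme.directions[:, 1],
        "uz": scheme.directions[:, 2],
        "b": scheme.b_values,
        "shell_id": scheme.shell_ids if scheme.shell_ids is not None
        else np.full(scheme.n_samples, -2),
    })
    df.to_csv(path, index=False, float_format="%.12g")


def scheme_from_csv(path, Delta: float = 43.1, delta: float = 10.6) -> GradientScheme:
    df = pd.read_csv(path)
    d = df[["ux", "uy", "uz"]].to_numpy(dtype=float)
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    sid = df["shell_id"].to_numpy(dtype=int)
    shell_ids = None if np.all(sid == -2) else sid
    return GradientScheme(d, df["b"].to_numpy(dtype=float), shell_ids, Delta, delta)


def signals_to_csv(signals: SignalArray, path) -> None:
    sch = signals.scheme
    df = pd.DataFrame({
        "ux": sch.directions[:, 0],
        "uy": sch.directions[:, 1],
        "uz": sch.directions[:, 2],
        "b": sch.b_values,
        "shell_id": sch.shell_ids if sch.shell_ids is not None
        else np.full(sch.n_samples, -2),
        "S": signals.values,
    })
    df.to_csv(path, index=False, float_format="%.12g")


def signals_from_csv(path, Delta: float = 43.1, delta: float = 10.6) -> SignalArray:
    df = pd.read_csv(path)
    d = df[["ux", "uy", "uz"]].to_numpy(dtype=float)
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    sid = df["shell_id"].to_numpy(dtype=int)
    shell_ids = None if np.all(sid == -2) else sid
    scheme = GradientScheme(d, df["b"].to_numpy(dtype=float), shell_ids, Delta, delta)
    return SignalArray(df["S"].to_numpy(dtype=float), scheme)


def powder_average_to_csv(pa: PowderAverage, path) -> None:
    pd.DataFrame({"b": pa.b_values, "s_bar": pa.s_bar,
                  "method": pa.method_tag}).to_csv(path, index=False,
                                                   float_format="%.12g")


# ---------------------------------------------------------------------------
# fixture generation
# ---------------------------------------------------------------------------

# (name, kind, n, needs b_max) - the study's point sets
_FIXTURE_SCHEMES = [
    ("shelled_488_61x8", "shelled_uniform", 61),
    ("shelled_344_43x8_lebedev", "shelled_lebedev", 43),
    ("shelled_152_19x8_lebedev", "shelled_lebedev", 19),
    ("shelled_344_43x8_random", "shelled_random", 43),
    ("nonshelled_488", "nonshelled", 488),
    ("nonshelled_344", "nonshelled", 344),
    ("nonshelled_152", "nonshelled", 152),
    ("nonshelled_344_random", "nonshelled_random", 344),
]

_FIXTURE_MODELS = [
    ("kappa1", lambda: TissueModel.single(1.0)),
    ("kappa9", lambda: TissueModel.single(9.0)),
    ("kappaInf", lambda: TissueModel.single(np.inf)),
    ("crossing90_kappa9", lambda: TissueModel.crossing(9.0, "90")),
    ("crossing45_kappa9", lambda: TissueModel.crossing(9.0, "45")),
]


def generate_fixtures(out_dir, master_seed: int = 0) -> RunManifest:
    """Materialize the study's scheme/signal grid as CSV files.

    Writes every point set (Table-of-experiments sizes 488/344/152,
    shelled and non-shelled, plus the two random 344 variants),
    noise-free signals for each dispersion level and both crossing
    configurations on each scheme, and one noisy realization per noise
    level (Gaussian and Rician) on the 43x8 Lebedev scheme.  A manifest
    with the seed and a content hash is written alongside.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs = []
    ss = np.random.SeedSequence(master_seed)
    schemes = {}
    for name, kind, n in _FIXTURE_SCHEMES:
        scheme = build_scheme(kind, n, b_shells=DEFAULT_B_SHELLS,
                              b_max=max(DEFAULT_B_SHELLS), seed=master_seed)
        schemes[name] = scheme
        p = out / f"scheme_{name}.csv"
        scheme_to_csv(scheme, p)
        outputs.append(p)
    for name, scheme in schemes.items():
        for tag, factory in _FIXTURE_MODELS:
            sig = simulate_signal(scheme, factory())
            p = out / f"signal_{name}_{tag}_noisefree.csv"
            signals_to_csv(sig, p)
            outputs.append(p)
    noisy_base = simulate_signal(schemes["shelled_344_43x8_lebedev"],
                                 TissueModel.single(9.0))
    for i, sigma in enumerate(SIGMA_LEVELS):
        for model in ("gaussian", "rician"):
            rng_seed = np.random.SeedSequence(entropy=master_seed,
                                              spawn_key=(1000 + i, hash(model) % 97))
            noisy = add_noise(noisy_base, sigma, model, seed=rng_seed)
            p = out / f"signal_shelled_344_43x8_lebedev_kappa9_{model}_sigma{sigma:g}.csv"
            signals_to_csv(noisy, p)
            outputs.append(p)
    config = json.dumps({"schemes": [s[:2] for s in _FIXTURE_SCHEMES],
                         "sigmas": SIGMA_LEVELS, "seed": master_seed}).encode()
    manifest = RunManifest.create(config, master_seed, outputs)
    manifest.write(out / "manifest.json")
    logger.info("wrote %d fixture files to %s", len(outputs), out)
    return manifest
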