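"""Stationary VAR(1) simulation.

A first-order vector autoregression

    x_t = C x_{t-1} + e_t,    e_t ~ N(0, diag(sigma^2))

is stationary iff the spectral radius of the coefficient matrix ``C`` is
below one.  This module carries three built-in coefficient matrices of
dimension 5, 7 and 10 whose transcription is checksummed against their
known eigenvalue spectra, draws diagonal residual variances uniformly on
[1, 5], and simulates reproducible series from a burned-in recursion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DimensionError, NonStationaryError

__all__ = [
    "VARProcess",
    "TimeSeries",
    "EigenReport",
    "FIXTURE_MATRICES",
    "FIXTURE_EIGENVALUES",
    "fixture_process",
    "eigen_report",
    "simulate_series",
]

# Transcribed k x k coefficient matrices, validated at import time against
# the reference eigenvalue spectra below (see _verify_fixture_spectra).
FIXTURE_MATRICES: dict[str, np.ndarray] = {
    "k5": np.array(
        [
            [0.00, -0.47, -0.11, 0.00, 0.00],
            [-0.95, 0.00, 0.00, 0.00, -0.45],
            [-0.68, 0.00, 0.00, -0.67, 0.48],
            [0.00, 0.00, 0.15, 0.00, -0.80],
            [-0.63, 0.00, 0.00, 0.00, 0.00],
        ]
    ),
    "k7": np.array(
        [
            [0.00, -0.85, -0.94, 0.16, 0.76, 0.00, -0.23],
            [0.15, 0.00, 0.00, 0.27, 0.00, 0.00, 0.00],
            [0.00, 0.00, 0.00, 0.00, -0.64, 0.39, -0.28],
            [0.00, 0.00, 0.00, 0.38, 0.00, 0.00, 0.48],
            [0.00, 0.10, 0.64, 0.00, 0.00, 0.00, 0.00],
            [-0.66, 0.44, 0.00, 0.38, 0.52, 0.00, 0.13],
            [0.00, 0.00, 0.00, 0.00, -0.65, 0.00, -0.05],
        ]
    ),
    "k10": np.array(
        [
            [0.00, -0.56, 0.00, 0.00, 0.00, 0.00, 0.29, -0.11, 0.78, 0.00],
            [0.21, 0.39, 0.00, -0.58, 0.00, 0.00, 0.00, -0.27, 0.95, 0.54],
            [0.00, 0.86, 0.00, 0.00, 0.00, 0.33, 0.53, 0.00, 0.00, 0.00],
            [0.58, 0.00, 0.00, -0.89, 0.00, 0.72, 0.00, 0.00, 0.00, 0.00],
            [-0.83, -0.71, -0.75, 0.02, 0.12, 0.00, 0.31, 0.00, 0.00, 0.00],
            [-0.13, 0.22, -0.09, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00, -0.43],
            [-0.18, 0.39, 0.88, 0.00, 0.00, -0.56, 0.00, 0.10, 0.22, 0.08],
            [0.31, 0.00, 0.00, 0.00, 0.81, 0.00, 0.00, 0.00, 0.00, 0.34],
            [0.00, 0.00, -0.57, 0.00, 0.28, 0.00, 0.00, 0.00, 0.00, -0.34],
            [-0.91, 0.00, 0.00, -0.34, 0.77, -0.32, -0.08, -0.62, 0.00, 0.00],
        ]
    ),
}

# Reference spectra used as a transcription checksum (modulus tolerance 5e-3).
FIXTURE_EIGENVALUES: dict[str, list[complex]] = {
    "k5": [-0.828, 0.643, 0.005 + 0.379j, 0.005 - 0.379j, 0.175],
    "k7": [
        -0.391 + 0.864j,
        -0.391 - 0.864j,
        0.547 + 0.290j,
        0.547 - 0.290j,
        0.140 + 0.373j,
        0.140 - 0.373j,
        -0.262,
    ],
    "k10": [
        -0.273 + 0.901j,
        -0.273 - 0.901j,
        0.624 + 0.690j,
        0.624 - 0.690j,
        -0.853 + 0.254j,
        -0.853 - 0.254j,
        -0.865,
        0.680 + 0.224j,
        0.680 - 0.224j,
        0.128,
    ],
}

#: Residual variances are drawn uniformly on this interval.
NOISE_VARIANCE_RANGE: tuple[float, float] = (1.0, 5.0)


@dataclass(frozen=True)
class VARProcess:
    """A lag-1 linear stochastic process with diagonal Gaussian noise."""

    C: np.ndarray
    noise_variances: np.ndarray
    lag: int = 1

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        v = np.asarray(self.noise_variances, dtype=float)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise DimensionError(f"coefficient matrix must be square, got {C.shape}")
        if v.shape != (C.shape[0],):
            raise DimensionError(
                f"need {C.shape[0]} noise variances, got shape {v.shape}"
            )
        if np.any(v <= 0):
            raise ConfigurationError("noise variances must be strictly positive")
        object.__setattr__(self, "C", C)
        object.__setattr__(self, "noise_variances", v)

    @property
    def k(self) -> int:
        return self.C.shape[0]

    @property
    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.C))))

    @property
    def stationary(self) -> bool:
        return self.spectral_radius < 1.0


@dataclass(frozen=True)
class TimeSeries:
    """A complete multivariate series: T rows, one column per variable."""

    values: np.ndarray
    variable_names: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise DimensionError("values must be a T x k matrix")
        if values.shape[0] < 2:
            raise DimensionError("a time series needs at least 2 time points")
        if values.shape[1] != len(self.variable_names):
            raise DimensionError("variable_names length must match column count")
        if not np.all(np.isfinite(values)):
            raise ConfigurationError("time series must not contain missing values")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "variable_names", tuple(self.variable_names))

    @property
    def T(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.variable_names))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TimeSeries":
        return cls(frame.to_numpy(dtype=float), tuple(map(str, frame.columns)))

    @classmethod
    def from_csv(cls, path) -> "TimeSeries":
        return cls.from_frame(pd.read_csv(path))


@dataclass(frozen=True)
class EigenReport:
    """Eigenvalues of a coefficient matrix, sorted by descending modulus."""

    eigenvalues: tuple[complex, ...]
    max_modulus: float
    stationary: bool


def default_names(k: int) -> tuple[str, ...]:
    return tuple(f"X{i + 1}" for i in range(k))


def eigen_report(C: np.ndarray) -> EigenReport:
    """Eigen-decompose ``C`` and flag stationarity (max modulus < 1)."""
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise DimensionError(f"expected a square matrix, got shape {C.shape}")
    ev = np.linalg.eigvals(C)
    order = np.argsort(-np.abs(ev), kind="stable")
    ev = ev[order]
    max_mod = float(np.abs(ev[0])) if ev.size else 0.0
    return EigenReport(tuple(ev), max_mod, max_mod < 1.0)


def _verify_fixture_spectra(tol: float = 5e-3) -> None:
    for name, C in FIXTURE_MATRICES.items():
        got = np.sort_complex(np.linalg.eigvals(C))
        want = np.sort_complex(np.array(FIXTURE_EIGENVALUES[name]))
        resid = float(np.max(np.abs(got - want)))
        if resid > tol:
            raise AssertionError(
                f"fixture {name} fails its eigenvalue checksum (residual {resid:.2e})"
            )


_verify_fixture_spectra()


def fixture_checksums() -> dict[str, float]:
    """Max modulus residual of each fixture against its reference spectrum."""
    out = {}
    for name, C in FIXTURE_MATRICES.items():
        got = np.sort_complex(np.linalg.eigvals(C))
        want = np.sort_complex(np.array(FIXTURE_EIGENVALUES[name]))
        out[name] = float(np.max(np.abs(got - want)))
    return out


def fixture_process(name: str, seed) -> VARProcess:
    """Build a fixture process: known coefficient matrix, fresh noise draw.

    Residual variances are independent uniforms on [1, 5] under ``seed``
    (an int or a :class:`numpy.random.Generator`).
    """
    if name not in FIXTURE_MATRICES:
        raise ConfigurationError(
            f"unknown fixture {name!r}; choose from {sorted(FIXTURE_MATRICES)}"
        )
    rng = np.random.default_rng(seed)
    C = FIXTURE_MATRICES[name]
    lo, hi = NOISE_VARIANCE_RANGE
    variances = rng.uniform(lo, hi, size=C.shape[0])
    return VARProcess(C=C, noise_variances=variances)


def simulate_series(
    process: VARProcess,
    T: int,
    seed,
    burn_in: int = 200,
    variable_names: tuple[str, ...] | None = None,
) -> TimeSeries:
    """Simulate ``T`` observations of the process after a burn-in.

    The recursion starts at the zero vector and the first ``burn_in``
    states are discarded, so retained rows are approximately draws from
    the stationary distribution.  Identical inputs give identical output.
    """
    if not process.stationary:
        raise NonStationaryError(
            "refusing to simulate: spectral radius "
            f"{process.spectral_radius:.3f} >= 1, the process is non-stationary"
        )
    if T < 2:
        raise DimensionError("T must be at least 2")
    if burn_in < 0:
        raise ConfigurationError("burn_in must be non-negative")
    rng = np.random.default_rng(seed)
    k = process.k
    sd = np.sqrt(process.noise_variances)
    total = burn_in + T
    noise = rng.standard_normal((total, k)) * sd
    out = np.empty((total, k))
    x = np.zeros(k)
    C = process.C
    for t in range(total):
        x = C @ x + noise[t]
        out[t] = x
    names = variable_names if variable_names is not None else default_names(k)
    return TimeSeries(out[burn_in:], names)
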