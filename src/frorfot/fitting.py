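"""Complex nonlinear least-squares estimation of the fractional-order model.

A spectrum's four parameters (FrL, alpha, FrC, beta) are estimated by
minimising the stacked real/imaginary residual vector with a bounded
trust-region Levenberg–Marquardt scheme (`scipy.optimize.least_squares`),
restarted from a small deterministic lattice of initial points plus one
data-driven heuristic start, and keeping the best result.

Goodness of fit follows the total-error convention

    MSEt = sqrt(MSEr + MSEx)

where MSEr and MSEx are the mean squared residuals of the resistance and
reactance components.  The mean (rather than the sum) is used so that the
metric is comparable across frequency grids of different size.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .model import (
    DEGENERACY_EPS,
    HALF_PI,
    DegenerateParameterError,
    FrequencyGrid,
    FrOrParameters,
    ImpedanceSpectrum,
    TissueParameters,
    derive_tissue,
    impedance_components,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "residuals",
    "goodness_of_fit",
    "fit_spectrum",
    "fit_cohort",
    "FEATURE_COLUMNS",
]

#: the seven model-derived features used throughout the diagnostic stages
FEATURE_COLUMNS = ["FrL", "alpha", "FrC", "beta", "G", "H", "eta"]

_DEFAULT_BOUNDS = {
    "FrL": (1e-4, 10.0),
    "alpha": (DEGENERACY_EPS, 1.0),
    "FrC": (1e-4, 10.0),
    "beta": (DEGENERACY_EPS, 1.0),
}


@dataclass(frozen=True)
class FitConfig:
    """Settings for the multistart bounded least-squares fit.

    ``lattice_points`` deterministic starts are laid out on a coarse
    log-spaced lattice over the amplitude bounds crossed with low/high
    exponent pairs; one extra heuristic start reads FrL off the
    high-frequency reactance and FrC off the low-frequency reactance with
    alpha = beta = 0.6.
    """

    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_BOUNDS)
    )
    n_lattice_starts: int = 8
    use_heuristic_start: bool = True
    xtol: float = 1e-10
    ftol: float = 1e-10
    gtol: float = 1e-10
    max_iterations: int = 1000
    min_points: int = FrequencyGrid.MIN_POINTS_FIT

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and 0 < lo < hi):
                raise ValueError(f"invalid bounds for {name}: ({lo}, {hi})")
        if self.n_lattice_starts < 0:
            raise ValueError("n_lattice_starts must be >= 0")
        if self.n_lattice_starts == 0 and not self.use_heuristic_start:
            raise ValueError("at least one start is required")
        if min(self.xtol, self.ftol, self.gtol) <= 0:
            raise ValueError("tolerances must be positive")

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.bounds[k][0] for k in ("FrL", "alpha", "FrC", "beta")])
        hi = np.array([self.bounds[k][1] for k in ("FrL", "alpha", "FrC", "beta")])
        return lo, hi


@dataclass(frozen=True)
class FitResult:
    """Best parameters across starts plus fit-quality diagnostics."""

    params: FrOrParameters
    tissue: TissueParameters | None
    mse_r: float
    mse_x: float
    mse_t: float
    n_iterations: int
    converged: bool
    winning_start: int

    def __post_init__(self) -> None:
        if min(self.mse_r, self.mse_x, self.mse_t) < 0:
            raise ValueError("error metrics must be non-negative")


def residuals(params: FrOrParameters, spectrum: ImpedanceSpectrum) -> np.ndarray:
    """Stacked residual vector [zr_meas - zr_model; zx_meas - zx_model].

    Real and imaginary components are weighted equally.
    """
    zr_m, zx_m = impedance_components(params, spectrum.grid.omega)
    return np.concatenate([spectrum.zr - zr_m, spectrum.zx - zx_m])


def goodness_of_fit(
    params: FrOrParameters, spectrum: ImpedanceSpectrum
) -> tuple[float, float, float]:
    """(MSEr, MSEx, MSEt) with MSEt = sqrt(MSEr + MSEx)."""
    if len(spectrum.grid) == 0:
        raise ValueError("empty spectrum")
    res = residuals(params, spectrum)
    n = len(spectrum.grid)
    mse_r = float(np.mean(res[:n] ** 2))
    mse_x = float(np.mean(res[n:] ** 2))
    return mse_r, mse_x, float(np.sqrt(mse_r + mse_x))


def _residual_vector(x: np.ndarray, omega: np.ndarray, zr: np.ndarray, zx: np.ndarray) -> np.ndarray:
    frl, a, frc, b = x
    airway = frl * omega**a
    tissue = 1.0 / (frc * omega**b)
    zr_m = airway * np.cos(HALF_PI * a) + tissue * np.cos(HALF_PI * b)
    zx_m = airway * np.sin(HALF_PI * a) - tissue * np.sin(HALF_PI * b)
    return np.concatenate([zr_m - zr, zx_m - zx])


def _jacobian(x: np.ndarray, omega: np.ndarray, zr: np.ndarray, zx: np.ndarray) -> np.ndarray:
    """Analytic Jacobian of the model residuals (d model / d params)."""
    frl, a, frc, b = x
    logw = np.log(omega)
    wa = omega**a
    wb_inv = omega**-b
    ca, sa = np.cos(HALF_PI * a), np.sin(HALF_PI * a)
    cb, sb = np.cos(HALF_PI * b), np.sin(HALF_PI * b)

    n = omega.size
    jac = np.empty((2 * n, 4))
    # resistance rows
    jac[:n, 0] = wa * ca
    jac[:n, 1] = frl * wa * (logw * ca - HALF_PI * sa)
    jac[:n, 2] = -(wb_inv / frc**2) * cb
    jac[:n, 3] = (wb_inv / frc) * (-logw * cb - HALF_PI * sb)
    # reactance rows
    jac[n:, 0] = wa * sa
    jac[n:, 1] = frl * wa * (logw * sa + HALF_PI * ca)
    jac[n:, 2] = (wb_inv / frc**2) * sb
    jac[n:, 3] = -(wb_inv / frc) * (-logw * sb + HALF_PI * cb)
    return jac


def _lattice_starts(config: FitConfig) -> list[np.ndarray]:
    """Coarse deterministic lattice: 2 log-spaced amplitudes x 2 exponent levels."""
    lo, hi = config.bounds_arrays()
    frl_vals = np.geomspace(lo[0] * 30, hi[0] / 10, 2)
    frc_vals = np.geomspace(lo[2] * 30, hi[2] / 10, 2)
    exps = [0.4, 0.8]
    starts = [
        np.array([frl, ab, frc, ab])
        for frl, frc, ab in itertools.product(frl_vals, frc_vals, exps)
    ]
    return starts[: config.n_lattice_starts]


def _heuristic_start(spectrum: ImpedanceSpectrum, config: FitConfig) -> np.ndarray:
    """Data-driven start: FrL from high-f reactance, FrC from low-f reactance."""
    lo, hi = config.bounds_arrays()
    omega = spectrum.grid.omega
    a0 = b0 = 0.6
    s06 = np.sin(HALF_PI * 0.6)
    w_hi, w_lo = omega[-1], omega[0]
    frl0 = spectrum.zx[-1] / (w_hi**a0 * s06)
    if not np.isfinite(frl0) or frl0 <= 0:
        frl0 = np.sqrt(lo[0] * hi[0])
    frl0 = float(np.clip(frl0, lo[0], hi[0]))
    tissue_x = frl0 * w_lo**a0 * s06 - spectrum.zx[0]
    if np.isfinite(tissue_x) and tissue_x > 0:
        frc0 = s06 / (tissue_x * w_lo**b0)
    else:
        frc0 = np.sqrt(lo[2] * hi[2])
    frc0 = float(np.clip(frc0, lo[2], hi[2]))
    return np.array([frl0, a0, frc0, b0])


def fit_spectrum(spectrum: ImpedanceSpectrum, config: FitConfig | None = None) -> FitResult:
    """Estimate model parameters for one spectrum.

    Runs bounded trust-region least squares from every configured start and
    returns the lowest-MSEt solution.  Deterministic: the start list is a
    fixed function of the configuration and the data.  If no start reaches
    a convergence criterion the best attempt is still returned with
    ``converged=False``.
    """
    config = config or FitConfig()
    if len(spectrum.grid) < config.min_points:
        raise ValueError(
            f"need >= {config.min_points} frequencies to fit, got {len(spectrum.grid)}"
        )
    if not spectrum.is_finite():
        raise ValueError(f"spectrum {spectrum.subject_id!r} contains non-finite values")

    omega = spectrum.grid.omega
    order = np.argsort(omega)  # fit is invariant to input frequency order
    omega_s = omega[order]
    zr_s, zx_s = spectrum.zr[order], spectrum.zx[order]

    starts = _lattice_starts(config)
    if config.use_heuristic_start:
        sorted_spec = ImpedanceSpectrum(
            spectrum.subject_id,
            FrequencyGrid(spectrum.grid.freqs_hz[order]),
            zr_s,
            zx_s,
        )
        starts.append(_heuristic_start(sorted_spec, config))

    lo, hi = config.bounds_arrays()
    best = None
    for idx, x0 in enumerate(starts):
        x0 = np.clip(x0, lo, hi)
        sol = least_squares(
            _residual_vector,
            x0,
            jac=_jacobian,
            bounds=(lo, hi),
            method="trf",
            x_scale="jac",
            xtol=config.xtol,
            ftol=config.ftol,
            gtol=config.gtol,
            max_nfev=config.max_iterations,
            args=(omega_s, zr_s, zx_s),
        )
        if best is None or sol.cost < best[1].cost:
            best = (idx, sol)

    winning_start, sol = best
    params = FrOrParameters.from_array(np.clip(sol.x, lo, hi))
    mse_r, mse_x, mse_t = goodness_of_fit(params, spectrum)
    try:
        tissue = derive_tissue(params)
    except DegenerateParameterError:
        tissue = None
    return FitResult(
        params=params,
        tissue=tissue,
        mse_r=mse_r,
        mse_x=mse_x,
        mse_t=mse_t,
        n_iterations=int(sol.nfev),
        converged=bool(sol.status > 0),
        winning_start=winning_start,
    )


def fit_cohort(
    spectra: list[ImpedanceSpectrum], config: FitConfig | None = None
) -> pd.DataFrame:
    """Fit every spectrum; one feature row per subject, failures flagged per row.

    Columns: subject_id, the seven model features, MSE diagnostics,
    convergence flag and an ``error`` column (empty string when clean).
    Row order follows the input. A corrupt spectrum never aborts the batch.
    """
    if not spectra:
        raise ValueError("empty cohort")
    rows = []
    for spec in spectra:
        row: dict[str, object] = {"subject_id": spec.subject_id}
        try:
            fit = fit_spectrum(spec, config)
            row.update(
                FrL=fit.params.FrL,
                alpha=fit.params.alpha,
                FrC=fit.params.FrC,
                beta=fit.params.beta,
                G=fit.tissue.G if fit.tissue else np.nan,
                H=fit.tissue.H if fit.tissue else np.nan,
                eta=fit.tissue.eta if fit.tissue else np.nan,
                mse_r=fit.mse_r,
                mse_x=fit.mse_x,
                mse_t=fit.mse_t,
                n_iterations=fit.n_iterations,
                converged=fit.converged,
                error="",
            )
        except (ValueError, DegenerateParameterError) as exc:
            row.update(
                {c: np.nan for c in FEATURE_COLUMNS + ["mse_r", "mse_x", "mse_t"]},
                n_iterations=0,
                converged=False,
                error=str(exc),
            )
        rows.append(row)
    return pd.DataFrame(rows)
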