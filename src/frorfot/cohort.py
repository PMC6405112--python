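"""Synthetic study cohorts for exercising the diagnostic pipeline.

Generates three groups — healthy controls, patients with a normal
spirometric exam (NE) and patients with an abnormal/restrictive exam (AE)
— with group sizes 23/21/24.  Per-subject model parameters are drawn from
independent truncated normals whose group means are placed on the correct
side of the published single-parameter diagnostic cutoffs (FrL 0.137,
beta 0.623, eta 0.599, G 14.098, H 25.06: patients above the FrL/G/eta
cutoffs, below the beta/H ones), with disease severity increasing from NE
to AE.  Noisy impedance spectra are produced by evaluating the model on
the standard 4–32 Hz grid and adding independent Gaussian measurement
noise to resistance and reactance.

Clinical covariates (percent-predicted flows, diffusion, oxygen
saturation, ...) are attached by a Gaussian-copula construction anchored
to a chosen model feature at a requested correlation, emulating the
reported feature–exam correlation structure.

Everything is driven by `numpy.random.default_rng`; a cohort regenerated
with the same specification and seed is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .fitting import FEATURE_COLUMNS
from .model import (
    DEGENERACY_EPS,
    FrequencyGrid,
    FrOrParameters,
    ImpedanceSpectrum,
    default_grid,
    derive_tissue,
    evaluate_model,
)

__all__ = [
    "GroupSpec",
    "NoiseSpec",
    "CovariateSpec",
    "CohortSpec",
    "SyntheticCohort",
    "default_group_specs",
    "default_covariate_specs",
    "sample_parameters",
    "generate_cohort",
    "attach_covariates",
]

_PARAM_NAMES = ("FrL", "alpha", "FrC", "beta")

_PARAM_BOUNDS = {
    "FrL": (1e-4, 10.0),
    "alpha": (DEGENERACY_EPS, 1.0),
    "FrC": (1e-4, 10.0),
    "beta": (DEGENERACY_EPS, 1.0),
}


@dataclass(frozen=True)
class GroupSpec:
    """Parameter distribution of one study group.

    ``means``/``sds`` map each of FrL, alpha, FrC, beta to the location and
    spread of an independent truncated normal; ``label`` is the disease
    indicator (0 control, 1 patient).
    """

    name: str
    n: int
    means: dict[str, float]
    sds: dict[str, float]
    label: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        for p in _PARAM_NAMES:
            if p not in self.means or p not in self.sds:
                raise ValueError(f"missing mean/sd for parameter {p}")
            lo, hi = _PARAM_BOUNDS[p]
            if not lo <= self.means[p] <= hi:
                raise ValueError(f"mean of {p} outside bounds: {self.means[p]}")
            if self.sds[p] < 0:
                raise ValueError(f"sd of {p} must be >= 0")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian measurement noise on each impedance component."""

    sd_zr: float = 0.15
    sd_zx: float = 0.15

    def __post_init__(self) -> None:
        if self.sd_zr < 0 or self.sd_zx < 0:
            raise ValueError("noise sds must be >= 0")


@dataclass(frozen=True)
class CovariateSpec:
    """One clinical covariate tied to a model feature by a target correlation."""

    name: str
    mean: float
    sd: float
    anchor: str
    target_r: float
    lower: float = -np.inf
    upper: float = np.inf

    def __post_init__(self) -> None:
        if abs(self.target_r) >= 1:
            raise ValueError(f"|target_r| must be < 1, got {self.target_r}")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.lower >= self.upper:
            raise ValueError("lower truncation bound must be below upper")


def default_group_specs() -> list[GroupSpec]:
    """Cutoff-consistent stand-in groups (not a reconstruction of any study).

    Group means straddle the published cutoffs: the control mean subject has
    FrL < 0.137, eta = cot(pi*0.70/2) ~ 0.51 < 0.599 and H ~ 26.2 > 25.06,
    while both patient groups sit on the other side of each cutoff.
    Amplitude parameters (FrL, FrC) get coefficients of variation of
    15–18%; the dimensionless exponents get tighter absolute spreads
    (alpha 10% CV, beta sd 0.045) as befits constant-phase exponents whose
    physiologic within-group range is narrow.
    """
    return [
        GroupSpec(
            name="control",
            n=23,
            means={"FrL": 0.09, "alpha": 0.70, "FrC": 0.034, "beta": 0.70},
            sds={"FrL": 0.016, "alpha": 0.070, "FrC": 0.0051, "beta": 0.045},
            label=0,
        ),
        GroupSpec(
            name="normal_exam",
            n=21,
            means={"FrL": 0.18, "alpha": 0.55, "FrC": 0.042, "beta": 0.58},
            sds={"FrL": 0.032, "alpha": 0.055, "FrC": 0.0063, "beta": 0.045},
            label=1,
        ),
        GroupSpec(
            name="abnormal_exam",
            n=24,
            means={"FrL": 0.28, "alpha": 0.50, "FrC": 0.048, "beta": 0.50},
            sds={"FrL": 0.050, "alpha": 0.050, "FrC": 0.0072, "beta": 0.045},
            label=1,
        ),
    ]


def default_covariate_specs() -> list[CovariateSpec]:
    """Covariates emulating the reported feature–exam correlation structure."""
    return [
        CovariateSpec("FEF_pct", 85.0, 20.0, anchor="FrL", target_r=-0.62, lower=5.0),
        CovariateSpec("DLCOa_pct", 80.0, 18.0, anchor="FrL", target_r=-0.71, lower=5.0),
        CovariateSpec("SpO2_final", 95.0, 3.0, anchor="eta", target_r=-0.57, upper=100.0),
        CovariateSpec("Pe_pct", 90.0, 25.0, anchor="beta", target_r=0.50, lower=5.0),
        CovariateSpec("Raw", 2.5, 1.0, anchor="FrL", target_r=0.60, lower=0.2),
    ]


@dataclass(frozen=True)
class CohortSpec:
    """Full generator specification: groups, grid, noise, covariates."""

    groups: list[GroupSpec] = field(default_factory=default_group_specs)
    grid: FrequencyGrid = field(default_factory=default_grid)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    covariates: list[CovariateSpec] = field(default_factory=default_covariate_specs)

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValueError("need at least two groups")
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate group names: {names}")


@dataclass(frozen=True)
class SyntheticCohort:
    """Generated truth parameters, noisy spectra and covariates, 1:1 by subject."""

    truth: pd.DataFrame
    spectra: list[ImpedanceSpectrum]
    covariates: pd.DataFrame | None
    seed: int

    def __post_init__(self) -> None:
        ids = list(self.truth["subject_id"])
        if [s.subject_id for s in self.spectra] != ids:
            raise ValueError("truth table and spectra subject ids differ")
        if self.covariates is not None and list(self.covariates["subject_id"]) != ids:
            raise ValueError("covariate table subject ids differ from truth")


def _truncnorm_draw(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, n: int
) -> np.ndarray:
    if sd == 0:
        return np.full(n, mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def sample_parameters(group: GroupSpec, seed: int | np.random.Generator) -> list[FrOrParameters]:
    """Draw per-subject parameters from the group's truncated normals."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    draws = {
        p: _truncnorm_draw(
            rng, group.means[p], group.sds[p], *_PARAM_BOUNDS[p], group.n
        )
        for p in _PARAM_NAMES
    }
    return [
        FrOrParameters(
            FrL=float(draws["FrL"][i]),
            alpha=float(draws["alpha"][i]),
            FrC=float(draws["FrC"][i]),
            beta=float(draws["beta"][i]),
        )
        for i in range(group.n)
    ]


def generate_cohort(
    spec: CohortSpec | None = None,
    seed: int = 0,
    with_covariates: bool = True,
) -> SyntheticCohort:
    """Generate a full cohort: truth table, noisy spectra, covariates.

    Deterministic: the same (spec, seed) pair regenerates a bit-identical
    cohort.  Subjects are numbered consecutively across groups
    (``S001``, ``S002``, ...).
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(seed)

    rows = []
    spectra: list[ImpedanceSpectrum] = []
    counter = 0
    for group in spec.groups:
        params_list = sample_parameters(group, rng)
        for params in params_list:
            counter += 1
            sid = f"S{counter:03d}"
            tissue = derive_tissue(params)
            rows.append(
                {
                    "subject_id": sid,
                    "group": group.name,
                    "label": group.label,
                    "FrL": params.FrL,
                    "alpha": params.alpha,
                    "FrC": params.FrC,
                    "beta": params.beta,
                    "G": tissue.G,
                    "H": tissue.H,
                    "eta": tissue.eta,
                }
            )
            clean = evaluate_model(params, spec.grid, subject_id=sid)
            n = len(spec.grid)
            zr = clean.zr + rng.normal(0.0, 1.0, n) * spec.noise.sd_zr
            zx = clean.zx + rng.normal(0.0, 1.0, n) * spec.noise.sd_zx
            spectra.append(ImpedanceSpectrum(sid, spec.grid, zr, zx))

    truth = pd.DataFrame(rows)
    cohort = SyntheticCohort(truth=truth, spectra=spectra, covariates=None, seed=seed)
    if with_covariates and spec.covariates:
        cohort = attach_covariates(cohort, spec.covariates, rng)
    return cohort


def attach_covariates(
    cohort: SyntheticCohort,
    specs: list[CovariateSpec],
    seed: int | np.random.Generator,
) -> SyntheticCohort:
    """Attach clinical covariates correlated with truth features.

    Gaussian copula: the anchor feature is rank-transformed to normal
    scores z; the covariate's latent normal is ``r*z + sqrt(1-r^2)*eps``,
    mapped to the requested marginal and clipped at the physiologic
    truncation limits.  Sample correlations approach ``target_r`` as n
    grows (truncation, if binding, attenuates slightly).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    truth = cohort.truth
    n = len(truth)
    out = {"subject_id": truth["subject_id"].to_numpy()}
    for cspec in specs:
        if cspec.anchor not in FEATURE_COLUMNS:
            raise ValueError(
                f"anchor {cspec.anchor!r} is not a model feature {FEATURE_COLUMNS}"
            )
        anchor = truth[cspec.anchor].to_numpy(dtype=float)
        ranks = sps.rankdata(anchor, method="average")
        z = sps.norm.ppf((ranks - 0.375) / (n + 0.25))  # Blom normal scores
        z = (z - z.mean()) / z.std()
        eps = rng.normal(0.0, 1.0, n)
        r = cspec.target_r
        latent = r * z + np.sqrt(1.0 - r**2) * eps
        values = cspec.mean + cspec.sd * latent
        out[cspec.name] = np.clip(values, cspec.lower, cspec.upper)
    covariates = pd.DataFrame(out)
    return replace(cohort, covariates=covariates)
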