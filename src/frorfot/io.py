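"""CSV schemas for spectra, truth/feature tables and run configuration.

Two tidy CSV layouts tie the pipeline stages together:

* spectra file — columns ``subject_id, group, freq_hz, zr, zx``, one row
  per (subject, frequency); each subject must carry a complete,
  duplicate-free frequency set.
* feature table — one row per subject with ``subject_id, group, label``,
  the seven model features, fit diagnostics and any covariate columns.

Numeric values are written with 12 significant digits, "." decimal and
"\n" line endings, so identical tables produce identical bytes on every
platform.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortSpec, CovariateSpec, GroupSpec, NoiseSpec, SyntheticCohort
from .fitting import FEATURE_COLUMNS
from .model import FrequencyGrid, ImpedanceSpectrum

__all__ = [
    "SpectraParseError",
    "read_spectra",
    "write_spectra",
    "read_feature_table",
    "write_feature_table",
    "RunConfig",
    "load_run_config",
]

SPECTRA_COLUMNS = ["subject_id", "group", "freq_hz", "zr", "zx"]
FEATURE_TABLE_REQUIRED = ["subject_id", "group", "label"] + FEATURE_COLUMNS
FEATURE_TABLE_DIAGNOSTICS = ["mse_r", "mse_x", "mse_t", "n_iterations", "converged", "error"]


class SpectraParseError(ValueError):
    """Validation failure in a spectra file; the message names the row."""


def _fmt(value: object) -> str:
    if isinstance(value, (float, np.floating)):
        return format(float(value), ".12g")
    if isinstance(value, (bool, np.bool_)):
        return "true" if value else "false"
    return str(value)


def read_spectra(path: str | Path) -> list[ImpedanceSpectrum]:
    """Read and validate a spectra CSV; subjects keep file order, frequencies sorted."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or any(
            c not in reader.fieldnames for c in SPECTRA_COLUMNS
        ):
            missing = [c for c in SPECTRA_COLUMNS if c not in (reader.fieldnames or [])]
            raise SpectraParseError(f"{path}: missing columns {missing}")
        per_subject: dict[str, dict[float, tuple[float, float]]] = {}
        groups: dict[str, str] = {}
        for lineno, row in enumerate(reader, start=2):
            sid = row["subject_id"]
            try:
                freq = float(row["freq_hz"])
                zr = float(row["zr"])
                zx = float(row["zx"])
            except (TypeError, ValueError) as exc:
                raise SpectraParseError(f"{path}:{lineno}: unparseable number ({exc})")
            if not np.isfinite([freq, zr, zx]).all():
                raise SpectraParseError(f"{path}:{lineno}: non-finite value")
            if freq <= 0:
                raise SpectraParseError(f"{path}:{lineno}: freq_hz must be > 0")
            bucket = per_subject.setdefault(sid, {})
            if freq in bucket:
                raise SpectraParseError(
                    f"{path}:{lineno}: duplicate (subject_id={sid!r}, freq_hz={freq})"
                )
            bucket[freq] = (zr, zx)
            groups.setdefault(sid, row["group"])

    if not per_subject:
        raise SpectraParseError(f"{path}: no data rows")
    expected = None
    spectra = []
    for sid, bucket in per_subject.items():
        freqs = np.array(sorted(bucket))
        if expected is None:
            expected = freqs
        elif not np.array_equal(freqs, expected):
            raise SpectraParseError(
                f"{path}: subject {sid!r} has an incomplete frequency set "
                f"({freqs.size} vs {expected.size} frequencies)"
            )
        zr = np.array([bucket[f][0] for f in freqs])
        zx = np.array([bucket[f][1] for f in freqs])
        spectra.append(ImpedanceSpectrum(sid, FrequencyGrid(freqs), zr, zx))
    return spectra


def write_spectra(
    spectra: Iterable[ImpedanceSpectrum],
    path: str | Path,
    groups: dict[str, str] | None = None,
) -> None:
    """Write spectra in the tidy CSV layout; ``groups`` maps subject id to group."""
    groups = groups or {}
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(SPECTRA_COLUMNS)
        for spec in spectra:
            grp = groups.get(spec.subject_id, "")
            for f, zr, zx in zip(spec.grid.freqs_hz, spec.zr, spec.zx):
                writer.writerow([spec.subject_id, grp, _fmt(f), _fmt(zr), _fmt(zx)])


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table with fixed column order and stable formatting."""
    missing = [c for c in FEATURE_TABLE_REQUIRED if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing required columns {missing}")
    ordered = FEATURE_TABLE_REQUIRED + [
        c for c in FEATURE_TABLE_DIAGNOSTICS if c in table.columns
    ]
    ordered += [c for c in table.columns if c not in ordered]
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(ordered)
        for _, row in table[ordered].iterrows():
            writer.writerow([_fmt(v) for v in row])


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature table, checking the required columns are present."""
    table = pd.read_csv(path)
    missing = [c for c in FEATURE_TABLE_REQUIRED if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: feature table missing required columns {missing}")
    if not table["label"].isin([0, 1]).all():
        raise ValueError(f"{path}: label column must be 0/1")
    return table


def cohort_feature_table(cohort: SyntheticCohort, fitted: pd.DataFrame) -> pd.DataFrame:
    """Join fitted features with group/label (and covariates when present)."""
    meta = cohort.truth[["subject_id", "group", "label"]]
    out = meta.merge(fitted, on="subject_id", validate="1:1")
    if cohort.covariates is not None:
        out = out.merge(cohort.covariates, on="subject_id", validate="1:1")
    return out


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline settings (YAML-loadable)."""

    seed: int = 0
    out_dir: Path = Path("results")
    cohort: CohortSpec = field(default_factory=CohortSpec)
    contrasts: dict[str, tuple[str, str]] = field(
        default_factory=lambda: {
            "control_vs_NE": ("control", "normal_exam"),
            "control_vs_AE": ("control", "abnormal_exam"),
        }
    )
    roc_features: tuple[str, ...] = tuple(FEATURE_COLUMNS)
    classifiers: tuple[str, ...] = ("SVML", "SVMR", "ADAB", "1-NN", "RF", "PARZEN")
    search: bool = False


def load_run_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from YAML; unspecified blocks fall back to defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict[str, object] = {}
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    if "out_dir" in raw:
        kwargs["out_dir"] = Path(raw["out_dir"])
    cohort_kwargs: dict[str, object] = {}
    if "groups" in raw:
        cohort_kwargs["groups"] = [GroupSpec(**g) for g in raw["groups"]]
    if "noise" in raw:
        cohort_kwargs["noise"] = NoiseSpec(**raw["noise"])
    if "covariates" in raw:
        cohort_kwargs["covariates"] = [CovariateSpec(**c) for c in raw["covariates"]]
    if "grid_hz" in raw:
        cohort_kwargs["grid"] = FrequencyGrid(np.asarray(raw["grid_hz"], dtype=float))
    if cohort_kwargs:
        kwargs["cohort"] = CohortSpec(**cohort_kwargs)
    if "contrasts" in raw:
        kwargs["contrasts"] = {k: tuple(v) for k, v in raw["contrasts"].items()}
    if "roc_features" in raw:
        kwargs["roc_features"] = tuple(raw["roc_features"])
    if "classifiers" in raw:
        kwargs["classifiers"] = tuple(raw["classifiers"])
    if "search" in raw:
        kwargs["search"] = bool(raw["search"])
    return RunConfig(**kwargs)
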