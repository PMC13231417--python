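"""End-to-end human-prediction workflows and fold-error reporting.

Two reproduction paths are provided: (1) allometric single-species
prediction of human DCmax/DAUC with generalized exponents, and (2)
translational-model projection of a single-species fit to a human
regimen.  Both emit a :class:`PredictionReport` of observed-vs-predicted
rows with signed fold errors and per-method summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .allometry import FoldError, allometric_predict, fold_error, geometric_mean
from .data import DoseEvent, SPECIES_WEIGHTS
from .errors import ConfigurationError, ValidationError
from .kinetics import (
    ScalingConfig,
    TranslationalParams,
    closed_form_dauc,
    project_params_cross_species,
    simulate,
    simulate_population,
)
from .nca import nca_subject

__all__ = [
    "ReportRow",
    "PredictionReport",
    "allometry_workflow",
    "model_projection_workflow",
    "report_from_pairs",
    "plot_profile",
]


@dataclass(frozen=True)
class ReportRow:
    compound: str
    parameter: str  # "dcmax" | "dauc"
    observed: float | None
    predicted: float
    fold: FoldError | None
    source_species: str
    method: str  # "allometry" | "model"

    def formatted(self) -> str:
        obs = "—" if self.observed is None else f"{self.observed:.3g}"
        fe = "" if self.fold is None else f" {self.fold}"
        return (f"{self.compound:<10} {self.parameter.upper():<6} "
                f"obs {obs:<9} pred {self.predicted:.3g}{fe} "
                f"[{self.method} from {self.source_species}]")


@dataclass
class PredictionReport:
    """Observed-vs-predicted human exposure rows with fold-error summaries."""

    rows: list[ReportRow]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(
                    compound=r.compound, parameter=r.parameter,
                    observed=r.observed, predicted=r.predicted,
                    ratio_pred_over_obs=None if r.fold is None
                    else r.fold.ratio_pred_over_obs,
                    fold=None if r.fold is None else r.fold.fold,
                    direction=None if r.fold is None else r.fold.direction,
                    source_species=r.source_species, method=r.method,
                )
                for r in self.rows
            ]
        )

    def summary(self) -> dict:
        """Max and geometric-mean fold per (method, source species)."""
        out: dict = {}
        for r in self.rows:
            if r.fold is None:
                continue
            key = f"{r.method}/{r.source_species}"
            out.setdefault(key, []).append(r.fold.fold)
        return {
            key: dict(
                n=len(folds),
                max_fold=float(max(folds)),
                geomean_fold=float(geometric_mean(folds)),
            )
            for key, folds in out.items()
        }

    def __str__(self) -> str:
        lines = [r.formatted() for r in self.rows]
        lines.append("")
        for key, s in sorted(self.summary().items()):
            lines.append(
                f"{key}: n={s['n']} max fold {s['max_fold']:.2f} "
                f"geomean fold {s['geomean_fold']:.2f}"
            )
        return "\n".join(lines)


def report_from_pairs(
    pairs: Sequence[tuple[str, str, float | None, float, str, str]],
) -> PredictionReport:
    """Build a report from (compound, parameter, observed, predicted,
    source_species, method) tuples, recomputing every fold from the inputs."""
    rows = []
    for compound, parameter, obs, pred, source, method in pairs:
        fe = None if obs is None else fold_error(pred, obs)
        rows.append(ReportRow(compound, parameter, obs, pred, fe, source, method))
    return PredictionReport(rows)


def allometry_workflow(
    species_exposures: Mapping[str, Mapping[str, tuple[float, float]]],
    human_observed: Mapping[str, Mapping[str, float]],
    exponent_config: Mapping[str, float] | None = None,
    w_target: float = SPECIES_WEIGHTS["human"],
) -> PredictionReport:
    """Predict human exposure from single-species values via fixed exponents.

    ``species_exposures[source_species][(compound:parameter key)]`` maps to
    ``(value, source_body_weight)``; ``human_observed[compound][parameter]``
    holds the observed human values (rows without one are emitted
    prediction-only).  ``exponent_config`` maps source species to the
    exponent; it defaults to the generalized exponents −1.26 (mouse) and
    −0.75 (NHP).
    """
    from .reference import GENERALIZED_EXPONENTS

    exponents = dict(GENERALIZED_EXPONENTS)
    if exponent_config:
        exponents.update(exponent_config)
    pairs = []
    for source, table in species_exposures.items():
        if source not in exponents:
            raise ConfigurationError(f"no exponent configured for source {source!r}")
        for key, (value, w_source) in table.items():
            compound, parameter = key.split(":")
            pred = allometric_predict(value, w_source, w_target, exponents[source])
            obs = human_observed.get(compound, {}).get(parameter)
            pairs.append((compound, parameter, obs, pred, source, "allometry"))
    return report_from_pairs(pairs)


def model_projection_workflow(
    p_fit: TranslationalParams,
    source_species: str,
    scaling: ScalingConfig,
    human_regimen: Sequence[DoseEvent],
    human_observed: Mapping[str, float] | None = None,
    compound: str = "compound",
    w_source: float | None = None,
    w_target: float = SPECIES_WEIGHTS["human"],
    times: Sequence[float] | None = None,
    n_band_replicates: int = 500,
    seed: int | None = None,
) -> tuple[PredictionReport, dict]:
    """Project a single-species translational-model fit to a human regimen.

    DCmax is the simulated maximum concentration over the first dosing
    interval divided by the first dose; DAUC is reported both in closed
    form k_t,eff/(k_elim,eff·CL_eff) and by NCA on the simulated profile.
    Returns the report and a profile dict with 10/50/90 percentile bands.
    """
    if w_source is None:
        w_source = SPECIES_WEIGHTS[source_species]
    if not human_regimen:
        raise ValidationError("human_regimen must contain at least one dose")
    p_human = project_params_cross_species(p_fit, w_source, w_target, scaling)

    dose_times = sorted(d.time for d in human_regimen)
    first_dose = next(d for d in human_regimen if d.time == dose_times[0])
    interval_end = dose_times[1] if len(dose_times) > 1 else None

    if times is None:
        horizon = (dose_times[-1] + 504.0)
        times = np.unique(np.concatenate([
            np.linspace(0, horizon, 400), np.asarray(dose_times, dtype=float)
        ]))
    times = np.asarray(times, dtype=float)
    profile = simulate(p_human, w_target, human_regimen, times)

    mask = np.ones_like(times, dtype=bool) if interval_end is None \
        else times <= interval_end
    dcmax_pred = float(np.max(profile.concentration[mask])) / first_dose.amount
    dauc_closed = closed_form_dauc(p_human, w_target)
    nca_mask = mask & (profile.concentration > 0)
    nca_res = nca_subject(times[nca_mask], profile.concentration[nca_mask],
                          first_dose.amount)
    bands = simulate_population(p_human, w_target, human_regimen, times,
                                n_replicates=n_band_replicates, seed=seed)

    obs = human_observed or {}
    pairs = [
        (compound, "dcmax", obs.get("dcmax"), dcmax_pred, source_species, "model"),
        (compound, "dauc", obs.get("dauc"), dauc_closed, source_species, "model"),
    ]
    report = report_from_pairs(pairs)
    extras = dict(
        profile=profile, bands=bands, dauc_closed_form=dauc_closed,
        dauc_nca=nca_res.dauc, dcmax=dcmax_pred, params_human=p_human,
    )
    return report, extras


def plot_profile(profile, path, bands: dict | None = None, semilog: bool = False,
                 title: str | None = None) -> None:
    """Write a concentration-time plot (PNG/PDF by extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(profile.times, profile.concentration, "-", label="typical")
    if bands is not None:
        for pct, row in zip(bands["percentiles"], bands["bands"]):
            ax.plot(bands["times"], row, ":", lw=1,
                    label=f"{pct:g}th percentile")
    if semilog:
        ax.set_yscale("log")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("concentration (µg/mL)")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
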