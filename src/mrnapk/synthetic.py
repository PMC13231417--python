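"""Synthetic multispecies PK studies and species-level exposure summaries.

No raw concentration-time data are publicly deposited for the programs this
package models, so every pipeline input is generated here: concentration-
time studies simulated from the translational model with log-normal
between-subject variability and proportional residual error, and
species-level exposure values drawn from a power law with log-normal
noise.  All randomness is driven by a single integer seed through
``numpy.random.SeedSequence`` spawning, so arms are mutually independent
and datasets are reproducible byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence
import warnings

import numpy as np
import pandas as pd

from .data import ConcentrationRecord, DoseEvent, PKDataset, SPECIES_WEIGHTS
from .errors import ValidationError
from .kinetics import STRUCTURAL, TranslationalParams, simulate

__all__ = [
    "StudyArm",
    "StudyDesign",
    "generate_study",
    "generate_powerlaw_exposures",
    "default_study_designs",
]


@dataclass(frozen=True)
class StudyArm:
    """One species arm: n subjects sharing a regimen and sampling schedule."""

    species: str
    body_weight: float
    n_subjects: int
    dose_amounts: tuple[float, ...]  # µg, one entry per administration
    dose_times: tuple[float, ...] = (0.0,)  # h
    infusion_duration: float = 0.0  # h, applied to every administration
    sampling_times: tuple[float, ...] = ()  # h since first dose

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        if self.body_weight <= 0:
            raise ValidationError("body_weight must be > 0")
        if len(self.dose_amounts) != len(self.dose_times):
            raise ValidationError("dose_amounts and dose_times must align")
        if any(a <= 0 for a in self.dose_amounts):
            raise ValidationError("doses must be > 0")
        if any(t2 <= t1 for t1, t2 in zip(self.dose_times, self.dose_times[1:])):
            raise ValidationError("dose times must be strictly increasing")
        if any(t2 < t1 for t1, t2 in
               zip(self.sampling_times, self.sampling_times[1:])):
            raise ValidationError("sampling times must be sorted")

    def regimen(self, subject_id: str) -> list[DoseEvent]:
        return [
            DoseEvent(subject_id, t, a, self.infusion_duration)
            for t, a in zip(self.dose_times, self.dose_amounts)
        ]


@dataclass(frozen=True)
class StudyDesign:
    """A named collection of species arms."""

    name: str
    arms: tuple[StudyArm, ...]


def generate_study(
    design: StudyDesign,
    p: TranslationalParams,
    seed: int | None = None,
    lloq: float | str | None = "auto",
) -> PKDataset:
    """Simulate a full study from the translational model.

    Per subject, each structural parameter named in ``p.omega`` is
    multiplied by exp(η), η ~ N(0, ω²); the simulated concentrations get
    proportional noise C_obs = C_pred·(1+ε), ε ~ N(0, σ_prop²), truncated
    at 0.  ``lloq="auto"`` flags observations below 1% of the arm's median
    Cmax as BLQ; a float sets the LLOQ explicitly, None disables flagging.
    """
    ss = np.random.SeedSequence(seed)
    arm_seeds = ss.spawn(len(design.arms))
    records: list[ConcentrationRecord] = []
    doses: list[DoseEvent] = []
    omega_names = [n for n in p.omega if n in STRUCTURAL]
    for arm, arm_ss in zip(design.arms, arm_seeds):
        rng = np.random.default_rng(arm_ss)
        times = np.asarray(arm.sampling_times, dtype=float)
        arm_concs = np.empty((arm.n_subjects, len(times)))
        arm_preds = np.empty_like(arm_concs)
        for i in range(arm.n_subjects):
            sid = f"{design.name}/{arm.species}/{i + 1}"
            mult = {
                n: float(np.exp(rng.normal(0.0, p.omega[n]))) for n in omega_names
            }
            p_i = p.with_multipliers(mult) if mult else p
            regimen = arm.regimen(sid)
            doses.extend(regimen)
            pred = simulate(p_i, arm.body_weight, regimen, times).concentration
            eps = rng.normal(0.0, p.sigma_prop, size=len(times)) if p.sigma_prop else 0
            obs = np.maximum(pred * (1.0 + eps), 0.0)
            arm_preds[i], arm_concs[i] = pred, obs
        if p.sigma_prop and np.mean(arm_concs[arm_preds > 0] == 0) > 1 / 3:
            warnings.warn(
                f"arm {arm.species!r}: over a third of the draws truncated at 0; "
                "sigma_prop is too large for a proportional error model",
                stacklevel=2,
            )
        if lloq == "auto":
            cmax_med = float(np.median(np.max(arm_preds, axis=1)))
            arm_lloq = 0.01 * cmax_med
        else:
            arm_lloq = lloq
        for i in range(arm.n_subjects):
            sid = f"{design.name}/{arm.species}/{i + 1}"
            for t, c in zip(times, arm_concs[i]):
                blq = arm_lloq is not None and c < arm_lloq
                records.append(
                    ConcentrationRecord(
                        sid, arm.species, arm.body_weight, float(t), float(c),
                        blq=blq, lloq=arm_lloq,
                    )
                )
    return PKDataset(records=records, doses=doses,
                     metadata={"design": design.name, "seed": seed})


def generate_powerlaw_exposures(
    p0: float,
    alpha: float,
    weights: Sequence[float],
    lognormal_cv: float = 0.0,
    n_replicates: int = 1,
    seed: int | None = None,
) -> pd.DataFrame:
    """Species-level exposure values from P = p0·W^α with log-normal noise.

    The noise multiplier is exp(η), η ~ N(0, ln(1+cv²)) — its coefficient
    of variation is ``lognormal_cv``.  Returns columns
    (replicate, weight_kg, value).
    """
    if p0 <= 0 or any(w <= 0 for w in weights):
        raise ValidationError("p0 and weights must be > 0")
    if lognormal_cv < 0:
        raise ValidationError("lognormal_cv must be >= 0")
    rng = np.random.default_rng(seed)
    w = np.asarray(weights, dtype=float)
    sd = np.sqrt(np.log1p(lognormal_cv**2))
    rows = []
    for rep in range(n_replicates):
        eta = rng.normal(0.0, sd, size=len(w)) if sd > 0 else np.zeros(len(w))
        values = p0 * w**alpha * np.exp(eta)
        for wi, vi in zip(w, values):
            rows.append({"replicate": rep, "weight_kg": wi, "value": vi})
    return pd.DataFrame(rows)


def default_study_designs(
    n_subjects: int = 12,
    dose_per_kg: float = 100.0,
    infusion_duration: float = 0.0,
) -> dict[str, StudyDesign]:
    """Built-in study designs emulating the modelled clinical programs.

    * ``bnt141-like`` — mouse/rat/NHP/human, human sampling at predose, end
      of infusion, 3, 6, 24, 48, 72, 168, 336 and 504 h.
    * ``bnt142-like`` — mouse/NHP/human, human sampling at predose, end of
      infusion, 3, 6, 10, 24, 48 and 168 h.
    * ``mrna1944-like`` — NHP only.

    Doses are ``dose_per_kg`` µg/kg single administrations; preclinical
    arms share a rich schedule.  Group sizes and dose levels are package
    conventions, not reported study values.
    """
    eoi = infusion_duration if infusion_duration > 0 else 0.5

    def arm(species, schedule):
        w = SPECIES_WEIGHTS[species]
        return StudyArm(
            species=species, body_weight=w, n_subjects=n_subjects,
            dose_amounts=(dose_per_kg * w,), dose_times=(0.0,),
            infusion_duration=infusion_duration,
            sampling_times=tuple(schedule),
        )

    preclin = (eoi, 3, 6, 24, 48, 72, 168, 336)
    human_141 = (0, eoi, 3, 6, 24, 48, 72, 168, 336, 504)
    human_142 = (0, eoi, 3, 6, 10, 24, 48, 168)
    designs = {
        "bnt141-like": StudyDesign(
            "bnt141-like",
            tuple(arm(s, preclin) for s in ("mouse", "rat", "nhp"))
            + (arm("human", human_141),),
        ),
        "bnt142-like": StudyDesign(
            "bnt142-like",
            tuple(arm(s, preclin) for s in ("mouse", "nhp"))
            + (arm("human", human_142),),
        ),
        "mrna1944-like": StudyDesign(
            "mrna1944-like",
            (arm("nhp", preclin),),
        ),
    }
    return designs
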