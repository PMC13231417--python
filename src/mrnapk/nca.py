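"""Noncompartmental analysis of translated-antibody concentration profiles.

Exposure summaries mirror standard IV-infusion NCA practice: Cmax/Tmax,
linear-up/log-down trapezoidal AUC, terminal slope (λz) selected by
adjusted R², extrapolation to infinity, and dose-normalized exposure
DCmax = Cmax/Dose (1/mL) and DAUC = AUC_0-inf/Dose (h/mL).

BLQ observations are excluded from all calculations here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import PKDataset
from .errors import ValidationError

__all__ = [
    "LambdaZFit",
    "NCAResult",
    "compute_cmax_tmax",
    "fit_lambda_z",
    "auc_trapezoid",
    "auc_inf",
    "nca_subject",
    "nca_summary",
    "summary_stats",
]


@dataclass(frozen=True)
class LambdaZFit:
    """Terminal log-linear regression. ``lambda_z`` is None when not estimable."""

    lambda_z: float | None
    n_points: int
    adjusted_r2: float | None
    intercept: float | None  # ln-concentration at t=0 of the regression line

    @property
    def estimable(self) -> bool:
        return self.lambda_z is not None

    @property
    def t_half(self) -> float | None:
        return math.log(2.0) / self.lambda_z if self.estimable else None

    def predict(self, t: float) -> float | None:
        if not self.estimable:
            return None
        return math.exp(self.intercept - self.lambda_z * t)


@dataclass(frozen=True)
class NCAResult:
    """Per-subject (or per-interval) exposure summary."""

    subject_id: str
    dose: float
    cmax: float | None
    tmax: float | None
    auc_last: float | None
    auc_inf: float | None
    auc_tau: float | None
    lambda_z: float | None
    t_half: float | None
    n_lambda_points: int
    pct_extrapolated: float | None
    dcmax: float | None
    dauc: float | None
    species: str | None = None

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _clean_profile(times, concs) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    if t.shape != c.shape:
        raise ValidationError("times and concentrations must have equal length")
    if np.any(np.diff(t) < 0):
        raise ValidationError("profile times must be sorted ascending")
    return t, c


def compute_cmax_tmax(profile: Sequence[tuple[float, float]] | tuple):
    """Maximum observed concentration and its earliest time of occurrence.

    ``profile`` is either a sequence of (time, concentration) pairs or a
    (times, concentrations) pair of arrays.  Returns ``(None, None)`` for an
    empty profile.
    """
    t, c = _as_arrays(profile)
    if len(t) == 0:
        return None, None
    i = int(np.argmax(c))  # argmax returns the first occurrence: earliest tie wins
    return float(c[i]), float(t[i])


def _as_arrays(profile) -> tuple[np.ndarray, np.ndarray]:
    # a 2-tuple is always (times, concs); any other sequence is (t, c) pairs
    if isinstance(profile, tuple) and len(profile) == 2:
        return _clean_profile(profile[0], profile[1])
    arr = np.asarray(profile, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == 2:
        return _clean_profile(arr[:, 0], arr[:, 1])
    raise ValidationError("profile must be (time, conc) pairs or a (times, concs) tuple")


def fit_lambda_z(profile, n_points: int | None = None) -> LambdaZFit:
    """Estimate the terminal elimination rate constant λz.

    Automatic mode (``n_points=None``) scans terminal windows from 3 points
    up to all points strictly after Tmax (Tmax itself excluded) and keeps
    the window with the highest adjusted R²; exact ties go to the window
    with more points.  Explicit mode regresses over the last ``n_points``.
    A non-positive slope yields a not-estimable result rather than an error.
    """
    t, c = _as_arrays(profile)
    pos = c > 0
    t, c = t[pos], c[pos]
    if len(t) < 3:
        return LambdaZFit(None, 0, None, None)

    if n_points is not None:
        if n_points < 3 or n_points > len(t):
            return LambdaZFit(None, 0, None, None)
        candidates = [len(t) - n_points]
    else:
        i_tmax = int(np.argmax(c))
        first_start = i_tmax + 1  # exclude tmax
        last_start = len(t) - 3
        if last_start < first_start:
            return LambdaZFit(None, 0, None, None)
        candidates = range(first_start, last_start + 1)

    best: LambdaZFit | None = None
    for start in candidates:
        tt, cc = t[start:], np.log(c[start:])
        if len(set(tt)) < 2:
            continue
        res = stats.linregress(tt, cc)
        n = len(tt)
        r2 = res.rvalue**2
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n > 2 else r2
        if res.slope >= 0:
            continue
        fit = LambdaZFit(-res.slope, n, adj, res.intercept)
        if best is None or (fit.adjusted_r2 > best.adjusted_r2 + 1e-12) or (
            abs(fit.adjusted_r2 - best.adjusted_r2) <= 1e-12
            and fit.n_points > best.n_points
        ):
            best = fit
    return best if best is not None else LambdaZFit(None, 0, None, None)


def _interp_conc(t, c, x: float) -> float:
    """Concentration at time x, log-interpolating on declining segments."""
    i = int(np.searchsorted(t, x))
    if i < len(t) and t[i] == x:
        return float(c[i])
    if i == 0 or i == len(t):
        raise ValidationError(f"time {x} outside profile range [{t[0]}, {t[-1]}]")
    t1, t2, c1, c2 = t[i - 1], t[i], c[i - 1], c[i]
    f = (x - t1) / (t2 - t1)
    if c1 > c2 > 0:
        return float(c1 * (c2 / c1) ** f)
    return float(c1 + f * (c2 - c1))


def auc_trapezoid(profile, t_start: float | None = None, t_end: float | None = None) -> float:
    """Linear-up/log-down trapezoidal AUC over [t_start, t_end].

    Segments with C2 >= C1 or a zero endpoint use the linear rule
    (C1+C2)·Δt/2; declining positive segments use the logarithmic rule
    (C1−C2)·Δt/ln(C1/C2).  Interval endpoints falling inside a sampling
    segment are interpolated and integrated with that segment's own rule,
    which makes the area exactly additive over adjacent intervals.
    """
    t, c = _as_arrays(profile)
    if len(t) < 2:
        return 0.0
    if t_start is None:
        t_start = float(t[0])
    if t_end is None:
        t_end = float(t[-1])
    if t_end < t_start:
        raise ValidationError(f"t_end {t_end} < t_start {t_start}")
    if t_end == t_start:
        return 0.0
    if t_start < t[0] or t_end > t[-1]:
        raise ValidationError(
            f"[{t_start}, {t_end}] outside profile range [{t[0]}, {t[-1]}]"
        )
    total = 0.0
    for i in range(len(t) - 1):
        t1, t2, c1, c2 = t[i], t[i + 1], c[i], c[i + 1]
        a, b = max(t1, t_start), min(t2, t_end)
        if b <= a or t2 == t1:
            continue
        log_rule = c1 > c2 > 0
        if log_rule:
            ca = c1 * (c2 / c1) ** ((a - t1) / (t2 - t1))
            cb = c1 * (c2 / c1) ** ((b - t1) / (t2 - t1))
            lr = math.log(ca) - math.log(cb)  # log(ca/cb) without ratio overflow
            # near-equal endpoints: the log rule degenerates to a rectangle
            total += (ca - cb) * (b - a) / lr if abs(lr) > 1e-12 else ca * (b - a)
        else:
            ca = c1 + (a - t1) / (t2 - t1) * (c2 - c1)
            cb = c1 + (b - t1) / (t2 - t1) * (c2 - c1)
            total += 0.5 * (ca + cb) * (b - a)
    return float(total)


def auc_inf(profile, lz: LambdaZFit | None = None, use_predicted_clast: bool = True):
    """AUC extrapolated to infinity.

    Returns ``(auc_inf, auc_last, pct_extrapolated)``; ``auc_inf`` and the
    percentage are None when λz is not estimable.  The extrapolation tail is
    C_last/λz with C_last taken from the λz regression line at t_last by
    default (``use_predicted_clast=False`` switches to the observed value).
    """
    t, c = _as_arrays(profile)
    if lz is None:
        lz = fit_lambda_z((t, c))
    auc_last = auc_trapezoid((t, c))
    if not lz.estimable:
        return None, auc_last, None
    c_last = lz.predict(t[-1]) if use_predicted_clast else float(c[-1])
    tail = c_last / lz.lambda_z
    total = auc_last + tail
    return float(total), float(auc_last), float(100.0 * tail / total)


def nca_subject(
    times,
    concs,
    dose: float,
    tau: float | None = None,
    subject_id: str = "",
    species: str | None = None,
    lambda_z_points: int | None = None,
) -> NCAResult:
    """Full NCA for one profile given the administered dose (µg)."""
    t, c = _clean_profile(times, concs)
    if len(t) == 0:
        return NCAResult(subject_id, dose, None, None, None, None, None, None,
                         None, 0, None, None, None, species)
    cmax, tmax = compute_cmax_tmax((t, c))
    lz = fit_lambda_z((t, c), n_points=lambda_z_points)
    a_inf, a_last, pct = auc_inf((t, c), lz)
    a_tau = auc_trapezoid((t, c), t[0], t[0] + tau) if tau is not None else None
    return NCAResult(
        subject_id=subject_id,
        dose=dose,
        cmax=cmax,
        tmax=tmax,
        auc_last=a_last,
        auc_inf=a_inf,
        auc_tau=a_tau,
        lambda_z=lz.lambda_z,
        t_half=lz.t_half,
        n_lambda_points=lz.n_points,
        pct_extrapolated=pct,
        dcmax=cmax / dose if cmax is not None and dose > 0 else None,
        dauc=a_inf / dose if a_inf is not None and dose > 0 else None,
        species=species,
    )


def summary_stats(values: Sequence[float]) -> dict:
    """Descriptive statistics: n, mean, sd, CV%, median, geometric mean/CV%, min, max."""
    x = np.asarray([v for v in values if v is not None and np.isfinite(v)], dtype=float)
    out = dict(n=int(len(x)))
    if len(x) == 0:
        return out
    out.update(
        mean=float(np.mean(x)),
        sd=float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
        median=float(np.median(x)),
        min=float(np.min(x)),
        max=float(np.max(x)),
    )
    out["cv_pct"] = 100.0 * out["sd"] / out["mean"] if out["mean"] != 0 else math.nan
    if np.all(x > 0):
        logs = np.log(x)
        out["geomean"] = float(np.exp(np.mean(logs)))
        gsd2 = float(np.var(logs, ddof=1)) if len(x) > 1 else 0.0
        out["geocv_pct"] = 100.0 * math.sqrt(math.exp(gsd2) - 1.0)
    return out


def nca_summary(
    ds: PKDataset,
    per_interval: bool = False,
    interval_mode: str = "first",
    lambda_z_points: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """NCA for every subject of a dataset plus per-group descriptive statistics.

    Multiple-dose subjects are reduced to one dosing interval. With
    ``interval_mode="first"`` (default) the first interval is analysed with
    extrapolation to infinity and the first dose normalizes the exposure;
    ``"steady_state"`` uses AUC_0-τ of the last interval instead.
    BLQ observations are dropped before any computation.
    """
    if interval_mode not in ("first", "steady_state"):
        raise ValidationError(f"unknown interval_mode {interval_mode!r}")
    results: list[NCAResult] = []
    for sid in ds.subjects:
        recs = [r for r in ds.subject_records(sid) if not r.blq]
        doses = ds.subject_doses(sid)
        if not doses:
            continue
        species = recs[0].species if recs else None
        t = np.array([r.time for r in recs])
        c = np.array([r.concentration for r in recs])
        if len(doses) == 1 or not per_interval:
            if len(doses) > 1 and interval_mode == "first":
                end = doses[1].time
                mask = t < end
                t, c = t[mask], c[mask]
            res = nca_subject(t, c, doses[0].amount, subject_id=sid,
                              species=species, lambda_z_points=lambda_z_points)
            if len(doses) > 1 and interval_mode == "steady_state":
                tau = doses[-1].time - doses[-2].time
                last = doses[-1].time
                mask = (t >= last) & (t <= last + tau)
                if mask.sum() >= 2:
                    a_tau = auc_trapezoid((t[mask], c[mask]))
                    res = NCAResult(**{**res.as_dict(), "auc_tau": a_tau,
                                       "dauc": a_tau / doses[-1].amount})
            results.append(res)
        else:
            bounds = [d.time for d in doses] + [math.inf]
            for k, d in enumerate(doses):
                mask = (t >= bounds[k]) & (t < bounds[k + 1])
                if mask.sum() == 0:
                    continue
                res = nca_subject(t[mask] - d.time, c[mask], d.amount,
                                  subject_id=f"{sid}/dose{k + 1}", species=species,
                                  lambda_z_points=lambda_z_points)
                results.append(res)

    table = pd.DataFrame([r.as_dict() for r in results])
    groups: dict = {}
    if len(table):
        for (species, dose), sub in table.groupby(["species", "dose"], dropna=False):
            key = f"{species}/dose={dose:g}"
            groups[key] = {
                col: summary_stats(sub[col].tolist())
                for col in ("cmax", "auc_last", "auc_inf", "t_half", "dcmax", "dauc")
                if col in sub
            }
    return table, groups
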