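"""Concentration-time datasets in a NONMEM-flavoured CSV dialect.

The package works on long-format event records: dose rows (EVID=1, AMT>0)
and observation rows (EVID=0, DV present).  Times are hours since the first
dose of each subject, concentrations are µg/mL and dose amounts are µg of
mRNA-LNP; DCmax (1/mL) and DAUC (h/mL) only cancel correctly when the
concentration and dose share the mass unit.

Default columns: ID, TIME, DV, AMT, DUR, EVID, MDV, WT, SPECIES, BLQ, LLOQ.
A ``schema`` mapping renames nonstandard columns on input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "ConcentrationRecord",
    "DoseEvent",
    "PKDataset",
    "SPECIES_WEIGHTS",
    "read_pk_dataset",
    "write_pk_dataset",
]

#: Typical body weights (kg) used for allometric work.
SPECIES_WEIGHTS: dict[str, float] = {
    "mouse": 0.025,
    "rat": 0.25,
    "nhp": 2.5,
    "human": 70.0,
}

_DEFAULT_SCHEMA = {
    "id": "ID",
    "time": "TIME",
    "dv": "DV",
    "amt": "AMT",
    "dur": "DUR",
    "evid": "EVID",
    "mdv": "MDV",
    "wt": "WT",
    "species": "SPECIES",
    "blq": "BLQ",
    "lloq": "LLOQ",
}

_MANDATORY = ("id", "time", "dv", "amt", "evid", "wt", "species")


@dataclass(frozen=True)
class ConcentrationRecord:
    """One measured translated-antibody concentration.

    ``concentration`` is in µg/mL and is only meaningful when ``blq`` is
    False; BLQ rows keep whatever value was reported (often the LLOQ or 0)
    but are excluded from fitting and NCA slope estimation.
    """

    subject_id: str
    species: str
    body_weight: float
    time: float
    concentration: float
    blq: bool = False
    lloq: float | None = None

    def __post_init__(self) -> None:
        if not self.body_weight > 0:
            raise ValidationError(f"body_weight must be > 0, got {self.body_weight}")
        if self.time < 0:
            raise ValidationError(f"time must be >= 0, got {self.time}")
        if not self.blq and self.concentration < 0:
            raise ValidationError(
                f"concentration must be >= 0 when not BLQ, got {self.concentration}"
            )


@dataclass(frozen=True)
class DoseEvent:
    """An IV dose of mRNA-LNP: ``amount`` µg given over ``duration`` h (0 = bolus)."""

    subject_id: str
    time: float
    amount: float
    duration: float = 0.0

    def __post_init__(self) -> None:
        if not self.amount > 0:
            raise ValidationError(f"dose amount must be > 0, got {self.amount}")
        if self.duration < 0:
            raise ValidationError(f"duration must be >= 0, got {self.duration}")
        if self.time < 0:
            raise ValidationError(f"dose time must be >= 0, got {self.time}")


@dataclass
class PKDataset:
    """A validated collection of concentration records and dose events."""

    records: list[ConcentrationRecord] = field(default_factory=list)
    doses: list[DoseEvent] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        dose_times: dict[str, list[float]] = {}
        for d in self.doses:
            dose_times.setdefault(d.subject_id, []).append(d.time)
        for sid, times in dose_times.items():
            if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
                raise ValidationError(
                    f"dose times for subject {sid!r} must be strictly increasing"
                )
        seen: set[tuple[str, float]] = set()
        last_time: dict[str, float] = {}
        for rec in self.records:
            key = (rec.subject_id, rec.time)
            if key in seen:
                raise ValidationError(
                    f"duplicate observation for subject {rec.subject_id!r} at t={rec.time}"
                )
            seen.add(key)
            if rec.time < last_time.get(rec.subject_id, -math.inf):
                raise ValidationError(
                    f"observations for subject {rec.subject_id!r} not sorted by time"
                )
            last_time[rec.subject_id] = rec.time
            times = dose_times.get(rec.subject_id, [])
            if not any(t <= rec.time for t in times):
                raise ValidationError(
                    f"subject {rec.subject_id!r} has an observation at t={rec.time} "
                    "before any dose"
                )

    # -- convenience accessors -------------------------------------------------

    @property
    def subjects(self) -> list[str]:
        out: list[str] = []
        for d in self.doses:
            if d.subject_id not in out:
                out.append(d.subject_id)
        for r in self.records:
            if r.subject_id not in out:
                out.append(r.subject_id)
        return out

    @property
    def species(self) -> list[str]:
        out: list[str] = []
        for r in self.records:
            if r.species not in out:
                out.append(r.species)
        return out

    def subject_records(self, subject_id: str) -> list[ConcentrationRecord]:
        return [r for r in self.records if r.subject_id == subject_id]

    def subject_doses(self, subject_id: str) -> list[DoseEvent]:
        return [d for d in self.doses if d.subject_id == subject_id]

    def filter_species(self, species: str | Iterable[str]) -> "PKDataset":
        wanted = {species} if isinstance(species, str) else set(species)
        keep = {r.subject_id for r in self.records if r.species in wanted}
        return PKDataset(
            records=[r for r in self.records if r.subject_id in keep],
            doses=[d for d in self.doses if d.subject_id in keep],
            metadata=dict(self.metadata),
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format event table in the canonical column order."""
        rows = []
        for d in self.doses:
            rows.append(
                dict(ID=d.subject_id, TIME=d.time, DV="", AMT=d.amount,
                     DUR=d.duration, EVID=1, MDV=1, WT="", SPECIES="",
                     BLQ=0, LLOQ="")
            )
        for r in self.records:
            rows.append(
                dict(ID=r.subject_id, TIME=r.time, DV=r.concentration, AMT="",
                     DUR="", EVID=0, MDV=0, WT=r.body_weight,
                     SPECIES=r.species, BLQ=int(r.blq),
                     LLOQ="" if r.lloq is None else r.lloq)
            )
        df = pd.DataFrame(rows, columns=list(_DEFAULT_SCHEMA.values()))
        if len(df):
            # stable sort: subject (insertion order), then time, doses first
            order = {sid: i for i, sid in enumerate(self.subjects)}
            df = df.sort_values(
                by=["ID", "TIME", "EVID"],
                key=lambda col: col.map(order) if col.name == "ID" else col,
                kind="stable",
                ascending=[True, True, False],
            ).reset_index(drop=True)
        return df


def _resolve_schema(columns: Sequence[str], schema: Mapping[str, str] | None) -> dict:
    mapping = dict(_DEFAULT_SCHEMA)
    if schema:
        unknown = set(schema) - set(_DEFAULT_SCHEMA)
        if unknown:
            raise SchemaError(f"unknown schema keys: {sorted(unknown)}")
        mapping.update(schema)
    for logical in _MANDATORY:
        if mapping[logical] not in columns:
            raise SchemaError(
                f"missing mandatory column {mapping[logical]!r} (for {logical!r})"
            )
    return mapping


def read_pk_dataset(
    path,
    schema: Mapping[str, str] | None = None,
    concentration_scale: float = 1.0,
) -> PKDataset:
    """Read a NONMEM-style CSV into a validated :class:`PKDataset`.

    Parameters
    ----------
    path : str or file-like
        CSV with a header row.
    schema : mapping, optional
        Maps logical names (``id``, ``time``, ``dv``, ``amt``, ``dur``,
        ``evid``, ``mdv``, ``wt``, ``species``, ``blq``, ``lloq``) to the
        column names actually present.
    concentration_scale : float
        Multiplier applied to DV and LLOQ on input (e.g. 1e-3 for ng/mL
        data to be stored as µg/mL).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    m = _resolve_schema(list(df.columns), schema)

    def _get(row, logical, default=""):
        col = m[logical]
        return row[col] if col in df.columns else default

    records: list[ConcentrationRecord] = []
    doses: list[DoseEvent] = []
    for idx, row in df.iterrows():
        try:
            evid = int(float(_get(row, "evid")))
            time = float(_get(row, "time"))
            sid = str(_get(row, "id"))
            if time < 0:
                raise ValidationError(f"negative time {time}")
            if evid == 1:
                amount = float(_get(row, "amt"))
                dur_raw = _get(row, "dur", "0")
                duration = float(dur_raw) if dur_raw != "" else 0.0
                doses.append(DoseEvent(sid, time, amount, duration))
            else:
                mdv_raw = _get(row, "mdv", "0")
                if mdv_raw != "" and int(float(mdv_raw)) == 1:
                    continue
                wt = float(_get(row, "wt"))
                if wt <= 0:
                    raise ValidationError(f"non-positive body weight {wt}")
                blq_raw = _get(row, "blq", "0")
                blq = blq_raw != "" and int(float(blq_raw)) == 1
                lloq_raw = _get(row, "lloq", "")
                lloq = float(lloq_raw) * concentration_scale if lloq_raw != "" else None
                dv_raw = _get(row, "dv", "")
                conc = float(dv_raw) * concentration_scale if dv_raw != "" else 0.0
                records.append(
                    ConcentrationRecord(
                        sid, str(_get(row, "species")), wt, time, conc, blq, lloq
                    )
                )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"row {idx}: {exc}") from exc
    return PKDataset(records=records, doses=doses)


def write_pk_dataset(ds: PKDataset, path) -> None:
    """Write ``ds`` as CSV; :func:`read_pk_dataset` inverts it exactly."""
    ds.to_frame().to_csv(path, index=False)
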