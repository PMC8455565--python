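"""Domain types and dataset I/O shared by every stage of the pipeline.

Units are fixed package-wide: time in hours, dose amounts in mg, plasma
concentration in ng/mL.  Molar conversion is available explicitly through
:func:`convert_concentration` and nowhere else.

Datasets use the long-format convention of pharmacometric software: one row
per dosing event or observation, identified by subject, time, and record
kind.  Below-quantification (BLQ) observations are retained and flagged so
that downstream consumers (NCA, estimation) can apply their own policy.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "ValidationError",
    "DatasetParseError",
    "DosingRegimen",
    "PKParameters",
    "TurnoverParameters",
    "ObservationRecord",
    "StudyDataset",
    "expand_regimen",
    "convert_concentration",
    "read_dataset",
    "write_dataset",
]

RECORD_KINDS = ("dose", "concentration", "free_btk", "total_btk")


class ValidationError(ValueError):
    """A domain object violated one of its invariants."""


class DatasetParseError(ValueError):
    """A dataset file could not be parsed; the message names the line."""


@dataclass(frozen=True)
class DosingRegimen:
    """Repeated oral dosing schedule (QD, BID, or arbitrary interval).

    Parameters
    ----------
    dose_amount : float
        Amount per administration, mg.
    n_doses : int
        Number of administrations (>= 1).
    interval : float
        Inter-dose interval, h.  Ignored when ``n_doses == 1``.
    start_time : float
        Time of the first dose, h.
    """

    dose_amount: float
    n_doses: int = 1
    interval: float = 24.0
    start_time: float = 0.0
    route: str = "oral"

    def __post_init__(self) -> None:
        if self.dose_amount <= 0:
            raise ValidationError(f"dose_amount must be > 0, got {self.dose_amount}")
        if self.n_doses < 1:
            raise ValidationError(f"n_doses must be >= 1, got {self.n_doses}")
        if self.n_doses > 1 and self.interval <= 0:
            raise ValidationError("interval must be > 0 for multiple dosing")
        if self.route != "oral":
            raise ValidationError(f"only the oral route is supported, got {self.route!r}")

    @property
    def last_dose_time(self) -> float:
        return self.start_time + (self.n_doses - 1) * self.interval


@dataclass(frozen=True)
class PKParameters:
    """Two-compartment disposition with an n-transit absorption chain.

    CL and Q are clearances (L/h); Vc and Vp volumes (L); F the absolute
    oral bioavailability; ktr the transit rate constant (1/h).  With
    ``n_transit == 0`` absorption collapses to a single first-order depot
    with rate ktr.
    """

    CL: float
    Vc: float
    Q: float
    Vp: float
    ktr: float
    F: float = 1.0
    n_transit: int = 3

    def __post_init__(self) -> None:
        for name in ("CL", "Vc", "Q", "Vp", "ktr"):
            v = getattr(self, name)
            if not (v >= 0) or not math.isfinite(v):
                raise ValidationError(f"{name} must be finite and >= 0, got {v}")
        if self.CL <= 0 or self.Vc <= 0 or self.ktr <= 0:
            raise ValidationError("CL, Vc and ktr must be strictly positive")
        if (self.Q > 0) != (self.Vp > 0):
            raise ValidationError("Q and Vp must both be zero or both positive")
        if not 0 < self.F <= 1:
            raise ValidationError(f"F must lie in (0, 1], got {self.F}")
        if self.n_transit < 0:
            raise ValidationError(f"n_transit must be >= 0, got {self.n_transit}")

    def with_updates(self, **kwargs: float) -> "PKParameters":
        return replace(self, **kwargs)

    @classmethod
    def default_human(cls) -> "PKParameters":
        """Illustrative healthy-volunteer parameter set.

        Chosen to reproduce the qualitative clinical behaviour of a rapidly
        absorbed, moderately distributed oral kinase inhibitor: Tmax in the
        1-2 h range, visible accumulation on twice-daily dosing, and troughs
        that fall below a 0.5 ng/mL quantification limit at low doses.  Not
        a fitted estimate.
        """
        return cls(CL=60.0, Vc=100.0, Q=20.0, Vp=200.0, ktr=8.0, F=0.3, n_transit=3)

    @classmethod
    def default_rat(cls) -> "PKParameters":
        """Illustrative rat parameter set scaled so that a 0.15 mg oral dose
        (1 mg/kg at 150 g body weight) produces exposures of the order of
        10 ng.h/mL with Tmax under 1.5 h."""
        return cls(CL=1.5, Vc=0.8, Q=0.4, Vp=2.0, ktr=6.0, F=0.1, n_transit=3)


@dataclass(frozen=True)
class TurnoverParameters:
    """Free-target turnover with irreversible second-order drug binding.

    ksyn : zero-order synthesis rate (a.u./h)
    kdeg : first-order degradation rate of free and bound target (1/h)
    kbind : second-order inactivation rate constant ((ng/mL)^-1 h^-1)

    Baseline free target is ksyn/kdeg; with the default normalisation
    ksyn == kdeg the baseline pool is 1.0 and only ratios are meaningful.
    """

    ksyn: float
    kdeg: float
    kbind: float

    def __post_init__(self) -> None:
        for name in ("ksyn", "kdeg", "kbind"):
            v = getattr(self, name)
            if v < 0 or not math.isfinite(v):
                raise ValidationError(f"{name} must be finite and >= 0, got {v}")

    @property
    def baseline(self) -> float:
        """Baseline free-target level ksyn/kdeg."""
        if self.kdeg <= 0:
            raise ValidationError("baseline undefined: kdeg must be > 0")
        return self.ksyn / self.kdeg

    @classmethod
    def default_human(cls) -> "TurnoverParameters":
        """Illustrative turnover set: target half-life of ~3 days (slow
        resynthesis, the signature of covalent-inhibitor PD persistence) and
        a binding rate that saturates occupancy within hours at tens of
        ng/mL.  Normalised to baseline 1.0."""
        return cls(ksyn=0.01, kdeg=0.01, kbind=0.02)


@dataclass(frozen=True)
class ObservationRecord:
    """One long-format row: a dose event or an observation."""

    subject_id: str
    time: float
    kind: str
    value: float
    blq_flag: bool = False
    dose_group: str = ""

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValidationError(f"time must be >= 0, got {self.time}")
        if self.kind not in RECORD_KINDS:
            raise ValidationError(f"unknown record kind {self.kind!r}")
        if self.kind == "dose" and self.blq_flag:
            raise ValidationError("dose records cannot be BLQ-flagged")
        if self.value < 0 and not self.blq_flag:
            raise ValidationError(
                f"negative value {self.value} requires a BLQ flag"
            )


@dataclass
class StudyDataset:
    """Ordered collection of dose and observation records with an LLOQ."""

    records: list[ObservationRecord]
    lloq: float = 0.5
    units_note: str = "time h; dose mg; concentration ng/mL; BTK arbitrary units"

    def __post_init__(self) -> None:
        if self.lloq <= 0:
            raise ValidationError(f"lloq must be > 0, got {self.lloq}")
        self.records = sorted(
            self.records, key=lambda r: (r.subject_id, r.time, r.kind != "dose")
        )
        self._flag_blq()

    def _flag_blq(self) -> None:
        flagged = []
        for r in self.records:
            if r.kind == "concentration" and r.value < self.lloq and not r.blq_flag:
                r = replace(r, blq_flag=True)
            flagged.append(r)
        self.records = flagged

    def __len__(self) -> int:
        return len(self.records)

    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.subject_id, None)
        return list(seen)

    def for_subject(self, subject_id: str) -> "StudyDataset":
        recs = [r for r in self.records if r.subject_id == subject_id]
        return StudyDataset(records=recs, lloq=self.lloq, units_note=self.units_note)

    def of_kind(self, kind: str) -> list[ObservationRecord]:
        return [r for r in self.records if r.kind == kind]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "id": [r.subject_id for r in self.records],
                "time": [r.time for r in self.records],
                "kind": [r.kind for r in self.records],
                "amt": [r.value if r.kind == "dose" else math.nan for r in self.records],
                "dv": [math.nan if r.kind == "dose" else r.value for r in self.records],
                "blq": [int(r.blq_flag) for r in self.records],
                "group": [r.dose_group for r in self.records],
            }
        )


def expand_regimen(regimen: DosingRegimen) -> list[tuple[float, float]]:
    """Expand a regimen into explicit ``(time, amount)`` dose events."""
    return [
        (regimen.start_time + k * regimen.interval, regimen.dose_amount)
        for k in range(regimen.n_doses)
    ]


def convert_concentration(value: float, molecular_weight: float) -> float:
    """Convert a mass concentration in ng/mL to a molar one in nM.

    ng/mL equals ug/L, so dividing by the molecular weight (g/mol) and
    scaling by 1000 yields nmol/L.
    """
    if molecular_weight <= 0:
        raise ValidationError(f"molecular_weight must be > 0, got {molecular_weight}")
    if value < 0:
        raise ValidationError(f"concentration must be >= 0, got {value}")
    return value / molecular_weight * 1000.0


_MISSING = {"", ".", "na", "nan", "none"}


def _parse_float(token: str, line_no: int, col: str) -> float | None:
    token = token.strip()
    if token.lower() in _MISSING:
        return None
    try:
        return float(token)
    except ValueError:
        raise DatasetParseError(
            f"line {line_no}: column {col!r} has non-numeric value {token!r}"
        ) from None


def read_dataset(path: str | Path | io.TextIOBase, lloq: float = 0.5) -> StudyDataset:
    """Read a long-format CSV dataset.

    Expected header columns: ``id,time,kind,amt,dv,blq`` with optional
    ``group``; ``evid`` (1 = dose) is accepted in place of ``kind``.  ``.``
    marks a missing value, following the common pharmacometric convention.
    Lines starting with ``#`` are provenance comments and skipped.
    """
    import csv

    if isinstance(path, io.TextIOBase):
        lines = path.read().splitlines()
        source = "<stream>"
    else:
        source = str(path)
        lines = Path(path).read_text().splitlines()

    rows = [(i + 1, ln) for i, ln in enumerate(lines) if ln.strip() and not ln.lstrip().startswith("#")]
    if not rows:
        raise DatasetParseError(f"{source}: no records")

    header_line = rows[0][1]
    header = [h.strip().lower() for h in next(csv.reader([header_line]))]
    required = {"id", "time"}
    if not required.issubset(header):
        raise DatasetParseError(f"{source}: header must contain columns id and time")
    if "kind" not in header and "evid" not in header:
        raise DatasetParseError(f"{source}: header must contain 'kind' or 'evid'")
    idx = {name: header.index(name) for name in header}

    records: list[ObservationRecord] = []
    for line_no, line in rows[1:]:
        fields = next(csv.reader([line]))
        if len(fields) != len(header):
            raise DatasetParseError(
                f"line {line_no}: expected {len(header)} fields, got {len(fields)}"
            )

        def get(col: str) -> str:
            return fields[idx[col]] if col in idx else ""

        time = _parse_float(get("time"), line_no, "time")
        if time is None:
            raise DatasetParseError(f"line {line_no}: missing time")
        if time < 0:
            raise ValidationError(f"line {line_no}: negative time {time}")

        if "kind" in idx and get("kind").strip() not in _MISSING:
            kind = get("kind").strip().lower()
        else:
            evid = _parse_float(get("evid"), line_no, "evid") or 0
            kind = "dose" if int(evid) == 1 else "concentration"
        if kind not in RECORD_KINDS:
            raise DatasetParseError(f"line {line_no}: unknown kind {kind!r}")

        amt = _parse_float(get("amt"), line_no, "amt")
        dv = _parse_float(get("dv"), line_no, "dv")
        blq_raw = _parse_float(get("blq"), line_no, "blq")
        blq = bool(blq_raw) if blq_raw is not None else False

        if kind == "dose":
            if amt is None:
                raise DatasetParseError(f"line {line_no}: dose record missing amt")
            value = amt
            blq = False
        else:
            if dv is None:
                if blq:
                    value = 0.0  # censored with unreported value
                else:
                    raise DatasetParseError(
                        f"line {line_no}: observation missing dv and not BLQ-flagged"
                    )
            else:
                value = dv
        try:
            records.append(
                ObservationRecord(
                    subject_id=get("id").strip(),
                    time=time,
                    kind=kind,
                    value=value,
                    blq_flag=blq,
                    dose_group=get("group").strip(),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"line {line_no}: {exc}") from None

    if not records:
        raise DatasetParseError(f"{source}: no records")
    return StudyDataset(records=records, lloq=lloq)


def write_dataset(dataset: StudyDataset, path: str | Path, header_comment: str | None = None) -> None:
    """Write a dataset as long-format CSV (inverse of :func:`read_dataset`)."""
    frame = dataset.to_frame()
    with open(path, "w") as fh:
        if header_comment:
            for ln in header_comment.splitlines():
                fh.write(f"# {ln}\n")
        frame.to_csv(fh, index=False, na_rep=".")
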