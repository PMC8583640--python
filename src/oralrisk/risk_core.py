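"""Deterministic oral-exposure risk arithmetic.

The chain implemented here is the standard US EPA ingestion model:

    ADD = C * IngR * EF * ED / (BW * AT) * (unit conversion)
    HQ  = ADD / RfD
    HI  = sum of HQ over exposure pathways (one substance)
    HIt = sum of HI over substances

with the non-carcinogenic convention AT = ED * 365 days, which makes the
EF*ED/AT factor exactly 1 when EF = 365 days/year.

Each pathway owns its unit conversion to mg/day of ingested metal:

* soil  — concentration mg/kg, intake mg/day  -> factor 1e-6
* food  — concentration mg/kg, intake g/day   -> factor 1e-3
* water — concentration ng/mL (== ug/L), intake mL/day -> factor 1e-6

All quantities are plain floats (or numpy arrays, which every operation
accepts element-wise); results are never rounded internally.  Two-significant
-figure presentation rounding (half away from zero) is available separately
as :func:`round_sig`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Metal",
    "Pathway",
    "ExposureFactors",
    "ConcentrationRecord",
    "RfDTable",
    "RiskRecord",
    "RiskSummary",
    "average_daily_dose",
    "hazard_quotient",
    "hazard_index",
    "total_hazard_index",
    "contribution_fractions",
    "risk_table",
    "assess_child",
    "assess_cohort",
    "pathway_contribution_report",
    "percentile",
    "round_sig",
]


class Metal(enum.Enum):
    """The five metal(loid)s assessed: Mn, Pb, Cr, Cd and As."""

    Mn = "Mn"
    Pb = "Pb"
    Cr = "Cr"
    Cd = "Cd"
    As = "As"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Pathway(enum.Enum):
    """Oral exposure pathway, carrying its native units and dose conversion.

    ``dose_factor`` converts (concentration in native unit) x (intake in
    native unit) into mg of metal per day.
    """

    food = ("food", "mg/kg", "g/day", 1e-3)
    water = ("water", "ng/mL", "mL/day", 1e-6)
    soil = ("soil", "mg/kg", "mg/day", 1e-6)

    def __new__(cls, value, conc_unit, intake_unit, dose_factor):
        obj = object.__new__(cls)
        obj._value_ = value
        obj.concentration_unit = conc_unit
        obj.intake_unit = intake_unit
        obj.dose_factor = dose_factor
        return obj

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


PATHWAYS: tuple[Pathway, ...] = (Pathway.food, Pathway.water, Pathway.soil)
METALS: tuple[Metal, ...] = tuple(Metal)


@dataclass
class ExposureFactors:
    """Per-child (or per-group) ingestion exposure factors.

    Parameters
    ----------
    body_weight
        BW in kg; must be positive.
    intake
        Map of :class:`Pathway` to ingestion rate in the pathway's native
        unit (food g/day, soil mg/day, water mL/day); rates must be >= 0.
    exposure_frequency
        EF in days/year, in (0, 365]; default 365.
    exposure_duration
        ED in years; default 6.
    averaging_time
        AT in days.  For non-carcinogenic risk AT = ED * 365, which is the
        default when omitted.
    """

    body_weight: float
    intake: Mapping[Pathway, float]
    exposure_frequency: float = 365.0
    exposure_duration: float = 6.0
    averaging_time: float | None = None

    def __post_init__(self) -> None:
        if not self.body_weight > 0:
            raise ValueError(
                f"body weight must be positive, got {self.body_weight!r}"
            )
        for pw, rate in self.intake.items():
            if not isinstance(pw, Pathway):
                raise ValueError(f"unknown pathway {pw!r}")
            if rate < 0:
                raise ValueError(f"intake rate for {pw} must be >= 0, got {rate}")
        if not 0 < self.exposure_frequency <= 365:
            raise ValueError(
                f"exposure frequency must lie in (0, 365], got {self.exposure_frequency}"
            )
        if self.exposure_duration <= 0:
            raise ValueError("exposure duration must be positive")
        if self.averaging_time is None:
            self.averaging_time = self.exposure_duration * 365.0
        if self.averaging_time <= 0:
            raise ValueError("averaging time must be positive")


@dataclass(frozen=True)
class ConcentrationRecord:
    """A single (metal, pathway) concentration in the pathway's native unit."""

    metal: Metal
    pathway: Pathway
    value: float
    nondetect: bool = False

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(
                f"concentration must be >= 0, got {self.value} for "
                f"{self.metal}/{self.pathway}"
            )


class RfDTable:
    """Oral reference doses (mg/kg/day), complete over the 5x3 grid."""

    def __init__(self, entries: Mapping[tuple[Metal, Pathway], float]):
        missing = [
            (m, p) for m in METALS for p in PATHWAYS if (m, p) not in entries
        ]
        if missing:
            raise ValueError(f"RfD table incomplete, missing cells: {missing}")
        for key, value in entries.items():
            if not value > 0:
                raise ValueError(f"RfD must be positive, got {value} for {key}")
        self._entries = dict(entries)

    def __call__(self, metal: Metal, pathway: Pathway) -> float:
        try:
            return self._entries[(metal, pathway)]
        except KeyError:
            raise KeyError(f"no RfD for ({metal}, {pathway})") from None

    def items(self):
        return self._entries.items()

    def __eq__(self, other) -> bool:
        return isinstance(other, RfDTable) and self._entries == other._entries


@dataclass(frozen=True)
class RiskRecord:
    """Per-child ADD (mg/kg/day) and HQ for one (metal, pathway)."""

    child_id: str
    metal: Metal
    pathway: Pathway
    add: float
    hq: float


def average_daily_dose(conc: ConcentrationRecord, factors: ExposureFactors):
    """Average daily dose through one ingestion pathway, mg/kg/day.

    ADD = C x IngR x EF x ED / (BW x AT), with the pathway-specific unit
    conversion folded in.  With the defaults EF=365 and AT=ED*365 the time
    factor is exactly 1 and the dose reduces to C x IngR x k / BW.
    """
    pathway = conc.pathway
    if pathway not in factors.intake:
        raise ValueError(f"no intake rate supplied for pathway {pathway}")
    ingr = factors.intake[pathway]
    time_factor = (
        factors.exposure_frequency
        * factors.exposure_duration
        / factors.averaging_time
    )
    return (
        conc.value
        * ingr
        * pathway.dose_factor
        * time_factor
        / factors.body_weight
    )


def hazard_quotient(add, metal: Metal, pathway: Pathway, rfd_table: RfDTable):
    """HQ = ADD / RfD (dimensionless).  HQ <= 1 is read as no appreciable
    non-carcinogenic concern."""
    add_arr = np.asarray(add)
    if np.any(add_arr < 0):
        raise ValueError("ADD must be >= 0")
    return add / rfd_table(metal, pathway)


def hazard_index(hqs: Sequence[float]) -> float:
    """HI: arithmetic sum of one substance's HQs across pathways."""
    hqs = list(hqs)
    if not hqs:
        raise ValueError("hazard_index requires at least one HQ")
    if any(h < 0 for h in hqs):
        raise ValueError("HQ values must be >= 0")
    return float(sum(hqs))


def total_hazard_index(his: Sequence[float]) -> float:
    """HIt: arithmetic sum of per-substance HIs."""
    his = list(his)
    if not his:
        raise ValueError("total_hazard_index requires at least one HI")
    if any(h < 0 for h in his):
        raise ValueError("HI values must be >= 0")
    return float(sum(his))


def contribution_fractions(values: Mapping) -> dict:
    """Normalise a map of nonnegative doses (or risks) to fractions of the sum.

    Fractions are each in [0, 1] and sum to 1 to within 1e-12.  An all-zero
    or negative input is rejected.
    """
    if any(v < 0 for v in values.values()):
        raise ValueError("contributions require nonnegative inputs")
    total = float(sum(values.values()))
    if total <= 0:
        raise ValueError("cannot form contribution fractions of an all-zero map")
    return {k: v / total for k, v in values.items()}


def percentile(values, q):
    """Shared percentile definition: linear interpolation between closest
    ranks, inclusive of the extremes (numpy's 'linear' method)."""
    return np.percentile(np.asarray(values, dtype=float), q, method="linear")


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures, half away from zero.

    Used only for presentation; raw doubles are retained everywhere else.
    """
    if x == 0 or not np.isfinite(x):
        return float(x)
    d = Decimal(repr(float(x)))
    shifted = d.scaleb(-d.adjusted())
    q = shifted.quantize(Decimal(1).scaleb(-(sig - 1)), rounding=ROUND_HALF_UP)
    return float(q.scaleb(d.adjusted()))


TOTAL_LABEL = "Total"
SUM_LABEL = "Sum"


@dataclass
class RiskSummary:
    """Cohort percentile grid of HQ/HI/HIt values.

    ``table`` is indexed by metal (plus a ``Total`` row) with a column
    MultiIndex (percentile, pathway-or-``Sum``).  Aggregates are formed per
    child *before* percentiles are taken (percentile-of-sums).
    """

    table: pd.DataFrame
    percentiles: tuple[float, ...] = (5, 50, 95)

    def value(self, metal, pathway, pct) -> float:
        m = metal.value if isinstance(metal, Metal) else str(metal)
        p = pathway.value if isinstance(pathway, Pathway) else str(pathway)
        return float(self.table.loc[m, (pct, p)])

    def rounded(self, sig: int = 2) -> pd.DataFrame:
        return self.table.map(lambda v: round_sig(v, sig))


def _records_frame(records: Iterable[RiskRecord]) -> pd.DataFrame:
    rows = [
        {
            "child_id": r.child_id,
            "metal": r.metal.value,
            "pathway": r.pathway.value,
            "add": r.add,
            "hq": r.hq,
        }
        for r in records
    ]
    if not rows:
        raise ValueError("no risk records supplied")
    return pd.DataFrame(rows)


def risk_table(
    records: Iterable[RiskRecord],
    percentiles: Sequence[float] = (5, 50, 95),
) -> RiskSummary:
    """Cohort percentile summary of HQs with per-child aggregation.

    For every child, pathway sums (HI per metal) and the metal sums
    (per-pathway totals and the overall HIt) are computed first; cohort
    percentiles are then taken cell-wise across children.  This is
    percentile-of-sums, which is what a per-subject risk table reports —
    summing cohort percentiles would overstate the extremes.
    """
    df = _records_frame(records)
    wide = df.pivot_table(
        index="child_id", columns=["metal", "pathway"], values="hq", aggfunc="sum"
    )
    metals = [m.value for m in METALS]
    pathways = [p.value for p in PATHWAYS]
    cells: dict[tuple[float, str], dict[str, float]] = {}
    per_child = {}
    for m in metals:
        for p in pathways:
            col = wide[(m, p)] if (m, p) in wide.columns else pd.Series(0.0, index=wide.index)
            per_child[(m, p)] = col.fillna(0.0)
    for m in metals:
        per_child[(m, SUM_LABEL)] = sum(per_child[(m, p)] for p in pathways)
    for p in pathways + [SUM_LABEL]:
        per_child[(TOTAL_LABEL, p)] = sum(per_child[(m, p)] for m in metals)

    index = metals + [TOTAL_LABEL]
    columns = pd.MultiIndex.from_product(
        [list(percentiles), pathways + [SUM_LABEL]], names=["percentile", "pathway"]
    )
    out = pd.DataFrame(index=index, columns=columns, dtype=float)
    for (m, p), series in per_child.items():
        vals = percentile(series.to_numpy(), list(percentiles))
        for q, v in zip(percentiles, np.atleast_1d(vals)):
            out.loc[m, (q, p)] = v
    return RiskSummary(table=out, percentiles=tuple(percentiles))


def assess_child(
    child_id: str,
    factors: ExposureFactors,
    concentrations: Iterable[ConcentrationRecord],
    rfd_table: RfDTable,
) -> list[RiskRecord]:
    """Run the ADD -> HQ chain for one child over all its concentration records."""
    records = []
    for conc in concentrations:
        add = average_daily_dose(conc, factors)
        hq = hazard_quotient(add, conc.metal, conc.pathway, rfd_table)
        records.append(
            RiskRecord(
                child_id=child_id,
                metal=conc.metal,
                pathway=conc.pathway,
                add=float(add),
                hq=float(hq),
            )
        )
    return records


def assess_cohort(children, rfd_table: RfDTable) -> list[RiskRecord]:
    """Assess every child in a cohort (objects exposing ``child_id``,
    ``factors`` and ``concentrations``)."""
    records: list[RiskRecord] = []
    for child in children:
        records.extend(
            assess_child(child.child_id, child.factors, child.concentrations, rfd_table)
        )
    return records


def pathway_contribution_report(records: Iterable[RiskRecord]) -> pd.DataFrame:
    """Per-metal pathway contributions to the oral dose, cohort level.

    For each metal the cohort *median* ADD per pathway is computed and
    normalised with :func:`contribution_fractions`; medians match how this
    kind of skewed exposure data is conventionally summarised.
    """
    df = _records_frame(records)
    rows = {}
    for m, sub in df.groupby("metal"):
        med = {
            p.value: float(sub.loc[sub["pathway"] == p.value, "add"].median())
            for p in PATHWAYS
        }
        rows[m] = contribution_fractions(med)
    out = pd.DataFrame(rows).T
    return out.reindex(index=[m.value for m in METALS], columns=[p.value for p in PATHWAYS])
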