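"""WHO toxic-equivalency (TEQ) arithmetic over dioxin congener measurements.

Each congener concentration (pg/g lipid) is weighted by its WHO toxic
equivalency factor (TEF) and summed. Non-detects are imputed at zero, half
the detection limit, or the full limit, per policy. Both the WHO-1998 and
WHO-2005 TEF schemes ship with the package; WHO-1998 is the default, being
the scheme in force when serum protocols of the study era were run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

FAMILIES = ("PCDD", "PCDF", "PCB")

ND_POLICIES = ("zero", "half", "full")

WHO1998_TEF = {
    # PCDDs
    "2378-TCDD": 1.0,
    "12378-PeCDD": 1.0,
    "123478-HxCDD": 0.1,
    "123678-HxCDD": 0.1,
    "123789-HxCDD": 0.1,
    "1234678-HpCDD": 0.01,
    "OCDD": 0.0001,
    # PCDFs
    "2378-TCDF": 0.1,
    "12378-PeCDF": 0.05,
    "23478-PeCDF": 0.5,
    "123478-HxCDF": 0.1,
    "123678-HxCDF": 0.1,
    "123789-HxCDF": 0.1,
    "234678-HxCDF": 0.1,
    "1234678-HpCDF": 0.01,
    "1234789-HpCDF": 0.01,
    "OCDF": 0.0001,
    # dioxin-like PCBs
    "PCB77": 0.0001,
    "PCB81": 0.0001,
    "PCB126": 0.1,
    "PCB169": 0.01,
    "PCB105": 0.0001,
    "PCB114": 0.0005,
    "PCB118": 0.0001,
    "PCB123": 0.0001,
    "PCB156": 0.0005,
    "PCB157": 0.0005,
    "PCB167": 0.00001,
    "PCB189": 0.0001,
}

WHO2005_TEF = {
    "2378-TCDD": 1.0,
    "12378-PeCDD": 1.0,
    "123478-HxCDD": 0.1,
    "123678-HxCDD": 0.1,
    "123789-HxCDD": 0.1,
    "1234678-HpCDD": 0.01,
    "OCDD": 0.0003,
    "2378-TCDF": 0.1,
    "12378-PeCDF": 0.03,
    "23478-PeCDF": 0.3,
    "123478-HxCDF": 0.1,
    "123678-HxCDF": 0.1,
    "123789-HxCDF": 0.1,
    "234678-HxCDF": 0.1,
    "1234678-HpCDF": 0.01,
    "1234789-HpCDF": 0.01,
    "OCDF": 0.0003,
    "PCB77": 0.0001,
    "PCB81": 0.0003,
    "PCB126": 0.1,
    "PCB169": 0.03,
    "PCB105": 0.00003,
    "PCB114": 0.00003,
    "PCB118": 0.00003,
    "PCB123": 0.00003,
    "PCB156": 0.00003,
    "PCB157": 0.00003,
    "PCB167": 0.00003,
    "PCB189": 0.00003,
}

TEF_SCHEMES = {"who1998": WHO1998_TEF, "who2005": WHO2005_TEF}

#: Serum congener panel of the exposed father (pg/g lipid): 7 PCDDs,
#: 10 PCDFs and 12 dioxin-like PCBs; n.d. rows carry their detection limit.
FATHER_SERUM_PANEL: list[tuple[str, str, Optional[float], Optional[float]]] = [
    # (congener, family, concentration or None, detection limit or None)
    ("2378-TCDD", "PCDD", 87.0, None),
    ("12378-PeCDD", "PCDD", 12.0, None),
    ("123478-HxCDD", "PCDD", 9.0, None),
    ("123678-HxCDD", "PCDD", 33.0, None),
    ("123789-HxCDD", "PCDD", 8.2, None),
    ("1234678-HpCDD", "PCDD", 35.0, None),
    ("OCDD", "PCDD", 385.0, None),
    ("2378-TCDF", "PCDF", 3.2, None),
    ("12378-PeCDF", "PCDF", 2.8, None),
    ("23478-PeCDF", "PCDF", 9.6, None),
    ("123478-HxCDF", "PCDF", 27.0, None),
    ("123678-HxCDF", "PCDF", 15.0, None),
    ("123789-HxCDF", "PCDF", None, 3.0),
    ("234678-HxCDF", "PCDF", 8.4, None),
    ("1234678-HpCDF", "PCDF", 18.0, None),
    ("1234789-HpCDF", "PCDF", None, 4.0),
    ("OCDF", "PCDF", None, 13.0),
    ("PCB77", "PCB", None, 690.0),
    ("PCB81", "PCB", None, 29.0),
    ("PCB126", "PCB", 123.0, None),
    ("PCB169", "PCB", 61.0, None),
    ("PCB105", "PCB", 5005.0, None),
    ("PCB114", "PCB", 742.0, None),
    ("PCB118", "PCB", 22592.0, None),
    ("PCB123", "PCB", 244.0, None),
    ("PCB156", "PCB", 5873.0, None),
    ("PCB157", "PCB", 1579.0, None),
    ("PCB167", "PCB", 2883.0, None),
    ("PCB189", "PCB", 938.0, None),
]


@dataclass(frozen=True)
class CongenerMeasurement:
    congener: str
    family: str
    concentration: float  # pg/g lipid; 0 for non-detects (limit carried apart)
    detected: bool
    detection_limit: Optional[float] = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown congener family {self.family!r}")
        if self.detected and self.concentration < 0:
            raise ValueError(f"{self.congener}: negative concentration")
        if not self.detected and self.detection_limit is None:
            raise ValueError(f"{self.congener}: non-detect without detection limit")

    def effective_concentration(self, nd_policy: str) -> float:
        if self.detected:
            return self.concentration
        limit = float(self.detection_limit)  # type: ignore[arg-type]
        if nd_policy == "zero":
            return 0.0
        if nd_policy == "half":
            return limit / 2.0
        if nd_policy == "full":
            return limit
        raise ValueError(f"unknown nd_policy {nd_policy!r}")


@dataclass
class TeqResult:
    scheme: str
    nd_policy: str
    contributions: dict[str, float]  # congener -> pg TEQ/g
    family_of: dict[str, str] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return sum(self.contributions.values())

    def family_total(self, family: str) -> float:
        return sum(
            c for name, c in self.contributions.items() if self.family_of[name] == family
        )

    def report(self) -> dict:
        return {
            "scheme": self.scheme,
            "nd_policy": self.nd_policy,
            "contributions": dict(self.contributions),
            "family_totals": {f: self.family_total(f) for f in FAMILIES},
            "total": self.total,
        }


def father_serum_measurements() -> list[CongenerMeasurement]:
    """The packaged serum congener panel as measurement objects."""
    out = []
    for congener, family, conc, limit in FATHER_SERUM_PANEL:
        detected = conc is not None
        out.append(
            CongenerMeasurement(
                congener=congener,
                family=family,
                concentration=conc if detected else 0.0,
                detected=detected,
                detection_limit=limit,
            )
        )
    return out


def measurements_from_frame(df: pd.DataFrame) -> list[CongenerMeasurement]:
    out = []
    for row in df.itertuples(index=False):
        limit = None if pd.isna(row.detection_limit) else float(row.detection_limit)
        conc = 0.0 if pd.isna(row.concentration) else float(row.concentration)
        out.append(
            CongenerMeasurement(
                congener=str(row.congener),
                family=str(row.family),
                concentration=conc,
                detected=bool(row.detected),
                detection_limit=limit,
            )
        )
    return out


def measurements_to_frame(measurements: Sequence[CongenerMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "congener": [m.congener for m in measurements],
            "family": [m.family for m in measurements],
            "concentration": [m.concentration if m.detected else None for m in measurements],
            "detected": [m.detected for m in measurements],
            "detection_limit": [m.detection_limit for m in measurements],
        }
    )


def _select(
    measurements: Iterable[CongenerMeasurement], families: Optional[Sequence[str]]
) -> list[CongenerMeasurement]:
    if families is None:
        return list(measurements)
    wanted = {f.upper() for f in families}
    unknown = wanted - set(FAMILIES)
    if unknown:
        raise ValueError(f"unknown families {sorted(unknown)}")
    return [m for m in measurements if m.family in wanted]


def compute_teq(
    measurements: Sequence[CongenerMeasurement],
    scheme: str = "who1998",
    nd_policy: str = "half",
    families: Optional[Sequence[str]] = ("PCDD", "PCDF"),
) -> TeqResult:
    """TEF-weighted sum over the selected congener families.

    Raises if any selected congener lacks a TEF in the chosen scheme.
    """
    if nd_policy not in ND_POLICIES:
        raise ValueError(f"unknown nd_policy {nd_policy!r}")
    tefs = TEF_SCHEMES.get(scheme.lower())
    if tefs is None:
        raise ValueError(f"unknown TEF scheme {scheme!r}")
    selected = _select(measurements, families)
    contributions: dict[str, float] = {}
    family_of: dict[str, str] = {}
    for m in selected:
        if m.congener not in tefs:
            raise KeyError(f"no {scheme} TEF for congener {m.congener!r}")
        contributions[m.congener] = m.effective_concentration(nd_policy) * tefs[m.congener]
        family_of[m.congener] = m.family
    return TeqResult(
        scheme=scheme.lower(),
        nd_policy=nd_policy,
        contributions=contributions,
        family_of=family_of,
    )


def congener_share(
    result: TeqResult, subset: Sequence[str]
) -> Optional[tuple[float, float]]:
    """(summed TEQ in ppt, percent of grand total) for a congener subset."""
    missing = [c for c in subset if c not in result.contributions]
    if missing:
        raise KeyError(f"congeners not in result: {missing}")
    total = result.total
    if total == 0:
        return None
    ppt = sum(result.contributions[c] for c in subset)
    return ppt, 100.0 * ppt / total


def sum_concentrations(
    measurements: Sequence[CongenerMeasurement],
    families: Optional[Sequence[str]] = ("PCDD", "PCDF"),
    nd_policy: str = "zero",
) -> float:
    """Plain (unweighted) concentration sum over the selected families."""
    if nd_policy not in ND_POLICIES:
        raise ValueError(f"unknown nd_policy {nd_policy!r}")
    return sum(m.effective_concentration(nd_policy) for m in _select(measurements, families))
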