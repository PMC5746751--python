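"""Gel (S) vs liquid-disordered (Ld) phase classification.

Six per-property thresholds separate the two phases of CmTMA+/CnS- bilayers
at 298 K: a system votes gel when its area per complex is below 0.45 nm^2,
its area expansion modulus above 700 mN/m, its tilt modulus above
10 J/mol/deg^2, its effective bending rigidity above 20 k_B T, its
middle-segment |S_CD| above 0.31, and its middle-segment gauche fraction
below 0.15 (all strict; boundary equality votes Ld).  The overall call is a
majority vote, tie-broken by the area-per-complex vote — area is the most
cleanly separated single criterion.  The composition rule ``gel iff
min(m, n) >= 12`` summarizes the observed phase boundary and serves as the
expected label in reports.

A transcription of the reference survey (16 m-n combinations with measured
properties) ships as package data; :func:`load_reference_table` returns it
as a DataFrame and :func:`build_report` reproduces its classification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .model import IPAComposition

PROPERTIES = ("a_ipa", "k_a", "chi_tilt", "kc_eff", "abs_scd", "gauche")

GEL = "S"
FLUID = "Ld"


@dataclass(frozen=True)
class Thresholds:
    """Phase-boundary constants separating the gel and Ld regimes."""

    a_ipa: float = 0.45  # nm^2
    k_a: float = 700.0  # mN/m
    chi_tilt: float = 10.0  # J/mol/deg^2
    kc_eff: float = 20.0  # k_B T
    abs_scd: float = 0.31
    gauche: float = 0.15

    def __post_init__(self):
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"threshold {f.name} must be positive")


@dataclass
class PropertyRecord:
    """One system's computed observables (a reference-table row analog)."""

    composition: IPAComposition
    a_ipa: float | None = None
    k_a: float | None = None
    chi_tilt: float | None = None
    kc_eff: float | None = None
    abs_scd: float | None = None
    gauche: float | None = None
    phase_label: str | None = None

    def __post_init__(self):
        for name in PROPERTIES:
            v = getattr(self, name)
            if v is not None and not math.isfinite(v):
                raise ValueError(f"property {name} must be finite, got {v}")


@dataclass
class PhaseCall:
    votes: dict[str, str | None]  # property -> S | Ld | None (abstain)
    overall: str
    tally: tuple[int, int]  # (S votes, Ld votes)
    rule_expected: str | None = None

    @property
    def agrees_with_rule(self) -> bool | None:
        return None if self.rule_expected is None else self.overall == self.rule_expected


# gel votes when the property is on the "ordered" side of its threshold;
# direction True means gel iff value < threshold
_GEL_IF_BELOW = {
    "a_ipa": True,
    "k_a": False,
    "chi_tilt": False,
    "kc_eff": False,
    "abs_scd": False,
    "gauche": True,
}


def property_votes(
    record: PropertyRecord, thresholds: Thresholds | None = None
) -> dict[str, str | None]:
    """Per-property gel/Ld votes; missing properties abstain (None)."""
    thresholds = thresholds or Thresholds()
    votes: dict[str, str | None] = {}
    for name in PROPERTIES:
        value = getattr(record, name)
        if value is None:
            votes[name] = None
            continue
        limit = getattr(thresholds, name)
        gel = value < limit if _GEL_IF_BELOW[name] else value > limit
        votes[name] = GEL if gel else FLUID
    return votes


def classify(votes: Mapping[str, str | None]) -> PhaseCall:
    """Majority vote over non-abstaining properties; ties follow a_ipa."""
    cast = {k: v for k, v in votes.items() if v is not None}
    if not cast:
        raise ValueError("all property votes abstained")
    n_gel = sum(1 for v in cast.values() if v == GEL)
    n_fluid = len(cast) - n_gel
    if n_gel != n_fluid:
        overall = GEL if n_gel > n_fluid else FLUID
    else:
        overall = cast.get("a_ipa") or FLUID
    return PhaseCall(dict(votes), overall, (n_gel, n_fluid))


def phase_rule(composition: IPAComposition) -> str:
    """Composition phase boundary: gel iff both chains have >= 12 carbons."""
    return GEL if min(composition.m, composition.n) >= 12 else FLUID


def classify_record(
    record: PropertyRecord, thresholds: Thresholds | None = None
) -> PhaseCall:
    call = classify(property_votes(record, thresholds))
    call.rule_expected = phase_rule(record.composition)
    return call


# ---------------------------------------------------------------------------
# packaged reference table
# ---------------------------------------------------------------------------


def load_reference_table() -> pd.DataFrame:
    """The packaged 16-system reference survey as a DataFrame."""
    with resources.files("ipabilayer.data").joinpath("reference_systems.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#", na_values=["NA"])
    return df


def records_from_table(df: pd.DataFrame) -> list[PropertyRecord]:
    records = []
    for _, row in df.iterrows():
        comp = IPAComposition(int(row["m"]), int(row["n"]), str(row["abbreviation"]))
        records.append(
            PropertyRecord(
                composition=comp,
                a_ipa=float(row["a_ipa_nm2"]),
                k_a=float(row["k_a_mN_m"]),
                chi_tilt=float(row["chi_tilt_J_mol_deg2"]),
                kc_eff=float(row["kc_eff_kBT"]),
                abs_scd=float(row["abs_scd"]),
                gauche=float(row["gauche_fraction"]),
            )
        )
    return records


def build_report(
    records: Iterable[PropertyRecord], thresholds: Thresholds | None = None
) -> tuple[pd.DataFrame, dict[str, dict[str, float]]]:
    """Classify each record and tabulate properties, votes, and agreement.

    Returns the per-system report plus group extrema: min and max of each
    property within the gel group and the Ld group (groups by overall call).
    """
    thresholds = thresholds or Thresholds()
    rows = []
    for rec in records:
        call = classify_record(rec, thresholds)
        row = {
            "m": rec.composition.m,
            "n": rec.composition.n,
            "abbreviation": rec.composition.abbreviation,
            "delta_c": rec.composition.delta_c,
            "total_carbons": rec.composition.total_carbons,
        }
        for name in PROPERTIES:
            row[name] = getattr(rec, name)
            row[f"vote_{name}"] = call.votes[name]
        row["overall"] = call.overall
        row["rule_expected"] = call.rule_expected
        row["agrees"] = call.agrees_with_rule
        rows.append(row)
    if not rows:
        raise ValueError("no records to report")
    report = pd.DataFrame(rows)

    extrema: dict[str, dict[str, float]] = {}
    for phase, group in report.groupby("overall"):
        stats = {}
        for name in PROPERTIES:
            col = group[name].dropna()
            if len(col):
                stats[f"min_{name}"] = float(col.min())
                stats[f"max_{name}"] = float(col.max())
        extrema[str(phase)] = stats
    return report, extrema
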