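"""Deterministic Hakanson potential ecological risk indices.

For element *i* with measured concentration ``C_i`` (mg/kg), background
``C_n_i`` and toxic response factor ``T_r_i``:

    C_f_i = C_i / C_n_i                (contamination factor)
    E_r_i = T_r_i * C_f_i              (single-factor ecological risk)
    RI    = sum_i E_r_i                (total risk index, m eligible elements)

Er is classified Low / Lower / Median / High / Extremely high at thresholds
40 / 80 / 160 / 320, and RI Low / Lower / Median / High at 150 / 300 / 600.
Intervals are half-open ``[lower, upper)``: a value exactly at a threshold
belongs to the upper class.

Elements lacking a background or a toxic response factor are *excluded*
from Er and RI — never imputed — and reported explicitly; ``m`` counts the
eligible elements only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_reference import (
    ReferenceEntry,
    SampleMeasurement,
    SedRiskError,
    reference_by_element,
)


class ExcludedElementError(SedRiskError):
    """The element lacks a background or toxic response factor."""


class EmptyAssessmentError(SedRiskError):
    """No element is eligible for the risk index."""


ER_LABELS = ("Low", "Lower", "Median", "High", "Extremely high")
RI_LABELS = ("Low", "Lower", "Median", "High")


@dataclass(frozen=True)
class RiskScheme:
    """Classification thresholds and labels for the Er and RI scales."""

    er_thresholds: tuple[float, ...] = (40.0, 80.0, 160.0, 320.0)
    er_labels: tuple[str, ...] = ER_LABELS
    ri_thresholds: tuple[float, ...] = (150.0, 300.0, 600.0)
    ri_labels: tuple[str, ...] = RI_LABELS

    def __post_init__(self) -> None:
        for name, thr, labels in (
            ("er", self.er_thresholds, self.er_labels),
            ("ri", self.ri_thresholds, self.ri_labels),
        ):
            if len(labels) != len(thr) + 1:
                raise ValueError(f"{name}: need {len(thr) + 1} labels for {len(thr)} thresholds")
            if any(b <= a for a, b in zip(thr, thr[1:])):
                raise ValueError(f"{name}: thresholds must be strictly increasing: {thr}")

    def er_bounds(self) -> list[str]:
        """Human-readable interval descriptions for the Er classes."""
        return _bounds("Er", self.er_thresholds)

    def ri_bounds(self) -> list[str]:
        return _bounds("RI", self.ri_thresholds)


def _bounds(name: str, thr: tuple[float, ...]) -> list[str]:
    out = [f"{name} < {thr[0]:g}"]
    out += [f"{a:g} <= {name} < {b:g}" for a, b in zip(thr, thr[1:])]
    out.append(f"{name} >= {thr[-1]:g}")
    return out


DEFAULT_SCHEME = RiskScheme()


def hakanson_cf(concentration: float, background: float) -> float:
    """Contamination factor ``C / C_n``."""
    if not background > 0:
        raise ExcludedElementError(f"background must be > 0, got {background!r}")
    if concentration < 0:
        raise SedRiskError(f"concentration must be >= 0, got {concentration!r}")
    return concentration / background

def hakanson_er(concentration: float, background: float, toxic_response: float | None) -> float:
    """Single-factor ecological risk ``E_r = T_r * C / C_n``."""
    if toxic_response is None:
        raise ExcludedElementError("toxic response factor absent; element excluded from Er")
    if toxic_response < 0:
        raise SedRiskError(f"toxic_response must be >= 0, got {toxic_response!r}")
    return toxic_response * hakanson_cf(concentration, background)

def hakanson_ri(er_values: Iterable[float]) -> float:
    """Total risk index: the sum of per-element Er (empty sum is 0).

    Correctly-rounded summation, so the result is independent of element
    order."""
    return math.fsum(er_values)


def classify(value: float, thresholds: Sequence[float], labels: Sequence[str]) -> str:
    """Label of the half-open interval ``[t_k, t_{k+1})`` containing *value*;
    a value exactly at a threshold belongs to the upper class."""
    if value < 0:
        raise SedRiskError(f"index value must be >= 0, got {value!r}")
    k = int(np.searchsorted(np.asarray(thresholds, dtype=float), value, side="right"))
    return labels[k]


def classify_er(er: float, scheme: RiskScheme = DEFAULT_SCHEME) -> str:
    return classify(er, scheme.er_thresholds, scheme.er_labels)


def classify_ri(ri: float, scheme: RiskScheme = DEFAULT_SCHEME) -> str:
    return classify(ri, scheme.ri_thresholds, scheme.ri_labels)


# ---------------------------------------------------------------------------
# Per-site assessment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ElementRisk:
    element: str
    concentration: float
    cf: float
    er: float
    er_class: str


@dataclass
class RiskAssessment:
    """Hakanson assessment of one site: per-element Cf/Er and the total RI."""

    sample_id: str
    elements: dict[str, ElementRisk] = field(default_factory=dict)
    ri: float = 0.0
    ri_class: str = ""
    m: int = 0  # number of eligible elements summed into RI


def eligible_elements(reference: Iterable[ReferenceEntry]) -> tuple[list[str], dict[str, str]]:
    """Split reference entries into eligible elements and an exclusion report.

    Eligible means both background and toxic response are present.  The
    report maps excluded elements to the missing field(s).
    """
    ok: list[str] = []
    excluded: dict[str, str] = {}
    for entry in reference:
        missing = []
        if entry.background is None:
            missing.append("background")
        if entry.toxic_response is None:
            missing.append("toxic_response")
        if missing:
            excluded[entry.element] = " and ".join(missing) + " absent"
        else:
            ok.append(entry.element)
    return ok, excluded


def assess_sites(
    measurements: Iterable[SampleMeasurement],
    reference: Iterable[ReferenceEntry],
    scheme: RiskScheme = DEFAULT_SCHEME,
) -> tuple[list[RiskAssessment], dict[str, str]]:
    """One :class:`RiskAssessment` per sample, plus the exclusion report.

    RI sums the Er of every eligible element measured at the site; ``m``
    is that count.  Raises :class:`EmptyAssessmentError` when no measured
    element is eligible anywhere.
    """
    ref = reference_by_element(reference)
    ok, excluded = eligible_elements(ref.values())
    ok_set = set(ok)

    by_sample: dict[str, list[SampleMeasurement]] = {}
    for m in measurements:
        by_sample.setdefault(m.sample_id, []).append(m)

    assessments: list[RiskAssessment] = []
    any_eligible = False
    for sid, rows in sorted(by_sample.items()):
        a = RiskAssessment(sample_id=sid)
        for meas in sorted(rows, key=lambda r: r.element):
            if meas.element not in ok_set:
                continue
            entry = ref[meas.element]
            cf = hakanson_cf(meas.concentration, entry.background)
            er = hakanson_er(meas.concentration, entry.background, entry.toxic_response)
            a.elements[meas.element] = ElementRisk(
                meas.element, meas.concentration, cf, er, classify_er(er, scheme)
            )
        a.m = len(a.elements)
        a.ri = hakanson_ri(e.er for e in a.elements.values())
        a.ri_class = classify_ri(a.ri, scheme)
        assessments.append(a)
        any_eligible = any_eligible or a.m > 0
    if not any_eligible:
        raise EmptyAssessmentError(
            "no measured element has both a background and a toxic response factor"
        )
    return assessments, excluded


def assessment_table(assessments: Iterable[RiskAssessment]) -> pd.DataFrame:
    """Long-format frame: one row per (sample, element) with the site RI."""
    rows = []
    for a in assessments:
        for el, r in a.elements.items():
            rows.append(
                {
                    "sample_id": a.sample_id,
                    "element": el,
                    "concentration": r.concentration,
                    "cf": r.cf,
                    "er": r.er,
                    "er_class": r.er_class,
                    "ri": a.ri,
                    "ri_class": a.ri_class,
                    "m": a.m,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id", "element", "concentration", "cf", "er", "er_class",
            "ri", "ri_class", "m",
        ],
    )
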