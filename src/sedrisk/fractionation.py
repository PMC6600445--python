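"""Sequential-extraction fractionation summaries.

From five-step extraction data (F1 ion-exchangeable … F5 residual) this
module computes, per element and sample:

* the **percentage profile** — each step's share of the total extracted
  content, ``100 * c_k / sum(c)``;
* the **mobility ordering** — fractions sorted by descending share, with
  near-equal neighbours tied by "≈";
* the **retention contamination factor** ``Cf = (c1+c2+c3+c4) / c5`` —
  mobile (non-residual) content over residual content.  A low Cf means the
  element is strongly retained in the sediment; a high Cf flags an element
  that is easily released into the water column;
* **recovery QC** — summed fraction content as a percentage of the
  independent total digest, flagged outside an acceptance band.

Note this retention Cf is distinct from the Hakanson contamination factor
``C/C_n`` of :mod:`sedrisk.risk_index`; the two are deliberately separate
operations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_reference import (
    FRACTION_LABELS,
    FractionRecord,
    SedRiskError,
    ValidationError,
)

#: Default tie threshold (percentage points) under which neighbouring
#: fractions in an ordering are reported as "≈".
DEFAULT_TIE_THRESHOLD = 2.0

#: Default recovery acceptance band (%), mirroring the certified-reference
#: accuracy range of the extraction procedure.
DEFAULT_RECOVERY_BAND = (80.0, 120.0)


class DegenerateProfileError(SedRiskError):
    """All five step concentrations are zero — no profile exists."""


class UndefinedFactorError(SedRiskError):
    """Residual step is zero — the retention factor is undefined (not inf)."""


@dataclass(frozen=True)
class FractionProfile:
    """Percentage distribution over the five extraction steps.

    ``scope`` identifies what the profile describes — a sample id, or
    ``"study_mean"`` for the element's across-sample average profile.
    ``retention_cf`` is present whenever the residual step is positive.
    """

    element: str
    scope: str
    percentages: tuple[float, float, float, float, float]
    retention_cf: float | None = None

    def __post_init__(self) -> None:
        total = float(sum(self.percentages))
        if abs(total - 100.0) > 1e-9 * 100.0:
            raise ValidationError(f"percentages sum to {total}, not 100")
        if self.retention_cf is not None and self.retention_cf < 0:
            raise ValidationError("retention_cf must be >= 0")


@dataclass(frozen=True)
class MobilityOrdering:
    """Fractions ordered by descending share, e.g. ``F5 > F2 ≈ F1 > F4 > F3``.

    ``order`` is a permutation of F1–F5; ``relations`` holds the four
    separators (``">"`` or ``"≈"``) between neighbours.
    """

    element: str
    order: tuple[str, str, str, str, str]
    relations: tuple[str, str, str, str]

    def __str__(self) -> str:
        parts = [self.order[0]]
        for rel, lab in zip(self.relations, self.order[1:]):
            parts += [rel, lab]
        return " ".join(parts)

    def tie_groups(self) -> tuple[frozenset, ...]:
        """Maximal runs of "≈"-tied fractions, in rank order.

        Two orderings are equivalent iff their tie groups are equal as
        sequences of sets (tied members are unordered within a group).
        """
        groups: list[set] = [{self.order[0]}]
        for rel, lab in zip(self.relations, self.order[1:]):
            if rel == "≈":
                groups[-1].add(lab)
            else:
                groups.append({lab})
        return tuple(frozenset(g) for g in groups)

    def equivalent(self, other: "MobilityOrdering") -> bool:
        return self.tie_groups() == other.tie_groups()


def parse_ordering(element: str, text: str) -> MobilityOrdering:
    """Parse an ordering string such as ``"F5 > F2 ≈ F1 > F4 > F3"``."""
    tokens = text.replace("~", "≈").split()
    order = tuple(t for t in tokens if t in FRACTION_LABELS)
    relations = tuple(t for t in tokens if t in (">", "≈"))
    if sorted(order) != sorted(FRACTION_LABELS) or len(relations) != 4:
        raise ValidationError(f"cannot parse ordering {text!r}")
    return MobilityOrdering(element, order, relations)  # type: ignore[arg-type]


def _as_steps(concentrations: Sequence[float]) -> np.ndarray:
    c = np.asarray(concentrations, dtype=float)
    if c.shape != (5,):
        raise ValidationError(f"expected five step concentrations, got shape {c.shape}")
    if np.any(c < 0):
        raise ValidationError(f"negative step concentration in {concentrations!r}")
    return c


def fraction_percentages(
    element: str,
    concentrations: Sequence[float],
    scope: str = "sample",
) -> FractionProfile:
    """Percentage profile of the five step concentrations.

    ``percentage_k = 100 * c_k / sum(c)``; the shares are computed against
    the summed extracted content, not the independent total digest (which
    is used only for recovery QC).
    """
    c = _as_steps(concentrations)
    total = c.sum()
    if total <= 0:
        raise DegenerateProfileError(f"all five steps zero for element {element!r}")
    pct = 100.0 * c / total
    cf = float((c[:4].sum()) / c[4]) if c[4] > 0 else None
    return FractionProfile(element, scope, tuple(pct.tolist()), cf)


def study_mean_profile(profiles: Sequence[FractionProfile]) -> FractionProfile:
    """Across-sample mean profile for one element, renormalized to 100."""
    if not profiles:
        raise ValidationError("need at least one profile")
    elements = {p.element for p in profiles}
    if len(elements) > 1:
        raise ValidationError(f"mixed elements in study mean: {sorted(elements)}")
    mat = np.array([p.percentages for p in profiles], dtype=float)
    mean = mat.mean(axis=0)
    mean = 100.0 * mean / mean.sum()
    return FractionProfile(profiles[0].element, "study_mean", tuple(mean.tolist()))


def mobility_order(
    profile: FractionProfile,
    tie_threshold: float = DEFAULT_TIE_THRESHOLD,
) -> MobilityOrdering:
    """Order fractions by descending share; neighbours closer than
    *tie_threshold* percentage points are joined by "≈".

    With threshold 0 this is the strict descending sort; raising the
    threshold can only merge neighbours, never reorder them.  Exact ties
    break deterministically by fraction index.
    """
    pct = np.asarray(profile.percentages)
    idx = sorted(range(5), key=lambda k: (-pct[k], k))
    order = tuple(FRACTION_LABELS[k] for k in idx)
    relations = tuple(
        "≈" if (pct[idx[i]] - pct[idx[i + 1]]) < tie_threshold else ">"
        for i in range(4)
    )
    return MobilityOrdering(profile.element, order, relations)  # type: ignore[arg-type]


def retention_cf(concentrations: Sequence[float]) -> float:
    """Retention contamination factor ``(c1 + c2 + c3 + c4) / c5``.

    Scale-invariant in the five concentrations.  Raises
    :class:`UndefinedFactorError` when the residual step is zero — the
    factor is undefined there, and downstream statistics must not mix
    finite values with infinities.
    """
    c = _as_steps(concentrations)
    if c[4] <= 0:
        raise UndefinedFactorError("residual step (F5) is zero; retention Cf undefined")
    return float(c[:4].sum() / c[4])


def recovery_percent(fraction_sum: float, total_digest: float) -> float:
    """Summed extracted content as % of the independent total digest."""
    if not total_digest > 0:
        raise ValidationError(f"total digest must be > 0, got {total_digest!r}")
    return 100.0 * fraction_sum / total_digest


def recovery_in_band(
    recovery: float,
    band: tuple[float, float] = DEFAULT_RECOVERY_BAND,
) -> bool:
    lo, hi = band
    return lo <= recovery <= hi


# ---------------------------------------------------------------------------
# Record-level orchestration
# ---------------------------------------------------------------------------


def steps_by_key(records: Iterable[FractionRecord]) -> dict[tuple[str, str], np.ndarray]:
    """Group records into complete five-step vectors keyed (sample, element).

    Pairs missing any step are skipped (they appear in the completeness
    summary at read time).
    """
    acc: dict[tuple[str, str], dict[int, float]] = {}
    for r in records:
        acc.setdefault((r.sample_id, r.element), {})[r.fraction] = r.concentration
    return {
        key: np.array([steps[k] for k in range(1, 6)])
        for key, steps in acc.items()
        if len(steps) == 5
    }


def profile_table(records: Iterable[FractionRecord]) -> pd.DataFrame:
    """Per-sample percentage profiles plus retention Cf, one row per
    (sample, element)."""
    rows = []
    for (sid, el), c in sorted(steps_by_key(records).items()):
        prof = fraction_percentages(el, c, scope=sid)
        row = {"sample_id": sid, "element": el}
        row.update({lab: p for lab, p in zip(FRACTION_LABELS, prof.percentages)})
        row["retention_cf"] = prof.retention_cf
        rows.append(row)
    return pd.DataFrame(rows, columns=["sample_id", "element", *FRACTION_LABELS, "retention_cf"])


def study_mean_table(records: Iterable[FractionRecord]) -> pd.DataFrame:
    """Study-mean percentage profile and mobility ordering per element."""
    by_element: dict[str, list[FractionProfile]] = {}
    for (sid, el), c in sorted(steps_by_key(records).items()):
        by_element.setdefault(el, []).append(fraction_percentages(el, c, scope=sid))
    rows = []
    for el, profs in sorted(by_element.items()):
        mean = study_mean_profile(profs)
        row = {"element": el, "n_samples": len(profs)}
        row.update({lab: p for lab, p in zip(FRACTION_LABELS, mean.percentages)})
        row["ordering"] = str(mobility_order(mean))
        rows.append(row)
    return pd.DataFrame(rows, columns=["element", "n_samples", *FRACTION_LABELS, "ordering"])


def retention_cf_table(
    records: Iterable[FractionRecord],
    per: str = "sample",
) -> pd.DataFrame:
    """Retention Cf per (sample, element) (``per="sample"``) or averaged
    per element (``per="element_mean"``).

    Pairs with a zero residual step are reported with an empty Cf and
    excluded from element means.
    """
    rows = []
    for (sid, el), c in sorted(steps_by_key(records).items()):
        try:
            cf = retention_cf(c)
        except UndefinedFactorError:
            cf = np.nan
        rows.append({"sample_id": sid, "element": el, "retention_cf": cf})
    frame = pd.DataFrame(rows, columns=["sample_id", "element", "retention_cf"])
    if per == "sample":
        return frame
    if per == "element_mean":
        out = (
            frame.groupby("element", sort=True)["retention_cf"]
            .agg(["mean", "count"])
            .reset_index()
            .rename(columns={"mean": "retention_cf_mean", "count": "n_samples"})
        )
        return out
    raise ValueError(f"per must be 'sample' or 'element_mean', got {per!r}")


def mobility_orderings(
    records: Iterable[FractionRecord],
    tie_threshold: float = DEFAULT_TIE_THRESHOLD,
) -> dict[str, MobilityOrdering]:
    """Study-mean mobility ordering per element."""
    by_element: dict[str, list[FractionProfile]] = {}
    for (sid, el), c in sorted(steps_by_key(records).items()):
        by_element.setdefault(el, []).append(fraction_percentages(el, c, scope=sid))
    return {
        el: mobility_order(study_mean_profile(profs), tie_threshold)
        for el, profs in sorted(by_element.items())
    }
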