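"""Tabular input/output for sediment risk studies.

Three tables make up a study:

* **totals** — one total concentration per (sample, element), long/tidy CSV
  with columns ``sample_id, river, site, element, concentration``;
* **fractions** — five sequential-extraction step concentrations per
  (sample, element), columns ``sample_id, element, fraction, concentration``
  with the fraction coded ``1``–``5`` or ``F1``–``F5``;
* **reference** — per-element background value ``C_n`` (mg/kg), toxic
  response factor ``T_r`` (dimensionless) and guideline value, read from a
  YAML/JSON config.  A packaged default carries the Serbian river-sediment
  reference table.

All concentrations are mg/kg dry weight; decimal separator is the dot and
scientific notation is accepted.  Validation is total: a malformed input
raises a structured error naming the offending row and field — a partially
read table is never returned.  Absent reference values are explicit
(``None``), never zero-filled: downstream code excludes such elements and
reports them.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

#: The eleven elements of the default study, in the study's printing order.
ELEMENTS: tuple[str, ...] = ("Cd", "Co", "Cr", "Cu", "Fe", "Mn", "Ni", "Pb", "V", "Zn", "As")

#: Sequential-extraction step labels: F1 ion-exchangeable; F2 carbonate /
#: easily reducible; F3 Fe-oxide (moderately reducible); F4 organic matter
#: and sulfides; F5 residual (aqua regia).
FRACTION_LABELS: tuple[str, ...] = ("F1", "F2", "F3", "F4", "F5")

TOTALS_COLUMNS = ("sample_id", "river", "site", "element", "concentration")
FRACTIONS_COLUMNS = ("sample_id", "element", "fraction", "concentration")


class SedRiskError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(SedRiskError):
    """A file does not have the expected columns or structure."""


class ValidationError(SedRiskError):
    """A row violates a domain invariant (named row and field)."""


class DuplicateKeyError(ValidationError):
    """A key that must be unique appears more than once."""


def canonical_element(symbol: str, element_set: Sequence[str] | None = None) -> str:
    """Canonicalize an element symbol case-insensitively to its IUPAC form.

    Raises :class:`ValidationError` if the symbol is not in *element_set*
    (default: the eleven studied elements).
    """
    sym = str(symbol).strip().capitalize()
    allowed = tuple(element_set) if element_set is not None else ELEMENTS
    if sym not in allowed:
        raise ValidationError(f"unknown element symbol {symbol!r} (allowed: {', '.join(allowed)})")
    return sym


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleMeasurement:
    """One total (exposure) concentration for one element at one site."""

    sample_id: str
    river: str
    site: str
    element: str
    concentration: float  # mg/kg dry weight

    def __post_init__(self) -> None:
        if not (self.concentration >= 0):
            raise ValidationError(
                f"negative concentration {self.concentration!r} for "
                f"(sample_id={self.sample_id!r}, element={self.element!r})"
            )


@dataclass(frozen=True)
class FractionRecord:
    """One sequential-extraction step concentration.

    ``fraction`` is the integer step index 1–5 (F1 … F5 residual).
    """

    sample_id: str
    element: str
    fraction: int
    concentration: float  # mg/kg dry weight

    def __post_init__(self) -> None:
        if self.fraction not in (1, 2, 3, 4, 5):
            raise ValidationError(
                f"fraction index {self.fraction!r} outside 1-5 for "
                f"(sample_id={self.sample_id!r}, element={self.element!r})"
            )
        if not (self.concentration >= 0):
            raise ValidationError(
                f"negative concentration {self.concentration!r} for "
                f"(sample_id={self.sample_id!r}, element={self.element!r}, "
                f"fraction={self.fraction})"
            )


@dataclass(frozen=True)
class ReferenceEntry:
    """Per-element background value, toxic response factor and guideline.

    Absent values are ``None`` — explicit, never zero-filled.  Elements with
    an absent background or toxic response are excluded from the risk
    indices downstream, with an exclusion report.
    """

    element: str
    background: float | None = None       # C_n, mg/kg, > 0 when present
    toxic_response: float | None = None   # T_r, dimensionless, >= 0 when present
    guideline: float | None = None        # mg/kg, > 0 when present

    def __post_init__(self) -> None:
        if self.background is not None and not (self.background > 0):
            raise ValidationError(
                f"background must be > 0, got {self.background!r} for element {self.element!r}"
            )
        if self.toxic_response is not None and not (self.toxic_response >= 0):
            raise ValidationError(
                f"toxic_response must be >= 0, got {self.toxic_response!r} "
                f"for element {self.element!r}"
            )
        if self.guideline is not None and not (self.guideline > 0):
            raise ValidationError(
                f"guideline must be > 0, got {self.guideline!r} for element {self.element!r}"
            )


@dataclass
class StudyTable:
    """A complete study: totals, fractions and the reference table."""

    measurements: list[SampleMeasurement] = field(default_factory=list)
    fractions: list[FractionRecord] = field(default_factory=list)
    reference: list[ReferenceEntry] = field(default_factory=list)

    def validate(self) -> None:
        """Check that every element appearing in the data has a reference row."""
        ref_elements = {e.element for e in self.reference}
        used = {m.element for m in self.measurements} | {f.element for f in self.fractions}
        missing = sorted(used - ref_elements)
        if missing:
            raise ValidationError(
                f"elements without a reference entry: {', '.join(missing)}"
            )


def reference_by_element(entries: Iterable[ReferenceEntry]) -> dict[str, ReferenceEntry]:
    out: dict[str, ReferenceEntry] = {}
    for e in entries:
        if e.element in out:
            raise DuplicateKeyError(f"element {e.element!r} repeated in reference table")
        out[e.element] = e
    return out


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: object) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")


def _parse_concentration(raw: object, context: str) -> float:
    try:
        value = float(raw)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric concentration {raw!r} for {context}") from exc
    if pd.isna(value):
        raise ValidationError(f"missing concentration for {context}")
    return value


def read_totals(
    path: str | Path,
    element_set: Sequence[str] | None = None,
) -> list[SampleMeasurement]:
    """Read a long-format totals CSV into validated measurements.

    Every row is validated (non-negative concentration, known element,
    unique ``(sample_id, element)``); the row count is preserved.
    """
    df = pd.read_csv(
        path,
        dtype={"sample_id": str, "river": str, "site": str},
        float_precision="round_trip",
    )
    _require_columns(df, TOTALS_COLUMNS, path)
    records: list[SampleMeasurement] = []
    seen: set[tuple[str, str]] = set()
    for i, row in df.iterrows():
        element = canonical_element(row["element"], element_set)
        context = f"row {i + 2} (sample_id={row['sample_id']!r}, element={element!r})"
        conc = _parse_concentration(row["concentration"], context)
        key = (str(row["sample_id"]), element)
        if key in seen:
            raise DuplicateKeyError(f"duplicated (sample_id, element) key at {context}")
        seen.add(key)
        try:
            records.append(
                SampleMeasurement(
                    sample_id=str(row["sample_id"]),
                    river=str(row["river"]),
                    site=str(row["site"]),
                    element=element,
                    concentration=conc,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: {exc} at {context}") from exc
    return records


def normalize_fraction_code(code: object) -> int:
    """Normalize a fraction code (``3``, ``"3"``, ``"F3"``/``"f3"``) to an int 1–5."""
    s = str(code).strip()
    if s and s[0] in "Ff":
        s = s[1:]
    try:
        value = float(s)
    except ValueError:
        raise ValidationError(f"unparseable fraction code {code!r}") from None
    if not value.is_integer() or not 1 <= value <= 5:
        raise ValidationError(f"fraction code {code!r} outside F1-F5")
    return int(value)


def read_fractions(
    path: str | Path,
    element_set: Sequence[str] | None = None,
) -> list[FractionRecord]:
    """Read a sequential-extraction fractions CSV.

    Fraction codes are normalized to integers 1–5.  A missing step for a
    (sample, element) pair is permitted here — use
    :func:`fraction_completeness` for the completeness summary.  An empty
    file yields an empty collection plus a warning.
    """
    df = pd.read_csv(path, dtype={"sample_id": str}, float_precision="round_trip")
    _require_columns(df, FRACTIONS_COLUMNS, path)
    if df.empty:
        warnings.warn(f"{path}: fractions file contains no rows", stacklevel=2)
        return []
    records: list[FractionRecord] = []
    seen: set[tuple[str, str, int]] = set()
    for i, row in df.iterrows():
        element = canonical_element(row["element"], element_set)
        step = normalize_fraction_code(row["fraction"])
        context = (
            f"row {i + 2} (sample_id={row['sample_id']!r}, element={element!r}, "
            f"fraction=F{step})"
        )
        conc = _parse_concentration(row["concentration"], context)
        key = (str(row["sample_id"]), element, step)
        if key in seen:
            raise DuplicateKeyError(f"duplicated (sample_id, element, fraction) key at {context}")
        seen.add(key)
        try:
            records.append(FractionRecord(str(row["sample_id"]), element, step, conc))
        except ValidationError as exc:
            raise ValidationError(f"{path}: {exc} at {context}") from exc
    return records


def fraction_completeness(records: Iterable[FractionRecord]) -> pd.DataFrame:
    """Report (sample, element) pairs missing one or more of the five steps.

    Returns a frame with columns ``sample_id, element, missing_steps`` —
    empty when every pair carries all five steps.
    """
    present: dict[tuple[str, str], set[int]] = {}
    for r in records:
        present.setdefault((r.sample_id, r.element), set()).add(r.fraction)
    rows = [
        {
            "sample_id": sid,
            "element": el,
            "missing_steps": ",".join(f"F{k}" for k in sorted(set(range(1, 6)) - steps)),
        }
        for (sid, el), steps in sorted(present.items())
        if steps != {1, 2, 3, 4, 5}
    ]
    return pd.DataFrame(rows, columns=["sample_id", "element", "missing_steps"])


def _entry_from_mapping(element: str, payload: Mapping | None) -> ReferenceEntry:
    payload = payload or {}
    unknown = set(payload) - {"background", "toxic_response", "guideline"}
    if unknown:
        raise SchemaError(f"unknown reference field(s) {sorted(unknown)} for element {element!r}")

    def _num(key: str) -> float | None:
        v = payload.get(key)
        return None if v is None else float(v)

    return ReferenceEntry(
        element=canonical_element(element, element_set=None if element in ELEMENTS else [element]),
        background=_num("background"),
        toxic_response=_num("toxic_response"),
        guideline=_num("guideline"),
    )


def read_reference(path: str | Path) -> list[ReferenceEntry]:
    """Read a reference config (YAML or JSON).

    The file maps element symbols to ``background`` / ``toxic_response`` /
    ``guideline`` values under a top-level ``elements`` key; absent values
    must be written as explicit nulls.  A list of ``{element: ..., ...}``
    entries is also accepted (and checked for duplicates).
    """
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping) or "elements" not in doc:
        raise SchemaError(f"{path}: expected a top-level 'elements' mapping or list")
    spec = doc["elements"]
    entries: list[ReferenceEntry] = []
    if isinstance(spec, Mapping):
        for element, payload in spec.items():
            entries.append(_entry_from_mapping(str(element), payload))
    elif isinstance(spec, list):
        for item in spec:
            if not isinstance(item, Mapping) or "element" not in item:
                raise SchemaError(f"{path}: each list entry needs an 'element' field")
            payload = {k: v for k, v in item.items() if k != "element"}
            entries.append(_entry_from_mapping(str(item["element"]), payload))
    else:
        raise SchemaError(f"{path}: 'elements' must be a mapping or a list")
    reference_by_element(entries)  # duplicate check
    return entries


def default_reference() -> list[ReferenceEntry]:
    """The packaged reference table for the Serbian river-sediment study."""
    source = resources.files("sedrisk.data").joinpath("reference_serbia.yaml")
    with resources.as_file(source) as p:
        return read_reference(p)


# ---------------------------------------------------------------------------
# Writers (round-trip exact: floats serialized via shortest repr)
# ---------------------------------------------------------------------------


def write_totals(records: Iterable[SampleMeasurement], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "river": r.river,
                "site": r.site,
                "element": r.element,
                "concentration": repr(r.concentration),
            }
            for r in records
        ],
        columns=list(TOTALS_COLUMNS),
    ).to_csv(path, index=False)


def write_fractions(records: Iterable[FractionRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "element": r.element,
                "fraction": f"F{r.fraction}",
                "concentration": repr(r.concentration),
            }
            for r in records
        ],
        columns=list(FRACTIONS_COLUMNS),
    ).to_csv(path, index=False)


def write_reference(entries: Iterable[ReferenceEntry], path: str | Path) -> None:
    path = Path(path)
    payload = {
        "elements": {
            e.element: {
                "background": e.background,
                "toxic_response": e.toxic_response,
                "guideline": e.guideline,
            }
            for e in entries
        }
    }
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False, default_flow_style=False))


def totals_wide_to_long(wide: pd.DataFrame, element_set: Sequence[str] | None = None) -> pd.DataFrame:
    """Convert a wide totals table (one column per element) to long format.

    Identifier columns ``sample_id``/``river``/``site`` are kept; every other
    column is treated as an element column.
    """
    id_cols = [c for c in ("sample_id", "river", "site") if c in wide.columns]
    if "sample_id" not in id_cols:
        raise SchemaError("wide totals table needs a 'sample_id' column")
    value_cols = [c for c in wide.columns if c not in id_cols]
    long = wide.melt(id_vars=id_cols, value_vars=value_cols, var_name="element", value_name="concentration")
    long["element"] = [canonical_element(e, element_set) for e in long["element"]]
    for col in ("river", "site"):
        if col not in long.columns:
            long[col] = ""
    return long[list(TOTALS_COLUMNS)]
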