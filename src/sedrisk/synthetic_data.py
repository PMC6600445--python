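"""Synthetic river-sediment study generator with known ground truth.

The real study's per-sample concentrations were never deposited; only
summary statistics (per-element min / max / mean), the study-mean fraction
orderings and the reference table are printed.  This module generates a
complete synthetic study shaped by those published anchors so every
pipeline stage — fractionation, deterministic indices, Monte Carlo — can be
exercised and checked against known truth:

* **totals** — per element, draws from a configurable concentration law,
  defaulting to a truncated normal on the published [min, max] with the
  published mean and a range-rule SD;
* **hotspots** — a few (site, element) pairs receive multiplied
  concentrations, emulating the study's outlier sites (Ibar: Cd/Zn/Pb/Ni;
  Pek: Cu/Zn; Porečka: Cu; West Morava: Pb; South Morava: Mn);
* **fractions** — five-step splits drawn around per-element mean profiles
  built to reproduce the published mobility orderings, rescaled so the
  steps sum to ``total x recovery`` with the recovery factor drawn inside a
  configurable band;
* **reference** — the packaged reference table.

Everything is deterministic under (config, seed), with per-element
substreams so adding an element never perturbs another element's draws.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_reference import (
    ELEMENTS,
    FractionRecord,
    SampleMeasurement,
    SedRiskError,
    StudyTable,
    default_reference,
)
from .mc_engine import DistributionSpec, draw_concentrations, element_seed, fit_from_summary

#: Published per-element total-concentration summaries (min, max, mean),
#: mg/kg dry weight — the anchors for the default concentration laws.
CONCENTRATION_SUMMARIES: dict[str, tuple[float, float, float]] = {
    "Cd": (1.28, 10.5, 4.82),
    "Co": (8.22, 36.2, 22.0),
    "Cr": (59.8, 230.0, 113.0),
    "Cu": (11.5, 870.0, 78.5),
    "Fe": (24_556.0, 62_800.0, 44_177.0),
    "Mn": (648.0, 3688.0, 1399.0),
    "Ni": (33.2, 274.0, 77.8),
    "Pb": (57.8, 318.0, 132.0),
    "V": (60.4, 149.0, 111.0),
    "Zn": (66.6, 1095.0, 353.0),
    "As": (3.67, 63.2, 14.7),
}

#: Published study-mean mobility orderings over the five extraction steps.
STUDY_ORDERINGS: dict[str, str] = {
    "Cd": "F5 > F2 > F1 > F4 > F3",
    "Cr": "F5 > F4 > F3 > F2 > F1",
    "Co": "F5 > F2 > F3 > F4 > F1",
    "Cu": "F5 ≈ F3 > F4 ≈ F2 > F1",
    "Fe": "F5 > F3 > F4 > F2 > F1",
    "Mn": "F2 > F1 > F5 > F4 > F3",
    "Ni": "F5 > F4 ≈ F2 ≈ F3 > F1",
    "Pb": "F2 > F4 > F3 ≈ F5 ≈ F1",
    "Zn": "F2 > F5 > F4 > F3 > F1",
    "V": "F5 > F3 > F2 > F4 > F1",
    "As": "F5 > F3 > F2 > F4 > F1",
}

#: Mean fraction percentages (F1..F5) per element, designed so that the
#: ranking of the means reproduces STUDY_ORDERINGS: "≈"-tied fractions get
#: equal means; distinct ranks are separated by >= 5 percentage points.
FRACTION_MEAN_PROFILES: dict[str, tuple[float, float, float, float, float]] = {
    "Cd": (18.0, 26.0, 4.0, 10.0, 42.0),
    "Cr": (3.0, 10.0, 18.0, 26.0, 43.0),
    "Co": (3.0, 26.0, 18.0, 10.0, 43.0),
    "Cu": (6.0, 16.0, 31.0, 16.0, 31.0),
    "Fe": (3.0, 10.0, 26.0, 18.0, 43.0),
    "Mn": (27.0, 40.0, 5.0, 10.0, 18.0),
    "Ni": (6.0, 16.0, 16.0, 16.0, 46.0),
    "Pb": (12.0, 38.0, 12.0, 26.0, 12.0),
    "Zn": (3.0, 43.0, 10.0, 18.0, 26.0),
    "V": (3.0, 18.0, 26.0, 10.0, 43.0),
    "As": (3.0, 18.0, 26.0, 10.0, 43.0),
}

#: The study's 32 sampling sites (river, site), in sample-number order.
SITES: tuple[tuple[str, str], ...] = (
    ("Tisa", "Martonoš"), ("Tisa", "Martonoš"), ("Tisa", "Martonoš"),
    ("Tisa", "Martonoš"), ("Tisa", "Martonoš"), ("Tisa", "Titel"),
    ("Tisa", "Titel"), ("Danube", "Gruja"), ("Danube", "Bezdan"),
    ("Danube", "Bezdan"), ("Danube", "Bezdan"), ("Danube", "Bezdan"),
    ("Sava", "Sremska Mitrovica"), ("Sava", "Šabac"), ("Sava", "Ostružnica"),
    ("Sava", "Jamena"), ("DTD canal", "Begej, Vrbas"), ("Tamiš", "Jaša Tomić"),
    ("Pek", "Kusiće"), ("Kolubara", "Draževac"), ("Porečka river", "Mosna"),
    ("Ibar", "Raška"), ("Ibar", "Kraljevo"), ("Topčiderska river", "Rakovica"),
    ("South Morava", "Mojsinje"), ("Great Morava", "Ljubičevski most"),
    ("Great Morava", "Bagrdan"), ("West Morava", "Maskare"), ("Nišava", "Niš"),
    ("Nišava", "Dimitrovgrad"), ("South Morava", "Vladičin Han"),
    ("Toplica", "Doljevac"),
)

#: Default hotspot contamination: (sample number, element, multiplier).
#: Sample numbers follow SITES; multipliers (3-10x) are large enough that a
#: hotspot concentration exceeds the base law's 99th percentile.
DEFAULT_HOTSPOTS: tuple[tuple[int, str, float], ...] = (
    (19, "Cu", 10.0), (19, "Zn", 4.0),        # Pek
    (21, "Cu", 10.0),                          # Porečka river
    (22, "Cd", 6.0), (22, "Zn", 4.0), (22, "Pb", 4.0), (22, "Ni", 4.0),  # Ibar
    (25, "Mn", 3.0),                           # South Morava
    (28, "Pb", 4.0),                           # West Morava
)

#: Recovery band emulating the certified-reference accuracy range of the
#: extraction (fractions sum to total x recovery, recovery drawn here).
DEFAULT_RECOVERY_BAND = (0.815, 1.14)


class ConfigError(SedRiskError):
    """Invalid synthetic-study configuration."""


def default_laws(
    elements: Sequence[str] = ELEMENTS,
    family: str = "truncated_normal",
    sd_rule: str | float = "range4",
) -> dict[str, DistributionSpec]:
    """Concentration laws fitted from the published summaries."""
    return {
        el: fit_from_summary(el, *CONCENTRATION_SUMMARIES[el], family=family, sd_rule=sd_rule)
        for el in elements
    }


@dataclass
class SynthConfig:
    """Configuration of the synthetic study.

    Defaults reproduce the published study's shape: 32 sites, 11 elements,
    concentration laws anchored to the printed min/max/mean, fraction-mean
    profiles reproducing the printed orderings, per-step profile noise of
    about 3 percentage points, and the named hotspot sites.
    """

    n_sites: int = 32
    elements: tuple[str, ...] = ELEMENTS
    laws: dict[str, DistributionSpec] = field(default_factory=dict)
    fraction_means: dict[str, tuple[float, ...]] = field(default_factory=dict)
    profile_sd: float = 3.0  # percentage points per step, before renormalization
    hotspots: tuple[tuple[int, str, float], ...] = DEFAULT_HOTSPOTS
    recovery_band: tuple[float, float] = DEFAULT_RECOVERY_BAND

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ConfigError("n_sites must be >= 1")
        if not self.laws:
            self.laws = default_laws(self.elements)
        if not self.fraction_means:
            self.fraction_means = {
                el: FRACTION_MEAN_PROFILES.get(el, (20.0, 20.0, 20.0, 20.0, 20.0))
                for el in self.elements
            }
        for el in self.elements:
            if el not in self.laws:
                raise ConfigError(f"no concentration law for element {el!r}")
            law = self.laws[el]
            if law.support is not None and law.support[1] <= 0:
                raise ConfigError(f"{el}: law support upper bound must be > 0")
            means = np.asarray(self.fraction_means[el], dtype=float)
            if means.shape != (5,) or abs(means.sum() - 100.0) > 1e-9:
                raise ConfigError(f"{el}: fraction means must be five values summing to 100")
        for site_no, el, mult in self.hotspots:
            if mult <= 0:
                raise ConfigError(f"hotspot multiplier must be > 0, got {mult}")
            if el not in self.elements:
                raise ConfigError(f"hotspot element {el!r} not in the element set")
        lo, hi = self.recovery_band
        if not 0 < lo <= hi:
            raise ConfigError(f"invalid recovery band {self.recovery_band}")


@dataclass
class SynthStudy:
    """A generated study plus the ground truth that produced it."""

    table: StudyTable
    config: SynthConfig
    seed: int
    recoveries: dict[str, float]  # per sample_id


def _site_row(i: int) -> tuple[str, str]:
    return SITES[i % len(SITES)]


def generate_study(config: SynthConfig | None = None, seed: int = 0) -> SynthStudy:
    """Generate a complete synthetic study, deterministic under (config, seed).

    Totals are drawn per element from the configured law (hotspot
    multipliers applied as ``multiplier x max(draw, law mean)``); fraction
    steps are drawn around the element's mean profile and rescaled so they
    sum exactly to ``total x recovery`` with the per-sample recovery drawn
    uniformly inside the configured band.
    """
    config = config or SynthConfig()
    n = config.n_sites
    width = max(2, len(str(n)))
    sample_ids = [f"S{i + 1:0{width}d}" for i in range(n)]

    hot = {(s - 1, el): mult for s, el, mult in config.hotspots if s <= n}

    measurements: list[SampleMeasurement] = []
    totals: dict[tuple[str, str], float] = {}
    for el in config.elements:
        law = config.laws[el]
        draws = draw_concentrations(law, n, element_seed(seed, el, stream=1))
        base_level = law.mean()
        for i, sid in enumerate(sample_ids):
            value = float(draws[i])
            mult = hot.get((i, el))
            if mult is not None:
                value = mult * max(value, base_level)
            river, site = _site_row(i)
            measurements.append(SampleMeasurement(sid, river, site, el, value))
            totals[(sid, el)] = value

    rec_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=[int(seed) % (2**31), 0x5EC])
    )
    lo, hi = config.recovery_band
    recoveries = {sid: float(rec_rng.uniform(lo, hi)) for sid in sample_ids}

    fractions: list[FractionRecord] = []
    for el in config.elements:
        means = np.asarray(config.fraction_means[el], dtype=float)
        frac_rng = np.random.default_rng(element_seed(seed, el, stream=2))
        noise = frac_rng.normal(0.0, config.profile_sd, size=(n, 5))
        pct = np.maximum(means + noise, 0.1)
        pct = 100.0 * pct / pct.sum(axis=1, keepdims=True)
        for i, sid in enumerate(sample_ids):
            extracted = totals[(sid, el)] * recoveries[sid]
            steps = extracted * pct[i] / 100.0
            # exact invariant: steps sum to total x recovery
            steps[4] = extracted - steps[:4].sum()
            for k in range(5):
                fractions.append(FractionRecord(sid, el, k + 1, float(steps[k])))

    reference = [e for e in default_reference() if e.element in config.elements]
    table = StudyTable(measurements=measurements, fractions=fractions, reference=reference)
    table.validate()
    return SynthStudy(table=table, config=config, seed=seed, recoveries=recoveries)


def true_parameters(study: SynthStudy) -> pd.DataFrame:
    """Ground-truth concentration law per element, with analytic moments.

    ``mean``/``sd`` are the analytic moments of the configured law — the
    quantities a moment-based refit of the generated totals estimates.
    """
    rows = []
    for el in study.config.elements:
        law = study.config.laws[el]
        lo, hi = law.support if law.support is not None else (np.nan, np.nan)
        rows.append(
            {
                "element": el,
                "family": law.family,
                "location": law.location,
                "scale": law.scale,
                "lower": lo,
                "upper": hi,
                "mean": law.mean(),
                "sd": law.sd(),
            }
        )
    return pd.DataFrame(rows)


def ground_truth_payload(study: SynthStudy) -> dict:
    """JSON-serializable ground truth (config echo + law table)."""
    cfg = study.config
    return {
        "seed": study.seed,
        "n_sites": cfg.n_sites,
        "elements": list(cfg.elements),
        "profile_sd": cfg.profile_sd,
        "recovery_band": list(cfg.recovery_band),
        "hotspots": [list(h) for h in cfg.hotspots],
        "fraction_means": {el: list(v) for el, v in cfg.fraction_means.items()},
        "laws": {
            el: {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(law).items()
                if k != "values"
            }
            for el, law in cfg.laws.items()
        },
        "recoveries": study.recoveries,
    }
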