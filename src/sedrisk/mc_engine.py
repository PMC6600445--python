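"""Seeded Monte Carlo simulation of the Hakanson risk indices.

Instead of a single-point RI, the risk is treated probabilistically: each
element's exposure concentration is a random variable, fitted either from
raw per-sample values or from printed summary statistics (min / max / mean).
Er draws are ``T_r * C / C_n`` per iteration; RI draws are the per-iteration
sum over eligible elements.  The outputs are risk-class probability tables
(percentage of draws per Er / RI class) and exceedance curves
``v -> P(index >= v)``.

Distribution families
---------------------
``truncated_normal`` (default when fitting from summaries) — a normal
restricted to the observed [min, max]; keeps every draw inside the printed
support.  ``normal`` — a plain normal with rejection of negative draws (and
of draws outside an optional support), mirroring a literal normal random
generator.  ``lognormal`` — location/scale are the log-space mean/sd.
``point_mass`` — degenerate, for consistency checks against the
deterministic index.  ``empirical`` — bootstrap resampling of stored values.

Determinism
-----------
Every simulation is reproducible from (inputs, seed): one master seed
deterministically derives a per-element substream keyed by the element
symbol, so adding or removing an element never perturbs another element's
draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_reference import ReferenceEntry, SedRiskError, reference_by_element
from .risk_index import DEFAULT_SCHEME, ExcludedElementError, RiskScheme

FAMILIES = ("normal", "truncated_normal", "lognormal", "point_mass", "empirical")

#: SD heuristics usable when only min/max/mean are printed.  The range rule
#: (max - min)/4 is the default; (max - min)/6 is the classic alternative.
SD_RULES: dict[str, Callable[[float, float], float]] = {
    "range4": lambda lo, hi: (hi - lo) / 4.0,
    "range6": lambda lo, hi: (hi - lo) / 6.0,
}


class DistributionError(SedRiskError):
    """Invalid or infeasible distribution specification."""


class InsufficientDataError(SedRiskError):
    """Too few values to fit the requested family."""


@dataclass(frozen=True)
class DistributionSpec:
    """A concentration sampling law for one element.

    ``location``/``scale`` are mg/kg for the normal families; for
    ``lognormal`` they are the mean/sd of log-concentration.  ``support``
    bounds draws to [lower, upper] where present.
    """

    element: str
    family: str
    location: float
    scale: float
    support: tuple[float, float] | None = None
    provenance: str = "user"  # fit_from_samples | fit_from_summary | user
    values: tuple[float, ...] | None = None  # stored sample for family="empirical"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise DistributionError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if self.family != "point_mass" and not self.scale > 0:
            raise DistributionError(f"scale must be > 0 for family {self.family!r}")
        if self.support is not None:
            lo, hi = self.support
            if not lo < hi:
                raise DistributionError(f"support needs lower < upper, got {self.support}")
            if self.family == "truncated_normal" and not (lo <= self.location <= hi):
                raise DistributionError(
                    f"truncated_normal location {self.location} outside support {self.support}"
                )
            if self.family == "lognormal" and lo < 0:
                raise DistributionError("lognormal support must have lower >= 0")
        elif self.family == "truncated_normal":
            raise DistributionError("truncated_normal requires a support")
        if self.family == "empirical" and not self.values:
            raise DistributionError("empirical family requires stored values")

    # -- analytic view -----------------------------------------------------

    def frozen(self):
        """The scipy frozen distribution of the *effective* law.

        For ``family="normal"`` the effective law accounts for rejection of
        negatives / out-of-support draws, i.e. it is a truncated normal on
        the feasible region.
        """
        if self.family == "point_mass":
            raise DistributionError("point_mass has no scipy frozen form")
        if self.family == "empirical":
            raise DistributionError("empirical law has no closed form; use the stored values")
        if self.family == "lognormal":
            dist = stats.lognorm(s=self.scale, scale=math.exp(self.location))
            if self.support is not None:
                raise DistributionError("truncated lognormal has no frozen form here")
            return dist
        lo, hi = self._effective_bounds()
        a = (lo - self.location) / self.scale
        b = (hi - self.location) / self.scale
        return stats.truncnorm(a, b, loc=self.location, scale=self.scale)

    def _effective_bounds(self) -> tuple[float, float]:
        if self.family == "truncated_normal":
            return self.support  # type: ignore[return-value]
        lo, hi = self.support if self.support is not None else (0.0, math.inf)
        return max(lo, 0.0), hi

    def mean(self) -> float:
        """Analytic mean of the effective law (sample mean for empirical)."""
        if self.family == "point_mass":
            return self.location
        if self.family == "empirical":
            return float(np.mean(self.values))
        return float(self.frozen().mean())

    def sd(self) -> float:
        if self.family == "point_mass":
            return 0.0
        if self.family == "empirical":
            return float(np.std(self.values, ddof=1))
        return float(self.frozen().std())

    def cdf(self, x) -> np.ndarray:
        if self.family == "point_mass":
            return (np.asarray(x, dtype=float) >= self.location).astype(float)
        if self.family == "empirical":
            v = np.sort(np.asarray(self.values, dtype=float))
            return np.searchsorted(v, np.asarray(x, dtype=float), side="right") / v.size
        return self.frozen().cdf(x)


@dataclass(frozen=True)
class MCConfig:
    """Monte Carlo run settings: iteration count, master seed, and the
    decimal places used when reporting class probabilities."""

    iterations: int = 100_000
    seed: int = 0
    rounding: int = 2

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def fit_from_samples(
    element: str,
    values: Sequence[float],
    family: str = "truncated_normal",
) -> DistributionSpec:
    """Method-of-moments fit of a concentration law to raw sample values.

    ``normal``/``truncated_normal`` use the sample mean and sd (ddof=1);
    the truncated family takes the sample min/max as its support.
    ``lognormal`` uses the mean/sd of log-values.  ``empirical`` stores the
    values for bootstrap resampling.  A constant sample collapses to a
    ``point_mass`` regardless of the requested family.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InsufficientDataError(f"{element}: need >= 2 values to estimate a scale, got {v.size}")
    if np.unique(v).size == 1:
        return DistributionSpec(element, "point_mass", float(v[0]), 0.0, provenance="fit_from_samples")
    if family == "empirical":
        return DistributionSpec(
            element, "empirical", float(v.mean()), float(v.std(ddof=1)),
            provenance="fit_from_samples", values=tuple(v.tolist()),
        )
    if family == "lognormal":
        if np.any(v <= 0):
            raise DistributionError(f"{element}: non-positive values cannot be fit as lognormal")
        logs = np.log(v)
        return DistributionSpec(
            element, "lognormal", float(logs.mean()), float(logs.std(ddof=1)),
            provenance="fit_from_samples",
        )
    if family == "normal":
        return DistributionSpec(
            element, "normal", float(v.mean()), float(v.std(ddof=1)), provenance="fit_from_samples"
        )
    if family == "truncated_normal":
        loc, sd = float(v.mean()), float(v.std(ddof=1))
        return DistributionSpec(
            element, "truncated_normal", loc, sd,
            support=(float(v.min()), float(v.max())), provenance="fit_from_samples",
        )
    raise DistributionError(f"unknown family {family!r}")


def fit_from_summary(
    element: str,
    minimum: float,
    maximum: float,
    mean: float,
    family: str = "truncated_normal",
    sd_rule: str | float = "range4",
) -> DistributionSpec:
    """Build a concentration law from printed min / max / mean summaries.

    The location is the printed mean; the scale comes from *sd_rule* —
    either a named heuristic (``"range4"``: (max-min)/4, the default;
    ``"range6"``) or an explicit SD in mg/kg.  ``truncated_normal`` takes
    [min, max] as its support.  A degenerate summary (min == max == mean)
    yields a point mass.
    """
    if not (minimum <= mean <= maximum):
        raise DistributionError(
            f"{element}: mean {mean} outside [min, max] = [{minimum}, {maximum}]"
        )
    if minimum == maximum:
        return DistributionSpec(element, "point_mass", float(mean), 0.0, provenance="fit_from_summary")
    if isinstance(sd_rule, str):
        try:
            sd = SD_RULES[sd_rule](minimum, maximum)
        except KeyError:
            raise DistributionError(f"unknown sd rule {sd_rule!r}; choose from {sorted(SD_RULES)}") from None
    else:
        sd = float(sd_rule)
    if family == "truncated_normal":
        return DistributionSpec(
            element, "truncated_normal", float(mean), sd,
            support=(float(minimum), float(maximum)), provenance="fit_from_summary",
        )
    if family == "normal":
        return DistributionSpec(element, "normal", float(mean), sd, provenance="fit_from_summary")
    if family == "lognormal":
        if minimum < 0:
            raise DistributionError(f"{element}: lognormal needs non-negative support")
        # moment-match on the arithmetic scale: mean -> mu, sd -> sigma of logs
        cv2 = (sd / mean) ** 2
        sigma = math.sqrt(math.log1p(cv2))
        mu = math.log(mean) - sigma**2 / 2.0
        return DistributionSpec(element, "lognormal", mu, sigma, provenance="fit_from_summary")
    raise DistributionError(f"family {family!r} cannot be fit from summaries")


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------


def element_seed(master_seed: int, element: str, stream: int = 0) -> np.random.SeedSequence:
    """Derive the per-element substream for a master seed.

    Keyed by the element symbol (not its position), so the substream is
    independent of which other elements are simulated.
    """
    key = int.from_bytes(element.encode("utf-8"), "big") % (2**31)
    return np.random.SeedSequence(entropy=[int(master_seed) % (2**31), key, stream])


def _rng(seed: int | np.random.SeedSequence | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def draw_concentrations(
    spec: DistributionSpec,
    n: int,
    seed: int | np.random.SeedSequence | np.random.Generator,
) -> np.ndarray:
    """Draw *n* non-negative concentrations from *spec*, reproducibly.

    Truncated families sample inside their support exactly; the plain
    normal rejects draws below zero (or outside the optional support) and
    raises :class:`DistributionError` when fewer than 1% of proposals would
    be feasible.
    """
    rng = _rng(seed)
    if spec.family == "point_mass":
        return np.full(n, spec.location, dtype=float)
    if spec.family == "empirical":
        return rng.choice(np.asarray(spec.values, dtype=float), size=n, replace=True)
    if spec.family == "truncated_normal":
        lo, hi = spec.support  # type: ignore[misc]
        a = (lo - spec.location) / spec.scale
        b = (hi - spec.location) / spec.scale
        return stats.truncnorm.rvs(a, b, loc=spec.location, scale=spec.scale, size=n, random_state=rng)
    if spec.family == "normal":
        lo, hi = spec._effective_bounds()
        feasible = stats.norm.cdf(hi, spec.location, spec.scale) - stats.norm.cdf(
            lo, spec.location, spec.scale
        )
        if feasible < 0.01:
            raise DistributionError(
                f"{spec.element}: normal({spec.location}, {spec.scale}) places "
                f"{100 * (1 - feasible):.1f}% of its mass outside [{lo}, {hi}]"
            )
        out = np.empty(0)
        while out.size < n:
            chunk = rng.normal(spec.location, spec.scale, size=max(n, 1024))
            out = np.concatenate([out, chunk[(chunk >= lo) & (chunk <= hi)]])
        return out[:n]
    if spec.family == "lognormal":
        draws = rng.lognormal(spec.location, spec.scale, size=n)
        return draws
    raise DistributionError(f"unknown family {spec.family!r}")


# ---------------------------------------------------------------------------
# Class probabilities and exceedance curves
# ---------------------------------------------------------------------------


def class_probabilities(
    draws: np.ndarray,
    thresholds: Sequence[float],
    rounding: int | None = None,
) -> np.ndarray:
    """Percentage of draws per class (half-open intervals, upper class at
    the threshold).  Unrounded unless *rounding* is given; rounding is
    half-even and applied only at this reporting layer."""
    idx = np.searchsorted(np.asarray(thresholds, dtype=float), draws, side="right")
    counts = np.bincount(idx, minlength=len(thresholds) + 1)
    probs = 100.0 * counts / draws.size
    if rounding is not None:
        probs = np.round(probs, rounding)
    return probs


def exceedance_curve(draws: Sequence[float]) -> pd.DataFrame:
    """Exceedance curve: for each distinct draw value v, ``P(X >= v)``.

    The curve starts at probability 1.0 and is nonincreasing.
    """
    x = np.asarray(draws, dtype=float)
    if x.size == 0:
        raise SedRiskError("exceedance_curve needs at least one draw")
    srt = np.sort(x)
    values = np.unique(srt)
    prob = (x.size - np.searchsorted(srt, values, side="left")) / x.size
    return pd.DataFrame({"value": values, "exceedance_probability": prob})


def _summary(draws: np.ndarray) -> dict[str, float]:
    qs = np.quantile(draws, [0.05, 0.25, 0.5, 0.75, 0.95])
    return {
        "count": int(draws.size),
        "mean": float(draws.mean()),
        "sd": float(draws.std(ddof=1)) if draws.size > 1 else 0.0,
        "min": float(draws.min()),
        "q05": float(qs[0]),
        "q25": float(qs[1]),
        "median": float(qs[2]),
        "q75": float(qs[3]),
        "q95": float(qs[4]),
        "max": float(draws.max()),
    }


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


@dataclass
class ElementMCResult:
    """Monte Carlo result for one element's Er."""

    element: str
    er_draws: np.ndarray
    summary: dict[str, float]
    class_probabilities: np.ndarray          # %, unrounded
    class_probabilities_rounded: np.ndarray  # %, per MCConfig.rounding


@dataclass
class MCResult:
    """Full simulation output: per-element Er and the summed RI."""

    elements: dict[str, ElementMCResult]
    ri_draws: np.ndarray
    ri_summary: dict[str, float]
    ri_class_probabilities: np.ndarray
    ri_class_probabilities_rounded: np.ndarray
    exceedance: dict[str, pd.DataFrame]  # per element + "RI"
    scheme: RiskScheme
    config: MCConfig
    excluded: dict[str, str] = field(default_factory=dict)

    def er_table(self) -> pd.DataFrame:
        """Risk-class probability table, rows = Er classes, columns = elements."""
        data = {
            el: r.class_probabilities_rounded for el, r in self.elements.items()
        }
        return pd.DataFrame(
            data,
            index=pd.Index(
                [f"{b} ({lab})" for b, lab in zip(self.scheme.er_bounds(), self.scheme.er_labels)],
                name="er_class",
            ),
        )

    def ri_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"probability_percent": self.ri_class_probabilities_rounded},
            index=pd.Index(
                [f"{b} ({lab})" for b, lab in zip(self.scheme.ri_bounds(), self.scheme.ri_labels)],
                name="ri_class",
            ),
        )


def simulate_element_risk(
    spec: DistributionSpec,
    reference: ReferenceEntry,
    config: MCConfig = MCConfig(),
    scheme: RiskScheme = DEFAULT_SCHEME,
    concentration_draws: np.ndarray | None = None,
) -> ElementMCResult:
    """Simulate one element's Er distribution and class probabilities.

    ``Er_j = T_r * C_j / C_n`` for each of the ``config.iterations`` draws
    ``C_j``.  Raises :class:`~sedrisk.risk_index.ExcludedElementError` when
    the reference entry lacks a background or toxic response.
    """
    if reference.background is None or reference.toxic_response is None:
        raise ExcludedElementError(
            f"{spec.element}: background and toxic_response are both required for Er"
        )
    if concentration_draws is None:
        concentration_draws = draw_concentrations(
            spec, config.iterations, element_seed(config.seed, spec.element)
        )
    # same association order as the deterministic index (T_r * (C / C_n)),
    # so point-mass specs reproduce assess_sites bit for bit
    er = reference.toxic_response * (concentration_draws / reference.background)
    probs = class_probabilities(er, scheme.er_thresholds)
    return ElementMCResult(
        element=spec.element,
        er_draws=er,
        summary=_summary(er),
        class_probabilities=probs,
        class_probabilities_rounded=np.round(probs, config.rounding),
    )


def simulate_total_risk(
    specs: Mapping[str, DistributionSpec] | Iterable[DistributionSpec],
    reference: Iterable[ReferenceEntry],
    config: MCConfig = MCConfig(),
    scheme: RiskScheme = DEFAULT_SCHEME,
    correlation: np.ndarray | None = None,
) -> MCResult:
    """Simulate Er per eligible element and RI as their per-draw sum.

    Elements are sampled independently by default, each from its own
    seeded substream.  An optional *correlation* matrix (Gaussian copula,
    order = sorted eligible elements) induces dependence between the
    concentration draws; the identity matrix reproduces independence in
    distribution (though from a single shared stream).
    """
    if not isinstance(specs, Mapping):
        specs = {s.element: s for s in specs}
    ref = reference_by_element(reference)

    eligible: list[str] = []
    excluded: dict[str, str] = {}
    for el in sorted(specs):
        entry = ref.get(el)
        if entry is None:
            excluded[el] = "no reference entry"
        elif entry.background is None or entry.toxic_response is None:
            missing = [
                f
                for f in ("background", "toxic_response")
                if getattr(entry, f) is None
            ]
            excluded[el] = " and ".join(missing) + " absent"
        else:
            eligible.append(el)
    if not eligible:
        raise ExcludedElementError("no element has both a spec and a complete reference entry")

    conc: dict[str, np.ndarray] = {}
    if correlation is None:
        for el in eligible:
            conc[el] = draw_concentrations(
                specs[el], config.iterations, element_seed(config.seed, el)
            )
    else:
        conc = _correlated_draws(
            [specs[el] for el in eligible], np.asarray(correlation, float), config
        )

    results: dict[str, ElementMCResult] = {}
    for el in eligible:
        results[el] = simulate_element_risk(
            specs[el], ref[el], config, scheme, concentration_draws=conc[el]
        )

    # correctly-rounded per-draw sum, matching hakanson_ri's fsum exactly
    stacked = np.stack([results[el].er_draws for el in eligible])
    if stacked.shape[0] == 1:
        ri = stacked[0].copy()
    else:
        ri = np.fromiter(
            (math.fsum(col) for col in stacked.T), dtype=float, count=stacked.shape[1]
        )
    ri_probs = class_probabilities(ri, scheme.ri_thresholds)
    exceedance = {el: exceedance_curve(results[el].er_draws) for el in eligible}
    exceedance["RI"] = exceedance_curve(ri)
    return MCResult(
        elements=results,
        ri_draws=ri,
        ri_summary=_summary(ri),
        ri_class_probabilities=ri_probs,
        ri_class_probabilities_rounded=np.round(ri_probs, config.rounding),
        exceedance=exceedance,
        scheme=scheme,
        config=config,
        excluded=excluded,
    )


def _correlated_draws(
    specs: Sequence[DistributionSpec],
    correlation: np.ndarray,
    config: MCConfig,
) -> dict[str, np.ndarray]:
    """Gaussian-copula sampling: one shared stream, marginals via ppf."""
    k = len(specs)
    if correlation.shape != (k, k):
        raise DistributionError(
            f"correlation matrix shape {correlation.shape} != ({k}, {k})"
        )
    rng = _rng(np.random.SeedSequence(entropy=[int(config.seed) % (2**31), 0x_C0_FF]))
    z = rng.multivariate_normal(np.zeros(k), correlation, size=config.iterations, method="cholesky")
    u = stats.norm.cdf(z)
    out: dict[str, np.ndarray] = {}
    for j, spec in enumerate(specs):
        out[spec.element] = _ppf(spec, u[:, j])
    return out


def _ppf(spec: DistributionSpec, u: np.ndarray) -> np.ndarray:
    if spec.family == "point_mass":
        return np.full(u.shape, spec.location, dtype=float)
    if spec.family == "empirical":
        v = np.sort(np.asarray(spec.values, dtype=float))
        idx = np.minimum((u * v.size).astype(int), v.size - 1)
        return v[idx]
    return spec.frozen().ppf(u)
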