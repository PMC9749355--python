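"""Parameter tables for the microsimulation: schema, validation, load/save.

All model inputs are carried in a single layered YAML document (bundled
defaults + optional user overrides).  Every section keeps a free-form
``provenance`` map tagging each parameter as ``paper``, ``supplement``,
``source-publication`` or ``assumption``; tags are preserved verbatim on
round-trip so a user re-transcribing the tables can see which defaults are
printed values and which are reconstructions.
"""

from __future__ import annotations

import copy
import importlib.resources
import math
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

MASS_TOL = 1e-9


class ConfigError(ValueError):
    """A parameter document is missing a table or violates an invariant."""


class _Frozen(BaseModel):
    model_config = ConfigDict(extra="forbid")


class RunConfig(_Frozen):
    n_individuals: int = 10000
    age_cap: int = 100
    cycle_length: int = 1
    discount_rate: float = 0.03
    wtp_threshold: float = 50000.0
    intervention_effect_sbp: float = -3.16
    effect_ci: tuple[float, float] = (-6.32, -0.01)
    intervention_years: int = 5
    adherence_years: int = 5
    # Duration of the SBP effect; defaults to adherence_years.  May exceed the
    # delivery period in threshold/sensitivity runs (effect persists, cost
    # does not).
    effect_years: Optional[int] = None
    master_seed: int = 20180301
    subgroup_age_range: Optional[tuple[float, float]] = None
    sbp_band_jitter: bool = True
    post_event_utility_from_event_cycle: bool = True
    budget_eligible_n: int = 502095
    budget_years: int = 5
    psa_inner_n: int = 2000
    psa_draws: int = 2000
    provenance: dict[str, str] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _invariants(self) -> "RunConfig":
        if not (0 <= self.discount_rate < 1):
            raise ConfigError(f"discount_rate must be in [0,1), got {self.discount_rate}")
        if self.n_individuals <= 0:
            raise ConfigError("n_individuals must be positive")
        if self.cycle_length != 1:
            raise ConfigError("cycle_length is fixed at 1 year")
        if not (self.intervention_years >= self.adherence_years >= 0):
            raise ConfigError(
                "require intervention_years >= adherence_years >= 0, got "
                f"{self.intervention_years} / {self.adherence_years}"
            )
        if self.effect_years is not None and self.effect_years < 0:
            raise ConfigError("effect_years must be >= 0")
        return self

    @property
    def effective_effect_years(self) -> int:
        return self.adherence_years if self.effect_years is None else self.effect_years


class Predictor(_Frozen):
    name: str
    transform: str
    beta: float
    center: float = 0.0
    scale: float = 1.0

    @model_validator(mode="after")
    def _check(self) -> "Predictor":
        if self.scale == 0:
            raise ConfigError(f"predictor {self.name}: scale must be nonzero")
        return self


class RiskModel(_Frozen):
    """A Cox-type linear-predictor risk equation.

    Horizon risk is ``1 - baseline_survival ** exp(lp)`` with
    ``lp = sum_j beta_j * (x_j - center_j) / scale_j``.
    """

    name: str
    horizon_years: int
    baseline_survival: float
    predictors: list[Predictor]
    provenance: dict[str, str] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _invariants(self) -> "RiskModel":
        if self.horizon_years not in (5, 10):
            raise ConfigError(f"risk model {self.name}: horizon must be 5 or 10 years")
        if not (0 < self.baseline_survival <= 1):
            raise ConfigError(
                f"risk model {self.name}: baseline_survival must be in (0,1], "
                f"got {self.baseline_survival}"
            )
        names = [p.name for p in self.predictors]
        if len(set(names)) != len(names):
            raise ConfigError(f"risk model {self.name}: duplicate predictor names")
        return self

    def predictor(self, name: str) -> Predictor:
        for p in self.predictors:
            if p.name == name:
                return p
        raise KeyError(name)


FIRST_EVER_SUBTYPES = (
    "MI",
    "UA",
    "ischaemic_stroke",
    "haemorrhagic_stroke",
    "TIA",
    "PVD",
    "CHF",
    "other_CHD",
    "other_CVD_death",
)
RECURRENT_SUBTYPES = ("nonfatal_stroke", "nonfatal_MI", "cvd_death")
FATAL_SUBTYPES = frozenset({"other_CVD_death", "cvd_death"})


def _check_mass(name: str, masses: dict[str, float] | list[float]) -> None:
    vals = list(masses.values()) if isinstance(masses, dict) else list(masses)
    if any(not (0 <= v <= 1) for v in vals):
        raise ConfigError(f"{name}: probabilities must lie in [0,1]")
    total = math.fsum(vals)
    if abs(total - 1.0) > MASS_TOL:
        raise ConfigError(f"{name}: masses must sum to 1, got {total!r}")


class SubtypeSplit(_Frozen):
    first_ever: dict[str, float]
    recurrent: dict[str, float]
    provenance: dict[str, str] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _invariants(self) -> "SubtypeSplit":
        if set(self.first_ever) != set(FIRST_EVER_SUBTYPES):
            raise ConfigError(
                "subtypes.first_ever must cover exactly "
                f"{sorted(FIRST_EVER_SUBTYPES)}, got {sorted(self.first_ever)}"
            )
        if set(self.recurrent) != set(RECURRENT_SUBTYPES):
            raise ConfigError(
                f"subtypes.recurrent must cover exactly {sorted(RECURRENT_SUBTYPES)}"
            )
        _check_mass("subtypes.first_ever", self.first_ever)
        _check_mass("subtypes.recurrent", self.recurrent)
        return self


class MortalityRow(_Frozen):
    age: int
    p: float


class MortalityTable(_Frozen):
    """Annual non-CVD death probability, step function over age."""

    rows: list[MortalityRow]
    provenance: dict[str, str] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _invariants(self) -> "MortalityTable":
        if not self.rows:
            raise ConfigError("mortality table is empty")
        ages = [r.age for r in self.rows]
        if ages != sorted(ages) or len(set(ages)) != len(ages):
            raise ConfigError("mortality rows must be strictly increasing in age")
        if any(not (0 <= r.p <= 1) for r in self.rows):
            raise ConfigError("mortality probabilities must lie in [0,1]")
        if ages[0] > 30:
            raise ConfigError("mortality table must cover ages from 30")
        return self

    def check_coverage(self, age_cap: int) -> None:
        # step function extends each row to the next; the last row covers all
        # older ages up to the cap it is validated against
        if self.rows[-1].age > age_cap:
            raise ConfigError("mortality table starts beyond age_cap")


class AgeBandValue(_Frozen):
    lo: float
    hi: float

    @model_validator(mode="after")
    def _ordered(self) -> "AgeBandValue":
        if not self.lo < self.hi:
            raise ConfigError(f"age band [{self.lo}, {self.hi}) is empty")
        return self


class UtilityBand(AgeBandValue):
    u: float


class EconTable(_Frozen):
    acute_costs: dict[str, float]
    mgmt_costs_annual: dict[str, float]
    intervention_cost_annual: float
    utilities_by_age: list[UtilityBand]
    post_event_utilities: dict[str, float]
    mrs_utilities: list[float]
    mrs_weights: list[float]
    dsa_ranges: dict[str, tuple[float, float]] = Field(default_factory=dict)
    psa_sd: dict[str, float] = Field(default_factory=dict)
    # how the age-curve and post-event utilities combine: "min" or "product"
    utility_combination: str = "min"
    # management cost after a recurrent event: "subtype" or "postCVD"
    mgmt_after_recurrent: str = "subtype"
    provenance: dict[str, str] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _invariants(self) -> "EconTable":
        for name, table in (("acute_costs", self.acute_costs),
                            ("mgmt_costs_annual", self.mgmt_costs_annual)):
            for k, v in table.items():
                if v < 0:
                    raise ConfigError(f"{name}.{k}: costs must be >= 0")
        if self.intervention_cost_annual < 0:
            raise ConfigError("intervention_cost_annual must be >= 0")
        for band in self.utilities_by_age:
            if not (0 <= band.u <= 1):
                raise ConfigError("utilities must lie in [0,1]")
        for k, v in self.post_event_utilities.items():
            if not (0 <= v <= 1):
                raise ConfigError(f"post_event_utilities.{k} must lie in [0,1]")
        if self.utility_combination not in ("min", "product"):
            raise ConfigError("utility_combination must be 'min' or 'product'")
        if self.mgmt_after_recurrent not in ("subtype", "postCVD"):
            raise ConfigError("mgmt_after_recurrent must be 'subtype' or 'postCVD'")
        if len(self.mrs_utilities) != len(self.mrs_weights):
            raise ConfigError("mrs_utilities and mrs_weights must align")
        _check_mass("mrs_weights", self.mrs_weights)
        for key in self.psa_sd:
            if self._base_value(key, required=False) is None:
                raise ConfigError(f"psa_sd.{key} has no base value in the tables")
        for key, (lo, hi) in self.dsa_ranges.items():
            base = self._base_value(key, required=False)
            if base is not None and not (lo <= base <= hi):
                raise ConfigError(
                    f"dsa_ranges.{key}: require lo <= base <= hi, got "
                    f"{lo} <= {base} <= {hi}"
                )
        return self

    # -- parameter lookup used by DSA/PSA ---------------------------------
    def _base_value(self, key: str, required: bool = True) -> Optional[float]:
        if key in self.acute_costs:
            return self.acute_costs[key]
        if key in self.mgmt_costs_annual:
            return self.mgmt_costs_annual[key]
        if key in self.post_event_utilities:
            return self.post_event_utilities[key]
        if key == "c_intervention":
            return self.intervention_cost_annual
        band = self._age_utility_band_for_key(key)
        if band is not None:
            return band.u
        if required:
            raise KeyError(key)
        return None

    def _age_utility_band_for_key(self, key: str) -> Optional[UtilityBand]:
        for band in self.utilities_by_age:
            if key == _age_band_key(band):
                return band
        return None

    def ischaemic_stroke_utility(self) -> float:
        """mRS-distribution-weighted post-ischaemic-stroke utility."""
        return math.fsum(w * u for w, u in zip(self.mrs_weights, self.mrs_utilities))

    def age_band_utility(self, age: float) -> float:
        for band in self.utilities_by_age:
            if band.lo <= age < band.hi:
                return band.u
        # beyond the oldest tabulated band: clamp to the oldest
        return self.utilities_by_age[-1].u


def _age_band_key(band: UtilityBand) -> str:
    if band.hi >= 120:
        return f"u_age_{int(band.lo)}plus"
    return f"u_age_{int(band.lo)}_{int(band.hi) - 1}"


class BandMass(AgeBandValue):
    mass: float


class BandProb(AgeBandValue):
    p: float


class BandDrift(AgeBandValue):
    d: float


class BandMeanSD(AgeBandValue):
    mean: float
    sd: float

    @model_validator(mode="after")
    def _sd(self) -> "BandMeanSD":
        if self.sd < 0:
            raise ConfigError("SDs must be >= 0")
        return self


class SmokingBand(AgeBandValue):
    never: float
    ex: float
    current: float

    @model_validator(mode="after")
    def _mass(self) -> "SmokingBand":
        _check_mass(f"smoking band [{self.lo},{self.hi})",
                    [self.never, self.ex, self.current])
        return self


class SBPBandSpec(_Frozen):
    edges: list[float]     # band midpoints, mmHg
    widths: list[float]

    @model_validator(mode="after")
    def _check(self) -> "SBPBandSpec":
        if len(self.edges) != len(self.widths):
            raise ConfigError("sbp_bands edges and widths must align")
        return self


class SBPBandMass(AgeBandValue):
    masses: list[float]


class PopulationMarginals(_Frozen):
    age_bands: list[BandMass]
    ses_quintile: list[float]
    smoking_by_age: list[SmokingBand]
    diabetes_prev_by_age: list[BandProb]
    sbp_bands: SBPBandSpec
    sbp_band_by_age: list[SBPBandMass]
    tc_by_age: list[BandMeanSD]
    hdl_by_age: list[BandMeanSD]
    sbp_annual_increment_by_age: list[BandDrift]
    tc_annual_increment_by_age: list[BandDrift]
    hdl_annual_increment_by_age: list[BandDrift]
    tc_floor: float = 2.0
    hdl_floor: float = 0.4
    provenance: dict[str, str] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _invariants(self) -> "PopulationMarginals":
        _check_mass("population.age_bands", [b.mass for b in self.age_bands])
        if len(self.ses_quintile) != 5:
            raise ConfigError("ses_quintile must have 5 masses")
        _check_mass("population.ses_quintile", self.ses_quintile)
        for band in self.sbp_band_by_age:
            if len(band.masses) != len(self.sbp_bands.edges):
                raise ConfigError(
                    f"sbp_band_by_age [{band.lo},{band.hi}): expected "
                    f"{len(self.sbp_bands.edges)} masses"
                )
            _check_mass(f"sbp_band_by_age [{band.lo},{band.hi})", band.masses)
        for b in self.age_bands:
            if b.lo < 30 or b.hi > 55:
                raise ConfigError("baseline age bands must lie within [30, 55)")
            for name, table in (
                ("smoking_by_age", self.smoking_by_age),
                ("diabetes_prev_by_age", self.diabetes_prev_by_age),
                ("sbp_band_by_age", self.sbp_band_by_age),
                ("tc_by_age", self.tc_by_age),
                ("hdl_by_age", self.hdl_by_age),
            ):
                if b.mass > 0 and _band_for_age(table, b.lo, required=False) is None:
                    raise ConfigError(
                        f"{name} has no band covering baseline age {b.lo}"
                    )
        return self


def _band_for_age(bands, age: float, required: bool = True):
    for b in bands:
        if b.lo <= age < b.hi:
            return b
    if required:
        raise ConfigError(f"no band covers age {age}")
    return None


class ModelParameters(_Frozen):
    """The full parameter bundle consumed by the simulator."""

    run: RunConfig
    risk_first_ever: RiskModel
    risk_recurrent: RiskModel
    subtypes: SubtypeSplit
    mortality: MortalityTable
    economics: EconTable
    population: PopulationMarginals

    @model_validator(mode="after")
    def _cross(self) -> "ModelParameters":
        self.mortality.check_coverage(self.run.age_cap)
        return self

    def mutated(self, **sections) -> "ModelParameters":
        """Return a copy with whole sections or dotted leaves replaced."""
        data = self.model_dump()
        for key, value in sections.items():
            parts = key.split(".")
            node = data
            for p in parts[:-1]:
                node = node[p]
            node[parts[-1]] = value
        return ModelParameters.model_validate(data)


REQUIRED_SECTIONS = (
    "run",
    "risk_first_ever",
    "risk_recurrent",
    "subtypes",
    "mortality",
    "economics",
    "population",
)


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def _default_raw() -> dict:
    text = (
        importlib.resources.files("cvdmicrosim")
        .joinpath("data/default_config.yaml")
        .read_text(encoding="utf-8")
    )
    return yaml.safe_load(text)


def default_parameters() -> ModelParameters:
    """The bundled default parameter set."""
    return ModelParameters.model_validate(_default_raw())


def load_config(path: str | Path | None = None, *, layered: bool = True) -> ModelParameters:
    """Load a parameter document.

    With ``layered=True`` (default) the document is merged over the bundled
    defaults, so a user file only needs to override what changes.  With
    ``layered=False`` the document must be complete.
    """
    if path is None:
        return default_parameters()
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
    if layered:
        raw = _deep_merge(_default_raw(), raw)
    missing = [s for s in REQUIRED_SECTIONS if s not in raw]
    if missing:
        raise ConfigError(f"missing required table(s): {', '.join(missing)}")
    return ModelParameters.model_validate(raw)


def save_config(params: ModelParameters, path: str | Path) -> None:
    """Write the full parameter set (lossless round-trip)."""
    data = params.model_dump(mode="json")
    Path(path).write_text(
        yaml.safe_dump(data, sort_keys=False, allow_unicode=True), encoding="utf-8"
    )
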