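"""Synthetic baseline cohort of women aged 30-54 drawn from survey marginals.

Individuals are sampled independently from configured marginal distributions
conditioned on age band only (no joint-dependence modelling).  Risk factors
drift deterministically with age during the simulation.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .config import ConfigError, PopulationMarginals, _band_for_age

SMOKING_LEVELS = ("never", "ex", "current")  # coded 0, 1, 2


@dataclasses.dataclass
class IndividualState:
    """One simulated woman."""

    id: int
    age: float
    ses_quintile: int
    smoking: str
    diabetes: bool
    sbp: float
    tc: float
    hdl: float
    alive: bool = True
    arm: str = "usual_care"
    on_intervention: bool = False
    cvd_history: list = dataclasses.field(default_factory=list)  # (subtype, cycle)
    first_event_cycle: Optional[int] = None

    def validate(self) -> None:
        if not (self.sbp > 0 and self.tc > 0 and self.hdl > 0):
            raise ValueError("risk factors must be positive")
        if (len(self.cvd_history) == 0) != (self.first_event_cycle is None):
            raise ValueError("cvd_history and first_event_cycle disagree")


@dataclasses.dataclass
class Cohort:
    """Column-oriented cohort; the engine operates on these arrays."""

    id: np.ndarray
    age: np.ndarray
    ses_quintile: np.ndarray
    smoking: np.ndarray        # int8 codes into SMOKING_LEVELS
    diabetes: np.ndarray
    sbp: np.ndarray
    tc: np.ndarray
    hdl: np.ndarray

    def __len__(self) -> int:
        return len(self.id)

    def subset(self, idx) -> "Cohort":
        return Cohort(**{
            f.name: getattr(self, f.name)[idx] for f in dataclasses.fields(self)
        })

    def individuals(self) -> list[IndividualState]:
        return [
            IndividualState(
                id=int(self.id[i]),
                age=float(self.age[i]),
                ses_quintile=int(self.ses_quintile[i]),
                smoking=SMOKING_LEVELS[int(self.smoking[i])],
                diabetes=bool(self.diabetes[i]),
                sbp=float(self.sbp[i]),
                tc=float(self.tc[i]),
                hdl=float(self.hdl[i]),
            )
            for i in range(len(self))
        ]

    @classmethod
    def from_individuals(cls, inds: list[IndividualState]) -> "Cohort":
        return cls(
            id=np.array([p.id for p in inds], dtype=np.int64),
            age=np.array([p.age for p in inds], dtype=float),
            ses_quintile=np.array([p.ses_quintile for p in inds], dtype=np.int8),
            smoking=np.array(
                [SMOKING_LEVELS.index(p.smoking) for p in inds], dtype=np.int8
            ),
            diabetes=np.array([p.diabetes for p in inds], dtype=bool),
            sbp=np.array([p.sbp for p in inds], dtype=float),
            tc=np.array([p.tc for p in inds], dtype=float),
            hdl=np.array([p.hdl for p in inds], dtype=float),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": self.id,
            "age": self.age,
            "ses": self.ses_quintile,
            "smoking": np.asarray(SMOKING_LEVELS)[self.smoking],
            "diabetes": self.diabetes.astype(int),
            "sbp": self.sbp,
            "tc": self.tc,
            "hdl": self.hdl,
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Cohort":
        df = pd.read_csv(path)
        return cls(
            id=df["id"].to_numpy(np.int64),
            age=df["age"].to_numpy(float),
            ses_quintile=df["ses"].to_numpy(np.int8),
            smoking=np.array(
                [SMOKING_LEVELS.index(s) for s in df["smoking"]], dtype=np.int8
            ),
            diabetes=df["diabetes"].to_numpy(bool),
            sbp=df["sbp"].to_numpy(float),
            tc=df["tc"].to_numpy(float),
            hdl=df["hdl"].to_numpy(float),
        )


def _truncated_normal(rng, mean, sd, floor):
    """Normal draw truncated below at a physiologic floor (element-wise)."""
    mean = np.asarray(mean, float)
    sd = np.asarray(sd, float)
    out = np.empty_like(mean)
    degenerate = sd <= 0
    out[degenerate] = np.maximum(mean[degenerate], floor)
    idx = ~degenerate
    if idx.any():
        a = (floor - mean[idx]) / sd[idx]
        u = rng.random(idx.sum())
        out[idx] = stats.truncnorm.ppf(u, a, np.inf, loc=mean[idx], scale=sd[idx])
    return out


def sample_cohort(
    marginals: PopulationMarginals, n: int, seed: int, *, sbp_jitter: bool = True
) -> Cohort:
    """Draw ``n`` independent individuals from the configured marginals.

    Age comes from the age-band masses (integer years uniform within band);
    SES quintile is unconditional; smoking, diabetes, SBP band, TC and HDL
    are drawn conditionally on the age band.  SBP is the band midpoint plus
    optional uniform within-band jitter.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if n == 0:
        return Cohort(*(np.empty(0, dtype=d) for d in
                        (np.int64, float, np.int8, np.int8, bool, float, float, float)))

    band_masses = np.array([b.mass for b in marginals.age_bands])
    band_idx = rng.choice(len(band_masses), size=n, p=band_masses / band_masses.sum())
    lo = np.array([b.lo for b in marginals.age_bands])[band_idx]
    hi = np.array([b.hi for b in marginals.age_bands])[band_idx]
    age = lo + np.floor(rng.random(n) * (hi - lo))

    ses = rng.choice(5, size=n, p=np.asarray(marginals.ses_quintile)) + 1

    smoking = np.empty(n, dtype=np.int8)
    diabetes = np.empty(n, dtype=bool)
    sbp = np.empty(n, dtype=float)
    tc_mean = np.empty(n)
    tc_sd = np.empty(n)
    hdl_mean = np.empty(n)
    hdl_sd = np.empty(n)

    edges = np.asarray(marginals.sbp_bands.edges)
    widths = np.asarray(marginals.sbp_bands.widths)

    for a in np.unique(age):
        sel = age == a
        m = int(sel.sum())
        smk = _band_for_age(marginals.smoking_by_age, a)
        smoking[sel] = rng.choice(
            3, size=m, p=np.array([smk.never, smk.ex, smk.current])
        )
        diabetes[sel] = rng.random(m) < _band_for_age(
            marginals.diabetes_prev_by_age, a
        ).p
        masses = np.asarray(_band_for_age(marginals.sbp_band_by_age, a).masses)
        bidx = rng.choice(len(edges), size=m, p=masses / masses.sum())
        jitter = (rng.random(m) - 0.5) * widths[bidx] if sbp_jitter else 0.0
        sbp[sel] = edges[bidx] + jitter
        tcb = _band_for_age(marginals.tc_by_age, a)
        hdlb = _band_for_age(marginals.hdl_by_age, a)
        tc_mean[sel], tc_sd[sel] = tcb.mean, tcb.sd
        hdl_mean[sel], hdl_sd[sel] = hdlb.mean, hdlb.sd

    tc = _truncated_normal(rng, tc_mean, tc_sd, marginals.tc_floor)
    hdl = _truncated_normal(rng, hdl_mean, hdl_sd, marginals.hdl_floor)

    return Cohort(
        id=np.arange(n, dtype=np.int64),
        age=age,
        ses_quintile=ses.astype(np.int8),
        smoking=smoking,
        diabetes=diabetes,
        sbp=sbp,
        tc=tc,
        hdl=hdl,
    )


def _drift(bands, age):
    """Vectorised per-year increment lookup for the band covering each age."""
    age = np.asarray(age, float)
    out = np.zeros_like(age)
    covered = np.zeros(age.shape, dtype=bool)
    for b in bands:
        sel = (age >= b.lo) & (age < b.hi)
        out[sel] = b.d
        covered |= sel
    out[~covered] = bands[-1].d  # extend the oldest band
    return out


def age_update_arrays(age, sbp, tc, hdl, marginals: PopulationMarginals):
    """One annual update: age + 1, risk factors shifted by the age-band drift.

    The drift of the band covering the *current* age applies, so trajectories
    are piecewise linear in age.  Floors keep lipids physiologic.
    """
    new_age = age + 1.0
    new_sbp = sbp + _drift(marginals.sbp_annual_increment_by_age, age)
    new_tc = np.maximum(tc + _drift(marginals.tc_annual_increment_by_age, age),
                        marginals.tc_floor)
    new_hdl = np.maximum(hdl + _drift(marginals.hdl_annual_increment_by_age, age),
                         marginals.hdl_floor)
    return new_age, new_sbp, new_tc, new_hdl


def age_update(individual: IndividualState,
               marginals: PopulationMarginals) -> IndividualState:
    """Return a copy of ``individual`` aged by one cycle."""
    if not individual.alive:
        raise ValueError("cannot age a dead individual")
    age, sbp, tc, hdl = (np.array([v], float) for v in
                         (individual.age, individual.sbp, individual.tc,
                          individual.hdl))
    a, s, t, h = age_update_arrays(age, sbp, tc, hdl, marginals)
    return dataclasses.replace(
        individual, age=float(a[0]), sbp=float(s[0]), tc=float(t[0]), hdl=float(h[0])
    )


def restrict_to_age_band(
    marginals: PopulationMarginals, lo: float, hi: float
) -> PopulationMarginals:
    """Zero age mass outside ``[lo, hi)`` and renormalise.

    Bands partially covered by the restriction are clipped and their mass
    scaled by the covered fraction (age is uniform within a band).  The
    conditional tables are untouched.
    """
    if hi <= lo:
        raise ValueError("empty age range")
    new_bands = []
    for b in marginals.age_bands:
        new_lo, new_hi = max(b.lo, lo), min(b.hi, hi)
        if new_hi > new_lo:
            frac = (new_hi - new_lo) / (b.hi - b.lo)
            new_bands.append({"lo": new_lo, "hi": new_hi, "mass": b.mass * frac})
    total = sum(b["mass"] for b in new_bands)
    if total <= 0:
        raise ConfigError(
            f"age restriction [{lo}, {hi}) leaves no population mass"
        )
    for b in new_bands:
        b["mass"] /= total
    data = marginals.model_dump()
    data["age_bands"] = new_bands
    return PopulationMarginals.model_validate(data)
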