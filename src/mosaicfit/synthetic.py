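"""Synthetic cohort generation with the statistical structure the fits assume.

Two generators are provided and serve as mutual oracles:

* ``sample_calls_theory`` draws detectable calls directly from the
  closed-form clone-size density: per person the detectable-clone count is
  Poisson with the prevalence-integral mean, and each clone's cell
  fraction is drawn by inverting the truncated CDF (an exponential
  integral) at the person's age.

* ``simulate_branching`` runs the forward stochastic process the density
  is derived from: mutant clones arise uniformly in time, survive drift
  with probability s*tau, and a surviving clone's odds x = f/(1-f) at age
  t is exponential with mean e^{s(t-t0)}/(Ntau*s).  An exact birth-death
  mode (``mode="exact"``) is available for small-scale validation.

Defaults emulate the UK Biobank study population: 482,789 people
(261,890 women / 220,899 men), age decades 40-49/50-59/60-69 weighted
23.8/33.6/42.6%, a 0.7% detection floor, and class-specific upper
cut-offs (losses 67%, CN-LOH 54%).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.special import exp1

from .exceptions import ConfigurationError, DomainError, ValidationError
from .inference import FEMALE, MALE, MCACall
from .theory import (
    CLASS_WINDOWS,
    UKB_AGE_MIXTURE,
    AgeMixture,
    DetectionWindow,
    TheoryParams,
    expected_prevalence,
    log_phi,
)

__all__ = [
    "CohortSpec",
    "ComponentTruth",
    "LabelTruth",
    "GroundTruth",
    "UKB_COHORT",
    "sample_calls_theory",
    "sample_spectrum_fractions",
    "simulate_branching",
    "apply_censoring",
    "simulate_allosome_interference",
]

#: Default lengths (MB) drawn for simulated calls, per class: wide enough to
#: exercise the allosomal size filters (mLOY > 2 MB, mLOX > 125 MB).
_LENGTH_RANGES = {
    "gain": (1.0, 150.0),
    "loss": (1.0, 150.0),
    "cnloh": (1.0, 150.0),
    "mloy": (2.5, 57.0),
    "mlox": (126.0, 155.0),
}


@dataclass(frozen=True)
class CohortSpec:
    """Cohort size, composition and detection windows.

    Defines both the observation model used by the fits (cohort size, age
    mixture, assumed Ntau, per-class windows) and the simulator.
    ``sex_ratio`` is the fraction of women.
    """

    n_people: int = 482_789
    sex_ratio: float = 261_890 / 482_789
    age_mixture: AgeMixture = UKB_AGE_MIXTURE
    ntau: float = 1e5
    windows: Mapping[str, DetectionWindow] = None  # type: ignore[assignment]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.windows is None:
            object.__setattr__(self, "windows", dict(CLASS_WINDOWS))
        if self.n_people < 1:
            raise ConfigurationError(f"n_people must be >= 1, got {self.n_people}")
        if not (0 <= self.sex_ratio <= 1):
            raise ConfigurationError(f"sex_ratio must lie in [0, 1], got {self.sex_ratio}")
        if self.ntau <= 0:
            raise ConfigurationError(f"ntau must be > 0, got {self.ntau}")

    @property
    def n_female(self) -> int:
        return int(round(self.n_people * self.sex_ratio))

    @property
    def n_male(self) -> int:
        return self.n_people - self.n_female

    def for_sex(self, sex: str) -> "CohortSpec":
        """Sub-cohort of one sex (used for sex-stratified fits)."""
        n = self.n_female if sex == FEMALE else self.n_male
        return replace(self, n_people=max(n, 1), sex_ratio=1.0 if sex == FEMALE else 0.0)


#: The study cohort with all defaults.
UKB_COHORT = CohortSpec()


@dataclass(frozen=True)
class ComponentTruth:
    s: float
    mu: float

    def __post_init__(self) -> None:
        if not (0 <= self.s <= 1):
            raise ConfigurationError(f"truth s must lie in [0, 1], got {self.s}")
        if self.mu < 0:
            raise ConfigurationError(f"truth mu must be >= 0, got {self.mu}")


@dataclass(frozen=True)
class LabelTruth:
    """Ground-truth parameters for one mCA label.

    ``s2``/``mu2`` add a second independent component (the two-event model
    for mosaic loss of X); ``female``/``male`` override (s, mu) per sex.
    """

    label: str
    mca_class: str
    s: float
    mu: float
    s2: float | None = None
    mu2: float | None = None
    female: ComponentTruth | None = None
    male: ComponentTruth | None = None

    def components_for(self, sex: str) -> list[ComponentTruth]:
        override = self.female if sex == FEMALE else self.male
        first = override if override is not None else ComponentTruth(self.s, self.mu)
        comps = [first]
        if self.s2 is not None and self.mu2 is not None:
            comps.append(ComponentTruth(self.s2, self.mu2))
        return comps

    def applies_to(self, sex: str) -> bool:
        if self.mca_class == "mloy":
            return sex == MALE
        if self.mca_class == "mlox":
            return sex == FEMALE
        return True


@dataclass(frozen=True)
class GroundTruth:
    labels: tuple[LabelTruth, ...]

    def __post_init__(self) -> None:
        if len({t.label for t in self.labels}) != len(self.labels):
            raise ConfigurationError("duplicate labels in ground truth")


# ---------------------------------------------------------------------------
# inverse-CDF machinery

_E1_GRID_U: np.ndarray | None = None
_E1_GRID_V: np.ndarray | None = None


def _inv_exp1(v: np.ndarray) -> np.ndarray:
    """Invert E1 on (0, inf): find u with E1(u) = v.  Interpolation + Newton."""
    global _E1_GRID_U, _E1_GRID_V
    if _E1_GRID_U is None:
        u = np.geomspace(1e-300, 740.0, 20000)
        _E1_GRID_U = u
        _E1_GRID_V = exp1(u)
    # E1 is decreasing; interpolate log u against E1 on reversed arrays
    log_u = np.interp(v, _E1_GRID_V[::-1], np.log(_E1_GRID_U)[::-1])
    u = np.exp(log_u)
    for _ in range(2):  # Newton polish: E1'(u) = -e^{-u}/u
        with np.errstate(over="ignore", divide="ignore"):
            step = (exp1(np.clip(u, 1e-300, 740.0)) - v) * u * np.exp(np.clip(u, None, 700.0))
        u = np.clip(u - step, 1e-300, 740.0)
    return u


def _draw_fractions(
    rng: np.random.Generator,
    s: float,
    ntau: float,
    ages: np.ndarray,
    window: DetectionWindow,
) -> np.ndarray:
    """Cell fractions of detectable clones for carriers of the given ages."""
    lp = log_phi(s, ages, ntau)
    x0 = window.f_lo / (1.0 - window.f_lo)
    x1 = window.f_hi / (1.0 - window.f_hi) if window.f_hi < 1.0 else np.inf
    u0 = np.clip(x0 * np.exp(-lp), 1e-300, None)
    e0 = np.where(u0 > 740.0, 0.0, exp1(np.clip(u0, None, 740.0)))
    if np.isfinite(x1):
        u1 = np.clip(x1 * np.exp(-lp), 1e-300, None)
        e1_ = np.where(u1 > 740.0, 0.0, exp1(np.clip(u1, None, 740.0)))
    else:
        e1_ = np.zeros_like(e0)
    r = rng.random(len(ages))
    target = e0 - r * (e0 - e1_)
    u = _inv_exp1(target)
    x = u * np.exp(lp)
    f = x / (1.0 + x)
    return np.clip(f, window.f_lo, window.f_hi)


def _draw_cohort(rng: np.random.Generator, cohort: CohortSpec) -> tuple[np.ndarray, np.ndarray]:
    """Ages (uniform within decade) and sexes for every person."""
    groups = cohort.age_mixture.groups
    gi = rng.choice(len(groups), size=cohort.n_people, p=cohort.age_mixture.weights)
    lo = np.array([g.lo for g in groups])[gi]
    hi = np.array([g.hi for g in groups])[gi]
    ages = lo + rng.random(cohort.n_people) * (hi - lo)
    female = rng.random(cohort.n_people) < cohort.sex_ratio
    return ages, female


def _person_id(i: int) -> str:
    return f"P{i:07d}"


def sample_calls_theory(
    truth: GroundTruth,
    cohort: CohortSpec,
    seed: int | None = None,
    full_window: bool = False,
) -> list[MCACall]:
    """Draw detectable mCA calls for a whole cohort from the clone-size theory.

    Per person and per truth component, the detectable-clone count is
    Poisson with mean equal to the prevalence integral at the person's
    age, and cell fractions are inverse-CDF draws from the truncated
    density.  ``full_window=True`` samples over (f_lo, 1) regardless of
    class, for censoring experiments.
    """
    rng = np.random.default_rng(seed if seed is not None else cohort.seed)
    ages, female = _draw_cohort(rng, cohort)
    sexes = np.where(female, FEMALE, MALE)
    calls: list[MCACall] = []
    for lt in truth.labels:
        if lt.mca_class not in cohort.windows:
            raise ConfigurationError(f"no detection window for class {lt.mca_class!r}")
        window = cohort.windows[lt.mca_class]
        if full_window:
            window = DetectionWindow(window.f_lo, 1.0)
        for sex in (FEMALE, MALE):
            if not lt.applies_to(sex):
                continue
            mask = female if sex == FEMALE else ~female
            idx_people = np.flatnonzero(mask)
            if len(idx_people) == 0:
                continue
            sub_ages = ages[idx_people]
            for comp in lt.components_for(sex):
                if comp.mu == 0:
                    continue
                params = TheoryParams(s=comp.s, ntau=cohort.ntau, mu=comp.mu)
                mean = expected_prevalence(params, sub_ages, window)
                counts = rng.poisson(mean)
                carriers = np.repeat(idx_people, counts)
                if len(carriers) == 0:
                    continue
                fr = _draw_fractions(rng, comp.s, cohort.ntau, ages[carriers], window)
                lo_mb, hi_mb = _LENGTH_RANGES[lt.mca_class]
                lengths = lo_mb + rng.random(len(carriers)) * (hi_mb - lo_mb)
                calls.extend(
                    MCACall(
                        person_id=_person_id(int(i)),
                        age=float(ages[i]),
                        sex=str(sexes[i]),
                        label=lt.label,
                        mca_class=lt.mca_class,
                        cell_fraction=float(f),
                        length_mb=float(mb),
                    )
                    for i, f, mb in zip(carriers, fr, lengths)
                )
    calls.sort(key=lambda c: (c.label, c.person_id, c.cell_fraction))
    return calls


def sample_spectrum_fractions(
    params: TheoryParams,
    mixture: AgeMixture,
    window: DetectionWindow,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw exactly ``n`` detectable cell fractions, ages uniform within decades.

    Lightweight sampler for estimator studies that do not need a full
    cohort; the carrier age distribution is the prevalence-weighted
    mixture, matching what a cohort sample produces.
    """
    groups = mixture.groups
    prev = np.array([g.weight * expected_prevalence(params, g.rep_age, window) for g in groups])
    p = prev / prev.sum()
    gi = rng.choice(len(groups), size=n, p=p)
    lo = np.array([g.lo for g in groups])[gi]
    hi = np.array([g.hi for g in groups])[gi]
    ages = lo + rng.random(n) * (hi - lo)
    return _draw_fractions(rng, params.s, params.ntau, ages, window)


def simulate_branching(
    s: float,
    mu: float,
    N: float,
    tau: float,
    age: float,
    seed: int | None = None,
    mode: str = "fast",
    max_cells: int = 1_000_000,
) -> np.ndarray:
    """Forward branching-process simulation of one stem-cell population.

    Returns the cell fractions of all surviving mutant clones at ``age``.

    ``mode="fast"`` uses the survival-conditioned exponential construction
    the clone-size density is derived from: surviving clones arrive as a
    Poisson process at rate N*mu*(s*tau) per year and a clone born at t0
    has odds x ~ Exp(mean e^{s(age-t0)}/(N*tau*s)).  ``mode="exact"`` runs
    a continuous-time critical-plus-s birth-death process per mutant
    (division rate (1+s*tau)/(2*tau), death rate (1-s*tau)/(2*tau)) and is
    intended for small-scale validation only.
    """
    if age <= 0:
        raise DomainError(f"age must be > 0, got {age}")
    if N <= 0 or tau <= 0 or mu < 0:
        raise DomainError("require N > 0, tau > 0, mu >= 0")
    if N * mu * age > 1e6:
        raise DomainError(
            f"expected mutant count N*mu*age = {N * mu * age:.3g} exceeds the desk-scale guard (1e6); "
            "rescale mu to keep Ntau*mu fixed"
        )
    rng = np.random.default_rng(seed)
    if mode == "fast":
        if s <= 0:
            raise DomainError("fast mode requires s > 0 (use mode='exact' for neutral clones)")
        if s * tau >= 1:
            raise DomainError(f"fast mode requires s*tau < 1, got {s * tau}")
        ntau = N * tau
        k = rng.poisson(ntau * mu * s * age)
        dt = age * rng.random(k)  # time since clone birth
        x = rng.exponential(1.0, size=k) * np.exp(s * dt) / (ntau * s)
        return x / (1.0 + x)
    if mode != "exact":
        raise ConfigurationError(f"mode must be 'fast' or 'exact', got {mode!r}")
    if s * tau >= 1:
        raise DomainError(f"exact mode requires s*tau < 1, got {s * tau}")
    birth = (1.0 + s * tau) / (2.0 * tau)
    death = (1.0 - s * tau) / (2.0 * tau)
    m = rng.poisson(N * mu * age)
    t0 = np.sort(age * rng.random(m))
    sizes = []
    for tb in t0:
        n_cells = 1
        t = tb
        while n_cells > 0:
            rate = n_cells * (birth + death)
            t += rng.exponential(1.0 / rate)
            if t >= age:
                break
            if rng.random() < birth / (birth + death):
                n_cells += 1
                if n_cells > max_cells:
                    raise DomainError("clone exceeded max_cells; reduce the horizon")
            else:
                n_cells -= 1
        if n_cells > 0:
            sizes.append(n_cells)
    x = np.array(sizes, dtype=float) / N
    return x / (1.0 + x)


def apply_censoring(
    calls: Sequence[MCACall],
    windows: Mapping[str, DetectionWindow] | None = None,
) -> list[MCACall]:
    """Drop calls outside their class detection window; removal counts are logged."""
    import logging

    windows = windows if windows is not None else CLASS_WINDOWS
    kept: list[MCACall] = []
    removed: dict[str, int] = {}
    for c in calls:
        w = windows.get(c.mca_class)
        if w is None or (w.f_lo <= c.cell_fraction <= w.f_hi):
            kept.append(c)
        else:
            removed[c.mca_class] = removed.get(c.mca_class, 0) + 1
    if removed:
        logging.getLogger(__name__).info("censoring removed calls per class: %s", removed)
    return kept


def _combine_fractions(fractions: np.ndarray, mode: str, f_cap: float) -> float:
    """Observable cell fraction of multiple same-class clones in one person."""
    if mode == "mloy_sum":
        return float(min(np.sum(fractions), f_cap))
    if mode == "mlox_difference":
        if len(fractions) == 1:
            return float(fractions[0])
        top2 = np.sort(fractions)[-2:]
        return float(min(abs(top2[1] - top2[0]), f_cap))
    raise ConfigurationError(f"mode must be 'mloy_sum' or 'mlox_difference', got {mode!r}")


def simulate_allosome_interference(
    truth: GroundTruth,
    cohort: CohortSpec,
    mode: str,
    seed: int | None = None,
) -> list[MCACall]:
    """Allosomal cohort where co-occurring independent clones are confounded.

    When a person carries multiple clones of the class, the single emitted
    call has the sum (mLOY: both events remove the same chromosome) or the
    absolute difference (mLOX: events can hit opposite homologs) of the
    clone fractions, capped at the window; the combined call is kept only
    if still detectable.
    """
    if mode not in ("mloy_sum", "mlox_difference"):
        raise ConfigurationError(f"unknown interference mode {mode!r}")
    want_class = "mloy" if mode == "mloy_sum" else "mlox"
    allo = [t for t in truth.labels if t.mca_class == want_class]
    if not allo:
        raise ValidationError(f"ground truth contains no {want_class} label")
    raw = sample_calls_theory(GroundTruth(tuple(allo)), cohort, seed=seed)
    window = cohort.windows[want_class]
    by_person: dict[str, list[MCACall]] = {}
    for c in raw:
        by_person.setdefault(c.person_id, []).append(c)
    out: list[MCACall] = []
    for pid in sorted(by_person):
        group = by_person[pid]
        if len(group) == 1:
            out.append(group[0])
            continue
        f = _combine_fractions(np.array([c.cell_fraction for c in group]), mode, window.f_hi)
        if f >= window.f_lo:
            out.append(replace(group[0], cell_fraction=f))
    return out
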