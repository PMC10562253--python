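"""Closed-form clone-size theory for mosaic chromosomal alterations (mCAs).

A stem cell pool of N cells, with symmetric division time tau (years),
acquires a given mCA at rate mu per cell per year.  A clone carrying the
mCA expands exponentially at a fitness effect s per year.  At age t the
expected density of clones per person, per unit l = log(cell fraction), is

    rho(l) = Ntau*mu / (1 - e^l) * exp(-e^l / (phi * (1 - e^l)))

with the characteristic scale

    phi = (e^{s t} - 1) / (Ntau * s),

below which the density plateaus at the amplitude Ntau*mu and above which
it falls off exponentially.  Writing x = f/(1-f) for the clone's odds the
density becomes Ntau*mu * e^{-x/phi} / x per unit x, so prevalence
integrals reduce to exponential integrals:

    P(f0 < f < f1) = Ntau*mu * [E1(x0/phi) - E1(x1/phi)].

Everything here is a pure deterministic function of (s, Ntau, mu, t); the
rest of the package builds estimation and simulation on top of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import exp1

from .exceptions import ConfigurationError, DomainError

__all__ = [
    "TheoryParams",
    "AgeGroup",
    "AgeMixture",
    "DetectionWindow",
    "UKB_AGE_MIXTURE",
    "CLASS_WINDOWS",
    "log_phi",
    "clone_density_log",
    "clone_density_cf",
    "age_mixture_density",
    "expected_prevalence",
    "expected_prevalence_mixture",
    "detection_conditional_cdf",
    "prevalence_linear_approx",
    "LinearApprox",
]

_TINY = 1e-300


@dataclass(frozen=True)
class TheoryParams:
    """Evolutionary parameters of one mCA.

    Parameters
    ----------
    s : float
        Fitness effect (clonal growth advantage), per year. ``s >= 0``.
    ntau : float
        Product of stem-cell number N and symmetric division time tau, years.
    mu : float
        Mutation rate towards this mCA, per cell per year.
    """

    s: float
    ntau: float
    mu: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.s) or self.s < 0:
            raise DomainError(f"s must be finite and >= 0, got {self.s}")
        if not np.isfinite(self.ntau) or self.ntau <= 0:
            raise DomainError(f"ntau must be finite and > 0, got {self.ntau}")
        if not np.isfinite(self.mu) or self.mu < 0:
            raise DomainError(f"mu must be finite and >= 0, got {self.mu}")

    @property
    def amplitude(self) -> float:
        """Low-frequency density plateau Ntau * mu (dimensionless)."""
        return self.ntau * self.mu

    @classmethod
    def from_amplitude(cls, s: float, amplitude: float, ntau: float = 1e5) -> "TheoryParams":
        """Build parameters from a fitted amplitude Ntau*mu and an assumed Ntau."""
        return cls(s=s, ntau=ntau, mu=amplitude / ntau)


@dataclass(frozen=True)
class AgeGroup:
    """One age interval with its cohort weight.

    ``representative`` defaults to the interval midpoint; it is the single
    age at which the group's density/prevalence is evaluated.
    """

    lo: float
    hi: float
    weight: float
    representative: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ConfigurationError(f"invalid age interval ({self.lo}, {self.hi})")
        if not (self.weight > 0):
            raise ConfigurationError(f"age-group weight must be > 0, got {self.weight}")

    @property
    def rep_age(self) -> float:
        return self.representative if self.representative is not None else 0.5 * (self.lo + self.hi)


@dataclass(frozen=True)
class AgeMixture:
    """Cohort age distribution as weighted, non-overlapping, ascending intervals."""

    groups: tuple[AgeGroup, ...]

    def __post_init__(self) -> None:
        if len(self.groups) == 0:
            raise ConfigurationError("age mixture must contain at least one group")
        total = sum(g.weight for g in self.groups)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"age-group weights must sum to 1, got {total}")
        for a, b in zip(self.groups, self.groups[1:]):
            if b.lo < a.hi:
                raise ConfigurationError("age intervals must be ascending and non-overlapping")

    @property
    def weights(self) -> np.ndarray:
        return np.array([g.weight for g in self.groups])

    @property
    def rep_ages(self) -> np.ndarray:
        return np.array([g.rep_age for g in self.groups])

    @classmethod
    def single_age(cls, t: float) -> "AgeMixture":
        """Degenerate mixture: everyone aged exactly ``t``."""
        return cls((AgeGroup(t - 0.5, t + 0.5, 1.0, representative=t),))


#: UK Biobank age-decade weights (ages 40-49 / 50-59 / 60-69).
UKB_AGE_MIXTURE = AgeMixture(
    (
        AgeGroup(40.0, 50.0, 0.238),
        AgeGroup(50.0, 60.0, 0.336),
        AgeGroup(60.0, 70.0, 0.426),
    )
)


@dataclass(frozen=True)
class DetectionWindow:
    """Cell-fraction interval within which calls of a class are observable."""

    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 < self.f_lo <= self.f_hi <= 1):
            raise DomainError(
                f"detection window must satisfy 0 < f_lo <= f_hi <= 1, got ({self.f_lo}, {self.f_hi})"
            )

    def contains(self, f: np.ndarray | float) -> np.ndarray | bool:
        return (np.asarray(f) >= self.f_lo) & (np.asarray(f) <= self.f_hi)


#: Class-specific detection windows: 0.7% phasing sensitivity floor everywhere;
#: losses and CN-LOH drop out of the calls above 67% / 54% cell fraction
#: (B-allele-frequency deviation > 0.25 in the upstream caller); gains and
#: allosomal losses have no stated upper cut-off.
CLASS_WINDOWS: dict[str, DetectionWindow] = {
    "gain": DetectionWindow(0.007, 1.0),
    "loss": DetectionWindow(0.007, 0.67),
    "cnloh": DetectionWindow(0.007, 0.54),
    "mloy": DetectionWindow(0.007, 1.0),
    "mlox": DetectionWindow(0.007, 1.0),
}


def log_phi(s: float, t, ntau: float):
    """log of phi(t) = (e^{s t} - 1)/(Ntau s), with a continuous s -> 0 limit.

    Evaluated in log space so that very large ``s*t`` (deep saturation)
    never overflows; for ``s*t < 1e-8`` the series limit phi -> t/Ntau is
    used, making the density continuous at s = 0.
    """
    t = np.asarray(t, dtype=float)
    s_arr = np.asarray(s, dtype=float)
    st = s_arr * t
    s_safe = np.maximum(s_arr, _TINY)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        mid = np.log(np.expm1(np.clip(st, 1e-12, 700.0))) - np.log(ntau * s_safe)
        big = st - np.log(ntau * s_safe)
        small = np.log(t / ntau)
    out = np.where(st < 1e-8, small, np.where(st > 700.0, big, mid))
    return out if out.ndim else float(out)


def _check_age(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)) or np.any(t <= 0):
        raise DomainError(f"age t must be finite and > 0, got {t}")
    return t


def clone_density_log(l, params: TheoryParams, t):
    """Expected clone density per person per unit l = log(cell fraction).

    Finite and non-negative for every l < 0; approaches the plateau
    Ntau*mu as l -> -inf and is exponentially suppressed for cell
    fractions above phi.
    """
    l = np.asarray(l, dtype=float)
    if not np.all(np.isfinite(l)):
        raise DomainError("l (log cell fraction) must be finite")
    if np.any(l >= 0):
        raise DomainError("l (log cell fraction) must be < 0, i.e. cell fraction in (0, 1)")
    t = _check_age(t)
    one_minus_f = -np.expm1(l)  # 1 - f, accurate near f -> 1
    log_x = l - np.log(one_minus_f)
    z = np.exp(log_x - log_phi(params.s, t, params.ntau))
    with np.errstate(divide="ignore"):
        log_rho = np.log(max(params.amplitude, _TINY)) - np.log(one_minus_f) - z
    rho = np.exp(log_rho) if params.amplitude > 0 else np.zeros_like(log_rho)
    return rho if rho.ndim else float(rho)


def clone_density_cf(f, params: TheoryParams, t):
    """Expected clone density per person per unit cell fraction.

    Equals ``clone_density_log(log f) / f`` (change of variables dl = df/f).
    """
    f = np.asarray(f, dtype=float)
    if not np.all(np.isfinite(f)) or np.any(f <= 0) or np.any(f >= 1):
        raise DomainError(f"cell fraction f must lie in (0, 1), got {f}")
    rho = clone_density_log(np.log(f), params, t) / f
    return rho if np.asarray(rho).ndim else float(rho)


def age_mixture_density(l, params: TheoryParams, mixture: AgeMixture):
    """Cohort-level density: the per-age density weighted over the age mixture."""
    if not isinstance(mixture, AgeMixture):
        raise ConfigurationError("mixture must be an AgeMixture")
    out = 0.0
    for g in mixture.groups:
        out = out + g.weight * clone_density_log(l, params, g.rep_age)
    return out


def _odds(f: float) -> float:
    return f / (1.0 - f) if f < 1.0 else np.inf


def _e1(arg):
    """exp1 with underflow/overflow guards (arg clipped away from 0; E1(inf)=0)."""
    arg = np.asarray(arg, dtype=float)
    out = np.where(arg > 700.0, 0.0, exp1(np.clip(arg, _TINY, 700.0)))
    return out


def expected_prevalence(params: TheoryParams, t, window: DetectionWindow):
    """Expected number of detectable clones per person of age ``t``.

    Exact value of the prevalence integral of the clone-size density over
    (f_lo, f_hi): with x = f/(1-f),

        Ntau*mu * [E1(x_lo/phi) - E1(x_hi/phi)].

    In the rare-event regimes of interest this is << 1 and doubles as the
    carrier probability; the simulator uses it as a Poisson mean, the
    exact convention for independent rare clone initiations.
    """
    t = _check_age(t)
    if window.f_lo == window.f_hi:
        return np.zeros_like(t) if t.ndim else 0.0
    lp = log_phi(params.s, t, params.ntau)
    x0 = _odds(window.f_lo)
    x1 = _odds(window.f_hi)
    term0 = _e1(x0 * np.exp(-lp))
    term1 = _e1(x1 * np.exp(-lp)) if np.isfinite(x1) else 0.0
    out = params.amplitude * (term0 - term1)
    return out if np.asarray(out).ndim else float(out)


def expected_prevalence_mixture(params: TheoryParams, mixture: AgeMixture, window: DetectionWindow) -> float:
    """Expected detectable-clone count per person, averaged over the age mixture."""
    return float(
        sum(g.weight * expected_prevalence(params, g.rep_age, window) for g in mixture.groups)
    )


def detection_conditional_cdf(f, params: TheoryParams, t: float, window: DetectionWindow):
    """CDF of the cell fraction of a detectable clone, conditioned on detection."""
    f = np.asarray(f, dtype=float)
    lp = log_phi(params.s, t, params.ntau)
    x0 = _odds(window.f_lo)
    x1 = _odds(window.f_hi)
    e0 = _e1(x0 * np.exp(-lp))
    e1_ = _e1(x1 * np.exp(-lp)) if np.isfinite(x1) else 0.0
    ef = _e1((f / (1.0 - f)) * np.exp(-lp))
    out = np.clip((e0 - ef) / (e0 - e1_), 0.0, 1.0)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class LinearApprox:
    """Linearised prevalence Ntau*mu*log(phi/f_lim) ~ Ntau*mu*s*t + C.

    ``valid`` is False when f_lim >= phi, where the logarithmic
    approximation to the prevalence integral breaks down.
    """

    value: float
    slope: float
    intercept: float
    valid: bool
    log_phi: float = field(repr=False, default=np.nan)


def prevalence_linear_approx(params: TheoryParams, t: float, f_lim: float) -> LinearApprox:
    """Linear-in-age approximation to the prevalence above detection limit f_lim.

    Returns the value Ntau*mu*log(phi/f_lim) together with the asymptotic
    slope Ntau*mu*s and intercept C = -Ntau*mu*log(Ntau*s*f_lim).  The
    result is flagged invalid (rather than raising) when f_lim >= phi.
    """
    if not (0 < f_lim < 1):
        raise DomainError(f"f_lim must lie in (0, 1), got {f_lim}")
    t_arr = _check_age(t)
    lp = log_phi(params.s, float(t_arr), params.ntau)
    amp = params.amplitude
    value = amp * (lp - np.log(f_lim))
    slope = amp * params.s
    with np.errstate(divide="ignore"):
        intercept = -amp * np.log(params.ntau * max(params.s, _TINY) * f_lim)
    return LinearApprox(
        value=float(value),
        slope=float(slope),
        intercept=float(intercept),
        valid=bool(np.log(f_lim) < lp),
        log_phi=float(lp),
    )
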