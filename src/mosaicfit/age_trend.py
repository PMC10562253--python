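"""Observed versus expected mCA prevalence by age group.

Under constant (s, mu), prevalence above a fixed detection limit grows
approximately linearly in age with slope Ntau*mu*s.  This module counts
carriers per age decade, computes the matching model expectation from a
fit, estimates both gradients by weighted least squares (weight T/(2p),
the inverse binomial variance for small p), and tests the relative
deviation (m_obs - m_exp)/m_exp against zero with a bootstrap
distribution-of-difference curve.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .exceptions import ConfigurationError, InsufficientDataError, ValidationError
from .inference import FitResult, MCACall
from .theory import DetectionWindow, TheoryParams, expected_prevalence

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic import CohortSpec

__all__ = [
    "AgePrevalencePoint",
    "GradientFit",
    "AgeTrend",
    "observed_prevalence",
    "expected_trend",
    "class_trend",
    "fit_gradient",
    "build_age_trend",
    "deviation_test",
    "mca_detection_floor",
]


@dataclass(frozen=True)
class AgePrevalencePoint:
    """Prevalence of one mCA in one age group."""

    age_lo: float
    age_hi: float
    t: float  # representative age used in gradient fits
    T: float  # persons in the group
    k: float  # carriers (expected points carry the non-integer model value)
    p: float
    sd: float


def _point(age_lo: float, age_hi: float, t: float, T: float, k: float) -> AgePrevalencePoint:
    p = k / T if T > 0 else 0.0
    sd = float(np.sqrt(max(p * (1 - p), 0.0) / T)) if T > 0 else 0.0
    return AgePrevalencePoint(age_lo=age_lo, age_hi=age_hi, t=t, T=T, k=k, p=p, sd=sd)


def _group_sizes(cohort: "CohortSpec", sex: str | None) -> np.ndarray:
    if sex is None:
        n = cohort.n_people
    elif sex == "female":
        n = cohort.n_female
    elif sex == "male":
        n = cohort.n_male
    else:
        raise ConfigurationError(f"sex must be None, 'female' or 'male', got {sex!r}")
    return n * cohort.age_mixture.weights


def observed_prevalence(
    calls: Sequence[MCACall],
    cohort: "CohortSpec",
    label: str,
    f_lo: float = 0.007,
    sex: str | None = None,
) -> list[AgePrevalencePoint]:
    """Carrier prevalence per age group, counting each person at most once.

    Only calls of ``label`` with cell fraction >= ``f_lo`` (the mCA's
    detection floor) count; an absent label yields all-zero points.
    """
    sizes = _group_sizes(cohort, sex)
    groups = cohort.age_mixture.groups
    carriers: list[set[str]] = [set() for _ in groups]
    for c in calls:
        if c.label != label or c.cell_fraction < f_lo:
            continue
        if sex is not None and c.sex != sex:
            continue
        for gi, g in enumerate(groups):
            if g.lo <= c.age < g.hi:
                carriers[gi].add(c.person_id)
                break
    return [
        _point(g.lo, g.hi, g.rep_age, float(T), float(len(ppl)))
        for g, T, ppl in zip(groups, sizes, carriers)
    ]


def expected_trend(
    fit: FitResult,
    cohort: "CohortSpec",
    window: DetectionWindow | None = None,
    sex: str | None = None,
) -> list[AgePrevalencePoint]:
    """Model-expected prevalence per age group for a converged fit."""
    if not fit.converged:
        raise ValidationError(f"fit for {fit.label!r} did not converge")
    window = window if window is not None else fit.window
    if window is None:
        raise ConfigurationError("expected_trend requires a detection window")
    params = TheoryParams.from_amplitude(fit.s_hat, fit.amplitude_hat, ntau=cohort.ntau)
    sizes = _group_sizes(cohort, sex)
    out = []
    for g, T in zip(cohort.age_mixture.groups, sizes):
        p = expected_prevalence(params, g.rep_age, window)
        out.append(_point(g.lo, g.hi, g.rep_age, float(T), float(p * T)))
    return out


def _sum_points(point_lists: list[list[AgePrevalencePoint]]) -> list[AgePrevalencePoint]:
    out = []
    for pts in zip(*point_lists):
        first = pts[0]
        k = sum(p.k for p in pts)
        out.append(_point(first.age_lo, first.age_hi, first.t, first.T, k))
    return out


def class_trend(
    fits: Sequence[FitResult],
    cohort: "CohortSpec",
    calls: Sequence[MCACall] | None = None,
    sex: str | None = None,
) -> "AgeTrend":
    """Class-level trend: per-decade expectations summed over member mCAs.

    With ``calls`` given, the observed side is the sum of per-label
    prevalences above the class window floor, as in the class-level
    age-dependence comparison.
    """
    if len(fits) == 0:
        raise InsufficientDataError("class_trend requires at least one fit")
    classes = {f.mca_class for f in fits}
    if len(classes) > 1:
        raise ValidationError(f"class_trend requires a single mCA class, got {sorted(classes)}")
    window = cohort.windows[fits[0].mca_class]
    expected = _sum_points([expected_trend(f, cohort, window=window, sex=sex) for f in fits])
    if calls is not None:
        observed = _sum_points(
            [observed_prevalence(calls, cohort, f.label, f_lo=window.f_lo, sex=sex) for f in fits]
        )
    else:
        observed = [_point(p.age_lo, p.age_hi, p.t, p.T, 0.0) for p in expected]
    return _assemble_trend("+".join(sorted(f.label for f in fits)), observed, expected, window=window)


@dataclass(frozen=True)
class GradientFit:
    m: float
    c: float
    determined: bool
    excluded: tuple[int, ...] = ()


def fit_gradient(
    points: Sequence[AgePrevalencePoint],
    weights: Sequence[float] | None = None,
    exclude: Sequence[int] = (),
) -> GradientFit:
    """Weighted least squares of p against y = m*t + c.

    Default weight is T/(2p) per point, proportional to the inverse
    binomial sampling variance of a small prevalence.  Points whose index
    is in ``exclude`` (and, with default weights, points with p = 0) do
    not contribute; fewer than two usable points yields an undetermined
    gradient rather than an error.
    """
    exclude = set(exclude)
    t, y, w, used = [], [], [], []
    for i, pt in enumerate(points):
        if i in exclude:
            continue
        if weights is None:
            if pt.p <= 0:
                exclude.add(i)
                continue
            wi = pt.T / (2.0 * pt.p)
        else:
            wi = float(weights[i])
            if not np.isfinite(wi) or wi <= 0:
                exclude.add(i)
                continue
        t.append(pt.t)
        y.append(pt.p)
        w.append(wi)
        used.append(i)
    if len(used) < 2:
        return GradientFit(m=np.nan, c=np.nan, determined=False, excluded=tuple(sorted(exclude)))
    t = np.array(t)
    y = np.array(y)
    w = np.array(w)
    sw = w.sum()
    tbar = np.dot(w, t) / sw
    ybar = np.dot(w, y) / sw
    stt = np.dot(w, (t - tbar) ** 2)
    if stt == 0:
        return GradientFit(m=np.nan, c=np.nan, determined=False, excluded=tuple(sorted(exclude)))
    m = float(np.dot(w, (t - tbar) * (y - ybar)) / stt)
    c = float(ybar - m * tbar)
    return GradientFit(m=m, c=c, determined=True, excluded=tuple(sorted(exclude)))


@dataclass(frozen=True)
class AgeTrend:
    """Observed and expected prevalence trend with the deviation statistic."""

    label: str
    points_observed: tuple[AgePrevalencePoint, ...]
    points_expected: tuple[AgePrevalencePoint, ...]
    m_obs: float
    m_exp: float
    c_obs: float
    c_exp: float
    deviation: float
    excluded_groups: tuple[int, ...]
    determined: bool
    window: DetectionWindow | None = None
    p_value: float | None = None
    significant: bool | None = None
    p_value_reason: str | None = None


def _assemble_trend(
    label: str,
    observed: list[AgePrevalencePoint],
    expected: list[AgePrevalencePoint],
    window: DetectionWindow | None = None,
) -> AgeTrend:
    # decades with zero observed carriers are excluded from both gradients
    zero_obs = tuple(i for i, p in enumerate(observed) if p.k == 0)
    g_obs = fit_gradient(observed, exclude=zero_obs)
    g_exp = fit_gradient(expected, exclude=zero_obs)
    determined = g_obs.determined and g_exp.determined
    if determined and g_exp.m != 0:
        deviation = (g_obs.m - g_exp.m) / g_exp.m
    else:
        deviation = np.nan
    return AgeTrend(
        label=label,
        points_observed=tuple(observed),
        points_expected=tuple(expected),
        m_obs=g_obs.m,
        m_exp=g_exp.m,
        c_obs=g_obs.c,
        c_exp=g_exp.c,
        deviation=float(deviation),
        excluded_groups=zero_obs,
        determined=determined,
        window=window,
    )


def mca_detection_floor(calls: Sequence[MCACall], factor: float = 1.5) -> float:
    """Per-mCA lower detection limit: 1.5x the minimum observed cell fraction."""
    if len(calls) == 0:
        raise InsufficientDataError("no calls to derive a detection floor from")
    return factor * min(c.cell_fraction for c in calls)


def build_age_trend(
    fit: FitResult,
    calls: Sequence[MCACall],
    cohort: "CohortSpec",
    sex: str | None = None,
    f_lo: float | None = None,
) -> AgeTrend:
    """Full observed-vs-expected trend for one mCA.

    The lower limit defaults to 1.5x the minimum observed cell fraction
    (reducing false negatives near the sensitivity floor); the upper
    limit is the class-specific cut-off from the fit's window.
    """
    own = [c for c in calls if c.label == fit.label]
    if f_lo is None:
        f_lo = mca_detection_floor(own) if own else fit.window.f_lo
    window = DetectionWindow(f_lo, fit.window.f_hi)
    observed = observed_prevalence(calls, cohort, fit.label, f_lo=f_lo, sex=sex)
    expected = expected_trend(fit, cohort, window=window, sex=sex)
    return _assemble_trend(fit.label, observed, expected, window=window)


def deviation_test(
    trend: AgeTrend,
    fit: FitResult,
    cohort: "CohortSpec",
    calls: Sequence[MCACall] | None = None,
    window: DetectionWindow | None = None,
    sex: str | None = None,
    n_draws: int | None = None,
    seed: int = 0,
    options: "FitOptions | None" = None,
) -> AgeTrend:
    """Bootstrap test of the observed against the expected age gradient.

    With ``calls`` given, the difference probability curve is built from
    joint Poisson-bootstrap resamples: every call receives a Poisson(1)
    weight, which reproduces the independent-Poisson fluctuations of both
    the per-decade carrier counts and the total call count.  Each
    resample yields a refit expected gradient (through the prevalence
    integral) and resampled observed decade counts, so the strong
    positive correlation between the fitted model and the observed
    prevalence — they share the same data — is retained in the
    difference distribution.

    With ``calls=None`` an independent-draws fallback pairs binomial
    count resamples with the fit's bootstrap replicates; it ignores that
    correlation and is therefore conservative.

    The reported p value is two-sided, 2*min(P(diff <= 0), P(diff >= 0)),
    so both stronger- and weaker-than-expected age dependence can reach
    significance at 0.05.
    """
    if not trend.determined:
        return replace(trend, p_value=None, significant=None,
                       p_value_reason="undetermined gradient")
    if fit.s_replicates is None or fit.amplitude_replicates is None:
        raise ValidationError("deviation_test requires a fit with bootstrap replicates")
    if window is None:
        window = trend.window if trend.window is not None else fit.window
    rng = np.random.default_rng(seed)
    B = len(fit.s_replicates)
    n = min(n_draws, B) if n_draws is not None else B

    sizes = _group_sizes(cohort, sex)
    groups = cohort.age_mixture.groups
    excluded = trend.excluded_groups

    def exp_gradient(s_b: float, a_b: float) -> float:
        params = TheoryParams.from_amplitude(s_b, a_b, ntau=cohort.ntau)
        pts = [
            _point(g.lo, g.hi, g.rep_age, float(T),
                   float(expected_prevalence(params, g.rep_age, window) * T))
            for g, T in zip(groups, sizes)
        ]
        return fit_gradient(pts, exclude=excluded).m

    obs_weights = [
        (p.T / (2.0 * p.p)) if p.p > 0 else np.nan for p in trend.points_observed
    ]

    def obs_gradient(k_by_group) -> float:
        pts = [
            _point(p.age_lo, p.age_hi, p.t, p.T, float(k))
            for p, k in zip(trend.points_observed, k_by_group)
        ]
        return fit_gradient(pts, weights=obs_weights, exclude=excluded).m

    if calls is not None:
        from .inference import FitOptions, _SpectrumObjective

        options = options or FitOptions()
        own = sorted(
            (c for c in calls if c.label == fit.label and (sex is None or c.sex == sex)),
            key=lambda c: c.cell_fraction,
        )
        f_floor = trend.window.f_lo if trend.window is not None else window.f_lo
        ages = np.array([c.age for c in own])
        fr = np.array([c.cell_fraction for c in own])
        n_calls = len(own)
        lo_edges = np.array([g.lo for g in groups])
        hi_edges = np.array([g.hi for g in groups])
        ws = _SpectrumObjective(fr, cohort.n_people, cohort.age_mixture,
                                cohort.ntau, fit.window, options)
        m_obs = np.empty(n)
        m_exp = np.empty(n)
        for b in range(n):
            weights_b = rng.poisson(1.0, size=n_calls)
            idx = np.repeat(np.arange(n_calls), weights_b)
            if len(idx) < 2:
                weights_b = np.ones(n_calls, dtype=int)
                idx = np.arange(n_calls)
            s_b, a_b, _, _ = ws.fit(idx)
            m_exp[b] = exp_gradient(s_b, a_b)
            in_floor = fr >= f_floor
            ks = [
                int(np.sum(weights_b[(ages >= lo) & (ages < hi) & in_floor]))
                for lo, hi in zip(lo_edges, hi_edges)
            ]
            m_obs[b] = obs_gradient(ks)
    else:
        m_exp = np.array([
            exp_gradient(float(fit.s_replicates[b]), float(fit.amplitude_replicates[b]))
            for b in range(n)
        ])
        m_obs = np.empty(n)
        for b in range(n):
            ks = [
                rng.binomial(int(round(p.T)), p.p) if p.p > 0 else 0
                for p in trend.points_observed
            ]
            m_obs[b] = obs_gradient(ks)

    diff = m_obs - m_exp
    p_le = float(np.mean(diff < 0) + 0.5 * np.mean(diff == 0))
    p_value = min(2.0 * min(p_le, 1.0 - p_le), 1.0)
    return replace(trend, p_value=p_value, significant=p_value < 0.05, p_value_reason=None)
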