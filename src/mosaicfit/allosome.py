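"""Allosomal mCAs: mLOY and the two-component model for mLOX.

Mosaic loss of Y behaves as a single high-mutation-rate mCA.  Mosaic loss
of X shows two plateaus in its clone-size spectrum, consistent with two
distinct events: a frequent low-fitness one (s1, mu1) and a rare
high-fitness one (s2, mu2).  When (s2 - s1)*age >> 1 and mu1 >> mu2 the
two regimes separate in cell fraction, so each component can be fit
independently below / above a pair of split points located where the
first fall-off gives way to the second plateau.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .age_trend import AgeTrend, _assemble_trend, _group_sizes, _point, observed_prevalence
from .exceptions import (
    ConfigurationError,
    InsufficientDataError,
    NoPlateauError,
    ValidationError,
)
from .inference import (
    FitOptions,
    FitResult,
    MCACall,
    SpectrumHistogram,
    bootstrap_ci,
    build_spectrum,
    fit_single,
)
from .theory import DetectionWindow, TheoryParams, expected_prevalence

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic import CohortSpec

__all__ = [
    "MIN_LENGTH_MB",
    "TwoComponentFit",
    "filter_allosome",
    "propose_split_points",
    "fit_two_component",
    "combined_allosome_trend",
]

#: Minimum event sizes guarding against focal losses mimicking whole-chromosome loss.
MIN_LENGTH_MB = {"mloy": 2.0, "mlox": 125.0}


def filter_allosome(
    calls: Sequence[MCACall],
    mca_class: str,
    min_length_mb: float | None = None,
) -> list[MCACall]:
    """Keep calls of the class strictly longer than the size threshold (MB)."""
    if mca_class not in MIN_LENGTH_MB:
        raise ConfigurationError(f"mca_class must be 'mloy' or 'mlox', got {mca_class!r}")
    threshold = min_length_mb if min_length_mb is not None else MIN_LENGTH_MB[mca_class]
    subset = [c for c in calls if c.mca_class == mca_class]
    missing = [c.person_id for c in subset if c.length_mb is None]
    if missing:
        raise ValidationError(
            f"{len(missing)} {mca_class} calls lack length_mb: {missing[:10]}"
        )
    return [c for c in subset if c.length_mb > threshold]


def propose_split_points(
    spectrum: SpectrumHistogram,
    min_populated: int = 8,
    min_drop: float = 1.5,
    sustain_bins: int = 4,
) -> tuple[float, float]:
    """Locate the lower/upper split points between the two mLOX regimes.

    Scanning upward in cell fraction past the density maximum, the lower
    split is the first bin where the smoothed log-density slope recovers
    above half its running minimum — the fall-off of the first component
    giving way to the plateau of the second — after the density has
    dropped by at least ``min_drop`` nats, with the recovery sustained for
    ``sustain_bins`` bins.  The upper split is three bins above the lower
    one, excising the region where both components contribute.  Raises
    NoPlateauError for single-component spectra; callers may always
    override the proposal.
    """
    counts = spectrum.counts
    if int(np.sum(counts > 0)) < min_populated:
        raise ValidationError(
            f"need >= {min_populated} populated bins, got {int(np.sum(counts > 0))}"
        )
    with np.errstate(divide="ignore"):
        logd = np.where(counts > 0, np.log(np.maximum(spectrum.density, 1e-300)), np.nan)
    # 3-bin moving average, ignoring empty bins
    sm = np.full_like(logd, np.nan)
    for i in range(len(logd)):
        w = logd[max(i - 1, 0): i + 2]
        w = w[np.isfinite(w)]
        if len(w):
            sm[i] = w.mean()
    slope = np.diff(sm)
    i_peak = int(np.nanargmax(np.where(counts > 0, logd, -np.inf)))
    run_min = np.inf
    centers = spectrum.centers
    n_slopes = len(slope)
    for j in range(i_peak, n_slopes):
        if not np.isfinite(slope[j]):
            continue
        run_min = min(run_min, slope[j])
        if run_min >= -1e-3:  # no fall-off yet
            continue
        dropped = np.isfinite(sm[j]) and (sm[i_peak] - sm[j]) >= min_drop
        if not dropped:
            continue
        if j + sustain_bins > n_slopes:
            break
        ahead = slope[j: j + sustain_bins]
        ahead = ahead[np.isfinite(ahead)]
        window_ok = (
            len(ahead) == sustain_bins and float(np.mean(ahead)) > 0.5 * run_min
        )
        if window_ok and slope[j] > 0.5 * run_min:
            lower_bin = j + 1
            upper_bin = lower_bin + 3
            if upper_bin >= len(centers):
                break
            return float(centers[lower_bin]), float(centers[upper_bin])
    raise NoPlateauError(
        "no plateau detected after the density fall-off; the spectrum looks "
        "single-component — specify split points manually if a two-component "
        "fit is still wanted"
    )


@dataclass(frozen=True)
class TwoComponentFit:
    """Independent fits to the low- and high-cell-fraction mLOX regimes."""

    component_low: FitResult  # (s1, mu1): high rate, low fitness
    component_high: FitResult  # (s2, mu2): low rate, high fitness
    split_lower: float
    split_upper: float
    calls_excluded: int

    def regime_diagnostic(self, age: float = 65.0) -> dict[str, float]:
        """Separation diagnostics: (s2 - s1)*age should be >> 1, mu1/mu2 >> 1."""
        return {
            "delta_s_times_age": (self.component_high.s_hat - self.component_low.s_hat) * age,
            "mu_ratio": self.component_low.mu_hat / max(self.component_high.mu_hat, 1e-300),
        }


def fit_two_component(
    calls: Sequence[MCACall],
    cohort: "CohortSpec",
    splits: tuple[float, float] | None = None,
    options: FitOptions | None = None,
    n_bins: int = 40,
    bootstrap: bool = False,
    B: int | None = None,
) -> TwoComponentFit:
    """Fit the two-event mLOX model via independent regime fits.

    Calls below the lower split are fit over (f_lo, split_lower); calls
    above the upper split over (split_upper, f_hi).  Calls between the
    splits contribute to neither objective.  ``splits=None`` uses the
    automated proposal from the spectrum.
    """
    options = options or FitOptions()
    if len(calls) == 0:
        raise InsufficientDataError("no calls to fit")
    mca_class = calls[0].mca_class
    window = cohort.windows[mca_class]
    if splits is None:
        spectrum = build_spectrum(calls, cohort.n_people, window, n_bins=n_bins)
        splits = propose_split_points(spectrum)
    split_lower, split_upper = splits
    if not (window.f_lo < split_lower < split_upper < window.f_hi):
        raise ConfigurationError(
            f"splits {splits} must be ordered inside the window ({window.f_lo}, {window.f_hi})"
        )
    low = [c for c in calls if c.cell_fraction < split_lower]
    high = [c for c in calls if c.cell_fraction > split_upper]
    excluded = len(calls) - len(low) - len(high)
    for side, subset in (("low", low), ("high", high)):
        if len(subset) < options.min_obs:
            raise InsufficientDataError(
                f"{side}-fraction side has {len(subset)} calls; need >= {options.min_obs}"
            )
    w_low = DetectionWindow(window.f_lo, split_lower)
    w_high = DetectionWindow(split_upper, window.f_hi)
    fitter = (lambda c, w: bootstrap_ci(c, cohort, window=w, options=options, B=B)) if bootstrap \
        else (lambda c, w: fit_single(c, cohort, window=w, options=options))
    fit_low = fitter(low, w_low)
    fit_high = fitter(high, w_high)
    from dataclasses import replace as _replace

    fit_low = _replace(fit_low, label=f"{fit_low.label}_1")
    fit_high = _replace(fit_high, label=f"{fit_high.label}_2")
    return TwoComponentFit(
        component_low=fit_low,
        component_high=fit_high,
        split_lower=float(split_lower),
        split_upper=float(split_upper),
        calls_excluded=excluded,
    )


def combined_allosome_trend(
    two_fit: TwoComponentFit,
    cohort: "CohortSpec",
    calls: Sequence[MCACall] | None = None,
    window: DetectionWindow | None = None,
    sex: str | None = None,
) -> AgeTrend:
    """Age trend with the expected prevalence summed over both components."""
    for side in (two_fit.component_low, two_fit.component_high):
        if not side.converged:
            raise ValidationError(f"component fit {side.label!r} did not converge")
    if window is None:
        mca_class = two_fit.component_low.mca_class
        window = cohort.windows[mca_class]
    sizes = _group_sizes(cohort, sex)
    groups = cohort.age_mixture.groups
    expected = []
    for g, T in zip(groups, sizes):
        p = 0.0
        for side in (two_fit.component_low, two_fit.component_high):
            params = TheoryParams.from_amplitude(side.s_hat, side.amplitude_hat, ntau=cohort.ntau)
            p += expected_prevalence(params, g.rep_age, window)
        expected.append(_point(g.lo, g.hi, g.rep_age, float(T), float(p * T)))
    label = two_fit.component_low.label.rsplit("_", 1)[0]
    if calls is not None:
        observed = observed_prevalence(calls, cohort, label, f_lo=window.f_lo, sex=sex)
    else:
        observed = [_point(p.age_lo, p.age_hi, p.t, p.T, 0.0) for p in expected]
    return _assemble_trend(label, observed, expected, window=window)
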