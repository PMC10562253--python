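"""Per-mCA estimation of fitness effect s and amplitude Ntau*mu.

Each mCA's observed cell fractions across the cohort form a clone-size
spectrum.  Fitting compares, on the log scale, the predicted cumulative
detectable-clone count up to each observed cell fraction

    C_pred(f) = cohort_size * Ntau*mu * [E1(x_lo/phi) - E1(x_f/phi)]

(averaged over the cohort age mixture) against the observed cumulative
rank C_obs(f), with evaluation points at the observed (logit) cell
fractions and midranks for ties.  The L2 objective

    sum_i (log C_pred(f_i) - log C_obs(f_i))^2

is exactly quadratic in log(Ntau*mu), so the amplitude is profiled out in
closed form and the search reduces to a 1-D problem in s (coarse log grid
plus bounded Brent refinement).  Confidence intervals come from
nonparametric bootstrap resampling of the calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import exp1

from .exceptions import (
    ConfigurationError,
    DomainError,
    InsufficientDataError,
    ValidationError,
)
from .theory import AgeMixture, DetectionWindow, log_phi

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic import CohortSpec

__all__ = [
    "MCACall",
    "SpectrumHistogram",
    "FitOptions",
    "FitResult",
    "FoldDifference",
    "SexStratifiedFits",
    "build_spectrum",
    "fit_single",
    "bootstrap_ci",
    "fit_sex_stratified",
    "fold_difference_test",
    "downsample_calls",
    "single_mca_calls",
]

FEMALE = "female"
MALE = "male"

MCA_CLASSES = ("gain", "loss", "cnloh", "mloy", "mlox")


@dataclass(frozen=True)
class MCACall:
    """One detected mCA in one person."""

    person_id: str
    age: float
    sex: str
    label: str
    mca_class: str
    cell_fraction: float
    length_mb: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.cell_fraction <= 1):
            raise ValidationError(
                f"cell_fraction must lie in (0, 1], got {self.cell_fraction} for {self.person_id}"
            )
        if self.mca_class not in MCA_CLASSES:
            raise ValidationError(f"unknown mca_class {self.mca_class!r}")
        if self.sex not in (FEMALE, MALE):
            raise ValidationError(f"sex must be 'female' or 'male', got {self.sex!r}")


def _fractions(calls: Sequence[MCACall]) -> np.ndarray:
    return np.array([c.cell_fraction for c in calls], dtype=float)


@dataclass(frozen=True)
class SpectrumHistogram:
    """Log-binned clone-size spectrum of one mCA across the cohort."""

    bin_edges: np.ndarray  # ascending cell fractions, len n_bins + 1
    counts: np.ndarray
    density: np.ndarray  # per person per unit log(cell fraction)
    sem: np.ndarray
    cohort_size: int

    @property
    def centers(self) -> np.ndarray:
        """Geometric bin centers."""
        return np.sqrt(self.bin_edges[:-1] * self.bin_edges[1:])

    @property
    def dl(self) -> float:
        return float(np.log(self.bin_edges[1] / self.bin_edges[0]))


def build_spectrum(
    calls: Sequence[MCACall],
    cohort_size: int,
    window: DetectionWindow,
    n_bins: int = 40,
) -> SpectrumHistogram:
    """Histogram the cell fractions of one mCA, uniformly in log cell fraction."""
    if len(calls) == 0:
        raise InsufficientDataError("cannot build a spectrum from an empty call set")
    if n_bins < 3:
        raise ConfigurationError(f"n_bins must be >= 3, got {n_bins}")
    labels = {c.label for c in calls}
    if len(labels) > 1:
        raise ValidationError(f"spectrum requires a single mCA label, got {sorted(labels)}")
    f = _fractions(calls)
    bad = ~((f >= window.f_lo) & (f <= window.f_hi))
    if np.any(bad):
        offenders = [calls[i].person_id for i in np.flatnonzero(bad)[:10]]
        raise ValidationError(
            f"{int(bad.sum())} calls outside window ({window.f_lo}, {window.f_hi}): {offenders}"
        )
    edges = np.geomspace(window.f_lo, window.f_hi, n_bins + 1)
    edges[-1] = window.f_hi  # close the top bin against round-off
    counts, _ = np.histogram(f, bins=edges)
    dl = np.log(edges[1] / edges[0])
    density = counts / (cohort_size * dl)
    sem = np.sqrt(counts) / (cohort_size * dl)
    return SpectrumHistogram(
        bin_edges=edges, counts=counts, density=density, sem=sem, cohort_size=cohort_size
    )


@dataclass(frozen=True)
class FitOptions:
    """Search box and thresholds for spectrum fits."""

    s_min: float = 0.02
    s_max: float = 1.0
    amp_min: float = 1e-7
    amp_max: float = 1.0  # must contain allosomal amplitudes (mLOX_1 has Ntau*mu ~ 0.16)
    n_grid: int = 60
    min_obs: int = 8
    bootstrap_B: int = 200
    seed: int = 0

    @property
    def grid_step(self) -> float:
        """Multiplicative spacing of the s search grid."""
        return (self.s_max / self.s_min) ** (1.0 / (self.n_grid - 1))


@dataclass(frozen=True)
class FitResult:
    """Inferred (s, Ntau*mu, mu) for one mCA with optional bootstrap CIs."""

    label: str
    mca_class: str
    n_obs: int
    s_hat: float
    amplitude_hat: float  # Ntau * mu
    mu_hat: float
    objective_value: float
    window: DetectionWindow
    seed: int
    converged: bool
    s_at_bound: bool
    amp_at_bound: bool
    ci_s: tuple[float, float] | None = None
    ci_amplitude: tuple[float, float] | None = None
    ci_mu: tuple[float, float] | None = None
    upper_ci_undetermined: bool = False
    degenerate_ci: bool = False
    bootstrap_seed: int | None = None
    s_replicates: np.ndarray | None = field(default=None, repr=False)
    amplitude_replicates: np.ndarray | None = field(default=None, repr=False)

    @property
    def mu_replicates(self) -> np.ndarray | None:
        if self.amplitude_replicates is None:
            return None
        return self.amplitude_replicates * (self.mu_hat / self.amplitude_hat)


def _midranks(f_sorted: np.ndarray) -> np.ndarray:
    """Cumulative observed count at each sorted value; ties share their midrank."""
    n = len(f_sorted)
    ranks = np.arange(1, n + 1, dtype=float)
    uniq, inv, counts = np.unique(f_sorted, return_inverse=True, return_counts=True)
    if len(uniq) < n:
        stop = np.cumsum(counts)
        start = stop - counts + 1
        mid = 0.5 * (start + stop)
        ranks = mid[inv]
    return ranks


class _SpectrumObjective:
    """Profiled L2 objective over s for a fixed set of observed fractions.

    Caches the mixture-weighted cumulative shape on the s search grid so
    bootstrap resamples (index subsets of the same fractions) are cheap.
    """

    def __init__(
        self,
        f_sorted: np.ndarray,
        cohort_size: int,
        mixture: AgeMixture,
        ntau: float,
        window: DetectionWindow,
        options: FitOptions,
    ):
        self.f = f_sorted
        self.cohort_size = cohort_size
        self.mixture = mixture
        self.ntau = ntau
        self.window = window
        self.opt = options
        self.s_grid = np.geomspace(options.s_min, options.s_max, options.n_grid)
        x = f_sorted / (1.0 - f_sorted)
        x0 = window.f_lo / (1.0 - window.f_lo)
        # keep evaluation points strictly above the window floor
        self.x = np.maximum(x, x0 * (1.0 + 1e-9))
        self.x0 = x0
        self._log_shape_grid = np.stack([self._log_shape(s) for s in self.s_grid])

    def _log_shape(self, s: float) -> np.ndarray:
        """log of cohort_size * mixture-averaged cumulative integral (unit amplitude)."""
        total = np.zeros_like(self.x)
        for g in self.mixture.groups:
            lp = log_phi(s, g.rep_age, self.ntau)
            scale = np.exp(-lp)
            e_lo = exp1(np.clip(self.x0 * scale, 1e-300, 700.0))
            e_f = exp1(np.clip(self.x * scale, 1e-300, 700.0))
            total += g.weight * np.maximum(e_lo - e_f, 0.0)
        with np.errstate(divide="ignore"):
            return np.log(np.maximum(self.cohort_size * total, 1e-300))

    def profiled(self, log_b: np.ndarray, a: np.ndarray) -> tuple[float, float]:
        """Minimise over log-amplitude in closed form; return (objective, logA*)."""
        ln_a_star = float(np.mean(log_b - a))
        ln_a_star = float(np.clip(ln_a_star, np.log(self.opt.amp_min), np.log(self.opt.amp_max)))
        r = ln_a_star + a - log_b
        return float(np.dot(r, r)), ln_a_star

    def fit(self, idx: np.ndarray | None = None) -> tuple[float, float, float, bool]:
        """Fit (s, amplitude) for the full data or a sorted bootstrap index subset.

        Returns (s_hat, amplitude_hat, objective, amp_clipped).
        """
        if idx is None:
            f = self.f
            shape_grid = self._log_shape_grid
        else:
            f = self.f[idx]
            shape_grid = self._log_shape_grid[:, idx]
        log_b = np.log(_midranks(f))

        grid_obj = np.empty(len(self.s_grid))
        for k in range(len(self.s_grid)):
            grid_obj[k], _ = self.profiled(log_b, shape_grid[k])
        k_best = int(np.argmin(grid_obj))

        x_sub = self.x if idx is None else self.x[idx]

        def obj_of_log_s(ls: float) -> float:
            a = self._log_shape_sub(np.exp(ls), x_sub)
            return self.profiled(log_b, a)[0]

        lo = np.log(self.s_grid[max(k_best - 1, 0)])
        hi = np.log(self.s_grid[min(k_best + 1, len(self.s_grid) - 1)])
        if hi > lo:
            res = minimize_scalar(obj_of_log_s, bounds=(lo, hi), method="bounded",
                                  options={"xatol": 1e-5})
            s_hat = float(np.exp(res.x))
            obj = float(res.fun)
        else:
            s_hat = float(self.s_grid[k_best])
            obj = float(grid_obj[k_best])
        a = self._log_shape_sub(s_hat, x_sub)
        obj, ln_a = self.profiled(log_b, a)
        amp = float(np.exp(ln_a))
        clipped = amp <= self.opt.amp_min * (1 + 1e-9) or amp >= self.opt.amp_max * (1 - 1e-9)
        return s_hat, amp, obj, clipped

    def _log_shape_sub(self, s: float, x_sub: np.ndarray) -> np.ndarray:
        total = np.zeros_like(x_sub)
        for g in self.mixture.groups:
            lp = log_phi(s, g.rep_age, self.ntau)
            scale = np.exp(-lp)
            e_lo = exp1(np.clip(self.x0 * scale, 1e-300, 700.0))
            e_f = exp1(np.clip(x_sub * scale, 1e-300, 700.0))
            total += g.weight * np.maximum(e_lo - e_f, 0.0)
        with np.errstate(divide="ignore"):
            return np.log(np.maximum(self.cohort_size * total, 1e-300))


def _resolve_window(calls: Sequence[MCACall], cohort: "CohortSpec",
                    window: DetectionWindow | None) -> DetectionWindow:
    if window is not None:
        return window
    mca_class = calls[0].mca_class
    try:
        return cohort.windows[mca_class]
    except KeyError as exc:
        raise ConfigurationError(f"no detection window configured for class {mca_class!r}") from exc


def fit_single(
    calls: Sequence[MCACall],
    cohort: "CohortSpec",
    window: DetectionWindow | None = None,
    options: FitOptions | None = None,
) -> FitResult:
    """Fit (s, Ntau*mu) to the cell-fraction spectrum of one mCA.

    Deterministic given the calls, options and seed.  The per-cell
    mutation rate is ``amplitude_hat / cohort.ntau``.
    """
    options = options or FitOptions()
    if len(calls) < options.min_obs:
        raise InsufficientDataError(
            f"need at least {options.min_obs} calls, got {len(calls)}"
        )
    labels = {c.label for c in calls}
    if len(labels) > 1:
        raise ValidationError(f"fit_single requires a single label, got {sorted(labels)}")
    window = _resolve_window(calls, cohort, window)
    f = np.sort(_fractions(calls))
    if f[0] < window.f_lo or f[-1] > window.f_hi:
        raise ValidationError(
            f"calls outside detection window ({window.f_lo}, {window.f_hi})"
        )
    ws = _SpectrumObjective(f, cohort.n_people, cohort.age_mixture, cohort.ntau, window, options)
    s_hat, amp, obj, amp_clipped = ws.fit()
    s_at_bound = s_hat <= options.s_min * (1 + 1e-3) or s_hat >= options.s_max * (1 - 1e-3)
    return FitResult(
        label=calls[0].label,
        mca_class=calls[0].mca_class,
        n_obs=len(calls),
        s_hat=s_hat,
        amplitude_hat=amp,
        mu_hat=amp / cohort.ntau,
        objective_value=obj,
        window=window,
        seed=options.seed,
        converged=not (s_at_bound and amp_clipped),
        s_at_bound=s_at_bound,
        amp_at_bound=amp_clipped,
    )


def bootstrap_ci(
    calls: Sequence[MCACall],
    cohort: "CohortSpec",
    window: DetectionWindow | None = None,
    options: FitOptions | None = None,
    B: int | None = None,
    seed: int | None = None,
) -> FitResult:
    """Attach percentile 95% bootstrap confidence intervals to a point fit.

    Calls are resampled with replacement B times and refit; the upper CI
    for s is flagged undetermined when its 97.5% quantile lies within one
    search-grid step of the s upper bound (the regime where upper-cut-off
    censoring leaves the fitness effect unbounded above).
    """
    options = options or FitOptions()
    B = B if B is not None else options.bootstrap_B
    if B < 20:
        raise ConfigurationError(f"bootstrap requires B >= 20, got {B}")
    point = fit_single(calls, cohort, window=window, options=options)
    boot_seed = seed if seed is not None else options.seed
    rng = np.random.default_rng(boot_seed)
    f = np.sort(_fractions(calls))
    n = len(f)
    ws = _SpectrumObjective(f, cohort.n_people, cohort.age_mixture, cohort.ntau,
                            point.window, options)
    s_reps = np.empty(B)
    a_reps = np.empty(B)
    for b in range(B):
        idx = np.sort(rng.integers(0, n, size=n))
        s_reps[b], a_reps[b], _, _ = ws.fit(idx)

    def _ci(reps: np.ndarray, pt: float, lo_b: float, hi_b: float) -> tuple[float, float]:
        lo, hi = np.percentile(reps, [2.5, 97.5])
        lo = float(np.clip(min(lo, pt), lo_b, hi_b))
        hi = float(np.clip(max(hi, pt), lo_b, hi_b))
        return lo, hi

    ci_s = _ci(s_reps, point.s_hat, options.s_min, options.s_max)
    ci_a = _ci(a_reps, point.amplitude_hat, options.amp_min, options.amp_max)
    ci_mu = (ci_a[0] / cohort.ntau, ci_a[1] / cohort.ntau)
    undetermined = ci_s[1] >= options.s_max / options.grid_step
    degenerate = bool(np.ptp(s_reps) == 0.0 and np.ptp(a_reps) == 0.0)
    return replace(
        point,
        ci_s=ci_s,
        ci_amplitude=ci_a,
        ci_mu=ci_mu,
        upper_ci_undetermined=bool(undetermined),
        degenerate_ci=degenerate,
        bootstrap_seed=boot_seed,
        s_replicates=s_reps,
        amplitude_replicates=a_reps,
    )


@dataclass(frozen=True)
class SexStratifiedFits:
    """Per-sex fits; a side is None with a reason when below the per-sex minimum."""

    female: FitResult | None
    male: FitResult | None
    reasons: dict[str, str]


def fit_sex_stratified(
    calls: Sequence[MCACall],
    cohort: "CohortSpec",
    window: DetectionWindow | None = None,
    options: FitOptions | None = None,
    min_per_sex: int = 10,
    bootstrap: bool = True,
    B: int | None = None,
) -> SexStratifiedFits:
    """Independent per-sex fits with sex-specific cohort sizes."""
    options = options or FitOptions()
    out: dict[str, FitResult | None] = {FEMALE: None, MALE: None}
    reasons: dict[str, str] = {}
    subsets = {
        FEMALE: [c for c in calls if c.sex == FEMALE],
        MALE: [c for c in calls if c.sex == MALE],
    }
    for sex, subset in subsets.items():
        if len(subset) < min_per_sex:
            reasons[sex] = f"below min per-sex count ({len(subset)} < {min_per_sex})"
            continue
        sub_cohort = cohort.for_sex(sex)
        if bootstrap:
            out[sex] = bootstrap_ci(subset, sub_cohort, window=window, options=options, B=B)
        else:
            out[sex] = fit_single(subset, sub_cohort, window=window, options=options)
    if out[FEMALE] is None and out[MALE] is None:
        raise InsufficientDataError(
            f"neither sex reaches {min_per_sex} calls: {reasons}"
        )
    return SexStratifiedFits(female=out[FEMALE], male=out[MALE], reasons=reasons)


@dataclass(frozen=True)
class FoldDifference:
    """Fold difference (group A / group B) in s or mu between two fits."""

    quantity: str
    fold: float
    ci: tuple[float, float]
    p_value: float
    significant: bool


def fold_difference_test(fit_a: FitResult, fit_b: FitResult, quantity: str = "s") -> FoldDifference:
    """Bootstrap fold-difference test between two independent fits.

    The fold-difference probability curve is the distribution of ratios of
    paired bootstrap draws; the p value is the probability mass of that
    curve at ratios <= 1 (mass exactly at 1 counted half), keeping the
    caller's A/B orientation.  Significant iff p < 0.05.
    """
    if quantity not in ("s", "mu"):
        raise ConfigurationError(f"quantity must be 's' or 'mu', got {quantity!r}")
    reps = {}
    points = {}
    for name, fit in (("a", fit_a), ("b", fit_b)):
        r = fit.s_replicates if quantity == "s" else fit.mu_replicates
        if r is None:
            raise ValidationError(
                f"fit {fit.label!r} carries no bootstrap replicates; run bootstrap_ci first"
            )
        reps[name] = r
        points[name] = fit.s_hat if quantity == "s" else fit.mu_hat
    m = min(len(reps["a"]), len(reps["b"]))
    ratios = reps["a"][:m] / reps["b"][:m]
    fold = points["a"] / points["b"]
    ci = tuple(float(q) for q in np.percentile(ratios, [2.5, 97.5]))
    p = float(np.mean(ratios < 1.0) + 0.5 * np.mean(ratios == 1.0))
    return FoldDifference(quantity=quantity, fold=float(fold), ci=ci, p_value=p,
                          significant=p < 0.05)


def downsample_calls(calls: Sequence[MCACall], n_max: int = 50, seed: int = 3) -> list[MCACall]:
    """Uniform random subset of at most ``n_max`` calls, reproducible from ``seed``."""
    if n_max < 1:
        raise ConfigurationError(f"n_max must be >= 1, got {n_max}")
    calls = list(calls)
    if len(calls) <= n_max:
        return calls
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(calls), size=n_max, replace=False)
    return [calls[i] for i in np.sort(idx)]


def single_mca_calls(calls: Iterable[MCACall]) -> list[MCACall]:
    """Calls from persons carrying exactly one autosomal mCA (plus all allosomal calls)."""
    calls = list(calls)
    autosomal = [c for c in calls if c.mca_class in ("gain", "loss", "cnloh")]
    counts: dict[str, int] = {}
    for c in autosomal:
        counts[c.person_id] = counts.get(c.person_id, 0) + 1
    keep = {pid for pid, k in counts.items() if k == 1}
    return [
        c for c in calls
        if c.mca_class not in ("gain", "loss", "cnloh") or c.person_id in keep
    ]
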