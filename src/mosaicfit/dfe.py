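"""Mutation-rate distributions of fitness effects (DFE).

Aggregates per-mCA fits into a mutation-rate histogram over fitness
bands, and evaluates the published exponential-power DFE for
nonsynonymous SNVs,

    mu(s) ds  proportional to  exp[-(s/sigma)^p] ds,

normalised so the total rate over s in (0, inf) equals a stated panel
rate.  Band integrals use the incomplete-gamma closed form obtained from
u = (s/sigma)^p, with total mass sigma*Gamma(1 + 1/p).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import gamma, gammainc

from .exceptions import DomainError, ValidationError
from .inference import FitResult

__all__ = [
    "ExPowerDFE",
    "SNV_PANEL_DFE",
    "DFEHistogram",
    "build_mca_dfe",
    "expower_band_rate",
    "fitness_risk_correlation",
]


@dataclass(frozen=True)
class ExPowerDFE:
    """Exponential-power mutation-rate DFE.

    ``total_rate`` is the haploid rate integrated over all s; the
    ``ploidy_factor`` (default 2) converts it to a per-cell rate for
    comparison against per-cell mCA rates, since a diploid cell carries
    two copies of the haploid mutational target.
    """

    shape_p: float
    scale_sigma: float
    total_rate: float
    ploidy_factor: float = 2.0

    def __post_init__(self) -> None:
        if self.shape_p <= 0 or self.scale_sigma <= 0 or self.total_rate < 0:
            raise DomainError("require shape_p > 0, scale_sigma > 0, total_rate >= 0")


#: Nonsynonymous SNV DFE across a ~1.1 MB cancer gene panel:
#: shape 3, scale 0.1 per year, haploid total 7.7e-6 per year.
SNV_PANEL_DFE = ExPowerDFE(shape_p=3.0, scale_sigma=0.1, total_rate=7.7e-6)


def expower_band_rate(dfe: ExPowerDFE, s_lo: float, s_hi: float) -> float:
    """Per-cell mutation rate towards fitness effects in [s_lo, s_hi).

    ploidy_factor * total_rate * [gammainc(1/p, (s_hi/sigma)^p)
                                  - gammainc(1/p, (s_lo/sigma)^p)],
    exact via the regularised incomplete gamma function.
    """
    if not (0 <= s_lo < s_hi):
        raise DomainError(f"require 0 <= s_lo < s_hi, got ({s_lo}, {s_hi})")
    a = 1.0 / dfe.shape_p
    u_lo = (s_lo / dfe.scale_sigma) ** dfe.shape_p
    frac_lo = gammainc(a, u_lo)
    frac_hi = 1.0 if np.isinf(s_hi) else gammainc(a, (s_hi / dfe.scale_sigma) ** dfe.shape_p)
    return float(dfe.ploidy_factor * dfe.total_rate * (frac_hi - frac_lo))


def expower_normalization(dfe: ExPowerDFE) -> float:
    """Total mass of exp[-(s/sigma)^p] over (0, inf): sigma * Gamma(1 + 1/p)."""
    return float(dfe.scale_sigma * gamma(1.0 + 1.0 / dfe.shape_p))


@dataclass(frozen=True)
class DFEHistogram:
    """Summed mutation rate per fitness band, with member labels."""

    bin_edges: np.ndarray
    rate: np.ndarray
    labels: tuple[tuple[str, ...], ...]

    @property
    def total_rate(self) -> float:
        return float(self.rate.sum())


def build_mca_dfe(fits: Sequence[FitResult], bin_edges: Sequence[float]) -> DFEHistogram:
    """Histogram fitted mutation rates by fitted fitness effect.

    Each converged mCA contributes its mu_hat to the band containing its
    s_hat; estimates outside the edges go to the nearest end band with a
    warning.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise DomainError("bin_edges must be ascending with at least two entries")
    n_bins = len(edges) - 1
    rate = np.zeros(n_bins)
    members: list[list[str]] = [[] for _ in range(n_bins)]
    for fit in fits:
        if not fit.converged:
            raise ValidationError(f"fit {fit.label!r} did not converge; filter before binning")
        idx = int(np.searchsorted(edges, fit.s_hat, side="right") - 1)
        if fit.s_hat < edges[0] or fit.s_hat > edges[-1]:
            warnings.warn(
                f"s_hat {fit.s_hat:.3g} for {fit.label!r} outside DFE edges; assigned to end bin",
                stacklevel=2,
            )
        idx = int(np.clip(idx, 0, n_bins - 1))
        rate[idx] += fit.mu_hat
        members[idx].append(fit.label)
    return DFEHistogram(bin_edges=edges, rate=rate, labels=tuple(tuple(m) for m in members))


def fitness_risk_correlation(
    s_hat: Sequence[float],
    odds_ratio: Sequence[float],
    scale: str = "log",
) -> tuple[float, float, tuple[float, float]]:
    """Pearson correlation between fitness effects and malignancy odds ratios.

    ``scale`` selects raw or log odds ratios (an explicit choice that any
    report should state).  Returns (r, two-tailed p, Fisher-z 95% CI).
    """
    s_hat = np.asarray(s_hat, dtype=float)
    odds = np.asarray(odds_ratio, dtype=float)
    if len(s_hat) != len(odds) or len(s_hat) < 3:
        raise DomainError("need >= 3 paired (s_hat, odds_ratio) rows")
    if scale == "log":
        if np.any(odds <= 0):
            raise DomainError("log scale requires odds ratios > 0")
        y = np.log(odds)
    elif scale == "linear":
        y = odds
    else:
        raise DomainError(f"scale must be 'log' or 'linear', got {scale!r}")
    r, p = stats.pearsonr(s_hat, y)
    n = len(s_hat)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    half = 1.959963984540054 / np.sqrt(n - 3)
    ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
    return float(r), float(p), ci
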