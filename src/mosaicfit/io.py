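"""Readers, writers, label parsing and the end-to-end pipeline.

Call tables are delimited text with one row per detected mCA:
``person_id, age, sex, mca_label, cell_fraction[, length_mb]``.  Labels
follow the arm+suffix convention: '+' gain, '-'/'−' loss, '=' CN-LOH,
'Y-' mosaic loss of Y, 'X-' mosaic loss of X.  Cell fractions given as
percentages are detected and rescaled automatically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .age_trend import build_age_trend, deviation_test
from .dfe import build_mca_dfe
from .exceptions import ConfigurationError, InsufficientDataError, ValidationError
from .inference import (
    FEMALE,
    MALE,
    FitOptions,
    FitResult,
    MCACall,
    bootstrap_ci,
    fit_sex_stratified,
    fold_difference_test,
    single_mca_calls,
)
from .synthetic import CohortSpec, ComponentTruth, GroundTruth, LabelTruth, sample_calls_theory

logger = logging.getLogger(__name__)

__all__ = [
    "MCALabel",
    "parse_label",
    "read_calls",
    "write_calls",
    "calls_to_frame",
    "frame_to_calls",
    "run_pipeline",
]

#: Acrocentric short arms with no callable probes.
EXCLUDED_ARMS = {"13p", "14p", "15p", "21p", "22p"}

_SUFFIX_CLASS = {"+": "gain", "-": "loss", "=": "cnloh"}
_LABEL_RE = re.compile(r"^(1[0-9]|2[0-2]|[1-9]|X|Y)(p|q)?([+\-=])$")

_SEX_ALIASES = {
    "f": FEMALE, "female": FEMALE, "w": FEMALE, "woman": FEMALE,
    "m": MALE, "male": MALE, "man": MALE,
}


@dataclass(frozen=True)
class MCALabel:
    chromosome: str  # '1'..'22', 'X', 'Y'
    arm: str  # 'p', 'q' or 'whole'
    mca_class: str

    def __str__(self) -> str:
        if self.mca_class == "mloy":
            return "Y-"
        if self.mca_class == "mlox":
            return "X-"
        arm = "" if self.arm == "whole" else self.arm
        suffix = {v: k for k, v in _SUFFIX_CLASS.items()}[self.mca_class]
        return f"{self.chromosome}{arm}{suffix}"


def parse_label(label: str) -> MCALabel:
    """Parse an mCA label like '20q-', '12+', '9p=', 'Y-' or 'X-'.

    The unicode minus sign is accepted alongside the ASCII hyphen; the
    acrocentric short arms 13p/14p/15p/21p/22p are rejected (never
    called).
    """
    normalized = label.strip().replace("−", "-").replace("–", "-")
    m = _LABEL_RE.match(normalized)
    if not m:
        raise ValidationError(f"cannot parse mCA label {label!r}")
    chrom, arm, suffix = m.group(1), m.group(2) or "whole", m.group(3)
    if chrom in ("X", "Y"):
        if arm != "whole" or suffix != "-":
            raise ValidationError(
                f"allosomal label {label!r} not supported: only whole-chromosome "
                "losses 'Y-' (mLOY) and 'X-' (mLOX) are modeled"
            )
        return MCALabel(chromosome=chrom, arm="whole",
                        mca_class="mloy" if chrom == "Y" else "mlox")
    if arm != "whole" and f"{chrom}{arm}" in EXCLUDED_ARMS:
        raise ValidationError(
            f"label {label!r} refers to an acrocentric short arm that is never called"
        )
    return MCALabel(chromosome=chrom, arm=arm, mca_class=_SUFFIX_CLASS[suffix])


def canonical_label(label: str) -> str:
    """Normalised label string (unicode minus folded to ASCII)."""
    return str(parse_label(label))


def _normalise_sex(value, sex_map: Mapping | None) -> str:
    if sex_map is not None and value in sex_map:
        value = sex_map[value]
    key = str(value).strip().lower()
    if key in _SEX_ALIASES:
        return _SEX_ALIASES[key]
    raise ValidationError(
        f"cannot interpret sex value {value!r}; pass sex_map for coded values"
    )


REQUIRED_COLUMNS = ("person_id", "age", "sex", "mca_label", "cell_fraction")


def read_calls(
    path: str | Path,
    sep: str | None = None,
    sex_map: Mapping | None = None,
) -> list[MCACall]:
    """Read and validate a call table (TSV/CSV autodetected).

    Cell fractions are accepted either in (0, 1] or as percentages; a
    column whose header mentions '%' or whose maximum exceeds 1 is
    divided by 100 (logged).  Record-level failures are collected and
    reported with their line numbers.
    """
    if sep is None:  # sniff the delimiter from the header line
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    cf = pd.to_numeric(df["cell_fraction"], errors="coerce")
    percent = "%" in str(df.columns[list(df.columns).index("cell_fraction")]) or (
        np.nanmax(cf.to_numpy()) > 1.0
    )
    if percent:
        logger.info("%s: cell_fraction column interpreted as percent; dividing by 100", path)
        cf = cf / 100.0
    calls: list[MCACall] = []
    errors: list[str] = []
    has_length = "length_mb" in df.columns
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        try:
            lab = parse_label(str(getattr(row, "mca_label")))
            f = float(cf.iloc[i - 2])
            if not (0 < f <= 1):
                raise ValidationError(f"cell_fraction {f} outside (0, 1] after normalization")
            length = getattr(row, "length_mb", None) if has_length else None
            if length is not None and pd.isna(length):
                length = None
            calls.append(
                MCACall(
                    person_id=str(getattr(row, "person_id")),
                    age=float(getattr(row, "age")),
                    sex=_normalise_sex(getattr(row, "sex"), sex_map),
                    label=str(lab),
                    mca_class=lab.mca_class,
                    cell_fraction=f,
                    length_mb=float(length) if length is not None else None,
                )
            )
        except (ValidationError, ValueError) as exc:
            errors.append(f"line {i}: {exc}")
    if errors:
        preview = "; ".join(errors[:10])
        raise ValidationError(f"{path}: {len(errors)} bad records ({preview})")
    return calls


def calls_to_frame(calls: Sequence[MCACall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "person_id": [c.person_id for c in calls],
            "age": [c.age for c in calls],
            "sex": [c.sex for c in calls],
            "mca_label": [c.label for c in calls],
            "cell_fraction": [c.cell_fraction for c in calls],
            "length_mb": [c.length_mb for c in calls],
        }
    )


def frame_to_calls(df: pd.DataFrame) -> list[MCACall]:
    out = []
    for row in df.itertuples(index=False):
        lab = parse_label(str(row.mca_label))
        length = getattr(row, "length_mb", None)
        if length is not None and pd.isna(length):
            length = None
        out.append(
            MCACall(
                person_id=str(row.person_id),
                age=float(row.age),
                sex=str(row.sex),
                label=str(lab),
                mca_class=lab.mca_class,
                cell_fraction=float(row.cell_fraction),
                length_mb=float(length) if length is not None else None,
            )
        )
    return out


def write_calls(calls: Sequence[MCACall], path: str | Path) -> None:
    # %.17g keeps cell fractions bit-exact through a round trip
    calls_to_frame(calls).to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# pipeline


def _config_hash(config: Mapping) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _cohort_from_config(config: Mapping) -> CohortSpec:
    cc = dict(config.get("cohort", {}))
    kwargs = {}
    for key in ("n_people", "sex_ratio", "ntau", "seed"):
        if key in cc:
            kwargs[key] = cc[key]
    return CohortSpec(**kwargs)


def _truth_from_config(scenario: Mapping) -> GroundTruth:
    labels = []
    for item in scenario.get("labels", []):
        lab = parse_label(item["label"])
        labels.append(
            LabelTruth(
                label=str(lab),
                mca_class=lab.mca_class,
                s=float(item["s"]),
                mu=float(item["mu"]),
                s2=float(item["s2"]) if "s2" in item else None,
                mu2=float(item["mu2"]) if "mu2" in item else None,
                female=ComponentTruth(**item["female"]) if "female" in item else None,
                male=ComponentTruth(**item["male"]) if "male" in item else None,
            )
        )
    return GroundTruth(tuple(labels))


def _fit_row(fit: FitResult) -> dict:
    flags = []
    if not fit.converged:
        flags.append("non_converged")
    if fit.s_at_bound:
        flags.append("s_at_bound")
    if fit.upper_ci_undetermined:
        flags.append("upper_ci_undetermined")
    if fit.degenerate_ci:
        flags.append("degenerate_ci")
    return {
        "label": fit.label,
        "class": fit.mca_class,
        "n_obs": fit.n_obs,
        "s_hat": fit.s_hat,
        "s_lo": fit.ci_s[0] if fit.ci_s else np.nan,
        "s_hi": fit.ci_s[1] if fit.ci_s else np.nan,
        "ntau_mu": fit.amplitude_hat,
        "mu_hat": fit.mu_hat,
        "mu_lo": fit.ci_mu[0] if fit.ci_mu else np.nan,
        "mu_hi": fit.ci_mu[1] if fit.ci_mu else np.nan,
        "flags": ";".join(flags),
        "seed": fit.seed,
    }


def run_pipeline(config: Mapping | str | Path, out_dir: str | Path | None = None) -> Path:
    """Run fits, sex differences, age trends and the DFE for a whole call table.

    ``config`` is a mapping or a YAML file naming either an ``input``
    call table or a simulation ``scenario``, plus cohort settings,
    thresholds and seeds.  Per-mCA failures are recorded in
    ``status.tsv`` and do not abort the run; identical config and input
    produce byte-identical outputs.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    config = dict(config)
    seed = int(config.get("seed", 0))
    out = Path(out_dir if out_dir is not None else config.get("out", "mosaicfit_out"))
    out.mkdir(parents=True, exist_ok=True)
    cohort = _cohort_from_config(config)
    min_obs = int(config.get("min_obs", 8))
    min_per_sex = int(config.get("min_per_sex", 10))
    min_age_trend = int(config.get("min_age_trend", 30))
    B = int(config.get("bootstrap_B", 200))

    if "input" in config:
        calls = read_calls(config["input"], sex_map=config.get("sex_map"))
    elif "scenario" in config:
        truth = _truth_from_config(config["scenario"])
        calls = sample_calls_theory(truth, cohort, seed=seed)
        write_calls(calls, out / "simulated_calls.tsv")
    else:
        raise ConfigurationError("config must provide either 'input' or 'scenario'")

    by_label: dict[str, list[MCACall]] = {}
    for c in calls:
        by_label.setdefault(c.label, []).append(c)
    if "scenario" in config:  # labels simulated to zero calls still get a status row
        for item in config["scenario"].get("labels", []):
            by_label.setdefault(canonical_label(item["label"]), [])
    labels = sorted(by_label)
    label_seeds = {
        lab: int(s.generate_state(1)[0] % (2**31))
        for lab, s in zip(labels, np.random.SeedSequence(seed).spawn(len(labels)))
    }

    fit_rows, sex_rows, trend_rows, status_rows = [], [], [], []
    fits: dict[str, FitResult] = {}
    for lab in labels:
        subset = by_label[lab]
        opts = FitOptions(min_obs=min_obs, seed=label_seeds[lab], bootstrap_B=B)
        try:
            fit = bootstrap_ci(subset, cohort, options=opts)
            fits[lab] = fit
            fit_rows.append(_fit_row(fit))
            status_rows.append({"label": lab, "stage": "fit", "status": "ok", "detail": ""})
        except InsufficientDataError as exc:
            status_rows.append(
                {"label": lab, "stage": "fit", "status": "not fit: below threshold",
                 "detail": str(exc)}
            )
            continue
        except Exception as exc:  # partial-failure contract
            status_rows.append({"label": lab, "stage": "fit", "status": "error", "detail": str(exc)})
            continue

        try:
            singles = [c for c in single_mca_calls(calls) if c.label == lab]
            strat = fit_sex_stratified(singles, cohort, options=opts,
                                       min_per_sex=min_per_sex, B=B)
            if strat.female is not None and strat.male is not None:
                for quantity in ("s", "mu"):
                    fd = fold_difference_test(strat.female, strat.male, quantity)
                    sex_rows.append(
                        {
                            "label": lab,
                            "quantity": quantity,
                            "fold_female_over_male": fd.fold,
                            "ci_lo": fd.ci[0],
                            "ci_hi": fd.ci[1],
                            "p_value": fd.p_value,
                            "significant": fd.significant,
                        }
                    )
        except InsufficientDataError:
            pass
        except Exception as exc:
            status_rows.append({"label": lab, "stage": "sex_diff", "status": "error",
                                "detail": str(exc)})

        try:
            if len(subset) >= min_age_trend:
                trend = build_age_trend(fit, subset, cohort)
                trend = deviation_test(trend, fit, cohort, seed=label_seeds[lab])
                for pt_o, pt_e in zip(trend.points_observed, trend.points_expected):
                    trend_rows.append(
                        {
                            "label": lab,
                            "decade": f"{pt_o.age_lo:.0f}-{pt_o.age_hi:.0f}",
                            "T": pt_o.T,
                            "k": pt_o.k,
                            "p_obs": pt_o.p,
                            "p_exp": pt_e.p,
                            "m_obs": trend.m_obs,
                            "m_exp": trend.m_exp,
                            "deviation": trend.deviation,
                            "p_value": trend.p_value,
                            "flags": "significant" if trend.significant else "",
                        }
                    )
        except Exception as exc:
            status_rows.append({"label": lab, "stage": "age_trend", "status": "error",
                                "detail": str(exc)})

    pd.DataFrame(fit_rows).to_csv(out / "fits.tsv", sep="\t", index=False)
    pd.DataFrame(sex_rows).to_csv(out / "sex_differences.tsv", sep="\t", index=False)
    pd.DataFrame(trend_rows).to_csv(out / "age_trends.tsv", sep="\t", index=False)
    pd.DataFrame(status_rows).to_csv(out / "status.tsv", sep="\t", index=False)

    converged = [f for f in fits.values() if f.converged]
    if converged:
        edges = list(np.arange(0.0, 0.45, 0.05)) + [1.0]
        hist = build_mca_dfe(converged, edges)
        pd.DataFrame(
            {
                "bin_lo": hist.bin_edges[:-1],
                "bin_hi": hist.bin_edges[1:],
                "rate": hist.rate,
                "labels": [",".join(m) for m in hist.labels],
            }
        ).to_csv(out / "dfe.tsv", sep="\t", index=False)

    log = {
        "version": __version__,
        "config_hash": _config_hash(config),
        "seed": seed,
        "label_seeds": label_seeds,
        "n_calls": len(calls),
        "n_labels": len(labels),
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    return out
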