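"""Agreement and summary statistics for vessel-density measurements.

Implements the method-comparison battery used to judge whether two
angiography modalities measure the same vessel density: per-modality
mean +/- sample SD, paired t-tests, Pearson correlation, Bland-Altman
95 % limits of agreement with confidence intervals, and unweighted
Cohen's kappa for ordinal (0-4) image-quality scores.

Conventions: sample SD uses the n-1 denominator throughout; limits of
agreement use the fixed 1.96 multiplier; the standard error of each
limit is sd * sqrt(3/n) with a t(n-1) quantile for its 95 % CI; all
tests are two-sided at alpha = 0.05 with no multiplicity correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError, InvalidParameterError
from .pipeline import VesselDensityRecord

__all__ = [
    "PairedAgreement",
    "ModalitySummary",
    "AgreementReport",
    "summarize",
    "paired_t_test",
    "pearson_r",
    "bland_altman",
    "cohens_kappa",
    "agreement_report",
    "records_to_frame",
]

LOA_MULTIPLIER = 1.96
MODALITIES = ("ICGA", "OMAG", "SSADA")
PAIRS = (("ICGA", "OMAG"), ("ICGA", "SSADA"), ("SSADA", "OMAG"))


@dataclass(frozen=True)
class ModalitySummary:
    modality: str
    n: int
    mean: float
    sd: float


@dataclass(frozen=True)
class PairedAgreement:
    """All pairwise agreement statistics for one modality pair.

    Differences are first-named-modality minus second.  ``ci_lower_limit``
    and ``ci_upper_limit`` are the 95 % confidence intervals of the lower
    and upper limits of agreement respectively.
    """

    pair: tuple[str, str]
    n: int
    mean_difference: float
    sd_difference: float
    loa_lower: float
    loa_upper: float
    ci_lower_limit: tuple[float, float]
    ci_upper_limit: tuple[float, float]
    pearson_r: float
    t_statistic: float
    degrees_freedom: int
    p_value: float
    points: tuple[tuple[float, float], ...] = ()  # (average, difference) pairs
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (self.loa_lower - 1e-9 <= self.mean_difference <= self.loa_upper + 1e-9):
            raise InvalidParameterError("mean difference outside its own limits")
        if abs(self.pearson_r) > 1 + 1e-12:
            raise InvalidParameterError("|r| must be <= 1")
        if not -1e-12 <= self.p_value <= 1 + 1e-12:
            raise InvalidParameterError("p must be in [0, 1]")


@dataclass(frozen=True)
class AgreementReport:
    """Per-modality summaries plus all pairwise agreement statistics."""

    summaries: tuple[ModalitySummary, ...]
    pairwise: tuple[PairedAgreement, ...]
    n_matched: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pa in self.pairwise:
            rows.append(
                {
                    "modality_a": pa.pair[0],
                    "modality_b": pa.pair[1],
                    "n": pa.n,
                    "mean_difference": pa.mean_difference,
                    "sd_difference": pa.sd_difference,
                    "loa_lower": pa.loa_lower,
                    "loa_upper": pa.loa_upper,
                    "loa_lower_ci_low": pa.ci_lower_limit[0],
                    "loa_lower_ci_high": pa.ci_lower_limit[1],
                    "loa_upper_ci_low": pa.ci_upper_limit[0],
                    "loa_upper_ci_high": pa.ci_upper_limit[1],
                    "pearson_r": pa.pearson_r,
                    "t_statistic": pa.t_statistic,
                    "degrees_freedom": pa.degrees_freedom,
                    "p_value": pa.p_value,
                }
            )
        return pd.DataFrame(rows)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"modality": s.modality, "n": s.n, "mean": s.mean, "sd": s.sd}
                for s in self.summaries
            ]
        )

    def to_text(self) -> str:
        lines = ["Per-modality vessel density (%):"]
        for s in self.summaries:
            lines.append(f"  {s.modality:6s} n={s.n:3d}  {s.mean:6.2f} +/- {s.sd:.2f}")
        lines.append("")
        lines.append("Pairwise agreement (difference = first - second):")
        for pa in self.pairwise:
            lines.append(
                f"  {pa.pair[0]} vs {pa.pair[1]}: "
                f"mean diff {pa.mean_difference:.2f}, "
                f"LOA ({pa.loa_lower:.2f}, {pa.loa_upper:.2f}), "
                f"r={pa.pearson_r:.2f}, t({pa.degrees_freedom})={pa.t_statistic:.2f}, "
                f"p={pa.p_value:.3f}"
            )
        return "\n".join(lines)


def _as_array(values: Iterable[float], name: str) -> np.ndarray:
    arr = np.asarray(list(values), dtype=float)
    if arr.ndim != 1:
        raise InvalidParameterError(f"{name} must be one-dimensional")
    if not np.isfinite(arr).all():
        raise InvalidParameterError(f"{name} contains non-finite values")
    return arr


def summarize(values: Iterable[float]) -> tuple[float, float]:
    """Arithmetic mean and sample SD (n-1 denominator)."""
    arr = _as_array(values, "values")
    if arr.size < 2:
        raise InsufficientDataError("summarize requires at least 2 values")
    return float(arr.mean()), float(arr.std(ddof=1))


def paired_t_test(
    x: Iterable[float], y: Iterable[float]
) -> tuple[float, int, float]:
    """Two-sided paired t-test; returns (t, df, p).

    t = mean(d) / (sd(d)/sqrt(n)) for d = x - y, df = n - 1.  When the
    differences have zero variance: identical inputs give (0, df, 1);
    a nonzero constant difference is reported as (inf-signed, df, 0).
    """
    xa, ya = _as_array(x, "x"), _as_array(y, "y")
    if xa.size != ya.size:
        raise InvalidParameterError("paired samples must have equal length")
    n = xa.size
    if n < 2:
        raise InsufficientDataError("paired t-test requires n >= 2")
    d = xa - ya
    df = n - 1
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d.mean() == 0.0:
            return 0.0, df, 1.0
        return math.copysign(math.inf, d.mean()), df, 0.0
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return float(t), df, p


def pearson_r(x: Iterable[float], y: Iterable[float]) -> float:
    """Product-moment correlation coefficient."""
    xa, ya = _as_array(x, "x"), _as_array(y, "y")
    if xa.size != ya.size:
        raise InvalidParameterError("inputs must have equal length")
    if xa.size < 3:
        raise InsufficientDataError("pearson_r requires n >= 3")
    if xa.std() == 0.0 or ya.std() == 0.0:
        raise InvalidParameterError("correlation undefined for a constant input")
    xc, yc = xa - xa.mean(), ya - ya.mean()
    return float(np.dot(xc, yc) / math.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))


def bland_altman(
    x: Iterable[float],
    y: Iterable[float],
    pair: tuple[str, str] = ("x", "y"),
) -> PairedAgreement:
    """Bland-Altman agreement between two paired measurement series.

    Differences d = x - y; 95 % limits of agreement are
    mean(d) +/- 1.96 sd(d), each with a 95 % CI built from the standard
    error sd * sqrt(3/n) and a t(n-1) quantile.  The paired t-test and
    Pearson r for the same pair are bundled into the returned record,
    along with the (average, difference) points for plotting.
    """
    xa, ya = _as_array(x, "x"), _as_array(y, "y")
    if xa.size != ya.size:
        raise InvalidParameterError("paired samples must have equal length")
    n = xa.size
    if n < 3:
        raise InsufficientDataError("bland_altman requires n >= 3")
    d = xa - ya
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    loa_lo = mean_d - LOA_MULTIPLIER * sd_d
    loa_hi = mean_d + LOA_MULTIPLIER * sd_d
    se_limit = sd_d * math.sqrt(3.0 / n)
    tq = float(sps.t.ppf(0.975, n - 1))
    ci_lo = (loa_lo - tq * se_limit, loa_lo + tq * se_limit)
    ci_hi = (loa_hi - tq * se_limit, loa_hi + tq * se_limit)

    t_stat, df, p = paired_t_test(xa, ya)
    degenerate = not math.isfinite(t_stat)
    if degenerate:
        t_stat = math.copysign(1e308, t_stat)  # keep the record finite-comparable
    try:
        r = pearson_r(xa, ya)
    except InvalidParameterError:
        r = float("nan")
        degenerate = True
    if math.isnan(r):
        r = 0.0

    points = tuple(
        (float(a), float(b)) for a, b in zip((xa + ya) / 2.0, d)
    )
    return PairedAgreement(
        pair=pair,
        n=n,
        mean_difference=mean_d,
        sd_difference=sd_d,
        loa_lower=loa_lo,
        loa_upper=loa_hi,
        ci_lower_limit=ci_lo,
        ci_upper_limit=ci_hi,
        pearson_r=r,
        t_statistic=t_stat,
        degrees_freedom=df,
        p_value=p,
        points=points,
        degenerate=degenerate,
    )


def cohens_kappa(a: Sequence[int], b: Sequence[int], n_categories: int = 5) -> float:
    """Unweighted Cohen's kappa for two raters' ordinal scores (0..4).

    kappa = (p_o - p_e) / (1 - p_e), with expected agreement p_e from
    the product of the raters' marginal score distributions.  Degenerate
    perfect agreement (p_e = p_o = 1) returns 1.
    """
    aa = np.asarray(list(a), dtype=int)
    bb = np.asarray(list(b), dtype=int)
    if aa.size != bb.size:
        raise InvalidParameterError("score sequences must have equal length")
    if aa.size < 1:
        raise InsufficientDataError("kappa requires at least one paired score")
    for name, arr in (("a", aa), ("b", bb)):
        if arr.min(initial=0) < 0 or arr.max(initial=0) >= n_categories:
            raise InvalidParameterError(
                f"scores in {name} must lie in 0..{n_categories - 1}"
            )
    n = aa.size
    table = np.zeros((n_categories, n_categories), dtype=float)
    np.add.at(table, (aa, bb), 1.0)
    p_o = np.trace(table) / n
    p_e = float(np.dot(table.sum(axis=1), table.sum(axis=0))) / (n * n)
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def records_to_frame(records: Iterable[VesselDensityRecord]) -> pd.DataFrame:
    """Flatten density records into a tidy DataFrame."""
    return pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "week": r.week,
                "modality": r.modality,
                "density_percent": r.density_percent,
            }
            for r in records
        ]
    )


def agreement_report(
    records: Iterable[VesselDensityRecord] | pd.DataFrame,
) -> AgreementReport:
    """Full inter-modality agreement analysis of a matched density dataset.

    Every (subject, week) must carry all three modalities; offenders are
    listed in the raised error.  Emits per-modality summaries and, for
    each modality pair, the paired t-test, Pearson r and Bland-Altman
    limits of agreement.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = records_to_frame(records)
    required = {"subject_id", "week", "modality", "density_percent"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidParameterError(f"records missing columns {sorted(missing)}")
    df["modality"] = df["modality"].str.upper()
    if df.duplicated(["subject_id", "week", "modality"]).any():
        raise InvalidParameterError("duplicate (subject, week, modality) records")

    wide = df.pivot(index=["subject_id", "week"], columns="modality",
                    values="density_percent")
    incomplete = wide[wide.isna().any(axis=1)].index.tolist()
    if incomplete or set(MODALITIES) - set(wide.columns):
        raise InvalidParameterError(
            "incomplete matched sets for (subject, week) keys: "
            f"{incomplete or sorted(wide.index.tolist())}"
        )
    wide = wide.sort_index()

    summaries = tuple(
        ModalitySummary(m, int(wide[m].size), *summarize(wide[m]))
        for m in MODALITIES
    )
    pairwise = tuple(
        bland_altman(wide[a].to_numpy(), wide[b].to_numpy(), pair=(a, b))
        for a, b in PAIRS
    )
    return AgreementReport(
        summaries=summaries, pairwise=pairwise, n_matched=len(wide)
    )
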