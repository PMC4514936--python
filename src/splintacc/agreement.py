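"""RMSD accuracy and Bland-Altman limits of agreement across specimens.

For each region and each axis (mm) or angle (degrees) the pipeline collects
one signed planned-vs-post-operative difference per specimen and summarises
the series two ways:

* RMSD = sqrt((1/n) * sum d_i^2) — note the 1/n denominator, so the RMSD
  mixes bias and spread: rmsd^2 = mean^2 + sd^2 * (n-1)/n with the sample
  (n-1) standard deviation.  An RMSD at or below the clinical cutoff
  (2 mm translational, 4 deg rotational) counts as accurate.
* Bland-Altman limits of agreement: mean +/- 1.96 * sd, with a 95% t-based
  confidence interval of half-width t * sqrt(3 * sd^2 / n) around each limit.

``stats_from_limits`` inverts the limit formulas; combined with the RMSD
identity above it reproduces an accuracy table from a limits table, which is
the cross-table consistency check used throughout.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats as sps

__all__ = [
    "DfMode",
    "MeasureKind",
    "DifferenceSeries",
    "AgreementResult",
    "rmsd",
    "bland_altman",
    "stats_from_limits",
    "classify_accuracy",
    "round_half_up",
    "DEFAULT_CUTOFFS",
]

#: Clinical accuracy cutoffs: 2 mm for translations, 4 degrees for rotations
#: (inclusive).
DEFAULT_CUTOFFS = {"translational": 2.0, "rotational": 4.0}

_LIMIT_FACTOR = 1.96  # fixed normal quantile for the limits themselves


class DfMode(str, enum.Enum):
    """Degrees of freedom for the t quantile of the limit CIs.

    ``n_minus_1`` is the statistical convention; ``n`` reproduces the CI
    widths of the original study's printed tables slightly better and is kept
    selectable.
    """

    N_MINUS_1 = "n_minus_1"
    N = "n"


class MeasureKind(str, enum.Enum):
    TRANSLATIONAL = "translational"
    ROTATIONAL = "rotational"


@dataclass(frozen=True)
class DifferenceSeries:
    """Signed per-specimen differences for one region x axis-or-angle."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        object.__setattr__(self, "values", v)
        if v.size == 0:
            raise ValueError(f"{self.label}: empty difference series")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"{self.label}: non-finite difference values")

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class AgreementResult:
    """Bland-Altman summary of one difference series."""

    label: str
    n: int
    mean_diff: float
    sd: float  # sample SD, n-1 denominator
    lower_limit: float
    upper_limit: float
    ci_lower_limit: tuple[float, float]
    ci_upper_limit: tuple[float, float]
    t_df: float
    df_mode: DfMode

    @property
    def ci_half_width(self) -> float:
        lo, hi = self.ci_lower_limit
        return (hi - lo) / 2.0


def rmsd(series: DifferenceSeries) -> float:
    """Root mean square deviation with the 1/n denominator."""
    return float(np.sqrt(np.mean(series.values**2)))


def bland_altman(
    series: DifferenceSeries, df_mode: DfMode | str = DfMode.N_MINUS_1
) -> AgreementResult:
    """Limits of agreement mean +/- 1.96 sd with t-based CIs on each limit.

    Requires n >= 3 (with fewer specimens the limit CIs are meaningless).
    The limit factor 1.96 is a fixed normal quantile; only the CI half-width
    uses the t distribution, with df selected by ``df_mode``.
    """
    df_mode = DfMode(df_mode)
    n = series.n
    if n < 3:
        raise ValueError(f"{series.label}: Bland-Altman needs n >= 3, got {n}")
    mean = float(np.mean(series.values))
    sd = float(np.std(series.values, ddof=1))
    lower = mean - _LIMIT_FACTOR * sd
    upper = mean + _LIMIT_FACTOR * sd
    df = n - 1 if df_mode is DfMode.N_MINUS_1 else n
    half = float(sps.t.ppf(0.975, df)) * np.sqrt(3.0 * sd**2 / n)
    return AgreementResult(
        label=series.label,
        n=n,
        mean_diff=mean,
        sd=sd,
        lower_limit=lower,
        upper_limit=upper,
        ci_lower_limit=(lower - half, lower + half),
        ci_upper_limit=(upper - half, upper + half),
        t_df=float(df),
        df_mode=df_mode,
    )


def stats_from_limits(
    lower: float, upper: float, n: int
) -> tuple[float, float, float]:
    """Invert Bland-Altman limits back to (mean, sd, implied RMSD).

    mean = (upper + lower) / 2, sd = (upper - lower) / (2 * 1.96), and the
    implied RMSD follows from rmsd^2 = mean^2 + sd^2 * (n-1)/n.  This is the
    identity that lets an accuracy (RMSD) table be recomputed from a limits
    table alone.
    """
    if upper < lower:
        raise ValueError(f"upper limit {upper} < lower limit {lower}")
    if n < 2:
        raise ValueError(f"need n >= 2 to imply an RMSD, got {n}")
    mean = (upper + lower) / 2.0
    sd = (upper - lower) / (2.0 * _LIMIT_FACTOR)
    implied = float(np.sqrt(mean**2 + sd**2 * (n - 1) / n))
    return mean, sd, implied


def classify_accuracy(
    rmsd_value: float,
    kind: MeasureKind | str,
    cutoffs: dict[str, float] | None = None,
) -> bool:
    """True when an RMSD is within the clinical cutoff (inclusive)."""
    if rmsd_value < 0:
        raise ValueError(f"RMSD cannot be negative, got {rmsd_value}")
    kind = MeasureKind(kind)
    table = DEFAULT_CUTOFFS if cutoffs is None else cutoffs
    return bool(rmsd_value <= table[kind.value])


def round_half_up(value: float, decimals: int = 2) -> float:
    """Decimal half-up rounding, matching the report tables."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
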