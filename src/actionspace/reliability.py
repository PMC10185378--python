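"""Two-way average-measures intraclass correlation and the reliability screen.

The reliability of a characteristic is the ICC of its actions x raters rating
matrix under a two-way ANOVA decomposition, with the "average" unit of
measurement (the rater mean is the analysed quantity downstream).  Two types
are exposed:

* ``consistency`` — ICC(C,k) = (MSR - MSE) / MSR, rater main effects ignored;
* ``agreement``   — ICC(A,k) per Shrout & Fleiss / McGraw & Wong, penalising
  rater mean differences.

Characteristics whose ICC falls below a threshold (default .5, the "poor"
band boundary) are flagged for exclusion from the factor analysis.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, MissingDataError
from .ratings import RatingStudy

#: Koo & Li interpretation bands, left-closed
BANDS = ((0.9, "excellent"), (0.75, "good"), (0.5, "moderate"), (-np.inf, "poor"))


def interpret_band(kappa: float) -> str:
    for cut, label in BANDS:
        if kappa >= cut:
            return label
    return "poor"  # pragma: no cover


@dataclass
class IccResult:
    kappa: float
    ci_low: float
    ci_high: float
    f_value: float
    df1: int
    df2: int
    p_value: float
    band: str
    icc_type: str
    n_subjects: int
    n_raters: int


def _anova_decomposition(x: np.ndarray):
    """Two-way mean squares (subjects, raters/columns, residual)."""
    n, k = x.shape
    gm = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = ((x - gm) ** 2).sum()
    ss_rows = k * ((row_means - gm) ** 2).sum()
    ss_cols = n * ((col_means - gm) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)
    return msr, msc, mse


def icc_two_way_average(ratings, icc_type: str = "consistency",
                        confidence: float = 0.95) -> IccResult:
    """Two-way average-measures ICC of a subjects x raters matrix."""
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise DegenerateDataError("need at least a 2 x 2 complete matrix")
    if np.isnan(x).any():
        raise MissingDataError("rating matrix has missing cells")
    n, k = x.shape
    msr, msc, mse = _anova_decomposition(x)
    if msr <= 0:
        raise DegenerateDataError("zero between-subject variance")
    df1, df2 = n - 1, (n - 1) * (k - 1)
    f_obs = np.inf if mse == 0 else msr / mse
    p_value = float(stats.f.sf(f_obs, df1, df2)) if np.isfinite(f_obs) else 0.0
    alpha = 1.0 - confidence

    if icc_type == "consistency":
        kappa = 1.0 if mse == 0 else (msr - mse) / msr
        if np.isfinite(f_obs):
            f_l = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
            f_u = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
            ci = (1 - 1 / f_l, 1 - 1 / f_u)
        else:
            ci = (1.0, 1.0)
    elif icc_type == "agreement":
        if mse == 0 and msc <= mse:
            kappa, ci = 1.0, (1.0, 1.0)
        else:
            kappa = (msr - mse) / (msr + (msc - mse) / n)
            # McGraw & Wong CI: Satterthwaite df for the MS ratio, through the
            # single-measures bounds and a Spearman-Brown step-up.
            icc2 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
            fj = msc / mse if mse > 0 else np.inf
            a_ = k * icc2 / (n * (1 - icc2)) if icc2 < 1 else np.inf
            b_ = 1 + k * icc2 * (n - 1) / (n * (1 - icc2)) if icc2 < 1 else np.inf
            v = ((a_ * msc + b_ * mse) ** 2) / (
                (a_ * msc) ** 2 / (k - 1) + (b_ * mse) ** 2 / ((n - 1) * (k - 1))
            )
            f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
            f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
            lo1 = n * (msr - f1 * mse) / (
                f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
            hi1 = n * (f2 * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f2 * msr)
            # step up single-measures bounds to average measures
            lo = lo1 * k / (1 + (k - 1) * lo1)
            hi = hi1 * k / (1 + (k - 1) * hi1)
            ci = (lo, hi)
    else:
        raise ValueError(f"unknown ICC type {icc_type!r}")

    return IccResult(
        kappa=float(kappa), ci_low=float(ci[0]), ci_high=float(ci[1]),
        f_value=float(f_obs), df1=df1, df2=df2, p_value=p_value,
        band=interpret_band(float(kappa)), icc_type=icc_type,
        n_subjects=n, n_raters=k,
    )


@dataclass
class ReliabilityReport:
    """Per-characteristic ICC results plus the exclusion decision."""

    results: dict[str, IccResult]
    threshold: float
    excluded: list[str] = field(default_factory=list)

    @property
    def retained(self) -> list[str]:
        return [c for c in self.results if c not in self.excluded]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, r in self.results.items():
            rows.append({
                "characteristic": name, "kappa": r.kappa,
                "ci_low": r.ci_low, "ci_high": r.ci_high,
                "f_value": r.f_value, "df1": r.df1, "df2": r.df2,
                "p_value": r.p_value, "band": r.band,
                "excluded": name in self.excluded,
            })
        return pd.DataFrame(rows)


def reliability_screen(study: RatingStudy, threshold: float = 0.5,
                       icc_type: str = "consistency") -> ReliabilityReport:
    """ICC per characteristic; flag those below ``threshold`` for exclusion."""
    results: dict[str, IccResult] = {}
    excluded: list[str] = []
    for name in study.characteristics:
        mat = study.rating_matrix(name)
        # a single incomplete action row (rater dropout) is dropped from the
        # ICC computation only, matching a complete-case two-way ANOVA
        complete = mat.dropna(axis=0, how="any")
        try:
            res = icc_two_way_average(complete.to_numpy(), icc_type=icc_type)
        except DegenerateDataError as exc:
            raise DegenerateDataError(f"characteristic {name!r}: {exc}") from exc
        results[name] = res
        if res.kappa < threshold:
            excluded.append(name)
    return ReliabilityReport(results=results, threshold=threshold, excluded=excluded)
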