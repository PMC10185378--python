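"""Sampling-adequacy diagnostics for the mean-rating matrix.

Before factoring, the Pearson correlation matrix of the characteristics is
checked for factorability: per-item Kaiser-Meyer-Olkin measures of sampling
adequacy (MSA), the overall KMO, and Bartlett's test that the correlation
matrix is the identity.  Items whose MSA falls below a threshold (default .6)
are removed in a single pass and the diagnostics recomputed on the rest.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError
from .ratings import MeanRatingMatrix

#: Kaiser's descriptive scale for MSA values (metadata only)
KAISER_LABELS = ((0.9, "marvellous"), (0.8, "meritorious"), (0.7, "middling"),
                 (0.6, "mediocre"), (0.5, "miserable"), (-np.inf, "unacceptable"))


def kaiser_label(msa: float) -> str:
    for cut, label in KAISER_LABELS:
        if msa >= cut:
            return label
    return "unacceptable"  # pragma: no cover


def pearson_corr(matrix: MeanRatingMatrix | pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix of the characteristics (columns)."""
    df = matrix.values if isinstance(matrix, MeanRatingMatrix) else matrix
    if len(df) < 3:
        raise DegenerateDataError("need at least 3 rows for correlations")
    sd = df.std(ddof=1)
    constant = sd.index[sd == 0].tolist()
    if constant:
        raise DegenerateDataError(f"constant column(s): {constant}")
    r = df.corr(method="pearson")
    np.fill_diagonal(r.values, 1.0)
    return r


def kmo(R: pd.DataFrame | np.ndarray) -> tuple[pd.Series, float]:
    """Per-item MSA and overall KMO from the anti-image of ``R``.

    With S = R^-1, the anti-image partial correlations are
    q_ij = -s_ij / sqrt(s_ii s_jj); MSA_j is the ratio of summed squared raw
    correlations to summed squared raw plus partial correlations over i != j,
    and the overall KMO is the same ratio over all pairs.
    """
    labels = list(R.columns) if isinstance(R, pd.DataFrame) else None
    r = np.asarray(R, dtype=float)
    p = r.shape[0]
    try:
        s = np.linalg.inv(r)
    except np.linalg.LinAlgError as exc:
        raise DegenerateDataError(
            "correlation matrix is singular; remove collinear items") from exc
    d = np.sqrt(np.outer(np.diag(s), np.diag(s)))
    q = -s / d
    off = ~np.eye(p, dtype=bool)
    r2 = np.where(off, r ** 2, 0.0)
    q2 = np.where(off, q ** 2, 0.0)
    msa = r2.sum(axis=1) / (r2.sum(axis=1) + q2.sum(axis=1))
    overall = r2.sum() / (r2.sum() + q2.sum())
    index = labels if labels is not None else list(range(p))
    return pd.Series(msa, index=index, name="msa"), float(overall)


def bartlett_sphericity(R: pd.DataFrame | np.ndarray, n: int) -> tuple[float, int, float]:
    """Bartlett's test of sphericity: chi2 = -(n-1-(2p+5)/6) * ln det R."""
    r = np.asarray(R, dtype=float)
    p = r.shape[0]
    sign, logdet = np.linalg.slogdet(r)
    if sign <= 0:
        raise DegenerateDataError("correlation matrix has non-positive determinant")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    p_value = float(stats.chi2.sf(chi2, df))
    return float(chi2), int(df), p_value


@dataclass
class AdequacyReport:
    corr: pd.DataFrame
    msa_per_item: pd.Series          # on the *input* item set
    kmo_overall: float               # on the retained set
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float
    retained: list[str]
    removed: list[str]
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "characteristic": self.msa_per_item.index,
            "msa": self.msa_per_item.values,
            "label": [kaiser_label(v) for v in self.msa_per_item.values],
            "removed": [c in self.removed for c in self.msa_per_item.index],
        })


def adequacy_screen(matrix: MeanRatingMatrix, msa_threshold: float = 0.6) -> AdequacyReport:
    """Single-pass MSA screen: drop items with MSA below the threshold, then
    recompute the correlation matrix, MSA/KMO and Bartlett's test on the
    retained set (n = number of rows/actions)."""
    r_all = pearson_corr(matrix)
    msa_all, _ = kmo(r_all)
    removed = [c for c in matrix.col_ids if msa_all[c] < msa_threshold]
    retained = [c for c in matrix.col_ids if c not in removed]
    if len(retained) < 3:
        raise DegenerateDataError("fewer than 3 items retained by the MSA screen")
    sub = matrix.subset(characteristics=retained)
    r = pearson_corr(sub)
    _, overall = kmo(r)
    chi2, df, p_value = bartlett_sphericity(r, n=sub.shape[0])
    return AdequacyReport(
        corr=r, msa_per_item=msa_all, kmo_overall=overall,
        bartlett_chi2=chi2, bartlett_df=df, bartlett_p=p_value,
        retained=retained, removed=removed, threshold=msa_threshold,
    )
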