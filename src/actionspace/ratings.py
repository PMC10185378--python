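"""Data model and I/O for multi-rater Likert rating studies.

The raw unit of data is a long-format record: one participant's 1-9 rating of
one action on one bipolar characteristic (each participant rates every action
on exactly one characteristic).  Aggregating over the raters of a
characteristic yields the actions x characteristics mean-rating matrix that
all downstream factor analysis consumes.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import MissingDataError, SchemaError, ValidationError

RATING_MIN = 1
RATING_MAX = 9

#: canonical long-format column names
LONG_COLUMNS = ("participant", "characteristic", "action", "rating")


@dataclass
class RatingStudy:
    """A long-format multi-rater Likert rating study.

    Parameters
    ----------
    records
        DataFrame with columns ``participant, characteristic, action, rating``
        and optionally ``rt_ms``.  Ratings are integers in 1-9.
    actions
        Optional per-action metadata (``action`` index plus e.g. ``actor_sex``,
        ``sociality``, ``transitivity``, ``recognisability_pct``).
    characteristics
        Ordered characteristic labels ("low pole - high pole"); defaults to
        order of first appearance in ``records``.
    """

    records: pd.DataFrame
    actions: pd.DataFrame | None = None
    characteristics: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in LONG_COLUMNS if c not in self.records.columns]
        if missing:
            raise SchemaError(f"records missing required column(s): {missing}")
        r = self.records["rating"]
        if not np.issubdtype(np.asarray(r).dtype, np.number):
            raise ValidationError("ratings must be numeric")
        bad = self.records.index[(r < RATING_MIN) | (r > RATING_MAX) | (r != np.floor(r))]
        if len(bad):
            row = bad[0]
            raise ValidationError(
                f"rating out of range or non-integer at row {row}: "
                f"{self.records.loc[row, 'rating']!r} (must be an integer in "
                f"{RATING_MIN}-{RATING_MAX})"
            )
        per_part = self.records.groupby("participant")["characteristic"].nunique()
        multi = per_part[per_part > 1]
        if len(multi):
            raise ValidationError(
                f"participant(s) rated more than one characteristic: "
                f"{list(multi.index[:5])}"
            )
        dup = self.records.duplicated(subset=["participant", "action"])
        if dup.any():
            row = self.records.index[dup][0]
            raise ValidationError(f"duplicate (participant, action) pair at row {row}")
        if not self.characteristics:
            self.characteristics = list(dict.fromkeys(self.records["characteristic"]))

    @property
    def action_ids(self) -> list:
        return sorted(self.records["action"].unique().tolist())

    def n_raters(self, characteristic: str) -> int:
        sub = self.records[self.records["characteristic"] == characteristic]
        return sub["participant"].nunique()

    def rating_matrix(self, characteristic: str) -> pd.DataFrame:
        """Actions x raters matrix for one characteristic (complete cells only)."""
        sub = self.records[self.records["characteristic"] == characteristic]
        if sub.empty:
            raise MissingDataError(f"no records for characteristic {characteristic!r}")
        return sub.pivot(index="action", columns="participant", values="rating")


@dataclass
class MeanRatingMatrix:
    """Actions x characteristics table of rater-averaged ratings."""

    values: pd.DataFrame          # actions x characteristics, floats in [1, 9]
    n_raters: pd.DataFrame | None = None   # per-cell contributing-rater counts

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if np.isnan(v).any():
            i, j = np.argwhere(np.isnan(v))[0]
            raise MissingDataError(
                f"missing cell: action {self.values.index[i]!r}, "
                f"characteristic {self.values.columns[j]!r}"
            )
        if (v < RATING_MIN).any() or (v > RATING_MAX).any():
            raise ValidationError("mean ratings must lie in [1, 9]")
        if self.n_raters is not None and (self.n_raters.to_numpy() < 1).any():
            raise ValidationError("every cell needs at least one rater")

    @property
    def row_ids(self) -> list:
        return list(self.values.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset(self, actions=None, characteristics=None) -> "MeanRatingMatrix":
        v = self.values
        n = self.n_raters
        if actions is not None:
            v = v.loc[actions]
            n = n.loc[actions] if n is not None else None
        if characteristics is not None:
            v = v[characteristics]
            n = n[characteristics] if n is not None else None
        return MeanRatingMatrix(v, n)


@dataclass
class RecognitionTable:
    """Per-action recognition scores from the binary name-match matrix."""

    table: pd.DataFrame           # columns: n_matched, n_participants, pct, rank
    majority_share: float         # fraction of actions recognised by > 50% of raters
    median_pct: float

    def to_json(self, path: str | Path) -> None:
        payload = {
            "actions": self.table.reset_index().to_dict(orient="records"),
            "majority_share": self.majority_share,
            "median_pct": self.median_pct,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_study(path: str | Path, schema: dict[str, str] | None = None,
               sep: str = ",") -> RatingStudy:
    """Read a long-format rating study from a delimited text file.

    ``schema`` maps canonical field names (``participant``, ``characteristic``,
    ``action``, ``rating``, optionally ``rt_ms``) to the file's column names.
    """
    df = pd.read_csv(path, sep=sep)
    schema = schema or {}
    rename = {schema.get(k, k): k for k in (*LONG_COLUMNS, "rt_ms")
              if schema.get(k, k) in df.columns}
    df = df.rename(columns=rename)
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    try:
        df["rating"] = pd.to_numeric(df["rating"])
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{path}: ratings not parseable as numbers: {exc}")
    return RatingStudy(records=df)


def read_mean_matrix(path: str | Path, sep: str = ",") -> MeanRatingMatrix:
    """Read a wide "matrix dialect" table (rows = actions, columns =
    characteristics, first column = action ids), as used for deposited
    mean-rating tables."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    return MeanRatingMatrix(values=df.astype(float))


def write_mean_matrix(matrix: MeanRatingMatrix, path: str | Path) -> None:
    """Write the mean-rating matrix; full double precision so that a
    write -> read round trip is lossless to >= 12 significant digits."""
    matrix.values.to_csv(path, float_format="%.17g")


def write_study(study: RatingStudy, path: str | Path) -> None:
    study.records.to_csv(path, index=False)


def aggregate_means(study: RatingStudy) -> MeanRatingMatrix:
    """Average ratings over raters per (action, characteristic) cell.

    Every cell must have at least one rating; missing cells raise
    :class:`MissingDataError` naming the offending pair.
    """
    grouped = study.records.groupby(["action", "characteristic"])["rating"]
    means = grouped.mean().unstack("characteristic")
    counts = grouped.size().unstack("characteristic")
    means = means[study.characteristics]
    counts = counts[study.characteristics]
    if means.isna().any().any():
        stacked = means.isna().stack()
        pairs = list(stacked[stacked].index[:5])
        raise MissingDataError(f"empty (action, characteristic) cell(s): {pairs}")
    return MeanRatingMatrix(values=means, n_raters=counts.astype(int))


def recognisability(matches: pd.DataFrame | np.ndarray,
                    action_ids=None) -> RecognitionTable:
    """Score action recognisability from a participants x actions binary
    name-match matrix: per-action percentage of participants whose name for
    the action matched, dense-ranked descending."""
    m = np.asarray(matches, dtype=float)
    if not np.isin(m, (0.0, 1.0)).all():
        raise ValidationError("match matrix entries must be 0 or 1")
    if isinstance(matches, pd.DataFrame):
        action_ids = list(matches.columns)
    elif action_ids is None:
        action_ids = list(range(m.shape[1]))
    n_participants = m.shape[0]
    n_matched = m.sum(axis=0).astype(int)
    pct = 100.0 * n_matched / n_participants
    # dense rank, highest percentage first
    rank = pd.Series(pct).rank(method="dense", ascending=False).astype(int).to_numpy()
    table = pd.DataFrame(
        {"n_matched": n_matched, "n_participants": n_participants,
         "pct": pct, "rank": rank},
        index=pd.Index(action_ids, name="action"),
    )
    return RecognitionTable(
        table=table,
        majority_share=float((pct > 50.0).mean()),
        median_pct=float(np.median(pct)),
    )
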