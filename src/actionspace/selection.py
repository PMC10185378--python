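"""Split-half EFA-to-CFA model selection and decimation robustness analyses.

The core procedure: randomly partition the actions into equal model and test
halves, run the exploratory analysis (PAF + direct oblimin, fixed k) on the
model half, convert its largest-|loading| assignments into a confirmatory
spec, and fit that spec by ML to the test half's covariance matrix.  Repeated
over many seeded partitions and candidate factor counts — with all k sharing
the partition within a simulation (paired design) — the per-simulation AIC
differences to the reference factor count summarise which dimensionality the
data support.  The decimation analyses re-run the comparison on randomly
reduced action sets, reduced rater pools, and recognisability-defined action
subsets.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cfa import CfaFit, build_cfa_spec, fit_cfa, sample_cov
from .efa import LoadingInterpretation, fit_efa
from .errors import ActionSpaceError, ValidationError
from .ratings import MeanRatingMatrix, RatingStudy, RecognitionTable, aggregate_means
from .reliability import IccResult, icc_two_way_average

logger = logging.getLogger(__name__)

Z95 = 1.96        # normal-approximation 95% CI multiplier over simulations
FIT_STATS = ("chi2", "cfi", "rmsea", "aic")


@dataclass
class SplitSimRecord:
    sim_id: int
    seed: int
    k: int
    model_half_ids: list
    test_half_ids: list
    fit: CfaFit


def _partition(action_ids: list, rng: np.random.Generator):
    ids = list(action_ids)
    perm = rng.permutation(len(ids))
    half = len(ids) // 2
    model_ids = [ids[i] for i in perm[:half]]
    test_ids = [ids[i] for i in perm[half:]]
    assert not set(model_ids) & set(test_ids)
    assert len(model_ids) + len(test_ids) == len(ids)
    return model_ids, test_ids


def _convert(matrix: MeanRatingMatrix, k: int, model_ids, test_ids,
             rot_seed: int = 0) -> CfaFit:
    efa = fit_efa(matrix.subset(actions=model_ids), k=k, seed=rot_seed)
    spec = build_cfa_spec(efa)
    test = matrix.subset(actions=test_ids)
    S = sample_cov(test.values.to_numpy(dtype=float))
    return fit_cfa(S, n=len(test_ids), spec=spec)


def split_half_convert(matrix: MeanRatingMatrix, k: int, seed: int,
                       sim_id: int = 0) -> SplitSimRecord:
    """One seeded split-half EFA-to-CFA conversion at factor count ``k``."""
    if matrix.shape[0] < 2 * (k + 2):
        raise ValidationError("too few actions for a split-half conversion")
    rng = np.random.default_rng(seed)
    model_ids, test_ids = _partition(matrix.row_ids, rng)
    fit = _convert(matrix, k, model_ids, test_ids)
    return SplitSimRecord(sim_id=sim_id, seed=seed, k=k,
                          model_half_ids=model_ids, test_half_ids=test_ids,
                          fit=fit)


@dataclass
class ModelComparison:
    """Per-k fit summaries and per-simulation AIC differences."""

    summary: pd.DataFrame        # index k; mean/ci_low/ci_high per fit stat
    delta_aic: pd.DataFrame      # index k; mean/ci_low/ci_high of AIC_k - AIC_ref
    records: pd.DataFrame        # one row per (sim, k)
    ks: tuple[int, ...]
    reference_k: int
    n_sims: int
    n_discarded: int = 0

    @property
    def winner(self) -> int:
        return int(self.summary["aic_mean"].idxmin())

    def manifest(self) -> dict:
        return {"ks": list(self.ks), "reference_k": self.reference_k,
                "n_sims": self.n_sims, "n_discarded": self.n_discarded,
                "winner_k": self.winner}


def _ci(values: np.ndarray) -> tuple[float, float, float]:
    m = float(np.mean(values))
    if len(values) < 2:
        return m, m, m
    half = Z95 * float(np.std(values, ddof=1)) / np.sqrt(len(values))
    return m, m - half, m + half


def _summarise(records: pd.DataFrame, ks, reference_k: int,
               n_sims: int, n_discarded: int) -> ModelComparison:
    rows = {}
    for k in ks:
        sub = records[records["k"] == k]
        row = {}
        for stat in FIT_STATS:
            m, lo, hi = _ci(sub[stat].to_numpy())
            row[f"{stat}_mean"], row[f"{stat}_ci_low"], row[f"{stat}_ci_high"] = m, lo, hi
        rows[k] = row
    summary = pd.DataFrame(rows).T.rename_axis("k")
    wide = records.pivot(index="sim_id", columns="k", values="aic")
    delta_rows = {}
    for k in ks:
        d = (wide[k] - wide[reference_k]).to_numpy()
        m, lo, hi = _ci(d)
        delta_rows[k] = {"delta_aic_mean": m, "ci_low": lo, "ci_high": hi}
    delta = pd.DataFrame(delta_rows).T.rename_axis("k")
    return ModelComparison(summary=summary, delta_aic=delta, records=records,
                           ks=tuple(ks), reference_k=reference_k,
                           n_sims=n_sims, n_discarded=n_discarded)


def compare_models(matrix: MeanRatingMatrix, ks=(2, 3, 4, 5), n_sims: int = 200,
                   master_seed: int = 0, reference_k: int = 4,
                   max_discard_frac: float = 0.10) -> ModelComparison:
    """Paired split-half comparison of candidate factor counts.

    All candidate k share the partition within a simulation.  Simulations in
    which any fit fails to converge after its jittered restarts are discarded
    and replaced by a fresh partition; more than ``max_discard_frac``
    discards is a hard error.
    """
    if n_sims == 1:
        logger.warning("n_sims=1: confidence intervals collapse to the mean")
    if reference_k not in ks:
        raise ValidationError("reference_k must be among the candidate ks")
    ss = np.random.SeedSequence(master_seed)
    rows = []
    discarded = 0
    sim_id = 0
    max_discard = max(int(np.ceil(max_discard_frac * n_sims)), 1)
    stream = iter(ss.generate_state(n_sims * 20))
    while sim_id < n_sims:
        seed = int(next(stream)) % (2 ** 31)
        rng = np.random.default_rng(seed)
        model_ids, test_ids = _partition(matrix.row_ids, rng)
        sim_rows = []
        ok = True
        for k in ks:
            try:
                fit = _convert(matrix, k, model_ids, test_ids)
            except ActionSpaceError as exc:
                logger.warning("sim %d k=%d failed (%s); discarding", sim_id, k, exc)
                ok = False
                break
            if not fit.converged:
                logger.warning("sim %d k=%d did not converge; discarding", sim_id, k)
                ok = False
                break
            sim_rows.append({"sim_id": sim_id, "seed": seed, "k": k,
                             "chi2": fit.chi2, "df": fit.df, "cfi": fit.cfi,
                             "rmsea": fit.rmsea, "aic": fit.aic,
                             "loglik": fit.loglik})
        if ok:
            rows.extend(sim_rows)
            sim_id += 1
        else:
            discarded += 1
            if discarded > max_discard:
                raise ActionSpaceError(
                    f"more than {max_discard_frac:.0%} of simulations discarded "
                    f"({discarded}); model comparison aborted")
    records = pd.DataFrame(rows)
    return _summarise(records, ks, reference_k, n_sims, discarded)


def decimate_actions(matrix: MeanRatingMatrix, ks=(2, 3, 4, 5),
                     grid=tuple(range(240, 90, -10)), n_sims: int = 200,
                     master_seed: int = 0, reference_k: int = 4) -> pd.DataFrame:
    """AIC-difference curves over progressively decimated action sets.

    At each grid level a fresh random action subset is drawn per simulation;
    the paired comparison runs on that subset.  Returns a long table
    (level, k, delta_aic_mean, ci_low, ci_high, aic_mean, winner_k).
    """
    n_actions = matrix.shape[0]
    ss = np.random.SeedSequence(master_seed)
    out = []
    for level, child in zip(grid, ss.spawn(len(list(grid)))):
        if level > n_actions:
            raise ValidationError(f"grid level {level} exceeds {n_actions} actions")
        if level < 2 * (max(ks) + 2):
            logger.warning("level %d below minimum identifiable size; skipped", level)
            continue
        rng = np.random.default_rng(child)
        rows = []
        sim_id = 0
        discarded = 0
        while sim_id < n_sims:
            keep_idx = rng.choice(n_actions, size=level, replace=False)
            keep = [matrix.row_ids[i] for i in sorted(keep_idx)]
            sub = matrix.subset(actions=keep)
            model_ids, test_ids = _partition(sub.row_ids, rng)
            sim_rows = []
            ok = True
            for k in ks:
                try:
                    fit = _convert(sub, k, model_ids, test_ids)
                except ActionSpaceError:
                    ok = False
                    break
                if not fit.converged:
                    ok = False
                    break
                sim_rows.append({"sim_id": sim_id, "k": k, "aic": fit.aic})
            if ok:
                rows.extend(sim_rows)
                sim_id += 1
            else:
                discarded += 1
                if discarded > max(n_sims // 5, 2):
                    raise ActionSpaceError(
                        f"too many discarded simulations at level {level}")
        rec = pd.DataFrame(rows)
        wide = rec.pivot(index="sim_id", columns="k", values="aic")
        winner = int(wide.mean().idxmin())
        for k in ks:
            d = (wide[k] - wide[reference_k]).to_numpy()
            m, lo, hi = _ci(d)
            out.append({"level": level, "k": k, "delta_aic_mean": m,
                        "ci_low": lo, "ci_high": hi,
                        "aic_mean": float(wide[k].mean()), "winner_k": winner})
    return pd.DataFrame(out)


def decimate_raters(study: RatingStudy, ks=(2, 3, 4, 5),
                    rater_counts=tuple(range(10, 0, -1)), n_sims: int = 200,
                    master_seed: int = 0, reference_k: int = 4) -> pd.DataFrame:
    """AIC-difference curves as the per-characteristic rater pool shrinks.

    Per simulation, a random subset of raters of the requested size is drawn
    independently for each characteristic, the mean-rating matrix re-aggregated
    from that subset, and the paired split-half comparison re-run.
    """
    pools = {c: sorted(study.records.loc[
        study.records["characteristic"] == c, "participant"].unique())
        for c in study.characteristics}
    min_pool = min(len(v) for v in pools.values())
    ss = np.random.SeedSequence(master_seed)
    out = []
    for count, child in zip(rater_counts, ss.spawn(len(list(rater_counts)))):
        if count > min_pool:
            raise ValidationError(
                f"requested {count} raters but a characteristic has only {min_pool}")
        rng = np.random.default_rng(child)
        rows = []
        sim_id = 0
        discarded = 0
        while sim_id < n_sims:
            chosen = []
            for c, pool in pools.items():
                idx = rng.choice(len(pool), size=count, replace=False)
                chosen.extend(pool[i] for i in idx)
            sub_records = study.records[study.records["participant"].isin(chosen)]
            sub_study = RatingStudy(records=sub_records.reset_index(drop=True),
                                    characteristics=study.characteristics)
            matrix = aggregate_means(sub_study)
            model_ids, test_ids = _partition(matrix.row_ids, rng)
            sim_rows = []
            ok = True
            for k in ks:
                try:
                    fit = _convert(matrix, k, model_ids, test_ids)
                except ActionSpaceError:
                    ok = False
                    break
                if not fit.converged:
                    ok = False
                    break
                sim_rows.append({"sim_id": sim_id, "k": k, "aic": fit.aic})
            if ok:
                rows.extend(sim_rows)
                sim_id += 1
            else:
                discarded += 1
                if discarded > max(n_sims // 5, 2):
                    raise ActionSpaceError(
                        f"too many discarded simulations at {count} raters")
        rec = pd.DataFrame(rows)
        wide = rec.pivot(index="sim_id", columns="k", values="aic")
        winner = int(wide.mean().idxmin())
        for k in ks:
            d = (wide[k] - wide[reference_k]).to_numpy()
            m, lo, hi = _ci(d)
            out.append({"rater_count": count, "k": k, "delta_aic_mean": m,
                        "ci_low": lo, "ci_high": hi,
                        "aic_mean": float(wide[k].mean()), "winner_k": winner})
    return pd.DataFrame(out)


def recognisability_split(matrix: MeanRatingMatrix, recognition: RecognitionTable,
                          ks=(2, 3, 4, 5), top_n: int = 180, n_sims: int = 200,
                          master_seed: int = 0, reference_k: int = 4
                          ) -> dict[str, ModelComparison]:
    """Paired model comparisons on the most- and least-recognisable actions.

    The two subsets each contain ``top_n`` actions ranked by recognisability
    percentage (ties broken by action id, logged); whenever 2*top_n exceeds
    the number of actions the subsets overlap in the middle of the ranking.
    """
    if top_n > matrix.shape[0]:
        raise ValidationError("top_n exceeds the number of actions")
    tab = recognition.table.copy()
    tab = tab.loc[[a for a in matrix.row_ids if a in tab.index]]
    order = tab.sort_values(["pct", "rank"], ascending=[False, True],
                            kind="stable")
    ordered_ids = sorted(order.index.tolist(),
                         key=lambda a: (-order.loc[a, "pct"], str(a)))
    most = ordered_ids[:top_n]
    least = ordered_ids[-top_n:]
    overlap = len(set(most) & set(least))
    logger.info("recognisability split: overlap of %d actions", overlap)
    # both arms share the master seed (paired design): identical subsets
    # therefore yield identical summaries
    out = {}
    for name, ids in (("most", most), ("least", least)):
        cmp_ = compare_models(matrix.subset(actions=ids), ks=ks, n_sims=n_sims,
                              master_seed=master_seed, reference_k=reference_k)
        out[name] = cmp_
    return out


def factor_reliability(matrix: MeanRatingMatrix,
                       interpretation: LoadingInterpretation
                       ) -> dict[int, IccResult]:
    """Inter-characteristic reliability of each factor: its substantial
    characteristics act as "raters" over the actions (negative loaders
    reverse-coded as 10 - x on the 1-9 scale), scored with the two-way
    average-measures ICC."""
    out: dict[int, IccResult] = {}
    for factor, items in sorted(interpretation.per_factor.items()):
        if len(items) < 2:
            logger.warning("factor %d has <2 substantial items; skipped", factor)
            continue
        block = matrix.values[items].copy()
        for item in items:
            if interpretation.loading_sign(item) < 0:
                block[item] = 10.0 - block[item]
        out[factor] = icc_two_way_average(block.to_numpy())
    return out


def comparison_to_csv(cmp_: ModelComparison, path: str | Path) -> None:
    cmp_.summary.join(cmp_.delta_aic, how="left").to_csv(path)


def manifest_to_json(cmp_: ModelComparison, path: str | Path) -> None:
    Path(path).write_text(json.dumps(cmp_.manifest(), indent=2))
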