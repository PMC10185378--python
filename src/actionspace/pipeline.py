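"""End-to-end orchestration: screens, factor analysis, model selection and
report assembly.

``run_pipeline`` executes the full analysis in publication order —
reliability screen, adequacy screen, scree/parallel analysis, EFA at the
selected and candidate factor counts, split-half model comparison, factor
reliability, factor scores — and writes a bundle of CSV tables plus a JSON
manifest recording seeds, exclusions and the winning model.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .adequacy import adequacy_screen
from .efa import factor_scores, fit_efa, interpret, parallel_analysis, scree
from .ratings import MeanRatingMatrix, RatingStudy, aggregate_means, write_mean_matrix
from .reliability import reliability_screen
from .selection import compare_models, comparison_to_csv, factor_reliability

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    icc_threshold: float = 0.5
    msa_threshold: float = 0.6
    primary_cut: float = 0.5
    cross_cut: float = 0.3
    delta_aic_threshold: float = 2.0
    candidate_ks: tuple[int, ...] = (2, 3, 4, 5)
    reference_k: int = 4
    n_sims: int = 200
    pa_reps: int = 1000
    seed: int = 0
    icc_type: str = "consistency"

    def __post_init__(self) -> None:
        assert 0 <= self.icc_threshold <= 1
        assert 0 <= self.msa_threshold <= 1
        assert 0 < self.primary_cut <= 1 and 0 < self.cross_cut <= 1
        assert self.reference_k in self.candidate_ks

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if "candidate_ks" in payload:
            payload["candidate_ks"] = tuple(payload["candidate_ks"])
        return cls(**payload)


@dataclass
class PipelineResult:
    reliability: object
    adequacy: object
    scree_result: object
    selected_k: int
    efa: object
    interpretation: object
    comparison: object
    factor_icc: dict
    scores: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def run_pipeline(study: RatingStudy | None = None,
                 matrix: MeanRatingMatrix | None = None,
                 config: PipelineConfig | None = None,
                 outdir: str | Path | None = None) -> PipelineResult:
    """Run the full analysis from a raw study (preferred) or a pre-aggregated
    mean-rating matrix (reliability screen skipped, logged)."""
    cfg = config or PipelineConfig()
    manifest: dict = {"version": __version__, "config": asdict(cfg),
                      "exclusions": []}

    rel_report = None
    if study is not None:
        rel_report = reliability_screen(study, threshold=cfg.icc_threshold,
                                        icc_type=cfg.icc_type)
        for c in rel_report.excluded:
            manifest["exclusions"].append(
                {"characteristic": c, "rule": f"icc<{cfg.icc_threshold}"})
        matrix = aggregate_means(study).subset(
            characteristics=rel_report.retained)
        logger.info("reliability screen excluded %s", rel_report.excluded)
    elif matrix is None:
        raise ValueError("provide a study or a mean-rating matrix")
    else:
        logger.info("pre-aggregated matrix given: reliability screen skipped")

    adq = adequacy_screen(matrix, msa_threshold=cfg.msa_threshold)
    for c in adq.removed:
        manifest["exclusions"].append(
            {"characteristic": c, "rule": f"msa<{cfg.msa_threshold}"})
    matrix = matrix.subset(characteristics=adq.retained)

    eig = scree(adq.corr)
    sr = parallel_analysis(adq.corr, n=matrix.shape[0], p=matrix.shape[1],
                           reps=cfg.pa_reps, seed=cfg.seed)
    sr.eigenvalues = eig     # report the unreduced scree alongside
    selected_k = sr.n_factors_pa
    logger.info("parallel analysis retains %d factors", selected_k)

    efa = fit_efa(matrix, k=selected_k, seed=cfg.seed)
    interp = interpret(efa.structure_frame(), primary_cut=cfg.primary_cut,
                       cross_cut=cfg.cross_cut)
    comparison = compare_models(matrix, ks=cfg.candidate_ks, n_sims=cfg.n_sims,
                                master_seed=cfg.seed,
                                reference_k=cfg.reference_k)
    ficc = factor_reliability(matrix, interp)
    scores = factor_scores(matrix, efa)

    manifest.update({
        "selected_k": int(selected_k),
        "winner_k": comparison.winner,
        "total_var_pct": efa.total_var_pct,
        "n_actions": matrix.shape[0],
        "n_characteristics": matrix.shape[1],
        "retained_characteristics": matrix.col_ids,
        "n_sims": cfg.n_sims,
        "seed": cfg.seed,
        "n_discarded": comparison.n_discarded,
    })

    result = PipelineResult(
        reliability=rel_report, adequacy=adq, scree_result=sr,
        selected_k=selected_k, efa=efa, interpretation=interp,
        comparison=comparison, factor_icc=ficc, scores=scores,
        manifest=manifest,
    )
    if outdir is not None:
        _write_bundle(result, matrix, Path(outdir))
    return result


def _write_bundle(result: PipelineResult, matrix: MeanRatingMatrix,
                  outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    if result.reliability is not None:
        result.reliability.to_frame().to_csv(outdir / "reliability.csv", index=False)
    result.adequacy.to_frame().to_csv(outdir / "adequacy.csv", index=False)
    result.adequacy.corr.to_csv(outdir / "correlations.csv")
    efa = result.efa
    efa.pattern_frame().to_csv(outdir / "pattern.csv")
    efa.structure_frame().to_csv(outdir / "structure.csv")
    efa.phi_frame().to_csv(outdir / "phi.csv")
    pd.DataFrame({"communality": efa.communalities}, index=efa.items) \
        .to_csv(outdir / "communalities.csv")
    pd.DataFrame({"eigenvalue": result.scree_result.eigenvalues,
                  "pa_reference": result.scree_result.pa_reference}) \
        .to_csv(outdir / "scree.csv", index=False)
    comparison_to_csv(result.comparison, outdir / "model_comparison.csv")
    rows = [{"factor": f, "kappa": r.kappa, "ci_low": r.ci_low,
             "ci_high": r.ci_high, "f_value": r.f_value, "df1": r.df1,
             "df2": r.df2, "band": r.band}
            for f, r in result.factor_icc.items()]
    pd.DataFrame(rows).to_csv(outdir / "factor_reliability.csv", index=False)
    result.scores.to_csv(outdir / "factor_scores.csv")
    write_mean_matrix(matrix, outdir / "mean_ratings_retained.csv")
    (outdir / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True, default=str))
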