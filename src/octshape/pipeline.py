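"""End-to-end analysis: contours -> descriptors -> features -> correlations."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .contours import Cohort
from .descriptors import ContourShapeTransformer, CurvatureCorrection
from .reference import LeaveGroupOutScorer, summarize
from .stats import DEFAULT_SE_CONST, correlation_table


@dataclass
class AnalysisResult:
    """All tables produced by one cohort analysis run."""

    descriptors: pd.DataFrame
    features_all: pd.DataFrame
    features_regional: pd.DataFrame
    eye_summary: pd.DataFrame
    regional_eye_summary: pd.DataFrame
    region_table: pd.DataFrame
    correlations: pd.DataFrame

    def save(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("descriptors", "features_all", "features_regional",
                     "eye_summary", "regional_eye_summary", "region_table",
                     "correlations"):
            getattr(self, name).to_csv(out / f"{name}.csv", index=False)


def run_shape_analysis(cohort: Cohort, *,
                       correction: CurvatureCorrection | None = None,
                       n_groups: int = 5, seed: int = 0,
                       normalization: str = "amplitude",
                       se_const: float = DEFAULT_SE_CONST,
                       alpha: float = 0.05,
                       exclude_eyes: tuple[str, ...] = ()) -> AnalysisResult:
    """Run the full shape-analysis pipeline on a loaded cohort.

    Descriptors are computed once; B scans are then scored twice — against
    pooled ("all") references for all-of-eye features and against
    same-region references for regional features — summarised per eye and
    per eye x region, and correlated with axial length under a joint Holm
    family.
    """
    descriptors = ContourShapeTransformer(
        correction=correction, normalization=normalization
    ).fit(None).transform(cohort.contours)

    scorer_all = LeaveGroupOutScorer(scope="all", n_groups=n_groups,
                                     random_state=seed).fit(descriptors)
    features_all = scorer_all.transform(descriptors)
    scorer_reg = LeaveGroupOutScorer(scope="regional", n_groups=n_groups,
                                     random_state=seed).fit(descriptors)
    features_regional = scorer_reg.transform(descriptors)

    eye_summary = summarize(features_all, level="eye")
    regional_eye_summary = summarize(features_regional, level="eye_region")
    region_table = summarize(features_regional, level="region")

    correlations = correlation_table(
        eye_summary, regional_eye_summary, alpha=alpha,
        se_const=se_const, exclude_eyes=exclude_eyes,
    )
    return AnalysisResult(
        descriptors=descriptors,
        features_all=features_all,
        features_regional=features_regional,
        eye_summary=eye_summary,
        regional_eye_summary=regional_eye_summary,
        region_table=region_table,
        correlations=correlations,
    )
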