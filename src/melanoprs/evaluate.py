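"""Incremental-value evaluation of genomic scores over a traditional model.

For each genomic score of interest (MC1R only, each biological pathway,
and the full SNP set), the score is added as a fixed-weight offset to the
base model (traditional risk score offset + freely fitted demographic
covariates) and the pair of models is compared on discrimination (AUC and
its paired chi-square test), reclassification (continuous NRI with case and
control components) and calibration (Hosmer-Lemeshow); the score's OPERA
(OR per age/sex-adjusted control-SD) is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .manifest import PATHWAYS, WeightsManifest
from .metrics import (
    AucComparison,
    AucResult,
    HlResult,
    NriResult,
    OperaResult,
    auc,
    compare_auc,
    continuous_nri,
    hosmer_lemeshow,
    opera,
)
from .modeling import ModelSpec, fixed_weight_model
from .scoring import TraditionalWeights, polygenic_score, traditional_score
from .stratification import (
    assign_tertiles,
    concordance,
    cross_tab,
    discordant_cells,
)

__all__ = ["EvaluationBundle", "evaluate_incremental", "crosstab_analysis",
           "SCORE_SETS"]

#: Genomic score sets evaluated against the base traditional model.
SCORE_SETS = ("mc1r", "pigmentation", "nevus", "telomere_senescence_other",
              "all_snps")


@dataclass(frozen=True)
class EvaluationBundle:
    """All comparison statistics for one genomic score added to the base model."""

    label: str
    auc_base: AucResult
    auc_new: AucResult
    comparison: AucComparison
    nri: NriResult
    hl: HlResult
    opera: OperaResult

    def to_dict(self) -> Dict:
        return {
            "label": self.label,
            "auc_base": self.auc_base.to_dict(),
            "auc_new": self.auc_new.to_dict(),
            "comparison": self.comparison.to_dict(),
            "nri": self.nri.to_dict(),
            "hosmer_lemeshow": self.hl.to_dict(),
            "opera": self.opera.to_dict(),
        }


def _score_for_set(cohort, manifest: WeightsManifest, label: str,
                   stratify_mc1r: bool, center: bool):
    if label == "mc1r":
        sub = manifest.subset(manifest.mc1r_snps)
        return polygenic_score(cohort, sub, stratify_mc1r=stratify_mc1r,
                               center=center)
    if label in PATHWAYS:
        return polygenic_score(cohort, manifest, pathway=label,
                               stratify_mc1r=stratify_mc1r, center=center)
    if label == "all_snps":
        return polygenic_score(cohort, manifest, stratify_mc1r=stratify_mc1r,
                               center=center)
    raise ValueError(f"unknown score set {label!r}; allowed: {SCORE_SETS}")


def evaluate_incremental(
    cohort: pd.DataFrame,
    manifest: WeightsManifest,
    trad_weights: Optional[TraditionalWeights] = None,
    spec: Optional[ModelSpec] = None,
    score_sets: Sequence[str] = SCORE_SETS,
    stratify_mc1r: bool = True,
    center: bool = True,
) -> List[EvaluationBundle]:
    """Compare base (traditional) vs base + genomic-score models.

    Both models carry the traditional risk score as a fixed-weight offset
    and estimate the demographic terms freely; the enhanced model adds the
    genomic score to the offset. Returns one bundle per score set.
    """
    spec = spec or ModelSpec()
    y = cohort[spec.outcome].to_numpy(dtype=int)
    trad = traditional_score(cohort, trad_weights)
    base = fixed_weight_model(cohort, [trad], spec)
    p_base = base.fitted_prob
    auc_base = auc(p_base, y)

    bundles = []
    for label in score_sets:
        prs = _score_for_set(cohort, manifest, label, stratify_mc1r, center)
        enhanced = fixed_weight_model(cohort, [trad, prs], spec)
        p_new = enhanced.fitted_prob
        bundles.append(EvaluationBundle(
            label=label,
            auc_base=auc_base,
            auc_new=auc(p_new, y),
            comparison=compare_auc(p_base, p_new, y),
            nri=continuous_nri(p_base, p_new, y),
            hl=hosmer_lemeshow(p_new, y),
            opera=opera(prs, cohort),
        ))
    return bundles


def crosstab_analysis(
    cohort: pd.DataFrame,
    manifest: WeightsManifest,
    trad_weights: Optional[TraditionalWeights] = None,
    stratify_mc1r: bool = True,
    center: bool = True,
) -> Dict:
    """Tertile cross-tabulation of polygenic vs traditional score.

    Returns the 3x3 table with concordance and the two extreme discordant
    cell proportions.
    """
    trad = traditional_score(cohort, trad_weights)
    prs = polygenic_score(cohort, manifest, stratify_mc1r=stratify_mc1r,
                          center=center)
    ct = cross_tab(assign_tertiles(trad), assign_tertiles(prs))
    return {
        "crosstab": ct,
        "concordance": concordance(ct),
        "discordant": discordant_cells(ct),
    }
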