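"""Risk-score construction from external per-SNP and per-factor weights.

The polygenic risk score is the standard log-OR-weighted dosage sum

    S_i = sum_j (d_ij - c_j) * ln(OR_j)

where ``d_ij`` is participant *i*'s effect-allele dosage at SNP *j* and
``c_j = 2 * eaf_j`` when centering is on (so the population-expected score
is ~0 and score ranges span negative and positive values). For MC1R
variants the per-allele OR may be stratified by the sun-sensitive
phenotype: a participant qualifies as sun-sensitive if they have any of
freckles (few/some/many), red hair, or skin that usually or always burns,
and then the sun-sensitive OR applies in place of the overall one.

The traditional risk score is the analogous linear predictor over
categorical risk-factor levels, each weighted by its external log OR
relative to the factor's reference level; it is returned on the log-odds
scale, which is monotone in predicted probability, so tertile assignment is
unaffected by the choice of scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd

from .manifest import PATHWAYS, WeightsManifest
from .simulate import CATEGORY_LEVELS

__all__ = [
    "ScoringError",
    "TraditionalWeights",
    "EXAMPLE_TRADITIONAL_LOG_OR",
    "example_traditional_weights",
    "sun_sensitive",
    "polygenic_score",
    "traditional_score",
]


class ScoringError(ValueError):
    """A score could not be computed from the given cohort and weights."""


@dataclass(frozen=True)
class TraditionalWeights:
    """Per-level log odds ratios for the traditional risk factors.

    ``log_or`` maps ``factor -> level -> log OR``; reference levels carry
    weight 0 (explicitly or by omission). Levels found in a cohort but not
    mapped (and not the implicit reference) raise at scoring time.
    """

    log_or: Dict[str, Dict[str, float]]

    def __post_init__(self) -> None:
        for factor, levels in self.log_or.items():
            for level, val in levels.items():
                if not np.isfinite(val):
                    raise ScoringError(
                        f"weight for {factor!r}={level!r} is not finite"
                    )


# Synthetic example weight set for the traditional factors (per-level ORs on
# a plausible scale for fair-skinned populations; reference levels first in
# CATEGORY_LEVELS carry OR 1). Real analyses supply their own weights.
_EXAMPLE_TRADITIONAL_OR: Dict[str, Dict[str, float]] = {
    "hair_color": {"light_brown": 1.01, "fair_blonde": 1.82, "red": 2.76},
    "eye_color": {"green_hazel": 1.05, "blue_grey": 1.39},
    "skin_color": {"medium": 1.30, "fair": 1.60},
    "freckling": {"few": 1.20, "some": 1.45, "many": 1.80},
    "photosensitivity": {"sometimes": 1.10, "usually": 1.40, "always": 1.70},
    "nevus_density": {"few": 1.19, "some": 3.13, "many": 5.36},
    "sunbed_use": {"1_10": 0.96, "gt_10": 1.79},
    "blistering_sunburn_child": {"1_or_more": 1.20},
    "kc_history": {"yes": 2.28},
    "family_history": {"1_or_more": 1.61},
    "vacation_sun_q": {"2": 1.10, "3": 1.20, "4": 1.35},
}

#: Same example weights on the log-OR scale (factor -> level -> log OR).
EXAMPLE_TRADITIONAL_LOG_OR: Dict[str, Dict[str, float]] = {
    factor: {lev: float(np.log(orr)) for lev, orr in levels.items()}
    for factor, levels in _EXAMPLE_TRADITIONAL_OR.items()
}


def example_traditional_weights() -> TraditionalWeights:
    """The packaged synthetic example :class:`TraditionalWeights`."""
    return TraditionalWeights(
        {f: dict(lv) for f, lv in EXAMPLE_TRADITIONAL_LOG_OR.items()}
    )


def _check_levels(cohort: pd.DataFrame, column: str) -> None:
    allowed = set(CATEGORY_LEVELS[column])
    seen = set(cohort[column].dropna().astype(str).unique())
    bad = seen - allowed
    if bad:
        raise ScoringError(
            f"column {column!r} has unrecognised levels {sorted(bad)}; "
            f"allowed: {sorted(allowed)}"
        )


def sun_sensitive(cohort: pd.DataFrame) -> pd.Series:
    """Boolean sun-sensitive phenotype flag per participant.

    True iff freckling in {few, some, many}, or red hair, or skin that
    usually or always burns.
    """
    for col in ("freckling", "hair_color", "photosensitivity"):
        if col not in cohort.columns:
            raise ScoringError(f"cohort lacks required column {col!r}")
        _check_levels(cohort, col)
    freckled = cohort["freckling"].astype(str).isin(["few", "some", "many"])
    red = cohort["hair_color"].astype(str) == "red"
    burns = cohort["photosensitivity"].astype(str).isin(["usually", "always"])
    out = freckled | red | burns
    out.name = "sun_sensitive"
    return out


def polygenic_score(
    cohort: pd.DataFrame,
    manifest: WeightsManifest,
    pathway: Optional[str] = None,
    stratify_mc1r: bool = False,
    center: bool = True,
) -> pd.Series:
    """Log-OR-weighted allele-dosage polygenic risk score.

    Parameters
    ----------
    pathway:
        If given, restrict to SNPs whose pathway set contains this label
        (SNPs may contribute to several pathway scores).
    stratify_mc1r:
        Use the sun-sensitive / not-sensitive OR for MC1R SNPs according to
        each participant's phenotype instead of the overall OR.
    center:
        Subtract the expected dosage ``2 * eaf`` from each dosage, shifting
        every participant by the same constant per SNP (ranks, tertiles and
        discrimination metrics are invariant to this).
    """
    tab = manifest.table
    if pathway is not None:
        if pathway not in PATHWAYS:
            raise ScoringError(
                f"unknown pathway {pathway!r}; allowed: {PATHWAYS}"
            )
        tab = tab[tab["pathways"].map(lambda s: pathway in s)]
        if tab.empty:
            raise ScoringError(f"no SNPs in pathway {pathway!r}")

    ss = sun_sensitive(cohort).to_numpy() if stratify_mc1r else None
    score = np.zeros(len(cohort))
    for _, row in tab.iterrows():
        col = f"dose_{row['snp_id']}"
        if col not in cohort.columns:
            raise ScoringError(f"cohort lacks dosage column {col!r}")
        dose = cohort[col].to_numpy(dtype=float)
        centered = dose - (2.0 * float(row["eaf"]) if center else 0.0)
        if stratify_mc1r and row["is_mc1r"]:
            if pd.isna(row["or_sun_sensitive"]) or pd.isna(row["or_not_sensitive"]):
                raise ScoringError(
                    f"stratify_mc1r requires both stratified ORs for "
                    f"{row['snp_id']!r}"
                )
            w = np.where(
                ss,
                np.log(float(row["or_sun_sensitive"])),
                np.log(float(row["or_not_sensitive"])),
            )
        else:
            w = np.log(float(row["or_overall"]))
        score += centered * w

    label = f"prs_{pathway}" if pathway else "prs_overall"
    return pd.Series(score, index=cohort.index, name=label)


def traditional_score(
    cohort: pd.DataFrame, weights: Optional[TraditionalWeights] = None
) -> pd.Series:
    """Traditional risk-factor score: sum of per-level external log ORs.

    Uses the packaged synthetic example weights when none are supplied.
    Reference levels (weight omitted but listed first among the factor's
    known levels) contribute 0; any other unmapped level is an error.
    """
    if weights is None:
        weights = example_traditional_weights()
    score = np.zeros(len(cohort))
    for factor, levels in weights.log_or.items():
        if factor not in cohort.columns:
            raise ScoringError(f"cohort lacks risk-factor column {factor!r}")
        reference = {CATEGORY_LEVELS[factor][0]} if factor in CATEGORY_LEVELS else {"1"}
        values = cohort[factor].astype(str)
        known = set(levels) | reference
        bad = set(values.unique()) - known
        if bad:
            raise ScoringError(
                f"factor {factor!r} has unmapped level(s) {sorted(bad)}; "
                f"weighted levels: {sorted(levels)}, reference: {sorted(reference)}"
            )
        score += values.map(lambda v: levels.get(v, 0.0)).to_numpy(dtype=float)
    return pd.Series(score, index=cohort.index, name="traditional")
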