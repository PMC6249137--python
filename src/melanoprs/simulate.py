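"""Synthetic case-control cohort generator.

Produces cohorts with the statistical structure the downstream analysis
assumes, so that every stage (scoring, modeling, evaluation) is testable
without access to individual-level study data:

* genotypes drawn in Hardy-Weinberg proportions from the manifest's effect
  allele frequencies (independent SNPs, no linkage disequilibrium);
* pigmentation phenotypes statistically coupled to MC1R dosage through
  configurable log-odds increments (red hair, heavy freckling and burn
  propensity all become more likely per MC1R effect allele), all other
  traits drawn independently from configurable category frequencies;
* disease status from an additive logistic model on the log-odds scale,
  with the intercept calibrated numerically so that the source-population
  prevalence matches the study profile, followed by case-control
  ascertainment to the profile's exact quotas and age windows.

The module's :class:`TrueEffects` records the generator's ground truth,
against which parameter recovery is tested.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional, Tuple, Union

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit, logit

from .manifest import WeightsManifest, default_manifest, read_manifest
from .profiles import StudyProfile, get_profile

__all__ = [
    "ConfigurationError",
    "SimulationError",
    "TrueEffects",
    "CATEGORY_LEVELS",
    "DEFAULT_CATEGORY_FREQS",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_outcome",
    "generate_study",
    "study_like_effects",
    "complete_cases",
    "COHORT_COLUMNS",
]


class ConfigurationError(ValueError):
    """A simulation configuration is invalid."""


class SimulationError(RuntimeError):
    """A simulation could not satisfy its design constraints."""


#: Categorical phenotype levels, in reference-first order.
CATEGORY_LEVELS: Dict[str, Tuple[str, ...]] = {
    "hair_color": ("dark", "light_brown", "fair_blonde", "red"),
    "eye_color": ("brown_black", "green_hazel", "blue_grey"),
    "skin_color": ("olive_dark", "medium", "fair"),
    "freckling": ("none", "few", "some", "many"),
    "photosensitivity": ("never", "sometimes", "usually", "always"),
    "nevus_density": ("none", "few", "some", "many"),
    "sunbed_use": ("none", "1_10", "gt_10"),
    "blistering_sunburn_child": ("none", "1_or_more"),
    "kc_history": ("no", "yes"),
    "family_history": ("none", "1_or_more"),
}

#: Default marginal category frequencies (configurable placeholders for a
#: fair-skinned European-ancestry population; not estimates of any study).
DEFAULT_CATEGORY_FREQS: Dict[str, Dict[str, float]] = {
    "hair_color": {"dark": 0.45, "light_brown": 0.30, "fair_blonde": 0.20, "red": 0.05},
    "eye_color": {"brown_black": 0.35, "green_hazel": 0.30, "blue_grey": 0.35},
    "skin_color": {"olive_dark": 0.25, "medium": 0.45, "fair": 0.30},
    "freckling": {"none": 0.45, "few": 0.30, "some": 0.15, "many": 0.10},
    "photosensitivity": {"never": 0.25, "sometimes": 0.40, "usually": 0.25, "always": 0.10},
    "nevus_density": {"none": 0.30, "few": 0.40, "some": 0.20, "many": 0.10},
    "sunbed_use": {"none": 0.70, "1_10": 0.20, "gt_10": 0.10},
    "blistering_sunburn_child": {"none": 0.60, "1_or_more": 0.40},
    "kc_history": {"no": 0.95, "yes": 0.05},
    "family_history": {"none": 0.90, "1_or_more": 0.10},
}

#: Cohort CSV column order (dosage columns follow these).
COHORT_COLUMNS = [
    "id", "status", "age", "sex", "center", "ancestry",
    "hair_color", "eye_color", "skin_color", "freckling", "photosensitivity",
    "nevus_density", "sunbed_use", "blistering_sunburn_child",
    "vacation_sun_q", "kc_history", "family_history",
]

_COUPLED_TRAITS = ("red_hair", "freckling", "burns")


@dataclass(frozen=True)
class TrueEffects:
    """Ground-truth effect sizes used by the generator.

    Attributes
    ----------
    snp_log_or:
        Per-SNP per-effect-allele log odds ratio on disease.
    pheno_log_or:
        ``factor -> level -> log OR`` on disease, relative to the factor's
        reference level (implicitly 0). ``vacation_sun_q`` levels are the
        integers 2-4 as strings.
    mc1r_pheno_coupling:
        ``snp -> trait -> log-odds increment`` per effect allele for the
        traits ``red_hair``, ``freckling`` (few/some/many vs none) and
        ``burns`` (usually/always vs never/sometimes).
    """

    snp_log_or: Dict[str, float] = field(default_factory=dict)
    pheno_log_or: Dict[str, Dict[str, float]] = field(default_factory=dict)
    mc1r_pheno_coupling: Dict[str, Dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, val in self.snp_log_or.items():
            if not np.isfinite(val):
                raise ConfigurationError(f"snp_log_or[{name!r}] is not finite")
        for factor, levels in self.pheno_log_or.items():
            for level, val in levels.items():
                if not np.isfinite(val):
                    raise ConfigurationError(
                        f"pheno_log_or[{factor!r}][{level!r}] is not finite"
                    )
        for snp, traits in self.mc1r_pheno_coupling.items():
            for trait, val in traits.items():
                if trait not in _COUPLED_TRAITS:
                    raise ConfigurationError(
                        f"unknown coupled trait {trait!r}; allowed: {_COUPLED_TRAITS}"
                    )
                if not np.isfinite(val):
                    raise ConfigurationError(
                        f"mc1r_pheno_coupling[{snp!r}][{trait!r}] is not finite"
                    )

    @classmethod
    def null(cls) -> "TrueEffects":
        """All-zero effects: disease independent of genotype and phenotype."""
        return cls()

    @classmethod
    def uniform_coupling(cls, snps, log_or: float, **kwargs) -> "TrueEffects":
        """Effects with the same coupling log-OR on every listed MC1R SNP."""
        coupling = {s: {t: log_or for t in _COUPLED_TRAITS} for s in snps}
        return cls(mc1r_pheno_coupling=coupling, **kwargs)


def simulate_genotypes(
    n: int, manifest: WeightsManifest, seed: int
) -> pd.DataFrame:
    """Draw an ``n x n_snps`` dosage table in Hardy-Weinberg proportions.

    Each dosage is the sum of two independent Bernoulli(eaf) draws, i.e.
    Binomial(2, eaf), giving genotype class frequencies (q^2, 2pq, p^2).
    Columns are named ``dose_<snp_id>``.
    """
    if n <= 0:
        raise ConfigurationError("n must be positive")
    rng = np.random.default_rng(seed)
    tab = manifest.table
    out = {}
    for _, row in tab.iterrows():
        p = row["eaf"]
        if pd.isna(p):
            raise ConfigurationError(
                f"SNP {row['snp_id']!r} has no effect-allele frequency"
            )
        out[f"dose_{row['snp_id']}"] = rng.binomial(2, float(p), size=n)
    return pd.DataFrame(out)


def _draw_categories(rng, levels, freqs, n):
    probs = np.array([freqs[lev] for lev in levels], dtype=float)
    probs = probs / probs.sum()
    return rng.choice(np.array(levels, dtype=object), size=n, p=probs)


def _coupled_binary(rng, base_p: float, eta_shift: np.ndarray) -> np.ndarray:
    return rng.random(len(eta_shift)) < expit(logit(base_p) + eta_shift)


def simulate_phenotypes(
    dosages: pd.DataFrame,
    effects: TrueEffects,
    profile: StudyProfile,
    seed: int,
    category_freqs: Optional[Mapping[str, Mapping[str, float]]] = None,
) -> pd.DataFrame:
    """Draw demographics and traditional risk-factor phenotypes.

    Red hair, heavy freckling (few/some/many) and burn propensity
    (usually/always) are drawn from logistic models whose linear predictors
    include ``mc1r_pheno_coupling`` times MC1R dosage; all other traits are
    independent draws from the configured category frequencies. Age is
    uniform over the union of the profile's case and control age windows;
    vacation sun exposure is a latent standard normal cut at its theoretical
    quartiles.
    """
    n = len(dosages)
    freqs = {
        factor: dict(DEFAULT_CATEGORY_FREQS[factor]) for factor in CATEGORY_LEVELS
    }
    if category_freqs:
        for factor, mapping in category_freqs.items():
            if factor not in freqs:
                raise ConfigurationError(f"unknown phenotype factor {factor!r}")
            freqs[factor].update(mapping)

    for snp in effects.mc1r_pheno_coupling:
        if f"dose_{snp}" not in dosages.columns:
            raise ConfigurationError(
                f"mc1r_pheno_coupling references SNP {snp!r} absent from the "
                "dosage table"
            )

    rng = np.random.default_rng(seed)
    out = pd.DataFrame(index=dosages.index)

    lo, hi = profile.age_range_source
    out["age"] = rng.uniform(lo, hi, size=n)
    out["sex"] = np.where(
        rng.random(n) < profile.prop_female, "female", "male"
    ).astype(object)
    centers = np.array(profile.center_list, dtype=object)
    out["center"] = rng.choice(centers, size=n)
    anc_levels = list(profile.ancestry_distribution)
    anc_probs = np.array([profile.ancestry_distribution[a] for a in anc_levels])
    out["ancestry"] = rng.choice(
        np.array(anc_levels, dtype=object), size=n, p=anc_probs / anc_probs.sum()
    )

    # Per-trait MC1R load on the logit scale.
    eta = {trait: np.zeros(n) for trait in _COUPLED_TRAITS}
    for snp, traits in effects.mc1r_pheno_coupling.items():
        dose = dosages[f"dose_{snp}"].to_numpy(dtype=float)
        for trait, beta in traits.items():
            eta[trait] += beta * dose

    hair_f = freqs["hair_color"]
    red = _coupled_binary(rng, hair_f["red"], eta["red_hair"])
    nonred_levels = ("dark", "light_brown", "fair_blonde")
    hair = _draw_categories(rng, nonred_levels, hair_f, n)
    hair[red] = "red"
    out["hair_color"] = hair

    frk_f = freqs["freckling"]
    p_heavy = frk_f["few"] + frk_f["some"] + frk_f["many"]
    heavy = _coupled_binary(rng, p_heavy, eta["freckling"])
    frk = np.full(n, "none", dtype=object)
    frk[heavy] = _draw_categories(rng, ("few", "some", "many"), frk_f, int(heavy.sum()))
    out["freckling"] = frk

    pho_f = freqs["photosensitivity"]
    p_burn = pho_f["usually"] + pho_f["always"]
    burns = _coupled_binary(rng, p_burn, eta["burns"])
    pho = _draw_categories(rng, ("never", "sometimes"), pho_f, n)
    pho[burns] = _draw_categories(
        rng, ("usually", "always"), pho_f, int(burns.sum())
    )
    out["photosensitivity"] = pho

    for factor in (
        "eye_color", "skin_color", "nevus_density", "sunbed_use",
        "blistering_sunburn_child", "kc_history", "family_history",
    ):
        out[factor] = _draw_categories(rng, CATEGORY_LEVELS[factor], freqs[factor], n)

    latent = rng.standard_normal(n)
    out["vacation_sun_q"] = 1 + np.searchsorted(
        [-0.6744897501960817, 0.0, 0.6744897501960817], latent, side="right"
    ).astype(int)
    # reorder
    cols = [c for c in COHORT_COLUMNS if c in out.columns]
    return out[cols]


def _linear_predictor(
    dosages: pd.DataFrame, phenotypes: pd.DataFrame, effects: TrueEffects
) -> np.ndarray:
    eta = np.zeros(len(dosages))
    for snp, beta in effects.snp_log_or.items():
        col = f"dose_{snp}"
        if col not in dosages.columns:
            raise ConfigurationError(
                f"snp_log_or references SNP {snp!r} absent from the dosage table"
            )
        eta += beta * dosages[col].to_numpy(dtype=float)
    for factor, levels in effects.pheno_log_or.items():
        if factor not in phenotypes.columns:
            raise ConfigurationError(
                f"pheno_log_or references factor {factor!r} absent from the "
                "phenotype table"
            )
        values = phenotypes[factor].astype(str)
        lut = {str(k): v for k, v in levels.items()}
        eta += values.map(lambda v: lut.get(v, 0.0)).to_numpy(dtype=float)
    return eta


def _calibrate_intercept(eta: np.ndarray, prevalence: float) -> float:
    """Solve mean(expit(c + eta)) = prevalence for c (root-finding to 1e-8)."""
    def f(c):
        return expit(c + eta).mean() - prevalence
    return float(brentq(f, -50.0, 50.0, xtol=1e-8))


def simulate_outcome(
    dosages: pd.DataFrame,
    phenotypes: pd.DataFrame,
    effects: TrueEffects,
    profile: StudyProfile,
    seed: int,
) -> pd.DataFrame:
    """Assign disease and ascertain the case-control sample.

    Disease probability is ``expit(intercept + genetic + phenotypic
    effects)`` with the intercept solved so that the source-population
    prevalence equals ``profile.baseline_prevalence``. Cases are then
    sampled without replacement among diseased individuals inside the case
    age window, controls among disease-free individuals inside the control
    age window, to exactly the profile's quotas.
    """
    if len(dosages) != len(phenotypes):
        raise ConfigurationError("dosage and phenotype tables differ in length")
    rng = np.random.default_rng(seed)
    eta = _linear_predictor(dosages, phenotypes, effects)
    intercept = _calibrate_intercept(eta, profile.baseline_prevalence)
    p = expit(intercept + eta)
    disease = rng.random(len(p)) < p

    age = phenotypes["age"].to_numpy(dtype=float)
    lo_c, hi_c = profile.age_range_cases
    lo_k, hi_k = profile.age_range_controls
    case_pool = np.flatnonzero(disease & (age >= lo_c) & (age < hi_c))
    ctrl_pool = np.flatnonzero(~disease & (age >= lo_k) & (age < hi_k))
    if len(case_pool) < profile.n_cases:
        raise SimulationError(
            f"only {len(case_pool)} eligible cases for a quota of "
            f"{profile.n_cases}; increase the source population size"
        )
    if len(ctrl_pool) < profile.n_controls:
        raise SimulationError(
            f"only {len(ctrl_pool)} eligible controls for a quota of "
            f"{profile.n_controls}; increase the source population size"
        )
    cases = np.sort(rng.choice(case_pool, size=profile.n_cases, replace=False))
    ctrls = np.sort(rng.choice(ctrl_pool, size=profile.n_controls, replace=False))

    idx = np.concatenate([cases, ctrls])
    cohort = pd.concat(
        [phenotypes.iloc[idx].reset_index(drop=True),
         dosages.iloc[idx].reset_index(drop=True)],
        axis=1,
    )
    cohort.insert(0, "status", np.r_[np.ones(len(cases), dtype=int),
                                     np.zeros(len(ctrls), dtype=int)])
    cohort.insert(0, "id", [f"P{i:06d}" for i in range(1, len(idx) + 1)])
    dose_cols = [c for c in cohort.columns if c.startswith("dose_")]
    return cohort[COHORT_COLUMNS + dose_cols]


def study_like_effects(
    manifest: WeightsManifest,
    traditional_log_or: Optional[Mapping[str, Mapping[str, float]]] = None,
    coupling_log_or: float = 0.9,
    snp_scale: float = 1.0,
) -> TrueEffects:
    """Ground truth emulating the analysis's working model.

    Per-SNP log ORs are taken from the manifest's overall odds ratios
    (scaled by ``snp_scale``), traditional-factor effects from the supplied
    (or packaged example) weights, and every MC1R variant carries the same
    phenotype-coupling log-OR so pigmentation effects are partially mediated
    by observable phenotype.
    """
    from .scoring import EXAMPLE_TRADITIONAL_LOG_OR  # deferred: avoid cycle

    tab = manifest.table
    snp_log_or = {
        row["snp_id"]: snp_scale * float(np.log(row["or_overall"]))
        for _, row in tab.iterrows()
    }
    pheno = {
        f: dict(levels)
        for f, levels in (traditional_log_or or EXAMPLE_TRADITIONAL_LOG_OR).items()
    }
    coupling = {
        snp: {t: coupling_log_or for t in _COUPLED_TRAITS}
        for snp in manifest.mc1r_snps
    }
    return TrueEffects(
        snp_log_or=snp_log_or, pheno_log_or=pheno, mc1r_pheno_coupling=coupling
    )


def complete_cases(cohort: pd.DataFrame) -> pd.DataFrame:
    """Drop rows with any missing value (the analysis is complete-case)."""
    return cohort.dropna(axis=0, how="any").reset_index(drop=True)


def _config_hash(config: Mapping) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _effects_from_config(cfg: Mapping, manifest: WeightsManifest) -> TrueEffects:
    spec = cfg.get("effects", "null")
    if spec == "null":
        return TrueEffects.null()
    if spec == "study_like":
        return study_like_effects(
            manifest,
            coupling_log_or=float(cfg.get("coupling_log_or", 0.9)),
            snp_scale=float(cfg.get("snp_scale", 1.0)),
        )
    if isinstance(spec, Mapping):
        return TrueEffects(
            snp_log_or={k: float(v) for k, v in spec.get("snp_log_or", {}).items()},
            pheno_log_or={
                f: {lv: float(v) for lv, v in levels.items()}
                for f, levels in spec.get("pheno_log_or", {}).items()
            },
            mc1r_pheno_coupling={
                s: {t: float(v) for t, v in traits.items()}
                for s, traits in spec.get("mc1r_pheno_coupling", {}).items()
            },
        )
    raise ConfigurationError(f"unrecognised effects specification: {spec!r}")


def generate_study(
    config: Union[str, Path, Mapping],
    seed: int,
    out_dir: Optional[Union[str, Path]] = None,
) -> Tuple[pd.DataFrame, Dict]:
    """Generate a full case-control cohort from a flat configuration.

    Recognised configuration keys: ``profile`` (``australia`` / ``leeds`` or
    a mapping of :class:`~melanoprs.profiles.StudyProfile` fields),
    ``source_n`` (source population size), ``weights`` (manifest TSV path or
    ``default``), ``effects`` (``null``, ``study_like`` or explicit
    mappings), ``coupling_log_or``, ``snp_scale``, ``missingness_rate``,
    ``category_freqs``.

    Returns the cohort table and a provenance/truth sidecar dict; when
    ``out_dir`` is given also writes ``cohort.csv`` and ``truth.json``.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            cfg = yaml.safe_load(fh)
        if not isinstance(cfg, dict):
            raise ConfigurationError(f"config {config} did not parse to a mapping")
    else:
        cfg = dict(config)

    prof_spec = cfg.get("profile", "australia")
    if isinstance(prof_spec, str):
        profile = get_profile(prof_spec)
    else:
        profile = StudyProfile(**{
            k: (tuple(v) if k.startswith(("age_range", "centers")) else v)
            for k, v in prof_spec.items()
        })

    weights = cfg.get("weights", "default")
    if weights == "default":
        manifest = default_manifest()
    else:
        if not Path(weights).exists():
            raise ConfigurationError(f"weights manifest not found: {weights}")
        manifest = read_manifest(weights)

    source_n = int(cfg.get("source_n", 150_000))
    effects = _effects_from_config(cfg, manifest)

    # Independent child seeds per stage, derived deterministically.
    ss = np.random.SeedSequence(seed).spawn(4)
    child = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    dosages = simulate_genotypes(source_n, manifest, seed=child[0])
    phenotypes = simulate_phenotypes(
        dosages, effects, profile, seed=child[1],
        category_freqs=cfg.get("category_freqs"),
    )
    cohort = simulate_outcome(dosages, phenotypes, effects, profile, seed=child[2])

    miss = float(cfg.get("missingness_rate", 0.0))
    if miss > 0:
        rng = np.random.default_rng(child[3])
        pheno_cols = [c for c in COHORT_COLUMNS if c not in ("id", "status")]
        mask = rng.random((len(cohort), len(pheno_cols))) < miss
        block = cohort[pheno_cols].to_numpy(dtype=object)
        block[mask] = np.nan
        cohort[pheno_cols] = block

    truth = {
        "seed": int(seed),
        "config_hash": _config_hash(cfg),
        "profile": profile.name,
        "n_cases": profile.n_cases,
        "n_controls": profile.n_controls,
        "effects": {
            "snp_log_or": effects.snp_log_or,
            "pheno_log_or": effects.pheno_log_or,
            "mc1r_pheno_coupling": effects.mc1r_pheno_coupling,
        },
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        cohort.to_csv(out_dir / "cohort.csv", index=False)
        with open(out_dir / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)
    return cohort, truth
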