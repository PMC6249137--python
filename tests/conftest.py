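import numpy as np
import pandas as pd
import pytest

import melanoprs as m
from melanoprs.manifest import WeightsManifest


def make_manifest(rows):
    """Build a WeightsManifest from plain dicts (pathways as iterables)."""
    recs = []
    for r in rows:
        rec = dict(
            snp_id=r["snp_id"],
            gene=r.get("gene", "GENE"),
            effect_allele=r.get("effect_allele", "A"),
            eaf=r.get("eaf", 0.3),
            or_overall=r.get("or_overall", 1.5),
            or_sun_sensitive=r.get("or_sun_sensitive", np.nan),
            or_not_sensitive=r.get("or_not_sensitive", np.nan),
            is_mc1r=r.get("is_mc1r", False),
            pathways=frozenset(r.get("pathways", ("pigmentation",))),
        )
        recs.append(rec)
    return WeightsManifest(pd.DataFrame(recs))


@pytest.fixture(scope="session")
def default_man():
    return m.default_manifest()


@pytest.fixture(scope="session")
def mini_profile():
    return m.StudyProfile(
        name="mini",
        n_cases=150,
        n_controls=150,
        age_range_cases=(18.0, 40.0),
        age_range_controls=(18.0, 45.0),
        baseline_prevalence=0.05,
    )


@pytest.fixture(scope="session")
def study_cohort(default_man, mini_profile):
    """Small cohort under the study-like configuration (strong MC1R effects)."""
    effects = m.study_like_effects(default_man)
    dosages = m.simulate_genotypes(12_000, default_man, seed=11)
    phenos = m.simulate_phenotypes(dosages, effects, mini_profile, seed=12)
    return m.simulate_outcome(dosages, phenos, effects, mini_profile, seed=13)


@pytest.fixture(scope="session")
def null_cohort(default_man, mini_profile):
    """Cohort generated under all-null effects."""
    effects = m.TrueEffects.null()
    dosages = m.simulate_genotypes(8_000, default_man, seed=21)
    phenos = m.simulate_phenotypes(dosages, effects, mini_profile, seed=22)
    return m.simulate_outcome(dosages, phenos, effects, mini_profile, seed=23)
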