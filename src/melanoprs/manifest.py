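"""External per-SNP weight manifests for polygenic score construction.

A weights manifest lists, for every variant entering the polygenic risk
score: the effect allele and its frequency, the per-allele odds ratio from
external (meta-analytic) sources, optional phenotype-stratified odds ratios
for MC1R variants (whose melanoma association is modified by sun-sensitive
phenotype), and the biological pathway(s) the host gene acts through.

The on-disk format is a TSV with columns::

    snp_id  gene  effect_allele  eaf  or_overall  or_sun_sensitive
    or_not_sensitive  is_mc1r  pathways

``pathways`` is a comma-joined subset of {pigmentation, nevus,
telomere_senescence_other}; absent stratified ORs are written ``NA``.

The packaged default manifest (:func:`default_manifest`) is a *skeleton* of
the canonical 45-SNP / 21-gene melanoma variant set: variant identifiers for
31 SNPs are the well-known melanoma GWAS hits, the remaining 14 (prefixed
``syn_``) and three genes are synthetic placeholders, and every allele
frequency and odds ratio in the file is a synthetic, merely plausible value.
It exists so that the pathway bookkeeping (pigmentation 14 genes / 31 SNPs,
nevus 7 / 13, telomere-senescence-other 5 / 9, with overlap) can be
exercised end-to-end; real analyses must supply their own weights.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import FrozenSet, Iterable, Optional, Union

import numpy as np
import pandas as pd

__all__ = [
    "PATHWAYS",
    "WeightsManifest",
    "ManifestError",
    "read_manifest",
    "default_manifest",
]

#: Recognised biological pathway labels.
PATHWAYS = ("pigmentation", "nevus", "telomere_senescence_other")

_REQUIRED_COLUMNS = [
    "snp_id",
    "gene",
    "effect_allele",
    "eaf",
    "or_overall",
    "or_sun_sensitive",
    "or_not_sensitive",
    "is_mc1r",
    "pathways",
]

# Expected counts for the default 45-SNP skeleton.
_DEFAULT_N_SNPS = 45
_DEFAULT_N_GENES = 21
_DEFAULT_PATHWAY_SNPS = {
    "pigmentation": 31,
    "nevus": 13,
    "telomere_senescence_other": 9,
}


class ManifestError(ValueError):
    """A weights manifest failed validation."""


@dataclass(frozen=True)
class WeightsManifest:
    """Validated table of per-SNP external weights.

    ``table`` has one row per SNP with the columns listed in the module
    docstring; ``pathways`` is held as a frozenset per row.
    """

    table: pd.DataFrame
    is_default_skeleton: bool = False

    def __post_init__(self) -> None:
        _validate(self.table)
        if self.is_default_skeleton:
            _validate_default_counts(self.table)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> list:
        return list(self.table["snp_id"])

    @property
    def genes(self) -> list:
        return sorted(self.table["gene"].unique())

    @property
    def mc1r_snps(self) -> list:
        return list(self.table.loc[self.table["is_mc1r"], "snp_id"])

    def pathway_snps(self, pathway: str) -> list:
        """SNP ids whose pathway set contains ``pathway``."""
        if pathway not in PATHWAYS:
            raise ManifestError(
                f"unknown pathway {pathway!r}; allowed: {PATHWAYS}"
            )
        mask = self.table["pathways"].map(lambda s: pathway in s)
        return list(self.table.loc[mask, "snp_id"])

    def subset(self, snp_ids: Iterable[str]) -> "WeightsManifest":
        """Manifest restricted to the given SNPs (order preserved)."""
        wanted = set(snp_ids)
        missing = wanted - set(self.table["snp_id"])
        if missing:
            raise ManifestError(f"SNPs not in manifest: {sorted(missing)}")
        sub = self.table[self.table["snp_id"].isin(wanted)].reset_index(drop=True)
        return WeightsManifest(sub)

    def write(self, path: Union[str, Path]) -> None:
        out = self.table.copy()
        out["pathways"] = out["pathways"].map(lambda s: ",".join(sorted(s)))
        out["is_mc1r"] = out["is_mc1r"].map(lambda b: "true" if b else "false")
        out.to_csv(path, sep="\t", index=False, na_rep="NA")


def _validate(table: pd.DataFrame) -> None:
    missing_cols = [c for c in _REQUIRED_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ManifestError(f"manifest missing columns: {missing_cols}")
    dup = table["snp_id"][table["snp_id"].duplicated()]
    if len(dup):
        raise ManifestError(f"duplicate snp_id: {sorted(dup.unique())}")
    for i, row in table.iterrows():
        where = f"row {i} (snp_id={row['snp_id']!r})"
        if not 0.0 <= row["eaf"] <= 1.0:
            raise ManifestError(f"{where}: eaf={row['eaf']} outside [0, 1]")
        if not row["or_overall"] > 0:
            raise ManifestError(
                f"{where}: or_overall={row['or_overall']} must be > 0"
            )
        for col in ("or_sun_sensitive", "or_not_sensitive"):
            val = row[col]
            if pd.notna(val) and not val > 0:
                raise ManifestError(f"{where}: {col}={val} must be > 0")
        if row["is_mc1r"]:
            if pd.isna(row["or_sun_sensitive"]) or pd.isna(row["or_not_sensitive"]):
                raise ManifestError(
                    f"{where}: MC1R rows require both stratified ORs"
                )
        pw = row["pathways"]
        if not isinstance(pw, frozenset) or not pw:
            raise ManifestError(f"{where}: empty pathway set")
        bad = pw - set(PATHWAYS)
        if bad:
            raise ManifestError(
                f"{where}: unknown pathways {sorted(bad)}; allowed: {PATHWAYS}"
            )


def _validate_default_counts(table: pd.DataFrame) -> None:
    n_snps, n_genes = len(table), table["gene"].nunique()
    if n_snps != _DEFAULT_N_SNPS or n_genes != _DEFAULT_N_GENES:
        raise ManifestError(
            f"default skeleton must have {_DEFAULT_N_SNPS} SNPs in "
            f"{_DEFAULT_N_GENES} genes, found {n_snps} in {n_genes}"
        )
    for pathway, expected in _DEFAULT_PATHWAY_SNPS.items():
        count = int(table["pathways"].map(lambda s: pathway in s).sum())
        if count != expected:
            raise ManifestError(
                f"default skeleton: pathway {pathway!r} has {count} SNPs, "
                f"expected {expected}"
            )


def _parse_pathways(raw: str) -> FrozenSet[str]:
    return frozenset(p.strip() for p in str(raw).split(",") if p.strip())


def _parse_bool(raw) -> bool:
    if isinstance(raw, (bool, np.bool_)):
        return bool(raw)
    return str(raw).strip().lower() in ("true", "1", "yes")


def read_manifest(
    path: Union[str, Path], default_skeleton: bool = False
) -> WeightsManifest:
    """Read and validate a weights manifest TSV.

    Parameters
    ----------
    path:
        Path to the TSV file.
    default_skeleton:
        If true, additionally enforce the 45-SNP / 21-gene skeleton counts
        (pigmentation 31, nevus 13, telomere-senescence-other 9 SNPs).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"weights manifest not found: {path}")
    raw = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "gene": str})
    missing_cols = [c for c in _REQUIRED_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise ManifestError(f"manifest {path} missing columns: {missing_cols}")
    raw = raw[_REQUIRED_COLUMNS].copy()
    raw["pathways"] = raw["pathways"].map(_parse_pathways)
    raw["is_mc1r"] = raw["is_mc1r"].map(_parse_bool)
    for col in ("eaf", "or_overall", "or_sun_sensitive", "or_not_sensitive"):
        raw[col] = pd.to_numeric(raw[col], errors="coerce")
    return WeightsManifest(raw, is_default_skeleton=default_skeleton)


def default_manifest() -> WeightsManifest:
    """The packaged 45-SNP / 21-gene skeleton manifest with synthetic weights."""
    resource = importlib.resources.files("melanoprs.data").joinpath(
        "synthetic_default_weights.tsv"
    )
    with importlib.resources.as_file(resource) as path:
        return read_manifest(path, default_skeleton=True)


def log_weights(
    manifest: WeightsManifest, column: str = "or_overall"
) -> pd.Series:
    """Per-SNP log odds ratios, indexed by snp_id."""
    tab = manifest.table
    return pd.Series(
        np.log(tab[column].to_numpy(dtype=float)), index=tab["snp_id"]
    )
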