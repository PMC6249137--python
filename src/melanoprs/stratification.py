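"""Tertile assignment and polygenic-versus-traditional cross-tabulation.

Categorising both the polygenic and the traditional risk score into
tertiles (low / average / high) and cross-tabulating them shows how far
genomic risk is concordant with phenotypic risk: the diagonal fraction is
the concordance, the (low traditional, high polygenic) cell identifies
people genetically susceptible despite lacking a visible risk phenotype,
and the (high traditional, low polygenic) cell the converse.

The packaged reference cross-tabulations
(:func:`reference_crosstab`) hold the printed 3x3 counts from the two
population-based melanoma case-control studies (Australia and Leeds), for
worked examples and checks of the cell arithmetic.
"""

from __future__ import annotations

import importlib.resources
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "StratificationError",
    "CrossTab3x3",
    "assign_tertiles",
    "cross_tab",
    "concordance",
    "discordant_cells",
    "reference_crosstab",
]


class StratificationError(ValueError):
    """Tertile assignment or cross-tabulation failed."""


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class CrossTab3x3:
    """3x3 cross-tabulation of traditional (rows) by polygenic (columns) tertile.

    ``counts`` is a 3x3 integer array; ``row_pct`` holds full-precision row
    percentages (display rounding is half-up to whole percent).
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=int)
        if arr.shape != (3, 3) or np.any(arr < 0):
            raise StratificationError("counts must be a non-negative 3x3 table")
        object.__setattr__(self, "counts", arr)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def row_pct(self) -> np.ndarray:
        totals = self.row_totals.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return 100.0 * self.counts / totals[:, None]

    def row_pct_display(self) -> np.ndarray:
        """Row percentages rounded half-up to whole percent."""
        return np.vectorize(_round_half_up)(self.row_pct)

    def to_dict(self) -> Dict:
        return {
            "counts": self.counts.tolist(),
            "row_pct": self.row_pct.tolist(),
            "n": self.n,
        }

    @classmethod
    def from_dict(cls, d: Dict) -> "CrossTab3x3":
        return cls(np.asarray(d["counts"], dtype=int))

    def to_tsv(self, path: Union[str, Path]) -> None:
        """Write the table with counts and (rounded) row percentages."""
        pct = self.row_pct_display()
        lines = ["\ttertile_1\ttertile_2\ttertile_3\ttotal"]
        for i in range(3):
            cells = "\t".join(
                f"{self.counts[i, j]} ({pct[i, j]})" for j in range(3)
            )
            lines.append(f"tertile_{i + 1}\t{cells}\t{self.row_totals[i]} (100)")
        lines.append(
            "total\t" + "\t".join(str(c) for c in self.col_totals)
            + f"\t{self.n}"
        )
        Path(path).write_text("\n".join(lines) + "\n")


def assign_tertiles(score: Sequence[float]) -> np.ndarray:
    """Assign 1/2/3 tertile categories at the 1/3 and 2/3 sample quantiles.

    Intervals are half-open with boundary values going to the upper
    category; with distinct values the category sizes are equal thirds up
    to rounding. Massive ties that empty a tertile raise.
    """
    s = np.asarray(score, dtype=float)
    if len(s) < 3:
        raise StratificationError("need at least 3 observations for tertiles")
    if not np.all(np.isfinite(s)):
        raise StratificationError("score contains non-finite values")
    cuts = np.quantile(s, [1 / 3, 2 / 3])
    cat = 1 + np.searchsorted(cuts, s, side="right")
    counts = np.bincount(cat, minlength=4)[1:]
    if np.any(counts == 0):
        raise StratificationError(
            f"tertile {int(np.argmin(counts)) + 1} is empty: ties collapse the "
            f"cutpoints {cuts.tolist()}"
        )
    return cat


def cross_tab(trad_t: Sequence[int], prs_t: Sequence[int]) -> CrossTab3x3:
    """Cross-tabulate traditional (rows) by polygenic (columns) tertiles."""
    a = np.asarray(trad_t, dtype=int)
    b = np.asarray(prs_t, dtype=int)
    if len(a) != len(b):
        raise StratificationError("tertile vectors differ in length")
    for name, v in (("traditional", a), ("polygenic", b)):
        if not np.all(np.isin(v, [1, 2, 3])):
            raise StratificationError(f"{name} tertiles must be coded 1/2/3")
    counts = np.zeros((3, 3), dtype=int)
    for i, j in zip(a, b):
        counts[i - 1, j - 1] += 1
    return CrossTab3x3(counts)


def concordance(ct: CrossTab3x3) -> float:
    """Fraction of participants on the diagonal (same tertile under both)."""
    if ct.n == 0:
        raise StratificationError("empty cross-tabulation")
    return float(np.trace(ct.counts) / ct.n)


def discordant_cells(ct: CrossTab3x3) -> Dict[str, float]:
    """Row proportions of the two extreme discordant cells.

    ``low_trad_high_prs``: of participants in the lowest traditional
    tertile, the fraction in the highest polygenic tertile;
    ``high_trad_low_prs``: the converse.
    """
    r1, r3 = ct.row_totals[0], ct.row_totals[2]
    if r1 == 0 or r3 == 0:
        raise StratificationError("empty extreme row in cross-tabulation")
    return {
        "low_trad_high_prs": float(ct.counts[0, 2] / r1),
        "high_trad_low_prs": float(ct.counts[2, 0] / r3),
    }


def reference_crosstab(study: str) -> CrossTab3x3:
    """Printed cross-tabulation counts for ``australia`` or ``leeds``."""
    resource = importlib.resources.files("melanoprs.data").joinpath(
        "reference_crosstabs.json"
    )
    data = json.loads(resource.read_text())
    key = study.lower()
    if key not in ("australia", "leeds"):
        raise StratificationError(
            f"unknown study {study!r}; available: australia, leeds"
        )
    return CrossTab3x3(np.asarray(data[key]["counts"], dtype=int))
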