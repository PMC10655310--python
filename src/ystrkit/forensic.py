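"""Forensic summary statistics for Y-STR haplotype tables.

All quantities reduce to the *class spectrum*: the multiset of haplotype
class sizes at a panel (how many haplotypes were seen once, twice, three
times...).  From a spectrum with class frequencies p_i = size_i / n:

* random matching probability  RMP = sum p_i^2
* haplotype diversity          HD  = n/(n-1) * (1 - sum p_i^2)
* discrimination capacity      DC  = (number of distinct haplotypes) / n

Gene diversity applies the HD formula to single-locus allele frequencies.
Display helpers follow the field's table conventions: 4 decimals for
RMP/HD, percentages truncated (not rounded) to 2 decimals.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import HaplotypeTable, LocusDef, PanelDef, project_panel

__all__ = [
    "ClassSpectrum",
    "class_spectrum",
    "haplotype_diversity",
    "haplotype_diversity_se",
    "match_probability",
    "discrimination_capacity",
    "allele_frequencies",
    "gene_diversity",
    "forensic_summary",
    "format_summary",
]


class DiversityUndefinedError(ValueError):
    """Diversity statistics need at least two sampled individuals."""


@dataclass(frozen=True)
class ClassSpectrum:
    """Multiset of haplotype class sizes: ``counts[size] = number of classes``.

    Sufficient statistic for HD, RMP and DC.  Example: 282 men falling into
    242 singletons, 14 pairs and 4 trios is ``ClassSpectrum(282, {1: 242,
    2: 14, 3: 4})``.
    """

    n: int
    counts: Mapping[int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", dict(self.counts))
        if any(s < 1 or c < 1 for s, c in self.counts.items()):
            raise ValueError("class sizes and multiplicities must be >= 1")
        total = sum(s * c for s, c in self.counts.items())
        if total != self.n:
            raise ValueError(
                f"spectrum sums to {total} individuals, declared n={self.n}"
            )

    @property
    def total_haplotypes(self) -> int:
        return sum(self.counts.values())

    @property
    def singletons(self) -> int:
        return self.counts.get(1, 0)

    @property
    def pairs(self) -> int:
        return self.counts.get(2, 0)

    @property
    def trios(self) -> int:
        return self.counts.get(3, 0)

    def sum_p2(self) -> float:
        # exact integer numerator, single division
        return sum(c * s * s for s, c in self.counts.items()) / (self.n * self.n)

    def sum_p3(self) -> float:
        return sum(c * s ** 3 for s, c in self.counts.items()) / self.n ** 3


def class_spectrum(table: HaplotypeTable) -> ClassSpectrum:
    """Group samples by exact haplotype identity and return the spectrum."""
    if table.n == 0:
        raise ValueError("empty haplotype table")
    sizes = Counter(table.haplotype_keys())
    spectrum = Counter(sizes.values())
    return ClassSpectrum(table.n, dict(spectrum))


def match_probability(s: ClassSpectrum) -> float:
    """Random matching probability: the chance two random men share a
    haplotype, ``sum p_i^2``."""
    return s.sum_p2()


def haplotype_diversity(s: ClassSpectrum) -> float:
    """Unbiased haplotype diversity ``n/(n-1) * (1 - sum p_i^2)``."""
    if s.n < 2:
        raise DiversityUndefinedError("haplotype diversity needs n >= 2")
    n = s.n
    ssq = sum(c * sz * sz for sz, c in s.counts.items())
    # single division keeps exact cases (all singletons -> 1) exact
    return (n * n - ssq) / (n * (n - 1))


def haplotype_diversity_se(s: ClassSpectrum) -> float:
    """Sampling standard error of haplotype diversity (Nei-style estimator).

    V(HD) = 2/(n(n-1)) * [ 2(n-2)(sum p^3 - (sum p^2)^2)
                           + sum p^2 - (sum p^2)^2 ].
    """
    if s.n < 2:
        raise DiversityUndefinedError("diversity variance needs n >= 2")
    n, p2, p3 = s.n, s.sum_p2(), s.sum_p3()
    var = 2.0 / (n * (n - 1)) * (2.0 * (n - 2) * (p3 - p2 * p2) + p2 - p2 * p2)
    return math.sqrt(max(var, 0.0))


def discrimination_capacity(s: ClassSpectrum) -> float:
    """Distinct haplotypes divided by sample size."""
    return s.total_haplotypes / s.n


def allele_frequencies(table: HaplotypeTable, locus: str | LocusDef) -> pd.Series:
    """Relative allele (or DYS385 pair-combination) frequencies at a locus,
    by direct counting over samples."""
    name = locus.name if isinstance(locus, LocusDef) else locus
    if name not in table.loci:
        raise KeyError(f"locus {name!r} not in panel {table.panel.name}")
    counts = Counter(table.data[name])
    freqs = pd.Series(counts, dtype=float).sort_index() / table.n
    freqs.name = name
    return freqs


def gene_diversity(freqs: Iterable[float], n: int) -> float:
    """Single-locus diversity ``n/(n-1) * (1 - sum f_a^2)``."""
    if n < 2:
        raise DiversityUndefinedError("gene diversity needs n >= 2")
    f = np.asarray(list(freqs), dtype=float)
    return n / (n - 1) * (1.0 - float(np.sum(f * f)))


_SUMMARY_ROWS = ["RMP", "HD", "HD_se", "TH", "UH", "PH", "tH", "DC", "UH_pct"]


def forensic_summary(
    table: HaplotypeTable, panels: Sequence[PanelDef]
) -> pd.DataFrame:
    """One column per panel with the full forensic parameter set.

    Rows: RMP, HD, HD_se, total/unique/pair/trio haplotype counts, DC and
    the fraction of individuals carrying a unique haplotype.  Values are
    unrounded; see :func:`format_summary` for table-style printing.
    """
    out = {}
    for panel in panels:
        sub = project_panel(table, panel)
        s = class_spectrum(sub)
        out[panel.name] = {
            "RMP": match_probability(s),
            "HD": haplotype_diversity(s),
            "HD_se": haplotype_diversity_se(s),
            "TH": s.total_haplotypes,
            "UH": s.singletons,
            "PH": s.pairs,
            "tH": s.trios,
            "DC": discrimination_capacity(s),
            "UH_pct": s.singletons / s.n,
        }
    return pd.DataFrame(out).reindex(_SUMMARY_ROWS)


def _truncate_pct(x: float) -> str:
    # Table convention: percentages are truncated, not rounded, to 2 dp.
    return f"{math.floor(x * 10000 + 1e-9) / 100:.2f}%"


def format_summary(summary: pd.DataFrame) -> pd.DataFrame:
    """Render a :func:`forensic_summary` frame with display conventions:
    RMP/HD rounded to 4 decimals, percentages truncated to 2."""
    disp = pd.DataFrame(index=summary.index, columns=summary.columns, dtype=object)
    for col in summary.columns:
        disp.at["RMP", col] = f"{summary.at['RMP', col]:.4f}"
        disp.at["HD", col] = (
            f"{summary.at['HD', col]:.4f} ± {summary.at['HD_se', col]:.4f}"
        )
        for row in ("TH", "UH", "PH", "tH"):
            disp.at[row, col] = str(int(summary.at[row, col]))
        disp.at["DC", col] = _truncate_pct(summary.at["DC", col])
        disp.at["UH_pct", col] = _truncate_pct(summary.at["UH_pct", col])
    return disp.drop(index="HD_se")
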