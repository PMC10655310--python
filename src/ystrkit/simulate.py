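"""Synthetic cohorts with the statistical structure the pipeline assumes.

Three generators stand in for a sampled male cohort:

* :func:`table_from_spectrum` inverts a haplotype class spectrum — e.g.
  242 singletons, 14 pairs and 4 trios among 282 men — into a concrete
  haplotype table whose grouping reproduces that spectrum exactly.
* :func:`island_model_haplogroups` draws per-population haplogroup
  frequencies from a Balding-Nichols island model: Dirichlet with
  parameters p_k * (1 - theta) / theta around ancestral frequencies, so
  the expected differentiation among islands is Fst = theta.
* :func:`smm_populations` evolves Y-STR repeat counts under the stepwise
  mutation model: each lineage accumulates a Poisson number of +/-1 repeat
  steps per locus, populations diverging independently from a shared
  ancestor for a configurable number of generations, with 50 generations
  of within-population history giving realistic internal diversity.

Defaults are fixed study-like conditions: ancestral haplogroup profile
matching the cohort's observed major clades (O-dominated East Asian
profile), Y-STR mutation rate 2e-3 per locus per generation, ancestral
repeat sizes near each locus's modal allele.  All draws flow through one
numpy Generator, so identical seed + configuration reproduce output
bit-for-bit.
"""

from __future__ import annotations

import itertools
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .forensic import ClassSpectrum
from .io import BUILTIN_PANELS, HaplotypeTable, PanelDef, LocusDef

__all__ = [
    "ANCESTRAL_HAPLOGROUP_FREQS",
    "ANCESTRAL_REPEATS",
    "table_from_spectrum",
    "island_model_haplogroups",
    "smm_populations",
    "star_expansion_table",
]

#: Ancestral haplogroup profile used by the island model: the observed
#: major-clade frequencies of an O-dominated East Asian cohort.
ANCESTRAL_HAPLOGROUP_FREQS: Mapping[str, float] = {
    "O": 0.57,
    "J": 0.0886,
    "C": 0.0851,
    "Q": 0.0815,
    "D": 0.0531,
    "N": 0.05,
    "R": 0.04,
    "other": 0.0317,
}

#: Modal-allele-like ancestral repeat counts per locus.
ANCESTRAL_REPEATS: Mapping[str, int] = {
    "DYS19": 15, "DYS389I": 13, "DYS389II": 29, "DYS390": 24, "DYS391": 10,
    "DYS392": 13, "DYS393": 12, "DYS438": 10, "DYS439": 12, "DYS437": 14,
    "DYS448": 19, "DYS456": 15, "DYS458": 16, "DYS635": 21, "GATA_H4": 12,
    "DYS481": 22, "DYS533": 11, "DYS549": 12, "DYS570": 17, "DYS576": 17,
    "DYS643": 10, "DYS388": 12, "DYS460": 10, "DYS449": 30,
}

_DYS385_BASE = (11, 14)

#: Canonical per-locus Y-STR mutation rate (per generation).
DEFAULT_MUTATION_RATE = 2e-3
#: Within-population history (generations) giving internal diversity.
DEFAULT_WITHIN_GENERATIONS = 50


def _rng(seed, rng):
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


def _base_vector(panel: PanelDef) -> dict[str, str]:
    cells = {}
    for locus in panel.loci:
        if locus.multi_copy:
            cells[locus.name] = f"{_DYS385_BASE[0]}-{_DYS385_BASE[1]}"
        else:
            cells[locus.name] = str(ANCESTRAL_REPEATS.get(locus.name, 14))
    return cells


def _offset_vectors(panel: PanelDef, count: int):
    """Distinct haplotypes: mixed-radix offsets (0-3 repeats) added to the
    base allele of each single-copy locus, keeping alleles in 7-30."""
    single = panel.single_copy_names()
    if not single:
        raise ValueError("panel needs at least one single-copy locus")
    if count > 4 ** len(single):
        raise ValueError(
            f"cannot build {count} distinct classes on panel {panel.name}"
        )
    base = _base_vector(panel)
    out = []
    for k in range(count):
        cells = dict(base)
        v = k
        for locus in single:
            cells[locus] = str(int(base[locus]) + v % 4)
            v //= 4
        out.append(cells)
    return out


def table_from_spectrum(
    spectrum: ClassSpectrum,
    panel: PanelDef | str = "GE26",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    population: str = "SimPop",
) -> HaplotypeTable:
    """Build a haplotype table whose class spectrum equals *spectrum* exactly.

    Distinct haplotype classes differ at >= 1 locus by construction;
    sample order is shuffled so class structure is not positional.
    """
    if isinstance(panel, str):
        panel = BUILTIN_PANELS[panel]
    gen = _rng(seed, rng)
    reps = _offset_vectors(panel, spectrum.total_haplotypes)
    rows = []
    class_idx = 0
    for size in sorted(spectrum.counts):
        for _ in range(spectrum.counts[size]):
            rows.extend([reps[class_idx]] * size)
            class_idx += 1
    order = gen.permutation(len(rows))
    data = pd.DataFrame([rows[i] for i in order])
    data.insert(0, "Population", population)
    data.index = [f"S{i+1:04d}" for i in range(len(rows))]
    data.index.name = "SampleID"
    return HaplotypeTable(data, panel)


def island_model_haplogroups(
    n_populations: int = 4,
    n: int = 100,
    theta: float = 0.05,
    ancestral_freqs: Mapping[str, float] = ANCESTRAL_HAPLOGROUP_FREQS,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, list[str]]:
    """Haplogroup assignments per island under the Balding-Nichols model.

    Island frequencies are Dirichlet(p_k (1-theta)/theta); individuals are
    drawn from their island's frequencies, so pairwise Fst estimates
    should scatter around theta.
    """
    if not 0 < theta < 1:
        raise ValueError("theta must lie in (0, 1)")
    p = np.array(list(ancestral_freqs.values()), dtype=float)
    if np.any(p <= 0) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("ancestral frequencies must be positive and sum to 1")
    labels = list(ancestral_freqs)
    gen = _rng(seed, rng)
    alpha = p * (1.0 - theta) / theta
    out = {}
    for k in range(n_populations):
        f = gen.dirichlet(alpha)
        draws = gen.choice(len(labels), size=n, p=f)
        out[f"Pop{k+1}"] = [labels[i] for i in draws]
    return out


def _smm_steps(rng, rate: float, generations: float, shape) -> np.ndarray:
    """Net repeat displacement: Poisson mutation count, each step +/-1."""
    hits = rng.poisson(rate * generations, size=shape)
    flat = hits.ravel()
    out = np.zeros_like(flat)
    for i, h in enumerate(flat):
        if h:
            out[i] = rng.choice([-1, 1], size=h).sum()
    return out.reshape(shape)


def smm_populations(
    n_populations: int = 2,
    n: int = 50,
    divergence_generations: float = 200.0,
    loci: Sequence[str] | None = None,
    mutation_rate: float = DEFAULT_MUTATION_RATE,
    within_generations: float = DEFAULT_WITHIN_GENERATIONS,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, HaplotypeTable]:
    """Per-population haplotype tables under the stepwise mutation model.

    Each population's founder drifts from the shared ancestral haplotype
    for *divergence_generations*; each individual then accumulates its own
    mutations over *within_generations*.  Zero divergence gives identical
    founders (Rst ~ 0); larger divergence separates populations.
    """
    gen = _rng(seed, rng)
    if loci is None:
        loci = list(BUILTIN_PANELS["GE26"].single_copy_names())
    panel = PanelDef("SMM", tuple(LocusDef(l) for l in loci))
    ancestor = np.array([ANCESTRAL_REPEATS.get(l, 14) for l in loci])
    out = {}
    for k in range(n_populations):
        founder = ancestor + _smm_steps(
            gen, mutation_rate, divergence_generations, (len(loci),)
        )
        alleles = founder + _smm_steps(
            gen, mutation_rate, within_generations, (n, len(loci))
        )
        alleles = np.clip(alleles, 5, None)
        data = pd.DataFrame(
            alleles.astype(int).astype(str), columns=list(loci),
            index=[f"P{k+1}_{i+1:03d}" for i in range(n)],
        )
        data.insert(0, "Population", f"Pop{k+1}")
        data.index.name = "SampleID"
        out[f"Pop{k+1}"] = HaplotypeTable(data, panel)
    return out


def star_expansion_table(
    n_offspring: int = 8,
    founder_multiplicity: int = 5,
    loci: Sequence[str] | None = None,
    population: str = "StarPop",
) -> HaplotypeTable:
    """Founder + single-step derivatives: the star-like expansion pattern.

    Each offspring haplotype differs from the founder by one repeat at one
    locus (distinct locus/direction combinations), the signature of a
    recent population expansion.  Deterministic by construction.
    """
    if loci is None:
        loci = list(BUILTIN_PANELS["GE26"].single_copy_names())
    if n_offspring > 2 * len(loci):
        raise ValueError("at most two single-step offspring per locus")
    panel = PanelDef("SMM", tuple(LocusDef(l) for l in loci))
    founder = [ANCESTRAL_REPEATS.get(l, 14) for l in loci]
    rows = [list(founder) for _ in range(founder_multiplicity)]
    for i in range(n_offspring):
        child = list(founder)
        locus_idx = i % len(loci)
        child[locus_idx] += 1 if i < len(loci) else -1
        rows.append(child)
    data = pd.DataFrame(
        [[str(a) for a in r] for r in rows], columns=list(loci),
        index=[f"S{i+1:03d}" for i in range(len(rows))],
    )
    data.insert(0, "Population", population)
    data.index.name = "SampleID"
    return HaplotypeTable(data, panel)
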