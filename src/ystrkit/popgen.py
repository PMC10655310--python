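"""AMOVA variance decomposition, pairwise Fst/Rst and permutation tests.

The analysis of molecular variance partitions the total sum of squared
pairwise distances among N individuals in P populations:

    SSD_total  = (1/2N) * sum_ij d2(i, j)
    SSD_within = sum_p (1/2n_p) * sum_{i,j in p} d2(i, j)
    SSD_among  = SSD_total - SSD_within

with df_among = P-1, df_within = N-P, sigma2_w = SSD_within/df_within and
sigma2_a = (SSD_among/df_among - sigma2_w) / n_c where
n_c = (N - sum n_p^2 / N) / (P - 1).  Phi_st = sigma2_a / (sigma2_a +
sigma2_w); its significance comes from permuting individuals across
populations.  Negative variance components are reported raw, preserving
the estimator's null distribution for the permutation test.

Fst uses haplogroup (or haplotype) identity distances d2 in {0, 1}; Rst
uses squared allele-size differences summed over shared loci, rescaled for
pairwise-complete missing data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Hashable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import HaplotypeTable

__all__ = [
    "AmovaResult",
    "DistanceMatrix",
    "ZeroVarianceError",
    "amova",
    "pairwise_fst",
    "pairwise_rst",
    "size_vectors",
]


class ZeroVarianceError(ValueError):
    """All pairwise distances are zero; Phi_st is undefined."""


@dataclass(frozen=True)
class AmovaResult:
    ssd_among: float
    ssd_within: float
    df_among: int
    df_within: int
    sigma2_among: float
    sigma2_within: float
    phi_st: float
    p_value: float | None
    permutations: int

    @property
    def ssd_total(self) -> float:
        return self.ssd_among + self.ssd_within


@dataclass
class DistanceMatrix:
    """Labelled symmetric distance matrix with optional p-value companion."""

    labels: list[str]
    values: np.ndarray
    p_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0.0):
            raise ValueError("distance matrix diagonal must be exactly zero")
        self.values = v
        if self.p_values is not None:
            p = np.asarray(self.p_values, dtype=float)
            off = ~np.eye(len(self.labels), dtype=bool)
            if np.any((p[off] < 0) | (p[off] > 1)):
                raise ValueError("p-values must lie in [0, 1]")
            self.p_values = p

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def combined_dataframe(self) -> pd.DataFrame:
        """Distances below the diagonal, p-values above (table convention)."""
        out = self.to_dataframe().copy()
        if self.p_values is not None:
            for i in range(len(self.labels)):
                for j in range(i + 1, len(self.labels)):
                    out.iat[i, j] = self.p_values[i, j]
        return out

    def adjusted_p_values(self) -> np.ndarray:
        """Benjamini-Hochberg adjusted p-values (off by default everywhere;
        provided for users who want FDR control across the pairs)."""
        from scipy.stats import false_discovery_control

        if self.p_values is None:
            raise ValueError("no p-values attached")
        k = len(self.labels)
        iu = np.triu_indices(k, 1)
        adj = false_discovery_control(self.p_values[iu], method="bh")
        out = np.zeros_like(self.p_values)
        out[iu] = adj
        out.T[iu] = adj
        return out


def _components(d2: np.ndarray, groups: Sequence[np.ndarray]):
    """Variance components from a squared-distance matrix and index groups."""
    n = d2.shape[0]
    sizes = np.array([len(g) for g in groups])
    p = len(groups)
    ssd_total = d2.sum() / (2.0 * n)
    ssd_within = sum(d2[np.ix_(g, g)].sum() / (2.0 * len(g)) for g in groups)
    ssd_among = ssd_total - ssd_within
    df_among = p - 1
    df_within = n - p
    sigma2_w = ssd_within / df_within
    n_c = (n - (sizes ** 2).sum() / n) / df_among
    sigma2_a = (ssd_among / df_among - sigma2_w) / n_c
    return ssd_among, ssd_within, df_among, df_within, sigma2_a, sigma2_w


def _phi(sigma2_a: float, sigma2_w: float) -> float:
    denom = sigma2_a + sigma2_w
    if denom == 0.0:
        raise ZeroVarianceError("total variance is zero; Phi_st undefined")
    return sigma2_a / denom


def amova(
    populations: Sequence[Sequence[Hashable]],
    d2: Callable[[Hashable, Hashable], float] | None = None,
    permutations: int = 0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> AmovaResult:
    """One-level AMOVA over individual observations grouped by population.

    *populations* is a list of observation sequences (haplogroup labels,
    size vectors, ...); *d2* maps an observation pair to its squared
    distance (default: 0/1 identity).  With ``permutations > 0`` the
    p-value is the proportion of label permutations whose Phi_st is >= the
    observed one, counting the observed arrangement itself.
    """
    if len(populations) < 2:
        raise ValueError("AMOVA needs at least two populations")
    if any(len(p) < 2 for p in populations):
        raise ValueError("each population needs at least two individuals")
    obs = [x for pop in populations for x in pop]
    n = len(obs)
    if d2 is None:
        d2 = lambda a, b: 0.0 if a == b else 1.0
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = d2(obs[i], obs[j])
    groups, start = [], 0
    for pop in populations:
        groups.append(np.arange(start, start + len(pop)))
        start += len(pop)
    return amova_from_matrix(mat, groups, permutations=permutations,
                             seed=seed, rng=rng)


def amova_from_matrix(
    d2: np.ndarray,
    groups: Sequence[np.ndarray],
    permutations: int = 0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> AmovaResult:
    """AMOVA on a precomputed squared-distance matrix with index groups."""
    ssd_a, ssd_w, df_a, df_w, s2a, s2w = _components(d2, groups)
    phi = _phi(s2a, s2w)
    p_value = None
    if permutations > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        n = d2.shape[0]
        sizes = [len(g) for g in groups]
        count = 1  # the observed arrangement itself
        for _ in range(permutations):
            perm = rng.permutation(n)
            g_perm, start = [], 0
            for s in sizes:
                g_perm.append(perm[start:start + s])
                start += s
            _, _, _, _, pa, pw = _components(d2, g_perm)
            denom = pa + pw
            if denom != 0.0 and pa / denom >= phi:
                count += 1
        p_value = count / (permutations + 1)
    return AmovaResult(ssd_a, ssd_w, df_a, df_w, s2a, s2w, phi,
                       p_value, permutations)


def _pairwise(
    pops: list[str],
    matrices: Callable[[str, str], tuple[np.ndarray, list[np.ndarray]]],
    permutations: int,
    seed: int | None,
) -> DistanceMatrix:
    k = len(pops)
    values = np.zeros((k, k))
    pvals = np.zeros((k, k)) if permutations > 0 else None
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(k * (k - 1) // 2)
    for idx, (i, j) in enumerate(itertools.combinations(range(k), 2)):
        d2, groups = matrices(pops[i], pops[j])
        rng = np.random.default_rng(children[idx])
        res = amova_from_matrix(d2, groups, permutations=permutations, rng=rng)
        values[i, j] = values[j, i] = res.phi_st
        if pvals is not None:
            pvals[i, j] = pvals[j, i] = res.p_value
    return DistanceMatrix(pops, values, pvals)


def pairwise_fst(
    assignments: Mapping[str, Sequence[Hashable]],
    permutations: int = 10000,
    seed: int | None = None,
) -> DistanceMatrix:
    """Pairwise Phi_st under identity distances (haplogroup labels by
    default; pass haplotype keys for an STR-haplotype mode)."""
    pops = list(assignments)
    if len(pops) < 2:
        raise ValueError("need at least two populations")

    def matrices(a: str, b: str):
        xs = list(assignments[a]) + list(assignments[b])
        arr = pd.factorize(pd.Series(xs, dtype=object))[0]
        mat = (arr[:, None] != arr[None, :]).astype(float)
        np.fill_diagonal(mat, 0.0)
        na = len(assignments[a])
        groups = [np.arange(na), np.arange(na, len(xs))]
        return mat, groups

    return _pairwise(pops, matrices, permutations, seed)


def size_vectors(table: HaplotypeTable, loci: Sequence[str]) -> np.ndarray:
    """Samples x loci allele sizes as floats, NaN for null alleles.

    Intermediate alleles are rounded to the nearest repeat (half away from
    zero); nulls are missing, never a numeric code — a sentinel like 99
    would corrupt squared-size distances.
    """
    out = np.full((table.n, len(loci)), np.nan)
    for j, locus in enumerate(loci):
        if table.panel.locus(locus).multi_copy:
            raise ValueError(f"multi-copy locus {locus} cannot enter Rst")
        for i, sample in enumerate(table.sample_ids):
            r = table.call(sample, locus).rounded_repeats()
            if r is not None:
                out[i, j] = float(r)
    return out


def _rst_matrix(x: np.ndarray) -> np.ndarray:
    """Squared size distances with pairwise-complete loci rescaling."""
    n, L = x.shape
    present = ~np.isnan(x)
    filled = np.where(present, x, 0.0)
    mat = np.zeros((n, n))
    for i in range(n):
        both = present[i] & present
        diff = (filled[i] - filled) ** 2
        shared = both.sum(axis=1)
        if np.any(shared == 0):
            bad = int(np.where(shared == 0)[0][0])
            raise ValueError(
                f"samples {i} and {bad} share no typed loci; cannot form Rst"
            )
        mat[i] = (diff * both).sum(axis=1) * (L / shared)
    np.fill_diagonal(mat, 0.0)
    return mat


def pairwise_rst(
    tables: Mapping[str, HaplotypeTable],
    loci: Sequence[str] | None = None,
    permutations: int = 10000,
    seed: int | None = None,
) -> DistanceMatrix:
    """Pairwise Rst: AMOVA Phi_st with squared allele-size distances over
    single-copy loci (DYS385 excluded), missing data handled by
    pairwise-complete rescaling."""
    pops = list(tables)
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    if loci is None:
        first = tables[pops[0]]
        loci = list(first.panel.single_copy_names())
    vecs = {p: size_vectors(t, loci) for p, t in tables.items()}

    def matrices(a: str, b: str):
        x = np.vstack([vecs[a], vecs[b]])
        mat = _rst_matrix(x)
        na = vecs[a].shape[0]
        groups = [np.arange(na), np.arange(na, x.shape[0])]
        return mat, groups

    return _pairwise(pops, matrices, permutations, seed)
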