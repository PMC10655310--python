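"""Y haplogroup assignment from SNP states and haplogroup frequency tables.

A :class:`HaplogroupTree` is a rooted hierarchy of haplogroup labels, each
non-root node carrying one or more defining SNPs with their ancestral and
derived alleles.  Assignment walks the hierarchy: a sample belongs to the
deepest node whose defining SNPs are all derived and whose ancestors are
derived or untyped — mirroring hierarchical genotyping assays, where an
untyped upstream marker is implied by a derived downstream one.  Derived
states on disjoint branches are biologically impossible for the
non-recombining Y and raise a conflict error.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from typing import Mapping, Sequence, TextIO, Union

import pandas as pd

__all__ = [
    "SNPDef",
    "HaplogroupTree",
    "HaplogroupConflictError",
    "Assignment",
    "assign_haplogroup",
    "haplogroup_frequencies",
    "haplogroup_diversity",
]

ANCESTRAL = "ancestral"
DERIVED = "derived"
MISSING = "missing"


class HaplogroupConflictError(ValueError):
    """Derived states imply two incompatible placements in the hierarchy."""


@dataclass(frozen=True)
class SNPDef:
    snp: str
    ancestral: str
    derived: str


@dataclass
class HaplogroupTree:
    """Rooted haplogroup hierarchy with per-node defining SNPs."""

    parent: dict[str, str | None]
    snps: dict[str, list[SNPDef]]

    def __post_init__(self) -> None:
        roots = [n for n, p in self.parent.items() if p is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {roots}")
        for node, p in self.parent.items():
            if p is not None and p not in self.parent:
                raise ValueError(f"node {node!r} has unknown parent {p!r}")
            if p is not None and not self.snps.get(node):
                raise ValueError(f"non-root node {node!r} has no defining SNP")
        # reject cycles / validate depth computability
        for node in self.parent:
            self.depth(node)

    @property
    def root(self) -> str:
        return next(n for n, p in self.parent.items() if p is None)

    def path(self, node: str) -> list[str]:
        """Root-to-node label path."""
        out, cur, seen = [], node, set()
        while cur is not None:
            if cur in seen:
                raise ValueError(f"cycle in tree at {cur!r}")
            seen.add(cur)
            out.append(cur)
            cur = self.parent[cur]
        return out[::-1]

    def depth(self, node: str) -> int:
        return len(self.path(node)) - 1

    def ancestor_at_depth(self, node: str, depth: int) -> str:
        p = self.path(node)
        return p[depth] if depth < len(p) else node

    def is_ancestor(self, anc: str, node: str) -> bool:
        return anc in self.path(node)

    @classmethod
    def from_tsv(cls, source: Union[str, TextIO]) -> "HaplogroupTree":
        """Load from a tab-separated (haplogroup, parent, snp, ancestral,
        derived) table; the root row leaves parent (and SNP fields) empty."""
        if isinstance(source, str) and "\t" not in source and "\n" not in source:
            df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
        else:
            buf = _io.StringIO(source) if isinstance(source, str) else source
            df = pd.read_csv(buf, sep="\t", dtype=str, keep_default_na=False)
        parent: dict[str, str | None] = {}
        snps: dict[str, list[SNPDef]] = {}
        for row in df.itertuples(index=False):
            hg = row.haplogroup.strip()
            par = row.parent.strip() or None
            if hg in parent and parent[hg] != par:
                raise ValueError(f"conflicting parents for {hg!r}")
            parent[hg] = par
            snp = getattr(row, "snp", "").strip()
            if snp:
                snps.setdefault(hg, []).append(
                    SNPDef(snp, row.ancestral.strip(), row.derived.strip())
                )
        return cls(parent, snps)


def _orient(state: str, snp: SNPDef) -> str:
    """Map an observed allele or state keyword onto ancestral/derived."""
    s = state.strip()
    # exact allele match outranks keyword shortcuts: bases A/C/G/T would
    # otherwise collide with the a(ncestral)/d(erived) abbreviations
    if s == snp.ancestral:
        return ANCESTRAL
    if s == snp.derived:
        return DERIVED
    if s.lower() in (ANCESTRAL, "a"):
        return ANCESTRAL
    if s.lower() in (DERIVED, "d"):
        return DERIVED
    if s.lower() in ("", ".", "missing", "nan", "n/a"):
        return MISSING
    raise ValueError(
        f"SNP {snp.snp}: observed {s!r} matches neither ancestral "
        f"{snp.ancestral!r} nor derived {snp.derived!r}"
    )


def _node_status(node: str, calls: Mapping[str, str], tree: HaplogroupTree) -> str:
    states = []
    for snp in tree.snps.get(node, []):
        raw = calls.get(snp.snp)
        if raw is None:
            states.append(MISSING)
        else:
            states.append(_orient(raw, snp))
    typed = [s for s in states if s != MISSING]
    if not typed:
        return MISSING
    if all(s == DERIVED for s in typed):
        return DERIVED
    if all(s == ANCESTRAL for s in typed):
        return ANCESTRAL
    raise HaplogroupConflictError(
        f"defining SNPs of {node!r} disagree (some derived, some ancestral)"
    )


@dataclass(frozen=True)
class Assignment:
    haplogroup: str
    path: tuple[str, ...]


def assign_haplogroup(
    calls: Mapping[str, str], tree: HaplogroupTree
) -> Assignment:
    """Assign the deepest haplogroup consistent with the observed SNP states.

    *calls* maps SNP id to an observed allele (oriented against the tree's
    ancestral/derived definitions) or to the keywords
    ``ancestral``/``derived``/``missing``.  A node qualifies when its own
    SNPs are derived and no ancestor is ancestral; the deepest qualifying
    node wins.  Qualifying nodes on disjoint branches raise
    :class:`HaplogroupConflictError`.  With no derived SNPs at all, the
    root label is returned.
    """
    status = {node: _node_status(node, calls, tree) for node in tree.parent}

    def qualifies(node: str) -> bool:
        if status[node] != DERIVED:
            return False
        for anc in tree.path(node)[:-1]:
            if anc != tree.root and status[anc] == ANCESTRAL:
                return False
        return True

    candidates = [n for n in tree.parent if qualifies(n)]
    if not candidates:
        return Assignment(tree.root, (tree.root,))
    # keep only maximal (deepest) candidates: drop any that is an ancestor
    # of another candidate
    maximal = [
        c for c in candidates
        if not any(c != o and tree.is_ancestor(c, o) for o in candidates)
    ]
    if len(maximal) > 1:
        paths = "; ".join("->".join(tree.path(m)) for m in sorted(maximal))
        raise HaplogroupConflictError(
            f"derived states on disjoint branches: {paths}"
        )
    best = maximal[0]
    return Assignment(best, tuple(tree.path(best)))


def haplogroup_frequencies(
    assignments: Mapping[str, Sequence[str]],
    tree: HaplogroupTree | None = None,
    collapse_depth: int | None = None,
) -> pd.DataFrame:
    """Populations x haplogroups relative-frequency matrix by direct counting.

    With *collapse_depth* and a tree, terminal labels are replaced by their
    ancestor at that depth (labels already at or above it are kept), so
    sub-lineage frequencies sum into their parent clade.  Rows sum to 1.
    """
    if not assignments:
        raise ValueError("no populations given")
    rows = {}
    for pop, labels in assignments.items():
        labels = list(labels)
        if not labels:
            raise ValueError(f"population {pop!r} is empty")
        if collapse_depth is not None:
            if tree is None:
                raise ValueError("collapse_depth requires a tree")
            labels = [tree.ancestor_at_depth(l, collapse_depth) for l in labels]
        counts = pd.Series(labels).value_counts()
        rows[pop] = counts / counts.sum()
    out = pd.DataFrame(rows).T.fillna(0.0)
    return out[sorted(out.columns)]


def haplogroup_diversity(freqs: Sequence[float] | pd.Series, n: int) -> float:
    """Unbiased diversity ``n/(n-1) * (1 - sum p_i^2)`` over a population's
    haplogroup frequency vector."""
    if n < 2:
        raise ValueError("haplogroup diversity needs n >= 2")
    p = pd.Series(freqs, dtype=float)
    total = float(p.sum())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"frequencies sum to {total:.6f}, expected 1")
    return n / (n - 1) * (1.0 - float((p * p).sum()))
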