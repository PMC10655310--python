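"""Reading, validating, projecting and writing Y-STR haplotype tables.

The central container is :class:`HaplotypeTable`: a pandas DataFrame of
canonical allele strings (one row per sampled man, one column per locus,
plus a ``Population`` column) together with the :class:`PanelDef` it was
validated against.  Allele calls follow forensic repeat nomenclature:
integer repeat counts (``"15"``), intermediate alleles with a partial
repeat digit (``"17.2"``), and null alleles (``"0"``, also accepted as
``"null"`` or ``"-"`` on input).  The multi-copy locus DYS385 is stored as
an order-normalised pair ``"11-14"``.

Six nested panels are built in, from the 9-locus minimal haplotype up to
the 26-locus Goldeneye set; DYS385a/b counts as two loci toward a panel's
nominal size but is carried as a single multi-copy column.
"""

from __future__ import annotations

import io as _io
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO, Union

import pandas as pd

__all__ = [
    "AlleleCall",
    "AlleleParseError",
    "HaplotypeTable",
    "HaplotypeTableError",
    "LocusDef",
    "PanelDef",
    "BUILTIN_PANELS",
    "PANEL_ORDER",
    "get_panel",
    "parse_allele",
    "parse_dys385_pair",
    "read_haplotype_table",
    "write_haplotype_table",
    "project_panel",
]


class AlleleParseError(ValueError):
    """Raised when an allele token cannot be interpreted."""


class HaplotypeTableError(ValueError):
    """Raised when a haplotype table violates its panel contract."""


_NULL_TOKENS = {"0", "null", "-"}
_INT_RE = re.compile(r"^(\d+)$")
_INTERMEDIATE_RE = re.compile(r"^(\d+)\.(\d)$")


@dataclass(frozen=True, order=True)
class AlleleCall:
    """A single allele call at a Y-STR locus.

    ``repeats`` is the integer repeat count; ``fraction`` the partial-repeat
    digit (0 for ordinary integer alleles, 1-3 for intermediate alleles such
    as 17.2); null alleles carry ``is_null=True`` and zero repeats.
    Ordering is by (repeats, fraction), which puts nulls first and makes
    DYS385 pair normalisation deterministic.
    """

    repeats: int = 0
    fraction: int = 0
    is_null: bool = False

    def __post_init__(self) -> None:
        if self.repeats < 0:
            raise AlleleParseError(f"negative repeat count {self.repeats}")
        if self.is_null and (self.repeats or self.fraction):
            raise AlleleParseError("null allele carries no repeat count")
        if not self.is_null and self.repeats == 0 and self.fraction == 0:
            raise AlleleParseError(
                "a zero-repeat call is the null allele; use is_null=True"
            )

    @property
    def kind(self) -> str:
        if self.is_null:
            return "null"
        return "intermediate" if self.fraction else "integer"

    def rounded_repeats(self) -> int | None:
        """Repeat count rounded to the nearest integer, half away from zero.

        Used for allele-size based analyses (Rst, network input); returns
        None for null alleles, which have no size.
        """
        if self.is_null:
            return None
        return self.repeats + (1 if self.fraction >= 5 else 0)

    def __str__(self) -> str:
        if self.is_null:
            return "0"
        if self.fraction:
            return f"{self.repeats}.{self.fraction}"
        return str(self.repeats)


def parse_allele(token: str) -> AlleleCall:
    """Parse a single allele token into an :class:`AlleleCall`.

    ``"15"`` -> integer 15; ``"17.2"`` -> intermediate (17 repeats + 2
    bases); ``"0"``/``"null"``/``"-"`` -> null.  Anything else raises
    :class:`AlleleParseError`.
    """
    tok = token.strip()
    if not tok:
        raise AlleleParseError("empty allele token")
    if tok.lower() in _NULL_TOKENS:
        return AlleleCall(is_null=True)
    m = _INT_RE.match(tok)
    if m:
        return AlleleCall(repeats=int(m.group(1)))
    m = _INTERMEDIATE_RE.match(tok)
    if m:
        frac = int(m.group(2))
        if frac not in (1, 2, 3):
            raise AlleleParseError(
                f"intermediate allele {tok!r}: partial-repeat digit must be 1-3"
            )
        return AlleleCall(repeats=int(m.group(1)), fraction=frac)
    raise AlleleParseError(f"malformed allele token {tok!r}")


def parse_dys385_pair(token: str) -> tuple[AlleleCall, AlleleCall]:
    """Parse a multi-copy cell like ``"11-14"`` into an ascending pair."""
    parts = token.strip().split("-")
    if len(parts) != 2:
        raise AlleleParseError(
            f"multi-copy cell {token!r} must hold exactly two alleles 'a-b'"
        )
    a, b = (parse_allele(p) for p in parts)
    return (a, b) if a <= b else (b, a)


def format_pair(pair: tuple[AlleleCall, AlleleCall]) -> str:
    a, b = sorted(pair)
    return f"{a}-{b}"


@dataclass(frozen=True)
class LocusDef:
    name: str
    multi_copy: bool = False


@dataclass(frozen=True)
class PanelDef:
    """An ordered set of Y-STR loci with a panel name (e.g. YF17)."""

    name: str
    loci: tuple[LocusDef, ...]

    @property
    def locus_names(self) -> tuple[str, ...]:
        return tuple(l.name for l in self.loci)

    @property
    def locus_count(self) -> int:
        """Nominal panel size; a multi-copy locus (DYS385a/b) counts as two."""
        return sum(2 if l.multi_copy else 1 for l in self.loci)

    def locus(self, name: str) -> LocusDef:
        for l in self.loci:
            if l.name == name:
                return l
        raise KeyError(name)

    def single_copy_names(self) -> tuple[str, ...]:
        return tuple(l.name for l in self.loci if not l.multi_copy)

    def is_subset_of(self, other: "PanelDef") -> bool:
        return set(self.locus_names) <= set(other.locus_names)


def _panel(name: str, names: Iterable[str]) -> PanelDef:
    return PanelDef(
        name,
        tuple(LocusDef(n, multi_copy=(n == "DYS385")) for n in names),
    )


_MH9 = ["DYS19", "DYS389I", "DYS389II", "DYS390", "DYS391", "DYS392",
        "DYS393", "DYS385"]
_EH11 = _MH9 + ["DYS438", "DYS439"]
_PPY12 = _EH11 + ["DYS437"]
_YF17 = _PPY12 + ["DYS448", "DYS456", "DYS458", "DYS635", "GATA_H4"]
_PPY23 = _YF17 + ["DYS481", "DYS533", "DYS549", "DYS570", "DYS576", "DYS643"]
_GE26 = _PPY23 + ["DYS388", "DYS460", "DYS449"]

#: The six nested panels: minimal haplotype, extended haplotype,
#: PowerPlex Y12, Yfiler, PowerPlex Y23 and the 26-locus Goldeneye set.
BUILTIN_PANELS: Mapping[str, PanelDef] = {
    "MH9": _panel("MH9", _MH9),
    "EH11": _panel("EH11", _EH11),
    "PPY12": _panel("PPY12", _PPY12),
    "YF17": _panel("YF17", _YF17),
    "PPY23": _panel("PPY23", _PPY23),
    "GE26": _panel("GE26", _GE26),
}

PANEL_ORDER = ("MH9", "EH11", "PPY12", "YF17", "PPY23", "GE26")


def get_panel(name: str) -> PanelDef:
    try:
        return BUILTIN_PANELS[name]
    except KeyError:
        raise KeyError(
            f"unknown panel {name!r}; built-in panels: {', '.join(PANEL_ORDER)}"
        ) from None


@dataclass
class HaplotypeTable:
    """Validated samples x loci table of canonical allele strings.

    ``data`` is indexed by sample id and holds a ``Population`` column
    followed by one column per panel locus.  All cells are canonical
    strings (re-formatted through :func:`parse_allele`), so haplotype
    identity is plain string-tuple equality.
    """

    data: pd.DataFrame
    panel: PanelDef

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def populations(self) -> pd.Series:
        return self.data["Population"]

    @property
    def loci(self) -> tuple[str, ...]:
        return self.panel.locus_names

    def call(self, sample: str, locus: str):
        """Parsed call: an AlleleCall, or an ascending pair for DYS385."""
        cell = self.data.at[sample, locus]
        if self.panel.locus(locus).multi_copy:
            return parse_dys385_pair(cell)
        return parse_allele(cell)

    def haplotype_key(self, sample: str) -> tuple[str, ...]:
        return tuple(self.data.loc[sample, list(self.loci)])

    def haplotype_keys(self) -> pd.Series:
        cols = list(self.loci)
        return pd.Series(
            [tuple(row) for row in self.data[cols].itertuples(index=False)],
            index=self.data.index,
        )

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise HaplotypeTableError(f"duplicate sample id {dup!r}")
        if "Population" not in self.data.columns:
            raise HaplotypeTableError("missing Population column")
        missing = [n for n in self.panel.locus_names if n not in self.data.columns]
        if missing:
            raise HaplotypeTableError(
                f"panel {self.panel.name} requires missing locus column(s): "
                + ", ".join(missing)
            )
        for locus in self.panel.loci:
            col = self.data[locus.name]
            for sample, cell in col.items():
                try:
                    if locus.multi_copy:
                        canon = format_pair(parse_dys385_pair(str(cell)))
                    else:
                        canon = str(parse_allele(str(cell)))
                except AlleleParseError as e:
                    raise HaplotypeTableError(
                        f"sample {sample!r}, locus {locus.name}: {e}"
                    ) from e
                if canon != cell:
                    self.data.at[sample, locus.name] = canon

    # -- I/O ---------------------------------------------------------------
    def write(self, dest: Union[str, TextIO]) -> None:
        write_haplotype_table(self, dest)


Source = Union[str, TextIO]


def _as_stream(source: Source):
    if isinstance(source, str) and "\t" not in source and "\n" not in source:
        return open(source, "r", encoding="utf-8"), True
    if isinstance(source, str):
        return _io.StringIO(source), True
    return source, False


def read_haplotype_table(source: Source, panel: PanelDef) -> HaplotypeTable:
    """Read a tab-delimited haplotype table and validate it against *panel*.

    The header must name ``SampleID``, ``Population``, then locus columns;
    the DYS385 column holds ``a-b`` pairs.  The first violation found is
    reported with its sample id and locus.
    """
    stream, close = _as_stream(source)
    try:
        df = pd.read_csv(stream, sep="\t", dtype=str, keep_default_na=False)
    finally:
        if close:
            stream.close()
    if "SampleID" not in df.columns:
        raise HaplotypeTableError("header must start with a SampleID column")
    df = df.set_index("SampleID")
    keep = ["Population"] + [n for n in panel.locus_names if n in df.columns]
    if "Population" not in df.columns:
        raise HaplotypeTableError("missing Population column")
    return HaplotypeTable(df[keep].copy(), panel)


def write_haplotype_table(table: HaplotypeTable, dest: Union[str, TextIO]) -> None:
    """Write the table back in the same tab-delimited dialect."""
    out = table.data.copy()
    out.insert(0, "SampleID", out.index)
    cols = ["SampleID", "Population"] + list(table.loci)
    if isinstance(dest, str):
        out[cols].to_csv(dest, sep="\t", index=False)
    else:
        out[cols].to_csv(dest, sep="\t", index=False)


def project_panel(table: HaplotypeTable, panel: PanelDef) -> HaplotypeTable:
    """Restrict a table to a smaller (nested) panel; samples unchanged."""
    missing = [n for n in panel.locus_names if n not in table.data.columns]
    if missing:
        raise HaplotypeTableError(
            f"cannot project to {panel.name}: table lacks " + ", ".join(missing)
        )
    cols = ["Population"] + list(panel.locus_names)
    return HaplotypeTable(table.data[cols].copy(), panel)
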