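"""Gene annotation tables and gene sets.

The central objects are :class:`GeneTable` — an annotated table of gene
records modelled on curated disease-gene databases (one row per HGNC-style
symbol, with a functional category in the style of BIG-C and an optional
hematopoietic/tissue cell-type tag in the style of IScope/TScope) — and
:class:`GeneSet`, a plain named set of symbols as used for risk-gene lists
and network modules.

Symbols are canonicalized by uppercasing and stripping whitespace; alias
resolution is deliberately not attempted, since curated symbol lists are
matched directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "GeneSet",
    "GeneTable",
    "GeneTableError",
    "read_gene_table",
    "write_gene_table",
    "read_gmt",
    "write_gmt",
    "read_symbol_list",
    "write_symbol_list",
    "category_breakdown",
    "compare_category_profiles",
]

#: Canonical column order for gene-table TSV round trips.
CANONICAL_COLUMNS = [
    "symbol",
    "entrez_id",
    "ensembl_id",
    "functional_category",
    "cell_type_tag",
    "chromosome",
    "start",
    "end",
    "is_pid",
    "inheritance",
    "phenotype",
]

#: Annotation schemes accepted by the breakdown operations.
SCHEME_COLUMNS = {
    "cell_type": "cell_type_tag",
    "functional": "functional_category",
}

UNTAGGED = "untagged"


class GeneTableError(ValueError):
    """Malformed or inconsistent gene-table input."""


def canonical_symbol(symbol: str) -> str:
    return str(symbol).strip().upper()


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols (risk list, module, universe...)."""

    name: str
    symbols: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "symbols", frozenset(canonical_symbol(s) for s in self.symbols)
        )

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return canonical_symbol(symbol) in self.symbols

    def intersect(self, other: "GeneSet | Iterable[str]") -> "GeneSet":
        other_symbols = other.symbols if isinstance(other, GeneSet) else {
            canonical_symbol(s) for s in other
        }
        return GeneSet(self.name, self.symbols & frozenset(other_symbols))

    @classmethod
    def from_symbols(cls, name: str, symbols: Iterable[str], description: str = "") -> "GeneSet":
        return cls(name, frozenset(symbols), description)


class GeneTable:
    """Ordered collection of annotated gene records.

    Wraps a :class:`pandas.DataFrame` with the canonical columns; rows are
    validated on construction (unique non-empty symbols, start <= end when
    both coordinates are present).
    """

    def __init__(self, records: pd.DataFrame, universe_name: str = "universe"):
        df = records.copy()
        if "symbol" not in df.columns:
            raise GeneTableError("gene table requires a 'symbol' column")
        df["symbol"] = df["symbol"].map(canonical_symbol)
        if (df["symbol"] == "").any():
            bad = df.index[df["symbol"] == ""].tolist()
            raise GeneTableError(f"empty gene symbols at rows {bad}")
        dup_mask = df["symbol"].duplicated(keep=False)
        if dup_mask.any():
            offenders = df.loc[dup_mask, "symbol"]
            listing = ", ".join(
                f"{sym} (row {idx})" for idx, sym in offenders.items()
            )
            raise GeneTableError(f"duplicate gene symbols: {listing}")
        for col in CANONICAL_COLUMNS:
            if col not in df.columns:
                df[col] = pd.NA
        if "is_pid" in records.columns:
            df["is_pid"] = df["is_pid"].fillna(False).astype(bool)
        else:
            df["is_pid"] = False
        both = df["start"].notna() & df["end"].notna()
        if both.any():
            starts = pd.to_numeric(df.loc[both, "start"])
            ends = pd.to_numeric(df.loc[both, "end"])
            bad = starts.index[(starts > ends).to_numpy()]
            if len(bad):
                raise GeneTableError(f"start > end at rows {list(bad)}")
        extra = [c for c in df.columns if c not in CANONICAL_COLUMNS]
        self.records = df[CANONICAL_COLUMNS + extra].reset_index(drop=True)
        self.universe_name = universe_name

    def __len__(self) -> int:
        return len(self.records)

    @property
    def symbols(self) -> list[str]:
        return self.records["symbol"].tolist()

    def as_gene_set(self, name: str | None = None) -> GeneSet:
        return GeneSet.from_symbols(name or self.universe_name, self.symbols)

    def pid_genes(self) -> GeneSet:
        mask = self.records["is_pid"]
        return GeneSet.from_symbols("PID", self.records.loc[mask, "symbol"])

    def subset(self, symbols: Iterable[str], universe_name: str | None = None) -> "GeneTable":
        wanted = {canonical_symbol(s) for s in symbols}
        mask = self.records["symbol"].isin(wanted)
        return GeneTable(self.records.loc[mask], universe_name or self.universe_name)

    def category_of(self, scheme: str) -> pd.Series:
        """Per-gene category labels under a scheme, indexed by symbol."""
        col = _scheme_column(scheme)
        return self.records.set_index("symbol")[col]


def _scheme_column(scheme: str) -> str:
    try:
        return SCHEME_COLUMNS[scheme]
    except KeyError:
        raise GeneTableError(
            f"unknown scheme {scheme!r}; expected one of {sorted(SCHEME_COLUMNS)}"
        ) from None


# ---------------------------------------------------------------------------
# IO


def read_gene_table(path: str | Path, universe_name: str | None = None) -> GeneTable:
    """Read a gene table from TSV/CSV (delimiter sniffed from the extension)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype={"symbol": str})
    if "symbol" not in df.columns:
        raise GeneTableError(
            f"{path}: no 'symbol' column among {list(df.columns)}"
        )
    return GeneTable(df, universe_name or path.stem)


def write_gene_table(table: GeneTable, path: str | Path) -> None:
    table.records.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from GMT (name<TAB>description<TAB>sym1<TAB>sym2...)."""
    sets = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise GeneTableError(f"{path}:{lineno}: GMT line has < 3 fields")
        name, description, *symbols = fields
        sets.append(GeneSet.from_symbols(name, [s for s in symbols if s], description))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    lines = []
    for gs in sets:
        lines.append("\t".join([gs.name, gs.description, *sorted(gs.symbols)]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_symbol_list(path: str | Path, name: str | None = None) -> GeneSet:
    """One symbol per line; blank lines and '#' comments ignored."""
    symbols = [
        ln.strip()
        for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    return GeneSet.from_symbols(name or Path(path).stem, symbols)


def write_symbol_list(gene_set: GeneSet, path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(gene_set.symbols)) + "\n")


# ---------------------------------------------------------------------------
# Category breakdowns


def category_breakdown(table: GeneTable, scheme: str) -> pd.DataFrame:
    """Counts and percentages per category under a scheme.

    Percentages are over *all* records in the table; genes without a tag are
    reported under the ``untagged`` row, so counts always sum to the table
    size.
    """
    col = _scheme_column(scheme)
    labels = table.records[col].fillna(UNTAGGED).replace("", UNTAGGED)
    if (labels == UNTAGGED).all():
        raise GeneTableError(f"no record carries a {scheme!r} tag")
    counts = labels.value_counts()
    out = pd.DataFrame(
        {
            "count": counts,
            "percent": 100.0 * counts / len(table),
        }
    )
    out.index.name = "category"
    return out.sort_index()


def compare_category_profiles(
    table_a: GeneTable, background: GeneTable, scheme: str = "functional"
) -> pd.DataFrame:
    """Paired per-category percentages for a table vs a background table.

    Categories absent from one side are reported with 0 for that side —
    the tabular equivalent of a paired-bar category profile.
    """
    bd_a = category_breakdown(table_a, scheme)
    bd_b = category_breakdown(background, scheme)
    cats = sorted(set(bd_a.index) | set(bd_b.index))
    out = pd.DataFrame(
        {
            "count_a": bd_a["count"].reindex(cats, fill_value=0).astype(int),
            "percent_a": bd_a["percent"].reindex(cats, fill_value=0.0),
            "count_background": bd_b["count"].reindex(cats, fill_value=0).astype(int),
            "percent_background": bd_b["percent"].reindex(cats, fill_value=0.0),
        }
    )
    out.index.name = "category"
    return out


def first_tag(tags: Iterable[str]) -> str | None:
    """Collapse multiple cell-type tags to one; first wins with a warning."""
    tags = [t for t in tags if t]
    if not tags:
        return None
    if len(tags) > 1:
        warnings.warn(
            f"multiple cell-type tags {tags}; keeping {tags[0]!r}", stacklevel=2
        )
    return tags[0]
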