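"""Reading, validating and manipulating pathway and marker gene lists.

Gene sets are ordered collections of unique gene symbols.  Two on-disk
dialects are supported: GMT (tab-separated ``name<TAB>description<TAB>gene...``,
the MSigDB distribution format) and marker tables in the PanglaoDB style
(one row per species/gene/cell-type triple).

Gene symbol matching throughout the package is case-sensitive exact string
match; no alias or ortholog resolution is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

#: below this size a pathway is unlikely to support stable mode detection
MIN_RECOMMENDED_GENES = 10


class GmtParseError(ValueError):
    """Raised when a GMT file violates the name/description/genes layout."""


@dataclass(frozen=True)
class GeneSet:
    """A named, ordered list of unique gene symbols."""

    name: str
    genes: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be non-empty")
        object.__setattr__(self, "genes", tuple(self.genes))
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"duplicate genes in set {self.name!r}")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


@dataclass
class GeneSetCollection:
    """An ordered collection of :class:`GeneSet` with unique names."""

    sets: list[GeneSet] = field(default_factory=list)
    source: str = ""

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate gene set names: {dup}")

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __getitem__(self, key: int | str) -> GeneSet:
        if isinstance(key, str):
            for s in self.sets:
                if s.name == key:
                    return s
            raise KeyError(key)
        return self.sets[key]

    def __contains__(self, name: str) -> bool:
        return name in self.names


def _dedup(genes: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    for g in genes:
        if g and g not in seen:
            seen.add(g)
            out.append(g)
    return out


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file into a :class:`GeneSetCollection`.

    Each non-blank line must have at least three tab-separated fields
    (name, description, one or more genes).  Duplicate genes within a line
    are dropped keeping the first occurrence; empty gene fields are ignored.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields "
                    f"(name, description, genes...), got {len(fields)}"
                )
            name, description = fields[0], fields[1]
            genes = _dedup(fields[2:])
            if not genes:
                raise GmtParseError(f"{path}: line {lineno}: set {name!r} has no genes")
            sets.append(GeneSet(name=name, genes=tuple(genes), description=description))
    return GeneSetCollection(sets=sets, source=str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection in GMT format (inverse of :func:`read_gmt`)."""
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


def read_marker_table(
    path: str | Path,
    species_filter: str | None = None,
    *,
    species_col: str = "species",
    symbol_col: str = "official gene symbol",
    celltype_col: str = "cell type",
) -> GeneSetCollection:
    """Read a PanglaoDB-style marker table into one gene set per cell type.

    Parameters
    ----------
    species_filter
        When given, rows whose species field does not contain this substring
        are dropped (PanglaoDB encodes species as e.g. ``"Mm Hs"``).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    for col in (species_col, symbol_col, celltype_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if species_filter is not None:
        df = df[df[species_col].astype(str).str.contains(species_filter, regex=False)]
    by_type: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        ct = str(row[celltype_col])
        gene = str(row[symbol_col])
        by_type.setdefault(ct, []).append(gene)
    sets = [
        GeneSet(name=ct, genes=tuple(_dedup(genes)))
        for ct, genes in by_type.items()
        if _dedup(genes)
    ]
    return GeneSetCollection(sets=sets, source=str(path))


def intersect_with_universe(gene_set: GeneSet, universe: Iterable[str]) -> GeneSet:
    """Restrict a gene set to the symbols present in ``universe``.

    Order is preserved.  An empty result is allowed (callers decide whether
    to skip the pathway); keeping fewer than :data:`MIN_RECOMMENDED_GENES`
    genes triggers a warning, as very short lists rarely support reliable
    mode detection.
    """
    uni = set(universe)
    kept = tuple(g for g in gene_set.genes if g in uni)
    n_dropped = len(gene_set) - len(kept)
    if 0 < len(kept) < MIN_RECOMMENDED_GENES:
        warnings.warn(
            f"gene set {gene_set.name!r} keeps only {len(kept)} genes after "
            f"intersection with the expression universe ({n_dropped} dropped); "
            f"lists with at least {MIN_RECOMMENDED_GENES} genes are recommended",
            stacklevel=2,
        )
    return GeneSet(name=gene_set.name, genes=kept, description=gene_set.description)


def spike_random_genes(
    gene_set: GeneSet, universe: Sequence[str], n_add: int, seed: int
) -> GeneSet:
    """Extend a gene set with ``n_add`` random genes from ``universe``.

    Sampling is uniform without replacement from the universe minus the
    existing members; deterministic given ``seed``.  Used to probe the
    robustness of mode detection to noisy, non-curated pathway lists.
    """
    if n_add < 0:
        raise ValueError("n_add must be >= 0")
    if n_add == 0:
        return gene_set
    existing = set(gene_set.genes)
    pool = [g for g in universe if g not in existing]
    if len(pool) < n_add:
        raise ValueError(
            f"universe has only {len(pool)} genes outside {gene_set.name!r}, "
            f"cannot add {n_add}"
        )
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(pool), size=n_add, replace=False)
    return GeneSet(
        name=gene_set.name,
        genes=gene_set.genes + tuple(pool[i] for i in picks),
        description=gene_set.description,
    )
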