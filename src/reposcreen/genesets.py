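"""Disease gene-set integration.

Merges gene lists from multiple named sources (curated databases, pathway
entries, hand lists) into a single provenance-tracked :class:`GeneSet`,
after normalising symbols and resolving aliases to their official
(HGNC-style) names.  The provenance map supports Venn-style source
breakdowns of the merged set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import ConfigurationError

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "normalize_symbol",
    "canonicalize",
    "merge_gene_sources",
    "venn_counts",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "read_alias_map",
    "write_provenance_table",
]


@dataclass
class GeneSet:
    """A named collection of gene symbols with per-gene source provenance.

    Invariants: ``provenance`` keys equal ``genes`` exactly, every
    provenance value is non-empty, and symbols are upper-case,
    whitespace-trimmed and unique.
    """

    name: str
    genes: set[str] = field(default_factory=set)
    provenance: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.provenance) != self.genes:
            raise ConfigurationError(
                f"gene set '{self.name}': provenance keys must equal the gene set"
            )
        for g, sources in self.provenance.items():
            if not sources:
                raise ConfigurationError(
                    f"gene set '{self.name}': gene {g} has empty provenance"
                )

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.genes

    def __iter__(self):
        return iter(sorted(self.genes))

    @property
    def sources(self) -> set[str]:
        out: set[str] = set()
        for srcs in self.provenance.values():
            out |= srcs
        return out


def normalize_symbol(symbol: str) -> str:
    """Trim whitespace and upper-case a gene symbol."""
    return symbol.strip().upper()


def _normalized_alias_map(alias_map: Mapping[str, str] | None) -> dict[str, str]:
    if not alias_map:
        return {}
    return {
        normalize_symbol(k): normalize_symbol(v) for k, v in alias_map.items()
    }


def canonicalize(
    symbols: Iterable[str], alias_map: Mapping[str, str] | None = None
) -> list[str]:
    """Normalise symbols and resolve aliases to canonical names.

    Each symbol is trimmed and upper-cased, then chased through
    ``alias_map`` until it reaches a fixed point.  Unknown symbols pass
    through unchanged.  Order is preserved and duplicates are retained
    (deduplication happens at merge time).

    Raises
    ------
    ConfigurationError
        If the alias map contains a cycle.
    """
    amap = _normalized_alias_map(alias_map)
    out: list[str] = []
    for raw in symbols:
        sym = normalize_symbol(raw)
        seen = {sym}
        while sym in amap and amap[sym] != sym:
            sym = amap[sym]
            if sym in seen:
                raise ConfigurationError(
                    f"alias map contains a cycle involving {sym!r}"
                )
            seen.add(sym)
        out.append(sym)
    return out


def merge_gene_sources(
    named_lists: Mapping[str, Sequence[str]],
    alias_map: Mapping[str, str] | None = None,
    drop_list: Iterable[str] = (),
    name: str = "merged",
) -> GeneSet:
    """Union multiple named gene lists into a provenance-tracked set.

    Symbols are canonicalized, the union is taken, and genes in
    ``drop_list`` (e.g. symbols judged to be of unknown function, a
    caller-supplied decision) are removed.  Provenance records every
    source that contributed each retained gene.
    """
    if not named_lists:
        raise ConfigurationError("merge_gene_sources requires at least one source")
    drops = {normalize_symbol(g) for g in drop_list}
    genes: set[str] = set()
    provenance: dict[str, set[str]] = {}
    for source in named_lists:
        for sym in canonicalize(named_lists[source], alias_map):
            if not sym or sym in drops:
                continue
            genes.add(sym)
            provenance.setdefault(sym, set()).add(source)
    if not genes:
        logger.warning("merge_gene_sources: all sources empty after filtering")
    return GeneSet(name=name, genes=genes, provenance=provenance)


def venn_counts(gene_set: GeneSet) -> dict[tuple[str, ...], int]:
    """Count genes per exact source combination.

    Keys are sorted tuples of source names; a gene contributes to exactly
    one region (the full combination of its sources), so the counts sum to
    ``len(gene_set)``.  Regions with zero genes are included for every
    non-empty combination of the observed sources.
    """
    from itertools import combinations

    sources = sorted(gene_set.sources)
    counts: dict[tuple[str, ...], int] = {}
    for r in range(1, len(sources) + 1):
        for combo in combinations(sources, r):
            counts[combo] = 0
    for srcs in gene_set.provenance.values():
        counts[tuple(sorted(srcs))] += 1
    return counts


# ---------------------------------------------------------------------------
# I/O: GMT, plain symbol lists, alias maps, provenance tables


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file into ``{set_name: [symbols...]}``.

    GMT rows are ``name <TAB> description <TAB> symbol...``; the
    description column is ignored.
    """
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                continue
            out[parts[0]] = [p for p in parts[2:] if p.strip()]
    return out


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for set_name in sets:
            symbols = "\t".join(sets[set_name])
            fh.write(f"{set_name}\t{description}\t{symbols}\n")


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-symbol-per-line text file (blank lines and '#' comments skipped)."""
    out: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def read_alias_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV ``alias <TAB> canonical``."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            alias, canonical = line.split("\t")[:2]
            out[alias] = canonical
    return out


def write_provenance_table(gene_set: GeneSet, path: str | Path) -> None:
    """Write ``gene <TAB> source1,source2,...`` rows, sorted by gene."""
    with open(path, "w") as fh:
        fh.write("gene\tsources\n")
        for gene in sorted(gene_set.genes):
            fh.write(f"{gene}\t{','.join(sorted(gene_set.provenance[gene]))}\n")
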