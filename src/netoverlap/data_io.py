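"""Readers and writers for interaction databases, gene lists and result tables.

Interaction data come either from BioGRID tab-delimited releases (TAB2 or TAB3
dialect, recognised by header column names) or from a generic two-column
edge-list TSV.  Gene symbols are case-insensitive throughout the package and
are uppercased at ingest.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

from netoverlap.errors import FormatError

__all__ = [
    "CATEGORY_PHYSICAL",
    "CATEGORY_GENETIC",
    "InteractionRecord",
    "InteractionNetwork",
    "GeneList",
    "read_biogrid",
    "build_network",
    "read_gene_list",
    "write_results_table",
    "read_results_table",
]

CATEGORY_PHYSICAL = "physical"
CATEGORY_GENETIC = "genetic"
_CATEGORIES = (CATEGORY_PHYSICAL, CATEGORY_GENETIC)


def _clean_symbol(symbol: str) -> str:
    return str(symbol).strip().upper()


@dataclass(frozen=True)
class InteractionRecord:
    """One row of an interaction database, after symbol normalisation."""

    gene_a: str
    gene_b: str
    organism_a: int
    organism_b: int
    interaction_category: str = CATEGORY_PHYSICAL
    source_version: str = ""

    def __post_init__(self):
        object.__setattr__(self, "gene_a", _clean_symbol(self.gene_a))
        object.__setattr__(self, "gene_b", _clean_symbol(self.gene_b))
        if not self.gene_a or not self.gene_b:
            raise ValueError("interaction endpoints must be non-empty symbols")
        if self.interaction_category not in _CATEGORIES:
            raise ValueError(
                f"interaction_category must be one of {_CATEGORIES}, "
                f"got {self.interaction_category!r}"
            )


class InteractionNetwork:
    """Undirected simple graph of gene symbols.

    Duplicate and endpoint-reversed records collapse onto a single edge.
    Self-loops are recorded as metadata but never contribute to a gene's
    neighbour count: a gene always belongs to its own +1 interactome via the
    seed rule, so counting a self-edge would double-count it.
    """

    def __init__(self, edges: Iterable[tuple[str, str]] = (), genes: Iterable[str] = ()):
        self._adj: dict[str, set[str]] = {}
        self._self_loops: set[str] = set()
        self._p1_cache: dict[str, frozenset[str]] = {}
        for g in genes:
            self.add_gene(g)
        for a, b in edges:
            self.add_edge(a, b)

    # -- construction -------------------------------------------------
    def add_gene(self, gene: str) -> None:
        self._adj.setdefault(_clean_symbol(gene), set())

    def add_edge(self, gene_a: str, gene_b: str) -> None:
        a, b = _clean_symbol(gene_a), _clean_symbol(gene_b)
        self._adj.setdefault(a, set())
        self._adj.setdefault(b, set())
        if a == b:
            self._self_loops.add(a)
        else:
            self._adj[a].add(b)
            self._adj[b].add(a)
        self._p1_cache.clear()

    # -- queries -------------------------------------------------------
    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self._adj)

    @property
    def n_genes(self) -> int:
        return len(self._adj)

    @property
    def n_edges(self) -> int:
        return sum(len(nbrs) for nbrs in self._adj.values()) // 2

    @property
    def self_loops(self) -> frozenset[str]:
        return frozenset(self._self_loops)

    def __contains__(self, gene: str) -> bool:
        return _clean_symbol(gene) in self._adj

    def __len__(self) -> int:
        return len(self._adj)

    def degree(self, gene: str) -> int:
        return len(self._adj[_clean_symbol(gene)])

    def neighbors(self, gene: str) -> frozenset[str]:
        return frozenset(self._adj[_clean_symbol(gene)])

    def has_self_loop(self, gene: str) -> bool:
        return _clean_symbol(gene) in self._self_loops

    def plus_one_members(self, gene: str) -> frozenset[str]:
        """The gene together with its distinct neighbours (cached)."""
        g = _clean_symbol(gene)
        cached = self._p1_cache.get(g)
        if cached is None:
            cached = frozenset(self._adj[g]) | {g}
            self._p1_cache[g] = cached
        return cached

    def edge_iter(self) -> Iterator[tuple[str, str]]:
        for a in self._adj:
            for b in self._adj[a]:
                if a < b:
                    yield (a, b)
        for g in sorted(self._self_loops):
            yield (g, g)

    def to_networkx(self):
        import networkx as nx

        graph = nx.Graph()
        graph.add_nodes_from(self._adj)
        graph.add_edges_from((a, b) for a, b in self.edge_iter() if a != b)
        return graph

    def __eq__(self, other) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        return self._adj == other._adj and self._self_loops == other._self_loops

    def __repr__(self) -> str:
        return (
            f"InteractionNetwork(n_genes={self.n_genes}, n_edges={self.n_edges}, "
            f"n_self_loops={len(self._self_loops)})"
        )


@dataclass(frozen=True)
class GeneList:
    """An ordered, duplicate-free list of uppercased gene symbols."""

    name: str
    genes: tuple[str, ...]
    provenance: str = ""

    @classmethod
    def from_iterable(cls, name: str, genes: Iterable[str], provenance: str = "") -> "GeneList":
        seen: dict[str, None] = {}
        n_dupes = 0
        for g in genes:
            sym = _clean_symbol(g)
            if not sym:
                continue
            if sym in seen:
                n_dupes += 1
            else:
                seen[sym] = None
        if n_dupes:
            warnings.warn(f"gene list {name!r}: collapsed {n_dupes} duplicate symbol(s)")
        return cls(name=name, genes=tuple(seen), provenance=provenance)

    def __iter__(self) -> Iterator[str]:
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return _clean_symbol(gene) in set(self.genes)


# ---------------------------------------------------------------------------
# BioGRID / edge-list reading

# Column aliases across the TAB2 and TAB3 dialects, resolved by name.
_SYMBOL_A = ("Official Symbol Interactor A",)
_SYMBOL_B = ("Official Symbol Interactor B",)
_ORGANISM_A = ("Organism Interactor A", "Organism ID Interactor A")
_ORGANISM_B = ("Organism Interactor B", "Organism ID Interactor B")
_CATEGORY_COL = ("Experimental System Type",)

_REQUIRED = (
    ("Official Symbol Interactor A", _SYMBOL_A),
    ("Official Symbol Interactor B", _SYMBOL_B),
    ("Organism Interactor A", _ORGANISM_A),
    ("Organism Interactor B", _ORGANISM_B),
    ("Experimental System Type", _CATEGORY_COL),
)


def _resolve(header: Sequence[str], aliases: Sequence[str]) -> str | None:
    for name in aliases:
        if name in header:
            return name
    return None


def read_biogrid(
    path: str | Path,
    taxid: int = 9606,
    category: str = CATEGORY_PHYSICAL,
) -> list[InteractionRecord]:
    """Read a BioGRID TAB2/TAB3 file (or generic 2-column edge list).

    Only records where *both* organisms equal ``taxid`` and the interaction
    category matches ``category`` are returned.  The reader does not
    de-duplicate; collapsing duplicates is :func:`build_network`'s job.

    A file whose first line matches neither dialect raises
    :class:`~netoverlap.errors.FormatError` naming the first missing column.
    An empty result after filtering yields a warning and an empty list.
    """
    path = Path(path)
    if category not in _CATEGORIES:
        raise ValueError(f"category must be one of {_CATEGORIES}")
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline().rstrip("\n")
    header = [c.lstrip("#").strip() for c in first.split("\t")]

    if _resolve(header, _SYMBOL_A):
        records = _read_biogrid_dialect(path, header, taxid, category)
    elif len(header) == 2:
        records = _read_edge_list(path, taxid)
    else:
        missing = next(name for name, aliases in _REQUIRED if not _resolve(header, aliases))
        raise FormatError(
            f"{path.name}: unrecognised header; required column {missing!r} not found "
            "and the file is not a 2-column edge list"
        )

    if not records:
        warnings.warn(
            f"{path.name}: no interactions left after filtering "
            f"(taxid={taxid}, category={category!r})"
        )
    return records


def _read_biogrid_dialect(
    path: Path, header: Sequence[str], taxid: int, category: str
) -> list[InteractionRecord]:
    for name, aliases in _REQUIRED:
        if not _resolve(header, aliases):
            raise FormatError(f"{path.name}: required column {name!r} not found in header")
    frame = pd.read_csv(path, sep="\t", header=0, dtype=str, keep_default_na=False)
    frame.columns = [c.lstrip("#").strip() for c in frame.columns]
    col_a = _resolve(frame.columns, _SYMBOL_A)
    col_b = _resolve(frame.columns, _SYMBOL_B)
    col_oa = _resolve(frame.columns, _ORGANISM_A)
    col_ob = _resolve(frame.columns, _ORGANISM_B)
    col_cat = _resolve(frame.columns, _CATEGORY_COL)
    version = path.name

    records: list[InteractionRecord] = []
    for row in frame.itertuples(index=False):
        mapping = dict(zip(frame.columns, row))
        sym_a = _clean_symbol(mapping[col_a])
        sym_b = _clean_symbol(mapping[col_b])
        if not sym_a or not sym_b or sym_a == "-" or sym_b == "-":
            continue
        try:
            org_a = int(str(mapping[col_oa]).strip())
            org_b = int(str(mapping[col_ob]).strip())
        except ValueError:
            continue
        cat = str(mapping[col_cat]).strip().lower()
        if cat not in _CATEGORIES:
            continue
        if org_a != taxid or org_b != taxid or cat != category:
            continue
        records.append(
            InteractionRecord(sym_a, sym_b, org_a, org_b, cat, source_version=version)
        )
    return records


def _read_edge_list(path: Path, taxid: int) -> list[InteractionRecord]:
    records: list[InteractionRecord] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(
                    f"{path.name}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
                )
            records.append(
                InteractionRecord(
                    parts[0], parts[1], taxid, taxid, CATEGORY_PHYSICAL,
                    source_version=path.name,
                )
            )
    return records


def build_network(records: Iterable[InteractionRecord]) -> InteractionNetwork:
    """Assemble an undirected simple graph from interaction records.

    Idempotent under record duplication and endpoint reversal; self-loops are
    recorded but excluded from degree.
    """
    network = InteractionNetwork()
    for rec in records:
        network.add_edge(rec.gene_a, rec.gene_b)
    return network


# ---------------------------------------------------------------------------
# Gene lists and result tables


def read_gene_list(path: str | Path, name: str | None = None) -> GeneList:
    """Read a one-symbol-per-line gene list; ``#`` lines are comments.

    Duplicates are collapsed with a warning.  An empty list is an error:
    every downstream stage is undefined on empty input.
    """
    path = Path(path)
    symbols: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            symbols.append(line)
    if not symbols:
        raise ValueError(f"{path.name}: gene list is empty")
    return GeneList.from_iterable(
        name=name or path.stem, genes=symbols, provenance=str(path)
    )


_RESULT_COLUMNS = (
    "gene",
    "p_value",
    "direction",
    "direct_interactor",
    "observed",
    "n_right",
    "n_left",
)


def write_results_table(results, path: str | Path) -> Path:
    """Write per-gene overlap test results as TSV, Table-style.

    Columns: gene, p_value, direction (larger/smaller), direct_interactor
    flag, plus the raw observed overlap and tail counts.  Rows are sorted by
    ascending p, ties broken by gene symbol.
    """
    path = Path(path)
    rows = []
    for res in results:
        rows.append(
            {
                "gene": res.gene,
                "p_value": res.p,
                "direction": res.direction,
                "direct_interactor": bool(res.direct_interactor),
                "observed": res.observed,
                "n_right": res.n_right,
                "n_left": res.n_left,
            }
        )
    frame = pd.DataFrame(rows, columns=_RESULT_COLUMNS)
    frame = frame.sort_values(["p_value", "gene"], kind="mergesort").reset_index(drop=True)
    frame.to_csv(path, sep="\t", index=False)
    return path


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Read a results TSV written by :func:`write_results_table`."""
    frame = pd.read_csv(Path(path), sep="\t")
    if "direct_interactor" in frame.columns:
        frame["direct_interactor"] = frame["direct_interactor"].astype(bool)
    return frame
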