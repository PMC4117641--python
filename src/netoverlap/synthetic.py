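"""Synthetic networks and gene lists with known planted structure.

The generator emulates the statistical features the analysis relies on: an
undirected interaction network with a heavy-tailed degree distribution
(degree-proportional growth), a designated orthologue "universe" subset, a
GWAS-like candidate list, and screen-hit lists in which a controllable
fraction of hits is planted to have unusually high size-normalised +1
overlap with the GWAS +1 interactome.  Every object can be serialised to a
plain-text fixture bundle that round-trips through the standard readers.

Default sizes are scaled-down study conditions (2000 genes, 800-gene
universe, lists of 60) so whole-pipeline tests run in seconds.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from types import SimpleNamespace

import numpy as np

from netoverlap._rng import derive_rng
from netoverlap.data_io import (
    CATEGORY_PHYSICAL,
    GeneList,
    InteractionNetwork,
    build_network,
    read_biogrid,
    read_gene_list,
)
from netoverlap.errors import ParameterError, SimulationError
from netoverlap.interactome import plus_one
from netoverlap.orthology import OrthologyCandidate

__all__ = [
    "SyntheticSpec",
    "PlantedTruth",
    "generate_network",
    "plant_lists",
    "write_fixture_bundle",
    "read_fixture_bundle",
]

WORM_PREFIX = "CEL-"


@dataclass(frozen=True)
class SyntheticSpec:
    n_genes: int = 2000
    m: int = 3  # edges added per new gene during growth
    universe_fraction: float = 0.4
    gwas_size: int = 60
    hit_size: int = 60
    enrichment: float = 0.5  # probability a hit is planted as enriched
    rng_seed: int = 0

    def __post_init__(self):
        if self.m < 1:
            raise ParameterError(f"m must be >= 1, got {self.m}")
        if self.n_genes < self.m + 1:
            raise ParameterError(
                f"n_genes must be at least the nucleus size m + 1 = {self.m + 1}, "
                f"got {self.n_genes}"
            )
        if not 0.0 < self.universe_fraction <= 1.0:
            raise ParameterError("universe_fraction must lie in (0, 1]")
        if self.gwas_size + self.hit_size > self.n_genes:
            raise ParameterError("gwas_size + hit_size exceeds n_genes")
        if not 0.0 <= self.enrichment <= 1.0:
            raise ParameterError("enrichment must lie in [0, 1]")


@dataclass(frozen=True)
class PlantedTruth:
    enriched_hits: frozenset[str]
    null_hits: frozenset[str]

    def __post_init__(self):
        if self.enriched_hits & self.null_hits:
            raise ValueError("enriched and null hits must be disjoint")


def _symbol(i: int) -> str:
    return f"G{i:06d}"


def generate_network(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> InteractionNetwork:
    """Degree-proportional growth network with a heavy-tailed degree profile.

    Starts from a fully connected nucleus of m+1 genes; each subsequent gene
    attaches to m distinct existing genes chosen with probability
    proportional to their current degree.  Total edges are therefore
    m(m+1)/2 + m(n_genes - m - 1).
    """
    if rng is None:
        rng = derive_rng(spec.rng_seed, "generate_network")
    n, m = spec.n_genes, spec.m
    symbols = [_symbol(i + 1) for i in range(n)]
    edges: list[tuple[str, str]] = []
    # degree-weighted sampling via an endpoint multiset
    endpoints: list[str] = []
    for i in range(m + 1):
        for j in range(i + 1, m + 1):
            edges.append((symbols[i], symbols[j]))
            endpoints.append(symbols[i])
            endpoints.append(symbols[j])
    for i in range(m + 1, n):
        new_gene = symbols[i]
        targets: set[str] = set()
        while len(targets) < m:
            targets.add(endpoints[rng.integers(len(endpoints))])
        for t in sorted(targets):
            edges.append((new_gene, t))
            endpoints.append(new_gene)
            endpoints.append(t)
    return InteractionNetwork(edges=edges)


# Planted signal strength: an enriched hit's +1 neighbourhood is extended
# into the reference +1 interactome until it has at least _BOOST_MIN_SIZE
# members of which at least _BOOST_MIN_FRAC are reference members — far
# outside the null envelope of size-matched random +1 interactomes.
_BOOST_MIN_SIZE = 60
_BOOST_MIN_FRAC = 0.9


def plant_lists(
    network: InteractionNetwork,
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
) -> tuple[GeneList, GeneList, PlantedTruth, GeneList]:
    """Draw universe, GWAS and hit lists, planting enrichment into the hits.

    The universe is a uniform ``universe_fraction`` subset of the genes; the
    GWAS list is a uniform ``gwas_size`` subset of all genes.  Universe genes
    outside the GWAS list are scored by their +1 overlap with the GWAS +1
    interactome normalised by their own +1 size (so hubs are not trivially
    favoured); the top decile is the enriched pool.  Each hit comes from the
    enriched pool with probability ``enrichment``, otherwise uniformly from
    the remaining universe genes.

    Planting is structural: ``network`` is modified in place, wiring each
    enriched hit to randomly chosen non-seed members of the GWAS +1
    interactome until its own +1 neighbourhood is large and almost entirely
    contained in the reference (reference membership itself is unchanged).
    Selection alone cannot plant a recoverable signal — on a null network
    only a few percent of genes have genuinely anomalous overlap — so the
    enrichment must be written into the graph.  Returns
    (gwas, hits, truth, universe).
    """
    if rng is None:
        rng = derive_rng(spec.rng_seed, "plant_lists")
    genes = sorted(network.genes)
    n_universe = int(round(spec.universe_fraction * len(genes)))
    n_universe = max(1, min(n_universe, len(genes)))
    uni_idx = rng.choice(len(genes), size=n_universe, replace=False)
    universe_genes = sorted(genes[i] for i in uni_idx)

    gwas_idx = rng.choice(len(genes), size=spec.gwas_size, replace=False)
    gwas_genes = sorted(genes[i] for i in gwas_idx)
    gwas_set = set(gwas_genes)
    gwas_p1 = plus_one(network, gwas_genes)

    pool = [g for g in universe_genes if g not in gwas_set]
    if len(pool) < spec.hit_size:
        raise ParameterError("universe (outside GWAS) smaller than hit_size")

    def score(g: str) -> float:
        members = network.plus_one_members(g)
        return len(members & gwas_p1.members) / len(members)

    ranked = sorted(pool, key=lambda g: (-score(g), g))
    n_enriched_pool = max(1, len(pool) // 10)
    enriched_pool = ranked[:n_enriched_pool]
    null_pool = ranked[n_enriched_pool:]

    flags = rng.random(spec.hit_size) < spec.enrichment
    n_enr = int(flags.sum())
    n_null = spec.hit_size - n_enr
    if n_enr > len(enriched_pool):
        raise SimulationError(
            f"enriched pool ({len(enriched_pool)}) smaller than required draws ({n_enr})",
            len(enriched_pool),
        )
    if n_null > len(null_pool):
        raise SimulationError(
            f"null pool ({len(null_pool)}) smaller than required draws ({n_null})",
            len(null_pool),
        )
    enr_draw = [enriched_pool[i] for i in rng.choice(len(enriched_pool), n_enr, replace=False)]
    null_draw = [null_pool[i] for i in rng.choice(len(null_pool), n_null, replace=False)]
    hits: list[str] = []
    it_enr, it_null = iter(enr_draw), iter(null_draw)
    for flag in flags:
        hits.append(next(it_enr) if flag else next(it_null))

    # structural boost of the enriched hits (in place)
    nonseed_members = sorted(gwas_p1.members - gwas_p1.seeds)
    for g in sorted(enr_draw):
        members = network.plus_one_members(g)
        s0 = len(members)
        o0 = len(members & gwas_p1.members)
        k = max(
            _BOOST_MIN_SIZE - s0,
            int(np.ceil((_BOOST_MIN_FRAC * s0 - o0) / (1.0 - _BOOST_MIN_FRAC))),
        )
        cands = [t for t in nonseed_members if t != g and t not in network.neighbors(g)]
        k = min(max(k, 0), len(cands))
        if k:
            for i in rng.choice(len(cands), size=k, replace=False):
                network.add_edge(g, cands[i])

    truth = PlantedTruth(
        enriched_hits=frozenset(enr_draw), null_hits=frozenset(null_draw)
    )
    return (
        GeneList("gwas", tuple(gwas_genes), provenance="synthetic"),
        GeneList("hits", tuple(hits), provenance="synthetic"),
        truth,
        GeneList("universe", tuple(universe_genes), provenance="synthetic"),
    )


# ---------------------------------------------------------------------------
# Fixture bundle I/O

_BIOGRID_HEADER = (
    "#BioGRID Interaction ID\tOfficial Symbol Interactor A\t"
    "Official Symbol Interactor B\tExperimental System Type\t"
    "Organism Interactor A\tOrganism Interactor B"
)


def write_fixture_bundle(
    network: InteractionNetwork,
    gwas: GeneList,
    hits: GeneList,
    universe: GeneList,
    truth: PlantedTruth,
    spec: SyntheticSpec,
    outdir: str | Path,
    taxid: int = 9606,
) -> Path:
    """Serialise a synthetic study to plain-text files readable by data_io.

    Writes a BioGRID-TAB-style interaction file, gene lists (the hit list as
    worm-style symbols), an orthology TSV mapping worm symbols to human ones
    at 100% identity for every universe gene, and a key=value manifest
    recording the generating parameters and planted truth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    with open(outdir / "interactions.tsv", "w", encoding="utf-8") as fh:
        fh.write(_BIOGRID_HEADER + "\n")
        for i, (a, b) in enumerate(sorted(network.edge_iter()), start=1):
            fh.write(f"{i}\t{a}\t{b}\t{CATEGORY_PHYSICAL}\t{taxid}\t{taxid}\n")

    def _write_list(name: str, genes) -> None:
        with open(outdir / name, "w", encoding="utf-8") as fh:
            fh.write(f"# synthetic gene list (seed {spec.rng_seed})\n")
            for g in genes:
                fh.write(g + "\n")

    _write_list("gwas.txt", gwas.genes)
    _write_list("universe.txt", universe.genes)
    _write_list("worm_hits.txt", [WORM_PREFIX + g for g in hits.genes])

    with open(outdir / "orthology.tsv", "w", encoding="utf-8") as fh:
        fh.write("worm_gene\thuman_gene\tpercent_identity\tconsistency_score\n")
        for g in universe.genes:
            fh.write(f"{WORM_PREFIX}{g}\t{g}\t100.0\t1.0\n")

    with open(outdir / "manifest.txt", "w", encoding="utf-8") as fh:
        for key, value in asdict(spec).items():
            fh.write(f"{key}={value}\n")
        fh.write("enriched_hits=" + ",".join(sorted(truth.enriched_hits)) + "\n")
        fh.write("null_hits=" + ",".join(sorted(truth.null_hits)) + "\n")
    return outdir


def read_fixture_bundle(bundle_dir: str | Path, taxid: int = 9606) -> SimpleNamespace:
    """Reconstruct the objects of a fixture bundle written by
    :func:`write_fixture_bundle`."""
    bundle_dir = Path(bundle_dir)
    records = read_biogrid(bundle_dir / "interactions.tsv", taxid=taxid)
    network = build_network(records)
    gwas = read_gene_list(bundle_dir / "gwas.txt", name="gwas")
    universe = read_gene_list(bundle_dir / "universe.txt", name="universe")
    worm_hits = read_gene_list(bundle_dir / "worm_hits.txt", name="worm_hits")

    manifest: dict[str, str] = {}
    with open(bundle_dir / "manifest.txt", "r", encoding="utf-8") as fh:
        for line in fh:
            if "=" in line:
                key, _, value = line.rstrip("\n").partition("=")
                manifest[key] = value
    spec = SyntheticSpec(
        n_genes=int(manifest["n_genes"]),
        m=int(manifest["m"]),
        universe_fraction=float(manifest["universe_fraction"]),
        gwas_size=int(manifest["gwas_size"]),
        hit_size=int(manifest["hit_size"]),
        enrichment=float(manifest["enrichment"]),
        rng_seed=int(manifest["rng_seed"]),
    )
    truth = PlantedTruth(
        enriched_hits=frozenset(filter(None, manifest["enriched_hits"].split(","))),
        null_hits=frozenset(filter(None, manifest["null_hits"].split(","))),
    )
    hits = GeneList(
        "hits",
        tuple(g[len(WORM_PREFIX):] for g in worm_hits.genes),
        provenance=str(bundle_dir / "worm_hits.txt"),
    )
    orthology = [
        OrthologyCandidate(WORM_PREFIX + g, g, 100.0, 1.0) for g in universe.genes
    ]
    return SimpleNamespace(
        network=network,
        gwas=gwas,
        hits=hits,
        worm_hits=worm_hits,
        universe=universe,
        truth=truth,
        spec=spec,
        orthology=orthology,
    )
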