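"""Size-matched random +1 interactome Monte Carlo overlap tests.

The question asked per screen-hit gene g is whether the overlap between g's
+1 interactome and a fixed reference (+1 interactome of a GWAS candidate
list) is larger or smaller than chance.  Because screen hits are biased
toward hub genes, the null model is size-matched: each random replicate is a
+1 interactome of exactly the same member count as g's, grown from randomly
drawn universe genes (the human genes with worm orthologues).

For each gene, n_sim replicates give a Monte Carlo overlap distribution;
n_right counts replicates with overlap >= observed, n_left those with
overlap <= observed (equality counts in BOTH tails, which makes the p-value
conservative).  The empirical p is the smaller tail count over n_sim,
floored at 1/n_sim, and the reported direction is "larger" when the right
tail is the smaller one.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from netoverlap._rng import derive_rng
from netoverlap.data_io import GeneList, InteractionNetwork
from netoverlap.errors import ParameterError, SimulationError
from netoverlap.interactome import PlusOneInteractome, plus_one

__all__ = [
    "MCConfig",
    "OverlapTestResult",
    "ListLevelResult",
    "random_plus_one",
    "overlap_test",
    "screen_overlap_tests",
    "null_list_significance",
]

logger = logging.getLogger(__name__)

DIRECTION_LARGER = "larger"
DIRECTION_SMALLER = "smaller"


@dataclass(frozen=True)
class MCConfig:
    """Monte Carlo settings.

    Defaults are the reference analysis conditions: 1000 replicates per
    gene, 100 random lists of 60 genes for list-level significance, and a
    0.05 significance threshold.  ``mid_p`` switches to the mid-p variant
    (half weight on ties); it is off by default.
    """

    n_sim: int = 1000
    n_lists: int = 100
    list_size: int = 60
    alpha: float = 0.05
    rng_seed: int = 0
    mid_p: bool = False

    def __post_init__(self):
        if self.n_sim < 1:
            raise ParameterError(f"n_sim must be >= 1, got {self.n_sim}")
        if self.list_size < 1:
            raise ParameterError(f"list_size must be >= 1, got {self.list_size}")
        if not 0.0 < self.alpha < 1.0:
            raise ParameterError(f"alpha must lie in (0, 1), got {self.alpha}")


@dataclass(frozen=True)
class OverlapTestResult:
    gene: str
    observed: int
    n_right: int
    n_left: int
    p: float
    direction: str
    direct_interactor: bool = False

    def __post_init__(self):
        if self.direction not in (DIRECTION_LARGER, DIRECTION_SMALLER):
            raise ValueError(f"invalid direction {self.direction!r}")


@dataclass(frozen=True)
class ListLevelResult:
    """Distribution of per-list significant-gene counts under the null."""

    counts_per_list: tuple[int, ...]
    mean: float
    ci95_halfwidth: float
    p_ge_k: float
    k_observed: int


def _universe_pool(network: InteractionNetwork, universe: GeneList | Iterable[str]) -> list[str]:
    pool = [g.strip().upper() for g in universe]
    pool = sorted({g for g in pool if g in network})
    return pool


def random_plus_one(
    network: InteractionNetwork,
    universe: GeneList | Iterable[str] | Sequence[str],
    target_size: int,
    rng: np.random.Generator,
) -> frozenset[str]:
    """Grow one random +1 interactome of exactly ``target_size`` genes.

    Universe genes are drawn uniformly without replacement; each drawn
    gene's +1 members are unioned into the accumulator (already-present
    genes contribute nothing).  The final gene's contribution is truncated —
    its new members are added in rng-shuffled order — the moment the
    accumulator reaches the target.  Exhausting the universe first raises
    :class:`SimulationError` carrying the achieved size.
    """
    if target_size < 1:
        raise ParameterError(f"target_size must be >= 1, got {target_size}")
    pool = universe if isinstance(universe, list) else _universe_pool(network, universe)
    if not pool:
        raise SimulationError("universe contains no gene present in the network", 0)

    acc: set[str] = set()
    order = rng.permutation(len(pool))
    for idx in order:
        members = network.plus_one_members(pool[idx])
        new = members - acc
        if not new:
            continue
        room = target_size - len(acc)
        if len(new) <= room:
            acc |= new
        else:
            new_sorted = sorted(new)
            take = rng.permutation(len(new_sorted))[:room]
            acc.update(new_sorted[i] for i in take)
        if len(acc) >= target_size:
            return frozenset(acc)
    raise SimulationError(
        f"universe exhausted at size {len(acc)} before reaching target {target_size}",
        len(acc),
    )


def overlap_test(
    network: InteractionNetwork,
    worm_gene: str,
    gwas_p1: PlusOneInteractome,
    universe: GeneList | Iterable[str],
    cfg: MCConfig,
    rng: np.random.Generator,
) -> OverlapTestResult:
    """Monte Carlo overlap test for a single gene.

    The observed statistic is |(+1 of {gene}) ∩ (reference members)|; the
    null replicates are size-matched random +1 interactomes drawn from the
    universe.  One-tailed construction: p = min(n_right, n_left) / n_sim.
    """
    gene = worm_gene.strip().upper()
    if gene not in network:
        raise KeyError(f"gene {gene!r} is not present in the network")
    pool = universe if isinstance(universe, list) else _universe_pool(network, universe)
    own = network.plus_one_members(gene)
    target = len(own)
    reference = gwas_p1.members
    observed = len(own & reference)

    n_right = 0
    n_left = 0
    for _ in range(cfg.n_sim):
        sim = random_plus_one(network, pool, target, rng)
        ov = len(sim & reference)
        if ov >= observed:
            n_right += 1
        if ov <= observed:
            n_left += 1

    n_ties = n_right + n_left - cfg.n_sim
    min_tail = min(n_right, n_left)
    if cfg.mid_p:
        p = (min_tail - 0.5 * n_ties) / cfg.n_sim
    else:
        p = min_tail / cfg.n_sim
    p = min(max(p, 1.0 / cfg.n_sim), 1.0)
    if n_right == n_left:
        logger.debug("overlap_test(%s): exact tail tie, direction set to larger", gene)
    direction = DIRECTION_LARGER if n_right <= n_left else DIRECTION_SMALLER
    return OverlapTestResult(
        gene=gene,
        observed=observed,
        n_right=n_right,
        n_left=n_left,
        p=p,
        direction=direction,
    )


def screen_overlap_tests(
    network: InteractionNetwork,
    worm_list: GeneList | Iterable[str],
    gwas_list: GeneList | Iterable[str],
    universe: GeneList | Iterable[str],
    cfg: MCConfig,
    rng: np.random.Generator | None = None,
) -> list[OverlapTestResult]:
    """Run :func:`overlap_test` for every gene of a screen-hit list.

    Genes absent from the network are skipped with a warning, mirroring a
    database snapshot missing some symbols.  Each result also flags whether
    the gene's product interacts *directly* with any gene of the reference
    list (the asterisk column of the headline results table).  Output is
    sorted by ascending p, ties by gene symbol.
    """
    if rng is None:
        rng = derive_rng(cfg.rng_seed, "screen_overlap_tests")
    gwas_p1 = plus_one(network, gwas_list)
    gwas_seeds = gwas_p1.seeds
    pool = _universe_pool(network, universe)

    results: list[OverlapTestResult] = []
    for gene in worm_list:
        gene = gene.strip().upper()
        if gene not in network:
            logger.warning("screen gene %s absent from network; skipped", gene)
            continue
        res = overlap_test(network, gene, gwas_p1, pool, cfg, rng)
        direct = bool(network.neighbors(gene) & gwas_seeds) or gene in gwas_seeds
        results.append(replace(res, direct_interactor=direct))
    results.sort(key=lambda r: (r.p, r.gene))
    return results


def null_list_significance(
    network: InteractionNetwork,
    universe: GeneList | Iterable[str],
    gwas_p1: PlusOneInteractome,
    cfg: MCConfig,
    k_observed: int,
    rng: np.random.Generator | None = None,
) -> ListLevelResult:
    """List-level significance by repeating the screen on random gene lists.

    Draws ``cfg.n_lists`` random lists of ``cfg.list_size`` genes (uniform,
    without replacement, from universe genes present in the network), runs
    the per-gene overlap test on each, and counts genes with p < alpha per
    list.  Reports the mean count, a normal-approximation 95% CI half-width
    (1.96 * sd / sqrt(n_lists)) and the fraction of lists reaching at least
    ``k_observed`` significant genes.
    """
    if k_observed < 0:
        raise ParameterError(f"k_observed must be >= 0, got {k_observed}")
    if rng is None:
        rng = derive_rng(cfg.rng_seed, "null_list_significance")
    pool = _universe_pool(network, universe)
    if len(pool) < cfg.list_size:
        raise ParameterError(
            f"universe has only {len(pool)} genes in the network; "
            f"cannot draw lists of {cfg.list_size}"
        )

    counts: list[int] = []
    for _ in range(cfg.n_lists):
        idx = rng.choice(len(pool), size=cfg.list_size, replace=False)
        n_sig = 0
        for i in idx:
            res = overlap_test(network, pool[i], gwas_p1, pool, cfg, rng)
            if res.p < cfg.alpha:
                n_sig += 1
        counts.append(n_sig)

    arr = np.asarray(counts, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    halfwidth = 1.96 * sd / np.sqrt(len(arr)) if len(arr) > 1 else 0.0
    p_ge_k = float(np.mean(arr >= k_observed))
    return ListLevelResult(
        counts_per_list=tuple(counts),
        mean=mean,
        ci95_halfwidth=float(halfwidth),
        p_ge_k=p_ge_k,
        k_observed=k_observed,
    )
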