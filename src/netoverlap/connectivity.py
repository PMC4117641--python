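"""Connectivity-bias analysis: degree ranking, universe-balanced binning,
log-log slope fits, and Monte Carlo slope comparison.

Screen-hit lists tend to be enriched for hub genes.  To quantify that bias,
all network genes are ranked by interactor count (descending) and split into
bins each holding the same number of *universe* genes (human genes with worm
orthologues), so a random universe list lands uniformly across bins.  A gene
list's per-bin fractions on a log-log plot against the bin rank boundaries
are then summarised by an OLS slope: ~0 for a random list, negative for a
hub-skewed list.  Significance comes from a one-sample Student's t-test of
Monte Carlo random-list slopes against the experimental slope.
"""
from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from netoverlap._rng import derive_rng
from netoverlap.data_io import GeneList, InteractionNetwork
from netoverlap.errors import FitError, ParameterError
from netoverlap.mc_overlap import MCConfig

__all__ = [
    "DegreeRanking",
    "BinningScheme",
    "BinProfile",
    "SlopeFit",
    "SlopeComparison",
    "rank_by_degree",
    "make_bins",
    "bin_profile",
    "loglog_slope",
    "slope_comparison",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DegreeRanking:
    """Genes ordered by degree descending, ties lexicographic; ranks 1-based."""

    order: tuple[tuple[str, int], ...]
    rank: dict[str, int]

    def __len__(self) -> int:
        return len(self.order)


@dataclass(frozen=True)
class BinningScheme:
    """Contiguous rank intervals, each holding ~equal numbers of universe genes."""

    n_bins: int
    boundaries: tuple[tuple[int, int], ...]  # inclusive [lo, hi] rank intervals
    universe_per_bin: int
    universe_counts: tuple[int, ...]

    def bin_of_rank(self, rank: int) -> int:
        """0-based bin index containing a 1-based rank."""
        los = [lo for lo, _ in self.boundaries]
        i = bisect.bisect_right(los, rank) - 1
        lo, hi = self.boundaries[i]
        if not lo <= rank <= hi:
            raise ValueError(f"rank {rank} outside binning scheme")
        return i


@dataclass(frozen=True)
class BinProfile:
    counts: tuple[int, ...]
    fractions: tuple[float, ...]
    missing: tuple[str, ...] = ()


@dataclass(frozen=True)
class SlopeFit:
    slope: float
    intercept: float
    n_points: int
    excluded_bins: tuple[int, ...] = ()


@dataclass(frozen=True)
class SlopeComparison:
    experimental_slope: float
    mc_slopes: tuple[float, ...]
    t_statistic: float
    p: float
    tails: str
    n_dropped: int = 0


def rank_by_degree(network: InteractionNetwork) -> DegreeRanking:
    """Total order over all network genes by interactor count, descending."""
    if network.n_genes == 0:
        raise ParameterError("cannot rank an empty network")
    order = sorted(network.genes, key=lambda g: (-network.degree(g), g))
    pairs = tuple((g, network.degree(g)) for g in order)
    rank = {g: i + 1 for i, (g, _) in enumerate(pairs)}
    return DegreeRanking(order=pairs, rank=rank)


def make_bins(
    ranking: DegreeRanking,
    universe: GeneList | Iterable[str],
    n_bins: int = 10,
) -> BinningScheme:
    """Split the ranking into ``n_bins`` intervals of equal universe content.

    Walking from rank 1, a bin closes at the rank of the gene that completes
    its universe quota; the last bin absorbs the ranking tail.  When the
    universe size is not divisible by ``n_bins`` the remainder is spread one
    gene per bin over the earliest bins.
    """
    universe_set = {g.strip().upper() for g in universe}
    in_ranking = [g for g, _ in ranking.order if g in universe_set]
    n_universe = len(in_ranking)
    if n_universe < n_bins:
        raise ParameterError(
            f"universe has {n_universe} ranked genes, fewer than n_bins={n_bins}"
        )
    base, rem = divmod(n_universe, n_bins)
    quotas = [base + 1] * rem + [base] * (n_bins - rem)

    boundaries: list[tuple[int, int]] = []
    lo = 1
    bin_idx = 0
    seen = 0
    for pos, (gene, _) in enumerate(ranking.order, start=1):
        if bin_idx >= n_bins - 1:
            break
        if gene in universe_set:
            seen += 1
            if seen == quotas[bin_idx]:
                boundaries.append((lo, pos))
                lo = pos + 1
                bin_idx += 1
                seen = 0
    boundaries.append((lo, len(ranking)))
    return BinningScheme(
        n_bins=n_bins,
        boundaries=tuple(boundaries),
        universe_per_bin=base,
        universe_counts=tuple(quotas),
    )


def bin_profile(
    scheme: BinningScheme,
    ranking: DegreeRanking,
    gene_list: GeneList | Iterable[str],
) -> BinProfile:
    """Per-bin counts and fractions for a gene list.

    Fractions are relative to the *full* list size, so genes absent from the
    ranking (logged in ``missing``) push the fraction sum below 1.
    """
    genes = [g.strip().upper() for g in gene_list]
    counts = [0] * scheme.n_bins
    missing: list[str] = []
    for g in genes:
        r = ranking.rank.get(g)
        if r is None:
            missing.append(g)
            continue
        counts[scheme.bin_of_rank(r)] += 1
    if missing:
        logger.info("bin_profile: %d gene(s) absent from the ranking", len(missing))
    n = len(genes)
    fractions = tuple(c / n for c in counts)
    return BinProfile(counts=tuple(counts), fractions=fractions, missing=tuple(missing))


def loglog_slope(
    profile: BinProfile,
    scheme: BinningScheme,
    boundary: str = "upper",
) -> SlopeFit:
    """OLS of log10(bin fraction) on log10(bin rank boundary).

    Zero-count bins are excluded (their log is undefined) and listed in the
    fit.  ``boundary`` selects the upper (default) or lower rank boundary of
    each bin as the x-coordinate; the slope, not the intercept, is the
    quantity of interest and a flat profile gives slope 0 either way.
    """
    if boundary not in ("upper", "lower"):
        raise ParameterError(f"boundary must be 'upper' or 'lower', got {boundary!r}")
    xs: list[float] = []
    ys: list[float] = []
    excluded: list[int] = []
    for i, frac in enumerate(profile.fractions):
        if frac <= 0.0:
            excluded.append(i)
            continue
        lo, hi = scheme.boundaries[i]
        x = hi if boundary == "upper" else lo
        xs.append(np.log10(x))
        ys.append(np.log10(frac))
    if len(xs) < 2:
        raise FitError(f"only {len(xs)} nonzero bin(s); need at least 2 for a fit")
    if len(set(xs)) == 1:
        raise FitError("degenerate fit: all usable bins share one boundary")
    fit = stats.linregress(xs, ys)
    return SlopeFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n_points=len(xs),
        excluded_bins=tuple(excluded),
    )


def _fit_list_slope(
    genes: Sequence[str],
    ranking: DegreeRanking,
    scheme: BinningScheme,
    boundary: str,
) -> float:
    profile = bin_profile(scheme, ranking, genes)
    return loglog_slope(profile, scheme, boundary=boundary).slope


def slope_comparison(
    network: InteractionNetwork,
    universe: GeneList | Iterable[str],
    scheme: BinningScheme,
    experimental_list: GeneList | Iterable[str],
    cfg: MCConfig,
    tails: str = "two",
    ranking: DegreeRanking | None = None,
    boundary: str = "upper",
    rng: np.random.Generator | None = None,
) -> SlopeComparison:
    """Compare an experimental list's log-log slope with random-list slopes.

    ``cfg.n_lists`` random lists of the experimental list's size are drawn
    from the universe (without replacement within a list); each is fitted
    and the Monte Carlo slope sample is tested against the experimental
    slope with a one-sample Student's t-test.  ``tails='two'`` asks whether
    the experimental slope differs from the MC slopes; ``tails='one'`` asks
    whether it is *below* them (the hub-bias direction).  Replicates whose
    fit fails (fewer than 2 nonzero bins) are dropped with a warning; fewer
    than 10 survivors is an error.
    """
    if tails not in ("one", "two"):
        raise ParameterError(f"tails must be 'one' or 'two', got {tails!r}")
    if ranking is None:
        ranking = rank_by_degree(network)
    if rng is None:
        rng = derive_rng(cfg.rng_seed, "slope_comparison")

    exp_genes = [g.strip().upper() for g in experimental_list]
    exp_slope = _fit_list_slope(exp_genes, ranking, scheme, boundary)

    pool = sorted({g.strip().upper() for g in universe} & set(ranking.rank))
    if len(pool) < len(exp_genes):
        raise ParameterError("universe smaller than the experimental list")

    mc_slopes: list[float] = []
    n_dropped = 0
    for _ in range(cfg.n_lists):
        idx = rng.choice(len(pool), size=len(exp_genes), replace=False)
        try:
            mc_slopes.append(_fit_list_slope([pool[i] for i in idx], ranking, scheme, boundary))
        except FitError:
            n_dropped += 1
    if n_dropped:
        logger.warning("slope_comparison: dropped %d failed MC fit(s)", n_dropped)
    if len(mc_slopes) < 10:
        raise FitError(
            f"only {len(mc_slopes)} surviving MC slope fits; need at least 10"
        )

    t_stat, p = slope_t_test(mc_slopes, exp_slope, tails)
    return SlopeComparison(
        experimental_slope=exp_slope,
        mc_slopes=tuple(mc_slopes),
        t_statistic=t_stat,
        p=p,
        tails=tails,
        n_dropped=n_dropped,
    )


def slope_t_test(
    mc_slopes: Sequence[float], experimental_slope: float, tails: str = "two"
) -> tuple[float, float]:
    """One-sample Student's t of an MC slope sample vs a reference slope.

    'two' tests a difference in either direction; 'one' tests whether the MC
    mean exceeds the experimental slope, i.e. whether the experimental slope
    is significantly more negative than random (the hub-bias direction).
    """
    if tails not in ("one", "two"):
        raise ParameterError(f"tails must be 'one' or 'two', got {tails!r}")
    alternative = "two-sided" if tails == "two" else "greater"
    res = stats.ttest_1samp(mc_slopes, popmean=experimental_slope, alternative=alternative)
    return float(res.statistic), float(min(max(res.pvalue, np.finfo(float).tiny), 1.0))
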