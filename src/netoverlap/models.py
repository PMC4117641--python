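"""Model/Results front end.

Two model classes organise the analysis the way statsmodels organises a
regression: a model object is built from the data (network + gene lists),
``fit()`` does the Monte Carlo work, and the returned Results object carries
the estimates, their uncertainties and a ``summary()`` table; simulation and
plotting hang off the Results.

``OverlapScreenModel``   — per-gene +1 interactome overlap tests against a
                           reference (GWAS-style) list, with list-level
                           significance via ``Results.simulate_null_lists``.
``ConnectivityBiasModel`` — degree-rank binning, log-log slope and Monte
                           Carlo slope comparison for a gene list.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from netoverlap._rng import derive_rng
from netoverlap.connectivity import (
    BinningScheme,
    BinProfile,
    DegreeRanking,
    SlopeComparison,
    SlopeFit,
    bin_profile,
    loglog_slope,
    make_bins,
    rank_by_degree,
    slope_comparison,
)
from netoverlap.data_io import GeneList, InteractionNetwork, write_results_table
from netoverlap.interactome import PlusOneInteractome, plus_one
from netoverlap.mc_overlap import (
    ListLevelResult,
    MCConfig,
    OverlapTestResult,
    null_list_significance,
    screen_overlap_tests,
)

__all__ = [
    "OverlapScreenModel",
    "OverlapScreenResults",
    "ConnectivityBiasModel",
    "ConnectivityBiasResults",
]


def _as_gene_list(obj, name: str) -> GeneList:
    if isinstance(obj, GeneList):
        return obj
    return GeneList.from_iterable(name, obj)


class OverlapScreenModel:
    """Size-matched Monte Carlo +1 overlap screen.

    Parameters
    ----------
    network : InteractionNetwork
        The interaction substrate.
    hits : GeneList or iterable of str
        Screen-hit genes (human symbols, e.g. mapped orthologues).
    reference : GeneList or iterable of str
        The reference candidate list (e.g. GWAS white+grey zone genes); its
        +1 interactome is computed once and held fixed.
    universe : GeneList or iterable of str
        Genes eligible as random seeds (orthologue universe); restricted to
        network members internally.
    config : MCConfig, optional
        Monte Carlo settings (n_sim, alpha, seed, ...).
    """

    def __init__(self, network: InteractionNetwork, hits, reference, universe,
                 config: MCConfig | None = None):
        self.network = network
        self.hits = _as_gene_list(hits, "hits")
        self.reference = _as_gene_list(reference, "reference")
        self.universe = _as_gene_list(universe, "universe")
        self.config = config or MCConfig()
        self.reference_p1: PlusOneInteractome = plus_one(network, self.reference)

    def fit(self, rng=None) -> "OverlapScreenResults":
        results = screen_overlap_tests(
            self.network, self.hits, self.reference, self.universe, self.config, rng=rng
        )
        return OverlapScreenResults(model=self, results=tuple(results))


@dataclass(frozen=True)
class OverlapScreenResults:
    model: OverlapScreenModel
    results: tuple[OverlapTestResult, ...]
    _list_level: list = field(default_factory=list, repr=False)

    @property
    def table(self) -> pd.DataFrame:
        rows = [
            {
                "gene": r.gene,
                "p_value": r.p,
                "direction": r.direction,
                "direct_interactor": r.direct_interactor,
                "observed": r.observed,
                "n_right": r.n_right,
                "n_left": r.n_left,
            }
            for r in self.results
        ]
        return pd.DataFrame(rows)

    def significant(self, alpha: float | None = None) -> tuple[OverlapTestResult, ...]:
        alpha = self.model.config.alpha if alpha is None else alpha
        return tuple(r for r in self.results if r.p < alpha)

    @property
    def n_significant(self) -> int:
        return len(self.significant())

    def simulate_null_lists(self, k_observed: int | None = None, rng=None) -> ListLevelResult:
        """List-level significance: how often do random gene lists produce at
        least as many significant genes as observed?"""
        k = self.n_significant if k_observed is None else k_observed
        res = null_list_significance(
            self.model.network,
            self.model.universe,
            self.model.reference_p1,
            self.model.config,
            k_observed=k,
            rng=rng,
        )
        self._list_level.clear()
        self._list_level.append(res)
        return res

    def save(self, path) -> None:
        write_results_table(self.results, path)

    def summary(self) -> str:
        cfg = self.model.config
        sig = self.significant()
        n_larger = sum(1 for r in sig if r.direction == "larger")
        lines = [
            "Overlap screen (size-matched Monte Carlo null)",
            "=" * 54,
            f"genes tested:        {len(self.results)}",
            f"reference +1 size:   {self.model.reference_p1.size}",
            f"replicates per gene: {cfg.n_sim}",
            f"significant (p < {cfg.alpha:g}): {len(sig)} "
            f"({n_larger} larger, {len(sig) - n_larger} smaller)",
            "-" * 54,
            f"{'gene':<14}{'p':>8}  {'direction':<11}{'direct':<8}{'overlap':>7}",
        ]
        for r in self.results:
            lines.append(
                f"{r.gene:<14}{r.p:>8.3f}  {r.direction:<11}"
                f"{'*' if r.direct_interactor else '':<8}{r.observed:>7d}"
            )
        if self._list_level:
            ll = self._list_level[-1]
            lines += [
                "-" * 54,
                f"null lists: mean significant {ll.mean:.2f} "
                f"(95% CI ±{ll.ci95_halfwidth:.2f}); "
                f"P(count >= {ll.k_observed}) = {ll.p_ge_k:.2f}",
            ]
        return "\n".join(lines)

    def plot_null(self, gene: str, ax=None):
        """Histogram of p-values is not stored per gene; plot the screen's
        p-value distribution instead."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist([r.p for r in self.results], bins=20, color="0.6", edgecolor="k")
        ax.set_xlabel("empirical p")
        ax.set_ylabel("genes")
        ax.set_title("Per-gene overlap p-values")
        return ax


class ConnectivityBiasModel:
    """Degree-rank binning and log-log slope analysis for a gene list.

    The network's genes are ranked by interactor count and split into
    ``n_bins`` bins each holding the same number of universe genes, so random
    universe lists spread flat across bins (slope ~ 0) while hub-enriched
    lists fall off with a negative slope.
    """

    def __init__(self, network: InteractionNetwork, gene_list, universe,
                 n_bins: int = 10, config: MCConfig | None = None,
                 tails: str = "two", boundary: str = "upper"):
        self.network = network
        self.gene_list = _as_gene_list(gene_list, "experimental")
        self.universe = _as_gene_list(universe, "universe")
        self.n_bins = n_bins
        self.config = config or MCConfig()
        self.tails = tails
        self.boundary = boundary

    def fit(self, rng=None) -> "ConnectivityBiasResults":
        ranking = rank_by_degree(self.network)
        scheme = make_bins(ranking, self.universe, n_bins=self.n_bins)
        profile = bin_profile(scheme, ranking, self.gene_list)
        fit = loglog_slope(profile, scheme, boundary=self.boundary)
        comparison = slope_comparison(
            self.network,
            self.universe,
            scheme,
            self.gene_list,
            self.config,
            tails=self.tails,
            ranking=ranking,
            boundary=self.boundary,
            rng=rng,
        )
        return ConnectivityBiasResults(
            model=self,
            ranking=ranking,
            scheme=scheme,
            profile=profile,
            slope_fit=fit,
            comparison=comparison,
        )


@dataclass(frozen=True)
class ConnectivityBiasResults:
    model: ConnectivityBiasModel
    ranking: DegreeRanking
    scheme: BinningScheme
    profile: BinProfile
    slope_fit: SlopeFit
    comparison: SlopeComparison

    @property
    def binning_table(self) -> pd.DataFrame:
        rows = []
        for i, (lo, hi) in enumerate(self.scheme.boundaries):
            rows.append(
                {
                    "bin": i + 1,
                    "rank_lo": lo,
                    "rank_hi": hi,
                    "universe_genes": self.scheme.universe_counts[i],
                    "list_count": self.profile.counts[i],
                    "list_fraction": self.profile.fractions[i],
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        mc = np.asarray(self.comparison.mc_slopes)
        lines = [
            "Connectivity-bias analysis (degree-rank binning)",
            "=" * 54,
            f"network genes ranked:   {len(self.ranking)}",
            f"bins (universe-equal):  {self.scheme.n_bins} "
            f"x {self.scheme.universe_per_bin} universe genes",
            f"list genes binned:      {sum(self.profile.counts)} "
            f"of {len(self.model.gene_list)}",
            f"experimental slope:     {self.slope_fit.slope:+.3f}",
            f"MC slopes (n={len(mc)}):     {mc.mean():+.3f} +/- {mc.std(ddof=1):.3f}",
            f"t = {self.comparison.t_statistic:+.3f}, "
            f"p = {self.comparison.p:.4g} ({self.comparison.tails}-tailed)",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Log-log plot of bin fraction vs bin rank boundary with the fitted
        line and the MC mean profile."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        xs = [hi for _, hi in self.scheme.boundaries]
        ys = list(self.profile.fractions)
        ax.plot(xs, ys, "kd", label="experimental")
        grid = np.log10([x for x, y in zip(xs, ys) if y > 0])
        line = self.slope_fit.intercept + self.slope_fit.slope * grid
        ax.plot(10 ** grid, 10 ** line, "k--",
                label=f"slope {self.slope_fit.slope:+.2f}")
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.set_xlabel("gene rank bin boundary")
        ax.set_ylabel("fraction of list")
        ax.legend()
        return ax
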