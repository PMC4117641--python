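"""Orthologue selection and orthologue-enrichment testing.

A worm gene may have several candidate human orthologues, each annotated with
the percent amino-acid identity to the query and a cross-database consistency
score in [0, 1] (1 = the orthology call is supported by every source
database).  Selection keeps, per worm gene, the candidate with the highest
identity at or above a minimum threshold (default 25%), breaking ties first
by consistency score and then — so that results are deterministic — by the
lexicographically smallest human symbol.

Enrichment of screen hits for orthologue-bearing genes is an exact one-sided
binomial test: with 7970 of ~20000 human protein-coding genes having worm
orthologues, observing k mapped hits among n is tested against
X ~ Binomial(n, 7970/20000), upper tail.
"""
from __future__ import annotations

import logging
import numbers
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy import stats

from netoverlap.errors import ParameterError

__all__ = [
    "OrthologyCandidate",
    "OrthologyMap",
    "EnrichmentParams",
    "select_orthologues",
    "orthologue_enrichment",
    "read_orthology_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OrthologyCandidate:
    worm_gene: str
    human_gene: str
    percent_identity: float
    consistency_score: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "worm_gene", self.worm_gene.strip().upper())
        object.__setattr__(self, "human_gene", self.human_gene.strip().upper())
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ParameterError(
                f"percent_identity must lie in [0, 100], got {self.percent_identity}"
            )
        if not 0.0 <= self.consistency_score <= 1.0:
            raise ParameterError(
                f"consistency_score must lie in [0, 1], got {self.consistency_score}"
            )


@dataclass(frozen=True)
class OrthologyMap:
    """At most one human orthologue per worm gene; the rest are unmapped."""

    mapping: dict[str, str]
    unmapped: tuple[str, ...]

    @property
    def mapped_human_genes(self) -> tuple[str, ...]:
        # in worm-gene order, duplicates (two worm genes sharing an
        # orthologue) preserved for the caller to collapse
        return tuple(self.mapping.values())

    def __len__(self) -> int:
        return len(self.mapping)


@dataclass(frozen=True)
class EnrichmentParams:
    successes: int
    trials: int
    success_probability: float

    def __post_init__(self):
        if not 0 <= self.successes <= self.trials:
            raise ParameterError(
                f"need 0 <= successes <= trials, got k={self.successes}, n={self.trials}"
            )
        if not 0.0 < self.success_probability < 1.0:
            raise ParameterError(
                f"success_probability must lie in (0, 1), got {self.success_probability}"
            )


def select_orthologues(
    candidates: list[OrthologyCandidate], min_identity: float = 25.0
) -> OrthologyMap:
    """Pick one human orthologue per worm gene.

    Candidates below ``min_identity`` percent identity are discarded; among
    the survivors the highest identity wins, with consistency score as the
    tie-breaker and the lexicographically smallest human symbol as the
    (logged) residual tie-breaker.  Worm genes with no surviving candidate
    are reported as unmapped.
    """
    by_worm: dict[str, list[OrthologyCandidate]] = {}
    for cand in candidates:
        by_worm.setdefault(cand.worm_gene, []).append(cand)

    mapping: dict[str, str] = {}
    unmapped: list[str] = []
    for worm_gene, cands in by_worm.items():
        survivors = [c for c in cands if c.percent_identity >= min_identity]
        if not survivors:
            unmapped.append(worm_gene)
            continue
        ranked = sorted(
            survivors,
            key=lambda c: (-c.percent_identity, -c.consistency_score, c.human_gene),
        )
        best = ranked[0]
        if (
            len(ranked) > 1
            and ranked[1].percent_identity == best.percent_identity
            and ranked[1].consistency_score == best.consistency_score
        ):
            logger.info(
                "orthology tie for %s resolved lexicographically in favour of %s",
                worm_gene,
                best.human_gene,
            )
        mapping[worm_gene] = best.human_gene
    return OrthologyMap(mapping=mapping, unmapped=tuple(unmapped))


def orthologue_enrichment(params: EnrichmentParams | None = None, **kwargs) -> float:
    """Exact upper-tail binomial probability P(X >= k), X ~ Binomial(n, p0).

    Accepts an :class:`EnrichmentParams` or the keyword triplet
    ``successes``, ``trials``, ``success_probability``.
    """
    if params is None:
        params = EnrichmentParams(**kwargs)
    elif not isinstance(params, EnrichmentParams):
        raise TypeError("params must be an EnrichmentParams")
    k, n, p0 = params.successes, params.trials, params.success_probability
    if k == 0:
        return 1.0
    # survival function at k-1 gives P(X >= k); scipy evaluates the exact
    # regularised incomplete beta, no normal approximation involved
    p = float(stats.binom.sf(k - 1, n, p0))
    return min(max(p, 0.0), 1.0)


def read_orthology_table(path: str | Path) -> list[OrthologyCandidate]:
    """Read a TSV with columns worm_gene, human_gene, percent_identity,
    consistency_score (the last defaults to 1.0 when absent)."""
    frame = pd.read_csv(Path(path), sep="\t")
    required = {"worm_gene", "human_gene", "percent_identity"}
    missing = required - set(frame.columns)
    if missing:
        raise ParameterError(f"orthology table missing column(s): {sorted(missing)}")
    has_score = "consistency_score" in frame.columns
    out = []
    for row in frame.itertuples(index=False):
        score = float(getattr(row, "consistency_score")) if has_score else 1.0
        out.append(
            OrthologyCandidate(
                worm_gene=str(row.worm_gene),
                human_gene=str(row.human_gene),
                percent_identity=float(row.percent_identity),
                consistency_score=score,
            )
        )
    return out
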