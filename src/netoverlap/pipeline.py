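"""End-to-end orchestration: orthology -> network -> overlap tests ->
list-level significance -> connectivity analysis, with reports and a run log.
"""
from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

import netoverlap
from netoverlap.connectivity import rank_by_degree
from netoverlap.data_io import (
    CATEGORY_PHYSICAL,
    GeneList,
    build_network,
    read_biogrid,
    read_gene_list,
)
from netoverlap.errors import NetOverlapError
from netoverlap._rng import derive_rng
from netoverlap.mc_overlap import MCConfig
from netoverlap.models import ConnectivityBiasModel, OverlapScreenModel
from netoverlap.orthology import read_orthology_table, select_orthologues

__all__ = ["RunConfig", "PipelineStageError", "load_config", "full_run"]


class PipelineStageError(NetOverlapError):
    """Wraps an error with the name of the pipeline stage that raised it."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class RunConfig:
    """Paths and parameters of a full pipeline run.

    All statistical defaults are the reference analysis values (n_sim=1000,
    n_lists=100, list_size=60, alpha=0.05, min_identity=25, n_bins=10) and
    every one is overridable from the YAML config or CLI flags.
    """

    network: str = ""
    worm_list: str = ""
    gwas_list: str = ""
    universe: str = ""
    orthology: str = ""          # optional; empty = worm_list is already human symbols
    outdir: str = "netoverlap_run"
    taxid: int = 9606
    category: str = CATEGORY_PHYSICAL
    min_identity: float = 25.0
    n_sim: int = 1000
    n_lists: int = 100
    list_size: int = 60
    alpha: float = 0.05
    rng_seed: int = 0
    n_bins: int = 10
    boundary: str = "upper"
    tails: str = "two"

    def mc_config(self) -> MCConfig:
        return MCConfig(
            n_sim=self.n_sim,
            n_lists=self.n_lists,
            list_size=self.list_size,
            alpha=self.alpha,
            rng_seed=self.rng_seed,
        )


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from a YAML key/value file; unknown keys are an error."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    valid = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise NetOverlapError(f"unknown config key(s): {sorted(unknown)}")
    return RunConfig(**raw)


def _sha256(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


class _RunLog:
    def __init__(self):
        self.lines: list[str] = []

    def add(self, text: str) -> None:
        self.lines.append(text)

    def stage(self, name: str, seconds: float, detail: str) -> None:
        self.add(f"stage={name} wall_time_s={seconds:.2f} {detail}")

    def write(self, path: Path) -> None:
        path.write_text("\n".join(self.lines) + "\n", encoding="utf-8")


def full_run(config: RunConfig) -> dict:
    """Execute every stage and write the four reports.

    Outputs in ``config.outdir``: ``overlap_results.tsv`` (per-gene table),
    ``binning.tsv`` (rank-bin boundaries and profile), ``slope_comparison.tsv``
    and ``run_log.txt`` (seed, version, input checksums, per-stage timings and
    record counts, list-level significance).  Returns a dict of result
    objects and report paths.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = _RunLog()
    log.add(f"netoverlap version={netoverlap.__version__} rng_seed={config.rng_seed}")
    for label in ("network", "worm_list", "gwas_list", "universe", "orthology"):
        path = getattr(config, label)
        if path and Path(path).is_file():
            log.add(f"input {label}={path} sha256={_sha256(path)}")

    def run_stage(name, func):
        t0 = time.perf_counter()
        try:
            result, detail = func()
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineStageError(name, exc) from exc
        log.stage(name, time.perf_counter() - t0, detail)
        return result

    # -- orthology ----------------------------------------------------
    def _orthology():
        worm = read_gene_list(config.worm_list, name="worm_hits")
        if config.orthology:
            candidates = read_orthology_table(config.orthology)
            omap = select_orthologues(candidates, min_identity=config.min_identity)
            mapped = [omap.mapping[g] for g in worm.genes if g in omap.mapping]
            hits = GeneList.from_iterable("mapped_hits", mapped, provenance=config.worm_list)
            detail = (
                f"worm_genes={len(worm)} mapped={len(hits)} "
                f"unmapped={len(worm) - len([g for g in worm.genes if g in omap.mapping])}"
            )
        else:
            hits = worm
            detail = f"worm_genes={len(worm)} mapped={len(worm)} (no orthology table)"
        return hits, detail

    hits = run_stage("orthology", _orthology)

    # -- network ------------------------------------------------------
    def _network():
        records = read_biogrid(config.network, taxid=config.taxid, category=config.category)
        net = build_network(records)
        return net, f"records={len(records)} genes={net.n_genes} edges={net.n_edges}"

    network = run_stage("network", _network)

    def _gene_lists():
        gwas = read_gene_list(config.gwas_list, name="gwas")
        universe = read_gene_list(config.universe, name="universe")
        return (gwas, universe), f"gwas={len(gwas)} universe={len(universe)}"

    gwas, universe = run_stage("gene_lists", _gene_lists)
    cfg = config.mc_config()

    # -- per-gene overlap tests --------------------------------------
    def _overlap():
        model = OverlapScreenModel(network, hits, gwas, universe, config=cfg)
        res = model.fit(rng=derive_rng(config.rng_seed, "overlap"))
        res.save(outdir / "overlap_results.tsv")
        return res, (
            f"genes_tested={len(res.results)} significant={res.n_significant} "
            f"alpha={cfg.alpha}"
        )

    screen = run_stage("overlap", _overlap)

    # -- list-level significance --------------------------------------
    def _list_level():
        res = screen.simulate_null_lists(rng=derive_rng(config.rng_seed, "list_level"))
        detail = (
            f"n_lists={cfg.n_lists} list_size={cfg.list_size} "
            f"mean_significant={res.mean:.3f} ci95_halfwidth={res.ci95_halfwidth:.3f} "
            f"p_ge_{res.k_observed}={res.p_ge_k:.3f}"
        )
        return res, detail

    list_level = run_stage("list_level", _list_level)

    # -- connectivity --------------------------------------------------
    def _connectivity():
        model = ConnectivityBiasModel(
            network,
            hits,
            universe,
            n_bins=config.n_bins,
            config=cfg,
            tails=config.tails,
            boundary=config.boundary,
        )
        res = model.fit(rng=derive_rng(config.rng_seed, "connectivity"))
        res.binning_table.to_csv(outdir / "binning.tsv", sep="\t", index=False)
        comp = res.comparison
        import pandas as pd

        pd.DataFrame(
            [
                {
                    "experimental_slope": comp.experimental_slope,
                    "mc_mean_slope": sum(comp.mc_slopes) / len(comp.mc_slopes),
                    "mc_n": len(comp.mc_slopes),
                    "t_statistic": comp.t_statistic,
                    "p_value": comp.p,
                    "tails": comp.tails,
                    "n_dropped": comp.n_dropped,
                }
            ]
        ).to_csv(outdir / "slope_comparison.tsv", sep="\t", index=False)
        return res, (
            f"slope={res.slope_fit.slope:.3f} t={comp.t_statistic:.3f} p={comp.p:.4g}"
        )

    connectivity = run_stage("connectivity", _connectivity)

    log.write(outdir / "run_log.txt")
    return {
        "screen": screen,
        "list_level": list_level,
        "connectivity": connectivity,
        "reports": {
            "overlap_results": outdir / "overlap_results.tsv",
            "binning": outdir / "binning.tsv",
            "slope_comparison": outdir / "slope_comparison.tsv",
            "run_log": outdir / "run_log.txt",
        },
    }
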