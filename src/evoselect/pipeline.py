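"""End-to-end orchestration: projection to enrichment from one config.

The pipeline runs the numbered stages in order — volume-to-site
projection, expression/network correlation, domain clustering
(optional), omega preparation and matrix concatenation, per-branch
per-direction biclustering, top-bicluster summarization, and cell-type
enrichment — writing every intermediate in its standard format and a
manifest with file hashes and derived seeds.  All randomness descends
deterministically from one master seed, so a rerun with the same
inputs and seed reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as eio
from .datatypes import Bicluster, DomainAssignment
from .enrichment import (
    CRITICAL_Z,
    collapse,
    enrich_gene_set,
    percentile_filter,
    zscore_binarize,
)
from .gabi import (
    GabiParams,
    binarize,
    branch_thresholds,
    gabi_search,
    global_optim_loop,
    merge_biclusters,
)
from .postprocess import BranchDomainSummary, select_top, summarize
from .prep import (
    apply_omega_constraints,
    build_gene_pools,
    concatenate,
    filter_spatial_genes,
    rank_normalize_correlations,
    rank_normalize_omega,
)
from .projection import ProjectionParams, project_all
from .transcriptomics import cluster_domains, spearman_correlate

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs, stage parameters and output location for a full run."""

    # input paths (ignored when a dataset object is passed to run_pipeline)
    volumes_dir: str | None = None
    sites_path: str | None = None
    expression_path: str | None = None
    omega_path: str | None = None
    omega_status_path: str | None = None
    cells_path: str | None = None
    cell_metadata_path: str | None = None

    projection: ProjectionParams = field(default_factory=ProjectionParams)
    k_range: tuple[int, int] | None = (2, 12)  # None skips domain clustering
    omega_mode: str = "relaxed"
    low_corr_cut: float = 0.1
    gene_filter_cut: float = 0.75
    apply_gene_filter: bool = False
    high_cut: float = 1.0
    low_cut: float = 0.0
    network_min: float = 0.75
    gabi_high: GabiParams = field(default_factory=lambda: GabiParams(popsize=250))
    gabi_low: GabiParams = field(default_factory=lambda: GabiParams(popsize=1200))
    branches: list[str] | None = None  # None = every branch in the omega table
    directions: tuple[str, ...] = ("high", "low")
    top_mode: str = "per_branch"
    top_n: int = 20
    enrichment_pct: float = 90.0
    critical_z: float = CRITICAL_Z
    seed: int = 0
    outdir: str | None = None


@dataclass
class PipelineResult:
    """In-memory results of a pipeline run plus the manifest."""

    fn = None
    correlations = None
    assignment: DomainAssignment | None = None
    biclusters: list[Bicluster] = field(default_factory=list)
    top_biclusters: list[Bicluster] = field(default_factory=list)
    summary: BranchDomainSummary | None = None
    enrichment = None
    collapsed: dict = field(default_factory=dict)
    gene_sets: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def validate_config(config: PipelineConfig) -> list[dict]:
    """Static checks on a config; returns findings, never raises."""
    findings: list[dict] = []
    for name in (
        "volumes_dir",
        "sites_path",
        "expression_path",
        "omega_path",
        "cells_path",
    ):
        value = getattr(config, name)
        if value is not None and not Path(value).exists():
            findings.append({"level": "error", "message": f"{name}: {value} does not exist"})
    if config.projection.gauss_sigma <= 0:
        findings.append({"level": "error", "message": "projection sigma must be positive"})
    if config.projection.density_threshold <= 0:
        findings.append({"level": "error", "message": "density threshold must be positive"})
    for name, params in (("gabi_high", config.gabi_high), ("gabi_low", config.gabi_low)):
        if params.global_optim and params.global_optim % 4 != 0:
            findings.append(
                {
                    "level": "warning",
                    "message": f"{name}.global_optim={params.global_optim} is ideally a multiple of 4",
                }
            )
    for name in ("low_corr_cut", "gene_filter_cut", "network_min"):
        v = getattr(config, name)
        if not 0.0 <= v <= 1.0:
            findings.append({"level": "error", "message": f"{name}={v} outside [0, 1]"})
    if config.omega_mode not in ("relaxed", "conservative"):
        findings.append(
            {"level": "error", "message": f"unknown omega_mode {config.omega_mode!r}"}
        )
    return findings


def derive_seed(master_seed: int, *parts) -> int:
    """Deterministic child seed from the master seed and stage labels."""
    entropy = [int(master_seed) & 0x7FFFFFFF]
    for p in parts:
        if isinstance(p, str):
            entropy.append(zlib.crc32(p.encode("utf-8")))
        else:
            entropy.append(int(p) & 0xFFFFFFFF)
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _single_network_assignment(networks: list[str]) -> DomainAssignment:
    """Degenerate assignment used when domain clustering is skipped."""
    labels = {n: n for n in networks}
    return DomainAssignment(
        labels=labels, domains=list(networks), k=len(networks), silhouette_by_k={}
    )


def load_inputs(config: PipelineConfig):
    volumes = eio.read_volume_dir(config.volumes_dir)
    sites = eio.read_sites(config.sites_path)
    expression = eio.read_matrix(config.expression_path, "expression")
    omega = eio.read_matrix(
        config.omega_path, "omega", status_path=config.omega_status_path
    )
    cells = eio.read_matrix(
        config.cells_path, "celltype", metadata_path=config.cell_metadata_path
    )
    return volumes, sites, expression, omega, cells


def run_pipeline(config: PipelineConfig, dataset=None) -> PipelineResult:
    """Run projection -> correlation -> domains -> prep -> biclustering ->
    summary -> enrichment; returns in-memory results and a manifest.

    ``dataset`` may be a :class:`evoselect.fixtures.FixtureDataset` (or
    any object with the same attributes) to run without file inputs;
    otherwise the paths in ``config`` are read.  When ``config.outdir``
    is set, every stage output is written beneath it.
    """
    t_start = time.time()
    result = PipelineResult()
    manifest: dict = {"seed": int(config.seed), "stages": {}, "files": {}}
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    def _stage(name):
        manifest["stages"][name] = {"t": round(time.time() - t_start, 3)}
        logger.info("stage %s", name)

    def _write(name, writer, *args):
        if not outdir:
            return
        path = outdir / name
        path.parent.mkdir(parents=True, exist_ok=True)
        writer(*args, path)
        manifest["files"][name] = _sha256(path)

    if dataset is not None:
        volumes, sites = dataset.volumes, dataset.sites
        expression, omega_raw, cells = dataset.expression, dataset.omega, dataset.cells
    else:
        volumes, sites, expression, omega_raw, cells = load_inputs(config)

    _stage("projection")
    fn = project_all(volumes, sites, config.projection)
    result.fn = fn
    _write("fn/fn.tsv", eio.write_matrix, fn)

    _stage("correlation")
    r = spearman_correlate(expression, fn)
    result.correlations = r
    _write("corr/r.tsv", eio.write_matrix, r)

    _stage("domains")
    if config.k_range is not None:
        kmin, kmax = config.k_range
        kmax_eff = min(kmax, len(r.networks) - 1)
        if kmax_eff != kmax:
            logger.info("clamping domain search range to k <= %d", kmax_eff)
        assignment = cluster_domains(r, (kmin, kmax_eff))
    else:
        # step skipped: biclusters are analyzed at single-network level
        assignment = _single_network_assignment(list(r.networks))
    result.assignment = assignment
    _write("domains/domains.json", eio.write_domains, assignment)

    _stage("prep")
    omega = apply_omega_constraints(omega_raw, config.omega_mode)
    omega_norm = rank_normalize_omega(omega)
    retained = filter_spatial_genes(r, config.low_corr_cut)
    r_norm = rank_normalize_correlations(
        r, low_corr_cut=config.low_corr_cut, gene_filter_cut=config.gene_filter_cut
    )
    if config.apply_gene_filter:
        retained &= {g for g, keep in zip(r_norm.genes, r_norm.retained) if keep}
    pools = build_gene_pools(
        omega, high_cut=config.high_cut, low_cut=config.low_cut, harmonize=True
    )
    manifest["stages"]["prep"]["retained_genes"] = len(retained)

    _stage("biclustering")
    branches = config.branches or list(omega.branches)
    all_biclusters: list[Bicluster] = []
    for direction in config.directions:
        base = config.gabi_high if direction == "high" else config.gabi_low
        for branch in branches:
            try:
                spec = branch_thresholds(
                    omega_norm, pools, branch, direction, network_min=config.network_min
                )
                matrix = concatenate(omega_norm, branch, r_norm, genes=retained)
            except (ValueError, KeyError) as exc:
                logger.warning("skipping %s/%s: %s", branch, direction, exc)
                continue
            incidence = binarize(matrix, spec)
            params = dataclasses.replace(
                base, seed=derive_seed(config.seed, branch, direction)
            )
            meta = {"branch": branch, "direction": direction}
            if params.global_optim >= 1:
                found = global_optim_loop(
                    incidence,
                    matrix.column_classes,
                    params,
                    gene_labels=matrix.genes,
                    column_labels=matrix.col_labels,
                )
                found = [
                    dataclasses.replace(
                        b, run_metadata=tuple(sorted({**b.meta, **meta}.items()))
                    )
                    for b in found
                ]
            else:
                found = gabi_search(
                    incidence,
                    matrix.column_classes,
                    params,
                    gene_labels=matrix.genes,
                    column_labels=matrix.col_labels,
                    run_metadata=meta,
                )
            merged = merge_biclusters(found, params=params)
            all_biclusters.extend(merged)
    result.biclusters = all_biclusters
    _write("biclusters/biclusters.json", eio.write_biclusters, all_biclusters)

    _stage("postprocess")
    top = select_top(all_biclusters, mode=config.top_mode, n=config.top_n)
    result.top_biclusters = top
    summary = summarize(top, assignment)
    result.summary = summary
    _write("summary/top_biclusters.json", eio.write_biclusters, top)
    _write("summary/summary.json", eio.write_json, summary.as_dict())

    _stage("enrichment")
    universe = [g for g in omega.genes if g in set(cells.genes)]
    filtered = percentile_filter(cells, config.enrichment_pct)
    gene_sets: dict[tuple[str, str], set[str]] = {}
    for b in top:
        doms = {assignment.domain_of(n) for n in b.networks}
        for br in b.branches:
            for d in doms:
                gene_sets.setdefault((br, d), set()).update(b.genes)
    universe_set = set(universe)
    correlations = {}
    kept_sets = {}
    for cell_key, genes in gene_sets.items():
        usable = genes & universe_set
        if not usable or usable == universe_set:
            logger.warning("cell %s: gene set unusable for enrichment", cell_key)
            continue
        kept_sets[cell_key] = usable
        correlations[cell_key] = enrich_gene_set(usable, filtered, universe)
    result.gene_sets = kept_sets
    enr = zscore_binarize(
        correlations, list(cells.clusters), dict(cells.metadata), config.critical_z
    )
    result.enrichment = enr
    result.collapsed = {
        by: collapse(enr, by) for by in ("supercluster", "class", "neurotransmitter")
    }
    _write("enrichment/enrichment.json", eio.write_json, enr.as_dict())
    _write("enrichment/collapsed.json", eio.write_json, result.collapsed)
    if outdir:
        listdir = outdir / "enrichment" / "gene_lists"
        listdir.mkdir(parents=True, exist_ok=True)
        for (br, d), genes in sorted(kept_sets.items()):
            path = listdir / f"{br}__{d}.txt"
            path.write_text("\n".join(sorted(genes)) + "\n", encoding="utf-8")
            manifest["files"][f"enrichment/gene_lists/{path.name}"] = _sha256(path)

    manifest["elapsed_s"] = round(time.time() - t_start, 3)
    manifest["n_biclusters"] = len(all_biclusters)
    result.manifest = manifest
    if outdir:
        eio.write_json(manifest, outdir / "manifest.json")
    return result
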