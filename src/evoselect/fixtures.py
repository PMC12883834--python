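"""Synthetic datasets with planted structure for end-to-end testing.

The generator emulates the shapes and statistical features of the real
inputs — per-network volumetric z-maps, a gene x biopsy-site expression
matrix, a gene x branch dN/dS table with PAML status codes, and a
cluster-level single-cell expression matrix — at a desk scale, with
known ground truth planted into each layer:

* networks are smooth Gaussian-blob activations grouped into a planted
  domain partition (same-domain networks share a base pattern);
* biopsy sites mix tightly paired locations (that trigger the direct
  nearest-voxel projection rule) with lattice-spaced ones (that
  trigger the Gaussian rule);
* each planted module ties a block of genes to a network set and a
  branch: module gene expression is an affine transform of its
  network's projected site profile plus Gaussian noise, and the module
  genes get extreme omega on their branch (high direction: omega > 1;
  low: omega = 0) with stable status;
* background omega is exponential-like in (0, 1), with per-branch
  scatterings of high, zero and degenerate-status cells so every
  branch has nonempty gene pools and every status code occurs;
* one cell cluster per module over-expresses the module's genes, so it
  survives the percentile filter and is recoverable by enrichment
  (this requires each module to hold at most ~10% of all genes, the
  survivor budget of the default 90th-percentile filter).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import (
    CellTypeMatrix,
    ExpressionMatrix,
    OmegaTable,
    SiteTable,
    VolumeMap,
)
from .projection import ProjectionParams, project_all

_BRANCH_NAMES = (
    "AMH",
    "Neanderthal",
    "Denisovan",
    "Chimp",
    "Branch1",
    "Branch2",
    "Branch3",
    "Branch4",
    "Branch5",
    "Branch6",
    "Branch7",
)

_SUPERCLUSTERS = ("MSN", "Amygdala excitatory", "Hippocampal CA", "Astrocyte", "Oligodendrocyte", "Microglia")
_CLASSES = ("excitatory", "inhibitory", "glial", "vascular")
_NEUROTRANSMITTERS = ("glutamate", "GABA", "none")


@dataclass
class PlantedModule:
    """One planted co-selection module: genes x networks on one branch."""

    n_genes: int
    networks: tuple[int, ...]
    branch: int
    direction: str  # "high" or "low"
    effect: float = 2.0


@dataclass
class FixtureConfig:
    n_genes: int = 800
    n_sites: int = 300
    n_networks: int = 12
    n_branches: int = 6
    n_clusters: int = 50
    n_domains: int = 4
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size: float = 2.0
    modules: list[PlantedModule] = field(default_factory=list)
    noise_sd: float = 0.5
    # background omega composition, per branch
    high_omega_rate: float = 0.06
    zero_omega_rate: float = 0.06
    degenerate_rate: float = 0.005  # per degenerate/unstable status code
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.modules:
            third = self.n_networks // self.n_domains
            self.modules = [
                PlantedModule(40, tuple(range(third)), 0, "high", 2.0),
                PlantedModule(40, tuple(range(third, 2 * third)), 1, "low", 2.0),
            ]
        for c in (self.n_genes, self.n_sites, self.n_networks, self.n_branches, self.n_clusters):
            if c < 2:
                raise ValueError("all fixture counts must be >= 2")
        if sum(m.n_genes for m in self.modules) > self.n_genes:
            raise ValueError("planted gene sets exceed n_genes")
        for m in self.modules:
            if m.branch >= self.n_branches or max(m.networks) >= self.n_networks:
                raise ValueError("planted module indexes outside fixture dimensions")
            if m.direction not in ("high", "low"):
                raise ValueError(f"module direction must be high/low, got {m.direction!r}")


@dataclass
class PlantedTruth:
    """Ground truth the generator plants, for recovery scoring."""

    modules: list[dict]
    enriched_clusters: dict[int, str]  # module index -> cluster label
    domain_partition: dict[str, int]  # network label -> domain index


@dataclass
class FixtureDataset:
    volumes: list[VolumeMap]
    sites: SiteTable
    expression: ExpressionMatrix
    omega: OmegaTable
    cells: CellTypeMatrix
    truth: PlantedTruth


def _gene_labels(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(n)]


def _branch_labels(n: int) -> list[str]:
    if n <= len(_BRANCH_NAMES):
        return list(_BRANCH_NAMES[:n])
    return list(_BRANCH_NAMES) + [f"b{i}" for i in range(len(_BRANCH_NAMES), n)]


def _make_volumes(config: FixtureConfig, rng: np.random.Generator):
    shape = np.array(config.grid_shape)
    affine = np.diag([config.voxel_size] * 3 + [1.0])
    affine[:3, 3] = -(shape - 1) / 2.0 * config.voxel_size
    idx = np.indices(config.grid_shape).reshape(3, -1).T
    centers = idx @ affine[:3, :3].T + affine[:3, 3]
    extent = (shape - 1) / 2.0 * config.voxel_size

    def blob(center, sigma, amp):
        d2 = ((centers - center) ** 2).sum(axis=1)
        return amp * np.exp(-d2 / (2.0 * sigma**2))

    domain_of = {}
    per_domain = int(np.ceil(config.n_networks / config.n_domains))
    volumes = []
    domain_fields = []
    for d in range(config.n_domains):
        f = np.zeros(centers.shape[0])
        for _ in range(2):
            c = rng.uniform(-0.6, 0.6, size=3) * extent
            f += blob(c, sigma=8.0, amp=3.0)
        domain_fields.append(f)
    for n in range(config.n_networks):
        d = min(n // per_domain, config.n_domains - 1)
        own = blob(rng.uniform(-0.6, 0.6, size=3) * extent, sigma=6.0, amp=0.6)
        grid = (
            domain_fields[d] * rng.uniform(0.85, 1.15)
            + own
            + 0.05 * rng.standard_normal(centers.shape[0])
        ).reshape(config.grid_shape)
        label = f"net{n:02d}"
        volumes.append(VolumeMap(grid=grid, affine=affine.copy(), network_id=label))
        domain_of[label] = d
    return volumes, domain_of


def _make_sites(config: FixtureConfig, rng: np.random.Generator) -> SiteTable:
    """Lattice-spaced sites plus tight pairs so both projection rules fire."""
    shape = np.array(config.grid_shape)
    extent = (shape - 1) / 2.0 * config.voxel_size
    lattice_n = int(np.ceil((config.n_sites) ** (1 / 3))) + 2
    axes = [np.linspace(-0.85 * e, 0.85 * e, lattice_n) for e in extent]
    cells = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    spacing = float(axes[0][1] - axes[0][0])
    jitter = min(1.0, max(0.1, (spacing - 2.5) / 2.0))
    order = rng.permutation(cells.shape[0])

    n_pairs = max(1, int(0.15 * config.n_sites))
    n_sparse = config.n_sites - 2 * n_pairs
    coords = []
    used = 0
    for _ in range(n_sparse):
        base = cells[order[used]] + rng.uniform(-jitter, jitter, size=3)
        coords.append(base)
        used += 1
    for _ in range(n_pairs):
        base = cells[order[used]] + rng.uniform(-jitter, jitter, size=3)
        offset = rng.normal(size=3)
        offset *= 1.0 / np.linalg.norm(offset)  # twin exactly 1 mm away
        coords.append(base)
        coords.append(base + offset)
        used += 1
    coords = np.array(coords[: config.n_sites])
    ids = [f"s{i:04d}" for i in range(coords.shape[0])]
    return SiteTable(site_ids=ids, coords=coords)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def _make_expression(
    config: FixtureConfig,
    F_values: np.ndarray,
    sites: SiteTable,
    rng: np.random.Generator,
    genes: list[str],
) -> tuple[ExpressionMatrix, list[dict]]:
    # background genes: unit-variance noise; noise_sd scales only the
    # module genes' residual around their network profile
    expr = rng.standard_normal((config.n_genes, config.n_sites))
    modules_truth = []
    cursor = 0
    for m in config.modules:
        gene_idx = list(range(cursor, cursor + m.n_genes))
        cursor += m.n_genes
        gene_network = {}
        for pos, gi in enumerate(gene_idx):
            net = m.networks[pos % len(m.networks)]
            profile = _zscore(F_values[net])
            noise = (
                config.noise_sd * rng.standard_normal(config.n_sites)
                if config.noise_sd > 0
                else 0.0
            )
            expr[gi] = m.effect * profile + noise
            gene_network[genes[gi]] = f"net{net:02d}"
        modules_truth.append(
            {
                "genes": [genes[i] for i in gene_idx],
                "networks": [f"net{n:02d}" for n in m.networks],
                "branch": m.branch,
                "direction": m.direction,
                "effect": m.effect,
                "gene_network": gene_network,
            }
        )
    matrix = ExpressionMatrix(genes, list(sites.site_ids), expr)
    return matrix, modules_truth


def _make_omega(
    config: FixtureConfig, rng: np.random.Generator, genes: list[str]
) -> OmegaTable:
    n_g, n_b = config.n_genes, config.n_branches
    omega = rng.exponential(0.25, size=(n_g, n_b))
    omega = np.clip(omega, 1e-4, 0.95)
    status = np.full((n_g, n_b), "STABLE", dtype=object)

    module_rows = set()
    cursor = 0
    for m in config.modules:
        rows = range(cursor, cursor + m.n_genes)
        cursor += m.n_genes
        module_rows.update(rows)
        for gi in rows:
            if m.direction == "high":
                omega[gi, m.branch] = rng.uniform(2.0, 4.0)
            else:
                omega[gi, m.branch] = 0.0

    background = np.array(sorted(set(range(n_g)) - module_rows))
    for j in range(n_b):
        n_high = int(config.high_omega_rate * background.size)
        n_zero = int(config.zero_omega_rate * background.size)
        n_deg = max(1, int(config.degenerate_rate * background.size))
        pick = rng.choice(background, size=n_high + n_zero + 5 * n_deg, replace=False)
        hi, zero, rest = pick[:n_high], pick[n_high : n_high + n_zero], pick[n_high + n_zero :]
        omega[hi, j] = rng.uniform(1.05, 1.9, size=n_high)
        omega[zero, j] = rng.uniform(0.0, 1e-10, size=n_zero)
        for k, code in enumerate(
            ("UNSTABLE", "SHORT_EDGE_UNSTABLE", "DN_ZERO", "DS_ZERO", "IDENTICAL")
        ):
            cells = rest[k * n_deg : (k + 1) * n_deg]
            status[cells, j] = code
            omega[cells, j] = np.nan
    return OmegaTable(genes, _branch_labels(n_b), omega, status=status)


def _make_cells(
    config: FixtureConfig, rng: np.random.Generator, genes: list[str]
) -> tuple[CellTypeMatrix, dict[int, str]]:
    vals = rng.lognormal(mean=0.0, sigma=1.0, size=(config.n_genes, config.n_clusters))
    labels = [f"cl{c:03d}" for c in range(config.n_clusters)]
    enriched: dict[int, str] = {}
    cursor = 0
    for mi, m in enumerate(config.modules):
        rows = np.arange(cursor, cursor + m.n_genes)
        cursor += m.n_genes
        cluster = (config.n_clusters - 1 - mi) % config.n_clusters
        col = vals[:, cluster]
        boost = np.quantile(col, 0.95) * rng.uniform(2.0, 3.0, size=rows.size)
        vals[rows, cluster] = boost
        enriched[mi] = labels[cluster]
    metadata = {
        lab: {
            "supercluster": _SUPERCLUSTERS[c % len(_SUPERCLUSTERS)],
            "class": _CLASSES[c % len(_CLASSES)],
            "neurotransmitter": _NEUROTRANSMITTERS[c % len(_NEUROTRANSMITTERS)],
            "neuronal": c < config.n_clusters // 2,
        }
        for c, lab in enumerate(labels)
    }
    return CellTypeMatrix(genes, labels, vals, metadata=metadata), enriched


def make_dataset(config: FixtureConfig | None = None) -> FixtureDataset:
    """Generate all four synthetic input layers plus the planted truth.

    Fully determined by ``config.seed``: the same configuration yields
    bit-identical outputs.
    """
    config = config or FixtureConfig()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, 17]))
    genes = _gene_labels(config.n_genes)
    volumes, domain_of = _make_volumes(config, rng)
    sites = _make_sites(config, rng)
    F = project_all(volumes, sites, ProjectionParams())
    expression, modules_truth = _make_expression(config, F.values, sites, rng, genes)
    omega = _make_omega(config, rng, genes)
    cells, enriched = _make_cells(config, rng, genes)
    truth = PlantedTruth(
        modules=modules_truth, enriched_clusters=enriched, domain_partition=domain_of
    )
    return FixtureDataset(
        volumes=volumes,
        sites=sites,
        expression=expression,
        omega=omega,
        cells=cells,
        truth=truth,
    )


def end_to_end_truth_check(
    truth: PlantedTruth,
    biclusters=None,
    assignment=None,
    enrichment=None,
) -> dict:
    """Score pipeline outputs against the planted truth.

    Reports, per module, the best gene-set Jaccard over the supplied
    biclusters and the network-set Jaccard of that best bicluster;
    the adjusted Rand index between a domain assignment and the
    planted partition; and the recall of planted enriched clusters in
    an enrichment result.  Sections whose inputs are not supplied are
    omitted from the report.
    """
    report: dict = {}
    if biclusters is not None:
        module_scores = []
        for mod in truth.modules:
            target_genes = set(mod["genes"])
            target_nets = set(mod["networks"])
            best_j, best_net_j = 0.0, 0.0
            for b in biclusters:
                inter = len(b.genes & target_genes)
                union = len(b.genes | target_genes)
                j = inter / union if union else 0.0
                if j > best_j:
                    best_j = j
                    nu = len(b.networks | target_nets)
                    best_net_j = len(b.networks & target_nets) / nu if nu else 0.0
            module_scores.append(
                {
                    "branch": mod["branch"],
                    "direction": mod["direction"],
                    "gene_jaccard": best_j,
                    "network_jaccard": best_net_j,
                }
            )
        report["modules"] = module_scores
        report["min_gene_jaccard"] = min(m["gene_jaccard"] for m in module_scores)
    if assignment is not None:
        from sklearn.metrics import adjusted_rand_score

        nets = sorted(truth.domain_partition)
        true_labels = [truth.domain_partition[n] for n in nets]
        pred = [assignment.domain_of(n) for n in nets]
        report["domain_ari"] = float(adjusted_rand_score(true_labels, pred))
    if enrichment is not None:
        planted = set(truth.enriched_clusters.values())
        found = set()
        for cell, flags in enrichment.enriched.items():
            for cluster, f in zip(enrichment.clusters, flags):
                if f:
                    found.add(cluster)
        report["enriched_recall"] = (
            len(planted & found) / len(planted) if planted else float("nan")
        )
    return report
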