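"""Domain types shared across the pipeline.

Conventions
-----------
* All spatial coordinates are MNI millimeters; voxel indices are 0-based
  and the affine maps voxel index -> mm.
* Matrices are stored as float arrays with ``numpy.nan`` for missing
  cells; label order always equals the order of the source file or of
  the constructing call.
* Omega (dN/dS) status codes follow the PAML-outcome categories: a cell
  is either a stable estimate, an unstable one (filtered), or a
  degenerate case (dN = 0, dS = 0, identical sequences) that the
  relaxed constraint mode maps to a usable value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

#: Valid per-cell omega status codes.
OMEGA_STATUS_CODES = (
    "STABLE",
    "UNSTABLE",
    "SHORT_EDGE_UNSTABLE",
    "DN_ZERO",
    "DS_ZERO",
    "IDENTICAL",
)


class FormatError(ValueError):
    """Raised when an input file violates the expected layout."""


def _check_unique(labels: Sequence[str], what: str) -> list[str]:
    labels = [str(x) for x in labels]
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise FormatError(f"duplicate {what} labels: {dupes[:5]}")
    return labels


@dataclass
class VolumeMap:
    """A 3D z-score volume for one functional network.

    ``grid`` holds z-scores (NaN marks voxels without coverage) and
    ``affine`` is the 4x4 voxel-index-to-MNI-mm transform.
    """

    grid: np.ndarray
    affine: np.ndarray
    network_id: str

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.grid.ndim != 3 or min(self.grid.shape) < 1:
            raise FormatError(
                f"volume grid must be 3D with positive dims, got shape {self.grid.shape}"
            )
        if self.affine.shape != (4, 4):
            raise FormatError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise FormatError("affine is singular")

    def voxel_centers_mm(self) -> np.ndarray:
        """Return an (n_voxels, 3) array of voxel-center MNI coordinates."""
        idx = np.indices(self.grid.shape).reshape(3, -1).T
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]


@dataclass
class SiteTable:
    """Biopsy-site locations in MNI mm."""

    site_ids: list[str]
    coords: np.ndarray  # (n_sites, 3) in mm

    def __post_init__(self) -> None:
        self.site_ids = _check_unique(self.site_ids, "site")
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.site_ids), 3):
            raise FormatError("coords must be (n_sites, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise FormatError("site coordinates must be finite")

    def __len__(self) -> int:
        return len(self.site_ids)


@dataclass
class LabelledMatrix:
    """Base for row x column float matrices with ordered string labels."""

    row_labels: list[str]
    col_labels: list[str]
    values: np.ndarray

    _row_kind = "row"
    _col_kind = "column"

    def __post_init__(self) -> None:
        self.row_labels = _check_unique(self.row_labels, self._row_kind)
        self.col_labels = _check_unique(self.col_labels, self._col_kind)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match labels "
                f"({len(self.row_labels)}, {len(self.col_labels)})"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row_index(self, label: str) -> int:
        try:
            return self.row_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown {self._row_kind} label {label!r}") from None

    def col_index(self, label: str) -> int:
        try:
            return self.col_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown {self._col_kind} label {label!r}") from None


@dataclass
class ExpressionMatrix(LabelledMatrix):
    """Gene x biopsy-site expression G(g, s); missing cells are NaN."""

    _row_kind = "gene"
    _col_kind = "site"

    @property
    def genes(self) -> list[str]:
        return self.row_labels

    @property
    def sites(self) -> list[str]:
        return self.col_labels


@dataclass
class OmegaTable(LabelledMatrix):
    """Gene x branch raw dN/dS values with per-cell PAML status codes.

    ``omega`` entries must be >= 0 or NaN; ``status`` is an object array
    of codes from :data:`OMEGA_STATUS_CODES` aligned cell-by-cell.
    """

    status: np.ndarray = None  # type: ignore[assignment]

    _row_kind = "gene"
    _col_kind = "branch"

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.status is None:
            self.status = np.full(self.values.shape, "STABLE", dtype=object)
        self.status = np.asarray(self.status, dtype=object)
        if self.status.shape != self.values.shape:
            raise FormatError("status shape must match omega shape")
        bad = set(np.unique(self.status)) - set(OMEGA_STATUS_CODES)
        if bad:
            raise FormatError(f"unknown omega status codes: {sorted(bad)}")
        with np.errstate(invalid="ignore"):
            if np.any(self.values[np.isfinite(self.values)] < 0):
                raise FormatError("omega values must be >= 0 where present")

    @property
    def genes(self) -> list[str]:
        return self.row_labels

    @property
    def branches(self) -> list[str]:
        return self.col_labels

    @property
    def omega(self) -> np.ndarray:
        return self.values


@dataclass
class CorrelationMatrix(LabelledMatrix):
    """Network x gene Spearman correlations r(g, n), in [-1, 1] or NaN."""

    _row_kind = "network"
    _col_kind = "gene"

    def __post_init__(self) -> None:
        super().__post_init__()
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
            raise FormatError("correlations must lie in [-1, 1]")

    @property
    def networks(self) -> list[str]:
        return self.row_labels

    @property
    def genes(self) -> list[str]:
        return self.col_labels


@dataclass
class CellTypeMatrix(LabelledMatrix):
    """Gene x cell-cluster mean expression with per-cluster annotations.

    ``metadata`` maps each cluster label to a dict with keys
    ``supercluster``, ``class``, ``neurotransmitter`` and ``neuronal``
    (bool), following cluster-level single-cell taxonomies.
    """

    metadata: dict[str, dict] = field(default_factory=dict)

    _row_kind = "gene"
    _col_kind = "cluster"

    def __post_init__(self) -> None:
        super().__post_init__()
        with np.errstate(invalid="ignore"):
            if np.any(self.values[np.isfinite(self.values)] < 0):
                raise FormatError("cell-type expression must be non-negative")
        missing = [c for c in self.col_labels if c not in self.metadata]
        if missing:
            raise FormatError(f"missing cluster metadata for {missing[:5]}")

    @property
    def genes(self) -> list[str]:
        return self.row_labels

    @property
    def clusters(self) -> list[str]:
        return self.col_labels


@dataclass
class FNSiteMatrix(LabelledMatrix):
    """Network x site projected z-scores F(n, s)."""

    _row_kind = "network"
    _col_kind = "site"

    @property
    def networks(self) -> list[str]:
        return self.row_labels

    @property
    def sites(self) -> list[str]:
        return self.col_labels


@dataclass(frozen=True)
class Bicluster:
    """A gene subset x column subset pattern B = (g_sub, [b_sub n_sub]).

    ``score`` is the size of the submatrix under the configured scoring
    rule (gene count x possibly class-weighted column count).
    """

    genes: frozenset[str]
    branches: frozenset[str]
    networks: frozenset[str]
    score: float
    run_metadata: tuple[tuple[str, object], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))
        object.__setattr__(self, "branches", frozenset(self.branches))
        object.__setattr__(self, "networks", frozenset(self.networks))
        if not self.genes:
            raise ValueError("bicluster gene set must be nonempty")
        if not (self.branches or self.networks):
            raise ValueError("bicluster must select at least one column")
        if self.score < 0:
            raise ValueError("bicluster score must be non-negative")
        meta = self.run_metadata
        if isinstance(meta, dict):
            meta = meta.items()
        object.__setattr__(self, "run_metadata", tuple(sorted(meta)))

    @property
    def meta(self) -> dict:
        return dict(self.run_metadata)


@dataclass
class DomainAssignment:
    """Partition of networks into domains chosen by average silhouette width."""

    labels: dict[str, str]  # network -> domain label
    domains: list[str]
    k: int
    silhouette_by_k: dict[int, float]

    def __post_init__(self) -> None:
        assigned = set(self.labels.values())
        if assigned - set(self.domains):
            raise ValueError("assignment uses domains not in the domain list")
        if self.k != len(set(self.labels.values())):
            raise ValueError("k must equal the number of distinct domains used")

    def domain_of(self, network: str) -> str:
        try:
            return self.labels[network]
        except KeyError:
            raise KeyError(f"network {network!r} has no domain assignment") from None

    def members(self, domain: str) -> list[str]:
        return [n for n, d in self.labels.items() if d == domain]


@dataclass
class AnalysisMatrix(LabelledMatrix):
    """Gene x (branch || network) matrix fed to the biclusterer.

    ``column_classes`` marks each column as ``"omega"`` or ``"network"``.
    """

    column_classes: list[str] = field(default_factory=list)

    _row_kind = "gene"
    _col_kind = "column"

    def __post_init__(self) -> None:
        super().__post_init__()
        if len(self.column_classes) != len(self.col_labels):
            raise FormatError("one column class required per column")
        bad = set(self.column_classes) - {"omega", "network"}
        if bad:
            raise FormatError(f"unknown column classes: {sorted(bad)}")

    @property
    def genes(self) -> list[str]:
        return self.row_labels

    def columns_of_class(self, cls: str) -> list[int]:
        return [i for i, c in enumerate(self.column_classes) if c == cls]


def as_mapping(meta: Mapping | None) -> dict:
    return dict(meta) if meta else {}
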