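"""Readers and writers for pipeline inputs and outputs.

Formats: NIfTI (via nibabel) for volumes, TSV (tab-separated, UTF-8,
'.' decimal, empty cell = missing) for matrices and site tables, JSON
for biclusters, domain assignments and enrichment results.  Omega
status codes travel in a second TSV aligned cell-by-cell with the
omega TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .datatypes import (
    Bicluster,
    CellTypeMatrix,
    CorrelationMatrix,
    DomainAssignment,
    ExpressionMatrix,
    FNSiteMatrix,
    FormatError,
    OmegaTable,
    SiteTable,
)

_MATRIX_KINDS = {
    "expression": ExpressionMatrix,
    "omega": OmegaTable,
    "correlation": CorrelationMatrix,
    "celltype": CellTypeMatrix,
    "fn": FNSiteMatrix,
}


# ---------------------------------------------------------------------------
# volumes

def read_volume(path: str | Path, network_id: str | None = None):
    """Load a 3D NIfTI z-map as a :class:`VolumeMap`.

    The network label defaults to the filename stem (``.nii``/``.nii.gz``
    suffixes stripped).
    """
    from .datatypes import VolumeMap

    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    data = np.squeeze(data) if data.ndim == 3 else data
    if data.ndim != 3:
        raise FormatError(f"{path.name}: expected a 3D image, got {data.ndim}D")
    if img.affine is None:
        raise FormatError(f"{path.name}: image has no affine")
    if network_id is None:
        network_id = path.name
        for suffix in (".gz", ".nii"):
            if network_id.endswith(suffix):
                network_id = network_id[: -len(suffix)]
    return VolumeMap(grid=data, affine=np.asarray(img.affine), network_id=network_id)


def write_volume(volume, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(volume.grid, dtype=np.float64), volume.affine)
    nib.save(img, str(path))


def read_volume_dir(directory: str | Path) -> list:
    """Read every ``.nii``/``.nii.gz`` file in a directory, sorted by name."""
    directory = Path(directory)
    paths = sorted(
        p for p in directory.iterdir() if p.name.endswith((".nii", ".nii.gz"))
    )
    return [read_volume(p) for p in paths]


# ---------------------------------------------------------------------------
# TSV matrices

def _read_tsv_frame(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        ncol = len(header)
        for lineno, line in enumerate(fh, start=2):
            if line.strip() == "":
                continue
            if len(line.rstrip("\n").split("\t")) != ncol:
                raise FormatError(f"{path.name}:{lineno}: ragged row")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path.name}: duplicate row labels {dupes[:5]}")
    return df


def _to_float(df: pd.DataFrame, name: str) -> np.ndarray:
    try:
        return (
            df.replace("", np.nan).astype(float).to_numpy()
        )
    except ValueError as exc:
        raise FormatError(f"{name}: non-numeric cell ({exc})") from None


def read_matrix(
    path: str | Path,
    kind: str,
    status_path: str | Path | None = None,
    metadata_path: str | Path | None = None,
):
    """Read a labelled TSV matrix as the typed object for ``kind``.

    ``kind`` is one of ``expression``, ``omega``, ``correlation``,
    ``celltype`` or ``fn``.  The omega kind accepts a parallel status
    TSV; the celltype kind accepts a cluster-metadata TSV with columns
    ``cluster``, ``supercluster``, ``class``, ``neurotransmitter``,
    ``neuronal``.
    """
    if kind not in _MATRIX_KINDS:
        raise ValueError(f"unknown matrix kind {kind!r}")
    path = Path(path)
    df = _read_tsv_frame(path)
    values = _to_float(df, path.name)
    rows = [str(x) for x in df.index]
    cols = [str(x) for x in df.columns]

    if kind == "omega":
        status = None
        if status_path is not None:
            sdf = _read_tsv_frame(status_path)
            if list(sdf.index) != rows or list(sdf.columns) != cols:
                raise FormatError("status TSV labels do not match omega TSV")
            status = sdf.to_numpy(dtype=object)
        return OmegaTable(rows, cols, values, status=status)
    if kind == "celltype":
        metadata = {}
        if metadata_path is not None:
            metadata = read_cluster_metadata(metadata_path)
        else:
            metadata = {
                c: {
                    "supercluster": "NA",
                    "class": "NA",
                    "neurotransmitter": "NA",
                    "neuronal": False,
                }
                for c in cols
            }
        return CellTypeMatrix(rows, cols, values, metadata=metadata)
    return _MATRIX_KINDS[kind](rows, cols, values)


def write_matrix(matrix, path: str | Path, float_format: str = "%.10g") -> None:
    """Write any labelled matrix as TSV (empty string for missing)."""
    df = pd.DataFrame(matrix.values, index=matrix.row_labels, columns=matrix.col_labels)
    df.to_csv(path, sep="\t", float_format=float_format, na_rep="")


def write_omega_status(omega: OmegaTable, path: str | Path) -> None:
    df = pd.DataFrame(omega.status, index=omega.genes, columns=omega.branches)
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# site tables and cluster metadata

def read_sites(path: str | Path) -> SiteTable:
    """Read a site table TSV with columns ``site_id``, ``x``, ``y``, ``z``."""
    df = pd.read_csv(path, sep="\t", dtype={"site_id": str})
    required = {"site_id", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise FormatError(f"site table needs columns {sorted(required)}")
    return SiteTable(
        site_ids=df["site_id"].tolist(),
        coords=df[["x", "y", "z"]].to_numpy(dtype=float),
    )


def write_sites(sites: SiteTable, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "site_id": sites.site_ids,
            "x": sites.coords[:, 0],
            "y": sites.coords[:, 1],
            "z": sites.coords[:, 2],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_cluster_metadata(path: str | Path) -> dict[str, dict]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"cluster", "supercluster", "class", "neurotransmitter", "neuronal"}
    if not required.issubset(df.columns):
        raise FormatError(f"cluster metadata needs columns {sorted(required)}")
    meta = {}
    for _, row in df.iterrows():
        meta[str(row["cluster"])] = {
            "supercluster": row["supercluster"],
            "class": row["class"],
            "neurotransmitter": row["neurotransmitter"],
            "neuronal": str(row["neuronal"]).lower() in {"1", "true", "yes"},
        }
    return meta


def write_cluster_metadata(metadata: dict[str, dict], path: str | Path) -> None:
    rows = [
        {
            "cluster": c,
            "supercluster": m["supercluster"],
            "class": m["class"],
            "neurotransmitter": m["neurotransmitter"],
            "neuronal": bool(m["neuronal"]),
        }
        for c, m in metadata.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# biclusters and domain assignments (JSON)

def _bicluster_to_dict(b: Bicluster) -> dict:
    return {
        "genes": sorted(b.genes),
        "branches": sorted(b.branches),
        "networks": sorted(b.networks),
        "score": b.score,
        "run_metadata": {str(k): v for k, v in b.run_metadata},
    }


def write_biclusters(biclusters: list[Bicluster], path: str | Path) -> None:
    """Serialize biclusters to a JSON array with deterministic key order."""
    payload = [_bicluster_to_dict(b) for b in biclusters]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_biclusters(path: str | Path) -> list[Bicluster]:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    out = []
    for rec in payload:
        out.append(
            Bicluster(
                genes=frozenset(rec["genes"]),
                branches=frozenset(rec["branches"]),
                networks=frozenset(rec["networks"]),
                score=rec["score"],
                run_metadata=tuple(sorted(rec.get("run_metadata", {}).items())),
            )
        )
    return out


def write_domains(assignment: DomainAssignment, path: str | Path) -> None:
    payload = {
        "labels": assignment.labels,
        "domains": assignment.domains,
        "k": assignment.k,
        "silhouette_by_k": {str(k): v for k, v in assignment.silhouette_by_k.items()},
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_domains(path: str | Path) -> DomainAssignment:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return DomainAssignment(
        labels=payload["labels"],
        domains=payload["domains"],
        k=payload["k"],
        silhouette_by_k={int(k): v for k, v in payload["silhouette_by_k"].items()},
    )


def write_json(obj, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
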