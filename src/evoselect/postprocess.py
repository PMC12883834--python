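"""Top-bicluster selection, domain assignment and branch x domain summaries."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import Bicluster, DomainAssignment


@dataclass
class BranchDomainSummary:
    """Branch x domain aggregation of bicluster scores and gene sets.

    ``normalized_score`` is the cumulative score of the contributing
    biclusters per cell divided by the maximum cell value of the whole
    matrix (so the strongest cell is 1); ``unique_genes`` counts the
    union of contributing biclusters' genes per cell.
    """

    branches: list[str]
    domains: list[str]
    normalized_score: np.ndarray  # branch x domain in [0, 1]
    unique_genes: np.ndarray  # branch x domain integer counts
    contributors: dict[tuple[str, str], list[int]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "branches": self.branches,
            "domains": self.domains,
            "normalized_score": self.normalized_score.tolist(),
            "unique_genes": self.unique_genes.tolist(),
            "contributors": {
                f"{b}|{d}": ids for (b, d), ids in sorted(self.contributors.items())
            },
        }


def _sort_key(item: tuple[int, Bicluster]):
    idx, b = item
    # higher score first, then larger gene count, then stable input order
    return (-b.score, -len(b.genes), idx)


def select_top(
    biclusters: list[Bicluster], mode: str = "overall", n: int = 40
) -> list[Bicluster]:
    """Keep the n highest-scoring biclusters, overall or per branch.

    Ties are broken toward the larger gene set, then by stable input
    order.  ``per_branch`` groups by the bicluster's branch set.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if mode not in ("overall", "per_branch"):
        raise ValueError(f"unknown selection mode {mode!r}")
    indexed = list(enumerate(biclusters))
    if mode == "overall":
        return [b for _, b in sorted(indexed, key=_sort_key)[:n]]
    by_branch: dict[frozenset[str], list[tuple[int, Bicluster]]] = {}
    for idx, b in indexed:
        by_branch.setdefault(b.branches, []).append((idx, b))
    chosen: list[tuple[int, Bicluster]] = []
    for group in by_branch.values():
        chosen.extend(sorted(group, key=_sort_key)[:n])
    # preserve deterministic overall ordering of the pooled selection
    return [b for _, b in sorted(chosen, key=_sort_key)]


def assign_domains(bicluster: Bicluster, assignment: DomainAssignment) -> set[str]:
    """Domains spanned by the bicluster's networks (all of them, not just one)."""
    return {assignment.domain_of(net) for net in bicluster.networks}


def summarize(
    biclusters: list[Bicluster],
    assignment: DomainAssignment,
    normalization: str = "global",
) -> BranchDomainSummary:
    """Aggregate biclusters into a branch x domain score/gene-count matrix.

    A bicluster contributes its score and genes to every (branch,
    domain) cell it spans; spanning several domains means contributing
    to each.  Scores are normalized by the global matrix maximum
    (``normalization="per_branch"`` normalizes each branch row by its
    own maximum instead).
    """
    if normalization not in ("global", "per_branch"):
        raise ValueError(f"unknown normalization {normalization!r}")
    branches = sorted({br for b in biclusters for br in b.branches})
    domains = list(assignment.domains)
    cum = np.zeros((len(branches), len(domains)))
    gene_sets: dict[tuple[int, int], set[str]] = {}
    contributors: dict[tuple[str, str], list[int]] = {}
    for idx, b in enumerate(biclusters):
        doms = assign_domains(b, assignment)
        for br in b.branches:
            i = branches.index(br)
            for d in doms:
                j = domains.index(d)
                cum[i, j] += b.score
                gene_sets.setdefault((i, j), set()).update(b.genes)
                contributors.setdefault((br, d), []).append(idx)
    counts = np.zeros_like(cum, dtype=int)
    for (i, j), genes in gene_sets.items():
        counts[i, j] = len(genes)
    norm = cum.copy()
    if normalization == "global":
        peak = cum.max()
        if peak > 0:
            norm /= peak
    else:
        for i in range(norm.shape[0]):
            peak = norm[i].max()
            if peak > 0:
                norm[i] /= peak
    return BranchDomainSummary(
        branches=branches,
        domains=domains,
        normalized_score=norm,
        unique_genes=counts,
        contributors=contributors,
    )
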