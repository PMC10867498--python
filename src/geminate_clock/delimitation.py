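"""Barcode-gap species delimitation.

A deliberately simple, deterministic stand-in for automatic
partitioning tools (ASAP/bPTP): sort all pairwise distances, find the
largest gap between consecutive values whose lower edge falls inside a
prior window, and cut the single-linkage dendrogram at the gap
midpoint. The substitution is recorded in the JSON summary the
pipeline writes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .distances import DistanceMatrix
from .errors import DistanceError

__all__ = ["PartitionResult", "barcode_gap_partition"]

METHOD_NOTE = (
    "deterministic barcode-gap detection with single-linkage clustering "
    "(stand-in for ASAP/bPTP probability-scored partitioning)"
)


@dataclass(frozen=True)
class PartitionResult:
    """Clusters plus the detected gap that separates them."""

    clusters: Mapping[str, tuple[str, ...]]
    threshold: float
    gap_width: float
    single_cluster_warning: bool = False

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def labels(self) -> dict[str, str]:
        return {s: cid for cid, members in self.clusters.items() for s in members}

    def to_json(self) -> str:
        return json.dumps(
            {
                "method": METHOD_NOTE,
                "n_clusters": self.n_clusters,
                "threshold": self.threshold,
                "gap_width": self.gap_width,
                "single_cluster_warning": self.single_cluster_warning,
                "clusters": {k: list(v) for k, v in self.clusters.items()},
            },
            indent=2,
        )

    def write(self, tsv_path: str | Path, json_path: str | Path) -> None:
        with open(tsv_path, "w") as fh:
            fh.write("sample_id\tcluster_id\n")
            for cid, members in self.clusters.items():
                for s in members:
                    fh.write(f"{s}\t{cid}\n")
        Path(json_path).write_text(self.to_json() + "\n")


def _single_linkage_clusters(dm: DistanceMatrix, threshold: float) -> dict[str, tuple[str, ...]]:
    if len(dm) == 1:
        return {"C1": (dm.ids[0],)}
    z = linkage(dm.condensed(), method="single")
    flat = fcluster(z, t=threshold, criterion="distance")
    # relabel deterministically by first occurrence in matrix order
    order: dict[int, list[str]] = {}
    for sample, raw in zip(dm.ids, flat):
        order.setdefault(int(raw), []).append(sample)
    clusters: dict[str, tuple[str, ...]] = {}
    seen: list[int] = []
    for sample, raw in zip(dm.ids, flat):
        if raw not in seen:
            seen.append(int(raw))
    for i, raw in enumerate(seen, start=1):
        clusters[f"C{i}"] = tuple(order[raw])
    return clusters


def barcode_gap_partition(
    dm: DistanceMatrix,
    d_min_prior: float = 0.005,
    d_max_prior: float = 0.1,
    min_gap_factor: float = 0.5,
) -> PartitionResult:
    """Partition samples at the largest barcode gap in a prior window.

    Parameters
    ----------
    dm:
        Pairwise distance matrix.
    d_min_prior, d_max_prior:
        The gap's lower edge must lie in ``[d_min_prior, d_max_prior]``
        — the plausible range of maximum intraspecific divergence.
    min_gap_factor:
        A gap narrower than ``min_gap_factor * lower_edge`` is not
        considered credible; the result is then a single cluster with a
        warning flag.
    """
    if not (0 <= d_min_prior < d_max_prior):
        raise DistanceError(
            f"invalid priors: need 0 <= d_min_prior < d_max_prior, "
            f"got {d_min_prior}, {d_max_prior}"
        )
    vals = np.unique(dm.condensed()) if len(dm) > 1 else np.array([0.0])
    best_width, best_lower = 0.0, None
    for lower, upper in zip(vals[:-1], vals[1:]):
        if d_min_prior <= lower <= d_max_prior:
            width = float(upper - lower)
            if width > best_width:
                best_width, best_lower = width, float(lower)
    if best_lower is None or best_width < min_gap_factor * max(best_lower, 1e-12):
        clusters = {"C1": tuple(dm.ids)}
        return PartitionResult(clusters, threshold=float(vals[-1]) + 1e-9,
                               gap_width=best_width, single_cluster_warning=True)
    threshold = best_lower + 0.5 * best_width
    clusters = _single_linkage_clusters(dm, threshold)
    return PartitionResult(clusters, threshold=threshold, gap_width=best_width)
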