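"""Uni-directional TSS cluster calling, quantification and filtering.

Pooled per-bp CAGE signal is merged, per strand, into clusters of
nonzero positions no more than ``merge_dist`` bp apart.  Clusters are
then quantified against every sample and filtered in two stages:

1. drop clusters whose pooled raw tag count is below
   ``min_cluster_count`` (default 10);
2. keep clusters "present" (>=10 raw counts, or >10 CTPM under the
   alternative rule) in at least ``representation_min_tissues`` tissues
   — two-thirds of the panel by default, i.e. 37 of 56.

A separate mode extracts tissue-specific clusters: those expressed
(>10 counts) in exactly one tissue, with no representation filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .genome import RegionIndex
from .tags import Key, TagProfile


class ClusteringError(ValueError):
    pass


@dataclass
class ClusteringParams:
    merge_dist: int = 20
    min_cluster_count: int = 10
    representation_min_tissues: Optional[int] = None
    representation_fraction: float = 2 / 3
    presence_rule: Literal["count_ge_10", "ctpm_gt_10"] = "count_ge_10"
    presence_count: int = 10
    presence_ctpm: float = 10.0

    def __post_init__(self):
        if self.merge_dist < 0:
            raise ClusteringError("merge_dist must be >= 0")


def representation_threshold(
    n_tissues: int,
    fraction: float = 2 / 3,
    rounding: Literal["floor", "ceil"] = "floor",
) -> int:
    """Minimum tissue count for the representation filter.

    floor(56 * 2/3) = 37, the two-thirds-of-tissues cutoff; ceil gives
    38.  Always at least 1.
    """
    if n_tissues < 1:
        raise ClusteringError("n_tissues must be >= 1")
    if not (0 < fraction <= 1):
        raise ClusteringError("fraction must be in (0, 1]")
    op = math.floor if rounding == "floor" else math.ceil
    return max(1, op(n_tissues * fraction))


@dataclass
class TagClusterSet:
    """Called clusters plus per-sample count/CTPM matrices.

    ``clusters`` columns: cluster_id, contig, strand, start, end, peak,
    pooled.  ``counts``/``ctpm`` are (n_clusters, n_samples) arrays
    aligned to ``sample_ids``.
    """

    clusters: pd.DataFrame
    counts: np.ndarray
    ctpm: np.ndarray
    sample_ids: list[str]
    params: ClusteringParams = field(default_factory=ClusteringParams)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def __len__(self) -> int:
        return len(self.clusters)

    def presence(self) -> np.ndarray:
        """Boolean (n_clusters, n_samples) presence matrix."""
        if self.params.presence_rule == "count_ge_10":
            return self.counts >= self.params.presence_count
        return self.ctpm > self.params.presence_ctpm

    def subset(self, mask: np.ndarray) -> "TagClusterSet":
        return TagClusterSet(
            clusters=self.clusters.loc[mask].reset_index(drop=True),
            counts=self.counts[mask],
            ctpm=self.ctpm[mask],
            sample_ids=list(self.sample_ids),
            params=self.params,
        )

    def to_bed(self, path) -> None:
        """BED12-lite: thickStart/thickEnd mark the peak base."""
        with open(path, "w") as fh:
            for row in self.clusters.itertuples():
                fh.write(
                    f"{row.contig}\t{row.start}\t{row.end}\t{row.cluster_id}\t"
                    f"{min(1000, round(row.pooled))}\t{row.strand}\t"
                    f"{row.peak}\t{row.peak + 1}\n"
                )

    def counts_tsv(self, path) -> None:
        df = pd.DataFrame(
            self.counts,
            index=self.clusters["cluster_id"],
            columns=self.sample_ids,
        )
        df.to_csv(path, sep="\t")


def _merge_positions(
    positions: np.ndarray, values: np.ndarray, merge_dist: int, strand: str
) -> list[tuple[int, int, int, float]]:
    """Runs of positions <= merge_dist apart -> (start, end, peak, pooled)."""
    order = np.argsort(positions)
    positions = positions[order]
    values = values[order]
    breaks = np.nonzero(np.diff(positions) > merge_dist)[0] + 1
    out = []
    for seg_pos, seg_val in zip(
        np.split(positions, breaks), np.split(values, breaks)
    ):
        best = seg_val.max()
        ties = seg_pos[seg_val == best]
        peak = int(ties.min() if strand == "+" else ties.max())
        out.append((int(seg_pos[0]), int(seg_pos[-1]) + 1, peak, float(seg_val.sum())))
    return out


def call_unidirectional_clusters(
    pooled: dict[Key, dict[int, float]],
    profiles: list[TagProfile],
    params: ClusteringParams | None = None,
) -> TagClusterSet:
    """Cluster pooled signal per strand and quantify per sample.

    Consecutive nonzero positions <= ``merge_dist`` apart merge into one
    cluster; the peak is the argmax of the pooled signal (ties break to
    the 5'-most position on the cluster strand).  Each sample is then
    quantified by summing its raw counts over [start, end).
    """
    params = params or ClusteringParams()
    rows = []
    for (contig, strand) in sorted(pooled):
        d = pooled[(contig, strand)]
        if not d:
            continue
        positions = np.fromiter(d.keys(), dtype=np.int64, count=len(d))
        values = np.fromiter(d.values(), dtype=np.float64, count=len(d))
        for start, end, peak, signal in _merge_positions(
            positions, values, params.merge_dist, strand
        ):
            rows.append((contig, strand, start, end, peak, signal))

    clusters = pd.DataFrame(
        rows, columns=["contig", "strand", "start", "end", "peak", "pooled"]
    )
    clusters.insert(
        0,
        "cluster_id",
        [
            f"TC:{c}:{'p' if s == '+' else 'm'}:{a}-{b}"
            for c, s, a, b in zip(
                clusters["contig"], clusters["strand"],
                clusters["start"], clusters["end"],
            )
        ],
    )
    counts = np.zeros((len(clusters), len(profiles)), dtype=np.int64)
    totals = np.array([max(1, p.total_mapped) for p in profiles], dtype=float)
    for j, prof in enumerate(profiles):
        for i, row in enumerate(clusters.itertuples()):
            d = prof.get(row.contig, row.strand)
            if not d:
                continue
            counts[i, j] = sum(
                d.get(pos, 0) for pos in range(row.start, row.end)
            )
    ctpm = counts / totals[None, :] * 1e6
    return TagClusterSet(
        clusters=clusters,
        counts=counts,
        ctpm=ctpm,
        sample_ids=[p.sample_id for p in profiles],
        params=params,
    )


def filter_clusters(
    cluster_set: TagClusterSet, params: ClusteringParams | None = None
) -> tuple[TagClusterSet, dict]:
    """Two-stage filter: pooled-count minimum, then tissue representation.

    Returns the retained set plus an attrition report (cluster counts
    before / after each stage).
    """
    params = params or cluster_set.params
    n = cluster_set.n_samples
    min_tissues = params.representation_min_tissues
    if min_tissues is None:
        min_tissues = representation_threshold(n, params.representation_fraction)
    if min_tissues > n:
        raise ClusteringError(
            f"representation_min_tissues {min_tissues} > n_samples {n}"
        )
    raw_total = cluster_set.counts.sum(axis=1)
    stage1 = raw_total >= params.min_cluster_count
    s1 = cluster_set.subset(stage1)
    n_present = s1.presence().sum(axis=1)
    stage2 = n_present >= min_tissues
    retained = s1.subset(stage2)
    retained.params = replace(params, representation_min_tissues=min_tissues)
    report = {
        "n_input": len(cluster_set),
        "n_after_count_filter": int(stage1.sum()),
        "n_after_representation_filter": int(stage2.sum()),
        "min_cluster_count": params.min_cluster_count,
        "representation_min_tissues": int(min_tissues),
        "presence_rule": params.presence_rule,
    }
    return retained, report


def tissue_specific_clusters(
    cluster_set: TagClusterSet, min_count: int = 10
) -> dict[str, TagClusterSet]:
    """Clusters expressed (> min_count tags) in exactly one tissue.

    Run on the unfiltered set; returns per-tissue subsets.
    """
    expressed = cluster_set.counts > min_count
    n_expr = expressed.sum(axis=1)
    specific = n_expr == 1
    out = {}
    for j, sample in enumerate(cluster_set.sample_ids):
        mask = specific & expressed[:, j]
        if mask.any():
            out[sample] = cluster_set.subset(mask)
    return out


def clusters_per_gene(
    cluster_set: TagClusterSet, index: RegionIndex
) -> tuple[pd.Series, dict]:
    """Count clusters hitting each gene's promoter window.

    Returns per-gene counts (captured genes only) and a summary with
    mean/median over captured genes plus the not-captured gene count.
    """
    hits: dict[str, int] = {}
    for row in cluster_set.clusters.itertuples():
        genes, _ = index.promoter_hits(row.contig, row.start, row.end, row.strand)
        for g in genes:
            hits[g] = hits.get(g, 0) + 1
    per_gene = pd.Series(hits, dtype=int).sort_index()
    all_genes = {m.gene_id for m in index.models}
    summary = {
        "n_genes_captured": len(per_gene),
        "n_genes_not_captured": len(all_genes) - len(per_gene),
        "mean_clusters_per_gene": float(per_gene.mean()) if len(per_gene) else 0.0,
        "median_clusters_per_gene": float(per_gene.median()) if len(per_gene) else 0.0,
    }
    return per_gene, summary
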