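"""Annotated-vs-novel TSS classification against gene-model promoters.

A retained cluster is "annotated" at range *w* when its interval comes
within *w* bp of a promoter anchor (the transcript 5' end): it overlaps
the inclusive window [anchor - w, anchor + w].  The short range is 50
bp, the long range 400 bp; everything outside both is a novel TSS.
Matching is strand-agnostic by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import TagClusterSet
from .genome import TranscriptModel


@dataclass
class NoveltyCall:
    cluster_id: str
    short_range_annotated: bool
    long_range_annotated: bool
    matched_tx_ids: list[str]
    matched_gene_ids: list[str]
    distance_to_nearest_promoter: int  # signed; negative = 5' of the anchor


def _interval_anchor_distance(start: int, end: int, anchor: int) -> int:
    """Genomic gap between [start, end) and a point (0 if inside)."""
    if anchor < start:
        return start - anchor
    if anchor > end - 1:
        return anchor - (end - 1)
    return 0


def call_novelty(
    clusters: pd.DataFrame,
    models: list[TranscriptModel],
    short_window: int = 50,
    long_window: int = 400,
    stranded: bool = False,
) -> list[NoveltyCall]:
    """Classify clusters (contig/strand/start/end rows) against promoters."""
    anchors: dict[str, list[tuple[int, str, str, str]]] = {}
    for m in models:
        anchors.setdefault(m.contig, []).append(
            (m.tss_position, m.strand, m.tx_id, m.gene_id)
        )
    for v in anchors.values():
        v.sort()

    calls = []
    for row in clusters.itertuples():
        cand = anchors.get(row.contig, [])
        best = None
        matched_tx, matched_gene = set(), set()
        for pos, astrand, tx, gene in cand:
            if stranded and astrand != row.strand:
                continue
            d = _interval_anchor_distance(row.start, row.end, pos)
            signed = d
            if d > 0:
                upstream = (pos > row.end - 1) if astrand == "+" else (pos < row.start)
                # cluster 5' of the anchor on the anchor's strand -> negative
                signed = -d if upstream else d
            if best is None or d < abs(best):
                best = signed
            if d <= long_window:
                matched_tx.add(tx)
                matched_gene.add(gene)
        dist = best if best is not None else np.iinfo(np.int32).max
        calls.append(
            NoveltyCall(
                cluster_id=row.cluster_id,
                short_range_annotated=abs(dist) <= short_window,
                long_range_annotated=abs(dist) <= long_window,
                matched_tx_ids=sorted(matched_tx),
                matched_gene_ids=sorted(matched_gene),
                distance_to_nearest_promoter=int(dist),
            )
        )
    return calls


def novel_flags(calls: list[NoveltyCall], range_: str = "short") -> np.ndarray:
    attr = "short_range_annotated" if range_ == "short" else "long_range_annotated"
    return np.array([not getattr(c, attr) for c in calls], dtype=bool)


def novelty_report(
    cluster_set: TagClusterSet,
    models: list[TranscriptModel],
    short_window: int = 50,
    long_window: int = 400,
) -> pd.DataFrame:
    """Per-tissue novelty table (plus an overall Average row).

    For each tissue the clusters present there (per the presence rule)
    are classified; columns: tissue, pct_novel, n_within_50bp,
    n_within_400bp, total.
    """
    calls = call_novelty(cluster_set.clusters, models, short_window, long_window)
    short = np.array([c.short_range_annotated for c in calls])
    long_ = np.array([c.long_range_annotated for c in calls])
    presence = cluster_set.presence()
    rows = []
    for j, tissue in enumerate(cluster_set.sample_ids):
        mask = presence[:, j]
        total = int(mask.sum())
        n_short = int((short & mask).sum())
        n_long = int((long_ & mask).sum())
        pct_novel = 100.0 * (total - n_short) / total if total else 0.0
        rows.append((tissue, pct_novel, n_short, n_long, total))
    df = pd.DataFrame(
        rows, columns=["tissue", "pct_novel", "n_within_50bp", "n_within_400bp", "total"]
    )
    avg = df[["pct_novel", "n_within_50bp", "n_within_400bp", "total"]].mean()
    df.loc[len(df)] = ["Average", avg.iloc[0], avg.iloc[1], avg.iloc[2], avg.iloc[3]]
    return df
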