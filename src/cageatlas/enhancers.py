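"""Bi-directional (divergent) TSS-Enhancer cluster detection and linking.

A candidate midpoint is scored by the Bhattacharyya coefficient between
the observed 4-way tally (upstream-minus, downstream-plus,
upstream-plus, downstream-minus; arms of ``window_halfwidth`` bp) and
the ideal divergent profile (0.5, 0.5, 0, 0):

    B = sqrt(0.5 * p_um) + sqrt(0.5 * p_dp)

Balanced local maxima (B >= threshold, both divergent arms nonzero) are
kept only when their midpoint lies 400-1,000 bp from the nearest
promoter centre; everything outside that range is excluded.  Retained
loci can then be linked to uni-directional TSS clusters by Kendall
co-expression across the tissue panel with BH multiple-testing control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import TagClusterSet
from .genome import ContigSet, TranscriptModel
from .tags import Key, TagProfile


class EnhancerError(ValueError):
    pass


@dataclass
class EnhancerParams:
    window_halfwidth: int = 200
    balance_threshold: float = 0.95
    promoter_distance_range: tuple[int, int] = (400, 1000)
    min_count: int = 10  # pooled raw tags; same rule as uni-directional clusters


def balance_score(
    upstream_minus: float,
    downstream_plus: float,
    upstream_plus: float,
    downstream_minus: float,
) -> float:
    """Bhattacharyya similarity to the ideal divergent profile.

    1.0 for purely divergent signal; sqrt(0.5) when all signal sits in a
    single divergent arm.  Invariant to uniform scaling.  All-zero input
    is undefined.
    """
    vals = (upstream_minus, downstream_plus, upstream_plus, downstream_minus)
    if any(v < 0 for v in vals):
        raise EnhancerError("negative tally")
    total = sum(vals)
    if total == 0:
        raise EnhancerError("balance undefined for all-zero input")
    return math.sqrt(0.5 * upstream_minus / total) + math.sqrt(
        0.5 * downstream_plus / total
    )


@dataclass
class BidirClusterSet:
    """Retained divergent clusters plus per-sample quantification."""

    clusters: pd.DataFrame  # cluster_id, contig, midpoint, start, end, balance,
    #                         minus_arm, plus_arm, promoter_distance, nearest_gene
    counts: np.ndarray
    ctpm: np.ndarray
    sample_ids: list[str]
    params: EnhancerParams = field(default_factory=EnhancerParams)

    def __len__(self):
        return len(self.clusters)

    def subset(self, mask: np.ndarray) -> "BidirClusterSet":
        return BidirClusterSet(
            self.clusters.loc[mask].reset_index(drop=True),
            self.counts[mask],
            self.ctpm[mask],
            list(self.sample_ids),
            self.params,
        )

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for row in self.clusters.itertuples():
                fh.write(
                    f"{row.contig}\t{row.start}\t{row.end}\t{row.cluster_id}\t"
                    f"{round(1000 * row.balance)}\t.\n"
                )


def _strand_cumsum(d: dict[int, float], size: int) -> np.ndarray:
    arr = np.zeros(size + 1)
    if d:
        pos = np.fromiter(d.keys(), dtype=np.int64, count=len(d))
        val = np.fromiter(d.values(), dtype=np.float64, count=len(d))
        np.add.at(arr, pos + 1, val)
    return np.cumsum(arr)


def call_bidirectional_clusters(
    pooled: dict[Key, dict[int, float]],
    models: list[TranscriptModel],
    contigs: ContigSet,
    profiles: list[TagProfile],
    params: EnhancerParams | None = None,
) -> tuple[BidirClusterSet, BidirClusterSet]:
    """Detect divergent loci and apply the promoter-distance window.

    Returns (retained, all_candidates): candidates are balanced local
    maxima before the 400-1,000 bp filter; retained is the subset whose
    midpoint distance to the nearest promoter centre is inside the
    range.  Candidate midpoints are every position within one window of
    signal on either strand; plateaus of equal balance resolve to their
    centre.  Per-sample quantification sums both strands over
    [mid - w, mid + w].
    """
    if not models:
        raise EnhancerError("no promoters supplied; range filter cannot run")
    params = params or EnhancerParams()
    w = params.window_halfwidth
    sizes = contigs.sizes

    anchors: dict[str, np.ndarray] = {}
    anchor_gene: dict[str, list[str]] = {}
    for contig in sizes:
        pairs = sorted(
            (m.tss_position, m.gene_id) for m in models if m.contig == contig
        )
        anchors[contig] = np.array([p for p, _ in pairs], dtype=np.int64)
        anchor_gene[contig] = [g for _, g in pairs]

    rows = []
    for contig, size in sizes.items():
        plus = pooled.get((contig, "+"), {})
        minus = pooled.get((contig, "-"), {})
        if not plus and not minus:
            continue
        cplus = _strand_cumsum(plus, size)
        cminus = _strand_cumsum(minus, size)

        signal_pos = np.array(sorted(set(plus) | set(minus)), dtype=np.int64)
        # candidate midpoints: union of +-w neighbourhoods of signal
        cand = []
        run_start = None
        prev_end = None
        for p in signal_pos:
            lo, hi = max(0, p - w), min(size - 1, p + w)
            if prev_end is not None and lo <= prev_end + 1:
                prev_end = max(prev_end, hi)
            else:
                if run_start is not None:
                    cand.append((run_start, prev_end))
                run_start, prev_end = lo, hi
        if run_start is not None:
            cand.append((run_start, prev_end))

        for lo, hi in cand:
            mids = np.arange(lo, hi + 1, dtype=np.int64)
            # arms: minus strand on [mid-w, mid), plus strand on (mid, mid+w]
            lo_edge = np.clip(mids - w, 0, size)
            hi_edge = np.clip(mids + w + 1, 0, size)
            um = cminus[mids] - cminus[lo_edge]
            dp = cplus[hi_edge] - cplus[mids + 1]
            up = cplus[mids] - cplus[lo_edge]
            dm = cminus[hi_edge] - cminus[mids + 1]
            tot = um + dp + up + dm
            ok = (tot > 0) & (um > 0) & (dp > 0)
            B = np.zeros_like(tot)
            nz = tot > 0
            B[nz] = np.sqrt(0.5 * um[nz] / tot[nz]) + np.sqrt(0.5 * dp[nz] / tot[nz])
            passing = ok & (B >= params.balance_threshold)
            if not passing.any():
                continue
            # split passing candidates into contiguous runs; one call per run,
            # placed at the run centre (robust to interior dips from stray tags)
            idx = np.nonzero(passing)[0]
            splits = np.nonzero(np.diff(idx) > 1)[0] + 1
            for seg in np.split(idx, splits):
                pick = seg[len(seg) // 2]
                mid = int(mids[pick])
                rows.append(
                    (contig, mid, float(B[seg].max()),
                     float(um[pick]), float(dp[pick]))
                )

    df = pd.DataFrame(
        rows, columns=["contig", "midpoint", "balance", "minus_arm", "plus_arm"]
    )
    dists, genes = [], []
    for row in df.itertuples():
        a = anchors.get(row.contig)
        if a is None or len(a) == 0:
            dists.append(np.inf)
            genes.append("")
            continue
        i = int(np.argmin(np.abs(a - row.midpoint)))
        dists.append(int(abs(a[i] - row.midpoint)))
        genes.append(anchor_gene[row.contig][i])
    df["promoter_distance"] = dists
    df["nearest_gene"] = genes
    df["start"] = (df["midpoint"] - w).clip(lower=0)
    df["end"] = df["midpoint"] + w + 1
    df.insert(
        0,
        "cluster_id",
        [f"BC:{c}:{m}" for c, m in zip(df["contig"], df["midpoint"])],
    )

    counts = np.zeros((len(df), len(profiles)), dtype=np.int64)
    totals = np.array([max(1, p.total_mapped) for p in profiles], dtype=float)
    for j, prof in enumerate(profiles):
        for i, row in enumerate(df.itertuples()):
            c = 0
            for strand in "+-":
                d = prof.get(row.contig, strand)
                if d:
                    c += sum(d.get(pos, 0) for pos in range(row.start, row.end))
            counts[i, j] = c
    ctpm = counts / totals[None, :] * 1e6

    all_calls = BidirClusterSet(
        df, counts, ctpm, [p.sample_id for p in profiles], params
    )
    # the <min_count pooled-tag cluster filter applies to divergent clusters too
    candidates = all_calls.subset(counts.sum(axis=1) >= params.min_count)
    lo, hi = params.promoter_distance_range
    dist = candidates.clusters["promoter_distance"]
    keep = (dist >= lo) & (dist <= hi)
    return candidates.subset(keep.to_numpy()), candidates


@dataclass
class CoexpressionLink:
    bidir_id: str
    uni_id: str
    kendall_tau: float
    p_value: float
    q_value: float
    distance: int


def find_links(
    bidir: BidirClusterSet,
    uni: TagClusterSet,
    max_link_distance: int = 10_000,
    alpha: float = 0.05,
) -> list[CoexpressionLink]:
    """Kendall tau-b co-expression links between divergent and TSS clusters.

    Tests every same-contig pair within ``max_link_distance`` (midpoint
    to cluster interval); BH-adjusts across all tested pairs and returns
    links with q <= alpha.  Constant expression vectors are skipped.
    """
    if bidir.sample_ids != uni.sample_ids:
        raise EnhancerError("bidir and uni sets quantified over different samples")
    if len(bidir.sample_ids) < 8:
        raise EnhancerError("need >= 8 samples for co-expression links")
    tested = []
    uni_by_contig = {
        contig: sub for contig, sub in uni.clusters.groupby("contig")
    }
    for bi, brow in enumerate(bidir.clusters.itertuples()):
        sub = uni_by_contig.get(brow.contig)
        if sub is None:
            continue
        x = bidir.ctpm[bi]
        if np.all(x == x[0]):
            continue
        gap = np.maximum(
            sub["start"].to_numpy() - brow.midpoint,
            brow.midpoint - (sub["end"].to_numpy() - 1),
        ).clip(min=0)
        for ui, dist in zip(sub.index[gap <= max_link_distance],
                            gap[gap <= max_link_distance]):
            y = uni.ctpm[ui]
            if np.all(y == y[0]):
                continue
            tau, p = stats.kendalltau(x, y)
            if np.isnan(tau):
                continue
            tested.append(
                (brow.cluster_id, uni.clusters.at[ui, "cluster_id"],
                 float(tau), float(p), int(dist))
            )
    if not tested:
        return []
    pvals = np.array([t[3] for t in tested])
    qvals = stats.false_discovery_control(pvals, method="bh")
    links = [
        CoexpressionLink(b, u, tau, p, float(q), d)
        for (b, u, tau, p, d), q in zip(tested, qvals)
        if q <= alpha
    ]
    return links


def write_links_tsv(links: list[CoexpressionLink], path) -> None:
    df = pd.DataFrame(
        [
            (l.bidir_id, l.uni_id, l.kendall_tau, l.p_value, l.q_value, l.distance)
            for l in links
        ],
        columns=["bidir_id", "uni_id", "kendall_tau", "p_value", "q_value", "distance"],
    )
    df.to_csv(path, sep="\t", index=False)
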