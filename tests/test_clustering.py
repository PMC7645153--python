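"""TSS clustering, filtering and per-gene metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cageatlas import clustering as cl
from cageatlas import genome as gn
from cageatlas import simulate as sim
from cageatlas import tags as tg


def brute_force_merge(signal: dict[int, float], merge_dist: int, strand: str):
    """Independent clustering oracle: walk sorted positions, group by gap."""
    if not signal:
        return []
    pos = sorted(signal)
    groups = [[pos[0]]]
    for p in pos[1:]:
        if p - groups[-1][-1] <= merge_dist:
            groups[-1].append(p)
        else:
            groups.append([p])
    out = []
    for g in groups:
        best = max(signal[p] for p in g)
        candidates = [p for p in g if signal[p] == best]
        peak = min(candidates) if strand == "+" else max(candidates)
        out.append((g[0], g[-1] + 1, peak, sum(signal[p] for p in g)))
    return out


def _call(signal, strand="+", merge_dist=20):
    prof = tg.TagProfile("s")
    for p, v in signal.items():
        prof.add("chr1", strand, p, int(v))
    pooled = {("chr1", strand): dict(signal)}
    cs = cl.call_unidirectional_clusters(
        pooled, [prof], cl.ClusteringParams(merge_dist=merge_dist)
    )
    return [
        (r.start, r.end, r.peak, r.pooled) for r in cs.clusters.itertuples()
    ]


def test_representation_threshold_values():
    assert cl.representation_threshold(56, 2 / 3) == 37
    assert cl.representation_threshold(56, 2 / 3, rounding="ceil") == 38
    assert cl.representation_threshold(56, 1.0) == 56
    assert cl.representation_threshold(3, 2 / 3) == 2
    with pytest.raises(cl.ClusteringError):
        cl.representation_threshold(0, 0.5)


def test_worked_example_clusters():
    got = _call({100: 12, 101: 30, 102: 8, 150: 9})
    assert got == [(100, 103, 101, 50.0), (150, 151, 150, 9.0)]


def test_single_position_single_cluster():
    assert _call({42: 7}) == [(42, 43, 42, 7.0)]


def test_merge_distance_boundary():
    two = _call({100: 5, 121: 5})  # 21 bp apart -> two clusters
    one = _call({100: 5, 120: 5})  # 20 bp apart -> one cluster
    assert len(two) == 2
    assert len(one) == 1 and one[0][:2] == (100, 121)


def test_peak_tie_breaks_five_prime():
    plus = _call({10: 5, 12: 5})
    minus = _call({10: 5, 12: 5}, strand="-")
    assert plus[0][2] == 10
    assert minus[0][2] == 12


def test_clustering_matches_brute_force_on_random_signals():
    rng = np.random.default_rng(17)
    for i in range(300):
        n = int(rng.integers(1, 25))
        positions = rng.choice(2000, size=n, replace=False)
        signal = {int(p): float(rng.integers(1, 40)) for p in positions}
        merge_dist = int(rng.integers(0, 40))
        strand = "+" if i % 2 else "-"
        assert _call(signal, strand, merge_dist) == brute_force_merge(
            signal, merge_dist, strand
        )


def test_clustering_order_independent():
    signal = {30: 2.0, 10: 5.0, 11: 1.0, 100: 3.0}
    shuffled = dict(reversed(list(signal.items())))
    assert _call(signal) == _call(shuffled)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(
    st.sets(st.integers(0, 500), min_size=1, max_size=40),
    st.integers(0, 30),
)
def test_merge_monotonicity(positions, merge_dist):
    """Raising merge_dist never increases the cluster count."""
    signal = {p: 1.0 for p in positions}
    n_small = len(brute_force_merge(signal, merge_dist, "+"))
    n_big = len(_call(signal, merge_dist=merge_dist + 5))
    assert n_big <= n_small


def _toy_set(counts: np.ndarray) -> cl.TagClusterSet:
    n_clusters, n_samples = counts.shape
    clusters = pd.DataFrame(
        {
            "cluster_id": [f"c{i}" for i in range(n_clusters)],
            "contig": "chr1",
            "strand": "+",
            "start": np.arange(n_clusters) * 100,
            "end": np.arange(n_clusters) * 100 + 5,
            "peak": np.arange(n_clusters) * 100 + 2,
            "pooled": counts.sum(axis=1).astype(float),
        }
    )
    return cl.TagClusterSet(
        clusters=clusters,
        counts=counts,
        ctpm=counts.astype(float),
        sample_ids=[f"t{j}" for j in range(n_samples)],
    )


def test_two_stage_filter_with_known_tissue_spread():
    """Clusters planted in 10/37/56 tissues: only 37 and 56 survive."""
    n = 56
    counts = np.zeros((4, n), dtype=np.int64)
    counts[0, :10] = 20   # 10 tissues -> dropped by representation
    counts[1, :37] = 20   # exactly the two-thirds cutoff -> kept
    counts[2, :] = 20     # ubiquitous -> kept
    counts[3, 0] = 9      # pooled count 9 -> dropped by stage 1
    cs = _toy_set(counts)
    kept, report = cl.filter_clusters(cs)
    assert list(kept.clusters["cluster_id"]) == ["c1", "c2"]
    assert report["n_after_count_filter"] == 3
    assert report["representation_min_tissues"] == 37


def test_filter_monotonic_in_threshold():
    rng = np.random.default_rng(2)
    counts = rng.integers(0, 30, size=(50, 12))
    cs = _toy_set(counts)
    sizes = []
    for thr in range(1, 13):
        params = cl.ClusteringParams(representation_min_tissues=thr)
        kept, _ = cl.filter_clusters(cs, params)
        sizes.append(len(kept))
    assert sizes == sorted(sizes, reverse=True)
    with pytest.raises(cl.ClusteringError):
        cl.filter_clusters(cs, cl.ClusteringParams(representation_min_tissues=13))


def test_tissue_specific_requires_exactly_one_tissue():
    counts = np.zeros((3, 5), dtype=np.int64)
    counts[0, 1] = 12              # specific to t1
    counts[1, [1, 2]] = 12         # two tissues -> excluded
    counts[2, 3] = 10              # not > 10 -> excluded
    per_tissue = cl.tissue_specific_clusters(_toy_set(counts))
    assert set(per_tissue) == {"t1"}
    assert list(per_tissue["t1"].clusters["cluster_id"]) == ["c0"]


def test_planted_tissue_specific_recovered(panel_analysis):
    truth = panel_analysis.truth
    per_tissue = cl.tissue_specific_clusters(panel_analysis.unfiltered)
    names = truth.config.tissue_names()
    found = 0
    for t in truth.tss:
        if t.category != "tissue_specific":
            continue
        tissue = names[t.tissues[0]]
        subs = per_tissue.get(tissue)
        if subs is not None and any(
            r.contig == t.contig and r.start - 5 <= t.position < r.end + 5
            for r in subs.clusters.itertuples()
        ):
            found += 1
    n_planted = sum(1 for t in truth.tss if t.category == "tissue_specific")
    assert found >= 0.9 * n_planted


def test_clusters_per_gene_counts_promoter_hits(toy_models):
    contigs, models = toy_models
    index = gn.build_region_index(models, contigs)
    counts = np.full((3, 4), 20, dtype=np.int64)
    cs = _toy_set(counts)
    cs.clusters["start"] = [1990, 2040, 8000]  # two in geneA promoter window
    cs.clusters["end"] = [1995, 2045, 8005]
    cs.clusters["peak"] = [1992, 2042, 8002]
    per_gene, summary = cl.clusters_per_gene(cs, index)
    assert per_gene["geneA"] == 2
    assert summary["n_genes_captured"] == 1
    assert summary["n_genes_not_captured"] == 2


def test_second_tss_fraction_shifts_mean_clusters_per_gene(tmp_path):
    """Planting a second promoter TSS in 30% of genes gives mean ~1.3."""
    cfg = sim.GeneratorConfig(
        seed=5, n_tissues=10, n_contigs=1, contig_length=150_000, n_genes=30,
        frac_multi_tss=0.3, frac_novel_tss=0.0, frac_tissue_specific=0.0,
        frac_restricted=0.0, frac_with_enhancer=0.0, enhancer_decoy_frac=0.0,
        n_families=2, family_block_size=0, n_wgbs_tissues=0, n_mrna_tissues=0,
        shared_tissue_range=(9, 10),
    )
    truth = sim.generate(cfg, tmp_path)
    contigs = gn.ContigSet.from_tsv(tmp_path / "contigs.tsv")
    models = gn.load_annotation(tmp_path / "annotation.gff3", contigs)
    profiles = [
        tg.load_tags(p, format="bedgraph_pair")
        for p in sorted((tmp_path / "cage").glob("*.plus.bedGraph"))
    ]
    pooled = tg.pool_profiles(profiles)
    params = cl.ClusteringParams(representation_min_tissues=7)
    kept, _ = cl.filter_clusters(
        cl.call_unidirectional_clusters(pooled, profiles, params), params
    )
    index = gn.build_region_index(models, contigs)
    _, summary = cl.clusters_per_gene(kept, index)
    assert summary["median_clusters_per_gene"] == 1
    assert summary["mean_clusters_per_gene"] == pytest.approx(1.3, abs=0.1)
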