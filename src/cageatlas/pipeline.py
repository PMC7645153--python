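"""End-to-end orchestration of the TSS / enhancer / methylation analysis.

``run_all`` drives the full workflow over a directory of input files
(the layout the synthetic generator writes): load tags, pool, call and
filter uni-directional clusters, detect bi-directional TSS-Enhancer
loci, classify genomic regions, annotate novelty per tissue, call
hypomethylated regions and cross them with the TSS calls, build MI
dendrograms and Kendall co-expression links, and leave a summary JSON
plus track exports in the output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering as cl
from . import enhancers as enh
from . import genome as gn
from . import methylation as meth
from . import novelty as nov
from . import profiles as pr
from . import tags as tg

log = logging.getLogger("cageatlas")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """All stage parameters plus input locations.

    ``input_dir`` must contain contigs.tsv, annotation.gff3, cage/
    (bedGraph pairs per tissue) and optionally wgbs/ (CGmap tables) and
    mrna/ (kallisto abundance tables).
    """

    input_dir: str = "."
    pooling_mode: str = "ctpm"
    clustering: cl.ClusteringParams = field(default_factory=cl.ClusteringParams)
    region: gn.RegionIndexParams = field(default_factory=gn.RegionIndexParams)
    enhancer: enh.EnhancerParams = field(default_factory=enh.EnhancerParams)
    hmm: meth.HMMParams = field(default_factory=meth.HMMParams)
    short_window: int = 50
    long_window: int = 400
    max_link_distance: int = 10_000
    link_alpha: float = 0.05
    n_bins: int = 10
    threshold_fractions: tuple = (None, None, 1 / 3, 1 / 2, 2 / 3, 1.0)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise PipelineError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if dataclasses.is_dataclass(current):
                value = type(current)(**value)
            setattr(cfg, key, value)
        return cfg

    def thresholds(self, n_tissues: int) -> list[int]:
        """Representation thresholds to compare: 1, 5, n/3, n/2, 2n/3, n."""
        out = [1, min(5, n_tissues)]
        for frac in self.threshold_fractions[2:]:
            out.append(cl.representation_threshold(n_tissues, frac))
        return sorted(set(t for t in out if 1 <= t <= n_tissues))


def load_inputs(config: RunConfig):
    base = Path(config.input_dir)
    contigs = gn.ContigSet.from_tsv(base / "contigs.tsv")
    models = gn.load_annotation(base / "annotation.gff3", contigs)
    plus_files = sorted((base / "cage").glob("*.plus.bedGraph"))
    if not plus_files:
        raise PipelineError(f"no CAGE bedGraph pairs under {base / 'cage'}")
    profiles = [
        tg.load_tags(p, format="bedgraph_pair",
                     sample_id=p.name.replace(".plus.bedGraph", ""))
        for p in plus_files
    ]
    return contigs, models, profiles


def _stage(name):
    log.info("stage: %s", name)
    return time.monotonic()


def run_all(config: RunConfig, outdir: str | Path) -> dict:
    """Run every stage; returns (and writes) the summary dictionary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "run_config.yaml")
    summary: dict = {}
    marker = outdir / "INCOMPLETE"
    marker.write_text("run in progress\n")
    try:
        t0 = _stage("load")
        contigs, models, profiles = load_inputs(config)
        summary["n_tissues"] = len(profiles)
        summary["n_transcripts"] = len(models)

        _stage("pool+cluster")
        pooled = tg.pool_profiles(profiles, mode=config.pooling_mode,
                                  contigs=set(contigs.sizes))
        unfiltered = cl.call_unidirectional_clusters(
            pooled, profiles, config.clustering)
        filtered, attrition = cl.filter_clusters(unfiltered, config.clustering)
        summary["attrition"] = attrition
        filtered.to_bed(outdir / "tss_clusters.bed")
        filtered.counts_tsv(outdir / "tss_counts.tsv")

        _stage("regions")
        index = gn.build_region_index(models, contigs, config.region)
        classes = [
            index.classify_interval(r.contig, r.start, r.end, r.strand, r.peak)[0]
            for r in filtered.clusters.itertuples()
        ]
        counts = pd.Series(classes).value_counts()
        summary["region_class_pct"] = {
            c: round(100.0 * counts.get(c, 0) / max(1, len(classes)), 2)
            for c in gn.REGION_CLASSES
        }
        per_gene, gene_summary = cl.clusters_per_gene(filtered, index)
        summary["clusters_per_gene"] = gene_summary

        _stage("enhancers")
        bidir, candidates = enh.call_bidirectional_clusters(
            pooled, models, contigs, profiles, config.enhancer)
        summary["n_bidirectional_candidates"] = len(candidates)
        summary["n_bidirectional_retained"] = len(bidir)
        bidir.to_bed(outdir / "enhancer_clusters.bed")

        _stage("novelty")
        calls = nov.call_novelty(
            filtered.clusters, models, config.short_window, config.long_window)
        flags = nov.novel_flags(calls, "short")
        report = nov.novelty_report(
            filtered, models, config.short_window, config.long_window)
        report.to_csv(outdir / "novelty_per_tissue.tsv", sep="\t", index=False)
        summary["pct_novel_overall"] = float(
            100.0 * flags.sum() / max(1, len(flags)))

        _stage("links")
        links = enh.find_links(bidir, filtered, config.max_link_distance,
                               config.link_alpha)
        enh.write_links_tsv(links, outdir / "coexpression_links.tsv")
        summary["n_links"] = len(links)

        _stage("methylation")
        wgbs_dir = Path(config.input_dir) / "wgbs"
        hypo_by_tissue = {}
        if wgbs_dir.is_dir():
            per_tissue = []
            for cgmap in sorted(wgbs_dir.glob("*.cgmap.tsv")):
                tissue = cgmap.name.replace(".cgmap.tsv", "")
                track = meth.merge_symmetric_cpgs(
                    meth.read_cgmap(cgmap), sample_id=tissue)
                hmrs, model, post = meth.fit_and_segment(track, config.hmm)
                hmrs.to_bed(outdir / f"hmr_{tissue}.bed")
                cats, vsum = meth.validate_tss(
                    filtered.clusters, flags, hmrs)
                vsum["tissue"] = tissue
                vsum["hmm_state_means"] = [round(x, 4)
                                           for x in model.state_means_]
                per_tissue.append(vsum)
                hypo_by_tissue[tissue] = hmrs
            summary["hypomethylation_validation"] = per_tissue
            if per_tissue:
                summary["pct_novel_hypo_mean"] = float(
                    np.mean([v["pct_novel_hypo"] for v in per_tissue]))
                summary["pct_annotated_hypo_mean"] = float(
                    np.mean([v["pct_annotated_hypo"] for v in per_tissue]))

        _stage("profiles")
        count_filtered = unfiltered.subset(
            unfiltered.counts.sum(axis=1) >= config.clustering.min_cluster_count)
        matrix = pd.DataFrame(
            count_filtered.ctpm,
            index=count_filtered.clusters["cluster_id"],
            columns=count_filtered.sample_ids,
        )
        newick, dm, linkage = pr.cluster_tissues(matrix, config.n_bins)
        (outdir / "tissue_dendrogram.nwk").write_text(newick + "\n")
        dm.to_phylip(outdir / "mi_distance.phylip")
        share = pr.sharing_matrix(filtered)
        share.to_csv(outdir / "sharing_matrix.tsv", sep="\t")

        summary["elapsed_s"] = round(time.monotonic() - t0, 2)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1)
        marker.unlink()
    except Exception as exc:
        marker.write_text(f"failed: {exc}\n")
        raise PipelineError(f"pipeline failed: {exc}") from exc
    return summary


def compare_thresholds(
    unfiltered: cl.TagClusterSet,
    index: gn.RegionIndex,
    thresholds: list[int],
    params: cl.ClusteringParams | None = None,
) -> pd.DataFrame:
    """Representation-threshold comparison table.

    For each candidate minimum-tissue threshold: clusters retained,
    genes tagged through promoter windows, and the percentage of
    retained clusters not associated with any gene ("untagged").
    """
    params = params or unfiltered.params
    rows = []
    for thr in thresholds:
        p = dataclasses.replace(params, representation_min_tissues=int(thr))
        retained, _ = cl.filter_clusters(unfiltered, p)
        tagged = 0
        genes = set()
        for r in retained.clusters.itertuples():
            g, _ = index.promoter_hits(r.contig, r.start, r.end, r.strand)
            if g:
                tagged += 1
                genes.update(g)
        n = len(retained)
        rows.append(
            (int(thr), n, len(genes),
             round(100.0 * (n - tagged) / n, 2) if n else 0.0)
        )
    return pd.DataFrame(
        rows, columns=["threshold", "clusters_retained", "genes_tagged",
                       "pct_untagged"]
    )
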