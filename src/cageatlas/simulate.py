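"""Synthetic tissue panel generator with a machine-readable truth table.

Emulates the data structure of a multi-tissue CAGE / WGBS annotation
study on a small genome: many tissues share a core set of
promoter-focal TSS; a minority of loci are tissue-restricted or
strictly tissue-specific; some genes carry a divergent TSS-Enhancer
locus 400-1,000 bp upstream of the promoter (plus out-of-range decoys);
background noise tags are sprinkled genome-wide; and CpG methylation
tracks carry hypomethylated islands over true promoters and a known
fraction of the novel TSS, but not over spurious loci.

Genes live in fixed 5 kb slots (alternating strands) so that planted
elements keep known distances to every promoter anchor:

* in-range enhancers 410-990 bp upstream, decoys at 150-300 or
  1,850-2,300 bp;
* novel TSS 1,300-1,750 bp upstream (always > 400 bp from any anchor);
* tissue-restricted / family-block loci 1,850-2,300 bp upstream.

Everything is drawn from one seeded generator: a fixed seed gives
byte-identical output files.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import genome as gn
from . import methylation as meth
from . import tags as tg

SLOT = 5000
JITTER_WEIGHTS = np.array([0.1, 0.2, 0.4, 0.2, 0.1])


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_tissues: int = 56
    n_contigs: int = 2
    contig_length: int = 500_000
    n_genes: int = 200
    frac_multi_tss: float = 0.1
    frac_novel_tss: float = 0.4
    frac_tissue_specific: float = 0.05
    frac_restricted: float = 0.05
    frac_with_enhancer: float = 0.2
    enhancer_decoy_frac: float = 0.05
    tss_count_mean: float = 50.0
    tss_count_dispersion: float = 0.5
    jitter: int = 2
    noise_rate: float = 1e-5
    frac_novel_with_hmr: float = 0.3
    promoter_hmr_frac: float = 0.9
    island_meth: tuple[float, float] = (1.0, 9.0)
    background_meth: tuple[float, float] = (9.0, 1.0)
    coverage_mean: float = 20.0
    n_wgbs_tissues: int = 8
    n_mrna_tissues: int = 52
    n_families: int = 4
    family_block_size: int = 24
    shared_tissue_range: tuple[int, int] = (45, 56)
    restricted_tissue_range: tuple[int, int] = (5, 36)
    enhancer_tissue_range: tuple[int, int] = (15, 30)
    enhancer_distance_range: tuple[int, int] = (410, 990)
    enhancer_arm_offset: int = 80
    island_halfwidth: int = 300

    def tissue_names(self) -> list[str]:
        return [f"tissue{i + 1:02d}" for i in range(self.n_tissues)]

    def families(self) -> dict[str, int]:
        groups = np.array_split(np.arange(self.n_tissues), self.n_families)
        names = self.tissue_names()
        return {
            names[t]: f for f, grp in enumerate(groups) for t in grp
        }


@dataclass
class PlantedTSS:
    contig: str
    position: int
    strand: str
    gene_id: str | None
    tissues: list[int]
    category: str  # gene | multi | novel | tissue_specific | restricted | family_block
    novel: bool
    has_hmr: bool = False


@dataclass
class PlantedEnhancer:
    contig: str
    midpoint: int
    distance: int
    in_range: bool
    gene_id: str
    tissues: list[int]


@dataclass
class TruthTable:
    config: GeneratorConfig
    tss: list[PlantedTSS]
    enhancers: list[PlantedEnhancer]
    hmr_islands: list[tuple[str, int, int]]
    family_of_tissue: dict[str, int]

    def tss_by_category(self, *categories: str) -> list[PlantedTSS]:
        return [t for t in self.tss if t.category in categories]

    def uni_truth_positions(self) -> list[tuple[str, str, int]]:
        """All planted transcribed 5'-end loci, enhancer arms included."""
        pts = [(t.contig, t.strand, t.position) for t in self.tss]
        off = self.config.enhancer_arm_offset
        for e in self.enhancers:
            pts.append((e.contig, "-", e.midpoint - off))
            pts.append((e.contig, "+", e.midpoint + off))
        return pts

    def to_json(self, path) -> None:
        payload = {
            "config": asdict(self.config),
            "tss": [asdict(t) for t in self.tss],
            "enhancers": [asdict(e) for e in self.enhancers],
            "hmr_islands": self.hmr_islands,
            "family_of_tissue": self.family_of_tissue,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        with open(path) as fh:
            payload = json.load(fh)
        cfg = payload["config"]
        for key in (
            "island_meth", "background_meth", "shared_tissue_range",
            "restricted_tissue_range", "enhancer_tissue_range",
            "enhancer_distance_range",
        ):
            cfg[key] = tuple(cfg[key])
        return cls(
            config=GeneratorConfig(**cfg),
            tss=[PlantedTSS(**t) for t in payload["tss"]],
            enhancers=[PlantedEnhancer(**e) for e in payload["enhancers"]],
            hmr_islands=[tuple(h) for h in payload["hmr_islands"]],
            family_of_tissue=payload["family_of_tissue"],
        )


# ------------------------------------------------------------------ helpers


def _nb_counts(rng, mean, dispersion, size):
    """Negative binomial with var = mean + dispersion * mean^2."""
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def _scatter_locus(rng, profile, contig, strand, peak, count, jitter):
    """Distribute a locus's tags over peak +- jitter positions."""
    if count <= 0:
        return
    if jitter == 0:
        profile.add(contig, strand, peak, int(count))
        return
    k = 2 * jitter + 1
    w = JITTER_WEIGHTS if k == 5 else np.ones(k) / k
    split = rng.multinomial(count, w / w.sum())
    for off, c in zip(range(-jitter, jitter + 1), split):
        if c > 0:
            profile.add(contig, strand, peak + off, int(c))


# ----------------------------------------------------------------- generate


def _build_gene_models(cfg: GeneratorConfig) -> tuple[gn.ContigSet, list[gn.TranscriptModel]]:
    slots_per_contig = cfg.contig_length // SLOT
    if cfg.n_genes > cfg.n_contigs * slots_per_contig:
        raise ValueError("too many genes for the genome size")
    contigs = gn.ContigSet.from_pairs(
        (f"chr{i + 1}", cfg.contig_length) for i in range(cfg.n_contigs)
    )
    models = []
    for g in range(cfg.n_genes):
        contig = f"chr{g // slots_per_contig + 1}"
        base = (g % slots_per_contig) * SLOT
        strand = "+" if g % 2 == 0 else "-"
        gid, tid = f"gene{g:03d}", f"tx{g:03d}"
        if strand == "+":
            exons = [(base + 2600, base + 3000), (base + 3500, base + 4100)]
            cds = [(base + 2800, base + 3000), (base + 3500, base + 3900)]
        else:
            exons = [(base + 900, base + 1500), (base + 2000, base + 2400)]
            cds = [(base + 1100, base + 1500), (base + 2000, base + 2200)]
        models.append(
            gn.TranscriptModel(
                tx_id=tid, gene_id=gid, contig=contig, strand=strand,
                exons=exons, cds=cds,
            )
        )
    return contigs, models


def _plan_truth(cfg: GeneratorConfig, models: list[gn.TranscriptModel], rng) -> TruthTable:
    n_genes = cfg.n_genes
    lo_s = min(cfg.shared_tissue_range[0], cfg.n_tissues)
    hi_s = min(cfg.shared_tissue_range[1], cfg.n_tissues)

    def shared_tissues():
        n = int(rng.integers(lo_s, hi_s + 1))
        return sorted(int(t) for t in rng.choice(cfg.n_tissues, n, replace=False))

    tss: list[PlantedTSS] = []
    for m in models:
        tss.append(
            PlantedTSS(m.contig, m.tss_position, m.strand, m.gene_id,
                       shared_tissues(), "gene", novel=False)
        )

    n_multi = round(cfg.frac_multi_tss * n_genes)
    multi_idx = rng.choice(n_genes, n_multi, replace=False)
    for gi in sorted(int(i) for i in multi_idx):
        m = models[gi]
        offset = 40 if m.strand == "+" else -40
        tss.append(
            PlantedTSS(m.contig, m.tss_position + offset, m.strand, m.gene_id,
                       tss[gi].tissues, "multi", novel=False)
        )

    n_annot = len(tss)
    n_novel = round(cfg.frac_novel_tss / (1 - cfg.frac_novel_tss) * n_annot)
    n_ts = round(cfg.frac_tissue_specific * (n_annot + n_novel))
    n_restricted = round(cfg.frac_restricted * (n_annot + n_novel))
    n_family = cfg.n_families * cfg.family_block_size

    def upstream_pos(m: gn.TranscriptModel, offset: int) -> int:
        return m.tss_position - offset if m.strand == "+" else m.tss_position + offset

    # zone B1 (1,300-1,750 bp upstream): novel + tissue-specific loci
    b1_slots = rng.permutation(n_genes)[: n_novel + n_ts]
    for j, gi in enumerate(sorted(int(i) for i in b1_slots)):
        m = models[gi]
        offset = int(rng.integers(1300, 1751))
        pos = upstream_pos(m, offset)
        strand = "+" if rng.random() < 0.5 else "-"
        if j < n_novel:
            tss.append(PlantedTSS(m.contig, pos, strand, None,
                                  shared_tissues(), "novel", novel=True))
        else:
            t = int(rng.integers(cfg.n_tissues))
            tss.append(PlantedTSS(m.contig, pos, strand, None, [t],
                                  "tissue_specific", novel=True))

    # zone B2 (1,850-2,300 bp upstream): restricted + family blocks (+ far decoys)
    lo_r = min(cfg.restricted_tissue_range[0], cfg.n_tissues)
    hi_r = min(cfg.restricted_tissue_range[1], cfg.n_tissues)
    fam_groups = np.array_split(np.arange(cfg.n_tissues), cfg.n_families)
    n_decoy = round(cfg.enhancer_decoy_frac * n_genes)
    n_decoy_near = n_decoy // 2
    n_decoy_far = n_decoy - n_decoy_near
    b2_slots = rng.permutation(n_genes)[: n_restricted + n_family + n_decoy_far]
    b2_slots = sorted(int(i) for i in b2_slots)
    far_decoy_slots = b2_slots[n_restricted + n_family:]
    for j, gi in enumerate(b2_slots[: n_restricted + n_family]):
        m = models[gi]
        offset = int(rng.integers(1850, 2301))
        pos = upstream_pos(m, offset)
        strand = "+" if rng.random() < 0.5 else "-"
        if j < n_restricted:
            n = int(rng.integers(lo_r, hi_r + 1))
            tissues = sorted(int(t) for t in rng.choice(cfg.n_tissues, n, replace=False))
            tss.append(PlantedTSS(m.contig, pos, strand, None, tissues,
                                  "restricted", novel=True))
        else:
            fam = (j - n_restricted) // cfg.family_block_size
            fam_tissues = [int(t) for t in fam_groups[fam]]
            tss.append(PlantedTSS(m.contig, pos, strand, None, fam_tissues,
                                  "family_block", novel=True))

    # zone A (enhancers 410-990 bp upstream, near decoys 150-300 bp)
    n_enh = round(cfg.frac_with_enhancer * n_genes)
    lo_e = min(cfg.enhancer_tissue_range[0], cfg.n_tissues)
    hi_e = min(cfg.enhancer_tissue_range[1], cfg.n_tissues)
    a_slots = sorted(int(i) for i in rng.permutation(n_genes)[: n_enh + n_decoy_near])
    enhancers: list[PlantedEnhancer] = []
    gene_tissues = {t.gene_id: t.tissues for t in tss if t.category == "gene"}

    def enh_tissues(gid):
        host = gene_tissues[gid]
        n = min(int(rng.integers(lo_e, hi_e + 1)), len(host))
        return sorted(int(t) for t in rng.choice(host, n, replace=False))

    for j, gi in enumerate(a_slots):
        m = models[gi]
        if j < n_enh:
            d = int(rng.integers(*cfg.enhancer_distance_range))
            in_range = True
        else:
            d = int(rng.integers(150, 301))
            in_range = False
        mid = upstream_pos(m, d)
        enhancers.append(
            PlantedEnhancer(m.contig, mid, d, in_range, m.gene_id,
                            enh_tissues(m.gene_id))
        )
    for gi in far_decoy_slots:
        m = models[gi]
        d = int(rng.integers(1850, 2301))
        enhancers.append(
            PlantedEnhancer(m.contig, upstream_pos(m, d), d, False, m.gene_id,
                            enh_tissues(m.gene_id))
        )

    # hypomethylated islands: most promoters + a fixed fraction of novel loci
    islands: list[tuple[str, int, int]] = []
    hw = cfg.island_halfwidth
    prom = [t for t in tss if t.category == "gene"]
    keep = rng.random(len(prom)) < cfg.promoter_hmr_frac
    for t, k in zip(prom, keep):
        if k:
            islands.append((t.contig, max(0, t.position - hw), t.position + hw))
    novel = [t for t in tss if t.category == "novel"]
    n_hmr = round(cfg.frac_novel_with_hmr * len(novel))
    hmr_idx = set(int(i) for i in rng.choice(len(novel), n_hmr, replace=False))
    for i, t in enumerate(novel):
        if i in hmr_idx:
            t.has_hmr = True
            islands.append((t.contig, max(0, t.position - hw), t.position + hw))
    islands.sort()

    return TruthTable(
        config=cfg, tss=tss, enhancers=enhancers, hmr_islands=islands,
        family_of_tissue=cfg.families(),
    )


def _family_multiplier(cfg, rng, n_loci) -> np.ndarray:
    """Per-locus per-family expression multipliers (family signature)."""
    mult = np.ones((n_loci, cfg.n_families))
    informative = rng.random(n_loci) < 0.5
    for i in np.nonzero(informative)[0]:
        mult[i, int(rng.integers(cfg.n_families))] = 4.0
    return mult


def simulate_profiles(
    truth: TruthTable, rng
) -> list[tg.TagProfile]:
    """Draw per-tissue tag profiles from the planted truth."""
    cfg = truth.config
    names = cfg.tissue_names()
    fam_of = [truth.family_of_tissue[n] for n in names]
    profiles = [tg.TagProfile(sample_id=n) for n in names]

    shared = truth.tss
    mult = _family_multiplier(cfg, rng, len(shared))
    gene_counts: dict[str, np.ndarray] = {}
    for i, t in enumerate(shared):
        for tissue in t.tissues:
            mean = cfg.tss_count_mean * mult[i, fam_of[tissue]]
            if t.category == "tissue_specific":
                count = 11 + int(rng.poisson(20))
            else:
                count = int(_nb_counts(rng, mean, cfg.tss_count_dispersion, 1)[0])
            if t.category == "gene":
                gene_counts.setdefault(
                    t.gene_id, np.zeros(cfg.n_tissues, dtype=np.int64)
                )[tissue] = count
            _scatter_locus(rng, profiles[tissue], t.contig, t.strand,
                           t.position, count, cfg.jitter)

    off = cfg.enhancer_arm_offset
    # enhancer arms: divergent eRNA tracking the host gene's expression
    for e in truth.enhancers:
        host = gene_counts[e.gene_id]
        for tissue in e.tissues:
            arm = max(5, int(host[tissue]) // 2)
            _scatter_locus(rng, profiles[tissue], e.contig, "-",
                           e.midpoint - off, arm, cfg.jitter)
            _scatter_locus(rng, profiles[tissue], e.contig, "+",
                           e.midpoint + off, arm, cfg.jitter)

    genome = cfg.n_contigs * cfg.contig_length
    for tissue, prof in enumerate(profiles):
        n_noise = int(rng.poisson(cfg.noise_rate * genome))
        for _ in range(n_noise):
            contig = f"chr{int(rng.integers(cfg.n_contigs)) + 1}"
            pos = int(rng.integers(cfg.contig_length))
            strand = "+" if rng.random() < 0.5 else "-"
            prof.add(contig, strand, pos, 1)
    return profiles


def _cpg_sites(cfg: GeneratorConfig, truth: TruthTable, rng) -> dict[str, np.ndarray]:
    """CpG coordinates: sparse background plus dense islands (fixed layout)."""
    islands_by_contig: dict[str, list[tuple[int, int]]] = {}
    for contig, s, e in truth.hmr_islands:
        islands_by_contig.setdefault(contig, []).append((s, e))
    sites = {}
    for i in range(cfg.n_contigs):
        contig = f"chr{i + 1}"
        pos = []
        p = float(rng.exponential(60))
        while p < cfg.contig_length - 2:
            pos.append(int(p))
            p += 2 + rng.exponential(60)
        ivs = islands_by_contig.get(contig, [])
        bg = np.array(pos, dtype=np.int64)
        if ivs:
            mask = np.ones(len(bg), dtype=bool)
            for s, e in ivs:
                mask &= ~((bg >= s) & (bg < e))
            bg = bg[mask]
            dense = []
            for s, e in ivs:
                p = s + float(rng.exponential(12))
                while p < e - 2:
                    dense.append(int(p))
                    p += 2 + rng.exponential(12)
            allpos = np.unique(np.concatenate([bg, np.array(dense, dtype=np.int64)]))
        else:
            allpos = bg
        sites[contig] = allpos
    return sites


def simulate_methylation(
    truth: TruthTable, sites: dict[str, np.ndarray], rng
) -> list[meth.CpGRecord]:
    """One tissue's CGmap records: hypo islands over true TSS only."""
    cfg = truth.config
    a_i, b_i = cfg.island_meth
    a_b, b_b = cfg.background_meth
    islands_by_contig: dict[str, np.ndarray] = {}
    for contig, s, e in truth.hmr_islands:
        islands_by_contig.setdefault(contig, []).append((s, e))
    records = []
    for contig in sorted(sites):
        pos = sites[contig]
        in_island = np.zeros(len(pos), dtype=bool)
        for s, e in islands_by_contig.get(contig, []):
            in_island |= (pos >= s) & (pos < e)
        p_meth = np.where(
            in_island,
            rng.beta(a_i, b_i, len(pos)),
            rng.beta(a_b, b_b, len(pos)),
        )
        for p, pm in zip(pos, p_meth):
            for strand, shift in (("+", 0), ("-", 1)):
                n = int(rng.poisson(cfg.coverage_mean / 2))
                if n == 0:
                    continue
                m = int(rng.binomial(n, pm))
                records.append(
                    meth.CpGRecord(contig, strand, int(p) + shift, "CG", m, n)
                )
    return records


def simulate_hmm_chain(
    alpha: tuple[float, float],
    beta: tuple[float, float],
    transmat: np.ndarray,
    n_sites: int,
    coverage_mean: float,
    rng,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample (states, methylated, coverage) from a known two-state model."""
    states = np.empty(n_sites, dtype=np.int64)
    states[0] = rng.integers(2)
    for t in range(1, n_sites):
        states[t] = rng.choice(2, p=transmat[states[t - 1]])
    n = rng.poisson(coverage_mean, n_sites)
    p = rng.beta(np.array(alpha)[states], np.array(beta)[states])
    m = rng.binomial(n, p)
    return states, m, n


def generate(cfg: GeneratorConfig, outdir: str | os.PathLike) -> TruthTable:
    """Write the full synthetic panel to *outdir* and return its truth.

    Emits contigs.tsv, annotation.gff3, per-tissue CAGE bedGraph pairs,
    per-tissue CGmap methylation tables (first ``n_wgbs_tissues``
    tissues), kallisto-style TPM tables and truth.json.
    """
    outdir = Path(outdir)
    for sub in ("cage", "wgbs", "mrna"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    contigs, models = _build_gene_models(cfg)
    truth = _plan_truth(cfg, models, rng)
    contigs.to_tsv(outdir / "contigs.tsv")
    gn.write_gff3(models, outdir / "annotation.gff3")
    truth.to_json(outdir / "truth.json")

    profiles = simulate_profiles(truth, rng)
    for prof in profiles:
        tg.write_bedgraph_pair(prof, outdir / "cage" / prof.sample_id)

    sites = _cpg_sites(cfg, truth, rng)
    for name in cfg.tissue_names()[: cfg.n_wgbs_tissues]:
        records = simulate_methylation(truth, sites, rng)
        meth.write_cgmap(records, outdir / "wgbs" / f"{name}.cgmap.tsv")

    # mRNA TPM tracks the host gene's CAGE expression with noise
    gene_tss = {t.gene_id: t for t in truth.tss if t.category == "gene"}
    tx_of_gene = {m.gene_id: m.tx_id for m in models}
    for tissue_idx, name in enumerate(cfg.tissue_names()[: cfg.n_mrna_tissues]):
        prof = profiles[tissue_idx]
        raw = {}
        for gid, t in gene_tss.items():
            d = prof.get(t.contig, t.strand)
            count = sum(
                d.get(p, 0)
                for p in range(t.position - cfg.jitter, t.position + cfg.jitter + 1)
            )
            raw[tx_of_gene[gid]] = count * float(rng.lognormal(0, 0.5))
        total = sum(raw.values()) or 1.0
        with open(outdir / "mrna" / f"{name}.abundance.tsv", "w") as fh:
            fh.write("target_id\tlength\teff_length\test_counts\ttpm\n")
            for tx in sorted(raw):
                tpm = raw[tx] / total * 1e6
                fh.write(f"{tx}\t1000\t800\t{raw[tx]:.2f}\t{tpm:.4f}\n")
    return truth


# ------------------------------------------------------------------ scoring


@dataclass
class RecoveryReport:
    n_truth: int
    n_called: int
    n_matched: int
    recall: float
    precision: float
    mean_offset: float = float("nan")
    mean_jaccard: float = float("nan")


def match_points(
    truth_points: list[int], called_points: list[int], tolerance: int
) -> list[tuple[int, int]]:
    """Greedy nearest-neighbour 1-1 matching within a distance tolerance."""
    pairs = []
    for i, tp in enumerate(truth_points):
        for j, cp in enumerate(called_points):
            d = abs(tp - cp)
            if d <= tolerance:
                pairs.append((d, i, j))
    pairs.sort()
    used_t, used_c, matches = set(), set(), []
    for d, i, j in pairs:
        if i in used_t or j in used_c:
            continue
        used_t.add(i)
        used_c.add(j)
        matches.append((i, j))
    return matches


def score_point_recovery(
    truth: list[tuple[str, str, int]] | list[tuple[str, int]],
    called: list[tuple[str, str, int]] | list[tuple[str, int]],
    tolerance: int,
) -> RecoveryReport:
    """Precision/recall of called point loci vs planted truth.

    Items are (contig, strand, position) or (contig, position); matching
    is greedy nearest within tolerance, per (contig[, strand]) group.
    """
    def group(items):
        g: dict[tuple, list[int]] = {}
        for it in items:
            g.setdefault(tuple(it[:-1]), []).append(it[-1])
        return g

    gt, gc = group(truth), group(called)
    n_matched = 0
    offsets = []
    for key, tps in gt.items():
        cps = gc.get(key, [])
        matches = match_points(tps, cps, tolerance)
        n_matched += len(matches)
        offsets.extend(abs(tps[i] - cps[j]) for i, j in matches)
    return RecoveryReport(
        n_truth=len(truth),
        n_called=len(called),
        n_matched=n_matched,
        recall=n_matched / len(truth) if truth else float("nan"),
        precision=n_matched / len(called) if called else float("nan"),
        mean_offset=float(np.mean(offsets)) if offsets else float("nan"),
    )


def score_interval_recovery(
    truth: list[tuple[str, int, int]],
    called: list[tuple[str, int, int]],
    min_jaccard: float = 0.0,
) -> RecoveryReport:
    """Match intervals by best Jaccard overlap (1-1, greedy by Jaccard)."""
    cand = []
    for i, (tc, ts, te) in enumerate(truth):
        for j, (cc, cs, ce) in enumerate(called):
            if cc != tc:
                continue
            inter = min(te, ce) - max(ts, cs)
            if inter <= 0:
                continue
            union = max(te, ce) - min(ts, cs)
            jac = inter / union
            if jac > min_jaccard:
                cand.append((jac, i, j))
    cand.sort(reverse=True)
    used_t, used_c, jacs = set(), set(), []
    for jac, i, j in cand:
        if i in used_t or j in used_c:
            continue
        used_t.add(i)
        used_c.add(j)
        jacs.append(jac)
    return RecoveryReport(
        n_truth=len(truth),
        n_called=len(called),
        n_matched=len(jacs),
        recall=len(jacs) / len(truth) if truth else float("nan"),
        precision=len(jacs) / len(called) if called else float("nan"),
        mean_jaccard=float(np.mean(jacs)) if jacs else 0.0,
    )


def family_recovery_score(
    assigned: dict[str, int], truth_families: dict[str, int]
) -> float:
    """Adjusted Rand index between recovered and planted tissue families."""
    labels = sorted(truth_families)
    return float(
        adjusted_rand_score(
            [truth_families[l] for l in labels], [assigned[l] for l in labels]
        )
    )


def checksum_tree(root: str | os.PathLike) -> dict[str, str]:
    """md5 of every file under *root* (determinism checks)."""
    root = Path(root)
    out = {}
    for path in sorted(root.rglob("*")):
        if path.is_file():
            out[str(path.relative_to(root))] = hashlib.md5(
                path.read_bytes()
            ).hexdigest()
    return out
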