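"""Gene-model parsing and genomic-region classification."""

import numpy as np
import pytest

from cageatlas import genome as gn

# ------------------------------------------------------- transcript models


def test_tss_is_five_prime_most_base_per_strand():
    plus = gn.TranscriptModel(
        "t", "g", "chr1", "+", exons=[(1000, 1200), (1500, 1800)]
    )
    minus = gn.TranscriptModel(
        "t", "g", "chr1", "-", exons=[(1000, 1200), (1500, 1800)]
    )
    assert plus.tss_position == 1000
    assert minus.tss_position == 1799


def test_utrs_derived_from_exons_minus_cds():
    m = gn.TranscriptModel(
        "t", "g", "chr1", "+",
        exons=[(100, 300), (500, 900)],
        cds=[(200, 300), (500, 700)],
    )
    assert m.five_utr == [(100, 200)]
    assert m.three_utr == [(700, 900)]
    minus = gn.TranscriptModel(
        "t", "g", "chr1", "-",
        exons=[(100, 300), (500, 900)],
        cds=[(200, 300), (500, 700)],
    )
    assert minus.five_utr == [(700, 900)]
    assert minus.three_utr == [(100, 200)]


def test_overlapping_exons_rejected():
    with pytest.raises(gn.AnnotationError):
        gn.TranscriptModel("t", "g", "chr1", "+", exons=[(100, 300), (200, 400)])


def test_gff3_round_trip(toy_models, tmp_path):
    contigs, models = toy_models
    path = tmp_path / "toy.gff3"
    gn.write_gff3(models, path)
    loaded = gn.load_annotation(path, contigs)
    assert len(loaded) == len(models)
    by_id = {m.tx_id: m for m in loaded}
    for m in models:
        got = by_id[m.tx_id]
        assert got.exons == m.exons
        assert got.tss_position == m.tss_position
        assert got.gene_id == m.gene_id


def test_generator_gff3_tss_match_planted(default_panel):
    truth, outdir = default_panel
    contigs = gn.ContigSet.from_tsv(outdir / "contigs.tsv")
    models = gn.load_annotation(outdir / "annotation.gff3", contigs)
    planted = {
        t.gene_id: t.position for t in truth.tss if t.category == "gene"
    }
    assert len(models) == len(planted)
    for m in models:
        assert m.tss_position == planted[m.gene_id]


def test_unknown_contig_is_an_error(toy_models, tmp_path):
    _, models = toy_models
    path = tmp_path / "toy.gff3"
    gn.write_gff3(models, path)
    wrong = gn.ContigSet.from_pairs([("chrX", 10_000)])
    with pytest.raises(gn.AnnotationError, match="unknown contig"):
        gn.load_annotation(path, wrong)


# ---------------------------------------------------------------- regions


def test_region_precedence_basics(toy_models):
    contigs, models = toy_models
    index = gn.build_region_index(models, contigs)
    tss = models[0].tss_position  # 2000, + strand
    assert index.classify_position("chr1", tss + 50, "+")[0] == "promoter"
    assert index.classify_position("chr1", tss - 500, "+")[0] == "proximal"
    assert index.classify_position("chr1", 6000, "+")[0] == "intergenic"
    # inside the gene body, outside promoter reach
    assert index.classify_position("chr1", 3200, "+")[0] == "exon"
    assert index.classify_position("chr1", 2700, "+")[0] == "intron"
    assert index.classify_position("chr1", 3500, "+")[0] == "threeUTR"


def test_interval_classified_by_peak(toy_models):
    contigs, models = toy_models
    index = gn.build_region_index(models, contigs)
    # spans promoter and 5'UTR; peak in the 5'UTR wins
    cls, genes, _ = index.classify_interval("chr1", 2050, 2150, "+", peak=2140)
    assert cls == "fiveUTR"
    assert genes == ["geneA"]
    with pytest.raises(gn.AnnotationError):
        index.classify_interval("chr1", 19_990, 20_050, "+")


def _brute_force_class(models, params, pos, strand):
    """Independent per-bp classifier straight from the region definitions."""
    best = None
    order = [
        "promoter", "proximal", "fiveUTR", "threeUTR", "exon", "intron",
    ]
    for m in models:
        cands = []
        tss = m.tss_position
        if abs(pos - tss) <= params.promoter_halfwidth and strand == m.strand:
            cands.append("promoter")
        upstream = tss - pos if m.strand == "+" else pos - tss
        if 0 < upstream <= params.proximal_length and strand == m.strand:
            cands.append("proximal")
        for s, e in m.five_utr:
            if s <= pos < e:
                cands.append("fiveUTR")
        for s, e in m.three_utr:
            if s <= pos < e:
                cands.append("threeUTR")
        if any(s <= pos < e for s, e in m.exons):
            cands.append("exon")
        if m.start <= pos < m.end:
            cands.append("intron")
        for c in cands:
            if best is None or order.index(c) < order.index(best):
                best = c
    return best or "intergenic"


def _random_annotation(rng, contig_len=6000):
    contigs = gn.ContigSet.from_pairs([("c", contig_len)])
    models = []
    for i in range(rng.integers(1, 4)):
        strand = "+" if rng.random() < 0.5 else "-"
        a = int(rng.integers(300, contig_len - 1500))
        e1 = (a, a + int(rng.integers(100, 300)))
        gap = int(rng.integers(50, 400))
        e2 = (e1[1] + gap, e1[1] + gap + int(rng.integers(100, 400)))
        cds = [(e1[0] + 50, e1[1]), (e2[0], e2[1] - 50)]
        models.append(
            gn.TranscriptModel(f"t{i}", f"g{i}", "c", strand, [e1, e2], cds)
        )
    return contigs, models


def test_classification_agrees_with_per_bp_oracle_and_is_exhaustive():
    rng = np.random.default_rng(5)
    params = gn.RegionIndexParams()
    for _ in range(30):
        contigs, models = _random_annotation(rng)
        index = gn.build_region_index(models, contigs, params)
        length = contigs.sizes["c"]
        totals = 0
        for pos in rng.integers(0, length, 200):
            got = index.classify_position("c", int(pos), "+")[0]
            want = _brute_force_class(models, params, int(pos), "+")
            assert got == want, f"pos {pos}: {got} != {want}"
        # exhaustiveness: every bp classified exactly once
        classes = [
            index.classify_position("c", p, "+")[0] for p in range(0, length, 7)
        ]
        assert all(c in gn.REGION_CLASSES for c in classes)


def test_strand_reflection_symmetry():
    """Mirroring the annotation mirrors the classification."""
    rng = np.random.default_rng(9)
    params = gn.RegionIndexParams()
    contigs, models = _random_annotation(rng)
    L = contigs.sizes["c"]
    flipped = [
        gn.TranscriptModel(
            m.tx_id, m.gene_id, "c",
            "-" if m.strand == "+" else "+",
            [(L - e, L - s) for s, e in reversed(m.exons)],
            [(L - e, L - s) for s, e in reversed(m.cds)] if m.cds else None,
        )
        for m in models
    ]
    fwd = gn.build_region_index(models, contigs, params)
    rev = gn.build_region_index(flipped, contigs, params)
    for pos in rng.integers(0, L, 300):
        a = fwd.classify_position("c", int(pos), "+")[0]
        b = rev.classify_position("c", L - 1 - int(pos), "-")[0]
        assert a == b
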