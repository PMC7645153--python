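"""Gene models and genomic-region classification.

Parses transcript models from GFF3, derives promoter / proximal / UTR
coordinates and classifies genomic positions (or CAGE cluster intervals)
into a fixed region hierarchy:

    promoter > proximal > fiveUTR > threeUTR > exon > intron > intergenic

Promoters are ±``promoter_halfwidth`` bp (default 100) around the
transcript 5' end; proximal is ``proximal_length`` bp (default 1,000)
immediately upstream of the promoter anchor; anything further than the
intergenic margin from every gene model is intergenic.

All coordinates are internally 0-based half-open.  GFF3 input (1-based
inclusive) is converted on load; BED output is written natively.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import gffutils
from intervaltree import IntervalTree

REGION_CLASSES = (
    "promoter",
    "proximal",
    "fiveUTR",
    "threeUTR",
    "exon",
    "intron",
    "intergenic",
)

_RANK = {c: i for i, c in enumerate(REGION_CLASSES)}


class AnnotationError(ValueError):
    """Raised for malformed annotation input."""


@dataclass(frozen=True)
class ContigSet:
    """Named contigs with lengths (bp)."""

    entries: tuple[tuple[str, int], ...]

    def __post_init__(self):
        names = [n for n, _ in self.entries]
        if len(set(names)) != len(names):
            raise AnnotationError("contig names must be unique")
        if any(l <= 0 for _, l in self.entries):
            raise AnnotationError("contig lengths must be positive")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, int]]) -> "ContigSet":
        return cls(tuple((str(n), int(l)) for n, l in pairs))

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "ContigSet":
        """Read a two-column contig table (name, length) or .fai dialect."""
        pairs = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.split("\t")
                pairs.append((parts[0], int(parts[1])))
        return cls.from_pairs(pairs)

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for name, length in self.entries:
                fh.write(f"{name}\t{length}\n")

    @property
    def sizes(self) -> dict[str, int]:
        return dict(self.entries)

    def __contains__(self, name: str) -> bool:
        return name in self.sizes

    def __len__(self) -> int:
        return len(self.entries)


def _derive_utrs(
    exons: list[tuple[int, int]], cds: list[tuple[int, int]], strand: str
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Exonic sequence outside the CDS span, split 5' / 3' by strand."""
    if not cds:
        return [], []
    cds_start = min(s for s, _ in cds)
    cds_end = max(e for _, e in cds)
    left, right = [], []
    for s, e in exons:
        if s < cds_start:
            left.append((s, min(e, cds_start)))
        if e > cds_end:
            right.append((max(s, cds_end), e))
    if strand == "+":
        return left, right
    return right, left


@dataclass
class TranscriptModel:
    """One transcript: exons, optional CDS, derived UTRs and TSS."""

    tx_id: str
    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    cds: Optional[list[tuple[int, int]]] = None
    five_utr: list[tuple[int, int]] = field(default_factory=list)
    three_utr: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in "+-":
            raise AnnotationError(f"bad strand {self.strand!r} for {self.tx_id}")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise AnnotationError(f"overlapping exons in {self.tx_id}")
        if self.cds:
            self.cds = sorted((int(s), int(e)) for s, e in self.cds)
        if not self.five_utr and not self.three_utr:
            self.five_utr, self.three_utr = _derive_utrs(
                self.exons, self.cds or [], self.strand
            )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss_position(self) -> int:
        """5'-most transcribed base on the transcript strand."""
        return self.start if self.strand == "+" else self.end - 1


def load_annotation(
    gff3_path: str | os.PathLike, contigs: ContigSet
) -> list[TranscriptModel]:
    """Parse a GFF3 file into transcript models.

    Accepts gene / mRNA(or transcript) / exon features, CDS optional.
    Coordinates are converted from GFF3 1-based inclusive to 0-based
    half-open.  A transcript on a contig absent from *contigs* is an
    error.
    """
    try:
        db = gffutils.create_db(
            str(gff3_path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # pragma: no cover - passthrough detail
        raise AnnotationError(f"malformed GFF3 {gff3_path}: {exc}") from exc

    models = []
    for kind in ("mRNA", "transcript"):
        for tx in db.features_of_type(kind):
            if tx.seqid not in contigs:
                raise AnnotationError(
                    f"transcript {tx.id} references unknown contig {tx.seqid}"
                )
            exons = [(f.start - 1, f.end) for f in db.children(tx, featuretype="exon")]
            cds = [(f.start - 1, f.end) for f in db.children(tx, featuretype="CDS")]
            if not exons:
                exons = [(tx.start - 1, tx.end)]
            gene_id = tx.attributes.get("Parent", [tx.id])[0]
            models.append(
                TranscriptModel(
                    tx_id=tx.id,
                    gene_id=gene_id,
                    contig=tx.seqid,
                    strand=tx.strand,
                    exons=exons,
                    cds=cds or None,
                )
            )
    if not models:
        raise AnnotationError(f"no transcript features found in {gff3_path}")
    return models


@dataclass
class RegionIndexParams:
    promoter_halfwidth: int = 100
    proximal_length: int = 1000
    intergenic_margin: int = 1000
    stranded: bool = True
    precedence: Sequence[str] = REGION_CLASSES


class RegionIndex:
    """Position -> region-class lookup over a set of transcript models.

    Every position maps to exactly one class under the precedence rule;
    promoter/proximal matching is strand-aware by default (feature strand
    must equal the query strand), gene-body classes are strand-agnostic.
    """

    def __init__(
        self,
        models: list[TranscriptModel],
        contigs: ContigSet,
        params: RegionIndexParams | None = None,
    ):
        if not models:
            raise AnnotationError("need at least one transcript model")
        self.params = params or RegionIndexParams()
        self.contigs = contigs
        self.models = list(models)
        self._trees: dict[str, IntervalTree] = {}
        self._promoter_trees: dict[str, IntervalTree] = {}
        p = self.params
        sizes = contigs.sizes
        for m in models:
            size = sizes[m.contig]
            tss = m.tss_position
            prom = (max(0, tss - p.promoter_halfwidth),
                    min(size, tss + p.promoter_halfwidth + 1))
            if m.strand == "+":
                prox = (max(0, tss - p.proximal_length), tss)
            else:
                prox = (tss + 1, min(size, tss + 1 + p.proximal_length))
            self._add(m.contig, prom, "promoter", m)
            self._add_promoter(m.contig, prom, m)
            if prox[0] < prox[1]:
                self._add(m.contig, prox, "proximal", m)
            for iv in m.five_utr:
                self._add(m.contig, iv, "fiveUTR", m)
            for iv in m.three_utr:
                self._add(m.contig, iv, "threeUTR", m)
            for iv in m.exons:
                self._add(m.contig, iv, "exon", m)
            self._add(m.contig, (m.start, m.end), "intron", m)

        self._rank = {c: i for i, c in enumerate(self.params.precedence)}

    def _add(self, contig, iv, cls, model):
        s, e = iv
        if e <= s:
            return
        self._trees.setdefault(contig, IntervalTree()).addi(
            s, e, (cls, model.gene_id, model.tx_id, model.strand)
        )

    def _add_promoter(self, contig, iv, model):
        s, e = iv
        self._promoter_trees.setdefault(contig, IntervalTree()).addi(
            s, e, (model.gene_id, model.tx_id, model.strand)
        )

    def classify_position(
        self, contig: str, position: int, strand: Optional[str] = None
    ) -> tuple[str, list[str], list[str]]:
        """Return (region class, gene ids, tx ids) for one position."""
        tree = self._trees.get(contig)
        best = None
        if tree is not None:
            for hit in tree.at(position):
                cls, gene, tx, fstrand = hit.data
                if (
                    self.params.stranded
                    and strand is not None
                    and cls in ("promoter", "proximal")
                    and fstrand != strand
                ):
                    continue
                rank = self._rank[cls]
                if best is None or rank < best[0]:
                    best = (rank, cls, {gene}, {tx})
                elif rank == best[0]:
                    best[2].add(gene)
                    best[3].add(tx)
        if best is None:
            return "intergenic", [], []
        return best[1], sorted(best[2]), sorted(best[3])

    def promoter_hits(
        self, contig: str, start: int, end: int, strand: Optional[str] = None
    ) -> tuple[list[str], list[str]]:
        """Gene/tx ids whose promoter window overlaps [start, end)."""
        tree = self._promoter_trees.get(contig)
        genes, txs = set(), set()
        if tree is not None:
            for hit in tree.overlap(start, end):
                gene, tx, fstrand = hit.data
                if self.params.stranded and strand is not None and fstrand != strand:
                    continue
                genes.add(gene)
                txs.add(tx)
        return sorted(genes), sorted(txs)

    def classify_interval(
        self,
        contig: str,
        start: int,
        end: int,
        strand: Optional[str] = None,
        peak: Optional[int] = None,
    ) -> tuple[str, list[str], list[str]]:
        """Classify an interval by its peak position.

        Returns the class at *peak* (default: interval start) plus all
        gene/tx ids whose promoter window overlaps the interval.
        """
        size = self.contigs.sizes.get(contig)
        if size is None or start < 0 or end > size or end <= start:
            raise AnnotationError(
                f"interval {contig}:{start}-{end} out of contig bounds"
            )
        pos = peak if peak is not None else start
        if not (start <= pos < end):
            raise AnnotationError("peak position outside interval")
        cls, _, _ = self.classify_position(contig, pos, strand)
        genes, txs = self.promoter_hits(contig, start, end, strand)
        return cls, genes, txs


def build_region_index(
    models: list[TranscriptModel],
    contigs: ContigSet,
    params: RegionIndexParams | None = None,
) -> RegionIndex:
    """Build the promoter/proximal/UTR/exon/intron/intergenic lookup."""
    return RegionIndex(models, contigs, params)


def write_promoter_bed(
    models: list[TranscriptModel],
    contigs: ContigSet,
    path: str | os.PathLike,
    halfwidth: int = 100,
) -> None:
    """Write promoter windows as BED6 (one row per transcript)."""
    sizes = contigs.sizes
    with open(path, "w") as fh:
        for m in sorted(models, key=lambda m: (m.contig, m.tss_position)):
            s = max(0, m.tss_position - halfwidth)
            e = min(sizes[m.contig], m.tss_position + halfwidth + 1)
            fh.write(f"{m.contig}\t{s}\t{e}\t{m.tx_id}\t0\t{m.strand}\n")


def write_gff3(
    models: list[TranscriptModel], path: str | os.PathLike
) -> None:
    """Write transcript models back out as minimal GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        by_gene: dict[str, list[TranscriptModel]] = {}
        for m in models:
            by_gene.setdefault(m.gene_id, []).append(m)
        for gene_id, txs in by_gene.items():
            contig = txs[0].contig
            strand = txs[0].strand
            g_start = min(t.start for t in txs)
            g_end = max(t.end for t in txs)
            fh.write(
                f"{contig}\tcageatlas\tgene\t{g_start + 1}\t{g_end}\t.\t{strand}\t.\t"
                f"ID={gene_id}\n"
            )
            for t in txs:
                fh.write(
                    f"{contig}\tcageatlas\tmRNA\t{t.start + 1}\t{t.end}\t.\t"
                    f"{t.strand}\t.\tID={t.tx_id};Parent={gene_id}\n"
                )
                for i, (s, e) in enumerate(t.exons):
                    fh.write(
                        f"{contig}\tcageatlas\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t"
                        f"ID={t.tx_id}.exon{i};Parent={t.tx_id}\n"
                    )
                for i, (s, e) in enumerate(t.cds or []):
                    fh.write(
                        f"{contig}\tcageatlas\tCDS\t{s + 1}\t{e}\t.\t{t.strand}\t0\t"
                        f"ID={t.tx_id}.cds{i};Parent={t.tx_id}\n"
                    )
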