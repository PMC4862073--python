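"""Read/write genome assemblies and annotations; bind Hox labels to genes.

FASTA parsing is delegated to Bio.SeqIO and GFF3 parsing to gffutils (an
in-memory feature database); this module owns the conversion of GFF3
1-based inclusive coordinates to the package's 0-based half-open
convention, UTR inference from exon-minus-CDS arithmetic, and the label
binding that produces the :class:`~hoxatlas.model.HoxClusterMap` every
other module consumes.
"""

from __future__ import annotations

import csv
import os
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import GeneLookupError, LinkageError, ParseError, VocabularyError
from .model import (
    HOX_CLASSES,
    GeneModel,
    GenomeAnnotation,
    HoxClusterMap,
    HoxEntry,
    Interval,
    Scaffold,
    TranscriptModel,
)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_label_table",
    "write_label_table",
    "bind_hox_labels",
    "write_bed",
]


def read_fasta(path: str) -> list[Scaffold]:
    """Read a (possibly wrapped) multi-record FASTA into scaffolds."""
    if not os.path.exists(path):
        raise ParseError(f"FASTA file not found: {path}")
    with open(path) as fh:
        first = fh.readline()
        if first and not first.startswith(">"):
            raise ParseError(f"{path}: line 1: expected FASTA header starting with '>'")
    scaffolds: list[Scaffold] = []
    for rec in SeqIO.parse(path, "fasta"):
        seq = str(rec.seq).upper()
        if not rec.id:
            raise ParseError(f"{path}: record with empty header")
        if not seq:
            raise ParseError(f"{path}: record {rec.id!r} has an empty sequence")
        scaffolds.append(Scaffold(id=rec.id, length=len(seq), sequence=seq))
    return scaffolds


def write_fasta(scaffolds: Iterable[Scaffold], path: str, width: int = 70) -> None:
    records = []
    for s in scaffolds:
        if s.sequence is None:
            raise ParseError(f"scaffold {s.id!r} has no sequence to write")
        records.append(SeqRecord(Seq(s.sequence), id=s.id, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def _subtract(intervals: list[Interval], remove: list[Interval]) -> list[Interval]:
    """Set-subtract sorted interval lists (0-based half-open)."""
    out: list[Interval] = []
    for s, e in intervals:
        cur = [(s, e)]
        for rs, re_ in remove:
            nxt: list[Interval] = []
            for cs, ce in cur:
                if re_ <= cs or rs >= ce:
                    nxt.append((cs, ce))
                    continue
                if cs < rs:
                    nxt.append((cs, rs))
                if re_ < ce:
                    nxt.append((re_, ce))
            cur = nxt
        out.extend(cur)
    return sorted(out)


def _infer_utrs(
    exons: list[Interval], cds: list[Interval], strand: str
) -> tuple[list[Interval], list[Interval]]:
    """Exon minus CDS, split into 5'/3' by position relative to the CDS span."""
    if not cds:
        return [], []
    non_cds = _subtract(exons, cds)
    cds_start = min(s for s, _ in cds)
    cds_end = max(e for _, e in cds)
    left = [iv for iv in non_cds if iv[1] <= cds_start]
    right = [iv for iv in non_cds if iv[0] >= cds_end]
    if strand == "+":
        return left, right
    return right, left


def read_gff3(path: str, scaffolds: Sequence[Scaffold]) -> GenomeAnnotation:
    """Parse a GFF3 file against known scaffolds.

    Recognises gene/mRNA/exon/CDS/five_prime_UTR/three_prime_UTR features;
    UTRs are inferred from exon-minus-CDS arithmetic when not annotated.
    Coordinates come in 1-based inclusive and are stored 0-based half-open.
    """
    if not os.path.exists(path):
        raise ParseError(f"GFF3 file not found: {path}")
    try:
        db = gffutils.create_db(
            path,
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise ParseError(f"{path}: failed to parse GFF3: {exc}") from exc

    ann = GenomeAnnotation(scaffolds={s.id: s for s in scaffolds})

    for mrna in db.features_of_type("mRNA"):
        if not list(db.parents(mrna, featuretype="gene")):
            raise LinkageError(f"mRNA {mrna.id!r} has no gene parent")

    for gene in db.features_of_type("gene"):
        scaf = ann.scaffolds.get(gene.seqid)
        if scaf is None:
            raise ParseError(f"gene {gene.id!r} on unknown scaffold {gene.seqid!r}")
        if gene.end > scaf.length or gene.start < 1:
            from .errors import BoundsError

            raise BoundsError(
                f"gene {gene.id!r} [{gene.start}..{gene.end}] outside scaffold "
                f"{scaf.id!r} (length {scaf.length})"
            )
        biotype = gene.attributes.get("biotype", ["protein_coding"])[0]
        transcripts: list[TranscriptModel] = []
        for mrna in db.children(gene, featuretype="mRNA"):
            exons = sorted(
                (f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")
            )
            cds = sorted(
                (f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS")
            )
            utr5 = sorted(
                (f.start - 1, f.end)
                for f in db.children(mrna, featuretype="five_prime_UTR")
            )
            utr3 = sorted(
                (f.start - 1, f.end)
                for f in db.children(mrna, featuretype="three_prime_UTR")
            )
            if not exons:
                exons = [(mrna.start - 1, mrna.end)]
            if not utr5 and not utr3:
                utr5, utr3 = _infer_utrs(exons, cds, gene.strand)
            transcripts.append(
                TranscriptModel(
                    transcript_id=mrna.id, exons=exons, cds=cds, utr5=utr5, utr3=utr3
                )
            )
        ann.add_gene(
            GeneModel(
                gene_id=gene.id,
                scaffold_id=gene.seqid,
                start=gene.start - 1,
                end=gene.end,
                strand=gene.strand,
                transcripts=transcripts,
                biotype=biotype,
            )
        )
    ann.validate()
    return ann


def write_gff3(annotation: GenomeAnnotation, path: str) -> None:
    """Emit gene/mRNA/exon/CDS/UTR features, converting back to 1-based."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for scaf in annotation.scaffolds.values():
            fh.write(f"##sequence-region {scaf.id} 1 {scaf.length}\n")

        def row(seqid, ftype, s, e, strand, attrs):
            fh.write(
                f"{seqid}\thoxatlas\t{ftype}\t{s + 1}\t{e}\t.\t{strand}\t.\t{attrs}\n"
            )

        for scaf in annotation.scaffolds.values():
            for g in annotation.genes_on(scaf.id):
                row(
                    scaf.id, "gene", g.start, g.end, g.strand,
                    f"ID={g.gene_id};biotype={g.biotype}",
                )
                for t in g.transcripts:
                    ts, te = t.span
                    row(
                        scaf.id, "mRNA", ts, te, g.strand,
                        f"ID={t.transcript_id};Parent={g.gene_id}",
                    )
                    for s, e in t.exons:
                        row(scaf.id, "exon", s, e, g.strand, f"Parent={t.transcript_id}")
                    for s, e in t.cds:
                        row(scaf.id, "CDS", s, e, g.strand, f"Parent={t.transcript_id}")
                    for s, e in t.utr5:
                        row(
                            scaf.id, "five_prime_UTR", s, e, g.strand,
                            f"Parent={t.transcript_id}",
                        )
                    for s, e in t.utr3:
                        row(
                            scaf.id, "three_prime_UTR", s, e, g.strand,
                            f"Parent={t.transcript_id}",
                        )


def read_label_table(path: str) -> list[tuple[str, str, str]]:
    """Read a 3-column TSV: gene_id, hox_class, species."""
    rows: list[tuple[str, str, str]] = []
    with open(path) as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 3:
                raise ParseError(f"{path}: line {lineno}: expected 3 columns, got {len(row)}")
            rows.append((row[0], row[1], row[2]))
    return rows


def write_label_table(rows: Iterable[tuple[str, str, str]], path: str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        for r in rows:
            w.writerow(r)


def bind_hox_labels(
    annotation: GenomeAnnotation,
    label_table: Iterable[tuple[str, str, str]],
    scaffold_order: Sequence[str] | None = None,
) -> HoxClusterMap:
    """Attach Hox class labels to gene models and order them along the cluster.

    Ordering is by position in ``scaffold_order`` then start coordinate;
    duplicate classes get paralog_index 1, 2, ... by coordinate.  The result
    is independent of label-table row order.
    """
    rows = sorted(set(label_table))
    if not rows:
        raise GeneLookupError("empty label table")
    species = rows[0][2]
    labelled: list[tuple[str, str]] = []
    for gene_id, hox_class, _sp in rows:
        if hox_class not in HOX_CLASSES:
            raise VocabularyError(
                f"unknown Hox class {hox_class!r}; expected one of {HOX_CLASSES}"
            )
        if gene_id not in annotation.genes:
            raise GeneLookupError(f"label table names unknown gene {gene_id!r}")
        labelled.append((gene_id, hox_class))

    seen_scaffolds: list[str] = []
    for gene_id, _ in labelled:
        sid = annotation.genes[gene_id].scaffold_id
        if sid not in seen_scaffolds:
            seen_scaffolds.append(sid)
    if scaffold_order is None:
        scaffold_order = sorted(seen_scaffolds)
    else:
        scaffold_order = list(scaffold_order)
        missing = [s for s in seen_scaffolds if s not in scaffold_order]
        if missing:
            raise GeneLookupError(
                f"labelled genes on scaffolds absent from scaffold_order: {missing}"
            )

    def sort_key(item: tuple[str, str]):
        g = annotation.genes[item[0]]
        return (scaffold_order.index(g.scaffold_id), g.start, g.gene_id)

    labelled.sort(key=sort_key)
    counts: dict[str, int] = {}
    entries: list[HoxEntry] = []
    for gene_id, hox_class in labelled:
        counts[hox_class] = counts.get(hox_class, 0) + 1
        entries.append(
            HoxEntry(hox_class=hox_class, paralog_index=counts[hox_class], gene_id=gene_id)
        )
    return HoxClusterMap(species=species, entries=entries, scaffold_order=scaffold_order)


def write_bed(
    loci: Iterable[tuple[str, int, int, str, float, str]], path: str
) -> None:
    """Write BED6 rows: (chrom, start, end, name, score, strand)."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in loci:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score:g}\t{strand}\n")
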