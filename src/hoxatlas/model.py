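"""Core data model: scaffolds, gene models, and Hox cluster maps.

All coordinates are stored 0-based half-open; GFF3 I/O converts at the
boundary.  A gene's *transcription unit* is the interval from the first to
the last exon over all of its transcripts (UTRs included) — the span
measure used throughout the cluster metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import BoundsError, VocabularyError

#: The canonical ten arthropod Hox classes, in ancestral cluster order
#: (3' to 5': lab at the 3' end of the cluster, Abd-B at the 5' end).
HOX_CLASSES: tuple[str, ...] = (
    "lab", "pb", "Hox3", "Dfd", "Scr", "ftz", "Antp", "Ubx", "abd-A", "Abd-B",
)

Interval = tuple[int, int]


@dataclass
class Scaffold:
    """An assembled sequence unit; sequence is optional for metrics-only runs."""

    id: str
    length: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise BoundsError(f"scaffold {self.id!r}: length must be >= 1, got {self.length}")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise BoundsError(
                f"scaffold {self.id!r}: sequence length {len(self.sequence)} != length {self.length}"
            )


@dataclass
class TranscriptModel:
    transcript_id: str
    exons: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)

    @property
    def span(self) -> Interval:
        return (min(s for s, _ in self.exons), max(e for _, e in self.exons))

    def exon_bp(self) -> int:
        return sum(e - s for s, e in self.exons)

    def cds_bp(self) -> int:
        return sum(e - s for s, e in self.cds)


@dataclass
class GeneModel:
    gene_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str
    transcripts: list[TranscriptModel] = field(default_factory=list)
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise BoundsError(
                f"gene {self.gene_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise BoundsError(f"gene {self.gene_id!r}: strand must be '+' or '-'")

    @property
    def transcription_unit(self) -> Interval:
        """Union span over all transcripts; falls back to gene bounds."""
        if not self.transcripts:
            return (self.start, self.end)
        starts, ends = zip(*(t.span for t in self.transcripts))
        return (min(starts), max(ends))

    @property
    def length(self) -> int:
        s, e = self.transcription_unit
        return e - s


@dataclass
class GenomeAnnotation:
    """Scaffolds plus gene models, indexed by id."""

    scaffolds: dict[str, Scaffold] = field(default_factory=dict)
    genes: dict[str, GeneModel] = field(default_factory=dict)

    def add_gene(self, gene: GeneModel) -> None:
        scaf = self.scaffolds.get(gene.scaffold_id)
        if scaf is None:
            raise BoundsError(
                f"gene {gene.gene_id!r} placed on unknown scaffold {gene.scaffold_id!r}"
            )
        if gene.end > scaf.length:
            raise BoundsError(
                f"gene {gene.gene_id!r} end {gene.end} exceeds scaffold "
                f"{scaf.id!r} length {scaf.length}"
            )
        self.genes[gene.gene_id] = gene

    def genes_on(self, scaffold_id: str, biotype: str | None = None) -> list[GeneModel]:
        out = [
            g
            for g in self.genes.values()
            if g.scaffold_id == scaffold_id and (biotype is None or g.biotype == biotype)
        ]
        out.sort(key=lambda g: (g.start, g.end, g.gene_id))
        return out

    @property
    def assembly_size(self) -> int:
        return sum(s.length for s in self.scaffolds.values())

    def validate(self) -> None:
        """Check every stored interval against its scaffold bounds."""
        for g in self.genes.values():
            scaf = self.scaffolds[g.scaffold_id]
            if not 0 <= g.start < g.end <= scaf.length:
                raise BoundsError(f"gene {g.gene_id!r} outside scaffold bounds")
            for t in g.transcripts:
                for name, ivals in (
                    ("exon", t.exons), ("CDS", t.cds), ("utr5", t.utr5), ("utr3", t.utr3)
                ):
                    for s, e in ivals:
                        if not g.start <= s < e <= g.end:
                            raise BoundsError(
                                f"{name} [{s},{e}) of {t.transcript_id!r} outside "
                                f"gene {g.gene_id!r} span [{g.start},{g.end})"
                            )


@dataclass(frozen=True)
class HoxEntry:
    hox_class: str
    paralog_index: int
    gene_id: str

    def __post_init__(self) -> None:
        if self.hox_class not in HOX_CLASSES:
            raise VocabularyError(
                f"unknown Hox class {self.hox_class!r}; expected one of {HOX_CLASSES}"
            )


@dataclass
class HoxClusterMap:
    """Ordered Hox-labelled genes for one species.

    ``scaffold_order`` is the user-supplied expected genomic arrangement of
    Hox-bearing scaffolds; entries are sorted by (scaffold_order, start).
    Cross-scaffold distances derived from it are minimum estimates.
    """

    species: str
    entries: list[HoxEntry] = field(default_factory=list)
    scaffold_order: list[str] = field(default_factory=list)

    def classes(self) -> list[str]:
        return [e.hox_class for e in self.entries]

    def gene_ids(self) -> list[str]:
        return [e.gene_id for e in self.entries]
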