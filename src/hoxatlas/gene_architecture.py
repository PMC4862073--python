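"""Per-gene architecture statistics: CDS, intron and UTR lengths.

One record per gene, computed on a representative transcript (longest
CDS; ties broken by longest transcription unit, then id), plus per-species
totals and means.  Missing UTR annotation is propagated as missing — it is
common in source genome databases and must never be imputed as zero, or
species means would be biased downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import HoxatlasError
from .model import GeneModel, TranscriptModel

__all__ = ["GeneArchitecture", "SpeciesArchitectureSummary", "gene_architecture", "species_summary"]


@dataclass
class GeneArchitecture:
    gene_id: str
    cds_bp: int | None
    intron_bp: int | None
    n_introns: int | None
    utr5_bp: int | None
    utr3_bp: int | None
    transcript_used: str | None
    missing: list[str] = field(default_factory=list)

    @property
    def utr_total_bp(self) -> int | None:
        if self.utr5_bp is None or self.utr3_bp is None:
            return None
        return self.utr5_bp + self.utr3_bp


@dataclass
class SpeciesArchitectureSummary:
    species: str
    n_genes: int
    total_cds_bp: int
    total_intron_bp: int
    total_utr_bp: int
    mean_cds_bp: float
    mean_intron_bp: float
    mean_n_introns: float
    mean_utr_bp: float | None
    missing_fields: list[tuple[str, str]]  # (gene_id, field)


def _representative(gene: GeneModel) -> TranscriptModel | None:
    with_cds = [t for t in gene.transcripts if t.cds]
    if not with_cds:
        return None
    return sorted(
        with_cds,
        key=lambda t: (-t.cds_bp(), t.span[0] - t.span[1], t.transcript_id),
    )[0]


def gene_architecture(gene: GeneModel) -> GeneArchitecture:
    """Architecture of one gene on its representative transcript.

    Introns are the gaps between consecutive exons; a gene with no
    CDS-bearing transcript is flagged missing rather than raising.
    """
    tx = _representative(gene)
    if tx is None:
        return GeneArchitecture(
            gene_id=gene.gene_id,
            cds_bp=None, intron_bp=None, n_introns=None,
            utr5_bp=None, utr3_bp=None, transcript_used=None,
            missing=["cds", "intron", "utr5", "utr3"],
        )
    exons = sorted(tx.exons)
    introns = [(a_end, b_start) for (_, a_end), (b_start, _) in zip(exons, exons[1:])]
    missing: list[str] = []
    utr5 = sum(e - s for s, e in tx.utr5) if tx.utr5 else None
    utr3 = sum(e - s for s, e in tx.utr3) if tx.utr3 else None
    if utr5 is None:
        missing.append("utr5")
    if utr3 is None:
        missing.append("utr3")
    return GeneArchitecture(
        gene_id=gene.gene_id,
        cds_bp=tx.cds_bp(),
        intron_bp=sum(e - s for s, e in introns),
        n_introns=len(introns),
        utr5_bp=utr5,
        utr3_bp=utr3,
        transcript_used=tx.transcript_id,
        missing=missing,
    )


def species_summary(
    records: list[GeneArchitecture], species: str = ""
) -> SpeciesArchitectureSummary:
    """Totals and means across genes; genes missing a field are excluded
    from that field's mean and listed in missing_fields."""
    if not records:
        raise HoxatlasError("species_summary requires at least one gene")
    with_cds = [r for r in records if r.cds_bp is not None]
    missing_fields = [
        (r.gene_id, f) for r in records for f in (r.missing or [])
    ] + [(r.gene_id, "cds") for r in records if r.cds_bp is None]
    with_utr = [r for r in records if r.utr_total_bp is not None]
    total_cds = sum(r.cds_bp for r in with_cds)
    total_intron = sum(r.intron_bp for r in with_cds)
    total_utr = sum(r.utr_total_bp for r in with_utr)
    n = len(with_cds)
    return SpeciesArchitectureSummary(
        species=species,
        n_genes=len(records),
        total_cds_bp=total_cds,
        total_intron_bp=total_intron,
        total_utr_bp=total_utr,
        mean_cds_bp=total_cds / n if n else 0.0,
        mean_intron_bp=total_intron / n if n else 0.0,
        mean_n_introns=(sum(r.n_introns for r in with_cds) / n) if n else 0.0,
        mean_utr_bp=(total_utr / len(with_utr)) if with_utr else None,
        missing_fields=sorted(set(missing_fields)),
    )
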