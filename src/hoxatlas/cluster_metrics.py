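"""Hox cluster dispersion metrics.

Quantities describing how a labelled Hox complement is arranged in a
genome: cluster span (transcription start of the most-3' gene to
transcription stop of the most-5' gene), genome fraction, intergenic gaps,
intervening protein-coding gene counts, intervening-space proportion,
split detection, orientation/inversion profiles, and tandem duplicates.

Cross-scaffold distances use the minimum-gap convention: scaffolds may
not be contiguous, so (trailing flank of scaffold A) + (leading flank of
scaffold B) is a lower bound on the true genomic gap, and is labelled as
such in every report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import HoxatlasError, ParameterError
from .model import GeneModel, GenomeAnnotation, HoxClusterMap, Interval

__all__ = [
    "ClusterMetrics",
    "SplitReport",
    "OrientationProfile",
    "DuplicationRecord",
    "cluster_span",
    "genome_fraction",
    "intergenic_gaps",
    "intervening_gene_counts",
    "intervening_space",
    "detect_splits",
    "orientation_profile",
    "detect_tandem_duplicates",
    "compute_metrics",
    "round_mb",
]

DEFAULT_SPLIT_THRESHOLD_BP = 1_000_000


def round_mb(bp: int, decimals: int = 2) -> float:
    """bp -> Mb, rounded half-up to match reported precision."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -decimals
    return float((Decimal(bp) / Decimal(1_000_000)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ClusterMetrics:
    span_bp: int
    genome_fraction: float
    intergenic_gaps: list[tuple[tuple[str, str], int]]
    intervening_counts: list[tuple[tuple[str, str], int]]
    intervening_space_bp: int
    intervening_space_fraction: float
    n_scaffolds: int
    block_spans: dict[str, int] = field(default_factory=dict)

    @property
    def span_mb(self) -> float:
        return round_mb(self.span_bp)


@dataclass
class SplitReport:
    is_split: bool
    break_pairs: list[tuple[str, str, int, bool]]  # (up, down, gap bp, same_scaffold)
    threshold_bp: int


@dataclass
class OrientationProfile:
    reference_strand: str
    inverted_genes: list[str]
    n_orientation_runs: int


@dataclass
class DuplicationRecord:
    hox_class: str
    gene_ids: list[str]
    tandem: bool


def _cluster_genes(
    cluster_map: HoxClusterMap, annotation: GenomeAnnotation
) -> list[GeneModel]:
    if not cluster_map.entries:
        raise HoxatlasError("empty Hox cluster map")
    return [annotation.genes[e.gene_id] for e in cluster_map.entries]


def _blocks(
    cluster_map: HoxClusterMap, annotation: GenomeAnnotation
) -> list[tuple[str, list[tuple[str, GeneModel]]]]:
    """Genes grouped by scaffold, following scaffold_order."""
    genes = _cluster_genes(cluster_map, annotation)
    scafs = {g.scaffold_id for g in genes}
    order = [s for s in cluster_map.scaffold_order if s in scafs]
    if set(order) != scafs:
        raise HoxatlasError(
            "cluster genes lie on scaffolds not covered by scaffold_order; "
            "supply the expected scaffold arrangement via scaffold_order"
        )
    by_scaf: dict[str, list[tuple[str, GeneModel]]] = {s: [] for s in order}
    for entry, gene in zip(cluster_map.entries, genes):
        by_scaf[gene.scaffold_id].append((entry.hox_class, gene))
    for s in order:
        by_scaf[s].sort(key=lambda cg: cg[1].transcription_unit)
    return [(s, by_scaf[s]) for s in order]


def _block_span(genes: list[tuple[str, GeneModel]]) -> tuple[int, int, int]:
    starts = [g.transcription_unit[0] for _, g in genes]
    ends = [g.transcription_unit[1] for _, g in genes]
    return min(starts), max(ends), max(ends) - min(starts)


def _cross_scaffold_min_gaps(
    blocks, annotation: GenomeAnnotation
) -> list[tuple[str, str, int]]:
    """Minimum gap between consecutive scaffold blocks: trailing flank of
    the upstream scaffold plus leading flank of the downstream one."""
    gaps = []
    for (sid_a, genes_a), (sid_b, genes_b) in zip(blocks, blocks[1:]):
        last_cls, last_gene = genes_a[-1]
        first_cls, first_gene = genes_b[0]
        trail = annotation.scaffolds[sid_a].length - last_gene.transcription_unit[1]
        lead = first_gene.transcription_unit[0]
        gaps.append((last_cls, first_cls, trail + lead))
    return gaps


def cluster_span(
    cluster_map: HoxClusterMap, annotation: GenomeAnnotation
) -> tuple[int, dict[str, int]]:
    """Total span in bp plus per-scaffold block spans.

    For a multi-scaffold cluster the total assumes the user-supplied
    scaffold order and adds the *minimum* cross-scaffold gaps, so it is a
    lower bound on the true arrangement.
    """
    blocks = _blocks(cluster_map, annotation)
    block_spans: dict[str, int] = {}
    total = 0
    for sid, genes in blocks:
        _, _, span = _block_span(genes)
        block_spans[sid] = span
        total += span
    for _, _, gap in _cross_scaffold_min_gaps(blocks, annotation):
        total += gap
    return total, block_spans


def genome_fraction(span_bp: int, assembly_size_bp: int) -> float:
    """Fraction of the assembly covered by the cluster span, in [0, 1]."""
    if assembly_size_bp <= 0:
        raise ParameterError("assembly size must be > 0")
    if span_bp < 0 or span_bp > assembly_size_bp:
        raise ParameterError(
            f"span {span_bp} bp outside [0, assembly size {assembly_size_bp}]"
        )
    return span_bp / assembly_size_bp


def intergenic_gaps(
    cluster_map: HoxClusterMap, annotation: GenomeAnnotation
) -> list[tuple[tuple[str, str], int, bool]]:
    """Gaps between adjacent Hox transcription units on shared scaffolds.

    Returns (pair, gap bp, overlap_flag); overlapping/nested neighbours are
    clamped to 0 with the flag set.
    """
    out = []
    for sid, genes in _blocks(cluster_map, annotation):
        for (cls_a, a), (cls_b, b) in zip(genes, genes[1:]):
            gap = b.transcription_unit[0] - a.transcription_unit[1]
            out.append(((cls_a, cls_b), max(gap, 0), gap < 0))
    return out


def intervening_gene_counts(
    cluster_map: HoxClusterMap, annotation: GenomeAnnotation
) -> list[tuple[tuple[str, str], int, list[str]]]:
    """Protein-coding genes strictly between adjacent Hox genes.

    Counts only genes whose transcription unit is fully contained in the
    gap; genes partially overlapping the gap are returned in the third
    element as a warning list, not counted.
    """
    hox_ids = set(cluster_map.gene_ids())
    out = []
    for sid, genes in _blocks(cluster_map, annotation):
        others = [
            g
            for g in annotation.genes_on(sid, biotype="protein_coding")
            if g.gene_id not in hox_ids
        ]
        for (cls_a, a), (cls_b, b) in zip(genes, genes[1:]):
            gap_s = a.transcription_unit[1]
            gap_e = b.transcription_unit[0]
            inside = 0
            partial: list[str] = []
            for g in others:
                s, e = g.transcription_unit
                if s >= gap_s and e <= gap_e:
                    inside += 1
                elif s < gap_e and e > gap_s:
                    partial.append(g.gene_id)
            out.append(((cls_a, cls_b), inside, partial))
    return out


def _merge_intervals(ivals: list[Interval]) -> list[Interval]:
    merged: list[Interval] = []
    for s, e in sorted(ivals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def intervening_space(
    cluster_map: HoxClusterMap, annotation: GenomeAnnotation
) -> tuple[int, float]:
    """Span minus the union of Hox transcription units, and its fraction.

    Overlapping/nested Hox units are merged before the subtraction, so the
    single-scaffold additivity span == merged-unit bp + intervening bp holds.
    Cross-scaffold minimum gaps count as intervening space.
    """
    blocks = _blocks(cluster_map, annotation)
    total_span, _ = cluster_span(cluster_map, annotation)
    hox_bp = 0
    for _, genes in blocks:
        merged = _merge_intervals([g.transcription_unit for _, g in genes])
        hox_bp += sum(e - s for s, e in merged)
    space = total_span - hox_bp
    return space, (space / total_span if total_span else 0.0)


def detect_splits(
    cluster_map: HoxClusterMap,
    annotation: GenomeAnnotation,
    threshold_bp: int = DEFAULT_SPLIT_THRESHOLD_BP,
) -> SplitReport:
    """Flag the cluster as split when adjacent Hox genes sit on different
    scaffolds, or an intra-scaffold gap exceeds threshold_bp.

    Cross-scaffold break pairs report the minimum gap (flank a + flank b).
    """
    if threshold_bp <= 0:
        raise ParameterError("split threshold must be > 0")
    blocks = _blocks(cluster_map, annotation)
    breaks: list[tuple[str, str, int, bool]] = []
    for (pair, gap, _flag) in intergenic_gaps(cluster_map, annotation):
        if gap > threshold_bp:
            breaks.append((pair[0], pair[1], gap, True))
    for up, down, gap in _cross_scaffold_min_gaps(blocks, annotation):
        breaks.append((up, down, gap, False))
    return SplitReport(is_split=bool(breaks), break_pairs=breaks, threshold_bp=threshold_bp)


def orientation_profile(
    cluster_map: HoxClusterMap, annotation: GenomeAnnotation
) -> OrientationProfile:
    """Majority-strand reference with inverted genes and orientation runs.

    Ties go to the strand of lab (or the first cluster entry when lab is
    absent).  Runs are counted along the cluster order.
    """
    genes = _cluster_genes(cluster_map, annotation)
    strands = [g.strand for g in genes]
    n_plus = strands.count("+")
    n_minus = strands.count("-")
    if n_plus > n_minus:
        ref = "+"
    elif n_minus > n_plus:
        ref = "-"
    else:
        by_class = {e.hox_class: g for e, g in zip(cluster_map.entries, genes)}
        ref = by_class.get("lab", genes[0]).strand
    inverted = [g.gene_id for g in genes if g.strand != ref]
    runs = 1 + sum(1 for a, b in zip(strands, strands[1:]) if a != b)
    return OrientationProfile(
        reference_strand=ref, inverted_genes=inverted, n_orientation_runs=runs
    )


def detect_tandem_duplicates(cluster_map: HoxClusterMap) -> list[DuplicationRecord]:
    """Duplicated Hox classes, flagged tandem when the copies are adjacent
    in the cluster (no other Hox class between them)."""
    classes = cluster_map.classes()
    out: list[DuplicationRecord] = []
    for cls in dict.fromkeys(classes):  # preserve cluster order
        idx = [i for i, c in enumerate(classes) if c == cls]
        if len(idx) < 2:
            continue
        tandem = all(j - i == 1 for i, j in zip(idx, idx[1:]))
        out.append(
            DuplicationRecord(
                hox_class=cls,
                gene_ids=[cluster_map.entries[i].gene_id for i in idx],
                tandem=tandem,
            )
        )
    return out


def compute_metrics(
    cluster_map: HoxClusterMap, annotation: GenomeAnnotation
) -> ClusterMetrics:
    """Convenience wrapper assembling the full ClusterMetrics record."""
    span, block_spans = cluster_span(cluster_map, annotation)
    space, frac = intervening_space(cluster_map, annotation)
    return ClusterMetrics(
        span_bp=span,
        genome_fraction=genome_fraction(span, annotation.assembly_size),
        intergenic_gaps=[(p, g) for p, g, _ in intergenic_gaps(cluster_map, annotation)],
        intervening_counts=[
            (p, c) for p, c, _ in intervening_gene_counts(cluster_map, annotation)
        ],
        intervening_space_bp=space,
        intervening_space_fraction=frac,
        n_scaffolds=len(block_spans),
        block_spans=block_spans,
    )
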