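"""Homology-based annotation of Hox gene-associated miRNAs.

The pipeline mirrors the classic conserved-miRNA screen: known pre-miRNA
stem-loops (mir-993, mir-10, mir-iab-4/mir-iab-8 in the Hox context) are
searched against a genome by exact local alignment on both strands; hits
passing the alignment thresholds (>=20 aligned nt, >=80% identity by
default) are extended by flanking sequence, folded, and kept only if they
form a single stem-loop with MFE <= -20 kcal/mol carrying the mature
sequence on one arm of the stem.  Surviving loci are deduplicated (tandem
copies closer than ~500 bp are reported as distinct copies of one locus)
and positioned relative to the Hox genes of the cluster.

Local alignment replaces the original BLAST step deliberately: the
thresholds, not the search engine, define the filter, and exhaustive
Smith-Waterman is deterministic at hairpin scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .alignment import PairwiseAlignment, ScoringScheme, percent_identity, revcomp, sw_align
from .errors import HoxatlasError, LocationError, ParameterError
from .model import GenomeAnnotation, HoxClusterMap
from .rna import HairpinFold, component_arms, fold_hairpin, stemloop_components

__all__ = [
    "MirnaScreenParams",
    "MirnaCandidate",
    "MirnaLocus",
    "screen_homologs",
    "stemloop_filter",
    "assign_position",
    "resolve_duplicates",
    "run_mirna_pipeline",
]


@dataclass
class MirnaScreenParams:
    """Thresholds of the homology screen and hairpin filter.

    Defaults are the screen's published operating point: alignment length
    >= 20 nt, identity >= 80%, hairpin MFE <= -20 kcal/mol (inclusive
    comparisons at every boundary), tandem copies merged into one locus
    report when closer than 500 bp.
    """

    min_alignment_len: int = 20
    min_identity: float = 80.0
    mfe_threshold: float = -20.0
    duplicate_merge_bp: int = 500
    flank_bp: int = 20
    mature_paired_min: float = 0.60  # fraction of mature bases paired on the arm

    def __post_init__(self) -> None:
        if self.min_alignment_len < 1:
            raise ParameterError("min_alignment_len must be >= 1")
        if not 0 < self.min_identity <= 100:
            raise ParameterError("min_identity must be in (0, 100]")
        if self.mfe_threshold >= 0:
            raise ParameterError("mfe_threshold must be negative (kcal/mol)")
        if self.flank_bp < 0 or self.duplicate_merge_bp < 0:
            raise ParameterError("flank_bp/duplicate_merge_bp must be >= 0")

    def min_sw_score(self, scheme: ScoringScheme) -> float:
        """Lowest local-alignment score a passing hit could have."""
        n = self.min_alignment_len
        n_match = self.min_identity / 100.0 * n
        return max(1.0, scheme.match * n_match + scheme.mismatch * (n - n_match))


@dataclass
class MirnaCandidate:
    """One screened locus, carrying its alignment and (optionally) fold."""

    scaffold_id: str
    start: int
    end: int
    strand: str
    source_query: str
    alignment: PairwiseAlignment
    sequence: str = ""
    fold: HairpinFold | None = None
    passes_filters: bool = False
    filter_diagnostics: dict = field(default_factory=dict)
    position_label: str = ""

    @property
    def locus(self) -> tuple[str, int, int, str]:
        return (self.scaffold_id, self.start, self.end, self.strand)


@dataclass
class MirnaLocus:
    """A resolved locus after duplicate merging: one or more tandem copies."""

    scaffold_id: str
    start: int
    end: int
    strand: str
    source_query: str
    copies: int
    candidates: list[MirnaCandidate] = field(default_factory=list)


def screen_homologs(
    annotation: GenomeAnnotation,
    query_premirnas: dict[str, str],
    params: MirnaScreenParams | None = None,
    scheme: ScoringScheme | None = None,
) -> list[MirnaCandidate]:
    """Local-alignment screen of query pre-miRNAs against all scaffolds.

    Both strands are searched; hits passing the (length, identity)
    thresholds are extended by ``flank_bp`` and returned pre-filter
    (folding and the stem-loop test happen downstream).  Hits are
    deduplicated per (query, locus).
    """
    params = params or MirnaScreenParams()
    scheme = scheme or ScoringScheme.blastn_like()
    if not annotation.scaffolds:
        raise HoxatlasError("annotation has no scaffolds")
    if not any(s.sequence for s in annotation.scaffolds.values()):
        raise HoxatlasError("no scaffold sequence loaded; the screen needs sequence")

    min_score = params.min_sw_score(scheme)
    out: list[MirnaCandidate] = []
    for scaf in annotation.scaffolds.values():
        if not scaf.sequence:
            continue
        target = scaf.sequence
        for name, query in sorted(query_premirnas.items()):
            q = query.upper().replace("U", "T")
            hits = sw_align(q, target, scheme, min_score=min_score, both_strands=True)
            seen: set[tuple[int, int, str]] = set()
            for hit in hits:
                if hit.n_columns < params.min_alignment_len:
                    continue
                if percent_identity(hit) < params.min_identity:
                    continue
                ts, te = hit.coords[2], hit.coords[3]
                start = max(0, ts - params.flank_bp)
                end = min(scaf.length, te + params.flank_bp)
                key = (start, end, hit.strand)
                if key in seen:
                    continue
                seen.add(key)
                segment = target[start:end]
                if hit.strand == "-":
                    segment = revcomp(segment)
                out.append(
                    MirnaCandidate(
                        scaffold_id=scaf.id,
                        start=start,
                        end=end,
                        strand=hit.strand,
                        source_query=name,
                        alignment=hit,
                        sequence=segment.replace("T", "U"),
                    )
                )
    out.sort(key=lambda c: (c.scaffold_id, c.start, c.strand, c.source_query))
    return out


def _locate_mature(candidate: MirnaCandidate, mature_seq: str) -> tuple[int, int]:
    """Position of the mature sequence within the candidate (best local hit)."""
    mature = mature_seq.upper().replace("U", "T")
    cand = candidate.sequence.upper().replace("U", "T")
    if mature in cand:
        s = cand.index(mature)
        return s, s + len(mature)
    hits = sw_align(mature, cand, ScoringScheme.dna_default(), min_score=1.0)
    if not hits:
        raise LocationError(
            f"mature sequence not locatable in candidate at "
            f"{candidate.scaffold_id}:{candidate.start}-{candidate.end}"
        )
    best = hits[0]
    qs, qe, ts, te = best.coords
    if (qe - qs) < 0.7 * len(mature):
        raise LocationError("mature sequence aligns over <70% of its length")
    return ts, te


def stemloop_filter(
    candidate: MirnaCandidate,
    mature_seq: str,
    params: MirnaScreenParams | None = None,
) -> tuple[bool, dict]:
    """Hairpin test: single stem-loop, MFE <= threshold (inclusive), and the
    mature sequence entirely on one arm with enough of its bases paired.

    Folds the candidate if not already folded; returns (verdict,
    diagnostics) and records both on the candidate.
    """
    params = params or MirnaScreenParams()
    if candidate.fold is None:
        candidate.fold = fold_hairpin(candidate.sequence)
    fold = candidate.fold
    diag: dict = {"mfe": fold.mfe}

    mfe_ok = fold.mfe <= params.mfe_threshold
    diag["mfe_ok"] = mfe_ok

    ms, me = _locate_mature(candidate, mature_seq)
    diag["mature_interval"] = (ms, me)

    # judge the stem-loop component holding the mature; flanking genomic
    # sequence may fold small independent side-stems that are not branches
    comps = stemloop_components(fold.structure)
    diag["n_components"] = len(comps)
    holding = [c for c in comps if c[0] <= ms and me <= c[1]]
    topology_ok = False
    mature_ok = False
    if holding:
        cs, ce, n_loops = holding[0]
        topology_ok = n_loops == 1
        diag["component"] = (cs, ce)
        diag["component_terminal_loops"] = n_loops
        if topology_ok:
            (a5s, a5e), (a3s, a3e), _loop = component_arms(fold.structure, cs, ce)
            on5 = a5s <= ms and me <= a5e
            on3 = a3s <= ms and me <= a3e
            diag["mature_arm"] = "5p" if on5 else ("3p" if on3 else None)
            if on5 or on3:
                frac = fold.paired_fraction(ms, me)
                diag["mature_paired_fraction"] = frac
                mature_ok = frac >= params.mature_paired_min
    diag["single_stemloop"] = topology_ok
    diag["mature_on_stem"] = mature_ok

    verdict = bool(mfe_ok and topology_ok and mature_ok)
    candidate.passes_filters = verdict
    candidate.filter_diagnostics = diag
    return verdict, diag


def assign_position(
    candidate: MirnaCandidate,
    cluster_map: HoxClusterMap,
    annotation: GenomeAnnotation,
) -> str:
    """Positional label of a locus relative to the Hox transcription units.

    ``between(X,Y)`` when flanked by Hox genes on the same scaffold;
    beyond the cluster's 3'-most gene the label is ``downstream(X)`` and
    beyond the 5'-most gene ``upstream(X)`` (cluster polarity runs lab at
    the 3' end to Abd-B at the 5' end); ``non_hox_scaffold`` otherwise.
    """
    hox = [
        (e, annotation.genes[e.gene_id])
        for e in cluster_map.entries
        if annotation.genes[e.gene_id].scaffold_id == candidate.scaffold_id
    ]
    if not hox:
        candidate.position_label = "non_hox_scaffold"
        return candidate.position_label
    hox.sort(key=lambda eg: eg[1].transcription_unit)
    mid = (candidate.start + candidate.end) / 2

    # Which genomic side holds the cluster's 3' end?  Canonically lab is
    # the 3'-most class and Abd-B the 5'-most, whichever way the cluster
    # happens to run along the scaffold.
    from .model import HOX_CLASSES

    rank = {c: i for i, c in enumerate(HOX_CLASSES)}
    first_entry, first_gene = hox[0]
    last_entry, last_gene = hox[-1]
    left_is_three_prime = rank[first_entry.hox_class] <= rank[last_entry.hox_class]

    if mid < first_gene.transcription_unit[0]:
        label = (
            f"downstream({first_entry.hox_class})"
            if left_is_three_prime
            else f"upstream({first_entry.hox_class})"
        )
    elif mid >= last_gene.transcription_unit[1]:
        label = (
            f"upstream({last_entry.hox_class})"
            if left_is_three_prime
            else f"downstream({last_entry.hox_class})"
        )
    else:
        label = None
        for (ea, ga), (eb, gb) in zip(hox, hox[1:]):
            if ga.transcription_unit[1] <= mid < gb.transcription_unit[0]:
                a, b = ea, eb
                if rank[a.hox_class] > rank[b.hox_class]:
                    a, b = b, a
                label = f"between({a.hox_class},{b.hox_class})"
                break
        if label is None:  # inside a Hox transcription unit
            for e, g in hox:
                s, t = g.transcription_unit
                if s <= mid < t:
                    label = f"within({e.hox_class})"
                    break
    candidate.position_label = label or "non_hox_scaffold"
    return candidate.position_label


def resolve_duplicates(
    candidates: list[MirnaCandidate], params: MirnaScreenParams | None = None
) -> list[MirnaLocus]:
    """Merge overlapping same-query hits; report non-overlapping hits within
    ``duplicate_merge_bp`` of each other as tandem copies of one locus."""
    params = params or MirnaScreenParams()
    by_query: dict[tuple[str, str], list[MirnaCandidate]] = {}
    for c in candidates:
        by_query.setdefault((c.scaffold_id, c.source_query), []).append(c)

    loci: list[MirnaLocus] = []
    for (scaf, query), group in sorted(by_query.items()):
        group.sort(key=lambda c: (c.start, c.end))
        # first pass: merge overlapping hits into single copies
        copies: list[MirnaCandidate] = []
        for c in group:
            if copies and c.start < copies[-1].end:
                prev = copies[-1]
                keep = prev if prev.alignment.score >= c.alignment.score else c
                keep.start = min(prev.start, c.start)
                keep.end = max(prev.end, c.end)
                copies[-1] = keep
            else:
                copies.append(c)
        # second pass: chain nearby copies into tandem loci
        chain: list[MirnaCandidate] = []
        for c in copies:
            if chain and c.start - chain[-1].end < params.duplicate_merge_bp:
                chain.append(c)
            else:
                if chain:
                    loci.append(_make_locus(scaf, query, chain))
                chain = [c]
        if chain:
            loci.append(_make_locus(scaf, query, chain))
    return loci


def _make_locus(scaf: str, query: str, chain: list[MirnaCandidate]) -> MirnaLocus:
    return MirnaLocus(
        scaffold_id=scaf,
        start=chain[0].start,
        end=chain[-1].end,
        strand=chain[0].strand,
        source_query=query,
        copies=len(chain),
        candidates=list(chain),
    )


def run_mirna_pipeline(
    annotation: GenomeAnnotation,
    query_premirnas: dict[str, str],
    matures: dict[str, str],
    cluster_map: HoxClusterMap | None = None,
    params: MirnaScreenParams | None = None,
) -> list[MirnaLocus]:
    """Screen, fold-filter, position and deduplicate in one call.

    ``matures`` maps query names to their mature sequences; queries lacking
    a mature entry are dropped with a diagnostics note.
    """
    params = params or MirnaScreenParams()
    candidates = screen_homologs(annotation, query_premirnas, params)
    kept: list[MirnaCandidate] = []
    for c in candidates:
        mature = matures.get(c.source_query)
        if mature is None:
            c.filter_diagnostics = {"error": "no mature sequence supplied"}
            continue
        try:
            ok, _ = stemloop_filter(c, mature, params)
        except LocationError as exc:
            c.passes_filters = False
            c.filter_diagnostics = {"error": str(exc)}
            continue
        if ok:
            if cluster_map is not None:
                assign_position(c, cluster_map, annotation)
            kept.append(c)
    return resolve_duplicates(kept, params)
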