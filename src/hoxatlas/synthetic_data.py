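"""Synthetic annotated genomes with planted, machine-readable ground truth.

Generates the study conditions the analysis modules assume: a Hox cluster
laid out with configurable intergenic gaps, intervening protein-coding
genes, losses, tandem or dispersed duplications, strand inversions and a
split across two scaffolds with known flank lengths; planted pre-miRNA
hairpins mutated stem-preservingly; HKY85-evolved alignments on a known
tree; and diverged paralog pairs hitting a target percent identity.

Every planted feature is recorded in a :class:`GroundTruth` so cluster
metrics, the miRNA screen and the phylogenetic machinery can be checked
for exact recovery.  All randomness flows through one integer seed;
identical spec + seed gives byte-identical outputs.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np

from .alignment import ScoringScheme, nw_align, revcomp
from .errors import CapacityError, HoxatlasError, ParameterError, PlacementError
from .model import (
    HOX_CLASSES,
    GeneModel,
    GenomeAnnotation,
    Scaffold,
    TranscriptModel,
)
from .phylo import HKY85Params, PhyloTree, SiteAlignment
from .rna import dotbracket_to_pairs, fold_hairpin

__all__ = [
    "Duplication",
    "ClusterSpec",
    "GroundTruth",
    "SyntheticGenome",
    "PlantedMirna",
    "HairpinTemplate",
    "generate_genome",
    "write_genome",
    "plant_mirna_hairpin",
    "make_hairpin_template",
    "default_mirna_templates",
    "simulate_hky85",
    "mutate_paralog",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class Duplication:
    hox_class: str
    copies: int = 2
    divergence: float = 0.25
    tandem: bool = True


@dataclass
class ClusterSpec:
    """Recipe for one synthetic Hox-bearing genome.

    Gaps default to a log-uniform law between 1 kb and 500 kb, spanning the
    tight-to-dispersed regimes seen across arthropod assemblies; explicit
    per-pair gaps override the law.  Intervening genes are single-exon
    protein-coding dummies placed fully inside their gap.
    """

    hox_order: tuple[str, ...] = HOX_CLASSES
    losses: tuple[str, ...] = ()
    duplications: tuple[Duplication, ...] = ()
    inversions: tuple[str, ...] = ()
    split_after: tuple[str, int, int] | None = None  # (class, flank_a, flank_b)
    gap_law: tuple = ("loguniform", 1_000, 500_000)
    gaps: tuple[int, ...] | None = None  # explicit gap per adjacent pair
    intervening_genes_per_gap: int | tuple[int, ...] = 0
    genome_size: int | None = None
    gc: float = 0.40
    species: str = "synthetic"
    seed: int = 0
    with_sequence: bool = True
    start_offset: int = 5_000
    end_flank: int = 5_000
    n_exons: int = 3
    exon_len: tuple[int, int] = (200, 400)
    intron_len: tuple[int, int] = (300, 2_000)
    utr5_len: tuple[int, int] = (50, 200)
    utr3_len: tuple[int, int] = (100, 300)
    intervening_len: tuple[int, int] = (500, 2_000)

    def __post_init__(self) -> None:
        bad = set(self.losses) & {d.hox_class for d in self.duplications}
        if bad:
            raise ParameterError(f"classes both lost and duplicated: {sorted(bad)}")
        for cls in (*self.losses, *self.inversions, *self.hox_order):
            if cls not in HOX_CLASSES:
                raise ParameterError(f"unknown Hox class {cls!r}")


@dataclass
class PlantedMirna:
    name: str
    scaffold_id: str
    start: int
    end: int
    strand: str
    sequence: str  # planted (possibly diverged) sequence, 5'->3' on its strand
    structure: str
    mfe: float
    mature_offset: tuple[int, int]  # within the planted sequence


@dataclass
class GroundTruth:
    """Expected values for every planted feature, computed at construction
    time by direct arithmetic on the layout (independently of the metrics
    code paths they validate)."""

    species: str
    span_bp: int
    block_spans: dict[str, int]
    intergenic_gaps: list[tuple[tuple[str, str], int]]
    intervening_counts: list[tuple[tuple[str, str], int]]
    intervening_space_bp: int
    intervening_space_fraction: float
    hox_unit_bp: int
    split: tuple[str, str, int] | None  # (upstream class, downstream class, min gap)
    inverted_gene_ids: list[str]
    reference_strand: str
    n_orientation_runs: int
    duplicates: list[tuple[str, list[str], bool]]  # (class, gene_ids, tandem)
    genome_size: int
    mirnas: list[PlantedMirna] = field(default_factory=list)


@dataclass
class SyntheticGenome:
    annotation: GenomeAnnotation
    labels: list[tuple[str, str, str]]
    scaffold_order: list[str]
    truth: GroundTruth
    spec: ClusterSpec


def _rand_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def _draw_gap(spec: ClusterSpec, rng: np.random.Generator) -> int:
    law, lo, hi = spec.gap_law
    if law == "loguniform":
        return int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    if law == "uniform":
        return int(rng.uniform(lo, hi))
    raise ParameterError(f"unknown gap law {law!r}")


@dataclass
class _GenePlan:
    exons: list[int]
    introns: list[int]
    utr5: int
    utr3: int

    @property
    def span(self) -> int:
        return sum(self.exons) + sum(self.introns)


def _plan_gene(spec: ClusterSpec, rng: np.random.Generator) -> _GenePlan:
    exons = [int(rng.integers(*spec.exon_len)) for _ in range(spec.n_exons)]
    introns = [int(rng.integers(*spec.intron_len)) for _ in range(spec.n_exons - 1)]
    utr5 = int(rng.integers(*spec.utr5_len))
    utr3 = int(rng.integers(*spec.utr3_len))
    exons[0] = max(exons[0], utr5 + 60)
    exons[-1] = max(exons[-1], utr3 + 60)
    return _GenePlan(exons=exons, introns=introns, utr5=utr5, utr3=utr3)


def _build_gene(
    gene_id: str, scaffold_id: str, start: int, strand: str, plan: _GenePlan,
    biotype: str = "protein_coding",
) -> GeneModel:
    exons = []
    pos = start
    for i, elen in enumerate(plan.exons):
        exons.append((pos, pos + elen))
        pos += elen
        if i < len(plan.introns):
            pos += plan.introns[i]
    end = exons[-1][1]
    # UTRs at the transcript's 5'/3' ends; orientation follows strand
    if strand == "+":
        utr5 = [(exons[0][0], exons[0][0] + plan.utr5)]
        utr3 = [(exons[-1][1] - plan.utr3, exons[-1][1])]
        cds_start, cds_end = utr5[0][1], utr3[0][0]
    else:
        utr5 = [(exons[-1][1] - plan.utr5, exons[-1][1])]
        utr3 = [(exons[0][0], exons[0][0] + plan.utr3)]
        cds_start, cds_end = utr3[0][1], utr5[0][0]
    cds = []
    for s, e in exons:
        cs, ce = max(s, cds_start), min(e, cds_end)
        if cs < ce:
            cds.append((cs, ce))
    tx = TranscriptModel(
        transcript_id=f"{gene_id}.t1", exons=exons, cds=cds, utr5=utr5, utr3=utr3
    )
    return GeneModel(
        gene_id=gene_id, scaffold_id=scaffold_id, start=start, end=end,
        strand=strand, transcripts=[tx], biotype=biotype,
    )


def generate_genome(spec: ClusterSpec) -> SyntheticGenome:
    """Lay out the planted cluster and return annotation + ground truth.

    Deterministic given the spec (which includes the seed).  Scaffold
    "scaffold_A" holds the cluster (and "scaffold_B" the distal part when
    split); a background scaffold pads the assembly to ``genome_size``.
    """
    rng = np.random.default_rng(spec.seed)

    # entry list: (hox_class, copy_index, tandem_placement)
    dup_by_class = {d.hox_class: d for d in spec.duplications}
    entries: list[tuple[str, int]] = []
    deferred: list[tuple[str, int]] = []
    for cls in spec.hox_order:
        if cls in spec.losses:
            continue
        entries.append((cls, 1))
        d = dup_by_class.get(cls)
        if d:
            for copy in range(2, d.copies + 1):
                (entries if d.tandem else deferred).append((cls, copy))
    entries.extend(deferred)
    if not entries:
        raise ParameterError("spec yields an empty cluster")

    n_gaps = len(entries) - 1
    if spec.gaps is not None and len(spec.gaps) != n_gaps:
        raise ParameterError(f"explicit gaps must have {n_gaps} values")
    iv = spec.intervening_genes_per_gap
    iv_counts = list(iv) if isinstance(iv, (tuple, list)) else [int(iv)] * n_gaps
    if len(iv_counts) != n_gaps:
        raise ParameterError(f"intervening_genes_per_gap must have {n_gaps} values")

    ann = GenomeAnnotation()
    labels: list[tuple[str, str, str]] = []
    prefix = spec.species[:2].lower() or "sp"

    split_cls = spec.split_after[0] if spec.split_after else None
    if split_cls is not None and split_cls not in [c for c, _ in entries]:
        raise ParameterError(f"split_after class {split_cls!r} not in cluster")

    scaffold_genes: dict[str, list[tuple[str, int, GeneModel]]] = {"scaffold_A": []}
    scaffold_ids = ["scaffold_A"]
    interveners: dict[str, list[GeneModel]] = {"scaffold_A": []}
    cur_scaf = "scaffold_A"
    cursor = spec.start_offset
    truth_gaps: list[tuple[tuple[str, str], int]] = []
    truth_counts: list[tuple[tuple[str, str], int]] = []
    pending: list[GeneModel] = []
    scaf_lengths: dict[str, int] = {}

    for idx, (cls, copy) in enumerate(entries):
        plan = _plan_gene(spec, rng)
        gene_id = f"{prefix}_{cls}" + (f"_{copy}" if (cls in dup_by_class) else "")
        strand = "-" if cls in spec.inversions else "+"
        gene = _build_gene(gene_id, cur_scaf, cursor, strand, plan)
        pending.append(gene)
        scaffold_genes[cur_scaf].append((cls, copy, gene))
        labels.append((gene_id, cls, spec.species))
        gene_end = gene.end

        if idx == len(entries) - 1:
            scaf_lengths[cur_scaf] = gene_end + spec.end_flank
            break

        if split_cls == cls and copy == max(
            c for cl, c in entries if cl == cls
        ) and cur_scaf == "scaffold_A":
            _, flank_a, flank_b = spec.split_after
            scaf_lengths[cur_scaf] = gene_end + flank_a
            cur_scaf = "scaffold_B"
            scaffold_ids.append(cur_scaf)
            scaffold_genes[cur_scaf] = []
            interveners[cur_scaf] = []
            cursor = flank_b
            continue

        k = iv_counts[idx]
        gap = spec.gaps[idx] if spec.gaps is not None else _draw_gap(spec, rng)
        iv_plans = [
            (int(rng.integers(*spec.intervening_len))) for _ in range(k)
        ]
        min_gap = (sum(iv_plans) + (k + 1) * 10) if k else 0
        gap = max(gap, min_gap)
        next_cls = entries[idx + 1][0]
        truth_gaps.append(((cls, next_cls), gap))
        truth_counts.append(((cls, next_cls), k))
        # place intervening genes evenly inside the gap
        if k:
            spare = gap - sum(iv_plans)
            step = spare // (k + 1)
            pos = gene_end + step
            for m, length in enumerate(iv_plans, start=1):
                ig = GeneModel(
                    gene_id=f"{prefix}_iv_{idx}_{m}",
                    scaffold_id=cur_scaf,
                    start=pos,
                    end=pos + length,
                    strand="+",
                    transcripts=[
                        TranscriptModel(
                            transcript_id=f"{prefix}_iv_{idx}_{m}.t1",
                            exons=[(pos, pos + length)],
                            cds=[(pos + 10, pos + length - 10)],
                            utr5=[(pos, pos + 10)],
                            utr3=[(pos + length - 10, pos + length)],
                        )
                    ],
                    biotype="protein_coding",
                )
                interveners[cur_scaf].append(ig)
                pos += length + step
        cursor = gene_end + gap

    # scaffolds + sequence
    total = 0
    for sid in scaffold_ids:
        length = scaf_lengths[sid]
        seq = _rand_seq(rng, length, spec.gc) if spec.with_sequence else None
        ann.scaffolds[sid] = Scaffold(id=sid, length=length, sequence=seq)
        total += length
    if spec.genome_size is not None:
        if spec.genome_size < total:
            raise CapacityError(
                f"cluster needs {total} bp but genome_size is {spec.genome_size}"
            )
        pad = spec.genome_size - total
        if pad > 0:
            ann.scaffolds["scaffold_bg"] = Scaffold(
                id="scaffold_bg",
                length=pad,
                sequence=_rand_seq(rng, pad, spec.gc) if spec.with_sequence else None,
            )
    for g in pending:
        ann.add_gene(g)
    for sid in scaffold_ids:
        for g in interveners[sid]:
            ann.add_gene(g)

    # ---- ground truth by direct arithmetic on the layout ----
    block_spans: dict[str, int] = {}
    hox_bp = 0
    for sid in scaffold_ids:
        genes = [g for _, _, g in scaffold_genes[sid]]
        block_spans[sid] = genes[-1].end - genes[0].start
        hox_bp += sum(g.end - g.start for g in genes)
    span = sum(block_spans.values())
    split_truth = None
    if spec.split_after:
        scls, fa, fb = spec.split_after
        down_cls = scaffold_genes["scaffold_B"][0][0]
        span += fa + fb
        split_truth = (scls, down_cls, fa + fb)
    space = span - hox_bp
    strands = ["-" if c in spec.inversions else "+" for c, _ in entries]
    n_minus = strands.count("-")
    ref = "+" if n_minus <= len(strands) - n_minus else "-"
    inverted = [
        g.gene_id
        for sid in scaffold_ids
        for c, _, g in scaffold_genes[sid]
        if g.strand != ref
    ]
    runs = 1 + sum(1 for a, b in zip(strands, strands[1:]) if a != b)
    dup_truth = []
    order_classes = [c for c, _ in entries]
    for d in spec.duplications:
        idxs = [i for i, c in enumerate(order_classes) if c == d.hox_class]
        ids = []
        for sid in scaffold_ids:
            ids.extend(
                g.gene_id for c, _, g in scaffold_genes[sid] if c == d.hox_class
            )
        tandem = all(j - i == 1 for i, j in zip(idxs, idxs[1:]))
        dup_truth.append((d.hox_class, ids, tandem))

    truth = GroundTruth(
        species=spec.species,
        span_bp=span,
        block_spans=block_spans,
        intergenic_gaps=truth_gaps,
        intervening_counts=truth_counts,
        intervening_space_bp=space,
        intervening_space_fraction=space / span if span else 0.0,
        hox_unit_bp=hox_bp,
        split=split_truth,
        inverted_gene_ids=inverted,
        reference_strand=ref,
        n_orientation_runs=runs,
        duplicates=dup_truth,
        genome_size=ann.assembly_size,
    )
    return SyntheticGenome(
        annotation=ann,
        labels=labels,
        scaffold_order=scaffold_ids,
        truth=truth,
        spec=spec,
    )


def write_genome(genome: SyntheticGenome, outdir: str) -> dict[str, str]:
    """Write FASTA + GFF3 + label TSV + truth JSON; returns the paths."""
    from . import annotation_io as aio

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "fasta": os.path.join(outdir, "genome.fa"),
        "gff3": os.path.join(outdir, "genome.gff3"),
        "labels": os.path.join(outdir, "labels.tsv"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    if genome.spec.with_sequence:
        aio.write_fasta(genome.annotation.scaffolds.values(), paths["fasta"])
    else:
        paths.pop("fasta")
    aio.write_gff3(genome.annotation, paths["gff3"])
    aio.write_label_table(genome.labels, paths["labels"])
    with open(paths["truth"], "w") as fh:
        json.dump(asdict(genome.truth), fh, indent=1, default=str)
    return paths


# ---------------------------------------------------------------------------
# miRNA hairpin planting

@dataclass(frozen=True)
class HairpinTemplate:
    """A synthetic pre-miRNA stem-loop used as screen query and plant
    template (a constructed stand-in for a real miRBase stem-loop)."""

    name: str
    sequence: str  # RNA, 5'->3'
    mature: str    # mature sequence on the 5' arm


def make_hairpin_template(
    name: str, stem_len: int = 28, loop_len: int = 5, seed: int = 0
) -> HairpinTemplate:
    """Design a stem-loop that folds to a single hairpin well below the
    -20 kcal/mol screen threshold, with a 22-nt mature on the 5' arm."""
    rng = np.random.default_rng(seed)
    for _ in range(50):
        arm = "".join(rng.choice(list("GCAUGC")) for _ in range(stem_len))
        seq = arm + "".join(rng.choice(list("ACU")) for _ in range(loop_len)) + (
            revcomp(arm.replace("U", "T")).replace("T", "U")
        )
        fold = fold_hairpin(seq)
        if fold.arms is not None and fold.mfe <= -25.0:
            mature = arm[1:23]
            return HairpinTemplate(name=name, sequence=seq, mature=mature)
    raise HoxatlasError("failed to design a stable hairpin template")


def default_mirna_templates(seed: int = 0) -> dict[str, HairpinTemplate]:
    """Synthetic stand-ins for the four conserved Hox-associated miRNA
    stem-loops (mir-993, mir-10, mir-iab-4/8 share one locus)."""
    return {
        "mir-993-like": make_hairpin_template("mir-993-like", seed=seed + 11),
        "mir-10-like": make_hairpin_template("mir-10-like", seed=seed + 22),
        "mir-iab-4-like": make_hairpin_template("mir-iab-4-like", seed=seed + 33),
    }


def _mutate_hairpin(
    template: HairpinTemplate, divergence: float, rng: np.random.Generator,
    compensatory_p: float = 0.8,
) -> str:
    """Mutate a hairpin at the given divergence, co-mutating paired bases
    (compensatory) with probability ``compensatory_p`` so the stem survives
    realistic divergence."""
    seq = list(template.sequence)
    fold = fold_hairpin(template.sequence)
    mate = {}
    for i, j in dotbracket_to_pairs(fold.structure):
        mate[i] = j
        mate[j] = i
    n_mut = int(round(divergence * len(seq)))
    positions = rng.choice(len(seq), size=min(n_mut, len(seq)), replace=False)
    pair_choices = ["AU", "UA", "GC", "CG", "GU", "UG"]
    for i in positions:
        old = seq[i]
        if i in mate:
            j = mate[i]
            if rng.random() < compensatory_p:
                cur = seq[i] + seq[j]
                alts = [p for p in pair_choices if p != cur and p[0] != old]
                new = alts[rng.integers(len(alts))]
                seq[i], seq[j] = new[0], new[1]
            else:
                alts = [b for b in "ACGU" if b != old]
                seq[i] = alts[rng.integers(3)]
        else:
            alts = [b for b in "ACGU" if b != old]
            seq[i] = alts[rng.integers(3)]
    return "".join(seq)


def plant_mirna_hairpin(
    genome: SyntheticGenome,
    scaffold_id: str,
    position: int,
    template: HairpinTemplate,
    divergence: float = 0.0,
    seed: int = 0,
    strand: str = "+",
) -> PlantedMirna:
    """Overwrite background sequence at ``position`` with a (possibly
    diverged) copy of the template hairpin and record the truth.

    The position must fall in intergenic background: overlap with any gene
    or previously planted hairpin raises PlacementError.
    """
    rng = np.random.default_rng(seed)
    scaf = genome.annotation.scaffolds.get(scaffold_id)
    if scaf is None or scaf.sequence is None:
        raise PlacementError(f"scaffold {scaffold_id!r} missing or has no sequence")
    if template.mature not in template.sequence:
        raise ParameterError("template mature sequence must occur in the stem-loop")
    base_fold = fold_hairpin(template.sequence)
    if base_fold.arms is None or base_fold.mfe > -20.0:
        raise ParameterError(
            "template must fold to a single stem-loop with MFE <= -20 kcal/mol"
        )
    mutated = _mutate_hairpin(template, divergence, rng) if divergence > 0 else template.sequence
    n = len(mutated)
    start, end = position, position + n
    if not 0 <= start < end <= scaf.length:
        raise PlacementError(f"plant interval [{start},{end}) outside scaffold")
    for g in genome.annotation.genes_on(scaffold_id):
        if g.start < end and g.end > start:
            raise PlacementError(
                f"plant interval overlaps gene {g.gene_id!r} [{g.start},{g.end})"
            )
    for m in genome.truth.mirnas:
        if m.scaffold_id == scaffold_id and m.start < end and m.end > start:
            raise PlacementError(f"plant interval overlaps planted miRNA {m.name!r}")

    dna = mutated.replace("U", "T")
    if strand == "-":
        dna = revcomp(dna)
    scaf.sequence = scaf.sequence[:start] + dna + scaf.sequence[end:]
    fold = fold_hairpin(mutated)
    mstart = template.sequence.index(template.mature)
    record = PlantedMirna(
        name=template.name,
        scaffold_id=scaffold_id,
        start=start,
        end=end,
        strand=strand,
        sequence=mutated,
        structure=fold.structure,
        mfe=fold.mfe,
        mature_offset=(mstart, mstart + len(template.mature)),
    )
    genome.truth.mirnas.append(record)
    return record


# ---------------------------------------------------------------------------
# sequence evolution and paralog divergence

def simulate_hky85(
    tree: PhyloTree, params: HKY85Params, n_sites: int, seed: int = 0
) -> SiteAlignment:
    """Evolve ``n_sites`` independent sites along the tree under HKY85.

    Root states are drawn from pi; each branch applies its transition
    matrix.  Deterministic per seed.
    """
    if n_sites <= 0:
        raise ParameterError("n_sites must be > 0")
    rng = np.random.default_rng(seed)
    internals = [n for n in tree.adj if len(tree.adj[n]) > 1]
    root = internals[0] if internals else next(iter(tree.adj))
    states: dict[int, np.ndarray] = {
        root: rng.choice(4, size=n_sites, p=params.base_freqs)
    }

    def down(node: int, parent: int | None) -> None:
        for child in sorted(tree.adj[node]):
            if child == parent:
                continue
            P = params.transition_matrix(tree.adj[node][child])
            parent_states = states[node]
            child_states = np.empty(n_sites, dtype=np.int64)
            for s in range(4):
                mask = parent_states == s
                k = int(mask.sum())
                if k:
                    child_states[mask] = rng.choice(4, size=k, p=P[s] / P[s].sum())
            states[child] = child_states
            down(child, node)

    down(root, None)
    taxa = [tree.labels[n] for n in tree.leaves()]
    data = np.stack([states[n] for n in tree.leaves()]).astype(np.int8)
    return SiteAlignment(taxa=taxa, data=data)


def mutate_paralog(
    cds: str,
    target_identity: float,
    seed: int = 0,
    truncate: bool = False,
    homeobox_window: int = 180,
    max_iter: int = 200,
    scheme: ScoringScheme | None = None,
) -> str:
    """Diverged copy of a coding sequence hitting a target NW percent
    identity within +-1 point.

    With ``truncate``, a 3n-length 5' chunk is deleted first (the
    homeobox-bearing 3' window is preserved), emulating the substantially
    smaller duplicates seen after partial duplication; substitutions then
    close in on the target identity, measured by global alignment.
    """
    if not 0 < target_identity <= 100:
        raise ParameterError("target_identity must be in (0, 100]")
    scheme = scheme or ScoringScheme.dna_default()
    rng = np.random.default_rng(seed)
    cds = cds.upper()
    work = cds
    if truncate:
        cut_max = max(3, (len(cds) - homeobox_window) // 2 // 3 * 3)
        cut = int(rng.integers(1, cut_max // 3 + 1)) * 3
        start = int(rng.integers(0, max(1, (len(cds) - homeobox_window - cut))))
        work = cds[:start] + cds[start + cut:]
    if target_identity == 100 and not truncate:
        return work

    seq = list(work)
    mutated: set[int] = set()
    originals = dict(enumerate(work))

    def identity() -> float:
        return nw_align(cds, "".join(seq), scheme).percent_identity

    cur = identity()
    step = max(1, int(len(seq) * 0.01))
    for _ in range(max_iter):
        if abs(cur - target_identity) <= 1.0:
            return "".join(seq)
        if cur > target_identity:  # add substitutions
            candidates = [i for i in range(len(seq)) if i not in mutated]
            if not candidates:
                break
            take = min(step, len(candidates),
                       max(1, int(len(seq) * (cur - target_identity) / 100 / 2)))
            for i in rng.choice(candidates, size=take, replace=False):
                alts = [b for b in "ACGT" if b != seq[i]]
                seq[i] = alts[rng.integers(3)]
                mutated.add(int(i))
        else:  # revert some
            if not mutated:
                break
            take = max(1, int(len(seq) * (target_identity - cur) / 100 / 2))
            back = rng.choice(sorted(mutated), size=min(take, len(mutated)), replace=False)
            for i in back:
                seq[int(i)] = originals[int(i)]
                mutated.discard(int(i))
        cur = identity()
    raise HoxatlasError(
        f"could not reach target identity {target_identity} (at {cur:.1f})"
    )
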