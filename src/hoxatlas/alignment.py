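"""Pairwise sequence alignment: global (Needleman-Wunsch/Gotoh) and
iterated local (Smith-Waterman) under affine gap scoring.

Used for paralog-divergence percent identities (global, nucleotide and
protein) and as the exact local-alignment engine behind the miRNA homology
screen.  The dynamic programming itself runs on Bio.Align.PairwiseAligner;
this module fixes the scoring conventions:

* a gap of length L costs ``gap_open + (L - 1) * gap_extend``;
* percent identity is ``100 * identities / alignment columns`` with gap
  columns in the denominator (an ungapped-denominator variant is available
  via ``include_gaps=False``);
* ties between co-optimal alignments are broken by the engine's
  deterministic first-optimal ordering, so output is bit-stable.

Default schemes follow EMBOSS needle/water: nucleotide +5/-4 with gap
10/0.5, protein BLOSUM62 with gap 10/0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import AlphabetError, ParameterError

__all__ = [
    "ScoringScheme",
    "PairwiseAlignment",
    "nw_align",
    "sw_align",
    "percent_identity",
]

_DNA = set("ACGT")
_DNA_AMBIG = set("ACGTUNRYSWKMBDHV")
_PROTEIN = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*")

_COMPLEMENT = str.maketrans("ACGTUNRYSWKMBDHV", "TGCAANYRSWMKVHDB")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ambiguity codes mapped)."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass
class ScoringScheme:
    """Substitution + affine gap parameters for one alphabet.

    For nucleotides, ``match``/``mismatch`` define the substitution scores
    (ambiguity codes score as mismatch); for proteins a named substitution
    matrix is used.
    """

    alphabet: str = "nucleotide"  # or "protein"
    match: float = 5.0
    mismatch: float = -4.0
    matrix_name: str | None = None
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self) -> None:
        if self.alphabet not in ("nucleotide", "protein"):
            raise ParameterError(f"unknown alphabet {self.alphabet!r}")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ParameterError("gap penalties must be >= 0")
        if self.gap_extend > self.gap_open:
            raise ParameterError("gap_extend must not exceed gap_open")

    @classmethod
    def dna_default(cls) -> "ScoringScheme":
        return cls()

    @classmethod
    def protein_default(cls) -> "ScoringScheme":
        return cls(alphabet="protein", matrix_name="BLOSUM62")

    @classmethod
    def blastn_like(cls) -> "ScoringScheme":
        """megablast-style scoring (2/-3, gap 5/2) for genome screens.

        Unlike the needle-style default, gaps cost proportionally to their
        length, so a local search cannot chain random k-mer matches through
        cheap long gaps — essential when scanning whole scaffolds.
        """
        return cls(match=2.0, mismatch=-3.0, gap_open=5.0, gap_extend=2.0)

    def check_sequence(self, seq: str) -> str:
        if not seq:
            raise AlphabetError("empty sequence")
        seq = seq.upper().replace("U", "T") if self.alphabet == "nucleotide" else seq.upper()
        valid = _DNA_AMBIG if self.alphabet == "nucleotide" else _PROTEIN
        bad = set(seq) - valid
        if bad:
            raise AlphabetError(f"invalid {self.alphabet} symbol(s): {sorted(bad)}")
        return seq

    def make_aligner(self, mode: str) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = mode
        if self.alphabet == "protein":
            m = substitution_matrices.load(self.matrix_name or "BLOSUM62")
            aligner.substitution_matrix = m
        else:
            # Explicit matrix over ambiguity codes: match on identical
            # unambiguous bases, mismatch otherwise (incl. N vs anything).
            letters = "".join(sorted(_DNA_AMBIG - {"U"}))
            m = substitution_matrices.Array(letters, dims=2)
            for a in letters:
                for b in letters:
                    good = a == b and a in _DNA
                    m[a, b] = self.match if good else self.mismatch
            aligner.substitution_matrix = m
        aligner.open_gap_score = -self.gap_open
        aligner.extend_gap_score = -self.gap_extend
        return aligner


@dataclass
class PairwiseAlignment:
    """One pairwise alignment with identity bookkeeping.

    ``coords`` are 0-based half-open (start_a, end_a, start_b, end_b) into
    the original (forward-strand) sequences; ``strand`` is the strand of
    sequence *b* the alignment lies on ('+' unless a reverse-strand local
    search produced it).
    """

    aligned_a: str
    aligned_b: str
    score: float
    coords: tuple[int, int, int, int]
    strand: str = "+"

    n_columns: int = field(init=False)
    n_identities: int = field(init=False)

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ParameterError("aligned strings differ in length")
        self.n_columns = len(self.aligned_a)
        self.n_identities = sum(
            1
            for x, y in zip(self.aligned_a, self.aligned_b)
            if x == y and x != "-"
        )

    @property
    def percent_identity(self) -> float:
        return percent_identity(self)

    @property
    def length(self) -> int:
        return self.n_columns


def percent_identity(alignment: PairwiseAlignment, include_gaps: bool = True) -> float:
    """100 * identities / columns; gap columns count in the denominator
    by default (EMBOSS convention)."""
    if alignment.n_columns == 0:
        raise ParameterError("alignment has zero columns")
    denom = alignment.n_columns
    if not include_gaps:
        denom = sum(
            1 for x, y in zip(alignment.aligned_a, alignment.aligned_b)
            if x != "-" and y != "-"
        )
        if denom == 0:
            raise ParameterError("alignment has no ungapped columns")
    return 100.0 * alignment.n_identities / denom


def _first_alignment(alignments) -> "Align.Alignment":
    return alignments[0]


def nw_align(seq_a: str, seq_b: str, scheme: ScoringScheme | None = None) -> PairwiseAlignment:
    """Optimal global alignment under affine-gap scoring (end gaps penalized)."""
    scheme = scheme or ScoringScheme.dna_default()
    a = scheme.check_sequence(seq_a)
    b = scheme.check_sequence(seq_b)
    aligner = scheme.make_aligner("global")
    alns = aligner.align(a, b)
    best = _first_alignment(alns)
    ga, gb = str(best[0]), str(best[1])
    return PairwiseAlignment(
        aligned_a=ga,
        aligned_b=gb,
        score=float(best.score),
        coords=(0, len(a), 0, len(b)),
    )


def _local_once(
    query: str, target: str, aligner: Align.PairwiseAligner
) -> tuple[float, str, str, int, int, int, int] | None:
    if not target or not query:
        return None
    alns = aligner.align(query, target)
    if len(alns) == 0:
        return None
    best = _first_alignment(alns)
    if best.score <= 0:
        return None
    blocks_q, blocks_t = best.aligned
    if len(blocks_q) == 0:
        return None
    qs, qe = int(blocks_q[0][0]), int(blocks_q[-1][1])
    ts, te = int(blocks_t[0][0]), int(blocks_t[-1][1])
    return float(best.score), str(best[0]), str(best[1]), qs, qe, ts, te


def _iter_local(
    query: str,
    target: str,
    offset: int,
    aligner: Align.PairwiseAligner,
    min_score: float,
    hits: list,
    depth: int = 0,
) -> None:
    # Iterated Smith-Waterman: take the best hit, then mask its target
    # interval by recursing on the flanking segments.  Hits are therefore
    # non-overlapping in the target.
    if depth > 64:
        return
    res = _local_once(query, target, aligner)
    if res is None:
        return
    score, ga, gb, qs, qe, ts, te = res
    if score < min_score:
        return
    hits.append((score, ga, gb, qs, qe, offset + ts, offset + te))
    _iter_local(query, target[:ts], offset, aligner, min_score, hits, depth + 1)
    _iter_local(query, target[te:], offset + te, aligner, min_score, hits, depth + 1)


def sw_align(
    query: str,
    target: str,
    scheme: ScoringScheme | None = None,
    min_score: float = 1.0,
    both_strands: bool = False,
) -> list[PairwiseAlignment]:
    """All non-overlapping local alignments with score >= min_score.

    Coordinates are always reported on the forward strand of ``target``;
    reverse-strand hits (when ``both_strands``) carry strand '-'.
    Hits are sorted by descending score, then target start.
    """
    scheme = scheme or ScoringScheme.dna_default()
    if min_score <= 0:
        raise ParameterError("min_score must be > 0")
    if both_strands and scheme.alphabet != "nucleotide":
        raise ParameterError("both_strands applies to nucleotide alignments only")
    q = scheme.check_sequence(query)
    t = scheme.check_sequence(target)
    aligner = scheme.make_aligner("local")

    raw: list[tuple] = []
    _iter_local(q, t, 0, aligner, min_score, raw)
    out: list[PairwiseAlignment] = []
    for score, ga, gb, qs, qe, ts, te in raw:
        out.append(
            PairwiseAlignment(
                aligned_a=ga, aligned_b=gb, score=score,
                coords=(qs, qe, ts, te), strand="+",
            )
        )
    if both_strands:
        rc = revcomp(t)
        raw_rc: list[tuple] = []
        _iter_local(q, rc, 0, aligner, min_score, raw_rc)
        n = len(t)
        for score, ga, gb, qs, qe, ts, te in raw_rc:
            out.append(
                PairwiseAlignment(
                    aligned_a=ga, aligned_b=gb, score=score,
                    coords=(qs, qe, n - te, n - ts), strand="-",
                )
            )
    out.sort(key=lambda h: (-h.score, h.coords[2], h.strand))
    return out
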