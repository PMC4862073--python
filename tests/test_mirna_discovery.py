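import numpy as np
import pytest

from hoxatlas.alignment import revcomp
from hoxatlas.annotation_io import bind_hox_labels
from hoxatlas.errors import HoxatlasError, LocationError, ParameterError
from hoxatlas.mirna_discovery import (
    MirnaCandidate,
    MirnaScreenParams,
    assign_position,
    resolve_duplicates,
    run_mirna_pipeline,
    screen_homologs,
    stemloop_filter,
)
from hoxatlas.model import (
    GeneModel,
    GenomeAnnotation,
    Scaffold,
    TranscriptModel,
)
from hoxatlas.rna import fold_hairpin
from hoxatlas.synthetic_data import (
    ClusterSpec,
    generate_genome,
    plant_mirna_hairpin,
)

from oracles import dinucleotide_shuffle

BASES = np.array(list("ACGT"))


def bare_genome(seq, scaffold_id="s1"):
    return GenomeAnnotation(
        scaffolds={scaffold_id: Scaffold(scaffold_id, len(seq), seq)}
    )


def random_dna(rng, n):
    return "".join(BASES[rng.integers(0, 4, n)])


class TestScreenParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"min_alignment_len": 0},
            {"min_identity": 0},
            {"min_identity": 101},
            {"mfe_threshold": 1.0},
            {"flank_bp": -1},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            MirnaScreenParams(**kwargs)

    def test_no_sequence_loaded_raises(self):
        ann = GenomeAnnotation(scaffolds={"s1": Scaffold("s1", 100)})
        with pytest.raises(HoxatlasError):
            screen_homologs(ann, {"q": "ACGUACGUACGUACGUACGUACGU"})


class TestScreenThresholds:
    def test_random_genome_without_homolog_yields_nothing(self, templates):
        queries = {n: t.sequence for n, t in templates.items()}
        matures = {n: t.mature for n, t in templates.items()}
        # at small scale the alignment screen itself stays empty under the null
        rng = np.random.default_rng(0)
        assert screen_homologs(bare_genome(random_dna(rng, 5_000)), queries) == []
        # at genome scale chance 20-nt/80% matches exist (the screen has no
        # E-value), but none survives the hairpin + mature-on-stem filter
        rng = np.random.default_rng(0)
        ann = bare_genome(random_dna(rng, 30_000))
        assert run_mirna_pipeline(ann, queries, matures) == []

    def test_planted_exact_copy_found_with_full_identity(self, templates):
        rng = np.random.default_rng(1)
        t = templates["mir-10-like"]
        bg = random_dna(rng, 10_000)
        dna = t.sequence.replace("U", "T")
        ann = bare_genome(bg[:4_000] + dna + bg[4_000:])
        hits = screen_homologs(ann, {"mir-10-like": t.sequence})
        (hit,) = [h for h in hits if h.alignment.percent_identity == 100.0]
        assert hit.strand == "+"
        assert hit.start <= 4_000 < 4_000 + len(dna) <= hit.end  # flank included

    def test_nineteen_nt_exact_hit_rejected_by_length(self):
        rng = np.random.default_rng(2)
        query = random_dna(rng, 19)
        bg = random_dna(rng, 5_000)
        ann = bare_genome(bg[:2_000] + query + bg[2_000:])
        assert screen_homologs(ann, {"q19": query}) == []

    def test_exact_eighty_percent_twenty_nt_accepted(self):
        # inclusive boundary: 20 aligned columns at exactly 80% identity
        rng = np.random.default_rng(3)
        query = random_dna(rng, 20)
        planted = list(query)
        for i in (3, 8, 12, 16):
            planted[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[planted[i]]
        bg = random_dna(rng, 5_000)
        ann = bare_genome(bg[:2_500] + "".join(planted) + bg[2_500:])
        hits = screen_homologs(ann, {"q20": query})
        assert any(
            h.alignment.n_columns == 20 and h.alignment.percent_identity == 80.0
            for h in hits
        )

    def test_just_below_eighty_percent_rejected(self):
        # 500 columns, 101 evenly spread mismatches: 79.8% identity
        rng = np.random.default_rng(4)
        query = random_dna(rng, 500)
        planted = list(query)
        positions = [2 + round(i * 493 / 100) for i in range(101)]
        assert len(set(positions)) == 101
        for i in positions:
            planted[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[planted[i]]
        bg = random_dna(rng, 4_000)
        ann = bare_genome(bg[:1_500] + "".join(planted) + bg[1_500:])
        hits = screen_homologs(ann, {"q500": query})
        assert not any(h.start < 2_000 and h.end > 1_500 for h in hits)

    def test_monotonicity_raising_thresholds_never_adds(self, templates):
        rng = np.random.default_rng(5)
        t = templates["mir-993-like"]
        bg = random_dna(rng, 20_000)
        dna = t.sequence.replace("U", "T")
        ann = bare_genome(bg[:7_000] + dna + bg[7_000:])
        queries = {t.name: t.sequence}
        loose = screen_homologs(ann, queries, MirnaScreenParams())
        for params in (
            MirnaScreenParams(min_identity=95.0),
            MirnaScreenParams(min_alignment_len=40),
        ):
            strict = screen_homologs(ann, queries, params)
            assert {c.locus for c in strict} <= {c.locus for c in loose}


class TestStemloopFilter:
    def _candidate(self, templates, name="mir-10-like", divergence=0.0, seed=0):
        t = templates[name]
        spec = ClusterSpec(
            gap_law=("loguniform", 2_000, 4_000), seed=seed, genome_size=100_000
        )
        genome = generate_genome(spec)
        gene_ids = [l[0] for l in genome.labels]
        g0 = genome.annotation.genes[gene_ids[0]]
        g1 = genome.annotation.genes[gene_ids[1]]
        pos = (g0.end + g1.start) // 2 - 30
        rec = plant_mirna_hairpin(genome, "scaffold_A", pos, t, divergence, seed=seed)
        hits = screen_homologs(genome.annotation, {t.name: t.sequence})
        # a strong hairpin is quasi-palindromic, so the screen may also hit
        # the minus strand of the same locus; take the best-scoring hit
        overl = [h for h in hits if h.start < rec.end and h.end > rec.start]
        cand = max(overl, key=lambda h: h.alignment.score)
        return cand, t

    def test_planted_canonical_hairpin_passes(self, templates):
        cand, t = self._candidate(templates)
        ok, diag = stemloop_filter(cand, t.mature)
        assert ok
        assert diag["mature_arm"] == "5p"
        assert diag["mature_paired_fraction"] >= 0.60
        assert cand.passes_filters

    def test_mfe_threshold_is_inclusive(self, templates):
        cand, t = self._candidate(templates)
        stemloop_filter(cand, t.mature)
        mfe = cand.fold.mfe
        ok_eq, _ = stemloop_filter(
            cand, t.mature, MirnaScreenParams(mfe_threshold=mfe)
        )
        assert ok_eq  # <= comparison: equality passes
        ok_above, diag = stemloop_filter(
            cand, t.mature, MirnaScreenParams(mfe_threshold=mfe - 0.01)
        )
        assert not ok_above
        assert not diag["mfe_ok"]

    def test_dinucleotide_shuffles_fail(self, templates):
        t = templates["mir-iab-4-like"]
        rng = np.random.default_rng(2016)
        fails = 0
        for _ in range(20):
            sh = dinucleotide_shuffle(t.sequence, rng)
            fold = fold_hairpin(sh)
            if fold.mfe > -20.0 or fold.arms is None:
                fails += 1
        assert fails >= 19  # >= 95% of shuffles

    def test_absent_mature_is_location_error(self, templates):
        cand, t = self._candidate(templates)
        with pytest.raises(LocationError):
            stemloop_filter(cand, "GGGGGGGGGGGGGGGGGGGGGG")


class TestAssignPosition:
    def _genome_with_cluster(self, seed=21):
        spec = ClusterSpec(
            gap_law=("loguniform", 2_000, 4_000), seed=seed, genome_size=80_000
        )
        genome = generate_genome(spec)
        cm = bind_hox_labels(genome.annotation, genome.labels, genome.scaffold_order)
        return genome, cm

    def _dummy_candidate(self, scaffold, start, end):
        from hoxatlas.alignment import PairwiseAlignment

        aln = PairwiseAlignment("A" * 20, "A" * 20, 40.0, (0, 20, start, end))
        return MirnaCandidate(
            scaffold_id=scaffold, start=start, end=end, strand="+",
            source_query="q", alignment=aln,
        )

    def test_non_hox_scaffold(self):
        genome, cm = self._genome_with_cluster()
        c = self._dummy_candidate("scaffold_bg", 100, 170)
        assert assign_position(c, cm, genome.annotation) == "non_hox_scaffold"

    def test_between_flanking_classes(self):
        genome, cm = self._genome_with_cluster()
        genes = {e.hox_class: genome.annotation.genes[e.gene_id] for e in cm.entries}
        mid = (genes["Dfd"].end + genes["Scr"].start) // 2
        c = self._dummy_candidate("scaffold_A", mid - 35, mid + 35)
        assert assign_position(c, cm, genome.annotation) == "between(Dfd,Scr)"

    def test_beyond_three_prime_end_is_downstream_of_lab(self):
        genome, cm = self._genome_with_cluster()
        lab = genome.annotation.genes[cm.entries[0].gene_id]
        c = self._dummy_candidate("scaffold_A", lab.start - 300, lab.start - 230)
        assert assign_position(c, cm, genome.annotation) == "downstream(lab)"

    def test_beyond_five_prime_end_is_upstream_of_abdb(self):
        genome, cm = self._genome_with_cluster()
        abdb = genome.annotation.genes[cm.entries[-1].gene_id]
        c = self._dummy_candidate("scaffold_A", abdb.end + 200, abdb.end + 270)
        assert assign_position(c, cm, genome.annotation) == "upstream(Abd-B)"


class TestResolveDuplicates:
    def _hit(self, start, end, query="mir-993-like", score=50.0):
        from hoxatlas.alignment import PairwiseAlignment

        aln = PairwiseAlignment("A" * 25, "A" * 25, score, (0, 25, start, end))
        return MirnaCandidate(
            scaffold_id="s1", start=start, end=end, strand="+",
            source_query=query, alignment=aln,
        )

    def test_single_hit_single_copy(self):
        (locus,) = resolve_duplicates([self._hit(100, 200)])
        assert (locus.copies, locus.start, locus.end) == (1, 100, 200)

    def test_tandem_copies_400bp_apart(self):
        (locus,) = resolve_duplicates([self._hit(100, 200), self._hit(600, 700)])
        assert locus.copies == 2
        assert (locus.start, locus.end) == (100, 700)

    def test_overlapping_hits_merge_to_one_copy(self):
        (locus,) = resolve_duplicates([self._hit(100, 200), self._hit(110, 210)])
        assert locus.copies == 1
        assert (locus.start, locus.end) == (100, 210)

    def test_distant_hits_stay_separate_loci(self):
        loci = resolve_duplicates([self._hit(100, 200), self._hit(5_000, 5_100)])
        assert [l.copies for l in loci] == [1, 1]

    def test_different_queries_never_merge(self):
        loci = resolve_duplicates(
            [self._hit(100, 200), self._hit(150, 250, query="mir-10-like")]
        )
        assert len(loci) == 2


class TestStrandCoherence:
    def _flip(self, ann):
        flipped = GenomeAnnotation()
        for s in ann.scaffolds.values():
            flipped.scaffolds[s.id] = Scaffold(
                s.id, s.length, revcomp(s.sequence) if s.sequence else None
            )
        for g in ann.genes.values():
            L = ann.scaffolds[g.scaffold_id].length

            def m(iv):
                return (L - iv[1], L - iv[0])

            txs = [
                TranscriptModel(
                    t.transcript_id,
                    sorted(m(e) for e in t.exons),
                    sorted(m(c) for c in t.cds),
                    sorted(m(u) for u in t.utr5),
                    sorted(m(u) for u in t.utr3),
                )
                for t in g.transcripts
            ]
            flipped.add_gene(
                GeneModel(
                    g.gene_id, g.scaffold_id, L - g.end, L - g.start,
                    "-" if g.strand == "+" else "+", txs, g.biotype,
                )
            )
        return flipped

    def test_screen_and_position_survive_reverse_complement(self, templates):
        t = templates["mir-10-like"]
        spec = ClusterSpec(
            gap_law=("loguniform", 2_000, 4_000), seed=31, genome_size=100_000
        )
        genome = generate_genome(spec)
        cm = bind_hox_labels(genome.annotation, genome.labels, genome.scaffold_order)
        genes = {e.hox_class: genome.annotation.genes[e.gene_id] for e in cm.entries}
        pos = (genes["Dfd"].end + genes["Scr"].start) // 2 - 30
        rec = plant_mirna_hairpin(genome, "scaffold_A", pos, t, 0.0, seed=1)
        L = genome.annotation.scaffolds["scaffold_A"].length

        def planted(hits, lo, hi):
            overl = [h for h in hits if h.start < hi and h.end > lo]
            best = max(h.alignment.score for h in overl)
            return [h for h in overl if h.alignment.score == best]

        fwd = planted(
            screen_homologs(genome.annotation, {t.name: t.sequence}),
            rec.start, rec.end,
        )
        flipped_ann = self._flip(genome.annotation)
        rev = planted(
            screen_homologs(flipped_ann, {t.name: t.sequence}),
            L - rec.end, L - rec.start,
        )
        assert len(fwd) == len(rev) == 1
        assert (rev[0].start, rev[0].end) == (L - fwd[0].end, L - fwd[0].start)
        assert {fwd[0].strand, rev[0].strand} == {"+", "-"}

        cm_flip = bind_hox_labels(flipped_ann, genome.labels, genome.scaffold_order)
        label_fwd = assign_position(fwd[0], cm, genome.annotation)
        label_rev = assign_position(rev[0], cm_flip, flipped_ann)
        assert label_fwd == label_rev == "between(Dfd,Scr)"


class TestPipeline:
    def test_planted_recovery_with_positions(self, templates):
        spec = ClusterSpec(
            gap_law=("loguniform", 3_000, 6_000), seed=41, genome_size=90_000
        )
        genome = generate_genome(spec)
        cm = bind_hox_labels(genome.annotation, genome.labels, genome.scaffold_order)
        genes = {e.hox_class: genome.annotation.genes[e.gene_id] for e in cm.entries}

        def midgap(a, b):
            return (genes[a].end + genes[b].start) // 2 - 30

        plant_mirna_hairpin(
            genome, "scaffold_A", midgap("pb", "Hox3"),
            templates["mir-993-like"], 0.05, seed=1,
        )
        plant_mirna_hairpin(
            genome, "scaffold_A", midgap("abd-A", "Abd-B"),
            templates["mir-iab-4-like"], 0.08, seed=2, strand="-",
        )
        queries = {n: t.sequence for n, t in templates.items()}
        matures = {n: t.mature for n, t in templates.items()}
        loci = run_mirna_pipeline(genome.annotation, queries, matures, cm)
        by_query = {l.source_query: l for l in loci}
        assert set(by_query) == {"mir-993-like", "mir-iab-4-like"}
        assert by_query["mir-iab-4-like"].strand == "-"
        assert by_query["mir-993-like"].candidates[0].position_label == (
            "between(pb,Hox3)"
        )
        assert by_query["mir-iab-4-like"].candidates[0].position_label == (
            "between(abd-A,Abd-B)"
        )
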