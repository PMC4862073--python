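import numpy as np
import pytest

from hoxatlas import cluster_metrics as cmx
from hoxatlas.annotation_io import bind_hox_labels
from hoxatlas.errors import HoxatlasError, ParameterError
from hoxatlas.model import HOX_CLASSES
from hoxatlas.synthetic_data import ClusterSpec, Duplication, generate_genome

from conftest import make_toy_annotation
from oracles import brute_cluster_metrics


def label_rows(ann, classes, species="toy"):
    genes = sorted(ann.genes.values(), key=lambda g: g.start)
    return [(g.gene_id, c, species) for g, c in zip(genes, classes)]


class TestSpanAndGaps:
    def test_single_gene_span_is_gene_length(self):
        ann = make_toy_annotation([(1_000, 5_000)])
        cm = bind_hox_labels(ann, label_rows(ann, ["lab"]))
        span, blocks = cmx.cluster_span(cm, ann)
        assert span == 4_000
        assert blocks == {"s1": 4_000}

    def test_hand_toy_gaps(self):
        ann = make_toy_annotation([(0, 10), (20, 30), (35, 40)], scaffold_len=100)
        cm = bind_hox_labels(ann, label_rows(ann, ["lab", "pb", "Dfd"]))
        gaps = cmx.intergenic_gaps(cm, ann)
        assert [(p, g) for p, g, _ in gaps] == [(("lab", "pb"), 10), (("pb", "Dfd"), 5)]

    def test_abutting_genes_gap_zero_and_overlap_clamped(self):
        ann = make_toy_annotation([(0, 10), (10, 30), (25, 40)], scaffold_len=100)
        cm = bind_hox_labels(ann, label_rows(ann, ["lab", "pb", "Dfd"]))
        gaps = cmx.intergenic_gaps(cm, ann)
        assert gaps[0] == (("lab", "pb"), 0, False)
        assert gaps[1] == (("pb", "Dfd"), 0, True)  # overlap flagged

    def test_empty_cluster_raises(self):
        ann = make_toy_annotation([(0, 10)])
        from hoxatlas.model import HoxClusterMap

        with pytest.raises(HoxatlasError):
            cmx.cluster_span(HoxClusterMap(species="x"), ann)


class TestGenomeFraction:
    def test_zero_span(self):
        assert cmx.genome_fraction(0, 1_000_000) == 0.0

    def test_identity_case(self):
        assert cmx.genome_fraction(5_000, 5_000) == 1.0

    def test_large_genome_percentage_rounds_to_two_decimals(self):
        # 3.48 Mb cluster in a 1.7 Gb assembly occupies 0.20% of the genome
        frac = cmx.genome_fraction(3_480_000, 1_700_000_000)
        assert round(100 * frac, 2) == 0.20

    def test_span_exceeding_assembly_raises(self):
        with pytest.raises(ParameterError):
            cmx.genome_fraction(10, 5)


class TestInterveningGenes:
    def test_empty_gap_counts_zero(self):
        ann = make_toy_annotation([(0, 10), (20, 30)], scaffold_len=100)
        cm = bind_hox_labels(ann, label_rows(ann, ["lab", "pb"]))
        counts = cmx.intervening_gene_counts(cm, ann)
        assert counts == [(("lab", "pb"), 0, [])]

    def test_planted_counts_recovered_exactly(self):
        spec = ClusterSpec(
            gap_law=("loguniform", 3_000, 8_000),
            intervening_genes_per_gap=(0, 1, 2, 3, 0, 2, 1, 0, 4),
            seed=9,
            with_sequence=False,
        )
        g = generate_genome(spec)
        cm = bind_hox_labels(g.annotation, g.labels, g.scaffold_order)
        counts = cmx.intervening_gene_counts(cm, g.annotation)
        assert [(p, c) for p, c, _ in counts] == g.truth.intervening_counts

    def test_partially_overlapping_gene_flagged_not_counted(self):
        ann = make_toy_annotation(
            [(0, 100), (90, 150), (200, 300)],
            scaffold_len=1_000,
        )
        # g1 overlaps the lab unit, dangles into the gap
        cm = bind_hox_labels(
            ann, [("g0", "lab", "t"), ("g2", "pb", "t")]
        )
        counts = cmx.intervening_gene_counts(cm, ann)
        (pair, n, partial), = counts
        assert n == 0
        assert partial == ["g1"]


class TestInterveningSpace:
    def test_back_to_back_cluster_zero_space(self):
        spec = ClusterSpec(gaps=(0,) * 9, seed=1, with_sequence=False)
        g = generate_genome(spec)
        cm = bind_hox_labels(g.annotation, g.labels, g.scaffold_order)
        space, frac = cmx.intervening_space(cm, g.annotation)
        assert space == 0
        assert frac == 0.0

    def test_additivity_on_single_scaffold(self):
        spec = ClusterSpec(
            gap_law=("loguniform", 2_000, 9_000), seed=12, with_sequence=False
        )
        g = generate_genome(spec)
        cm = bind_hox_labels(g.annotation, g.labels, g.scaffold_order)
        span, _ = cmx.cluster_span(cm, g.annotation)
        space, _ = cmx.intervening_space(cm, g.annotation)
        hox_bp = sum(
            g.annotation.genes[e.gene_id].length for e in cm.entries
        )
        assert space + hox_bp == span


class TestSplits:
    def test_tight_single_scaffold_not_split(self):
        spec = ClusterSpec(
            gap_law=("loguniform", 1_000, 5_000), seed=7, with_sequence=False
        )
        g = generate_genome(spec)
        cm = bind_hox_labels(g.annotation, g.labels, g.scaffold_order)
        report = cmx.detect_splits(cm, g.annotation)
        assert not report.is_split
        assert report.break_pairs == []

    def test_planted_two_scaffold_split_min_gap_exact(self):
        a, b = 123_456, 78_901
        spec = ClusterSpec(
            split_after=("Scr", a, b),
            gap_law=("loguniform", 1_000, 5_000),
            seed=8,
            with_sequence=False,
        )
        g = generate_genome(spec)
        cm = bind_hox_labels(g.annotation, g.labels, g.scaffold_order)
        report = cmx.detect_splits(cm, g.annotation)
        assert report.is_split
        (up, down, gap, same), = report.break_pairs
        assert (up, down, gap, same) == ("Scr", "ftz", a + b, False)

    def test_intra_scaffold_gap_above_threshold(self):
        ann = make_toy_annotation(
            [(0, 10_000), (2_000_000, 2_010_000)], scaffold_len=3_000_000
        )
        cm = bind_hox_labels(ann, label_rows(ann, ["lab", "pb"]))
        report = cmx.detect_splits(cm, ann, threshold_bp=1_000_000)
        assert report.is_split
        assert report.break_pairs == [("lab", "pb", 1_990_000, True)]

    def test_nonpositive_threshold_rejected(self):
        ann = make_toy_annotation([(0, 10)])
        cm = bind_hox_labels(ann, label_rows(ann, ["lab"]))
        with pytest.raises(ParameterError):
            cmx.detect_splits(cm, ann, threshold_bp=0)


class TestOrientation:
    def test_uniform_strand_one_run(self):
        ann = make_toy_annotation([(0, 10), (20, 30), (40, 50)])
        cm = bind_hox_labels(ann, label_rows(ann, ["lab", "pb", "Dfd"]))
        prof = cmx.orientation_profile(cm, ann)
        assert prof.reference_strand == "+"
        assert prof.inverted_genes == []
        assert prof.n_orientation_runs == 1

    def test_planted_contiguous_block_inversion(self):
        spec = ClusterSpec(
            inversions=("Scr", "ftz", "Antp"),
            gap_law=("loguniform", 1_000, 4_000),
            seed=13,
            with_sequence=False,
        )
        g = generate_genome(spec)
        cm = bind_hox_labels(g.annotation, g.labels, g.scaffold_order)
        prof = cmx.orientation_profile(cm, g.annotation)
        assert sorted(prof.inverted_genes) == sorted(g.truth.inverted_gene_ids)
        assert len(prof.inverted_genes) == 3
        assert prof.n_orientation_runs == 3

    def test_tie_breaks_to_lab_strand(self):
        ann = make_toy_annotation(
            [(0, 10), (20, 30), (40, 50), (60, 70)],
            strands=["-", "-", "+", "+"],
        )
        cm = bind_hox_labels(
            ann, label_rows(ann, ["lab", "pb", "Dfd", "Scr"])
        )
        prof = cmx.orientation_profile(cm, ann)
        assert prof.reference_strand == "-"
        assert sorted(prof.inverted_genes) == ["g2", "g3"]


class TestTandemDuplicates:
    def test_no_repeats_empty(self):
        ann = make_toy_annotation([(0, 10), (20, 30)])
        cm = bind_hox_labels(ann, label_rows(ann, ["lab", "pb"]))
        assert cmx.detect_tandem_duplicates(cm) == []

    def test_tetranychus_style_double_tandems(self):
        spec = ClusterSpec(
            duplications=(Duplication("ftz"), Duplication("Antp")),
            losses=("Hox3", "abd-A"),
            gap_law=("loguniform", 1_000, 4_000),
            seed=14,
            with_sequence=False,
        )
        g = generate_genome(spec)
        cm = bind_hox_labels(g.annotation, g.labels, g.scaffold_order)
        dups = cmx.detect_tandem_duplicates(cm)
        assert {(d.hox_class, d.tandem, len(d.gene_ids)) for d in dups} == {
            ("ftz", True, 2),
            ("Antp", True, 2),
        }

    def test_distal_duplicate_reported_but_not_tandem(self):
        spec = ClusterSpec(
            duplications=(Duplication("Dfd", tandem=False),),
            gap_law=("loguniform", 1_000, 4_000),
            seed=15,
            with_sequence=False,
        )
        g = generate_genome(spec)
        cm = bind_hox_labels(g.annotation, g.labels, g.scaffold_order)
        (d,) = cmx.detect_tandem_duplicates(cm)
        assert d.hox_class == "Dfd"
        assert not d.tandem


class TestInvariances:
    def _random_toy(self, rng, shift=0, flip=False):
        n = 20
        starts = np.cumsum(rng.integers(50, 500, size=n))
        genes = [(int(s) + shift, int(s) + shift + int(rng.integers(20, 200)))
                 for s in starts]
        scaffold_len = genes[-1][1] + 1_000 + shift
        strands = [rng.choice(["+", "-"], p=[0.8, 0.2]) for _ in range(n)]
        if flip:
            genes = [(scaffold_len - e, scaffold_len - s) for s, e in genes][::-1]
            strands = [{"+": "-", "-": "+"}[x] for x in strands][::-1]
        return make_toy_annotation(
            genes, scaffold_len=scaffold_len, strands=strands
        )

    def test_translation_invariance(self, rng):
        classes = list(HOX_CLASSES) * 2
        base = self._random_toy(np.random.default_rng(1))
        shifted = self._random_toy(np.random.default_rng(1), shift=777)
        cm_b = bind_hox_labels(base, label_rows(base, classes))
        cm_s = bind_hox_labels(shifted, label_rows(shifted, classes))
        span_b, _ = cmx.cluster_span(cm_b, base)
        span_s, _ = cmx.cluster_span(cm_s, shifted)
        assert span_b == span_s
        assert [
            (p, g) for p, g, _ in cmx.intergenic_gaps(cm_b, base)
        ] == [(p, g) for p, g, _ in cmx.intergenic_gaps(cm_s, shifted)]
        assert cmx.intervening_space(cm_b, base) == cmx.intervening_space(
            cm_s, shifted
        )

    def test_strand_flip_invariance(self):
        classes = list(HOX_CLASSES) * 2
        base = self._random_toy(np.random.default_rng(2))
        flipped = self._random_toy(np.random.default_rng(2), flip=True)
        cm_b = bind_hox_labels(base, label_rows(base, classes))
        cm_f = bind_hox_labels(flipped, label_rows(flipped, classes))
        assert cmx.cluster_span(cm_b, base)[0] == cmx.cluster_span(cm_f, flipped)[0]
        gaps_b = sorted(g for _, g, _ in cmx.intergenic_gaps(cm_b, base))
        gaps_f = sorted(g for _, g, _ in cmx.intergenic_gaps(cm_f, flipped))
        assert gaps_b == gaps_f
        assert cmx.intervening_space(cm_b, base)[0] == cmx.intervening_space(
            cm_f, flipped
        )[0]
        # inverted set is strand-relative, so sizes match after the flip
        prof_b = cmx.orientation_profile(cm_b, base)
        prof_f = cmx.orientation_profile(cm_f, flipped)
        assert len(prof_b.inverted_genes) == len(prof_f.inverted_genes)
        assert prof_b.n_orientation_runs == prof_f.n_orientation_runs

    def test_brute_force_oracle_equivalence(self):
        classes = list(HOX_CLASSES) * 2
        for seed in range(5):
            ann = self._random_toy(np.random.default_rng(seed))
            cm = bind_hox_labels(ann, label_rows(ann, classes))
            oracle = brute_cluster_metrics(cm, ann)
            span, _ = cmx.cluster_span(cm, ann)
            assert span == oracle["span"]
            assert cmx.intervening_space(cm, ann)[0] == oracle["intervening_space"]
            assert [
                (p, g) for p, g, _ in cmx.intergenic_gaps(cm, ann)
            ] == oracle["gaps"]
            assert [
                (p, c) for p, c, _ in cmx.intervening_gene_counts(cm, ann)
            ] == oracle["counts"]


def test_round_mb_half_up():
    assert cmx.round_mb(340_000) == 0.34
    assert cmx.round_mb(3_480_000) == 3.48
    assert cmx.round_mb(2_945_000) == 2.95  # half rounds up
    assert cmx.round_mb(2_944_999) == 2.94
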