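import numpy as np
import pytest

from heatmir._seq import revcomp
from heatmir.config import LIBRARIES, PipelineConfig
from heatmir.genome import GenomeIndex
from heatmir.identify import (
    ArmRead,
    HairpinCandidate,
    _duplex_geometry,
    cluster_families,
    evaluate_hairpin,
    excise_precursor,
    homology_mismatches,
    match_known,
    terminal_shift_match,
)
from heatmir.preprocess import SequenceTag
from heatmir.synthetic import design_hairpin

MATURE = "TGGAGCTCCCTTCATTCCAAT"


class TestKnownMatching:
    @pytest.mark.parametrize(
        "tag,expected",
        [
            (MATURE, True),                      # identity
            (MATURE[:-1], True),                 # 3' trim of 1
            (MATURE[2:], True),                  # 5' trim of 2
            (MATURE[3:], False),                 # 5' shift of 3 exceeds 2
            (MATURE[1:-2], True),                # trims at both ends
            (MATURE[:10] + "A" + MATURE[11:], False),  # internal mismatch
            ("AC" + MATURE[:-2], True),   # 2-nt 5' extension + 3' trim
            ("ACT" + MATURE[:-3], False),  # 3-nt shift exceeds tolerance
        ],
    )
    def test_terminal_shift_rule(self, tag, expected):
        assert terminal_shift_match(tag, MATURE, 2) is expected

    def test_counts_summed_over_isomirs(self, config):
        catalog = [("gma-miRx", "miRx", MATURE)]
        tags = [
            SequenceTag(MATURE, {"NF1NT": 5}),
            SequenceTag(MATURE[:-1], {"NF1NT": 2, "NF1HT": 1}),
        ]
        records, assigned = match_known(tags, catalog, config)
        assert len(records) == 1
        assert records[0].counts == {"NF1NT": 7, "NF1HT": 1}
        assert assigned == {MATURE, MATURE[:-1]}

    def test_ambiguous_tag_assigned_to_both(self, config):
        catalog = [
            ("gma-miRa", "miRa", MATURE),
            ("gma-miRb", "miRb", MATURE[:-1]),  # 1-nt variant entry
        ]
        tags = [SequenceTag(MATURE, {"NF1NT": 4})]
        records, _ = match_known(tags, catalog, config)
        assert len(records) == 2
        assert all(r.ambiguous for r in records)

    def test_empty_catalog_rejected(self, config):
        with pytest.raises(ValueError):
            match_known([], [], config)


class TestHomology:
    def test_equal_length_hamming(self):
        a = "ACGTACGTACGTACGTACGTA"
        b = "ACGTACGTACGTACGTACGTT"
        assert homology_mismatches(a, b) == 1

    def test_length_difference_beyond_two_is_incomparable(self):
        assert homology_mismatches("ACGTACGT", "ACGTACGTACGT") is None

    def test_best_offset_chosen(self):
        short = "ACGTACGTACGTACGTACG"
        long_ = "GG" + short
        assert homology_mismatches(short, long_) == 0


@pytest.fixture(scope="module")
def designs():
    rng = np.random.default_rng(42)
    config = PipelineConfig()
    return {
        violation: design_hairpin(rng, violation, config)
        for violation in ("none", "c1", "c2", "c3", "c3b", "mfe", "mfei")
    }


class TestHairpinEvaluation:
    """The five criteria, each probed through a designed fixture whose
    single structural defect must flip exactly one verdict."""

    def _evaluate(self, design, counts5=600, counts3=200):
        core, a5, m5, a3, m3 = design
        return evaluate_hairpin(
            core,
            ("chr1", 0, len(core), "+"),
            [
                (m5, a5, {lib: counts5 for lib in LIBRARIES}),
                (m3, a3, {lib: counts3 for lib in LIBRARIES}),
            ],
            PipelineConfig(),
        )

    def test_compliant_hairpin_passes_all(self, designs):
        cand = self._evaluate(designs["none"])
        assert cand.passed
        assert cand.duplex.matched_pairs > 16
        assert cand.duplex.overhangs == (2, 2)
        assert cand.mfe < 0

    @pytest.mark.parametrize(
        "violation,criterion",
        [("c1", "c1"), ("c2", "c2"), ("c3", "c3"), ("c3b", "c3"),
         ("mfe", "mfe"), ("mfei", "mfei")],
    )
    def test_single_defect_flips_single_criterion(
        self, designs, violation, criterion
    ):
        cand = self._evaluate(designs[violation])
        verdicts = dict(cand.criterion_verdicts)
        assert verdicts.pop(criterion) is False
        assert all(verdicts.values())

    def test_sixteen_matched_pairs_fail_criterion_one(self, designs):
        # 'exceeding 16' is strict: a duplex of exactly 16 pairs fails
        cand = self._evaluate(designs["c1"])
        assert cand.duplex.matched_pairs == 16
        assert cand.criterion_verdicts["c1"] is False

    def test_low_support_fails_criterion_four_only(self, designs):
        cand = self._evaluate(designs["none"], counts5=9, counts3=3)
        assert cand.criterion_verdicts["c4"] is False
        assert all(
            v for c, v in cand.criterion_verdicts.items() if c != "c4"
        )

    def test_support_threshold_met_in_one_sample_is_enough(self, designs):
        core, a5, m5, a3, m3 = designs["none"]
        counts = {lib: 1 for lib in LIBRARIES}
        counts["NF1HT"] = 10
        cand = evaluate_hairpin(
            core, ("chr1", 0, len(core), "+"),
            [(m5, a5, counts), (m3, a3, {lib: 1 for lib in LIBRARIES})],
            PipelineConfig(),
        )
        assert cand.criterion_verdicts["c4"] is True

    def test_read_outside_window_raises(self, designs):
        core, a5, m5, a3, m3 = designs["none"]
        with pytest.raises(ValueError, match="not within"):
            evaluate_hairpin(
                core, ("chr1", 0, len(core), "+"),
                [(m5, len(core) - 3, {"NF1NT": 5})],
                PipelineConfig(),
            )

    def test_mfei_arithmetic(self):
        # length 100, MFE -45, GC 0.5: MFE/nt = -0.45, MFEI = 45/50 = 0.90
        cand = HairpinCandidate(
            precursor_sequence=("AT" * 25) + ("GC" * 25),
            locus=("chr1", 0, 100, "+"),
            structure="." * 100,
            mfe=-45.0,
        )
        assert cand.mfe_per_nt == pytest.approx(-0.45)
        assert cand.gc == pytest.approx(0.5)
        assert cand.mfei == pytest.approx(0.90)

    def test_mfei_decreases_with_gc_at_fixed_energy(self):
        # MFEI monotonicity: same length and MFE, more GC => lower MFEI
        seqs = ["AT" * 50, ("AT" * 30) + ("GC" * 20), "GC" * 50]
        mfeis = []
        for seq in seqs[1:]:
            cand = HairpinCandidate(
                precursor_sequence=seq, locus=("c", 0, 100, "+"),
                structure="." * 100, mfe=-40.0,
            )
            mfeis.append(cand.mfei)
        assert mfeis == sorted(mfeis, reverse=True)


class TestDuplexGeometry:
    def _pt_perfect(self, n):
        return [n - 1 - i for i in range(n)]

    def test_two_single_bulges_counted_separately(self):
        # hand-built pairing with two 1-nt gaps on the 3p side only
        pt = [-1] * 60
        j = 53
        for i in range(5, 26):
            if i in (12, 19):  # 3p-side bulges: j skips one extra
                j -= 1
            pt[i] = j
            pt[j] = i
            j -= 1
        arm5 = ArmRead("A" * 21, 5, {"L": 10})
        arm3 = ArmRead("A" * 23, 31, {"L": 5})
        info = _duplex_geometry(pt, arm5, arm3)
        assert info.asymmetric_bulges == [1, 1]

    def test_symmetric_internal_loop_is_not_a_bulge(self):
        pt = [-1] * 55
        j = 50
        for i in range(5, 26):
            if i == 15:  # both strands skip one base: symmetric loop
                pt[i] = -1
                j -= 1
                continue
            pt[i] = j
            pt[j] = i
            j -= 1
        arm5 = ArmRead("A" * 21, 5, {"L": 10})
        arm3 = ArmRead("A" * 21, 30, {"L": 5})
        info = _duplex_geometry(pt, arm5, arm3)
        assert info.asymmetric_bulges == []


class TestExcision:
    @pytest.fixture()
    def index(self, rng):
        from heatmir._seq import random_seq

        return GenomeIndex({"chr1": random_seq(rng, 1000, 0.5)})

    def test_windows_contain_the_tag(self, index, config):
        windows = excise_precursor(index, ("chr1", 500, "+"), 21, config)
        assert windows
        tag = index.fetch("chr1", 500, 521)
        for seq, (chrom, start, end, strand) in windows:
            assert start <= 500 and end >= 521
            assert tag in seq

    def test_contig_edge_windows_clipped(self, index, config):
        windows = excise_precursor(index, ("chr1", 2, "+"), 21, config)
        for seq, (chrom, start, end, strand) in windows:
            assert start >= 0
            assert len(seq) >= config.precursor_min_len

    def test_minus_strand_windows_reverse_complemented(self, index, config):
        plus = excise_precursor(index, ("chr1", 500, "+"), 21, config)
        minus = excise_precursor(index, ("chr1", 500, "-"), 21, config)
        minus_by_span = {
            (start, end): seq for seq, (_, start, end, _) in minus
        }
        shared = [
            (seq, minus_by_span[(start, end)])
            for seq, (_, start, end, _) in plus
            if (start, end) in minus_by_span
        ]
        assert shared
        for plus_seq, minus_seq in shared:
            assert minus_seq == revcomp(plus_seq)


class TestFamilies:
    def test_single_mismatch_joins_family(self):
        a = "ACGTACGTACGTACGTACGTA"
        b = a[:-1] + "C"
        labels = cluster_families([a, b], max_mismatches=2)
        assert labels[0] == labels[1]

    def test_distant_sequences_split(self):
        a = "ACGTACGTACGTACGTACGTA"
        b = "TTTTGGGGCCCCAAAATTTTG"
        labels = cluster_families([a, b], max_mismatches=2)
        assert labels[0] != labels[1]

    def test_single_linkage_is_transitive(self):
        a = "ACGTACGTACGTACGTACGTA"
        b = a[:-2] + "CC"   # 2 mm from a
        c = b[:1] + "T" + b[2:]  # 1 mm from b, 3 from a
        labels = cluster_families([a, b, c], max_mismatches=2)
        assert len(set(labels)) == 1
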