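import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dgepipe.fastq_filter import (
    FilterPolicy,
    ReadRecord,
    base_fractions,
    classify_read,
    filter_reads,
)
from dgepipe.synthetic import DEFAULT_ADAPTOR, FastqSpec, QualityModel, generate_fastq


def make_read(sequence, quality, identifier="r0"):
    return ReadRecord(identifier=identifier, sequence=sequence, quality=tuple(quality))


class TestBaseFractions:
    def test_n_counting(self):
        read = make_read("N" * 5 + "A" * 95, [40] * 100)
        n_frac, lq = base_fractions(read, FilterPolicy.transcriptome())
        assert n_frac == 0.05
        assert lq == 0.0

    def test_high_quality_read_has_zero_low_quality_fraction(self):
        read = make_read("ACGT" * 25, [40] * 100)
        for policy in (FilterPolicy.transcriptome(), FilterPolicy.profile()):
            assert base_fractions(read, policy)[1] == 0.0

    def test_91bp_read_with_19_low_quality_bases(self):
        """19/91 ~ 0.2088 exceeds the strict >0.20 assembly-stage rule."""
        read = make_read("A" * 91, [9] * 19 + [40] * 72)
        policy = FilterPolicy.transcriptome()
        n_frac, lq = base_fractions(read, policy)
        assert lq == pytest.approx(19 / 91)
        assert lq > policy.max_low_quality_fraction
        assert classify_read(read, policy) == "quality"

    def test_empty_read_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            base_fractions(make_read("", []), FilterPolicy.transcriptome())


class TestBoundaries:
    """Thresholds are strict: a read exactly at a limit is retained."""

    @pytest.mark.parametrize(
        "policy_name, n_at_limit, n_over",
        [("transcriptome", 5, 6), ("profile", 10, 11)],
    )
    def test_n_fraction_boundary(self, policy_name, n_at_limit, n_over):
        policy = getattr(FilterPolicy, policy_name)()
        at = make_read("N" * n_at_limit + "A" * (100 - n_at_limit), [40] * 100)
        over = make_read("N" * n_over + "A" * (100 - n_over), [40] * 100)
        assert classify_read(at, policy) == "clean"
        assert classify_read(over, policy) == "n"

    @pytest.mark.parametrize(
        "policy_name, qual, k_at_limit",
        [("transcriptome", 10, 20), ("profile", 5, 50)],
    )
    def test_low_quality_boundary(self, policy_name, qual, k_at_limit):
        policy = getattr(FilterPolicy, policy_name)()
        at = make_read("A" * 100, [qual] * k_at_limit + [40] * (100 - k_at_limit))
        over = make_read(
            "A" * 100, [qual] * (k_at_limit + 1) + [40] * (99 - k_at_limit)
        )
        assert classify_read(at, policy) == "clean"
        assert classify_read(over, policy) == "quality"

    def test_quality_just_above_threshold_does_not_count(self):
        policy = FilterPolicy.transcriptome()
        read = make_read("A" * 100, [11] * 100)
        assert classify_read(read, policy) == "clean"


class TestAdaptorRule:
    def test_adaptor_prefix_match_discards(self):
        policy = FilterPolicy.transcriptome(adaptor=DEFAULT_ADAPTOR)
        probe = DEFAULT_ADAPTOR[:10]
        read = make_read("A" * 30 + probe + "C" * 60, [40] * 100)
        assert classify_read(read, policy) == "adaptor"

    def test_partial_match_below_min_is_kept(self):
        policy = FilterPolicy.transcriptome(adaptor=DEFAULT_ADAPTOR)
        read = make_read(DEFAULT_ADAPTOR[:9] + "T" * 91, [40] * 100)
        assert classify_read(read, policy) == "clean"

    def test_rule_order_adaptor_before_n(self):
        policy = FilterPolicy.transcriptome(adaptor=DEFAULT_ADAPTOR)
        read = make_read(DEFAULT_ADAPTOR[:10] + "N" * 90, [2] * 100)
        assert classify_read(read, policy) == "adaptor"


class TestFilterReads:
    def test_clean_stream_fully_retained(self):
        spec = FastqSpec(n_reads=500, seed=3, quality=QualityModel(mean=40, sd=0))
        reads, labels = generate_fastq(spec)
        assert set(labels) == {"clean"}
        retained, report = filter_reads(
            reads, FilterPolicy.transcriptome(adaptor=DEFAULT_ADAPTOR)
        )
        assert report.retained == report.total_reads == 500
        assert report.discarded_adaptor == report.discarded_n == 0

    def test_full_contamination_all_discarded(self):
        spec = FastqSpec(n_reads=200, seed=5, contamination_rate=1.0)
        reads, labels = generate_fastq(spec)
        assert set(labels) == {"adaptor"}
        _, report = filter_reads(
            reads, FilterPolicy.transcriptome(adaptor=DEFAULT_ADAPTOR)
        )
        assert report.discarded_adaptor == 200

    def test_mixed_fixture_tallies_equal_labels(self):
        spec = FastqSpec(
            n_reads=2000,
            seed=11,
            n_fraction_per_read=0.04,
            contamination_rate=0.05,
            quality=QualityModel(low_read_rate=0.1, low_mean=4.0),
        )
        policy = FilterPolicy.transcriptome(adaptor=DEFAULT_ADAPTOR)
        reads, labels = generate_fastq(spec, policy)
        retained, report = filter_reads(reads, policy)
        assert report.discarded_adaptor == labels.count("adaptor")
        assert report.discarded_n == labels.count("n")
        assert report.discarded_quality == labels.count("quality")
        assert report.retained == labels.count("clean")

    def test_idempotence(self):
        spec = FastqSpec(
            n_reads=1000, seed=13, n_fraction_per_read=0.04,
            quality=QualityModel(low_read_rate=0.2, low_mean=4.0),
        )
        policy = FilterPolicy.profile(adaptor=DEFAULT_ADAPTOR)
        reads, _ = generate_fastq(spec, policy)
        retained, _ = filter_reads(reads, policy)
        again, report = filter_reads(retained, policy)
        assert report.retained == report.total_reads == len(retained)
        assert again == retained

    def test_monotonicity_relaxing_thresholds(self):
        spec = FastqSpec(
            n_reads=1000, seed=17, n_fraction_per_read=0.05,
            quality=QualityModel(low_read_rate=0.3, low_mean=8.0, sd=4.0),
        )
        reads, _ = generate_fastq(spec)
        strict = FilterPolicy.transcriptome()
        relaxed = FilterPolicy(
            max_n_fraction=0.10,
            low_quality_threshold=10,
            max_low_quality_fraction=0.5,
        )
        _, rep_strict = filter_reads(reads, strict)
        _, rep_relaxed = filter_reads(reads, relaxed)
        assert rep_relaxed.retained >= rep_strict.retained

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        seq=st.text(alphabet="ACGTN", min_size=1, max_size=150),
        data=st.data(),
    )
    def test_classification_is_exhaustive_and_consistent(self, seq, data):
        quals = data.draw(
            st.lists(st.integers(2, 40), min_size=len(seq), max_size=len(seq))
        )
        read = make_read(seq, quals)
        policy = FilterPolicy.profile(adaptor=DEFAULT_ADAPTOR)
        label = classify_read(read, policy)
        assert label in {"clean", "adaptor", "n", "quality"}
        retained, report = filter_reads([read], policy)
        assert (label == "clean") == (len(retained) == 1)

    def test_length_mismatch_aborts_with_identifier(self):
        with pytest.raises(ValueError, match="badread"):
            ReadRecord(identifier="badread", sequence="ACGT", quality=(40, 40))
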