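import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from consenstax.assignment import Composition, CompositionEntry
from consenstax.benchmark import (
    ConfusionCounts,
    ExpectedComposition,
    downsample_reads,
    downsample_seed,
    euclidean_distance,
    evaluate,
    fbeta,
    gpr,
    match_compositions,
    percent,
    pr_threshold_sweep,
    precision_recall,
    relative_error,
    splitting_level,
    staged_yields,
    yield_fraction,
)
from consenstax.fixtures import FixtureSpec, make_fastq


def comp(sample_id, props):
    return Composition(
        sample_id, {t: CompositionEntry(0, p) for t, p in props.items()}
    )


def expected(sample_id, props):
    return ExpectedComposition(sample_id, dict(props))


class TestMatchCompositions:
    def test_identical_compositions(self, tax):
        e = expected("s", {9913: 0.6, 9823: 0.4})
        o = comp("s", {9913: 0.6, 9823: 0.4})
        c = match_compositions(e, o, tax, "species")
        assert (c.tp, c.fp, c.fn) == (2, 0, 0)

    def test_missed_component_is_fn(self, tax):
        e = expected("s", {9823: 0.5, 9913: 0.5})
        o = comp("s", {9823: 1.0})
        c = match_compositions(e, o, tax, "genus")
        assert (c.tp, c.fp, c.fn) == (1, 0, 1)

    def test_extra_component_is_fp(self, tax):
        e = expected("s", {9823: 1.0})
        o = comp("s", {9823: 0.9, 9031: 0.1})
        c = match_compositions(e, o, tax, "genus")
        assert (c.tp, c.fp, c.fn) == (1, 1, 0)

    def test_genus_match_despite_wrong_species(self, tax):
        # observed Bos indicus vs expected Bos taurus: FP+FN at species,
        # TP at genus
        e = expected("s", {9913: 1.0})
        o = comp("s", {9915: 1.0})
        sp = match_compositions(e, o, tax, "species")
        ge = match_compositions(e, o, tax, "genus")
        assert (sp.tp, sp.fp, sp.fn) == (0, 1, 1)
        assert (ge.tp, ge.fp, ge.fn) == (1, 0, 0)

    def test_above_rank_observation_counts_fp(self, tax):
        # a family-level assignment cannot match at genus rank
        e = expected("s", {9913: 1.0})
        o = comp("s", {9895: 1.0})
        c = match_compositions(e, o, tax, "genus")
        assert (c.tp, c.fp, c.fn) == (0, 1, 1)

    def test_threshold_applied_before_matching(self, tax):
        e = expected("s", {9913: 1.0})
        o = comp("s", {9913: 0.9995, 9031: 0.0005})
        c = match_compositions(e, o, tax, "genus", threshold=0.001)
        assert (c.tp, c.fp, c.fn) == (1, 0, 0)


class TestScores:
    def test_published_confusion_percentages(self):
        p, _ = precision_recall(ConfusionCounts(tp=490, fp=56, fn=39))
        _, r = precision_recall(ConfusionCounts(tp=490, fp=56, fn=39))
        assert percent(p) == 90
        assert percent(r) == 93

    def test_undefined_ratios_are_none(self):
        p, r = precision_recall(ConfusionCounts(0, 0, 0))
        assert p is None and r is None

    def test_percent_rounds_half_away_from_zero(self):
        assert percent(0.985) == 99
        assert percent(0.9849) == 98
        assert percent(-0.985) == -99

    @pytest.mark.parametrize("x", [0.0, 0.3, 1.0])
    def test_fbeta_symmetry_point(self, x):
        if x == 0:
            assert fbeta(x, x) == 0.0
        else:
            assert math.isclose(fbeta(x, x, beta=2), x)
            assert math.isclose(fbeta(x, x, beta=0.5), x)

    def test_fbeta_limits_and_arithmetic(self):
        assert fbeta(1.0, 0.0) == 0.0
        assert math.isclose(fbeta(0.5, 1.0, beta=2), 5 * 0.5 / (4 * 0.5 + 1))
        assert math.isclose(fbeta(0.5, 1.0, beta=2), 0.8333, abs_tol=1e-4)

    def test_fbeta_between_min_and_max(self):
        rng = random.Random(3)
        for _ in range(100):
            p, r = rng.random(), rng.random()
            f = fbeta(p, r, beta=rng.choice([0.5, 1, 2]))
            assert min(p, r) - 1e-12 <= f <= max(p, r) + 1e-12

    def test_gpr(self):
        assert gpr(0.7, 0.7) == pytest.approx(0.7)
        assert gpr(1.0, 0.0) == 0.0
        assert gpr(0.9, 0.4) == pytest.approx(0.6)


class TestEuclidean:
    def test_identical_is_zero(self, tax):
        e = expected("s", {9913: 0.6, 9823: 0.4})
        o = comp("s", {9913: 0.6, 9823: 0.4})
        assert euclidean_distance(e, o, tax, "species") == 0.0

    def test_disjoint_unit_masses(self, tax):
        e = expected("s", {9913: 1.0})
        o = comp("s", {9031: 1.0})
        assert euclidean_distance(e, o, tax, "species") == pytest.approx(math.sqrt(2))

    def test_union_vector_arithmetic(self, tax):
        e = expected("s", {9913: 0.6, 9823: 0.4})
        o = comp("s", {9913: 0.5, 9823: 0.5})
        assert euclidean_distance(e, o, tax, "species") == pytest.approx(
            math.sqrt(0.02)
        )

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from([9913, 9915, 9901, 9823, 9031]),
                st.floats(0.001, 1.0, allow_nan=False),
            ),
            min_size=1,
            max_size=4,
        ),
        st.lists(
            st.tuples(
                st.sampled_from([9913, 9915, 9901, 9823, 9031]),
                st.floats(0.001, 1.0, allow_nan=False),
            ),
            min_size=1,
            max_size=4,
        ),
        st.lists(
            st.tuples(
                st.sampled_from([9913, 9915, 9901, 9823, 9031]),
                st.floats(0.001, 1.0, allow_nan=False),
            ),
            min_size=1,
            max_size=4,
        ),
    )
    def test_metric_properties(self, tax, a, b, c):
        """Symmetry and triangle inequality on rank-level vectors."""
        ca, cb, cc = (comp("s", dict(x)) for x in (a, b, c))

        def dist(x, y):
            e = ExpectedComposition("s", x.proportions())
            return euclidean_distance(e, y, tax, "species")

        d_ab = dist(ca, cb)
        d_ba = dist(cb, ca)
        assert d_ab == pytest.approx(d_ba, abs=1e-12)
        assert dist(ca, cc) <= dist(ca, cb) + dist(cb, cc) + 1e-9


class TestErrorsAndYields:
    def test_relative_error_signs(self):
        assert relative_error(0.5, 0.5) == 0.0
        assert relative_error(0.01, 0.016) == pytest.approx(0.6)
        assert relative_error(0.5, 0.25) == pytest.approx(-0.5)

    def test_relative_error_requires_positive_expected(self):
        with pytest.raises(ValueError):
            relative_error(0.0, 0.1)

    def test_yield_fraction(self):
        assert yield_fraction(100000, 99000) == pytest.approx(0.99)
        assert yield_fraction(5, 5) == 1.0
        with pytest.raises(ValueError):
            yield_fraction(0, 0)

    def test_staged_yields(self):
        stages = {"in": 1000, "merged": 980, "clustered": 970, "assigned": 960}
        assert staged_yields(stages) == pytest.approx(
            {"merged": 0.98, "clustered": 0.97, "assigned": 0.96}
        )

    def test_splitting_level(self):
        assert splitting_level(10, 1) == pytest.approx(1.0)
        assert splitting_level(7, 7) == 0.0
        with pytest.raises(ValueError):
            splitting_level(0, 1)


class TestSweep:
    def test_perfect_sample_flat_below_smallest_component(self, tax):
        e = expected("s", {9913: 0.9, 9823: 0.1})
        o = comp("s", {9913: 0.9, 9823: 0.1})
        res = pr_threshold_sweep([e], [o], tax, "genus", step=0.01)
        low = res.curve[res.curve["threshold"] < 0.1]
        assert (low["precision"] == 1.0).all() and (low["recall"] == 1.0).all()

    def test_recall_monotone_nonincreasing_in_threshold(self, tax):
        e = expected("s", {9913: 0.7, 9823: 0.2, 9031: 0.1})
        o = comp("s", {9913: 0.69, 9823: 0.2, 9031: 0.1, 9915: 0.01})
        res = pr_threshold_sweep([e], [o], tax, "genus", step=0.005)
        recalls = res.curve["recall"].dropna().tolist()
        assert all(a >= b - 1e-12 for a, b in zip(recalls, recalls[1:]))

    def test_recall_drop_at_component_threshold(self, tax):
        # one of two components sits at exactly 1%; just above it recall
        # loses 1/(tp+fn)
        e = expected("s", {9913: 0.99, 9823: 0.01})
        o = comp("s", {9913: 0.99, 9823: 0.01})
        res = pr_threshold_sweep([e], [o], tax, "genus", step=0.0001)
        curve = res.curve
        just_at = curve.loc[(curve["threshold"] - 0.01).abs() < 1e-9, "recall"].iloc[0]
        just_above = curve.loc[
            (curve["threshold"] - 0.0101).abs() < 1e-9, "recall"
        ].iloc[0]
        assert just_at == 1.0
        assert just_above == pytest.approx(1.0 - 1 / 2)

    def test_optimal_is_smallest_argmax(self, tax):
        # noise at 0.4%: every threshold in (0.004, min component] attains
        # F2 = 1; the smallest grid point above the noise wins
        e = expected("s", {9913: 0.9, 9823: 0.096})
        o = comp("s", {9913: 0.9, 9823: 0.096, 9031: 0.004})
        res = pr_threshold_sweep([e], [o], tax, "genus", step=0.001)
        assert res.optimal_threshold == pytest.approx(0.005)

    def test_empty_sample_set_rejected(self, tax):
        with pytest.raises(ValueError):
            pr_threshold_sweep([], [], tax, "genus")


@pytest.fixture(scope="module")
def fastq_pair(tmp_path_factory):
    d = tmp_path_factory.mktemp("fastq")
    spec = FixtureSpec(seed=5)
    make_fastq(spec, 200, d / "r1.fastq.gz", d / "r2.fastq.gz")
    return d / "r1.fastq.gz", d / "r2.fastq.gz"


class TestDownsampling:
    def test_seed_concatenation(self):
        assert downsample_seed(1000, 1) == 10001
        assert downsample_seed(1000, 2) == 10002
        assert downsample_seed(350000, 12) == 35000012

    def test_identity_when_size_equals_total(self, fastq_pair, tmp_path):
        r1, r2 = fastq_pair
        downsample_reads(r1, r2, 200, 1, tmp_path / "o1.fq", tmp_path / "o2.fq")
        import gzip

        from Bio import SeqIO

        with gzip.open(r1, "rt") as fh:
            orig = [r.id for r in SeqIO.parse(fh, "fastq")]
        out = [r.id for r in SeqIO.parse(str(tmp_path / "o1.fq"), "fastq")]
        assert out == orig

    def test_deterministic_and_pair_preserving(self, fastq_pair, tmp_path):
        r1, r2 = fastq_pair
        from Bio import SeqIO

        for rep in (1, 2):
            a1, a2 = tmp_path / f"a1_{rep}.fq", tmp_path / f"a2_{rep}.fq"
            b1, b2 = tmp_path / f"b1_{rep}.fq", tmp_path / f"b2_{rep}.fq"
            downsample_reads(r1, r2, 50, rep, a1, a2)
            downsample_reads(r1, r2, 50, rep, b1, b2)
            assert a1.read_bytes() == b1.read_bytes()
            assert a2.read_bytes() == b2.read_bytes()
            ids1 = [r.id.rsplit("/", 1)[0] for r in SeqIO.parse(str(a1), "fastq")]
            ids2 = [r.id.rsplit("/", 1)[0] for r in SeqIO.parse(str(a2), "fastq")]
            assert ids1 == ids2  # same index set on both mates

    def test_replicates_differ(self, fastq_pair, tmp_path):
        r1, r2 = fastq_pair
        downsample_reads(r1, r2, 50, 1, tmp_path / "x1.fq", tmp_path / "x2.fq")
        downsample_reads(r1, r2, 50, 2, tmp_path / "y1.fq", tmp_path / "y2.fq")
        assert (tmp_path / "x1.fq").read_bytes() != (tmp_path / "y1.fq").read_bytes()

    def test_oversampling_rejected(self, fastq_pair, tmp_path):
        r1, r2 = fastq_pair
        with pytest.raises(ValueError):
            downsample_reads(r1, r2, 201, 1, tmp_path / "o1.fq", tmp_path / "o2.fq")


class TestEvaluate:
    def test_aggregates_over_samples(self, tax):
        e1 = expected("s1", {9913: 1.0})
        o1 = comp("s1", {9913: 1.0})
        e2 = expected("s2", {9823: 0.9, 9913: 0.1})
        o2 = comp("s2", {9823: 0.9, 9031: 0.1})
        rep = evaluate([e1, e2], [o1, o2], tax, "genus", threshold=0.001)
        assert (rep.confusion.tp, rep.confusion.fp, rep.confusion.fn) == (2, 1, 1)
        assert rep.precision == pytest.approx(2 / 3)
        assert rep.recall == pytest.approx(2 / 3)
        assert len(rep.per_sample) == 2
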