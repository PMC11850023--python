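"""Unit and property tests for the ideal-observer engine."""

from fractions import Fraction

import pytest
from hypothesis import given, strategies as st

import oracles
from urnlearn import (
    COPY_AFTER_FIRST,
    INDEPENDENT,
    LITERAL_PRODUCT,
    MAXIMIZE,
    PROBABILITY_MATCH,
    SHARED,
    HypothesisSpace,
    InformantModel,
    Jar,
    LearnerData,
    TestimonySet,
    colour_likelihood,
    endorsement_distribution,
    posterior,
    posterior_from_samples,
    predicted_choice_probability,
    single_testimony_likelihood,
    testimony_set_likelihood,
)

MATCH = InformantModel(PROBABILITY_MATCH)
MAX = InformantModel(MAXIMIZE)

# ---------------------------------------------------------------------------
# hypothesis strategies for random small spaces / testimony sets


@st.composite
def small_spaces(draw):
    colours = ["c0", "c1", "c2", "c3"][: draw(st.integers(2, 4))]
    n_jars = draw(st.integers(2, 3))
    jars = []
    for i in range(n_jars):
        subset = draw(
            st.lists(st.sampled_from(colours), min_size=1, max_size=len(colours), unique=True)
        )
        comp = {c: draw(st.integers(1, 6)) for c in subset}
        jars.append(Jar(f"jar{i}", comp))
    # every colour must be drawable somewhere for testimony marginals to be valid
    drawable = {c for j in jars for c in j.composition}
    jars[0] = Jar("jar0", {**jars[0].composition, **{c: 1 for c in colours if c not in drawable}})
    return HypothesisSpace(jars)


@st.composite
def spaces_and_testimony(draw):
    space = draw(small_spaces())
    n = draw(st.integers(0, 4))
    endorsements = [draw(st.sampled_from(space.labels)) for _ in range(n)]
    structure = draw(st.sampled_from([INDEPENDENT, SHARED])) if n >= 1 else INDEPENDENT
    variant = draw(st.sampled_from([LITERAL_PRODUCT, COPY_AFTER_FIRST]))
    return space, TestimonySet(endorsements, structure, variant)


# ---------------------------------------------------------------------------
# colour likelihoods


def test_colour_likelihood_is_count_ratio(ball_space):
    jar = ball_space.jar("mostly_red")
    assert colour_likelihood("red", jar) == pytest.approx(5 / 7, abs=1e-15)
    assert colour_likelihood("green", jar) == 0.0
    assert sum(colour_likelihood(c, jar) for c in ball_space.colours) == pytest.approx(1.0)


def test_unknown_jar_label_raises(ball_space):
    with pytest.raises(KeyError):
        ball_space.jar("mostly_blue")


# ---------------------------------------------------------------------------
# informant endorsement models


def test_maximizing_informant_is_deterministic(ball_space):
    dist = endorsement_distribution(MAX, "red", ball_space)
    assert dist == {"mostly_red": 1.0, "mostly_yellow": 0.0}


def test_probability_matching_informant_returns_single_datum_posterior(ball_space):
    dist = endorsement_distribution(MATCH, "yellow", ball_space)
    assert dist["mostly_yellow"] == pytest.approx(5 / 6, abs=1e-15)
    assert dist["mostly_red"] == pytest.approx(1 / 6, abs=1e-15)


def test_maximizer_splits_ties_uniformly(tie_space):
    dist = endorsement_distribution(MAX, "blue", tie_space)
    assert dist == {"left": 0.5, "right": 0.5}


def test_impossible_colour_raises(ball_space):
    with pytest.raises(ValueError, match="zero likelihood"):
        endorsement_distribution(MATCH, "purple", ball_space)


# ---------------------------------------------------------------------------
# single-testimony likelihoods (marginalizing the private draw)


@pytest.mark.parametrize(
    "model, expected",
    [(MAX, Fraction(6, 7)), (MATCH, Fraction(16, 21))],
    ids=["maximize", "probability_match"],
)
def test_single_testimony_likelihood_matches_enumeration(ball_space, model, expected):
    got = single_testimony_likelihood("mostly_red", "mostly_red", model, ball_space)
    assert got == pytest.approx(float(expected), abs=1e-12)
    oracle = oracles.single_likelihood(ball_space, "mostly_red", "mostly_red", model.strategy)
    assert oracle == expected


@given(small_spaces(), st.sampled_from([MAXIMIZE, PROBABILITY_MATCH]))
def test_single_testimony_normalizes_over_endorsements(space, strategy):
    model = InformantModel(strategy)
    for h in space.labels:
        total = sum(
            single_testimony_likelihood(t, h, model, space) for t in space.labels
        )
        assert total == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# testimony-set likelihoods


def test_independent_set_is_product_of_singles(ball_space):
    tset = TestimonySet(["mostly_red", "mostly_red"], INDEPENDENT)
    got = testimony_set_likelihood(tset, "mostly_red", MAX, ball_space)
    assert got == pytest.approx((6 / 7) ** 2, abs=1e-12)


def test_shared_literal_product_matches_enumeration(ball_space):
    tset = TestimonySet(["mostly_red", "mostly_red"], SHARED, LITERAL_PRODUCT)
    got = testimony_set_likelihood(tset, "mostly_red", MATCH, ball_space)
    assert got == pytest.approx(162 / 252, abs=1e-12)


def test_single_informant_structures_coincide(ball_space):
    for variant in (LITERAL_PRODUCT, COPY_AFTER_FIRST):
        shared = testimony_set_likelihood(
            TestimonySet(["mostly_red"], SHARED, variant), "mostly_red", MATCH, ball_space
        )
        indep = testimony_set_likelihood(
            TestimonySet(["mostly_red"], INDEPENDENT), "mostly_red", MATCH, ball_space
        )
        assert shared == pytest.approx(indep, abs=1e-15)


def test_empty_independent_set_has_unit_likelihood(ball_space):
    tset = TestimonySet([], INDEPENDENT)
    assert testimony_set_likelihood(tset, "mostly_red", MATCH, ball_space) == 1.0


@given(spaces_and_testimony(), st.sampled_from([MAXIMIZE, PROBABILITY_MATCH]))
def test_set_likelihood_equals_brute_force(space_tset, strategy):
    """Both structures and both shared variants agree with exact enumeration
    over all colour assignments to informants."""
    space, tset = space_tset
    model = InformantModel(strategy)
    for h in space.labels:
        got = testimony_set_likelihood(tset, h, model, space)
        oracle = oracles.brute_force_set_likelihood(space, tset, h, strategy)
        assert got == pytest.approx(float(oracle), abs=1e-12)


def test_copy_after_first_ignores_majority_size(ball_space):
    """Unanimous shared testimony under deterministic copying is the same
    evidence no matter how many informants repeat it."""
    liks = [
        testimony_set_likelihood(
            TestimonySet(["mostly_red"] * n, SHARED, COPY_AFTER_FIRST),
            "mostly_red",
            MATCH,
            ball_space,
        )
        for n in (1, 2, 3, 4)
    ]
    assert all(l == liks[0] for l in liks)


def test_maximizer_shared_unanimous_equals_single_when_no_ties(ball_space):
    """With deterministic endorsements (no tie colours), a shared unanimous
    majority carries exactly one testimony's worth of evidence, either variant."""
    single = single_testimony_likelihood("mostly_red", "mostly_red", MAX, ball_space)
    for variant in (LITERAL_PRODUCT, COPY_AFTER_FIRST):
        tset = TestimonySet(["mostly_red"] * 3, SHARED, variant)
        got = testimony_set_likelihood(tset, "mostly_red", MAX, ball_space)
        assert got == pytest.approx(single, abs=1e-15)


# ---------------------------------------------------------------------------
# posterior integration


def test_shared_majority_vs_dissenter_is_exact_chance_for_maximizer(ball_space):
    """Two maximizers sharing one ball against one independent dissenter:
    the evidence cancels exactly (one ball of each colour), posterior 1/2."""
    groups = [
        TestimonySet(["mostly_red", "mostly_red"], SHARED, COPY_AFTER_FIRST),
        TestimonySet(["mostly_yellow"], INDEPENDENT),
    ]
    post = posterior(ball_space, groups, LearnerData(), MAX)
    assert post["mostly_red"] == 0.5


def test_independent_majority_vs_own_ball(ball_space):
    groups = TestimonySet(["mostly_red"] * 3, INDEPENDENT)
    post = posterior(ball_space, groups, LearnerData(["yellow"]), MAX)
    assert post["mostly_red"] == pytest.approx(216 / 221, abs=1e-12)


def test_no_evidence_returns_prior():
    space = HypothesisSpace(
        [Jar("a", {"x": 1, "y": 3}), Jar("b", {"x": 3, "y": 1})], {"a": 0.25, "b": 0.75}
    )
    post = posterior(space, None, LearnerData(), None)
    assert post == {"a": 0.25, "b": 0.75}


def test_impossible_evidence_raises(ball_space):
    # a non-unanimous shared set under deterministic copying cannot occur
    tset = TestimonySet(["mostly_red", "mostly_yellow"], SHARED, COPY_AFTER_FIRST)
    with pytest.raises(ValueError, match="impossible evidence"):
        posterior(ball_space, tset, LearnerData(), MAX)


@given(spaces_and_testimony(), st.sampled_from([MAXIMIZE, PROBABILITY_MATCH]))
def test_posterior_sums_to_one_and_matches_enumeration(space_tset, strategy):
    space, tset = space_tset
    model = InformantModel(strategy)
    try:
        post = posterior(space, tset, LearnerData(), model)
    except ValueError:
        return  # impossible-evidence combinations are a legitimate error path
    assert sum(post.values()) == pytest.approx(1.0, abs=1e-12)
    oracle = oracles.brute_force_posterior(space, [tset], [], strategy)
    for lab in space.labels:
        assert post[lab] == pytest.approx(float(oracle[lab]), abs=1e-12)


@given(small_spaces(), st.sampled_from([MAXIMIZE, PROBABILITY_MATCH]), st.data())
def test_label_swap_symmetry(space, strategy, data):
    """Consistently relabeling jars and colours permutes every posterior."""
    n = data.draw(st.integers(1, 3))
    endorsements = [data.draw(st.sampled_from(space.labels)) for _ in range(n)]
    tset = TestimonySet(endorsements, INDEPENDENT)
    model = InformantModel(strategy)

    jar_map = {lab: f"swap_{lab}" for lab in space.labels}
    colour_map = {c: f"swap_{c}" for c in space.colours}
    swapped_space = HypothesisSpace(
        [
            Jar(jar_map[j.label], {colour_map[c]: k for c, k in j.composition.items()})
            for j in space.jars
        ],
        {jar_map[lab]: w for lab, w in space.prior.items()},
    )
    swapped_tset = TestimonySet([jar_map[t] for t in endorsements], INDEPENDENT)

    try:
        post = posterior(space, tset, LearnerData(), model)
    except ValueError:
        return  # endorsement impossible under every jar: legitimate error path
    swapped = posterior(swapped_space, swapped_tset, LearnerData(), model)
    for lab in space.labels:
        assert swapped[jar_map[lab]] == pytest.approx(post[lab], abs=1e-12)


def test_independent_unanimity_strictly_increases_with_majority_size(toy_space):
    """Each extra independent concurring endorsement strengthens the endorsed
    jar whenever the testimony favours it."""
    prev = 0.0
    for n in (1, 2, 3, 4, 5):
        post = posterior(
            toy_space,
            TestimonySet(["mostly_frog"] * n, INDEPENDENT),
            LearnerData(),
            MATCH,
        )
        assert post["mostly_frog"] > prev
        prev = post["mostly_frog"]


# ---------------------------------------------------------------------------
# testimony-free posteriors


def test_sample_only_posterior_values(toy_space):
    post = posterior_from_samples(toy_space, LearnerData(["frog"] * 3 + ["fish"]))
    assert post["mostly_frog"] == pytest.approx(125 / 130, abs=1e-12)
    balanced = posterior_from_samples(toy_space, LearnerData(["frog", "fish"]))
    assert balanced["mostly_frog"] == 0.5
    single = posterior_from_samples(toy_space, LearnerData(["frog"]))
    assert single["mostly_frog"] == pytest.approx(5 / 6, abs=1e-12)


def test_sample_only_posterior_requires_observations(toy_space):
    with pytest.raises(ValueError, match="at least one observation"):
        posterior_from_samples(toy_space, LearnerData([]))


# ---------------------------------------------------------------------------
# response rules


@pytest.mark.parametrize(
    "value, rule, expected",
    [
        (0.762, "posterior_match", 0.762),
        (0.762, "posterior_maximize", 1.0),
        (0.3, "posterior_maximize", 0.0),
        (0.5, "posterior_maximize", 0.5),
    ],
)
def test_predicted_choice_probability(value, rule, expected):
    assert predicted_choice_probability(value, rule) == expected


def test_predicted_choice_probability_rejects_bad_input():
    with pytest.raises(ValueError):
        predicted_choice_probability(1.2, "posterior_match")
    with pytest.raises(ValueError):
        predicted_choice_probability(0.5, "softmax")


# ---------------------------------------------------------------------------
# type validation


def test_type_invariants():
    with pytest.raises(ValueError):
        Jar("empty", {})
    with pytest.raises(ValueError):
        Jar("bad", {"red": 0})
    with pytest.raises(ValueError):
        HypothesisSpace([Jar("only", {"x": 1}), Jar("only", {"x": 2})])
    with pytest.raises(ValueError):
        HypothesisSpace(
            [Jar("a", {"x": 1}), Jar("b", {"x": 1})], {"a": 0.6, "b": 0.6}
        )
    with pytest.raises(ValueError):
        InformantModel("greedy")
    with pytest.raises(ValueError):
        TestimonySet([], SHARED)
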