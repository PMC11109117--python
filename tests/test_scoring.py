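"""Scoring engine: formula arithmetic, algebraic identities, composition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scoredfu.errors import NoLesionError, ValidationError
from scoredfu.scoring import feature_ratios, feature_scores, score_image, total_score
from scoredfu.segmentation import OracleSegmenter, areas_from_labelmap
from scoredfu.stratification import OracleClassifier
from scoredfu.types import ClassProbabilities, LesionAreas, ScoreWeights


def oracle_score(areas: dict, probs: dict, w: dict):
    """Independent direct evaluation of the scoring formulas from raw dicts."""
    s = {
        "ulcer": (areas["ulcer1"], areas["ulcer2"]),
        "infection": (areas["infection1"], areas["infection2"]),
        "gangrene": (areas["gangrene1"], areas["gangrene2"]),
    }
    tot = sum(sum(v) for v in s.values())
    x = {}
    for fam, (s1, s2) in s.items():
        x[fam] = w[f"w_{fam}"] * probs[fam] * (
            w[f"w_{fam}1"] * s1 + w[f"w_{fam}2"] * s2) / tot
    v = w["scale"] * sum(x.values()) + w["epsilon"]
    return x, v


UNIT_W = ScoreWeights(w_ulcer=1, w_infection=1, w_gangrene=1,
                      w_ulcer1=1, w_ulcer2=1, w_infection1=1, w_infection2=1,
                      w_gangrene1=1, w_gangrene2=1, scale=100, epsilon=0)


@pytest.mark.parametrize("areas,expected", [
    (LesionAreas(ulcer1=25, infection1=25, gangrene1=50), (0.25, 0.25, 0.50)),
    (LesionAreas(gangrene1=30, gangrene2=50), (0.0, 0.0, 1.0)),
    (LesionAreas(ulcer1=10, ulcer2=15, infection2=25, gangrene1=50),
     (0.25, 0.25, 0.50)),
])
def test_feature_ratios_are_area_shares(areas, expected):
    a = feature_ratios(areas)
    assert a == pytest.approx(expected)
    assert sum(a) == pytest.approx(1.0)


def test_feature_ratios_zero_area_signals_degenerate():
    with pytest.raises(NoLesionError):
        feature_ratios(LesionAreas())
    with pytest.raises(NoLesionError):
        feature_scores(LesionAreas(),
                       ClassProbabilities(1.0, 0.0, 0.0, 0.0))


def test_feature_scores_unit_weight_reduction():
    # equal areas of 10 per subcategory, unit weights, all P_i = 1
    areas = LesionAreas(10, 10, 10, 10, 10, 10)
    unit_p = {"ulcer": 1.0, "infection": 1.0, "gangrene": 1.0}
    x = feature_scores(areas, unit_p, UNIT_W)
    assert x == pytest.approx((20 / 60,) * 3)


def test_feature_score_worked_example():
    # W_ulcer=2, W_u1=1, W_u2=3, P_ulcer=0.5, S_u1=10, S_u2=20, sum S = 100
    areas = LesionAreas(ulcer1=10, ulcer2=20, infection1=70)
    probs = ClassProbabilities(0.5, 0.0, 0.5, 0.0)
    w = ScoreWeights(w_ulcer=2, w_ulcer1=1, w_ulcer2=3)
    x_u, x_i, x_g = feature_scores(areas, probs, w)
    assert x_u == pytest.approx(2 * 0.5 * (1 * 10 + 3 * 20) / 100)  # = 0.7
    assert x_i == 0.0  # P_infection = 0
    assert x_g == 0.0


def test_total_score_scale_identity_and_epsilon():
    areas = LesionAreas(3, 1, 4, 1, 5, 9)
    unit_p = {"ulcer": 1.0, "infection": 1.0, "gangrene": 1.0}
    assert total_score(areas, unit_p, UNIT_W).v == pytest.approx(100.0)
    w_eps = ScoreWeights(**{**UNIT_W.as_dict(), "epsilon": 5.0})
    assert total_score(areas, unit_p, w_eps).v == pytest.approx(105.0)


def test_total_score_worked_example():
    areas = LesionAreas(ulcer1=20, infection1=30, gangrene1=50)
    probs = {"ulcer": 0.5, "infection": 0.5, "gangrene": 1.0}
    w = ScoreWeights(w_ulcer=1, w_infection=1, w_gangrene=2,
                     w_ulcer1=1, w_ulcer2=1, w_infection1=1, w_infection2=1,
                     w_gangrene1=1, w_gangrene2=1, scale=10, epsilon=0)
    bd = total_score(areas, probs, w)
    assert bd.v == pytest.approx(10 * (1 * 0.5 * 20 / 100 + 1 * 0.5 * 30 / 100
                                       + 2 * 1 * 50 / 100))  # = 12.5


def test_no_lesion_returns_epsilon_with_flag():
    w = ScoreWeights(epsilon=2.5)
    bd = total_score(LesionAreas(), ClassProbabilities(1, 0, 0, 0), w)
    assert bd.no_lesion
    assert bd.v == 2.5
    assert bd.a_ulcer == bd.x_gangrene == 0.0


def test_negative_weights_rejected():
    with pytest.raises(ValidationError):
        ScoreWeights(w_ulcer=-1)
    with pytest.raises(ValidationError):
        ScoreWeights(scale=0)


def test_clamp_flag_bounds_v():
    areas = LesionAreas(gangrene2=100)
    probs = ClassProbabilities(0, 0, 0, 1)
    w = ScoreWeights(w_gangrene=5.0, scale=100)
    assert total_score(areas, probs, w).v > 100
    assert total_score(areas, probs, w, clamp=True).v == 100


areas_st = st.lists(st.integers(0, 1000), min_size=6, max_size=6).filter(
    lambda xs: sum(xs) > 0)
probs_st = st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4).map(
    lambda xs: ClassProbabilities.from_vector(np.array(xs) / sum(xs)))


@settings(derandomize=True, max_examples=60)
@given(areas=areas_st, probs=probs_st, mult=st.integers(2, 9))
def test_score_homogeneity_under_area_rescaling(areas, probs, mult):
    a1 = LesionAreas(*areas)
    a2 = LesionAreas(*(x * mult for x in areas))
    w = ScoreWeights()
    v1 = total_score(a1, probs, w).v
    v2 = total_score(a2, probs, w).v
    assert v1 == pytest.approx(v2, rel=1e-12)


@settings(derandomize=True, max_examples=60)
@given(areas=areas_st, probs=probs_st)
def test_feature_ratios_always_sum_to_one(areas, probs):
    assert sum(feature_ratios(LesionAreas(*areas))) == pytest.approx(1.0)


@settings(derandomize=True, max_examples=60)
@given(areas=areas_st, probs=probs_st, shift=st.integers(0, 100))
def test_moving_area_to_deeper_level_never_decreases_score(areas, probs, shift):
    # shift gangrene area from level 1 to level 2 (W_i2 > W_i1 by default)
    g1 = areas[4]
    shift = min(shift, g1)
    before = LesionAreas(*areas)
    moved = list(areas)
    moved[4] -= shift
    moved[5] += shift
    after = LesionAreas(*moved)
    w = ScoreWeights()
    assert total_score(after, probs, w).v >= total_score(before, probs, w).v - 1e-9


@settings(derandomize=True, max_examples=60)
@given(areas=areas_st, probs=probs_st, bump=st.floats(0.0, 0.5))
def test_raising_class_probability_never_decreases_score(areas, probs, bump):
    # move probability mass from normal (unused by scoring) into gangrene
    bump = min(bump, probs.normal)
    bumped = ClassProbabilities(probs.normal - bump, probs.infection,
                                probs.ulcer, probs.gangrene + bump)
    w = ScoreWeights()
    a = LesionAreas(*areas)
    assert total_score(a, bumped, w).v >= total_score(a, probs, w).v - 1e-9


def test_matches_independent_oracle_on_random_inputs(rng):
    w_names = ["w_ulcer", "w_infection", "w_gangrene", "w_ulcer1", "w_ulcer2",
               "w_infection1", "w_infection2", "w_gangrene1", "w_gangrene2"]
    for _ in range(300):
        areas_d = dict(zip(
            ("ulcer1", "ulcer2", "infection1", "infection2", "gangrene1",
             "gangrene2"),
            rng.integers(0, 500, 6).tolist()))
        if sum(areas_d.values()) == 0:
            areas_d["ulcer1"] = 1
        p = rng.dirichlet(np.ones(4))
        probs = ClassProbabilities.from_vector(p)
        wd = {n: float(rng.uniform(0, 4)) for n in w_names}
        wd["scale"] = float(rng.uniform(1, 200))
        wd["epsilon"] = float(rng.uniform(-5, 5))
        w = ScoreWeights(**wd)
        areas = LesionAreas(**areas_d)
        probs_d = {"ulcer": p[2], "infection": p[1], "gangrene": p[3]}
        ox, ov = oracle_score(areas_d, probs_d, wd)
        x = feature_scores(areas, probs, w)
        bd = total_score(areas, probs, w)
        assert x[0] == pytest.approx(ox["ulcer"], abs=1e-12)
        assert x[1] == pytest.approx(ox["infection"], abs=1e-12)
        assert x[2] == pytest.approx(ox["gangrene"], abs=1e-12)
        assert bd.v == pytest.approx(ov, abs=1e-9)


def test_score_image_composition_identity(small_dataset):
    w = ScoreWeights()
    for img, truth in small_dataset[:10]:
        binary = OracleSegmenter(binary=True)
        multi = OracleSegmenter()
        clf = OracleClassifier()
        probs = ClassProbabilities(0.1, 0.2, 0.3, 0.4)
        binary.register(img, truth.label_map)
        multi.register(img, truth.label_map)
        clf.register(img, probs)
        bd, label_map, p = score_image(img, binary, multi, clf, w)
        assert np.array_equal(label_map, truth.label_map)
        direct = total_score(truth.areas, probs, w)
        assert bd.v == pytest.approx(direct.v, abs=1e-12)
        assert bd == direct


def test_score_image_normal_scene_yields_epsilon(small_dataset):
    w = ScoreWeights(epsilon=1.25)
    normal = next((img, t) for img, t in small_dataset
                  if t.severity_label.value == "normal")
    img, truth = normal
    binary = OracleSegmenter(binary=True)
    multi = OracleSegmenter()
    clf = OracleClassifier()
    binary.register(img, truth.label_map)
    multi.register(img, truth.label_map)
    clf.register(img, ClassProbabilities(0.97, 0.01, 0.01, 0.01))
    bd, _, _ = score_image(img, binary, multi, clf, w)
    assert bd.no_lesion and bd.v == 1.25


def test_score_monotone_in_gangrene_area():
    """Growing the gangrene blob (oracle components) never lowers V."""
    from scoredfu.synth import BlobSpec, SceneSpec, generate_scene
    from scoredfu.types import Subcategory

    w = ScoreWeights()  # W_gangrene largest by default
    probs = ClassProbabilities(0.05, 0.05, 0.1, 0.8)
    last_v = -np.inf
    for radius in (4, 7, 10, 13, 16):
        spec = SceneSpec(64, 64, blobs=(
            BlobSpec(Subcategory.ULCER1, (20, 20), 5, 0.0),
            BlobSpec(Subcategory.GANGRENE2, (40, 40), radius, 0.0),
        ), seed=2)
        img, truth = generate_scene(spec)
        binary = OracleSegmenter(binary=True)
        multi = OracleSegmenter()
        clf = OracleClassifier()
        binary.register(img, truth.label_map)
        multi.register(img, truth.label_map)
        clf.register(img, probs)
        bd, _, _ = score_image(img, binary, multi, clf, w)
        assert bd.v >= last_v - 1e-12
        last_v = bd.v
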