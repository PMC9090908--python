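import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import braycurtis as scipy_braycurtis
from scipy.stats import rankdata

from defenscan import (ArsenalProfile, ProphageRegion, arsenal_profiles,
                       assign_location, bray_curtis,
                       covariate_adjusted_association,
                       filter_prophage_predictions, frequency_table,
                       spearman_assoc, system_span, validation_metrics)


class _Span:
    def __init__(self, start_bp, end_bp, replicon_id="R1"):
        self.start_bp = start_bp
        self.end_bp = end_bp
        self.replicon_id = replicon_id


def test_system_span_is_the_literal_coordinate_difference():
    assert system_span(_Span(100, 3696)) == 3596
    assert system_span(_Span(500, 500)) == 0
    # translation invariance
    assert system_span(_Span(100 + 10_000, 3696 + 10_000)) == 3596


def test_prophage_location_requires_full_containment():
    region = ProphageRegion("R1", 1, 2000, 0.9)
    assert assign_location(_Span(500, 1500), [region]) == "prophage"
    assert assign_location(_Span(500, 2500), [region]) == "chromosome"
    assert assign_location(_Span(1, 2000), [region]) == "prophage"  # inclusive
    other = _Span(500, 1500, replicon_id="R2")
    assert assign_location(other, [region]) == "chromosome"


def test_prophage_filter_boundaries_are_strict():
    mk = lambda score, kb: ProphageRegion("R1", 1, kb * 1000, score)
    kept = filter_prophage_predictions(
        [mk(0.9, 150), mk(0.8, 150), mk(0.9, 200), mk(0.81, 199)])
    assert [(r.max_score, r.length_bp) for r in kept] == \
        [(0.9, 150_000), (0.81, 199_000)]


class _Call:
    def __init__(self, genome_id, model_name, family):
        self.genome_id = genome_id
        self.model_name = model_name
        self.family = family


def test_arsenal_counts_systems_and_distinct_families():
    calls = [_Call("G1", m, f) for m, f in
             [("RM-I", "RM"), ("RM-II", "RM"), ("CAS-IE", "CRISPR-Cas"),
              ("CAS-IF", "CRISPR-Cas"), ("Wadjet-I", "Wadjet")]]
    (prof,) = arsenal_profiles(calls)
    assert prof.n_systems == 5
    assert prof.n_families == 3
    assert prof.n_families <= prof.n_systems


def test_genomes_without_calls_appear_with_zeros():
    profs = arsenal_profiles([_Call("G1", "RM-I", "RM")],
                             all_genomes=["G1", "G2"])
    by_id = {p.genome_id: p for p in profs}
    assert by_id["G2"].n_systems == 0 and by_id["G2"].n_families == 0


def test_family_diversity_is_monotone_under_additional_calls():
    base = [_Call("G1", "RM-I", "RM"), _Call("G1", "CAS-IE", "CRISPR-Cas")]
    (small,) = arsenal_profiles(base)
    (big,) = arsenal_profiles(base + [_Call("G1", "Wadjet-I", "Wadjet")])
    assert big.n_families >= small.n_families


def _arsenal(**counts):
    fam = {k.split("-")[0]: 0 for k in counts}
    for k, v in counts.items():
        fam[k.split("-")[0]] += v
    return ArsenalProfile("g", dict(counts), fam)


def test_bray_curtis_examples():
    a = _arsenal(**{"RM-I": 2, "CBASS-I": 1})
    b = _arsenal(**{"RM-I": 1})
    assert bray_curtis(a, b) == pytest.approx(0.5)  # 1 - 2*1/4
    assert bray_curtis(a, a) == 0.0
    disjoint = _arsenal(**{"Wadjet-I": 3})
    assert bray_curtis(a, disjoint) == 1.0
    empty = ArsenalProfile("e")
    assert bray_curtis(empty, ArsenalProfile("f")) == 0.0  # both empty


@settings(max_examples=80, deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 9), min_size=1, max_size=6),
       st.lists(st.integers(0, 9), min_size=1, max_size=6))
def test_bray_curtis_is_a_semimetric_matching_scipy(xs, ys):
    n = max(len(xs), len(ys))
    xs = xs + [0] * (n - len(xs))
    ys = ys + [0] * (n - len(ys))
    a = ArsenalProfile("a", {f"s{i}": v for i, v in enumerate(xs) if v}, {})
    b = ArsenalProfile("b", {f"s{i}": v for i, v in enumerate(ys) if v}, {})
    d = bray_curtis(a, b)
    assert d == pytest.approx(bray_curtis(b, a))
    assert 0.0 <= d <= 1.0
    if sum(xs) + sum(ys) > 0:
        assert d == pytest.approx(scipy_braycurtis(xs, ys))


def test_spearman_perfect_correlations_and_bonferroni():
    x = [1.0, 2.0, 3.0, 5.0, 8.0, 13.0]
    up = spearman_assoc(x, x, m_tests=4)
    assert up.rho == pytest.approx(1.0)
    down = spearman_assoc(x, [-v for v in x])
    assert down.rho == pytest.approx(-1.0)
    assert up.adjusted_p == pytest.approx(min(1.0, up.p_value * 4))


def test_spearman_matches_direct_rank_formula():
    x = [3.0, 1.0, 4.0, 1.0, 5.0, 9.0]
    y = [2.0, 7.0, 1.0, 8.0, 2.0, 8.0]
    res = spearman_assoc(x, y)
    rx, ry = rankdata(x), rankdata(y)  # average ranks for ties
    manual = np.corrcoef(rx, ry)[0, 1]
    assert res.rho == pytest.approx(manual)


def test_spearman_constant_vector_is_flagged_undefined():
    res = spearman_assoc([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
    assert res.undefined and res.rho is None


def test_forward_selection_ignores_uninformative_predictor(rng):
    cov = rng.normal(size=200)
    y = 2.0 * cov + rng.normal(scale=0.5, size=200)
    x = rng.normal(size=200)
    report = covariate_adjusted_association(x, y, cov)
    assert report["selected"] == ["covariate"]
    assert not report["x_selected"]
    assert not report["x_significant_given_covariate"]


def test_forward_selection_keeps_real_signal_beyond_covariate(rng):
    cov = rng.normal(size=200)
    x = rng.normal(size=200)
    y = x + cov + rng.normal(scale=0.5, size=200)
    report = covariate_adjusted_association(x, y, cov)
    assert report["x_selected"]
    assert report["x_significant_given_covariate"]
    assert set(report["selected"]) == {"covariate", "x"}


def test_permuted_predictor_breaks_selection_at_alpha(rng):
    cov = rng.normal(size=150)
    x = rng.normal(size=150)
    y = x + cov + rng.normal(scale=0.5, size=150)
    n_selected = 0
    n_rep = 100
    for _ in range(n_rep):
        perm = rng.permutation(x)
        if covariate_adjusted_association(perm, y, cov)["x_selected"]:
            n_selected += 1
    # false-selection rate should sit near alpha = 0.05
    assert n_selected / n_rep <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_rep)


def test_collinear_inputs_are_flagged_not_crashed(rng):
    cov = rng.normal(size=50)
    y = cov + rng.normal(scale=0.1, size=50)
    report = covariate_adjusted_association(cov.copy(), y, cov)
    assert report["collinear"]
    assert not report["x_significant_given_covariate"]


def test_validation_sensitivity_quotient_from_reference_counts():
    ref = pd.DataFrame({"genome_id": [f"g{i}" for i in range(417666)],
                        "model_name": "RM"})
    ours = ref.iloc[:384231]
    m = validation_metrics(ref, ours)
    assert m.sensitivity == pytest.approx(384231 / 417666)
    assert round(m.sensitivity, 4) == 0.9199


def test_validation_self_comparison_is_perfect():
    calls = pd.DataFrame({"genome_id": ["g1", "g1", "g2"],
                          "model_name": ["RM", "RM", "CBASS"]})
    m = validation_metrics(calls, calls, all_genomes=["g1", "g2", "g3"])
    assert m.sensitivity == 1.0
    assert m.extra_call_ratio == 0.0
    assert m.specificity_complement == 1.0


def test_validation_hand_tallied_confusion():
    ref = pd.DataFrame({"genome_id": ["g1", "g1", "g2", "g3"],
                        "model_name": ["RM", "RM", "CBASS", "RM"]})
    ours = pd.DataFrame({"genome_id": ["g1", "g2", "g4", "g5"],
                         "model_name": ["RM", "CBASS", "RM", "Wadjet"]})
    m = validation_metrics(ref, ours, all_genomes=[f"g{i}" for i in range(1, 7)])
    # matched: one RM of two in g1, the CBASS in g2 -> 2 of 4
    assert m.n_detected == 2 and m.n_reference == 4
    assert m.sensitivity == pytest.approx(0.5)
    # reference-negative genomes: g4, g5, g6; we call in g4 and g5
    assert m.n_negative_genomes == 3 and m.n_extra_genomes == 2
    assert m.extra_call_ratio == pytest.approx(2 / 3)


def test_validation_empty_reference_is_undefined():
    ours = pd.DataFrame({"genome_id": ["g1"], "model_name": ["RM"]})
    m = validation_metrics(ours.iloc[:0], ours)
    assert m.sensitivity is None


def test_frequency_table_fraction_of_carrier_genomes():
    profs = []
    for i in range(10):
        counts = {"RM": 1} if i < 8 else {}
        profs.append(ArsenalProfile(f"g{i}", dict(counts), dict(counts)))
    table = frequency_table(profs)
    assert table.loc["RM", "all"] == pytest.approx(0.8)


def test_frequency_table_group_threshold_and_order_invariance(rng):
    meta = pd.DataFrame({"genome_id": [f"g{i}" for i in range(12)],
                         "phylum": ["Big"] * 10 + ["Tiny"] * 2})
    profs = [ArsenalProfile(f"g{i}", {"RM": 1}, {"RM": 1}) for i in range(12)]
    table = frequency_table(profs, meta, group_by="phylum", min_group_size=5)
    assert list(table.columns) == ["Big"]  # Tiny dropped
    shuffled = list(profs)
    rng.shuffle(shuffled)
    table2 = frequency_table(shuffled, meta, group_by="phylum", min_group_size=5)
    pd.testing.assert_frame_equal(table, table2)
    assert ((table.values >= 0) & (table.values <= 1)).all()
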