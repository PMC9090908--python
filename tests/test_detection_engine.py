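import itertools

import numpy as np
import pytest

from defenscan import (ComponentDef, HmmHit, SystemModel, best_hit_per_gene,
                       cluster_hits, detect, evaluate_model, generate_genome,
                       resolve_overlaps, scan_proteome, score_candidate)
from defenscan.detection_engine import CandidateSystem, MemberGene
from defenscan.synthetic_fixtures import PlantSpec

from .conftest import hit_at, make_replicon


def test_best_hit_per_gene_keeps_max_and_breaks_ties_lexicographically():
    hits = [HmmHit("g1", "P1", 12.0, None, True),
            HmmHit("g1", "P2", 9.0, None, True),
            HmmHit("g2", "PB", 7.0, None, True),
            HmmHit("g2", "PA", 7.0, None, True),
            HmmHit("g3", "PZ", 1.0, None, True)]
    best = {h.gene_id: h.profile_name for h in best_hit_per_gene(hits)}
    assert best == {"g1": "P1", "g2": "PA", "g3": "PZ"}


def test_cluster_hits_window_rule():
    rep = make_replicon(30)
    hits = [hit_at(rep, r, "P") for r in (4, 6, 20)]
    clusters = cluster_hits(rep, hits, window_W=5)
    assert [c.ranks for c in clusters] == [[4, 6], [20]]  # gap 1 <= 5; 13 > 5
    (single,) = cluster_hits(rep, [hit_at(rep, 9, "P")], window_W=5)
    assert single.ranks == [9]


def test_cluster_hits_wraps_on_circular_replicon():
    rep = make_replicon(30, topology="circular")
    hits = [hit_at(rep, 1, "P"), hit_at(rep, 29, "P")]
    clusters = cluster_hits(rep, hits, window_W=5)
    assert len(clusters) == 1 and clusters[0].wrapped
    assert sorted(clusters[0].ranks) == [1, 29]
    linear = make_replicon(30)
    assert len(cluster_hits(linear, hits, window_W=5)) == 2


def _evaluate(model, rep, member_specs, forbidden=()):
    hits = [hit_at(rep, r, p) for r, p in member_specs]
    forb = [hit_at(rep, r, p) for r, p in forbidden]
    (cluster,) = cluster_hits(rep, hits, model.window_W)
    return evaluate_model([cluster], model, rep, forb)


def test_cbass_rule_accepts_system_missing_only_the_accessory_sensor(cbass_model):
    rep = make_replicon(20)
    cand = _evaluate(cbass_model, rep, [(5, "CD-NTase"), (6, "Effector_2TM")])
    assert cand is not None
    assert cand.matched_components == {"cyclase": "mandatory",
                                       "effector": "mandatory"}
    assert cand.score == pytest.approx(2.0)


def test_cbass_rule_rejects_when_a_mandatory_component_is_missing(cbass_model):
    rep = make_replicon(20)
    assert _evaluate(cbass_model, rep,
                     [(5, "CD-NTase"), (6, "Sensor_STK")]) is None


def test_cbass_rule_rejects_forbidden_hit_within_window_radius(cbass_model):
    rep = make_replicon(20)
    members = [(5, "CD-NTase"), (6, "Effector_1TM")]
    # forbidden hit 2 genes beyond the cluster end: inside span +/- W = 5
    assert _evaluate(cbass_model, rep, members,
                     forbidden=[(8, "Acb_like")]) is None
    # outside the radius: accepted
    assert _evaluate(cbass_model, rep, members,
                     forbidden=[(12, "Acb_like")]) is not None


def test_full_cbass_scores_mandatory_plus_half_accessory(cbass_model):
    rep = make_replicon(20)
    cand = _evaluate(cbass_model, rep,
                     [(5, "CD-NTase"), (6, "Effector_2TM"), (7, "Sensor_STK")])
    assert cand.score == pytest.approx(2.5)  # 2 x 1.0 + 1 x 0.5
    assert score_candidate(cand) == pytest.approx(cand.score)
    minimal = _evaluate(cbass_model, rep, [(5, "CD-NTase"), (6, "Effector_2TM")])
    assert cand.score > minimal.score  # accessory strictly increases score


def test_interchangeable_profiles_evidence_one_component_once(cbass_model):
    rep = make_replicon(20)
    # two effector homologs cannot satisfy both mandatory components
    assert _evaluate(cbass_model, rep,
                     [(5, "Effector_1TM"), (6, "Effector_2TM")]) is None


# ---------------------------------------------------------------------------
# overlap resolution


def _toy_model(name):
    return SystemModel(name, name, f"{name}-I",
                       [ComponentDef("c", "mandatory", ("P",))])


def _candidate(name, gene_ids, score, ranks=None):
    ranks = ranks or list(range(1, len(gene_ids) + 1))
    members = [MemberGene(g, r, r * 100, r * 100 + 50, "P", "c", "mandatory", 10.0)
               for g, r in zip(gene_ids, ranks)]
    return CandidateSystem(_toy_model(name), "R1", members,
                           {"c": "mandatory"}, score)


def test_disjoint_candidates_are_both_called():
    calls = resolve_overlaps([_candidate("A", ["g1", "g2"], 2.0),
                              _candidate("B", ["g3"], 1.0, [5])], "G")
    assert {c.model_name for c in calls} == {"A", "B"}
    assert calls[0].sys_id == "G_A_1"


def test_conflicting_candidates_keep_higher_score():
    calls = resolve_overlaps([_candidate("A", ["g1", "g2"], 3.0),
                              _candidate("B", ["g2", "g3"], 2.0)], "G")
    assert [c.model_name for c in calls] == ["A"]


def _brute_force_max_disjoint_score(cands):
    best = 0.0
    for r in range(len(cands) + 1):
        for subset in itertools.combinations(cands, r):
            genes = [g for c in subset for g in c.gene_ids]
            if len(genes) == len(set(genes)):
                best = max(best, sum(c.score for c in subset))
    return best


@pytest.mark.parametrize("trial", range(60))
def test_overlap_resolution_matches_exhaustive_maximization(trial):
    rng = np.random.default_rng(1000 + trial)
    n = int(rng.integers(2, 11))
    pool = [f"g{i}" for i in range(12)]
    cands = []
    for i in range(n):
        genes = list(rng.choice(pool, size=int(rng.integers(1, 4)),
                                replace=False))
        score = float(np.round(rng.uniform(0.5, 4.0), 1))
        cands.append(_candidate(f"M{i}", genes, score,
                                ranks=sorted(rng.choice(50, size=len(genes),
                                                        replace=False) + 1)))
    calls = resolve_overlaps(cands, "G")
    gene_lists = [g.gene_id for c in calls for g in c.members]
    assert len(gene_lists) == len(set(gene_lists))  # gene-disjoint
    assert sum(c.score for c in calls) == pytest.approx(
        _brute_force_max_disjoint_score(cands))


# ---------------------------------------------------------------------------
# full detection


def _run(kit, sim):
    hits = scan_proteome([sim.replicon], kit.registry)
    return detect([sim.replicon], kit.registry, hits, genome_id=sim.genome_id)


def test_detect_recovers_planted_systems_among_decoys(kit):
    sim = generate_genome([PlantSpec("ToyFam1-I", insert_rank=3),
                           PlantSpec("ToyFam2-I", insert_rank=12,
                                     spacer_genes=1)],
                          20, kit, seed=42, genome_id="two")
    calls = _run(kit, sim)
    got = {(c.model_name, tuple(m.gene_id for m in c.members)) for c in calls}
    want = {(t["model_name"], tuple(t["gene_ids"])) for t in sim.truth_calls}
    assert got == want


def test_detect_is_silent_on_decoy_only_genome(kit):
    sim = generate_genome([], 30, kit, seed=43, genome_id="null")
    assert _run(kit, sim) == []


def test_two_separated_copies_of_one_subtype_give_two_calls(kit):
    sim = generate_genome([PlantSpec("ToyFam1-I", insert_rank=3),
                           PlantSpec("ToyFam1-I", insert_rank=20)],
                          26, kit, seed=44, genome_id="dup")
    calls = _run(kit, sim)
    assert [c.model_name for c in calls] == ["ToyFam1-I", "ToyFam1-I"]
    assert calls[0].sys_id != calls[1].sys_id
    assert not ({m.gene_id for m in calls[0].members}
                & {m.gene_id for m in calls[1].members})


def test_removing_mandatory_gene_removes_call_but_accessory_does_not(kit):
    # ToyFam2-I: two mandatory + one accessory component
    degraded = generate_genome([PlantSpec("ToyFam2-I", insert_rank=5,
                                          completeness="missing_mandatory")],
                               20, kit, seed=45, genome_id="degr")
    assert degraded.truth_calls == []
    assert _run(kit, degraded) == []

    no_acc = generate_genome([PlantSpec("ToyFam2-I", insert_rank=5,
                                        completeness="missing_accessory")],
                             20, kit, seed=46, genome_id="noacc")
    calls = _run(kit, no_acc)
    assert [tuple(m.gene_id for m in c.members) for c in calls] == \
        [tuple(no_acc.truth_calls[0]["gene_ids"])]


def test_detection_is_translation_invariant_under_leading_padding(kit):
    base = generate_genome([PlantSpec("ToyFam1-I", insert_rank=4)], 15, kit,
                           seed=47, genome_id="shift")
    shifted = generate_genome([PlantSpec("ToyFam1-I", insert_rank=11)], 22,
                              kit, seed=47, genome_id="shift")
    calls_a = _run(kit, base)
    calls_b = _run(kit, shifted)
    assert len(calls_a) == len(calls_b) == 1
    assert calls_b[0].begin_rank - calls_a[0].begin_rank == 7
    assert calls_b[0].end_rank - calls_a[0].end_rank == 7
    assert (calls_b[0].end_bp - calls_b[0].start_bp ==
            calls_a[0].end_bp - calls_a[0].start_bp)


def test_forbidden_hit_near_planted_system_vetoes_the_call(kit, cbass_model):
    # plant a ToyFam3-I (has a forbidden component) and drop a forbidden gene
    # 2 genes downstream: the candidate must be vetoed
    model = kit.registry.get_model("ToyFam3-I")
    forb_profile = sorted(model.forbidden_profiles)[0]
    sim = generate_genome([PlantSpec("ToyFam3-I", insert_rank=5)], 20, kit,
                          seed=48, genome_id="veto")
    clean_calls = _run(kit, sim)
    assert len(clean_calls) == 1

    rng = np.random.default_rng(7)
    from defenscan.synthetic_fixtures import mutate_sequence
    end_rank = sim.truth_calls[0]["end_rank"]
    victim = sim.replicon.genes[end_rank + 1]  # 2 genes past the cluster
    victim.sequence = mutate_sequence(kit.consensus[forb_profile], 0.05, rng)
    assert _run(kit, sim) == []
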