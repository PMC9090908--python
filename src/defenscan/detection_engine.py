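"""Turning GA-passing hits on ordered replicons into system calls.

The engine realizes the second step of the two-step detection strategy:
after profile search has produced significant (GA-passing) hits, decision
rules are applied so that only hit sets satisfying the genetic architecture
of a system are called.  Per model this means:

1. keep, per gene, only its best hit among the model's profiles;
2. cluster hits along the replicon — two successive hits co-localize when at
   most ``window_W`` non-hit genes intervene (rank gap - 1 <= W); circular
   replicons wrap the gap across the origin;
3. check the quorum: at least ``min_mandatory`` distinct mandatory components
   and ``min_total`` distinct (mandatory + accessory) components matched,
   each gene evidencing at most one component through the component's set of
   interchangeable profiles;
4. reject candidates with a forbidden-profile hit inside the cluster span
   extended by ``window_W`` genes on each side;
5. resolve overlaps across models so no gene evidences two systems, keeping
   the gene-disjoint subset of candidates with maximal summed score (exact
   search on small conflict components, greedy beyond).

Candidate scores are 1.0 per matched mandatory component plus 0.5 per
matched accessory; only their relative order matters for overlap resolution.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

from .io_gembase import HmmHit, Replicon
from .model_registry import Registry, SystemModel
from .profile_hmm import apply_ga_filter

logger = logging.getLogger(__name__)

MANDATORY_WEIGHT = 1.0
ACCESSORY_WEIGHT = 0.5
EXACT_RESOLUTION_LIMIT = 20  # exhaustive search bound per conflict component


@dataclass
class Cluster:
    replicon_id: str
    hits: list[HmmHit]          # rank-sorted members
    ranks: list[int]
    wrapped: bool = False       # circular cluster spanning the origin

    @property
    def begin_rank(self) -> int:
        return self.ranks[0]

    @property
    def end_rank(self) -> int:
        return self.ranks[-1]


@dataclass
class MemberGene:
    gene_id: str
    rank: int
    start_bp: int
    end_bp: int
    profile_name: str
    component_name: str
    role: str
    score: float


@dataclass
class CandidateSystem:
    model: SystemModel
    replicon_id: str
    members: list[MemberGene]
    matched_components: dict[str, str]  # component name -> role
    score: float

    @property
    def gene_ids(self) -> frozenset[str]:
        return frozenset(m.gene_id for m in self.members)


@dataclass
class SystemCall:
    sys_id: str
    genome_id: str
    replicon_id: str
    model_name: str
    family: str
    subtype: str
    members: list[MemberGene]
    begin_rank: int
    end_rank: int
    start_bp: int
    end_bp: int
    score: float
    location: str = "chromosome"


def best_hit_per_gene(hits: list[HmmHit]) -> list[HmmHit]:
    """Keep, per gene, the highest-scoring hit; ties broken by profile name."""
    best: dict[str, HmmHit] = {}
    for h in hits:
        cur = best.get(h.gene_id)
        if (cur is None or h.score_bits > cur.score_bits
                or (h.score_bits == cur.score_bits and h.profile_name < cur.profile_name)):
            best[h.gene_id] = h
    return list(best.values())


def cluster_hits(replicon: Replicon, hits: list[HmmHit], window_W: int) -> list[Cluster]:
    """Group hits by co-localization: rank gap - 1 <= window_W joins a cluster."""
    rank_of = {g.gene_id: g.rank for g in replicon.genes}
    ordered = sorted(
        (h for h in hits if h.gene_id in rank_of), key=lambda h: rank_of[h.gene_id]
    )
    if not ordered:
        return []
    clusters: list[Cluster] = []
    cur_hits = [ordered[0]]
    for h in ordered[1:]:
        if rank_of[h.gene_id] - rank_of[cur_hits[-1].gene_id] - 1 <= window_W:
            cur_hits.append(h)
        else:
            clusters.append(Cluster(replicon.replicon_id, cur_hits,
                                    [rank_of[x.gene_id] for x in cur_hits]))
            cur_hits = [h]
    clusters.append(Cluster(replicon.replicon_id, cur_hits,
                            [rank_of[x.gene_id] for x in cur_hits]))

    if replicon.topology == "circular" and len(clusters) > 1:
        n = len(replicon.genes)
        first, last = clusters[0], clusters[-1]
        wrap_gap = (first.begin_rank - 1) + (n - last.end_rank)
        if wrap_gap <= window_W:
            merged = Cluster(replicon.replicon_id, last.hits + first.hits,
                             last.ranks + first.ranks, wrapped=True)
            clusters = [merged] + clusters[1:-1]
    return clusters


def _component_cover(genes: list[tuple[str, str]], model: SystemModel
                     ) -> tuple[dict[str, str], dict[str, str]]:
    """Best assignment of genes to distinct components.

    ``genes`` is [(gene_id, profile_name)].  Each gene may evidence any
    component whose profile set contains its profile, each gene consumed at
    most once and each component counted once.  Among feasible component
    subsets, the one maximizing (mandatory matched, total matched) wins; ties
    resolved by lexicographic component names for determinism.

    Returns (component name -> role for matched components,
             gene_id -> component name for the supporting assignment).
    """
    comps = sorted((c for c in model.components if c.role != "forbidden"),
                   key=lambda c: c.name)
    eligible = {
        c.name: [gid for gid, prof in genes if prof in c.profiles] for c in comps
    }
    role_of = {c.name: c.role for c in comps}
    quorum_comps = [c.name for c in comps if c.role in ("mandatory", "accessory")]

    def matchable(subset: tuple[str, ...]) -> dict[str, str] | None:
        # small bipartite matching: components -> distinct genes
        assignment: dict[str, str] = {}

        def assign(i: int, used: frozenset[str]) -> bool:
            if i == len(subset):
                return True
            for gid in eligible[subset[i]]:
                if gid not in used and assign(i + 1, used | {gid}):
                    assignment[subset[i]] = gid
                    return True
            return False

        return assignment if assign(0, frozenset()) else None

    best_key = (-1, -1)
    best_subset: tuple[str, ...] = ()
    best_assignment: dict[str, str] = {}
    for r in range(len(quorum_comps), -1, -1):
        for subset in itertools.combinations(quorum_comps, r):
            n_mand = sum(1 for c in subset if role_of[c] == "mandatory")
            key = (n_mand, len(subset))
            if key <= best_key:
                continue
            assignment = matchable(subset)
            if assignment is not None:
                best_key, best_subset, best_assignment = key, subset, assignment
    matched = {c: role_of[c] for c in best_subset}
    gene_to_comp = {gid: c for c, gid in best_assignment.items()}
    return matched, gene_to_comp


def evaluate_model(
    clusters: list[Cluster],
    model: SystemModel,
    replicon: Replicon,
    forbidden_hits: list[HmmHit],
) -> CandidateSystem | None:
    """Apply a model's decision rule to one candidate locus.

    ``clusters`` has length 1 for single-locus models; multi-locus models may
    pass the union of clusters on one replicon.  Returns None on rejection.
    """
    all_hits = [h for c in clusters for h in c.hits]
    genes = [(h.gene_id, h.profile_name) for h in all_hits]
    matched, gene_to_comp = _component_cover(genes, model)

    n_mand = sum(1 for role in matched.values() if role == "mandatory")
    n_total = len(matched)
    if n_mand < model.min_mandatory or n_total < model.min_total:
        return None

    # forbidden check: any forbidden hit within each cluster span +/- window_W
    if forbidden_hits:
        rank_of = {g.gene_id: g.rank for g in replicon.genes}
        n = len(replicon.genes)
        for c in clusters:
            lo, hi = c.begin_rank - model.window_W, c.end_rank + model.window_W
            for fh in forbidden_hits:
                r = rank_of.get(fh.gene_id)
                if r is None:
                    continue
                inside = lo <= r <= hi
                if replicon.topology == "circular" and not inside:
                    inside = (r + n <= hi) or (r - n >= lo)
                if inside:
                    return None

    gene_rec = {g.gene_id: g for g in replicon.genes}
    comp_by_profile: dict[str, str] = {}
    for c in sorted(model.components, key=lambda c: c.name):
        if c.role == "forbidden":
            continue
        for p in c.profiles:
            comp_by_profile.setdefault(p, c.name)
    role_of = {c.name: c.role for c in model.components}

    members = []
    for h in all_hits:
        g = gene_rec[h.gene_id]
        comp = gene_to_comp.get(h.gene_id) or comp_by_profile.get(h.profile_name, "")
        members.append(MemberGene(
            g.gene_id, g.rank, g.start_bp, g.end_bp, h.profile_name,
            comp, role_of.get(comp, "neutral"), h.score_bits,
        ))
    members.sort(key=lambda m: m.rank)
    score = score_candidate_counts(n_mand, n_total - n_mand)
    return CandidateSystem(model, replicon.replicon_id, members, matched, score)


def score_candidate_counts(n_mandatory: int, n_accessory: int) -> float:
    return MANDATORY_WEIGHT * n_mandatory + ACCESSORY_WEIGHT * n_accessory


def score_candidate(candidate: CandidateSystem, model: SystemModel | None = None) -> float:
    """1.0 per matched mandatory component + 0.5 per matched accessory."""
    n_mand = sum(1 for r in candidate.matched_components.values() if r == "mandatory")
    n_acc = sum(1 for r in candidate.matched_components.values() if r == "accessory")
    return score_candidate_counts(n_mand, n_acc)


def _candidate_key(c: CandidateSystem) -> tuple:
    return (-c.score, len(c.members), c.model.model_name, c.replicon_id,
            min(m.rank for m in c.members))


def _select_exact(cands: list[CandidateSystem]) -> list[CandidateSystem]:
    order = sorted(cands, key=_candidate_key)
    best_score = -1.0
    best_genes = None
    best_sel: list[CandidateSystem] = []

    def recurse(i: int, sel: list[CandidateSystem], used: frozenset[str], score: float):
        nonlocal best_score, best_genes, best_sel
        if i == len(order):
            n_genes = len(used)
            if score > best_score or (score == best_score and
                                      (best_genes is None or n_genes < best_genes)):
                best_score, best_genes, best_sel = score, n_genes, list(sel)
            return
        c = order[i]
        if not (c.gene_ids & used):
            sel.append(c)
            recurse(i + 1, sel, used | c.gene_ids, score + c.score)
            sel.pop()
        recurse(i + 1, sel, used, score)

    recurse(0, [], frozenset(), 0.0)
    return best_sel


def _select_greedy(cands: list[CandidateSystem]) -> list[CandidateSystem]:
    selected: list[CandidateSystem] = []
    used: set[str] = set()
    for c in sorted(cands, key=_candidate_key):
        if not (c.gene_ids & used):
            selected.append(c)
            used |= c.gene_ids
    return selected


def resolve_overlaps(candidates: list[CandidateSystem],
                     genome_id: str = "genome") -> list[SystemCall]:
    """Select a gene-disjoint candidate subset of maximal summed score.

    Conflict components with <= 20 candidates are solved exactly by
    exhaustive subset search (ties: fewer total genes, then deterministic
    candidate order); larger components fall back to a greedy sweep by
    (score desc, fewer genes, model name).
    """
    # connected conflict components via shared genes
    parent = list(range(len(candidates)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    by_gene: dict[str, int] = {}
    for i, c in enumerate(candidates):
        for gid in c.gene_ids:
            if gid in by_gene:
                ri, rj = find(i), find(by_gene[gid])
                parent[ri] = rj
            else:
                by_gene[gid] = i

    groups: dict[int, list[CandidateSystem]] = {}
    for i, c in enumerate(candidates):
        groups.setdefault(find(i), []).append(c)

    selected: list[CandidateSystem] = []
    for group in groups.values():
        if len(group) <= EXACT_RESOLUTION_LIMIT:
            selected.extend(_select_exact(group))
        else:
            selected.extend(_select_greedy(group))

    selected.sort(key=lambda c: (c.replicon_id, min(m.rank for m in c.members)))
    ordinals: dict[str, int] = {}
    calls = []
    for c in selected:
        ordinals[c.model.model_name] = ordinals.get(c.model.model_name, 0) + 1
        sys_id = f"{genome_id}_{c.model.model_name}_{ordinals[c.model.model_name]}"
        calls.append(SystemCall(
            sys_id=sys_id,
            genome_id=genome_id,
            replicon_id=c.replicon_id,
            model_name=c.model.model_name,
            family=c.model.family,
            subtype=c.model.subtype,
            members=c.members,
            begin_rank=min(m.rank for m in c.members),
            end_rank=max(m.rank for m in c.members),
            start_bp=min(m.start_bp for m in c.members),
            end_bp=max(m.end_bp for m in c.members),
            score=c.score,
        ))
    return calls


def detect(replicons: list[Replicon], registry: Registry, hits: list[HmmHit],
           genome_id: str = "genome") -> list[SystemCall]:
    """Full decision-rule pass: hits in, gene-disjoint system calls out.

    ``hits`` must carry GA flags (run ``registry.annotate_ga`` on parsed
    tables first); only GA-passing hits are considered.  A genome may yield
    several calls of the same (sub)type when they are gene-disjoint.
    """
    ga_hits = apply_ga_filter(hits)
    candidates: list[CandidateSystem] = []
    for model in sorted(registry.models, key=lambda m: m.model_name):
        det_profiles = model.detection_profiles
        forb_profiles = model.forbidden_profiles
        model_hits = [h for h in ga_hits if h.profile_name in det_profiles]
        for rep in replicons:
            rep_gene_ids = {g.gene_id for g in rep.genes}
            rep_hits = [h for h in model_hits if h.gene_id in rep_gene_ids]
            if not rep_hits:
                continue
            forb_hits = [h for h in ga_hits
                         if h.profile_name in forb_profiles and h.gene_id in rep_gene_ids]
            best = best_hit_per_gene(rep_hits)
            clusters = cluster_hits(rep, best, model.window_W)
            if model.multi_loci and clusters:
                cand = evaluate_model(clusters, model, rep, forb_hits)
                if cand is not None:
                    candidates.append(cand)
            else:
                for cl in clusters:
                    cand = evaluate_model([cl], model, rep, forb_hits)
                    if cand is not None:
                        candidates.append(cand)
    calls = resolve_overlaps(candidates, genome_id)
    logger.info("genome %s: %d candidate(s), %d call(s)", genome_id,
                len(candidates), len(calls))
    return calls
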