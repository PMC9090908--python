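"""Census statistics over detected systems: arsenals, spans, locations,
distances, associations and validation metrics.

The "arsenal" of a genome is the multiset of defense systems it encodes,
summarized per genome as counts by (sub)type and by family.  This module
computes the downstream statistics of the census: per-genome counts and
family diversity, system spans and prophage co-location, Bray-Curtis
distances between arsenals, rank correlations with genome features (with
Bonferroni adjustment), forward-selection regression controls, per-group
system frequencies, and sensitivity/specificity-style validation against a
reference call set.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model_registry import Registry


@dataclass
class ArsenalProfile:
    """Per-genome vector of system counts keyed by (sub)type and by family."""

    genome_id: str
    counts_by_subtype: dict[str, int] = field(default_factory=dict)
    counts_by_family: dict[str, int] = field(default_factory=dict)
    genome_size_bp: int | None = None
    n_prophages: int | None = None

    @property
    def n_systems(self) -> int:
        return sum(self.counts_by_subtype.values())

    @property
    def n_families(self) -> int:
        return sum(1 for v in self.counts_by_family.values() if v > 0)


@dataclass
class ProphageRegion:
    replicon_id: str
    start_bp: int
    end_bp: int
    max_score: float = 1.0

    def __post_init__(self):
        if self.end_bp < self.start_bp:
            raise ValueError("prophage region: end_bp < start_bp")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass
class ValidationMetrics:
    sensitivity: float | None
    extra_call_ratio: float | None   # verbatim "specificity" ratio: share of
    # reference-negative genomes where a system is nevertheless called
    specificity_complement: float | None  # 1 - extra_call_ratio
    n_detected: int
    n_reference: int
    n_extra_genomes: int
    n_negative_genomes: int


@dataclass
class AssociationResult:
    rho: float | None
    p_value: float | None
    n: int
    adjusted_p: float | None
    undefined: bool = False


# -- spans and locations -----------------------------------------------------

def system_span(call) -> int:
    """System size in bp: end of the last protein minus beginning of the
    first (the literal difference, translation-invariant)."""
    return int(call.end_bp - call.start_bp)


def assign_location(call, prophages: list[ProphageRegion]) -> str:
    """'prophage' iff first and last protein lie inside one prophage region
    (inclusive boundaries, same replicon); partial overlap is chromosomal."""
    for region in prophages:
        if region.replicon_id != call.replicon_id:
            continue
        if call.start_bp >= region.start_bp and call.end_bp <= region.end_bp:
            return "prophage"
    return "chromosome"


def filter_prophage_predictions(rows) -> list[ProphageRegion]:
    """Keep confident predictions only: max score strictly > 0.8 and size
    strictly < 200 kb (less confident rows may be remnants or artifacts).

    Accepts ProphageRegion objects or a DataFrame with columns replicon_id,
    start_bp, end_bp, max_score.
    """
    if isinstance(rows, pd.DataFrame):
        rows = [ProphageRegion(str(r.replicon_id), int(r.start_bp),
                               int(r.end_bp), float(r.max_score))
                for r in rows.itertuples()]
    return [r for r in rows if r.max_score > 0.8 and r.length_bp < 200_000]


# -- arsenals ---------------------------------------------------------------

def arsenal_profiles(calls, registry: Registry | None = None,
                     metadata: pd.DataFrame | None = None,
                     all_genomes: list[str] | None = None) -> list[ArsenalProfile]:
    """Summarize calls into one arsenal per genome.

    ``calls`` may be SystemCall objects or a systems.tsv DataFrame.  Genomes
    listed in ``all_genomes`` (or in the metadata) but without calls are
    included with zero counts.
    """
    if isinstance(calls, pd.DataFrame):
        records = [(str(r.genome_id), str(r.model_name), str(r.family))
                   for r in calls.itertuples()]
    else:
        records = [(c.genome_id, c.model_name, c.family) for c in calls]

    genomes: dict[str, ArsenalProfile] = {}
    ids = list(all_genomes or [])
    if metadata is not None and "genome_id" in metadata.columns:
        ids.extend(str(g) for g in metadata["genome_id"])
    for gid in ids:
        genomes.setdefault(gid, ArsenalProfile(gid))
    for gid, model, family in records:
        prof = genomes.setdefault(gid, ArsenalProfile(gid))
        prof.counts_by_subtype[model] = prof.counts_by_subtype.get(model, 0) + 1
        prof.counts_by_family[family] = prof.counts_by_family.get(family, 0) + 1
    if metadata is not None:
        meta = metadata.set_index(metadata["genome_id"].astype(str))
        for gid, prof in genomes.items():
            if gid in meta.index:
                row = meta.loc[gid]
                if "genome_size_bp" in meta.columns and pd.notna(row["genome_size_bp"]):
                    prof.genome_size_bp = int(row["genome_size_bp"])
                if "n_prophages" in meta.columns and pd.notna(row["n_prophages"]):
                    prof.n_prophages = int(row["n_prophages"])
    return [genomes[g] for g in sorted(genomes)]


def bray_curtis(a: ArsenalProfile, b: ArsenalProfile) -> float:
    """Bray-Curtis dissimilarity between two arsenals on subtype counts:
    ``1 - 2 * sum(min(a_k, b_k)) / (sum a + sum b)``; two empty arsenals are
    identical (distance 0)."""
    ca, cb = Counter(a.counts_by_subtype), Counter(b.counts_by_subtype)
    total = sum(ca.values()) + sum(cb.values())
    if total == 0:
        return 0.0
    shared = sum(min(ca[k], cb[k]) for k in set(ca) | set(cb))
    return 1.0 - 2.0 * shared / total


# -- associations ------------------------------------------------------------

def spearman_assoc(x, y, m_tests: int = 1) -> AssociationResult:
    """Two-sided Spearman rank correlation with Bonferroni adjustment.

    Average ranks for ties; p-value from the t approximation.  A constant
    vector leaves rho undefined (flagged, not raised).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return AssociationResult(None, None, int(x.size), None, undefined=True)
    res = stats.spearmanr(x, y)
    adj = min(1.0, float(res.pvalue) * m_tests)
    return AssociationResult(float(res.statistic), float(res.pvalue),
                             int(x.size), adj)


def pearson_assoc(x, y, m_tests: int = 1) -> AssociationResult:
    """Two-sided Pearson correlation (species-level analyses use it too)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return AssociationResult(None, None, int(x.size), None, undefined=True)
    r, p = stats.pearsonr(x, y)
    return AssociationResult(float(r), float(p), int(x.size), min(1.0, float(p) * m_tests))


def covariate_adjusted_association(x, y, covariate, alpha: float = 0.05) -> dict:
    """Forward-selection OLS control: is x informative about y beyond the
    covariate?

    Forward selection over {covariate, x}: at each step the candidate whose
    addition gives the smallest partial-F p-value enters if p < alpha.  The
    report states the selection order and whether x is significant when added
    after the covariate (partial F-test).  Collinear inputs are flagged.
    """
    import statsmodels.api as sm

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cov = np.asarray(covariate, dtype=float)
    if not (x.shape == y.shape == cov.shape):
        raise ValueError("x, y, covariate must have equal length")

    X_full = np.column_stack([cov, x])
    collinear = np.linalg.matrix_rank(np.column_stack([np.ones_like(x), X_full])) < 3

    def fit(cols: list[np.ndarray]):
        X = sm.add_constant(np.column_stack(cols)) if cols else np.ones((len(y), 1))
        return sm.OLS(y, X).fit()

    def partial_f(base_model, full_model, df_added: int = 1):
        ssr_red, ssr_full = base_model.ssr, full_model.ssr
        df_resid = full_model.df_resid
        if df_resid <= 0 or ssr_full <= 0:
            return math.inf, 0.0
        F = ((ssr_red - ssr_full) / df_added) / (ssr_full / df_resid)
        return F, float(stats.f.sf(F, df_added, df_resid))

    names = ["covariate", "x"]
    terms = {"covariate": cov, "x": x}
    null_model = fit([])
    selected: list[str] = []
    current = null_model
    steps = []
    while True:
        candidates = []
        for name in names:
            if name in selected:
                continue
            trial = fit([terms[t] for t in selected] + [terms[name]])
            F, p = partial_f(current, trial)
            candidates.append((p, name, trial, F))
        if not candidates:
            break
        candidates.sort(key=lambda t: (t[0], t[1]))
        p, name, trial, F = candidates[0]
        if p < alpha and not (collinear and name == "x" and "covariate" in selected):
            selected.append(name)
            steps.append({"term": name, "partial_F": F, "p_value": p})
            current = trial
        else:
            break

    # the headline control: x added after the covariate
    base = fit([cov])
    full = fit([cov, x])
    F_x, p_x = partial_f(base, full)
    return {
        "selected": selected,
        "steps": steps,
        "x_selected": "x" in selected,
        "x_partial_F_given_covariate": None if collinear else F_x,
        "x_p_value_given_covariate": None if collinear else p_x,
        "x_significant_given_covariate": (not collinear) and (p_x < alpha),
        "collinear": bool(collinear),
        "alpha": alpha,
    }


# -- validation --------------------------------------------------------------

def _call_keys(calls) -> list[tuple[str, str]]:
    if isinstance(calls, pd.DataFrame):
        return [(str(r.genome_id), str(r.model_name)) for r in calls.itertuples()]
    return [(c.genome_id, c.model_name) for c in calls]


def validation_metrics(reference_calls, our_calls, per: str = "system",
                       all_genomes: list[str] | None = None) -> ValidationMetrics:
    """Sensitivity and the quoted extra-call ratio against a reference.

    Sensitivity (system level): the fraction of reference systems that we
    also detect, matching (genome, model) as multisets.  The second quantity
    is computed verbatim as defined in the source validation protocol — the
    number of reference-negative genomes where we call at least one system,
    over all reference-negative genomes — and is reported alongside its
    complement, which behaves like a conventional specificity.
    """
    if per not in {"system", "genome"}:
        raise ValueError("per must be 'system' or 'genome'")
    ref = Counter(_call_keys(reference_calls))
    ours = Counter(_call_keys(our_calls))
    if per == "genome":
        ref = Counter(set(ref))
        ours = Counter(set(ours))
    n_reference = sum(ref.values())
    n_detected = sum((ref & ours).values())
    sensitivity = (n_detected / n_reference) if n_reference else None

    genomes = set(all_genomes or []) | {g for g, _ in ref} | {g for g, _ in ours}
    ref_pos = {g for g, _ in ref}
    our_pos = {g for g, _ in ours}
    negatives = genomes - ref_pos
    n_extra = len(negatives & our_pos)
    ratio = (n_extra / len(negatives)) if negatives else None
    return ValidationMetrics(
        sensitivity=sensitivity,
        extra_call_ratio=ratio,
        specificity_complement=(1.0 - ratio) if ratio is not None else None,
        n_detected=n_detected,
        n_reference=n_reference,
        n_extra_genomes=n_extra,
        n_negative_genomes=len(negatives),
    )


# -- frequency tables --------------------------------------------------------

def frequency_table(profiles: list[ArsenalProfile],
                    metadata: pd.DataFrame | None = None,
                    group_by: str = "all",
                    min_group_size: int = 1) -> pd.DataFrame:
    """Per-group frequency of genomes carrying >= 1 system of each family.

    ``group_by`` is 'all' or a metadata column (e.g. phylum, species); groups
    smaller than ``min_group_size`` genomes are dropped.  Cells lie in [0, 1]
    and are invariant to genome ordering.
    """
    if group_by == "all":
        group_of = {p.genome_id: "all" for p in profiles}
    else:
        if metadata is None or group_by not in metadata.columns:
            raise ValueError(f"metadata column {group_by!r} required for grouping")
        group_of = dict(zip(metadata["genome_id"].astype(str),
                            metadata[group_by].astype(str)))
    families = sorted({f for p in profiles for f in p.counts_by_family})
    groups: dict[str, list[ArsenalProfile]] = {}
    for p in profiles:
        g = group_of.get(p.genome_id)
        if g is not None:
            groups.setdefault(g, []).append(p)
    groups = {g: ps for g, ps in groups.items() if len(ps) >= min_group_size}
    data = {
        g: [np.mean([p.counts_by_family.get(f, 0) > 0 for p in ps]) for f in families]
        for g, ps in sorted(groups.items())
    }
    return pd.DataFrame(data, index=families)
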