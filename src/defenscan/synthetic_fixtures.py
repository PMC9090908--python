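"""Synthetic ordered proteomes with planted defense systems and truth tables.

Every stage of the pipeline is testable without downloads: this module
generates toy decision-rule registries with their own profiles, calibrates
per-profile gathering thresholds, and emits ordered proteomes in which
multi-gene systems are planted at known ranks among composition-matched
decoys, together with the truth table of expected calls, prophage intervals
and genome metadata.

Null model: decoys are residue-shuffled copies of true component sequences,
so they match the true sequences' composition — the hardest null that keeps
threshold calibration honest.  True-family variants are consensus sequences
with independent per-site substitution at 5% to a uniformly random residue
and no indels.  Each genome draws from its own RNG stream derived from
(master seed, genome index), so corpora are reproducible under parallel
generation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .arsenal_analysis import ProphageRegion
from .io_gembase import GeneRecord, Replicon, write_ordered_fasta
from .model_registry import (MECHANISMS, ComponentDef, Registry, SystemModel,
                             write_registry)
from .profile_hmm import ALPHABET, build_profile_from_alignment, viterbi_local_score

DEFAULT_MUTATION_RATE = 0.05
DEFAULT_WINDOW = 5


class CalibrationError(RuntimeError):
    """True and decoy score distributions overlap; no separating GA exists."""


@dataclass
class PlantSpec:
    """One system planted into a genome.

    ``insert_rank`` is the rank of the system's first gene; ``spacer_genes``
    decoys are placed between successive member genes (keep <= window_W for
    plants intended to be detected).
    """

    model_name: str
    completeness: str = "intact"  # intact | missing_mandatory | missing_accessory
    insert_rank: int = 1
    spacer_genes: int = 0
    inside_prophage: bool = False

    def __post_init__(self):
        if self.completeness not in {"intact", "missing_mandatory", "missing_accessory"}:
            raise ValueError(f"unknown completeness {self.completeness!r}")


@dataclass
class ToyKit:
    """A toy registry plus the consensus sequences behind its profiles."""

    registry: Registry
    consensus: dict[str, str]
    mutation_rate: float = DEFAULT_MUTATION_RATE


@dataclass
class GenomeSim:
    """One simulated genome with its ground truth."""

    genome_id: str
    replicon: Replicon
    truth_calls: list[dict] = field(default_factory=list)
    prophages: list[ProphageRegion] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(ALPHABET), size=length))


def mutate_sequence(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Independent per-site substitution at ``rate`` to a uniformly random
    residue (which may equal the original); no indels."""
    out = list(seq)
    hits = rng.random(len(seq)) < rate
    for i in np.flatnonzero(hits):
        out[i] = ALPHABET[rng.integers(20)]
    return "".join(out)


def shuffle_sequence(seq: str, rng: np.random.Generator) -> str:
    return "".join(rng.permutation(list(seq)))


# -- toy registries ----------------------------------------------------------

def generate_toy_registry(n_models: int, seed: int,
                          profile_length_range: tuple[int, int] = (50, 70),
                          n_alignment_rows: int = 8,
                          window_W: int = DEFAULT_WINDOW) -> ToyKit:
    """Generate ``n_models`` toy system models with their own profiles.

    Models carry 2-5 components; across the registry all four roles occur
    (two mandatory components always; accessory from three components up;
    forbidden from four; a neutral fifth).  Some components accept two
    interchangeable profiles.  GA thresholds are placeholders (0) until
    :func:`calibrate_ga` is run.  Deterministic for a fixed seed.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    rng = np.random.default_rng(seed)
    models = []
    manifest: dict[str, dict] = {}
    profiles: dict = {}
    consensus: dict[str, str] = {}

    role_plan = ["mandatory", "mandatory", "accessory", "forbidden", "neutral"]
    comp_names = ["core1", "core2", "acc1", "forb1", "extra1"]

    for i in range(n_models):
        fam = f"ToyFam{i + 1}"
        n_comp = 2 + (i % 4)  # cycles 2..5
        components = []
        for j in range(n_comp):
            # interchangeable homologs on the first mandatory component of
            # every other model
            n_prof = 2 if (j == 0 and i % 2 == 1) else 1
            prof_names = []
            for v in range(n_prof):
                pname = f"{fam}_{comp_names[j]}_p{v + 1}"
                length = int(rng.integers(profile_length_range[0],
                                          profile_length_range[1] + 1))
                cons = _random_sequence(rng, length)
                aln = [cons] + [mutate_sequence(cons, DEFAULT_MUTATION_RATE, rng)
                                for _ in range(n_alignment_rows - 1)]
                prof = build_profile_from_alignment(aln, pname, GA_bits=0.0)
                profiles[pname] = prof
                consensus[pname] = cons
                manifest[pname] = {"GA_bits": 0.0, "source": "toy"}
                prof_names.append(pname)
            components.append(ComponentDef(comp_names[j], role_plan[j],
                                           tuple(prof_names)))
        models.append(SystemModel(
            model_name=f"{fam}-I", family=fam, subtype=f"{fam}-I",
            components=components, window_W=window_W,
            mechanism=MECHANISMS[i % len(MECHANISMS)],
        ))
    registry = Registry(models, manifest, profiles)
    return ToyKit(registry, consensus)


def calibrate_ga(kit: ToyKit, n_decoys: int = 200, n_true: int = 100,
                 seed: int = 0, mutation_rate: float | None = None) -> ToyKit:
    """Set each profile's GA to the midpoint between true and decoy scores.

    For every profile, true scores come from ``n_true`` mutated copies of its
    consensus; decoy scores from ``n_decoys`` residue-shuffled true sequences
    plus one mutated variant of every *other* profile's consensus (so that
    cross-profile hits also stay below threshold).  GA = midpoint of the
    minimum true score and the maximum decoy score, guaranteeing separation
    on the generated population.  Overlapping distributions raise
    :class:`CalibrationError`.
    """
    rate = kit.mutation_rate if mutation_rate is None else mutation_rate
    rng = np.random.default_rng(seed)
    names = sorted(kit.consensus)
    for pname in names:
        prof = kit.registry.profiles[pname]
        cons = kit.consensus[pname]
        true_scores = [viterbi_local_score(prof, mutate_sequence(cons, rate, rng))
                       for _ in range(n_true)]
        decoys = [shuffle_sequence(kit.consensus[names[i % len(names)]], rng)
                  for i in range(n_decoys)]
        decoys += [mutate_sequence(kit.consensus[q], rate, rng)
                   for q in names if q != pname]
        decoy_scores = [viterbi_local_score(prof, d) for d in decoys]
        lo_true = min(true_scores)
        if not decoy_scores:
            warnings.warn(f"{pname}: empty decoy set, GA degenerates to the "
                          "minimum true score")
            ga = lo_true
        else:
            hi_decoy = max(decoy_scores)
            if lo_true <= hi_decoy:
                raise CalibrationError(
                    f"{pname}: true scores (min {lo_true:.1f}) overlap decoy "
                    f"scores (max {hi_decoy:.1f}); no separating GA"
                )
            ga = 0.5 * (lo_true + hi_decoy)
        prof.GA_bits = ga
        kit.registry.profile_manifest[pname]["GA_bits"] = ga
    return kit


# -- genome generation -------------------------------------------------------

def _plant_genes(model: SystemModel, completeness: str, kit: ToyKit,
                 rng: np.random.Generator) -> list[tuple[str, str]]:
    """(profile_name, sequence) per planted gene, in component order."""
    comps = [c for c in model.components if c.role in ("mandatory", "accessory")]
    if completeness == "missing_mandatory":
        dropped = [c for c in comps if c.role == "mandatory"][-1]
        comps = [c for c in comps if c is not dropped]
    elif completeness == "missing_accessory":
        comps = [c for c in comps if c.role != "accessory"]
    out = []
    for c in comps:
        pname = c.profiles[0]
        out.append((pname, mutate_sequence(kit.consensus[pname],
                                           kit.mutation_rate, rng)))
    return out


def generate_genome(plants: list[PlantSpec], n_background: int,
                    kit: ToyKit, seed: int, genome_id: str = "genomeS",
                    prophage_spec: list[ProphageRegion] | None = None,
                    topology: str = "linear") -> GenomeSim:
    """Assemble one ordered proteome with planted systems and decoys.

    Background genes are residue-shuffled copies of randomly chosen true
    component sequences.  Base-pair coordinates follow the 1 kb grid used for
    coordinate-free input.  Prophage intervals cover plants flagged
    ``inside_prophage`` end to end; extra regions may be supplied via
    ``prophage_spec``.  Overlapping plants are rejected.
    """
    rng = np.random.default_rng(seed)
    replicon_id = f"{genome_id}_r1"
    names = sorted(kit.consensus)

    def decoy_seq() -> str:
        return shuffle_sequence(kit.consensus[names[rng.integers(len(names))]], rng)

    # lay out plant blocks (member genes with interleaved spacer decoys)
    blocks: list[tuple[int, PlantSpec, list[tuple[str | None, str]]]] = []
    for spec in sorted(plants, key=lambda p: p.insert_rank):
        model = kit.registry.get_model(spec.model_name)
        genes = _plant_genes(model, spec.completeness, kit, rng)
        block: list[tuple[str | None, str]] = []
        for gi, (pname, seq) in enumerate(genes):
            if gi > 0:
                block.extend((None, decoy_seq()) for _ in range(spec.spacer_genes))
            block.append((pname, seq))
        blocks.append((spec.insert_rank, spec, block))

    for (r1, s1, b1), (r2, s2, b2) in zip(blocks, blocks[1:]):
        if r1 + len(b1) > r2:
            raise ValueError(
                f"overlapping plants: {s1.model_name}@{r1} and {s2.model_name}@{r2}"
            )

    total = n_background + sum(len(b) for _, _, b in blocks)
    if blocks and blocks[-1][0] + len(blocks[-1][2]) - 1 > total:
        raise ValueError("plant insert_rank beyond genome length")

    slots: list[tuple[str | None, str] | None] = [None] * total
    for r, _, block in blocks:
        for off, item in enumerate(block):
            if slots[r - 1 + off] is not None:
                raise ValueError("overlapping plants")
            slots[r - 1 + off] = item
    for i in range(total):
        if slots[i] is None:
            slots[i] = (None, decoy_seq())

    genes: list[GeneRecord] = []
    gene_profile: dict[int, str | None] = {}
    for rank, (pname, seq) in enumerate(slots, start=1):
        start_bp = (rank - 1) * 1000 + 1
        end_bp = start_bp + 3 * len(seq) - 1
        gid = f"{genome_id}_g{rank:04d}"
        genes.append(GeneRecord(gid, replicon_id, rank, start_bp, end_bp, "+", seq))
        gene_profile[rank] = pname
    replicon = Replicon(replicon_id, genes, topology)

    truth_calls = []
    prophages = list(prophage_spec or [])
    for r, spec, block in blocks:
        member_ranks = [r + off for off, (pname, _) in enumerate(block)
                        if pname is not None]
        member_ids = [genes[k - 1].gene_id for k in member_ranks]
        start_bp = genes[member_ranks[0] - 1].start_bp
        end_bp = genes[member_ranks[-1] - 1].end_bp
        if spec.inside_prophage:
            prophages.append(ProphageRegion(replicon_id,
                                            max(1, start_bp - 500),
                                            end_bp + 500, 0.95))
        if spec.completeness != "missing_mandatory":
            truth_calls.append({
                "genome_id": genome_id,
                "replicon_id": replicon_id,
                "model_name": spec.model_name,
                "gene_ids": member_ids,
                "begin_rank": member_ranks[0],
                "end_rank": member_ranks[-1],
                "start_bp": start_bp,
                "end_bp": end_bp,
                "span_bp": end_bp - start_bp,
                "expected_location": "prophage" if spec.inside_prophage
                                     else "chromosome",
            })

    metadata = {
        "genome_id": genome_id,
        "species": "Toyus syntheticus",
        "phylum": "Toyphyla",
        "genome_size_bp": genes[-1].end_bp if genes else 0,
        "n_prophages": len(prophages),
        "replicon_type": "chromosome",
    }
    return GenomeSim(genome_id, replicon, truth_calls, prophages, metadata)


def generate_benchmark(n_genomes: int, family_frequencies: dict[str, float],
                       kit: ToyKit, seed: int, n_background: int = 30,
                       prophage_fraction: float = 0.2) -> list[GenomeSim]:
    """A corpus of genomes, each planting each model independently at its
    stated frequency.

    Planted systems occupy random non-adjacent positions; a planted system is
    placed inside a prophage with probability ``prophage_fraction``.  One RNG
    stream per genome, derived from (seed, genome index).
    """
    for m, f in family_frequencies.items():
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"frequency for {m} outside [0, 1]")
    sims = []
    for i in range(n_genomes):
        rng = np.random.default_rng([seed, i])
        gid = f"genome{i + 1:04d}"
        plants = []
        next_rank = 1
        for model_name in sorted(family_frequencies):
            if rng.random() >= family_frequencies[model_name]:
                continue
            spacers = int(rng.integers(0, 2))
            model = kit.registry.get_model(model_name)
            n_genes = sum(1 for c in model.components
                          if c.role in ("mandatory", "accessory"))
            block_len = n_genes + spacers * (n_genes - 1)
            insert = next_rank + int(rng.integers(0, 4))
            plants.append(PlantSpec(
                model_name, "intact", insert, spacers,
                inside_prophage=bool(rng.random() < prophage_fraction),
            ))
            next_rank = insert + block_len + 1
        sims.append(generate_genome(plants, n_background, kit,
                                    seed=int(rng.integers(2**31)),
                                    genome_id=gid))
    return sims


# -- corpus serialization ----------------------------------------------------

def truth_table(sims: list[GenomeSim]) -> pd.DataFrame:
    rows = []
    for sim in sims:
        for call in sim.truth_calls:
            row = dict(call)
            row["gene_ids"] = ",".join(row["gene_ids"])
            rows.append(row)
    cols = ["genome_id", "replicon_id", "model_name", "gene_ids", "begin_rank",
            "end_rank", "start_bp", "end_bp", "span_bp", "expected_location"]
    return pd.DataFrame(rows, columns=cols)


def write_corpus(sims: list[GenomeSim], kit: ToyKit, out_dir: str | Path) -> None:
    """Emit genomes/*.faa, registry/, truth.tsv, prophages.tsv, metadata.tsv."""
    out_dir = Path(out_dir)
    (out_dir / "genomes").mkdir(parents=True, exist_ok=True)
    for sim in sims:
        write_ordered_fasta([sim.replicon], out_dir / "genomes" / f"{sim.genome_id}.faa")
    write_registry(kit.registry, out_dir / "registry")
    truth_table(sims).to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"replicon_id": p.replicon_id, "start_bp": p.start_bp,
          "end_bp": p.end_bp, "max_score": p.max_score}
         for sim in sims for p in sim.prophages],
        columns=["replicon_id", "start_bp", "end_bp", "max_score"],
    ).to_csv(out_dir / "prophages.tsv", sep="\t", index=False)
    pd.DataFrame([sim.metadata for sim in sims]).to_csv(
        out_dir / "metadata.tsv", sep="\t", index=False)
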