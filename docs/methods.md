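# Methods

## Detection model

`defenscan` treats a defense system as a *macromolecular system*: a set of
protein components encoded close together on a replicon, described by a
declarative decision rule rather than code. Detection has two stages.

### Profile scoring

Proteins are scored against position-specific profiles: per match state,
log-odds emissions in bits relative to a uniform 1/20 amino-acid
background. The scorer maximizes over *local* alignments under a fixed,
deliberately simplified plan-7-like scheme:

- free entry before any match state and free exit after any match state
  (unaligned profile and sequence flanks cost nothing);
- insert emissions at background (0 bits);
- every transition into an insert state (M→I, I→I) costs −1 bit; every
  transition into a delete state (M→D, D→D) costs −1 bit; transitions into
  match states are free; I↔D transitions are disallowed;
- an alignment starts and ends on a match state and matches ≥ 1 residue; an
  empty sequence scores −∞ ("no hit").

The maximization is exact (Viterbi dynamic programme, vectorized across
sequences) and is verified in the test suite against brute-force enumeration
of every alignment path for all small profiles (M ≤ 4) and sequences
(length ≤ 6). The fixed transition costs make the scorer self-contained and
oracle-testable; the price is that its bit scores are *not* numerically
comparable with HMMER's (which fits per-profile transition and insert
probabilities and adds a null-model correction). Genuine HMMER3 ASCII
profiles can be imported: NAME/LENG/GA and the match emissions are read and
converted to this scheme, and GA thresholds imported this way should be
re-examined because of the scheme difference.

There is no E-value machinery. Filtering is purely by the per-profile
gathering threshold GA in bits on the full-sequence score, with `score ≥ GA`
passing (the `--cut_ga` convention; a hit exactly at the threshold is
significant). Domain i-E-values from ingested `hmmsearch --domtblout` tables
are carried through for reporting but never used for filtering. When a gene
has several domains against one profile, the maximum full-sequence score is
kept: the decision rules operate per (gene, profile) pair.

Non-standard residues (X, B, Z, U, …) emit at background (0 bits) — neutral
handling that neither rewards nor penalizes ambiguity.

### Decision rules

A system model lists components with roles — **mandatory**, **accessory**,
**forbidden**, plus a *neutral* role for registry plumbing — each with a
non-empty set of interchangeable profiles, a quorum and a window:

- `window_W` (default 5): maximum number of *intervening genes* between two
  successive member hits of one cluster (rank gap − 1 ≤ W). Counting genes
  rather than base pairs is robust to gene-length variation. Circular
  replicons wrap the gap across the origin.
- `min_mandatory` (default: *all* mandatory components) and `min_total`
  (default: `min_mandatory`): distinct components that must be matched.
  The defaults are conservative full-system detection; registries for
  large, variable systems can relax them per model. `min_total` counts
  mandatory + accessory components; neutral components are reported as
  cluster members but never count toward quorum or score.
- forbidden components veto a candidate when one of their profiles has a
  GA-passing hit within the cluster span extended by `window_W` genes on
  each side. The radius is a design choice — the role itself implies no
  particular distance.
- `multi_loci` (default false): when set, all clusters of the model on one
  replicon are pooled before quorum evaluation (never across replicons).

Component matching assigns each gene (with its single best GA-passing hit,
ties broken by lexicographic profile name) to at most one component; among
feasible component subsets the engine maximizes mandatory matches first,
then total matches, via exhaustive subset search with a small bipartite
matching check (component counts per model are small, ≤ ~10).

Candidate score = 1.0 per matched mandatory + 0.5 per matched accessory
component. These weights echo common macromolecular-system annotation
practice; only their relative order matters, because the score's sole use is
overlap resolution. Overlaps across models are resolved to a gene-disjoint
candidate subset of maximal summed score: exact branch-and-bound within each
connected conflict component of ≤ 20 candidates (ties: fewer total genes,
then a deterministic candidate order), greedy by (score desc, fewer genes,
model name) beyond — the threshold keeps the exact search under 2²⁰ subsets.
Multiple gene-disjoint instances of the same (sub)type in one genome are
reported separately: a census counts systems, not presence/absence.

Systems never span replicon boundaries.

## Census statistics

- **Arsenal profiles**: per genome, counts by (sub)type and by family;
  `n_systems = Σ counts`, `n_families` = families with count > 0. Genomes
  with zero calls are kept with zeros.
- **Span**: `end_bp − start_bp` over a call's members — the literal
  coordinate difference (not +1), translation-invariant.
- **Prophage co-location**: a system is prophage-encoded iff its first and
  last protein lie inside one prophage interval, boundaries inclusive;
  partial overlap counts as chromosomal. Prophage predictions are
  pre-filtered with strict inequalities: max score > 0.8 and length
  < 200 kb. Replicon type is metadata; span/location comparisons are meant
  for chromosomal replicons (plasmid calls can be excluded via metadata).
- **Bray-Curtis** between arsenals on subtype-count vectors:
  `1 − 2·Σ min(aₖ,bₖ)/(Σaₖ+Σbₖ)`; two empty arsenals have distance 0
  (identical emptiness). Cross-checked against `scipy.spatial.distance` in
  the tests.
- **Associations**: two-sided Spearman via average ranks and the
  t-approximation (`scipy.stats.spearmanr`), Bonferroni-adjusted
  (`min(1, p·m)`); Pearson is available for species-level analyses.
  Constant vectors leave ρ undefined and are flagged rather than raised.
- **Covariate control**: "is x informative about y beyond a covariate?"
  is realized as forward OLS selection over {covariate, x} with a partial
  F-test at α = 0.05 (statsmodels), reporting the selection order and the
  significance of x given the covariate. Collinear inputs are flagged, not
  fatal.
- **Validation**: system-level sensitivity = |detected ∩ reference| /
  |reference|, matching (genome, model) as multisets. The companion
  quantity is computed verbatim as the share of reference-negative genomes
  where the tool nevertheless calls a system (an extra-call rate); its
  complement, which behaves like a conventional specificity, is reported
  alongside, and neither is silently substituted for the other. Ratios are
  reported as exact quotients, not re-rounded to chase any particular
  printed precision. An empty reference leaves sensitivity undefined.
- **Frequency tables**: per group (phylum, species, or all), the fraction
  of genomes carrying ≥ 1 system of each family; small groups can be
  dropped via a minimum group size.

## Synthetic fixtures

The generator emulates what detection actually consumes: *ordered*
proteomes with multi-gene systems planted among decoys.

- Toy registries: 2–5 components per model covering all roles, some
  components with two interchangeable profiles; profiles are built from toy
  alignments (a random consensus of 50–70 residues plus 7 variants mutated
  at 5%) with the ≥ 50% column-occupancy rule (ties kept) and add-one
  pseudocount emissions `log2(((count+1)/(n+20))·20)`.
- GA calibration: per profile, GA = midpoint between the minimum score of
  sampled true variants (5% per-site substitution) and the maximum score
  over residue-shuffled decoys plus one variant of every other profile's
  consensus. This guarantees separation on the generated population and
  keeps cross-profile hits below threshold; overlapping distributions are a
  hard error. This is an automated surrogate for manual threshold curation
  by score-distribution inspection, which has no reproducible rule.
- Decoys are residue-shuffled true sequences — composition-matched, the
  hardest null for a composition-blind scorer.
- Mutation model: independent per-site substitution at 5% to a uniformly
  random residue (so the effective substitution rate is 19/20 of the
  nominal), no indels — keeping the expected alignment trivial.
- Coordinates: when inputs carry no base-pair coordinates, genes sit on a
  1 kb grid (`start_bp = (rank−1)·1000 + 1`,
  `end_bp = start_bp + 3·len − 1`), which keeps span statistics
  well-defined on toy data.
- Corpora: each genome plants each model independently at its stated
  frequency among ~30 background decoys, with a 20% chance of placement
  inside a generated prophage interval; each genome uses an RNG stream
  derived from (master seed, genome index).

What passing on these fixtures does **not** show: real defense-system
homologs diverge by indels, domain shuffling and remote homology, real
genomes contain compositional biases and paralogs, and real profile
databases have hand-set thresholds — so perfect recovery here validates the
*decision machinery* (clustering, quorum, vetoes, overlap resolution, IO),
not the discriminative power of any particular profile database.

## Problem sizes and numerical choices

The shipped benchmark scale is 200 genomes × 4 models (~10 profiles,
~30–36 genes/genome), which the vectorized scanner processes in well under
a minute on one CPU; the scorer oracle runs 500 random trials (M ≤ 4,
length ≤ 6) and the overlap oracle 200 random conflict graphs (≤ 10
candidates). Scores are floats in bits; GA comparison is `≥` with no
tolerance; determinism everywhere comes from sorted iteration orders,
lexicographic tie-breaks and explicit seeds. Degenerate inputs have defined
behavior: empty FASTA → empty list with a warning, empty sequence → no hit,
empty call list → empty mechanism map, both-empty arsenals → distance 0,
empty reference → undefined sensitivity.

## Known limitations

- The internal scorer's fixed gap scheme is not score-compatible with
  HMMER; use ingested `domtblout` tables when exact parity with an hmmsearch
  run matters.
- No E-values, domain segmentation, or multi-hit alignment model.
- Candidate scoring (1.0/0.5) is a declared stand-in for richer annotation
  scoring functions; call *sets* are comparable across implementations,
  score values are not.
- No defense-island discovery, novel-system prediction, prophage
  *detection* (predictions are consumed, not produced), tree inference, or
  nucleotide-level input.
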