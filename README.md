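# defenscan

Detection of anti-phage defense systems in prokaryotic genomes, and census
statistics over the resulting "arsenals".

Bacteria and archaea defend themselves against their viruses with dozens of
families of defense systems — restriction-modification (RM), CRISPR-Cas,
CBASS, Gabija, Wadjet and many more. Most of these systems are *multi-gene*:
a single homolog is weak evidence, but a set of the right genes next to each
other on the chromosome is strong evidence. `defenscan` implements the
two-step detection strategy this implies, plus the downstream statistics a
genome census needs, for anyone studying phage–host conflict, defense-system
ecology, or annotating strains of interest.

## The method

**Step 1 — homology search with gathering thresholds.** Every protein in an
ordered proteome (a "gembase"-style multi-FASTA whose sequence order follows
gene order along each replicon) is scored against a database of protein
profiles. A hit is significant iff its bit score reaches the profile's
gathering threshold GA (the comparison is `score ≥ GA`, the `--cut_ga`
convention). `defenscan` can either ingest precomputed `hmmsearch
--domtblout` tables or score internally with its own local-alignment
profile scorer (a simplified plan-7 scheme, exact Viterbi maximization;
see `docs/methods.md`).

**Step 2 — genetic-architecture decision rules.** Each defense system
(sub)type is described by a declarative model: components with roles
(**mandatory**, **accessory**, **forbidden**, neutral), a set of
interchangeable profiles per component, a quorum (`min_mandatory`,
`min_total`) and a co-localization window *W*. Significant hits are
clustered along each replicon (two hits co-localize when at most *W*
non-hit genes intervene; circular replicons wrap), the quorum is checked
with each gene evidencing at most one component, candidates with a
forbidden hit within the cluster span ± *W* genes are vetoed, and
overlapping candidates across models are resolved to the gene-disjoint set
of maximal summed score (1.0 per mandatory + 0.5 per accessory component).

**Census statistics.** Per-genome arsenal profiles (system and family
counts), system spans (`end_bp − start_bp`), prophage co-location (a system
is prophage-encoded iff its first and last protein lie inside a predicted
prophage interval; predictions are pre-filtered to max score > 0.8 and size
< 200 kb), Bray-Curtis distances between arsenals
(`1 − 2·Σ min(aₖ,bₖ)/(Σaₖ+Σbₖ)`), two-sided Spearman correlations with
Bonferroni adjustment, forward-selection OLS controls (partial F-tests),
per-group system frequencies, and sensitivity / extra-call validation
metrics against a reference call set.

Because real profile databases are large and curated elsewhere, the package
ships a first-class synthetic-fixture module: it generates toy registries
with their own profiles, calibrates GA thresholds so that mutated true
sequences and residue-shuffled decoys separate perfectly, and plants
multi-gene systems at known positions in decoy genomes with a machine-checkable
truth table.

## Worked example

Simulate a small corpus and detect:

```sh
$ defenscan simulate --out demo --n-genomes 3 --n-models 3 --seed 11
INFO defenscan: wrote 3 genomes (5 planted systems) to demo
$ defenscan detect --input demo/genomes --models demo/registry --out demo_out
...
INFO defenscan: genome0003: 1 call(s) in 0.05 s
$ cat demo_out/genome0001/systems.tsv
sys_id	genome_id	replicon_id	model_name	family	subtype	n_genes	begin_rank	end_rank	start_bp	end_bp	score	location
genome0001_ToyFam1-I_1	genome0001	genome0001_r1	ToyFam1-I	ToyFam1	ToyFam1-I	2	2	4	1001	3171	2.0	chromosome
genome0001_ToyFam2-I_1	genome0001	genome0001_r1	ToyFam2-I	ToyFam2	ToyFam2-I	3	6	8	5001	7177	2.5	chromosome
genome0001_ToyFam3-I_1	genome0001	genome0001_r1	ToyFam3-I	ToyFam3	ToyFam3-I	3	10	14	9001	13153	2.5	chromosome
```

Each row is one detected system: `ToyFam1-I` spans gene ranks 2–4 (its two
member genes with one intervening non-member gene, well inside the window),
and its score 2.0 reflects two matched mandatory components; `ToyFam2-I`
scores 2.5 because its accessory component is present too. The calls match
`demo/truth.tsv` — the planted ground truth — gene for gene. `genes.tsv`
lists the member proteins with their component and role, and `hits.tsv`
every GA-passing hit including those outside called systems.

Downstream:

```sh
defenscan analyze --systems all_systems.tsv --models demo/registry \
    --prophages demo/prophages.tsv --metadata demo/metadata.tsv --out census
defenscan validate --reference demo/truth.tsv --detected all_systems.tsv
```

`validate` prints `"sensitivity": 1.0` on this corpus: every planted system
is recovered and no decoy-only genome produces a call.

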