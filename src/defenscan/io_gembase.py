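"""Reading ordered proteomes and hit tables; writing the three result files.

The detection engine operates on *ordered* proteomes: one protein FASTA per
genome whose sequence order follows gene order along each replicon (the
"gembase"-style layout).  Gene rank along the replicon — not base-pair
coordinates — is what the co-localization window counts, so rank is assigned
from file order and is authoritative.

Coordinates are 1-based inclusive base pairs.  When the input FASTA carries no
coordinate tokens, coordinates are synthesized on a uniform 1 kb grid
(``start_bp = (rank-1)*1000 + 1``, ``end_bp = start_bp + 3*len(seq) - 1``) so
that span statistics stay well-defined on toy data.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

SYSTEMS_COLUMNS = [
    "sys_id", "genome_id", "replicon_id", "model_name", "family", "subtype",
    "n_genes", "begin_rank", "end_rank", "start_bp", "end_bp", "score",
    "location",
]
GENES_COLUMNS = ["sys_id", "gene_id", "profile_name", "component_name", "role", "score"]
HITS_COLUMNS = ["gene_id", "replicon_id", "rank", "profile_name", "score", "i_evalue", "ga_pass"]


@dataclass
class GeneRecord:
    """One protein in an ordered replicon.

    ``rank`` is the 1-based position in the replicon's gene order; ``start_bp``
    and ``end_bp`` are 1-based inclusive. ``sequence`` may be empty when hits
    are supplied precomputed.
    """

    gene_id: str
    replicon_id: str
    rank: int
    start_bp: int
    end_bp: int
    strand: str = "+"
    sequence: str = ""

    def __post_init__(self):
        if self.start_bp < 1:
            raise ValueError(f"{self.gene_id}: start_bp must be >= 1")
        if self.end_bp < self.start_bp:
            raise ValueError(f"{self.gene_id}: end_bp < start_bp")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")


@dataclass
class Replicon:
    """An ordered sequence of genes on one replicon."""

    replicon_id: str
    genes: list[GeneRecord] = field(default_factory=list)
    topology: str = "linear"  # or "circular"

    def __post_init__(self):
        if self.topology not in {"linear", "circular"}:
            raise ValueError(f"unknown topology {self.topology!r}")
        for i, g in enumerate(self.genes, start=1):
            if g.rank != i:
                raise ValueError(
                    f"replicon {self.replicon_id}: gene ranks must be 1..n "
                    f"without gaps (gene {g.gene_id} has rank {g.rank}, expected {i})"
                )

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


@dataclass
class HmmHit:
    """A profile-vs-protein match.

    ``ga_pass`` is True iff ``score_bits`` reaches the profile's gathering
    threshold (GA); the comparison is ``>=``, matching hmmsearch ``--cut_ga``
    semantics. ``i_evalue`` is carried through from parsed hmmsearch tables
    only; it is never used for filtering.
    """

    gene_id: str
    profile_name: str
    score_bits: float
    i_evalue: float | None = None
    ga_pass: bool = False


def _parse_header_tokens(description: str) -> dict[str, str]:
    tokens = {}
    for part in description.split():
        if "=" in part:
            k, _, v = part.partition("=")
            tokens[k] = v
    return tokens


def read_ordered_fasta(
    path: str | Path,
    coordinate_source: str = "sequential",
    default_replicon_id: str | None = None,
    topology: str = "linear",
) -> list[Replicon]:
    """Read an ordered multi-FASTA protein file into Replicons.

    Gene rank is assigned in file order per replicon.  Headers may carry
    ``key=value`` tokens (``replicon=``, ``start=``, ``end=``, ``strand=``);
    with ``coordinate_source="header"`` the coordinate tokens are required,
    with ``"sequential"`` base-pair coordinates are synthesized on a 1 kb grid.
    """
    if coordinate_source not in {"header", "sequential"}:
        raise ValueError("coordinate_source must be 'header' or 'sequential'")
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        warnings.warn(f"{path}: empty FASTA, no replicons read")
        return []

    seen_ids: set[str] = set()
    replicons: dict[str, Replicon] = {}
    for rec in records:
        gene_id = rec.id
        if gene_id in seen_ids:
            raise ValueError(f"{path}: duplicate gene_id {gene_id!r}")
        seen_ids.add(gene_id)
        tokens = _parse_header_tokens(rec.description)
        replicon_id = tokens.get("replicon") or default_replicon_id or path.stem
        rep = replicons.setdefault(replicon_id, Replicon(replicon_id, [], topology))
        rank = len(rep.genes) + 1
        seq = str(rec.seq)
        if coordinate_source == "header":
            try:
                start_bp = int(tokens["start"])
                end_bp = int(tokens["end"])
                strand = tokens.get("strand", "+")
            except KeyError as exc:
                raise ValueError(
                    f"{path}: header of {gene_id} lacks coordinate token {exc}"
                ) from None
        else:
            start_bp = (rank - 1) * 1000 + 1
            end_bp = start_bp + 3 * max(len(seq), 1) - 1
            strand = tokens.get("strand", "+")
        rep.genes.append(
            GeneRecord(gene_id, replicon_id, rank, start_bp, end_bp, strand, seq)
        )
    # re-validate rank contiguity
    return [Replicon(r.replicon_id, r.genes, r.topology) for r in replicons.values()]


def write_ordered_fasta(replicons: Iterable[Replicon], path: str | Path) -> None:
    """Write replicons as an ordered FASTA with ``key=value`` header tokens."""
    records = []
    for rep in replicons:
        for g in rep.genes:
            desc = f"replicon={g.replicon_id} start={g.start_bp} end={g.end_bp} strand={g.strand}"
            records.append(SeqRecord(Seq(g.sequence), id=g.gene_id, description=desc))
    SeqIO.write(records, str(path), "fasta")


# -- hmmsearch domain-table ingestion ---------------------------------------

def parse_domain_table(path: str | Path) -> list[HmmHit]:
    """Parse an hmmsearch ``--domtblout`` table into hits.

    Keeps one hit per (gene, profile) pair: the maximum full-sequence bit
    score (decision rules operate per gene-profile pair, not per domain).
    ``ga_pass`` is left False; apply the registry's GA thresholds afterwards.
    """
    path = Path(path)
    best: dict[tuple[str, str], HmmHit] = {}
    order: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 14:
                raise ValueError(f"{path}:{lineno}: malformed domain-table row "
                                 f"({len(fields)} columns, expected >= 14)")
            try:
                gene_id = fields[0]
                profile = fields[3]
                full_score = float(fields[7])
                i_evalue = float(fields[12])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed domain-table row: {exc}") from None
            key = (gene_id, profile)
            if key not in best:
                order.append(key)
                best[key] = HmmHit(gene_id, profile, full_score, i_evalue)
            elif full_score > best[key].score_bits:
                best[key] = HmmHit(gene_id, profile, full_score, i_evalue)
    return [best[k] for k in order]


def write_domain_table(hits: Sequence[HmmHit], path: str | Path,
                       query_lengths: dict[str, int] | None = None) -> None:
    """Write hits in the hmmsearch domtblout dialect (one domain per hit)."""
    query_lengths = query_lengths or {}
    with open(path, "w") as fh:
        fh.write("# target name        accession   tlen query name           accession"
                 "   qlen   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias"
                 "  from    to  from    to  from    to  acc description of target\n")
        fh.write("#------------------- ---------- ----- -------------------- ----------"
                 " ----- --------- ------ ----- --- --- --------- --------- ------ -----"
                 " ----- ----- ----- ----- ----- ----- ---- ---------------------\n")
        for h in hits:
            ieval = h.i_evalue if h.i_evalue is not None else 0.0
            qlen = query_lengths.get(h.profile_name, 0)
            fh.write(
                f"{h.gene_id} - 0 {h.profile_name} - {qlen} "
                f"{ieval:.2g} {h.score_bits:.1f} 0.0 1 1 {ieval:.2g} {ieval:.2g} "
                f"{h.score_bits:.1f} 0.0 0 0 0 0 0 0 0.00 -\n"
            )


# -- result files -----------------------------------------------------------

def write_results(calls, hits: Sequence[HmmHit], out_dir: str | Path,
                  gene_index: dict[str, GeneRecord] | None = None) -> dict[str, Path]:
    """Write the three result files: systems.tsv, genes.tsv and hits.tsv.

    ``systems.tsv`` holds one row per called system, ``genes.tsv`` one row per
    member gene of a call, and ``hits.tsv`` every GA-passing hit including
    those outside called systems.  Rows are sorted by replicon then start
    rank.  Every member gene must appear among the hits.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    hit_genes = {h.gene_id for h in hits}
    for call in calls:
        for m in call.members:
            if m.gene_id not in hit_genes:
                raise ValueError(
                    f"system {call.sys_id}: member gene {m.gene_id} not among hits"
                )

    sys_rows = []
    gene_rows = []
    for call in sorted(calls, key=lambda c: (c.replicon_id, c.begin_rank)):
        sys_rows.append({
            "sys_id": call.sys_id, "genome_id": call.genome_id,
            "replicon_id": call.replicon_id, "model_name": call.model_name,
            "family": call.family, "subtype": call.subtype,
            "n_genes": len(call.members), "begin_rank": call.begin_rank,
            "end_rank": call.end_rank, "start_bp": call.start_bp,
            "end_bp": call.end_bp, "score": call.score, "location": call.location,
        })
        for m in call.members:
            gene_rows.append({
                "sys_id": call.sys_id, "gene_id": m.gene_id,
                "profile_name": m.profile_name, "component_name": m.component_name,
                "role": m.role, "score": m.score,
            })

    gene_index = gene_index or {}
    hit_rows = []
    for h in hits:
        g = gene_index.get(h.gene_id)
        hit_rows.append({
            "gene_id": h.gene_id,
            "replicon_id": g.replicon_id if g else "",
            "rank": g.rank if g else math.nan,
            "profile_name": h.profile_name,
            "score": h.score_bits,
            "i_evalue": h.i_evalue if h.i_evalue is not None else math.nan,
            "ga_pass": h.ga_pass,
        })
    hit_rows.sort(key=lambda r: (r["replicon_id"], r["rank"] if r["rank"] == r["rank"] else -1))

    paths = {}
    for name, rows, cols in [
        ("systems", sys_rows, SYSTEMS_COLUMNS),
        ("genes", gene_rows, GENES_COLUMNS),
        ("hits", hit_rows, HITS_COLUMNS),
    ]:
        df = pd.DataFrame(rows, columns=cols)
        p = out_dir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[name] = p
    logger.info("wrote %d systems, %d member genes, %d hits to %s",
                len(sys_rows), len(gene_rows), len(hit_rows), out_dir)
    return paths


def read_systems_table(path: str | Path) -> pd.DataFrame:
    """Read a systems.tsv file back into a DataFrame."""
    df = pd.read_csv(path, sep="\t")
    missing = set(SYSTEMS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing systems.tsv columns {sorted(missing)}")
    return df
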