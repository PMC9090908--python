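"""Profile scoring against proteins and gathering-threshold filtering.

A profile here is a position-specific scoring model over the 20 amino acids:
per match state, log-odds emissions in bits relative to a uniform 1/20
background.  Scoring uses a deliberately simplified local alignment scheme
(a stripped-down plan-7):

* free entry before any match state and free exit after any match state
  (local in both profile and sequence; unaligned flanks cost nothing);
* insert emissions at background (0 bits);
* fixed gap costs: every transition into an insert state costs -1 bit
  (M->I and I->I), every transition into a delete state costs -1 bit
  (M->D and D->D); transitions into match states are free; I<->D moves are
  disallowed;
* an alignment starts and ends on a match state and contains at least one
  matched residue.

The score of a sequence is the maximum over all such local alignments; a
sequence that admits none (empty input) scores -inf ("no hit").  There is no
E-value machinery: filtering is purely by the per-profile gathering (GA)
bit-score threshold, and the comparison is ``score >= GA`` (a hit exactly at
the threshold passes), matching hmmsearch ``--cut_ga`` semantics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .io_gembase import HmmHit, Replicon

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(ALPHABET)}

GAP_OPEN_INSERT = -1.0   # bits, M->I and I->I
GAP_OPEN_DELETE = -1.0   # bits, M->D and D->D
_NEG = -1e30             # effective -inf that survives additions


@dataclass
class ProfileHMM:
    """Match-state log-odds profile (bits vs uniform background)."""

    profile_name: str
    match_bits: np.ndarray  # shape (M, 20)
    GA_bits: float = 0.0

    def __post_init__(self):
        self.match_bits = np.asarray(self.match_bits, dtype=float)
        if self.match_bits.ndim != 2 or self.match_bits.shape[1] != 20:
            raise ValueError("match_bits must have shape (M, 20)")
        if self.match_bits.shape[0] < 1:
            raise ValueError("profile needs at least one match state")
        if not np.all(np.isfinite(self.match_bits)):
            raise ValueError("match emissions must be finite")

    @property
    def length_M(self) -> int:
        return int(self.match_bits.shape[0])


def encode_sequence(seq: str) -> np.ndarray:
    """Map residues to alphabet indices; non-standard residues to -1.

    Non-standard residues (X, B, Z, U, ...) emit at background, i.e. 0 bits
    when matched.
    """
    return np.array([_AA_INDEX.get(a, -1) for a in seq.upper()], dtype=int)


def build_profile_from_alignment(
    aligned_seqs: Sequence[str], name: str, GA_bits: float = 0.0,
    match_occupancy: float = 0.5,
) -> ProfileHMM:
    """Build a profile from a gapped alignment.

    Columns with at least ``match_occupancy`` (default 50%, ties kept) residue
    occupancy become match states.  Emissions use add-one pseudocounts:
    ``bits = log2(((count + 1) / (n + 20)) / (1/20))`` with n the number of
    aligned sequences and a uniform 1/20 background.
    """
    if not aligned_seqs:
        raise ValueError("empty alignment")
    lengths = {len(s) for s in aligned_seqs}
    if len(lengths) != 1:
        raise ValueError("aligned sequences must have equal length")
    (width,) = lengths
    n = len(aligned_seqs)
    rows = []
    for col in range(width):
        residues = [s[col].upper() for s in aligned_seqs]
        occupied = [r for r in residues if r in _AA_INDEX]
        if len(occupied) / n < match_occupancy:
            continue
        counts = np.zeros(20)
        for r in occupied:
            counts[_AA_INDEX[r]] += 1
        probs = (counts + 1.0) / (n + 20.0)
        rows.append(np.log2(probs * 20.0))
    if not rows:
        raise ValueError(f"alignment for {name!r} yields no match columns")
    return ProfileHMM(name, np.vstack(rows), GA_bits)


def _shift1_cols(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    out[:, 0] = _NEG
    out[:, 1:] = x[:, :-1]
    return out


def viterbi_local_scores(profile: ProfileHMM, seqs: Sequence[str]) -> np.ndarray:
    """Best local alignment scores of several sequences, in bits.

    One dynamic programme over match/insert/delete states under the fixed
    scheme described in the module docstring, vectorized across sequences
    (padded to the longest; padding cannot be matched and cannot affect real
    cells, which precede it).  Empty sequences score ``-inf`` (the null
    alignment is not a hit).
    """
    n = len(seqs)
    if n == 0:
        return np.empty(0)
    lengths = np.array([len(s) for s in seqs])
    L = int(lengths.max()) if lengths.size else 0
    if L == 0:
        return np.full(n, -np.inf)
    idx = np.full((n, L), -2, dtype=int)  # -2 = padding (unmatchable)
    for i, s in enumerate(seqs):
        if s:
            idx[i, : len(s)] = encode_sequence(s)
    E = profile.match_bits
    safe = np.clip(idx, 0, 19)
    nonstd = idx == -1
    pad = idx == -2
    steps = np.arange(L, dtype=float)

    prevM = np.full((n, L), _NEG)
    prevI = np.full((n, L), _NEG)
    prevD = np.full((n, L), _NEG)
    best = np.full(n, _NEG)
    for k in range(profile.length_M):
        em = E[k, safe]
        em = np.where(nonstd, 0.0, em)
        em = np.where(pad, _NEG, em)
        # into M: free entry, or from M/I/D of previous state, one residue back
        pred = np.maximum(
            0.0, _shift1_cols(np.maximum(np.maximum(prevM, prevI), prevD))
        )
        Mk = em + pred
        # into D (no residue consumed): from M or D of previous state, -1 bit
        Dk = np.maximum(prevM, prevD) + GAP_OPEN_DELETE
        # into I after state k: running max over earlier positions in this column
        a = _shift1_cols(Mk) + steps - 1.0  # I[i] + i = max(M[i-1] + (i-1), ...)
        Ik = np.maximum.accumulate(a, axis=1) - steps
        best = np.maximum(best, Mk.max(axis=1))
        prevM, prevI, prevD = Mk, Ik, Dk
    return np.where(best <= _NEG / 2, -np.inf, best)


def viterbi_local_score(profile: ProfileHMM, seq: str) -> float:
    """Best local alignment score of ``seq`` against ``profile``, in bits.

    Deterministic; returns ``-inf`` for an empty sequence ("no hit").
    """
    return float(viterbi_local_scores(profile, [seq])[0])


def apply_ga_filter(hits: Iterable[HmmHit]) -> list[HmmHit]:
    """Keep hits whose ga_pass flag is set; order preserved, idempotent."""
    return [h for h in hits if h.ga_pass]


def scan_proteome(replicons: Iterable[Replicon], registry,
                  ga_only: bool = True) -> list[HmmHit]:
    """Score every gene against every manifest profile and flag GA passes.

    With ``ga_only`` (default) only GA-passing hits are emitted; otherwise all
    hits with positive score are retained, carrying the ga_pass flag.  The hit
    set is independent of gene order.
    """
    for name in registry.profile_manifest:
        if name not in registry.profiles:
            raise ValueError(
                f"profile {name!r} has no loadable parameters; "
                "use precomputed hit tables or provide profiles/"
            )
    hits: list[HmmHit] = []
    for rep in replicons:
        genes = [g for g in rep.genes if g.sequence]
        if not genes:
            continue
        seqs = [g.sequence for g in genes]
        for name in sorted(registry.profile_manifest):
            prof = registry.profiles[name]
            ga_bits = registry.ga_bits(name)
            scores = viterbi_local_scores(prof, seqs)
            for gene, score in zip(genes, scores):
                if not math.isfinite(score):
                    continue
                ga = score >= ga_bits
                if ga or (not ga_only and score > 0):
                    hits.append(HmmHit(gene.gene_id, name, float(score), None, ga))
    return hits


# -- profile serialization ---------------------------------------------------

def write_profile(profile: ProfileHMM, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"NAME {profile.profile_name}\n")
        fh.write(f"LENG {profile.length_M}\n")
        fh.write(f"GA {profile.GA_bits:.6g}\n")
        fh.write(f"ALPH {ALPHABET}\n")
        for k in range(profile.length_M):
            vals = " ".join(f"{v:.6f}" for v in profile.match_bits[k])
            fh.write(f"M{k + 1} {vals}\n")


def read_profile(path: str | Path) -> ProfileHMM:
    name, ga, rows = None, 0.0, []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0]
            if key == "NAME":
                name = parts[1]
            elif key == "GA":
                ga = float(parts[1])
            elif key.startswith("M") and key[1:].isdigit():
                rows.append([float(v) for v in parts[1:]])
    if name is None or not rows:
        raise ValueError(f"{path}: not a profile file")
    return ProfileHMM(name, np.array(rows), ga)


def read_hmmer3_profile(path: str | Path) -> ProfileHMM:
    """Convert a HMMER3 ASCII profile to this package's scoring scheme.

    Parses NAME/LENG/GA from the header and the per-state match emission
    lines (stored as negative natural-log probabilities); emissions are
    re-expressed as bits against a uniform 1/20 background and the fixed gap
    scheme replaces HMMER's fitted transition probabilities, so scores are
    not comparable with hmmsearch output.
    """
    path = Path(path)
    name, leng, ga = None, None, 0.0
    hmmer_alph = None
    rows: list[list[float]] = []
    in_model = False
    expect_match = False
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if not in_model:
                if parts[0] == "NAME":
                    name = parts[1]
                elif parts[0] == "LENG":
                    leng = int(parts[1])
                elif parts[0] == "GA":
                    ga = float(parts[1])
                elif parts[0] == "HMM":
                    hmmer_alph = parts[1:21]
                    in_model = True
                    expect_match = False
            else:
                if parts[0] == "//":
                    break
                if parts[0] == "COMPO":
                    continue
                if parts[0].isdigit():
                    vals = parts[1:21]
                    nll = np.array([float("inf") if v == "*" else float(v) for v in vals])
                    probs = np.exp(-nll)
                    reordered = np.zeros(20)
                    for aa, p in zip(hmmer_alph, probs):
                        if aa in _AA_INDEX:
                            reordered[_AA_INDEX[aa]] = p
                    with np.errstate(divide="ignore"):
                        bits = np.log2(np.maximum(reordered, 1e-12) * 20.0)
                    rows.append(bits.tolist())
                    expect_match = True
                elif expect_match:
                    # insert-emission / transition lines: ignored under the fixed scheme
                    continue
    if name is None or not rows:
        raise ValueError(f"{path}: not a HMMER3 ASCII profile")
    if leng is not None and leng != len(rows):
        raise ValueError(f"{path}: LENG {leng} != parsed match states {len(rows)}")
    return ProfileHMM(name, np.array(rows), ga)
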