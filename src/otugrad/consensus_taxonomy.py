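"""Paired consensus taxonomy assignment with rank-specific identity cutoffs.

Concatenated OTU centroids are split at the junction and each half is
aligned against every reference sequence (both strands).  Hits shorter
than a minimum alignment length (by default 90% of the query) are
dropped.  Classification then proceeds on the references hit by *both*
halves:

1. per candidate, the paired identity is the minimum of the forward and
   reverse identities (the conservative combination);
2. the allowed rank per candidate is the deepest rank whose identity
   cutoff is met (cutoffs are non-decreasing from kingdom to species, by
   default 90% for kingdom..family, 97% for genus, 99% for species);
   candidates failing even the kingdom cutoff are dropped, and the
   overall allowed rank is the maximum over candidates;
3. a single surviving candidate donates its lineage, truncated to its
   allowed rank;
4. with several candidates, the forward+reverse bit-score sums are
   compared and only candidates within 95% of the best sum are retained;
   the lineage is the deepest rank at which all retained candidates
   agree, further truncated to the overall allowed rank;
5. no shared candidate means unclassified.

Merged (single-sequence) centroids are classified by the same rules with
the paired identity replaced by the hit identity.

Alignment is end-free (full query against an infix of the reference) with
the per-column score path trimmed to its best-scoring local segment, so
hit lengths and identities behave like local alignment statistics.
Bit-scores use the standard Karlin-Altschul form
``(lambda * raw - ln K) / ln 2``; only ratios to the best sum matter for
the 95% rule, so the constants are configurable and non-critical.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import re
from typing import Optional

import edlib
import numpy as np

from otugrad.core_io import Lineage, N_RANKS, ReferenceDB, reverse_complement

logger = logging.getLogger(__name__)

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclasses.dataclass(frozen=True, slots=True)
class ScoringScheme:
    """Megablast-style scoring and Karlin-Altschul constants."""

    match: float = 1.0
    mismatch: float = 2.0  # penalty (positive)
    gap: float = 2.5  # per gap column (open == extend)
    lam: float = 1.28
    k: float = 0.46

    def bitscore(self, raw: float) -> float:
        return (self.lam * raw - math.log(self.k)) / math.log(2.0)


@dataclasses.dataclass(slots=True)
class Hit:
    """One query-vs-reference alignment."""

    ref_id: str
    identity: float
    aln_len: int
    bitscore: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"identity must be in [0, 1], got {self.identity}")
        if self.aln_len < 1:
            raise ValueError("alignment length must be >= 1")
        if not math.isfinite(self.bitscore):
            raise ValueError("bitscore must be finite")


@dataclasses.dataclass(slots=True)
class HitSet:
    """Per-query hits, at most one (the best) per reference id."""

    query_id: str
    hits: list[Hit]

    def __post_init__(self) -> None:
        ids = [h.ref_id for h in self.hits]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate reference ids in HitSet")

    def by_ref(self) -> dict[str, Hit]:
        return {h.ref_id: h for h in self.hits}


@dataclasses.dataclass(frozen=True, slots=True)
class CutoffScheme:
    """Per-rank identity cutoffs (PR2 levels 1-8), non-decreasing."""

    cutoffs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.cutoffs) != N_RANKS:
            raise ValueError(f"need {N_RANKS} cutoffs, got {len(self.cutoffs)}")
        if any(b < a for a, b in zip(self.cutoffs, self.cutoffs[1:])):
            raise ValueError("cutoffs must be non-decreasing from kingdom to species")

    @classmethod
    def default(cls) -> "CutoffScheme":
        """90% for kingdom..family, 97% for genus, 99% for species."""
        return cls((0.90,) * 6 + (0.97, 0.99))

    @classmethod
    def flat(cls, cutoff: float) -> "CutoffScheme":
        return cls((cutoff,) * N_RANKS)

    def allowed_rank(self, identity: float) -> int:
        """Deepest rank whose cutoff is met (inclusive); 0 if below kingdom."""
        rank = 0
        for i, cutoff in enumerate(self.cutoffs):
            if identity >= cutoff:
                rank = i + 1
            else:
                break
        return rank


@dataclasses.dataclass(slots=True)
class Assignment:
    """The classifier's verdict for one OTU."""

    otu_id: str
    lineage: Lineage
    evidence: list[str]
    reason: Optional[str] = None  # identity_cutoff | consensus_conflict | no_hits | length_filter

    @property
    def depth(self) -> int:
        return self.lineage.depth


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


def _best_local_segment(cigar: str, scoring: ScoringScheme) -> tuple[float, int, int]:
    """Best-scoring contiguous segment of the alignment path.

    Returns (raw score, matches, columns) of the maximum-sum run of
    per-column scores (match +, mismatch/gap -), i.e. the best local
    sub-alignment contained in the end-free path.
    """
    best = 0.0
    best_m = best_c = 0
    run = 0.0
    run_m = run_c = 0
    for num, op in _CIGAR_RE.findall(cigar):
        n = int(num)
        if op == "=":
            run += n * scoring.match
            run_m += n
            run_c += n
        else:
            penalty = scoring.mismatch if op in "XM" else scoring.gap
            run -= n * penalty
            run_c += n
        if run > best:
            best, best_m, best_c = run, run_m, run_c
        if run <= 0.0:
            run, run_m, run_c = 0.0, 0, 0
    return best, best_m, best_c


def _align_one(query: str, ref_seq: str, scoring: ScoringScheme) -> Optional[tuple[float, int, int]]:
    res = edlib.align(query, ref_seq, mode="HW", task="path")
    if res["editDistance"] < 0:
        return None
    return _best_local_segment(res["cigar"], scoring)


def align_query_to_refs(
    query: str,
    refdb: ReferenceDB,
    min_aln_len: Optional[int] = None,
    scoring: ScoringScheme = ScoringScheme(),
    query_id: str = "query",
) -> HitSet:
    """Align a query against every reference (both strands) and filter hits.

    ``min_aln_len`` defaults to 90% of the query length.  Per reference,
    the best-scoring strand is kept; hits whose best local segment is
    shorter than ``min_aln_len`` columns or scores non-positively are
    dropped.
    """
    if len(refdb) == 0:
        raise ValueError("empty reference database")
    if not query:
        raise ValueError("empty query")
    if min_aln_len is None:
        min_aln_len = int(round(0.9 * len(query)))
    if min_aln_len < 1:
        raise ValueError(f"min_aln_len must be >= 1, got {min_aln_len}")
    rc = reverse_complement(query)
    hits: list[Hit] = []
    for rid, entry in refdb.entries.items():
        best: Optional[tuple[float, int, int]] = None
        for strand_query in (query, rc):
            res = _align_one(strand_query, entry.seq, scoring)
            if res is not None and (best is None or res[0] > best[0]):
                best = res
        if best is None:
            continue
        raw, matches, cols = best
        if cols < min_aln_len or raw <= 0.0 or matches == 0:
            continue
        hits.append(Hit(rid, matches / cols, cols, scoring.bitscore(raw)))
    return HitSet(query_id, hits)


# ---------------------------------------------------------------------------
# Consensus assignment
# ---------------------------------------------------------------------------


def _consensus_depth(lineages: list[Lineage]) -> int:
    """Deepest rank at which all lineages carry the same name."""
    depth = 0
    for level in range(N_RANKS):
        names = {lin.ranks[level] for lin in lineages}
        if len(names) == 1 and next(iter(names)):
            depth = level + 1
        else:
            break
    return depth


def _assign_from_candidates(
    otu_id: str,
    candidates: dict[str, tuple[float, float]],  # ref_id -> (paired identity, summed bitscore)
    refdb: ReferenceDB,
    cutoffs: CutoffScheme,
    bitscore_fraction: float = 0.95,
) -> Assignment:
    if not candidates:
        return Assignment(otu_id, Lineage.unclassified(), [], "no_hits")
    allowed: dict[str, int] = {}
    for rid, (identity, _) in candidates.items():
        rank = cutoffs.allowed_rank(identity)
        if rank >= 1:
            allowed[rid] = rank
    if not allowed:
        return Assignment(otu_id, Lineage.unclassified(), [], "identity_cutoff")
    overall_allowed = max(allowed.values())
    if len(allowed) == 1:
        (rid, rank), = allowed.items()
        return _finish(otu_id, [rid], refdb, rank, N_RANKS)
    best_score = max(candidates[rid][1] for rid in allowed)
    retained = sorted(
        rid for rid in allowed if candidates[rid][1] >= bitscore_fraction * best_score
    )
    consensus = _consensus_depth([refdb.lineage(rid) for rid in retained])
    return _finish(otu_id, retained, refdb, overall_allowed, consensus)


def _finish(
    otu_id: str, retained: list[str], refdb: ReferenceDB, allowed: int, consensus: int
) -> Assignment:
    depth = min(allowed, consensus)
    lineage = refdb.lineage(retained[0]).truncate(depth)
    if depth == N_RANKS:
        reason = None
    elif consensus < allowed:
        reason = "consensus_conflict"
    else:
        reason = "identity_cutoff"
    return Assignment(otu_id, lineage, retained, reason)


def assign_paired(
    fwd_hits: HitSet,
    rev_hits: HitSet,
    refdb: ReferenceDB,
    cutoffs: CutoffScheme = CutoffScheme.default(),
    bitscore_fraction: float = 0.95,
    otu_id: Optional[str] = None,
) -> Assignment:
    """Consensus assignment from the split halves of a concatenated centroid.

    Candidates are references hit by both halves; the paired identity is
    min(forward, reverse) and the candidate score is the sum of the two
    bit-scores.  See the module docstring for the full rule.
    """
    otu_id = otu_id or fwd_hits.query_id
    fwd = fwd_hits.by_ref()
    rev = rev_hits.by_ref()
    candidates = {
        rid: (min(fwd[rid].identity, rev[rid].identity), fwd[rid].bitscore + rev[rid].bitscore)
        for rid in fwd
        if rid in rev
    }
    return _assign_from_candidates(otu_id, candidates, refdb, cutoffs, bitscore_fraction)


def assign_single(
    hits: HitSet,
    refdb: ReferenceDB,
    cutoffs: CutoffScheme = CutoffScheme.default(),
    bitscore_fraction: float = 0.95,
    otu_id: Optional[str] = None,
) -> Assignment:
    """Classify a merged centroid with the same rules as :func:`assign_paired`."""
    otu_id = otu_id or hits.query_id
    candidates = {h.ref_id: (h.identity, h.bitscore) for h in hits.hits}
    return _assign_from_candidates(otu_id, candidates, refdb, cutoffs, bitscore_fraction)


# ---------------------------------------------------------------------------
# Manual overrides
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True, slots=True)
class ManualOverride:
    otu_id: str
    lineage: Lineage
    coverage: float
    identity: float


def apply_manual_overrides(
    assignments: dict[str, Assignment], overrides: list[ManualOverride]
) -> dict[str, Assignment]:
    """Replace automatic lineages with curated ones, gated at >99%/99%.

    An override is applied only when both its coverage and identity exceed
    0.99; every application (and every skip) is logged.
    """
    out = dict(assignments)
    for override in overrides:
        if override.otu_id not in out:
            raise KeyError(f"manual override for unknown OTU {override.otu_id!r}")
        if override.coverage > 0.99 and override.identity > 0.99:
            old = out[override.otu_id]
            out[override.otu_id] = Assignment(
                override.otu_id, override.lineage, old.evidence, "manual_override"
            )
            logger.info("manual override applied to %s", override.otu_id)
        else:
            logger.warning(
                "manual override for %s ignored (coverage %.3f, identity %.3f <= 0.99)",
                override.otu_id,
                override.coverage,
                override.identity,
            )
    return out


# ---------------------------------------------------------------------------
# Tabular I/O (BLAST outfmt-6-style hits; assignment TSV)
# ---------------------------------------------------------------------------


def write_hits_tsv(hitsets: list[HitSet], path) -> None:
    """Export hits as BLAST tabular (qseqid, sseqid, pident, length, bitscore)."""
    with open(path, "w") as fh:
        for hs in hitsets:
            for h in hs.hits:
                fh.write(f"{hs.query_id}\t{h.ref_id}\t{h.identity * 100:.2f}\t{h.aln_len}\t{h.bitscore:.1f}\n")


def read_hits_tsv(path) -> list[HitSet]:
    by_query: dict[str, list[Hit]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            q, s, pident, length, bits = line.rstrip("\n").split("\t")
            by_query.setdefault(q, []).append(
                Hit(s, float(pident) / 100.0, int(length), float(bits))
            )
    return [HitSet(q, hits) for q, hits in by_query.items()]


def write_assignments_tsv(assignments: dict[str, Assignment], path) -> None:
    with open(path, "w") as fh:
        fh.write("otu_id\t" + "\t".join(f"rank{i + 1}" for i in range(N_RANKS)) + "\tdepth\treason\n")
        for otu_id, a in assignments.items():
            fh.write(
                otu_id
                + "\t"
                + "\t".join(a.lineage.ranks)
                + f"\t{a.depth}\t{a.reason or ''}\n"
            )
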