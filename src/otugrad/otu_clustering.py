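"""Two-pass OTU construction at a configurable identity threshold.

Pass one (stringent reads): exact dereplication, abundance sort, then
greedy first-fit clustering — scanning uniques from most to least
abundant, a sequence joins the first existing centroid it matches at or
above the identity threshold, otherwise it founds a new centroid.  Pass
two (lenient reads): every read is mapped to the centroid of maximal
identity (ties toward the earlier, i.e. more abundant, centroid) to build
the OTU x sample count table.

Identity is computed over a semi-global (end-free) alignment so that
terminal length differences — mapping-pass reads are shorter than
centroid-pass reads by construction — are not penalized: identity =
matching columns / total alignment columns, with the shorter sequence
aligned as an infix of the longer.
"""

from __future__ import annotations

import dataclasses
import re
from collections.abc import Iterable
from typing import Optional

import edlib
import numpy as np

from otugrad.core_io import OtuTable, QualRead  # noqa: F401  (QualRead re-exported for callers)
from otugrad.read_prep import PreparedSequence

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def _cigar_columns_matches(cigar: str) -> tuple[int, int]:
    cols = 0
    matches = 0
    for num, op in _CIGAR_RE.findall(cigar):
        n = int(num)
        cols += n
        if op == "=":
            matches += n
    return cols, matches


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of matching columns in the optimal end-free alignment.

    Symmetric by construction: the shorter sequence (ties broken
    lexicographically) is aligned as an infix of the longer, so unaligned
    overhangs of the longer sequence cost nothing.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    query, target = (a, b) if (len(a), a) <= (len(b), b) else (b, a)
    res = edlib.align(query, target, mode="HW", task="path")
    cols, matches = _cigar_columns_matches(res["cigar"])
    return matches / cols


def _identity_banded_dist(
    query: str, target: str, threshold: float
) -> tuple[Optional[float], int]:
    """(identity, edit distance) if identity can reach ``threshold``, else
    (None, -1) — banded early-out.

    Any end-free alignment with identity >= t satisfies
    edit_distance <= len(query) * (1 - t) / t, so the edlib search can be
    capped at that band and abandoned early for distant pairs.
    """
    if len(query) > len(target) or (len(query) == len(target) and query > target):
        query, target = target, query
    k = int(np.ceil(len(query) * (1.0 - threshold) / threshold)) + 1
    res = edlib.align(query, target, mode="HW", task="path", k=k)
    dist = res["editDistance"]
    if dist < 0:
        return None, -1
    cols, matches = _cigar_columns_matches(res["cigar"])
    identity = matches / cols
    return (identity if identity >= threshold else None), dist


def _identity_banded(query: str, target: str, threshold: float) -> Optional[float]:
    return _identity_banded_dist(query, target, threshold)[0]


@dataclasses.dataclass(slots=True)
class UniqueSequence:
    """An exact-dereplicated sequence with per-sample counts."""

    seq: str
    total_count: int
    per_sample_counts: dict[str, int]
    junction: Optional[int] = None


@dataclasses.dataclass(slots=True)
class Centroid:
    otu_id: str
    seq: str
    junction: Optional[int] = None


@dataclasses.dataclass(slots=True)
class ClusterResult:
    centroids: list[Centroid]
    membership: dict[str, str]  # unique sequence -> otu_id


class Dereplicator:
    """Streaming exact dereplication with per-sample counting.

    All sequences added must share one kind (merged vs concatenated); the
    junction recorded for a sequence is that of its first occurrence.
    """

    def __init__(self) -> None:
        self._kind: Optional[str] = None
        self._counts: dict[str, dict[str, int]] = {}
        self._junctions: dict[str, int] = {}

    def add(self, prepared: PreparedSequence, count: int = 1) -> None:
        if self._kind is None:
            self._kind = prepared.kind
        elif prepared.kind != self._kind:
            raise ValueError(
                f"mixed sequence kinds in dereplication: {self._kind!r} vs {prepared.kind!r}"
            )
        per_sample = self._counts.setdefault(prepared.seq, {})
        per_sample[prepared.sample_id] = per_sample.get(prepared.sample_id, 0) + count
        if prepared.junction is not None and prepared.seq not in self._junctions:
            self._junctions[prepared.seq] = prepared.junction

    def finalize(self) -> list[UniqueSequence]:
        uniques = [
            UniqueSequence(seq, sum(per.values()), per, self._junctions.get(seq))
            for seq, per in self._counts.items()
        ]
        uniques.sort(key=lambda u: (-u.total_count, u.seq))
        return uniques


def dereplicate(prepared: Iterable[PreparedSequence]) -> list[UniqueSequence]:
    """Exact string dereplication, sorted by total count desc (ties: lexicographic)."""
    derep = Dereplicator()
    for seq in prepared:
        derep.add(seq)
    return derep.finalize()


def greedy_cluster(
    uniques: list[UniqueSequence],
    threshold: float = 0.99,
    min_unique_size: int = 1,
) -> ClusterResult:
    """Greedy first-fit centroid clustering of abundance-sorted uniques.

    Each unique joins the first centroid (in founding order) with identity
    >= ``threshold``, else founds a new OTU whose centroid is the unique
    itself.  ``min_unique_size`` drops rare uniques (e.g. singletons) from
    centroid founding *and* membership; they are still counted later by
    the mapping pass.  For concatenated input the identity is computed on
    the full concatenation and the founder's junction is kept.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    centroids: list[Centroid] = []
    exact: dict[str, str] = {}
    membership: dict[str, str] = {}
    for unique in uniques:
        if unique.total_count < min_unique_size:
            continue
        hit = exact.get(unique.seq)
        if hit is None:
            for centroid in centroids:
                ident = _identity_banded(unique.seq, centroid.seq, threshold)
                if ident is not None:
                    hit = centroid.otu_id
                    break
        if hit is None:
            otu_id = f"OTU_{len(centroids) + 1}"
            centroids.append(Centroid(otu_id, unique.seq, unique.junction))
            exact[unique.seq] = otu_id
            membership[unique.seq] = otu_id
        else:
            membership[unique.seq] = hit
    return ClusterResult(centroids, membership)


def map_reads_to_centroids(
    prepared: Iterable[PreparedSequence],
    centroids: list[Centroid],
    sample_ids: list[str],
    threshold: float = 0.99,
    marker: str = "16S",
) -> tuple[OtuTable, dict[str, int]]:
    """Map lenient-pass reads to centroids and accumulate per-sample counts.

    Each read goes to the centroid of maximal identity if that identity is
    >= ``threshold``; ties break toward the earlier (more abundant)
    centroid; everything else is counted as unassigned.  Reads are
    dereplicated internally so each distinct sequence is aligned once.
    Returns the OTU table and the per-sample unassigned counts
    (assigned + unassigned = input reads, per sample).
    """
    derep = Dereplicator()
    known = set(sample_ids)
    for read in prepared:
        if read.sample_id not in known:
            raise KeyError(f"unknown sample id {read.sample_id!r}")
        derep.add(read)
    return map_uniques_to_centroids(derep.finalize(), centroids, sample_ids, threshold, marker)


def map_uniques_to_centroids(
    uniques: list[UniqueSequence],
    centroids: list[Centroid],
    sample_ids: list[str],
    threshold: float = 0.99,
    marker: str = "16S",
) -> tuple[OtuTable, dict[str, int]]:
    """Best-fit mapping of dereplicated sequences onto centroids.

    The work-horse behind :func:`map_reads_to_centroids`; operating on
    uniques keeps deep samples cheap (each distinct sequence is aligned
    once, counts flow through)."""
    sample_index = {s: j for j, s in enumerate(sample_ids)}
    counts = np.zeros((len(centroids), len(sample_ids)), dtype=np.int64)
    unassigned = {s: 0 for s in sample_ids}
    exact = {c.seq: i for i, c in enumerate(centroids)}
    for unique in uniques:
        unknown = [s for s in unique.per_sample_counts if s not in sample_index]
        if unknown:
            raise KeyError(f"unknown sample id {unknown[0]!r}")
        best = exact.get(unique.seq)
        if best is None:
            best_ident = 0.0
            for i, centroid in enumerate(centroids):
                ident, dist = _identity_banded_dist(unique.seq, centroid.seq, threshold)
                if ident is not None and ident > best_ident:
                    best, best_ident = i, ident
                    # centroids sit >= ~1% apart, so a near-exact hit
                    # (distance <= 1) cannot be beaten by a later centroid
                    if dist <= 1:
                        break
        if best is None:
            for sample, c in unique.per_sample_counts.items():
                unassigned[sample] += c
        else:
            for sample, c in unique.per_sample_counts.items():
                counts[best, sample_index[sample]] += c

    table = OtuTable(
        otu_ids=[c.otu_id for c in centroids],
        sample_ids=list(sample_ids),
        counts=counts,
        centroids={c.otu_id: c.seq for c in centroids},
        lineages={},
        marker=marker,
        junctions={c.otu_id: c.junction for c in centroids if c.junction is not None},
    )
    return table, unassigned
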