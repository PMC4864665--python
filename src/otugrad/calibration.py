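"""In-silico calibration of the rank-specific identity cutoffs.

A random subset of reference sequences is held out, artificial forward/
reverse read pairs are excised from them at the primer-binding
coordinates (error-free by default), and the pairs are classified against
the remaining references under a grid of cutoff schemes.  For each rank
and scheme the run reports

* sensitivity — the fraction of test reads assigned at that depth or
  deeper ("percentage of sequences classified"), and
* precision — the fraction of those whose assigned name at the rank
  equals the true lineage's name ("classification accuracy"); undefined
  (NaN) when nothing is assigned at the rank, which is distinct from 0.

The selected scheme takes, per rank, the lowest cutoff whose precision
meets a floor (maximizing sensitivity subject to the floor) and is then
forced monotone non-decreasing across ranks.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from otugrad.consensus_taxonomy import CutoffScheme, HitSet, align_query_to_refs, assign_paired
from otugrad.core_io import Lineage, N_RANKS, ReferenceDB, reverse_complement
from otugrad.read_prep import _iupac_regex

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True, slots=True)
class ReadGeometry:
    """Where and how long the artificial reads are cut from a reference."""

    fwd_primer: str
    rev_primer: str
    fwd_len: int = 250
    rev_len: int = 210


@dataclasses.dataclass(slots=True)
class TestRead:
    ref_id: str
    fwd: str
    rev: str
    lineage: Lineage


@dataclasses.dataclass(slots=True)
class CalibrationResult:
    """Grid of (rank, cutoff, precision, sensitivity, n_test) rows."""

    grid: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.grid.to_csv(path, sep="\t", index=False)


def _excise_reads(seq: str, geometry: ReadGeometry, rng: np.random.Generator,
                  error_rate: float) -> Optional[tuple[str, str]]:
    """Cut a fwd/rev read pair at the primer-binding coordinates, or None."""
    fwd_m = _iupac_regex(geometry.fwd_primer).search(seq)
    rev_m: Optional[re.Match] = None
    for m in _iupac_regex(reverse_complement(geometry.rev_primer)).finditer(seq):
        rev_m = m  # last occurrence: the 3' primer site
    if fwd_m is None or rev_m is None:
        return None
    fwd_start = fwd_m.end()
    rev_end = rev_m.start()
    if rev_end - fwd_start < max(geometry.fwd_len, geometry.rev_len):
        return None
    fwd = seq[fwd_start : fwd_start + geometry.fwd_len]
    rev = reverse_complement(seq[rev_end - geometry.rev_len : rev_end])
    if error_rate > 0:
        fwd = _mutate(fwd, error_rate, rng)
        rev = _mutate(rev, error_rate, rng)
    return fwd, rev


_OTHER = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    chars = list(seq)
    for i in np.flatnonzero(rng.random(len(chars)) < rate):
        if chars[i] in _OTHER:
            chars[i] = _OTHER[chars[i]][rng.integers(3)]
    return "".join(chars)


def make_holdout_testset(
    refdb: ReferenceDB,
    n: int,
    geometry: ReadGeometry,
    seed: int | np.random.Generator = 0,
    error_rate: float = 0.0,
) -> tuple[list[TestRead], ReferenceDB]:
    """Sample ``n`` references without replacement, excise read pairs from
    them, and return (test reads, reference with the sampled entries removed).

    Entries in which the primers cannot be located are skipped with a
    warning and replaced by resampling.
    """
    if n >= len(refdb):
        raise ValueError(f"n={n} must be < reference size {len(refdb)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ids = np.array(refdb.ids())
    order = rng.permutation(len(ids))
    test: list[TestRead] = []
    held_out: list[str] = []
    for idx in order:
        if len(test) == n:
            break
        rid = str(ids[idx])
        reads = _excise_reads(refdb.seq(rid), geometry, rng, error_rate)
        if reads is None:
            logger.warning("primers not found in %s; resampling", rid)
            continue
        test.append(TestRead(rid, reads[0], reads[1], refdb.lineage(rid)))
        held_out.append(rid)
    if len(test) < n:
        raise ValueError(f"could only excise {len(test)} of {n} requested test reads")
    return test, refdb.without(held_out)


def classify_testset(
    testset: list[TestRead],
    reduced_refdb: ReferenceDB,
    min_aln_frac: float = 0.9,
) -> list[tuple[HitSet, HitSet]]:
    """Precompute forward/reverse hit sets for each test pair (cutoff-free)."""
    out = []
    for i, tr in enumerate(testset):
        fwd = align_query_to_refs(
            tr.fwd, reduced_refdb, int(round(min_aln_frac * len(tr.fwd))), query_id=f"test_{i}_f"
        )
        rev = align_query_to_refs(
            tr.rev, reduced_refdb, int(round(min_aln_frac * len(tr.rev))), query_id=f"test_{i}_r"
        )
        out.append((fwd, rev))
    return out


def evaluate_cutoff_grid(
    testset: list[TestRead],
    reduced_refdb: ReferenceDB,
    schemes: Sequence[CutoffScheme],
    min_aln_frac: float = 0.9,
    hitsets: Optional[list[tuple[HitSet, HitSet]]] = None,
) -> CalibrationResult:
    """Classify every test pair under every scheme; tabulate per-rank
    precision and sensitivity.

    Alignments are computed once and shared across schemes (the cutoffs
    only gate the post-alignment logic).
    """
    if not schemes:
        raise ValueError("empty cutoff grid")
    if hitsets is None:
        hitsets = classify_testset(testset, reduced_refdb, min_aln_frac)
    n_test = len(testset)
    rows = []
    for scheme in schemes:
        assigned_depth = np.zeros(n_test, dtype=int)
        correct_at = np.zeros((n_test, N_RANKS), dtype=bool)
        for i, ((fwd, rev), tr) in enumerate(zip(hitsets, testset)):
            a = assign_paired(fwd, rev, reduced_refdb, scheme)
            assigned_depth[i] = a.depth
            for level in range(1, a.depth + 1):
                correct_at[i, level - 1] = (
                    a.lineage.name_at(level) == tr.lineage.name_at(level)
                )
        for level in range(1, N_RANKS + 1):
            reached = assigned_depth >= level
            n_reached = int(reached.sum())
            sensitivity = n_reached / n_test
            precision = (
                float(correct_at[reached, level - 1].mean()) if n_reached else float("nan")
            )
            rows.append(
                {
                    "rank": level,
                    "cutoff": scheme.cutoffs[level - 1],
                    "precision": precision,
                    "sensitivity": sensitivity,
                    "n_test": n_test,
                }
            )
    return CalibrationResult(pd.DataFrame(rows))


DEFAULT_GRID = (0.80, 0.85, 0.90, 0.95, 0.97, 0.99)


def flat_schemes(grid: Sequence[float] = DEFAULT_GRID) -> list[CutoffScheme]:
    """One flat (same cutoff at every rank) scheme per grid value."""
    return [CutoffScheme.flat(c) for c in grid]


def select_cutoffs(
    result: CalibrationResult, precision_floor: Sequence[float]
) -> CutoffScheme:
    """Per rank, the lowest cutoff meeting its precision floor; the scheme
    is then forced monotone non-decreasing across ranks."""
    if result.grid.empty:
        raise ValueError("empty calibration result")
    if len(precision_floor) != N_RANKS:
        raise ValueError(f"need {N_RANKS} precision floors")
    chosen = []
    for level in range(1, N_RANKS + 1):
        sub = result.grid[result.grid["rank"] == level].sort_values("cutoff")
        ok = sub[sub["precision"] >= precision_floor[level - 1]]
        if ok.empty:
            raise ValueError(
                f"no grid point at rank {level} meets precision floor "
                f"{precision_floor[level - 1]}"
            )
        chosen.append(float(ok.iloc[0]["cutoff"]))
    monotone = np.maximum.accumulate(chosen)
    return CutoffScheme(tuple(float(c) for c in monotone))
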