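"""Paired-read preparation: primer, tail and quality trimming; merge/concat.

Amplicon read pairs are turned into clustering-ready sequences in four
steps: (1) the PCR primer is trimmed off the 5' end of each read under
IUPAC degeneracy, (2) a fixed number of low-quality bases is cut from the
3' end of the reverse read, (3) each read is truncated at the first base
whose Phred score falls below a threshold, so that every surviving base
meets the threshold, and (4) the pair is either merged over its overlap
(short amplicons) or concatenated fwd + revcomp(rev) with the junction
recorded (amplicons too long for the reads to overlap).

Merging rejects pairs that overlap by fewer than ``min_overlap`` bases,
contain more than ``max_mismatches`` mismatches in the overlap, or merge
to fewer than ``min_merged_len`` bases.  In the overlap, conflicting bases
are resolved toward the higher Phred score and the merged quality is the
maximum of the two.

Two preparation profiles are used per marker: a stringent one (Q >= 25)
for building OTU centroids and a lenient one (Q >= 20) for the reads that
are mapped back onto the centroids, so that centroids are clean while as
many reads as possible are assigned.
"""

from __future__ import annotations

import dataclasses
import re
from collections.abc import Iterable
from typing import Optional, Union

import numpy as np
from Bio.Data.IUPACData import ambiguous_dna_values

from otugrad.core_io import QualRead, reverse_complement

# IUPAC code -> set of concrete bases it stands for ("N" matches anything).
IUPAC = {code: set(bases) for code, bases in ambiguous_dna_values.items()}


@dataclasses.dataclass(slots=True)
class AmpliconPair:
    """A forward/reverse read pair from one sample."""

    fwd: QualRead
    rev: QualRead
    sample_id: str


@dataclasses.dataclass(slots=True)
class PreparedSequence:
    """A clustering-ready sequence: either merged or concatenated.

    ``junction`` is the index where the forward part ends and is present
    iff ``kind == "concatenated"``.
    """

    seq: str
    kind: str  # "merged" | "concatenated"
    sample_id: str
    junction: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind == "merged":
            if self.junction is not None:
                raise ValueError("merged sequences carry no junction")
        elif self.kind == "concatenated":
            if self.junction is None or not 0 < self.junction < len(self.seq):
                raise ValueError("concatenated sequences need 0 < junction < length")
        else:
            raise ValueError(f"unknown kind {self.kind!r}")


@dataclasses.dataclass(slots=True)
class Rejection:
    """A pair that failed preparation, with a reason code.

    Reason codes: ``primer``, ``empty``, ``overlap``, ``mismatches``,
    ``length``.
    """

    sample_id: str
    read_id: str
    reason: str


PrepOutcome = Union[PreparedSequence, Rejection]


def _iupac_regex(primer: str) -> re.Pattern:
    parts = []
    for code in primer.upper():
        bases = IUPAC.get(code)
        if bases is None:
            raise ValueError(f"invalid IUPAC code {code!r} in primer")
        parts.append(next(iter(bases)) if len(bases) == 1 else "[" + "".join(sorted(bases)) + "]")
    return re.compile("".join(parts))


def trim_primer(read: QualRead, primer: str, max_mismatches: int = 0) -> QualRead:
    """Remove a 5'-anchored IUPAC primer; flag the read discarded on no match.

    The primer must match at position 0 with at most ``max_mismatches``
    mismatches beyond IUPAC degeneracy.
    """
    if not primer:
        raise ValueError("empty primer")
    primer = primer.upper()
    if len(read.seq) < len(primer):
        return dataclasses.replace(read, discarded=True, reason="primer")
    prefix = read.seq[: len(primer)]
    mismatches = 0
    for base, code in zip(prefix, primer):
        allowed = IUPAC.get(code)
        if allowed is None:
            raise ValueError(f"invalid IUPAC code {code!r} in primer")
        if base not in allowed:
            mismatches += 1
            if mismatches > max_mismatches:
                return dataclasses.replace(read, discarded=True, reason="primer")
    n = len(primer)
    out = QualRead(read.id, read.seq[n:], read.quals[n:], read.orientation)
    if not out.seq:
        out.discarded, out.reason = True, "empty"
    return out


def trim_fixed_tail(read: QualRead, n: int) -> QualRead:
    """Drop the last ``n`` bases; the read is discarded if nothing remains."""
    if n < 0:
        raise ValueError(f"tail length must be >= 0, got {n}")
    if n == 0:
        return read
    if n >= len(read.seq):
        return QualRead(read.id, "", read.quals[:0], read.orientation, True, "empty")
    return QualRead(read.id, read.seq[:-n], read.quals[:-n], read.orientation)


def quality_truncate(read: QualRead, qmin: int) -> QualRead:
    """Truncate at the first base (5'->3') with quality below ``qmin``.

    Every base of the result has quality >= ``qmin``; this is the only
    deterministic truncation rule with that guarantee.
    """
    if not 0 <= qmin <= 60:
        raise ValueError(f"qmin must be in [0, 60], got {qmin}")
    if len(read.quals) == 0 or read.quals.min() >= qmin:
        return read
    cut = int(np.argmax(read.quals < qmin))
    if cut == 0:
        return QualRead(read.id, "", read.quals[:0], read.orientation, True, "empty")
    return QualRead(read.id, read.seq[:cut], read.quals[:cut], read.orientation)


_BASES = b"ACGT"


def _overlap_match_counts(fwd: str, rc_rev: str) -> np.ndarray:
    """Matching-base counts for every overlap length L = 1..min(m, n).

    ``counts[L-1]`` is the number of positions where the last L bases of
    ``fwd`` equal the first L bases of ``rc_rev``.  Computed as a sum of
    per-base cross-correlations so the exhaustive search stays cheap.
    """
    f = np.frombuffer(fwd.encode("ascii"), dtype=np.uint8)
    r = np.frombuffer(rc_rev.encode("ascii"), dtype=np.uint8)
    m, n = len(f), len(r)
    total = np.zeros(m + n - 1, dtype=np.float32)
    for b in _BASES:
        total += np.correlate((f == b).astype(np.float32), (r == b).astype(np.float32), "full")
    # Overlap L corresponds to lag m - L, i.e. index (m - L) + (n - 1).
    lmax = min(m, n)
    idx = (np.arange(1, lmax + 1) * -1) + (m + n - 1)
    return np.rint(total[idx]).astype(np.int64)


def merge_pair(
    pair: AmpliconPair,
    min_overlap: int = 100,
    max_mismatches: int = 3,
    min_merged_len: int = 300,
) -> PrepOutcome:
    """Merge a read pair over its best overlap, or reject it with a reason.

    The reverse read is reverse-complemented, the overlap length maximizing
    the number of matching bases is chosen (ties toward the longer
    overlap), and the pair is rejected if the best overlap is shorter than
    ``min_overlap`` (reason ``overlap``), has more than ``max_mismatches``
    mismatches (reason ``mismatches``), or merges to fewer than
    ``min_merged_len`` bases (reason ``length``).
    """
    fwd, rev = pair.fwd, pair.rev
    if fwd.discarded or rev.discarded or not fwd.seq or not rev.seq:
        return Rejection(pair.sample_id, fwd.id, "empty")
    rc_seq = reverse_complement(rev.seq)
    rc_quals = rev.quals[::-1]
    counts = _overlap_match_counts(fwd.seq, rc_seq)
    best_l = int(np.flatnonzero(counts == counts.max()).max()) + 1
    mismatches = best_l - int(counts[best_l - 1])
    m = len(fwd.seq)
    if best_l < min_overlap:
        return Rejection(pair.sample_id, fwd.id, "overlap")
    if mismatches > max_mismatches:
        return Rejection(pair.sample_id, fwd.id, "mismatches")
    merged_len = m + len(rc_seq) - best_l
    if merged_len < min_merged_len:
        return Rejection(pair.sample_id, fwd.id, "length")

    f_over = fwd.seq[m - best_l :]
    r_over = rc_seq[:best_l]
    fq = fwd.quals[m - best_l :]
    rq = rc_quals[:best_l]
    if mismatches == 0:
        overlap_seq = f_over
    else:
        # conflicting bases resolved toward the higher Phred score (tie: fwd)
        take_rev = (np.frombuffer(f_over.encode(), np.uint8) != np.frombuffer(r_over.encode(), np.uint8)) & (
            rq > fq
        )
        chars = np.frombuffer(f_over.encode(), np.uint8).copy()
        chars[take_rev] = np.frombuffer(r_over.encode(), np.uint8)[take_rev]
        overlap_seq = chars.tobytes().decode("ascii")
    seq = fwd.seq[: m - best_l] + overlap_seq + rc_seq[best_l:]
    return PreparedSequence(seq, "merged", pair.sample_id)


def concatenate_pair(pair: AmpliconPair) -> PrepOutcome:
    """Join fwd + revcomp(rev) with the junction at the forward length."""
    fwd, rev = pair.fwd, pair.rev
    if fwd.discarded or rev.discarded or not fwd.seq or not rev.seq:
        return Rejection(pair.sample_id, fwd.id, "empty")
    seq = fwd.seq + reverse_complement(rev.seq)
    return PreparedSequence(seq, "concatenated", pair.sample_id, junction=len(fwd.seq))


@dataclasses.dataclass(slots=True)
class PrepProfile:
    """One preparation recipe (primers, tail trim, quality threshold, mode)."""

    fwd_primer: str
    rev_primer: str
    tail_trim_rev: int
    qmin: int
    mode: str  # "merge" | "concatenate"
    max_primer_mismatches: int = 0
    min_overlap: int = 100
    max_mismatches: int = 3
    min_merged_len: int = 300

    def __post_init__(self) -> None:
        if self.mode not in ("merge", "concatenate"):
            raise ValueError(f"unknown prep mode {self.mode!r}")


def prepare_pair(pair: AmpliconPair, profile: PrepProfile) -> PrepOutcome:
    """Run the full preparation chain for one pair under one profile."""
    fwd = trim_primer(pair.fwd, profile.fwd_primer, profile.max_primer_mismatches)
    rev = trim_primer(pair.rev, profile.rev_primer, profile.max_primer_mismatches)
    if fwd.discarded or rev.discarded:
        return Rejection(pair.sample_id, pair.fwd.id, fwd.reason or rev.reason or "primer")
    rev = trim_fixed_tail(rev, profile.tail_trim_rev)
    fwd = quality_truncate(fwd, profile.qmin)
    rev = quality_truncate(rev, profile.qmin)
    if fwd.discarded or rev.discarded:
        return Rejection(pair.sample_id, pair.fwd.id, "empty")
    trimmed = AmpliconPair(fwd, rev, pair.sample_id)
    if profile.mode == "merge":
        return merge_pair(
            trimmed,
            min_overlap=profile.min_overlap,
            max_mismatches=profile.max_mismatches,
            min_merged_len=profile.min_merged_len,
        )
    return concatenate_pair(trimmed)


def prepare_pairs(
    pairs: Iterable[AmpliconPair], profile: PrepProfile
) -> tuple[list[PreparedSequence], list[Rejection]]:
    """Prepare a batch of pairs; returns (survivors, rejections)."""
    kept: list[PreparedSequence] = []
    rejected: list[Rejection] = []
    for pair in pairs:
        out = prepare_pair(pair, profile)
        if isinstance(out, PreparedSequence):
            kept.append(out)
        else:
            rejected.append(out)
    return kept, rejected


def write_rejection_audit(rejections: Iterable[Rejection], path) -> None:
    """Log rejected pairs (sample, read id, reason) to a TSV audit file."""
    with open(path, "w") as fh:
        fh.write("sample_id\tread_id\treason\n")
        for rej in rejections:
            fh.write(f"{rej.sample_id}\t{rej.read_id}\t{rej.reason}\n")
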