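"""Linking chloroplast 16S OTUs to nuclear 18S OTUs.

Phytoplankton appear twice in paired-marker surveys: through their
nuclear 18S rRNA gene and through the plastid 16S rRNA gene amplified by
bacterial primers.  This module correlates all 16S OTUs against all 18S
OTUs across samples (Spearman, on relative abundances), extracts strongly
correlated pairs (rho >= 0.8 by default), counts how often the 16S OTUs
flagged as chloroplast share a class-level taxonomy with their 18S
partner, and computes an empirical p-value for that level of matching by
shuffling the class labels among the correlated 18S OTUs: p = n / N,
where n of N shuffles reach at least the observed number of matches.

An exact enumeration (multiset-aware, for shuffle populations of up to
ten OTUs) serves as the oracle for the Monte-Carlo shuffler.
"""

from __future__ import annotations

import dataclasses
import logging


import numpy as np
from scipy import stats
from sympy.utilities.iterables import multiset_permutations

from otugrad.core_io import CLASS_LEVEL, OtuTable

logger = logging.getLogger(__name__)


@dataclasses.dataclass(slots=True)
class LinkedPair:
    """A strongly correlated 16S/18S OTU pair."""

    otu16_id: str
    otu18_id: str
    rho: float
    chloroplast_flag: bool
    class16: str
    class18: str


def _rank_rows(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mid-ranked, standardized rows; second output flags zero variance."""
    ranks = stats.rankdata(matrix, axis=1)
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((ranks**2).sum(axis=1))
    flat = norms == 0
    norms[flat] = 1.0
    return ranks / norms[:, None], flat


def _is_chloroplast(table: OtuTable, otu_id: str, token: str) -> bool:
    lineage = table.lineages.get(otu_id)
    return lineage is not None and token in lineage.ranks[: lineage.depth]


def _class_name(table: OtuTable, otu_id: str) -> str:
    lineage = table.lineages.get(otu_id)
    if lineage is None or lineage.depth < CLASS_LEVEL + 1:
        return ""
    return lineage.name_at(CLASS_LEVEL + 1)


def correlate_tables(
    table16: OtuTable,
    table18: OtuTable,
    min_rho: float = 0.8,
    chloroplast_token: str = "Chloroplast",
) -> list[LinkedPair]:
    """All-vs-all Spearman correlation of 16S against 18S OTU frequencies.

    Pairs with rho >= ``min_rho`` are returned, annotated with the
    class-level names of both sides and a chloroplast flag for the 16S
    OTU (its lineage contains ``chloroplast_token``).  OTUs with zero
    variance across samples are skipped with a log note.
    """
    if table16.sample_ids != table18.sample_ids:
        raise ValueError("16S and 18S tables must cover the same samples in the same order")
    freq16 = table16.counts / table16.counts.sum(axis=0, keepdims=True)
    freq18 = table18.counts / table18.counts.sum(axis=0, keepdims=True)
    r16, flat16 = _rank_rows(freq16)
    r18, flat18 = _rank_rows(freq18)
    n_flat = int(flat16.sum() + flat18.sum())
    if n_flat:
        logger.info("skipping %d zero-variance OTUs in correlation", n_flat)
    rho = r16 @ r18.T  # Pearson of mid-ranks == Spearman
    rho[flat16, :] = np.nan
    rho[:, flat18] = np.nan
    pairs: list[LinkedPair] = []
    for i, j in zip(*np.where(rho >= min_rho)):
        otu16 = table16.otu_ids[i]
        otu18 = table18.otu_ids[j]
        pairs.append(
            LinkedPair(
                otu16,
                otu18,
                float(rho[i, j]),
                _is_chloroplast(table16, otu16, chloroplast_token),
                _class_name(table16, otu16),
                _class_name(table18, otu18),
            )
        )
    return pairs


def count_class_matches(pairs: list[LinkedPair]) -> tuple[int, int]:
    """(matches, evaluable) over the chloroplast-16S pairs.

    A pair is evaluable when both sides carry a class-level name; matches
    are pairs with identical class names.
    """
    chloro = [p for p in pairs if p.chloroplast_flag]
    evaluable = [p for p in chloro if p.class16 and p.class18]
    dropped = len(chloro) - len(evaluable)
    if dropped:
        logger.info("%d chloroplast pairs lack a class annotation and are not evaluable", dropped)
    matches = sum(1 for p in evaluable if p.class16 == p.class18)
    return matches, len(evaluable)


def _shuffle_setup(
    pairs: list[LinkedPair], annotated_only: bool = True
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Shuffle population (distinct correlated 18S OTUs), their class
    labels (encoded), and the chloroplast pairs as (position, class16 code)."""
    population: dict[str, str] = {}
    for p in pairs:
        if p.otu18_id not in population:
            population[p.otu18_id] = p.class18
    if annotated_only:
        population = {o: c for o, c in population.items() if c}
    otus = list(population)
    classes = sorted({c for c in population.values()} | {p.class16 for p in pairs if p.class16})
    code = {c: i for i, c in enumerate(classes)}
    code[""] = -1
    labels = np.array([code[population[o]] for o in otus], dtype=np.int64)
    pos = {o: i for i, o in enumerate(otus)}
    chloro = [
        (pos[p.otu18_id], code[p.class16])
        for p in pairs
        if p.chloroplast_flag and p.class16 and p.otu18_id in pos
    ]
    targets = np.array(chloro, dtype=np.int64).reshape(-1, 2)
    return otus, labels, targets


def permutation_pvalue(
    pairs: list[LinkedPair],
    threshold_k: int,
    n_shuffles: int = 10**6,
    rng: int | np.random.Generator = 0,
    annotated_only: bool = True,
) -> float:
    """Monte-Carlo p-value of observing >= ``threshold_k`` class matches.

    The class labels of the correlated 18S OTUs (one label per distinct
    OTU) are shuffled ``n_shuffles`` times; each shuffle recounts the
    matches between chloroplast 16S OTUs and their partner's shuffled
    label; p = n / N where n shuffles reach the threshold.
    """
    if n_shuffles < 1:
        raise ValueError("need at least one shuffle")
    if threshold_k <= 0:
        return 1.0
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    otus, labels, targets = _shuffle_setup(pairs, annotated_only)
    if threshold_k > len(targets):
        logger.warning(
            "threshold %d exceeds the %d evaluable pairs; p = 0", threshold_k, len(targets)
        )
        return 0.0
    label_multiset = np.sort(labels)
    hits = 0
    chunk = 100_000
    done = 0
    while done < n_shuffles:
        size = min(chunk, n_shuffles - done)
        perms = rng.permuted(np.tile(labels, (size, 1)), axis=1)
        if __debug__ and size:
            assert np.array_equal(np.sort(perms[0]), label_multiset)
        matches = np.zeros(size, dtype=np.int64)
        for position, class16 in targets:
            matches += perms[:, position] == class16
        hits += int((matches >= threshold_k).sum())
        done += size
    return hits / n_shuffles


def exact_pvalue_small(
    pairs: list[LinkedPair],
    threshold_k: int,
    annotated_only: bool = True,
    max_population: int = 10,
) -> float:
    """Exact shuffle p-value by enumerating all distinct label arrangements.

    Each distinct arrangement of the label multiset is equally likely
    under a uniform random permutation, so the p-value is the fraction of
    arrangements reaching the threshold.  Only feasible for small
    populations (<= ``max_population``).
    """
    if threshold_k <= 0:
        return 1.0
    otus, labels, targets = _shuffle_setup(pairs, annotated_only)
    if len(otus) > max_population:
        raise ValueError(
            f"population of {len(otus)} OTUs is too large for exact enumeration; "
            "use permutation_pvalue"
        )
    if threshold_k > len(targets):
        return 0.0
    total = 0
    hits = 0
    for arrangement in multiset_permutations(labels.tolist()):
        total += 1
        matches = sum(1 for position, class16 in targets if arrangement[position] == class16)
        if matches >= threshold_k:
            hits += 1
    return hits / total


def write_pairs_tsv(pairs: list[LinkedPair], path) -> None:
    with open(path, "w") as fh:
        fh.write("otu16_id\totu18_id\trho\tchloroplast\tclass16\tclass18\n")
        for p in pairs:
            fh.write(
                f"{p.otu16_id}\t{p.otu18_id}\t{p.rho:.4f}\t"
                f"{int(p.chloroplast_flag)}\t{p.class16}\t{p.class18}\n"
            )
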