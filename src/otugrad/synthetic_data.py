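"""Synthetic data with the statistical structure the analysis assumes.

Three generators make the whole pipeline testable without downloads:

* a rank-structured reference database — sequences mutated down an
  8-rank taxonomic tree so that the realized pairwise identity between
  leaves whose deepest shared rank is r hits a per-rank target (siblings
  within a genus more similar than siblings within a family, and so on);
  primer-binding sites are kept unmutated so reads can be excised at
  them;
* brackish-gradient communities — each taxon gets a Gaussian niche
  response (optimum uniform over the salinity range, lognormal
  tolerance and baseline), so composition turns over smoothly along the
  gradient; a linked 16S community adds chloroplast taxa whose
  abundances track a chosen fraction of the eukaryotic taxa and whose
  class-level annotation is the host's class, mirroring how plastid 16S
  sequences classify to their host lineage;
* paired reads — drawn multinomially per station from taxon abundances
  (scaled by lognormal rRNA copy-number multipliers), excised at the
  primer coordinates with a short-amplicon (overlapping, mergeable)
  16S geometry or a long-amplicon (inner gap, concatenation-only) 18S
  geometry, with per-base substitution errors at Phred-consistent rates.

Everything is driven by one seed; all outputs are byte-identical across
runs with the same configuration.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional

import numpy as np
import pandas as pd

from otugrad.core_io import (
    Lineage,
    N_RANKS,
    QualRead,
    RefEntry,
    ReferenceDB,
    reverse_complement,
)
from otugrad.read_prep import AmpliconPair, IUPAC

# Primer sequences of the targeted V3-V4 (16S) and V4-V5 (18S) regions.
PRIMER_16S_F = "CCTACGGGNGGCWGCAG"  # 341F
PRIMER_16S_R = "GACTACHVGGGTATCTAATCC"  # 805R
PRIMER_18S_F = "CGGTAAYTCCAGCTCYV"  # 574*F
PRIMER_18S_R = "CCGTCAATTHCTTYAAR"  # 1132R

_RANK_CODES = ("k", "sg", "dv", "cl", "or", "fa", "ge", "sp")


@dataclasses.dataclass(frozen=True, slots=True)
class MarkerGeometry:
    """Amplicon and read geometry for one marker.

    With the defaults, 16S read pairs overlap by >100 bases after
    trimming (mergeable) while 18S pairs leave an inner gap and must be
    concatenated.
    """

    marker: str
    fwd_primer: str
    rev_primer: str
    core_len: int
    read_len: int = 300
    tail_trim_rev: int = 40
    mode: str = "merge"  # "merge" | "concatenate"

    @property
    def amplicon_len(self) -> int:
        return len(self.fwd_primer) + self.core_len + len(self.rev_primer)


GEOMETRY_16S = MarkerGeometry("16S", PRIMER_16S_F, PRIMER_16S_R, 390, 300, 40, "merge")
GEOMETRY_18S = MarkerGeometry("18S", PRIMER_18S_F, PRIMER_18S_R, 560, 300, 44, "concatenate")


@dataclasses.dataclass(frozen=True, slots=True)
class SimConfig:
    """Study conditions for the synthetic gradient survey.

    ``rank_identity_targets[r]`` is the expected pairwise identity (over
    the amplicon core) of two leaves whose deepest shared rank is r + 1;
    targets must be strictly increasing from kingdom to species.
    """

    seed: int = 1
    n_stations: int = 21
    salinity_range: tuple[float, float] = (2.0, 30.0)
    children_per_rank: tuple[int, ...] = (2, 1, 2, 2, 1, 2, 2, 2)
    rank_identity_targets: tuple[float, ...] = (
        0.75,
        0.79,
        0.83,
        0.87,
        0.91,
        0.945,
        0.975,
        0.995,
    )
    reads_per_sample: int = 50_000
    error_rate: float = 0.001
    qual_range: tuple[int, int] = (36, 24)
    copy_number_sigma: float = 0.5
    chloroplast_fraction: float = 0.5
    chloroplast_total_fraction: float = 0.05
    niche_tolerance_mean: float = 6.0
    niche_tolerance_sigma: float = 0.3
    baseline_sigma: float = 1.0
    station_noise_sigma: float = 0.8
    metazoan_spike: int = 0
    metazoan_spike_factor: float = 20.0
    geometry_16s: MarkerGeometry = GEOMETRY_16S
    geometry_18s: MarkerGeometry = GEOMETRY_18S

    def __post_init__(self) -> None:
        if len(self.children_per_rank) != N_RANKS:
            raise ValueError(f"children_per_rank needs {N_RANKS} entries")
        t = self.rank_identity_targets
        if len(t) != N_RANKS:
            raise ValueError(f"rank_identity_targets needs {N_RANKS} entries")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("rank identity targets must be strictly increasing")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error rate must be in [0, 1)")
        if not 0.0 <= self.chloroplast_fraction <= 1.0:
            raise ValueError("chloroplast fraction must be in [0, 1]")

    def salinities(self) -> np.ndarray:
        lo, hi = self.salinity_range
        return np.linspace(lo, hi, self.n_stations)


# ---------------------------------------------------------------------------
# Reference taxonomy
# ---------------------------------------------------------------------------


def _resolve_iupac(primer: str, rng: np.random.Generator) -> str:
    return "".join(sorted(IUPAC[c])[rng.integers(len(IUPAC[c]))] for c in primer)


def _per_lineage_mutations(target_identity: float, core_len: int) -> int:
    """Mutated positions per lineage below a shared node so that the
    expected pairwise difference hits 1 - target.

    With two lineages each mutating a fraction f of positions (disjoint
    within a lineage, independent between lineages, substitutions to a
    uniform other base), the expected differing fraction is
    p = 2 f - (4/3) f^2; invert for f.
    """
    p = 1.0 - target_identity
    disc = 4.0 - (16.0 / 3.0) * p
    if disc < 0:
        raise ValueError(f"identity target {target_identity} unreachable")
    f = (2.0 - math.sqrt(disc)) / (8.0 / 3.0)
    return int(round(f * core_len))


_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


def _mutate_core(
    core: np.ndarray, n_mut: int, available: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Mutate ``n_mut`` positions drawn from ``available`` (no position is
    mutated twice along one root-to-leaf path); returns (core, remaining)."""
    if n_mut == 0:
        return core, available
    pick = rng.choice(len(available), size=min(n_mut, len(available)), replace=False)
    positions = available[pick]
    core = core.copy()
    shifts = rng.integers(1, 4, size=len(positions))
    idx = np.searchsorted(_BASE_ARR, core[positions])
    core[positions] = _BASE_ARR[(idx + shifts) % 4]
    keep = np.ones(len(available), dtype=bool)
    keep[pick] = False
    return core, available[keep]


def simulate_reference_taxonomy(
    config: SimConfig,
    geometry: MarkerGeometry,
    rng: int | np.random.Generator = None,
    prefix: str = "T",
    root_edge_factor: float = 0.3,
) -> ReferenceDB:
    """Mutate a random root amplicon down an 8-rank tree.

    Per-edge mutation counts are derived from the per-rank identity
    targets (deeper shared ranks leave fewer private mutations); primer
    sites flank the core unmutated.  Deterministic per rng state.
    """
    if rng is None:
        rng = config.seed
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    L = geometry.core_len
    # cum[r-1] = per-lineage mutated positions below a rank-r node; two
    # leaves with their MRCA at rank r then differ by ~2*cum[r-1] positions
    # (collision-corrected), matching rank_identity_targets[r-1].  Targets
    # are whole-amplicon identities, but only the core mutates: rescale the
    # wanted divergence by amplicon/core length before inverting.
    flank = geometry.amplicon_len / L
    cum = []
    for t in config.rank_identity_targets:
        core_target = 1.0 - (1.0 - t) * flank
        if core_target <= 0:
            raise ValueError(f"identity target {t} unreachable at this amplicon geometry")
        cum.append(_per_lineage_mutations(core_target, L))
    edge = [int(round(cum[0] * root_edge_factor))]  # kingdom edge: target-free
    for level in range(1, N_RANKS - 1):
        k = cum[level - 1] - cum[level]
        if k < 0:
            raise ValueError("identity targets yield a negative edge mutation count")
        edge.append(k)
    # species edge: the full within-genus budget (the species-level target
    # governs intra-species copies, which references do not carry here)
    edge.append(cum[N_RANKS - 2])

    fwd_site = _resolve_iupac(geometry.fwd_primer, rng)
    rev_site = reverse_complement(_resolve_iupac(geometry.rev_primer, rng))
    root_core = _BASE_ARR[rng.integers(0, 4, size=L)]

    entries: dict[str, RefEntry] = {}

    def descend(
        core: np.ndarray,
        available: np.ndarray,
        level: int,
        path: tuple[str, ...],
    ) -> None:
        if level == N_RANKS:
            name = path[-1]
            seq = fwd_site + core.tobytes().decode("ascii") + rev_site
            entries[name] = RefEntry(seq, Lineage(path, N_RANKS))
            return
        n_children = config.children_per_rank[level]
        n_mut = edge[level]
        for child in range(1, n_children + 1):
            child_core, child_avail = _mutate_core(core, n_mut, available, rng)
            label = f"{prefix}.{_RANK_CODES[level]}{child}" if level == 0 else (
                f"{path[-1]}.{_RANK_CODES[level]}{child}"
            )
            descend(child_core, child_avail, level + 1, path + (label,))

    descend(root_core, np.arange(L), 0, ())
    return ReferenceDB(entries)


def measure_rank_identities(refdb: ReferenceDB, pairwise_identity) -> dict[int, list[float]]:
    """Observed leaf-pair identities grouped by deepest shared rank (1-based)."""
    ids = refdb.ids()
    out: dict[int, list[float]] = {}
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            li, lj = refdb.lineage(ids[i]), refdb.lineage(ids[j])
            shared = 0
            for level in range(N_RANKS):
                if li.ranks[level] == lj.ranks[level]:
                    shared = level + 1
                else:
                    break
            out.setdefault(shared, []).append(
                pairwise_identity(refdb.seq(ids[i]), refdb.seq(ids[j]))
            )
    return out


# ---------------------------------------------------------------------------
# Communities
# ---------------------------------------------------------------------------


@dataclasses.dataclass(slots=True)
class TrueCommunity:
    """Ground-truth taxon x station abundances along the gradient."""

    sample_ids: list[str]
    salinities: np.ndarray
    taxon_ids: list[str]
    abundances: np.ndarray  # taxon x station, arbitrary units
    optima: np.ndarray
    tolerances: np.ndarray
    lineages: dict[str, Lineage]
    copy_numbers: np.ndarray
    chloroplast_flags: np.ndarray

    def __post_init__(self) -> None:
        if (self.abundances < 0).any():
            raise ValueError("abundances must be non-negative")
        if (self.abundances.sum(axis=0) <= 0).any():
            raise ValueError("every station needs a positive total abundance")

    def read_weights(self) -> np.ndarray:
        """Per-station multinomial probabilities (abundance x copy number)."""
        w = self.abundances * self.copy_numbers[:, None]
        return w / w.sum(axis=0, keepdims=True)


def _station_frame(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    sal = config.salinities()
    temp = 20.0 - 0.25 * sal + rng.normal(0.0, 1.0, size=len(sal))
    return pd.DataFrame(
        {
            "sample_id": [f"S{i + 1:02d}" for i in range(len(sal))],
            "salinity": np.round(sal, 2),
            "temperature": np.round(temp, 2),
            "station": [f"ST{i + 1:02d}" for i in range(len(sal))],
        }
    )


def simulate_gradient_communities(
    refdb: ReferenceDB,
    config: SimConfig,
    rng: int | np.random.Generator = None,
    metadata: Optional[pd.DataFrame] = None,
) -> TrueCommunity:
    """Gaussian niche responses along the salinity gradient.

    abundance(taxon, station) = lognormal baseline
    x exp(-(salinity - optimum)^2 / (2 tolerance^2)) x lognormal
    station-level noise, stations ordered by salinity.  Copy-number
    multipliers (lognormal) are stored separately so they bias read
    counts, not the truth community.
    """
    if rng is None:
        rng = config.seed
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if metadata is None:
        metadata = _station_frame(config, rng)
    sal = metadata["salinity"].to_numpy(dtype=float)
    taxa = refdb.ids()
    n = len(taxa)
    lo, hi = config.salinity_range
    optima = rng.uniform(lo, hi, size=n)
    tolerances = np.exp(
        rng.normal(math.log(config.niche_tolerance_mean), config.niche_tolerance_sigma, size=n)
    )
    baseline = np.exp(rng.normal(0.0, config.baseline_sigma, size=n))
    response = np.exp(-((sal[None, :] - optima[:, None]) ** 2) / (2.0 * tolerances[:, None] ** 2))
    abundances = baseline[:, None] * response
    if config.station_noise_sigma > 0:
        # biological/sampling overdispersion: taxa do not track their niche
        # exactly, which keeps unrelated taxa from correlating perfectly
        abundances = abundances * np.exp(
            rng.normal(0.0, config.station_noise_sigma, size=abundances.shape)
        )
    copy_numbers = np.exp(rng.normal(0.0, config.copy_number_sigma, size=n))
    if config.metazoan_spike:
        spike = rng.choice(n, size=min(config.metazoan_spike, n), replace=False)
        copy_numbers[spike] *= config.metazoan_spike_factor
    return TrueCommunity(
        sample_ids=list(metadata["sample_id"]),
        salinities=sal,
        taxon_ids=taxa,
        abundances=abundances,
        optima=optima,
        tolerances=tolerances,
        lineages={t: refdb.lineage(t) for t in taxa},
        copy_numbers=copy_numbers,
        chloroplast_flags=np.zeros(n, dtype=bool),
    )


def simulate_linked_marker_communities(
    euk_community: TrueCommunity,
    bacterial_refdb: ReferenceDB,
    bacterial_community: TrueCommunity,
    config: SimConfig,
    rng: int | np.random.Generator = None,
    scramble: int = 0,
) -> tuple[ReferenceDB, TrueCommunity, pd.DataFrame]:
    """Add chloroplast 16S taxa that track eukaryotic 18S abundances.

    A ``chloroplast_fraction`` of the eukaryotic taxa each contribute one
    chloroplast 16S taxon whose station profile is a fixed per-taxon
    multiple of the host's 18S profile and whose class-level annotation
    is the host's class (plastid sequences classify to the host lineage).
    ``scramble`` chloroplast taxa instead get an independent profile —
    still annotated with their nominal host's class — to emulate
    coincidental correlations.  Returns the extended 16S reference, the
    combined 16S community, and the link truth table.
    """
    if rng is None:
        rng = config.seed
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    n_euk = len(euk_community.taxon_ids)
    n_linked = int(round(config.chloroplast_fraction * n_euk))
    geometry = config.geometry_16s
    entries = dict(bacterial_refdb.entries)
    rows = []
    chl_abund = []
    chl_ids: list[str] = []
    chl_lineages: dict[str, Lineage] = {}
    if n_linked:
        hosts = rng.choice(n_euk, size=n_linked, replace=False)
        root_core = _BASE_ARR[rng.integers(0, 4, size=geometry.core_len)]
        fwd_site = _resolve_iupac(geometry.fwd_primer, rng)
        rev_site = reverse_complement(_resolve_iupac(geometry.rev_primer, rng))
        n_div = max(1, int(round(0.05 * geometry.core_len)))
        bact_total = bacterial_community.abundances.sum()
        for k, host_idx in enumerate(hosts, start=1):
            host = euk_community.taxon_ids[host_idx]
            host_class = euk_community.lineages[host].name_at(4)
            core, _ = _mutate_core(root_core, n_div, np.arange(geometry.core_len), rng)
            name = f"Chl.sp{k}"
            lineage = Lineage(
                (
                    "Bacteria_chl",
                    "Cyanobacteriota",
                    "Chloroplast",
                    host_class,
                    f"Chl.or{k}",
                    f"Chl.fa{k}",
                    f"Chl.ge{k}",
                    name,
                ),
                N_RANKS,
            )
            entries[name] = RefEntry(fwd_site + core.tobytes().decode("ascii") + rev_site, lineage)
            ratio = math.exp(rng.normal(0.0, 0.2))
            if k > n_linked - scramble:
                profile = ratio * rng.permutation(euk_community.abundances[host_idx])
                linked = False
            else:
                profile = ratio * euk_community.abundances[host_idx]
                linked = True
            chl_abund.append(profile)
            chl_ids.append(name)
            chl_lineages[name] = lineage
            rows.append({"chloroplast_taxon": name, "host_taxon": host, "ratio": ratio,
                         "host_class": host_class, "linked": linked})
        chl_matrix = np.array(chl_abund)
        scale = config.chloroplast_total_fraction * bact_total / chl_matrix.sum()
        chl_matrix *= scale
    else:
        chl_matrix = np.zeros((0, len(bacterial_community.sample_ids)))

    combined = TrueCommunity(
        sample_ids=list(bacterial_community.sample_ids),
        salinities=bacterial_community.salinities,
        taxon_ids=list(bacterial_community.taxon_ids) + chl_ids,
        abundances=np.vstack([bacterial_community.abundances, chl_matrix]),
        optima=np.concatenate([bacterial_community.optima, np.full(len(chl_ids), np.nan)]),
        tolerances=np.concatenate([bacterial_community.tolerances, np.full(len(chl_ids), np.nan)]),
        lineages={**bacterial_community.lineages, **chl_lineages},
        copy_numbers=np.concatenate([bacterial_community.copy_numbers, np.ones(len(chl_ids))]),
        chloroplast_flags=np.concatenate(
            [np.zeros(len(bacterial_community.taxon_ids), dtype=bool), np.ones(len(chl_ids), dtype=bool)]
        ),
    )
    return ReferenceDB(entries), combined, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------


def quality_profile(
    read_len: int, error_rate: float, qual_range: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """(Phred scores, per-base substitution rates) for one read.

    Qualities ramp linearly from ``qual_range[0]`` at the 5' end to
    ``qual_range[1]`` at the 3' end, rescaled so the mean error
    probability equals ``error_rate``; scores are Phred-consistent with
    the rates used to draw errors.
    """
    if error_rate == 0.0:
        return np.full(read_len, 40, dtype=np.int16), np.zeros(read_len)
    q = np.linspace(qual_range[0], qual_range[1], read_len)
    rates = 10.0 ** (-q / 10.0)
    rates *= error_rate / rates.mean()
    quals = np.clip(np.rint(-10.0 * np.log10(rates)), 2, 41).astype(np.int16)
    return quals, rates


def simulate_sample_reads(
    community: TrueCommunity,
    refdb: ReferenceDB,
    geometry: MarkerGeometry,
    sample_id: str,
    n_reads: int,
    rng: np.random.Generator,
    error_rate: float,
    qual_range: tuple[int, int] = (36, 24),
) -> tuple[list[AmpliconPair], pd.Series]:
    """Paired reads for one station, plus the truth taxon counts.

    Read counts are multinomial in abundance x copy number; each read is
    the amplicon's first/last ``read_len`` bases (the reverse read
    reverse-complemented) with substitution errors applied per base at
    the Phred-consistent rate.
    """
    col = community.sample_ids.index(sample_id)
    weights = community.read_weights()[:, col]
    counts = rng.multinomial(n_reads, weights)
    quals, rates = quality_profile(geometry.read_len, error_rate, qual_range)
    pairs: list[AmpliconPair] = []
    for taxon, count in zip(community.taxon_ids, counts):
        if count == 0:
            continue
        amplicon = refdb.seq(taxon)
        if geometry.read_len > len(amplicon):
            raise ValueError(
                f"read length {geometry.read_len} exceeds amplicon length {len(amplicon)}"
            )
        fwd_t = amplicon[: geometry.read_len]
        rev_t = reverse_complement(amplicon[-geometry.read_len :])
        fwd_seqs = _apply_errors(fwd_t, int(count), rates, rng)
        rev_seqs = _apply_errors(rev_t, int(count), rates, rng)
        for k in range(int(count)):
            rid = f"{sample_id}:{taxon}:{k}"
            pairs.append(
                AmpliconPair(
                    QualRead(rid, fwd_seqs[k], quals, "forward"),
                    QualRead(rid, rev_seqs[k], quals, "reverse"),
                    sample_id,
                )
            )
    truth = pd.Series(counts, index=community.taxon_ids, name=sample_id)
    return pairs, truth


def _apply_errors(
    template: str, count: int, rates: np.ndarray, rng: np.random.Generator
) -> list[str]:
    if rates.max() == 0.0:
        return [template] * count
    hit_rows, hit_cols = np.where(rng.random((count, len(rates))) < rates[None, :])
    seqs: list[str] = [template] * count
    if len(hit_rows) == 0:
        return seqs
    arr = np.frombuffer(template.encode("ascii"), dtype=np.uint8)
    shifts = rng.integers(1, 4, size=len(hit_rows))
    start = 0
    for row in np.unique(hit_rows):
        end = np.searchsorted(hit_rows, row, side="right")
        cols = hit_cols[start:end]
        mutated = arr.copy()
        idx = np.searchsorted(_BASE_ARR, mutated[cols])
        mutated[cols] = _BASE_ARR[(idx + shifts[start:end]) % 4]
        seqs[row] = mutated.tobytes().decode("ascii")
        start = end
    return seqs


# ---------------------------------------------------------------------------
# Whole-dataset convenience
# ---------------------------------------------------------------------------


@dataclasses.dataclass(slots=True)
class SimulatedDataset:
    """A complete two-marker synthetic survey, read generation included."""

    config: SimConfig
    metadata: pd.DataFrame
    refdbs: dict[str, ReferenceDB]
    communities: dict[str, TrueCommunity]
    link_truth: pd.DataFrame

    def geometry(self, marker: str) -> MarkerGeometry:
        return self.config.geometry_16s if marker == "16S" else self.config.geometry_18s

    def _read_rng(self, marker: str, sample_index: int) -> np.random.Generator:
        key = 1000 + (0 if marker == "16S" else 1) * 500 + sample_index
        return np.random.default_rng(np.random.SeedSequence((self.config.seed, key)))

    def reads_for_sample(self, marker: str, sample_id: str) -> tuple[list[AmpliconPair], pd.Series]:
        idx = list(self.metadata["sample_id"]).index(sample_id)
        return simulate_sample_reads(
            self.communities[marker],
            self.refdbs[marker],
            self.geometry(marker),
            sample_id,
            self.config.reads_per_sample,
            self._read_rng(marker, idx),
            self.config.error_rate,
            self.config.qual_range,
        )


def simulate_dataset(config: SimConfig, scramble: int = 0) -> SimulatedDataset:
    """Build the full two-marker survey from one seed."""
    root = np.random.SeedSequence(config.seed)
    rng_meta, rng_ref16, rng_ref18, rng_comm16, rng_comm18, rng_link = (
        np.random.default_rng(s) for s in root.spawn(6)
    )
    metadata = _station_frame(config, rng_meta)
    refdb16 = simulate_reference_taxonomy(config, config.geometry_16s, rng_ref16, prefix="B")
    refdb18 = simulate_reference_taxonomy(config, config.geometry_18s, rng_ref18, prefix="E")
    comm16_bact = simulate_gradient_communities(refdb16, config, rng_comm16, metadata)
    comm18 = simulate_gradient_communities(refdb18, config, rng_comm18, metadata)
    refdb16_full, comm16, link_truth = simulate_linked_marker_communities(
        comm18, refdb16, comm16_bact, config, rng_link, scramble=scramble
    )
    return SimulatedDataset(
        config,
        metadata,
        {"16S": refdb16_full, "18S": refdb18},
        {"16S": comm16, "18S": comm18},
        link_truth,
    )
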