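"""End-to-end orchestration: reads -> OTU tables -> taxonomy -> statistics.

``run_pipeline`` executes, per marker, the two-pass OTU construction
(stringent centroid pass, lenient mapping pass), classifies the centroids
against the reference, and then runs the gradient statistics: Spearman
beta-diversity with PCoA and the PC1-salinity correlation, hierarchical
clustering, a Mantel test between the two markers, subsampled
alpha-diversity (community-wide and per phylum with the horohalinicum
contrast), and the chloroplast 16S / nuclear 18S linking test.

Inputs are either per-sample FASTQ pairs plus a reference database and
metadata, or a :class:`~otugrad.synthetic_data.SimConfig`, in which case
the whole survey is simulated in memory.  Every randomized stage draws
from generators spawned off the single configured seed, so a fixed
configuration reproduces its output bundle bit for bit; any stage
failure aborts with the stage name and cause.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from otugrad import community_analysis as ca
from otugrad import core_io, cross_domain_linking as link
from otugrad.consensus_taxonomy import (
    Assignment,
    CutoffScheme,
    align_query_to_refs,
    assign_paired,
    assign_single,
    write_assignments_tsv,
)
from otugrad.core_io import OtuTable, ReferenceDB, parse_fastq
from otugrad.otu_clustering import Dereplicator, greedy_cluster, map_uniques_to_centroids
from otugrad.read_prep import AmpliconPair, PreparedSequence, PrepProfile, prepare_pair
from otugrad.synthetic_data import (
    MarkerGeometry,
    GEOMETRY_16S,
    GEOMETRY_18S,
    SimConfig,
    SimulatedDataset,
    simulate_dataset,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclasses.dataclass(slots=True)
class MarkerInput:
    """Where one marker's reads and reference come from (file mode)."""

    geometry: MarkerGeometry
    fastq_pairs: dict[str, tuple[str, str]]  # sample_id -> (fwd, rev)
    reference_fasta: str
    reference_taxonomy: str


@dataclasses.dataclass(slots=True)
class PipelineConfig:
    """Everything ``run_pipeline`` needs; synthetic or file-backed."""

    seed: int = 1
    sim: Optional[SimConfig] = None
    scramble_links: int = 0
    markers: dict[str, MarkerInput] = dataclasses.field(default_factory=dict)
    metadata_path: Optional[str] = None
    cluster_threshold: float = 0.99
    min_unique_size: int = 2
    qmin_centroid: int = 25
    qmin_mapping: int = 20
    cutoffs: CutoffScheme = dataclasses.field(default_factory=CutoffScheme.default)
    min_rho: float = 0.8
    link_shuffles: int = 10**6
    alpha_reps: int = 1000
    min_phylum_reads: int = 1000
    phylum_min_fraction: float = 0.01
    mantel_perms: int = 999
    gradient_perms: int = 9999
    outdir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sim is None and not self.markers:
            raise ValueError("config needs either a synthetic SimConfig or marker inputs")
        if self.sim is not None and self.sim.seed != self.seed:
            self.sim = dataclasses.replace(self.sim, seed=self.seed)


@dataclasses.dataclass(slots=True)
class MarkerResult:
    table: OtuTable
    unassigned: dict[str, int]
    assignments: dict[str, Assignment]
    dissimilarity: object  # skbio DistanceMatrix
    ordination: ca.Ordination
    gradient_rho: float
    gradient_p: float
    dendrogram_newick: str
    alpha: pd.DataFrame


@dataclasses.dataclass(slots=True)
class PipelineResult:
    config: PipelineConfig
    metadata: pd.DataFrame
    markers: dict[str, MarkerResult]
    mantel_rho: Optional[float]
    mantel_p: Optional[float]
    phylum_alpha: pd.DataFrame
    horohalinicum: pd.DataFrame
    linked_pairs: list
    class_matches: tuple[int, int]
    link_pvalue: Optional[float]
    run_log: dict


# ---------------------------------------------------------------------------
# Per-marker OTU construction
# ---------------------------------------------------------------------------


def _profiles(geometry: MarkerGeometry, config: PipelineConfig) -> tuple[PrepProfile, PrepProfile]:
    """(centroid-pass, mapping-pass) preparation profiles for a marker.

    Concatenated markers use the mapping threshold for both passes: a
    per-read quality truncation would move the junction between passes
    and misalign centroid and mapping sequences.
    """
    mode = geometry.mode
    q_centroid = config.qmin_centroid if mode == "merge" else config.qmin_mapping
    common = dict(
        fwd_primer=geometry.fwd_primer,
        rev_primer=geometry.rev_primer,
        tail_trim_rev=geometry.tail_trim_rev,
        mode=mode,
    )
    return (
        PrepProfile(qmin=q_centroid, **common),
        PrepProfile(qmin=config.qmin_mapping, **common),
    )


def _pair_key(pair: AmpliconPair) -> tuple:
    return (
        pair.fwd.seq,
        pair.fwd.quals.tobytes(),
        pair.rev.seq,
        pair.rev.quals.tobytes(),
    )


def build_otu_table(
    pairs_by_sample: dict[str, list[AmpliconPair]],
    geometry: MarkerGeometry,
    config: PipelineConfig,
) -> tuple[OtuTable, dict[str, int], dict[str, int]]:
    """Two-pass OTU construction for one marker.

    Returns (table, per-sample unassigned counts, per-sample rejected
    counts).  Identical raw pairs within a sample are prepared once and
    counted, which keeps deep samples cheap.
    """
    centroid_profile, mapping_profile = _profiles(geometry, config)
    derep_centroid = Dereplicator()
    derep_mapping = Dereplicator()
    rejected: dict[str, int] = {}
    sample_ids = list(pairs_by_sample)
    for sample_id, pairs in pairs_by_sample.items():
        unique_pairs: dict[tuple, tuple[AmpliconPair, int]] = {}
        for pair in pairs:
            key = _pair_key(pair)
            if key in unique_pairs:
                unique_pairs[key] = (unique_pairs[key][0], unique_pairs[key][1] + 1)
            else:
                unique_pairs[key] = (pair, 1)
        for pair, count in unique_pairs.values():
            out_c = prepare_pair(pair, centroid_profile)
            if isinstance(out_c, PreparedSequence):
                derep_centroid.add(out_c, count)
            out_m = prepare_pair(pair, mapping_profile)
            if isinstance(out_m, PreparedSequence):
                derep_mapping.add(out_m, count)
            else:
                rejected[sample_id] = rejected.get(sample_id, 0) + count
    uniques = derep_centroid.finalize()
    clusters = greedy_cluster(
        uniques, threshold=config.cluster_threshold, min_unique_size=config.min_unique_size
    )
    logger.info(
        "%s: %d uniques (centroid pass) -> %d OTU centroids",
        geometry.marker,
        len(uniques),
        len(clusters.centroids),
    )
    table, unassigned = map_uniques_to_centroids(
        derep_mapping.finalize(),
        clusters.centroids,
        sample_ids,
        config.cluster_threshold,
        geometry.marker,
    )
    return table, unassigned, rejected


def classify_centroids(
    table: OtuTable,
    refdb: ReferenceDB,
    cutoffs: CutoffScheme,
    min_aln_frac: float = 0.9,
) -> dict[str, Assignment]:
    """Classify every centroid; concatenated ones are split at the junction
    and assigned from the paired halves."""
    assignments: dict[str, Assignment] = {}
    for otu in table.otu_ids:
        seq = table.centroids[otu]
        junction = table.junctions.get(otu)
        if junction is None:
            hits = align_query_to_refs(
                seq, refdb, int(round(min_aln_frac * len(seq))), query_id=otu
            )
            assignments[otu] = assign_single(hits, refdb, cutoffs, otu_id=otu)
        else:
            fwd, rev = seq[:junction], seq[junction:]
            fwd_hits = align_query_to_refs(
                fwd, refdb, int(round(min_aln_frac * len(fwd))), query_id=otu
            )
            rev_hits = align_query_to_refs(
                rev, refdb, int(round(min_aln_frac * len(rev))), query_id=otu
            )
            assignments[otu] = assign_paired(fwd_hits, rev_hits, refdb, cutoffs, otu_id=otu)
    for otu, a in assignments.items():
        if a.depth:
            table.lineages[otu] = a.lineage
    return assignments


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, exc) from exc
            return False

    return _Ctx()


def _load_pairs_from_files(marker_input: MarkerInput) -> dict[str, list[AmpliconPair]]:
    out: dict[str, list[AmpliconPair]] = {}
    for sample_id, (fwd_path, rev_path) in marker_input.fastq_pairs.items():
        fwd = list(parse_fastq(fwd_path, "forward"))
        rev = list(parse_fastq(rev_path, "reverse"))
        if len(fwd) != len(rev):
            raise ValueError(
                f"sample {sample_id!r}: {len(fwd)} forward vs {len(rev)} reverse reads"
            )
        out[sample_id] = [AmpliconPair(f, r, sample_id) for f, r in zip(fwd, rev)]
    return out


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the whole analysis; deterministic given config and seed."""
    rng_root = np.random.SeedSequence((config.seed, 77))
    keys = {
        name: np.random.default_rng(s)
        for name, s in zip(
            ("alpha", "mantel", "gradient", "link", "phylum"), rng_root.spawn(5)
        )
    }

    dataset: Optional[SimulatedDataset] = None
    with _stage("inputs"):
        if config.sim is not None:
            dataset = simulate_dataset(config.sim, scramble=config.scramble_links)
            metadata = dataset.metadata.set_index("sample_id", drop=False)
            marker_names = list(dataset.refdbs)
        else:
            if config.metadata_path is None:
                raise ValueError("metadata_path required for file-backed runs")
            metadata = core_io.parse_sample_metadata(config.metadata_path)
            marker_names = list(config.markers)

    markers: dict[str, MarkerResult] = {}
    for marker in marker_names:
        with _stage(f"{marker}:reads"):
            if dataset is not None:
                geometry = dataset.geometry(marker)
                refdb = dataset.refdbs[marker]
                pairs_by_sample = {}
                for sample_id in metadata["sample_id"]:
                    pairs, _ = dataset.reads_for_sample(marker, sample_id)
                    pairs_by_sample[sample_id] = pairs
            else:
                marker_input = config.markers[marker]
                geometry = marker_input.geometry
                refdb = core_io.parse_reference_db(
                    marker_input.reference_fasta, marker_input.reference_taxonomy
                )
                pairs_by_sample = _load_pairs_from_files(marker_input)
        with _stage(f"{marker}:otu_table"):
            table, unassigned, _rejected = build_otu_table(pairs_by_sample, geometry, config)
            del pairs_by_sample
        with _stage(f"{marker}:taxonomy"):
            assignments = classify_centroids(table, refdb, config.cutoffs)
        with _stage(f"{marker}:beta_diversity"):
            freqs = ca.relative_abundance(table)
            dm = ca.spearman_dissimilarity(freqs)
            ordination = ca.pcoa(dm)
            rho, p = ca.correlate_axis_with_gradient(
                ordination, metadata, axis=1, n_perm=config.gradient_perms, rng=keys["gradient"]
            )
            _, newick = ca.hierarchical_cluster(dm)
        with _stage(f"{marker}:alpha_diversity"):
            estimates = ca.community_alpha(table, reps=config.alpha_reps, rng=keys["alpha"])
            alpha = ca.alpha_to_dataframe(estimates, phylum="")
        markers[marker] = MarkerResult(
            table, unassigned, assignments, dm, ordination, rho, p, newick, alpha
        )

    mantel_rho = mantel_p = None
    if len(markers) == 2:
        with _stage("mantel"):
            m16, m18 = (markers[m] for m in marker_names)
            mantel_rho, mantel_p = ca.mantel_test(
                m16.dissimilarity, m18.dissimilarity, config.mantel_perms, keys["mantel"]
            )

    phylum_alpha = pd.DataFrame()
    horo = pd.DataFrame()
    if "18S" in markers:
        with _stage("phylum_alpha"):
            table18 = markers["18S"].table
            freqs18 = ca.relative_abundance(table18)
            mean_rel = freqs18.mean(axis=1)
            phyla = sorted(
                {
                    table18.lineages[o].name_at(3)
                    for o in table18.otu_ids
                    if o in table18.lineages and table18.lineages[o].depth >= 3
                    if mean_rel[o] >= config.phylum_min_fraction
                }
            )
            frames = []
            for phylum in phyla:
                est = ca.per_phylum_alpha(
                    table18,
                    phylum,
                    min_reads=config.min_phylum_reads,
                    reps=config.alpha_reps,
                    rng=keys["phylum"],
                )
                if est:
                    frames.append(ca.alpha_to_dataframe(est, phylum=phylum))
            phylum_alpha = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
            horo = _horohalinicum_safe(phylum_alpha, metadata)

    linked_pairs: list = []
    class_matches = (0, 0)
    link_p: Optional[float] = None
    if len(markers) == 2:
        with _stage("cross_domain_linking"):
            m16, m18 = (markers[m] for m in marker_names)
            linked_pairs = link.correlate_tables(m16.table, m18.table, config.min_rho)
            class_matches = link.count_class_matches(linked_pairs)
            k, m = class_matches
            if m > 0 and k > 0:
                link_p = link.permutation_pvalue(
                    linked_pairs, k, config.link_shuffles, keys["link"]
                )

    run_log = _build_run_log(config, metadata, markers)
    result = PipelineResult(
        config,
        metadata,
        markers,
        mantel_rho,
        mantel_p,
        phylum_alpha,
        horo,
        linked_pairs,
        class_matches,
        link_p,
        run_log,
    )
    if config.outdir is not None:
        with _stage("write_outputs"):
            write_result_bundle(result, Path(config.outdir))
    return result


def _horohalinicum_safe(
    phylum_alpha: pd.DataFrame, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Run the horohalinicum contrast on phyla whose retained samples cover
    both salinity groups; others are skipped (too few samples to test)."""
    if phylum_alpha.empty:
        return pd.DataFrame()
    sal = metadata["salinity"]
    testable = []
    for phylum, sub in phylum_alpha.groupby("phylum"):
        in_band = sub["sample_id"].map(lambda s: 5.0 <= sal[s] <= 8.0)
        if in_band.any() and (~in_band).any():
            testable.append(phylum)
    sub = phylum_alpha[phylum_alpha["phylum"].isin(testable)]
    if sub.empty:
        return pd.DataFrame()
    return ca.horohalinicum_test(sub, metadata)


def _build_run_log(config, metadata, markers) -> dict:
    def _clean(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: _clean(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {str(k): _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        if isinstance(obj, (str, int, float, bool)) or obj is None:
            return obj
        return str(obj)

    return {
        "parameters": _clean(config),
        "samples": list(metadata["sample_id"]),
        "markers": {
            m: {
                "n_otus": r.table.n_otus,
                "assigned_reads": r.table.sample_totals(),
                "unassigned_reads": r.unassigned,
            }
            for m, r in markers.items()
        },
    }


def write_result_bundle(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for marker, mr in result.markers.items():
        core_io.write_otu_table(mr.table, outdir / f"otu_table_{marker}.tsv")
        core_io.export_centroids_fasta(mr.table, outdir / f"centroids_{marker}.fasta")
        write_assignments_tsv(mr.assignments, outdir / f"assignments_{marker}.tsv")
        mr.ordination.to_dataframe().to_csv(outdir / f"pcoa_{marker}.tsv", sep="\t")
        (outdir / f"dendrogram_{marker}.nwk").write_text(mr.dendrogram_newick + "\n")
        mr.alpha.to_csv(outdir / f"alpha_{marker}.tsv", sep="\t", index=False)
    core_io.write_sample_metadata(result.metadata, outdir / "metadata.tsv")
    if not result.phylum_alpha.empty:
        result.phylum_alpha.to_csv(outdir / "alpha_per_phylum_18S.tsv", sep="\t", index=False)
    if not result.horohalinicum.empty:
        result.horohalinicum.to_csv(outdir / "horohalinicum_tests.tsv", sep="\t", index=False)
    link.write_pairs_tsv(result.linked_pairs, outdir / "linked_pairs.tsv")
    summary = {
        "gradient": {
            m: {"rho_pc1_salinity": mr.gradient_rho, "p": mr.gradient_p}
            for m, mr in result.markers.items()
        },
        "mantel": {"rho": result.mantel_rho, "p": result.mantel_p},
        "link": {
            "class_matches": result.class_matches[0],
            "evaluable_pairs": result.class_matches[1],
            "n_pairs": len(result.linked_pairs),
            "p": result.link_pvalue,
        },
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    (outdir / "run_log.json").write_text(json.dumps(result.run_log, indent=2) + "\n")
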