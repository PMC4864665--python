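"""Gradient beta-diversity and subsampled alpha-diversity statistics.

Beta-diversity is 1 - Spearman rank correlation of OTU frequency vectors
between samples (range [0, 2]); the resulting dissimilarity matrix feeds
principal coordinates analysis (classical scaling), average-linkage
hierarchical clustering, a Spearman correlation of the first principal
coordinate with the salinity gradient (permutation p-value), and a Mantel
test between two matrices.

Alpha-diversity is computed by seeded subsampling without replacement to
a common depth (rarefaction): observed OTU richness and the
Shannon-Wiener index (natural log), averaged over repeated draws.  A
per-phylum variant restricts the table to one phylum, drops samples with
fewer than a minimum number of reads from it, and subsamples to the
minimum remaining total, so diversity is not confounded by the phylum's
relative abundance.  Samples inside a salinity band (the horohalinicum,
5-8 by default) are contrasted against the rest with two-sided exact
Wilcoxon rank-sum tests, Benjamini-Hochberg adjusted across phyla within
each metric.

Permutation p-values use the (count + 1) / (N + 1) convention so p is
never zero.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy import stats
from skbio import DistanceMatrix
from skbio.tree import TreeNode
from statsmodels.stats.multitest import multipletests

from otugrad.core_io import OtuTable


# ---------------------------------------------------------------------------
# Beta-diversity
# ---------------------------------------------------------------------------


def relative_abundance(table: OtuTable) -> pd.DataFrame:
    """OTU x sample frequency matrix; every column sums to 1."""
    df = table.to_dataframe().astype(float)
    totals = df.sum(axis=0)
    empty = totals[totals <= 0]
    if not empty.empty:
        raise ValueError(f"samples with zero total count: {list(empty.index)}")
    return df / totals


def spearman_dissimilarity(freqs: pd.DataFrame) -> DistanceMatrix:
    """d(i, j) = 1 - Spearman rho between the samples' OTU frequency vectors."""
    if freqs.shape[1] < 2 or freqs.shape[0] < 2:
        raise ValueError("need at least 2 samples and 2 OTUs")
    constant = freqs.columns[(freqs.nunique(axis=0) <= 1)]
    if len(constant):
        raise ValueError(f"constant frequency vector (rho undefined) in: {list(constant)}")
    rho = stats.spearmanr(freqs.values, axis=0).statistic
    if np.ndim(rho) == 0:  # spearmanr returns a scalar for exactly 2 samples
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # enforce exact symmetry against float noise
    return DistanceMatrix(d, ids=list(freqs.columns))


@dataclasses.dataclass(slots=True)
class Ordination:
    """PCoA result: coordinates, eigenvalues and variance explained."""

    sample_ids: list[str]
    coordinates: np.ndarray  # sample x axis
    eigenvalues: np.ndarray
    variance_explained: np.ndarray

    def axis(self, number: int = 1) -> pd.Series:
        """1-based principal coordinate as a Series indexed by sample."""
        return pd.Series(self.coordinates[:, number - 1], index=self.sample_ids)

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.sample_ids, columns=cols)


def pcoa(dm: DistanceMatrix) -> Ordination:
    """Classical scaling: double-center -D^2/2, eigendecompose, keep the
    positive eigenvalues.

    Axes are ordered by decreasing eigenvalue; each axis is flipped so its
    first nonzero coordinate is positive; variance explained is relative
    to the positive-eigenvalue total.
    """
    d = dm.data
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals[0]), 1.0) * 1e-12 if n else 0.0
    positive = eigvals > tol
    eigvals = eigvals[positive]
    coords = eigvecs[:, positive] * np.sqrt(eigvals)
    for k in range(coords.shape[1]):
        col = coords[:, k]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if len(nz) and col[nz[0]] < 0:
            coords[:, k] = -col
    total = eigvals.sum()
    explained = eigvals / total if total > 0 else np.zeros_like(eigvals)
    return Ordination(list(dm.ids), coords, eigvals, explained)


def correlate_axis_with_gradient(
    ordination: Ordination,
    metadata: pd.DataFrame,
    axis: int = 1,
    gradient: str = "salinity",
    n_perm: int = 9999,
    rng: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Spearman rho between an ordination axis and an environmental gradient,
    with a seeded two-sided permutation p-value."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    coords = ordination.axis(axis)
    missing = [s for s in coords.index if s not in metadata.index]
    if missing:
        raise KeyError(f"samples without metadata: {missing}")
    values = metadata.loc[coords.index, gradient].to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError(f"missing {gradient} values")
    rho_obs = stats.spearmanr(coords.to_numpy(), values).statistic
    count = 0
    x = coords.to_numpy()
    for _ in range(n_perm):
        rho_p = stats.spearmanr(x, rng.permutation(values)).statistic
        if abs(rho_p) >= abs(rho_obs):
            count += 1
    return float(rho_obs), (count + 1) / (n_perm + 1)


def hierarchical_cluster(
    dm: DistanceMatrix, linkage: str = "average"
) -> tuple[np.ndarray, str]:
    """Agglomerative clustering of the dissimilarity matrix.

    Returns the SciPy linkage matrix and a newick string with branch
    lengths derived from merge heights.
    """
    if dm.shape[0] < 2:
        raise ValueError("need at least 2 samples to cluster")
    z = sch.linkage(dm.condensed_form(), method=linkage)
    tree = TreeNode.from_linkage_matrix(z, list(dm.ids))
    return z, str(tree).strip()


def mantel_test(
    dm1: DistanceMatrix,
    dm2: DistanceMatrix,
    n_perm: int = 999,
    rng: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Spearman Mantel test between two distance matrices (same samples).

    The p-value is one-sided (rho_perm >= rho_obs) over seeded
    permutations of the sample labels of the second matrix, with the +1
    correction.
    """
    if list(dm1.ids) != list(dm2.ids):
        raise ValueError("distance matrices must share the same samples in the same order")
    x = dm1.condensed_form()
    d2 = dm2.data
    rho_obs = stats.spearmanr(x, dm2.condensed_form()).statistic
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        y = d2[np.ix_(perm, perm)][iu]
        if stats.spearmanr(x, y).statistic >= rho_obs:
            count += 1
    return float(rho_obs), (count + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Alpha-diversity
# ---------------------------------------------------------------------------


@dataclasses.dataclass(slots=True)
class AlphaEstimate:
    """Subsampled richness and Shannon index for one sample."""

    sample_id: str
    depth: int
    mean_richness: float
    sd_richness: float
    mean_shannon: float
    sd_shannon: float
    replicates: int


def _shannon(draws: np.ndarray, depth: int) -> np.ndarray:
    p = draws / depth
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log(p), 0.0)
    return terms.sum(axis=1)


def subsampled_alpha(
    table: OtuTable,
    sample_id: str,
    n: int,
    reps: int = 1000,
    rng: int | np.random.Generator = 0,
) -> AlphaEstimate:
    """Rarefied alpha-diversity: ``reps`` seeded draws of ``n`` reads
    without replacement; richness = distinct OTUs per draw, Shannon
    H = -sum p ln p over the draw."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if sample_id not in table.sample_ids:
        raise KeyError(f"unknown sample {sample_id!r}")
    counts = table.counts[:, table.sample_ids.index(sample_id)]
    total = int(counts.sum())
    if n > total:
        raise ValueError(f"subsample depth {n} exceeds sample total {total}")
    if n < 1:
        raise ValueError("subsample depth must be >= 1")
    draws = rng.multivariate_hypergeometric(counts, n, size=reps)
    richness = (draws > 0).sum(axis=1).astype(float)
    shannon = _shannon(draws, n)
    return AlphaEstimate(
        sample_id,
        n,
        float(richness.mean()),
        float(richness.std(ddof=1)) if reps > 1 else 0.0,
        float(shannon.mean()),
        float(shannon.std(ddof=1)) if reps > 1 else 0.0,
        reps,
    )


def community_alpha(
    table: OtuTable,
    reps: int = 1000,
    rng: int | np.random.Generator = 0,
    depth: Optional[int] = None,
) -> list[AlphaEstimate]:
    """Whole-community alpha for every sample, subsampled to the lowest
    per-sample total (or an explicit common depth)."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    totals = table.counts.sum(axis=0)
    n = int(totals.min()) if depth is None else depth
    return [subsampled_alpha(table, s, n, reps, rng) for s in table.sample_ids]


def per_phylum_alpha(
    table: OtuTable,
    phylum: str,
    phylum_level: int = 3,
    min_reads: int = 1000,
    reps: int = 1000,
    rng: int | np.random.Generator = 0,
) -> list[AlphaEstimate]:
    """Alpha-diversity within one phylum (PR2 division by default).

    The table is restricted to OTUs of the phylum, samples with fewer
    than ``min_reads`` reads from it are excluded, and the rest are
    subsampled to the minimum remaining total.  Returns an empty list
    (with a warning) when no sample is retained.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    keep = [
        o
        for o in table.otu_ids
        if o in table.lineages and table.lineages[o].name_at(phylum_level) == phylum
    ]
    if not keep:
        return []
    sub = table.subset_otus(keep)
    totals = sub.counts.sum(axis=0)
    retained = [s for s, t in zip(sub.sample_ids, totals) if t >= min_reads]
    if not retained:
        import logging

        logging.getLogger(__name__).warning(
            "no sample has >= %d reads of phylum %s", min_reads, phylum
        )
        return []
    idx = [sub.sample_ids.index(s) for s in retained]
    n = int(totals[idx].min())
    return [subsampled_alpha(sub, s, n, reps, rng) for s in retained]


def horohalinicum_test(
    alpha: pd.DataFrame,
    metadata: pd.DataFrame,
    salinity_range: tuple[float, float] = (5.0, 8.0),
) -> pd.DataFrame:
    """Contrast alpha-diversity inside a salinity band against the rest.

    ``alpha`` has columns (phylum, sample_id, mean_richness, mean_shannon)
    with one row per retained sample.  For each phylum and each metric a
    two-sided exact Wilcoxon rank-sum test compares the samples with
    salinity in ``salinity_range`` (inclusive) to the others; p-values are
    Benjamini-Hochberg adjusted across phyla within each metric.
    """
    lo, hi = salinity_range
    sal = metadata["salinity"]
    rows = []
    for phylum, sub in alpha.groupby("phylum"):
        in_band = sub["sample_id"].map(lambda s: lo <= sal[s] <= hi)
        for metric in ("mean_richness", "mean_shannon"):
            a = sub.loc[in_band, metric].to_numpy(dtype=float)
            b = sub.loc[~in_band, metric].to_numpy(dtype=float)
            if len(a) == 0 or len(b) == 0:
                raise ValueError(
                    f"phylum {phylum!r}: a group is empty for salinity range [{lo}, {hi}]"
                )
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            rows.append(
                {
                    "phylum": phylum,
                    "metric": metric.replace("mean_", ""),
                    "statistic": float(res.statistic),
                    "p": float(res.pvalue),
                    "n_in": len(a),
                    "n_out": len(b),
                }
            )
    df = pd.DataFrame(rows)
    df["q"] = np.nan
    for metric in df["metric"].unique():
        mask = df["metric"] == metric
        df.loc[mask, "q"] = multipletests(df.loc[mask, "p"], method="fdr_bh")[1]
    return df


def alpha_to_dataframe(estimates: Sequence[AlphaEstimate], phylum: str = "") -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "phylum": phylum,
                "sample_id": e.sample_id,
                "depth": e.depth,
                "mean_richness": e.mean_richness,
                "sd_richness": e.sd_richness,
                "mean_shannon": e.mean_shannon,
                "sd_shannon": e.sd_shannon,
                "replicates": e.replicates,
            }
            for e in estimates
        ]
    )


def plot_ordination(ordination: Ordination, metadata: pd.DataFrame, path) -> None:
    """PC1/PC2 scatter colored by salinity (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    sal = metadata.loc[ordination.sample_ids, "salinity"]
    sc = ax.scatter(
        ordination.coordinates[:, 0], ordination.coordinates[:, 1], c=sal, cmap="viridis"
    )
    fig.colorbar(sc, label="salinity")
    ax.set_xlabel(f"PC1 ({ordination.variance_explained[0] * 100:.0f}%)")
    if ordination.coordinates.shape[1] > 1:
        ax.set_ylabel(f"PC2 ({ordination.variance_explained[1] * 100:.0f}%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
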