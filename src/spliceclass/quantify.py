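"""Quantification: count matrices, cluster ratios, per-sample unproductive
read fractions, and QTL-ready phenotype preparation.

Phenotype preparation follows the splicing-QTL recipe: keep clusters
observed (total > 0) in at least 60% of samples, compute percent spliced
in (PSI = junction count / cluster total), impute missing PSI with the
junction's across-sample mean, Z-score each junction across samples,
then inverse-normal rank-transform each sample across junctions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .clustering import IntronCluster
from .junctions import Junction, SampleJunctionCounts

log = logging.getLogger(__name__)

DEFAULT_MIN_SAMPLE_FRACTION = 0.6


def _row_id(j: Junction, cluster_id: str) -> str:
    return f"{j.chrom}:{j.start}:{j.end}:{cluster_id}"


@dataclass
class ClusterCountMatrix:
    counts: pd.DataFrame  # junction rows x sample columns, int
    ratios: pd.DataFrame  # same shape; NaN where the cluster total is 0
    clusters: pd.Series  # row id -> cluster id
    junctions: dict[str, Junction]  # row id -> junction


def build_count_matrix(
    clusters: list[IntronCluster], samples: list[SampleJunctionCounts]
) -> ClusterCountMatrix:
    """Junction x sample counts over final clusters, with per-sample ratios.

    Every cluster junction appears for every sample (zero-filled); the
    ratio of a junction is its count divided by its cluster's total in
    that sample, undefined (NaN) when that total is 0.
    """
    row_ids, cluster_ids, jmap = [], [], {}
    for c in clusters:
        for j in c.junctions:
            rid = _row_id(j, c.cluster_id)
            row_ids.append(rid)
            cluster_ids.append(c.cluster_id)
            jmap[rid] = j
    sample_ids = [s.sample_id for s in samples]
    counts = pd.DataFrame(0, index=row_ids, columns=sample_ids, dtype=int)
    for s in samples:
        if not s.counts:
            log.warning("sample %s has no junctions; all-zero column", s.sample_id)
        for c in clusters:
            for j in c.junctions:
                v = s.counts.get(j)
                if v:
                    counts.loc[_row_id(j, c.cluster_id), s.sample_id] = v
    clusters_s = pd.Series(cluster_ids, index=row_ids, name="cluster")
    totals = counts.groupby(clusters_s).transform("sum")
    ratios = counts / totals.where(totals > 0)
    return ClusterCountMatrix(counts, ratios, clusters_s, jmap)


def unproductive_read_fraction(
    matrix: ClusterCountMatrix, classification: pd.DataFrame
) -> pd.Series:
    """Per-sample fraction of junction reads that are unproductive.

    UTR-category junctions are excluded from numerator and denominator;
    the denominator is productive + unproductive reads. NaN where the
    denominator is 0. The log of this fraction (as a percentage) is the
    usual differential-splicing confounder.
    """
    cat = {
        (r["chrom"], r["start"], r["end"]): r["category"]
        for _, r in classification.iterrows()
    }
    cats = pd.Series(
        [
            cat.get((j.chrom, j.start, j.end), "UTR")
            for j in (matrix.junctions[rid] for rid in matrix.counts.index)
        ],
        index=matrix.counts.index,
    )
    unprod = matrix.counts[cats == "unproductive"].sum()
    prod = matrix.counts[cats == "productive"].sum()
    denom = unprod + prod
    return (unprod / denom.where(denom > 0)).rename("unproductive_fraction")


def inverse_normal_transform(values: np.ndarray) -> np.ndarray:
    """Map values to standard-normal quantiles of (rank - 0.5)/n, average ranks for ties."""
    r = rankdata(values, method="average")
    return norm.ppf((r - 0.5) / len(values))


@dataclass
class PhenotypeMatrix:
    values: pd.DataFrame  # junction x sample, normalized
    psi: pd.DataFrame  # PSI after imputation
    retained_clusters: list[str]


def prepare_phenotypes(
    matrix: ClusterCountMatrix,
    min_sample_fraction: float = DEFAULT_MIN_SAMPLE_FRACTION,
    rank_normalize_axis: str = "sample",
) -> PhenotypeMatrix:
    """PSI -> per-junction Z-score -> per-sample inverse-normal ranks.

    ``rank_normalize_axis`` selects whether the final rank transform runs
    within each sample across junctions ('sample', default) or within
    each junction across samples ('junction').
    """
    if matrix.counts.shape[1] < 2:
        raise ValueError("prepare_phenotypes needs at least 2 samples")
    if rank_normalize_axis not in ("sample", "junction"):
        raise ValueError(f"unknown rank_normalize_axis {rank_normalize_axis!r}")
    totals = matrix.counts.groupby(matrix.clusters).transform("sum")
    observed = (totals > 0).groupby(matrix.clusters).any()  # cluster x sample
    frac_observed = observed.mean(axis=1)
    retained = sorted(frac_observed.index[frac_observed >= min_sample_fraction])
    keep = matrix.clusters.isin(retained)
    psi = matrix.ratios.loc[keep].copy()
    # impute missing PSI (cluster unobserved in a sample) with the junction mean
    row_means = psi.mean(axis=1)
    psi = psi.apply(lambda row: row.fillna(row_means[row.name]), axis=1)
    psi = psi.dropna(how="all")  # rows with no observation anywhere

    mean = psi.mean(axis=1)
    sd = psi.std(axis=1, ddof=1)
    zero_var = sd == 0
    if zero_var.any():
        log.warning("%d junctions with zero PSI variance; Z-scores set to 0", zero_var.sum())
    z = psi.sub(mean, axis=0).div(sd.where(~zero_var, np.inf), axis=0)

    if rank_normalize_axis == "sample":
        out = z.apply(lambda col: inverse_normal_transform(col.to_numpy()), axis=0)
    else:
        norm_rows = np.apply_along_axis(inverse_normal_transform, 1, z.to_numpy())
        out = pd.DataFrame(norm_rows, index=z.index, columns=z.columns)
    return PhenotypeMatrix(out, psi, retained)


def select_num_pcs(phenotypes: pd.DataFrame, seed: int = 0) -> int:
    """Number of phenotype PCs explaining more variance than the top PC of
    a permuted matrix.

    Each junction row is permuted independently across samples (breaking
    inter-junction correlation while keeping marginals), the permuted
    matrix's top PC variance is the null bar, and the count of true PCs
    above it is returned.
    """
    X = phenotypes.to_numpy(dtype=float)
    n_samples = X.shape[1]
    if n_samples < 3:
        log.warning("fewer than 3 samples; 0 covariate PCs selected")
        return 0
    rng = np.random.default_rng(seed)
    Xc = X - X.mean(axis=1, keepdims=True)
    true_var = np.linalg.svd(Xc, compute_uv=False) ** 2
    Xp = np.array([rng.permutation(row) for row in X])
    Xp -= Xp.mean(axis=1, keepdims=True)
    null_top = np.linalg.svd(Xp, compute_uv=False)[0] ** 2
    return int((true_var > null_top).sum())


def phenotype_pcs(phenotypes: pd.DataFrame, n_pcs: int) -> pd.DataFrame:
    """Top sample-space principal components (rows: PC1..PCn, columns: samples)."""
    X = phenotypes.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    return pd.DataFrame(
        vt[:n_pcs],
        index=[f"PC{i + 1}" for i in range(n_pcs)],
        columns=phenotypes.columns,
    )
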