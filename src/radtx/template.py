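"""Gradual-template gene selection (Pavlidis Template Matching).

The supervised selection step: an ANOVA screen and hierarchical clustering
identify the dominant expression pattern across treatment arms, whose
centroids motivate a 3-step gradual template ordering the arm categories
EndoRT-only < EBRT-only < combined. Every filtered transcript is then
correlated against that template (Pearson r over non-control samples) and
genes with r at or beyond +/- the cutoff form the UpCor / DownCor lists.
Significance of the correlation uses the standard t-transform
t = r * sqrt((n-2)/(1-r^2)) with n-2 degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .containers import FoldChangeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "TemplateProfile",
    "GeneSelection",
    "anova_pvalues",
    "anova_screen",
    "cluster_genes",
    "centroid_profiles",
    "gradual_template",
    "ptm",
    "select_correlated",
]

DEFAULT_LEVELS: dict[str, float] = {"endoRT": 1.0, "EBRT": 2.0, "combined": 3.0}


@dataclass
class TemplateProfile:
    """Per-sample template values encoding the gradual arm ordering.

    Control samples are excluded from the template domain: they are the
    normalization baseline, and the 3-step profile spans only the treated
    categories. Pearson correlation with the template is invariant to affine
    rescaling of the level values, so only their ordering matters.
    """

    values: pd.Series  # sample_id -> level value, non-control samples only
    levels: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.values.nunique() < 2:
            raise ValueError("template needs at least two distinct values")

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index


@dataclass
class GeneSelection:
    """UpCor / DownCor gene lists at a correlation cutoff."""

    up_cor: list[str]
    down_cor: list[str]
    cutoff: float
    universe_size: int

    def __post_init__(self) -> None:
        if set(self.up_cor) & set(self.down_cor):
            raise ValueError("a gene cannot be both up- and down-correlated")


def anova_pvalues(fc: FoldChangeMatrix) -> pd.Series:
    """One-way ANOVA p-value per gene across treatment arms.

    Missing entries are dropped per group; groups left with no observation
    are dropped for that gene. Genes where F is undefined (fewer than two
    populated groups, or zero variance everywhere) get NaN.
    """
    arm_cols = {arm: fc.samples_in_arm(arm) for arm in fc.arm_order()}
    if sum(len(c) >= 2 for c in arm_cols.values()) < 2:
        raise ValueError("ANOVA needs at least two arms with two or more samples")
    X = fc.values.to_numpy(dtype=float)
    col_idx = {s: i for i, s in enumerate(fc.sample_ids)}
    groups_idx = [np.array([col_idx[s] for s in cols]) for cols in arm_cols.values()]

    pvals = np.full(X.shape[0], np.nan)
    for i in range(X.shape[0]):
        samples = [X[i, idx] for idx in groups_idx]
        samples = [s[np.isfinite(s)] for s in samples]
        samples = [s for s in samples if s.size > 0]
        if len(samples) < 2 or sum(s.size for s in samples) <= len(samples):
            continue
        flat = np.concatenate(samples)
        if np.ptp(flat) == 0:  # no variance at all: F undefined
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            _, p = stats.f_oneway(*samples)
        pvals[i] = p
    return pd.Series(pvals, index=fc.gene_ids, name="anova_p")


def anova_screen(
    fc: FoldChangeMatrix, alpha: float = 0.01, top_n: int = 500
) -> list[str]:
    """Genes with ANOVA p < ``alpha``, ranked ascending by p, truncated to ``top_n``."""
    pvals = anova_pvalues(fc)
    undefined = pvals.isna()
    if undefined.any():
        logger.info("%d genes with undefined ANOVA F excluded", int(undefined.sum()))
    hits = pvals[pvals < alpha].sort_values(kind="mergesort")
    return list(hits.index[:top_n])


def cluster_genes(
    fc: FoldChangeMatrix, genes: Sequence[str], n_clusters: int = 4
) -> tuple[pd.Series, np.ndarray]:
    """Agglomerative clustering of per-gene arm-mean profiles.

    Euclidean metric, average linkage. Genes whose arm-mean profile contains
    an undefined entry (an arm with every value missing) are excluded with a
    log message. Returns flat cluster assignments (1..n_clusters) and the
    linkage matrix (the dendrogram). Deterministic for a given input order;
    equal-distance merges follow the linkage algorithm's fixed ordering.
    """
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("clustering needs at least two genes")
    profiles = fc.arm_means(genes)
    complete = profiles.notna().all(axis=1)
    if (~complete).any():
        logger.warning(
            "%d genes with undefined arm means excluded from clustering",
            int((~complete).sum()),
        )
    profiles = profiles.loc[complete]
    link = hierarchy.linkage(profiles.to_numpy(), method="average", metric="euclidean")
    flat = hierarchy.fcluster(link, t=n_clusters, criterion="maxclust")
    return pd.Series(flat, index=profiles.index, name="cluster"), link


def centroid_profiles(
    fc: FoldChangeMatrix, clusters: pd.Series
) -> tuple[pd.DataFrame, pd.Series]:
    """Arithmetic mean arm profile of each cluster, with cluster sizes."""
    if clusters.empty:
        raise ValueError("no clusters given")
    profiles = fc.arm_means(clusters.index)
    sizes = clusters.value_counts().sort_index()
    if (sizes == 0).any():
        raise ValueError("empty cluster")
    centroids = profiles.groupby(clusters).mean()
    centroids.index.name = "cluster"
    return centroids, sizes.rename("size")


def gradual_template(
    arms: pd.Series,
    categories: Mapping[str, str],
    levels: Mapping[str, float] | None = None,
) -> TemplateProfile:
    """The 3-step gradual template over non-control samples.

    Each sample receives the numeric level of its arm's category
    (default endoRT=1, EBRT=2, combined=3; both photon- and carbon-EBRT
    arms map to the single EBRT level). Raises if a non-control category
    has no samples.
    """
    levels = dict(levels or DEFAULT_LEVELS)
    sample_cats = arms.map(categories)
    if sample_cats.isna().any():
        missing = sorted(arms[sample_cats.isna()].unique())
        raise ValueError(f"arms without category: {missing}")
    treated = sample_cats[sample_cats != "control"]
    present = set(treated)
    absent = set(levels) - present
    if absent:
        raise ValueError(f"categories missing from annotation: {sorted(absent)}")
    values = treated.map(levels).astype(float)
    values.name = "template"
    return TemplateProfile(values=values, levels=levels)


def ptm(
    fc: FoldChangeMatrix,
    template: TemplateProfile,
    min_obs: int = 3,
    arm_means: bool = False,
) -> pd.DataFrame:
    """Pavlidis Template Matching: correlate every gene with the template.

    Pearson r between each gene's per-sample values and the template over
    the template's (non-control) samples, with pairwise deletion of missing
    entries. Two-sided p from t = r*sqrt((n_obs-2)/(1-r^2)) on n_obs-2
    degrees of freedom. Genes with fewer than ``min_obs`` paired
    observations, or constant over the template samples, are excluded with
    a log message.

    With ``arm_means=True`` the correlation is computed between per-arm mean
    profiles and per-arm template levels instead of sample-level values.

    Returns a frame indexed by gene with columns (r, n_obs, p).
    """
    if arm_means:
        t_by_arm = template.values.groupby(fc.arms.loc[template.sample_ids]).mean()
        X = fc.arm_means()[t_by_arm.index].to_numpy(dtype=float)
        t = t_by_arm.to_numpy(dtype=float)
    else:
        X = fc.values[template.sample_ids].to_numpy(dtype=float)
        t = template.values.to_numpy(dtype=float)

    mask = np.isfinite(X)
    n = mask.sum(axis=1)
    Xz = np.where(mask, X, 0.0)
    T = np.where(mask, t, 0.0)
    sx = Xz.sum(axis=1)
    st = T.sum(axis=1)
    sxx = (Xz**2).sum(axis=1)
    stt = (T**2).sum(axis=1)
    sxt = (Xz * T).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxt - sx * st
        var_x = n * sxx - sx**2
        var_t = n * stt - st**2
        r = cov / np.sqrt(var_x * var_t)

    valid = (n >= min_obs) & (var_x > 0) & (var_t > 0) & np.isfinite(r)
    excluded = int((~valid).sum())
    if excluded:
        logger.info(
            "%d genes excluded from template matching (too few observations "
            "or constant profile)",
            excluded,
        )
    r = np.clip(r[valid], -1.0, 1.0)
    n_obs = n[valid]
    with np.errstate(divide="ignore", over="ignore"):
        denom = np.maximum(1.0 - r**2, np.finfo(float).tiny)
        t_stat = r * np.sqrt((n_obs - 2) / denom)
    p = 2.0 * stats.t.sf(np.abs(t_stat), df=n_obs - 2)
    p = np.minimum(np.maximum(p, np.finfo(float).tiny), 1.0)
    return pd.DataFrame(
        {"r": r, "n_obs": n_obs, "p": p}, index=fc.gene_ids[valid]
    ).rename_axis("gene_id")


def select_correlated(results: pd.DataFrame, r_min: float = 0.7) -> GeneSelection:
    """Split template-matching results into UpCor (r >= r_min) and DownCor (r <= -r_min)."""
    if not 0 < r_min < 1:
        raise ValueError("r_min must lie strictly between 0 and 1")
    up = list(results.index[results["r"] >= r_min])
    down = list(results.index[results["r"] <= -r_min])
    return GeneSelection(up_cor=up, down_cor=down, cutoff=r_min, universe_size=len(results))
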