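"""Hypergeometric gene-set enrichment and the gene x pathway population map.

Given a selection of genes (e.g. the UpCor list) and a collection of named
gene sets over a universe of tested transcripts, each set is scored with the
upper-tail hypergeometric probability P[X >= k] of observing at least the
actual overlap k by chance when drawing the selection uniformly from the
universe. Raw p < alpha declares significance (Benjamini-Hochberg adjusted
values are emitted alongside as a non-default extra column).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["GeneSetCollection", "hypergeometric_enrichment", "population_map"]


@dataclass
class GeneSetCollection:
    """Named gene sets plus the universe they are tested against."""

    sets: Mapping[str, Sequence[str]]
    universe: tuple[str, ...]

    def __post_init__(self) -> None:
        self.universe = tuple(self.universe)
        if len(set(self.universe)) != len(self.universe):
            raise ValueError("universe contains duplicate genes")
        self.sets = {sid: tuple(dict.fromkeys(members)) for sid, members in self.sets.items()}

    def restricted(self) -> dict[str, tuple[str, ...]]:
        """Sets intersected with the universe (order preserved)."""
        uni = set(self.universe)
        return {sid: tuple(g for g in members if g in uni) for sid, members in self.sets.items()}

    @property
    def set_ids(self) -> list[str]:
        return list(self.sets)


def hypergeometric_enrichment(
    selection: Sequence[str],
    collection: GeneSetCollection,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``selection`` in every set.

    Returns a frame with one row per set, columns
    (set_id, k, K, n, N, p, p_adj, significant), sorted ascending by p
    (ties broken by set_id for determinism). k is the overlap of the
    selection with the set, K the set size within the universe, n the
    selection size within the universe and N the universe size;
    p = P[X >= k] for X hypergeometric(N, K, n). ``significant`` flags raw
    p < alpha; ``p_adj`` is Benjamini-Hochberg across the collection.
    """
    if not collection.universe:
        raise ValueError("empty universe")
    uni = set(collection.universe)
    sel = [g for g in dict.fromkeys(selection) if g in uni]
    dropped = len(set(selection)) - len(sel)
    if dropped:
        logger.warning("%d selection genes outside the universe were dropped", dropped)
    if not sel:
        raise ValueError("selection is empty after restriction to the universe")

    N = len(uni)
    n = len(sel)
    sel_set = set(sel)
    rows = []
    for sid, members in collection.restricted().items():
        K = len(members)
        k = len(sel_set.intersection(members))
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((sid, k, K, n, N, min(p, 1.0)))
    frame = pd.DataFrame(rows, columns=["set_id", "k", "K", "n", "N", "p"])
    frame["p_adj"] = multipletests(frame["p"], method="fdr_bh")[1]
    frame["significant"] = frame["p"] < alpha
    return frame.sort_values(["p", "set_id"], kind="mergesort").reset_index(drop=True)


def population_map(
    selection: Sequence[str],
    enrichment: pd.DataFrame,
    collection: GeneSetCollection,
) -> pd.DataFrame:
    """Binary gene x set membership matrix over significant sets.

    Rows are selection genes belonging to at least one significant set,
    columns the significant sets; rows and columns are ordered by
    average-linkage Euclidean clustering of the membership vectors so that
    genes shared across pathways appear as blocks. Returns an empty frame
    when no set is significant.
    """
    sig = enrichment.loc[enrichment["significant"], "set_id"].tolist()
    if not sig:
        logger.info("no significant sets; population map is empty")
        return pd.DataFrame(index=pd.Index([], name="gene_id"))
    restricted = collection.restricted()
    sel = list(dict.fromkeys(selection))
    mat = pd.DataFrame(
        {sid: [1 if g in set(restricted[sid]) else 0 for g in sel] for sid in sig},
        index=pd.Index(sel, name="gene_id"),
        dtype=int,
    )
    mat = mat.loc[mat.sum(axis=1) > 0]
    if mat.empty:
        return mat

    def _order(frame: pd.DataFrame) -> list:
        if frame.shape[0] < 3:
            return list(frame.index)
        link = hierarchy.linkage(frame.to_numpy(dtype=float), method="average", metric="euclidean")
        return [frame.index[i] for i in hierarchy.leaves_list(link)]

    rows = _order(mat)
    cols = _order(mat.T) if mat.shape[1] >= 2 else list(mat.columns)
    return mat.loc[rows, cols]
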