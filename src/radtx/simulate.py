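"""Synthetic study generator with known ground truth.

Emulates the structure of a two-model preclinical radiotherapy study: a
gene x sample intensity matrix over six treatment arms (control, EndoRT,
photon-EBRT, carbon-EBRT, and the two combined arms PERT/CERT), a planted
fraction of genes following the 3-step gradual profile
EndoRT < EBRT < combined (and its mirror image), a gene-set collection with
one truly enriched set, a protein-protein interaction graph with a planted
connected module among the upregulated genes, and tidy caliper / organ
radioactivity tables for the efficacy endpoints.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .enrichment import GeneSetCollection

__all__ = [
    "StudyDesign",
    "SimulationConfig",
    "TruthLabels",
    "GrowthParams",
    "BiodistParams",
    "default_design",
    "generate_expression_study",
    "generate_ppi",
    "generate_gene_sets",
    "generate_efficacy_tables",
]

ARM_CATEGORIES = ("control", "endoRT", "EBRT", "combined")

#: numeric level of each arm category in the gradual profile; control sits
#: at the baseline and is excluded from the template domain downstream.
CATEGORY_LEVEL = {"control": 0, "endoRT": 1, "EBRT": 2, "combined": 3}


@dataclass(frozen=True)
class StudyDesign:
    """Treatment arms, replicate counts and the arm -> category map."""

    arms: tuple[str, ...]
    replicates: Mapping[str, int]
    categories: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.arms:
            raise ValueError("design needs at least one arm")
        for arm in self.arms:
            if self.replicates.get(arm, 0) < 1:
                raise ValueError(f"arm {arm!r} needs at least one replicate")
            cat = self.categories.get(arm)
            if cat not in ARM_CATEGORIES:
                raise ValueError(f"arm {arm!r} has unknown category {cat!r}")
        cats = [self.categories[a] for a in self.arms]
        if cats.count("control") != 1:
            raise ValueError("exactly one arm must have category 'control'")
        for needed in ("endoRT", "EBRT", "combined"):
            if needed not in cats:
                raise ValueError(f"design lacks an arm of category {needed!r}")

    @property
    def control_arm(self) -> str:
        return next(a for a in self.arms if self.categories[a] == "control")

    def sample_ids(self) -> list[str]:
        return [f"{arm}_{i + 1}" for arm in self.arms for i in range(self.replicates[arm])]

    def sample_arms(self) -> pd.Series:
        return pd.Series(
            {sid: sid.rsplit("_", 1)[0] for sid in self.sample_ids()}, name="arm"
        )

    @property
    def n_samples(self) -> int:
        return sum(self.replicates[a] for a in self.arms)


def default_design(replicates: int = 3) -> StudyDesign:
    """A431-like design: six arms with equal replication (3 arrays per arm).

    Photon- and carbon-EBRT share the EBRT category (one template level), as
    do the two combined arms; this pools the two radiation qualities into the
    single ``EBRT only`` step of the gradual profile.
    """
    arms = ("control", "EndoRT", "photon_EBRT", "carbon_EBRT", "PERT", "CERT")
    cats = {
        "control": "control",
        "EndoRT": "endoRT",
        "photon_EBRT": "EBRT",
        "carbon_EBRT": "EBRT",
        "PERT": "combined",
        "CERT": "combined",
    }
    return StudyDesign(arms, {a: replicates for a in arms}, cats)


@dataclass(frozen=True)
class SimulationConfig:
    """Expression-matrix generation parameters.

    Intensities are drawn on the natural-log scale and exponentiated, so
    values are positive by construction. ``effect_step`` is the
    multiplicative step between consecutive template levels: an up-gradual
    gene has expected arm means baseline * step^1/2/3 for
    endoRT/EBRT/combined (ratio 1:2:4 at the default step of 2), a
    down-gradual gene the reciprocal profile, and control stays at baseline.
    Defaults are desk-scale (2,000 genes instead of the ~48,000 probes of a
    whole-genome chip) with multiplicative noise of 0.25 on the log scale
    and 2% missingness completely at random.
    """

    n_genes: int = 2000
    frac_up_gradual: float = 0.05
    frac_down_gradual: float = 0.05
    effect_step: float = 2.0
    baseline_log_mean: float = 7.0
    baseline_log_sd: float = 0.8
    noise_log_sd: float = 0.25
    missing_rate: float = 0.02
    low_intensity_frac: float = 0.10
    low_intensity_log_mean: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.effect_step <= 1:
            raise ValueError("effect_step must exceed 1")
        for name in ("frac_up_gradual", "frac_down_gradual", "missing_rate", "low_intensity_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.frac_up_gradual + self.frac_down_gradual + self.low_intensity_frac > 1:
            raise ValueError("gradual and low-intensity fractions must sum to <= 1")
        if self.noise_log_sd < 0 or self.baseline_log_sd < 0:
            raise ValueError("log-scale standard deviations must be non-negative")


@dataclass
class TruthLabels:
    """Ground-truth per-gene labels plus planted enrichment/network truth."""

    labels: pd.Series  # gene -> up_gradual | down_gradual | null | low_intensity
    planted_set_id: str | None = None
    planted_module: list[str] = field(default_factory=list)

    def genes(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])

    @property
    def up_gradual(self) -> list[str]:
        return self.genes("up_gradual")

    @property
    def down_gradual(self) -> list[str]:
        return self.genes("down_gradual")

    @property
    def null(self) -> list[str]:
        return self.genes("null")


def generate_expression_study(
    design: StudyDesign, config: SimulationConfig
) -> tuple[ExpressionMatrix, TruthLabels]:
    """Draw an intensity matrix with planted gradual genes.

    Returns the matrix (NaN at non-assessable entries) and the truth labels.
    Reproducible bit-for-bit given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = pd.Index([f"g{i:05d}" for i in range(n)], name="gene_id")

    n_up = round(config.frac_up_gradual * n)
    n_down = round(config.frac_down_gradual * n)
    n_low = round(config.low_intensity_frac * n)

    order = rng.permutation(n)
    labels = pd.Series("null", index=genes, name="label")
    labels.iloc[order[:n_up]] = "up_gradual"
    labels.iloc[order[n_up : n_up + n_down]] = "down_gradual"
    labels.iloc[order[n_up + n_down : n_up + n_down + n_low]] = "low_intensity"

    log_baseline = rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=n)
    log_baseline[(labels == "low_intensity").to_numpy()] = rng.normal(
        config.low_intensity_log_mean, config.baseline_log_sd, size=n_low
    )

    sample_arms = design.sample_arms()
    sample_level = np.array(
        [CATEGORY_LEVEL[design.categories[a]] for a in sample_arms], dtype=float
    )
    direction = np.zeros(n)
    direction[(labels == "up_gradual").to_numpy()] = 1.0
    direction[(labels == "down_gradual").to_numpy()] = -1.0

    log_step = np.log(config.effect_step)
    # expected log-intensity: baseline + direction * level * log(step)
    log_mu = log_baseline[:, None] + np.outer(direction, sample_level) * log_step
    noise = rng.normal(0.0, config.noise_log_sd, size=log_mu.shape) if config.noise_log_sd > 0 else 0.0
    values = np.exp(log_mu + noise)

    if config.missing_rate > 0:
        mask = rng.random(values.shape) < config.missing_rate
        values = np.where(mask, np.nan, values)

    frame = pd.DataFrame(values, index=genes, columns=sample_arms.index)
    return ExpressionMatrix(frame, sample_arms), TruthLabels(labels)


def generate_ppi(
    genes: Sequence[str],
    labels: TruthLabels,
    extra_edge_prob: float = 0.001,
    module_size: int = 20,
    seed: int = 0,
) -> nx.Graph:
    """Random interaction graph with a planted connected module.

    The module is a path through ``module_size`` up-gradual genes (connected
    with the minimal ``module_size - 1`` edges); background edges are added
    independently with probability ``extra_edge_prob`` between every other
    gene pair. All genes appear as nodes, including isolated ones.
    ``labels.planted_module`` is set on return.
    """
    up = labels.up_gradual
    if module_size > len(up):
        raise ValueError(
            f"module_size {module_size} exceeds the {len(up)} up-gradual genes"
        )
    if not 0 <= extra_edge_prob <= 1:
        raise ValueError("extra_edge_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = list(genes)
    module = [up[i] for i in rng.choice(len(up), size=module_size, replace=False)]

    graph = nx.Graph()
    graph.add_nodes_from(genes)
    graph.add_edges_from(zip(module[:-1], module[1:]))

    if extra_edge_prob > 0:
        background = nx.fast_gnp_random_graph(
            len(genes), extra_edge_prob, seed=int(rng.integers(2**31))
        )
        relabel = dict(enumerate(genes))
        graph.add_edges_from(
            (relabel[u], relabel[v]) for u, v in background.edges if relabel[u] != relabel[v]
        )

    labels.planted_module = module
    return graph


def generate_gene_sets(
    genes: Sequence[str],
    labels: TruthLabels,
    n_sets: int = 20,
    set_size_range: tuple[int, int] = (10, 50),
    planted_up_fraction: float = 1.0,
    seed: int = 0,
) -> GeneSetCollection:
    """Named gene sets over the gene universe, one planted in up-gradual genes.

    The planted set draws a fraction ``planted_up_fraction`` of its members
    from the up-gradual genes (the rest uniformly from the remainder); all
    other sets are uniform draws from the universe. ``labels.planted_set_id``
    is set on return.
    """
    genes = list(genes)
    lo, hi = set_size_range
    if not 1 <= lo <= hi:
        raise ValueError("set_size_range must satisfy 1 <= lo <= hi")
    if hi > len(genes):
        raise ValueError("set_size_range exceeds the gene universe")
    if not 0 <= planted_up_fraction <= 1:
        raise ValueError("planted_up_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    up = labels.up_gradual
    others = [g for g in genes if g not in set(up)]

    sets: dict[str, list[str]] = {}
    planted_id = "set_planted"
    size = int(rng.integers(lo, hi + 1))
    n_from_up = min(round(planted_up_fraction * size), len(up))
    members = [up[i] for i in rng.choice(len(up), size=n_from_up, replace=False)]
    if size - n_from_up > 0:
        members += [others[i] for i in rng.choice(len(others), size=size - n_from_up, replace=False)]
    sets[planted_id] = sorted(members)

    for j in range(n_sets - 1):
        size = int(rng.integers(lo, hi + 1))
        draw = rng.choice(len(genes), size=size, replace=False)
        sets[f"set_{j + 1:03d}"] = sorted(genes[i] for i in draw)

    labels.planted_set_id = planted_id
    return GeneSetCollection(sets=sets, universe=tuple(genes))


@dataclass(frozen=True)
class GrowthParams:
    """Exponential tumor growth with an arm-specific post-treatment rate.

    Volumes follow V(t) = V0 * 2^(min(t, t0)/d_pre) * 2^(max(t - t0, 0)/d_arm)
    where ``t0`` is the treatment day, ``d_pre`` the pre-treatment doubling
    time shared by all arms and ``d_arm`` the arm-specific doubling time.
    With ``treatment_day=0`` (default) the arm rate applies throughout, so a
    control animal follows the closed form V0 * 2^(t/d) exactly at zero noise.
    Caliper width and length are reported as the cube side of an equivalent
    (width^2 x length)/2 volume. Defaults mimic a fast-growing xenograft
    treated once: untreated tumors double every ~2.5 days, EBRT slows growth
    substantially and the combined arms nearly arrest it.
    """

    v0_mm3: float = 86.0
    doubling_days: Mapping[str, float] = field(
        default_factory=lambda: {
            "control": 2.5,
            "EndoRT": 3.0,
            "photon_EBRT": 6.0,
            "carbon_EBRT": 6.0,
            "PERT": 14.0,
            "CERT": 14.0,
        }
    )
    pre_treatment_doubling_days: float = 2.5
    treatment_day: float = 0.0
    days: tuple[float, ...] = tuple(range(0, 40, 2))
    n_animals: int = 8
    noise_log_sd: float = 0.10

    def expected_volume(self, arm: str, day: float) -> float:
        d_pre = self.pre_treatment_doubling_days
        d_arm = self.doubling_days[arm]
        t0 = self.treatment_day
        return (
            self.v0_mm3
            * 2.0 ** (min(day, t0) / d_pre)
            * 2.0 ** (max(day - t0, 0.0) / d_arm)
        )


@dataclass(frozen=True)
class BiodistParams:
    """Organ %ID/g means for the biodistribution table.

    Defaults emulate a melanin-targeting small-molecule tracer 24 h after
    injection: high tumor uptake (9.0 %ID/g), very low muscle uptake (a
    tumor-to-muscle ratio of 107.6), and modest uptake elsewhere. Noise is
    log-normal with the mean preserved, so arithmetic organ means match the
    configured values in expectation. The dispersion (~0.45 on the log
    scale, i.e. a coefficient of variation near 0.47) matches the reported
    spread of tumor uptake relative to its mean.
    """

    organ_means: Mapping[str, float] = field(
        default_factory=lambda: {
            "tumor": 9.0,
            "muscle": 9.0 / 107.6,
            "spleen": 2.4,
            "liver": 0.6,
            "kidney": 0.5,
            "lung": 0.5,
        }
    )
    n_animals: int = 11
    noise_log_sd: float = 0.45


def generate_efficacy_tables(
    design: StudyDesign,
    growth_params: GrowthParams | None = None,
    biodist_params: BiodistParams | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy caliper and organ-activity tables for the efficacy endpoints.

    Returns ``(growth, biodist)``: growth has one row per animal x day with
    columns (animal_id, arm, day, width_mm, length_mm); biodist one row per
    animal x organ with columns (animal_id, organ, pct_id_per_g).
    """
    gp = growth_params or GrowthParams()
    bp = biodist_params or BiodistParams()
    for arm in design.arms:
        if arm not in gp.doubling_days:
            raise ValueError(f"no doubling time configured for arm {arm!r}")
    rng = np.random.default_rng(seed)

    rows = []
    for arm in design.arms:
        for i in range(gp.n_animals):
            animal = f"{arm}_a{i + 1}"
            for day in gp.days:
                vol = gp.expected_volume(arm, day)
                if gp.noise_log_sd > 0:
                    vol *= np.exp(rng.normal(0.0, gp.noise_log_sd))
                side = (2.0 * vol) ** (1.0 / 3.0)  # width = length => V = s^3/2
                rows.append((animal, arm, float(day), side, side))
    growth = pd.DataFrame(rows, columns=["animal_id", "arm", "day", "width_mm", "length_mm"])

    rows = []
    for i in range(bp.n_animals):
        animal = f"bd_a{i + 1}"
        for organ, mean in bp.organ_means.items():
            value = mean
            if bp.noise_log_sd > 0:
                # mean-preserving log-normal: E[m * exp(N(-s^2/2, s))] = m
                value = mean * np.exp(
                    rng.normal(-0.5 * bp.noise_log_sd**2, bp.noise_log_sd)
                )
            rows.append((animal, organ, value))
    biodist = pd.DataFrame(rows, columns=["animal_id", "organ", "pct_id_per_g"])
    return growth, biodist


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of ``config`` with a different seed."""
    return replace(config, seed=seed)
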