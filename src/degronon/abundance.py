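"""Protein abundance analysis for degradation-regulatory modules.

Abundances are PaxDb-style parts-per-million (ppm) values: within one
dataset every protein's abundance is expressed relative to the whole
expressed proteome, so dataset totals sum to ~10^6.  For cross-dataset
comparisons each dataset is converted to 100 equally populated rank bins
(bin 1 = top 1% most abundant).

A degradation-regulatory module groups, for one substrate, the E3 ligase(s)
that target its degron and the alternate partners (APs) whose binding sites
overlap the degron and hence compete with the E3.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .stats import spearman, two_group_test

logger = logging.getLogger(__name__)

PPM_TOTAL = 1_000_000.0


class DatasetCategory(str, Enum):
    INTEGRATED = "integrated"
    WHOLE_ORGANISM = "whole_organism"
    TISSUE = "tissue"
    CELL_LINE = "cell_line"


class Role(str, Enum):
    SUBSTRATE = "substrate"
    E3 = "e3"
    AP = "ap"


@dataclass
class AbundanceDataset:
    """One proteome abundance snapshot: protein -> ppm."""

    dataset_id: str
    abundances: dict[str, float]
    category: DatasetCategory = DatasetCategory.INTEGRATED

    def __post_init__(self) -> None:
        total = sum(self.abundances.values())
        if self.abundances and not (0.9 * PPM_TOTAL <= total <= 1.1 * PPM_TOTAL):
            logger.warning(
                "dataset %s ppm total %.4g outside [0.9, 1.1] million",
                self.dataset_id,
                total,
            )


@dataclass
class RegulatoryModule:
    substrate: str
    e3s: set[str]
    aps: set[str]

    def __post_init__(self) -> None:
        if {self.substrate} & self.e3s or {self.substrate} & self.aps or self.e3s & self.aps:
            raise ValueError(
                f"module for {self.substrate}: substrate/e3/ap sets must be disjoint"
            )


def rank_bins(ds: AbundanceDataset, n_bins: int = 100) -> dict[str, int]:
    """Convert one dataset's ppm values to equally populated rank bins.

    Proteins are sorted from highest to lowest ppm (ties broken by protein
    id, lexicographic) and assigned ``bin = floor(n_bins * (rank-1) / N) + 1``
    with rank 1 for the most abundant protein.  Bin occupancies differ by at
    most one and the most abundant protein always lands in bin 1, for any
    dataset size (including N < n_bins).
    """
    if not ds.abundances:
        raise ValueError(f"dataset {ds.dataset_id} is empty")
    order = sorted(ds.abundances.items(), key=lambda kv: (-kv[1], kv[0]))
    n = len(order)
    return {
        protein: n_bins * rank // n + 1
        for rank, (protein, _) in enumerate(order)
    }


@dataclass
class RoleComparison:
    values: dict[Role, np.ndarray]
    medians: dict[Role, float]
    n: dict[Role, int]
    pvalues: dict[tuple[Role, Role], float] = field(default_factory=dict)


def role_abundance_comparison(
    datasets: Sequence[AbundanceDataset],
    modules: Sequence[RegulatoryModule],
    once_per_module: bool = True,
) -> RoleComparison:
    """Pool ppm values per role across datasets and compare the roles.

    Each (protein, dataset) occurrence contributes one observation to its
    role's pooled vector; with ``once_per_module`` a protein appearing in
    several modules contributes once per module occurrence, else once per
    dataset.  Pairwise role comparisons use the two-sided Mann-Whitney U.
    """
    role_members: dict[Role, list[str]] = {Role.SUBSTRATE: [], Role.E3: [], Role.AP: []}
    for m in modules:
        role_members[Role.SUBSTRATE].append(m.substrate)
        role_members[Role.E3].extend(sorted(m.e3s))
        role_members[Role.AP].extend(sorted(m.aps))
    if not once_per_module:
        role_members = {r: sorted(set(v)) for r, v in role_members.items()}

    pooled: dict[Role, list[float]] = {r: [] for r in Role}
    for ds in datasets:
        for role, members in role_members.items():
            for p in members:
                if p in ds.abundances:
                    pooled[role].append(ds.abundances[p])

    values = {r: np.asarray(v, dtype=float) for r, v in pooled.items()}
    medians = {
        r: float(np.median(v)) if v.size else float("nan") for r, v in values.items()
    }
    n = {r: int(v.size) for r, v in values.items()}
    comp = RoleComparison(values=values, medians=medians, n=n)
    roles = [r for r in Role if n[r] > 0]
    for i, r1 in enumerate(roles):
        for r2 in roles[i + 1 :]:
            _, p = two_group_test(values[r1], values[r2])
            comp.pvalues[(r1, r2)] = p
    return comp


def substrate_partner_correlation(
    modules: Sequence[RegulatoryModule],
    datasets: Sequence[AbundanceDataset],
    mode: str = "per_e3",
) -> tuple[float, float, int]:
    """Spearman correlation of substrate vs partner abundances across datasets.

    ``mode='per_e3'``: one point per (substrate, E3, dataset) where both are
    measured.  ``mode='summed_aps'``: one point per (substrate, dataset)
    pairing the substrate's ppm with the summed ppm of all its APs, only for
    datasets where the substrate and *every* AP are measured.
    """
    xs: list[float] = []
    ys: list[float] = []
    for ds in datasets:
        for m in modules:
            sub_ppm = ds.abundances.get(m.substrate)
            if sub_ppm is None:
                continue
            if mode == "per_e3":
                for e3 in sorted(m.e3s):
                    if e3 in ds.abundances:
                        xs.append(sub_ppm)
                        ys.append(ds.abundances[e3])
            elif mode == "summed_aps":
                if m.aps and all(ap in ds.abundances for ap in m.aps):
                    xs.append(sub_ppm)
                    ys.append(sum(ds.abundances[ap] for ap in m.aps))
            else:
                raise ValueError(f"unknown mode: {mode}")
    return spearman(xs, ys)


def module_rank_heatmap(
    proteins: Sequence[str],
    datasets: Sequence[AbundanceDataset],
    n_bins: int = 100,
) -> pd.DataFrame:
    """Rank-bin matrix (protein x dataset) with NaN marking missing data.

    Row order follows ``proteins``; column order follows ``datasets``.  A
    protein absent from a dataset gets NaN, never a synthetic bin.
    """
    cols = {}
    for ds in datasets:
        bins = rank_bins(ds, n_bins)
        cols[ds.dataset_id] = [bins.get(p, np.nan) for p in proteins]
    return pd.DataFrame(cols, index=list(proteins))
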