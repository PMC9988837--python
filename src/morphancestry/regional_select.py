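"""Regional labelling, median-threshold filtering and balanced subsampling.

Individuals are labelled by their maximum admixture proportion, each
regional group is thresholded at the median of its members' maximum
proportions (inclusive), and a balanced cohort is drawn by sampling a fixed
number of survivors per region without replacement. Regions with at most
the target count keep everyone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import AdmixtureQ

__all__ = [
    "RegionalAssignment",
    "assign_max_region",
    "median_threshold_filter",
    "balanced_subsample",
    "select_cohort",
]


@dataclass
class RegionalAssignment:
    """Per-individual regional label, max proportion and selection state."""

    table: pd.DataFrame                 # index id; columns region, max_proportion, selected
    region_names: list[str]
    region_medians: dict[str, float] = field(default_factory=dict)

    @property
    def ids(self) -> list[str]:
        return list(self.table.index)

    def selected_ids(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])

    def selected_mask(self) -> np.ndarray:
        return self.table["selected"].to_numpy()

    def counts(self) -> pd.DataFrame:
        """Composition table: members, median threshold and selected count
        per region."""
        rows = []
        for region in self.region_names:
            members = self.table[self.table["region"] == region]
            rows.append({
                "region": region,
                "n_members": len(members),
                "median_max_proportion": self.region_medians.get(region, np.nan),
                "n_selected": int(members["selected"].sum()),
            })
        return pd.DataFrame(rows)


def assign_max_region(q: AdmixtureQ, region_names=None) -> RegionalAssignment:
    """Label each individual by its maximum contributing ancestry
    proportion; ties break to the lowest region column index."""
    if region_names is None:
        region_names = q.region_names
    region_names = list(region_names)
    if q.proportions.shape[0] == 0:
        raise ValueError("empty admixture matrix")
    if len(region_names) != q.proportions.shape[1]:
        raise ValueError("region_names length must equal Q column count")
    argmax = q.proportions.argmax(axis=1)   # numpy argmax takes first on ties
    table = pd.DataFrame({
        "region": [region_names[j] for j in argmax],
        "max_proportion": q.proportions.max(axis=1),
        "selected": True,
    }, index=pd.Index(q.ids, name="id"))
    return RegionalAssignment(table, region_names)


def median_threshold_filter(assignment: RegionalAssignment) -> RegionalAssignment:
    """Keep individuals whose max proportion is >= their regional group's
    median max proportion (midpoint median for even counts, boundary
    inclusive)."""
    table = assignment.table.copy()
    medians: dict[str, float] = {}
    for region in assignment.region_names:
        mask = table["region"] == region
        if not mask.any():
            warnings.warn(f"region {region!r} has no members; median undefined")
            continue
        med = float(table.loc[mask, "max_proportion"].median())
        medians[region] = med
        table.loc[mask, "selected"] = table.loc[mask, "max_proportion"] >= med
    return RegionalAssignment(table, assignment.region_names, medians)


def balanced_subsample(assignment: RegionalAssignment, n_target: int,
                       seed: int | None = None) -> RegionalAssignment:
    """Per region, keep a uniform random ``n_target``-subset of the selected
    members (all of them when the region has <= n_target survivors).

    Sampling shuffles the region's sorted ids with a seeded generator, so
    the draw is reproducible and independent of input row order.
    """
    if n_target <= 0:
        raise ValueError("n_target must be positive")
    rng = np.random.default_rng(seed)
    table = assignment.table.copy()
    for region in assignment.region_names:
        mask = (table["region"] == region) & table["selected"]
        survivors = sorted(table.index[mask])
        if len(survivors) <= n_target:
            continue
        keep = set(np.array(survivors)[rng.permutation(len(survivors))[:n_target]])
        drop = [i for i in survivors if i not in keep]
        table.loc[drop, "selected"] = False
    return RegionalAssignment(table, assignment.region_names,
                              dict(assignment.region_medians))


def select_cohort(q: AdmixtureQ, n_target: int = 186, seed: int | None = None,
                  region_names=None) -> RegionalAssignment:
    """Full selection pipeline: argmax labels -> median filter -> balanced
    subsample."""
    assignment = assign_max_region(q, region_names)
    assignment = median_threshold_filter(assignment)
    return balanced_subsample(assignment, n_target, seed)
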