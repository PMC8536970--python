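"""Model-style front end for the assembly-process partition.

``CommunityAssembly`` bundles the inputs (count table, tree, group
map); ``fit`` runs both null models and returns a
``CommunityAssemblyResults`` carrying the betaNTI and RC_bray matrices,
the per-pair process labels and contribution summaries, with a
``summary()`` table mirroring the usual pie-chart percentages.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from .data import GroupMap, OtuTable, PhyloTree
from .nullmodels import (
    BetaNtiMatrix,
    ContributionSummary,
    RcMatrix,
    beta_nti,
    classify_pairs,
    raup_crick_bray,
    summarize_contributions,
)


class CommunityAssembly:
    """Null-model partition of assembly processes for one community table.

    Parameters
    ----------
    table
        Rarefied OTU table (samples x taxa).
    tree
        Phylogeny covering every taxon in the table.
    groups
        Sample-to-group assignment; drives the within/between summaries.
    """

    def __init__(self, table: OtuTable, tree: PhyloTree, groups: GroupMap):
        unknown = [s for s in table.sample_ids if s not in set(groups.sample_ids)]
        if unknown:
            raise ValueError(f"samples without group assignment: {unknown}")
        self.table = table
        self.tree = tree
        self.groups = groups

    def fit(
        self,
        reps: int = 999,
        abundance_weighted: bool = True,
        seed: int | None = None,
    ) -> "CommunityAssemblyResults":
        bnti = beta_nti(
            self.table, self.tree, reps=reps,
            abundance_weighted=abundance_weighted, seed=seed,
        )
        rc = raup_crick_bray(self.table, reps=reps, seed=None if seed is None else seed + 1)
        return CommunityAssemblyResults(model=self, bnti=bnti, rc=rc)


@dataclass
class CommunityAssemblyResults:
    model: CommunityAssembly
    bnti: BetaNtiMatrix
    rc: RcMatrix
    _pairs: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def pairs(self) -> pd.DataFrame:
        """Long-format per-pair betaNTI, RC_bray and process label."""
        if self._pairs is None:
            df = classify_pairs(self.bnti, self.rc)
            df["group_a"] = df["sample_a"].map(self.model.groups.group_of)
            df["group_b"] = df["sample_b"].map(self.model.groups.group_of)
            self._pairs = df
        return self._pairs

    def contributions(self, scope="regional") -> ContributionSummary:
        return summarize_contributions(self.bnti, self.rc, self.model.groups, scope)

    def all_contributions(self) -> dict[str, ContributionSummary]:
        """Regional, every within-group and every between-group summary."""
        out = {"regional": self.contributions("regional")}
        names = self.model.groups.group_names
        for g in names:
            out[f"within:{g}"] = self.contributions(("within", g))
        for g1, g2 in combinations(names, 2):
            out[f"between:{g1}-{g2}"] = self.contributions(("between", g1, g2))
        return out

    def summary(self) -> pd.DataFrame:
        """Percentage of pairs per process at every scope (1 decimal)."""
        rows = {}
        for name, summ in self.all_contributions().items():
            rows[name] = {**summ.percentages, "n_pairs": summ.n_pairs}
        df = pd.DataFrame(rows).T
        df["n_pairs"] = df["n_pairs"].astype(int)
        df.index.name = "scope"
        return df
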