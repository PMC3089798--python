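"""Cross-species comparison of differential-expression calls over orthologs.

Ortholog groups (HomoloGene-style) are the unit of comparison.  Each group
gets a per-species status in {up, down, ns, absent} — absent meaning the
species' platform carries no probe for the group — and one of five mutually
exclusive categories:

* conserved: every represented species is significant, all in one direction;
* divergent: at least two species significant with opposite directions;
* specific: exactly one of >= 2 represented species is significant;
* partial: >= 2 species significant in the same direction, but at least one
  represented species is not significant;
* none: no species significant (also used for groups represented on fewer
  than two platforms, which admit no cross-species comparison).

The direction a species contributes from a time course is the sign of the
fold change at its significant time point of maximal |fold change|.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Mapping, Sequence

import pandas as pd

STATUSES = ("up", "down", "ns", "absent")
CATEGORIES = ("conserved", "divergent", "specific", "partial", "none")


def categorize(statuses: Mapping[str, str]) -> str:
    """Assign the cross-species category from per-species statuses."""
    represented = {sp: s for sp, s in statuses.items() if s != "absent"}
    calls = {sp: s for sp, s in represented.items() if s in ("up", "down")}
    signs = set(calls.values())
    if len(calls) == 0:
        return "none"
    if len(represented) < 2:
        return "none"  # a single-platform group supports no comparison
    if len(calls) >= 2 and len(signs) == 2:
        return "divergent"
    if len(calls) == 1:
        return "specific"
    # >= 2 calls, all same sign
    if len(calls) == len(represented):
        return "conserved"
    return "partial"


def map_calls(
    species_calls: Mapping[str, pd.DataFrame],
    ortholog_table: pd.DataFrame,
    platform_universes: Mapping[str, set] | None = None,
) -> pd.DataFrame:
    """Project per-species any-time calls onto ortholog groups.

    ``species_calls`` maps species -> DataFrame with ``gene_id``,
    ``any_time`` and ``direction`` columns (one row per gene, as produced by
    ``expression.collapse_any_time``).  ``platform_universes`` maps species
    -> the set of gene ids its platform represents; genes of a group missing
    from a species' universe are marked absent.  When omitted, the universe
    is the set of genes in that species' call table.

    Returns one row per ortholog group with ``status_<species>`` columns and
    a ``category`` column.
    """
    if platform_universes is None:
        platform_universes = {
            sp: set(df["gene_id"]) for sp, df in species_calls.items()
        }
    lookup: dict[str, dict[str, str]] = {}
    for sp, df in species_calls.items():
        if len(df) == 0 or "gene_id" not in df.columns:
            lookup[sp] = {}
            continue
        sub = df.set_index("gene_id")
        lookup[sp] = {
            g: (row["direction"] if row.get("any_time", row["direction"] != "ns") else "ns")
            for g, row in sub.iterrows()
        }
    species = list(species_calls)
    rows = []
    for group_id, grp in ortholog_table.groupby("group_id", sort=True):
        statuses = {sp: "absent" for sp in species}
        for _, rec in grp.iterrows():
            sp, gene = rec["species"], rec["gene_id"]
            if sp not in statuses:
                continue
            if gene not in platform_universes.get(sp, set()):
                continue
            statuses[sp] = lookup[sp].get(gene, "ns")
        row = {"group_id": group_id}
        row.update({f"status_{sp}": statuses[sp] for sp in species})
        row["category"] = categorize(statuses)
        rows.append(row)
    return pd.DataFrame(rows)


def _status_cols(calls: pd.DataFrame) -> list[str]:
    return [c for c in calls.columns if c.startswith("status_")]


def pairwise_overlap(
    calls: pd.DataFrame, species_a: str, species_b: str
) -> tuple[int, int]:
    """(groups represented on both platforms, groups significant in both)."""
    for sp in (species_a, species_b):
        if f"status_{sp}" not in calls.columns:
            raise KeyError(f"unknown species {sp!r} in cross-species calls")
    a = calls[f"status_{species_a}"]
    b = calls[f"status_{species_b}"]
    shared = (a != "absent") & (b != "absent")
    de_both = shared & a.isin(["up", "down"]) & b.isin(["up", "down"])
    return int(shared.sum()), int(de_both.sum())


def overlap_matrix(calls: pd.DataFrame, species: Sequence[str]) -> pd.DataFrame:
    rows = []
    for sa, sb in combinations(species, 2):
        n_shared, n_de = pairwise_overlap(calls, sa, sb)
        rows.append(
            dict(
                species_a=sa,
                species_b=sb,
                n_shared_orthologs=n_shared,
                n_shared_de=n_de,
                pct_shared_de=shared_fraction(n_de, n_shared) if n_shared else 0.0,
            )
        )
    return pd.DataFrame(rows)


def venn_partition(calls: pd.DataFrame, species: Sequence[str]) -> dict[str, int]:
    """Seven-region Venn counts over groups represented on all three platforms.

    Region keys are sorted species tuples joined by '&' (e.g. 'human',
    'human&mouse', 'human&mouse&rat'); counts are of groups significant in
    exactly that species set.
    """
    if len(species) != 3:
        raise ValueError("venn_partition is defined for exactly 3 species")
    cols = {sp: f"status_{sp}" for sp in species}
    on_all = calls.copy()
    for sp, c in cols.items():
        on_all = on_all[on_all[c] != "absent"]
    regions: dict[str, int] = {}
    for r in range(1, 4):
        for combo in combinations(sorted(species), r):
            regions["&".join(combo)] = 0
    for _, row in on_all.iterrows():
        de_in = tuple(sorted(sp for sp in species if row[cols[sp]] in ("up", "down")))
        if de_in:
            regions["&".join(de_in)] += 1
    return regions


def shared_fraction(n_shared_de: int, n_shared_orthologs: int) -> float:
    """Percentage of shared orthologs responding in both species, 1 decimal."""
    if n_shared_orthologs <= 0:
        raise ValueError("n_shared_orthologs must be positive")
    if not 0 <= n_shared_de <= n_shared_orthologs:
        raise ValueError("need 0 <= n_shared_de <= n_shared_orthologs")
    pct = Decimal(100) * Decimal(n_shared_de) / Decimal(n_shared_orthologs)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def category_counts(calls: pd.DataFrame) -> pd.Series:
    return calls["category"].value_counts().reindex(CATEGORIES, fill_value=0)
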