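"""Primary vs secondary response classification from the CHX factorial design.

Cycloheximide (CHX) blocks protein synthesis, so a gene whose TCDD response
survives CHX co-treatment cannot require a newly translated intermediate:
it is a putative primary (direct AhR-mediated) response.  Responses
attenuated or blocked by CHX are putative secondary responses.

Two contrasts are fit per time point with the same empirical-Bayes machinery
as the main analysis: r0 = TCDD vs vehicle and r1 = TCDD+CHX vs CHX (the
CHX-alone baseline absorbs CHX's own transcriptional effects).  A responsive
gene (r0 passes the DE thresholds) is

* primary    when r1 also passes, has the same sign as r0, and retains at
  least ``retention_alpha`` of |r0| (superinduction |r1| > |r0| is always
  primary);
* secondary  when r1 fails the thresholds or retains less than
  ``retention_alpha`` of |r0|;
* unclassified when r1 is significant but with the opposite sign.

Classes at 4 h and 12 h merge conservatively: equal classes stand; a
classified time point beats a nonresponsive one; primary vs secondary is a
conflict and yields unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionTable, FormatError
from .expression import fit_empirical_bayes

CLASSES = ("primary", "secondary", "unclassified", "nonresponsive")


def fit_factorial(
    table: ExpressionTable,
    sheet: pd.DataFrame,
    times_hr: tuple[float, ...] = (4.0, 12.0),
    species: str | None = None,
    prior_active: float = 0.01,
    signal_variance_ratio: float = 64.0,
) -> pd.DataFrame:
    """Per-gene, per-time contrasts r0 (TCDD effect) and r1 (effect under CHX).

    Requires all four factorial conditions at each time point.  Probe-level
    statistics are collapsed to genes by best P1 per contrast.  Returns a
    DataFrame with ``gene_id, time_hr, r0, r1, fc0, fc1, p1_r0, p1_r1``.
    """
    present = set(sheet["treatment"])
    for needed in ("vehicle", "TCDD", "CHX", "TCDD+CHX"):
        if needed not in present:
            raise FormatError(f"missing factorial condition {needed!r}")
    frames = []
    for t in times_hr:
        r0 = fit_empirical_bayes(
            table, sheet, species=species, time_hr=t,
            treatment="TCDD", control="vehicle",
            prior_active=prior_active,
            signal_variance_ratio=signal_variance_ratio,
        )
        r1 = fit_empirical_bayes(
            table, sheet, species=species, time_hr=t,
            treatment="TCDD+CHX", control="CHX",
            prior_active=prior_active,
            signal_variance_ratio=signal_variance_ratio,
        )

        def collapse(df: pd.DataFrame) -> pd.DataFrame:
            df = df.dropna(subset=["p1"])
            idx = df.groupby("gene_id")["p1"].idxmax()
            return df.loc[idx].set_index("gene_id")

        g0, g1 = collapse(r0), collapse(r1)
        genes = sorted(set(g0.index) & set(g1.index))
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": genes,
                    "time_hr": t,
                    "r0": g0.loc[genes, "m_bar"].to_numpy(),
                    "r1": g1.loc[genes, "m_bar"].to_numpy(),
                    "fc0": g0.loc[genes, "fc"].to_numpy(),
                    "fc1": g1.loc[genes, "fc"].to_numpy(),
                    "p1_r0": g0.loc[genes, "p1"].to_numpy(),
                    "p1_r1": g1.loc[genes, "p1"].to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def classify_primary_secondary(
    r0: float,
    r1: float,
    p1_r0: float,
    p1_r1: float,
    p1_min: float = 0.999,
    abs_fc_min: float = 1.4,
    retention_alpha: float = 0.5,
) -> str:
    """Classify one gene at one time point; see the module docstring for rules."""
    fc0 = 2.0 ** abs(r0)
    fc1 = 2.0 ** abs(r1)
    responsive = (p1_r0 > p1_min) and (fc0 > abs_fc_min)
    if not responsive:
        return "nonresponsive"
    r1_significant = (p1_r1 > p1_min) and (fc1 > abs_fc_min)
    retained = abs(r1) >= retention_alpha * abs(r0)
    same_sign = np.sign(r1) == np.sign(r0)
    if abs(r1) > abs(r0) and same_sign and r1_significant:
        return "primary"  # superinduction
    if r1_significant and same_sign and retained:
        return "primary"
    if (not r1_significant) or (same_sign and not retained):
        return "secondary"
    return "unclassified"  # significant opposite-sign response under CHX


def merge_times(class_a: str, class_b: str) -> str:
    """Combine the 4 h and 12 h classes into an overall call."""
    for c in (class_a, class_b):
        if c not in CLASSES:
            raise ValueError(f"unknown class {c!r}")
    if class_a == class_b:
        return class_a
    pair = {class_a, class_b}
    if "nonresponsive" in pair:
        (other,) = pair - {"nonresponsive"}
        return other
    if pair == {"primary", "secondary"}:
        return "unclassified"
    return "unclassified"


@dataclass
class FactorialResults:
    """Per-gene factorial contrasts with per-time and merged classes."""

    table: pd.DataFrame  # gene_id, time_hr, r0, r1, p1_r0, p1_r1, class
    overall: pd.Series  # gene_id -> merged class

    def summary(self) -> pd.DataFrame:
        counts = self.overall.value_counts().reindex(CLASSES, fill_value=0)
        return counts.rename_axis("class").reset_index(name="n_genes")


class FactorialCHXModel:
    """2x2 TCDD x CHX factorial model over a normalized expression table."""

    def __init__(
        self,
        table: ExpressionTable,
        sheet: pd.DataFrame,
        times_hr: tuple[float, ...] = (4.0, 12.0),
        species: str | None = None,
        p1_min: float = 0.999,
        abs_fc_min: float = 1.4,
        retention_alpha: float = 0.5,
        prior_active: float = 0.01,
        signal_variance_ratio: float = 64.0,
    ) -> None:
        from .expression import normalize

        if table.value_kind == "raw_two_channel":
            table = normalize(table, sheet)
        self.table = table
        self.sheet = sheet
        self.times_hr = times_hr
        self.species = species
        self.p1_min = p1_min
        self.abs_fc_min = abs_fc_min
        self.retention_alpha = retention_alpha
        self.prior_active = prior_active
        self.signal_variance_ratio = signal_variance_ratio

    def fit(self) -> FactorialResults:
        fac = fit_factorial(
            self.table,
            self.sheet,
            times_hr=self.times_hr,
            species=self.species,
            prior_active=self.prior_active,
            signal_variance_ratio=self.signal_variance_ratio,
        )
        fac["class"] = [
            classify_primary_secondary(
                row.r0, row.r1, row.p1_r0, row.p1_r1,
                p1_min=self.p1_min,
                abs_fc_min=self.abs_fc_min,
                retention_alpha=self.retention_alpha,
            )
            for row in fac.itertuples()
        ]
        merged = {}
        for gene, grp in fac.groupby("gene_id"):
            classes = list(grp["class"])
            overall = classes[0]
            for c in classes[1:]:
                overall = merge_times(overall, c)
            merged[gene] = overall
        overall = pd.Series(merged, name="overall_class").rename_axis("gene_id")
        return FactorialResults(fac, overall)
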