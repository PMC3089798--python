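"""Normalization, empirical-Bayes differential expression, calling, clustering.

Two-color arrays measure the log ratio M = log2(Cy5/Cy3) per spot; dye
chemistry induces an intensity-dependent bias in M that is removed per array
by subtracting a smooth trend of M on the mean log intensity
A = (log2 Cy5 + log2 Cy3)/2 (LOWESS by default).  Differential expression is
then assessed per condition with a moderated t statistic: per-gene sample
variances are shrunk toward a pooled inverse-chi-square prior (hyperparameters
estimated from the data by the method of moments on log variances), and the
posterior probability of activity P1(t) is computed from a two-component
mixture in which a fraction ``prior_active`` of genes carry effects whose
variance exceeds the null sampling variance by ``signal_variance_ratio``.
P1 is strictly increasing in |t|, so thresholding P1 is a t-threshold with a
data-calibrated scale.

A gene is called differentially expressed when P1(t) > 0.999 and the signed
fold change exceeds 1.4-fold in magnitude, both strictly; the "any time"
call is the OR over conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io import TREATMENT_PRECEDENCE, ExpressionTable, FormatError

MIN_PROBES_FOR_TREND = 20


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def _array_channels(sheet: pd.DataFrame, array_id: str) -> tuple[pd.Series, pd.Series]:
    """Return (treated sample row, control sample row) for one array."""
    grp = sheet[sheet["array_id"] == array_id]
    a, b = (grp.iloc[0], grp.iloc[1])
    if TREATMENT_PRECEDENCE[a["treatment"]] >= TREATMENT_PRECEDENCE[b["treatment"]]:
        return a, b
    return b, a


def normalize(
    table: ExpressionTable,
    sheet: pd.DataFrame,
    lowess_frac: float = 0.4,
) -> ExpressionTable:
    """Intensity-dependent trend removal per array; output oriented M ratios.

    For each array, M = log2(treated channel / control channel) and
    A = mean log2 intensity; the LOWESS fit of M on A is subtracted, which
    absorbs both constant offsets and smooth dye bias.  Dye-swap replicates
    need no further sign handling because M is formed treated-over-control
    regardless of which dye carried the treated sample.

    Returns a log2-ratio table with one column per array.
    """
    if table.value_kind != "raw_two_channel":
        raise FormatError("normalize expects raw two-channel intensities")
    n_probes = table.values.notna().any(axis=1).sum()
    if n_probes < MIN_PROBES_FOR_TREND:
        raise FormatError(
            f"only {n_probes} probes; the intensity trend cannot be fit "
            f"(need >= {MIN_PROBES_FOR_TREND}). Consider passing log ratios "
            "directly instead of normalizing."
        )
    cols: dict[str, np.ndarray] = {}
    for array_id in sheet["array_id"].drop_duplicates():
        treated, control = _array_channels(sheet, array_id)
        t = np.log2(table.values[treated["sample_id"]].to_numpy(dtype=float))
        c = np.log2(table.values[control["sample_id"]].to_numpy(dtype=float))
        m = t - c
        a = (t + c) / 2.0
        ok = np.isfinite(m) & np.isfinite(a)
        if ok.sum() < MIN_PROBES_FOR_TREND:
            raise FormatError(
                f"array {array_id!r} has {int(ok.sum())} usable probes; "
                "trend unfittable"
            )
        fit = lowess(
            m[ok], a[ok], frac=lowess_frac, it=2, xvals=a[ok], return_sorted=False
        )
        out = np.full_like(m, np.nan)
        out[ok] = m[ok] - fit
        cols[array_id] = out
    values = pd.DataFrame(cols, index=table.values.index)
    return ExpressionTable(values, table.gene_map, "log2_ratio")


# ---------------------------------------------------------------------------
# Empirical-Bayes moderated statistics
# ---------------------------------------------------------------------------


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on the inverse scale)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def estimate_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior to sample variances.

    Returns ``(d0, s0_sq)``: prior degrees of freedom (may be inf when the
    variances are no more dispersed than chi-square sampling alone explains)
    and the prior variance.
    """
    keep = (s2 > 0) & (df > 0)
    s2, df = s2[keep], df[keep]
    if len(s2) == 0:
        raise FormatError("no genes with positive residual degrees of freedom")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1) * (len(e) - 1) / len(e) if len(e) > 1 else 0.0
    e_var -= special.polygamma(1, df / 2.0).mean()
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_sq = math.exp(e_mean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0_sq = math.exp(e_mean)
    return d0, s0_sq


def posterior_activity(
    t_mod: np.ndarray,
    df_total: np.ndarray,
    prior_active: float = 0.01,
    signal_variance_ratio: float = 64.0,
) -> np.ndarray:
    """P1: posterior probability a gene is active given its moderated t.

    Two-component Gaussian mixture on the moderated-statistic scale: with
    prior probability ``prior_active`` the true effect is nonzero with
    variance ``signal_variance_ratio`` times the sampling variance of the
    mean (component N(0, 1 + ratio)); otherwise the statistic is N(0, 1).
    P1 = pi1 f1 / (pi1 f1 + (1 - pi1) f0), strictly increasing in |t| and
    unbounded in the log-odds, so arbitrarily strong evidence is expressible.
    ``df_total`` is accepted for interface symmetry; the moderation that
    produced t already accounts for variance-estimation uncertainty.
    """
    t_mod = np.asarray(t_mod, dtype=float)
    scale = math.sqrt(1.0 + signal_variance_ratio)
    # log densities for numerical stability in the far tails
    logf0 = stats.norm.logpdf(t_mod)
    logf1 = stats.norm.logpdf(t_mod / scale) - math.log(scale)
    log_odds = (
        math.log(prior_active) - math.log1p(-prior_active) + logf1 - logf0
    )
    return special.expit(log_odds)


def signed_fold_change(m_bar: np.ndarray) -> np.ndarray:
    """Signed fold change with magnitude >= 1: -1.56 means 1.56-fold down."""
    m_bar = np.asarray(m_bar, dtype=float)
    return np.sign(m_bar) * 2.0 ** np.abs(m_bar) + (m_bar == 0) * 1.0


def fit_empirical_bayes(
    table: ExpressionTable,
    sheet: pd.DataFrame,
    species: str | None = None,
    time_hr: float | None = None,
    treatment: str = "TCDD",
    control: str = "vehicle",
    prior_active: float = 0.01,
    signal_variance_ratio: float = 64.0,
) -> pd.DataFrame:
    """Moderated statistics and P1 for one condition (species x time x contrast).

    Selects the arrays of the requested condition from the sample sheet,
    computes per-gene replicate means and shrunken variances, and returns a
    DataFrame with columns ``m_bar, fc, t_mod, df_total, p1`` indexed by
    probe id (plus a ``gene_id`` column).
    """
    if table.value_kind != "log2_ratio":
        raise FormatError("fit_empirical_bayes expects a normalized log2-ratio table")
    sel = sheet["treatment"].isin([treatment, control])
    if species is not None:
        sel &= sheet["species"] == species
    if time_hr is not None:
        sel &= sheet["time_hr"] == time_hr
    arrays = sheet[sel]["array_id"].drop_duplicates()
    arrays = [a for a in arrays if a in table.values.columns]
    if len(arrays) < 2:
        raise FormatError(
            f"condition (species={species}, time={time_hr}, {treatment} vs "
            f"{control}) has {len(arrays)} arrays; need >= 2 replicates"
        )
    m = table.values[arrays]
    m = m[m.notna().any(axis=1)]  # probes absent from this platform drop out
    n = m.notna().sum(axis=1).to_numpy(dtype=float)
    m_bar = m.mean(axis=1).to_numpy()
    s2 = m.var(axis=1, ddof=1).to_numpy()
    df = np.maximum(n - 1.0, 0.0)
    usable = n >= 2
    d0, s0_sq = estimate_variance_prior(s2[usable], df[usable])
    if not np.isfinite(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.full_like(s2, 1e6)
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df
    if np.any(df_total[usable] <= 0):
        raise FormatError("zero residual degrees of freedom after shrinkage")
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = m_bar / np.sqrt(s2_post / np.maximum(n, 1.0))
    p1 = posterior_activity(t_mod, df_total, prior_active, signal_variance_ratio)
    out = pd.DataFrame(
        {
            "gene_id": table.gene_map.reindex(m.index),
            "m_bar": m_bar,
            "fc": signed_fold_change(m_bar),
            "t_mod": t_mod,
            "df_total": df_total,
            "p1": p1,
        },
        index=m.index,
    )
    out.loc[~usable, ["t_mod", "p1"]] = np.nan
    out.index.name = "probe_id"
    return out


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------


class DifferentialExpressionModel:
    """Empirical-Bayes differential expression across all conditions of a design.

    Parameters
    ----------
    table : ExpressionTable
        Normalized log2-ratio table (or raw two-channel, normalized on fit).
    sheet : pandas.DataFrame
        Sample sheet; conditions are the (species, time) pairs carrying the
        requested treatment/control contrast.
    """

    def __init__(
        self,
        table: ExpressionTable,
        sheet: pd.DataFrame,
        treatment: str = "TCDD",
        control: str = "vehicle",
        prior_active: float = 0.01,
        signal_variance_ratio: float = 64.0,
        lowess_frac: float = 0.4,
    ) -> None:
        if table.value_kind == "raw_two_channel":
            table = normalize(table, sheet, lowess_frac=lowess_frac)
        self.table = table
        self.sheet = sheet
        self.treatment = treatment
        self.control = control
        self.prior_active = prior_active
        self.signal_variance_ratio = signal_variance_ratio

    def conditions(self) -> list[tuple[str, float]]:
        sel = self.sheet["treatment"] == self.treatment
        pairs = self.sheet[sel][["species", "time_hr"]].drop_duplicates()
        return sorted(map(tuple, pairs.to_numpy()))

    def fit(self) -> "DEResults":
        frames = []
        for species, time_hr in self.conditions():
            stats_df = fit_empirical_bayes(
                self.table,
                self.sheet,
                species=species,
                time_hr=time_hr,
                treatment=self.treatment,
                control=self.control,
                prior_active=self.prior_active,
                signal_variance_ratio=self.signal_variance_ratio,
            ).reset_index()
            stats_df.insert(1, "species", species)
            stats_df.insert(2, "time_hr", time_hr)
            frames.append(stats_df)
        return DEResults(self, pd.concat(frames, ignore_index=True))


@dataclass
class DEResults:
    """Per-(probe, condition) moderated statistics with threshold calling."""

    model: DifferentialExpressionModel
    stats: pd.DataFrame  # probe_id, species, time_hr, gene_id, m_bar, fc, t_mod, p1

    def calls(self, p1_min: float = 0.999, abs_fc_min: float = 1.4) -> pd.DataFrame:
        return call_de(self.stats, p1_min=p1_min, abs_fc_min=abs_fc_min)

    def summary(self, p1_min: float = 0.999, abs_fc_min: float = 1.4) -> pd.DataFrame:
        """Per-condition DE counts at probe and gene level, with percentages."""
        calls = self.calls(p1_min, abs_fc_min)
        rows = []
        for (species, t), grp in calls.groupby(["species", "time_hr"]):
            sig = grp[grp["significant"]]
            n_probe = len(grp["probe_id"].unique())
            n_gene = len(grp["gene_id"].unique())
            rows.append(
                dict(
                    species=species,
                    time_hr=t,
                    n_probes=n_probe,
                    n_genes=n_gene,
                    de_probes=len(sig["probe_id"].unique()),
                    de_genes=len(sig["gene_id"].unique()),
                    pct_genes=response_percentage(
                        len(sig["gene_id"].unique()), n_gene
                    ),
                )
            )
        return pd.DataFrame(rows)

    def any_time_calls(
        self, p1_min: float = 0.999, abs_fc_min: float = 1.4, by_gene: bool = True
    ) -> pd.DataFrame:
        return collapse_any_time(self.calls(p1_min, abs_fc_min), by_gene=by_gene)


def call_de(
    stats_df: pd.DataFrame, p1_min: float = 0.999, abs_fc_min: float = 1.4
) -> pd.DataFrame:
    """Apply the strict dual threshold P1 > p1_min AND |fc| > abs_fc_min.

    Returns the input plus ``significant`` and ``direction`` ('up'/'down'/'ns')
    columns.  Both comparisons are strict: a gene exactly at P1 = 0.999 or
    |fc| = 1.4 is not called.
    """
    out = stats_df.copy()
    sig = (out["p1"] > p1_min) & (out["fc"].abs() > abs_fc_min)
    sig &= out["p1"].notna()
    out["significant"] = sig.to_numpy()
    direction = np.where(out["fc"] > 0, "up", "down")
    out["direction"] = np.where(out["significant"], direction, "ns")
    return out


def collapse_any_time(calls: pd.DataFrame, by_gene: bool = True) -> pd.DataFrame:
    """Per-gene (or per-probe) any-time call with the strongest significant signal.

    Direction follows the significant condition with maximal |fc|; genes with
    multiple probes take the probe with the highest P1 (best-probe collapse).
    """
    key = "gene_id" if by_gene else "probe_id"
    rows = []
    for (species, gene), grp in calls.groupby(["species", key], sort=True):
        sig = grp[grp["significant"]]
        if len(sig):
            best = sig.loc[sig["fc"].abs().idxmax()]
            rows.append(
                dict(
                    species=species,
                    **{key: gene},
                    any_time=True,
                    direction=best["direction"],
                    fc=best["fc"],
                    p1=best["p1"],
                )
            )
        else:
            best = grp.loc[grp["p1"].idxmax()] if grp["p1"].notna().any() else grp.iloc[0]
            rows.append(
                dict(
                    species=species,
                    **{key: gene},
                    any_time=False,
                    direction="ns",
                    fc=best["fc"],
                    p1=best["p1"],
                )
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Hierarchical clustering of DE profiles
# ---------------------------------------------------------------------------


def _masked_euclidean(profiles: np.ndarray) -> np.ndarray:
    """Pairwise-complete Euclidean distance, rescaled by sqrt(total/observed)."""
    n, p = profiles.shape
    dist = np.zeros((n, n))
    finite = np.isfinite(profiles)
    for i in range(n):
        for j in range(i + 1, n):
            both = finite[i] & finite[j]
            k = both.sum()
            if k == 0:
                raise FormatError(
                    "gene pair with no common observed conditions; impute first"
                )
            d2 = np.sum((profiles[i, both] - profiles[j, both]) ** 2)
            dist[i, j] = dist[j, i] = math.sqrt(d2 * p / k)
    return dist


def cluster_de_profiles(profile_matrix: pd.DataFrame):
    """Average-linkage Euclidean clustering of gene expression profiles.

    ``profile_matrix`` is genes x conditions (e.g. mean M per time point),
    restricted upstream to any-time DE genes.  Rows are sorted by gene id
    before linkage so the tree is deterministic under input permutation.
    Returns ``(linkage_matrix, leaf_labels, leaf_order)``.
    """
    if len(profile_matrix) < 2:
        raise FormatError("clustering needs >= 2 genes")
    mat = profile_matrix.sort_index()
    arr = mat.to_numpy(dtype=float)
    all_missing = ~np.isfinite(arr)
    if all_missing.all(axis=1).any():
        bad = mat.index[all_missing.all(axis=1)][0]
        raise FormatError(f"gene {bad!r} has no observed values")
    from scipy.cluster.hierarchy import leaves_list, linkage
    from scipy.spatial.distance import squareform

    dist = _masked_euclidean(arr)
    link = linkage(squareform(dist, checks=False), method="average")
    order = leaves_list(link)
    return link, list(mat.index), [mat.index[i] for i in order]


# ---------------------------------------------------------------------------
# Summary percentages
# ---------------------------------------------------------------------------


def response_percentage(n_de: int, n_total: int) -> float:
    """Percentage of responsive genes, one decimal, round half up.

    (691, 6995) -> 9.9; round-half-up matches conventional reporting
    (9.879 -> 9.9, 2.427 -> 2.4).
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_de <= n_total:
        raise ValueError("need 0 <= n_de <= n_total")
    pct = Decimal(100) * Decimal(n_de) / Decimal(n_total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
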