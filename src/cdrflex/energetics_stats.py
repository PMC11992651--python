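"""Cluster-resolved interaction-energy statistics.

Per-frame interaction free energies (consumed from tables; the
end-state solver that produced them is out of scope) are windowed,
paired with the loop-extension metric, classified into loop clusters
A/B/C, and summarised per (variant, isoform, cluster) group.  Group
comparisons use two-way ANOVA (Type II sums of squares on the
unbalanced design) with Tukey-Kramer multiple-comparison tests; the
ensemble binding energy of a complex is the occupancy-weighted mean of
its cluster energies, and the most-populated (MP) cluster provides the
single-conformation energy paired against experimental affinities by
rank concordance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .conformational_clustering import CLUSTER_LABELS, LoopStats, assign_clusters

__all__ = [
    "GroupSummary",
    "AlignmentError",
    "DegenerateVarianceError",
    "window_frame_times",
    "classify_energy_frames",
    "summarize_groups",
    "two_way_anova",
    "tukey_kramer",
    "weighted_cluster_mean",
    "mp_cluster",
    "rank_concordance",
]


class AlignmentError(ValueError):
    """Energy and loop-metric time grids disagree."""


class DegenerateVarianceError(ValueError):
    """Zero residual variance: test statistics undefined."""


@dataclass(frozen=True)
class GroupSummary:
    """Descriptive statistics of one (variant, isoform, cluster) group."""

    key: tuple
    n: int
    mean: float
    sd: float  # NaN for n = 1
    sem: float  # NaN for n = 1
    minimum: float
    maximum: float


def window_frame_times(t_start: float, t_end: float, dt: float) -> np.ndarray:
    """Inclusive arithmetic time grid ``t_start, t_start+dt, ..., t_end`` (ns).

    The span must be an exact multiple of ``dt``; the default analysis
    window (450, 500, 0.5) yields 101 frame times per complex.
    """
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    if dt <= 0:
        raise ValueError("dt must be positive")
    span = t_end - t_start
    steps = span / dt
    if abs(steps - round(steps)) > 1e-9:
        raise ValueError(
            f"window span {span} ns is not a multiple of dt = {dt} ns"
        )
    n = int(round(steps)) + 1
    return t_start + dt * np.arange(n)


def classify_energy_frames(
    energies: pd.DataFrame,
    loop1: pd.DataFrame,
    stats: LoopStats,
    time_tol: float = 1e-6,
) -> pd.DataFrame:
    """Join per-frame energies with loop distances and label clusters.

    ``energies`` needs columns ``time_ns`` and ``energy_kcal_mol`` (any
    further identity columns pass through); ``loop1`` needs ``time_ns``
    and ``loop1_A``.  The two time grids must agree exactly (within
    ``time_tol``); any mismatch raises :class:`AlignmentError` listing
    the offending times.  Cluster labels come from the mean±SD rule on
    the supplied loop statistics.
    """
    for col in ("time_ns", "energy_kcal_mol"):
        if col not in energies.columns:
            raise ValueError(f"energies table lacks column {col!r}")
    for col in ("time_ns", "loop1_A"):
        if col not in loop1.columns:
            raise ValueError(f"loop1 table lacks column {col!r}")

    e_times = energies["time_ns"].to_numpy(float)
    l_times = loop1["time_ns"].to_numpy(float)
    if len(e_times) != len(l_times) or np.any(np.abs(e_times - l_times) > time_tol):
        e_set = np.round(e_times, 9)
        l_set = np.round(l_times, 9)
        offending = sorted(set(e_set).symmetric_difference(l_set))[:10]
        raise AlignmentError(
            f"energy and loop time grids differ "
            f"({len(e_times)} vs {len(l_times)} frames; first mismatches: {offending})"
        )

    out = energies.copy()
    out["loop1_A"] = loop1["loop1_A"].to_numpy(float)
    assignment = assign_clusters(out["loop1_A"].to_numpy(), stats)
    out["cluster"] = assignment.labels
    return out


def summarize_groups(
    records: pd.DataFrame,
    keys: list[str] = ("trem2_variant", "apoe_isoform", "cluster"),
    value: str = "energy_kcal_mol",
) -> list[GroupSummary]:
    """Per-group n, mean, SD (n−1), SEM, min and max.

    Groups with a single record report NaN SD/SEM rather than failing.
    """
    if records.empty:
        raise ValueError("records table is empty")
    keys = list(keys)
    summaries = []
    for key, grp in records.groupby(keys, sort=True, observed=True):
        vals = grp[value].to_numpy(float)
        n = len(vals)
        sd = float(np.std(vals, ddof=1)) if n > 1 else float("nan")
        summaries.append(
            GroupSummary(
                key=key if isinstance(key, tuple) else (key,),
                n=n,
                mean=float(vals.mean()),
                sd=sd,
                sem=sd / np.sqrt(n) if n > 1 else float("nan"),
                minimum=float(vals.min()),
                maximum=float(vals.max()),
            )
        )
    return summaries


def two_way_anova(
    records: pd.DataFrame,
    factor_a: str = "cluster",
    factor_b: str = "apoe_isoform",
    value: str = "energy_kcal_mol",
) -> pd.DataFrame:
    """Two-way ANOVA with Type II sums of squares on the unbalanced design.

    Returns a table indexed by effect (factor_a, factor_b, interaction,
    residual) with columns ``sum_sq, df, F, p``.  The interaction is
    dropped (and flagged by its absence) when empty cells make it
    unestimable; zero residual variance raises
    :class:`DegenerateVarianceError`.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    data = records[[factor_a, factor_b, value]].rename(
        columns={factor_a: "fa", factor_b: "fb", value: "y"}
    )
    if data["fa"].nunique() < 2 or data["fb"].nunique() < 2:
        raise ValueError("both factors need at least two levels")

    cell_counts = data.groupby(["fa", "fb"], observed=True).size()
    full_cells = data["fa"].nunique() * data["fb"].nunique()
    with_interaction = len(cell_counts) == full_cells and (cell_counts > 0).all()

    formula = "y ~ C(fa) * C(fb)" if with_interaction else "y ~ C(fa) + C(fb)"
    model = smf.ols(formula, data=data).fit()
    if model.df_resid < 1:
        raise DegenerateVarianceError("no residual degrees of freedom")
    if model.ssr <= 1e-12 * max(1.0, float(np.var(data["y"]) * len(data))):
        raise DegenerateVarianceError("zero residual variance; F undefined")
    table = sm.stats.anova_lm(model, typ=2)

    rename = {"C(fa)": factor_a, "C(fb)": factor_b,
              "C(fa):C(fb)": f"{factor_a}:{factor_b}", "Residual": "residual"}
    table = table.rename(index=rename)
    table = table.rename(columns={"PR(>F)": "p"})
    return table[["sum_sq", "df", "F", "p"]]


def tukey_kramer(
    records: pd.DataFrame,
    grouping: list[str] = ("trem2_variant", "apoe_isoform", "cluster"),
    value: str = "energy_kcal_mol",
) -> pd.DataFrame:
    """Tukey-Kramer pairwise comparisons over the grouping's cells.

    Unequal group sizes are handled by the Kramer form (pooled MSE with
    per-pair harmonic sample sizes); adjusted p-values come from the
    studentized-range distribution.  Returns a table with columns
    ``group1, group2, meandiff, p_adj, lower, upper, reject``.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    grouping = list(grouping)
    labels = records[grouping].astype(str).agg("/".join, axis=1)
    if labels.nunique() < 2:
        raise ValueError("need at least two groups")
    counts = labels.value_counts()
    if (counts < 1).any():
        raise ValueError("every group needs at least one record")
    res = pairwise_tukeyhsd(records[value].to_numpy(float), labels.to_numpy(), alpha=0.05)
    table = pd.DataFrame(
        res.summary().data[1:],
        columns=[c.strip() for c in res.summary().data[0]],
    )
    table = table.rename(columns={"p-adj": "p_adj"})
    # summary() rounds; take exact values from the result object
    table["meandiff"] = res.meandiffs
    table["p_adj"] = res.pvalues
    table["lower"] = res.confint[:, 0]
    table["upper"] = res.confint[:, 1]
    table["reject"] = res.reject
    return table[["group1", "group2", "meandiff", "p_adj", "lower", "upper", "reject"]]


def weighted_cluster_mean(summaries: list[GroupSummary]) -> float:
    """Occupancy-weighted ensemble energy: Σ n_c·mean_c / Σ n_c.

    Algebraically identical to the plain mean of all records of the
    complex; clusters absent from ``summaries`` contribute n = 0.
    """
    total = sum(s.n for s in summaries)
    if total <= 0:
        raise ValueError("cluster occupancies sum to zero")
    return float(sum(s.n * s.mean for s in summaries) / total)


def mp_cluster(summaries: list[GroupSummary]) -> GroupSummary:
    """Most-populated cluster of one complex (largest frame count).

    Ties are broken towards the lowest (most favourable) mean energy,
    and reported via the returned summary itself.
    """
    if not summaries or all(s.n == 0 for s in summaries):
        raise ValueError("no occupied clusters")
    return min(summaries, key=lambda s: (-s.n, s.mean))


def rank_concordance(
    model_means: dict[str, float],
    inverse_affinities: dict[str, float],
) -> float:
    """Spearman rank correlation between binding strength and affinity.

    ``model_means`` maps isoform to a (negative) interaction free energy
    in kcal/mol; ``inverse_affinities`` maps the same isoforms to 1/K_D.
    More negative energy means stronger binding, so the correlation is
    computed between −energy and 1/K_D; +1 is perfect concordance.
    """
    keys = sorted(model_means)
    if sorted(inverse_affinities) != keys:
        raise ValueError("model_means and inverse_affinities keys must match")
    if len(keys) < 3:
        raise ValueError("need at least three paired values")
    x = np.array([-model_means[k] for k in keys])
    y = np.array([inverse_affinities[k] for k in keys])
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateVarianceError("constant vector: correlation undefined")
    rho, _ = sps.spearmanr(x, y)
    return float(rho)
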