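"""Chemotaxis-index computation and the group-comparison harness.

The statistical routines themselves (Welch's t, Mann-Whitney, Kruskal-Wallis,
one- and two-way ANOVA, Dunnett, Fisher's exact, Sidak adjustment) delegate to
scipy and statsmodels; this module contributes the typed harness, the
comparison plan, and a hand-rolled Dunn's rank posttest (not available in the
installed libraries).  All p-values are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .errors import InvalidArgumentError

__all__ = [
    "ChemotaxisCounts",
    "CohortTable",
    "PosthocComparison",
    "TestResult",
    "chemotaxis_index",
    "compare_two",
    "compare_multi",
    "compare_categorical",
    "dunn_posthoc",
    "sidak_adjust",
]


@dataclass(frozen=True)
class ChemotaxisCounts:
    """Worm counts from one chemotaxis assay plate.

    ``n_origin`` counts worms that never left the origin region; they are
    excluded from the index by default.
    """

    n_test: int
    n_control: int
    plate_id: str = ""
    n_origin: int = 0

    def __post_init__(self) -> None:
        if self.n_test < 0 or self.n_control < 0 or self.n_origin < 0:
            raise InvalidArgumentError("counts must be non-negative")
        if self.n_test + self.n_control + self.n_origin < 1:
            raise InvalidArgumentError("at least one worm must be scored")


def chemotaxis_index(c: ChemotaxisCounts, include_origin: bool = False) -> float:
    """Normalized count difference, in [-1, 1].

    ``(n_test - n_control) / (n_test + n_control)``; with
    ``include_origin=True`` worms at the origin enter the denominator.
    """
    denom = c.n_test + c.n_control + (c.n_origin if include_origin else 0)
    if denom <= 0:
        raise InvalidArgumentError("cannot compute index with zero scored worms")
    return (c.n_test - c.n_control) / denom


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PosthocComparison:
    pair: tuple[str, str]
    statistic: float
    p_raw: float
    p_adj: float


@dataclass(frozen=True)
class TestResult:
    """Omnibus statistic, p-value, and optional adjusted pairwise posttests."""

    test_name: str
    statistic: float
    p_value: float
    n_per_group: dict[str, int] = field(default_factory=dict)
    posthoc: tuple[PosthocComparison, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise InvalidArgumentError(f"p-value out of range: {self.p_value}")


@dataclass
class CohortTable:
    """Long-format per-animal (or per-plate) metric table.

    Columns: ``id``, ``group``, ``metric``, ``value``; no duplicate
    (id, metric) pairs within a group.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"id", "group", "metric", "value"}
        if not required.issubset(self.data.columns):
            raise InvalidArgumentError(f"CohortTable needs columns {sorted(required)}")
        if self.data.duplicated(subset=["id", "group", "metric"]).any():
            raise InvalidArgumentError("duplicate (id, group, metric) rows")

    @classmethod
    def from_wide(cls, wide: pd.DataFrame, id_col: str, group_col: str,
                  metric_cols: list[str]) -> "CohortTable":
        long = wide.melt(
            id_vars=[id_col, group_col], value_vars=metric_cols,
            var_name="metric", value_name="value",
        ).rename(columns={id_col: "id", group_col: "group"})
        return cls(long)

    def values_by_group(self, metric: str, groups: list[str] | None = None) -> dict[str, np.ndarray]:
        sub = self.data[self.data["metric"] == metric]
        if sub.empty:
            raise InvalidArgumentError(f"no rows for metric {metric!r}")
        out: dict[str, np.ndarray] = {}
        for g, grp in sub.groupby("group"):
            if groups is None or g in groups:
                out[str(g)] = grp["value"].to_numpy(dtype=float)
        if groups is not None:
            missing = [g for g in groups if g not in out]
            if missing:
                raise InvalidArgumentError(f"groups {missing} absent for metric {metric!r}")
            out = {g: out[g] for g in groups}
        return out


# ---------------------------------------------------------------------------
# two-group comparisons
# ---------------------------------------------------------------------------

def compare_two(values_a, values_b, method: str = "welch_t") -> TestResult:
    """Two-group comparison: Welch's t or Mann-Whitney U (two-sided).

    Mann-Whitney uses scipy's exact null distribution for small tie-free
    samples and the normal approximation otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidArgumentError("each group needs at least 2 values")
    if method == "welch_t":
        res = sps.ttest_ind(a, b, equal_var=False)
    elif method == "mann_whitney":
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    else:
        raise InvalidArgumentError(f"unknown two-group method {method!r}")
    return TestResult(
        test_name=method,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_per_group={"a": a.size, "b": b.size},
    )


# ---------------------------------------------------------------------------
# multi-group comparisons
# ---------------------------------------------------------------------------

def sidak_adjust(p: np.ndarray) -> np.ndarray:
    """Sidak family-wise adjustment: ``1 - (1 - p)^m``."""
    p = np.asarray(p, dtype=float)
    return 1.0 - (1.0 - p) ** p.size


def dunn_posthoc(groups: dict[str, np.ndarray], adjust: str = "bonferroni") -> list[PosthocComparison]:
    """Dunn's rank-based pairwise posttest after Kruskal-Wallis.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)) with the
    standard tie correction T = sum(t^3 - t) / (12 (N - 1)); two-sided normal
    p-values adjusted over all pairs.
    """
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_rank: dict[str, float] = {}
    i = 0
    for g in names:
        n = groups[g].size
        mean_rank[g] = float(np.mean(ranks[i : i + n]))
        i += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    zs, praw, pairs = [], [], []
    for g1, g2 in combinations(names, 2):
        se = np.sqrt(var_base * (1.0 / groups[g1].size + 1.0 / groups[g2].size))
        z = (mean_rank[g1] - mean_rank[g2]) / se if se > 0 else 0.0
        zs.append(z)
        praw.append(2.0 * sps.norm.sf(abs(z)))
        pairs.append((g1, g2))
    padj = multipletests(praw, method=adjust)[1] if praw else []
    return [
        PosthocComparison(pair=p, statistic=float(z), p_raw=float(pr), p_adj=float(pa))
        for p, z, pr, pa in zip(pairs, zs, praw, padj)
    ]


def _as_group_dict(groups) -> dict[str, np.ndarray]:
    if isinstance(groups, dict):
        return {str(k): np.asarray(v, dtype=float) for k, v in groups.items()}
    return {f"g{i}": np.asarray(v, dtype=float) for i, v in enumerate(groups)}


def compare_multi(
    groups,
    method: str,
    design: pd.DataFrame | None = None,
    reference: str | None = None,
    pairs: list[tuple] | None = None,
) -> TestResult:
    """Multi-group comparison with the posttest the method name implies.

    Methods
    -------
    ``kruskal_dunn``
        Kruskal-Wallis omnibus + Dunn's pairwise posttest (Bonferroni-family
        adjustment), all pairs.
    ``anova_dunnett``
        One-way ANOVA omnibus + Dunnett's test of every group against
        ``reference`` (defaults to the first group).
    ``anova2_sidak``
        Two-way factorial ANOVA on ``design`` (columns ``value``, ``factor_a``,
        ``factor_b``) + Sidak-adjusted pooled-variance cell contrasts for the
        requested ``pairs`` (default: levels of factor_a compared within each
        level of factor_b).  The omnibus statistic reported is the
        interaction F.
    """
    if method == "anova2_sidak":
        return _anova2_sidak(design, pairs)
    gd = _as_group_dict(groups)
    if len(gd) < 2:
        raise InvalidArgumentError("need at least 2 groups")
    for g, v in gd.items():
        if v.size < 2:
            raise InvalidArgumentError(f"group {g!r} has fewer than 2 observations")
    arrays = list(gd.values())
    names = list(gd)
    n_per = {g: int(v.size) for g, v in gd.items()}
    if method == "kruskal_dunn":
        stat, p = sps.kruskal(*arrays)
        post = dunn_posthoc(gd)
        return TestResult("kruskal_dunn", float(stat), float(p), n_per, tuple(post))
    if method == "anova_dunnett":
        stat, p = sps.f_oneway(*arrays)
        ref = reference if reference is not None else names[0]
        if ref not in gd:
            raise InvalidArgumentError(f"reference group {ref!r} not among groups")
        treat_names = [g for g in names if g != ref]
        res = sps.dunnett(*[gd[g] for g in treat_names], control=gd[ref])
        post = tuple(
            PosthocComparison(pair=(g, ref), statistic=float(s), p_raw=float(pv), p_adj=float(pv))
            for g, s, pv in zip(treat_names, np.atleast_1d(res.statistic), np.atleast_1d(res.pvalue))
        )
        return TestResult("anova_dunnett", float(stat), float(p), n_per, post)
    raise InvalidArgumentError(f"unknown multi-group method {method!r}")


def _anova2_sidak(design: pd.DataFrame | None, pairs: list[tuple] | None) -> TestResult:
    if design is None or not {"value", "factor_a", "factor_b"}.issubset(design.columns):
        raise InvalidArgumentError("anova2_sidak needs a design frame with value, factor_a, factor_b")
    cells = design.groupby(["factor_a", "factor_b"])["value"]
    sizes = cells.size()
    if (sizes < 2).any():
        bad = sizes[sizes < 2].index.tolist()
        raise InvalidArgumentError(f"degenerate cells with < 2 observations: {bad}")
    model = smf.ols("value ~ C(factor_a) * C(factor_b)", data=design).fit()
    table = sm.stats.anova_lm(model, typ=2)
    f_inter = float(table.loc["C(factor_a):C(factor_b)", "F"])
    p_inter = float(table.loc["C(factor_a):C(factor_b)", "PR(>F)"])
    mse = float(model.mse_resid)
    dof = float(model.df_resid)
    means = cells.mean()
    if pairs is None:
        a_levels = sorted(design["factor_a"].unique())
        b_levels = sorted(design["factor_b"].unique())
        if len(a_levels) != 2:
            raise InvalidArgumentError("default pairs need exactly 2 levels of factor_a")
        pairs = [((a_levels[0], b), (a_levels[1], b)) for b in b_levels]
    praw, stats, names = [], [], []
    for c1, c2 in pairs:
        se = np.sqrt(mse * (1.0 / sizes[c1] + 1.0 / sizes[c2]))
        tstat = (means[c1] - means[c2]) / se
        praw.append(2.0 * sps.t.sf(abs(tstat), dof))
        stats.append(float(tstat))
        names.append((str(c1), str(c2)))
    padj = sidak_adjust(np.array(praw))
    post = tuple(
        PosthocComparison(pair=nm, statistic=s, p_raw=float(pr), p_adj=float(min(1.0, pa)))
        for nm, s, pr, pa in zip(names, stats, praw, padj)
    )
    n_per = {f"{a}|{b}": int(n) for (a, b), n in sizes.items()}
    return TestResult("anova2_sidak", f_inter, p_inter, n_per, post)


# ---------------------------------------------------------------------------
# categorical
# ---------------------------------------------------------------------------

def compare_categorical(table) -> TestResult:
    """Fisher's exact test on a 2x2 count table (two-sided, point-mass rule)."""
    tab = np.asarray(table)
    if tab.shape != (2, 2):
        raise InvalidArgumentError("Fisher's exact test needs a 2x2 table")
    if np.any(tab < 0) or not np.issubdtype(tab.dtype, np.integer):
        tab_int = tab.astype(int)
        if np.any(tab_int != tab) or np.any(tab_int < 0):
            raise InvalidArgumentError("counts must be non-negative integers")
        tab = tab_int
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise InvalidArgumentError("table has an empty margin")
    odds, p = sps.fisher_exact(tab, alternative="two-sided")
    return TestResult(
        "fisher_exact",
        float(odds),
        float(p),
        n_per_group={"row0": int(tab[0].sum()), "row1": int(tab[1].sum())},
    )
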