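"""Normality-gated statistical testing and EM morphometry summaries.

Decision logic: when the total sample size n exceeds 100 or the number of
independent experiments N exceeds 5, each group is screened with the
D'Agostino-Pearson K^2 normality test; if any group rejects normality
(p < alpha) the comparison routes to the non-parametric branch.  The
concrete test then follows the design: unpaired two-tailed t-test vs
Mann-Whitney for two groups, one-sample t vs one-sample Wilcoxon for
values normalized to a reference, one-way ANOVA + Tukey HSD vs
Kruskal-Wallis + Dunn's multiple comparisons for three or more groups.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "Branch", "TestKind", "TestPlan", "StatResult",
    "normality_gate", "compare_groups", "mannwhitney_exact_oracle",
    "dunn_test", "density_per_area", "DensitySummary",
]


class Branch(str, enum.Enum):
    PARAMETRIC = "parametric"
    NONPARAMETRIC = "nonparametric"


class TestKind(str, enum.Enum):
    T_UNPAIRED = "t_unpaired"
    MANN_WHITNEY = "mann_whitney"
    ONE_SAMPLE_T = "one_sample_t"
    ONE_SAMPLE_WILCOXON = "one_sample_wilcoxon"
    ANOVA_TUKEY = "anova_tukey"
    KRUSKAL_DUNN = "kruskal_dunn"


@dataclass
class TestPlan:
    branch: Branch
    test: TestKind
    gate_applied: bool
    normality_p: dict[str, float] = field(default_factory=dict)
    gate_skipped_reason: str = ""


@dataclass
class StatResult:
    test: TestKind
    statistic: float
    p_value: float
    group_labels: list[str]
    n_per_group: list[int]
    posthoc: pd.DataFrame | None = None   # pair, statistic, p, p_adj
    plan: TestPlan | None = None

    def summary(self) -> str:
        lines = [f"{self.test.value}: statistic={self.statistic:.4g}, "
                 f"p={self.p_value:.4g}",
                 "groups: " + ", ".join(
                     f"{l} (n={n})" for l, n in
                     zip(self.group_labels, self.n_per_group))]
        if self.plan is not None:
            lines.append(f"branch={self.plan.branch.value}, "
                         f"gate_applied={self.plan.gate_applied}")
        if self.posthoc is not None:
            lines.append(self.posthoc.to_string(index=False))
        return "\n".join(lines)


def _as_groups(groups) -> dict[str, np.ndarray]:
    if isinstance(groups, Mapping):
        out = {str(k): np.asarray(v, dtype=float) for k, v in groups.items()}
    else:
        out = {f"group{i}": np.asarray(g, dtype=float)
               for i, g in enumerate(groups)}
    for k, v in out.items():
        if v.ndim != 1 or len(v) == 0:
            raise ValueError(f"group {k!r} must be a non-empty 1-D array")
    return out


# ---------------------------------------------------------------------------
# normality gate
# ---------------------------------------------------------------------------

GATE_N_TOTAL = 100     # gate applies when total n exceeds this ...
GATE_N_EXPERIMENTS = 5  # ... or the number of independent experiments this
MIN_NORMALITY_N = 8    # validity floor of the K^2 test per group


def normality_gate(groups,
                   n_total: int | None = None,
                   n_experiments: int | None = None,
                   alpha_normality: float = 0.05,
                   design: str | None = None) -> TestPlan:
    """Choose the statistical branch and concrete test.

    ``design`` is "two_group", "one_sample" or "multi_group"; inferred from
    the group count when omitted (one group implies a one-sample design
    against a normalization reference).  Any group with K^2 p < alpha
    routes the comparison to the non-parametric branch.
    """
    gs = _as_groups(groups)
    if design is None:
        design = {1: "one_sample", 2: "two_group"}.get(len(gs), "multi_group")
    if design == "multi_group" and len(gs) < 3:
        raise ValueError("multi_group design needs >= 3 groups")
    if design == "one_sample" and len(gs) != 1:
        raise ValueError("one_sample design takes exactly one group")

    if n_total is None:
        n_total = sum(len(v) for v in gs.values())
    applies = n_total > GATE_N_TOTAL or (
        n_experiments is not None and n_experiments > GATE_N_EXPERIMENTS)

    normality_p: dict[str, float] = {}
    skipped = ""
    branch = Branch.PARAMETRIC
    if applies:
        small = [k for k, v in gs.items() if len(v) < MIN_NORMALITY_N]
        if small:
            applies = False
            skipped = (f"groups below the {MIN_NORMALITY_N}-sample floor for "
                       f"the K^2 test: {', '.join(small)}")
        else:
            for k, v in gs.items():
                normality_p[k] = float(sps.normaltest(v).pvalue)
            if any(p < alpha_normality for p in normality_p.values()):
                branch = Branch.NONPARAMETRIC

    table = {
        ("two_group", Branch.PARAMETRIC): TestKind.T_UNPAIRED,
        ("two_group", Branch.NONPARAMETRIC): TestKind.MANN_WHITNEY,
        ("one_sample", Branch.PARAMETRIC): TestKind.ONE_SAMPLE_T,
        ("one_sample", Branch.NONPARAMETRIC): TestKind.ONE_SAMPLE_WILCOXON,
        ("multi_group", Branch.PARAMETRIC): TestKind.ANOVA_TUKEY,
        ("multi_group", Branch.NONPARAMETRIC): TestKind.KRUSKAL_DUNN,
    }
    return TestPlan(branch=branch, test=table[(design, branch)],
                    gate_applied=applies, normality_p=normality_p,
                    gate_skipped_reason=skipped)


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

def _mannwhitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return float(len(a) * len(b) / 2.0), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(a) * len(b) <= 400 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def compare_groups(groups,
                   plan: TestPlan,
                   reference_value: float | None = None) -> StatResult:
    """Execute the planned test; post-hoc tables for >= 3 groups.

    One-sample tests require ``reference_value`` (the normalization
    reference, typically 100 or 1).
    """
    gs = _as_groups(groups)
    labels = list(gs)
    arrays = [gs[k] for k in labels]
    ns = [len(a) for a in arrays]
    posthoc = None

    if plan.test in (TestKind.T_UNPAIRED, TestKind.MANN_WHITNEY):
        if len(arrays) != 2:
            raise ValueError("two-group test needs exactly two groups")
        a, b = arrays
        if plan.test is TestKind.T_UNPAIRED:
            res = sps.ttest_ind(a, b)
            stat, p = float(res.statistic), float(res.pvalue)
        else:
            stat, p = _mannwhitney(a, b)
    elif plan.test in (TestKind.ONE_SAMPLE_T, TestKind.ONE_SAMPLE_WILCOXON):
        if len(arrays) != 1:
            raise ValueError("one-sample test takes exactly one group")
        if reference_value is None:
            raise ValueError("one-sample test needs a reference_value")
        (a,) = arrays
        if plan.test is TestKind.ONE_SAMPLE_T:
            res = sps.ttest_1samp(a, reference_value)
            stat, p = float(res.statistic), float(res.pvalue)
        else:
            d = a - reference_value
            if np.all(d == 0):
                raise ValueError("all values equal the reference; "
                                 "rank test undefined")
            res = sps.wilcoxon(d)
            stat, p = float(res.statistic), float(res.pvalue)
    elif plan.test is TestKind.ANOVA_TUKEY:
        if len(arrays) < 3:
            raise ValueError("ANOVA branch needs >= 3 groups")
        if all(np.ptp(a) == 0 for a in arrays) and np.ptp(
                np.concatenate(arrays)) == 0:
            raise ValueError("all groups identical and constant; "
                             "ANOVA undefined")
        res = sps.f_oneway(*arrays)
        stat, p = float(res.statistic), float(res.pvalue)
        tk = sps.tukey_hsd(*arrays)
        rows = []
        for i, j in itertools.combinations(range(len(arrays)), 2):
            t_unadj = float(sps.ttest_ind(arrays[i], arrays[j]).pvalue)
            rows.append((f"{labels[i]} vs {labels[j]}",
                         float(tk.statistic[i, j]), t_unadj,
                         float(tk.pvalue[i, j])))
        posthoc = pd.DataFrame(rows, columns=["pair", "statistic",
                                              "p_unadjusted", "p_adjusted"])
    elif plan.test is TestKind.KRUSKAL_DUNN:
        if len(arrays) < 3:
            raise ValueError("Kruskal-Wallis branch needs >= 3 groups")
        if np.ptp(np.concatenate(arrays)) == 0:
            raise ValueError("tied-only data; rank test undefined")
        res = sps.kruskal(*arrays)
        stat, p = float(res.statistic), float(res.pvalue)
        posthoc = dunn_test(dict(zip(labels, arrays)))
    else:  # pragma: no cover
        raise ValueError(f"unknown test {plan.test}")

    return StatResult(test=plan.test, statistic=stat, p_value=p,
                      group_labels=labels, n_per_group=ns,
                      posthoc=posthoc, plan=plan)


def dunn_test(groups: Mapping[str, np.ndarray],
              p_adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's rank-based multiple comparisons after Kruskal-Wallis.

    z_ij = (Rbar_i - Rbar_j) / sqrt([N(N+1)/12 - T] (1/n_i + 1/n_j)) with
    the tie correction T = sum(t^3 - t) / [12 (N - 1)]; two-sided normal
    p-values, Bonferroni-adjusted over all pairs by default.
    """
    labels = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    pooled = np.concatenate(arrays)
    n_tot = len(pooled)
    ranks = sps.rankdata(pooled)
    # mean rank per group
    splits = np.cumsum([len(a) for a in arrays])[:-1]
    mean_ranks = [r.mean() for r in np.split(ranks, splits)]
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_tot - 1))
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_term

    pairs = list(itertools.combinations(range(len(arrays)), 2))
    rows = []
    for i, j in pairs:
        se = math.sqrt(var_base * (1.0 / len(arrays[i]) + 1.0 / len(arrays[j])))
        if se == 0:
            raise ValueError("zero variance in Dunn comparison (all ties)")
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append([f"{labels[i]} vs {labels[j]}", z, p])
    df = pd.DataFrame(rows, columns=["pair", "statistic", "p_unadjusted"])
    if p_adjust == "bonferroni":
        df["p_adjusted"] = np.minimum(df["p_unadjusted"] * len(pairs), 1.0)
    elif p_adjust == "none":
        df["p_adjusted"] = df["p_unadjusted"]
    else:
        raise ValueError(f"unknown p_adjust {p_adjust!r}")
    return df


def mannwhitney_exact_oracle(group_a, group_b) -> float:
    """Exact two-sided Mann-Whitney p by exhaustive enumeration.

    Enumerates all C(n_a + n_b, n_a) assignments of the pooled values and
    returns the probability of a U at least as extreme (min of the two
    one-sided tails, doubled, capped at 1).  Test oracle only; capped at
    n_a + n_b <= 12.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    n_a, n_b = len(a), len(b)
    if n_a + n_b > 12:
        raise ValueError("enumeration oracle capped at n_a + n_b <= 12")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)

    def u_stat(idx_a: tuple[int, ...]) -> float:
        ra = ranks[list(idx_a)].sum()
        return ra - n_a * (n_a + 1) / 2.0

    u_obs = u_stat(tuple(range(n_a)))
    us = np.array([u_stat(c) for c in
                   itertools.combinations(range(n_a + n_b), n_a)])
    mean_u = n_a * n_b / 2.0
    # two-sided: mass at least as far from the mean as observed
    p = float(np.mean(np.abs(us - mean_u) >= abs(u_obs - mean_u) - 1e-12))
    return min(p, 1.0)


# ---------------------------------------------------------------------------
# morphometry summaries
# ---------------------------------------------------------------------------

@dataclass
class DensitySummary:
    structure: str
    densities: pd.Series       # per synapse, count/um^2
    mean: float
    sem: float
    n: int
    rejected: pd.DataFrame     # records with non-positive area


def density_per_area(records: pd.DataFrame, structure: str) -> DensitySummary:
    """Per-synapse structure density (count/um^2) with mean +- SEM.

    Records need columns ``bouton_area`` and ``structure``; rows with
    non-positive area are rejected and reported, not silently dropped.
    """
    if structure not in records.columns:
        raise KeyError(f"structure {structure!r} not in records")
    if "bouton_area" not in records.columns:
        raise KeyError("records need a bouton_area column")
    bad = records[records["bouton_area"] <= 0]
    good = records[records["bouton_area"] > 0]
    if len(good) == 0:
        raise ValueError("no records with positive bouton area")
    dens = good[structure] / good["bouton_area"]
    n = len(dens)
    sem = float(dens.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return DensitySummary(structure=structure, densities=dens,
                          mean=float(dens.mean()), sem=sem, n=n,
                          rejected=bad)
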