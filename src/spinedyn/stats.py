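"""Normality-routed statistical tests and Bonferroni reporting.

Each comparison first checks every group with the Shapiro–Wilk test; if
all groups are consistent with normality at alpha = 0.05 the parametric
branch is used (Student's t, one-sample t, repeated-measures ANOVA with
Bonferroni post hoc), otherwise the rank-based branch (Mann–Whitney,
Wilcoxon signed-rank, Friedman with Dunn's post hoc).  The routing
decision, the per-group normality p-values and any post hoc comparisons
are all reported so downstream tables are self-describing.

Test kernels are delegated to scipy / statsmodels; this module owns the
routing, the pairing structure (each post-deprivation session against the
pooled baseline), and the reporting contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.anova import AnovaRM

__all__ = ["StatResult", "route_test", "bonferroni", "DESIGNS"]

DESIGNS = (
    "two_group", "one_sample_vs_1", "repeated_oneway", "repeated_twoway",
    "paired_nonparam",
)


@dataclass
class StatResult:
    test_name: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    direction: str = ""
    post_hoc: list[tuple[str, float]] = field(default_factory=list)
    alpha: float = 0.05
    normality_p: tuple[float, ...] = ()
    parametric: bool = True

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def to_row(self) -> dict:
        return dict(
            test=self.test_name, statistic=self.statistic, p=self.p_value,
            n="/".join(str(k) for k in self.n), direction=self.direction,
            parametric=self.parametric,
        )


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: ``min(1, p * m)`` for m comparisons."""
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    m = len(p) if m is None else int(m)
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(1.0, p * m)


def _shapiro_all(groups, alpha: float) -> tuple[bool, tuple[float, ...]]:
    ps = []
    for g in groups:
        g = np.asarray(g, dtype=float)
        g = g[np.isfinite(g)]
        if len(g) < 3:
            raise ValueError("each group needs >= 3 values for normality testing")
        if np.ptp(g) == 0:
            ps.append(1.0)  # constant group: treat as compatible with normality
        else:
            ps.append(float(sps.shapiro(g).pvalue))
    return all(p >= alpha for p in ps), tuple(ps)


def _direction(a: float, b: float) -> str:
    if a > b:
        return "greater"
    if a < b:
        return "less"
    return "equal"


def _dunn_repeated(data: np.ndarray, labels, pairs) -> list[tuple[str, float]]:
    """Dunn's post hoc on within-subject Friedman ranks.

    z = (Ri - Rj) / sqrt(k(k+1) / (6 n)) on mean ranks, Bonferroni over
    the requested pairs.
    """
    n, k = data.shape
    ranks = sps.rankdata(data, axis=1)
    mean_ranks = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    raw = []
    for i, j in pairs:
        z = abs(mean_ranks[i] - mean_ranks[j]) / se
        raw.append(2.0 * sps.norm.sf(z))
    adj = bonferroni(raw, len(pairs))
    return [(f"{labels[i]} vs {labels[j]}", float(p))
            for (i, j), p in zip(pairs, adj)]


def route_test(groups, design: str, *, alpha: float = 0.05,
               labels: tuple[str, ...] | None = None,
               baseline_cols: tuple[int, ...] = (),
               ) -> StatResult:
    """Run the comparison the design calls for, routed by normality.

    ``groups`` depends on the design:

    - ``two_group``: two independent 1-D samples.
    - ``one_sample_vs_1``: one 1-D sample of ratios compared against 1.
    - ``repeated_oneway``: (n_units, n_conditions) matrix, each row one
      unit measured at every condition.  ``baseline_cols`` names the
      columns pooled into the baseline; post hoc compares every other
      column to that pooled baseline.
    - ``repeated_twoway``: (n_units, n_levels_a, n_levels_b) array of two
      within-unit factors.
    - ``paired_nonparam``: two paired 1-D samples, rank test regardless
      of normality.
    """
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}; valid: {DESIGNS}")

    if design == "two_group":
        a, b = (np.asarray(g, dtype=float) for g in groups)
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        normal, norm_ps = _shapiro_all([a, b], alpha)
        if normal:
            if np.ptp(a) == 0 and np.ptp(b) == 0:
                eq = a[0] == b[0]
                stat = 0.0 if eq else np.inf * np.sign(a[0] - b[0])
                p = 1.0 if eq else 0.0
            else:
                stat, p = sps.ttest_ind(a, b)
            name = "Student's t-test"
        else:
            stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
            name = "Mann-Whitney U"
        return StatResult(name, float(stat), float(p), (len(a), len(b)),
                          _direction(np.mean(a), np.mean(b)),
                          alpha=alpha, normality_p=norm_ps, parametric=normal)

    if design == "one_sample_vs_1":
        x = np.asarray(groups, dtype=float)
        x = x[np.isfinite(x)]
        normal, norm_ps = _shapiro_all([x], alpha)
        if normal:
            if np.ptp(x) == 0:
                # degenerate constant sample: zero deviation -> t = 0 when
                # the sample sits exactly at 1, infinite otherwise
                stat = 0.0 if x[0] == 1.0 else np.inf * np.sign(x[0] - 1.0)
                p = 1.0 if x[0] == 1.0 else 0.0
            else:
                stat, p = sps.ttest_1samp(x, 1.0)
            name = "one-sample t-test vs 1"
        else:
            if np.allclose(x, 1.0):
                stat, p = 0.0, 1.0
            else:
                stat, p = sps.wilcoxon(x - 1.0)
            name = "Wilcoxon signed-rank vs 1"
        return StatResult(name, float(stat), float(p), (len(x),),
                          _direction(float(np.mean(x)), 1.0),
                          alpha=alpha, normality_p=norm_ps, parametric=normal)

    if design == "paired_nonparam":
        a, b = (np.asarray(g, dtype=float) for g in groups)
        ok = np.isfinite(a) & np.isfinite(b)
        a, b = a[ok], b[ok]
        if np.allclose(a, b):
            stat, p = 0.0, 1.0
        else:
            stat, p = sps.wilcoxon(a, b)
        return StatResult("Wilcoxon signed-rank (paired)", float(stat),
                          float(p), (len(a),),
                          _direction(float(np.mean(a)), float(np.mean(b))),
                          alpha=alpha, parametric=False)

    if design == "repeated_oneway":
        data = np.asarray(groups, dtype=float)
        if data.ndim != 2:
            raise ValueError("repeated_oneway expects an (n_units, k) matrix")
        data = data[np.isfinite(data).all(axis=1)]
        n, k = data.shape
        if n < 2 or k < 2:
            raise ValueError("need >= 2 complete units and >= 2 conditions")
        labels = labels or tuple(f"c{i}" for i in range(k))
        normal, norm_ps = _shapiro_all([data[:, j] for j in range(k)], alpha)
        base = list(baseline_cols)
        others = [j for j in range(k) if j not in base]
        if normal:
            long = pd.DataFrame({
                "unit": np.repeat(np.arange(n), k),
                "cond": np.tile(np.arange(k), n),
                "value": data.ravel(),
            })
            res = AnovaRM(long, "value", "unit", within=["cond"]).fit()
            stat = float(res.anova_table["F Value"].iloc[0])
            p = float(res.anova_table["Pr > F"].iloc[0])
            name = "repeated-measures one-way ANOVA"
            post = []
            if base and others:
                pooled = data[:, base].mean(axis=1)
                raw = []
                for j in others:
                    d = data[:, j] - pooled
                    if np.allclose(d, 0):
                        raw.append(1.0)
                    else:
                        raw.append(float(sps.ttest_rel(data[:, j], pooled).pvalue))
                adj = bonferroni(raw, len(others))
                post = [(f"{labels[j]} vs baseline", float(q))
                        for j, q in zip(others, adj)]
        else:
            stat, p = sps.friedmanchisquare(*[data[:, j] for j in range(k)])
            name = "Friedman test"
            post = []
            if base and others:
                pooled = data[:, base].mean(axis=1, keepdims=True)
                aug = np.concatenate([pooled, data[:, others]], axis=1)
                aug_labels = ["baseline"] + [labels[j] for j in others]
                pairs = [(j + 1, 0) for j in range(len(others))]
                post = _dunn_repeated(aug, aug_labels, pairs)
            name = "Friedman test (Dunn post hoc)" if post else name
        return StatResult(name, float(stat), float(p), (n,) * k, "",
                          post_hoc=post, alpha=alpha, normality_p=norm_ps,
                          parametric=normal)

    # repeated_twoway
    data = np.asarray(groups, dtype=float)
    if data.ndim != 3:
        raise ValueError("repeated_twoway expects (n_units, a, b) data")
    data = data[np.isfinite(data).reshape(len(data), -1).all(axis=1)]
    n, ka, kb = data.shape
    if n < 2:
        raise ValueError("need >= 2 complete units")
    long = pd.DataFrame({
        "unit": np.repeat(np.arange(n), ka * kb),
        "A": np.tile(np.repeat(np.arange(ka), kb), n),
        "B": np.tile(np.arange(kb), n * ka),
        "value": data.ravel(),
    })
    res = AnovaRM(long, "value", "unit", within=["A", "B"]).fit()
    tab = res.anova_table
    stat = float(tab["F Value"].iloc[-1])   # interaction term
    p = float(tab["Pr > F"].iloc[-1])
    post = [(f"main {idx}", float(row["Pr > F"]))
            for idx, row in tab.iloc[:-1].iterrows()]
    return StatResult("repeated-measures two-way ANOVA (interaction)",
                      stat, p, (n, ka, kb), "", post_hoc=post, alpha=alpha,
                      parametric=True)
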