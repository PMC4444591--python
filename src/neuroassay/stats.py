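"""Group summaries (mean ± SEM) and ANOVA across experimental groups.

One-way fixed-effects ANOVA is used for single-factor designs (with two
groups it reduces exactly to the square of the equal-variance two-sample t
statistic); two-factor designs (e.g. treatment × day) go through an ordinary
least-squares fit with a type-II decomposition.  The end-to-end report
compares every metric across scenarios against the sham and hypoxia
reference groups, with Holm correction over the pairwise comparisons of each
metric.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05  # significance level used throughout


@dataclass
class GroupSummary:
    """Per-group descriptive statistics: mean ± SEM over replicates."""

    group: str
    metric: str
    n: int
    mean: float
    sem: float | None
    values: list

    @classmethod
    def from_values(cls, group, metric, values) -> "GroupSummary":
        v = np.asarray(values, dtype=float)
        if v.size == 0:
            raise ValueError(f"group {group!r} is empty")
        sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else None
        return cls(
            group=str(group),
            metric=str(metric),
            n=int(v.size),
            mean=float(v.mean()),
            sem=sem,
            values=[float(x) for x in v],
        )


def summarize(groups: dict, metric: str = "") -> list:
    """Mean ± SEM per group; ``groups`` maps labels to replicate values."""
    return [GroupSummary.from_values(g, metric, v) for g, v in groups.items()]


@dataclass
class AnovaResult:
    F: float
    p: float
    df_effect: float
    df_resid: float

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


def anova(groups, factors: int = 1, response: str = "value") -> "AnovaResult | dict":
    """Fixed-effects ANOVA over experimental groups.

    With ``factors=1``, ``groups`` is a dict (or sequence) of per-group value
    arrays; the result is a single :class:`AnovaResult`.  With ``factors=2``,
    ``groups`` is a DataFrame with columns ``factor_a``, ``factor_b`` and
    ``response``; the result is a dict of term name -> :class:`AnovaResult`
    (main effects and interaction, type-II sums of squares).
    """
    if factors == 1:
        vals = list(groups.values()) if isinstance(groups, dict) else list(groups)
        if len(vals) < 2:
            raise ValueError("one-way ANOVA needs at least 2 groups")
        arrs = [np.asarray(v, dtype=float) for v in vals]
        if any(a.size < 2 for a in arrs):
            raise ValueError("each group needs at least 2 observations")
        res = sps.f_oneway(*arrs)
        k = len(arrs)
        n = sum(a.size for a in arrs)
        F = float(res.statistic)
        p = float(res.pvalue)
        if np.isnan(F):  # all observations identical: no variance at all
            F, p = 0.0, 1.0
        return AnovaResult(F=F, p=p, df_effect=k - 1, df_resid=n - k)
    if factors == 2:
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        df = pd.DataFrame(groups)
        for col in ("factor_a", "factor_b", response):
            if col not in df:
                raise ValueError(f"two-way ANOVA input needs a {col!r} column")
        cell_sizes = df.groupby(["factor_a", "factor_b"]).size()
        if (cell_sizes < 1).any():
            raise ValueError("degenerate design: empty factor cell")
        model = smf.ols(f"{response} ~ C(factor_a) * C(factor_b)", data=df).fit()
        table = sm.stats.anova_lm(model, typ=2)
        out = {}
        df_resid = float(table.loc["Residual", "df"])
        for term in table.index:
            if term == "Residual":
                continue
            key = (
                term.replace("C(factor_a)", "factor_a")
                .replace("C(factor_b)", "factor_b")
            )
            out[key] = AnovaResult(
                F=float(table.loc[term, "F"]),
                p=float(table.loc[term, "PR(>F)"]),
                df_effect=float(table.loc[term, "df"]),
                df_resid=df_resid,
            )
        return out
    raise ValueError("factors must be 1 or 2")


def holm_correction(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def build_report(
    scenario_metrics: dict,
    baseline: str = "sham",
    secondary: str = "hypoxia",
) -> dict:
    """Comparison table of all metrics across all scenario outputs.

    ``scenario_metrics`` maps scenario name -> {metric name -> per-replicate
    values}.  Every scenario must provide the same metric set.  For each
    metric, each non-reference group is compared with the ``baseline`` (flag
    ``vs_sham``) and with ``secondary`` (flag ``vs_hypoxia``) by two-group
    ANOVA, Holm-corrected over the comparisons belonging to that metric.
    Returns a JSON-serializable dict.
    """
    scenarios = list(scenario_metrics)
    if len(scenarios) < 2:
        raise ValueError("need at least 2 scenario outputs")
    metric_sets = {s: set(m) for s, m in scenario_metrics.items()}
    ref = metric_sets[scenarios[0]]
    for s, mset in metric_sets.items():
        if mset != ref:
            raise ValueError(f"scenario {s!r} has a mismatched metric set")
    metrics = sorted(ref)
    report = {"groups": scenarios, "baseline": baseline, "metrics": {}}
    for metric in metrics:
        entry = {"summary": {}, "comparisons": []}
        for s in scenarios:
            gs = GroupSummary.from_values(s, metric, scenario_metrics[s][metric])
            entry["summary"][s] = {"n": gs.n, "mean": gs.mean, "sem": gs.sem}
        comps = []
        for refname, flag in ((baseline, "vs_" + str(baseline)),
                              (secondary, "vs_" + str(secondary))):
            if refname not in scenario_metrics:
                continue
            for s in scenarios:
                if s == refname:
                    continue
                a = np.asarray(scenario_metrics[s][metric], dtype=float)
                b = np.asarray(scenario_metrics[refname][metric], dtype=float)
                if a.size < 2 or b.size < 2:
                    continue
                res = anova([a, b])
                comps.append({"group": s, "reference": refname, "flag": flag,
                              "F": res.F, "p": res.p})
        if comps:
            adj = holm_correction([c["p"] for c in comps])
            for c, pa in zip(comps, adj):
                c["p_holm"] = float(pa)
                c["significant"] = bool(pa < ALPHA)
        entry["comparisons"] = comps
        report["metrics"][metric] = entry
    return report


def format_report_table(report: dict) -> str:
    """Human-readable table: metric x group, mean ± SEM with significance flags."""
    groups = report["groups"]
    base = report["baseline"]
    lines = []
    header = f"{'metric':<28}" + "".join(f"{g:>24}" for g in groups)
    lines.append(header)
    lines.append("-" * len(header))
    for metric, entry in report["metrics"].items():
        row = f"{metric:<28}"
        for g in groups:
            s = entry["summary"][g]
            cell = f"{s['mean']:.3g}"
            if s["sem"] is not None:
                cell += f" ± {s['sem']:.2g}"
            flags = "".join(
                ("*" if c["flag"].endswith(str(base)) else "#")
                for c in entry["comparisons"]
                if c["group"] == g and c.get("significant")
            )
            row += f"{cell + flags:>24}"
        lines.append(row)
    lines.append("")
    lines.append(f"*: p<{ALPHA} vs {base} (Holm-corrected two-group ANOVA); "
                 "#: vs the secondary reference")
    return "\n".join(lines)


def save_report(report: dict, path) -> None:
    with open(path, "w") as f:
        json.dump(report, f, indent=2)


def load_report(path) -> dict:
    with open(path) as f:
        return json.load(f)
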