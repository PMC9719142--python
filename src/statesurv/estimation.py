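"""Design-based prevalence estimation, source comparisons, and report tables.

Point estimates are weighted proportions on the percent scale. Standard
errors come from Taylor linearization of the ratio estimator under a
with-replacement stratified cluster design: survey sources use their
(stratum, PSU) identifiers, the EHR uses state as stratum and county as
cluster so the geographic weights enter the variance. 95 % confidence
intervals are symmetric and then truncated to [0, 100]. Cross-source
differences use t = (p1 - p2) / sqrt(SE1^2 + SE2^2) with a normal reference
by default, flagged at alpha = 0.01 in the report with up/down arrow tokens
(doubled when a source differs from both comparators).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .impute import rubin_combine

Z95 = 1.959963984540054

FLAG_TOKENS = {"none": "", "up": "↑", "up2": "↑↑", "down": "↓", "down2": "↓↓",
               "mixed": "↕"}


@dataclass
class PrevalenceEstimate:
    """Weighted prevalence with design-based uncertainty (percent scale)."""

    measure: str
    state: str
    source: str
    point: float          # percent
    se: float             # percent
    ci_low: float
    ci_high: float
    n: int
    weighted_n: float
    denominator: str = ""
    defined: bool = True

    @property
    def variance(self) -> float:
        return self.se ** 2


def weighted_prevalence(df: pd.DataFrame, y: str = "y", weight: str = "weight",
                        stratum: str = "stratum", psu: str = "psu",
                        measure: str = "", state: str = "", source: str = "",
                        denominator: str = "") -> PrevalenceEstimate:
    """Estimate a weighted proportion with a linearized SE.

    ``df`` must already be restricted to the denominator population; ``y``
    is a 0/1 indicator defined for every row. Strata containing a single
    cluster contribute nothing to the variance. An empty or zero-weight
    denominator yields an undefined estimate (``defined=False``).
    """
    if not len(df) or df[weight].sum() <= 0:
        return PrevalenceEstimate(measure, state, source, math.nan, math.nan,
                                  math.nan, math.nan, 0, 0.0, denominator, False)
    w = df[weight].to_numpy(dtype=float)
    yv = df[y].to_numpy(dtype=float)
    if np.isnan(yv).any():
        raise ValueError("indicator contains missing values inside the denominator")
    wsum = w.sum()
    p = float(np.dot(w, yv) / wsum)
    u = w * (yv - p) / wsum
    g = pd.DataFrame({"stratum": df[stratum].to_numpy(),
                      "psu": df[psu].to_numpy(), "u": u})
    psu_tot = g.groupby(["stratum", "psu"], observed=True)["u"].sum()
    var = 0.0
    for _, t in psu_tot.groupby(level="stratum", observed=True):
        n_h = len(t)
        if n_h < 2:
            continue
        var += n_h / (n_h - 1) * float(((t - t.mean()) ** 2).sum())
    se = math.sqrt(var) * 100.0
    point = p * 100.0
    lo = max(0.0, point - Z95 * se)
    hi = min(100.0, point + Z95 * se)
    return PrevalenceEstimate(measure, state, source, point, se, lo, hi,
                              len(df), float(wsum), denominator, True)


def combine_mi_estimates(estimates: list[PrevalenceEstimate]) -> PrevalenceEstimate:
    """Rubin-combine per-completion estimates of the same quantity."""
    defined = [e for e in estimates if e.defined]
    if not defined:
        return estimates[0]
    comb = rubin_combine(np.array([e.point for e in defined]),
                         np.array([e.se ** 2 for e in defined]))
    se = math.sqrt(comb["variance"])
    point = comb["point"]
    return replace(defined[0], point=point, se=se,
                   ci_low=max(0.0, point - Z95 * se),
                   ci_high=min(100.0, point + Z95 * se))


@dataclass
class ComparisonResult:
    measure: str
    state: str
    source_1: str
    source_2: str
    difference: float   # percentage points, source_1 - source_2
    t: float
    p_value: float
    significant: bool


def compare_sources(e1: PrevalenceEstimate, e2: PrevalenceEstimate,
                    alpha: float = 0.01, df: float | None = None) -> ComparisonResult:
    """Two-sided test of equality of two independent source estimates.

    Uses a normal reference by default; pass ``df`` for a Satterthwaite-style
    t reference. Two exactly equal, zero-variance estimates compare as t=0.
    """
    if e1.measure != e2.measure or e1.state != e2.state:
        raise ValueError("can only compare estimates of the same measure and state")
    diff = e1.point - e2.point
    denom = math.sqrt(e1.se ** 2 + e2.se ** 2)
    if denom == 0:
        t = 0.0 if diff == 0 else math.inf * np.sign(diff)
    else:
        t = diff / denom
    if not math.isfinite(t):
        p = 0.0
    elif df is None:
        p = 2.0 * stats.norm.sf(abs(t))
    else:
        p = 2.0 * stats.t.sf(abs(t), df)
    return ComparisonResult(e1.measure, e1.state, e1.source, e2.source,
                            diff, t, p, bool(p < alpha))


def _flag(est: PrevalenceEstimate, others: list[PrevalenceEstimate],
          alpha: float) -> str:
    """Arrow token for one source against its comparators."""
    above = below = 0
    for o in others:
        if not (est.defined and o.defined):
            continue
        c = compare_sources(est, o, alpha=alpha)
        if c.significant:
            if c.difference > 0:
                above += 1
            else:
                below += 1
    if above and below:
        return "mixed"
    if above:
        return "up2" if above >= len(others) and len(others) > 1 else "up"
    if below:
        return "down2" if below >= len(others) and len(others) > 1 else "down"
    return "none"


PREVALENCE_MEASURES = ("diagnosed_diabetes", "undiagnosed_diabetes")
COMORBIDITY_MEASURES = ("high_cholesterol", "hypertension", "both", "neither")
CONTROL_MEASURES = ("a1c_control", "bp_control", "chol_control", "all_three")


def build_report(estimates: list[PrevalenceEstimate], alpha: float = 0.01,
                 completeness: pd.DataFrame | None = None) -> dict[str, pd.DataFrame]:
    """Assemble the three output tables (diabetes prevalence; comorbidity
    prevalence in the diabetes population; ABC control in the diagnosed
    population) with CI strings and significance arrow tokens, plus the
    tidy estimate table and all pairwise comparisons."""
    by_key: dict[tuple[str, str], list[PrevalenceEstimate]] = {}
    for e in estimates:
        by_key.setdefault((e.measure, e.state), []).append(e)

    rows, comp_rows = [], []
    for (measure, state), ests in sorted(by_key.items()):
        for e in ests:
            others = [o for o in ests if o.source != e.source]
            flag = _flag(e, others, alpha) if e.defined else "none"
            rows.append({
                "measure": measure, "state": state, "source": e.source,
                "pct": round(e.point, 1) if e.defined else None,
                "se": round(e.se, 2) if e.defined else None,
                "ci": (f"{e.ci_low:.1f}, {e.ci_high:.1f}" if e.defined else ""),
                "flag": flag, "arrow": FLAG_TOKENS[flag],
                "n": e.n, "weighted_n": e.weighted_n,
            })
        for i, e1 in enumerate(ests):
            for e2 in ests[i + 1:]:
                if e1.defined and e2.defined:
                    c = compare_sources(e1, e2, alpha=alpha)
                    comp_rows.append(vars(c))
    tidy = pd.DataFrame(rows)
    comparisons = pd.DataFrame(comp_rows)

    def _table(measures) -> pd.DataFrame:
        sub = tidy[tidy["measure"].isin(measures)]
        if not len(sub):
            return pd.DataFrame()
        t = sub.pivot_table(index=["state", "measure"], columns="source",
                            values="pct", aggfunc="first", observed=True)
        ci = sub.pivot_table(index=["state", "measure"], columns="source",
                             values="ci", aggfunc="first", observed=True)
        fl = sub.pivot_table(index=["state", "measure"], columns="source",
                             values="flag", aggfunc="first", observed=True)
        out = pd.concat({"pct": t, "ci": ci, "flag": fl}, axis=1)
        out.columns = [f"{src}_{kind}" for kind, src in out.columns]
        return out.reset_index()

    report = {
        "estimates": tidy,
        "comparisons": comparisons,
        "prevalence": _table(PREVALENCE_MEASURES),
        "comorbidity": _table(COMORBIDITY_MEASURES),
        "control": _table(CONTROL_MEASURES),
    }
    if completeness is not None:
        report["completeness"] = completeness
    return report


def report_markdown(report: dict[str, pd.DataFrame]) -> str:
    """Render the report tables as a markdown document."""
    titles = {
        "prevalence": "Diabetes prevalence by data source and state (%)",
        "comorbidity": "Hypertension and high cholesterol in the diabetes population (%)",
        "control": "ABC control in the diagnosed diabetes population (%)",
        "completeness": "Measurement completeness among diagnosed EHR patients",
    }
    parts = []
    for key, title in titles.items():
        df = report.get(key)
        if df is None or not len(df):
            continue
        parts.append(f"## {title}\n\n{df.to_markdown(index=False)}\n")
    return "\n".join(parts)


def bootstrap_se(df: pd.DataFrame, y: str = "y", weight: str = "weight",
                 stratum: str = "stratum", psu: str = "psu",
                 n_boot: int = 500, seed: int = 0) -> float:
    """With-replacement cluster bootstrap SE (percent scale) of the weighted
    proportion, resampling PSUs within strata. A cross-check on the
    linearization, not a production variance path."""
    rng = np.random.default_rng(seed)
    key = df[stratum].astype(str) + "||" + df[psu].astype(str)
    groups = {k: v.index.to_numpy() for k, v in df.groupby(key, observed=True)}
    strata: dict[str, list[str]] = {}
    for k in groups:
        strata.setdefault(k.split("||")[0], []).append(k)
    w = df[weight].to_numpy(dtype=float)
    yv = df[y].to_numpy(dtype=float)
    pos = {k: df.index.get_indexer(v) for k, v in groups.items()}
    stats_out = np.empty(n_boot)
    # Rao-Wu rescaling: draw n_h - 1 clusters with replacement per stratum
    # and scale by n_h/(n_h - 1), so the bootstrap variance is unbiased for
    # the with-replacement design variance.
    for b in range(n_boot):
        num = den = 0.0
        for h, psus in strata.items():
            n_h = len(psus)
            if n_h == 1:
                idx = pos[psus[0]]
                num += float(np.dot(w[idx], yv[idx]))
                den += float(w[idx].sum())
                continue
            scale = n_h / (n_h - 1)
            pick = rng.integers(0, n_h, n_h - 1)
            for j in pick:
                idx = pos[psus[j]]
                num += scale * float(np.dot(w[idx], yv[idx]))
                den += scale * float(w[idx].sum())
        stats_out[b] = num / den
    return float(stats_out.std(ddof=1) * 100.0)
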