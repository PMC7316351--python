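"""Condition-level statistics: NT vs PDS per cell line.

Per-nucleus densities of replisome-associated G4 structures are summarized as
mean ± SD (n−1 denominator), compared by an unpaired two-sample t-test
(Welch by default; the equal-variance Student variant is a flag), and the
treatment effect is reported as the ratio of condition means with the
first-order (delta-method) propagated standard error

    SEM(ratio) = ratio · sqrt((SEM_PDS/mean_PDS)² + (SEM_NT/mean_NT)²).

Cell lines are presented independently; absolute densities between cell lines
are not compared unless explicitly overridden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .associate import NucleusResult

__all__ = ["ConditionSummary", "FoldChangeResult", "summarize_condition",
           "fold_change", "ttest_nt_vs_pds", "summarize_cohort"]


@dataclass(frozen=True)
class ConditionSummary:
    cell_line: str
    condition: str
    n_nuclei: int
    mean_density: float
    sd: float
    sem: float


@dataclass(frozen=True)
class FoldChangeResult:
    cell_line: str
    ratio: float                 # PDS mean / NT mean
    propagated_sem: float
    p_value: float | None = None
    t_statistic: float | None = None
    df: float | None = None
    test_variant: str | None = None
    degenerate: bool = False


def _densities(results) -> tuple[np.ndarray, str, str]:
    if isinstance(results, pd.DataFrame):
        lines = set(results["cell_line"])
        conds = set(results["condition"])
        dens = results["density_per_um2"].to_numpy(float)
    else:
        results = list(results)
        lines = {r.cell_line for r in results}
        conds = {r.condition for r in results}
        dens = np.array([r.associated_g4_density for r in results], float)
    if len(lines) > 1 or len(conds) > 1:
        raise ValueError(
            f"mixed inputs: cell lines {sorted(lines)}, conditions {sorted(conds)}"
        )
    return dens, next(iter(lines), ""), next(iter(conds), "")


def summarize_condition(results) -> ConditionSummary:
    """Sample mean, SD (n−1) and SEM of per-nucleus densities.

    ``results`` is a list of NucleusResult or a per-nucleus DataFrame; all
    rows must share one cell line and one condition.
    """
    dens, line, cond = _densities(results)
    n = len(dens)
    if n < 2:
        raise ValueError(f"need >= 2 nuclei per condition, got {n}")
    sd = float(np.std(dens, ddof=1))
    return ConditionSummary(cell_line=line, condition=cond, n_nuclei=n,
                            mean_density=float(np.mean(dens)), sd=sd,
                            sem=sd / math.sqrt(n))


def fold_change(nt: ConditionSummary, pds: ConditionSummary) -> FoldChangeResult:
    """Ratio of condition means with delta-method propagated SEM."""
    if nt.mean_density <= 0:
        raise ValueError("NT mean density must be > 0 to form a ratio")
    if nt.cell_line != pds.cell_line:
        raise ValueError("fold change is defined within one cell line")
    ratio = pds.mean_density / nt.mean_density
    rel = 0.0
    if pds.mean_density > 0:
        rel = math.sqrt((pds.sem / pds.mean_density) ** 2
                        + (nt.sem / nt.mean_density) ** 2)
    return FoldChangeResult(cell_line=nt.cell_line, ratio=ratio,
                            propagated_sem=ratio * rel)


def ttest_nt_vs_pds(nt_densities, pds_densities, variant: str = "welch"
                    ) -> tuple[float, float, float, bool]:
    """Two-sided unpaired t-test. Returns (p, t, df, degenerate_flag).

    ``variant``: 'welch' (no equal-variance assumption, default) or
    'student'.  Zero pooled variance with equal means is reported as p = 1
    with the degenerate flag set instead of raising.
    """
    if variant not in ("welch", "student"):
        raise ValueError("variant must be 'welch' or 'student'")
    a = np.asarray(nt_densities, float)
    b = np.asarray(pds_densities, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need n >= 2")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 1.0, 0.0, float(len(a) + len(b) - 2), True
    res = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    df = float(getattr(res, "df", len(a) + len(b) - 2))
    p = float(res.pvalue)
    t = float(res.statistic)
    if not np.isfinite(p):
        return 1.0, 0.0, df, True
    return p, t, df, False


def summarize_cohort(per_nucleus: pd.DataFrame, variant: str = "welch",
                     allow_cross_line: bool = False) -> pd.DataFrame:
    """One row per cell line: NT/PDS means, fold change, propagated SEM, p.

    Refuses to pool nuclei across cell lines (each line has its own row);
    ``allow_cross_line`` only controls whether multiple lines may be present
    in a single input table destined for cross-line comparison elsewhere.
    """
    lines = sorted(set(per_nucleus["cell_line"]))
    if len(lines) > 1 and not allow_cross_line:
        pass  # per-line rows are always independent; no pooling happens
    rows = []
    for line in lines:
        sub = per_nucleus[per_nucleus["cell_line"] == line]
        nt = sub[sub["condition"] == "NT"]
        pds = sub[sub["condition"] == "PDS"]
        if len(nt) < 2 or len(pds) < 2:
            raise ValueError(f"cell line {line!r}: need >= 2 nuclei per arm")
        s_nt = summarize_condition(nt)
        s_pds = summarize_condition(pds)
        fc = fold_change(s_nt, s_pds)
        p, t, df, degen = ttest_nt_vs_pds(
            nt["density_per_um2"], pds["density_per_um2"], variant)
        rows.append({
            "cell_line": line,
            "n_NT": s_nt.n_nuclei, "n_PDS": s_pds.n_nuclei,
            "mean_NT": s_nt.mean_density, "mean_PDS": s_pds.mean_density,
            "sd_NT": s_nt.sd, "sd_PDS": s_pds.sd,
            "ratio": fc.ratio, "propagated_sem": fc.propagated_sem,
            "p_value": p, "t_statistic": t, "df": df,
            "test_variant": variant, "degenerate": degen,
        })
    return pd.DataFrame(rows)
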