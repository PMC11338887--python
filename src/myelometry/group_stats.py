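"""Two-group morphometric statistics, stratified by cortical layer.

Workflow per (metric, layer) cell: screen each group for normality with the
Shapiro-Wilk test, compare group means with an unpaired t-test (Student's
pooled-variance form by default, Welch optional), and report means +/- SD with
group sizes. Significance is two-sided at alpha = 0.05. A failed normality
screen is logged as a warning but does not change the test — the screen is a
validation step, not a decision rule — and no multiple-testing correction is
applied across the six (metric x layer) comparisons; the report footer says so.

The unit of analysis defaults to the sheath (all sheaths pooled across images
within a group); per-image means are available via ``unit="image"``. Reports
always print n at the chosen unit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import StatsError
from .layering import LAYER_1, LAYER_2_3

logger = logging.getLogger(__name__)

ALPHA = 0.05
METRICS = ("thickness_mean_nm", "g_ratio", "axon_diameter_nm")
LAYERS = (LAYER_1, LAYER_2_3)
NO_CORRECTION_NOTE = (
    "Six raw two-sided p-values reported at alpha=0.05; no multiple-testing correction applied."
)


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk normality test (Royston's algorithm); returns (W, p)."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if x.size < 3:
        raise StatsError(f"Shapiro-Wilk requires n >= 3, got n={x.size}")
    if x.size > 5000:
        raise StatsError(f"Shapiro-Wilk p-values unreliable for n > 5000, got n={x.size}")
    if not np.all(np.isfinite(x)):
        raise StatsError("Shapiro-Wilk requires finite values")
    if np.ptp(x) == 0:
        raise StatsError("zero variance: all values identical")
    w, p = stats.shapiro(x)
    return float(w), float(p)


def unpaired_t_test(a, b, mode: str = "student") -> tuple[float, float, float]:
    """Unpaired two-sample t-test; returns (t, df, two-sided p).

    ``mode='student'`` uses the pooled-variance statistic; ``mode='welch'``
    the unequal-variance form. Two groups that are both constant and equal
    give t=0, p=1 (no evidence of difference) rather than an error.
    """
    if mode not in ("student", "welch"):
        raise StatsError(f"mode must be 'student' or 'welch', got {mode!r}")
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise StatsError(f"each group needs n >= 2, got n_a={x.size}, n_b={y.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise StatsError("t-test requires finite values")
    if np.ptp(x) == 0 and np.ptp(y) == 0 and x[0] == y[0]:
        df = x.size + y.size - 2 if mode == "student" else float("nan")
        return 0.0, float(df), 1.0
    res = stats.ttest_ind(x, y, equal_var=(mode == "student"))
    return float(res.statistic), float(res.df), float(res.pvalue)


@dataclass(frozen=True)
class GroupSummary:
    name: str
    n: int
    mean: float
    sd: float
    shapiro_w: float
    shapiro_p: float


@dataclass(frozen=True)
class GroupComparison:
    """One per-layer, per-metric two-group comparison (mean +/- SD, t, df, p)."""

    metric: str
    layer: str
    group_a: GroupSummary
    group_b: GroupSummary
    t: float
    df: float
    p: float
    alpha: float = ALPHA
    unit_of_analysis: str = "sheath"
    n_sheaths: tuple[int, int] = (0, 0)

    @property
    def significant(self) -> bool:
        return self.p < self.alpha

    def to_dict(self) -> dict:
        d = asdict(self)
        d["significant"] = self.significant
        d["n_sheaths"] = list(self.n_sheaths)
        return d


def _group_values(
    table: pd.DataFrame, metric: str, layer: str, unit: str
) -> tuple[dict[str, np.ndarray], dict[str, int]]:
    if metric not in table.columns:
        raise StatsError(f"metric {metric!r} not found in sheath table")
    if "group" not in table.columns:
        raise StatsError("sheath table has no 'group' column; join the cohort manifest first")
    sel = table.loc[table["layer"] == layer]
    if "qc" in sel.columns:
        sel = sel.loc[sel["qc"].fillna("").astype(str).str.len() == 0]
    values: dict[str, np.ndarray] = {}
    n_sheaths: dict[str, int] = {}
    for name, sub in sel.groupby("group", sort=True):
        n_sheaths[name] = len(sub)
        if unit == "sheath":
            values[name] = sub[metric].to_numpy(dtype=float)
        elif unit == "image":
            if "image" not in sub.columns:
                raise StatsError("unit='image' requires an 'image' column in the sheath table")
            values[name] = sub.groupby("image")[metric].mean().to_numpy(dtype=float)
        else:
            raise StatsError(f"unit must be 'sheath' or 'image', got {unit!r}")
    return values, n_sheaths


def attach_groups(sheath_table: pd.DataFrame, manifest: dict | str | Path) -> pd.DataFrame:
    """Join cohort group labels onto a per-sheath table via its manifest."""
    if not isinstance(manifest, dict):
        manifest = json.loads(Path(manifest).read_text())
    mapping = {entry["image"]: entry["group"] for entry in manifest["images"]}
    if "image" not in sheath_table.columns:
        raise StatsError("sheath table needs an 'image' column to join the manifest")
    out = sheath_table.copy()
    out["group"] = out["image"].map(mapping)
    if out["group"].isna().any():
        missing = sorted(out.loc[out["group"].isna(), "image"].unique())
        raise StatsError(f"images missing from manifest: {missing}")
    return out


def compare_groups(
    sheath_table: pd.DataFrame,
    metric: str,
    layer: str,
    manifest: dict | str | Path | None = None,
    unit_of_analysis: str = "sheath",
    mode: str = "student",
    alpha: float = ALPHA,
) -> GroupComparison:
    """Run one per-layer, per-metric two-group comparison.

    Pipeline: filter to the layer, drop QC-excluded sheaths, aggregate to the
    unit of analysis, Shapiro-Wilk screen per group (warning if p < alpha),
    unpaired t-test, report mean +/- SD and n per group.
    """
    table = attach_groups(sheath_table, manifest) if manifest is not None else sheath_table
    values, n_sheaths = _group_values(table, metric, layer, unit_of_analysis)
    names = sorted(values)
    if len(names) != 2:
        raise StatsError(
            f"need exactly 2 groups after filtering (metric={metric}, layer={layer}, "
            f"unit={unit_of_analysis}); got groups {names}"
        )
    for name in names:
        if values[name].size < 2:
            raise StatsError(
                f"empty or degenerate group {name!r} after filter chain "
                f"layer={layer} -> qc -> unit={unit_of_analysis} (n={values[name].size})"
            )
    summaries = []
    for name in names:
        v = values[name]
        if v.size >= 3 and np.ptp(v) > 0:
            w, p_sw = shapiro_wilk(v)
            if p_sw < alpha:
                logger.warning(
                    "normality screen failed for group=%s metric=%s layer=%s (Shapiro-Wilk p=%.4g); "
                    "t-test reported regardless",
                    name, metric, layer, p_sw,
                )
        else:
            w, p_sw = float("nan"), float("nan")
        summaries.append(
            GroupSummary(
                name=name, n=int(v.size), mean=float(np.mean(v)),
                sd=float(np.std(v, ddof=1)), shapiro_w=w, shapiro_p=p_sw,
            )
        )
    t, df, p = unpaired_t_test(values[names[0]], values[names[1]], mode=mode)
    return GroupComparison(
        metric=metric,
        layer=layer,
        group_a=summaries[0],
        group_b=summaries[1],
        t=t,
        df=df,
        p=p,
        alpha=alpha,
        unit_of_analysis=unit_of_analysis,
        n_sheaths=(n_sheaths[names[0]], n_sheaths[names[1]]),
    )


def full_report(
    sheath_table: pd.DataFrame,
    manifest: dict | str | Path | None = None,
    metrics=METRICS,
    layers=LAYERS,
    unit_of_analysis: str = "sheath",
    mode: str = "student",
    alpha: float = ALPHA,
) -> dict:
    """All (metric x layer) comparisons — six by default — as a JSON-ready dict."""
    table = attach_groups(sheath_table, manifest) if manifest is not None else sheath_table
    comparisons = [
        compare_groups(table, metric, layer, unit_of_analysis=unit_of_analysis, mode=mode, alpha=alpha)
        for metric in metrics
        for layer in layers
    ]
    return {
        "comparisons": [c.to_dict() for c in comparisons],
        "alpha": alpha,
        "unit_of_analysis": unit_of_analysis,
        "t_test": mode,
        "note": NO_CORRECTION_NOTE,
    }


def format_report(report: dict) -> str:
    """Human-readable table of a full_report dict."""
    lines = [
        f"{'metric':<18} {'layer':<6} {'group':<10} {'n':>5} {'mean':>12} {'sd':>10} "
        f"{'t':>8} {'df':>7} {'p':>8} {'sig':>4}"
    ]
    for c in report["comparisons"]:
        for i, g in enumerate((c["group_a"], c["group_b"])):
            stat = (
                f"{c['t']:>8.3f} {c['df']:>7.1f} {c['p']:>8.4f} "
                f"{'*' if c['significant'] else '':>4}"
            ) if i == 0 else " " * 30
            lines.append(
                f"{c['metric'] if i == 0 else '':<18} {c['layer'] if i == 0 else '':<6} "
                f"{g['name']:<10} {g['n']:>5} {g['mean']:>12.4f} {g['sd']:>10.4f} {stat}"
            )
    lines.append(f"alpha={report['alpha']}, t-test={report['t_test']}, unit={report['unit_of_analysis']}")
    lines.append(report["note"])
    return "\n".join(lines)
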