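"""Nonparametric comparison cascade and comparison-table assembly.

The cascade mirrors standard practice for small behavioral/EEG samples:
each metric is screened with Shapiro-Wilk (the outcome is recorded; the
pipeline proceeds nonparametrically regardless, since normality routinely
fails for these metrics), compared across groups with the Kruskal-Wallis
omnibus test, and -- only when the omnibus test is significant at 0.05 --
followed up with pairwise two-sided Mann-Whitney U tests.  No
multiple-testing correction is applied; reports carry a metadata note to
that effect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

__all__ = [
    "ALPHA",
    "NormalityResult",
    "normality_gate",
    "MetricComparison",
    "omnibus_then_pairwise",
    "ComparisonReport",
    "build_comparison_table",
]

ALPHA = 0.05
_NO_CORRECTION_NOTE = (
    "p-values are uncorrected for multiple comparisons; "
    "significance threshold 0.05 throughout"
)


@dataclass(frozen=True)
class NormalityResult:
    statistic: float    # Shapiro-Wilk W
    p_value: float
    is_normal: bool     # p >= 0.05


def normality_gate(sample: Sequence[float]) -> NormalityResult:
    """Shapiro-Wilk normality screen for 3 <= n <= 5000."""
    x = np.asarray(sample, dtype=float)
    if x.ndim != 1 or not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk needs a 1-D sample with 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: normality test undefined")
    res = _st.shapiro(x)
    return NormalityResult(float(res.statistic), float(res.pvalue),
                           bool(res.pvalue >= ALPHA))


def _kruskal(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H and p with tie correction; identical-value input
    (zero rank variance) is reported as H=0, p=1."""
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if pooled.size and np.ptp(pooled) == 0:
        return 0.0, 1.0
    try:
        res = _st.kruskal(*groups)
    except ValueError as exc:
        if "identical" in str(exc):
            return 0.0, 1.0
        raise
    return float(res.statistic), float(res.pvalue)


@dataclass
class MetricComparison:
    """One metric's row of a comparison table."""

    metric: str
    group_labels: tuple
    means: tuple[float, ...]
    stds: tuple[float, ...]
    ns: tuple[int, ...]
    kw_statistic: float
    kw_p: float
    pairwise: dict[tuple, float] | None = None   # only when kw_p < ALPHA
    stars: dict | None = None                    # per-group extra significance marks

    @property
    def significant_pairs(self) -> str:
        if not self.pairwise:
            return "-"
        parts = [
            f"{a}–{b} ({p:.3f})"
            for (a, b), p in self.pairwise.items()
            if p < ALPHA
        ]
        return ", ".join(parts) if parts else "-"


def omnibus_then_pairwise(
    groups: Mapping, metric: str = ""
) -> MetricComparison:
    """Kruskal-Wallis across labeled groups; pairwise two-sided Mann-Whitney
    U tests run iff the omnibus p is below 0.05.

    ``groups`` maps a label to a 1-D sample; at least two groups of n >= 2.
    """
    labels = tuple(groups.keys())
    arrays = [np.asarray(groups[lbl], dtype=float) for lbl in labels]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for lbl, arr in zip(labels, arrays):
        if arr.size == 0:
            raise ValueError(f"group {lbl!r} is empty")
    kw_stat, kw_p = _kruskal(arrays)
    pairwise = None
    if kw_p < ALPHA:
        pairwise = {}
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                res = _st.mannwhitneyu(
                    arrays[i], arrays[j], alternative="two-sided",
                    use_continuity=True,
                )
                pairwise[(labels[i], labels[j])] = float(res.pvalue)
    return MetricComparison(
        metric=metric,
        group_labels=labels,
        means=tuple(float(a.mean()) for a in arrays),
        stds=tuple(float(a.std(ddof=1)) if a.size > 1 else 0.0 for a in arrays),
        ns=tuple(int(a.size) for a in arrays),
        kw_statistic=kw_stat,
        kw_p=kw_p,
        pairwise=pairwise,
    )


DEFAULT_METRICS = (
    "T", "A", "S", "PSD_alpha", "PSD_beta", "PSD_theta",
    "Amax", "Amean", "Astd", "H",
)


@dataclass
class ComparisonReport:
    """Metric x group comparison table (means +- std, omnibus and pairwise p).

    The structural invariant of the cascade holds by construction: a row
    carries pairwise p-values only when its omnibus p is significant.
    """

    grouping: str
    rows: list[MetricComparison]
    note: str = _NO_CORRECTION_NOTE
    meta: dict = field(default_factory=dict)

    @property
    def group_labels(self) -> tuple:
        return self.rows[0].group_labels if self.rows else ()

    def to_dataframe(self) -> pd.DataFrame:
        data = []
        for row in self.rows:
            rec = {"metric": row.metric}
            for lbl, m, s in zip(row.group_labels, row.means, row.stds):
                star = " *" if row.stars and row.stars.get(lbl) else ""
                rec[str(lbl)] = f"{m:.3f} ± {s:.3f}{star}"
            rec["kw_p"] = f"{row.kw_p:.3f}"
            rec["pairwise"] = row.significant_pairs
            data.append(rec)
        return pd.DataFrame(data)

    def to_markdown(self) -> str:
        df = self.to_dataframe()
        lines = [
            "| " + " | ".join(df.columns) + " |",
            "| " + " | ".join("---" for _ in df.columns) + " |",
        ]
        for _, r in df.iterrows():
            lines.append("| " + " | ".join(str(v) for v in r) + " |")
        lines.append("")
        lines.append(f"_{self.note}_")
        return "\n".join(lines)

    def to_json(self) -> str:
        """Machine-readable rendering with full-precision p-values."""
        payload = {
            "grouping": self.grouping,
            "note": self.note,
            "meta": self.meta,
            "rows": [
                {
                    "metric": r.metric,
                    "groups": [
                        {"label": str(lbl), "mean": m, "std": s, "n": n,
                         "star": bool(r.stars.get(lbl)) if r.stars else False}
                        for lbl, m, s, n in zip(r.group_labels, r.means, r.stds, r.ns)
                    ],
                    "kw_statistic": r.kw_statistic,
                    "kw_p": r.kw_p,
                    "pairwise": (
                        None if r.pairwise is None
                        else {f"{a}|{b}": p for (a, b), p in r.pairwise.items()}
                    ),
                }
                for r in self.rows
            ],
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def build_comparison_table(
    features: pd.DataFrame,
    group_col: str,
    metrics: Sequence[str] = DEFAULT_METRICS,
    grouping_name: str = "",
    group_order: Sequence | None = None,
) -> ComparisonReport:
    """Assemble a comparison report from a tidy features table.

    Each requested metric is compared across the values of ``group_col``
    with the omnibus-then-pairwise cascade.  Missing metric columns raise.
    """
    missing = [m for m in metrics if m not in features.columns]
    if missing:
        raise ValueError(f"features table lacks metric column(s): {missing}")
    if group_col not in features.columns:
        raise ValueError(f"no grouping column {group_col!r}")
    labels = (
        list(group_order) if group_order is not None
        else sorted(features[group_col].unique())
    )
    rows = []
    normality = {}
    for metric in metrics:
        groups = {
            lbl: features.loc[features[group_col] == lbl, metric].to_numpy()
            for lbl in labels
        }
        rows.append(omnibus_then_pairwise(groups, metric=metric))
        pooled = features[metric].to_numpy()
        try:
            normality[metric] = normality_gate(pooled).p_value
        except ValueError:
            normality[metric] = None
    return ComparisonReport(
        grouping=grouping_name or group_col,
        rows=rows,
        meta={"shapiro_p": normality, "n_records": int(len(features))},
    )
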