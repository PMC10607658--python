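"""Clustering-based discovery of phobia-susceptible participant subgroups.

Each participant is summarized as a vector of nine values -- accuracy,
duration and speed for the three scenes of one exercise -- optionally
extended by their mean interhemispheric asymmetry in the alpha, beta and
theta rhythms (twelve values).  Vectors are z-scored per feature.  Three
clustering algorithms (k-means, Birch's CF-tree hierarchical method, and
spectral clustering on an RBF affinity) are run for k in {2, 3}; each
candidate partition is scored by the Kruskal-Wallis p-value between
clusters on the record-level quantitative metrics (A, T, S).  Candidates
with all three p below 0.05 are feasible; among feasible candidates the
smallest k wins, ties broken by lowest mean p.  If no candidate is
feasible the result reports "no statistically separable subgroups" rather
than raising.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import Birch, KMeans, SpectralClustering

from .compare import ALPHA, ComparisonReport, _kruskal, build_comparison_table
from .features import BANDS
from .montage import IHA_PAIRS

__all__ = [
    "ParticipantVectors",
    "build_vectors",
    "SubgroupAssignment",
    "select_clustering",
    "SubgroupReportBundle",
    "subgroup_reports",
]

CLUSTER_METRICS = ("A", "T", "S")
ALGORITHM_ORDER = ("kmeans", "birch", "spectral")


@dataclass
class ParticipantVectors:
    """Standardized per-participant feature vectors for one exercise."""

    exercise: str
    ids: tuple[str, ...]
    matrix: np.ndarray              # (n_participants, n_features), z-scored
    feature_names: tuple[str, ...]
    dropped: tuple[str, ...] = ()   # zero-variance features removed


def build_vectors(
    features: pd.DataFrame, exercise: str, include_iha: bool = False
) -> ParticipantVectors:
    """Build z-scored participant vectors from the tidy features table.

    Ordering is documented and fixed: (A, T, S) for each scene of the
    exercise in ascending scene id (9 values), then, when requested, the
    participant's mean IHA over all derivation pairs and scenes in the
    alpha, beta and theta bands (3 more).  Every participant must have all
    three scenes; zero-variance features are dropped with a warning.
    """
    sub = features[features["exercise"] == exercise]
    if sub.empty:
        raise ValueError(f"no rows for exercise {exercise!r}")
    scene_ids = sorted(sub["scene_id"].unique())
    counts = sub.groupby("participant_id")["scene_id"].nunique()
    incomplete = counts[counts < len(scene_ids)]
    if len(incomplete):
        raise ValueError(
            f"participant(s) missing scenes: {', '.join(incomplete.index)}"
        )
    ids = sorted(sub["participant_id"].unique())
    names: list[str] = []
    for sid in scene_ids:
        names += [f"{m}_scene{sid}" for m in CLUSTER_METRICS]
    wide = sub.pivot(index="participant_id", columns="scene_id",
                     values=list(CLUSTER_METRICS))
    cols = {f"{m}_scene{sid}": wide[(m, sid)] for sid in scene_ids
            for m in CLUSTER_METRICS}
    mat = pd.DataFrame(cols).loc[ids, names]
    if include_iha:
        iha_cols = [c for c in sub.columns if c.startswith("IHA_")]
        if not iha_cols:
            raise ValueError("features table has no IHA columns")
        for band in BANDS:
            band_cols = [c for c in iha_cols if c.startswith(f"IHA_{band}_")]
            mean_iha = sub.groupby("participant_id")[band_cols].mean().mean(axis=1)
            mat[f"IHA_{band}"] = mean_iha.loc[ids]
            names.append(f"IHA_{band}")
    X = mat.to_numpy(dtype=float)
    sd = X.std(axis=0)
    dropped = tuple(np.array(names)[sd == 0])
    if dropped:
        warnings.warn(
            f"dropping zero-variance feature(s) from standardization: {dropped}",
            stacklevel=2,
        )
    keep = sd > 0
    Xz = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    return ParticipantVectors(
        exercise=exercise,
        ids=tuple(ids),
        matrix=Xz,
        feature_names=tuple(np.array(names)[keep]),
        dropped=dropped,
    )


@dataclass
class SubgroupAssignment:
    """Outcome of the algorithm/cluster-count selection."""

    exercise: str
    feasible: bool
    algorithm: str | None
    k: int | None
    labels: dict[str, int] | None          # participant id -> cluster
    p_grid: pd.DataFrame                   # algorithm x k x metric KW p-values
    rationale: str
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "exercise": self.exercise,
                "feasible": self.feasible,
                "algorithm": self.algorithm,
                "k": self.k,
                "labels": self.labels,
                "rationale": self.rationale,
                "seed": self.seed,
                "p_grid": self.p_grid.to_dict(orient="records"),
            },
            indent=2, sort_keys=True,
        )


def _make_algorithm(name: str, k: int, seed: int):
    if name == "kmeans":
        return KMeans(n_clusters=k, n_init=10, random_state=seed)
    if name == "birch":
        return Birch(n_clusters=k)
    if name == "spectral":
        return SpectralClustering(n_clusters=k, affinity="rbf", random_state=seed)
    raise ValueError(f"unknown algorithm {name!r}")


def select_clustering(
    vectors: ParticipantVectors,
    metrics: pd.DataFrame,
    k_values: tuple[int, ...] = (2, 3),
    seed: int = 0,
) -> SubgroupAssignment:
    """Run all algorithms x cluster counts and keep the best separable one.

    ``metrics`` is the record-level features table (one row per
    participant x scene) providing the A, T, S samples that each candidate
    partition is scored on.  Selection is a pure function of its inputs
    and the seed.
    """
    sub = metrics[metrics["exercise"] == vectors.exercise]
    if len(vectors.ids) < 2 * max(k_values):
        raise ValueError("too few participants for the requested cluster counts")
    grid_rows = []
    candidates = []
    for k in sorted(k_values):
        for name in ALGORITHM_ORDER:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    labels = _make_algorithm(name, k, seed).fit_predict(vectors.matrix)
                except Exception:
                    labels = None
            ps = {}
            if labels is not None and len(np.unique(labels)) == k:
                lab_of = dict(zip(vectors.ids, labels))
                rec_labels = sub["participant_id"].map(lab_of)
                for metric in CLUSTER_METRICS:
                    groups = [
                        sub.loc[rec_labels == c, metric].to_numpy()
                        for c in np.unique(labels)
                    ]
                    ps[metric] = _kruskal(groups)[1]
            else:
                ps = {metric: np.nan for metric in CLUSTER_METRICS}
            grid_rows.append({"algorithm": name, "k": k, **ps})
            if ps and not any(np.isnan(list(ps.values()))):
                feasible = all(p < ALPHA for p in ps.values())
                if feasible:
                    candidates.append(
                        (k, float(np.mean(list(ps.values()))),
                         ALGORITHM_ORDER.index(name), name, labels)
                    )
    p_grid = pd.DataFrame(grid_rows)
    if not candidates:
        return SubgroupAssignment(
            exercise=vectors.exercise, feasible=False, algorithm=None, k=None,
            labels=None, p_grid=p_grid,
            rationale="no statistically separable subgroups "
                      f"(no candidate with all A/T/S Kruskal-Wallis p < {ALPHA})",
            seed=seed,
        )
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    k, mean_p, _, name, labels = candidates[0]
    return SubgroupAssignment(
        exercise=vectors.exercise, feasible=True, algorithm=name, k=k,
        labels={pid: int(lab) for pid, lab in zip(vectors.ids, labels)},
        p_grid=p_grid,
        rationale=(
            f"selected {name} with k={k}: smallest separable cluster count, "
            f"mean A/T/S Kruskal-Wallis p = {mean_p:.3g}"
        ),
        seed=seed,
    )


@dataclass
class SubgroupReportBundle:
    """Per-scene subgroup comparisons plus the IHA table for one exercise."""

    exercise: str
    scene_reports: dict[int, ComparisonReport]
    iha_table: pd.DataFrame
    skipped: list[str] = field(default_factory=list)


def _across_scene_stars(
    sub: pd.DataFrame, metrics, labels_col: str
) -> dict[int, dict[str, bool]]:
    """For each subgroup x metric: is the across-scene Kruskal-Wallis
    difference significant (the star convention of subgroup tables)?"""
    stars: dict[int, dict[str, bool]] = {}
    for cluster, grp in sub.groupby(labels_col):
        stars[int(cluster)] = {}
        for metric in metrics:
            groups = [g.to_numpy() for _, g in grp.groupby("scene_id")[metric]]
            if len(groups) >= 2 and all(len(g) >= 2 for g in groups):
                stars[int(cluster)][metric] = _kruskal(groups)[1] < ALPHA
            else:
                stars[int(cluster)][metric] = False
    return stars


def subgroup_reports(
    assignment: SubgroupAssignment,
    features: pd.DataFrame,
    metrics=None,
) -> SubgroupReportBundle:
    """Re-run the comparison cascade between subgroups within each scene,
    and tabulate per-subgroup IHA (pair x band x scene) with Mann-Whitney
    significance marks and direction flags.

    Subgroups of fewer than two records in a scene are skipped with a note
    rather than tested.
    """
    from scipy.stats import mannwhitneyu

    if not assignment.feasible or assignment.labels is None:
        raise ValueError("assignment has no subgroups to report on")
    from .compare import DEFAULT_METRICS

    metrics = tuple(metrics or [m for m in DEFAULT_METRICS
                                if m in features.columns])
    sub = features[features["exercise"] == assignment.exercise].copy()
    sub["subgroup"] = sub["participant_id"].map(assignment.labels)
    if sub["subgroup"].isna().any():
        raise ValueError("features table contains participants not in the assignment")

    star_map = _across_scene_stars(sub, metrics, "subgroup")
    scene_reports: dict[int, ComparisonReport] = {}
    skipped: list[str] = []
    for sid, scene_df in sub.groupby("scene_id"):
        sizes = scene_df.groupby("subgroup").size()
        if (sizes < 2).any() or len(sizes) < 2:
            skipped.append(f"scene {sid}: subgroup with fewer than 2 records")
            continue
        report = build_comparison_table(
            scene_df, group_col="subgroup", metrics=metrics,
            grouping_name=f"{assignment.exercise} scene {sid} subgroups",
        )
        for row in report.rows:
            row.stars = {lbl: star_map.get(int(lbl), {}).get(row.metric, False)
                         for lbl in row.group_labels}
        scene_reports[int(sid)] = report

    clusters = sorted(sub["subgroup"].unique())
    iha_rows = []
    for sid, scene_df in sub.groupby("scene_id"):
        for right, left in IHA_PAIRS:
            pair = f"{right}-{left}"
            for band in BANDS:
                col = f"IHA_{band}_{pair}"
                if col not in sub.columns:
                    continue
                samples = {
                    c: scene_df.loc[scene_df["subgroup"] == c, col].to_numpy()
                    for c in clusters
                }
                row: dict = {"scene_id": int(sid), "pair": pair, "band": band}
                for c in clusters:
                    row[f"mean_{c}"] = float(samples[c].mean()) if samples[c].size else np.nan
                    row[f"std_{c}"] = (
                        float(samples[c].std(ddof=1)) if samples[c].size > 1 else np.nan
                    )
                if len(clusters) == 2 and all(s.size >= 2 for s in samples.values()):
                    a, b = (samples[c] for c in clusters[:2])
                    if np.ptp(np.concatenate([a, b])) == 0:
                        p = 1.0
                    else:
                        p = float(mannwhitneyu(a, b, alternative="two-sided").pvalue)
                    row["mw_p"] = p
                    row["significant"] = p < ALPHA
                    # direction of the second subgroup relative to the first
                    row["direction"] = (
                        "up" if row[f"mean_{clusters[1]}"] > row[f"mean_{clusters[0]}"]
                        else "down"
                    )
                else:
                    row["mw_p"] = np.nan
                    row["significant"] = False
                    row["direction"] = ""
                iha_rows.append(row)
    iha_table = pd.DataFrame(iha_rows)
    return SubgroupReportBundle(
        exercise=assignment.exercise,
        scene_reports=scene_reports,
        iha_table=iha_table,
        skipped=skipped,
    )
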