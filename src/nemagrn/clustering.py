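"""Correlation clustering of standardized profiles and gene-group selection.

Profiles are compared with the Pearson correlation distance ``1 - r`` and
clustered with unweighted average linkage (UPGMA); the dendrogram is cut at a
fixed linkage distance (0.6 in the gut-formation study) to obtain spatial
clusters.  Genes are then partitioned into four groups by their temporal
appearance (cleavage / gastrula) and their planula-stage spatial cluster, and
one representative gene per group — the one with the most profiles — is
selected for simulation.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .quantification import StandardizedProfile

DEFAULT_CUT_HEIGHT = 0.6

#: Stage windows in hours post-fertilization (16 degrees C).
STAGE_BOUNDS = (("cleavage", 0.0, 10.0), ("blastula", 10.0, 20.0),
                ("gastrula", 20.0, 48.0), ("planula", 48.0, np.inf))


class ClusteringError(ValueError):
    pass


def assign_stage(hours: float) -> str:
    """Map hours post-fertilization to a named developmental stage."""
    for name, lo, hi in STAGE_BOUNDS:
        if lo <= hours < hi:
            return name
    raise ClusteringError(f"cannot stage {hours} hours")


def _profile_matrix(profiles: Sequence[StandardizedProfile] | np.ndarray) -> np.ndarray:
    if isinstance(profiles, np.ndarray):
        return np.asarray(profiles, dtype=float)
    return np.vstack([p.values for p in profiles])


def correlation_distance(profiles) -> np.ndarray:
    """Square distance matrix ``d(i, j) = 1 - Pearson(i, j)``.

    A constant (zero-variance) profile has no defined correlation and is
    rejected, naming the offending gene.
    """
    X = _profile_matrix(profiles)
    if len(X) < 2:
        raise ClusteringError("need at least 2 profiles")
    sd = X.std(axis=1)
    if np.any(sd == 0):
        bad = int(np.argmax(sd == 0))
        name = (profiles[bad].gene if not isinstance(profiles, np.ndarray)
                else f"profile {bad}")
        raise ClusteringError(f"constant (zero-variance) profile: {name}")
    D = 1.0 - np.corrcoef(X)
    np.fill_diagonal(D, 0.0)
    return np.clip((D + D.T) / 2.0, 0.0, 2.0)


def average_linkage(distances: np.ndarray) -> np.ndarray:
    """UPGMA merge tree from a square distance matrix.

    Returns a SciPy linkage matrix; the inter-cluster distance is the
    unweighted mean over all cross-cluster pairs.
    """
    D = np.asarray(distances, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ClusteringError("expected a square distance matrix")
    return hierarchy.linkage(squareform(D, checks=False), method="average")


def cut_tree(linkage_matrix: np.ndarray, height: float) -> np.ndarray:
    """Flat cluster labels after removing merges above ``height``.

    Labels are 1-based consecutive integers as returned by
    ``scipy.cluster.hierarchy.fcluster``.
    """
    if height < 0:
        raise ClusteringError("cut height must be non-negative")
    return hierarchy.fcluster(linkage_matrix, t=height, criterion="distance")


def to_newick(linkage_matrix: np.ndarray, names: Sequence[str]) -> str:
    """Newick export of the dendrogram with ultrametric branch lengths."""
    tree = hierarchy.to_tree(linkage_matrix)

    def rec(node) -> str:
        if node.is_leaf():
            return str(names[node.id])
        left, right = node.get_left(), node.get_right()
        parts = []
        for child in (left, right):
            bl = (node.dist - child.dist) / 2.0
            parts.append(f"{rec(child)}:{bl:.10g}")
        return "(" + ",".join(parts) + ")"

    return rec(tree) + ";"


def infer_cluster_domains(profiles: Sequence[StandardizedProfile],
                          labels: np.ndarray) -> dict[int, str]:
    """Classify each cluster's mean profile as endoderm, oral-pole or border.

    Heuristic tuned to the observed cluster shapes: a single broad central
    peak (segments ~40-60) is endodermal; two peaks flanking the center are
    oral-pole if they sit far from the center (~35/65) and border if they hug
    the domain edges (~40/60).
    """
    X = _profile_matrix(profiles)
    domains: dict[int, str] = {}
    for label in np.unique(labels):
        mean = X[labels == label].mean(axis=0)
        mean = mean / mean.max() if mean.max() > 0 else mean
        peaks = [i for i in range(1, len(mean) - 1)
                 if mean[i] > mean[i - 1] and mean[i] > mean[i + 1]
                 and mean[i] > 0.5]
        seg = np.array(peaks) + 1  # 1-based segments
        if len(seg) >= 2 and seg.min() < 45 and seg.max() > 55:
            spread = float(np.mean(np.abs(seg - 50)))
            domains[int(label)] = "oral" if spread >= 12 else "border"
        elif len(seg) and 40 <= np.median(seg) <= 60:
            domains[int(label)] = "endoderm"
        else:
            domains[int(label)] = "other"
    return domains


def build_gene_groups(profile_meta: pd.DataFrame,
                      cluster_domains: Mapping[int, str]) -> pd.DataFrame:
    """Partition genes into the four temporal/spatial groups.

    ``profile_meta`` needs columns ``gene``, ``stage`` (or ``stage_hours``)
    and ``cluster`` (label from :func:`cut_tree`).  Group logic: genes with
    profiles at the cleavage stage form group 1; genes absent at the gastrula
    stage form group 4; the rest are split by the spatial domain of their
    planula-stage cluster into group 2 (endoderm) and group 3 (oral pole).
    A gene whose planula profiles fall in conflicting clusters is assigned by
    majority; an exact tie leaves it unresolved.
    """
    meta = profile_meta.copy()
    if "stage" not in meta.columns:
        meta["stage"] = meta["stage_hours"].map(assign_stage)
    rows = []
    for gene, sub in meta.groupby("gene", sort=True):
        stages = set(sub["stage"])
        planula = sub[sub["stage"] == "planula"]
        domain, status = None, "ok"
        if len(planula):
            counts = planula["cluster"].map(lambda c: cluster_domains.get(int(c), "other"))
            tally = counts.value_counts()
            if len(tally) > 1:
                status = "conflict"
                if len(tally) > 1 and tally.iloc[0] == tally.iloc[1]:
                    status = "unresolved"
            domain = tally.index[0] if status != "unresolved" else None
        if "cleavage" in stages:
            group = 1
        elif "gastrula" not in stages:
            group = 4
        elif domain == "endoderm":
            group = 2
        elif domain == "oral":
            group = 3
        else:
            group, status = 0, "unresolved"
        rows.append({"gene": gene, "group": group, "planula_domain": domain,
                     "n_profiles": len(sub), "status": status})
    return pd.DataFrame(rows)


def select_representatives(group_table: pd.DataFrame) -> dict[int, str]:
    """One representative gene per group: the gene with the most profiles,
    ties broken lexicographically.  Empty groups are skipped."""
    reps: dict[int, str] = {}
    for group, sub in group_table[group_table["group"] > 0].groupby("group"):
        sub = sub.sort_values(["n_profiles", "gene"],
                              ascending=[False, True], kind="stable")
        reps[int(group)] = str(sub.iloc[0]["gene"])
    return reps


def cluster_profiles(profiles: Sequence[StandardizedProfile],
                     cut_height: float = DEFAULT_CUT_HEIGHT) -> dict:
    """Convenience wrapper: distances, linkage, labels and metadata table."""
    D = correlation_distance(profiles)
    Z = average_linkage(D)
    labels = cut_tree(Z, cut_height)
    meta = pd.DataFrame({
        "gene": [p.gene for p in profiles],
        "stage_hours": [p.stage_hours for p in profiles],
        "stage": [assign_stage(p.stage_hours) for p in profiles],
        "cluster": labels,
    })
    return {"distances": D, "linkage": Z, "labels": labels, "meta": meta,
            "cut_height": cut_height}
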