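"""Protein-to-marker correlation, Ward clustering and the protein network.

Each protein gets a profile of Spearman correlations to the six CSF AD
markers (Abeta40, Abeta42, Abeta42/40 ratio, t-tau, p-tau, NfL), computed
on pairwise-complete samples of the chosen group, with the correlation to
the albumin CSF/serum quotient kept as a side annotation. Proteins are
then clustered hierarchically on those profiles (Euclidean distance,
Ward.D2 linkage) and the k = 3 cut is labelled semantically: the cluster
with the weakest overall marker correlation is peripheral; of the other
two, the one correlating more with t-tau/p-tau is tau-associated and the
remaining one amyloid-associated. The protein-protein Spearman network
keeps only edges with |rho| strictly above the threshold.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

MARKER_COLS = ["abeta40", "abeta42", "abeta_ratio_x10", "ttau", "ptau", "nfl"]
TAU_MARKERS = ["ttau", "ptau"]
LABELS = ("peripheral", "amyloid_associated", "tau_associated")


def marker_correlations(matrix: pd.DataFrame, markers: pd.DataFrame,
                        sample_ids=None
                        ) -> tuple[pd.DataFrame, pd.Series]:
    """Spearman rho of every protein against the six markers (+ Q-Alb side
    table), on pairwise-complete observations of the selected samples."""
    if sample_ids is not None:
        matrix = matrix.loc[sample_ids]
        markers = markers.loc[sample_ids]
    if len(matrix) < 10:
        raise ValueError("need >= 10 samples for marker correlations")
    corr = {}
    for m in MARKER_COLS + ["qalb"]:
        col = markers[m]
        if col.notna().sum() == 0:
            warnings.warn(f"marker {m!r} entirely missing in group",
                          stacklevel=2)
            corr[m] = pd.Series(np.nan, index=matrix.columns)
            continue
        corr[m] = matrix.corrwith(col, method="spearman")
    corr = pd.DataFrame(corr)
    corr.index.name = "protein"
    return corr[MARKER_COLS], corr["qalb"].rename("rho_qalb")


@dataclass
class ClusterAssignment:
    cluster_id: pd.Series            # protein -> 1..k
    linkage: np.ndarray              # scipy linkage matrix (heights on distance scale)
    k: int
    semantic: pd.Series | None = None  # protein -> block label (k = 3 only)


def ward_cluster(corr: pd.DataFrame, k: int) -> ClusterAssignment:
    """Agglomerative clustering of protein rho-profiles (Euclidean, Ward.D2)
    cut into k clusters."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(corr):
        raise ValueError(f"k = {k} exceeds {len(corr)} proteins")
    if corr.isna().any().any():
        raise ValueError("rho matrix contains missing values")
    X = corr.to_numpy(dtype=float)
    if len(corr) == 1:
        Z = np.empty((0, 4))
        ids = pd.Series([1], index=corr.index, name="cluster_id")
        return ClusterAssignment(ids, Z, k)
    Z = linkage(X, method="ward")
    ids = pd.Series(fcluster(Z, t=k, criterion="maxclust"),
                    index=corr.index, name="cluster_id")
    return ClusterAssignment(ids, Z, k)


def label_clusters(assignment: ClusterAssignment,
                   corr: pd.DataFrame) -> ClusterAssignment:
    """Attach semantic labels to a k = 3 partition.

    Lowest mean |rho| over the six markers -> peripheral; of the remaining
    two clusters the one with higher mean rho to t-tau/p-tau ->
    tau_associated, the other -> amyloid_associated. Exact ties raise.
    """
    ids = assignment.cluster_id
    uniq = sorted(ids.unique())
    if len(uniq) != 3:
        raise ValueError("semantic labelling expects exactly 3 clusters")
    mean_abs = {c: corr.loc[ids[ids == c].index, MARKER_COLS].abs()
                .to_numpy().mean() for c in uniq}
    ranked = sorted(uniq, key=lambda c: mean_abs[c])
    if mean_abs[ranked[0]] == mean_abs[ranked[1]]:
        raise ValueError("tie in peripheral labelling statistic; "
                         "label clusters manually")
    peripheral = ranked[0]
    rest = ranked[1:]
    tau_strength = {c: corr.loc[ids[ids == c].index, TAU_MARKERS]
                    .to_numpy().mean() for c in rest}
    if tau_strength[rest[0]] == tau_strength[rest[1]]:
        raise ValueError("tie in tau/amyloid labelling statistic; "
                         "label clusters manually")
    tau_c = max(rest, key=lambda c: tau_strength[c])
    amy_c = min(rest, key=lambda c: tau_strength[c])
    mapping = {peripheral: "peripheral", tau_c: "tau_associated",
               amy_c: "amyloid_associated"}
    semantic = ids.map(mapping).rename("block")
    return ClusterAssignment(ids, assignment.linkage, assignment.k, semantic)


def correlation_network(matrix: pd.DataFrame, sample_ids=None,
                        threshold: float = 0.5) -> pd.DataFrame:
    """All pairwise protein Spearman correlations; edges with |rho| strictly
    above the threshold, undirected, no self-edges or duplicates."""
    if sample_ids is not None:
        matrix = matrix.loc[sample_ids]
    if len(matrix) < 10:
        raise ValueError("need >= 10 samples for the correlation network")
    rho = matrix.corr(method="spearman")
    prots = list(matrix.columns)
    rows = []
    for i, a in enumerate(prots):
        for b in prots[i + 1:]:
            r = rho.loc[a, b]
            if np.isfinite(r) and abs(r) > threshold:
                rows.append((a, b, float(r)))
    return pd.DataFrame(rows, columns=["protein_a", "protein_b", "rho"])


def export_graphml(edges: pd.DataFrame, path) -> None:
    g = nx.Graph()
    for _, row in edges.iterrows():
        g.add_edge(row["protein_a"], row["protein_b"], rho=float(row["rho"]))
    nx.write_graphml(g, path)
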