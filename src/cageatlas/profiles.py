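"""Tissue expression profiles: MI distance, dendrograms, sharing, mRNA checks.

Expression vectors are discretised into equal-width bins (n = 10 by
default) and pairwise mutual information (plug-in estimate, nats) is
transformed to a distance:

    delta = sqrt(1 - exp(-2 * MI))        (|rho| for bivariate normal)
    d     = 1 - delta

Tissues are grouped by average-linkage hierarchical clustering on this
distance; the dendrogram is exported as Newick.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from skbio import TreeNode

from .clustering import TagClusterSet


class ProfileError(ValueError):
    pass


def bin_profile(values: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Equal-width bin indices over [min, max] of the vector.

    A constant vector maps entirely to bin 0.
    """
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros(len(values), dtype=np.int64)
    idx = np.floor((values - lo) / (hi - lo) * n_bins).astype(np.int64)
    return np.clip(idx, 0, n_bins - 1)


def mutual_information(x_bins: np.ndarray, y_bins: np.ndarray) -> float:
    """Plug-in mutual information (nats) of two binned vectors."""
    x_bins = np.asarray(x_bins)
    y_bins = np.asarray(y_bins)
    if len(x_bins) != len(y_bins):
        raise ProfileError("length mismatch")
    joint = pd.crosstab(x_bins, y_bins).to_numpy().astype(float)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


def mi_distance(mi: float) -> float:
    """d = 1 - sqrt(1 - exp(-2 * MI)); 1 at MI = 0, -> 0 as MI grows."""
    if mi < -1e-12:
        raise ProfileError("MI must be non-negative")
    mi = max(0.0, mi)
    delta = np.sqrt(1.0 - np.exp(-2.0 * mi))
    return float(1.0 - delta)


@dataclass
class MIDistanceMatrix:
    labels: list[str]
    mi: np.ndarray
    distance: np.ndarray

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for lab, row in zip(self.labels, self.distance):
                fh.write(lab + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def mi_distance_matrix(
    matrix: pd.DataFrame, n_bins: int = 10
) -> MIDistanceMatrix:
    """Pairwise MI distances between the columns (tissues) of a matrix."""
    labels = list(matrix.columns)
    binned = np.stack([bin_profile(matrix[c].to_numpy(), n_bins) for c in labels])
    k = len(labels)
    mi = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            mi[i, j] = mi[j, i] = mutual_information(binned[i], binned[j])
    dist = np.vectorize(mi_distance)(mi)
    return MIDistanceMatrix(labels=labels, mi=mi, distance=dist)


def cluster_tissues(
    matrix: pd.DataFrame, n_bins: int = 10
) -> tuple[str, MIDistanceMatrix, np.ndarray]:
    """Average-linkage tissue dendrogram on the MI distance.

    Returns (newick string, distance matrix, linkage matrix).
    """
    if matrix.shape[1] < 3:
        raise ProfileError("need at least 3 tissues")
    dm = mi_distance_matrix(matrix, n_bins)
    off = dm.distance.copy()
    np.fill_diagonal(off, 0.0)
    linkage = hierarchy.average(squareform(off, checks=False))
    tree = TreeNode.from_linkage_matrix(linkage, dm.labels)
    return str(tree).strip(), dm, linkage


def cut_families(linkage: np.ndarray, labels: list[str], k: int) -> dict[str, int]:
    """Cut the dendrogram into k groups; returns label -> group id."""
    assign = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    return dict(zip(labels, (int(a) for a in assign)))


def sharing_matrix(cluster_set: TagClusterSet) -> pd.DataFrame:
    """Tissue x tissue counts of co-present clusters.

    S[t, u] = number of clusters present in both tissues; the diagonal
    is the per-tissue cluster count.  Chord-diagram input.
    """
    presence = cluster_set.presence().astype(np.int64)
    S = presence.T @ presence
    return pd.DataFrame(S, index=cluster_set.sample_ids, columns=cluster_set.sample_ids)


def correlate_cage_mrna(
    cage_ctpm: pd.DataFrame, mrna_tpm: pd.DataFrame
) -> tuple[float, float]:
    """Pearson correlation between matched CAGE and mRNA profiles.

    Rows are matched cluster/transcript pairs, columns the shared
    tissues; values are flattened and correlated.
    """
    common = [c for c in cage_ctpm.columns if c in mrna_tpm.columns]
    if not common:
        raise ProfileError("no shared tissues")
    common_rows = cage_ctpm.index.intersection(mrna_tpm.index)
    if len(common_rows) < 10:
        raise ProfileError("need >= 10 linked pairs")
    x = cage_ctpm.loc[common_rows, common].to_numpy().ravel()
    y = mrna_tpm.loc[common_rows, common].to_numpy().ravel()
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ProfileError("zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def read_kallisto_abundance(path, tissue: str | None = None) -> pd.Series:
    """Read a kallisto abundance table (target_id, tpm columns)."""
    df = pd.read_csv(path, sep="\t")
    if "target_id" not in df.columns or "tpm" not in df.columns:
        raise ProfileError(f"{path}: expected target_id and tpm columns")
    s = df.set_index("target_id")["tpm"]
    s.name = tissue
    return s
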