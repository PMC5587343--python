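"""Cross-dataset concordance: overlap statistics and clustering tests.

Two independent datasets yielding candidate gene sets A and B from a
common evaluable universe of N genes are compared with the upper-tail
hypergeometric probability of observing at least the seen overlap,

    P(X >= k),   X ~ Hypergeometric(N, |A|, |B|),

computed in log space (log-gamma binomials + logsumexp) so that extreme
tails far below double-precision underflow of individual terms remain
accurate.

Group structure is probed by complete-linkage hierarchical clustering of
samples under 1 - Pearson correlation (or Euclidean) distance; the two
main branches (children of the dendrogram root) are cross-tabulated
against the low/high passage groups and tested with a two-tailed Fisher's
exact test.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from scipy.special import gammaln, logsumexp

from .types import BetaMatrix, ExprMatrix, GroupAssignment, SampleTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# hypergeometric overlap
# ---------------------------------------------------------------------------

def _log_binom(n: np.ndarray | int, k: np.ndarray | int) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_overlap_logp(overlap: int, universe: int, size_a: int, size_b: int) -> float:
    """log of the upper-tail P(X >= overlap) for the overlap of two sets."""
    if not (0 <= size_a <= universe and 0 <= size_b <= universe):
        raise ValueError("set sizes must be within the universe")
    k_max = min(size_a, size_b)
    k_min_feasible = max(0, size_a + size_b - universe)
    if overlap > k_max:
        raise ValueError("overlap exceeds the smaller set")
    lo = max(overlap, k_min_feasible)
    if lo > k_max:
        return -np.inf
    ks = np.arange(lo, k_max + 1)
    logs = (
        _log_binom(size_a, ks)
        + _log_binom(universe - size_a, size_b - ks)
        - _log_binom(universe, size_b)
    )
    return float(min(0.0, logsumexp(logs)))


def hypergeom_overlap_pvalue(overlap: int, universe: int, size_a: int, size_b: int) -> float:
    return float(np.exp(hypergeom_overlap_logp(overlap, universe, size_a, size_b)))


@dataclass
class OverlapResult:
    set_a_size: int
    set_b_size: int
    universe_size: int
    overlap: set[str]
    p_value: float
    log10_p: float

    def to_json_dict(self) -> dict:
        return {
            "set_a_size": self.set_a_size,
            "set_b_size": self.set_b_size,
            "universe_size": self.universe_size,
            "overlap": sorted(self.overlap),
            "overlap_size": len(self.overlap),
            "p_value": self.p_value,
            "log10_p": self.log10_p,
        }


def intersect_candidates(a: set[str], b: set[str], universe: int) -> OverlapResult:
    """Overlap of two candidate gene sets with its hypergeometric tail probability.

    ``universe`` must be the number of genes evaluable in *both* datasets
    (it is a required input: overlap significance is meaningless without
    an explicit universe).
    """
    a, b = set(a), set(b)
    if universe < len(a | b):
        raise ValueError(f"universe {universe} smaller than |A ∪ B| = {len(a | b)}")
    overlap = a & b
    logp = hypergeom_overlap_logp(len(overlap), universe, len(a), len(b))
    return OverlapResult(
        set_a_size=len(a),
        set_b_size=len(b),
        universe_size=universe,
        overlap=overlap,
        p_value=float(np.exp(logp)),
        log10_p=float(logp / np.log(10)),
    )


# ---------------------------------------------------------------------------
# hierarchical clustering of samples
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    samples: list[str]
    linkage: np.ndarray
    branches: pd.Series  # sample_id -> 1 | 2 (children of the root)
    distance: str

    def to_newick(self) -> str:
        """Export the dendrogram as a Newick string."""
        tree = hierarchy.to_tree(self.linkage)

        def rec(node) -> str:
            if node.is_leaf():
                return self.samples[node.id]
            left, right = node.get_left(), node.get_right()
            ldist = node.dist - left.dist
            rdist = node.dist - right.dist
            return f"({rec(left)}:{ldist:.6g},{rec(right)}:{rdist:.6g})"

        return rec(tree) + ";"


def hierarchical_cluster(
    matrix: BetaMatrix | ExprMatrix,
    distance: str = "pearson",
    feature_subset: list[str] | None = None,
) -> ClusterResult:
    """Complete-linkage clustering of samples.

    Distance between samples is ``1 - Pearson correlation`` of their
    profiles (default) or Euclidean.  Features (probes) with any missing
    value are dropped before computing distances.  The two main branches
    are the children of the dendrogram root.
    """
    if distance not in ("pearson", "euclidean"):
        raise ValueError("distance must be 'pearson' or 'euclidean'")
    data = matrix.data
    if feature_subset is not None:
        data = data.loc[list(feature_subset)]
    data = data.dropna(axis=0, how="any")
    if data.shape[1] < 4:
        raise ValueError("need >= 4 samples to cluster")
    if data.shape[0] < 2:
        raise ValueError("need >= 2 complete features to cluster")
    obs = data.T.to_numpy()  # samples x features
    samples = list(data.columns)
    if distance == "pearson":
        sd = obs.std(axis=1)
        if (sd == 0).any():
            bad = samples[int(np.argmax(sd == 0))]
            raise ValueError(
                f"sample {bad!r} has a constant profile; Pearson distance undefined"
            )
        d = 1.0 - np.corrcoef(obs)
        np.fill_diagonal(d, 0.0)
        d = (d + d.T) / 2  # enforce exact symmetry against fp jitter
        condensed = squareform(np.clip(d, 0.0, None), checks=False)
    else:
        condensed = pdist(obs, metric="euclidean")
    Z = hierarchy.linkage(condensed, method="complete")
    branches = pd.Series(
        hierarchy.fcluster(Z, t=2, criterion="maxclust"), index=samples, name="branch"
    )
    return ClusterResult(samples=samples, linkage=Z, branches=branches, distance=distance)


# ---------------------------------------------------------------------------
# branch composition tests
# ---------------------------------------------------------------------------

@dataclass
class ClusterTest:
    data_kind: str
    distance: str
    linkage: str
    branch_counts: list[list[int]]  # 2x2: branch x (low, high)
    fisher_p: float
    stratum: str | None = None

    def to_json_dict(self) -> dict:
        return {
            "data_kind": self.data_kind,
            "distance": self.distance,
            "linkage": self.linkage,
            "branch_counts": self.branch_counts,
            "fisher_p": self.fisher_p,
            "stratum": self.stratum,
        }


def branch_composition_test(
    branches: pd.Series,
    groups: GroupAssignment,
    data_kind: str = "",
    distance: str = "",
) -> ClusterTest:
    """Two-tailed Fisher's exact test on the branch x passage-group table.

    The two-tailed p-value is the sum of probabilities of all tables with
    the observed margins whose probability does not exceed the observed
    table's.  Degenerate margins (all samples in one group or one branch)
    give p = 1 with a warning.
    """
    labels = groups.labels.reindex(branches.index)
    if labels.isna().any():
        missing = list(branches.index[labels.isna()])[:5]
        raise ValueError(f"samples without group label: {missing}")
    table = np.zeros((2, 2), dtype=int)
    for br in (1, 2):
        in_br = branches == br
        table[br - 1, 0] = int((in_br & (labels == "low")).sum())
        table[br - 1, 1] = int((in_br & (labels == "high")).sum())
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        warnings.warn("degenerate margin in branch composition table; p = 1", stacklevel=2)
        p = 1.0
    else:
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return ClusterTest(
        data_kind=data_kind,
        distance=distance,
        linkage="complete",
        branch_counts=table.tolist(),
        fisher_p=p,
    )


def stratified_clustering(
    matrix: BetaMatrix | ExprMatrix,
    samples: SampleTable,
    groups: GroupAssignment,
    stratify_by: str = "sex",
    distance: str = "pearson",
    data_kind: str = "",
    min_stratum: int = 4,
) -> list[ClusterTest]:
    """Cluster and test within each stratum (e.g. per sex).

    ``stratify_by='none'`` runs a single unstratified analysis.  Strata
    with fewer than ``min_stratum`` samples are skipped with a warning.
    """
    if stratify_by not in ("sex", "none"):
        raise ValueError("stratify_by must be 'sex' or 'none'")
    cols = [s for s in matrix.data.columns if s in samples.data.index]
    if stratify_by == "none":
        strata = {"all": cols}
    else:
        sex = samples.data.loc[cols, "sex"]
        strata = {str(v): list(sex.index[sex == v]) for v in sex.unique()}
    results = []
    for name, members in sorted(strata.items()):
        if len(members) < min_stratum:
            warnings.warn(
                f"stratum {name!r} has {len(members)} samples (< {min_stratum}); skipped",
                stacklevel=2,
            )
            continue
        sub = type(matrix)(matrix.data[members])
        res = hierarchical_cluster(sub, distance=distance)
        test = branch_composition_test(
            res.branches, groups, data_kind=data_kind, distance=distance
        )
        test.stratum = name
        results.append(test)
    return results
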