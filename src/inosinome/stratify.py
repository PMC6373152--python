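"""Inosinome-based tumor stratification and ordination.

Tumors are stratified on editing alone: sites detected in nearly every tumor
(default >= 140/145 of samples) and lying in genic features (exon, intron,
UTR) define the signature; Euclidean distances between sample editing
profiles are clustered agglomeratively with the classic Ward criterion
applied to the *unsquared* distances (the "ward.D" linkage of R's hclust,
reproduced here via the Lance-Williams recurrence since SciPy only ships the
squared-distance Ward-D2 variant).  Cutting the dendrogram at k = 2 yields
the two editing subgroups; the cluster with the higher grand-mean editing
over the signature sites is INO-1, the lower one INO-2.

Ordination of whole cohorts uses Kruskal's nonmetric multidimensional
scaling on 1 − Spearman-ρ dissimilarities between sample profiles, with an
explicit SMACOF loop (isotonic regression of configuration distances on
dissimilarity order, then a Guttman transform) so the stress trajectory is
available to callers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

from .model import NONREP, EditingMatrix, GenomicSite
from .differential import benjamini_hochberg, mann_whitney_u_two_tailed, support_mask

INO1 = "INO-1"
INO2 = "INO-2"

#: detection rule: fraction of samples in which a signature site must be seen
DEFAULT_MIN_DETECTED_FRACTION = 140 / 145
DEFAULT_ALLOWED_FEATURES = ("exon", "intron", "UTR")


# ---------------------------------------------------------------------------
# Signature-site selection and distances
# ---------------------------------------------------------------------------


def select_stratification_sites(matrix: EditingMatrix,
                                min_detected: float | int = DEFAULT_MIN_DETECTED_FRACTION,
                                allowed_features: tuple[str, ...] = DEFAULT_ALLOWED_FEATURES,
                                ) -> list[GenomicSite]:
    """Sites detected (non-missing) in enough samples and in allowed features.

    ``min_detected`` below 1 is read as a fraction of the cohort (rounded up),
    so the 140-of-145 rule transfers to cohorts of any size.
    """
    n = len(matrix.samples)
    if min_detected < 1:
        threshold = int(np.ceil(min_detected * n))
    else:
        threshold = int(min_detected)
    if threshold > n:
        raise ValueError(f"min_detected={threshold} exceeds cohort size {n}")
    detected = matrix.freq.notna().sum(axis=0)
    allowed = set(allowed_features)
    return [s for s in matrix.sites
            if detected[s.label] >= threshold and s.feature in allowed]


def impute_site_median(freq: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Fill missing cells with the per-site median; returns the fill count."""
    n_missing = int(freq.isna().to_numpy().sum())
    filled = freq.fillna(freq.median(axis=0))
    if filled.isna().any().any():
        raise ValueError("site with no observed value cannot be imputed")
    return filled, n_missing


def euclidean_distance_matrix(freq: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Euclidean sample-distance matrix; rejects missing cells."""
    if freq.isna().any().any():
        raise ValueError("distance matrix requires a fully imputed matrix")
    d = squareform(pdist(freq.to_numpy(dtype=float), metric="euclidean"))
    return pd.DataFrame(d, index=freq.index, columns=freq.index)


# ---------------------------------------------------------------------------
# ward.D agglomeration (Lance-Williams on unsquared distances)
# ---------------------------------------------------------------------------


def ward_hierarchical_clustering(distances: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Agglomerate with the ward.D criterion; returns a SciPy-style linkage.

    The Lance-Williams update is applied directly to the input distances
    (not their squares):

        d(u∪v, w) = [(n_u+n_w) d(u,w) + (n_v+n_w) d(v,w) − n_w d(u,v)]
                    / (n_u+n_v+n_w)

    Ties in the minimum pairwise distance are broken on the smallest pair of
    cluster ids, so the merge order is deterministic.  Output rows are
    ``(id_a, id_b, height, size)`` with leaves numbered 0..n−1 and the merge
    of step t numbered n+t, as in ``scipy.cluster.hierarchy.linkage``.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least two samples to cluster")
    d = d.copy()
    sizes = {i: 1 for i in range(n)}
    index_of = {i: i for i in range(n)}  # cluster id -> row in d
    active = list(range(n))
    Z = np.zeros((n - 1, 4))
    for step in range(n - 1):
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                dist = d[index_of[a], index_of[b]]
                if best is None or dist < best[0] or \
                        (dist == best[0] and (a, b) < (best[1], best[2])):
                    best = (dist, a, b)
        dist, a, b = best  # type: ignore[misc]
        na, nb = sizes[a], sizes[b]
        new_id = n + step
        ia, ib = index_of[a], index_of[b]
        # Lance-Williams row update in place on cluster a's row
        for c in active:
            if c in (a, b):
                continue
            ic = index_of[c]
            nc = sizes[c]
            upd = ((na + nc) * d[ia, ic] + (nb + nc) * d[ib, ic] - nc * dist) \
                / (na + nb + nc)
            d[ia, ic] = d[ic, ia] = upd
        Z[step] = (min(a, b), max(a, b), dist, na + nb)
        sizes[new_id] = na + nb
        index_of[new_id] = ia
        active.remove(a)
        active.remove(b)
        active.append(new_id)
        del sizes[a], sizes[b], index_of[a], index_of[b]
    return Z


def cut_tree(merge_tree: np.ndarray, k: int) -> np.ndarray:
    """Labels from the first n−k merges of the tree (k clusters).

    Implemented by union-find over the merge order rather than a height
    threshold, so it stays well-defined even if a linkage carries inversions.
    """
    n = merge_tree.shape[0] + 1
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step in range(n - k):
        a, b = int(merge_tree[step, 0]), int(merge_tree[step, 1])
        new = n + step
        parent[find(a)] = new
        parent[find(b)] = new
    roots = {}
    labels = np.zeros(n, dtype=int)
    for i in range(n):
        r = find(i)
        labels[i] = roots.setdefault(r, len(roots))
    return labels


def merge_tree_to_newick(merge_tree: np.ndarray, leaf_names: list[str]) -> str:
    """Render the dendrogram as a Newick string with merge heights as depths."""
    n = merge_tree.shape[0] + 1
    height = {i: 0.0 for i in range(n)}
    node = {i: leaf_names[i] for i in range(n)}
    for step in range(n - 1):
        a, b, h = int(merge_tree[step, 0]), int(merge_tree[step, 1]), merge_tree[step, 2]
        la = max(h - height[a], 0.0)
        lb = max(h - height[b], 0.0)
        node[n + step] = f"({node[a]}:{la:.6g},{node[b]}:{lb:.6g})"
        height[n + step] = h
    return node[2 * n - 2] + ";"


# ---------------------------------------------------------------------------
# INO labelling
# ---------------------------------------------------------------------------


@dataclass
class StratificationResult:
    labels: pd.Series  # sample -> INO-1 / INO-2
    merge_tree: np.ndarray
    sites_used: list[GenomicSite]
    n_imputed: int = 0
    cluster_means: dict[str, float] = field(default_factory=dict)


def assign_ino_labels(cluster_labels: np.ndarray, matrix: EditingMatrix,
                      sites_used: list[GenomicSite],
                      merge_tree: np.ndarray | None = None,
                      n_imputed: int = 0) -> StratificationResult:
    """Name the higher-editing cluster INO-1 and the other INO-2.

    The grand mean of the observed editing frequencies over the signature
    sites decides; on an exact tie the cluster holding the lexicographically
    smallest sample id becomes INO-1 (with a warning).
    """
    unique = np.unique(cluster_labels)
    if unique.size != 2:
        raise ValueError(f"expected exactly 2 clusters, got {unique.size}")
    labels_arr = np.asarray(cluster_labels)
    sub = matrix.freq[[s.label for s in sites_used]]
    means = {}
    for c in unique:
        members = np.asarray(matrix.samples)[labels_arr == c]
        means[c] = float(np.nanmean(sub.loc[members].to_numpy()))
    c0, c1 = unique
    if means[c0] == means[c1]:
        warnings.warn("tied cluster means; INO-1 set by smallest sample id",
                      stacklevel=2)
        first0 = min(np.asarray(matrix.samples)[labels_arr == c0])
        first1 = min(np.asarray(matrix.samples)[labels_arr == c1])
        high = c0 if first0 < first1 else c1
    else:
        high = c0 if means[c0] > means[c1] else c1
    named = pd.Series([INO1 if c == high else INO2 for c in labels_arr],
                      index=matrix.samples, name="ino_group")
    cluster_means = {INO1 if c == high else INO2: means[c] for c in unique}
    return StratificationResult(
        labels=named,
        merge_tree=merge_tree if merge_tree is not None else np.zeros((0, 4)),
        sites_used=sites_used,
        n_imputed=n_imputed,
        cluster_means=cluster_means,
    )


def stratify_inosinome(matrix: EditingMatrix,
                       min_detected: float | int = DEFAULT_MIN_DETECTED_FRACTION,
                       allowed_features: tuple[str, ...] = DEFAULT_ALLOWED_FEATURES,
                       k: int = 2) -> StratificationResult:
    """End-to-end stratification: site selection, imputation, ward.D, labels."""
    sites = select_stratification_sites(matrix, min_detected, allowed_features)
    if len(sites) < 2:
        raise ValueError("fewer than 2 signature sites pass the detection gate")
    freq = matrix.freq[[s.label for s in sites]]
    filled, n_imputed = impute_site_median(freq)
    dist = euclidean_distance_matrix(filled)
    tree = ward_hierarchical_clustering(dist)
    labels = cut_tree(tree, k)
    return assign_ino_labels(labels, matrix, sites, merge_tree=tree,
                             n_imputed=n_imputed)


# ---------------------------------------------------------------------------
# Subtype-differential site discovery (DEI site list)
# ---------------------------------------------------------------------------


def discover_subtype_differential_sites(matrix: EditingMatrix,
                                        subtypes: pd.Series,
                                        alpha: float = 0.05,
                                        min_coverage: int = 10,
                                        min_frequency: float = 0.01,
                                        use_bh: bool = True) -> list[GenomicSite]:
    """Non-repetitive sites separating at least one pair of expression subtypes.

    Every pairwise subtype contrast is tested per site with the two-tailed
    Mann-Whitney U; multiplicity is controlled across sites within each
    contrast (BH by default, raw p with ``use_bh=False``).  A site enters the
    discriminating list as soon as one contrast is significant.  Subtypes
    with fewer than two samples are skipped with a warning.
    """
    subtypes = subtypes.reindex(matrix.samples).dropna()
    names = sorted(subtypes.unique())
    usable = [s for s in names if (subtypes == s).sum() >= 2]
    for s in set(names) - set(usable):
        warnings.warn(f"subtype {s!r} has <2 samples; its contrasts are skipped",
                      stacklevel=2)
    if len(usable) < 2:
        raise ValueError("need at least two subtypes with >= 2 samples")
    nonrep = [s for s in matrix.sites if s.region_class == NONREP]
    mask = support_mask(matrix, min_coverage, min_frequency)
    selected: set[str] = set()
    for i in range(len(usable)):
        for j in range(i + 1, len(usable)):
            g1 = list(subtypes.index[subtypes == usable[i]])
            g2 = list(subtypes.index[subtypes == usable[j]])
            labels, pvals = [], []
            for site in nonrep:
                col = matrix.freq[site.label]
                m = mask[site.label]
                v1 = col.loc[g1][m.loc[g1]].to_numpy(dtype=float)
                v2 = col.loc[g2][m.loc[g2]].to_numpy(dtype=float)
                if v1.size < 2 or v2.size < 2:
                    continue
                labels.append(site.label)
                pvals.append(mann_whitney_u_two_tailed(v1, v2)[1])
            if not labels:
                continue
            crit = benjamini_hochberg(pvals) if use_bh else np.asarray(pvals)
            selected.update(l for l, q in zip(labels, crit) if q <= alpha)
    by_label = matrix.site_by_label()
    return sorted((by_label[l] for l in selected), key=lambda s: s.key)


# ---------------------------------------------------------------------------
# Nonmetric MDS on Spearman dissimilarities
# ---------------------------------------------------------------------------


@dataclass
class OrdinationResult:
    coords: pd.DataFrame  # samples x n_dims, centered
    stress: float  # Kruskal stress-1 of the best restart
    stress_trace: list[float]  # per-iteration stress of the best restart
    dissimilarity_used: str = "1 - spearman rho"


def spearman_dissimilarity(matrix: EditingMatrix) -> pd.DataFrame:
    """1 − Spearman-ρ between sample editing profiles (pairwise complete)."""
    freq_t = matrix.freq.T  # sites x samples: corr() correlates columns
    constant = freq_t.nunique(dropna=True) <= 1
    if constant.any():
        bad = list(freq_t.columns[constant])
        raise ValueError(f"constant editing profile, rho undefined: {bad[0]}")
    rho = freq_t.corr(method="spearman", min_periods=3)
    if rho.isna().any().any():
        raise ValueError("Spearman correlation undefined for some sample pair")
    d = 1.0 - rho
    np.fill_diagonal(d.to_numpy(), 0.0)
    return d


def _kruskal_stress(dist: np.ndarray, disp: np.ndarray) -> float:
    denom = float(np.sum(dist ** 2))
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((dist - disp) ** 2) / denom))


def _nmds_single(diss: np.ndarray, n_dims: int, rng: np.random.Generator,
                 init: np.ndarray | None, max_iter: int,
                 tol: float) -> tuple[np.ndarray, float, list[float]]:
    n = diss.shape[0]
    iu = np.triu_indices(n, 1)
    delta = diss[iu]
    order = np.argsort(delta, kind="stable")
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    X = init if init is not None else rng.normal(size=(n, n_dims))
    X = X - X.mean(axis=0)
    trace: list[float] = []
    prev = np.inf
    for _ in range(max_iter):
        dist = squareform(pdist(X))[iu]
        disp = np.empty_like(dist)
        disp[order] = iso.fit_transform(np.arange(order.size), dist[order])
        stress = _kruskal_stress(dist, disp)
        trace.append(stress)
        if prev - stress < tol:
            break
        prev = stress
        # Guttman transform toward the disparities
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, disp / dist, 0.0)
        B = np.zeros((n, n))
        B[iu] = -ratio
        B = B + B.T
        np.fill_diagonal(B, -B.sum(axis=1))
        X = (B @ X) / n
        X = X - X.mean(axis=0)
    return X, trace[-1], trace


def _classical_mds_init(diss: np.ndarray, n_dims: int) -> np.ndarray:
    n = diss.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (diss ** 2) @ J
    w, v = np.linalg.eigh(B)
    idx = np.argsort(w)[::-1][:n_dims]
    lam = np.clip(w[idx], 0, None)
    return v[:, idx] * np.sqrt(lam)


def nmds_ordination(matrix: EditingMatrix | pd.DataFrame, n_dims: int = 2,
                    seed: int = 0, n_restarts: int = 20, max_iter: int = 300,
                    tol: float = 1e-7) -> OrdinationResult:
    """Kruskal nonmetric MDS of samples on 1 − Spearman-ρ dissimilarities.

    A precomputed square dissimilarity DataFrame may be passed instead of an
    editing matrix.  The first start is the classical-scaling configuration,
    the rest are random; the restart with the lowest final stress-1 wins.
    Deterministic under a fixed seed.
    """
    if isinstance(matrix, EditingMatrix):
        diss_df = spearman_dissimilarity(matrix)
        desc = "1 - spearman rho"
    else:
        diss_df = matrix
        desc = "precomputed"
    samples = list(diss_df.index)
    diss = diss_df.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, float, list[float]] | None = None
    for restart in range(max(n_restarts, 1)):
        init = _classical_mds_init(diss, n_dims) if restart == 0 else None
        X, stress, trace = _nmds_single(diss, n_dims, rng, init, max_iter, tol)
        if best is None or stress < best[1]:
            best = (X, stress, trace)
    X, stress, trace = best  # type: ignore[misc]
    coords = pd.DataFrame(X - X.mean(axis=0), index=samples,
                          columns=[f"dim{i+1}" for i in range(n_dims)])
    return OrdinationResult(coords=coords, stress=stress, stress_trace=trace,
                            dissimilarity_used=desc)
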