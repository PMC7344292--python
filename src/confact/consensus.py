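"""Consensus ensemble subtyping.

Every factor representation of every omics is clustered with k-means (best
of many starts, cluster count chosen by an explained-variance plateau
rule), producing a binary connectivity matrix per representation. A
weighted meta-clustering then merges them:

1. pair weight s_ij = mean connectivity over all matrices (the consensus
   matrix: co-clustering frequency);
2. patient weight v_i = Σ_{j≠i} s_ij (how consistently patient i co-travels
   with the rest of the cohort);
3. all clusters from all partitions are pooled; cluster-cluster similarity
   is the patient-weighted Jaccard sim(A,B) = Σ_{i∈A∩B} v_i / Σ_{i∈A∪B} v_i;
4. average-linkage hierarchical clustering on 1 − sim cuts the pooled
   clusters into k_final meta-clusters;
5. each patient joins the meta-cluster holding the plurality of its source
   clusters (ties go to the meta-cluster with the larger summed similarity
   to the patient's clusters).

When every partition agrees this reduces to plain consensus clustering:
the consensus matrix is binary and the final labels reproduce the shared
partition.
"""

from __future__ import annotations

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .config import RunConfig
from .datatypes import (
    ConnectivityMatrix,
    FactorRepresentation,
    OmicsMatrix,
    Partition,
    SubtypeResult,
)
from .errors import ValidationError
from .factor import generate_representations
from .feature_filter import apply_filter
from .rng import derive_seed

__all__ = [
    "optimal_cluster_count",
    "cluster_representation",
    "connectivity_matrix",
    "weighted_meta_cluster",
    "subtype",
]


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Renumber cluster ids 1..k in order of first patient occurrence."""
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def _best_kmeans(x: np.ndarray, k: int, n_starts: int, seed: int):
    """k-means from ``n_starts`` seeded initializations; smallest SSE wins."""
    best = None
    for s in range(n_starts):
        km = KMeans(n_clusters=k, n_init=1, random_state=derive_seed(seed, "start", s)).fit(x)
        if best is None or km.inertia_ < best.inertia_:
            best = km
    return best


def optimal_cluster_count(
    rep: FactorRepresentation,
    k_min: int = 2,
    k_max: int = 10,
    n_starts: int = 20,
    seed: int = 0,
    delta: float = 0.05,
) -> int:
    """Choose the cluster count by the explained-variance plateau.

    For each k, r_k = BSS/TSS of the best k-means run (equivalently
    1 − WSS/TSS, so the gain r_{k+1} − r_k is the drop in within-cluster
    sum of squares). Returns the smallest k whose gain falls below
    ``delta``, or ``k_max`` when the ratio keeps climbing.
    """
    x = rep.scores
    n = x.shape[0]
    k_max = min(k_max, n - 1)
    if not (2 <= k_min <= k_max):
        raise ValidationError(f"invalid cluster-count range [{k_min}, {k_max}]")
    if k_min == k_max:
        return k_min
    tss = float(((x - x.mean(axis=0)) ** 2).sum())
    if tss == 0:
        return k_min
    r = {}
    for k in range(k_min, k_max + 2):
        if k > n - 1:
            break
        km = _best_kmeans(x, k, n_starts, derive_seed(seed, "optk", k))
        r[k] = 1.0 - km.inertia_ / tss
    ks = sorted(r)
    for k in ks[:-1]:
        if r[k + 1] - r[k] < delta:
            return k
    return k_max


def cluster_representation(
    rep: FactorRepresentation, k: int, n_starts: int = 20, seed: int = 0
) -> Partition:
    """Best-of-``n_starts`` k-means partition of the factor scores."""
    x = rep.scores
    n = x.shape[0]
    if not (2 <= k <= n - 1):
        raise ValidationError(f"k must lie in [2, {n - 1}], got {k}")
    if np.unique(x, axis=0).shape[0] < k:
        raise ValidationError(f"k={k} exceeds the number of distinct points")
    km = _best_kmeans(x, k, n_starts, seed)
    labels = _canonical_labels(km.labels_ + 1)
    src = rep.source or {}
    return Partition(
        labels=labels,
        k=k,
        sse=float(km.inertia_),
        source=f"{src.get('data_type', '?')}/k={src.get('k', rep.k)}",
    )


def connectivity_matrix(p: Partition) -> ConnectivityMatrix:
    """Binary co-membership matrix: 1 iff two patients share a cluster."""
    lab = p.labels
    return ConnectivityMatrix((lab[:, None] == lab[None, :]).astype(float))


def _auto_k_final(partitions: list[Partition]) -> int:
    ks = np.array([p.k for p in partitions])
    counts = np.bincount(ks)
    return int(np.flatnonzero(counts == counts.max())[0])  # mode, ties → smaller k


def weighted_meta_cluster(
    connectivities: list[ConnectivityMatrix],
    partitions: list[Partition],
    k_final="auto",
) -> SubtypeResult:
    """Merge an ensemble of partitions into final subtypes (steps 1–5 above)."""
    if not connectivities or len(connectivities) != len(partitions):
        raise ValidationError("need equal, non-empty lists of connectivities and partitions")
    n = connectivities[0].values.shape[0]
    for cm in connectivities:
        if cm.values.shape[0] != n:
            raise ValidationError("connectivity matrices cover different patient sets")
    for p in partitions:
        if len(p.labels) != n:
            raise ValidationError("partition length does not match patient count")

    consensus = np.mean([cm.values for cm in connectivities], axis=0)
    v = consensus.sum(axis=1) - np.diag(consensus)  # patient weights

    # pooled clusters as boolean membership masks
    masks = []
    owner = []  # (partition index, cluster id)
    for pi, p in enumerate(partitions):
        for cid in range(1, p.k + 1):
            masks.append(p.labels == cid)
            owner.append((pi, cid))
    m = len(masks)
    mask_arr = np.asarray(masks)  # m × n

    inter = (mask_arr * v) @ mask_arr.T
    tot = (mask_arr * v).sum(axis=1)
    union = tot[:, None] + tot[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / union, 0.0)
    np.fill_diagonal(sim, 1.0)
    sim = np.clip((sim + sim.T) / 2.0, 0.0, 1.0)

    if k_final == "auto":
        kf = _auto_k_final(partitions)
    else:
        kf = int(k_final)
    kf = max(2, min(kf, m))

    if m == 1:
        meta = np.array([1])
    else:
        z = linkage(squareform(1.0 - sim, checks=False), method="average")
        meta = fcluster(z, t=kf, criterion="maxclust")

    n_meta = meta.max()
    # patient -> meta-cluster by plurality of its source clusters
    votes = np.zeros((n, n_meta))
    for ci, mc in enumerate(meta):
        votes[mask_arr[ci], mc - 1] += 1.0
    # tie-break: summed similarity between each meta-cluster's member
    # clusters and the patient's own source clusters
    cluster_sim_to_meta = np.zeros((m, n_meta))
    for mc in range(1, n_meta + 1):
        cluster_sim_to_meta[:, mc - 1] = sim[:, meta == mc].sum(axis=1)
    simsum = mask_arr.T.astype(float) @ cluster_sim_to_meta

    labels = np.empty(n, dtype=int)
    for i in range(n):
        top = votes[i].max()
        cand = np.flatnonzero(votes[i] == top)
        if len(cand) > 1:
            best = cand[np.argmax(simsum[i, cand])]
        else:
            best = cand[0]
        labels[i] = best + 1
    labels = _canonical_labels(labels)

    consensus_out = consensus.copy()
    np.fill_diagonal(consensus_out, 1.0)
    return SubtypeResult(
        labels=labels,
        k_final=kf,
        consensus=consensus_out,
        partitions=partitions,
        patient_weights=v,
    )


def build_ensemble(
    omics: list[OmicsMatrix], cfg: RunConfig
) -> tuple[list[ConnectivityMatrix], list[Partition]]:
    """Filter → factor representations → per-representation partition and
    connectivity, for every omics."""
    connectivities: list[ConnectivityMatrix] = []
    partitions: list[Partition] = []
    for m in omics:
        fm = apply_filter(m, cfg.filter, derive_seed(cfg.seed, "filter", m.data_type))
        n = fm.n_patients
        counts = [k for k in cfg.fa.factor_counts if k <= n - 1]
        reps = generate_representations(fm, counts, cfg.fa.max_iter, cfg.fa.tol)
        for rep in reps:
            rseed = derive_seed(cfg.seed, "cluster", m.data_type, rep.k)
            k_opt = optimal_cluster_count(
                rep, cfg.cluster.k_min, cfg.cluster.k_max, cfg.cluster.n_starts,
                rseed, cfg.cluster.delta,
            )
            part = cluster_representation(rep, k_opt, cfg.cluster.n_starts, rseed)
            partitions.append(part)
            connectivities.append(connectivity_matrix(part))
    return connectivities, partitions


def align_omics(omics: list[OmicsMatrix]) -> list[OmicsMatrix]:
    """Align all omics to the first matrix's patient order (by ID)."""
    ref = omics[0].patient_ids
    ref_set = set(ref)
    for m in omics[1:]:
        diff = ref_set.symmetric_difference(m.patient_ids)
        if diff:
            raise ValidationError(
                f"patient-ID mismatch across omics; offenders include {sorted(diff)[:5]}"
            )
    return [omics[0]] + [m.reindex_patients(ref) for m in omics[1:]]


def subtype(dataset: list[OmicsMatrix], config: RunConfig | None = None) -> SubtypeResult:
    """End-to-end consensus subtyping of a multi-omics dataset."""
    if not dataset:
        raise ValidationError("need at least one omics matrix")
    for m in dataset:
        if m.n_patients < 10:
            raise ValidationError(f"{m.data_type}: fewer than 10 patients")
    cfg = (config or RunConfig()).validate()
    omics = align_omics(dataset)
    connectivities, partitions = build_ensemble(omics, cfg)
    result = weighted_meta_cluster(connectivities, partitions, cfg.cluster.k_final)
    result.patient_ids = omics[0].patient_ids
    return result
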