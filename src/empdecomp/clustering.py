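"""Mental-health profiles: Gower dissimilarity + PAM (k-medoids) clustering.

Nine mixed-type indicators (six binary disorder/suicidality flags, two 5-point
ordinals, one 3-level ordinal for positive mental health) are combined with
Gower's coefficient — match/mismatch for binaries, range-normalized absolute
difference for ordinals, averaged over the variables observed in both rows —
and partitioned around medoids with the classic BUILD initialization and SWAP
refinement. With k=4 the clusters are labelled by their indicator composition:
flourishing with no life stress, flourishing with some life stress, moderate
mental health and stress, and clinical mood disorder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import MH_BINARY_ITEMS, POSITIVE_MH_LEVELS

PROFILE_LABELS = (
    "flourishing_no_stress",
    "flourishing_some_stress",
    "moderate_mh_stress",
    "clinical_mood_disorder",
)

#: (column, kind, range) descriptors of the nine indicators. Ordinal ranges are
#: max-min of the declared support.
MH_VARIABLE_SPEC: tuple[tuple[str, str, float], ...] = tuple(
    [(c, "binary", 1.0) for c in MH_BINARY_ITEMS]
    + [("self_rated_mental_health", "ordinal", 4.0),
       ("life_stress", "ordinal", 4.0),
       ("positive_mental_health", "ordinal_levels", 2.0)]
)

_PMH_CODE = {lab: float(i) for i, lab in enumerate(POSITIVE_MH_LEVELS)}


def _numeric_matrix(items: pd.DataFrame,
                    spec=MH_VARIABLE_SPEC) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Items -> (values, observed mask, ranges); ordinal levels coded 0..L-1."""
    cols = []
    obs = []
    ranges = []
    for name, kind, rng in spec:
        if name not in items.columns:
            raise KeyError(f"missing indicator column {name!r}")
        col = items[name]
        if kind == "ordinal_levels":
            v = col.map(_PMH_CODE).to_numpy(dtype=float)
        else:
            v = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
        cols.append(v)
        obs.append(np.isfinite(v))
        ranges.append(rng)
    return np.column_stack(cols), np.column_stack(obs), np.asarray(ranges)


def gower_matrix(items: pd.DataFrame, spec=MH_VARIABLE_SPEC) -> np.ndarray:
    """Pairwise Gower dissimilarities in [0, 1] with pairwise deletion.

    Variables missing in either row of a pair are dropped and the mean is
    renormalized over the rest; a pair with no shared observed variable raises.
    """
    V, M, R = _numeric_matrix(items, spec)
    n = len(items)
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for j, (name, kind, rng) in enumerate(spec):
        v = V[:, j]
        m = M[:, j]
        if kind == "binary":
            d = (v[:, None] != v[None, :]).astype(float)
        else:
            d = np.abs(v[:, None] - v[None, :]) / R[j]
        both = m[:, None] & m[None, :]
        num += np.where(both, d, 0.0)
        den += both
    if (den == 0).any():
        i, jj = np.argwhere(den == 0)[0]
        raise ValueError(f"rows {i} and {jj} share no observed indicator; "
                         "Gower distance undefined")
    D = num / den
    np.fill_diagonal(D, 0.0)
    return D


def gower_distance(a: pd.Series | dict, b: pd.Series | dict,
                   spec=MH_VARIABLE_SPEC) -> float:
    """Gower dissimilarity between two records (see :func:`gower_matrix`)."""
    df = pd.DataFrame([dict(a), dict(b)])
    return float(gower_matrix(df, spec)[0, 1])


@dataclass
class ClusterSolution:
    """A PAM partition: medoid row indices, assignments, and total cost."""

    medoids: np.ndarray
    labels: np.ndarray              # medoid position in `medoids` per row
    cost: float
    label_names: dict[int, str] | None = None

    def named_labels(self) -> np.ndarray:
        if self.label_names is None:
            raise ValueError("clusters have not been labelled yet")
        return np.asarray([self.label_names[int(l)] for l in self.labels], dtype=object)


def _validate_dissimilarity(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if (D < 0).any():
        raise ValueError("dissimilarity matrix has negative entries")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("dissimilarity matrix must be symmetric")
    return D


def pam(D: np.ndarray, k: int, seed=None) -> ClusterSolution:
    """Partitioning Around Medoids: BUILD then SWAP to a local optimum.

    Deterministic: ties in BUILD and SWAP are broken toward the lowest row
    index (lexicographic (medoid, candidate) order in SWAP); ``seed`` is
    accepted for interface compatibility but unused.
    """
    D = _validate_dissimilarity(D)
    n = D.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside 1..{n}")

    # BUILD: start from the row minimizing total dissimilarity, then greedily
    # add the medoid giving the largest cost reduction.
    medoids = [int(np.argmin(D.sum(axis=1)))]
    nearest = D[medoids[0]].copy()
    while len(medoids) < k:
        gains = np.minimum(D, nearest[None, :]).sum(axis=1)
        gains[medoids] = np.inf
        best = int(np.argmin(gains))
        medoids.append(best)
        nearest = np.minimum(nearest, D[best])

    medoids = sorted(medoids)
    cost = float(D[medoids].min(axis=0).sum()) if k > 1 else float(D[medoids[0]].sum())

    # SWAP: replace one medoid by one non-medoid while any swap strictly
    # reduces the cost; take the globally best swap each pass.
    while True:
        med_arr = np.asarray(medoids)
        dist_to_meds = D[med_arr]                 # k x n
        best_delta = -1e-12
        best_swap = None
        for mi, m in enumerate(medoids):
            if k > 1:
                others = np.delete(dist_to_meds, mi, axis=0).min(axis=0)
            else:
                others = np.full(n, np.inf)
            cand = np.setdiff1d(np.arange(n), med_arr, assume_unique=False)
            # cost after swapping m -> h, for all h at once
            after = np.minimum(D[:, cand], others[:, None]).sum(axis=0)
            deltas = after - cost
            order = np.argsort(cand)  # cand already sorted; keep explicit
            for pos in order:
                if deltas[pos] < best_delta - 1e-15:
                    best_delta = float(deltas[pos])
                    best_swap = (mi, int(cand[pos]))
        if best_swap is None:
            break
        mi, h = best_swap
        medoids[mi] = h
        medoids = sorted(medoids)
        cost += best_delta
        cost = float(D[np.asarray(medoids)].min(axis=0).sum())

    med_arr = np.asarray(medoids)
    labels = np.argmin(D[med_arr], axis=0)
    cost = float(D[med_arr, :][labels, np.arange(n)].sum())
    return ClusterSolution(medoids=med_arr, labels=labels, cost=cost)


def cluster_statistics(solution: ClusterSolution, items: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster indicator composition (prevalence/mean of each indicator)."""
    V, M, _ = _numeric_matrix(items)
    rows = {}
    for ci in range(len(solution.medoids)):
        mask = solution.labels == ci
        vals = np.where(M[mask], V[mask], np.nan)
        rows[ci] = np.nanmean(vals, axis=0)
    cols = [name for name, _, _ in MH_VARIABLE_SPEC]
    stats = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    # flourishing prevalence (top positive-mental-health level)
    pmh = items["positive_mental_health"].astype(object)
    stats["flourishing_prev"] = [
        float((pmh[solution.labels == ci] == "flourishing").mean())
        for ci in range(len(solution.medoids))
    ]
    return stats


def label_clusters(solution: ClusterSolution, items: pd.DataFrame) -> ClusterSolution:
    """Name the four clusters from their indicator composition.

    Highest mood-disorder prevalence -> clinical mood disorder; among the rest
    the lowest flourishing prevalence -> moderate mental health and stress; the
    remaining two are split by mean life stress (lower -> the no-stress
    profile). Ties in any deciding statistic raise.
    """
    if len(solution.medoids) != 4:
        raise ValueError("labelling requires exactly 4 clusters")
    stats = cluster_statistics(solution, items)

    def _argmax_unique(s: pd.Series, what: str) -> int:
        top = s.max()
        winners = s[s == top].index.tolist()
        if len(winners) > 1:
            raise ValueError(f"tie on {what} between clusters {winners}")
        return int(winners[0])

    names: dict[int, str] = {}
    clinical = _argmax_unique(stats["mood_disorder"], "mood-disorder prevalence")
    names[clinical] = "clinical_mood_disorder"
    rest = stats.drop(index=clinical)
    moderate = _argmax_unique(-rest["flourishing_prev"], "flourishing prevalence")
    names[moderate] = "moderate_mh_stress"
    last2 = rest.drop(index=moderate)
    low_stress = _argmax_unique(-last2["life_stress"], "mean life stress")
    names[low_stress] = "flourishing_no_stress"
    high_stress = [i for i in last2.index if i != low_stress][0]
    names[high_stress] = "flourishing_some_stress"
    return ClusterSolution(medoids=solution.medoids, labels=solution.labels,
                           cost=solution.cost, label_names=names)


def derive_mh_profiles(frame: pd.DataFrame, k: int = 4) -> tuple[pd.Series, pd.DataFrame]:
    """Cluster the indicator columns of a cohort and return named profiles.

    Rows with every indicator missing are left unclassified (missing profile).
    Returns (profile series, per-cluster composition report).
    """
    cols = [name for name, _, _ in MH_VARIABLE_SPEC]
    sub = frame[cols]
    has_any = sub.notna().any(axis=1)
    items = sub.loc[has_any]
    D = gower_matrix(items)
    sol = pam(D, k)
    if k == 4:
        sol = label_clusters(sol, items.reset_index(drop=True))
        named = sol.named_labels()
    else:
        named = np.asarray([f"cluster_{i}" for i in sol.labels], dtype=object)
    out = pd.Series(pd.NA, index=frame.index, dtype=object, name="mh_profile")
    out.loc[has_any] = named
    report = cluster_statistics(sol, items.reset_index(drop=True))
    if sol.label_names is not None:
        report.index = [sol.label_names[i] for i in report.index]
    return out, report


def silhouette_by_k(D: np.ndarray, ks=(2, 3, 4, 5, 6)) -> pd.Series:
    """Diagnostic mean silhouette width per candidate k (k is fixed at 4
    for the analysis; this is exploratory only)."""
    from sklearn.metrics import silhouette_score

    out = {}
    for k in ks:
        sol = pam(D, k)
        if len(np.unique(sol.labels)) < 2:
            out[k] = float("nan")
            continue
        out[k] = float(silhouette_score(D, sol.labels, metric="precomputed"))
    return pd.Series(out, name="mean_silhouette")
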