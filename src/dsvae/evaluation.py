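"""Evaluation suite for context embeddings.

Four analyses:

1. **Window classification** — linear SVM separating patient from control
   windows in embedding space, fit on train+val, scored on test windows.
2. **Cross-seed reliability** — for every ordered pair of seeds, the
   R-squared of a linear map from one seed's context embeddings to
   another's, as a measure of computational reproducibility.
3. **Manifold comparison** — R-squared between normalized pairwise window
   distances in two embedding spaces (e.g. model embeddings vs wFNC),
   quantifying how much of one geometry the other explains.
4. **Cluster analysis** — k-means over patient windows in context space,
   dwell-time statistics of cluster membership against covariates, and
   cluster-average wFNC difference maps.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.linear_model import LinearRegression
from sklearn.metrics import r2_score
from sklearn.svm import LinearSVC

from .io_windows import DatasetSplit, EmbeddingTable, SubjectRecord, Window
from .wfnc import WfncMatrix, compute_wfnc

TRAIN_SPLITS = ("train", "val")
TEST_SPLITS = ("test",)


# ---------------------------------------------------------------------------
# Window classification
# ---------------------------------------------------------------------------

def classify_context(
    table: EmbeddingTable,
    split: DatasetSplit | None = None,
    C: float = 1.0,
) -> float:
    """Window-level patient-vs-control accuracy of a linear SVM.

    The SVM (linear kernel, squared hinge, fixed C — nothing is tuned) is
    fit on the concatenated train+val context embeddings and scored on the
    test-split windows. Windows are labeled by their subject's diagnosis,
    and splits are by subject, so no subject contributes to both sides.
    """
    if split is not None:
        # table rows must agree with the provided subject-level split
        for sid, sp in zip(table.subject_ids, table.splits):
            if split[sid] != sp:
                raise ValueError(f"subject {sid!r}: table split {sp!r} != {split[sid]!r}")
    fit = table.select(splits=TRAIN_SPLITS)
    test = table.select(splits=TEST_SPLITS)
    if len(test) == 0:
        raise ValueError("test split is empty")
    y_fit = (fit.diagnoses.astype(str) == "patient").astype(int)
    if len(np.unique(y_fit)) < 2:
        raise ValueError("training set contains a single class")
    clf = LinearSVC(C=C, loss="squared_hinge", random_state=0)
    clf.fit(fit.embeddings, y_fit)
    y_test = (test.diagnoses.astype(str) == "patient").astype(int)
    return float(np.mean(clf.predict(test.embeddings) == y_test))


# ---------------------------------------------------------------------------
# Cross-seed reliability
# ---------------------------------------------------------------------------

@dataclass
class ReliabilityReport:
    """Per ordered seed pair (a -> b): R-squared of the linear map from
    seed-a embeddings to seed-b embeddings; plus the mean across pairs."""

    pair_r2: dict
    mean_r2: float

    def to_dict(self) -> dict:
        return {
            "pairs": {f"{a}->{b}": v for (a, b), v in sorted(self.pair_r2.items(),
                                                             key=lambda kv: str(kv[0]))},
            "mean_r2": self.mean_r2,
        }


def seed_reliability(
    tables: Mapping[int, EmbeddingTable],
    fit_on: Sequence[str] = TRAIN_SPLITS,
    eval_on: Sequence[str] = TEST_SPLITS,
) -> ReliabilityReport:
    """Across-seed embedding reliability.

    For each ordered pair of seeds (a, b), fit ordinary least squares from
    seed-a context embeddings to seed-b context embeddings on the rows in
    ``fit_on`` splits, and compute the uniformly-averaged multi-output
    R-squared on the ``eval_on`` rows. Tables must cover the same windows;
    rows are aligned on (subject_id, window_start).
    """
    if len(tables) < 2:
        raise ValueError("need at least two seeds")
    sorted_tables = {s: t.sorted() for s, t in tables.items()}
    ref_keys = None
    for s, t in sorted_tables.items():
        keys = list(zip(t.subject_ids.astype(str), t.window_starts))
        if ref_keys is None:
            ref_keys = keys
        elif keys != ref_keys:
            raise ValueError(f"seed {s}: embedding rows do not align across seeds")
    seeds = sorted(sorted_tables)
    any_t = sorted_tables[seeds[0]]
    fit_mask = any_t.mask(splits=fit_on)
    eval_mask = any_t.mask(splits=eval_on)
    if fit_mask.sum() == 0 or eval_mask.sum() == 0:
        raise ValueError("empty fit or eval subset")

    pair_r2 = {}
    for a in seeds:
        for b in seeds:
            if a == b:
                continue
            Xa, Xb = sorted_tables[a].embeddings, sorted_tables[b].embeddings
            reg = LinearRegression().fit(Xa[fit_mask], Xb[fit_mask])
            pred = reg.predict(Xa[eval_mask])
            pair_r2[(a, b)] = float(
                r2_score(Xb[eval_mask], pred, multioutput="uniform_average")
            )
    return ReliabilityReport(pair_r2, float(np.mean(list(pair_r2.values()))))


# ---------------------------------------------------------------------------
# Manifold comparison
# ---------------------------------------------------------------------------

def _pair_indices(n_points: int, max_pairs: int, rng: np.random.Generator):
    """All (i < j) pairs, or a seeded uniform subsample without replacement
    when their count exceeds max_pairs."""
    total = n_points * (n_points - 1) // 2
    if total <= max_pairs:
        return np.triu_indices(n_points, k=1)
    k = rng.choice(total, size=max_pairs, replace=False)
    k = np.sort(k)
    # invert the row-major upper-triangle linear index
    i = (
        n_points
        - 2
        - np.floor(
            (np.sqrt(4 * n_points * (n_points - 1) - 8 * k - 7) - 1) / 2
        ).astype(int)
    )
    j = k + i + 1 - (i * (2 * n_points - i - 1)) // 2
    return i, j


def manifold_similarity(
    embeddings_a: np.ndarray,
    embeddings_b: np.ndarray,
    max_pairs: int = 10**6,
    rng: np.random.Generator | None = None,
) -> float:
    """R-squared between normalized pairwise Euclidean distances of the same
    windows in two embedding spaces.

    Distances over all window pairs (or a seeded uniform subsample of at
    most ``max_pairs`` pairs) are computed in each space, z-scored, and a
    simple linear regression predicts space-b distances from space-a
    distances; its R-squared is returned. 1.0 means the two geometries agree
    up to isotropic scaling; near 0 means unrelated.
    """
    A = np.asarray(embeddings_a, dtype=float)
    B = np.asarray(embeddings_b, dtype=float)
    if A.shape[0] != B.shape[0]:
        raise ValueError("the two spaces must embed the same windows")
    if A.shape[0] < 2:
        raise ValueError("need at least 2 windows")
    rng = rng or np.random.default_rng(0)
    i, j = _pair_indices(A.shape[0], max_pairs, rng)
    da = np.linalg.norm(A[i] - A[j], axis=1)
    db = np.linalg.norm(B[i] - B[j], axis=1)
    if da.std() == 0 or db.std() == 0:
        # degenerate geometry (all pairwise distances equal): no variance to
        # explain; identical spaces count as perfectly matched
        return 1.0 if np.allclose(da, db) else 0.0
    za = (da - da.mean()) / da.std()
    zb = (db - db.mean()) / db.std()
    reg = LinearRegression().fit(za[:, None], zb)
    return float(r2_score(zb, reg.predict(za[:, None])))


# ---------------------------------------------------------------------------
# Cluster analysis
# ---------------------------------------------------------------------------

@dataclass
class ClusterReport:
    """K-means clustering of patient windows in context space.

    ``counts`` has one row per subject present in the clustered table and
    one column per cluster; rows sum to the subject's window total.
    """

    k: int
    centroids: np.ndarray
    assignments: np.ndarray
    table: EmbeddingTable
    counts: pd.DataFrame
    inertia: float

    def subjects(self) -> list[str]:
        return list(self.counts.index)


def kmeans_fit(table: EmbeddingTable, k: int = 3, seed: int = 0) -> ClusterReport:
    """K-means (k-means++ init, 10 restarts, best inertia kept) over the
    rows of ``table``; assignment is the nearest centroid in Euclidean
    distance. Deterministic given seed."""
    if len(table) < k:
        raise ValueError(f"k={k} exceeds the number of windows ({len(table)})")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    labels = km.fit_predict(table.embeddings)
    subjects = sorted(set(table.subject_ids.astype(str)))
    counts = pd.DataFrame(0, index=subjects, columns=range(k))
    for sid, lab in zip(table.subject_ids.astype(str), labels):
        counts.loc[sid, lab] += 1
    return ClusterReport(
        k=k,
        centroids=km.cluster_centers_,
        assignments=labels,
        table=table,
        counts=counts,
        inertia=float(km.inertia_),
    )


def dwell_statistics(
    report: ClusterReport,
    subjects: Sequence[SubjectRecord] | Mapping[str, float],
    covariate: str = "age",
) -> pd.DataFrame:
    """Per-cluster covariate statistics of cluster membership.

    For each cluster: (i) a Welch two-sided t-test on the covariate between
    subjects with at least one window in the cluster and subjects with
    none; (ii) the Pearson correlation (two-sided p) between the number of
    windows a subject has in the cluster — the dwell time — and the
    covariate, both as a raw count and normalized by the subject's total
    window count.

    Subjects lacking the covariate are excluded and counted in the
    ``n_excluded`` column. A t-test side with fewer than 2 subjects, or a
    constant covariate, yields undefined (NaN) / degenerate statistics
    rather than an exception. Raw p-values are reported (matching the
    analysis protocol); a Bonferroni-adjusted column (factor = number of
    clusters) is included so users can choose.
    """
    if isinstance(subjects, Mapping):
        values = dict(subjects)
    else:
        values = {r.subject_id: getattr(r, covariate) for r in subjects}
    sids = report.subjects()
    missing = [s for s in sids if values.get(s) is None or
               (isinstance(values.get(s), float) and np.isnan(values[s]))]
    kept = [s for s in sids if s not in set(missing)]
    cov = np.array([values[s] for s in kept], dtype=float)
    counts = report.counts.loc[kept]
    totals = counts.sum(axis=1).to_numpy(dtype=float)

    rows = []
    constant = cov.size > 0 and np.all(cov == cov[0])
    for c in range(report.k):
        in_c = counts[c].to_numpy() > 0
        n_in, n_out = int(in_c.sum()), int((~in_c).sum())
        if constant:
            t, t_p = 0.0, 1.0
        elif n_in < 2 or n_out < 2:
            t, t_p = float("nan"), float("nan")
        else:
            t, t_p = stats.ttest_ind(cov[in_c], cov[~in_c], equal_var=False)
        raw = counts[c].to_numpy(dtype=float)
        frac = np.divide(raw, totals, out=np.zeros_like(raw), where=totals > 0)
        if constant or raw.std() == 0 or cov.std() == 0:
            r, r_p = 0.0, 1.0
        else:
            r, r_p = stats.pearsonr(raw, cov)
        if constant or frac.std() == 0 or cov.std() == 0:
            rf, rf_p = 0.0, 1.0
        else:
            rf, rf_p = stats.pearsonr(frac, cov)
        rows.append(
            {
                "cluster": c,
                "covariate": covariate,
                "n_present": n_in,
                "n_absent": n_out,
                "n_excluded": len(missing),
                "t": float(t),
                "t_p": float(t_p),
                "t_p_bonferroni": float(min(1.0, t_p * report.k)) if np.isfinite(t_p) else float("nan"),
                "r_count": float(r),
                "r_count_p": float(r_p),
                "r_fraction": float(rf),
                "r_fraction_p": float(rf_p),
            }
        )
    return pd.DataFrame(rows)


def cluster_wfnc_maps(
    report: ClusterReport,
    windows: Sequence[Window],
) -> list[WfncMatrix]:
    """Cluster-average wFNC difference maps.

    ``windows`` must cover exactly the windows in the clustered table
    (matched on subject_id and window_start). Each cluster's map is its mean
    wFNC minus the mean wFNC over ALL clustered windows, so maps are
    symmetric with zero diagonal and their size-weighted sum is the zero
    matrix. An empty cluster yields a zero map (flagged via a zero window
    count in ``report.counts``).
    """
    by_key = {(w.subject_id, w.start): w for w in windows}
    mats = []
    for sid, start in zip(report.table.subject_ids, report.table.window_starts):
        key = (str(sid), int(start))
        if key not in by_key:
            raise KeyError(f"no window supplied for {key}")
        mats.append(compute_wfnc(by_key[key]).matrix)
    mats = np.stack(mats)
    grand = mats.mean(axis=0)
    maps = []
    for c in range(report.k):
        sel = report.assignments == c
        if sel.sum() == 0:
            maps.append(WfncMatrix(np.zeros_like(grand)))
            continue
        diff = mats[sel].mean(axis=0) - grand
        np.fill_diagonal(diff, 0.0)
        maps.append(WfncMatrix(diff))
    return maps
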