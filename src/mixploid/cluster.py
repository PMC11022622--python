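"""Genetic group inference.

Two complementary routes, mirroring common practice for taxonomically messy
collections:

* **DAPC** — principal components of the dosage matrix, k-means over a range
  of K scored by BIC, an a-score to pick how many PCs to keep, then linear
  discriminant analysis of the retained PCs.  Model-free; makes no
  Hardy–Weinberg or linkage assumptions.
* **EM admixture** — a binomial-likelihood admixture model (dosage g_il ~
  Binomial(c_i, sum_k Q_ik F_kl)) fit by expectation–maximisation, handling
  mixed diploid/tetraploid coding through the per-sample ploidy c_i.
  Replicated restarts feed the Evanno ΔK statistic used to choose K.

Lineage assignment thresholds the admixture matrix at Q >= 0.75 and splits
any cluster that spans designated geographically disjoint regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import softmax
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .containers import GenotypeMatrix, RunTable

__all__ = [
    "ClusterScan",
    "DapcModel",
    "AdmixtureResult",
    "pca_genotypes",
    "kmeans_bic_scan",
    "a_score",
    "DAPC",
    "dapc_fit",
    "AdmixtureEM",
    "admixture_em",
    "evanno_delta_k",
    "assign_lineages",
]


def _impute_locus_mean(dosage: np.ndarray) -> np.ndarray:
    X = dosage.astype(float).copy()
    mean = np.nanmean(X, axis=0)
    mean = np.where(np.isnan(mean), 0.0, mean)
    idx = np.where(np.isnan(X))
    X[idx] = mean[idx[1]]
    return X


def pca_genotypes(G: GenotypeMatrix | np.ndarray,
                  n_axes: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the dosage matrix (missing entries imputed to the locus mean).

    Returns (scores, eigenvalues); eigenvalues are non-increasing.
    """
    X = G.dosage if isinstance(G, GenotypeMatrix) else np.asarray(G, float)
    if X.shape[0] < 2:
        raise ValueError("PCA requires at least 2 samples")
    X = _impute_locus_mean(X)
    k = min(X.shape[0] - 1, X.shape[1]) if n_axes is None else n_axes
    pca = PCA(n_components=k, svd_solver="full" if k > min(X.shape) // 2 else "auto",
              random_state=0)
    scores = pca.fit_transform(X)
    return scores, pca.explained_variance_


@dataclass
class ClusterScan:
    k_values: list[int]
    bic: list[float]
    selected_k: int
    labels: dict[int, np.ndarray]  # best k-means labels per k
    n_restarts: int
    seed: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"K": self.k_values, "BIC": self.bic})


def kmeans_bic_scan(scores: np.ndarray, kmax: int = 70, n_restarts: int = 10,
                    seed: int = 0, kmin: int = 1) -> ClusterScan:
    """k-means over K = kmin..kmax scored by BIC_k = n ln(WSS_k/n) + k ln(n).

    The selected K minimises BIC (an override is a caller decision).
    """
    n = scores.shape[0]
    if kmax < 2:
        raise ValueError("kmax must be >= 2")
    if kmax >= n:
        raise ValueError("kmax must be below the number of samples")
    ks, bics, labels = [], [], {}
    for k in range(kmin, kmax + 1):
        if k == 1:
            wss = ((scores - scores.mean(axis=0)) ** 2).sum()
            lab = np.zeros(n, dtype=int)
        else:
            km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
            lab = km.fit_predict(scores)
            wss = km.inertia_
        wss = max(wss, 1e-12)
        ks.append(k)
        bics.append(n * np.log(wss / n) + k * np.log(n))
        labels[k] = lab
    sel = ks[int(np.argmin(bics))]
    return ClusterScan(k_values=ks, bic=bics, selected_k=sel, labels=labels,
                       n_restarts=n_restarts, seed=seed)


def _reassignment_proportion(scores: np.ndarray, labels: np.ndarray,
                             n_pcs: int) -> np.ndarray:
    """Per-group proportion of individuals reassigned to their own group by
    the discriminant step."""
    lda = LinearDiscriminantAnalysis()
    X = scores[:, :n_pcs]
    pred = lda.fit(X, labels).predict(X)
    groups = np.unique(labels)
    return np.array([(pred[labels == g] == g).mean() for g in groups])


def a_score(scores: np.ndarray, labels: np.ndarray,
            n_pcs_grid: list[int] | None = None, n_permutations: int = 10,
            seed: int = 0) -> tuple[int, dict[int, float]]:
    """Optimise the number of retained PCs by the a-score.

    For each candidate, a-score = observed reassignment proportion minus its
    permutation expectation, averaged over groups; returns the argmax and the
    per-candidate mean a-scores.
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("a-score needs at least two groups")
    max_pc = scores.shape[1]
    grid = n_pcs_grid or sorted({max(1, p) for p in
                                 np.linspace(1, max_pc, min(max_pc, 10)).astype(int)})
    if any(p < 1 or p > max_pc for p in grid):
        raise ValueError("n_pcs grid outside available PCs")
    rng = np.random.default_rng(seed)
    means: dict[int, float] = {}
    for p in grid:
        pt = _reassignment_proportion(scores, labels, p)
        pr = np.zeros_like(pt)
        for _ in range(n_permutations):
            pr += _reassignment_proportion(scores, rng.permutation(labels), p)
        pr /= n_permutations
        means[p] = float((pt - pr).mean())
    best = max(means, key=means.get)
    return best, means


@dataclass
class DapcModel:
    n_pcs: int
    coefficients: np.ndarray  # discriminant loadings on the retained PCs
    coordinates: np.ndarray  # individual positions on the discriminant axes
    percent_variance: np.ndarray  # per discriminant axis
    posterior: np.ndarray  # membership probabilities, rows sum to 1
    groups: np.ndarray
    labels: np.ndarray  # input group labels
    assigned: np.ndarray  # argmax-posterior group per individual


class DAPC(BaseEstimator):
    """Discriminant analysis of principal components.

    ``fit(X, y)`` takes PCA scores (or a raw dosage matrix via
    :func:`pca_genotypes`) and group labels; linear discriminants maximise the
    between/within variance ratio on the first ``n_pcs`` score columns.
    Posterior memberships come from squared Euclidean distance to group
    centroids in discriminant space through a softmax.

    Fitted attributes: ``coordinates_``, ``percent_variance_``,
    ``posterior_``, ``model_`` (a :class:`DapcModel`).
    """

    def __init__(self, n_pcs: int = 50, n_da: int | None = None):
        self.n_pcs = n_pcs
        self.n_da = n_da

    def fit(self, scores: np.ndarray, y: np.ndarray):
        y = np.asarray(y)
        groups = np.unique(y)
        n_da = self.n_da or len(groups) - 1
        if n_da > len(groups) - 1:
            raise ValueError("n_da must be <= groups - 1")
        n_pcs = min(self.n_pcs, scores.shape[1])
        X = scores[:, :n_pcs]
        lda = LinearDiscriminantAnalysis(solver="svd", n_components=n_da)
        coords = lda.fit_transform(X, y)
        self.lda_ = lda
        centroids = np.array([coords[y == g].mean(axis=0) for g in groups])
        d2 = ((coords[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        post = softmax(-0.5 * d2, axis=1)
        pv = 100.0 * lda.explained_variance_ratio_[:n_da]
        self.groups_ = groups
        self.coordinates_ = coords
        self.posterior_ = post
        self.percent_variance_ = pv
        self.assigned_ = groups[np.argmax(post, axis=1)]
        self.model_ = DapcModel(
            n_pcs=n_pcs, coefficients=lda.scalings_[:, :n_da],
            coordinates=coords, percent_variance=pv, posterior=post,
            groups=groups, labels=y, assigned=self.assigned_,
        )
        return self

    def transform(self, scores: np.ndarray) -> np.ndarray:
        return self.lda_.transform(scores[:, :self.model_.n_pcs])

    def predict(self, scores: np.ndarray) -> np.ndarray:
        return self.lda_.predict(scores[:, :self.model_.n_pcs])


def dapc_fit(scores: np.ndarray, labels: np.ndarray, n_pcs: int,
             n_da: int | None = None) -> DapcModel:
    return DAPC(n_pcs=n_pcs, n_da=n_da).fit(scores, labels).model_


@dataclass
class AdmixtureResult:
    K: int
    Q: np.ndarray  # (n, K), rows sum to 1
    F: np.ndarray  # (K, L) cluster alt-allele frequencies
    loglik: float
    loglik_trace: np.ndarray
    restart_logliks: np.ndarray
    seed: int


class AdmixtureEM(BaseEstimator):
    """Maximum-likelihood admixture proportions by EM.

    Model: dosage ``g_il ~ Binomial(c_i, p_il)`` with ``p_il = sum_k Q_ik
    F_kl``; ``c_i`` is the (coded) per-sample ploidy, so mixed diploid /
    tetraploid matrices are handled directly.  Q is initialised from a
    symmetric Dirichlet and F from perturbed pooled frequencies; the best of
    ``n_init`` restarts by log-likelihood is kept and the per-restart
    log-likelihoods are retained for ΔK analysis.

    The log-likelihood is non-decreasing across iterations (EM guarantee);
    missing dosages simply drop out of the update sums.
    """

    def __init__(self, K: int = 2, n_init: int = 10, max_iter: int = 500,
                 tol: float = 1e-4, random_state: int = 0):
        self.K = K
        self.n_init = n_init
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def _run(self, g, c, mask, rng):
        n, L = g.shape
        K = self.K
        pooled = np.nansum(np.where(mask, np.nan, g), axis=0) / np.maximum(
            (c[:, None] * ~mask).sum(axis=0), 1)
        Q = rng.dirichlet(np.ones(K), size=n)
        F = np.clip(pooled[None, :] + rng.normal(0, 0.05, size=(K, L)),
                    0.01, 0.99)
        gz = np.where(mask, 0.0, g)
        cz = np.where(mask, 0.0, np.broadcast_to(c[:, None], g.shape))
        trace = []
        prev = -np.inf
        for _ in range(self.max_iter):
            P = np.clip(Q @ F, 1e-9, 1 - 1e-9)
            ll = float((gz * np.log(P) + (cz - gz) * np.log1p(-P)).sum())
            trace.append(ll)
            if ll - prev < self.tol and np.isfinite(prev):
                break
            prev = ll
            # responsibilities for alt and ref allele copies
            A = gz / P          # (n, L)
            B = (cz - gz) / (1.0 - P)
            # alt copies credited to cluster k at locus l: F_kl * sum_i Q_ik A_il
            QA = Q.T @ A        # (K, L)
            QB = Q.T @ B        # (K, L)
            alt = F * QA
            ref = (1.0 - F) * QB
            F = np.clip(alt / np.maximum(alt + ref, 1e-12), 1e-6, 1 - 1e-6)
            # Q update: expected copies drawn from cluster k for individual i
            Ai = (A @ F.T) * Q          # (n, K)
            Bi = (B @ (1.0 - F).T) * Q
            num = Ai + Bi
            Q = num / np.maximum(num.sum(axis=1, keepdims=True), 1e-12)
        return Q, F, np.array(trace)

    def fit(self, G: GenotypeMatrix | np.ndarray, ploidy: np.ndarray | None = None):
        if isinstance(G, GenotypeMatrix):
            g, c = G.dosage, G.ploidy.astype(float)
        else:
            g = np.asarray(G, float)
            c = (np.full(g.shape[0], 2.0) if ploidy is None
                 else np.asarray(ploidy, float))
        if self.K < 1:
            raise ValueError("K must be >= 1")
        mask = np.isnan(g)
        if self.K == 1:
            pooled = np.nansum(g, axis=0) / np.maximum(
                (c[:, None] * ~mask).sum(axis=0), 1)
            F = pooled[None, :]
            Q = np.ones((g.shape[0], 1))
            P = np.clip(F, 1e-9, 1 - 1e-9)
            gz = np.where(mask, 0.0, g)
            cz = np.where(mask, 0.0, np.broadcast_to(c[:, None], g.shape))
            ll = float((gz * np.log(P) + (cz - gz) * np.log1p(-P)).sum())
            self.Q_, self.F_, self.loglik_ = Q, F, ll
            self.loglik_trace_ = np.array([ll])
            self.restart_logliks_ = np.array([ll])
            self.result_ = AdmixtureResult(1, Q, F, ll, self.loglik_trace_,
                                           self.restart_logliks_,
                                           self.random_state)
            return self
        seeds = np.random.SeedSequence(self.random_state).spawn(self.n_init)
        best = None
        restart_lls = []
        for ss in seeds:
            rng = np.random.default_rng(ss)
            Q, F, trace = self._run(g, c, mask, rng)
            restart_lls.append(trace[-1])
            if best is None or trace[-1] > best[2][-1]:
                best = (Q, F, trace)
        Q, F, trace = best
        self.Q_, self.F_ = Q, F
        self.loglik_ = float(trace[-1])
        self.loglik_trace_ = trace
        self.restart_logliks_ = np.array(restart_lls)
        self.result_ = AdmixtureResult(self.K, Q, F, self.loglik_, trace,
                                       self.restart_logliks_, self.random_state)
        return self

    def predict_proba(self, G=None) -> np.ndarray:
        return self.Q_


def admixture_em(G, K: int, max_iter: int = 500, tol: float = 1e-4,
                 seed: int = 0, n_init: int = 10,
                 ploidy: np.ndarray | None = None) -> AdmixtureResult:
    est = AdmixtureEM(K=K, n_init=n_init, max_iter=max_iter, tol=tol,
                      random_state=seed)
    est.fit(G, ploidy=ploidy)
    return est.result_


def evanno_delta_k(runs: RunTable) -> pd.DataFrame:
    """ΔK = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd L(K).

    Defined only for interior K with replicate sd > 0; the returned frame has
    one row per K with columns mean_lnP, sd_lnP and delta_K (NaN where
    undefined).
    """
    frame = runs.lnP_frame()
    stats = frame.groupby("K")["lnP"].agg(["mean", "std", "count"])
    if (stats["count"] < 2).any():
        raise ValueError("ΔK needs >= 2 replicates per K")
    ks = stats.index.to_numpy()
    if not np.array_equal(ks, np.arange(ks.min(), ks.max() + 1)):
        raise ValueError("K range must be contiguous")
    out = []
    for k in ks:
        row = {"K": k, "mean_lnP": stats.loc[k, "mean"],
               "sd_lnP": stats.loc[k, "std"], "delta_K": np.nan}
        if k - 1 in stats.index and k + 1 in stats.index:
            sd = stats.loc[k, "std"]
            if sd > 0:
                second = (stats.loc[k + 1, "mean"] - 2 * stats.loc[k, "mean"]
                          + stats.loc[k - 1, "mean"])
                row["delta_K"] = abs(second) / sd
        out.append(row)
    return pd.DataFrame(out)


def assign_lineages(
    Q: np.ndarray,
    threshold: float = 0.75,
    regions: list[str] | None = None,
    split_regions: tuple[str, str] = ("Alaska", "Europe"),
) -> list[str]:
    """Assign each sample to the cluster where its Q value reaches the
    threshold; below-threshold samples are ``admixed``.

    Any cluster whose assigned samples span both ``split_regions`` is divided
    into two lineages named ``<cluster>@<region>`` to respect geographic
    separation.
    """
    Q = np.asarray(Q)
    if np.any(np.abs(Q.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("Q rows must sum to 1")
    base = []
    for row in Q:
        k = int(np.argmax(row))
        base.append(f"K{k + 1}" if row[k] >= threshold else "admixed")
    split_needed = set()
    for lab in set(base) - {"admixed"}:
        idx = [i for i, b in enumerate(base) if b == lab]
        if regions is None:
            continue
        present = {regions[i] for i in idx} & set(split_regions)
        if len(present) == 2:
            split_needed.add(lab)
    out = []
    for i, lab in enumerate(base):
        if lab in split_needed:
            if regions is None or regions[i] is None:
                raise ValueError("region label required to split lineage")
            region = regions[i] if regions[i] in split_regions else split_regions[0]
            out.append(f"{lab}@{region}")
        else:
            out.append(lab)
    return out
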