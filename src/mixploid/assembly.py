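"""Construction of the analysis datasets: quality filters, clone detection
and mixed-ploidy recoding.

Two nuclear datasets are built from the called genotypes.  The "initial
diploid" dataset codes every sample as diploid and applies a 40% individual
missingness cap, locus filters (MAF >= 0.01, < 30% missing) and clone
collapsing at genetic distance 350.  The "diploid-tetraploid" dataset codes
every non-diploid (including ambiguous) sample as tetraploid, relaxes the
individual cap to 50% and collapses clones at distance 300.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator, ClusterMixin

from .containers import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CloneGroups",
    "filter_samples_by_missingness",
    "filter_loci",
    "genetic_distance_matrix",
    "detect_clones",
    "CloneDetector",
    "diploid_recode",
    "recode_mixed_ploidy",
    "assemble_dataset",
]


@dataclass
class CloneGroups:
    """Partition of samples into clonal groups (genets)."""

    groups: list[list[str]]  # every sample in exactly one group
    representatives: list[str]  # one member per group, least missing data
    threshold: float

    def genet_of(self) -> dict[str, str]:
        out = {}
        for group, rep in zip(self.groups, self.representatives):
            for s in group:
                out[s] = rep
        return out


def filter_samples_by_missingness(G: GenotypeMatrix,
                                  max_missing: float) -> GenotypeMatrix:
    """Drop samples whose missing-genotype fraction exceeds ``max_missing``."""
    if not 0.0 <= max_missing <= 1.0:
        raise ValueError("max_missing must be in [0, 1]")
    frac = G.missing_fraction_per_sample()
    keep = np.flatnonzero(frac <= max_missing)
    if keep.size == 0:
        raise ValueError("all samples exceed the missingness threshold")
    removed = G.n_samples - keep.size
    if removed:
        logger.info("missingness filter removed %d of %d samples (> %.0f%%)",
                    removed, G.n_samples, 100 * max_missing)
    return G.take_samples(keep)


def locus_allele_frequency(G: GenotypeMatrix) -> np.ndarray:
    """Ploidy-aware alt-allele frequency: sum(dosage) / sum(ploidy) over
    non-missing samples, per locus."""
    present = ~G.missing
    num = np.nansum(G.dosage, axis=0)
    den = (present * G.ploidy[:, None]).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def filter_loci(G: GenotypeMatrix, maf_min: float = 0.01,
                max_missing: float = 0.30) -> GenotypeMatrix:
    """Keep polymorphic loci (MAF >= ``maf_min``) with < ``max_missing``
    missing data."""
    if not (0.0 <= maf_min <= 0.5 and 0.0 <= max_missing <= 1.0):
        raise ValueError("thresholds out of range")
    p = locus_allele_frequency(G)
    maf = np.minimum(p, 1.0 - p)
    miss = G.missing_fraction_per_locus()
    keep = np.flatnonzero((maf >= maf_min) & (miss < max_missing))
    if keep.size == 0:
        raise ValueError("no loci pass the filters")
    logger.info("locus filters kept %d of %d loci", keep.size, G.n_loci)
    return G.take_loci(keep)


def genetic_distance_matrix(G: GenotypeMatrix) -> np.ndarray:
    """Pairwise absolute-dosage-difference distance over shared loci.

    d(i, j) = sum over loci non-missing in both samples of |dosage_i - dosage_j|.
    """
    if G.n_samples == 0:
        raise ValueError("empty genotype matrix")
    X = G.dosage
    ok = ~np.isnan(X)
    Xz = np.where(ok, X, 0.0)
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        both = ok[i] & ok
        D[i] = np.abs(Xz[i] - Xz).sum(axis=1, where=both)
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2  # numerically symmetric


def detect_clones(D: np.ndarray, threshold: float,
                  sample_ids: list[str],
                  missing_fraction: np.ndarray | None = None) -> CloneGroups:
    """Single-linkage clone grouping: i and j share a genet iff connected by a
    chain of pairs at distance <= ``threshold``.

    The representative of each group is the member with the least missing
    data, ties broken by lexicographically smallest id.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    n = D.shape[0]
    adj = csr_matrix(D <= threshold)
    _, labels = connected_components(adj, directed=False)
    if missing_fraction is None:
        missing_fraction = np.zeros(n)
    groups, reps = [], []
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        ids = [sample_ids[i] for i in members]
        order = sorted(range(len(members)),
                       key=lambda k: (missing_fraction[members[k]], ids[k]))
        groups.append(ids)
        reps.append(ids[order[0]])
    return CloneGroups(groups=groups, representatives=reps,
                       threshold=float(threshold))


class CloneDetector(BaseEstimator, ClusterMixin):
    """sklearn-style wrapper: ``fit`` labels each sample with its genet.

    Attributes after fit: ``labels_`` (group index per sample), ``groups_``
    (:class:`CloneGroups`), ``distance_matrix_``.
    """

    def __init__(self, threshold: float = 350.0):
        self.threshold = threshold

    def fit(self, G: GenotypeMatrix, y=None):
        D = genetic_distance_matrix(G)
        self.distance_matrix_ = D
        self.groups_ = detect_clones(
            D, self.threshold, G.samples,
            missing_fraction=G.missing_fraction_per_sample())
        genet = self.groups_.genet_of()
        reps = {r: k for k, r in enumerate(self.groups_.representatives)}
        self.labels_ = np.array([reps[genet[s]] for s in G.samples])
        return self

    def fit_predict(self, G: GenotypeMatrix, y=None):
        return self.fit(G).labels_


def diploid_recode(G: GenotypeMatrix) -> GenotypeMatrix:
    """Code every sample as diploid regardless of its data ploidy.

    Mirrors genotype calls made under a diploid assumption: fully homozygous
    dosages map to 0 or 2, anything mixed maps to heterozygous (1).
    """
    d = G.dosage
    c = G.ploidy[:, None].astype(float)
    out = np.where(d == 0, 0.0, np.where(d == c, 2.0, 1.0))
    out = np.where(np.isnan(d), np.nan, out)
    return replace(G, dosage=out, ploidy=np.full(G.n_samples, 2),
                   provenance="initial_diploid")


def recode_mixed_ploidy(G: GenotypeMatrix,
                        calls: dict[str, str]) -> GenotypeMatrix:
    """Annotate coded ploidy from the per-sample calls.

    Diploid-called samples keep coded ploidy 2; tetraploid, triploid,
    pentaploid and unknown (ambiguous) calls are all coded tetraploid.  The
    underlying dosages are untouched — a diploid-data sample coded tetraploid
    is written on the four-row representation with two pad rows at file-write
    time.
    """
    missing = [s for s in G.samples if s not in calls]
    if missing:
        raise ValueError(f"missing ploidy call for samples: {missing[:5]}")
    coded = np.array([2 if calls[s] == "diploid" else 4 for s in G.samples])
    if np.nanmax(np.where(np.isnan(G.dosage), 0, G.dosage), initial=0) > 4:
        raise ValueError("dosages exceed tetraploid coding")
    bad = np.nansum(G.dosage > coded[:, None])
    if bad:
        raise ValueError("non-diploid dosages present for diploid-called samples")
    return replace(G, ploidy=coded, provenance="diploid_tetraploid")


def assemble_dataset(
    G: GenotypeMatrix,
    max_missing_ind: float,
    clone_threshold: float,
    maf_min: float = 0.01,
    max_missing_locus: float = 0.30,
) -> tuple[GenotypeMatrix, CloneGroups]:
    """Sample missingness filter -> locus filters -> clone collapsing.

    MAF and locus missingness are recomputed after sample removal.  Returns
    the genet-level matrix (one representative per clone group) and the clone
    partition.
    """
    G = filter_samples_by_missingness(G, max_missing_ind)
    G = filter_loci(G, maf_min=maf_min, max_missing=max_missing_locus)
    det = CloneDetector(threshold=clone_threshold).fit(G)
    reps = det.groups_.representatives
    keep = np.array([G.samples.index(r) for r in sorted(reps, key=G.samples.index)])
    n_clones = G.n_samples - keep.size
    if n_clones:
        logger.info("clone detection collapsed %d samples into genets", n_clones)
    return G.take_samples(keep), det.groups_
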