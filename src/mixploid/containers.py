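"""In-memory containers shared by every pipeline stage.

Three matrices move through the pipeline: per-sample read counts at each SNP
(:class:`AlleleDepthMatrix`), per-sample alternate-allele dosages with a ploidy
annotation (:class:`GenotypeMatrix`), and tables of clustering runs
(:class:`RunTable`).  Dosage matrices use ``NaN`` for missing entries so the
whole stack stays vectorised numpy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

NUCLEAR = "nuclear"
CHLOROPLAST = "chloroplast"
MITOCHONDRIAL = "mitochondrial"

COMPARTMENTS = (NUCLEAR, CHLOROPLAST, MITOCHONDRIAL)

#: site-table columns required by AlleleDepthMatrix
SITE_COLUMNS = ("compartment", "chrom", "pos", "ref", "alt")


@dataclass
class AlleleDepthMatrix:
    """Per-sample x per-site read counts for bi-allelic SNPs.

    Parameters
    ----------
    samples : list of str
        Ordered sample identifiers (rows).
    sites : pandas.DataFrame
        One row per SNP with columns ``compartment`` (nuclear / chloroplast /
        mitochondrial), ``chrom``, ``pos`` (1-based), ``ref`` and ``alt``.
    depth : ndarray of int, shape (n_samples, n_sites)
        Total read depth per cell.
    alt_depth : ndarray of int
        Reads supporting the alternate allele; ``0 <= alt_depth <= depth``.
    missing : ndarray of bool
        True where the cell carries no usable observation.
    """

    samples: list[str]
    sites: pd.DataFrame
    depth: np.ndarray
    alt_depth: np.ndarray
    missing: np.ndarray

    def __post_init__(self) -> None:
        n, m = len(self.samples), len(self.sites)
        for name in ("depth", "alt_depth", "missing"):
            arr = getattr(self, name)
            if arr.shape != (n, m):
                raise ValueError(f"{name} has shape {arr.shape}, expected {(n, m)}")
        for col in SITE_COLUMNS:
            if col not in self.sites.columns:
                raise ValueError(f"site table lacks required column {col!r}")
        bad = self.sites["compartment"].loc[
            ~self.sites["compartment"].isin(COMPARTMENTS)
        ]
        if len(bad):
            raise ValueError(f"unknown compartments: {sorted(set(bad))}")
        if np.any(self.alt_depth > self.depth):
            raise ValueError("alt_depth exceeds depth")
        if np.any(self.depth < 0):
            raise ValueError("negative read depths")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def restrict(self, compartment: str) -> "AlleleDepthMatrix":
        """Return the sub-matrix for one genome compartment."""
        keep = (self.sites["compartment"] == compartment).to_numpy()
        return AlleleDepthMatrix(
            samples=list(self.samples),
            sites=self.sites.loc[keep].reset_index(drop=True),
            depth=self.depth[:, keep],
            alt_depth=self.alt_depth[:, keep],
            missing=self.missing[:, keep],
        )


@dataclass
class GenotypeMatrix:
    """Alternate-allele dosages with per-sample ploidy.

    ``dosage`` is a float matrix with integer values in ``[0, ploidy]`` and
    ``NaN`` for missing genotypes.  ``provenance`` records which analysis
    dataset the matrix belongs to: ``initial_diploid`` (everything coded 0/1/2),
    ``diploid_tetraploid`` (mixed 2x/4x coding) or ``chloroplast`` (haploid,
    dosages in {0, 1}).
    """

    samples: list[str]
    loci: pd.DataFrame
    dosage: np.ndarray
    ploidy: np.ndarray
    provenance: str = "initial_diploid"

    def __post_init__(self) -> None:
        n, m = len(self.samples), len(self.loci)
        if self.dosage.shape != (n, m):
            raise ValueError(f"dosage has shape {self.dosage.shape}, expected {(n, m)}")
        if self.ploidy.shape != (n,):
            raise ValueError("ploidy must be one value per sample")
        with np.errstate(invalid="ignore"):
            over = np.nansum(self.dosage > self.ploidy[:, None])
        if over:
            raise ValueError("dosage exceeds sample ploidy")
        if self.provenance == "chloroplast":
            vals = self.dosage[~np.isnan(self.dosage)]
            if vals.size and not np.isin(vals, (0.0, 1.0)).all():
                raise ValueError("chloroplast dosages must be 0/1")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.dosage)

    def missing_fraction_per_sample(self) -> np.ndarray:
        return self.missing.mean(axis=1)

    def missing_fraction_per_locus(self) -> np.ndarray:
        return self.missing.mean(axis=0)

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return replace(
            self,
            samples=[self.samples[i] for i in index],
            dosage=self.dosage[index],
            ploidy=self.ploidy[index],
        )

    def take_loci(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return replace(
            self,
            loci=self.loci.iloc[index].reset_index(drop=True),
            dosage=self.dosage[:, index],
        )


@dataclass
class RunTable:
    """Replicated clustering runs: one row per (K, replicate).

    Each row stores the estimated log probability of the data and the n x K
    membership matrix Q.  Rows of Q must sum to one.
    """

    rows: list[dict] = field(default_factory=list)

    def add(self, K: int, replicate: int, lnP: float, Q: np.ndarray) -> None:
        Q = np.asarray(Q, dtype=float)
        if Q.ndim != 2 or Q.shape[1] != K:
            raise ValueError(f"Q has shape {Q.shape}, expected (*, {K})")
        sums = Q.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-3):
            raise ValueError("Q rows do not sum to 1 within 1e-3")
        Q = Q / sums[:, None]
        self.rows.append({"K": int(K), "replicate": int(replicate),
                          "lnP": float(lnP), "Q": Q})

    def lnP_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"K": r["K"], "replicate": r["replicate"], "lnP": r["lnP"]}
             for r in self.rows]
        )

    def k_values(self) -> list[int]:
        return sorted({r["K"] for r in self.rows})

    def __len__(self) -> int:
        return len(self.rows)
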