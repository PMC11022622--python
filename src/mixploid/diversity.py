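"""Nuclear diversity and differentiation statistics for diploid dosages.

Per-population observed heterozygosity Ho, within-population gene diversity
Hs (Nei's unbiased estimator with the small-sample correction), and the
inbreeding coefficient FIS = 1 - Ho/Hs; pairwise Weir & Cockerham (1984)
theta between groups as the ratio of summed variance components over loci;
and vcftools-style per-individual heterozygosity (observed vs. expected
homozygote counts and the method-of-moments F).

All functions operate on the diploid-coded dosage matrix (0/1/2 with NaN
missing); negative estimates are reported as computed, never truncated.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix

__all__ = [
    "population_diversity",
    "pairwise_fst",
    "weir_cockerham_components",
    "individual_heterozygosity",
]


def _dosage_of(G) -> np.ndarray:
    return G.dosage if isinstance(G, GenotypeMatrix) else np.asarray(G, float)


def population_diversity(G, populations: list[str]) -> pd.DataFrame:
    """Ho, Hs and FIS per population (locus-averaged) and overall.

    Per locus and population with n non-missing diploid individuals:
    ``Ho`` = fraction heterozygous; ``Hs = n/(n-1) * (1 - sum p_a^2 - Ho/(2n))``;
    ``FIS = 1 - Ho/Hs`` where Hs > 0.  Loci with fewer than two genotyped
    individuals in a population are skipped for that population; averages
    weight loci by data presence (mean over contributing loci).
    """
    X = _dosage_of(G)
    pops = np.asarray(populations)
    out = []
    for pop in list(dict.fromkeys(pops)) + ["__overall__"]:
        sub = X if pop == "__overall__" else X[pops == pop]
        n = (~np.isnan(sub)).sum(axis=0).astype(float)
        ok = n >= 2
        if not ok.any():
            out.append({"population": pop, "Ho": np.nan, "Hs": np.nan,
                        "FIS": np.nan, "n_loci": 0})
            continue
        sub = sub[:, ok]
        n = n[ok]
        ho = np.nansum(sub == 1, axis=0) / n
        p = np.nansum(sub, axis=0) / (2 * n)
        hs = n / (n - 1) * (1 - p ** 2 - (1 - p) ** 2 - ho / (2 * n))
        with np.errstate(invalid="ignore", divide="ignore"):
            fis = np.where(hs > 0, 1 - ho / hs, np.nan)
        out.append({
            "population": "overall" if pop == "__overall__" else pop,
            "Ho": float(ho.mean()),
            "Hs": float(hs.mean()),
            "FIS": float(np.nanmean(fis)) if np.isfinite(fis).any() else np.nan,
            "n_loci": int(ok.sum()),
        })
    return pd.DataFrame(out)


def weir_cockerham_components(
    X: np.ndarray, groups: np.ndarray, labels: tuple,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus Weir & Cockerham variance components (a, b, c) for the given
    group pair/set on a diploid dosage matrix."""
    r = len(labels)
    n_il = np.stack([(~np.isnan(X[groups == g])).sum(axis=0) for g in labels])
    p_il = np.stack([np.nansum(X[groups == g], axis=0) for g in labels])
    h_il = np.stack([np.nansum(X[groups == g] == 1, axis=0) for g in labels])
    ok = (n_il >= 1).all(axis=0) & (n_il.sum(axis=0) > r)
    n_il = n_il[:, ok].astype(float)
    p_il = p_il[:, ok] / (2 * n_il)
    h_il = h_il[:, ok] / n_il

    nbar = n_il.mean(axis=0)
    nsum = n_il.sum(axis=0)
    nc = (nsum - (n_il ** 2).sum(axis=0) / nsum) / (r - 1)
    pbar = (n_il * p_il).sum(axis=0) / nsum
    s2 = (n_il * (p_il - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n_il * h_il).sum(axis=0) / nsum

    with np.errstate(invalid="ignore", divide="ignore"):
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
    c = hbar / 2
    good = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    return a[good], b[good], c[good]


def pairwise_fst(G, groups: list[str], min_group_size: int = 2) -> pd.DataFrame:
    """Multi-locus Weir–Cockerham theta between every pair of groups.

    Theta = sum(a) / sum(a + b + c) over loci (ratio of sums).  Groups with
    fewer than ``min_group_size`` genotyped individuals are excluded.
    Returns a symmetric DataFrame with zero diagonal; small negative values
    are legitimate estimator output.
    """
    X = _dosage_of(G)
    groups = np.asarray(groups)
    sizes = {g: int((groups == g).sum()) for g in dict.fromkeys(groups)}
    kept = [g for g, s in sizes.items() if s >= min_group_size]
    if len(kept) < 2:
        raise ValueError("pairwise FST needs at least two groups of adequate size")
    mat = pd.DataFrame(0.0, index=kept, columns=kept)
    for g1, g2 in itertools.combinations(kept, 2):
        a, b, c = weir_cockerham_components(X, groups, (g1, g2))
        denom = (a + b + c).sum()
        theta = a.sum() / denom if denom != 0 else np.nan
        mat.loc[g1, g2] = mat.loc[g2, g1] = theta
    return mat


@dataclass
class IndividualHet:
    table: pd.DataFrame  # sample, O_hom, E_hom, N_sites, F


def individual_heterozygosity(G, samples: list[str] | None = None) -> pd.DataFrame:
    """vcftools-style per-sample homozygosity statistics.

    Over each sample's non-missing loci: observed homozygote count O(Hom);
    expected homozygote count ``E(Hom) = sum_l (1 - 2 p_l (1 - p_l) * 2n_l /
    (2n_l - 1))`` with p_l the sample-wide allele frequency; and
    ``F = (O(Hom) - E(Hom)) / (N - E(Hom))``.
    """
    X = _dosage_of(G)
    if samples is None:
        samples = G.samples if isinstance(G, GenotypeMatrix) else [
            f"S{i}" for i in range(X.shape[0])]
    n_l = (~np.isnan(X)).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_l = np.nansum(X, axis=0) / (2 * n_l)
        e_hom_l = 1 - 2 * p_l * (1 - p_l) * (2 * n_l) / (2 * n_l - 1)
    rows = []
    for i, sid in enumerate(samples):
        ok = ~np.isnan(X[i]) & np.isfinite(e_hom_l)
        N = int(ok.sum())
        if N == 0:
            rows.append({"sample": sid, "O_hom": np.nan, "E_hom": np.nan,
                         "N_sites": 0, "F": np.nan})
            continue
        o_hom = float((X[i, ok] != 1).sum())
        e_hom = float(e_hom_l[ok].sum())
        denom = N - e_hom
        f = (o_hom - e_hom) / denom if denom != 0 else np.nan
        rows.append({"sample": sid, "O_hom": o_hom, "E_hom": e_hom,
                     "N_sites": N, "F": f})
    return pd.DataFrame(rows)
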