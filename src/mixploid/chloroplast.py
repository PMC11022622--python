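"""Chloroplast haplotypes and their sharing across nuclear clusters.

Haploid chloroplast SNPs are reduced to a uniquely informative subset (sites
inducing the same sample partition — identical columns up to a global allele
swap — are redundant; the least-missing one is kept), concatenated into
haplotype strings, and summarised: haplotypes present in more than one
nuclear cluster are flagged as shared (chloroplast capture), the rest as
endemic.  A sample missing any retained site has no haplotype.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix

__all__ = [
    "HaplotypeTable",
    "informative_cp_snps",
    "cp_haplotypes",
    "haplotype_summary",
]


@dataclass
class HaplotypeTable:
    """Per-sample haplotype strings and letter ids (None = missing)."""

    samples: list[str]
    strings: list[str | None]
    ids: list[str | None]
    retained_sites: np.ndarray  # column indices into the cp genotype matrix

    def counts(self) -> pd.Series:
        return pd.Series([i for i in self.ids if i is not None]).value_counts()


def _columns_equivalent(a: np.ndarray, b: np.ndarray) -> bool:
    """Same sample partition on shared non-missing entries, up to 0<->1 swap."""
    both = ~np.isnan(a) & ~np.isnan(b)
    if not both.any():
        return True  # no shared information to distinguish them
    x, y = a[both], b[both]
    return bool(np.all(x == y) or np.all(x == 1 - y))


def informative_cp_snps(cpG: GenotypeMatrix,
                        max_missing: float = 0.10) -> np.ndarray:
    """Indices of uniquely informative chloroplast sites.

    Sites above the missingness cap are dropped; among partition-equivalent
    sites the one with least missing data is kept (ties: smallest genomic
    position).  Idempotent: re-running on the retained set changes nothing.
    """
    vals = cpG.dosage
    bad = set(np.flatnonzero(cpG.missing_fraction_per_locus() > max_missing))
    miss = cpG.missing_fraction_per_locus()
    pos = cpG.loci["pos"].to_numpy() if "pos" in cpG.loci.columns else np.arange(
        cpG.n_loci)
    order = sorted((j for j in range(cpG.n_loci) if j not in bad),
                   key=lambda j: (miss[j], pos[j]))
    kept: list[int] = []
    for j in order:
        if any(_columns_equivalent(vals[:, j], vals[:, k]) for k in kept):
            continue
        kept.append(j)
    if not kept:
        raise ValueError("no chloroplast sites retained")
    return np.array(sorted(kept), dtype=int)


def cp_haplotypes(cpG: GenotypeMatrix,
                  retained_sites: np.ndarray) -> HaplotypeTable:
    """Concatenate retained sites (genomic order) into haplotype strings.

    Any missing retained site voids the whole haplotype.  Ids are letters
    A, B, C, ... assigned by decreasing global frequency, ties broken by
    first occurrence.
    """
    retained_sites = np.asarray(retained_sites, dtype=int)
    if retained_sites.size == 0:
        raise ValueError("retained site list is empty")
    sub = cpG.dosage[:, retained_sites]
    strings: list[str | None] = []
    for row in sub:
        if np.isnan(row).any():
            strings.append(None)
        else:
            strings.append("".join(str(int(v)) for v in row))
    present = [s for s in strings if s is not None]
    first_seen = {}
    for k, s in enumerate(present):
        first_seen.setdefault(s, k)
    freq = pd.Series(present).value_counts()
    ranked = sorted(freq.index, key=lambda s: (-freq[s], first_seen[s]))
    letters = _letters(len(ranked))
    id_of = dict(zip(ranked, letters))
    ids = [id_of[s] if s is not None else None for s in strings]
    return HaplotypeTable(samples=list(cpG.samples), strings=strings, ids=ids,
                          retained_sites=retained_sites)


def _letters(n: int) -> list[str]:
    az = string.ascii_uppercase
    out = []
    for i in range(n):
        label, j = "", i
        while True:
            label = az[j % 26] + label
            j = j // 26 - 1
            if j < 0:
                break
        out.append(label)
    return out


def haplotype_summary(
    H: HaplotypeTable,
    clusters: list[str],
    populations: list[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Sharing report: per-haplotype cluster sets and shared/endemic flags,
    per-cluster richness, and (optionally) per-population richness and
    frequency spectra."""
    rows = [(s, h, c) for s, h, c in zip(H.samples, H.ids, clusters)
            if h is not None]
    if any(c is None for _, _, c in rows):
        raise ValueError("cluster label missing for a sample with a haplotype")
    frame = pd.DataFrame(rows, columns=["sample", "haplotype", "cluster"])
    hap_rows = []
    for h, grp in frame.groupby("haplotype"):
        cset = sorted(set(grp["cluster"]))
        hap_rows.append({"haplotype": h, "abundance": len(grp),
                         "clusters": ",".join(cset),
                         "status": "shared" if len(cset) > 1 else "endemic"})
    haplotypes = pd.DataFrame(hap_rows).sort_values(
        "abundance", ascending=False).reset_index(drop=True)
    per_cluster = frame.groupby("cluster")["haplotype"].nunique().rename(
        "richness").reset_index()
    out = {"haplotypes": haplotypes, "clusters": per_cluster}
    if populations is not None:
        pframe = pd.DataFrame(
            [(p, h) for p, h in zip(populations, H.ids) if h is not None],
            columns=["population", "haplotype"])
        rich = pframe.groupby("population")["haplotype"].nunique().rename(
            "richness").reset_index()
        spectrum = (pframe.groupby(["population", "haplotype"]).size()
                    .rename("count").reset_index())
        out["populations"] = rich
        out["population_spectra"] = spectrum
    return out
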