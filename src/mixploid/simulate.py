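"""Synthetic mixed-ploidy, multi-species SNP datasets with known truth.

The generator emulates the statistical structure of a targeted-sequencing
survey of interfertile shrub-birch species: several nuclear genetic clusters
with tunable divergence (Balding–Nichols allele frequencies around a shared
ancestral frequency), one tetraploid species among diploids, admixed hybrids
and trihybrids, beta-binomial allele-specific read counts at ~24x mean depth,
MCAR missingness, clonal duplicates, chloroplast haplotypes that can be shared
across clusters (chloroplast capture), and a multi-team sampling design in
which some teams collect more than one genetic cluster.

Truth (species, ploidy, admixture vector, clone parentage, haplotype) is
returned alongside the reads so every downstream stage can be scored exactly.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CHLOROPLAST, NUCLEAR, AlleleDepthMatrix, GenotypeMatrix

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_dataset",
    "simulate_allelic_depths",
    "default_config",
    "small_config",
]


@dataclass
class SimulationConfig:
    """Conditions of a simulated sampling campaign.

    Defaults mirror the study design the generator emulates: five genetic
    clusters (two core diploid lineages, a small hybrid-derived diploid group,
    one tetraploid species, one geographically split Alaska/Europe group),
    mean sequencing depth 24x, and 29 sampling teams.
    """

    n_clusters: int = 5
    cluster_sizes: tuple[int, ...] = (198, 109, 10, 127, 25)
    cluster_ploidy: tuple[int, ...] = (2, 2, 2, 4, 2)
    #: Balding-Nichols F per cluster (differentiation from the shared ancestor)
    cluster_divergence: tuple[float, ...] = (0.15, 0.12, 0.18, 0.30, 0.35)
    #: regions a cluster's populations are spread over; a cluster listing two
    #: regions reproduces the geographically split lineage
    cluster_regions: tuple[tuple[str, ...], ...] = (
        ("east_canada",),
        ("west_canada",),
        ("west_canada",),
        ("central_canada",),
        ("Alaska", "Europe"),
    )
    n_nuclear_sites: int = 5000
    n_cp_sites: int = 85
    mean_depth: float = 24.0
    #: negative-binomial size parameter for total depth (larger = tighter)
    depth_dispersion: float = 12.0
    #: sigma of the per-site lognormal coverage factor (amplicon-to-amplicon
    #: variability; the reference-SNP mean-depth filter leans on this)
    site_depth_sd: float = 1.0
    #: beta-binomial concentration of read ratios around dosage/ploidy
    read_overdispersion: float = 200.0
    sequencing_error: float = 0.005
    missing_rate: float = 0.05
    #: list of (cluster index tuple, admixture weights, n individuals)
    hybrid_specs: tuple[tuple[tuple[int, ...], tuple[float, ...], int], ...] = (
        ((1, 2), (0.5, 0.5), 10),
        ((0, 1, 4), (0.34, 0.33, 0.33), 14),
    )
    n_clones: int = 30
    clone_error: float = 0.01
    cp_pool_size: int = 20
    cp_sharing_prob: float = 0.3
    samples_per_population: int = 8
    n_teams: int = 29
    #: fraction of teams whose populations span >= 2 clusters
    team_multicluster_fraction: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        K = self.n_clusters
        for name in ("cluster_sizes", "cluster_ploidy", "cluster_divergence",
                     "cluster_regions"):
            if len(getattr(self, name)) != K:
                raise ValueError(f"{name} must have length n_clusters={K}")
        if any(p not in (2, 3, 4, 5) for p in self.cluster_ploidy):
            raise ValueError("cluster ploidies must be in {2,3,4,5}")
        if any(not 0.0 < f < 1.0 for f in self.cluster_divergence):
            raise ValueError("divergence F must lie in (0, 1)")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if min(self.cluster_sizes) < 0 or self.n_nuclear_sites < 0:
            raise ValueError("counts must be non-negative")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        for clusters, weights, count in self.hybrid_specs:
            if len(clusters) != len(weights):
                raise ValueError("hybrid weights must match cluster tuple")
            if any(c < 0 or c >= K for c in clusters):
                raise ValueError(f"hybrid spec references unknown cluster in {clusters}")
            if abs(sum(weights) - 1.0) > 1e-9:
                raise ValueError("admixture vector must sum to 1")
            if count < 0:
                raise ValueError("hybrid counts must be non-negative")
        if not 0.0 <= self.team_multicluster_fraction <= 1.0:
            raise ValueError("team_multicluster_fraction must be in [0, 1]")


@dataclass
class SyntheticDataset:
    """Simulated reads plus complete truth tables."""

    config: SimulationConfig
    #: id, population, team, region, true_species, true_ploidy, clone_of
    samples: pd.DataFrame
    #: nuclear read counts
    allele_depths: AlleleDepthMatrix
    #: haploid chloroplast genotypes (with missingness applied)
    cp_genotypes: GenotypeMatrix
    #: true per-cluster nuclear allele frequencies, shape (K, L)
    cluster_freqs: np.ndarray
    #: true admixture matrix, shape (n, K)
    true_Q: np.ndarray
    #: true nuclear dosages (no missingness), shape (n, L)
    true_dosage: np.ndarray
    #: true chloroplast haplotype string per sample
    true_haplotype: list[str]

    def __post_init__(self) -> None:
        n = len(self.samples)
        if not (self.allele_depths.n_samples == self.true_Q.shape[0]
                == self.true_dosage.shape[0] == len(self.true_haplotype) == n):
            raise ValueError("inconsistent sample dimensions across truth tables")
        known = set(self.samples["id"])
        parents = self.samples["clone_of"].dropna()
        if not set(parents).issubset(known):
            raise ValueError("clone parent id not present in sample table")


def _beta_binomial(rng, depth, mu, concentration):
    """Read counts ~ BetaBinomial(depth, mu*c, (1-mu)*c); binomial if c = inf."""
    mu = np.clip(mu, 1e-9, 1.0 - 1e-9)
    if concentration is None or np.isinf(concentration):
        return rng.binomial(depth, mu)
    lam = rng.beta(mu * concentration, (1.0 - mu) * concentration)
    return rng.binomial(depth, lam)


def _draw_depth(rng, mean_depth, dispersion, size):
    if dispersion is None or np.isinf(dispersion):
        return np.full(size, int(round(mean_depth)), dtype=int)
    p = dispersion / (dispersion + mean_depth)
    return rng.negative_binomial(dispersion, p, size=size)


def simulate_allelic_depths(
    ploidy: int,
    n_sites: int,
    mean_depth: float = 24.0,
    overdispersion: float | None = 200.0,
    error: float = 0.0,
    seed: int = 0,
    depth_dispersion: float | None = 12.0,
    dosage: int | None = None,
) -> np.ndarray:
    """Simulate (ref, alt) read pairs at heterozygous sites of one individual.

    Dosage at each site is uniform on ``{1, ..., ploidy-1}`` unless ``dosage``
    pins it; the expected alternate-read fraction at a site is dosage/ploidy
    before overdispersion.  ``overdispersion=None`` gives pure binomial reads
    and ``depth_dispersion=None`` a constant total depth.

    Returns an ``(n_sites, 2)`` integer array of (ref, alt) counts.
    """
    if ploidy not in (2, 3, 4, 5):
        raise ValueError(f"unsupported ploidy {ploidy}")
    rng = np.random.default_rng(seed)
    if dosage is None:
        dose = rng.integers(1, ploidy, size=n_sites)
    else:
        if not 1 <= dosage <= ploidy - 1:
            raise ValueError("pinned dosage must be heterozygous")
        dose = np.full(n_sites, dosage)
    depth = _draw_depth(rng, mean_depth, depth_dispersion, n_sites)
    mu = dose / ploidy
    mu = mu * (1.0 - 2.0 * error) + error
    alt = _beta_binomial(rng, depth, mu, overdispersion)
    return np.column_stack([depth - alt, alt])


def _haplotype_labels(n: int) -> list[str]:
    letters = string.ascii_uppercase
    out = []
    for i in range(n):
        label = ""
        j = i
        while True:
            label = letters[j % 26] + label
            j = j // 26 - 1
            if j < 0:
                break
        out.append(label)
    return out


def _assign_cp_haplotypes(rng, config):
    """Pool of distinct binary haplotypes; per-cluster sets with sharing."""
    pool = rng.integers(0, 2, size=(config.cp_pool_size, config.n_cp_sites))
    # force distinctness by flipping a private site pattern if collisions occur
    seen: dict[bytes, int] = {}
    for i in range(pool.shape[0]):
        while pool[i].tobytes() in seen:
            pool[i, rng.integers(config.n_cp_sites)] ^= 1
        seen[pool[i].tobytes()] = i
    used: list[int] = []
    cluster_sets: list[list[int]] = []
    unused = list(range(config.cp_pool_size))
    for _ in range(config.n_clusters):
        n_hap = 1 + rng.poisson(2)
        haps: list[int] = []
        for _ in range(n_hap):
            if used and (rng.random() < config.cp_sharing_prob or not unused):
                h = used[rng.integers(len(used))]  # chloroplast capture
            else:
                h = unused.pop(rng.integers(len(unused)))
            if h not in haps:
                haps.append(h)
            if h not in used:
                used.append(h)
        cluster_sets.append(haps)
    return pool, cluster_sets


def _assign_teams(rng, pop_cluster: dict[str, int], config) -> dict[str, str]:
    """Map populations to teams; a configured fraction of teams spans >= 2 clusters."""
    pops = sorted(pop_cluster)
    n_teams = min(config.n_teams, len(pops))
    team_names = [f"T{t + 1:02d}" for t in range(n_teams)]
    n_multi = int(round(config.team_multicluster_fraction * n_teams))
    by_cluster: dict[int, list[str]] = {}
    for p in pops:
        by_cluster.setdefault(pop_cluster[p], []).append(p)
    clusters_avail = [c for c in sorted(by_cluster) if by_cluster[c]]
    assignment: dict[str, str] = {}
    ti = 0
    # multi-cluster teams take one population from each of two clusters
    while ti < n_multi and len([c for c in by_cluster if by_cluster[c]]) >= 2:
        have = [c for c in sorted(by_cluster) if by_cluster[c]]
        c1, c2 = rng.choice(have, size=2, replace=False)
        assignment[by_cluster[c1].pop(0)] = team_names[ti]
        assignment[by_cluster[c2].pop(0)] = team_names[ti]
        ti += 1
    # remaining teams each stay within one cluster: allocate teams to
    # clusters proportionally to population count, then chunk within cluster
    single_teams = team_names[ti:] or team_names[:1]
    clusters_left = [c for c in sorted(by_cluster) if by_cluster[c]]
    counts = np.array([len(by_cluster[c]) for c in clusters_left], dtype=float)
    if clusters_left:
        alloc = np.maximum(1, np.round(
            counts / counts.sum() * len(single_teams)).astype(int))
        while alloc.sum() > len(single_teams):
            alloc[int(np.argmax(alloc))] -= 1
        t = 0
        for c, n_teams_c in zip(clusters_left, alloc):
            teams_c = single_teams[t:t + n_teams_c] or [single_teams[-1]]
            t += n_teams_c
            for chunk, team in zip(
                    np.array_split(np.array(by_cluster[c]), len(teams_c)),
                    teams_c):
                for p in chunk:
                    assignment[p] = team
    for p in pops:
        assignment.setdefault(p, team_names[-1])
    return assignment


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Draw one full dataset under ``config``.  Deterministic given the seed.

    Nuclear model: ancestral frequency p ~ U[0.05, 0.95] per locus; cluster
    frequency ~ Beta(p(1-F)/F, (1-p)(1-F)/F); individual dosage ~
    Binomial(ploidy, pi) with pi the admixture-weighted frequency; total depth
    negative binomial around ``mean_depth``; alternate reads beta-binomial
    centred on dosage/ploidy with sequencing error pulling homozygote ratios
    off 0 and 1; entries knocked out MCAR at ``missing_rate``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    K, L = config.n_clusters, config.n_nuclear_sites

    p_anc = rng.uniform(0.05, 0.95, size=L)
    F = np.asarray(config.cluster_divergence)
    a = p_anc[None, :] * (1.0 - F[:, None]) / F[:, None]
    b = (1.0 - p_anc[None, :]) * (1.0 - F[:, None]) / F[:, None]
    cluster_freqs = rng.beta(a, b)

    # --- sample roster ----------------------------------------------------
    rows = []
    Q_rows = []
    for c in range(K):
        for _ in range(config.cluster_sizes[c]):
            q = np.zeros(K)
            q[c] = 1.0
            rows.append({"true_species": f"C{c + 1}", "dominant_cluster": c,
                         "true_ploidy": config.cluster_ploidy[c],
                         "clone_of": None})
            Q_rows.append(q)
    for clusters, weights, count in config.hybrid_specs:
        dom = clusters[int(np.argmax(weights))]
        name = "x".join(f"C{c + 1}" for c in clusters)
        for _ in range(count):
            q = np.zeros(K)
            for c, w in zip(clusters, weights):
                q[c] += w
            rows.append({"true_species": f"hybrid_{name}", "dominant_cluster": dom,
                         "true_ploidy": config.cluster_ploidy[dom],
                         "clone_of": None})
            Q_rows.append(q)

    samples = pd.DataFrame(rows)
    true_Q = np.array(Q_rows)
    n_base = len(samples)

    # --- nuclear dosages --------------------------------------------------
    pi = true_Q @ cluster_freqs
    ploidy = samples["true_ploidy"].to_numpy()
    true_dosage = rng.binomial(ploidy[:, None], pi).astype(float)

    # --- clones -----------------------------------------------------------
    clone_rows = []
    if config.n_clones > 0:
        parents = rng.choice(n_base, size=config.n_clones, replace=False)
        for pi_idx in parents:
            parent = samples.iloc[pi_idx]
            d = true_dosage[pi_idx].copy()
            if config.clone_error > 0:
                flip = rng.random(L) < config.clone_error
                step = rng.choice([-1, 1], size=flip.sum())
                d[flip] = np.clip(d[flip] + step, 0, parent["true_ploidy"])
            clone_rows.append((pi_idx, parent, d))
    for pi_idx, parent, d in clone_rows:
        samples.loc[len(samples)] = {
            "true_species": parent["true_species"],
            "dominant_cluster": parent["dominant_cluster"],
            "true_ploidy": parent["true_ploidy"],
            "clone_of": pi_idx,  # resolved to an id below
        }
        true_Q = np.vstack([true_Q, true_Q[pi_idx]])
        true_dosage = np.vstack([true_dosage, d])

    n = len(samples)
    ids = [f"S{i + 1:04d}" for i in range(n)]
    samples.insert(0, "id", ids)
    samples["clone_of"] = [
        ids[int(v)] if v is not None and not (isinstance(v, float) and np.isnan(v))
        else None
        for v in samples["clone_of"]
    ]
    ploidy = samples["true_ploidy"].to_numpy()

    # --- populations, regions, teams --------------------------------------
    pop_labels = np.empty(n, dtype=object)
    region_labels = np.empty(n, dtype=object)
    pop_cluster: dict[str, int] = {}
    pop_counter = 0
    for c in range(K):
        idx = np.flatnonzero(samples["dominant_cluster"].to_numpy() == c)
        regions = config.cluster_regions[c]
        for j, chunk in enumerate(
            np.array_split(idx, max(1, int(np.ceil(len(idx) / config.samples_per_population))))
        ):
            if len(chunk) == 0:
                continue
            pop_counter += 1
            pname = f"P{pop_counter:03d}"
            pop_cluster[pname] = c
            pop_labels[chunk] = pname
            region_labels[chunk] = regions[j % len(regions)]
    team_of = _assign_teams(rng, pop_cluster, config)
    samples["population"] = pop_labels
    samples["region"] = region_labels
    samples["team"] = [team_of[p] for p in pop_labels]

    # --- reads ------------------------------------------------------------
    site_scale = np.exp(rng.normal(-config.site_depth_sd ** 2 / 2,
                                   config.site_depth_sd, size=L))
    site_mean = config.mean_depth * site_scale
    disp = config.depth_dispersion
    depth = rng.negative_binomial(disp, disp / (disp + site_mean[None, :]),
                                  size=(n, L))
    mu = true_dosage / ploidy[:, None]
    mu = mu * (1.0 - 2.0 * config.sequencing_error) + config.sequencing_error
    alt = _beta_binomial(rng, depth, mu, config.read_overdispersion)
    missing = rng.random((n, L)) < config.missing_rate
    missing |= depth == 0
    depth = np.where(missing, 0, depth)
    alt = np.where(missing, 0, alt)

    nuclear_sites = pd.DataFrame({
        "compartment": NUCLEAR,
        "chrom": "chr1",
        "pos": np.arange(1, L + 1) * 10,
        "ref": "A",
        "alt": "C",
    })
    ad = AlleleDepthMatrix(
        samples=ids, sites=nuclear_sites,
        depth=depth, alt_depth=alt, missing=missing,
    )

    # --- chloroplast ------------------------------------------------------
    pool, cluster_sets = _assign_cp_haplotypes(rng, config)
    hap_idx = np.empty(n, dtype=int)
    for i in range(n):
        parent = samples.at[i, "clone_of"]
        if parent is not None:
            hap_idx[i] = hap_idx[ids.index(parent)]
        else:
            haps = cluster_sets[samples.at[i, "dominant_cluster"]]
            hap_idx[i] = haps[rng.integers(len(haps))]
    cp = pool[hap_idx].astype(float)
    cp_missing = rng.random(cp.shape) < config.missing_rate
    cp[cp_missing] = np.nan
    cp_sites = pd.DataFrame({
        "compartment": CHLOROPLAST,
        "chrom": "cp",
        "pos": np.arange(1, config.n_cp_sites + 1) * 5,
        "ref": "G",
        "alt": "T",
    })
    cp_geno = GenotypeMatrix(
        samples=ids, loci=cp_sites, dosage=cp,
        ploidy=np.ones(n, dtype=int), provenance="chloroplast",
    )
    labels = _haplotype_labels(config.cp_pool_size)
    true_hap = [labels[h] for h in hap_idx]
    samples["true_haplotype"] = true_hap

    samples = samples[[
        "id", "population", "team", "region", "true_species",
        "true_ploidy", "clone_of", "dominant_cluster", "true_haplotype",
    ]]
    return SyntheticDataset(
        config=config, samples=samples, allele_depths=ad,
        cp_genotypes=cp_geno, cluster_freqs=cluster_freqs,
        true_Q=true_Q, true_dosage=true_dosage, true_haplotype=true_hap,
    )


def default_config(seed: int = 0) -> SimulationConfig:
    """Study-scale conditions: 537 individuals incl. clones/hybrids, 5000 SNPs."""
    return SimulationConfig(seed=seed)


def small_config(seed: int = 0) -> SimulationConfig:
    """Scaled-down conditions preserving the cluster composition and depth regime."""
    return SimulationConfig(
        cluster_sizes=(60, 40, 8, 45, 14),
        n_nuclear_sites=800,
        n_cp_sites=40,
        hybrid_specs=(((1, 2), (0.5, 0.5), 4), ((0, 1, 4), (0.34, 0.33, 0.33), 5)),
        n_clones=8,
        cp_pool_size=12,
        n_teams=12,
        seed=seed,
    )
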