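"""End-to-end multicriteria workflow.

Stages (in order): simulate or load a variant file -> per-sample ploidy from
allelic-ratio profiles -> assembly of the initial-diploid and
diploid-tetraploid datasets (missingness / MAF / clone filters) -> DAPC and
EM-admixture clustering with ΔK -> diversity statistics -> chloroplast
haplotypes -> optional leaf morphology -> per-sample multicriteria table and
summary reports (cluster sizes, ploidy counts with "putative" categories
resolved by pooled profiles, team-by-cluster cross-tab).

The final species-level label requires the two necessary criteria to concur:
a confident cluster assignment and a ploidy call compatible with that
cluster's modal ploidy.  Morphology and chlorotype only corroborate; they
never decide.  Samples below the membership threshold are flagged putative
hybrids (or trihybrids when three clusters each hold >= 0.2 membership).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assembly, chloroplast, cluster, diversity, vcfio
from .morphology import LeafTraits, match_species
from .ploidy import PloidyClassifier
from .simulate import SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "ploidy_percentages",
    "team_share_percent",
    "team_cluster_crosstab",
    "multicriteria_labels",
]


@dataclass
class PipelineConfig:
    """One structured configuration for the whole workflow (YAML-friendly)."""

    seed: int = 0
    outdir: str = "mixploid_out"
    #: input VCF; None means simulate with ``simulation``
    vcf: str | None = None
    sample_table: str | None = None  # population/team/region metadata (TSV)
    leaf_table: str | None = None  # optional morphology TSV
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # ploidy
    min_ratio_depth: int = 15
    # dataset assembly
    max_missing_initial: float = 0.40
    max_missing_mixed: float = 0.50
    maf_min: float = 0.01
    max_missing_locus: float = 0.30
    clone_threshold_initial: float = 350.0
    clone_threshold_mixed: float = 300.0
    # clustering
    kmax: int = 70
    force_k: int | None = None
    n_pcs: int | str = "auto"
    k_range: tuple[int, int] = (1, 6)
    replicates: int = 3
    em_n_init: int = 3
    q_threshold: float = 0.75
    split_regions: tuple[str, str] = ("Alaska", "Europe")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in
                     {f.name for f in dataclasses.fields(cls)}})
        if sim:
            cfg.simulation = SimulationConfig(**sim)
        return cfg

    def to_yaml(self, path: str) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


@dataclass
class PipelineResult:
    multicriteria: pd.DataFrame
    cluster_sizes: pd.DataFrame
    ploidy_counts: pd.DataFrame
    team_crosstab: pd.DataFrame
    fst_clusters: pd.DataFrame
    diversity: pd.DataFrame
    delta_k: pd.DataFrame
    haplotype_report: dict
    dapc: "cluster.DapcModel"
    admixture: "cluster.AdmixtureResult"
    lineages: list[str]
    truth: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# report arithmetic
# ---------------------------------------------------------------------------

def ploidy_percentages(counts: dict[str, int]) -> pd.DataFrame:
    """Percentages of each ploidy class among genets, to one decimal."""
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty count table")
    return pd.DataFrame({
        "ploidy": list(counts),
        "count": list(counts.values()),
        "percent": [round(100.0 * v / total, 1) for v in counts.values()],
    })


def team_share_percent(n_teams_with_property: int, n_teams: int) -> float:
    """Share of sampling teams with a property, as a whole-number percent."""
    if not 0 <= n_teams_with_property <= n_teams:
        raise ValueError("team counts out of range")
    return round(100.0 * n_teams_with_property / n_teams)


def team_cluster_crosstab(teams: list[str], clusters: list[str]) -> pd.DataFrame:
    """Teams x genetic clusters contingency table."""
    return pd.crosstab(pd.Series(teams, name="team"),
                       pd.Series(clusters, name="cluster"))


def multicriteria_labels(
    cluster_label: list[str],
    ploidy_call: list[str],
    cluster_modal_ploidy: dict[str, str],
    Q: np.ndarray | None = None,
    q_threshold: float = 0.75,
) -> pd.DataFrame:
    """Combine the necessary criteria into a final per-sample label.

    A sample gets its cluster's label when its ploidy call (or putative call)
    is compatible with the cluster's modal ploidy; otherwise ``unresolved``.
    Samples without a confident cluster assignment are ``putative hybrid``
    (``putative trihybrid`` when three memberships each reach 0.2).
    """
    rows = []
    for i, (cl, pl) in enumerate(zip(cluster_label, ploidy_call)):
        trace = []
        if cl in ("admixed", None):
            label = "putative hybrid"
            if Q is not None and (np.sort(Q[i])[-3:] >= 0.2).all():
                label = "putative trihybrid"
            trace.append("membership below threshold")
        else:
            modal = cluster_modal_ploidy.get(cl)
            base = pl.replace("putative ", "")
            if base == modal:
                label = cl
                trace.append(f"cluster {cl} + ploidy {pl} concur")
            elif base == "unknown":
                label = "unresolved"
                trace.append("ploidy unknown")
            else:
                label = "unresolved"
                trace.append(f"ploidy {pl} conflicts with modal {modal}")
        rows.append({"final_label": label, "rule_trace": "; ".join(trace)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng_seed = int(config.seed)

    # --- stage: input -----------------------------------------------------
    truth = None
    if config.vcf is None:
        sim_cfg = dataclasses.replace(config.simulation, seed=rng_seed)
        ds = simulate_dataset(sim_cfg)
        vcf_path = outdir / "simulated.vcf"
        vcfio.write_vcf(str(vcf_path), ds.allele_depths,
                        np.where(ds.allele_depths.missing, np.nan,
                                 ds.true_dosage),
                        ds.samples["true_ploidy"].to_numpy(),
                        cp_genotypes=ds.cp_genotypes)
        _write(ds.samples, outdir / "truth_samples.tsv")
        meta = ds.samples[["id", "population", "team", "region"]]
        truth = ds.samples
        logger.info("simulated %d samples, %d nuclear sites",
                    len(ds.samples), ds.allele_depths.n_sites)
    else:
        vcf_path = Path(config.vcf)
        if config.sample_table is None:
            raise ValueError("sample metadata table required with an input VCF")
        meta = pd.read_csv(config.sample_table, sep="\t")

    data = vcfio.read_variant_table(str(vcf_path))
    meta = meta.set_index("id").loc[data.allele_depths.samples].reset_index()

    # --- stage: ploidy ----------------------------------------------------
    clf = PloidyClassifier(min_depth=config.min_ratio_depth)
    clf.fit(data.allele_depths)
    calls = {s: c.label for s, c in zip(data.nuclear.samples, clf.calls_)}
    pd.DataFrame({
        "id": data.nuclear.samples,
        "label": [c.label for c in clf.calls_],
        "peaks": [",".join(f"{p:.3f}" for p in c.peaks) for c in clf.calls_],
        "n_sites": [c.n_sites for c in clf.calls_],
    }).to_csv(outdir / "ploidy_calls.tsv", sep="\t", index=False)
    logger.info("ploidy: %s", pd.Series(list(calls.values()))
                .value_counts().to_dict())

    # --- stage: datasets --------------------------------------------------
    initial = assembly.diploid_recode(data.nuclear)
    initial, clones_initial = assembly.assemble_dataset(
        initial, config.max_missing_initial, config.clone_threshold_initial,
        maf_min=config.maf_min, max_missing_locus=config.max_missing_locus)
    mixed = assembly.recode_mixed_ploidy(data.nuclear, calls)
    mixed, clones_mixed = assembly.assemble_dataset(
        mixed, config.max_missing_mixed, config.clone_threshold_mixed,
        maf_min=config.maf_min, max_missing_locus=config.max_missing_locus)
    genets = initial.samples
    gmeta = meta.set_index("id").loc[genets].reset_index()

    # --- stage: clustering (DAPC on the initial diploid dataset) ----------
    scores, eigvals = cluster.pca_genotypes(initial)
    kmax = min(config.kmax, initial.n_samples - 1)
    scan = cluster.kmeans_bic_scan(scores, kmax=kmax, seed=rng_seed)
    k_used = config.force_k or scan.selected_k
    if k_used < 2:
        k_used = max(2, scan.selected_k)
    labels0 = scan.labels.get(k_used)
    if config.n_pcs == "auto":
        grid = sorted({p for p in (5, 10, 20, 30, 50, 80)
                       if p <= scores.shape[1]})
        n_pcs, _ = cluster.a_score(scores, labels0, n_pcs_grid=grid,
                                   seed=rng_seed)
    else:
        n_pcs = int(config.n_pcs)
    dapc = cluster.DAPC(n_pcs=n_pcs).fit(scores, labels0)
    dapc_label = [f"D{g + 1}" for g in dapc.assigned_]
    scan.as_frame().to_csv(outdir / "bic_scan.tsv", sep="\t", index=False)

    # --- stage: admixture + ΔK on the diploid-tetraploid dataset ----------
    runs = None
    from .containers import RunTable
    runs = RunTable()
    lo, hi = config.k_range
    best_by_k = {}
    for K in range(lo, hi + 1):
        for rep in range(config.replicates):
            res = cluster.admixture_em(
                mixed, K, seed=rng_seed + 1000 * K + rep,
                n_init=config.em_n_init)
            runs.add(K, rep, res.loglik, res.Q)
            if K not in best_by_k or res.loglik > best_by_k[K].loglik:
                best_by_k[K] = res
    delta_k = cluster.evanno_delta_k(runs)
    delta_k.to_csv(outdir / "delta_k.tsv", sep="\t", index=False)
    adm_k = config.force_k or int(
        delta_k.loc[delta_k["delta_K"].idxmax(), "K"]
        if delta_k["delta_K"].notna().any() else max(best_by_k))
    adm_k = min(max(adm_k, lo), hi)
    admixture = best_by_k[adm_k]

    mixed_meta = meta.set_index("id").loc[mixed.samples].reset_index()
    lineages = cluster.assign_lineages(
        admixture.Q, threshold=config.q_threshold,
        regions=list(mixed_meta["region"]),
        split_regions=config.split_regions)

    # --- stage: diversity -------------------------------------------------
    div = diversity.population_diversity(initial, list(gmeta["population"]))
    fst_clusters = diversity.pairwise_fst(initial, dapc_label)
    indiv_het = diversity.individual_heterozygosity(initial)
    _write(div, outdir / "diversity.tsv")
    fst_clusters.to_csv(outdir / "fst_clusters.tsv", sep="\t")
    _write(indiv_het, outdir / "individual_heterozygosity.tsv")

    # --- stage: chloroplast -----------------------------------------------
    hap_report = {}
    if data.chloroplast is not None:
        cp_genets = data.chloroplast.take_samples(
            np.array([data.chloroplast.samples.index(s) for s in genets]))
        retained = chloroplast.informative_cp_snps(cp_genets)
        H = chloroplast.cp_haplotypes(cp_genets, retained)
        hap_report = chloroplast.haplotype_summary(
            H, dapc_label, populations=list(gmeta["population"]))
        pd.DataFrame({"id": H.samples, "haplotype": H.ids,
                      "string": H.strings}).to_csv(
            outdir / "haplotypes.tsv", sep="\t", index=False)
        chlorotype = dict(zip(H.samples, H.ids))
    else:
        chlorotype = {}

    # --- stage: morphology -------------------------------------------------
    morpho: dict[str, str] = {}
    if config.leaf_table is not None:
        leaves = pd.read_csv(config.leaf_table, sep="\t")
        for _, row in leaves.iterrows():
            traits = LeafTraits(row["blade_shape"], row["length_cm"],
                                row["width_cm"], row["margin"], row["teeth"])
            morpho[row["id"]] = ";".join(sorted(match_species(traits))) or "none"

    # --- stage: reports ----------------------------------------------------
    # pooled refinement of unknowns by DAPC cluster ("putative" categories)
    call_series = pd.Series({s: calls[s] for s in genets})
    putative: dict[str, str] = {}
    for lab in sorted(set(dapc_label)):
        members = [s for s, l in zip(genets, dapc_label) if l == lab]
        unknowns = [s for s in members if calls[s] == "unknown"]
        if len(unknowns) >= 2:
            pooled = clf.pooled_call(unknowns)
            if pooled.label != "unknown":
                for s in unknowns:
                    putative[s] = f"putative {pooled.label}"
    refined = {s: putative.get(s, calls[s]) for s in genets}

    counts = pd.Series(list(refined.values())).value_counts()
    order = ["diploid", "putative diploid", "tetraploid",
             "putative tetraploid", "triploid", "pentaploid", "unknown"]
    ploidy_counts = ploidy_percentages(
        {k: int(counts.get(k, 0)) for k in order if counts.get(k, 0) or
         k in ("diploid", "tetraploid", "unknown")})

    cluster_sizes = (pd.Series(dapc_label, name="cluster").value_counts()
                     .rename("n").reset_index())
    crosstab = team_cluster_crosstab(list(gmeta["team"]), dapc_label)
    crosstab.to_csv(outdir / "team_crosstab.tsv", sep="\t")

    modal = {}
    for lab in sorted(set(dapc_label)):
        members = [s for s, l in zip(genets, dapc_label) if l == lab]
        base = [refined[s].replace("putative ", "") for s in members]
        base = [b for b in base if b != "unknown"]
        modal[lab] = pd.Series(base).mode().iloc[0] if base else "unknown"

    lineage_of = dict(zip(mixed.samples, lineages))
    Qmap = {s: admixture.Q[i] for i, s in enumerate(mixed.samples)}
    Qgen = np.array([Qmap.get(s, np.full(admixture.K, np.nan)) for s in genets])
    final = multicriteria_labels(
        dapc_label, [refined[s] for s in genets], modal,
        Q=np.where(np.isnan(Qgen), 0, Qgen), q_threshold=config.q_threshold)
    multicriteria = pd.DataFrame({
        "id": genets,
        "ploidy_call": [refined[s] for s in genets],
        "dapc_cluster": dapc_label,
        "lineage": [lineage_of.get(s, "NA") for s in genets],
        "chlorotype": [chlorotype.get(s) or "NA" for s in genets],
        "morphology": [morpho.get(s, "NA") for s in genets],
    })
    multicriteria = pd.concat([multicriteria, final], axis=1)
    _write(multicriteria, outdir / "multicriteria.tsv")
    _write(cluster_sizes, outdir / "cluster_sizes.tsv")
    _write(ploidy_counts, outdir / "ploidy_counts.tsv")

    return PipelineResult(
        multicriteria=multicriteria, cluster_sizes=cluster_sizes,
        ploidy_counts=ploidy_counts, team_crosstab=crosstab,
        fst_clusters=fst_clusters, diversity=div, delta_k=delta_k,
        haplotype_report=hap_report, dapc=dapc.model_, admixture=admixture,
        lineages=lineages, truth=truth,
    )
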