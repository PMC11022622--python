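"""Readers and writers for the formats the pipeline touches.

Variant files are a VCF v4.x dialect with per-sample ``GT``, ``DP`` and ``AD``
fields; genome compartments (nuclear vs. chloroplast vs. mitochondrial) are
identified by contig name.  STRUCTURE input uses the mixed-ploidy coding in
which every individual occupies four allele rows — diploids carry two allele
rows followed by two rows of ``-9`` — and STRUCTURE-style run outputs are
parsed back into a :class:`~mixploid.containers.RunTable`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import (
    CHLOROPLAST,
    MITOCHONDRIAL,
    NUCLEAR,
    AlleleDepthMatrix,
    GenotypeMatrix,
    RunTable,
)

logger = logging.getLogger(__name__)

MISSING_CODE = -9  # STRUCTURE missing-allele code

#: contig-name prefixes mapped to compartments (case-insensitive)
DEFAULT_CONTIG_MAP = {
    "cp": CHLOROPLAST,
    "chloroplast": CHLOROPLAST,
    "pltd": CHLOROPLAST,
    "mt": MITOCHONDRIAL,
    "chrm": MITOCHONDRIAL,
    "mitochond": MITOCHONDRIAL,
}


def compartment_of(chrom: str, contig_map: dict[str, str] | None = None) -> str:
    cmap = DEFAULT_CONTIG_MAP if contig_map is None else contig_map
    low = chrom.lower()
    for prefix, comp in cmap.items():
        if low.startswith(prefix):
            return comp
    return NUCLEAR


@dataclass
class VariantData:
    """Parsed variant file: read counts plus compartment genotype matrices."""

    allele_depths: AlleleDepthMatrix  # nuclear sites only
    nuclear: GenotypeMatrix
    chloroplast: GenotypeMatrix | None
    n_multiallelic_dropped: int = 0


def read_variant_table(
    path: str,
    min_depth: int = 5,
    contig_map: dict[str, str] | None = None,
) -> VariantData:
    """Read a VCF with AD/DP fields into allele-depth and dosage matrices.

    Multi-allelic records are dropped (count logged); genotypes observed with
    fewer than ``min_depth`` reads are set missing.  Per-sample ploidy is taken
    from the arity of the nuclear GT field.
    """
    vcf = VCF(path)
    samples = list(vcf.samples)
    n = len(samples)

    site_rows, depth_cols, alt_cols, dosage_cols, arity_cols = [], [], [], [], []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        comp = compartment_of(v.CHROM, contig_map)
        dp = v.format("DP")
        ad = v.format("AD")
        if ad is None:
            raise ValueError(f"record {v.CHROM}:{v.POS} lacks an AD field")
        dp = np.zeros(n, dtype=int) if dp is None else np.maximum(dp.reshape(n), 0)
        ad = ad.reshape(n, -1)
        altd = np.maximum(ad[:, 1] if ad.shape[1] > 1 else np.zeros(n, int), 0)
        altd = np.minimum(altd, dp)

        dosage = np.full(n, np.nan)
        arity = np.zeros(n, dtype=int)
        for i, g in enumerate(v.genotypes):
            alleles = [a for a in g[:-1] if a != -2]  # -2 pads short GT fields
            arity[i] = len(alleles)
            if alleles and all(a >= 0 for a in alleles):
                dosage[i] = sum(1 for a in alleles if a > 0)
        dosage[dp < min_depth] = np.nan

        site_rows.append({"compartment": comp, "chrom": v.CHROM, "pos": v.POS,
                          "ref": v.REF, "alt": v.ALT[0]})
        depth_cols.append(dp)
        alt_cols.append(altd)
        dosage_cols.append(dosage)
        arity_cols.append(arity)

    if n_multi:
        logger.info("dropped %d multi-allelic records", n_multi)
    if not site_rows:
        raise ValueError(f"no usable bi-allelic records in {path}")

    sites = pd.DataFrame(site_rows)
    depth = np.column_stack(depth_cols)
    alt_depth = np.column_stack(alt_cols)
    dosage = np.column_stack(dosage_cols)
    arity = np.column_stack(arity_cols)

    is_nuc = (sites["compartment"] == NUCLEAR).to_numpy()
    is_cp = (sites["compartment"] == CHLOROPLAST).to_numpy()

    ad_matrix = AlleleDepthMatrix(
        samples=samples,
        sites=sites.loc[is_nuc].reset_index(drop=True),
        depth=depth[:, is_nuc],
        alt_depth=alt_depth[:, is_nuc],
        missing=(depth[:, is_nuc] == 0) | np.isnan(dosage[:, is_nuc]),
    )
    nuc_arity = arity[:, is_nuc]
    ploidy = np.array([
        int(nuc_arity[i][nuc_arity[i] > 0].max()) if (nuc_arity[i] > 0).any() else 2
        for i in range(n)
    ])
    nuclear = GenotypeMatrix(
        samples=samples,
        loci=sites.loc[is_nuc].reset_index(drop=True),
        dosage=dosage[:, is_nuc],
        ploidy=ploidy,
        provenance="initial_diploid" if (ploidy == 2).all() else "diploid_tetraploid",
    )
    chloroplast = None
    if is_cp.any():
        chloroplast = GenotypeMatrix(
            samples=samples,
            loci=sites.loc[is_cp].reset_index(drop=True),
            dosage=np.clip(dosage[:, is_cp], 0, 1),
            ploidy=np.ones(n, dtype=int),
            provenance="chloroplast",
        )
    return VariantData(ad_matrix, nuclear, chloroplast, n_multi)


def write_vcf(
    path: str,
    ad: AlleleDepthMatrix,
    dosage: np.ndarray,
    ploidy: np.ndarray,
    cp_genotypes: GenotypeMatrix | None = None,
    cp_depth: int = 30,
) -> None:
    """Write nuclear read counts + genotypes (and haploid cp sites) as VCF text.

    ``dosage`` must align with ``ad`` (NaN = missing).  Chloroplast genotypes
    get synthetic read counts of ``cp_depth`` supporting the called allele so
    depth filters downstream behave sensibly.
    """
    n = ad.n_samples
    contigs = sorted(set(ad.sites["chrom"]))
    if cp_genotypes is not None:
        contigs += sorted(set(cp_genotypes.loci["chrom"]) - set(contigs))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths (ref,alt)">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(ad.samples) + "\n")
        for j in range(ad.n_sites):
            site = ad.sites.iloc[j]
            cells = []
            for i in range(n):
                d = dosage[i, j]
                c = int(ploidy[i])
                if np.isnan(d) or ad.missing[i, j]:
                    gt = "/".join(["."] * c)
                else:
                    d = int(d)
                    gt = "/".join(["0"] * (c - d) + ["1"] * d)
                cells.append(f"{gt}:{ad.depth[i, j]}:"
                             f"{ad.depth[i, j] - ad.alt_depth[i, j]},{ad.alt_depth[i, j]}")
            fh.write(f"{site['chrom']}\t{site['pos']}\t.\t{site['ref']}\t"
                     f"{site['alt']}\t.\tPASS\t.\tGT:DP:AD\t" + "\t".join(cells) + "\n")
        if cp_genotypes is not None:
            for j in range(cp_genotypes.n_loci):
                site = cp_genotypes.loci.iloc[j]
                cells = []
                for i in range(n):
                    d = cp_genotypes.dosage[i, j]
                    if np.isnan(d):
                        cells.append(".:0:0,0")
                    elif d > 0:
                        cells.append(f"1:{cp_depth}:0,{cp_depth}")
                    else:
                        cells.append(f"0:{cp_depth}:{cp_depth},0")
                fh.write(f"{site['chrom']}\t{site['pos']}\t.\t{site['ref']}\t"
                         f"{site['alt']}\t.\tPASS\t.\tGT:DP:AD\t"
                         + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# STRUCTURE flat files (mixed-ploidy four-row coding)
# ---------------------------------------------------------------------------

def write_structure_file(G: GenotypeMatrix, ploidy_calls: dict[str, str],
                         path: str) -> None:
    """Write the mixed-ploidy STRUCTURE input: four rows per individual.

    Diploid-called samples carry their two allele rows then two rows of -9;
    samples called anything else carry allele rows at their data ploidy,
    padded to four rows with -9.  A dosage d in data-ploidy c is laid out
    ref-first: (c - d) rows of 0 then d rows of 1.  Missing genotypes are -9
    on every allele row.
    """
    missing_calls = [s for s in G.samples if s not in ploidy_calls]
    if missing_calls:
        raise ValueError(f"no ploidy call for samples: {missing_calls[:5]}")
    with open(path, "w") as fh:
        fh.write("\t".join(str(l) for l in _locus_ids(G)) + "\n")
        for i, sid in enumerate(G.samples):
            data_rows = 2 if ploidy_calls[sid] == "diploid" else int(G.ploidy[i])
            data_rows = min(data_rows, 4)
            for r in range(4):
                codes = []
                for j in range(G.n_loci):
                    d = G.dosage[i, j]
                    if r >= data_rows or np.isnan(d):
                        codes.append(MISSING_CODE)
                    else:
                        codes.append(0 if r < data_rows - int(d) else 1)
                fh.write(sid + "\t" + "\t".join(str(c) for c in codes) + "\n")


def _locus_ids(G: GenotypeMatrix) -> list[str]:
    if {"chrom", "pos"}.issubset(G.loci.columns):
        return [f"{c}_{p}" for c, p in zip(G.loci["chrom"], G.loci["pos"])]
    return [f"L{j + 1}" for j in range(G.n_loci)]


def read_structure_file(path: str) -> tuple[list[str], np.ndarray]:
    """Parse a four-row STRUCTURE file back to per-sample dosage sums.

    Returns sample ids and a dosage matrix (sum of alt codes over allele rows,
    NaN where every allele row is -9).
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        n_loci = len(header)
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    if len(rows) % 4:
        raise ValueError("row count is not a multiple of 4")
    ids, dosages = [], []
    for start in range(0, len(rows), 4):
        block = rows[start:start + 4]
        sid = block[0][0]
        if any(r[0] != sid for r in block):
            raise ValueError(f"rows of individual {sid} are not contiguous")
        codes = np.array([[int(x) for x in r[1:]] for r in block])
        if codes.shape[1] != n_loci:
            raise ValueError(f"locus count mismatch for {sid}")
        valid = codes != MISSING_CODE
        d = np.where(valid, codes, 0).sum(axis=0).astype(float)
        d[~valid.any(axis=0)] = np.nan
        ids.append(sid)
        dosages.append(d)
    return ids, np.array(dosages)


# ---------------------------------------------------------------------------
# STRUCTURE-style run outputs
# ---------------------------------------------------------------------------

_LNP_RE = re.compile(r"Estimated Ln Prob of Data\s*=\s*(-?[\d.]+)")
_K_RE = re.compile(r"(\d+)\s+populations assumed")


def write_structure_run(path: str, K: int, lnP: float, Q: np.ndarray,
                        sample_ids: list[str]) -> None:
    """Write one clustering replicate in the standard run-output layout."""
    Q = np.asarray(Q)
    with open(path, "w") as fh:
        fh.write(f"{K} populations assumed\n")
        fh.write(f"Estimated Ln Prob of Data = {lnP:.4f}\n\n")
        fh.write("Inferred ancestry of individuals:\n")
        fh.write("        Label (%Miss) Pop:  Inferred clusters\n")
        for i, sid in enumerate(sample_ids):
            qs = "  ".join(f"{q:.4f}" for q in Q[i])
            fh.write(f"  {i + 1} {sid}    (0)    1 :  {qs}\n")


def read_structure_runs(paths: list[str]) -> RunTable:
    """Parse run-output files into a RunTable, one row per (K, replicate)."""
    table = RunTable()
    rep_counter: dict[int, int] = {}
    for path in paths:
        with open(path) as fh:
            text = fh.read()
        m = _LNP_RE.search(text)
        if m is None:
            raise ValueError(f"missing estimated Ln Prob of Data in {path}")
        lnP = float(m.group(1))
        km = _K_RE.search(text)
        declared_k = int(km.group(1)) if km else None
        q_rows = []
        in_block = False
        for line in text.splitlines():
            if "Inferred ancestry of individuals" in line:
                in_block = True
                continue
            if in_block:
                if ":" not in line:
                    if q_rows:
                        break
                    continue
                tail = line.split(":", 1)[1].split()
                try:
                    q_rows.append([float(x) for x in tail])
                except ValueError:
                    if q_rows:
                        break
                    continue  # column-header line inside the block
        if not q_rows:
            raise ValueError(f"no membership matrix found in {path}")
        Q = np.array(q_rows)
        K = declared_k if declared_k is not None else Q.shape[1]
        if Q.shape[1] != K:
            raise ValueError(
                f"{path}: Q rows have {Q.shape[1]} columns but K={K} declared")
        rep_counter[K] = rep_counter.get(K, 0) + 1
        table.add(K, rep_counter[K], lnP, Q)
    return table
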