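"""Ploidy inference from allelic-ratio density profiles.

At a heterozygous site, the fraction of reads carrying the alternate allele
concentrates around dosage/ploidy: diploids show a single mode near 0.5,
triploids modes near 1/3 and 2/3, tetraploids near 0.25, 0.5 and 0.75, and
pentaploids near 0.2, 0.4, 0.6 and 0.8.  The workflow is:

1. compute per-sample allelic ratios (missing below a read-depth floor);
2. select "reference" SNPs whose ratio distribution across a clear-diploid
   panel is well behaved (adequate coverage, central mode, concentrated mass);
3. build a kernel density of each sample's ratios at the reference SNPs;
4. match the detected density peaks against the ploidy templates.

Samples whose peak pattern matches no template are labelled ``unknown``; the
pooled profile of a group of unknowns can still be classified collectively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks
from sklearn.base import BaseEstimator

from .containers import NUCLEAR, AlleleDepthMatrix

__all__ = [
    "RatioMatrix",
    "ReferenceSnpCriteria",
    "PloidyCall",
    "allelic_ratios",
    "select_reference_snps",
    "ratio_density",
    "classify_ploidy",
    "pooled_classification",
    "PloidyClassifier",
    "PLOIDY_TEMPLATES",
]

#: expected peak positions per ploidy label
PLOIDY_TEMPLATES: dict[str, tuple[float, ...]] = {
    "diploid": (0.5,),
    "triploid": (1 / 3, 2 / 3),
    "tetraploid": (0.25, 0.5, 0.75),
    "pentaploid": (0.2, 0.4, 0.6, 0.8),
}


@dataclass
class RatioMatrix:
    """Allelic ratios alt/(ref+alt); NaN below the depth floor."""

    samples: list[str]
    ratios: np.ndarray  # (n_samples, n_sites), NaN = missing
    depth: np.ndarray  # raw per-cell depth (for reference-SNP coverage rule)
    min_depth_used: int


@dataclass
class ReferenceSnpCriteria:
    """Filters defining a well-behaved reference SNP on a diploid panel."""

    min_mean_depth: float = 24.0
    mode_window: tuple[float, float] = (0.45, 0.55)
    tail_exclusion: tuple[float, float] = (0.05, 0.95)
    central_mass_window: tuple[float, float] = (0.4, 0.6)
    central_mass_min: float = 2 / 3
    mode_bin_width: float = 0.02


@dataclass
class PloidyCall:
    label: str  # diploid / triploid / tetraploid / pentaploid / unknown
    peaks: tuple[float, ...] = ()
    n_sites: int = 0
    note: str = ""


def allelic_ratios(ad: AlleleDepthMatrix, min_depth: int = 15) -> RatioMatrix:
    """Ratio = alt/(ref+alt) where depth >= ``min_depth``, else missing."""
    nuc = ad if (ad.sites["compartment"] == NUCLEAR).all() else ad.restrict(NUCLEAR)
    usable = (nuc.depth >= min_depth) & ~nuc.missing
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(usable, nuc.alt_depth / np.maximum(nuc.depth, 1), np.nan)
    return RatioMatrix(samples=list(nuc.samples), ratios=r,
                       depth=nuc.depth, min_depth_used=min_depth)


def select_reference_snps(
    R: RatioMatrix,
    diploid_panel: list[str],
    criteria: ReferenceSnpCriteria | None = None,
) -> np.ndarray:
    """Indices of sites that look clean across a panel of diploid samples.

    A site is retained iff, pooling the panel's non-missing ratios:
    (a) its mean depth over the panel meets ``min_mean_depth``;
    (b) after excluding tail ratios, the histogram mode (bin midpoint, ties
        broken toward 0.5) lies inside ``mode_window``;
    (c) at least ``central_mass_min`` of the remaining ratios fall inside
        ``central_mass_window``.
    """
    if not diploid_panel:
        raise ValueError("diploid panel is empty")
    crit = criteria or ReferenceSnpCriteria()
    idx = [R.samples.index(s) for s in diploid_panel]
    sub = R.ratios[idx]
    sub_depth = R.depth[idx]
    lo, hi = crit.tail_exclusion
    wlo, whi = crit.central_mass_window
    edges = np.arange(0.0, 1.0 + crit.mode_bin_width / 2, crit.mode_bin_width)
    mids = (edges[:-1] + edges[1:]) / 2

    keep = []
    for j in range(sub.shape[1]):
        if sub_depth[:, j].mean() < crit.min_mean_depth:
            continue
        r = sub[:, j]
        r = r[~np.isnan(r)]
        r = r[(r >= lo) & (r <= hi)]
        if r.size == 0:
            continue
        counts, _ = np.histogram(r, bins=edges)
        best = counts.max()
        tied = np.flatnonzero(counts == best)
        mode = mids[tied[np.argmin(np.abs(mids[tied] - 0.5))]]
        if not crit.mode_window[0] <= mode <= crit.mode_window[1]:
            continue
        if np.mean((r >= wlo) & (r <= whi)) < crit.central_mass_min:
            continue
        keep.append(j)
    return np.array(keep, dtype=int)


def _silverman_bandwidth(x: np.ndarray) -> float:
    sd = x.std(ddof=1) if x.size > 1 else 0.0
    iqr = np.subtract(*np.percentile(x, [75, 25])) / 1.34
    a = min(sd, iqr) if iqr > 0 else sd
    if a <= 0:
        a = 0.01
    return 0.9 * a * x.size ** (-1 / 5)


def ratio_density(
    ratios: np.ndarray,
    bandwidth: float | None = None,
    grid_size: int = 512,
    min_sites: int = 30,
) -> tuple[np.ndarray, np.ndarray] | None:
    """Gaussian KDE of allelic ratios on [0, 1] with boundary reflection.

    Returns ``(grid, density)`` normalised to integrate to one, or ``None``
    when fewer than ``min_sites`` usable ratios are available (the caller
    then reports the sample as ``unknown``).
    """
    r = np.asarray(ratios, dtype=float)
    r = r[~np.isnan(r)]
    if r.size < min_sites:
        return None
    bw = _silverman_bandwidth(r) if bandwidth is None else float(bandwidth)
    grid = np.linspace(0.0, 1.0, grid_size)
    data = np.concatenate([r, -r, 2.0 - r])  # reflect at both boundaries
    z = (grid[:, None] - data[None, :]) / bw
    dens = np.exp(-0.5 * z ** 2).sum(axis=1) / (r.size * bw * np.sqrt(2 * np.pi))
    area = np.trapezoid(dens, grid)
    if area > 0:
        dens = dens / area
    return grid, dens


def classify_ploidy(
    curve: tuple[np.ndarray, np.ndarray] | None,
    tolerance: float = 0.08,
    min_prominence: float = 0.05,
    n_sites: int = 0,
    min_separation: float = 0.1,
) -> PloidyCall:
    """Match detected density peaks to the ploidy templates.

    Local maxima with prominence >= ``min_prominence`` of the global maximum
    and pairwise separation >= ``min_separation`` are detected (adjacent
    template positions are never closer than 0.2, so two maxima within 0.1
    cannot both be genuine modes); a template matches iff every detected peak
    lies within ``tolerance`` of a distinct template position and every
    template position is hit.  Anything else (including degenerate curves)
    is ``unknown``.
    """
    if curve is None:
        return PloidyCall("unknown", note="too few usable sites")
    grid, dens = curve
    if not np.all(np.isfinite(dens)) or dens.max() <= 0:
        return PloidyCall("unknown", note="degenerate density")
    spacing = grid[1] - grid[0] if len(grid) > 1 else 1.0
    peaks_idx, _ = find_peaks(dens, prominence=min_prominence * dens.max(),
                              distance=max(1, int(min_separation / spacing)))
    peaks = tuple(np.round(grid[peaks_idx], 4))
    for label, template in PLOIDY_TEMPLATES.items():
        if len(peaks) != len(template):
            continue
        if all(abs(p - t) <= tolerance
               for p, t in zip(sorted(peaks), sorted(template))):
            return PloidyCall(label, peaks=peaks, n_sites=n_sites)
    return PloidyCall("unknown", peaks=peaks, n_sites=n_sites,
                      note="peak pattern matches no template")


def pooled_classification(
    ratios_per_sample: list[np.ndarray],
    bandwidth: float | None = None,
    min_sites: int = 30,
    tolerance: float = 0.08,
    min_prominence: float = 0.05,
) -> PloidyCall:
    """Classify a group of samples from their concatenated ratio profiles."""
    if not ratios_per_sample:
        raise ValueError("empty group")
    pooled = np.concatenate([np.asarray(r)[~np.isnan(np.asarray(r))]
                             for r in ratios_per_sample])
    curve = ratio_density(pooled, bandwidth=bandwidth, min_sites=min_sites)
    return classify_ploidy(curve, tolerance=tolerance,
                           min_prominence=min_prominence, n_sites=pooled.size)


class PloidyClassifier(BaseEstimator):
    """Per-sample ploidy calls from an allele-depth matrix.

    ``fit`` bootstraps the diploid reference panel: an initial pass classifies
    every sample on all nuclear sites, samples called diploid form the panel
    used to select reference SNPs, and one refinement pass repeats selection
    with the updated panel.  Fitted attributes: ``reference_sites_`` (column
    indices), ``panel_`` (sample ids), ``calls_`` (list of PloidyCall) and
    ``labels_``.

    Parameters follow the reference-SNP filters and the template matcher:
    ratios below ``min_depth`` reads are missing, peak matching uses
    ``tolerance`` and ``min_prominence``, and samples with fewer than
    ``min_sites`` usable ratios are ``unknown``.
    """

    def __init__(self, min_depth: int = 15, min_mean_depth: float = 24.0,
                 central_mass_min: float = 2 / 3, tolerance: float = 0.08,
                 min_prominence: float = 0.05, min_sites: int = 30,
                 bandwidth: float | None = 0.025, n_refinements: int = 1):
        self.min_depth = min_depth
        self.min_mean_depth = min_mean_depth
        self.central_mass_min = central_mass_min
        self.tolerance = tolerance
        self.min_prominence = min_prominence
        self.min_sites = min_sites
        self.bandwidth = bandwidth
        self.n_refinements = n_refinements

    # per-sample heterozygote proxy: drop near-fixed ratios before the KDE.
    # The window is wider than the 0.05/0.95 tail rule used for reference-SNP
    # selection: single error reads at ~20x land just above 0.05 on homozygous
    # sites and would otherwise fake an edge peak.
    @staticmethod
    def _het_ratios(row: np.ndarray) -> np.ndarray:
        r = row[~np.isnan(row)]
        return r[(r > 0.1) & (r < 0.9)]

    def _classify_rows(self, ratios: np.ndarray, cols=None) -> list[PloidyCall]:
        calls = []
        for i in range(ratios.shape[0]):
            row = ratios[i] if cols is None else ratios[i, cols]
            r = self._het_ratios(row)
            curve = ratio_density(r, bandwidth=self.bandwidth,
                                  min_sites=self.min_sites)
            calls.append(classify_ploidy(curve, tolerance=self.tolerance,
                                         min_prominence=self.min_prominence,
                                         n_sites=r.size))
        return calls

    def fit(self, ad: AlleleDepthMatrix, y=None):
        R = allelic_ratios(ad, min_depth=self.min_depth)
        self.ratio_matrix_ = R
        criteria = ReferenceSnpCriteria(min_mean_depth=self.min_mean_depth,
                                        central_mass_min=self.central_mass_min)
        calls = self._classify_rows(R.ratios)
        sites = np.arange(R.ratios.shape[1])
        for _ in range(self.n_refinements + 1):
            panel = [s for s, c in zip(R.samples, calls) if c.label == "diploid"]
            if not panel:
                break
            sites = select_reference_snps(R, panel, criteria)
            if sites.size == 0:
                break
            calls = self._classify_rows(R.ratios, cols=sites)
        self.panel_ = [s for s, c in zip(R.samples, calls) if c.label == "diploid"]
        self.reference_sites_ = sites
        self.calls_ = calls
        self.labels_ = np.array([c.label for c in calls])
        return self

    def predict(self, ad: AlleleDepthMatrix) -> np.ndarray:
        """Classify new samples at the fitted reference SNPs."""
        R = allelic_ratios(ad, min_depth=self.min_depth)
        calls = self._classify_rows(R.ratios, cols=self.reference_sites_)
        return np.array([c.label for c in calls])

    def pooled_call(self, sample_ids: list[str]) -> PloidyCall:
        """Collective call for a group (typically per-species unknowns)."""
        R = self.ratio_matrix_
        idx = [R.samples.index(s) for s in sample_ids]
        rows = [self._het_ratios(R.ratios[i, self.reference_sites_])
                for i in idx]
        return pooled_classification(rows, bandwidth=self.bandwidth,
                                     min_sites=self.min_sites,
                                     tolerance=self.tolerance,
                                     min_prominence=self.min_prominence)
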