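"""Allelic ratios, reference-SNP selection, density profiles and template
matching."""

import numpy as np
import pytest

from mixploid import ploidy as P
from mixploid.simulate import simulate_allelic_depths
from tests.conftest import make_allele_depths


class TestAllelicRatios:
    def test_values_and_depth_floor(self):
        depth = np.array([[24, 14, 20]])
        alt = np.array([[12, 4, 20]])
        R = P.allelic_ratios(make_allele_depths(depth, alt), min_depth=15)
        assert R.ratios[0, 0] == pytest.approx(0.5)
        assert np.isnan(R.ratios[0, 1])  # 14 reads < 15 -> missing
        assert R.ratios[0, 2] == pytest.approx(1.0)


class TestReferenceSnpSelection:
    def make_R(self, cols):
        """cols: list of per-site ratio arrays over a 20-sample panel."""
        n = 20
        ratios = np.column_stack([np.asarray(c, float) for c in cols])
        depth = np.full(ratios.shape, 30)
        return P.RatioMatrix(samples=[f"S{i}" for i in range(n)],
                             ratios=ratios, depth=depth, min_depth_used=15)

    def test_clean_site_retained(self):
        rng = np.random.default_rng(0)
        R = self.make_R([np.clip(rng.normal(0.5, 0.03, 20), 0, 1)])
        kept = P.select_reference_snps(R, R.samples)
        assert list(kept) == [0]

    def test_shifted_mode_rejected(self):
        rng = np.random.default_rng(1)
        R = self.make_R([np.clip(rng.normal(0.7, 0.03, 20), 0, 1)])
        assert len(P.select_reference_snps(R, R.samples)) == 0

    def test_dispersed_site_rejected(self):
        # mode at 0.5 but only half the mass inside [0.4, 0.6]
        vals = np.concatenate([np.full(10, 0.5),
                               np.linspace(0.07, 0.93, 10)])
        R = self.make_R([vals])
        assert len(P.select_reference_snps(R, R.samples)) == 0

    def test_low_coverage_rejected(self):
        rng = np.random.default_rng(2)
        R = self.make_R([np.clip(rng.normal(0.5, 0.03, 20), 0, 1)])
        R.depth[:] = 20  # below the 24x panel-mean rule
        assert len(P.select_reference_snps(R, R.samples)) == 0

    def test_empty_panel_rejected(self):
        R = self.make_R([np.full(20, 0.5)])
        with pytest.raises(ValueError):
            P.select_reference_snps(R, [])


class TestRatioDensity:
    def test_point_mass_argmax(self):
        curve = P.ratio_density(np.full(100, 0.5), bandwidth=0.02)
        grid, dens = curve
        assert abs(grid[np.argmax(dens)] - 0.5) < 0.01

    def test_normalised_and_non_negative(self):
        rng = np.random.default_rng(3)
        curve = P.ratio_density(rng.uniform(0.2, 0.8, 500))
        grid, dens = curve
        assert (dens >= 0).all()
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)

    def test_too_few_sites_sentinel(self):
        assert P.ratio_density(np.array([0.5] * 10), min_sites=30) is None
        call = P.classify_ploidy(None)
        assert call.label == "unknown"

    def test_simulated_triploid_bimodal(self):
        pairs = simulate_allelic_depths(3, 2000, mean_depth=40,
                                        overdispersion=None,
                                        depth_dispersion=None, seed=5)
        r = pairs[:, 1] / pairs.sum(axis=1)
        grid, dens = P.ratio_density(r, bandwidth=0.025)
        # histogram oracle: the two most loaded coarse bins bracket 1/3, 2/3
        counts, edges = np.histogram(r, bins=10, range=(0, 1))
        top2 = np.sort(np.argsort(counts)[-2:])
        assert top2[0] in (2, 3) and top2[1] in (5, 6)
        call = P.classify_ploidy((grid, dens))
        assert call.label == "triploid"


def _template_sample(positions, n=3000, sd=0.03, seed=0):
    rng = np.random.default_rng(seed)
    parts = [rng.normal(p, sd, n // len(positions)) for p in positions]
    return np.clip(np.concatenate(parts), 0.01, 0.99)


class TestTemplateMatching:
    @pytest.mark.parametrize("positions,label", [
        ((0.5,), "diploid"),
        ((1 / 3, 2 / 3), "triploid"),
        ((0.25, 0.5, 0.75), "tetraploid"),
        ((0.2, 0.4, 0.6, 0.8), "pentaploid"),
        ((0.1, 0.35, 0.62, 0.9), "unknown"),
    ])
    def test_labels(self, positions, label):
        r = _template_sample(positions)
        call = P.classify_ploidy(P.ratio_density(r, bandwidth=0.02))
        assert call.label == label

    @pytest.mark.parametrize("positions", [
        (0.5,), (1 / 3, 2 / 3), (0.25, 0.5, 0.75), (0.2, 0.4, 0.6, 0.8),
    ])
    def test_mirror_symmetry(self, positions):
        r = _template_sample(positions, seed=7)
        a = P.classify_ploidy(P.ratio_density(r, bandwidth=0.02))
        b = P.classify_ploidy(P.ratio_density(1 - r, bandwidth=0.02))
        assert a.label == b.label


class TestPooledClassification:
    def test_pooled_tetraploids(self):
        rows = []
        for i in range(10):
            pairs = simulate_allelic_depths(4, 120, mean_depth=40,
                                            overdispersion=None,
                                            depth_dispersion=None, seed=100 + i)
            rows.append(pairs[:, 1] / pairs.sum(axis=1))
        call = P.pooled_classification(rows, bandwidth=0.025)
        assert call.label == "tetraploid"

    def test_pooled_diploids(self):
        rows = []
        for i in range(10):
            pairs = simulate_allelic_depths(2, 120, mean_depth=40,
                                            overdispersion=None,
                                            depth_dispersion=None, seed=200 + i)
            rows.append(pairs[:, 1] / pairs.sum(axis=1))
        call = P.pooled_classification(rows, bandwidth=0.025)
        assert call.label == "diploid"

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            P.pooled_classification([])


def test_lower_depth_weakly_raises_unknown_rate():
    def unknown_rate(depth):
        unk = 0
        for i in range(30):
            pairs = simulate_allelic_depths(4, 400, mean_depth=depth,
                                            seed=300 + i)
            tot = pairs.sum(axis=1)
            r = pairs[tot >= 15, 1] / tot[tot >= 15]
            r = r[(r > 0.1) & (r < 0.9)]
            call = P.classify_ploidy(P.ratio_density(r, bandwidth=0.025))
            unk += call.label != "tetraploid"
        return unk / 30
    assert unknown_rate(12) >= unknown_rate(40)
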