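"""Filters, genetic distances, clone detection and mixed-ploidy recoding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from mixploid import assembly
from mixploid.containers import GenotypeMatrix
from mixploid.simulate import SimulationConfig, simulate_dataset


def make_G(dosage, ploidy=None, provenance="initial_diploid"):
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    loci = pd.DataFrame({"chrom": "chr1", "pos": np.arange(1, m + 1)})
    ploidy = np.full(n, 2) if ploidy is None else np.asarray(ploidy)
    return GenotypeMatrix(samples=[f"S{i}" for i in range(n)], loci=loci,
                          dosage=dosage, ploidy=ploidy, provenance=provenance)


class TestSampleFilter:
    def test_thresholds(self):
        d = np.zeros((3, 20))
        d[1, :9] = np.nan   # 45% missing
        d = np.vstack([d[0], d[1], d[2]])
        d[1, 9] = np.nan    # make it exactly 50% -> 10/20
        d[1, :10] = np.nan
        d[1, 10:] = 1
        G = make_G(np.array([[0.0] * 20,
                             [np.nan] * 9 + [1.0] * 11,
                             [1.0] * 20]))
        kept = assembly.filter_samples_by_missingness(G, 0.40)
        assert kept.samples == ["S0", "S2"]
        kept = assembly.filter_samples_by_missingness(G, 0.50)
        assert kept.samples == ["S0", "S1", "S2"]

    def test_all_removed_errors(self):
        G = make_G(np.full((2, 4), np.nan))
        with pytest.raises(ValueError):
            assembly.filter_samples_by_missingness(G, 0.30)

    def test_idempotent(self, toy_genotypes):
        once = assembly.filter_samples_by_missingness(toy_genotypes, 0.40)
        twice = assembly.filter_samples_by_missingness(once, 0.40)
        assert once.samples == twice.samples


class TestLocusFilter:
    def test_maf_and_missingness(self):
        # locus 0: monomorphic; locus 1: MAF 0.005 at ploidy-weighted freq;
        # locus 2: fine; locus 3: 40% missing
        n = 100
        d = np.zeros((n, 4))
        d[0, 1] = 1.0  # freq 1/200 = 0.005
        d[:, 2] = 1.0
        d[: int(0.4 * n), 3] = np.nan
        d[int(0.4 * n):, 3] = 1.0
        G = make_G(d)
        kept = assembly.filter_loci(G, maf_min=0.01, max_missing=0.30)
        assert list(kept.loci["pos"]) == [3]

    def test_ploidy_aware_frequency(self):
        d = np.array([[1.0], [2.0]])
        G = make_G(d, ploidy=[2, 4])
        assert assembly.locus_allele_frequency(G)[0] == pytest.approx(0.5)

    def test_idempotent(self, toy_genotypes):
        once = assembly.filter_loci(toy_genotypes, 0.01, 0.40)
        twice = assembly.filter_loci(once, 0.01, 0.40)
        assert once.loci.equals(twice.loci)


class TestDistances:
    def test_hand_cases(self):
        G = make_G([[0, 0], [2, 0], [1, np.nan]])
        D = assembly.genetic_distance_matrix(G)
        assert D[0, 1] == 2  # single locus difference 0 vs 2
        assert D[0, 2] == 1  # only the shared locus counts
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0)

    @settings(max_examples=25, deadline=None)
    @given(arrays(np.float64, (5, 8),
                  elements=st.sampled_from([0.0, 1.0, 2.0])))
    def test_symmetry_property(self, d):
        D = assembly.genetic_distance_matrix(make_G(d))
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0)


class TestClones:
    def test_pair_at_zero_distance(self):
        G = make_G([[0, 1, 2], [0, 1, 2], [2, 2, 0]])
        det = assembly.CloneDetector(threshold=1).fit(G)
        assert det.labels_[0] == det.labels_[1] != det.labels_[2]

    def test_chain_closure(self):
        # d(a,b)=300, d(b,c)=300, d(a,c)=600 -> one group at threshold 350
        D = np.array([[0, 300, 600], [300, 0, 300], [600, 300, 0]], float)
        groups = assembly.detect_clones(D, 350, ["a", "b", "c"])
        assert sorted(map(sorted, groups.groups)) == [["a", "b", "c"]]

    def test_all_singletons_above_threshold(self):
        D = np.array([[0, 10, 10], [10, 0, 10], [10, 10, 0]], float)
        groups = assembly.detect_clones(D, 5, ["a", "b", "c"])
        assert len(groups.groups) == 3

    def test_representative_least_missing_then_lexicographic(self):
        D = np.zeros((2, 2))
        g = assembly.detect_clones(D, 1, ["b", "a"],
                                   missing_fraction=np.array([0.0, 0.0]))
        assert g.representatives == ["a"]
        g = assembly.detect_clones(D, 1, ["b", "a"],
                                   missing_fraction=np.array([0.0, 0.5]))
        assert g.representatives == ["b"]

    def test_recovers_true_partition_at_zero_error(self):
        cfg = SimulationConfig(
            n_clusters=2, cluster_sizes=(15, 15), cluster_ploidy=(2, 2),
            cluster_divergence=(0.3, 0.3), cluster_regions=(("a",), ("b",)),
            n_nuclear_sites=400, hybrid_specs=(), n_clones=5,
            clone_error=0.0, missing_rate=0.0, n_teams=3, seed=9)
        ds = simulate_dataset(cfg)
        G = make_G(ds.true_dosage)
        G.samples[:] = list(ds.samples["id"])
        det = assembly.CloneDetector(threshold=0).fit(G)
        genet = det.groups_.genet_of()
        for _, row in ds.samples.iterrows():
            if row["clone_of"] is not None:
                assert genet[row["id"]] == genet[row["clone_of"]]


class TestRecoding:
    def test_diploid_recode_collapses_dosage(self):
        G = make_G([[0, 2, 4, 3, np.nan]], ploidy=[4])
        out = assembly.diploid_recode(G)
        np.testing.assert_array_equal(out.dosage[0, :4], [0, 1, 2, 1])
        assert np.isnan(out.dosage[0, 4])
        assert (out.ploidy == 2).all()

    @pytest.mark.parametrize("call,coded", [
        ("diploid", 2), ("triploid", 4), ("tetraploid", 4),
        ("pentaploid", 4), ("unknown", 4),
    ])
    def test_coded_ploidy(self, call, coded):
        G = make_G([[1, 0]], ploidy=[4] if call != "diploid" else [2])
        out = assembly.recode_mixed_ploidy(G, {"S0": call})
        assert out.ploidy[0] == coded
        assert out.provenance == "diploid_tetraploid"

    def test_missing_call_errors(self):
        G = make_G([[1, 0]])
        with pytest.raises(ValueError):
            assembly.recode_mixed_ploidy(G, {})
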