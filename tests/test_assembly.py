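"""Assembly tests: stacks, depth-outlier filter, catalog, haplotype calls."""

import warnings

import numpy as np
import pytest

import ddradsex as dx
from ddradsex.assembly import (
    AssemblyParams,
    CatalogLocus,
    IndividualLocus,
    build_catalog,
    build_stacks,
    call_haplotypes,
    depth_outlier_filter,
    matches_to_frame,
)
from oracles import oracle_stacks, random_clustery_reads

L = 20
BASE = "ACGTACGTACGTACGTACGT"


def mutate(seq, *positions):
    out = list(seq)
    for p in positions:
        out[p] = "A" if out[p] != "A" else "C"
    return "".join(out)


class TestBuildStacks:
    def test_identical_reads_single_locus(self):
        loci = build_stacks([BASE] * 10)
        assert len(loci) == 1
        assert loci[0].depth == 10
        assert loci[0].haplotype_count == 1
        assert loci[0].consensus == BASE

    def test_heterozygote_two_stacks_merge(self):
        alt = mutate(BASE, 3, 7)  # Hamming distance 2 <= M=4
        loci = build_stacks([BASE] * 6 + [alt] * 6)
        assert len(loci) == 1
        assert loci[0].haplotype_count == 2
        assert loci[0].depth == 12
        assert set(loci[0].alleles) == {BASE, alt}

    def test_three_linked_primaries_blacklisted(self):
        a, b, c = BASE, mutate(BASE, 1, 2), mutate(BASE, 3, 4)  # pairwise <= 4
        loci = build_stacks([a] * 5 + [b] * 5 + [c] * 5)
        assert loci == []
        assert oracle_stacks([a] * 5 + [b] * 5 + [c] * 5) == set()

    def test_secondary_reads_add_depth_only(self):
        err = mutate(BASE, 9)
        loci = build_stacks([BASE] * 8 + [err] * 2)  # err group below m=3
        assert len(loci) == 1
        assert loci[0].depth == 10
        assert loci[0].haplotype_count == 1  # secondaries are not alleles

    def test_ambiguous_secondary_dropped(self):
        # two loci 8 apart (> M, not merged); a midpoint read is within
        # N=10 of both consensuses, so its depth goes nowhere
        far = mutate(BASE, 10, 11, 12, 13, 14, 15, 16, 17)
        mid = mutate(BASE, 10, 11, 12, 13)
        loci = build_stacks([BASE] * 5 + [far] * 5 + [mid] * 2)
        assert sorted(l.depth for l in loci) == [5, 5]

    def test_unequal_read_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            build_stacks([BASE, BASE[:-1]])

    def test_consensus_majority_with_lexicographic_ties(self):
        alt = mutate(BASE, 0)
        # equal depths at the variable column -> alphabetically first base
        loci = build_stacks([BASE] * 5 + [alt] * 5)
        expected = min(BASE[0], alt[0]) + BASE[1:]
        assert loci[0].consensus == expected

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        reads = random_clustery_reads(rng, n_reads=int(rng.integers(20, 150)))
        ours = {(frozenset(l.alleles), l.depth, l.consensus) for l in build_stacks(reads)}
        assert ours == oracle_stacks(reads)

    def test_error_free_individual_recovers_carried_loci(self, ef_discovery, ef_config):
        """Each error-free individual assembles exactly one locus per
        reference locus it carries (before the depth-outlier filter, which
        may trim the extreme right tail of the depth distribution)."""
        carried = {
            "female": ef_config.genome.n_autosomal_loci + ef_config.genome.n_w_specific_loci,
            "male": ef_config.genome.n_autosomal_loci,
        }
        for ind in ef_discovery.individuals:
            loci = build_stacks(ef_discovery.process.assigned[ind.individual_id])
            assert len(loci) == carried[ind.sex]


class TestDepthOutlierFilter:
    def _locus(self, depth, i=0):
        return IndividualLocus(i, BASE, (BASE,), depth, 1)

    def test_equal_depths_nothing_removed(self):
        loci = [self._locus(20, i) for i in range(10)]
        assert len(depth_outlier_filter(loci)) == 10

    def test_extreme_outlier_removed(self):
        depths = [20] * 99 + [1000]
        loci = [self._locus(d, i) for i, d in enumerate(depths)]
        cutoff = np.mean(depths) + 3 * np.std(depths, ddof=1)
        kept = depth_outlier_filter(loci)
        assert [l.depth for l in kept] == [20] * 99
        assert 1000 > cutoff > 20

    def test_single_locus_untouched(self):
        loci = [self._locus(1000)]
        assert depth_outlier_filter(loci) == loci

    def test_planted_repeat_locus_removed_in_simulation(self):
        """A locus receiving ~10x autosomal depth (a collapsed repeat) is
        removed by the per-individual mean + 3 SD rule."""
        rng = np.random.default_rng(8)
        depths = rng.poisson(30, size=99).tolist() + [300]
        loci = [self._locus(d, i) for i, d in enumerate(depths)]
        kept = depth_outlier_filter(loci)
        assert all(l.depth != 300 for l in kept)
        assert len(kept) >= 98


class TestCatalog:
    def _ind_locus(self, consensus, depth=10):
        return IndividualLocus(1, consensus, (consensus,), depth, 1)

    def test_shared_consensus_merges(self):
        catalog = build_catalog({"a": [self._ind_locus(BASE)], "b": [self._ind_locus(BASE)]})
        assert len(catalog) == 1
        assert set(catalog[0].members) == {"a", "b"}

    def test_one_mismatch_stays_separate_at_n0(self):
        catalog = build_catalog(
            {"a": [self._ind_locus(BASE)], "b": [self._ind_locus(mutate(BASE, 0))]}
        )
        assert len(catalog) == 2

    def test_partition_invariant_under_individual_order(self):
        rng = np.random.default_rng(9)
        seqs = [mutate(BASE, int(p)) for p in rng.integers(0, L, size=6)]
        forward = {f"i{k}": [self._ind_locus(s)] for k, s in enumerate(seqs)}
        backward = dict(reversed(list(forward.items())))
        a = [(c.catalog_id, c.consensus, tuple(sorted(c.members))) for c in build_catalog(forward)]
        b = [(c.catalog_id, c.consensus, tuple(sorted(c.members))) for c in build_catalog(backward)]
        assert a == b

    def test_greedy_merge_with_positive_n_warns(self):
        params = AssemblyParams(catalog_mismatch=2)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            catalog = build_catalog(
                {"a": [self._ind_locus(BASE)], "b": [self._ind_locus(mutate(BASE, 0))]}, params
            )
        assert len(catalog) == 1
        assert any("order" in str(w.message) for w in caught)

    def test_error_free_monomorphic_catalog_equals_planted_count(self):
        """With snp_rate 0 every individual's consensus is the planted
        sequence, so the catalog has exactly one locus per planted locus."""
        from ddradsex.pipeline import ScanParams

        cfg = dx.RunConfig(
            genome=dx.GenomeSpec(n_autosomal_loci=20, n_w_specific_loci=3, snp_rate=0.0),
            sim=dx.SimConfig(mean_depth_per_locus=25.0),
            scan=ScanParams(min_autosomal_loci=10),
            n_females=4, n_males=4, error_rate=0.0, seed=21,
        )
        result = dx.discover(cfg)
        assert len(result.catalog) == 23


class TestCallHaplotypes:
    def _member(self, *alleles, depth=10):
        return IndividualLocus(1, alleles[0], tuple(alleles), depth, len(alleles))

    def test_haplotypes_at_variable_columns(self):
        # variable columns {17, 80}; the heterozygote carries A/C at 17 and
        # G/G at 80 -> haplotypes {"AG", "CG"}
        background = "A" * 80 + "G" + "A" * 19
        a_allele = background
        c_allele = background[:17] + "C" + background[18:]
        t80 = background[:80] + "T" + background[81:]  # second member varies column 80
        locus = CatalogLocus(
            1, background, {"het": self._member(a_allele, c_allele), "other": self._member(t80)}
        )
        haps, variable, excluded = call_haplotypes(locus)
        assert variable == [17, 80]
        assert set(haps["het"]) == {"AG", "CG"}
        assert haps["other"] == ("AT",)
        assert not excluded

    def test_monomorphic_locus_yields_consensus_haplotype(self):
        locus = CatalogLocus(1, BASE, {"a": self._member(BASE), "b": self._member(BASE)})
        haps, variable, excluded = call_haplotypes(locus)
        assert variable == []
        assert haps == {"a": ("consensus",), "b": ("consensus",)}
        assert not excluded

    def test_triallelic_member_flags_exclusion(self):
        a, b, c = BASE, mutate(BASE, 0), mutate(BASE, 1)
        locus = CatalogLocus(1, BASE, {"bad": self._member(a, b, c), "ok": self._member(a)})
        _, _, excluded = call_haplotypes(locus)
        assert excluded

    def test_matches_frame_columns(self):
        locus = CatalogLocus(1, BASE, {"a": self._member(BASE, depth=7)})
        frame = matches_to_frame([locus])
        assert list(frame.columns) == ["catalog_id", "individual", "haplotypes", "haplotype_count", "depth"]
        assert frame.iloc[0]["depth"] == 7
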