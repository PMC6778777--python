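"""Simulator tests: digestion, size selection, reference and read generation."""

import hashlib
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ddradsex as dx
from ddradsex import synth as sy

DNA = st.text(alphabet="ACGT", min_size=0, max_size=200)


class TestDigest:
    def test_no_sites_yields_single_terminal_fragment(self):
        frags = dx.in_silico_digest("ACGTACGTACGT", dx.SPHI, dx.ECORI)
        assert len(frags) == 1
        assert (frags[0].end5_type, frags[0].end3_type) == ("terminus", "terminus")

    def test_one_site_of_each_enzyme(self):
        # TT GCATGC TTTTTTTT GAATTC TT: SphI cuts after 5 bases of its site,
        # EcoRI after 1, giving boundaries at 7 and 17.
        seq = "TTGCATGCTTTTTTTTGAATTCTT"
        frags = dx.in_silico_digest(seq, dx.SPHI, dx.ECORI)
        assert [(f.start, f.end) for f in frags] == [(0, 7), (7, 17), (17, 24)]
        middle = frags[1]
        assert (middle.end5_type, middle.end3_type) == ("SphI", "EcoRI")
        assert sum(f.length for f in frags) == len(seq)
        assert seq[middle.start:middle.end].startswith(dx.SPHI.remnant_5prime)
        assert seq[middle.start:middle.end].endswith(dx.ECORI.remnant_3prime)

    def test_concatenation_doubles_fragments_minus_one(self):
        unit = "AAAGCATGCAAAGAATTCAAA"  # one SphI + one EcoRI site -> 3 fragments
        k = len(dx.in_silico_digest(unit, dx.SPHI, dx.ECORI))
        assert k == 3
        linker = "TTTTTTTT"  # no sites
        joined = unit + linker + unit
        assert len(dx.in_silico_digest(joined, dx.SPHI, dx.ECORI)) == 2 * k - 1

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            dx.in_silico_digest("ACGTX", dx.SPHI, dx.ECORI)

    def test_identical_enzymes_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            dx.in_silico_digest("ACGT", dx.SPHI, dx.SPHI)

    @settings(max_examples=60, derandomize=True)
    @given(st.lists(DNA, min_size=1, max_size=6))
    def test_conservation_and_boundary_positions_match_reference_library(self, chunks):
        """Fragment lengths always sum to the input length, and internal cut
        positions agree with Biopython's restriction machinery."""
        from Bio.Restriction import EcoRI, SphI
        from Bio.Seq import Seq

        seq = "GCATGC".join(chunks) + "GAATTC" + chunks[0]
        frags = dx.in_silico_digest(seq, dx.SPHI, dx.ECORI)
        assert sum(f.length for f in frags) == len(seq)
        internal = [f.start for f in frags[1:]]
        expected = sorted([p - 1 for p in SphI.search(Seq(seq))] + [p - 1 for p in EcoRI.search(Seq(seq))])
        assert internal == expected


class TestSizeSelect:
    def test_empty_input(self):
        assert dx.size_select([], (450, 550)) == []

    def test_dual_cut_in_window_retained(self):
        frag = sy.Fragment(0, 500, "SphI", "EcoRI")
        assert dx.size_select([frag], (450, 550)) == [frag]

    def test_single_enzyme_fragment_excluded_despite_length(self):
        frag = sy.Fragment(0, 500, "SphI", "SphI")
        assert dx.size_select([frag], (450, 550)) == []

    def test_wrong_orientation_and_out_of_window_excluded(self):
        frags = [
            sy.Fragment(0, 500, "EcoRI", "SphI"),
            sy.Fragment(0, 449, "SphI", "EcoRI"),
            sy.Fragment(0, 551, "SphI", "EcoRI"),
        ]
        assert dx.size_select(frags, (450, 550)) == []


class TestReference:
    def test_no_sex_limited_loci_when_none_requested(self):
        spec = dx.GenomeSpec(n_autosomal_loci=5, n_w_specific_loci=0)
        ref = dx.simulate_reference(spec, np.random.default_rng(0))
        assert ref.sex_limited_ids() == []

    def test_planted_counts_and_truth_table(self):
        spec = dx.GenomeSpec(n_autosomal_loci=100, n_w_specific_loci=5)
        ref = dx.simulate_reference(spec, np.random.default_rng(1))
        classes = Counter(ref.truth_table.values())
        assert classes == {"autosome": 100, "W": 5}
        assert len(ref.sex_limited_ids()) == 5

    def test_locus_structure_and_separability(self):
        config = dx.SimConfig()
        spec = dx.GenomeSpec(n_autosomal_loci=30, n_w_specific_loci=3)
        ref = dx.simulate_reference(spec, np.random.default_rng(2), config)
        low, high = spec.locus_length_window
        views = []
        for locus in ref.loci:
            for allele in locus.alleles:
                assert allele.startswith(dx.SPHI.remnant_5prime)
                assert allele.endswith(dx.ECORI.remnant_3prime)
                assert low <= len(allele) <= high
                assert dx.SPHI.recognition not in allele
                assert dx.ECORI.recognition not in allele
                views.append((locus.locus_id, sy.stitched_view(allele, config)))
        # any two distinct loci differ at more than M=4 read-visible positions
        for i in range(len(views)):
            for j in range(i + 1, len(views)):
                if views[i][0] != views[j][0]:
                    d = sum(x != y for x, y in zip(views[i][1], views[j][1]))
                    assert d > 4

    def test_window_too_small_for_reads_rejected(self):
        spec = dx.GenomeSpec(locus_length_window=(200, 250))
        with pytest.raises(ValueError, match="at least"):
            dx.simulate_reference(spec, np.random.default_rng(0))

    def test_genome_round_trip_digest_recovers_loci(self):
        """Reassembling a pseudo-chromosome and double-digesting it yields
        exactly the planted fragments."""
        config = dx.SimConfig()
        spec = dx.GenomeSpec(n_autosomal_loci=8, n_w_specific_loci=2)
        rng = np.random.default_rng(3)
        ref = dx.simulate_reference(spec, rng, config)
        genome = sy.build_genome(ref, rng, config)
        frags = dx.in_silico_digest(genome, dx.SPHI, dx.ECORI)
        kept = dx.size_select(frags, spec.locus_length_window)
        recovered = sorted(genome[f.start:f.end] for f in kept)
        planted = sorted(locus.alleles[0] for locus in ref.loci)
        assert recovered == planted


class TestReadSimulation:
    def test_error_free_reads_identical_per_allele(self):
        config = dx.SimConfig(mean_depth_per_locus=10.0, seed=4)
        spec = dx.GenomeSpec(n_autosomal_loci=1, n_w_specific_loci=0, snp_rate=0.0)
        rng = np.random.default_rng(4)
        ref = dx.simulate_reference(spec, rng, config)
        cohort = dx.make_cohort(ref, 1, 0, config, rng, error_rate=0.0)
        r1, r2 = dx.simulate_read_records(ref, cohort, config)
        assert len(r1) == cohort[0].target_read_pairs
        assert len({rec.sequence for rec in r1}) == 1
        assert len({rec.sequence for rec in r2}) == 1

    def test_hemizygous_depth_is_half_diploid(self):
        """Across >=1000 loci, mean W depth in a ZW female converges to half
        the mean autosomal depth (single copy vs two copies)."""
        config = dx.SimConfig(mean_depth_per_locus=20.0, seed=5)
        spec = dx.GenomeSpec(n_autosomal_loci=600, n_w_specific_loci=600, snp_rate=0.0)
        rng = np.random.default_rng(5)
        ref = dx.simulate_reference(spec, rng, config)
        cohort = dx.make_cohort(ref, 1, 0, config, rng, error_rate=0.0)
        r1, _ = dx.simulate_read_records(ref, cohort, config)
        per_class = Counter()
        for rec in r1:
            locus_id = rec.read_id.split("|")[1]
            per_class[ref.truth_table[locus_id]] += 1
        mean_w = per_class["W"] / 600
        mean_auto = per_class["autosome"] / 600
        assert mean_w / mean_auto == pytest.approx(0.5, rel=0.05)

    def test_xy_males_carry_all_y_loci_females_none(self):
        config = dx.SimConfig(mean_depth_per_locus=12.0, seed=6)
        spec = dx.GenomeSpec(n_autosomal_loci=10, n_w_specific_loci=4, system="XY")
        rng = np.random.default_rng(6)
        ref = dx.simulate_reference(spec, rng, config)
        cohort = dx.make_cohort(ref, 2, 2, config, rng, error_rate=0.0)
        r1, _ = dx.simulate_read_records(ref, cohort, config)
        y_ids = set(ref.sex_limited_ids())
        seen_by_male = set()
        for rec in r1:
            ind, locus_id = rec.read_id.split("|")[:2]
            sex = next(i.sex for i in cohort if i.individual_id == ind)
            if locus_id in y_ids:
                assert sex == "male", "a female read originated from a Y locus"
                seen_by_male.add(locus_id)
        assert seen_by_male == y_ids

    def test_seed_determinism_byte_identical_files(self, tmp_path):
        config = dx.SimConfig(mean_depth_per_locus=8.0, seed=7)
        spec = dx.GenomeSpec(n_autosomal_loci=6, n_w_specific_loci=1)

        def digest_of_run(tag):
            rng = np.random.default_rng(11)
            ref = dx.simulate_reference(spec, rng, config)
            cohort = dx.make_cohort(ref, 2, 2, config, rng, error_rate=0.001)
            paths = dx.simulate_reads(ref, cohort, config, tmp_path / tag)
            return {k: hashlib.sha256(p.read_bytes()).hexdigest() for k, p in paths.items()}

        assert digest_of_run("a") == digest_of_run("b")

    def test_individual_spec_validation(self):
        with pytest.raises(ValueError, match="barcode"):
            dx.IndividualSpec("x", "female", "ACGTN", 10)
        with pytest.raises(ValueError, match="target_read_pairs"):
            dx.IndividualSpec("x", "female", "ACGTA", 0)

    def test_genome_spec_validation(self):
        with pytest.raises(ValueError):
            dx.GenomeSpec(n_autosomal_loci=-1)
        with pytest.raises(ValueError):
            dx.GenomeSpec(system="WZ")
        with pytest.raises(ValueError):
            dx.GenomeSpec(locus_length_window=(550, 450))
        with pytest.raises(ValueError):
            dx.GenomeSpec(gc_content=1.5)
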