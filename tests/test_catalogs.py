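"""Channel classification, opportunity counting, and catalog conversion."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from ucsomatic.catalogs import (
    DBS78_CHANNELS,
    ID83_CHANNELS,
    SBS96_CHANNELS,
    TRINUCLEOTIDES_32,
    MutationCatalog,
    OpportunityVector,
    build_catalog,
    classify_indel,
    compute_opportunities,
    convert_catalog,
    dbs_channel,
    id_channel,
    revcomp,
    sbs_channel,
)
from ucsomatic.filtering import SomaticVariant

BASES = "ACGT"


class TestSbsChannel:
    def test_pyrimidine_passthrough(self):
        assert sbs_channel("C", "T", "A", "G") == "A[C>T]G"

    def test_purine_reverse_complemented(self):
        # G>A in trinucleotide TGA
        assert sbs_channel("G", "A", "T", "A") == "T[C>T]A"

    def test_ref_equals_alt_is_error(self):
        with pytest.raises(ValueError):
            sbs_channel("C", "C", "A", "A")

    def test_non_acgt_is_error(self):
        with pytest.raises(ValueError):
            sbs_channel("C", "T", "N", "A")

    @given(
        ref=st.sampled_from(BASES),
        alt=st.sampled_from(BASES),
        five=st.sampled_from(BASES),
        three=st.sampled_from(BASES),
    )
    def test_strand_symmetry(self, ref, alt, five, three):
        """A substitution and its reverse complement share one channel."""
        if ref == alt:
            return
        forward = sbs_channel(ref, alt, five, three)
        reverse = sbs_channel(revcomp(ref), revcomp(alt), revcomp(three), revcomp(five))
        assert forward == reverse
        assert forward in SBS96_CHANNELS


class TestDbsChannel:
    def test_canonical_passthrough(self):
        assert dbs_channel("TC", "CA") == "TC>CA"

    def test_noncanonical_ref_reverse_complemented(self):
        assert dbs_channel("CA", "TG") == "TG>CA"

    def test_identical_doublets_error(self):
        with pytest.raises(ValueError):
            dbs_channel("TG", "TG")

    def test_single_base_change_rejected(self):
        with pytest.raises(ValueError, match="both bases"):
            dbs_channel("TC", "TA")

    def test_enumeration_covers_78_channels_exactly(self):
        """Brute-force enumeration of all true doublet substitutions maps
        onto the 78 channels, with reverse-complement pairs collapsing."""
        seen = {}
        for r0, r1, a0, a1 in itertools.product(BASES, repeat=4):
            ref, alt = r0 + r1, a0 + a1
            if r0 == a0 or r1 == a1:
                continue
            label = dbs_channel(ref, alt)
            assert label in DBS78_CHANNELS
            assert dbs_channel(revcomp(ref), revcomp(alt)) == label
            seen.setdefault(label, set()).add((ref, alt))
        assert set(seen) == set(DBS78_CHANNELS)
        # 144 raw substitutions collapse pairwise, except revcomp-fixed points
        assert sum(len(v) for v in seen.values()) == 144
        assert all(len(v) in (1, 2) for v in seen.values())


class TestIdChannel:
    def test_deletion_in_long_homopolymer(self):
        # one T deleted from a run of six T's: longest homopolymer bin
        left, right = "GACGACGACG" + "TT", "TTT" + "GACGACGACG"
        assert classify_indel("Del", "T", left, right) == "1:Del:T:5"

    def test_deletion_with_no_repeat(self):
        # T deleted in a CTG context: single-copy bin
        assert classify_indel("Del", "T", "GAGAGAGAC", "GCGCGCGCG") == "1:Del:T:0"

    def test_purine_mapped_to_pyrimidine(self):
        assert classify_indel("Del", "A", "GCGCGCGCG", "CGCGCGCGC") == "1:Del:T:0"

    def test_microhomology_two_bases(self):
        # 4-bp deletion TCGA whose 3' flank begins TC
        left = "GGGTTGGGTTGGGTTGGGTT"
        right = "TCTTTAATTTAATTTAATTT"
        assert classify_indel("Del", "TCGA", left, right) == "4:Del:M:2"

    def test_tandem_repeat_deletion(self):
        left, right = "G" * 20, "CAGCAG" + "T" * 14
        assert classify_indel("Del", "CAG", left, right) == "3:Del:R:2"

    def test_insertion_into_existing_run(self):
        left, right = "G" * 20, "TTT" + "G" * 17
        assert classify_indel("Ins", "T", left, right) == "1:Ins:T:3"

    def test_insufficient_flank_is_error(self):
        with pytest.raises(ValueError, match="flank"):
            classify_indel("Del", "TCGA", "AT", "GC")

    def test_channels_are_valid(self):
        assert classify_indel("Del", "T", "G" * 9, "C" * 9) in ID83_CHANNELS

    def test_id_channel_from_genome(self):
        genome = {"chr1": "GGGGGGGGGG" + "CTTTTTTG" + "GGGGGGGGGGGG"}
        # VCF-anchored deletion of one T at the run start: pos 11 = C anchor
        v = SomaticVariant(
            chrom="chr1", pos=11, ref="CT", alt="C", variant_class="DEL",
            tumor_depth=50, tumor_alt=20, normal_depth=50, normal_alt=0,
            sample_id="T1",
        )
        assert id_channel(v, genome) == "1:Del:T:5"


class TestBuildCatalog:
    def _snv(self, pos, ref, alt, sample="T1"):
        return SomaticVariant(
            chrom="chr1", pos=pos, ref=ref, alt=alt, variant_class="SNV",
            tumor_depth=60, tumor_alt=30, normal_depth=60, normal_alt=0,
            sample_id=sample,
        )

    def test_single_snv_single_channel(self, tiny_genome):
        pos = 500
        ref = tiny_genome["chr1"][pos - 1]
        alt = "A" if ref != "A" else "G"
        cat = build_catalog([self._snv(pos, ref, alt)], tiny_genome, "SBS96")
        assert cat.counts.to_numpy().sum() == 1
        assert (cat.counts["T1"] > 0).sum() == 1

    def test_empty_variant_list_all_zero(self, tiny_genome):
        cat = build_catalog([], tiny_genome, "SBS96", sample_ids=["A", "B"])
        assert cat.sample_ids == ["A", "B"]
        assert cat.counts.to_numpy().sum() == 0

    def test_mixed_list_partitions_and_skips(self, tiny_genome):
        rng = np.random.default_rng(3)
        variants = []
        k = 25
        for _ in range(k):
            pos = int(rng.integers(100, 90_000))
            ref = tiny_genome["chr1"][pos - 1]
            alt = str(rng.choice([b for b in BASES if b != ref]))
            variants.append(self._snv(pos, ref, alt))
        m = 7
        for _ in range(m):
            pos = int(rng.integers(100, 90_000))
            anchor = tiny_genome["chr1"][pos - 1]
            deleted = tiny_genome["chr1"][pos : pos + 2]
            variants.append(
                SomaticVariant(
                    chrom="chr1", pos=pos, ref=anchor + deleted, alt=anchor,
                    variant_class="DEL", tumor_depth=60, tumor_alt=30,
                    normal_depth=60, normal_alt=0, sample_id="T1",
                )
            )
        cat = build_catalog(variants, tiny_genome, "SBS96")
        assert cat.counts["T1"].sum() == k
        assert sum(cat.skipped.values()) == m

    def test_locus_outside_genome_is_error(self, tiny_genome):
        with pytest.raises(KeyError, match="chr9"):
            build_catalog(
                [
                    SomaticVariant(
                        chrom="chr9", pos=5, ref="C", alt="T", variant_class="SNV",
                        tumor_depth=60, tumor_alt=30, normal_depth=60,
                        normal_alt=0, sample_id="T1",
                    )
                ],
                tiny_genome,
                "SBS96",
            )


class TestOpportunities:
    def test_five_base_contig_brute_force(self):
        genome = {"c": "ACGTA"}
        opps = compute_opportunities(genome, [("c", 0, 5)], flank=0)
        # trinucleotides ACG (center C), CGT (center G -> ACG), GTA (center T)
        assert opps.counts["ACG"] == 2
        assert opps.counts["GTA"] == 1
        assert opps.counts.sum() == 3

    def test_overlapping_intervals_equal_merged_union(self, tiny_genome):
        a = compute_opportunities(
            tiny_genome, [("chr1", 100, 600), ("chr1", 400, 900)], flank=0
        )
        b = compute_opportunities(tiny_genome, [("chr1", 100, 900)], flank=0)
        assert a.counts.equals(b.counts)

    def test_flank_extends_territory(self, tiny_genome):
        narrow = compute_opportunities(tiny_genome, [("chr1", 100, 200)], flank=0)
        wide = compute_opportunities(tiny_genome, [("chr1", 98, 202)], flank=0)
        flanked = compute_opportunities(tiny_genome, [("chr1", 100, 200)], flank=2)
        assert flanked.counts.equals(wide.counts)
        assert flanked.counts.sum() == narrow.counts.sum() + 4

    def test_empty_intervals_error(self, tiny_genome):
        with pytest.raises(ValueError):
            compute_opportunities(tiny_genome, [])

    def test_n_contexts_skipped(self):
        genome = {"c": "ACGNACGTAA"}
        opps = compute_opportunities(genome, [("c", 0, 10)], flank=0)
        recount = 0
        for p in range(1, 9):
            tri = genome["c"][p - 1 : p + 2]
            if "N" not in tri:
                recount += 1
        assert opps.counts.sum() == recount


class TestConvertCatalog:
    def _uniform_opps(self, value=100.0):
        return OpportunityVector(
            counts=pd.Series(value, index=list(TRINUCLEOTIDES_32))
        )

    def _toy_catalog(self):
        counts = pd.DataFrame(0.0, index=list(SBS96_CHANNELS), columns=["S"])
        counts.loc["A[C>T]G", "S"] = 70
        counts.loc["T[T>A]A", "S"] = 30
        return MutationCatalog(counts=counts, scheme="SBS96")

    def test_identity_when_opportunities_match(self):
        cat = self._toy_catalog()
        opps = self._uniform_opps()
        out = convert_catalog(cat, opps, opps)
        pd.testing.assert_frame_equal(out.counts, cat.counts)

    def test_doubling_target_context_doubles_relative_weight(self):
        cat = self._toy_catalog()
        src = self._uniform_opps()
        tgt_counts = pd.Series(100.0, index=list(TRINUCLEOTIDES_32))
        tgt_counts["ACG"] *= 2  # context of A[C>T]G
        tgt = OpportunityVector(counts=tgt_counts)
        out = convert_catalog(cat, src, tgt, preserve_totals=False)
        ratio = (out.counts.loc["A[C>T]G", "S"] / cat.counts.loc["A[C>T]G", "S"]) / (
            out.counts.loc["T[T>A]A", "S"] / cat.counts.loc["T[T>A]A", "S"]
        )
        assert ratio == pytest.approx(2.0)

    def test_row_totals_preserved(self, tiny_genome, two_signature_cohort):
        cat = two_signature_cohort["catalog"]
        src = two_signature_cohort["opportunities"]
        tgt = compute_opportunities(tiny_genome, [("chr1", 0, 50_000)], flank=0)
        out = convert_catalog(cat, src, tgt)
        pd.testing.assert_series_equal(out.sample_totals(), cat.sample_totals())

    def test_zero_source_opportunity_is_error(self):
        cat = self._toy_catalog()
        bad = pd.Series(100.0, index=list(TRINUCLEOTIDES_32))
        bad["ACG"] = 0.0
        with pytest.raises(ValueError, match="ACG"):
            convert_catalog(cat, OpportunityVector(counts=bad), self._uniform_opps())


def test_catalog_converges_to_opportunity_weighted_signature(tiny_genome):
    """At many draws the empirical spectrum matches the reweighted truth."""
    from ucsomatic import synthetic as syn
    from ucsomatic.catalogs import channel_context
    from ucsomatic.signatures import SignatureMatrix, cosine_similarity

    sigs = SignatureMatrix(
        data=pd.DataFrame({"PT": syn.pt_like_signature()}), scheme="SBS96"
    )
    config = syn.SimulationConfig(
        seed=11,
        n_samples=1,
        mutations_per_sample=100_000,
        signatures=sigs,
        exposures=pd.DataFrame({"PT": [1.0]}, index=["S01"]),
        contig_lengths={"chr1": 200_000},
    )
    genome, exome, _ = syn.generate_reference(config)
    variants, _ = syn.simulate_variants(config, genome, exome)
    cat = build_catalog(variants, genome, "SBS96")
    opps = compute_opportunities(genome, exome, flank=0)
    w = np.array([opps.counts[channel_context(c)] for c in SBS96_CHANNELS])
    truth = sigs.column("PT") * w
    assert cosine_similarity(cat.spectrum("S01"), truth) >= 0.99
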