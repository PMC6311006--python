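"""Allele-specific primer design, in-silico PCR and band-based sex calls."""

import pytest

from sexmarker import (
    BandSexCall,
    HaplotypePair,
    PrimerDesignError,
    PrimerPairSpec,
    PrimerRole,
    PrimerSpec,
    Strand,
    ValidationError,
    call_divergent_sites,
    design_allele_specific_primer,
    design_control_pair,
    in_silico_pcr,
    locate_primer,
    melting_temperature,
    predict_band_pattern,
    reverse_complement,
    simulate_haplotype_pair,
)
from sexmarker.fixtures import (
    SPFS_FORWARD,
    SPFS_MISMATCH_OFFSETS,
    load_fixture_primers,
)
from sexmarker.primers import design_sex_specific_pair


def synthetic_template(n: int, seed: int = 0) -> str:
    import numpy as np

    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


class TestDivergentSites:
    def test_identical_sequences(self):
        s = synthetic_template(100)
        assert call_divergent_sites(s, s) == []

    def test_planted_differences(self):
        z = synthetic_template(60)
        w = list(z)
        w[6] = "A" if z[6] != "A" else "C"
        w[41] = "A" if z[41] != "A" else "C"
        assert call_divergent_sites("".join(w), z) == [7, 42]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            call_divergent_sites("ACGT", "ACG")

    def test_simulated_pair_matches_generator_plan(self):
        pair = simulate_haplotype_pair(length=500, n_divergent=8, region=(50, 450), seed=9)
        assert len(pair.divergent_sites) == 8
        assert all(50 <= p <= 450 for p in pair.divergent_sites)
        assert call_divergent_sites(pair.w_seq, pair.z_seq) == list(pair.divergent_sites)


class TestMeltingTemperature:
    @pytest.mark.parametrize(
        "seq, tm",
        [("ACGT", 12.0), ("AAAA", 8.0), ("GGCC", 16.0)],
    )
    def test_wallace_rule_short(self, seq, tm):
        assert melting_temperature(seq) == tm

    def test_gc_formula_long(self):
        # 29-mer with 10 G+C: 64.9 + 41*(10 - 16.4)/29
        assert melting_temperature(SPFS_FORWARD) == pytest.approx(
            64.9 + 41 * (10 - 16.4) / 29
        )

    def test_agrees_with_biopython_wallace(self):
        from Bio.SeqUtils import MeltingTemp

        for seq in ("ACGTACGTAC", "AATTGGCC", "GATTACA"):
            assert melting_temperature(seq) == pytest.approx(
                MeltingTemp.Tm_Wallace(seq)
            )

    def test_invariant_under_reversal_and_revcomp(self):
        for seq in ("ACGTACGTACGTACGTACG", "AATTGGCCAATTGG"):
            assert melting_temperature(seq) == melting_temperature(seq[::-1])
            assert melting_temperature(seq) == melting_temperature(
                reverse_complement(seq)
            )

    def test_non_acgt_rejected(self):
        with pytest.raises(ValidationError):
            melting_temperature("ACGN")


class TestAlleleSpecificDesign:
    def _pair_with_sites(
        self, sites: dict[int, str], length: int = 400, seed: int = 1
    ) -> HaplotypePair:
        z = synthetic_template(length, seed=seed)
        w = list(z)
        for pos, base in sites.items():
            assert z[pos - 1] != base
            w[pos - 1] = base
        return HaplotypePair("".join(w), z)

    def _mutated(self, z: str, pos: int) -> str:
        return "A" if z[pos - 1] != "A" else "C"

    def test_single_divergent_site(self):
        z = synthetic_template(400, seed=2)
        w_base = self._mutated(z, 200)
        pair = self._pair_with_sites({200: w_base}, 400, seed=2)
        primer = design_allele_specific_primer(pair, 200)
        assert primer.sequence[-1] == w_base
        assert primer.bind_start + len(primer) - 1 == 200
        # matches Z everywhere except the 3' terminus
        site = pair.z_seq[primer.bind_start - 1 : 200]
        mismatches = [i for i, (p, t) in enumerate(zip(primer.sequence, site)) if p != t]
        assert mismatches == [len(primer) - 1]

    def test_extra_mismatches_pick_sites_nearest_three_prime(self):
        z = synthetic_template(400, seed=3)
        sites = {p: self._mutated(z, p) for p in (180, 192, 197, 200)}
        pair = self._pair_with_sites(sites, 400, seed=3)
        primer = design_allele_specific_primer(
            pair, 200, length_range=(18, 30), n_extra_snp_mismatches=2
        )
        start = primer.bind_start
        # carries W alleles at 197 and 192 (nearest the 3' end), not at 180
        for pos in (192, 197, 200):
            assert primer.sequence[pos - start] == sites[pos]
        if start <= 180:
            assert primer.sequence[180 - start] == pair.z_seq[179]
        offsets = set(primer.designed_mismatch_offsets)
        assert offsets == {192 - start + 1, 197 - start + 1, len(primer)}

    def test_five_prime_artificial_mismatch(self):
        z = synthetic_template(400, seed=4)
        pair = self._pair_with_sites({200: self._mutated(z, 200)}, 400, seed=4)
        primer = design_allele_specific_primer(
            pair, 200, add_five_prime_mismatch=True
        )
        start = primer.bind_start
        assert 1 in primer.designed_mismatch_offsets
        assert primer.sequence[0] != pair.w_seq[start - 1]
        assert primer.sequence[0] != pair.z_seq[start - 1]

    def test_anchor_must_be_divergent(self):
        pair = simulate_haplotype_pair(length=300, n_divergent=5, region=(50, 250), seed=5)
        bad = next(p for p in range(60, 240) if p not in pair.divergent_sites)
        with pytest.raises(PrimerDesignError, match="not a divergent site"):
            design_allele_specific_primer(pair, bad)

    def test_unsatisfiable_extra_mismatches(self):
        z = synthetic_template(400, seed=6)
        pair = self._pair_with_sites({200: self._mutated(z, 200)}, 400, seed=6)
        with pytest.raises(PrimerDesignError, match="cannot satisfy mismatch design"):
            design_allele_specific_primer(pair, 200, n_extra_snp_mismatches=2)

    def test_spfs_fixture_geometry(self):
        primers = load_fixture_primers()
        spfs = primers["SPFS"]
        assert spfs.role is PrimerRole.SEX_SPECIFIC
        assert len(spfs.forward) == 29
        assert spfs.forward.designed_mismatch_offsets == SPFS_MISMATCH_OFFSETS
        assert spfs.expected_product_bp == 320
        assert primers["SPC"].expected_product_bp == 282
        validation = [p for p in primers.values() if p.role is PrimerRole.VALIDATION]
        assert len(validation) == 10


class TestControlPair:
    def test_unconstrained_template(self):
        template = synthetic_template(600, seed=7)
        pair = design_control_pair(template, target_product_range=(250, 300))
        assert 250 <= pair.expected_product_bp <= 300
        res = in_silico_pcr(pair, template)
        assert res.amplifies and res.product_bp == pair.expected_product_bp

    def test_saturated_divergence_is_infeasible(self):
        z = synthetic_template(300, seed=8)
        w = "".join("A" if b != "A" else "C" for b in z)  # diverges everywhere
        pair = HaplotypePair(w, z)
        with pytest.raises(PrimerDesignError):
            design_control_pair(pair, target_product_range=(100, 150))

    def test_avoids_clustered_divergent_sites_and_amplifies_both(self):
        pair = simulate_haplotype_pair(length=2000, n_divergent=10,
                                       region=(900, 1100), seed=9)
        control = design_control_pair(pair, target_product_range=(250, 300))
        for template in (pair.w_seq, pair.z_seq):
            res = in_silico_pcr(control, template)
            assert res.amplifies
            assert res.product_bp == control.expected_product_bp
            assert res.n_mismatches_forward == res.n_mismatches_reverse == 0


class TestInSilicoPcr:
    def _perfect_pair(self, template: str, start: int, product: int) -> PrimerPairSpec:
        fwd = PrimerSpec(template[start - 1 : start + 19], Strand.PLUS, bind_start=start)
        end = start + product - 1
        rev = PrimerSpec(
            reverse_complement(template[end - 20 : end]), Strand.MINUS, bind_start=end
        )
        return PrimerPairSpec(fwd, rev, PrimerRole.CONTROL)

    def test_perfect_match_product_282(self):
        template = synthetic_template(500, seed=10)
        pair = self._perfect_pair(template, 100, 282)
        res = in_silico_pcr(pair, template)
        assert res.amplifies and res.product_bp == 282

    def test_three_prime_terminal_mismatch_vetoes(self):
        template = synthetic_template(500, seed=11)
        pair = self._perfect_pair(template, 100, 282)
        seq = pair.forward.sequence
        bad = seq[:-1] + ("A" if seq[-1] != "A" else "C")
        vetoed = PrimerPairSpec(
            PrimerSpec(bad, Strand.PLUS, bind_start=100),
            pair.reverse,
            PrimerRole.CONTROL,
        )
        res = in_silico_pcr(vetoed, template)
        assert not res.amplifies
        assert res.three_prime_mismatch

    def test_unmapped_primer_is_diagnostic_not_error(self):
        template = synthetic_template(300, seed=12)
        pair = PrimerPairSpec(
            PrimerSpec("A" * 25, Strand.PLUS),
            PrimerSpec("C" * 25, Strand.MINUS),
            PrimerRole.CONTROL,
        )
        res = in_silico_pcr(pair, template, use_bind_positions=False)
        assert not res.amplifies
        assert "does not map" in res.note or res.note == ""

    def test_free_search_recovers_design_positions(self):
        template = synthetic_template(800, seed=13)
        pair = self._perfect_pair(template, 151, 282)
        unplaced = PrimerPairSpec(
            PrimerSpec(pair.forward.sequence, Strand.PLUS),
            PrimerSpec(pair.reverse.sequence, Strand.MINUS),
            PrimerRole.CONTROL,
        )
        res = in_silico_pcr(unplaced, template, use_bind_positions=False)
        assert res.amplifies and res.product_bp == 282
        loc = locate_primer(pair.forward, template)
        assert loc == (151, 0)

    def test_reverse_complement_consistency(self):
        """Amplification is strand-symmetric: flipping the template and
        swapping primer roles preserves the product length."""
        template = synthetic_template(600, seed=14)
        pair = self._perfect_pair(template, 120, 250)
        flipped_template = reverse_complement(template)
        swapped = PrimerPairSpec(
            PrimerSpec(pair.reverse.sequence, Strand.PLUS),
            PrimerSpec(pair.forward.sequence, Strand.MINUS),
            PrimerRole.CONTROL,
        )
        res = in_silico_pcr(swapped, flipped_template, use_bind_positions=False)
        assert res.amplifies and res.product_bp == 250


class TestSexingAssay:
    @pytest.fixture()
    def assay(self):
        pair = simulate_haplotype_pair(seed=42)
        sex_pair = design_sex_specific_pair(pair, add_five_prime_mismatch=True)
        control = design_control_pair(pair)
        return pair, sex_pair, control

    def test_heterogametic_female_shows_both_bands(self, assay):
        pair, sex_pair, control = assay
        call = predict_band_pattern(sex_pair, control, [pair.w_seq, pair.z_seq])
        assert call is BandSexCall.FEMALE

    def test_homogametic_male_shows_control_only(self, assay):
        pair, sex_pair, control = assay
        assert predict_band_pattern(sex_pair, control, [pair.z_seq]) is BandSexCall.MALE

    def test_unrelated_template_is_invalid(self, assay):
        _, sex_pair, control = assay
        foreign = synthetic_template(2400, seed=99)
        assert predict_band_pattern(sex_pair, control, foreign) is BandSexCall.INVALID

    def test_expected_product_matches_insilico_product(self, assay):
        pair, sex_pair, control = assay
        res = in_silico_pcr(sex_pair, pair.w_seq)
        assert res.product_bp == sex_pair.expected_product_bp

    @pytest.mark.parametrize("seed", range(1, 21))
    def test_designed_primer_discriminates_haplotypes(self, seed):
        pair = simulate_haplotype_pair(seed=seed)
        sex_pair = design_sex_specific_pair(pair, add_five_prime_mismatch=True)
        assert in_silico_pcr(sex_pair, pair.w_seq).amplifies
        z_res = in_silico_pcr(sex_pair, pair.z_seq)
        assert not z_res.amplifies
        assert z_res.three_prime_mismatch
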