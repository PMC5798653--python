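"""Allele alignment, orientation to raising alleles, and molar-ratio coding."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from igfmr.harmonize import (
    HarmonizationError,
    HarmonizedPair,
    PalindromeDropped,
    PalindromePolicy,
    align_alleles,
    code_molar_ratio,
    orient_to_raising_allele,
)
from igfmr.mr import select_subset
from igfmr.sumstats_io import Affects, AssociationRecord, InstrumentSpec, Scale


def rec(rsid="rs1", ea="A", oa="G", beta=0.03, se=0.01, trait="AD", eaf=0.3,
        scale=Scale.LOG_ODDS):
    return AssociationRecord(
        rsid=rsid, effect_allele=ea, other_allele=oa, beta=beta, se=se,
        pvalue=0.5, trait=trait, scale=scale, eaf=eaf,
    )


def exposure(ea="A", oa="G", beta=0.12, se=0.008, eaf=0.3):
    return rec(ea=ea, oa=oa, beta=beta, se=se, trait="IGF1", eaf=eaf, scale=Scale.SD_UNITS)


class TestAlignAlleles:
    def test_matching_alleles_identity(self):
        pair = align_alleles(exposure(), rec(beta=0.03))
        assert pair.beta_gy == 0.03
        assert pair.flips_applied == ()
        assert pair.coded_allele == "A"

    def test_swapped_alleles_negate_outcome(self):
        pair = align_alleles(exposure(), rec(ea="G", oa="A", beta=0.03, eaf=0.7))
        assert pair.beta_gy == -0.03
        assert "allele_swap" in pair.flips_applied

    def test_strand_complement_then_align(self):
        # exposure A/G; outcome reported as T/C on the other strand
        pair = align_alleles(exposure(), rec(ea="T", oa="C", beta=0.03))
        assert pair.beta_gy == 0.03
        assert "strand_complement" in pair.flips_applied

    def test_complement_plus_swap(self):
        pair = align_alleles(exposure(), rec(ea="C", oa="T", beta=0.03, eaf=0.7))
        assert pair.beta_gy == -0.03
        assert set(pair.flips_applied) == {"strand_complement", "allele_swap"}

    def test_irreconcilable_alleles_hard_error(self):
        with pytest.raises(HarmonizationError, match="irreconcilable"):
            align_alleles(exposure(), rec(ea="A", oa="C"))

    def test_ses_unchanged_by_flips(self):
        pair = align_alleles(exposure(se=0.008), rec(ea="G", oa="A", se=0.02, eaf=0.7))
        assert pair.se_gx == 0.008
        assert pair.se_gy == 0.02

    def test_rsid_mismatch_rejected(self):
        with pytest.raises(HarmonizationError, match="rsid"):
            align_alleles(exposure(), rec(rsid="rs2"))


class TestPalindromes:
    def test_drop_ambiguous_policy_excludes(self):
        with pytest.raises(PalindromeDropped):
            align_alleles(
                exposure(ea="A", oa="T", eaf=0.3),
                rec(ea="A", oa="T", eaf=0.5),
                PalindromePolicy(mode="drop_ambiguous"),
            )

    def test_eaf_in_ambiguous_band_dropped(self):
        with pytest.raises(PalindromeDropped, match="ambiguous"):
            align_alleles(exposure(ea="C", oa="G", eaf=0.3), rec(ea="C", oa="G", eaf=0.50))

    def test_missing_eaf_dropped(self):
        with pytest.raises(PalindromeDropped, match="EAF missing"):
            align_alleles(exposure(ea="A", oa="T", eaf=0.2), rec(ea="A", oa="T", eaf=None))

    def test_eaf_matching_keeps_concordant_orientation(self):
        pair = align_alleles(exposure(ea="A", oa="T", eaf=0.2), rec(ea="A", oa="T", beta=0.03, eaf=0.22))
        assert pair.beta_gy == 0.03
        assert pair.flips_applied == ()

    def test_eaf_matching_flips_discordant_orientation(self):
        # outcome's coded-allele frequency matches the exposure's OTHER allele
        pair = align_alleles(exposure(ea="A", oa="T", eaf=0.2), rec(ea="A", oa="T", beta=0.03, eaf=0.78))
        assert pair.beta_gy == -0.03
        assert "palindrome_eaf_flip" in pair.flips_applied


def spec_for(pair, raising, affects=Affects.IGF1_ONLY, trait="IGF1"):
    return InstrumentSpec(rsid=pair.rsid, exposure_trait=trait, raising_allele=raising, affects=affects)


class TestOrientation:
    def pair(self, beta_gx=0.12, beta_gy=0.02):
        return HarmonizedPair(
            rsid="rs1", coded_allele="A", other_allele="G",
            beta_gx=beta_gx, se_gx=0.008, beta_gy=beta_gy, se_gy=0.01, eaf=0.3,
        )

    def test_already_raising_unchanged(self):
        p = self.pair(beta_gy=0.02)
        out = orient_to_raising_allele(p, spec_for(p, "A"))
        assert (out.beta_gx, out.beta_gy) == (p.beta_gx, p.beta_gy)
        assert out.orientation == "exposure_raising"

    def test_lowering_allele_subtracts_log_odds_from_zero(self):
        p = self.pair(beta_gx=-0.12, beta_gy=0.05)
        out = orient_to_raising_allele(p, spec_for(p, "G"))
        assert out.beta_gy == -0.05
        assert out.beta_gx == 0.12
        assert out.coded_allele == "G"
        assert "orient_flip" in out.flips_applied
        assert (out.se_gx, out.se_gy) == (p.se_gx, p.se_gy)

    def test_zero_beta_survives_flip(self):
        p = self.pair(beta_gx=-0.12, beta_gy=0.0)
        out = orient_to_raising_allele(p, spec_for(p, "G"))
        assert out.beta_gy == 0.0

    def test_double_orientation_is_identity(self):
        p = self.pair()
        spec = spec_for(p, "A")
        once = orient_to_raising_allele(p, spec)
        twice = orient_to_raising_allele(once, spec)
        assert twice == once

    def test_unknown_raising_allele_hard_error(self):
        p = self.pair()
        with pytest.raises(HarmonizationError, match="raising allele"):
            orient_to_raising_allele(p, spec_for(p, "C"))

    @given(
        beta_gx=st.floats(-1, 1, allow_nan=False).filter(lambda x: abs(x) > 1e-6),
        beta_gy=st.floats(-1, 1, allow_nan=False),
    )
    def test_sign_flip_involution(self, beta_gx, beta_gy):
        """Orienting to one allele then the other restores the original betas."""
        p = self.pair(beta_gx=beta_gx, beta_gy=beta_gy)
        flipped = orient_to_raising_allele(p, spec_for(p, "G"))
        back = orient_to_raising_allele(flipped, spec_for(p, "A"))
        assert back.beta_gx == p.beta_gx
        assert back.beta_gy == p.beta_gy


class TestMolarRatio:
    def pairs_and_specs(self):
        pairs, specs = [], []
        layout = (
            [(f"rsI{i}", Affects.IGF1_ONLY) for i in range(5)]
            + [(f"rsB{i}", Affects.IGFBP3_ONLY) for i in range(2)]
            + [("rs646776", Affects.BIVARIATE_OPPOSITE)]
        )
        for i, (rsid, affects) in enumerate(layout):
            pairs.append(
                HarmonizedPair(
                    rsid=rsid, coded_allele="A", other_allele="G",
                    beta_gx=0.1, se_gx=0.01, beta_gy=0.04, se_gy=0.02,
                    orientation="exposure_raising",
                )
            )
            specs.append(InstrumentSpec(rsid, "IGF1", "A", affects))
        return pairs, specs

    def test_eight_snp_ratio_set(self):
        pairs, specs = self.pairs_and_specs()
        iset = code_molar_ratio(pairs, specs)
        assert len(iset) == 8
        assert all(p.orientation == "ratio_raising" for p in iset.pairs)

    def test_igfbp3_pairs_coded_on_lowering_allele(self):
        pairs, specs = self.pairs_and_specs()
        iset = code_molar_ratio(pairs, specs)
        bp3 = [p for p in iset.pairs if p.rsid.startswith("rsB")]
        assert all(p.beta_gy == -0.04 for p in bp3)
        assert all("ratio_flip" in p.flips_applied for p in bp3)

    def test_bivariate_snp_keeps_orientation(self):
        pairs, specs = self.pairs_and_specs()
        iset = code_molar_ratio(pairs, specs)
        biv = next(p for p in iset.pairs if p.rsid == "rs646776")
        assert biv.beta_gy == 0.04
        assert "ratio_flip" not in biv.flips_applied

    def test_both_class_snp_rejected(self):
        pairs, specs = self.pairs_and_specs()
        specs[0] = InstrumentSpec(pairs[0].rsid, "IGF1", "A", Affects.BOTH)
        with pytest.raises(HarmonizationError, match="molar-ratio"):
            code_molar_ratio(pairs, specs)


class TestFixtureCardinalities:
    """The packaged panel reproduces the study's subset arithmetic."""

    def test_main_and_subset_sizes(self, harmonized):
        iset, _ = harmonized
        assert len(select_subset(iset, "main9")) == 9
        assert len(select_subset(iset, "igf1_only5")) == 5
        assert len(select_subset(iset, "igfbp3_only2")) == 2

    def test_molar_ratio_set_is_eight(self, harmonized):
        iset, _ = harmonized
        eligible = [
            p
            for p in iset.pairs
            if iset.spec_for(p.rsid).affects
            in (Affects.IGF1_ONLY, Affects.IGFBP3_ONLY, Affects.BIVARIATE_OPPOSITE)
        ]
        assert len(code_molar_ratio(eligible, iset.specs)) == 8

    def test_exactly_five_betas_recoded(self, harmonized):
        iset, _ = harmonized
        n_recoded = sum("orient_flip" in p.flips_applied for p in iset.pairs)
        assert n_recoded == 5
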