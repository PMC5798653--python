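"""Allele harmonization and effect-orientation for two-sample MR.

The exposure and outcome associations for one SNP come from different GWAS
and may be coded on different alleles or reported on opposite strands. This
module aligns each outcome record to the exposure's coded allele, then
orients the pair so the coded allele is the exposure-raising one (the
convention under which all SNP-outcome log-odds are expressed per copy of
the IGF-raising allele; orienting flips "subtract the log-odds from zero").

Every sign flip is recorded in ``flips_applied`` so the mapping from input
records to stored betas is fully auditable — the analysis recodes a specific
subset of betas and that recoding must be reproducible and reviewable.

Palindromic SNPs (A/T or C/G) cannot be strand-resolved from alleles alone;
the default policy drops them when the effect-allele frequency is ambiguous
(within [0.42, 0.58]) and otherwise resolves orientation by frequency
matching. Additive allele effects are assumed throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from igfmr.sumstats_io import (
    Affects,
    AssociationRecord,
    InstrumentSpec,
    VALID_ALLELES,
)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

EXPOSURE_RAISING = "exposure_raising"
RATIO_RAISING = "ratio_raising"


class HarmonizationError(Exception):
    """Hard harmonization failure (irreconcilable alleles, bad orientation)."""


class PalindromeDropped(Exception):
    """A palindromic SNP was excluded under the active policy (soft exclusion)."""


@dataclass(frozen=True)
class PalindromePolicy:
    """How to treat A/T and C/G SNPs.

    mode:
      ``drop_if_eaf_ambiguous`` — resolve by EAF matching unless either EAF
        is missing or the outcome EAF falls inside ``ambiguous_band``;
      ``drop_ambiguous`` — always exclude palindromic SNPs;
      ``keep`` — assume both sources report the same strand.
    """

    mode: str = "drop_if_eaf_ambiguous"
    ambiguous_band: tuple[float, float] = (0.42, 0.58)


DEFAULT_POLICY = PalindromePolicy()


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure/outcome effects for one SNP on a common coded allele."""

    rsid: str
    coded_allele: str
    other_allele: str
    beta_gx: float
    se_gx: float
    beta_gy: float
    se_gy: float
    orientation: str | None = None
    flips_applied: tuple[str, ...] = ()
    eaf: float | None = None
    exposure_trait: str = ""

    @property
    def alleles(self) -> frozenset[str]:
        return frozenset((self.coded_allele, self.other_allele))


@dataclass
class InstrumentSet:
    """A named set of harmonized pairs with their instrument specs."""

    name: str
    exposure: str
    pairs: list[HarmonizedPair]
    specs: list[InstrumentSpec] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    def spec_for(self, rsid: str) -> InstrumentSpec | None:
        for s in self.specs:
            if s.rsid == rsid:
                return s
        return None


def _is_palindromic(a1: str, a2: str) -> bool:
    return COMPLEMENT[a1] == a2


def align_alleles(
    exposure: AssociationRecord,
    outcome: AssociationRecord,
    policy: PalindromePolicy = DEFAULT_POLICY,
) -> HarmonizedPair:
    """Align an outcome record to the exposure's coded allele.

    Returns an unoriented pair coded on the exposure's effect allele. If the
    outcome's alleles are swapped relative to the exposure, the outcome beta
    is negated (and EAF complemented); if they match only after strand
    complement, the outcome is complemented first. Raises
    :class:`HarmonizationError` when the allele sets are irreconcilable and
    :class:`PalindromeDropped` when the palindrome policy excludes the SNP.
    """
    if exposure.rsid != outcome.rsid:
        raise HarmonizationError(
            f"rsid mismatch: exposure {exposure.rsid} vs outcome {outcome.rsid}"
        )
    for rec in (exposure, outcome):
        if not rec.alleles <= VALID_ALLELES or len(rec.alleles) != 2:
            raise HarmonizationError(f"{rec.rsid}: invalid alleles {sorted(rec.alleles)}")

    flips: list[str] = []
    exp_a, exp_o = exposure.effect_allele, exposure.other_allele
    out_ea, out_oa = outcome.effect_allele, outcome.other_allele
    beta_gy = outcome.beta
    out_eaf = outcome.eaf

    palindromic = _is_palindromic(exp_a, exp_o)
    if palindromic:
        if {out_ea, out_oa} != {exp_a, exp_o}:
            raise HarmonizationError(
                f"{exposure.rsid}: allele sets irreconcilable: exposure "
                f"{exp_a}/{exp_o} vs outcome {out_ea}/{out_oa}"
            )
        if policy.mode == "drop_ambiguous":
            raise PalindromeDropped(
                f"{exposure.rsid}: palindromic {exp_a}/{exp_o} SNP excluded (drop_ambiguous)"
            )
        if policy.mode == "drop_if_eaf_ambiguous":
            lo, hi = policy.ambiguous_band
            if exposure.eaf is None or out_eaf is None:
                raise PalindromeDropped(
                    f"{exposure.rsid}: palindromic SNP excluded (EAF missing)"
                )
            if lo <= out_eaf <= hi or lo <= exposure.eaf <= hi:
                raise PalindromeDropped(
                    f"{exposure.rsid}: palindromic SNP excluded "
                    f"(EAF {out_eaf:.3f} ambiguous in [{lo}, {hi}])"
                )
            # Resolve orientation by frequency matching: the outcome's coded
            # allele is whichever exposure allele has the nearer frequency.
            if abs(out_eaf - exposure.eaf) > abs((1 - out_eaf) - exposure.eaf):
                beta_gy = -beta_gy
                out_eaf = 1 - out_eaf
                flips.append("palindrome_eaf_flip")
        elif policy.mode == "keep":
            if out_ea != exp_a:
                beta_gy = -beta_gy
                out_eaf = 1 - out_eaf if out_eaf is not None else None
                flips.append("allele_swap")
        elif policy.mode != "drop_if_eaf_ambiguous":
            raise ValueError(f"unknown palindrome policy mode {policy.mode!r}")
    else:
        if {out_ea, out_oa} == {exp_a, exp_o}:
            pass
        elif {COMPLEMENT[out_ea], COMPLEMENT[out_oa]} == {exp_a, exp_o}:
            out_ea, out_oa = COMPLEMENT[out_ea], COMPLEMENT[out_oa]
            flips.append("strand_complement")
        else:
            raise HarmonizationError(
                f"{exposure.rsid}: allele sets irreconcilable: exposure "
                f"{exp_a}/{exp_o} vs outcome {outcome.effect_allele}/{outcome.other_allele}"
            )
        if out_ea != exp_a:
            beta_gy = -beta_gy
            out_eaf = 1 - out_eaf if out_eaf is not None else None
            flips.append("allele_swap")

    return HarmonizedPair(
        rsid=exposure.rsid,
        coded_allele=exp_a,
        other_allele=exp_o,
        beta_gx=exposure.beta,
        se_gx=exposure.se,
        beta_gy=beta_gy,
        se_gy=outcome.se,
        orientation=None,
        flips_applied=tuple(flips),
        eaf=exposure.eaf,
        exposure_trait=exposure.trait,
    )


def orient_to_raising_allele(pair: HarmonizedPair, spec: InstrumentSpec) -> HarmonizedPair:
    """Orient a pair so its coded allele is the exposure-raising allele.

    When the coded allele is the lowering allele, both betas are negated
    (log-odds subtracted from zero) and the coded/other alleles switch;
    standard errors are untouched. Orienting an already-oriented pair is the
    identity.
    """
    raising = spec.raising_allele
    if raising == pair.coded_allele:
        if pair.orientation == EXPOSURE_RAISING:
            return pair
        return replace(pair, orientation=EXPOSURE_RAISING)
    if raising == pair.other_allele:
        return replace(
            pair,
            coded_allele=pair.other_allele,
            other_allele=pair.coded_allele,
            beta_gx=-pair.beta_gx,
            beta_gy=-pair.beta_gy,
            eaf=(1.0 - pair.eaf) if pair.eaf is not None else None,
            orientation=EXPOSURE_RAISING,
            flips_applied=pair.flips_applied + ("orient_flip",),
        )
    raise HarmonizationError(
        f"{pair.rsid}: raising allele {raising!r} not in pair alleles "
        f"{pair.coded_allele}/{pair.other_allele}"
    )


def code_molar_ratio(
    pairs: Sequence[HarmonizedPair],
    specs: Sequence[InstrumentSpec],
) -> InstrumentSet:
    """Code instruments on alleles expected to raise the IGF1:IGFBP3 molar ratio.

    Inputs are pairs already oriented to their own exposure-raising alleles.
    IGF1-only SNPs keep that orientation (more IGF1 → higher ratio);
    IGFBP3-only SNPs are sign-flipped to their IGFBP3-*lowering* alleles
    (less binding protein → higher free-IGF1 ratio); a bivariate-opposite
    SNP (rs646776-like, higher IGF1 / lower IGFBP3 per allele) keeps its
    orientation. SNPs affecting both traits concordantly are rejected — the
    ratio analysis has no coherent coding for them.
    """
    spec_by_rsid = {s.rsid: s for s in specs}
    out_pairs: list[HarmonizedPair] = []
    out_specs: list[InstrumentSpec] = []
    for pair in pairs:
        spec = spec_by_rsid.get(pair.rsid)
        if spec is None:
            raise HarmonizationError(f"{pair.rsid}: no instrument spec supplied")
        if spec.affects is Affects.BOTH:
            raise HarmonizationError(
                f"{pair.rsid}: affects both IGF1 and IGFBP3 concordantly; "
                "not part of the molar-ratio analysis"
            )
        if spec.affects in (Affects.IGF1_ONLY, Affects.BIVARIATE_OPPOSITE):
            coded = replace(pair, orientation=RATIO_RAISING)
        elif spec.affects is Affects.IGFBP3_ONLY:
            coded = replace(
                pair,
                coded_allele=pair.other_allele,
                other_allele=pair.coded_allele,
                beta_gx=-pair.beta_gx,
                beta_gy=-pair.beta_gy,
                eaf=(1.0 - pair.eaf) if pair.eaf is not None else None,
                orientation=RATIO_RAISING,
                flips_applied=pair.flips_applied + ("ratio_flip",),
            )
        else:  # pragma: no cover - Affects enum is closed
            raise HarmonizationError(f"{pair.rsid}: unknown affects class {spec.affects}")
        out_pairs.append(coded)
        out_specs.append(spec)
    return InstrumentSet(
        name="molar_ratio",
        exposure="IGF1:IGFBP3 molar ratio",
        pairs=out_pairs,
        specs=out_specs,
    )


@dataclass
class HarmonizationReport:
    """Per-SNP audit of flips applied and exclusions with reasons."""

    pairs: list[HarmonizedPair] = field(default_factory=list)
    exclusions: list[tuple[str, str]] = field(default_factory=list)

    def to_rows(self) -> list[dict]:
        rows = [
            {
                "rsid": p.rsid,
                "status": "harmonized",
                "coded_allele": p.coded_allele,
                "flips": ",".join(p.flips_applied) or "none",
            }
            for p in self.pairs
        ]
        rows += [
            {"rsid": rsid, "status": "excluded", "coded_allele": "", "flips": reason}
            for rsid, reason in self.exclusions
        ]
        return rows


def harmonize_tables(
    exposure: Iterable[AssociationRecord],
    outcome: Iterable[AssociationRecord],
    specs: Sequence[InstrumentSpec],
    policy: PalindromePolicy = DEFAULT_POLICY,
) -> tuple[InstrumentSet, HarmonizationReport]:
    """Align and orient all instrument SNPs present in both tables.

    Returns the oriented instrument set (coded on exposure-raising alleles)
    and the audit report. SNPs missing from either table, or dropped by the
    palindrome policy, land in the report's exclusion list; irreconcilable
    alleles raise.
    """
    exp_by_rsid = {r.rsid: r for r in exposure}
    out_by_rsid = {r.rsid: r for r in outcome}
    report = HarmonizationReport()
    pairs: list[HarmonizedPair] = []
    kept_specs: list[InstrumentSpec] = []
    for spec in specs:
        exp = exp_by_rsid.get(spec.rsid)
        out = out_by_rsid.get(spec.rsid)
        if exp is None or out is None:
            which = "exposure" if exp is None else "outcome"
            report.exclusions.append((spec.rsid, f"missing from {which} table"))
            continue
        try:
            pair = align_alleles(exp, out, policy)
        except PalindromeDropped as exc:
            report.exclusions.append((spec.rsid, str(exc)))
            continue
        pair = orient_to_raising_allele(pair, spec)
        pairs.append(pair)
        kept_specs.append(spec)
        report.pairs.append(pair)
    exposure_label = "+".join(sorted({s.exposure_trait for s in kept_specs})) or "exposure"
    return (
        InstrumentSet(name="main", exposure=exposure_label, pairs=pairs, specs=kept_specs),
        report,
    )
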