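"""Genotype calling and maternal-plasma interpretation.

Parental genomic samples are genotyped from locus read profiles with a
sequential rule table keyed on how many haplotypes exceed 10% relative
frequency; plasma (a maternal/foetal cfDNA mixture) is screened instead:
the maternal haplotypes must dominate, any other haplotype above the
maternal cut-off voids the locus, and haplotypes in the foetal detection
window (1-12% relative frequency) are candidate paternally inherited
foetal haplotypes. The paternally inherited haplotype carries half of the
total foetal fraction, so the total is estimated as twice the per-locus
paternal-only relative frequency, summarised by the median across
informative loci.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

from .read_processing import LocusReadProfile

__all__ = [
    "GenotypeThresholds",
    "PlasmaThresholds",
    "GenotypeCall",
    "PlasmaLocusProfile",
    "FoetalFractionEstimate",
    "call_genotype",
    "analyze_plasma_locus",
    "estimate_foetal_fraction",
]


@dataclass(frozen=True)
class GenotypeThresholds:
    """Rule-table thresholds for parental genotype calling.

    ``min_coverage`` is the locus-level accepted-observation count a sample
    must exceed (strictly) to be callable; the frequency bounds mirror the
    sequential criteria: haplotypes above ``noise`` (10%) are considered,
    one above ``homozygous`` (80%) is called homozygous, two inside
    [``het_low``, ``het_high``] = [20%, 80%] heterozygous, and with three
    above noise, exactly two above ``three_way`` (35%) heterozygous.
    """

    min_coverage: int = 20
    noise: float = 0.10
    homozygous: float = 0.80
    het_low: float = 0.20
    het_high: float = 0.80
    three_way: float = 0.35


@dataclass(frozen=True)
class PlasmaThresholds:
    """Plasma screening thresholds.

    Plasma needs deeper sequencing than genomic DNA (>= 1000x per locus)
    because the foetal signal sits at a few percent. ``maternal_cutoff`` is
    the minimum relative frequency for each confirmed maternal haplotype and
    simultaneously the ceiling for any non-maternal haplotype; the foetal
    window [``ff_low``, ``ff_high``] = [1%, 12%] bounds the relative
    frequency a paternally inherited foetal haplotype may show.
    """

    min_coverage: int = 1000
    maternal_cutoff: float = 0.12
    ff_low: float = 0.01
    ff_high: float = 0.12


@dataclass
class GenotypeCall:
    """Called zygosity and haplotypes for a genomic (non-plasma) sample."""

    locus_id: str
    status: str  # called | no_call | low_coverage
    haplotypes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.status == "called" and len(self.haplotypes) not in (1, 2):
            raise ValueError("called genotype must carry 1 or 2 haplotypes")

    @property
    def zygosity(self) -> str | None:
        if self.status != "called":
            return None
        return "homozygous" if len(self.haplotypes) == 1 else "heterozygous"

    @property
    def haplotype_multiset(self) -> tuple[str, str]:
        """The two chromosomal haplotypes (duplicated when homozygous)."""
        if self.status != "called":
            raise ValueError(f"{self.locus_id}: genotype not called")
        if len(self.haplotypes) == 1:
            return (self.haplotypes[0], self.haplotypes[0])
        return (self.haplotypes[0], self.haplotypes[1])


@dataclass
class PlasmaLocusProfile:
    """Screened plasma profile at one locus.

    ``candidate_paternal`` maps non-maternal haplotypes inside the foetal
    window to their relative frequencies; dismissed loci carry a reason and
    no candidates.
    """

    locus_id: str
    usable: bool
    dismiss_reason: str | None  # low_coverage | maternal_below_cutoff | foreign_above_cutoff
    maternal_haplotypes: dict[str, float] = field(default_factory=dict)
    candidate_paternal: dict[str, float] = field(default_factory=dict)


@dataclass
class FoetalFractionEstimate:
    """Foetal fraction from paternal-only plasma haplotypes.

    The paternal-only haplotype carries half the foetal DNA, hence
    ``total_ff = 2 * paternal_fraction`` with the paternal fraction taken as
    the median over informative loci.
    """

    per_locus: dict[str, float]

    @property
    def available(self) -> bool:
        return bool(self.per_locus)

    @property
    def paternal_fraction(self) -> float:
        if not self.per_locus:
            raise ValueError("no informative locus for foetal fraction")
        return statistics.median(self.per_locus.values())

    @property
    def total_ff(self) -> float:
        return 2.0 * self.paternal_fraction


# ---------------------------------------------------------------------------

def call_genotype(
    profile: LocusReadProfile,
    thresholds: GenotypeThresholds = GenotypeThresholds(),
) -> GenotypeCall:
    """Call a parental genotype from a locus read profile.

    The rule table, applied to the relative frequencies of accepted
    haplotypes with k = number of haplotypes strictly above the 10% noise
    floor:

    * coverage <= 20          -> low_coverage
    * k = 1, that one > 80%   -> homozygous
    * k = 2, one > 80%        -> homozygous for it
    * k = 2, both in [20,80]% -> heterozygous
    * k = 3, exactly 2 > 35%  -> heterozygous for those two
    * anything else           -> no_call
    """
    t = thresholds
    if profile.coverage <= t.min_coverage:
        return GenotypeCall(profile.locus_id, "low_coverage")
    freqs = profile.rel_freqs
    above = [(h, f) for h, f in freqs.items() if f > t.noise]
    k = len(above)
    if k == 1:
        h, f = above[0]
        if f > t.homozygous:
            return GenotypeCall(profile.locus_id, "called", (h,))
    elif k == 2:
        top = [h for h, f in above if f > t.homozygous]
        if len(top) == 1:
            return GenotypeCall(profile.locus_id, "called", (top[0],))
        if all(t.het_low <= f <= t.het_high for _, f in above):
            haps = tuple(sorted(h for h, _ in above))
            return GenotypeCall(profile.locus_id, "called", haps)
    elif k == 3:
        strong = [h for h, f in above if f > t.three_way]
        if len(strong) == 2:
            return GenotypeCall(profile.locus_id, "called", tuple(sorted(strong)))
    return GenotypeCall(profile.locus_id, "no_call")


def analyze_plasma_locus(
    profile: LocusReadProfile,
    mother_call: GenotypeCall,
    thresholds: PlasmaThresholds = PlasmaThresholds(),
) -> PlasmaLocusProfile:
    """Screen one plasma locus against the mother's called genotype.

    Dismissal, in order: coverage below the plasma minimum; a maternal
    haplotype below the maternal cut-off; any non-maternal haplotype above
    that cut-off (an apparent foetal fraction too high to be real is treated
    as artefact and the locus dropped). Otherwise usable, with candidates =
    non-maternal haplotypes inside the foetal window.
    """
    if mother_call.status != "called":
        raise ValueError(f"{profile.locus_id}: mother genotype not called")
    t = thresholds
    maternal_set = set(mother_call.haplotypes)
    freqs = profile.rel_freqs
    maternal = {h: freqs.get(h, 0.0) for h in sorted(maternal_set)}
    if profile.coverage < t.min_coverage:
        return PlasmaLocusProfile(profile.locus_id, False, "low_coverage", maternal)
    if any(f < t.maternal_cutoff for f in maternal.values()):
        return PlasmaLocusProfile(profile.locus_id, False, "maternal_below_cutoff", maternal)
    foreign = {h: f for h, f in freqs.items() if h not in maternal_set}
    if any(f > t.maternal_cutoff for f in foreign.values()):
        return PlasmaLocusProfile(profile.locus_id, False, "foreign_above_cutoff", maternal)
    candidates = {h: f for h, f in sorted(foreign.items())
                  if t.ff_low <= f <= t.ff_high}
    return PlasmaLocusProfile(profile.locus_id, True, None, maternal, candidates)


def estimate_foetal_fraction(
    plasma_profiles: dict[str, PlasmaLocusProfile],
    father_calls: dict[str, GenotypeCall],
) -> FoetalFractionEstimate:
    """Estimate the total foetal fraction from plasma candidates matching
    the alleged father.

    Only usable plasma loci whose candidate haplotype is carried by the
    (called) father are informative; when a locus offers several matching
    candidates the most frequent one is taken as the paternal haplotype.
    """
    per_locus: dict[str, float] = {}
    for locus_id, plasma in plasma_profiles.items():
        if not plasma.usable:
            continue
        father = father_calls.get(locus_id)
        if father is None or father.status != "called":
            continue
        matching = {h: f for h, f in plasma.candidate_paternal.items()
                    if h in set(father.haplotypes)}
        if matching:
            per_locus[locus_id] = max(matching.values())
    return FoetalFractionEstimate(per_locus)
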