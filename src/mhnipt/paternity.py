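"""Paternity evidence, per-locus paternity indices, and the probability
of paternity.

At each usable locus the observed haplotypes of mother, alleged father and
plasma are reduced to two numbers: the haplotypes shared between the
parents, and the plasma foetal candidates that match the alleged father.
A locus with neither is discrepant; two or more discrepant loci exclude
paternity, exactly one is inconclusive, and with none the per-locus
paternity indices (likelihood ratios "alleged father" vs "random man")
are multiplied into the combined paternity index CPI, giving the
probability of paternity W = CPI / (1 + CPI) under 1:1 prior odds.

A discrepant locus inside an otherwise consistent case can be explained by
mutation; with a per-locus SNP mutation rate of 1e-8 and a floor haplotype
frequency of 2e-4 the corresponding index is 5e-5 regardless of how many
SNPs differ.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

from scipy.special import expit

from .genotyping import GenotypeCall, PlasmaLocusProfile
from .panel import FrequencyTable, lookup_frequency

__all__ = [
    "PaternityConfig",
    "LocusEvidence",
    "PaternityReport",
    "evaluate_locus",
    "locus_pi",
    "mutation_pi",
    "combine_evidence",
    "tabulated_log10_cpi",
    "w_from_log10_cpi",
]

LOG10 = math.log(10.0)


@dataclass(frozen=True)
class PaternityConfig:
    """Case-level parameters.

    ``mutation_rate`` is the per-locus per-generation SNP mutation rate;
    ``min_haplotype_freq`` the lowest population frequency an observed
    haplotype can take (2e-4 for a 2504-sample reference). Their ratio is
    the mutation paternity index, 5e-5 at the defaults. ``min_loci`` flags
    thin cases; at least 15 markers are recommended for reporting.
    ``mutation_pi_in_w`` controls whether a single discrepant locus
    contributes its mutation index to W in inconclusive cases (off by
    default: audit only).
    """

    mutation_rate: float = 1e-8
    min_haplotype_freq: float = 2e-4
    min_loci: int = 15
    w_report_threshold: float = 0.99
    mutation_pi_in_w: bool = False


@dataclass
class LocusEvidence:
    """Per-locus paternity evidence.

    ``shared_count`` = |SP ∩ M|, haplotypes common to alleged father and
    mother; ``ff_count`` = |FF|, plasma foetal candidates matching the
    father and absent from the mother. ``obligate`` is the inferred
    paternal haplotype, or the ambiguity set (maternal haplotypes the
    father also carries) when no foreign candidate was seen.
    ``consistent_set`` lists every haplotype whose paternal transmission is
    compatible with the plasma observation — the denominator universe for
    the likelihood ratio. Under the default candidate handling a locus is
    discrepant exactly when ``shared_count == ff_count == 0``; the strict
    mode (see ``evaluate_locus``) can also mark a haplotype-sharing locus
    discrepant when plasma carries an unexplained foetal candidate.
    """

    locus_id: str
    shared_count: int
    ff_count: int
    verdict: str  # consistent | discrepant
    obligate: tuple[str, ...] = ()
    consistent_set: tuple[str, ...] = ()
    pi: float | None = None
    ignored_candidates: tuple[str, ...] = ()

    @property
    def discrepant(self) -> bool:
        return self.verdict == "discrepant"


@dataclass
class PaternityReport:
    """Case-level verdict with audit trail."""

    case_id: str
    evidences: list[LocusEvidence]
    n_used: int
    n_discrepant: int
    decision: str  # exclusion | inconclusive | inclusion
    log10_cpi: float | None
    cpi: float | None
    w: float | None
    low_marker_flag: bool
    inconclusive_w_flag: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------

def evaluate_locus(
    father_call: GenotypeCall,
    mother_call: GenotypeCall,
    plasma: PlasmaLocusProfile,
    freq_table: FrequencyTable,
    *,
    foreign_candidates: str = "ignore",
) -> LocusEvidence:
    """Classify one locus and compute its paternity index.

    The verdict follows the observed-haplotype combination table: the locus
    is discrepant exactly when the parents share no haplotype and no plasma
    candidate matches the father. With two matching candidates (both of the
    father's haplotypes apparently in plasma) one must be an artefact; the
    one with the higher population frequency is taken as the true paternal
    haplotype. With a shared parental haplotype and no foreign candidate the
    paternal haplotype is ambiguous among the maternal haplotypes the
    father carries.

    ``foreign_candidates`` sets how a plasma candidate matching no father
    haplotype is treated. ``"ignore"`` (default) leaves the verdict to the
    shared/matching counts alone — the right reading when in-window artefact
    haplotypes are common, as in real semiconductor plasma data, where such
    a candidate is most likely noise. ``"exclude"`` treats an unexplained
    foetal candidate as evidence against paternity (the locus becomes
    discrepant unless a candidate matches the father) — the right reading
    for noise-free or genotype-level data, where the candidate is the
    child's true paternal haplotype. Either way the candidate never counts
    towards |FF| and is recorded on the evidence.
    """
    if foreign_candidates not in ("ignore", "exclude"):
        raise ValueError("foreign_candidates must be 'ignore' or 'exclude'")
    if father_call.status != "called" or mother_call.status != "called":
        raise ValueError(f"{plasma.locus_id}: both parents must be called")
    if not plasma.usable:
        raise ValueError(f"{plasma.locus_id}: plasma locus was dismissed")
    father_set = set(father_call.haplotypes)
    mother_set = set(mother_call.haplotypes)
    shared = father_set & mother_set
    matching = sorted(h for h in plasma.candidate_paternal if h in father_set)
    ignored = tuple(sorted(h for h in plasma.candidate_paternal if h not in father_set))

    discrepant = not shared and not matching
    if foreign_candidates == "exclude" and not matching and ignored:
        discrepant = True
    if discrepant:
        return LocusEvidence(
            plasma.locus_id, len(shared), 0, "discrepant", ignored_candidates=ignored
        )
    if len(matching) == 1:
        obligate = (matching[0],)
        consistent = obligate
    elif len(matching) >= 2:
        # both father haplotypes seen: keep the most frequent in the population
        best = max(matching, key=lambda h: (lookup_frequency(freq_table, h), h))
        obligate = (best,)
        consistent = obligate
    else:  # no matching candidate, but parents share >= 1 haplotype
        obligate = tuple(sorted(shared))
        # any maternal haplotype transmitted paternally is invisible in plasma
        consistent = tuple(sorted(mother_set))
    ev = LocusEvidence(
        plasma.locus_id,
        shared_count=len(shared),
        ff_count=len(matching),
        verdict="consistent",
        obligate=obligate,
        consistent_set=consistent,
        ignored_candidates=ignored,
    )
    ev.pi = locus_pi(ev, father_call, freq_table)
    return ev


def locus_pi(
    evidence: LocusEvidence,
    father_call: GenotypeCall,
    freq_table: FrequencyTable,
) -> float:
    """Paternity index for a consistent locus.

    Likelihood ratio of the plasma-compatible paternal transmission under
    "alleged father" versus "random man": the numerator is the fraction of
    the father's two haplotype copies lying in the plasma-consistent set,
    the denominator the total population frequency of that set (capped at
    1). With a single unambiguous obligate haplotype h this reduces to the
    textbook trio index T/p(h), T = 1 for a homozygous and 0.5 for a
    heterozygous father.
    """
    if evidence.discrepant:
        raise ValueError(
            f"{evidence.locus_id}: no index for a discrepant locus; use mutation_pi"
        )
    consistent = set(evidence.consistent_set)
    copies = father_call.haplotype_multiset
    t = sum(h in consistent for h in copies) / 2.0
    f = min(1.0, sum(lookup_frequency(freq_table, h) for h in evidence.consistent_set))
    if t == 0:
        raise ValueError(f"{evidence.locus_id}: father carries no consistent haplotype")
    return t / f


def mutation_pi(
    mutation_rate: float = PaternityConfig.mutation_rate,
    min_haplotype_freq: float = PaternityConfig.min_haplotype_freq,
) -> float:
    """Paternity index assigned to a discrepant locus under the mutation
    explanation: mutation_rate / min_haplotype_freq (5e-5 at the defaults).

    Haplotypes differing at several SNPs get the same value — with an index
    this small the extra factors are irrelevant to the case total.
    """
    if mutation_rate <= 0 or min_haplotype_freq <= 0:
        raise ValueError("mutation_rate and min_haplotype_freq must be positive")
    return mutation_rate / min_haplotype_freq


def combine_evidence(
    evidences: list[LocusEvidence],
    config: PaternityConfig = PaternityConfig(),
    case_id: str = "case",
) -> PaternityReport:
    """Combine per-locus evidence into the case decision and W.

    Two or more discrepant loci exclude paternity (no W is reported); one is
    inconclusive (W over the consistent loci is reported with a prominent
    flag, optionally folding in the discrepant locus's mutation index); none
    yields inclusion with W = CPI/(1+CPI). The CPI is accumulated in log
    space, so a hundred loci with extreme indices neither overflow nor
    underflow.
    """
    if not evidences:
        raise ValueError("no locus evidence to combine")
    n_discrepant = sum(e.discrepant for e in evidences)
    consistent = [e for e in evidences if not e.discrepant]
    n_used = len(consistent)
    log10_cpi = sum(math.log10(e.pi) for e in consistent)
    mut = mutation_pi(config.mutation_rate, config.min_haplotype_freq)

    if n_discrepant >= 2:
        decision = "exclusion"
        return PaternityReport(
            case_id, evidences, n_used, n_discrepant, decision,
            log10_cpi=None, cpi=None, w=None,
            low_marker_flag=n_used < config.min_loci,
        )
    if n_discrepant == 1 and config.mutation_pi_in_w:
        log10_cpi += math.log10(mut)
    cpi = 10.0 ** log10_cpi if abs(log10_cpi) < 300 else math.inf if log10_cpi > 0 else 0.0
    w = float(expit(log10_cpi * LOG10))
    decision = "inconclusive" if n_discrepant == 1 else "inclusion"
    return PaternityReport(
        case_id, evidences, n_used, n_discrepant, decision,
        log10_cpi=log10_cpi, cpi=cpi, w=w,
        low_marker_flag=n_used < config.min_loci,
        inconclusive_w_flag=decision == "inconclusive",
    )


def tabulated_log10_cpi(
    evidences: list[LocusEvidence],
    config: PaternityConfig = PaternityConfig(),
) -> float:
    """Log10 CPI with every discrepant locus contributing its mutation
    index — the quantity tabulated when plotting W against marker count for
    simulated non-fathers."""
    mut = mutation_pi(config.mutation_rate, config.min_haplotype_freq)
    total = 0.0
    for e in evidences:
        total += math.log10(mut) if e.discrepant else math.log10(e.pi)
    return total


def w_from_log10_cpi(log10_cpi: float) -> float:
    """W = CPI/(1+CPI), computed stably from log10(CPI)."""
    return float(expit(log10_cpi * LOG10))
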