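"""End-to-end case processing: aligned reads in, paternity report out.

Composes the pipeline stages — read filtering and haplotype observation,
parental genotype calling, plasma screening, per-locus evidence and the
combined probability of paternity — for one mother / alleged-father /
plasma case. Also bundles a read-level case simulator for benchmarking the
whole chain on synthetic data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotyping import (
    FoetalFractionEstimate,
    GenotypeCall,
    GenotypeThresholds,
    PlasmaLocusProfile,
    PlasmaThresholds,
    analyze_plasma_locus,
    call_genotype,
    estimate_foetal_fraction,
)
from .panel import FrequencyTable, MicrohapDef
from .paternity import PaternityConfig, PaternityReport, combine_evidence, evaluate_locus
from .read_processing import AlignedReadView, build_locus_profile
from .synthetic import (
    Family,
    ReadSimSpec,
    generate_plasma_reads,
    generate_sample_reads,
)

__all__ = ["CaseResult", "simulate_case_reads", "process_case"]


@dataclass
class CaseResult:
    """Everything a case yields, stage by stage."""

    report: PaternityReport
    mother_calls: dict[str, GenotypeCall]
    father_calls: dict[str, GenotypeCall]
    plasma: dict[str, PlasmaLocusProfile]
    foetal_fraction: FoetalFractionEstimate
    skipped_loci: dict[str, str]


def simulate_case_reads(
    family: Family,
    defs: list[MicrohapDef],
    rng: np.random.Generator,
    *,
    gdna_spec: ReadSimSpec = ReadSimSpec(coverage=200),
    plasma_spec: ReadSimSpec = ReadSimSpec(coverage=2000),
) -> dict[str, dict[str, list[AlignedReadView]]]:
    """Simulate the three sequencing runs of a case.

    Returns reads keyed by sample role (``mother``, ``alleged_father``,
    ``plasma``) then locus. Plasma mixes the mother's and the true child's
    haplotypes at ``plasma_spec.foetal_fraction``.
    """
    reads: dict[str, dict[str, list[AlignedReadView]]] = {
        "mother": {}, "alleged_father": {}, "plasma": {},
    }
    for d in defs:
        lid = d.locus_id
        reads["mother"][lid] = generate_sample_reads(
            family.genotypes["mother"][lid], d, gdna_spec, rng, "mother"
        )
        reads["alleged_father"][lid] = generate_sample_reads(
            family.genotypes["alleged_father"][lid], d, gdna_spec, rng, "father"
        )
        reads["plasma"][lid] = generate_plasma_reads(
            family.genotypes["mother"][lid], family.genotypes["child"][lid],
            d, plasma_spec, rng, "plasma",
        )
    return reads


def process_case(
    reads: dict[str, dict[str, list[AlignedReadView]]],
    defs: list[MicrohapDef],
    freq_tables: dict[str, FrequencyTable],
    *,
    case_id: str = "case",
    genotype_thresholds: GenotypeThresholds = GenotypeThresholds(),
    plasma_thresholds: PlasmaThresholds = PlasmaThresholds(),
    config: PaternityConfig = PaternityConfig(),
    foreign_candidates: str = "ignore",
) -> CaseResult:
    """Run the full pipeline on one case's aligned reads.

    Loci are skipped (with a reason) when a parent cannot be genotyped or
    the plasma is dismissed; the remaining loci contribute evidence to the
    verdict and the foetal-fraction estimate.
    """
    mother_calls: dict[str, GenotypeCall] = {}
    father_calls: dict[str, GenotypeCall] = {}
    plasma_profiles: dict[str, PlasmaLocusProfile] = {}
    skipped: dict[str, str] = {}
    evidences = []
    for d in defs:
        lid = d.locus_id
        m_prof = build_locus_profile(reads["mother"][lid], d, "mother")
        f_prof = build_locus_profile(reads["alleged_father"][lid], d, "alleged_father")
        p_prof = build_locus_profile(reads["plasma"][lid], d, "plasma")
        m_call = call_genotype(m_prof, genotype_thresholds)
        f_call = call_genotype(f_prof, genotype_thresholds)
        mother_calls[lid] = m_call
        father_calls[lid] = f_call
        if m_call.status != "called":
            skipped[lid] = f"mother_{m_call.status}"
            continue
        plasma = analyze_plasma_locus(p_prof, m_call, plasma_thresholds)
        plasma_profiles[lid] = plasma
        if not plasma.usable:
            skipped[lid] = f"plasma_{plasma.dismiss_reason}"
            continue
        if f_call.status != "called":
            skipped[lid] = f"father_{f_call.status}"
            continue
        evidences.append(evaluate_locus(
            f_call, m_call, plasma, freq_tables[lid],
            foreign_candidates=foreign_candidates,
        ))
    if not evidences:
        raise ValueError(f"{case_id}: no usable locus")
    report = combine_evidence(evidences, config, case_id=case_id)
    ff = estimate_foetal_fraction(plasma_profiles, father_calls)
    return CaseResult(
        report=report,
        mother_calls=mother_calls,
        father_calls=father_calls,
        plasma=plasma_profiles,
        foetal_fraction=ff,
        skipped_loci=skipped,
    )
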