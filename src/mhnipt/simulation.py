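"""In-silico paternity experiments on a reference panel.

Two study designs are supported. The power curve draws couples from the
panel, builds a Mendelian child, and evaluates either the true father or a
second, unrelated man against the mother-child evidence while the number
of markers grows from 1 to the panel size — measuring how many
microhaplotypes are needed before false inclusions (a non-father reaching
W above the reporting threshold) become rare. The cross-evaluation pairs
every mother-plasma duo with every alleged father in a set of processed
cases and summarises discrimination as ROC curves, one per minimum-marker
cutoff.

Genotype-level replicates reuse the full evidence machinery through an
ideal-plasma adapter: maternal haplotypes at high relative frequency and
the child's non-maternal haplotype, if any, placed inside the foetal
detection window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotyping import GenotypeCall, PlasmaLocusProfile
from .panel import FrequencyTable, ReferencePanel
from .paternity import (
    PaternityConfig,
    evaluate_locus,
    mutation_pi,
    w_from_log10_cpi,
)
from .synthetic import Family, generate_family

__all__ = [
    "SimulatedTrio",
    "SimulationResult",
    "CaseData",
    "simulate_trio",
    "genotypes_to_ideal_plasma",
    "genotype_calls_from_pairs",
    "paternity_power_curve",
    "cross_evaluate",
    "roc_points",
]


@dataclass
class SimulatedTrio:
    """Mother, father and Mendelian child genotypes over the panel loci."""

    mother: dict[str, tuple[str, str]]
    father: dict[str, tuple[str, str]]
    child: dict[str, tuple[str, str]]
    population: str | None = None
    mother_id: str = ""
    father_id: str = ""


@dataclass
class SimulationResult:
    """Power-curve output.

    ``records`` holds one row per (replicate, n_loci) with the tabulated W
    (discrepant loci contributing the mutation index) and the decision;
    ``false_inclusions`` counts, per n_loci, non-father replicates reaching
    an inclusion decision with W above the threshold.
    """

    mode: str  # per_population | random
    hypothesis: str  # true_father | false_father
    n_reps: int
    records: pd.DataFrame
    false_inclusions: dict[int, int] = field(default_factory=dict)

    def false_inclusion_rate(self, n_loci: int) -> float:
        return self.false_inclusions.get(n_loci, 0) / self.n_reps


@dataclass
class CaseData:
    """One processed case for cross-evaluation: the mother-plasma duo plus
    the alleged father's genotype calls."""

    case_id: str
    mother_calls: dict[str, GenotypeCall]
    plasma: dict[str, PlasmaLocusProfile]
    father_calls: dict[str, GenotypeCall]


# ---------------------------------------------------------------------------
# trio simulation and the ideal-plasma adapter

def simulate_trio(
    panel: ReferencePanel,
    mode: str = "per_population",
    rng: int | np.random.Generator = 0,
) -> SimulatedTrio:
    """Draw a couple from the panel and build their Mendelian child.

    ``per_population`` draws both parents from one (uniformly chosen)
    population; ``random`` pools all samples. The child takes one haplotype
    of each parent, uniformly and independently per locus.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if mode not in ("per_population", "random"):
        raise ValueError("mode must be 'per_population' or 'random'")
    population = None
    if mode == "per_population":
        labels = panel.population_labels()
        if not labels:
            raise ValueError("per_population mode needs population labels")
        population = labels[int(rng.integers(len(labels)))]
        n_pop = sum(1 for s in panel.samples if panel.populations.get(s) == population)
        if n_pop < 2:
            raise ValueError(f"population {population!r} has < 2 samples")
    fam = generate_family(panel, True, rng, population=population)
    return SimulatedTrio(
        mother=fam.genotypes["mother"],
        father=fam.genotypes["true_father"],
        child=fam.genotypes["child"],
        population=population,
        mother_id=fam.mother_id,
        father_id=fam.true_father_id,
    )


def genotypes_to_ideal_plasma(
    mother: dict[str, tuple[str, str]],
    child: dict[str, tuple[str, str]],
    candidate_freq: float = 0.05,
) -> dict[str, PlasmaLocusProfile]:
    """Noise-free plasma profiles from genotype-level simulations.

    Maternal haplotypes take the bulk of the relative frequency; the
    child's non-maternal haplotype, if any, is placed at ``candidate_freq``
    (inside the foetal detection window). When both child haplotypes match
    maternal ones no candidate is emitted.
    """
    profiles: dict[str, PlasmaLocusProfile] = {}
    for locus_id, m_gt in mother.items():
        maternal_set = set(m_gt)
        foreign = [h for h in child[locus_id] if h not in maternal_set]
        candidates = {foreign[0]: candidate_freq} if foreign else {}
        bulk = 1.0 - sum(candidates.values())
        maternal = {h: bulk / len(maternal_set) for h in sorted(maternal_set)}
        profiles[locus_id] = PlasmaLocusProfile(
            locus_id=locus_id,
            usable=True,
            dismiss_reason=None,
            maternal_haplotypes=maternal,
            candidate_paternal=candidates,
        )
    return profiles


def genotype_calls_from_pairs(
    genotypes: dict[str, tuple[str, str]],
) -> dict[str, GenotypeCall]:
    """Wrap known haplotype pairs as called genotypes."""
    return {
        locus_id: GenotypeCall(locus_id, "called", tuple(sorted(set(gt))))
        for locus_id, gt in genotypes.items()
    }


# ---------------------------------------------------------------------------
# power curve

def paternity_power_curve(
    panel: ReferencePanel,
    freq_tables: dict[str, FrequencyTable],
    n_reps: int,
    mode: str = "per_population",
    hypothesis: str = "true_father",
    rng: int | np.random.Generator = 0,
    *,
    config: PaternityConfig = PaternityConfig(),
    locus_order: str = "panel",
    foreign_candidates: str = "exclude",
) -> SimulationResult:
    """Evaluate paternity while the marker count grows from 1 to L.

    Per replicate a trio is simulated; under ``false_father`` a second man
    — distinct from the true father and, in per_population mode, from the
    same population — is evaluated instead. For each n_loci the first n
    loci (panel order, or a random permutation per replicate with
    ``locus_order='random'``) feed the evidence machinery via ideal plasma.
    W is tabulated with discrepant loci contributing the mutation index; a
    false inclusion is a non-father replicate whose decision is inclusion
    with W above ``config.w_report_threshold``.

    Ideal plasma is noise-free, so by default an in-window candidate that
    matches no alleged-father haplotype is the child's true paternal
    haplotype and counts against paternity (``foreign_candidates='exclude'``
    — the full-trio reading appropriate for genotype-level simulation).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if hypothesis not in ("true_father", "false_father"):
        raise ValueError("hypothesis must be 'true_father' or 'false_father'")
    loci = list(freq_tables)
    n_loci_max = len(loci)
    log_mut = np.log10(mutation_pi(config.mutation_rate, config.min_haplotype_freq))
    rows = []
    false_inclusions = {n: 0 for n in range(1, n_loci_max + 1)}
    for rep in range(n_reps):
        population = None
        if mode == "per_population":
            labels = panel.population_labels()
            population = labels[int(rng.integers(len(labels)))]
        fam = generate_family(
            panel, hypothesis == "true_father", rng, population=population
        )
        mother_calls = genotype_calls_from_pairs(fam.genotypes["mother"])
        father_calls = genotype_calls_from_pairs(fam.genotypes["alleged_father"])
        plasma = genotypes_to_ideal_plasma(
            fam.genotypes["mother"], fam.genotypes["child"]
        )
        order = loci if locus_order == "panel" else [
            loci[i] for i in rng.permutation(n_loci_max)
        ]
        log_pi = np.empty(n_loci_max)
        disc = np.empty(n_loci_max, dtype=bool)
        for i, locus_id in enumerate(order):
            ev = evaluate_locus(
                father_calls[locus_id], mother_calls[locus_id],
                plasma[locus_id], freq_tables[locus_id],
                foreign_candidates=foreign_candidates,
            )
            disc[i] = ev.discrepant
            log_pi[i] = log_mut if ev.discrepant else np.log10(ev.pi)
        cum_disc = np.cumsum(disc)
        cum_log = np.cumsum(log_pi)
        for n in range(1, n_loci_max + 1):
            w = w_from_log10_cpi(float(cum_log[n - 1]))
            if cum_disc[n - 1] >= 2:
                decision = "exclusion"
            elif cum_disc[n - 1] == 1:
                decision = "inconclusive"
            else:
                decision = "inclusion"
            if (
                hypothesis == "false_father"
                and decision == "inclusion"
                and w > config.w_report_threshold
            ):
                false_inclusions[n] += 1
            rows.append((rep, n, w, decision))
    records = pd.DataFrame(rows, columns=["replicate", "n_loci", "w", "decision"])
    return SimulationResult(
        mode=mode,
        hypothesis=hypothesis,
        n_reps=n_reps,
        records=records,
        false_inclusions=false_inclusions,
    )


# ---------------------------------------------------------------------------
# cross-evaluation ROC

def roc_points(labels, scores) -> tuple[pd.DataFrame, float]:
    """ROC curve and AUC from binary labels and scores.

    Thin wrapper over scikit-learn's threshold sweep (equal scores are
    grouped; AUC by trapezoid). Degenerate label sets raise.
    """
    from sklearn.metrics import auc, roc_curve

    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.min() == labels.max():
        raise ValueError("need at least one positive and one negative label")
    fpr, tpr, thresholds = roc_curve(labels, scores)
    return (
        pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds}),
        float(auc(fpr, tpr)),
    )


def cross_evaluate(
    cases: list[CaseData],
    freq_tables: dict[str, FrequencyTable],
    min_loci_values: tuple[int, ...] = (10, 13, 15),
    config: PaternityConfig = PaternityConfig(),
    foreign_candidates: str = "ignore",
) -> dict[int, dict]:
    """Pair every mother-plasma duo with every alleged father and build ROC
    curves per minimum-marker cutoff.

    For each pair, evidence is evaluated over the loci where the plasma is
    usable and both parents are called. Pairs with exactly one discrepant
    locus (inconclusive) are excluded; at each cutoff, pairs with fewer
    usable loci are dropped. Scores are W with exclusions scored 0; labels
    mark the true pairing. A cutoff left without both classes yields
    ``auc=None`` (curve undefined).
    """
    if len(cases) < 2:
        raise ValueError("cross-evaluation needs >= 2 cases")
    pair_rows = []
    for duo in cases:
        for father_case in cases:
            usable = [
                lid for lid, pl in duo.plasma.items()
                if pl.usable
                and duo.mother_calls.get(lid) is not None
                and duo.mother_calls[lid].status == "called"
                and father_case.father_calls.get(lid) is not None
                and father_case.father_calls[lid].status == "called"
            ]
            evidences = [
                evaluate_locus(
                    father_case.father_calls[lid],
                    duo.mother_calls[lid],
                    duo.plasma[lid],
                    freq_tables[lid],
                    foreign_candidates=foreign_candidates,
                )
                for lid in usable
            ]
            n_disc = sum(e.discrepant for e in evidences)
            if n_disc == 1:
                continue  # inconclusive pairs are excluded
            if n_disc >= 2:
                score = 0.0
            else:
                log_cpi = float(np.sum([np.log10(e.pi) for e in evidences]))
                score = w_from_log10_cpi(log_cpi)
            pair_rows.append({
                "duo": duo.case_id,
                "father": father_case.case_id,
                "label": int(duo.case_id == father_case.case_id),
                "n_usable": len(usable),
                "score": score,
            })
    pairs = pd.DataFrame(pair_rows)
    out: dict[int, dict] = {}
    for cutoff in min_loci_values:
        sub = pairs[pairs["n_usable"] >= cutoff]
        if sub.empty or sub["label"].nunique() < 2:
            out[cutoff] = {"points": None, "auc": None, "n_pairs": len(sub)}
            continue
        points, auc_val = roc_points(sub["label"].to_numpy(), sub["score"].to_numpy())
        out[cutoff] = {"points": points, "auc": auc_val, "n_pairs": len(sub)}
    return out
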