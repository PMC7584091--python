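"""Synthetic panels, families and error-bearing aligned reads.

Every stage of the pipeline is testable without external downloads: this
module generates (i) a phased reference panel with population structure,
drawn per locus from Dirichlet haplotype frequencies under Hardy-Weinberg
proportions; (ii) Mendelian families with a true or unrelated alleged
father; and (iii) aligned amplicon reads with substitution errors,
two-point base qualities, truncated reads (producing partial haplotypes),
and a sprinkling of low-mapq / indel-cigar / non-unique reads so every
read-filter branch is exercised. Plasma reads are a maternal/foetal
mixture: each read comes from the child's haplotypes with probability f
(the total foetal fraction), so the paternal-only haplotype has expected
relative frequency f/2.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel import FrequencyTable, MicrohapDef, ReferencePanel, haplotype_frequencies
from .read_processing import AlignedReadView

__all__ = [
    "SynthPanelSpec",
    "ReadSimSpec",
    "Family",
    "generate_defs",
    "generate_panel",
    "generate_family",
    "generate_sample_reads",
    "generate_plasma_reads",
    "write_vcf",
    "write_sam",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SynthPanelSpec:
    """Shape of a synthetic reference panel.

    Loci carry ``haplotypes_per_locus`` distinct haplotypes (>= 3, as a
    useful microhaplotype must). Base frequencies per locus come from a
    symmetric Dirichlet with concentration ``alpha`` — small alpha gives
    skewed frequencies and lower effective allele numbers, large alpha
    near-equal ones. Each population then draws its own frequencies from
    Dirichlet(base * population_concentration), a Balding-Nichols-style
    perturbation with F_st ~ 1/(1 + population_concentration); the default
    of 50 corresponds to the mild differentiation (F_st ~ 0.02) of
    continental human populations. Defaults give per-locus pooled A_e in
    roughly the 3-5 range typical of curated forensic panels.
    """

    n_loci: int = 20
    n_snps: tuple[int, int] = (3, 5)  # inclusive range per locus
    haplotypes_per_locus: int = 6
    alpha: float = 1.2
    population_concentration: float = 50.0
    populations: tuple[tuple[str, int], ...] = (
        ("POP1", 50), ("POP2", 50), ("POP3", 50), ("POP4", 50),
    )

    def __post_init__(self) -> None:
        if self.haplotypes_per_locus < 3:
            raise ValueError("a microhaplotype locus needs >= 3 haplotypes")
        if sum(n for _, n in self.populations) < 2:
            raise ValueError("need at least 2 samples in total")


@dataclass(frozen=True)
class ReadSimSpec:
    """Noise model for simulated amplicon reads.

    ``coverage`` is reads per locus; ``error_rate`` the per-base
    substitution probability (uniform over the three other bases);
    base qualities are a two-point mixture Q``q_high``/Q``q_low`` with
    ``low_qual_fraction`` of bases low — enough to exercise the unknown-base
    masking. ``truncated_fraction`` of reads cover only a prefix or suffix
    of the amplicon's SNPs and so yield partial haplotypes;
    ``low_mapq_fraction``, ``indel_fraction`` and ``nonunique_fraction``
    produce reads the filter must reject. ``foetal_fraction`` applies to
    plasma generation only.
    """

    coverage: int = 200
    error_rate: float = 0.005
    q_high: int = 30
    q_low: int = 10
    low_qual_fraction: float = 0.03
    truncated_fraction: float = 0.05
    low_mapq_fraction: float = 0.01
    indel_fraction: float = 0.01
    nonunique_fraction: float = 0.01
    foetal_fraction: float = 0.08

    def __post_init__(self) -> None:
        if not 0 <= self.foetal_fraction <= 0.5:
            raise ValueError("foetal fraction must be in [0, 0.5]")
        if not 0 <= self.error_rate <= 0.1:
            raise ValueError("error rate must be in [0, 0.1]")


@dataclass
class Family:
    """A simulated trio plus the alleged father under test.

    ``genotypes[member][locus_id]`` is an ordered haplotype pair for members
    ``mother``, ``true_father``, ``alleged_father`` and ``child``. When
    ``true_father_case`` the alleged father IS the true father.
    """

    mother_id: str
    true_father_id: str
    alleged_father_id: str
    true_father_case: bool
    genotypes: dict[str, dict[str, tuple[str, str]]]
    population: str | None = None


# ---------------------------------------------------------------------------
# panel generation

def generate_defs(spec: SynthPanelSpec, rng: np.random.Generator) -> list[MicrohapDef]:
    """Marker definitions, one synthetic contig per locus."""
    defs = []
    lo, hi = spec.n_snps
    for i in range(spec.n_loci):
        n_snps = int(rng.integers(lo, hi + 1))
        length = int(rng.integers(100, 141))
        start = 1001
        pos = np.sort(rng.choice(np.arange(start + 5, start + length - 5),
                                 size=n_snps, replace=False))
        defs.append(MicrohapDef(
            locus_id=f"MH{i + 1:02d}",
            chrom=f"ctg{i + 1:02d}",
            start=start,
            end=start + length - 1,
            snp_positions=tuple(int(p) for p in pos),
        ))
    return defs


def _locus_haplotypes(n_snps: int, k: int, rng: np.random.Generator) -> list[str]:
    """k distinct haplotype strings over a biallelic base pair per SNP."""
    if 2 ** n_snps < k:
        raise ValueError(f"{n_snps} biallelic SNPs cannot host {k} haplotypes")
    alleles = []
    for _ in range(n_snps):
        pair = rng.choice(4, size=2, replace=False)
        alleles.append([chr(_BASES[a]) for a in pair])
    combos = rng.choice(2 ** n_snps, size=k, replace=False)
    haps = []
    for c in combos:
        haps.append("".join(alleles[j][(c >> j) & 1] for j in range(n_snps)))
    return haps


def generate_panel(
    spec: SynthPanelSpec,
    seed: int | np.random.Generator = 0,
) -> tuple[list[MicrohapDef], ReferencePanel, dict[str, FrequencyTable]]:
    """Generate a phased reference panel under within-population HWE.

    Returns the marker definitions, the panel, and pooled per-locus
    frequency tables computed from the realised haplotype counts.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    defs = generate_defs(spec, rng)
    samples, populations = [], {}
    for label, size in spec.populations:
        for j in range(size):
            sid = f"{label}_S{j + 1:03d}"
            samples.append(sid)
            populations[sid] = label
    haplotypes: dict[str, dict[str, tuple[str, str]]] = {}
    for d in defs:
        haps = _locus_haplotypes(d.n_snps, spec.haplotypes_per_locus, rng)
        base = rng.dirichlet([spec.alpha] * len(haps))
        locus_map: dict[str, tuple[str, str]] = {}
        for label, size in spec.populations:
            freqs = rng.dirichlet(
                np.maximum(base * spec.population_concentration, 1e-3)
            )
            pop_samples = [s for s in samples if populations[s] == label]
            draws = rng.choice(len(haps), size=(size, 2), p=freqs)
            for s, (a, b) in zip(pop_samples, draws):
                locus_map[s] = (haps[a], haps[b])
        haplotypes[d.locus_id] = locus_map
    panel = ReferencePanel(samples=samples, populations=populations, haplotypes=haplotypes)
    tables = {d.locus_id: haplotype_frequencies(panel, d.locus_id) for d in defs}
    return defs, panel, tables


# ---------------------------------------------------------------------------
# families

def generate_family(
    panel: ReferencePanel,
    true_father: bool,
    rng: np.random.Generator,
    *,
    population: str | None = None,
) -> Family:
    """Draw a Mendelian family from the panel.

    Mother and true father are distinct panel samples (from ``population``
    when given); the child inherits one haplotype from each, chosen
    uniformly per locus. When ``true_father`` is False the alleged father
    is a third, independent sample.
    """
    pool = [s for s in panel.samples
            if population is None or panel.populations.get(s) == population]
    if len(pool) < 3:
        raise ValueError("need >= 3 samples to draw a family")
    mother_id, father_id, stranger_id = (
        pool[i] for i in rng.choice(len(pool), size=3, replace=False)
    )
    alleged_id = father_id if true_father else stranger_id
    members = {
        "mother": mother_id,
        "true_father": father_id,
        "alleged_father": alleged_id,
    }
    genotypes: dict[str, dict[str, tuple[str, str]]] = {m: {} for m in members}
    genotypes["child"] = {}
    for locus_id, called in panel.haplotypes.items():
        for member, sid in members.items():
            genotypes[member][locus_id] = called[sid]
        m_gt, f_gt = called[mother_id], called[father_id]
        genotypes["child"][locus_id] = (
            m_gt[int(rng.integers(2))], f_gt[int(rng.integers(2))]
        )
    return Family(
        mother_id=mother_id,
        true_father_id=father_id,
        alleged_father_id=alleged_id,
        true_father_case=true_father,
        genotypes=genotypes,
        population=population,
    )


# ---------------------------------------------------------------------------
# reads

def _reads_from_pool(
    pool: list[str],
    probs: list[float],
    locus: MicrohapDef,
    spec: ReadSimSpec,
    rng: np.random.Generator,
    sample_tag: str,
) -> list[AlignedReadView]:
    """Draw ``spec.coverage`` reads from a weighted haplotype pool."""
    n = spec.coverage
    length = locus.length
    snp_off = np.array(locus.snp_positions) - locus.start
    # reference background: deterministic arbitrary sequence
    ref = _BASES[np.arange(length) % 4].copy()
    hap_codes = np.array(
        [[b"ACGT".index(h[j].encode()) for j in range(locus.n_snps)] for h in pool],
        dtype=np.uint8,
    )
    src = rng.choice(len(pool), size=n, p=np.asarray(probs) / np.sum(probs))
    bases = np.tile(ref, (n, 1))
    bases[:, snp_off] = _BASES[hap_codes[src]]
    # substitution errors, uniform over the 3 other bases
    if spec.error_rate > 0:
        err = rng.random((n, length)) < spec.error_rate
        shift = rng.integers(1, 4, size=(n, length), dtype=np.uint8)
        codes = np.searchsorted(_BASES, bases)
        bases = np.where(err, _BASES[(codes + shift) % 4], bases)
    quals = np.where(
        rng.random((n, length)) < spec.low_qual_fraction, spec.q_low, spec.q_high
    ).astype(np.int16)
    truncated = rng.random(n) < spec.truncated_fraction
    suffix_side = rng.random(n) < 0.5
    low_mapq = rng.random(n) < spec.low_mapq_fraction
    indel = rng.random(n) < spec.indel_fraction
    nonunique = rng.random(n) < spec.nonunique_fraction
    mapqs = np.where(low_mapq, 10, 60)

    reads = []
    for i in range(n):
        row = bases[i]
        qrow = quals[i]
        start = locus.start
        if truncated[i] and locus.n_snps >= 2:
            # cover only a prefix or suffix of the SNPs
            cut_snp = int(rng.integers(1, locus.n_snps))
            if suffix_side[i]:
                s0 = int(snp_off[cut_snp])
                row, qrow = row[s0:], qrow[s0:]
                start = locus.start + s0
            else:
                e0 = int(snp_off[cut_snp - 1]) + 1
                row, qrow = row[:e0], qrow[:e0]
        if indel[i]:
            a = len(row) // 2
            cigar = (("M", a), ("I", 1), ("M", len(row) - a))
        else:
            cigar = (("M", len(row)),)
        reads.append(AlignedReadView(
            read_id=f"{sample_tag}:{locus.locus_id}:r{i}",
            mapq=int(mapqs[i]),
            cigar_ops=cigar,
            ref_start=start,
            bases=bytes(row).decode(),
            base_quals=qrow,
            unique_flag=not nonunique[i],
        ))
    return reads


def generate_sample_reads(
    genotype: tuple[str, str],
    locus: MicrohapDef,
    spec: ReadSimSpec,
    rng: np.random.Generator,
    sample_tag: str = "gdna",
) -> list[AlignedReadView]:
    """Aligned reads from a diploid genomic sample: each read drawn from one
    of the two haplotypes with probability 1/2, noise per ``spec``."""
    h1, h2 = genotype
    return _reads_from_pool([h1, h2], [0.5, 0.5], locus, spec, rng, sample_tag)


def generate_plasma_reads(
    mother_gt: tuple[str, str],
    child_gt: tuple[str, str],
    locus: MicrohapDef,
    spec: ReadSimSpec,
    rng: np.random.Generator,
    sample_tag: str = "plasma",
) -> list[AlignedReadView]:
    """Aligned plasma reads: a maternal/foetal cfDNA mixture.

    Each read is foetal with probability ``spec.foetal_fraction`` and
    maternal otherwise, uniform over the source's two haplotypes, so a
    haplotype the child carries but the mother does not appears at expected
    relative frequency f/2.
    """
    f = spec.foetal_fraction
    pool = [mother_gt[0], mother_gt[1], child_gt[0], child_gt[1]]
    probs = [(1 - f) / 2, (1 - f) / 2, f / 2, f / 2]
    return _reads_from_pool(pool, probs, locus, spec, rng, sample_tag)


# ---------------------------------------------------------------------------
# serialization

def write_vcf(panel: ReferencePanel, defs: list[MicrohapDef], path) -> None:
    """Write the panel as a phased multi-sample VCF (v4.2, plain text).

    Alleles at each SNP are those observed across the panel; samples absent
    from a locus are written as ``./.`` at its sites.
    """
    lines = ["##fileformat=VCFv4.2"]
    for d in defs:
        lines.append(f"##contig=<ID={d.chrom},length={d.end + 100}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.samples))
    for d in defs:
        called = panel.haplotypes[d.locus_id]
        for j, pos in enumerate(d.snp_positions):
            observed = sorted({gt[k][j] for gt in called.values() for k in (0, 1)})
            ref, alts = observed[0], observed[1:]
            allele_idx = {b: i for i, b in enumerate(observed)}
            fields = [d.chrom, str(pos), f"{d.locus_id}_snp{j + 1}", ref,
                      ",".join(alts) if alts else ".", ".", "PASS", ".", "GT"]
            for s in panel.samples:
                gt = called.get(s)
                fields.append(
                    "./." if gt is None
                    else f"{allele_idx[gt[0][j]]}|{allele_idx[gt[1][j]]}"
                )
            lines.append("\t".join(fields))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_sam(
    reads_by_locus: dict[str, list[AlignedReadView]],
    defs: list[MicrohapDef],
    path,
) -> None:
    """Write simulated reads as a plain-text SAM file.

    Reads whose cigar contains an insertion get a base/quality inserted so
    the sequence length matches the cigar's query consumption.
    """
    by_id = {d.locus_id: d for d in defs}
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for d in defs:
        lines.append(f"@SQ\tSN:{d.chrom}\tLN:{d.end + 100}")
    for locus_id, reads in reads_by_locus.items():
        d = by_id[locus_id]
        for r in reads:
            seq, qual = list(r.bases), list(r.base_quals)
            consumed = 0
            for op, length in r.cigar_ops:
                if op == "I":
                    seq.insert(consumed, "A")
                    qual.insert(consumed, 30)
                consumed += length if op in "MI=XS" else 0
            flag = 0 if r.unique_flag else 256
            cigar = "".join(f"{length}{op}" for op, length in r.cigar_ops)
            qual_str = "".join(chr(q + 33) for q in qual)
            lines.append("\t".join([
                r.read_id, str(flag), d.chrom, str(r.ref_start), str(r.mapq),
                cigar, "*", "0", "0", "".join(seq), qual_str,
            ]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
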