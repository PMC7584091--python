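"""Population reference panel for microhaplotype markers.

A microhaplotype is a short (< 200 bp) amplicon containing two or more SNPs
whose phased base combination defines a multi-allelic marker. This module
builds the population side of the analysis: it loads marker definitions,
extracts phased per-locus haplotypes from a multi-sample VCF, derives
haplotype frequency tables (with the effective number of alleles, A_e), and
screens loci for Hardy-Weinberg equilibrium and pairwise linkage
equilibrium — the independence assumptions that license multiplying
per-locus paternity indices.

Coordinates are 1-based inclusive throughout (SAM/VCF convention).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MicrohapDef",
    "ReferencePanel",
    "FrequencyTable",
    "load_microhap_defs",
    "extract_panel_haplotypes",
    "haplotype_frequencies",
    "lookup_frequency",
    "effective_alleles",
    "hwe_test",
    "le_test",
    "qc_report",
    "write_frequency_table",
]

#: amplicon size range typical of cfDNA-compatible assays; outside it we warn
AMPLICON_RANGE = (80, 180)


@dataclass(frozen=True)
class MicrohapDef:
    """A named genomic interval with the ordered SNP positions defining the
    haplotype alphabet at that locus.

    ``start``/``end`` and ``snp_positions`` are 1-based inclusive reference
    coordinates; ``snp_positions`` must be strictly increasing with at least
    two entries, all inside the interval.
    """

    locus_id: str
    chrom: str
    start: int
    end: int
    snp_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        pos = tuple(int(p) for p in self.snp_positions)
        object.__setattr__(self, "snp_positions", pos)
        if len(pos) < 2:
            raise ValueError(f"{self.locus_id}: need >= 2 SNP positions, got {len(pos)}")
        if len(set(pos)) != len(pos):
            raise ValueError(f"{self.locus_id}: duplicate SNP positions")
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError(f"{self.locus_id}: SNP positions must be strictly increasing")
        if self.start > pos[0] or pos[-1] > self.end:
            raise ValueError(
                f"{self.locus_id}: SNP positions {pos} outside interval "
                f"[{self.start}, {self.end}]"
            )
        if self.start > self.end:
            raise ValueError(f"{self.locus_id}: start > end")
        if not AMPLICON_RANGE[0] <= self.length <= AMPLICON_RANGE[1]:
            warnings.warn(
                f"{self.locus_id}: amplicon length {self.length} outside the "
                f"typical cfDNA range {AMPLICON_RANGE}",
                stacklevel=2,
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def n_snps(self) -> int:
        return len(self.snp_positions)


@dataclass
class ReferencePanel:
    """Phased diploid haplotypes for a cohort of reference samples.

    ``haplotypes[locus_id][sample_id]`` is an ordered pair of haplotype
    strings (alphabet ACGT, one symbol per SNP). Samples with missing or
    unphased data at a locus are simply absent from that locus's mapping.
    """

    samples: list[str]
    populations: dict[str, str]
    haplotypes: dict[str, dict[str, tuple[str, str]]]

    @property
    def loci(self) -> list[str]:
        return list(self.haplotypes)

    def samples_for(self, locus_id: str, population: str | None = None) -> list[str]:
        called = self.haplotypes[locus_id]
        if population is None:
            return [s for s in self.samples if s in called]
        return [
            s for s in self.samples
            if s in called and self.populations.get(s) == population
        ]

    def population_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.populations.get(s, ""), None)
        return [p for p in seen if p]


@dataclass
class FrequencyTable:
    """Haplotype counts and frequencies at one locus.

    Ordered by descending frequency, ties broken lexicographically.
    ``a_e = 1 / sum(p_i^2)`` is the effective number of alleles.
    """

    locus_id: str
    counts: dict[str, int]
    n_chromosomes: int
    frequencies: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        if self.n_chromosomes <= 0:
            raise ValueError(f"{self.locus_id}: empty frequency table")
        if sum(self.counts.values()) != self.n_chromosomes:
            raise ValueError(f"{self.locus_id}: counts do not sum to n_chromosomes")
        ordered = sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        self.counts = dict(ordered)
        self.frequencies = {h: c / self.n_chromosomes for h, c in ordered}

    @property
    def a_e(self) -> float:
        return effective_alleles(self)

    @property
    def haplotype_length(self) -> int:
        return len(next(iter(self.counts)))

    @property
    def min_frequency(self) -> float:
        """Lowest frequency an observed haplotype can have (a singleton)."""
        return 1.0 / self.n_chromosomes

    @property
    def unseen_frequency(self) -> float:
        """Frequency attributed to a haplotype never seen in the panel,
        1/(n_chromosomes + 1): with a 2504-sample diploid panel this is 1/5009.
        """
        return 1.0 / (self.n_chromosomes + 1)


# ---------------------------------------------------------------------------
# definitions file

def load_microhap_defs(path) -> list[MicrohapDef]:
    """Load microhaplotype definitions from a tab- or comma-separated table.

    Required columns: locus_id, chrom, start, end, snp_positions (the last a
    comma-separated list of 1-based positions). Rows keep input order.
    Duplicate locus ids reject the whole file; an invalid row raises with the
    offending locus named.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, skipinitialspace=True)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"locus_id", "chrom", "start", "end", "snp_positions"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"definition file missing columns: {sorted(missing)}")
    ids = df["locus_id"].str.strip()
    dupes = ids[ids.duplicated()].unique()
    if len(dupes):
        raise ValueError(f"duplicate locus_id values: {sorted(dupes)}")
    defs = []
    for _, row in df.iterrows():
        locus_id = row["locus_id"].strip()
        try:
            snps = tuple(int(p) for p in str(row["snp_positions"]).replace(";", ",").split(","))
            defs.append(
                MicrohapDef(
                    locus_id=locus_id,
                    chrom=row["chrom"].strip(),
                    start=int(row["start"]),
                    end=int(row["end"]),
                    snp_positions=snps,
                )
            )
        except ValueError as exc:
            raise ValueError(f"invalid definition row for {locus_id!r}: {exc}") from exc
    return defs


# ---------------------------------------------------------------------------
# haplotype extraction from a phased VCF

def extract_panel_haplotypes(
    vcf_path,
    defs: list[MicrohapDef],
    on_unphased: str = "drop",
) -> ReferencePanel:
    """Extract per-locus phased haplotypes for every sample in a VCF.

    For each sample and locus, haplotype 1 concatenates the first-phase
    alleles at the locus's SNP positions in order, haplotype 2 the second
    phase. A sample with a missing or (by default) unphased genotype at any
    of the locus's SNPs is omitted from that locus.

    Parameters
    ----------
    vcf_path
        Multi-sample VCF, phased GT (``|`` separator). Plain or bgzipped.
    defs
        Marker definitions; every SNP position must be present in the VCF.
    on_unphased
        ``"drop"`` (default) excludes a sample-locus with an unphased
        genotype; ``"abort"`` raises instead.

    Population labels are not stored in VCFs; they start empty and can be
    attached afterwards via ``panel.populations.update(...)``.
    """
    from cyvcf2 import VCF

    if on_unphased not in ("drop", "abort"):
        raise ValueError("on_unphased must be 'drop' or 'abort'")
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    wanted: dict[tuple[str, int], None] = {}
    for d in defs:
        for p in d.snp_positions:
            wanted[(d.chrom, p)] = None
    # site -> (n_samples, 2) allele index array, and site -> allele strings
    site_gt: dict[tuple[str, int], np.ndarray] = {}
    site_alleles: dict[tuple[str, int], list[str]] = {}
    site_phased: dict[tuple[str, int], np.ndarray] = {}
    for var in vcf:
        key = (var.CHROM, var.POS)
        if key not in wanted or key in site_gt:
            continue
        gts = np.asarray(var.genotypes)  # (n, 3): allele1, allele2, phased
        site_gt[key] = gts[:, :2]
        site_phased[key] = gts[:, 2].astype(bool)
        site_alleles[key] = [var.REF] + list(var.ALT)
    panel_haps: dict[str, dict[str, tuple[str, str]]] = {}
    for d in defs:
        keys = [(d.chrom, p) for p in d.snp_positions]
        absent = [k for k in keys if k not in site_gt]
        if absent:
            raise ValueError(f"{d.locus_id}: VCF lacks sites {absent}")
        locus_haps: dict[str, tuple[str, str]] = {}
        for i, sample in enumerate(samples):
            h1, h2 = [], []
            ok = True
            for k in keys:
                a1, a2 = site_gt[k][i]
                if a1 < 0 or a2 < 0:
                    ok = False
                    break
                if not site_phased[k][i] and a1 != a2:
                    if on_unphased == "abort":
                        raise ValueError(
                            f"unphased heterozygous genotype for {sample} at {k}"
                        )
                    ok = False
                    break
                alleles = site_alleles[k]
                h1.append(alleles[a1])
                h2.append(alleles[a2])
            if ok:
                locus_haps[sample] = ("".join(h1), "".join(h2))
        panel_haps[d.locus_id] = locus_haps
    return ReferencePanel(samples=samples, populations={}, haplotypes=panel_haps)


# ---------------------------------------------------------------------------
# frequencies

def haplotype_frequencies(
    panel: ReferencePanel,
    locus_id: str,
    population: str | None = None,
) -> FrequencyTable:
    """Count haplotypes over the panel's phased chromosomes at one locus.

    ``population`` restricts to samples carrying that label; ``None`` pools
    the whole panel.
    """
    if locus_id not in panel.haplotypes:
        raise KeyError(f"unknown locus {locus_id!r}")
    chosen = panel.samples_for(locus_id, population)
    if not chosen:
        raise ValueError(
            f"no called samples at {locus_id}"
            + (f" in population {population!r}" if population else "")
        )
    counts: dict[str, int] = {}
    called = panel.haplotypes[locus_id]
    for s in chosen:
        for h in called[s]:
            counts[h] = counts.get(h, 0) + 1
    return FrequencyTable(locus_id=locus_id, counts=counts, n_chromosomes=2 * len(chosen))


def lookup_frequency(table: FrequencyTable, haplotype: str) -> float:
    """Population frequency of ``haplotype``, with the add-one rule for
    haplotypes never observed in the panel.

    An unseen haplotype gets 1/(n_chromosomes + 1): for a 2504-sample
    reference (5008 chromosomes) this is 1/5009.
    """
    if len(haplotype) != table.haplotype_length:
        raise ValueError(
            f"haplotype {haplotype!r} has length {len(haplotype)}, "
            f"locus {table.locus_id} expects {table.haplotype_length}"
        )
    freq = table.frequencies.get(haplotype)
    return freq if freq is not None else table.unseen_frequency


def effective_alleles(table: FrequencyTable) -> float:
    """Effective number of alleles, A_e = 1 / sum(p_i^2)."""
    p = np.fromiter(table.frequencies.values(), dtype=float)
    if p.size == 0:
        raise ValueError("empty frequency table")
    return 1.0 / float(np.sum(p * p))


# ---------------------------------------------------------------------------
# Hardy-Weinberg equilibrium (Monte-Carlo exact test)

def _genotype_codes(pairs: np.ndarray, n_alleles: int) -> np.ndarray:
    """Map unordered allele-index pairs to a single genotype code."""
    lo = np.minimum(pairs[..., 0], pairs[..., 1])
    hi = np.maximum(pairs[..., 0], pairs[..., 1])
    return lo * n_alleles + hi


def _hwe_chi2(geno_codes: np.ndarray, expected: np.ndarray, code_index: dict[int, int]) -> float:
    obs = np.zeros(len(expected))
    for c in geno_codes:
        obs[code_index[int(c)]] += 1
    return float(np.sum((obs - expected) ** 2 / expected))


def hwe_test(
    panel: ReferencePanel,
    locus_id: str,
    population: str | None = None,
    *,
    n_permutations: int = 2000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Monte-Carlo exact test of Hardy-Weinberg equilibrium at one locus.

    Microhaplotypes are highly multi-allelic, so the asymptotic chi-square
    on the genotype table is unreliable; instead the observed alleles are
    permuted among individuals and re-paired into genotypes, which samples
    genotype configurations uniformly under the HWE null conditional on the
    allele counts. The p-value is the (add-one corrected) fraction of
    permutations whose chi-square distance from Hardy-Weinberg expectation
    is at least the observed one.

    A monomorphic locus returns p = 1 with a warning.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    chosen = panel.samples_for(locus_id, population)
    if len(chosen) < 2:
        raise ValueError(f"{locus_id}: need >= 2 samples for an HWE test")
    called = panel.haplotypes[locus_id]
    haps = sorted({h for s in chosen for h in called[s]})
    if len(haps) < 2:
        warnings.warn(f"{locus_id}: monomorphic, HWE p-value set to 1", stacklevel=2)
        return 1.0
    idx = {h: i for i, h in enumerate(haps)}
    n_all = len(haps)
    pairs = np.array([[idx[called[s][0]], idx[called[s][1]]] for s in chosen])
    n = len(pairs)
    alleles = pairs.ravel()
    p = np.bincount(alleles, minlength=n_all) / (2 * n)
    # expected genotype counts under HWE given the allele frequencies
    codes, expected = [], []
    for i in range(n_all):
        for j in range(i, n_all):
            e = n * (p[i] ** 2 if i == j else 2 * p[i] * p[j])
            if e > 0:
                codes.append(i * n_all + j)
                expected.append(e)
    expected_arr = np.array(expected)
    code_index = {c: k for k, c in enumerate(codes)}
    obs_stat = _hwe_chi2(_genotype_codes(pairs, n_all), expected_arr, code_index)

    # vectorised permutation null: shuffle alleles, re-pair consecutively
    perm = np.tile(alleles, (n_permutations, 1))
    perm = rng.permuted(perm, axis=1)
    perm_pairs = perm.reshape(n_permutations, n, 2)
    perm_codes = _genotype_codes(perm_pairs, n_all)
    cat = np.searchsorted(codes, perm_codes)
    counts = np.zeros((n_permutations, len(codes)))
    rows = np.repeat(np.arange(n_permutations), n)
    np.add.at(counts, (rows, cat.ravel()), 1.0)
    stats_null = np.sum((counts - expected_arr) ** 2 / expected_arr, axis=1)
    n_extreme = int(np.sum(stats_null >= obs_stat - 1e-9))
    return (1 + n_extreme) / (n_permutations + 1)


# ---------------------------------------------------------------------------
# linkage equilibrium (pairwise haplotype association on chromosomes)

def le_test(
    panel: ReferencePanel,
    locus_a: str,
    locus_b: str,
    *,
    population: str | None = None,
    n_permutations: int = 2000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Test for allelic association between two loci on phased chromosomes.

    Builds the joint haplotype contingency table over the 2n phased
    chromosomes of the shared samples and applies a chi-square independence
    test; when any expected cell count is below 5 the null distribution is
    taken from seeded Monte-Carlo permutations of one locus's chromosome
    labels instead of the asymptotic distribution.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    shared = [s for s in panel.samples_for(locus_a, population)
              if s in panel.haplotypes[locus_b]]
    if len(shared) < 2:
        raise ValueError(f"no shared called samples for {locus_a} and {locus_b}")
    a_called, b_called = panel.haplotypes[locus_a], panel.haplotypes[locus_b]
    a_chr = [h for s in shared for h in a_called[s]]
    b_chr = [h for s in shared for h in b_called[s]]
    a_levels = sorted(set(a_chr))
    b_levels = sorted(set(b_chr))
    if len(a_levels) < 2 or len(b_levels) < 2:
        warnings.warn("monomorphic locus in LE test, p-value set to 1", stacklevel=2)
        return 1.0
    ai = np.array([a_levels.index(h) for h in a_chr])
    bi = np.array([b_levels.index(h) for h in b_chr])
    table = np.zeros((len(a_levels), len(b_levels)))
    np.add.at(table, (ai, bi), 1.0)
    chi2, p_asym, _, expected = stats.chi2_contingency(table)
    if expected.min() >= 5:
        return float(p_asym)
    # Monte-Carlo null: permute one margin over chromosomes
    n_extreme = 0
    row = np.bincount(ai, minlength=len(a_levels)).astype(float)
    col = np.bincount(bi, minlength=len(b_levels)).astype(float)
    exp = np.outer(row, col) / len(ai)
    nz = exp > 0
    for _ in range(n_permutations):
        perm_b = rng.permutation(bi)
        t = np.zeros_like(table)
        np.add.at(t, (ai, perm_b), 1.0)
        stat = np.sum((t[nz] - exp[nz]) ** 2 / exp[nz])
        if stat >= chi2 - 1e-9:
            n_extreme += 1
    return (1 + n_extreme) / (n_permutations + 1)


# ---------------------------------------------------------------------------
# QC report / serialization

def qc_report(
    panel: ReferencePanel,
    defs: list[MicrohapDef],
    *,
    alpha: float = 0.05,
    n_permutations: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-locus QC table: A_e, HWE p-value, and Bonferroni-adjusted pass.

    Raw p-values are reported alongside a pass/fail column at the
    Bonferroni-corrected level alpha / n_loci.
    """
    rows = []
    rng = np.random.default_rng(seed)
    for d in defs:
        table = haplotype_frequencies(panel, d.locus_id)
        p = hwe_test(panel, d.locus_id, n_permutations=n_permutations, seed=rng)
        rows.append({"locus_id": d.locus_id, "a_e": table.a_e, "hwe_p": p})
    df = pd.DataFrame(rows)
    df["hwe_pass_bonferroni"] = df["hwe_p"] >= alpha / len(df)
    return df


def write_frequency_table(table: FrequencyTable, path) -> None:
    """Write one locus's frequency table as TSV
    (locus_id, haplotype, count, frequency)."""
    pd.DataFrame(
        {
            "locus_id": table.locus_id,
            "haplotype": list(table.counts),
            "count": list(table.counts.values()),
            "frequency": [table.frequencies[h] for h in table.counts],
        }
    ).to_csv(path, sep="\t", index=False)
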