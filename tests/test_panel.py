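"""Reference panel: definitions, haplotype extraction, frequencies, HWE/LE."""

import io
import itertools
import math

import numpy as np
import pytest

from mhnipt import (
    FrequencyTable,
    MicrohapDef,
    ReferencePanel,
    effective_alleles,
    extract_panel_haplotypes,
    haplotype_frequencies,
    hwe_test,
    le_test,
    load_microhap_defs,
    lookup_frequency,
)
from mhnipt.panel import qc_report


# ---------------------------------------------------------------------------
# definitions

class TestMicrohapDefs:
    def test_parse_row(self, tmp_path):
        f = tmp_path / "defs.tsv"
        f.write_text("locus_id\tchrom\tstart\tend\tsnp_positions\n"
                     "MH01\tchr1\t1000\t1120\t1010,1050,1100\n")
        (d,) = load_microhap_defs(f)
        assert d.n_snps == 3
        assert d.length == 121
        assert d.snp_positions == (1010, 1050, 1100)

    def test_snp_outside_interval_rejects_row(self, tmp_path):
        f = tmp_path / "defs.tsv"
        f.write_text("locus_id\tchrom\tstart\tend\tsnp_positions\n"
                     "MH01\tchr1\t1000\t1120\t1010,1500\n")
        with pytest.raises(ValueError, match="MH01"):
            load_microhap_defs(f)

    def test_duplicate_locus_id_rejects_file(self, tmp_path):
        f = tmp_path / "defs.tsv"
        f.write_text("locus_id\tchrom\tstart\tend\tsnp_positions\n"
                     "MH01\tchr1\t1000\t1120\t1010,1050\n"
                     "MH01\tchr2\t2000\t2120\t2010,2050\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_microhap_defs(f)

    def test_atypical_amplicon_length_warns(self):
        with pytest.warns(UserWarning, match="amplicon length"):
            MicrohapDef("MHX", "chr1", 1000, 1400, (1010, 1300))

    @pytest.mark.parametrize("snps", [(1010,), (1010, 1010), (1050, 1010)])
    def test_bad_snp_positions_rejected(self, snps):
        with pytest.raises(ValueError):
            MicrohapDef("MHX", "chr1", 1000, 1120, snps)


# ---------------------------------------------------------------------------
# VCF extraction

VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=2000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
"""

DEF_2SNP = MicrohapDef("MH01", "chr1", 1000, 1120, (1010, 1050))


def _write_vcf(tmp_path, body):
    f = tmp_path / "panel.vcf"
    f.write_text(VCF_HEADER + body)
    return f


class TestExtractHaplotypes:
    def test_phase_concatenation(self, tmp_path):
        f = _write_vcf(
            tmp_path,
            "chr1\t1010\t.\tA\tG\t.\tPASS\t.\tGT\t0|1\t1|1\n"
            "chr1\t1050\t.\tC\tT\t.\tPASS\t.\tGT\t1|1\t0|1\n",
        )
        panel = extract_panel_haplotypes(f, [DEF_2SNP])
        assert panel.haplotypes["MH01"]["S1"] == ("AT", "GT")
        assert panel.haplotypes["MH01"]["S2"] == ("GC", "GT")

    def test_missing_genotype_excludes_sample(self, tmp_path):
        f = _write_vcf(
            tmp_path,
            "chr1\t1010\t.\tA\tG\t.\tPASS\t.\tGT\t0|1\t./.\n"
            "chr1\t1050\t.\tC\tT\t.\tPASS\t.\tGT\t1|1\t0|1\n",
        )
        panel = extract_panel_haplotypes(f, [DEF_2SNP])
        assert "S2" not in panel.haplotypes["MH01"]
        assert "S1" in panel.haplotypes["MH01"]

    def test_unphased_het_dropped_or_aborts(self, tmp_path):
        f = _write_vcf(
            tmp_path,
            "chr1\t1010\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t0|0\n"
            "chr1\t1050\t.\tC\tT\t.\tPASS\t.\tGT\t1|1\t0|1\n",
        )
        panel = extract_panel_haplotypes(f, [DEF_2SNP])
        assert "S1" not in panel.haplotypes["MH01"]
        with pytest.raises(ValueError, match="unphased"):
            extract_panel_haplotypes(f, [DEF_2SNP], on_unphased="abort")

    def test_missing_site_errors(self, tmp_path):
        f = _write_vcf(tmp_path, "chr1\t1010\t.\tA\tG\t.\tPASS\t.\tGT\t0|1\t1|1\n")
        with pytest.raises(ValueError, match="lacks sites"):
            extract_panel_haplotypes(f, [DEF_2SNP])


# ---------------------------------------------------------------------------
# frequencies

def _panel(hap_pairs, populations=None):
    samples = [f"S{i}" for i in range(len(hap_pairs))]
    pops = populations or {}
    return ReferencePanel(
        samples=samples,
        populations={s: pops.get(s, "P1") for s in samples},
        haplotypes={"L1": dict(zip(samples, hap_pairs))},
    )


class TestFrequencies:
    def test_direct_count(self):
        panel = _panel([("AT", "AT"), ("GT", "GT")])
        table = haplotype_frequencies(panel, "L1")
        assert table.frequencies == {"AT": 0.5, "GT": 0.5}
        assert table.n_chromosomes == 4

    def test_population_filter(self):
        panel = _panel([("AT", "AT"), ("GT", "GT")], {"S0": "PA", "S1": "PB"})
        table = haplotype_frequencies(panel, "L1", population="PA")
        assert table.frequencies == {"AT": 1.0}

    def test_empty_population_errors(self):
        panel = _panel([("AT", "AT")])
        with pytest.raises(ValueError, match="NOPE"):
            haplotype_frequencies(panel, "L1", population="NOPE")

    def test_counts_conserved_under_population_partition(self, synth_panel):
        defs, panel, tables = synth_panel
        locus = defs[0].locus_id
        whole = haplotype_frequencies(panel, locus)
        summed: dict[str, int] = {}
        for pop in panel.population_labels():
            for h, c in haplotype_frequencies(panel, locus, pop).counts.items():
                summed[h] = summed.get(h, 0) + c
        assert summed == whole.counts

    def test_frequencies_sum_to_one(self, synth_panel):
        _, panel, tables = synth_panel
        for table in tables.values():
            assert math.isclose(sum(table.frequencies.values()), 1.0, abs_tol=1e-12)


class TestLookupFrequency:
    def test_observed(self):
        table = FrequencyTable("L1", {"AT": 2, "GT": 2}, 4)
        assert lookup_frequency(table, "AT") == 0.5

    def test_unseen_full_scale_panel(self):
        # a 2504-sample diploid reference: 5008 chromosomes, unseen -> 1/5009
        table = FrequencyTable("L1", {"AT": 5000, "GT": 8}, 5008)
        assert lookup_frequency(table, "CC") == pytest.approx(1 / 5009)
        assert lookup_frequency(table, "CC") == pytest.approx(1.9964e-4, rel=1e-4)

    def test_unseen_small_panel(self):
        table = FrequencyTable("L1", {"AT": 6, "GT": 4}, 10)
        assert lookup_frequency(table, "CC") == pytest.approx(1 / 11)

    def test_length_mismatch(self):
        table = FrequencyTable("L1", {"AT": 4}, 4)
        with pytest.raises(ValueError, match="length"):
            lookup_frequency(table, "ATG")

    def test_observed_always_above_unseen(self, synth_panel):
        _, _, tables = synth_panel
        for table in tables.values():
            assert min(table.frequencies.values()) >= table.min_frequency
            assert table.min_frequency > table.unseen_frequency


class TestEffectiveAlleles:
    @pytest.mark.parametrize(
        "counts,n,expected",
        [
            ({"A": 2, "B": 2}, 4, 2.0),
            ({"A": 4}, 4, 1.0),
            ({"A": 7, "B": 2, "C": 1}, 10, 1 / (0.49 + 0.04 + 0.01)),
        ],
    )
    def test_values(self, counts, n, expected):
        assert effective_alleles(FrequencyTable("L", counts, n)) == pytest.approx(expected)

    def test_equals_k_iff_equifrequent(self):
        equal = FrequencyTable("L", {"A": 5, "B": 5, "C": 5}, 15)
        assert effective_alleles(equal) == pytest.approx(3.0)
        skew = FrequencyTable("L", {"A": 9, "B": 5, "C": 1}, 15)
        assert effective_alleles(skew) < 3.0


# ---------------------------------------------------------------------------
# HWE

def _hwe_enumeration_oracle(pairs):
    """Exact permutation HWE p-value: enumerate every pairing of the 2n
    allele copies into n unordered pairs, all equally likely under the null.
    """
    alleles = [a for pair in pairs for a in pair]
    n_all = len(set(alleles))
    n = len(pairs)
    p = np.bincount(alleles, minlength=n_all) / (2 * n)
    expected = {}
    for i in range(n_all):
        for j in range(i, n_all):
            e = n * (p[i] ** 2 if i == j else 2 * p[i] * p[j])
            if e > 0:
                expected[(i, j)] = e

    def stat(genos):
        obs = {k: 0 for k in expected}
        for g in genos:
            obs[g] += 1
        return sum((obs[k] - expected[k]) ** 2 / expected[k] for k in expected)

    obs_stat = stat([tuple(sorted(pr)) for pr in pairs])

    def matchings(idx):
        if not idx:
            yield []
            return
        first, rest = idx[0], idx[1:]
        for k in range(len(rest)):
            partner = rest[k]
            for m in matchings(rest[:k] + rest[k + 1:]):
                yield [(first, partner)] + m

    total = extreme = 0
    for m in matchings(list(range(2 * n))):
        genos = [tuple(sorted((alleles[i], alleles[j]))) for i, j in m]
        total += 1
        if stat(genos) >= obs_stat - 1e-9:
            extreme += 1
    return extreme / total


def _panel_from_pairs(pairs):
    haps = "ABCDEFGH"
    return _panel([(haps[a] * 2, haps[b] * 2) for a, b in pairs])


class TestHwe:
    def test_null_case_large_n(self):
        # genotype counts exactly at HW proportions for 2 equifrequent alleles
        pairs = [(0, 0)] * 25 + [(0, 1)] * 50 + [(1, 1)] * 25
        panel = _panel_from_pairs(pairs)
        assert hwe_test(panel, "L1", seed=0) > 0.5

    def test_all_heterozygous_rejected(self):
        panel = _panel_from_pairs([(0, 1)] * 50)
        assert hwe_test(panel, "L1", seed=0) < 0.01

    def test_single_sample_errors(self):
        panel = _panel([("AA", "AA")])
        with pytest.raises(ValueError, match=">= 2 samples"):
            hwe_test(panel, "L1")

    def test_monomorphic_warns_p_one(self):
        panel = _panel([("AA", "AA"), ("AA", "AA")])
        with pytest.warns(UserWarning, match="monomorphic"):
            assert hwe_test(panel, "L1") == 1.0

    @pytest.mark.parametrize(
        "pairs",
        [
            [(0, 1), (0, 1), (0, 0), (1, 1)],
            [(0, 1), (0, 2), (1, 2), (0, 0), (2, 2)],
            [(0, 0), (0, 1), (1, 1), (0, 1), (0, 0)],
        ],
    )
    def test_monte_carlo_matches_enumeration(self, pairs):
        exact = _hwe_enumeration_oracle(pairs)
        panel = _panel_from_pairs(pairs)
        mc = hwe_test(panel, "L1", n_permutations=40000, seed=7)
        assert mc == pytest.approx(exact, abs=3 * math.sqrt(exact * (1 - exact) / 40000) + 1e-4)

    def test_type_one_error_calibration(self):
        # panels simulated under HWE reject at ~ alpha (binomial band)
        rng = np.random.default_rng(99)
        n_reps, alpha, rejects = 300, 0.05, 0
        for _ in range(n_reps):
            freqs = rng.dirichlet([2.0] * 4)
            draws = rng.choice(4, size=(40, 2), p=freqs)
            panel = _panel_from_pairs([tuple(d) for d in draws])
            if hwe_test(panel, "L1", n_permutations=400, seed=rng) <= alpha:
                rejects += 1
        rate = rejects / n_reps
        # 3-sigma binomial band around alpha
        assert abs(rate - alpha) < 3 * math.sqrt(alpha * (1 - alpha) / n_reps) + 0.01


# ---------------------------------------------------------------------------
# LE

def _two_locus_panel(pairs_a, pairs_b):
    samples = [f"S{i}" for i in range(len(pairs_a))]
    return ReferencePanel(
        samples=samples,
        populations={s: "P1" for s in samples},
        haplotypes={
            "LA": dict(zip(samples, pairs_a)),
            "LB": dict(zip(samples, pairs_b)),
        },
    )


class TestLe:
    def test_independent_loci_rarely_rejected(self, small_panel):
        # under independence p is uniform-ish: most pairs should be > 0.05
        defs, panel, _ = small_panel
        pvals = [
            le_test(panel, a.locus_id, b.locus_id, seed=5)
            for a, b in itertools.combinations(defs, 2)
        ]
        assert sum(p <= 0.05 for p in pvals) <= 1
        assert max(pvals) > 0.2

    def test_perfect_association_rejected(self, small_panel):
        defs, panel, _ = small_panel
        locus = defs[0].locus_id
        dup = ReferencePanel(
            samples=panel.samples,
            populations=panel.populations,
            haplotypes={"A": panel.haplotypes[locus], "B": panel.haplotypes[locus]},
        )
        assert le_test(dup, "A", "B", seed=5) < 0.01

    def test_diagonal_table_rejected(self):
        # 3x3 joint table with all mass on the diagonal, n = 60 chromosomes
        haps = ["AA", "CC", "GG"]
        pairs = [(haps[i % 3], haps[i % 3]) for i in range(30)]
        panel = _two_locus_panel(pairs, pairs)
        assert le_test(panel, "LA", "LB", seed=5) < 0.001

    def test_no_shared_samples_errors(self):
        panel = ReferencePanel(
            samples=["S0", "S1"],
            populations={"S0": "P1", "S1": "P1"},
            haplotypes={"LA": {"S0": ("AA", "AA")}, "LB": {"S1": ("CC", "CC")}},
        )
        with pytest.raises(ValueError, match="shared"):
            le_test(panel, "LA", "LB")


class TestQcReport:
    def test_report_shape(self, small_panel):
        defs, panel, _ = small_panel
        df = qc_report(panel, defs, n_permutations=200, seed=0)
        assert list(df["locus_id"]) == [d.locus_id for d in defs]
        assert set(df.columns) >= {"a_e", "hwe_p", "hwe_pass_bonferroni"}
        assert ((df["a_e"] >= 1) & (df["hwe_p"] <= 1)).all()
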