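"""ICS correlation scan, exonic enrichment, MK statistics, Nei-Gojobori site
counts, binned dN/dS and shared polymorphism."""

import numpy as np
import pandas as pd
import pytest

from invrad import (
    ForwardSimConfig,
    MKTable,
    binned_dnds,
    cohort_from_mutations,
    exonic_enrichment,
    genotype_region,
    ics_scan,
    mk_test,
    ng_site_counts,
    polarize,
    rephase_by_inversion,
    shared_polymorphism_fraction,
    simulate_radiation,
    simulate_selection_forward,
)
from invrad.core_io import EFFECT_CODES, EFFECT_NAMES
from invrad.selection_stats import (
    ICSRecord,
    correlation_scan,
    permutation_pvalue,
    records_to_frame,
)
from invrad.cli import default_scenario, scenario_from_dict

from conftest import PLANTED_REGION


class TestCorrelationScan:
    def test_identity_gives_r_one_and_capped_score(self):
        g = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2, 2, 1, 0])
        X = g[:, None].astype(np.int8)
        r, score, n = correlation_scan(X, g, min_obs=10)
        assert r[0] == pytest.approx(1.0)
        assert score[0] == 300.0  # configured maximum

    def test_hand_computed_pearson_and_permutation_p(self):
        """Dosages (0,0,1,2,1,2) against genotypes (0,0,1,1,2,2): r = 0.75 by
        direct computation; the small-n permutation option agrees with the
        exhaustive enumeration of all 6! dosage orderings."""
        from itertools import permutations

        x = np.array([0, 0, 1, 2, 1, 2], dtype=np.int8)
        g = np.array([0, 0, 1, 1, 2, 2])
        r, score, n = correlation_scan(x[:, None], g, min_obs=5)
        assert r[0] == pytest.approx(0.75, abs=1e-12)
        obs = abs(np.corrcoef(x, g)[0, 1])
        hits = sum(
            abs(np.corrcoef(np.array(perm), g)[0, 1]) >= obs - 1e-12
            for perm in permutations(x)
        )
        p_exact = hits / 720
        p_perm = permutation_pvalue(x, g, n_perm=20000, seed=1)
        assert abs(p_perm - p_exact) < 3 * np.sqrt(p_exact * (1 - p_exact) / 20000) + 1e-4

    def test_monomorphic_snp_skipped(self):
        X = np.zeros((12, 1), dtype=np.int8)
        g = np.arange(12) % 3
        r, score, n = correlation_scan(X, g)
        assert np.isnan(r[0])

    def test_antisymmetric_under_polarity_flip(self):
        rng = np.random.default_rng(5)
        X = rng.integers(0, 3, size=(30, 20)).astype(np.int8)
        g = rng.integers(0, 3, size=30)
        r1, _, _ = correlation_scan(X, g)
        r2, _, _ = correlation_scan((2 - X).astype(np.int8), g)
        sel = ~np.isnan(r1)
        assert np.allclose(r1[sel], -r2[sel], atol=1e-12)


class TestIcsScan:
    def test_unpolarized_dataset_rejected(self, default_sim, inversion_call):
        ds, _, _ = default_sim
        with pytest.raises(ValueError, match="polarize"):
            ics_scan(ds, inversion_call)

    def test_planted_fixed_differences_score_as_ics(
        self, polarized_dataset, inversion_call, ingroup_samples, default_sim
    ):
        _, _, truth = default_sim
        records = ics_scan(
            polarized_dataset, inversion_call, samples=ingroup_samples, chrom="chr1"
        )
        df = records_to_frame(records)
        in_region = df[(df.pos >= PLANTED_REGION.start) & (df.pos <= PLANTED_REGION.end)]
        assert in_region.is_ics.sum() > 100
        outside = df[(df.pos < PLANTED_REGION.start) | (df.pos > PLANTED_REGION.end)]
        assert outside.is_ics.mean() < 0.01
        # sign convention: derived-on-inverted SNPs correlate positively.
        # Restrict to sites where the outgroup-based polarization matches the
        # simulated truth (ancestral = REF); ancestral-class-branch mutations
        # shared with the outgroup lineage are mispolarized by construction.
        ds, _, _ = default_sim
        sl = ds.snp_slice(PLANTED_REGION)
        cd = polarized_dataset.data["chr1"]
        correctly_polarized = dict(
            zip(cd.positions[sl].tolist(), (~cd.ancestral_is_alt[sl]).tolist())
        )
        bg = dict(zip(ds.data["chr1"].positions[sl].tolist(),
                      truth.snp_background["chr1"][sl].tolist()))
        ics = in_region[in_region.is_ics]
        signs_ok = [
            (row.r > 0) == (bg[row.pos] == "inverted")
            for row in ics.itertuples()
            if bg.get(row.pos) in ("inverted", "ancestral")
            and correctly_polarized[row.pos]
        ]
        assert len(signs_ok) > 50
        assert np.mean(signs_ok) > 0.95


class TestExonicEnrichment:
    @staticmethod
    def _records(a, b, c, d):
        recs = []
        for _ in range(a):
            recs.append(ICSRecord("c", 1, 1.0, 10, "nonsynonymous", True))
        for _ in range(b):
            recs.append(ICSRecord("c", 1, 1.0, 10, "noncoding", True))
        for _ in range(c):
            recs.append(ICSRecord("c", 1, 0.0, 0, "synonymous", False))
        for _ in range(d):
            recs.append(ICSRecord("c", 1, 0.0, 0, "noncoding", False))
        return recs

    def test_odds_ratio_arithmetic(self):
        res = exonic_enrichment(self._records(30, 70, 10, 90))
        assert res["odds_ratio"] == pytest.approx(3.857, abs=1e-3)

    def test_identical_proportions_null(self):
        res = exonic_enrichment(self._records(10, 30, 10, 30))
        assert res["odds_ratio"] == pytest.approx(1.0)
        assert res["p"] == pytest.approx(1.0)

    def test_zero_ics_rejected(self):
        with pytest.raises(ValueError, match="ICS"):
            exonic_enrichment(self._records(0, 0, 5, 5))

    def test_positive_selection_enriches_ics_for_exonic(self):
        """Forward simulation with beneficial coding variants: OR > 1."""
        cfg = ForwardSimConfig(ne=500, generations=2000, seed=2)
        muts = simulate_selection_forward(cfg)
        dos, gts, effs = cohort_from_mutations(muts, n_samples=100, seed=2)
        r, score, _ = correlation_scan(dos, gts)
        recs = [
            ICSRecord("sim", j, float(r[j]), float(score[j]),
                      EFFECT_NAMES[int(effs[j])],
                      bool(score[j] >= 7 and abs(r[j]) >= 0.9))
            for j in range(len(r))
            if not np.isnan(r[j])
        ]
        res = exonic_enrichment(recs)
        assert res["odds_ratio"] > 1
        assert res["p"] < 0.05


class TestMkTest:
    def test_neutral_identity(self):
        t = MKTable(1, 1, 1, 1)
        assert t.ni == pytest.approx(1.0)
        assert t.dos == pytest.approx(0.0)

    def test_direct_arithmetic(self):
        t = MKTable(10, 5, 2, 8)
        assert t.ni == pytest.approx(0.125)
        assert t.dos == pytest.approx(10 / 15 - 2 / 10, abs=1e-12)

    def test_zero_denominators_flagged(self):
        t = MKTable(3, 0, 2, 5)
        assert not t.ni_defined and np.isnan(t.ni)
        assert t.dos_defined  # Dn+Ds = 3 > 0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            MKTable(-1, 0, 0, 0)

    def test_counts_from_planted_phased_haplotypes(self, default_sim, phased_region):
        ds, _, _ = default_sim
        eff = ds.data["chr1"].effect[ds.snp_slice(PLANTED_REGION)]
        table = mk_test(phased_region, eff)
        n_coding = int(
            ((eff == EFFECT_CODES["synonymous"]) | (eff == EFFECT_CODES["nonsynonymous"])).sum()
        )
        # each coding site counted at most once
        assert table.dn + table.ds + table.pn + table.ps <= n_coding
        assert table.dn + table.ds > 0  # fixed class differences exist

    def test_single_class_rejected(self, phased_region):
        import dataclasses

        eff = np.full(len(phased_region.positions), EFFECT_CODES["synonymous"])
        broken = dataclasses.replace(
            phased_region,
            hap1_class=np.full(len(phased_region.sample_ids), "inverted", dtype="U9"),
            hap2_class=np.full(len(phased_region.sample_ids), "inverted", dtype="U9"),
        )
        with pytest.raises(ValueError, match="class"):
            mk_test(broken, eff)


def brute_force_site_counts(seq):
    """Independent enumeration of NG site counts via Biopython translation."""
    from Bio.Seq import Seq

    bases = "ACGT"
    l_n = l_s = 0.0
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        aa = str(Seq(codon).translate())
        if aa == "*":
            continue
        for pos in range(3):
            muts = []
            for b in bases:
                if b == codon[pos]:
                    continue
                mut = codon[:pos] + b + codon[pos + 1 :]
                mut_aa = str(Seq(mut).translate())
                if mut_aa == "*":
                    continue
                muts.append(mut_aa != aa)
            if muts:
                l_n += sum(muts) / len(muts)
                l_s += (len(muts) - sum(muts)) / len(muts)
    return l_n, l_s


class TestNgSiteCounts:
    @pytest.mark.parametrize(
        "gene",
        [
            "ATGGAA",
            "ATGAAACCCGGGTTT",
            "ATGTGGTATCATCGA",
            "ATGGCTAGCGATTAA",  # internal stop codon at the end is skipped
        ],
    )
    def test_matches_exhaustive_codon_enumeration(self, gene):
        got = ng_site_counts(gene)
        want = brute_force_site_counts(gene)
        assert got[0] == pytest.approx(want[0], abs=1e-12)
        assert got[1] == pytest.approx(want[1], abs=1e-12)

    def test_sites_sum_to_enumerated_changes(self):
        l_n, l_s = ng_site_counts("ATGGAA")
        assert l_n + l_s == pytest.approx(6.0)  # 2 codons x 3 sites (no stops)

    def test_frame_violation_rejected(self):
        with pytest.raises(ValueError):
            ng_site_counts("ATGG")


class TestBinnedDnds:
    def test_equal_counts_equal_sites_give_one(self):
        df = pd.DataFrame(
            {"r": [0.95] * 10, "effect": ["nonsynonymous"] * 5 + ["synonymous"] * 5}
        )
        bins = binned_dnds(df, site_counts=(100.0, 100.0))
        assert bins[-1].dnds == pytest.approx(1.0)

    def test_bins_partition_unit_interval(self):
        bins = binned_dnds(pd.DataFrame({"r": [], "effect": []}), site_counts=(1.0, 1.0))
        assert len(bins) == 20
        assert bins[0].lo == -1.0 and bins[-1].hi == 1.0
        for a, b in zip(bins, bins[1:]):
            assert a.hi == b.lo

    def test_r_equal_one_lands_in_top_bin(self):
        df = pd.DataFrame({"r": [1.0], "effect": ["nonsynonymous"]})
        bins = binned_dnds(df, site_counts=(1.0, 1.0))
        assert bins[-1].n_nonsyn == 1

    def test_missing_normalisation_rejected(self):
        with pytest.raises(ValueError, match="site_counts"):
            binned_dnds(pd.DataFrame({"r": [0.5], "effect": ["synonymous"]}))

    def test_site_counts_from_coding_sequences(self):
        df = pd.DataFrame({"r": [0.95, 0.95], "effect": ["nonsynonymous", "synonymous"]})
        bins = binned_dnds(df, coding_sequences=["ATGGAA"], bin_width=0.1)
        l_n, l_s = brute_force_site_counts("ATGGAA")
        assert bins[-1].dnds == pytest.approx((1 / l_n) / (1 / l_s))

    def test_neutral_bins_split_evenly_around_one(self):
        """Under strict neutrality the fraction of bins with dN/dS > 1 is
        binomially consistent with 1/2 (pooled over 5 seeds)."""
        from scipy.stats import binomtest

        above = total = 0
        for seed in range(1, 6):
            cfg = ForwardSimConfig(
                ne=500, generations=2000, s_beneficial=0.0, s_deleterious=0.0,
                f_beneficial=0.0, seed=seed,
            )
            muts = simulate_selection_forward(cfg)
            dos, gts, effs = cohort_from_mutations(muts, n_samples=100, seed=400 + seed)
            r, _, _ = correlation_scan(dos, gts)
            df = pd.DataFrame(
                {"r": r, "effect": [EFFECT_NAMES[int(e)] for e in effs]}
            ).dropna()
            for b in binned_dnds(df, site_counts=(muts.attrs["L_n"], muts.attrs["L_s"])):
                if b.defined and b.n_nonsyn + b.n_syn >= 10:
                    total += 1
                    above += b.dnds > 1
        assert binomtest(above, total, 0.5).pvalue > 0.01


class TestSharedPolymorphism:
    def _phased(self, inv_rows, anc_rows, positions):
        """Minimal phased object: one sample per haplotype row."""
        from invrad.inversion_genotyping import PhasedRegionHaplotypes
        from invrad import GenomicRegion

        rows = inv_rows + anc_rows
        n = len(rows)
        hap = np.array(rows, dtype=np.int8)
        return PhasedRegionHaplotypes(
            region=GenomicRegion("chr1", 1, int(positions[-1]) + 1),
            sample_ids=[f"s{i}" for i in range(n)],
            genotypes=np.array([2] * len(inv_rows) + [0] * len(anc_rows)),
            positions=np.asarray(positions),
            hap1=hap,
            hap2=hap,
            hap1_class=np.array(
                ["inverted"] * len(inv_rows) + ["ancestral"] * len(anc_rows), dtype="U9"
            ),
            hap2_class=np.array(
                ["inverted"] * len(inv_rows) + ["ancestral"] * len(anc_rows), dtype="U9"
            ),
        )

    def _records(self, positions, rs):
        return [
            ICSRecord("chr1", int(p), float(r), 50.0, "noncoding", True)
            for p, r in zip(positions, rs)
        ]

    def test_all_fixed_differences_give_zero(self):
        ph = self._phased([[1, 1]], [[0, 0]], [10, 20])
        recs = self._records([10, 20], [1.0, 1.0])
        assert shared_polymorphism_fraction(ph, recs, ics_score=7, ics_r=0.9) == 0.0

    def test_single_shared_ics_gives_one(self):
        ph = self._phased([[1], [0]], [[1], [0]], [10])
        recs = self._records([10], [0.95])
        assert shared_polymorphism_fraction(ph, recs, ics_score=7, ics_r=0.9) == 1.0

    def test_zero_ics_rejected(self):
        ph = self._phased([[1]], [[0]], [10])
        with pytest.raises(ValueError, match="ICS"):
            shared_polymorphism_fraction(ph, [], ics_score=7, ics_r=0.9)

    def test_gene_flux_increases_sharing(self):
        """Paired runs: pooled shared-ICS count strictly larger with gene flux
        than without (same seeds)."""

        def shared_count(flux, seed):
            d = default_scenario(seed)
            d["inversions"][0]["gene_flux"] = flux
            ds, meta, _ = simulate_radiation(scenario_from_dict(d))
            outg = meta.samples_for("clade", "outgroup")
            call = genotype_region(ds, PLANTED_REGION, outgroup_samples=outg, seed=1)
            pol = polarize(ds, outg)
            ing = [s for s in ds.sample_ids if s not in outg]
            recs = ics_scan(pol, call, samples=ing, chrom="chr1", ics_r=0.8)
            ph = rephase_by_inversion(ds, PLANTED_REGION, call)
            n_ics = sum(1 for r in recs if r.is_ics)
            frac = shared_polymorphism_fraction(ph, recs, ics_r=0.8)
            return frac * n_ics

        seeds = (4, 7, 9)
        without = sum(shared_count(0.0, s) for s in seeds)
        with_flux = sum(shared_count(5e-5, s) for s in seeds)
        assert with_flux > without
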