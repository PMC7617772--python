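"""Inversion genotyping, region heterozygosity, rephasing, carrier-haplotype
extraction and pedigree crossover counting."""

import numpy as np
import pytest

from invrad import (
    GenomicRegion,
    count_crossovers,
    extract_carrier_haplotype,
    genotype_region,
    region_heterozygosity,
    rephase_by_inversion,
    simulate_radiation,
)
from invrad.core_io import MISSING, UNASSIGNED
from invrad.cli import default_scenario, scenario_from_dict

from conftest import CROSS_REGION, PLANTED_REGION
from test_core_io import make_dataset


class TestGenotypeRegion:
    def test_planted_genotypes_recovered(self, default_sim, inversion_call):
        """>= 59/60 correct assignments with correct polarity on planted truth."""
        _, _, truth = default_sim
        tg = truth.inversion_genotypes.iloc[:, 0].to_numpy()
        correct = int((inversion_call.genotypes == tg).sum())
        assert correct >= 59
        assert inversion_call.valid and inversion_call.k == 3

    def test_identical_homozygous_samples_single_cluster(self):
        G = np.zeros((6, 60), dtype=np.int8)
        ds = make_dataset(G)
        call = genotype_region(ds, GenomicRegion("chr1", 1, 6100), seed=0)
        assert call.k == 1
        assert (call.genotypes == 0).all()
        assert np.allclose(call.het_per_10kb, 0.0)

    def test_chr9_like_two_cluster_configuration(self):
        """Only heterozygous and homozygous-inverted classes present:
        k = 2 selected, no genotype-0 in the ingroup."""
        d = default_scenario(5)
        d["inversions"][0]["sex_linked"] = True  # males 1, females 2
        ds, meta, truth = simulate_radiation(scenario_from_dict(d))
        outg = meta.samples_for("clade", "outgroup")
        call = genotype_region(ds, PLANTED_REGION, outgroup_samples=outg, seed=1)
        assert call.k == 2
        ingroup = [s for s in ds.sample_ids if s not in outg]
        gts = np.array([call.genotype_of(s) for s in ingroup])
        assert set(gts) <= {1, 2}
        tg = truth.inversion_genotypes.loc[ingroup].iloc[:, 0].to_numpy()
        assert (gts == tg).mean() >= 0.98

    def test_label_stability_under_sample_permutation(self, default_sim, outgroup_samples, inversion_call):
        ds, _, _ = default_sim
        from invrad.core_io import ChromosomeData, GenotypeDataset

        rng = np.random.default_rng(7)
        order = rng.permutation(ds.n_samples)
        cd = ds.data["chr1"]
        permuted = GenotypeDataset(
            [ds.sample_ids[i] for i in order],
            ds.chrom_lengths,
            {"chr1": ChromosomeData(cd.positions, cd.dosages[order], cd.ref, cd.alt,
                                    cd.ancestral_known, cd.ancestral_is_alt, cd.effect)},
        )
        call_p = genotype_region(
            permuted, PLANTED_REGION, outgroup_samples=outgroup_samples, seed=1
        )
        for s in ds.sample_ids:
            assert call_p.genotype_of(s) == inversion_call.genotype_of(s)

    def test_too_few_snps_rejected(self):
        ds = make_dataset(np.zeros((4, 10), dtype=np.int8))
        with pytest.raises(ValueError, match="SNPs"):
            genotype_region(ds, GenomicRegion("chr1", 1, 1100), seed=0)


class TestRegionHeterozygosity:
    def test_zero_het_snps(self):
        ds = make_dataset(np.zeros((2, 5), dtype=np.int8))
        assert region_heterozygosity(ds, GenomicRegion("chr1", 1, 600), "s0") == 0.0

    def test_arithmetic(self):
        """500 het SNPs in a 1 Mbp region -> 5.0 per 10 kbp."""
        G = np.ones((1, 500), dtype=np.int8)
        pos = np.linspace(1, 999_999, 500).astype(np.int64)
        ds = make_dataset(G, positions=pos)
        ds.chrom_lengths["chr1"] = 1_000_000
        val = region_heterozygosity(ds, GenomicRegion("chr1", 1, 1_000_000), "s0")
        assert val == pytest.approx(5.0)

    def test_all_missing_sample_unassigned(self):
        G = np.array([[MISSING, MISSING], [1, 1]], dtype=np.int8)
        ds = make_dataset(G)
        assert region_heterozygosity(ds, GenomicRegion("chr1", 1, 300), "s0") == UNASSIGNED

    def test_heterokaryotype_exceeds_homokaryotype(self, default_sim, inversion_call):
        het = inversion_call.het_per_10kb
        g = inversion_call.genotypes
        assert het[g == 1].mean() > het[g == 0].max()
        assert het[g == 1].mean() > het[g == 2].max()

    def test_heterozygosity_ordering_invariant(self, inversion_call):
        """Mean region heterozygosity is maximal for genotype 1."""
        het, g = inversion_call.het_per_10kb, inversion_call.genotypes
        assert het[g == 1].mean() > het[g == 0].mean() > 0 or het[g == 0].mean() == 0
        assert het[g == 1].mean() > het[g == 2].mean()


class TestRephase:
    def test_consensus_rule_and_hom_sites(self):
        # samples: s0,s1 genotype 2 (inverted, fixed ALT at SNP0, REF at SNP1);
        # s2,s3 genotype 0; s4 heterokaryotype
        G = np.array(
            [
                [2, 0, 2],
                [2, 0, 2],
                [0, 0, 0],
                [0, 0, 0],
                [1, 2, 1],
            ],
            dtype=np.int8,
        )
        ds = make_dataset(G)
        from invrad.inversion_genotyping import InversionCall

        call = InversionCall(
            region=GenomicRegion("chr1", 1, 400),
            sample_ids=ds.sample_ids,
            genotypes=np.array([2, 2, 0, 0, 1]),
            confidence=np.ones(5),
            het_per_10kb=np.zeros(5),
        )
        ph = rephase_by_inversion(ds, call.region, call)
        # het sample, SNP0: inverted consensus ALT -> inverted hap gets ALT
        assert ph.hap_inverted[4, 0] == 1 and ph.hap_ancestral[4, 0] == 0
        # het sample, SNP1 is homozygous ALT in the sample itself
        assert ph.hap_inverted[4, 1] == 1 and ph.hap_ancestral[4, 1] == 1
        # genotype-1 samples carry exactly one haplotype of each label
        assert ph.hap1_class[4] == "inverted" and ph.hap2_class[4] == "ancestral"

    def test_haplotype_pair_sums_to_dosage(self, default_sim, phased_region):
        ds, _, _ = default_sim
        G = ds.dosages("chr1", region=PLANTED_REGION)
        ok = (phased_region.hap1 != UNASSIGNED) & (phased_region.hap2 != UNASSIGNED) & (G != MISSING)
        assert np.array_equal((phased_region.hap1 + phased_region.hap2)[ok], G[ok])

    def test_planted_het_assignments_match_truth(self, default_sim, inversion_call, phased_region):
        """>= 95% of het-site assignments match the true haplotype class at
        sites with class-consensus frequency >= 0.9."""
        ds, _, truth = default_sim
        sl = ds.snp_slice(PLANTED_REGION)
        bg = truth.snp_background["chr1"][sl]
        G = ds.dosages("chr1", region=PLANTED_REGION)
        # class-consensus frequency among homozygous-inverted samples
        g2 = G[inversion_call.genotypes == 2].astype(float)
        f_alt = g2.sum(axis=0) / (2 * g2.shape[0])
        strong = (f_alt >= 0.9) | (f_alt <= 0.1)
        correct = total = 0
        for i in np.where(inversion_call.genotypes == 1)[0]:
            for j in np.where((G[i] == 1) & strong)[0]:
                if bg[j] == "both" or phased_region.hap_inverted[i, j] == UNASSIGNED:
                    continue
                total += 1
                want = 1 if bg[j] == "inverted" else 0
                correct += int(phased_region.hap_inverted[i, j] == want)
        assert total > 100
        assert correct / total >= 0.95

    def test_missing_consensus_class_rejected(self):
        G = np.array([[1, 1]], dtype=np.int8)
        ds = make_dataset(G)
        from invrad.inversion_genotyping import InversionCall

        call = InversionCall(
            region=GenomicRegion("chr1", 1, 300),
            sample_ids=ds.sample_ids,
            genotypes=np.array([1]),
            confidence=np.ones(1),
            het_per_10kb=np.zeros(1),
        )
        with pytest.raises(ValueError, match="consensus"):
            rephase_by_inversion(ds, call.region, call)


class TestExtractCarrierHaplotype:
    def _call(self, ds, genotypes):
        from invrad.inversion_genotyping import InversionCall

        return InversionCall(
            region=GenomicRegion("chr1", 1, 100 * ds.data["chr1"].n_snps + 100),
            sample_ids=ds.sample_ids,
            genotypes=np.asarray(genotypes),
            confidence=np.ones(len(genotypes)),
            het_per_10kb=np.zeros(len(genotypes)),
        )

    def test_single_carrier_subtraction(self):
        # inverted class fixed ALT; carrier het -> carrier haplotype is REF
        G = np.array([[2], [2], [1]], dtype=np.int8)
        ds = make_dataset(G)
        hap, support, _ = extract_carrier_haplotype(ds, self._call(ds, [2, 2, 1]).region, self._call(ds, [2, 2, 1]))
        assert hap[0] == 0
        assert support[0] == 1.0

    def test_disagreeing_carriers_flagged(self):
        # two carriers: one het (-> REF), one hom ALT (-> ALT): support 0.5
        G = np.array([[2], [2], [1], [2]], dtype=np.int8)
        ds = make_dataset(G)
        call = self._call(ds, [2, 2, 1, 1])
        hap, support, _ = extract_carrier_haplotype(ds, call.region, call)
        assert support[0] == 0.5

    def test_no_heterozygotes_rejected(self):
        G = np.array([[2], [2]], dtype=np.int8)
        ds = make_dataset(G)
        call = self._call(ds, [2, 2])
        with pytest.raises(ValueError, match="het"):
            extract_carrier_haplotype(ds, call.region, call)

    def test_introgressed_carrier_haplotype_nearest_to_donor(self):
        """chr9-like configuration: the extracted ancestral haplotype is
        closer to the donor-clade consensus than to recipient haplotypes."""
        d = {
            "clades": [
                {"name": "recipient", "n": 20, "ne": 5000},
                {"name": "donor", "n": 10, "ne": 5000},
            ],
            "splits": [
                {"time": 40000, "derived": ["recipient", "donor"],
                 "ancestral": "root", "ne": 5000}
            ],
            "chromosomes": [{"name": "chr1", "length": 3_000_000}],
            "inversions": [
                {"chrom": "chr1", "start": 500_001, "end": 2_500_000,
                 "origin_time": 60000,
                 "freqs": {"recipient": 0.85, "donor": 0.0}}
            ],
            "seed": 3,
        }
        ds, meta, truth = simulate_radiation(scenario_from_dict(d))
        region = GenomicRegion("chr1", 500_001, 2_500_000)
        rec = meta.samples_for("clade", "recipient")
        tg = truth.inversion_genotypes.loc[rec].iloc[:, 0]
        from invrad.inversion_genotyping import InversionCall

        genotypes = np.array(
            [truth.inversion_genotypes.loc[s].iloc[0] for s in ds.sample_ids]
        )
        call = InversionCall(
            region=region, sample_ids=ds.sample_ids, genotypes=genotypes,
            confidence=np.ones(ds.n_samples), het_per_10kb=np.zeros(ds.n_samples),
        )
        assert (tg == 1).any() and (tg == 2).any()
        hap, support, pos = extract_carrier_haplotype(ds, region, call)
        G = ds.dosages("chr1", region=region).astype(float)
        donor = ds.sample_indices(meta.samples_for("clade", "donor"))
        rec2 = ds.sample_indices([s for s in rec if truth.inversion_genotypes.loc[s].iloc[0] == 2])
        ok = hap != UNASSIGNED
        donor_cons = (G[donor].mean(axis=0) / 2 > 0.5).astype(int)
        rec_cons = (G[rec2].mean(axis=0) / 2 > 0.5).astype(int)
        d_donor = np.mean(hap[ok] != donor_cons[ok])
        d_rec = np.mean(hap[ok] != rec_cons[ok])
        assert d_donor < d_rec


class TestCountCrossovers:
    def _track_from_states(self, states):
        regions = [
            GenomicRegion("chr1", i * 100_000 + 1, (i + 1) * 100_000)
            for i in range(len(states))
        ]
        return np.array(states, dtype=float)[:, None], regions

    def test_full_suppression_gives_zero_in_region(self, cross_sim):
        from invrad.region_detection import WindowSpec, windowed_pc1_track

        ds, meta, _ = cross_sim
        regions, track = windowed_pc1_track(ds, WindowSpec(500_000, 500_000, 10))
        names = ds.sample_ids
        centres = np.array(
            [
                np.nanmean(track[:, names.index("founderA")]),
                np.nanmean(track[:, names.index("F1_0")]),
                np.nanmean(track[:, names.index("founderB")]),
            ]
        )
        inside, outside, flagged = count_crossovers(track, regions, CROSS_REGION, centres)
        prog = [i for i, n in enumerate(names) if n.startswith(("F2", "F3"))]
        assert np.nansum(inside[prog]) == 0
        assert np.nansum(outside[prog]) > 0
        assert not flagged[prog].any()

    def test_planted_single_crossover_found_at_boundary(self):
        track, regions = self._track_from_states([0, 0, 0, 0, 1, 1, 1, 1])
        region = GenomicRegion("chr1", 1, 200_000)
        inside, outside, _ = count_crossovers(track, regions, region, np.array([0.0, 1.0, 2.0]))
        assert outside[0] == 1 and inside[0] == 0

    def test_constant_state_individual_zero_everywhere(self):
        track, regions = self._track_from_states([1] * 8)
        inside, outside, _ = count_crossovers(
            track, regions, GenomicRegion("chr1", 1, 200_000), np.array([0.0, 1.0, 2.0])
        )
        assert inside[0] == 0 and outside[0] == 0

    def test_single_window_island_smoothed(self):
        track, regions = self._track_from_states([0, 0, 0, 1, 0, 0, 0, 0])
        inside, outside, _ = count_crossovers(
            track, regions, GenomicRegion("chr1", 1, 100), np.array([0.0, 1.0, 2.0])
        )
        assert outside[0] == 0

    def test_unassignable_individual_flagged(self):
        track = np.full((8, 1), np.nan)
        track[:3, 0] = 0.0
        regions = [
            GenomicRegion("chr1", i * 100_000 + 1, (i + 1) * 100_000) for i in range(8)
        ]
        inside, outside, flagged = count_crossovers(
            track, regions, GenomicRegion("chr1", 1, 100), np.array([0.0, 1.0, 2.0])
        )
        assert flagged[0]
        assert np.isnan(inside[0])


def test_haplotype_fasta_export(phased_region, tmp_path):
    from invrad.inversion_genotyping import write_haplotypes_fasta

    path = tmp_path / "haps.fasta"
    write_haplotypes_fasta(phased_region, path)
    lines = path.read_text().splitlines()
    assert lines[0].startswith(">") and "|" in lines[0]
    n_sites = len(phased_region.positions)
    assert all(len(l) == n_sites for l in lines[1::2])
    assert set("".join(lines[1::2])) <= {"0", "1", "N"}
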