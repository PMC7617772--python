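"""Per-sample inversion genotyping, rephasing and pedigree crossover counting.

Genotypes within a called inversion region follow from the characteristic
karyotype geometry: principal-component projection of the region dosage
matrix separates samples into two or three clusters (homozygous ancestral /
heterozygous / homozygous inverted), with the heterozygous cluster showing
elevated SNP heterozygosity and the ancestral cluster lying nearest the
outgroup projection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core_io import MISSING, UNASSIGNED, GenomicRegion, GenotypeDataset

logger = logging.getLogger(__name__)


@dataclass
class InversionCall:
    """Per-sample inversion genotypes for one region.

    ``genotypes``: 0 homozygous ancestral, 1 heterozygous, 2 homozygous
    inverted, UNASSIGNED for low-confidence samples. ``confidence`` is
    1 - (distance to nearest cluster centre / distance to second nearest).
    ``het_per_10kb`` is region heterozygosity (het SNPs per 10 kbp).
    """

    region: GenomicRegion
    sample_ids: list[str]
    genotypes: np.ndarray  # int, {0,1,2,UNASSIGNED}
    confidence: np.ndarray
    het_per_10kb: np.ndarray
    polarity_source: list[str] = field(default_factory=list)
    valid: bool = True
    k: int = 0
    pc1: np.ndarray | None = None

    def genotype_of(self, sample: str) -> int:
        return int(self.genotypes[self.sample_ids.index(sample)])

    def samples_with(self, genotype: int) -> list[str]:
        return [s for s, g in zip(self.sample_ids, self.genotypes) if g == genotype]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "sample": self.sample_ids,
                "region": f"{self.region.chrom}:{self.region.start}-{self.region.end}",
                "genotype": self.genotypes,
                "confidence": self.confidence,
                "het_per_10kb": self.het_per_10kb,
            }
        )


@dataclass
class PhasedRegionHaplotypes:
    """Region haplotypes split by orientation class.

    Each sample carries two allele vectors ``hap1`` / ``hap2`` (0/1 = ALT
    count per copy, UNASSIGNED where the allele could not be assigned) with
    per-copy orientation labels in ``hap1_class`` / ``hap2_class``
    ("inverted" / "ancestral"; empty for unassigned genotypes).
    Heterokaryotypes carry one copy of each class (``hap1`` inverted by
    convention); homokaryotypes carry two copies of their class, so a
    heterozygous site inside a homokaryotype contributes both alleles to
    that class. At every non-missing assigned site the pair sums to the
    sample's dosage.
    """

    region: GenomicRegion
    sample_ids: list[str]
    genotypes: np.ndarray
    positions: np.ndarray
    hap1: np.ndarray  # samples x snps, int8
    hap2: np.ndarray
    hap1_class: np.ndarray  # per sample, "inverted"/"ancestral"/""
    hap2_class: np.ndarray

    @property
    def hap_inverted(self) -> np.ndarray:
        """Inverted-class copy per sample (hap1 where labelled inverted)."""
        out = np.full_like(self.hap1, UNASSIGNED)
        sel1 = self.hap1_class == "inverted"
        sel2 = self.hap2_class == "inverted"
        out[sel1] = self.hap1[sel1]
        out[sel2 & ~sel1] = self.hap2[sel2 & ~sel1]
        return out

    @property
    def hap_ancestral(self) -> np.ndarray:
        out = np.full_like(self.hap1, UNASSIGNED)
        sel2 = self.hap2_class == "ancestral"
        sel1 = self.hap1_class == "ancestral"
        out[sel2] = self.hap2[sel2]
        out[sel1 & ~sel2] = self.hap1[sel1 & ~sel2]
        return out

    def class_haplotypes(self, label: str) -> np.ndarray:
        """All copies of one orientation class, stacked (haplotypes x SNPs)."""
        if label not in ("inverted", "ancestral"):
            raise ValueError(label)
        rows = []
        for i in range(len(self.sample_ids)):
            if self.hap1_class[i] == label:
                rows.append(self.hap1[i])
            if self.hap2_class[i] == label:
                rows.append(self.hap2[i])
        if not rows:
            return np.empty((0, len(self.positions)), dtype=np.int8)
        return np.array(rows, dtype=np.int8)


# -- heterozygosity -----------------------------------------------------------


def region_heterozygosity(
    dataset: GenotypeDataset, region: GenomicRegion, sample: str | None = None
):
    """Het SNPs per 10 kbp of region length (per sample, or vector for all)."""
    if region.length <= 0:
        raise ValueError("region length must be positive")
    G = dataset.dosages(region.chrom, region=region)
    idx = (
        dataset.sample_indices([sample])
        if sample is not None
        else np.arange(dataset.n_samples)
    )
    G = G[idx]
    het = (G == 1).sum(axis=1).astype(float)
    all_missing = (G == MISSING).all(axis=1) & (G.shape[1] > 0)
    out = het / region.length * 10_000
    out[all_missing] = UNASSIGNED
    return float(out[0]) if sample is not None else out


# -- genotyping ---------------------------------------------------------------


def _kmeans_1d(x: np.ndarray, k: int, seed: int):
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(x.reshape(-1, 1))
    centres = km.cluster_centers_.ravel()
    return labels, centres, km.inertia_


def _choose_k(x: np.ndarray, seed: int):
    """Choose k in {2,3} by the larger relative within-dispersion improvement.

    imp(k) = (W_{k-1} - W_k) / W_{k-1}; pick k = 3 iff imp(3) > imp(2).
    Degenerate inputs (fewer than 3 distinct values) fall back to the number
    of distinct values.
    """
    distinct = len(np.unique(x))
    if distinct == 1:
        return 1
    if distinct == 2:
        return 2
    w1 = float(np.sum((x - x.mean()) ** 2))
    _, _, w2 = _kmeans_1d(x, 2, seed)
    _, _, w3 = _kmeans_1d(x, 3, seed)
    if w1 <= 0:
        return 2
    imp2 = (w1 - w2) / w1
    imp3 = (w2 - w3) / w2 if w2 > 0 else 0.0
    return 3 if imp3 > imp2 else 2


def genotype_region(
    dataset: GenotypeDataset,
    region: GenomicRegion,
    outgroup_samples=None,
    reference_panel=None,
    seed: int = 0,
    min_confidence: float = 0.2,
    min_snps: int = 50,
) -> InversionCall:
    """Infer per-sample inversion genotypes in ``region``.

    Steps: (1) PCA (PC1) of region dosages fitted on the reference panel
    (default: all ingroup samples, i.e. everything except the outgroups);
    (2) 1-D k-means on panel PC1 with k chosen from {2,3} by the larger
    relative dispersion improvement; (3) non-panel samples projected onto
    PC1 and assigned to the nearest centre; (4) clusters mapped to genotypes:
    with k=3 the middle cluster is heterozygous and the end cluster nearest
    the outgroup projection is 0; with k=2 the higher-heterozygosity cluster
    is 1 and the other is 0 or 2 by outgroup polarity. If the middle cluster
    is not the most heterozygous the call is returned with ``valid=False``.
    Without outgroups, polarity is unresolved and genotypes are reported up
    to a label swap (``polarity_source`` empty).
    """
    if dataset.n_samples < 3:
        raise ValueError("need at least 3 samples")
    G_all = dataset.dosages(region.chrom, region=region).astype(np.float64)
    if G_all.shape[1] < min_snps:
        raise ValueError(
            f"region has {G_all.shape[1]} SNPs; needs >= {min_snps}"
        )
    outgroup_samples = list(outgroup_samples or [])
    out_idx = dataset.sample_indices(outgroup_samples) if outgroup_samples else np.empty(0, dtype=np.intp)
    if reference_panel is None:
        panel_idx = np.setdiff1d(np.arange(dataset.n_samples), out_idx)
    else:
        panel_idx = dataset.sample_indices(reference_panel)

    # mean-impute missing, centre on panel means
    X = G_all.copy()
    X[X == MISSING] = np.nan
    col_mean = np.nanmean(X[panel_idx], axis=0)
    col_mean = np.nan_to_num(col_mean, nan=0.0)
    inds = np.where(np.isnan(X))
    X[inds] = col_mean[inds[1]]
    Xc = X - col_mean

    # PC1 fitted on the panel, all samples projected
    u, s, vt = np.linalg.svd(Xc[panel_idx], full_matrices=False)
    axis = vt[0]
    pc1 = Xc @ axis

    k = _choose_k(pc1[panel_idx], seed)
    if k == 1:
        centres = np.array([float(pc1[panel_idx].mean())])
        labels_all = np.zeros(dataset.n_samples, dtype=int)
    else:
        _, centres, _ = _kmeans_1d(pc1[panel_idx], k, seed)
        centres = np.sort(centres)
        labels_all = np.argmin(np.abs(pc1[:, None] - centres[None, :]), axis=1)

    het = region_heterozygosity(dataset, region)

    # confidence from centre distances
    if len(centres) >= 2:
        d = np.abs(pc1[:, None] - centres[None, :])
        d.sort(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            confidence = 1.0 - d[:, 0] / d[:, 1]
        confidence = np.nan_to_num(confidence, nan=1.0)
    else:
        confidence = np.ones(dataset.n_samples)

    ingroup = np.setdiff1d(np.arange(dataset.n_samples), out_idx)

    def mean_het(cluster):
        members = ingroup[labels_all[ingroup] == cluster]
        return float(het[members].mean()) if len(members) else -np.inf

    valid = True
    out_pc1 = float(pc1[out_idx].mean()) if len(out_idx) else None

    if k == 1:
        genotype_of_cluster = {0: 0}
    elif k == 3:
        genotype_of_cluster = {1: 1}
        hets_by_cluster = [mean_het(c) for c in range(3)]
        if np.argmax(hets_by_cluster) != 1:
            valid = False
        if out_pc1 is not None:
            low_is_ancestral = abs(out_pc1 - centres[0]) <= abs(out_pc1 - centres[2])
        else:
            low_is_ancestral = True
        genotype_of_cluster[0] = 0 if low_is_ancestral else 2
        genotype_of_cluster[2] = 2 if low_is_ancestral else 0
    else:  # k == 2
        het_cluster = int(np.argmax([mean_het(0), mean_het(1)]))
        other = 1 - het_cluster
        if out_pc1 is not None:
            # other cluster is ancestral (0) iff it is nearer the outgroup
            # projection than the heterozygous cluster is
            other_gt = (
                0
                if abs(out_pc1 - centres[other]) < abs(out_pc1 - centres[het_cluster])
                else 2
            )
        else:
            other_gt = 0
        genotype_of_cluster = {het_cluster: 1, other: other_gt}

    genotypes = np.array(
        [genotype_of_cluster[int(l)] for l in labels_all], dtype=int
    )
    genotypes[confidence < min_confidence] = UNASSIGNED
    if len(out_idx):
        genotypes[out_idx] = 0  # outgroups carry the ancestral orientation

    return InversionCall(
        region=region,
        sample_ids=list(dataset.sample_ids),
        genotypes=genotypes,
        confidence=confidence,
        het_per_10kb=het,
        polarity_source=outgroup_samples,
        valid=valid,
        k=k,
        pc1=pc1,
    )


# -- rephasing ----------------------------------------------------------------


def _class_consensus(H: np.ndarray) -> np.ndarray:
    """Majority ALT allele per site over haplotypes; UNASSIGNED on ties/empty."""
    if H.shape[0] == 0:
        return np.full(H.shape[1], UNASSIGNED, dtype=np.int8)
    valid = (H != MISSING) & (H != UNASSIGNED)
    alt = np.where(valid, H, 0).sum(axis=0)
    n = valid.sum(axis=0)
    cons = np.full(H.shape[1], UNASSIGNED, dtype=np.int8)
    cons[2 * alt > n] = 1
    cons[2 * alt < n] = 0
    cons[n == 0] = UNASSIGNED
    return cons


def _dosage_consensus(G_class: np.ndarray) -> np.ndarray:
    """Majority allele per site from class-member dosages (allele counting)."""
    if G_class.shape[0] == 0:
        return np.full(G_class.shape[1], UNASSIGNED, dtype=np.int8)
    valid = G_class != MISSING
    alt_copies = np.where(valid, G_class, 0).sum(axis=0)
    total = 2 * valid.sum(axis=0)
    cons = np.full(G_class.shape[1], UNASSIGNED, dtype=np.int8)
    cons[2 * alt_copies > total] = 1
    cons[(2 * alt_copies < total) & (total > 0)] = 0
    return cons


def rephase_by_inversion(
    dataset: GenotypeDataset, region: GenomicRegion, call: InversionCall
) -> PhasedRegionHaplotypes:
    """Phase region heterozygous SNPs using known inversion genotypes.

    Homozygotes contribute two identical haplotypes of their class. At each
    heterozygous site of a genotype-1 sample, the allele matching the
    inverted-class consensus (majority allele among homozygous-inverted
    samples, or derived by subtraction from heterozygotes when a homozygote
    class is absent) goes to the inverted haplotype; ties leave the site
    UNASSIGNED.
    """
    if not call.valid:
        raise ValueError("cannot rephase from an invalid inversion call")
    G = dataset.dosages(region.chrom, region=region)
    gt = call.genotypes
    n_het = int((gt == 1).sum())

    have_inv = (gt == 2).any()
    have_anc = (gt == 0).any()
    if not have_inv and not have_anc:
        raise ValueError("no consensus source for either haplotype class")
    if not have_inv and n_het < 2:
        raise ValueError("no consensus source for class 'inverted'")
    if not have_anc and n_het < 2:
        raise ValueError("no consensus source for class 'ancestral'")

    if have_inv:
        cons_inv = _dosage_consensus(G[gt == 2])
        if have_anc:
            cons_anc = _dosage_consensus(G[gt == 0])
        else:
            # subtract the inverted consensus from heterozygote dosages
            cons_anc = _class_consensus(_het_subtraction(G[gt == 1], cons_inv))
    else:
        cons_anc = _dosage_consensus(G[gt == 0])
        cons_inv = _class_consensus(_het_subtraction(G[gt == 1], cons_anc))

    n_samples, n_snps = G.shape
    hap1 = np.full((n_samples, n_snps), UNASSIGNED, dtype=np.int8)
    hap2 = np.full((n_samples, n_snps), UNASSIGNED, dtype=np.int8)
    class1 = np.full(n_samples, "", dtype="U9")
    class2 = np.full(n_samples, "", dtype="U9")
    for i in range(n_samples):
        g, row = gt[i], G[i]
        if g not in (0, 1, 2):
            continue
        hom_site = (row == 0) | (row == 2)
        het_site = row == 1
        hap1[i, hom_site] = row[hom_site] // 2
        hap2[i, hom_site] = row[hom_site] // 2
        if g == 1:
            class1[i], class2[i] = "inverted", "ancestral"
            use = het_site & (cons_inv != UNASSIGNED)
            hap1[i, use] = cons_inv[use]
            hap2[i, use] = 1 - cons_inv[use]
        else:
            # both copies share the class; a het site is class-resolved even
            # though the copies themselves cannot be ordered
            class1[i] = class2[i] = "inverted" if g == 2 else "ancestral"
            hap1[i, het_site] = 0
            hap2[i, het_site] = 1

    positions = dataset.data[region.chrom].positions[dataset.snp_slice(region)]
    return PhasedRegionHaplotypes(
        region=region,
        sample_ids=list(call.sample_ids),
        genotypes=gt.copy(),
        positions=positions.copy(),
        hap1=hap1,
        hap2=hap2,
        hap1_class=class1,
        hap2_class=class2,
    )


def _het_subtraction(G_het: np.ndarray, cons_known: np.ndarray) -> np.ndarray:
    """Other-class haplotype alleles of heterozygotes, by consensus subtraction."""
    out = np.full_like(G_het, UNASSIGNED)
    hom = (G_het == 0) | (G_het == 2)
    out[hom] = G_het[hom] // 2
    het = G_het == 1
    known = cons_known != UNASSIGNED
    for i in range(G_het.shape[0]):
        use = het[i] & known
        out[i, use] = 1 - cons_known[use]
    return out.astype(np.int8)


def extract_carrier_haplotype(
    dataset: GenotypeDataset, region: GenomicRegion, call: InversionCall
):
    """Consensus ancestral-orientation haplotype carried only by heterozygotes.

    For configurations where the ancestral orientation exists only in
    heterozygous state: per SNP, each het carrier's ancestral allele is its
    non-inverted-consensus allele; the returned haplotype is the majority
    over carriers, with per-site support = fraction of carriers consistent
    with the call. Returns ``(haplotype, support, positions)``.
    """
    gt = call.genotypes
    if not (gt == 1).any():
        raise ValueError("no heterozygous carriers in region")
    if not (gt == 2).any():
        raise ValueError("no homozygous-inverted samples to derive the consensus")
    G = dataset.dosages(region.chrom, region=region)
    cons_inv = _dosage_consensus(G[gt == 2])
    carriers = _het_subtraction(G[gt == 1], cons_inv)

    valid = carriers != UNASSIGNED
    alt = np.where(valid, carriers, 0).sum(axis=0)
    n = valid.sum(axis=0)
    hap = np.full(G.shape[1], UNASSIGNED, dtype=np.int8)
    hap[n > 0] = (2 * alt[n > 0] >= n[n > 0]).astype(np.int8)
    with np.errstate(invalid="ignore", divide="ignore"):
        agree = np.where(hap == 1, alt, n - alt)
        support = np.where(n > 0, agree / np.maximum(n, 1), 0.0)
    positions = dataset.data[region.chrom].positions[dataset.snp_slice(region)]
    return hap, support, positions


# -- pedigree crossover counting ----------------------------------------------


def count_crossovers(
    track: np.ndarray,
    window_regions,
    region: GenomicRegion,
    state_centres: np.ndarray,
    min_island: int = 2,
    max_unassigned: float = 0.2,
):
    """Count genotype-state switches along windowed PC1 tracks.

    ``track`` is windows x individuals PC1 values; ``state_centres`` the PC1
    centroids of the three founder/F1 states. Each window is assigned to the
    nearest centroid; single-window state islands shorter than ``min_island``
    are smoothed out; a crossover is a change of state between consecutive
    windows. Returns ``(inside_counts, outside_counts, flagged)`` per
    individual; individuals with > ``max_unassigned`` unassignable windows
    are flagged and excluded from counts (NaN).
    """
    track = np.asarray(track, dtype=float)
    n_windows, n_ind = track.shape
    centres = np.asarray(state_centres, dtype=float)
    in_region = np.array(
        [
            r.chrom == region.chrom
            and r.start <= (r.start + r.end) // 2 <= region.end
            and not (r.end < region.start or r.start > region.end)
            for r in window_regions
        ]
    )
    inside = np.zeros(n_ind)
    outside = np.zeros(n_ind)
    flagged = np.zeros(n_ind, dtype=bool)
    for j in range(n_ind):
        x = track[:, j]
        unassigned = np.isnan(x)
        if unassigned.mean() > max_unassigned:
            flagged[j] = True
            inside[j] = outside[j] = np.nan
            continue
        states = np.argmin(np.abs(x[:, None] - centres[None, :]), axis=1).astype(float)
        states[unassigned] = np.nan
        states = _smooth_islands(states, min_island)
        prev_state, prev_idx = None, None
        for i in range(n_windows):
            if np.isnan(states[i]):
                continue
            if prev_state is not None and states[i] != prev_state:
                # attribute the crossover to the boundary between windows
                if in_region[i] and in_region[prev_idx]:
                    inside[j] += abs(states[i] - prev_state)
                else:
                    outside[j] += abs(states[i] - prev_state)
            prev_state, prev_idx = states[i], i
    return inside, outside, flagged


def _smooth_islands(states: np.ndarray, min_island: int) -> np.ndarray:
    """Remove runs shorter than ``min_island`` bounded by a common state."""
    s = states.copy()
    n = len(s)
    i = 0
    while i < n:
        if np.isnan(s[i]):
            i += 1
            continue
        j = i
        while j + 1 < n and s[j + 1] == s[i]:
            j += 1
        run_len = j - i + 1
        left = s[i - 1] if i > 0 and not np.isnan(s[i - 1]) else None
        right = s[j + 1] if j + 1 < n and not np.isnan(s[j + 1]) else None
        if run_len < min_island and left is not None and right is not None and left == right:
            s[i : j + 1] = left
        i = j + 1
    return s


def write_haplotypes_fasta(phased: PhasedRegionHaplotypes, path) -> None:
    """FASTA-like allele strings over region SNPs, one record per copy.

    Alleles are written 0/1 (ALT count) with N for unassigned sites; headers
    carry the sample id, copy index and orientation-class label.
    """
    def allele_string(vec):
        return "".join("N" if a == UNASSIGNED else str(int(a)) for a in vec)

    with open(path, "w") as fh:
        for i, sample in enumerate(phased.sample_ids):
            for copy, (hap, cls) in enumerate(
                ((phased.hap1[i], phased.hap1_class[i]),
                 (phased.hap2[i], phased.hap2_class[i])),
                start=1,
            ):
                if not cls:
                    continue
                fh.write(f">{sample}|{copy}|{cls}\n{allele_string(hap)}\n")
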