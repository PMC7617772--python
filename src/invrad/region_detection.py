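"""Detection of genomic regions with aberrant local relationship structure.

The genome is tiled with overlapping windows; in each window the pairwise
genetic distance matrix between samples is decomposed by classical
multidimensional scaling (PCoA), the per-window principal coordinates are
sign-aligned against a genome-wide anchor, and k-means clustering of the
window feature vectors separates a "genome background" cluster from outlier
windows. Runs of consecutive outlier windows become region calls — the
signature of large polymorphic inversions, whose suppressed recombination
gives whole regions a sample relationship structure (three karyotype
clusters) unlike the rest of the genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core_io import MISSING, GenomicRegion, GenotypeDataset

logger = logging.getLogger(__name__)


@dataclass
class WindowSpec:
    """Window tiling parameters (defaults: 1 Mbp windows, half overlap)."""

    size: int = 1_000_000
    step: int = 500_000
    min_snps: int = 25
    max_missingness: float = 0.5

    def __post_init__(self):
        if self.step > self.size:
            raise ValueError("window step must be <= size")
        if self.min_snps < 2:
            raise ValueError("min_snps must be >= 2")


@dataclass
class WindowProfile:
    """PCoA coordinates of one genomic window."""

    region: GenomicRegion
    n_snps: int
    coords: np.ndarray  # samples x n_pcs, centered
    variance_explained: np.ndarray  # per PC

    @property
    def feature_vector(self) -> np.ndarray:
        """Flattened, per-window standardised PC coordinates."""
        v = self.coords.T.ravel()
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


@dataclass
class RegionCall:
    """A called outlier region: merged run of non-background windows."""

    region: GenomicRegion
    window_indices: list[int]
    cluster_label: int
    score: float  # fraction of member windows in the outlier cluster

    def __post_init__(self):
        if not 0 < self.score <= 1:
            raise ValueError("score must be in (0, 1]")


# -- distances and PCoA ------------------------------------------------------


def distance_matrix_from_dosages(G: np.ndarray) -> np.ndarray:
    """Mean per-site allelic difference |d_i - d_j|/2 over pairwise-complete sites.

    ``G`` is samples x SNPs with values {0,1,2,MISSING}. Entries with zero
    comparable sites are NaN; the diagonal is 0. Range [0, 1].
    """
    G = np.asarray(G)
    if G.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    M = (G != MISSING).astype(np.float64)
    X = [((G == k) & (G != MISSING)).astype(np.float64) for k in (0, 1, 2)]
    # sum over sites of |a-b| for dosage categories a,b
    diff = np.zeros((G.shape[0], G.shape[0]))
    for a in range(3):
        for b in range(3):
            w = abs(a - b)
            if w:
                diff += w * (X[a] @ X[b].T)
    comparable = M @ M.T
    with np.errstate(invalid="ignore", divide="ignore"):
        D = diff / (2.0 * comparable)
    D[comparable == 0] = np.nan
    np.fill_diagonal(D, 0.0)
    return D


def pairwise_distance_matrix(
    dataset: GenotypeDataset, region: GenomicRegion, samples=None, min_snps: int = 2
) -> np.ndarray:
    """Pairwise distance matrix over the SNPs of ``region``."""
    G = dataset.dosages(region.chrom, region=region, samples=samples)
    if G.shape[1] < min_snps:
        raise ValueError(
            f"region {region.chrom}:{region.start}-{region.end} has "
            f"{G.shape[1]} SNPs < min_snps={min_snps}"
        )
    return distance_matrix_from_dosages(G)


def classical_mds(D: np.ndarray, n_pcs: int):
    """Classical MDS / PCoA of a distance matrix.

    Eigendecomposition of the double-centered squared-distance matrix; returns
    (coords samples x n_pcs, variance_explained per PC). Non-positive
    eigenvalues yield zero coordinates.
    """
    n = D.shape[0]
    if n_pcs > n - 1:
        raise ValueError(f"n_pcs={n_pcs} > n_samples-1={n - 1}")
    D = np.nan_to_num(D, nan=0.0)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = np.clip(vals, 0.0, None)
    total = pos.sum()
    coords = vecs[:, :n_pcs] * np.sqrt(pos[:n_pcs])
    varexp = pos[:n_pcs] / total if total > 0 else np.zeros(n_pcs)
    return coords, varexp


# -- window profiles ---------------------------------------------------------


def window_starts(chrom_length: int, spec: WindowSpec) -> list[int]:
    """1-based window start positions tiling a chromosome."""
    if chrom_length < spec.size:
        return [1]
    starts = []
    s = 1
    while s + spec.size - 1 <= chrom_length:
        starts.append(s)
        s += spec.step
    return starts


def compute_window_profiles(
    dataset: GenotypeDataset,
    spec: WindowSpec | None = None,
    n_pcs: int = 2,
    chroms=None,
    samples=None,
) -> list[WindowProfile]:
    """PCoA profile per window; low-SNP / high-missingness windows skipped."""
    spec = spec or WindowSpec()
    if dataset.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if n_pcs > dataset.n_samples - 1:
        raise ValueError("n_pcs must be < number of samples")
    profiles = []
    n_skipped = 0
    for chrom in chroms or dataset.chromosomes:
        length = dataset.chrom_lengths[chrom]
        for start in window_starts(length, spec):
            region = GenomicRegion(chrom, start, min(start + spec.size - 1, length))
            G = dataset.dosages(chrom, region=region, samples=samples)
            if G.shape[1] < spec.min_snps:
                n_skipped += 1
                continue
            if np.mean(G == MISSING) > spec.max_missingness:
                n_skipped += 1
                continue
            D = distance_matrix_from_dosages(G)
            coords, varexp = classical_mds(D, n_pcs)
            profiles.append(WindowProfile(region, G.shape[1], coords, varexp))
    if n_skipped:
        logger.info("compute_window_profiles: skipped %d windows", n_skipped)
    return profiles


def genomewide_profile(
    dataset: GenotypeDataset, n_pcs: int = 2, max_snps: int = 20_000, samples=None
) -> WindowProfile:
    """Anchor profile from genome-wide SNPs (evenly thinned to ``max_snps``)."""
    mats = [dataset.dosages(c, samples=samples) for c in dataset.chromosomes]
    G = np.concatenate([m for m in mats if m.shape[1]], axis=1)
    if G.shape[1] > max_snps:
        G = G[:, :: int(np.ceil(G.shape[1] / max_snps))]
    D = distance_matrix_from_dosages(G)
    coords, varexp = classical_mds(D, n_pcs)
    first = dataset.chromosomes[0]
    region = GenomicRegion(first, 1, dataset.chrom_lengths[first])
    return WindowProfile(region, G.shape[1], coords, varexp)


def align_pc_signs(profiles, anchor_profile: WindowProfile):
    """Flip each window PC whose correlation with the anchor PC is negative.

    Zero-variance or uncorrelated (|r| == 0) PCs are left unchanged.
    Idempotent and deterministic. Profiles are modified in place and returned.
    """
    A = anchor_profile.coords
    for prof in profiles:
        for k in range(prof.coords.shape[1]):
            x, a = prof.coords[:, k], A[:, k]
            if x.std() == 0 or a.std() == 0:
                continue
            r = float(np.corrcoef(x, a)[0, 1])
            if r < 0:
                prof.coords[:, k] = -x
            elif r == 0:
                logger.warning("align_pc_signs: PC%d orthogonal to anchor", k + 1)
    return profiles


# -- outlier region detection ------------------------------------------------


def detect_outlier_regions(
    profiles: list[WindowProfile],
    k_clusters: int = 2,
    min_run: int = 3,
    seed: int = 0,
    min_silhouette: float = 0.4,
    max_stages: int = 8,
) -> list[RegionCall]:
    """Iterative k-means on window feature vectors; outlier runs -> calls.

    Each stage splits the current genome-background windows into
    ``k_clusters`` (k-means, 10 restarts, fixed seed); the majority cluster
    stays background, the rest become outlier windows. A stage whose mean
    silhouette falls below ``min_silhouette`` is treated as structureless and
    stops the iteration: k-means always produces k clusters, so without this
    guard chance runs of noise windows would be called. Iterating the split
    matters because distinct inversions carry independent karyotype
    compositions and therefore distinct outlier geometries.
    Maximal runs of >= ``min_run`` consecutive non-background windows become
    calls; runs separated by < ``min_run`` background windows are merged.
    """
    from sklearn.cluster import KMeans
    from sklearn.metrics import silhouette_score

    if len(profiles) < 2 * min_run:
        raise ValueError("need at least 2*min_run windows")
    X = np.array([p.feature_vector for p in profiles])

    labels = np.zeros(len(profiles), dtype=int)  # 0 = background
    background_idx = np.arange(len(profiles))
    next_label = 1
    for _ in range(max_stages):
        if len(background_idx) < 2 * min_run:
            break
        Xb = X[background_idx]
        km = KMeans(n_clusters=k_clusters, n_init=10, random_state=seed)
        stage = km.fit_predict(Xb)
        if len(np.unique(stage)) < 2:
            break
        if silhouette_score(Xb, stage) < min_silhouette:
            break
        majority = int(np.argmax(np.bincount(stage)))
        for c in np.unique(stage):
            if c == majority:
                continue
            labels[background_idx[stage == c]] = next_label
            next_label += 1
        background_idx = background_idx[stage == majority]
    if next_label == 1:
        logger.info("detect_outlier_regions: no separated outlier cluster")
        return []
    background = 0

    calls = []
    # group windows by chromosome, in input (positional) order
    by_chrom: dict[str, list[int]] = {}
    for i, p in enumerate(profiles):
        by_chrom.setdefault(p.region.chrom, []).append(i)
    for chrom, idxs in by_chrom.items():
        runs = []  # [start_i, end_i] index ranges into idxs
        cur = None
        for j, i in enumerate(idxs):
            if labels[i] != background:
                cur = [j, j] if cur is None else [cur[0], j]
            else:
                if cur is not None:
                    runs.append(cur)
                    cur = None
        if cur is not None:
            runs.append(cur)
        runs = [r for r in runs if r[1] - r[0] + 1 >= min_run]
        # merge runs separated by < min_run background windows
        merged = []
        for r in runs:
            if merged and r[0] - merged[-1][1] - 1 < min_run:
                merged[-1][1] = r[1]
            else:
                merged.append(list(r))
        for lo, hi in merged:
            member = idxs[lo : hi + 1]
            outlier_frac = float(np.mean([labels[i] != background for i in member]))
            lab = int(
                np.bincount([labels[i] for i in member if labels[i] != background]).argmax()
            )
            calls.append(
                RegionCall(
                    region=GenomicRegion(
                        chrom,
                        profiles[member[0]].region.start,
                        profiles[member[-1]].region.end,
                    ),
                    window_indices=list(member),
                    cluster_label=lab,
                    score=outlier_frac,
                )
            )
    return calls


def windowed_pc1_track(
    dataset: GenotypeDataset,
    spec: WindowSpec | None = None,
    samples=None,
    chrom: str | None = None,
):
    """Sign-aligned PC1 per sample per window along a chromosome.

    Returns ``(window_regions, track)`` where ``track`` is
    windows x samples. Used for plotting and crossover counting.
    """
    chrom = chrom or dataset.chromosomes[0]
    profiles = compute_window_profiles(
        dataset, spec, n_pcs=2, chroms=[chrom], samples=samples
    )
    anchor = genomewide_profile(dataset, n_pcs=2, samples=samples)
    align_pc_signs(profiles, anchor)
    regions = [p.region for p in profiles]
    track = np.array([p.coords[:, 0] for p in profiles])
    return regions, track


# -- export ------------------------------------------------------------------


def profiles_to_frame(profiles: list[WindowProfile], sample_ids):
    """Window PC coordinates as a long-format DataFrame (for TSV export)."""
    import pandas as pd

    rows = []
    for w, p in enumerate(profiles):
        for i, s in enumerate(sample_ids):
            row = {
                "window": w,
                "chrom": p.region.chrom,
                "start": p.region.start,
                "end": p.region.end,
                "n_snps": p.n_snps,
                "sample": s,
            }
            for k in range(p.coords.shape[1]):
                row[f"pc{k + 1}"] = p.coords[i, k]
            rows.append(row)
    return pd.DataFrame(rows)


def write_calls_tsv(calls: list[RegionCall], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "chrom": c.region.chrom,
                "start": c.region.start,
                "end": c.region.end,
                "n_windows": len(c.window_indices),
                "cluster": c.cluster_label,
                "score": c.score,
            }
            for c in calls
        ]
    ).to_csv(path, sep="\t", index=False)
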