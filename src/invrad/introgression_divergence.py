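"""Divergence times, Patterson's D with block jackknife, the
inversion-state-conditioned D experiment, and the coalescent
incomplete-lineage-sorting (ILS) retention probability.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_io import MISSING, GenomicRegion, GenotypeDataset

logger = logging.getLogger(__name__)

#: Default mutation rate per bp per generation used for divergence times.
DEFAULT_MU = 3e-9


@dataclass
class DivergenceResult:
    pair: tuple[str, str]
    d: float  # mean per-bp pairwise difference
    mu: float
    scope: str

    @property
    def t(self) -> float:
        """Divergence (coalescence) time in generations, t = d / (2 mu)."""
        return self.d / (2.0 * self.mu)


@dataclass
class DStatResult:
    quartet: tuple[str, str, str, str]  # (P1, P2, P3, O)
    abba: float
    baba: float
    d: float
    se: float
    n_blocks: int
    scope: str = "genome"

    @property
    def z(self) -> float:
        return self.d / self.se if self.se > 0 else float("nan")


@dataclass
class ILSParams:
    """Parameters of the ILS retention calculation.

    ``ne``: diploid effective size; ``t``: generations of independent
    sorting; ``n_lineages`` x ``k_inversions``: number of independent
    lineage/inversion combinations that must all retain the polymorphism.
    """

    ne: float
    t: float
    n_lineages: int = 1
    k_inversions: int = 1

    def __post_init__(self):
        if self.ne <= 0 or self.t < 0 or self.n_lineages <= 0 or self.k_inversions <= 0:
            raise ValueError("ILS parameters must be positive (t >= 0)")


# -- scope helpers -------------------------------------------------------------


def _scope_columns(dataset, chrom, include=None, exclude=()):
    """Boolean SNP mask and bp extent for a chromosome under a scope."""
    pos = dataset.data[chrom].positions
    mask = np.ones(len(pos), dtype=bool)
    length = dataset.chrom_lengths[chrom]
    if include is not None:
        if include.chrom != chrom:
            return np.zeros(len(pos), dtype=bool), 0
        mask &= include.contains(pos)
        length = include.length
    for reg in exclude:
        if reg.chrom == chrom:
            mask &= ~reg.contains(pos)
            length -= min(reg.end, dataset.chrom_lengths[chrom]) - reg.start + 1
    return mask, max(length, 0)


# -- pairwise divergence time ---------------------------------------------------


def pairwise_divergence_time(
    dataset: GenotypeDataset,
    pair: tuple[str, str],
    scope: GenomicRegion | None = None,
    exclude_regions=(),
    mu: float = DEFAULT_MU,
    min_sites: int = 1000,
) -> DivergenceResult:
    """Pairwise sequence divergence translated into a coalescence time.

    d is the mean per-bp allelic difference (|d_i - d_j| / 2 summed over
    SNPs, divided by the bp extent of the scope; invariant sites count as
    zero difference), and t = d / (2 mu) generations.
    """
    i, j = dataset.sample_indices(pair)
    total_diff = 0.0
    total_bp = 0
    for chrom in dataset.chromosomes:
        mask, length = _scope_columns(dataset, chrom, scope, exclude_regions)
        if scope is not None and scope.chrom != chrom:
            continue
        gi = dataset.data[chrom].dosages[i, mask]
        gj = dataset.data[chrom].dosages[j, mask]
        ok = (gi != MISSING) & (gj != MISSING)
        total_diff += float(np.abs(gi[ok].astype(int) - gj[ok].astype(int)).sum()) / 2.0
        total_bp += length
    if total_bp < min_sites:
        raise ValueError(f"scope covers {total_bp} bp < min_sites={min_sites}")
    d = total_diff / total_bp
    scope_name = (
        f"{scope.chrom}:{scope.start}-{scope.end}" if scope else
        ("genome-outside-regions" if exclude_regions else "genome")
    )
    return DivergenceResult(pair=tuple(pair), d=d, mu=mu, scope=scope_name)


def group_divergence_times(dataset, group_a, group_b, **kwargs):
    """Divergence results for all cross-group sample pairs."""
    return [
        pairwise_divergence_time(dataset, (a, b), **kwargs)
        for a in group_a
        for b in group_b
    ]


# -- Patterson's D ---------------------------------------------------------------


def _population_frequencies(dataset, chrom, samples, mask):
    idx = dataset.sample_indices(samples)
    G = dataset.data[chrom].dosages[idx][:, mask].astype(float)
    G[G == MISSING] = np.nan
    with np.errstate(invalid="ignore"):
        n = 2 * np.sum(~np.isnan(G), axis=0)
        p = np.nansum(G, axis=0) / np.maximum(n, 1)
    p[n == 0] = np.nan
    return p


def d_statistic(
    dataset: GenotypeDataset,
    populations: dict[str, list],
    block_size: int = 1_000_000,
    exclude_regions=(),
    min_blocks: int = 20,
) -> DStatResult:
    """Patterson's D for a quartet of populations with block-jackknife SE.

    ``populations`` maps "P1"/"P2"/"P3"/"O" to sample lists. Per SNP,
    ABBA = (1-p1) p2 p3 (1-pO) and BABA = p1 (1-p2) p3 (1-pO) on ALT-allele
    frequencies (complete-case per population); D = (ABBA-BABA)/(ABBA+BABA).
    SE by delete-one jackknife over contiguous genomic blocks.
    """
    abba_blocks: dict[tuple, float] = {}
    baba_blocks: dict[tuple, float] = {}
    for chrom in dataset.chromosomes:
        mask, _ = _scope_columns(dataset, chrom, None, exclude_regions)
        if not mask.any():
            continue
        freqs = {
            key: _population_frequencies(dataset, chrom, samp, mask)
            for key, samp in populations.items()
        }
        p1, p2, p3, po = freqs["P1"], freqs["P2"], freqs["P3"], freqs["O"]
        ok = ~(np.isnan(p1) | np.isnan(p2) | np.isnan(p3) | np.isnan(po))
        abba = (1 - p1) * p2 * p3 * (1 - po)
        baba = p1 * (1 - p2) * p3 * (1 - po)
        pos = dataset.data[chrom].positions[mask]
        block_ids = (pos - 1) // block_size
        for b in np.unique(block_ids):
            sel = ok & (block_ids == b)
            if not sel.any():
                continue
            key = (chrom, int(b))
            abba_blocks[key] = float(abba[sel].sum())
            baba_blocks[key] = float(baba[sel].sum())

    keys = list(abba_blocks)
    n_blocks = len(keys)
    if n_blocks < min_blocks:
        raise ValueError(f"only {n_blocks} non-empty blocks; need >= {min_blocks}")
    A = np.array([abba_blocks[k] for k in keys])
    B = np.array([baba_blocks[k] for k in keys])
    tot_a, tot_b = A.sum(), B.sum()
    d = (tot_a - tot_b) / (tot_a + tot_b) if tot_a + tot_b > 0 else 0.0

    d_jack = np.array(
        [
            ((tot_a - A[j]) - (tot_b - B[j])) / ((tot_a - A[j]) + (tot_b - B[j]))
            if (tot_a - A[j]) + (tot_b - B[j]) > 0
            else 0.0
            for j in range(n_blocks)
        ]
    )
    se = float(np.sqrt((n_blocks - 1) / n_blocks * np.sum((d_jack - d_jack.mean()) ** 2)))
    return DStatResult(
        quartet=tuple(str(k) for k in ("P1", "P2", "P3", "O")),
        abba=float(tot_a),
        baba=float(tot_b),
        d=float(d),
        se=se,
        n_blocks=n_blocks,
        scope="genome-outside-regions" if exclude_regions else "genome",
    )


# -- conditioned D experiment -----------------------------------------------------


def conditioned_d_experiment(
    dataset: GenotypeDataset,
    calls,
    species_samples: dict[str, list],
    species_states: dict[str, int],
    p3_species: list[str],
    outgroup_species: str,
    focal_state: int = 2,
    block_size: int = 1_000_000,
    min_blocks: int = 20,
):
    """Patterson's D outside inversions, conditioned on shared inversion state.

    Quartets (P1, P2, P3, O) are enumerated over ingroup species pairs and
    ``p3_species`` such that exactly one of the pair shares the focal
    inversion state (majority genotype == ``focal_state``) with P3, and
    ordered so that P2 is the sharing species. D is computed on SNPs outside
    all called regions. Returns ``(results, summary)`` where the summary
    holds the mean D, fraction positive and a two-sided sign-test p: under a
    no-gene-flow null the D distribution is symmetric around zero, while
    introgression accompanying inversion transfer shifts it positive.
    """
    exclude = [c.region if hasattr(c, "region") else c for c in calls]
    ingroup = [
        s
        for s in species_states
        if s not in p3_species and s != outgroup_species
    ]
    results = []
    for p3 in p3_species:
        p3_shares = species_states[p3] == focal_state
        for a, b in itertools.combinations(ingroup, 2):
            a_shares = (species_states[a] == focal_state) == p3_shares
            b_shares = (species_states[b] == focal_state) == p3_shares
            if a_shares == b_shares:
                continue  # need exactly one of the pair sharing with P3
            p1, p2 = (b, a) if a_shares else (a, b)
            res = d_statistic(
                dataset,
                {
                    "P1": species_samples[p1],
                    "P2": species_samples[p2],
                    "P3": species_samples[p3],
                    "O": species_samples[outgroup_species],
                },
                block_size=block_size,
                exclude_regions=exclude,
                min_blocks=min_blocks,
            )
            res.quartet = (p1, p2, p3, outgroup_species)
            res.scope = "genome-outside-inversions"
            results.append(res)
    if not results:
        raise ValueError("no qualifying quartets")
    ds = np.array([r.d for r in results])
    n_pos = int((ds > 0).sum())
    n_nonzero = int((ds != 0).sum())
    sign_p = float(stats.binomtest(n_pos, n_nonzero, 0.5).pvalue) if n_nonzero else 1.0
    summary = {
        "mean_d": float(ds.mean()),
        "fraction_positive": n_pos / len(ds) if len(ds) else float("nan"),
        "sign_test_p": sign_p,
        "n_quartets": len(results),
    }
    return results, summary


def holm_correction(pvalues) -> np.ndarray:
    """Holm step-down FWER-adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj


# -- ILS retention ------------------------------------------------------------------


def ils_retention_probability(params: ILSParams) -> float:
    """Probability of retaining a neutral polymorphism through drift alone.

    Per lineage per inversion the retention is approximated by the
    heterozygosity-decay factor exp(-t / (2 Ne)); the joint probability over
    ``n_lineages`` x ``k_inversions`` independent combinations is that factor
    raised to their product. This understates the probability that a
    polymorphism is merely still segregating, but matches the expected
    fraction of heterozygosity retained.
    """
    per = np.exp(-params.t / (2.0 * params.ne))
    return float(per ** (params.n_lineages * params.k_inversions))


def wf_heterozygosity_retention(
    ne: int, t: int, p0: float = 0.5, n_replicates: int = 10_000, seed: int = 17
):
    """Forward Wright-Fisher estimate of relative heterozygosity retained.

    Simulates ``n_replicates`` neutral biallelic loci of initial frequency
    ``p0`` in a diploid population of size ``ne`` for ``t`` generations and
    returns (mean H_t / H_0, Monte-Carlo SE of that mean).
    """
    rng = np.random.default_rng(seed)
    n_copies = 2 * ne
    p = np.full(n_replicates, p0)
    for _ in range(t):
        p = rng.binomial(n_copies, p) / n_copies
    h = 2 * p * (1 - p) / (2 * p0 * (1 - p0))
    return float(h.mean()), float(h.std(ddof=1) / np.sqrt(n_replicates))
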