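"""Genotype-frequency and sex-association tests for inversion genotypes.

Hardy-Weinberg heterozygote-excess exact tests (Levene's conditional
distribution), Fisher's-method pooling across species, Fisher's exact
genotype-sex tests (per population and on pooled counts), and the Mendelian
1:2:1 segregation chi-square for pedigree data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln

logger = logging.getLogger(__name__)


@dataclass
class GenotypeCounts:
    """Counts of inversion genotypes 0/1/2 within one species."""

    species: str
    n0: int
    n1: int
    n2: int

    def __post_init__(self):
        if min(self.n0, self.n1, self.n2) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n0 + self.n1 + self.n2


@dataclass
class SexGenotypeTable:
    """(female, male) x (genotype 0, 1, 2) counts."""

    female: tuple[int, int, int]
    male: tuple[int, int, int]

    def __post_init__(self):
        if min(*self.female, *self.male) < 0:
            raise ValueError("counts must be non-negative")

    def collapse(self, rule: str = "het_vs_hom"):
        """Collapse to 2x2 (rows female/male; columns het / homozygous).

        ``het_vs_hom`` keeps every sample (hom = genotype 0 + genotype 2);
        ``het_vs_hom_inverted`` compares heterozygous against
        homozygous-inverted only (genotype-0 samples dropped).
        """
        f0, f1, f2 = self.female
        m0, m1, m2 = self.male
        if rule == "het_vs_hom":
            return np.array([[f1, f0 + f2], [m1, m0 + m2]])
        if rule == "het_vs_hom_inverted":
            return np.array([[f1, f2], [m1, m2]])
        raise ValueError(f"unknown collapse rule {rule!r}")


# -- HWE exact heterozygote-excess test ------------------------------------------


def levene_het_distribution(n: int, n_a: int):
    """Levene's exact conditional distribution of heterozygote counts.

    Given ``n`` diploid genotypes and ``n_a`` copies of allele A (out of 2n),
    returns (het_values, probabilities): P(n_het = h | n, n_a) =
    n! / (n_aa! n_ab! n_bb!) * 2^h * n_a! n_b! / (2n)! over feasible h with
    h = n_a (mod 2).
    """
    n_b = 2 * n - n_a
    hs = np.arange(n_a % 2, min(n_a, n_b) + 1, 2)
    log_const = gammaln(n + 1) + gammaln(n_a + 1) + gammaln(n_b + 1) - gammaln(2 * n + 1)
    logp = (
        log_const
        + hs * np.log(2.0)
        - gammaln((n_a - hs) / 2 + 1)
        - gammaln(hs + 1)
        - gammaln((n_b - hs) / 2 + 1)
    )
    p = np.exp(logp)
    return hs, p / p.sum()


def hwe_excess_het_test(counts: GenotypeCounts):
    """One-sided exact p for heterozygote excess: P(n_het >= observed).

    Monomorphic species (one allele absent) return p = 1 with
    ``monomorphic=True``.
    """
    n = counts.total
    if n < 2:
        raise ValueError("need at least 2 genotyped samples")
    n_a = 2 * counts.n0 + counts.n1  # copies of the ancestral-orientation allele
    n_b = 2 * counts.n2 + counts.n1
    if n_a == 0 or n_b == 0:
        return {"p": 1.0, "monomorphic": True, "observed_het": counts.n1}
    hs, probs = levene_het_distribution(n, n_a)
    p = float(probs[hs >= counts.n1].sum())
    return {"p": min(p, 1.0), "monomorphic": False, "observed_het": counts.n1}


def pool_species_tests(pvalues, eps: float | None = None):
    """Fisher's combination of per-species p-values: -2 sum(ln p) ~ chi2(2k).

    Zero p-values are rejected unless a floor ``eps`` is supplied.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if len(p) == 0:
        raise ValueError("no eligible species")
    if np.any(p == 0):
        if eps is None:
            raise ValueError(
                "p-value of 0 supplied; pass eps to floor exact zeros"
            )
        p = np.maximum(p, eps)
    statistic = -2.0 * np.sum(np.log(p))
    combined = float(stats.chi2.sf(statistic, 2 * len(p)))
    return {"statistic": float(statistic), "df": 2 * len(p), "p": combined}


# -- Fisher sex-association test --------------------------------------------------


def fisher_sex_test(table: SexGenotypeTable, collapse: str = "het_vs_hom"):
    """Two-sided Fisher's exact test of inversion genotype vs sex.

    The two-sided p sums hypergeometric probabilities of tables at most as
    probable as the observed one. The direction is reported as the odds
    ratio of (male & heterozygous), so OR > 1 matches the XY-like
    expectation of heterozygous males. An empty margin yields p = 1 with
    ``degenerate=True``.
    """
    t = table.collapse(collapse)
    if t.sum() < 1:
        raise ValueError("empty table")
    degenerate = (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any()
    if degenerate:
        return {
            "p": 1.0,
            "odds_ratio": float("nan"),
            "male_het_direction": 0.0,
            "degenerate": True,
            "table": t,
        }
    # orient: rows (male, female), cols (het, hom) so OR>1 = male-het enrichment
    oriented = np.array([[t[1, 0], t[1, 1]], [t[0, 0], t[0, 1]]])
    oddsratio, p = stats.fisher_exact(oriented)
    direction = 1.0 if oddsratio > 1 else (-1.0 if oddsratio < 1 else 0.0)
    return {
        "p": float(p),
        "odds_ratio": float(oddsratio),
        "male_het_direction": direction,
        "degenerate": False,
        "table": t,
    }


def pooled_sex_table(tables) -> SexGenotypeTable:
    """Element-wise sum of per-species sex-genotype tables (raw-count pooling)."""
    f = np.sum([t.female for t in tables], axis=0)
    m = np.sum([t.male for t in tables], axis=0)
    return SexGenotypeTable(tuple(int(x) for x in f), tuple(int(x) for x in m))


def sex_table_from_calls(call, metadata, samples=None) -> SexGenotypeTable:
    """Build a sex x genotype table from an inversion call and metadata.

    Samples of unknown sex or unassigned genotype are excluded (logged).
    """
    samples = samples if samples is not None else call.sample_ids
    counts = {"female": [0, 0, 0], "male": [0, 0, 0]}
    n_excluded = 0
    for s in samples:
        g = call.genotype_of(s)
        sex = metadata.sex_of(s)
        if sex not in counts or g not in (0, 1, 2):
            n_excluded += 1
            continue
        counts[sex][g] += 1
    if n_excluded:
        logger.info("sex_table_from_calls: excluded %d samples", n_excluded)
    return SexGenotypeTable(tuple(counts["female"]), tuple(counts["male"]))


# -- Mendelian segregation ---------------------------------------------------------


def mendelian_segregation_test(n0: int, n1: int, n2: int):
    """Chi-square test of genotype counts against the Mendelian 1:2:1 ratio.

    Returns the chi-square statistic and its p-value with 2 degrees of
    freedom (for df = 2 the survival function is exp(-chi2/2)).
    """
    total = n0 + n1 + n2
    if total <= 0:
        raise ValueError("zero total count")
    expected = np.array([0.25, 0.5, 0.25]) * total
    observed = np.array([n0, n1, n2], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return {"chi2": chi2, "p": float(stats.chi2.sf(chi2, df=2))}
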