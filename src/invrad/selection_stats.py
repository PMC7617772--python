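"""Selection statistics on inversion haplotypes.

Inversion-correlated SNPs (ICS) are identified by the Pearson correlation
between derived-allele dosage and inversion genotype across samples (r > 0:
derived allele enriched on inverted haplotypes). On top of the ICS scan sit
an exonic-enrichment contrast, McDonald-Kreitman style tests between
orientation classes (with the neutrality index NI and the direction of
selection DoS), correlation-binned normalised dN/dS with Nei-Gojobori style
site counts, and the shared-polymorphism fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import (
    EFFECT_CODES,
    EFFECT_NAMES,
    MISSING,
    UNASSIGNED,
    GenotypeDataset,
)
from .inversion_genotyping import InversionCall, PhasedRegionHaplotypes

logger = logging.getLogger(__name__)

#: Default ICS definition: -log10 p >= 7 and |r| >= 0.9 (configurable).
DEFAULT_ICS_SCORE = 7.0
DEFAULT_ICS_R = 0.9
MAX_SCORE = 300.0


@dataclass
class ICSRecord:
    chrom: str
    pos: int
    r: float
    score: float  # -log10 p of the correlation
    effect: str
    is_ics: bool


@dataclass
class MKTable:
    """McDonald-Kreitman 2x2 counts and derived statistics.

    Dn/Ds: fixed nonsynonymous/synonymous differences between orientation
    classes; Pn/Ps: polymorphic counts within classes. NI = (Pn/Ps)/(Dn/Ds);
    DoS = Dn/(Dn+Ds) - Pn/(Pn+Ps). Zero denominators leave the statistic
    NaN with ``ni_defined`` / ``dos_defined`` False.
    """

    dn: int
    ds: int
    pn: int
    ps: int

    def __post_init__(self):
        for v in (self.dn, self.ds, self.pn, self.ps):
            if v < 0 or int(v) != v:
                raise ValueError("MK counts must be non-negative integers")

    @property
    def ni_defined(self) -> bool:
        return self.ps > 0 and self.ds > 0 and self.dn > 0

    @property
    def ni(self) -> float:
        if not self.ni_defined:
            return float("nan")
        return (self.pn / self.ps) / (self.dn / self.ds)

    @property
    def dos_defined(self) -> bool:
        return (self.dn + self.ds) > 0 and (self.pn + self.ps) > 0

    @property
    def dos(self) -> float:
        if not self.dos_defined:
            return float("nan")
        return self.dn / (self.dn + self.ds) - self.pn / (self.pn + self.ps)

    @property
    def p(self) -> float:
        return float(
            stats.fisher_exact([[self.dn, self.ds], [self.pn, self.ps]])[1]
        )


@dataclass
class DnDsBin:
    """One inversion-correlation bin of the normalised dN/dS curve."""

    lo: float
    hi: float
    n_nonsyn: int
    n_syn: int
    l_n: float
    l_s: float

    @property
    def defined(self) -> bool:
        return self.n_syn > 0 and self.l_n > 0 and self.l_s > 0

    @property
    def dnds(self) -> float:
        if not self.defined:
            return float("nan")
        return (self.n_nonsyn / self.l_n) / (self.n_syn / self.l_s)


# -- core correlation scan -----------------------------------------------------


def correlation_scan(
    dosages: np.ndarray,
    genotypes: np.ndarray,
    min_obs: int = 10,
    max_score: float = MAX_SCORE,
):
    """Pearson r and -log10 p of each SNP's dosage against inversion genotype.

    ``dosages``: samples x SNPs derived-dosage matrix ({0,1,2,MISSING});
    ``genotypes``: per-sample inversion genotype (UNASSIGNED excluded).
    Monomorphic SNPs and SNPs with < ``min_obs`` complete observations get
    NaN (count logged). Returns (r, score, n_used) arrays.
    """
    X = np.asarray(dosages, dtype=float).copy()
    X[X == MISSING] = np.nan
    g = np.asarray(genotypes, dtype=float).copy()
    g[g == UNASSIGNED] = np.nan
    valid = ~np.isnan(X) & ~np.isnan(g)[:, None]
    n = valid.sum(axis=0)

    Xm = np.where(valid, X, 0.0)
    Gm = np.where(valid, g[:, None], 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_x = Xm.sum(axis=0) / n
        mean_g = Gm.sum(axis=0) / n
        sxx = (Xm**2).sum(axis=0) / n - mean_x**2
        sgg = (Gm**2).sum(axis=0) / n - mean_g**2
        sxg = (Xm * Gm).sum(axis=0) / n - mean_x * mean_g
        r = sxg / np.sqrt(sxx * sgg)
    bad = (n < min_obs) | (sxx <= 0) | (sgg <= 0)
    r = np.where(bad, np.nan, np.clip(r, -1.0, 1.0))
    n_skipped = int(bad.sum())
    if n_skipped:
        logger.info("correlation_scan: skipped %d SNPs (monomorphic or < %d obs)",
                    n_skipped, min_obs)

    with np.errstate(invalid="ignore", divide="ignore"):
        df = n - 2
        t = r * np.sqrt(df / np.maximum(1e-300, 1 - r**2))
        p = 2 * stats.t.sf(np.abs(t), np.maximum(df, 1))
    score = np.where(np.isnan(r), np.nan, -np.log10(np.maximum(p, 10.0**-max_score)))
    score = np.minimum(score, max_score)
    return r, score, n


def permutation_pvalue(x, g, n_perm: int = 10_000, seed: int = 0) -> float:
    """Two-sided permutation p-value for a single SNP's correlation (small n)."""
    rng = np.random.default_rng(seed)
    x = np.asarray(x, dtype=float)
    g = np.asarray(g, dtype=float)
    obs = abs(np.corrcoef(x, g)[0, 1])
    hits = 0
    for _ in range(n_perm):
        if abs(np.corrcoef(rng.permutation(x), g)[0, 1]) >= obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def ics_scan(
    dataset: GenotypeDataset,
    call: InversionCall,
    samples=None,
    chrom: str | None = None,
    ics_score: float = DEFAULT_ICS_SCORE,
    ics_r: float = DEFAULT_ICS_R,
    min_obs: int = 10,
) -> list[ICSRecord]:
    """Scan polarized SNPs for correlation with inversion genotype.

    Requires a polarized dataset (run :func:`invrad.core_io.polarize` first)
    and inversion genotypes for >= 10 samples. Unpolarized SNPs are skipped.
    """
    if not dataset.has_polarization():
        raise ValueError("dataset is not polarized; run polarize() first")
    sample_ids = samples if samples is not None else call.sample_ids
    idx_in_call = [call.sample_ids.index(s) for s in sample_ids]
    g = call.genotypes[idx_in_call]
    if int((g != UNASSIGNED).sum()) < 10:
        raise ValueError("need inversion genotypes for >= 10 samples")

    records = []
    for c in [chrom] if chrom else dataset.chromosomes:
        D, known = dataset.derived_dosages(c, samples=sample_ids)
        if D.shape[1] == 0:
            continue
        r, score, _ = correlation_scan(D, g, min_obs=min_obs)
        r = np.where(known, r, np.nan)
        pos = dataset.data[c].positions
        eff = dataset.data[c].effect
        for j in np.where(~np.isnan(r))[0]:
            rec = ICSRecord(
                chrom=c,
                pos=int(pos[j]),
                r=float(r[j]),
                score=float(score[j]),
                effect=EFFECT_NAMES[int(eff[j])],
                is_ics=bool(score[j] >= ics_score and abs(r[j]) >= ics_r),
            )
            records.append(rec)
    return records


def records_to_frame(records: list[ICSRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "pos": r.pos,
                "r": r.r,
                "score": r.score,
                "effect": r.effect,
                "is_ics": r.is_ics,
            }
            for r in records
        ]
    )


# -- exonic enrichment --------------------------------------------------------


def exonic_enrichment(records: list[ICSRecord]):
    """2x2 ICS x exonic contrast: counts, odds ratio and two-sided Fisher p.

    "Exonic" means effect class synonymous or nonsynonymous.
    """
    exonic = {"synonymous", "nonsynonymous"}
    a = sum(1 for r in records if r.is_ics and r.effect in exonic)
    b = sum(1 for r in records if r.is_ics and r.effect not in exonic)
    c = sum(1 for r in records if not r.is_ics and r.effect in exonic)
    d = sum(1 for r in records if not r.is_ics and r.effect not in exonic)
    if a + b == 0:
        raise ValueError("no ICS among records")
    oddsratio, p = stats.fisher_exact([[a, b], [c, d]])
    return {"table": ((a, b), (c, d)), "odds_ratio": float(oddsratio), "p": float(p)}


# -- McDonald-Kreitman ---------------------------------------------------------


def mk_test(phased: PhasedRegionHaplotypes, effect_codes: np.ndarray) -> MKTable:
    """MK counts between orientation classes from phased region haplotypes.

    A site is a fixed difference if the two classes are fixed for different
    alleles, polymorphic if variable within either class; each site counts at
    most once. Only synonymous/nonsynonymous sites contribute.
    """
    H_inv = phased.class_haplotypes("inverted")
    H_anc = phased.class_haplotypes("ancestral")
    if H_inv.shape[0] < 2 or H_anc.shape[0] < 2:
        raise ValueError("need >= 2 haplotypes per orientation class")

    counts = {"dn": 0, "ds": 0, "pn": 0, "ps": 0}
    effect_codes = np.asarray(effect_codes)
    for j in range(len(phased.positions)):
        eff = int(effect_codes[j])
        if eff == EFFECT_CODES["nonsynonymous"]:
            suffix = "n"
        elif eff == EFFECT_CODES["synonymous"]:
            suffix = "s"
        else:
            continue
        inv = H_inv[:, j]
        anc = H_anc[:, j]
        inv = inv[inv != UNASSIGNED]
        anc = anc[anc != UNASSIGNED]
        if len(inv) == 0 or len(anc) == 0:
            continue
        inv_alleles = set(int(x) for x in np.unique(inv))
        anc_alleles = set(int(x) for x in np.unique(anc))
        if len(inv_alleles) > 1 or len(anc_alleles) > 1:
            counts["p" + suffix] += 1
        elif inv_alleles != anc_alleles:
            counts["d" + suffix] += 1
    return MKTable(counts["dn"], counts["ds"], counts["pn"], counts["ps"])


# -- Nei-Gojobori site counting -------------------------------------------------


def _codon_table():
    from Bio.Data import CodonTable

    return CodonTable.unambiguous_dna_by_id[1]


def ng_site_counts(coding_sequence: str):
    """Nei-Gojobori style (L_n, L_s) site counts for an in-frame coding sequence.

    For every codon position, the fraction of the three possible single-base
    changes that are nonsynonymous contributes to L_n and the synonymous
    fraction to L_s. Changes creating a stop codon are excluded from both
    counts, and stop codons themselves are skipped.
    """
    table = _codon_table()
    fwd = table.forward_table
    stops = set(table.stop_codons)
    bases = "ACGT"
    seq = coding_sequence.upper().replace("U", "T")
    if len(seq) % 3:
        raise ValueError("coding sequence length must be a multiple of 3")
    l_n = l_s = 0.0
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if codon in stops or any(b not in bases for b in codon):
            continue
        aa = fwd[codon]
        for pos in range(3):
            n_non, n_syn = 0, 0
            for b in bases:
                if b == codon[pos]:
                    continue
                mut = codon[:pos] + b + codon[pos + 1 :]
                if mut in stops:
                    continue
                if fwd[mut] == aa:
                    n_syn += 1
                else:
                    n_non += 1
            tot = n_non + n_syn
            if tot:
                l_n += n_non / tot
                l_s += n_syn / tot
    return l_n, l_s


# -- binned dN/dS ----------------------------------------------------------------


def binned_dnds(
    records,
    site_counts: tuple[float, float] | None = None,
    bin_width: float = 0.1,
    coding_sequences=None,
) -> list[DnDsBin]:
    """Normalised dN/dS per inversion-correlation bin.

    ``records`` may be a list of :class:`ICSRecord` or a DataFrame with
    columns ``r`` and ``effect``. ``site_counts`` is the global (L_n, L_s)
    pair; alternatively ``coding_sequences`` (iterable of in-frame coding
    sequences) is enumerated with :func:`ng_site_counts`. Bins partition
    [-1, 1]; each coding SNP contributes to the bin containing its r (the
    final bin is closed at 1).
    """
    if site_counts is None:
        if coding_sequences is None:
            raise ValueError("need site_counts or coding_sequences for normalisation")
        l_n = l_s = 0.0
        for seq in coding_sequences:
            a, b = ng_site_counts(seq)
            l_n += a
            l_s += b
        site_counts = (l_n, l_s)
    l_n, l_s = site_counts

    if isinstance(records, pd.DataFrame):
        rs = records["r"].to_numpy(dtype=float)
        effs = records["effect"].to_numpy()
    else:
        rs = np.array([rec.r for rec in records], dtype=float)
        effs = np.array([rec.effect for rec in records])

    n_bins = int(round(2 / bin_width))
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(rs, edges[1:-1], right=False), 0, n_bins - 1)
    bins = []
    for b in range(n_bins):
        sel = (idx == b) & ~np.isnan(rs)
        n_non = int(np.sum(sel & (effs == "nonsynonymous")))
        n_syn = int(np.sum(sel & (effs == "synonymous")))
        bins.append(DnDsBin(edges[b], edges[b + 1], n_non, n_syn, l_n, l_s))
    return bins


def bins_to_frame(bins: list[DnDsBin]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lo": b.lo,
                "hi": b.hi,
                "n_nonsyn": b.n_nonsyn,
                "n_syn": b.n_syn,
                "dnds": b.dnds,
            }
            for b in bins
        ]
    )


# -- shared polymorphism ----------------------------------------------------------


def shared_polymorphism_fraction(
    phased: PhasedRegionHaplotypes,
    records: list[ICSRecord],
    ics_score: float = DEFAULT_ICS_SCORE,
    ics_r: float = DEFAULT_ICS_R,
) -> float:
    """Fraction of ICS with both alleles on >= 1 haplotype of each class."""
    ics_pos = {
        rec.pos
        for rec in records
        if rec.chrom == phased.region.chrom
        and rec.score >= ics_score
        and abs(rec.r) >= ics_r
    }
    cols = [j for j, p in enumerate(phased.positions) if int(p) in ics_pos]
    if not cols:
        raise ValueError("zero ICS inside the phased region")
    H_inv = phased.class_haplotypes("inverted")
    H_anc = phased.class_haplotypes("ancestral")
    shared = 0
    for j in cols:
        inv = H_inv[:, j]
        anc = H_anc[:, j]
        inv = inv[inv != UNASSIGNED]
        anc = anc[anc != UNASSIGNED]
        both_inv = (0 in inv) and (1 in inv)
        both_anc = (0 in anc) and (1 in anc)
        if both_inv and both_anc:
            shared += 1
    return shared / len(cols)
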