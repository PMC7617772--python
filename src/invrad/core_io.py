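"""Core data model and I/O for SNP genotype data.

The central container is :class:`GenotypeDataset`: a per-chromosome matrix of
biallelic-SNP ALT-allele dosages (samples x variants, values 0/1/2 or
:data:`MISSING`), together with positions, alleles, optional ancestral-allele
polarization and an optional coding-effect class per SNP.

Coordinates are 1-based inclusive internally (VCF convention); BED export
converts to 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype dosage.
MISSING = np.int8(-1)

#: Sentinel for an unassigned inversion genotype / value.
UNASSIGNED = -9

# Coding-effect classes, stored as int8 codes.
EFFECT_UNKNOWN = np.int8(0)
EFFECT_NONCODING = np.int8(1)
EFFECT_SYNONYMOUS = np.int8(2)
EFFECT_NONSYNONYMOUS = np.int8(3)

EFFECT_CODES = {
    "unknown": EFFECT_UNKNOWN,
    "noncoding": EFFECT_NONCODING,
    "synonymous": EFFECT_SYNONYMOUS,
    "nonsynonymous": EFFECT_NONSYNONYMOUS,
}
EFFECT_NAMES = {int(v): k for k, v in EFFECT_CODES.items()}


@dataclass(frozen=True)
class GenomicRegion:
    """A genomic interval, 1-based inclusive on both ends."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(
                f"region start {self.start} > end {self.end} on {self.chrom}"
            )
        if self.start < 1:
            raise ValueError(f"region start must be >= 1, got {self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, positions: np.ndarray) -> np.ndarray:
        """Boolean mask over ``positions`` (same chromosome assumed)."""
        positions = np.asarray(positions)
        return (positions >= self.start) & (positions <= self.end)

    def reciprocal_overlap(self, other: "GenomicRegion") -> float:
        """min(overlap/len(self), overlap/len(other)); 0 if different chrom."""
        if self.chrom != other.chrom:
            return 0.0
        ov = min(self.end, other.end) - max(self.start, other.start) + 1
        if ov <= 0:
            return 0.0
        return min(ov / self.length, ov / other.length)


@dataclass
class ChromosomeData:
    """Per-chromosome SNP table (columns of the dataset)."""

    positions: np.ndarray  # int64, strictly increasing, 1-based
    dosages: np.ndarray  # int8, n_samples x n_snps, values {0,1,2,MISSING}
    ref: np.ndarray  # unicode, per SNP
    alt: np.ndarray
    ancestral_known: np.ndarray  # bool per SNP
    ancestral_is_alt: np.ndarray  # bool per SNP (meaningful where known)
    effect: np.ndarray  # int8 per SNP, EFFECT_* codes

    @property
    def n_snps(self) -> int:
        return len(self.positions)


def _empty_chrom(n_samples: int) -> ChromosomeData:
    return ChromosomeData(
        positions=np.empty(0, dtype=np.int64),
        dosages=np.empty((n_samples, 0), dtype=np.int8),
        ref=np.empty(0, dtype="U8"),
        alt=np.empty(0, dtype="U8"),
        ancestral_known=np.empty(0, dtype=bool),
        ancestral_is_alt=np.empty(0, dtype=bool),
        effect=np.empty(0, dtype=np.int8),
    )


class GenotypeDataset:
    """Biallelic-SNP dosage matrices for a set of samples.

    Parameters
    ----------
    sample_ids :
        Ordered unique sample identifiers.
    chrom_lengths :
        Ordered mapping chromosome name -> length in bp.
    data :
        Mapping chromosome name -> :class:`ChromosomeData`. Chromosomes
        without data get empty tables.
    """

    def __init__(self, sample_ids, chrom_lengths, data=None):
        self.sample_ids = list(sample_ids)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        self.chrom_lengths = dict(chrom_lengths)
        self.data: dict[str, ChromosomeData] = {}
        data = data or {}
        for chrom in self.chrom_lengths:
            cd = data.get(chrom, _empty_chrom(len(self.sample_ids)))
            self._validate_chrom(chrom, cd)
            self.data[chrom] = cd

    def _validate_chrom(self, chrom: str, cd: ChromosomeData) -> None:
        if cd.n_snps and not np.all(np.diff(cd.positions) > 0):
            bad = int(cd.positions[np.argmin(np.diff(cd.positions) > 0) + 1])
            raise ValueError(
                f"positions not strictly increasing on {chrom} near {bad}"
            )
        if cd.dosages.shape != (len(self.sample_ids), cd.n_snps):
            raise ValueError(
                f"dosage matrix shape {cd.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {cd.n_snps} SNPs on {chrom}"
            )
        ok = (cd.dosages >= 0) & (cd.dosages <= 2) | (cd.dosages == MISSING)
        if not ok.all():
            raise ValueError(f"dosage outside {{0,1,2,MISSING}} on {chrom}")

    # -- basic accessors ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.chrom_lengths)

    @property
    def n_snps(self) -> int:
        return sum(cd.n_snps for cd in self.data.values())

    def sample_indices(self, samples) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in samples], dtype=np.intp)
        except KeyError as e:
            raise KeyError(f"unknown sample id {e.args[0]!r}") from None

    def snp_slice(self, region: GenomicRegion) -> slice:
        """Column slice of SNPs inside ``region`` on its chromosome."""
        pos = self.data[region.chrom].positions
        lo = int(np.searchsorted(pos, region.start, side="left"))
        hi = int(np.searchsorted(pos, region.end, side="right"))
        return slice(lo, hi)

    def dosages(self, chrom, region=None, samples=None) -> np.ndarray:
        """ALT-allele dosage matrix (samples x SNPs) for a chromosome/region."""
        cd = self.data[chrom]
        G = cd.dosages
        if region is not None:
            G = G[:, self.snp_slice(region)]
        if samples is not None:
            G = G[self.sample_indices(samples), :]
        return G

    def derived_dosages(self, chrom, region=None, samples=None):
        """Derived-allele dosage matrix plus the per-SNP ``ancestral_known`` mask.

        Where the ancestral allele is ALT, dosage is recoded 2 - ALT dosage
        (MISSING preserved). Columns where the ancestral state is unknown are
        returned unchanged but flagged False in the mask.
        """
        cd = self.data[chrom]
        sl = self.snp_slice(region) if region is not None else slice(None)
        G = cd.dosages[:, sl]
        if samples is not None:
            G = G[self.sample_indices(samples), :]
        known = cd.ancestral_known[sl]
        flip = cd.ancestral_is_alt[sl] & known
        D = G.copy()
        cols = np.where(flip)[0]
        sub = D[:, cols]
        miss = sub == MISSING
        sub = (2 - sub).astype(np.int8)
        sub[miss] = MISSING
        D[:, cols] = sub
        return D, known.copy()

    def has_polarization(self) -> bool:
        return any(cd.ancestral_known.any() for cd in self.data.values())


@dataclass
class SampleMetadata:
    """Per-sample metadata table.

    Wraps a DataFrame indexed by sample id with columns: species, clade, sex
    (male/female/unknown), generation, parent1, parent2, depth_m.
    """

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    COLUMNS = ("species", "clade", "sex", "generation", "parent1", "parent2", "depth_m")

    def __post_init__(self):
        for col in self.COLUMNS:
            if col not in self.table.columns:
                self.table[col] = np.nan if col == "depth_m" else ""
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise ValueError(f"duplicate sample id in metadata: {dup!r}")
        # pedigree parents, when present, must exist in the table
        for col in ("parent1", "parent2"):
            parents = self.table[col].astype(str)
            known = parents.isin(self.table.index.astype(str)) | parents.isin(("", "nan"))
            if not known.all():
                missing = parents[~known].iloc[0]
                raise ValueError(f"pedigree parent {missing!r} not in metadata")

    @property
    def samples(self) -> list[str]:
        return list(self.table.index)

    def samples_for(self, column: str, value) -> list[str]:
        return list(self.table.index[self.table[column] == value])

    def species_of(self, sample: str) -> str:
        return str(self.table.loc[sample, "species"])

    def sex_of(self, sample: str) -> str:
        return str(self.table.loc[sample, "sex"]) or "unknown"

    @classmethod
    def read_tsv(cls, path) -> "SampleMetadata":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        if "sample" not in df.columns:
            raise ValueError("metadata TSV must have a 'sample' column")
        df = df.set_index("sample")
        if "depth_m" in df.columns:
            df["depth_m"] = pd.to_numeric(df["depth_m"], errors="coerce")
        return cls(df)

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="sample")


# -- VCF -------------------------------------------------------------------


def read_vcf(path, region: GenomicRegion | None = None, sample_subset=None) -> GenotypeDataset:
    """Read biallelic SNPs from a VCF into a :class:`GenotypeDataset`.

    Multi-allelic records and indels are dropped (count logged). Genotype
    ``./.`` becomes :data:`MISSING`. Raises on unsorted positions and on
    unknown sample ids in ``sample_subset``.

    Coding-effect classes are read from an ``EFF`` INFO field when present
    (values: synonymous/nonsynonymous/noncoding), else left "unknown".
    Ancestral alleles are read from an ``AA`` INFO field when present.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    all_samples = list(vcf.samples)
    if sample_subset is not None:
        unknown = [s for s in sample_subset if s not in all_samples]
        if unknown:
            raise KeyError(f"sample subset contains unknown ids: {unknown}")
        keep = np.array([all_samples.index(s) for s in sample_subset], dtype=np.intp)
        samples = list(sample_subset)
    else:
        keep = np.arange(len(all_samples), dtype=np.intp)
        samples = all_samples

    chrom_lengths: dict[str, int] = {}
    for name, length in zip(vcf.seqnames, vcf.seqlens or []):
        chrom_lengths[name] = int(length)

    per_chrom: dict[str, dict[str, list]] = {}
    n_dropped = 0
    # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
    gt_map = np.array([0, 1, MISSING, 2], dtype=np.int8)
    last_pos: dict[str, int] = {}
    for v in vcf:
        if region is not None and (
            v.CHROM != region.chrom or not (region.start <= v.POS <= region.end)
        ):
            continue
        if len(v.ALT) != 1 or not v.is_snp:
            n_dropped += 1
            continue
        prev = last_pos.get(v.CHROM, 0)
        if v.POS <= prev:
            raise ValueError(
                f"VCF not sorted: {v.CHROM} position {v.POS} after {prev}"
            )
        last_pos[v.CHROM] = v.POS
        rec = per_chrom.setdefault(
            v.CHROM,
            {"pos": [], "dos": [], "ref": [], "alt": [], "aa": [], "eff": []},
        )
        rec["pos"].append(v.POS)
        rec["dos"].append(gt_map[np.asarray(v.gt_types)][keep])
        rec["ref"].append(v.REF)
        rec["alt"].append(v.ALT[0])
        rec["aa"].append(v.INFO.get("AA") or "")
        rec["eff"].append(v.INFO.get("EFF") or "")
    vcf.close()
    if n_dropped:
        logger.info("read_vcf: dropped %d non-biallelic-SNP records", n_dropped)

    data = {}
    for chrom, rec in per_chrom.items():
        pos = np.array(rec["pos"], dtype=np.int64)
        dos = np.vstack(rec["dos"]).T.astype(np.int8)  # samples x snps
        ref = np.array(rec["ref"], dtype="U8")
        alt = np.array(rec["alt"], dtype="U8")
        aa = np.array(rec["aa"], dtype="U8")
        known = aa != ""
        is_alt = known & (aa == alt)
        eff = np.array(
            [EFFECT_CODES.get(e, EFFECT_UNKNOWN) for e in rec["eff"]], dtype=np.int8
        )
        if chrom not in chrom_lengths:
            chrom_lengths[chrom] = int(pos[-1])
        data[chrom] = ChromosomeData(pos, dos, ref, alt, known, is_alt, eff)

    # keep declared chromosome ordering; restrict to chroms seen or declared
    if not chrom_lengths:
        chrom_lengths = {c: int(d.positions[-1]) for c, d in data.items()}
    ds = GenotypeDataset(samples, chrom_lengths, data)
    ds.n_dropped_records = n_dropped
    return ds


def write_vcf(dataset: GenotypeDataset, path) -> None:
    """Write the dataset as an uncompressed VCF 4.2 text file.

    Ancestral alleles go to the ``AA`` INFO field and effect classes to
    ``EFF``, so that :func:`read_vcf` round-trips the dataset exactly.
    """
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", int(MISSING): "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in dataset.chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##INFO=<ID=EFF,Number=1,Type=String,Description="Coding effect class">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(dataset.sample_ids)
            + "\n"
        )
        for chrom in dataset.chromosomes:
            cd = dataset.data[chrom]
            for j in range(cd.n_snps):
                info = []
                if cd.ancestral_known[j]:
                    info.append(f"AA={cd.alt[j] if cd.ancestral_is_alt[j] else cd.ref[j]}")
                eff = EFFECT_NAMES[int(cd.effect[j])]
                if eff != "unknown":
                    info.append(f"EFF={eff}")
                gts = "\t".join(gt_strings[int(d)] for d in cd.dosages[:, j])
                fh.write(
                    f"{chrom}\t{cd.positions[j]}\t.\t{cd.ref[j]}\t{cd.alt[j]}"
                    f"\t.\tPASS\t{';'.join(info) or '.'}\tGT\t{gts}\n"
                )


# -- internal table TSV round-trip ------------------------------------------


def write_dataset_tsv(dataset: GenotypeDataset, path) -> None:
    """Write the internal SNP table as TSV (one row per SNP)."""
    rows = []
    for chrom in dataset.chromosomes:
        cd = dataset.data[chrom]
        for j in range(cd.n_snps):
            rows.append(
                (
                    chrom,
                    int(cd.positions[j]),
                    cd.ref[j],
                    cd.alt[j],
                    ("A" if cd.ancestral_is_alt[j] else "R") if cd.ancestral_known[j] else ".",
                    EFFECT_NAMES[int(cd.effect[j])],
                    ",".join(str(int(d)) for d in cd.dosages[:, j]),
                )
            )
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "ancestral", "effect", "dosages"]
    )
    header = "#samples=" + ",".join(dataset.sample_ids)
    lengths = "#lengths=" + ",".join(
        f"{c}:{l}" for c, l in dataset.chrom_lengths.items()
    )
    with open(path, "w") as fh:
        fh.write(header + "\n" + lengths + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_dataset_tsv(path) -> GenotypeDataset:
    with open(path) as fh:
        samples = fh.readline().strip().removeprefix("#samples=").split(",")
        lengths_line = fh.readline().strip().removeprefix("#lengths=")
        chrom_lengths = {}
        for part in lengths_line.split(","):
            c, l = part.rsplit(":", 1)
            chrom_lengths[c] = int(l)
        df = pd.read_csv(fh, sep="\t", dtype=str)
    data = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        pos = sub["pos"].astype(np.int64).to_numpy()
        dos = np.array(
            [[np.int8(x) for x in row.split(",")] for row in sub["dosages"]],
            dtype=np.int8,
        ).T
        anc = sub["ancestral"].to_numpy()
        data[chrom] = ChromosomeData(
            positions=pos,
            dosages=dos,
            ref=sub["ref"].to_numpy(dtype="U8"),
            alt=sub["alt"].to_numpy(dtype="U8"),
            ancestral_known=anc != ".",
            ancestral_is_alt=anc == "A",
            effect=np.array([EFFECT_CODES[e] for e in sub["effect"]], dtype=np.int8),
        )
    return GenotypeDataset(samples, chrom_lengths, data)


# -- polarization ------------------------------------------------------------


def polarize(
    dataset: GenotypeDataset,
    outgroup_samples,
    min_outgroup_agreement: float = 1.0,
) -> GenotypeDataset:
    """Assign ancestral alleles from outgroup genotypes.

    The ancestral allele is the allele whose frequency among non-missing
    outgroup haplotypes is >= ``min_outgroup_agreement``; otherwise the SNP
    stays unpolarized. All-missing outgroup at a SNP leaves it unpolarized.
    Idempotent: re-applying with the same outgroups changes nothing.
    """
    if not outgroup_samples:
        raise ValueError("polarize requires at least one outgroup sample")
    idx = dataset.sample_indices(outgroup_samples)
    data = {}
    for chrom in dataset.chromosomes:
        cd = dataset.data[chrom]
        G = cd.dosages[idx, :].astype(np.float64)
        G[G == MISSING] = np.nan
        n_hap = 2 * np.sum(~np.isnan(G), axis=0)
        alt_count = np.nansum(G, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f_alt = np.where(n_hap > 0, alt_count / np.maximum(n_hap, 1), np.nan)
        anc_ref = (n_hap > 0) & (1 - f_alt >= min_outgroup_agreement)
        anc_alt = (n_hap > 0) & (f_alt >= min_outgroup_agreement) & ~anc_ref
        known = anc_ref | anc_alt
        data[chrom] = ChromosomeData(
            positions=cd.positions.copy(),
            dosages=cd.dosages.copy(),
            ref=cd.ref.copy(),
            alt=cd.alt.copy(),
            ancestral_known=known,
            ancestral_is_alt=anc_alt,
            effect=cd.effect.copy(),
        )
    return GenotypeDataset(dataset.sample_ids, dataset.chrom_lengths, data)


# -- BED --------------------------------------------------------------------


def write_regions_bed(regions, path) -> None:
    """Write regions as BED3 (0-based half-open), input order preserved."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\n")


def read_regions_bed(path) -> list[GenomicRegion]:
    regions = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end = line.split()[:3]
            regions.append(GenomicRegion(chrom, int(start) + 1, int(end)))
    return regions
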