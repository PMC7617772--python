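"""Synthetic datasets with planted truth for inversion analyses.

Three generators:

* :func:`simulate_radiation` — a coalescent (msprime) backbone of clades
  splitting on a fixed tree, with planted non-recombining inversion regions
  (two haplotype classes diverged at an origin time), optional introgression
  (mass-migration) events and optional XY-like sex linkage.
* :func:`simulate_cross` — an interspecific pedigree (founders, F1, F2, F3)
  with Poisson crossovers outside, and zero crossovers inside, a suppressed
  region in region-heterozygous parents; true crossover positions recorded.
* :func:`simulate_selection_forward` — a minimal discrete-generation
  Wright-Fisher forward simulator of coding variation on two non-recombining
  inversion backgrounds, with per-mutation selection coefficients.

All three are byte-reproducible given their seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (
    EFFECT_CODES,
    EFFECT_NAMES,
    ChromosomeData,
    GenomicRegion,
    GenotypeDataset,
    SampleMetadata,
)

logger = logging.getLogger(__name__)

_SEED_MOD = 2**31 - 1


def _derive_seed(rng: np.random.Generator) -> int:
    """A fresh positive msprime-compatible seed."""
    return int(rng.integers(1, _SEED_MOD))


# --------------------------------------------------------------------------
# Scenario specification
# --------------------------------------------------------------------------


@dataclass
class CladeSpec:
    """A sampled clade/species: name, number of diploid samples, diploid Ne."""

    name: str
    n: int
    ne: float


@dataclass
class SplitSpec:
    """Population split: ``derived`` clades merge into ``ancestral`` at ``time``
    generations ago. ``ancestral`` is created with diploid size ``ne``."""

    time: float
    derived: list[str]
    ancestral: str
    ne: float


@dataclass
class IntrogressionSpec:
    """Pulse admixture: at ``time`` generations ago a ``fraction`` of the
    recipient clade's ancestry is replaced by the donor clade."""

    time: float
    donor: str
    recipient: str
    fraction: float


@dataclass
class InversionSpec:
    """A planted inversion polymorphism.

    The two orientation classes ("inverted" / "ancestral") are simulated as
    two populations that split ``origin_time`` generations ago and do not
    recombine with each other; ``gene_flux`` is an optional low symmetric
    migration rate between classes mimicking rare double crossovers /
    gene conversion. ``freqs`` maps clade name -> inverted-haplotype
    frequency (clades absent from the map carry frequency 0). With
    ``sex_linked`` (XY-like, ancestral orientation acting as Y), males in
    carrier clades are forced heterozygous and females homozygous inverted.
    """

    region: GenomicRegion
    origin_time: float
    freqs: dict[str, float] = field(default_factory=dict)
    class_ne: float | None = None
    gene_flux: float = 0.0
    sex_linked: bool = False
    name: str = ""

    def __post_init__(self):
        if not self.name:
            self.name = f"inv_{self.region.chrom}_{self.region.start}"
        for clade, f in self.freqs.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"inversion frequency {f} for {clade} not in [0,1]")


@dataclass
class RadiationScenario:
    """Full specification of a synthetic radiation dataset."""

    clades: list[CladeSpec]
    splits: list[SplitSpec]
    chromosomes: list[tuple[str, int]]
    mutation_rate: float = 3e-9
    recombination_rate: float = 1e-8
    inversions: list[InversionSpec] = field(default_factory=list)
    introgressions: list[IntrogressionSpec] = field(default_factory=list)
    # clades outside the radiation: inside inversion regions their haplotypes
    # descend from the ancestral-orientation lineage, splitting from it at
    # their own (clade) split time, which must postdate the inversion origin
    outgroup_clades: list[str] = field(default_factory=list)
    # fraction of SNPs annotated noncoding / synonymous / nonsynonymous
    effect_fractions: tuple[float, float, float] = (0.90, 0.035, 0.065)
    seed: int = 1

    def validate(self) -> None:
        names = [c.name for c in self.clades]
        if len(set(names)) != len(names):
            raise ValueError("duplicate clade names")
        if self.mutation_rate <= 0:
            raise ValueError("mutation rate must be positive")
        for spl in self.splits:
            if spl.time <= 0:
                raise ValueError("split times must be positive")
        for inv in self.inversions:
            if inv.origin_time <= 0:
                raise ValueError(
                    f"inversion {inv.name}: frequency > 0 requires a positive "
                    "origin time"
                )
            if dict(inv.freqs) and inv.region.chrom not in dict(self.chromosomes):
                raise ValueError(f"inversion {inv.name} on unknown chromosome")
            for clade in self.outgroup_clades:
                if inv.freqs.get(clade, 0.0) > 0:
                    raise ValueError(
                        f"outgroup clade {clade} cannot carry inversion {inv.name}"
                    )
        for ev in self.introgressions:
            if not 0 <= ev.fraction <= 1:
                raise ValueError("introgression fraction must be in [0,1]")

    def clade_split_time(self, name: str) -> float:
        """Time at which a tip clade first merges into an ancestor (its age)."""
        times = [s.time for s in self.splits if name in s.derived]
        return min(times) if times else 0.0


@dataclass
class TruthTables:
    """Planted truth emitted alongside every synthetic dataset."""

    # sample x inversion-name -> genotype in {0,1,2}
    inversion_genotypes: pd.DataFrame = field(default_factory=pd.DataFrame)
    # chrom -> per-SNP background class of the derived allele
    # ("inverted" / "ancestral" / "both" / "" for backbone SNPs)
    snp_background: dict[str, np.ndarray] = field(default_factory=dict)
    # sample -> list of true crossover positions (bp), pedigree sims only
    crossovers: dict[str, list[int]] = field(default_factory=dict)
    # forward-simulation mutation table
    mutations: pd.DataFrame = field(default_factory=pd.DataFrame)

    def write_tsvs(self, prefix) -> None:
        if len(self.inversion_genotypes):
            self.inversion_genotypes.to_csv(
                f"{prefix}.inversion_genotypes.tsv", sep="\t", index_label="sample"
            )
        if self.crossovers:
            with open(f"{prefix}.crossovers.tsv", "w") as fh:
                fh.write("sample\tpositions\n")
                for s, xs in self.crossovers.items():
                    fh.write(f"{s}\t{','.join(map(str, xs))}\n")
        if len(self.mutations):
            self.mutations.to_csv(f"{prefix}.mutations.tsv", sep="\t", index=False)


# --------------------------------------------------------------------------
# Radiation simulator
# --------------------------------------------------------------------------


def _build_demography(scenario: RadiationScenario):
    import msprime

    demog = msprime.Demography()
    for clade in scenario.clades:
        demog.add_population(name=clade.name, initial_size=clade.ne)
    for spl in sorted(scenario.splits, key=lambda s: s.time):
        demog.add_population(name=spl.ancestral, initial_size=spl.ne)
        demog.add_population_split(
            time=spl.time, derived=list(spl.derived), ancestral=spl.ancestral
        )
    for ev in scenario.introgressions:
        demog.add_mass_migration(
            time=ev.time, source=ev.recipient, dest=ev.donor, proportion=ev.fraction
        )
    demog.sort_events()
    return demog


def _sim_genotypes(demog, sample_sets, length, recomb, mu, seed_a, seed_m, ploidy=2):
    """Run msprime and return (positions 1-based, haplotype matrix sites x haps)."""
    import msprime

    ts = msprime.sim_ancestry(
        samples=sample_sets,
        demography=demog,
        sequence_length=length,
        recombination_rate=recomb,
        random_seed=seed_a,
        ploidy=ploidy,
    )
    mts = msprime.sim_mutations(
        ts, rate=mu, random_seed=seed_m, model=msprime.BinaryMutationModel()
    )
    H = mts.genotype_matrix()  # sites x haplotypes, 0/1
    pos = np.array([int(s.position) + 1 for s in mts.sites()], dtype=np.int64)
    # drop sites that ended up invariant (possible via back mutation)
    seg = (H.sum(axis=1) > 0) & (H.sum(axis=1) < H.shape[1])
    return pos[seg], H[seg].astype(np.int8)


def _inversion_genotype_draw(inv, clade, sex, rng):
    f = inv.freqs.get(clade, 0.0)
    if f == 0.0:
        return 0
    if inv.sex_linked:
        return 1 if sex == "male" else 2
    return int(rng.binomial(2, f))


def simulate_radiation(scenario: RadiationScenario):
    """Simulate a multi-clade SNP dataset with planted inversions.

    Returns ``(GenotypeDataset, SampleMetadata, TruthTables)``. Inside every
    inversion region the two orientation classes never recombine with each
    other (they are separate coalescent populations joined ``origin_time``
    generations ago), so heterokaryotypes show elevated heterozygosity and
    between-class divergence exceeds the genome background whenever the
    origin time is large relative to Ne.
    """
    import msprime

    scenario.validate()
    rng = np.random.default_rng(scenario.seed)

    sample_ids, species, clades_of = [], [], []
    for clade in scenario.clades:
        for i in range(clade.n):
            sample_ids.append(f"{clade.name}_{i:03d}")
            species.append(clade.name)
            clades_of.append(clade.name)
    sexes = rng.choice(["female", "male"], size=len(sample_ids)).tolist()

    demog = _build_demography(scenario)
    sample_sets = [
        msprime.SampleSet(c.n, population=c.name, ploidy=2) for c in scenario.clades
    ]

    # planted genotypes per inversion
    truth_gt = pd.DataFrame(index=sample_ids, dtype=int)
    for inv in scenario.inversions:
        truth_gt[inv.name] = [
            _inversion_genotype_draw(inv, cl, sx, rng)
            for cl, sx in zip(clades_of, sexes)
        ]

    mean_ne = float(np.mean([c.ne for c in scenario.clades]))
    chrom_lengths = dict(scenario.chromosomes)
    data: dict[str, ChromosomeData] = {}
    snp_background: dict[str, np.ndarray] = {}

    for chrom, length in scenario.chromosomes:
        pos, H = _sim_genotypes(
            demog,
            sample_sets,
            length,
            scenario.recombination_rate,
            scenario.mutation_rate,
            _derive_seed(rng),
            _derive_seed(rng),
        )
        G = (H[:, ::2] + H[:, 1::2]).T.astype(np.int8)  # samples x snps
        background = np.full(len(pos), "", dtype="U9")

        for inv in scenario.inversions:
            if inv.region.chrom != chrom:
                continue
            keep = ~inv.region.contains(pos)
            pos, G, background = pos[keep], G[:, keep], background[keep]
            ipos, iG, ibg = _simulate_inversion_region(
                scenario, inv, truth_gt[inv.name].to_numpy(), clades_of, mean_ne, rng
            )
            order_pos = np.concatenate([pos, ipos])
            order = np.argsort(order_pos, kind="stable")
            pos = order_pos[order]
            G = np.concatenate([G, iG], axis=1)[:, order]
            background = np.concatenate([background, ibg])[order]

        # deduplicate any coincident positions (backbone vs inserted region edge)
        uniq = np.concatenate([[True], np.diff(pos) > 0])
        pos, G, background = pos[uniq], G[:, uniq], background[uniq]

        n = len(pos)
        effect = rng.choice(
            [EFFECT_CODES["noncoding"], EFFECT_CODES["synonymous"],
             EFFECT_CODES["nonsynonymous"]],
            size=n,
            p=list(scenario.effect_fractions),
        ).astype(np.int8)
        data[chrom] = ChromosomeData(
            positions=pos,
            dosages=G,
            ref=np.full(n, "A", dtype="U8"),
            alt=np.full(n, "T", dtype="U8"),
            # truth polarization available: the simulated ancestral allele is REF
            ancestral_known=np.zeros(n, dtype=bool),
            ancestral_is_alt=np.zeros(n, dtype=bool),
            effect=effect,
        )
        snp_background[chrom] = background

    dataset = GenotypeDataset(sample_ids, chrom_lengths, data)
    meta = SampleMetadata(
        pd.DataFrame(
            {
                "species": species,
                "clade": clades_of,
                "sex": sexes,
                "generation": "",
                "parent1": "",
                "parent2": "",
                "depth_m": np.nan,
            },
            index=sample_ids,
        )
    )
    truth = TruthTables(inversion_genotypes=truth_gt, snp_background=snp_background)
    return dataset, meta, truth


def _simulate_inversion_region(scenario, inv, genotypes, clades_of, mean_ne, rng):
    """Coalescent simulation of one inversion region.

    The two orientation classes are populations split at the inversion origin
    with no migration between them (besides optional ``gene_flux``). Clades
    listed in ``scenario.outgroup_clades`` carry haplotypes descending from
    the ancestral-orientation lineage, splitting from it at their own clade
    split time (an old, trans-radiation inversion polymorphism): the outgroup
    is therefore genuinely closer to the non-inverted class, which is what
    makes outgroup-based orientation polarity meaningful.

    Returns (positions, dosage matrix samples x snps, background labels).
    """
    import msprime

    outgroups = set(scenario.outgroup_clades)
    is_out = np.array([c in outgroups for c in clades_of])
    n_inv_haps = int(genotypes[~is_out].sum())
    n_anc_haps = int(2 * (~is_out).sum() - n_inv_haps)
    n_out_haps = int(2 * is_out.sum())
    class_ne = inv.class_ne if inv.class_ne is not None else mean_ne / 2

    demog = msprime.Demography()
    demog.add_population(name="inverted", initial_size=class_ne)
    demog.add_population(name="ancestral", initial_size=class_ne)
    demog.add_population(name="root", initial_size=mean_ne)
    if inv.gene_flux > 0:
        demog.set_symmetric_migration_rate(["inverted", "ancestral"], inv.gene_flux)
    sample_sets = [
        msprime.SampleSet(n_inv_haps, population="inverted", ploidy=1),
        msprime.SampleSet(n_anc_haps, population="ancestral", ploidy=1),
    ]
    if n_out_haps:
        t_out = min(scenario.clade_split_time(c) for c in outgroups)
        # the outgroup lineage must split after the inversion arose
        t_out = min(t_out, 0.8 * inv.origin_time)
        demog.add_population(name="outlin", initial_size=mean_ne)
        demog.add_population(name="anc_stem", initial_size=class_ne)
        demog.add_population_split(
            time=t_out, derived=["ancestral", "outlin"], ancestral="anc_stem"
        )
        demog.add_population_split(
            time=inv.origin_time, derived=["inverted", "anc_stem"], ancestral="root"
        )
        sample_sets.append(msprime.SampleSet(n_out_haps, population="outlin", ploidy=1))
    else:
        demog.add_population_split(
            time=inv.origin_time, derived=["inverted", "ancestral"], ancestral="root"
        )
    demog.sort_events()
    pos0, H = _sim_genotypes(
        demog,
        sample_sets,
        inv.region.length,
        scenario.recombination_rate,
        scenario.mutation_rate,
        _derive_seed(rng),
        _derive_seed(rng),
        ploidy=1,
    )
    pos = pos0 + inv.region.start - 1
    inside = pos <= inv.region.end
    pos, H = pos[inside], H[inside]

    # assign haplotypes to samples: class queues for ingroup, outgroup queue
    inv_queue = iter(range(n_inv_haps))
    anc_queue = iter(range(n_inv_haps, n_inv_haps + n_anc_haps))
    out_queue = iter(range(n_inv_haps + n_anc_haps, n_inv_haps + n_anc_haps + n_out_haps))
    n_samples = len(genotypes)
    G = np.zeros((n_samples, len(pos)), dtype=np.int8)
    for i, g in enumerate(genotypes):
        if is_out[i]:
            hap_idx = [next(out_queue), next(out_queue)]
        else:
            hap_idx = [next(inv_queue) for _ in range(g)] + [
                next(anc_queue) for _ in range(2 - g)
            ]
        G[i, :] = H[:, hap_idx].sum(axis=1)

    on_inv = H[:, :n_inv_haps].sum(axis=1) > 0
    on_anc = H[:, n_inv_haps : n_inv_haps + n_anc_haps].sum(axis=1) > 0
    background = np.where(
        on_inv & on_anc,
        "both",
        np.where(on_inv, "inverted", np.where(on_anc, "ancestral", "none")),
    ).astype("U9")
    return pos, G, background


# --------------------------------------------------------------------------
# Pedigree cross simulator
# --------------------------------------------------------------------------


def simulate_cross(
    founderA_genotype: np.ndarray,
    founderB_genotype: np.ndarray,
    n_F2: int,
    n_F3: int,
    positions: np.ndarray,
    chrom_length: int,
    recomb_rate: float,
    suppressed_region: GenomicRegion,
    seed: int = 1,
    chrom: str = "chr1",
):
    """Simulate an interspecific cross with a recombination-suppressed region.

    Founders must be homozygous at every marker (dosage 0 or 2) and carry
    opposite orientations in ``suppressed_region``. Gametes of parents that
    are heterozygous across the suppressed region carry zero crossovers
    inside it and Poisson-distributed crossovers elsewhere (rate
    ``recomb_rate`` Morgans/bp); homokaryotypic parents recombine freely.

    Returns ``(GenotypeDataset, SampleMetadata, TruthTables)`` containing the
    two founders, two F1s, ``n_F2`` F2s and ``n_F3`` F3s.
    """
    positions = np.asarray(positions, dtype=np.int64)
    fa = np.asarray(founderA_genotype, dtype=np.int8)
    fb = np.asarray(founderB_genotype, dtype=np.int8)
    if suppressed_region.chrom != chrom or suppressed_region.end > chrom_length:
        raise ValueError("suppressed_region outside the simulated chromosome")
    if np.any(fa == 1) or np.any(fb == 1):
        raise ValueError("founders must be homozygous at every marker")
    in_region = suppressed_region.contains(positions)
    if not np.all(fa[in_region] != fb[in_region]):
        raise ValueError("founders must be homozygous for opposite orientations")

    rng = np.random.default_rng(seed)
    # a haplotype = per-marker founder-origin (0 = founder A, 1 = founder B)
    hapA = np.zeros(len(positions), dtype=np.int8)
    hapB = np.ones(len(positions), dtype=np.int8)
    allele = np.stack([fa // 2, fb // 2])  # origin -> ALT allele count per marker

    def region_class(hap):
        # origin label of the haplotype inside the suppressed region
        return int(np.round(hap[in_region].mean())) if in_region.any() else 0

    def gamete(h1, h2):
        """One meiosis; returns (haplotype, crossover positions)."""
        heterokaryo = region_class(h1) != region_class(h2)
        if heterokaryo:
            spans = [
                (1, suppressed_region.start - 1),
                (suppressed_region.end + 1, chrom_length),
            ]
        else:
            spans = [(1, chrom_length)]
        xovers = []
        for lo, hi in spans:
            if hi < lo:
                continue
            k = rng.poisson(recomb_rate * (hi - lo + 1))
            xovers.extend(int(x) for x in rng.integers(lo, hi + 1, size=k))
        xovers.sort()
        phase = int(rng.integers(2))
        hap = np.empty_like(h1)
        haps = (h1, h2)
        prev = 0
        cuts = np.searchsorted(positions, np.array(xovers + [chrom_length + 1]))
        for cut in cuts:
            hap[prev:cut] = haps[phase][prev:cut]
            phase ^= 1
            prev = cut
        return hap, xovers

    individuals = {}  # name -> (h1, h2)
    meta_rows = []
    crossovers: dict[str, list[int]] = {}

    def add(name, h1, h2, generation, p1="", p2="", xo=()):
        individuals[name] = (h1, h2)
        meta_rows.append((name, generation, p1, p2))
        crossovers[name] = sorted(xo)

    add("founderA", hapA.copy(), hapA.copy(), "founder")
    add("founderB", hapB.copy(), hapB.copy(), "founder")
    for i in range(2):
        add(f"F1_{i}", hapA.copy(), hapB.copy(), "F1", "founderA", "founderB")

    def breed(name, p1, p2, generation):
        g1, x1 = gamete(*individuals[p1])
        g2, x2 = gamete(*individuals[p2])
        add(name, g1, g2, generation, p1, p2, x1 + x2)

    for i in range(n_F2):
        breed(f"F2_{i:03d}", "F1_0", "F1_1", "F2")
    f2_names = [f"F2_{i:03d}" for i in range(n_F2)]
    for i in range(n_F3):
        p1, p2 = rng.choice(f2_names, size=2, replace=False)
        breed(f"F3_{i:03d}", p1, p2, "F3")

    names = list(individuals)
    G = np.array(
        [allele[individuals[n][0], np.arange(len(positions))]
         + allele[individuals[n][1], np.arange(len(positions))]
         for n in names],
        dtype=np.int8,
    )
    n = len(positions)
    data = {
        chrom: ChromosomeData(
            positions=positions,
            dosages=G,
            ref=np.full(n, "A", dtype="U8"),
            alt=np.full(n, "T", dtype="U8"),
            ancestral_known=np.zeros(n, dtype=bool),
            ancestral_is_alt=np.zeros(n, dtype=bool),
            effect=np.full(n, EFFECT_CODES["unknown"], dtype=np.int8),
        )
    }
    dataset = GenotypeDataset(names, {chrom: chrom_length}, data)
    meta = SampleMetadata(
        pd.DataFrame(
            {
                "species": ["cross"] * len(names),
                "clade": ["cross"] * len(names),
                "sex": ["unknown"] * len(names),
                "generation": [r[1] for r in meta_rows],
                "parent1": [r[2] for r in meta_rows],
                "parent2": [r[3] for r in meta_rows],
                "depth_m": np.nan,
            },
            index=names,
        )
    )
    # truth genotype at the suppressed region: count of founder-B-origin
    # region haplotypes (founder B carries the "inverted" orientation)
    region_gt = {
        name: region_class(h1) + region_class(h2)
        for name, (h1, h2) in individuals.items()
    }
    truth = TruthTables(
        inversion_genotypes=pd.DataFrame(
            {suppressed_region.chrom: pd.Series(region_gt)}
        ),
        crossovers=crossovers,
    )
    return dataset, meta, truth


# --------------------------------------------------------------------------
# Forward Wright-Fisher simulator for selection on inversion backgrounds
# --------------------------------------------------------------------------


@dataclass
class ForwardSimConfig:
    """Configuration for the two-background forward simulator.

    ``ns_site_ratio`` is the nonsynonymous:synonymous site ratio per gene;
    ``f_beneficial`` is the fraction of nonsynonymous mutations arising on
    the *inverted* background that are beneficial (coefficient
    ``s_beneficial``); all other nonsynonymous mutations take
    ``s_deleterious``. Synonymous and noncoding mutations are neutral.
    The inversion polymorphism itself is held at constant frequency
    (``inv_freq``), i.e. the two backgrounds are fixed-size subpopulations;
    within a background sites evolve independently (free recombination),
    between backgrounds there is no exchange.
    """

    ne: int = 1000
    n_genes: int = 100
    ns_site_ratio: float = 2.8
    s_beneficial: float = 0.05
    s_deleterious: float = -0.01
    f_beneficial: float = 0.1
    generations: int = 4000
    inv_freq: float = 0.5
    seed: int = 1
    gene_length_codons: int = 300
    mutation_rate: float = 2.5e-7  # per site per haplotype per generation
    noncoding_sites: int = 100_000

    def validate(self):
        if self.ne < 2:
            raise ValueError("Ne must be >= 2")
        for name in ("f_beneficial", "inv_freq"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1]")

    @property
    def coding_sites(self) -> int:
        return 3 * self.gene_length_codons * self.n_genes

    @property
    def l_nonsyn(self) -> float:
        return self.coding_sites * self.ns_site_ratio / (1 + self.ns_site_ratio)

    @property
    def l_syn(self) -> float:
        return self.coding_sites / (1 + self.ns_site_ratio)


_STATUS = ("lost", "polymorphic", "fixed_inverted", "fixed_ancestral")


def simulate_selection_forward(config: ForwardSimConfig) -> pd.DataFrame:
    """Forward Wright-Fisher simulation of mutations on two inversion backgrounds.

    Returns a mutation table with one row per mutation that ever arose:
    ``effect`` (synonymous/nonsynonymous/noncoding), ``background`` (origin),
    ``s``, ``freq_inverted``, ``freq_ancestral`` and ``status`` (lost /
    polymorphic / fixed_inverted / fixed_ancestral). The frame's ``attrs``
    carry the site counts ``L_n``, ``L_s``, ``L_nc`` used for normalisation.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_i = int(round(2 * config.ne * config.inv_freq))
    n_a = 2 * config.ne - n_i
    sizes = {"inverted": n_i, "ancestral": n_a}
    l_n, l_s, l_nc = config.l_nonsyn, config.l_syn, float(config.noncoding_sites)
    total_l = l_n + l_s + l_nc
    class_p = np.array([l_n, l_s, l_nc]) / total_l
    class_codes = np.array(
        [EFFECT_CODES["nonsynonymous"], EFFECT_CODES["synonymous"],
         EFFECT_CODES["noncoding"]]
    )

    finished = {"effect": [], "background": [], "s": [], "count": [], "status": []}
    active = {
        bg: {
            "count": np.empty(0, dtype=np.int64),
            "s": np.empty(0, dtype=np.float64),
            "effect": np.empty(0, dtype=np.int8),
        }
        for bg in sizes
    }

    def flush(bg, state, absorbed_mask, status_of):
        idx = np.where(absorbed_mask)[0]
        for i in idx:
            finished["effect"].append(int(state["effect"][i]))
            finished["background"].append(bg)
            finished["s"].append(float(state["s"][i]))
            finished["count"].append(int(state["count"][i]))
            finished["status"].append(status_of(int(state["count"][i])))
        keep = ~absorbed_mask
        for key in state:
            state[key] = state[key][keep]

    for _ in range(config.generations):
        for bg, nb in sizes.items():
            if nb == 0:
                continue
            state = active[bg]
            # new mutations
            k = rng.poisson(nb * config.mutation_rate * total_l)
            if k:
                eff = class_codes[rng.choice(3, size=k, p=class_p)]
                s = np.zeros(k)
                nonsyn = eff == EFFECT_CODES["nonsynonymous"]
                s[nonsyn] = config.s_deleterious
                if bg == "inverted":
                    beneficial = nonsyn & (rng.random(k) < config.f_beneficial)
                    s[beneficial] = config.s_beneficial
                state["count"] = np.concatenate([state["count"], np.ones(k, dtype=np.int64)])
                state["s"] = np.concatenate([state["s"], s])
                state["effect"] = np.concatenate([state["effect"], eff.astype(np.int8)])
            if len(state["count"]) == 0:
                continue
            c, s = state["count"], state["s"]
            w = c * (1.0 + s)
            p = w / (w + (nb - c))
            state["count"] = rng.binomial(nb, p)
            absorbed = (state["count"] == 0) | (state["count"] == nb)
            if absorbed.any():
                status_of = (
                    lambda cnt, nb=nb, bg=bg: "lost" if cnt == 0 else f"fixed_{bg}"
                )
                flush(bg, state, absorbed, status_of)

    # surviving polymorphic mutations
    for bg, state in active.items():
        flush(bg, state, np.ones(len(state["count"]), dtype=bool),
              lambda cnt, bg=bg, nb=sizes[bg]: (
                  "lost" if cnt == 0 else (f"fixed_{bg}" if cnt == nb else "polymorphic")
              ))

    df = pd.DataFrame(
        {
            "effect": [EFFECT_NAMES[e] for e in finished["effect"]],
            "background": finished["background"],
            "s": finished["s"],
            "count": finished["count"],
        }
    )
    df["status"] = finished["status"]
    nb_arr = df["background"].map(sizes).to_numpy(dtype=float)
    freq = df["count"].to_numpy() / np.maximum(nb_arr, 1)
    df["freq_inverted"] = np.where(df["background"] == "inverted", freq, 0.0)
    df["freq_ancestral"] = np.where(df["background"] == "ancestral", freq, 0.0)
    df.attrs["L_n"] = l_n
    df.attrs["L_s"] = l_s
    df.attrs["L_nc"] = l_nc
    df.attrs["config"] = config
    return df


def cohort_from_mutations(
    mutations: pd.DataFrame,
    n_samples: int = 100,
    inv_freq: float | None = None,
    seed: int = 1,
):
    """Draw a diploid cohort from a forward-simulation mutation table.

    Each sample gets an inversion genotype (Hardy-Weinberg at ``inv_freq``,
    default the simulation's frequency) and carries each surviving mutation
    on a haplotype of the mutation's background with probability equal to
    its final within-background frequency.

    Returns ``(derived_dosages, inversion_genotypes, effect_codes)`` for the
    mutations that are still present (not lost) in the population.
    """
    rng = np.random.default_rng(seed)
    cfg = mutations.attrs.get("config")
    if inv_freq is None:
        inv_freq = cfg.inv_freq if cfg is not None else 0.5
    live = mutations[mutations["status"] != "lost"].reset_index(drop=True)
    m = len(live)
    f = np.stack(
        [live["freq_inverted"].to_numpy(), live["freq_ancestral"].to_numpy()]
    )  # class (0=inverted,1=ancestral) x mutation

    genotypes = rng.binomial(2, inv_freq, size=n_samples)
    # hap class labels: 0 = inverted, 1 = ancestral
    hap_class = np.ones((n_samples, 2), dtype=np.int8)
    hap_class[genotypes == 2] = 0
    hap_class[genotypes == 1, 0] = 0
    carrier = rng.random((n_samples, 2, m)) < f[hap_class]
    dosages = carrier.sum(axis=1).astype(np.int8)
    effects = np.array([EFFECT_CODES[e] for e in live["effect"]], dtype=np.int8)
    return dosages, genotypes, effects
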