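"""Synthetic genotype panels with known ancestry truth.

Two generators cover the downstream analyses:

* :func:`simulate_dataset` builds a two-taxon haploid panel in which one or
  more "admixed" recipient-taxon genomes are Markovian mosaics of recipient
  and donor ancestry.  Recombination breakpoints fall as a Poisson process
  with rate ``v`` per Morgan along a linear genetic map (plus chromosome
  ends), and each segment is independently labelled donor with probability
  ``alpha`` -- the block-length arithmetic this emulates assumes exactly this
  process.  Mutations are sprinkled on an infinite-sites binary alphabet:
  taxon consensus sequences differ at per-site rate ``pi_between``, and each
  sample carries private noise at rate ``pi_within / 2`` so conspecific pairs
  differ at ~``pi_within``.
* :func:`simulate_unlinked_loci` delegates to msprime for statistically
  independent neutral coalescent loci under a two-population split (optional
  bottleneck in one population, optional migration pulse).

Panels list *assayable* sites explicitly (default density 100 sites/kb,
emulating callable-site density after depth/quality filtering) so that
pairwise-diversity denominators are exact.  Seeds are explicit fields, never
global state: the same :class:`SimConfig` reproduces the dataset exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .variant_io import GeneModel, GeneticMap, GenotypePanel, MISSING, STOP_CODONS, CODON_TABLE

__all__ = [
    "SimConfig",
    "AncestrySegment",
    "SimulatedDataset",
    "simulate_admixed_genome",
    "draw_ancestry_segments",
    "simulate_dataset",
    "simulate_unlinked_loci",
    "plant_gene_models_and_stops",
    "write_truth_bed",
]

RECIPIENT = "recipient"
DONOR = "donor"


@dataclass
class SimConfig:
    """Parameters of the mosaic-genome simulator.

    Defaults mirror the study system: mutation rate ``mu`` = 1.5e-8 per bp
    per generation, a 14.7-Morgan map over 14 chromosomes and a 2.6e8 bp
    genome, admixture proportion ``alpha`` = 0.15 at ``v`` = 150 generations
    (the northern sympatric scenario).  ``genome_bp`` may be scaled down for
    desk-size runs; scale ``map_length_morgans`` with it to preserve the
    per-bp recombination rate (14.7 / 2.6e8 Morgan/bp).
    """

    n_recipient: int = 4
    n_donor: int = 4
    n_admixed: int = 1
    genome_bp: int = 260_000_000
    n_chromosomes: int = 14
    map_length_morgans: float = 14.7
    mu: float = 1.5e-8
    pi_within: float = 0.003
    pi_between: float = 0.04
    alpha: float = 0.15
    v: int = 150
    pulse_times: list[int] = field(default_factory=list)
    sites_per_kb: float = 600.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must be in [0, 1]")
        if self.pi_between < self.pi_within or self.pi_within < 0:
            raise ValueError("require pi_between >= pi_within >= 0")
        if self.genome_bp <= 0 or self.n_chromosomes <= 0 or self.map_length_morgans <= 0:
            raise ValueError("genome_bp, n_chromosomes, map_length_morgans must be > 0")

    @property
    def chrom_bp(self) -> int:
        return self.genome_bp // self.n_chromosomes

    @property
    def morgans_per_bp(self) -> float:
        return self.map_length_morgans / self.genome_bp

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]


@dataclass
class AncestrySegment:
    """Contiguous region of one ancestry: 0-based half-open [start, end)."""

    chromosome: str
    start: int
    end: int
    ancestry: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("segment must have start < end")

    @property
    def length_bp(self) -> int:
        return self.end - self.start


@dataclass
class SimulatedDataset:
    panel: GenotypePanel
    truth: dict[str, list[AncestrySegment]]
    genes: list[GeneModel]
    gmap: GeneticMap
    config: SimConfig
    reference: dict[str, str] = field(default_factory=dict)
    planted_stops: list[dict] = field(default_factory=list)

    @property
    def recipient_samples(self) -> list[str]:
        return [s for s in self.panel.samples if s.startswith("recipient")]

    @property
    def donor_samples(self) -> list[str]:
        return [s for s in self.panel.samples if s.startswith("donor")]

    @property
    def admixed_samples(self) -> list[str]:
        return [s for s in self.panel.samples if s.startswith("admixed")]

    def donor_fraction(self, sample: str) -> float:
        """Realized donor-ancestry bp fraction of a sample's truth segments."""
        segs = self.truth[sample]
        total = sum(s.length_bp for s in segs)
        donor = sum(s.length_bp for s in segs if s.ancestry == DONOR)
        return donor / total


def draw_ancestry_segments(config: SimConfig, seed: int | None = None) -> list[AncestrySegment]:
    """Draw one genome's true ancestry segments without building a panel.

    Uses ``config.seed`` unless ``seed`` is given.  Cheap even at full
    genome scale (no site-level data is generated).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    return _mosaic_segments(config, rng)


def _mosaic_segments(config: SimConfig, rng: np.random.Generator) -> list[AncestrySegment]:
    """Poisson breakpoints at rate v per Morgan along the map, plus chromosome
    ends; each segment independently donor with probability alpha."""
    segs: list[AncestrySegment] = []
    m_per_bp = config.morgans_per_bp
    for name in config.chrom_names():
        L = config.chrom_bp
        cuts = [0]
        x = 0.0
        while True:
            # exponential waiting distance in Morgans, converted to bp
            x += rng.exponential(1.0 / config.v) / m_per_bp
            if x >= L:
                break
            cuts.append(int(round(x)))
        cuts.append(L)
        cuts = sorted(set(cuts))
        for s, e in zip(cuts[:-1], cuts[1:]):
            anc = DONOR if rng.random() < config.alpha else RECIPIENT
            segs.append(AncestrySegment(name, s, e, anc))
    # raw Poisson segments are the truth (adjacent same-ancestry segments are
    # NOT merged: segment counts and lengths then follow the chunk arithmetic
    # X = vL + C with exponential(mean 1/v) Morgan lengths exactly)
    return segs


def _site_grid(config: SimConfig, rng: np.random.Generator):
    """Assayable-site positions per chromosome (uniform random, sorted)."""
    n_per_chrom = int(round(config.chrom_bp * config.sites_per_kb / 1000.0))
    chroms, positions = [], []
    for name in config.chrom_names():
        pos = np.sort(rng.choice(config.chrom_bp, size=n_per_chrom, replace=False))
        chroms.append(np.full(n_per_chrom, name, dtype=object))
        positions.append(pos.astype(np.int64))
    return np.concatenate(chroms), np.concatenate(positions)


def simulate_admixed_genome(
    config: SimConfig, sample_index: int
) -> tuple[np.ndarray, list[AncestrySegment]]:
    """Simulate one admixed haplotype on the config's assayable-site grid.

    Returns the haplotype (allele codes over the shared site grid, which is
    determined by ``config.seed`` alone) and the true ancestry segments.
    Provided for direct use; :func:`simulate_dataset` builds whole panels.
    """
    ds = simulate_dataset(dataclasses.replace(config, n_admixed=max(config.n_admixed, sample_index + 1)))
    name = ds.admixed_samples[sample_index]
    j = ds.panel.sample_index(name)
    return ds.panel.calls[:, j].copy(), ds.truth[name]


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate the full two-taxon panel with mosaic admixed genomes.

    Sample layout: ``recipient0..`` (pure recipient taxon), ``donor0..``
    (donor taxon), ``admixed0..`` (recipient-taxon samples carrying mosaic
    donor ancestry).  Alleles are binary; allele 0 is the recipient-taxon
    consensus (the reference).
    """
    rng = np.random.default_rng(config.seed)
    chrom, pos = _site_grid(config, rng)
    n_sites = len(pos)

    # taxon consensus divergence
    donor_consensus = (rng.random(n_sites) < config.pi_between).astype(np.int8)

    names = (
        [f"recipient{i}" for i in range(config.n_recipient)]
        + [f"donor{i}" for i in range(config.n_donor)]
        + [f"admixed{i}" for i in range(config.n_admixed)]
    )
    calls = np.zeros((n_sites, len(names)), dtype=np.int8)
    truth: dict[str, list[AncestrySegment]] = {}
    half = config.pi_within / 2.0

    col = 0
    for i in range(config.n_recipient):
        noise = rng.random(n_sites) < half
        calls[:, col] = noise.astype(np.int8)  # flip away from consensus 0
        col += 1
    for i in range(config.n_donor):
        noise = rng.random(n_sites) < half
        calls[:, col] = np.where(noise, 1 - donor_consensus, donor_consensus)
        col += 1
    # contiguous index range of each chromosome in the concatenated site grid
    n_per_chrom = n_sites // config.n_chromosomes
    chrom_offset = {name: i * n_per_chrom for i, name in enumerate(config.chrom_names())}

    for i in range(config.n_admixed):
        segs = _mosaic_segments(config, rng)
        name = names[col]
        truth[name] = segs
        hap = np.zeros(n_sites, dtype=np.int8)
        donor_mask = np.zeros(n_sites, dtype=bool)
        for seg in segs:
            if seg.ancestry == DONOR:
                off = chrom_offset[seg.chromosome]
                sl = pos[off: off + n_per_chrom]
                lo = off + np.searchsorted(sl, seg.start, side="left")
                hi = off + np.searchsorted(sl, seg.end, side="left")
                donor_mask[lo:hi] = True
        hap[donor_mask] = donor_consensus[donor_mask]
        noise = rng.random(n_sites) < half
        calls[:, col] = np.where(noise, 1 - hap, hap)
        col += 1

    panel = GenotypePanel(
        samples=names,
        chrom=chrom,
        pos=pos,
        calls=calls,
    )
    gmap = _linear_map(config)
    return SimulatedDataset(panel=panel, truth=truth, genes=[], gmap=gmap, config=config)


def _linear_map(config: SimConfig) -> GeneticMap:
    """Linear genetic map: constant Morgan/bp rate, markers at chromosome
    ends and every megabase."""
    rows = []
    cm_per_bp = 100.0 * config.morgans_per_bp
    step = max(1_000_000, config.chrom_bp // 10)
    for name in config.chrom_names():
        for bp in list(range(0, config.chrom_bp, step)) + [config.chrom_bp]:
            rows.append((name, bp, bp * cm_per_bp))
    return GeneticMap.from_table(rows)


# ---------------------------------------------------------------------------
# Coalescent loci (msprime)
# ---------------------------------------------------------------------------

def simulate_unlinked_loci(
    n_loci: int,
    samples_per_pop: int,
    *,
    Ne: float = 10_000,
    split_generations: float = 0.0,
    n_pops: int = 2,
    bottleneck_Ne: float | None = None,
    migration_pulse: tuple[float, float] | None = None,
    locus_bp: int = 1_000,
    mu: float = 1.5e-8,
    variant_rows_only: bool = False,
    seed: int = 0,
) -> GenotypePanel:
    """Simulate statistically independent neutral loci with msprime.

    Two populations (``pop0``, ``pop1``) split from a common ancestor
    ``split_generations`` ago (0 = single panmictic population).  Optionally
    ``pop1`` is bottlenecked to ``bottleneck_Ne`` after the split (emulating
    the diversity-reducing transition to selfing), and ``migration_pulse =
    (time, fraction)`` moves a pulse of ancestry from pop1 into pop0 at
    ``time`` generations ago.  Haploid sampling; loci are returned as
    separate chromosomes ``L0, L1, ...`` so block resampling by chromosome is
    exact.

    Samples are named ``pop{k}_{i}``.
    """
    import msprime

    if n_loci <= 0:
        raise ValueError("n_loci must be > 0")
    if split_generations < 0 or Ne <= 0 or (bottleneck_Ne is not None and bottleneck_Ne <= 0):
        raise ValueError("invalid demography: negative times or sizes")

    demography = msprime.Demography()
    demography.add_population(name="pop0", initial_size=Ne)
    if split_generations > 0 or n_pops > 1:
        demography.add_population(
            name="pop1",
            initial_size=bottleneck_Ne if bottleneck_Ne is not None else Ne,
        )
        demography.add_population(name="anc", initial_size=Ne)
        if migration_pulse is not None:
            t_m, frac = migration_pulse
            demography.add_mass_migration(time=t_m, source="pop0", dest="pop1", proportion=frac)
        demography.add_population_split(
            time=max(split_generations, 1e-9), derived=["pop0", "pop1"], ancestral="anc"
        )
        sample_sets = [
            msprime.SampleSet(samples_per_pop, population="pop0", ploidy=1),
            msprime.SampleSet(samples_per_pop, population="pop1", ploidy=1),
        ]
        pops = 2
    else:
        sample_sets = [msprime.SampleSet(samples_per_pop, population="pop0", ploidy=1)]
        pops = 1

    names = [f"pop{k}_{i}" for k in range(pops) for i in range(samples_per_pop)]
    reps = msprime.sim_ancestry(
        samples=sample_sets,
        demography=demography,
        sequence_length=locus_bp,
        recombination_rate=0.0,
        num_replicates=n_loci,
        random_seed=max(1, seed),
    )
    chroms, positions, calls = [], [], []
    rng = np.random.default_rng(seed + 1)
    for li, ts in enumerate(reps):
        mts = msprime.sim_mutations(
            ts, rate=mu, random_seed=int(rng.integers(1, 2**31 - 1)),
            model=msprime.BinaryMutationModel(),
        )
        gm = mts.genotype_matrix()  # (n_var, n_samples)
        sites = [int(s.position) for s in mts.sites()]
        var_pos = {}
        for p, row in zip(sites, gm):
            var_pos.setdefault(p, np.minimum(row, 1).astype(np.int8))
        n = len(names)
        if variant_rows_only:
            # compact panel of segregating sites only (frequency-based tests)
            ps = sorted(var_pos)
            loc_calls = (np.vstack([var_pos[p] for p in ps]) if ps
                         else np.empty((0, n), dtype=np.int8))
            chroms.append(np.full(len(ps), f"L{li}", dtype=object))
            positions.append(np.array(ps, dtype=np.int64))
            calls.append(loc_calls.astype(np.int8))
        else:
            # full locus span: variant rows carry genotypes, the invariant
            # remainder is all-zero so diversity denominators are exact
            loc_calls = np.zeros((locus_bp, n), dtype=np.int8)
            for p, row in var_pos.items():
                loc_calls[p] = row
            chroms.append(np.full(locus_bp, f"L{li}", dtype=object))
            positions.append(np.arange(locus_bp, dtype=np.int64))
            calls.append(loc_calls)
    return GenotypePanel(
        samples=names,
        chrom=np.concatenate(chroms),
        pos=np.concatenate(positions),
        calls=np.vstack(calls),
    )


# ---------------------------------------------------------------------------
# Gene models and planted premature stops
# ---------------------------------------------------------------------------

def plant_gene_models_and_stops(
    dataset: SimulatedDataset,
    stop_positions: list[tuple[str, int, str]],
    *,
    n_genes: int = 5,
    codons_per_gene: int = 100,
    seed: int | None = None,
) -> SimulatedDataset:
    """Add coding regions with known frames and plant premature stops.

    Synthesizes ``n_genes`` single-exon genes (alternating strand) on the
    first chromosome, each an open reading frame of ``codons_per_gene``
    codons (ATG start, clean internal codons, terminal stop), and writes the
    corresponding reference sequence.  ``stop_positions`` is a list of
    ``(gene_id, codon_index_1based, sample)``: the gene's codon at that index
    is mutated to TAA in that sample by adding the needed variant site(s) to
    the panel.  The planted events are recorded in ``planted_stops``.

    Raises ``ValueError`` if a requested codon falls outside the gene.
    """
    rng = np.random.default_rng(dataset.config.seed + 7 if seed is None else seed)
    chrom_name = dataset.config.chrom_names()[0]
    chrom_len = dataset.config.chrom_bp

    safe = sorted(c for c, a in CODON_TABLE.items() if a not in "*M")
    genes: list[GeneModel] = []
    gene_seqs: dict[str, str] = {}
    gap = max(10, (chrom_len - n_genes * codons_per_gene * 3) // (n_genes + 1))
    cursor = gap
    for gi in range(n_genes):
        seq = "ATG" + "".join(rng.choice(safe) for _ in range(codons_per_gene - 2)) + "TAA"
        strand = "+" if gi % 2 == 0 else "-"
        start = cursor
        end = start + len(seq)
        cursor = end + gap
        if end > chrom_len:
            raise ValueError("genes do not fit on chromosome")
        gid = f"gene{gi}"
        genes.append(GeneModel(gid, chrom_name, strand, [(start, end)]))
        gene_seqs[gid] = seq

    # reference sequence for the gene-bearing chromosome: neutral background
    background = rng.choice(list("ACGT"), size=chrom_len)
    for g in genes:
        s, e = g.intervals[0]
        coding = gene_seqs[g.gene_id]
        if g.strand == "-":
            from .variant_io import revcomp
            coding = revcomp(coding)
        background[s:e] = list(coding)
    reference = {chrom_name: "".join(background)}

    # drop synthetic background sites inside gene intervals: they carry the
    # binary A/T alphabet, not the planted coding sequence
    panel = dataset.panel
    in_gene = np.zeros(panel.n_sites, dtype=bool)
    for g in genes:
        for s, e in g.intervals:
            in_gene |= (panel.chrom == g.chromosome) & (panel.pos >= s) & (panel.pos < e)
    panel = panel.subset_sites(np.nonzero(~in_gene)[0])

    planted: list[dict] = []
    new_sites: list[tuple[str, int, tuple[str, str], dict[int, int]]] = []
    for gid, codon_idx, sample in stop_positions:
        gene = next(g for g in genes if g.gene_id == gid)
        if not (1 <= codon_idx <= gene.n_codons()):
            raise ValueError(f"codon {codon_idx} outside {gid}")
        coding_pos = gene.coding_positions()
        idx0 = (codon_idx - 1) * 3
        codon = gene_seqs[gid][idx0: idx0 + 3]
        # choose a single-base change to a stop codon where possible
        target = None
        for stop in ("TAA", "TAG", "TGA"):
            diffs = [k for k in range(3) if codon[k] != stop[k]]
            if len(diffs) == 1:
                target = (stop, diffs)
                break
        if target is None:
            target = ("TAA", [k for k in range(3) if codon[k] != "TAA"[k]])
        stop, diffs = target
        j = panel.sample_index(sample)
        for k in diffs:
            gpos = int(coding_pos[idx0 + k])
            ref_base = reference[chrom_name][gpos]
            new_base = stop[k]
            if gene.strand == "-":
                from .variant_io import revcomp
                new_base = revcomp(new_base)
            new_sites.append((chrom_name, gpos, (ref_base, new_base), {j: 1}))
        planted.append({"gene_id": gid, "codon_index": codon_idx, "sample": sample,
                        "codon": stop})

    out_panel = _merge_sites(panel, new_sites)
    return dataclasses.replace(
        dataset, panel=out_panel, genes=genes, reference=reference, planted_stops=planted
    )


def _merge_sites(panel: GenotypePanel, new_sites) -> GenotypePanel:
    """Insert explicit allele-coded sites into a panel, keeping sort order.
    Existing sites at the same position are overwritten."""
    if not new_sites:
        return panel
    records = {}
    for c, p, alleles, sample_calls in new_sites:
        key = (c, p)
        if key in records:
            records[key][2].update(sample_calls)
        else:
            records[key] = (alleles, MISSING, dict(sample_calls))
    chrom = list(panel.chrom)
    pos = list(panel.pos)
    alleles_list = (
        list(panel.alleles) if panel.alleles is not None
        else [("A", "T")] * panel.n_sites
    )
    calls = panel.calls
    rows = {(panel.chrom[i], int(panel.pos[i])): i for i in range(panel.n_sites)}
    add_chrom, add_pos, add_alleles, add_calls = [], [], [], []
    for (c, p), (alleles, _, sc) in records.items():
        row = np.zeros(panel.n_samples, dtype=np.int8)
        for j, a in sc.items():
            row[j] = a
        if (c, p) in rows:
            i = rows[(c, p)]
            calls = calls.copy()
            calls[i] = row
            alleles_list[i] = alleles
        else:
            add_chrom.append(c)
            add_pos.append(p)
            add_alleles.append(alleles)
            add_calls.append(row)
    if add_pos:
        chrom = np.concatenate([panel.chrom, np.array(add_chrom, dtype=object)])
        pos = np.concatenate([panel.pos, np.array(add_pos, dtype=np.int64)])
        calls = np.vstack([calls, np.array(add_calls, dtype=np.int8)])
        alleles_list = alleles_list + add_alleles
        deg = np.concatenate([panel.degeneracy, np.full(len(add_pos), -1, dtype=np.int8)])
        order = np.lexsort((pos, np.array([str(c) for c in chrom])))
        return GenotypePanel(
            samples=list(panel.samples),
            chrom=np.asarray(chrom, dtype=object)[order],
            pos=np.asarray(pos)[order],
            calls=calls[order],
            alleles=[alleles_list[i] for i in order],
            degeneracy=deg[order],
        )
    return dataclasses.replace(panel, calls=calls, alleles=alleles_list)


def write_truth_bed(truth: dict[str, list[AncestrySegment]], path: str) -> None:
    """BED (0-based half-open) of true ancestry segments, one row per segment."""
    with open(path, "w") as fh:
        for sample, segs in truth.items():
            for s in segs:
                fh.write(f"{s.chromosome}\t{s.start}\t{s.end}\t{sample}:{s.ancestry}\n")
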