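"""Genotype panels, site filtering, codon degeneracy, and genetic-map interpolation.

The central container is :class:`GenotypePanel`: a samples x sites matrix of
haploid calls (fully inbred lines resolved to single alleles), with per-sample
read depth and a per-site codon-degeneracy class.  Panels list every assayable
site explicitly -- including invariant ones -- so that pairwise-diversity
denominators (sites co-called in both samples) are exact.

Coordinates are 0-based half-open internally; VCF I/O converts to/from 1-based.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GenotypePanel",
    "GeneModel",
    "GeneticMap",
    "MISSING",
    "NONCODING",
    "apply_site_filters",
    "resolve_heterozygotes",
    "classify_degeneracy",
    "interpolate_cm",
    "read_vcf",
    "write_vcf",
    "read_gene_models",
    "write_gene_models",
    "read_genetic_map",
    "write_genetic_map",
    "CODON_TABLE",
    "STOP_CODONS",
]

MISSING = -1          # call / depth sentinel
NONCODING = -1        # degeneracy sentinel

# Standard nuclear genetic code.
_BASES = "ACGT"
CODON_TABLE: dict[str, str] = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
STOP_CODONS = frozenset(c for c, a in CODON_TABLE.items() if a == "*")
_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class GenotypePanel:
    """Haploid multi-sample genotype panel.

    Attributes
    ----------
    samples : list of str
    chrom : (n_sites,) array of chromosome ids (object dtype)
    pos : (n_sites,) int64 array, 0-based positions, strictly increasing
        within each chromosome
    alleles : list of tuples of allele strings per site, or ``None`` for
        synthetic binary panels (allele index 0/1 with implicit A/T bases)
    calls : (n_sites, n_samples) int8 array of allele indices, -1 = missing
    depth : (n_sites, n_samples) int32 array of read depths, or ``None``
    degeneracy : (n_sites,) int8 array in {0, 2, 3, 4}, -1 = noncoding
    het : residual-heterozygote record mapping (site_index, sample_index) ->
        (allele_i, allele_j); ``calls`` holds the first allele until
        :func:`resolve_heterozygotes` picks one at random
    """

    samples: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    calls: np.ndarray
    alleles: list[tuple[str, ...]] | None = None
    depth: np.ndarray | None = None
    degeneracy: np.ndarray | None = None
    het: dict[tuple[int, int], tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2 or self.calls.shape != (len(self.pos), len(self.samples)):
            raise ValueError("calls must be (n_sites, n_samples)")
        if self.degeneracy is None:
            self.degeneracy = np.full(len(self.pos), NONCODING, dtype=np.int8)
        else:
            self.degeneracy = np.asarray(self.degeneracy, dtype=np.int8)
        if self.n_sites > 1:
            same = self.chrom[1:] == self.chrom[:-1]
            if np.any(same & (np.diff(self.pos) <= 0)):
                raise ValueError("positions not strictly increasing within chromosome")

    # -- basic accessors -------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, name: str) -> int:
        try:
            return self.samples.index(name)
        except ValueError:
            raise KeyError(f"sample {name!r} not in panel") from None

    def chromosomes(self) -> list:
        seen: dict = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def subset_sites(self, idx: np.ndarray) -> "GenotypePanel":
        """Return a new panel restricted to site indices ``idx`` (kept in the
        given order; callers are responsible for preserving sortedness)."""
        idx = np.asarray(idx)
        alleles = None
        if self.alleles is not None:
            alleles = [self.alleles[i] for i in np.atleast_1d(idx)]
        return GenotypePanel(
            samples=list(self.samples),
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            calls=self.calls[idx],
            alleles=alleles,
            depth=None if self.depth is None else self.depth[idx],
            degeneracy=self.degeneracy[idx],
        )

    def class_mask(self, site_class: Iterable[int] | None) -> np.ndarray:
        """Boolean mask of sites whose degeneracy class is in ``site_class``
        (``None`` selects every site)."""
        if site_class is None:
            return np.ones(self.n_sites, dtype=bool)
        return np.isin(self.degeneracy, list(site_class))


@dataclass
class GeneModel:
    """Protein-coding gene: ordered coding intervals on one strand.

    Intervals are 0-based half-open in genome coordinates, ordered 5'->3'
    along the coding strand (for '-' strand genes the first interval is the
    one with the largest coordinates).  Total coding length must be divisible
    by three; ``frame`` gives the codon offset of the first coding base and is
    0 for complete gene models.
    """

    gene_id: str
    chromosome: str
    strand: str
    intervals: list[tuple[int, int]]
    frame: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if self.coding_length() % 3 != 0:
            raise ValueError(
                f"gene {self.gene_id}: coding length {self.coding_length()} "
                "not divisible by 3"
            )

    def coding_length(self) -> int:
        return sum(e - s for s, e in self.intervals)

    def n_codons(self) -> int:
        return self.coding_length() // 3

    def coding_positions(self) -> np.ndarray:
        """Genome positions of coding bases in 5'->3' (codon) order."""
        parts = []
        for s, e in self.intervals:
            p = np.arange(s, e, dtype=np.int64)
            if self.strand == "-":
                p = p[::-1]
            parts.append(p)
        return np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)


@dataclass
class GeneticMap:
    """Per-chromosome ordered (bp, cM) marker lists with cM non-decreasing."""

    markers: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    @classmethod
    def from_table(cls, rows: Iterable[tuple[str, int, float]]) -> "GeneticMap":
        by_chrom: dict[str, list[tuple[int, float]]] = {}
        for c, bp, cm in rows:
            by_chrom.setdefault(str(c), []).append((int(bp), float(cm)))
        markers = {}
        for c, pts in by_chrom.items():
            pts.sort()
            bp = np.array([p[0] for p in pts], dtype=np.int64)
            cm = np.array([p[1] for p in pts], dtype=float)
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"cM not non-decreasing on chromosome {c}")
            markers[c] = (bp, cm)
        return cls(markers)

    def chromosomes(self) -> list[str]:
        return list(self.markers)

    def span(self, chromosome: str) -> tuple[int, int]:
        bp, _ = self.markers[str(chromosome)]
        return int(bp[0]), int(bp[-1])


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def apply_site_filters(
    panel: GenotypePanel,
    min_depth: int = 10,
    depth_sd: float = 2.0,
) -> GenotypePanel:
    """Apply the depth and allele-count site filters.

    Per-sample calls with depth below ``min_depth`` are set missing; calls
    whose depth is more than ``depth_sd`` sample standard deviations from the
    sample's mean depth (mean/SD computed over calls surviving the minimum-
    depth filter) are censored; sites with more than two alleles among the
    retained calls are dropped.  Idempotent.
    """
    if panel.n_sites == 0:
        raise ValueError("empty panel")
    calls = panel.calls.copy()
    if panel.depth is not None:
        depth = panel.depth
        low = depth < min_depth
        calls[low] = MISSING
        # per-sample censoring, two-sided; mean/SD computed from the depth
        # matrix over entries passing the min-depth cut (a fixed reference,
        # so filtering is idempotent)
        for j in range(panel.n_samples):
            ok = depth[:, j] >= min_depth
            if not ok.any():
                continue
            d = depth[ok, j].astype(float)
            mu, sd = d.mean(), d.std()
            if sd > 0:
                far = np.abs(depth[:, j] - mu) > depth_sd * sd
                calls[far & (calls[:, j] != MISSING), j] = MISSING
    # drop sites with >2 alleles among retained calls
    keep = np.ones(panel.n_sites, dtype=bool)
    for i in range(panel.n_sites):
        obs = calls[i][calls[i] != MISSING]
        if len(np.unique(obs)) > 2:
            keep[i] = False
    out = panel.subset_sites(np.nonzero(keep)[0])
    out.calls = calls[keep]
    return out


def resolve_heterozygotes(panel: GenotypePanel, seed: int = 0) -> GenotypePanel:
    """Resolve residual heterozygous calls to haploid calls.

    Each entry of ``panel.het`` -- (site_index, sample_index) ->
    (allele_i, allele_j) -- is replaced by one of its two alleles chosen
    uniformly at random.  Panels without a het record (already homozygous)
    are returned unchanged.  Deterministic under ``seed``.
    """
    if not panel.het:
        return panel
    rng = np.random.default_rng(seed)
    calls = panel.calls.copy()
    for (i, j), (a, b) in sorted(panel.het.items()):
        calls[i, j] = a if rng.random() < 0.5 else b
    return dataclasses.replace(panel, calls=calls, het=None)


# ---------------------------------------------------------------------------
# Codon degeneracy
# ---------------------------------------------------------------------------

def _degeneracy_of(codon: str, offset: int) -> int:
    """Degeneracy class of position ``offset`` of ``codon``: 1 + the number
    of alternative nucleotides that are synonymous (0-fold = no synonymous
    alternative, coded 0; 2/3/4-fold coded as such)."""
    aa = CODON_TABLE[codon]
    n_syn = 0
    for b in _BASES:
        if b == codon[offset]:
            continue
        alt = codon[:offset] + b + codon[offset + 1:]
        if CODON_TABLE[alt] == aa:
            n_syn += 1
    return (0, 2, 3, 4)[n_syn]


def classify_degeneracy(
    genes: Sequence[GeneModel],
    reference: Mapping[str, str],
) -> dict[tuple[str, int], int]:
    """Label each coding site 0/2/3/4-fold degenerate against the reference.

    ``reference`` maps chromosome id -> sequence string.  Classification is
    strand-aware: for '-' strand genes codons are read off the reverse
    complement.  Sites whose codon contains a non-ACGT base are skipped.
    Returns ``{(chromosome, position): class}``.

    Raises ``ValueError`` naming the gene if its coding length is frame-
    inconsistent with the model.
    """
    out: dict[tuple[str, int], int] = {}
    for gene in genes:
        seq = reference[gene.chromosome]
        pos = gene.coding_positions()
        if len(pos) % 3 != 0:
            raise ValueError(f"gene {gene.gene_id} is frame-inconsistent")
        bases = [seq[p] for p in pos]
        if gene.strand == "-":
            bases = [b.translate(_COMP) for b in bases]
        for ci in range(len(pos) // 3):
            codon = "".join(bases[3 * ci: 3 * ci + 3]).upper()
            if any(b not in _BASES for b in codon):
                continue
            for off in range(3):
                out[(gene.chromosome, int(pos[3 * ci + off]))] = _degeneracy_of(codon, off)
    return out


def annotate_degeneracy(
    panel: GenotypePanel,
    genes: Sequence[GeneModel],
    reference: Mapping[str, str],
) -> GenotypePanel:
    """Return a panel whose ``degeneracy`` field is filled from the gene
    models; sites outside coding regions keep the noncoding sentinel."""
    classes = classify_degeneracy(genes, reference)
    deg = np.full(panel.n_sites, NONCODING, dtype=np.int8)
    for i in range(panel.n_sites):
        deg[i] = classes.get((panel.chrom[i], int(panel.pos[i])), NONCODING)
    return dataclasses.replace(panel, degeneracy=deg)


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------

def interpolate_cm(gmap: GeneticMap, chromosome: str, bp) -> np.ndarray | float:
    """Piecewise-linear interpolation of cM at ``bp`` (scalar or array).

    Positions outside the marker range are clamped to the terminal marker's
    cM (no extrapolation; avoids negative implied rates).
    """
    key = str(chromosome)
    if key not in gmap.markers:
        raise KeyError(f"chromosome {chromosome!r} not in genetic map")
    mbp, mcm = gmap.markers[key]
    res = np.interp(np.asarray(bp, dtype=float), mbp.astype(float), mcm)
    return float(res) if np.isscalar(bp) or np.ndim(bp) == 0 else res


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

_SYNTH_ALLELES = ("A", "T")  # implicit bases for binary panels


def write_vcf(panel: GenotypePanel, path: str) -> None:
    """Write the panel as an uncompressed VCF with haploid GT (and DP)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##INFO=<ID=DEG,Number=1,Type=Integer,Description='
                 '"Codon degeneracy class; -1 noncoding">\n')
        for c in panel.chromosomes():
            n = int(panel.pos[panel.chrom == c].max()) + 1
            fh.write(f"##contig=<ID={c},length={n}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.samples) + "\n")
        fmt = "GT" if panel.depth is None else "GT:DP"
        for i in range(panel.n_sites):
            al = panel.alleles[i] if panel.alleles is not None else _SYNTH_ALLELES
            ref, alts = al[0], list(al[1:])
            alt_field = ",".join(alts) if alts else "."
            cols = [
                str(panel.chrom[i]), str(int(panel.pos[i]) + 1), ".",
                ref, alt_field, ".", "PASS", f"DEG={int(panel.degeneracy[i])}", fmt,
            ]
            for j in range(panel.n_samples):
                g = int(panel.calls[i, j])
                gt = "." if g == MISSING else str(g)
                if panel.depth is not None:
                    gt += f":{int(panel.depth[i, j])}"
                cols.append(gt)
            fh.write("\t".join(cols) + "\n")


def read_vcf(path: str) -> GenotypePanel:
    """Read a haploid (or randomly-phased first-allele diploid) VCF."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    chrom, pos, alleles, calls, depth, deg = [], [], [], [], [], []
    het: dict[tuple[int, int], tuple[int, int]] = {}
    has_dp = True
    for var in vcf:
        chrom.append(var.CHROM)
        pos.append(var.POS - 1)
        alleles.append(tuple([var.REF] + list(var.ALT)))
        row = []
        for j, g in enumerate(var.genotypes):
            a = g[0]
            if len(g) >= 3 and g[1] is not None and g[1] >= 0 and g[1] != a:
                het[(len(pos) - 1, j)] = (int(a), int(g[1]))
            row.append(MISSING if a is None or a < 0 else a)
        calls.append(row)
        try:
            dp = var.format("DP")
        except Exception:
            dp = None
        if dp is None:
            has_dp = False
            depth.append([0] * len(samples))
        else:
            depth.append([int(x) if x >= 0 else 0 for x in dp[:, 0]])
        d = var.INFO.get("DEG")
        deg.append(NONCODING if d is None else int(d))
    return GenotypePanel(
        samples=samples,
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        calls=np.array(calls, dtype=np.int8),
        alleles=alleles,
        depth=np.array(depth, dtype=np.int32) if has_dp else None,
        degeneracy=np.array(deg, dtype=np.int8),
        het=het or None,
    )


def write_gene_models(genes: Sequence[GeneModel], path: str) -> None:
    """GFF-like TSV: gene_id, chromosome, strand, start, end, exon_rank, frame."""
    with open(path, "w") as fh:
        fh.write("gene_id\tchromosome\tstrand\tstart\tend\texon_rank\tframe\n")
        for g in genes:
            for k, (s, e) in enumerate(g.intervals):
                fh.write(f"{g.gene_id}\t{g.chromosome}\t{g.strand}\t{s}\t{e}\t{k}\t{g.frame}\n")


def read_gene_models(path: str) -> list[GeneModel]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    genes = []
    for gid, sub in df.groupby("gene_id", sort=False):
        sub = sub.sort_values("exon_rank")
        genes.append(GeneModel(
            gene_id=str(gid),
            chromosome=str(sub.iloc[0]["chromosome"]),
            strand=str(sub.iloc[0]["strand"]),
            intervals=[(int(r.start), int(r.end)) for r in sub.itertuples()],
            frame=int(sub.iloc[0]["frame"]),
        ))
    return genes


def write_genetic_map(gmap: GeneticMap, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("chromosome\tbp\tcM\n")
        for c, (bp, cm) in gmap.markers.items():
            for b, m in zip(bp, cm):
                fh.write(f"{c}\t{int(b)}\t{m:.6f}\n")


def read_genetic_map(path: str) -> GeneticMap:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return GeneticMap.from_table(
        (str(r.chromosome), int(r.bp), float(r.cM)) for r in df.itertuples()
    )
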