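"""Premature-stop-codon calling and pi_N/pi_S summaries.

A mutant stop codon counts as premature only under three conjunctive rules:

1. all three nucleotide sites of the codon have data in the sample;
2. the gene has at least 25% of its codons available in that sample
   (a codon is "available" when all three of its positions are non-missing);
3. the codon does not occur in the last 5% of codons at the 3' end.

Relaxing any rule can only add events (monotonicity).  A codon containing
two substitutions that jointly produce a stop counts once, per codon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .diversity import block_bootstrap, pairwise_pi
from .variant_io import (
    CODON_TABLE,
    GeneModel,
    GenotypePanel,
    MISSING,
    STOP_CODONS,
    revcomp,
)

__all__ = ["StopEvent", "find_premature_stops", "pn_ps"]


@dataclass
class StopEvent:
    gene_id: str
    codon_index: int       # 1-based from the start codon
    codon_fraction: float  # codon_index / n_codons
    sample: str
    codon: str             # coding-strand codon sequence observed


def _sample_base(panel_lookup, reference, chromosome, pos, sample_j):
    """Base carried by the sample at a genome position: the allele it was
    called for at a panel site, otherwise the reference base; None = missing."""
    rec = panel_lookup.get((chromosome, pos))
    if rec is None:
        return reference[chromosome][pos]
    alleles, call = rec
    a = call[sample_j]
    if a == MISSING:
        return None
    return alleles[a]


def find_premature_stops(
    panel: GenotypePanel,
    sample: str,
    genes: Sequence[GeneModel],
    reference: Mapping[str, str],
    min_codon_fraction_available: float = 0.25,
    tail_fraction: float = 0.05,
) -> list[StopEvent]:
    """Premature stop codons in one sample under the three admissibility rules.

    The sample's coding sequence is reconstructed codon-by-codon from the
    reference plus its panel calls (panel sites inside genes override the
    reference; missing calls make the position unavailable).  Stops are
    evaluated on the coding strand.  The genuine terminal stop codon of a
    complete gene falls in the final 5% and is never reported.
    """
    j = panel.sample_index(sample)
    lookup = {}
    for i in range(panel.n_sites):
        alleles = panel.alleles[i] if panel.alleles is not None else ("A", "T")
        lookup[(panel.chrom[i], int(panel.pos[i]))] = (alleles, panel.calls[i])

    events: list[StopEvent] = []
    for gene in genes:
        pos = gene.coding_positions()
        n_codons = gene.n_codons()
        ref_bases = []
        for p in pos:
            b = reference[gene.chromosome][int(p)]
            ref_bases.append(revcomp(b) if gene.strand == "-" else b)
        bases = []
        for p in pos:
            b = _sample_base(lookup, reference, gene.chromosome, int(p), j)
            if b is not None and gene.strand == "-":
                b = revcomp(b)
            bases.append(b)
        # availability per codon
        avail = np.array([
            all(bases[3 * c + k] is not None for k in range(3))
            for c in range(n_codons)
        ])
        if avail.mean() < min_codon_fraction_available:
            continue  # rule 2: too little of the gene surveyed
        cutoff = (1.0 - tail_fraction) * n_codons
        for c in range(n_codons):
            if not avail[c]:
                continue  # rule 1
            if (c + 1) > cutoff:
                continue  # rule 3: last 5% of codons
            codon = "".join(bases[3 * c: 3 * c + 3]).upper()
            ref_codon = "".join(ref_bases[3 * c: 3 * c + 3]).upper()
            if codon in STOP_CODONS and ref_codon not in STOP_CODONS:
                events.append(StopEvent(
                    gene_id=gene.gene_id,
                    codon_index=c + 1,
                    codon_fraction=(c + 1) / n_codons,
                    sample=sample,
                    codon=codon,
                ))
    return events


def pn_ps(
    panel: GenotypePanel,
    a: str,
    b: str,
    n_boot: int = 200,
    block_bp: int = 100_000,
    seed: int = 0,
) -> dict:
    """pi_N / pi_S for a sample pair, with a block-bootstrap CI on the ratio.

    pi_N is mean pairwise diversity per zerofold-degenerate site, pi_S per
    fourfold-degenerate site.  A zero pi_S makes the ratio undefined
    (flagged, ratio NaN).  Requires both site classes in the panel.
    """
    if not np.any(panel.degeneracy == 0) or not np.any(panel.degeneracy == 4):
        raise ValueError("panel must contain both 0-fold and 4-fold sites")

    def ratio(p: GenotypePanel) -> float:
        pn = pairwise_pi(p, a, b, site_class={0}).pi
        ps = pairwise_pi(p, a, b, site_class={4}).pi
        if not np.isfinite(ps) or ps == 0:
            return float("nan")
        return (0.0 if not np.isfinite(pn) else pn) / ps

    pi_n = pairwise_pi(panel, a, b, site_class={0}).pi
    pi_s = pairwise_pi(panel, a, b, site_class={4}).pi
    undefined = (not np.isfinite(pi_s)) or pi_s == 0
    if undefined:
        return {"pi_N": pi_n, "pi_S": pi_s, "ratio": float("nan"),
                "lo": float("nan"), "hi": float("nan"), "undefined": True}
    point, lo, hi = block_bootstrap(ratio, panel, block_bp=block_bp,
                                    n_boot=n_boot, seed=seed)
    return {"pi_N": pi_n, "pi_S": pi_s, "ratio": point, "lo": lo, "hi": hi,
            "undefined": False}
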