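"""End-to-end orchestration: simulate (optional) -> filter -> diversity ->
timescales -> HMM -> blocks -> D test -> outlier scan -> recombination scan.

A :class:`RunConfig` names the inputs (or a synthetic-simulation seed), the
sample roles, and the per-stage parameters.  ``run_pipeline`` executes the
stages in order, writes TSV/BED outputs plus a machine-readable JSON
summary into the run directory, and echoes the configuration (with a hash)
for reproducibility.  Each stage is also importable on its own; the driver
only sequences them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np

from . import (
    ancestry_hmm,
    blocks as blocks_mod,
    diversity,
    introgression_tests,
    recomb_scan,
    synthetic_data,
    timescales,
    variant_io,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """Stage-named pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration for a full run.

    With ``vcf`` unset, a synthetic dataset is generated from ``sim`` and
    the sample roles default to the simulator's layout.  Sample roles:
    ``focal`` (recipient samples scanned for donor ancestry), ``donors``
    (donor-taxon panel), ``recipients`` (pure recipient references).
    """

    out_dir: str = "selfmix_run"
    seed: int = 0
    vcf: str | None = None
    gene_models: str | None = None
    genetic_map: str | None = None
    sim: synthetic_data.SimConfig | None = None
    focal: list[str] = field(default_factory=list)
    donors: list[str] = field(default_factory=list)
    recipients: list[str] = field(default_factory=list)
    outgroup: str | None = None
    min_depth: int = 10
    depth_sd: float = 2.0
    window_bp: int = 5_000
    slide_bp: int = 1_000
    min_sites: int = 100
    hmm_window_bp: int = 1_000
    block_threshold: float = 0.95
    heal_gap_kb: int = 0
    pi_threshold: float = 0.01
    region_bp: int = 20_000
    recomb_window_bp: int = 100_000
    recomb_smooth_bp: int = 500_000

    def config_hash(self) -> str:
        """Hash of the analytic configuration (output location excluded)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _validate_roles(panel, config: RunConfig) -> None:
    for role, names in (("focal", config.focal), ("donors", config.donors),
                        ("recipients", config.recipients)):
        for s in names:
            if s not in panel.samples:
                raise PipelineError("validate", f"{role} sample {s!r} not in panel")
    if set(config.focal) & set(config.donors):
        raise PipelineError("validate", "focal and donor roles must be disjoint")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the pipeline; returns the summary dict (also written to
    ``summary.json`` in the run directory)."""
    os.makedirs(config.out_dir, exist_ok=True)
    summary: dict = {"config_hash": config.config_hash(), "seed": config.seed}
    log_path = os.path.join(config.out_dir, "run.log")
    log = open(log_path, "w")

    def note(msg: str) -> None:
        log.write(msg + "\n")

    note(f"config hash {config.config_hash()}")
    note(json.dumps(dataclasses.asdict(config), default=str))

    try:
        # ---- acquire data -------------------------------------------------
        if config.vcf is not None:
            panel = variant_io.read_vcf(config.vcf)
            gmap = (variant_io.read_genetic_map(config.genetic_map)
                    if config.genetic_map else None)
            ds = None
        else:
            sim = config.sim or synthetic_data.SimConfig(seed=config.seed)
            ds = synthetic_data.simulate_dataset(sim)
            panel = ds.panel
            gmap = ds.gmap
            synthetic_data.write_truth_bed(ds.truth,
                                           os.path.join(config.out_dir, "truth.bed"))
            if not config.focal:
                config = dataclasses.replace(
                    config,
                    focal=ds.admixed_samples,
                    donors=ds.donor_samples,
                    recipients=ds.recipient_samples,
                )
        _validate_roles(panel, config)

        # ---- filter -------------------------------------------------------
        if panel.depth is not None:
            panel = variant_io.apply_site_filters(panel, config.min_depth, config.depth_sd)
        panel = variant_io.resolve_heterozygotes(panel, seed=config.seed)
        note(f"panel: {panel.n_sites} sites x {panel.n_samples} samples")

        # ---- diversity ----------------------------------------------------
        pi_rows = []
        for i, a in enumerate(panel.samples):
            for b in panel.samples[i + 1:]:
                st = diversity.pairwise_pi(panel, a, b)
                pi_rows.append((a, b, st.n_sites, st.n_diff, st.pi))
        _write_tsv(os.path.join(config.out_dir, "pairwise_pi.tsv"),
                   ["a", "b", "n_sites", "n_diff", "pi"], pi_rows)
        summary["pairwise_pi"] = {f"{a}|{b}": p for a, b, _, _, p in pi_rows}

        # ---- timescales (synthetic runs: within/between taxa) -------------
        if config.recipients and config.donors:
            wi = np.mean([diversity.pairwise_pi(panel, a, b).pi
                          for i, a in enumerate(config.recipients)
                          for b in config.recipients[i + 1:]])
            bt = np.mean([diversity.pairwise_pi(panel, a, b).pi
                          for a in config.recipients for b in config.donors])
            est = timescales.split_time(bt, wi)
            summary["split_time_generations"] = est.tau_generations
            note(f"pi_within={wi:.5f} pi_between={bt:.5f} tau={est.tau_generations:.0f}")

        # ---- HMM + blocks per focal sample --------------------------------
        hmm_out = {}
        for focal in config.focal:
            fw = ancestry_hmm.compute_emission_windows(
                panel, focal, config.donors, window_bp=config.hmm_window_bp)
            con, het = [], []
            for d in config.donors:
                con += ancestry_hmm.compute_emission_windows(
                    panel, d, [x for x in config.donors if x != d],
                    window_bp=config.hmm_window_bp)
            for r in config.recipients:
                het += ancestry_hmm.compute_emission_windows(
                    panel, r, config.donors, window_bp=config.hmm_window_bp)
            model = ancestry_hmm.build_emission_model(
                con, het, m=len(config.donors),
                m_conspecific=max(len(config.donors) - 1, 1), seed=config.seed)
            fit, track, info = ancestry_hmm.fit_hmm(fw, model, n_restarts=2)
            frac = ancestry_hmm.admixture_fraction(track)
            bl = blocks_mod.call_blocks(track, threshold=config.block_threshold,
                                        window_bp=config.hmm_window_bp)
            bl = blocks_mod.heal_blocks(bl, gap_kb=config.heal_gap_kb)
            entry = {"alpha": fit.alpha, "r": fit.r,
                     "log_likelihood": info["log_likelihood"],
                     "admixture_fraction": frac, "n_blocks": len(bl)}
            if bl and ds is not None:
                pulse = blocks_mod.summarize_pulse(
                    bl, ds.config.map_length_morgans, ds.config.genome_bp,
                    seed=config.seed)
                entry["T_generations"] = pulse.T_generations
                entry["dispersion_p"] = pulse.dispersion_p
            if ds is not None:
                entry["true_donor_fraction"] = ds.donor_fraction(focal)
            hmm_out[focal] = entry
            _write_tsv(os.path.join(config.out_dir, f"posterior_{focal}.tsv"),
                       ["chromosome", "start", "n_sites", "k_min", "posterior_donor"],
                       [(w.chromosome, w.start, w.n_sites, w.k_min, p)
                        for w, p in zip(track.windows, track.posterior_donor)])
            with open(os.path.join(config.out_dir, f"blocks_{focal}.bed"), "w") as fh:
                for b in bl:
                    fh.write(f"{b.chromosome}\t{b.start}\t{b.end}\t{focal}\t"
                             f"{b.mean_posterior:.4f}\n")
            note(f"HMM {focal}: alpha={fit.alpha:.4f} r={fit.r:.5f} blocks={len(bl)}")
        summary["hmm"] = hmm_out

        # ---- D statistic (synthetic role layout) --------------------------
        if len(config.focal) >= 1 and len(config.recipients) >= 2 and config.donors:
            y = introgression_tests.allele_frequencies(panel, config.focal[:1])
            z = introgression_tests.allele_frequencies(panel, config.recipients[:1])
            w = introgression_tests.allele_frequencies(panel, config.donors)
            x = introgression_tests.allele_frequencies(panel, config.recipients[1:2])
            try:
                dres = introgression_tests.block_jackknife(y, z, w, x, panel.chrom)
                summary["d_stat"] = {"D": dres.D, "se": dres.se, "Z": dres.Z}
                note(f"D={dres.D:.4f} Z={dres.Z:.2f}")
            except ValueError as e:
                note(f"D test skipped: {e}")

        # ---- outlier scan among donors ------------------------------------
        if len(config.donors) >= 3:
            regions = introgression_tests.find_outlier_regions(
                panel, config.donors, window_bp=config.window_bp,
                pi_threshold=config.pi_threshold, region_bp=config.region_bp)
            summary["outlier_regions"] = len(regions)
            if regions and config.recipients:
                t = introgression_tests.outlier_source_test(
                    regions, panel, config.donors, config.recipients[0])
                summary["outlier_test"] = {"k": t.k, "n": t.n, "p": t.p}

        # ---- recombination scan -------------------------------------------
        if gmap is not None and config.focal and config.donors:
            rates = recomb_scan.window_recomb_rates(
                gmap, config.recomb_window_bp, config.recomb_smooth_bp)
            ws = diversity.windowed_pi(
                panel, config.focal[0], config.donors[0],
                window_bp=config.recomb_window_bp, slide_bp=config.recomb_window_bp,
                min_sites=config.min_sites)
            try:
                corr = recomb_scan.divergence_recomb_correlation(ws, rates,
                                                                 min_comparisons=config.min_sites)
                summary["recomb_correlation"] = {"rho": corr.rho, "p": corr.p,
                                                 "n": corr.n}
                note(f"recomb rho={corr.rho:.4f} p={corr.p:.4g}")
            except ValueError as e:
                note(f"recomb scan skipped: {e}")
    except PipelineError:
        log.close()
        raise
    except Exception as e:  # halt with stage context, keep partial outputs
        log.close()
        raise PipelineError("pipeline", str(e)) from e

    with open(os.path.join(config.out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    log.close()
    return summary


def _write_tsv(path: str, header: list[str], rows) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
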