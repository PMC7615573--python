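"""End-to-end study-like pipeline: simulate -> fstats -> ROH -> tracts -> dN/dS.

Chains every stage on a synthetic dataset with known truth and emits a
consolidated JSON report plus TSV/BED side files.  All randomness flows
from the single seed in the configuration; rerunning with the same seed
reproduces every output byte for byte (no timestamps are written).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .fstats import d_statistic, f4_ratio, scan_panel
from .genotype import MISSING, filter_transversions, population_frequencies
from .io import write_bed
from .roh import call_roh, estimate_heterozygosity, roh_summary, window_het
from .simulate import (
    SCREEN_COMPARATORS,
    SCREEN_FOCAL,
    SCREEN_OUTGROUPS,
    make_study_like_dataset,
)
from .dnds import coverage_filter, polarize_focal_changes, screen_candidates
from .tracts import decode_and_date

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a study-like end-to-end run."""

    seed: int = 42
    out_dir: str = "woolgen_run"
    focal: str = SCREEN_FOCAL
    outgroup: str = "GrayFox"
    pcd_panel: str = "PCD"
    pcd_reference: str = "PCD_PaC"
    eur_panels: tuple = ("EurA", "EurB")
    block_span: int = 5_000_000
    window_bp: int = 1_000_000
    l_min: int = 2_500_000
    threshold: float = 1.5
    generation_time: float = 3.0
    alpha_for_dating: float | None = None  # default: the f4-ratio estimate
    n_sites: int = 50_000
    n_genes: int = 200

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "eur_panels" in raw:
            raw["eur_panels"] = tuple(raw["eur_panels"])
        return cls(**raw)


def _pooled_frequencies(matrix, populations):
    """Alt-allele frequency over the union of several populations."""
    cols = np.concatenate(
        [matrix.population_columns(p) for p in populations]
    )
    sub = matrix.calls[:, cols]
    ploidy = matrix.ploidy[cols]
    present = sub != MISSING
    n_alleles = (present * ploidy[None, :]).sum(axis=1)
    alt = np.where(present, sub, 0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        freq = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
    return freq, n_alleles


def _header_lines(config: RunConfig) -> str:
    params = json.dumps(asdict(config), sort_keys=True)
    return f"# woolgen {__version__}\n# config {params}\n"


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage in dependency order and write the report.

    Stage failures abort with the stage name attached; per-stage wall
    times are logged at INFO.  Returns the report dict.
    """
    # validate population references before any computation
    from .simulate import AdmixtureGraphSpec

    known = set(AdmixtureGraphSpec().panel_sizes) | {AdmixtureGraphSpec().focal_name}
    referenced = {
        config.focal, config.outgroup, config.pcd_panel, config.pcd_reference,
        *config.eur_panels,
    }
    unknown = referenced - known
    if unknown:
        raise ValueError(
            f"config references unknown populations {sorted(unknown)}; "
            f"available: {sorted(known)}"
        )

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    stage_seeds = {
        name: int(rng.integers(2**31))
        for name in ("simulate", "roh", "tracts", "screen")
    }
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
    }

    def _stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            raise RuntimeError(
                f"pipeline stage {name!r} failed (seed {config.seed}): {exc}"
            ) from exc
        logger.info("stage %s finished in %.1f s", name, time.perf_counter() - t0)
        return result

    data = _stage(
        "simulate",
        lambda: make_study_like_dataset(
            stage_seeds["simulate"],
            n_sites=config.n_sites,
            n_genes=config.n_genes,
        ),
    )
    matrix, truth = data["matrix"], data["truth"]

    # ---- f-statistics ------------------------------------------------
    def _fstats():
        panel_pops = [
            p
            for p in matrix.samples["population"].unique()
            if p not in (config.focal, config.outgroup)
        ]
        f3_scan = scan_panel(
            matrix, config.focal, panel_pops,
            {"stat": "f3", "outgroup": config.outgroup},
            block_span=config.block_span,
        )
        d = d_statistic(
            matrix, config.pcd_reference, config.focal,
            config.eur_panels[1], config.outgroup,
            block_span=config.block_span,
        )
        ratios = []
        for a, b in (
            (config.eur_panels[0], config.eur_panels[1]),
            (config.eur_panels[1], config.eur_panels[0]),
        ):
            ratios.append(
                f4_ratio(
                    matrix, a, b, config.outgroup, config.focal,
                    config.pcd_reference, block_span=config.block_span,
                )
            )
        return f3_scan, d, ratios

    f3_scan, d_res, ratios = _stage("fstats", _fstats)
    alpha_mean = float(np.mean([r.estimate for r in ratios]))
    with open(out / "fstats_f3_scan.tsv", "w") as fh:
        fh.write(_header_lines(config))
        f3_scan.to_csv(fh, sep="\t", index=False)
    report["fstats"] = {
        "f3_scan_top": f3_scan.iloc[0]["panel"],
        "f3_scan": f3_scan.drop(columns="error").to_dict("records"),
        "d_statistic": {
            "estimate": d_res.estimate, "se": d_res.se, "z": d_res.z,
            "n_sites": d_res.n_sites,
        },
        "f4_ratio": {
            "per_pair": [
                {"A": r.config["A"], "B": r.config["B"],
                 "alpha": r.estimate, "se": r.se}
                for r in ratios
            ],
            "alpha_mean": alpha_mean,
            "alpha_truth": truth.alpha,
        },
    }

    # ---- heterozygosity / ROH ---------------------------------------
    def _roh():
        pileup = data["pileup"]
        rr = np.random.default_rng(stage_seeds["roh"])
        het = estimate_heterozygosity(pileup, config.focal, rr)
        roh_lengths = {
            ch: data["spec"].chrom_lengths[ch]
            for ch in pileup.sites["chrom"].unique()
        }
        ws = window_het(
            pileup, config.focal, rr, window_bp=config.window_bp,
            chrom_lengths=roh_lengths,
        )
        profile = call_roh(ws, l_min=config.l_min)
        return het, profile

    het, profile = _stage("roh", _roh)
    long_tracts = profile.tracts[profile.tracts["length"] >= profile.l_min]
    write_bed(long_tracts, out / "roh_tracts.bed", extra_columns=("mean_het",))
    with open(out / "roh_summary.tsv", "w") as fh:
        fh.write(_header_lines(config))
        roh_summary(profile, config.focal).to_csv(fh, sep="\t", index=False)
    planted = data["truth"].roh_tracts
    planted_frac = float(
        (planted["end"] - planted["start"] + 1).sum()
        / sum(
            data["spec"].chrom_lengths[ch]
            for ch in data["pileup"].sites["chrom"].unique()
        )
    )
    report["roh_het"] = {
        "het_rate": het.het_rate,
        "het_truth": truth.het_rate,
        "n_sites_used": het.n_sites_used,
        "f_roh": profile.f_roh,
        "f_roh_planted": planted_frac,
        "n_long_tracts": int(len(long_tracts)),
        "L_min": profile.l_min,
    }

    # ---- ancestry tracts + dating -----------------------------------
    def _tracts():
        focal_j = matrix.sample_index(config.focal)
        calls = matrix.calls[:, focal_j]
        pcd_f, pcd_n = population_frequencies(matrix, config.pcd_panel)
        eur_f, eur_n = _pooled_frequencies(matrix, config.eur_panels)
        tv = matrix.sites["is_transversion"].to_numpy()
        alpha = (
            config.alpha_for_dating
            if config.alpha_for_dating is not None
            else min(max(alpha_mean, 0.01), 0.99)
        )
        return decode_and_date(
            calls[tv], matrix.sites[tv].reset_index(drop=True),
            pcd_f[tv], pcd_n[tv], eur_f[tv], eur_n[tv],
            data["rec_map"], alpha,
            rng=stage_seeds["tracts"],
            generation_time=config.generation_time,
        )

    tract_set, date = _stage("tracts", _tracts)
    tracts_bed = tract_set.tracts.copy()
    write_bed(tracts_bed, out / "ancestry_tracts.bed", extra_columns=("ancestry",))
    with open(out / "admixture_date.json", "w") as fh:
        json.dump(date.to_dict(), fh, indent=1, sort_keys=True)
    report["admixture_tracts"] = {
        **date.to_dict(),
        "t_truth": truth.t_admix,
        "posterior_eur_fraction": tract_set.posterior_eur_fraction,
        "eur_fraction_morgans": tract_set.eur_fraction_morgans,
    }

    # ---- dN/dS screen -----------------------------------------------
    def _screen():
        required = [SCREEN_FOCAL] + SCREEN_COMPARATORS + SCREEN_OUTGROUPS
        retained, low_cov = coverage_filter(data["alignments"], required)
        genes = [
            polarize_focal_changes(
                a, SCREEN_FOCAL, SCREEN_COMPARATORS, SCREEN_OUTGROUPS
            )
            for a in retained
        ]
        return screen_candidates(
            genes, threshold=config.threshold, low_coverage=low_cov
        )

    screen = _stage("screen", _screen)
    with open(out / "dnds_screen.tsv", "w") as fh:
        fh.write(_header_lines(config))
        screen.table.to_csv(fh, sep="\t", index=False)
    omegas = truth.gene_omega or {}
    selected = {g for g, w in omegas.items() if w > 1}
    neutral = {g for g, w in omegas.items() if w <= 1}
    cand = set(screen.candidates)
    report["dnds_screen"] = {
        "n_genes": int(len(screen.table)),
        "n_candidates": len(cand),
        "ds_genome": screen.ds_genome,
        "sensitivity": (
            len(cand & selected) / len(selected) if selected else float("nan")
        ),
        "false_candidacy": (
            len(cand & neutral) / len(neutral) if neutral else float("nan")
        ),
        "candidates": sorted(cand),
    }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
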