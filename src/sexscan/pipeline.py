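"""End-to-end orchestration of the sex-linked-region scan.

Stage order: MAF filter -> association scan -> significant-site
classification -> heterogamety call -> sex-reversal detection and
exclusion -> recomputation of the het-density and F_ST tracks on the
pruned cohort -> change-point segmentation and PAR/SLR calling ->
region fractions (-> X/Y Ks when annotation is supplied).  Exclusion is
a single pass.  Every stage's parameters and outputs are recorded in a
run manifest; identical config and seed give identical results.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import popstats, sexassoc, segment as segmod

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs, thresholds and window geometry for one full scan.

    Defaults mirror the scan's standard parameters: 50 kb/25 kb windows,
    MAF 0.05, genome-wide alpha 0.05, top-100 reversal SNPs with 0.9
    match fraction, at most three changepoints per track.
    """

    vcf: str
    sex: str
    out_dir: str
    chrom_length: int
    fasta: str | None = None
    gff: str | None = None
    depth: str | None = None
    window_size: int = 50_000
    window_step: int = 25_000
    maf_min: float = 0.05
    alpha: float = 0.05
    assoc_test: str = "fisher_allelic"
    class_frac: float = 0.8
    het_min_fraction: float = 0.8
    het_alpha: float = 0.01
    top_k: int = 100
    match_frac: float = 0.9
    max_cpts: int = 3
    penalty: str | float = "mbic"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


@dataclass
class ScanResult:
    regions: segmod.RegionCall | None
    heterogamety: sexassoc.HeterogametyCall
    reversals: sexassoc.ReversalReport | None
    fractions: dict
    summary: dict = field(default_factory=dict)


def run_full_scan(config: PipelineConfig) -> ScanResult:
    """Run the whole scan from files on disk, writing outputs and a
    manifest under ``config.out_dir``; returns the in-memory results."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gm = popstats.read_vcf(config.vcf)
    sexes = popstats.SexLabels.from_tsv(config.sex)
    depth = pd.read_csv(config.depth, sep="\t") if config.depth else None
    result, manifest = scan(gm, sexes, config, depth=depth, out_dir=out)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
        fh.write("\n")
    return result


def scan(
    gm: popstats.GenotypeMatrix,
    sexes: popstats.SexLabels,
    config: PipelineConfig,
    depth: pd.DataFrame | None = None,
    out_dir: Path | None = None,
):
    """In-memory scan over an already-loaded genotype matrix.

    Returns (ScanResult, manifest dict).  A failing stage raises with
    the stage name; outputs written before the failure are preserved.
    """
    manifest: dict = {"parameters": asdict(config), "stages": []}
    spec = popstats.WindowSpec(size=config.window_size, step=config.window_step)
    stage = "filter"
    try:
        t0 = time.time()
        gm = popstats.filter_sites(gm, maf_min=config.maf_min)
        _log_stage(manifest, stage, t0, n_sites=gm.n_sites)

        stage = "assoc"
        t0 = time.time()
        assoc = sexassoc.assoc_scan(gm, sexes, test=config.assoc_test, alpha=config.alpha)
        _log_stage(manifest, stage, t0, n_tested=assoc.n_tested,
                   threshold=assoc.threshold,
                   n_significant=int(assoc.table["significant"].fillna(False).sum()))

        stage = "heterogamety"
        t0 = time.time()
        m, f = sexassoc.classify_significant_sites(gm, sexes, assoc, frac=config.class_frac)
        het = sexassoc.heterogamety_call(
            m, f, min_fraction=config.het_min_fraction, alpha=config.het_alpha
        )
        _log_stage(manifest, stage, t0, call=het.call, n_male_het=m, n_female_het=f)

        stage = "reversals"
        reversals = None
        if het.call != "undetermined":
            t0 = time.time()
            reversals, sexes = sexassoc.detect_sex_reversals(
                gm, sexes, assoc, het,
                top_k=config.top_k, match_frac=config.match_frac,
            )
            _log_stage(manifest, stage, t0, flagged=reversals.flagged)

        stage = "tracks"
        t0 = time.time()
        fst = popstats.fst_windowed(gm, sexes, spec, config.chrom_length)
        hets = popstats.sex_het_site_classes(gm, sexes, spec, config.chrom_length)
        tracks = fst.merge(hets, on=["chrom", "start", "end"])
        tracks = tracks.merge(
            popstats.snp_density(gm, spec, config.chrom_length),
            on=["chrom", "start", "end"],
        )
        atrack = popstats.assoc_track(assoc.table, spec, config.chrom_length, gm.chrom)
        if depth is not None:
            tracks = tracks.merge(
                popstats.coverage_ratio(depth, sexes, spec, config.chrom_length),
                on=["chrom", "start", "end"],
            )
        if config.fasta:
            tracks = tracks.merge(
                popstats.gc_windows(config.fasta, spec, gm.chrom, config.chrom_length),
                on=["chrom", "start", "end"],
            )
        _log_stage(manifest, stage, t0, n_windows=len(tracks))

        stage = "segment"
        t0 = time.time()
        regions = None
        fractions: dict = {}
        if het.call != "undetermined":
            regions = segmod.call_regions(
                tracks, atrack, config.chrom_length,
                max_cpts=config.max_cpts, penalty=config.penalty,
            )
            fractions = segmod.region_fractions(regions, config.chrom_length)
        _log_stage(
            manifest, stage, t0,
            segments=[(int(s), int(e), c) for s, e, c in regions.segments] if regions else [],
            fractions=fractions,
        )

        summary = {
            "heterogamety": het.call,
            "n_significant_snps": int(assoc.table["significant"].fillna(False).sum()),
            "bonferroni_threshold": assoc.threshold,
            "flagged_reversals": reversals.flagged if reversals else [],
            "region_fractions_pct": fractions,
            "sex_linked_region_found": bool(
                regions and any(c == "SLR" for _, _, c in regions.segments)
            ),
        }
        if out_dir is not None:
            tracks.merge(atrack, on=["chrom", "start", "end"]).to_csv(
                out_dir / "tracks.tsv", sep="\t", index=False
            )
            assoc.table.to_csv(out_dir / "assoc.tsv", sep="\t", index=False)
            if reversals is not None:
                reversals.table.to_csv(out_dir / "reversals.tsv", sep="\t", index=False)
            with open(out_dir / "heterogamety.json", "w") as fh:
                json.dump(asdict(het), fh, indent=1)
                fh.write("\n")
            if regions is not None:
                regions.to_bed(out_dir / "regions.bed")
            with open(out_dir / "summary.json", "w") as fh:
                json.dump(summary, fh, indent=1, default=str)
                fh.write("\n")
        return (
            ScanResult(
                regions=regions, heterogamety=het, reversals=reversals,
                fractions=fractions, summary=summary,
            ),
            manifest,
        )
    except Exception:
        logger.exception("pipeline failed at stage %r", stage)
        manifest["failed_stage"] = stage
        if out_dir is not None:
            with open(out_dir / "manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=1, default=str)
                fh.write("\n")
        raise


def _log_stage(manifest: dict, name: str, t0: float, **info) -> None:
    entry = {"stage": name, "seconds": round(time.time() - t0, 3), **info}
    manifest["stages"].append(entry)
    logger.info("stage %s done in %.1fs: %s", name, entry["seconds"], info)
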