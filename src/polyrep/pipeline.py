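"""End-to-end orchestration: synthetic or user data in, report bundle out.

A :class:`RunConfig` (YAML-representable) names either a simulation block or
input files, the caller parameters, permutation counts, and a master seed.
``run_pipeline`` executes the stages in order — simulate (optional), UR
calling per tissue with replicate intersection, UR geometry, cross-tissue
specificity, ORC statistics, interval statistics vs TADs and γH2Av, and
expression summaries — writing BED/TSV outputs, a JSON metrics file, and a
log that records every parameter and derived stage seed.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import io as pio
from .caller import CallerParams, call_tissue
from .genome import GenomeLayout, GInterval, IntervalSet, complement
from .metrics import average_replicates, profile_ur, specificity_matrix, width_depth_relation
from .orc import depletion_test, low_density_domains, orc_density, orc_free_zone, urs_with_orc
from .simulate import FPKMModel, SimConfig, SimulatedTissue, URSpec, simulate_tissue
from .stats import classify_vs_tads, jaccard, peaks_per_region, placement_permutation_test, projection_test
from .transcription import fraction_expressed_in_regions

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: master seed mixed with a stage-name hash."""
    return (int(master_seed) ^ zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    """Everything one run needs; round-trips through YAML."""

    seed: int
    outdir: str
    simulate: Mapping[str, Any] | None = None
    inputs: Mapping[str, Any] | None = None
    caller: Mapping[str, Any] = field(default_factory=dict)
    n_perm: int = 2_000
    schema_version: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _build_sim_configs(block: Mapping[str, Any], seed: int) -> dict[str, SimConfig]:
    genome = GenomeLayout({str(k): int(v) for k, v in block["genome"].items()})
    shared = {
        k: block[k]
        for k in ("probe_spacing", "noise_sd", "noise_skew", "orc_base_rate",
                  "orc_poor_rate", "tad_mean_width", "n_transcripts",
                  "h2av_inside_rate", "h2av_outside_rate")
        if k in block
    }
    configs = {}
    for i, (tissue, spec) in enumerate(block["tissues"].items()):
        urs = [
            URSpec(GInterval(str(c), int(s), int(e)), float(d))
            for c, s, e, d in spec.get("urs", [])
        ]
        ur_set = IntervalSet.from_intervals([u.interval for u in urs])
        configs[tissue] = SimConfig(
            genome=genome,
            seed=stage_seed(seed, f"simulate:{tissue}"),
            ur_specs=urs,
            orc_poor_domains=ur_set if len(ur_set) else None,
            **shared,
        )
    return configs


def _load_inputs(block: Mapping[str, Any]):
    genome = pio.read_chrom_sizes(block["genome"])
    tissues = {}
    for tissue, spec in block["tissues"].items():
        rep_paths = spec["probes"]
        if len(rep_paths) != 2:
            raise ValueError(f"tissue {tissue!r}: need exactly 2 replicate probe tables")
        profiles = tuple(pio.read_probe_table(p, genome) for p in rep_paths)
        tissues[tissue] = profiles
    extras = {}
    for key, reader in (
        ("orc_peaks", pio.read_points),
        ("h2av_peaks", pio.read_points),
        ("tads", pio.read_bed),
    ):
        if key in block:
            extras[key] = reader(block[key], genome)
    if "transcripts" in block:
        extras["transcripts"] = pio.read_transcripts(block["transcripts"])
    return genome, tissues, extras


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns the metrics dict (also written to
    ``metrics.json`` in the output directory)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("polyrep")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    metrics: dict[str, Any] = {"seed": config.seed, "stages": {}}
    try:
        return _run(config, outdir, metrics)
    except Exception as exc:  # annotate which stage died
        stage = metrics.get("current_stage", "setup")
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, outdir: Path, metrics: dict) -> dict:
    params = CallerParams(**dict(config.caller))
    logger.info("caller params: %s", params)

    metrics["current_stage"] = "inputs"
    sims: dict[str, SimulatedTissue] = {}
    if config.simulate is not None:
        sim_configs = _build_sim_configs(config.simulate, config.seed)
        for tissue, sc in sim_configs.items():
            logger.info("simulating tissue %s with seed %d", tissue, sc.seed)
            sims[tissue] = simulate_tissue(sc)
        genome = next(iter(sim_configs.values())).genome
        tissues = {t: s.profiles for t, s in sims.items()}
        first = next(iter(sims.values()))
        extras = {
            "orc_peaks": first.orc_peaks,
            "h2av_peaks": first.h2av_peaks,
            "tads": first.tads,
            "transcripts": first.transcripts,
        }
        for tissue, sim in sims.items():
            for r, prof in enumerate(sim.profiles, start=1):
                pio.write_probe_table(prof, outdir / f"{tissue}_rep{r}.bedgraph")
            pio.write_points(sim.orc_peaks, outdir / f"{tissue}_orc.bed")
        pio.write_bed(first.tads, outdir / "tads.bed")
        pio.write_transcripts(first.transcripts, outdir / "transcripts.tsv")
    elif config.inputs is not None:
        genome, tissues, extras = _load_inputs(config.inputs)
    else:
        raise ValueError("config needs a 'simulate' or 'inputs' block")

    metrics["current_stage"] = "call_ur"
    hc_urs: dict[str, IntervalSet] = {}
    for tissue, profiles in tissues.items():
        hc, reps = call_tissue(profiles, params)
        hc_urs[tissue] = hc
        pio.write_bed(hc, outdir / f"{tissue}_urs.bed")
        meta = {f"rep{i+1}": r.to_metadata() for i, r in enumerate(reps)}
        meta["high_confidence_n"] = len(hc)
        meta["high_confidence_bp"] = hc.coverage_bp
        metrics["stages"][f"call_ur:{tissue}"] = meta
        with open(outdir / f"{tissue}_caller.json", "w") as fh:
            json.dump(meta, fh, indent=2)
        logger.info("tissue %s: %d high-confidence URs", tissue, len(hc))

    metrics["current_stage"] = "profile_ur"
    geometry: dict[str, list] = {}
    for tissue, profiles in tissues.items():
        from .caller import center_profile, smooth_profile

        smoothed = []
        for rep in profiles:
            s = smooth_profile(rep, params.smoothing_bandwidth)
            c, _ = center_profile(s)
            smoothed.append(c)
        profs = []
        for iv in hc_urs[tissue]:
            pair = [profile_ur(iv, rep, genome) for rep in smoothed]
            profs.append(average_replicates(pair[0], pair[1]))
        geometry[tissue] = profs
        rows = [
            {
                "chrom": p.ur.chrom, "start": p.ur.start, "end": p.ur.end,
                "min_log2": p.min_log2, "min_pos": p.min_pos,
                "halfmin_width": p.halfmin_width, "max_fold_ur": p.max_fold_ur,
                "pericentric": p.pericentric, "edge_truncated": p.edge_truncated,
            }
            for p in profs
        ]
        import pandas as pd

        pd.DataFrame(rows).to_csv(outdir / f"{tissue}_urprofiles.tsv", sep="\t", index=False)
        if len(profs) >= 3:
            wd = width_depth_relation(profs)
            metrics["stages"][f"width_depth:{tissue}"] = {
                "n": wd["n"], "spearman_rho": wd["spearman_rho"], "p": wd["p_value"],
            }

    if len(tissues) >= 2:
        metrics["current_stage"] = "specificity"
        spec = specificity_matrix(list(hc_urs.items()))
        spec.clusters.to_csv(outdir / "specificity_matrix.tsv", sep="\t", index=False)
        metrics["stages"]["specificity"] = {
            "n_clusters": int(spec.counts_by_class.sum()),
            "counts_by_class": {int(k): int(v) for k, v in spec.counts_by_class.items()},
            "fraction_specific_clusters": spec.fraction_specific_clusters,
            "fraction_specific_bp": spec.fraction_specific_bp,
        }

    focal = next(iter(tissues))
    urs = hc_urs[focal]
    if "orc_peaks" in extras and len(urs):
        metrics["current_stage"] = "orc_stats"
        peaks = extras["orc_peaks"]
        fully = complement(urs, genome)
        depl = depletion_test(
            peaks, urs, genome,
            n_perm=config.n_perm, seed=stage_seed(config.seed, "depletion"),
        )
        frac_occ, _ = urs_with_orc(urs, peaks)
        zones = [orc_free_zone(iv, peaks) for iv in urs]
        domains, dom_table = low_density_domains(peaks, genome)
        dom_table.to_csv(outdir / "low_density_domains.tsv", sep="\t", index=False)
        pio.write_bed(domains, outdir / "low_density_domains.bed")
        orc_metrics = {
            "density_in_urs_per_100kb": orc_density(peaks, urs),
            "density_fully_replicated_per_100kb": orc_density(peaks, fully),
            "depletion_observed": depl.observed,
            "depletion_null_mean": depl.null_mean,
            "depletion_p": depl.p_value,
            "fraction_urs_with_orc": frac_occ,
            "n_low_density_domains": len(domains),
        }
        if len(domains):
            proj = projection_test(
                urs, domains, genome, mode="permutation",
                n_perm=config.n_perm, seed=stage_seed(config.seed, "projection"),
            )
            orc_metrics["jaccard_urs_vs_low_density"] = jaccard(urs, domains)
            orc_metrics["projection_p_urs_vs_low_density"] = proj.projection_p
        widths = [z.zone_width for z in zones if z.zone_width is not None]
        if widths:
            orc_metrics["median_orc_free_zone_bp"] = float(np.median(widths))
        metrics["stages"]["orc_stats"] = orc_metrics

    if "tads" in extras and len(urs):
        metrics["current_stage"] = "interval_stats"
        tads = extras["tads"]
        cls = classify_vs_tads(urs, tads)
        placement = placement_permutation_test(
            urs, tads, genome,
            n_iter=config.n_perm, seed=stage_seed(config.seed, "placement"),
        )
        metrics["stages"]["tads"] = {
            "fractions": cls.fractions,
            "placement_observed": placement.observed,
            "placement_null_mean": placement.null_mean,
            "placement_p": placement.p_value,
        }

    if "h2av_peaks" in extras and len(urs):
        frac, mean_nz, _ = peaks_per_region(urs, extras["h2av_peaks"])
        metrics["stages"]["h2av"] = {
            "fraction_urs_with_peak": frac,
            "mean_peaks_per_occupied_ur": mean_nz,
        }

    if "transcripts" in extras and len(urs):
        metrics["current_stage"] = "expression"
        tx = extras["transcripts"]
        tissue_cols = [
            c for c in tx.columns
            if c not in ("transcript_id", "chrom", "tss", "strand")
        ]
        expr = {}
        fully = complement(urs, genome)
        for col in tissue_cols:
            f_ur, n_ur, _ = fraction_expressed_in_regions(tx, urs, col)
            f_full, n_full, _ = fraction_expressed_in_regions(tx, fully, col)
            expr[col] = {
                "fraction_expressed_in_urs": f_ur,
                "n_tss_in_urs": n_ur,
                "fraction_expressed_fully_replicated": f_full,
                "n_tss_fully_replicated": n_full,
            }
        metrics["stages"]["expression"] = expr

    metrics.pop("current_stage", None)
    with open(outdir / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
    logger.info("wrote %s", outdir / "metrics.json")
    return metrics
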