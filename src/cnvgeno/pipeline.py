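"""End-to-end pipeline: segments -> filter/merge -> restrict -> call -> scan -> interaction.

Configured by a single YAML file (shareable, hashable into the run manifest)
with CLI flags allowed to override individual entries.  Every stage writes
its TSV artifact and logs row counts; floating-point output is serialized at
6 significant digits so reruns with the same config are byte-stable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .association import (
    MeffScope,
    dosage_matrix,
    effective_num_tests,
    logistic_interaction,
    majority_allele_coding,
    manhattan_table,
    region_scan,
)
from .calling import ThresholdScheme, call_rate, call_region
from .cnv_regions import filter_cnvs, merge_cnvs, restrict_to_region, segment_lrr
from .signal_io import (
    genes_for_positions,
    read_gene_map,
    read_penncnv_rawcnv,
    read_phenotype_table,
    read_signal_table,
    write_association_table,
    write_calls_table,
    write_phenotype_table,
    write_segments_table,
    write_signal_table,
    _fmt,
)
from .simdata import SimParams, simulate_cohort
from .types import Diagnosis, Region

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: pipeline config must be a mapping")
    return cfg


def _region_from_config(cfg: dict) -> Optional[Region]:
    r = cfg.get("region")
    if r is None:
        return None
    return Region(chrom=str(r["chrom"]), start=int(r["start"]), end=int(r["end"]))


def _scheme_from_config(cfg: dict) -> ThresholdScheme:
    if "scheme" in cfg:
        return ThresholdScheme.from_dict(cfg["scheme"])
    return ThresholdScheme()


def _sim_params_from_config(cfg: dict, seed_override: Optional[int] = None) -> SimParams:
    sim = dict(cfg.get("simulate", {}))
    if "region" in sim:
        r = sim.pop("region")
        region = Region(chrom=str(r["chrom"]), start=int(r["start"]), end=int(r["end"]))
    else:
        region = _region_from_config(cfg) or SimParams().region
    if seed_override is not None:
        sim["seed"] = seed_override
    return SimParams(region=region, **sim)


def run_pipeline(config: dict, outdir, seed: Optional[int] = None) -> dict:
    """Execute the full pipeline and write artifacts under ``outdir``.

    Returns the run manifest (also written to ``manifest.json``).  Any stage
    failure raises :class:`StageError` naming the stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "cnvgeno_version": __version__,
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(config, sort_keys=True).encode()
        ).hexdigest(),
        "stages": {},
    }
    scheme = _scheme_from_config(config)
    region = _region_from_config(config)

    # ---- stage: inputs -------------------------------------------------
    stage = "inputs"
    try:
        inputs = config.get("inputs", {})
        if "simulate" in config:
            params = _sim_params_from_config(config, seed_override=seed)
            signals, phenotypes, truth = simulate_cohort(params, scheme=scheme)
            if region is None:
                region = params.region
            sim_dir = outdir / "simulated"
            sim_dir.mkdir(exist_ok=True)
            for sig in signals:
                write_signal_table(sig, sim_dir / f"{sig.sample_id}.signal.tsv")
            write_phenotype_table(phenotypes, sim_dir / "phenotypes.tsv")
            truth.genotypes.to_csv(sim_dir / "truth_genotypes.tsv", sep="\t", index=False)
            resolved = asdict(params)
            resolved["allele_freqs"] = None  # frozen in truth table; keep config small
            resolved["region"] = {"chrom": params.region.chrom, "start": params.region.start, "end": params.region.end}
            with open(sim_dir / "sim_config.yaml", "w") as fh:
                yaml.safe_dump(resolved, fh, sort_keys=True)
            rawcnv_segments = None
        else:
            signal_paths = inputs.get("signals", {})
            if not signal_paths:
                raise ValueError("config.inputs.signals is required when not simulating")
            signals = [read_signal_table(p, sample_id=s) for s, p in sorted(signal_paths.items())]
            phenotypes = read_phenotype_table(inputs["phenotypes"])
            rawcnv_segments = (
                read_penncnv_rawcnv(inputs["rawcnv"]) if "rawcnv" in inputs else None
            )
        manifest["stages"][stage] = {"n_samples": len(signals)}
    except StageError:
        raise
    except Exception as e:
        raise StageError(stage, str(e)) from e

    # ---- stage: segments -----------------------------------------------
    stage = "segments"
    try:
        seg_cfg = config.get("segmenter", {})
        if rawcnv_segments is not None:
            raw = rawcnv_segments
        else:
            raw = []
            for sig in signals:
                raw.extend(
                    segment_lrr(
                        sig,
                        cn1_cut=float(seg_cfg.get("cn1_cut", -0.3)),
                        cn3_cut=float(seg_cfg.get("cn3_cut", 0.2)),
                        min_run=int(seg_cfg.get("min_run", 10)),
                    )
                )
        write_segments_table(raw, outdir / "segments_raw.tsv")

        filt_cfg = config.get("filter", {})
        filtered = filter_cnvs(
            raw,
            min_snps=int(filt_cfg.get("min_snps", 10)),
            min_length=int(filt_cfg.get("min_length", 10_000)),
        )
        max_gap = int(config.get("merge", {}).get("max_gap", 1_000))
        merged = []
        for sample_id in sorted({s.sample_id for s in filtered}):
            merged.extend(merge_cnvs([s for s in filtered if s.sample_id == sample_id], max_gap=max_gap))
        working = restrict_to_region(merged, region) if region is not None else merged
        write_segments_table(working, outdir / "segments.tsv")
        manifest["stages"][stage] = {
            "n_raw": len(raw), "n_filtered": len(filtered), "n_merged": len(merged), "n_in_region": len(working),
        }
        logger.info("segments: %d raw -> %d filtered -> %d merged -> %d in region",
                    len(raw), len(filtered), len(merged), len(working))
    except Exception as e:
        raise StageError(stage, str(e)) from e

    # ---- stage: call ----------------------------------------------------
    stage = "call"
    try:
        by_sample = {sig.sample_id: sig for sig in signals}
        calls = []
        for seg in working:
            if seg.copy_number not in (1, 3):
                continue
            calls.extend(call_region(by_sample[seg.sample_id], seg, scheme=scheme))
        write_calls_table(calls, outdir / "calls.tsv")
        diag = {p.sample_id: p.diagnosis for p in phenotypes}
        rates = {}
        for group in (Diagnosis.DEL, Diagnosis.DUP):
            group_calls = [c for c in calls if diag.get(c.sample_id) is group]
            summary = call_rate(group_calls)
            rates[group.value] = {
                "n_called": summary.n_called,
                "n_total": summary.n_total,
                "rate_percent": summary.rate_percent,
            }
        with open(outdir / "call_rates.json", "w") as fh:
            json.dump(rates, fh, indent=2, sort_keys=True)
        manifest["stages"][stage] = {"n_calls": len(calls), "call_rates": rates}
    except Exception as e:
        raise StageError(stage, str(e)) from e

    # ---- stage: scan ----------------------------------------------------
    stage = "scan"
    try:
        del_samples = {p.sample_id for p in phenotypes if p.diagnosis is Diagnosis.DEL}
        del_calls = [c for c in calls if c.sample_id in del_samples]
        gene_map = None
        if "gene_map" in inputs:
            gm = read_gene_map(inputs["gene_map"])
            positions = (
                pd.DataFrame(
                    {"snp_id": [c.snp_id for c in del_calls],
                     "chrom": [c.chrom for c in del_calls],
                     "pos": [c.pos for c in del_calls]}
                )
                .drop_duplicates("snp_id")
            )
            gene_map = genes_for_positions(positions, gm)

        scopes = []
        for sc in config.get("scopes", []):
            if sc.get("estimate"):
                genes = sc.get("genes")
                scope_calls = del_calls
                if genes and gene_map:
                    scope_calls = [c for c in del_calls if gene_map.get(c.snp_id) in set(genes)]
                est = effective_num_tests(dosage_matrix(scope_calls), scope=sc.get("label", "estimated"))
                meff = est.meff
            else:
                meff = float(sc["meff"])
            scopes.append(
                MeffScope(
                    meff=meff,
                    genes=frozenset(sc["genes"]) if sc.get("genes") else None,
                    label=sc.get("label", ""),
                )
            )
        results = region_scan(del_calls, phenotypes, gene_map=gene_map, scopes=scopes) if del_calls else []
        write_association_table(results, outdir / "assoc.tsv")
        mtab = manhattan_table(results)
        mtab["neglog10_p"] = mtab["neglog10_p"].map(_fmt)
        mtab.to_csv(outdir / "manhattan.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "n_snps": len(results),
            "n_testable": sum(not r.untestable for r in results),
            "top_snp": results[0].snp_id if results and not results[0].untestable else None,
        }
    except Exception as e:
        raise StageError(stage, str(e)) from e

    # ---- stage: interaction ---------------------------------------------
    stage = "interaction"
    try:
        inter_cfg = config.get("interaction", {})
        snp = inter_cfg.get("snp")
        if snp is None and results and not results[0].untestable:
            snp = results[0].snp_id
        if snp is not None:
            coding = majority_allele_coding(calls, snp, risk_allele=inter_cfg.get("risk_allele", "B"))
            fit = logistic_interaction(phenotypes, coding)
            payload = {
                "snp_id": snp,
                "n": fit.n,
                "coefficients": {k: float(_fmt(v)) for k, v in fit.coefficients.items()},
                "loglik_full": float(_fmt(fit.loglik_full)),
                "loglik_null": float(_fmt(fit.loglik_null)),
                "nagelkerke_r2": None if fit.nagelkerke_r2 is None else float(_fmt(fit.nagelkerke_r2)),
                "model_p": float(_fmt(fit.model_p)),
                "separation_flag": fit.separation_flag,
                "converged": fit.converged,
            }
        else:
            payload = {"snp_id": None, "note": "no testable SNP available for the interaction model"}
        with open(outdir / "interaction.json", "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
        manifest["stages"][stage] = {"snp": snp}
    except Exception as e:
        raise StageError(stage, str(e)) from e

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
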