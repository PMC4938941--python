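"""End-to-end orchestration: QC -> Δβ -> FhmC -> differential -> annotation
-> enrichment, from a single config, with deterministic seeding and a JSON
summary plus provenance record.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as oio
from .annotation import annotate_probes, enlarge_sites, probes_in_track, smooth_track, transcripts_from_bed12
from .differential import crosstab_sets, detect_differential, split_directions
from .enrichment import enrich_categorical, enrich_qualitative, shift_quantitative
from .errors import ConfigError
from .fhmc import call_fhmc
from .qc import clip_nonnegative, compute_hydroxy, filter_by_detection
from .synth import (
    SynthConfig,
    generate_annotation,
    generate_detection_p,
    generate_paired_betas,
    sample_sheet_long,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One config drives a full run: a synthetic block *or* real input paths,
    plus all analysis thresholds."""

    outdir: str
    seed: int = 0
    synthetic: SynthConfig | None = None
    inputs: dict | None = None
    fhmc_level: float = 0.1
    fhmc_frac: float = 0.5
    p_gate: float = 0.05
    fdr_differential: float = 0.25
    fdr_enrichment: float = 0.05
    drop_frac: float = 0.30
    probe_fail_n: int = 2
    sample_fail_n: float = 5500
    detp_cut: float = 0.01
    density_window: int = 2000
    smoothing_bin: int = 100_000
    enlarge_width: int = 200_000
    log_level: str = "INFO"

    def __post_init__(self):
        if (self.synthetic is None) == (self.inputs is None):
            raise ConfigError("config needs exactly one of a synthetic block or real inputs")
        for name in ("fhmc_level", "fhmc_frac", "p_gate", "fdr_differential",
                     "fdr_enrichment", "drop_frac", "detp_cut"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ConfigError(f"{name} must lie in (0, 1), got {v}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("synthetic") is not None and not isinstance(d["synthetic"], SynthConfig):
            d["synthetic"] = SynthConfig(**d["synthetic"])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        return cls.from_dict(oio.load_config_file(path))

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _load_real_inputs(inputs: dict):
    bs = oio.read_beta_tsv(inputs["bs"])
    oxbs = oio.read_beta_tsv(inputs["oxbs"])
    sheet = oio.read_sample_sheet(inputs["sample_sheet"])
    samples = sheet.drop_duplicates("sample_id").set_index("sample_id")[["age", "group"]]
    samples["batch"] = sheet.drop_duplicates("sample_id").set_index("sample_id").get("batch", "b1")
    detp = oio.read_beta_tsv(inputs["detp"]) if inputs.get("detp") else None
    probes = oio.read_probe_annotation(inputs["probes"])
    transcripts = transcripts_from_bed12(oio.read_bed(inputs["transcripts"]))
    cgis = oio.read_bed(inputs["cgis"])
    gaps = oio.read_bed(inputs["gaps"])
    peaks = {name: oio.read_bed(path) for name, path in inputs.get("peaks", {}).items()}
    states = {name: oio.read_bed(path) for name, path in inputs.get("states", {}).items()}
    return bs, oxbs, samples, detp, probes, transcripts, cgis, gaps, peaks, states, None, None


def _enrichment_block(cfg, subset, background, context, peaks_members, state_members):
    """All enrichment analyses for one probe subset against the background."""
    out = {}
    if peaks_members:
        out["histone"] = enrich_qualitative(
            subset, background, peaks_members, test="fisher", fdr=cfg.fdr_enrichment
        )
    if state_members:
        out["states"] = enrich_qualitative(
            subset, background, state_members, test="fisher", fdr=cfg.fdr_enrichment
        )
    stat, p, per = enrich_categorical(subset, background, context["region"].astype(str))
    out["region"] = per
    out["region_overall"] = {"statistic": stat, "p": p}
    stat, p, per = enrich_categorical(subset, background, context["cgi_status"].astype(str))
    out["cgi"] = per
    out["cgi_overall"] = {"statistic": stat, "p": p}

    rest = [p for p in background if p not in set(subset)]
    quant = {}
    for metric in ("cpg_density", "dist_centromere", "dist_telomere"):
        if metric not in context.columns:
            continue
        pval, d = shift_quantitative(
            context.loc[list(subset), metric].to_numpy(dtype=float),
            context.loc[rest, metric].to_numpy(dtype=float),
        )
        quant[metric] = {"p": pval, "cliffs_delta": d}
    out["quantitative"] = quant
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write all tables under ``config.outdir``.

    Returns the summary dict (also written to ``summary.json``).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    genome = None
    truth = None
    if config.synthetic is not None:
        ann = generate_annotation(config.synthetic)
        paired, truth = generate_paired_betas(config.synthetic, ann.probes)
        detp = generate_detection_p(config.synthetic, ann.probes, paired.sample_ids)
        probes, transcripts, cgis, gaps = ann.probes, ann.transcripts, ann.cgis, ann.gaps
        peaks, states, genome = ann.peaks, ann.states, ann.genome
        oio.write_beta_tsv(paired.bs, outdir / "betas_bs.tsv")
        oio.write_beta_tsv(paired.oxbs, outdir / "betas_oxbs.tsv")
        oio.write_beta_tsv(detp, outdir / "detection_p.tsv")
        oio.write_sample_sheet(sample_sheet_long(paired.samples), outdir / "sample_sheet.tsv")
        truth.to_csv(outdir / "truth.tsv", sep="\t", float_format=oio.FLOAT_FMT)
        probes.to_csv(outdir / "probes.tsv", sep="\t")
        oio.write_bed(cgis, outdir / "cgis.bed")
        oio.write_bed(gaps, outdir / "gaps.bed")
    else:
        (bs, oxbs, samples, detp, probes, transcripts, cgis, gaps, peaks, states,
         genome, truth) = _load_real_inputs(config.inputs)
        from .qc import PairedBetaSet
        paired = PairedBetaSet(bs=bs, oxbs=oxbs, samples=samples)

    n_probes_in, n_samples_in = len(paired.probe_ids), len(paired.sample_ids)

    if detp is not None:
        paired = filter_by_detection(
            paired.bs, paired.oxbs, detp.loc[paired.probe_ids, paired.sample_ids],
            samples=paired.samples,
            probe_fail_n=config.probe_fail_n,
            sample_fail_n=config.sample_fail_n,
            p_cut=config.detp_cut,
        )

    hydro = compute_hydroxy(paired)
    oio.write_beta_tsv(hydro.hmc, outdir / "hmc.tsv")
    oio.write_beta_tsv(hydro.mc, outdir / "mc.tsv")
    oio.write_beta_tsv(hydro.total, outdir / "total.tsv")
    oio.write_beta_tsv(clip_nonnegative(hydro.hmc), outdir / "hmc_clipped.tsv")

    calls, per_sample = call_fhmc(hydro.hmc, level=config.fhmc_level, frac=config.fhmc_frac)
    calls.to_csv(outdir / "fhmc_calls.tsv", sep="\t")
    per_sample.to_frame().to_csv(outdir / "fhmc_per_sample.tsv", sep="\t")
    fhmc_set = list(calls.index[calls["is_fhmc"]])

    groups = paired.samples["group"]
    diff = {}
    splits = {}
    for name, mat in (("5hmc", hydro.hmc), ("5mc", hydro.mc)):
        table = detect_differential(
            mat, groups, fdr=config.fdr_differential,
            p_gate=config.p_gate, drop_frac=config.drop_frac,
        )
        table.to_csv(outdir / f"differential_{name}.tsv", sep="\t", float_format=oio.FLOAT_FMT)
        diff[name] = table
        splits[name] = split_directions(table)

    xtab = crosstab_sets(
        splits["5hmc"].hyper, splits["5hmc"].hypo,
        splits["5mc"].hyper, splits["5mc"].hypo,
        a_labels=("hyper5hmc", "hypo5hmc"), b_labels=("hyper5mc", "hypo5mc"),
    )
    xtab.counts.to_csv(outdir / "crosstab_counts.tsv", sep="\t")
    xtab.row_pct.to_csv(outdir / "crosstab_row_pct.tsv", sep="\t", float_format=oio.FLOAT_FMT)

    kept = probes.loc[paired.probe_ids]
    context = annotate_probes(
        kept, transcripts, cgis, gaps, genome=genome, window=config.density_window
    )
    context.to_csv(outdir / "probe_context.tsv", sep="\t", float_format=oio.FLOAT_FMT)

    background = list(paired.probe_ids)
    peaks_members = {name: probes_in_track(kept, track) for name, track in peaks.items()}
    state_members = {}
    for cell, seg in states.items():
        for state in seg["name"].unique():
            state_members[f"{cell}.{state}"] = probes_in_track(
                kept, seg[seg["name"] == state]
            )

    subsets = {"fhmc": fhmc_set,
               "hyper5hmc": sorted(splits["5hmc"].hyper),
               "hypo5hmc": sorted(splits["5hmc"].hypo)}
    enrich_results = {}
    for sub_name, subset in subsets.items():
        if not subset:
            logger.info("subset %s empty; enrichment skipped", sub_name)
            continue
        block = _enrichment_block(config, subset, background, context,
                                  peaks_members, state_members)
        enrich_results[sub_name] = block
        for fam in ("histone", "states", "region", "cgi"):
            if fam in block:
                block[fam].to_csv(outdir / f"enrichment_{sub_name}_{fam}.tsv",
                                  sep="\t", float_format=oio.FLOAT_FMT)

    # circular-plot helper tracks
    if peaks:
        first = sorted(peaks)[0]
        chrom_sizes = (config.synthetic.chrom_sizes if config.synthetic is not None
                       else {c: int(g["end"].max()) for c, g in gaps.groupby("chrom")})
        smoothed = smooth_track(peaks[first], chrom_sizes, bin_size=config.smoothing_bin)
        smoothed.to_csv(outdir / f"smoothed_{first}.tsv", sep="\t",
                        float_format=oio.FLOAT_FMT, index=False)
        if fhmc_set:
            enlarged = enlarge_sites(kept.loc[fhmc_set], width=config.enlarge_width,
                                     chrom_sizes=chrom_sizes)
            oio.write_bed(enlarged.assign(name="fhmc"), outdir / "fhmc_enlarged.bed")

    summary = {
        "n_probes_input": n_probes_in,
        "n_samples_input": n_samples_in,
        "n_probes_analyzed": len(paired.probe_ids),
        "n_samples_analyzed": len(paired.sample_ids),
        "n_fhmc": len(fhmc_set),
        "differential": {
            name: {
                "n_significant": splits[name].n_total,
                "n_hyper": splits[name].n_hyper,
                "n_hypo": splits[name].n_hypo,
                "pct_hyper": splits[name].pct_hyper,
                "pct_hypo": splits[name].pct_hypo,
            }
            for name in splits
        },
        "crosstab": {
            "counts": {r: xtab.counts.loc[r].to_dict() for r in xtab.counts.index},
            "row_pct": {r: xtab.row_pct.loc[r].to_dict() for r in xtab.row_pct.index},
            "set_sizes": xtab.set_sizes,
        },
        "enrichment": {
            sub: {
                fam: int(block[fam]["enriched"].sum())
                for fam in ("histone", "states", "region", "cgi") if fam in block
            } | {"quantitative": block["quantitative"]}
            for sub, block in enrich_results.items()
        },
    }
    if truth is not None:
        summary["truth"] = {
            "n_fhmc_true": int(truth["is_fhmc"].sum()),
            "n_hyper5hmc_true": int(truth["is_hyper5hmc"].sum()),
            "n_hypo5hmc_true": int(truth["is_hypo5hmc"].sum()),
        }

    def _json_default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            v = float(o)
            return None if np.isnan(v) else v
        raise TypeError(f"not JSON serializable: {type(o)}")

    def _clean(obj):
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, float) and np.isnan(obj):
            return None
        return obj

    summary = _clean(summary)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=_json_default))

    cfg_dict = config.to_dict()
    provenance = {
        "package": "oxbs5hmc",
        "version": __version__,
        "seed": config.seed,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return summary
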