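"""Synthetic paired oxBS/BS array data with known ground truth.

Generates a toy genome (sequence, transcripts, CpG islands, centromere /
telomere gaps, histone-peak and chromatin-state tracks) and paired BS/oxBS
beta matrices for a young/old donor cohort, spiking known frequently
hydroxymethylated probes and differential 5hmC / 5mC effects so every
downstream stage can be validated against a truth table.

The default cohort is 11 young and 6 old donors — the unbalanced small-n
regime the analysis is designed for.  5hmC is additive by construction:
BS beta draws around 5mC + 5hmC, oxBS around 5mC alone, so the subtraction
estimator Δβ = BS − oxBS is unbiased for the planted 5hmC level.  Noise is
Beta-distributed around each target mean (precision mapped from ``noise_sd``),
which respects the [0, 1] bounds without clipping artifacts; ``noise_sd = 0``
returns the exact means.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .annotation import Transcript
from .errors import ConfigError
from .qc import PairedBetaSet

STATE_NAMES = ("Promoter", "Enhancer", "Transcribed", "Repressed", "Heterochromatin")
CELL_LINES = ("CellA", "CellB")
HISTONE_MARKS = ("H3k4me1", "H3k9me3", "H3k27me3")


def _default_chrom_sizes():
    return {"chr1": 10_000_000, "chr2": 6_000_000}


@dataclass
class SynthConfig:
    """Parameters of the synthetic study.

    ``n_young``/``n_old`` default to the 11/6 cohort; ``fhmc_level`` is the
    planted Δβ at frequently hydroxymethylated probes; ``effect_size`` the
    old-group shift at spiked differential probes; ``noise_sd`` the per-cell
    beta dispersion.
    """

    seed: int = 0
    n_probes: int = 10_000
    n_young: int = 11
    n_old: int = 6
    frac_fhmc: float = 0.05
    fhmc_level: float = 0.2
    n_hyper5hmc: int = 50
    n_hypo5hmc: int = 50
    n_hyper5mc: int = 50
    n_hypo5mc: int = 50
    effect_size: float = 0.2
    noise_sd: float = 0.03
    detp_fail_rate: float = 0.0005
    chrom_sizes: dict = field(default_factory=_default_chrom_sizes)

    def __post_init__(self):
        if not self.chrom_sizes or any(int(v) <= 0 for v in self.chrom_sizes.values()):
            raise ConfigError("chrom_sizes must be non-empty with positive lengths")
        for name in ("n_probes", "n_young", "n_old", "n_hyper5hmc", "n_hypo5hmc",
                     "n_hyper5mc", "n_hypo5mc"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.n_probes < 1:
            raise ConfigError("n_probes must be >= 1")
        if self.n_young < 1 or self.n_old < 1:
            raise ConfigError("both age groups need at least one sample")
        if not (0 < self.fhmc_level <= 1):
            raise ConfigError("fhmc_level must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if not (0 <= self.frac_fhmc <= 1):
            raise ConfigError("frac_fhmc must lie in [0, 1]")
        n_fhmc = int(round(self.frac_fhmc * self.n_probes))
        if self.n_hypo5hmc > n_fhmc:
            raise ConfigError("n_hypo5hmc spikes must fit inside the FhmC set")
        if n_fhmc + self.n_hyper5hmc + self.n_hyper5mc + self.n_hypo5mc > self.n_probes:
            raise ConfigError("spiked probe sets exceed n_probes")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SynthAnnotation:
    """Toy genome and tracks: everything annotate_probes and enrichment need."""

    probes: pd.DataFrame              # index probe_id; chrom, pos (1-based), strand
    genome: dict                      # chrom -> sequence string
    transcripts: list                 # Transcript models
    transcripts_bed: pd.DataFrame     # BED12 frame of the same models
    cgis: pd.DataFrame                # BED: chrom, start, end, name
    gaps: pd.DataFrame                # BED: one centromere + two telomeres per chrom
    peaks: dict                       # "cellline.mark" -> scored BED frame
    states: dict                      # cell line -> state-labeled BED frame


def _chrom_rng_streams(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    # independent streams so annotation and betas can be regenerated separately
    return np.random.default_rng([seed, 11]), np.random.default_rng([seed, 22])


def _gap_intervals(chrom: str, size: int) -> list[tuple]:
    tel = max(1, min(size // 20, 50_000))
    cen_half = max(1, min(size // 10, 100_000)) // 2
    mid = size // 2
    return [
        (chrom, 0, tel, "telomere"),
        (chrom, max(tel, mid - cen_half), min(size - tel, mid + cen_half), "centromere"),
        (chrom, size - tel, size, "telomere"),
    ]


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    # CpG-poor background, as in real genomes
    return rng.choice(bases, size=length, p=[0.30, 0.20, 0.20, 0.30])


def _plant_cg_rich(arr: np.ndarray, start: int, end: int):
    arr[start:end:2] = ord("C")
    arr[start + 1:end:2] = ord("G")


def generate_annotation(config: SynthConfig) -> SynthAnnotation:
    """Toy genome, tracks, and probe placement for a SynthConfig.

    Probes get unique 1-based positions sampled uniformly outside the gap
    intervals (so gap-distance statistics are non-degenerate); transcripts
    carry strand, exon blocks and a CDS; the gap track holds one centromere
    and two telomeres per chromosome; CpG islands are planted as CG-dense
    sequence so island probes really have high measured CpG density.
    """
    rng, _ = _chrom_rng_streams(config.seed)
    chroms = {c: int(s) for c, s in config.chrom_sizes.items()}

    gaps = pd.DataFrame(
        [g for c, s in chroms.items() for g in _gap_intervals(c, s)],
        columns=["chrom", "start", "end", "name"],
    )

    genome_arr = {c: _random_sequence(rng, s) for c, s in chroms.items()}

    # CpG islands
    n_cgi = max(3, config.n_probes // 40)
    total = sum(chroms.values())
    cgi_rows = []
    for i in range(n_cgi):
        chrom = rng.choice(list(chroms), p=[s / total for s in chroms.values()])
        size = chroms[chrom]
        length = int(rng.integers(400, 2000))
        if size <= length + 2:
            continue
        start = int(rng.integers(0, size - length))
        cgi_rows.append((chrom, start, start + length, f"cgi_{i:05d}"))
        _plant_cg_rich(genome_arr[chrom], start, start + length)
    cgis = (
        pd.DataFrame(cgi_rows, columns=["chrom", "start", "end", "name"])
        .sort_values(["chrom", "start"])
        .reset_index(drop=True)
    )

    genome = {c: a.tobytes().decode("ascii") for c, a in genome_arr.items()}

    # transcripts with exon structure and CDS
    transcripts = []
    n_tx = max(5, config.n_probes // 50)
    for i in range(n_tx):
        chrom = rng.choice(list(chroms), p=[s / total for s in chroms.values()])
        size = chroms[chrom]
        length = int(rng.integers(4_000, 40_000))
        if size <= length + 4_000:
            continue
        start = int(rng.integers(2_000, size - length - 2_000))
        end = start + length
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(2, 9))
        cuts = np.sort(rng.choice(np.arange(1, length), size=2 * n_exons - 2, replace=False))
        bounds = np.concatenate([[0], cuts, [length]])
        exons = [(start + int(bounds[2 * k]), start + int(bounds[2 * k + 1]))
                 for k in range(n_exons)]
        if rng.random() < 0.8:
            cs = start + int(rng.integers(int(length * 0.1), int(length * 0.45)))
            ce = start + int(rng.integers(int(length * 0.55), int(length * 0.9)))
            cds = (cs, ce)
        else:
            cds = None
        transcripts.append(
            Transcript(chrom=chrom, start=start, end=end, strand=strand,
                       exons=exons, cds=cds, name=f"tx_{i:05d}")
        )
    transcripts_bed = transcripts_to_bed12(transcripts)

    # histone peak tracks per cell line x mark
    peaks = {}
    n_peaks = max(10, config.n_probes // 20)
    for cell in CELL_LINES:
        for mark in HISTONE_MARKS:
            rows = []
            for _ in range(n_peaks):
                chrom = rng.choice(list(chroms), p=[s / total for s in chroms.values()])
                size = chroms[chrom]
                length = int(rng.integers(500, 5_000))
                if size <= length:
                    continue
                start = int(rng.integers(0, size - length))
                rows.append((chrom, start, start + length,
                             f"{cell}.{mark}", int(rng.integers(100, 1000))))
            peaks[f"{cell}.{mark}"] = pd.DataFrame(
                rows, columns=["chrom", "start", "end", "name", "score"]
            ).sort_values(["chrom", "start"]).reset_index(drop=True)

    # chromatin-state segmentations: tile each chromosome per cell line
    states = {}
    for cell in CELL_LINES:
        rows = []
        for chrom, size in chroms.items():
            pos = 0
            while pos < size:
                seg = int(rng.integers(50_000, 500_000))
                state = STATE_NAMES[int(rng.integers(0, len(STATE_NAMES)))]
                rows.append((chrom, pos, min(pos + seg, size), state))
                pos += seg
        states[cell] = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])

    probes = _place_probes(rng, config, chroms, gaps)
    return SynthAnnotation(
        probes=probes, genome=genome, transcripts=transcripts,
        transcripts_bed=transcripts_bed, cgis=cgis, gaps=gaps,
        peaks=peaks, states=states,
    )


def _place_probes(rng, config, chroms, gaps) -> pd.DataFrame:
    # allowed = non-gap segments; allocate probes proportionally to length
    segments = []
    for chrom, size in chroms.items():
        g = gaps[gaps["chrom"] == chrom].sort_values("start")
        pos = 0
        for s, e in zip(g["start"], g["end"]):
            if pos < s:
                segments.append((chrom, pos, s))
            pos = max(pos, e)
        if pos < size:
            segments.append((chrom, pos, size))
    lengths = np.array([e - s for _, s, e in segments], dtype=float)
    if lengths.sum() < config.n_probes:
        raise ConfigError("genome too small for the requested probe count")
    offsets = np.cumsum(np.concatenate([[0], lengths]))
    total_len = int(lengths.sum())
    # rejection-sample unique flat coordinates; each accepted draw is uniform
    chosen: set[int] = set()
    while len(chosen) < config.n_probes:
        for v in rng.integers(0, total_len, size=config.n_probes - len(chosen) + 16):
            if len(chosen) == config.n_probes:
                break
            chosen.add(int(v))
    flat = np.sort(np.fromiter(chosen, dtype=np.int64))
    seg_idx = np.searchsorted(offsets, flat, side="right") - 1
    rows = []
    for v, k in zip(flat, seg_idx):
        chrom, s, _ = segments[k]
        rows.append((chrom, int(s + (v - offsets[k]) + 1)))  # 1-based
    probes = pd.DataFrame(rows, columns=["chrom", "pos"])
    probes["strand"] = np.where(rng.random(len(probes)) < 0.5, "+", "-")
    probes = probes.sort_values(["chrom", "pos"]).reset_index(drop=True)
    probes.index = pd.Index([f"cg{i:08d}" for i in range(len(probes))], name="probe_id")
    return probes


def transcripts_to_bed12(transcripts) -> pd.DataFrame:
    rows = []
    for tx in transcripts:
        cs, ce = tx.cds if tx.cds is not None else (tx.start, tx.start)
        sizes = ",".join(str(e - s) for s, e in tx.exons)
        starts = ",".join(str(s - tx.start) for s, e in tx.exons)
        rows.append((tx.chrom, tx.start, tx.end, tx.name, 0, tx.strand,
                     cs, ce, "0", len(tx.exons), sizes, starts))
    return pd.DataFrame(rows, columns=[
        "chrom", "start", "end", "name", "score", "strand",
        "thick_start", "thick_end", "item_rgb", "block_count",
        "block_sizes", "block_starts",
    ])


def _beta_noise(rng, mean: np.ndarray, sd: float) -> np.ndarray:
    m = np.clip(mean, 1e-4, 1 - 1e-4)
    if sd == 0:
        return m
    nu = np.maximum(m * (1 - m) / sd**2 - 1, 0.5)
    return rng.beta(m * nu, (1 - m) * nu)


def generate_paired_betas(
    config: SynthConfig, probes: pd.DataFrame
) -> tuple[PairedBetaSet, pd.DataFrame]:
    """Paired BS/oxBS betas for the synthetic cohort plus the truth table.

    Planted structure: a fraction ``frac_fhmc`` of probes carries 5hmC at
    ``fhmc_level`` in both groups; hyper-5hmC spikes add ``effect_size`` of
    5hmC in the old group at otherwise 5hmC-free probes; hypo-5hmC spikes
    subtract it (floored at 0) at FhmC probes; 5mC spikes shift the oxBS
    level of the old group by ±``effect_size``.  All four spike sets are
    disjoint.  The truth table records flags and the signed planted effects.
    """
    if config.n_young < 1 or config.n_old < 1:
        raise ConfigError("both age groups need at least one sample")
    _, rng = _chrom_rng_streams(config.seed)
    n = len(probes)
    n_fhmc = int(round(config.frac_fhmc * n))
    perm = rng.permutation(n)

    fhmc_idx = perm[:n_fhmc]
    hypo5hmc_idx = fhmc_idx[: config.n_hypo5hmc]
    cursor = n_fhmc
    hyper5hmc_idx = perm[cursor:cursor + config.n_hyper5hmc]; cursor += config.n_hyper5hmc
    hyper5mc_idx = perm[cursor:cursor + config.n_hyper5mc]; cursor += config.n_hyper5mc
    hypo5mc_idx = perm[cursor:cursor + config.n_hypo5mc]; cursor += config.n_hypo5mc
    if cursor > n:
        raise ConfigError("spiked probe sets exceed n_probes")

    is_fhmc = np.zeros(n, bool); is_fhmc[fhmc_idx] = True
    flags = {
        "is_hyper5hmc": hyper5hmc_idx, "is_hypo5hmc": hypo5hmc_idx,
        "is_hyper5mc": hyper5mc_idx, "is_hypo5mc": hypo5mc_idx,
    }

    # base 5mC: bimodal like a real array, but bounded away from 1 wherever
    # 5hmC or an effect must fit on top without clipping the mean
    low = rng.beta(1.5, 8.0, size=n)
    high = rng.beta(8.0, 1.5, size=n)
    mc = np.where(rng.random(n) < 0.5, low, high) * 0.96 + 0.02
    headroom = 1.0 - (config.fhmc_level + config.effect_size) - 0.02
    constrained = is_fhmc.copy()
    constrained[hyper5hmc_idx] = True
    mc[constrained] = rng.uniform(0.05, max(0.10, min(0.55, headroom)), size=constrained.sum())
    mc[hyper5mc_idx] = rng.uniform(0.05, max(0.06, 0.95 - config.effect_size),
                                   size=len(hyper5mc_idx))
    mc[hypo5mc_idx] = rng.uniform(min(config.effect_size + 0.05, 0.90), 0.95,
                                  size=len(hypo5mc_idx))

    hmc_young = np.where(is_fhmc, config.fhmc_level, 0.0)
    hmc_old = hmc_young.copy()
    hmc_old[hyper5hmc_idx] += config.effect_size
    hmc_old[hypo5hmc_idx] = np.maximum(0.0, hmc_old[hypo5hmc_idx] - config.effect_size)

    mc_young = mc.copy()
    mc_old = mc.copy()
    mc_old[hyper5mc_idx] = np.minimum(0.98, mc_old[hyper5mc_idx] + config.effect_size)
    mc_old[hypo5mc_idx] = np.maximum(0.0, mc_old[hypo5mc_idx] - config.effect_size)

    ages_young = np.sort(rng.integers(2, 30, size=config.n_young))
    ages_old = np.sort(rng.integers(63, 90, size=config.n_old))
    bio_ids = [f"Y{i+1:02d}" for i in range(config.n_young)] + \
              [f"O{i+1:02d}" for i in range(config.n_old)]
    samples = pd.DataFrame(
        {
            "age": np.concatenate([ages_young, ages_old]),
            "group": ["young"] * config.n_young + ["old"] * config.n_old,
            "batch": [f"b{i % 2 + 1}" for i in range(config.n_young + config.n_old)],
        },
        index=pd.Index(bio_ids, name="sample_id"),
    )

    bs_cols, ox_cols = {}, {}
    for sid, grp in zip(samples.index, samples["group"]):
        hmc_mean = hmc_young if grp == "young" else hmc_old
        mc_mean = mc_young if grp == "young" else mc_old
        bs_cols[sid] = _beta_noise(rng, mc_mean + hmc_mean, config.noise_sd)
        ox_cols[sid] = _beta_noise(rng, mc_mean, config.noise_sd)
    bs = pd.DataFrame(bs_cols, index=probes.index)
    oxbs = pd.DataFrame(ox_cols, index=probes.index)

    truth = pd.DataFrame({"is_fhmc": is_fhmc}, index=probes.index)
    for name, idx in flags.items():
        col = np.zeros(n, bool); col[idx] = True
        truth[name] = col
    truth["hmc_young"] = hmc_young
    truth["hmc_old"] = hmc_old
    truth["mc_young"] = mc_young
    truth["mc_old"] = mc_old
    truth["d5hmc_effect"] = hmc_old - hmc_young
    truth["d5mc_effect"] = mc_old - mc_young
    return PairedBetaSet(bs=bs, oxbs=oxbs, samples=samples), truth


def generate_detection_p(
    config: SynthConfig, probes: pd.DataFrame, sample_ids
) -> pd.DataFrame:
    """Detection-p matrix: tiny p for nearly all cells, occasional failures
    (p in (0.02, 0.5]) at rate ``detp_fail_rate``."""
    rng = np.random.default_rng([config.seed, 33])
    shape = (len(probes), len(sample_ids))
    detp = rng.uniform(0.0, 0.005, size=shape)
    fails = rng.random(shape) < config.detp_fail_rate
    detp[fails] = rng.uniform(0.02, 0.5, size=int(fails.sum()))
    return pd.DataFrame(detp, index=probes.index, columns=list(sample_ids))


def sample_sheet_long(samples: pd.DataFrame) -> pd.DataFrame:
    """Array-level sample sheet: one row per biological sample x conversion."""
    rows = []
    for bio, meta in samples.iterrows():
        for conv in ("BS", "oxBS"):
            rows.append((f"{bio}-{conv}", bio, meta["age"], meta["group"], conv, meta["batch"]))
    return pd.DataFrame(
        rows, columns=["sample_id", "biological_id", "age", "group", "conversion", "batch"]
    )
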