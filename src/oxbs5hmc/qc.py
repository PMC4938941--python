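"""Detection-p filtering and derivation of the 5hmC / 5mC / total datasets.

The array reports, for every probe and sample, a beta value in [0, 1] from
each of two conversions of the same DNA: bisulfite only (BS, reads 5mC + 5hmC)
and oxidative bisulfite (oxBS, reads 5mC alone).  Subtracting the oxBS beta
from its paired BS beta estimates the 5hmC level per probe per sample (Δβ);
the oxBS matrix doubles as the 5mC dataset and the BS matrix as total
methylation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, EmptyResultError

SAMPLE_SHEET_COLUMNS = ("age", "group", "batch")


@dataclass
class PairedBetaSet:
    """BS and oxBS beta matrices sharing a probe x biological-sample index.

    ``bs`` and ``oxbs`` are probes-in-rows DataFrames whose columns are
    biological sample ids; ``samples`` is indexed by those ids and carries at
    least ``age`` (years), ``group`` ('young'/'old') and ``batch``.
    """

    bs: pd.DataFrame
    oxbs: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        if not self.bs.index.equals(self.oxbs.index):
            raise AlignmentError("BS and oxBS probe indices differ")
        if not self.bs.columns.equals(self.oxbs.columns):
            raise AlignmentError("BS and oxBS sample columns differ")
        missing = self.bs.columns.difference(self.samples.index)
        if len(missing):
            raise AlignmentError(f"samples absent from sample sheet: {list(missing)[:5]}")
        for m, name in ((self.bs, "BS"), (self.oxbs, "oxBS")):
            vals = m.to_numpy(dtype=float)
            bad = np.nansum((vals < 0) | (vals > 1))
            if bad:
                raise AlignmentError(f"{name} matrix has {int(bad)} beta values outside [0, 1]")

    @property
    def probe_ids(self) -> pd.Index:
        return self.bs.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.bs.columns

    def subset(self, probes=None, samples=None) -> "PairedBetaSet":
        bs, ox = self.bs, self.oxbs
        if probes is not None:
            bs, ox = bs.loc[probes], ox.loc[probes]
        if samples is not None:
            bs, ox = bs[samples], ox[samples]
        return PairedBetaSet(bs, ox, self.samples.loc[bs.columns])


@dataclass
class HydroxySet:
    """Per-probe, per-sample 5hmC (Δβ = BS − oxBS), 5mC (oxBS) and total (BS)."""

    hmc: pd.DataFrame
    mc: pd.DataFrame
    total: pd.DataFrame
    samples: pd.DataFrame = field(default=None)

    def __post_init__(self):
        if not (self.hmc.index.equals(self.mc.index) and self.hmc.index.equals(self.total.index)):
            raise AlignmentError("hmc/mc/total probe indices differ")
        if not (self.hmc.columns.equals(self.mc.columns) and self.hmc.columns.equals(self.total.columns)):
            raise AlignmentError("hmc/mc/total sample columns differ")


def _fail_matrix(detp: pd.DataFrame, p_cut: float) -> pd.DataFrame:
    # NaN detection-p is treated as non-failing (probe was not interrogated)
    return detp > p_cut


def filter_by_detection(
    bs: pd.DataFrame,
    oxbs: pd.DataFrame,
    detp: pd.DataFrame,
    samples: pd.DataFrame | None = None,
    detp_oxbs: pd.DataFrame | None = None,
    probe_fail_n: int = 2,
    sample_fail_n: float = 5500,
    p_cut: float = 0.01,
) -> PairedBetaSet:
    """Two-stage detection-p filter: drop bad samples first, then bad probes.

    A cell "fails" when its detection p exceeds ``p_cut`` in either
    conversion (``detp`` for BS; ``detp_oxbs`` for oxBS, defaulting to the
    same matrix when only one is supplied).  Samples accumulating at least
    ``sample_fail_n`` failing probes are removed; then probes failing in at
    least ``probe_fail_n`` of the *surviving* samples are removed.
    ``sample_fail_n`` < 1 is interpreted as a fraction of the probe count,
    since the array-scale default of 5500 is meaningless on small matrices.
    """
    if probe_fail_n <= 0 or sample_fail_n <= 0:
        raise ValueError("thresholds must be positive")
    if not (bs.index.equals(oxbs.index) and bs.columns.equals(oxbs.columns)):
        raise AlignmentError("BS and oxBS matrices misaligned")
    if not (detp.index.equals(bs.index) and detp.columns.equals(bs.columns)):
        raise AlignmentError("detection-p matrix not aligned to betas")
    if detp_oxbs is not None and not (
        detp_oxbs.index.equals(bs.index) and detp_oxbs.columns.equals(bs.columns)
    ):
        raise AlignmentError("oxBS detection-p matrix not aligned to betas")

    fails = _fail_matrix(detp, p_cut)
    if detp_oxbs is not None:
        fails = fails | _fail_matrix(detp_oxbs, p_cut)

    n_probes = len(bs.index)
    sample_cut = sample_fail_n if sample_fail_n >= 1 else max(1, int(np.ceil(sample_fail_n * n_probes)))

    keep_samples = fails.sum(axis=0) < sample_cut
    surviving_samples = bs.columns[keep_samples]
    if len(surviving_samples) == 0:
        raise EmptyResultError("detection filter removed every sample")

    keep_probes = fails[surviving_samples].sum(axis=1) < probe_fail_n
    surviving_probes = bs.index[keep_probes]
    if len(surviving_probes) == 0:
        raise EmptyResultError("detection filter removed every probe")

    if samples is None:
        samples = pd.DataFrame(index=bs.columns)
    return PairedBetaSet(
        bs.loc[surviving_probes, surviving_samples],
        oxbs.loc[surviving_probes, surviving_samples],
        samples.loc[surviving_samples],
    )


def compute_hydroxy(paired: PairedBetaSet) -> HydroxySet:
    """Δβ = BS − oxBS per cell; 5mC = oxBS and total = BS ride along unchanged.

    Missing values propagate through the subtraction.  Negative Δβ values are
    retained: the FhmC caller uses a strict positive threshold and the
    rank-sum test is applied to raw Δβ, so clipping (``clip_nonnegative``)
    belongs only in reporting/clustering outputs.
    """
    hmc = paired.bs - paired.oxbs
    return HydroxySet(hmc=hmc, mc=paired.oxbs.copy(), total=paired.bs.copy(), samples=paired.samples)


def clip_nonnegative(mat: pd.DataFrame) -> pd.DataFrame:
    """Element-wise max(value, 0); NaN preserved.  For display datasets only."""
    return mat.clip(lower=0)
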