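"""Calling frequently hydroxymethylated CpG sites (FhmC).

A probe is an FhmC site when its estimated 5hmC level (Δβ) exceeds a fixed
level in at least a given fraction of samples — by default Δβ > 0.1 in at
least 50% of samples.  The comparison is strictly greater-than, so a probe
sitting exactly at the level never counts.
"""

from __future__ import annotations

import pandas as pd

from .errors import EmptyResultError


def call_fhmc(
    hmc: pd.DataFrame, level: float = 0.1, frac: float = 0.5
) -> tuple[pd.DataFrame, pd.Series]:
    """Flag FhmC probes and count hydroxymethylated sites per sample.

    Parameters
    ----------
    hmc : probes x samples Δβ matrix; NaN cells are excluded from both the
        per-probe numerator and denominator.
    level : Δβ threshold; a sample counts only when Δβ is strictly above it.
    frac : minimum fraction of (non-missing) samples above ``level``.

    Returns
    -------
    (calls, per_sample) where ``calls`` has columns
    ``n_samples_above, n_samples_total, is_fhmc`` indexed by probe id, and
    ``per_sample`` counts probes with Δβ > level in each sample.
    """
    if hmc.size == 0:
        raise EmptyResultError("empty Δβ matrix")
    above = hmc > level  # NaN compares False
    n_above = above.sum(axis=1).astype(int)
    n_total = hmc.notna().sum(axis=1).astype(int)
    is_fhmc = (n_above >= frac * n_total) & (n_total > 0)
    calls = pd.DataFrame(
        {"n_samples_above": n_above, "n_samples_total": n_total, "is_fhmc": is_fhmc}
    )
    per_sample = above.sum(axis=0).astype(int).rename("n_hydroxylated_probes")
    return calls, per_sample
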