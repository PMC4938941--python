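"""Age-group differential testing of 5hmC / 5mC levels.

Per probe, the two age groups are compared with a two-sided Wilcoxon rank-sum
(Mann-Whitney) test: exact enumeration when the pooled sample count is small
and there are no ties, tie-corrected normal approximation otherwise.  Only p
values below a gate (default 0.05) enter Benjamini-Hochberg adjustment, with m
equal to the size of that subset; probes passing the FDR threshold are then
pruned by a shift-size filter that drops the fraction (default 30%) with the
smallest absolute difference of group means.  Direction (hyper/hypo) follows
the sign of mean(old) − mean(young).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

logger = logging.getLogger(__name__)

EXACT_MAX_N = 20  # pooled-size cutoff below which the exact null is used


def wilcoxon_rank_sum(x, y, exact_max_n: int = EXACT_MAX_N) -> float:
    """Two-sided rank-sum p value; NaN when either group is empty.

    Exact enumeration of the rank-sum null when ``len(x)+len(y) <=
    exact_max_n`` and the pooled values contain no ties; otherwise the normal
    approximation with tie correction.  Degenerate dispersion (all pooled
    values identical) yields p = 1.0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        return float("nan")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if not has_ties and len(pooled) <= exact_max_n:
        method = "exact"
    else:
        method = "asymptotic"
    if np.ptp(pooled) == 0:  # zero statistic, no dispersion
        return 1.0
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=False)
    p = float(res.pvalue)
    if np.isnan(p):
        return 1.0
    return p


def bh_adjust(p, validate: bool = True) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (capped at 1).

    NaN entries pass through untouched and do not count toward m.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    vals = p[mask]
    if validate and ((vals < 0) | (vals > 1)).any():
        raise ValidationError("p values must lie in [0, 1]")
    if vals.size:
        out[mask] = multipletests(vals, method="fdr_bh")[1]
    return out


def detect_differential(
    data: pd.DataFrame,
    groups: pd.Series | dict,
    fdr: float = 0.25,
    p_gate: float = 0.05,
    drop_frac: float = 0.30,
    adjust_all: bool = False,
) -> pd.DataFrame:
    """Per-probe differential table between the young and old groups.

    Parameters
    ----------
    data : probes x samples matrix (Δβ for the 5hmC dataset, oxBS beta for
        5mC, BS beta for total methylation).
    groups : sample id -> 'young' | 'old'.
    fdr : BH threshold on q.
    p_gate : only probes with raw p below this enter BH adjustment (m = size
        of that subset).  ``adjust_all=True`` switches to conventional
        adjustment across all tested probes.
    drop_frac : among FDR-passing probes, this fraction with the smallest
        |shift| is filtered out (floor rounding; |shift| ties broken by probe
        id so results are deterministic).

    Returns a DataFrame indexed by probe id with columns p, q, mean_young,
    mean_old, shift, passed_fdr, passed_shift_filter, direction, significant.
    """
    groups = pd.Series(groups)
    young = [s for s in data.columns if groups.get(s) == "young"]
    old = [s for s in data.columns if groups.get(s) == "old"]
    if not young or not old:
        raise ValidationError("both a young and an old group are required")
    if min(len(young), len(old)) < 2:
        logger.warning(
            "a group has fewer than 2 samples (young=%d, old=%d); exact test still attempted",
            len(young), len(old),
        )

    ymat = data[young].to_numpy(dtype=float)
    omat = data[old].to_numpy(dtype=float)
    with np.errstate(all="ignore"):
        mean_young = np.nanmean(ymat, axis=1)
        mean_old = np.nanmean(omat, axis=1)
    shift = mean_old - mean_young

    pvals = np.array([
        wilcoxon_rank_sum(omat[i], ymat[i]) for i in range(data.shape[0])
    ])

    q = np.full(pvals.shape, np.nan)
    if adjust_all:
        tested = ~np.isnan(pvals)
    else:
        tested = (~np.isnan(pvals)) & (pvals < p_gate)
    if tested.any():
        q[tested] = bh_adjust(pvals[tested], validate=False)

    passed_fdr = np.where(np.isnan(q), False, q < fdr)

    table = pd.DataFrame(
        {
            "p": pvals,
            "q": q,
            "mean_young": mean_young,
            "mean_old": mean_old,
            "shift": shift,
            "passed_fdr": passed_fdr,
        },
        index=data.index,
    )

    table["passed_shift_filter"] = True
    passed = table.index[table["passed_fdr"]]
    n_drop = int(np.floor(drop_frac * len(passed)))
    if n_drop > 0:
        # stable sort on |shift| with the index pre-sorted lexicographically
        # gives the deterministic probe-id tie-break
        order = (
            table.loc[passed.sort_values()]
            .assign(abs_shift=lambda t: t["shift"].abs())
            .sort_values("abs_shift", kind="stable")
        )
        dropped = order.index[:n_drop]
        table.loc[dropped, "passed_shift_filter"] = False

    significant = table["passed_fdr"] & table["passed_shift_filter"]
    direction = np.where(
        significant & (table["shift"] > 0), "hyper",
        np.where(significant & (table["shift"] < 0), "hypo", "none"),
    )
    table["direction"] = direction
    table["significant"] = significant & (table["direction"] != "none")
    return table


@dataclass
class DirectionSplit:
    """Significant probes partitioned by sign of the age-group shift."""

    hyper: frozenset
    hypo: frozenset

    @property
    def n_hyper(self) -> int:
        return len(self.hyper)

    @property
    def n_hypo(self) -> int:
        return len(self.hypo)

    @property
    def n_total(self) -> int:
        return self.n_hyper + self.n_hypo

    @property
    def pct_hyper(self) -> float:
        return 100.0 * self.n_hyper / self.n_total if self.n_total else float("nan")

    @property
    def pct_hypo(self) -> float:
        return 100.0 * self.n_hypo / self.n_total if self.n_total else float("nan")


def split_directions(table: pd.DataFrame) -> DirectionSplit:
    """Disjoint hyper/hypo probe-id sets from a differential table, with the
    share of each in the significant union (NaN percentages when empty)."""
    hyper = frozenset(table.index[table["direction"] == "hyper"])
    hypo = frozenset(table.index[table["direction"] == "hypo"])
    return DirectionSplit(hyper=hyper, hypo=hypo)


def split_from_sets(hyper, hypo) -> DirectionSplit:
    """DirectionSplit straight from two probe-id collections (e.g. published
    site lists), bypassing the per-probe table."""
    hyper, hypo = frozenset(hyper), frozenset(hypo)
    if hyper & hypo:
        raise ValidationError("hyper and hypo sets must be disjoint")
    return DirectionSplit(hyper=hyper, hypo=hypo)


@dataclass
class SetCrossTab:
    """Pairwise intersections of two direction splits (e.g. d5hmC vs d5mC)."""

    counts: pd.DataFrame   # rows: a-sets; cols: b-sets; intersection sizes
    row_pct: pd.DataFrame  # percentage of each a-set covered by each b-set
    set_sizes: dict


def crosstab_sets(
    hyper_a, hypo_a, hyper_b, hypo_b,
    a_labels=("hyper_a", "hypo_a"), b_labels=("hyper_b", "hypo_b"),
) -> SetCrossTab:
    """Cross-tabulate two pairs of probe sets.

    Returns intersection counts and, for each a-set (row), the percentage of
    its probes found in each b-set — e.g. the share of hyper-5hmC sites that
    lose 5mC with age.
    """
    a_sets = {a_labels[0]: set(hyper_a), a_labels[1]: set(hypo_a)}
    b_sets = {b_labels[0]: set(hyper_b), b_labels[1]: set(hypo_b)}
    counts = pd.DataFrame(
        {bl: {al: len(a & b) for al, a in a_sets.items()} for bl, b in b_sets.items()}
    )[list(b_labels)].loc[list(a_labels)]
    sizes = pd.Series({al: len(a) for al, a in a_sets.items()})
    row_pct = counts.div(sizes, axis=0).mul(100.0)
    set_sizes = {**{k: len(v) for k, v in a_sets.items()}, **{k: len(v) for k, v in b_sets.items()}}
    return SetCrossTab(counts=counts, row_pct=row_pct, set_sizes=set_sizes)
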