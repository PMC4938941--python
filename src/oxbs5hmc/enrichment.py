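"""Background-corrected enrichment of probe subsets.

The 450K-style array interrogates a biased sample of the genome, so every
test here is run against the array's own probe background rather than the
genome: qualitative features (histone peaks, chromatin states, region and CGI
classes) via contingency tables on background probes cross-classified by
subset membership, and quantitative per-probe metrics (CpG density, gap
distances) via a rank-sum test of the subset against the background
remainder, with Cliff's Delta as effect size.

Odds ratios are the plain sample OR (ad/bc); a zero cell yields OR 0 or inf
with log2OR missing — no Haldane correction by default, since published ORs
for this analysis style are uncorrected (``haldane=True`` adds +0.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust, wilcoxon_rank_sum
from .errors import ValidationError


def build_contingency(subset, background, labeling) -> pd.DataFrame:
    """Cross-classify background probes by subset membership and a label.

    ``labeling`` maps probe id -> category (or bool for in-feature /
    not-in-feature) and must cover the background.  Returns a k x 2 integer
    frame with columns ``in_subset`` / ``out_subset``; for boolean labels the
    rows are ``in_feature`` / ``not_in_feature`` in that order, giving the
    2 x 2 layout [[a, b], [c, d]] with a = in-feature & in-subset.
    """
    subset = set(subset)
    background = set(background)
    if not subset <= background:
        raise ValidationError("subset must be contained in background")
    lab = pd.Series(labeling)
    missing = background - set(lab.index)
    if missing:
        raise ValidationError(f"labeling missing {len(missing)} background probes")
    lab = lab.loc[list(background)]
    in_sub = lab.index.isin(subset)
    if lab.dtype == bool or set(lab.unique()) <= {True, False}:
        cats = [True, False]
        names = ["in_feature", "not_in_feature"]
    else:
        cats = sorted(lab.unique())
        names = cats
    rows = []
    for c in cats:
        mask = (lab == c).to_numpy()
        rows.append((int((mask & in_sub).sum()), int((mask & ~in_sub).sum())))
    return pd.DataFrame(rows, index=pd.Index(names, name="category"), columns=["in_subset", "out_subset"])


def fisher_exact(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    p is the sum of hypergeometric probabilities of tables (at the observed
    margins) no more likely than the observed one; the odds ratio is the
    sample OR ad/bc (0 or inf when a cross cell is empty).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValidationError("fisher_exact needs a non-negative 2x2 table")
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return float(p), float(odds)


def chisq_test(table) -> tuple[float, float]:
    """Pearson chi-square without continuity correction on a k x 2 table.

    Returns (statistic, p) with df = (k-1); (nan, nan) when a zero margin
    makes expected counts undefined.
    """
    t = np.asarray(table, dtype=float)
    if (t < 0).any():
        raise ValidationError("counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return float("nan"), float("nan")
    res = stats.chi2_contingency(t, correction=False)
    return float(res.statistic), float(res.pvalue)


def cliffs_delta(x, y) -> float:
    """Cliff's Delta D = (#{x_i > y_j} - #{x_i < y_j}) / (n*m), in [-1, 1].

    Computed in O((n+m) log(n+m)) from midranks: with U the tie-adjusted
    Mann-Whitney count for x over y, D = 2U/(nm) - 1.  Negative D means the
    x values tend to lie below the y values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("cliffs_delta requires non-empty inputs")
    n, m = len(x), len(y)
    ranks = stats.rankdata(np.concatenate([x, y]))
    u = ranks[:n].sum() - n * (n + 1) / 2.0  # counts ties as 1/2
    return float(2.0 * u / (n * m) - 1.0)


@dataclass
class EnrichmentRecord:
    """One feature-track (or category) tested for a probe subset."""

    feature: str
    a: int  # in-feature, in-subset
    b: int  # in-feature, out-subset
    c: int  # not-in-feature, in-subset
    d: int  # not-in-feature, out-subset
    odds_ratio: float
    log2_or: float
    p: float
    q: float
    enriched: bool
    untestable: bool
    test: str


def _or_and_log(a, b, c, d, haldane=False) -> tuple[float, float]:
    if haldane:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if b * c == 0:
        odds = float("nan") if a * d == 0 else float("inf")
    else:
        odds = (a * d) / (b * c)
    log2or = np.log2(odds) if np.isfinite(odds) and odds > 0 else float("nan")
    return float(odds), float(log2or)


def enrich_qualitative(
    subset,
    background,
    features: dict,
    test: str = "fisher",
    fdr: float | None = 0.05,
    alpha: float = 0.05,
    haldane: bool = False,
) -> pd.DataFrame:
    """Per-feature 2x2 enrichment of ``subset`` against ``background``.

    ``features`` maps feature id -> boolean labeling over the background
    (dict/Series probe -> bool, or a collection of in-feature probe ids).
    ``test`` is 'fisher' (histone peaks, chromatin states) or 'chisq'
    (region / CGI-class follow-ups).  With ``fdr`` set, p values are BH
    adjusted across the features of this call — one analysis family — and
    ``enriched`` means q < fdr; with ``fdr=None`` the raw ``alpha`` is used,
    matching analyses reported without multiplicity adjustment.
    """
    background = list(background)
    recs = []
    for name, lab in features.items():
        if not isinstance(lab, (pd.Series, dict)):
            member = set(lab)
            lab = {p: (p in member) for p in background}
        table = build_contingency(subset, background, lab)
        a, b = int(table.iloc[0, 0]), int(table.iloc[0, 1])
        c, d = int(table.iloc[1, 0]), int(table.iloc[1, 1])
        untestable = (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0)
        if untestable:
            p = float("nan")
        elif test == "fisher":
            p, _ = fisher_exact([[a, b], [c, d]])
        elif test == "chisq":
            _, p = chisq_test([[a, b], [c, d]])
            untestable = np.isnan(p)
        else:
            raise ValidationError(f"unknown test {test!r}")
        odds, log2or = _or_and_log(a, b, c, d, haldane=haldane)
        recs.append((name, a, b, c, d, odds, log2or, p, untestable))

    out = pd.DataFrame(
        recs, columns=["feature", "a", "b", "c", "d", "odds_ratio", "log2_or", "p", "untestable"]
    ).set_index("feature")
    if fdr is not None:
        out["q"] = bh_adjust(out["p"].to_numpy(), validate=False)
        out["enriched"] = (out["q"] < fdr) & ~out["untestable"]
    else:
        out["q"] = np.nan
        out["enriched"] = (out["p"] < alpha) & ~out["untestable"]
    out["test"] = test
    return out


def enrich_categorical(
    subset, background, labels: pd.Series, alpha: float = 0.05
) -> tuple[float, float, pd.DataFrame]:
    """k-category association of a subset with a probe labeling (region or
    CGI class): an overall k x 2 Pearson chi-square, then one 2 x 2
    chi-square per category with its sample OR, each at raw ``alpha``.

    Returns (overall statistic, overall p, per-category frame).
    """
    table = build_contingency(subset, background, labels)
    stat, p_overall = chisq_test(table)
    per = enrich_qualitative(
        subset, background,
        {str(cat): (labels == cat) for cat in table.index},
        test="chisq", fdr=None, alpha=alpha,
    )
    return stat, p_overall, per


def shift_quantitative(subset_values, rest_values) -> tuple[float, float]:
    """Rank-sum p and Cliff's Delta of a subset metric against the background
    remainder (subset lower => negative D)."""
    p = wilcoxon_rank_sum(subset_values, rest_values)
    d = cliffs_delta(subset_values, rest_values)
    return p, d
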