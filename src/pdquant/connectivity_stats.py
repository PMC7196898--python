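"""Statistics for microprojectile-bombardment connectivity assays.

A bombardment site is a single epidermal cell hit with a GFP plasmid;
16 h later the number of cells showing GFP measures how freely GFP
moved through plasmodesmata.  Counts are normalized to the mock-treated
mean within each genotype, compared between treatments with
distribution-free tests, and summarized with notched boxplot statistics
and ANOVA + Tukey compact letter displays for multi-group figures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    InsufficientDataError,
    InvalidArgumentError,
    MissingBaselineError,
)

__all__ = [
    "REQUIRED_COLUMNS",
    "validate_bombardment_table",
    "normalize_counts",
    "compare_treatment",
    "BoxplotSummary",
    "boxplot_summary",
    "GroupComparison",
    "anova_tukey_letters",
    "significance_stars",
]

REQUIRED_COLUMNS = ["genotype", "treatment", "replicate", "n_cells"]

TREATMENTS = ("mock", "chitin", "H2O2")


def validate_bombardment_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the per-site count table contract and return it unchanged."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise InvalidArgumentError(f"table missing columns {missing}")
    if len(table) == 0:
        raise InvalidArgumentError("empty bombardment table")
    n = table["n_cells"].to_numpy()
    if np.any(n < 1) or not np.allclose(n, np.round(n)):
        raise InvalidArgumentError(
            "n_cells must be integers >= 1 (a site shows at least the hit cell)"
        )
    if np.any(table["replicate"].to_numpy() < 1):
        raise InvalidArgumentError("replicate must be >= 1")
    return table


@dataclass
class BoxplotSummary:
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    notch_low: float
    notch_high: float
    n: int


@dataclass
class GroupComparison:
    groups: tuple
    statistic: float
    p_value: float
    significance_stars: str
    test: str
    letter_codes: dict | None = None
    pairwise_p: dict | None = None


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def normalize_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Add ``normalized_count`` = n_cells / (mock mean within genotype).

    After normalization the mock group of every genotype has mean 1, so
    treatment effects are expressed as fold changes comparable across
    genotypes with different baseline connectivity.
    """
    validate_bombardment_table(table)
    out = table.copy()
    out["normalized_count"] = np.nan
    for genotype, sub in table.groupby("genotype", sort=False):
        mock = sub.loc[sub["treatment"] == "mock", "n_cells"]
        if len(mock) == 0:
            raise MissingBaselineError(
                f"genotype {genotype!r} has no mock sites to normalize against"
            )
        out.loc[sub.index, "normalized_count"] = sub["n_cells"] / mock.mean()
    return out


def compare_treatment(
    table: pd.DataFrame,
    genotype: str,
    treatment: str = "chitin",
    test: str = "mann_whitney",
    n_permutations: int = 10_000,
    seed: int = 0,
) -> GroupComparison:
    """Two-sided mock-vs-treated comparison within one genotype.

    Operates on normalized counts (computed on the fly if absent).
    ``test`` is 'mann_whitney' (rank-sum, default: counts are non-normal)
    or 'permutation' (difference in means, ``n_permutations`` shuffles).
    """
    if "normalized_count" not in table.columns:
        table = normalize_counts(table)
    sub = table[table["genotype"] == genotype]
    a = sub.loc[sub["treatment"] == "mock", "normalized_count"].to_numpy()
    b = sub.loc[sub["treatment"] == treatment, "normalized_count"].to_numpy()
    if a.size < 5 or b.size < 5:
        raise InsufficientDataError(
            f"need >= 5 sites per group, got mock n={a.size}, {treatment} n={b.size}"
        )
    if test == "mann_whitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        statistic, p = float(res.statistic), float(res.pvalue)
    elif test == "permutation":
        rng = np.random.default_rng(seed)
        res = stats.permutation_test(
            (a, b),
            lambda x, y, axis: np.mean(x, axis=axis) - np.mean(y, axis=axis),
            permutation_type="independent",
            n_resamples=n_permutations,
            alternative="two-sided",
            rng=rng,
            vectorized=True,
        )
        statistic, p = float(res.statistic), float(res.pvalue)
    else:
        raise InvalidArgumentError(f"unknown test {test!r}")
    return GroupComparison(
        groups=(f"{genotype}:mock", f"{genotype}:{treatment}"),
        statistic=statistic,
        p_value=p,
        significance_stars=significance_stars(p),
        test=test,
    )


def boxplot_summary(values) -> BoxplotSummary:
    """Notched-boxplot statistics.

    Quartiles by linear interpolation (type-7); whiskers at the most
    extreme data points within 1.5 IQR beyond the quartiles; notches at
    median +/- 1.58 IQR / sqrt(n), the standard approximate 95% CI of
    the median.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size < 5:
        raise InsufficientDataError(f"need >= 5 values, got {v.size}")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    # if every point on one side is an outlier, the whisker ends at the box
    whisk_lo = float(min(inside.min(), q1))
    whisk_hi = float(max(inside.max(), q3))
    half_notch = 1.58 * iqr / np.sqrt(v.size)
    return BoxplotSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=whisk_lo,
        whisker_high=whisk_hi,
        notch_low=float(med - half_notch),
        notch_high=float(med + half_notch),
        n=int(v.size),
    )


def _compact_letter_display(names, sig_pairs):
    """Insert-and-absorb compact letter display.

    ``names`` in display order (sorted by group mean descending outside);
    ``sig_pairs`` is a set of frozensets of significantly different pairs.
    Returns {name: letters}, such that two groups share a letter iff they
    are NOT in sig_pairs (guaranteed by construction for the shared
    direction; the converse is enforced by the splitting step).
    """
    letters = [set(names)]  # start: everyone shares one letter
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if frozenset((a, b)) not in sig_pairs:
                continue
            new = []
            for group in letters:
                if a in group and b in group:
                    ga = group - {b}
                    gb = group - {a}
                    new.extend([ga, gb])
                else:
                    new.append(group)
            # absorb: a letter set strictly contained in another is redundant
            # (every pair it witnesses is witnessed by the superset)
            letters = []
            for g in new:
                if g and not any(g < h for h in new) and g not in letters:
                    letters.append(g)
    # ensure non-significant pairs still share a letter (true by construction:
    # splitting only separates significant pairs)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    # order letters by the first (highest-mean) group they contain
    def first_index(g):
        return min(names.index(x) for x in g)

    letters.sort(key=first_index)
    codes = {name: "" for name in names}
    for li, group in enumerate(letters):
        for name in names:
            if name in group:
                codes[name] += alphabet[li % len(alphabet)]
    return codes


def anova_tukey_letters(groups: dict, alpha: float = 0.01) -> GroupComparison:
    """One-way ANOVA with Tukey HSD post hoc and compact letter display.

    ``groups`` maps label -> values.  Letters are assigned greedily after
    sorting groups by mean (descending); groups sharing a letter are not
    significantly different at ``alpha`` under Tukey HSD.
    """
    if not 0 < alpha < 1:
        raise InvalidArgumentError("alpha must be in (0, 1)")
    clean = {}
    for name, vals in groups.items():
        v = np.asarray(list(vals), dtype=float)
        if v.size < 3:
            raise InsufficientDataError(f"group {name!r} has n={v.size} < 3")
        clean[name] = v
    if len(clean) < 2:
        raise InsufficientDataError("need >= 2 groups")
    pooled = np.concatenate(list(clean.values()))
    if np.ptp(pooled) == 0:
        # all observations identical: no test to run, all groups share "a"
        names = sorted(clean, key=lambda k: -clean[k].mean())
        return GroupComparison(
            groups=tuple(names), statistic=0.0, p_value=1.0,
            significance_stars="ns", test="anova_tukey",
            letter_codes={n: "a" for n in names}, pairwise_p={},
        )

    f_stat, p_anova = stats.f_oneway(*clean.values())
    names = sorted(clean, key=lambda k: -clean[k].mean())
    res = stats.tukey_hsd(*[clean[n] for n in names])
    pairwise = {}
    sig_pairs = set()
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            p = float(res.pvalue[i, j])
            pairwise[frozenset((names[i], names[j]))] = p
            if p < alpha:
                sig_pairs.add(frozenset((names[i], names[j])))
    codes = _compact_letter_display(names, sig_pairs)
    return GroupComparison(
        groups=tuple(names),
        statistic=float(f_stat),
        p_value=float(p_anova),
        significance_stars=significance_stars(float(p_anova)),
        test="anova_tukey",
        letter_codes=codes,
        pairwise_p={tuple(sorted(k)): v for k, v in pairwise.items()},
    )
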