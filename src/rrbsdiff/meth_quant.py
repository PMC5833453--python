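"""Per-CpG methylation quantification and sample-level summaries.

The central container is the *wide* count table: a DataFrame indexed by
(chrom, pos) with a two-level column index (sample, field) where field is
``meth`` or ``total``. Replicates are pooled by summing counts, sites are
gated on coverage in *all* samples, and levels are the exact proportions
meth/total.

Category thresholds follow the printed conventions: a CpG is "high" at level
>= 0.8, "intermediate" at 0.3 <= level < 0.8, "low" below 0.3; sites are kept
only with >= 10-fold coverage in every sample. Category assignment compares
the rational meth/total against the thresholds exactly (via cross
multiplication), so boundary counts such as 24/30 are never misclassified by
float rounding.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pandas as pd

__all__ = [
    "to_wide",
    "to_long",
    "merge_replicates",
    "filter_coverage",
    "methylation_levels",
    "categorize_levels",
    "categorize_counts",
    "sample_correlation",
    "level_histogram",
]


def to_wide(long_table: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long count table (chrom, pos, sample, meth, total) wide."""
    wide = long_table.pivot_table(
        index=["chrom", "pos"], columns="sample", values=["meth", "total"],
        aggfunc="sum",
    )
    wide = wide.swaplevel(axis=1).sort_index(axis=1)
    wide.columns.names = ["sample", "field"]
    return wide


def to_long(wide: pd.DataFrame) -> pd.DataFrame:
    long = wide.stack(level="sample", future_stack=True).reset_index()
    long = long.dropna(subset=["meth", "total"])
    long[["meth", "total"]] = long[["meth", "total"]].astype(int)
    return long[["chrom", "pos", "sample", "meth", "total"]].sort_values(
        ["chrom", "pos", "sample"], kind="stable"
    ).reset_index(drop=True)


def samples_of(wide: pd.DataFrame) -> list[str]:
    return list(wide.columns.get_level_values("sample").unique())


def merge_replicates(
    wide: pd.DataFrame, replicate_groups: dict[str, list[str]]
) -> pd.DataFrame:
    """Pool replicate counts: per site and group, (sum meth, sum total).

    ``replicate_groups`` maps a merged sample name to its replicate column
    names; groups must be non-empty and reference existing samples. A missing
    replicate observation at a site contributes zero counts.
    """
    available = set(samples_of(wide))
    frames = {}
    for merged, members in replicate_groups.items():
        if not members:
            raise ValueError(f"replicate group {merged!r} is empty")
        unknown = sorted(set(members) - available)
        if unknown:
            raise KeyError(f"unknown replicate ids in group {merged!r}: {unknown}")
        block = wide.loc[:, [(m, f) for m in members for f in ("meth", "total")]]
        meth = block.xs("meth", axis=1, level="field").fillna(0).sum(axis=1)
        total = block.xs("total", axis=1, level="field").fillna(0).sum(axis=1)
        frames[(merged, "meth")] = meth
        frames[(merged, "total")] = total
    out = pd.DataFrame(frames)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["sample", "field"])
    return out.sort_index(axis=1)


def filter_coverage(wide: pd.DataFrame, min_cov: int = 10) -> pd.DataFrame:
    """Keep sites with total_count >= min_cov in every sample (inclusive)."""
    if wide.columns.get_level_values("sample").nunique() < 1:
        raise ValueError("count table has no samples")
    totals = wide.xs("total", axis=1, level="field")
    keep = (totals.fillna(0) >= min_cov).all(axis=1)
    return wide[keep]


def methylation_levels(wide: pd.DataFrame) -> pd.DataFrame:
    """Exact per-site levels meth/total; columns are samples.

    Every retained cell must have total > 0 (the coverage gate guarantees
    this); a zero total on a retained site is an internal invariant violation.
    """
    meth = wide.xs("meth", axis=1, level="field")
    total = wide.xs("total", axis=1, level="field")
    if (total.fillna(0) <= 0).any().any():
        raise ValueError("zero-coverage cell in a retained site; gate first")
    return meth / total


_CATEGORIES = ["low", "intermediate", "high"]


def categorize_levels(
    levels: pd.DataFrame, low_cut: float = 0.3, high_cut: float = 0.8
) -> pd.DataFrame:
    """Per-sample fractions of low / intermediate / high methylation.

    high: level >= high_cut; intermediate: low_cut <= level < high_cut;
    low: level < low_cut. The three fractions sum to 1 per sample.
    """
    out = {}
    for sample in levels.columns:
        v = levels[sample].dropna().to_numpy()
        n = v.size
        if n == 0:
            out[sample] = pd.Series([np.nan] * 3, index=_CATEGORIES)
            continue
        high = int((v >= high_cut).sum())
        low = int((v < low_cut).sum())
        out[sample] = pd.Series(
            [Fraction(low, n), Fraction(n - low - high, n), Fraction(high, n)],
            index=_CATEGORIES, dtype=object,
        )
    frame = pd.DataFrame(out).T
    frame.index.name = "sample"
    return frame


def categorize_counts(
    wide: pd.DataFrame,
    low_cut: Fraction = Fraction(3, 10),
    high_cut: Fraction = Fraction(8, 10),
) -> pd.DataFrame:
    """Category fractions computed on exact meth/total rationals.

    Equivalent to :func:`categorize_levels` but compares count ratios against
    the thresholds by cross multiplication, immune to float boundary effects.
    """
    meth = wide.xs("meth", axis=1, level="field")
    total = wide.xs("total", axis=1, level="field")
    low_cut, high_cut = Fraction(low_cut), Fraction(high_cut)
    out = {}
    for sample in meth.columns:
        m = meth[sample].to_numpy()
        t = total[sample].to_numpy()
        ok = ~np.isnan(t) & (t > 0)
        m, t = m[ok].astype(np.int64), t[ok].astype(np.int64)
        n = m.size
        # level >= cut  <=>  m * cut.den >= t * cut.num
        high = int((m * high_cut.denominator >= t * high_cut.numerator).sum())
        low = int((m * low_cut.denominator < t * low_cut.numerator).sum())
        out[sample] = pd.Series(
            [Fraction(low, n), Fraction(n - low - high, n), Fraction(high, n)],
            index=_CATEGORIES, dtype=object,
        )
    frame = pd.DataFrame(out).T
    frame.index.name = "sample"
    return frame


def sample_correlation(
    levels: pd.DataFrame, method: str = "spearman"
) -> pd.DataFrame:
    """Pairwise inter-sample correlation of methylation levels.

    Spearman is Pearson on mid-ranks (average ranks for ties), computed over
    sites with defined levels in both samples of each pair; fewer than 3
    common sites is an error.
    """
    if levels.shape[1] < 2:
        raise ValueError("need at least two samples")
    notna = levels.notna()
    for i, a in enumerate(levels.columns):
        for b in levels.columns[i + 1:]:
            if int((notna[a] & notna[b]).sum()) < 3:
                raise ValueError(
                    f"samples {a!r} and {b!r} share fewer than 3 sites"
                )
    return levels.corr(method=method)


def level_histogram(
    levels: pd.DataFrame, n_bins: int = 20
) -> pd.DataFrame:
    """Equal-width level histogram on [0, 1] per sample (tidy format).

    The last bin is right-closed so level 1.0 is counted. Returns a DataFrame
    with columns (bin_left, bin_right, sample, count); counts per sample sum
    to that sample's number of defined sites.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    rows = []
    for sample in levels.columns:
        v = levels[sample].dropna().to_numpy()
        counts, _ = np.histogram(v, bins=edges)
        for i in range(n_bins):
            rows.append((edges[i], edges[i + 1], sample, int(counts[i])))
    return pd.DataFrame(rows, columns=["bin_left", "bin_right", "sample", "count"])
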