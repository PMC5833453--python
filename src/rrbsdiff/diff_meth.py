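"""DMC and DMR calling between two samples.

A differentially methylated cytosine (DMC) is a gated CpG whose methylated /
unmethylated counts differ between two samples under a two-sided Fisher's
exact test; a *strong* DMC additionally shows a methylation-level difference
strictly above the effect threshold (default one third, the printed "33.3%")
at p strictly below 0.05. Strong same-direction DMCs are chained into DMRs,
and DMR sets from different comparisons can be merged by interval union with
region levels recomputed as the unweighted mean over the gated CpGs inside.

The effect-size comparison is carried out on the exact rationals meth/total
(cross multiplication), so a difference of exactly 1/3 — e.g. 25/30 vs 15/30
— is *not* strong under the strict inequality, regardless of float rounding.

Benjamini-Hochberg q-values are reported for transparency but do not gate
calls: ``is_strong`` uses the raw p-value, as the thresholds are defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "fisher_exact_2x2",
    "call_strong_dmcs",
    "call_dmrs",
    "merge_dmr_sets",
    "compare_dmc_sets",
    "volcano_table",
    "DEFAULT_DELTA_THRESHOLD",
    "DEFAULT_P_THRESHOLD",
]

logger = logging.getLogger(__name__)

#: the printed ">33.3%" effect threshold, read as one third
DEFAULT_DELTA_THRESHOLD = Fraction(1, 3)
DEFAULT_P_THRESHOLD = 0.05


@lru_cache(maxsize=1_000_000)
def _cached_fisher(meth_a: int, unmeth_a: int, meth_b: int, unmeth_b: int) -> float:
    return float(
        stats.fisher_exact(
            [[meth_a, unmeth_a], [meth_b, unmeth_b]], alternative="two-sided"
        ).pvalue
    )


def fisher_exact_2x2(
    meth_a: int, unmeth_a: int, meth_b: int, unmeth_b: int
) -> float:
    """Two-sided Fisher's exact p-value for a 2x2 count table.

    The two-sided p is the sum of hypergeometric probabilities of all tables
    with the observed margins whose point probability does not exceed the
    observed table's (with a small relative tolerance for floating ties).
    Both sample margins must be positive.
    """
    counts = (meth_a, unmeth_a, meth_b, unmeth_b)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    if meth_a + unmeth_a == 0 or meth_b + unmeth_b == 0:
        raise ValueError("Fisher's exact test undefined on an empty margin")
    return _cached_fisher(*counts)


def _exceeds(num: int, den: int, threshold: Fraction) -> bool:
    """|num/den| > threshold using exact integer arithmetic."""
    t = Fraction(threshold)
    return abs(num) * t.denominator > den * t.numerator


def call_strong_dmcs(
    wide: pd.DataFrame,
    comparison: tuple[str, str],
    delta_threshold: Fraction | float = DEFAULT_DELTA_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> pd.DataFrame:
    """Per-site differential calls for sample A vs sample B.

    ``wide`` is a gated wide count table containing both samples of the
    comparison. delta = level_A - level_B (first-named sample minus second);
    direction "hyper" means A more methylated than B. ``is_strong`` requires
    |delta| strictly above ``delta_threshold`` and p strictly below
    ``p_threshold``. Sites lacking counts in either sample are skipped (count
    logged). Returns a DataFrame with columns chrom, pos, level_a, level_b,
    delta, p, q, direction, is_strong.
    """
    sample_a, sample_b = comparison
    cols = {}
    for s in (sample_a, sample_b):
        for f in ("meth", "total"):
            if (s, f) not in wide.columns:
                raise KeyError(f"sample {s!r} missing from count table")
            cols[(s, f)] = wide[(s, f)].to_numpy()
    ok = ~np.isnan(cols[(sample_a, "total")]) & ~np.isnan(cols[(sample_b, "total")])
    n_skipped = int((~ok).sum())
    if n_skipped:
        logger.info("call_strong_dmcs: skipped %d sites missing in one sample",
                    n_skipped)

    ma = cols[(sample_a, "meth")][ok].astype(np.int64)
    ta = cols[(sample_a, "total")][ok].astype(np.int64)
    mb = cols[(sample_b, "meth")][ok].astype(np.int64)
    tb = cols[(sample_b, "total")][ok].astype(np.int64)
    if (ta <= 0).any() or (tb <= 0).any():
        raise ValueError("zero-coverage site in comparison; gate the table first")

    level_a = ma / ta
    level_b = mb / tb
    delta = level_a - level_b
    p = np.fromiter(
        (fisher_exact_2x2(int(a), int(t1 - a), int(b), int(t2 - b))
         for a, t1, b, t2 in zip(ma, ta, mb, tb)),
        dtype=float, count=len(ma),
    )
    q = multipletests(p, method="fdr_bh")[1] if len(p) else np.array([])

    # exact effect-size gate: |ma/ta - mb/tb| > threshold
    num = ma * tb - mb * ta          # delta numerator over common denominator
    den = ta * tb
    t = Fraction(delta_threshold)
    strong_effect = np.abs(num) * t.denominator > den * t.numerator
    is_strong = strong_effect & (p < p_threshold)

    idx = wide.index[ok]
    out = pd.DataFrame({
        "chrom": idx.get_level_values("chrom"),
        "pos": idx.get_level_values("pos"),
        "level_a": level_a,
        "level_b": level_b,
        "delta": delta,
        "p": p,
        "q": q,
        "direction": np.where(delta > 0, "hyper",
                              np.where(delta < 0, "hypo", "none")),
        "is_strong": is_strong,
    })
    out.attrs["comparison"] = (sample_a, sample_b)
    out.attrs["n_skipped"] = n_skipped
    return out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def call_dmrs(
    dmcs: pd.DataFrame,
    levels: pd.DataFrame,
    max_gap: int = 300,
    min_cpgs: int = 3,
) -> pd.DataFrame:
    """Chain strong same-direction DMCs into differentially methylated regions.

    Strong DMCs on one chromosome with the same direction and consecutive
    inter-CpG gaps <= ``max_gap`` form a chain; chains with >= ``min_cpgs``
    sites become DMRs spanning first to last CpG (+1, half-open). The region
    level per sample is the unweighted mean of the constituent CpG levels
    taken from ``levels``.
    """
    strong = dmcs[dmcs["is_strong"]].sort_values(["chrom", "pos"], kind="stable")
    rows = []
    for (chrom, direction), grp in strong.groupby(["chrom", "direction"],
                                                  sort=True):
        positions = grp["pos"].to_numpy()
        if positions.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(positions) > max_gap) + 1
        for chunk in np.split(positions, breaks):
            if chunk.size < min_cpgs:
                continue
            idx = [(chrom, int(p)) for p in chunk]
            region_levels = levels.loc[idx].mean(axis=0)
            row = {
                "chrom": chrom,
                "start": int(chunk[0]),
                "end": int(chunk[-1]) + 1,
                "direction": direction,
                "n_cpgs": int(chunk.size),
                "cpg_positions": ",".join(str(int(p)) for p in chunk),
            }
            for s in levels.columns:
                row[f"level_{s}"] = float(region_levels[s])
            rows.append(row)
    columns = ["chrom", "start", "end", "direction", "n_cpgs", "cpg_positions"] + [
        f"level_{s}" for s in levels.columns
    ]
    out = pd.DataFrame(rows, columns=columns)
    out.attrs["comparison"] = dmcs.attrs.get("comparison")
    return out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def merge_dmr_sets(
    dmr_set_1: pd.DataFrame,
    dmr_set_2: pd.DataFrame,
    levels: pd.DataFrame,
) -> pd.DataFrame:
    """Union-merge overlapping DMRs from two comparisons.

    Intervals overlapping by >= 1 bp are unioned transitively; each output
    region's level per sample is recomputed as the unweighted mean over *all*
    gated CpGs inside the (possibly merged) interval, taken from ``levels``.
    Non-overlapping DMRs pass through with their interval unchanged.
    """
    both = pd.concat([
        dmr_set_1[["chrom", "start", "end"]],
        dmr_set_2[["chrom", "start", "end"]],
    ], ignore_index=True)
    chrom_index = levels.index.get_level_values("chrom").to_numpy()
    pos_index = levels.index.get_level_values("pos").to_numpy()

    rows = []
    for chrom, grp in both.groupby("chrom", sort=True):
        ivs = grp.sort_values(["start", "end"]).to_numpy()[:, 1:].astype(np.int64)
        cur_s, cur_e, members = None, None, 0
        merged: list[tuple[int, int, int]] = []
        for s, e in ivs:
            if cur_s is None:
                cur_s, cur_e, members = s, e, 1
            elif s < cur_e:  # >=1 bp overlap
                cur_e = max(cur_e, e)
                members += 1
            else:
                merged.append((cur_s, cur_e, members))
                cur_s, cur_e, members = s, e, 1
        if cur_s is not None:
            merged.append((cur_s, cur_e, members))

        on_chrom = chrom_index == chrom
        for s, e, m in merged:
            inside = on_chrom & (pos_index >= s) & (pos_index < e)
            sub = levels[inside]
            row = {"chrom": chrom, "start": int(s), "end": int(e),
                   "n_source_dmrs": int(m), "n_cpgs": int(len(sub))}
            for col in levels.columns:
                row[f"level_{col}"] = float(sub[col].mean()) if len(sub) else np.nan
            rows.append(row)
    columns = ["chrom", "start", "end", "n_source_dmrs", "n_cpgs"] + [
        f"level_{c}" for c in levels.columns
    ]
    return pd.DataFrame(rows, columns=columns).sort_values(
        ["chrom", "start"], kind="stable"
    ).reset_index(drop=True)


@dataclass(frozen=True)
class SetComparison:
    common: list[tuple[str, int]]
    only_a: list[tuple[str, int]]
    only_b: list[tuple[str, int]]

    @property
    def counts(self) -> tuple[int, int, int]:
        return len(self.common), len(self.only_a), len(self.only_b)


def compare_dmc_sets(set_a: pd.DataFrame, set_b: pd.DataFrame) -> SetComparison:
    """Exact overlap of two DMC site sets keyed by (chrom, pos)."""
    keys_a = {(c, int(p)) for c, p in zip(set_a["chrom"], set_a["pos"])}
    keys_b = {(c, int(p)) for c, p in zip(set_b["chrom"], set_b["pos"])}
    return SetComparison(
        common=sorted(keys_a & keys_b),
        only_a=sorted(keys_a - keys_b),
        only_b=sorted(keys_b - keys_a),
    )


def volcano_table(
    common_sites: list[tuple[str, int]],
    wide: pd.DataFrame,
    sample_1: str,
    sample_2: str,
) -> pd.DataFrame:
    """Per-site (delta, p) between two samples at the given common sites.

    delta = level(sample_1) - level(sample_2); p from Fisher's exact test on
    the two samples' (meth, unmeth) counts. Ungated sites are skipped with a
    logged count. Tidy output for volcano plotting; the p = 0.05 reference
    line is a rendering concern.
    """
    rows, skipped = [], 0
    for chrom, pos in common_sites:
        key = (chrom, pos)
        if key not in wide.index:
            skipped += 1
            continue
        rec = wide.loc[key]
        vals = [rec[(s, f)] for s in (sample_1, sample_2) for f in ("meth", "total")]
        if any(pd.isna(v) for v in vals):
            skipped += 1
            continue
        m1, t1, m2, t2 = (int(v) for v in vals)
        rows.append({
            "chrom": chrom, "pos": pos,
            "delta": m1 / t1 - m2 / t2,
            "p": fisher_exact_2x2(m1, t1 - m1, m2, t2 - m2),
        })
    if skipped:
        logger.info("volcano_table: skipped %d ungated sites", skipped)
    out = pd.DataFrame(rows, columns=["chrom", "pos", "delta", "p"])
    out.attrs["n_skipped"] = skipped
    return out
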