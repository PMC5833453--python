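"""Promoter definition, CpG-density classes, and genomic-location annotation.

Promoters are the symmetric -1 kb / +1 kb windows around transcription start
sites. Promoter CpG-density classes follow the windowed criteria of the
Weber-style classification: sliding 500-bp windows (5-bp step) across the
promoter, with CpG observed/expected ratio

    O/E = (N_CpG * L) / (N_C * N_G)

(0 when the window lacks C or G). A promoter is HCP if any window reaches
O/E >= 0.75 with GC >= 55%, LCP if no window reaches O/E >= 0.48, and ICP
otherwise. All five constants are arguments.

Genomic-location labels are exclusive with precedence promoter > exon >
intron > intergenic; repeat / imprinted-cluster / gDMR overlaps are reported
as additional non-exclusive flags. Overlap semantics everywhere: >= 1 bp on
half-open intervals, strand-blind (methylation is strand-pooled).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .meth_quant import categorize_counts, level_histogram, methylation_levels
from .synth_genome import FEATURE_CLASSES, FeatureCatalogue, GenomeAssembly

__all__ = [
    "PromoterRecord",
    "define_promoters",
    "classify_promoter_cpg_density",
    "classify_promoters",
    "assign_genomic_location",
    "annotate_dmrs",
    "region_restricted_summary",
]

LOCATION_PRECEDENCE = ("promoter", "exon", "intron")
FLAG_CLASSES = ("repeat_LINE", "repeat_SINE", "repeat_LTR",
                "imprinted_cluster", "gDMR")


@dataclass
class PromoterRecord:
    gene: str
    chrom: str
    tss: int
    strand: str
    start: int
    end: int
    cpg_class: str | None = None
    best_window: tuple[int, float, float] | None = None  # (offset, GC, O/E)


def define_promoters(
    tss_table: pd.DataFrame,
    contig_lengths: dict[str, int],
    flank: int = 1000,
) -> list[PromoterRecord]:
    """Promoter intervals [TSS - flank, TSS + flank), clipped at contig ends.

    ``tss_table`` needs columns gene, chrom, pos, strand. The flank is
    symmetric, so strand does not change the interval (it is retained).
    """
    records = []
    for _, row in tss_table.iterrows():
        chrom, tss = row["chrom"], int(row["pos"])
        if chrom not in contig_lengths:
            raise ValueError(f"TSS on unknown contig {chrom!r}")
        length = contig_lengths[chrom]
        if not 0 <= tss < length:
            raise ValueError(
                f"TSS {tss} outside contig {chrom!r} (length {length})"
            )
        records.append(PromoterRecord(
            gene=row["gene"], chrom=chrom, tss=tss, strand=row["strand"],
            start=max(0, tss - flank), end=min(length, tss + flank),
        ))
    return records


def _window_stats(seq: np.ndarray, offsets: np.ndarray, window: int
                  ) -> tuple[np.ndarray, np.ndarray]:
    """(GC fraction, CpG O/E) for each window offset, via cumulative sums."""
    is_c = (seq == b"C").astype(np.int64)
    is_g = (seq == b"G").astype(np.int64)
    is_cg = np.zeros(seq.size, dtype=np.int64)
    if seq.size > 1:
        is_cg[:-1] = ((seq[:-1] == b"C") & (seq[1:] == b"G")).astype(np.int64)
    cum_c = np.concatenate([[0], np.cumsum(is_c)])
    cum_g = np.concatenate([[0], np.cumsum(is_g)])
    cum_cg = np.concatenate([[0], np.cumsum(is_cg)])
    n_c = cum_c[offsets + window] - cum_c[offsets]
    n_g = cum_g[offsets + window] - cum_g[offsets]
    # a CpG counts only if both bases are inside the window
    n_cpg = cum_cg[offsets + window - 1] - cum_cg[offsets]
    gc = (n_c + n_g) / window
    denom = n_c * n_g
    oe = np.zeros(offsets.size, dtype=float)
    nz = denom > 0
    oe[nz] = n_cpg[nz] * window / denom[nz]
    return gc, oe


def classify_promoter_cpg_density(
    promoter: PromoterRecord,
    genome: GenomeAssembly,
    window: int = 500,
    step: int = 5,
    oe_high: float = 0.75,
    oe_low: float = 0.48,
    gc_min: float = 0.55,
) -> PromoterRecord:
    """Assign HCP / ICP / LCP from sliding-window CpG density.

    If the promoter is shorter than ``window`` the whole interval is the
    single window. ``best_window`` records the offset with the highest O/E
    (GC and O/E at that offset). Returns the record, mutated in place.
    """
    seq = np.frombuffer(
        genome.sequence(promoter.chrom)[promoter.start:promoter.end].encode(),
        dtype="S1",
    )
    w = min(window, seq.size)
    offsets = np.arange(0, seq.size - w + 1, step, dtype=np.int64)
    gc, oe = _window_stats(seq, offsets, w)
    if np.any((oe >= oe_high) & (gc >= gc_min)):
        cls = "HCP"
    elif np.all(oe < oe_low):
        cls = "LCP"
    else:
        cls = "ICP"
    best = int(np.argmax(oe))
    promoter.cpg_class = cls
    promoter.best_window = (int(offsets[best]), float(gc[best]), float(oe[best]))
    return promoter


def classify_promoters(
    promoters: list[PromoterRecord], genome: GenomeAssembly, **kwargs
) -> list[PromoterRecord]:
    return [classify_promoter_cpg_density(p, genome, **kwargs) for p in promoters]


def _class_tree(catalogue: FeatureCatalogue, feature_class: str,
                chrom: str) -> IntervalTree:
    sub = catalogue.by_class(feature_class)
    sub = sub[sub["chrom"] == chrom]
    return IntervalTree.from_tuples(
        (int(s), int(e), n) for s, e, n in zip(sub["start"], sub["end"],
                                               sub["name"])
    )


def assign_genomic_location(
    sites: pd.DataFrame, catalogue: FeatureCatalogue
) -> pd.DataFrame:
    """Exclusive location label plus overlap flags for each (chrom, pos) site.

    Labels follow the precedence promoter > exon > intron > intergenic; every
    site receives exactly one. Overlaps with repeats, imprinted clusters and
    gDMRs are reported in the ``flags`` column (comma-joined feature names),
    not in the exclusive label.
    """
    out = sites[["chrom", "pos"]].copy().reset_index(drop=True)
    location = np.full(len(out), "intergenic", dtype=object)
    flags = [[] for _ in range(len(out))]
    for chrom, grp in out.groupby("chrom", sort=False):
        trees = {cls: _class_tree(catalogue, cls, chrom)
                 for cls in LOCATION_PRECEDENCE + FLAG_CLASSES}
        for i, pos in zip(grp.index, grp["pos"]):
            for cls in LOCATION_PRECEDENCE:
                if trees[cls].overlaps_point(int(pos)):
                    location[i] = cls
                    break
            for cls in FLAG_CLASSES:
                for iv in trees[cls][int(pos)]:
                    flags[i].append(f"{cls}:{iv.data}")
    out["location"] = location
    out["flags"] = [",".join(f) for f in flags]
    return out


def annotate_dmrs(dmrs: pd.DataFrame, catalogue: FeatureCatalogue) -> pd.DataFrame:
    """Non-exclusive region labels: a DMR gets a label iff it overlaps the
    corresponding feature by >= 1 bp.

    Adds boolean columns promoter_dmr, imprinted_dmr, gdmr_overlap,
    repeat_overlap and a ``feature_names`` column listing touched features.
    """
    out = dmrs.copy().reset_index(drop=True)
    label_sources = {
        "promoter_dmr": ("promoter",),
        "imprinted_dmr": ("imprinted_cluster",),
        "gdmr_overlap": ("gDMR",),
        "repeat_overlap": ("repeat_LINE", "repeat_SINE", "repeat_LTR"),
    }
    cols = {k: np.zeros(len(out), dtype=bool) for k in label_sources}
    names = [[] for _ in range(len(out))]
    for chrom, grp in out.groupby("chrom", sort=False):
        trees = {cls: _class_tree(catalogue, cls, chrom)
                 for cls in set(sum(label_sources.values(), ()))}
        for i, (s, e) in zip(grp.index, zip(grp["start"], grp["end"])):
            for label, classes in label_sources.items():
                for cls in classes:
                    hits = trees[cls].overlap(int(s), int(e))
                    if hits:
                        cols[label][i] = True
                        names[i].extend(sorted(h.data for h in hits))
    for label, values in cols.items():
        out[label] = values
    out["feature_names"] = [",".join(n) for n in names]
    return out


def region_restricted_summary(
    wide: pd.DataFrame,
    catalogue: FeatureCatalogue,
    feature_class: str,
    n_bins: int = 20,
) -> dict:
    """Level histogram and category fractions for gated CpGs inside a class.

    ``feature_class`` may be any catalogued class or the pseudo-class
    ``"other"`` meaning outside every promoter/repeat interval (mirrors the
    "other genomic regions" compartment of per-compartment level histograms).
    """
    named = [c for c in FEATURE_CLASSES if c != "other"]
    if feature_class not in FEATURE_CLASSES:
        raise ValueError(f"unknown feature class {feature_class!r}")
    chroms = wide.index.get_level_values("chrom").to_numpy()
    positions = wide.index.get_level_values("pos").to_numpy()
    mask = np.zeros(len(wide), dtype=bool)
    target = named if feature_class == "other" else [feature_class]
    for chrom in np.unique(chroms):
        on = chroms == chrom
        hit = np.zeros(int(on.sum()), dtype=bool)
        for cls in target:
            hit |= catalogue.interval_set(cls, chrom).contains(positions[on])
        mask[on] = hit
    if feature_class == "other":
        mask = ~mask
    sub = wide[mask]
    if len(sub) == 0:
        return {"n_cpgs": 0, "histogram": None, "category_fractions": None}
    return {
        "n_cpgs": int(len(sub)),
        "histogram": level_histogram(methylation_levels(sub), n_bins=n_bins),
        "category_fractions": categorize_counts(sub),
    }
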