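"""In-silico RRBS: MspI digestion, size selection, bisulfite count simulation.

RRBS reduces genome complexity by digesting with MspI (recognition CCGG, cut
C^CGG, methylation-insensitive) and size-selecting fragments before bisulfite
conversion, which enriches coverage around CpG-dense regions. This module
mirrors that protocol on a :class:`~rrbsdiff.synth_genome.GenomeAssembly` and
emits per-CpG methylated/total read counts directly (alignment is out of
scope, so no reads are written).

Bisulfite chemistry converts unmethylated C to T while methylated C is
protected; incomplete conversion therefore *inflates* apparent methylation.
With true methylation probability m and conversion efficiency c, a sequenced
read reports C with probability ``q = m + (1 - m) * (1 - c)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._intervals import IntervalSet
from .synth_genome import GenomeAssembly

__all__ = [
    "RRBSFragment",
    "digest_mspi",
    "size_select",
    "simulate_counts",
    "fragments_to_frame",
]

MSPI_SITE = "CCGG"
#: MspI cuts C^CGG: the cut offset is 1 base into the recognition site
MSPI_CUT_OFFSET = 1

COUNT_COLUMNS = ["chrom", "pos", "sample", "meth", "total"]


@dataclass(frozen=True)
class RRBSFragment:
    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def digest_mspi(genome: GenomeAssembly) -> list[RRBSFragment]:
    """Fragment every contig at MspI cut offsets.

    Cut offsets are p + 1 for every (possibly overlapping) occurrence of CCGG
    starting at p; fragments are the intervals between consecutive cuts plus
    the contig ends, so they tile each contig exactly. A contig without any
    recognition site yields a single fragment spanning it.
    """
    fragments: list[RRBSFragment] = []
    for name, seq in genome.contigs:
        cuts = [0]
        p = seq.find(MSPI_SITE)
        while p != -1:
            cuts.append(p + MSPI_CUT_OFFSET)
            p = seq.find(MSPI_SITE, p + 1)  # overlapping sites each cut
        cuts.append(len(seq))
        for s, e in zip(cuts[:-1], cuts[1:]):
            if e > s:
                fragments.append(RRBSFragment(name, s, e))
    return fragments


def size_select(
    fragments: list[RRBSFragment], min_len: int = 170, max_len: int = 370
) -> list[RRBSFragment]:
    """Keep fragments with min_len <= length <= max_len (bounds inclusive)."""
    if min_len > max_len:
        raise ValueError("min_len must not exceed max_len")
    return [f for f in fragments if min_len <= f.length <= max_len]


def fragments_to_frame(fragments: list[RRBSFragment]) -> pd.DataFrame:
    return pd.DataFrame(
        [(f.chrom, f.start, f.end) for f in fragments],
        columns=["chrom", "start", "end"],
    )


def simulate_counts(
    fragments: list[RRBSFragment],
    state_map: pd.DataFrame,
    mean_coverage: float = 30.0,
    conversion_efficiency: float = 0.995,
    replicate_dispersion: float = 0.0,
    sample_plan: dict[str, str] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate per-CpG bisulfite counts over the size-selected library.

    Only CpGs inside retained fragments receive coverage. Per CpG and sample,
    total_count ~ Poisson(mean_coverage); with ``replicate_dispersion`` d > 0
    the per-site rate is Gamma(1/d, d)-multiplied (negative-binomial style
    overdispersion across replicates). meth_count ~ Binomial(total, q) with
    q = m_true + (1 - m_true) * (1 - conversion_efficiency).

    Parameters
    ----------
    state_map
        DataFrame indexed by (chrom, pos) with one m_true column per cell
        type (as produced by ``assign_methylation_states``).
    sample_plan
        Mapping sample_id -> cell type column of ``state_map``; defaults to
        one sample per cell type, named after it.

    Returns a long-format DataFrame (chrom, pos, sample, meth, total) with
    zero-coverage records dropped. Deterministic given ``seed``.
    """
    if mean_coverage <= 0:
        raise ValueError("mean_coverage must be positive")
    if not 0.0 < conversion_efficiency <= 1.0:
        raise ValueError("conversion_efficiency must be in (0, 1]")
    if replicate_dispersion < 0:
        raise ValueError("replicate_dispersion must be non-negative")
    if sample_plan is None:
        sample_plan = {ct: ct for ct in state_map.columns}
    missing = sorted(set(sample_plan.values()) - set(state_map.columns))
    if missing:
        raise KeyError(f"sample_plan references unknown cell types: {missing}")

    # restrict the CpG universe to retained fragments
    chroms = state_map.index.get_level_values("chrom").to_numpy()
    positions = state_map.index.get_level_values("pos").to_numpy()
    covered = np.zeros(len(state_map), dtype=bool)
    for chrom in np.unique(chroms):
        frs = [f for f in fragments if f.chrom == chrom]
        iv = IntervalSet([f.start for f in frs], [f.end for f in frs]) if frs \
            else IntervalSet([], [])
        mask = chroms == chrom
        covered[mask] = iv.contains(positions[mask])
    sub = state_map[covered]
    n = len(sub)

    records = []
    seed_seq = np.random.SeedSequence(seed)
    children = seed_seq.spawn(len(sample_plan))
    for (sample_id, cell_type), child in zip(sorted(sample_plan.items()), children):
        rng = np.random.default_rng(child)
        m_true = sub[cell_type].to_numpy()
        if m_true.min() < 0 or m_true.max() > 1:
            raise ValueError("m_true values must lie in [0, 1]")
        rate = np.full(n, float(mean_coverage))
        if replicate_dispersion > 0:
            d = replicate_dispersion
            rate = rate * rng.gamma(shape=1.0 / d, scale=d, size=n)
        total = rng.poisson(rate)
        q = m_true + (1.0 - m_true) * (1.0 - conversion_efficiency)
        meth = rng.binomial(total, q)
        keep = total > 0
        records.append(pd.DataFrame({
            "chrom": sub.index.get_level_values("chrom")[keep],
            "pos": sub.index.get_level_values("pos")[keep],
            "sample": sample_id,
            "meth": meth[keep],
            "total": total[keep],
        }))
    out = pd.concat(records, ignore_index=True) if records else pd.DataFrame(
        columns=COUNT_COLUMNS
    )
    return out.sort_values(["chrom", "pos", "sample"], kind="stable").reset_index(
        drop=True
    )
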