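"""Synthetic genome, feature catalogue and ground-truth methylation states.

This module builds a seeded toy genome with the statistical structure an RRBS
comparison of pluripotent cell types assumes: MspI sites spaced so that a
substantial share of fragments falls in the size-selected range, promoters
that are either CpG-island-like (high CpG observed/expected, high GC) or
CpG-poor, interspersed repeats (LINE/SINE/LTR), and imprinted clusters each
containing a germline DMR (gDMR) sub-interval.

Ground-truth per-CpG methylation probabilities are drawn per cell type from a
two-component Beta mixture whose mixing weight depends on the feature class
containing the CpG. The shipped default profiles encode three archetypes:

* ``4F-like``   — globally the most methylated; repeats, imprinted clusters
  and gDMRs strongly hypermethylated (bimodal genome-wide distribution).
* ``C-like``    — intermediate: partial hypermethylation of the same classes.
* ``ESC-like``  — globally hypomethylated.

All mixture parameters are generator settings chosen to produce these
qualitative contrasts; they are configuration, not measured biology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._intervals import IntervalSet

__all__ = [
    "GenomeAssembly",
    "FeatureCatalogue",
    "BetaMixture",
    "CellTypeProfile",
    "SizingError",
    "FEATURE_CLASSES",
    "STATE_PRECEDENCE",
    "default_profiles",
    "find_cpg_sites",
    "generate_genome",
    "assign_methylation_states",
    "simulate_expression",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

FEATURE_CLASSES = (
    "promoter",
    "exon",
    "intron",
    "repeat_LINE",
    "repeat_SINE",
    "repeat_LTR",
    "imprinted_cluster",
    "gDMR",
    "other",
)

#: innermost-wins precedence used when a CpG lies in nested features
STATE_PRECEDENCE = (
    "gDMR",
    "imprinted_cluster",
    "promoter",
    "repeat_LINE",
    "repeat_SINE",
    "repeat_LTR",
    "exon",
    "intron",
)


class SizingError(ValueError):
    """Requested features do not fit in the genome without overlap."""


@dataclass
class GenomeAssembly:
    """Ordered contigs with uppercase A/C/G/T sequences."""

    contigs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.contigs]
        if len(set(names)) != len(names):
            raise ValueError("contig names must be unique")
        for name, seq in self.contigs:
            if not seq:
                raise ValueError(f"contig {name!r} is empty")
            if set(seq) - set("ACGT"):
                raise ValueError(f"contig {name!r} contains non-ACGT characters")

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs}

    def sequence(self, chrom: str) -> str:
        for name, seq in self.contigs:
            if name == chrom:
                return seq
        raise KeyError(chrom)


class FeatureCatalogue:
    """Strand-aware genomic intervals on 0-based half-open coordinates.

    Wraps a DataFrame with columns chrom, start, end, strand, feature_class,
    name (plus optional generator bookkeeping columns such as ``flavor``).
    """

    def __init__(self, frame: pd.DataFrame):
        required = ["chrom", "start", "end", "strand", "feature_class", "name"]
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise ValueError(f"catalogue frame missing columns: {missing}")
        bad = frame[frame["start"] >= frame["end"]]
        if len(bad):
            raise ValueError("catalogue contains intervals with start >= end")
        unknown = set(frame["feature_class"]) - set(FEATURE_CLASSES)
        if unknown:
            raise ValueError(f"unknown feature classes: {sorted(unknown)}")
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def by_class(self, feature_class: str) -> pd.DataFrame:
        return self.frame[self.frame["feature_class"] == feature_class]

    def interval_set(self, feature_class: str, chrom: str) -> IntervalSet:
        sub = self.frame[
            (self.frame["feature_class"] == feature_class)
            & (self.frame["chrom"] == chrom)
        ]
        return IntervalSet(sub["start"].to_numpy(), sub["end"].to_numpy())

    def classes_present(self) -> list[str]:
        return sorted(set(self.frame["feature_class"]))


@dataclass(frozen=True)
class BetaMixture:
    """Two-component Beta mixture for per-CpG methylation probabilities."""

    weight_high: float
    alpha_high: float = 30.0
    beta_high: float = 1.5
    alpha_low: float = 1.5
    beta_low: float = 30.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight_high <= 1.0:
            raise ValueError("weight_high must be in [0, 1]")
        for p in (self.alpha_high, self.beta_high, self.alpha_low, self.beta_low):
            if p <= 0:
                raise ValueError("Beta parameters must be positive")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        high = rng.random(n) < self.weight_high
        out = rng.beta(self.alpha_low, self.beta_low, size=n)
        n_high = int(high.sum())
        if n_high:
            out[high] = rng.beta(self.alpha_high, self.beta_high, size=n_high)
        return out

    def quantile(self, u_component: np.ndarray, v: np.ndarray) -> np.ndarray:
        """Comonotone draw: component from ``u_component`` (< weight_high
        selects the high component), value from the Beta quantile at ``v``.

        Sharing (u, v) across cell types couples their states — a CpG
        hypermethylated under a low-weight profile is also hypermethylated
        under any higher-weight profile — while each marginal remains the
        profile's own mixture.
        """
        from scipy.stats import beta as beta_dist
        high = u_component < self.weight_high
        out = beta_dist.ppf(v, self.alpha_low, self.beta_low)
        if high.any():
            out[high] = beta_dist.ppf(v[high], self.alpha_high, self.beta_high)
        return out


@dataclass
class CellTypeProfile:
    """Per-feature-class Beta mixtures for one cell type.

    ``mixtures`` must provide an entry for every feature class a CpG can fall
    in, plus ``"background"`` for CpGs outside all catalogued features.
    """

    name: str
    mixtures: dict[str, BetaMixture] = field(default_factory=dict)

    def mixture_for(self, feature_class: str) -> BetaMixture:
        key = "background" if feature_class == "other" else feature_class
        if key not in self.mixtures:
            raise KeyError(
                f"profile {self.name!r} has no mixture for class {key!r}"
            )
        return self.mixtures[key]


def _profile(name: str, background: float, promoter: float, genic: float,
             repeat: float, imprinted: float, gdmr: float) -> CellTypeProfile:
    w = {
        "background": background,
        "promoter": promoter,
        "exon": genic,
        "intron": genic,
        "repeat_LINE": repeat,
        "repeat_SINE": repeat,
        "repeat_LTR": repeat,
        "imprinted_cluster": imprinted,
        "gDMR": gdmr,
    }
    return CellTypeProfile(name, {k: BetaMixture(v) for k, v in w.items()})


def default_profiles() -> dict[str, CellTypeProfile]:
    """Shipped archetype profiles (generator settings, not measurements).

    High-methylation mixing weights are ordered 4F-like > C-like > ESC-like in
    every compartment, strongest in repeats, imprinted clusters and gDMRs.
    """
    return {
        "ESC-like": _profile("ESC-like", 0.03, 0.01, 0.03, 0.05, 0.05, 0.08),
        "C-like": _profile("C-like", 0.08, 0.05, 0.10, 0.40, 0.40, 0.40),
        "4F-like": _profile("4F-like", 0.22, 0.10, 0.30, 0.80, 0.80, 0.80),
    }


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

def find_cpg_sites(genome: GenomeAssembly) -> dict[str, np.ndarray]:
    """0-based positions of the C of every forward-strand CpG, per contig.

    Counts from the reverse-strand G of the symmetric CpG are pooled into the
    same site throughout the package.
    """
    out: dict[str, np.ndarray] = {}
    for name, seq in genome.contigs:
        arr = np.frombuffer(seq.encode(), dtype="S1")
        hits = (arr[:-1] == b"C") & (arr[1:] == b"G")
        out[name] = np.flatnonzero(hits).astype(np.int64)
    return out


def _random_background(rng: np.random.Generator, length: int,
                       cpg_keep: float = 0.2) -> np.ndarray:
    """CpG-depleted random sequence (byte array).

    An i.i.d. sequence has CpG observed/expected near 1, which real genomes do
    not; after drawing i.i.d. bases (GC 42%), each CpG dinucleotide survives
    with probability ``cpg_keep``, otherwise the G is mutated to A/T. The
    resulting background O/E is ~0.2.
    """
    seq = rng.choice(_BASES, size=length, p=[0.29, 0.21, 0.21, 0.29])
    is_cpg = (seq[:-1] == b"C") & (seq[1:] == b"G")
    kill = is_cpg & (rng.random(length - 1) >= cpg_keep)
    idx = np.flatnonzero(kill) + 1
    seq[idx] = rng.choice(np.frombuffer(b"AT", dtype="S1"), size=idx.size)
    return seq


def _cpg_rich_insert(rng: np.random.Generator, length: int) -> np.ndarray:
    """CpG-island-like sequence: GC ~60%, forced CG every 8 bp (O/E > 1)."""
    seq = rng.choice(_BASES, size=length, p=[0.20, 0.30, 0.30, 0.20])
    for p in range(0, length - 1, 8):
        seq[p] = b"C"
        seq[p + 1] = b"G"
    return seq


def _place_block(rng: np.random.Generator, occupied: list[tuple[int, int]],
                 contig_len: int, length: int, tries: int = 100) -> int:
    """Sample a non-overlapping start for a block, or raise SizingError.

    Rejection sampling first (uniform over the contig); if the contig is too
    fragmented for that to land, fall back to an exact scan of the free gaps
    and draw uniformly over the remaining feasible offsets, so failure means
    the block genuinely does not fit.
    """
    if length > contig_len:
        raise SizingError(f"feature of length {length} exceeds contig ({contig_len})")
    for _ in range(tries):
        start = int(rng.integers(0, contig_len - length + 1))
        end = start + length
        if all(end <= s or start >= e for s, e in occupied):
            occupied.append((start, end))
            return start
    # exact fallback: enumerate feasible start ranges within free gaps
    merged = sorted(occupied)
    gaps, cursor = [], 0
    for s, e in merged:
        if s > cursor:
            gaps.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < contig_len:
        gaps.append((cursor, contig_len))
    feasible = [(gs, ge - length) for gs, ge in gaps if ge - gs >= length]
    total = sum(hi - lo + 1 for lo, hi in feasible)
    if total == 0:
        raise SizingError(
            "could not place all requested features without overlap; "
            "reduce feature counts or enlarge the genome"
        )
    pick = int(rng.integers(0, total))
    for lo, hi in feasible:
        span = hi - lo + 1
        if pick < span:
            start = lo + pick
            occupied.append((start, start + length))
            return start
        pick -= span
    raise AssertionError("unreachable")


def generate_genome(
    n_contigs: int = 2,
    contig_length: int = 250_000,
    n_promoters: int = 40,
    n_repeats: int = 60,
    n_imprinted_clusters: int = 4,
    cpg_island_fraction: float = 0.5,
    seed: int = 0,
    *,
    promoter_flank: int = 1000,
    gene_body_length: int = 4000,
    repeat_length: int = 600,
    imprinted_length: int = 8000,
    gdmr_length: int = 800,
    mspi_spacing: tuple[int, int] = (150, 330),
) -> tuple[GenomeAssembly, FeatureCatalogue]:
    """Generate a seeded toy genome plus feature catalogue.

    Promoters span exactly [TSS - flank, TSS + flank); a fraction
    ``cpg_island_fraction`` of them receives a CpG-island-like core (a 500-bp
    window with CpG O/E >= 0.75 and GC >= 55% is guaranteed by construction),
    the rest stay on the CpG-depleted background. Each imprinted cluster
    contains one gDMR sub-interval. MspI sites (CCGG) are planted genome-wide
    at spacings drawn from ``mspi_spacing`` so that many digest fragments fall
    in the 170-370 bp size-selected range. Deterministic given ``seed``.
    """
    if min(n_contigs, contig_length, n_promoters, n_repeats,
           n_imprinted_clusters) < 0 or n_contigs == 0 or contig_length == 0:
        raise ValueError("counts must be non-negative and genome non-empty")
    if not 0.0 <= cpg_island_fraction <= 1.0:
        raise ValueError("cpg_island_fraction must be in [0, 1]")

    rng = np.random.default_rng(seed)
    gene_block = promoter_flank + gene_body_length
    demand = (
        n_promoters * gene_block
        + n_repeats * repeat_length
        + n_imprinted_clusters * imprinted_length
    )
    capacity = n_contigs * contig_length
    if demand > 0.6 * capacity:
        raise SizingError(
            f"requested features need ~{demand} bp but the genome offers "
            f"{capacity} bp; placement would be infeasible"
        )

    contig_names = [f"chr{i + 1}" for i in range(n_contigs)]
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in contig_names}
    sequences = {
        c: _random_background(rng, contig_length) for c in contig_names
    }

    rows: list[dict] = []
    n_rich = round(cpg_island_fraction * n_promoters)

    # place the largest blocks first so packing stays feasible
    for i in range(n_imprinted_clusters):
        chrom = contig_names[int(rng.integers(0, n_contigs))]
        start = _place_block(rng, occupied[chrom], contig_length, imprinted_length)
        end = start + imprinted_length
        rows.append(dict(chrom=chrom, start=start, end=end, strand=".",
                         feature_class="imprinted_cluster",
                         name=f"icr{i:02d}", flavor="", tss=-1))
        off = int(rng.integers(0, imprinted_length - gdmr_length + 1))
        rows.append(dict(chrom=chrom, start=start + off,
                         end=start + off + gdmr_length, strand=".",
                         feature_class="gDMR", name=f"icr{i:02d}.gdmr",
                         flavor="", tss=-1))

    # genes: promoter +-flank around the TSS, 3 exons, introns in between
    exon_offsets = [(0, 300), (1500, 1800), (3400, 3700)]
    for i in range(n_promoters):
        chrom = contig_names[int(rng.integers(0, n_contigs))]
        block_start = _place_block(rng, occupied[chrom], contig_length, gene_block)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            tss = block_start + promoter_flank
            body = (tss, tss + gene_body_length)
            exons = [(tss + a, tss + b) for a, b in exon_offsets]
        else:
            tss = block_start + gene_body_length
            body = (tss - gene_body_length, tss)
            exons = [(tss - b, tss - a) for a, b in exon_offsets]
        gene = f"gene{i:04d}"
        flavor = "cpg_rich" if i < n_rich else "cpg_poor"
        rows.append(dict(chrom=chrom, start=tss - promoter_flank,
                         end=tss + promoter_flank, strand=strand,
                         feature_class="promoter", name=gene, flavor=flavor,
                         tss=tss))
        exons = sorted(exons)
        for j, (s, e) in enumerate(exons):
            rows.append(dict(chrom=chrom, start=s, end=e, strand=strand,
                             feature_class="exon", name=f"{gene}.ex{j + 1}",
                             flavor="", tss=-1))
        introns = [(exons[j][1], exons[j + 1][0]) for j in range(len(exons) - 1)]
        tail = (exons[-1][1], max(body)) if exons[-1][1] < max(body) else None
        if tail:
            introns.append(tail)
        for j, (s, e) in enumerate(i for i in introns if i[0] < i[1]):
            rows.append(dict(chrom=chrom, start=s, end=e, strand=strand,
                             feature_class="intron", name=f"{gene}.in{j + 1}",
                             flavor="", tss=-1))
        if flavor == "cpg_rich":
            half = 350
            ins = _cpg_rich_insert(rng, 2 * half)
            lo = max(0, tss - half)
            sequences[chrom][lo:lo + ins.size] = ins[: contig_length - lo]

    repeat_classes = ["repeat_LINE", "repeat_SINE", "repeat_LTR"]
    for i in range(n_repeats):
        chrom = contig_names[int(rng.integers(0, n_contigs))]
        start = _place_block(rng, occupied[chrom], contig_length, repeat_length)
        cls = repeat_classes[i % 3]
        rows.append(dict(chrom=chrom, start=start, end=start + repeat_length,
                         strand=".", feature_class=cls,
                         name=f"{cls.split('_')[1]}{i:04d}", flavor="", tss=-1))

    # plant MspI sites so the digest yields size-selectable fragments
    lo, hi = mspi_spacing
    for chrom in contig_names:
        seq = sequences[chrom]
        pos = int(rng.integers(lo, hi + 1))
        while pos + 4 <= contig_length:
            seq[pos:pos + 4] = np.frombuffer(b"CCGG", dtype="S1")
            pos += int(rng.integers(lo, hi + 1))

    genome = GenomeAssembly(
        [(c, sequences[c].tobytes().decode()) for c in contig_names]
    )
    frame = pd.DataFrame(rows).sort_values(
        ["chrom", "start", "end"], kind="stable"
    ).reset_index(drop=True)
    return genome, FeatureCatalogue(frame)


# ---------------------------------------------------------------------------
# methylation states
# ---------------------------------------------------------------------------

def classify_cpgs(
    catalogue: FeatureCatalogue, cpg_sites: dict[str, np.ndarray]
) -> pd.Series:
    """Feature-class label per CpG under the innermost-wins precedence.

    Returns a Series indexed by (chrom, pos) with values in FEATURE_CLASSES;
    CpGs outside every catalogued feature are labelled ``other``.
    """
    parts = []
    for chrom, positions in cpg_sites.items():
        labels = np.full(positions.shape, "other", dtype=object)
        for cls in reversed(STATE_PRECEDENCE):  # low precedence first
            iv = catalogue.interval_set(cls, chrom)
            labels[iv.contains(positions)] = cls
        idx = pd.MultiIndex.from_arrays(
            [np.full(positions.shape, chrom, dtype=object), positions],
            names=["chrom", "pos"],
        )
        parts.append(pd.Series(labels, index=idx))
    return pd.concat(parts).sort_index()


def assign_methylation_states(
    genome: GenomeAssembly,
    catalogue: FeatureCatalogue,
    profiles: dict[str, CellTypeProfile],
    seed: int = 0,
) -> pd.DataFrame:
    """Draw ground-truth per-CpG methylation probabilities per cell type.

    Every forward-strand CpG in the genome gets one m_true in [0, 1] per cell
    type, drawn from the Beta mixture of its enclosing feature class (ties
    broken by gDMR > imprinted_cluster > promoter > repeats > exon > intron >
    other). Cell types are coupled comonotonically through shared per-CpG
    uniforms, so methylomes are highly correlated across cell types (as real
    pluripotent methylomes are) while each cell type's marginal distribution
    is exactly its profile's mixture. Deterministic given ``seed``.
    """
    cpg_sites = find_cpg_sites(genome)
    labels = classify_cpgs(catalogue, cpg_sites)
    n = len(labels)
    out = pd.DataFrame(index=labels.index)
    rng = np.random.default_rng(seed)
    u_component = rng.random(n)   # shared mixture-component uniform
    v_quantile = rng.random(n)    # shared Beta-quantile uniform
    label_values = labels.to_numpy()
    for cell_type in sorted(profiles):
        profile = profiles[cell_type]
        m = np.empty(n, dtype=float)
        for cls in np.unique(label_values):
            mask = label_values == cls
            m[mask] = profile.mixture_for(str(cls)).quantile(
                u_component[mask], v_quantile[mask]
            )
        out[cell_type] = m
    return out


def simulate_expression(
    catalogue: FeatureCatalogue,
    state_map: pd.DataFrame,
    seed: int = 0,
    *,
    base_fpkm: float = 30.0,
    repression: float = 6.0,
    noise_sd: float = 0.25,
    silent_fraction: float = 0.05,
) -> pd.DataFrame:
    """Synthetic FPKM table (genes x cell types) tied to promoter methylation.

    Expression follows base_fpkm * 2**(-repression * m_promoter) with
    log-normal noise, so promoter hypermethylation represses; a small random
    gene subset is silenced (FPKM 0) in all cell types to exercise the
    all-zero filter downstream. Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    promoters = catalogue.by_class("promoter")
    cell_types = list(state_map.columns)
    rows = {}
    for _, p in promoters.iterrows():
        sub = state_map.loc[
            (state_map.index.get_level_values("chrom") == p["chrom"])
            & (state_map.index.get_level_values("pos") >= p["start"])
            & (state_map.index.get_level_values("pos") < p["end"])
        ]
        mean_m = sub.mean() if len(sub) else pd.Series(0.0, index=cell_types)
        noise = np.exp(rng.normal(0.0, noise_sd, size=len(cell_types)))
        rows[p["name"]] = base_fpkm * np.power(2.0, -repression * mean_m.to_numpy()) * noise
    fpkm = pd.DataFrame.from_dict(rows, orient="index", columns=cell_types)
    fpkm.index.name = "gene"
    silent = rng.random(len(fpkm)) < silent_fraction
    fpkm.loc[silent, :] = 0.0
    return fpkm.sort_index()
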