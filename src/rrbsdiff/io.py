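"""Readers/writers for the pipeline's file formats and the run configuration.

Formats: FASTA (genome), BED3/BED6 (features, fragments, DMRs), long
tab-separated count tables (chrom, pos, sample, meth, total), state maps
(chrom, pos, cell_type, m_true) and a YAML configuration. Tabular outputs
carry ``#``-prefixed header lines naming the thresholds used, for audit;
readers skip such lines.
"""

from __future__ import annotations

import dataclasses
from fractions import Fraction
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from .rrbs_sim import COUNT_COLUMNS
from .synth_genome import FeatureCatalogue, GenomeAssembly

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_counts",
    "write_counts",
    "read_counts_bedgraph",
    "read_state_map",
    "write_state_map",
    "write_table",
    "read_table",
    "PipelineConfig",
]

_FASTA_ALPHABET = set("ACGTN")


def read_fasta(path: str | Path) -> GenomeAssembly:
    """Read a FASTA genome; sequences uppercased, contig order preserved.

    Duplicate headers, empty records and non-ACGTN characters are rejected
    with the offending record named.
    """
    contigs: list[tuple[str, str]] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id
        if name in seen:
            raise ValueError(f"{path}: duplicate FASTA header {name!r}")
        seen.add(name)
        seq = str(record.seq).upper()
        if not seq:
            raise ValueError(f"{path}: empty FASTA record {name!r}")
        bad = set(seq) - _FASTA_ALPHABET
        if bad:
            raise ValueError(
                f"{path}: record {name!r} contains non-ACGTN characters "
                f"{sorted(bad)}"
            )
        contigs.append((name, seq))
    if not contigs:
        raise ValueError(f"{path}: no FASTA records found")
    return GenomeAssembly(contigs)


def write_fasta(genome: GenomeAssembly, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_bed(path: str | Path, genome: GenomeAssembly | None = None
             ) -> FeatureCatalogue:
    """Read BED3/BED6 features (0-based half-open).

    The name field encodes ``feature_class:name``; 3-column records default
    to class ``other``. Records with start >= end, or on contigs absent from
    an attached genome, are rejected.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            if genome is not None:
                lengths = genome.contig_lengths
                if chrom not in lengths:
                    raise ValueError(f"{path}:{lineno}: unknown contig {chrom!r}")
                if end > lengths[chrom]:
                    raise ValueError(f"{path}:{lineno}: interval exceeds contig")
            raw_name = parts[3] if len(parts) > 3 else f"feature{lineno}"
            if ":" in raw_name:
                feature_class, name = raw_name.split(":", 1)
            else:
                feature_class, name = "other", raw_name
            strand = parts[5] if len(parts) > 5 else "."
            rows.append(dict(chrom=chrom, start=start, end=end, strand=strand,
                             feature_class=feature_class, name=name))
    return FeatureCatalogue(pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "feature_class",
                       "name"]
    ))


def write_bed(catalogue: FeatureCatalogue, path: str | Path) -> None:
    with open(path, "w") as fh:
        for _, r in catalogue.frame.iterrows():
            fh.write(
                f"{r['chrom']}\t{r['start']}\t{r['end']}\t"
                f"{r['feature_class']}:{r['name']}\t0\t{r['strand']}\n"
            )


def write_table(frame: pd.DataFrame, path: str | Path,
                params: dict | None = None, index: bool = False) -> None:
    """Write a TSV with ``#``-prefixed parameter header lines."""
    with open(path, "w") as fh:
        for key in sorted(params or {}):
            fh.write(f"# {key}={params[key]}\n")
        frame.to_csv(fh, sep="\t", index=index, float_format="%.17g")


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_counts(long_counts: pd.DataFrame, path: str | Path,
                 params: dict | None = None) -> None:
    write_table(long_counts[COUNT_COLUMNS], path, params=params)


def read_counts(path: str | Path) -> pd.DataFrame:
    frame = read_table(path)
    missing = [c for c in COUNT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: count table missing columns {missing}")
    if ((frame["meth"] < 0) | (frame["meth"] > frame["total"])).any():
        raise ValueError(f"{path}: counts violate 0 <= meth <= total")
    return frame[COUNT_COLUMNS]


def read_counts_bedgraph(path: str | Path, sample: str) -> pd.DataFrame:
    """Shim for 6-column ``chrom start end level meth unmeth`` dialects."""
    frame = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "level", "meth", "unmeth"],
    )
    out = pd.DataFrame({
        "chrom": frame["chrom"],
        "pos": frame["start"].astype(int),
        "sample": sample,
        "meth": frame["meth"].astype(int),
        "total": (frame["meth"] + frame["unmeth"]).astype(int),
    })
    return out


def write_state_map(state_map: pd.DataFrame, path: str | Path) -> None:
    long = state_map.stack().reset_index()
    long.columns = ["chrom", "pos", "cell_type", "m_true"]
    write_table(long, path)


def read_state_map(path: str | Path) -> pd.DataFrame:
    long = read_table(path)
    wide = long.pivot(index=["chrom", "pos"], columns="cell_type",
                      values="m_true")
    wide.columns.name = None
    return wide


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PipelineConfig:
    """All pipeline parameters; defaults follow the printed analysis values.

    ``delta_threshold`` is a Fraction so the printed ">33.3%" effect cutoff
    can be represented exactly as one third; it serialises as ``"1/3"``.
    """

    seed: int = 0
    # simulator
    n_contigs: int = 2
    contig_length: int = 250_000
    n_promoters: int = 40
    n_repeats: int = 60
    n_imprinted_clusters: int = 4
    cpg_island_fraction: float = 0.5
    cell_types: tuple[str, ...] = ("ESC-like", "C-like", "4F-like")
    n_replicates: int = 2
    mean_coverage: float = 30.0
    conversion_efficiency: float = 0.995
    replicate_dispersion: float = 0.05
    # thresholds
    min_cov: int = 10
    delta_threshold: Fraction = Fraction(1, 3)
    p_threshold: float = 0.05
    low_cut: float = 0.3
    high_cut: float = 0.8
    size_min: int = 170
    size_max: int = 370
    promoter_flank: int = 1000
    window: int = 500
    step: int = 5
    oe_high: float = 0.75
    oe_low: float = 0.48
    gc_min: float = 0.55
    max_gap: int = 300
    min_cpgs: int = 3
    k: int = 3

    def thresholds(self) -> dict:
        keys = ["min_cov", "delta_threshold", "p_threshold", "low_cut",
                "high_cut", "size_min", "size_max", "promoter_flank",
                "window", "step", "oe_high", "oe_low", "gc_min", "max_gap",
                "min_cpgs", "k"]
        return {k: getattr(self, k) for k in keys}

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["delta_threshold"] = str(self.delta_threshold)
        data["cell_types"] = list(self.cell_types)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a config file; every field must be present (no silent
        defaulting), so an incomplete file is refused before any compute."""
        with open(path) as fh:
            data = yaml.safe_load(fh)
        fields = {f.name for f in dataclasses.fields(cls)}
        missing = sorted(fields - set(data))
        if missing:
            raise ValueError(f"{path}: config missing required keys {missing}")
        extra = sorted(set(data) - fields)
        if extra:
            raise ValueError(f"{path}: unknown config keys {extra}")
        raw = data["delta_threshold"]
        if isinstance(raw, str) and "/" in raw:
            num, den = raw.split("/")
            data["delta_threshold"] = Fraction(int(num), int(den))
        else:
            data["delta_threshold"] = Fraction(raw).limit_denominator(10**9)
        data["cell_types"] = tuple(data["cell_types"])
        return cls(**data)
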