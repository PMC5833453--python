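import numpy as np
import pandas as pd
import pytest

from rrbsdiff import annotate as ann
from rrbsdiff import meth_quant as mq
from rrbsdiff.synth_genome import FeatureCatalogue, GenomeAssembly

from oracles import window_class, window_max_oe


def tss_table(rows):
    return pd.DataFrame(rows, columns=["gene", "chrom", "pos", "strand"])


class TestDefinePromoters:
    def test_symmetric_flank(self):
        recs = ann.define_promoters(
            tss_table([("g", "c1", 5000, "+")]), {"c1": 10_000})
        assert (recs[0].start, recs[0].end) == (4000, 6000)

    def test_clipped_at_contig_start(self):
        recs = ann.define_promoters(
            tss_table([("g", "c1", 500, "-")]), {"c1": 10_000})
        assert (recs[0].start, recs[0].end) == (0, 1500)

    def test_order_preserving(self):
        rows = [(f"g{i}", "c1", 2000 + i * 100, "+") for i in range(5)]
        recs = ann.define_promoters(tss_table(rows), {"c1": 10_000})
        assert [r.gene for r in recs] == [f"g{i}" for i in range(5)]

    def test_tss_outside_contig_rejected(self):
        with pytest.raises(ValueError):
            ann.define_promoters(tss_table([("g", "c1", 10_000, "+")]),
                                 {"c1": 10_000})


class TestCpgDensityClass:
    def _record(self, start, end, chrom="c1"):
        return ann.PromoterRecord(gene="g", chrom=chrom, tss=(start + end) // 2,
                                  strand="+", start=start, end=end)

    def test_cg_repeat_window_is_hcp(self):
        # ("CG" * 250): N_CpG=250, N_C=N_G=250, O/E = 250*500/250^2 = 2.0
        genome = GenomeAssembly([("c1", "CG" * 1000)])
        rec = ann.classify_promoter_cpg_density(self._record(0, 2000), genome)
        assert rec.cpg_class == "HCP"
        assert rec.best_window[2] == pytest.approx(2.0)

    def test_all_a_promoter_is_lcp(self):
        genome = GenomeAssembly([("c1", "A" * 2000)])
        rec = ann.classify_promoter_cpg_density(self._record(0, 2000), genome)
        assert rec.cpg_class == "LCP"
        assert rec.best_window[2] == 0.0

    def test_short_promoter_uses_whole_interval(self):
        genome = GenomeAssembly([("c1", "CG" * 150)])
        rec = ann.classify_promoter_cpg_density(self._record(0, 300), genome)
        assert rec.cpg_class == "HCP"

    def test_step_one_equals_exhaustive_oracle(self, small_genome):
        """At step=1 the implementation must agree with the brute-force
        every-offset window scan on every generated promoter."""
        genome, catalogue = small_genome
        promoters = catalogue.by_class("promoter")
        for _, p in promoters.iterrows():
            rec = self._record(p["start"], p["end"], p["chrom"])
            got = ann.classify_promoter_cpg_density(rec, genome, step=1)
            seq = genome.sequence(p["chrom"])[p["start"]:p["end"]]
            assert got.cpg_class == window_class(seq)

    def test_default_step_is_conservative_subset_of_oracle(self, small_genome):
        """Scanning every 5th offset sees a subset of the step=1 windows, so
        it can only miss enrichment, never invent it: a step-5 HCP is an
        oracle HCP, an oracle LCP is a step-5 LCP, and away from the O/E
        thresholds (margin > 0.05) the classes agree exactly."""
        genome, catalogue = small_genome
        promoters = catalogue.by_class("promoter")
        for _, p in promoters.iterrows():
            rec = self._record(p["start"], p["end"], p["chrom"])
            got = ann.classify_promoter_cpg_density(rec, genome, step=5)
            seq = genome.sequence(p["chrom"])[p["start"]:p["end"]]
            oracle_cls = window_class(seq)
            if got.cpg_class == "HCP":
                assert oracle_cls == "HCP"
            if oracle_cls == "LCP":
                assert got.cpg_class == "LCP"
            max_oe = window_max_oe(seq)
            if min(abs(max_oe - 0.48), abs(max_oe - 0.75)) > 0.05:
                assert got.cpg_class == oracle_cls


def _toy_catalogue():
    rows = [
        ("c1", 1000, 3000, "+", "promoter", "gA"),
        ("c1", 2000, 2300, "+", "exon", "gA.ex1"),
        ("c1", 2300, 3500, "+", "intron", "gA.in1"),
        ("c1", 5000, 5600, ".", "repeat_LINE", "L1"),
        ("c1", 7000, 9000, ".", "imprinted_cluster", "icr"),
        ("c1", 7500, 8000, ".", "gDMR", "icr.g"),
    ]
    return FeatureCatalogue(pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "feature_class",
                       "name"]))


class TestGenomicLocation:
    def test_promoter_beats_exon(self):
        sites = pd.DataFrame({"chrom": ["c1"], "pos": [2100]})
        out = ann.assign_genomic_location(sites, _toy_catalogue())
        assert out["location"].iloc[0] == "promoter"

    def test_intergenic_when_nothing_overlaps(self):
        sites = pd.DataFrame({"chrom": ["c1"], "pos": [4000]})
        out = ann.assign_genomic_location(sites, _toy_catalogue())
        assert out["location"].iloc[0] == "intergenic"
        assert out["flags"].iloc[0] == ""

    def test_flags_reported_separately(self):
        sites = pd.DataFrame({"chrom": ["c1"], "pos": [7700]})
        out = ann.assign_genomic_location(sites, _toy_catalogue())
        assert out["location"].iloc[0] == "intergenic"
        assert "imprinted_cluster:icr" in out["flags"].iloc[0]
        assert "gDMR:icr.g" in out["flags"].iloc[0]

    def test_labels_partition_and_match_scan_oracle(self):
        cat = _toy_catalogue()
        rng = np.random.default_rng(51)
        positions = rng.integers(0, 10_000, size=300)
        sites = pd.DataFrame({"chrom": "c1", "pos": positions})
        out = ann.assign_genomic_location(sites, cat)
        assert set(out["location"]) <= {"promoter", "exon", "intron",
                                        "intergenic"}
        frame = cat.frame
        for _, row in out.iterrows():
            pos = row["pos"]
            hit = frame[(frame["start"] <= pos) & (pos < frame["end"])]
            classes = set(hit["feature_class"])
            expected = next(
                (c for c in ("promoter", "exon", "intron") if c in classes),
                "intergenic")
            assert row["location"] == expected


class TestAnnotateDmrs:
    def test_one_bp_overlap_suffices(self):
        dmrs = pd.DataFrame({"chrom": ["c1"], "start": [100], "end": [200]})
        cat = FeatureCatalogue(pd.DataFrame(
            [("c1", 199, 400, "+", "promoter", "g")],
            columns=["chrom", "start", "end", "strand", "feature_class",
                     "name"]))
        out = ann.annotate_dmrs(dmrs, cat)
        assert out["promoter_dmr"].iloc[0]

    def test_imprinted_but_not_gdmr(self):
        """A DMR inside a cluster that misses the cluster's gDMR is labelled
        imprinted but not gDMR-overlapping."""
        dmrs = pd.DataFrame({"chrom": ["c1"], "start": [8200], "end": [8500]})
        out = ann.annotate_dmrs(dmrs, _toy_catalogue())
        assert out["imprinted_dmr"].iloc[0]
        assert not out["gdmr_overlap"].iloc[0]

    def test_labels_match_intersection_oracle(self):
        cat = _toy_catalogue()
        rng = np.random.default_rng(61)
        starts = rng.integers(0, 9_500, size=100)
        dmrs = pd.DataFrame({"chrom": "c1", "start": starts,
                             "end": starts + rng.integers(50, 500, size=100)})
        out = ann.annotate_dmrs(dmrs, cat)
        frame = cat.frame
        mapping = {"promoter_dmr": {"promoter"},
                   "imprinted_dmr": {"imprinted_cluster"},
                   "gdmr_overlap": {"gDMR"},
                   "repeat_overlap": {"repeat_LINE", "repeat_SINE",
                                      "repeat_LTR"}}
        for _, row in out.iterrows():
            hit = frame[(frame["start"] < row["end"])
                        & (frame["end"] > row["start"])]
            classes = set(hit["feature_class"])
            for label, wanted in mapping.items():
                assert row[label] == bool(classes & wanted)

    def test_monotone_under_extension(self):
        cat = _toy_catalogue()
        base = pd.DataFrame({"chrom": ["c1"], "start": [4500], "end": [4800]})
        grown = pd.DataFrame({"chrom": ["c1"], "start": [4500], "end": [5200]})
        flags = ["promoter_dmr", "imprinted_dmr", "gdmr_overlap",
                 "repeat_overlap"]
        small = ann.annotate_dmrs(base, cat)[flags].iloc[0]
        big = ann.annotate_dmrs(grown, cat)[flags].iloc[0]
        assert all(big[f] or not small[f] for f in flags)
        assert big["repeat_overlap"] and not small["repeat_overlap"]


class TestRegionRestrictedSummary:
    def test_empty_class_gives_zero_count(self, small_gated, small_genome):
        _, catalogue = small_genome
        trimmed = FeatureCatalogue(
            catalogue.frame[catalogue.frame["feature_class"] != "gDMR"]
            .assign(dummy=1).drop(columns="dummy"))
        out = ann.region_restricted_summary(small_gated, trimmed, "gDMR")
        assert out["n_cpgs"] == 0

    def test_complement_partitions_gated_universe(self, small_gated,
                                                  small_genome):
        _, catalogue = small_genome
        named = [c for c in
                 ("promoter", "exon", "intron", "repeat_LINE", "repeat_SINE",
                  "repeat_LTR", "imprinted_cluster", "gDMR")]
        other = ann.region_restricted_summary(small_gated, catalogue, "other")
        # union of named classes (NOT the sum: classes can nest/overlap)
        chroms = small_gated.index.get_level_values("chrom").to_numpy()
        positions = small_gated.index.get_level_values("pos").to_numpy()
        in_named = np.zeros(len(small_gated), dtype=bool)
        for chrom in np.unique(chroms):
            mask = chroms == chrom
            for cls in named:
                in_named[mask] |= catalogue.interval_set(
                    cls, chrom).contains(positions[mask])
        assert other["n_cpgs"] == int((~in_named).sum())
        assert other["n_cpgs"] + int(in_named.sum()) == len(small_gated)

    def test_repeat_hypermethylation_ordering(self, small_gated, small_genome):
        """In repeats the 4F-like archetype shows a larger high-methylation
        fraction than ESC-like (per-compartment histogram contrast)."""
        _, catalogue = small_genome
        out = ann.region_restricted_summary(small_gated, catalogue,
                                            "repeat_LINE")
        frac = out["category_fractions"]
        assert float(frac.loc["4F-like", "high"]) > \
            float(frac.loc["ESC-like", "high"])

    def test_unknown_class_rejected(self, small_gated, small_genome):
        _, catalogue = small_genome
        with pytest.raises(ValueError):
            ann.region_restricted_summary(small_gated, catalogue, "enhancer")
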