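"""Priority annotation, length bins, composition, TSS windows, enrichment."""

import math
import random

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from capscape.annot import (
    LENGTH_BINS,
    PRIORITY,
    AnnotationFeature,
    annotate_tags,
    build_feature_index,
    cluster_and_enrich,
    composition_table,
    length_bin,
    read_features_bed,
    read_features_gff3,
    resolve_annotation,
    site_window_profile,
    write_features_bed,
)
from capscape.reads import Tag, TagAlignment


def _aln(chrom, start, end, strand="+", name="t", length=None, lib="lib", unique=True):
    tag = Tag(name, "", inferred_length=length if length is not None else end - start,
              library_id=lib)
    return TagAlignment(tag, chrom, start, end, strand, unique)


def _feat(start, end, biotype, strand="+", chrom="chr1", name=""):
    return AnnotationFeature(chrom, start, end, strand, biotype, name or biotype)


class TestResolveAnnotation:
    def test_snorna_beats_exon(self):
        index = build_feature_index([_feat(0, 100, "exon"), _feat(50, 80, "snoRNA")])
        assert resolve_annotation(_aln("chr1", 60, 75), index) == "snoRNA"

    def test_no_overlap_is_unknown(self):
        index = build_feature_index([_feat(0, 100, "exon")])
        assert resolve_annotation(_aln("chr1", 200, 220), index) == "unknown"
        assert resolve_annotation(_aln("chrX", 10, 20), index) == "unknown"

    def test_trna_tops_priority(self):
        index = build_feature_index(
            [_feat(0, 100, "intron"), _feat(0, 100, "exon"), _feat(0, 100, "tRNA")]
        )
        assert resolve_annotation(_aln("chr1", 10, 30), index) == "tRNA"

    def test_strand_awareness(self):
        index = build_feature_index([_feat(0, 100, "miRNA", strand="+")])
        antisense = _aln("chr1", 10, 30, strand="-")
        assert resolve_annotation(antisense, index) == "unknown"
        assert resolve_annotation(antisense, index, ignore_strand=True) == "miRNA"

    def test_one_nt_overlap_counts(self):
        index = build_feature_index([_feat(100, 200, "miRNA")])
        assert resolve_annotation(_aln("chr1", 99, 101), index) == "miRNA"
        assert resolve_annotation(_aln("chr1", 90, 100), index) == "unknown"

    def test_agrees_with_brute_force_scan(self):
        rnd = random.Random(7)
        biotypes = PRIORITY[1:]
        features = [
            _feat(s := rnd.randrange(0, 5000), s + rnd.randrange(20, 200),
                  rnd.choice(biotypes), rnd.choice("+-"))
            for _ in range(500)
        ]
        index = build_feature_index(features)
        rank = {b: i for i, b in enumerate(PRIORITY)}
        for _ in range(200):
            start = rnd.randrange(0, 5200)
            aln = _aln("chr1", start, start + rnd.randrange(15, 100), rnd.choice("+-"))
            brute = "unknown"
            for f in features:
                if (f.start < aln.end and aln.start < f.end and f.strand == aln.strand
                        and rank[f.biotype] > rank[brute]):
                    brute = f.biotype
            assert resolve_annotation(aln, index) == brute


class TestLengthBin:
    @pytest.mark.parametrize(
        "length, expected",
        [(0, "0-18"), (18, "0-18"), (19, "19-29"), (27, "19-29"), (29, "19-29"),
         (30, "30-50"), (50, "30-50"), (51, "51-100"), (100, "51-100"),
         (101, "101-200"), (200, "101-200"), (201, ">200"), (None, "unmeasured")],
    )
    def test_bin_assignment(self, length, expected):
        assert length_bin(length) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            length_bin(-1)

    @given(length=st.integers(0, 200))
    def test_bins_partition(self, length):
        hits = [lab for lab, lo, hi in LENGTH_BINS if lo <= length <= hi]
        assert len(hits) == 1 and length_bin(length) == hits[0]


class TestComposition:
    def test_planted_mixture_recovered_exactly(self):
        feats = [_feat(0, 1000, "miRNA"), _feat(2000, 3000, "exon")]
        alns = [_aln("chr1", 10, 32, name=f"m{i}", length=22) for i in range(60)]
        alns += [_aln("chr1", 2010, 2032, name=f"e{i}", length=22) for i in range(40)]
        table = composition_table(annotate_tags(alns, feats), group_by=("length_bin",))
        row = table[(table.length_bin == "19-29") & (table.biotype == "miRNA")]
        assert row["fraction"].iloc[0] == pytest.approx(0.60)

    def test_fractions_sum_to_one_per_group(self, sim_small):
        from capscape.reads import clip_adapter, toy_align
        from capscape.simulate import gen_library

        config, sim = sim_small
        reads, _ = gen_library(config, "capped_sRNA", sim)
        tags = [clip_adapter(r.sequence, config.adapter, 8, r.read_id, "capped", "capped_sRNA")
                for r in reads[:400]]
        alns = toy_align(tags, sim.genome)
        table = composition_table(annotate_tags(alns, sim.features))
        sums = table.groupby(["library", "length_bin"], observed=True)["fraction"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_empty_input(self):
        assert composition_table([]).empty

    def test_all_unknown_single_row(self):
        alns = [_aln("chr1", i * 100, i * 100 + 20, name=f"t{i}") for i in range(5)]
        table = composition_table(annotate_tags(alns, []), group_by=("library",))
        assert list(table.biotype) == ["unknown"]
        assert table["fraction"].iloc[0] == 1.0

    def test_multimappers_excluded_by_default(self):
        alns = [_aln("chr1", 0, 20, unique=False), _aln("chr1", 30, 50)]
        assert len(annotate_tags(alns, [])) == 1
        assert len(annotate_tags(alns, [], unique_only=False)) == 2


class TestSiteWindowProfile:
    def test_reads_planted_in_windows(self):
        sites = [("chr1", 500, "+"), ("chr1", 1500, "+")]
        alns = [_aln("chr1", 480 + i, 500 + i, name=f"a{i}") for i in range(20)]
        table, frac = site_window_profile(alns, sites, window=100)
        assert frac == 1.0
        assert table["count"].tolist() == [20, 0]

    def test_no_sites(self):
        table, frac = site_window_profile([_aln("chr1", 0, 20)], [], window=100)
        assert table.empty and frac == 0.0

    def test_read_exactly_at_site_counted_once_per_window(self):
        # window is [site-50, site+50): a 5' end on the site is inside
        aln = _aln("chr1", 1000, 1020)
        table, frac = site_window_profile([aln], [("chr1", 1000, "+"), ("chr1", 1050, "+")], 100)
        assert table["count"].tolist() == [1, 1] and frac == 1.0
        # boundary: 5' end at site+50 is outside
        table2, _ = site_window_profile([aln], [("chr1", 950, "+")], 100)
        assert table2["count"].tolist() == [0]

    def test_minus_strand_five_prime_is_end(self):
        aln = _aln("chr1", 900, 1001, strand="-")
        table, _ = site_window_profile([aln], [("chr1", 1000, "-")], 100)
        assert table["count"].tolist() == [1]

    def test_nonpositive_window_rejected(self):
        with pytest.raises(ValueError):
            site_window_profile([], [], window=0)


class TestClusterEnrichment:
    def _libs(self):
        t = [_aln("chr1", 100, 130, name=f"t{i}", lib="T") for i in range(10)]
        t += [_aln("chr1", 5000, 5030, name="t_bg", lib="T")]
        c = [_aln("chr1", 105, 135, name="c0", lib="C")]
        c += [_aln("chr1", 5000, 5030, name=f"c{i}", lib="C") for i in range(10)]
        return {"T": t, "C": c}

    def test_fold_change_formula(self):
        libs = self._libs()
        clusters = cluster_and_enrich(libs, ["T"], ["C"], pseudocount=1.0)
        clus = {(c.chrom, c.start): c for c in clusters}
        c1 = clus[("chr1", 100)]
        cpm_t = 10 / 11 * 1e6
        cpm_c = 1 / 11 * 1e6
        assert c1.fold_change_log2 == pytest.approx(math.log2((cpm_t + 1) / (cpm_c + 1)))
        assert c1.mean_expression == pytest.approx((cpm_t + cpm_c) / 2)

    def test_antisymmetry_under_swap(self):
        libs = self._libs()
        fwd = cluster_and_enrich(libs, ["T"], ["C"])
        rev = cluster_and_enrich(libs, ["C"], ["T"])
        for a, b in zip(fwd, rev):
            assert a.fold_change_log2 == pytest.approx(-b.fold_change_log2, abs=1e-12)

    def test_identical_libraries_zero_fold_change(self):
        base = [_aln("chr1", 100, 130, name=f"x{i}") for i in range(5)]
        clusters = cluster_and_enrich({"A": base, "B": list(base)}, ["A"], ["B"])
        assert all(c.fold_change_log2 == 0.0 for c in clusters)

    def test_clusters_are_maximal_overlap_runs(self):
        libs = {
            "A": [_aln("chr1", 0, 30), _aln("chr1", 20, 50), _aln("chr1", 100, 120)],
            "B": [_aln("chr1", 40, 60)],
        }
        clusters = cluster_and_enrich(libs, ["A"], ["B"])
        assert sorted((c.start, c.end) for c in clusters) == [(0, 60), (100, 120)]

    def test_requires_both_arms(self):
        with pytest.raises(ValueError):
            cluster_and_enrich({"A": [_aln("chr1", 0, 10)]}, ["A"], [])

    def test_planted_snrna_enrichment_ranks_top_decile(self, sim_small):
        """snRNA fragments planted 10x enriched in IP libraries dominate the
        top decile of fold changes among expressed clusters (singleton
        clusters, whose fold change is dominated by the pseudocount, are
        excluded by a minimum mean-expression filter)."""
        from capscape.reads import clip_adapter, toy_align
        from capscape.simulate import gen_library

        config, sim = sim_small
        libs = {}
        for lib_type in ("IP_K121", "IP_control"):
            reads, _ = gen_library(config, lib_type, sim)
            tags = [clip_adapter(r.sequence, config.adapter, 8, r.read_id, lib_type, lib_type)
                    for r in reads]
            libs[lib_type] = toy_align(tags, sim.genome)
        clusters = cluster_and_enrich(libs, ["IP_K121"], ["IP_control"])
        snrna_ivs = [(f.start, f.end) for f in sim.features if f.biotype == "snRNA"]
        expressed = [c for c in clusters if c.mean_expression >= 5000]  # >= ~3 tags/library
        fcs = np.array([c.fold_change_log2 for c in expressed])
        decile = np.quantile(fcs, 0.9)
        top = [c for c in expressed if c.fold_change_log2 >= decile]
        in_snrna = [
            c for c in top
            if any(c.start < e and s < c.end for s, e in snrna_ivs)
        ]
        assert len(in_snrna) / len(top) >= 0.8


class TestFeatureIO:
    def test_bed_round_trip(self, tmp_path):
        feats = [_feat(10, 60, "tRNA", name="tRNA-1"), _feat(100, 200, "snoRNA", "-")]
        path = tmp_path / "f.bed"
        write_features_bed(feats, path)
        assert read_features_bed(path) == feats

    def test_gff3_biotype_from_type_column(self, tmp_path):
        path = tmp_path / "f.gff3"
        path.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tmiRNA\t11\t60\t.\t+\t.\tID=mir1;Name=mir-1\n"
            "chr1\tsrc\tgene\t100\t200\t.\t-\t.\tID=g1;biotype=snRNA\n"
        )
        feats = read_features_gff3(path)
        assert feats[0] == AnnotationFeature("chr1", 10, 60, "+", "miRNA", "mir-1")
        assert feats[1].biotype == "snRNA" and feats[1].start == 99

    def test_invalid_biotype_rejected(self):
        with pytest.raises(ValueError):
            _feat(0, 10, "lincRNA")
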