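"""Hierarchical biotype annotation, length binning and cluster enrichment.

A tag overlapping several genomic features is labelled with the
highest-priority biotype, the priority running (low to high): unknown,
intron, exon, miRNA, snRNA, snoRNA, tRNA.  Length composition uses size
bins matched to small-RNA biotype classes (tiRNAs, miRNAs, TASRs/PASRs,
tRNAs, snRNA/snoRNAs).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .reads import TagAlignment

__all__ = [
    "PRIORITY",
    "LENGTH_BINS",
    "AnnotationFeature",
    "AnnotatedTag",
    "TagCluster",
    "build_feature_index",
    "resolve_annotation",
    "length_bin",
    "annotate_tags",
    "composition_table",
    "site_window_profile",
    "cluster_and_enrich",
    "read_features_bed",
    "read_features_gff3",
    "write_features_bed",
]

#: Biotype priority, lowest to highest.  A tag overlapping both an exon and
#: a tRNA is a tRNA tag.
PRIORITY = ("unknown", "intron", "exon", "miRNA", "snRNA", "snoRNA", "tRNA")
_RANK = {b: i for i, b in enumerate(PRIORITY)}

#: Inclusive length bins (label, lo, hi).  The upper two classes abut at
#: 100/101 so the bins partition every length.
LENGTH_BINS = (
    ("0-18", 0, 18),
    ("19-29", 19, 29),
    ("30-50", 30, 50),
    ("51-100", 51, 100),
    ("101-200", 101, 200),
)
UNMEASURED_BIN = "unmeasured"
OVERLONG_BIN = ">200"


@dataclass(frozen=True)
class AnnotationFeature:
    """One annotated genomic feature; 0-based half-open, stranded."""

    chrom: str
    start: int
    end: int
    strand: str
    biotype: str
    name: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"feature {self.name!r}: start {self.start} >= end {self.end}")
        if self.biotype not in _RANK or self.biotype == "unknown":
            raise ValueError(f"biotype {self.biotype!r} not in {PRIORITY[1:]}")


@dataclass(frozen=True)
class AnnotatedTag:
    alignment: TagAlignment
    biotype: str
    length_bin: str


@dataclass(frozen=True)
class TagCluster:
    """A maximal run of overlapping tag intervals with per-library expression."""

    chrom: str
    start: int
    end: int
    cpm: Mapping[str, float]
    fold_change_log2: float
    mean_expression: float


def build_feature_index(features: Iterable[AnnotationFeature]) -> dict[str, IntervalTree]:
    """Chromosome -> interval tree of features, for overlap queries."""
    index: dict[str, IntervalTree] = {}
    for f in features:
        index.setdefault(f.chrom, IntervalTree()).addi(f.start, f.end, f)
    return index


def resolve_annotation(
    alignment: TagAlignment,
    index: Mapping[str, IntervalTree],
    ignore_strand: bool = False,
) -> str:
    """Highest-priority biotype among features overlapping by >= 1 nt.

    Strand-aware by default (an antisense tag does not inherit a sense
    feature's annotation); returns ``"unknown"`` with no overlap.
    """
    tree = index.get(alignment.chrom)
    if tree is None:
        return "unknown"
    best = "unknown"
    for iv in tree.overlap(alignment.start, alignment.end):
        f: AnnotationFeature = iv.data
        if not ignore_strand and f.strand != alignment.strand:
            continue
        if _RANK[f.biotype] > _RANK[best]:
            best = f.biotype
    return best


def length_bin(inferred_length: int | None) -> str:
    """Map an inferred insert length to its size-class bin.

    ``None`` (no adapter found, length not measurable) gets its own class,
    as do lengths beyond 200 nt.
    """
    if inferred_length is None:
        return UNMEASURED_BIN
    if inferred_length < 0:
        raise ValueError("negative length")
    for label, lo, hi in LENGTH_BINS:
        if lo <= inferred_length <= hi:
            return label
    return OVERLONG_BIN


def annotate_tags(
    alignments: Iterable[TagAlignment],
    features: Iterable[AnnotationFeature],
    ignore_strand: bool = False,
    unique_only: bool = True,
) -> list[AnnotatedTag]:
    """Resolve biotype and length bin for each alignment.

    Multi-mapping tags are excluded by default (``unique_only``); pass
    ``False`` to annotate every hit.
    """
    index = build_feature_index(features)
    out = []
    for aln in alignments:
        if unique_only and not aln.unique:
            continue
        out.append(
            AnnotatedTag(
                aln,
                resolve_annotation(aln, index, ignore_strand),
                length_bin(aln.tag.inferred_length),
            )
        )
    return out


def composition_table(
    annotated: Sequence[AnnotatedTag],
    group_by: Sequence[str] = ("library", "length_bin"),
) -> pd.DataFrame:
    """Per-group biotype counts and fractions (fractions sum to 1 per group).

    ``group_by`` may contain ``"library"`` and/or ``"length_bin"``.
    """
    if not annotated:
        return pd.DataFrame(columns=[*group_by, "biotype", "count", "fraction"])
    df = pd.DataFrame(
        {
            "library": t.alignment.tag.library_id,
            "length_bin": t.length_bin,
            "biotype": t.biotype,
        }
        for t in annotated
    )
    keys = list(group_by)
    counts = df.groupby([*keys, "biotype"], observed=True).size().rename("count").reset_index()
    totals = counts.groupby(keys, observed=True)["count"].transform("sum")
    counts["fraction"] = counts["count"] / totals
    return counts


def site_window_profile(
    alignments: Sequence[TagAlignment],
    sites: Sequence[tuple[str, int, str]],
    window: int = 100,
) -> tuple[pd.DataFrame, float]:
    """Count tag 5' ends in fixed windows centred on sites (TSS or TTS).

    Each site is ``(chrom, position, strand)``; its window is the half-open
    interval ``[position - window//2, position + window//2)``.  Returns the
    per-site counts and the fraction of all alignments whose 5' end falls in
    at least one window.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    half = window // 2
    rows = []
    covered = set()
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for i, a in enumerate(alignments):
        by_chrom.setdefault(a.chrom, []).append((a.five_prime, i))
    for chrom, pos, strand in sites:
        lo, hi = pos - half, pos + half
        count = 0
        for p, i in by_chrom.get(chrom, ()):
            if lo <= p < hi:
                count += 1
                covered.add(i)
        rows.append({"chrom": chrom, "position": pos, "strand": strand, "count": count})
    frac = len(covered) / len(alignments) if alignments else 0.0
    return pd.DataFrame(rows, columns=["chrom", "position", "strand", "count"]), frac


def _merge_intervals(intervals: Sequence[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    """Single-linkage merge of overlapping intervals, per chromosome."""
    merged: list[tuple[str, int, int]] = []
    for chrom in sorted({c for c, _, _ in intervals}):
        rows = sorted((s, e) for c, s, e in intervals if c == chrom)
        cur_s, cur_e = rows[0]
        for s, e in rows[1:]:
            if s < cur_e:  # overlap (half-open)
                cur_e = max(cur_e, e)
            else:
                merged.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((chrom, cur_s, cur_e))
    return merged


def cluster_and_enrich(
    alignments_by_library: Mapping[str, Sequence[TagAlignment]],
    treatment_ids: Sequence[str],
    control_ids: Sequence[str],
    pseudocount: float = 1.0,
) -> list[TagCluster]:
    """Cluster overlapping tags across libraries and score enrichment.

    Clusters are maximal sets of overlapping tag intervals pooled over all
    libraries (strand-blind).  Per-library counts are normalised to counts
    per million aligned tags; the fold change is
    ``log2((mean treatment CPM + p) / (mean control CPM + p))`` and
    ``mean_expression`` averages CPM over every library.
    """
    if not treatment_ids or not control_ids:
        raise ValueError("need at least one treatment and one control library")
    libs = list(alignments_by_library)
    all_ivs = [
        (a.chrom, a.start, a.end)
        for alns in alignments_by_library.values()
        for a in alns
    ]
    if not all_ivs:
        raise ValueError("no alignments in any library")
    clusters = _merge_intervals(all_ivs)
    index: dict[str, IntervalTree] = {}
    for ci, (chrom, s, e) in enumerate(clusters):
        index.setdefault(chrom, IntervalTree()).addi(s, e, ci)
    counts = np.zeros((len(clusters), len(libs)))
    totals = np.array([max(len(alignments_by_library[l]), 1) for l in libs], dtype=float)
    for li, lib in enumerate(libs):
        for a in alignments_by_library[lib]:
            hits = index.get(a.chrom, IntervalTree()).overlap(a.start, a.end)
            for iv in hits:  # by construction each tag is inside exactly one cluster
                counts[iv.data, li] += 1
    cpm = counts / totals[None, :] * 1e6
    t_idx = [libs.index(l) for l in treatment_ids]
    c_idx = [libs.index(l) for l in control_ids]
    out = []
    for ci, (chrom, s, e) in enumerate(clusters):
        t_mean = cpm[ci, t_idx].mean()
        c_mean = cpm[ci, c_idx].mean()
        out.append(
            TagCluster(
                chrom,
                s,
                e,
                {lib: cpm[ci, li] for li, lib in enumerate(libs)},
                float(np.log2((t_mean + pseudocount) / (c_mean + pseudocount))),
                float(cpm[ci].mean()),
            )
        )
    return out


# --- feature IO --------------------------------------------------------------


def read_features_bed(path) -> list[AnnotationFeature]:
    """Read features from 6-column BED; the name column carries the biotype,
    either bare (``tRNA``) or prefixed (``tRNA:tRNA-Glu-7``)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, name, _score, strand = line.split("\t")[:6]
            biotype, _, fname = name.partition(":")
            out.append(AnnotationFeature(chrom, int(start), int(end), strand, biotype, fname or name))
    return out


def read_features_gff3(path) -> list[AnnotationFeature]:
    """Read features from GFF3; the type column (or a ``biotype`` attribute)
    is the biotype.  Coordinates convert from 1-based closed to 0-based
    half-open."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                continue
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = cols[:9]
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            biotype = attr.get("biotype", ftype)
            name = attr.get("Name", attr.get("ID", ""))
            out.append(
                AnnotationFeature(chrom, int(start) - 1, int(end), strand, biotype, name)
            )
    return out


def write_features_bed(features: Iterable[AnnotationFeature], path) -> int:
    n = 0
    with open(path, "w") as fh:
        for f in features:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.biotype}:{f.name}\t0\t{f.strand}\n")
            n += 1
    return n
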