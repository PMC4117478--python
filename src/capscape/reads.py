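"""Adapter clipping, insert-length inference, rRNA dusting and toy alignment.

Small-RNA libraries carry a fixed 3' adapter; when at least ``min_match``
adapter bases are found in a read, the bases before the match are the RNA
insert and its length is known exactly.  With 100-nt reads and an 8-base
minimum match, inserts of 0-92 nt are measurable; longer RNAs yield full
100-nt tags of unmeasured length.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "DEFAULT_ADAPTER",
    "Tag",
    "TagAlignment",
    "clip_adapter",
    "clip_fastq",
    "rrna_filter",
    "toy_align",
    "cage_truncate",
    "read_fasta",
    "write_tags_fasta",
    "read_tags_fasta",
    "write_bed",
    "read_bed_alignments",
    "alignments_from_sam",
]

#: 3' sequencing adapter ligated to the small RNAs.
DEFAULT_ADAPTER = "CTGTAGGCACCATCAAT"

LIBRARY_TYPES = ("sRNA", "capped_sRNA", "sRNA_CAGE", "IP_K121", "IP_control")


@dataclass(frozen=True)
class Tag:
    """A clipped read: the RNA insert plus length/provenance bookkeeping.

    ``inferred_length`` is ``None`` when no adapter match was found (the
    insert runs past the read end, so only a lower bound on length exists);
    otherwise it equals ``len(sequence)``.
    """

    read_id: str
    sequence: str
    inferred_length: int | None
    adapter_match: int = 0
    library_id: str = ""
    library_type: str = "sRNA"

    @property
    def unmeasured(self) -> bool:
        return self.inferred_length is None

    @property
    def empty(self) -> bool:
        """True for a read that was adapter from base one (zero-length insert)."""
        return self.inferred_length == 0


@dataclass(frozen=True)
class TagAlignment:
    """Genomic placement of a tag; 0-based half-open, BED-native."""

    tag: Tag
    chrom: str
    start: int
    end: int
    strand: str
    unique: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def five_prime(self) -> int:
        """0-based coordinate of the 5' end of the aligned tag."""
        return self.start if self.strand == "+" else self.end - 1


def clip_adapter(
    read: str,
    adapter: str = DEFAULT_ADAPTER,
    min_match: int = 8,
    read_id: str = "",
    library_id: str = "",
    library_type: str = "sRNA",
) -> Tag:
    """Clip the 3' adapter off a read, inferring the insert length.

    The leftmost position where a prefix of the adapter matches the read
    exactly — either the full adapter internally, or an adapter prefix of at
    least ``min_match`` bases running to the end of the read — marks the end
    of the insert.  If no such match exists the whole read is kept and the
    length is flagged unmeasured.
    """
    if not read:
        raise ValueError("empty read")
    if not (1 <= min_match <= len(adapter)):
        raise ValueError(f"min_match {min_match} outside 1..{len(adapter)}")
    read = read.upper()
    n = len(read)
    for i in range(n - min_match + 1):
        span = min(len(adapter), n - i)
        if read[i : i + span] == adapter[:span]:
            return Tag(
                read_id,
                read[:i],
                inferred_length=i,
                adapter_match=span,
                library_id=library_id,
                library_type=library_type,
            )
    return Tag(
        read_id,
        read,
        inferred_length=None,
        adapter_match=0,
        library_id=library_id,
        library_type=library_type,
    )


def clip_fastq(
    path,
    adapter: str = DEFAULT_ADAPTER,
    min_match: int = 8,
    library_id: str = "",
    library_type: str = "sRNA",
) -> Iterator[Tag]:
    """Clip every read in a FASTQ file (gzip accepted via ``.gz`` suffix)."""
    import gzip

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield clip_adapter(
                str(rec.seq), adapter, min_match, rec.id, library_id, library_type
            )


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def rrna_filter(tags: Iterable[Tag], rdna_reference: str) -> tuple[list[Tag], list[Tag]]:
    """Split tags into (kept, removed) by exact match against the rDNA unit.

    A tag is removed iff its clipped sequence occurs as an exact substring
    of the reference on either strand.  Empty inserts are kept (they carry
    no sequence evidence).  The operation is idempotent.
    """
    if not rdna_reference:
        raise ValueError("empty rDNA reference")
    ref = rdna_reference.upper()
    ref_rc = _revcomp(ref)
    kept, removed = [], []
    for tag in tags:
        seq = tag.sequence.upper()
        if seq and (seq in ref or seq in ref_rc):
            removed.append(tag)
        else:
            kept.append(tag)
    return kept, removed


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def toy_align(tags: Iterable[Tag], genome: Mapping[str, str]) -> list[TagAlignment]:
    """Exact-substring alignment of tags against both strands of a genome.

    A desk-scale stand-in for a real aligner: every exact occurrence is
    reported; tags with exactly one hit across the genome are flagged
    ``unique``.  Empty and unmeasured-length tags are aligned by their
    sequence as-is.
    """
    out: list[TagAlignment] = []
    for tag in tags:
        seq = tag.sequence.upper()
        if not seq:
            continue
        hits: list[tuple[str, int, int, str]] = []
        rc = _revcomp(seq)
        for chrom, chrom_seq in genome.items():
            chrom_seq = chrom_seq.upper()
            for i in _find_all(chrom_seq, seq):
                hits.append((chrom, i, i + len(seq), "+"))
            for i in _find_all(chrom_seq, rc):
                hits.append((chrom, i, i + len(seq), "-"))
        unique = len(hits) == 1
        out.extend(
            TagAlignment(tag, chrom, s, e, strand, unique)
            for chrom, s, e, strand in hits
        )
    return out


def cage_truncate(tag: Tag, tag_length: int = 27) -> Tag:
    """Truncate a tag to its 5'-most ``tag_length`` bases (EcoP15I-style).

    Type III restriction cleavage during CAGE library preparation yields
    fixed-length tags; shorter tags pass through unchanged.
    """
    if len(tag.sequence) <= tag_length:
        return tag
    return replace(
        tag, sequence=tag.sequence[:tag_length], inferred_length=tag_length
    )


# --- IO ----------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    """FASTA file to a dict of id -> sequence."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_tags_fasta(tags: Iterable[Tag], path) -> int:
    n = 0
    with open(path, "w") as fh:
        for tag in tags:
            if not tag.sequence:
                continue
            length = tag.inferred_length if not tag.unmeasured else "unmeasured"
            fh.write(
                f">{tag.read_id} length={length} library={tag.library_id or '.'} "
                f"type={tag.library_type}\n{tag.sequence}\n"
            )
            n += 1
    return n


def read_tags_fasta(path) -> list[Tag]:
    """Read tags back from FASTA written by :func:`write_tags_fasta`."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        attrs = dict(
            kv.split("=", 1) for kv in rec.description.split()[1:] if "=" in kv
        )
        raw_len = attrs.get("length", "")
        length = None if raw_len in ("", "unmeasured") else int(raw_len)
        lib = attrs.get("library", ".")
        out.append(
            Tag(
                rec.id,
                str(rec.seq).upper(),
                inferred_length=length,
                library_id="" if lib == "." else lib,
                library_type=attrs.get("type", "sRNA"),
            )
        )
    return out


def write_bed(alignments: Iterable[TagAlignment], path) -> int:
    """Write alignments as 6-column BED (score column carries uniqueness)."""
    n = 0
    with open(path, "w") as fh:
        for a in alignments:
            score = 1 if a.unique else 0
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{a.tag.read_id}\t{score}\t{a.strand}\n")
            n += 1
    return n


def read_bed_alignments(path, library_id: str = "", library_type: str = "sRNA") -> list[TagAlignment]:
    """Read 6-column BED back into alignments (tags carry no sequence)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, name, score, strand = line.split("\t")[:6]
            start, end = int(start), int(end)
            tag = Tag(name, "", inferred_length=end - start,
                      library_id=library_id, library_type=library_type)
            out.append(TagAlignment(tag, chrom, start, end, strand, unique=score not in ("0", "0.0")))
    return out


def alignments_from_sam(path, library_id: str = "", library_type: str = "sRNA") -> list[TagAlignment]:
    """Ingest mapped records from a SAM file as tag alignments.

    Coordinates are converted to 0-based half-open; uniqueness follows the
    absence of the secondary/supplementary flags and MAPQ > 0.
    """
    import pysam

    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            seq = rec.query_sequence or ""
            tag = Tag(
                rec.query_name,
                seq,
                inferred_length=len(seq) if seq else None,
                library_id=library_id,
                library_type=library_type,
            )
            unique = not (rec.is_secondary or rec.is_supplementary) and (rec.mapping_quality or 0) > 0
            out.append(
                TagAlignment(
                    tag,
                    rec.reference_name,
                    rec.reference_start,
                    rec.reference_end,
                    "-" if rec.is_reverse else "+",
                    unique,
                )
            )
    return out
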