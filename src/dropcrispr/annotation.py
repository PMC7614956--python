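"""Genomes, TSS-anchored feature annotations, and neighbor-orientation analysis.

Coordinates are 0-based, half-open everywhere in memory (BED dialect on
disk); only human-readable reports use 1-based positions.  Features are
anchored on their transcription start site (TSS): for a ``+`` feature the
TSS is the span start, for a ``-`` feature the last base of the span.

The neighbor analysis serves screens of long non-coding RNAs (SUTs/CUTs in
yeast): an enriched guide targeting a ncRNA is explained by looking at every
annotated feature within a window (default 1 kb) centred on the guide and
classifying its orientation relative to the targeted strand — antisense
overlap, divergent (shared bidirectional promoter), tandem, or convergent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

VALID_BASES = set("ACGTN")
FEATURE_TYPES = ("ORF", "SUT", "CUT")

ORIENTATION_CLASSES = (
    "antisense_overlapping",
    "divergent",
    "convergent",
    "tandem_upstream",
    "tandem_downstream",
    "sense_overlapping",
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


class AnnotationError(ValueError):
    """Malformed genome or feature input."""


@dataclass(frozen=True)
class Genome:
    """Named DNA sequences, uppercase over {A,C,G,T,N}."""

    sequences: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise AnnotationError("genome holds no records")
        for name, seq in self.sequences.items():
            if not seq:
                raise AnnotationError(f"sequence {name!r} is empty")
            bad = set(seq) - VALID_BASES
            if bad:
                raise AnnotationError(
                    f"sequence {name!r} contains invalid characters {sorted(bad)}"
                )

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Slice [start, end) of a chromosome; out-of-bounds lookups are errors."""
        seq = self.sequences.get(chrom)
        if seq is None:
            raise KeyError(chrom)
        if not (0 <= start <= end <= len(seq)):
            raise IndexError(f"[{start}, {end}) outside {chrom} of length {len(seq)}")
        return seq[start:end]

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])


@dataclass(frozen=True)
class Feature:
    """A TSS-anchored transcribed feature (ORF, SUT or CUT)."""

    feature_id: str
    feature_type: str
    chrom: str
    strand: str
    tss: int
    span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.feature_type not in FEATURE_TYPES:
            raise AnnotationError(
                f"{self.feature_id}: unknown feature_type {self.feature_type!r} "
                f"(expected one of {FEATURE_TYPES})"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.feature_id}: strand must be + or -")
        if self.span is not None:
            start, end = self.span
            if start >= end:
                raise AnnotationError(
                    f"{self.feature_id}: empty span [{start}, {end})"
                )
            anchor = start if self.strand == "+" else end - 1
            if self.tss != anchor:
                raise AnnotationError(
                    f"{self.feature_id}: tss {self.tss} does not match span anchor "
                    f"{anchor} on strand {self.strand}"
                )


@dataclass(frozen=True)
class NeighborHit:
    feature: Feature
    orientation: str
    distance: int  # |feature TSS - query position|


@dataclass(frozen=True)
class NeighborReport:
    chrom: str
    query_position: int
    query_strand: str
    window: int
    hits: tuple[NeighborHit, ...] = field(default_factory=tuple)


def read_genome(path: str | Path) -> Genome:
    """Read a FASTA file into a :class:`Genome`.

    Sequences are uppercased and RNA ``U`` is mapped to ``T``.  Characters
    outside {A,C,G,T,N} and duplicate headers are rejected.
    """
    path = Path(path)
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise AnnotationError(f"duplicate FASTA header {record.id!r} in {path}")
        seq = str(record.seq).upper().replace("U", "T")
        bad = set(seq) - VALID_BASES
        if bad:
            raise AnnotationError(
                f"record {record.id!r} contains invalid characters {sorted(bad)}"
            )
        if not seq:
            raise AnnotationError(f"record {record.id!r} is empty")
        sequences[record.id] = seq
    if not sequences:
        raise AnnotationError(f"no records found in {path}")
    return Genome(sequences)


def write_genome(genome: Genome, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_features(path: str | Path) -> list[Feature]:
    """Read a BED6-style feature table.

    Columns: chrom, start, end, feature_id, feature_type, strand — whitespace
    separated, 0-based half-open coordinates.  The TSS is derived from the
    span and strand (start for ``+``, end-1 for ``-``).
    """
    features: list[Feature] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise AnnotationError(
                    f"{path} line {lineno}: expected 6 columns, got {len(parts)}"
                )
            chrom, start_s, end_s, fid, ftype, strand = parts[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise AnnotationError(
                    f"{path} line {lineno}: non-integer coordinates"
                ) from exc
            if start >= end:
                raise AnnotationError(
                    f"{path} line {lineno}: start {start} >= end {end}"
                )
            if fid in seen:
                raise AnnotationError(f"{path} line {lineno}: duplicate id {fid!r}")
            seen.add(fid)
            tss = start if strand == "+" else end - 1
            features.append(
                Feature(
                    feature_id=fid,
                    feature_type=ftype,
                    chrom=chrom,
                    strand=strand,
                    tss=tss,
                    span=(start, end),
                )
            )
    return features


def write_features(features: Iterable[Feature], path: str | Path) -> None:
    """Write features as the BED6-style table :func:`read_features` reads."""
    with open(path, "w") as fh:
        for f in features:
            if f.span is None:
                span = (f.tss, f.tss + 1) if f.strand == "+" else (f.tss, f.tss + 1)
            else:
                span = f.span
            fh.write(
                f"{f.chrom}\t{span[0]}\t{span[1]}\t{f.feature_id}\t"
                f"{f.feature_type}\t{f.strand}\n"
            )


def _feature_interval(feature: Feature) -> tuple[int, int]:
    if feature.span is not None:
        return feature.span
    return (feature.tss, feature.tss + 1)


def classify_orientation(
    query_position: int, query_strand: str, feature: Feature
) -> str:
    """Orientation of a neighboring feature relative to a stranded query point.

    Same strand: overlapping span -> ``sense_overlapping``; feature TSS
    downstream of the query (in the query's transcriptional direction) ->
    ``tandem_upstream`` (the query sits upstream of the feature); otherwise
    ``tandem_downstream``.  Opposite strand: overlapping span ->
    ``antisense_overlapping``; transcribing away from the query ->
    ``divergent`` (bidirectional-promoter candidate); transcribing toward
    the query -> ``convergent``.
    """
    start, end = _feature_interval(feature)
    overlaps = start <= query_position < end
    same_strand = feature.strand == query_strand
    if same_strand:
        if overlaps:
            return "sense_overlapping"
        downstream = (
            feature.tss > query_position
            if query_strand == "+"
            else feature.tss < query_position
        )
        return "tandem_upstream" if downstream else "tandem_downstream"
    if overlaps:
        return "antisense_overlapping"
    # Opposite strand, non-overlapping: a "-" feature left of a "+" query
    # (or a "+" feature right of a "-" query) transcribes away => divergent.
    if query_strand == "+":
        pointing_apart = feature.tss < query_position
    else:
        pointing_apart = feature.tss > query_position
    return "divergent" if pointing_apart else "convergent"


def neighbor_features(
    position: int,
    chrom: str,
    annotation: Iterable[Feature],
    window: int = 1000,
    query_strand: str = "+",
) -> NeighborReport:
    """Features whose span intersects the closed window centred on a position.

    The window is ``[position - window//2, position + window//2]``, closed on
    both ends.  A chromosome absent from the annotation yields an empty
    report, not an error.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    half = window // 2
    lo, hi = position - half, position + half
    hits = []
    for feature in annotation:
        if feature.chrom != chrom:
            continue
        start, end = _feature_interval(feature)
        if start <= hi and end - 1 >= lo:  # closed-window vs half-open span
            hits.append(
                NeighborHit(
                    feature=feature,
                    orientation=classify_orientation(position, query_strand, feature),
                    distance=abs(feature.tss - position),
                )
            )
    hits.sort(key=lambda h: (h.distance, h.feature.feature_id))
    return NeighborReport(
        chrom=chrom,
        query_position=position,
        query_strand=query_strand,
        window=window,
        hits=tuple(hits),
    )


def neighbor_report_table(report: NeighborReport) -> str:
    """Render a neighbor report as TSV (1-based positions, human-facing)."""
    lines = ["feature_id\tfeature_type\tstrand\ttss_1based\torientation\tdistance"]
    for h in report.hits:
        lines.append(
            f"{h.feature.feature_id}\t{h.feature.feature_type}\t{h.feature.strand}\t"
            f"{h.feature.tss + 1}\t{h.orientation}\t{h.distance}"
        )
    return "\n".join(lines) + "\n"
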