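"""Read demultiplexing and guide counting.

Screen readout amplicons carry a short inline sample barcode (4-6 nt) at the
read start, a constant vector flank, then the 20-nt guide.  Because the
library is built so that any two guides differ at three or more positions,
exact matching recovers essentially every read that alignment would; the
counter therefore demultiplexes by exact prefix match and looks the 20-mer
after the flank up directly in the library (an optional 1-mismatch mode
covers sequencing errors).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd


class SampleSheetError(ValueError):
    pass


@dataclass(frozen=True)
class Sample:
    sample_id: str
    barcode: str
    screen_id: str
    fraction: str  # "high" or "low"
    replicate: int


@dataclass(frozen=True)
class SampleSheet:
    samples: tuple[Sample, ...]

    def __post_init__(self) -> None:
        barcodes = [s.barcode for s in self.samples]
        if len(set(barcodes)) != len(barcodes):
            raise SampleSheetError("duplicate barcodes in sample sheet")
        for b in barcodes:
            if not 4 <= len(b) <= 6 or set(b) - set("ACGT"):
                raise SampleSheetError(f"barcode {b!r} must be 4-6 nt over ACGT")
        for a in barcodes:
            for b in barcodes:
                if a != b and b.startswith(a):
                    raise SampleSheetError(
                        f"barcode {a!r} is a prefix of {b!r}; set must be prefix-free"
                    )
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise SampleSheetError("duplicate sample ids")
        for s in self.samples:
            if s.fraction not in ("high", "low"):
                raise SampleSheetError(
                    f"sample {s.sample_id}: fraction must be high or low"
                )

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def fractions(self) -> dict[str, str]:
        return {s.sample_id: s.fraction for s in self.samples}


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """TSV with columns sample_id, barcode, screen_id, fraction, replicate."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "barcode", "screen_id", "fraction", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise SampleSheetError(f"sample sheet missing columns {sorted(missing)}")
    samples = tuple(
        Sample(
            sample_id=row.sample_id,
            barcode=row.barcode,
            screen_id=row.screen_id,
            fraction=row.fraction,
            replicate=int(row.replicate),
        )
        for row in df.itertuples()
    )
    return SampleSheet(samples)


@dataclass
class CountTable:
    """Guides x samples integer counts plus unassigned-read accounting."""

    counts: pd.DataFrame  # index = guide ids, columns = sample ids
    fractions: dict[str, str]  # sample -> high/low
    unassigned: pd.DataFrame | None = None  # rows no_barcode / no_guide

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be nonnegative")
        self.counts = self.counts.astype(np.int64)

    @property
    def guide_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def group_labels(self) -> pd.Series:
        return pd.Series({s: self.fractions[s] for s in self.sample_ids})

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for s in self.sample_ids:
                fh.write(f"# sample\t{s}\t{self.fractions[s]}\n")
            self.counts.rename_axis("guide_id").to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountTable":
        fractions: dict[str, str] = {}
        with open(path) as fh:
            lines = fh.readlines()
        body_start = 0
        for i, line in enumerate(lines):
            if line.startswith("# sample\t"):
                _, sid, frac = line.rstrip("\n").split("\t")
                fractions[sid] = frac
                body_start = i + 1
            else:
                break
        from io import StringIO

        df = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t", index_col=0)
        df.index.name = None
        if not fractions:
            fractions = {c: "" for c in df.columns}
        return cls(counts=df, fractions=fractions)


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (read_id, sequence, quality) from a FASTQ file (gzip allowed)."""
    with _open_maybe_gzip(path) as fh:
        while True:
            header = fh.readline().rstrip("\n")
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not plus.startswith("+"):
                raise ValueError(f"malformed FASTQ near {header!r}")
            yield header[1:], seq.upper(), qual


def demultiplex(
    reads: Iterable[tuple[str, str, str]], sheet: SampleSheet
) -> tuple[dict[str, list[str]], int]:
    """Assign reads to samples by exact barcode prefix, trimming the barcode.

    Returns per-sample trimmed sequences and the no_barcode count.  A
    prefix-free barcode set (enforced by the sheet) makes assignment unique.
    """
    by_len: dict[int, dict[str, str]] = {}
    for s in sheet.samples:
        by_len.setdefault(len(s.barcode), {})[s.barcode] = s.sample_id
    streams: dict[str, list[str]] = {s.sample_id: [] for s in sheet.samples}
    no_barcode = 0
    for _rid, seq, _qual in reads:
        for blen in sorted(by_len):
            sid = by_len[blen].get(seq[:blen])
            if sid is not None:
                streams[sid].append(seq[blen:])
                break
        else:
            no_barcode += 1
    return streams, no_barcode


def _one_mismatch_lookup(library: Sequence[str]) -> dict[str, str]:
    table: dict[str, str | None] = {}
    for g in library:
        for i in range(len(g)):
            for b in "ACGT":
                if b != g[i]:
                    variant = g[:i] + b + g[i + 1 :]
                    table[variant] = None if variant in table else g
    return {k: v for k, v in table.items() if v is not None}


def count_guides(
    streams: dict[str, list[str]],
    library: Sequence[str],
    flank: str,
    fractions: dict[str, str] | None = None,
    max_mm: int = 0,
) -> CountTable:
    """Count library 20-mers in demultiplexed reads.

    The 20 nt following the first occurrence of the constant flank are
    looked up in the library; reads whose flank is missing or whose 20-mer
    is not in the library increment ``no_guide``.  ``max_mm=1`` tolerates a
    single mismatch in the guide (ambiguous one-off variants stay unassigned;
    the library's >= 3 mismatch separation makes ambiguity impossible there).
    """
    if len(set(library)) != len(library):
        raise ValueError("library 20-mers must be unique")
    glen = len(library[0]) if library else 20
    lib_set = set(library)
    near = _one_mismatch_lookup(library) if max_mm >= 1 else {}
    per_sample: dict[str, dict[str, int]] = {}
    no_guide = {sid: 0 for sid in streams}
    for sid, seqs in streams.items():
        tally: dict[str, int] = {}
        for seq in seqs:
            pos = seq.find(flank)
            if pos < 0:
                no_guide[sid] += 1
                continue
            mer = seq[pos + len(flank) : pos + len(flank) + glen]
            if mer in lib_set:
                tally[mer] = tally.get(mer, 0) + 1
            elif max_mm >= 1 and mer in near:
                hit = near[mer]
                tally[hit] = tally.get(hit, 0) + 1
            else:
                no_guide[sid] += 1
        per_sample[sid] = tally
    counts = pd.DataFrame(
        {sid: [per_sample[sid].get(g, 0) for g in library] for sid in streams},
        index=list(library),
        dtype=np.int64,
    )
    unassigned = pd.DataFrame(
        {sid: {"no_guide": no_guide[sid]} for sid in streams}
    )
    fractions = fractions or {sid: "" for sid in streams}
    return CountTable(counts=counts, fractions=fractions, unassigned=unassigned)


def quantify_fastq(
    fastq_path: str | Path,
    sheet: SampleSheet,
    library: Sequence[str],
    flank: str,
    max_mm: int = 0,
) -> CountTable:
    """FASTQ -> demultiplex -> count, with full read accounting."""
    streams, no_barcode = demultiplex(iter_fastq(fastq_path), sheet)
    table = count_guides(streams, library, flank, sheet.fractions(), max_mm)
    assert table.unassigned is not None
    table.unassigned.loc["no_barcode"] = 0
    if sheet.samples:
        table.unassigned.loc["no_barcode", sheet.samples[0].sample_id] = no_barcode
    return table
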