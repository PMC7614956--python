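"""Genome-wide mismatch off-target screening of guide candidates.

Every PAM-adjacent 20-mer in the genome (both strands, strand-normalized to
protospacer orientation) is indexed; a guide survives only if no other
indexed site — and no other guide in the library — lies within fewer than
three mismatches (full-length Hamming distance, no indels, PAM excluded).

Scaling: an exact 20-mer hash answers distance-0 queries; a pigeonhole seed
index over three protospacer segments answers distance <= 2 queries (any two
20-mers within 2 mismatches agree exactly on at least one of three disjoint
segments).  A brute-force scan remains available as the testing oracle and
as the fallback for exact minimum distances >= 3.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .annotation import Genome
from .design import DesignParams, GuideCandidate, PamSite, scan_pam_sites

NO_OTHER_SITE = -1  # sentinel: the index holds only the guide itself

_SEGMENTS = ((0, 7), (7, 14), (14, 20))  # pigeonhole split for d <= 2

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(seqs: Sequence[str]) -> np.ndarray:
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8)
    return arr.reshape(len(seqs), -1)


@dataclass
class SiteIndex:
    """All PAM-adjacent protospacer 20-mers of a genome with locations."""

    entries: dict[str, list[tuple[str, str, int]]]  # 20-mer -> (chrom, strand, start)
    seed_buckets: tuple[dict[str, list[int]], ...]
    seqs: list[str]
    matrix: np.ndarray  # uint8 byte codes, n_unique x 20

    @property
    def total_sites(self) -> int:
        return sum(len(v) for v in self.entries.values())

    def locations(self, protospacer: str) -> list[tuple[str, str, int]]:
        return self.entries.get(protospacer, [])

    def neighbors_within(self, protospacer: str, max_mm: int) -> list[tuple[str, int]]:
        """Distinct indexed 20-mers within ``max_mm`` mismatches (inclusive),
        as (sequence, distance) pairs.  Uses the seed index for max_mm <= 2,
        the full matrix scan beyond."""
        if max_mm <= 2:
            cand_ids: set[int] = set()
            for seg_i, (a, b) in enumerate(_SEGMENTS):
                cand_ids.update(self.seed_buckets[seg_i].get(protospacer[a:b], ()))
            if not cand_ids:
                return []
            ids = np.fromiter(cand_ids, dtype=np.intp)
            query = np.frombuffer(protospacer.encode(), dtype=np.uint8)
            dists = (self.matrix[ids] != query).sum(axis=1)
            keep = dists <= max_mm
            return [(self.seqs[i], int(d)) for i, d in zip(ids[keep], dists[keep])]
        query = np.frombuffer(protospacer.encode(), dtype=np.uint8)
        dists = (self.matrix != query).sum(axis=1)
        keep = np.flatnonzero(dists <= max_mm)
        return [(self.seqs[i], int(dists[i])) for i in keep]


def build_site_index(
    genome: Genome,
    params: DesignParams | None = None,
    sites: Sequence[PamSite] | None = None,
) -> SiteIndex:
    """Index every PAM-adjacent 20-mer of the genome (scan both strands)."""
    if sites is None:
        sites = scan_pam_sites(genome, params or DesignParams())
    entries: dict[str, list[tuple[str, str, int]]] = {}
    for site in sites:
        entries.setdefault(site.protospacer, []).append(
            (site.chrom, site.strand, site.start)
        )
    seqs = sorted(entries)
    buckets: tuple[dict[str, list[int]], ...] = tuple({} for _ in _SEGMENTS)
    for idx, seq in enumerate(seqs):
        for seg_i, (a, b) in enumerate(_SEGMENTS):
            buckets[seg_i].setdefault(seq[a:b], []).append(idx)
    matrix = (
        _encode(seqs) if seqs else np.empty((0, 20), dtype=np.uint8)
    )
    return SiteIndex(entries=entries, seed_buckets=buckets, seqs=seqs, matrix=matrix)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    return sum(x != y for x, y in zip(a, b))


def min_mismatch_to_others(guide: GuideCandidate, index: SiteIndex) -> int:
    """Minimum Hamming distance from a guide to any indexed site other than
    its own originating location.

    A second genomic occurrence of the identical 20-mer counts (distance 0).
    Returns :data:`NO_OTHER_SITE` when the index holds only the guide itself.
    """
    own = (guide.chrom, guide.guide_strand, guide.start)
    locs = index.locations(guide.protospacer)
    if own not in locs:
        raise ValueError(
            f"guide {guide.protospacer} at {own} absent from index "
            "(index/genome mismatch)"
        )
    if index.total_sites == 1:
        return NO_OTHER_SITE
    if len(locs) > 1:
        return 0
    # Nearest distinct 20-mer: try the seed index (d <= 2) before the scan.
    best = 21
    for seq, d in index.neighbors_within(guide.protospacer, 2):
        if seq != guide.protospacer:
            best = min(best, d)
    if best <= 2:
        return best
    query = np.frombuffer(guide.protospacer.encode(), dtype=np.uint8)
    dists = (index.matrix != query).sum(axis=1)
    dists[index.seqs.index(guide.protospacer)] = 21
    return int(dists.min())


def _mutual_conflicts(protospacers: Sequence[str], min_mm: int) -> np.ndarray:
    """Boolean mask of candidates within < min_mm mismatches of another
    candidate (identical sequences always conflict).  Pigeonhole bucketing
    keeps the pairwise comparisons near-linear for separated libraries."""
    n = len(protospacers)
    conflict = np.zeros(n, dtype=bool)
    if n < 2:
        return conflict
    mat = _encode(protospacers)
    if min_mm <= 3:
        # d <= min_mm - 1 <= 2: pairs must share one of the three segments
        buckets: dict[tuple[int, str], list[int]] = {}
        for i, seq in enumerate(protospacers):
            for seg_i, (a, b) in enumerate(_SEGMENTS):
                buckets.setdefault((seg_i, seq[a:b]), []).append(i)
        pairs: set[tuple[int, int]] = set()
        for ids in buckets.values():
            if len(ids) > 1:
                for x in range(len(ids)):
                    for y in range(x + 1, len(ids)):
                        pairs.add((ids[x], ids[y]))
        for i, j in pairs:
            if (mat[i] != mat[j]).sum() < min_mm:
                conflict[i] = conflict[j] = True
        return conflict
    for i in range(n):
        dists = (mat[i + 1 :] != mat[i]).sum(axis=1)
        hit = np.flatnonzero(dists < min_mm)
        if hit.size:
            conflict[i] = True
            conflict[i + 1 + hit] = True
    return conflict


def filter_offtargets(
    candidates: Sequence[GuideCandidate],
    index: SiteIndex,
    min_mm: int = 3,
) -> list[GuideCandidate]:
    """Flag every candidate: kept iff its nearest other genomic site is at
    least ``min_mm`` mismatches away AND no other candidate in the input
    (across all features) lies within fewer than ``min_mm`` mismatches.

    Both members of a conflicting candidate pair are removed.  All
    candidates are returned with ``offtarget_ok`` set; callers subset on it.
    """
    genome_ok = []
    for cand in candidates:
        mm = min_mismatch_to_others(cand, index)
        genome_ok.append(mm == NO_OTHER_SITE or mm >= min_mm)
    mutual = _mutual_conflicts([c.protospacer for c in candidates], min_mm)
    return [
        replace(c, offtarget_ok=bool(ok and not bad))
        for c, ok, bad in zip(candidates, genome_ok, mutual)
    ]


def brute_force_min_mismatch(
    guide: GuideCandidate, sites: Iterable[PamSite]
) -> int:
    """O(n) reference scan used as the testing oracle."""
    best = NO_OTHER_SITE
    for site in sites:
        if (site.chrom, site.strand, site.start) == (
            guide.chrom, guide.guide_strand, guide.start
        ):
            continue
        d = hamming(guide.protospacer, site.protospacer)
        best = d if best == NO_OTHER_SITE else min(best, d)
    return best
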