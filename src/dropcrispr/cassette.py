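"""Type IIS oligo cassette packing and digest simulation.

Array-synthesized 190-bp oligos each carry four 20-nt guides between spacer
sequences bearing BspQI (SapI-family, GCTCTTC) recognition sites on both
strands, so a single digest releases every guide while removing the
recognition sites.  This module assembles those cassettes from an ordered
guide list and simulates the digest to verify release.

The digest uses a single-breakpoint model: BspQI cuts one nucleotide 3' of
its recognition heptamer (GCTCTTCN^ on the carrying strand), and each site
yields one double-strand breakpoint at that top-strand coordinate.  The real
enzyme leaves 3-nt 5' overhangs; overhang chemistry does not affect which
guides are released and is not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .annotation import revcomp

FILLER_GUIDE = "ACGTACGTACACGTACGTAC"


class CassetteError(ValueError):
    """Guide or layout incompatible with cassette assembly."""


@dataclass(frozen=True)
class CassetteLayout:
    """Fixed sequence scaffold of a synthesis oligo.

    Defaults encode the standard 190-bp cassette:
    11 nt left flank | 11 nt left BspQI site | 4 x 20 nt guides separated by
    3 x 22 nt double-site spacers | 11 nt right site | 11 nt right flank.
    """

    left_flank: str = "TCAGTCGATCG"
    left_site: str = "GCTCTTCAAGG"
    internal_spacer: str = "GTTAGAAGAGCGCTCTTCTAGG"
    right_site: str = "GTTCGAAGAGC"
    right_flank: str = "GCTAGCTCCAT"
    guides_per_oligo: int = 4
    guide_len: int = 20
    recognition: str = "GCTCTTC"

    def __post_init__(self) -> None:
        spacer = self.internal_spacer
        if self.recognition not in spacer or revcomp(self.recognition) not in spacer:
            raise CassetteError(
                "internal spacer must carry the recognition site on both strands"
            )

    @property
    def oligo_len(self) -> int:
        n = self.guides_per_oligo
        return (
            len(self.left_flank) + len(self.left_site)
            + n * self.guide_len
            + (n - 1) * len(self.internal_spacer)
            + len(self.right_site) + len(self.right_flank)
        )

    def assemble(self, guides: Sequence[str]) -> str:
        body = self.internal_spacer.join(guides)
        return (
            self.left_flank + self.left_site + body
            + self.right_site + self.right_flank
        )


@dataclass(frozen=True)
class OligoSlot:
    oligo_index: int
    slot: int
    guide: str
    is_filler: bool


@dataclass(frozen=True)
class OligoPool:
    oligos: tuple[str, ...]
    manifest: tuple[OligoSlot, ...]
    layout: CassetteLayout = field(default_factory=CassetteLayout)


def _validate_guide(guide: str, layout: CassetteLayout) -> None:
    if len(guide) != layout.guide_len:
        raise CassetteError(
            f"guide {guide!r} is {len(guide)} nt, expected {layout.guide_len}"
        )
    if set(guide) - set("ACGT"):
        raise CassetteError(f"guide {guide!r} contains non-ACGT characters")
    site, rc_site = layout.recognition, revcomp(layout.recognition)
    if site in guide or rc_site in guide:
        raise CassetteError(
            f"guide {guide!r} contains the recognition site and would be shredded"
        )


def pack_oligos(
    guides: Sequence[str], layout: CassetteLayout | None = None
) -> OligoPool:
    """Assemble guides, four per oligo in order, into synthesis cassettes.

    A trailing partial oligo is completed with :data:`FILLER_GUIDE` slots
    flagged in the manifest.  Guides carrying the recognition site — or
    creating one across a junction with the scaffold — are rejected by name.
    """
    layout = layout or CassetteLayout()
    for g in guides:
        _validate_guide(g, layout)
    per = layout.guides_per_oligo
    padded = list(guides)
    n_filler = (-len(padded)) % per
    padded.extend([FILLER_GUIDE] * n_filler)
    oligos: list[str] = []
    manifest: list[OligoSlot] = []
    site, rc_site = layout.recognition, revcomp(layout.recognition)
    expected_sites = _scaffold_site_count(layout)
    for oi in range(0, len(padded), per):
        chunk = padded[oi : oi + per]
        oligo = layout.assemble(chunk)
        n_sites = _count_sites(oligo, site) + _count_sites(oligo, rc_site)
        if n_sites != expected_sites:
            culprit = _junction_culprit(chunk, layout)
            raise CassetteError(
                f"guide {culprit!r} creates a recognition site at a cassette junction"
            )
        idx = oi // per
        oligos.append(oligo)
        for slot, g in enumerate(chunk):
            is_filler = oi + slot >= len(guides)
            manifest.append(OligoSlot(idx, slot, g, is_filler))
    return OligoPool(tuple(oligos), tuple(manifest), layout)


def _count_sites(seq: str, motif: str) -> int:
    count = start = 0
    while True:
        pos = seq.find(motif, start)
        if pos < 0:
            return count
        count += 1
        start = pos + 1


def _scaffold_site_count(layout: CassetteLayout) -> int:
    neutral = "A" * layout.guide_len  # site-free placeholder guides
    oligo = layout.assemble([neutral] * layout.guides_per_oligo)
    return _count_sites(oligo, layout.recognition) + _count_sites(
        oligo, revcomp(layout.recognition)
    )


def _junction_culprit(chunk: Sequence[str], layout: CassetteLayout) -> str:
    neutral = "A" * layout.guide_len
    expected = _scaffold_site_count(layout)
    site, rc = layout.recognition, revcomp(layout.recognition)
    for i, g in enumerate(chunk):
        trial = [neutral] * len(chunk)
        trial[i] = g
        oligo = layout.assemble(trial)
        if _count_sites(oligo, site) + _count_sites(oligo, rc) != expected:
            return g
    return chunk[0]


@dataclass(frozen=True)
class DigestFragment:
    start: int  # top-strand interval on the oligo, half-open
    end: int
    sequence: str
    guide_core: str | None


def digest_oligo(
    oligo: str,
    recognition: str = "GCTCTTC",
    library: Iterable[str] | None = None,
) -> list[DigestFragment]:
    """Simulate a type IIS digest of one oligo.

    Each recognition occurrence on either strand contributes one breakpoint
    one nucleotide 3' of the heptamer on its own strand (top occurrence over
    [s, s+7) cuts at s+8; a bottom-strand occurrence, seen as the
    reverse-complement heptamer on the top strand at [s, s+7), cuts at s-1).
    Fragments tile the oligo between successive breakpoints.  A fragment's
    ``guide_core`` is the library 20-mer it contains when a library is
    supplied, else its interior after trimming the 3-nt spacer remnants each
    released guide carries.
    """
    if set(oligo) - set("ACGT"):
        raise CassetteError("oligo contains non-ACGT characters")
    rc = revcomp(recognition)
    step = len(recognition) + 1
    cuts: set[int] = set()
    start = 0
    while (pos := oligo.find(recognition, start)) >= 0:
        cuts.add(pos + step)
        start = pos + 1
    start = 0
    while (pos := oligo.find(rc, start)) >= 0:
        cuts.add(pos - 1)
        start = pos + 1
    bounds = sorted({0, len(oligo)} | {c for c in cuts if 0 < c < len(oligo)})
    lib = set(library) if library is not None else None
    fragments = []
    for a, b in zip(bounds, bounds[1:]):
        seq = oligo[a:b]
        core: str | None = None
        if lib is not None:
            for k in range(0, len(seq) - 19):
                if seq[k : k + 20] in lib:
                    core = seq[k : k + 20]
                    break
        elif len(seq) == 26:
            core = seq[3:23]
        fragments.append(DigestFragment(a, b, seq, core))
    return fragments


def released_guides(
    pool: OligoPool, library: Iterable[str] | None = None
) -> list[str]:
    """All guide cores released by digesting every oligo in a pool."""
    out = []
    for oligo in pool.oligos:
        for frag in digest_oligo(oligo, pool.layout.recognition, library):
            if frag.guide_core is not None:
                out.append(frag.guide_core)
    return out


def pool_to_fasta(pool: OligoPool, path) -> None:
    with open(path, "w") as fh:
        for i, oligo in enumerate(pool.oligos):
            fh.write(f">oligo_{i}\n{oligo}\n")


def manifest_to_tsv(pool: OligoPool, path) -> None:
    with open(path, "w") as fh:
        fh.write("oligo_id\tslot\tguide\tis_filler\n")
        for s in pool.manifest:
            fh.write(
                f"oligo_{s.oligo_index}\t{s.slot}\t{s.guide}\t"
                f"{str(s.is_filler).lower()}\n"
            )
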