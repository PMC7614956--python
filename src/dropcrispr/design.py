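"""SpCas9 guide enumeration, promoter-window assignment and bin selection.

The library design follows the promoter-tiling strategy used for joint
CRISPRa/CRISPRi libraries: all NGG protospacers whose cut site falls from
400 bp upstream to 100 bp downstream of a feature's TSS are candidates; when
a promoter offers six or more, the region from 300 bp upstream to the TSS is
divided into six 50-bp bins and the top-scoring guide per bin is kept,
otherwise every available candidate is used.

Scoring is a pluggable ``protospacer -> [0, 1]`` callable.  The default is a
deterministic GC/homopolymer heuristic that keeps the toolkit self-contained;
callers may inject any trained on-target model instead.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Iterable, Sequence

from .annotation import Feature, Genome, revcomp

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


def _matches_iupac(seq: str, pattern: str) -> bool:
    return len(seq) == len(pattern) and all(
        b in _IUPAC[p] for b, p in zip(seq, pattern)
    )


@dataclass(frozen=True)
class DesignParams:
    """Promoter window and bin-selection parameters.

    Defaults encode the standard design: candidate window [-400, +100]
    around the TSS, six 50-bp score bins covering [-300, 0), SpCas9 NGG PAM,
    20-nt protospacers.
    """

    window_upstream: int = 400
    window_downstream: int = 100
    bin_region: int = 300
    bin_width: int = 50
    max_per_feature: int = 6
    pam: str = "NGG"
    protospacer_len: int = 20

    def __post_init__(self) -> None:
        if self.bin_region % self.bin_width != 0:
            raise ValueError("bin_region must be divisible by bin_width")
        if self.window_upstream < self.bin_region:
            raise ValueError("window_upstream must cover the bin region")
        if self.n_bins != self.max_per_feature:
            raise ValueError(
                "bin_region / bin_width must equal max_per_feature "
                f"({self.n_bins} != {self.max_per_feature})"
            )
        if any(ch not in _IUPAC for ch in self.pam):
            raise ValueError(f"PAM {self.pam!r} is not an IUPAC string")

    @property
    def n_bins(self) -> int:
        return self.bin_region // self.bin_width


@dataclass(frozen=True)
class PamSite:
    """A PAM-adjacent protospacer occurrence on one genomic strand."""

    chrom: str
    strand: str
    start: int  # protospacer interval [start, start + protospacer_len)
    end: int
    protospacer: str  # in guide (protospacer) orientation
    pam_seq: str

    @property
    def cut_site(self) -> int:
        """Blunt-cut coordinate 3 bp 5' of the PAM (between protospacer
        positions 17 and 18)."""
        return self.start + 17 if self.strand == "+" else self.start + 3


@dataclass(frozen=True)
class GuideCandidate:
    protospacer: str
    pam_seq: str
    chrom: str
    guide_strand: str
    start: int
    end: int
    cut_site: int
    feature_id: str
    tss_offset: int  # negative = upstream of the TSS, transcript orientation
    bin_index: int | None
    score: float
    offtarget_ok: bool | None = None

    @property
    def guide_id(self) -> str:
        return f"{self.feature_id}:{self.chrom}:{self.start}:{self.guide_strand}"


def scan_pam_sites(genome: Genome, params: DesignParams | None = None) -> list[PamSite]:
    """Enumerate every PAM-adjacent protospacer on both strands.

    A site on the ``+`` strand is a protospacer immediately 5' of an NGG
    (pattern match of ``params.pam``); a ``-`` strand site shows as the
    reverse-complement PAM (CCN for NGG) on the top strand immediately 5' of
    the reverse-complement protospacer.  Sites containing N are excluded.
    Output is sorted by (chrom, start, strand).
    """
    params = params or DesignParams()
    k = params.protospacer_len
    pam = params.pam
    plen = len(pam)
    pam_rc = revcomp(pam)
    sites: list[PamSite] = []
    for chrom in sorted(genome.sequences):
        seq = genome.sequences[chrom]
        n = len(seq)
        # + strand: protospacer [i, i+k), PAM [i+k, i+k+plen)
        for i in range(0, n - k - plen + 1):
            pam_seq = seq[i + k : i + k + plen]
            if _matches_iupac(pam_seq, pam):
                proto = seq[i : i + k]
                if "N" in proto or "N" in pam_seq:
                    continue
                sites.append(PamSite(chrom, "+", i, i + k, proto, pam_seq))
        # - strand: top shows revcomp(PAM) at [j, j+plen), protospacer
        # occupies [j+plen, j+plen+k) read on the bottom strand.
        for j in range(0, n - k - plen + 1):
            top_pam = seq[j : j + plen]
            if _matches_iupac(top_pam, pam_rc):
                top_proto = seq[j + plen : j + plen + k]
                if "N" in top_proto or "N" in top_pam:
                    continue
                sites.append(
                    PamSite(
                        chrom, "-", j + plen, j + plen + k,
                        revcomp(top_proto), revcomp(top_pam),
                    )
                )
    sites.sort(key=lambda s: (s.chrom, s.start, s.strand))
    return sites


def tss_offset_of(cut_site: int, feature: Feature) -> int:
    """Signed cut-site offset from the TSS in transcript orientation."""
    if feature.strand == "+":
        return cut_site - feature.tss
    return feature.tss - cut_site


def bin_index_of(offset: int, params: DesignParams) -> int | None:
    """Bin for an offset in [-bin_region, 0); None outside.

    Bins are half-open 50-bp tiles: [-300,-250) -> 0 ... [-50, 0) -> 5 under
    defaults.
    """
    if -params.bin_region <= offset < 0:
        return (offset + params.bin_region) // params.bin_width
    return None


def default_score(protospacer: str) -> float:
    """Deterministic on-target heuristic in [0, 1].

    score = clamp(1 - 2*|gc - 0.5| - 0.25*H, 0, 1) where gc is the G+C
    fraction and H is 1 when any single-nucleotide run reaches 5.  Guides of
    balanced GC without homopolymer runs score 1.
    """
    if len(protospacer) != 20 or set(protospacer) - set("ACGT"):
        raise ValueError(f"protospacer must be 20 nt over ACGT: {protospacer!r}")
    gc = sum(b in "GC" for b in protospacer) / len(protospacer)
    run = 1
    homopolymer = False
    for a, b in zip(protospacer, protospacer[1:]):
        run = run + 1 if a == b else 1
        if run >= 5:
            homopolymer = True
            break
    raw = 1.0 - 2.0 * abs(gc - 0.5) - (0.25 if homopolymer else 0.0)
    return min(1.0, max(0.0, raw))


def candidates_for_feature(
    feature: Feature,
    sites: Sequence[PamSite],
    params: DesignParams | None = None,
    scorer: Callable[[str], float] = default_score,
) -> list[GuideCandidate]:
    """Sites on the feature's chromosome whose cut site falls in the TSS
    window [-window_upstream, +window_downstream] (closed interval)."""
    params = params or DesignParams()
    out = []
    for site in sites:
        if site.chrom != feature.chrom:
            continue
        offset = tss_offset_of(site.cut_site, feature)
        if -params.window_upstream <= offset <= params.window_downstream:
            out.append(
                GuideCandidate(
                    protospacer=site.protospacer,
                    pam_seq=site.pam_seq,
                    chrom=site.chrom,
                    guide_strand=site.strand,
                    start=site.start,
                    end=site.end,
                    cut_site=site.cut_site,
                    feature_id=feature.feature_id,
                    tss_offset=offset,
                    bin_index=bin_index_of(offset, params),
                    score=scorer(site.protospacer),
                )
            )
    return out


def select_guides(
    candidates: Sequence[GuideCandidate], params: DesignParams | None = None
) -> list[GuideCandidate]:
    """Per-feature selection: all candidates when fewer than six exist,
    otherwise the top-scoring guide from each 50-bp bin.

    In bin mode, candidates outside the binned [-300, 0) region are
    ineligible.  Score ties break to the smaller |tss_offset|, then the
    lexicographically smaller protospacer, keeping libraries reproducible.
    """
    params = params or DesignParams()
    if not candidates:
        return []
    feature_ids = {c.feature_id for c in candidates}
    if len(feature_ids) != 1:
        raise ValueError("select_guides expects candidates of a single feature")
    if len(candidates) < params.max_per_feature:
        return list(candidates)
    best: dict[int, GuideCandidate] = {}
    for cand in candidates:
        if cand.bin_index is None:
            continue
        key = (-cand.score, abs(cand.tss_offset), cand.protospacer)
        incumbent = best.get(cand.bin_index)
        if incumbent is None or key < (
            -incumbent.score, abs(incumbent.tss_offset), incumbent.protospacer
        ):
            best[cand.bin_index] = cand
    return [best[b] for b in sorted(best)]


def design_library(
    genome: Genome,
    features: Iterable[Feature],
    params: DesignParams | None = None,
    scorer: Callable[[str], float] = default_score,
    sites: Sequence[PamSite] | None = None,
) -> list[GuideCandidate]:
    """Full design pass: scan PAMs once, then window + bin-select per feature."""
    params = params or DesignParams()
    if sites is None:
        sites = scan_pam_sites(genome, params)
    by_chrom: dict[str, list[PamSite]] = {}
    for site in sites:
        by_chrom.setdefault(site.chrom, []).append(site)
    library: list[GuideCandidate] = []
    for feature in features:
        cands = candidates_for_feature(
            feature, by_chrom.get(feature.chrom, []), params, scorer
        )
        library.extend(select_guides(cands, params))
    return library


def library_to_tsv(library: Iterable[GuideCandidate], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "feature_id\tprotospacer\tchrom\tstrand\tstart\tend\t"
            "tss_offset\tbin\tscore\tofftarget_ok\n"
        )
        for g in library:
            bin_s = "" if g.bin_index is None else str(g.bin_index)
            ok = "" if g.offtarget_ok is None else str(g.offtarget_ok).lower()
            fh.write(
                f"{g.feature_id}\t{g.protospacer}\t{g.chrom}\t{g.guide_strand}\t"
                f"{g.start}\t{g.end}\t{g.tss_offset}\t{bin_s}\t{g.score:.4f}\t{ok}\n"
            )


def library_to_fasta(library: Iterable[GuideCandidate], path) -> None:
    with open(path, "w") as fh:
        for g in library:
            fh.write(f">{g.guide_id}\n{g.protospacer}\n")


def with_offtarget_flag(
    candidate: GuideCandidate, ok: bool
) -> GuideCandidate:
    return replace(candidate, offtarget_ok=ok)
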