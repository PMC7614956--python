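"""Synthetic data generators for end-to-end testing without downloads.

Three generators mirror the three experimental layers: a toy genome whose
promoters carry plantable PAM sites (so the design stage always has
material), an NB-distributed screen count table with spiked enrichment (the
statistical structure the readout model assumes), and FASTQ read pools
emitted from a known count matrix (so quantification can be checked by
round trip).  All generators are pure functions of their parameters and a
seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import Feature, Genome
from .quantify import CountTable, SampleSheet

_BASES = np.array(list("ACGT"))

# Promoter geometry the planted sites must respect (cut site inside the
# binned [-300, 0) region; cut site sits 17 nt into a + strand protospacer).
_BIN_REGION = 300
_FEATURE_STRIDE = 620  # window [-400, +100] plus margin


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def simulate_genome(
    n_features: int = 10,
    promoter_pam_min: int = 6,
    length: int = 20_000,
    seed: int = 0,
) -> tuple[Genome, list[Feature]]:
    """A random genome with TSS-anchored features and guaranteed promoter
    PAM sites.

    Each feature's binned promoter region ([-300, 0) upstream of its TSS)
    receives at least ``promoter_pam_min`` planted protospacer+NGG sites,
    one per 50-bp bin first, so the design stage can always fill its bins.
    Features alternate strand and are spaced so their design windows never
    overlap.  Deterministic given the seed.
    """
    needed = n_features * _FEATURE_STRIDE + _FEATURE_STRIDE
    if length < needed:
        raise ValueError(
            f"length {length} cannot pack {n_features} features "
            f"(needs >= {needed})"
        )
    if promoter_pam_min > 12:
        raise ValueError("at most 12 sites can be planted per promoter")
    rng = np.random.default_rng(seed)
    seq = list(_random_seq(rng, length))
    features: list[Feature] = []
    for i in range(n_features):
        tss = _FEATURE_STRIDE // 2 + 400 + i * _FEATURE_STRIDE
        strand = "+" if i % 2 == 0 else "-"
        span = (tss, tss + 300) if strand == "+" else (tss - 299, tss + 1)
        ftype = ("ORF", "SUT", "CUT")[i % 3]
        features.append(
            Feature(
                feature_id=f"FEAT{i:03d}",
                feature_type=ftype,
                chrom="chrSim",
                strand=strand,
                tss=tss,
                span=span,
            )
        )
        # Plant one site per 50-bp bin (then a second pass) until the quota
        # is met; sites are spaced >= 25 apart so they never overlap.
        offsets = []
        n_bins = _BIN_REGION // 50
        for k in range(promoter_pam_min):
            b = k % n_bins
            sub = 5 if k < n_bins else 30
            offsets.append(-_BIN_REGION + b * 50 + sub)
        for off in offsets:
            cut = tss + off if strand == "+" else tss - off
            proto = _random_seq(rng, 20)
            cassette = proto + "TGG"  # protospacer + NGG on the + strand
            start = cut - 17
            seq[start : start + 23] = list(cassette)
    genome = Genome({"chrSim": "".join(seq)})
    return genome, features


@dataclass(frozen=True)
class ScreenSimParams:
    """Conditions of a simulated sorting screen.

    Defaults reflect a deeply sequenced pooled screen: a few thousand
    guides, four replicates per fraction, mean depth 200 reads per guide,
    NB dispersion 0.15, 5% of guides truly enriched in the high fraction
    at log2FC 4.
    """

    n_guides: int = 2000
    n_samples_per_group: int = 4
    mean_depth: float = 200.0
    dispersion: float = 0.15
    spike_fraction: float = 0.05
    spike_log2fc: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_guides <= 0 or self.n_samples_per_group <= 0:
            raise ValueError("counts must be positive")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be nonnegative")
        if not 0 <= self.spike_fraction <= 1:
            raise ValueError("spike_fraction must lie in [0, 1]")


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, phi: float
) -> np.ndarray:
    if phi <= 0:
        return rng.poisson(mean)
    shape = 1.0 / phi  # gamma-Poisson mixture: var = mu + phi mu^2
    lam = rng.gamma(shape, mean * phi)
    return rng.poisson(lam)


def simulate_screen_counts(
    params: ScreenSimParams,
) -> tuple[CountTable, pd.Series]:
    """NB count table for a two-fraction screen with spiked enrichment.

    Per-guide baseline abundances are lognormal around ``mean_depth``
    (library skew); spiked guides are shifted symmetrically — up by half the
    effect in the high fraction, down by half in the low — so fraction
    library sizes stay comparable.  Returns the table and boolean truth
    labels indexed by guide id.
    """
    rng = np.random.default_rng(params.seed)
    g, n = params.n_guides, params.n_samples_per_group
    guide_ids = [f"g{i:05d}" for i in range(g)]
    base = params.mean_depth * rng.lognormal(mean=-0.125, sigma=0.5, size=g)
    n_spike = round(params.spike_fraction * g)
    spiked = np.zeros(g, dtype=bool)
    if n_spike:
        spiked[rng.choice(g, size=n_spike, replace=False)] = True
    half = 2.0 ** (params.spike_log2fc / 2.0)
    mean_high = np.where(spiked, base * half, base)
    mean_low = np.where(spiked, base / half, base)
    cols: dict[str, np.ndarray] = {}
    fractions: dict[str, str] = {}
    for j in range(n):
        sid = f"high_{j + 1}"
        cols[sid] = _nb_draw(rng, mean_high, params.dispersion)
        fractions[sid] = "high"
    for j in range(n):
        sid = f"low_{j + 1}"
        cols[sid] = _nb_draw(rng, mean_low, params.dispersion)
        fractions[sid] = "low"
    counts = pd.DataFrame(cols, index=guide_ids)
    table = CountTable(counts=counts, fractions=fractions)
    return table, pd.Series(spiked, index=guide_ids, name="spiked")


DEFAULT_FLANK = "GGAAAGGACGAAACACCG"  # U6-style vector sequence before the guide
DEFAULT_ADAPTER = "GTTTAAGAGCTAAGCTGG"  # scaffold start after the guide


def simulate_reads(
    table: CountTable,
    library: dict[str, str],
    sheet: SampleSheet,
    flank: str = DEFAULT_FLANK,
    adapter: str = DEFAULT_ADAPTER,
    seed: int = 0,
) -> list[tuple[str, str, str]]:
    """Emit exactly count_ij reads of barcode.flank.guide.adapter, shuffled.

    ``library`` maps guide id (the table's row index) to its 20-mer.
    Returns (read_id, sequence, quality) tuples ready for FASTQ writing.
    """
    missing = set(table.guide_ids) - set(library)
    if missing:
        raise ValueError(f"table guides missing from library: {sorted(missing)[:5]}")
    barcodes = {s.sample_id: s.barcode for s in sheet.samples}
    reads: list[tuple[str, str, str]] = []
    k = 0
    for sid in table.sample_ids:
        bc = barcodes[sid]
        col = table.counts[sid]
        for gid, count in col.items():
            seq = bc + flank + library[gid] + adapter
            for _ in range(int(count)):
                reads.append((f"read_{k}", seq, "I" * len(seq)))
                k += 1
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(reads))
    return [reads[i] for i in order]


def write_fastq(reads: list[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
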