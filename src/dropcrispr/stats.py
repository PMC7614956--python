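"""Screen readout statistics.

Guide enrichment between the high- and low-fluorescence droplet fractions is
tested guide-by-guide with a negative-binomial (NB) log-link GLM: the full
model fits one mean per fraction (offset by the effective library size), the
reduced model a single mean, and twice the log-likelihood difference is
referred to chi-square with one degree of freedom.  Counts are normalized
with relative-log-expression (RLE, median-of-ratios) size factors; the NB
dispersion phi (variance mu + phi*mu^2) is estimated by maximizing the
Cox-Reid adjusted profile likelihood shared across guides, optionally shrunk
per guide.  P-values are Benjamini-Hochberg adjusted and guides are called
enriched at the strict gate log2FC > 3 and FDR < 0.05; per-gene
representatives take the highest fold-change guide passing a relaxed FDR <
0.3 gate.

Droplet helpers convert a Poisson loading mean (cells per droplet, lambda)
into occupancy probabilities, and droplets x lambda / library size into the
screen's fold coverage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats as sps
from statsmodels.stats.multitest import multipletests

from .quantify import CountTable

_MIN_MU = 1e-10
_BETA_CLAMP = 40.0


# ---------------------------------------------------------------- filtering

def low_count_filter(
    table: CountTable, min_cpm: float = 1.0, min_samples: float = 0.5
) -> tuple[CountTable, dict]:
    """Drop guides sequenced below ``min_cpm`` counts-per-million in more
    than ``1 - min_samples`` of samples.

    Returns the filtered table and a small report (kept count, kept fraction
    of the pool) mirroring how screens report the surviving guide pool.
    """
    counts = table.counts
    if counts.empty:
        raise ValueError("empty count table")
    libsize = counts.sum(axis=0).to_numpy(dtype=float)
    if (libsize == 0).any():
        raise ValueError("sample with zero total counts")
    cpm = counts.to_numpy(dtype=float) / libsize * 1e6
    need = math.ceil(min_samples * counts.shape[1])
    keep = (cpm > min_cpm).sum(axis=1) >= need
    kept = CountTable(
        counts=counts.loc[keep],
        fractions=table.fractions,
        unassigned=table.unassigned,
    )
    report = {
        "kept": int(keep.sum()),
        "total": int(counts.shape[0]),
        "kept_fraction": float(keep.mean()),
    }
    return kept, report


# ------------------------------------------------------------ normalization

@dataclass(frozen=True)
class NormFactors:
    """Per-sample RLE size factors, rescaled to geometric mean 1."""

    factors: pd.Series  # indexed by sample id
    library_sizes: pd.Series

    @property
    def effective_library_sizes(self) -> pd.Series:
        return self.library_sizes * self.factors


def rle_norm_factors(table: CountTable) -> NormFactors:
    """Median-of-ratios size factors.

    For each guide with positive counts in every sample, form the ratio of
    each sample's count to the guide's geometric mean across samples; the
    per-sample median of those ratios, rescaled so the factors have
    geometric mean 1, is the sample's factor.
    """
    counts = table.counts.to_numpy(dtype=float)
    libsize = pd.Series(
        table.counts.sum(axis=0), index=table.counts.columns, dtype=float
    )
    all_pos = (counts > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no guide has positive counts in every sample; "
            "apply low_count_filter first"
        )
    pos = counts[all_pos]
    log_geomean = np.log(pos).mean(axis=1, keepdims=True)
    ratios = pos / np.exp(log_geomean)
    factors = np.median(ratios, axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormFactors(
        factors=pd.Series(factors, index=table.counts.columns),
        library_sizes=libsize,
    )


# --------------------------------------------------------- NB GLM machinery

def nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    """Row-wise NB log-likelihood (phi = 0 falls back to Poisson)."""
    mu = np.maximum(mu, _MIN_MU)
    if phi <= 0:
        return (y * np.log(mu) - mu - special.gammaln(y + 1)).sum(axis=-1)
    alpha = 1.0 / phi
    return (
        special.gammaln(y + alpha)
        - special.gammaln(alpha)
        - special.gammaln(y + 1)
        + alpha * np.log(alpha / (alpha + mu))
        + y * np.log(mu / (alpha + mu))
    ).sum(axis=-1)


def _fit_intercept(
    y: np.ndarray, offsets: np.ndarray, phi: float, n_iter: int = 50
) -> np.ndarray:
    """Vectorized Newton fit of one log-scale intercept per guide row.

    Model mu_ij = exp(beta_i + o_j); solves the NB score equation
    sum_j (y - mu) / (1 + phi * mu) = 0 per row.
    """
    expo = np.exp(offsets)[None, :]
    total = y.sum(axis=1)
    beta = np.log(np.maximum(total, 0.5) / expo.sum())
    for _ in range(n_iter):
        mu = np.exp(np.clip(beta[:, None], -_BETA_CLAMP, _BETA_CLAMP)) * expo
        denom = 1.0 + phi * mu
        score = ((y - mu) / denom).sum(axis=1)
        info = (mu * (1.0 + phi * y) / denom**2).sum(axis=1)
        step = score / np.maximum(info, 1e-12)
        step = np.clip(step, -5.0, 5.0)
        beta = np.clip(beta + step, -_BETA_CLAMP, _BETA_CLAMP)
        if np.max(np.abs(step)) < 1e-10:
            break
    return beta


def _group_masks(groups: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    g = np.asarray(groups)
    labels = set(g.tolist())
    if labels != {"high", "low"}:
        raise ValueError(
            f"expected exactly the two fractions high/low, got {sorted(labels)}"
        )
    return g == "high", g == "low"


@dataclass(frozen=True)
class DispersionEstimate:
    common: float
    tagwise: np.ndarray | None = None
    prior_df: float = 10.0


def _apl(
    y: np.ndarray,
    offsets: np.ndarray,
    high: np.ndarray,
    low: np.ndarray,
    phi: float,
) -> np.ndarray:
    """Per-guide Cox-Reid adjusted profile log-likelihood at dispersion phi.

    The two-fraction design is group-saturated, so the full-model fit
    decomposes into two independent intercept fits and the Cox-Reid
    adjustment is -0.5 * sum over groups of log(sum of working weights).
    """
    mu = np.empty_like(y, dtype=float)
    cr = np.zeros(y.shape[0])
    for mask in (high, low):
        beta = _fit_intercept(y[:, mask], offsets[mask], phi)
        mu_g = np.exp(np.clip(beta[:, None], -_BETA_CLAMP, _BETA_CLAMP)) * np.exp(
            offsets[mask]
        )[None, :]
        mu[:, mask] = mu_g
        w = mu_g / (1.0 + phi * mu_g)
        cr += np.log(np.maximum(w.sum(axis=1), _MIN_MU))
    return nb_loglik(y, mu, phi) - 0.5 * cr


def estimate_dispersion(
    table: CountTable,
    factors: NormFactors,
    groups: Mapping[str, str] | None = None,
    tagwise: bool = False,
    prior_df: float = 10.0,
    grid: tuple[float, float, int] = (1e-4, 4.0, 25),
) -> DispersionEstimate:
    """Common (and optionally shrunk tagwise) NB dispersion.

    The common dispersion maximizes the summed Cox-Reid adjusted profile
    likelihood over a log-spaced grid on [1e-4, 4], refined by golden-section
    search to an absolute tolerance of 1e-4.  Tagwise dispersions maximize a
    weighted likelihood that shrinks each guide toward the common value with
    weight ``prior_df``.
    """
    counts = table.counts
    if counts.shape[1] < 2:
        raise ValueError("dispersion estimation needs at least two samples")
    labels = groups or table.fractions
    group_vec = [labels[s] for s in counts.columns]
    high, low = _group_masks(group_vec)
    y = counts.to_numpy(dtype=float)
    informative = y.sum(axis=1) > 0
    y = y[informative]
    offsets = np.log(factors.effective_library_sizes.loc[counts.columns].to_numpy())

    lo, hi, n_grid = grid
    phis = np.geomspace(lo, hi, int(n_grid))
    apl_sums = np.array(
        [_apl(y, offsets, high, low, p).sum() for p in phis]
    )
    best = int(np.argmax(apl_sums))
    a = phis[max(best - 1, 0)]
    b = phis[min(best + 1, len(phis) - 1)]
    if a == b:
        common = float(a)
    else:
        res = optimize.minimize_scalar(
            lambda p: -_apl(y, offsets, high, low, p).sum(),
            bounds=(a, b),
            method="bounded",
            options={"xatol": 1e-4},
        )
        common = float(res.x)
    tag = None
    if tagwise:
        apl_matrix = np.stack(
            [_apl(y, offsets, high, low, p) for p in phis]
        )  # grid x guides
        mean_apl = apl_matrix.mean(axis=1, keepdims=True)
        n_resid = max(y.shape[1] - 2, 1)
        weighted = apl_matrix + (prior_df / n_resid) * mean_apl
        picked = phis[np.argmax(weighted, axis=0)]
        tag_full = np.full(counts.shape[0], common)
        tag_full[np.flatnonzero(informative)] = picked
        tag = tag_full
    return DispersionEstimate(common=common, tagwise=tag, prior_df=prior_df)


# ------------------------------------------------------------------ testing

RESULT_COLUMNS = ["guide_id", "log2fc", "lr_stat", "p_value", "fdr", "enriched"]


def glm_lrt(
    table: CountTable,
    factors: NormFactors,
    dispersion: DispersionEstimate,
    groups: Mapping[str, str] | None = None,
    prior_count: float = 0.125,
    lfc_threshold: float = 3.0,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-guide NB GLM likelihood-ratio test of high vs low fraction.

    Full model: one mean per fraction with log effective-library-size
    offsets; reduced model: a single mean.  The LR statistic is referred to
    chi-square (1 df).  The reported log2 fold change adds a prior count of
    0.125 to each fraction's pooled rate to stabilize zero-count guides; the
    test itself uses raw counts.  Returns a DataFrame with columns
    guide_id, log2fc, lr_stat, p_value, fdr, enriched.
    """
    counts = table.counts
    labels = groups or table.fractions
    group_vec = [labels[s] for s in counts.columns]
    high, low = _group_masks(group_vec)
    y = np.asarray(counts.to_numpy(dtype=float))
    offsets = np.log(factors.effective_library_sizes.loc[counts.columns].to_numpy())
    phi = dispersion.common

    nonzero = y.sum(axis=1) > 0
    yz = y[nonzero]
    lr = np.zeros(y.shape[0])
    if yz.shape[0]:
        mu_full = np.empty_like(yz)
        for mask in (high, low):
            beta = _fit_intercept(yz[:, mask], offsets[mask], phi)
            mu_full[:, mask] = np.exp(
                np.clip(beta[:, None], -_BETA_CLAMP, _BETA_CLAMP)
            ) * np.exp(offsets[mask])[None, :]
        beta0 = _fit_intercept(yz, offsets, phi)
        mu_red = np.exp(np.clip(beta0[:, None], -_BETA_CLAMP, _BETA_CLAMP)) * np.exp(
            offsets
        )[None, :]
        lr[nonzero] = np.maximum(
            2.0 * (nb_loglik(yz, mu_full, phi) - nb_loglik(yz, mu_red, phi)), 0.0
        )
    p = np.ones(y.shape[0])
    p[nonzero] = sps.chi2.sf(lr[nonzero], df=1)

    # Reported fold change: pooled per-fraction rates with a prior count.
    eff = np.exp(offsets)
    rate_high = (y[:, high].sum(axis=1) + prior_count) / eff[high].sum()
    rate_low = (y[:, low].sum(axis=1) + prior_count) / eff[low].sum()
    log2fc = np.log2(rate_high / rate_low)
    log2fc[~nonzero] = 0.0

    fdr = bh_adjust(p)
    out = pd.DataFrame(
        {
            "guide_id": counts.index,
            "log2fc": log2fc,
            "lr_stat": lr,
            "p_value": p,
            "fdr": fdr,
        }
    )
    return call_enriched(out, lfc_threshold, fdr_threshold)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment (values must lie in (0,1])."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_enriched(
    results: pd.DataFrame, lfc_threshold: float = 3.0, fdr_threshold: float = 0.05
) -> pd.DataFrame:
    """Flag guides enriched at the strict gate (both inequalities strict)."""
    out = results.copy()
    out["enriched"] = (out["log2fc"] > lfc_threshold) & (out["fdr"] < fdr_threshold)
    return out


def summarize_genes(
    results: pd.DataFrame,
    guide_to_gene: Mapping[str, str],
    lfc_threshold: float = 3.0,
    fdr_threshold: float = 0.3,
) -> pd.DataFrame:
    """One representative guide per gene: the highest fold-change guide
    passing log2FC > lfc_threshold and FDR < fdr_threshold (relaxed gate).
    Genes without a passing guide are omitted."""
    missing = set(results["guide_id"]) - set(guide_to_gene)
    if missing:
        raise ValueError(f"guides without gene mapping: {sorted(missing)[:5]}")
    df = results.copy()
    df["gene_id"] = df["guide_id"].map(guide_to_gene)
    passing = df[(df["log2fc"] > lfc_threshold) & (df["fdr"] < fdr_threshold)]
    if passing.empty:
        return pd.DataFrame(
            columns=["gene_id", "representative_guide", "log2fc", "fdr"]
        )
    idx = passing.groupby("gene_id")["log2fc"].idxmax()
    reps = passing.loc[idx]
    out = pd.DataFrame(
        {
            "gene_id": reps["gene_id"].to_numpy(),
            "representative_guide": reps["guide_id"].to_numpy(),
            "log2fc": reps["log2fc"].to_numpy(),
            "fdr": reps["fdr"].to_numpy(),
        }
    ).sort_values("gene_id", ignore_index=True)
    return out


# ------------------------------------------------------- droplet arithmetic

@dataclass(frozen=True)
class ScreenDesign:
    """A droplet screen sizing: droplets screened, Poisson loading mean
    (cells per droplet), and the designed guide library size."""

    n_droplets: int
    lam: float = 0.4
    library_size: int = 0

    def __post_init__(self) -> None:
        if self.n_droplets < 0:
            raise ValueError("n_droplets must be nonnegative")
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")


def fold_coverage(design: ScreenDesign) -> float:
    """Screen fold coverage: droplets x loading mean / library size."""
    return design.n_droplets * design.lam / design.library_size


def droplet_occupancy(lam: float) -> tuple[float, float, float]:
    """Poisson loading occupancy: P(empty), P(single cell), P(multiple)."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    empty = math.exp(-lam)
    single = lam * math.exp(-lam)
    return empty, single, 1.0 - empty - single
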