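"""Variant calling from pooled allele counts, dual-caller consensus, the
low-VAF artifact filter, and cultivar heterogeneity.

In pool-seq the fraction of reads carrying the alternative allele (VAF)
estimates the allele frequency among the pooled plants.  Two transparent
caller analogues are provided — a frequency-threshold caller and an exact
one-sided binomial caller against the sequencing error rate — and only sites
detected by both are retained (consensus), mirroring the dual-caller design
used for amplicon panels.  Variants whose VAF never reaches the floor
(default 20%) in any cultivar are then discarded as likely artifacts from
sequencing error, PCR mispriming or off-target amplification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genemodel import GenomicSite

__all__ = [
    "CALLER_THRESHOLD",
    "CALLER_BINOMIAL",
    "AlleleCountMatrix",
    "VariantCall",
    "ConsensusCall",
    "HeterogeneityReport",
    "ThresholdParams",
    "BinomialParams",
    "estimate_vaf",
    "vaf_matrix",
    "call_variants_threshold",
    "call_variants_binomial",
    "consensus",
    "filter_low_vaf",
    "heterogeneity",
]

CALLER_THRESHOLD = "caller_a_threshold"
CALLER_BINOMIAL = "caller_b_binomial"

DEFAULT_MIN_DEPTH = 8
DEFAULT_VAF_FLOOR = 0.20


@dataclass
class AlleleCountMatrix:
    """Per-(site, cultivar) ref/alt read counts from pooled sequencing."""

    sites: list[GenomicSite]
    cultivars: list[str]
    ref_count: np.ndarray  # (n_sites, n_cultivars) ints
    alt_count: np.ndarray
    gene_ids: list[str] | None = None

    def __post_init__(self) -> None:
        shape = (len(self.sites), len(self.cultivars))
        self.ref_count = np.asarray(self.ref_count, dtype=np.int64)
        self.alt_count = np.asarray(self.alt_count, dtype=np.int64)
        for name, mat in (("ref_count", self.ref_count), ("alt_count", self.alt_count)):
            if mat.shape != shape:
                raise ValueError(f"{name} shape {mat.shape} != (sites, cultivars) {shape}")
            if (mat < 0).any():
                raise ValueError(f"{name} contains negative counts")
        if self.gene_ids is not None and len(self.gene_ids) != len(self.sites):
            raise ValueError("gene_ids length must match sites")

    @property
    def depth(self) -> np.ndarray:
        return self.ref_count + self.alt_count

    @property
    def n_sites(self) -> int:
        return len(self.sites)


@dataclass
class VariantCall:
    """One called site from one caller with per-cultivar VAFs.

    ``vaf`` is NaN where the depth is below the caller's minimum (no
    evidence, not imputed).
    """

    site: GenomicSite
    caller_id: str
    cultivars: list[str]
    vaf: np.ndarray
    depth: np.ndarray
    gene_id: str | None = None


@dataclass
class ConsensusCall:
    """A site detected by both callers; carries each caller's VAF vector."""

    site: GenomicSite
    cultivars: list[str]
    vaf: dict[str, np.ndarray]
    depth: np.ndarray
    gene_id: str | None = None

    def max_vaf(self) -> float:
        stacked = np.concatenate(list(self.vaf.values()))
        return float(np.nanmax(stacked)) if not np.all(np.isnan(stacked)) else float("nan")

    def mean_vaf(self) -> np.ndarray:
        """Per-cultivar VAF averaged across callers (NaN-aware)."""
        stacked = np.vstack(list(self.vaf.values()))
        with np.errstate(invalid="ignore"):
            return np.nanmean(stacked, axis=0)


@dataclass
class HeterogeneityReport:
    """Per (cultivar, gene) counts of intermediate-VAF sites, plus flags."""

    counts: pd.DataFrame  # index cultivar, columns gene
    flagged: pd.Series  # bool per cultivar
    band: tuple[float, float]

    @property
    def flagged_fraction(self) -> float:
        return float(self.flagged.mean())


@dataclass(frozen=True)
class ThresholdParams:
    min_depth: int = DEFAULT_MIN_DEPTH
    min_alt_reads: int = 2
    min_vaf_call: float = 0.05

    def __post_init__(self) -> None:
        if self.min_depth <= 0 or self.min_alt_reads <= 0 or self.min_vaf_call <= 0:
            raise ValueError("threshold caller parameters must be positive")


@dataclass(frozen=True)
class BinomialParams:
    min_depth: int = DEFAULT_MIN_DEPTH
    error_rate: float = 0.005
    alpha: float = 1e-6

    def __post_init__(self) -> None:
        if self.min_depth <= 0:
            raise ValueError("min_depth must be positive")
        if not 0 <= self.error_rate < 0.1:
            raise ValueError("error_rate must be in [0, 0.1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def estimate_vaf(ref_count: int, alt_count: int, min_depth: int = DEFAULT_MIN_DEPTH) -> float:
    """alt/(ref+alt) when depth reaches min_depth, else NaN (missing)."""
    if ref_count < 0 or alt_count < 0:
        raise ValueError("counts must be non-negative")
    depth = ref_count + alt_count
    if depth < min_depth:
        return float("nan")
    return alt_count / depth


def vaf_matrix(counts: AlleleCountMatrix, min_depth: int = DEFAULT_MIN_DEPTH) -> np.ndarray:
    depth = counts.depth
    with np.errstate(divide="ignore", invalid="ignore"):
        vaf = np.where(depth > 0, counts.alt_count / np.maximum(depth, 1), np.nan)
    vaf = np.where(depth >= min_depth, vaf, np.nan)
    return vaf


def _make_calls(
    counts: AlleleCountMatrix, called: np.ndarray, vaf: np.ndarray, caller_id: str
) -> list[VariantCall]:
    calls = []
    for i in np.flatnonzero(called):
        calls.append(
            VariantCall(
                site=counts.sites[i],
                caller_id=caller_id,
                cultivars=list(counts.cultivars),
                vaf=vaf[i].copy(),
                depth=counts.depth[i].copy(),
                gene_id=counts.gene_ids[i] if counts.gene_ids else None,
            )
        )
    return calls


def call_variants_threshold(
    counts: AlleleCountMatrix, params: ThresholdParams = ThresholdParams()
) -> list[VariantCall]:
    """Frequency-threshold caller: a site is called when at least one
    cultivar has depth ≥ min_depth, alt reads ≥ min_alt_reads and VAF ≥
    min_vaf_call.  VAFs are reported for all cultivars at called sites."""
    if counts.n_sites == 0:
        return []
    vaf = vaf_matrix(counts, params.min_depth)
    depth = counts.depth
    ok = (
        (depth >= params.min_depth)
        & (counts.alt_count >= params.min_alt_reads)
        & (np.nan_to_num(vaf, nan=-1.0) >= params.min_vaf_call)
    )
    return _make_calls(counts, ok.any(axis=1), vaf, CALLER_THRESHOLD)


def binomial_pvalues(
    alt_count: np.ndarray, depth: np.ndarray, error_rate: float
) -> np.ndarray:
    """One-sided exact binomial tail P(X >= alt) with X ~ Binom(depth, e)."""
    alt = np.asarray(alt_count)
    return stats.binom.sf(alt - 1, np.asarray(depth), error_rate)


def call_variants_binomial(
    counts: AlleleCountMatrix, params: BinomialParams = BinomialParams()
) -> list[VariantCall]:
    """Exact-binomial caller: a site is called when in at least one cultivar
    a one-sided test of alt reads against Binomial(depth, error_rate)
    rejects at level alpha."""
    if counts.n_sites == 0:
        return []
    vaf = vaf_matrix(counts, params.min_depth)
    depth = counts.depth
    pvals = binomial_pvalues(counts.alt_count, depth, params.error_rate)
    ok = (depth >= params.min_depth) & (pvals < params.alpha)
    return _make_calls(counts, ok.any(axis=1), vaf, CALLER_BINOMIAL)


def consensus(
    calls_a: list[VariantCall], calls_b: list[VariantCall]
) -> list[ConsensusCall]:
    """Sites called by both callers, keyed on (chrom, pos, ref, alt); each
    retained site carries both callers' VAF vectors."""
    index_b = {call.site.key: call for call in calls_b}
    merged = []
    for call_a in calls_a:
        call_b = index_b.get(call_a.site.key)
        if call_b is None:
            continue
        if call_a.cultivars != call_b.cultivars:
            raise ValueError("callers disagree on cultivar panel")
        merged.append(
            ConsensusCall(
                site=call_a.site,
                cultivars=list(call_a.cultivars),
                vaf={call_a.caller_id: call_a.vaf, call_b.caller_id: call_b.vaf},
                depth=call_a.depth,
                gene_id=call_a.gene_id or call_b.gene_id,
            )
        )
    return merged


def filter_low_vaf(
    calls: list[ConsensusCall], vaf_floor: float = DEFAULT_VAF_FLOOR
) -> list[ConsensusCall]:
    """Drop variants whose VAF stays below the floor in every cultivar.

    The boundary is closed: a single cultivar at exactly the floor retains
    the variant.  Missing VAFs are no evidence and cannot retain a site.
    """
    if not 0 <= vaf_floor <= 1:
        raise ValueError("vaf_floor must be in [0, 1]")
    kept = []
    for call in calls:
        stacked = np.concatenate(list(call.vaf.values()))
        finite = stacked[~np.isnan(stacked)]
        if finite.size and (finite >= vaf_floor).any():
            kept.append(call)
    return kept


def heterogeneity(
    calls: list[ConsensusCall],
    band: tuple[float, float] = (0.2, 0.8),
    gene_of: dict[tuple, str] | None = None,
) -> HeterogeneityReport:
    """Count intermediate-VAF sites per (cultivar, gene).

    A pooled cultivar is heterogeneous at a site when neither allele is
    fixed, i.e. its caller-averaged VAF lies strictly inside ``band``.  A
    cultivar is flagged when any gene shows at least one such site.
    """
    low, high = band
    if not 0 <= low < high <= 1:
        raise ValueError("band must satisfy 0 <= low < high <= 1")
    if not calls:
        empty = pd.DataFrame(dtype=int)
        return HeterogeneityReport(empty, pd.Series(dtype=bool), band)

    cultivars = calls[0].cultivars
    genes = []
    rows = {}
    for call in calls:
        gene = call.gene_id
        if gene is None and gene_of is not None:
            gene = gene_of.get(call.site.key)
        gene = gene or "unassigned"
        if gene not in genes:
            genes.append(gene)
        mean_vaf = call.mean_vaf()
        inside = (mean_vaf > low) & (mean_vaf < high) & ~np.isnan(mean_vaf)
        rows.setdefault(gene, np.zeros(len(cultivars), dtype=int))
        rows[gene] += inside.astype(int)

    counts = pd.DataFrame({g: rows[g] for g in genes}, index=pd.Index(cultivars, name="cultivar"))
    flagged = (counts >= 1).any(axis=1)
    return HeterogeneityReport(counts=counts, flagged=flagged, band=band)
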