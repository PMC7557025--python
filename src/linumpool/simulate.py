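"""Synthetic cohort generator: cultivar pools with known allele frequencies,
pooled read counts, and compositional fatty-acid phenotypes.

The generator emulates the study design the pipeline targets: 84 flax
cultivars/lines, each sequenced as a pool of ~50 diploid plants (so true
within-cultivar alternative-allele frequencies are multiples of 1/100),
mean amplicon coverage 400x, and per-gene variant densities skewed towards
FAD3A and FAD3B.  Two key variants — a FAD3A nonsense and a FAD3B missense —
define three genotype strata (both present / one present / neither) that
drive the linolenic-acid (LIN) class low / mid / high; one cultivar carries
an alternative FAD3A nonsense variant instead (the "A6" exception pattern).
Linoleic acid (LIO) absorbs the complementary change so the five acids close
to a constant compositional total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import datasets
from .calling import AlleleCountMatrix
from .genemodel import GeneModel, GeneReference, GenomicSite, classify_location, codon_effect
from .io import FATTY_ACIDS

__all__ = [
    "ConfigError",
    "CohortConfig",
    "CohortTruth",
    "simulate_truth",
    "simulate_pool_counts",
    "simulate_phenotypes",
    "simulate_cohort",
    "write_cohort",
    "expected_lin",
]

STRATA = ("both", "fad3a_only", "fad3b_only", "alt_nonsense", "neither")


class ConfigError(ValueError):
    """Invalid generator settings."""


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings; the defaults are the emulated study conditions."""

    n_cultivars: int = 84
    pool_size: int = 50
    #: per-gene background site counts, skewed towards FAD3A/FAD3B (about a
    #: third of the dual-caller variant tallies the design emulates)
    sites_per_gene: dict[str, int] = field(
        default_factory=lambda: {
            "SAD1": 4, "SAD2": 4, "FAD2A": 7, "FAD2B": 4, "FAD3A": 30, "FAD3B": 21,
        }
    )
    n_monomorphic: int = 10
    het_fraction: float = 0.3
    het_site_rate: float = 0.2
    prevalence_range: tuple[float, float] = (0.1, 0.6)
    #: when True each background site is fixed (all-ref or all-alt), leaving
    #: the key sites as the only source of between-cultivar variation — the
    #: "low noise" three-strata geometry used for clustering demonstrations
    background_fixed: bool = False
    # genotype strata sizes (remaining cultivars are "neither")
    n_both: int = 9
    n_fad3a_only: int = 2
    n_fad3b_only: int = 2
    n_alt_nonsense: int = 1
    key_high_range: tuple[float, float] = (0.9, 1.0)
    alt_nonsense_vaf: float = 0.8
    n_alt_nonsense_trace: int = 3
    trace_range: tuple[float, float] = (0.05, 0.10)
    # sequencing
    mean_coverage: float = 400.0
    error_rate: float = 0.005
    # phenotypes
    total_pct: float = 97.0
    noise_sd: float = 0.4
    presence_floor: float = 0.4
    lin_windows: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "low": (4.8, 8.2), "mid": (33.0, 44.0), "high": (51.0, 53.0),
        }
    )
    pal_range: tuple[float, float] = (5.3, 7.3)
    ste_range: tuple[float, float] = (3.0, 6.1)
    ole_range: tuple[float, float] = (13.4, 16.8)
    sad_ole_effect: float = 0.5
    noise_weights: dict[str, float] = field(
        default_factory=lambda: {"PAL": 0.2, "STE": 0.2, "OLE": 0.5, "LIN": 1.0}
    )

    def __post_init__(self) -> None:
        if self.n_cultivars < 2 or self.pool_size < 1:
            raise ConfigError("n_cultivars >= 2 and pool_size >= 1 required")
        if any(n < 0 for n in self.sites_per_gene.values()) or self.n_monomorphic < 0:
            raise ConfigError("site counts must be non-negative")
        for name, frac in (("het_fraction", self.het_fraction),
                           ("het_site_rate", self.het_site_rate)):
            if not 0 <= frac <= 1:
                raise ConfigError(f"{name} must be in [0, 1]")
        strata_n = self.n_both + self.n_fad3a_only + self.n_fad3b_only + self.n_alt_nonsense
        if strata_n > self.n_cultivars:
            raise ConfigError("strata sizes exceed n_cultivars")
        if not 0 <= self.error_rate < 0.1:
            raise ConfigError("error_rate must be in [0, 0.1)")
        if self.mean_coverage <= 0:
            raise ConfigError("mean_coverage must be positive")
        if not 90 < self.total_pct <= 100:
            raise ConfigError("total_pct must be in (90, 100]")
        lo, mid, hi = (self.lin_windows[k] for k in ("low", "mid", "high"))
        if not (lo[1] <= 10 and 30 <= mid[0] and mid[1] <= 47 and hi[0] >= 50):
            raise ConfigError(
                "lin_windows must give class means low <= 10, mid in 30-47, high >= 50"
            )

    @classmethod
    def three_strata_demo(cls, **overrides) -> "CohortConfig":
        """Low-noise cohort whose geometry is driven by the key sites."""
        return cls(background_fixed=True, het_fraction=0.0, **overrides)

    @property
    def granularity(self) -> float:
        """Smallest realizable frequency step: 2·pool_size haploid copies."""
        return 1.0 / (2 * self.pool_size)


@dataclass
class CohortTruth:
    """Ground truth for one simulated cohort."""

    config: CohortConfig
    seed: int
    cultivars: list[str]
    sites: list[GenomicSite]
    gene_ids: list[str]
    true_freq: np.ndarray  # (n_sites, n_cultivars) in [0, 1]
    strata: np.ndarray  # per-cultivar stratum label
    key_fad3a_index: int
    key_fad3b_index: int
    alt_nonsense_index: int

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site_index(self, site: GenomicSite) -> int:
        return [s.key for s in self.sites].index(site.key)


def _snap(freq: np.ndarray | float, pool_size: int) -> np.ndarray | float:
    copies = 2 * pool_size
    return np.round(np.asarray(freq, dtype=float) * copies) / copies


def _draw_background_site(
    rng: np.random.Generator,
    model: GeneModel,
    reference: GeneReference,
    used: set[int],
) -> GenomicSite:
    """Random SNP in the gene span ± flank, never a FAD3A nonsense variant.

    FAD3A nonsense alleles are reserved for the designated key/exception
    sites (in a real panel strong purifying selection keeps additional
    loss-of-function alleles rare), so random background variation cannot
    collide with the two-locus classification rule.
    """
    bases = "ACGT"
    while True:
        pos = int(rng.integers(model.gene_start - model.flank_bp,
                               model.gene_end + model.flank_bp + 1))
        if pos in used:
            continue
        ref_base = reference.base_at(pos)
        alt_base = bases[rng.integers(4)]
        if alt_base == ref_base:
            continue
        site = GenomicSite(model.chromosome_id, pos, ref_base, alt_base)
        if model.gene_id == "FAD3A" and model.in_exon(pos):
            effect = codon_effect(site, model, reference)
            if effect.is_nonsense:
                continue
        used.add(pos)
        return site


def simulate_truth(
    config: CohortConfig = CohortConfig(),
    seed: int = 0,
    models: list[GeneModel] | None = None,
    references: dict[str, GeneReference] | None = None,
) -> CohortTruth:
    """Draw ground-truth allele frequencies for a cohort.

    Background sites get a per-site alt prevalence; cultivars are fixed for
    one allele except in heterogeneous cultivars, where a random subset of
    sites takes intermediate frequencies.  All frequencies are snapped to
    multiples of 1/(2·pool_size).
    """
    if models is None:
        models = datasets.load_fixture_gene_models()
    if references is None:
        references = datasets.build_references(models)
    by_id = {m.gene_id: m for m in models}
    rng = np.random.default_rng([seed, 101])
    n = config.n_cultivars
    cultivars = [f"C{i + 1:03d}" for i in range(n)]

    # strata assignment
    strata = np.array(["neither"] * n, dtype=object)
    order = rng.permutation(n)
    cursor = 0
    for label, count in (
        ("both", config.n_both),
        ("fad3a_only", config.n_fad3a_only),
        ("fad3b_only", config.n_fad3b_only),
        ("alt_nonsense", config.n_alt_nonsense),
    ):
        strata[order[cursor : cursor + count]] = label
        cursor += count

    sites: list[GenomicSite] = []
    gene_ids: list[str] = []
    freq_rows: list[np.ndarray] = []
    used_positions: dict[str, set[int]] = {}

    het_cultivar = rng.random(n) < config.het_fraction

    key_sites = {
        "FAD3A": [datasets.KEY_FAD3A_NONSENSE, datasets.ALT_FAD3A_NONSENSE],
        "FAD3B": [datasets.KEY_FAD3B_MISSENSE],
    }
    for gene_id in sorted(config.sites_per_gene):
        model = by_id[gene_id]
        reference = references[gene_id]
        used = used_positions.setdefault(model.chromosome_id, set())
        n_background = config.sites_per_gene[gene_id] - len(key_sites.get(gene_id, []))
        if n_background < 0:
            raise ConfigError(f"{gene_id}: sites_per_gene smaller than its key sites")
        for _ in range(n_background):
            site = _draw_background_site(rng, model, reference, used)
            sites.append(site)
            gene_ids.append(gene_id)
            if config.background_fixed:
                row = np.full(n, float(rng.random() < 0.5))
            else:
                prevalence = rng.uniform(*config.prevalence_range)
                row = (rng.random(n) < prevalence).astype(float)
                het_mask = het_cultivar & (rng.random(n) < config.het_site_rate)
                row[het_mask] = _snap(rng.uniform(0.2, 0.8, het_mask.sum()),
                                      config.pool_size)
            freq_rows.append(row)

    # monomorphic-reference sites (spread over the genes round-robin)
    gene_cycle = sorted(g for g, c in config.sites_per_gene.items() if c > 0) or ["FAD3A"]
    for k in range(config.n_monomorphic):
        gene_id = gene_cycle[k % len(gene_cycle)]
        model = by_id[gene_id]
        used = used_positions.setdefault(model.chromosome_id, set())
        site = _draw_background_site(rng, model, references[gene_id], used)
        sites.append(site)
        gene_ids.append(gene_id)
        freq_rows.append(np.zeros(n))

    # key sites
    def key_row(present_mask: np.ndarray) -> np.ndarray:
        row = np.zeros(n)
        row[present_mask] = _snap(
            rng.uniform(*config.key_high_range, present_mask.sum()), config.pool_size
        )
        return row

    fa_present = np.isin(strata, ["both", "fad3a_only"])
    fb_present = np.isin(strata, ["both", "fad3b_only"])
    alt_present = strata == "alt_nonsense"

    sites.append(datasets.KEY_FAD3A_NONSENSE)
    gene_ids.append("FAD3A")
    key_fad3a_index = len(sites) - 1
    freq_rows.append(key_row(fa_present))

    sites.append(datasets.KEY_FAD3B_MISSENSE)
    gene_ids.append("FAD3B")
    key_fad3b_index = len(sites) - 1
    freq_rows.append(key_row(fb_present))

    sites.append(datasets.ALT_FAD3A_NONSENSE)
    gene_ids.append("FAD3A")
    alt_nonsense_index = len(sites) - 1
    alt_row = np.zeros(n)
    alt_row[alt_present] = _snap(config.alt_nonsense_vaf, config.pool_size)
    carriers = np.flatnonzero(~alt_present)
    n_trace = min(config.n_alt_nonsense_trace, carriers.size)
    if n_trace:
        trace_idx = rng.choice(carriers, size=n_trace, replace=False)
        alt_row[trace_idx] = _snap(rng.uniform(*config.trace_range, n_trace),
                                   config.pool_size)
    freq_rows.append(alt_row)

    true_freq = np.vstack(freq_rows)
    assert ((0 <= true_freq) & (true_freq <= 1)).all()
    return CohortTruth(
        config=config,
        seed=seed,
        cultivars=cultivars,
        sites=sites,
        gene_ids=gene_ids,
        true_freq=true_freq,
        strata=strata,
        key_fad3a_index=key_fad3a_index,
        key_fad3b_index=key_fad3b_index,
        alt_nonsense_index=alt_nonsense_index,
    )


def simulate_pool_counts(
    truth: CohortTruth,
    mean_coverage: float | None = None,
    error_rate: float | None = None,
    seed: int = 0,
) -> AlleleCountMatrix:
    """Pooled read counts: depth ~ Poisson(mean_coverage) and alt reads ~
    Binomial(depth, f·(1−e) + (1−f)·e) for true frequency f and per-base
    error rate e (symmetric miscalls)."""
    config = truth.config
    mean_coverage = config.mean_coverage if mean_coverage is None else mean_coverage
    error_rate = config.error_rate if error_rate is None else error_rate
    if mean_coverage <= 0:
        raise ConfigError("mean_coverage must be positive")
    if not 0 <= error_rate < 0.1:
        raise ConfigError("error_rate must be in [0, 0.1)")
    rng = np.random.default_rng([seed, 211])
    shape = truth.true_freq.shape
    depth = rng.poisson(mean_coverage, size=shape)
    p_alt = truth.true_freq * (1 - error_rate) + (1 - truth.true_freq) * error_rate
    alt = rng.binomial(depth, p_alt)
    return AlleleCountMatrix(
        sites=list(truth.sites),
        cultivars=list(truth.cultivars),
        ref_count=depth - alt,
        alt_count=alt,
        gene_ids=list(truth.gene_ids),
    )


def _lin_class(config: CohortConfig, fa: float, fb: float, falt: float) -> str:
    floor = config.presence_floor
    a, b, alt = fa >= floor, fb >= floor, falt >= floor
    if (a and b) or alt:
        return "low"
    if a or b:
        return "mid"
    return "high"


def expected_lin(config: CohortConfig, fa: float, fb: float, falt: float) -> float:
    """Noise-free LIN percentage for the key-variant frequencies.

    Piecewise-decreasing in the key-site burden fa + fb + falt: each class
    window is traversed top-to-bottom as the burden grows, so raising a key
    frequency never raises LIN.
    """
    burden = fa + fb + falt
    cls = _lin_class(config, fa, fb, falt)
    hi_w: tuple[float, float] = config.lin_windows[cls]
    lo, hi = hi_w
    spans = {"high": (0.0, 2 * config.presence_floor),
             "mid": (config.presence_floor, 1.0 + config.presence_floor),
             "low": (2 * config.presence_floor, 3.0)}
    b0, b1 = spans[cls]
    t = min(max((burden - b0) / (b1 - b0), 0.0), 1.0)
    return hi - (hi - lo) * t


def simulate_phenotypes(
    truth: CohortTruth, noise_sd: float | None = None, seed: int = 0
) -> pd.DataFrame:
    """Compositional phenotypes (percent of total oil) per cultivar.

    LIN follows the genotype class defined by the key variants; PAL, STE and
    OLE are drawn inside the observed ranges (OLE with a weak positive
    dependence on SAD1 allele frequencies); LIO absorbs the residual so the
    five acids sum exactly to ``total_pct``.  Gaussian noise (clipped at
    ±2 sd, per-acid weights) is applied before LIO closes the composition.
    """
    config = truth.config
    noise_sd = config.noise_sd if noise_sd is None else noise_sd
    if noise_sd < 0:
        raise ConfigError("noise_sd must be >= 0")
    rng = np.random.default_rng([seed, 307])
    n = len(truth.cultivars)

    fa = truth.true_freq[truth.key_fad3a_index]
    fb = truth.true_freq[truth.key_fad3b_index]
    falt = truth.true_freq[truth.alt_nonsense_index]

    pal = rng.uniform(*config.pal_range, n)
    ste = rng.uniform(*config.ste_range, n)
    ole = rng.uniform(*config.ole_range, n)
    sad1_rows = [i for i, g in enumerate(truth.gene_ids) if g == "SAD1"]
    if sad1_rows and config.sad_ole_effect:
        ole = ole + config.sad_ole_effect * truth.true_freq[sad1_rows].mean(axis=0)
    lin = np.array([
        expected_lin(config, fa[i], fb[i], falt[i]) for i in range(n)
    ])

    if noise_sd > 0:
        def noise(weight: float, size: int) -> np.ndarray:
            sd = noise_sd * weight
            return np.clip(rng.normal(0.0, sd, size), -2 * sd, 2 * sd)

        pal = pal + noise(config.noise_weights["PAL"], n)
        ste = ste + noise(config.noise_weights["STE"], n)
        ole = ole + noise(config.noise_weights["OLE"], n)
        lin = lin + noise(config.noise_weights["LIN"], n)

    lio = config.total_pct - pal - ste - ole - lin
    table = pd.DataFrame(
        {"PAL": pal, "STE": ste, "OLE": ole, "LIO": lio, "LIN": lin},
        index=pd.Index(truth.cultivars, name="cultivar"),
    )[list(FATTY_ACIDS)]

    ranges = datasets.load_background_ranges()
    for acid in FATTY_ACIDS:
        lo, hi = ranges.loc[acid, "min_pct"], ranges.loc[acid, "max_pct"]
        bad = (table[acid] <= 0) | (table[acid] < lo) | (table[acid] > hi)
        if bad.any():
            raise ConfigError(
                f"configured effects push {acid} outside [{lo}, {hi}] "
                f"for cultivar(s) {table.index[bad].tolist()[:5]}"
            )
    return table


def simulate_cohort(
    config: CohortConfig = CohortConfig(), seed: int = 0,
    models: list[GeneModel] | None = None,
    references: dict[str, GeneReference] | None = None,
) -> tuple[CohortTruth, AlleleCountMatrix, pd.DataFrame]:
    """Truth, pooled counts and phenotypes in one call (sub-seeds derived)."""
    truth = simulate_truth(config, seed=seed, models=models, references=references)
    counts = simulate_pool_counts(truth, seed=seed)
    phenotypes = simulate_phenotypes(truth, seed=seed)
    return truth, counts, phenotypes


def write_cohort(truth: CohortTruth, counts: AlleleCountMatrix,
                 phenotypes: pd.DataFrame, out_dir) -> dict[str, str]:
    """Write counts (TSV + VCF), phenotypes (TSV) and a truth sidecar."""
    from pathlib import Path

    from .io import write_counts_tsv, write_counts_vcf, write_phenotypes, write_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts_tsv": str(out / "counts.tsv"),
        "counts_vcf": str(out / "counts.vcf"),
        "phenotypes": str(out / "phenotypes.tsv"),
        "truth": str(out / "truth.tsv"),
    }
    write_counts_tsv(counts, paths["counts_tsv"], stage="simulate")
    write_counts_vcf(counts, paths["counts_vcf"])
    write_phenotypes(phenotypes, paths["phenotypes"], stage="simulate")
    truth_df = pd.DataFrame(
        {
            "chromosome": [s.chromosome_id for s in truth.sites],
            "position": [s.position for s in truth.sites],
            "ref_allele": [s.ref_allele for s in truth.sites],
            "alt_allele": [s.alt_allele for s in truth.sites],
            "gene": truth.gene_ids,
        }
    )
    for j, cultivar in enumerate(truth.cultivars):
        truth_df[cultivar] = truth.true_freq[:, j]
    write_table(truth_df, paths["truth"], stage="simulate")
    return paths
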