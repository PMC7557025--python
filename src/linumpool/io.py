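"""Formats and configuration: TSV and VCF 4.2 input/output, the pipeline
configuration object, and provenance-stamped table writing.

Counts travel either as a wide TSV (one row per site, a ``<cultivar>.ref``
and ``<cultivar>.alt`` column pair per cultivar) or as VCF 4.2 with per-
sample AD/DP.  Consensus calls travel as a long TSV (site, gene, cultivar,
caller, vaf, depth).  Every table written by the pipeline starts with
comment lines naming the producing stage and a hash of the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calling import AlleleCountMatrix, ConsensusCall
from .genemodel import GenomicSite

__all__ = [
    "ParseError",
    "PipelineConfig",
    "FATTY_ACIDS",
    "write_table",
    "read_table",
    "write_counts_tsv",
    "read_counts_tsv",
    "write_counts_vcf",
    "read_counts_vcf",
    "write_phenotypes",
    "read_phenotypes",
    "write_consensus_long",
    "read_consensus_long",
]

FATTY_ACIDS = ("PAL", "STE", "OLE", "LIO", "LIN")


class ParseError(ValueError):
    """Malformed input file; the message names the file and offending row."""


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """All pipeline thresholds plus the cohort-simulation settings.

    Defaults are the published constants where printed (VAF floor 0.20,
    |rs| cut 0.25, p cut 0.05, zeroing floor 0.20, 84 cultivars, 50-plant
    pools, 400x coverage) and this package's documented choices elsewhere.
    """

    # calling
    min_depth: int = 8
    min_alt_reads: int = 2
    min_vaf_call: float = 0.05
    error_rate: float = 0.005
    alpha: float = 1e-6
    vaf_floor: float = 0.20
    het_band: tuple[float, float] = (0.2, 0.8)
    # association
    rs_cut: float = 0.25
    p_cut: float = 0.05
    # classification
    presence_floor: float = 0.40
    # clustering
    zero_floor: float = 0.20
    cluster_caller: str = "caller_a_threshold"
    # gene models
    flank_bp: int = 2000
    # simulation
    n_cultivars: int = 84
    pool_size: int = 50
    mean_coverage: float = 400.0
    noise_sd: float = 0.4
    het_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        self.het_band = tuple(self.het_band)  # yaml round-trips as list
        checks = [
            (self.min_depth > 0, "min_depth must be positive"),
            (self.min_alt_reads > 0, "min_alt_reads must be positive"),
            (0 < self.min_vaf_call <= 1, "min_vaf_call must be in (0, 1]"),
            (0 <= self.error_rate < 0.1, "error_rate must be in [0, 0.1)"),
            (0 < self.alpha < 1, "alpha must be in (0, 1)"),
            (0 <= self.vaf_floor <= 1, "vaf_floor must be in [0, 1]"),
            (0 <= self.het_band[0] < self.het_band[1] <= 1, "het_band must be 0<=lo<hi<=1"),
            (0 < self.rs_cut < 1, "rs_cut must be in (0, 1)"),
            (0 < self.p_cut < 1, "p_cut must be in (0, 1)"),
            (0 < self.presence_floor < 1, "presence_floor must be in (0, 1)"),
            (0 <= self.zero_floor <= 1, "zero_floor must be in [0, 1]"),
            (self.flank_bp >= 0, "flank_bp must be >= 0"),
            (self.n_cultivars >= 2, "n_cultivars must be >= 2"),
            (self.pool_size >= 1, "pool_size must be >= 1"),
            (self.mean_coverage > 0, "mean_coverage must be positive"),
            (self.noise_sd >= 0, "noise_sd must be >= 0"),
            (0 <= self.het_fraction <= 1, "het_fraction must be in [0, 1]"),
        ]
        for ok, message in checks:
            if not ok:
                raise ValueError(message)

    def to_yaml(self, path) -> None:
        Path(path).write_text(self.to_yaml_str())

    def to_yaml_str(self) -> str:
        data = dataclasses.asdict(self)
        data["het_band"] = list(data["het_band"])
        return yaml.safe_dump(data, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ParseError(f"{path}: config must be a YAML mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    @property
    def hash(self) -> str:
        return hashlib.sha256(self.to_yaml_str().encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Generic provenance-stamped tables
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path, stage: str, config: PipelineConfig | None = None) -> None:
    header = [f"# producer=linumpool stage={stage}"]
    if config is not None:
        header.append(f"# config_hash={config.hash}")
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# Allele counts (TSV)
# ---------------------------------------------------------------------------

_SITE_COLS = ["chromosome", "position", "ref_allele", "alt_allele", "gene"]


def write_counts_tsv(counts: AlleleCountMatrix, path, stage: str = "counts",
                     config: PipelineConfig | None = None) -> None:
    data = {
        "chromosome": [s.chromosome_id for s in counts.sites],
        "position": [s.position for s in counts.sites],
        "ref_allele": [s.ref_allele for s in counts.sites],
        "alt_allele": [s.alt_allele for s in counts.sites],
        "gene": counts.gene_ids or [""] * counts.n_sites,
    }
    for j, cultivar in enumerate(counts.cultivars):
        data[f"{cultivar}.ref"] = counts.ref_count[:, j]
        data[f"{cultivar}.alt"] = counts.alt_count[:, j]
    write_table(pd.DataFrame(data), path, stage=stage, config=config)


def read_counts_tsv(path) -> AlleleCountMatrix:
    df = read_table(path)
    missing = [c for c in _SITE_COLS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    pair_cols = [c for c in df.columns if c.endswith(".ref")]
    cultivars = [c[: -len(".ref")] for c in pair_cols]
    if len(set(cultivars)) != len(cultivars):
        raise ParseError(f"{path}: duplicate cultivar IDs")
    for cultivar in cultivars:
        if f"{cultivar}.alt" not in df.columns:
            raise ParseError(f"{path}: cultivar {cultivar} lacks an .alt column")
    try:
        sites = [
            GenomicSite(row.chromosome, int(row.position), row.ref_allele, row.alt_allele)
            for row in df.itertuples()
        ]
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{path}: bad site row: {exc}") from exc
    ref = df[[f"{c}.ref" for c in cultivars]].to_numpy(dtype=np.int64)
    alt = df[[f"{c}.alt" for c in cultivars]].to_numpy(dtype=np.int64)
    genes = df["gene"].fillna("").astype(str).tolist()
    return AlleleCountMatrix(
        sites=sites, cultivars=cultivars, ref_count=ref, alt_count=alt,
        gene_ids=genes if any(genes) else None,
    )


# ---------------------------------------------------------------------------
# Allele counts (VCF 4.2, per-sample AD/DP)
# ---------------------------------------------------------------------------

def write_counts_vcf(counts: AlleleCountMatrix, path) -> None:
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_line('##INFO=<ID=GENE,Number=1,Type=String,Description="Assigned gene">')
    max_pos: dict[str, int] = {}
    for site in counts.sites:
        end = site.position + len(site.ref_allele)
        max_pos[site.chromosome_id] = max(max_pos.get(site.chromosome_id, 0), end)
    for chrom in sorted(max_pos):
        header.add_line(f"##contig=<ID={chrom},length={max_pos[chrom] + 10000}>")
    for cultivar in counts.cultivars:
        header.add_sample(cultivar)

    order = sorted(
        range(counts.n_sites),
        key=lambda i: (counts.sites[i].chromosome_id, counts.sites[i].position,
                       counts.sites[i].alt_allele),
    )
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for i in order:
            site = counts.sites[i]
            rec = vcf.new_record(
                contig=site.chromosome_id,
                start=site.position - 1,
                alleles=(site.ref_allele, site.alt_allele),
            )
            if counts.gene_ids and counts.gene_ids[i]:
                rec.info["GENE"] = counts.gene_ids[i]
            for j, cultivar in enumerate(counts.cultivars):
                rec.samples[cultivar]["AD"] = (
                    int(counts.ref_count[i, j]), int(counts.alt_count[i, j])
                )
                rec.samples[cultivar]["DP"] = int(counts.depth[i, j])
            vcf.write(rec)


def read_counts_vcf(path) -> AlleleCountMatrix:
    import pysam

    sites, genes, refs, alts = [], [], [], []
    last: dict[str, int] = {}
    with pysam.VariantFile(str(path)) as vcf:
        cultivars = list(vcf.header.samples)
        for rec in vcf:
            if rec.chrom in last and rec.pos < last[rec.chrom]:
                raise ParseError(
                    f"{path}: unsorted positions on {rec.chrom} at {rec.pos}"
                )
            last[rec.chrom] = rec.pos
            if rec.alts is None or len(rec.alts) != 1:
                raise ParseError(f"{path}: record at {rec.chrom}:{rec.pos} must be biallelic")
            sites.append(GenomicSite(rec.chrom, rec.pos, rec.ref, rec.alts[0]))
            try:
                genes.append(rec.info.get("GENE", "") if "GENE" in rec.info else "")
            except ValueError:  # INFO field not declared in the header
                genes.append("")
            row_ref, row_alt = [], []
            for cultivar in cultivars:
                ad = rec.samples[cultivar]["AD"]
                row_ref.append(ad[0])
                row_alt.append(ad[1])
            refs.append(row_ref)
            alts.append(row_alt)
    return AlleleCountMatrix(
        sites=sites,
        cultivars=cultivars,
        ref_count=np.array(refs, dtype=np.int64).reshape(len(sites), len(cultivars)),
        alt_count=np.array(alts, dtype=np.int64).reshape(len(sites), len(cultivars)),
        gene_ids=genes if any(genes) else None,
    )


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def write_phenotypes(phenotypes: pd.DataFrame, path, stage: str = "phenotypes",
                     config: PipelineConfig | None = None) -> None:
    df = phenotypes.reset_index()
    df = df.rename(columns={df.columns[0]: "cultivar"})
    write_table(df, path, stage=stage, config=config)


def read_phenotypes(path) -> pd.DataFrame:
    """Phenotype table: one row per cultivar, the five fatty-acid percentages.

    Rejects missing/extra acid columns (naming them), duplicate cultivars and
    non-numeric cells.
    """
    df = read_table(path)
    if "cultivar" not in df.columns:
        raise ParseError(f"{path}: missing 'cultivar' column")
    missing = [a for a in FATTY_ACIDS if a not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing fatty-acid column(s) {missing}")
    if df["cultivar"].duplicated().any():
        dupes = df.loc[df["cultivar"].duplicated(), "cultivar"].tolist()
        raise ParseError(f"{path}: duplicate cultivar IDs {dupes}")
    out = df.set_index("cultivar")[list(FATTY_ACIDS)]
    for acid in FATTY_ACIDS:
        numeric = pd.to_numeric(out[acid], errors="coerce")
        if numeric.isna().any():
            bad = out.index[numeric.isna()][0]
            raise ParseError(f"{path}: non-numeric {acid} value for cultivar {bad}")
        out[acid] = numeric
    return out


# ---------------------------------------------------------------------------
# Consensus calls (long TSV)
# ---------------------------------------------------------------------------

def consensus_to_long(calls: list[ConsensusCall]) -> pd.DataFrame:
    rows = []
    for call in calls:
        for caller_id, vaf in call.vaf.items():
            for j, cultivar in enumerate(call.cultivars):
                rows.append(
                    (
                        call.site.chromosome_id,
                        call.site.position,
                        call.site.ref_allele,
                        call.site.alt_allele,
                        call.gene_id or "",
                        cultivar,
                        caller_id,
                        vaf[j],
                        int(call.depth[j]),
                    )
                )
    return pd.DataFrame(
        rows,
        columns=["chromosome", "position", "ref_allele", "alt_allele", "gene",
                 "cultivar", "caller", "vaf", "depth"],
    )


def write_consensus_long(calls: list[ConsensusCall], path, stage: str = "call",
                         config: PipelineConfig | None = None) -> None:
    write_table(consensus_to_long(calls), path, stage=stage, config=config)


def read_consensus_long(path) -> list[ConsensusCall]:
    df = read_table(path)
    needed = {"chromosome", "position", "ref_allele", "alt_allele", "gene",
              "cultivar", "caller", "vaf", "depth"}
    missing = needed - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    calls = []
    site_keys = df[["chromosome", "position", "ref_allele", "alt_allele"]].apply(tuple, axis=1)
    for key, group in df.groupby(site_keys, sort=False):
        chrom, pos, ref, alt = key
        site = GenomicSite(chrom, int(pos), ref, alt)
        gene = str(group["gene"].iloc[0]) if not pd.isna(group["gene"].iloc[0]) else ""
        vaf: dict[str, np.ndarray] = {}
        cultivars = None
        depth = None
        for caller_id, sub in group.groupby("caller", sort=True):
            if cultivars is None:
                cultivars = sub["cultivar"].tolist()
                depth = sub["depth"].to_numpy(dtype=np.int64)
            elif sub["cultivar"].tolist() != cultivars:
                raise ParseError(f"{path}: inconsistent cultivar order at {chrom}:{pos}")
            vaf[caller_id] = sub["vaf"].to_numpy(dtype=float)
        calls.append(
            ConsensusCall(site=site, cultivars=cultivars, vaf=vaf, depth=depth,
                          gene_id=gene or None)
        )
    return calls
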