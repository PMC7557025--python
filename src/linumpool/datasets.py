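"""Packaged fixtures: gene models, the reference association table, printed
fatty-acid ranges, and a deterministic synthetic reference sequence.

The gene models and reference sequences are synthetic stand-ins: they use the
real chromosome accessions and variant-site coordinates of the published
84-cultivar flax association table, but invented gene/exon coordinates and a
generated sequence, constructed so that every tabulated region label and
every reported codon effect (the FAD3A Trp→stop key variant, the FAD3B
His→Tyr key variant, the alternative FAD3A Arg→stop variant, the Ala→Thr and
Ile→Ser missense variants, and the silent exonic variants) is reproduced.
"""

from __future__ import annotations

import zlib
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .genemodel import (
    DEFAULT_FLANK_BP,
    GeneModel,
    GeneReference,
    GenomicSite,
    load_gene_models,
)

__all__ = [
    "KEY_FAD3A_NONSENSE",
    "KEY_FAD3B_MISSENSE",
    "ALT_FAD3A_NONSENSE",
    "TABLE1_ROUNDING_TOL",
    "gene_models_path",
    "load_fixture_gene_models",
    "load_table1",
    "table1_records",
    "load_background_ranges",
    "build_references",
    "write_reference_fasta",
]

#: FAD3A tryptophan→stop key variant (minus-strand gene; genomic C→T).
KEY_FAD3A_NONSENSE = GenomicSite("CP027631.1", 16092348, "C", "T")
#: FAD3B histidine→tyrosine key variant (CAT→TAT).
KEY_FAD3B_MISSENSE = GenomicSite("CP027622.1", 1035655, "C", "T")
#: Alternative FAD3A arginine→stop variant (the A6-pattern exception).
ALT_FAD3A_NONSENSE = GenomicSite("CP027631.1", 16090340, "G", "A")

#: Half an ulp of the association table's two-decimal rs values; used when
#: applying the strict |rs| > 0.25 rule to printed (rounded) coefficients.
TABLE1_ROUNDING_TOL = 0.005

_DATA = resources.files("linumpool.data")


def _data_path(name: str) -> Path:
    return Path(str(_DATA / name))


def gene_models_path() -> Path:
    return _data_path("gene_models_fixture.gff3")


def load_fixture_gene_models(flank_bp: int = DEFAULT_FLANK_BP) -> list[GeneModel]:
    return load_gene_models(gene_models_path(), flank_bp=flank_bp)


def load_table1() -> pd.DataFrame:
    """The packaged transcription of the published association table.

    One row per (variant site, fatty acid); rs/p columns per caller, rounded
    as printed (rs to two decimals).
    """
    df = pd.read_csv(_data_path("table1_transcription.tsv"), sep="\t")
    df["key_site"] = df["key_site"].astype(bool)
    return df


def table1_records() -> pd.DataFrame:
    """Table rows in the column layout produced by screen_associations."""
    df = load_table1().rename(
        columns={
            "rs_varscan": "rs_caller_a",
            "p_varscan": "p_caller_a",
            "rs_freebayes": "rs_caller_b",
            "p_freebayes": "p_caller_b",
        }
    )
    return df


def load_background_ranges() -> pd.DataFrame:
    return pd.read_csv(_data_path("background_ranges.tsv"), sep="\t", index_col="fatty_acid")


# ---------------------------------------------------------------------------
# Synthetic reference sequences
# ---------------------------------------------------------------------------

_STOPS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"
_NON_STOP_CODONS = tuple(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
)

# Codons planted at fixed positions of each spliced CDS (1-based codon index)
# so that the tabulated exonic variants reproduce their reported effects.
_PLANTED_CODONS: dict[str, dict[int, str]] = {
    "SAD1": {1: "ATG", 397: "TGA"},
    # codon 89 covers 17365164 at codon position 1: TTA→CTA is silent (Leu).
    "SAD2": {1: "ATG", 89: "TTA", 397: "TAG"},
    # codons 268/366 put 5296364 and 5296658 at codon position 3 (silent).
    "FAD2A": {1: "ATG", 268: "CTG", 366: "GGC", 379: "TAA"},
    "FAD2B": {1: "ATG", 383: "TAA"},
    # codon 8: GCA→ACA Ala→Thr (16092575); codon 64: TGG→TGA Trp→stop
    # (16092348, codon position 3 on the minus strand); codon 82: CCA→CCG
    # silent (16092294); codon 264: CGA→TGA Arg→stop (16090340).
    "FAD3A": {1: "ATG", 8: "GCA", 64: "TGG", 82: "CCA", 264: "CGA", 393: "TAA"},
    # codon 77: CCA→CCG silent (1035480); codon 118: CAT→TAT His→Tyr
    # (1035655); codon 124: ATC→AGC Ile→Ser (1035674).
    "FAD3B": {1: "ATG", 77: "CCA", 118: "CAT", 124: "ATC", 392: "TAA"},
}

# Forward-strand bases pinned at the tabulated non-exonic sites so the
# reference agrees with each site's declared reference allele.
_PINNED_BASES: dict[str, dict[int, str]] = {
    "CP027620.1": {2257330: "A", 2257353: "T", 2258938: "C", 2258980: "T", 2260202: "T"},
    "CP027621.1": {17364707: "A", 17367383: "G"},
    "CP027619.1": {5296705: "C"},
    "CP027631.1": {
        16092241: "T",
        16092273: "C",
        16092674: "G",
        16092741: "T",
        16093029: "T",
        16093040: "C",
    },
    "CP027622.1": {
        1034358: "G",
        1034389: "A",
        1034526: "C",
        1034873: "G",
        1034904: "G",
        1035028: "A",
        1036195: "G",
        1037964: "G",
    },
}


def build_references(
    models: list[GeneModel] | None = None, seed: int = 2020
) -> dict[str, GeneReference]:
    """Deterministic synthetic reference covering each gene span ± flank.

    The CDS is filled with random non-stop codons (start codon first, one
    stop codon last) before the planted codons above are written in, so each
    gene carries a plausible open reading frame.
    """
    if models is None:
        models = load_fixture_gene_models()
    references: dict[str, GeneReference] = {}
    for model in sorted(models, key=lambda m: m.gene_id):
        rng = np.random.default_rng([seed, zlib.crc32(model.gene_id.encode())])
        span_start = model.gene_start - model.flank_bp
        span_end = model.gene_end + model.flank_bp
        seq = rng.choice(list(_BASES), size=span_end - span_start + 1)

        n_codons = model.coding_length // 3
        planted = _PLANTED_CODONS.get(model.gene_id, {})
        codons = []
        for i in range(1, n_codons + 1):
            if i in planted:
                codons.append(planted[i])
            elif i == 1:
                codons.append("ATG")
            elif i == n_codons:
                codons.append("TAA")
            else:
                codons.append(_NON_STOP_CODONS[rng.integers(len(_NON_STOP_CODONS))])
        transcript = "".join(codons)
        spliced = transcript if model.strand == "+" else str(Seq(transcript).reverse_complement())

        # write the spliced CDS into the exons in ascending genomic order
        cursor = 0
        for start, end in model.exons:
            length = end - start + 1
            chunk = spliced[cursor : cursor + length]
            seq[start - span_start : end - span_start + 1] = list(chunk)
            cursor += length

        for pos, base in _PINNED_BASES.get(model.chromosome_id, {}).items():
            if span_start <= pos <= span_end and not model.in_exon(pos):
                seq[pos - span_start] = base

        references[model.gene_id] = GeneReference(
            gene_id=model.gene_id,
            chromosome_id=model.chromosome_id,
            span_start=span_start,
            sequence="".join(seq),
        )
    return references


def write_reference_fasta(references: dict[str, GeneReference], path) -> None:
    """FASTA export; headers carry the span so coordinates can be recovered."""
    with open(path, "w") as fh:
        for gene_id in sorted(references):
            ref = references[gene_id]
            fh.write(
                f">{gene_id} {ref.chromosome_id}:{ref.span_start}-{ref.span_end}\n"
            )
            for i in range(0, len(ref.sequence), 80):
                fh.write(ref.sequence[i : i + 80] + "\n")
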