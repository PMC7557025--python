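"""Gene models for the flax desaturase loci and codon-level variant annotation.

Flax (*Linum usitatissimum*) carries three pairs of paralogous desaturase
genes acting sequentially on the C18 backbone: *SAD1*/*SAD2* (stearic →
oleic; three exons each), *FAD2A*/*FAD2B* (oleic → linoleic; intronless) and
*FAD3A*/*FAD3B* (linoleic → linolenic; six exons each).  This module
represents those gene structures, places genomic sites into
upstream/exon/intron/downstream regions relative to the transcription
direction, and predicts the codon-level consequence (silent, missense,
nonsense, in-frame or frameshift indel) of a variant given a reference
sequence for the gene span.

All coordinates are 1-based inclusive, the convention of both VCF and the
genome-assembly positions used for these genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from Bio.Seq import Seq

__all__ = [
    "GENE_IDS",
    "DEFAULT_FLANK_BP",
    "GeneModelError",
    "ReferenceMismatchError",
    "GenomicSite",
    "GeneModel",
    "GeneReference",
    "CodonEffect",
    "load_gene_models",
    "classify_location",
    "codon_effect",
]

GENE_IDS = ("SAD1", "SAD2", "FAD2A", "FAD2B", "FAD3A", "FAD3B")

#: Exon counts reported for the six desaturase genes (FAD2A/FAD2B are
#: intronless; SADs have three exons, FAD3s six).  Enforced only for these
#: canonical gene ids so toy genes can be built freely in tests.
EXPECTED_EXON_COUNTS = {
    "SAD1": 3,
    "SAD2": 3,
    "FAD2A": 1,
    "FAD2B": 1,
    "FAD3A": 6,
    "FAD3B": 6,
}

DEFAULT_FLANK_BP = 2000

_VALID_BASES = frozenset("ACGT")


class GeneModelError(ValueError):
    """A gene model violates a structural invariant (frame, exon layout...)."""


class ReferenceMismatchError(ValueError):
    """Reference sequence disagrees with a site's declared reference allele."""


@dataclass(frozen=True)
class GenomicSite:
    """A variant site: chromosome accession, 1-based position, ref/alt alleles."""

    chromosome_id: str
    position: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        for name, allele in (("ref", self.ref_allele), ("alt", self.alt_allele)):
            if not allele or not set(allele) <= _VALID_BASES:
                raise ValueError(f"{name} allele must be a nonempty ACGT string, got {allele!r}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")

    @property
    def is_snp(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1

    @property
    def is_indel(self) -> bool:
        return len(self.ref_allele) != len(self.alt_allele)

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity used for caller consensus: (chrom, pos, ref, alt)."""
        return (self.chromosome_id, self.position, self.ref_allele, self.alt_allele)


@dataclass(frozen=True)
class GeneModel:
    """Structure of one gene: span, strand, exons and coding frame.

    ``exons`` are (start, end) 1-based inclusive intervals in genomic order.
    ``coding_offset`` is the 0-based offset within the spliced transcript at
    which the start codon begins; for the packaged fixtures the exons are the
    CDS, so it is 0.
    """

    gene_id: str
    chromosome_id: str
    strand: str
    gene_start: int
    gene_end: int
    exons: tuple[tuple[int, int], ...]
    coding_offset: int = 0
    flank_bp: int = DEFAULT_FLANK_BP

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GeneModelError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if self.gene_start > self.gene_end:
            raise GeneModelError(f"{self.gene_id}: gene_start > gene_end")
        if not self.exons:
            raise GeneModelError(f"{self.gene_id}: at least one exon required")
        prev_end = None
        for start, end in self.exons:
            if start > end:
                raise GeneModelError(f"{self.gene_id}: exon ({start},{end}) has start > end")
            if start < self.gene_start or end > self.gene_end:
                raise GeneModelError(
                    f"{self.gene_id}: exon ({start},{end}) outside gene span "
                    f"[{self.gene_start},{self.gene_end}]"
                )
            if prev_end is not None and start <= prev_end:
                raise GeneModelError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = end
        expected = EXPECTED_EXON_COUNTS.get(self.gene_id)
        if expected is not None and len(self.exons) != expected:
            raise GeneModelError(
                f"{self.gene_id}: expected {expected} exon(s), got {len(self.exons)}"
            )
        if not 0 <= self.coding_offset < self.spliced_length:
            raise GeneModelError(f"{self.gene_id}: coding_offset out of transcript")
        if self.coding_length % 3 != 0:
            raise GeneModelError(
                f"{self.gene_id}: coding length {self.coding_length} is not a multiple of 3"
            )
        if self.flank_bp < 0:
            raise GeneModelError(f"{self.gene_id}: flank_bp must be >= 0")

    # -- derived lengths -------------------------------------------------

    @property
    def gene_length(self) -> int:
        return self.gene_end - self.gene_start + 1

    @property
    def spliced_length(self) -> int:
        return sum(end - start + 1 for start, end in self.exons)

    @property
    def coding_length(self) -> int:
        return self.spliced_length - self.coding_offset

    @property
    def protein_length(self) -> int:
        """Number of encoded residues, excluding the stop codon."""
        return self.coding_length // 3 - 1

    # -- coordinate mapping ----------------------------------------------

    def contains(self, position: int) -> bool:
        return self.gene_start <= position <= self.gene_end

    def in_exon(self, position: int) -> bool:
        return any(start <= position <= end for start, end in self.exons)

    def transcript_offset(self, position: int) -> int | None:
        """1-based offset of a genomic position in the spliced transcript.

        Returns None for non-exonic positions.  On the minus strand the
        transcript runs from the highest-coordinate exon downwards.
        """
        if not self.in_exon(position):
            return None
        if self.strand == "+":
            offset = 0
            for start, end in self.exons:
                if position > end:
                    offset += end - start + 1
                else:
                    return offset + (position - start + 1)
        else:
            offset = 0
            for start, end in reversed(self.exons):
                if position < start:
                    offset += end - start + 1
                else:
                    return offset + (end - position + 1)
        return None  # pragma: no cover - unreachable

    def with_flank(self, flank_bp: int) -> "GeneModel":
        return replace(self, flank_bp=flank_bp)


@dataclass(frozen=True)
class GeneReference:
    """Reference sequence covering a gene span (plus flanks), forward strand."""

    gene_id: str
    chromosome_id: str
    span_start: int
    sequence: str

    @property
    def span_end(self) -> int:
        return self.span_start + len(self.sequence) - 1

    def covers(self, start: int, end: int) -> bool:
        return self.span_start <= start and end <= self.span_end

    def slice(self, start: int, end: int) -> str:
        """Forward-strand bases for 1-based inclusive [start, end]."""
        if not self.covers(start, end):
            raise ValueError(
                f"[{start},{end}] outside reference span [{self.span_start},{self.span_end}]"
            )
        i = start - self.span_start
        return self.sequence[i : i + (end - start + 1)]

    def base_at(self, position: int) -> str:
        return self.slice(position, position)


@dataclass(frozen=True)
class CodonEffect:
    """Predicted consequence of a variant on the encoded protein."""

    effect: str  # silent | missense | nonsense | indel_frameshift | indel_inframe | noncoding
    ref_codon: str | None = None
    alt_codon: str | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None
    aa_position: int | None = None

    @property
    def is_nonsense(self) -> bool:
        return self.effect == "nonsense"


# ---------------------------------------------------------------------------
# GFF3 loading
# ---------------------------------------------------------------------------

def load_gene_models(gff3_path, flank_bp: int = DEFAULT_FLANK_BP) -> list[GeneModel]:
    """Load gene models from a GFF3 file with ``gene`` and ``exon`` features.

    Exons are attached to genes through their ``Parent`` attribute.  Raises a
    parse error naming the offending line for malformed records and a
    :class:`GeneModelError` when a model breaks the reading frame.
    """
    import gffutils

    # gffutils skips malformed lines silently; fail loudly instead, naming
    # the offending line number.
    with open(gff3_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped or stripped.startswith("#"):
                continue
            if len(stripped.split("\t")) != 9:
                raise ValueError(
                    f"malformed GFF3 {gff3_path}: line {lineno} does not have 9 "
                    f"tab-separated fields"
                )

    try:
        db = gffutils.create_db(
            str(gff3_path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="error",
        )
    except Exception as exc:  # gffutils raises several parse error types
        raise ValueError(f"malformed GFF3 {gff3_path}: {exc}") from exc

    models = []
    for gene in db.features_of_type("gene", order_by="start"):
        exons = sorted(
            (f.start, f.end) for f in db.children(gene, featuretype="exon")
        )
        if not exons:
            raise ValueError(f"malformed GFF3 {gff3_path}: gene {gene.id} has no exons")
        coding_offset = int(gene.attributes.get("coding_offset", ["0"])[0])
        models.append(
            GeneModel(
                gene_id=gene.id,
                chromosome_id=gene.seqid,
                strand=gene.strand,
                gene_start=gene.start,
                gene_end=gene.end,
                exons=tuple(exons),
                coding_offset=coding_offset,
                flank_bp=flank_bp,
            )
        )
    return models


# ---------------------------------------------------------------------------
# Region classification
# ---------------------------------------------------------------------------

def classify_location(site: GenomicSite | int, model: GeneModel) -> str:
    """Classify a site relative to a gene: upstream/exon/intron/downstream/intergenic.

    Upstream and downstream follow the transcription direction, so for a
    minus-strand gene positions above ``gene_end`` (within ``flank_bp``) are
    upstream.  Total function: anything beyond the flanks, or on another
    chromosome, is intergenic.
    """
    if isinstance(site, GenomicSite):
        if site.chromosome_id != model.chromosome_id:
            return "intergenic"
        position = site.position
    else:
        position = int(site)

    if model.contains(position):
        return "exon" if model.in_exon(position) else "intron"

    before = model.gene_start - model.flank_bp <= position < model.gene_start
    after = model.gene_end < position <= model.gene_end + model.flank_bp
    if model.strand == "+":
        if before:
            return "upstream"
        if after:
            return "downstream"
    else:
        if after:
            return "upstream"
        if before:
            return "downstream"
    return "intergenic"


def assign_gene(site: GenomicSite, models: Sequence[GeneModel]) -> str | None:
    """Gene id whose span ± flank contains the site, or None."""
    for model in models:
        if classify_location(site, model) != "intergenic":
            return model.gene_id
    return None


# ---------------------------------------------------------------------------
# Codon effects
# ---------------------------------------------------------------------------

def _spliced_cds(model: GeneModel, reference: GeneReference) -> str:
    parts = [reference.slice(start, end) for start, end in model.exons]
    spliced = "".join(parts)
    if model.strand == "-":
        spliced = str(Seq(spliced).reverse_complement())
    return spliced[model.coding_offset :]


def _translate(cds: str) -> str:
    return str(Seq(cds).translate())


def codon_effect(
    site: GenomicSite, model: GeneModel, reference: GeneReference | str
) -> CodonEffect:
    """Predict the codon-level effect of ``site`` on ``model``'s protein.

    ``reference`` must cover the gene span on the forward genomic strand;
    alleles are reverse-complemented internally for minus-strand genes.
    Single-base exonic substitutions yield silent/missense/nonsense; exonic
    length-changing indels yield frameshift iff the length change is not a
    multiple of 3; multi-base same-length substitutions are resolved by
    rebuilding the spliced CDS with the alternative allele and diffing the
    translations.  Non-exonic sites are noncoding.
    """
    if isinstance(reference, str):
        reference = GeneReference(
            gene_id=model.gene_id,
            chromosome_id=model.chromosome_id,
            span_start=model.gene_start,
            sequence=reference,
        )

    ref_span_end = site.position + len(site.ref_allele) - 1
    observed = reference.slice(site.position, ref_span_end)
    if observed != site.ref_allele:
        raise ReferenceMismatchError(
            f"{site.chromosome_id}:{site.position} reference has {observed!r}, "
            f"site declares ref {site.ref_allele!r}"
        )

    if not model.in_exon(site.position):
        return CodonEffect(effect="noncoding")

    if site.is_indel:
        shift = abs(len(site.alt_allele) - len(site.ref_allele))
        return CodonEffect(
            effect="indel_frameshift" if shift % 3 else "indel_inframe"
        )

    cds = _spliced_cds(model, reference)

    if site.is_snp:
        offset = model.transcript_offset(site.position)
        coding_pos = offset - model.coding_offset  # 1-based within CDS
        if coding_pos < 1 or coding_pos > len(cds):
            return CodonEffect(effect="noncoding")
        ref_base = site.ref_allele
        alt_base = site.alt_allele
        if model.strand == "-":
            ref_base = str(Seq(ref_base).reverse_complement())
            alt_base = str(Seq(alt_base).reverse_complement())
        codon_index = (coding_pos - 1) // 3  # 0-based
        within = (coding_pos - 1) % 3
        ref_codon = cds[codon_index * 3 : codon_index * 3 + 3]
        assert ref_codon[within] == ref_base
        alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
        ref_aa = _translate(ref_codon)
        alt_aa = _translate(alt_codon)
    else:
        # same-length multi-base substitution: rebuild the CDS with the alt
        # allele and compare translations at the first differing residue.
        mutated = list(reference.sequence)
        i = site.position - reference.span_start
        mutated[i : i + len(site.ref_allele)] = list(site.alt_allele)
        alt_ref = GeneReference(
            gene_id=reference.gene_id,
            chromosome_id=reference.chromosome_id,
            span_start=reference.span_start,
            sequence="".join(mutated),
        )
        alt_cds = _spliced_cds(model, alt_ref)
        prot_ref = _translate(cds)
        prot_alt = _translate(alt_cds)
        diff = [
            (k, a, b) for k, (a, b) in enumerate(zip(prot_ref, prot_alt)) if a != b
        ]
        if not diff:
            return CodonEffect(effect="silent")
        k, ref_aa, alt_aa = diff[0]
        codon_index = k
        ref_codon = cds[k * 3 : k * 3 + 3]
        alt_codon = alt_cds[k * 3 : k * 3 + 3]

    if alt_aa == ref_aa:
        effect = "silent"
    elif alt_aa == "*":
        effect = "nonsense"
    else:
        effect = "missense"
    return CodonEffect(
        effect=effect,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        aa_position=codon_index + 1,
    )


def annotate_sites(
    sites: Iterable[GenomicSite],
    models: Sequence[GeneModel],
    references: dict[str, GeneReference],
) -> list[tuple[GenomicSite, str | None, str, CodonEffect | None]]:
    """Annotate sites against all models: (site, gene_id, location, effect).

    Effect is computed only for sites whose gene has a reference sequence;
    sites matching no gene get location "intergenic" and effect None.
    """
    by_id = {m.gene_id: m for m in models}
    out = []
    for site in sites:
        gene_id = assign_gene(site, models)
        if gene_id is None:
            out.append((site, None, "intergenic", None))
            continue
        model = by_id[gene_id]
        location = classify_location(site, model)
        effect = None
        ref = references.get(gene_id)
        if ref is not None and ref.covers(site.position, site.position + len(site.ref_allele) - 1):
            effect = codon_effect(site, model, ref)
        out.append((site, gene_id, location, effect))
    return out
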