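"""Parental variant filtering and alternate-genome construction.

In a reciprocal-cross design the mother (queen, diploid) and father (drone,
haploid) of each colony are sequenced so that offspring reads can later be
assigned to the parental allele they were transcribed from.  This module
implements the variant-side preparation:

* quality/depth filters on called SNPs,
* restriction of queen calls to homozygous-alternate sites (a heterozygous
  queen transmits either allele, so her het sites are uninformative),
* subtraction of shared sites to obtain parent-unique *informative* SNPs,
* substitution of those SNPs into the reference to build per-parent
  alternate genomes.

Coordinates are 1-based inclusive at every VCF-facing interface; genome
strings are indexed 0-based internally.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Sequence, Tuple

log = logging.getLogger(__name__)

#: contig name -> uppercase nucleotide string
GenomeSeq = Dict[str, str]

_VALID_GENOTYPES = ("hom_ref", "het", "hom_alt")


class UnsupportedVariantError(ValueError):
    """Raised for variants the pipeline cannot represent (indels, MNPs)."""


@dataclass(frozen=True)
class SnpRecord:
    """A single called variant for one parent.

    ``pos`` is 1-based.  ``alt_obs`` is the number of reads supporting the
    alternate allele (freebayes' AO).  ``ploidy`` is 1 for the haploid
    drone and 2 for the diploid queen.
    """

    contig: str
    pos: int
    ref_allele: str
    alt_allele: str
    qual: float
    depth: int
    alt_obs: int
    genotype: str
    ploidy: int = 2

    def __post_init__(self) -> None:
        if self.genotype not in _VALID_GENOTYPES:
            raise ValueError(f"invalid genotype {self.genotype!r}")
        if self.alt_obs > self.depth:
            raise ValueError(
                f"alt_obs {self.alt_obs} exceeds depth {self.depth} at "
                f"{self.contig}:{self.pos}"
            )
        if self.ploidy == 1 and self.genotype == "het":
            raise ValueError(
                f"haploid record cannot be heterozygous at {self.contig}:{self.pos}"
            )

    @property
    def is_snp(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1


@dataclass(frozen=True)
class InformativeSnp:
    """A site carried by exactly one parent.

    A read covering this position matches only that parent's alternate
    genome, so ``parent`` records which parent the ``parent_allele`` belongs
    to.  ``pos`` is 1-based.
    """

    contig: str
    pos: int
    parent: str  # "maternal" | "paternal"
    parent_allele: str
    other_allele: str
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.parent not in ("maternal", "paternal"):
            raise ValueError(f"invalid parent {self.parent!r}")
        if self.parent_allele == self.other_allele:
            raise ValueError(
                f"parent and other allele identical at {self.contig}:{self.pos}"
            )


def filter_snps(
    records: Sequence[SnpRecord],
    min_qual: float = 20.0,
    min_depth: int = 5,
    min_alt_obs: int = 2,
) -> List[SnpRecord]:
    """Keep records with qual >= min_qual, depth >= min_depth and
    alt_obs >= min_alt_obs; order preserved.

    Defaults are the standard call-quality gates for this design: phred
    quality 20, five reads of coverage, two alternate-allele observations.
    """
    if min_qual < 0 or min_depth < 0 or min_alt_obs < 0:
        raise ValueError("filter thresholds must be non-negative")
    return [
        r
        for r in records
        if r.qual >= min_qual and r.depth >= min_depth and r.alt_obs >= min_alt_obs
    ]


def select_queen_homalt(records: Sequence[SnpRecord]) -> List[SnpRecord]:
    """Keep only homozygous-alternate queen records.

    Only a hom-alt queen is guaranteed to transmit the alternate allele to
    every offspring; het sites are discarded.  Raises if a haploid record is
    passed (the queen is diploid).
    """
    for r in records:
        if r.ploidy != 2:
            raise ValueError(
                f"select_queen_homalt expects diploid records; got ploidy "
                f"{r.ploidy} at {r.contig}:{r.pos}"
            )
    return [r for r in records if r.genotype == "hom_alt"]


def _sorted_check(records: Sequence[SnpRecord], name: str) -> List[SnpRecord]:
    keys = [(r.contig, r.pos) for r in records]
    if keys != sorted(keys):
        warnings.warn(f"{name} records were not position-sorted; sorting internally")
        return sorted(records, key=lambda r: (r.contig, r.pos))
    return list(records)


def unique_snps(
    parent_a: Sequence[SnpRecord],
    parent_b: Sequence[SnpRecord],
    role_a: str = "maternal",
    role_b: str = "paternal",
) -> Tuple[List[InformativeSnp], List[InformativeSnp]]:
    """Set-subtract the two parents' SNP positions.

    Returns ``(a_unique, b_unique)``: sites present in one parent and absent
    from the other, labeled with that parent's role.  Subtraction is on
    (contig, pos) — a site called in both parents is uninformative even if
    the alternate alleles differ, because both alternate genomes deviate
    from the reference there.
    """
    parent_a = _sorted_check(parent_a, "parent_a")
    parent_b = _sorted_check(parent_b, "parent_b")
    pos_a = {(r.contig, r.pos) for r in parent_a}
    pos_b = {(r.contig, r.pos) for r in parent_b}

    def to_informative(records: Iterable[SnpRecord], other: set, role: str):
        out = []
        for r in records:
            if (r.contig, r.pos) in other:
                continue
            if not r.is_snp:
                raise UnsupportedVariantError(
                    f"indel at {r.contig}:{r.pos} ({r.ref_allele}>{r.alt_allele}); "
                    "only single-base substitutions are supported"
                )
            out.append(
                InformativeSnp(
                    contig=r.contig,
                    pos=r.pos,
                    parent=role,
                    parent_allele=r.alt_allele,
                    other_allele=r.ref_allele,
                )
            )
        return out

    return to_informative(parent_a, pos_b, role_a), to_informative(parent_b, pos_a, role_b)


def apply_snps(reference: GenomeSeq, snps: Sequence[InformativeSnp]) -> GenomeSeq:
    """Substitute each SNP's parent allele into the reference.

    Returns a new genome identical to ``reference`` except for single-base
    substitutions at SNP positions; contig lengths are unchanged.  Indel
    alleles raise :class:`UnsupportedVariantError`; out-of-range positions
    raise ``ValueError`` naming the site.
    """
    mutable = {contig: list(seq) for contig, seq in reference.items()}
    for snp in snps:
        if len(snp.parent_allele) != 1 or len(snp.other_allele) != 1:
            raise UnsupportedVariantError(
                f"indel allele at {snp.contig}:{snp.pos}; only single-base "
                "substitutions are supported"
            )
        if snp.contig not in mutable:
            raise ValueError(f"unknown contig {snp.contig!r} for SNP at pos {snp.pos}")
        seq = mutable[snp.contig]
        if not 1 <= snp.pos <= len(seq):
            raise ValueError(
                f"SNP position out of range: {snp.contig}:{snp.pos} "
                f"(contig length {len(seq)})"
            )
        seq[snp.pos - 1] = snp.parent_allele
    return {contig: "".join(seq) for contig, seq in mutable.items()}
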