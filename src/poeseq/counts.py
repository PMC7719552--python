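"""Allelic read assignment and count filtering.

Reads are matched with zero mismatches against both parental alternate
genomes.  Because the two genomes differ exactly at the informative
(parent-unique) SNPs, a read covering such a SNP matches exactly one
genome and is thereby assigned to that parent; a read covering no
informative SNP matches both genomes and is discarded, as is any read
matching at multiple loci (the analogue of a non-uniquely mapping read).

Downstream, counts pass the cascade used for this design:

1. per-SNP, per-library maternal/paternal tallies restricted to SNPs
   inside gene models (:func:`count_by_snp`),
2. removal of any SNP with zero maternal reads in at least one library —
   everywhere — to avoid paternal-count inflation from a mis-called queen
   genotype (:func:`drop_zero_maternal_snps`),
3. the analyzed gene universe: at least ``min_snps`` surviving SNPs and
   allelic data in every family x direction cell (:func:`gene_universe`),
4. paternal totals of zero set to one to avoid complete separation in the
   per-gene logistic regression (:func:`substitute_paternal_zero`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .variants import GenomeSeq, InformativeSnp

log = logging.getLogger(__name__)

GENE_COLUMNS = ["gene_id", "library_id", "maternal", "paternal", "n_snps"]
SNP_COLUMNS = ["gene_id", "snp_id", "library_id", "maternal", "paternal"]


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    library_id: str
    contig: str
    start: int  # 0-based
    end: int  # exclusive
    parent: str  # "maternal" | "paternal"
    snps_covered: Tuple[str, ...]  # informative SNP ids "contig:pos"


def _find_all(haystack: str, needle: str) -> List[int]:
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def snp_key(snp: InformativeSnp) -> str:
    return f"{snp.contig}:{snp.pos}"


def assign_reads(
    reads: Iterable[Tuple[str, str]],
    library_id: str,
    maternal_genome: GenomeSeq,
    paternal_genome: GenomeSeq,
    informative: Sequence[InformativeSnp],
) -> Tuple[List[ReadAssignment], int]:
    """Assign reads to the parental allele by exact matching.

    ``reads`` are ``(read_id, sequence)`` pairs for one library.  Returns
    ``(assignments, n_discarded)``; discarded reads are those matching
    both genomes (no informative SNP covered), neither genome (sequencing
    error or foreign sequence), or more than one locus (ambiguous).
    """
    by_contig: Dict[str, List[InformativeSnp]] = {}
    for snp in informative:
        by_contig.setdefault(snp.contig, []).append(snp)
    snp_pos = {
        contig: np.array(sorted(s.pos - 1 for s in snps))
        for contig, snps in by_contig.items()
    }
    snp_by_pos = {(s.contig, s.pos - 1): s for s in informative}

    assignments: List[ReadAssignment] = []
    n_discarded = 0
    for read_id, seq in reads:
        hits_m = [
            (contig, start)
            for contig, g in maternal_genome.items()
            if len(seq) <= len(g)
            for start in _find_all(g, seq)
        ]
        hits_p = [
            (contig, start)
            for contig, g in paternal_genome.items()
            if len(seq) <= len(g)
            for start in _find_all(g, seq)
        ]
        if any(len(seq) > len(g) for g in maternal_genome.values()):
            log.info("read %s longer than a contig", read_id)
        if len(hits_m) == 1 and len(hits_p) == 0:
            parent, (contig, start) = "maternal", hits_m[0]
        elif len(hits_p) == 1 and len(hits_m) == 0:
            parent, (contig, start) = "paternal", hits_p[0]
        else:
            n_discarded += 1
            continue
        end = start + len(seq)
        pos = snp_pos.get(contig)
        covered: Tuple[str, ...] = ()
        if pos is not None:
            lo, hi = np.searchsorted(pos, [start, end])
            covered = tuple(
                snp_key(snp_by_pos[(contig, int(p))]) for p in pos[lo:hi]
            )
        if not covered:  # cannot happen for a uniquely-matching read; be safe
            n_discarded += 1
            continue
        assignments.append(
            ReadAssignment(read_id, library_id, contig, start, end, parent, covered)
        )
    return assignments, n_discarded


def _gene_lookup(gene_models: pd.DataFrame):
    """Return a (contig, pos0) -> gene_id mapper; models must not overlap."""
    per_contig = {}
    for contig, grp in gene_models.groupby("contig"):
        grp = grp.sort_values("start")
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if np.any(ends[:-1] > starts[1:]):
            raise ValueError(f"overlapping gene models on contig {contig}")
        per_contig[contig] = (starts, ends, grp["gene_id"].to_numpy())

    def lookup(contig: str, pos0: int):
        entry = per_contig.get(contig)
        if entry is None:
            return None
        starts, ends, ids = entry
        i = np.searchsorted(starts, pos0, side="right") - 1
        if i >= 0 and pos0 < ends[i]:
            return ids[i]
        return None

    return lookup


def count_by_snp(
    assignments: Sequence[ReadAssignment], gene_models: pd.DataFrame
) -> pd.DataFrame:
    """Tally maternal/paternal reads per (gene, SNP, library).

    Each covered SNP's row is incremented once per read; SNPs outside any
    gene model are dropped.  Use :func:`gene_level_counts` to aggregate to
    genes (with per-read deduplication).
    """
    lookup = _gene_lookup(gene_models)
    tallies: Dict[Tuple[str, str, str], List[int]] = {}
    for a in assignments:
        for key in a.snps_covered:
            contig, pos = key.rsplit(":", 1)
            gene = lookup(contig, int(pos) - 1)
            if gene is None:
                continue
            t = tallies.setdefault((gene, key, a.library_id), [0, 0])
            t[0 if a.parent == "maternal" else 1] += 1
    rows = [
        {"gene_id": g, "snp_id": s, "library_id": l, "maternal": m, "paternal": p}
        for (g, s, l), (m, p) in sorted(tallies.items())
    ]
    return pd.DataFrame(rows, columns=SNP_COLUMNS)


def gene_level_counts(
    snp_table: pd.DataFrame,
    assignments: Sequence[ReadAssignment] | None = None,
    gene_models: pd.DataFrame | None = None,
    dedup: bool = True,
) -> pd.DataFrame:
    """Aggregate SNP-level counts to the gene level.

    With ``assignments`` given and ``dedup`` (the default), a read spanning
    several informative SNPs of one gene contributes once to that gene's
    totals, avoiding pseudo-replication in the per-gene model; only reads
    whose covered SNPs survive in ``snp_table`` are counted.  Without
    assignments (count-level simulations, where each simulated read covers
    one SNP) SNP rows are summed directly.
    """
    if assignments is None or not dedup:
        out = (
            snp_table.groupby(["gene_id", "library_id"], as_index=False)
            .agg(maternal=("maternal", "sum"), paternal=("paternal", "sum"),
                 n_snps=("snp_id", "nunique"))
        )
        return out[GENE_COLUMNS]

    if gene_models is None:
        raise ValueError("gene_models required for read-level deduplication")
    lookup = _gene_lookup(gene_models)
    kept_snps = set(snp_table["snp_id"].unique())
    n_snps_per_gene = snp_table.groupby("gene_id")["snp_id"].nunique()
    tallies: Dict[Tuple[str, str], List[int]] = {}
    for a in assignments:
        genes_hit = set()
        for key in a.snps_covered:
            if key not in kept_snps:
                continue
            contig, pos = key.rsplit(":", 1)
            gene = lookup(contig, int(pos) - 1)
            if gene is not None:
                genes_hit.add(gene)
        for gene in genes_hit:
            t = tallies.setdefault((gene, a.library_id), [0, 0])
            t[0 if a.parent == "maternal" else 1] += 1
    rows = [
        {
            "gene_id": g,
            "library_id": l,
            "maternal": m,
            "paternal": p,
            "n_snps": int(n_snps_per_gene.get(g, 0)),
        }
        for (g, l), (m, p) in sorted(tallies.items())
    ]
    return pd.DataFrame(rows, columns=GENE_COLUMNS)


def drop_zero_maternal_snps(
    snp_table: pd.DataFrame, libraries: Sequence[str] | None = None
) -> pd.DataFrame:
    """Remove — from every library — any SNP with zero maternal reads in at
    least one library.

    A SNP absent from a library's rows has zero maternal reads there, so
    the full library universe matters; it defaults to the libraries present
    in the table.
    """
    if snp_table.empty:
        return snp_table.copy()
    if libraries is None:
        libraries = snp_table["library_id"].unique()
    n_libs = len(libraries)
    ok = (
        snp_table[snp_table["maternal"] > 0]
        .groupby("snp_id")["library_id"]
        .nunique()
    )
    keep = set(ok[ok == n_libs].index)
    return snp_table[snp_table["snp_id"].isin(keep)].reset_index(drop=True)


def gene_universe(
    snp_table: pd.DataFrame,
    design: pd.DataFrame,
    min_snps: int = 2,
) -> List[str]:
    """Genes eligible for the parent-of-origin analysis.

    A gene qualifies if it retains at least ``min_snps`` SNPs and has
    nonzero allelic data in every family x direction cell of the design.
    """
    cells = design[["family", "direction"]].drop_duplicates()
    n_fam = design["family"].nunique()
    n_dir = design["direction"].nunique()
    if len(cells) != n_fam * n_dir:
        missing = [
            (f, d)
            for f in design["family"].unique()
            for d in design["direction"].unique()
            if not ((cells["family"] == f) & (cells["direction"] == d)).any()
        ]
        raise ValueError(f"design lacks family x direction cells: {missing}")
    n_cells = len(cells)

    snp_ok = snp_table.groupby("gene_id")["snp_id"].nunique() >= min_snps
    lib_cell = design.set_index("library_id")[["family", "direction"]]
    tab = snp_table[(snp_table["maternal"] + snp_table["paternal"]) > 0].copy()
    tab = tab.join(lib_cell, on="library_id")
    cell_counts = tab.groupby("gene_id").apply(
        lambda d: d[["family", "direction"]].drop_duplicates().shape[0],
        include_groups=False,
    )
    genes = sorted(
        g
        for g in snp_ok.index[snp_ok]
        if cell_counts.get(g, 0) == n_cells
    )
    return genes


def substitute_paternal_zero(gene_table: pd.DataFrame) -> pd.DataFrame:
    """Replace paternal totals of zero with one.

    A zero paternal count makes the per-gene logistic regression perfectly
    separable; the one-read substitution is deliberately asymmetric (only
    paternal counts are rescued) to stay conservative about maternal bias.
    The number of substituted rows is logged and recorded in
    ``result.attrs['n_paternal_zero_substituted']``.
    """
    out = gene_table.copy()
    mask = out["paternal"] == 0
    out.loc[mask, "paternal"] = 1
    n = int(mask.sum())
    if n:
        log.info("substituted paternal zero -> 1 in %d gene x library rows", n)
    out.attrs["n_paternal_zero_substituted"] = n
    return out
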