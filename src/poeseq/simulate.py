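"""Synthetic reciprocal-cross experiments with known truth.

The generator emulates the study design this package targets: two families,
each crossed in both directions between two subspecies lineages (A and B),
giving four colonies; eight workers per colony (two dominant reproductives,
two subordinate reproductives, two nurses, two foragers), each contributing
a head and an abdomen RNA library — 64 libraries in all, 32 per
reproductive status.

Genes are assigned a ground-truth class:

* ``MATERNAL`` / ``PATERNAL`` — imprinted: the maternal-allele proportion is
  fixed regardless of cross direction,
* ``LINEAGE_A`` / ``LINEAGE_B`` — the bias follows the subspecies lineage,
  so the maternal proportion flips between cross directions,
* ``BIALLELIC`` — balanced expression (proportion 0.5).

Per gene and library, total allelic depth is negative-binomial and the
maternal count is beta-binomial (intraclass correlation ``rho`` models the
overdispersion the inference stage must absorb); counts are split across
the gene's SNPs so that maternal + paternal always sums to the allelic
depth at every SNP.  A sequence-level generator produces a reference
contig, parental VCFs, gene models and error-free reads with per-read
parent-of-origin truth, so read assignment can be audited exactly.

All randomness flows from a single root seed through deterministic
per-purpose substreams, so identical configs give byte-identical artifacts.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .variants import GenomeSeq, SnpRecord

MATERNAL = "MATERNAL"
PATERNAL = "PATERNAL"
LINEAGE_A = "LINEAGE_A"
LINEAGE_B = "LINEAGE_B"
BIALLELIC = "BIALLELIC"

#: which subspecies lineage the mother belongs to in each cross direction
DIRECTION_MATERNAL_LINEAGE = {"initial": "A", "reciprocal": "B"}

_WORKER_TYPES = ("dominant_rep", "subordinate_rep", "nurse", "forager")
_STATUS_OF_TYPE = {
    "dominant_rep": "reproductive",
    "subordinate_rep": "reproductive",
    "nurse": "sterile",
    "forager": "sterile",
}

# substream identifiers under the root seed
_STREAM_DESIGN = 0
_STREAM_TRUTH = 1
_STREAM_GENE = 2
_STREAM_SIZE_FACTORS = 3
_STREAM_SEQUENCE = 4


class SimConfigError(ValueError):
    """Raised when a simulation configuration is inconsistent."""


@dataclass
class SimConfig:
    """Parameters of a synthetic reciprocal-cross experiment.

    The design constants (families, directions, workers, tissues) default
    to the full 64-library layout.  ``mean_allelic_depth`` is the expected
    number of informative-SNP reads per gene per library; the default of
    1000 reflects deep bulk libraries where a few percent of reads overlap
    an informative SNP of a given expressed gene.  ``nb_mean`` and
    ``nb_dispersion`` control the whole-gene expression matrix used by the
    differential-expression stage.
    """

    n_genes: int = 500
    snps_per_gene_mean: float = 13.0  # median SNPs/gene observed in this design
    snps_per_gene_min: int = 2
    genome_contig_length: int = 100_000
    n_families: int = 2
    directions: Tuple[str, ...] = ("initial", "reciprocal")
    workers_per_colony: int = 8
    tissues: Tuple[str, ...] = ("head", "abdomen")
    mean_allelic_depth: float = 1000.0
    maternal_prop_imprinted: float = 0.9
    frac_maternal: float = 0.1
    frac_paternal: float = 0.1
    frac_lineage: float = 0.05
    overdispersion_rho: float = 0.05
    nb_mean: float = 50.0
    nb_dispersion: float = 0.3
    status_log2fc: float = 2.0
    frac_de: float = 0.1
    status_effect_on_prop: float = 0.0  # logit shift in reproductive workers
    size_factor_sigma: float = 0.15
    gene_length: int = 400
    gene_gap: int = 100
    read_length: int = 90
    error_rate: float = 0.0
    plant_filter_violations: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise SimConfigError("n_genes must be positive")
        if not 0 < self.maternal_prop_imprinted < 1:
            raise SimConfigError("maternal_prop_imprinted must lie in (0, 1)")
        for name in ("frac_maternal", "frac_paternal", "frac_lineage", "frac_de"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise SimConfigError(f"{name} must lie in [0, 1]")
        if self.frac_maternal + self.frac_paternal + self.frac_lineage > 1:
            raise SimConfigError(
                "frac_maternal + frac_paternal + frac_lineage must not exceed 1"
            )
        if not 0 <= self.overdispersion_rho < 1:
            raise SimConfigError("overdispersion_rho must lie in [0, 1)")
        if self.nb_dispersion < 0 or self.nb_mean <= 0 or self.mean_allelic_depth <= 0:
            raise SimConfigError("count-model parameters must be positive")
        if self.snps_per_gene_min < 0 or self.snps_per_gene_mean < self.snps_per_gene_min:
            raise SimConfigError("snps_per_gene_mean must be >= snps_per_gene_min >= 0")
        if self.workers_per_colony % len(_WORKER_TYPES) != 0:
            raise SimConfigError("workers_per_colony must be a multiple of 4")
        if not set(self.directions) <= {"initial", "reciprocal"}:
            raise SimConfigError("directions must be a subset of {initial, reciprocal}")
        if not 0 <= self.error_rate < 1:
            raise SimConfigError("error_rate must lie in [0, 1)")

    def rng(self, *key: int) -> np.random.Generator:
        """Deterministic substream of the root seed."""
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=key))


def _family_names(n: int) -> List[str]:
    return list(string.ascii_uppercase[:n])


def make_design(config: SimConfig) -> pd.DataFrame:
    """Build the per-library design table.

    One row per library with columns ``library_id, colony, family,
    direction, tissue, worker_type, status, age, weight``.  Families and
    directions are fully crossed (one colony per cell); each colony holds
    equal numbers of the four worker types; every worker yields one library
    per tissue.  Age and weight are standard-normal nuisance covariates.
    """
    config.validate()
    rng = config.rng(_STREAM_DESIGN)
    rows = []
    per_type = config.workers_per_colony // len(_WORKER_TYPES)
    for family in _family_names(config.n_families):
        for direction in config.directions:
            colony = f"{family}-{direction}"
            widx = 0
            for wtype in _WORKER_TYPES:
                for _ in range(per_type):
                    widx += 1
                    age = float(rng.normal())
                    weight = float(rng.normal())
                    for tissue in config.tissues:
                        rows.append(
                            {
                                "library_id": f"{colony}_w{widx:02d}_{tissue}",
                                "colony": colony,
                                "family": family,
                                "direction": direction,
                                "tissue": tissue,
                                "worker_type": wtype,
                                "status": _STATUS_OF_TYPE[wtype],
                                "age": age,
                                "weight": weight,
                            }
                        )
    return pd.DataFrame(rows)


def assign_truth(config: SimConfig) -> pd.DataFrame:
    """Assign each gene a ground-truth class, maternal proportion and
    differential-expression status.

    ``true_maternal_prop`` is the parent-coded proportion: it equals 0.5
    for lineage-biased and biallelic genes because a lineage bias averages
    out across reciprocal directions.
    """
    config.validate()
    rng = config.rng(_STREAM_TRUTH)
    n = config.n_genes
    n_mat = int(round(config.frac_maternal * n))
    n_pat = int(round(config.frac_paternal * n))
    n_lin = int(round(config.frac_lineage * n))
    classes = np.array([BIALLELIC] * n, dtype=object)
    order = rng.permutation(n)
    classes[order[:n_mat]] = MATERNAL
    classes[order[n_mat : n_mat + n_pat]] = PATERNAL
    lin = order[n_mat + n_pat : n_mat + n_pat + n_lin]
    classes[lin[: (n_lin + 1) // 2]] = LINEAGE_A
    classes[lin[(n_lin + 1) // 2 :]] = LINEAGE_B

    m = config.maternal_prop_imprinted
    props = np.where(classes == MATERNAL, m, np.where(classes == PATERNAL, 1 - m, 0.5))

    de_status = np.array(["none"] * n, dtype=object)
    n_de = int(round(config.frac_de * n))
    de_idx = rng.permutation(n)[:n_de]
    de_status[de_idx[: n_de // 2]] = "up"
    de_status[de_idx[n_de // 2 :]] = "down"

    return pd.DataFrame(
        {
            "gene_id": [f"gene{i:05d}" for i in range(n)],
            "true_class": classes,
            "true_maternal_prop": props,
            "de_status": de_status,
        }
    )


def _library_maternal_prop(
    true_class: str, config: SimConfig, direction: str, status: str
) -> float:
    """Expected maternal proportion for one library, before overdispersion."""
    m = config.maternal_prop_imprinted
    if true_class == MATERNAL:
        p = m
    elif true_class == PATERNAL:
        p = 1 - m
    elif true_class in (LINEAGE_A, LINEAGE_B):
        favored = "A" if true_class == LINEAGE_A else "B"
        p = m if DIRECTION_MATERNAL_LINEAGE[direction] == favored else 1 - m
    else:
        p = 0.5
    if config.status_effect_on_prop and status == "reproductive":
        p = float(expit(logit(p) + config.status_effect_on_prop))
    return p


def library_size_factors(config: SimConfig, design: pd.DataFrame) -> pd.Series:
    """Per-library sequencing-depth factors (lognormal, geometric mean 1)."""
    rng = config.rng(_STREAM_SIZE_FACTORS)
    sf = rng.lognormal(mean=0.0, sigma=config.size_factor_sigma, size=len(design))
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=design["library_id"].to_numpy(), name="size_factor")


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Negative binomial with mean mu and variance mu + alpha*mu^2."""
    mu = np.asarray(mu, dtype=float)
    if alpha <= 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mu)
    return rng.poisson(lam)


def _beta_binomial(
    rng: np.random.Generator, n: np.ndarray, p: np.ndarray, rho: float
) -> np.ndarray:
    """Beta-binomial draws with mean n*p and intraclass correlation rho."""
    n = np.asarray(n)
    p = np.asarray(p, dtype=float)
    if rho <= 0:
        return rng.binomial(n, p)
    a = p * (1 - rho) / rho
    b = (1 - p) * (1 - rho) / rho
    return rng.binomial(n, rng.beta(a, b))


def _de_multiplier(de_status: str, status: str, config: SimConfig) -> float:
    if de_status == "none" or status != "reproductive":
        return 1.0
    lfc = config.status_log2fc if de_status == "up" else -config.status_log2fc
    return float(2.0**lfc)


def simulate_allelic_counts(
    config: SimConfig, design: pd.DataFrame, truth: pd.DataFrame | None = None
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the SNP-resolution allelic count table.

    Returns ``(snp_table, truth)`` where ``snp_table`` has one row per
    (gene_id, snp_id, library_id) with positive total depth and columns
    ``maternal``/``paternal``.  Per gene and library the total allelic
    depth is negative-binomial (mean ``mean_allelic_depth`` scaled by the
    library size factor and any differential-expression effect), the
    maternal count is beta-binomial around the class-determined proportion,
    and both are split across the gene's SNPs by a multinomial /
    multivariate-hypergeometric allocation so maternal + paternal equals
    the SNP's depth exactly.
    """
    config.validate()
    if design.empty:
        raise SimConfigError("design must be non-empty")
    if truth is None:
        truth = assign_truth(config)
    sf = library_size_factors(config, design).to_numpy()
    lib_ids = design["library_id"].to_numpy()
    directions = design["direction"].to_numpy()
    statuses = design["status"].to_numpy()
    n_libs = len(design)

    genes, snps, libs, mats, pats = [], [], [], [], []
    for g, row in enumerate(truth.itertuples()):
        rng = config.rng(_STREAM_GENE, g)
        n_snps = config.snps_per_gene_min + int(
            rng.poisson(config.snps_per_gene_mean - config.snps_per_gene_min)
        )
        if n_snps == 0:
            continue
        p_lib = np.array(
            [
                _library_maternal_prop(row.true_class, config, d, s)
                for d, s in zip(directions, statuses)
            ]
        )
        de_mult = np.array(
            [_de_multiplier(row.de_status, s, config) for s in statuses]
        )
        mu = config.mean_allelic_depth * sf * de_mult
        total = _nb_sample(rng, mu, config.nb_dispersion)
        maternal = _beta_binomial(rng, total, p_lib, config.overdispersion_rho)
        snp_ids = [f"{row.gene_id}:snp{j:03d}" for j in range(n_snps)]
        probs = np.full(n_snps, 1.0 / n_snps)
        for i in range(n_libs):
            if total[i] == 0:
                continue
            depth_snp = rng.multinomial(total[i], probs)
            mat_snp = rng.multivariate_hypergeometric(depth_snp, int(maternal[i]))
            nz = np.nonzero(depth_snp)[0]
            for j in nz:
                genes.append(row.gene_id)
                snps.append(snp_ids[j])
                libs.append(lib_ids[i])
                mats.append(int(mat_snp[j]))
                pats.append(int(depth_snp[j] - mat_snp[j]))

    snp_table = pd.DataFrame(
        {
            "gene_id": genes,
            "snp_id": snps,
            "library_id": libs,
            "maternal": mats,
            "paternal": pats,
        }
    )
    return snp_table, truth


def simulate_expression_counts(
    config: SimConfig, design: pd.DataFrame, truth: pd.DataFrame | None = None
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the whole-gene expression matrix (genes x libraries).

    Counts are negative-binomial with mean ``nb_mean`` scaled by library
    size factors, with a ``2**status_log2fc`` effect in reproductive
    workers for genes flagged as differentially expressed.
    """
    config.validate()
    if truth is None:
        truth = assign_truth(config)
    sf = library_size_factors(config, design).to_numpy()
    statuses = design["status"].to_numpy()
    mat = np.zeros((len(truth), len(design)), dtype=int)
    for g, row in enumerate(truth.itertuples()):
        rng = config.rng(_STREAM_GENE, g, 1)
        de_mult = np.array([_de_multiplier(row.de_status, s, config) for s in statuses])
        mu = config.nb_mean * sf * de_mult
        mat[g] = _nb_sample(rng, mu, config.nb_dispersion)
    counts = pd.DataFrame(mat, index=truth["gene_id"], columns=design["library_id"])
    return counts, truth


# ------------------------------------------------------------ sequence level


@dataclass
class SequenceSim:
    """Sequence-level fixture for one colony of a reciprocal cross."""

    reference: GenomeSeq
    queen_records: List[SnpRecord]
    drone_records: List[SnpRecord]
    gene_models: pd.DataFrame  # contig, start (0-based), end, gene_id
    maternal_haplotype: GenomeSeq
    paternal_haplotype: GenomeSeq
    reads: Dict[str, List[Tuple[str, str]]]  # library_id -> [(read_id, seq)]
    read_truth: pd.DataFrame  # read_id, library_id, gene_id, parent, start
    truth: pd.DataFrame
    design: pd.DataFrame


def simulate_sequences(config: SimConfig, direction: str = "initial") -> SequenceSim:
    """Simulate one colony at sequence level.

    Builds a random reference contig carrying non-overlapping gene models,
    places parent-unique SNPs inside genes (the queen's as diploid hom-alt
    calls, the drone's as haploid calls), constructs the true maternal and
    paternal offspring haplotypes, and draws error-free fixed-length reads
    from the haplotype dictated by each gene's truth class.  When
    ``plant_filter_violations`` is set, spurious variant calls (low
    quality, low depth, heterozygous queen, shared by both parents) are
    added to the VCF records; they do not enter the haplotypes and must be
    eliminated by the variant-preparation filters for read assignment to
    be exact.

    Read assignment operates per colony, so one queen/drone pair covers the
    machinery; the count-level generator covers the full 4-colony design.
    """
    config.validate()
    if direction not in DIRECTION_MATERNAL_LINEAGE:
        raise SimConfigError(f"unknown direction {direction!r}")
    span = config.gene_length + config.gene_gap
    needed = config.n_genes * span + config.gene_gap
    if config.genome_contig_length < needed:
        raise SimConfigError(
            f"genome_contig_length {config.genome_contig_length} too small for "
            f"{config.n_genes} genes (need >= {needed})"
        )
    if config.read_length > config.gene_length:
        raise SimConfigError("read_length must not exceed gene_length")

    rng = config.rng(_STREAM_SEQUENCE)
    contig = "contig1"
    bases = np.array(list("ACGT"))
    ref = "".join(rng.choice(bases, size=config.genome_contig_length))

    truth = assign_truth(config)
    models = []
    for g in range(config.n_genes):
        start = config.gene_gap + g * span
        models.append(
            {
                "contig": contig,
                "start": start,
                "end": start + config.gene_length,
                "gene_id": truth["gene_id"].iloc[g],
            }
        )
    gene_models = pd.DataFrame(models)

    queen_records: List[SnpRecord] = []
    drone_records: List[SnpRecord] = []
    maternal_subs: Dict[int, str] = {}  # 0-based pos -> allele
    paternal_subs: Dict[int, str] = {}

    def alt_of(pos0: int) -> str:
        choices = [b for b in "ACGT" if b != ref[pos0]]
        return str(rng.choice(choices))

    for g, gm in enumerate(gene_models.itertuples()):
        n_snps = config.snps_per_gene_min + int(
            rng.poisson(config.snps_per_gene_mean - config.snps_per_gene_min)
        )
        n_snps = min(n_snps, config.gene_length // 4)
        positions = np.sort(
            rng.choice(np.arange(gm.start, gm.end), size=n_snps, replace=False)
        )
        for pos0 in positions:
            alt = alt_of(int(pos0))
            if rng.random() < 0.5:  # maternal-unique: queen hom-alt, drone ref
                maternal_subs[int(pos0)] = alt
                queen_records.append(
                    SnpRecord(contig, int(pos0) + 1, ref[pos0], alt, 60.0, 30, 28, "hom_alt", 2)
                )
            else:  # paternal-unique: drone alt, queen hom-ref
                paternal_subs[int(pos0)] = alt
                drone_records.append(
                    SnpRecord(contig, int(pos0) + 1, ref[pos0], alt, 60.0, 30, 29, "hom_alt", 1)
                )

    if config.plant_filter_violations:
        used = set(maternal_subs) | set(paternal_subs)
        free = [p for p in range(config.gene_gap, needed - 1) if p not in used]
        noise_pos = rng.choice(free, size=4, replace=False)
        p0, p1, p2, p3 = (int(p) for p in noise_pos)
        # spurious calls: removed by the quality filter, the queen hom-alt
        # filter and the parent-unique subtraction respectively
        queen_records.append(SnpRecord(contig, p0 + 1, ref[p0], alt_of(p0), 10.0, 30, 20, "hom_alt", 2))
        queen_records.append(SnpRecord(contig, p1 + 1, ref[p1], alt_of(p1), 60.0, 3, 2, "hom_alt", 2))
        queen_records.append(SnpRecord(contig, p2 + 1, ref[p2], alt_of(p2), 60.0, 30, 14, "het", 2))
        shared_alt = alt_of(p3)
        queen_records.append(SnpRecord(contig, p3 + 1, ref[p3], shared_alt, 60.0, 30, 28, "hom_alt", 2))
        drone_records.append(SnpRecord(contig, p3 + 1, ref[p3], shared_alt, 60.0, 30, 29, "hom_alt", 1))

    ref_list = list(ref)
    mat_list = list(ref)
    pat_list = list(ref)
    for pos0, allele in maternal_subs.items():
        mat_list[pos0] = allele
    for pos0, allele in paternal_subs.items():
        pat_list[pos0] = allele
    reference = {contig: "".join(ref_list)}
    maternal_hap = {contig: "".join(mat_list)}
    paternal_hap = {contig: "".join(pat_list)}

    design_cfg = SimConfig(**{**config.__dict__, "n_families": 1, "directions": (direction,)})
    design = make_design(design_cfg)

    reads: Dict[str, List[Tuple[str, str]]] = {lib: [] for lib in design["library_id"]}
    truth_rows = []
    read_counter = 0
    for lib_row in design.itertuples():
        lib_rng = config.rng(_STREAM_SEQUENCE, 1, lib_row.Index)
        for g, gm in enumerate(gene_models.itertuples()):
            tclass = truth["true_class"].iloc[g]
            p_mat = _library_maternal_prop(tclass, config, lib_row.direction, lib_row.status)
            n_reads = lib_rng.poisson(config.mean_allelic_depth)
            if n_reads == 0:
                continue
            starts = lib_rng.integers(gm.start, gm.end - config.read_length + 1, size=n_reads)
            parents = np.where(lib_rng.random(n_reads) < p_mat, "maternal", "paternal")
            for start, parent in zip(starts, parents):
                hap = maternal_hap if parent == "maternal" else paternal_hap
                seq = hap[contig][start : start + config.read_length]
                if config.error_rate > 0:
                    seq_arr = np.array(list(seq))
                    errs = np.nonzero(lib_rng.random(len(seq)) < config.error_rate)[0]
                    for e in errs:
                        seq_arr[e] = lib_rng.choice([b for b in "ACGT" if b != seq_arr[e]])
                    seq = "".join(seq_arr)
                read_id = f"read{read_counter:07d}"
                read_counter += 1
                reads[lib_row.library_id].append((read_id, seq))
                truth_rows.append(
                    {
                        "read_id": read_id,
                        "library_id": lib_row.library_id,
                        "gene_id": gm.gene_id,
                        "parent": parent,
                        "start": int(start),
                    }
                )

    queen_records.sort(key=lambda r: (r.contig, r.pos))
    drone_records.sort(key=lambda r: (r.contig, r.pos))
    return SequenceSim(
        reference=reference,
        queen_records=queen_records,
        drone_records=drone_records,
        gene_models=gene_models,
        maternal_haplotype=maternal_hap,
        paternal_haplotype=paternal_hap,
        reads=reads,
        read_truth=pd.DataFrame(truth_rows),
        truth=truth,
        design=design,
    )
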