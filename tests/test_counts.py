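"""Read assignment and the count-filter cascade."""

import collections

import numpy as np
import pandas as pd
import pytest

from poeseq import (
    assign_reads,
    count_by_snp,
    drop_zero_maternal_snps,
    gene_level_counts,
    gene_universe,
    substitute_paternal_zero,
)
from poeseq.counts import ReadAssignment
from poeseq.variants import (
    InformativeSnp,
    apply_snps,
    filter_snps,
    select_queen_homalt,
    unique_snps,
)


@pytest.fixture(scope="module")
def prepared(small_seq_sim):
    """Variant-prep products for the shared sequence simulation."""
    cfg, sim = small_seq_sim
    queen = select_queen_homalt(filter_snps(sim.queen_records))
    drone = filter_snps(sim.drone_records)
    mat_u, pat_u = unique_snps(queen, drone)
    informative = mat_u + pat_u
    mg = apply_snps(sim.reference, mat_u)
    pg = apply_snps(sim.reference, pat_u)
    return cfg, sim, informative, mg, pg


@pytest.fixture(scope="module")
def assigned(prepared):
    cfg, sim, informative, mg, pg = prepared
    assignments = []
    n_discarded = 0
    for lib, reads in sim.reads.items():
        a, d = assign_reads(reads, lib, mg, pg, informative)
        assignments.extend(a)
        n_discarded += d
    return assignments, n_discarded


class TestVariantPrepRecoversHaplotypes:
    def test_filtered_genomes_equal_true_haplotypes(self, prepared):
        cfg, sim, informative, mg, pg = prepared
        assert mg == sim.maternal_haplotype
        assert pg == sim.paternal_haplotype


class TestAssignReads:
    def test_all_retained_assignments_match_truth(self, prepared, assigned):
        cfg, sim, *_ = prepared
        assignments, _ = assigned
        truth = sim.read_truth.set_index("read_id")["parent"]
        assert len(assignments) > 0
        assert all(truth[a.read_id] == a.parent for a in assignments)
        assert all(a.snps_covered for a in assignments)

    def test_conservation_assigned_plus_discarded(self, prepared, assigned):
        cfg, sim, *_ = prepared
        assignments, n_discarded = assigned
        n_reads = sum(len(r) for r in sim.reads.values())
        assert len(assignments) + n_discarded == n_reads

    def test_read_without_informative_snp_discarded(self):
        mg = {"c1": "AAAATTTTCCCCGGGG"}
        pg = {"c1": "AAAATTTTCCCCGGGA"}  # differ only at last base
        informative = [InformativeSnp("c1", 16, "maternal", "G", "A")]
        reads = [("r1", "AAAATTTT")]  # matches both genomes
        a, d = assign_reads(reads, "lib1", mg, pg, informative)
        assert a == [] and d == 1

    def test_snp_covering_read_assigned_to_matching_parent(self):
        mg = {"c1": "AAAATTTTCCCCGGGG"}
        pg = {"c1": "AAAATTTTCACCGGGG"}  # paternal allele A at pos 10
        informative = [InformativeSnp("c1", 10, "paternal", "A", "C")]
        a, d = assign_reads([("r1", "CACCGG")], "lib1", mg, pg, informative)
        assert len(a) == 1 and a[0].parent == "paternal"
        assert a[0].snps_covered == ("c1:10",)
        b, _ = assign_reads([("r2", "CCCCGG")], "lib1", mg, pg, informative)
        assert b[0].parent == "maternal"

    def test_per_snp_counts_equal_truth_allocations(self, prepared, assigned):
        cfg, sim, informative, *_ = prepared
        assignments, _ = assigned
        table = count_by_snp(assignments, sim.gene_models)
        snp_pos = {f"{s.contig}:{s.pos}": s.pos - 1 for s in informative}
        oracle = collections.Counter()
        for r in sim.read_truth.itertuples():
            for key, p0 in snp_pos.items():
                if r.start <= p0 < r.start + cfg.read_length:
                    oracle[(r.gene_id, key, r.library_id, r.parent)] += 1
        for row in table.itertuples():
            assert oracle[(row.gene_id, row.snp_id, row.library_id, "maternal")] == row.maternal
            assert oracle[(row.gene_id, row.snp_id, row.library_id, "paternal")] == row.paternal
        n_expected_rows = len({k[:3] for k in oracle})
        assert len(table) == n_expected_rows

    def test_label_symmetry_swapping_genomes(self, prepared):
        cfg, sim, informative, mg, pg = prepared
        lib, reads = next(iter(sim.reads.items()))
        fwd, _ = assign_reads(reads, lib, mg, pg, informative)
        rev, _ = assign_reads(reads, lib, pg, mg, informative)
        swap = {"maternal": "paternal", "paternal": "maternal"}
        assert {a.read_id: swap[a.parent] for a in fwd} == {
            a.read_id: a.parent for a in rev
        }


def _asg(read_id, lib, snps, parent="maternal", contig="c1", start=0, end=10):
    return ReadAssignment(read_id, lib, contig, start, end, parent, tuple(snps))


class TestCountBySnp:
    GENES = pd.DataFrame(
        {"contig": ["c1", "c1"], "start": [0, 100], "end": [50, 150],
         "gene_id": ["g1", "g2"]}
    )

    def test_read_covering_two_snps_counts_once_per_gene(self):
        a = [_asg("r1", "L1", ["c1:10", "c1:20"])]
        snp_tab = count_by_snp(a, self.GENES)
        assert len(snp_tab) == 2
        assert (snp_tab["maternal"] == 1).all()
        gene_tab = gene_level_counts(snp_tab, a, self.GENES)
        assert len(gene_tab) == 1
        assert gene_tab["maternal"].iloc[0] == 1

    def test_empty_assignments(self):
        assert count_by_snp([], self.GENES).empty

    def test_intergenic_snps_dropped(self):
        a = [_asg("r1", "L1", ["c1:60"])]  # between the two genes
        assert count_by_snp(a, self.GENES).empty

    def test_overlapping_models_rejected(self):
        bad = pd.DataFrame(
            {"contig": ["c1", "c1"], "start": [0, 30], "end": [50, 80],
             "gene_id": ["g1", "g2"]}
        )
        with pytest.raises(ValueError, match="overlap"):
            count_by_snp([], bad)


def _snp_row(gene, snp, lib, m, p):
    return {"gene_id": gene, "snp_id": snp, "library_id": lib,
            "maternal": m, "paternal": p}


class TestDropZeroMaternal:
    def test_zero_in_one_library_removed_everywhere(self):
        libs = [f"L{i}" for i in range(4)]
        rows = [_snp_row("g1", "s1", l, 5, 5) for l in libs[:3]]
        rows += [_snp_row("g1", "s1", "L3", 0, 7)]
        rows += [_snp_row("g1", "s2", l, 3, 3) for l in libs]
        tab = pd.DataFrame(rows)
        out = drop_zero_maternal_snps(tab, libraries=libs)
        assert set(out["snp_id"]) == {"s2"}

    def test_missing_library_counts_as_zero(self):
        libs = ["L0", "L1"]
        tab = pd.DataFrame([_snp_row("g1", "s1", "L0", 5, 5)])
        out = drop_zero_maternal_snps(tab, libraries=libs)
        assert out.empty

    def test_matches_bruteforce_scan(self, rng):
        libs = [f"L{i}" for i in range(6)]
        rows = []
        for s in range(30):
            for l in libs:
                if rng.random() < 0.9:
                    rows.append(
                        _snp_row("g1", f"s{s}", l, int(rng.integers(0, 4)),
                                 int(rng.integers(0, 4)))
                    )
        tab = pd.DataFrame(rows)
        out = drop_zero_maternal_snps(tab, libraries=libs)
        expected = set()
        for s in tab["snp_id"].unique():  # naive per-SNP scan
            sub = tab[tab["snp_id"] == s].set_index("library_id")["maternal"]
            if all(sub.get(l, 0) > 0 for l in libs):
                expected.add(s)
        assert set(out["snp_id"]) == expected

    def test_idempotent(self, rng):
        libs = [f"L{i}" for i in range(3)]
        rows = [
            _snp_row("g1", f"s{s}", l, int(rng.integers(0, 3)), 1)
            for s in range(10) for l in libs
        ]
        tab = pd.DataFrame(rows)
        once = drop_zero_maternal_snps(tab, libraries=libs)
        twice = drop_zero_maternal_snps(once, libraries=libs)
        pd.testing.assert_frame_equal(once, twice)


class TestGeneUniverse:
    def _design(self):
        rows = []
        for fam in "AB":
            for direction in ("initial", "reciprocal"):
                rows.append(
                    {"library_id": f"{fam}-{direction}-lib", "family": fam,
                     "direction": direction}
                )
        return pd.DataFrame(rows)

    def test_single_snp_gene_excluded(self):
        design = self._design()
        rows = [
            _snp_row("g1", "g1s1", lib, 2, 2) for lib in design["library_id"]
        ]
        assert gene_universe(pd.DataFrame(rows), design) == []

    def test_gene_present_everywhere_included(self):
        design = self._design()
        rows = []
        for snp in ("s1", "s2", "s3"):
            rows += [_snp_row("g1", snp, lib, 2, 2) for lib in design["library_id"]]
        assert gene_universe(pd.DataFrame(rows), design) == ["g1"]

    def test_gene_missing_one_cell_excluded(self):
        design = self._design()
        libs = design["library_id"].tolist()
        rows = []
        for snp in ("s1", "s2"):
            rows += [_snp_row("g1", snp, lib, 2, 2) for lib in libs[:3]]
        assert gene_universe(pd.DataFrame(rows), design) == []

    def test_matches_bruteforce_predicate(self, rng):
        design = self._design()
        libs = design["library_id"].tolist()
        rows = []
        for g in range(20):
            n_snps = int(rng.integers(1, 4))
            for s in range(n_snps):
                for lib in libs:
                    if rng.random() < 0.7:
                        rows.append(_snp_row(f"g{g}", f"g{g}s{s}", lib, 1, 1))
        tab = pd.DataFrame(rows)
        got = gene_universe(tab, design, min_snps=2)
        cell_of = design.set_index("library_id").apply(tuple, axis=1)
        expected = []
        for g in sorted(tab["gene_id"].unique()):
            sub = tab[tab["gene_id"] == g]
            if sub["snp_id"].nunique() < 2:
                continue
            cells = {tuple(cell_of[l]) for l in sub["library_id"]}
            if len(cells) == 4:
                expected.append(g)
        assert got == expected

    def test_missing_design_cell_raises(self):
        design = self._design().iloc[:3]
        with pytest.raises(ValueError, match="family x direction"):
            gene_universe(pd.DataFrame([_snp_row("g", "s", "L", 1, 1)]), design)


class TestSubstitutePaternalZero:
    def test_zero_becomes_one(self):
        tab = pd.DataFrame(
            [{"gene_id": "g1", "library_id": "L1", "maternal": 40, "paternal": 0,
              "n_snps": 2}]
        )
        out = substitute_paternal_zero(tab)
        assert out["paternal"].iloc[0] == 1
        assert out["maternal"].iloc[0] == 40

    def test_nonzero_untouched(self):
        tab = pd.DataFrame(
            [{"gene_id": "g1", "library_id": "L1", "maternal": 40, "paternal": 7,
              "n_snps": 2}]
        )
        out = substitute_paternal_zero(tab)
        assert out["paternal"].iloc[0] == 7

    def test_substitution_count_matches_scan(self, rng):
        n = 50
        tab = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n)],
                "library_id": "L1",
                "maternal": rng.integers(1, 50, n),
                "paternal": rng.integers(0, 3, n),
                "n_snps": 2,
            }
        )
        expected = int(sum(1 for v in tab["paternal"] if v == 0))
        out = substitute_paternal_zero(tab)
        assert out.attrs["n_paternal_zero_substituted"] == expected
        assert int((out["paternal"] == 1).sum()) >= expected
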