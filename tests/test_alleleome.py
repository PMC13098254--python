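"""Allele tables, dominance thresholds, substitution character, clade splits."""
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pangem.alleleome import (
    Allele,
    allele_length_summary,
    allele_tree,
    build_allele_table,
    dominant_alleles,
    nj_tree,
    p_distance,
    substitution_profile,
)
from pangem.pangenome import GeneFamily, ProteinRecord


def family_from(seqs_by_strain: dict[str, str], fid: str = "F1") -> GeneFamily:
    members = [ProteinRecord(s, f"{s}_g", seq) for s, seq in seqs_by_strain.items()]
    return GeneFamily(fid, members[0], members, [100.0] * len(members))


class TestAlleleTable:
    def test_identical_sequences_one_allele(self):
        fam = family_from({f"S{i}": "MKLV" * 10 for i in range(10)})
        table = build_allele_table([fam])
        alleles = table.alleles["F1"]
        assert len(alleles) == 1
        assert alleles[0].strain_count == 10

    def test_two_alleles_ranked_by_count(self):
        fam = family_from({"S1": "MKLV", "S2": "MKLV", "S3": "MALV"})
        alleles = build_allele_table([fam]).alleles["F1"]
        assert [a.strain_count for a in alleles] == [2, 1]
        assert alleles[0].sequence == "MKLV"

    def test_shared_count_alleles_get_sequential_suffixes(self):
        fam = family_from({"S1": "AAAA", "S2": "AAAA", "S3": "CCCC", "S4": "DDDD", "S5": "EEEE"})
        names = [a.name for a in build_allele_table([fam]).alleles["F1"]]
        assert names == ["2", "1-1", "1-2", "1-3"]

    def test_zero_mutation_world_has_one_allele_per_family(self):
        from pangem.synth import WorldConfig, generate_world
        from pangem.pangenome import cluster_gene_families

        w = generate_world(
            WorldConfig(n_strains=5, n_core_families=6, n_accessory_families=6, n_rare_families=1,
                        allele_mutation_rate=0.0, n_substrates=2, n_pathways=2,
                        pathway_length_range=(1, 2), seed=9)
        )
        recs = [ProteinRecord(s, g, seq) for s, genes in w.proteomes.items() for g, seq in genes]
        table = build_allele_table(cluster_gene_families(recs, 0.9))
        assert all(len(v) == 1 for v in table.alleles.values())

    def test_strain_counts_conserve_member_pairs(self, small_world):
        from pangem.pangenome import cluster_gene_families

        recs = [
            ProteinRecord(s, g, seq) for s, genes in small_world.proteomes.items() for g, seq in genes
        ]
        fams = cluster_gene_families(recs, 0.9)
        table = build_allele_table(fams)
        for fam in fams:
            pairs = {(m.strain, m.sequence) for m in fam.members}
            assert sum(a.strain_count for a in table.alleles[fam.family_id]) == len(pairs)


class TestDominance:
    def _table(self, count: int, total_alleles: int = 2) -> tuple:
        fam = family_from(
            {f"S{i}": "AAAA" for i in range(count)} | {f"T{i}": "CCCC" for i in range(3)}
        )
        return build_allele_table([fam])

    def test_strictly_over_half_included(self):
        table = self._table(83)
        assert any(a.strain_count == 83 for _, a in dominant_alleles(table, 164))

    def test_exactly_half_excluded(self):
        table = self._table(82)
        assert all(a.strain_count != 82 for _, a in dominant_alleles(table, 164))

    @given(st.floats(0.1, 0.9), st.floats(0.1, 0.9))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_fraction(self, f1, f2):
        table = self._table(40)
        lo, hi = sorted([f1, f2])
        assert {a.name for _, a in dominant_alleles(table, 60, hi)} <= {
            a.name for _, a in dominant_alleles(table, 60, lo)
        }


class TestLengths:
    def test_mean_median_simple(self):
        fam = family_from({"S1": "A" * 100, "S2": "C" * 200})
        table = build_allele_table([fam])
        subset = [("F1", a) for a in table.alleles["F1"]]
        assert allele_length_summary(table, subset) == (150.0, 150.0)

    def test_skewed_lengths(self):
        fam = family_from({"S1": "A", "S2": "CC", "S3": "D" * 1000})
        table = build_allele_table([fam])
        subset = [("F1", a) for a in table.alleles["F1"]]
        mean, median = allele_length_summary(table, subset)
        assert mean == pytest.approx(334.33, abs=0.01)
        assert median == 2

    def test_empty_subset_rejected(self):
        table = build_allele_table([family_from({"S1": "AAAA"})])
        with pytest.raises(ValueError):
            allele_length_summary(table, [])


class TestSubstitutions:
    def test_d_to_e_is_conservative(self):
        a = Allele("F", "2", "MKDLV", frozenset({"S1", "S2"}))
        b = Allele("F", "1", "MKELV", frozenset({"S3"}))
        prof = substitution_profile([a, b])
        assert prof == {"conservative": 1, "non_conservative": 0, "indel_columns": 0}

    def test_g_to_w_is_non_conservative(self):
        a = Allele("F", "2", "MKGLV", frozenset({"S1", "S2"}))
        b = Allele("F", "1", "MKWLV", frozenset({"S3"}))
        prof = substitution_profile([a, b])
        assert prof["non_conservative"] == 1 and prof["conservative"] == 0

    def test_within_group_generator_is_fully_conservative(self):
        rng = np.random.default_rng(12)
        groups = ["AVLIMC", "FWY", "ST", "NQ", "DE", "KRH"]
        base = "".join(rng.choice(list("".join(groups)), size=120))
        variants = []
        for k in range(4):
            arr = list(base)
            for pos in rng.choice(120, size=5, replace=False):
                grp = next(g for g in groups if arr[pos] in g)
                alternatives = [c for c in grp if c != arr[pos]]
                if alternatives:
                    arr[pos] = rng.choice(alternatives)
            variants.append("".join(arr))
        alleles = [Allele("F", str(9 - i), s, frozenset({f"S{i}"})) for i, s in enumerate([base] + variants)]
        prof = substitution_profile(alleles)
        assert prof["non_conservative"] == 0 and prof["conservative"] > 0


class TestDistancesAndTrees:
    @given(st.integers(0, 5000))
    @settings(max_examples=40, deadline=None)
    def test_p_distance_is_a_metric_on_equal_lengths(self, seed):
        rng = np.random.default_rng(seed)
        seqs = ["".join(rng.choice(list("ACDEFGHIKL"), size=30)) for _ in range(3)]
        a, b, c = seqs
        assert p_distance(a, b) == p_distance(b, a)
        assert p_distance(a, c) <= p_distance(a, b) + p_distance(b, c) + 1e-12
        assert p_distance(a, a) == 0.0

    def test_two_tight_pairs_split_into_pairs(self):
        base1 = "MKLVAGHTRW" * 6
        base2 = "PFYQNCDEIS" * 6
        alleles = [
            Allele("F", "4", base1, frozenset({"S1"})),
            Allele("F", "3", base1[:-1] + "A", frozenset({"S2"})),
            Allele("F", "2", base2, frozenset({"S3"})),
            Allele("F", "1", base2[:-1] + "A", frozenset({"S4"})),
        ]
        split = allele_tree(alleles)
        assert {tuple(sorted(split.major)), tuple(sorted(split.minor))} == {("3", "4"), ("1", "2")}

    def test_three_equidistant_alleles_tie_resolved_by_strain_count(self):
        # pairwise distances all equal; major clade = 2 alleles, fraction 2/3
        alleles = [
            Allele("F", "5", "AAAA", frozenset({f"S{i}" for i in range(5)})),
            Allele("F", "1-1", "CCCC", frozenset({"T1"})),
            Allele("F", "1-2", "DDDD", frozenset({"T2"})),
        ]
        split = allele_tree(alleles)
        assert split.major_fraction == pytest.approx(2 / 3)
        assert len(split.major) == 2

    def test_star_data_major_clade_contains_dominant(self):
        base = "MKLVAGHTRWPFYQNCDEIS" * 3
        sats = []
        for i in range(4):
            arr = list(base)
            arr[i * 3] = "W" if arr[i * 3] != "W" else "Y"
            sats.append("".join(arr))
        alleles = [Allele("F", "9", base, frozenset({f"S{i}" for i in range(9)}))] + [
            Allele("F", f"1-{i+1}", s, frozenset({f"T{i}"})) for i, s in enumerate(sats)
        ]
        split = allele_tree(alleles)
        assert "9" in split.major

    def test_fewer_than_three_alleles_rejected(self):
        alleles = [Allele("F", "2", "AAAA", frozenset({"S1", "S2"})), Allele("F", "1", "CCCC", frozenset({"S3"}))]
        with pytest.raises(ValueError):
            allele_tree(alleles)

    @given(st.integers(0, 2000))
    @settings(max_examples=25, deadline=None)
    def test_nj_recovers_additive_five_leaf_trees(self, seed):
        """NJ on additive 5-leaf distances recovers the generating topology's splits."""
        rng = np.random.default_rng(seed)
        names = list("abcde")
        # random unrooted binary topology via random split {x,y} | {rest}
        pairs = list(itertools.combinations(range(5), 2))
        cherry = pairs[rng.integers(len(pairs))]
        rest = [i for i in range(5) if i not in cherry]
        rng.shuffle(rest)
        # tree: ((x,y),(u,v),w) with internal edges
        bl = rng.uniform(0.05, 1.0, size=7)
        dist = np.zeros((5, 5))
        x, y = cherry
        u, v, w = rest
        # leaf edges bl[0..4]; internal edges bl[5] (xy-node) and bl[6] (uv-node)
        d_to_center = {x: bl[0] + bl[5], y: bl[1] + bl[5], u: bl[2] + bl[6], v: bl[3] + bl[6], w: bl[4]}
        for i, j in itertools.combinations(range(5), 2):
            if {i, j} == {x, y}:
                dist[i, j] = bl[0] + bl[1]
            elif {i, j} == {u, v}:
                dist[i, j] = bl[2] + bl[3]
            else:
                dist[i, j] = d_to_center[i] + d_to_center[j]
            dist[j, i] = dist[i, j]
        tree = nj_tree(dist, names)
        splits = set()
        for node in tree.non_tips():
            tips = frozenset(t.name for t in node.tips())
            if 2 <= len(tips) <= 3:
                splits.add(frozenset({tips, frozenset(names) - tips}))
        true_splits = {
            frozenset({frozenset({names[x], names[y]}), frozenset({names[u], names[v], names[w]})}),
            frozenset({frozenset({names[u], names[v]}), frozenset({names[x], names[y], names[w]})}),
        }
        assert true_splits <= splits
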