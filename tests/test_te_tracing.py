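import numpy as np
import pytest

from symbiocensus.io_formats import GeneFeature, SequenceRecord, read_newick
from symbiocensus.pangenome_identity import OrthologFamily
from symbiocensus.synthetic_data import (
    SimulationConfig,
    TEHistorySpec,
    simulate_te_families,
)
from symbiocensus.te_tracing import (
    MSA,
    TEFamily,
    bootstrap_support,
    build_msa,
    classify_sharing,
    find_shared_te_families,
    flag_degraded,
    nj_tree,
    protein_distance_matrix,
    trace_family,
    trim_alignment,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestFindShared:
    def _features(self):
        return [
            GeneFeature("t1", "X", "X", 1, 300, "+", "transposase", "IS6", "M" * 99),
            GeneFeature("t2", "Y", "Y", 1, 300, "+", "transposase", "IS6", "M" * 99),
            GeneFeature("c1", "X", "X", 400, 700, "+", "CDS", "x", "K" * 99),
        ]

    def test_family_spanning_two_genomes_is_shared(self):
        fams = [OrthologFamily("t1", [("t1", "X"), ("t2", "Y")])]
        out = find_shared_te_families(fams, self._features())
        assert len(out) == 1 and out[0].genomes == {"X", "Y"}

    def test_single_genome_family_not_shared(self):
        fams = [OrthologFamily("t1", [("t1", "X")])]
        assert find_shared_te_families(fams, self._features()) == []

    def test_non_transposase_members_excluded(self):
        fams = [OrthologFamily("t1", [("t1", "X"), ("c1", "X"), ("t2", "Y")])]
        (fam,) = find_shared_te_families(fams, self._features())
        assert sorted(r.id for _, r in fam.members) == ["t1", "t2"]

    def test_recovery_of_simulated_shared_families(self):
        cfg = SimulationConfig(seed=21)
        res = simulate_te_families(cfg)
        fams = []
        feats = []
        for fid, members in res.families.items():
            fams.append(
                OrthologFamily(fid, [(rec.id, g) for g, rec in members])
            )
            for g, rec in members:
                feats.append(
                    GeneFeature(rec.id, g, g, 1, 3 * len(rec.residues) + 3, "+",
                                "transposase", "IS256 family transposase",
                                rec.residues)
                )
        shared = {f.family_id for f in find_shared_te_families(fams, feats)}
        expected = {fid for fid, lab in res.labels.items() if lab != "none"}
        assert shared == expected


class TestBuildMsa:
    def test_identical_sequences_gapless(self):
        m = build_msa([("a", "MKLVWT"), ("b", "MKLVWT")])
        assert m.rows == ["MKLVWT", "MKLVWT"]

    def test_single_deletion_places_gap_opposite_missing_residue(self):
        m = build_msa([("x", "ACDEFG"), ("y", "ACEFG")])
        rows = dict(zip(m.ids, m.rows))
        assert rows["x"] == "ACDEFG"
        assert rows["y"] == "AC-EFG"

    def test_pairwise_score_matches_exhaustive_dp_oracle(self):
        from _oracles import exhaustive_affine_nw, msa_pair_score

        rng = np.random.default_rng(11)
        for _ in range(10):
            a = "".join(rng.choice(list(AA), size=int(rng.integers(8, 30))))
            b = list(a)
            for _ in range(int(rng.integers(0, 5))):
                op = rng.integers(3)
                pos = int(rng.integers(len(b)))
                if op == 0:
                    b[pos] = AA[int(rng.integers(20))]
                elif op == 1 and len(b) > 5:
                    del b[pos]
                else:
                    b.insert(pos, AA[int(rng.integers(20))])
            b = "".join(b)
            m = build_msa([("a", a), ("b", b)])
            rows = dict(zip(m.ids, m.rows))
            assert msa_pair_score(rows["a"], rows["b"]) == pytest.approx(
                exhaustive_affine_nw(a, b)
            )

    def test_rows_degap_to_inputs_and_column_count(self):
        rng = np.random.default_rng(12)
        seqs = []
        for i in range(6):
            n = int(rng.integers(50, 120))
            seqs.append((f"s{i}", "".join(rng.choice(list(AA), size=n))))
        m = build_msa(seqs)
        originals = dict(seqs)
        for i, sid in enumerate(m.ids):
            assert m.degapped(i) == originals[sid]
        assert m.n_cols >= max(len(s) for _, s in seqs)

    def test_single_sequence_error(self):
        with pytest.raises(ValueError):
            build_msa([("a", "MKLV")])


class TestTrim:
    def test_all_gap_column_removed(self):
        m = MSA(["a", "b"], ["MK-L", "MK-L"])
        assert trim_alignment(m).rows == ["MKL", "MKL"]

    def test_fully_conserved_alignment_unchanged(self):
        m = MSA(["a", "b", "c"], ["MKLV"] * 3)
        assert trim_alignment(m).rows == ["MKLV"] * 3

    def test_gap_fraction_threshold(self):
        # column 1: 3 gaps of 5 rows (0.6 > 0.5) -> removed
        rows = ["-K", "-K", "-K", "MK", "MK"]
        m = MSA(list("abcde"), rows)
        t = trim_alignment(m)
        assert t.rows == ["K"] * 5

    def test_high_entropy_column_removed(self):
        # 20 distinct residues in one column: normalized entropy 1 > 0.6
        rows = [a + "K" for a in AA]
        m = MSA([f"s{i}" for i in range(20)], rows)
        t = trim_alignment(m)
        assert t.rows == ["K"] * 20

    def test_idempotent(self):
        rng = np.random.default_rng(13)
        seqs = [(f"s{i}", "".join(rng.choice(list(AA), size=60))) for i in range(4)]
        m = build_msa(seqs)
        t1 = trim_alignment(m)
        t2 = trim_alignment(t1)
        assert t1.rows == t2.rows

    def test_everything_removed_error(self):
        m = MSA(["a", "b"], ["M-", "-K"])
        with pytest.raises(ValueError, match="relax"):
            trim_alignment(m, max_gap_fraction=0.3)


class TestDistances:
    def test_identical_rows_zero(self):
        m = MSA(["a", "b"], ["MKLV" * 10, "MKLV" * 10])
        _, D = protein_distance_matrix(m)
        assert D[0, 1] == 0.0

    def test_poisson_correction_closed_form(self):
        # 10% mismatches -> d = -ln(0.9)
        a = "A" * 100
        b = "A" * 90 + "C" * 10
        _, D = protein_distance_matrix(MSA(["a", "b"], [a, b]))
        assert D[0, 1] == pytest.approx(-np.log(0.9), abs=1e-9)

    def test_simulated_divergence_recovered(self):
        spec = TEHistorySpec(n_recent=0, n_ancient=6, n_vertical=0,
                             divergence=0.3, te_length=300, copies_per_genome=2)
        cfg = SimulationConfig(seed=22, te_history=spec)
        res = simulate_te_families(cfg)
        ds = []
        for fid, members in res.families.items():
            msa = build_msa([rec for _, rec in members])
            labels, D = protein_distance_matrix(msa)
            genome_of = {rec.id: g for g, rec in members}
            cross = [
                D[i, j]
                for i in range(len(labels))
                for j in range(i + 1, len(labels))
                if genome_of[labels[i]] != genome_of[labels[j]]
            ]
            ds.append(np.mean(cross))
        assert np.mean(ds) == pytest.approx(0.3, abs=0.05)

    def test_insufficient_overlap_error_names_pair(self):
        m = MSA(["a", "b"], ["MK" + "-" * 40, "-" * 40 + "MK"])
        with pytest.raises(ValueError, match="a.*b"):
            protein_distance_matrix(m)


class TestNeighborJoining:
    def test_four_taxon_additive_matrix_exact(self):
        # tree ((A:1,B:2):1,(C:3,D:4))
        labels = ["A", "B", "C", "D"]
        D = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        tree = nj_tree(labels, D)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for i in range(4):
            for j in range(i + 1, 4):
                assert pdm.patristic_distance(
                    taxa[labels[i]], taxa[labels[j]]
                ) == pytest.approx(D[i, j], abs=1e-9)
        # internal branch of length 1 separates AB from CD
        from _oracles import tree_quartets

        quartets = tree_quartets(tree, labels)
        assert quartets[(0, 1, 2, 3)] == frozenset(
            (frozenset((0, 1)), frozenset((2, 3)))
        )

    def test_three_taxon_closed_form(self):
        labels = ["A", "B", "C"]
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = nj_tree(labels, D)
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
        }
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_taxon_order_invariance(self):
        from _oracles import random_additive_tree

        rng = np.random.default_rng(14)
        _, labels, D = random_additive_tree(rng, 6)
        tree1 = nj_tree(labels, D)
        perm = list(rng.permutation(len(labels)))
        labels2 = [labels[i] for i in perm]
        D2 = D[np.ix_(perm, perm)]
        tree2 = nj_tree(labels2, D2)
        pdm1 = tree1.phylogenetic_distance_matrix()
        pdm2 = tree2.phylogenetic_distance_matrix()
        tax1 = {x.label: x for x in tree1.taxon_namespace}
        tax2 = {x.label: x for x in tree2.taxon_namespace}
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                assert pdm1.patristic_distance(tax1[a], tax1[b]) == pytest.approx(
                    pdm2.patristic_distance(tax2[a], tax2[b]), abs=1e-9
                )

    def test_random_additive_matrices_recovered(self):
        from _oracles import four_point_quartet, random_additive_tree, tree_quartets

        import itertools

        for seed in range(25):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(4, 9))
            _, labels, D = random_additive_tree(rng, n)
            tree = nj_tree(labels, D)
            pdm = tree.phylogenetic_distance_matrix()
            taxa = {t.label: t for t in tree.taxon_namespace}
            for i in range(n):
                for j in range(i + 1, n):
                    assert pdm.patristic_distance(
                        taxa[labels[i]], taxa[labels[j]]
                    ) == pytest.approx(D[i, j], abs=1e-9)
            quartets = tree_quartets(tree, labels)
            for quad in itertools.combinations(range(n), 4):
                assert quartets[quad] == four_point_quartet(D, *quad)

    def test_non_symmetric_matrix_rejected(self):
        D = np.array([[0, 1, 2], [1, 0, 3], [2, 4, 0]], float)
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(["A", "B", "C"], D)


class TestBootstrap:
    def _signal_msa(self, n_cols=500, div=0.3, seed=15):
        rng = np.random.default_rng(seed)
        base = "".join(rng.choice(list(AA), size=n_cols))
        other = list(base)
        idx = rng.choice(n_cols, size=int(div * n_cols), replace=False)
        for i in idx:
            alt = [a for a in AA if a != other[i]]
            other[i] = alt[int(rng.integers(19))]
        other = "".join(other)
        return MSA(
            ["x1", "x2", "y1", "y2"],
            [base, base, other, other],
        )

    def test_strong_signal_high_support(self):
        tree = bootstrap_support(self._signal_msa(), n_replicates=100, seed=1)
        supports = [
            float(n.label)
            for n in tree.postorder_internal_node_iter()
            if n.label is not None
        ]
        assert supports and min(supports) >= 95

    def test_duplicate_sequences_cherry_full_support(self):
        tree = bootstrap_support(self._signal_msa(), n_replicates=50, seed=2)
        supports = [
            float(n.label)
            for n in tree.postorder_internal_node_iter()
            if n.label is not None
        ]
        assert 100.0 in supports

    def test_fixed_seed_reproducible(self):
        m = self._signal_msa(div=0.5, seed=16)
        t1 = bootstrap_support(m, n_replicates=30, seed=9)
        t2 = bootstrap_support(m, n_replicates=30, seed=9)
        from symbiocensus.io_formats import write_newick

        assert write_newick(t1) == write_newick(t2)

    def test_too_few_replicates_error(self):
        with pytest.raises(ValueError):
            bootstrap_support(self._signal_msa(), n_replicates=5, seed=1)


class TestFlagDegraded:
    def _family_msa(self, seed=17, truncate_frac=0.3):
        rng = np.random.default_rng(seed)
        base = "".join(rng.choice(list(AA), size=200))
        near = list(base)
        near[5] = "A" if near[5] != "A" else "C"
        truncated = base[int(truncate_frac * 200) :]
        members = [
            ("X", SequenceRecord("full1", "", base)),
            ("X", SequenceRecord("full2", "", "".join(near))),
            ("Y", SequenceRecord("trunc", "", truncated)),
        ]
        fam = TEFamily("fam", members)
        msa = build_msa([rec for _, rec in members])
        return fam, msa

    def test_truncated_near_identical_copy_removed(self):
        fam, msa = self._family_msa()
        res = flag_degraded(fam, msa)
        assert res.removed == ["trunc"]
        assert not res.testable  # only 2 members left

    def test_divergent_full_length_copy_kept(self):
        rng = np.random.default_rng(18)
        base = "".join(rng.choice(list(AA), size=200))
        divergent = list(base)
        idx = rng.choice(200, size=80, replace=False)
        for i in idx:
            alt = [a for a in AA if a != divergent[i]]
            divergent[i] = alt[int(rng.integers(19))]
        members = [
            ("X", SequenceRecord("a", "", base)),
            ("X", SequenceRecord("b", "", base)),
            ("Y", SequenceRecord("div", "", "".join(divergent))),
        ]
        fam = TEFamily("fam", members)
        msa = build_msa([rec for _, rec in members])
        res = flag_degraded(fam, msa)
        assert res.removed == []
        assert res.testable

    def test_simulator_truncations_recovered(self):
        spec = TEHistorySpec(
            n_recent=0, n_ancient=10, n_vertical=0, degradation_rate=0.25,
            copies_per_genome=4,
        )
        cfg = SimulationConfig(seed=23, te_history=spec)
        res = simulate_te_families(cfg)
        tp = fp = fn = tn = 0
        for fid, members in res.families.items():
            fam = TEFamily(fid, members)
            msa = build_msa([rec for _, rec in members])
            out = flag_degraded(fam, msa)
            removed = set(out.removed)
            for g, rec in members:
                if rec.id in res.degraded:
                    tp += rec.id in removed
                    fn += rec.id not in removed
                else:
                    fp += rec.id in removed
                    tn += rec.id not in removed
        assert tp / (tp + fn) >= 0.9  # recall on truncated copies
        assert fp / (fp + tn) <= 0.05  # false removals


class TestClassifySharing:
    def test_identical_cross_genome_copies_recent(self):
        tree = read_newick("((x1:0.0,y1:0.0):0.1,x2:0.2,x3:0.25);")
        genome_of = {"x1": "X", "x2": "X", "x3": "X", "y1": "Y"}
        (call,) = classify_sharing(tree, genome_of)
        assert call.classification == "recent"
        assert call.min_cross_genome_patristic <= 0.02

    def test_supported_sister_clades_ancient(self):
        tree = read_newick(
            "((x1:0.01,x2:0.01)100:0.3,(y1:0.01,y2:0.01)100:0.3,out:1.0);"
        )
        genome_of = {"x1": "X", "x2": "X", "y1": "Y", "y2": "Y"}
        (call,) = classify_sharing(tree, genome_of)
        assert call.classification == "ancient_sister"
        assert call.monophyletic == (True, True)
        assert call.sister_support == 100.0

    def test_low_support_unresolved(self):
        tree = read_newick(
            "((x1:0.01,x2:0.01)60:0.3,(y1:0.01,y2:0.01)60:0.3,out:1.0);"
        )
        genome_of = {"x1": "X", "x2": "X", "y1": "Y", "y2": "Y"}
        (call,) = classify_sharing(tree, genome_of)
        assert call.classification == "unresolved"

    def test_interleaved_genomes_unresolved(self):
        tree = read_newick("((x1:0.2,y1:0.2):0.2,(x2:0.2,y2:0.2):0.2,x3:0.4);")
        genome_of = {"x1": "X", "x2": "X", "x3": "X", "y1": "Y", "y2": "Y"}
        (call,) = classify_sharing(tree, genome_of)
        assert call.classification == "unresolved"
        assert call.monophyletic[1] is False

    def test_end_to_end_recovery_small(self):
        spec = TEHistorySpec(n_recent=6, n_ancient=6, n_vertical=0, divergence=0.3)
        cfg = SimulationConfig(seed=24, te_history=spec)
        res = simulate_te_families(cfg)
        correct = total = 0
        for fid in sorted(res.families):
            fam = TEFamily(fid, res.families[fid])
            _, tree, calls = trace_family(fam, n_bootstrap=100, seed=3)
            if not calls:
                continue
            expected = "recent" if res.labels[fid] == "recent" else "ancient_sister"
            total += 1
            correct += calls[0].classification == expected
            # a recent family must never be called ancient and vice versa
            if res.labels[fid] == "recent":
                assert calls[0].classification != "ancient_sister"
            else:
                assert calls[0].classification != "recent"
        assert total >= 10
        assert correct / total >= 0.9
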