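"""Distances, Neighbor-Joining, bootstrap support, clade classification."""

import numpy as np
import pytest
from skbio import DistanceMatrix

from mipkit.msa import MultipleAlignment
from mipkit.phylo import (
    bipartitions, bootstrap_support, classify_all, classify_subfamily,
    msa_distance, neighbor_joining, robinson_foulds,
)
from mipkit.synth import SynthConfig, evolve_family, simulate_tree


class TestMsaDistance:
    def test_identical_rows_zero_both_models(self):
        aln = MultipleAlignment(["a", "b"], ["MKVLINAPWE", "MKVLINAPWE"])
        for model in ("p", "poisson"):
            assert msa_distance(aln, model)["a", "b"] == 0.0

    def test_hand_counted_p_distance(self):
        # 10 columns, 2 gap columns -> 8 shared, 2 mismatches -> p = 0.25
        aln = MultipleAlignment(["a", "b"], ["MKVAINAPWE", "MKCAL--PWE"])
        assert msa_distance(aln, "p")["a", "b"] == pytest.approx(0.25)

    def test_poisson_closed_form(self):
        aln = MultipleAlignment(["a", "b"], ["MKVAINAPWE", "MKCAL--PWE"])
        assert msa_distance(aln, "poisson")["a", "b"] == pytest.approx(
            -np.log(0.75), abs=1e-12
        )

    def test_no_shared_columns_rejected(self):
        aln = MultipleAlignment(["a", "b"], ["MK--", "--VL"])
        with pytest.raises(ValueError, match="share no aligned columns"):
            msa_distance(aln, "p")

    def test_saturated_pair_named_under_poisson(self):
        aln = MultipleAlignment(["a", "b"], ["MKVL", "ACDE"])
        with pytest.raises(ValueError, match="'a'.*'b'"):
            msa_distance(aln, "poisson")


def additive_matrix(tree):
    """Leaf-to-leaf path-length distances of a tree (the additive oracle)."""
    return tree.tip_tip_distances()


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(
            np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float), ["A", "B", "C"]
        )
        tree = neighbor_joining(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        # a = (dAB + dAC - dBC)/2 etc.
        assert lengths["A"] == pytest.approx(2.0)
        assert lengths["B"] == pytest.approx(3.0)
        assert lengths["C"] == pytest.approx(7.0)
        total = sum(n.length or 0 for n in tree.traverse(include_self=False))
        assert total == pytest.approx((5 + 9 + 10) / 2)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(np.zeros((2, 2)), ["a", "b"]))

    @pytest.mark.parametrize("n", [4, 6, 8, 10])
    def test_additive_distances_recovered_exactly(self, n):
        src = simulate_tree(n, seed=100 + n, branch_mean=1.0)
        dm = additive_matrix(src)
        tree = neighbor_joining(dm)
        assert robinson_foulds(tree, src) == 0
        back = tree.tip_tip_distances()
        a = dm.filter(sorted(dm.ids)).data
        b = back.filter(sorted(back.ids)).data
        assert np.abs(a - b).max() < 1e-9

    def test_matches_skbio_nj_on_additive_matrix(self):
        from skbio.tree import nj as skbio_nj

        src = simulate_tree(7, seed=5)
        dm = additive_matrix(src)
        assert robinson_foulds(neighbor_joining(dm), skbio_nj(dm)) == 0

    def test_small_noise_keeps_topology(self, rng):
        src = simulate_tree(8, seed=77, branch_mean=1.0)
        dm = additive_matrix(src)
        noisy = dm.data + rng.uniform(-1e-3, 1e-3, dm.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0)
        tree = neighbor_joining(DistanceMatrix(noisy, dm.ids))
        assert robinson_foulds(tree, src) == 0

    def test_deterministic(self):
        src = simulate_tree(9, seed=3)
        dm = additive_matrix(src)
        assert str(neighbor_joining(dm)) == str(neighbor_joining(dm))


def clean_signal_alignment():
    """Members only (no anchor row): each subfamily is a zero-divergence
    pair, so every subfamily cherry is unambiguous."""
    fam = evolve_family(SynthConfig(
        n_subfamilies=3, members_per_subfamily=2, refs_per_subfamily=0,
        per_site_rate=0.0, near_duplicate_count=0, rng_seed=21,
    ))
    ids = [r.id for r in fam.records]
    return MultipleAlignment(ids, [fam.alignment.row(i) for i in ids])


class TestBootstrap:
    def test_same_seed_identical_supports(self):
        aln = clean_signal_alignment()
        t1 = bootstrap_support(aln, n_reps=25, seed=9)
        t2 = bootstrap_support(aln, n_reps=25, seed=9)
        s1 = sorted(n.name for n in t1.non_tips(include_self=False) if n.name)
        s2 = sorted(n.name for n in t2.non_tips(include_self=False) if n.name)
        assert s1 == s2

    def test_clean_clades_get_full_support(self):
        aln = clean_signal_alignment()
        tree = bootstrap_support(aln, n_reps=100, seed=4)
        cherries = {
            frozenset(t.name for t in n.tips())
            for n in tree.non_tips(include_self=False)
            if sum(1 for _ in n.tips()) == 2
        }
        assert frozenset({"PIP_01", "PIP_02"}) in cherries
        for n in tree.non_tips(include_self=False):
            names = {t.name for t in n.tips()}
            if len(names) == 2 and len({x.split("_")[0] for x in names}) == 1:
                assert n.support >= 99.0

    def test_shuffled_columns_reduce_mean_support(self, rng):
        aln = clean_signal_alignment()
        clean = bootstrap_support(aln, n_reps=50, seed=2)
        # destroy the signal: shuffle residues within every column
        arr = np.array([list(r) for r in aln.rows])
        for c in range(arr.shape[1]):
            rng.shuffle(arr[:, c])
        shuffled = MultipleAlignment(aln.ids, ["".join(r) for r in arr])
        noise = bootstrap_support(shuffled, n_reps=50, seed=2)
        mean = lambda t: np.mean([
            n.support for n in t.non_tips(include_self=False)
            if getattr(n, "support", None) is not None
        ])
        assert mean(noise) < mean(clean)

    def test_zero_reps_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_support(clean_signal_alignment(), n_reps=0)


@pytest.fixture(scope="module")
def fam_tree(small_family):
    from mipkit.msa import progressive_align

    aln = progressive_align(small_family.all_records)
    tree = neighbor_joining(msa_distance(aln, "poisson"))
    refs = {r.id: r.subfamily_label for r in small_family.references}
    subgroups = {r.id: r.subgroup_label for r in small_family.references}
    return small_family, tree, refs, subgroups


class TestClassification:
    def test_all_planted_labels_recovered(self, fam_tree):
        fam, tree, refs, subgroups = fam_tree
        truth = dict(zip(fam.truth.sequences.id, fam.truth.sequences.subfamily))
        calls = classify_all(tree, refs, [r.id for r in fam.records], subgroups)
        assert all(c.subfamily == truth[c.id] for c in calls)
        assert all(c.subgroup == f"{c.subfamily}1" for c in calls)

    def test_invariant_to_leaf_order(self, fam_tree):
        fam, tree, refs, subgroups = fam_tree
        # rebuild from a permuted alignment: classification must not change
        from mipkit.msa import progressive_align
        from mipkit.phylo import msa_distance, neighbor_joining

        recs = list(reversed(fam.all_records))
        tree2 = neighbor_joining(msa_distance(progressive_align(recs), "poisson"))
        c1 = classify_all(tree, refs, [r.id for r in fam.records])
        c2 = classify_all(tree2, refs, [r.id for r in fam.records])
        assert [(c.id, c.subfamily) for c in c1] == [(c.id, c.subfamily) for c in c2]

    def test_no_references_rejected(self, fam_tree):
        _, tree, _, _ = fam_tree
        with pytest.raises(ValueError, match="reference"):
            classify_subfamily(tree, {"not_in_tree": "PIP"}, "PIP_01")

    def test_query_with_identical_reference_is_clade_evidence(self, fam_tree):
        fam, tree, refs, _ = fam_tree
        call = classify_subfamily(tree, refs, fam.records[0].id)
        assert call.evidence in ("clade", "nearest-neighbor")
        assert call.subfamily == fam.records[0].id.split("_")[0]
        assert call.evidence == "clade"
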