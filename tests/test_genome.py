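import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcjmoments import (
    AugmentedGenome,
    ModelParams,
    apply_dcj,
    augment,
    build_genome,
    count_breakpoints,
    enumerate_dcj_moves,
    random_genome,
)
from dcjmoments.genome import GenomeFormatError, head, tail


class TestBuildGenome:
    def test_linear_three_genes(self):
        G = build_genome([[1, 2, 3]])
        assert G.adjacencies == {
            (head(1), tail(2)),
            (head(2), tail(3)),
        } == {(2, 3), (4, 5)}
        assert G.telomere_extremities == {tail(1), head(3)}

    def test_single_circular_gene_closes_on_itself(self):
        G = build_genome([[1]], circular=True)
        assert G.adjacencies == {(tail(1), head(1))}
        assert not G.telomere_extremities

    def test_two_singleton_linear_chromosomes_all_telomeres(self):
        G = build_genome([[1], [2]])
        assert G.adjacencies == frozenset()
        assert len(G.telomere_extremities) == 4

    def test_negative_sign_flips_extremities(self):
        # 1 -2: right end of 1 (head) meets right end of 2 (head)
        G = build_genome([[1, -2]])
        assert G.adjacencies == {(head(1), head(2))}

    @pytest.mark.parametrize("chroms", [[[1, 2, 1]], [[1], [1]], [[1, 3]], [[0]]])
    def test_bad_gene_ids_rejected(self, chroms):
        with pytest.raises(GenomeFormatError):
            build_genome(chroms)


class TestAugment:
    def test_three_gene_augmentation_counts(self, three_gene_pair):
        red, _ = three_gene_pair
        A = augment(red, f=0)
        assert len(A.telomeric) == 2
        assert A.n == 4 == A.params.n
        assert A.a == 2
        A.validate()

    def test_no_telomeres_with_fictional(self):
        G = build_genome([[1, 2]], circular=True)
        A = augment(G, f=4)
        assert A.n == G.g + 2
        assert sum(1 for p in A.adjacencies if A.adjacency_kind(p) == "fictional") == 2

    def test_f2_single_fictional_adjacency(self, three_gene_pair):
        A = augment(three_gene_pair[0], f=2)
        kinds = [A.adjacency_kind(p) for p in A.adjacencies]
        assert kinds.count("fictional") == 1

    def test_odd_f_rejected(self, three_gene_pair):
        with pytest.raises(ValueError):
            augment(three_gene_pair[0], f=3)

    def test_vertex_count_identity(self):
        # 4g - 2a + f vertices in the augmented genome
        G = augment(build_genome([[1, 2], [3]]), f=2)
        n_vertices = len({v for p in G.adjacencies for v in p})
        assert n_vertices == 4 * G.g - 2 * G.a + G.f
        assert 2 * G.n == n_vertices


class TestApplyDcj:
    def test_rewiring_choices(self, three_gene_pair_augmented):
        red, _ = three_gene_pair_augmented
        a1, a2 = sorted(red.adjacencies)[:2]
        (A, B), (C, D) = a1, a2
        out0 = apply_dcj(red, a1, a2, 0)
        assert tuple(sorted((A, C))) in out0.adjacencies
        assert tuple(sorted((B, D))) in out0.adjacencies
        assert a1 not in out0.adjacencies and a2 not in out0.adjacencies
        out1 = apply_dcj(red, a1, a2, 1)
        assert tuple(sorted((A, D))) in out1.adjacencies

    def test_involution(self, three_gene_pair_augmented):
        # the move is reversible: cutting the two new adjacencies with one
        # of the two rewirings restores the original genome
        red, _ = three_gene_pair_augmented
        a1, a2 = sorted(red.adjacencies)[:2]
        once = apply_dcj(red, a1, a2, 0)
        new1, new2 = sorted(once.adjacencies - red.adjacencies)
        restored = {
            apply_dcj(once, new1, new2, c).adjacencies for c in (0, 1)
        }
        assert red.adjacencies in restored

    def test_identical_adjacencies_rejected(self, three_gene_pair_augmented):
        red, _ = three_gene_pair_augmented
        a1 = next(iter(red.adjacencies))
        with pytest.raises(ValueError):
            apply_dcj(red, a1, a1, 0)

    def test_two_dcjs_transform_red_into_blue(self, three_gene_pair_augmented):
        # under the cycle-maximizing telomere correspondence the red
        # genome reaches the blue one in two DCJs, one per cycle
        red, blue = three_gene_pair_augmented
        relabel = {7: 8, 8: 7}
        target = frozenset(
            tuple(sorted((relabel.get(u, u), relabel.get(v, v))))
            for u, v in blue.adjacencies
        )
        step1 = apply_dcj(red, (2, 3), (6, 8), 1)  # {2,3},{6,8} -> {2,6},{3,8}
        step2 = apply_dcj(step1, (4, 5), (1, 7), 0)  # {4,5},{1,7} -> {1,4},{5,7}
        assert step2.adjacencies == target

    def test_every_move_preserves_perfect_matching(self, three_gene_pair_augmented):
        red, _ = three_gene_pair_augmented
        for a1, a2, choice in enumerate_dcj_moves(red):
            out = apply_dcj(red, a1, a2, choice)
            out.validate()
            assert out.adjacencies != red.adjacencies


class TestEnumerateMoves:
    @pytest.mark.parametrize(
        "builder,expected",
        [
            (lambda: augment(build_genome([[1]], circular=True), f=2), 2),
            (lambda: augment(build_genome([[1, 2, 3]])), 12),
            (lambda: random_genome(10, 0, f=0, seed=0), 90),
        ],
    )
    def test_n_times_n_minus_1_moves(self, builder, expected):
        G = builder()
        assert len(enumerate_dcj_moves(G)) == G.n * (G.n - 1) == expected


class TestCountBreakpoints:
    def test_three_gene_pair_has_two(self, three_gene_pair):
        red, blue = three_gene_pair
        assert count_breakpoints(red, blue) == 2
        assert count_breakpoints(blue, red) == 2

    def test_self_comparison_zero(self, three_gene_pair):
        red, _ = three_gene_pair
        assert count_breakpoints(red, red) == 0

    def test_matches_brute_force_set_difference(self):
        G1 = build_genome([[1, 2, 3]])
        G2 = build_genome([[2, 1, 3]])
        expected = len(G1.observed_adjacencies - G2.observed_adjacencies)
        assert count_breakpoints(G1, G2) == expected == 2

    def test_bounded_by_a(self, three_gene_pair):
        red, blue = three_gene_pair
        assert 0 <= count_breakpoints(red, blue) <= red.a

    def test_mismatched_gene_sets_rejected(self):
        with pytest.raises(ValueError):
            count_breakpoints(build_genome([[1]]), build_genome([[1, 2]]))


class TestRandomGenome:
    def test_requested_counts(self):
        G = random_genome(980, 40, f=10, seed=1)
        assert G.a == 960
        assert len(G.telomeric) == 40
        assert G.f == 10
        G.validate()

    def test_all_telomeres(self):
        G = random_genome(3, 6, f=0, seed=2)
        assert G.a == 0

    def test_seed_determinism(self):
        assert (
            random_genome(50, 10, f=4, seed=7).adjacencies
            == random_genome(50, 10, f=4, seed=7).adjacencies
        )

    def test_infeasible_counts_rejected(self):
        with pytest.raises(ValueError):
            random_genome(5, 3, seed=0)  # odd telomere count
        with pytest.raises(ValueError):
            random_genome(5, 12, seed=0)  # more telomeres than extremities


class TestModelParams:
    def test_n_identity(self):
        p = ModelParams(g=1000, a=980, f=0)
        assert p.n == 1020
        assert p.telomeres == 40

    def test_from_an(self):
        p = ModelParams.from_an(980, 1020)
        assert (p.a, p.n) == (980, 1020)

    def test_invalid(self):
        with pytest.raises(ValueError):
            ModelParams(g=3, a=2, f=1)
        with pytest.raises(ValueError):
            ModelParams(g=3, a=4, f=0)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    g=st.integers(2, 15),
    data=st.data(),
)
def test_random_dcj_walk_preserves_matching_and_vertex_kinds(g, data):
    """Perfect matching and telomeric+fictional vertex count are invariant
    under arbitrary DCJ sequences."""
    telo = data.draw(st.integers(0, g)) * 2
    f = data.draw(st.integers(0, 3)) * 2
    seed = data.draw(st.integers(0, 2**16))
    G = random_genome(g, telo, f=f, seed=seed)
    non_observed = len(G.telomeric) + len(G.fictional)
    rng = np.random.default_rng(seed)
    for _ in range(5):
        adjs = sorted(G.adjacencies)
        if len(adjs) < 2:
            break
        i, j = rng.choice(len(adjs), size=2, replace=False)
        G = apply_dcj(G, adjs[i], adjs[j], int(rng.integers(0, 2)))
        G.validate()
        assert len(G.telomeric) + len(G.fictional) == non_observed
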