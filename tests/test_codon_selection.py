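import numpy as np
import pytest
import dendropy

from divsel.codon_selection import (
    CODON_INDEX,
    CODONS,
    N_STATES,
    BranchSitePruner,
    CodonModelParams,
    FitOptions,
    beb_site_posteriors,
    build_codon_rate_matrix,
    f3x4_frequencies,
    fit_null_and_alt,
    label_foreground,
    lrt,
    multi_tree_robustness,
    prune_outgroup,
    transition_probs,
)
from conftest import enumeration_site_likelihood, random_labeled_tree

UNIFORM = np.full(N_STATES, 1.0 / N_STATES)


def codon_seqs_from_states(ltree, states_by_tip):
    return {
        name: "".join(CODONS[s] if s >= 0 else "---" for s in states)
        for name, states in zip(ltree.tip_names, states_by_tip)
    }


class TestRateMatrix:
    @pytest.mark.parametrize("kappa,omega", [(2.0, 0.5), (0.7, 3.0), (11.0, 1.0)])
    def test_rows_sum_to_zero_and_detailed_balance(self, kappa, omega, rng):
        pi = rng.dirichlet(np.ones(N_STATES))
        q = build_codon_rate_matrix(kappa, omega, pi)
        assert np.allclose(q.sum(axis=1), 0.0, atol=1e-12)
        flux = pi[:, None] * q
        assert np.allclose(flux, flux.T, atol=1e-12)

    def test_rate_term_ratio(self):
        # AAA->AAG synonymous transition vs AAA->AAC nonsynonymous transversion
        q = build_codon_rate_matrix(2.0, 0.5, UNIFORM)
        i, j, k = CODON_INDEX["AAA"], CODON_INDEX["AAG"], CODON_INDEX["AAC"]
        assert q[i, j] / q[i, k] == pytest.approx(2.0 / 0.5)

    def test_neutral_normalization_preserves_relative_rates(self):
        pi = UNIFORM
        q_slow = build_codon_rate_matrix(2.0, 0.1, pi)
        q_fast = build_codon_rate_matrix(2.0, 4.0, pi)
        rate = lambda q: -float(pi @ np.diag(q))
        assert rate(q_fast) > rate(q_slow)
        assert rate(build_codon_rate_matrix(2.0, 1.0, pi)) == pytest.approx(1.0)

    def test_bad_frequencies_error(self):
        with pytest.raises(ValueError):
            build_codon_rate_matrix(2.0, 1.0, UNIFORM * 1.01)


class TestTransitionProbs:
    def test_t_zero_is_identity(self):
        q = build_codon_rate_matrix(2.0, 0.5, UNIFORM)
        assert np.allclose(transition_probs(q, 0.0), np.eye(N_STATES), atol=1e-12)

    def test_semigroup(self):
        q = build_codon_rate_matrix(2.0, 0.5, UNIFORM)
        p_s, p_t, p_st = (transition_probs(q, t) for t in (0.3, 0.5, 0.8))
        assert np.allclose(p_s @ p_t, p_st, atol=1e-8)
        assert np.allclose(p_st.sum(axis=1), 1.0, atol=1e-10)

    def test_small_t_taylor(self):
        q = build_codon_rate_matrix(2.0, 0.5, UNIFORM)
        t = 1e-4
        p = transition_probs(q, t)
        assert np.abs(p - (np.eye(N_STATES) + q * t)).max() < 10 * t**2

    def test_negative_t_errors(self):
        q = build_codon_rate_matrix(2.0, 0.5, UNIFORM)
        with pytest.raises(ValueError):
            transition_probs(q, -0.1)


class TestLabelForeground:
    def make_tree(self, newick, pops):
        tree = dendropy.Tree.get(data=newick, schema="newick")
        meta = {name: (name, pop) for name, pop in pops.items()}
        return tree, meta

    def fg_map(self, ltree):
        out = {}
        for kids in ltree.children:
            for idx, _t, fg in kids:
                key = (
                    ltree.tip_names[idx]
                    if idx < ltree.n_tips
                    else f"internal_{idx}"
                )
                out[key] = fg
        return out

    def test_four_tip_rule(self):
        tree, meta = self.make_tree(
            "((a,b),(c,d));", {"a": "A", "b": "A", "c": "B", "d": "B"}
        )
        lt = label_foreground(tree, meta, "A")
        fg = self.fg_map(lt)
        assert fg["a"] and fg["b"]
        internals = [k for k in fg if k.startswith("internal")]
        # the (a,b) clade branch is foreground; the (c,d) branch is not
        assert sum(fg[k] for k in internals) == 1

    def test_all_focal_all_foreground(self):
        tree, meta = self.make_tree(
            "((a,b),(c,d));", {k: "A" for k in "abcd"}
        )
        lt = label_foreground(tree, meta, "A")
        assert all(fg for _, _, fg in lt.branch_list())
        assert lt.n_branches == 6  # root stem carries no branch

    def test_mixed_cherry(self):
        tree, meta = self.make_tree("((a,c),(b,d));", {"a": "A", "c": "B", "b": "B", "d": "B"})
        lt = label_foreground(tree, meta, "A")
        fg = self.fg_map(lt)
        assert fg["a"]
        assert sum(fg.values()) == 1

    def test_missing_metadata_errors(self):
        tree, meta = self.make_tree("((a,b),(c,d));", {"a": "A", "b": "A", "c": "B"})
        with pytest.raises(ValueError, match="d"):
            label_foreground(tree, meta, "A")

    def test_prune_outgroup(self):
        tree, meta = self.make_tree(
            "(((a,b),(c,d)),og);", {k: "A" for k in "abcd"} | {"og": "out"}
        )
        pruned = prune_outgroup(tree, "og")
        labels = {l.taxon.label for l in pruned.leaf_node_iter()}
        assert labels == {"a", "b", "c", "d"}
        with pytest.raises(ValueError):
            prune_outgroup(tree, "nope")


class TestSiteLikelihood:
    def test_matches_enumeration_small(self, rng):
        # quick check; the exhaustive version lives in the acceptance suite
        for n_tips in (3, 4):
            lt = random_labeled_tree(rng, n_tips)
            params = CodonModelParams(
                kappa=2.3, codon_freqs=UNIFORM, p0=0.6, p1=0.25, omega0=0.2, omega2=3.0
            )
            states = rng.integers(-1, N_STATES, size=(n_tips, 8))
            seqs = codon_seqs_from_states(lt, states)
            pruner = BranchSitePruner(seqs, lt, UNIFORM)
            got = pruner.site_log_likelihoods(params)
            w = params.class_weights()
            for s in range(8):
                mix = 0.0
                for c, (w_bg, w_fg) in enumerate(
                    [(0.2, 0.2), (1.0, 1.0), (0.2, 3.0), (1.0, 3.0)]
                ):
                    ps = [
                        transition_probs(
                            build_codon_rate_matrix(
                                2.3, w_fg if fg else w_bg, UNIFORM
                            ),
                            t,
                        )
                        for _i, t, fg in lt.branch_list()
                    ]
                    mix += w[c] * enumeration_site_likelihood(
                        lt, states[:, s], ps, UNIFORM
                    )
                assert got[s] == pytest.approx(np.log(mix), rel=1e-8)

    def test_all_missing_site_contributes_zero(self, rng):
        lt = random_labeled_tree(rng, 4)
        states = np.array([[5], [12], [30], [44]])
        states_missing = np.full((4, 1), -1)
        params = CodonModelParams(
            kappa=2.0, codon_freqs=UNIFORM, p0=0.7, p1=0.2, omega0=0.1, omega2=2.0
        )
        seqs = codon_seqs_from_states(lt, states_missing)
        pruner = BranchSitePruner(seqs, lt, UNIFORM)
        assert pruner.site_log_likelihoods(params)[0] == pytest.approx(0.0, abs=1e-12)

    def test_alt_with_omega2_one_equals_null(self, rng):
        lt = random_labeled_tree(rng, 5)
        states = rng.integers(0, N_STATES, size=(5, 20))
        seqs = codon_seqs_from_states(lt, states)
        pruner = BranchSitePruner(seqs, lt, UNIFORM)
        null = CodonModelParams(2.0, UNIFORM, 0.6, 0.3, 0.2, 1.0)
        alt = CodonModelParams(2.0, UNIFORM, 0.6, 0.3, 0.2, 1.0 + 1e-12)
        assert pruner.log_likelihood(null) == pytest.approx(
            pruner.log_likelihood(alt), abs=1e-6
        )

    def test_stop_codon_rejected_with_site_index(self, rng):
        lt = random_labeled_tree(rng, 3)
        seqs = {name: "AAATGAAAA" for name in lt.tip_names}
        with pytest.raises(ValueError, match="site 2"):
            BranchSitePruner(seqs, lt, UNIFORM)

    def test_column_order_invariance(self, rng):
        lt = random_labeled_tree(rng, 5)
        states = rng.integers(0, N_STATES, size=(5, 30))
        params = CodonModelParams(2.0, UNIFORM, 0.6, 0.3, 0.2, 2.5)
        seqs = codon_seqs_from_states(lt, states)
        perm = rng.permutation(30)
        seqs_perm = codon_seqs_from_states(lt, states[:, perm])
        l1 = BranchSitePruner(seqs, lt, UNIFORM).log_likelihood(params)
        l2 = BranchSitePruner(seqs_perm, lt, UNIFORM).log_likelihood(params)
        assert l1 == pytest.approx(l2, rel=1e-12)

    def test_root_placement_invariance(self, rng):
        # reversible model: rerooting must not move the likelihood
        # (no foreground branches, so branch classes are rooting-invariant)
        newick = "((a:0.1,b:0.2):0.15,(c:0.3,(d:0.1,e:0.25):0.2):0.05);"
        tree = dendropy.Tree.get(data=newick, schema="newick")
        meta = {n: (n, "pop") for n in "abcde"}
        states = rng.integers(0, N_STATES, size=(5, 25))
        params = CodonModelParams(2.0, UNIFORM, 0.6, 0.3, 0.2, 2.0)

        def lnl(t):
            lt = label_foreground(t, meta, "not_present")
            seqs = {
                name: "".join(
                    CODONS[s] for s in states["abcde".index(name)]
                )
                for name in lt.tip_names
            }
            return BranchSitePruner(seqs, lt, UNIFORM).log_likelihood(params)

        base = lnl(tree)
        for leaf in ("c", "e"):
            t2 = dendropy.Tree.get(data=newick, schema="newick")
            node = t2.find_node_with_taxon_label(leaf)
            t2.reroot_at_edge(node.edge, length1=node.edge.length / 2,
                              length2=node.edge.length / 2)
            assert lnl(t2) == pytest.approx(base, abs=1e-6)


class TestFitAndLrt:
    def small_dataset(self, rng, omega2=4.0, n_tips=6, n_codons=80):
        from divsel.synthetic_data import SimConfig, simulate_codon_alignment

        lt = random_labeled_tree(rng, n_tips, fg_prob=0.5, t_range=(0.1, 0.6))
        cfg = SimConfig(
            seed=1, n_codons=n_codons, omega2=omega2, p0=0.6, p1=0.2, intron_length=0
        )
        seqs, _ = simulate_codon_alignment(lt, cfg, rng)
        return seqs, lt

    def test_alt_never_below_null_and_lrt_examples(self, rng):
        seqs, lt = self.small_dataset(rng)
        opts = FitOptions(optimize_scale=False, maxiter=25, confirm_restart=False)
        fit_null, fit_alt = fit_null_and_alt(seqs, lt, opts)
        assert fit_alt.lnL >= fit_null.lnL - 1e-6
        res = lrt(fit_alt, fit_null)
        assert res.df == 1
        assert 0 < res.p_value <= 1

    def test_lrt_reference_values(self):
        from divsel.codon_selection import BranchSiteFit

        params = CodonModelParams(2.0, UNIFORM, 0.6, 0.3, 0.2, 2.0)
        mk = lambda l, m: BranchSiteFit(params, l, 1, True, None, m)
        equal = lrt(mk(-100.0, "alt"), mk(-100.0, "null"))
        assert equal.two_delta_lnl == 0.0
        assert equal.p_value == 1.0
        res = lrt(mk(-100.0, "alt"), mk(-100.0 - 3.841 / 2, "null"))
        assert res.p_value == pytest.approx(0.0500, abs=5e-4)
        with pytest.raises(ValueError):
            lrt(mk(-105.0, "alt"), mk(-100.0, "null"))

    def test_beb_refuses_unconverged(self, rng):
        seqs, lt = self.small_dataset(rng)
        from divsel.codon_selection import BranchSiteFit

        fake = BranchSiteFit(
            CodonModelParams(2.0, UNIFORM, 0.6, 0.3, 0.2, 2.0),
            -1.0, 1, False, None, "alt",
        )
        with pytest.raises(ValueError, match="unconverged"):
            beb_site_posteriors(seqs, lt, fake)

    def test_beb_invariant_alignment_flags_nothing(self, rng):
        lt = random_labeled_tree(rng, 5)
        states = np.tile(rng.integers(0, N_STATES, size=(1, 40)), (5, 1))
        seqs = codon_seqs_from_states(lt, states)
        opts = FitOptions(optimize_scale=False, maxiter=15, confirm_restart=False)
        _fn, fa = fit_null_and_alt(seqs, lt, opts)
        post = beb_site_posteriors(seqs, lt, fa, allow_unconverged=True)
        assert (post <= 0.95).all()


class TestMultiTree:
    def test_duplicated_trees_identical_rows(self, rng):
        from divsel.synthetic_data import SimConfig, simulate_codon_alignment

        lt = random_labeled_tree(rng, 6, fg_prob=0.5)
        cfg = SimConfig(seed=2, n_codons=60, omega2=3.0, intron_length=0)
        seqs, _ = simulate_codon_alignment(lt, cfg, rng)
        newick = "((t0:0.2,t1:0.3):0.1,((t2:0.2,t3:0.1):0.2,(t4:0.3,t5:0.2):0.1):0.1);"
        tree = dendropy.Tree.get(data=newick, schema="newick")
        meta = {f"t{i}": (f"t{i}", "A" if i < 3 else "B") for i in range(6)}
        opts = FitOptions(optimize_scale=False, maxiter=20, confirm_restart=False)
        table, summary = multi_tree_robustness(
            seqs, [tree, tree.clone(depth=1)], meta, "A", opts
        )
        assert len(table) == 2
        assert table.iloc[0]["lnL_alt"] == pytest.approx(table.iloc[1]["lnL_alt"])
        assert table.iloc[0]["flagged_sites"] == table.iloc[1]["flagged_sites"]
        assert set(summary) == {"fraction_significant", "site_flag_frequency"}

    def test_tip_mismatch_named(self, rng):
        tree = dendropy.Tree.get(data="((t0,t1),(t2,tX));", schema="newick")
        meta = {n: (n, "A") for n in ["t0", "t1", "t2", "tX"]}
        seqs = {f"t{i}": "AAA" for i in range(4)}
        with pytest.raises(ValueError, match="t3|tX"):
            multi_tree_robustness(seqs, [tree, tree], meta, "A")


def test_f3x4_frequencies_sum_and_bias(rng):
    seqs = ["".join(rng.choice(list("ACGT"), 300, p=[0.4, 0.3, 0.2, 0.1]))
            for _ in range(5)]
    pi = f3x4_frequencies(seqs)
    assert pi.sum() == pytest.approx(1.0)
    assert pi.min() > 0
    # A-rich input should favour A-rich codons
    assert pi[CODON_INDEX["AAA"]] > pi[CODON_INDEX["TTT"]]


def test_paml_foreground_export_marks():
    from divsel.codon_selection import paml_foreground_newick

    tree = dendropy.Tree.get(data="((a:0.1,b:0.2):0.1,(c:0.1,d:0.3):0.2);",
                             schema="newick")
    meta = {n: (n, "A" if n in "ab" else "B") for n in "abcd"}
    lt = label_foreground(tree, meta, "A")
    s = paml_foreground_newick(lt)
    assert s.count("#1") == 3  # a, b, and the (a,b) clade branch
    assert "a #1" in s and "b #1" in s
    assert "c" in s and "c #1" not in s
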