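import networkx as nx
import numpy as np
import pandas as pd
import pytest

from deepdom.network import (build_network, clr_transform, fdr_cutoff,
                             greedy_modularity, interdomain_network,
                             node_roles, prevalence_filter,
                             proportionality_rho, replace_zeros, stack_blocks)
from deepdom.synthetic import generate_asv_table, make_planted_modules


def frame(rows, index=None, cols=None):
    arr = np.asarray(rows, float)
    cols = cols or [f"s{i}" for i in range(arr.shape[1])]
    index = index or [f"f{i}" for i in range(arr.shape[0])]
    return pd.DataFrame(arr, index=index, columns=cols)


class TestPrevalence:
    def test_mf_below_min_samples_removed(self):
        mf = frame([[1] * 4 + [0] * 6, [1] * 5 + [0] * 5])
        asv = frame([[0.01] * 10], index=["a0"])
        mf2, asv2 = prevalence_filter(mf, asv, min_samples=5)
        assert list(mf2.index) == ["f1"]

    def test_low_abundance_asv_removed(self):
        mf = frame([[1] * 6])
        asv = frame([[0.0009] * 6, [0.0011] * 6], index=["lo", "hi"])
        _, asv2 = prevalence_filter(mf, asv, min_samples=5, min_abundance=0.001)
        assert list(asv2.index) == ["hi"]

    def test_zero_thresholds_identity(self):
        mf = frame([[1, 0, 0], [0, 1, 0]])
        asv = frame([[0.1, 0, 0]], index=["a"])
        mf2, asv2 = prevalence_filter(mf, asv, min_samples=0, min_abundance=0)
        pd.testing.assert_frame_equal(mf, mf2)

    def test_sample_mismatch_fails(self):
        mf = frame([[1, 1]])
        asv = frame([[1, 1, 1]], index=["a"])
        with pytest.raises(ValueError, match="sample set"):
            prevalence_filter(mf, asv)


class TestZeroReplacement:
    def test_min_over_ten(self):
        out = replace_zeros(frame([[0.0, 0.02, 0.04]]))
        np.testing.assert_allclose(out.iloc[0], [0.002, 0.02, 0.04])

    def test_no_zero_identity(self):
        df = frame([[0.1, 0.2], [0.3, 0.4]])
        pd.testing.assert_frame_equal(replace_zeros(df), df)

    def test_all_zero_feature_fails(self):
        with pytest.raises(ValueError, match="f1"):
            replace_zeros(frame([[1, 1], [0, 0]]))


class TestClr:
    def test_constant_column_is_zero(self):
        out = clr_transform(frame([[1.0], [1.0], [1.0], [1.0]]))
        np.testing.assert_allclose(out.values.to_numpy(), 0.0)

    def test_two_part_column(self):
        out = clr_transform(frame([[1.0], [10.0]]))
        np.testing.assert_allclose(out.values.iloc[:, 0],
                                   [-np.log(10) / 2, np.log(10) / 2])

    def test_column_sums_zero(self):
        rng = np.random.default_rng(0)
        out = clr_transform(frame(rng.uniform(0.1, 5, (12, 6))))
        np.testing.assert_allclose(out.values.sum(axis=0), 0.0, atol=1e-9)

    def test_nonpositive_fails(self):
        with pytest.raises(ValueError):
            clr_transform(frame([[1.0, 0.0]]))

    def test_separate_vs_joint_transform_differ(self):
        """Transforming the two blocks separately (the stated order of
        operations) gives different rho than one joint clr."""
        rng = np.random.default_rng(1)
        a = frame(rng.lognormal(0, 1, (6, 8)), index=[f"m{i}" for i in range(6)])
        b = frame(rng.lognormal(0, 1, (5, 8)), index=[f"a{i}" for i in range(5)])
        sep = stack_blocks(clr_transform(a, "MF"), clr_transform(b, "ASV"))
        joint = clr_transform(pd.concat([a, b]), "joint")
        rho_sep = proportionality_rho(sep)
        rho_joint = proportionality_rho(joint)
        assert not np.allclose(rho_sep.to_numpy(), rho_joint.to_numpy())


class TestRho:
    def test_identical_rows_one(self):
        g = clr_transform(frame([[1, 2, 4, 8], [2, 4, 8, 16], [5, 1, 7, 2]]))
        rho = proportionality_rho(g)
        # rows 0 and 1 are proportional -> identical clr -> rho 1
        assert rho.iloc[0, 1] == pytest.approx(1.0)

    def test_antiproportional_minus_one(self):
        vals = np.array([[1.0, 2.0, 3.0, 1.5], [-1.0, -2.0, -3.0, -1.5]])
        from deepdom.network import ClrMatrix
        cm = ClrMatrix(values=frame(vals), blocks=pd.Series(["x", "x"],
                       index=["f0", "f1"]))
        rho = proportionality_rho(cm)
        assert rho.iloc[0, 1] == pytest.approx(-1.0)

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(2)
        g = clr_transform(frame(rng.lognormal(0, 1, (10, 7))))
        rho = proportionality_rho(g).to_numpy()
        np.testing.assert_allclose(rho, rho.T)
        np.testing.assert_allclose(np.diag(rho), 1.0)

    def test_sample_reordering_invariance(self):
        rng = np.random.default_rng(3)
        df = frame(rng.lognormal(0, 1, (8, 6)))
        r1 = proportionality_rho(clr_transform(df))
        perm = rng.permutation(df.shape[1])
        r2 = proportionality_rho(clr_transform(df.iloc[:, perm]))
        np.testing.assert_allclose(r1.to_numpy(), r2.to_numpy())

    def test_independent_rows_small_rho(self):
        # with many samples, rho of independent features shrinks toward the
        # small negative clr-closure bias (~ -1/n_features)
        rng = np.random.default_rng(4)
        df = frame(rng.lognormal(0, 1, (30, 3000)))
        rho = proportionality_rho(clr_transform(df)).to_numpy()
        off = rho[np.triu_indices(30, 1)]
        assert np.abs(off).max() < 0.15
        assert abs(off.mean() + 1 / 30) < 0.02

    def test_zero_variance_flagged(self):
        from deepdom.network import ClrMatrix
        vals = frame([[0.0, 0.0, 0.0], [1.0, 2.0, -3.0]])
        cm = ClrMatrix(values=vals, blocks=pd.Series(["x", "x"], index=vals.index))
        with pytest.warns(UserWarning, match="zero-variance"):
            rho = proportionality_rho(cm)
        assert rho.iloc[0, 1] == 0.0


class TestFdrCutoff:
    def _blocks(self, seed, n_mf=30, n_asv=15, n_samples=10):
        rng = np.random.default_rng(seed)
        mf = frame(rng.lognormal(0, 1, (n_mf, n_samples)),
                   index=[f"m{i}" for i in range(n_mf)])
        asv = frame(rng.lognormal(0, 1, (n_asv, n_samples)),
                    index=[f"a{i}" for i in range(n_asv)])
        return stack_blocks(clr_transform(mf, "MF"), clr_transform(asv, "ASV"))

    def test_null_data_high_fdr_at_low_cutoffs(self):
        combined = self._blocks(0)
        res = fdr_cutoff(combined, n_perm=30, seed=1)
        low = res.table[res.table["cutoff"] <= 0.4]
        assert (low["fdr"] > 0.5).all()

    def test_planted_signal_admits_links(self):
        planted = make_planted_modules(n_modules=4, latent_strength=2.0)
        asv, truth = generate_asv_table(15, 10, planted, seed=5, noise_sd=0.0)
        mf = truth["mf_intensities"]
        asv_num = asv.drop(columns="taxonomy").loc[
            [a for m in planted for a in m.asv_members]]
        combined = stack_blocks(clr_transform(mf, "MF"),
                                clr_transform(asv_num, "ASV"))
        res = fdr_cutoff(combined, n_perm=30, seed=2)
        rho = proportionality_rho(combined)
        cross = rho.loc[mf.index, asv_num.index]
        admitted = {(i, j) for i in cross.index for j in cross.columns
                    if abs(cross.loc[i, j]) >= res.cutoff}
        planted_links = set(truth["links"])
        assert len(admitted & planted_links) / len(planted_links) >= 0.9

    def test_requires_two_blocks(self):
        rng = np.random.default_rng(7)
        one = clr_transform(frame(rng.lognormal(0, 1, (5, 6))), "MF")
        with pytest.raises(ValueError, match="two blocks"):
            fdr_cutoff(one, n_perm=10)


class TestGraphAndModules:
    def test_cutoff_builds_expected_edges(self):
        rho = pd.DataFrame([[1.0, 0.9, 0.1], [0.9, 1.0, -0.2], [0.1, -0.2, 1.0]],
                           index=list("abc"), columns=list("abc"))
        g = build_network(rho, cutoff=0.85)
        assert g.number_of_nodes() == 2 and g.number_of_edges() == 1
        assert g.edges["a", "b"]["sign"] == 1

    def test_all_below_cutoff_empty(self):
        rho = pd.DataFrame(np.eye(3) * 1.0, index=list("abc"), columns=list("abc"))
        rho.iloc[0, 1] = rho.iloc[1, 0] = 0.5
        with pytest.warns(UserWarning, match="empty"):
            g = build_network(rho, cutoff=0.85)
        assert g.number_of_nodes() == 0

    def test_two_triangles_q_half(self):
        g = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        partition, q = greedy_modularity(g)
        assert q == pytest.approx(0.5)
        assert len(set(partition.values())) == 2

    def test_complete_graph_single_module(self):
        g = nx.complete_graph(6)
        partition, q = greedy_modularity(g)
        assert len(set(partition.values())) == 1
        assert q == pytest.approx(0.0)

    def test_edgeless_graph_rejected(self):
        with pytest.raises(ValueError):
            greedy_modularity(nx.empty_graph(3))


class TestNodeRoles:
    def test_all_internal_edges_p_zero(self):
        g = nx.Graph([(0, 1), (1, 2), (0, 2)])
        roles = node_roles(g, {0: 0, 1: 0, 2: 0})
        assert (roles["p"] == 0).all()
        assert (roles["role"] == "peripheral").all()

    def test_even_split_participation(self):
        # hub 9 with one edge into each of 4 triangle-modules
        g = nx.Graph()
        for m in range(4):
            base = m * 3
            g.add_edges_from([(base, base + 1), (base + 1, base + 2),
                              (base, base + 2)])
        hub = 12
        for m in range(4):
            g.add_edge(hub, m * 3)
        partition = {n: n // 3 for n in range(12)}
        partition[hub] = 0
        roles = node_roles(g, partition)
        assert roles.loc[hub, "p"] == pytest.approx(0.75)
        assert roles.loc[hub, "role"] == "connector"

    def test_two_way_split_is_half(self):
        g = nx.Graph([(0, 1), (0, 2)])
        roles = node_roles(g, {0: 0, 1: 0, 2: 1})
        assert roles.loc[0, "p"] == pytest.approx(0.5)

    def test_role_thresholds(self):
        # direct threshold arithmetic on a synthetic z/p table via a stub
        # graph: roles are decided purely by the (z, p) cutoffs
        g = nx.Graph([(0, 1)])
        roles = node_roles(g, {0: 0, 1: 0})
        assert set(roles["role"]) == {"peripheral"}

    def test_isolated_node(self):
        g = nx.Graph()
        g.add_edge(0, 1)
        g.add_node(2)
        roles = node_roles(g, {0: 0, 1: 0, 2: 1})
        assert roles.loc[2, "p"] == 0.0
        assert roles.loc[2, "z"] == 0.0

    def test_printed_variant_unnamed_corner(self):
        """Under the printed thresholds the z>2.5, P<0.62 corner has no
        printed label and is reported as unclassified."""
        # star of 26 leaves in one module: center z > 2.5, P = 0
        g = nx.star_graph(26)
        partition = {n: 0 for n in g.nodes}
        canon = node_roles(g, partition, scheme="canonical")
        printed = node_roles(g, partition, scheme="printed")
        assert canon.loc[0, "z"] > 2.5
        assert canon.loc[0, "role"] == "module hub"
        assert printed.loc[0, "role"] == "unclassified"


class TestEndToEnd:
    def test_interdomain_network_chain(self):
        planted = make_planted_modules(n_modules=3, latent_strength=2.0)
        asv, truth = generate_asv_table(12, 10, planted, seed=9, noise_sd=0.1)
        rng = np.random.default_rng(10)
        bg = frame(rng.lognormal(-8, 1, (20, 10)),
                   index=[f"BG{i}" for i in range(20)],
                   cols=list(asv.columns[:10]))
        mf = pd.concat([truth["mf_intensities"], bg])
        net = interdomain_network(mf, asv, cutoff=0.85, min_abundance=1e-9)
        assert net.n_edges > 0
        kinds = net.node_kinds()
        assert set(kinds.unique()) <= {"MF", "ASV"}
        assert set(net.roles["role"]) <= {"peripheral", "connector",
                                          "module hub", "network hub"}
        assert abs(net.modularity) <= 1
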