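"""AWM selection rule, trait clustering, PCIT and hub ranking."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from fenet.awm import (
    AWMatrix,
    CoAssocNetwork,
    hub_ranking,
    partial_correlation,
    pcit,
    pcit_reference,
    select_awm_snps,
    trait_structure,
)
from fenet.simdata import SnpAnnotation

TRAITS = ["RFI", "FCR", "ADFI", "ADG", "CW", "KO", "BF", "LEAN", "IMF"]


def _fake_scans(pmat: pd.DataFrame, seed=0):
    rng = np.random.default_rng(seed)
    scans = {}
    snps = list(pmat.index)
    for t in TRAITS:
        z = rng.normal(size=len(snps))
        scans[t] = pd.DataFrame({
            "snp": snps, "p": pmat[t].to_numpy(), "z": z,
        })
    return scans


def _fake_annotation(snps, distances, tf=None):
    tf = tf or [False] * len(snps)
    snp_genes = pd.DataFrame({
        "snp": snps,
        "gene": [f"g{i}" for i in range(len(snps))],
        "distance": distances,
        "tf": tf,
    })
    genes = pd.DataFrame({
        "gene": snp_genes["gene"], "chrom": "1",
        "start": range(1000, 1000 + 1000 * len(snps), 1000),
        "end": range(2000, 2000 + 1000 * len(snps), 1000),
        "tf": tf,
    })
    return SnpAnnotation(snp_genes=snp_genes, genes=genes)


class TestSelection:
    def test_key_trait_arm_and_distance(self):
        snps = ["a", "b", "c"]
        pmat = pd.DataFrame(1.0, index=snps, columns=TRAITS)
        pmat.loc["a", "RFI"] = 0.04       # key-trait arm, distance 5 kb -> kept
        pmat.loc["b", "RFI"] = 0.04       # key-trait arm but 15 kb away -> dropped
        pmat.loc["c", "RFI"] = 0.2        # nothing significant -> dropped
        scans = _fake_scans(pmat)
        ann = _fake_annotation(snps, [5000, 15000, 0])
        out = select_awm_snps(scans, ann)
        assert list(out.z.index) == ["a"]
        assert bool(out.provenance.loc["a", "key_significant"])

    def test_multi_trait_arm_boundary(self):
        snps = ["x3", "x2"]
        pmat = pd.DataFrame(1.0, index=snps, columns=TRAITS)
        pmat.loc["x3", ["FCR", "ADG", "IMF"]] = 0.01    # exactly 3 others
        pmat.loc["x2", ["FCR", "ADG"]] = 0.01           # only 2 others
        out = select_awm_snps(_fake_scans(pmat), _fake_annotation(snps, [0, 0]))
        assert list(out.z.index) == ["x3"]
        assert int(out.provenance.loc["x3", "n_other_significant"]) == 3

    def test_toy_matches_hand_enumeration(self):
        rng = np.random.default_rng(4)
        snps = [f"s{i}" for i in range(20)]
        pmat = pd.DataFrame(rng.uniform(size=(20, 9)), index=snps, columns=TRAITS)
        dist = rng.integers(0, 20000, size=20)
        out = select_awm_snps(_fake_scans(pmat), _fake_annotation(snps, list(dist)))
        expected = [
            s for i, s in enumerate(snps)
            if (pmat.loc[s, "RFI"] < 0.05
                or (pmat.loc[s, TRAITS[1:]] < 0.05).sum() >= 3)
            and dist[i] <= 10000
        ]
        assert list(out.z.index) == expected

    def test_missing_key_trait(self):
        pmat = pd.DataFrame(1.0, index=["a"], columns=TRAITS)
        scans = _fake_scans(pmat)
        del scans["RFI"]
        with pytest.raises(ValueError, match="key trait"):
            select_awm_snps(scans, _fake_annotation(["a"], [0]))


class TestTraitStructure:
    def _awm(self, z):
        prov = pd.DataFrame(index=z.index)
        return AWMatrix(z=z, provenance=prov)

    def test_duplicated_column_merges_first(self):
        rng = np.random.default_rng(0)
        z = pd.DataFrame(rng.normal(size=(30, 3)), columns=["t1", "t2", "t3"])
        z["t2"] = z["t1"]
        corr, link, newick = trait_structure(self._awm(z))
        assert corr.loc["t1", "t2"] == pytest.approx(1.0)
        assert link[0, 2] == pytest.approx(0.0, abs=1e-12)  # zero merge height
        assert "t1" in newick and newick.endswith(";")

    def test_correlations_match_naive_oracle(self):
        rng = np.random.default_rng(1)
        z = pd.DataFrame(rng.normal(size=(25, 3)), columns=["a", "b", "c"])
        corr, *_ = trait_structure(self._awm(z))
        for i, j in itertools.combinations(z.columns, 2):
            x, y = z[i].to_numpy(), z[j].to_numpy()
            xc, yc = x - x.mean(), y - y.mean()
            r = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
            assert corr.loc[i, j] == pytest.approx(r, abs=1e-12)

    def test_shared_architecture_clusters_fe_traits(self):
        """Traits sharing SNP effects merge first in the dendrogram."""
        rng = np.random.default_rng(2)
        base = rng.normal(size=100)
        z = pd.DataFrame({
            "RFI": base + 0.3 * rng.normal(size=100),
            "FCR": base + 0.3 * rng.normal(size=100),
            "ADG": rng.normal(size=100),
            "BF": rng.normal(size=100),
        })
        corr, link, _ = trait_structure(self._awm(z))
        first = sorted(link[0, :2].astype(int))
        names = list(z.columns)
        assert [names[k] for k in first] == ["RFI", "FCR"]

    def test_constant_column_warns(self):
        z = pd.DataFrame({"a": [1.0, 1.0, 1.0, 1.0], "b": [1, 2, 3, 4.0],
                          "c": [2, 1, 4, 3.0]})
        with pytest.warns(UserWarning, match="constant"):
            trait_structure(self._awm(z))


class TestPcit:
    def test_partial_correlation_closed_form(self):
        assert partial_correlation(0.9, 0.8, 0.5) == pytest.approx(0.9623, abs=5e-5)
        assert partial_correlation(0.8, 0.9, 0.5) == pytest.approx(0.9272, abs=5e-5)
        assert partial_correlation(0.5, 0.9, 0.8) == pytest.approx(-0.8412, abs=5e-5)
        # zero-correlation limit: r_xy.z = r_xy
        assert partial_correlation(0.7, 0.0, 0.0) == pytest.approx(0.7)

    @pytest.mark.parametrize("aggregation", ["any", "all"])
    def test_matches_bruteforce_oracle(self, aggregation):
        rng = np.random.default_rng(6)
        for _ in range(10):
            n = rng.integers(8, 16)
            z = pd.DataFrame(rng.normal(size=(n, 9)),
                             index=[f"n{i}" for i in range(n)])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                net = pcit(z, aggregation=aggregation)
            ref = pcit_reference(z, aggregation=aggregation)
            got = {frozenset(e) for e in zip(net.edges["node_a"], net.edges["node_b"])}
            want = {frozenset(e) for e in zip(ref["node_a"], ref["node_b"])}
            assert got == want

    def test_permutation_invariance(self):
        rng = np.random.default_rng(7)
        z = pd.DataFrame(rng.normal(size=(12, 9)),
                         index=[f"n{i}" for i in range(12)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            net1 = pcit(z)
            perm = rng.permutation(12)
            net2 = pcit(z.iloc[perm])
        e1 = {frozenset(e) for e in zip(net1.edges["node_a"], net1.edges["node_b"])}
        e2 = {frozenset(e) for e in zip(net2.edges["node_a"], net2.edges["node_b"])}
        assert e1 == e2

    def test_small_profile_warns_about_significance(self):
        rng = np.random.default_rng(8)
        z = pd.DataFrame(rng.normal(size=(5, 9)))
        with pytest.warns(UserWarning, match="significance"):
            pcit(z)

    def test_too_few_rows(self):
        z = pd.DataFrame(np.eye(2))
        with pytest.raises(ValueError, match="3 rows"):
            pcit(z)

    def test_edge_weights_are_row_correlations(self):
        rng = np.random.default_rng(9)
        z = pd.DataFrame(rng.normal(size=(8, 9)), index=[f"n{i}" for i in range(8)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            net = pcit(z)
        R = np.corrcoef(z.to_numpy())
        idx = {f"n{i}": i for i in range(8)}
        for a, b, w in zip(net.edges["node_a"], net.edges["node_b"], net.edges["weight"]):
            assert w == pytest.approx(R[idx[a], idx[b]], abs=1e-12)
            assert abs(w) <= 1.0


class TestHubs:
    def _net(self, edges):
        nodes = sorted({x for e in edges for x in e})
        return CoAssocNetwork(
            nodes=nodes,
            edges=pd.DataFrame([{"node_a": a, "node_b": b, "weight": 0.5}
                                for a, b in edges]),
        )

    def test_star_topology(self):
        net = self._net([("h", f"l{i}") for i in range(6)])
        table, _, mean_deg = hub_ranking(net)
        assert table.iloc[0]["node"] == "h" and table.iloc[0]["degree"] == 6
        assert (table["degree"].iloc[1:] == 1).all()
        assert mean_deg == pytest.approx((6 + 6) / 7)

    def test_hand_counted_degrees(self):
        edges = [("a", "b"), ("a", "c"), ("b", "c"), ("c", "d"), ("d", "e"), ("e", "f")]
        table, _, _ = hub_ranking(self._net(edges))
        got = dict(zip(table["node"], table["degree"]))
        assert got == {"a": 2, "b": 2, "c": 3, "d": 2, "e": 2, "f": 1}
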