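import numpy as np
import pandas as pd
import pytest

from conftest import random_profiles
from terpomics.coexpression import (
    build_anchored_network,
    correlation_edges,
    export_network,
)


def brute_force_edges(a, b, threshold, inclusive=True):
    """Independent double loop over all cross pairs."""
    found = {}
    for ida in a.index:
        for idb in b.index:
            if ida == idb:
                continue
            x = a.loc[ida].to_numpy(float)
            y = b.loc[idb].to_numpy(float)
            if x.std() == 0 or y.std() == 0:
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            keep = abs(r) >= threshold if inclusive else abs(r) > threshold
            if keep:
                found[tuple(sorted((str(ida), str(idb))))] = r
    return found


class TestCorrelationEdges:
    def test_identical_profile_gives_unit_edge(self, rng):
        a = random_profiles(rng, 2, prefix="a")
        b = pd.concat([a.iloc[[0]].rename(index={"a0": "b0"})])
        edges = correlation_edges(a, b, threshold=0.8)
        match = [e for e in edges if {e.source, e.target} == {"a0", "b0"}]
        assert len(match) == 1 and match[0].r == pytest.approx(1.0)

    def test_inclusive_boundary(self):
        # construct a pair with r exactly 0.8 via rotation coordinates
        n = 10
        rng = np.random.default_rng(0)
        z = rng.standard_normal(n)
        z = (z - z.mean()) / z.std(ddof=0)
        v = rng.standard_normal(n)
        v = v - (v @ z) / (z @ z) * z  # z is centered: corr(v, z) = 0
        v = (v - v.mean()) / v.std(ddof=0)
        y = 0.8 * z + np.sqrt(1 - 0.64) * v
        a = pd.DataFrame([z], index=["x"], columns=[f"c{i}" for i in range(n)])
        b = pd.DataFrame([y], index=["y"], columns=a.columns)
        assert np.corrcoef(z, y)[0, 1] == pytest.approx(0.8, abs=1e-12)
        assert len(correlation_edges(a, b, threshold=0.8, inclusive=True)) == 1
        assert len(correlation_edges(a, b, threshold=0.8, inclusive=False)) == 0

    def test_matches_brute_force_all_pairs(self, rng):
        a = random_profiles(rng, 3, prefix="a")
        b = random_profiles(rng, 3, prefix="b")
        edges = correlation_edges(a, b, threshold=0.0)
        assert len(edges) == 9
        oracle = brute_force_edges(a, b, threshold=0.0)
        got = {(e.source, e.target): e.r for e in edges}
        assert set(got) == set(oracle)
        for key in oracle:
            assert got[key] == pytest.approx(oracle[key], abs=1e-9)

    def test_symmetric_in_argument_order(self, rng):
        a = random_profiles(rng, 4, prefix="a")
        b = random_profiles(rng, 4, prefix="b")
        e1 = {(e.source, e.target, round(e.r, 9))
              for e in correlation_edges(a, b, threshold=0.3)}
        e2 = {(e.source, e.target, round(e.r, 9))
              for e in correlation_edges(b, a, threshold=0.3)}
        assert e1 == e2

    def test_raising_threshold_never_adds_edges(self, rng):
        a = random_profiles(rng, 5, prefix="a")
        b = random_profiles(rng, 5, prefix="b")
        prev = None
        for thr in (0.0, 0.2, 0.4, 0.6, 0.8, 1.0):
            cur = {(e.source, e.target) for e in
                   correlation_edges(a, b, threshold=thr)}
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_zero_variance_profile_skipped_with_warning(self, rng):
        a = random_profiles(rng, 2, prefix="a")
        a.loc["a0"] = 1.0
        b = random_profiles(rng, 2, prefix="b")
        with pytest.warns(UserWarning, match="zero-variance"):
            edges = correlation_edges(a, b, threshold=0.0)
        assert all("a0" not in (e.source, e.target) for e in edges)

    def test_too_few_cells_rejected(self, rng):
        a = random_profiles(rng, 2, cells=2)
        with pytest.raises(ValueError):
            correlation_edges(a, a.copy())


def exact_plane_profiles(n=16, seed=0):
    """Anchors and TFs placed at exact correlation coordinates in the
    (z, v) plane; v is in-sample orthogonalized against z."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    z = (z - z.mean()) / z.std(ddof=0)
    v = rng.standard_normal(n)
    v = v - (v @ z) / (z @ z) * z  # z is centered: corr(v, z) = 0
    v = (v - v.mean()) / v.std(ddof=0)
    return z, v


class TestAnchoredNetwork:
    def _profiles(self):
        z, v = exact_plane_profiles()
        cells = [f"c{i}" for i in range(len(z))]
        rho = 0.9
        mix = rho * z + np.sqrt(1 - rho**2) * v  # corr(mix, z) = 0.9 exactly
        anchors = pd.DataFrame([z, mix], index=["anchor1", "anchor2"],
                               columns=cells)
        both = (z + mix) / np.linalg.norm(z + mix)  # corr ~ 0.975 to each
        tfs = pd.DataFrame(
            [
                both,                      # positive to both anchors
                -both,                     # negative to both
                -both * 2 + 0.5,           # negative to both (affine of -both)
                0.85 * z - 0.527 * v,      # r=0.85 to anchor1, ~0.54 to anchor2
                0.6 * z + 0.8 * v,         # r=0.6 to anchor1, ~0.89 to anchor2
            ],
            index=["TFpos", "TFneg1", "TFneg2", "TFone1", "TFone2"],
            columns=cells,
        )
        rip = pd.DataFrame(
            [both + 0.1, v], index=["rip_hit", "rip_miss"], columns=cells
        )
        return anchors, tfs, rip

    def test_planted_tf_layer_recovered(self):
        anchors, tfs, rip = self._profiles()
        net = build_anchored_network(anchors, tfs, rip, threshold=0.8)
        assert set(net.tfs) == {"TFpos", "TFneg1", "TFneg2"}
        assert net.tf_signs == {
            "TFpos": "positive", "TFneg1": "negative", "TFneg2": "negative"
        }
        # every admitted TF has an edge to EVERY anchor
        for tf in net.tfs:
            touched = {
                e.source if e.target == tf else e.target
                for e in net.anchor_tf_edges
                if tf in (e.source, e.target)
            }
            assert touched == {"anchor1", "anchor2"}
        assert set(net.ripening) == {"rip_hit"}
        # no anchor-ripening edges by construction
        for e in net.tf_ripening_edges:
            assert "anchor1" not in (e.source, e.target)
            assert "anchor2" not in (e.source, e.target)

    def test_ripening_gene_of_excluded_tf_is_excluded(self):
        anchors, tfs, rip = self._profiles()
        # rip profile matching only the excluded single-anchor TF
        rip2 = pd.DataFrame([tfs.loc["TFone2"] + 0.01], index=["rip_orphan"],
                            columns=rip.columns)
        net = build_anchored_network(anchors, tfs, rip2, threshold=0.8)
        assert net.ripening == []

    def test_below_threshold_tf_excluded(self):
        z, v = exact_plane_profiles()
        cells = [f"c{i}" for i in range(len(z))]
        anchors = pd.DataFrame([z], index=["g"], columns=cells)
        tf = 0.79 * z + np.sqrt(1 - 0.79**2) * v
        tfs = pd.DataFrame([tf], index=["TF79"], columns=cells)
        net = build_anchored_network(anchors, tfs,
                                     pd.DataFrame(columns=cells), threshold=0.8)
        assert net.tfs == []

    def test_threshold_above_max_r_gives_empty_network(self, rng):
        anchors = random_profiles(rng, 2, prefix="anchor")
        tfs = random_profiles(rng, 5, prefix="tf")
        net = build_anchored_network(anchors, tfs,
                                     random_profiles(rng, 3, prefix="rip"),
                                     threshold=1.0000001)
        assert net.tfs == [] and net.ripening == []

    def test_empty_anchor_set_rejected(self, rng):
        empty = random_profiles(rng, 0)
        with pytest.raises(ValueError):
            build_anchored_network(empty, random_profiles(rng, 2),
                                   random_profiles(rng, 2))


class TestExport:
    def test_sif_lines_and_graphml_roundtrip(self, rng, tmp_path):
        import networkx as nx

        anchors, tfs, rip = TestAnchoredNetwork()._profiles()
        net = build_anchored_network(anchors, tfs, rip, threshold=0.8)
        paths = export_network(net, tmp_path, basename="net")
        sif_lines = paths["sif"].read_text().strip().split("\n")
        assert len(sif_lines) == len(net.edges)
        for line in sif_lines:
            src, kind, dst = line.split("\t")
            assert kind in ("pos", "neg")
        back = nx.read_graphml(paths["graphml"])
        ours = net.to_graph()
        assert set(back.edges()) == set(ours.edges())
        for u, v in ours.edges():
            assert back.edges[u, v]["r"] == pytest.approx(
                ours.edges[u, v]["r"], abs=1e-9
            )

    def test_empty_network_valid_files_with_warning(self, tmp_path):
        with pytest.warns(UserWarning, match="empty"):
            paths = export_network([], tmp_path, basename="empty")
        assert paths["sif"].read_text() == ""
        import networkx as nx

        assert nx.read_graphml(paths["graphml"]).number_of_edges() == 0
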