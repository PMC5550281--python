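"""Container validation, synapse counting convention, and file round trips."""

import numpy as np
import pandas as pd
import pytest

from alphalobe.io import (
    export_edges,
    read_skeleton,
    read_synapse_table,
    write_connectome,
    write_skeleton,
)
from alphalobe.model import Connectome, ConnectomeError, Neuron, Skeleton

from conftest import build_connectome


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadSynapseTable:
    def test_empty_contact_file_gives_zero_synapses(self, tmp_path):
        conn = read_synapse_table(
            _write(tmp_path, "sites.csv", "site_id,pre_neuron,x,y,z\n"),
            _write(tmp_path, "contacts.csv", "site_id,post_neuron\n"),
            _write(tmp_path, "ann.csv", "neuron_id,cell_type\nk1,KC-ab-s\n"),
        )
        assert conn.n_synapses == 0 and conn.n_sites == 0

    def test_polyadic_site_counts_one_synapse_per_contact(self, tmp_path):
        conn = read_synapse_table(
            _write(tmp_path, "s.csv", "site_id,pre_neuron,x,y,z\ns1,k1,0,0,0\n"),
            _write(
                tmp_path,
                "c.csv",
                "site_id,post_neuron\ns1,m1\ns1,m2\ns1,k2\n",
            ),
            _write(
                tmp_path,
                "a.csv",
                "neuron_id,cell_type\nk1,KC-ab-s\nk2,KC-ab-s\n"
                "m1,MBON-a3\nm2,MBON-a3\n",
            ),
        )
        assert conn.n_sites == 1
        assert conn.n_synapses == 3

    @pytest.mark.parametrize(
        "contacts,annotations,match",
        [
            ("site_id,post_neuron\nmissing,m1\n",
             "neuron_id,cell_type\nk1,KC-ab-s\nm1,MBON-a3\n", "unknown site_id"),
            ("site_id,post_neuron\ns1,ghost\n",
             "neuron_id,cell_type\nk1,KC-ab-s\nm1,MBON-a3\n",
             "unknown postsynaptic neuron"),
            ("site_id,post_neuron\ns1,m1\n",
             "neuron_id,cell_type\nk1,KC-xx\nm1,MBON-a3\n", "unknown cell_type"),
        ],
    )
    def test_referential_and_vocabulary_errors(
        self, tmp_path, contacts, annotations, match
    ):
        sites = _write(tmp_path, "s.csv", "site_id,pre_neuron,x,y,z\ns1,k1,0,0,0\n")
        with pytest.raises(ConnectomeError, match=match):
            read_synapse_table(
                sites,
                _write(tmp_path, "c.csv", contacts),
                _write(tmp_path, "a.csv", annotations),
            )

    def test_malformed_coordinate_is_a_hard_error(self, tmp_path):
        with pytest.raises(ConnectomeError, match="malformed y coordinate"):
            read_synapse_table(
                _write(
                    tmp_path, "s.csv", "site_id,pre_neuron,x,y,z\ns1,k1,0,oops,0\n"
                ),
                _write(tmp_path, "c.csv", "site_id,post_neuron\n"),
                _write(tmp_path, "a.csv", "neuron_id,cell_type\nk1,KC-ab-s\n"),
            )

    def test_duplicate_contact_rejected(self, tmp_path):
        with pytest.raises(ConnectomeError, match="duplicate"):
            read_synapse_table(
                _write(tmp_path, "s.csv", "site_id,pre_neuron,x,y,z\ns1,k1,0,0,0\n"),
                _write(tmp_path, "c.csv", "site_id,post_neuron\ns1,m1\ns1,m1\n"),
                _write(
                    tmp_path, "a.csv",
                    "neuron_id,cell_type\nk1,KC-ab-s\nm1,MBON-a3\n",
                ),
            )

    def test_round_trip_is_identity(self, tmp_path, small_generated):
        conn, _ = small_generated
        paths = write_connectome(conn, tmp_path / "out")
        back = read_synapse_table(
            paths["sites"], paths["contacts"], paths["annotations"]
        )
        pd.testing.assert_frame_equal(back.sites, conn.sites)
        pd.testing.assert_frame_equal(
            back.contacts.sort_values(["site_id", "post_neuron"]).reset_index(drop=True),
            conn.contacts.sort_values(["site_id", "post_neuron"]).reset_index(drop=True),
        )
        assert (back.neurons["cell_type"] == conn.neurons["cell_type"]).all()


class TestEdgeExport:
    def test_polyadic_site_grouped_by_neuron(self, tiny_connectome):
        edges = export_edges(tiny_connectome, group_by="neuron")
        assert edges["n_synapses"].sum() == tiny_connectome.n_synapses

    def test_single_row_when_all_cells_share_one_type(self):
        conn = build_connectome(
            neurons=[("k1", "KC-ab-s"), ("k2", "KC-ab-s")],
            sites=[("s1", "k1", (0, 0, 0), "a1"), ("s2", "k1", (9, 9, 9), "a1")],
            contacts=[("s1", "k2"), ("s2", "k2")],
        )
        edges = export_edges(conn, group_by="cell_type")
        assert len(edges) == 1 and edges.loc[0, "n_synapses"] == 2

    def test_per_type_sums_match_brute_force_tally(self, small_generated):
        conn, _ = small_generated
        edges = export_edges(conn, group_by="cell_type")
        t = conn.contact_table()
        for row in edges.itertuples(index=False):
            expected = sum(
                1
                for pre, post, comp in zip(
                    t["pre_type"], t["post_type"], t["compartment"]
                )
                if (pre, post, comp) == (row.pre, row.post, row.compartment)
            )
            assert row.n_synapses == expected

    def test_partition_counts_sum_to_global_contact_count(self, small_generated):
        conn, _ = small_generated
        for group_by in ("neuron", "cell_type"):
            assert export_edges(conn, group_by)["n_synapses"].sum() == conn.n_synapses


class TestSkeletonIO:
    def test_three_node_path_has_two_edges(self, tmp_path):
        swc = tmp_path / "path.swc"
        swc.write_text("1 0 0 0 0 1 -1\n2 0 1000 0 0 1 1\n3 0 3000 0 0 1 2\n")
        sk = read_skeleton(swc)
        assert sk.n_nodes() == 3 and len(sk.edges()) == 2
        assert sk.total_cable_length == pytest.approx(3000.0)

    def test_two_roots_is_an_error(self, tmp_path):
        swc = tmp_path / "bad.swc"
        swc.write_text("1 0 0 0 0 1 -1\n2 0 1 0 0 1 -1\n")
        with pytest.raises(ConnectomeError, match="exactly one root"):
            read_skeleton(swc)

    def test_missing_parent_is_an_error(self, tmp_path):
        swc = tmp_path / "bad.swc"
        swc.write_text("1 0 0 0 0 1 -1\n2 0 1 0 0 1 99\n")
        with pytest.raises(ConnectomeError, match="missing parent"):
            read_skeleton(swc)

    def test_cable_length_invariant_under_reindexing(self, tmp_path):
        rng = np.random.default_rng(3)
        n = 30
        positions = rng.uniform(0, 10000, (n, 3))
        parents = [-1] + [int(rng.integers(1, i + 1)) for i in range(1, n)]
        sk = Skeleton(list(range(1, n + 1)), positions, parents)
        # re-index: node i -> 100 + i
        sk2 = Skeleton(
            [i + 100 for i in range(1, n + 1)],
            positions,
            [-1] + [p + 100 for p in parents[1:]],
        )
        assert sk.total_cable_length == pytest.approx(sk2.total_cable_length)

    def test_skeleton_round_trip(self, tmp_path):
        from conftest import path_skeleton

        sk = path_skeleton()
        write_skeleton(sk, tmp_path / "rt.swc")
        back = read_skeleton(tmp_path / "rt.swc")
        assert back.total_cable_length == pytest.approx(sk.total_cable_length)
        assert back.root_id == sk.root_id
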