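"""Convergence/rosette/triangle detection and dopamine proximity/coverage."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from alphalobe.model import ConnectomeError
from alphalobe.motifs import (
    coverage_curve,
    dan_proximity_fraction,
    find_convergences,
    find_rosettes,
    motif_fractions,
    nearest_modulation_stats,
    triangle_motifs,
)
from alphalobe.synthetic import GeneratorConfig, generate

from conftest import build_connectome


def _two_kc_connectome(gap_nm, kc_kc=False, kc_kc_between_members=True):
    neurons = [
        ("kc1", "KC-ab-s"),
        ("kc2", "KC-ab-s"),
        ("kc3", "KC-ab-s"),
        ("m1", "MBON-a3", "A"),
    ]
    sites = [
        ("s1", "kc1", (1000.0, 1000.0, 41000.0), "a3"),
        ("s2", "kc2", (1000.0 + gap_nm, 1000.0, 41000.0), "a3"),
        ("s9", "kc3", (50_000.0, 50_000.0, 41000.0), "a3"),
    ]
    contacts = [("s1", "m1"), ("s2", "m1"), ("s9", "m1")]
    if kc_kc:
        post = "kc2" if kc_kc_between_members else "kc3"
        contacts.append(("s1", post))
    return build_connectome(neurons, sites, contacts)


class TestConvergences:
    def test_sites_within_radius_form_one_convergence(self):
        conn = _two_kc_connectome(200.0)
        clusters = find_convergences(conn)
        assert len(clusters) == 1
        assert set(clusters[0].member_sites) == {"s1", "s2"}

    def test_sites_beyond_radius_do_not(self):
        assert find_convergences(_two_kc_connectome(500.0)) == []

    def test_tie_at_exactly_the_radius_counts_as_within(self):
        assert len(find_convergences(_two_kc_connectome(300.0))) == 1

    def test_same_kc_grouping_is_not_a_convergence(self):
        conn = build_connectome(
            neurons=[("kc1", "KC-ab-s"), ("m1", "MBON-a3")],
            sites=[
                ("s1", "kc1", (0.0, 0.0, 0.0), "a1"),
                ("s2", "kc1", (100.0, 0.0, 0.0), "a1"),
            ],
            contacts=[("s1", "m1"), ("s2", "m1")],
        )
        assert find_convergences(conn) == []

    def test_rigid_transform_invariance(self, small_generated):
        conn, _ = small_generated
        base = find_convergences(conn, post_selector="MBON-a3-A")
        # rotate 90 degrees about z and translate
        sites = conn.sites.copy()
        x, y = sites["x"].to_numpy().copy(), sites["y"].to_numpy().copy()
        sites["x"], sites["y"] = -y + 200_000.0, x + 10_000.0
        from alphalobe.model import Connectome

        rotated = Connectome(conn.neurons, sites, conn.contacts)
        moved = find_convergences(rotated, post_selector="MBON-a3-A")
        assert sorted(frozenset(c.member_sites) for c in base) == sorted(
            frozenset(c.member_sites) for c in moved
        )


class TestRosettes:
    def test_kc_kc_between_members_makes_a_rosette(self):
        conn = _two_kc_connectome(200.0, kc_kc=True)
        clusters = find_rosettes(find_convergences(conn), conn)
        assert clusters[0].is_rosette

    def test_kc_kc_to_non_member_does_not(self):
        conn = _two_kc_connectome(200.0, kc_kc=True, kc_kc_between_members=False)
        clusters = find_rosettes(find_convergences(conn), conn)
        assert not clusters[0].is_rosette

    def test_planted_recovery_is_exact_with_separation(self):
        cfg = GeneratorConfig(
            n_kc_per_subtype={"KC-ab-s": 40},
            cells_per_compartment={"a3": [("MBON-a3", 1)]},
            wiring_rate={("KC-ab-s", "MBON-a3", "a3"): 2.0},
            convergence_rate=0.6,
            rosette_rate=0.5,
            min_site_separation=900.0,  # 3x the 300 nm clustering radius
            seed=21,
        )
        conn, truth = generate(cfg)
        clusters = find_rosettes(find_convergences(conn), conn)
        planted = {frozenset(c.site_ids) for c in truth.clusters}
        detected = {frozenset(c.member_sites) for c in clusters}
        assert planted and detected == planted  # 100% precision and recall
        assert {frozenset(c.site_ids) for c in truth.rosettes} == {
            frozenset(c.member_sites) for c in clusters if c.is_rosette
        }


class TestMotifFractions:
    def test_isolated_sites_have_zero_fractions(self):
        conn = _two_kc_connectome(500.0)
        conv, ros = motif_fractions(conn, "MBON-a3")
        assert conv == 0.0 and ros == 0.0

    def test_fully_planted_rosettes_give_hundred_percent(self):
        cfg = GeneratorConfig(
            n_kc_per_subtype={"KC-ab-s": 20},
            cells_per_compartment={"a3": [("MBON-a3", 1)]},
            wiring_rate={("KC-ab-s", "MBON-a3", "a3"): 2.0},
            convergence_rate=1.0,
            rosette_rate=1.0,
            min_site_separation=900.0,
            seed=8,
        )
        conn, truth = generate(cfg)
        # an odd synapse count leaves at most one unpaired singleton
        n_sites = conn.contact_table().query(
            "pre_class == 'KC' and post_class == 'MBON'"
        )["site_id"].nunique()
        expected = 100.0 * 2 * len(truth.clusters) / n_sites
        conv, ros = motif_fractions(conn, "MBON-a3")
        assert conv == pytest.approx(expected)
        assert ros == pytest.approx(expected)

    def test_zero_denominator_signalled(self):
        conn = build_connectome(
            neurons=[("kc1", "KC-ab-s"), ("m1", "MBON-a3"), ("m2", "MBON-a1")],
            sites=[("s1", "kc1", (0.0, 0.0, 0.0), "a1")],
            contacts=[("s1", "m2")],
        )
        with pytest.raises(ConnectomeError, match="undefined"):
            motif_fractions(conn, "MBON-a3")


def _brute_force_triangles(conn, radius=300.0):
    """Exhaustive triple enumeration: single linkage by union-find, then scan."""
    t = conn.contact_table()
    mbons = set(conn.neurons.index[conn.neurons["type_class"] == "MBON"])
    triples = set()
    for mbon in mbons:
        rows = t[(t["post_neuron"] == mbon) & (t["pre_class"] == "KC")]
        rows = rows.drop_duplicates("site_id")
        ids = list(rows["site_id"])
        if not ids:
            continue
        pos = rows[["x", "y", "z"]].to_numpy(dtype=float)
        parent = list(range(len(ids)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        d = cdist(pos, pos)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if d[i, j] <= radius:
                    parent[find(i)] = find(j)
        comp = {}
        for i, sid in enumerate(ids):
            comp.setdefault(find(i), []).append(sid)
        kk = t[(t["pre_class"] == "KC") & (t["post_class"] == "KC")]
        for members in comp.values():
            kcs = set(rows[rows["site_id"].isin(members)]["pre_neuron"])
            if len(kcs) < 2:
                continue
            member_pos = rows[rows["site_id"].isin(members)][["x", "y", "z"]].to_numpy(
                dtype=float
            )
            for _, row in kk.iterrows():
                if row["pre_neuron"] in kcs and row["post_neuron"] in kcs:
                    p = np.array([row["x"], row["y"], row["z"]], dtype=float)
                    if np.min(np.linalg.norm(member_pos - p, axis=1)) <= radius:
                        a, b = sorted((row["pre_neuron"], row["post_neuron"]))
                        triples.add((a, b, mbon))
    return sorted(triples)


class TestTriangles:
    def test_constructed_rosette_yields_one_triple(self):
        conn = _two_kc_connectome(200.0, kc_kc=True)
        assert triangle_motifs(conn) == [("kc1", "kc2", "m1")]

    def test_no_kc_kc_contacts_yields_none(self, small_generated):
        conn = _two_kc_connectome(200.0, kc_kc=False)
        assert triangle_motifs(conn) == []

    def test_matches_exhaustive_enumeration_on_toy(self):
        cfg = GeneratorConfig(
            n_kc_per_subtype={"KC-ab-s": 12, "KC-ab-p": 4},
            cells_per_compartment={"a3": [("MBON-a3", 2)]},
            wiring_rate={
                ("KC-ab-s", "MBON-a3", "a3"): 3.0,
                ("KC-ab-p", "MBON-a3", "a3"): 2.0,
            },
            convergence_rate=0.7,
            rosette_rate=0.6,
            seed=13,
        )
        conn, _ = generate(cfg)
        assert triangle_motifs(conn) == _brute_force_triangles(conn)


class TestDanProximity:
    def test_no_dan_sites_gives_zero(self):
        conn = _two_kc_connectome(200.0)
        assert dan_proximity_fraction(conn) == 0.0

    def test_colocated_dan_gives_one(self):
        conn = build_connectome(
            neurons=[("kc1", "KC-ab-s"), ("m1", "MBON-a3"), ("d1", "PPL1-a3")],
            sites=[
                ("s1", "kc1", (100.0, 100.0, 100.0), "a3"),
                ("sd", "d1", (100.0, 100.0, 100.0), "a3"),
            ],
            contacts=[("s1", "m1"), ("sd", "kc1")],
        )
        assert dan_proximity_fraction(conn) == 1.0

    def test_matches_all_pairs_oracle(self, small_generated):
        conn, _ = small_generated
        t = conn.contact_table()
        km = t[(t["pre_class"] == "KC") & (t["post_class"] == "MBON")]
        dan_pos = conn.sites[
            conn.sites["pre_neuron"].map(conn.neurons["type_class"]).eq("DAN")
        ][["x", "y", "z"]].to_numpy(dtype=float)
        km_pos = km[["x", "y", "z"]].to_numpy(dtype=float)
        for radius in (300.0, 2000.0):
            brute = float(
                np.mean(cdist(km_pos, dan_pos).min(axis=1) <= radius)
            )
            assert dan_proximity_fraction(conn, radius) == pytest.approx(brute)


class TestNearestModulation:
    def test_single_pair_distance(self):
        conn = build_connectome(
            neurons=[("kc1", "KC-ab-s"), ("m1", "MBON-a3"), ("d1", "PPL1-a3")],
            sites=[
                ("s1", "kc1", (0.0, 0.0, 0.0), "a3"),
                ("sd", "d1", (500.0, 0.0, 0.0), "a3"),
            ],
            contacts=[("s1", "m1"), ("sd", "kc1")],
        )
        mean_d, interspersed = nearest_modulation_stats(conn)
        assert mean_d == pytest.approx(500.0)
        assert interspersed == 0.0

    def test_colocated_dan_kc_synapse(self):
        conn = build_connectome(
            neurons=[("kc1", "KC-ab-s"), ("m1", "MBON-a3"), ("d1", "PPL1-a3")],
            sites=[
                ("s1", "kc1", (10.0, 10.0, 10.0), "a3"),
                ("sd", "d1", (10.0, 10.0, 10.0), "a3"),
            ],
            contacts=[("s1", "m1"), ("sd", "kc1")],
        )
        assert nearest_modulation_stats(conn) == (0.0, 0.0)

    def test_matches_all_pairs_oracle(self, small_generated):
        conn, _ = small_generated
        t = conn.contact_table()
        km = t[(t["pre_class"] == "KC") & (t["post_class"] == "MBON")]
        dk = t[(t["pre_class"] == "DAN") & (t["post_class"] == "KC")]
        dk_pos = dk.drop_duplicates("site_id")[["x", "y", "z"]].to_numpy(dtype=float)
        all_pos = conn.sites[["x", "y", "z"]].to_numpy(dtype=float)
        site_of = {sid: i for i, sid in enumerate(conn.sites.index)}
        dists, counts = [], []
        for _, row in km.iterrows():
            p = np.array([row["x"], row["y"], row["z"]], dtype=float)
            d = np.linalg.norm(dk_pos - p, axis=1).min()
            dists.append(d)
            site_d = np.linalg.norm(all_pos - p, axis=1)
            closer = site_d < d
            closer[site_of[row["site_id"]]] = False
            counts.append(int(closer.sum()))
        mean_d, interspersed = nearest_modulation_stats(conn)
        assert mean_d == pytest.approx(np.mean(dists))
        assert interspersed == pytest.approx(np.mean(counts))


class TestCoverage:
    def test_monotone_and_bounded(self, small_generated):
        conn, _ = small_generated
        curve = coverage_curve(conn, np.arange(0.0, 4001.0, 250.0))
        same = curve.same_compartment_fraction
        adj = curve.adjacent_compartment_fraction
        assert np.all(np.diff(same) >= 0)
        assert np.all(np.diff(adj) >= 0)
        assert same.max() <= 1.0 and adj.max() <= 1.0

    def test_radii_below_minimum_distance_give_zero(self):
        conn = build_connectome(
            neurons=[("kc1", "KC-ab-s"), ("m1", "MBON-a3"), ("d1", "PPL1-a3")],
            sites=[
                ("s1", "kc1", (0.0, 0.0, 100.0), "a1"),
                ("sd", "d1", (5000.0, 0.0, 100.0), "a1"),
            ],
            contacts=[("s1", "m1"), ("sd", "kc1")],
        )
        curve = coverage_curve(conn, np.array([100.0, 1000.0, 4000.0]))
        assert np.all(curve.same_compartment_fraction == 0.0)

    def test_dense_same_compartment_dan_saturates(self):
        rng = np.random.default_rng(0)
        neurons = [("kc1", "KC-ab-s"), ("m1", "MBON-a3"), ("d1", "PPL1-a3")]
        sites = [("s1", "kc1", (5000.0, 5000.0, 5000.0), "a1")]
        contacts = [("s1", "m1")]
        for i in range(50):
            pos = tuple(rng.uniform(4500, 5500, 3))
            sites.append((f"d{i}", "d1", pos, "a1"))
            contacts.append((f"d{i}", "kc1"))
        conn = build_connectome(neurons, sites, contacts)
        curve = coverage_curve(conn, np.array([1000.0, 2000.0]))
        assert np.all(curve.same_compartment_fraction == 1.0)
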