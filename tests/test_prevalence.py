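"""Presence matrix, prevalence, site overlap and rarefaction."""

import numpy as np
import pandas as pd
import pytest

from lectiscope.prevalence import (
    GeneCatalog,
    PresenceMatrix,
    build_presence_matrix,
    prevalence_summary,
    rarefaction_curve,
    site_overlap,
    top_prevalent,
)
from lectiscope.synth import AA20

from helpers import exhaustive_rarefaction


def _seq(rng, length=60):
    return "".join(rng.choice(list(AA20), size=length))


def matrix_from(data: dict[str, dict[str, bool]], site_map: dict[str, str]):
    df = pd.DataFrame(data).T.astype(bool)  # rows = lectins
    return PresenceMatrix(data=df, site_map=site_map)


class TestBuildPresenceMatrix:
    def test_exact_copy_detected(self):
        rng = np.random.default_rng(0)
        lectin = _seq(rng)
        catalogs = [GeneCatalog("s1", "stool", (("g1", lectin),))]
        m = build_presence_matrix([("L1", lectin)], catalogs)
        assert m.data.loc["L1", "s1"]

    def test_empty_catalog_gives_false_column(self):
        rng = np.random.default_rng(1)
        catalogs = [GeneCatalog("s1", "stool", ())]
        m = build_presence_matrix([("L1", _seq(rng))], catalogs)
        assert not m.data.loc["L1", "s1"]

    def test_homolog_and_absence(self):
        rng = np.random.default_rng(2)
        l1, l2 = _seq(rng, 100), _seq(rng, 100)
        # 95%-identity homolog of l2: 5 substitutions
        chars = list(l2)
        for pos in rng.choice(100, size=5, replace=False):
            chars[pos] = [a for a in AA20 if a != chars[pos]][0]
        homolog = "".join(chars)
        catalogs = [
            GeneCatalog("A", "stool", (("c1", l1), ("c2", homolog))),
            GeneCatalog("B", "stool", (("c3", _seq(rng, 100)),)),
        ]
        m = build_presence_matrix([("L1", l1), ("L2", l2)], catalogs, 0.90, 0.8)
        assert m.data.to_numpy().tolist() == [[True, False], [True, False]]

    def test_duplicate_sample_id_rejected(self):
        rng = np.random.default_rng(3)
        cats = [
            GeneCatalog("s1", "stool", ()),
            GeneCatalog("s1", "stool", ()),
        ]
        with pytest.raises(ValueError):
            build_presence_matrix([("L1", _seq(rng))], cats)

    def test_invariant_to_gene_and_sample_order(self):
        rng = np.random.default_rng(4)
        l1, l2 = _seq(rng), _seq(rng)
        noise = _seq(rng)
        cats = [
            GeneCatalog("s1", "stool", (("a", noise), ("b", l1))),
            GeneCatalog("s2", "buccal_mucosa", (("c", l2),)),
        ]
        cats_flipped = [
            GeneCatalog("s2", "buccal_mucosa", (("c", l2),)),
            GeneCatalog("s1", "stool", (("b", l1), ("a", noise))),
        ]
        m1 = build_presence_matrix([("L1", l1), ("L2", l2)], cats)
        m2 = build_presence_matrix([("L1", l1), ("L2", l2)], cats_flipped)
        assert m1.data.sort_index(axis=1).equals(m2.data.sort_index(axis=1))


class TestPrevalenceSummary:
    def test_two_lectins_one_sample(self):
        m = matrix_from({"a": {"s1": True}, "b": {"s1": True}}, {"s1": "stool"})
        s = prevalence_summary(m)["stool"]
        assert (s["richness"], s["mean_per_sample"]) == (2, 2.0)

    def test_all_false(self):
        m = matrix_from({"a": {"s1": False}}, {"s1": "stool"})
        s = prevalence_summary(m)["stool"]
        assert (s["richness"], s["mean_per_sample"]) == (0, 0.0)

    def test_partial_prevalence(self):
        samples = {f"s{i}": "stool" for i in range(1, 5)}
        m = matrix_from(
            {"a": {"s1": True, "s2": True, "s3": True, "s4": False}}, samples
        )
        s = prevalence_summary(m)["stool"]
        assert s["per_lectin_counts"] == {"a": 3}
        assert s["mean_per_sample"] == 0.75


class TestSiteOverlap:
    def test_three_lectin_example(self):
        m = matrix_from(
            {
                "a": {"st": True, "bu": False},
                "b": {"st": True, "bu": True},
                "c": {"st": False, "bu": True},
            },
            {"st": "stool", "bu": "buccal_mucosa"},
        )
        o = site_overlap(m)
        assert o["shared_fraction"] == pytest.approx(1 / 3)
        assert o["site_specific_fraction"]["stool"] == pytest.approx(1 / 2)
        assert o["venn_counts"]["buccal_mucosa&stool"] == 1

    def test_single_site(self):
        m = matrix_from({"a": {"s1": True}}, {"s1": "stool"})
        assert site_overlap(m)["shared_fraction"] == 0.0

    def test_everything_everywhere(self):
        m = matrix_from(
            {"a": {"s1": True, "s2": True}, "b": {"s1": True, "s2": True}},
            {"s1": "stool", "s2": "buccal_mucosa"},
        )
        o = site_overlap(m)
        assert o["shared_fraction"] == 1.0
        assert all(v == 0.0 for v in o["site_specific_fraction"].values())

    def test_shared_plus_exclusive_partition(self):
        rng = np.random.default_rng(11)
        samples = {}
        for site in ("stool", "buccal_mucosa", "tongue_dorsum"):
            for i in range(3):
                samples[f"{site}_{i}"] = site
        data = {
            f"lec{j}": {s: bool(rng.random() < 0.3) for s in samples}
            for j in range(12)
        }
        m = matrix_from(data, samples)
        o = site_overlap(m)
        exclusive = sum(
            1 for sites in o["site_sets"].values() if len(sites) == 1
        )
        if o["n_observed"]:
            assert o["shared_fraction"] + exclusive / o["n_observed"] == pytest.approx(1.0)


class TestTopPrevalent:
    def _matrix(self, counts):
        samples = {f"s{i}": "stool" for i in range(10)}
        data = {
            f"lec{j:02d}": {f"s{i}": i < c for i in range(10)}
            for j, c in enumerate(counts)
        }
        return matrix_from(data, samples)

    def test_top_ten_percent_of_ten(self):
        m = self._matrix([10, 9, 8, 7, 6, 5, 4, 3, 2, 1])
        assert top_prevalent(m, "stool", 0.1) == ["lec00"]

    def test_fraction_one_returns_all_present(self):
        m = self._matrix([3, 2, 0, 1])
        assert top_prevalent(m, "stool", 1.0) == ["lec00", "lec01", "lec03"]

    def test_ceiling_and_tie_break(self):
        m = self._matrix([9, 9, 3, 2, 1])
        assert top_prevalent(m, "stool", 0.5) == ["lec00", "lec01", "lec02"]

    def test_empty_site_richness(self):
        m = self._matrix([0, 0])
        assert top_prevalent(m, "stool", 0.5) == []


class TestRarefaction:
    def _matrix(self, incidences, N):
        samples = {f"s{i}": "stool" for i in range(N)}
        data = {
            f"lec{j}": {f"s{i}": i < c for i in range(N)}
            for j, c in enumerate(incidences)
        }
        return matrix_from(data, samples)

    def test_endpoints(self):
        m = self._matrix([1, 2, 4], 4)
        curve = rarefaction_curve(m, "stool")
        summary = prevalence_summary(m)["stool"]
        assert curve.expected_richness(4) == pytest.approx(summary["richness"])
        assert curve.expected_richness(1) == pytest.approx(summary["mean_per_sample"])

    def test_matches_exhaustive_subset_average(self):
        m = self._matrix([1, 2, 4], 4)
        curve = rarefaction_curve(m, "stool")
        block = m.data.to_numpy()
        for n in range(1, 5):
            assert curve.points[n - 1] == pytest.approx(
                exhaustive_rarefaction(block, n), abs=1e-9
            )

    def test_monotone_and_concave(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            N = int(rng.integers(2, 10))
            incid = rng.integers(0, N + 1, size=int(rng.integers(1, 8)))
            m = self._matrix(list(incid), N)
            pts = rarefaction_curve(m, "stool").points
            diffs = np.diff(pts)
            assert (diffs >= -1e-12).all()
            assert (np.diff(diffs) <= 1e-12).all()

    def test_out_of_range_n(self):
        m = self._matrix([1], 3)
        curve = rarefaction_curve(m, "stool")
        with pytest.raises(ValueError):
            curve.expected_richness(0)
        with pytest.raises(ValueError):
            curve.expected_richness(4)

    def test_resampling_sd_is_seeded(self):
        m = self._matrix([1, 2, 4], 4)
        c1 = rarefaction_curve(m, "stool", resample=50, seed=9)
        c2 = rarefaction_curve(m, "stool", resample=50, seed=9)
        assert np.array_equal(c1.sd, c2.sd)
        assert c1.sd[-1] == pytest.approx(0.0)  # full subset has no variance

    def test_unknown_site(self):
        m = self._matrix([1], 2)
        with pytest.raises(ValueError):
            rarefaction_curve(m, "skin")
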