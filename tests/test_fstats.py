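import numpy as np
import pandas as pd
import pytest

from paleokin import fstats as fs
from paleokin import simdata as sd
from paleokin.core import MISSING, GenotypeStore, IndividualRecord, SNPPanel


def brute_f3(o, a, b):
    vals = [(o[i] - a[i]) * (o[i] - b[i]) for i in range(len(o))
            if np.isfinite(o[i]) and np.isfinite(a[i]) and np.isfinite(b[i])]
    return sum(vals) / len(vals)


def brute_d(w, x, y, z):
    num = den = 0.0
    for i in range(len(w)):
        if not all(np.isfinite(v[i]) for v in (w, x, y, z)):
            continue
        num += (w[i] - x[i]) * (y[i] - z[i])
        den += (w[i] + x[i] - 2 * w[i] * x[i]) * (y[i] + z[i] - 2 * y[i] * z[i])
    return num / den


@pytest.fixture(scope="module")
def random_freqs():
    rng = np.random.default_rng(7)
    n = 400
    blocks = np.repeat(np.arange(8), 50)
    tracks = {k: rng.uniform(0.02, 0.98, n) for k in "OABCD"}
    tracks["A"][rng.random(n) < 0.1] = np.nan     # some missingness
    return tracks, blocks


class TestOracleEquivalence:
    def test_f3_matches_brute_force(self, random_freqs):
        t, blocks = random_freqs
        r = fs.f3(t["O"], t["A"], t["B"], blocks)
        assert r.estimate == pytest.approx(brute_f3(t["O"], t["A"], t["B"]),
                                           abs=1e-12)

    def test_f4_matches_brute_force(self, random_freqs):
        t, blocks = random_freqs
        r = fs.f4(t["O"], t["A"], t["B"], t["C"], blocks)
        naive = np.nanmean((t["O"] - t["A"]) * (t["B"] - t["C"]))
        assert r.estimate == pytest.approx(naive, abs=1e-12)

    def test_d_matches_brute_force(self, random_freqs):
        t, blocks = random_freqs
        r = fs.d_stat(t["O"], t["A"], t["B"], t["C"], blocks)
        assert r.estimate == pytest.approx(
            brute_d(t["O"], t["A"], t["B"], t["C"]), abs=1e-12)

    def test_fixed_two_site_example(self):
        o = np.array([0.0, 0.0])
        a = np.array([1.0, 0.5])
        b = np.array([1.0, 0.5])
        r = fs.f3(o, a, b, np.array([0, 1]))
        assert r.estimate == pytest.approx(0.625, abs=1e-15)

    def test_f3_symmetry_exact(self, random_freqs):
        t, blocks = random_freqs
        r1 = fs.f3(t["O"], t["A"], t["B"], blocks)
        r2 = fs.f3(t["O"], t["B"], t["A"], blocks)
        assert r1.estimate == r2.estimate

    def test_f4_antisymmetry_exact(self, random_freqs):
        t, blocks = random_freqs
        r1 = fs.d_stat(t["O"], t["A"], t["B"], t["C"], blocks)
        r2 = fs.d_stat(t["O"], t["A"], t["C"], t["B"], blocks)
        assert r1.estimate == -r2.estimate

    def test_d_identical_sisters_zero(self, random_freqs):
        t, blocks = random_freqs
        r = fs.d_stat(t["O"], t["A"], t["B"], t["B"], blocks)
        assert r.estimate == 0.0

    def test_degenerate_all_equal_zero(self):
        o = np.full(100, 0.4)
        r = fs.f3(o, o, o, np.repeat(np.arange(4), 25))
        assert r.estimate == 0.0


class TestJackknife:
    def test_equal_weights_reduce_to_classical(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 1, 200)
        blocks = np.repeat(np.arange(10), 20)
        den = np.ones_like(vals)
        r = fs._ratio_jackknife(vals, den, blocks, "f4", ("t",))
        # classical delete-one jackknife on per-block means
        loo = np.array([vals[blocks != b].mean() for b in range(10)])
        classical = np.sqrt(9 / 10 * ((loo - loo.mean()) ** 2).sum())
        assert r.se == pytest.approx(classical, rel=1e-9)

    def test_z_is_estimate_over_se(self, random_freqs):
        t, blocks = random_freqs
        r = fs.f4(t["O"], t["A"], t["B"], t["C"], blocks)
        assert r.z == pytest.approx(r.estimate / r.se)

    def test_single_block_no_se(self):
        vals = np.ones(10) * 0.3
        r = fs._ratio_jackknife(vals, np.ones(10), np.zeros(10, dtype=int),
                                "f4", ("t",))
        assert np.isnan(r.se) and r.n_blocks == 1

    def test_no_overlap_errors(self):
        vals = np.full(5, np.nan)
        with pytest.raises(ValueError, match="no overlapping"):
            fs._ratio_jackknife(vals, vals, np.zeros(5, dtype=int),
                                "f3", ("x",))


def test_null_f4_z_calibration():
    """Independent drift on all four leaves: |Z| > 3 must be rare."""
    g = sd.AdmixtureGraphSpec(
        nodes=["R", "A", "B", "C", "D"],
        edges={x: ("R", 0.05) for x in "ABCD"})
    n_exceed = 0
    n_stats = 120
    for rep in range(n_stats // 3):
        freqs, panel = sd.simulate_graph_frequencies(g, 5000, 300 + rep)
        blocks = fs.block_assignment(panel)
        for (w, x, y, z) in (("A", "B", "C", "D"), ("A", "C", "B", "D"),
                             ("A", "D", "B", "C")):
            r = fs.f4(freqs[w], freqs[x], freqs[y], freqs[z], blocks)
            n_exceed += abs(r.z) > 3
    assert n_exceed / n_stats <= 0.03


class TestFilterCohort:
    def _store(self):
        panel = SNPPanel([f"s{i}" for i in range(10)], ["1"] * 10,
                         ["autosome"] * 10, np.arange(1, 11) * 100,
                         ["C"] * 10, ["A"] * 10)
        store = GenotypeStore(["a", "b", "c"], panel)
        store.pseudohap[:] = 0
        return panel, store

    def test_85_percent_rule(self):
        panel, store = self._store()
        store.pseudohap[1, :2] = MISSING      # b: 80% genotyped -> dropped
        recs = [IndividualRecord(id=x, coverage=1.0) for x in "abc"]
        sub, kept = fs.filter_cohort(store, recs)
        assert kept == ["a", "c"]

    def test_849_percent_removed(self):
        panel = SNPPanel([f"s{i}" for i in range(1000)], ["1"] * 1000,
                         ["autosome"] * 1000, np.arange(1, 1001),
                         ["C"] * 1000, ["A"] * 1000)
        store = GenotypeStore(["a", "b"], panel)
        store.pseudohap[:] = 0
        store.pseudohap[0, :151] = MISSING    # 84.9% genotyped
        recs = [IndividualRecord(id=x, coverage=1.0) for x in "ab"]
        _, kept = fs.filter_cohort(store, recs)
        assert kept == ["b"]

    def test_singleton_variant_removed(self):
        panel, store = self._store()
        store.pseudohap[0, 0] = 1             # variant in exactly one
        recs = [IndividualRecord(id=x, coverage=1.0) for x in "abc"]
        sub, _ = fs.filter_cohort(store, recs)
        assert sub.panel.n_sites == 9
        assert "s0" not in sub.panel.ids

    def test_doubleton_kept(self):
        panel, store = self._store()
        store.pseudohap[0, 0] = 1
        store.pseudohap[1, 0] = 1
        recs = [IndividualRecord(id=x, coverage=1.0) for x in "abc"]
        sub, _ = fs.filter_cohort(store, recs)
        assert sub.panel.n_sites == 10

    def test_kin_group_keeps_highest_coverage(self):
        from paleokin.kinstats import PairKinship
        panel, store = self._store()
        recs = [IndividualRecord(id="a", coverage=0.1),
                IndividualRecord(id="b", coverage=0.5),
                IndividualRecord(id="c", coverage=0.2)]
        pairs = []
        for x, y in (("a", "b"), ("b", "c")):
            pk = PairKinship(x, y)
            pk.degree_final = "first"
            pairs.append(pk)
        _, kept = fs.filter_cohort(store, recs, kin_pairs=pairs)
        assert kept == ["b"]

    def test_all_filtered_errors(self):
        panel, store = self._store()
        store.pseudohap[:] = MISSING
        recs = [IndividualRecord(id=x, coverage=1.0) for x in "abc"]
        with pytest.raises(ValueError, match="all individuals"):
            fs.filter_cohort(store, recs)


class TestWithinGroupDiversity:
    def _sim(self, f_group, seed, n=6):
        g = sd.AdmixtureGraphSpec(
            nodes=["R", "O", "G"], edges={"O": ("R", 0.2),
                                          "G": ("R", f_group)})
        freqs, panel = sd.simulate_graph_frequencies(g, 8000, seed)
        members = [sd.PedigreeMember(f"g{i}", "M") for i in range(n)]
        truth = sd.gene_drop(sd.PedigreeSpec(members), {"POP": freqs["G"]},
                             panel, seed + 1)
        store = truth.diploid_store()
        blocks = fs.block_assignment(store.panel)
        return store, freqs["O"], blocks

    def test_relative_pairs_excluded(self):
        store, of, blocks = self._sim(0.05, 60)
        members = store.individuals
        df = fs.within_group_diversity(store, members, of, blocks,
                                       relative_pairs=[("g0", "g1")],
                                       use="diploid")
        listed = {frozenset((r.id1, r.id2)) for r in df.itertuples()}
        assert frozenset(("g0", "g1")) not in listed
        assert len(df) == 14

    def test_too_few_individuals_error(self):
        store, of, blocks = self._sim(0.05, 61)
        with pytest.raises(ValueError, match="eligible"):
            fs.within_group_diversity(store, ["g0", "g1"], of, blocks,
                                      relative_pairs=[("g0", "g1")])

    def test_bottleneck_lowers_one_minus_f3(self):
        # strong drift (bottleneck) -> more shared drift -> lower 1-f3
        lo_div, of, blocks = self._sim(0.25, 62)
        hi_div, of2, blocks2 = self._sim(0.02, 62)
        d_lo = fs.diversity_summary(fs.within_group_diversity(
            lo_div, lo_div.individuals, of, blocks, use="diploid"))
        d_hi = fs.diversity_summary(fs.within_group_diversity(
            hi_div, hi_div.individuals, of2, blocks2, use="diploid"))
        assert d_lo["median"] < d_hi["median"]


def test_patrilocality_focal_excluded_from_site_term():
    """The focal individual never contributes to its own site frequency."""
    g = sd.AdmixtureGraphSpec(nodes=["R", "O", "P"],
                              edges={"O": ("R", 0.2), "P": ("R", 0.05)})
    freqs, panel = sd.simulate_graph_frequencies(g, 4000, 70)
    members = [sd.PedigreeMember(f"s{i}", "M" if i % 2 else "F")
               for i in range(4)]
    members += [sd.PedigreeMember(f"t{i}", "M") for i in range(3)]
    truth = sd.gene_drop(sd.PedigreeSpec(members), {"POP": freqs["P"]},
                         panel, 71)
    store = truth.diploid_store()
    blocks = fs.block_assignment(store.panel)
    records = [IndividualRecord(id=f"s{i}",
                                genetic_sex="XY" if i % 2 else "XX",
                                group="SITE") for i in range(4)]
    records += [IndividualRecord(id=f"t{i}", genetic_sex="XY", group="TC")
                for i in range(3)]
    df, summary = fs.patrilocality_dtest(
        store, records, "SITE", freqs["O"], [f"t{i}" for i in range(3)],
        blocks, use="diploid")
    assert set(df["id"]) == {f"s{i}" for i in range(4)}
    # excluding all of a focal's site-mates leaves it out of the table
    rel = [("s0", x) for x in ("s1", "s2", "s3")]
    df2, _ = fs.patrilocality_dtest(
        store, records, "SITE", freqs["O"], [f"t{i}" for i in range(3)],
        blocks, relative_pairs=rel, use="diploid")
    assert "s0" not in set(df2["id"])
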