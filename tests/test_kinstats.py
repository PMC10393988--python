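import numpy as np
import pytest

from paleokin import genocall as gc
from paleokin import kinstats as ks
from paleokin import simdata as sd
from paleokin.core import MISSING


class TestReadP0:
    def test_identical_vectors_zero(self):
        h = np.array([0, 1, 0, 1, 1], dtype=np.int8)
        p0, _, n = ks.read_p0(h, h.copy(), np.arange(5) * 1000)
        assert p0 == 0.0 and n == 5

    def test_complementary_vectors_one(self):
        h = np.array([0, 1, 0, 1], dtype=np.int8)
        p0, _, _ = ks.read_p0(h, 1 - h, np.arange(4) * 1000)
        assert p0 == 1.0

    def test_missing_excluded_from_overlap(self):
        h1 = np.array([0, MISSING, 1], dtype=np.int8)
        h2 = np.array([0, 1, 0], dtype=np.int8)
        p0, _, n = ks.read_p0(h1, h2, np.arange(3) * 10)
        assert n == 2 and p0 == 0.5

    def test_zero_overlap_missing(self):
        h1 = np.full(3, MISSING, dtype=np.int8)
        p0, wins, n = ks.read_p0(h1, h1, np.arange(3))
        assert n == 0 and np.isnan(p0)

    def test_self_pair_half_of_unrelated(self, pop_freqs):
        # two pseudo-haploid samplings of one individual mismatch at half
        # the rate of an unrelated pair (phi = 0.5)
        freqs, panel = pop_freqs
        members = [sd.PedigreeMember(x, "M") for x in ("a", "b")]
        truth = sd.gene_drop(sd.PedigreeSpec(members), {"POP": freqs["POP"]},
                             panel, 3)
        # two independent sequencing runs of the same library
        spec1 = sd.SequencingSpec(mean_depth=5, seed=4, base_error=0.0,
                                  deamination_rate=0.0)
        spec2 = sd.SequencingSpec(mean_depth=5, seed=5, base_error=0.0,
                                  deamination_rate=0.0)
        piles1 = sd.sequence(truth, spec1)
        piles2 = sd.sequence(truth, spec2)
        maf = np.minimum(freqs["POP"], 1 - freqs["POP"]) >= 0.1
        h_a1 = gc.pseudohaploid_all(piles1["a"], 1, "a")[maf]
        h_a2 = gc.pseudohaploid_all(piles2["a"], 2, "a")[maf]
        h_b = gc.pseudohaploid_all(piles1["b"], 1, "b")[maf]
        pos = panel.pos[maf]
        p0_self, _, _ = ks.read_p0(h_a1, h_a2, pos)
        p0_unrel, _, _ = ks.read_p0(h_a1, h_b, pos)
        assert p0_self / p0_unrel == pytest.approx(0.5, abs=0.06)


class TestClassifyRead:
    @pytest.mark.parametrize("pn,expected", [
        (0.60, "identical"), (0.624, "identical"), (0.63, "first"),
        (0.80, "first"), (0.82, "second"), (0.90, "second"),
        (0.91, "unrelated"), (1.0, "unrelated")])
    def test_cutoffs(self, pn, expected):
        raw = {("a", f"u{i}"): 1.0 for i in range(11)}
        raw[("x", "y")] = pn
        out, norm = ks.classify_read(raw)
        assert norm == 1.0
        assert out[("x", "y")][1] == expected

    def test_small_cohort_refused(self):
        with pytest.raises(ValueError, match="normalization"):
            ks.classify_read({("a", "b"): 0.2})

    def test_small_cohort_with_explicit_normalizer(self):
        out, _ = ks.classify_read({("a", "b"): 0.15}, normalizer=0.2)
        assert out[("a", "b")][1] == "first"


class TestIbsStats:
    def test_identical_vectors_king_half(self):
        g = np.array([0, 1, 2, 1, 1, 0], dtype=np.int8)
        st = ks.ibs_stats(g, g.copy())
        assert st["king_theta"] == pytest.approx(0.5)
        assert st["ibs0"] == 0

    def test_parent_offspring_r0_zero(self, family_truth):
        truth, _ = family_truth
        store = truth.diploid_store()
        auto = truth.panel.chrom_class == "autosome"
        st = ks.ibs_stats(store.diploid[store.index_of("mother")][auto],
                          store.diploid[store.index_of("child1")][auto])
        assert st["ibs0"] == 0
        assert st["r0"] == 0.0

    def test_unrelated_king_near_zero(self, family_truth):
        truth, _ = family_truth
        store = truth.diploid_store()
        auto = truth.panel.chrom_class == "autosome"
        st = ks.ibs_stats(store.diploid[store.index_of("mother")][auto],
                          store.diploid[store.index_of("father")][auto])
        assert abs(st["king_theta"]) < 0.02

    def test_no_both_het_r0_missing(self):
        st = ks.ibs_stats(np.array([0, 2], dtype=np.int8),
                          np.array([0, 2], dtype=np.int8))
        assert np.isnan(st["r0"])


class TestMlK:
    def test_same_individual_k2_one(self, family_store):
        store, truth = family_store
        auto = store.panel.chrom_class == "autosome"
        gl = store.gl[store.index_of("mother")][auto]
        q = store.panel.freqs["POP"][auto]
        k, theta, n, _ = ks.ml_k_coefficients(gl, gl.copy(), q)
        assert k[2] > 0.85
        assert theta > 0.43

    def test_parent_offspring_k1(self, family_store):
        store, truth = family_store
        auto = store.panel.chrom_class == "autosome"
        q = store.panel.freqs["POP"][auto]
        k, theta, n, _ = ks.ml_k_coefficients(
            store.gl[store.index_of("mother")][auto],
            store.gl[store.index_of("child1")][auto], q)
        assert abs(k[1] - 1.0) < 0.1
        assert theta == pytest.approx(0.25, abs=0.03)

    def test_unrelated_k0(self, family_store):
        store, truth = family_store
        auto = store.panel.chrom_class == "autosome"
        q = store.panel.freqs["POP"][auto]
        k, theta, _, _ = ks.ml_k_coefficients(
            store.gl[store.index_of("mother")][auto],
            store.gl[store.index_of("father")][auto], q)
        assert abs(k[0] - 1.0) < 0.05

    def test_k_simplex(self, family_store):
        store, _ = family_store
        auto = store.panel.chrom_class == "autosome"
        q = store.panel.freqs["POP"][auto]
        k, _, _, _ = ks.ml_k_coefficients(
            store.gl[store.index_of("child1")][auto],
            store.gl[store.index_of("child2")][auto], q)
        assert k.sum() == pytest.approx(1.0, abs=1e-6)
        assert (k >= 0).all()

    def test_king_and_ml_theta_agree_high_depth(self, pop_freqs):
        freqs, panel = pop_freqs
        truth = sd.gene_drop(sd.nuclear_family(2), {"POP": freqs["POP"]},
                             panel, 17)
        spec = sd.SequencingSpec(mean_depth=25, base_error=0.0,
                                 deamination_rate=0.0, seed=18)
        piles = sd.sequence(truth, spec)
        store = gc.build_store(piles, gc.DamageProfile(), seed=19)
        q = freqs["POP"]
        i, j = store.index_of("child1"), store.index_of("child2")
        _, theta_ml, _, _ = ks.ml_k_coefficients(store.gl[i], store.gl[j], q)
        king = ks.ibs_stats(store.diploid[i], store.diploid[j])["king_theta"]
        assert abs(theta_ml - king) < 0.05


class TestThetaX:
    def test_father_son_low_mother_son_high(self, family_store):
        store, truth = family_store
        isx = store.panel.chrom_class == "X"
        q = store.panel.freqs["POP"][isx]

        def tx(a, b):
            return ks.theta_x(store.gl[store.index_of(a)][isx],
                              store.gl[store.index_of(b)][isx],
                              truth.sex[a], truth.sex[b], q)[0]
        assert tx("father", "child1") < 0.1
        assert tx("mother", "child1") > 0.25

    def test_identical_male_maximal(self, family_store):
        store, truth = family_store
        isx = store.panel.chrom_class == "X"
        q = store.panel.freqs["POP"][isx]
        gl = store.gl[store.index_of("child1")][isx]
        t, _, _ = ks.theta_x(gl, gl.copy(), "M", "M", q)
        assert t > 0.7

    def test_gate_withholds_result(self, family_store):
        store, _ = family_store
        isx = np.flatnonzero(store.panel.chrom_class == "X")[:999]
        q = store.panel.freqs["POP"][isx]
        t, n, gate = ks.theta_x(store.gl[0][isx], store.gl[1][isx],
                                "M", "F", q)
        assert t is None and not gate and n <= 999


class TestConsolidate:
    @pytest.mark.parametrize("read,ml,expect", [
        (("first"), ("first"), ("first", "both_agree", False)),
        (("second"), ("first"), ("first", "ml_priority", True)),
        (("first"), (None), ("first", "read_only", False)),
        ((None), ("second"), ("second", "ml_only", False)),
        ((None), (None), (None, None, False))])
    def test_rules(self, read, ml, expect):
        assert ks.consolidate_degree(read, ml) == expect


def test_p0_monotone_across_degrees_and_depths(pop_freqs):
    """Mean normalized P0 strictly increases identical < first < second <
    unrelated at every tested coverage."""
    freqs, panel = pop_freqs
    members = [sd.PedigreeMember(x, s) for x, s in
               [("A", "F"), ("B", "M"), ("F1", "M"), ("G", "M"), ("H", "F"),
                ("I", "M"), ("J", "F")]]
    members += [sd.PedigreeMember("C", "F", 1), sd.PedigreeMember("D", "M", 1),
                sd.PedigreeMember("E", "M", 2)]
    links = {"C": ("A", "B"), "D": ("A", "B"), "E": ("C", "F1")}
    truth = sd.gene_drop(sd.PedigreeSpec(members, links),
                         {"POP": freqs["POP"]}, panel, 51)
    maf = np.minimum(freqs["POP"], 1 - freqs["POP"]) >= 0.1
    pos = panel.pos[maf]
    for depth in (0.5, 2.0, 10.0):
        spec = sd.SequencingSpec(mean_depth=depth, seed=int(depth * 10) + 1,
                                 deamination_rate=0.1)
        piles = sd.sequence(truth, spec)
        ph = {n: gc.pseudohaploid_all(p, 52, n)[maf]
              for n, p in piles.items()}
        names = list(ph)
        raw = {}
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                raw[(names[i], names[j])] = ks.read_p0(
                    ph[names[i]], ph[names[j]], pos)[0]
        # duplicate sampling of A stands in for the identical pair
        ph_a2 = gc.pseudohaploid_all(piles["A"], 53, "A")[maf]
        identical = ks.read_p0(ph["A"], ph_a2, pos)[0]
        out, norm = ks.classify_read(raw)
        first = np.mean([raw[("A", "C")], raw[("B", "C")], raw[("C", "D")]])
        second = np.mean([raw[("A", "E")], raw[("B", "E")]])
        unrel = np.mean([raw[("G", "H")], raw[("I", "J")], raw[("G", "J")]])
        assert identical / norm < first / norm < second / norm < unrel / norm


def test_pairwise_kinship_pipeline(family_store):
    store, truth = family_store
    pairs = ks.pairwise_kinship(store, "POP", sexes=truth.sex,
                                read_normalizer=None)
    bymap = {tuple(sorted((p.id1, p.id2))): p for p in pairs}
    po = bymap[("child1", "mother")]
    assert po.degree_ml == "first"
    assert po.gate_auto
    assert po.n_overlap_auto > 10_000
    unrel = bymap[("father", "mother")]
    assert unrel.degree_ml == "unrelated"
    # theta consistency between scales
    assert po.theta_auto == pytest.approx(po.k1 / 4 + po.k2 / 2, abs=1e-9)
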