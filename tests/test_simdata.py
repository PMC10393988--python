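import numpy as np
import pytest

from paleokin import simdata as sd


class TestGraphSpec:
    def test_cycle_rejected_naming_cycle(self):
        with pytest.raises(ValueError, match="cycle"):
            sd.AdmixtureGraphSpec(nodes=["A", "B"],
                                  edges={"A": ("B", 0.1), "B": ("A", 0.1)})

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="proportion"):
            sd.AdmixtureGraphSpec(
                nodes=["R", "A", "B", "C"],
                edges={"A": ("R", 0.1), "B": ("R", 0.1)},
                admixture_edges={"C": ("A", "B", 1.5, 0.0)})

    def test_single_root_required(self):
        with pytest.raises(ValueError, match="root"):
            sd.AdmixtureGraphSpec(nodes=["R1", "R2", "A"],
                                  edges={"A": ("R1", 0.1)})


class TestGraphFrequencies:
    def test_zero_drift_gives_identical_frequencies(self):
        g = sd.AdmixtureGraphSpec(nodes=["R", "A", "B"],
                                  edges={"A": ("R", 0.0), "B": ("R", 0.0)})
        freqs, _ = sd.simulate_graph_frequencies(g, 1000, 1)
        assert np.array_equal(freqs["A"], freqs["B"])
        assert np.array_equal(freqs["A"], freqs["R"])

    def test_f2_matches_closed_form_within_3se(self):
        # two leaves with drifts F1, F2: E[f2] = (F1+F2) E[p(1-p)] at root
        g = sd.AdmixtureGraphSpec(nodes=["R", "A", "B"],
                                  edges={"A": ("R", 0.02), "B": ("R", 0.03)})
        n = 20_000
        freqs, _ = sd.simulate_graph_frequencies(g, n, 5)
        d2 = (freqs["A"] - freqs["B"]) ** 2
        se = d2.std(ddof=1) / np.sqrt(n)
        assert abs(d2.mean() - sd.expected_f2(g, "A", "B")) < 3 * se

    def test_degenerate_admixture_copies_source(self):
        g = sd.AdmixtureGraphSpec(
            nodes=["R", "A", "B", "C"],
            edges={"A": ("R", 0.05), "B": ("R", 0.05)},
            admixture_edges={"C": ("A", "B", 1.0, 0.0)})
        freqs, _ = sd.simulate_graph_frequencies(g, 500, 9)
        assert np.array_equal(freqs["C"], freqs["A"])

    def test_same_seed_bit_identical(self):
        g = sd.AdmixtureGraphSpec(nodes=["R", "A"], edges={"A": ("R", 0.1)})
        f1, _ = sd.simulate_graph_frequencies(g, 200, 3)
        f2, _ = sd.simulate_graph_frequencies(g, 200, 3)
        assert all(np.array_equal(f1[k], f2[k]) for k in f1)

    def test_expected_moments_admixture_linearity(self):
        # f4 that measures A-side drift shared by the admixed child scales
        # with alpha
        def graph(alpha):
            return sd.AdmixtureGraphSpec(
                nodes=["R", "O", "A", "A2", "B", "C"],
                edges={"O": ("R", 0.1), "A": ("R", 0.05), "A2": ("A", 0.01),
                       "B": ("R", 0.05)},
                admixture_edges={"C": ("A2", "B", alpha, 0.0)})
        f_half = sd.expected_f4(graph(0.5), "O", "C", "O", "A2")
        f_zero = sd.expected_f4(graph(0.0), "O", "C", "O", "A2")
        f_one = sd.expected_f4(graph(1.0), "O", "C", "O", "A2")
        assert f_half == pytest.approx((f_zero + f_one) / 2, rel=1e-12)


class TestGeneDrop:
    def test_parent_offspring_no_opposite_homozygotes(self, family_truth):
        truth, _ = family_truth
        store = truth.diploid_store()
        auto = truth.panel.chrom_class == "autosome"
        g1 = store.diploid[store.index_of("mother")][auto]
        g2 = store.diploid[store.index_of("child1")][auto]
        assert (np.abs(g1.astype(int) - g2.astype(int)) == 2).sum() == 0

    def test_uniparental_transmission(self, family_truth):
        truth, _ = family_truth
        assert truth.y_label["child1"] == truth.y_label["father"]
        assert truth.mito["child1"] == truth.mito["mother"]
        assert truth.y_label["child2"] is None  # daughter

    def test_sibling_realized_k2_near_quarter(self, pop_freqs):
        freqs, panel = pop_freqs
        big = sd.make_panel(50_000, 123)
        g = sd.AdmixtureGraphSpec(nodes=["R", "POP"],
                                  edges={"POP": ("R", 0.05)})
        f, big = sd.simulate_graph_frequencies(g, 50_000, 124, panel=big)
        truth = sd.gene_drop(sd.nuclear_family(2), {"POP": f["POP"]}, big, 7)
        k0, k1, k2 = truth.realized_ibd("child1", "child2")
        assert abs(k2 - 0.25) < 0.05
        assert abs(k1 - 0.5) < 0.05

    def test_missing_parent_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            sd.PedigreeSpec(
                members=[sd.PedigreeMember("kid", "M", 1)],
                parent_links={"kid": ("mom", "dad")})

    def test_father_sex_enforced(self):
        with pytest.raises(ValueError, match="father"):
            sd.PedigreeSpec(
                members=[sd.PedigreeMember("kid", "M", 1),
                         sd.PedigreeMember("mom", "F"),
                         sd.PedigreeMember("dad", "F")],
                parent_links={"kid": ("mom", "dad")})

    def test_founder_frequencies_converge(self):
        # law of large numbers: founder allele frequencies approach input
        g = sd.AdmixtureGraphSpec(nodes=["R", "POP"],
                                  edges={"POP": ("R", 0.05)})
        f, panel = sd.simulate_graph_frequencies(g, 300, 42)
        members = [sd.PedigreeMember(f"f{i}", "M") for i in range(500)]
        truth = sd.gene_drop(sd.PedigreeSpec(members), {"POP": f["POP"]},
                             panel, 43)
        realized = truth.auto_alleles.mean(axis=(0, 1))
        p = f["POP"]
        se = np.sqrt(p * (1 - p) / (2 * 500))
        frac_in = (np.abs(realized - p) <= 3 * se).mean()
        assert frac_in > 0.99 - 3 * np.sqrt(0.01 * 0.99 / 300)

    def test_x_transmission_father_daughter(self, family_truth):
        truth, _ = family_truth
        # daughters carry the father's X verbatim in one copy
        fi = truth.index_of("father")
        di = truth.index_of("child2")
        assert np.array_equal(truth.x_ids[di, 1], truth.x_ids[fi, 0])
        # sons never carry paternal X
        si = truth.index_of("child1")
        assert not np.intersect1d(truth.x_ids[si].ravel(),
                                  truth.x_ids[fi, 0]).size

    def test_same_seed_bit_identical(self, pop_freqs):
        freqs, panel = pop_freqs
        t1 = sd.gene_drop(sd.nuclear_family(), {"POP": freqs["POP"]}, panel, 3)
        t2 = sd.gene_drop(sd.nuclear_family(), {"POP": freqs["POP"]}, panel, 3)
        assert np.array_equal(t1.auto_alleles, t2.auto_alleles)
        assert np.array_equal(t1.auto_ids, t2.auto_ids)


class TestSequence:
    def _truth(self, pop_freqs, n=2000):
        freqs, panel = pop_freqs
        sub = panel.subset(np.arange(n))
        return sd.gene_drop(sd.nuclear_family(1),
                            {"POP": freqs["POP"][:n]}, sub, 5)

    def test_tiny_depth_mostly_empty(self, pop_freqs):
        truth = self._truth(pop_freqs)
        piles = sd.sequence(truth, sd.SequencingSpec(mean_depth=1e-4, seed=1))
        assert (piles["mother"].counts == 0).mean() >= 0.999

    def test_noiseless_consensus_equals_truth(self, pop_freqs):
        truth = self._truth(pop_freqs)
        spec = sd.SequencingSpec(mean_depth=30, base_error=0.0,
                                 deamination_rate=0.0, seed=2)
        piles = sd.sequence(truth, spec)
        store = truth.diploid_store()
        p = piles["mother"]
        dip = store.diploid[store.index_of("mother")]
        panel = truth.panel
        for i in range(200):
            reads = p.pileup(i)
            if not reads:
                continue
            alt = sum(b == panel.a2[i] for b, _, _ in reads) / len(reads)
            expected = dip[i] / 2.0
            assert abs(alt - expected) < 0.5 or len(reads) < 4

    def test_terminal_deamination_rate(self, pop_freqs):
        freqs, panel = pop_freqs
        n = panel.n_sites
        cc_sites = np.flatnonzero((panel.a1 == "C") & (panel.a2 == "T"))
        truth = self._truth(pop_freqs, n=2000)
        spec = sd.SequencingSpec(mean_depth=10, base_error=0.0,
                                 deamination_rate=0.3, seed=3)
        piles = sd.sequence(truth, spec)
        p = piles["father"]
        store = truth.diploid_store()
        dip = store.diploid[store.index_of("father")]
        t_term = n_term = 0
        for i in cc_sites[cc_sites < 2000]:
            if dip[i] != 0:       # want true CC at C/T sites
                continue
            for b, _, d in p.pileup(i):
                if d == 1:
                    n_term += 1
                    t_term += b == "T"
        assert n_term > 200
        rate = t_term / n_term
        assert abs(rate - 0.3) < 3 * np.sqrt(0.3 * 0.7 / n_term)

    def test_zero_depth_sites_yield_empty_pileups(self, pop_freqs):
        truth = self._truth(pop_freqs)
        piles = sd.sequence(truth, sd.SequencingSpec(mean_depth=0.5, seed=4))
        p = piles["child1"]
        i = int(np.flatnonzero(p.counts == 0)[0])
        assert p.pileup(i) == []

    def test_same_seed_bit_identical(self, pop_freqs):
        truth = self._truth(pop_freqs)
        s = sd.SequencingSpec(mean_depth=2, seed=9)
        p1 = sd.sequence(truth, s)["mother"]
        p2 = sd.sequence(truth, s)["mother"]
        assert np.array_equal(p1.base, p2.base)
        assert np.array_equal(p1.dist, p2.dist)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            sd.SequencingSpec(base_error=1.5)
        with pytest.raises(ValueError):
            sd.SequencingSpec(mean_depth=0.0)


def test_null_graph_f4_z_scores(two_pop_graph):
    """With all drift zero every f4 is exactly 0 (degenerate null)."""
    from paleokin import fstats as fs
    g = sd.AdmixtureGraphSpec(nodes=["R", "A", "B", "C", "D"],
                              edges={x: ("R", 0.0) for x in "ABCD"})
    freqs, panel = sd.simulate_graph_frequencies(g, 2000, 8)
    blocks = fs.block_assignment(panel)
    r = fs.f4(freqs["A"], freqs["B"], freqs["C"], freqs["D"], blocks)
    assert r.estimate == 0.0


class TestTruthFilesAndConfig:
    def test_graph_spec_round_trip(self, two_pop_graph, tmp_path):
        from paleokin.simdata import read_graph_spec, write_graph_spec
        g = sd.AdmixtureGraphSpec(
            nodes=["R", "A", "B", "C"],
            edges={"A": ("R", 0.1), "B": ("R", 0.2)},
            admixture_edges={"C": ("A", "B", 0.3, 0.01)})
        write_graph_spec(tmp_path / "g.yaml", g)
        back = read_graph_spec(tmp_path / "g.yaml")
        assert back.edges == g.edges
        assert back.admixture_edges["C"] == ("A", "B", 0.3, 0.01)
        f1, _ = sd.simulate_graph_frequencies(g, 100, 1)
        f2, _ = sd.simulate_graph_frequencies(back, 100, 1)
        assert all(np.array_equal(f1[k], f2[k]) for k in f1)

    def test_truth_files_written(self, family_truth, tmp_path):
        import pandas as pd
        from paleokin.simdata import write_truth_files
        truth, ped = family_truth
        write_truth_files(tmp_path / "t", truth, ped)
        peddf = pd.read_csv(tmp_path / "t.pedigree.tsv", sep="\t")
        assert set(peddf["id"]) == {m.id for m in ped.members}
        ibd = pd.read_csv(tmp_path / "t.realized_ibd.tsv", sep="\t")
        po = ibd[(ibd.id1 == "mother") & (ibd.id2 == "child1")]
        assert float(po["k1"].iloc[0]) == 1.0
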