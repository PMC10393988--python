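"""End-to-end benchmark scenarios on synthetic truth.

Each function builds a cohort with the synthetic-data generator, runs the
relevant pipeline stage, and returns summary metrics against the known
truth. They power both the validation test suite and the reproduction
script; problem sizes are chosen so every scenario runs in seconds to a
few minutes on one core.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import fstats as fs
from . import genocall as gc
from . import kinstats as ks
from . import pedigree as pg
from . import qpadm as qa
from . import simdata as sd
from . import ylineage as yl
from .core import IndividualRecord


def demo_admixture_graph(alpha: float = 0.3) -> sd.AdmixtureGraphSpec:
    """Six analysis populations: outgroup, two sources with sister
    populations (usable as differential rights), one steppe-like
    population, and an admixed target."""
    return sd.AdmixtureGraphSpec(
        nodes=["R", "O", "E", "WH", "WHG", "WHG2", "AH", "AN", "AN2",
               "YAM", "TC"],
        edges={"O": ("R", 0.2), "E": ("R", 0.02), "WH": ("E", 0.05),
               "WHG": ("WH", 0.03), "WHG2": ("WH", 0.03),
               "AH": ("E", 0.04), "AN": ("AH", 0.03), "AN2": ("AH", 0.03),
               "YAM": ("E", 0.08)},
        admixture_edges={"TC": ("WHG", "AN", alpha, 0.01)})


DEMO_RIGHTS = ["O", "WHG2", "AN2", "YAM"]


# ---------------------------------------------------------------------------
# f4 vs path-overlap expectation
# ---------------------------------------------------------------------------

def f4_graph_expectation_check(n_sites: int = 50_000, seed: int = 0) -> dict:
    """Estimate every 4-population f4 among the six analysis populations
    and compare with the closed-form graph expectation.

    Returns the fraction of statistics within 3 jackknife SEs of their
    expectation, plus the worst |z-to-expectation|.
    """
    import itertools
    g = demo_admixture_graph()
    freqs, panel = sd.simulate_graph_frequencies(g, n_sites, seed)
    blocks = fs.block_assignment(panel)
    pops = ["O", "WHG", "AN", "WHG2", "AN2", "YAM"]
    n_ok = n_tot = 0
    worst = 0.0
    for quad in itertools.combinations(pops, 4):
        for w, x, y, z in (quad, (quad[0], quad[2], quad[1], quad[3]),
                           (quad[0], quad[3], quad[1], quad[2])):
            r = fs.f4(freqs[w], freqs[x], freqs[y], freqs[z], blocks)
            exp = sd.expected_f4(g, w, x, y, z)
            zdev = abs(r.estimate - exp) / r.se
            worst = max(worst, zdev)
            n_ok += zdev <= 3
            n_tot += 1
    return {"frac_within_3se": n_ok / n_tot, "n_stats": n_tot,
            "worst_z_dev": worst, "n_sites": n_sites}


# ---------------------------------------------------------------------------
# qpAdm recovery
# ---------------------------------------------------------------------------

def qpadm_recovery(n_reps: int = 20, n_sites: int = 50_000,
                   seed: int = 0, alpha: float = 0.3) -> dict:
    """Two-way admixture recovery and the nested/wrong-model rules."""
    g = demo_admixture_graph(alpha)
    alpha_hat, true_pass, wrong_fail = [], 0, 0
    for rep in range(n_reps):
        freqs, panel = sd.simulate_graph_frequencies(
            g, n_sites, seed + 1000 * rep)
        blocks = fs.block_assignment(panel)
        m = qa.fit_weights("TC", ["WHG", "AN"], DEMO_RIGHTS, freqs, blocks)
        qa.nested_rule(m, freqs, blocks)
        alpha_hat.append(float(m.weights[0]))
        true_pass += m.plausible
        wrong = qa.fit_weights("TC", ["YAM"], DEMO_RIGHTS, freqs, blocks)
        wrong_fail += wrong.p_value < 0.05
    alpha_hat = np.array(alpha_hat)
    return {"alpha_true": alpha,
            "alpha_hat_mean": float(alpha_hat.mean()),
            "alpha_abs_err_max": float(np.abs(alpha_hat - alpha).max()),
            "true_model_pass_frac": true_pass / n_reps,
            "wrong_model_fail_frac": wrong_fail / n_reps,
            "n_reps": n_reps}


# ---------------------------------------------------------------------------
# Kinship recovery
# ---------------------------------------------------------------------------

_KIN_TRUTH = {
    ("A", "C"): "first", ("A", "D"): "first", ("B", "C"): "first",
    ("B", "D"): "first", ("C", "D"): "first", ("C", "E"): "first",
    ("F1", "E"): "first",
    ("A", "E"): "second", ("B", "E"): "second", ("D", "E"): "second",
    ("A", "B"): "unrelated", ("A", "F1"): "unrelated",
    ("A", "G"): "unrelated", ("G", "H"): "unrelated",
    ("B", "H"): "unrelated",
}


def _kin_pedigree() -> sd.PedigreeSpec:
    """Parents A,B; sibling children C,D; grandchild E (via C and F1);
    unrelated G,H."""
    members = [sd.PedigreeMember(x, s) for x, s in
               [("A", "F"), ("B", "M"), ("F1", "M"), ("G", "M"), ("H", "F")]]
    members += [sd.PedigreeMember("C", "F", 1), sd.PedigreeMember("D", "M", 1),
                sd.PedigreeMember("E", "M", 2)]
    return sd.PedigreeSpec(members, {"C": ("A", "B"), "D": ("A", "B"),
                                     "E": ("C", "F1")})


def kinship_recovery(n_reps: int = 20, n_sites: int = 135_000,
                     depth: float = 1.2, seed: int = 0) -> dict:
    """Mismatch-rate classification of PO/sib/2nd/unrelated dyads from
    pseudo-haploid data, plus ML k1 for a parent-offspring pair.

    Coverage is set so each dyad overlaps at >= ~50k MAF-filtered sites.
    Also reports the P0 ordering (identical < first < second < unrelated
    in every replicate).
    """
    g = sd.AdmixtureGraphSpec(nodes=["R", "POP"], edges={"POP": ("R", 0.06)})
    ped = _kin_pedigree()
    correct = {"first": 0, "second": 0, "unrelated": 0}
    total = {"first": 0, "second": 0, "unrelated": 0}
    identical_correct = 0
    k1_errors = []
    monotone = 0
    min_overlap = np.inf
    for rep in range(n_reps):
        base = seed + 10_000 * rep
        freqs, panel = sd.simulate_graph_frequencies(g, n_sites, base)
        truth = sd.gene_drop(ped, {"POP": freqs["POP"]}, panel, base + 1)
        spec = sd.SequencingSpec(mean_depth=depth, base_error=0.002,
                                 deamination_rate=0.15, seed=base + 2)
        piles = sd.sequence(truth, spec)
        maf = np.minimum(freqs["POP"], 1 - freqs["POP"]) >= 0.1
        pos = panel.pos[maf]
        ph = {n: gc.pseudohaploid_all(p, base + 3, n)[maf]
              for n, p in piles.items()}
        names = sorted(ph)
        raw = {}
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                p0, _, nov = ks.read_p0(ph[names[i]], ph[names[j]], pos)
                raw[(names[i], names[j])] = p0
                min_overlap = min(min_overlap, nov)
        out, norm = ks.classify_read(raw)
        for key, want in _KIN_TRUTH.items():
            k = key if key in out else (key[1], key[0])
            total[want] += 1
            correct[want] += out[k][1] == want
        # identical: the same individual sequenced twice, independently
        spec2 = sd.SequencingSpec(mean_depth=depth, base_error=0.002,
                                  deamination_rate=0.15, seed=base + 4)
        piles2 = sd.sequence(truth, spec2)
        ph_a2 = gc.pseudohaploid_all(piles2["A"], base + 5, "A")[maf]
        p0_id, _, _ = ks.read_p0(ph["A"], ph_a2, pos)
        identical_correct += p0_id / norm < ks.P0_CUT_IDENTICAL
        first_m = np.mean([raw[k if k in raw else (k[1], k[0])]
                           for k, v in _KIN_TRUTH.items() if v == "first"])
        second_m = np.mean([raw[k if k in raw else (k[1], k[0])]
                            for k, v in _KIN_TRUTH.items() if v == "second"])
        unrel_m = np.mean([raw[k if k in raw else (k[1], k[0])]
                           for k, v in _KIN_TRUTH.items() if v == "unrelated"])
        monotone += p0_id < first_m < second_m < unrel_m
        # ML k1 on a deeper-coverage parent-offspring pair
        sub = panel.subset(np.arange(30_000))
        truth_po = sd.gene_drop(
            sd.PedigreeSpec([sd.PedigreeMember("P", "F"),
                             sd.PedigreeMember("Q", "M"),
                             sd.PedigreeMember("K", "M", 1)],
                            {"K": ("P", "Q")}),
            {"POP": freqs["POP"][:30_000]}, sub, base + 6)
        piles_po = sd.sequence(truth_po, sd.SequencingSpec(
            mean_depth=4.0, base_error=0.002, deamination_rate=0.15,
            seed=base + 7))
        store = gc.build_store(piles_po, gc.DamageProfile.terminal(0.15),
                               seed=base + 8)
        k, theta, _, _ = ks.ml_k_coefficients(
            store.gl[store.index_of("P")], store.gl[store.index_of("K")],
            freqs["POP"][:30_000])
        k1_errors.append(abs(float(k[1]) - 1.0))
    return {
        "first_correct_frac": correct["first"] / total["first"],
        "second_correct_frac": correct["second"] / total["second"],
        "unrelated_correct_frac": correct["unrelated"] / total["unrelated"],
        "identical_correct_frac": identical_correct / n_reps,
        "p0_monotone_frac": monotone / n_reps,
        "po_k1_abs_err_max": float(np.max(k1_errors)),
        "po_k1_abs_err_mean": float(np.mean(k1_errors)),
        "min_pair_overlap": int(min_overlap),
        "n_reps": n_reps,
    }


# ---------------------------------------------------------------------------
# Pedigree-engine exactness
# ---------------------------------------------------------------------------

def pedigree_exactness(seed: int = 0, n_sites: int = 50_000,
                       n_x: int = 5_000) -> dict:
    """Reconstruct the canned 4-generation, 12-member pedigree from
    complete error-free evidence and score edge recovery."""
    g = sd.AdmixtureGraphSpec(nodes=["R", "POP"], edges={"POP": ("R", 0.05)})
    freqs, panel = sd.simulate_graph_frequencies(g, n_sites, seed)
    xp = sd.make_panel(n_x, seed + 1, "X", prefix="x")
    xf, xp = sd.simulate_graph_frequencies(g, n_x, seed + 2, panel=xp)
    ped = sd.four_generation_pedigree()
    truth = sd.gene_drop(ped, {"POP": freqs["POP"]}, panel, seed + 3,
                         x_panel=xp, x_freqs={"POP": xf["POP"]})
    pairs, records = sd.perfect_evidence(truth, ped)
    graph = pg.build_pedigree(pairs, records)
    want_parent = {("gm0", "s1"), ("gm0", "s2"), ("gf0", "s1"), ("gf0", "s2"),
                   ("w1", "c1"), ("w1", "c2"), ("s1", "c1"), ("s1", "c2"),
                   ("c2", "d1"), ("c2", "d2"), ("h2", "d1"), ("h2", "d2")}
    want_sib = {frozenset(("s1", "s2")), frozenset(("c1", "c2")),
                frozenset(("d1", "d2"))}
    want_second = {frozenset(p): t for p, t in [
        (("gm0", "c1"), "grandparental"), (("gm0", "c2"), "grandparental"),
        (("gf0", "c1"), "grandparental"), (("gf0", "c2"), "grandparental"),
        (("w1", "d1"), "grandparental"), (("w1", "d2"), "grandparental"),
        (("s1", "d1"), "grandparental"), (("s1", "d2"), "grandparental"),
        (("s2", "c1"), "avuncular"), (("s2", "c2"), "avuncular"),
        (("c1", "d1"), "avuncular"), (("c1", "d2"), "avuncular")]}
    got_parent = graph.parent_of()
    got_sib = {frozenset(p) for p in graph.sibling_pairs()}
    got_second = {frozenset((e.id1, e.id2)): e.subtype
                  for e in graph.second_edges}
    tp = len(want_parent & got_parent) + len(want_sib & got_sib) \
        + sum(got_second.get(k) == v for k, v in want_second.items())
    n_want = len(want_parent) + len(want_sib) + len(want_second)
    n_got = len(got_parent) + len(got_sib) + len(got_second)
    return {"edge_recall": tp / n_want, "edge_precision": tp / n_got,
            "exact": tp == n_want == n_got}


# ---------------------------------------------------------------------------
# Gates and filters
# ---------------------------------------------------------------------------

def gate_filter_checks() -> dict:
    """Deterministic fixtures for every numeric gate and filter."""
    from .core import GenotypeStore, SNPPanel
    from .ioformats import thin_by_distance

    out = {}
    # overlap gates
    pk_lo = ks.PairKinship("a", "b", n_overlap_auto=9_999)
    pk_hi = ks.PairKinship("a", "b", n_overlap_auto=10_000, n_overlap_x=1_000)
    gated = pg.gate_pairs([pk_lo, pk_hi])
    out["overlap_gate_pass"] = len(gated)
    out["x_gate_pass"] = int(pk_hi.gate_x)
    # MAF filter
    panel = SNPPanel([f"s{i}" for i in range(5)], ["1"] * 5, ["autosome"] * 5,
                     np.arange(1, 6) * 1000, ["C"] * 5, ["A"] * 5,
                     {"POP": np.array([0.05, 0.1, 0.5, 0.95, 0.9])})
    out["maf_filter_pass"] = int(panel.maf_mask("POP", 0.1).sum())
    # thinning
    t = SNPPanel(["a", "b", "c", "d"], ["1"] * 4, ["autosome"] * 4,
                 [100, 2000, 2700, 5300], ["C"] * 4, ["A"] * 4)
    out["thin_2500_kept"] = thin_by_distance(t, 2500).n_sites
    # genotyping-fraction + singleton filters
    big = SNPPanel([f"s{i}" for i in range(1000)], ["1"] * 1000,
                   ["autosome"] * 1000, np.arange(1, 1001),
                   ["C"] * 1000, ["A"] * 1000)
    store = GenotypeStore(["lo", "hi", "x2"], big)
    store.pseudohap[:] = 0
    store.pseudohap[0, :151] = -1         # 84.9% genotyped
    store.pseudohap[1, 0] = 1             # singleton variant
    recs = [IndividualRecord(id=x, coverage=1.0) for x in ("lo", "hi", "x2")]
    sub, kept = fs.filter_cohort(store, recs)
    out["individuals_kept_85pct"] = len(kept)
    out["sites_kept_after_singleton"] = sub.panel.n_sites
    # kin-group deduplication
    pkin = ks.PairKinship("hi", "x2")
    pkin.degree_final = "first"
    recs2 = [IndividualRecord(id="hi", coverage=0.5),
             IndividualRecord(id="x2", coverage=0.2)]
    store2 = GenotypeStore(["hi", "x2"], big)
    store2.pseudohap[:] = 0
    _, kept2 = fs.filter_cohort(store2, recs2, kin_pairs=[pkin])
    out["kin_group_kept"] = int(kept2 == ["hi"])
    # QC gates
    out["qc_contamination_fail"] = int(not gc.qc_gate(
        IndividualRecord(id="q", contamination=0.21, terminal_damage=0.3))[0])
    out["qc_damage_fail"] = int(not gc.qc_gate(
        IndividualRecord(id="q", contamination=0.05, terminal_damage=0.24))[0])
    out["qc_pass"] = int(gc.qc_gate(
        IndividualRecord(id="q", contamination=0.05, terminal_damage=0.30))[0])
    return out


# ---------------------------------------------------------------------------
# Y-haplogroup recovery
# ---------------------------------------------------------------------------

def y_recovery(n_reps: int = 100, n_nodes: int = 50, seed: int = 0,
               missing: float = 0.2, damage: float = 0.15,
               low_gq_frac: float = 0.4) -> dict:
    """Haplogroup recovery on a random tree with missingness and
    deamination-style corruption, recoding rules active.

    Transition markers carry low GQ with probability ``low_gq_frac``;
    damaged C/G templates read as T/A (dropped at low-GQ transitions,
    recoded back at T/A-free transversions).
    """
    tree = yl.random_tree(n_nodes, seed=seed)
    rng = np.random.default_rng(seed + 1)
    nodes = list(tree.parent)
    n_ok = 0
    n_recoded_total = 0
    for rep in range(n_reps):
        target = nodes[int(rng.integers(1, len(nodes)))]
        path = set(tree.path_to(target))
        rows = []
        for pos, m in tree.marker_at.items():
            if rng.random() < missing:
                continue
            derived = m.haplogroup in path
            allele = m.derived if derived else m.ancestral
            from .core import mutation_class
            mclass = mutation_class(m.ancestral, m.derived)
            gq = 99
            if mclass == "transition" and rng.random() < low_gq_frac:
                gq = 40
            if allele == "C" and rng.random() < damage and \
                    "T" not in (m.ancestral, m.derived):
                allele = "T"          # recodable transversion damage
            elif allele == "C" and gq < 50 and rng.random() < damage:
                allele = "T"          # dropped by the GQ rule
            elif allele == "G" and rng.random() < damage and \
                    "A" not in (m.ancestral, m.derived):
                allele = "A"
            rows.append({"position": pos, "allele": allele, "gq": gq})
        usable = yl.recode_y_calls(pd.DataFrame(rows), tree)
        n_recoded_total += int(usable["recoded"].sum()) if len(usable) else 0
        a = yl.assign_haplogroup(usable, tree)
        n_ok += a.haplogroup == target
    return {"recovery_frac": n_ok / n_reps, "n_reps": n_reps,
            "n_recoded_calls": n_recoded_total}


# ---------------------------------------------------------------------------
# Sex-biased admixture and patrilocality
# ---------------------------------------------------------------------------

def _sexbias_graph():
    return sd.AdmixtureGraphSpec(
        nodes=["R", "O", "E", "HH", "HG", "HGp", "FF", "FA", "FAp",
               "Ep1", "Ep2"],
        edges={"O": ("R", 0.2), "E": ("R", 0.02), "HH": ("E", 0.06),
               "HG": ("HH", 0.02), "HGp": ("HH", 0.02), "FF": ("E", 0.05),
               "FA": ("FF", 0.02), "FAp": ("FF", 0.02), "Ep1": ("E", 0.04),
               "Ep2": ("E", 0.05)})


def sexbias_contrast(seed: int, biased: bool = True, n_fam: int = 12,
                     n_part: int = 8, n_auto: int = 20_000,
                     n_x: int = 6_000) -> pd.DataFrame:
    """F1 cohort from hunter-gatherer fathers and farmer mothers (or
    sex-balanced founders), contrasted on autosomes vs X against
    partner panels."""
    g = _sexbias_graph()
    freqs, panel = sd.simulate_graph_frequencies(g, n_auto, seed)
    xp = sd.make_panel(n_x, seed + 1000, "X", prefix="x")
    xf, xp = sd.simulate_graph_frequencies(g, n_x, seed + 2000, panel=xp)
    members, links, fpop = [], {}, {}
    for k in range(n_fam):
        f, m, c = f"fa{k}", f"mo{k}", f"ch{k}"
        members += [sd.PedigreeMember(f, "M"), sd.PedigreeMember(m, "F"),
                    sd.PedigreeMember(c, "M" if k % 2 == 0 else "F", 1)]
        links[c] = (m, f)
        if biased:
            fpop[f], fpop[m] = "HG", "FA"
        else:
            fpop[f] = fpop[m] = "HG" if k % 2 == 0 else "FA"
    parts = {}
    for pname in ("HGp", "FAp", "Ep1", "Ep2"):
        ids = []
        for k in range(n_part):
            i = f"{pname}_{k}"
            members.append(sd.PedigreeMember(i, "M" if k % 2 else "F"))
            fpop[i] = pname
            ids.append(i)
        parts[pname] = ids
    ped = sd.PedigreeSpec(members, links, founder_population=fpop)
    truth = sd.gene_drop(ped, freqs, panel, seed + 3000,
                         x_panel=xp, x_freqs=xf)
    store = truth.diploid_store()
    auto_mask = store.panel.chrom_class == "autosome"
    auto_store = store.subset_sites(auto_mask)
    x_store = store.subset_sites(~auto_mask)
    children = [f"ch{k}" for k in range(n_fam)]
    return fs.x_autosome_contrast(
        auto_store, x_store, children, parts, "O",
        fs.block_assignment(auto_store.panel),
        fs.block_assignment(x_store.panel), use="diploid")


def sexbias_recovery(n_reps: int = 20, seed: int = 0) -> dict:
    pos = 0
    null_scores = []
    for rep in range(n_reps):
        df = sd_seed = seed + rep * 17 + 3
        df = sexbias_contrast(sd_seed, biased=True)
        pos += float(df[df.partner == "HGp"]["deviation_score"].iloc[0]) > 0
        df0 = sexbias_contrast(sd_seed + 9_000_000, biased=False)
        null_scores.append(
            float(df0[df0.partner == "HGp"]["deviation_score"].iloc[0]))
    return {"hg_residual_positive_frac": pos / n_reps,
            "null_residual_mean": float(np.mean(null_scores)),
            "n_reps": n_reps}


def patrilocal_site(seed: int, n_auto: int = 20_000, n_other: int = 12,
                    exogamous: bool = False):
    """A three-generation patriline with married-in wives, embedded in a
    wider cohort; returns the per-individual site-affinity D table, the
    per-sex summary and haplotype diversities."""
    g = sd.AdmixtureGraphSpec(nodes=["R", "O", "POP"],
                              edges={"O": ("R", 0.2), "POP": ("R", 0.06)})
    freqs, panel = sd.simulate_graph_frequencies(g, n_auto, seed)
    members = [sd.PedigreeMember("F0", "M"), sd.PedigreeMember("M0", "F")]
    links, fpop = {}, {"F0": "POP", "M0": "POP"}
    mito = {"M0": "mt0"}
    ylab = {"F0": "Y_pat"}
    for s in range(3):
        sid, wid = f"S{s}", f"W{s}"
        members += [sd.PedigreeMember(sid, "M", 1),
                    sd.PedigreeMember(wid, "F", 1)]
        links[sid] = ("M0", "F0")
        fpop[wid] = "POP"
        mito[wid] = f"mtW{s}"
        for c in range(2):
            gid = f"G{s}{c}"
            members.append(sd.PedigreeMember(gid, "M", 2))
            links[gid] = (wid, sid)
    others = []
    for k in range(n_other):
        oid = f"T{k}"
        members.append(sd.PedigreeMember(oid, "M" if k % 2 else "F"))
        fpop[oid] = "POP"
        mito[oid] = f"mtT{k}"
        if k % 2:
            ylab[oid] = f"Y_T{k}"
        others.append(oid)
    for k in range(8):
        oid = f"O{k}"
        members.append(sd.PedigreeMember(oid, "F"))
        fpop[oid] = "O"
    ped = sd.PedigreeSpec(members, links, mito_lineage=mito,
                          y_lineage=ylab, founder_population=fpop)
    truth = sd.gene_drop(ped, freqs, panel, seed + 1)
    store = truth.diploid_store()
    blocks = fs.block_assignment(store.panel)
    site = (["F0", "M0"] + [f"S{s}" for s in range(3)]
            + [f"W{s}" for s in range(3)]
            + [f"G{s}{c}" for s in range(3) for c in range(2)])
    if exogamous:
        # scramble residence: site membership is unrelated to the pedigree
        rng = np.random.default_rng(seed + 2)
        pool = site + others
        site = sorted(rng.choice(pool, size=len(site), replace=False))
        others = [x for x in pool if x not in site]
    records = []
    for m in ped.members:
        if m.id.startswith("O"):
            continue
        records.append(IndividualRecord(
            id=m.id, genetic_sex="XY" if ped.by_id[m.id].sex == "M" else "XX",
            age_class="adult", group="SITE" if m.id in site else "TC",
            mito_haplogroup=truth.mito[m.id],
            y_haplogroup=truth.y_label[m.id]))
    rel = []
    for i in range(len(site)):
        for j in range(i + 1, len(site)):
            k0, k1, k2 = truth.realized_ibd(site[i], site[j])
            if k1 / 4 + k2 / 2 >= 0.0884:
                rel.append((site[i], site[j]))
    ofreq = fs.group_freq(store, [f"O{k}" for k in range(8)], use="diploid")
    df, summary = fs.patrilocality_dtest(store, records, "SITE", ofreq,
                                         others, blocks,
                                         relative_pairs=rel, use="diploid")
    site_recs = [r for r in records if r.group == "SITE"]
    males = [r.y_haplogroup for r in site_recs
             if r.genetic_sex == "XY" and r.y_haplogroup]
    mitos = [r.mito_haplogroup for r in site_recs if r.mito_haplogroup]
    summary["h_y"] = pg.haplotype_diversity(males)
    summary["h_mito"] = pg.haplotype_diversity(mitos)
    return df, summary


def patrilocality_recovery(n_reps: int = 20, seed: int = 0) -> dict:
    male_shift = diversity_ok = 0
    for rep in range(n_reps):
        _, summ = patrilocal_site(seed + 100 + rep * 7)
        male_shift += summ["median_d_XY"] > summ["median_d_XX"]
        diversity_ok += summ["h_y"] < summ["h_mito"]
    return {"male_shifted_frac": male_shift / n_reps,
            "y_lt_mito_diversity_frac": diversity_ok / n_reps,
            "n_reps": n_reps}
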