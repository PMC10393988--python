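"""f3/f4/D statistics with weighted block jackknife, plus the cohort
filters and the affinity / diversity / sex-bias / patrilocality contrasts
built on them.

Estimates are per-site means (f3, f4) or ratios of per-site sums (D),
with standard errors from a delete-one-genomic-block jackknife weighted
by per-block SNP counts (Busing-style). Population allele frequencies
are plain allele-count means — the heterozygosity correction is off by
default, which is the standard choice for pseudo-haploid data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .core import MISSING, GenotypeStore, IndividualRecord, SNPPanel

DEFAULT_BLOCK_SPAN = 5_000_000


@dataclass
class FStatResult:
    kind: str
    labels: tuple
    estimate: float
    se: float
    z: float
    n_snps: int
    n_blocks: int


# ---------------------------------------------------------------------------
# Blocks and jackknife
# ---------------------------------------------------------------------------

def block_assignment(panel: SNPPanel, block_span: int = DEFAULT_BLOCK_SPAN
                     ) -> np.ndarray:
    """Assign every site to a genomic block of `block_span` bp."""
    blocks = np.zeros(panel.n_sites, dtype=np.int64)
    next_block = 0
    for c in dict.fromkeys(panel.chrom):
        m = panel.chrom == c
        local = panel.pos[m] // block_span
        _, inv = np.unique(local, return_inverse=True)
        blocks[m] = inv + next_block
        next_block = blocks[m].max() + 1
    return blocks


def weighted_jackknife(est_full: float, est_loo: np.ndarray,
                       weights: np.ndarray) -> float:
    """Weighted delete-one-block jackknife standard error.

    ``est_loo[j]`` is the estimate with block j removed and
    ``weights[j]`` its SNP count. With equal weights this reduces to the
    classical delete-one jackknife formula.
    """
    m = np.asarray(weights, dtype=float)
    g = len(m)
    n = m.sum()
    h = n / m
    theta_jack = g * est_full - ((1.0 - m / n) * est_loo).sum()
    tau = h * est_full - (h - 1.0) * est_loo
    var = ((tau - theta_jack) ** 2 / (h - 1.0)).sum() / g
    return float(np.sqrt(var))


def _ratio_jackknife(num: np.ndarray, den: np.ndarray, blocks: np.ndarray,
                     kind: str, labels: tuple) -> FStatResult:
    """Jackknife a statistic of the form sum(num)/sum(den) over sites."""
    ok = np.isfinite(num) & np.isfinite(den)
    num, den, blocks = num[ok], den[ok], blocks[ok]
    if len(num) == 0:
        raise ValueError(f"{kind}{labels}: no overlapping polymorphic sites")
    uniq, inv = np.unique(blocks, return_inverse=True)
    nb = len(uniq)
    num_b = np.bincount(inv, weights=num, minlength=nb)
    den_b = np.bincount(inv, weights=den, minlength=nb)
    counts = np.bincount(inv, minlength=nb).astype(float)
    tot_n, tot_d = num_b.sum(), den_b.sum()
    if tot_d == 0:
        raise ValueError(f"{kind}{labels}: zero denominator (no informative sites)")
    est = float(tot_n / tot_d)
    if nb < 2:
        return FStatResult(kind, labels, est, float("nan"), float("nan"),
                           len(num), nb)
    loo_d = tot_d - den_b
    if (loo_d == 0).any():
        raise ValueError(f"{kind}{labels}: a block carries the whole denominator")
    loo = (tot_n - num_b) / loo_d
    se = weighted_jackknife(est, loo, counts)
    z = est / se if se > 0 else float("nan")
    return FStatResult(kind, labels, est, se, z, len(num), nb)


# ---------------------------------------------------------------------------
# Frequencies
# ---------------------------------------------------------------------------

def individual_freq(store: GenotypeStore, name: str,
                    use: str = "pseudohap") -> np.ndarray:
    """One individual's allele2 frequency track (NaN where missing)."""
    i = store.index_of(name)
    if use == "pseudohap":
        h = store.pseudohap[i].astype(float)
        h[store.pseudohap[i] == MISSING] = np.nan
        return h
    d = store.diploid[i].astype(float)
    d[store.diploid[i] == MISSING] = np.nan
    return d / 2.0


def group_freq(store: GenotypeStore, names: Iterable[str],
               use: str = "pseudohap") -> np.ndarray:
    """Allele-count mean frequency over a set of individuals."""
    tracks = np.stack([individual_freq(store, n, use) for n in names])
    with np.errstate(invalid="ignore"):
        return np.nanmean(tracks, axis=0)


# ---------------------------------------------------------------------------
# Core statistics
# ---------------------------------------------------------------------------

def f3(freq_o: np.ndarray, freq_a: np.ndarray, freq_b: np.ndarray,
       blocks: np.ndarray, labels: tuple = ("O", "A", "B"),
       kind: str = "f3_outgroup") -> FStatResult:
    """f3(O; A, B) = mean over sites of (pO - pA)(pO - pB)."""
    num = (freq_o - freq_a) * (freq_o - freq_b)
    den = np.where(np.isfinite(num), 1.0, np.nan)
    return _ratio_jackknife(num, den, blocks, kind, labels)


def f4(freq_w, freq_x, freq_y, freq_z, blocks,
       labels: tuple = ("W", "X", "Y", "Z")) -> FStatResult:
    """f4(W, X; Y, Z) = mean over sites of (pW - pX)(pY - pZ)."""
    num = (freq_w - freq_x) * (freq_y - freq_z)
    den = np.where(np.isfinite(num), 1.0, np.nan)
    return _ratio_jackknife(num, den, blocks, "f4", labels)


def d_stat(freq_w, freq_x, freq_y, freq_z, blocks,
           labels: tuple = ("W", "X", "Y", "Z")) -> FStatResult:
    """D(W, X; Y, Z): the f4 numerator normalized by total heterozygosity.

    D = sum (pW-pX)(pY-pZ) / sum (pW+pX-2 pW pX)(pY+pZ-2 pY pZ).
    """
    num = (freq_w - freq_x) * (freq_y - freq_z)
    den = ((freq_w + freq_x - 2 * freq_w * freq_x)
           * (freq_y + freq_z - 2 * freq_y * freq_z))
    return _ratio_jackknife(num, den, blocks, "D", labels)


# ---------------------------------------------------------------------------
# Cohort filters
# ---------------------------------------------------------------------------

def kin_groups(pairs, max_degree: str = "second") -> list[set[str]]:
    """Connected components of the close-kin graph (degree <= 2nd)."""
    import networkx as nx
    keep = {"identical", "first"}
    if max_degree == "second":
        keep.add("second")
    g = nx.Graph()
    for pk in pairs:
        if pk.degree_final in keep:
            g.add_edge(pk.id1, pk.id2)
    return [set(c) for c in nx.connected_components(g)]


def filter_cohort(store: GenotypeStore, records: Sequence[IndividualRecord],
                  kin_pairs=None, min_genotyped: float = 0.85
                  ) -> tuple[GenotypeStore, list[str]]:
    """The pre-analysis cohort filters.

    Drops individuals genotyped at < 85% of panel sites; keeps only the
    highest-coverage member of each close-kin group; then drops variants
    whose minor allele is observed in exactly one remaining individual.
    """
    recs = {r.id: r for r in records}
    called = store.pseudohap != MISSING
    frac = called.mean(axis=1)
    keep_names = [n for j, n in enumerate(store.individuals)
                  if frac[j] >= min_genotyped]
    if kin_pairs:
        for group in kin_groups(kin_pairs):
            members = [n for n in group if n in keep_names]
            if len(members) > 1:
                best = max(members,
                           key=lambda n: recs[n].coverage if n in recs else 0.0)
                for n in members:
                    if n != best:
                        keep_names.remove(n)
    if not keep_names:
        raise ValueError("all individuals removed by cohort filters")
    sub = store.subset_individuals(keep_names)
    carrier = (sub.pseudohap == 1).sum(axis=0)
    observed = (sub.pseudohap != MISSING).sum(axis=0)
    singleton = (carrier == 1) & (observed > 1)   # variant in one individual
    sub = sub.subset_sites(~singleton)
    return sub, keep_names


# ---------------------------------------------------------------------------
# Diversity, sex bias, patrilocality
# ---------------------------------------------------------------------------

def within_group_diversity(store: GenotypeStore, members: Sequence[str],
                           outgroup_freq: np.ndarray, blocks: np.ndarray,
                           relative_pairs: Iterable[tuple[str, str]] = (),
                           use: str = "pseudohap") -> pd.DataFrame:
    """Distribution of 1 - f3(O; i, j) over non-relative pairs in a group.

    ``relative_pairs`` lists dyads of degree <= 2 to exclude. Higher
    1 - f3 means lower shared drift, i.e. higher within-group diversity.
    """
    excluded = {frozenset(p) for p in relative_pairs}
    eligible = [(a, b) for i, a in enumerate(members)
                for b in members[i + 1:] if frozenset((a, b)) not in excluded]
    if len({m for p in eligible for m in p}) < 2:
        raise ValueError("fewer than 2 eligible individuals after the "
                         "relative filter")
    rows = []
    for a, b in eligible:
        res = f3(outgroup_freq, individual_freq(store, a, use),
                 individual_freq(store, b, use), blocks, labels=("O", a, b),
                 kind="f3_outgroup")
        rows.append({"id1": a, "id2": b, "f3": res.estimate,
                     "one_minus_f3": 1.0 - res.estimate, "se": res.se,
                     "n_snps": res.n_snps})
    return pd.DataFrame(rows)


def diversity_summary(df: pd.DataFrame) -> dict:
    v = df["one_minus_f3"]
    return {"median": float(v.median()),
            "iqr": float(v.quantile(0.75) - v.quantile(0.25)),
            "n_pairs": int(len(v))}


def x_autosome_contrast(auto_store: GenotypeStore, x_store: GenotypeStore,
                        target: Sequence[str] | str,
                        partners: Mapping[str, Sequence[str]],
                        outgroup: str, auto_blocks: np.ndarray,
                        x_blocks: np.ndarray,
                        use: str = "pseudohap") -> pd.DataFrame:
    """Outgroup-f3 on autosomes vs the X for each partner population.

    A positive residual from the cross-partner regression of f3_auto on
    f3_X marks a partner whose affinity to the target is stronger on the
    autosomes — the signature of male-biased gene flow from that source.
    Partners without X data are skipped.
    """
    t_names = [target] if isinstance(target, str) else list(target)
    fa_t = group_freq(auto_store, t_names, use)
    fo_a = group_freq(auto_store, partners[outgroup], use) \
        if outgroup in partners else auto_store.panel.freqs[outgroup]
    fx_t = group_freq(x_store, [n for n in t_names if n in x_store.individuals], use)
    fo_x = group_freq(x_store, partners[outgroup], use) \
        if outgroup in partners else x_store.panel.freqs[outgroup]
    rows = []
    for name, members in partners.items():
        if name == outgroup:
            continue
        try:
            ra = f3(fo_a, fa_t, group_freq(auto_store, members, use),
                    auto_blocks, labels=(outgroup, "target", name))
            rx = f3(fo_x, fx_t,
                    group_freq(x_store,
                               [m for m in members if m in x_store.individuals],
                               use),
                    x_blocks, labels=(outgroup, "target", name))
        except (ValueError, KeyError):
            continue
        rows.append({"partner": name, "f3_auto": ra.estimate, "se_auto": ra.se,
                     "f3_x": rx.estimate, "se_x": rx.se})
    df = pd.DataFrame(rows)
    if len(df) >= 3:
        a = np.vstack([np.ones(len(df)), df["f3_x"]]).T
        coef, *_ = np.linalg.lstsq(a, df["f3_auto"], rcond=None)
        resid = df["f3_auto"] - a @ coef
        sd = resid.std(ddof=1)
        df["residual"] = resid
        df["deviation_score"] = resid / sd if sd > 0 else np.nan
    return df


def patrilocality_dtest(store: GenotypeStore,
                        records: Sequence[IndividualRecord],
                        site_label: str, outgroup_freq: np.ndarray,
                        cohort_members: Sequence[str], blocks: np.ndarray,
                        relative_pairs: Iterable[tuple[str, str]] = (),
                        use: str = "pseudohap") -> tuple[pd.DataFrame, dict]:
    """Per-individual D(O, individual; own-site population, wider cohort).

    The tested individual — and its 1st/2nd-degree relatives — are
    removed from the site-population term (leakage and kin-inflation
    guard). Positive D means the individual clades with its own site.
    Results are summarized per sex with a rank-based two-sided
    comparison of the male and female D distributions.
    """
    recs = {r.id: r for r in records}
    site_members = [r.id for r in records
                    if r.group == site_label and r.id in store.individuals]
    rel = {}
    for a, b in relative_pairs:
        rel.setdefault(a, set()).add(b)
        rel.setdefault(b, set()).add(a)
    others = [n for n in cohort_members
              if n in store.individuals and n not in site_members]
    rows = []
    for name in site_members:
        ref = [m for m in site_members
               if m != name and m not in rel.get(name, ())]
        if not ref or not others:
            continue
        res = d_stat(outgroup_freq, individual_freq(store, name, use),
                     group_freq(store, ref, use), group_freq(store, others, use),
                     blocks, labels=("O", name, site_label, "cohort"))
        # positive when the individual is closer to its own site
        rows.append({"id": name, "sex": recs[name].genetic_sex,
                     "d": -res.estimate, "z": -res.z, "n_snps": res.n_snps})
    df = pd.DataFrame(rows)
    summary: dict = {}
    for sex in ("XY", "XX"):
        sub = df[df["sex"] == sex] if len(df) else df
        if len(sub):
            summary[f"median_d_{sex}"] = float(sub["d"].median())
            summary[f"n_{sex}"] = int(len(sub))
    if summary.get("n_XY", 0) >= 2 and summary.get("n_XX", 0) >= 2:
        stat = mannwhitneyu(df[df["sex"] == "XY"]["d"],
                            df[df["sex"] == "XX"]["d"],
                            alternative="two-sided")
        summary["rank_test_p"] = float(stat.pvalue)
    return df, summary
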