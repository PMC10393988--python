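"""Pairwise relatedness for low-coverage pseudo-haploid and
genotype-likelihood data.

Two complementary estimators, mirroring common ancient-DNA practice:

* a mismatch-rate ("READ"-style) classifier on pseudo-haploid calls —
  the pairwise mismatch fraction P0 is normalized by the cohort median
  (assumed mostly unrelated) and cut at the midpoints between the
  expectations ``1 - phi`` for identical/first/second/unrelated pairs;
* a maximum-likelihood estimator of the IBD-sharing coefficients
  (k0, k1, k2) from genotype likelihoods and reference allele
  frequencies, via EM over the standard non-inbred 9-cell
  joint-genotype table. theta = k1/4 + k2/2.

Plus IBS summaries (R0, R1, KING-robust theta), an X-chromosome kinship
moment estimator, and the conflict-resolution rule that prefers the
likelihood-based call when the two methods disagree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import MISSING, GenotypeStore

# classification cutoffs: midpoints of 1-phi for phi = 0.5, 0.25, 0.125, 0
P0_CUT_IDENTICAL = 0.625
P0_CUT_FIRST = 0.8125
P0_CUT_SECOND = 0.90625

# theta cutoffs at 1/2^(3/2), 1/2^(5/2), 1/2^(7/2) (KING convention)
THETA_CUTS = (0.3536, 0.1768, 0.0884)

AUTO_OVERLAP_GATE = 10_000
X_OVERLAP_GATE = 1_000

DEGREES = ("identical", "first", "second", "unrelated")


@dataclass
class PairKinship:
    """All pairwise evidence for one dyad."""

    id1: str
    id2: str
    n_overlap_auto: int = 0
    n_overlap_x: int = 0
    p0_raw: float = float("nan")
    p0_normalized: float = float("nan")
    p0_windows: list = field(default_factory=list)
    ibs0: int = 0
    ibs1: int = 0
    ibs2: int = 0
    r0: float = float("nan")
    r1: float = float("nan")
    king_theta: float = float("nan")
    k0: float = float("nan")
    k1: float = float("nan")
    k2: float = float("nan")
    theta_auto: float = float("nan")
    theta_x: float = float("nan")
    degree_read: str | None = None
    degree_ml: str | None = None
    degree_final: str | None = None
    degree_source: str | None = None
    conflict: bool = False
    gate_auto: bool = False
    gate_x: bool = False

    @property
    def r2(self) -> float:
        """Alias for KING theta (reported alongside R0/R1)."""
        return self.king_theta


# ---------------------------------------------------------------------------
# READ-style mismatch classifier
# ---------------------------------------------------------------------------

def read_p0(hap1: np.ndarray, hap2: np.ndarray, pos: np.ndarray,
            window: int = 1_000_000):
    """Pairwise mismatch fraction of two pseudo-haploid vectors.

    Returns ``(p0_mean, per_window_p0, n_overlap)`` with the mean taken
    over all overlapping sites and windows formed by genomic span.
    Input vectors must already be restricted to the MAF-filtered panel.
    """
    both = (hap1 != MISSING) & (hap2 != MISSING)
    n = int(both.sum())
    if n == 0:
        return float("nan"), [], 0
    mism = (hap1 != hap2) & both
    p0 = float(mism.sum() / n)
    wins = []
    wid = pos // window
    for w in np.unique(wid):
        m = both & (wid == w)
        cnt = int(m.sum())
        if cnt:
            wins.append(float(mism[m].sum() / cnt))
    return p0, wins, n


def classify_read(p0_raw_by_pair: dict, normalizer: float | None = None):
    """Normalize P0 by the cohort median and classify each pair.

    With fewer than 10 pairs the cohort median is unreliable; pass an
    explicit ``normalizer`` (e.g. the unrelated-pair expectation from a
    reference cohort) or an error is raised.
    """
    vals = np.array([v for v in p0_raw_by_pair.values() if np.isfinite(v)])
    if normalizer is None:
        if len(vals) < 10:
            raise ValueError(
                "cohort has fewer than 10 pairs; supply an explicit "
                "normalization value instead of the cohort median")
        normalizer = float(np.median(vals))
    out = {}
    for pair, p0 in p0_raw_by_pair.items():
        if not np.isfinite(p0):
            out[pair] = (float("nan"), None)
            continue
        pn = p0 / normalizer
        if pn < P0_CUT_IDENTICAL:
            deg = "identical"
        elif pn < P0_CUT_FIRST:
            deg = "first"
        elif pn < P0_CUT_SECOND:
            deg = "second"
        else:
            deg = "unrelated"
        out[pair] = (pn, deg)
    return out, normalizer


# ---------------------------------------------------------------------------
# IBS summaries
# ---------------------------------------------------------------------------

def ibs_stats(dip1: np.ndarray, dip2: np.ndarray):
    """IBS0/1/2 counts plus R0, R1 and KING-robust theta.

    Operative formulas (frozen):
    ``king_theta = (N_both_het - 2 N_opposite_hom) / (N_het_1 + N_het_2)``;
    ``R0 = N_opposite_hom / N_both_het``;
    ``R1 = N_both_het / (N_IBS0 + N_IBS1)``.
    """
    both = (dip1 != MISSING) & (dip2 != MISSING)
    g1, g2 = dip1[both].astype(int), dip2[both].astype(int)
    ibs2 = int((g1 == g2).sum())
    ibs0 = int((np.abs(g1 - g2) == 2).sum())
    ibs1 = int(len(g1) - ibs2 - ibs0)
    het1 = int((g1 == 1).sum())
    het2 = int((g2 == 1).sum())
    both_het = int(((g1 == 1) & (g2 == 1)).sum())
    king = ((both_het - 2.0 * ibs0) / (het1 + het2)
            if het1 + het2 > 0 else float("nan"))
    r0 = ibs0 / both_het if both_het > 0 else float("nan")
    r1 = both_het / (ibs0 + ibs1) if ibs0 + ibs1 > 0 else float("nan")
    return {"ibs0": ibs0, "ibs1": ibs1, "ibs2": ibs2, "n": int(both.sum()),
            "r0": r0, "r1": r1, "king_theta": king}


# ---------------------------------------------------------------------------
# ML k-coefficients
# ---------------------------------------------------------------------------

def _joint_tables(q: np.ndarray) -> np.ndarray:
    """P(g1, g2 | IBD state, allele2 freq q): shape (3, n, 3, 3)."""
    p = 1.0 - q
    hw = np.stack([p * p, 2 * p * q, q * q], axis=-1)          # (n,3)
    t0 = hw[:, :, None] * hw[:, None, :]
    n = len(q)
    t1 = np.zeros((n, 3, 3))
    t1[:, 0, 0] = p ** 3
    t1[:, 0, 1] = p * p * q
    t1[:, 1, 0] = p * p * q
    t1[:, 1, 1] = p * q
    t1[:, 1, 2] = p * q * q
    t1[:, 2, 1] = p * q * q
    t1[:, 2, 2] = q ** 3
    t2 = np.zeros((n, 3, 3))
    for g in range(3):
        t2[:, g, g] = hw[:, g]
    return np.stack([t0, t1, t2])


def ml_k_coefficients(gl1: np.ndarray, gl2: np.ndarray, freqs: np.ndarray,
                      max_iter: int = 2000, tol: float = 1e-6):
    """EM estimate of (k0, k1, k2) from two genotype-likelihood matrices.

    Sites missing in either individual are dropped; frequencies are the
    allele2 frequency in the chosen reference population. EM needs a few
    thousand iterations when the optimum sits on the simplex boundary
    (e.g. k2 = 0 for parent-offspring); non-convergence is flagged and
    the last iterate returned. Returns ``(k, theta, n_sites, converged)``.
    """
    ok = (~np.isnan(gl1[:, 0])) & (~np.isnan(gl2[:, 0])) & np.isfinite(freqs)
    g1, g2 = gl1[ok], gl2[ok]
    q = np.clip(freqs[ok], 1e-6, 1 - 1e-6)
    n = len(q)
    if n == 0:
        return np.full(3, np.nan), float("nan"), 0, False
    tables = _joint_tables(q)
    # per-site likelihood of each IBD state, marginalized over genotypes
    state_l = np.einsum("si,msij,sj->sm", g1, tables, g2)
    state_l = np.maximum(state_l, 1e-300)
    k = np.full(3, 1.0 / 3.0)
    last = -np.inf
    converged = False
    for _ in range(max_iter):
        mix = state_l @ k
        ll = float(np.log(mix).sum())
        gamma = state_l * k / mix[:, None]
        k = gamma.mean(axis=0)
        k /= k.sum()
        if abs(ll - last) < tol:
            converged = True
            break
        last = ll
    theta = float(k[1] / 4.0 + k[2] / 2.0)
    return k, theta, n, converged


def degree_from_theta(theta: float) -> str | None:
    if not np.isfinite(theta):
        return None
    if theta >= THETA_CUTS[0]:
        return "identical"
    if theta >= THETA_CUTS[1]:
        return "first"
    if theta >= THETA_CUTS[2]:
        return "second"
    return "unrelated"


# ---------------------------------------------------------------------------
# X-chromosome kinship
# ---------------------------------------------------------------------------

def _posterior_dosage(gl: np.ndarray, q: np.ndarray, haploid: bool) -> np.ndarray:
    """Posterior mean allele2 dosage on the haploid [0,1] scale.

    Uses a Hardy–Weinberg prior at the reference frequency (haploid
    Bernoulli prior for male X), so low-coverage sites shrink toward q.
    """
    p = 1.0 - q
    if haploid:
        prior = np.stack([p, np.zeros_like(q), q], axis=1)
    else:
        prior = np.stack([p * p, 2 * p * q, q * q], axis=1)
    post = gl * prior
    post /= post.sum(axis=1, keepdims=True)
    return post[:, 1] * 0.5 + post[:, 2]


def theta_x(gl1: np.ndarray, gl2: np.ndarray, sex1: str, sex2: str,
            freqs: np.ndarray, min_overlap: int = X_OVERLAP_GATE):
    """Kinship-scale X-chromosome sharing, comparable across pair types.

    A moment estimator on posterior allele dosages:
    ``theta_X = sum (x1-q)(x2-q) / sum q(1-q)``, with male X treated as
    haploid. On this haploid-sharing scale father-son is ~0 and
    mother-son ~0.5. Below the overlap gate the result is withheld.
    Returns ``(theta_x or None, n_overlap, gate_passed)``.
    """
    ok = (~np.isnan(gl1[:, 0])) & (~np.isnan(gl2[:, 0])) & np.isfinite(freqs)
    n = int(ok.sum())
    if n < min_overlap:
        return None, n, False
    q = np.clip(freqs[ok], 1e-6, 1 - 1e-6)
    x1 = _posterior_dosage(gl1[ok], q, haploid=sex1 in ("M", "XY"))
    x2 = _posterior_dosage(gl2[ok], q, haploid=sex2 in ("M", "XY"))
    num = float(((x1 - q) * (x2 - q)).sum())
    den = float((q * (1.0 - q)).sum())
    return num / den, n, True


# ---------------------------------------------------------------------------
# Consolidation
# ---------------------------------------------------------------------------

def consolidate_degree(degree_read: str | None, degree_ml: str | None):
    """Merge the two methods' degree calls.

    Agreement keeps the shared call; on conflict the likelihood-based
    call wins (and the conflict is flagged); a single available method
    is used with its provenance recorded.
    Returns ``(degree_final, source, conflict)``.
    """
    if degree_read is None and degree_ml is None:
        return None, None, False
    if degree_read is None:
        return degree_ml, "ml_only", False
    if degree_ml is None:
        return degree_read, "read_only", False
    if degree_read == degree_ml:
        return degree_ml, "both_agree", False
    return degree_ml, "ml_priority", True


# ---------------------------------------------------------------------------
# Cohort pipeline
# ---------------------------------------------------------------------------

def pairwise_kinship(store: GenotypeStore, freq_pop: str,
                     sexes: dict[str, str] | None = None,
                     thin_gap: int = 2500, maf_min: float = 0.1,
                     window: int = 1_000_000,
                     read_normalizer: float | None = None,
                     x_store: GenotypeStore | None = None,
                     x_freq_pop: str | None = None) -> list[PairKinship]:
    """Full pairwise analysis of a cohort.

    Pseudo-haploid mismatch classification on the MAF-filtered autosomal
    panel, ML k-coefficients on the per-pair thinned GL panel annotated
    with ``freq_pop`` frequencies, IBS summaries on best-genotype calls,
    optional X-chromosome theta from ``x_store``, and consolidated
    degrees. Overlap gates (10,000 autosomal / 1,000 X sites) are
    recorded on each pair; sub-gate evidence yields no degree call.
    """
    panel = store.panel
    auto = panel.chrom_class == "autosome"
    freqs = panel.freqs[freq_pop]
    maf_ok = auto & (np.minimum(freqs, 1 - freqs) >= maf_min)
    pos = panel.pos
    names = store.individuals
    sexes = sexes or {}

    pairs: list[PairKinship] = []
    p0_raw: dict[tuple[str, str], float] = {}
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            pk = PairKinship(names[a], names[b])
            # READ-style on pseudo-haploid, MAF-filtered sites
            h1, h2 = store.pseudohap[a], store.pseudohap[b]
            sel = maf_ok
            p0, wins, n_p0 = read_p0(h1[sel], h2[sel], pos[sel], window)
            pk.p0_raw, pk.p0_windows = p0, wins
            # IBS on best-genotype diploid calls
            stats = ibs_stats(store.diploid[a][auto], store.diploid[b][auto])
            pk.ibs0, pk.ibs1, pk.ibs2 = stats["ibs0"], stats["ibs1"], stats["ibs2"]
            pk.r0, pk.r1, pk.king_theta = stats["r0"], stats["r1"], stats["king_theta"]
            # ML k on the per-pair thinned GL panel
            covered = auto & (~np.isnan(store.gl[a, :, 0])) \
                & (~np.isnan(store.gl[b, :, 0]))
            pk.n_overlap_auto = int(covered.sum())
            # per-pair thinning of the intersected panel (greedy scan)
            thin_keep = np.zeros(panel.n_sites, dtype=bool)
            last: dict[str, int] = {}
            for i in np.flatnonzero(covered):
                c = panel.chrom[i]
                if c not in last or pos[i] - last[c] >= thin_gap:
                    thin_keep[i] = True
                    last[c] = int(pos[i])
            k, theta, n_ml, _ = ml_k_coefficients(
                store.gl[a][thin_keep], store.gl[b][thin_keep], freqs[thin_keep])
            pk.k0, pk.k1, pk.k2 = (float(x) for x in k)
            pk.theta_auto = theta
            pk.gate_auto = pk.n_overlap_auto >= AUTO_OVERLAP_GATE
            if pk.gate_auto:
                pk.degree_ml = degree_from_theta(theta)
                p0_raw[(pk.id1, pk.id2)] = p0
            # X-chromosome theta
            if x_store is not None:
                xa = x_store.index_of(pk.id1)
                xb = x_store.index_of(pk.id2)
                xq = x_store.panel.freqs[x_freq_pop or freq_pop]
                tx, n_x, gate = theta_x(x_store.gl[xa], x_store.gl[xb],
                                        sexes.get(pk.id1, "U"),
                                        sexes.get(pk.id2, "U"), xq)
                pk.n_overlap_x, pk.gate_x = n_x, gate
                if tx is not None:
                    pk.theta_x = tx
            pairs.append(pk)

    if p0_raw:
        try:
            classified, _ = classify_read(p0_raw, read_normalizer)
        except ValueError:
            classified = {}
        for pk in pairs:
            res = classified.get((pk.id1, pk.id2))
            if res is not None:
                pk.p0_normalized, pk.degree_read = res
    for pk in pairs:
        pk.degree_final, pk.degree_source, pk.conflict = consolidate_degree(
            pk.degree_read, pk.degree_ml)
    return pairs
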