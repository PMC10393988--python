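"""Damage-aware genotype calling, pseudo-haploid sampling, QC gating and
genetic-sex assignment.

The likelihood model: a read's observed base arises from a true allele by
(optionally) terminal deamination (C→T assessed with the 5'-distance
profile, G→A with the 3'), followed by sequencing error at the rate
implied by the base quality. Site likelihoods are per-read products under
each candidate genotype; GQ is the phred difference between the best and
second-best genotype posterior under a flat prior.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binomtest

from .core import MISSING, GenotypeStore, IndividualRecord, SNPPanel
from .simdata import Pileups

_BASES = np.array(["A", "C", "G", "T"], dtype=object)
_CODE = {b: i for i, b in enumerate(_BASES)}
_C, _G, _T, _A = _CODE["C"], _CODE["G"], _CODE["T"], _CODE["A"]


@dataclass
class DamageProfile:
    """Terminal deamination probabilities by distance from the read end.

    ``ct_by_distance[k]`` is the C→T probability at distance k+1 from the
    5' end; ``ga_by_distance`` the G→A probability from the 3' end.
    Distances beyond the profile (or reads without a distance tag,
    distance <= 0) fall back to ``flat_rate``.
    """

    ct_by_distance: np.ndarray = field(default_factory=lambda: np.zeros(0))
    ga_by_distance: np.ndarray = field(default_factory=lambda: np.zeros(0))
    flat_rate: float = 0.0

    def __post_init__(self):
        self.ct_by_distance = np.asarray(self.ct_by_distance, dtype=float)
        self.ga_by_distance = np.asarray(self.ga_by_distance, dtype=float)
        for arr in (self.ct_by_distance, self.ga_by_distance):
            if ((arr < 0) | (arr > 1)).any():
                raise ValueError("damage probabilities must lie in [0,1]")
        if not 0 <= self.flat_rate <= 1:
            raise ValueError("flat_rate must lie in [0,1]")

    @classmethod
    def flat(cls, rate: float) -> "DamageProfile":
        return cls(np.array([rate]), np.array([rate]), rate)

    @classmethod
    def terminal(cls, rate: float, length: int = 1) -> "DamageProfile":
        """Damage confined to the first `length` positions at each end."""
        return cls(np.full(length, rate), np.full(length, rate), 0.0)

    def _lookup(self, arr: np.ndarray, dist: np.ndarray) -> np.ndarray:
        out = np.full(dist.shape, self.flat_rate, dtype=float)
        ok = (dist >= 1) & (dist <= len(arr))
        if ok.any():
            out[ok] = arr[dist[ok] - 1]
        return out

    def ct(self, dist: np.ndarray) -> np.ndarray:
        return self._lookup(self.ct_by_distance, np.asarray(dist))

    def ga(self, dist: np.ndarray) -> np.ndarray:
        return self._lookup(self.ga_by_distance, np.asarray(dist))


def _read_given_allele(base: np.ndarray, qual: np.ndarray, dist: np.ndarray,
                       allele: np.ndarray, damage: DamageProfile) -> np.ndarray:
    """P(observed base | true allele) per read, damage then sequencing error."""
    e = 10.0 ** (-np.asarray(qual, dtype=float) / 10.0)
    hit = np.where(base == allele, 1.0 - e, e / 3.0)
    d_ct = damage.ct(dist)
    d_ga = damage.ga(dist)
    # allele C: with prob d the template reads T
    to_t = np.where(base == _T, 1.0 - e, e / 3.0)
    p_c = (1.0 - d_ct) * hit + d_ct * to_t
    to_a = np.where(base == _A, 1.0 - e, e / 3.0)
    p_g = (1.0 - d_ga) * hit + d_ga * to_a
    p = np.where(allele == _C, p_c, np.where(allele == _G, p_g, hit))
    return p


def call_genotype_likelihoods(pileup, site, damage: DamageProfile,
                              ploidy: int = 2):
    """Call one site from a list of (base, quality, distance) reads.

    `site` is anything with ``a1``/``a2`` attributes or a (a1, a2) pair.
    Returns ``(likelihood_triple, gq, best_code)`` with the triple
    normalized in linear scale and best_code the allele2 count; an empty
    pileup yields a missing call ``(None, MISSING, MISSING)``.
    """
    if not pileup:
        return None, MISSING, MISSING
    a1, a2 = (site.a1, site.a2) if hasattr(site, "a1") else site
    base = np.array([_CODE[b] for b, _, _ in pileup])
    qual = np.array([q for _, q, _ in pileup], dtype=float)
    dist = np.array([d for _, _, d in pileup], dtype=int)
    p1 = _read_given_allele(base, qual, dist, np.full(len(base), _CODE[a1]), damage)
    p2 = _read_given_allele(base, qual, dist, np.full(len(base), _CODE[a2]), damage)
    with np.errstate(divide="ignore"):
        ll = np.array([np.log(np.maximum(p1, 1e-300)).sum(),
                       np.log(np.maximum(0.5 * (p1 + p2), 1e-300)).sum(),
                       np.log(np.maximum(p2, 1e-300)).sum()])
    if ploidy == 1:
        ll[1] = -np.inf
    lin = np.exp(ll - ll.max())
    lin /= lin.sum()
    order = np.argsort(ll)[::-1]
    gq = min(int(round(10.0 / np.log(10.0) * (ll[order[0]] - ll[order[1]]))), 99)
    return lin, gq, int(order[0])


def call_all(pileups: Pileups, damage: DamageProfile,
             haploid_mask: np.ndarray | None = None):
    """Vectorized caller over a whole panel for one individual.

    Returns (gl, gq, best) arrays; sites in ``haploid_mask`` (e.g. male X)
    are called hemizygous (het likelihood zero, best code 0/2).
    """
    panel = pileups.panel
    m = panel.n_sites
    a1c = np.array([_CODE[b] for b in panel.a1])
    a2c = np.array([_CODE[b] for b in panel.a2])
    site = np.repeat(np.arange(m), pileups.counts)
    p1 = _read_given_allele(pileups.base, pileups.qual, pileups.dist,
                            a1c[site], damage)
    p2 = _read_given_allele(pileups.base, pileups.qual, pileups.dist,
                            a2c[site], damage)
    logs = np.log(np.maximum(np.stack([p1, 0.5 * (p1 + p2), p2], axis=1),
                             1e-300))
    ll = np.zeros((m, 3))
    covered = pileups.counts > 0
    if covered.any():
        # offsets of covered sites are strictly increasing; empty sites
        # contribute no reads between consecutive covered offsets
        idx = pileups.offsets[:-1][covered]
        ll[covered] = np.add.reduceat(logs, idx, axis=0)
    if haploid_mask is not None:
        ll[haploid_mask, 1] = -np.inf
    gl = np.full((m, 3), np.nan)
    gq = np.full(m, MISSING, dtype=np.int16)
    best = np.full(m, MISSING, dtype=np.int8)
    if covered.any():
        sub = ll[covered]
        lin = np.exp(sub - sub.max(axis=1, keepdims=True))
        gl[covered] = lin / lin.sum(axis=1, keepdims=True)
        srt = np.sort(sub, axis=1)
        gq[covered] = np.minimum(
            np.round(10.0 / np.log(10.0) * (srt[:, 2] - srt[:, 1])), 99
        ).astype(np.int16)
        best[covered] = np.argmax(sub, axis=1).astype(np.int8)
    return gl, gq, best


def call_pseudohaploid(pileup, site, rng: np.random.Generator):
    """One random read's allele stands in for the genotype (0/1/missing)."""
    if not pileup:
        return MISSING
    a1, a2 = (site.a1, site.a2) if hasattr(site, "a1") else site
    b = pileup[int(rng.integers(0, len(pileup)))][0]
    if b == a1:
        return 0
    if b == a2:
        return 1
    return MISSING


def pseudohaploid_all(pileups: Pileups, seed: int, individual: str = "") -> np.ndarray:
    """Vectorized pseudo-haploid draw across the panel.

    The RNG stream is keyed by (seed, crc32(individual)) so results are
    independent of calling order across individuals.
    """
    rng = np.random.default_rng((seed, zlib.crc32(individual.encode())))
    panel = pileups.panel
    m = panel.n_sites
    out = np.full(m, MISSING, dtype=np.int8)
    covered = pileups.counts > 0
    pick = (pileups.offsets[:-1]
            + (rng.random(m) * np.maximum(pileups.counts, 1)).astype(np.int64))
    chosen = np.full(m, -1, dtype=np.int64)
    chosen[covered] = pileups.base[pick[covered]]
    a1c = np.array([_CODE[b] for b in panel.a1])
    a2c = np.array([_CODE[b] for b in panel.a2])
    out[covered & (chosen == a1c)] = 0
    out[covered & (chosen == a2c)] = 1
    return out


def build_store(pileups_by_individual: dict[str, Pileups],
                damage: DamageProfile, seed: int,
                sexes: dict[str, str] | None = None) -> GenotypeStore:
    """Run the caller and the pseudo-haploid sampler over a cohort."""
    names = list(pileups_by_individual)
    panel = pileups_by_individual[names[0]].panel
    store = GenotypeStore(names, panel)
    non_auto = panel.chrom_class != "autosome"
    for j, name in enumerate(names):
        pu = pileups_by_individual[name]
        hap = non_auto if (sexes or {}).get(name) in ("M", "XY") else None
        gl, gq, best = call_all(pu, damage, haploid_mask=hap)
        store.gl[j] = gl
        store.gq[j] = gq
        store.diploid[j] = best
        store.pseudohap[j] = pseudohaploid_all(pu, seed, name)
    return store


# ---------------------------------------------------------------------------
# Genetic sex and QC
# ---------------------------------------------------------------------------

@dataclass
class SexCall:
    sex: str
    ry: float
    ci_low: float
    ci_high: float


def assign_genetic_sex(reads_x: int, reads_y: int, reads_autosomal: int = 0,
                       female_threshold: float = 0.016,
                       male_threshold: float = 0.075) -> SexCall:
    """Sex from the Y fraction of sex-chromosome reads.

    Ry = nY/(nX+nY) with a 95% Wilson binomial CI; XY when the whole CI
    sits above the male threshold, XX when below the female threshold,
    otherwise unknown. Zero sex-chromosome reads give unknown.
    """
    if reads_x < 0 or reads_y < 0:
        raise ValueError("read counts must be >= 0")
    n = reads_x + reads_y
    if n == 0:
        return SexCall("unknown", float("nan"), float("nan"), float("nan"))
    ci = binomtest(reads_y, n).proportion_ci(confidence_level=0.95,
                                             method="wilson")
    ry = reads_y / n
    if ci.low > male_threshold:
        sex = "XY"
    elif ci.high < female_threshold:
        sex = "XX"
    else:
        sex = "unknown"
    return SexCall(sex, ry, ci.low, ci.high)


@dataclass
class QCThresholds:
    max_contamination: float = 0.2
    min_terminal_damage: float = 0.25


def qc_gate(record: IndividualRecord,
            thresholds: QCThresholds | None = None) -> tuple[bool, list[str]]:
    """Authenticity gate: fail on contamination > 0.2 or terminal damage
    < 25%; missing fields are noted but never fail the individual."""
    t = thresholds or QCThresholds()
    reasons: list[str] = []
    if record.contamination is None:
        reasons.append("contamination: missing, not assessed")
    elif record.contamination > t.max_contamination:
        reasons.append("contamination")
    if record.terminal_damage is None:
        reasons.append("damage: missing, not assessed")
    elif record.terminal_damage < t.min_terminal_damage:
        reasons.append("damage")
    failed = "contamination" in reasons or "damage" in reasons
    return (not failed), reasons
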