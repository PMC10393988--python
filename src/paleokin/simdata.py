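"""Synthetic cohorts with known truth.

Three layers, mirroring how real ancient-DNA data arise:

1. **Population history** — allele frequencies drift along an admixture
   graph under the Balding–Nichols model (child frequency Beta-distributed
   around the parent with variance ``F p (1-p)``). Because the model is a
   martingale with multiplicative heterozygosity decay, every f-statistic
   expectation is available in closed form from second moments propagated
   through the graph (:func:`expected_moments`), giving downstream
   estimators an exact oracle.
2. **Pedigrees** — Mendelian gene-drop with autosomal, X-linked, Y and
   mitochondrial transmission; founder-allele identifiers are recorded per
   transmitted allele so realized IBD sharing is known exactly.
3. **Sequencing** — Poisson read depth, base error, terminal C→T/G→A
   deamination, and a contamination fraction drawn from a contaminant
   population's frequencies.

Sites are exchangeable (no recombination map); positions exist only for
block bookkeeping (jackknife, thinning).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .core import MISSING, GenotypeStore, SNPPanel

_BASES = np.array(["A", "C", "G", "T"], dtype=object)
_BASE_CODE = {b: i for i, b in enumerate(_BASES)}
_FREQ_CLAMP = 1e-6
# allele pairs sampled for simulated panels (4 transversions, 2 transitions)
_ALLELE_PAIRS = [("C", "A"), ("C", "G"), ("A", "T"), ("G", "T"),
                 ("C", "T"), ("A", "G")]


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class AdmixtureGraphSpec:
    """Population history: drift edges plus two-source admixture events.

    ``edges`` maps child -> (parent, F); ``admixture_edges`` maps
    child -> (sourceA, sourceB, alpha, F_after) where the child frequency
    is ``alpha*pA + (1-alpha)*pB`` followed by its own drift ``F_after``.
    ``root_freq_range`` is the uniform spectrum for ancestral frequencies.
    """

    nodes: Sequence[str]
    edges: Mapping[str, tuple[str, float]] = field(default_factory=dict)
    admixture_edges: Mapping[str, tuple[str, str, float, float]] = field(
        default_factory=dict)
    root_freq_range: tuple[float, float] = (0.05, 0.95)

    def __post_init__(self):
        for child, (a, b, alpha, f_after) in self.admixture_edges.items():
            if not 0.0 <= alpha <= 1.0:
                raise ValueError(f"admixture proportion for {child} not in [0,1]")
            if f_after < 0:
                raise ValueError(f"negative drift after admixture into {child}")
        for child, (parent, f) in self.edges.items():
            if f < 0:
                raise ValueError(f"negative drift on {parent}->{child}")
        both = set(self.edges) & set(self.admixture_edges)
        if both:
            raise ValueError(f"nodes with both drift and admixture parents: {both}")
        g = self.to_networkx()
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle:
            raise ValueError(f"admixture graph contains a cycle: {cycle}")
        roots = [n for n in self.nodes
                 if n not in self.edges and n not in self.admixture_edges]
        if len(roots) != 1:
            raise ValueError(f"graph must have exactly one root, found {roots}")
        self.root = roots[0]

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for child, (parent, _) in self.edges.items():
            g.add_edge(parent, child)
        for child, (a, b, _, _) in self.admixture_edges.items():
            g.add_edge(a, child)
            g.add_edge(b, child)
        return g

    def topological_order(self) -> list[str]:
        return list(nx.topological_sort(self.to_networkx()))


@dataclass
class PedigreeMember:
    id: str
    sex: str                  # "M" / "F"
    generation: int = 0
    age_class: str = "adult"  # adult / juvenile


@dataclass
class PedigreeSpec:
    """A multigenerational pedigree with uniparental founder labels.

    ``parent_links`` maps child id -> (mother id, father id); individuals
    absent from it are founders. Founders carry ``mito_lineage`` /
    ``y_lineage`` labels (Y for males only) and optionally a population in
    ``founder_population`` (default ``"POP"``).
    """

    members: Sequence[PedigreeMember]
    parent_links: Mapping[str, tuple[str, str]] = field(default_factory=dict)
    mito_lineage: Mapping[str, str] = field(default_factory=dict)
    y_lineage: Mapping[str, str] = field(default_factory=dict)
    founder_population: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.by_id = {m.id: m for m in self.members}
        g = nx.DiGraph()
        g.add_nodes_from(self.by_id)
        for child, (mother, father) in self.parent_links.items():
            if child not in self.by_id:
                raise ValueError(f"parent link for unknown member {child!r}")
            for p, role, want in ((mother, "mother", "F"), (father, "father", "M")):
                if p not in self.by_id:
                    raise ValueError(
                        f"child {child!r} has missing {role} record {p!r}")
                if self.by_id[p].sex != want:
                    raise ValueError(f"{role} {p!r} of {child!r} is not sex {want}")
                g.add_edge(p, child)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("pedigree contains an ancestry cycle")

    @property
    def founders(self) -> list[str]:
        return [m.id for m in self.members if m.id not in self.parent_links]

    def topological_order(self) -> list[str]:
        g = nx.DiGraph()
        g.add_nodes_from(self.by_id)
        for child, (m, f) in self.parent_links.items():
            g.add_edge(m, child)
            g.add_edge(f, child)
        return list(nx.topological_sort(g))


@dataclass
class SequencingSpec:
    """Read-level noise model for pseudo-data generation."""

    mean_depth: float = 1.0
    base_error: float = 0.001
    deamination_rate: float = 0.1
    contamination_fraction: float = 0.0
    contaminant_population: str | None = None
    terminal_fraction: float = 0.3    # P(read observed at its terminal base)
    max_interior_distance: int = 15
    seed: int = 0

    def __post_init__(self):
        for name in ("base_error", "deamination_rate", "contamination_fraction",
                     "terminal_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} out of [0,1]: {v}")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")


# ---------------------------------------------------------------------------
# Graph frequencies and the path-overlap oracle
# ---------------------------------------------------------------------------

def make_panel(n_sites: int, seed: int, chrom_class: str = "autosome",
               n_chrom: int = 10, spacing: int = 3000,
               prefix: str = "snp") -> SNPPanel:
    """A synthetic site map with evenly spaced positions.

    Autosomal panels spread sites across ``n_chrom`` chromosomes;
    X/Y panels use a single chromosome. Allele pairs are drawn from a
    mix of transversions and transitions.
    """
    rng = np.random.default_rng(seed)
    if chrom_class == "autosome":
        chroms = np.array([f"{(i % n_chrom) + 1}" for i in range(n_sites)],
                          dtype=object)
        order = np.argsort([int(c) for c in chroms], kind="stable")
        chroms = chroms[order]
    else:
        chroms = np.array([chrom_class] * n_sites, dtype=object)
    pos = np.empty(n_sites, dtype=np.int64)
    start = 0
    for c in dict.fromkeys(chroms):
        m = chroms == c
        k = int(m.sum())
        pos[m] = spacing * (1 + np.arange(k))
        start += k
    pairs = [_ALLELE_PAIRS[i] for i in rng.integers(0, len(_ALLELE_PAIRS), n_sites)]
    ids = np.array([f"{prefix}_{chroms[i]}_{pos[i]}" for i in range(n_sites)],
                   dtype=object)
    return SNPPanel(ids, chroms, [chrom_class] * n_sites, pos,
                    [p[0] for p in pairs], [p[1] for p in pairs])


def _balding_nichols(rng, p: np.ndarray, f: float) -> np.ndarray:
    if f == 0:
        return p.copy()
    scale = (1.0 - f) / f
    out = rng.beta(np.maximum(p * scale, 1e-12),
                   np.maximum((1.0 - p) * scale, 1e-12))
    return np.clip(out, _FREQ_CLAMP, 1.0 - _FREQ_CLAMP)


def simulate_graph_frequencies(spec: AdmixtureGraphSpec, n_sites: int,
                               seed: int, panel: SNPPanel | None = None
                               ) -> tuple[dict[str, np.ndarray], SNPPanel]:
    """Draw per-population allele frequencies along the admixture graph.

    Returns (frequency table, panel); the frequencies are also attached
    to the returned panel's ``freqs``.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = spec.root_freq_range
    freqs: dict[str, np.ndarray] = {}
    for node in spec.topological_order():
        if node == spec.root:
            freqs[node] = np.clip(rng.uniform(lo, hi, n_sites),
                                  _FREQ_CLAMP, 1 - _FREQ_CLAMP)
        elif node in spec.edges:
            parent, f = spec.edges[node]
            freqs[node] = _balding_nichols(rng, freqs[parent], f)
        else:
            a, b, alpha, f_after = spec.admixture_edges[node]
            mixed = alpha * freqs[a] + (1.0 - alpha) * freqs[b]
            freqs[node] = _balding_nichols(rng, mixed, f_after)
    if panel is None:
        panel = make_panel(n_sites, seed=seed + 1)
    elif panel.n_sites != n_sites:
        raise ValueError("panel size does not match n_sites")
    panel.freqs.update(freqs)
    return freqs, panel


def expected_moments(spec: AdmixtureGraphSpec) -> dict[tuple[str, str], float]:
    """Exact second moments E[p_X p_Y] under the Balding–Nichols graph.

    Propagated in topological order: drift leaves cross-moments untouched
    and shrinks own-variance toward the martingale mean; admixture mixes
    moments linearly. All f-statistics follow from these (the mean terms
    cancel), which is the closed-form path-overlap oracle.
    """
    lo, hi = spec.root_freq_range
    mu = (lo + hi) / 2.0
    m2_root = (lo * lo + lo * hi + hi * hi) / 3.0
    order = spec.topological_order()
    c: dict[tuple[str, str], float] = {}

    def get(x, y):
        return c[(x, y)] if (x, y) in c else c[(y, x)]

    done: list[str] = []
    for node in order:
        if node == spec.root:
            c[(node, node)] = m2_root
        elif node in spec.edges:
            parent, f = spec.edges[node]
            for other in done:
                c[(node, other)] = get(parent, other)
            c[(node, node)] = f * mu + (1.0 - f) * get(parent, parent)
        else:
            a, b, alpha, f_after = spec.admixture_edges[node]
            for other in done:
                c[(node, other)] = alpha * get(a, other) + (1 - alpha) * get(b, other)
            m2 = (alpha ** 2 * get(a, a) + 2 * alpha * (1 - alpha) * get(a, b)
                  + (1 - alpha) ** 2 * get(b, b))
            c[(node, node)] = f_after * mu + (1.0 - f_after) * m2
        done.append(node)
    return c


def expected_f4(spec: AdmixtureGraphSpec, w: str, x: str, y: str, z: str) -> float:
    """E[f4(W,X;Y,Z)] = E[(pW-pX)(pY-pZ)] from propagated moments."""
    c = expected_moments(spec)

    def get(p, q):
        return c[(p, q)] if (p, q) in c else c[(q, p)]

    return get(w, y) - get(w, z) - get(x, y) + get(x, z)


def expected_f3(spec: AdmixtureGraphSpec, o: str, a: str, b: str) -> float:
    return expected_f4(spec, o, a, o, b)


def expected_f2(spec: AdmixtureGraphSpec, a: str, b: str) -> float:
    return expected_f4(spec, a, b, a, b)


# ---------------------------------------------------------------------------
# Gene drop
# ---------------------------------------------------------------------------

class TrueGenotypes:
    """Truth produced by :func:`gene_drop`.

    ``auto_alleles``/``auto_ids``: (n_ind, 2, n_auto) allele codes (0/1 =
    allele1/allele2) and globally unique founder-allele identifiers.
    X arrays are (n_ind, 2, n_x) with the second row of males a copy of
    the first (males are hemizygous; ``sex`` disambiguates). ``mito`` and
    ``y_label`` carry the uniparental lineage labels.
    """

    def __init__(self, individuals, sex, panel, auto_alleles, auto_ids,
                 x_alleles, x_ids, mito, y_label):
        self.individuals = list(individuals)
        self.sex = dict(sex)
        self.panel = panel
        self.auto_alleles = auto_alleles
        self.auto_ids = auto_ids
        self.x_alleles = x_alleles
        self.x_ids = x_ids
        self.mito = dict(mito)
        self.y_label = dict(y_label)
        self._index = {n: i for i, n in enumerate(self.individuals)}

    def index_of(self, name: str) -> int:
        return self._index[name]

    def diploid_store(self) -> GenotypeStore:
        """True genotypes as a GenotypeStore (male X coded hemizygous 0/2)."""
        n = len(self.individuals)
        auto = self.auto_alleles.sum(axis=1).astype(np.int8)
        parts = [auto]
        if self.x_alleles is not None:
            x = self.x_alleles.sum(axis=1).astype(np.int8)
            for i, name in enumerate(self.individuals):
                if self.sex[name] == "M":
                    x[i] = 2 * self.x_alleles[i, 0]
            parts.append(x)
        dip = np.concatenate(parts, axis=1) if len(parts) > 1 else parts[0]
        return GenotypeStore(self.individuals, self.panel, diploid=dip)

    def realized_theta_x(self, i: str, j: str) -> float:
        """Realized X kinship on the haploid-sharing scale: the chance a
        random X allele from each is identical by descent."""
        if self.x_ids is None:
            return float("nan")
        ii, jj = self.index_of(i), self.index_of(j)
        rows_i = [0] if self.sex[i] == "M" else [0, 1]
        rows_j = [0] if self.sex[j] == "M" else [0, 1]
        match = np.zeros(self.x_ids.shape[2])
        for a in rows_i:
            for b in rows_j:
                match += self.x_ids[ii, a] == self.x_ids[jj, b]
        return float(match.mean() / (len(rows_i) * len(rows_j)))

    def realized_ibd(self, i: str, j: str) -> tuple[float, float, float]:
        """Realized (k0, k1, k2) on autosomes from the transmission record."""
        a, b = self.auto_ids[self.index_of(i)], self.auto_ids[self.index_of(j)]
        m00 = a[0] == b[0]
        m01 = a[0] == b[1]
        m10 = a[1] == b[0]
        m11 = a[1] == b[1]
        both = (m00 & m11) | (m01 & m10)
        one = (m00 | m01 | m10 | m11) & ~both
        k2 = both.mean()
        k1 = one.mean()
        return 1.0 - k1 - k2, float(k1), float(k2)


def gene_drop(pedigree: PedigreeSpec, founder_freqs: Mapping[str, np.ndarray],
              panel: SNPPanel, seed: int,
              x_panel: SNPPanel | None = None,
              x_freqs: Mapping[str, np.ndarray] | None = None) -> TrueGenotypes:
    """Drop alleles through the pedigree with Mendelian transmission.

    Autosomes: one allele from each parent, chosen independently per site
    (sites exchangeable). X: daughters get one maternal and the paternal X,
    sons the maternal X only. Y label passes father→son; mitochondrial
    label mother→all offspring. Founder alleles are drawn as Bernoulli of
    their population's frequency and tagged with unique identifiers so
    realized IBD is exactly known.
    """
    rng = np.random.default_rng(seed)
    auto_mask = panel.chrom_class == "autosome"
    auto_panel = panel.subset(auto_mask)
    n_auto = auto_panel.n_sites
    if x_panel is not None:
        n_x = x_panel.n_sites
        full_ids = np.concatenate([auto_panel.ids, x_panel.ids])
        full = SNPPanel(full_ids,
                        np.concatenate([auto_panel.chrom, x_panel.chrom]),
                        np.concatenate([auto_panel.chrom_class, x_panel.chrom_class]),
                        np.concatenate([auto_panel.pos, x_panel.pos]),
                        np.concatenate([auto_panel.a1, x_panel.a1]),
                        np.concatenate([auto_panel.a2, x_panel.a2]))
        for pop, track in founder_freqs.items():
            t = np.asarray(track)
            t = t[auto_mask] if len(t) == panel.n_sites else t
            if x_freqs is not None and pop in x_freqs:
                full.freqs[pop] = np.concatenate([t, np.asarray(x_freqs[pop])])
    else:
        n_x = 0
        full = auto_panel
        for pop, track in founder_freqs.items():
            t = np.asarray(track)
            full.freqs[pop] = t[auto_mask] if len(t) == panel.n_sites else t

    order = pedigree.topological_order()
    n = len(order)
    idx = {name: i for i, name in enumerate(order)}
    sex = {m.id: m.sex for m in pedigree.members}

    auto_alleles = np.zeros((n, 2, n_auto), dtype=np.int8)
    auto_ids = np.zeros((n, 2, n_auto), dtype=np.int64)
    x_alleles = np.zeros((n, 2, n_x), dtype=np.int8) if n_x else None
    x_ids = np.zeros((n, 2, n_x), dtype=np.int64) if n_x else None
    mito: dict[str, str] = {}
    y_label: dict[str, str | None] = {}
    next_id = 1

    for name in order:
        i = idx[name]
        if name not in pedigree.parent_links:       # founder
            pop = pedigree.founder_population.get(name, "POP")
            if pop not in founder_freqs:
                raise ValueError(f"founder population {pop!r} missing from table")
            f = np.asarray(founder_freqs[pop])[auto_mask] \
                if len(founder_freqs[pop]) == panel.n_sites else founder_freqs[pop]
            auto_alleles[i] = (rng.random((2, n_auto)) < f).astype(np.int8)
            auto_ids[i, 0] = next_id + np.arange(n_auto)
            auto_ids[i, 1] = next_id + n_auto + np.arange(n_auto)
            next_id += 2 * n_auto
            if n_x:
                if x_freqs is None:
                    raise ValueError("x_panel given but x_freqs missing")
                fx = np.asarray(x_freqs[pop])
                x_alleles[i] = (rng.random((2, n_x)) < fx).astype(np.int8)
                x_ids[i, 0] = next_id + np.arange(n_x)
                x_ids[i, 1] = next_id + n_x + np.arange(n_x)
                next_id += 2 * n_x
                if sex[name] == "M":            # hemizygous: mirror the single X
                    x_alleles[i, 1] = x_alleles[i, 0]
                    x_ids[i, 1] = x_ids[i, 0]
            mito[name] = pedigree.mito_lineage.get(name, f"mt_{name}")
            y_label[name] = (pedigree.y_lineage.get(name, f"Y_{name}")
                             if sex[name] == "M" else None)
        else:
            mother, father = pedigree.parent_links[name]
            mi, fi = idx[mother], idx[father]
            pick_m = rng.integers(0, 2, n_auto)
            pick_f = rng.integers(0, 2, n_auto)
            cols = np.arange(n_auto)
            auto_alleles[i, 0] = auto_alleles[mi, pick_m, cols]
            auto_ids[i, 0] = auto_ids[mi, pick_m, cols]
            auto_alleles[i, 1] = auto_alleles[fi, pick_f, cols]
            auto_ids[i, 1] = auto_ids[fi, pick_f, cols]
            if n_x:
                colx = np.arange(n_x)
                pick_mx = rng.integers(0, 2, n_x)
                x_alleles[i, 0] = x_alleles[mi, pick_mx, colx]
                x_ids[i, 0] = x_ids[mi, pick_mx, colx]
                if sex[name] == "F":            # paternal X (his single copy)
                    x_alleles[i, 1] = x_alleles[fi, 0]
                    x_ids[i, 1] = x_ids[fi, 0]
                else:                           # hemizygous son
                    x_alleles[i, 1] = x_alleles[i, 0]
                    x_ids[i, 1] = x_ids[i, 0]
            mito[name] = mito[mother]
            y_label[name] = y_label[father] if sex[name] == "M" else None

    return TrueGenotypes(order, sex, full, auto_alleles, auto_ids,
                         x_alleles, x_ids, mito, y_label)


# ---------------------------------------------------------------------------
# Sequencing
# ---------------------------------------------------------------------------

class Pileups:
    """Reads for one individual across a panel, stored flat for speed.

    ``counts[i]`` reads at site i; ``base``/``qual``/``dist`` are flat
    arrays indexed through ``offsets``. ``pileup(i)`` materializes the
    per-site (base, quality, distance) tuple list the caller consumes.
    """

    def __init__(self, panel: SNPPanel, counts, base, qual, dist):
        self.panel = panel
        self.counts = counts
        self.offsets = np.concatenate([[0], np.cumsum(counts)])
        self.base = base
        self.qual = qual
        self.dist = dist

    def pileup(self, i: int) -> list[tuple[str, int, int]]:
        s, e = self.offsets[i], self.offsets[i + 1]
        return [(str(_BASES[self.base[k]]), int(self.qual[k]), int(self.dist[k]))
                for k in range(s, e)]

    def __len__(self) -> int:
        return self.panel.n_sites


def sequence(true_genotypes: TrueGenotypes, seqspec: SequencingSpec,
             contaminant_freqs: Mapping[str, np.ndarray] | None = None
             ) -> dict[str, Pileups]:
    """Simulate read pileups for every individual.

    Per covered site the read count is Poisson(mean_depth); each read
    copies one of the individual's true alleles (or, with probability
    ``contamination_fraction``, a contaminant allele drawn from the
    contaminant population's frequency), suffers base error with the
    stated probability, and — at terminal positions — C→T / G→A
    deamination. Zero-depth sites yield empty pileups.
    """
    panel = true_genotypes.panel
    m = panel.n_sites
    a1c = np.array([_BASE_CODE[b] for b in panel.a1], dtype=np.int8)
    a2c = np.array([_BASE_CODE[b] for b in panel.a2], dtype=np.int8)
    is_x = panel.chrom_class == "X"
    n_x = int(is_x.sum())
    n_auto = m - n_x
    eps = seqspec.contamination_fraction
    cont = None
    if eps > 0:
        if seqspec.contaminant_population is None or contaminant_freqs is None:
            raise ValueError("contamination requested without contaminant freqs")
        cont = np.asarray(contaminant_freqs[seqspec.contaminant_population])
        if len(cont) != m:
            raise ValueError("contaminant frequency track length mismatch")
    qual_val = (45 if seqspec.base_error == 0
                else int(round(-10 * np.log10(seqspec.base_error))))

    out: dict[str, Pileups] = {}
    for name in true_genotypes.individuals:
        # per-individual stream keyed by (seed, crc32(id)): deterministic
        # across processes and order-independent under parallel calling
        rng = np.random.default_rng((seqspec.seed, zlib.crc32(name.encode())))
        i = true_genotypes.index_of(name)
        alleles = np.empty((2, m), dtype=np.int8)
        alleles[:, :n_auto] = true_genotypes.auto_alleles[i]
        if n_x:
            alleles[:, n_auto:] = true_genotypes.x_alleles[i]
        counts = rng.poisson(seqspec.mean_depth, m)
        total = int(counts.sum())
        site = np.repeat(np.arange(m), counts)
        which = rng.integers(0, 2, total)
        allele = alleles[which, site]
        if eps > 0:
            is_cont = rng.random(total) < eps
            cont_allele = (rng.random(total) < cont[site]).astype(np.int8)
            allele = np.where(is_cont, cont_allele, allele)
        base = np.where(allele == 1, a2c[site], a1c[site]).astype(np.int8)
        if seqspec.base_error > 0:
            err = rng.random(total) < seqspec.base_error
            shift = rng.integers(1, 4, total)
            base = np.where(err, (base + shift) % 4, base).astype(np.int8)
        terminal = rng.random(total) < seqspec.terminal_fraction
        dist = np.where(terminal, 1,
                        rng.integers(2, seqspec.max_interior_distance + 1, total)
                        ).astype(np.int16)
        if seqspec.deamination_rate > 0:
            deam = terminal & (rng.random(total) < seqspec.deamination_rate)
            base = np.where(deam & (base == _BASE_CODE["C"]),
                            _BASE_CODE["T"], base).astype(np.int8)
            base = np.where(deam & (base == _BASE_CODE["G"]),
                            _BASE_CODE["A"], base).astype(np.int8)
        qual = np.full(total, qual_val, dtype=np.int16)
        out[name] = Pileups(panel, counts, base, qual, dist)
    return out


# ---------------------------------------------------------------------------
# Truth files and graph-spec config
# ---------------------------------------------------------------------------

def write_truth_files(prefix, truth: TrueGenotypes,
                      pedigree: PedigreeSpec) -> None:
    """Write the truth record as TSVs: the pedigree (with uniparental
    labels) and the realized IBD coefficients per pair (the oracle the
    kinship estimators are judged against)."""
    import pandas as pd
    rows = []
    for m in pedigree.members:
        mother, father = pedigree.parent_links.get(m.id, ("", ""))
        rows.append({"id": m.id, "sex": m.sex, "generation": m.generation,
                     "age_class": m.age_class, "mother": mother,
                     "father": father, "mito": truth.mito[m.id],
                     "y": truth.y_label[m.id] or ""})
    pd.DataFrame(rows).to_csv(f"{prefix}.pedigree.tsv", sep="\t", index=False)
    names = [m.id for m in pedigree.members]
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            k0, k1, k2 = truth.realized_ibd(names[i], names[j])
            rows.append({"id1": names[i], "id2": names[j],
                         "k0": round(k0, 6), "k1": round(k1, 6),
                         "k2": round(k2, 6),
                         "theta": round(k1 / 4 + k2 / 2, 6),
                         "theta_x": round(truth.realized_theta_x(
                             names[i], names[j]), 6)
                         if truth.x_ids is not None else ""})
    pd.DataFrame(rows).to_csv(f"{prefix}.realized_ibd.tsv", sep="\t",
                              index=False)


def write_graph_spec(path, spec: AdmixtureGraphSpec) -> None:
    import yaml
    doc = {"nodes": list(spec.nodes),
           "edges": {c: [p, float(f)] for c, (p, f) in spec.edges.items()},
           "admixture_edges": {c: [a, b, float(al), float(fa)]
                               for c, (a, b, al, fa)
                               in spec.admixture_edges.items()},
           "root_freq_range": [float(x) for x in spec.root_freq_range]}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_graph_spec(path) -> AdmixtureGraphSpec:
    import yaml
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return AdmixtureGraphSpec(
        nodes=doc["nodes"],
        edges={c: (p, f) for c, (p, f) in doc.get("edges", {}).items()},
        admixture_edges={c: tuple(v) for c, v
                         in doc.get("admixture_edges", {}).items()},
        root_freq_range=tuple(doc.get("root_freq_range", (0.05, 0.95))))


# ---------------------------------------------------------------------------
# Perfect-evidence extraction (complete, error-free pairwise records)
# ---------------------------------------------------------------------------

def perfect_evidence(truth: TrueGenotypes, pedigree: PedigreeSpec):
    """Exact pairwise kinship evidence straight from the truth record.

    Returns ``(pairs, records)``: PairKinship objects with realized
    k-coefficients, IBS summaries from the true diploid genotypes,
    realized theta_X, and degrees implied by realized theta — the input
    contract of the pedigree engine under complete error-free data —
    plus matching IndividualRecords carrying sex, age class and
    uniparental labels.
    """
    from .core import IndividualRecord
    from .kinstats import PairKinship, degree_from_theta, ibs_stats

    store = truth.diploid_store()
    auto = truth.panel.chrom_class == "autosome"
    n_auto = int(auto.sum())
    n_x = truth.panel.n_sites - n_auto
    sex_map = {"M": "XY", "F": "XX"}
    records = [IndividualRecord(
        id=m.id, genetic_sex=sex_map[m.sex], age_class=m.age_class,
        group="SIM", mito_haplogroup=truth.mito[m.id],
        y_haplogroup=truth.y_label[m.id], coverage=1.0)
        for m in pedigree.members]
    names = [m.id for m in pedigree.members]
    pairs = []
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            i, j = names[a], names[b]
            pk = PairKinship(i, j, n_overlap_auto=n_auto, n_overlap_x=n_x)
            k0, k1, k2 = truth.realized_ibd(i, j)
            pk.k0, pk.k1, pk.k2 = k0, k1, k2
            pk.theta_auto = k1 / 4.0 + k2 / 2.0
            st = ibs_stats(store.diploid[store.index_of(i)][auto],
                           store.diploid[store.index_of(j)][auto])
            pk.ibs0, pk.ibs1, pk.ibs2 = st["ibs0"], st["ibs1"], st["ibs2"]
            pk.r0, pk.r1, pk.king_theta = st["r0"], st["r1"], st["king_theta"]
            pk.theta_x = truth.realized_theta_x(i, j)
            pk.gate_auto, pk.gate_x = True, n_x >= 1
            deg = degree_from_theta(pk.theta_auto)
            pk.degree_ml = deg
            pk.degree_read = deg
            pk.degree_final, pk.degree_source = deg, "both_agree"
            pairs.append(pk)
    return pairs, records


# ---------------------------------------------------------------------------
# Canned pedigrees for tests and examples
# ---------------------------------------------------------------------------

def nuclear_family(n_children: int = 2, prefix: str = "") -> PedigreeSpec:
    members = [PedigreeMember(f"{prefix}mother", "F"),
               PedigreeMember(f"{prefix}father", "M")]
    links = {}
    for k in range(n_children):
        cid = f"{prefix}child{k + 1}"
        members.append(PedigreeMember(cid, "M" if k % 2 == 0 else "F", 1))
        links[cid] = (f"{prefix}mother", f"{prefix}father")
    return PedigreeSpec(members, links,
                        mito_lineage={f"{prefix}mother": "mtA", f"{prefix}father": "mtB"},
                        y_lineage={f"{prefix}father": "Y1"})


def four_generation_pedigree() -> PedigreeSpec:
    """A 12-member, 4-generation family used as the pedigree-engine fixture.

    Generation 0: founding couple (gm0, gf0). Generation 1: two sibling
    sons (s1, s2) with a married-in wife (w1) for s1. Generation 2: s1's
    children c1 (M) and c2 (F), plus c2's husband (h2). Generation 3:
    c2's children d1 (M) and d2 (F); plus an extra founder couple whose
    role is to be unrelated controls (u1 male, u2 female).
    """
    members = [
        PedigreeMember("gm0", "F", 0), PedigreeMember("gf0", "M", 0),
        PedigreeMember("s1", "M", 1), PedigreeMember("s2", "M", 1),
        PedigreeMember("w1", "F", 1),
        PedigreeMember("c1", "M", 2), PedigreeMember("c2", "F", 2),
        PedigreeMember("h2", "M", 2),
        PedigreeMember("d1", "M", 3, "juvenile"),
        PedigreeMember("d2", "F", 3, "juvenile"),
        PedigreeMember("u1", "M", 0), PedigreeMember("u2", "F", 0),
    ]
    links = {
        "s1": ("gm0", "gf0"), "s2": ("gm0", "gf0"),
        "c1": ("w1", "s1"), "c2": ("w1", "s1"),
        "d1": ("c2", "h2"), "d2": ("c2", "h2"),
    }
    mito = {"gm0": "mtH1", "gf0": "mtU5", "w1": "mtK1", "h2": "mtJ2",
            "u1": "mtT2", "u2": "mtX2"}
    y = {"gf0": "R1a", "h2": "I2a", "u1": "G2a"}
    return PedigreeSpec(members, links, mito_lineage=mito, y_lineage=y)
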