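"""Core in-memory containers shared across the pipeline.

Coordinates are 1-based inclusive everywhere (EIGENSTRAT/VCF convention).
Genotype codes count copies of ``allele2`` (the variant allele); ``-1`` is
missing throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

MISSING = -1

_TRANSITION_PAIRS = {frozenset("AG"), frozenset("CT")}


def mutation_class(a1: str, a2: str) -> str:
    """Classify a biallelic site as transition or transversion."""
    pair = frozenset((a1, a2))
    if len(pair) != 2 or not pair <= set("ACGT"):
        raise ValueError(f"not a biallelic SNP: {a1}/{a2}")
    return "transition" if pair in _TRANSITION_PAIRS else "transversion"


class SNPPanel:
    """A site map: chromosome class, position, alleles, optional frequencies.

    Parameters
    ----------
    ids, chrom, chrom_class, pos, a1, a2
        Per-site arrays. ``chrom_class`` entries are ``autosome``/``X``/``Y``.
    freqs
        Optional mapping population -> frequency of ``allele2`` per site.
    """

    def __init__(self, ids, chrom, chrom_class, pos, a1, a2,
                 freqs: Mapping[str, np.ndarray] | None = None):
        self.ids = np.asarray(ids, dtype=object)
        self.chrom = np.asarray(chrom, dtype=object)
        self.chrom_class = np.asarray(chrom_class, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.a1 = np.asarray(a1, dtype=object)
        self.a2 = np.asarray(a2, dtype=object)
        self.freqs = {k: np.asarray(v, dtype=float) for k, v in (freqs or {}).items()}
        self._validate()

    # -- construction helpers -------------------------------------------------
    @classmethod
    def from_frame(cls, df: pd.DataFrame, freqs=None) -> "SNPPanel":
        return cls(df["id"], df["chrom"], df["chrom_class"], df["pos"],
                   df["a1"], df["a2"], freqs)

    def _validate(self) -> None:
        n = len(self.ids)
        for name in ("chrom", "chrom_class", "pos", "a1", "a2"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"panel column {name!r} has wrong length")
        bad = self.a1 == self.a2
        if bad.any():
            raise ValueError(f"monomorphic site at row {int(np.flatnonzero(bad)[0])}")
        unknown = ~np.isin(self.chrom_class, ["autosome", "X", "Y"])
        if unknown.any():
            raise ValueError("chrom_class must be autosome/X/Y")
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not (np.diff(p) > 0).all():
                i = int(np.flatnonzero(np.diff(p) <= 0)[0])
                raise ValueError(
                    f"positions not strictly increasing on {c} near row {i + 1}")
        for k, v in self.freqs.items():
            if len(v) != n:
                raise ValueError(f"frequency track {k!r} has wrong length")

    # -- basic API ------------------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.ids)

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def mutation_class(self) -> np.ndarray:
        return np.array([mutation_class(x, y) for x, y in zip(self.a1, self.a2)],
                        dtype=object)

    @property
    def is_transversion(self) -> np.ndarray:
        return self.mutation_class == "transversion"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": self.ids, "chrom": self.chrom, "chrom_class": self.chrom_class,
            "pos": self.pos, "a1": self.a1, "a2": self.a2,
        })

    def subset(self, mask_or_index) -> "SNPPanel":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return SNPPanel(self.ids[idx], self.chrom[idx], self.chrom_class[idx],
                        self.pos[idx], self.a1[idx], self.a2[idx],
                        {k: v[idx] for k, v in self.freqs.items()})

    def where(self, chrom_class: str) -> np.ndarray:
        return self.chrom_class == chrom_class

    def maf_mask(self, pop: str, min_maf: float = 0.1) -> np.ndarray:
        """Sites whose minor-allele frequency in `pop` is >= min_maf."""
        f = self.freqs[pop]
        return np.minimum(f, 1.0 - f) >= min_maf

    def transversion_outgroup_panel(self, pop: str, min_maf: float = 0.1) -> "SNPPanel":
        """Autosomal transversions with outgroup MAF >= min_maf.

        Mirrors the 1000-Genomes "transversions with Yoruba MAF >= 0.1"
        panel design used for outgroup-f3 work.
        """
        mask = self.is_transversion & (self.chrom_class == "autosome") & \
            self.maf_mask(pop, min_maf)
        return self.subset(mask)


class GenotypeStore:
    """Diploid calls, pseudo-haploid calls and genotype likelihoods.

    Arrays are (n_individuals, n_sites); ``diploid`` counts copies of
    allele2 in {0,1,2}, ``pseudohap`` in {0,1}, -1 missing. ``gl`` holds
    linear-scale normalized likelihood triples (NaN where missing) and
    ``gq`` phred-scaled genotype qualities.
    """

    def __init__(self, individuals: Iterable[str], panel: SNPPanel,
                 diploid=None, pseudohap=None, gl=None, gq=None):
        self.individuals = list(individuals)
        self.panel = panel
        n, m = len(self.individuals), panel.n_sites
        self.diploid = (np.full((n, m), MISSING, dtype=np.int8)
                        if diploid is None else np.asarray(diploid, dtype=np.int8))
        self.pseudohap = (np.full((n, m), MISSING, dtype=np.int8)
                          if pseudohap is None else np.asarray(pseudohap, dtype=np.int8))
        self.gl = (np.full((n, m, 3), np.nan, dtype=np.float64)
                   if gl is None else np.asarray(gl, dtype=np.float64))
        self.gq = (np.full((n, m), MISSING, dtype=np.int16)
                   if gq is None else np.asarray(gq, dtype=np.int16))
        if self.diploid.shape != (n, m) or self.gl.shape != (n, m, 3):
            raise ValueError("genotype array shapes inconsistent with panel")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def index_of(self, individual: str) -> int:
        return self.individuals.index(individual)

    def subset_sites(self, mask_or_index) -> "GenotypeStore":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeStore(self.individuals, self.panel.subset(idx),
                             self.diploid[:, idx], self.pseudohap[:, idx],
                             self.gl[:, idx, :], self.gq[:, idx])

    def subset_individuals(self, names: Iterable[str]) -> "GenotypeStore":
        names = list(names)
        rows = [self.index_of(n) for n in names]
        return GenotypeStore(names, self.panel, self.diploid[rows],
                             self.pseudohap[rows], self.gl[rows], self.gq[rows])

    def validate_gl(self, atol: float = 1e-6) -> None:
        present = ~np.isnan(self.gl[..., 0])
        if present.any():
            s = self.gl[present].sum(axis=-1)
            if not np.allclose(s, 1.0, atol=atol):
                raise ValueError("genotype-likelihood triples do not normalize")


@dataclass
class IndividualRecord:
    """Per-individual metadata and QC fields."""

    id: str
    genetic_sex: str = "unknown"          # XX / XY / unknown
    age_class: str = "unknown"            # adult / juvenile / unknown
    group: str = ""
    culture: str = ""
    mito_haplogroup: str = ""
    y_haplogroup: str | None = None
    coverage: float = float("nan")
    contamination: float | None = None
    terminal_damage: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.genetic_sex not in ("XX", "XY", "unknown"):
            raise ValueError(f"bad genetic_sex {self.genetic_sex!r}")
        if self.age_class not in ("adult", "juvenile", "unknown"):
            raise ValueError(f"bad age_class {self.age_class!r}")
        for name in ("contamination", "terminal_damage"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} out of [0,1]: {v}")


def records_to_frame(records: Iterable[IndividualRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = {k: getattr(r, k) for k in (
            "id", "genetic_sex", "age_class", "group", "culture",
            "mito_haplogroup", "y_haplogroup", "coverage", "contamination",
            "terminal_damage")}
        rows.append(d)
    return pd.DataFrame(rows)
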