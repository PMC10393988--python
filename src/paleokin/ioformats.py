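"""Readers and writers for the text formats the pipeline touches.

EIGENSTRAT geno/snp/ind triplets, a VCF dialect carrying GT/PL/GQ and
``INFO AF_<POP>`` population frequencies, metadata TSVs, and panel
thinning. All readers reject malformed input with the offending line
number rather than coercing; every writer produces files its own reader
accepts (round-trip property, covered in tests).
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeStore, IndividualRecord, SNPPanel

log = logging.getLogger(__name__)

_CHROM_CLASS = {"23": "X", "X": "X", "24": "Y", "Y": "Y"}


def _class_of(chrom: str) -> str:
    return _CHROM_CLASS.get(str(chrom), "autosome")


# ---------------------------------------------------------------------------
# EIGENSTRAT
# ---------------------------------------------------------------------------

def read_eigenstrat(prefix: str | Path):
    """Read a geno/snp/ind triplet.

    Geno digits count copies of allele1 (the EIGENSTRAT reference-allele
    convention); they are converted to the internal allele2-count code.
    Returns ``(panel, store, records)``.
    """
    prefix = Path(prefix)
    snp_rows = []
    seen = set()
    with open(f"{prefix}.snp") as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 6:
                raise ValueError(f"{prefix}.snp line {ln}: expected 6 columns")
            sid, chrom, _gpos, pos, a1, a2 = parts[:6]
            if sid in seen:
                raise ValueError(f"{prefix}.snp line {ln}: duplicate site id {sid!r}")
            seen.add(sid)
            snp_rows.append((sid, chrom, _class_of(chrom), int(pos), a1, a2))
    df = pd.DataFrame(snp_rows, columns=["id", "chrom", "chrom_class", "pos", "a1", "a2"])
    try:
        panel = SNPPanel.from_frame(df)
    except ValueError as e:
        raise ValueError(f"{prefix}.snp: {e}") from e

    ind_rows = []
    with open(f"{prefix}.ind") as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 3:
                raise ValueError(f"{prefix}.ind line {ln}: expected 3 columns")
            ind_rows.append(parts)
    names = [r[0] for r in ind_rows]
    sex_map = {"M": "XY", "F": "XX", "U": "unknown"}
    records = [IndividualRecord(id=r[0], genetic_sex=sex_map.get(r[1], "unknown"),
                                group=r[2]) for r in ind_rows]

    n, m = len(names), panel.n_sites
    diploid = np.full((m, n), MISSING, dtype=np.int8)
    with open(f"{prefix}.geno") as fh:
        ln = 0
        for ln, line in enumerate(fh, 1):
            row = line.rstrip("\n")
            if len(row) != n:
                raise ValueError(
                    f"{prefix}.geno line {ln}: expected {n} characters, got {len(row)}")
            for j, ch in enumerate(row):
                if ch == "9":
                    continue
                if ch not in "012":
                    raise ValueError(f"{prefix}.geno line {ln}: unknown character {ch!r}")
                # geno digit counts allele1 copies; internal code counts allele2
                diploid[ln - 1, j] = 2 - int(ch)
        if ln != m:
            raise ValueError(f"{prefix}.geno: {ln} lines but {m} snp records")
    store = GenotypeStore(names, panel, diploid=diploid.T)
    return panel, store, records


def write_eigenstrat(prefix: str | Path, panel: SNPPanel, store: GenotypeStore,
                     records: Iterable[IndividualRecord] | None = None) -> None:
    prefix = Path(prefix)
    chrom_out = {"X": "23", "Y": "24"}
    with open(f"{prefix}.snp", "w") as fh:
        for i in range(panel.n_sites):
            chrom = chrom_out.get(str(panel.chrom_class[i]), str(panel.chrom[i]))
            fh.write(f"{panel.ids[i]}\t{chrom}\t0.0\t{panel.pos[i]}"
                     f"\t{panel.a1[i]}\t{panel.a2[i]}\n")
    recs = {r.id: r for r in (records or [])}
    sex_out = {"XY": "M", "XX": "F", "unknown": "U"}
    with open(f"{prefix}.ind", "w") as fh:
        for name in store.individuals:
            r = recs.get(name)
            sex = sex_out[r.genetic_sex] if r else "U"
            grp = (r.group or "Pop") if r else "Pop"
            fh.write(f"{name}\t{sex}\t{grp}\n")
    dip = store.diploid
    with open(f"{prefix}.geno", "w") as fh:
        for i in range(panel.n_sites):
            chars = ["9" if dip[j, i] == MISSING else str(2 - int(dip[j, i]))
                     for j in range(store.n_individuals)]
            fh.write("".join(chars) + "\n")


# ---------------------------------------------------------------------------
# VCF with genotype likelihoods
# ---------------------------------------------------------------------------

def read_vcf_gl(path: str | Path):
    """Read a VCF with GT + PL (or GL) into a panel and store.

    Multiallelic records are skipped with a logged count; INFO ``AF_<POP>``
    tags become population frequency tracks on the panel. Raises if no
    record carries PL/GL.
    """
    names: list[str] = []
    rows, dip, gls, gqs = [], [], [], []
    freq_tracks: dict[str, list[float]] = {}
    n_multi = 0
    any_pl = False
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                names = line.rstrip("\n").split("\t")[9:]
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 10:
                raise ValueError(f"{path} line {ln}: truncated record")
            chrom, pos, sid, ref, alt = parts[0], parts[1], parts[2], parts[3], parts[4]
            if "," in alt or alt == ".":
                n_multi += 1
                continue
            info = dict(kv.split("=", 1) for kv in parts[7].split(";")
                        if "=" in kv) if parts[7] not in (".", "") else {}
            fmt = parts[8].split(":")
            rows.append((sid if sid != "." else f"{chrom}_{pos}", chrom,
                         _class_of(chrom), int(pos), ref, alt))
            for key, val in info.items():
                if key.startswith("AF_"):
                    freq_tracks.setdefault(key[3:], []).append(float(val))
            gt_i = fmt.index("GT") if "GT" in fmt else None
            pl_i = fmt.index("PL") if "PL" in fmt else None
            gl_i = fmt.index("GL") if "GL" in fmt else None
            gq_i = fmt.index("GQ") if "GQ" in fmt else None
            drow, lrow, qrow = [], [], []
            for cell in parts[9:]:
                fields = cell.split(":")
                g = MISSING
                if gt_i is not None and gt_i < len(fields):
                    gt = fields[gt_i].replace("|", "/")
                    if "." not in gt:
                        g = sum(int(x) for x in gt.split("/"))
                drow.append(g)
                trip = (np.nan, np.nan, np.nan)
                if pl_i is not None and pl_i < len(fields) and fields[pl_i] != ".":
                    pl = np.array([float(x) for x in fields[pl_i].split(",")])
                    lin = 10 ** (-pl / 10.0)
                    trip = tuple(lin / lin.sum())
                    any_pl = True
                elif gl_i is not None and gl_i < len(fields) and fields[gl_i] != ".":
                    gl10 = np.array([float(x) for x in fields[gl_i].split(",")])
                    lin = 10 ** (gl10 - gl10.max())
                    trip = tuple(lin / lin.sum())
                    any_pl = True
                lrow.append(trip)
                q = MISSING
                if gq_i is not None and gq_i < len(fields) and fields[gq_i] != ".":
                    q = int(fields[gq_i])
                qrow.append(q)
            dip.append(drow)
            gls.append(lrow)
            gqs.append(qrow)
    if n_multi:
        log.info("skipped %d multiallelic records in %s", n_multi, path)
    if not any_pl:
        raise ValueError(f"{path}: no record carries PL or GL genotype likelihoods")
    df = pd.DataFrame(rows, columns=["id", "chrom", "chrom_class", "pos", "a1", "a2"])
    freqs = {k: np.array(v) for k, v in freq_tracks.items()
             if len(v) == len(df)}
    panel = SNPPanel.from_frame(df, freqs)
    store = GenotypeStore(names, panel,
                          diploid=np.array(dip, dtype=np.int8).T,
                          gl=np.transpose(np.array(gls, dtype=float), (1, 0, 2)),
                          gq=np.array(gqs, dtype=np.int16).T)
    store.n_multiallelic_skipped = n_multi
    return panel, store


def write_vcf_gl(path: str | Path, panel: SNPPanel, store: GenotypeStore) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=PL,Number=G,Type=Integer,Description="Phred likelihoods">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        for pop in panel.freqs:
            fh.write(f'##INFO=<ID=AF_{pop},Number=1,Type=Float,'
                     f'Description="Allele2 frequency in {pop}">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(store.individuals) + "\n")
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for i in range(panel.n_sites):
            info = ";".join(f"AF_{p}={panel.freqs[p][i]:.6f}" for p in panel.freqs) or "."
            cells = []
            for j in range(store.n_individuals):
                gt = gt_str[int(store.diploid[j, i])]
                trip = store.gl[j, i]
                if np.isnan(trip[0]):
                    pl = "."
                else:
                    with np.errstate(divide="ignore"):
                        phred = -10 * np.log10(np.maximum(trip, 1e-300))
                    phred -= phred.min()
                    pl = ",".join(str(int(round(min(x, 9999)))) for x in phred)
                gq = "." if store.gq[j, i] == MISSING else str(int(store.gq[j, i]))
                cells.append(f"{gt}:{pl}:{gq}")
            fh.write(f"{panel.chrom[i]}\t{panel.pos[i]}\t{panel.ids[i]}\t"
                     f"{panel.a1[i]}\t{panel.a2[i]}\t.\t.\t{info}\tGT:PL:GQ\t"
                     + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Thinning and metadata
# ---------------------------------------------------------------------------

def thin_by_distance(panel: SNPPanel, min_gap: int) -> SNPPanel:
    """Greedy left-to-right LD thinning: keep a site only if it lies at
    least ``min_gap`` bp after the last kept site on its chromosome.

    Deterministic; ``min_gap=0`` is the identity. Mirrors the
    ``vcftools --thin`` behaviour used for per-pair panels.
    """
    if min_gap < 0:
        raise ValueError("min_gap must be >= 0")
    keep = np.zeros(panel.n_sites, dtype=bool)
    last: dict[str, int] = {}
    for i in range(panel.n_sites):
        c = panel.chrom[i]
        if c not in last or panel.pos[i] - last[c] >= min_gap:
            keep[i] = True
            last[c] = int(panel.pos[i])
    return panel.subset(keep)


_META_COLS = ["id", "genetic_sex", "age_class", "group", "culture",
              "mito_haplogroup", "y_haplogroup", "coverage", "contamination",
              "terminal_damage"]


def read_metadata(path: str | Path) -> list[IndividualRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    records = []
    for _, row in df.iterrows():
        kwargs = {}
        for col in _META_COLS:
            if col in df.columns and not (isinstance(row[col], float)
                                          and math.isnan(row[col])):
                kwargs[col] = row[col]
        for opt in ("contamination", "terminal_damage", "coverage"):
            if opt in kwargs:
                kwargs[opt] = float(kwargs[opt])
        records.append(IndividualRecord(**kwargs))
    return records


def write_metadata(path: str | Path, records: Iterable[IndividualRecord]) -> None:
    from .core import records_to_frame
    records_to_frame(records).to_csv(path, sep="\t", index=False)
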