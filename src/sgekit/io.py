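"""File formats, genotype quality control and run configuration.

Formats are deliberately plain: a 3-column pedigree (animal, sire, dam with
0/NA for unknown), a delimited phenotype table with named columns, genotypes
either as a PLINK PED/MAP pair (ACGT/0 alleles) or as a dosage matrix with a
4-column MAP (chrom, marker, cM -- ignored --, bp), and a key = value
configuration file.  All writers round-trip losslessly through the readers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .relatedness import GenotypeMatrix, Pedigree, PedigreeError

log = logging.getLogger(__name__)

PHENOTYPE_COLUMNS = ("animal", "y", "yearmonth", "sex", "pen", "group",
                     "litter", "dam", "age")


# ---------------------------------------------------------------- pedigree

def read_pedigree(path) -> Pedigree:
    """Read a 3-column pedigree file (header optional, 0/NA = unknown).

    Records listed before their parents are reordered automatically (with a
    warning); cycles and parents that never appear as animals are errors.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if ln == 1 and parts[0].lower() in ("animal", "id"):
                continue
            if len(parts) < 3:
                raise PedigreeError(f"{path}:{ln}: expected 3 columns")
            rows.append(tuple(parts[:3]))
    order_ok = True
    seen = set()
    for a, s, d in rows:
        for p in (s, d):
            if p not in ("0", "NA", "") and p not in seen:
                order_ok = False
        seen.add(a)
    if not order_ok:
        log.warning("%s: offspring listed before parents; reordering", path)
    return Pedigree.from_records(rows, reorder=True)


def write_pedigree(pedigree: Pedigree, path) -> None:
    with open(path, "w") as fh:
        fh.write("animal sire dam\n")
        for i, a in enumerate(pedigree.ids):
            s = pedigree.ids[pedigree.sire[i]] if pedigree.sire[i] >= 0 else "0"
            d = pedigree.ids[pedigree.dam[i]] if pedigree.dam[i] >= 0 else "0"
            fh.write(f"{a} {s} {d}\n")


# -------------------------------------------------------------- phenotypes

def read_phenotypes(path):
    """Delimited phenotype table with the named model columns."""
    from .model import GroupedPhenotypes

    df = pd.read_csv(path, sep=r"\s+")
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing phenotype columns {missing}")
    df = df.astype({c: str for c in ("animal", "yearmonth", "sex", "pen",
                                     "group", "litter", "dam")})
    return GroupedPhenotypes(df[list(PHENOTYPE_COLUMNS)])


def write_phenotypes(data, path) -> None:
    data.records[list(PHENOTYPE_COLUMNS)].to_csv(
        path, sep=" ", index=False, float_format="%.10g")


# --------------------------------------------------------------- genotypes

def _read_map(path) -> pd.DataFrame:
    mp = pd.read_csv(path, sep=r"\s+", header=None,
                     names=["chrom", "marker", "cm", "bp"])
    mp = mp.astype({"chrom": str, "marker": str, "bp": np.int64})
    out = mp[["marker", "chrom", "bp"]]
    if not out.sort_values(["chrom", "bp"]).equals(out.reset_index(drop=True)):
        out = out.sort_values(["chrom", "bp"], kind="stable").reset_index(
            drop=True)
    return out


def read_dosage_matrix(dosage_path, map_path) -> GenotypeMatrix:
    """Plain dosage matrix (first column id) with its 4-column MAP file."""
    marker_map = _read_map(map_path)
    ids = []
    rows = []
    with open(dosage_path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if ln == 1 and parts[0].lower() in ("animal", "id"):
                continue
            ids.append(parts[0])
            try:
                rows.append([float(v) if v != "NA" else np.nan
                             for v in parts[1:]])
            except ValueError as exc:
                raise ValueError(
                    f"{dosage_path}:{ln}: non-numeric dosage") from exc
    if len(set(ids)) != len(ids):
        raise ValueError(f"{dosage_path}: duplicate animal ids")
    dosages = np.array(rows, dtype=float)
    if dosages.shape[1] != len(marker_map):
        raise ValueError("dosage column count does not match the MAP file")
    return GenotypeMatrix(dosages=dosages, animal_ids=ids,
                          marker_map=marker_map)


def write_dosage_matrix(gm: GenotypeMatrix, dosage_path, map_path) -> None:
    with open(map_path, "w") as fh:
        for _, r in gm.marker_map.iterrows():
            fh.write(f"{r['chrom']} {r['marker']} 0 {r['bp']}\n")
    with open(dosage_path, "w") as fh:
        for aid, row in zip(gm.animal_ids, gm.dosages):
            vals = " ".join("NA" if np.isnan(v) else "%g" % v for v in row)
            fh.write(f"{aid} {vals}\n")


def read_plink(ped_path, map_path) -> GenotypeMatrix:
    """PLINK PED/MAP pair; dosages count the minor allele at each marker.

    Alleles are ACGT with 0 for missing; the counted (tracked) allele per
    marker is the less frequent one, so stored allele frequencies are minor
    allele frequencies.
    """
    marker_map = _read_map(map_path)
    m = len(marker_map)
    ids = []
    geno: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f"{ped_path}:{ln}: expected {6 + 2 * m} fields, "
                    f"got {len(parts)}")
            ids.append(parts[1])
            alleles = parts[6:]
            geno.append([(alleles[2 * j], alleles[2 * j + 1])
                         for j in range(m)])
    if len(set(ids)) != len(ids):
        raise ValueError(f"{ped_path}: duplicate animal ids")
    dosages = np.full((len(ids), m), np.nan)
    for j in range(m):
        counts: dict[str, int] = {}
        for i in range(len(ids)):
            for al in geno[i][j]:
                if al != "0":
                    counts[al] = counts.get(al, 0) + 1
        if not counts:
            continue
        if len(counts) > 2:
            raise ValueError(f"marker {j} has more than two alleles")
        minor = min(sorted(counts), key=lambda k: counts[k])
        for i in range(len(ids)):
            a1, a2 = geno[i][j]
            if a1 == "0" or a2 == "0":
                continue
            dosages[i, j] = (a1 == minor) + (a2 == minor)
    return GenotypeMatrix(dosages=dosages, animal_ids=ids,
                          marker_map=marker_map)


# ---------------------------------------------------------------------- QC

@dataclass(frozen=True)
class QcThresholds:
    """Genotype quality-control thresholds (None disables a rule)."""

    maf_min: float | None = 0.05
    marker_call_rate_min: float | None = 0.90
    animal_call_rate_min: float | None = 0.90
    hwe_p_min: float | None = 1e-6
    drop_sex_chromosomes: bool = True
    drop_monomorphic: bool = True
    sex_chromosomes: tuple[str, ...] = ("X", "Y")


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided exact Hardy-Weinberg test on genotype counts.

    Conditional on the allele counts, the heterozygote count follows a
    known distribution under HWE; the p-value sums the probabilities of all
    outcomes no more likely than the observed one (Wigginton et al. 2005).
    """
    n = n_aa + n_ab + n_bb
    if n == 0:
        return 1.0
    n_a = 2 * n_aa + n_ab  # rarer allele by convention below
    if n_a > n:  # make 'a' the rarer allele
        n_a = 2 * n - n_a
    logprob = {}
    # unnormalised log-probabilities via the hypergeometric-style recurrence
    import math

    h0 = n_a % 2
    lp = 0.0
    logprob[h0] = lp
    for h in range(h0, n_a - 1, 2):
        rare_hom = (n_a - h) // 2
        common_hom = n - h - rare_hom
        lp += math.log((h + 2.0) * (h + 1.0)) * -1 + math.log(
            4.0 * rare_hom * common_hom)
        logprob[h + 2] = lp
    mx = max(logprob.values())
    probs = {h: math.exp(v - mx) for h, v in logprob.items()}
    total = sum(probs.values())
    p_obs = probs[n_ab] / total
    return min(1.0, sum(p for p in probs.values() if p / total <= p_obs * (
        1 + 1e-12)) / total)


def qc_genotypes(
    gm: GenotypeMatrix, thresholds: QcThresholds | None = None
) -> tuple[GenotypeMatrix, dict]:
    """Filter genotypes, then mean-impute remaining missing dosages.

    Rules apply in a fixed order: animal call rate, marker call rate,
    monomorphic markers, minor-allele frequency, Hardy-Weinberg exact-test
    p-value, sex-chromosome markers.  The report counts removals per rule.
    """
    thresholds = thresholds or QcThresholds()
    report: dict[str, int] = {}
    dos = gm.dosages.copy()
    ids = list(gm.animal_ids)
    mmap = gm.marker_map.reset_index(drop=True)

    if thresholds.animal_call_rate_min is not None:
        call = 1.0 - np.isnan(dos).mean(axis=1)
        keep = call >= thresholds.animal_call_rate_min
        report["animal_call_rate"] = int((~keep).sum())
        dos = dos[keep]
        ids = [a for a, k in zip(ids, keep) if k]
    else:
        report["animal_call_rate"] = 0

    def drop_markers(mask_keep: np.ndarray, rule: str):
        nonlocal dos, mmap
        report[rule] = int((~mask_keep).sum())
        dos = dos[:, mask_keep]
        mmap = mmap[mask_keep].reset_index(drop=True)

    if thresholds.marker_call_rate_min is not None:
        call = 1.0 - np.isnan(dos).mean(axis=0)
        drop_markers(call >= thresholds.marker_call_rate_min,
                     "marker_call_rate")
    else:
        report["marker_call_rate"] = 0

    with np.errstate(invalid="ignore"):
        freq = np.nanmean(dos, axis=0) / 2.0
    if thresholds.drop_monomorphic:
        drop_markers(~((freq == 0.0) | (freq == 1.0)), "monomorphic")
        freq = np.nanmean(dos, axis=0) / 2.0 if dos.shape[1] else freq[:0]
    else:
        report["monomorphic"] = 0

    if thresholds.maf_min is not None and dos.shape[1]:
        maf = np.minimum(freq, 1.0 - freq)
        drop_markers(maf >= thresholds.maf_min, "maf")
        freq = np.nanmean(dos, axis=0) / 2.0 if dos.shape[1] else freq[:0]
    else:
        report["maf"] = 0

    if thresholds.hwe_p_min is not None and dos.shape[1]:
        keep = np.ones(dos.shape[1], dtype=bool)
        for j in range(dos.shape[1]):
            col = dos[:, j]
            col = col[~np.isnan(col)]
            p = hwe_exact_test(int((col == 2).sum()), int((col == 1).sum()),
                               int((col == 0).sum()))
            keep[j] = p >= thresholds.hwe_p_min
        drop_markers(keep, "hwe")
    else:
        report["hwe"] = 0

    if thresholds.drop_sex_chromosomes and dos.shape[1]:
        on_sex = mmap["chrom"].isin(thresholds.sex_chromosomes).to_numpy()
        drop_markers(~on_sex, "sex_chromosome")
    else:
        report["sex_chromosome"] = 0

    if dos.shape[1] == 0:
        raise ValueError("quality control removed every marker")

    # mean imputation of residual missingness, per marker
    col_mean = np.nanmean(dos, axis=0)
    nan_r, nan_c = np.where(np.isnan(dos))
    dos[nan_r, nan_c] = col_mean[nan_c]
    report["imputed_dosages"] = int(len(nan_r))
    return GenotypeMatrix(dosages=dos, animal_ids=ids, marker_map=mmap), report


# ------------------------------------------------------------------ config

@dataclass
class RunConfig:
    """Pipeline configuration, serialisable as plain ``key = value`` text."""

    pedigree_file: str = ""
    phenotype_file: str = ""
    dosage_file: str = ""
    map_file: str = ""
    out_dir: str = "results"
    rounds: int = 55_000
    burn_in: int = 5_000
    thin: int = 5
    seed: int = 20191709
    eps_blend: float = 0.05
    window_bp: int = 1_000_000
    qtl_threshold_pct: float = 0.5
    n_weight_iterations: int = 2
    effect_kind: str = "SGE"
    maf_min: float = 0.05
    marker_call_rate_min: float = 0.90
    animal_call_rate_min: float = 0.90
    hwe_p_min: float = 1e-6


def read_config(path) -> RunConfig:
    values: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}: malformed config line {line!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            values[key] = val
    cfg = RunConfig()
    for f in fields(RunConfig):
        if f.name in values:
            raw = values.pop(f.name)
            typ = type(getattr(cfg, f.name))
            setattr(cfg, f.name, typ(raw))
    if values:
        raise ValueError(f"{path}: unknown config keys {sorted(values)}")
    return cfg


def write_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        for f in fields(RunConfig):
            fh.write(f"{f.name} = {getattr(cfg, f.name)}\n")


# ----------------------------------------------------------------- results

def write_table(df: pd.DataFrame, path) -> None:
    """Deterministic delimited output used for every result table."""
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
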