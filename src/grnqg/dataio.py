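"""Genotype, map, phenotype and tree I/O plus pre-analysis quality control.

In-memory containers
--------------------
:class:`GenotypeMatrix`
    strains x markers integer matrix, codes 0/1/2 with ``-1`` for missing.
    Code 0 is the reference (parent-A / N2-like) homozygote, 2 the alternate
    homozygote, 1 a heterozygote (rare in the nominally inbred material this
    package targets; preserved at I/O and handled per-analysis).
:class:`MarkerMap`
    per-marker chromosome, physical position (bp, 1-based as in VCF) and
    genetic position (cM, chromosome-local).
:class:`PhenotypeTable`
    per (strain, trait) penetrance value in [0, 1], optionally backed by
    replicate-level embryo counts (scored / with differentiated gut).

On-disk formats
---------------
* vcftools ``--012`` trio: ``<prefix>.012`` (rows = samples, first column a
  0-based sample index, ``-1`` = missing), ``<prefix>.012.indv`` (sample
  names), ``<prefix>.012.pos`` (chrom, pos).
* minimal VCF (GT-only); read via cyvcf2, written as plain text.
* phenotype CSV in long form (strain, trait, value, n_scored, n_with_gut,
  replicate) and a wide convenience form.
* marker-map TSV (marker, chrom, bp, cM) and Newick trees via dendropy.

Readers reject dimensionally inconsistent inputs instead of truncating.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, FormatError

MISSING = -1

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "MarkerMap",
    "PhenotypeTable",
    "QcReport",
    "read_012_trio",
    "write_012_trio",
    "read_vcf_minimal",
    "write_vcf_minimal",
    "read_phenotypes_csv",
    "write_phenotypes_csv",
    "read_marker_map",
    "write_marker_map",
    "read_newick",
    "write_newick",
    "qc_filter",
    "assign_cm_from_bp",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    strain_ids: list[str]
    marker_ids: list[str]
    values: np.ndarray  # (n_strains, n_markers) int8/int16; MISSING == -1

    def __post_init__(self) -> None:
        self.strain_ids = [str(s) for s in self.strain_ids]
        self.marker_ids = [str(m) for m in self.marker_ids]
        self.values = np.asarray(self.values, dtype=np.int8)
        n, m = self.values.shape
        if n != len(self.strain_ids) or m != len(self.marker_ids):
            raise DataError(
                f"genotype matrix {self.values.shape} inconsistent with "
                f"{len(self.strain_ids)} strains / {len(self.marker_ids)} markers"
            )
        if len(set(self.strain_ids)) != n:
            raise DataError("duplicate strain ids")
        if len(set(self.marker_ids)) != m:
            raise DataError("duplicate marker ids")
        bad = ~np.isin(self.values, (MISSING, 0, 1, 2))
        if bad.any():
            raise DataError(f"genotype codes outside {{-1,0,1,2}} at {bad.sum()} cells")

    @property
    def n_strains(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def observed(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return self.values != MISSING

    def sample_missing_fraction(self) -> np.ndarray:
        return (self.values == MISSING).mean(axis=1)

    def maf(self) -> np.ndarray:
        """Minor allele frequency per marker; missing calls excluded from the
        denominator. Markers with no calls at all get MAF 0."""
        obs = self.observed()
        vals = np.where(obs, self.values, 0)
        n_called = obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_alt = vals.sum(axis=0) / (2.0 * n_called)
        p_alt = np.where(n_called > 0, p_alt, 0.0)
        return np.minimum(p_alt, 1.0 - p_alt)

    def subset(self, strains=None, markers=None) -> "GenotypeMatrix":
        """Subset by boolean masks or index arrays (order preserved)."""
        si = np.arange(self.n_strains) if strains is None else np.asarray(strains)
        mi = np.arange(self.n_markers) if markers is None else np.asarray(markers)
        if si.dtype == bool:
            si = np.flatnonzero(si)
        if mi.dtype == bool:
            mi = np.flatnonzero(mi)
        return GenotypeMatrix(
            [self.strain_ids[i] for i in si],
            [self.marker_ids[j] for j in mi],
            self.values[np.ix_(si, mi)],
        )

    def strain_index(self, names) -> np.ndarray:
        lut = {s: i for i, s in enumerate(self.strain_ids)}
        try:
            return np.array([lut[str(n)] for n in names], dtype=int)
        except KeyError as exc:
            raise DataError(f"unknown strain {exc.args[0]!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.strain_ids, columns=self.marker_ids)


@dataclass
class MarkerMap:
    """Marker coordinates, ordered as the genotype matrix columns.

    ``frame`` is indexed by marker id with columns ``chrom`` (str), ``bp``
    (int, 1-based) and ``cM`` (float, chromosome-local; may be NaN when only
    physical positions are known).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"chrom", "bp", "cM"}
        if not need.issubset(self.frame.columns):
            raise DataError(f"marker map needs columns {sorted(need)}")
        if self.frame.index.duplicated().any():
            raise DataError("duplicate marker ids in map")
        f = self.frame
        for chrom, sub in f.groupby("chrom", sort=False):
            s = sub.sort_values("bp")
            cm = s["cM"].to_numpy(float)
            cm = cm[~np.isnan(cm)]
            if cm.size and np.any(np.diff(cm) < -1e-9):
                raise DataError(f"genetic positions decrease along {chrom}")

    @classmethod
    def from_arrays(cls, marker_ids, chrom, bp, cM=None) -> "MarkerMap":
        cM = np.full(len(marker_ids), np.nan) if cM is None else cM
        return cls(
            pd.DataFrame(
                {"chrom": [str(c) for c in chrom],
                 "bp": np.asarray(bp, dtype=np.int64),
                 "cM": np.asarray(cM, dtype=float)},
                index=[str(m) for m in marker_ids],
            )
        )

    @property
    def marker_ids(self) -> list[str]:
        return list(self.frame.index)

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.frame["chrom"]:
            seen.setdefault(c, None)
        return list(seen)

    def chrom_markers(self, chrom: str) -> np.ndarray:
        """Column indices of markers on ``chrom`` ordered by physical position."""
        idx = np.flatnonzero((self.frame["chrom"] == chrom).to_numpy())
        order = np.argsort(self.frame["bp"].to_numpy()[idx], kind="stable")
        return idx[order]

    def sorted_by_position(self, genotypes: GenotypeMatrix):
        """Return (genotypes, map) with markers sorted by (chromosome in input
        order, physical position)."""
        order = np.concatenate([self.chrom_markers(c) for c in self.chromosomes()])
        gm = genotypes.subset(markers=order)
        mm = MarkerMap(self.frame.iloc[order])
        return gm, mm


def assign_cm_from_bp(marker_map: MarkerMap, cm_per_mb: float = 4.0) -> MarkerMap:
    """Fill genetic positions from physical ones at a constant rate.

    Default 4 cM/Mb (1 cM per 250 kb), a round figure for a compact
    nematode-like genome; each chromosome starts at 0 cM.
    """
    f = marker_map.frame.copy()
    f["cM"] = f["bp"].to_numpy(np.float64) * (cm_per_mb / 1e6)
    for chrom in marker_map.chromosomes():
        sel = f["chrom"] == chrom
        f.loc[sel, "cM"] -= f.loc[sel, "cM"].min()
    return MarkerMap(f)


@dataclass
class PhenotypeTable:
    """Penetrance phenotypes: fraction of arrested embryos with differentiated
    gut, per strain and trait.

    ``values`` is wide (index = strain, one column per trait, floats in
    [0, 1], NaN = unscored). ``replicates``, when present, is long with
    columns (strain, trait, replicate, n_scored, n_with_gut); the wide value
    must equal the mean of per-replicate fractions.
    """

    values: pd.DataFrame
    replicates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        v = self.values.to_numpy(float)
        if np.nanmin(v, initial=0.0) < -1e-12 or np.nanmax(v, initial=0.0) > 1 + 1e-12:
            raise DataError("penetrance values outside [0, 1]")
        if self.values.index.duplicated().any():
            raise DataError("duplicate strains in phenotype table")
        if self.replicates is not None:
            r = self.replicates
            need = {"strain", "trait", "replicate", "n_scored", "n_with_gut"}
            if not need.issubset(r.columns):
                raise DataError(f"replicate table needs columns {sorted(need)}")
            if (r["n_with_gut"] > r["n_scored"]).any():
                raise DataError("n_with_gut exceeds n_scored")
            frac = r["n_with_gut"] / r["n_scored"]
            agg = frac.groupby([r["strain"], r["trait"]]).mean()
            for (strain, trait), mean_frac in agg.items():
                got = self.values.at[strain, trait]
                if not np.isclose(got, mean_frac, atol=1e-9):
                    raise DataError(
                        f"value for ({strain}, {trait}) not reproducible from "
                        f"replicate counts: {got} vs {mean_frac}"
                    )

    @property
    def traits(self) -> list[str]:
        return list(self.values.columns)

    def trait_vector(self, trait: str, strains=None) -> pd.Series:
        """Phenotype for one trait, optionally aligned to a strain list."""
        if trait not in self.values.columns:
            raise DataError(f"unknown trait {trait!r}")
        s = self.values[trait]
        if strains is not None:
            s = s.reindex([str(x) for x in strains])
        return s


# ---------------------------------------------------------------------------
# vcftools 012 trio
# ---------------------------------------------------------------------------

def write_012_trio(prefix: str | os.PathLike, genotypes: GenotypeMatrix,
                   marker_map: MarkerMap) -> None:
    prefix = os.fspath(prefix)
    if marker_map.marker_ids != genotypes.marker_ids:
        raise DataError("marker map does not match genotype matrix columns")
    with open(prefix + ".012", "w") as fh:
        for i in range(genotypes.n_strains):
            row = "\t".join(str(int(v)) for v in genotypes.values[i])
            fh.write(f"{i}\t{row}\n")
    with open(prefix + ".012.indv", "w") as fh:
        fh.write("\n".join(genotypes.strain_ids) + "\n")
    with open(prefix + ".012.pos", "w") as fh:
        for _, rec in marker_map.frame.iterrows():
            fh.write(f"{rec['chrom']}\t{int(rec['bp'])}\n")


def read_012_trio(prefix: str | os.PathLike) -> tuple[GenotypeMatrix, MarkerMap]:
    prefix = os.fspath(prefix)
    for suffix in (".012", ".012.indv", ".012.pos"):
        if not os.path.exists(prefix + suffix):
            raise FormatError(f"missing file {prefix + suffix}")
    with open(prefix + ".012.indv") as fh:
        strains = [ln.strip() for ln in fh if ln.strip()]
    chroms: list[str] = []
    bps: list[int] = []
    with open(prefix + ".012.pos") as fh:
        for lineno, ln in enumerate(fh, 1):
            if not ln.strip():
                continue
            parts = ln.split()
            if len(parts) < 2:
                raise FormatError(f"{prefix}.012.pos line {lineno}: expected chrom and pos")
            chroms.append(parts[0])
            bps.append(int(parts[1]))
    rows = []
    with open(prefix + ".012") as fh:
        for lineno, ln in enumerate(fh, 1):
            if not ln.strip():
                continue
            parts = ln.split()
            vals = [int(x) for x in parts[1:]]  # first column = sample index
            if len(vals) != len(bps):
                raise FormatError(
                    f"{prefix}.012 line {lineno}: {len(vals)} genotypes, "
                    f"{len(bps)} positions in {prefix}.012.pos"
                )
            rows.append(vals)
    if len(rows) != len(strains):
        raise FormatError(
            f"{prefix}.012 has {len(rows)} rows but {prefix}.012.indv "
            f"lists {len(strains)} samples"
        )
    marker_ids = [f"{c}:{p}" for c, p in zip(chroms, bps)]
    gm = GenotypeMatrix(strains, marker_ids, np.array(rows, dtype=np.int8))
    mm = MarkerMap.from_arrays(marker_ids, chroms, bps)
    return gm, mm


# ---------------------------------------------------------------------------
# minimal VCF (GT only)
# ---------------------------------------------------------------------------

_GT_CODE = {(0, 0): 0, (0, 1): 1, (1, 0): 1, (1, 1): 2}


def write_vcf_minimal(path: str | os.PathLike, genotypes: GenotypeMatrix,
                      marker_map: MarkerMap) -> None:
    """Write a GT-only VCF; homozygous codes become 0/0 and 1/1 diploid calls."""
    if marker_map.marker_ids != genotypes.marker_ids:
        raise DataError("marker map does not match genotype matrix columns")
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in marker_map.chromosomes():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.strain_ids) + "\n")
        for j, (mid, rec) in enumerate(marker_map.frame.iterrows()):
            calls = "\t".join(gt_str[int(v)] for v in genotypes.values[:, j])
            fh.write(f"{rec['chrom']}\t{int(rec['bp'])}\t{mid}\tA\tT\t.\tPASS\t.\tGT\t{calls}\n")


def read_vcf_minimal(path: str | os.PathLike) -> tuple[GenotypeMatrix, MarkerMap]:
    """Read a diploid GT-only VCF into genotype codes.

    0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2, ./. -> missing. Multi-allelic sites
    are skipped; their count is reported on the returned map as the attribute
    ``n_multiallelic_skipped``.
    """
    from cyvcf2 import VCF

    path = os.fspath(path)
    if not os.path.exists(path):
        raise FormatError(f"no such VCF: {path}")
    vcf = VCF(path)
    strains = list(vcf.samples)
    if not strains:
        raise FormatError(f"{path}: no samples / GT field")
    cols: list[np.ndarray] = []
    ids: list[str] = []
    chroms: list[str] = []
    bps: list[int] = []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) > 1:
            n_multi += 1
            continue
        gts = rec.genotype.array()  # (n, ploidy+1); -1 = missing allele
        alleles = gts[:, :2]
        col = np.where((alleles < 0).any(axis=1), MISSING, alleles.clip(min=0).sum(axis=1))
        cols.append(col.astype(np.int8))
        ids.append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}")
        chroms.append(rec.CHROM)
        bps.append(rec.POS)
    vcf.close()
    if not cols:
        raise FormatError(f"{path}: no biallelic records")
    gm = GenotypeMatrix(strains, ids, np.column_stack(cols))
    mm = MarkerMap.from_arrays(ids, chroms, bps)
    mm.n_multiallelic_skipped = n_multi  # type: ignore[attr-defined]
    return gm, mm


# ---------------------------------------------------------------------------
# phenotype CSV, map TSV, newick
# ---------------------------------------------------------------------------

def write_phenotypes_csv(path: str | os.PathLike, table: PhenotypeTable) -> None:
    """Long CSV: strain, trait, value, n_scored, n_with_gut, replicate.

    Replicate rows carry counts; a strain/trait without replicate data gets a
    single row with empty count fields.
    """
    rows = []
    if table.replicates is not None:
        for _, r in table.replicates.iterrows():
            rows.append({
                "strain": r["strain"], "trait": r["trait"],
                "value": table.values.at[r["strain"], r["trait"]],
                "n_scored": int(r["n_scored"]), "n_with_gut": int(r["n_with_gut"]),
                "replicate": int(r["replicate"]),
            })
    covered = {(r["strain"], r["trait"]) for r in rows}
    for strain in table.values.index:
        for trait in table.values.columns:
            v = table.values.at[strain, trait]
            if (strain, trait) in covered or pd.isna(v):
                continue
            rows.append({"strain": strain, "trait": trait, "value": v,
                         "n_scored": "", "n_with_gut": "", "replicate": ""})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_phenotypes_csv(path: str | os.PathLike) -> PhenotypeTable:
    df = pd.read_csv(path, dtype={"strain": str, "trait": str})
    need = {"strain", "trait", "value"}
    if not need.issubset(df.columns):
        raise FormatError(f"{path}: phenotype CSV needs columns {sorted(need)}")
    reps = None
    if "n_scored" in df.columns and df["n_scored"].notna().any():
        sub = df[df["n_scored"].notna()]
        reps = pd.DataFrame({
            "strain": sub["strain"], "trait": sub["trait"],
            "replicate": sub["replicate"].astype(int),
            "n_scored": sub["n_scored"].astype(int),
            "n_with_gut": sub["n_with_gut"].astype(int),
        }).reset_index(drop=True)
    wide = df.groupby(["strain", "trait"], sort=False)["value"].first().unstack("trait")
    wide.index.name = None
    wide.columns.name = None
    return PhenotypeTable(wide, reps)


def write_marker_map(path: str | os.PathLike, marker_map: MarkerMap) -> None:
    out = marker_map.frame.reset_index(names="marker")
    out.to_csv(path, sep="\t", index=False)


def read_marker_map(path: str | os.PathLike) -> MarkerMap:
    df = pd.read_csv(path, sep="\t", dtype={"marker": str, "chrom": str})
    need = {"marker", "chrom", "bp", "cM"}
    if not need.issubset(df.columns):
        raise FormatError(f"{path}: marker map TSV needs columns {sorted(need)}")
    return MarkerMap(df.set_index("marker"))


def read_newick(path_or_text: str | os.PathLike) -> dendropy.Tree:
    src = os.fspath(path_or_text) if not isinstance(path_or_text, str) else path_or_text
    if isinstance(src, str) and not src.lstrip().startswith("(") and os.path.exists(src):
        tree = dendropy.Tree.get(path=src, schema="newick")
    else:
        tree = dendropy.Tree.get(data=str(src), schema="newick")
    return tree


def write_newick(path: str | os.PathLike, tree: dendropy.Tree) -> None:
    tree.write(path=os.fspath(path), schema="newick", suppress_rooting=True)


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

@dataclass
class QcReport:
    removed_strains: list[str] = field(default_factory=list)
    removed_markers: list[str] = field(default_factory=list)
    n_strains_in: int = 0
    n_markers_in: int = 0
    n_strains_out: int = 0
    n_markers_out: int = 0


def qc_filter(genotypes: GenotypeMatrix, max_sample_missing: float = 0.90,
              min_maf: float = 0.01) -> tuple[GenotypeMatrix, QcReport]:
    """Remove heavily missing samples, then low-MAF markers.

    Order is fixed: samples whose missing fraction is *strictly greater* than
    ``max_sample_missing`` go first; then markers with MAF strictly below
    ``min_maf``, the MAF computed on the surviving samples with missing calls
    excluded from the denominator. Idempotent on its own output.
    """
    for name, thr in (("max_sample_missing", max_sample_missing), ("min_maf", min_maf)):
        if not 0.0 <= thr <= 1.0:
            raise ConfigurationError(f"{name} must lie in [0, 1], got {thr}")
    report = QcReport(n_strains_in=genotypes.n_strains, n_markers_in=genotypes.n_markers)
    keep_s = genotypes.sample_missing_fraction() <= max_sample_missing
    report.removed_strains = [s for s, k in zip(genotypes.strain_ids, keep_s) if not k]
    if not keep_s.any():
        raise DataError("qc_filter removed every sample")
    gm = genotypes.subset(strains=keep_s)
    keep_m = gm.maf() >= min_maf
    report.removed_markers = [m for m, k in zip(gm.marker_ids, keep_m) if not k]
    gm = gm.subset(markers=keep_m)
    report.n_strains_out = gm.n_strains
    report.n_markers_out = gm.n_markers
    return gm, report
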