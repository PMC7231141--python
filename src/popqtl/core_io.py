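"""Domain containers and on-disk formats for the eQTL pipeline.

Coordinate convention: all in-memory positions are 1-based and inclusive
(the convention of dbSNP and of the gene tables this package reproduces).
BED input/output converts at the boundary (BED is 0-based, half-open).

Missing genotypes are coded with the sentinel :data:`MISSING` (-1); 0 is a
legal dosage and is never used to mean "absent".
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("popqtl")

#: Sentinel for a missing genotype call.
MISSING: int = -1

VARIANT_COLUMNS = ["rsid", "chrom", "pos", "ref", "alt", "r2"]


class FormatError(ValueError):
    """A file violated the expected on-disk format."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Samples x variants additive alt-allele dosages plus variant metadata.

    Parameters
    ----------
    sample_ids
        Unique sample identifiers, one per row of ``calls``.
    variants
        One record per column of ``calls`` with columns
        ``rsid, chrom, pos, ref, alt, r2`` (``r2`` may be NaN when the
        variant was directly genotyped rather than imputed).
    calls
        Integer array of shape ``(n_samples, n_variants)`` with entries in
        ``{0, 1, 2}`` or :data:`MISSING`.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        self.variants = self.variants.reset_index(drop=True)
        missing_cols = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing_cols:
            raise ValueError(f"variant table lacks columns {missing_cols}")
        rsids = self.variants["rsid"]
        if rsids.duplicated().any():
            dupes = sorted(rsids[rsids.duplicated()].unique())
            raise ValueError(f"duplicate rsids: {dupes[:5]}")
        if (self.variants["pos"] < 1).any():
            raise ValueError("variant positions must be >= 1 (1-based)")
        self.calls = np.asarray(self.calls, dtype=np.int16)
        if self.calls.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.sample_ids)}, {len(self.variants)})"
            )
        valid = np.isin(self.calls, (MISSING, 0, 1, 2))
        if not valid.all():
            bad = np.unique(self.calls[~valid])
            raise ValueError(f"illegal dosage values {bad.tolist()}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def rsids(self) -> list[str]:
        return self.variants["rsid"].tolist()

    def dosages(self, rsid: str) -> np.ndarray:
        """Dosage vector for one variant (``MISSING`` where uncalled)."""
        idx = self.variants.index[self.variants["rsid"] == rsid]
        if len(idx) == 0:
            raise KeyError(rsid)
        return self.calls[:, idx[0]]

    def take_variants(self, indices: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        indices = np.asarray(indices, dtype=int)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            variants=self.variants.iloc[indices].reset_index(drop=True),
            calls=self.calls[:, indices],
        )

    def take_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise KeyError(f"samples absent from genotypes: {missing[:5]}")
        rows = [index[s] for s in sample_ids]
        return GenotypeMatrix(
            sample_ids=list(sample_ids),
            variants=self.variants.copy(),
            calls=self.calls[rows, :],
        )

    def equals(self, other: "GenotypeMatrix", r2_tol: float = 1e-9) -> bool:
        if self.sample_ids != other.sample_ids:
            return False
        a, b = self.variants, other.variants
        for col in ("rsid", "chrom", "pos", "ref", "alt"):
            if not a[col].reset_index(drop=True).equals(b[col].reset_index(drop=True)):
                return False
        ra = a["r2"].to_numpy(dtype=float)
        rb = b["r2"].to_numpy(dtype=float)
        both_nan = np.isnan(ra) & np.isnan(rb)
        close = np.isclose(ra, rb, atol=r2_tol, equal_nan=True)
        if not (both_nan | close).all():
            return False
        return bool(np.array_equal(self.calls, other.calls))


@dataclass
class PopulationPanel:
    """Mapping from sample id to population code (e.g. CEU/CHB/JPT)."""

    assignments: dict[str, str]

    def __post_init__(self) -> None:
        self.assignments = {str(k): str(v) for k, v in self.assignments.items()}

    @property
    def populations(self) -> list[str]:
        return sorted(set(self.assignments.values()))

    def population_of(self, sample_id: str) -> str:
        try:
            return self.assignments[sample_id]
        except KeyError:
            raise KeyError(
                f"sample {sample_id!r} has no population assignment"
            ) from None

    def samples_in(self, population: str) -> list[str]:
        return [s for s, p in self.assignments.items() if p == population]

    def require(self, sample_ids: Iterable[str]) -> None:
        """Raise if any of ``sample_ids`` is absent (joins must be total)."""
        missing = [s for s in sample_ids if s not in self.assignments]
        if missing:
            raise KeyError(f"samples missing from panel: {missing[:5]}")


@dataclass
class ExpressionMatrix:
    """Genes x samples continuous expression (log-intensity scale)."""

    values: pd.DataFrame  # index: gene ids, columns: sample ids

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if v.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if v.shape[0] and v.isna().all(axis=1).any():
            bad = v.index[v.isna().all(axis=1)][0]
            raise ValueError(f"gene {bad!r} has no observed values")
        self.values = v.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.values.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.columns]

    def gene(self, gene_id: str) -> pd.Series:
        if gene_id not in self.values.index:
            raise KeyError(gene_id)
        return self.values.loc[gene_id]

    def take_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples absent from expression: {missing[:5]}")
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)])


@dataclass
class GeneAnnotation:
    """Gene coordinates, 1-based inclusive on both ends."""

    table: pd.DataFrame  # columns: gene_id, chrom, start, end, strand

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True).copy()
        for col in ("gene_id", "chrom", "start", "end"):
            if col not in t.columns:
                raise ValueError(f"gene annotation lacks column {col!r}")
        if "strand" not in t.columns:
            t["strand"] = "."
        t["start"] = t["start"].astype(int)
        t["end"] = t["end"].astype(int)
        if (t["start"] > t["end"]).any():
            bad = t.loc[t["start"] > t["end"], "gene_id"].iloc[0]
            raise FormatError(f"gene {bad!r} has start > end")
        if t["gene_id"].duplicated().any():
            raise ValueError("duplicate gene ids in annotation")
        self.table = t

    @property
    def gene_ids(self) -> list[str]:
        return self.table["gene_id"].tolist()

    def get(self, gene_id: str) -> pd.Series:
        rows = self.table[self.table["gene_id"] == gene_id]
        if rows.empty:
            raise KeyError(gene_id)
        return rows.iloc[0]


@dataclass
class SurvivalDataset:
    """Right-censored time-to-event records, optionally with covariates.

    ``time`` is in months (>= 0); ``event`` is 1 for an observed event
    (progression/death) and 0 for censoring. Any further columns are
    treated as continuous covariates.
    """

    table: pd.DataFrame  # columns: sample_id, time, event, *covariates

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True).copy()
        for col in ("sample_id", "time", "event"):
            if col not in t.columns:
                raise ValueError(f"survival table lacks column {col!r}")
        t["time"] = t["time"].astype(float)
        t["event"] = t["event"].astype(int)
        if (t["time"] < 0).any():
            raise ValueError("negative survival times")
        if not t["event"].isin((0, 1)).all():
            raise ValueError("event indicator must be 0 or 1")
        if t["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in survival data")
        self.table = t

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.table.columns if c not in ("sample_id", "time", "event")]

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def times(self) -> np.ndarray:
        return self.table["time"].to_numpy(float)

    @property
    def events(self) -> np.ndarray:
        return self.table["event"].to_numpy(int)


# ---------------------------------------------------------------------------
# Genotype I/O
# ---------------------------------------------------------------------------


def _dosage_from_gt(alleles: Sequence[int]) -> int:
    if any(a < 0 for a in alleles):
        return MISSING
    return int(sum(1 for a in alleles if a == 1))


def _read_genotypes_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    records = []
    columns = []
    seen: set[str] = set()
    for v in vcf:
        if len(v.ALT) != 1:
            raise FormatError(
                f"multi-allelic record at {v.CHROM}:{v.POS} "
                f"({v.REF}->{','.join(v.ALT)}); split or drop it first"
            )
        rsid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        if rsid in seen:
            raise FormatError(f"duplicate rsid {rsid!r} in {path}")
        seen.add(rsid)
        dosages = np.empty(len(sample_ids), dtype=np.int16)
        for i, gt in enumerate(v.genotypes):
            alleles = gt[:-1]  # last entry is the phasing flag
            if len(alleles) != 2:
                raise FormatError(
                    f"non-diploid genotype for sample {sample_ids[i]} at {rsid}"
                )
            if min(alleles) < 0 and max(alleles) >= 0:
                dosages[i] = MISSING  # half-missing treated as missing
            else:
                dosages[i] = _dosage_from_gt(alleles)
        r2 = v.INFO.get("R2")
        records.append((rsid, v.CHROM, v.POS, v.REF, v.ALT[0],
                        float(r2) if r2 is not None else math.nan))
        columns.append(dosages)
    variants = pd.DataFrame(records, columns=VARIANT_COLUMNS)
    calls = (np.column_stack(columns) if columns
             else np.empty((len(sample_ids), 0), dtype=np.int16))
    return GenotypeMatrix(sample_ids=sample_ids, variants=variants, calls=calls)


def _read_genotypes_table(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = VARIANT_COLUMNS
    if list(df.columns[: len(expected)]) != expected:
        raise FormatError(
            f"genotype table header must start with {expected}, "
            f"got {list(df.columns[:len(expected)])}"
        )
    sample_ids = list(df.columns[len(expected):])
    if not sample_ids:
        raise FormatError("genotype table has no sample columns")
    variants = df[expected].copy()
    variants["pos"] = variants["pos"].astype(int)
    variants["r2"] = pd.to_numeric(variants["r2"].replace({".": None, "NA": None}))
    raw = df[sample_ids].replace({".": str(MISSING), "NA": str(MISSING)})
    try:
        calls = raw.to_numpy(dtype=float).astype(np.int16).T  # -> samples x variants
    except ValueError as exc:
        raise FormatError(f"non-numeric genotype cell in {path}: {exc}") from exc
    return GenotypeMatrix(sample_ids=sample_ids, variants=variants, calls=calls)


def read_genotypes(path: str | Path, dialect: str = "vcf") -> GenotypeMatrix:
    """Read genotypes from a VCF (``dialect="vcf"``) or a dosage table.

    VCF handling: only the GT field is consumed; dosage is the count of
    alt alleles; half-missing or fully missing calls become
    :data:`MISSING`; multi-allelic records are rejected with the offending
    record named. Imputation quality is read from the INFO key ``R2`` when
    present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "vcf":
        return _read_genotypes_vcf(path)
    if dialect == "table":
        return _read_genotypes_table(path)
    raise ValueError(f"unknown genotype dialect {dialect!r}")


def write_genotypes(gm: GenotypeMatrix, path: str | Path, dialect: str = "vcf") -> None:
    """Write genotypes as VCF 4.2 (GT + INFO/R2) or as a dosage table."""
    path = Path(path)
    if dialect == "table":
        df = gm.variants.copy()
        body = pd.DataFrame(
            gm.calls.T, columns=gm.sample_ids
        ).astype(str).replace({str(MISSING): "."})
        out = pd.concat([df, body], axis=1)
        out.to_csv(path, sep="\t", index=False, na_rep=".")
        return
    if dialect != "vcf":
        raise ValueError(f"unknown genotype dialect {dialect!r}")
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(gm.variants["chrom"]):
            sub = gm.variants[gm.variants["chrom"] == chrom]
            length = int(sub["pos"].max()) + 1_000_000
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##INFO=<ID=R2,Number=1,Type=Float,'
                 'Description="Imputation accuracy (squared correlation)">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.sample_ids) + "\n")
        # matrix order is preserved so read(write(x)) is the identity
        for j in gm.variants.index:
            row = gm.variants.iloc[j]
            info = "." if pd.isna(row["r2"]) else f"R2={row['r2']:.6g}"
            gts = "\t".join(gt_map[int(d)] for d in gm.calls[:, j])
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['rsid']}\t{row['ref']}\t"
                     f"{row['alt']}\t.\tPASS\t{info}\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Gene annotation I/O
# ---------------------------------------------------------------------------


def read_gene_annotation(path: str | Path, dialect: str = "bed") -> GeneAnnotation:
    """Read gene coordinates from BED (0-based half-open) or a 1-based table.

    BED start ``s`` becomes internal ``s + 1``; the BED end is already the
    1-based inclusive end. BED6 strand is kept when present.
    """
    path = Path(path)
    if dialect == "bed":
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise FormatError(f"{path}:{lineno}: BED needs >= 4 columns")
                chrom, start, end, name = fields[:4]
                strand = fields[5] if len(fields) >= 6 else "."
                rows.append((name, chrom, int(start) + 1, int(end), strand))
        table = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
        return GeneAnnotation(table)
    if dialect == "table":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
        return GeneAnnotation(df)
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def write_gene_annotation(ann: GeneAnnotation, path: str | Path,
                          dialect: str = "bed") -> None:
    path = Path(path)
    if dialect == "bed":
        with open(path, "w") as fh:
            for _, r in ann.table.iterrows():
                fh.write(f"{r['chrom']}\t{r['start'] - 1}\t{r['end']}\t"
                         f"{r['gene_id']}\t0\t{r['strand']}\n")
        return
    if dialect == "table":
        ann.table[["gene_id", "chrom", "start", "end", "strand"]].to_csv(
            path, sep="\t", index=False)
        return
    raise ValueError(f"unknown annotation dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Expression / panel / survival I/O (tab-separated, header row)
# ---------------------------------------------------------------------------


def read_expression(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise FormatError(f"non-numeric expression column {col!r}")
    return ExpressionMatrix(df)


def write_expression(em: ExpressionMatrix, path: str | Path) -> None:
    em.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


def read_panel(path: str | Path) -> PopulationPanel:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample_id", "population"]:
        raise FormatError("panel header must be 'sample_id<TAB>population'")
    if df["sample_id"].duplicated().any():
        raise FormatError("duplicate sample ids in panel")
    return PopulationPanel(dict(zip(df["sample_id"], df["population"])))


def write_panel(panel: PopulationPanel, path: str | Path) -> None:
    pd.DataFrame(
        sorted(panel.assignments.items()), columns=["sample_id", "population"]
    ).to_csv(path, sep="\t", index=False)


def read_survival(path: str | Path) -> SurvivalDataset:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return SurvivalDataset(df)


def write_survival(ds: SurvivalDataset, path: str | Path) -> None:
    ds.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Sample intersection
# ---------------------------------------------------------------------------


def intersect_samples(
    genotypes: GenotypeMatrix,
    expression: ExpressionMatrix | None = None,
    panel: PopulationPanel | None = None,
) -> list[str]:
    """Samples shared by all provided inputs, in genotype order.

    The panel must cover every sample in the genotype/expression overlap
    (a partial panel is a join failure, not a silent drop). An empty
    intersection is an error.
    """
    samples = list(genotypes.sample_ids)
    if expression is not None:
        expr = set(expression.sample_ids)
        samples = [s for s in samples if s in expr]
    if panel is not None:
        panel.require(samples)
    if not samples:
        raise ValueError("no samples shared between genotype and expression data")
    logger.info("analysis sample intersection: %d samples", len(samples))
    return samples
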