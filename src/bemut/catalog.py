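"""Domain types and I/O for somatic mutation catalogs, covariates and pathways.

The central in-memory container is a pandas DataFrame with one row per
somatic call (``COLUMNS`` below); :class:`MutationRecord` is the validated
row-level view. Coordinates are 1-based for point records and 0-based
half-open for intervals, converted only at I/O boundaries.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "CATEGORIES",
    "FUNCTIONAL_CATEGORIES",
    "COLUMNS",
    "MutationRecord",
    "PatientMeta",
    "PathwayDB",
    "classify_functional",
    "read_catalog",
    "write_catalog",
    "read_meta",
    "write_meta",
    "read_gmt",
    "records_to_frame",
    "frame_to_records",
]

#: Five annotation classes treated as likely functional (protein or
#: regulatory impact on RefSeq transcripts).
FUNCTIONAL_CATEGORIES = (
    "exon-non-synonymous",
    "3'utr-exon",
    "5'utr-exon",
    "coding-splicing",
    "utr-splicing",
)

#: Ten classes treated as presumed non-functional. Together with the five
#: functional classes these form the fixed 15-way annotation taxonomy.
NONFUNCTIONAL_CATEGORIES = (
    "exon-synonymous",
    "intron-coding-gene",
    "3'utr-intron",
    "5'utr-intron",
    "upstream-1kb",
    "downstream-1kb",
    "non-coding-RNA-exon",
    "non-coding-RNA-intron",
    "intergenic-near-capture",
    "other",
)

CATEGORIES = FUNCTIONAL_CATEGORIES + NONFUNCTIONAL_CATEGORIES

MUT_TYPES = ("SNV", "INS", "DEL")

#: Canonical catalog column order (TSV dialect).
COLUMNS = [
    "patient_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "mut_type",
    "context3",
    "vaf",
    "genes",
    "category",
]

_BASES = set("ACGT")


def classify_functional(category: str) -> bool:
    """True iff ``category`` is one of the five functional classes.

    Raises ``ValueError`` for a category outside the 15-way taxonomy.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown mutation category: {category!r}")
    return category in FUNCTIONAL_CATEGORIES


@dataclass(frozen=True)
class MutationRecord:
    """One somatic SNV or indel with context, VAF and gene links."""

    patient_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    mut_type: str
    context3: str  # 3-mer on the reference strand; "" for indels
    vaf: float | None
    genes_within_1kb: frozenset[str] = field(default_factory=frozenset)
    category: str = "other"
    diploid_balanced: bool = True

    def __post_init__(self) -> None:
        if self.mut_type not in MUT_TYPES:
            raise ValueError(f"mut_type must be one of {MUT_TYPES}")
        if self.mut_type == "SNV":
            if len(self.ref) != 1 or len(self.alt) != 1:
                raise ValueError("SNV ref/alt must be single bases")
            if self.ref == self.alt:
                raise ValueError("SNV ref and alt must differ")
            if (
                len(self.context3) != 3
                or set(self.context3) - _BASES
                or self.context3[1] != self.ref
            ):
                raise ValueError(
                    f"context3 {self.context3!r} invalid or not centred on ref {self.ref!r}"
                )
        if self.vaf is not None and not (0.0 <= self.vaf <= 1.0):
            raise ValueError(f"vaf out of range: {self.vaf}")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown mutation category: {self.category!r}")

    @property
    def functional(self) -> bool:
        return classify_functional(self.category)


@dataclass(frozen=True)
class PatientMeta:
    patient_id: str
    nsaid_user: bool
    ever_smoker: bool
    tp53_mutant: bool
    target_mb: float

    def __post_init__(self) -> None:
        if self.target_mb <= 0:
            raise ValueError("target_mb must be > 0")


class PathwayDB:
    """Named gene sets. Genes may belong to several pathways."""

    def __init__(self, pathways: dict[str, set[str]]):
        for name, genes in pathways.items():
            if not genes:
                raise ValueError(f"pathway {name!r} is empty")
            if any(not g for g in genes):
                raise ValueError(f"pathway {name!r} contains an empty gene symbol")
        self._pathways = {name: frozenset(genes) for name, genes in pathways.items()}

    def __getitem__(self, name: str) -> frozenset[str]:
        return self._pathways[name]

    def __contains__(self, name: str) -> bool:
        return name in self._pathways

    def __len__(self) -> int:
        return len(self._pathways)

    def __iter__(self):
        return iter(self._pathways)

    @property
    def names(self) -> list[str]:
        return list(self._pathways)

    def gene_count(self, name: str) -> int:
        return len(self._pathways[name])

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self._pathways.values():
            out |= genes
        return frozenset(out)

    def pathways_of(self, gene: str) -> list[str]:
        return [n for n, g in self._pathways.items() if gene in g]


# ---------------------------------------------------------------------------
# catalog I/O


def _parse_genes(s: str) -> frozenset[str]:
    if not s or s == ".":
        return frozenset()
    return frozenset(s.split(","))


def _format_genes(genes) -> str:
    if not genes:
        return "."
    return ",".join(sorted(genes))


def _validate_catalog_frame(df: pd.DataFrame, meta: pd.DataFrame | None) -> None:
    bad_vaf = df["vaf"].notna() & ((df["vaf"] < 0) | (df["vaf"] > 1))
    if bad_vaf.any():
        lines = (df.index[bad_vaf] + 2).tolist()  # +2: header + 1-based
        raise ValueError(f"vaf out of range at line(s) {lines}")
    bad_cat = ~df["category"].isin(CATEGORIES)
    if bad_cat.any():
        lines = (df.index[bad_cat] + 2).tolist()
        raise ValueError(f"unknown category at line(s) {lines}")
    bad_type = ~df["mut_type"].isin(MUT_TYPES)
    if bad_type.any():
        lines = (df.index[bad_type] + 2).tolist()
        raise ValueError(f"unknown mut_type at line(s) {lines}")
    snv = df["mut_type"] == "SNV"
    ctx = df.loc[snv, "context3"].astype(str)
    ref = df.loc[snv, "ref"].astype(str)
    bad_ctx = (ctx.str.len() != 3) | (ctx.str[1] != ref) | (df.loc[snv, "ref"] == df.loc[snv, "alt"])
    if bad_ctx.any():
        lines = (bad_ctx.index[bad_ctx] + 2).tolist()
        raise ValueError(f"invalid SNV ref/alt/context3 at line(s) {lines}")
    if meta is not None:
        known = set(meta["patient_id"])
        unknown = set(df["patient_id"]) - known
        if unknown:
            raise ValueError(f"unknown patient_id(s) in catalog: {sorted(unknown)}")


def read_catalog(path, meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read a mutation catalog from the canonical TSV dialect or a VCF.

    Every patient in the catalog must appear in ``meta`` when given.
    Malformed rows raise ``ValueError`` naming the offending line numbers.
    """
    path = str(path)
    if path.endswith((".vcf", ".vcf.gz")):
        df = _read_catalog_vcf(path)
    else:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "patient_id": str},
                         na_values=["."], keep_default_na=False)
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing required column(s): {missing}")
        df = df[COLUMNS].copy()
        df["context3"] = df["context3"].fillna("")
        df["genes"] = df["genes"].fillna("")
        df["vaf"] = pd.to_numeric(df["vaf"], errors="coerce")
        df["pos"] = df["pos"].astype(int)
    _validate_catalog_frame(df, meta)
    return df.reset_index(drop=True)


def _read_catalog_vcf(path: str) -> pd.DataFrame:
    import pysam

    rows = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            info = rec.info
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) == len(alt) == 1:
                mut_type = "SNV"
            elif len(alt) > len(ref):
                mut_type = "INS"
            else:
                mut_type = "DEL"
            genes = info.get("GENES", ())
            if isinstance(genes, str):
                genes = (genes,)
            rows.append(
                {
                    "patient_id": info["PATIENT"],
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "ref": ref,
                    "alt": alt,
                    "mut_type": mut_type,
                    "context3": info.get("CTX3", ""),
                    "vaf": float(info["VAF"]) if "VAF" in info else float("nan"),
                    "genes": ",".join(sorted(g for g in genes if g and g != ".")),
                    "category": info.get("CAT", "other"),
                }
            )
    return pd.DataFrame(rows, columns=COLUMNS)


def write_catalog(df: pd.DataFrame, path) -> None:
    """Write the canonical TSV dialect (round-trips through read_catalog)."""
    out = df[COLUMNS].copy()
    out["genes"] = out["genes"].map(lambda s: s if s else ".")
    out["context3"] = out["context3"].map(lambda s: s if s else ".")
    out.to_csv(path, sep="\t", index=False, na_rep=".")


def records_to_frame(records: list[MutationRecord]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": r.patient_id,
            "chrom": r.chrom,
            "pos": r.pos,
            "ref": r.ref,
            "alt": r.alt,
            "mut_type": r.mut_type,
            "context3": r.context3,
            "vaf": float("nan") if r.vaf is None else r.vaf,
            "genes": ",".join(sorted(r.genes_within_1kb)),
            "category": r.category,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[MutationRecord]:
    records = []
    for row in df.itertuples(index=False):
        vaf = None if pd.isna(row.vaf) else float(row.vaf)
        records.append(
            MutationRecord(
                patient_id=str(row.patient_id),
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref=row.ref,
                alt=row.alt,
                mut_type=row.mut_type,
                context3="" if row.context3 in ("", ".") else row.context3,
                vaf=vaf,
                genes_within_1kb=_parse_genes(row.genes),
                category=row.category,
            )
        )
    return records


# ---------------------------------------------------------------------------
# covariates


def read_meta(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    required = ["patient_id", "nsaid_user", "ever_smoker", "tp53_mutant", "target_mb"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    if df["patient_id"].duplicated().any():
        dupes = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValueError(f"duplicate patient_id(s): {dupes}")
    if (df["target_mb"] <= 0).any():
        raise ValueError("target_mb must be > 0 for all patients")
    for col in ("nsaid_user", "ever_smoker", "tp53_mutant"):
        df[col] = df[col].astype(int).astype(bool)
    return df


def write_meta(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for col in ("nsaid_user", "ever_smoker", "tp53_mutant"):
        out[col] = out[col].astype(int)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pathways (GMT)


def read_gmt(path) -> PathwayDB:
    """Read gene sets from GMT (name, description, then genes per line)."""
    pathways: dict[str, set[str]] = {}
    if isinstance(path, io.TextIOBase):
        lines = path.readlines()
    else:
        with open(path) as fh:
            lines = fh.readlines()
    for i, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line {i}: expected >= 3 tab-separated fields")
        name, _desc, *genes = fields
        pathways[name] = {g for g in genes if g}
    return PathwayDB(pathways)


def write_gmt(db: PathwayDB, path) -> None:
    with open(path, "w") as fh:
        for name in db.names:
            genes = "\t".join(sorted(db[name]))
            fh.write(f"{name}\tna\t{genes}\n")
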