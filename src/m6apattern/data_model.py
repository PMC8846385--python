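"""Core typed containers, file readers/writers and the built-in m6A regulator catalog.

All tabular interchange is TSV (UTF-8, '.' decimal, genes in rows for
matrices), gene sets are GMT, somatic mutations are MAF.  Every writer emits
a sidecar JSON manifest recording input hashes and parameters so runs can be
audited.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "RegulatorCatalog",
    "SurvivalOutcome",
    "ClinicalTable",
    "GeneSetCollection",
    "MAFTable",
    "CNVMatrix",
    "canonical_symbol",
    "default_regulator_catalog",
    "cohort_manifest",
    "load_expression",
    "write_expression",
    "load_gene_sets",
    "write_gene_sets",
    "load_maf",
    "load_clinical",
    "load_cnv",
    "merge_cohorts",
    "GEO_ACCESSIONS",
]

# GEO series of the study cohort, alongside TCGA-BRCA.  Downloading them is
# out of scope; the manifest documents provenance for users who re-run the
# pipeline on the real data.
GEO_ACCESSIONS: tuple[str, ...] = (
    "GSE21653",
    "GSE24450",
    "GSE42568",
    "GSE45255",
    "GSE51783",
    "GSE61304",
)

# Alternate spellings seen in the literature for the canonical 23 regulators.
_DEFAULT_ALIASES: dict[str, str] = {
    "KIAA1429": "VIRMA",
    "LRPPPRC": "LRPPRC",  # frequent typo for the LRPPRC reader
}

_WRITERS = ("METTL3", "METTL14", "WTAP", "VIRMA", "RBM15", "RBM15B", "ZC3H13", "CBLL1")
_ERASERS = ("FTO", "ALKBH5")
_READERS = (
    "YTHDC1", "YTHDC2", "YTHDF1", "YTHDF2", "YTHDF3",
    "HNRNPC", "HNRNPA2B1", "FMR1", "LRPPRC", "RBMX",
    "IGF2BP1", "IGF2BP2", "IGF2BP3",
)


def canonical_symbol(symbol: str, aliases: dict[str, str] | None = None) -> str:
    """Uppercase, strip whitespace, and resolve known aliases."""
    s = str(symbol).strip().upper()
    table = _DEFAULT_ALIASES if aliases is None else aliases
    return table.get(s, s)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _write_manifest(path: Path, params: dict) -> None:
    manifest = {"file": Path(path).name, "sha256": _sha256(path), "params": params}
    Path(str(path) + ".manifest.json").write_text(json.dumps(manifest, indent=1, default=str))


def cohort_manifest() -> dict:
    """Provenance manifest of the study cohorts (TCGA-BRCA plus six GEO series)."""
    return {"tcga": "TCGA-BRCA", "geo_series": list(GEO_ACCESSIONS)}


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log2-scale expression values.

    ``values`` is a DataFrame with unique canonical gene symbols as the index
    and unique sample ids as columns; values must be finite (missing data is
    a hard error, never imputed — every downstream statistic assumes a
    complete matrix).
    """

    values: pd.DataFrame
    cohort_labels: pd.Series | None = None
    load_report: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] < 2 or v.shape[1] < 2:
            raise ValueError("expression matrix needs >=2 genes and >=2 samples")
        if v.index.duplicated().any():
            raise ValueError("duplicate gene ids after canonicalization")
        if v.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("non-numeric expression values")
        if not np.isfinite(arr).all():
            raise ValueError("expression matrix contains NaN/Inf values")
        if self.cohort_labels is not None:
            self.cohort_labels = self.cohort_labels.reindex(v.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def restrict(self, genes: list[str], *, missing: str = "warn") -> "ExpressionMatrix":
        """Subset to ``genes`` (canonicalized); absent genes dropped with a warning."""
        wanted = [canonical_symbol(g) for g in genes]
        present = [g for g in wanted if g in self.values.index]
        absent = sorted(set(wanted) - set(present))
        if absent:
            if missing == "error":
                raise KeyError(f"genes absent from matrix: {absent}")
            warnings.warn(f"{len(absent)} requested genes absent from matrix: {absent[:5]}...")
        return ExpressionMatrix(self.values.loc[present].copy(), self.cohort_labels)


@dataclass
class RegulatorCatalog:
    """The m6A regulator symbols with writer/eraser/reader roles plus aliases."""

    entries: dict[str, str]
    aliases: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {r for r in self.entries.values()} - {"writer", "eraser", "reader"}
        if bad:
            raise ValueError(f"unknown regulator roles: {bad}")
        for alt, canon in self.aliases.items():
            if canon not in self.entries:
                raise ValueError(f"alias {alt!r} -> {canon!r} does not land on a canonical symbol")
            if alt in self.entries:
                raise ValueError(f"alias {alt!r} shadows a canonical symbol")

    @property
    def symbols(self) -> list[str]:
        return list(self.entries)

    def role_counts(self) -> dict[str, int]:
        counts = {"writer": 0, "eraser": 0, "reader": 0}
        for role in self.entries.values():
            counts[role] += 1
        return counts

    def lookup(self, symbol: str) -> tuple[str, str]:
        """Resolve a (possibly aliased) symbol to (canonical symbol, role)."""
        s = str(symbol).strip().upper()
        s = self.aliases.get(s, s)
        if s not in self.entries:
            raise KeyError(f"unknown regulator symbol: {symbol!r}")
        return s, self.entries[s]


def default_regulator_catalog() -> RegulatorCatalog:
    """The 23 canonical m6A regulators: 8 writers, 2 erasers, 13 readers."""
    entries: dict[str, str] = {}
    for g in _WRITERS:
        entries[g] = "writer"
    for g in _ERASERS:
        entries[g] = "eraser"
    for g in _READERS:
        entries[g] = "reader"
    return RegulatorCatalog(entries=entries, aliases=dict(_DEFAULT_ALIASES))


@dataclass
class SurvivalOutcome:
    """Per-sample overall-survival follow-up: time (days) and event indicator."""

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if len(self.sample_ids) != len(set(self.sample_ids)):
            raise ValueError("duplicate sample ids in survival outcome")
        if len(self.time) != len(self.sample_ids) or len(self.event) != len(self.sample_ids):
            raise ValueError("time/event length mismatch")
        if (self.time < 0).any():
            raise ValueError("negative follow-up time")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicator must be 0/1")

    def subset(self, sample_ids: list[str]) -> "SurvivalOutcome":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"samples without survival information: {missing[:5]}")
        idx = [pos[s] for s in sample_ids]
        return SurvivalOutcome(list(sample_ids), self.time[idx], self.event[idx])

    def __len__(self) -> int:
        return len(self.sample_ids)


@dataclass
class ClinicalTable:
    """Survival outcome plus optional clinical annotation columns.

    ``table`` is indexed by sample id, with mandatory ``os_time``/``os_event``
    and optional columns such as age, T/N/tumor stage, molecular subtype and
    precomputed immunophenoscore (IPS) columns.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("os_time", "os_event"):
            if col not in self.table.columns:
                raise ValueError(f"clinical table missing mandatory column {col!r}")
        if self.table.index.duplicated().any():
            raise ValueError("duplicate sample ids in clinical table")
        if (self.table["os_time"] < 0).any():
            raise ValueError("negative os_time in clinical table")
        if not self.table["os_event"].isin((0, 1)).all():
            raise ValueError("os_event must coerce to 0/1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def outcome(self, sample_ids: list[str] | None = None) -> SurvivalOutcome:
        t = self.table if sample_ids is None else self.table.loc[sample_ids]
        return SurvivalOutcome(list(t.index), t["os_time"].to_numpy(float), t["os_event"].to_numpy(int))


@dataclass
class GeneSetCollection:
    """Named gene sets with an optional category tag per set."""

    sets: dict[str, list[str]]
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise ValueError(f"gene set {name!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def restricted_to(self, genes: list[str] | pd.Index, min_size: int = 2) -> "GeneSetCollection":
        """Intersect every set with ``genes``; drop sets below ``min_size`` with a warning."""
        universe = set(genes)
        kept: dict[str, list[str]] = {}
        for name, members in self.sets.items():
            present = [g for g in dict.fromkeys(canonical_symbol(m) for m in members) if g in universe]
            if len(present) >= min_size:
                kept[name] = present
            else:
                warnings.warn(f"gene set {name!r} dropped: {len(present)} members present (< {min_size})")
        if not kept:
            raise ValueError("all gene sets dropped after intersecting with the expression matrix")
        return GeneSetCollection(kept, {k: v for k, v in self.categories.items() if k in kept})


# MAF Variant_Classification vocabulary (maftools convention).
MAF_CLASSIFICATIONS = frozenset({
    "Missense_Mutation", "Nonsense_Mutation", "Frame_Shift_Del", "Frame_Shift_Ins",
    "In_Frame_Del", "In_Frame_Ins", "Splice_Site", "Translation_Start_Site",
    "Nonstop_Mutation", "Silent", "3'UTR", "5'UTR", "3'Flank", "5'Flank",
    "Intron", "RNA", "IGR", "Targeted_Region", "Splice_Region",
})

NONSYNONYMOUS_CLASSES = frozenset({
    "Missense_Mutation", "Nonsense_Mutation", "Frame_Shift_Del", "Frame_Shift_Ins",
    "In_Frame_Del", "In_Frame_Ins", "Splice_Site", "Translation_Start_Site",
    "Nonstop_Mutation",
})


@dataclass
class MAFTable:
    """Somatic mutation records in MAF convention (1-based coordinates)."""

    records: pd.DataFrame

    _REQUIRED = ("Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification")

    def __post_init__(self) -> None:
        for col in self._REQUIRED:
            if col not in self.records.columns:
                raise ValueError(f"MAF missing mandatory column {col!r}")
        if (self.records["Tumor_Sample_Barcode"].astype(str).str.len() == 0).any():
            raise ValueError("empty Tumor_Sample_Barcode in MAF")

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.records["Tumor_Sample_Barcode"].unique())

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class CNVMatrix:
    """Gene x sample copy-number calls in {-2,-1,0,1,2} (or continuous + threshold)."""

    values: pd.DataFrame
    discrete: bool = True

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids in CNV matrix")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids in CNV matrix")
        arr = self.values.to_numpy()
        if not np.isfinite(arr.astype(float)).all():
            raise ValueError("CNV matrix contains missing values")
        if self.discrete and not np.isin(arr, (-2, -1, 0, 1, 2)).all():
            raise ValueError("discrete CNV calls must lie in {-2,-1,0,1,2}")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

# values above this are assumed to be on a linear (FPKM-like) scale and are
# log2(x+1) transformed under the "auto" policy
AUTO_LOG_THRESHOLD = 50.0


def load_expression(path: str | Path, log_transform_policy: str = "auto") -> ExpressionMatrix:
    """Read a genes-in-rows TSV expression matrix.

    Duplicate gene symbols (after canonicalization) are collapsed by mean;
    under ``auto`` the matrix is log2(x+1)-transformed when its maximum
    exceeds ``AUTO_LOG_THRESHOLD``.  The decision is recorded in
    ``ExpressionMatrix.load_report``.
    """
    if log_transform_policy not in ("auto", "force", "never"):
        raise ValueError(f"unknown log_transform_policy {log_transform_policy!r}")
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(header) != len(set(header)):  # pandas would silently mangle these
        dups = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"duplicate sample ids in {path}: {dups}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise ValueError(f"non-numeric cell in {path} at row {row!r}, column {col!r}")
    if df.isna().any().any():
        raise ValueError(f"missing values in expression matrix {path}")
    df.index = [canonical_symbol(g) for g in df.index]
    n_before = df.shape[0]
    df = df.groupby(level=0, sort=False).mean()
    transformed = False
    if log_transform_policy == "force" or (
        log_transform_policy == "auto" and float(df.to_numpy().max()) > AUTO_LOG_THRESHOLD
    ):
        if (df.to_numpy() < 0).any():
            raise ValueError("cannot log2(x+1)-transform: negative values present")
        df = np.log2(df + 1.0)
        transformed = True
    report = {
        "path": str(path),
        "policy": log_transform_policy,
        "log2_transformed": transformed,
        "duplicate_symbols_collapsed": n_before - df.shape[0],
    }
    return ExpressionMatrix(df, load_report=report)


def write_expression(X: ExpressionMatrix, path: str | Path, **params) -> None:
    path = Path(path)
    X.values.to_csv(path, sep="\t", index_label="gene")
    _write_manifest(path, {"kind": "expression", **params})


def load_gene_sets(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (name, description, tab-separated member symbols)."""
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: malformed GMT line (<3 fields)")
            name, _desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            sets[name] = members
    return GeneSetCollection(sets)


def write_gene_sets(sets: GeneSetCollection, path: str | Path, **params) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in sets.sets.items():
            desc = sets.categories.get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")
    _write_manifest(path, {"kind": "gmt", **params})


def load_maf(path: str | Path, *, classification_policy: str = "warn") -> MAFTable:
    """Read a tab-separated MAF; unknown classification strings warn (or raise)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in MAFTable._REQUIRED:
        if col not in df.columns:
            raise ValueError(f"MAF {path} missing mandatory column {col!r}")
    unknown = set(df["Variant_Classification"].unique()) - MAF_CLASSIFICATIONS
    if unknown:
        msg = f"MAF {path} has non-standard Variant_Classification values: {sorted(unknown)}"
        if classification_policy == "error":
            raise ValueError(msg)
        warnings.warn(msg)
    return MAFTable(df)


def write_maf(maf: MAFTable, path: str | Path, **params) -> None:
    path = Path(path)
    maf.records.to_csv(path, sep="\t", index=False)
    _write_manifest(path, {"kind": "maf", **params})


_EVENT_CODES = {"0": 0, "1": 1, "ALIVE": 0, "DEAD": 1, "0.0": 0, "1.0": 1}


def load_clinical(path: str | Path) -> ClinicalTable:
    """Read a clinical TSV with mandatory sample_id, os_time, os_event columns."""
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "os_time", "os_event"):
        if col not in df.columns:
            raise ValueError(f"clinical table {path} missing mandatory column {col!r}")
    ev = df["os_event"].astype(str).str.strip().str.upper()
    unknown = set(ev.unique()) - set(_EVENT_CODES)
    if unknown:
        raise ValueError(f"unrecognized os_event codes in {path}: {sorted(unknown)}")
    df["os_event"] = ev.map(_EVENT_CODES).astype(int)
    df["os_time"] = pd.to_numeric(df["os_time"])
    if (df["os_time"] < 0).any():
        raise ValueError(f"negative os_time in clinical table {path}")
    return ClinicalTable(df.set_index("sample_id"))


def write_clinical(clin: ClinicalTable, path: str | Path, **params) -> None:
    path = Path(path)
    clin.table.to_csv(path, sep="\t", index_label="sample_id")
    _write_manifest(path, {"kind": "clinical", **params})


def load_cnv(path: str | Path, *, discrete: bool = True) -> CNVMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = [canonical_symbol(g) for g in df.index]
    return CNVMatrix(df, discrete=discrete)


def write_cnv(cnv: CNVMatrix, path: str | Path, **params) -> None:
    path = Path(path)
    cnv.values.to_csv(path, sep="\t", index_label="gene")
    _write_manifest(path, {"kind": "cnv", **params})


# ---------------------------------------------------------------------------
# cohort merging
# ---------------------------------------------------------------------------

def merge_cohorts(matrices: list[ExpressionMatrix], method: str = "zscore",
                  cohort_names: list[str] | None = None) -> ExpressionMatrix:
    """Merge cohorts on their shared genes.

    ``zscore``: each cohort is gene-wise standardized (population sd) before
    concatenation, removing cohort-specific location/scale.  ``quantile``:
    each sample's values are replaced by the pooled reference distribution at
    the same ranks (classic quantile normalization).
    """
    if method not in ("zscore", "quantile"):
        raise ValueError(f"unknown merge method {method!r}")
    if not matrices:
        raise ValueError("no cohorts to merge")
    if cohort_names is None:
        cohort_names = [f"cohort{i + 1}" for i in range(len(matrices))]
    common = matrices[0].values.index
    for m in matrices[1:]:
        common = common.intersection(m.values.index)
    if len(common) == 0:
        raise ValueError("empty gene intersection across cohorts")
    all_ids = [sid for m in matrices for sid in m.sample_ids]
    collide = len(all_ids) != len(set(all_ids))
    blocks, labels = [], []
    for m, name in zip(matrices, cohort_names):
        v = m.values.loc[common]
        if collide:  # disambiguate shared sample ids across cohorts
            v = v.rename(columns=lambda s: f"{name}:{s}")
        if method == "zscore":
            mu = v.mean(axis=1)
            sd = v.std(axis=1, ddof=0).replace(0.0, 1.0)
            v = v.sub(mu, axis=0).div(sd, axis=0)
        blocks.append(v)
        labels.extend([name] * v.shape[1])
    merged = pd.concat(blocks, axis=1)
    if method == "quantile":
        arr = merged.to_numpy(float)
        order = np.argsort(arr, axis=0)
        ranked = np.take_along_axis(arr, order, axis=0)
        reference = ranked.mean(axis=1)
        out = np.empty_like(arr)
        np.put_along_axis(out, order, reference[:, None], axis=0)
        merged = pd.DataFrame(out, index=merged.index, columns=merged.columns)
    return ExpressionMatrix(merged, cohort_labels=pd.Series(labels, index=merged.columns))
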