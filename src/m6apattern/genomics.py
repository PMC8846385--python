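"""Somatic-mutation and copy-number summaries: TMB, waterfall tables, CNV frequency."""

from __future__ import annotations

import warnings

import pandas as pd

from .data_model import CNVMatrix, MAFTable, NONSYNONYMOUS_CLASSES, canonical_symbol

__all__ = ["compute_tmb", "mutation_frequency", "cnv_frequency"]


def compute_tmb(maf: MAFTable, sample_universe: list[str], exome_size_mb: float = 38.0,
                *, unknown_policy: str = "ignore") -> pd.DataFrame:
    """Tumor mutational burden: nonsynonymous record count per sample.

    Samples in the universe without MAF records get 0 (an explicit universe
    resolves the not-sequenced vs no-mutation ambiguity).  Both the raw
    count and a per-megabase rate (count / exome_size_mb) are reported;
    which to use is the caller's choice.
    """
    if len(sample_universe) == 0:
        raise ValueError("empty sample universe")
    rec = maf.records
    unknown = set(rec["Variant_Classification"].unique()) - NONSYNONYMOUS_CLASSES - {
        "Silent", "3'UTR", "5'UTR", "3'Flank", "5'Flank", "Intron", "RNA", "IGR",
        "Targeted_Region", "Splice_Region",
    }
    if unknown:
        msg = f"unknown Variant_Classification values ignored: {sorted(unknown)}"
        if unknown_policy == "error":
            raise ValueError(msg)
        warnings.warn(msg)
    nonsyn = rec[rec["Variant_Classification"].isin(NONSYNONYMOUS_CLASSES)]
    counts = nonsyn.groupby("Tumor_Sample_Barcode").size()
    out = pd.DataFrame(index=pd.Index(sample_universe, name="sample_id"))
    out["tmb_count"] = counts.reindex(out.index).fillna(0).astype(int)
    out["tmb_per_mb"] = out["tmb_count"] / exome_size_mb
    return out


def mutation_frequency(maf: MAFTable, genes: list[str],
                       groups: pd.Series | dict) -> pd.DataFrame:
    """Per-gene, per-group fraction of samples carrying >=1 nonsilent record.

    Counting is sample-level (a sample mutated twice in a gene counts once).
    Also reports the overall altered-sample count/fraction per gene and, in
    ``.attrs``, the cohort-wide fraction of samples altered in any queried
    gene (the "n of N samples carried a regulator mutation" headline).
    """
    groups = pd.Series(groups)
    if groups.isna().any():
        raise ValueError("groups must cover all samples")
    sizes = groups.value_counts()
    if (sizes == 0).any() or len(sizes) == 0:
        raise ValueError("empty group")
    genes = [canonical_symbol(g) for g in genes]
    rec = maf.records
    nonsilent = rec[rec["Variant_Classification"].isin(NONSYNONYMOUS_CLASSES)].copy()
    nonsilent["Hugo_Symbol"] = [canonical_symbol(g) for g in nonsilent["Hugo_Symbol"]]
    in_universe = nonsilent["Tumor_Sample_Barcode"].isin(groups.index)
    nonsilent = nonsilent[in_universe]
    rows = []
    altered_any: set[str] = set()
    for gene in genes:
        carriers = set(nonsilent.loc[nonsilent["Hugo_Symbol"] == gene, "Tumor_Sample_Barcode"])
        altered_any |= carriers
        row: dict = {"gene": gene, "altered_samples": len(carriers),
                     "altered_fraction": len(carriers) / len(groups)}
        for gname, gsize in sizes.items():
            members = set(groups.index[groups == gname])
            row[f"freq_{gname}"] = len(carriers & members) / gsize
        rows.append(row)
    out = pd.DataFrame(rows).set_index("gene")
    out.attrs["any_gene_altered_samples"] = len(altered_any)
    out.attrs["any_gene_altered_fraction"] = len(altered_any) / len(groups)
    return out


def cnv_frequency(cnv: CNVMatrix, genes: list[str], *, threshold: float = 1.0) -> pd.DataFrame:
    """Per-gene copy-number gain/loss frequency across samples.

    Gain = fraction of samples with call >= +threshold, loss = fraction with
    call <= -threshold.  Genes absent from the matrix are dropped with a
    warning.
    """
    wanted = [canonical_symbol(g) for g in genes]
    present = [g for g in wanted if g in cnv.values.index]
    absent = sorted(set(wanted) - set(present))
    if absent:
        warnings.warn(f"{len(absent)} genes absent from CNV matrix: {absent[:5]}")
    vals = cnv.values.loc[present].to_numpy(float)
    gain = (vals >= threshold).mean(axis=1)
    loss = (vals <= -threshold).mean(axis=1)
    return pd.DataFrame({"gain_fraction": gain, "loss_fraction": loss},
                        index=pd.Index(present, name="gene"))
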