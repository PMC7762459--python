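"""Flat-file I/O: TSV matrices, gene lists, MAF collapse, cohort export."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def read_matrix(path) -> pd.DataFrame:
    """Read a features-in-rows, samples-in-columns TSV matrix."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_gene_list(path) -> list[str]:
    """One id per line; blank lines and '#' comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def maf_to_binary(maf: pd.DataFrame,
                  exclude_classes=("Silent",)) -> pd.DataFrame:
    """Collapse a MAF-like table to a binary gene x sample matrix.

    Needs columns Hugo_Symbol, Tumor_Sample_Barcode and (optionally)
    Variant_Classification; classes in ``exclude_classes`` are dropped.
    """
    need = {"Hugo_Symbol", "Tumor_Sample_Barcode"}
    if not need <= set(maf.columns):
        raise ValueError(f"MAF table requires columns {sorted(need)}")
    if "Variant_Classification" in maf.columns:
        maf = maf[~maf["Variant_Classification"].isin(exclude_classes)]
    return (pd.crosstab(maf["Hugo_Symbol"], maf["Tumor_Sample_Barcode"]) > 0
            ).astype(int)


def write_cohort(cohort, truth, outdir) -> None:
    """Export a synthetic cohort and its ground truth as TSV files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_matrix(cohort.expression, out / "expression.tsv")
    write_matrix(cohort.mutation, out / "mutation.tsv")
    write_matrix(cohort.cnv, out / "cnv.tsv")
    write_matrix(cohort.methylation, out / "methylation.tsv")
    write_matrix(cohort.mirna, out / "mirna.tsv")
    cohort.mirna_targets.to_csv(out / "mirna_targets.tsv", sep="\t",
                                index=False)
    cohort.clinical.to_csv(out / "clinical.tsv", sep="\t")
    cohort.tumor_flags.rename("is_tumor").to_csv(out / "samples.tsv",
                                                 sep="\t")
    (out / "tf_list.txt").write_text("\n".join(cohort.tf_list) + "\n")
    (out / "literature_list.txt").write_text(
        "\n".join(cohort.literature_list) + "\n")
    if truth is not None:
        truth.module_of_gene.to_csv(out / "truth_modules.tsv", sep="\t")
        pd.DataFrame(
            [(r.id, r.platform, r.module, r.sign)
             for r in truth.planted_regulators],
            columns=["id", "platform", "module", "sign"]
        ).to_csv(out / "truth_regulators.tsv", sep="\t", index=False)
        truth.subtype_of_sample.to_csv(out / "truth_subtypes.tsv", sep="\t")
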