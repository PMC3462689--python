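"""Comparative-Ct (2^-ddCt) quantification of miRNA expression.

Replicate Ct values are averaged on the Ct scale; dCt = Ct_target -
Ct_reference per sample; ddCt = dCt_sample - dCt_calibrator; fold change =
2^-ddCt, so the calibrator sample is 1 by construction.  No amplification
efficiency correction is applied.  The standard error accompanying each
fold change is computed by propagating each target replicate through the
ddCt chain against the mean reference values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd

CT_COLUMNS = ["gene_id", "sample_id", "replicate", "ct"]


@dataclass
class CtTable:
    """Long-format Ct measurements plus the normalisation choices."""

    data: pd.DataFrame          # columns: gene_id, sample_id, replicate, ct
    reference_gene_id: str      # e.g. a 5.8S rRNA or gapdh control
    calibrator_sample_id: str   # the sample whose expression is set to 1

    def __post_init__(self) -> None:
        missing = set(CT_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"Ct table missing columns {sorted(missing)}")
        if (self.data["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")
        if self.reference_gene_id not in set(self.data["gene_id"]):
            raise ValueError(f"reference gene {self.reference_gene_id!r} absent")
        ref = self.data[self.data["gene_id"] == self.reference_gene_id]
        samples = set(self.data["sample_id"])
        missing_ref = samples - set(ref["sample_id"])
        if missing_ref:
            raise ValueError(
                f"no reference measurements for sample(s) {sorted(missing_ref)}"
            )
        if self.calibrator_sample_id not in samples:
            raise ValueError(f"calibrator sample {self.calibrator_sample_id!r} absent")


@dataclass
class RelExpression:
    gene_id: str
    sample_id: str
    ddct: float
    fold_change: float
    sem: float = 0.0


def delta_delta_ct(table: CtTable) -> List[RelExpression]:
    """Relative expression of every (gene, sample) vs the calibrator sample."""
    df = table.data
    mean_ct = df.groupby(["gene_id", "sample_id"])["ct"].mean()
    ref_ct = mean_ct[table.reference_gene_id]

    out: List[RelExpression] = []
    genes = [g for g in df["gene_id"].unique() if g != table.reference_gene_id]
    for gene in genes:
        gene_ct = mean_ct[gene]
        if table.calibrator_sample_id not in gene_ct.index:
            raise ValueError(
                f"gene {gene!r} has no calibrator-sample measurements"
            )
        dct_cal = gene_ct[table.calibrator_sample_id] - ref_ct[table.calibrator_sample_id]
        for sample in gene_ct.index:
            dct = gene_ct[sample] - ref_ct[sample]
            ddct = dct - dct_cal
            reps = df[(df["gene_id"] == gene) & (df["sample_id"] == sample)]["ct"]
            rep_folds = 2.0 ** -((reps - ref_ct[sample]) - dct_cal)
            sem = float(rep_folds.std(ddof=1) / np.sqrt(len(rep_folds))) if len(rep_folds) > 1 else 0.0
            out.append(
                RelExpression(
                    gene_id=gene,
                    sample_id=sample,
                    ddct=float(ddct),
                    fold_change=float(2.0 ** -ddct),
                    sem=sem,
                )
            )
    return out


def fold_ratio(
    expr: List[RelExpression], gene: str, sample_a: str, sample_b: str
) -> float:
    """Ratio of fold changes of one gene between two samples."""
    by_sample = {e.sample_id: e for e in expr if e.gene_id == gene}
    for s in (sample_a, sample_b):
        if s not in by_sample:
            raise ValueError(f"no expression value for gene {gene!r} in sample {s!r}")
    return by_sample[sample_a].fold_change / by_sample[sample_b].fold_change


def read_ct_table(path, reference_gene_id: str, calibrator_sample_id: str) -> CtTable:
    df = pd.read_csv(path, sep="\t")
    return CtTable(df, reference_gene_id, calibrator_sample_id)


def write_expression(expr: List[RelExpression], path) -> None:
    pd.DataFrame(
        [
            {
                "gene_id": e.gene_id,
                "sample_id": e.sample_id,
                "ddct": e.ddct,
                "fold_change": e.fold_change,
                "sem": e.sem,
            }
            for e in expr
        ]
    ).to_csv(path, sep="\t", index=False)


def plot_expression(expr: List[RelExpression], path) -> None:
    """Bar plot of fold changes with SEM error bars, one group per gene."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = pd.DataFrame(
        [(e.gene_id, e.sample_id, e.fold_change, e.sem) for e in expr],
        columns=["gene", "sample", "fold", "sem"],
    )
    genes = df["gene"].unique()
    samples = list(df["sample"].unique())
    width = 0.8 / len(samples)
    fig, ax = plt.subplots(figsize=(1.5 + len(genes), 3.2))
    for si, sample in enumerate(samples):
        sub = df[df["sample"] == sample].set_index("gene").reindex(genes)
        x = np.arange(len(genes)) + si * width
        ax.bar(x, sub["fold"], width, yerr=sub["sem"], capsize=2, label=sample)
    ax.set_xticks(np.arange(len(genes)) + 0.4 - width / 2)
    ax.set_xticklabels(genes, rotation=45, ha="right")
    ax.set_ylabel("relative expression (2^-ddCt)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
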