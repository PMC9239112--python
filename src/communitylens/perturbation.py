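"""Attribution of partner-induced regulation to the antibiotic locus.

A gene of a receiver species X is called koreenceine-dependent when it is
strongly regulated by the wild-type producer in pairwise coculture
(|log2FC| > fc_cut at fdr < alpha in X vs XP) and its regulation flips
direction in the mutant contrast.  The mutant contrast is oriented
baseline = wild-type pairwise, treatment = delta-kec pairwise, i.e.
``fc_mut = log2(XP_dkec / XP_wt)``: for a gene whose wild-type regulation
disappears in the mutant coculture this has the opposite sign of the
wild-type fold change, which is the reversal signature (and yields the
strong Spearman anticorrelation between the two fold-change vectors).
No fold-change cutoff is applied on the mutant contrast.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import DETable


@dataclass
class AttributionTable:
    """Per-gene reversal attribution plus the summary counts."""

    table: pd.DataFrame  # columns: fc_wt, fdr_wt, fc_mut_contrast, fdr_mut_contrast, eligible, dependent
    n_eligible: int
    n_dependent: int

    @property
    def fraction(self) -> float:
        return self.n_dependent / self.n_eligible if self.n_eligible else float("nan")


def attribute_reversal(de_wt: DETable, de_mut_contrast: DETable,
                       fc_cut: float = 1.0, alpha: float = 0.05) -> AttributionTable:
    """Flag genes whose wild-type regulation reverses in the mutant contrast.

    ``de_wt`` compares X vs X+P(WT); ``de_mut_contrast`` compares the
    wild-type pairwise (baseline) vs the mutant pairwise (treatment) of the
    same focal species, over a shared gene universe.  Eligible genes have
    |fc_wt| > fc_cut at fdr < alpha; dependent genes are eligible, significant
    in the mutant contrast (no FC cutoff) and opposite in sign.
    """
    if not de_wt.genes.equals(de_mut_contrast.genes):
        raise ValueError("DE tables cover different gene universes")
    fc_wt = de_wt.table["log2FC"].values
    fc_mut = de_mut_contrast.table["log2FC"].values
    eligible = de_wt.significant(alpha, fc_cut).values
    mut_sig = de_mut_contrast.significant(alpha).values
    dependent = eligible & mut_sig & (fc_wt * fc_mut < 0)
    table = pd.DataFrame({
        "fc_wt": fc_wt, "fdr_wt": de_wt.table["fdr"].values,
        "fc_mut_contrast": fc_mut, "fdr_mut_contrast": de_mut_contrast.table["fdr"].values,
        "eligible": eligible, "dependent": dependent,
    }, index=de_wt.genes)
    table.index.name = "gene_id"
    return AttributionTable(table=table, n_eligible=int(eligible.sum()),
                            n_dependent=int(dependent.sum()))


def reversal_correlation(fc_wt, fc_mut_contrast) -> float:
    """Spearman rank correlation between the two fold-change vectors."""
    x = np.asarray(fc_wt, dtype=float)
    y = np.asarray(fc_mut_contrast, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors differ in length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    return float(stats.spearmanr(x, y).statistic)


def summarize_gene_set_fc(de: DETable, gene_set):
    """Mean linear-scale fold change of a gene set with its dominant direction.

    Returns ``(mean_fold, direction, per_gene_table)`` where mean_fold is the
    mean of ``2**|log2FC|``, direction is "up"/"down" by the majority sign
    ("mixed" flagged when signs disagree).
    """
    genes = pd.Index(gene_set)
    if not len(genes):
        raise ValueError("empty gene set")
    missing = genes.difference(de.genes)
    if len(missing):
        raise ValueError(f"genes not in DE universe: {list(missing[:3])}")
    fc = de.table.loc[genes, "log2FC"]
    mean_fold = float((2.0 ** fc.abs()).mean())
    n_up = int((fc > 0).sum())
    n_down = int((fc < 0).sum())
    if n_up and n_down:
        direction = "mixed"
    else:
        direction = "up" if n_up >= n_down else "down"
    per_gene = pd.DataFrame({"log2FC": fc, "fold_change": 2.0 ** fc.abs(),
                             "direction": np.where(fc > 0, "up", "down")})
    return mean_fold, direction, per_gene


def inoculum_contrast_summary(de_tables: dict, fc_cut: float = 1.0,
                              alpha: float = 0.05) -> pd.DataFrame:
    """DEG-count matrix across inoculation/genotype schemes.

    ``de_tables`` maps ``(scheme, comparison_label)`` to a DETable (or None
    for a comparison that could not be run).  Cells count genes with
    fdr < alpha and |log2FC| > fc_cut; missing comparisons are NA, not zero.
    """
    schemes = sorted({k[0] for k in de_tables})
    labels = sorted({k[1] for k in de_tables})
    out = pd.DataFrame(index=labels, columns=schemes, dtype="Float64")
    for (scheme, label), de in de_tables.items():
        if de is None:
            continue
        out.loc[label, scheme] = int(de.significant(alpha, fc_cut).sum())
    out.index.name = "comparison"
    return out


def write_attribution(at: AttributionTable, path) -> None:
    buf = io.StringIO()
    at.table.to_csv(buf, sep="\t", lineterminator="\n", float_format="%.6g")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(buf.getvalue())
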