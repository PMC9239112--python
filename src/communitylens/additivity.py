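"""Additive-null ("Sum") analysis of community expression.

For a focal species, each gene's mean cpm in a coculture condition is
divided by its mean cpm in monoculture (pseudo-counted), giving expression
ratios for the two pairwise conditions and the community.  The additive null
predicts the community ratio as the product of the two pairwise ratios --
on the log scale, the sum of the two pairwise log-ratios:

    Sum = 10 ** (log10(A/PC) + log10(B/PC))

where PC is the monoculture ("pure culture") level and A, B the two pairwise
levels.  Community-vs-pairwise and community-vs-Sum contrasts are tested with
an exact paired Wilcoxon signed-rank test and Bonferroni correction.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .conditions import Condition
from .count_data import NormalizedMatrix, condition_means


def expression_ratios(nm: NormalizedMatrix, cond: Condition, alone: Condition,
                      pseudo_cpm: float = 0.5) -> pd.Series:
    """Per-gene ``(mean cpm in cond + pseudo) / (mean cpm alone + pseudo)``."""
    if alone.members != {nm.species}:
        raise ValueError(f"{alone.name!r} is not the monoculture of {nm.species!r}")
    if nm.species not in cond.members:
        raise ValueError(f"{cond.name!r} does not contain {nm.species!r}")
    num = condition_means(nm, cond) + pseudo_cpm
    den = condition_means(nm, alone) + pseudo_cpm
    return num / den


def pairwise_sum(ratio_a: pd.Series, ratio_b: pd.Series) -> pd.Series:
    """Additive-null prediction: the product of the two pairwise ratios.

    Equivalently ``10 ** (log10 ratio_a + log10 ratio_b)``; a neutral partner
    (ratio 1) is the identity, and opposite regulation cancels.
    """
    a = np.asarray(ratio_a, dtype=float)
    b = np.asarray(ratio_b, dtype=float)
    if (a <= 0).any() or (b <= 0).any():
        raise ValueError("expression ratios must be positive")
    return pd.Series(a * b, index=getattr(ratio_a, "index", None))


@dataclass
class RatioTable:
    """Expression ratios to monoculture plus the additive-null prediction.

    ``table`` carries the three pseudo-counted ratios, ``sum_predicted``
    (exactly the product of the two pairwise ratios) and, for diagnostics,
    the raw condition mean cpm values the ratios came from.

    Log-ratio comparisons are only meaningful for genes quantifiable in
    every condition involved; build the table from a matrix filtered with
    the per-condition ("each") low-expression mode, otherwise genes whose
    community-level counts sit at the measurement floor bias the Sum test.
    """

    species: str
    alone: str  # condition names
    pairwise1: str
    pairwise2: str
    community: str
    table: pd.DataFrame
    pseudo_cpm: float = 0.5


def build_ratio_table(nm: NormalizedMatrix, alone: Condition, pair1: Condition,
                      pair2: Condition, community: Condition,
                      pseudo_cpm: float = 0.5) -> RatioTable:
    r1 = expression_ratios(nm, pair1, alone, pseudo_cpm)
    r2 = expression_ratios(nm, pair2, alone, pseudo_cpm)
    rc = expression_ratios(nm, community, alone, pseudo_cpm)
    table = pd.DataFrame({
        "ratio_pairwise1": r1, "ratio_pairwise2": r2,
        "ratio_community": rc, "sum_predicted": pairwise_sum(r1, r2),
        "mean_alone": condition_means(nm, alone),
        "mean_pairwise1": condition_means(nm, pair1),
        "mean_pairwise2": condition_means(nm, pair2),
        "mean_community": condition_means(nm, community),
    })
    table.index.name = "gene_id"
    return RatioTable(species=nm.species, alone=alone.name, pairwise1=pair1.name,
                      pairwise2=pair2.name, community=community.name, table=table,
                      pseudo_cpm=pseudo_cpm)


def exact_wilcoxon_signed(x, y) -> float:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped before ranking (Wilcoxon's original
    convention) and ties receive average ranks.  For n <= 25 remaining pairs
    the null distribution of the positive-rank sum is enumerated exactly by
    dynamic programming over sign assignments; above that a normal
    approximation with continuity and tie corrections is used.  All-zero
    differences give p = 1.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    if d.size == 0:
        raise ValueError("empty vectors")
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    if n <= 25:
        return _exact_signed_rank_p(ranks, w)
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts ** 3 - tie_counts).sum() / 48.0
    if var == 0:
        return 1.0
    z = (w - mu - 0.5 * np.sign(w - mu)) / np.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def _exact_signed_rank_p(ranks: np.ndarray, w: float) -> float:
    # average ranks are multiples of 1/2: double them to work on integers
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    ways = np.zeros(total + 1)
    ways[0] = 1.0
    for r in r2:
        nxt = ways.copy()
        nxt[r:] += ways[: total + 1 - r]
        ways = nxt
    ways /= ways.sum()
    w2 = int(round(2 * w))
    cdf = float(ways[: w2 + 1].sum())
    sf = float(ways[w2:].sum())
    return min(1.0, 2.0 * min(cdf, sf))


def bonferroni_adjust(pvalues, family_size: int | None = None) -> np.ndarray:
    """``min(1, p * m)`` with m the family size (defaults to the vector length)."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p) if family_size is None else int(family_size)
    if m < len(p):
        raise ValueError("family_size must be >= number of p-values")
    return np.minimum(1.0, p * m)


def additivity_tests(rt: RatioTable, gene_set, family_size: int | None = None) -> pd.DataFrame:
    """Paired tests of community vs pairwise levels and vs the additive null.

    On log10 ratios restricted to ``gene_set``: community vs each pairwise
    condition and community vs sum_predicted, with Bonferroni-adjusted
    p-values and median log10 ratios per distribution.
    """
    genes = pd.Index(gene_set)
    if not len(genes):
        raise ValueError("empty gene set")
    if len(genes) < 5:
        warnings.warn(f"additivity test on only {len(genes)} genes", stacklevel=2)
    ratio_cols = ["ratio_pairwise1", "ratio_pairwise2", "ratio_community",
                  "sum_predicted"]
    sub = np.log10(rt.table.loc[genes, ratio_cols])
    contrasts = [
        (f"{rt.community}_vs_{rt.pairwise1}", "ratio_community", "ratio_pairwise1"),
        (f"{rt.community}_vs_{rt.pairwise2}", "ratio_community", "ratio_pairwise2"),
        (f"{rt.community}_vs_Sum", "ratio_community", "sum_predicted"),
    ]
    rows = []
    for name, cx, cy in contrasts:
        p = exact_wilcoxon_signed(sub[cx].values, sub[cy].values)
        rows.append({"contrast": name, "n": len(genes),
                     "median_log10_x": float(sub[cx].median()),
                     "median_log10_y": float(sub[cy].median()),
                     "p": p})
    report = pd.DataFrame(rows)
    report["p_adjusted"] = bonferroni_adjust(report["p"].values, family_size)
    return report


def write_additivity_report(report: pd.DataFrame, path) -> None:
    buf = io.StringIO()
    report.to_csv(buf, sep="\t", index=False, lineterminator="\n", float_format="%.6g")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(buf.getvalue())
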