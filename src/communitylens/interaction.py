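"""The comparison framework for a three-member community.

For each focal species X with partners Y and Z, five comparisons over the
four culture conditions define three categories:

* category I  ("pairwise"):     X vs XY and X vs XZ
* category II ("third member"): XY vs XYZ and XZ vs XYZ
* category III ("community"):   X vs XYZ

Genes are classified from the two category-I tables into partner-specific,
dual-same, dual-opposite or unresponsive classes; higher-order (third-member)
regulation is read from the category-II tables; and community fold changes
are regressed on pairwise fold changes to identify the driving partner.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .conditions import Condition
from .diffexpr import DETable


@dataclass(frozen=True)
class ComparisonSpec:
    """One baseline-vs-treatment comparison for a focal species."""

    focal: str
    baseline: Condition
    treatment: Condition
    category: str = field(init=False)

    def __post_init__(self):
        if self.focal not in self.baseline.members:
            raise ValueError(f"focal {self.focal!r} not in baseline {self.baseline.name!r}")
        if self.focal not in self.treatment.members:
            raise ValueError(f"focal {self.focal!r} not in treatment {self.treatment.name!r}")
        if not self.baseline.members < self.treatment.members:
            raise ValueError(
                f"baseline members {self.baseline.name!r} must be a proper subset "
                f"of treatment members {self.treatment.name!r}")
        b, t = len(self.baseline.members), len(self.treatment.members)
        # I: monoculture vs pairwise; III: monoculture vs larger community;
        # II: partial community vs larger community ("third member")
        if b == 1 and t == 2:
            cat = "I"
        elif b == 1:
            cat = "III"
        else:
            cat = "II"
        object.__setattr__(self, "category", cat)

    @property
    def label(self) -> str:
        return f"{self.focal}:{self.baseline.name}_vs_{self.treatment.name}:cat{self.category}"

    @property
    def added_members(self) -> frozenset:
        return self.treatment.members - self.baseline.members


def enumerate_comparisons(focal: str, roster, allow_any_size: bool = False):
    """The five comparisons for a focal species in a three-member roster.

    Returns ``[X vs XY, X vs XZ, XY vs XYZ, XZ vs XYZ, X vs XYZ]`` with
    partners in sorted order.  ``allow_any_size`` generalizes to N members
    (monoculture vs each pair, each pair containing X vs full set, and
    monoculture vs full set).
    """
    roster = tuple(sorted(roster))
    if focal not in roster:
        raise ValueError(f"focal {focal!r} not in roster {roster}")
    if len(roster) != 3 and not allow_any_size:
        raise ValueError(f"roster must have 3 species (got {len(roster)}); "
                         "pass allow_any_size=True to generalize")
    partners = [s for s in roster if s != focal]
    alone = Condition({focal})
    full = Condition(roster)
    specs = [ComparisonSpec(focal, alone, Condition({focal, p})) for p in partners]
    specs += [ComparisonSpec(focal, Condition({focal, p}), full) for p in partners]
    specs.append(ComparisonSpec(focal, alone, full))
    return specs


@dataclass
class ClassificationTable:
    """Per-gene response class from the two category-I comparisons.

    Classes partition the tested gene universe:
    ``{X}_only_up/down``, ``{Y}_only_up/down``, ``dual_same_up``,
    ``dual_same_down``, ``dual_opposite``, ``none`` where X, Y are the two
    partner species.
    """

    partner_x: str
    partner_y: str
    table: pd.DataFrame  # columns: class, log2FC_x, fdr_x, log2FC_y, fdr_y

    def genes_in_class(self, cls: str) -> pd.Index:
        return self.table.index[self.table["class"] == cls]

    def class_counts(self) -> pd.Series:
        classes = [f"{self.partner_x}_only_up", f"{self.partner_x}_only_down",
                   f"{self.partner_y}_only_up", f"{self.partner_y}_only_down",
                   "dual_same_up", "dual_same_down", "dual_opposite", "none"]
        return self.table["class"].value_counts().reindex(classes, fill_value=0)


def classify_pairwise_response(de_x: DETable, de_y: DETable, alpha: float = 0.05,
                               fc_cut: float | None = None) -> ClassificationTable:
    """Classify genes by which partner(s) regulate them in pairwise coculture.

    ``de_x`` and ``de_y`` are the two category-I tables of the same focal
    species (same gene universe).  A gene significant in exactly one table
    gets a partner-only class with sign; significant in both, ``dual_same_*``
    when the signs agree else ``dual_opposite``; otherwise ``none``.  By
    default there is no fold-change cutoff.
    """
    if not de_x.genes.equals(de_y.genes):
        raise ValueError("the two DE tables cover different gene universes")
    px = _partner_label(de_x)
    py = _partner_label(de_y)
    sig_x = de_x.significant(alpha, fc_cut).values
    sig_y = de_y.significant(alpha, fc_cut).values
    fx = de_x.table["log2FC"].values
    fy = de_y.table["log2FC"].values

    cls = np.full(len(fx), "none", dtype=object)
    only_x = sig_x & ~sig_y
    only_y = sig_y & ~sig_x
    both = sig_x & sig_y
    cls[only_x & (fx > 0)] = f"{px}_only_up"
    cls[only_x & (fx <= 0)] = f"{px}_only_down"
    cls[only_y & (fy > 0)] = f"{py}_only_up"
    cls[only_y & (fy <= 0)] = f"{py}_only_down"
    same = np.sign(fx) == np.sign(fy)
    cls[both & same & (fx > 0)] = "dual_same_up"
    cls[both & same & (fx <= 0)] = "dual_same_down"
    cls[both & ~same] = "dual_opposite"

    table = pd.DataFrame({
        "class": cls,
        "log2FC_x": fx, "fdr_x": de_x.table["fdr"].values,
        "log2FC_y": fy, "fdr_y": de_y.table["fdr"].values,
    }, index=de_x.genes)
    table.index.name = "gene_id"
    return ClassificationTable(partner_x=px, partner_y=py, table=table)


def _partner_label(de: DETable) -> str:
    spec = de.comparison
    added = getattr(spec, "added_members", None)
    if added is not None and len(added) == 1:
        return next(iter(added))
    return de.label


def regulated_fraction(de: DETable, fc_cut: float = 1.0, alpha: float = 0.05,
                       genome_size: int = 0) -> float:
    """Qualifying DEGs (>2-fold by default) as a percentage of the genome.

    Reported to one decimal, e.g. 1,850 of a 5,207-gene genome -> 35.5.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    n = int(de.significant(alpha, fc_cut).sum())
    if n > genome_size:
        raise ValueError("more qualifying genes than genome_size")
    return round(100.0 * n / genome_size, 1)


def detect_higher_order(species_specific_genes, cat2_table: DETable,
                        alpha: float = 0.05) -> pd.DataFrame:
    """Third-member regulation of partner-specific genes (no FC cutoff).

    Returns the subset of ``species_specific_genes`` that is significant in
    the category-II comparison, annotated with the direction of the
    third-member effect.  An empty input yields an empty table.
    """
    genes = pd.Index(species_specific_genes)
    missing = genes.difference(cat2_table.genes)
    if len(missing):
        raise ValueError(f"genes not in the category-II universe: {list(missing[:3])}...")
    if not len(genes):
        return pd.DataFrame(columns=["log2FC", "fdr", "direction"])
    sub = cat2_table.table.loc[genes]
    flagged = sub[sub["fdr"] < alpha].copy()
    flagged["direction"] = np.where(flagged["log2FC"] > 0, "up", "down")
    return flagged[["log2FC", "fdr", "direction"]]


def community_specific_genes(de_x: DETable, de_y: DETable, cat2_tables,
                             cat3_table: DETable, alpha: float = 0.05,
                             fc_cut: float = 1.0) -> pd.Index:
    """Genes regulated only in the full community.

    No category-I significance with either partner, significant in at least
    one category-II comparison (no FC cutoff), and >``fc_cut`` category-III
    regulation.
    """
    no_cat1 = ~(de_x.significant(alpha) | de_y.significant(alpha))
    cat2_any = pd.Series(False, index=cat3_table.genes)
    for t in cat2_tables:
        cat2_any |= t.significant(alpha)
    cat3 = cat3_table.significant(alpha, fc_cut)
    return cat3_table.genes[no_cat1 & cat2_any & cat3]


def driver_regression(fc_cat3, fc_other):
    """OLS of another comparison's fold changes on the community fold changes.

    Returns ``(slope, intercept, r_squared)`` over the supplied (equal
    length, >= 3) category-III DEG fold-change vectors.
    """
    x = np.asarray(fc_cat3, dtype=float)
    y = np.asarray(fc_other, dtype=float)
    if x.shape != y.shape:
        raise ValueError("fold-change vectors differ in length")
    if x.size < 3:
        raise ValueError("need at least 3 points for a regression")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)


def write_classification(ct: ClassificationTable, path) -> None:
    out = ct.table.rename(columns={
        "log2FC_x": f"log2FC_{ct.partner_x}", "fdr_x": f"fdr_{ct.partner_x}",
        "log2FC_y": f"log2FC_{ct.partner_y}", "fdr_y": f"fdr_{ct.partner_y}"})
    buf = io.StringIO()
    out.to_csv(buf, sep="\t", lineterminator="\n", float_format="%.6g")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(buf.getvalue())
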