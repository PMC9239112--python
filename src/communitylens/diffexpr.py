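"""Negative-binomial exact differential expression.

A self-contained DE engine for small replicated count designs: per-gene
method-of-moments dispersions moderated toward the all-gene median, an exact
conditional NB test for two groups, Benjamini-Hochberg FDR, and per-comparison
DE tables.  Externally computed DE tables can be loaded with
:func:`read_de_table` for users wanting parity with other engines.

Model
-----
Counts for gene g, sample j are NB with mean mu_gj and dispersion phi_g
(variance mu + phi*mu^2).  After scaling each sample to a common effective
library size, the within-group sums are NB with size n_k/phi.  Conditioning
on the two-group total T, the null split follows a beta-binomial law that is
free of the unknown mean; the two-sided p-value sums the probabilities of
all splits no more probable than the observed one (minimum-likelihood
method, ties included).  As phi -> 0 the split law reduces to a binomial,
so the test reduces to the exact binomial test.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .count_data import CountMatrix, NormalizedMatrix, condition_means

#: relative tolerance when collecting outcomes tied with the observed one
_TIE_RTOL = 1e-9


def estimate_dispersions(cm: CountMatrix, groups, prior_weight: float = 20.0,
                         lib_sizes: pd.Series | None = None,
                         common_only: bool = False) -> pd.Series:
    """Moderated method-of-moments dispersion per gene.

    ``groups`` is a partition of sample ids (list of lists).  Per-gene raw
    estimates (on counts scaled to a common library size) are shrunk toward
    the all-gene median with ``prior_weight`` pseudo-observations and clipped
    at zero.  Groups need >= 2 samples unless ``common_only`` is set, in
    which case every gene receives the common (median) value.
    """
    libs = (cm.counts.sum(axis=0).astype(float) if lib_sizes is None
            else lib_sizes.astype(float))
    usable = []
    for group in groups:
        if len(group) < 2:
            if not common_only:
                raise ValueError(
                    f"group {group} has <2 replicates; set common_only to "
                    "fall back on the common dispersion")
            continue
        usable.append(list(group))
    if not usable:
        raise ValueError("no group with >=2 replicates to estimate dispersion from")

    L = float(np.exp(np.mean(np.log(libs.loc[[s for g in usable for s in g]]))))
    num = np.zeros(len(cm.genes))
    den = 0.0
    for group in usable:
        scaled = cm.counts[group].values * (L / libs.loc[group].values)
        m = scaled.mean(axis=1)
        v = scaled.var(axis=1, ddof=1)
        w = len(group) - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            contrib = np.where(m > 0, (v - m) / np.maximum(m, 1e-300) ** 2, 0.0)
        num += w * contrib
        den += w
    raw = num / den
    common = max(0.0, float(np.median(raw)))
    if common_only and any(len(g) < 2 for g in groups):
        shrunk = np.full(len(raw), common)
    else:
        shrunk = (den * raw + prior_weight * common) / (den + prior_weight)
    return pd.Series(np.clip(shrunk, 0.0, None), index=cm.genes)


_lfact_cache = np.zeros(1)


def _lfact(total: int) -> np.ndarray:
    """gammaln(k+1) for k = 0..total, grown lazily and cached."""
    global _lfact_cache
    if _lfact_cache.size <= total:
        _lfact_cache = gammaln(np.arange(max(total + 1, 2 * _lfact_cache.size)) + 1.0)
    return _lfact_cache[: total + 1]


def _split_log_pmf(total: int, n_a: int, n_b: int, phi: float) -> np.ndarray:
    """Unnormalized log-probabilities of the splits k, total-k under the null."""
    k = np.arange(total + 1)
    lf = _lfact(total)
    if phi <= 1e-12:
        # Poisson limit: Binomial(total, n_a/(n_a+n_b))
        p = n_a / (n_a + n_b)
        return -lf - lf[::-1] + k * np.log(p) + (total - k) * np.log1p(-p)
    r_a, r_b = n_a / phi, n_b / phi
    ga = gammaln(k + r_a)
    gb = ga[::-1] if r_a == r_b else gammaln(k + r_b)[::-1]
    return ga + gb - lf - lf[::-1]


def nb_exact_test(counts_a, counts_b, lib_a, lib_b, phi: float) -> float:
    """Two-sided exact NB test for a difference between two groups.

    ``counts_a``/``counts_b`` are the per-replicate counts of one gene;
    ``lib_a``/``lib_b`` the matching (effective) library sizes.  Counts are
    scaled to a common library size and summed per group; the p-value is
    computed conditionally on the two-group total.  A zero total returns 1
    (no evidence).
    """
    counts_a = np.asarray(counts_a, dtype=float)
    counts_b = np.asarray(counts_b, dtype=float)
    lib_a = np.asarray(lib_a, dtype=float)
    lib_b = np.asarray(lib_b, dtype=float)
    if phi < 0:
        raise ValueError("dispersion must be >= 0")
    if (lib_a <= 0).any() or (lib_b <= 0).any():
        raise ValueError("library sizes must be > 0")
    L = np.exp(np.mean(np.log(np.concatenate([lib_a, lib_b]))))
    y_a = int(round(float(np.sum(counts_a * (L / lib_a)))))
    y_b = int(round(float(np.sum(counts_b * (L / lib_b)))))
    total = y_a + y_b
    if total == 0:
        return 1.0
    lw = _split_log_pmf(total, len(counts_a), len(counts_b), phi)
    probs = np.exp(lw - lw.max())
    obs = probs[y_a]
    p = float(probs[probs <= obs * (1.0 + _TIE_RTOL)].sum() / probs.sum())
    return min(1.0, p)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR, order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DETable:
    """Per-gene differential-expression results for one comparison."""

    comparison: object  # ComparisonSpec or a plain label
    table: pd.DataFrame  # columns: log2FC, pvalue, fdr, mean_cpm_baseline, mean_cpm_treatment

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    @property
    def label(self) -> str:
        return getattr(self.comparison, "label", str(self.comparison))

    def significant(self, alpha: float = 0.05, fc_cut: float | None = None) -> pd.Series:
        """Boolean mask: fdr < alpha and, when given, |log2FC| > fc_cut (strict)."""
        sig = self.table["fdr"] < alpha
        if fc_cut is not None:
            sig = sig & (self.table["log2FC"].abs() > fc_cut)
        return sig


def run_comparison(cm: CountMatrix, nm: NormalizedMatrix, spec,
                   pseudo_cpm: float = 0.5, alpha: float = 0.05,
                   prior_weight: float = 20.0,
                   dispersions: pd.Series | None = None) -> DETable:
    """Run the NB exact test for one baseline-vs-treatment comparison.

    ``spec`` carries ``baseline`` and ``treatment`` conditions (and a label);
    positive log2FC means higher expression in the treatment (more complex)
    condition.  ``cm`` must be the filtered matrix that ``nm`` was normalized
    from (same gene universe).
    """
    if not cm.genes.equals(nm.genes):
        raise ValueError("count matrix and normalized matrix have different gene sets")
    base_samples = cm.samples_of(spec.baseline)
    treat_samples = cm.samples_of(spec.treatment)
    if not base_samples or not treat_samples:
        missing = spec.baseline.name if not base_samples else spec.treatment.name
        raise ValueError(f"condition {missing!r} has no samples")
    libs = nm.library_sizes
    if dispersions is None:
        dispersions = estimate_dispersions(
            cm, [base_samples, treat_samples], prior_weight=prior_weight,
            lib_sizes=libs, common_only=(len(base_samples) < 2 or len(treat_samples) < 2))
    mean_base = condition_means(nm, spec.baseline)
    mean_treat = condition_means(nm, spec.treatment)
    log2fc = np.log2((mean_treat + pseudo_cpm) / (mean_base + pseudo_cpm))

    counts_a = cm.counts[base_samples].values
    counts_b = cm.counts[treat_samples].values
    lib_a = libs.loc[base_samples].values
    lib_b = libs.loc[treat_samples].values
    pvals = np.empty(len(cm.genes))
    phi = dispersions.values
    for i in range(len(cm.genes)):
        pvals[i] = nb_exact_test(counts_a[i], counts_b[i], lib_a, lib_b, phi[i])
    fdr = bh_adjust(pvals)
    table = pd.DataFrame({
        "log2FC": log2fc.values,
        "pvalue": pvals,
        "fdr": fdr,
        "mean_cpm_baseline": mean_base.values,
        "mean_cpm_treatment": mean_treat.values,
    }, index=cm.genes)
    table.index.name = "gene_id"
    return DETable(comparison=spec, table=table)


def write_de_table(de: DETable, path) -> None:
    out = de.table.copy()
    out["comparison"] = de.label
    buf = io.StringIO()
    out.to_csv(buf, sep="\t", lineterminator="\n", float_format="%.6g")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(buf.getvalue())


def read_de_table(path, label: str | None = None) -> DETable:
    """Load an externally computed DE TSV (gene_id, log2FC, pvalue, fdr, ...)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("log2FC", "pvalue", "fdr"):
        if col not in df.columns:
            raise ValueError(f"{path}: DE table missing column {col!r}")
    if label is None:
        label = str(df["comparison"].iloc[0]) if "comparison" in df.columns else str(path)
    df = df.drop(columns=[c for c in ("comparison",) if c in df.columns])
    return DETable(comparison=label, table=df)
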