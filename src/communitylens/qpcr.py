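"""qRT-PCR validation arithmetic.

One-pass Grubbs outlier removal on technical replicate Ct values and
relative quantification by the 2^-ddCt method against a species-specific
reference gene (gyrA) and a control condition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def grubbs_test(values, alpha: float = 0.05):
    """Two-sided single-outlier Grubbs test.

    Returns ``(outlier_index or None, G)``.  G = max|x - mean| / s is
    compared with the t-based critical value at ``alpha``; one pass only.
    Constant input (zero variance) returns no outlier by convention.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("Grubbs test needs at least 3 values")
    if not np.isfinite(x).all():
        raise ValueError("Ct values must be finite")
    s = x.std(ddof=1)
    if s == 0:
        return None, 0.0
    dev = np.abs(x - x.mean())
    idx = int(np.argmax(dev))
    g = float(dev[idx] / s)
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    crit = (n - 1) / np.sqrt(n) * np.sqrt(t ** 2 / (n - 2 + t ** 2))
    return (idx, g) if g > crit else (None, g)


def clean_mean_ct(values, alpha: float = 0.05):
    """Mean Ct after one-pass Grubbs removal; returns (mean, n_removed)."""
    x = np.asarray(values, dtype=float)
    if x.size >= 3:
        idx, _ = grubbs_test(x, alpha=alpha)
        if idx is not None:
            x = np.delete(x, idx)
            return float(x.mean()), 1
    return float(x.mean()), 0


def ddct_fold_change(ct_target_cond: float, ct_ref_cond: float,
                     ct_target_ctrl: float, ct_ref_ctrl: float) -> float:
    """2^-ddCt relative fold change.

    ddCt = (Ct_target,cond - Ct_ref,cond) - (Ct_target,ctrl - Ct_ref,ctrl);
    a target dropping one cycle while the reference is unchanged doubles
    the fold change.
    """
    ddct = (ct_target_cond - ct_ref_cond) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))


def qpcr_fold_changes(records: pd.DataFrame, control_sample: str,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Fold changes for every (sample, target gene) against a control sample.

    ``records`` has columns sample, gene, role ("target"/"reference"),
    replicate, ct.  Technical replicates are averaged after one-pass Grubbs
    removal; each target is normalized to its sample's reference gene and to
    the control sample.  Output columns: sample, gene, fold_change,
    n_outliers_removed.
    """
    for col in ("sample", "gene", "role", "ct"):
        if col not in records.columns:
            raise ValueError(f"Ct table missing column {col!r}")
    means: dict = {}
    removed: dict = {}
    for (sample, gene, role), grp in records.groupby(["sample", "gene", "role"]):
        m, r = clean_mean_ct(grp["ct"].values, alpha=alpha)
        means[(sample, role, gene)] = m
        removed[(sample, gene)] = removed.get((sample, gene), 0) + r

    def ref_ct(sample):
        refs = [v for (s, role, g), v in means.items() if s == sample and role == "reference"]
        if len(refs) != 1:
            raise ValueError(f"sample {sample!r} needs exactly one reference gene")
        return refs[0]

    ctrl_ref = ref_ct(control_sample)
    rows = []
    for (sample, role, gene), ct in sorted(means.items()):
        if role != "target" or sample == control_sample:
            continue
        key_ctrl = (control_sample, "target", gene)
        if key_ctrl not in means:
            raise ValueError(f"control sample lacks target gene {gene!r}")
        fc = ddct_fold_change(ct, ref_ct(sample), means[key_ctrl], ctrl_ref)
        rows.append({"sample": sample, "gene": gene, "fold_change": fc,
                     "n_outliers_removed": removed[(sample, gene)]})
    return pd.DataFrame(rows, columns=["sample", "gene", "fold_change",
                                       "n_outliers_removed"])
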