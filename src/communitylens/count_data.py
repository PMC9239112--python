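"""Count-matrix data model and I/O.

Per-species gene x sample integer count tables (as produced by read-counting
tools), a sample sheet mapping samples to culture :class:`~communitylens.conditions.Condition`,
low-expression filtering and counts-per-million normalization.

File formats (UTF-8, tab-separated, LF line endings):

* counts:        header ``gene_id<TAB>sample1<TAB>...``, integer body
* sample sheet:  columns ``sample_id, species_present, genotype, inoculum, replicate``
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conditions import Condition, GENOTYPES, INOCULA


@dataclass
class CountMatrix:
    """Gene x sample integer counts for one species.

    ``sample_meta`` maps sample id -> ``(Condition, replicate)``; it may cover
    a superset of the matrix's samples (a global sample sheet).
    """

    species: str
    counts: pd.DataFrame
    sample_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        if (self.counts.values < 0).any():
            g, s = np.argwhere(self.counts.values < 0)[0]
            raise ValueError(
                f"negative count at gene {self.counts.index[g]!r}, "
                f"sample {self.counts.columns[s]!r}")
        for s in self.counts.columns:
            meta = self.sample_meta.get(s)
            if meta is not None and self.species not in meta[0].members:
                raise ValueError(
                    f"sample {s!r} has condition {meta[0].name!r} that does not "
                    f"contain species {self.species!r}")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def condition_of(self, sample: str) -> Condition:
        try:
            return self.sample_meta[sample][0]
        except KeyError:
            raise KeyError(f"sample {sample!r} missing from sample sheet") from None

    def samples_of(self, cond: Condition) -> list:
        """Sample ids of this matrix belonging to ``cond`` (sheet order)."""
        return [s for s in self.samples
                if s in self.sample_meta and self.sample_meta[s][0] == cond]

    def conditions(self) -> list:
        seen = {}
        for s in self.samples:
            if s in self.sample_meta:
                seen.setdefault(self.sample_meta[s][0], None)
        return list(seen)


@dataclass
class NormalizedMatrix:
    """Counts-per-million values with the library sizes used for scaling."""

    species: str
    values: pd.DataFrame
    library_sizes: pd.Series
    sample_meta: dict = field(default_factory=dict)
    norm_factors: pd.Series | None = None

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def samples_of(self, cond: Condition) -> list:
        return [s for s in self.values.columns
                if s in self.sample_meta and self.sample_meta[s][0] == cond]


def read_counts(path, species: str, sample_meta: dict | None = None) -> CountMatrix:
    """Read a per-species counts TSV into a :class:`CountMatrix`.

    Parse failures identify the offending row/column; negative or
    non-integer counts and duplicate ids are format errors.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
    if raw.index.name is None:
        raise ValueError(f"{path}: missing header row")
    body = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        if converted.isna().any():
            gene = raw.index[int(np.argmax(converted.isna().values))]
            raise ValueError(f"{path}: non-numeric count at gene {gene!r}, sample {col!r}")
        if (converted % 1 != 0).any():
            gene = raw.index[int(np.argmax((converted % 1 != 0).values))]
            raise ValueError(f"{path}: non-integer count at gene {gene!r}, sample {col!r}")
        if (converted < 0).any():
            gene = raw.index[int(np.argmax((converted < 0).values))]
            raise ValueError(f"{path}: negative count at gene {gene!r}, sample {col!r}")
        body[col] = converted.astype(np.int64)
    return CountMatrix(species=species, counts=body, sample_meta=dict(sample_meta or {}))


def write_counts(cm: CountMatrix, path) -> None:
    """Write counts as TSV (UTF-8, LF), round-tripping :func:`read_counts`."""
    buf = io.StringIO()
    out = cm.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(buf, sep="\t", lineterminator="\n")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(buf.getvalue())


def read_sample_sheet(path) -> dict:
    """Read a sample sheet TSV into ``{sample_id: (Condition, replicate)}``.

    Membership strings are canonicalized ("PF" and "FP" name the same
    condition); unknown genotype/inoculum values and duplicate sample ids
    are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "species_present", "genotype", "inoculum", "replicate"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: sample sheet missing columns {missing}")
    meta: dict = {}
    for _, row in df.iterrows():
        sid = row["sample_id"]
        if sid in meta:
            raise ValueError(f"{path}: sample {sid!r} listed twice")
        members = row["species_present"]
        if not isinstance(members, str) or not members.strip():
            raise ValueError(f"{path}: sample {sid!r} has empty species_present")
        genotype = row["genotype"]
        inoculum = row["inoculum"]
        if genotype not in GENOTYPES:
            raise ValueError(f"{path}: sample {sid!r} has unknown genotype {genotype!r}")
        if inoculum not in INOCULA:
            raise ValueError(f"{path}: sample {sid!r} has unknown inoculum {inoculum!r}")
        cond = Condition(frozenset(members.strip()), genotype=genotype, inoculum=inoculum)
        meta[sid] = (cond, int(row["replicate"]))
    return meta


def write_sample_sheet(meta: dict, path) -> None:
    rows = [{"sample_id": sid,
             "species_present": "".join(sorted(cond.members)),
             "genotype": cond.genotype,
             "inoculum": cond.inoculum,
             "replicate": rep}
            for sid, (cond, rep) in meta.items()]
    df = pd.DataFrame(rows, columns=["sample_id", "species_present",
                                     "genotype", "inoculum", "replicate"])
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def filter_low_expression(cm: CountMatrix, core_conditions, min_total: int = 10,
                          mode: str = "sum") -> CountMatrix:
    """Drop genes with very low expression over the four core conditions.

    ``mode="sum"`` (default) retains genes whose summed count across *all*
    samples of the core conditions is >= ``min_total``; ``mode="each"``
    requires the per-condition sum to reach ``min_total`` in every core
    condition.  Gene order is preserved and the operation is idempotent.
    """
    if mode not in ("sum", "each"):
        raise ValueError(f"unknown filter mode {mode!r}")
    per_cond_samples = []
    for cond in core_conditions:
        if cm.species not in cond.members:
            raise ValueError(f"core condition {cond.name!r} lacks species {cm.species!r}")
        samples = cm.samples_of(cond)
        if not samples:
            raise ValueError(f"core condition {cond.name!r} has no samples")
        per_cond_samples.append(samples)
    if mode == "sum":
        allsamples = [s for group in per_cond_samples for s in group]
        keep = cm.counts[allsamples].sum(axis=1) >= min_total
    else:
        keep = pd.Series(True, index=cm.genes)
        for samples in per_cond_samples:
            keep &= cm.counts[samples].sum(axis=1) >= min_total
    return CountMatrix(species=cm.species, counts=cm.counts.loc[keep].copy(),
                       sample_meta=cm.sample_meta)


def median_of_ratios_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios normalization factors (relative effective depth).

    For each sample the factor is the median, over genes positive in every
    sample, of the ratio of that gene's count share to its geometric-mean
    share across samples.  Factors are scaled to geometric mean 1 and
    multiply the total-count library sizes; they absorb composition shifts
    caused by a large mass of regulated genes, which plain cpm cannot.
    """
    counts = cm.counts.values.astype(float)
    libs = counts.sum(axis=0)
    if (libs <= 0).any():
        bad = cm.samples[int(np.argmax(libs <= 0))]
        raise ValueError(f"sample {bad!r} has zero library size")
    shares = counts / libs
    pos = (counts > 0).all(axis=1)
    if pos.sum() < 10:
        # too few always-positive genes to anchor the reference
        return pd.Series(1.0, index=cm.samples)
    ref = np.exp(np.log(shares[pos]).mean(axis=1))
    factors = np.median(shares[pos] / ref[:, None], axis=0)
    factors = factors / np.exp(np.log(factors).mean())
    return pd.Series(factors, index=cm.samples)


def cpm_normalize(cm: CountMatrix, norm_factors: pd.Series | None = None) -> NormalizedMatrix:
    """Counts-per-million: ``count / library_size * 1e6`` per sample.

    Library sizes are the column sums of the (already filtered) matrix; a
    user-supplied ``norm_factors`` series multiplies them (effective library
    sizes), e.g. from :func:`median_of_ratios_factors`.  Without factors every
    cpm column sums to 1e6.
    """
    libs = cm.counts.sum(axis=0).astype(float)
    if (libs == 0).any():
        bad = libs.index[int(np.argmax(libs.values == 0))]
        raise ValueError(f"sample {bad!r} has an all-zero count column")
    if norm_factors is not None:
        factors = norm_factors.reindex(cm.samples)
        if factors.isna().any():
            bad = factors.index[int(np.argmax(factors.isna().values))]
            raise ValueError(f"missing normalization factor for sample {bad!r}")
        libs = libs * factors
    values = cm.counts.div(libs, axis=1) * 1e6
    return NormalizedMatrix(species=cm.species, values=values, library_sizes=libs,
                            sample_meta=cm.sample_meta, norm_factors=norm_factors)


def condition_means(nm: NormalizedMatrix, cond: Condition) -> pd.Series:
    """Per-gene arithmetic mean cpm across a condition's replicates."""
    samples = nm.samples_of(cond)
    if not samples:
        raise ValueError(f"condition {cond.name!r} has no samples in the matrix")
    return nm.values[samples].mean(axis=1)
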