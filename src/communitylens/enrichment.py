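"""COG functional enrichment, shared annotations and bucket accounting.

The enrichment index of a COG category in a gene set is the category's
frequency in the set divided by its frequency in the genome; an index > 1
means over-representation.  Significance uses Fisher's exact test on the
2x2 membership table with Bonferroni correction over the categories tested.
Genes without a COG letter form the first-class pseudo-category ``"none"``;
multi-letter genes (e.g. "OU") count once toward each letter.
"""

from __future__ import annotations

import io
import re

import pandas as pd
from scipy import stats

from .additivity import bonferroni_adjust

#: standard single-letter COG functional categories
COG_LETTERS = set("ABCDEFGHIJKLMNOPQRSTUVWXYZ")
BUCKETS = ("prophage", "cd_hit", "unannotated")


def read_annotations(path) -> pd.DataFrame:
    """Annotation TSV: gene_id, cog_letters, annotation_name[, bucket]."""
    df = pd.read_csv(path, sep="\t", dtype=str, index_col=0).fillna("")
    for col in ("cog_letters", "annotation_name"):
        if col not in df.columns:
            raise ValueError(f"{path}: annotation table missing column {col!r}")
    if "bucket" not in df.columns:
        df["bucket"] = ""
    bad = set("".join(df["cog_letters"])) - COG_LETTERS
    if bad:
        raise ValueError(f"{path}: invalid COG letters {sorted(bad)}")
    return df


def _categories_of(letters: str):
    return list(letters) if letters else ["none"]


def _category_counts(genes, ann: pd.DataFrame) -> pd.Series:
    counts: dict = {}
    for g in genes:
        for cat in _categories_of(ann.loc[g, "cog_letters"]):
            counts[cat] = counts.get(cat, 0) + 1
    return pd.Series(counts, dtype=int)


def fisher_exact_2x2(a: int, b: int, c: int, d: int,
                     alternative: str = "two-sided") -> float:
    """Fisher's exact test on the table [[a, b], [c, d]].

    Two-sided p sums the hypergeometric probabilities of all tables (with
    the observed margins) no more probable than the observed one.
    """
    cells = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in cells):
        raise ValueError("cells must be nonnegative integers")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValueError("all margins must be positive")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative=alternative)[1])


def enrichment_index_table(gene_set, ann: pd.DataFrame, genome,
                           alternative: str = "two-sided") -> pd.DataFrame:
    """Enrichment index + Fisher exact p per COG category.

    One row per category present in the genome (including "none").  The 2x2
    table counts genes in/out of the set crossed with in/out of the
    category; Bonferroni is over the categories tested.
    """
    genome = pd.Index(genome)
    genes = pd.Index(gene_set)
    if not len(genes):
        raise ValueError("empty gene set")
    if not genes.isin(genome).all():
        raise ValueError("gene_set must be a subset of the genome")
    missing = genome.difference(ann.index)
    if len(missing):
        raise ValueError(f"genes without annotation rows: {list(missing[:3])}")
    n_set_tot, n_gen_tot = len(genes), len(genome)
    set_counts = _category_counts(genes, ann)
    gen_counts = _category_counts(genome, ann)
    rows = []
    for cat in sorted(gen_counts.index):
        n_set = int(set_counts.get(cat, 0))
        n_gen = int(gen_counts[cat])
        index = (n_set / n_set_tot) / (n_gen / n_gen_tot)
        a, b = n_set, n_set_tot - n_set
        c, d = n_gen - n_set, n_gen_tot - n_set_tot - (n_gen - n_set)
        p = fisher_exact_2x2(a, b, c, d, alternative=alternative)
        rows.append({"category": cat, "n_set": n_set,
                     "set_pct": 100.0 * n_set / n_set_tot,
                     "n_genome": n_gen,
                     "genome_pct": 100.0 * n_gen / n_gen_tot,
                     "index": index, "p": p})
    out = pd.DataFrame(rows)
    out["p_bonf"] = bonferroni_adjust(out["p"].values)
    return out


def jaccard_similarity(n_a: int, n_b: int, shared: int) -> float:
    """``shared / (n_a + n_b - shared)``, reported to 3 decimals."""
    if shared > min(n_a, n_b) or min(n_a, n_b, shared) < 0:
        raise ValueError("need 0 <= shared <= min(n_a, n_b)")
    return round(shared / (n_a + n_b - shared), 3)


def _normalize_name(name: str) -> str:
    return re.sub(r"\s+", " ", name.strip().casefold())


def shared_annotations(set_a, ann_a: pd.DataFrame, set_b, ann_b: pd.DataFrame,
                       fc_a: pd.Series | None = None,
                       fc_b: pd.Series | None = None) -> pd.DataFrame:
    """Annotation names present in both gene sets, with per-species details.

    Names are normalized (case-folded, whitespace-collapsed) before
    matching; multiple genes sharing a name have their fold changes joined
    with "; ".  Genes with empty annotation names never match.
    """
    def collect(genes, ann, fc):
        groups: dict = {}
        for g in genes:
            name = ann.loc[g, "annotation_name"]
            key = _normalize_name(name)
            if not key:
                continue
            entry = groups.setdefault(key, {"name": name.strip(), "genes": [],
                                            "cogs": set(), "fcs": []})
            entry["genes"].append(g)
            entry["cogs"].update(_categories_of(ann.loc[g, "cog_letters"]))
            if fc is not None:
                entry["fcs"].append(fc.loc[g])
        return groups

    ga = collect(set_a, ann_a, fc_a)
    gb = collect(set_b, ann_b, fc_b)
    rows = []
    for key in sorted(set(ga) & set(gb)):
        ea, eb = ga[key], gb[key]
        rows.append({
            "annotation": ea["name"],
            "cog_a": "".join(sorted(c for c in ea["cogs"] if c != "none")),
            "cog_b": "".join(sorted(c for c in eb["cogs"] if c != "none")),
            "genes_a": "; ".join(ea["genes"]), "genes_b": "; ".join(eb["genes"]),
            "fc_a": "; ".join(f"{v:.1f}" for v in ea["fcs"]),
            "fc_b": "; ".join(f"{v:.1f}" for v in eb["fcs"]),
        })
    return pd.DataFrame(rows, columns=["annotation", "cog_a", "cog_b",
                                       "genes_a", "genes_b", "fc_a", "fc_b"])


def bucket_counts(gene_set, ann: pd.DataFrame) -> dict:
    """Partition a gene set into prophage / cd_hit / unannotated buckets."""
    counts = {b: 0 for b in BUCKETS}
    for g in gene_set:
        bucket = ann.loc[g, "bucket"] if g in ann.index else ""
        bucket = bucket or "unannotated"
        if bucket not in counts:
            raise ValueError(f"gene {g!r} has unknown bucket label {bucket!r}")
        counts[bucket] += 1
    return counts


def write_enrichment(table: pd.DataFrame, path, direction: str | None = None) -> None:
    out = table.copy()
    if direction is not None:
        out["direction"] = direction
    buf = io.StringIO()
    out.to_csv(buf, sep="\t", index=False, lineterminator="\n", float_format="%.6g")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(buf.getvalue())
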