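"""Model/Results interface over the full coculture interaction analysis.

:class:`CommunityInteractionModel` is built from per-species count matrices
plus a sample sheet (and optionally gene annotations); ``fit()`` runs
filter -> normalization -> NB exact DE over the five per-species comparisons
-> response classification -> higher-order detection -> additive-null tests
-> mutant-reversal attribution -> enrichment, and returns an
:class:`InteractionResults` carrying every table, a ``summary()`` report and
deterministic writers.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import additivity as addmod
from . import count_data as cdmod
from . import enrichment as enmod
from . import interaction as intmod
from . import perturbation as pertmod
from .conditions import Condition, PRODUCER, core_conditions
from .diffexpr import DETable, run_comparison, write_de_table


@dataclass(frozen=True)
class PlainContrast:
    """A baseline-vs-treatment contrast outside the category scheme
    (e.g. wild-type pairwise vs mutant pairwise: same membership set)."""

    focal: str
    baseline: Condition
    treatment: Condition

    @property
    def label(self) -> str:
        return f"{self.focal}:{self.baseline.name}_vs_{self.treatment.name}"


@dataclass
class SpeciesResult:
    species: str
    genome_size: int
    n_filtered: int
    de: dict = field(default_factory=dict)          # label -> DETable
    classification: object = None
    ratio_table: object = None
    regulated_pct: dict = field(default_factory=dict)
    higher_order: dict = field(default_factory=dict)  # set name -> flagged DataFrame
    community_specific: list = field(default_factory=list)
    driver: dict = field(default_factory=dict)       # label -> (slope, intercept, r2)
    additivity: dict = field(default_factory=dict)   # set name -> report DataFrame
    attribution: object = None
    reversal_rho: float | None = None
    enrichment: dict = field(default_factory=dict)   # set name -> table
    skipped: list = field(default_factory=list)


class CommunityInteractionModel:
    """Comparative coculture interaction model for a small community.

    Parameters
    ----------
    counts : dict
        species label -> :class:`~communitylens.count_data.CountMatrix`
        (sample_meta populated from the sample sheet).
    annotations : dict, optional
        species label -> annotation DataFrame (gene -> cog_letters,
        annotation_name, bucket).
    alpha, fc_cut : float
        significance level (FDR) and log2 fold-change cutoff for "regulated"
        gene sets; classification itself applies no FC cutoff.
    min_total, filter_mode : low-expression filter settings.
    normalization : "median_ratios" (composition-robust effective library
        sizes, default) or "total" (plain cpm).
    kec_genes : optional list of producer antibiotic-locus gene ids for the
        inoculum fold-change summary.
    """

    def __init__(self, counts: dict, annotations: dict | None = None,
                 roster=None, alpha: float = 0.05, fc_cut: float = 1.0,
                 min_total: int = 10, pseudo_cpm: float = 0.5,
                 filter_mode: str = "sum", normalization: str = "median_ratios",
                 dispersion_prior_weight: float = 20.0,
                 kec_genes: list | None = None):
        self.counts = dict(counts)
        self.annotations = dict(annotations or {})
        self.roster = tuple(sorted(roster or self.counts.keys()))
        for sp in self.counts:
            if sp not in self.roster:
                raise ValueError(f"count matrix species {sp!r} not in roster")
        if normalization not in ("median_ratios", "total"):
            raise ValueError(f"unknown normalization {normalization!r}")
        self.alpha = alpha
        self.fc_cut = fc_cut
        self.min_total = min_total
        self.pseudo_cpm = pseudo_cpm
        self.filter_mode = filter_mode
        self.normalization = normalization
        self.dispersion_prior_weight = dispersion_prior_weight
        self.kec_genes = list(kec_genes or [])

    @classmethod
    def from_tsv(cls, counts_paths: dict, sample_sheet_path,
                 annotation_paths: dict | None = None, **kwargs):
        meta = cdmod.read_sample_sheet(sample_sheet_path)
        counts = {sp: cdmod.read_counts(path, sp, meta)
                  for sp, path in sorted(counts_paths.items())}
        ann = {sp: enmod.read_annotations(path)
               for sp, path in sorted((annotation_paths or {}).items())}
        return cls(counts, annotations=ann or None, **kwargs)

    # ---------------------------------------------------------------- fit

    def fit(self) -> "InteractionResults":
        self._norm_cache: dict = {}
        species_results = {}
        for sp in self.roster:
            if sp in self.counts:
                species_results[sp] = self._fit_species(sp)
        res = InteractionResults(model=self, species=species_results)
        self._cross_species(res)
        self._norm_cache = {}
        return res

    def _available(self, cm, cond: Condition) -> bool:
        return bool(cm.samples_of(cond))

    def _fit_species(self, sp: str) -> SpeciesResult:
        cm = self.counts[sp]
        result = SpeciesResult(species=sp, genome_size=len(cm.genes), n_filtered=0)

        core = core_conditions(sp, self.roster)
        core_avail = [c for c in core if self._available(cm, c)]
        for c in core:
            if c not in core_avail:
                result.skipped.append(f"no samples for core condition {c.name}")
        if not core_avail:
            result.skipped.append("no core conditions at all; species skipped")
            return result
        filtered = cdmod.filter_low_expression(cm, core_avail, self.min_total,
                                               mode=self.filter_mode)
        result.n_filtered = len(filtered.genes)
        factors = (cdmod.median_of_ratios_factors(filtered)
                   if self.normalization == "median_ratios" else None)
        nm = cdmod.cpm_normalize(filtered, norm_factors=factors)
        self._norm_cache[sp] = (filtered, nm)

        specs = intmod.enumerate_comparisons(sp, self.roster)
        for spec in specs:
            if self._available(cm, spec.baseline) and self._available(cm, spec.treatment):
                result.de[spec.label] = run_comparison(
                    filtered, nm, spec, pseudo_cpm=self.pseudo_cpm,
                    prior_weight=self.dispersion_prior_weight)
            else:
                result.skipped.append(f"comparison {spec.label} (missing condition)")

        cat1 = [result.de[s.label] for s in specs if s.category == "I"
                and s.label in result.de]
        cat2 = {next(iter(s.added_members)): result.de[s.label]
                for s in specs if s.category == "II" and s.label in result.de}
        cat3 = next((result.de[s.label] for s in specs
                     if s.category == "III" and s.label in result.de), None)

        for de in cat1:
            result.regulated_pct[de.label] = intmod.regulated_fraction(
                de, self.fc_cut, self.alpha, genome_size=result.genome_size)

        if len(cat1) == 2:
            ct = intmod.classify_pairwise_response(cat1[0], cat1[1], alpha=self.alpha)
            result.classification = ct
            self._higher_order(result, ct, cat1, cat2)
            if cat3 is not None and cat2:
                result.community_specific = list(intmod.community_specific_genes(
                    cat1[0], cat1[1], list(cat2.values()), cat3,
                    alpha=self.alpha, fc_cut=self.fc_cut))
            self._additivity(result, cm, sp, ct)
        if cat3 is not None:
            sig3 = cat3.significant(self.alpha)
            genes3 = cat3.genes[sig3]
            if len(genes3) >= 3:
                for label, de in result.de.items():
                    if de is cat3:
                        continue
                    result.driver[label] = intmod.driver_regression(
                        cat3.table.loc[genes3, "log2FC"].values,
                        de.table.loc[genes3, "log2FC"].values)
        self._attribution(result, sp, cm, filtered, nm)
        return result

    def _higher_order(self, result, ct, cat1, cat2):
        """Category-II regulation of the >fc_cut partner-specific gene sets."""
        for partner, other in ((ct.partner_x, ct.partner_y), (ct.partner_y, ct.partner_x)):
            col = "log2FC_x" if partner == ct.partner_x else "log2FC_y"
            for sign, suffix in ((1, "up"), (-1, "down")):
                cls = f"{partner}_only_{suffix}"
                genes = ct.genes_in_class(cls)
                genes = genes[ct.table.loc[genes, col].abs() > self.fc_cut]
                if other in cat2 and len(genes):
                    result.higher_order[cls] = intmod.detect_higher_order(
                        genes, cat2[other], alpha=self.alpha)

    def _additivity(self, result, cm, sp, ct):
        core = core_conditions(sp, self.roster)
        if any(not cm.samples_of(c) for c in core):
            result.skipped.append("additivity (incomplete core conditions)")
            return
        # log-ratio comparisons need per-condition quantifiability: refilter
        # with the "each" mode so every gene has counts in all four conditions
        quant = cdmod.filter_low_expression(cm, core, self.min_total, mode="each")
        factors = (cdmod.median_of_ratios_factors(quant)
                   if self.normalization == "median_ratios" else None)
        nm = cdmod.cpm_normalize(quant, norm_factors=factors)
        alone, pair1, pair2, community = core[0], core[1], core[2], core[3]
        rt = addmod.build_ratio_table(nm, alone, pair1, pair2, community,
                                      pseudo_cpm=self.pseudo_cpm)
        sets = {}
        for cls in ("dual_same_up", "dual_same_down", "dual_opposite"):
            genes = ct.genes_in_class(cls)
            mask = (ct.table.loc[genes, ["log2FC_x", "log2FC_y"]].abs()
                    > self.fc_cut).all(axis=1)
            sets[cls] = genes[mask.values]
        for partner in (ct.partner_x, ct.partner_y):
            col = "log2FC_x" if partner == ct.partner_x else "log2FC_y"
            for suffix in ("up", "down"):
                genes = ct.genes_in_class(f"{partner}_only_{suffix}")
                genes = genes[ct.table.loc[genes, col].abs() > self.fc_cut]
                sets[f"{partner}_only_{suffix}"] = genes
        result.ratio_table = rt
        for name, genes in sets.items():
            genes = genes.intersection(rt.table.index)
            if len(genes) >= 5:
                result.additivity[name] = addmod.additivity_tests(rt, genes)

    def _attribution(self, result, sp, cm, filtered, nm):
        """Wild-type vs producer-mutant reversal for receiver species."""
        if sp == PRODUCER or PRODUCER not in self.roster:
            return
        pair_wt = Condition({sp, PRODUCER})
        pair_mut = Condition({sp, PRODUCER}, genotype="dkec")
        if not (self._available(cm, pair_wt) and self._available(cm, pair_mut)):
            result.skipped.append("attribution (no mutant pairwise condition)")
            return
        wt_label = intmod.ComparisonSpec(sp, Condition({sp}), pair_wt).label
        de_wt = result.de.get(wt_label)
        if de_wt is None:
            return
        contrast = PlainContrast(sp, pair_wt, pair_mut)
        de_mut = run_comparison(filtered, nm, contrast, pseudo_cpm=self.pseudo_cpm,
                                prior_weight=self.dispersion_prior_weight)
        result.de[contrast.label] = de_mut
        at = pertmod.attribute_reversal(de_wt, de_mut, fc_cut=self.fc_cut,
                                        alpha=self.alpha)
        result.attribution = at
        eligible = at.table.index[at.table["eligible"]]
        if len(eligible) >= 3:
            result.reversal_rho = pertmod.reversal_correlation(
                at.table.loc[eligible, "fc_wt"].values,
                at.table.loc[eligible, "fc_mut_contrast"].values)
        self._dependent_enrichment(result, sp, at)

    def _dependent_enrichment(self, result, sp, at):
        ann = self.annotations.get(sp)
        if ann is None:
            return
        genome = at.table.index
        dep = at.table["dependent"]
        for direction, mask in (("up", dep & (at.table["fc_wt"] > 0)),
                                ("down", dep & (at.table["fc_wt"] < 0))):
            genes = genome[mask]
            if len(genes):
                result.enrichment[f"kec_dependent_{direction}"] = \
                    enmod.enrichment_index_table(genes, ann, genome)

    def _cross_species(self, res: "InteractionResults"):
        self._producer_summaries(res)
        self._shared_dependent(res)

    def _producer_summaries(self, res):
        """Inoculum/genotype DEG-count heat map and antibiotic-locus fold change."""
        sp = PRODUCER
        if sp not in self.counts or sp not in res.species:
            return
        cm = self.counts[sp]
        result = res.species[sp]
        partners = [s for s in self.roster if s != sp]
        if sp not in self._norm_cache:
            return
        filtered, nm = self._norm_cache[sp]

        schemes = {}
        alone_wt = Condition({sp})

        def find_existing(baseline, treatment):
            for de in result.de.values():
                c = de.comparison
                if (getattr(c, "baseline", None) == baseline
                        and getattr(c, "treatment", None) == treatment):
                    return de
            return None

        def add(scheme, label, baseline, treatment):
            if self._available(cm, baseline) and self._available(cm, treatment):
                de = find_existing(baseline, treatment)
                if de is None:
                    contrast = PlainContrast(sp, baseline, treatment)
                    de = run_comparison(filtered, nm, contrast,
                                        pseudo_cpm=self.pseudo_cpm,
                                        prior_weight=self.dispersion_prior_weight)
                    result.de[contrast.label] = de
                schemes[(scheme, label)] = de
            else:
                schemes[(scheme, label)] = None

        full = Condition(self.roster)
        for pr in partners:
            add("WT", f"alone_vs_+{pr}", alone_wt, Condition({sp, pr}))
            add("WT", f"+{pr}_vs_community", Condition({sp, pr}), full)
            add("dkec", f"alone_vs_+{pr}", Condition({sp}, genotype="dkec"),
                Condition({sp, pr}, genotype="dkec"))
            add("dkec", f"+{pr}_vs_community", Condition({sp, pr}, genotype="dkec"),
                Condition(self.roster, genotype="dkec"))
        li = Condition({sp, "F"}, inoculum="low") if "F" in partners else None
        if li is not None:
            add("PLI", "alone_vs_+F", alone_wt, li)
        res.inoculum_summary = pertmod.inoculum_contrast_summary(
            schemes, fc_cut=self.fc_cut, alpha=self.alpha)

        if self.kec_genes and li is not None:
            de_li = schemes.get(("PLI", "alone_vs_+F"))
            if de_li is not None:
                kec = [g for g in self.kec_genes if g in de_li.genes]
                if kec:
                    fold, direction, per_gene = pertmod.summarize_gene_set_fc(de_li, kec)
                    res.kec_fold = {"mean_fold": fold, "direction": direction,
                                    "n_genes": len(kec)}

    def _shared_dependent(self, res):
        """Shared annotations + Jaccard between the two receivers' dependent sets."""
        receivers = [s for s in self.roster if s != PRODUCER]
        if len(receivers) != 2:
            return
        a, b = receivers
        ra, rb = res.species.get(a), res.species.get(b)
        if not (ra and rb and ra.attribution is not None and rb.attribution is not None
                and a in self.annotations and b in self.annotations):
            return
        for direction in ("up", "down"):
            sign = 1 if direction == "up" else -1
            sets = {}
            fcs = {}
            for sp, r in ((a, ra), (b, rb)):
                t = r.attribution.table
                mask = t["dependent"] & (np.sign(t["fc_wt"]) == sign)
                sets[sp] = t.index[mask]
                fcs[sp] = t["fc_wt"]
            shared = enmod.shared_annotations(sets[a], self.annotations[a],
                                              sets[b], self.annotations[b],
                                              fc_a=fcs[a], fc_b=fcs[b])
            jac = enmod.jaccard_similarity(len(sets[a]), len(sets[b]), len(shared))
            res.shared[direction] = {"table": shared, "n_a": len(sets[a]),
                                     "n_b": len(sets[b]), "jaccard": jac}

    # -------------------------------------------------------------- config

    def config_dict(self) -> dict:
        return {"roster": list(self.roster), "alpha": self.alpha,
                "fc_cut": self.fc_cut, "min_total": self.min_total,
                "pseudo_cpm": self.pseudo_cpm, "filter_mode": self.filter_mode,
                "normalization": self.normalization,
                "dispersion_prior_weight": self.dispersion_prior_weight,
                "kec_genes": self.kec_genes}

    def config_hash(self) -> str:
        blob = json.dumps(self.config_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class InteractionResults:
    """Fitted results: DE tables, classifications, additivity and
    attribution reports, enrichment tables and machine-readable summaries."""

    def __init__(self, model: CommunityInteractionModel, species: dict):
        self.model = model
        self.species = species
        self.inoculum_summary: pd.DataFrame | None = None
        self.kec_fold: dict | None = None
        self.shared: dict = {}

    @property
    def complete(self) -> bool:
        return all(not r.skipped for r in self.species.values())

    def summary_dict(self) -> dict:
        out = {"config": self.model.config_dict(),
               "config_hash": self.model.config_hash(), "species": {}}
        for sp, r in self.species.items():
            entry = {
                "genome_size": r.genome_size, "n_filtered": r.n_filtered,
                "filtered_pct": round(100.0 * r.n_filtered / r.genome_size, 1)
                if r.genome_size else None,
                "regulated_pct": r.regulated_pct,
                "deg_counts": {label: int(de.significant(self.model.alpha,
                                                         self.model.fc_cut).sum())
                               for label, de in r.de.items()},
                "skipped": r.skipped,
            }
            if r.classification is not None:
                entry["class_counts"] = {k: int(v) for k, v
                                         in r.classification.class_counts().items()}
            if r.higher_order:
                entry["higher_order_counts"] = {k: int(len(v))
                                                for k, v in r.higher_order.items()}
            entry["community_specific_n"] = len(r.community_specific)
            if r.driver:
                entry["driver_r2"] = {k: round(v[2], 4) for k, v in r.driver.items()}
            if r.attribution is not None:
                entry["attribution"] = {
                    "n_eligible": r.attribution.n_eligible,
                    "n_dependent": r.attribution.n_dependent,
                    "fraction": round(r.attribution.fraction, 4)
                    if r.attribution.n_eligible else None,
                    "spearman_rho": round(r.reversal_rho, 4)
                    if r.reversal_rho is not None else None,
                }
            out["species"][sp] = entry
        if self.inoculum_summary is not None:
            out["inoculum_deg_counts"] = {
                col: {idx: (None if pd.isna(v) else int(v))
                      for idx, v in self.inoculum_summary[col].items()}
                for col in self.inoculum_summary.columns}
        if self.kec_fold is not None:
            out["kec_fold"] = {"mean_fold": round(self.kec_fold["mean_fold"], 2),
                               "direction": self.kec_fold["direction"],
                               "n_genes": self.kec_fold["n_genes"]}
        if self.shared:
            out["shared_dependent"] = {
                d: {"n_a": v["n_a"], "n_b": v["n_b"],
                    "n_shared": int(len(v["table"])), "jaccard": v["jaccard"]}
                for d, v in self.shared.items()}
        return out

    def summary(self) -> str:
        lines = [f"CommunityInteractionModel results "
                 f"(config {self.model.config_hash()})", ""]
        for sp, r in self.species.items():
            lines.append(f"[{sp}] genome {r.genome_size}, "
                         f"{r.n_filtered} genes pass the expression filter "
                         f"({100.0 * r.n_filtered / max(r.genome_size, 1):.1f}%)")
            for label, pct in r.regulated_pct.items():
                lines.append(f"  {label}: {pct}% of genome regulated "
                             f"(>|{self.model.fc_cut}| log2, fdr<{self.model.alpha})")
            if r.classification is not None:
                cc = r.classification.class_counts()
                lines.append("  classes: " + ", ".join(f"{k}={v}" for k, v in cc.items()
                                                       if v))
            if r.attribution is not None and r.attribution.n_eligible:
                lines.append(f"  antibiotic-dependent: {r.attribution.n_dependent}"
                             f"/{r.attribution.n_eligible} "
                             f"({100 * r.attribution.fraction:.0f}%)"
                             + (f", Spearman rho {r.reversal_rho:.3f}"
                                if r.reversal_rho is not None else ""))
            for s in r.skipped:
                lines.append(f"  skipped: {s}")
        if self.kec_fold is not None:
            lines.append(f"antibiotic locus: {self.kec_fold['mean_fold']:.1f}-fold "
                         f"{self.kec_fold['direction']} at low producer inoculum")
        for d, v in self.shared.items():
            lines.append(f"shared dependent ({d}): {len(v['table'])} annotations, "
                         f"Jaccard {v['jaccard']}")
        return "\n".join(lines)

    def to_directory(self, outdir) -> None:
        os.makedirs(outdir, exist_ok=True)
        for sp, r in self.species.items():
            for label, de in r.de.items():
                safe = label.replace(":", "__")
                write_de_table(de, os.path.join(outdir, f"de_{safe}.tsv"))
            if r.classification is not None:
                intmod.write_classification(
                    r.classification, os.path.join(outdir, f"classification_{sp}.tsv"))
            for name, report in r.additivity.items():
                addmod.write_additivity_report(
                    report, os.path.join(outdir, f"additivity_{sp}_{name}.tsv"))
            if r.attribution is not None:
                pertmod.write_attribution(
                    r.attribution, os.path.join(outdir, f"attribution_{sp}.tsv"))
            for name, table in r.enrichment.items():
                enmod.write_enrichment(
                    table, os.path.join(outdir, f"enrichment_{sp}_{name}.tsv"))
        if self.inoculum_summary is not None:
            with open(os.path.join(outdir, "inoculum_deg_counts.tsv"), "w",
                      encoding="utf-8", newline="\n") as fh:
                self.inoculum_summary.to_csv(fh, sep="\t", lineterminator="\n")
        for d, v in self.shared.items():
            with open(os.path.join(outdir, f"shared_dependent_{d}.tsv"), "w",
                      encoding="utf-8", newline="\n") as fh:
                v["table"].to_csv(fh, sep="\t", index=False, lineterminator="\n")
        with open(os.path.join(outdir, "summary.json"), "w",
                  encoding="utf-8", newline="\n") as fh:
            json.dump(self.summary_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def run_pipeline(counts_paths: dict, sample_sheet_path, outdir,
                 annotation_paths: dict | None = None, **config):
    """Convenience wrapper: build the model from TSVs, fit, write outputs.

    Returns the fitted :class:`InteractionResults`; callers can inspect
    ``results.complete`` to distinguish full from partial runs.
    """
    model = CommunityInteractionModel.from_tsv(
        counts_paths, sample_sheet_path, annotation_paths, **config)
    results = model.fit()
    results.to_directory(outdir)
    return results
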