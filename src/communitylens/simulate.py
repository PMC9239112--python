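"""Synthetic coculture RNA-seq count generator with planted ground truth.

Emulates the statistical structure of a three-member coculture
metatranscriptomics design: per-species gene x sample negative-binomial
counts over monoculture, pairwise, community, antibiotic-null mutant
(``dkec``) and low-producer-inoculum (``PLI``) conditions, with

* planted interaction classes (partner-specific, dual-same, dual-opposite),
* per-gene community rules (additive, dominant-partner, muted),
* koreenceine-dependent effects that vanish (or reverse) under ``dkec``,
* inoculum-gated producer responses that switch on only at low inoculum,
* species-abundance-coupled sequencing depth (the receiver suppressed by
  the producer yields far fewer mapped reads),

plus a per-species truth table for recovery scoring.  The same seed gives
bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .conditions import Condition, DEFAULT_ROSTER, PRODUCER
from .count_data import CountMatrix, write_counts, write_sample_sheet

#: per-gene response classes relative to the two (sorted) partners
CLASS_KEYS = ("none",
              "partner1_only_up", "partner1_only_down",
              "partner2_only_up", "partner2_only_down",
              "dual_same_up", "dual_same_down", "dual_opposite")

DEFAULT_CLASS_PROBS = {
    "none": 0.85,
    "partner1_only_up": 0.025, "partner1_only_down": 0.025,
    "partner2_only_up": 0.025, "partner2_only_down": 0.025,
    "dual_same_up": 0.02, "dual_same_down": 0.02,
    "dual_opposite": 0.01,
}

DEFAULT_RULE_PROBS = {"additive": 0.6, "dominant_partner": 0.3, "muted": 0.1}

#: expected mapped reads per species, mirroring a design where the producer
#: numerically dominates cocultures and suppresses the receiver's depth
DEFAULT_DEPTH_ALONE = {"B": 4.0e6, "F": 1.7e6, "P": 2.3e6}
DEFAULT_DEPTH_COCULTURE = {"B": 2.9e6, "P": 17.5e6}
SUPPRESSED_DEPTH = {"F": 0.4e6}  # receiver with wild-type producer, standard inoculum


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic community."""

    roster: tuple = DEFAULT_ROSTER
    genome_sizes: dict = field(default_factory=lambda: {"B": 6155, "F": 5207, "P": 5854})
    conditions: list = None  # default: 7 WT + 4 dkec + FP_PLI
    replicates: int = 4
    expressed_fraction: float = 0.78
    baseline_sigma: float = 1.6
    unexpressed_scale: float = 2e-4
    dispersion: float = 0.1
    class_probs: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_PROBS))
    effect_range: tuple = (1.5, 4.0)
    community_rule_probs: dict = field(default_factory=lambda: dict(DEFAULT_RULE_PROBS))
    kec_dependent_fraction: float = 0.8
    dkec_mode: str = "null"  # "null": effect absent in mutant coculture; "reverse": sign flips
    n_kec_genes: int = 11
    kec_li_fold: float = 12.5
    kec_deletion_factor: float = 1e-4
    li_always_on_fraction: float = 0.01
    depth_overrides: dict = field(default_factory=dict)  # (species, cond_name) -> reads
    depth_scale: float = 1.0  # global depth multiplier (scaled-down designs)
    seed: int = 0

    def __post_init__(self):
        if self.conditions is None:
            self.conditions = default_conditions(self.roster)
        if abs(sum(self.class_probs.values()) - 1) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if abs(sum(self.community_rule_probs.values()) - 1) > 1e-9:
            raise ValueError("community rule proportions must sum to 1")
        if any(v <= 0 for v in self.depth_overrides.values()):
            raise ValueError("depths must be > 0")
        if self.dkec_mode not in ("null", "reverse"):
            raise ValueError("dkec_mode must be 'null' or 'reverse'")
        for key in self.class_probs:
            if key not in CLASS_KEYS:
                raise ValueError(f"unknown class {key!r}")

    def depth(self, species: str, cond: Condition) -> float:
        override = self.depth_overrides.get((species, cond.name))
        if override is not None:
            return float(override) * self.depth_scale
        if len(cond.members) == 1:
            base = DEFAULT_DEPTH_ALONE.get(species, 2e6)
        elif (species in SUPPRESSED_DEPTH and PRODUCER in cond.members
                and cond.genotype == "WT" and cond.inoculum == "standard"):
            base = SUPPRESSED_DEPTH[species]
        elif species in SUPPRESSED_DEPTH:
            base = DEFAULT_DEPTH_ALONE.get(species, 2e6)
        else:
            base = DEFAULT_DEPTH_COCULTURE.get(species, 2e6)
        return base * self.depth_scale


def default_conditions(roster=DEFAULT_ROSTER) -> list:
    """7 wild-type membership sets + 4 producer-mutant sets + low inoculum."""
    roster = tuple(sorted(roster))
    conds = []
    for r in range(1, len(roster) + 1):
        conds.extend(Condition(frozenset(c)) for c in _subsets(roster, r))
    if PRODUCER in roster:
        for c in conds[:]:
            if PRODUCER in c.members:
                conds.append(Condition(c.members, genotype="dkec"))
        partner = "F" if "F" in roster else None
        if partner:
            conds.append(Condition({partner, PRODUCER}, inoculum="low"))
    return conds


def _subsets(roster, r):
    from itertools import combinations
    return ["".join(c) for c in combinations(roster, r)]


@dataclass
class SimResult:
    config: SimConfig
    counts: dict  # species -> CountMatrix
    truth: dict   # species -> DataFrame
    sample_meta: dict


def _plant_species_truth(cfg: SimConfig, species: str, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.genome_sizes[species]
    partners = sorted(s for s in cfg.roster if s != species)
    genes = [f"{species}_{i:05d}" for i in range(1, n + 1)]
    expressed = rng.random(n) < cfg.expressed_fraction
    baseline = np.exp(rng.normal(0.0, cfg.baseline_sigma, size=n))
    baseline[~expressed] *= cfg.unexpressed_scale

    keys = list(cfg.class_probs)
    cls = rng.choice(keys, size=n, p=[cfg.class_probs[k] for k in keys])
    cls[~expressed] = "none"

    lo, hi = cfg.effect_range
    mag1 = rng.uniform(lo, hi, size=n)
    mag2 = rng.uniform(lo, hi, size=n)
    opp_first_up = rng.random(n) < 0.5
    eff1 = np.zeros(n)
    eff2 = np.zeros(n)
    for i, c in enumerate(cls):
        if c == "partner1_only_up":
            eff1[i] = mag1[i]
        elif c == "partner1_only_down":
            eff1[i] = -mag1[i]
        elif c == "partner2_only_up":
            eff2[i] = mag2[i]
        elif c == "partner2_only_down":
            eff2[i] = -mag2[i]
        elif c == "dual_same_up":
            eff1[i], eff2[i] = mag1[i], mag2[i]
        elif c == "dual_same_down":
            eff1[i], eff2[i] = -mag1[i], -mag2[i]
        elif c == "dual_opposite":
            sgn = 1.0 if opp_first_up[i] else -1.0
            eff1[i], eff2[i] = sgn * mag1[i], -sgn * mag2[i]

    rules = list(cfg.community_rule_probs)
    rule = rng.choice(rules, size=n, p=[cfg.community_rule_probs[r] for r in rules])

    has_p_effect = np.zeros(n, dtype=bool)
    if species != PRODUCER and PRODUCER in partners:
        p_idx = partners.index(PRODUCER)
        has_p_effect = (eff1 if p_idx == 0 else eff2) != 0
    kec_dependent = has_p_effect & (rng.random(n) < cfg.kec_dependent_fraction)

    li_responsive = np.zeros(n, dtype=bool)
    if species == PRODUCER and "F" in partners:
        f_idx = partners.index("F")
        has_f_effect = (eff1 if f_idx == 0 else eff2) != 0
        always_on = rng.random(n) < cfg.li_always_on_fraction
        li_responsive = has_f_effect & ~always_on

    kec_marker = np.zeros(n, dtype=bool)
    if species == PRODUCER:
        # the antibiotic cluster is actively transcribed in monoculture:
        # markers come from the above-median-expression stratum
        elig = np.flatnonzero(expressed & (baseline > np.median(baseline[expressed])))
        marker_idx = elig[: cfg.n_kec_genes]
        kec_marker[marker_idx] = True
        for arr in (eff1, eff2):
            arr[marker_idx] = 0.0
        cls[marker_idx] = "none"
        li_responsive[marker_idx] = False

    df = pd.DataFrame({
        "expressed": expressed, "baseline": baseline, "class": cls,
        f"effect_{partners[0]}": eff1, f"effect_{partners[1]}": eff2,
        "community_rule": rule, "kec_dependent": kec_dependent,
        "li_responsive": li_responsive, "kec_marker": kec_marker,
    }, index=pd.Index(genes, name="gene_id"))
    # the class recoverable from wild-type standard pairwise contrasts
    df["class_catI"] = _effective_classes(df, species, partners)
    return df


def _gated_effects(truth: pd.DataFrame, partner: str, species: str, genotype: str,
                   inoculum: str, dkec_mode: str) -> np.ndarray:
    """Planted partner effects after genotype / inoculum gating."""
    e = truth[f"effect_{partner}"].values.astype(float).copy()
    if species != PRODUCER and partner == PRODUCER and genotype == "dkec":
        dep = truth["kec_dependent"].values
        e[dep] = -e[dep] if dkec_mode == "reverse" else 0.0
    if species == PRODUCER and partner == "F" and inoculum != "low":
        e[truth["li_responsive"].values] = 0.0
    return e


def _effective_classes(truth: pd.DataFrame, species: str, partners) -> np.ndarray:
    e1 = _gated_effects(truth, partners[0], species, "WT", "standard", "null")
    e2 = _gated_effects(truth, partners[1], species, "WT", "standard", "null")
    out = np.full(len(truth), "none", dtype=object)
    only1 = (e1 != 0) & (e2 == 0)
    only2 = (e2 != 0) & (e1 == 0)
    both = (e1 != 0) & (e2 != 0)
    out[only1 & (e1 > 0)] = f"{partners[0]}_only_up"
    out[only1 & (e1 < 0)] = f"{partners[0]}_only_down"
    out[only2 & (e2 > 0)] = f"{partners[1]}_only_up"
    out[only2 & (e2 < 0)] = f"{partners[1]}_only_down"
    same = np.sign(e1) == np.sign(e2)
    out[both & same & (e1 > 0)] = "dual_same_up"
    out[both & same & (e1 < 0)] = "dual_same_down"
    out[both & ~same] = "dual_opposite"
    return out


def _condition_log2_effect(truth: pd.DataFrame, species: str, cond: Condition,
                           cfg: SimConfig) -> np.ndarray:
    partners = sorted(s for s in cfg.roster if s != species)
    active = [p for p in partners if p in cond.members]
    gated = {p: _gated_effects(truth, p, species, cond.genotype, cond.inoculum,
                               cfg.dkec_mode)
             for p in active}
    n = len(truth)
    if not active:
        eff = np.zeros(n)
    elif len(active) == 1:
        eff = gated[active[0]]
    else:
        add = sum(gated[p] for p in active)
        dominant = PRODUCER if species != PRODUCER else ("B" if "B" in active else active[0])
        dom = gated.get(dominant, np.zeros(n))
        rule = truth["community_rule"].values
        eff = np.where(rule == "additive", add,
                       np.where(rule == "dominant_partner", dom, 0.0))
    if species == PRODUCER:
        marker = truth["kec_marker"].values
        if cond.genotype == "dkec":
            eff = eff + np.where(marker, np.log2(cfg.kec_deletion_factor), 0.0)
        elif cond.inoculum == "low":
            eff = eff + np.where(marker, -np.log2(cfg.kec_li_fold), 0.0)
    return eff


def simulate_community(cfg: SimConfig, seed: int | None = None) -> SimResult:
    """Generate count matrices, truth tables and a sample sheet.

    Counts for gene g in condition c are NB(mean, phi) with
    ``mean = baseline_g * 2^(effects active in c)`` scaled so the expected
    column sum equals the species' depth target for c.
    """
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    sample_meta: dict = {}
    for cond in cfg.conditions:
        for r in range(1, cfg.replicates + 1):
            sample_meta[f"{cond.name}_r{r}"] = (cond, r)

    counts: dict = {}
    truth: dict = {}
    for species in cfg.roster:
        t = _plant_species_truth(cfg, species, rng)
        truth[species] = t
        cols = {}
        for cond in cfg.conditions:
            if species not in cond.members:
                continue
            eff = _condition_log2_effect(t, species, cond, cfg)
            rel = t["baseline"].values * np.exp2(eff)
            mean = rel / rel.sum() * cfg.depth(species, cond)
            for r in range(1, cfg.replicates + 1):
                cols[f"{cond.name}_r{r}"] = _nb_draw(rng, mean, cfg.dispersion)
        mat = pd.DataFrame(cols, index=t.index)
        counts[species] = CountMatrix(species=species, counts=mat, sample_meta=sample_meta)
    return SimResult(config=cfg, counts=counts, truth=truth, sample_meta=sample_meta)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    if phi <= 0:
        return rng.poisson(mean)
    size = 1.0 / phi
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def write_simulation(sim: SimResult, outdir) -> None:
    """Write counts TSVs, sample sheet, truth TSVs and the resolved config."""
    import os
    os.makedirs(outdir, exist_ok=True)
    write_sample_sheet(sim.sample_meta, os.path.join(outdir, "sample_sheet.tsv"))
    for species, cm in sim.counts.items():
        write_counts(cm, os.path.join(outdir, f"counts_{species}.tsv"))
        with open(os.path.join(outdir, f"truth_{species}.tsv"), "w",
                  encoding="utf-8", newline="\n") as fh:
            sim.truth[species].to_csv(fh, sep="\t", lineterminator="\n",
                                      float_format="%.6g")
    resolved = dataclasses.asdict(sim.config)
    resolved["conditions"] = [c.name for c in sim.config.conditions]
    resolved["depth_overrides"] = {f"{sp}:{cn}": v for (sp, cn), v
                                   in sim.config.depth_overrides.items()}
    with open(os.path.join(outdir, "config_resolved.yaml"), "w",
              encoding="utf-8", newline="\n") as fh:
        yaml.safe_dump(resolved, fh, sort_keys=True)


def load_sim_config(path) -> SimConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if "conditions" in raw and raw["conditions"] is not None:
        raw["conditions"] = [Condition.from_name(n) for n in raw["conditions"]]
    if "roster" in raw:
        raw["roster"] = tuple(raw["roster"])
    if "effect_range" in raw:
        raw["effect_range"] = tuple(raw["effect_range"])
    if "depth_overrides" in raw:
        raw["depth_overrides"] = {tuple(k.split(":", 1)): v
                                  for k, v in raw["depth_overrides"].items()}
    return SimConfig(**raw)


def recovery_metrics(truth: pd.DataFrame, classification) -> dict:
    """Score an observed classification against the planted truth.

    Uses the truth's wild-type-pairwise effective class (``class_catI``).
    Returns per-class sensitivity, aggregate partner-specific sensitivity,
    the false-positive rate on planted-null genes, and the confusion matrix.
    """
    universe = classification.table.index
    missing = universe.difference(truth.index)
    if len(missing):
        raise ValueError("classification universe not aligned with truth")
    t = truth.loc[universe, "class_catI"]
    o = classification.table["class"]
    confusion = pd.crosstab(t, o, dropna=False)
    per_class = {}
    for cls in t.unique():
        mask = t == cls
        per_class[cls] = float((o[mask] == cls).mean())
    partner_classes = [c for c in t.unique() if c.endswith(("_only_up", "_only_down"))]
    partner_mask = t.isin(partner_classes)
    partner_sens = float((o[partner_mask] == t[partner_mask]).mean()) if partner_mask.any() else float("nan")
    null_mask = t == "none"
    null_fpr = float((o[null_mask] != "none").mean()) if null_mask.any() else float("nan")
    return {"per_class_sensitivity": per_class,
            "partner_specific_sensitivity": partner_sens,
            "null_fpr": null_fpr,
            "confusion": confusion}
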