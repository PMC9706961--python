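"""Orchestration of the full simulation study and its statistics.

``run_study`` chains the stages: sample X_i uniformly from the networks
producing phenotype A, derive the paired ensembles X_D (duplication) and
X_a (unrelated-gene addition), run the robustness / similarity / access
assays on every network before and after the gene gain, and assemble
tidy result tables plus the statistical comparisons (Spearman
correlations, paired Wilcoxon signed-rank tests, Mann-Whitney U tests,
and a type-II two-way ANOVA of similarity on regulator class x target
class with classical eta-squared effect sizes).  All randomness derives
from one master seed through spawned generator streams, so a rerun with
the same configuration reproduces every table byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

from .assays import (
    AccessClassification,
    StratifiedSimilarityRecord,
    access_profile,
    assay_addition,
    assay_duplication,
    assay_mutational,
    classify_access,
    duplicate_structural_props,
    stratified_mutation_assay,
)
from .core import ModelConfig, Phenotype, pattern_from_matrix, phenotype_similarity
from .sampler import NetworkSample, build_paired_ensembles, make_founder, mc_walk_sample

__all__ = [
    "StudyConfig",
    "StatResult",
    "run_study",
    "anova2_typeII",
    "summarize_access",
    "spearman",
    "wilcoxon_paired",
    "mann_whitney",
]


@dataclass
class StudyConfig:
    """Configuration of one full study run.

    ``n_networks`` is the X_i sample size (the study headline numbers use
    1000; directional effects are already stable near 200).
    ``n_stratified`` caps how many duplicate-carrying networks enter the
    deletion/addition stratified assay, the single most expensive stage.
    """

    model: ModelConfig = field(default_factory=ModelConfig)
    n_networks: int = 1000
    master_seed: int = 0
    output_dir: str | None = None
    alpha: float = 0.01
    n_stratified: int = 100

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.n_networks < 2:
            raise ValueError("n_networks must be >= 2")


@dataclass
class StatResult:
    test_name: str
    statistic: float
    p_value: float
    effect_size: float | None = None
    n: int | tuple = 0


def spearman(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Spearman rank correlation with mid-rank tie handling."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return StatResult("spearman", math.nan, math.nan, n=len(x))
    rho, p = sps.spearmanr(x, y)
    return StatResult("spearman", float(rho), float(p), n=len(x))


def wilcoxon_paired(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Paired Wilcoxon signed-rank test; zero differences are dropped."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    nz = x != y
    if not nz.any():
        return StatResult("wilcoxon_signed_rank", math.nan, 1.0, n=len(x))
    res = sps.wilcoxon(x[nz], y[nz], zero_method="wilcox")
    return StatResult(
        "wilcoxon_signed_rank", float(res.statistic), float(res.pvalue), n=int(nz.sum())
    )


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> StatResult:
    res = sps.mannwhitneyu(x, y, alternative="two-sided")
    return StatResult(
        "mann_whitney_u", float(res.statistic), float(res.pvalue), n=(len(x), len(y))
    )


def anova2_typeII(
    records: Iterable[StratifiedSimilarityRecord] | pd.DataFrame,
) -> dict[str, StatResult]:
    """Type-II two-way ANOVA of similarity on regulator class and target
    class, with classical eta-squared (SS_effect / SS_total) per term.

    Raises ``ValueError`` naming the first empty design cell if any
    regulator x target combination has no observations.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(
            {
                "regulator_class": [r.regulator_class for r in records],
                "target_class": [r.target_class for r in records],
                "similarity": [r.similarity for r in records],
            }
        )
    for col in ("regulator_class", "target_class"):
        if df[col].nunique() < 2:
            raise ValueError(f"factor {col} needs at least two levels")
    cells = df.groupby(["regulator_class", "target_class"], observed=True).size()
    for rc in df["regulator_class"].unique():
        for tc in df["target_class"].unique():
            if (rc, tc) not in cells.index:
                raise ValueError(f"empty design cell: regulator={rc}, target={tc}")
    y = df["similarity"].to_numpy(dtype=float)
    ss_total = float(np.sum((y - y.mean()) ** 2))
    out: dict[str, StatResult] = {}
    terms = {
        "regulator": "C(regulator_class)",
        "target": "C(target_class)",
        "interaction": "C(regulator_class):C(target_class)",
    }
    if ss_total == 0.0:  # constant response: no variance to attribute
        for name in terms:
            out[name] = StatResult("anova2_typeII", 0.0, 1.0, effect_size=0.0, n=len(df))
        return out
    model = smf.ols(
        "similarity ~ C(regulator_class) * C(target_class)", data=df
    ).fit()
    table = sm.stats.anova_lm(model, typ=2)
    for name, label in terms.items():
        ss = float(table.loc[label, "sum_sq"])
        out[name] = StatResult(
            "anova2_typeII",
            float(table.loc[label, "F"]),
            float(table.loc[label, "PR(>F)"]),
            effect_size=ss / ss_total,
            n=len(df),
        )
    return out


def summarize_access(
    classifications: Sequence[AccessClassification],
    reference: Phenotype,
    resistant: Sequence[bool] | None = None,
) -> pd.DataFrame:
    """Per-network access summary: class sizes, the recurrent share of the
    post-gain repertoire, mean pre-gain mutation counts of recurrent vs.
    lost phenotypes, and mean similarity to the reference per class.

    Classes with no members yield NaN means.  ``resistant`` flags, when
    given, are carried through for group-level aggregation.
    """
    rows = []
    for idx, cls in enumerate(classifications):
        n_rec, n_lost, n_new = len(cls.recurrent), len(cls.lost), len(cls.newcomer)
        n_after = n_rec + n_new

        def mean_count(phenos: frozenset) -> float:
            if not phenos:
                return math.nan
            return float(np.mean([cls.before_counts[p] for p in phenos]))

        def mean_sim(phenos: frozenset) -> float:
            if not phenos:
                return math.nan
            return float(np.mean([phenotype_similarity(reference, p) for p in phenos]))

        rows.append(
            {
                "network": idx,
                "n_recurrent": n_rec,
                "n_lost": n_lost,
                "n_newcomer": n_new,
                "recurrent_fraction": n_rec / n_after if n_after else math.nan,
                "mean_before_count_recurrent": mean_count(cls.recurrent),
                "mean_before_count_lost": mean_count(cls.lost),
                "mean_sim_recurrent": mean_sim(cls.recurrent),
                "mean_sim_lost": mean_sim(cls.lost),
                "mean_sim_newcomer": mean_sim(cls.newcomer),
            }
        )
    df = pd.DataFrame(rows)
    if resistant is not None:
        df["resistant"] = list(resistant)
    return df


def _gain_tables(
    sample: NetworkSample,
    xi: NetworkSample,
    a: Phenotype,
    rng_assay: np.random.Generator,
    rng_access: np.random.Generator,
    before_profiles: list,
) -> tuple[pd.DataFrame, list[AccessClassification], list[bool]]:
    """Post-gain measurements for one paired ensemble (X_D or X_a)."""
    rows, classifications, resistant_flags = [], [], []
    for idx, g in enumerate(sample.networks):
        post_pattern = pattern_from_matrix(g.matrix, g.n_reg, g.n_struct, g.initial_state)
        resistant = post_pattern == a.pattern
        post_mu = assay_mutational(g, a, rng_assay)
        after_profile = access_profile(g, a, rng_access)
        cls = classify_access(before_profiles[idx], after_profile)
        rows.append(
            {
                "network": idx,
                "gain_kind": sample.kind,
                "gain_index": sample.gain_indices[idx] if sample.gain_indices else -1,
                "resistant": resistant,
                "post_R_mu": post_mu.robustness,
                "post_S_mu": post_mu.mean_similarity,
                "n_accessible_after": after_profile.n_accessible,
                "n_recurrent": len(cls.recurrent),
                "n_lost": len(cls.lost),
                "n_newcomer": len(cls.newcomer),
            }
        )
        classifications.append(cls)
        resistant_flags.append(resistant)
    return pd.DataFrame(rows), classifications, resistant_flags


def run_study(cfg: StudyConfig) -> dict[str, pd.DataFrame]:
    """Run the complete study and return its result tables.

    Tables: ``per_network`` (pre-gain R/S for the three perturbation
    classes plus access counts over X_i), ``paired_duplication`` /
    ``paired_addition`` (post-gain measurements, index-aligned with X_i),
    ``access_duplication`` / ``access_addition`` (per-network access
    summaries), ``duplicate_props`` (structural traits of the duplicated
    gene split by resistance), ``stratified`` (deletion/addition mutants
    of duplicate-carrying networks) and ``stats`` (every statistical
    comparison).  When ``cfg.output_dir`` is set each table is flushed as
    TSV as soon as it exists and a JSON manifest with seeds and file
    hashes is written at the end.
    """
    out_dir = Path(cfg.output_dir) if cfg.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}

    def flush(name: str, df: pd.DataFrame) -> None:
        if out_dir:
            path = out_dir / f"{name}.tsv"
            df.to_csv(path, sep="\t", index=False)
            written[name] = hashlib.sha256(path.read_bytes()).hexdigest()

    streams = np.random.SeedSequence(cfg.master_seed).spawn(8)
    (rng_founder, rng_walk, rng_pair, rng_mu, rng_add, rng_access,
     rng_gain, rng_strat) = (np.random.default_rng(s) for s in streams)

    founder, a = make_founder(cfg.model, rng_founder)
    xi = mc_walk_sample(founder, a, cfg.n_networks, cfg.model, rng_walk)
    xd, xa = build_paired_ensembles(xi, rng_pair)

    # --- pre-gain measurements over X_i
    rows, before_profiles = [], []
    for idx, g in enumerate(xi.networks):
        mu = assay_mutational(g, a, rng_mu)
        dup = assay_duplication(g, a)
        add = assay_addition(g, a, rng_add)
        prof = access_profile(g, a, rng_access)
        before_profiles.append(prof)
        rows.append(
            {
                "network": idx,
                "R_mu": mu.robustness,
                "S_mu": mu.mean_similarity,
                "R_D": dup.robustness,
                "S_D": dup.mean_similarity,
                "R_a": add.robustness,
                "S_a": add.mean_similarity,
                "n_accessible_before": prof.n_accessible,
            }
        )
    per_network = pd.DataFrame(rows)
    flush("per_network", per_network)

    # --- post-gain measurements for the paired ensembles
    paired_d, cls_d, res_d = _gain_tables(xd, xi, a, rng_gain, rng_gain, before_profiles)
    paired_a, cls_a, res_a = _gain_tables(xa, xi, a, rng_gain, rng_gain, before_profiles)
    flush("paired_duplication", paired_d)
    flush("paired_addition", paired_a)

    access_d = summarize_access(cls_d, a, res_d)
    access_a = summarize_access(cls_a, a, res_a)
    flush("access_duplication", access_d)
    flush("access_addition", access_a)

    # --- structural traits of the duplicated gene (pre-duplication genotype)
    prop_rows = []
    for idx, (g, i) in enumerate(zip(xi.networks, xd.gain_indices)):
        props = duplicate_structural_props(g, i)
        prop_rows.append(
            {
                "network": idx,
                "dup_index": i,
                "resistant": res_d[idx],
                "path_length": props.path_length,
                "in_degree": props.in_degree,
                "out_degree": props.out_degree,
            }
        )
    duplicate_props = pd.DataFrame(prop_rows)
    flush("duplicate_props", duplicate_props)

    # --- stratified deletion/addition assay on duplicate-carrying networks
    strat_rows = []
    for idx in range(min(cfg.n_stratified, len(xd.networks))):
        for rec in stratified_mutation_assay(xd.networks[idx], a, rng_strat):
            strat_rows.append(
                {
                    "network": idx,
                    "mutation_kind": rec.mutation_kind,
                    "regulator_class": rec.regulator_class,
                    "target_class": rec.target_class,
                    "similarity": rec.similarity,
                }
            )
    stratified = pd.DataFrame(strat_rows)
    flush("stratified", stratified)

    stats_table = _stats_table(
        per_network, paired_d, paired_a, access_d, duplicate_props, stratified
    )
    flush("stats", stats_table)

    if out_dir:
        manifest = {
            "master_seed": cfg.master_seed,
            "n_networks": cfg.n_networks,
            "model": {
                "n_reg": cfg.model.n_reg,
                "n_struct": cfg.model.n_struct,
                "target_connections": cfg.model.target_connections,
            },
            "walk_stats": xi.walk_stats,
            "files": written,
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return {
        "per_network": per_network,
        "paired_duplication": paired_d,
        "paired_addition": paired_a,
        "access_duplication": access_d,
        "access_addition": access_a,
        "duplicate_props": duplicate_props,
        "stratified": stratified,
        "stats": stats_table,
    }


def _stats_table(
    per_network: pd.DataFrame,
    paired_d: pd.DataFrame,
    paired_a: pd.DataFrame,
    access_d: pd.DataFrame,
    duplicate_props: pd.DataFrame,
    stratified: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble every reported statistical comparison into one table."""
    rows: list[dict] = []

    def add(name: str, res: StatResult, p_adj: float | None = None) -> None:
        rows.append(
            {
                "comparison": name,
                "test": res.test_name,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "p_bonferroni": p_adj if p_adj is not None else res.p_value,
                "effect_size": res.effect_size,
                "n": str(res.n),
            }
        )

    for x, y in (("R_mu", "S_mu"), ("R_mu", "R_D"), ("S_mu", "S_D"),
                 ("R_mu", "R_a"), ("R_a", "S_a"), ("R_D", "S_D")):
        add(f"spearman {x}~{y}", spearman(per_network[x], per_network[y]))

    add("R_D vs R_a", mann_whitney(per_network["R_D"], per_network["R_a"]))
    add("S_D vs S_a", mann_whitney(per_network["S_D"], per_network["S_a"]))

    for paired, label in ((paired_d, "duplication"), (paired_a, "addition")):
        for stat in ("R_mu", "S_mu"):
            pre, post = per_network[stat], paired[f"post_{stat}"]
            add(f"{stat} pre vs post {label} (all)", wilcoxon_paired(pre, post))
            for flag, grp in ((True, "resistant"), (False, "susceptible")):
                mask = paired["resistant"] == flag
                if mask.sum() >= 2:
                    add(
                        f"{stat} pre vs post {label} ({grp})",
                        wilcoxon_paired(pre[mask], post[mask]),
                    )

    res_mask = duplicate_props["resistant"]
    if res_mask.nunique() == 2:
        for prop in ("path_length", "in_degree", "out_degree"):
            r = mann_whitney(
                duplicate_props.loc[res_mask, prop],
                duplicate_props.loc[~res_mask, prop],
            )
            add(f"duplicate {prop} resistant vs susceptible", r,
                p_adj=min(1.0, r.p_value * 3))  # Bonferroni over 3 traits

    before_rec = access_d["mean_before_count_recurrent"].dropna()
    before_lost = access_d["mean_before_count_lost"].dropna()
    common = before_rec.index.intersection(before_lost.index)
    if len(common) >= 2:
        add(
            "before-count recurrent vs lost (duplication)",
            wilcoxon_paired(before_rec[common], before_lost[common]),
        )

    if not stratified.empty:
        for kind in ("delete", "add"):
            sub = stratified[stratified["mutation_kind"] == kind]
            if sub.empty:
                continue
            try:
                for term, res in anova2_typeII(sub).items():
                    add(f"anova2 {kind}: {term}", res)
            except ValueError:
                pass  # degenerate design at tiny sample sizes

    return pd.DataFrame(rows)
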