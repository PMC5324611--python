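"""End-to-end pipeline: world -> popgen -> comparative -> morphometrics -> cross.

A run is driven by a :class:`RunConfig` that is either *synthetic* (a
:class:`~tailkit.synthetic.WorldConfig` plus :class:`CrossSpec`, everything
generated and written to disk first) or *real-input* (paths to a VCF, a
samples CSV, a vertebrae CSV and a cross CSV).  Stages execute in a fixed
order with explicit persisted intermediates; each stage's outputs land in
the report dict, which is written as both JSON and a human-readable
Markdown summary.  A stage failure is recorded and dependent stages are
skipped, producing a partial report.

All randomness flows from one root seed, split per stage with
``numpy.random.SeedSequence``.  Reports contain no timestamps, so a rerun
with the same config and seed reproduces the report byte-identically.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .contrasts import contrast_regression, pic_contrasts
from .filters import FilterConfig, apply_variant_filters
from .fst import pairwise_fst_table
from .intercross import (F2Dataset, correlation_power, decoupling_test,
                         dominance_index)
from .kinship import king_kinship
from .lmm import (fst_similarity, kinship_similarity, ols_habitat_test,
                  population_lmm, relatedness_lmm)
from .pca import genotype_pca
from .synthetic import (CrossSpec, WorldConfig, columns_from_frame,
                        simulate_columns, simulate_genotypes,
                        simulate_intercross, simulate_traits, write_fixtures)
from .trees import is_monophyletic, pc_distance_tree
from .variants import VariantTable
from .vertebrae import (compare_groups, decomposition_fit,
                        insertion_counterfactual, profile_compare,
                        summarize_column, summaries_frame, tail_body_stats)

REPORT_SCHEMA_VERSION = 1

#: Seed used for the canonical regression-test fixture set.
CANONICAL_FIXTURE_SEED = 2016


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``world`` (synthetic mode) or the four input paths
    (real-input mode) must be active.  Stage toggles let a run stop at any
    point; thresholds default to the standard filter values.
    """

    out_dir: str = "tailkit_run"
    seed: int = 0
    world: WorldConfig | None = None
    cross_spec: CrossSpec | None = None
    vcf_path: str | None = None
    samples_path: str | None = None
    vertebrae_path: str | None = None
    cross_path: str | None = None
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    run_popgen: bool = True
    run_comparative: bool = True
    run_morphometrics: bool = True
    run_cross: bool = True
    min_pop_size: int = 3      # populations entering the population-level model
    pca_min_call_frac: float = 0.5

    def validate(self) -> None:
        synthetic = self.world is not None
        paths = {"vcf_path": self.vcf_path, "samples_path": self.samples_path,
                 "vertebrae_path": self.vertebrae_path,
                 "cross_path": self.cross_path}
        if synthetic and any(p is not None for p in paths.values()):
            raise ValueError("give either a synthetic world or input paths, not both")
        if not synthetic:
            need = []
            if self.run_popgen or self.run_comparative:
                need += ["vcf_path", "samples_path"]
            if self.run_morphometrics:
                need += ["vertebrae_path", "samples_path"]
            if self.run_cross:
                need += ["cross_path"]
            missing = [k for k in dict.fromkeys(need)
                       if paths[k] is None or not os.path.exists(paths[k])]
            if missing:
                raise ValueError(f"missing input files: {missing}")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return round(float(obj), 10)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (frozenset, set)):
        return sorted(obj)
    return obj


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all enabled stages; returns (and persists) the report dict."""
    cfg.validate()
    os.makedirs(cfg.out_dir, exist_ok=True)
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION,
                    "tailkit_version": __version__,
                    "mode": "synthetic" if cfg.world is not None else "real",
                    "seed": cfg.seed, "stages": {}, "errors": {}}
    ss = np.random.SeedSequence(cfg.seed)
    stage_seed = {name: int(child.generate_state(1)[0] % (2 ** 31))
                  for name, child in zip(
                      ("genotypes", "traits", "columns", "cross"), ss.spawn(4))}

    # ------------------------------------------------------------- inputs
    variants = samples = columns = cross = None
    try:
        if cfg.world is not None:
            in_dir = os.path.join(cfg.out_dir, "inputs")
            variants = simulate_genotypes(cfg.world, seed=stage_seed["genotypes"])
            samples = simulate_traits(cfg.world, variants,
                                      seed=stage_seed["traits"])
            columns = simulate_columns(cfg.world, seed=stage_seed["columns"])
            spec = cfg.cross_spec or CrossSpec()
            cross = simulate_intercross(spec, seed=stage_seed["cross"])
            write_fixtures(in_dir, variants=variants, samples=samples,
                           columns=columns, cross=cross, config=cfg.world,
                           cross_spec=spec)
            # read back from disk so both modes exercise the same readers
            variants = VariantTable.from_vcf(os.path.join(in_dir, "genotypes.vcf"))
            samples = pd.read_csv(os.path.join(in_dir, "samples.csv"))
            columns = columns_from_frame(
                pd.read_csv(os.path.join(in_dir, "vertebrae.csv")))
            cross = F2Dataset.from_csv(os.path.join(in_dir, "cross.csv"))
        else:
            if cfg.vcf_path:
                variants = VariantTable.from_vcf(cfg.vcf_path)
            if cfg.samples_path:
                samples = pd.read_csv(cfg.samples_path)
            if cfg.vertebrae_path:
                columns = columns_from_frame(pd.read_csv(cfg.vertebrae_path))
            if cfg.cross_path:
                cross = F2Dataset.from_csv(cfg.cross_path)
    except Exception as exc:  # input stage failure aborts everything
        report["errors"]["inputs"] = str(exc)
        _write_report(report, cfg.out_dir)
        return report

    kin = pca = tree = filtered = None

    # ------------------------------------------------------------- popgen
    if cfg.run_popgen and variants is not None:
        try:
            filtered, flog = apply_variant_filters(variants, cfg.filter_config)
            filtered.to_vcf(os.path.join(cfg.out_dir, "filtered.vcf"))
            pops = samples.set_index("individual_id").loc[
                filtered.ids, "population"].to_numpy()
            fst_results = pairwise_fst_table(filtered, pops)
            kin = king_kinship(filtered)
            kin.to_csv(os.path.join(cfg.out_dir, "kinship.csv"))
            pca = genotype_pca(filtered, cfg.pca_min_call_frac)
            tree = pc_distance_tree(pca, fallback_k=2)
            tree.write(os.path.join(cfg.out_dir, "pc_tree.nwk"))
            forest_tips = samples.loc[samples["habitat"] == "forest",
                                      "individual_id"].tolist()
            mono, _ = is_monophyletic(tree, forest_tips)
            pd.DataFrame([{"pop_a": r.pair[0], "pop_b": r.pair[1],
                           "weighted_fst": r.weighted_global,
                           "mean_fst": r.mean_global,
                           "n_sites": r.n_sites_used}
                          for r in fst_results]).to_csv(
                os.path.join(cfg.out_dir, "fst_pairs.csv"), index=False,
                float_format="%.6f")
            report["stages"]["popgen"] = {
                "filter_log": flog,
                "fst": {f"{r.pair[0]}|{r.pair[1]}":
                        {"weighted": r.weighted_global, "mean": r.mean_global}
                        for r in fst_results},
                "kinship_mean_offdiag": float(np.nanmean(
                    kin.phi[~np.eye(len(kin.ids), dtype=bool)])),
                "pca": {"k_significant": pca.k_significant,
                        "tw_pvalues": pca.tw_pvalues[:5],
                        "eigenvalues": pca.eigenvalues[:5]},
                "forest_monophyletic": bool(mono),
                "n_forest_tips": len(forest_tips),
            }
        except Exception as exc:
            report["errors"]["popgen"] = str(exc)

    # -------------------------------------------------------- comparative
    if cfg.run_comparative and variants is not None:
        try:
            if kin is None or tree is None:
                raise RuntimeError("comparative stage needs popgen outputs")
            s = samples.set_index("individual_id").loc[list(kin.ids)]
            assoc = s[s["habitat"].isin(["forest", "nonforest"])]
            ratio = (assoc["tail_mm"] / assoc["body_mm"]).to_numpy()
            habitat = (assoc["habitat"] == "forest").to_numpy(float)

            keep_idx = [i for i, x in enumerate(kin.ids) if x in set(assoc.index)]
            kin_sub = kinship_similarity(king_kinship(
                filtered.take_individuals(keep_idx)))
            ind_fit = relatedness_lmm(ratio, habitat, kin_sub)
            _, ols_t, ols_df, ols_p = ols_habitat_test(ratio, habitat)

            tip_ratio = dict(zip(assoc.index, ratio))
            tip_hab = dict(zip(assoc.index, habitat))
            sub_tree = tree
            drop = set(tree.tips) - set(assoc.index)
            if drop:
                sub_tree = type(tree)(root=tree.root.copy().shear(
                    set(assoc.index)))
            contrasts = pic_contrasts(sub_tree, tip_hab, tip_ratio)
            contrasts.to_frame().to_csv(
                os.path.join(cfg.out_dir, "contrasts.csv"), index=False,
                float_format="%.6f")
            pic_fit = contrast_regression(contrasts)

            pop_sizes = assoc.groupby("population").size()
            big = pop_sizes[pop_sizes >= cfg.min_pop_size].index.tolist()
            pop_block = assoc[assoc["population"].isin(big)]
            pop_means = pop_block.groupby("population").apply(
                lambda g: float((g["tail_mm"] / g["body_mm"]).mean()),
                include_groups=False)
            pop_hab = pop_block.groupby("population")["habitat"].first() == "forest"
            pop_report = None
            if len(big) >= 4:
                sub = filtered.take_individuals(
                    [i for i, x in enumerate(filtered.ids)
                     if x in set(pop_block.index)])
                sub_pops = pop_block.loc[list(sub.ids), "population"].to_numpy()
                fst_sim = fst_similarity(pairwise_fst_table(sub, sub_pops))
                order = fst_sim.labels
                pop_fit = population_lmm(pop_means.loc[order].to_numpy(),
                                         pop_hab.loc[order].to_numpy(float),
                                         fst_sim)
                pop_report = {"beta_habitat": float(pop_fit.beta[1]),
                              "p": pop_fit.p_value, "n_populations": len(order)}
            report["stages"]["comparative"] = {
                "lmm_individual": {"beta_habitat": float(ind_fit.beta[1]),
                                   "se": float(ind_fit.se[1]),
                                   "t": ind_fit.wald_t, "df": ind_fit.df,
                                   "p": ind_fit.p_value,
                                   "sigma_g2": ind_fit.sigma_g2,
                                   "sigma_e2": ind_fit.sigma_e2},
                "ols_naive": {"t": ols_t, "df": ols_df, "p": ols_p},
                "pic": {"slope": pic_fit.slope, "r2_adj": pic_fit.r2_adjusted,
                        "p": pic_fit.p_value,
                        "n_contrasts": pic_fit.n_contrasts},
                "lmm_population": pop_report,
            }
        except Exception as exc:
            report["errors"]["comparative"] = str(exc)

    # ----------------------------------------------------- morphometrics
    if cfg.run_morphometrics and columns is not None:
        try:
            summaries = [summarize_column(c) for c in columns]
            summaries_frame(summaries).to_csv(
                os.path.join(cfg.out_dir, "vertebral_summaries.csv"),
                index=False, float_format="%.6f")
            comparison = compare_groups(summaries, "habitat", "population")
            forest_cols = [c for c in columns if c.habitat == "forest"]
            prairie_cols = [c for c in columns if c.habitat == "nonforest"]
            profile = profile_compare(forest_cols, prairie_cols)
            counterfactual = insertion_counterfactual(prairie_cols, forest_cols)
            decomp = decomposition_fit(summaries)
            morpho = {
                "comparison": comparison,
                "elongated_segment": profile.elongated_segment,
                "reference_mm": profile.reference,
                "counterfactual": {"k": counterfactual.k,
                                   "compensation": counterfactual.compensation,
                                   "numerator": counterfactual.numerator,
                                   "denominator": counterfactual.denominator},
                "decomposition": {"r2": decomp.r2,
                                  "coef_longest": decomp.coef_longest,
                                  "coef_count": decomp.coef_count},
            }
            if samples is not None:
                tb = tail_body_stats(samples)
                tb.pop("ratios")
                morpho["tail_body"] = tb
            report["stages"]["morphometrics"] = morpho
        except Exception as exc:
            report["errors"]["morphometrics"] = str(exc)

    # -------------------------------------------------------------- cross
    if cfg.run_cross and cross is not None:
        try:
            dec = decoupling_test(cross)
            n_f2 = dec.n
            report["stages"]["cross"] = {
                "dominance_count": dominance_index(cross, "caudal_count").__dict__,
                "dominance_length": dominance_index(cross, "longest_caudal_mm").__dict__,
                "decoupling": {"r": dec.r, "t": dec.t, "df": dec.df,
                               "p": dec.p_value, "n_F2": n_f2},
                "power_r025_onesided": correlation_power(
                    n_f2, 0.25, 0.05, method="analytic", sides=1),
            }
        except Exception as exc:
            report["errors"]["cross"] = str(exc)

    _write_report(report, cfg.out_dir)
    return report


def _write_report(report: dict, out_dir: str) -> None:
    clean = _jsonable(report)
    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        json.dump(clean, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(os.path.join(out_dir, "report.md"), "w") as fh:
        fh.write(_markdown_report(clean))


def _markdown_report(report: dict) -> str:
    lines = [f"# tailkit run report (schema v{report['schema_version']})", ""]
    lines.append(f"- mode: {report['mode']}, seed: {report['seed']}")
    st = report.get("stages", {})
    if "popgen" in st:
        p = st["popgen"]
        lines += ["", "## Population genetics",
                  f"- sites in/out: {p['filter_log']['sites_in']} / "
                  f"{p['filter_log']['sites_out']}",
                  f"- significant PCs (Tracy-Widom p < 0.05): "
                  f"{p['pca']['k_significant']}",
                  f"- forest tips monophyletic: {p['forest_monophyletic']}"]
        for pair, v in p.get("fst", {}).items():
            lines.append(f"- F_ST {pair}: weighted {v['weighted']:.4f}")
    if "comparative" in st:
        c = st["comparative"]
        lines += ["", "## Habitat association",
                  f"- kinship LMM habitat effect: "
                  f"{c['lmm_individual']['beta_habitat']:.4f} "
                  f"(p = {c['lmm_individual']['p']:.3g})",
                  f"- PIC regression slope: {c['pic']['slope']:.4f} "
                  f"(adj R2 = {c['pic']['r2_adj']:.3f}, "
                  f"p = {c['pic']['p']:.3g})"]
        if c.get("lmm_population"):
            lines.append(f"- population LMM habitat effect: "
                         f"{c['lmm_population']['beta_habitat']:.4f} "
                         f"(p = {c['lmm_population']['p']:.3g})")
    if "morphometrics" in st:
        m = st["morphometrics"]
        seg = m["elongated_segment"]
        comp = m["counterfactual"]["compensation"]
        lines += ["", "## Vertebral morphometrics",
                  f"- elongated caudal segment: {seg}",
                  f"- prairie+{m['counterfactual']['k']} compensation: "
                  + (f"{comp:.3f}" if comp is not None else "undefined"),
                  f"- total ~ longest + count R2: "
                  f"{m['decomposition']['r2']:.3f}"]
    if "cross" in st:
        x = st["cross"]
        lines += ["", "## F2 intercross",
                  f"- count locus d/a: {x['dominance_count']['d_over_a']:.3f} "
                  f"({x['dominance_count']['classification']})",
                  f"- length locus d/a: {x['dominance_length']['d_over_a']:.3f} "
                  f"({x['dominance_length']['classification']})",
                  f"- F2 decoupling: r = {x['decoupling']['r']:.3f}, "
                  f"t = {x['decoupling']['t']:.2f}, "
                  f"df = {x['decoupling']['df']}, "
                  f"p = {x['decoupling']['p']:.3f}",
                  f"- power to detect r > 0.25 (one-sided): "
                  f"{x['power_r025_onesided']:.3f}"]
    if report.get("errors"):
        lines += ["", "## Errors"]
        for k, v in report["errors"].items():
            lines.append(f"- {k}: {v}")
    return "\n".join(lines) + "\n"


def make_fixtures(out_dir: str, seed: int = CANONICAL_FIXTURE_SEED) -> dict:
    """Write the canonical small fixture set used by the regression tests.

    40 individuals x 2000 sites across 4 demes (2 clades x forest/nonforest),
    vertebral columns for 60 individuals (15 per deme), and a cross of 12
    animals per parental line, 10 F1s and 96 F2s.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(4)]
    world = WorldConfig.default(n_per_deme=10, n_sites=2000, seed=seed)
    variants = simulate_genotypes(world, seed=seeds[0])
    samples = simulate_traits(world, variants, seed=seeds[1])
    columns_world = WorldConfig.default(n_per_deme=15, n_sites=2000, seed=seed)
    columns = simulate_columns(columns_world, seed=seeds[2])
    spec = CrossSpec(seed=seed)
    cross = simulate_intercross(spec, seed=seeds[3])
    return write_fixtures(out_dir, variants=variants, samples=samples,
                          columns=columns, cross=cross, config=world,
                          cross_spec=spec)
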