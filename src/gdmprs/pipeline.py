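"""End-to-end pipeline: QC -> association -> LD pruning -> GMDR -> PRS ->
interaction, with an optional dietary-pattern stage.

The pipeline is driven by a single declarative config (YAML file or dict).
Inputs are either file paths (PLINK/VCF genotypes, CSV/TSV phenotypes and
food-frequency intakes) or a ``simulate`` block that generates a synthetic
cohort; every stage threshold is a config key whose default is the study
convention (association p < 1e-4, LD r2 <= 0.3, QC missing < 4% / het < 30%
/ HWE p > 0.05, PRS categories <=3 / 4-5 / >=6, dietary eigenvalue > 1.5).

Stage outputs are returned as a result bundle (dict of tables) and written
as TSV/JSON when ``out_dir`` is set; a counts log records how many variants
enter and leave each reduction stage.  Because the PRS x dietary-pattern
interactions require the dietary stage, they are reported with the diet
outputs; the interaction stage proper covers the GDM-status and
breastfeeding stratifiers, so skipping the diet stage leaves every other
stage's output unchanged.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import diet as diet_mod
from . import gmdr as gmdr_mod
from . import gxe, prs as prs_mod, qc as qc_mod, simulate as sim
from .cohort import GenotypeMatrix, PhenotypeTable
from .io import read_genotypes, read_phenotypes

__all__ = ["run_pipeline", "load_config", "DEFAULT_CONFIG"]

log = logging.getLogger("gdmprs")
if not log.handlers:  # structured-ish logging to stderr
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s :: %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": ["qc", "assoc", "prune", "gmdr", "prs", "interact", "diet"],
    "simulate": {"n_subjects": 10_000},
    # The 30% heterozygosity criterion is a chip-level per-sample rule; at the
    # variant level it would reject every common SNP (2pq -> 0.5), so the
    # pipeline default keeps the variant-level check only as a heterozygote-
    # excess guard above the Hardy-Weinberg maximum of 0.5.
    "qc": {"max_missing_rate": 0.04, "max_het_rate": 0.55, "min_hwe_p": 0.05},
    "assoc": {
        "p_threshold": 1e-4,
        "covariates": ["age_first_pregnancy", "bmi_at_20", "residence_area",
                       "childbirth", "education"],
    },
    "prune": {"r2_threshold": 0.3, "top_n": 10},
    "gmdr": {"k_max": 5, "n_folds": 10, "sign_alpha": 0.05},
    "prs": {"cutoffs": [3, 6], "missing_policy": "exclude"},
    "interact": {"covariates": ["age", "education", "income", "energy_intake",
                                "residence_area", "alcohol", "smoking"]},
    "diet": {"eigen_threshold": 1.5, "loading_threshold": 0.40, "percentile": 70.0},
}


def load_config(path_or_dict) -> dict:
    """Merge a user config (YAML path or dict) over the defaults."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict or {})
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, val in user.items():
        if isinstance(val, Mapping) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


class EmptyCandidateSet(RuntimeError):
    """A reduction stage removed every remaining variant."""


def _load_inputs(cfg: dict) -> tuple[GenotypeMatrix, PhenotypeTable, pd.DataFrame | None, dict]:
    truth: dict = {}
    if "inputs" in cfg:
        inp = cfg["inputs"]
        genotypes = read_genotypes(inp["genotypes"], inp.get("format"))
        phenotypes = read_phenotypes(inp["phenotypes"], inp.get("phenotype_schema"))
        ffq = None
        if inp.get("ffq"):
            ffq = pd.read_csv(inp["ffq"], index_col=0)
        return genotypes, phenotypes, ffq, truth
    simcfg = dict(cfg.get("simulate", {}))
    bundle = sim.simulate_cohort(
        n_subjects=int(simcfg.get("n_subjects", 10_000)),
        seed=int(cfg.get("seed", 0)),
    )
    truth = {"true_model_snps": bundle["true_model_snps"],
             "true_epistasis_pairs": bundle["true_epistasis_pairs"]}
    return bundle["genotypes"], bundle["phenotypes"], bundle["ffq"], truth


def run_pipeline(config, out_dir: str | Path | None = None) -> dict:
    """Execute the configured stages in order and return the result bundle.

    Bundle keys (depending on stages run): ``qc_report``, ``assoc_table``,
    ``candidates``, ``pruned``, ``gmdr_table``, ``best_model``,
    ``prs_table``, ``prs_association``, ``interaction_table``,
    ``diet_loadings``, ``diet_interactions`` and ``counts`` (the stage log).
    """
    cfg = load_config(config)
    out_dir = Path(out_dir) if out_dir else (Path(cfg["out_dir"]) if cfg.get("out_dir") else None)
    stages = list(cfg["stages"])
    genotypes, phenotypes, ffq, truth = _load_inputs(cfg)
    pheno = phenotypes.data
    bundle: dict = dict(truth)
    counts: list[dict] = [{"stage": "input", "n_variants": genotypes.n_variants,
                           "n_subjects": genotypes.n_subjects}]

    if "qc" in stages:
        thr = qc_mod.QcThresholds(
            max_missing_rate=cfg["qc"]["max_missing_rate"],
            max_het_rate=cfg["qc"]["max_het_rate"],
            min_hwe_p=cfg["qc"]["min_hwe_p"],
        )
        genotypes, report = qc_mod.apply_qc_filters(genotypes, thr)
        bundle["qc_report"] = report.table
        counts.append({"stage": "qc", "n_variants": genotypes.n_variants})
        log.info("QC kept %d variants", genotypes.n_variants)

    assoc_results = None
    if "assoc" in stages:
        covs = [c for c in cfg["assoc"]["covariates"] if c in pheno.columns]
        assoc_results = qc_mod.association_scan(
            genotypes, pheno["gdm_status"].to_numpy(), pheno[covs]
        )
        bundle["assoc_table"] = _assoc_frame(assoc_results, genotypes)
        candidates = qc_mod.select_candidates(assoc_results, cfg["assoc"]["p_threshold"])
        if not candidates:
            raise EmptyCandidateSet(
                f"no variants below p < {cfg['assoc']['p_threshold']}"
            )
        bundle["candidates"] = [r.variant_id for r in candidates]
        counts.append({"stage": "assoc", "n_variants": len(candidates)})
        log.info("association selected %d candidates", len(candidates))
    else:
        candidates = None

    if "prune" in stages:
        if candidates is None:
            raise ValueError("prune stage requires the assoc stage")
        pruned = qc_mod.ld_prune(candidates, genotypes, cfg["prune"]["r2_threshold"])
        pruned = pruned[: int(cfg["prune"]["top_n"])]
        if not pruned:
            raise EmptyCandidateSet("LD pruning removed every candidate")
        bundle["pruned"] = [r.variant_id for r in pruned]
        counts.append({"stage": "prune", "n_variants": len(pruned)})
        log.info("LD pruning kept %d candidates", len(pruned))
    else:
        pruned = candidates

    best = None
    if "gmdr" in stages:
        if not pruned:
            raise ValueError("gmdr stage requires candidates")
        covs = [c for c in cfg["assoc"]["covariates"] if c in pheno.columns]
        scores = gmdr_mod.compute_score_residuals(
            pheno["gdm_status"].to_numpy(), pheno[covs]
        )
        ids = [r.variant_id for r in pruned]
        k_max = min(int(cfg["gmdr"]["k_max"]), len(ids))
        results = gmdr_mod.run_gmdr_search(
            ids, scores, genotypes, k_range=range(1, k_max + 1),
            n_folds=int(cfg["gmdr"]["n_folds"]), seed=int(cfg.get("seed", 0)),
        )
        bundle["gmdr_results"] = results
        bundle["gmdr_table"] = gmdr_mod.results_table(results)
        significant = [r for r in results if r.sign_p <= cfg["gmdr"]["sign_alpha"]]
        pool = significant or results
        best = max(pool, key=lambda r: (r.cvc, r.teba))
        bundle["best_model"] = best
        log.info("best GMDR model: %s (CVC %d/%d, sign p %.4g)",
                 "+".join(best.snp_ids), best.cvc, best.n_folds, best.sign_p)

    profile = None
    if "prs" in stages:
        if best is None or assoc_results is None:
            raise ValueError("prs stage requires the assoc and gmdr stages")
        model = prs_mod.risk_alleles_from_association(
            genotypes, assoc_results, list(best.snp_ids)
        )
        profile = prs_mod.compute_prs(genotypes, model,
                                      cfg["prs"]["missing_policy"])
        # fixed <=3 / 4-5 / >=6 cutoffs are meaningful for the 5-SNP scale;
        # other model sizes fall back to tertiles unless cutoffs are forced
        if len(model.snp_ids) == 5 or cfg["prs"].get("force_cutoffs"):
            cats = prs_mod.categorize_prs_series(
                profile.prs, tuple(cfg["prs"]["cutoffs"]))
        else:
            cats = prs_mod.categorize_prs_series(profile.prs, mode="tertile")
        profile.table["category"] = cats
        bundle["prs_model"] = model
        bundle["prs_table"] = profile.table
        covs = [c for c in prs_mod.COVARIATE_PRESETS["model2"] if c in pheno.columns]
        bundle["prs_association"] = prs_mod.prs_association(
            cats, pheno["gdm_status"].to_numpy(), pheno[covs]
        )

    if "interact" in stages:
        if profile is None:
            raise ValueError("interact stage requires the prs stage")
        covs = [c for c in cfg["interact"]["covariates"] if c in pheno.columns]
        stratifiers = {}
        if "gdm_status" in pheno.columns:
            stratifiers["gdm_status"] = pheno["gdm_status"].to_numpy()
        if "breastfeeding_years" in pheno.columns:
            stratifiers["breastfeeding_1y"] = (
                pheno["breastfeeding_years"].to_numpy() >= 1.0
            ).astype(int)
        reports = gxe.interaction_report(
            profile.table["category"], pheno["t2dm_status"].to_numpy(),
            stratifiers, pheno[covs],
        )
        bundle["interaction_results"] = reports
        bundle["interaction_table"] = pd.concat(
            [r.to_frame() for r in reports], ignore_index=True
        )

    if "diet" in stages:
        if ffq is None:
            raise ValueError("diet stage requires a food-frequency table")
        pat = diet_mod.extract_patterns(
            ffq, cfg["diet"]["eigen_threshold"], cfg["diet"]["loading_threshold"],
            cfg["diet"]["percentile"],
        )
        bundle["diet_patterns"] = pat
        bundle["diet_loadings"] = pat.loadings
        if profile is not None and pat.n_patterns:
            covs = [c for c in cfg["interact"]["covariates"] if c in pheno.columns]
            diet_strats = {
                name: pat.high_flags[name].to_numpy().astype(int)
                for name in pat.high_flags.columns
            }
            reports = gxe.interaction_report(
                profile.table["category"], pheno["t2dm_status"].to_numpy(),
                diet_strats, pheno[covs],
            )
            bundle["diet_interaction_results"] = reports
            bundle["diet_interactions"] = pd.concat(
                [r.to_frame() for r in reports], ignore_index=True
            )

    bundle["counts"] = pd.DataFrame(counts)
    if out_dir is not None:
        _write_bundle(bundle, out_dir)
    return bundle


def _assoc_frame(results, genotypes: GenotypeMatrix) -> pd.DataFrame:
    rows = []
    for r in results:
        v = genotypes.variant(r.variant_id)
        rows.append(dict(
            Chr=v.chrom, SNP=v.id, Position=v.pos, Mi=v.minor_allele,
            Ma=v.major_allele, OR=round(r.or_value, 4),
            CI=f"{r.ci_low:.3f}-{r.ci_high:.3f}",
            p=r.p_adjusted_model, MAF=round(v.maf, 4),
        ))
    return pd.DataFrame(rows)


def _write_bundle(bundle: dict, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for key in ("qc_report", "assoc_table", "gmdr_table", "prs_table",
                "interaction_table", "diet_loadings", "diet_interactions",
                "counts"):
        if key in bundle:
            bundle[key].to_csv(out_dir / f"{key}.tsv", sep="\t",
                               float_format="%.10g")
    simple = {}
    for key in ("candidates", "pruned", "true_model_snps", "true_epistasis_pairs"):
        if key in bundle:
            simple[key] = bundle[key]
    if "best_model" in bundle:
        b = bundle["best_model"]
        simple["best_model"] = {
            "snp_ids": list(b.snp_ids), "trba": b.trba, "teba": b.teba,
            "sign_stat": b.sign_stat, "sign_p": b.sign_p,
            "cvc": b.cvc, "n_folds": b.n_folds,
            "cell_labels": {"|".join(map(str, k)): v
                            for k, v in b.cell_labels.items()},
        }
    if simple:
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(simple, fh, indent=2, sort_keys=True)
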