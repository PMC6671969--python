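"""End-to-end orchestration: simulate -> (impute) -> call -> similarity ->
networks -> enrichment, with every stage output written to disk and a JSON
run report tying them together."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import calling, enrichment, impute, networks, phenosim
from .catalogue import catalogue_frame, make_catalogue
from .cohort import (
    CohortSpec,
    simulate_cohort,
    simulate_gene_annotations,
    simulate_gene_sets,
    simulate_network,
)
from .io import (
    RunConfig,
    child_seed,
    write_catalogue,
    write_gmt,
    write_ground_truth,
    write_network,
    write_phenotype_table,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Run the full synthetic-screen pipeline under one config and seed.

    Returns the run report (also written to ``report.json`` in the output
    directory); any stage failure aborts with the stage name and cause.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "outputs": {},
    }

    def _save(name: str, path: Path) -> None:
        report["outputs"][name] = str(path)

    stage = "simulate"
    try:
        params = make_catalogue(
            {
                "B+0.98": config.n_params_coronal,
                "B-1.34": config.n_params_coronal,
                "L0.60": config.n_params_sagittal,
            },
            wt_cv=config.wt_cv,
            seed=child_seed(config.seed, "catalogue"),
        )
        cat = catalogue_frame(params)
        spec = CohortSpec(
            n_lines=config.n_lines,
            replicates_per_line=config.replicates_per_line,
            n_wt=config.n_wt,
            n_batches=config.n_batches,
            batch_sd_frac=config.batch_sd_frac,
            fraction_nap=config.fraction_nap,
            missing_rate=config.missing_rate,
            seed=child_seed(config.seed, "cohort"),
        )
        table, truth = simulate_cohort(spec, params)
        net = simulate_network(
            n_genes=config.n_lines,
            n_modules=config.n_modules,
            p_in=config.p_in,
            p_out=config.p_out,
            seed=child_seed(config.seed, "network"),
            genes=sorted(table.loc[table["line_id"] != "WT", "gene"].unique()),
        )
        truth.planted_modules = {
            g: net.nodes[g]["module"] for g in net.nodes
        }
        genes = sorted(net.nodes)
        annotations = simulate_gene_annotations(
            genes, truth, assoc_strength=1.0,
            seed=child_seed(config.seed, "annotations"),
        )
        gene_sets = simulate_gene_sets(
            genes,
            [("truth_overlap", max(2, len(genes) // 10), 0.5),
             ("random_set", max(2, len(genes) // 10), 0.0)],
            truth,
            seed=child_seed(config.seed, "gene_sets"),
        )
        write_phenotype_table(table, out / "phenotypes.tsv")
        write_catalogue(cat, out / "catalogue.tsv")
        write_ground_truth(truth, out / "ground_truth.json")
        write_network(net, out / "network_edges.tsv", out / "network_nodes.tsv")
        annotations.to_csv(out / "annotations.tsv", sep="\t", index=False)
        write_gmt(gene_sets, out / "gene_sets.gmt")
        for name in ("phenotypes.tsv", "catalogue.tsv", "ground_truth.json",
                     "network_edges.tsv", "network_nodes.tsv",
                     "annotations.tsv", "gene_sets.gmt"):
            _save(name.split(".")[0], out / name)
    except Exception as e:  # noqa: BLE001 - report stage and re-raise
        raise StageError(stage, e) from e

    if config.impute:
        stage = "impute"
        try:
            model = impute.fit_mvn_em(table)
            table, mask = impute.impute_missing(table, model)
            write_phenotype_table(table, out / "phenotypes_imputed.tsv")
            mask.to_csv(out / "imputation_mask.tsv", sep="\t", index=False)
            _save("phenotypes_imputed", out / "phenotypes_imputed.tsv")
            _save("imputation_mask", out / "imputation_mask.tsv")
            report["imputation"] = {
                "n_imputed": int(mask.to_numpy().sum()),
                "em_iterations": model.n_iter,
            }
        except Exception as e:
            raise StageError(stage, e) from e

    stage = "call"
    try:
        results = calling.adjust_bh(
            calling.run_association(table), family=config.bh_family
        )
        calls = calling.call_naps(results, cat, threshold=config.bh_threshold)
        results.to_csv(out / "associations.tsv", sep="\t", index=False,
                       na_rep="NA", float_format="%.6g")
        calls.to_csv(out / "nap_calls.tsv", sep="\t", index=False, na_rep="NA")
        _save("associations", out / "associations.tsv")
        _save("nap_calls", out / "nap_calls.tsv")
        fdr = calling.permutation_fdr(
            table, n_perm=config.fdr_permutations, alpha=config.bh_threshold,
            seed=child_seed(config.seed, "fdr"), family=config.bh_family,
        )
        nap_genes = set(calls.loc[calls["is_nap"], "gene"])
        planted = truth.nap_genes
        called_lines = set(calls.loc[calls["is_nap"], "line_id"])
        report["calling"] = {
            "n_lines_tested": int(calls["line_id"].nunique()),
            "n_nap": int(calls["is_nap"].sum()),
            "severity_counts": calls.loc[calls["is_nap"], "severity"]
            .value_counts().to_dict(),
            "direction_counts": calls.loc[calls["is_nap"], "direction"]
            .value_counts().to_dict(),
            "category_counts": calls.loc[calls["is_nap"], "categories_affected"]
            .str.split(";").explode().value_counts().to_dict(),
            "fdr_observed": fdr.observed,
            "fdr_null_mean": fdr.null_mean,
            "fdr_null_sd": fdr.null_sd,
            "sensitivity": (
                len(called_lines & truth.nap_lines) / len(truth.nap_lines)
                if truth.nap_lines else None
            ),
        }
    except Exception as e:
        raise StageError(stage, e) from e

    stage = "similarity"
    try:
        sim = phenosim.goodall3_coronal(results, cat, cutoff=config.binarize_cutoff)
        sim.to_frame().to_csv(out / "similarity.tsv", sep="\t",
                              float_format="%.6g")
        _save("similarity", out / "similarity.tsv")
        module0 = {g for g, m in truth.planted_modules.items() if m == 0}
        module0 &= set(sim.genes)
        if len(module0) >= 2:
            conv = phenosim.convergence_test(
                sim, module0, n_perm=config.convergence_permutations,
                seed=child_seed(config.seed, "convergence"),
                smoothed=config.smoothed_p,
            )
            report["similarity"] = {
                "module0_convergence_p": conv.p_empirical,
                "module0_observed": conv.observed,
            }
    except Exception as e:
        raise StageError(stage, e) from e

    stage = "networks"
    try:
        itest = networks.interconnectedness_test(
            net, nap_genes & set(net.nodes), n_perm=config.network_permutations,
            seed=child_seed(config.seed, "interconnectedness"),
            smoothed=config.smoothed_p,
        ) if len(nap_genes & set(net.nodes)) >= 2 else None
        assignment, q = networks.louvain_partition(
            net, resolution=1.0, seed=child_seed(config.seed, "louvain") % 10000
        )
        pd.DataFrame(
            {"gene": list(assignment), "module": list(assignment.values())}
        ).to_csv(out / "modules.tsv", sep="\t", index=False)
        _save("modules", out / "modules.tsv")
        report["networks"] = {
            "n_modules": len(set(assignment.values())),
            "modularity": q,
        }
        if itest is not None:
            report["networks"]["nap_interconnectedness_p"] = itest.p_empirical
            report["networks"]["nap_interconnectedness"] = itest.observed
    except Exception as e:
        raise StageError(stage, e) from e

    stage = "enrichment"
    try:
        universe = set(annotations["gene_id"])
        enr = enrichment.enrich_gene_sets(nap_genes & universe, gene_sets, universe)
        enr.to_csv(out / "enrichment.tsv", sep="\t", index=False,
                   float_format="%.6g")
        _save("enrichment", out / "enrichment.tsv")
        report["enrichment"] = {
            r["set_name"]: {"odds_ratio": r["odds_ratio"], "p_right": r["p_right"],
                            "p_bh": r["p_bh"]}
            for _, r in enr.iterrows()
        }
        if calls["max_abs_z"].notna().sum() >= 20:
            top, bottom = enrichment.select_extreme_deciles(calls)
            ann = annotations.set_index("gene_id")
            u, p = enrichment.mwu_property_test(
                ann.loc[sorted(top & set(ann.index)), "pli"].to_numpy(),
                ann.loc[sorted(bottom & set(ann.index)), "pli"].to_numpy(),
                tail="right",
            )
            report["enrichment"]["top_vs_bottom_pli_mwu_p"] = p
    except Exception as e:
        raise StageError(stage, e) from e

    (out / "report.json").write_text(json.dumps(report, indent=1, default=str))
    return report
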