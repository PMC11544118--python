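"""End-to-end orchestration of the screening stages.

``run_pipeline`` chains normalisation, the DE screen, the ligand
correlation screen and set intersection, interaction-source
intersection, triplet assembly, hub ranking, the survival screen,
enrichment and the association stages, writing every stage's output
(with provenance headers) into the output directory.  Stage failures
abort with the stage name attached; outputs of completed stages are
retained.  Stages listed in ``config.skip_stages`` are skipped.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path
from types import SimpleNamespace

import pandas as pd

from . import assoc as assoc_mod
from . import cerna, diffexpr, enrichment, io
from . import survival as surv
from .config import PipelineConfig
from .matrix import normalize_gene_id
from .rankstats import spearman

log = logging.getLogger("spongescreen")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _triplet_table(triplets) -> pd.DataFrame:
    rows = [{
        "lnc_id": t.lnc_id, "mi_id": t.mi_id, "mrna_id": t.mrna_id,
        "rho_lnc_mrna": t.rho_lnc_mrna, "p_lnc_mrna": t.p_lnc_mrna,
        "rho_lnc_mi": t.rho_lnc_mi, "p_lnc_mi": t.p_lnc_mi,
        "rho_mi_mrna": t.rho_mi_mrna, "p_mi_mrna": t.p_mi_mrna,
        "sources": "|".join(t.sources),
    } for t in triplets]
    return pd.DataFrame(rows, columns=[
        "lnc_id", "mi_id", "mrna_id", "rho_lnc_mrna", "p_lnc_mrna",
        "rho_lnc_mi", "p_lnc_mi", "rho_mi_mrna", "p_mi_mrna", "sources"])


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the in-memory result bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config.config_hash(), "seed": config.seed}
    config.to_yaml(outdir / "resolved_config.yaml")
    results: dict = {"outdir": str(outdir)}
    skipped = set(config.skip_stages)

    def stage(name):
        def wrapper(fn):
            if name in skipped:
                log.info("stage %s skipped by config", name)
                return None
            t0 = time.perf_counter()
            try:
                out = fn()
            except Exception as err:  # noqa: BLE001 - re-raised with stage name
                raise PipelineError(name, err) from err
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapper

    # -- load + normalise ------------------------------------------------
    @stage("normalize")
    def _normalize():
        counts = io.read_expression_tsv(config.expression, scale="counts")
        logcpm = diffexpr.cpm_log_normalize(counts)
        results["counts"] = counts
        results["logcpm"] = logcpm
        return logcpm
    if "counts" not in results:
        raise PipelineError("normalize", ValueError("normalize stage may not be skipped"))
    logcpm = results["logcpm"]

    # -- differential expression -----------------------------------------
    @stage("de")
    def _de():
        records = diffexpr.differential_expression(logcpm, gene_class="lncRNA")
        up, down = diffexpr.filter_de(records, config.lfc_threshold,
                                      config.p_threshold)
        table = diffexpr.de_table(records)
        io.write_table_tsv(table, outdir / "de_lncrna.tsv", meta)
        results["de_records"] = records
        results["de_up"], results["de_down"] = up, down
        results["de_lncs"] = sorted(up | down)

    # -- ligand correlation screen + intersection ------------------------
    @stage("ligand_screen")
    def _ligand_screen():
        ligands = [normalize_gene_id(g) for g in config.ligands]
        de_lncs = results.get("de_lncs", [])
        per_ligand = {}
        for ligand in ligands:
            hits = cerna.ligand_correlated_lncs(
                logcpm, de_lncs, ligand, rho_min=config.rho_min,
                p_max=config.p_max, tumor_only=config.tumor_only)
            per_ligand[ligand] = hits
            frame = pd.DataFrame(
                [(lnc, r.rho, r.p, r.n) for lnc, r in sorted(hits.items())],
                columns=["lnc_id", "rho", "p", "n"]).set_index("lnc_id")
            io.write_table_tsv(frame, outdir / f"ligand_screen_{ligand}.tsv", meta)
        candidates = cerna.intersect_gene_sets(*[set(per_ligand[l]) for l in ligands]) \
            if len(ligands) == 2 else sorted(per_ligand[ligands[0]])
        results["ligand_hits"] = per_ligand
        results["candidates"] = candidates
        io.write_table_tsv(pd.DataFrame({"lnc_id": candidates}),
                           outdir / "intersected_candidates.tsv", meta,
                           index=False)

    # -- interaction-source intersection ---------------------------------
    @stage("interactions")
    def _interactions():
        lnc_mi_tables = []
        for path in config.lnc_mi:
            lnc_mi_tables.extend(io.read_interaction_tsv(path, "lnc_mi"))
        mi_mrna_tables = []
        for path in config.mi_mrna:
            mi_mrna_tables.extend(io.read_interaction_tsv(path, "mi_mrna"))
        results["lnc_mi"] = cerna.intersect_interaction_sources(lnc_mi_tables)
        results["mi_mrna"] = cerna.intersect_interaction_sources(mi_mrna_tables)

    # -- triplet assembly + network export -------------------------------
    @stage("triplets")
    def _triplets():
        if config.triplet_candidates == "de":
            candidates = results.get("de_lncs", [])
        else:
            candidates = results.get("candidates", [])
        mi_mrna = results["mi_mrna"]
        if config.triplet_targets == "ligands":
            targets = [normalize_gene_id(g) for g in config.ligands]
        else:
            targets = sorted({t for _, t in mi_mrna.edges})
        warnings: list = []
        triplets = cerna.assemble_triplets(
            logcpm, candidates, results["lnc_mi"], mi_mrna, targets,
            rho_pos_min=config.rho_pos_min, p_max=config.p_max,
            neg_p_max=config.neg_p_max, tumor_only=config.tumor_only,
            warnings_out=warnings)
        for w in warnings:
            log.warning("%s", w)
        results["triplets"] = triplets
        io.write_table_tsv(_triplet_table(triplets), outdir / "triplets.tsv",
                           meta, index=False)
        cerna.export_network(triplets, sif_path=outdir / "network.sif",
                             graphml_path=outdir / "network.graphml")

    # -- hub ranking ------------------------------------------------------
    @stage("hub")
    def _hub():
        candidates = results.get("candidates", [])
        ligands = [normalize_gene_id(g) for g in config.ligands]
        mat = logcpm.tumor_only() if config.tumor_only else logcpm
        corr = {}
        for lnc in candidates:
            corr[lnc] = tuple(
                spearman(mat.expression_of(lnc).to_numpy(float),
                         mat.expression_of(l).to_numpy(float))
                for l in ligands)
        ranked = cerna.rank_hub_lnc(candidates, corr) if candidates else []
        results["hub_ranking"] = ranked
        results["hub"] = ranked[0] if ranked else None
        frame = pd.DataFrame(
            [(lnc, corr[lnc][0].rho, corr[lnc][1].rho,
              (corr[lnc][0].rho + corr[lnc][1].rho) / 2) for lnc in ranked],
            columns=["lnc_id", "rho_ligand1", "rho_ligand2", "mean_rho"])
        io.write_table_tsv(frame, outdir / "hub_ranking.tsv", meta, index=False)

    # -- survival ----------------------------------------------------------
    @stage("survival")
    def _survival():
        hub = results.get("hub")
        if hub is None:
            log.warning("no hub candidate; survival stage skipped")
            return
        clinical = io.read_table_tsv(config.clinical)
        tumor = logcpm.tumor_only()
        values = tumor.expression_of(hub)
        shared = clinical.index.intersection(values.index)
        clinical = clinical.loc[shared]
        group = surv.median_split(values.loc[shared])
        records = clinical.assign(expr_group=group)
        results["expr_group"] = group
        for label in ("high", "low"):
            km = surv.kaplan_meier(records[records["expr_group"] == label])
            io.write_table_tsv(km, outdir / f"km_{label}.tsv", meta, index=False)
        lr = surv.logrank_test(records, group_col="expr_group")
        results["logrank"] = lr
        candidates = ["expr_group", "age", "sex", "stage", "grade",
                      "t_stage", "n_stage", "m_stage", "msi", "ebv"]
        candidates = [c for c in candidates
                      if c == "expr_group" or c in records.columns]
        univ, multi = surv.cox_screen(records, candidates,
                                      univ_p_enter=config.univ_p_enter)
        io.write_table_tsv(univ, outdir / "cox_univariate.tsv", meta, index=False)
        if multi is not None:
            io.write_table_tsv(multi.table, outdir / "cox_multivariate.tsv",
                               meta, index=False)
        results["cox_univariate"] = univ
        results["cox_multivariate"] = multi
        io.write_table_tsv(pd.DataFrame(
            {"statistic": [lr.statistic], "p": [lr.p]}),
            outdir / "logrank.tsv", meta, index=False)

    # -- enrichment --------------------------------------------------------
    @stage("enrichment")
    def _enrichment():
        hub = results.get("hub")
        if not config.gmt or hub is None:
            log.warning("no GMT or hub; enrichment stage skipped")
            return
        gene_sets = io.read_gmt(config.gmt)
        tumor = logcpm.tumor_only()
        group = results.get("expr_group")
        if group is None:
            group = surv.median_split(tumor.expression_of(hub))
        high = group.index[group == "high"]
        low = group.index[group == "low"]
        lfc = (tumor.values[high].mean(axis=1)
               - tumor.values[low].mean(axis=1))
        records = [SimpleNamespace(gene_id=g, log2fc=float(v))
                   for g, v in lfc.items()]
        ranked = enrichment.rank_by_log2fc(records)
        gsea = enrichment.gsea_batch(ranked, gene_sets, n_perm=config.n_perm,
                                     seed=config.seed, weight=config.weight)
        frame = pd.DataFrame(
            [(r.set_name, r.es, r.nes, r.p, r.adj_p, len(r.leading_edge))
             for r in gsea],
            columns=["set", "es", "nes", "p", "adj_p", "leading_edge_size"])
        io.write_table_tsv(frame, outdir / "gsea.tsv", meta, index=False)
        results["gsea"] = gsea

        counts_tumor = results["counts"].tumor_only()
        score_rows = []
        scores_frame = {}
        genes_of_interest = [hub] + [normalize_gene_id(g) for g in config.ligands]
        for gene_set in gene_sets:
            try:
                scores, absent = enrichment.signature_score_geomean(
                    counts_tumor, gene_set, pseudocount=config.pseudocount)
            except ValueError:
                continue
            scores_frame[gene_set.name] = scores
            for gene in genes_of_interest:
                if gene not in tumor.values.index:
                    continue
                res = enrichment.score_correlation(scores,
                                                   tumor.expression_of(gene))
                score_rows.append((gene_set.name, gene, res["result"].rho,
                                   res["result"].p, res["n"]))
        if scores_frame:
            io.write_table_tsv(pd.DataFrame(scores_frame),
                               outdir / "signature_scores.tsv", meta)
        frame = pd.DataFrame(score_rows, columns=["set", "gene", "rho", "p", "n"])
        io.write_table_tsv(frame, outdir / "signature_correlations.tsv", meta,
                           index=False)
        results["signature_correlations"] = frame

    # -- associations -------------------------------------------------------
    @stage("assoc")
    def _assoc():
        hub = results.get("hub")
        if hub is None:
            log.warning("no hub candidate; association stage skipped")
            return
        tumor = logcpm.tumor_only()
        values = tumor.expression_of(hub)
        rows = []
        if config.clinical:
            clinical = io.read_table_tsv(config.clinical)
            for factor in ("stage", "grade", "t_stage", "n_stage",
                           "m_stage", "msi", "ebv"):
                if factor not in clinical.columns:
                    continue
                try:
                    res = assoc_mod.clinical_association(values,
                                                         clinical[factor])
                except ValueError as err:
                    log.warning("factor %s skipped: %s", factor, err)
                    continue
                rows.append((factor, res["test"].method,
                             res["test"].statistic, res["test"].p))
        io.write_table_tsv(pd.DataFrame(
            rows, columns=["factor", "method", "statistic", "p"]),
            outdir / "clinical_associations.tsv", meta, index=False)
        if config.fractions:
            fractions = io.read_table_tsv(config.fractions)
            group = results.get("expr_group")
            if group is None:
                group = surv.median_split(values)
            comp = assoc_mod.fraction_group_compare(fractions, group)
            io.write_table_tsv(comp, outdir / "fraction_group_compare.tsv", meta)
            corr = assoc_mod.fraction_expression_correlation(fractions, values)
            io.write_table_tsv(corr, outdir / "fraction_correlations.tsv", meta)
            results["fraction_compare"] = comp
            results["fraction_correlations"] = corr

    # -- qPCR ---------------------------------------------------------------
    @stage("qpcr")
    def _qpcr():
        if not config.ct:
            return
        ct = pd.read_csv(config.ct, sep="\t", comment="#")
        target = [g for g in ct["gene"].unique() if g != "ACTB"][0]
        folds = assoc_mod.delta_delta_ct(ct, target, "ACTB", "adjacent")
        io.write_table_tsv(folds, outdir / "qpcr_folds.tsv", meta)
        rel = assoc_mod.delta_ct(ct, target, "ACTB")
        cond = ct[["sample_id", "condition"]].drop_duplicates() \
            .set_index("sample_id")["condition"].reindex(rel.index)
        pair = rel.index.str.replace(r"_(tumor|adjacent)$", "", regex=True)
        pair = pd.Series(pair, index=rel.index)
        res = assoc_mod.paired_expression_compare(
            rel[cond == "tumor"], rel[cond == "adjacent"],
            pair_ids=pair)
        results["qpcr_paired"] = res
        io.write_table_tsv(pd.DataFrame({
            "statistic": [res["test"].statistic], "p": [res["test"].p],
            "n_pairs": [res["n_pairs"]], "direction": [res["direction"]]}),
            outdir / "qpcr_paired_test.tsv", meta, index=False)

    return results
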