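"""End-to-end orchestration: simulate -> filter -> normalize -> X:A ->
structure -> pairwise DE -> overlap -> ASE -> report.

Stage outputs are flat TSV/JSON files in a run directory with a manifest;
all randomness derives from the single config seed via fixed substreams
(simulation uses the seed itself, overlap resampling uses seed + 1).
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, ase, de, dosage, overlap, simulate
from . import io as xio
from .exceptions import InputError

log = logging.getLogger("xadose")

#: Default genotype contrasts (group_a, group_b); DE direction is b over a.
DEFAULT_PAIRS = [("XX", "XY"), ("XXY", "XX"), ("XXY", "XY"),
                 ("XY", "XO"), ("XX", "XO")]


def compare_genotypes(counts: pd.DataFrame, annotation: pd.DataFrame,
                      sample_sheet: pd.DataFrame,
                      pairs: list[tuple[str, str]] | None = None,
                      size_factors: pd.Series | None = None,
                      lfc_threshold: float = 0.5,
                      padj_threshold: float = 0.05,
                      ) -> dict[tuple[str, str], pd.DataFrame]:
    """Run the two-group NB DE analysis for each genotype pair.

    Each genotype in a pair needs >= 2 samples; self-pairs are rejected.
    Returns {(genotype_a, genotype_b): per-gene DE table}.
    """
    if pairs is None:
        pairs = DEFAULT_PAIRS
    if not pairs:
        import warnings
        warnings.warn("empty pair list: nothing to compare", stacklevel=2)
        return {}
    sheet = sample_sheet.set_index("sample_id")
    by_geno = {g: list(grp.index)
               for g, grp in sheet.groupby("genotype", sort=False)}
    if size_factors is None:
        size_factors = dosage.size_factors_median_of_ratios(counts)
    results = {}
    for ga, gb in pairs:
        if ga == gb:
            raise InputError(f"self-comparison {ga} vs {gb} is not meaningful")
        for g in (ga, gb):
            if g not in by_geno:
                raise InputError(f"genotype {g} absent from the sample sheet")
            if len(by_geno[g]) < 2:
                raise InputError(f"genotype {g} has fewer than 2 samples")
        results[(ga, gb)] = de.run_de(
            counts, size_factors, by_geno[ga], by_geno[gb],
            lfc_threshold=lfc_threshold, padj_threshold=padj_threshold,
            annotation=annotation)
    return results


def run_pipeline(outdir: str | Path,
                 config: xio.PipelineConfig | None = None,
                 params: simulate.SimulationParams | None = None,
                 counts: pd.DataFrame | None = None,
                 annotation: pd.DataFrame | None = None,
                 sample_sheet: pd.DataFrame | None = None,
                 allele_counts: pd.DataFrame | None = None,
                 pairs: list[tuple[str, str]] | None = None,
                 simulate_inputs: bool = False) -> dict:
    """Run the full analysis and write stage outputs plus ``report.json``.

    Either pass the input tables (counts, annotation, sample sheet and
    optionally allele counts) or set ``simulate_inputs=True`` to generate
    them from ``params``. Deterministic given the config seed; on stage
    failure, completed stage outputs remain on disk next to a
    ``FAILED`` marker naming the stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config or xio.PipelineConfig()
    cfg.validate()
    report: dict = {"version": __version__, "seed": cfg.seed,
                    "config": {k: getattr(cfg, k) for k in vars(cfg)},
                    "stages": {}}
    manifest: list[str] = []
    stage = "setup"

    def _emit(name: str, writer, *args) -> None:
        writer(*args, outdir / name)
        manifest.append(name)

    try:
        t0 = time.time()
        if simulate_inputs:
            stage = "simulate"
            params = params or simulate.SimulationParams(seed=cfg.seed)
            annotation, truth = simulate.build_annotation(params)
            sample_sheet = simulate.build_sample_sheet(params)
            counts, truth = simulate.simulate_counts(annotation, sample_sheet,
                                                     params, truth)
            allele_counts = simulate.simulate_allele_counts(
                annotation, sample_sheet, params)
            _emit("counts.tsv", xio.write_count_matrix, counts)
            _emit("annotation.tsv", xio.write_annotation, annotation)
            _emit("sample_sheet.tsv", xio.write_sample_sheet, sample_sheet)
            _emit("truth.tsv", xio.write_truth_table, truth)
            _emit("allele_counts.tsv", xio.write_allele_counts, allele_counts)
            xio.write_json(params.to_dict(), outdir / "sim_params.json")
            manifest.append("sim_params.json")
        if counts is None or annotation is None or sample_sheet is None:
            raise InputError("counts, annotation and sample sheet are required "
                             "(or pass simulate_inputs=True)")
        xio.validate_tables(counts, annotation, sample_sheet)
        report["stages"]["input"] = {"n_genes": int(counts.shape[0]),
                                     "n_samples": int(counts.shape[1]),
                                     "seconds": round(time.time() - t0, 3)}
        log.info("input: %d genes x %d samples", *counts.shape)

        stage = "filter"
        t0 = time.time()
        filtered = dosage.filter_low_expression(counts, cfg.min_row_sum)
        report["stages"]["filter"] = {"n_genes": int(filtered.shape[0]),
                                      "min_row_sum": cfg.min_row_sum,
                                      "seconds": round(time.time() - t0, 3)}
        log.info("filter: %d genes retained", filtered.shape[0])

        stage = "normalize"
        t0 = time.time()
        sf = dosage.size_factors_median_of_ratios(filtered)
        vst = dosage.transform(filtered, sf)
        sf.to_frame().to_csv(outdir / "size_factors.tsv", sep="\t",
                             index_label="sample_id")
        manifest.append("size_factors.tsv")
        report["stages"]["normalize"] = {
            "size_factors": {k: float(v) for k, v in sf.items()},
            "seconds": round(time.time() - t0, 3)}

        stage = "xa_ratio"
        t0 = time.time()
        ratios = dosage.xa_ratio(vst, annotation)
        by_geno = dosage.xa_ratio_by_genotype(ratios, sample_sheet)
        ratios.to_csv(outdir / "xa_ratio.tsv", sep="\t",
                      index_label="sample_id")
        manifest.append("xa_ratio.tsv")
        report["stages"]["xa_ratio"] = {
            "per_sample": {k: float(v) for k, v in ratios["xa_ratio"].items()},
            "per_genotype": {g: {"mean": float(r["mean"]),
                                 "sd": (None if pd.isna(r["sd"])
                                        else float(r["sd"])),
                                 "n": int(r["n"])}
                             for g, r in by_geno.iterrows()},
            "seconds": round(time.time() - t0, 3)}
        log.info("xa_ratio: %s", {g: round(v["mean"], 3) for g, v in
                                  report["stages"]["xa_ratio"]["per_genotype"].items()})

        stage = "structure"
        t0 = time.time()
        top = dosage.top_variable_genes(vst, cfg.top_n_variable)
        coords, evr = dosage.pca_embed(vst, top, k=2)
        corr = dosage.correlation_matrix(vst, top)
        coords.to_csv(outdir / "pca.tsv", sep="\t", index_label="sample_id")
        corr.to_csv(outdir / "correlation.tsv", sep="\t",
                    index_label="sample_id")
        manifest += ["pca.tsv", "correlation.tsv"]
        report["stages"]["structure"] = {
            "n_top_genes": len(top),
            "explained_variance": [float(v) for v in evr],
            "seconds": round(time.time() - t0, 3)}

        stage = "differential_expression"
        t0 = time.time()
        de_results = compare_genotypes(
            filtered, annotation, sample_sheet, pairs=pairs, size_factors=sf,
            lfc_threshold=cfg.lfc_threshold, padj_threshold=cfg.padj_threshold)
        de_summaries = {}
        for (ga, gb), res in de_results.items():
            name = f"de_{ga}_vs_{gb}.tsv"
            res.to_csv(outdir / name, sep="\t", index_label="gene_id")
            manifest.append(name)
            de_summaries[f"{ga}_vs_{gb}"] = de.summarize_de(res, annotation)
        report["stages"]["de"] = {"summaries": de_summaries,
                                  "seconds": round(time.time() - t0, 3)}
        log.info("de: %s", {k: v["n_de"] for k, v in de_summaries.items()})

        stage = "overlap"
        t0 = time.time()
        overlap_out = {}
        xo_pairs = [(ga, gb) for ga, gb in de_results if "XO" in (ga, gb)]
        if len(xo_pairs) >= 2:
            universe = list(filtered.index)
            sets = {p: list(de_results[p].index[de_results[p]["is_de"]])
                    for p in xo_pairs[:2]}
            (p1, p2) = xo_pairs[:2]
            if all(len(s) > 0 for s in sets.values()):
                result = overlap.overlap_permutation_test(
                    universe, sets[p1], sets[p2],
                    n_permutations=cfg.n_permutations, seed=cfg.seed + 1)
                overlap.adjust_overlap_pvalues([result])
                overlap_out[f"{p1[0]}_vs_{p1[1]}__{p2[0]}_vs_{p2[1]}"] = \
                    result.to_dict()
        report["stages"]["overlap"] = {"results": overlap_out,
                                       "seconds": round(time.time() - t0, 3)}

        stage = "ase"
        t0 = time.time()
        ase_out = {}
        if allele_counts is not None and len(allele_counts):
            calls = ase.call_xci_status(
                allele_counts, cfg.min_snp_coverage,
                cfg.ase_mono_threshold, cfg.ase_biallelic_threshold)
            summary = ase.aggregate_line_xci(calls, annotation,
                                             cfg.erosion_biallelic_cutoff)
            calls.to_csv(outdir / "xci_calls.tsv", sep="\t", index=False)
            summary.to_csv(outdir / "xci_summary.tsv", sep="\t", index=False)
            manifest += ["xci_calls.tsv", "xci_summary.tsv"]
            ase_out = {row["sample_id"]: {
                "erosion_flag": bool(row["erosion_flag"]),
                "xci_subject_monoallelic": int(row["xci_subject_monoallelic"]),
                "xci_subject_biallelic": int(row["xci_subject_biallelic"])}
                for _, row in summary.iterrows()}
        report["stages"]["ase"] = {"per_sample": ase_out,
                                   "seconds": round(time.time() - t0, 3)}

        stage = "report"
        report["manifest"] = manifest
        xio.write_json(report, outdir / "report.json")
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise
    return report
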