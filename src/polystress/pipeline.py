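"""End-to-end orchestration: simulate -> translation -> proteome -> integrate.

Each stage reads/writes plain TSV tables under the output directory and
the run ends with a JSON manifest (configuration, seed, input checksums,
outputs), so a run is reproducible from the manifest alone. Stages whose
input layer is absent are skipped with a log line; results are
deterministic given the configuration and seed.
"""

from __future__ import annotations

import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import integrate, io, profiles, proteome, simulate
from .config import RunConfig, SimulationConfig

log = logging.getLogger("polystress")

__all__ = ["write_synthetic_dataset", "run_pipeline"]


def write_synthetic_dataset(config: SimulationConfig, outdir) -> dict[str, list[Path]]:
    """Generate all three synthetic layers and write them to ``outdir``.

    Writes one fraction file per condition/replicate, the mRNA table,
    the spectrum-count and unique-peptide matrices, the ground-truth
    table, and the configuration as YAML. Returns the written paths per
    layer.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = simulate.assign_labels(config)
    pools = simulate.simulate_fraction_pools(config, truth)
    mrna = simulate.simulate_mrna_table(config, truth)
    counts = simulate.simulate_spectrum_counts(config, truth)

    written: dict[str, list[Path]] = {"fractions": [], "mrna": [], "counts": [],
                                      "truth": [], "config": []}
    for rep, df in pools.control.items():
        p = outdir / f"fractions_control_0_rep{rep}.tsv"
        io.write_matrix(df, p)
        written["fractions"].append(p)
    for t, reps in pools.stress.items():
        for rep, df in reps.items():
            p = outdir / f"fractions_{config.condition}_{t}_rep{rep}.tsv"
            io.write_matrix(df, p)
            written["fractions"].append(p)

    p = outdir / "mrna_log2.tsv"
    io.write_matrix(mrna, p)
    written["mrna"].append(p)

    pc = outdir / "spectrum_counts.tsv"
    io.write_matrix(counts.counts, pc)
    pu = outdir / "unique_peptides.tsv"
    io.write_matrix(counts.unique_peptides, pu)
    written["counts"] += [pc, pu]

    pt = outdir / "ground_truth.tsv"
    truth.genes.to_csv(pt, sep="\t")
    written["truth"].append(pt)
    if truth.scale_factors is not None:
        ps = outdir / "true_scale_factors.tsv"
        truth.scale_factors.to_csv(ps, sep="\t")
        written["truth"].append(ps)

    pcfg = outdir / "config.yaml"
    pcfg.write_text(config.to_yaml())
    written["config"].append(pcfg)
    log.info("simulate: wrote %d files to %s", sum(map(len, written.values())), outdir)
    return written


def translation_stage(
    control_files: list, stress_files: list, run_config: RunConfig
) -> pd.DataFrame:
    """Translation calling from four-pool fraction files.

    Control and stress files are paired by position (acquisition round);
    unequal lists fall back to all stress x control pairs.
    """
    control = {i + 1: io.read_matrix(f, "fractions") for i, f in enumerate(control_files)}
    stress = {i + 1: io.read_matrix(f, "fractions") for i, f in enumerate(stress_files)}
    pairing = None
    if len(control) != len(stress):
        pairing = [(rs, rc) for rs in sorted(stress) for rc in sorted(control)]
        log.info("translation: unequal replicate lists, averaging all pairs")
    result = profiles.compare_conditions(
        control, stress,
        thresholds=run_config.thresholds,
        strict=run_config.strict,
        pairing=pairing,
    )
    log.info(
        "translation: %d genes, %d excluded, %d up, %d down",
        len(result), int(result["excluded"].sum()),
        int((result["direction"] == "up").sum()),
        int((result["direction"] == "down").sum()),
    )
    return result


def proteome_stage(
    counts_file, peptides_file, run_config: RunConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    counts = io.read_matrix(counts_file, "counts")
    peptides = io.read_matrix(peptides_file, "counts")
    fits, traj, factors = proteome.analyze_counts(
        counts, peptides, alpha=run_config.alpha, pseudocount=run_config.pseudocount
    )
    log.info(
        "proteome: %d/%d proteins retained, %d significant",
        len(fits), len(counts), int(fits["significant"].sum()),
    )
    return fits, traj, factors


def integrate_stage(
    mrna_tables: list[pd.DataFrame],
    translation: pd.DataFrame | None,
    protein_fits: pd.DataFrame | None,
    protein_traj: pd.DataFrame | None,
    run_config: RunConfig,
    gene_sets: dict[str, set] | None = None,
) -> dict:
    """Cross-level calls, discordance classes, correlations, enrichment."""
    mrna_calls = integrate.call_mrna_direction(
        mrna_tables, run_config.fold_cutoff, run_config.min_timepoints
    )
    results: dict = {"mrna_calls": mrna_calls}

    trans_dir = (
        translation["direction"]
        if translation is not None
        else pd.Series(dtype=object)
    )
    prot_cat = (
        protein_fits["category"]
        if protein_fits is not None
        else pd.Series(dtype=object)
    )
    results["discordance"] = integrate.classify_discordance(
        mrna_calls["direction"], trans_dir, prot_cat
    )

    correlations = []
    mrna_avg = pd.concat(mrna_tables, axis=1)
    stress_cols = [c for c in mrna_avg.columns if float(str(c).split(":")[1]) > 0]
    mrna_change = mrna_avg[stress_cols].mean(axis=1)
    if translation is not None:
        shared = mrna_change.index.intersection(translation.index)
        log2_r = np.log2(translation.loc[shared, "R"])
        ok = log2_r.notna() & mrna_change.loc[shared].notna()
        if ok.sum() >= 3:
            r, p = integrate.correlate(
                mrna_change.loc[shared][ok], log2_r[ok], "pearson"
            )
            correlations.append(
                {"comparison": "mrna_vs_translation", "method": "pearson",
                 "r": r, "p": p, "n": int(ok.sum())}
            )
    if protein_traj is not None:
        prot_change = protein_traj.apply(integrate.max_change, axis=1)
        shared = mrna_change.index.intersection(prot_change.index)
        if len(shared) >= 3:
            r, p = integrate.correlate(
                mrna_change.loc[shared], prot_change.loc[shared], "pearson"
            )
            correlations.append(
                {"comparison": "mrna_vs_protein", "method": "pearson",
                 "r": r, "p": p, "n": len(shared)}
            )
    results["correlations"] = pd.DataFrame(correlations)

    if gene_sets:
        regulated = set(mrna_calls.index[mrna_calls["direction"] != "none"])
        results["enrichment"] = integrate.hypergeom_enrichment(
            regulated, gene_sets, set(mrna_calls.index)
        )

    regulated_idx = mrna_calls.index[mrna_calls["direction"] != "none"]
    if len(regulated_idx) >= 2 and len(stress_cols) >= 2:
        sub = mrna_avg.loc[regulated_idx, stress_cols]
        try:
            Z, leaves, kept_index, _dropped = integrate.cluster_genes(sub)
            results["tree_newick"] = integrate.tree_to_newick(Z, kept_index)
            results["leaf_order"] = leaves
        except ValueError as exc:
            log.info("integrate: clustering skipped (%s)", exc)
    log.info("integrate: %d correlations, %d mRNA calls",
             len(correlations), int((mrna_calls["direction"] != "none").sum()))
    return results


def run_pipeline(
    sim_config: SimulationConfig,
    run_config: RunConfig,
    outdir,
    gene_sets: dict[str, set] | None = None,
) -> dict:
    """Full synthetic run: simulate, then all three analysis stages.

    Writes every result table plus a manifest and returns the in-memory
    results. Re-running with the same configuration and seed reproduces
    the outputs byte for byte.
    """
    outdir = Path(outdir)
    data_dir = outdir / "data"
    written = write_synthetic_dataset(sim_config, data_dir)

    control_files = sorted(p for p in written["fractions"] if "control" in p.name)
    outputs: list[Path] = []
    results: dict = {}

    # translation stage, one comparison per stress time point
    trans_results = {}
    for t in sim_config.stress_timepoints_min:
        stress_files = sorted(
            p for p in written["fractions"]
            if f"_{sim_config.condition}_{t}_" in p.name
        )
        res = translation_stage(control_files, stress_files, run_config)
        trans_results[t] = res
        p = outdir / f"translation_calls_{t}min.tsv"
        io.write_matrix(res.drop(columns=["direction"]).assign(direction=res["direction"]), p)
        outputs.append(p)
    results["translation"] = trans_results

    fits, traj, factors = proteome_stage(
        data_dir / "spectrum_counts.tsv", data_dir / "unique_peptides.tsv", run_config
    )
    results["proteome"] = {"fits": fits, "trajectories": traj, "factors": factors}
    for name, df in (("proteome_fits", fits), ("proteome_trajectories", traj)):
        p = outdir / f"{name}.tsv"
        io.write_matrix(df if isinstance(df, pd.DataFrame) else df.to_frame(), p)
        outputs.append(p)

    mrna = io.read_matrix(data_dir / "mrna_log2.tsv", "mrna")
    last_t = max(sim_config.stress_timepoints_min)
    integration = integrate_stage(
        [mrna], trans_results[last_t], fits, traj, run_config, gene_sets
    )
    results["integration"] = integration
    for name in ("mrna_calls", "discordance", "correlations"):
        obj = integration.get(name)
        if obj is not None and len(obj):
            p = outdir / f"{name}.tsv"
            io.write_matrix(obj, p)
            outputs.append(p)
    if "tree_newick" in integration:
        p = outdir / "mrna_cluster_tree.nwk"
        p.write_text(integration["tree_newick"] + "\n")
        outputs.append(p)

    manifest = io.write_manifest(
        outdir,
        {"simulation": asdict(sim_config),
         "run": {**asdict(run_config), "thresholds": asdict(run_config.thresholds)}},
        [f for group in written.values() for f in group],
        outputs,
    )
    results["manifest"] = manifest
    return results
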