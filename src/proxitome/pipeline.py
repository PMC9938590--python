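"""End-to-end orchestration: simulate -> enrich x6 -> HCI -> overlap ->
profile -> gene sets -> report, from one YAML configuration.

One global seed deterministically spawns per-stage seeds (all recorded in
the run manifest); re-running the same configuration reproduces every
output byte-exactly. Outputs are TSVs plus one JSON manifest; no
timestamps are embedded anywhere. A stage failure writes a ``FAILED``
marker naming the stage and re-raises; earlier stage outputs are retained.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import enrichment, genesets, hci, io, overlap as overlap_mod, profiles
from . import synthetic
from .containers import GeneList
from .errors import ConfigurationError, ProxitomeError
from .genome import ChromSizes

DEFAULT_COMPARISONS = (
    {"bait": "nt_kdm5", "reference": "control", "experiment": "exp1"},
    {"bait": "ct_kdm5", "reference": "control", "experiment": "exp1"},
    {"bait": "nt_kdm5", "reference": "control", "experiment": "exp2"},
    {"bait": "ct_kdm5", "reference": "control", "experiment": "exp2"},
    {"bait": "nt_kdm5", "reference": "dcas9", "experiment": "exp2"},
    {"bait": "ct_kdm5", "reference": "dcas9", "experiment": "exp2"},
)

_SECTION_DEFAULTS: dict[str, dict] = {
    "imputation": {"downshift": 2.0, "width_factor": 0.3, "scope": "per_sample"},
    "alpha": {"volcano": 0.05, "hci": 0.1},
    "overlap": {"n_permutations": 100, "permute": "target",
                "significance": 0.05},
    "profile": {"flank": 2000, "bin_size": 5, "smooth_bins": 5,
                "prominence": 0.5},
    "geneset": {"min_ortholog_score": 8},
    "peaks": {"n_query": 60, "n_target": 60, "offset_sd": 50.0,
              "flank_offset": 500, "peak_width": 200,
              "chrom_length": 200000, "n_chromosomes": 4,
              "peak_height": 10.0, "background": 1.0},
}
_TOP_LEVEL_KEYS = {"seed", "output_dir", "synthetic", "comparisons",
                   *_SECTION_DEFAULTS}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration with defaults injected."""

    seed: int
    output_dir: str
    synthetic: dict = field(default_factory=dict)
    comparisons: list[dict] = field(default_factory=lambda:
                                    [dict(c) for c in DEFAULT_COMPARISONS])
    imputation: dict = field(default_factory=dict)
    alpha: dict = field(default_factory=dict)
    overlap: dict = field(default_factory=dict)
    profile: dict = field(default_factory=dict)
    geneset: dict = field(default_factory=dict)
    peaks: dict = field(default_factory=dict)

    def echo(self) -> dict:
        """Plain-dict form with every default made explicit."""
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


def _check_keys(section: str, given: dict, allowed: set[str]) -> None:
    unknown = sorted(set(given) - allowed)
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) in {section}: {unknown} (allowed: {sorted(allowed)})"
        )


def validate_config(source: str | dict) -> PipelineConfig:
    """Load + validate a YAML pipeline config; inject and echo defaults.

    Unknown keys anywhere are errors (no silent typo tolerance); the six
    comparisons must cover three per bait terminus with unique slots;
    significance levels must lie in (0, 1).
    """
    if isinstance(source, dict):
        raw = dict(source)
    else:
        with open(source, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("pipeline config must be a mapping")
    _check_keys("config", raw, _TOP_LEVEL_KEYS)
    if "seed" not in raw or "output_dir" not in raw:
        raise ConfigurationError("config requires 'seed' and 'output_dir'")

    sections: dict[str, dict] = {}
    for name, defaults in _SECTION_DEFAULTS.items():
        given = raw.get(name) or {}
        if not isinstance(given, dict):
            raise ConfigurationError(f"section {name!r} must be a mapping")
        _check_keys(name, given, set(defaults))
        sections[name] = {**defaults, **given}

    syn = raw.get("synthetic") or {}
    syn_allowed = {f.name for f in dc_fields(synthetic.SyntheticStudyConfig)} - {"seed"}
    _check_keys("synthetic", syn, syn_allowed)

    comparisons = raw.get("comparisons")
    if comparisons is None:
        comparisons = [dict(c) for c in DEFAULT_COMPARISONS]
    if len(comparisons) != 6:
        raise ConfigurationError(
            f"exactly six comparisons required, got {len(comparisons)}"
        )
    slots = []
    per_bait: dict[str, int] = {}
    for comp in comparisons:
        _check_keys("comparisons entry", comp, {"bait", "reference", "experiment"})
        for key in ("bait", "reference", "experiment"):
            if key not in comp:
                raise ConfigurationError(f"comparison missing {key!r}: {comp}")
        slot = f"{comp['bait']}_vs_{comp['reference']}_{comp['experiment']}"
        slots.append(slot)
        per_bait[comp["bait"]] = per_bait.get(comp["bait"], 0) + 1
    dupes = sorted({s for s in slots if slots.count(s) > 1})
    if dupes:
        raise ConfigurationError(f"duplicate comparison slot(s): {dupes}")
    if sorted(per_bait.values()) != [3, 3]:
        raise ConfigurationError(
            f"need three comparisons per bait terminus, got {per_bait}"
        )
    for name, level in sections["alpha"].items():
        if not (0 < float(level) < 1):
            raise ConfigurationError(
                f"alpha.{name} must lie in (0, 1), got {level}"
            )
    return PipelineConfig(
        seed=int(raw["seed"]), output_dir=str(raw["output_dir"]),
        synthetic=syn, comparisons=[dict(c) for c in comparisons],
        imputation=sections["imputation"], alpha=sections["alpha"],
        overlap=sections["overlap"], profile=sections["profile"],
        geneset=sections["geneset"], peaks=sections["peaks"],
    )


def _spawn_seeds(seed: int, names: list[str]) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: int(child.generate_state(1)[0] % (2 ** 31))
            for name, child in zip(names, children)}


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages on a synthetic study; return the run manifest.

    The synthetic generators provide every input (abundance matrix,
    annotation tables, peak sets, signal track) from the spawned stage
    seeds; all per-stage tables are written under ``output_dir`` and the
    manifest records seeds, parameters, row counts and file checksums.
    """
    outdir = config.output_dir
    os.makedirs(outdir, exist_ok=True)
    inputs_dir = os.path.join(outdir, "inputs")
    os.makedirs(inputs_dir, exist_ok=True)
    failed_marker = os.path.join(outdir, "FAILED")
    if os.path.exists(failed_marker):
        os.remove(failed_marker)

    seeds = _spawn_seeds(config.seed, [
        "simulate", "impute_exp1", "impute_exp2", "peaks_coincident",
        "peaks_flanking", "peaks_independent", "overlap",
    ])
    manifest: dict = {
        "proxitome_version": __version__,
        "config": config.echo(),
        "stage_seeds": seeds,
        "stages": {},
        "files": {},
    }
    stage = "simulate"
    try:
        # --- simulate -----------------------------------------------------
        syn_config = synthetic.SyntheticStudyConfig(
            **config.synthetic, seed=seeds["simulate"])
        matrix, truth = synthetic.generate_abundance_study(syn_config)
        bundle = synthetic.generate_annotation_tables(syn_config, truth)
        io.write_abundance_table(matrix,
                                 os.path.join(inputs_dir, "abundance.tsv"),
                                 os.path.join(inputs_dir, "metadata.tsv"))
        io.write_gene_list(bundle.nuclear, os.path.join(inputs_dir, "nuclear.txt"))
        io.write_gene_list(bundle.known,
                           os.path.join(inputs_dir, "known_interactors.txt"))
        io.write_ortholog_map(bundle.orthologs,
                              os.path.join(inputs_dir, "orthologs.tsv"))
        io.write_gene_list(bundle.universe, os.path.join(inputs_dir, "universe.txt"))
        for name, glist in bundle.disease.items():
            io.write_gene_list(glist, os.path.join(inputs_dir, f"{name}.tsv"))
        truth_table = pd.DataFrame(
            {"label": pd.Series(truth.labels),
             "nuclear": pd.Series({p: p in truth.nuclear for p in truth.labels})})
        truth_table.index.name = "protein_id"
        io.write_results(truth_table, os.path.join(outdir, "planted_truth.tsv"),
                         provenance={"seed": seeds["simulate"]})
        manifest["stages"]["simulate"] = {
            "n_proteins": matrix.n_proteins, "n_samples": matrix.n_samples,
            "n_planted": len(truth.planted_interactors),
        }

        # genomic inputs
        pk = config.peaks
        sizes = ChromSizes({f"chr{i + 1}": int(pk["chrom_length"])
                            for i in range(int(pk["n_chromosomes"]))})
        io.write_chrom_sizes(sizes, os.path.join(inputs_dir, "genome.sizes"))
        peak_sets = {}
        for mode, seed_name in (("coincident", "peaks_coincident"),
                                ("flanking_bimodal", "peaks_flanking"),
                                ("independent", "peaks_independent")):
            query, target = synthetic.generate_peak_sets(
                sizes, int(pk["n_query"]), int(pk["n_target"]), mode,
                offset_sd=float(pk["offset_sd"]), seed=seeds[seed_name],
                query_width=int(pk["peak_width"]),
                target_width=int(pk["peak_width"]),
                flank_offset=int(pk["flank_offset"]))
            target.label = f"target_{mode}"
            peak_sets[mode] = (query, target)
            io.write_bed(target, os.path.join(inputs_dir, f"target_{mode}.bed"))
        # one query set serves all overlap tests: the coincident-mode query
        # plays the role of the bait's own binding sites
        bait_query = peak_sets["coincident"][0]
        io.write_bed(bait_query, os.path.join(inputs_dir, "query.bed"))
        bait_track = synthetic.generate_signal_track(
            bait_query, float(pk["peak_height"]), float(pk["background"]), sizes)
        io.write_bedgraph(bait_track, os.path.join(inputs_dir, "query_signal.bedgraph"))

        # --- enrichment x6 ------------------------------------------------
        stage = "enrich"
        specs = [enrichment.ComparisonSpec(
            bait=c["bait"], reference=c["reference"], experiment=c["experiment"],
            alpha_volcano=float(config.alpha["volcano"]),
            alpha_hci=float(config.alpha["hci"])) for c in config.comparisons]
        results: dict[str, pd.DataFrame] = {}
        for experiment in sorted({s.experiment for s in specs}):
            params = enrichment.ImputationParams(
                downshift=float(config.imputation["downshift"]),
                width_factor=float(config.imputation["width_factor"]),
                scope=str(config.imputation["scope"]),
                seed=seeds[f"impute_{experiment}"])
            prepared = enrichment.prepare_experiment(matrix, experiment, params)
            for spec in specs:
                if spec.experiment != experiment:
                    continue
                res = enrichment.run_comparison(
                    prepared.complete, spec, prepared.imputed_mask,
                    prepared.metadata)
                results[spec.slot] = res
                io.write_results(
                    res, os.path.join(outdir, f"enrichment_{spec.slot}.tsv"),
                    provenance={"bait": spec.bait, "reference": spec.reference,
                                "experiment": spec.experiment,
                                "imputation_seed": params.seed})
        manifest["stages"]["enrich"] = {
            slot: {"n_tested": int((df["excluded_reason"] == "").sum()),
                   "n_enriched_05": int(df["enriched_05"].sum())}
            for slot, df in results.items()}

        # --- HCI ----------------------------------------------------------
        stage = "hci"
        calls = hci.call_significant(results, alpha_hci=float(config.alpha["hci"]))
        hci_table = hci.apply_hci_workflow(calls, bundle.nuclear)
        audit = hci_table.join(calls)
        io.write_results(audit, os.path.join(outdir, "hci.tsv"),
                         provenance={"alpha_hci": config.alpha["hci"]})
        hci_ids = hci.hci_set(hci_table)
        per_comp_sets = {slot: set(df.index[df["enriched_05"]])
                         for slot, df in results.items()}
        recovery = hci.recover_known_interactors(
            {"hci": set(hci_ids), **per_comp_sets}, bundle.known)
        io.write_results(recovery, os.path.join(outdir, "recovery.tsv"),
                         index=True, index_label="set_name")
        planted = set(truth.planted_interactors)
        planted_in_hci = planted & hci_ids
        correct = sum(
            1 for p in planted
            if p in hci_ids and _category_matches(truth.labels[p],
                                                  hci_table.loc[p, "category"]))
        contaminants = sorted(hci_ids - planted)
        planted_recovery = pd.DataFrame([{
            "n_planted": len(planted),
            "n_planted_in_hci": len(planted_in_hci),
            "n_correct_category": correct,
            "n_hci": len(hci_ids),
            "n_contaminant": len(contaminants),
        }])
        io.write_results(planted_recovery,
                         os.path.join(outdir, "planted_recovery.tsv"),
                         index=False)
        manifest["stages"]["hci"] = planted_recovery.iloc[0].to_dict()

        # --- genomic overlap ---------------------------------------------
        stage = "overlap"
        targets = [peak_sets[m][1] for m in ("coincident", "flanking_bimodal",
                                             "independent")]
        ov_table, ov_summary = overlap_mod.batch_overlap(
            bait_query, targets, sizes,
            n_permutations=int(config.overlap["n_permutations"]),
            seed=seeds["overlap"],
            significance=float(config.overlap["significance"]))
        io.write_results(ov_table, os.path.join(outdir, "overlap.tsv"),
                         index=True, index_label="target_label")
        manifest["stages"]["overlap"] = ov_summary

        # --- signal profiles ----------------------------------------------
        stage = "profile"
        prof_rows = []
        for mode in ("coincident", "flanking_bimodal", "independent"):
            target = peak_sets[mode][1]
            mat = profiles.compute_matrix(
                bait_track, target, flank=int(config.profile["flank"]),
                bin_size=int(config.profile["bin_size"]))
            summary = profiles.summarize_profile(
                mat, smooth_bins=int(config.profile["smooth_bins"]),
                prominence=float(config.profile["prominence"]))
            mat_df = pd.DataFrame(mat.values, columns=[
                f"{off:.1f}" for off in mat.bin_offsets])
            io.write_results(mat_df,
                             os.path.join(outdir, f"profile_{mode}_matrix.tsv"),
                             index=False)
            prof_rows.append({
                "target": target.label, "shape": summary.shape,
                "peak_offsets_bp": ",".join(f"{o:.1f}"
                                            for o in summary.peak_offsets_bp),
                "max_signal": float(summary.mean_profile.max()),
            })
        prof_table = pd.DataFrame(prof_rows).set_index("target")
        io.write_results(prof_table, os.path.join(outdir, "profile_summary.tsv"),
                         index=True, index_label="target")
        manifest["stages"]["profile"] = {r["target"]: r["shape"]
                                         for r in prof_rows}

        # --- gene sets ------------------------------------------------------
        stage = "geneset"
        hci_list = GeneList(name="hci", members=tuple(sorted(hci_ids)))
        mapping = genesets.map_orthologs(
            hci_list, bundle.orthologs,
            min_score_exclusive=int(config.geneset["min_ortholog_score"]))
        io.write_gene_list(mapping.mapped,
                           os.path.join(outdir, "hci_human_orthologs.txt"))
        gs_rows = []
        overlap_results = {}
        for name, ref in bundle.disease.items():
            res = genesets.hypergeometric_overlap(mapping.mapped, ref,
                                                  bundle.universe)
            overlap_results[name] = res
            gs_rows.append(res.as_row())
        gs_table = pd.DataFrame(gs_rows).set_index("reference")
        io.write_results(gs_table, os.path.join(outdir, "geneset_overlap.tsv"),
                         index=True, index_label="reference")
        if overlap_results:
            first = next(iter(overlap_results.values()))
            report, cross = genesets.scored_overlap_report(first, bundle.disease)
            io.write_results(report, os.path.join(outdir, "geneset_members.tsv"),
                             index=True, index_label="member")
            manifest["stages"]["geneset"] = {
                "n_orthologs": len(mapping.mapped),
                "overlaps": {name: res.k for name, res in overlap_results.items()},
                "cross_counts": {f"{a}&{b}": v for (a, b), v in cross.items()},
            }

        # --- manifest -------------------------------------------------------
        stage = "manifest"
        for root, _, files in os.walk(outdir):
            for fname in sorted(files):
                if fname == "manifest.json":
                    continue
                path = os.path.join(root, fname)
                rel = os.path.relpath(path, outdir)
                manifest["files"][rel] = _sha256(path)
        with open(os.path.join(outdir, "manifest.json"), "w",
                  encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest
    except ProxitomeError as exc:
        with open(failed_marker, "w", encoding="utf-8") as fh:
            fh.write(f"stage={stage}\nerror={exc}\n")
        raise ProxitomeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _category_matches(label: str, category: str) -> bool:
    return {"shared": "shared", "nt_only": "nt_exclusive",
            "ct_only": "ct_exclusive"}.get(label) == category
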