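"""Config-driven end-to-end runs and report generation.

A run executes simulate (optional) -> frequency -> gsea -> modules ->
overrep into an output directory, recording a manifest with input
checksums, parameters, and the package version.  Every stage consumes
only files named in the manifest, so a run is reproducible from its
config + seed alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml

from . import __version__, exprio, frequency, gsea, modules, overrep, synthetic

__all__ = ["PipelineError", "load_config", "run_pipeline", "report"]

STAGES = ("simulate", "frequency", "gsea", "modules", "overrep")


@dataclass
class PipelineError(Exception):
    stage: str
    message: str

    def __str__(self) -> str:
        return f"stage {self.stage!r}: {self.message}"


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise PipelineError("config", f"{path} is not a mapping")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _require(cfg: dict, key: str, stage: str) -> Any:
    if key not in cfg:
        raise PipelineError(stage, f"missing required config key {key!r}")
    return cfg[key]


def run_pipeline(config: dict, out_dir: str | Path, seed: int | None = None) -> Path:
    """Execute all stages; returns the run directory.

    ``config`` must provide either a ``simulate`` section or explicit
    ``inputs`` paths (matrix, metadata, lists).  ``seed`` overrides the
    config's global seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0) if seed is None else seed)
    manifest: dict[str, Any] = {
        "schema_version": 1,
        "package_version": __version__,
        "seed": seed,
        "stages": {},
        "inputs": {},
    }

    # --- resolve inputs (simulate or load) --------------------------------
    if "simulate" in config:
        sim_cfg = dict(config["simulate"] or {})
        list_specs = sim_cfg.pop("lists", None)
        try:
            atlas_cfg = synthetic.AtlasConfig(**{**sim_cfg, "seed": seed})
            matrix, truth = synthetic.generate_atlas(atlas_cfg)
            specs = [synthetic.ListSpec(**s) for s in (list_specs or _default_list_specs(atlas_cfg))]
            lists = synthetic.generate_gene_lists(truth, specs, seed=seed + 1)
        except (TypeError, ValueError) as e:
            raise PipelineError("simulate", str(e)) from e
        sim_dir = out / "simulate"
        paths = synthetic.write_atlas(matrix, truth, sim_dir, lists=lists)
        matrix_path, metadata_path, lists_path = (
            paths["matrix"], paths["metadata"], paths["lists"],
        )
        manifest["stages"]["simulate"] = {
            "outputs": {k: str(v.relative_to(out)) for k, v in paths.items()},
            "parameters": {**sim_cfg, "seed": seed},
        }
    else:
        inputs = _require(config, "inputs", "config")
        matrix_path = Path(_require(inputs, "matrix", "config"))
        metadata_path = Path(_require(inputs, "metadata", "config"))
        lists_path = Path(_require(inputs, "lists", "config"))

    for name, p in (
        ("matrix", matrix_path), ("metadata", metadata_path), ("lists", lists_path),
    ):
        p = Path(p)
        if not p.exists():
            raise PipelineError("frequency", f"input file not found: {p}")
        manifest["inputs"][name] = {"path": str(p), "sha256": _sha256(p)}

    try:
        matrix = exprio.read_expression_matrix(matrix_path, metadata_path)
        gene_lists = exprio.read_gene_lists(lists_path)
    except ValueError as e:
        raise PipelineError("frequency", str(e)) from e

    mapped_lists = []
    mapping_reports = []
    for gl in gene_lists:
        mapped, rep = exprio.map_symbols(gl, matrix.gene_ids, mode="case-normalize")
        mapped_lists.append(mapped)
        mapping_reports.append(rep)

    profile = exprio.average_replicates(matrix)

    # --- frequency --------------------------------------------------------
    fcfg = dict(config.get("frequency", {}) or {})
    q = float(fcfg.get("q", 0.05))
    include = None
    if not fcfg.get("include_mesc", True):
        include = [
            r for r in profile.regions if profile.region_groups.get(r) != "stemcell"
        ]
    try:
        freq = frequency.frequency_table(profile, include=include)
        freq_dir = out / "frequency"
        freq_dir.mkdir(exist_ok=True)
        freq.values.rename_axis("gene_id").to_csv(freq_dir / "frequency_table.tsv", sep="\t")
        summary_rows = []
        test_rows = []
        for gl in mapped_lists:
            summ = frequency.list_summary(freq, gl)
            for region, row in summ.table.iterrows():
                summary_rows.append(
                    (gl.name, region, row["mean"], row["sem"], int(row["n"]))
                )
            if len([g for g in gl.genes if g in freq.values.index]) >= 2:
                f_stat, anova_p, tests = frequency.pairwise_region_tests(freq, gl, q=q)
                for t in tests:
                    test_rows.append(
                        (gl.name, f_stat, anova_p, t.region_a, t.region_b,
                         t.t_stat, t.p_value, t.significant, t.q_level)
                    )
        pd.DataFrame(
            summary_rows, columns=["list_name", "region", "mean", "sem", "n"]
        ).to_csv(freq_dir / "list_summaries.tsv", sep="\t", index=False)
        pd.DataFrame(
            test_rows,
            columns=["list_name", "anova_f", "anova_p", "region_a", "region_b",
                     "t_stat", "p_value", "significant", "q_level"],
        ).to_csv(freq_dir / "pairwise_tests.tsv", sep="\t", index=False)
    except ValueError as e:
        raise PipelineError("frequency", str(e)) from e
    manifest["stages"]["frequency"] = {
        "outputs": {
            "frequency_table": "frequency/frequency_table.tsv",
            "list_summaries": "frequency/list_summaries.tsv",
            "pairwise_tests": "frequency/pairwise_tests.tsv",
        },
        "parameters": {"q": q, "include_mesc": bool(fcfg.get("include_mesc", True))},
        "dropped_zero_total_genes": len(freq.dropped_zero_total),
        "symbol_mapping": [
            {"list": r.list_name, "n_input": r.n_input, "n_mapped": r.n_mapped,
             "dropped": list(r.dropped)}
            for r in mapping_reports
        ],
    }

    # --- gsea -------------------------------------------------------------
    gcfg = dict(config.get("gsea", {}) or {})
    try:
        gsea_df = gsea.gsea_all(
            matrix,
            mapped_lists,
            level=gcfg.get("level", "group"),
            n_perm=int(gcfg.get("n_perm", 1000)),
            seed=seed,
            q=float(gcfg.get("q", 0.05)),
            exponent=float(gcfg.get("exponent", 1.0)),
        )
    except ValueError as e:
        raise PipelineError("gsea", str(e)) from e
    gsea_dir = out / "gsea"
    gsea_dir.mkdir(exist_ok=True)
    gsea_df.to_csv(gsea_dir / "enrichment.tsv", sep="\t", index=False)
    manifest["stages"]["gsea"] = {
        "outputs": {"enrichment": "gsea/enrichment.tsv"},
        "parameters": {
            "level": gcfg.get("level", "group"),
            "n_perm": int(gcfg.get("n_perm", 1000)),
            "q": float(gcfg.get("q", 0.05)),
            "seed": seed,
        },
        "skipped_lists": gsea_df.attrs.get("skipped_lists", []),
    }

    # --- modules ----------------------------------------------------------
    mcfg = dict(config.get("modules", {}) or {})
    method = mcfg.get("method", "wgcna")
    scaled_all = exprio.scale_per_gene(profile)
    if mcfg.get("restrict_to_lists", True):
        union = sorted({g for gl in mapped_lists for g in gl.genes})
        cluster_genes = [g for g in scaled_all.index if g in set(union)]
    else:
        cluster_genes = list(scaled_all.index)
    scaled = scaled_all.loc[cluster_genes]
    # drop genes with no regional variance (undefined correlation)
    variable = scaled.to_numpy().std(axis=1) > 0
    scaled = scaled.loc[scaled.index[variable]]
    mod_dir = out / "modules"
    mod_dir.mkdir(exist_ok=True)
    try:
        mod_params: dict[str, Any] = {"method": method}
        if method == "wgcna":
            beta_grid = mcfg.get("beta_grid", list(range(1, 13)))
            st = modules.pick_soft_threshold(
                scaled,
                beta_grid=beta_grid,
                r2_cutoff=float(mcfg.get("r2_cutoff", 0.8)),
                min_module_size=int(mcfg.get("min_module_size", 3)),
                cut_fraction=float(mcfg.get("cut_fraction", 0.99)),
            )
            adj = modules.adjacency_matrix(scaled, st.beta, signed=bool(mcfg.get("signed", False)))
            tom = modules.tom_similarity(adj)
            assignment = modules.detect_modules(
                tom,
                scaled.index,
                min_module_size=int(mcfg.get("min_module_size", 3)),
                cut_fraction=float(mcfg.get("cut_fraction", 0.99)),
            )
            mod_params.update({"beta": st.beta, "beta_criterion": st.criterion})
            st.fit_table.to_csv(mod_dir / "soft_threshold.tsv", sep="\t", index=False)
        elif method in ("hier", "kmeans"):
            k = mcfg.get("k")
            if k is None:
                elbow = modules.choose_k_elbow(
                    scaled,
                    k_range=mcfg.get("k_range", list(range(2, 13))),
                    restarts=int(mcfg.get("restarts", 25)),
                    seed=seed,
                )
                k = elbow.k
                mod_params["weak_elbow"] = elbow.weak_elbow
            k = int(k)
            if method == "hier":
                assignment = modules.hierarchical_modules(scaled, k)
            else:
                assignment = modules.kmeans_modules(
                    scaled, k, restarts=int(mcfg.get("restarts", 25)), seed=seed
                )
            mod_params["k"] = k
        else:
            raise ValueError(f"unknown module method {method!r}")
    except ValueError as e:
        raise PipelineError("modules", str(e)) from e
    assignment.to_frame().to_csv(mod_dir / "assignment.tsv", sep="\t", index=False)
    sample_tree = modules.cluster_samples(matrix)
    (mod_dir / "sample_dendrogram.nwk").write_text(sample_tree.to_newick() + "\n")
    order = modules.heatmap_gene_order(assignment, scaled)
    pd.DataFrame({"gene": order, "position": range(len(order))}).to_csv(
        mod_dir / "heatmap_order.tsv", sep="\t", index=False
    )
    manifest["stages"]["modules"] = {
        "outputs": {
            "assignment": "modules/assignment.tsv",
            "sample_dendrogram": "modules/sample_dendrogram.nwk",
            "heatmap_order": "modules/heatmap_order.tsv",
        },
        "parameters": mod_params,
        "n_modules": assignment.n_modules,
        "n_genes_clustered": len(assignment.module_of),
    }

    # --- overrep ----------------------------------------------------------
    ocfg = dict(config.get("overrep", {}) or {})
    try:
        table = overrep.overrepresentation_table(
            assignment,
            mapped_lists,
            formula=ocfg.get("formula", "paper"),
            include_unassigned=bool(ocfg.get("include_unassigned", False)),
        )
    except ValueError as e:
        raise PipelineError("overrep", str(e)) from e
    ov_dir = out / "overrep"
    ov_dir.mkdir(exist_ok=True)
    table.table.to_csv(ov_dir / "overrepresentation.tsv", sep="\t", index=False)
    manifest["stages"]["overrep"] = {
        "outputs": {"overrepresentation": "overrep/overrepresentation.tsv"},
        "parameters": {
            "formula": ocfg.get("formula", "paper"),
            "include_unassigned": bool(ocfg.get("include_unassigned", False)),
        },
        "excluded_unassigned_genes": table.excluded_unassigned,
    }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out


def _default_list_specs(cfg: synthetic.AtlasConfig) -> list[dict]:
    groups = cfg.groups
    return [
        {"name": f"list_{g}", "size": 15, "target_group": g, "strength": 1.0}
        for g in groups[: min(3, len(groups))]
    ]


def report(run_dir: str | Path, make_plots: bool = True) -> Path:
    """Summarize a (possibly partial) run into ``<run_dir>/report``.

    Emits the heatmap gene order, an enrichment target x list matrix,
    per-list frequency bars, and overrepresentation bars -- all as TSV
    (plot-backing numbers), plus PNG plots when matplotlib is usable.
    Missing stages are skipped and flagged in ``report.json``.
    """
    run = Path(run_dir)
    manifest_path = run / "manifest.json"
    if not manifest_path.exists():
        raise PipelineError("report", f"no manifest.json in {run}")
    manifest = json.loads(manifest_path.read_text())
    rep_dir = run / "report"
    rep_dir.mkdir(exist_ok=True)
    available = {}

    freq_path = run / "frequency" / "list_summaries.tsv"
    if freq_path.exists():
        summ = pd.read_csv(freq_path, sep="\t")
        summ.to_csv(rep_dir / "frequency_bars.tsv", sep="\t", index=False)
        available["frequency"] = True
        if make_plots:
            _plot_frequency(summ, rep_dir / "frequency_bars.png")

    gsea_path = run / "gsea" / "enrichment.tsv"
    if gsea_path.exists():
        enr = pd.read_csv(gsea_path, sep="\t")
        mat = enr.pivot(index="target", columns="list_name", values="es")
        mat.to_csv(rep_dir / "enrichment_matrix.tsv", sep="\t")
        flags = enr.pivot(index="target", columns="list_name", values="significant")
        flags.to_csv(rep_dir / "enrichment_flags.tsv", sep="\t")
        available["gsea"] = True

    order_path = run / "modules" / "heatmap_order.tsv"
    if order_path.exists():
        order = pd.read_csv(order_path, sep="\t")
        order.to_csv(rep_dir / "heatmap_order.tsv", sep="\t", index=False)
        available["modules"] = True

    ov_path = run / "overrep" / "overrepresentation.tsv"
    if ov_path.exists():
        ov = pd.read_csv(ov_path, sep="\t")
        ov.to_csv(rep_dir / "overrepresentation_bars.tsv", sep="\t", index=False)
        available["overrep"] = True
        if make_plots:
            _plot_overrep(ov, rep_dir / "overrepresentation_bars.png")

    payload = {
        "run": str(run),
        "stages_reported": sorted(available),
        "stages_missing": sorted(set(STAGES[1:]) - set(available)),
        "package_version": manifest.get("package_version"),
        "seed": manifest.get("seed"),
    }
    (rep_dir / "report.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
    return rep_dir


def _plot_frequency(summary: pd.DataFrame, path: Path) -> None:
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except Exception:  # pragma: no cover - plotting is best-effort
        return
    lists = summary["list_name"].unique()
    fig, axes = plt.subplots(len(lists), 1, figsize=(10, 2.2 * len(lists)), squeeze=False)
    for ax, name in zip(axes[:, 0], lists):
        sub = summary[summary["list_name"] == name]
        ax.bar(sub["region"], sub["mean"], yerr=sub["sem"], color="#4878a8")
        ax.set_ylabel("% of total TPM")
        ax.set_title(name, fontsize=9)
        ax.tick_params(axis="x", rotation=90, labelsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_overrep(table: pd.DataFrame, path: Path) -> None:
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except Exception:  # pragma: no cover
        return
    pivot = table.pivot(index="module", columns="list_name", values="score")
    ax = pivot.plot.bar(figsize=(10, 4))
    ax.axhline(0.0, color="black", lw=0.8)
    ax.set_ylabel("overrepresentation score")
    fig = ax.get_figure()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
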