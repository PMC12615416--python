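"""End-to-end orchestration of the synthetic demo pipeline.

Stages: simulate single-cell data and build the in-vivo modulation axes;
simulate bulk perturbation experiments with planted effects for a
pro-modulation, an anti-modulation and a null variant; run the bulk DE stage
and DEG calling; compute composite modulation scores per (variant, axis) with
quadrant decomposition; quantify a synthetic imaging experiment against its
ground truth; and write a combined TSV + markdown report.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Mapping

import numpy as np
import pandas as pd

from .bulk import CountMatrix, DEGCallParams, call_degs, compute_tpm, nb_wald_test, overexpression_fold, prefilter_genes
from .composite import CompositeScore, composite_score, score_all_variants, score_decomposition
from .imaging import proliferation_fraction, transduction_efficiency, wound_closure_pct, wound_series_from_images
from .sc import build_modulation_reference
from .synthetic import BulkSimSpec, ImageSimSpec, PopulationSpec, ScSimSpec, simulate_bulk, simulate_field, simulate_sc

log = logging.getLogger("modscore.pipeline")

#: demo study design: three single-cell populations spanning the modulation
#: axis, two scored axes, and three bulk variants with planted direction
DEFAULT_CONFIG: Dict = {
    "seed": 0,
    "n_cells_per_pop": 300,
    "sc_n_genes": 6000,
    "bulk_n_genes": 2000,
    "n_reps_per_group": 4,
    "planted_magnitude": 2.0,
    "overexpression_gene": "TWIST1",
    "overexpression_fold": 100.0,
    "padj_cut": 0.05,
    "lfc_cut": 1.5,
    "populations": {
        "differentiated": ["CNN1", "ACTA2", "TAGLN", "MYH11"],
        "fmc": ["DCN", "LUM", "FMOD", "OGN"],
        "cmc": ["IBSP", "TMEM119", "VCAM1", "MXRA5", "PDPN"],
    },
    "axes": {
        "all_modulated": (["fmc", "cmc"], ["differentiated"]),
        "cmc": (["cmc"], ["differentiated"]),
    },
}


def _sc_spec(config: Mapping, seed: int) -> ScSimSpec:
    pops = [
        PopulationSpec(name, list(markers))
        for name, markers in config["populations"].items()
    ]
    return ScSimSpec(
        n_cells_per_pop=config["n_cells_per_pop"],
        populations=pops,
        n_genes=config["sc_n_genes"],
        seed=seed,
    )


def build_axes(config: Mapping, seed: int):
    """Simulate the single-cell stage and build one reference per axis."""
    sc, truth = simulate_sc(_sc_spec(config, seed))
    refs = {
        axis: build_modulation_reference(sc, mod, diff)
        for axis, (mod, diff) in config["axes"].items()
    }
    return sc, truth, refs


def planted_bulk_spec(
    config: Mapping,
    ref: pd.DataFrame,
    direction: int,
    seed: int,
) -> BulkSimSpec:
    """Bulk simulation whose planted effects are aligned (+1) or anti-aligned
    (-1) with a modulation reference, on the bulk/sc shared gene universe.

    The bulk gene universe reuses the single-cell symbols (marker genes first,
    fillers after, mito excluded) so in-vitro DEGs can intersect the in-vivo
    list. Planted in-vitro log2FCs are ``direction * sign * magnitude`` on the
    reference genes present in the universe; ``direction=0`` plants nothing.
    """
    markers = [g for markers in config["populations"].values() for g in markers]
    n = config["bulk_n_genes"]
    fillers = [f"GENE{i:05d}" for i in range(n - len(markers) - 1)]
    gene_names = [config["overexpression_gene"]] + markers + fillers
    effects = {config["overexpression_gene"]: float(np.log2(config["overexpression_fold"]))}
    if direction:
        mag = config["planted_magnitude"]
        universe = set(gene_names[1:])
        for g in ref.index:
            if g in universe:
                effects[g] = direction * int(ref.loc[g, "sign"]) * mag
    return BulkSimSpec(
        n_genes=n,
        n_reps_per_group=config["n_reps_per_group"],
        planted_effects=effects,
        gene_names=gene_names,
        seed=seed,
    )


def run_bulk_stage(spec: BulkSimSpec, params: DEGCallParams) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame]:
    """simulate -> prefilter -> NB Wald -> DEG call; returns (matrix, table, degs)."""
    m, _ = simulate_bulk(spec)
    kept = prefilter_genes(m)
    table = nb_wald_test(m.subset_genes(kept))
    return m, table, call_degs(table, params)


def validate_overexpression(
    m: CountMatrix, gene: str
) -> pd.DataFrame:
    """Mean control TPM and treated-over-control fold for the target gene."""
    tpm = compute_tpm(m)
    if gene not in tpm.index:
        raise KeyError(f"target gene {gene!r} absent from count matrix")
    ctrl = m.samples("control")
    return pd.DataFrame(
        {
            "gene": [gene],
            "control_mean_tpm": [float(tpm.loc[gene, ctrl].mean())],
            "fold_increase": [overexpression_fold(tpm, m.condition, gene)],
        }
    )


def direction_recovery_trial(
    seed: int,
    n_cells_per_pop: int = 300,
    sc_n_genes: int = 2000,
    bulk_n_genes: int = 2000,
) -> bool:
    """One seeded end-to-end run: does the composite score recover direction?

    Simulates the single-cell stage and builds the all-modulated axis, then
    simulates one pro-modulation and one anti-modulation bulk variant with
    planted effects aligned / anti-aligned with the axis, runs the full DE +
    DEG + composite stages, and reports whether both recovered signs are
    correct (pro > 0 and anti < 0).
    """
    cfg = dict(
        DEFAULT_CONFIG,
        n_cells_per_pop=n_cells_per_pop,
        sc_n_genes=sc_n_genes,
        bulk_n_genes=bulk_n_genes,
        axes={"all_modulated": (["fmc", "cmc"], ["differentiated"])},
    )
    _, _, refs = build_axes(cfg, seed)
    ref = refs["all_modulated"]
    params = DEGCallParams(cfg["padj_cut"], cfg["lfc_cut"])
    _, _, degs_pro = run_bulk_stage(planted_bulk_spec(cfg, ref, 1, seed + 10), params)
    _, _, degs_anti = run_bulk_stage(planted_bulk_spec(cfg, ref, -1, seed + 11), params)
    s_pro = composite_score(degs_pro, ref).total
    s_anti = composite_score(degs_anti, ref).total
    return s_pro > 0 and s_anti < 0


def run_demo(config: Mapping, outdir: str | Path) -> str:
    """Run the full synthetic pipeline; returns the markdown report text."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    params = DEGCallParams(config["padj_cut"], config["lfc_cut"])

    log.info("stage sc: simulating populations and building modulation axes")
    sc, sc_truth, refs = build_axes(config, seed)
    for axis, ref in refs.items():
        ref.to_csv(outdir / f"reference_{axis}.tsv", sep="\t", index_label="gene")

    log.info("stage bulk: simulating and testing planted variants")
    directions = {"pro_modulation": 1, "anti_modulation": -1, "null_variant": 0}
    deg_lists, deg_counts, oe_rows = {}, {}, []
    for i, (variant, direction) in enumerate(directions.items()):
        spec = planted_bulk_spec(config, refs["all_modulated"], direction, seed + 10 + i)
        m, table, degs = run_bulk_stage(spec, params)
        table.to_csv(outdir / f"de_table_{variant}.tsv", sep="\t", index_label="gene")
        degs.to_csv(outdir / f"degs_{variant}.tsv", sep="\t", index_label="gene")
        deg_lists[variant] = degs
        deg_counts[variant] = (
            len(degs), int((degs.direction > 0).sum()), int((degs.direction < 0).sum())
        )
        oe = validate_overexpression(m, config["overexpression_gene"])
        oe.insert(0, "variant", variant)
        oe_rows.append(oe)

    log.info("stage composite: scoring variants against axes")
    totals, details = score_all_variants(deg_lists, refs)
    totals.to_csv(outdir / "composite_scores.tsv", sep="\t", index_label="variant")
    quad_rows = []
    for (v, axis), cs in details.items():
        q = score_decomposition(cs)
        q.insert(0, "axis", axis)
        q.insert(0, "variant", v)
        quad_rows.append(q.reset_index(names="quadrant"))
    quadrants = pd.concat(quad_rows, ignore_index=True)
    quadrants.to_csv(outdir / "quadrants.tsv", sep="\t", index=False)

    log.info("stage imaging: quantifying synthetic field vs truth")
    img_spec = ImageSimSpec(seed=seed + 20)
    sim = simulate_field(img_spec)
    h, w = img_spec.field_shape
    areas = wound_series_from_images(sim.wound_images, (h / 2, w / 2, img_spec.wound_radius_series[0]))
    imaging = pd.DataFrame(
        {
            "metric": [
                "transduction_efficiency_pct",
                "proliferation_transduced_pct",
                "proliferation_untransduced_pct",
                "wound_closure_pct_t4h",
            ],
            "measured": [
                transduction_efficiency(sim.field),
                proliferation_fraction(sim.field, "transduced"),
                proliferation_fraction(sim.field, "untransduced"),
                wound_closure_pct(areas.to_dict(), 4.0),
            ],
            "truth": [
                100.0 * sim.nuclei.transduced.mean(),
                100.0 * sim.nuclei.edu[sim.nuclei.transduced].mean(),
                100.0 * (sim.nuclei.edu & ~sim.nuclei.transduced).sum() / len(sim.nuclei),
                wound_closure_pct(dict(zip(sim.wound_truth.timepoint_h, sim.wound_truth.area_px)), 4.0),
            ],
        }
    )
    imaging.to_csv(outdir / "image_quant.tsv", sep="\t", index=False)
    oe_table = pd.concat(oe_rows, ignore_index=True)
    oe_table.to_csv(outdir / "overexpression.tsv", sep="\t", index=False)

    lines = [
        "# modscore synthetic demo report",
        "",
        f"seed: {seed}",
        "",
        "## Overexpression validation (TPM)",
        oe_table.to_markdown(index=False, floatfmt=".2f"),
        "",
        "## DEG counts per variant (padj < "
        f"{params.padj_cut}, |log2FC| > {params.lfc_cut})",
        "",
        "| variant | n DEGs | up | down |",
        "|---|---|---|---|",
    ]
    for v, (n, up, down) in deg_counts.items():
        lines.append(f"| {v} | {n} | {up} | {down} |")
    lines += [
        "",
        "## Composite modulation scores (positive = toward modulated phenotype)",
        totals.to_markdown(floatfmt=".2f"),
        "",
        "## Quadrant decomposition",
        quadrants.to_markdown(index=False, floatfmt=".2f"),
        "",
        "## Image quantification vs ground truth",
        imaging.to_markdown(index=False, floatfmt=".2f"),
        "",
    ]
    report = "\n".join(lines)
    (outdir / "report.md").write_text(report)
    log.info("report written to %s", outdir / "report.md")
    return report
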