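"""End-to-end quantification pipeline.

``analyze_micrograph`` runs the per-image chain (segment → partition →
cortical metrics → radial tip search → registration) and is the unit both
the CLI and the batch runner build on.  ``run_pipeline`` executes a full
simulated study (conditions × experiments × cells), writing the per-cell
CSV, tip table, summary JSON, comparison CSV and a run manifest.

Reproducibility contract: the single config seed feeds a hierarchical
seed sequence (per condition, experiment and cell), so results are
identical regardless of execution order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig, config_hash
from .cortical import cortex_cyto_ratio, cortical_asymmetry
from .filopodia import (
    TipSearchConfig,
    estimate_background,
    radial_tip_search,
    register_tips_to_cells,
)
from .groupstats import build_summary_table, one_way_anova
from .imgio import Micrograph, max_project, write_results
from .segment import SegmentationConfig, partition_cortex, segment_cells
from .simulate import SceneParams, make_cell_scene

logger = logging.getLogger("cortifilo")

__all__ = ["CellResult", "analyze_micrograph", "run_pipeline"]


@dataclass
class CellResult:
    field_id: str
    cell_id: int
    experiment_id: str
    cortex_cyto_ratio: float | None
    cortical_sd: float | None
    filopodia_count: int | None
    qc_flags: str
    tips: list = field(default_factory=list)


def analyze_micrograph(
    img: Micrograph,
    field_id: str = "field0",
    experiment_id: str = "exp0",
    seg_config: SegmentationConfig | None = None,
    tip_config: TipSearchConfig | None = None,
    band_width_um: float = 0.8,
    n_bins: int = 360,
    normalized_sd: bool = False,
) -> list[CellResult]:
    """Quantify every analyzable cell in one projected micrograph."""
    seg_config = seg_config or SegmentationConfig()
    tip_config = tip_config or TipSearchConfig()
    cells = segment_cells(img, seg_config)
    if not cells:
        return []
    background = estimate_background(img, [c.filled_mask for c in cells])
    results: list[CellResult] = []
    all_tips = []
    for cell in cells:
        part = partition_cortex(cell, band_width_um=band_width_um)
        ratio = None
        sd = None
        if "unmeasurable" in part.flags:
            cell.flags.add("unmeasurable")
        else:
            ratio = cortex_cyto_ratio(img, part)
            sd, _ = cortical_asymmetry(
                img, part, cell, n_bins=n_bins, normalized=normalized_sd
            )
        tips = radial_tip_search(img, cell, tip_config, background=background)
        all_tips.extend(tips)
        results.append(
            CellResult(
                field_id=field_id,
                cell_id=cell.cell_id,
                experiment_id=experiment_id,
                cortex_cyto_ratio=ratio,
                cortical_sd=sd,
                filopodia_count=None,  # filled after registration
                qc_flags=";".join(sorted(cell.flags)),
                tips=[],
            )
        )
    registered = register_tips_to_cells(all_tips, cells, tip_config.max_length_um)
    by_cell: dict[int, list] = {}
    for t in registered:
        by_cell.setdefault(t.cell_id, []).append(t)
    for res in results:
        res.tips = by_cell.get(res.cell_id, [])
        res.filopodia_count = len(res.tips)
    return results


def run_pipeline(config: PipelineConfig) -> Path:
    """Run a full simulated study and write all artifacts to output_dir."""
    if config.simulate is None:
        raise ValueError("run_pipeline currently requires a simulation spec")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    records = []
    tip_rows = []
    for ci, cond in enumerate(config.simulate.conditions):
        per_exp = int(np.ceil(cond.n_cells / cond.n_experiments))
        cell_counter = 0
        for ei in range(cond.n_experiments):
            for k in range(per_exp):
                if cell_counter >= cond.n_cells:
                    break
                cell_counter += 1
                # hierarchical, order-independent seeding
                sub = int(
                    np.random.SeedSequence(
                        [config.seed, ci, ei, k]
                    ).generate_state(1)[0] % (2**31)
                )
                params = SceneParams(**{**cond.params, "seed": sub})
                stack, _truth = make_cell_scene(params)
                img = max_project(stack)
                field_id = f"{cond.name}_e{ei}_c{k}"
                res = analyze_micrograph(
                    img,
                    field_id=field_id,
                    experiment_id=f"{cond.name}_exp{ei}",
                    seg_config=config.segmentation,
                    tip_config=config.tips,
                    band_width_um=config.cortical.band_width_um,
                    n_bins=config.cortical.n_bins,
                    normalized_sd=config.cortical.normalized_sd,
                )
                for r in res:
                    records.append(
                        {
                            "field_id": r.field_id,
                            "cell_id": r.cell_id,
                            "experiment_id": r.experiment_id,
                            "group": cond.name,
                            "cortex_cyto_ratio": r.cortex_cyto_ratio,
                            "cortical_sd": r.cortical_sd,
                            "filopodia_count": r.filopodia_count,
                            "qc_flags": r.qc_flags,
                        }
                    )
                    for t in r.tips:
                        tip_rows.append(
                            {
                                "field_id": r.field_id,
                                "cell_id": t.cell_id,
                                "tip_row": t.position[0],
                                "tip_col": t.position[1],
                                "angle_deg": np.rad2deg(t.angle),
                                "distance_um": t.distance_um,
                                "peak_intensity": t.peak_intensity,
                            }
                        )
        logger.info("condition %s: %d cells analyzed", cond.name, cell_counter)

    chash = config_hash(config)
    df = pd.DataFrame(records)
    write_results(
        df,
        out / "per_cell.csv",
        summary_path=out / "run_summary.json",
        config_hash=chash,
    )
    pd.DataFrame(
        tip_rows,
        columns=[
            "field_id",
            "cell_id",
            "tip_row",
            "tip_col",
            "angle_deg",
            "distance_um",
            "peak_intensity",
        ],
    ).to_csv(out / "tips.csv", index=False)

    summary = build_summary_table(df, group_col="group", rout=config.stats.rout)
    summary.to_json(out / "summary.json", orient="records", indent=2)

    groups = {
        g: sub["cortex_cyto_ratio"].dropna().to_numpy()
        for g, sub in df.groupby("group")
    }
    comparisons = None
    if len(groups) >= 2 and all(v.size >= 2 for v in groups.values()):
        table = one_way_anova(
            groups, posthoc=config.stats.posthoc, control=config.stats.control
        )
        comparisons = table.pairwise
        header = pd.DataFrame(
            [
                {
                    "test": table.test,
                    "statistic": table.statistic,
                    "df_between": table.df[0],
                    "df_within": table.df[1],
                    "p_value": table.p_value,
                }
            ]
        )
        header.to_csv(out / "anova.csv", index=False)
        if comparisons is not None:
            comparisons.to_csv(out / "comparisons.csv", index=False)

    manifest = {
        "config_hash": chash,
        "seed": config.seed,
        "version": __version__,
        "n_cells_total": int(len(df)),
        "conditions": {
            cond.name: int((df["group"] == cond.name).sum())
            for cond in config.simulate.conditions
        },
        "config": config.model_dump(mode="json"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
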