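"""End-to-end pipeline: inputs -> availability -> caloric -> features -> prediction.

Driven by a single YAML-able configuration with either an ``inputs``
block (paths to the five CSV tables) or a ``generate`` block (synthetic
world parameters). All artifacts are CSV plus a ``manifest.json``
recording the configuration hash, seeds, package versions and row
counts, so a rerun with the same configuration reproduces identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__, availability as avail_mod, caloric, features, io, predict
from .records import DEFAULT_REGIONS, CategoryRegistry
from .synthetic import CategorySpec, WorldConfig, default_config, generate_world

log = logging.getLogger(__name__)

__all__ = ["PipelineError", "run_pipeline", "world_config_from_dict"]


class PipelineError(RuntimeError):
    """Pipeline failure with a shell exit code."""

    def __init__(self, message: str, exit_code: int = 1):
        super().__init__(message)
        self.exit_code = exit_code


def world_config_from_dict(block: dict) -> WorldConfig:
    """Build a :class:`WorldConfig` from a YAML ``generate`` block."""
    block = dict(block)
    if "categories" in block:
        block["categories"] = tuple(
            CategorySpec(c["label"], float(c["true_density"]),
                         float(c.get("obesogenic_weight", 0.0)))
            for c in block["categories"]
        )
    for key in ("n_categories_probs", "price_tier_probs", "regions"):
        if key in block and block[key] is not None:
            block[key] = tuple(block[key])
    seed = int(block.pop("seed", 0))
    return default_config(seed=seed, **block)


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(canon).hexdigest()[:16]


def _load_inputs(paths: dict, regions) -> dict:
    for key in ("businesses", "nutrition", "popular_dishes", "obesity"):
        if key not in paths:
            raise PipelineError(f"inputs block is missing {key!r}", exit_code=2)
        if not Path(paths[key]).exists():
            raise PipelineError(
                f"input file not found: {paths[key]} ({key})", exit_code=2
            )
    registry: Optional[CategoryRegistry] = None
    if paths.get("category_registry"):
        if not Path(paths["category_registry"]).exists():
            raise PipelineError(
                f"input file not found: {paths['category_registry']} "
                "(category_registry)", exit_code=2,
            )
        registry = io.read_category_registry(paths["category_registry"])
    return {
        "businesses": io.read_businesses(paths["businesses"], registry, regions),
        "nutrition": io.read_nutrition(paths["nutrition"]),
        "popular_dishes": io.read_popular_dishes(paths["popular_dishes"]),
        "obesity": io.read_obesity(paths["obesity"]),
    }


def run_pipeline(config: dict, out_dir: str | Path) -> Path:
    """Run every stage and write artifacts under ``out_dir``.

    Returns the artifact directory. On stage failure a FAILED marker
    naming the stage is left next to any partial outputs and the error
    is re-raised.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "configure"
    try:
        regions = tuple(config.get("regions") or DEFAULT_REGIONS)
        analysis = config.get("analysis", {})
        seed = int(analysis.get("seed", config.get("generate", {}).get("seed", 0)))

        stage = "inputs"
        if "generate" in config and config.get("inputs"):
            raise PipelineError("give either 'inputs' or 'generate', not both", 2)
        if "generate" in config:
            wc = world_config_from_dict(config["generate"] or {})
            world = generate_world(wc)
            data = {
                "businesses": world.businesses,
                "nutrition": world.nutrition,
                "popular_dishes": world.popular_dishes,
                "obesity": world.obesity,
            }
            regions = world.config.region_codes()
            inp = out / "inputs"
            inp.mkdir(exist_ok=True)
            io.write_businesses(world.businesses, inp / "businesses.csv")
            io.write_nutrition(world.nutrition, inp / "nutrition.csv")
            io.write_popular_dishes(world.popular_dishes, inp / "popular_dishes.csv")
            io.write_obesity(world.obesity, inp / "obesity.csv")
            io.write_category_registry(world.registry, inp / "category_registry.csv")
            world.truth.to_csv(inp / "truth.csv")
        elif "inputs" in config:
            data = _load_inputs(config["inputs"], regions)
        else:
            raise PipelineError("config needs an 'inputs' or 'generate' block", 2)

        stage = "availability"
        table = avail_mod.compute_availability(data["businesses"])
        table.proportions().to_csv(out / "availability.csv")

        # compare the regions with the highest and lowest obesity rates
        rates = data["obesity"].rates
        pair = analysis.get("compare_regions")
        if pair is None:
            in_table = [r for r in table.regions if r in rates]
            if len(in_table) >= 2:
                pair = (max(in_table, key=rates.get), min(in_table, key=rates.get))
        if pair is not None:
            a, b = pair
            comps = avail_mod.rank_net_differences(
                table, a, b,
                benjamini_hochberg=bool(analysis.get("benjamini_hochberg", False)),
            )
            avail_mod.comparisons_to_frame(comps).to_csv(
                out / f"comparisons_{a}_vs_{b}.csv", index=False
            )

        stage = "caloric"
        registry = caloric.build_density_registry(
            data["nutrition"], data["popular_dishes"],
            max_density=analysis.get("max_dish_density"),
        )
        registry.dish.rename_axis("dish").to_csv(out / "dish_density.csv")
        registry.category.rename_axis("category").to_csv(out / "category_density.csv")
        scores = caloric.state_scores(table, registry)
        scores.to_series().rename_axis("region").to_csv(out / "state_scores.csv")
        score_r, score_p = caloric.score_obesity_correlation(scores, data["obesity"])

        stage = "features"
        sets = tuple(analysis.get("feature_sets", features.FEATURE_SETS))
        matrix = features.build_features(
            data["businesses"], table, scores, sets=sets, obesity=data["obesity"]
        )
        matrix.to_frame().rename_axis("region").to_csv(out / "features.csv")
        pd.DataFrame(
            {"feature": matrix.feature_names, "set": matrix.set_tags}
        ).to_csv(out / "feature_meta.csv", index=False)

        stage = "predict"
        families = tuple(analysis.get("families", predict.MODEL_FAMILIES))
        combos = analysis.get("set_combinations")
        combos = (
            tuple(tuple(c) for c in combos)
            if combos
            else tuple(c for c in predict.DEFAULT_SET_COMBINATIONS
                       if set(c) <= set(sets))
        )
        grid = predict.evaluate_grid(
            matrix, data["obesity"], families=families,
            set_combinations=combos, seed=seed,
        )
        grid.rename_axis("feature_sets").to_csv(out / "grid.csv")
        best_combo = grid.index[(grid["best"] != "").to_numpy()][0]
        best_family = grid.loc[best_combo, "best"]
        best = predict.loocv_predict(
            matrix.select_sets(tuple(best_combo.split("+"))),
            data["obesity"],
            predict.ModelSpec(best_family, seed=seed),
        )
        best.to_frame().to_csv(out / "predictions.csv", index=False)

        stage = "report"
        report = [
            "# Food-environment pipeline report",
            "",
            f"- businesses: {len(data['businesses'])}",
            f"- nutrition records: {len(data['nutrition'])}",
            f"- regions analysed: {len(matrix.regions)}",
            f"- zero-filled per-category cells: "
            f"{matrix.n_zero_filled}/{matrix.n_per_category_cells} "
            f"({100 * features.zero_fill_fraction(matrix):.1f}%)",
            f"- weighted score vs obesity: r = {score_r:.3f} (p = {score_p:.2g})",
            f"- best LOOCV model: {best_family} on [{best_combo}], "
            f"r = {best.pearson_r:.3f}",
            "",
            "actual vs predicted (held-out) per region:",
            "",
            best.to_frame().to_csv(index=False),
        ]
        (out / "report.md").write_text("\n".join(report))

        stage = "manifest"
        manifest = {
            "foodenv_version": __version__,
            "config_hash": _config_hash(config),
            "seed": seed,
            "n_businesses": len(data["businesses"]),
            "n_nutrition_records": len(data["nutrition"]),
            "n_regions": len(matrix.regions),
            "n_features": len(matrix.feature_names),
            "zero_fill_fraction": features.zero_fill_fraction(matrix),
            "score_obesity_r": score_r,
            "best_model": {"family": best_family, "sets": best_combo,
                           "pearson_r": best.pearson_r},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise
    return out
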