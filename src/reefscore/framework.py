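"""End-to-end orchestration: checklist -> index comparison -> stability.

:func:`run_framework` executes the three framework stages in order on a
reference design plus candidate designs, writing every artefact (JSON
checklists, comparison tables, stability reports, the three-axis figure)
to a run directory together with a machine-readable ``manifest.json`` and
a log.  Machine-readable outputs are byte-identical across repeated runs
with the same inputs and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
import yaml

from .areit import FactorSet, RoundingMode, areit_index
from .checklist import meem_checklist
from .compare import ComparisonSet, compare_designs
from .design import ARUnitDesign
from .errors import ReefscoreError
from .io import read_design
from .plotting import plot_index_planes
from .stability import (
    ForceCoefficients,
    WaveConditions,
    design_wave,
    size_slab,
    stability_check,
)

logger = logging.getLogger("reefscore")

DEFAULT_SEA_STATE = {
    "hs": 5.5,
    "tp": 16.1,
    "depth": 12.0,
    "n_waves": 1000,
    "current": 0.08,
}


@dataclass
class FrameworkConfig:
    """Run configuration (parsed from YAML)."""

    factors: FactorSet = field(default_factory=FactorSet)
    rounding: RoundingMode = "paper"
    sea_state: dict = field(default_factory=lambda: dict(DEFAULT_SEA_STATE))
    coefficients: ForceCoefficients = field(default_factory=ForceCoefficients)
    gamma: float = 0.78
    ursell_threshold: float = 26.0
    target_sliding: float = 1.2
    target_overturning: float = 1.2
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path | None) -> "FrameworkConfig":
        if path is None:
            return cls()
        payload = yaml.safe_load(Path(path).read_text()) or {}
        factors_kw = payload.get("factors", {})
        if "weights" in payload:
            factors_kw["weights"] = tuple(payload["weights"])
        elif "weights" in factors_kw:
            factors_kw["weights"] = tuple(factors_kw["weights"])
        return cls(
            factors=FactorSet(**factors_kw),
            rounding=payload.get("rounding", "paper"),
            sea_state={**DEFAULT_SEA_STATE, **payload.get("sea_state", {})},
            coefficients=ForceCoefficients(**payload.get("coefficients", {})),
            gamma=payload.get("gamma", 0.78),
            ursell_threshold=payload.get("ursell_threshold", 26.0),
            target_sliding=payload.get("target_sliding", 1.2),
            target_overturning=payload.get("target_overturning", 1.2),
            seed=payload.get("seed", 0),
        )


@dataclass
class FrameworkBundle:
    """Everything a run produced, plus where it was written."""

    out_dir: Path
    checklists: dict[str, list]
    comparison: ComparisonSet
    stability: dict[str, dict]
    manifest: dict


def _json_default(obj):
    import numpy as np

    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _write_json(path: Path, payload) -> None:
    path.write_text(
        json.dumps(payload, indent=2, sort_keys=True, default=_json_default) + "\n"
    )


def run_framework(
    reference_path: str | Path,
    candidate_paths: list[str | Path],
    out_dir: str | Path,
    config_path: str | Path | None = None,
    stability_all: bool = False,
    make_plot: bool = True,
) -> FrameworkBundle:
    """Run checklist, comparison and stability stages on design files.

    Stability runs on the top-ranked candidate only unless
    ``stability_all``.  Stage failures abort with the stage named; partial
    outputs already written are retained.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    config = FrameworkConfig.from_yaml(config_path)
    manifest: dict = {"stages": {}, "seed": config.seed, "outputs": []}

    try:
        # stage 0: load and validate everything up front (fail fast)
        reference = read_design(reference_path)
        candidates = [read_design(p) for p in candidate_paths]
        if not candidates:
            raise ReefscoreError("no candidate designs supplied")
        designs: list[ARUnitDesign] = [reference, *candidates]
        logger.info(
            "loaded %d designs (reference %s)", len(designs), reference.name
        )

        # stage 1: ecological checklist
        checklists = {}
        for d in designs:
            findings = meem_checklist(d)
            checklists[d.name] = findings
            path = out / f"checklist_{d.name}.json"
            _write_json(path, [f.to_dict() for f in findings])
            manifest["outputs"].append(path.name)
        manifest["stages"]["checklist"] = sorted(checklists)
        logger.info("checklist stage complete (%d designs)", len(designs))

        # stage 2: index comparison
        comparison = compare_designs(reference, candidates, config.factors)
        _write_json(out / "comparison.json", comparison.to_dict())
        comparison.to_frame().to_csv(out / "comparison.csv", index=False)
        manifest["outputs"] += ["comparison.json", "comparison.csv"]
        comparison_block = comparison.to_dict()
        # reporting view with the configured (default two-decimal) rounding
        comparison_block["display"] = {
            c.name: areit_index(
                c, reference, config.factors, rounding=config.rounding
            ).to_dict()
            for c in candidates
        }
        manifest["stages"]["comparison"] = comparison_block
        logger.info(
            "comparison stage complete; top candidate %s (AREIT %.4f)",
            comparison.ranking[0],
            comparison.top().areit,
        )
        if make_plot and all(w > 0 for w in config.factors.weights):
            plot_path = out / "index_planes.png"
            plot_index_planes(comparison, plot_path)
            manifest["outputs"].append(plot_path.name)
        elif make_plot:
            logger.info(
                "three-axis plot skipped: it needs all three partial indices"
            )

        # stage 3: stability of the selected design(s)
        conditions = WaveConditions(**config.sea_state)
        wave = design_wave(conditions, config.gamma, config.ursell_threshold)
        selected = (
            list(comparison.ranking) if stability_all else [comparison.ranking[0]]
        )
        by_name = {d.name: d for d in designs}
        stability_out: dict[str, dict] = {}
        for name in selected:
            design = by_name[name]
            try:
                slab = size_slab(
                    design,
                    wave,
                    conditions,
                    config.coefficients,
                    target_sliding=config.target_sliding,
                    target_overturning=config.target_overturning,
                )
            except ReefscoreError as exc:
                logger.warning("slab sizing failed for %s: %s", name, exc)
                slab = None
            checked = design.model_copy(
                update={"slab_height": slab if slab is not None else design.slab_height}
            )
            report = stability_check(checked, wave, conditions, config.coefficients)
            payload = report.to_dict()
            payload["required_slab_height_m"] = slab
            stability_out[name] = payload
            path = out / f"stability_{name}.json"
            _write_json(path, payload)
            manifest["outputs"].append(path.name)
        manifest["stages"]["stability"] = sorted(stability_out)
        logger.info("stability stage complete (%d designs)", len(selected))

        _write_json(out / "manifest.json", manifest)
        manifest["outputs"].append("manifest.json")
        return FrameworkBundle(
            out_dir=out,
            checklists=checklists,
            comparison=comparison,
            stability=stability_out,
            manifest=manifest,
        )
    except Exception as exc:
        stage = manifest["stages"]
        done = ", ".join(stage) if stage else "none"
        logger.error("run aborted (stages completed: %s): %s", done, exc)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
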