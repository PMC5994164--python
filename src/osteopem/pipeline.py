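"""End-to-end study workflow.

One call runs the full analysis the way the original study does: read the
time tree and trait table, round branch lengths to integer Ma, build the
PEM on the analysis tree, fit and AICc-select the regression, leave-one-out
cross-validate it, predict every fossil target with 95% intervals, and
reconstruct ancestral states over the complete (measured + predicted)
sample set.  Outputs are plain-text reports; identical inputs produce
byte-identical reports.
"""

from __future__ import annotations

import io
import json
import logging
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import ancestral as anc_mod
from . import model as model_mod
from .model import TraitTable
from .trees import PhyloTree

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_INPUT_ERROR = 2
EXIT_NUMERICAL_ERROR = 3


class InputValidationError(ValueError):
    """Input files inconsistent (missing species, bad roles, unreadable files)."""


class NumericalError(RuntimeError):
    """The model could not be fit or validated on otherwise valid inputs."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run (also parsable from ``key = value`` text)."""

    tree_path: str
    traits_path: str
    output_dir: str
    response_label: str = "response"
    response_units: str = ""
    steepness: str = "grid"  # "grid" or a number as text
    selection: str = "forward"  # forward | all | none
    interval: str = "prediction"  # prediction | confidence
    round_branches: bool = True
    run_loocv: bool = True
    seed: int = 0

    def steepness_value(self) -> float | str:
        if self.steepness == "grid":
            return "grid"
        return float(self.steepness)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Parse a plain ``key = value`` config file (# starts a comment)."""
        values: dict[str, str] = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise InputValidationError(f"bad config line: {raw!r}")
            key, val = (part.strip() for part in line.split("=", 1))
            values[key] = val
        kwargs: dict = {}
        for fld, caster in (
            ("tree_path", str),
            ("traits_path", str),
            ("output_dir", str),
            ("response_label", str),
            ("response_units", str),
            ("steepness", str),
            ("selection", str),
            ("interval", str),
            ("round_branches", lambda v: v.lower() in ("1", "true", "yes")),
            ("run_loocv", lambda v: v.lower() in ("1", "true", "yes")),
            ("seed", int),
        ):
            if fld in values:
                kwargs[fld] = caster(values.pop(fld))
        if values:
            raise InputValidationError(f"unknown config keys: {sorted(values)}")
        for required in ("tree_path", "traits_path", "output_dir"):
            if required not in kwargs:
                raise InputValidationError(f"config missing required key {required!r}")
        return cls(**kwargs)


@dataclass
class RunReport:
    """In-memory result bundle of one pipeline run."""

    fit: model_mod.ModelFit
    predictions: list[model_mod.PredictionResult]
    loocv: model_mod.LoocvResult | None
    node_table: pd.DataFrame
    edge_table: pd.DataFrame
    log_text: str
    output_dir: Path


def _validate_inputs(tree: PhyloTree, table: TraitTable) -> None:
    tips = set(tree.tip_labels())
    species = set(table.data["species"])
    problems = []
    for lab in sorted(species - tips):
        problems.append(f"species {lab!r} in trait table but not in tree")
    for lab in sorted(tips - species):
        problems.append(f"tip {lab!r} in tree but not in trait table")
    if problems:
        raise InputValidationError("; ".join(problems))


def report_ordering(predictions: list[model_mod.PredictionResult]) -> pd.DataFrame:
    """Species ranked by point estimate (ascending); ties broken alphabetically."""
    if len(predictions) < 2:
        raise ValueError("ranking needs at least 2 predictions")
    df = pd.DataFrame(
        [{"species": p.species, "point": p.point} for p in predictions]
    ).sort_values(["point", "species"], kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def _json_dump(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_analysis(config: RunConfig) -> RunReport:
    """Execute the full workflow and write the report bundle to ``output_dir``."""
    log_stream = io.StringIO()
    handler = logging.StreamHandler(log_stream)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root_logger = logging.getLogger("osteopem")
    root_logger.addHandler(handler)
    root_logger.setLevel(logging.INFO)
    log = logging.getLogger("osteopem.pipeline")
    try:
        for path_attr in ("tree_path", "traits_path"):
            p = Path(getattr(config, path_attr))
            if not p.exists():
                raise InputValidationError(f"{path_attr} does not exist: {p}")
        try:
            tree = PhyloTree.read(config.tree_path)
        except ValueError as exc:
            raise InputValidationError(f"tree file: {exc}") from exc
        try:
            table = TraitTable.from_csv(config.traits_path)
        except (ValueError, KeyError) as exc:
            raise InputValidationError(f"trait table: {exc}") from exc
        log.info("config: %s", json.dumps(asdict(config), sort_keys=True))
        log.info(
            "tree: %d tips; traits: %d training, %d target",
            tree.n_tips(),
            len(table.training),
            len(table.targets),
        )
        if config.round_branches:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                tree = tree.round_branch_lengths()
            for w in caught:
                log.warning("%s", w.message)
        _validate_inputs(tree, table)

        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)

        try:
            fit, scores = model_mod.fit_trait_model(
                tree,
                table,
                steepness=config.steepness_value(),
                selection=config.selection,
            )
        except (ValueError, np.linalg.LinAlgError) as exc:
            raise NumericalError(f"model fit failed: {exc}") from exc
        log.info(
            "selected steepness a=%.2f, eigenvectors %s, AICc=%.6f",
            fit.a,
            list(fit.selected),
            fit.aicc,
        )

        predictions = model_mod.predict_targets(
            fit, scores, table, interval=config.interval
        )
        for pred in predictions:
            log.info(
                "predicted %s: %.6g [%.6g, %.6g] %s",
                pred.species,
                pred.point,
                pred.lower,
                pred.upper,
                config.response_units,
            )

        loocv_result = None
        if config.run_loocv:
            try:
                loocv_result = model_mod.loocv(
                    tree,
                    table,
                    steepness=config.steepness_value(),
                    selection=config.selection,
                    interval=config.interval,
                )
            except ValueError as exc:
                raise NumericalError(f"LOOCV failed: {exc}") from exc
            log.info(
                "LOOCV: PRESS=%.6g over %d folds",
                loocv_result.press,
                loocv_result.n_folds_completed,
            )
            for lab in loocv_result.failed_folds:
                log.warning("LOOCV fold failed for %s", lab)

        # ancestral states over the complete sample set: observed responses for
        # training tips, model predictions for targets, all on the log10 scale
        log_table = model_mod.log_transform(table)
        tip_values = dict(
            zip(log_table.training["species"], log_table.training["response"])
        )
        tip_values.update({p.species: p.log_point for p in predictions})
        states = anc_mod.bm_ancestral_states(tree, tip_values)
        node_table, edge_table = anc_mod.export_tree_map(tree, states)
        log.info("ancestral reconstruction: sigma2_BM=%.6g per Ma", states.sigma2)

        # ---- write the bundle
        _json_dump(
            {
                "response_label": config.response_label,
                "response_units": config.response_units,
                "model": fit.report(),
                "loocv_press": None if loocv_result is None else loocv_result.press,
                "predictions": [p.as_dict() for p in predictions],
            },
            outdir / "fit.json",
        )
        pred_df = pd.DataFrame([p.as_dict() for p in predictions])
        pred_df.to_csv(outdir / "predictions.csv", index=False, float_format="%.12g")
        if len(predictions) >= 2:
            report_ordering(predictions).to_csv(
                outdir / "ranking.csv", index=False, float_format="%.12g"
            )
        if loocv_result is not None:
            loocv_result.table.to_csv(
                outdir / "loocv.csv", index=False, float_format="%.12g"
            )
        node_table.to_csv(outdir / "ancestral_nodes.csv", index=False, float_format="%.12g")
        edge_table.to_csv(outdir / "ancestral_edges.csv", index=False, float_format="%.12g")
        log_text = log_stream.getvalue()
        (outdir / "run.log").write_text(log_text)
        return RunReport(
            fit=fit,
            predictions=predictions,
            loocv=loocv_result,
            node_table=node_table,
            edge_table=edge_table,
            log_text=log_text,
            output_dir=outdir,
        )
    finally:
        root_logger.removeHandler(handler)
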