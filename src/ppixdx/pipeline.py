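"""End-to-end orchestration: cohort → scores → calibration → report.

``run_pipeline`` takes a single :class:`RunConfig`, obtains a cohort (either
generated on the fly or loaded from a cohort directory), scores every node
with the requested unmixing methods, calibrates a cutoff per method on the
full score table (the calibrate-on-the-large-cohort pattern), classifies an
evaluation subset, and assembles a :class:`DiagnosticReport`.  Runs are
deterministic given the seed, and every output (scores CSV, report JSON,
resolved config, log) is written next to the others so a run is fully
reproducible from its output directory.

External scores (e.g. a human stereoscopic reading of the same nodes) can be
passed through untouched as an additional "method".
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .bands import METASTATIC, NodeRecord
from .cohort import CohortConfig, iter_cohort
from .diagnostics import (
    ConfusionMatrix,
    auc_ci_bootstrap,
    calibrate,
    classify,
    mann_whitney,
    metrics,
)
from .differential import differential_score
from .exceptions import DataError, PipelineError, ValidationError
from .io import iter_cohort_dir, write_cohort
from .ratio import DEFAULT_FLUENCE, DEFAULT_MARGIN_MM, ratio_score

logger = logging.getLogger("ppixdx")

METHODS = ("differential", "ratio")


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    cohort: CohortConfig | None = None  #: generate mode
    cohort_dir: str | None = None  #: load mode (directory written by write_cohort)
    methods: tuple[str, ...] = METHODS
    cutoff_rule: str = "youden"
    margin: float = DEFAULT_MARGIN_MM
    epsilon: float | None = None
    required_fluence: float = DEFAULT_FLUENCE
    smooth: bool = True
    eval_fraction: float = 1.0
    eval_node_ids: tuple[str, ...] | None = None
    external_scores: str | None = None  #: CSV with columns node_id, score
    n_boot: int = 1000
    out_dir: str | None = None
    make_plots: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.cohort is None) == (self.cohort_dir is None):
            raise ValidationError("exactly one of cohort / cohort_dir must be set")
        if not 0.0 < self.eval_fraction <= 1.0:
            raise ValidationError("eval_fraction must be in (0, 1]")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValidationError(f"unknown methods {sorted(unknown)}")


@dataclass
class MethodReport:
    method: str
    n_pos: int
    n_neg: int
    mann_whitney_u: float
    mann_whitney_p: float
    auc: float
    auc_ci95: tuple[float, float]
    cutoff: float
    cutoff_rule: str
    confusion: ConfusionMatrix
    sensitivity_pct: float
    specificity_pct: float
    accuracy_pct: float
    n_eval: int


@dataclass
class DiagnosticReport:
    methods: dict[str, MethodReport]
    spearman_between_methods: float | None
    n_nodes: int
    seed: int

    def to_dict(self) -> dict:
        out = {
            "n_nodes": self.n_nodes,
            "seed": self.seed,
            "spearman_between_methods": self.spearman_between_methods,
            "methods": {},
        }
        for name, m in self.methods.items():
            d = dataclasses.asdict(m)
            d["confusion"] = dataclasses.asdict(m.confusion)
            d["auc_ci95"] = list(m.auc_ci95)
            out["methods"][name] = d
        return out


def score_records(
    records: Iterable[NodeRecord],
    methods: tuple[str, ...] = METHODS,
    margin: float = DEFAULT_MARGIN_MM,
    epsilon: float | None = None,
    required_fluence: float = DEFAULT_FLUENCE,
    smooth: bool = True,
) -> pd.DataFrame:
    """Score a stream of node records; one row per (node, method).

    Streaming-friendly: each record is released after scoring.
    """
    rows = []
    for record in records:
        for method in methods:
            try:
                if method == "differential":
                    s = differential_score(record, smooth=smooth)
                else:
                    s = ratio_score(
                        record,
                        margin=margin,
                        epsilon=epsilon,
                        required_fluence=required_fluence,
                        smooth=smooth,
                    )
            except Exception as exc:
                raise PipelineError("scoring", record.node_id, str(exc)) from exc
            rows.append(
                {
                    "node_id": record.node_id,
                    "method": method,
                    "score": s,
                    "label": record.label,
                }
            )
            logger.info("scored node=%s method=%s score=%.6g", record.node_id, method, s)
    return pd.DataFrame(rows, columns=["node_id", "method", "score", "label"])


def _evaluate_method(
    slice_df: pd.DataFrame,
    method: str,
    cutoff_rule: str,
    eval_ids: np.ndarray | None,
    n_boot: int,
    seed: int,
) -> MethodReport:
    scores = slice_df["score"].to_numpy(dtype=float)
    labels = slice_df["label"].to_numpy()
    try:
        roc = calibrate(scores, labels, pos_label=METASTATIC, rule=cutoff_rule)
        pos = scores[labels == METASTATIC]
        neg = scores[labels != METASTATIC]
        mw = mann_whitney(pos, neg)
        ci = auc_ci_bootstrap(
            scores, labels, pos_label=METASTATIC, n_boot=n_boot, seed=seed
        )
        if eval_ids is not None:
            sel = slice_df["node_id"].isin(eval_ids).to_numpy()
            ev_scores, ev_labels = scores[sel], labels[sel]
        else:
            ev_scores, ev_labels = scores, labels
        if ev_scores.size == 0:
            raise DataError("evaluation subset is empty")
        cm = classify(ev_scores, ev_labels, roc.cutoff, pos_label=METASTATIC)
        sens, spec, acc = metrics(cm)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("diagnostics", None, f"method {method}: {exc}") from exc
    logger.info(
        "method=%s cutoff=%.6g auc=%.4f sens=%.1f spec=%.1f acc=%.1f "
        "(tp=%d fp=%d fn=%d tn=%d)",
        method, roc.cutoff, roc.auc, sens, spec, acc, cm.tp, cm.fp, cm.fn, cm.tn,
    )
    return MethodReport(
        method=method,
        n_pos=int(pos.size),
        n_neg=int(neg.size),
        mann_whitney_u=mw.u,
        mann_whitney_p=mw.p_value,
        auc=roc.auc,
        auc_ci95=ci,
        cutoff=float(roc.cutoff),
        cutoff_rule=cutoff_rule,
        confusion=cm,
        sensitivity_pct=sens,
        specificity_pct=spec,
        accuracy_pct=acc,
        n_eval=int(ev_scores.size),
    )


def _spearman(table: pd.DataFrame) -> float | None:
    present = [m for m in METHODS if (table["method"] == m).any()]
    if len(present) < 2:
        return None
    wide = table[table["method"].isin(present)].pivot(
        index="node_id", columns="method", values="score"
    )
    rho = stats.spearmanr(wide[present[0]], wide[present[1]]).statistic
    return float(rho)


def _resolved_config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def run_pipeline(config: RunConfig) -> tuple[DiagnosticReport, pd.DataFrame]:
    """Run the full pipeline; returns (report, score table)."""
    out_dir = Path(config.out_dir) if config.out_dir else None
    old_level, old_propagate = logger.level, logger.propagate
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(out_dir / "run.log", mode="w")
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
        # per-node lines go to run.log; the console keeps its own log level
        logger.setLevel(logging.INFO)
        if logging.getLogger().getEffectiveLevel() > logging.INFO:
            logger.propagate = False
    try:
        if config.cohort is not None:
            stream = (rec for rec, _row in iter_cohort(config.cohort))
        else:
            stream = iter_cohort_dir(config.cohort_dir)
        table = score_records(
            stream,
            methods=config.methods,
            margin=config.margin,
            epsilon=config.epsilon,
            required_fluence=config.required_fluence,
            smooth=config.smooth,
        )
        if table["label"].isna().any():
            raise PipelineError(
                "scoring", None, "ground-truth labels required for calibration"
            )
        if config.external_scores is not None:
            ext = pd.read_csv(config.external_scores)
            label_map = table.drop_duplicates("node_id").set_index("node_id")["label"]
            ext = pd.DataFrame(
                {
                    "node_id": ext["node_id"],
                    "method": "external",
                    "score": ext["score"].astype(float),
                    "label": ext["node_id"].map(label_map),
                }
            )
            table = pd.concat([table, ext], ignore_index=True)

        if config.eval_node_ids is not None:
            eval_ids = np.asarray(config.eval_node_ids)
        elif config.eval_fraction < 1.0:
            ids = table["node_id"].unique()
            rng = np.random.default_rng(config.seed)
            n_eval = max(1, int(round(config.eval_fraction * ids.size)))
            eval_ids = rng.choice(ids, size=n_eval, replace=False)
        else:
            eval_ids = None

        methods = {}
        all_methods = list(config.methods) + (
            ["external"] if config.external_scores is not None else []
        )
        for method in all_methods:
            slice_df = table[table["method"] == method]
            methods[method] = _evaluate_method(
                slice_df, method, config.cutoff_rule, eval_ids, config.n_boot,
                config.seed,
            )
        report = DiagnosticReport(
            methods=methods,
            spearman_between_methods=_spearman(table),
            n_nodes=int(table["node_id"].nunique()),
            seed=config.seed,
        )
        if out_dir:
            table.to_csv(out_dir / "scores.csv", index=False)
            (out_dir / "report.json").write_text(
                json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
            )
            (out_dir / "resolved_config.json").write_text(
                json.dumps(_resolved_config_dict(config), indent=2, sort_keys=True,
                           default=str) + "\n"
            )
            if config.make_plots:
                _write_roc_plots(table, report, out_dir)
        return report, table
    finally:
        if out_dir:
            logger.removeHandler(handler)
            handler.close()
            logger.setLevel(old_level)
            logger.propagate = old_propagate


def _write_roc_plots(
    table: pd.DataFrame, report: DiagnosticReport, out_dir: Path
) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for method, m in report.methods.items():
        slice_df = table[table["method"] == method]
        roc = calibrate(
            slice_df["score"].to_numpy(float),
            slice_df["label"].to_numpy(),
            pos_label=METASTATIC,
            rule=m.cutoff_rule,
        )
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.plot(roc.one_minus_specificities, roc.sensitivities, drawstyle="steps-post")
        ax.plot([0, 1], [0, 1], ls=":", color="gray")
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.set_title(f"{method}: AUC = {roc.auc:.3f}")
        fig.tight_layout()
        fig.savefig(out_dir / f"roc_{method}.png", dpi=120)
        plt.close(fig)


def make_fixtures(out_dir, seed: int = 7) -> pd.DataFrame:
    """Write a small versioned cohort for tests and demos.

    Eight nodes: 2 macro-metastatic, 2 micro-metastatic (< 2 mm), 2 inflamed
    negatives and 2 clean negatives, small node diameters to keep files small.
    """
    config = CohortConfig(
        n_nodes=8,
        metastasis_prevalence=0.5,
        micro_fraction=0.5,
        inflammation_rate=0.5,
        node_diameter_range=(3.0, 6.0),
        seed=seed,
    )
    truth = write_cohort(iter_cohort(config), out_dir)
    kinds = set(truth["lesion_kind"])
    expected = {"macro_metastasis", "micro_metastasis", "inflammation", "none"}
    if kinds != expected:
        raise PipelineError(
            "fixtures", None, f"fixture cohort kinds {kinds} != {expected}"
        )
    return truth
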