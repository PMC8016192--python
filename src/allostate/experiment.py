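"""End-to-end experiment orchestration over a declarative configuration.

One configuration object describes the whole ensemble design — which
ligands train and which test, replicate counts, production spans and
strides — and the pipeline stages (simulate, train, cross-validate,
predict, aggregate, boundary + regression) run from it deterministically
under a single seed.

The dataset design mirrors the comparative ensemble layout:

* **original training set** — 9 bound systems (3 training ligands x 3
  replicates) and 9 free replicates, 80 ns at 20 ps stride -> 4000
  records per system, 72 000 labeled rows in total;
* **extended training set** — 200 ns more per system sampled every
  100 ps, adding 2000 records each -> 108 000 rows;
* **small test set** — 8 held-out ligands x 3 replicates plus 24 free
  replicates at 4000 records each -> 192 000 unlabeled rows;
* **large test set** — the small test set plus the 200 ns extensions of
  one replicate per training ligand and of three free replicates (2000
  records each) -> 204 000 rows, giving 11 bound and 11 free
  observation groups.

A ``frame_scale`` below 1 shrinks every per-system record count by the
same factor, preserving all set-size ratios for desk-scale runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .featurize import FEATURE_COLUMNS
from .models import (SVM_PRESETS, predict_nb, train_gnb, train_knb,
                     train_svm)
from .state_regression import run_boundary_analysis
from .synthetic import (MixtureSpec, _matrix_from_components, _system_rng,
                        default_anchor_mixtures, sample_ligand_matrix)
from .validation import aggregate_by_group, cross_validate

__all__ = [
    "ExperimentConfig", "DesignData", "build_design_data",
    "assemble_dataset", "run_experiment", "panel_quorum", "SET_NAMES",
]

logger = logging.getLogger(__name__)

SET_NAMES = ("original-train", "extended-train", "small-test", "large-test")


def panel_quorum(n_free_groups: int) -> float:
    """Quorum fraction used for the boundary at a given free-group count.

    Panels of eight observation groups use 5/8 and panels of eleven use
    8/11; other panel sizes fall back to 62.5%.
    """
    if n_free_groups == 8:
        return 5.0 / 8.0
    if n_free_groups == 11:
        return 8.0 / 11.0
    return 0.625


@dataclass
class ExperimentConfig:
    """Declarative description of one synthetic end-to-end experiment."""

    seed: int = 0
    train_ligand_effects: dict[str, float] = field(
        default_factory=lambda: {"5": 1.0, "7": 0.99, "6": 0.96})
    test_ligand_effects: dict[str, float] = field(
        default_factory=lambda: {"8": 0.87, "1": 0.68, "9": 0.67,
                                 "10": 0.66, "2": 0.52, "4": 0.47,
                                 "11": 0.36, "3": 0.35})
    n_replicates: int = 3
    production_ns: float = 80.0
    stride_ps: float = 20.0
    extension_ns: float = 200.0
    extension_stride_ps: float = 100.0
    discard_ns: float = 20.0
    inhibition_link: tuple[float, float, float] = (76.0, 0.0, 3.0)
    frame_scale: float = 1.0
    training_set: str = "original-train"
    svm_preset: str = "medium"
    k_folds: int = 5
    algorithms: tuple[str, ...] = ("gnb", "knb", "svm")

    def validate(self) -> None:
        overlap = set(self.train_ligand_effects) & set(
            self.test_ligand_effects)
        if overlap:
            raise ValueError(f"ligands in both train and test: {overlap}")
        if self.training_set not in ("original-train", "extended-train"):
            raise ValueError("training_set must be original-train or "
                             "extended-train")
        if self.svm_preset not in SVM_PRESETS:
            raise ValueError(f"unknown SVM preset {self.svm_preset!r}")
        if not 0.0 < self.frame_scale <= 1.0:
            raise ValueError("frame_scale must lie in (0, 1]")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        unknown = set(self.algorithms) - {"gnb", "knb", "svm"}
        if unknown:
            raise ValueError(f"unknown algorithms {sorted(unknown)}")

    @property
    def frames_original(self) -> int:
        return max(1, int(round(self.production_ns * 1000.0
                                / self.stride_ps * self.frame_scale)))

    @property
    def frames_extension(self) -> int:
        return max(1, int(round(self.extension_ns * 1000.0
                                / self.extension_stride_ps
                                * self.frame_scale)))

    def to_json(self) -> str:
        payload = asdict(self)
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "ExperimentConfig":
        text = str(text_or_path)
        if not text.lstrip().startswith("{"):
            text = Path(text_or_path).read_text()
        payload = json.loads(text)
        for key in ("inhibition_link", "algorithms"):
            if key in payload:
                payload[key] = tuple(payload[key])
        config = cls(**payload)
        config.validate()
        return config

    def content_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclass
class DesignData:
    """All per-system matrices plus manifest and ground truth."""

    matrices: dict[tuple[str, str], pd.DataFrame]  # (system_id, segment)
    manifest: pd.DataFrame
    ground_truth: pd.DataFrame
    config: ExperimentConfig


def _simulated_inhibition(config: ExperimentConfig) -> dict[str, float]:
    slope, intercept, noise_sd = config.inhibition_link
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, zlib.crc32(b"assay")]))
    out = {}
    effects = dict(config.train_ligand_effects)
    effects.update(config.test_ligand_effects)
    for lig in sorted(effects):
        value = slope * effects[lig] + intercept
        if noise_sd > 0:
            value += rng.normal(0.0, noise_sd)
        out[lig] = float(np.clip(value, 0.0, 100.0))
    return out


def build_design_data(config: ExperimentConfig,
                      mixtures: MixtureSpec | None = None) -> DesignData:
    """Simulate every system of the four-set design.

    Each system owns one RNG stream; its extension segment continues the
    stream that produced the original segment, so the extended sets
    contain the original spans unchanged.
    """
    config.validate()
    if mixtures is None:
        mixtures = default_anchor_mixtures()
    mixtures.validate()

    n1, n2 = config.frames_original, config.frames_extension
    inhibition = _simulated_inhibition(config)

    matrices: dict[tuple[str, str], pd.DataFrame] = {}
    manifest_rows = []
    truth_rows = []

    def simulate(system_id, effect, label, ligand_id, group_id, replicate,
                 role, with_extension, extension_in_large_test):
        rng = _system_rng(config.seed, system_id)
        segments = {"original": n1}
        if with_extension:
            segments["extension"] = n2
        for segment, n_frames in segments.items():
            stride = (config.stride_ps if segment == "original"
                      else config.extension_stride_ps)
            if label == "A":
                matrix = _matrix_from_components(
                    mixtures.components["A"], n_frames, rng, label,
                    system_id, replicate, ligand_id, stride)
            else:
                matrix = sample_ligand_matrix(
                    mixtures, effect, n_frames, rng, label=label,
                    system_id=system_id, replicate_id=replicate,
                    ligand_id=ligand_id, frame_interval_ps=stride)
            matrices[(system_id, segment)] = matrix
            manifest_rows.append(dict(
                system_id=system_id, segment=segment, state=label,
                ligand_id=ligand_id, group_id=group_id,
                replicate_id=replicate, role=role, n_frames=n_frames,
                production_ns=(config.production_ns if segment == "original"
                               else config.extension_ns),
                stride_ps=stride, discard_ns=config.discard_ns,
                in_large_test=(segment == "extension"
                               and extension_in_large_test)))
        truth_rows.append(dict(
            system_id=system_id, state=label, ligand_id=ligand_id,
            group_id=group_id, replicate_id=replicate, role=role,
            true_I_occupancy=(0.0 if label == "A" else
                              {**config.train_ligand_effects,
                               **config.test_ligand_effects}[ligand_id]),
            pct_inhibition=(0.0 if label == "A"
                            else inhibition[ligand_id])))

    # training ligands: replicate 1 extensions join the large test set
    for lig in sorted(config.train_ligand_effects):
        effect = config.train_ligand_effects[lig]
        for rep in range(1, config.n_replicates + 1):
            simulate(f"I-{lig}-r{rep}", effect, "I", lig, f"lig-{lig}", rep,
                     role="train", with_extension=True,
                     extension_in_large_test=(rep == 1))
    # free training replicates, in blocks of n_replicates
    n_free_train = len(config.train_ligand_effects) * config.n_replicates
    for k in range(n_free_train):
        group = k // config.n_replicates + 1
        rep = k % config.n_replicates + 1
        simulate(f"A-train-g{group}-r{rep}", 0.0, "A",
                 "none", f"free-train-g{group}", rep, role="train",
                 with_extension=True,
                 extension_in_large_test=(rep == 1))
    # held-out test ligands and matched free replicates, original span only
    for lig in sorted(config.test_ligand_effects):
        effect = config.test_ligand_effects[lig]
        for rep in range(1, config.n_replicates + 1):
            simulate(f"I-{lig}-r{rep}", effect, "I", lig, f"lig-{lig}", rep,
                     role="test", with_extension=False,
                     extension_in_large_test=False)
    n_free_test = len(config.test_ligand_effects) * config.n_replicates
    for k in range(n_free_test):
        group = k // config.n_replicates + 1
        rep = k % config.n_replicates + 1
        simulate(f"A-test-g{group}-r{rep}", 0.0, "A",
                 "none", f"free-test-g{group}", rep, role="test",
                 with_extension=False, extension_in_large_test=False)

    return DesignData(matrices=matrices,
                      manifest=pd.DataFrame(manifest_rows),
                      ground_truth=pd.DataFrame(truth_rows),
                      config=config)


def assemble_dataset(data: DesignData, set_name: str) -> pd.DataFrame:
    """Concatenate the matrices belonging to one named set.

    Training sets keep their labels; test sets are returned with labels
    stripped to ``unlabeled`` (the truth stays in ``data.ground_truth``).
    """
    if set_name not in SET_NAMES:
        raise ValueError(f"unknown set {set_name!r}; choose from "
                         f"{SET_NAMES}")
    m = data.manifest
    if set_name == "original-train":
        wanted = m[(m["role"] == "train") & (m["segment"] == "original")]
        labeled = True
    elif set_name == "extended-train":
        wanted = m[m["role"] == "train"]
        labeled = True
    elif set_name == "small-test":
        wanted = m[(m["role"] == "test") & (m["segment"] == "original")]
        labeled = False
    else:  # large-test
        wanted = pd.concat([
            m[(m["role"] == "test") & (m["segment"] == "original")],
            m[m["in_large_test"]],
        ])
    blocks = [data.matrices[(r.system_id, r.segment)]
              for r in wanted.itertuples()]
    if not blocks:
        raise ValueError(f"set {set_name!r} resolved no matrices")
    df = pd.concat(blocks, ignore_index=True)
    if set_name in ("small-test", "large-test"):
        df = df.assign(label="unlabeled")
    logger.info("assembled %s: %d rows from %d matrices", set_name, len(df),
                len(blocks))
    return df


def _external_grouping(data: DesignData, set_name: str) -> pd.DataFrame:
    """Per-system grouping manifest for external prediction aggregation.

    In the large test set the extension segments each form their own
    single-replicate observation group, giving the 11 + 11 layout.
    """
    m = data.manifest
    if set_name == "small-test":
        rows = m[(m["role"] == "test") & (m["segment"] == "original")]
        return rows[["system_id", "state", "ligand_id", "group_id"]] \
            .drop_duplicates()
    if set_name != "large-test":
        raise ValueError("external grouping exists for test sets only")
    base = m[(m["role"] == "test") & (m["segment"] == "original")]
    extra = m[m["in_large_test"]].copy()
    extra["group_id"] = [
        (f"lig-{r.ligand_id}-ext" if r.state == "I"
         else f"free-ext-{r.system_id}")
        for r in extra.itertuples()]
    combined = pd.concat([
        base[["system_id", "state", "ligand_id", "group_id"]],
        extra[["system_id", "state", "ligand_id", "group_id"]],
    ], ignore_index=True)
    return combined.drop_duplicates()


def _predictions_for_set(data: DesignData, set_name: str, models: dict
                         ) -> dict[str, pd.DataFrame]:
    """Row-level predictions of each trained model on one test set.

    For the large test set the extension rows of training systems are
    predicted from their own matrices so the system ids survive.
    """
    m = data.manifest
    if set_name == "small-test":
        wanted = m[(m["role"] == "test") & (m["segment"] == "original")]
    else:
        wanted = pd.concat([
            m[(m["role"] == "test") & (m["segment"] == "original")],
            m[m["in_large_test"]],
        ])
    blocks = [data.matrices[(r.system_id, r.segment)]
              for r in wanted.itertuples()]
    stacked = pd.concat(blocks, ignore_index=True)
    out = {}
    for name, (model, predictor) in models.items():
        pred = predictor(model, stacked)
        pred = pred.assign(system_id=stacked["system_id"].to_numpy())
        out[name] = pred
    return out


def run_experiment(config: ExperimentConfig,
                   mixtures: MixtureSpec | None = None,
                   external_set: str = "small-test") -> dict:
    """Simulate, train, cross-validate, predict and regress in one call.

    Returns a provenance-stamped bundle: per-algorithm CV metrics,
    external per-group rates, the boundary construction and the
    TPR%-vs-inhibition regression (against the simulated assay values of
    the synthetic ground truth).
    """
    config.validate()
    data = build_design_data(config, mixtures)
    train = assemble_dataset(data, config.training_set)
    logger.info("training on %s (%d rows)", config.training_set, len(train))

    trainers = {
        "gnb": (lambda df: train_gnb(df), predict_nb),
        "knb": (lambda df: train_knb(df), predict_nb),
        "svm": (lambda df: train_svm(df, preset=config.svm_preset),
                lambda model, df: model.predict(df)),
    }
    models = {}
    cv_reports = {}
    for algo in config.algorithms:
        trainer, predictor = trainers[algo]
        cv_reports[algo] = cross_validate(train, trainer, predictor,
                                          k=config.k_folds,
                                          rng_seed=config.seed)
        models[algo] = (trainer(train), predictor)
        logger.info("%s: <Q> = %.4f", algo, cv_reports[algo].mean_q)

    grouping = _external_grouping(data, external_set)
    predictions = _predictions_for_set(data, external_set, models)
    truth_state = data.ground_truth.set_index("system_id")["state"]

    inhibition = data.ground_truth.groupby("ligand_id")["pct_inhibition"] \
        .first().drop("none", errors="ignore")

    boundary_analysis = {}
    group_rates = {}
    external_metrics = {}
    for algo, pred in predictions.items():
        rates = aggregate_by_group(pred, grouping)
        group_rates[algo] = rates
        n_free = int((rates["state"] == "A").sum())
        boundary_analysis[algo] = run_boundary_analysis(
            rates, inhibition, quorum=panel_quorum(n_free))
        from .validation import compute_metrics
        external_metrics[algo] = compute_metrics(
            truth_state.loc[pred["system_id"]].to_numpy(),
            pred["predicted"].to_numpy())

    return {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "config": json.loads(config.to_json()),
        "data": data,
        "cv_reports": cv_reports,
        "models": {k: v[0] for k, v in models.items()},
        "group_rates": group_rates,
        "external_metrics": external_metrics,
        "boundary_analysis": boundary_analysis,
    }


def bundle_summary(bundle: dict) -> pd.DataFrame:
    """Flat per-algorithm summary table of an experiment bundle."""
    rows = []
    for algo, cv in bundle["cv_reports"].items():
        fig = bundle["boundary_analysis"][algo]
        ext = bundle["external_metrics"][algo]
        rows.append({
            "algorithm": algo,
            "cv_mean_Q": cv.mean_q,
            "cv_pooled_TPR": cv.pooled.tpr,
            "cv_pooled_TNR": cv.pooled.tnr,
            "external_Q": ext.q,
            "external_TPR": ext.tpr,
            "external_TNR": ext.tnr,
            "threshold_1_FPRpct": fig["boundary"].threshold_1,
            "threshold_2_TPRpct": fig["boundary"].threshold_2,
            "n_I_like": len(fig["boundary"].i_like_ligands),
            "regression_slope": fig["regression"].slope,
            "regression_intercept": fig["regression"].intercept,
            "regression_r2": fig["regression"].r_squared,
        })
    return pd.DataFrame(rows)
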