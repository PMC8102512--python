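"""End-to-end orchestration: generate -> rebalance -> split -> train ->
Grad-CAM on the test split -> binarize -> score -> grading metrics.

Each stage writes plain-text artifacts (CSV/JSON) plus PNG images and
heatmaps into a run directory; the scoring stage reads the heatmaps back
from disk, so it can be re-run standalone on any image+mask+heatmap
directory laid out the same way (``score_only``), e.g. to apply the
analysis to real annotated fundus data without retraining.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import metrics as metrics_mod
from . import models as models_mod
from . import saliency as saliency_mod
from . import scoring as scoring_mod
from . import synthetic

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run; the global seed is propagated
    deterministically to every stage."""

    scene: synthetic.SceneSpec = field(default_factory=synthetic.SceneSpec)
    n_per_grade: int = 50
    rebalance_cap: int = 500
    split_fractions: tuple = (0.8, 0.1, 0.1)
    variants: tuple = ("plain",)
    train: models_mod.TrainConfig = field(default_factory=models_mod.TrainConfig)
    base_channels: int = 8
    tau: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        self.scene.validate()
        self.train.validate()
        for v in self.variants:
            if v not in models_mod.VARIANTS:
                raise ValueError(f"unknown variant {v!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        scene = synthetic.SceneSpec(**raw.pop("scene", {}))
        if isinstance(scene.lesion_counts, dict):
            scene.lesion_counts = {k: tuple(v) for k, v in scene.lesion_counts.items()}
        train = models_mod.TrainConfig(**raw.pop("train", {}))
        cfg = cls(scene=scene, train=train, **raw)
        cfg.split_fractions = tuple(cfg.split_fractions)
        cfg.variants = tuple(cfg.variants)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _stage_seed(seed: int, stage: str) -> int:
    return int(np.random.SeedSequence(
        [seed, int.from_bytes(stage.encode(), "little") % (2**31)]
    ).generate_state(1)[0])


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute every stage; returns the summary dict (also written as JSON)."""
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    hashes: dict[str, str] = {}
    stage = "init"
    try:
        stage = "generate"
        logger.info("stage=%s seed=%d", stage, _stage_seed(config.seed, stage))
        data_dir = out_dir / "data"
        manifest = synthetic.generate_dataset(
            config.scene, config.n_per_grade, _stage_seed(config.seed, stage), data_dir)

        stage = "rebalance"
        logger.info("stage=%s", stage)
        manifest = synthetic.rebalance(
            manifest, config.rebalance_cap, _stage_seed(config.seed, stage))

        stage = "split"
        logger.info("stage=%s", stage)
        manifest = synthetic.split(
            manifest, config.split_fractions, _stage_seed(config.seed, stage))
        synthetic.save_manifest(manifest, out_dir / "manifest.csv")
        hashes["manifest.csv"] = _hash_file(out_dir / "manifest.csv")

        train_x, train_y = synthetic.load_split_arrays(manifest, "train")
        val_x, val_y = synthetic.load_split_arrays(manifest, "val")
        test_rows = manifest[manifest["split"] == "test"].drop_duplicates("image_id")
        test_items = [synthetic.load_item(r) for _, r in test_rows.iterrows()]
        test_x = np.stack([it.image for it in test_items])
        test_y = np.array([it.grade for it in test_items])

        ckpt_dir = out_dir / "checkpoints"
        ckpt_dir.mkdir(exist_ok=True)
        trained: dict[str, models_mod.GraderModel] = {}
        for variant in config.variants:
            stage = f"train[{variant}]"
            logger.info("stage=%s", stage)
            mcfg = models_mod.ModelConfig(
                variant=variant, input_size=config.scene.image_size,
                base_channels=config.base_channels,
                seed=_stage_seed(config.seed, stage))
            model = models_mod.build_model(mcfg)
            history = models_mod.train(model, train_x, train_y, val_x, val_y,
                                       config.train)
            history.to_csv(out_dir / f"history_{variant}.csv", index=False)
            model.save(ckpt_dir / f"{variant}.npz")
            (ckpt_dir / f"{variant}_run.json").write_text(
                json.dumps({"train": dataclasses.asdict(config.train),
                            "model": dataclasses.asdict(mcfg)}, indent=2))
            trained[variant] = model

        stage = "saliency"
        logger.info("stage=%s", stage)
        hm_dir = out_dir / "heatmaps"
        for variant, model in trained.items():
            vdir = hm_dir / variant
            vdir.mkdir(parents=True, exist_ok=True)
            overlay_dir = out_dir / "overlays" / variant
            overlay_dir.mkdir(parents=True, exist_ok=True)
            for item in test_items:
                sal = saliency_mod.gradcam(model, item.image)
                sal.model_id = variant
                sal.image_id = item.image_id
                saliency_mod.save_heatmap(sal, vdir / f"{item.image_id}.png")
                rgb = saliency_mod.overlay(item.image, sal)
                iio.imwrite(overlay_dir / f"{item.image_id}.png",
                            np.round(rgb * 255).astype(np.uint8))

        stage = "score"
        logger.info("stage=%s", stage)
        reports_dir = out_dir / "reports"
        score_outputs = score_only(data_dir, hm_dir, reports_dir, tau=config.tau,
                                   manifest=test_rows)

        stage = "metrics"
        logger.info("stage=%s", stage)
        metrics_summary = {}
        for variant, model in trained.items():
            scores = model.predict_proba(test_x)
            preds = np.argmax(scores, axis=1)
            cm = metrics_mod.confusion(test_y, preds)
            report = metrics_mod.overall_metrics(cm, test_y, scores)
            rep = report.to_dict()
            rep["confusion"] = cm.tolist()
            (reports_dir / f"metrics_{variant}.json").write_text(
                json.dumps(rep, indent=2))
            report.per_grade.to_csv(reports_dir / f"per_grade_{variant}.csv",
                                    index=False)
            pd.DataFrame([{k: rep[k] for k in
                           ("accuracy", "auc", "kappa", "matthews",
                            "se", "sp", "ppv", "npv")}]).to_csv(
                reports_dir / f"metrics_{variant}.csv", index=False)
            roc = metrics_mod.roc_points(test_y, scores)
            roc.to_csv(reports_dir / f"roc_{variant}.csv", index=False)
            _plot_roc(roc, reports_dir / f"roc_{variant}.png")
            metrics_summary[variant] = {k: rep[k] for k in
                                        ("accuracy", "auc", "kappa", "matthews")}

        stage = "summary"
        for p in sorted(reports_dir.glob("*.csv")):
            hashes[f"reports/{p.name}"] = _hash_file(p)
        summary = {
            "config": config.to_dict(),
            "mean_iou": score_outputs["mean_iou"].to_dict(orient="records"),
            "agreement": score_outputs["agreement"].to_dict(),
            "missed_pathology_percent_by_model":
                score_outputs["missed_by_model"],
            "metrics": metrics_summary,
            "hashes": hashes,
        }
        (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
        return summary
    except Exception:
        logger.exception("pipeline aborted at stage=%s (partial outputs kept in %s)",
                         stage, out_dir)
        raise


def score_only(
    data_dir: str | Path,
    heatmaps_dir: str | Path,
    out_dir: str | Path,
    tau: float = 0.0,
    manifest: pd.DataFrame | None = None,
) -> dict:
    """Score saved heatmaps against saved masks; emits the IoU-record,
    mean-IoU, agreement and missed-pathology CSVs plus figure analogues."""
    data_dir, heatmaps_dir, out_dir = Path(data_dir), Path(heatmaps_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if manifest is None:
        manifest = synthetic.read_manifest(data_dir / "manifest.csv")
        manifest = manifest.drop_duplicates("image_id")
    manifest = manifest.sort_values("image_id")
    model_dirs = sorted(d for d in heatmaps_dir.iterdir() if d.is_dir()) \
        if heatmaps_dir.exists() else []

    iou_records: list[scoring_mod.IoURecord] = []
    missed_records: list[scoring_mod.MissedPathologyRecord] = []
    binary_by_model: dict[str, dict[str, scoring_mod.BinaryMap]] = {}
    masks_by_image: dict[str, dict] = {}
    skipped = []

    for mdir in model_dirs:
        model_id = mdir.name
        binary_by_model[model_id] = {}
        for _, row in manifest.iterrows():
            image_id = str(row["image_id"])
            hm_path = mdir / f"{image_id}.png"
            if not hm_path.exists():
                skipped.append((model_id, image_id))
                continue
            sal = saliency_mod.load_heatmap(hm_path)
            bmap = scoring_mod.binarize_otsu(sal, model_id=model_id,
                                             image_id=image_id)
            binary_by_model[model_id][image_id] = bmap
            if image_id not in masks_by_image:
                item = synthetic.load_item(row)
                masks_by_image[image_id] = item.masks
            masks = masks_by_image[image_id]
            for comp in synthetic.COMPONENTS:
                if comp not in masks:
                    logger.warning("missing mask %s for %s; skipped", comp, image_id)
                    continue
                iou_records.append(scoring_mod.IoURecord(
                    image_id=image_id, model_id=model_id, component=comp,
                    score=scoring_mod.iou(bmap.values, masks[comp])))
            missed_records.append(scoring_mod.missed_pathology(
                bmap, {c: masks[c] for c in synthetic.PATHOLOGY_COMPONENTS
                       if c in masks},
                tau=tau, image_id=image_id))
    if skipped:
        logger.warning("missing heatmaps skipped: %s", skipped)

    iou_df = pd.DataFrame([r.__dict__ for r in iou_records],
                          columns=["image_id", "model_id", "component", "score"])
    iou_df.to_csv(out_dir / "iou_records.csv", index=False)
    missed_df = pd.DataFrame(
        [r.__dict__ for r in missed_records],
        columns=["image_id", "model_id", "lesions_total", "lesions_missed",
                 "percent_missed", "percent_pixels_missed"])
    missed_df.to_csv(out_dir / "missed_pathology.csv", index=False)

    if iou_records:
        mean_iou = scoring_mod.mean_iou_by_component(iou_records)
    else:
        mean_iou = pd.DataFrame(columns=["model_id", "component", "mean_iou",
                                         "n_defined", "n_total"])
    mean_iou.to_csv(out_dir / "mean_iou.csv", index=False)

    # agreement only over models covering the full scored image set
    all_ids = sorted({i for v in binary_by_model.values() for i in v})
    complete = {m: [v[i] for i in all_ids]
                for m, v in binary_by_model.items() if set(v) == set(all_ids)}
    if complete and all_ids:
        agreement = scoring_mod.pairwise_agreement(complete)
    else:
        agreement = pd.DataFrame()
    agreement.to_csv(out_dir / "agreement.csv")

    missed_by_model = {}
    if not missed_df.empty:
        with_lesions = missed_df[missed_df["lesions_total"] > 0]
        missed_by_model = (with_lesions.groupby("model_id")["percent_missed"]
                          .mean().to_dict())
    if not mean_iou.empty:
        _plot_mean_iou(mean_iou, out_dir / "mean_iou.png")
    if not agreement.empty:
        _plot_agreement(agreement, out_dir / "agreement.png")
    if missed_by_model:
        _plot_missed(missed_by_model, out_dir / "missed_pathology.png")
    return {"iou_records": iou_df, "mean_iou": mean_iou, "agreement": agreement,
            "missed": missed_df, "missed_by_model": missed_by_model}


# ---- figure analogues ---------------------------------------------------

def _plot_mean_iou(mean_iou: pd.DataFrame, path: Path) -> None:
    pivot = mean_iou.pivot(index="component", columns="model_id", values="mean_iou")
    ax = pivot.plot.bar(figsize=(7, 4))
    ax.set_ylabel("mean IoU")
    ax.set_title("Mean IoU of binarized Grad-CAM maps by ocular component")
    plt.tight_layout()
    plt.savefig(path)
    plt.close()


def _plot_agreement(agreement: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(agreement.values, vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(len(agreement.columns)), agreement.columns, rotation=45)
    ax.set_yticks(range(len(agreement.index)), agreement.index)
    fig.colorbar(im, ax=ax, label="mean pairwise IoU")
    ax.set_title("Inter-model agreement of binarized saliency maps")
    plt.tight_layout()
    plt.savefig(path)
    plt.close()


def _plot_missed(missed_by_model: dict, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.bar(list(missed_by_model), list(missed_by_model.values()))
    ax.set_ylabel("% lesions missed")
    ax.set_title("Pathology missed by each model's binarized saliency map")
    plt.tight_layout()
    plt.savefig(path)
    plt.close()


def _plot_roc(roc: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for grade, grp in roc.groupby("grade"):
        ax.plot(grp["fpr"], grp["tpr"], label=f"grade {grade}")
    ax.plot([0, 1], [0, 1], "k--", lw=0.5)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend()
    plt.tight_layout()
    plt.savefig(path)
    plt.close()
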