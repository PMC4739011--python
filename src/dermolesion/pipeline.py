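"""End-to-end orchestration: images -> features -> trained model -> diagnosis.

``extract_features`` walks a manifest of images (with optional ground-truth
masks and labels), runs preprocessing, segmentation and all four feature
families, and emits one feature row per image — per-image failures are
recorded, never fatal to the batch. ``TrainedBundle`` freezes the
preparation chain (scaler, selected feature subset, one-vs-all models) so
a single new image can be classified end to end.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from PIL import Image

from . import asymmetry, classify, color, preprocess, segment, shape, texture
from .prep import LABEL_COLUMN, FeatureScaler, cfs_select, smote

log = logging.getLogger("dermolesion")


def load_image(path: str) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def load_mask(path: str) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L")) > 127


def save_mask(mask: np.ndarray, path: str) -> None:
    Image.fromarray((np.asarray(mask, dtype=bool) * 255).astype(np.uint8)).save(path)


def extract_one(rgb: np.ndarray, mask: np.ndarray | None = None, seed: int = 0,
                config: dict | None = None) -> dict[str, float]:
    """Full feature vector for one RGB image (segmenting when no mask given)."""
    config = config or {}
    pre = preprocess.preprocess_image(rgb, **config.get("preprocess", {}))
    gray = pre["gray"]
    if mask is None:
        lesion = segment.segment_lesion(gray, config.get("segment", {}).get("tolerance"))
    else:
        top, bottom, left, right = pre["crop_offsets"]
        h, w = mask.shape
        cropped = mask[top : h - bottom, left : w - right]
        lesion = segment.LesionMask.from_array(cropped)
    lab = color.rgb_to_lab(pre["rgb"])
    feats: dict[str, float] = {}
    feats.update(shape.shape_features(lesion))
    feats.update(color.color_features(lab, lesion, seed=seed))
    feats.update(texture.texture_features(gray, lesion))
    feats.update(asymmetry.asymmetry_features(pre["rgb"], gray, lab, lesion))
    return feats


def extract_features(manifest: pd.DataFrame, seed: int = 0,
                     config: dict | None = None) -> pd.DataFrame:
    """One feature row per manifest entry (columns: path, mask_path, label).

    A failing image yields a row with ``status != "ok"`` and NaN features;
    the batch always completes.
    """
    if len(manifest) == 0:
        raise ValueError("empty manifest")
    rows = []
    for _, entry in manifest.iterrows():
        row: dict = {"path": entry["path"], "status": "ok"}
        try:
            rgb = load_image(entry["path"])
            mask = None
            if "mask_path" in entry and isinstance(entry.get("mask_path"), str) and entry["mask_path"]:
                mask = load_mask(entry["mask_path"])
            row.update(extract_one(rgb, mask, seed=seed, config=config))
        except Exception as exc:  # noqa: BLE001 - per-image isolation is the contract
            log.warning("feature extraction failed for %s: %s", entry["path"], exc)
            row["status"] = f"error: {exc}"
        if "label" in entry and isinstance(entry.get("label"), str):
            row[LABEL_COLUMN] = entry["label"]
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class TrainedBundle:
    """Frozen preparation chain + one-vs-all models for inference."""

    scaler: FeatureScaler
    features: list[str]
    model: classify.OneVsAllModel
    seed: int

    @classmethod
    def fit(cls, table: pd.DataFrame, spec: classify.ClassifierSpec,
            select: bool = True, k_max: int = 20, rebalance: bool = True,
            seed: int = 0) -> "TrainedBundle":
        feat_cols = [c for c in table.columns if c != LABEL_COLUMN]
        table = table[feat_cols + [LABEL_COLUMN]].dropna()
        scaler = FeatureScaler().fit(table)
        scaled = scaler.transform(table)
        if select:
            subset = cfs_select(scaled, k_max)
            features = subset.features or feat_cols
        else:
            features = feat_cols
        train_tbl = scaled[features + [LABEL_COLUMN]]
        if rebalance:
            train_tbl = smote(train_tbl, seed=seed)
        model = classify.train(spec, train_tbl, seed=seed)
        return cls(scaler, features, model, seed)

    def classify_table(self, table: pd.DataFrame):
        scaled = self.scaler.transform(table)
        return self.model.predict(scaled[self.features])

    def classify_image(self, rgb: np.ndarray, config: dict | None = None) -> dict:
        """Diagnose one image; explicit failure instead of a silent guess."""
        try:
            feats = extract_one(rgb, seed=self.seed, config=config)
        except segment.SegmentationError as exc:
            return {"class": None, "status": f"unclassifiable: {exc}"}
        row = pd.DataFrame([feats])
        pred, scores = self.classify_table(row)
        return {
            "class": str(pred[0]),
            "scores": dict(zip(self.model.classes, scores[0].tolist())),
            "status": "ok",
        }


def save_report(report: classify.EvaluationReport, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
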