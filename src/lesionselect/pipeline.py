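"""Full pipeline runner: fuse → select → evaluate, with a run manifest.

A :class:`RunConfig` names either on-disk feature blocks + labels or a
synthetic-data specification, a selector configuration, the classifier
panel, and seeds.  ``run_pipeline`` executes the stages, writes each
artifact (fused matrix, mask, selection report, evaluation reports) and a
manifest recording configuration hash, seeds and the SHA-256 of every file
it produced, so a run is traceable and byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import __version__
from .fusion import FusedFeatures, fuse
from .gwo import GWOConfig
from .harness import compare_conditions, evaluate
from .selection import SelectorConfig, select
from .store import (
    Dataset,
    FeatureBlock,
    LabelVector,
    assemble_dataset,
    read_feature_block,
    read_labels,
    write_feature_block,
    write_mask,
)
from .synthetic import SyntheticSpec, generate

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs.

    Exactly one of ``block_paths`` (+ ``labels_path``) or ``synthetic`` must
    be provided.
    """

    out_dir: str
    block_paths: tuple[str, ...] = ()
    labels_path: str = ""
    synthetic: SyntheticSpec | None = None
    selector: SelectorConfig = field(default_factory=SelectorConfig)
    classifiers: tuple[str, ...] = ("fine-knn",)
    eval_seeds: tuple[int, ...] = (0,)
    train_fraction: float = 0.7

    def __post_init__(self) -> None:
        has_files = bool(self.block_paths)
        if has_files == (self.synthetic is not None):
            raise ValueError("provide either block_paths+labels_path or synthetic, not both")
        if has_files and not self.labels_path:
            raise ValueError("labels_path required with block_paths")
        if not self.classifiers:
            raise ValueError("need at least one classifier")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        synth = raw.pop("synthetic", None)
        selector_raw = raw.pop("selector", {})
        gwo_raw = selector_raw.pop("gwo", {})
        return cls(
            out_dir=raw.pop("out_dir"),
            block_paths=tuple(raw.pop("block_paths", ())),
            labels_path=raw.pop("labels_path", ""),
            synthetic=SyntheticSpec(**synth) if synth is not None else None,
            selector=SelectorConfig(gwo=GWOConfig(**gwo_raw), **selector_raw),
            classifiers=tuple(raw.pop("classifiers", ("fine-knn",))),
            eval_seeds=tuple(int(s) for s in raw.pop("eval_seeds", (0,))),
            train_fraction=float(raw.pop("train_fraction", 0.7)),
        )


def _config_fingerprint(config: RunConfig) -> str:
    def encode(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: encode(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, (tuple, list)):
            return [encode(x) for x in obj]
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return obj

    payload = encode(config)
    payload.pop("out_dir", None)  # where results land does not change them
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_dataset(config: RunConfig) -> Dataset:
    if config.synthetic is not None:
        dataset, _ = generate(config.synthetic)
        return dataset
    for p in list(config.block_paths) + [config.labels_path]:
        if not Path(p).exists():
            raise FileNotFoundError(f"configured input does not exist: {p}")
    blocks = [read_feature_block(p) for p in config.block_paths]
    labels = read_labels(config.labels_path)
    return assemble_dataset(blocks, labels)


def run_pipeline(config: RunConfig) -> dict:
    """Execute fuse → select → evaluate (both conditions) and write artifacts.

    Returns the manifest (also written to ``<out_dir>/manifest.json``).
    Stage failures abort with the stage name in the raised error.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    stage = "validate"
    try:
        dataset = _load_dataset(config)

        stage = "fuse"
        t0 = time.perf_counter()
        fused = fuse(dataset.blocks)
        fused_block = FeatureBlock(name="fused", values=np.asarray(fused.values))
        fused_path = out / "fused.csv"
        write_feature_block(fused_block, fused_path)
        artifacts["fused.csv"] = _sha256(fused_path)
        log.info("fuse: %d×%d in %.2fs", fused.n_samples, fused.d_fused, time.perf_counter() - t0)

        stage = "select"
        t0 = time.perf_counter()
        result = select(fused, config.selector, labels=dataset.labels)
        mask_path = out / "mask.txt"
        write_mask(result.mask, mask_path, column_origin=fused.column_origin)
        artifacts["mask.txt"] = _sha256(mask_path)
        artifacts["mask.txt.json"] = _sha256(Path(str(mask_path) + ".json"))
        report_path = out / "selection.json"
        report_path.write_text(
            json.dumps(result.as_report(), sort_keys=True, indent=1) + "\n",
            encoding="utf-8",
        )
        artifacts["selection.json"] = _sha256(report_path)
        log.info(
            "select: %d → %d columns (%d%%) in %.2fs",
            result.d_in, result.d_out, result.reduction_pct, time.perf_counter() - t0,
        )

        stage = "evaluate"
        t0 = time.perf_counter()
        reports = []
        for seed in config.eval_seeds:
            for spec in config.classifiers:
                for mask in (None, result.mask):
                    rep = evaluate(
                        fused,
                        dataset.labels,
                        mask=mask,
                        spec=spec,
                        train_fraction=config.train_fraction,
                        seed=int(seed),
                    )
                    reports.append(rep.as_dict())
        eval_path = out / "evaluation.json"
        eval_path.write_text(
            json.dumps(reports, sort_keys=True, indent=1) + "\n", encoding="utf-8"
        )
        artifacts["evaluation.json"] = _sha256(eval_path)
        log.info("evaluate: %d reports in %.2fs", len(reports), time.perf_counter() - t0)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "config_sha256": _config_fingerprint(config),
        "selector_seed": config.selector.gwo.seed,
        "eval_seeds": list(config.eval_seeds),
        "n_evaluation_reports": len(reports),
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1) + "\n", encoding="utf-8"
    )
    return manifest
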