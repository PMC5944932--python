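"""End-to-end study runner and run configuration.

``run_full_study`` reproduces the complete validation loop on freshly
generated phantoms: build the object library, generate the binned
dataset, write images and exact ground truth, measure areas from the
images alone, calibrate the quadratic area-to-count mapping with the
one-image-per-bin held-out protocol, predict the count ratio for every
image, and score the predictions against ground truth.

A single top-level seed is fanned out to per-stage child seeds by fixed
offsets (library +1, dataset +2, held-out draw +3, all mod 2^31), so
each stage is independently reproducible and reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import agreement, estimator, mapping, ratios
from .errors import PhantomError, ProtocolError
from .objects import ObjectLibrary, build_procedural_library, load_library
from .phantom import (
    TABLE1_COUNTS,
    TABLE1_BINS,
    Phantom,
    PhantomSpec,
    generate_dataset,
    save_ground_truth,
    save_image,
)

log = logging.getLogger("ihcphantom")

_SEED_MOD = 2**31


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to rerun a study; round-trips through YAML."""

    seed: int = 0
    out_dir: str = "study_out"
    library_path: str | None = None  # procedural library when None
    n_positive: int = 50
    n_negative: int = 40
    design_counts: tuple[int, ...] = TABLE1_COUNTS
    canvas_size: int = 1000
    grid_n: int = 30
    total_nuclei: int = 900
    bg_low: int = 190
    bg_high: int = 250
    jitter: int = 11
    scale_range: tuple[float, float] = (0.8, 1.25)
    smoothing_sigma: float = 1.0
    log_level: str = "INFO"

    def spec_template(self) -> PhantomSpec:
        return PhantomSpec(
            canvas_size=self.canvas_size,
            grid_n=self.grid_n,
            bg_low=self.bg_low,
            bg_high=self.bg_high,
            jitter=self.jitter,
            total_nuclei=self.total_nuclei,
            scale_range=self.scale_range,
            smoothing_sigma=self.smoothing_sigma,
        )

    def stage_seed(self, offset: int) -> int:
        return (self.seed + offset) % _SEED_MOD

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["design_counts"] = list(self.design_counts)
        d["scale_range"] = list(self.scale_range)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text)
        if not isinstance(d, dict):
            raise PhantomError("config file must contain a mapping")
        if "design_counts" in d:
            d["design_counts"] = tuple(d["design_counts"])
        if "scale_range" in d:
            d["scale_range"] = tuple(d["scale_range"])
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise PhantomError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class StudyReport:
    """Key numbers and artifact paths of one full study run."""

    out_dir: Path
    n_images: int
    ccc_rn: float
    heldout_sd: float
    model: mapping.MappingModel
    truth_csv: Path
    estimates_csv: Path
    model_json: Path
    agreement_csv: Path


def _load_or_build_library(config: RunConfig) -> ObjectLibrary:
    if config.library_path is not None:
        return load_library(config.library_path)
    return build_procedural_library(
        seed=config.stage_seed(1),
        n_positive=config.n_positive,
        n_negative=config.n_negative,
    )


def _stage(name: str):
    """Decorator: abort with the stage name and seed on any stage error."""

    def wrap(fn):
        def inner(config, *args, **kwargs):
            try:
                return fn(config, *args, **kwargs)
            except PhantomError as exc:
                raise PhantomError(f"stage '{name}' (seed {config.seed}): {exc}") from exc

        return inner

    return wrap


@_stage("dataset")
def _generate(config: RunConfig, library: ObjectLibrary) -> list[Phantom]:
    design = list(zip(TABLE1_BINS, config.design_counts))
    return generate_dataset(
        design=design,
        seed=config.stage_seed(2),
        library=library,
        spec_template=config.spec_template(),
    )


def run_full_study(config: RunConfig) -> StudyReport:
    """Generate, measure, calibrate and score; write all artifacts to out_dir."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(config.to_yaml())

    log.info("building object library (seed %d)", config.stage_seed(1))
    library = _load_or_build_library(config)
    log.info("generating %d-bin dataset (seed %d)", len(config.design_counts), config.stage_seed(2))
    phantoms = _generate(config, library)
    image_ids = [f"img_{i:03d}" for i in range(len(phantoms))]
    for image_id, ph in zip(image_ids, phantoms):
        save_image(ph.image, out / "images" / f"{image_id}.png")
        save_ground_truth(
            ph.truth,
            out / "truth" / f"{image_id}.json",
            out / "truth" / f"{image_id}_mask.png",
        )

    truth_df = ratios.truth_table([p.truth for p in phantoms], image_ids)
    truth_csv = out / "ratios.csv"
    truth_df.to_csv(truth_csv, index=False)

    log.info("measuring areas from images")
    est_areas = np.array([estimator.estimate_areas(p.image) for p in phantoms])
    est_ra, est_rt = est_areas[:, 0], est_areas[:, 1]
    truth_rn = truth_df["r_n"].to_numpy()

    pairs = np.column_stack([est_ra, truth_rn])
    try:
        model, heldout = mapping.heldout_protocol(pairs, seed=config.stage_seed(3))
        heldout_sd = heldout.sd
        heldout.table.to_csv(out / "heldout.csv", index=False)
    except ProtocolError as exc:
        warnings.warn(
            f"held-out protocol not applicable ({exc}); fitting the mapping on all images",
            stacklevel=2,
        )
        model = mapping.fit_mapping(pairs)
        heldout_sd = float("nan")
    model_json = out / "model.json"
    model.save(model_json)

    pred_rn = mapping.predict_rn(model, est_ra)
    est_df = pd.DataFrame(
        {
            "image_id": image_ids,
            "reader_id": "algorithm",
            "r_n_est": pred_rn,
            "r_t_est": est_rt,
            "r_a_est": est_ra,
        }
    )
    estimates_csv = out / "estimates.csv"
    est_df.to_csv(estimates_csv, index=False)

    log.info("scoring the estimator against ground truth")
    reports = agreement.evaluate_panel(truth_df, est_df)
    agreement_csv = out / "agreement.csv"
    agreement.panel_summary_table(reports).to_csv(agreement_csv, index=False)
    ba = agreement.bland_altman(truth_rn, pred_rn)
    pd.DataFrame(
        {"image_id": image_ids, "mean": ba.means, "difference": ba.differences}
    ).to_csv(out / "bland_altman_algorithm.csv", index=False)

    ccc_rn = reports[("algorithm", "r_n")].ccc[0]
    summary = {
        "seed": config.seed,
        "n_images": len(phantoms),
        "ccc_rn": ccc_rn,
        "heldout_sd": heldout_sd,
        "mapping": model.to_dict(),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    log.info("CCC(r_n) = %.4f, held-out SD = %.3f%%", ccc_rn, heldout_sd)
    return StudyReport(
        out_dir=out,
        n_images=len(phantoms),
        ccc_rn=ccc_rn,
        heldout_sd=heldout_sd,
        model=model,
        truth_csv=truth_csv,
        estimates_csv=estimates_csv,
        model_json=model_json,
        agreement_csv=agreement_csv,
    )
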