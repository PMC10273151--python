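"""Dataset, model and configuration (de)serialisation.

On-disk dataset layout (one directory):

* ``manifest.json`` -- cohort metadata and one record per specimen
  (id, truth class, FS call, bench delay, group count);
* ``spectra.csv`` -- one row per spectrum: specimen_id, site,
  point_index, modality, replicate, then 1,025 intensity columns;
* ``grids.csv`` -- one row per modality with its 1,025 wavelengths (nm).

Intensities are written at full ``repr`` precision so a read-back is
bit-identical.  Readers validate structure (spectrum length, specimen
completeness, manifest/spectra id agreement) and raise
:class:`DatasetError` naming the offending specimen or row.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from .data import (
    SPECTRUM_LENGTH,
    FSCall,
    Modality,
    Site,
    SpectralClass,
    SpectralGroup,
    Specimen,
    Spectrum,
    WavelengthGrid,
)
from .model import ModelConfig, SplitSpec
from .nn import SpectralCNN
from .synthetic import GeneratorConfig

__all__ = [
    "DatasetError",
    "write_dataset",
    "read_dataset",
    "StudyConfig",
    "load_study_config",
    "save_study_config",
    "config_hash",
    "save_model",
    "load_model",
]

_INTENSITY_COLS = [f"i{k:04d}" for k in range(SPECTRUM_LENGTH)]


class DatasetError(ValueError):
    """Malformed on-disk dataset."""


def write_dataset(cohort: Sequence[Specimen], path: str | pathlib.Path) -> None:
    path = pathlib.Path(path)
    path.mkdir(parents=True, exist_ok=True)

    grids: dict[Modality, WavelengthGrid] = {}
    rows = []
    for s in cohort:
        for g in s.groups:
            for replicate, sp in enumerate(g.spectra, start=1):
                grids.setdefault(sp.modality, sp.grid)
                rows.append(
                    [s.specimen_id, g.site.value, g.point_index, sp.modality.value,
                     replicate, *sp.intensities.tolist()]
                )
    spectra = pd.DataFrame(
        rows,
        columns=["specimen_id", "site", "point_index", "modality", "replicate",
                 *_INTENSITY_COLS],
    )
    spectra.to_csv(path / "spectra.csv", index=False)

    grid_rows = [[m.value, *grids[m].points.tolist()] for m in grids]
    pd.DataFrame(grid_rows, columns=["modality", *_INTENSITY_COLS]).to_csv(
        path / "grids.csv", index=False
    )

    manifest = {
        "format": "specdx-dataset",
        "version": 1,
        "n_specimens": len(cohort),
        "specimens": [
            {
                "specimen_id": s.specimen_id,
                "truth_class": s.truth_class.value,
                "fs_call": None if s.fs_call is None else s.fs_call.value,
                "delay_minutes": s.delay_minutes,
                "n_groups": len(s.groups),
            }
            for s in cohort
        ],
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_dataset(path: str | pathlib.Path) -> tuple[list[Specimen], dict]:
    path = pathlib.Path(path)
    try:
        manifest = json.loads((path / "manifest.json").read_text())
    except FileNotFoundError as exc:
        raise DatasetError(f"missing manifest.json under {path}") from exc
    if manifest.get("format") != "specdx-dataset":
        raise DatasetError("manifest.json is not a specdx dataset manifest")

    grid_df = pd.read_csv(path / "grids.csv", float_precision="round_trip")
    grids: dict[Modality, WavelengthGrid] = {}
    for _, row in grid_df.iterrows():
        m = Modality(row["modality"])
        pts = row[_INTENSITY_COLS].to_numpy(dtype=float)
        grids[m] = WavelengthGrid(m, pts)

    spectra = pd.read_csv(path / "spectra.csv", float_precision="round_trip")
    missing = set(["specimen_id", "site", "point_index", "modality", "replicate"]) - set(
        spectra.columns
    )
    if missing:
        raise DatasetError(f"spectra.csv missing columns {sorted(missing)}")
    got_cols = [c for c in spectra.columns if c.startswith("i")]
    if got_cols != _INTENSITY_COLS:
        raise DatasetError(
            f"spectra.csv must carry exactly {SPECTRUM_LENGTH} intensity columns, "
            f"found {len(got_cols)}"
        )
    if spectra[_INTENSITY_COLS].isna().any().any():
        bad = int(spectra[_INTENSITY_COLS].isna().any(axis=1).idxmax())
        raise DatasetError(f"spectra.csv row {bad}: truncated or non-numeric spectrum")

    csv_ids = list(spectra["specimen_id"].drop_duplicates())
    manifest_ids = [rec["specimen_id"] for rec in manifest["specimens"]]
    if set(csv_ids) != set(manifest_ids):
        raise DatasetError(
            "specimen ids disagree between manifest.json and spectra.csv: "
            f"only-manifest={sorted(set(manifest_ids) - set(csv_ids))} "
            f"only-csv={sorted(set(csv_ids) - set(manifest_ids))}"
        )

    cohort = []
    by_id = dict(tuple(spectra.groupby("specimen_id", sort=False)))
    for rec in manifest["specimens"]:
        sid = rec["specimen_id"]
        sub = by_id[sid]
        groups = []
        for (site, point), gsub in sub.groupby(["site", "point_index"], sort=True):
            fl = gsub[gsub["modality"] == Modality.FLUORESCENCE.value].sort_values(
                "replicate"
            )
            rf = gsub[gsub["modality"] == Modality.REFLECTANCE.value]
            if len(fl) != 2 or len(rf) != 1:
                raise DatasetError(
                    f"specimen {sid} {site} point {point}: expected 2 fluorescence "
                    f"+ 1 reflectance spectra, found {len(fl)} + {len(rf)}"
                )
            groups.append(
                SpectralGroup(
                    point_index=int(point),
                    site=Site(site),
                    fluorescence=tuple(
                        Spectrum(
                            grids[Modality.FLUORESCENCE],
                            r[_INTENSITY_COLS].to_numpy(dtype=float),
                        )
                        for _, r in fl.iterrows()
                    ),
                    reflectance=Spectrum(
                        grids[Modality.REFLECTANCE],
                        rf.iloc[0][_INTENSITY_COLS].to_numpy(dtype=float),
                    ),
                )
            )
        cohort.append(
            Specimen(
                specimen_id=sid,
                truth_class=SpectralClass(rec["truth_class"]),
                groups=groups,
                fs_call=None if rec.get("fs_call") is None else FSCall(rec["fs_call"]),
                delay_minutes=float(rec.get("delay_minutes", 0.0)),
            )
        )
    return cohort, manifest


# ---------------------------------------------------------------------------
# Study configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class StudyConfig:
    """End-to-end settings for a full study replication run."""

    generator: GeneratorConfig = dataclasses.field(default_factory=GeneratorConfig)
    split: SplitSpec = dataclasses.field(default_factory=SplitSpec)
    model: ModelConfig = dataclasses.field(default_factory=ModelConfig)
    #: Validation-arm cohort size (the clinical validation arm used 40).
    validation_n: int = 40
    #: Operating threshold profile for the simulated validation arm.
    validation_threshold: str = "majority"
    #: Threshold profile for the shipped worked-example fixture.
    fixture_threshold: str = "strict"
    #: Bootstrap resamples for AUC confidence intervals in reports.
    bootstrap_b: int = 500
    seed: int = 0


def _to_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {getattr(k, "value", k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if hasattr(obj, "value"):
        return obj.value
    return obj


def study_config_to_dict(config: StudyConfig) -> dict:
    return _to_jsonable(config)


def _parse_generator(d: dict) -> GeneratorConfig:
    kwargs: dict[str, Any] = dict(d)
    if "class_mix" in kwargs:
        kwargs["class_mix"] = {
            SpectralClass(k): float(v) for k, v in kwargs["class_mix"].items()
        }
    if "grid_ranges" in kwargs:
        kwargs["grid_ranges"] = {
            Modality(k): tuple(v) for k, v in kwargs["grid_ranges"].items()
        }
    if "baselines" in kwargs:
        kwargs["baselines"] = {
            Modality(k): tuple(v) for k, v in kwargs["baselines"].items()
        }
    if "peaks" in kwargs:
        kwargs["peaks"] = {
            Modality(m): {
                SpectralClass(c): tuple(tuple(p) for p in plist)
                for c, plist in table.items()
            }
            for m, table in kwargs["peaks"].items()
        }
    if "focal_mixing" in kwargs:
        kwargs["focal_mixing"] = {
            SpectralClass(k): (tuple(v) if isinstance(v, (list, tuple)) else float(v))
            for k, v in kwargs["focal_mixing"].items()
        }
    if "delay_range" in kwargs:
        kwargs["delay_range"] = tuple(kwargs["delay_range"])
    return GeneratorConfig(**kwargs)


def study_config_from_dict(d: dict) -> StudyConfig:
    d = dict(d)
    gen = _parse_generator(d.pop("generator", {}))
    split_d = d.pop("split", {})
    model_d = d.pop("model", {})
    if "conv_channels" in model_d:
        model_d["conv_channels"] = tuple(model_d["conv_channels"])
    return StudyConfig(
        generator=gen,
        split=SplitSpec(**split_d),
        model=ModelConfig(**model_d),
        **d,
    )


def save_study_config(config: StudyConfig, path: str | pathlib.Path) -> None:
    pathlib.Path(path).write_text(
        yaml.safe_dump(study_config_to_dict(config), sort_keys=False)
    )


def load_study_config(path: str | pathlib.Path) -> StudyConfig:
    return study_config_from_dict(yaml.safe_load(pathlib.Path(path).read_text()) or {})


def config_hash(config: StudyConfig) -> str:
    """Stable short hash identifying a study configuration."""
    payload = json.dumps(study_config_to_dict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Model checkpoints
# ---------------------------------------------------------------------------

def save_model(results, path: str | pathlib.Path, extra: dict | None = None) -> None:
    """Write a fitted model: .npz weights + .json sidecar (config, history)."""
    path = pathlib.Path(path)
    np.savez(path, **results.net.state_dict())
    npz_path = path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
    sidecar = {
        "model_config": _to_jsonable(results.model.config),
        "history": results.history,
        "seed": results.seed,
        "n_train_groups": len(results.model.train_records),
    }
    if extra:
        sidecar.update(extra)
    npz_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_model(path: str | pathlib.Path):
    """Load a checkpoint into a results object usable for prediction.

    The returned object has no training/test records attached; it serves
    pure inference (``predict_records`` / ``score_cohort``).
    """
    from .model import InvasionClassifier, InvasionClassifierResults

    path = pathlib.Path(path)
    npz_path = path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
    sidecar = json.loads(npz_path.with_suffix(".json").read_text())
    mc = dict(sidecar["model_config"])
    mc["conv_channels"] = tuple(mc["conv_channels"])
    config = ModelConfig(**mc)
    net = SpectralCNN(config.net_config(), seed=sidecar.get("seed", 0))
    with np.load(npz_path) as state:
        net.load_state_dict({k: state[k] for k in state.files})
    model = InvasionClassifier.__new__(InvasionClassifier)
    model.config = config
    model.train_records = []
    model.test_records = []
    return InvasionClassifierResults(model, net, sidecar.get("history", []),
                                     sidecar.get("seed", 0))
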