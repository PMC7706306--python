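"""CSV/image formats, run configuration and end-to-end pipeline orchestration.

Schemas (all plain CSV with an ISO-8601 minute-resolution ``timestamp``):

* stem.csv        timestamp, diameter_mm
* env.csv         timestamp, ppfd, temperature, rh, vpd  (a ``lux`` column is
                  accepted instead of ``ppfd`` and converted on read)
* irrigation.csv  timestamp, volume_ml
* wilt.csv        timestamp, delta_wilt, up, down, masked_pixels
* image dirs      <plant>_<YYYYMMDD>-<HHMM>.png

``run_pipeline`` ties simulate -> quantify -> correlate -> regress into one
reproducible run and writes a manifest holding every tunable plus the seed.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import env_regression, lag_correlation, stem_processing, synthetic_data
from . import wilt_quantification as wq

SCHEMA_VERSION = 1

_FILENAME_RE = re.compile(r"^(?P<plant>.+)_(?P<date>\d{8})-(?P<hm>\d{4})\.(png|jpg|jpeg)$")


class SchemaError(ValueError):
    """A sensor CSV violates its schema; message names the offending row."""


_SCHEMAS = {
    "stem": {"required": ["timestamp", "diameter_mm"]},
    "env": {"required": ["timestamp"]},
    "irrigation": {"required": ["timestamp", "volume_ml"]},
    "wilt": {"required": ["timestamp", "delta_wilt"]},
}


def _parse_timestamps(df: pd.DataFrame, path) -> pd.DatetimeIndex:
    try:
        ts = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as err:
        raise SchemaError(f"{path}: unparseable timestamp ({err})") from err
    dup = ts.duplicated()
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0]) + 2  # 1-based + header
        raise SchemaError(f"{path}: duplicated timestamp at row {row}")
    if not ts.is_monotonic_increasing:
        row = int(np.flatnonzero(ts.diff().dt.total_seconds().to_numpy() < 0)[0]) + 2
        raise SchemaError(f"{path}: non-monotonic timestamp at row {row}")
    return pd.DatetimeIndex(ts)


def read_sensor_csv(path, schema: str):
    """Read a typed minute-resolution sensor CSV.

    Returns a Series (stem), DataFrame (env, wilt) or event DataFrame
    (irrigation).  Environment files carrying ``lux`` instead of ``ppfd`` get
    the PPFD channel derived on read (flagged in ``attrs['derived']``).
    """
    if schema not in _SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    df = pd.read_csv(path)
    missing = [c for c in _SCHEMAS[schema]["required"] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    index = _parse_timestamps(df, path)
    df = df.drop(columns=["timestamp"]).set_index(index)
    df.index.name = "timestamp"

    if schema == "stem":
        out = df["diameter_mm"].astype(float)
        out.attrs["gaps"] = _minute_gaps(out.index)
        return out
    if schema == "env":
        derived = []
        if "ppfd" not in df.columns:
            if "lux" not in df.columns:
                raise SchemaError(f"{path}: env needs a ppfd or lux column")
            df["ppfd"] = stem_processing.lux_to_ppfd(df["lux"].to_numpy(dtype=float))
            derived.append("ppfd from lux / 54")
        if "vpd" not in df.columns:
            if not {"temperature", "rh"} <= set(df.columns):
                raise SchemaError(f"{path}: env needs vpd or temperature+rh columns")
            df["vpd"] = synthetic_data.vpd_from_t_rh(
                df["temperature"].to_numpy(dtype=float), df["rh"].to_numpy(dtype=float)
            )
            derived.append("vpd from Tetens(temperature, rh)")
        df.attrs["derived"] = derived
        df.attrs["gaps"] = _minute_gaps(df.index)
        return df
    if schema == "irrigation":
        return df.reset_index()
    df.attrs["w"] = int(df["w"].iloc[0]) if "w" in df.columns else None
    return df


def _minute_gaps(index: pd.DatetimeIndex) -> list:
    if len(index) < 2:
        return []
    expected = pd.date_range(index[0], index[-1], freq="min")
    return list(expected.difference(index))


def write_stem_csv(stem: pd.Series, path) -> None:
    out = stem.rename("diameter_mm").to_frame()
    out.insert(0, "timestamp", out.index.strftime("%Y-%m-%dT%H:%M"))
    out.to_csv(path, index=False)


def write_env_csv(env: pd.DataFrame, path) -> None:
    out = env.copy()
    out.insert(0, "timestamp", out.index.strftime("%Y-%m-%dT%H:%M"))
    out.to_csv(path, index=False)


def write_irrigation_csv(log: pd.DataFrame, path) -> None:
    out = log.copy()
    if "timestamp" in out.columns:
        out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M")
    out.to_csv(path, index=False)


def write_wilt_csv(wilt: pd.DataFrame, path) -> None:
    out = wilt.copy()
    out["w"] = wilt.attrs.get("w")
    out.insert(0, "timestamp", out.index.strftime("%Y-%m-%dT%H:%M"))
    out.to_csv(path, index=False)


def write_image_dir(images: wq.ImageSequence, path) -> None:
    """Write frames as ``<plant>_<YYYYMMDD>-<HHMM>.png``."""
    import imageio.v3 as iio

    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    for frame, ts in zip(images.frames, images.timestamps):
        name = f"{images.plant_id}_{ts.strftime('%Y%m%d-%H%M')}.png"
        iio.imwrite(outdir / name, frame)


def read_image_dir(path, size: int = wq.WORKING_SIZE) -> wq.ImageSequence:
    """Load a timestamped frame directory; resize mismatched frames to 144x144."""
    import imageio.v3 as iio

    entries = []
    plant = None
    for f in sorted(Path(path).iterdir()):
        m = _FILENAME_RE.match(f.name)
        if not m:
            continue
        ts = pd.Timestamp(f"{m['date']}T{m['hm']}")
        plant = m["plant"]
        entries.append((ts, f))
    if not entries:
        raise FileNotFoundError(f"no <plant>_<YYYYMMDD>-<HHMM> images under {path}")
    entries.sort()
    frames = []
    for _ts, f in entries:
        img = np.asarray(iio.imread(f))
        if img.ndim == 2:
            img = np.stack([img] * 3, axis=-1)
        frames.append(wq._resize_frame(img[..., :3], size=size))
    timestamps = pd.DatetimeIndex([ts for ts, _ in entries])
    return wq.ImageSequence(
        frames=np.stack(frames), timestamps=timestamps, plant_id=plant,
        gaps=_minute_gaps(timestamps),
    )


@dataclass
class RunConfig:
    """Everything a reproducible pipeline run depends on."""

    scenario: synthetic_data.ScenarioConfig | None = None
    image_dir: str | None = None
    stem_csv: str | None = None
    env_csv: str | None = None
    w: int = 5
    max_lag: int = 60
    flow_method: str = "block_match"
    use_flow_fast_path: bool = True  # scenario runs: synthetic flow fields vs rendering
    exg_threshold: float = 0.0
    t_rsr: float = 0.9975
    sunrise_ppfd: float = stem_processing.SUNRISE_PPFD
    outdir: str = "results"
    seed: int = 0
    plant_id: str = "plant1"

    def __post_init__(self):
        has_real = self.stem_csv is not None
        has_scenario = self.scenario is not None
        if has_real == has_scenario:
            raise ValueError("exactly one of real-input paths or scenario must be set")


@dataclass
class ResultsBundle:
    summary: pd.DataFrame
    regressions: pd.DataFrame
    wilt: pd.DataFrame
    delta_stem: pd.Series
    correlograms: pd.DataFrame
    skipped: list = field(default_factory=list)
    manifest: dict = field(default_factory=dict)


def _manifest(config: RunConfig) -> dict:
    def encode(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            obj = dataclasses.asdict(obj)
        if isinstance(obj, dict):
            return {k: encode(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [encode(v) for v in obj]
        return str(obj) if not isinstance(obj, (int, float, str, bool, type(None))) else obj

    import wiltlag

    return {
        "schema_version": SCHEMA_VERSION,
        "package_version": wiltlag.__version__,
        "config": encode(config),
    }


def run_pipeline(config: RunConfig) -> ResultsBundle:
    """Execute simulate -> quantify -> correlate -> regress and write outputs."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.scenario is not None:
        scenario = dataclasses.replace(config.scenario, seed=config.seed)
        images = "flows" if config.use_flow_fast_path else "frames"
        dataset = synthetic_data.generate_dataset(scenario, images=images, w=config.w)
        env = dataset.env
        stem = dataset.stem
        if config.use_flow_fast_path:
            wilt = wq.quantify_wilt_from_flows(dataset.flows)
        else:
            wilt = wq.quantify_wilt_series(
                dataset.frames, w=config.w, method=config.flow_method,
                exg_threshold=config.exg_threshold,
            )
    else:
        stem = read_sensor_csv(config.stem_csv, "stem")
        env = read_sensor_csv(config.env_csv, "env")
        if config.image_dir is None:
            raise ValueError("real-input run needs an image directory (missing stage: wilt)")
        images = read_image_dir(config.image_dir)
        wilt = wq.quantify_wilt_series(
            images, w=config.w, method=config.flow_method,
            exg_threshold=config.exg_threshold,
        )

    dstem = stem_processing.delta_stem(stem, w=config.w)
    summary, skipped = lag_correlation.summarize_days(
        [(config.plant_id, wilt["delta_wilt"], dstem)], env, max_lag=config.max_lag
    )

    gram_rows = []
    for _, row in summary.iterrows():
        pair = lag_correlation.align_day(
            wilt["delta_wilt"], dstem, row["date"], plant_id=row["plant"]
        )
        gram = lag_correlation.cross_correlation(pair, max_lag=config.max_lag)
        for lag, c, ci in zip(gram.lags, gram.c, gram.ci99):
            gram_rows.append(
                {"plant": row["plant"], "date": row["date"], "lag_min": int(lag),
                 "c": c, "ci99": ci}
            )
    correlograms = pd.DataFrame(gram_rows)

    reg_rows = []
    if len(summary) >= 6:
        for response in ("r_max", "l_max"):
            for predictor in ("mean_ppfd", "mean_vpd"):
                x = summary[predictor].to_numpy()
                y = summary[response].to_numpy(dtype=float)
                try:
                    chosen = env_regression.select_model(x, y)
                except env_regression.FitError as err:
                    skipped.append(f"regression {response}~{predictor}: {err}")
                    continue
                for family in env_regression.FAMILIES:
                    try:
                        fit = env_regression.fit_family(x, y, family)
                    except env_regression.FitError:
                        continue
                    reg_rows.append(
                        {"response": response, "predictor": predictor,
                         "family": family, "params": json.dumps(fit.params),
                         "r2": fit.r_squared, "p": fit.p_value, "n": fit.n,
                         "selected": family == chosen.family}
                    )
    regressions = pd.DataFrame(reg_rows)

    manifest = _manifest(config)
    manifest["skipped"] = skipped

    write_wilt_csv(wilt, outdir / "wilt.csv")
    dstem_out = dstem.rename("delta_mm").to_frame()
    dstem_out.insert(0, "timestamp", dstem_out.index.strftime("%Y-%m-%dT%H:%M"))
    dstem_out.to_csv(outdir / "delta_stem.csv", index=False)
    summary.to_csv(outdir / "summary.csv", index=False)
    correlograms.to_csv(outdir / "correlograms.csv", index=False)
    regressions.to_csv(outdir / "regression.csv", index=False)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    return ResultsBundle(
        summary=summary, regressions=regressions, wilt=wilt, delta_stem=dstem,
        correlograms=correlograms, skipped=skipped, manifest=manifest,
    )
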