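"""Trial-bundle discovery and format I/O.

A trial is one directory holding a single ``metadata.json`` plus the
modality files it references (multi-page TIFF or PNG sequence for frames,
WAV or CSV for sound in Pa, CSV for pressure in kPa). One directory per
trial is the canonical layout: synchronization bugs are the main hazard
in multimodal pipelines, so loose files are rejected and the metadata is
validated on load.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import SchemaError
from .segmentation import FrameStack
from .signals import PressureTrace, SoundTrace

REQUIRED_METADATA = (
    "fps", "sound_fs", "pressure_fs", "pixel_scale", "rotation_deg",
    "gray_threshold", "video_t0", "mode",
)


@dataclass
class TrialBundle:
    """A validated on-disk trial."""

    trial_id: str
    path: Path
    metadata: dict
    frames_path: Path | None
    sound_path: Path
    pressure_path: Path

    @property
    def has_video(self) -> bool:
        return self.frames_path is not None

    def load_frames(self) -> FrameStack:
        import tifffile

        pixels = tifffile.imread(self.frames_path)
        if pixels.ndim == 2:
            pixels = pixels[None]
        return FrameStack(pixels, fps=self.metadata["fps"],
                          pixel_scale=self.metadata["pixel_scale"],
                          t0=self.metadata.get("video_t0") or 0.0)

    def load_sound(self) -> SoundTrace:
        if self.sound_path.suffix.lower() == ".wav":
            from scipy.io import wavfile

            fs, samples = wavfile.read(self.sound_path)
            samples = np.asarray(samples, dtype=float)
            if samples.dtype != float:
                samples = samples.astype(float)
        else:
            import pandas as pd

            df = pd.read_csv(self.sound_path)
            fs, samples = self.metadata["sound_fs"], df.iloc[:, -1].to_numpy(float)
        if abs(fs - self.metadata["sound_fs"]) > 1e-6:
            raise SchemaError(
                f"sound file rate {fs} != metadata sound_fs {self.metadata['sound_fs']}"
            )
        return SoundTrace(samples, fs=float(fs))

    def load_pressure(self) -> PressureTrace:
        import pandas as pd

        df = pd.read_csv(self.pressure_path)
        return PressureTrace(df["pressure_kPa"].to_numpy(float),
                             fs=self.metadata["pressure_fs"])


def load_trial(path) -> TrialBundle:
    """Validate and load a trial directory.

    Raises :class:`SchemaError` naming the first missing metadata field,
    and on a sampling-rate mismatch between sound and pressure.
    """
    path = Path(path)
    meta_path = path / "metadata.json"
    if not meta_path.exists():
        raise SchemaError(f"no metadata.json in {path}")
    metadata = json.loads(meta_path.read_text())
    for key in REQUIRED_METADATA:
        if key not in metadata:
            raise SchemaError(f"metadata missing required field '{key}'")
    if metadata["sound_fs"] != metadata["pressure_fs"]:
        raise SchemaError(
            f"sound_fs {metadata['sound_fs']} != pressure_fs "
            f"{metadata['pressure_fs']}: modalities must share one clock"
        )
    for key in ("fps", "sound_fs", "pressure_fs", "pixel_scale"):
        if metadata[key] is not None and not metadata[key] > 0:
            raise SchemaError(f"metadata field '{key}' must be positive")

    frames_path = path / "frames.tif"
    has_video = metadata.get("has_video", frames_path.exists())
    if has_video and not frames_path.exists():
        raise SchemaError(f"metadata declares video but {frames_path} is missing")
    sound_path = path / "sound.wav"
    if not sound_path.exists():
        sound_path = path / "sound.csv"
    if not sound_path.exists():
        raise SchemaError(f"no sound.wav or sound.csv in {path}")
    pressure_path = path / "pressure.csv"
    if not pressure_path.exists():
        raise SchemaError(f"no pressure.csv in {path}")
    return TrialBundle(
        trial_id=metadata.get("trial_id", path.name), path=path,
        metadata=metadata, frames_path=frames_path if has_video else None,
        sound_path=sound_path, pressure_path=pressure_path,
    )
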