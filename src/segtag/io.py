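"""File formats: lexicon TSV, trial container (HDF5), WAV, ROI JSON, config YAML."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .lexicon import Lexicon, Syllable, WordEntry
from .simulate import SimulationConfig, TrialDataset

__all__ = ["write_lexicon_tsv", "read_lexicon_tsv", "write_trials_h5",
           "read_trials_h5", "write_wav", "write_rois_json", "read_rois_json",
           "load_config_yaml"]

_LEX_COLUMNS = ["syllable1", "syllable2", "frequency"]
_SYL_COLUMNS = ["syllable", "onset", "nucleus", "coda", "cv_pattern", "manner"]


def write_lexicon_tsv(lexicon: Lexicon, path: str | Path) -> None:
    """Write entries plus per-syllable phoneme annotation columns (UTF-8 TSV)."""
    syl = lexicon.syllables
    rows = []
    for e in lexicon.entries:
        row = {"syllable1": e.syllable1, "syllable2": e.syllable2,
               "frequency": e.frequency}
        for pos, lab in (("1", e.syllable1), ("2", e.syllable2)):
            s = syl[lab]
            row.update({f"onset{pos}": s.onset, f"nucleus{pos}": s.nucleus,
                        f"coda{pos}": s.coda, f"cv_pattern{pos}": s.cv_pattern,
                        f"manner{pos}": s.manner})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_lexicon_tsv(path: str | Path, profile: str = "native_like") -> Lexicon:
    df = pd.read_csv(path, sep="\t", encoding="utf-8",
                     keep_default_na=False, dtype=str)
    for col in _LEX_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"lexicon TSV is missing required column {col!r}")
    syllables: dict[str, Syllable] = {}
    entries = []
    for _, r in df.iterrows():
        for pos in ("1", "2"):
            lab = r[f"syllable{pos}"]
            if lab not in syllables:
                syllables[lab] = Syllable(lab, r[f"onset{pos}"],
                                          r[f"nucleus{pos}"], r[f"coda{pos}"])
        entries.append(WordEntry(r["syllable1"], r["syllable2"],
                                 int(r["frequency"])))
    return Lexicon(entries, syllables, profile)


def write_trials_h5(dataset: TrialDataset, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=dataset.data, compression="gzip")
        f.create_dataset("envelope", data=dataset.envelope, compression="gzip")
        f.create_dataset("condition",
                         data=np.asarray(dataset.condition, dtype="S"))
        f.create_dataset("correct_response", data=dataset.correct_response)
        f.create_dataset("block_index", data=dataset.block_index)
        f.attrs["fs_hz"] = dataset.fs_hz
        f.attrs["t_start_s"] = dataset.t_start_s


def read_trials_h5(path: str | Path) -> TrialDataset:
    with h5py.File(path, "r") as f:
        return TrialDataset(
            data=f["data"][()], envelope=f["envelope"][()],
            condition=f["condition"][()].astype(str),
            fs_hz=float(f.attrs["fs_hz"]), t_start_s=float(f.attrs["t_start_s"]),
            correct_response=f["correct_response"][()].astype(bool),
            block_index=f["block_index"][()].astype(int))


def write_wav(path: str | Path, waveform: np.ndarray, fs_hz: float) -> None:
    """16-bit PCM mono WAV, peak-normalized if needed."""
    from scipy.io import wavfile

    x = np.asarray(waveform, float)
    peak = np.abs(x).max()
    if peak > 1.0:
        x = x / peak
    wavfile.write(path, int(fs_hz), (x * 32767).astype(np.int16))


def write_rois_json(rois: dict[str, np.ndarray], path: str | Path) -> None:
    Path(path).write_text(json.dumps({k: [int(i) for i in v]
                                      for k, v in rois.items()}, indent=1))


def read_rois_json(path: str | Path) -> dict[str, np.ndarray]:
    raw = json.loads(Path(path).read_text())
    return {k: np.asarray(v, int) for k, v in raw.items()}


def load_config_yaml(path: str | Path) -> SimulationConfig:
    """SimulationConfig from a YAML mapping of its fields."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "epoch_window_s" in raw:
        raw["epoch_window_s"] = tuple(raw["epoch_window_s"])
    return SimulationConfig(**raw)
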