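"""Domain containers and on-disk formats.

Recordings travel as SNIRF (the HDF5-based fNIRS interchange layout) or as
wide CSV (time column first, then one column per channel/wavelength named
``LABEL@WAVELENGTH``).  Tabular results are plain UTF-8 CSV with a header
row and "." decimals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .montage import Montage, default_montage

__all__ = [
    "FnirsRecording",
    "TaskDesign",
    "Block",
    "Trial",
    "make_task_design",
    "read_recording",
    "write_recording",
    "write_table",
    "read_table",
    "FormatError",
]

#: Operating wavelengths (nm) of the dual-wavelength instrument.
WAVELENGTHS_NM = (760.0, 850.0)
#: Default sampling rate (Hz).
FS_HZ = 3.9
#: n-back block duration (s).
BLOCK_DURATION_S = 72.0
#: The four n-back conditions, in presentation order.
CONDITIONS = ("0b_1", "0b_2", "1b", "2b")


class FormatError(ValueError):
    """A file did not conform to the expected layout."""


@dataclass
class FnirsRecording:
    """Dual-wavelength intensity time series over a montage.

    ``intensities`` has shape (n_channels, n_wavelengths, n_time) and is
    dimensionless (relative to source power).
    """

    intensities: np.ndarray
    wavelengths_nm: tuple[float, float] = WAVELENGTHS_NM
    fs_hz: float = FS_HZ
    montage: Montage = field(default_factory=default_montage)
    quality_mask: np.ndarray | None = None  # True = good channel
    ground_truth: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be (channels, wavelengths, time)")
        n_ch, n_wl, _ = self.intensities.shape
        if len(set(self.wavelengths_nm)) != 2 or n_wl != 2:
            raise ValueError("exactly two distinct wavelengths are required")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if n_ch != self.montage.n_channels:
            raise ValueError(
                f"{n_ch} channels in data but montage defines {self.montage.n_channels}"
            )
        if self.quality_mask is None:
            self.quality_mask = np.ones(n_ch, dtype=bool)

    @property
    def n_time(self) -> int:
        return self.intensities.shape[2]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_time) / self.fs_hz


@dataclass(frozen=True)
class Trial:
    stimulus: str
    is_target: bool
    onset_s: float


@dataclass(frozen=True)
class Block:
    condition: str
    onset_s: float
    duration_s: float = BLOCK_DURATION_S
    trials: tuple[Trial, ...] = ()


@dataclass(frozen=True)
class TaskDesign:
    """Ordered n-back blocks with per-block trial streams."""

    blocks: tuple[Block, ...]

    def __post_init__(self) -> None:
        onsets = [b.onset_s for b in self.blocks]
        if any(b2 <= b1 for b1, b2 in zip(onsets, onsets[1:])):
            raise ValueError("block onsets must be strictly increasing")
        bad = [b.condition for b in self.blocks if b.condition not in CONDITIONS]
        if bad:
            raise ValueError(f"unknown conditions: {bad}")

    @property
    def conditions(self) -> list[str]:
        return [b.condition for b in self.blocks]

    @property
    def duration_s(self) -> float:
        last = self.blocks[-1]
        return last.onset_s + last.duration_s

    def block(self, condition: str) -> Block:
        for b in self.blocks:
            if b.condition == condition:
                return b
        raise KeyError(condition)


_LETTERS = "ABDEHKMRSTX"


def make_task_design(
    rest_s: float = 20.0,
    lead_in_s: float = 10.0,
    trials_per_block: int = 24,
    target_rate: float = 0.3,
    seed: int = 0,
) -> TaskDesign:
    """Standard single-session paradigm: 0b_1, 0b_2, 1b, 2b blocks of 72 s.

    Trial streams are constructed so that the requested fraction of trials
    are targets under each condition's rule (a "W" for 0-back, immediate
    repeats for 1-back, every-other repeats for 2-back).
    """
    rng = np.random.default_rng(seed)
    isi = BLOCK_DURATION_S / trials_per_block
    blocks = []
    t = lead_in_s
    for cond in CONDITIONS:
        letters: list[str] = []
        targets: list[bool] = []
        for i in range(trials_per_block):
            make_target = bool(rng.random() < target_rate)
            if cond.startswith("0b"):
                if make_target:
                    letters.append("W")
                else:
                    letters.append(rng.choice([c for c in _LETTERS if c != "W"]))
                targets.append(make_target)
            else:
                lag = 1 if cond == "1b" else 2
                if make_target and i >= lag:
                    letters.append(letters[i - lag])
                    targets.append(True)
                else:
                    prev = letters[i - lag] if i >= lag else None
                    choice = rng.choice([c for c in _LETTERS if c != prev])
                    letters.append(choice)
                    targets.append(False)
        trials = tuple(
            Trial(stimulus=s, is_target=tg, onset_s=t + i * isi)
            for i, (s, tg) in enumerate(zip(letters, targets))
        )
        blocks.append(Block(condition=cond, onset_s=t, trials=trials))
        t += BLOCK_DURATION_S + rest_s
    return TaskDesign(blocks=tuple(blocks))


# ---------------------------------------------------------------------------
# recording I/O
# ---------------------------------------------------------------------------

def write_recording(rec: FnirsRecording, path: str | Path, format: str = "snirf") -> Path:
    path = Path(path)
    if format == "snirf":
        _write_snirf(rec, path)
    elif format == "csv":
        _write_csv(rec, path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def read_recording(
    path: str | Path, format: str | None = None, montage: Montage | None = None
) -> FnirsRecording:
    """Read a recording from SNIRF or wide CSV.

    Channels listed in the montage but absent from a CSV file are kept in
    the array (as NaN) and flagged poor in ``quality_mask``.
    """
    path = Path(path)
    if format is None:
        format = "snirf" if path.suffix.lower() == ".snirf" else "csv"
    if format == "snirf":
        return _read_snirf(path)
    if format == "csv":
        return _read_csv(path, montage or default_montage())
    raise ValueError(f"unknown format {format!r}")


def _write_snirf(rec: FnirsRecording, path: Path) -> None:
    n_ch, _, n_t = rec.intensities.shape
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("LengthUnit", data="cm")
        meta.create_dataset("TimeUnit", data="s")
        meta.create_dataset("FrequencyUnit", data="Hz")
        data = nirs.create_group("data1")
        # SNIRF stores (time, measurement); measurements = channel-major pairs
        ts = rec.intensities.reshape(n_ch * 2, n_t).T
        data.create_dataset("dataTimeSeries", data=ts)
        data.create_dataset("time", data=rec.times)
        src_index = {s: i + 1 for i, s in enumerate(rec.montage.sources)}
        det_index = {d: i + 1 for i, d in enumerate(rec.montage.detectors)}
        m = 1
        for (s, d, _label) in rec.montage.channels:
            for wl in (1, 2):
                ml = data.create_group(f"measurementList{m}")
                ml.create_dataset("sourceIndex", data=src_index[s])
                ml.create_dataset("detectorIndex", data=det_index[d])
                ml.create_dataset("wavelengthIndex", data=wl)
                ml.create_dataset("dataType", data=1)
                ml.create_dataset("dataTypeIndex", data=1)
                m += 1
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(rec.wavelengths_nm))
        probe.create_dataset(
            "sourceLabels", data=np.array(rec.montage.sources, dtype=object),
            dtype=h5py.string_dtype(),
        )
        probe.create_dataset(
            "detectorLabels", data=np.array(rec.montage.detectors, dtype=object),
            dtype=h5py.string_dtype(),
        )


def _read_snirf(path: Path) -> FnirsRecording:
    with h5py.File(path, "r") as f:
        if "nirs" not in f:
            raise FormatError(f"{path}: missing /nirs group")
        nirs = f["nirs"]
        if "data1" not in nirs or "probe" not in nirs:
            raise FormatError(f"{path}: missing /nirs/data1 or /nirs/probe")
        wavelengths = np.asarray(nirs["probe"]["wavelengths"])
        if wavelengths.size != 2:
            raise FormatError(
                f"{path}: expected 2 wavelengths, found {wavelengths.size}"
            )
        src = [s.decode() if isinstance(s, bytes) else str(s)
               for s in nirs["probe"]["sourceLabels"][()]]
        det = [d.decode() if isinstance(d, bytes) else str(d)
               for d in nirs["probe"]["detectorLabels"][()]]
        data = nirs["data1"]
        ts = np.asarray(data["dataTimeSeries"])
        time = np.asarray(data["time"])
        keys = sorted(
            (k for k in data.keys() if k.startswith("measurementList")),
            key=lambda k: int(k[len("measurementList"):]),
        )
        if len(keys) != ts.shape[1]:
            raise FormatError(f"{path}: measurementList count != data columns")
        pairs: list[tuple[str, str]] = []
        for k in keys[::2]:
            ml = data[k]
            s = src[int(ml["sourceIndex"][()]) - 1]
            d = det[int(ml["detectorIndex"][()]) - 1]
            pairs.append((s, d))
        fs = 1.0 / float(np.median(np.diff(time)))
    base = default_montage()
    if [(c[0], c[1]) for c in base.channels] == pairs:
        montage = base
    else:
        labels = [f"{s}-{d}" for s, d in pairs]
        montage = Montage(
            sources=tuple(src), detectors=tuple(det),
            channels=tuple((s, d, f"{s}-{d}") for s, d in pairs),
            separation_cm=tuple(3.0 for _ in pairs),
            ldlpfc_labels=tuple(l for l in base.ldlpfc_labels if l in labels)
            or (labels[0],),
        )
    n_ch = len(pairs)
    intensities = ts.T.reshape(n_ch, 2, -1)
    return FnirsRecording(
        intensities=intensities,
        wavelengths_nm=(float(wavelengths[0]), float(wavelengths[1])),
        fs_hz=fs,
        montage=montage,
    )


def _col(label: str, wl: float) -> str:
    return f"{label}@{wl:g}"


def _write_csv(rec: FnirsRecording, path: Path) -> None:
    cols = {"time_s": rec.times}
    for i, label in enumerate(rec.montage.labels):
        for j, wl in enumerate(rec.wavelengths_nm):
            cols[_col(label, wl)] = rec.intensities[i, j]
    pd.DataFrame(cols).to_csv(path, index=False)


def _read_csv(path: Path, montage: Montage) -> FnirsRecording:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise FormatError(f"{path}: missing 'time_s' column")
    wavelengths = sorted(
        {float(c.split("@")[1]) for c in df.columns if "@" in c}
    )
    if len(wavelengths) != 2:
        raise FormatError(
            f"{path}: expected 2 wavelengths in header, found {len(wavelengths)}"
        )
    t = df["time_s"].to_numpy()
    fs = 1.0 / float(np.median(np.diff(t)))
    n_t = len(df)
    arr = np.full((montage.n_channels, 2, n_t), np.nan)
    mask = np.ones(montage.n_channels, dtype=bool)
    for i, label in enumerate(montage.labels):
        for j, wl in enumerate(wavelengths):
            name = _col(label, wl)
            if name in df.columns:
                arr[i, j] = df[name].to_numpy()
            else:
                mask[i] = False
    return FnirsRecording(
        intensities=arr,
        wavelengths_nm=(wavelengths[0], wavelengths[1]),
        fs_hz=fs,
        montage=montage,
        quality_mask=mask,
    )


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

def write_table(records, path: str | Path, format: str = "csv") -> Path:
    """Write homogeneous records (DataFrame or list of dicts) as CSV."""
    if format != "csv":
        raise ValueError("only csv is supported for tables")
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        records = list(records)
        if not records:
            raise ValueError("records must be nonempty")
        keys = list(records[0].keys())
        if any(list(r.keys()) != keys for r in records):
            raise ValueError("records must share fields")
        df = pd.DataFrame(records, columns=keys)
    if df.empty:
        raise ValueError("records must be nonempty")
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    # pipeline outputs carry a leading "# config_hash=..." comment line
    return pd.read_csv(path, comment="#")
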