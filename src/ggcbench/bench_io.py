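"""Reader/writer for the companion SEP dataset layout and a synthetic stand-in.

The benchmark recordings are distributed as MAT-files, one per animal, each
holding a structure named ``RAT`` with four fields: ``data`` (time x
channel x trial), ``dimord`` (a string describing the dimension order),
``times`` (per-sample time stamps in ms) and ``Fs`` (sampling rate in Hz).
The recordings are 15-channel epicranial somatosensory evoked potentials
sampled at 2000 Hz in epochs from -100 to +200 ms around whisker-stimulus
onset, with contralateral primary somatosensory cortex (cS1, channel 12)
the expected dominant driver at early latencies (5-20 ms) in the gamma
band, propagating to the surrounding channels 10 and 14.

``generate_synthetic_sep`` emulates exactly that layout and driving
structure so every downstream stage is testable without the real
recordings.  It is synthetic data: a stationary narrowband gamma kernel
under a post-onset decaying envelope on a 1/f background, not a recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import loadmat, savemat

from .mvar import TrialsArray
from .observation import _pink_noise

__all__ = [
    "RatRecording",
    "read_rat_mat",
    "write_rat_mat",
    "generate_synthetic_sep",
]

_FIELDS = ("data", "dimord", "times", "Fs")


@dataclass
class RatRecording:
    """One animal's trial-epoch recording in the RAT layout."""

    data: np.ndarray  # (time, channel, trial)
    dimord: str
    times: np.ndarray  # ms
    Fs: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float).ravel()
        if self.data.ndim != 3:
            raise ValueError("data must be 3-dimensional (time, channel, trial)")
        if self.data.shape[2] == 0:
            raise ValueError("recording has no trials")
        if len(self.times) != self.data.shape[0]:
            raise ValueError("times length must equal the first data dimension")
        dt_ms = np.diff(self.times)
        if len(dt_ms) and not np.allclose(dt_ms, dt_ms[0], rtol=1e-6, atol=0):
            raise ValueError("times must be uniformly spaced")
        if len(dt_ms):
            fs_from_times = 1000.0 / dt_ms[0]
            if abs(fs_from_times - self.Fs) > 1e-6 * self.Fs:
                raise ValueError(
                    f"Fs = {self.Fs} Hz inconsistent with times spacing "
                    f"({fs_from_times:.6f} Hz)"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    def to_trials(self, t_min_ms: float | None = None, t_max_ms: float | None = None) -> TrialsArray:
        """View (optionally a time window of) the recording as a TrialsArray."""
        lo = -np.inf if t_min_ms is None else t_min_ms
        hi = np.inf if t_max_ms is None else t_max_ms
        mask = (self.times >= lo) & (self.times <= hi)
        if not mask.any():
            raise ValueError("time window selects no samples")
        return TrialsArray(
            data=self.data[mask],
            sampling_rate=self.Fs,
            times=self.times[mask],
            time_unit="ms",
        )


def read_rat_mat(path) -> RatRecording:
    """Read a RAT-structure MAT-file (v7, with an HDF5 fallback for v7.3)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    contents = None
    try:
        contents = loadmat(path, simplify_cells=True)
    except NotImplementedError:
        # scipy refuses v7.3 (HDF5-backed) files
        data, dimord, times, fs = _read_rat_hdf5(path)
    except ValueError:
        import h5py

        if not h5py.is_hdf5(path):
            raise
        data, dimord, times, fs = _read_rat_hdf5(path)
    if contents is not None:
        if "RAT" not in contents:
            raise ValueError(f"{path} does not contain a structure named 'RAT'")
        rat = contents["RAT"]
        missing = [f for f in _FIELDS if f not in rat]
        if missing:
            raise ValueError(f"RAT structure is missing fields: {missing}")
        data = np.asarray(rat["data"], dtype=float)
        dimord = str(rat["dimord"])
        times = np.asarray(rat["times"], dtype=float).ravel()
        fs = float(np.asarray(rat["Fs"]).ravel()[0])
    if data.ndim == 2:  # single-trial files collapse the third dimension
        data = data[:, :, None]
    # verify dimension order: trust times length, falling back to dimord
    if data.shape[0] != len(times):
        if data.shape[-1] == len(times):
            data = data.transpose(2, 1, 0)
        else:
            raise ValueError(
                f"no data dimension matches the times vector "
                f"(data {data.shape}, times {len(times)}; dimord {dimord!r})"
            )
    return RatRecording(data=data, dimord=dimord, times=times, Fs=fs,
                        meta={"path": str(path)})


def _read_rat_hdf5(path: Path):
    """v7.3 MAT-files are HDF5; MATLAB stores arrays in reversed dim order."""
    import h5py

    with h5py.File(path, "r") as fh:
        if "RAT" not in fh:
            raise ValueError(f"{path} does not contain a structure named 'RAT'")
        grp = fh["RAT"]
        missing = [f for f in _FIELDS if f not in grp]
        if missing:
            raise ValueError(f"RAT structure is missing fields: {missing}")
        data = np.asarray(grp["data"]).T
        raw = np.asarray(grp["dimord"]).ravel()
        dimord = "".join(chr(int(c)) for c in raw)
        times = np.asarray(grp["times"]).ravel()
        fs = float(np.asarray(grp["Fs"]).ravel()[0])
    return data, dimord, times, fs


def write_rat_mat(rec: RatRecording, path) -> None:
    """Write a RAT-structure MAT-file (v7 dialect, re-readable by this module)."""
    savemat(
        str(path),
        {
            "RAT": {
                "data": rec.data,
                "dimord": rec.dimord,
                "times": rec.times,
                "Fs": float(rec.Fs),
            }
        },
    )


def _sub_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def generate_synthetic_sep(
    n_trials: int = 65,
    seed: int = 0,
    driver_channel: int = 12,
    target_channels: tuple[int, ...] = (10, 14),
    onset_ms: float = 5.0,
    gamma_hz: float = 60.0,
    lag_ms: float = 2.0,
    n_channels: int = 15,
    fs: float = 2000.0,
    t_start_ms: float = -100.0,
    t_stop_ms: float = 200.0,
    driver_gain: float = 3.0,
    target_gain: float = 1.5,
    envelope_tau_ms: float = 15.0,
) -> RatRecording:
    """Synthetic SEP-like fixture in the RAT layout.

    All channels carry independent unit-variance 1/f background noise.
    From ``onset_ms`` the driver channel carries a stochastic narrowband
    gamma oscillation (an AR(2) kernel at ``gamma_hz``) under an
    exponentially decaying envelope; each target channel receives an
    attenuated copy of the same oscillation delayed by ``lag_ms``, so the
    driver Granger-causes the targets with a short positive lag.
    """
    for ch in (driver_channel, *target_channels):
        if not 1 <= ch <= n_channels:
            raise ValueError(f"channel {ch} outside 1..{n_channels}")
    times = np.arange(t_start_ms, t_stop_ms + 1e-9, 1000.0 / fs)
    if not t_start_ms < onset_ms < t_stop_ms:
        raise ValueError("onset_ms must lie inside the epoch")
    n = len(times)
    lag = int(round(lag_ms * fs / 1000.0))
    data = np.empty((n, n_channels, n_trials))
    # AR(2) gamma kernel coefficients
    r = 0.97
    th = 2 * np.pi * gamma_hz / fs
    a1, a2 = 2 * r * np.cos(th), -(r**2)
    env = np.where(
        times >= onset_ms,
        np.exp(-np.maximum(times - onset_ms, 0.0) / envelope_tau_ms),
        0.0,
    )
    env_lagged = np.where(
        times >= onset_ms + lag_ms,
        np.exp(-np.maximum(times - onset_ms - lag_ms, 0.0) / envelope_tau_ms),
        0.0,
    )
    burn = 200
    for tr in range(n_trials):
        for ch in range(n_channels):  # background 1/f noise
            data[:, ch, tr] = _pink_noise(_sub_rng(seed, tr, ch), n)
        # shared narrowband gamma kernel for this trial
        w = _sub_rng(seed, tr, n_channels).standard_normal(n + burn + lag)
        g = np.zeros(n + burn + lag)
        for i in range(len(g)):
            g[i] = w[i]
            if i >= 1:
                g[i] += a1 * g[i - 1]
            if i >= 2:
                g[i] += a2 * g[i - 2]
        g = g / g.std()
        g_now = g[burn + lag :]
        g_del = g[burn : burn + n]
        data[:, driver_channel - 1, tr] += driver_gain * env * g_now
        for tgt in target_channels:
            data[:, tgt - 1, tr] += target_gain * env_lagged * g_del
    return RatRecording(
        data=data,
        dimord="time_chan_trial",
        times=times,
        Fs=fs,
        meta={"synthetic": True, "seed": seed, "driver_channel": driver_channel},
    )
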