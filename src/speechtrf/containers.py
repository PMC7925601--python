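"""EEG data containers, channel layouts and HDF5 persistence."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "EEGRecording",
    "ChannelLayout",
    "make_sphere_layout",
    "centroparietal_gain",
    "write_eeg_h5",
    "read_eeg_h5",
]

SCALP = "scalp"
MASTOID = "mastoid"


@dataclass
class EEGRecording:
    """One trial of multichannel EEG.

    data : channels x samples, finite reals.
    fs : sampling rate in Hz.
    channel_labels / channel_roles : per-channel metadata; roles are
        ``"scalp"`` or ``"mastoid"``.
    bad_mask : per-channel bad flag (True = contaminated).
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    channel_roles: list[str] = field(default_factory=list)
    bad_mask: np.ndarray | None = None
    subject_id: str = ""
    trial_id: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        n = self.data.shape[0]
        if not self.channel_labels:
            self.channel_labels = [f"ch{i:03d}" for i in range(n)]
        if not self.channel_roles:
            self.channel_roles = [SCALP] * n
        if self.bad_mask is None:
            self.bad_mask = np.zeros(n, dtype=bool)
        self.bad_mask = np.asarray(self.bad_mask, dtype=bool)
        if not (len(self.channel_labels) == len(self.channel_roles) == n == self.bad_mask.shape[0]):
            raise ValueError("channel metadata length mismatch")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray, fs: float | None = None) -> "EEGRecording":
        return replace(self, data=np.asarray(data, dtype=float), fs=fs or self.fs)

    def mastoid_indices(self) -> list[int]:
        return [i for i, r in enumerate(self.channel_roles) if r == MASTOID]

    def scalp_indices(self) -> list[int]:
        return [i for i, r in enumerate(self.channel_roles) if r == SCALP]


@dataclass
class ChannelLayout:
    """Per-channel unit-sphere sensor coordinates (n_channels x 3)."""

    positions: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be n_channels x 3")
        norms = np.linalg.norm(pos, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero-length position vector")
        self.positions = pos / norms[:, None]

    @property
    def n_channels(self) -> int:
        return self.positions.shape[0]


def make_sphere_layout(n_channels: int, n_mastoids: int = 2) -> tuple[ChannelLayout, list[str]]:
    """Quasi-uniform Fibonacci layout on the upper hemisphere.

    The last ``n_mastoids`` channels are placed low and lateral (behind the
    ears). Returns the layout and the per-channel role list.
    """
    n_scalp = n_channels - n_mastoids
    if n_scalp < 1:
        raise ValueError("need at least one scalp channel")
    i = np.arange(n_scalp)
    golden = (1 + 5**0.5) / 2
    theta = 2 * np.pi * i / golden
    # z spans the upper hemisphere (cap above z = 0.05)
    z = np.linspace(0.05, 0.95, n_scalp)
    r = np.sqrt(1 - z**2)
    pos = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    mastoids = np.array([[0.85, 0.45, -0.28], [-0.85, 0.45, -0.28]])[:n_mastoids]
    layout = ChannelLayout(np.vstack([pos, mastoids]))
    roles = [SCALP] * n_scalp + [MASTOID] * n_mastoids
    return layout, roles


def centroparietal_gain(layout: ChannelLayout, width: float = 0.8) -> np.ndarray:
    """Smooth gain profile peaking at a centro-parietal site.

    Gaussian in angular distance from a point midway between vertex and the
    back of the head; mastoid-depth channels receive near-zero gain.
    """
    peak = np.array([0.0, -0.45, 0.89])
    peak = peak / np.linalg.norm(peak)
    cosang = np.clip(layout.positions @ peak, -1.0, 1.0)
    ang = np.arccos(cosang)
    return np.exp(-0.5 * (ang / width) ** 2)


def write_eeg_h5(
    path: str | Path, recordings: Sequence[EEGRecording], group: str = "eeg"
) -> None:
    """Write trials as datasets ``<group>/trial<k>`` with fs/label/role attrs."""
    import h5py

    with h5py.File(path, "a") as fh:
        if group in fh:
            del fh[group]
        g = fh.create_group(group)
        for rec in recordings:
            d = g.create_dataset(f"trial{rec.trial_id}", data=rec.data)
            d.attrs["fs"] = rec.fs
            d.attrs["channel_labels"] = [s.encode() for s in rec.channel_labels]
            d.attrs["channel_roles"] = [s.encode() for s in rec.channel_roles]
            d.attrs["bad_mask"] = rec.bad_mask.astype(np.uint8)
            d.attrs["subject_id"] = rec.subject_id
            d.attrs["trial_id"] = rec.trial_id


def read_eeg_h5(path: str | Path, group: str = "eeg") -> list[EEGRecording]:
    import h5py

    out: list[EEGRecording] = []
    with h5py.File(path, "r") as fh:
        g = fh[group]
        for name in sorted(g):
            d = g[name]
            out.append(
                EEGRecording(
                    data=d[()],
                    fs=float(d.attrs["fs"]),
                    channel_labels=[
                        b.decode() if isinstance(b, bytes) else str(b)
                        for b in d.attrs["channel_labels"]
                    ],
                    channel_roles=[
                        b.decode() if isinstance(b, bytes) else str(b)
                        for b in d.attrs["channel_roles"]
                    ],
                    bad_mask=np.asarray(d.attrs["bad_mask"], dtype=bool),
                    subject_id=str(d.attrs["subject_id"]),
                    trial_id=int(d.attrs["trial_id"]),
                )
            )
    return out
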