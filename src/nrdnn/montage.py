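"""EEG trials, electrode montages and brain-region partitioning.

A trial is a ``channels x samples`` matrix with labelled rows.  A
:class:`RegionMap` assigns every channel of a montage to exactly one named
brain region (frontal, temporal, ...); :func:`partition_trial` slices a
trial into the per-region sub-matrices ``X^j`` that the per-region feature
extractors consume, alongside the untouched global matrix.

The 32-channel DEAP montage grouped into five regions ships with the
package (:func:`deap32_region_map`).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .exceptions import ConfigError, DataError, InvalidMapError, MontageMismatchError

__all__ = [
    "EEGTrial",
    "RegionMap",
    "RegionBundle",
    "partition_trial",
    "read_region_map",
    "write_region_map",
    "deap32_region_map",
]


@dataclass(frozen=True)
class EEGTrial:
    """One EEG trial: an ``m x t`` real matrix plus metadata.

    Parameters
    ----------
    data : ndarray, shape (m, t)
        Channel-by-sample signal, microvolt-scale arbitrary units.
    srate : float
        Sampling rate in Hz.
    channels : tuple of str
        Ordered channel labels, one per row of ``data``.
    subject : str
        Subject identifier.
    rating : float, optional
        Self-assessed valence rating in [1, 9].
    label : int, optional
        Binary class label in {+1, -1}.
    """

    data: np.ndarray
    srate: float
    channels: tuple
    subject: str = "S01"
    rating: Optional[float] = None
    label: Optional[int] = None

    def __post_init__(self):
        data = np.asarray(self.data, dtype=np.float64)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "channels", tuple(self.channels))
        if data.ndim != 2:
            raise DataError(f"trial data must be 2-D, got ndim={data.ndim}")
        m, t = data.shape
        if len(self.channels) != m:
            raise DataError(
                f"{len(self.channels)} channel labels for {m} data rows"
            )
        if len(set(self.channels)) != len(self.channels):
            raise DataError("duplicate channel labels within a trial")
        if not self.srate > 0:
            raise DataError(f"sampling rate must be positive, got {self.srate}")
        if t < 1:
            raise DataError("trial must contain at least one sample")
        if self.label is not None and self.label not in (-1, 1):
            raise DataError(f"label must be +1 or -1, got {self.label}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray, srate: Optional[float] = None) -> "EEGTrial":
        """Copy of this trial with new signal (and optionally new rate)."""
        return replace(self, data=data, srate=self.srate if srate is None else srate)


@dataclass(frozen=True)
class RegionMap:
    """Ordered assignment of channel labels to named brain regions.

    ``regions`` is a tuple of ``(name, (channel, ...))`` pairs.  Channel
    lists are pairwise disjoint; their union is the montage.  Within a
    region, the listed order is authoritative (it fixes the row order of
    every ``X^j``, independent of recording order).
    """

    regions: tuple

    def __post_init__(self):
        regions = tuple((str(name), tuple(chs)) for name, chs in self.regions)
        object.__setattr__(self, "regions", regions)
        if len(regions) < 1:
            raise InvalidMapError("a region map needs at least one region")
        names = [name for name, _ in regions]
        if len(set(names)) != len(names):
            raise InvalidMapError("duplicate region names")
        seen: dict = {}
        for name, chs in regions:
            if not chs:
                raise InvalidMapError(f"region {name!r} has no channels")
            for ch in chs:
                if ch in seen:
                    raise InvalidMapError(
                        f"channel {ch!r} assigned to both {seen[ch]!r} and {name!r}"
                    )
                seen[ch] = name

    @property
    def J(self) -> int:
        """Number of regions."""
        return len(self.regions)

    @property
    def names(self) -> tuple:
        return tuple(name for name, _ in self.regions)

    @property
    def channels(self) -> tuple:
        """All channels in region order (concatenation of the lists)."""
        return tuple(ch for _, chs in self.regions for ch in chs)

    @property
    def sizes(self) -> tuple:
        """Per-region channel counts (m_1, ..., m_J)."""
        return tuple(len(chs) for _, chs in self.regions)

    def channels_of(self, name: str) -> tuple:
        for rname, chs in self.regions:
            if rname == name:
                return chs
        raise KeyError(name)


@dataclass(frozen=True)
class RegionBundle:
    """A trial partitioned by brain region.

    ``parts[j]`` holds the rows of the source trial whose channels belong
    to region j, in the map's listed order; ``global_part`` is the full
    trial matrix.  Metadata is carried over unchanged.
    """

    parts: tuple
    global_part: np.ndarray
    region_names: tuple
    srate: float
    subject: str
    label: Optional[int] = None


def partition_trial(trial: EEGTrial, region_map: RegionMap) -> RegionBundle:
    """Split a trial into per-region sub-matrices plus the global matrix.

    Every channel the map names must occur in the trial; the partition
    covers each mapped channel exactly once, so the per-region row counts
    sum to the montage size.

    Raises
    ------
    MontageMismatchError
        If the map references a channel the trial does not carry.
    """
    index = {ch: i for i, ch in enumerate(trial.channels)}
    parts = []
    for name, chs in region_map.regions:
        rows = []
        for ch in chs:
            if ch not in index:
                raise MontageMismatchError(
                    f"montage channel {ch!r} (region {name!r}) not present in trial"
                )
            rows.append(index[ch])
        parts.append(trial.data[rows, :])
    return RegionBundle(
        parts=tuple(parts),
        global_part=trial.data,
        region_names=region_map.names,
        srate=trial.srate,
        subject=trial.subject,
        label=trial.label,
    )


def read_region_map(source) -> RegionMap:
    """Read a region map from a ``region,channel`` CSV file or stream.

    Region order is first-appearance order; channel order within a region
    follows the file.
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", newline="") as fh:
            return read_region_map(fh)
    reader = csv.reader(source)
    rows = [r for r in reader if r and any(cell.strip() for cell in r)]
    if not rows:
        raise ConfigError("empty montage file")
    if [c.strip().lower() for c in rows[0][:2]] == ["region", "channel"]:
        rows = rows[1:]
    order: list = []
    grouped: dict = {}
    for r in rows:
        if len(r) < 2:
            raise ConfigError(f"montage row needs region,channel: {r!r}")
        region, channel = r[0].strip(), r[1].strip()
        if region not in grouped:
            grouped[region] = []
            order.append(region)
        grouped[region].append(channel)
    return RegionMap(tuple((name, tuple(grouped[name])) for name in order))


def write_region_map(region_map: RegionMap, path) -> None:
    """Write a region map as a ``region,channel`` CSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["region", "channel"])
        for name, chs in region_map.regions:
            for ch in chs:
                writer.writerow([name, ch])


def deap32_region_map() -> RegionMap:
    """The packaged 32-channel DEAP montage grouped into 5 brain regions."""
    text = resources.files("nrdnn").joinpath("data/deap32.csv").read_text()
    return read_region_map(io.StringIO(text))
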