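"""32-channel 10–20 montage: positions, adjacency graph, posterior weighting.

Electrode coordinates come from the standard 10–20 template shipped with MNE,
restricted to the 32 channels of a g.Nautilus-style cap. All geometry is in
millimetres.
"""

from __future__ import annotations

import functools
import warnings

import numpy as np
import scipy.sparse as sp

#: Channel order used throughout the package (extended 10–20, 32 electrodes).
CHANNELS_32: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6",
    "P7", "P3", "Pz", "P4", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "O2",
)

#: Parieto-occipital region of interest used for grand averages and the
#: synthetic ERP spatial pattern.
POSTERIOR_ROI: tuple[str, ...] = ("P3", "Pz", "P4", "PO3", "PO4")


@functools.lru_cache(maxsize=4)
def channel_positions(channels: tuple[str, ...] = CHANNELS_32) -> np.ndarray:
    """Return 3-D electrode positions in mm, shape ``(n_channels, 3)``."""
    import mne  # deferred: mne import is slow

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mont = mne.channels.make_standard_montage("standard_1020")
    pos = mont.get_positions()["ch_pos"]
    missing = [c for c in channels if c not in pos]
    if missing:
        raise KeyError(f"channels not in the 10-20 template: {missing}")
    return np.array([pos[c] for c in channels]) * 1000.0


def channel_index(names, channels=CHANNELS_32) -> np.ndarray:
    """Indices of `names` within the montage channel order."""
    lookup = {c: i for i, c in enumerate(channels)}
    try:
        return np.array([lookup[n] for n in names], dtype=int)
    except KeyError as e:  # pragma: no cover - message only
        raise KeyError(f"unknown channel {e.args[0]!r}") from None


def channel_adjacency(radius_mm: float = 60.0,
                      channels: tuple[str, ...] = CHANNELS_32) -> sp.csr_matrix:
    """Boolean channel-neighbourhood graph: electrodes closer than `radius_mm`.

    Returned as a sparse symmetric matrix without self-loops; used as the
    spatial adjacency for TFCE over topographic statistic maps.
    """
    p = channel_positions(channels)
    d = np.linalg.norm(p[:, None] - p[None, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    return sp.csr_matrix(d < radius_mm)


def posterior_weights(sigma_mm: float = 55.0,
                      channels: tuple[str, ...] = CHANNELS_32) -> np.ndarray:
    """Smooth posterior spatial pattern peaking over the parieto-occipital ROI.

    A Gaussian fall-off (scale `sigma_mm`) from the ROI centroid, normalised
    so the ROI mean weight is 1. Used as the projection pattern of simulated
    ERP components and alpha oscillations.
    """
    p = channel_positions(channels)
    roi = channel_index(POSTERIOR_ROI, channels)
    center = p[roi].mean(axis=0)
    w = np.exp(-0.5 * (np.linalg.norm(p - center, axis=1) / sigma_mm) ** 2)
    return w / w[roi].mean()


def neighbor_map(radius_mm: float = 60.0,
                 channels: tuple[str, ...] = CHANNELS_32) -> dict[int, np.ndarray]:
    """Per-channel neighbour indices within `radius_mm` (for interpolation)."""
    adj = channel_adjacency(radius_mm, channels)
    return {i: adj[i].indices.copy() for i in range(adj.shape[0])}
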