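"""Electrode-mesh feature tensors for the CNN.

Each trial's channels x samples matrix is rearranged onto a fixed 10 x 11
scalp grid (anterior rows first, left columns first), giving a
trials x 10 x 11 x depth tensor.  Depth is either the 72 retained time
samples (spatiotemporal) or 5 band powers delta..gamma (spatio-spectral).
Grid cells with no electrode — "null electrodes" — are exactly zero at every
depth plane.

The channel -> cell assignment projects standard scalp positions onto the
grid by rank-binning the anteroposterior and lateral coordinates against the
full standard 10-05 reference montage; ties for a cell go to the nearest
free neighbor in a deterministic scan.  The layout is a versioned modeling
choice: classifier behavior depends on it, and no equivalence with any
particular historical grid is claimed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .epochs import EpochSet, META_COLUMNS
from .labels import HIGH, label_for_state
from .montage import REGIONS, positions_2d, standard_positions_2d

N_ROWS, N_COLS = 10, 11
TEMPORAL_DEPTH = 72
#: half-open band edges in Hz: delta, theta, alpha, beta, gamma
BAND_EDGES: tuple[tuple[float, float], ...] = (
    (1.5, 4.0), (4.0, 8.0), (8.0, 13.0), (13.0, 30.0), (30.0, 40.0),
)
BAND_NAMES = ("delta", "theta", "alpha", "beta", "gamma")
_NFFT = 1024

LAYOUT_VERSION = "grid-rankbin-1"


@dataclass(frozen=True)
class MeshLayout:
    """Injective channel -> (row, col) map onto the 10 x 11 grid."""

    mapping: dict[str, tuple[int, int]]
    region_sets: dict[str, tuple[str, ...]]
    n_rows: int = N_ROWS
    n_cols: int = N_COLS
    version: str = LAYOUT_VERSION

    def __post_init__(self) -> None:
        cells = list(self.mapping.values())
        if len(set(cells)) != len(cells):
            raise ValueError("layout mapping must be injective")
        for r, c in cells:
            if not (0 <= r < self.n_rows and 0 <= c < self.n_cols):
                raise ValueError(f"cell ({r}, {c}) outside the {self.n_rows}x{self.n_cols} grid")

    @property
    def null_cells(self) -> set[tuple[int, int]]:
        used = set(self.mapping.values())
        return {(r, c) for r in range(self.n_rows) for c in range(self.n_cols)} - used

    def to_json(self) -> str:
        return json.dumps({
            "version": self.version,
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "mapping": {k: list(v) for k, v in self.mapping.items()},
            "region_sets": {k: list(v) for k, v in self.region_sets.items()},
        })

    @classmethod
    def from_json(cls, s: str) -> "MeshLayout":
        d = json.loads(s)
        return cls(
            mapping={k: tuple(v) for k, v in d["mapping"].items()},
            region_sets={k: tuple(v) for k, v in d["region_sets"].items()},
            n_rows=d["n_rows"], n_cols=d["n_cols"], version=d["version"],
        )


def build_layout(channel_labels, extra_positions: dict | None = None) -> MeshLayout:
    """Deterministic 10 x 11 grid assignment for the given channels."""
    labels = list(channel_labels)
    if len(labels) > N_ROWS * N_COLS:
        raise ValueError(f"at most {N_ROWS * N_COLS} channels fit the grid, got {len(labels)}")
    pos = positions_2d(labels, extra=extra_positions)
    ref = np.array(list(standard_positions_2d().values()))
    ref_x = np.sort(ref[:, 0])
    ref_y = np.sort(ref[:, 1])
    n_ref = len(ref)

    def desired_cell(p: np.ndarray) -> tuple[int, int]:
        # anterior (large y) -> row 0; left (small x) -> col 0
        rank_y = n_ref - np.searchsorted(ref_y, p[1], side="left")
        rank_x = np.searchsorted(ref_x, p[0], side="left")
        row = min(N_ROWS - 1, int(rank_y * N_ROWS / (n_ref + 1)))
        col = min(N_COLS - 1, int(rank_x * N_COLS / (n_ref + 1)))
        return row, col

    # collision resolution scans channels in sorted-label order so the layout
    # is independent of channel order in the recording
    order = sorted(range(len(labels)), key=lambda i: labels[i])
    taken: set[tuple[int, int]] = set()
    mapping: dict[str, tuple[int, int]] = {}
    all_cells = [(r, c) for r in range(N_ROWS) for c in range(N_COLS)]
    for i in order:
        want = desired_cell(pos[i])
        if want not in taken:
            cell = want
        else:
            free = [cl for cl in all_cells if cl not in taken]
            cell = min(free, key=lambda cl: ((cl[0] - want[0]) ** 2 + (cl[1] - want[1]) ** 2, cl))
        taken.add(cell)
        mapping[labels[i]] = cell

    present = set(labels)
    regions = {name: tuple(ch for ch in chans if ch in present) for name, chans in REGIONS.items()}
    return MeshLayout(mapping=mapping, region_sets=regions)


@dataclass
class FeatureTensor:
    """CNN input: ``values[trial, row, col, depth]`` plus per-trial labels."""

    values: np.ndarray
    depth_kind: str                       # "temporal" or "spectral"
    layout: MeshLayout
    trial_meta: pd.DataFrame = field(repr=False)
    band_edges: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 4:
            raise ValueError("values must be trial x rows x cols x depth")
        want = TEMPORAL_DEPTH if self.depth_kind == "temporal" else len(BAND_EDGES)
        if self.depth_kind not in ("temporal", "spectral"):
            raise ValueError(f"depth_kind must be temporal or spectral, got {self.depth_kind!r}")
        if self.values.shape[3] != want:
            raise ValueError(f"{self.depth_kind} depth must be {want}, got {self.values.shape[3]}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature tensor contains non-finite values")
        if len(self.trial_meta) != self.values.shape[0]:
            raise ValueError("metadata rows do not match trial count")
        self.trial_meta = self.trial_meta.reset_index(drop=True)

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def depth(self) -> int:
        return self.values.shape[3]

    def component_labels(self, component: str) -> np.ndarray:
        """0/1 array: 1 where the trial's state is labeled high on the component."""
        states = self.trial_meta["state"]
        return np.array(
            [int(label_for_state(s).component(component) == HIGH) for s in states], dtype=int
        )

    def select_trials(self, index) -> "FeatureTensor":
        index = np.asarray(index)
        rows = np.flatnonzero(index) if index.dtype == bool else index
        return FeatureTensor(
            values=self.values[index].copy(),
            depth_kind=self.depth_kind,
            layout=self.layout,
            trial_meta=self.trial_meta.iloc[rows],
            band_edges=self.band_edges,
        )

    def session_key(self) -> pd.Series:
        m = self.trial_meta
        return m["participant_id"].astype(str) + "/" + m["session_id"].astype(str)


def _scatter(e: EpochSet, layout: MeshLayout, per_channel: np.ndarray, depth: int) -> np.ndarray:
    values = np.zeros((e.n_trials, layout.n_rows, layout.n_cols, depth), dtype=np.float32)
    for ch_i, lab in enumerate(e.channel_labels):
        if lab not in layout.mapping:
            raise ValueError(f"channel {lab!r} not present in the layout")
        r, c = layout.mapping[lab]
        values[:, r, c, :] = per_channel[:, ch_i, :]
    return values


def to_spatiotemporal(e: EpochSet, layout: MeshLayout) -> FeatureTensor:
    """Mesh tensor whose depth axis is the 72 retained time samples."""
    if e.n_samples != TEMPORAL_DEPTH:
        raise ValueError(
            f"spatiotemporal features need exactly {TEMPORAL_DEPTH} samples per trial "
            f"(a 200 ms window at 362.5 Hz); got {e.n_samples}"
        )
    return FeatureTensor(
        values=_scatter(e, layout, e.data, TEMPORAL_DEPTH),
        depth_kind="temporal",
        layout=layout,
        trial_meta=e.trial_meta,
    )


def band_powers(data: np.ndarray, srate_hz: float) -> np.ndarray:
    """Per-trial, per-channel periodogram power in the five canonical bands.

    Magnitude-squared FFT with zero padding to 1024 points, summed over
    in-band bins (half-open [lo, hi)).  The delta band (1.5-4 Hz) sits below
    the frequency resolution a 200 ms window supports; its value is dominated
    by spectral leakage and is computed for structural completeness only.
    """
    if data.shape[-1] < 2:
        raise ValueError("band powers need at least 2 samples per trial")
    spec = np.abs(np.fft.rfft(data, n=_NFFT, axis=-1)) ** 2
    freqs = np.fft.rfftfreq(_NFFT, d=1.0 / srate_hz)
    out = np.empty(data.shape[:-1] + (len(BAND_EDGES),), dtype=np.float64)
    for b, (lo, hi) in enumerate(BAND_EDGES):
        sel = (freqs >= lo) & (freqs < hi)
        out[..., b] = spec[..., sel].sum(axis=-1)
    return out


def to_spatiospectral(e: EpochSet, layout: MeshLayout) -> FeatureTensor:
    """Mesh tensor whose depth axis is band power in delta..gamma."""
    return FeatureTensor(
        values=_scatter(e, layout, band_powers(e.data, e.srate_hz), len(BAND_EDGES)),
        depth_kind="spectral",
        layout=layout,
        trial_meta=e.trial_meta,
        band_edges=BAND_EDGES,
    )


def reconstruct_channels(t: FeatureTensor, channel_labels) -> np.ndarray:
    """Invert the mesh scatter: trials x channels x depth matrix."""
    out = np.empty((t.n_trials, len(channel_labels), t.depth), dtype=t.values.dtype)
    for i, lab in enumerate(channel_labels):
        r, c = t.layout.mapping[lab]
        out[:, i, :] = t.values[:, r, c, :]
    return out


def write_tensor(path, t: FeatureTensor) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=t.values, track_times=False)
        g = f.create_group("meta")
        for col in META_COLUMNS:
            g.create_dataset(col, data=t.trial_meta[col].astype(str).to_numpy(dtype="S64"),
                             track_times=False)
        f.attrs["depth_kind"] = t.depth_kind
        f.attrs["layout"] = t.layout.to_json()
        if t.band_edges is not None:
            f.create_dataset("band_edges", data=np.array(t.band_edges), track_times=False)


def read_tensor(path) -> FeatureTensor:
    with h5py.File(path, "r") as f:
        meta = pd.DataFrame(
            {col: [v.decode() for v in f["meta"][col][()]] for col in META_COLUMNS}
        )
        band = tuple(map(tuple, f["band_edges"][()])) if "band_edges" in f else None
        return FeatureTensor(
            values=f["values"][()],
            depth_kind=str(f.attrs["depth_kind"]),
            layout=MeshLayout.from_json(str(f.attrs["layout"])),
            trial_meta=meta,
            band_edges=band,
        )
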