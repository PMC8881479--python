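"""Standard preprocessing for evoked / resting epochs.

The chain applies, in order: polyphase downsampling to 362.5 Hz, zero-phase
band-pass 0.5-45 Hz (Butterworth, order 2), segmentation to -400..1000 ms
around the pulse (evoked) or the 1-s segment (resting), baseline correction
over the 400 ms pre-pulse window, spherical-spline interpolation of an
explicitly supplied bad-channel list, rejection of any trial exceeding
+/-100 microvolts on a retained channel, and common-average re-referencing.

Bad channels are never auto-detected; interpolation requires an explicit
list.  Ocular ICA cleanup is supported only as a pluggable hook
(``ChainOptions.ica_hook``) operating on the epoch array.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Callable

import numpy as np
from scipy import signal

from .epochs import EpochSet, read_container, read_sidecar

TARGET_SRATE = 362.5
BAND_HZ = (0.5, 45.0)
FILTER_ORDER = 2
REJECT_UV = 100.0


@dataclass
class ChainOptions:
    target_srate: float = TARGET_SRATE
    band_hz: tuple[float, float] = BAND_HZ
    filter_order: int = FILTER_ORDER
    reject_uv: float = REJECT_UV
    bad_channels: tuple[str, ...] = ()
    baseline_ms: tuple[float, float] = (-400.0, 0.0)
    #: optional cleanup hook: f(data[trial, ch, sample], srate_hz) -> data
    ica_hook: Callable[[np.ndarray, float], np.ndarray] | None = None


@dataclass
class ChainLog:
    """Per-step bookkeeping of the preprocessing chain."""

    n_in: int = 0
    n_rejected: int = 0
    n_out: int = 0
    srate_in: float = 0.0
    srate_out: float = 0.0
    interpolated: tuple[str, ...] = ()
    steps: list[str] = field(default_factory=list)


def read_epochs(path, format: str, sidecar=None,
                epoch_window_ms: tuple[float, float] | None = None) -> EpochSet:
    """Read epoched EEG from a supported format into an EpochSet.

    ``container`` is the package HDF5 layout (bit-exact round trip with
    :func:`eci.epochs.write_container`).  ``fif`` reads MNE epochs files.
    ``edf`` and ``brainvision`` are continuous formats: a sidecar table with a
    per-trial ``onset_sample`` column is required to cut epochs, and
    ``epoch_window_ms`` gives the window around each onset (default 0-1000 ms).
    Trial metadata comes from the sidecar for every format that lacks it.
    """
    if format == "container":
        return read_container(path)

    import mne

    side = read_sidecar(sidecar) if sidecar is not None else None
    if format == "fif":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ep = mne.read_epochs(path, preload=True, verbose="error")
        data = ep.get_data(copy=True) * 1e6
        meta = side if side is not None else ep.metadata
        if meta is None:
            raise ValueError(
                "fif file carries no trial metadata; supply a sidecar with columns "
                "trial,participant_id,session_id,domain,state,modality"
            )
        return EpochSet(
            data=data,
            srate_hz=float(ep.info["sfreq"]),
            channel_labels=list(ep.ch_names),
            times_ms=ep.times * 1000.0,
            trial_meta=meta.reset_index(drop=True),
        )

    if format in ("edf", "brainvision"):
        reader = mne.io.read_raw_edf if format == "edf" else mne.io.read_raw_brainvision
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = reader(path, preload=True, verbose="error")
        if side is None:
            raise ValueError(
                f"{format} is a continuous format; a sidecar with columns "
                "trial,participant_id,session_id,domain,state,modality,onset_sample is required"
            )
        if "onset_sample" not in side.columns:
            raise ValueError("sidecar missing required columns: ['onset_sample']")
        lo_ms, hi_ms = epoch_window_ms if epoch_window_ms is not None else (0.0, 1000.0)
        sr = float(raw.info["sfreq"])
        cont = raw.get_data() * 1e6
        i_lo = int(round(lo_ms / 1000.0 * sr))
        n_sm = int(round((hi_ms - lo_ms) / 1000.0 * sr))
        trials = []
        for _, row in side.iterrows():
            start = int(row["onset_sample"]) + i_lo
            if start < 0 or start + n_sm > cont.shape[1]:
                raise ValueError(f"trial {int(row['trial'])} window falls outside the recording")
            trials.append(cont[:, start:start + n_sm])
        return EpochSet(
            data=np.stack(trials),
            srate_hz=sr,
            channel_labels=list(raw.ch_names),
            times_ms=lo_ms + np.arange(n_sm) / sr * 1000.0,
            trial_meta=side.drop(columns=["onset_sample"]).reset_index(drop=True),
        )

    raise ValueError(f"unknown format {format!r}; expected edf, brainvision, fif or container")


def _resample(e: EpochSet, target: float) -> EpochSet:
    if np.isclose(e.srate_hz, target):
        return e
    if e.srate_hz < target:
        raise ValueError(f"cannot downsample from {e.srate_hz} Hz to {target} Hz")
    frac = Fraction(target / e.srate_hz).limit_denominator(1000)
    out_blocks = []
    for lo in range(0, e.n_trials, 64):  # chunked: raw cohorts are large
        block = e.data[lo:lo + 64].astype(np.float64)
        out_blocks.append(signal.resample_poly(block, frac.numerator, frac.denominator, axis=2))
    data = np.concatenate(out_blocks, axis=0) if out_blocks else e.data[:, :, :0]
    n_out = data.shape[2]
    times = e.times_ms[0] + np.arange(n_out) / target * 1000.0
    return replace(e, data=data, srate_hz=target, times_ms=times)


def _bandpass(data: np.ndarray, srate: float, band: tuple[float, float], order: int) -> np.ndarray:
    sos = signal.butter(order, band, btype="bandpass", fs=srate, output="sos")
    return signal.sosfiltfilt(sos, data, axis=-1)


def _interpolate(e: EpochSet, bads: tuple[str, ...]) -> EpochSet:
    unknown = [b for b in bads if b not in e.channel_labels]
    if unknown:
        raise ValueError(f"bad-channel list names unknown channels: {unknown}")
    if not bads:
        return e
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        info = mne.create_info(list(e.channel_labels), e.srate_hz, ch_types="eeg")
        ep = mne.EpochsArray(e.data * 1e-6, info, tmin=e.times_ms[0] / 1000.0, verbose="error")
        ep.set_montage("standard_1005", on_missing="raise")
        ep.info["bads"] = list(bads)
        ep.interpolate_bads(reset_bads=True, verbose="error")
    return replace(e, data=ep.get_data(copy=True) * 1e6)


def reject_amplitude(e: EpochSet, threshold_uv: float = REJECT_UV) -> tuple[EpochSet, int]:
    """Drop trials whose absolute amplitude exceeds the threshold anywhere."""
    keep = np.max(np.abs(e.data), axis=(1, 2)) <= threshold_uv
    n_rej = int((~keep).sum())
    if not keep.any():
        raise ValueError(f"all {e.n_trials} trials exceed +/-{threshold_uv} microvolts")
    return e.select_trials(keep), n_rej


def standard_chain(e: EpochSet, opts: ChainOptions | None = None) -> tuple[EpochSet, ChainLog]:
    """Apply the full preprocessing chain; returns surviving trials and a log."""
    opts = opts or ChainOptions()
    log = ChainLog(n_in=e.n_trials, srate_in=e.srate_hz)
    evoked = bool((e.trial_meta["modality"] == "tms").any())

    e = _resample(e, opts.target_srate)
    log.srate_out = e.srate_hz
    log.steps.append(f"resampled to {e.srate_hz} Hz")

    e = replace(e, data=_bandpass(e.data, e.srate_hz, opts.band_hz, opts.filter_order))
    log.steps.append(f"band-pass {opts.band_hz[0]}-{opts.band_hz[1]} Hz order {opts.filter_order} (zero-phase)")

    if evoked:
        e = window(e, -400.0, 1000.0, _interior_cap=False)
        base = (e.times_ms >= opts.baseline_ms[0]) & (e.times_ms < opts.baseline_ms[1])
        if base.any():
            e = replace(e, data=e.data - e.data[:, :, base].mean(axis=2, keepdims=True))
            log.steps.append("baseline-corrected (-400..0 ms mean)")

    if opts.ica_hook is not None:
        e = replace(e, data=np.asarray(opts.ica_hook(e.data, e.srate_hz)))
        log.steps.append("ica hook applied")

    e = _interpolate(e, opts.bad_channels)
    log.interpolated = tuple(opts.bad_channels)
    if opts.bad_channels:
        log.steps.append(f"interpolated {list(opts.bad_channels)}")

    e, n_rej = reject_amplitude(e, opts.reject_uv)
    log.n_rejected = n_rej
    log.steps.append(f"rejected {n_rej} trials at +/-{opts.reject_uv} microvolts")

    e = replace(e, data=e.data - e.data.mean(axis=1, keepdims=True))
    log.steps.append("re-referenced to common average")
    log.n_out = e.n_trials
    return e, log


def window(e: EpochSet, start_ms: float, end_ms: float, *, _interior_cap: bool = True) -> EpochSet:
    """Crop epochs to the half-open window [start_ms, end_ms).

    The first retained sample is the first one at or after ``start_ms``.  A
    window of duration ``d`` interior to the epoch keeps at most
    ``floor(d * srate)`` samples, so windows of equal duration always contain
    equally many samples regardless of how they align with the sample grid
    (at 362.5 Hz a 200 ms window is exactly 72 samples).  When ``end_ms``
    reaches past the last recorded sample the cap is moot and everything from
    ``start_ms`` on is kept, so a window covering the whole epoch is the
    identity.
    """
    if end_ms <= start_ms:
        raise ValueError("window end must exceed window start")
    times = e.times_ms
    tol = 1e-6 * 1000.0 / e.srate_hz
    i0 = int(np.searchsorted(times, start_ms - tol, side="left"))
    i1 = int(np.searchsorted(times, end_ms - tol, side="left"))
    if end_ms <= times[-1] + tol and _interior_cap:
        cap = int(np.floor((end_ms - start_ms) * e.srate_hz / 1000.0 + 1e-9))
        i1 = min(i1, i0 + cap)
    if i0 >= len(times) or i1 <= i0:
        raise ValueError(
            f"window [{start_ms}, {end_ms}) ms contains no samples of the epoch "
            f"spanning [{times[0]:.2f}, {times[-1]:.2f}] ms"
        )
    return replace(e, data=e.data[:, :, i0:i1].copy(), times_ms=times[i0:i1].copy())
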