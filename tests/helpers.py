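"""Test-only writers for standard EEG interchange formats.

The package only *reads* EDF and BrainVision (through MNE); these minimal
writers exist so fixtures can be created on the fly in temporary
directories.  They implement just enough of each format for round-trip
tests: EDF with int16 samples and one-second records, BrainVision with
IEEE float32 multiplexed binary data.
"""

from __future__ import annotations

import numpy as np


def write_edf(path, data_uv: np.ndarray, srate_hz: float, channel_names) -> None:
    """data_uv: channels x samples, whole seconds at integer srate."""
    n_ch, n_sm = data_uv.shape
    fs = int(round(srate_hz))
    assert n_sm % fs == 0, "EDF fixture needs whole one-second records"
    n_rec = n_sm // fs
    phys_min, phys_max = -1000.0, 1000.0
    dig_min, dig_max = -32768, 32767

    def pad(s, n):
        s = str(s)[:n]
        return s + " " * (n - len(s))

    hdr = b""
    hdr += pad("0", 8).encode()
    hdr += pad("synthetic fixture", 80).encode()
    hdr += pad("synthetic recording", 80).encode()
    hdr += pad("01.01.20", 8).encode()
    hdr += pad("00.00.00", 8).encode()
    hdr += pad(str(256 * (n_ch + 1)), 8).encode()
    hdr += pad("", 44).encode()
    hdr += pad(str(n_rec), 8).encode()
    hdr += pad("1", 8).encode()
    hdr += pad(str(n_ch), 4).encode()
    for name in channel_names:
        hdr += pad(name, 16).encode()
    hdr += pad("", 80).encode() * n_ch
    hdr += pad("uV", 8).encode() * n_ch
    hdr += pad(str(phys_min), 8).encode() * n_ch
    hdr += pad(str(phys_max), 8).encode() * n_ch
    hdr += pad(str(dig_min), 8).encode() * n_ch
    hdr += pad(str(dig_max), 8).encode() * n_ch
    hdr += pad("", 80).encode() * n_ch
    hdr += pad(str(fs), 8).encode() * n_ch
    hdr += pad("", 32).encode() * n_ch

    scale = (dig_max - dig_min) / (phys_max - phys_min)
    dig = np.clip((data_uv - phys_min) * scale + dig_min, dig_min, dig_max)
    dig = np.round(dig).astype("<i2")
    with open(path, "wb") as f:
        f.write(hdr)
        for r in range(n_rec):
            for ch in range(n_ch):
                f.write(dig[ch, r * fs:(r + 1) * fs].tobytes())


def write_brainvision(base_path, data_uv: np.ndarray, srate_hz: float, channel_names) -> None:
    """Write base.vhdr / base.eeg / base.vmrk; data_uv: channels x samples."""
    base = str(base_path)
    stem = base.rsplit("/", 1)[-1]
    n_ch = data_uv.shape[0]
    interval_us = 1e6 / srate_hz
    vhdr = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        f"MarkerFile={stem}.vmrk",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={n_ch}",
        f"SamplingInterval={interval_us}",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "[Channel Infos]",
    ]
    vhdr += [f"Ch{i + 1}={name},,1,µV" for i, name in enumerate(channel_names)]
    with open(base + ".vhdr", "w", encoding="utf-8") as f:
        f.write("\n".join(vhdr) + "\n")
    vmrk = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,00000000000000000000",
    ]
    with open(base + ".vmrk", "w", encoding="utf-8") as f:
        f.write("\n".join(vmrk) + "\n")
    data_uv.T.astype("<f4").tofile(base + ".eeg")
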