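"""EDF input: continuous-recording epoching around cue markers.

Continuous recordings come in as EDF+ files with annotations marking cue
onsets.  :func:`epoch_edf` reads the file (via MNE), maps annotation
descriptions to raw cue conditions, and cuts half-open epochs
[start, end) in samples so every epoch has exactly
round(fs * window_span / 1000) samples; events too close to the record
edges are dropped and counted.

Manual artifact screening of the emulated workflow is replaced here by a
documented amplitude-threshold rejection: epochs containing any sample
beyond ±``reject_uv`` µV (default 100) are discarded.

:func:`write_edf` is a minimal EDF+C writer used to produce synthetic
recordings for tests and simulations; it writes 16-bit data records with
a standard annotations channel.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .datasets import EpochSet


def epoch_edf(
    path: str | Path,
    marker_map: Mapping[str, str],
    window_ms: tuple[float, float] = (-500.0, 1000.0),
    reject_uv: float | None = 100.0,
) -> tuple[list[EpochSet], int]:
    """Cut condition epochs around annotated cue markers of an EDF file.

    Parameters
    ----------
    path : EDF/EDF+ file.
    marker_map : annotation description -> raw condition label
        (e.g. ``{"cue_sr": "small_reward", ...}``).
    window_ms : epoch window (start, end) in ms relative to cue onset;
        start must be negative and end positive.
    reject_uv : absolute amplitude threshold in µV for epoch rejection;
        None disables rejection.

    Returns
    -------
    epochsets : one :class:`EpochSet` per condition found (subject id is
        taken from the file stem).
    n_dropped : number of marker events skipped because their window
        fell outside the recording.
    """
    import mne

    if not marker_map:
        raise ValueError("marker_map is empty")
    start_ms, end_ms = window_ms
    if not (start_ms < 0 < end_ms):
        raise ValueError("window must satisfy start < 0 < end")
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    fs = raw.info["sfreq"]
    if not fs or fs <= 0:
        raise ValueError("sampling rate missing from EDF header")
    data = raw.get_data() * 1e6  # volts -> µV
    n_total = data.shape[1]
    offset = round(fs * start_ms / 1000.0)
    n_samples = round(fs * (end_ms - start_ms) / 1000.0)

    events: dict[str, list[int]] = {}
    matched = 0
    for onset_s, desc in zip(raw.annotations.onset, raw.annotations.description):
        if desc not in marker_map:
            continue
        matched += 1
        events.setdefault(marker_map[desc], []).append(round(onset_s * fs))
    if matched == 0:
        raise ValueError("no annotations match marker_map")

    subject_id = Path(path).stem
    t0_offset = offset / fs * 1000.0
    epochsets: list[EpochSet] = []
    n_dropped = 0
    for condition, onsets in sorted(events.items()):
        epochs = []
        for onset in onsets:
            a = onset + offset
            b = a + n_samples
            if a < 0 or b > n_total:
                n_dropped += 1
                continue
            epochs.append(data[:, a:b])
        stack = (
            np.stack(epochs)
            if epochs
            else np.empty((0, data.shape[0], n_samples))
        )
        es = EpochSet(subject_id, condition, stack, fs, t0_offset)
        if reject_uv is not None:
            es = reject_epochs(es, reject_uv)
        epochsets.append(es)
    return epochsets, n_dropped


def reject_epochs(epochset: EpochSet, threshold_uv: float = 100.0) -> EpochSet:
    """Drop epochs containing any sample beyond ±threshold_uv µV."""
    if threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    keep = np.abs(epochset.epochs).max(axis=(1, 2)) <= threshold_uv
    return EpochSet(
        epochset.subject_id,
        epochset.condition,
        epochset.epochs[keep],
        epochset.fs,
        epochset.t0_offset,
    )


# ---------------------------------------------------------------------------
# minimal EDF+C writer (synthetic recordings only)


def _field(value: str, width: int) -> bytes:
    b = value.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field too long: {value!r} > {width}")
    return b.ljust(width)


def write_edf(
    path: str | Path,
    data_uv: np.ndarray,
    fs: float,
    channel_labels: Sequence[str],
    events: Sequence[tuple[float, str]] = (),
    record_duration_s: float = 1.0,
) -> Path:
    """Write a synthetic continuous recording as EDF+C.

    ``data_uv`` is channels x samples in µV; ``events`` are
    (onset_seconds, description) annotations.  16-bit digital encoding
    with symmetric physical range; the last data record is zero-padded.
    This is a minimal writer intended for synthetic test recordings, not
    a general-purpose EDF exporter.
    """
    data_uv = np.asarray(data_uv, dtype=float)
    n_ch, n_total = data_uv.shape
    if len(channel_labels) != n_ch:
        raise ValueError("one label per channel required")
    if fs * record_duration_s != int(fs * record_duration_s):
        raise ValueError("fs * record_duration must be an integer")
    spr = int(fs * record_duration_s)  # samples per record per channel
    n_records = math.ceil(n_total / spr)

    phys_max = max(1.0, float(np.abs(data_uv).max()) * 1.01)
    dig_max = 32767
    scale = dig_max / phys_max
    padded = np.zeros((n_ch, n_records * spr))
    padded[:, :n_total] = data_uv
    digital = np.clip(np.round(padded * scale), -dig_max, dig_max).astype("<i2")

    # annotation TALs per record: a timestamp TAL plus this record's events
    tals: list[bytes] = []
    for r in range(n_records):
        t0 = r * record_duration_s
        block = f"+{t0:g}\x14\x14\x00".encode("ascii")
        for onset, desc in events:
            if t0 <= onset < t0 + record_duration_s:
                block += f"+{onset:g}\x14{desc}\x14\x00".encode("ascii")
        tals.append(block)
    ann_bytes = max(len(b) for b in tals)
    ann_spr = math.ceil(ann_bytes / 2) + 8  # headroom, in 2-byte samples

    n_signals = n_ch + 1
    header = b""
    header += _field("0", 8)
    header += _field("X X X X", 80)
    header += _field("Startdate 01-JAN-2000 X X X", 80)
    header += _field("01.01.00", 8)
    header += _field("00.00.00", 8)
    header += _field(str(256 * (1 + n_signals)), 8)
    header += _field("EDF+C", 44)
    header += _field(str(n_records), 8)
    header += _field(f"{record_duration_s:g}", 8)
    header += _field(str(n_signals), 4)

    labels = [str(l) for l in channel_labels] + ["EDF Annotations"]
    transducer = [""] * n_ch + [""]
    dims = ["uV"] * n_ch + [""]
    pmin = [f"{-phys_max:.4f}"[:8]] * n_ch + ["-1"]
    pmax = [f"{phys_max:.4f}"[:8]] * n_ch + ["1"]
    dmin = [str(-dig_max)] * n_ch + ["-32768"]
    dmax = [str(dig_max)] * n_signals
    prefilter = [""] * n_signals
    sprs = [str(spr)] * n_ch + [str(ann_spr)]
    for values, width in (
        (labels, 16), (transducer, 80), (dims, 8), (pmin, 8), (pmax, 8),
        (dmin, 8), (dmax, 8), (prefilter, 80), (sprs, 8),
    ):
        for v in values:
            header += _field(v, width)
    header += b" " * (32 * n_signals)

    out = Path(path)
    with open(out, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            for ch in range(n_ch):
                fh.write(digital[ch, r * spr : (r + 1) * spr].tobytes())
            fh.write(tals[r].ljust(ann_spr * 2, b"\x00"))
    return out
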