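"""Reading BCI Competition IV 2b GDF sessions and the packed trial container.

The GDF path wraps :func:`mne.io.read_raw_gdf`.  A session yields a
:class:`RawRecording` (channels x samples in microvolts plus cue events);
:func:`extract_epochs` cuts cue-locked 4 s epochs out of it.  Epochs,
labels and metadata travel between pipeline stages in a ``.npz``
packed-array container with a JSON metadata sidecar entry.

BCI IV 2b specifics: 250 Hz sampling, three EEG channels mapped in order
to C3, Cz, C4 (EOG channels are dropped), cue annotations ``769`` (left
hand) and ``770`` (right hand), motor imagery in the 3-7 s window of each
trial (the cue onset is at second 3).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FormatError",
    "RawRecording",
    "EpochedTrial",
    "load_gdf_session",
    "extract_epochs",
    "save_container",
    "load_container",
    "CUE_CODES",
]

logger = logging.getLogger(__name__)

#: GDF annotation codes for the two motor-imagery cues
CUE_CODES = {"769": "left", "770": "right"}

EEG_CHANNELS = ("C3", "Cz", "C4")


class FormatError(ValueError):
    """The file is not a readable GDF session with MI cue annotations."""


@dataclass
class RawRecording:
    """One continuous session: (channels, samples) in microvolts."""

    data: np.ndarray
    fs: float
    channel_names: tuple[str, ...]
    events: list[tuple[int, str]]  # (onset_sample, label)
    subject_id: str = ""
    session_id: str = ""

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EpochedTrial:
    """One labelled 3-channel, 4 s MI epoch (3 x 1000 at 250 Hz)."""

    data: np.ndarray
    label: str | None
    fs: float = 250.0
    subject_id: str = ""
    session_id: str = ""
    #: parallel as-recorded copy for the raw branch; the ``data`` field is
    #: replaced by its filtered version when the preprocessing stage runs
    raw_data: np.ndarray | None = field(default=None, repr=False)


def load_gdf_session(path) -> RawRecording:
    """Read one BCI IV 2b GDF file into a :class:`RawRecording`.

    EOG channels are dropped; the remaining (first three) EEG channels are
    mapped in order to C3, Cz, C4.  Events are the left/right cue
    annotations.  Raises :class:`FormatError` for non-GDF input, a wrong
    EEG channel count, or missing cue annotations.
    """
    import mne

    try:
        raw = mne.io.read_raw_gdf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types for bad files
        raise FormatError(f"could not read {path} as GDF: {exc}") from exc
    drop = [ch for ch in raw.ch_names if "EOG" in ch.upper()]
    if drop:
        raw.drop_channels(drop)
    if len(raw.ch_names) != 3:
        raise FormatError(
            f"expected 3 EEG channels after dropping EOG, got {len(raw.ch_names)}"
        )
    fs = float(raw.info["sfreq"])
    data_uv = raw.get_data() * 1e6  # volts -> microvolts
    events = []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        code = str(desc).strip()
        if code in CUE_CODES:
            events.append((int(round(onset * fs)), CUE_CODES[code]))
    if not events:
        raise FormatError(f"no MI cue annotations (769/770) found in {path}")
    return RawRecording(
        data=np.ascontiguousarray(data_uv),
        fs=fs,
        channel_names=EEG_CHANNELS,
        events=sorted(events),
        session_id=str(path),
    )


def extract_epochs(
    recording: RawRecording,
    window: tuple[float, float] = (0.0, 4.0),
    epoch_s: float = 4.0,
) -> list[EpochedTrial]:
    """One 4 s epoch per cue event, cue-relative ``window`` in seconds.

    The default window (0, 4) s after the cue covers the 3-7 s MI interval
    of the trial (the cue fires at second 3).  Epochs are half-open sample
    ranges ``[onset + start, onset + start + fs * 4)``, 0-based; events too
    close to the recording edge are dropped with a warning.
    """
    start_s, end_s = window
    if abs((end_s - start_s) - epoch_s) > 1e-9:
        raise ValueError(f"window must span {epoch_s} s, got {window}")
    n_samp = int(round(recording.fs * epoch_s))
    offset = int(round(recording.fs * start_s))
    trials = []
    dropped = 0
    for onset, label in recording.events:
        lo = onset + offset
        hi = lo + n_samp
        if lo < 0 or hi > recording.n_samples:
            dropped += 1
            continue
        trials.append(
            EpochedTrial(
                data=recording.data[:, lo:hi].copy(),
                label=label,
                fs=recording.fs,
                subject_id=recording.subject_id,
                session_id=recording.session_id,
            )
        )
    if dropped:
        logger.warning(
            "dropped %d cue(s) whose epoch window left the recording", dropped
        )
    if not trials:
        raise ValueError("no cue event yields an epoch inside the recording")
    return trials


def save_container(path, arrays: dict[str, np.ndarray], meta: dict | None = None) -> None:
    """Write named arrays plus a JSON metadata sidecar entry to ``path`` (.npz)."""
    payload = dict(arrays)
    payload["__meta__"] = np.frombuffer(
        json.dumps(meta or {}, sort_keys=True).encode(), dtype=np.uint8
    )
    np.savez(path, **payload)


def load_container(path) -> tuple[dict[str, np.ndarray], dict]:
    """Inverse of :func:`save_container`; round-trips bit-identically."""
    with np.load(path) as z:
        arrays = {k: z[k] for k in z.files if k != "__meta__"}
        meta = json.loads(bytes(z["__meta__"].tobytes()).decode()) if "__meta__" in z.files else {}
    return arrays, meta


def trials_to_container(trials: list[EpochedTrial]) -> tuple[dict[str, np.ndarray], dict]:
    """Pack a list of epoched trials into container arrays + metadata."""
    data = np.stack([t.data for t in trials])
    labels = np.asarray([t.label or "" for t in trials])
    meta = {
        "fs": trials[0].fs,
        "subject_ids": [t.subject_id for t in trials],
        "session_ids": [t.session_id for t in trials],
    }
    out = {"data": data, "labels": labels}
    if trials[0].raw_data is not None:
        out["raw_data"] = np.stack([t.raw_data for t in trials])
    return out, meta


def container_to_trials(arrays: dict[str, np.ndarray], meta: dict) -> list[EpochedTrial]:
    """Inverse of :func:`trials_to_container`."""
    fs = float(meta.get("fs", 250.0))
    subj = meta.get("subject_ids") or [""] * len(arrays["labels"])
    sess = meta.get("session_ids") or [""] * len(arrays["labels"])
    raw = arrays.get("raw_data")
    return [
        EpochedTrial(
            data=arrays["data"][i],
            label=str(arrays["labels"][i]) or None,
            fs=fs,
            subject_id=subj[i],
            session_id=sess[i],
            raw_data=None if raw is None else raw[i],
        )
        for i in range(len(arrays["labels"]))
    ]
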