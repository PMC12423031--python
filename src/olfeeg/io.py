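"""File I/O: the native array container, EDF, sub-band and model storage.

The native on-disk form of a trial set is an array container - a ``.npz``
with the (trials x channels x samples) tensor plus a JSON sidecar carrying
per-trial subject id / label / odor and the shared sampling rate and channel
names.  The pair round-trips bit-exactly.

EDF support: :func:`read_edf` epochs a continuous EDF recording using a JSON
events sidecar (onset sample, subject, label, odor per epoch);
:func:`write_edf` emits a minimal plain-EDF file (int16, 1-second records)
so round-trips can be exercised without shipping binary fixtures.  EDF is a
16-bit format, so amplitudes survive only to quantization precision.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .dataset import DEFAULT_CHANNELS, EEGTrial, EEGTrialSet, Label, Odor
from .errors import DataError, StructuralError
from .model import FusionConfig, FusionModel, TrainParams
from .tqwt import SubbandSet, TQWTParams

__all__ = [
    "save_trialset",
    "load_trialset",
    "save_subbands",
    "load_subbands",
    "save_checkpoint",
    "load_checkpoint",
    "write_edf",
    "read_edf",
]


# ---------------------------------------------------------------------------
# native array container
# ---------------------------------------------------------------------------

def save_trialset(ts: EEGTrialSet, basepath: str | Path) -> tuple[Path, Path]:
    """Write ``<base>.npz`` + ``<base>.json``; returns both paths."""
    base = Path(basepath)
    npz_path = base.with_suffix(".npz")
    json_path = base.with_suffix(".json")
    np.savez(npz_path, data=ts.data_tensor())
    meta = {
        "fs": ts.fs,
        "channel_names": list(ts.channel_names),
        "subject_ids": [t.subject_id for t in ts.trials],
        "labels": [t.label.name for t in ts.trials],
        "odors": [t.odor.value for t in ts.trials],
    }
    json_path.write_text(json.dumps(meta))
    return npz_path, json_path


def load_trialset(basepath: str | Path) -> EEGTrialSet:
    base = Path(basepath)
    with np.load(base.with_suffix(".npz")) as f:
        data = f["data"]
    meta = json.loads(base.with_suffix(".json").read_text())
    trials = [
        EEGTrial(
            data=data[i],
            subject_id=meta["subject_ids"][i],
            label=Label[meta["labels"][i]],
            odor=Odor(meta["odors"][i]),
            fs=meta["fs"],
        )
        for i in range(data.shape[0])
    ]
    return EEGTrialSet(trials, list(meta["channel_names"]))


# ---------------------------------------------------------------------------
# sub-band serialization (ragged bands -> flat vector + offsets)
# ---------------------------------------------------------------------------

def save_subbands(sb: SubbandSet, path: str | Path) -> Path:
    path = Path(path).with_suffix(".npz")
    flat = np.concatenate(sb.coeffs)
    lengths = np.array([len(c) for c in sb.coeffs])
    np.savez(
        path,
        flat=flat,
        lengths=lengths,
        params=np.array([sb.params.q_factor, sb.params.redundancy, sb.params.levels]),
        original_length=np.array(sb.original_length),
        padded=np.array(int(sb.padded)),
    )
    return path


def load_subbands(path: str | Path) -> SubbandSet:
    with np.load(Path(path).with_suffix(".npz")) as f:
        flat, lengths = f["flat"], f["lengths"]
        q, r, j = f["params"]
        n = int(f["original_length"])
        padded = bool(f["padded"])
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    coeffs = [flat[offsets[i]:offsets[i + 1]] for i in range(len(lengths))]
    return SubbandSet(
        coeffs=coeffs,
        params=TQWTParams(q_factor=float(q), redundancy=float(r), levels=int(j)),
        original_length=n,
        padded=padded,
    )


# ---------------------------------------------------------------------------
# model checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: FusionModel, path: str | Path,
                    train_params: TrainParams | None = None) -> Path:
    path = Path(path).with_suffix(".npz")
    blobs = {f"w::{k}": v for k, v in model.get_weights().items()}
    meta = {
        "fusion": asdict(model.cfg),
        "train": asdict(train_params) if train_params else None,
    }
    np.savez(path, __meta__=np.array(json.dumps(meta)), **blobs)
    return path


def load_checkpoint(path: str | Path) -> FusionModel:
    with np.load(Path(path).with_suffix(".npz"), allow_pickle=False) as f:
        meta = json.loads(str(f["__meta__"]))
        state = {k[3:]: f[k] for k in f.files if k.startswith("w::")}
    fusion = meta["fusion"]
    fusion["head_hidden"] = tuple(fusion["head_hidden"])
    model = FusionModel(FusionConfig(**fusion))
    model.set_weights(state)
    return model


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _pad_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(data: np.ndarray, fs: float, channel_names: list[str],
              path: str | Path) -> Path:
    """Write a continuous multi-channel recording as minimal plain EDF.

    ``data`` is channels x samples in microvolts; records last 1 second, so
    ``fs`` must be a positive integer; the tail is zero-padded to a whole
    record.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise DataError(f"data must be channels x samples, got {data.shape}")
    if fs <= 0 or int(fs) != fs:
        raise DataError(f"EDF writer needs an integer sampling rate, got {fs}")
    fs = int(fs)
    nch, nsamp = data.shape
    if len(channel_names) != nch:
        raise StructuralError(f"{len(channel_names)} names for {nch} channels")
    n_records = int(np.ceil(nsamp / fs))
    padded = np.zeros((nch, n_records * fs))
    padded[:, :nsamp] = data
    # physical scaling per channel (symmetric, nonzero span); the range is
    # quantized to what the 8-char ASCII header field actually stores so the
    # digital scaling is exactly consistent with what readers parse back
    phys_max = np.array([
        float(f"{m:.5g}"[:7]) for m in np.maximum(np.abs(padded).max(axis=1) * 1.001, 1e-6)
    ])
    dig_max, dig_min = 32767, -32768
    header = b"".join([
        _pad_field(0, 8),
        _pad_field("X X X X", 80),
        _pad_field("Startdate 01-JAN-2000 X X X", 80),
        _pad_field("01.01.00", 8),
        _pad_field("00.00.00", 8),
        _pad_field(256 * (1 + nch), 8),
        _pad_field("", 44),
        _pad_field(n_records, 8),
        _pad_field(1, 8),
        _pad_field(nch, 4),
    ])
    sig_header = b"".join([
        b"".join(_pad_field(name, 16) for name in channel_names),
        b"".join(_pad_field("", 80) for _ in range(nch)),
        b"".join(_pad_field("uV", 8) for _ in range(nch)),
        b"".join(_pad_field(f"{-m:.5g}"[:8], 8) for m in phys_max),
        b"".join(_pad_field(f"{m:.5g}"[:7], 8) for m in phys_max),
        b"".join(_pad_field(dig_min, 8) for _ in range(nch)),
        b"".join(_pad_field(dig_max, 8) for _ in range(nch)),
        b"".join(_pad_field("", 80) for _ in range(nch)),
        b"".join(_pad_field(fs, 8) for _ in range(nch)),
        b"".join(_pad_field("", 32) for _ in range(nch)),
    ])
    scale = dig_max / phys_max
    digital = np.clip(np.round(padded * scale[:, None]), dig_min, dig_max).astype("<i2")
    path = Path(path)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for rec in range(n_records):
            block = digital[:, rec * fs:(rec + 1) * fs]
            fh.write(block.tobytes())  # channel-major within each record
    return path


def read_edf(
    path: str | Path,
    events: "str | Path | list[dict]",
    epoch_samples: int,
    channels: list[str] | None = None,
) -> EEGTrialSet:
    """Epoch an EDF/EDF+ recording into an :class:`EEGTrialSet`.

    ``events`` is a JSON file (or an already-loaded list) of objects with
    ``onset`` (sample index), ``subject_id``, ``label`` (AD/MCI/Healthy) and
    ``odor`` (lemon/rose).  ``channels`` selects and orders channels by name
    (default: the standard Fp1/Fz/Cz/Pz subset where present).
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    available = list(raw.ch_names)
    if channels is None:
        channels = [c for c in DEFAULT_CHANNELS if c in available] or available
    missing = [c for c in channels if c not in available]
    if missing:
        raise DataError(
            f"channel(s) {missing} not in recording; available: {available}"
        )
    raw.pick(channels)
    data = raw.get_data(picks=channels) * 1e6  # volts -> microvolts
    fs = float(raw.info["sfreq"])
    if not isinstance(events, list):
        events = json.loads(Path(events).read_text())
    trials = []
    for ev in events:
        onset = int(ev["onset"])
        stop = onset + epoch_samples
        if stop > data.shape[1]:
            raise DataError(
                f"epoch at onset {onset} (+{epoch_samples}) exceeds recording "
                f"length {data.shape[1]}"
            )
        trials.append(
            EEGTrial(
                data=data[:, onset:stop].copy(),
                subject_id=str(ev["subject_id"]),
                label=Label[str(ev["label"]).upper()],
                odor=Odor(str(ev["odor"]).lower()),
                fs=fs,
            )
        )
    return EEGTrialSet(trials, list(channels))
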