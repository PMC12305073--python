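"""Delimited-table readers/writers for photometry, pose and annotations.

Photometry is a TSV of (t, sig490, iso405); jaw pose uses the three-row
header convention of common markerless-pose exports (scorer / bodyparts /
coords with x, y, likelihood columns); annotations are an event table of
(event_type, onset_s, offset_s, label); session ground truth round-trips
through a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError
from .preprocess import DffTrace
from .synthetic import (
    BehaviorAnnotations,
    FreqProfile,
    JawTrace,
    PhotometryRecording,
    SessionParams,
    SessionTruth,
)

__all__ = [
    "write_photometry",
    "read_photometry",
    "write_jaw",
    "read_jaw",
    "write_annotations",
    "read_annotations",
    "write_truth",
    "read_truth",
    "write_dff",
    "read_dff",
]

_SCORER = "synthetic"
_BODYPART = "jaw"


def _fs_from_t(t: np.ndarray) -> float:
    dt = np.diff(t)
    if len(dt) == 0 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ParameterError("time base is not uniformly spaced")
    return 1.0 / float(dt[0])


def write_photometry(rec: PhotometryRecording, path) -> None:
    pd.DataFrame({"t": rec.t, "sig490": rec.sig490, "iso405": rec.iso405}).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_photometry(path) -> PhotometryRecording:
    df = pd.read_csv(path, sep="\t")
    t = df["t"].to_numpy()
    return PhotometryRecording(
        t=t,
        sig490=df["sig490"].to_numpy(),
        iso405=df["iso405"].to_numpy(),
        fs=_fs_from_t(t),
    )


def write_dff(dff: DffTrace, path) -> None:
    pd.DataFrame({"t": dff.t, "dff": dff.dff}).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_dff(path) -> DffTrace:
    df = pd.read_csv(path, sep="\t")
    t = df["t"].to_numpy()
    return DffTrace(t=t, dff=df["dff"].to_numpy(), fs=_fs_from_t(t))


def write_jaw(jaw: JawTrace, path) -> None:
    """Pose-track CSV with the scorer/bodyparts/coords header convention.

    The single tracked part is the jaw genu; x carries the frame-wise
    horizontal coordinate (constant for the 1-D synthetic trace) and y the
    vertical jaw coordinate.
    """
    cols = pd.MultiIndex.from_tuples(
        [(_SCORER, _BODYPART, c) for c in ("x", "y", "likelihood")],
        names=["scorer", "bodyparts", "coords"],
    )
    df = pd.DataFrame(
        np.column_stack([np.zeros_like(jaw.pos), jaw.pos, jaw.confidence]),
        columns=cols,
        index=pd.Index(jaw.frame, name=None),
    )
    df.to_csv(path, float_format="%.6f")


def read_jaw(path, fs: float = 120.0) -> JawTrace:
    df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    scorer = df.columns.get_level_values(0)[0]
    part = df.columns.get_level_values(1)[0]
    return JawTrace(
        frame=df.index.to_numpy(),
        pos=df[(scorer, part, "y")].to_numpy(),
        confidence=df[(scorer, part, "likelihood")].to_numpy(),
        fs=fs,
    )


def write_annotations(ann: BehaviorAnnotations, path) -> None:
    rows = []
    for tb in ann.bite_onsets:
        rows.append(("bite_onset", tb, "", ann.food_type))
    for s, e, label in ann.bite_epochs:
        rows.append(("bite_epoch", s, e, label))
    for s, e, label in ann.chew_epochs:
        rows.append(("chew_epoch", s, e, label))
    for tl in ann.lick_times:
        rows.append(("lick", tl, "", ""))
    for s, d in ann.laser_pulses:
        rows.append(("laser", s, s + d, ""))
    pd.DataFrame(rows, columns=["event_type", "onset_s", "offset_s", "label"]).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )


def read_annotations(path) -> BehaviorAnnotations:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    df["onset_s"] = pd.to_numeric(df["onset_s"])
    off = pd.to_numeric(df["offset_s"], errors="coerce")

    def _sel(kind):
        return df[df["event_type"] == kind]

    bites = _sel("bite_onset")
    bite_ep = _sel("bite_epoch")
    chew_ep = _sel("chew_epoch")
    licks = _sel("lick")
    laser = _sel("laser")
    food = ""
    if len(bites):
        food = str(bites["label"].iloc[0])
    elif len(chew_ep):
        food = str(chew_ep["label"].iloc[0])
    return BehaviorAnnotations(
        bite_onsets=bites["onset_s"].to_numpy(),
        bite_epochs=[
            (r.onset_s, off[i], r.label) for i, r in bite_ep.iterrows()
        ],
        chew_epochs=[
            (r.onset_s, off[i], r.label) for i, r in chew_ep.iterrows()
        ],
        lick_times=licks["onset_s"].to_numpy(),
        laser_pulses=[
            (r.onset_s, off[i] - r.onset_s) for i, r in laser.iterrows()
        ],
        food_type=food or "almond",
    )


def write_truth(truth: SessionTruth, path) -> None:
    payload = {
        "params": {k: v for k, v in truth.params.__dict__.items()},
        "bite_times": truth.bite_times.tolist(),
        "chew_epochs": [[s, e, lab] for s, e, lab in truth.chew_epochs],
        "lick_times": truth.lick_times.tolist(),
        "laser_pulses": [[s, d] for s, d in truth.laser_pulses],
        "transient_times": truth.transient_times.tolist(),
        "transient_amps": truth.transient_amps.tolist(),
        "closure_onset_times": truth.closure_onset_times.tolist(),
        "chew_profiles": [
            {"t_knots": p.t_knots.tolist(), "f_knots": p.f_knots.tolist()}
            for p in truth.chew_profiles
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path) -> SessionTruth:
    payload = json.loads(Path(path).read_text())
    return SessionTruth(
        bite_times=np.asarray(payload["bite_times"]),
        chew_epochs=[(s, e, lab) for s, e, lab in payload["chew_epochs"]],
        lick_times=np.asarray(payload["lick_times"]),
        laser_pulses=[(s, d) for s, d in payload["laser_pulses"]],
        transient_times=np.asarray(payload["transient_times"]),
        transient_amps=np.asarray(payload["transient_amps"]),
        closure_onset_times=np.asarray(payload["closure_onset_times"]),
        chew_profiles=[
            FreqProfile(np.asarray(p["t_knots"]), np.asarray(p["f_knots"]))
            for p in payload["chew_profiles"]
        ],
        params=SessionParams(**payload["params"]),
    )
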