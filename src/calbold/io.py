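"""Readers, writers and the end-to-end calibration pipeline.

File formats (all plain text except NIfTI):

* end-tidal traces — TSV/CSV with header columns ``time_s``, ``peto2_mmHg``,
  ``petco2_mmHg``;
* ROI timecourses — TSV/CSV with ``time_s``, ``signal``;
* paradigms — JSON with ``variant``, ``tr_s``, a ``blocks`` table
  (label/start_s/end_s) and a ``trials`` table
  (onset_s/duration_s/off_end_s/usable);
* results — JSON with explicit ``units`` keys (fractions in machine-facing
  output; percentages only in human-facing text);
* volumes/masks/maps — NIfTI via nibabel (float32 maps, uint8 masks).
"""

from __future__ import annotations

import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .calibration import (
    CalibrationFit,
    CMRO2Result,
    fick_rcmro2,
    fit_calibration,
    points_from_summaries,
    rescale_q_act,
)
from .gas import DEFAULT_CONSTANTS, EndTidalTrace, GasConstants, hyperoxia_contrast, petco2_trial_qc
from .preprocess import (
    GasBlock,
    Paradigm,
    RoiTimecourse,
    Trial,
    detrend_linear,
    normalise_to_baseline,
    trial_summaries,
)

__all__ = [
    "RunConfig",
    "read_endtidal",
    "write_endtidal",
    "read_timecourse",
    "write_timecourse",
    "read_paradigm",
    "write_paradigm",
    "read_volume",
    "write_map",
    "run_calibration",
]

_ENDTIDAL_COLS = ["time_s", "peto2_mmHg", "petco2_mmHg"]
_TIMECOURSE_COLS = ["time_s", "signal"]


def _read_table(path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ValueError(f"{path}: cannot parse delimited text: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    return df


def read_endtidal(path) -> EndTidalTrace:
    """Read an end-tidal trace (TSV/CSV; columns time_s, peto2_mmHg, petco2_mmHg)."""
    df = _read_table(path, _ENDTIDAL_COLS)
    return EndTidalTrace(
        times=df["time_s"].to_numpy(float),
        peto2=df["peto2_mmHg"].to_numpy(float),
        petco2=df["petco2_mmHg"].to_numpy(float),
    )


def write_endtidal(trace: EndTidalTrace, path) -> None:
    pd.DataFrame(
        {"time_s": trace.times, "peto2_mmHg": trace.peto2, "petco2_mmHg": trace.petco2}
    ).to_csv(path, sep="\t", index=False)


def read_timecourse(path) -> RoiTimecourse:
    """Read an ROI timecourse (TSV/CSV; columns time_s, signal)."""
    df = _read_table(path, _TIMECOURSE_COLS)
    return RoiTimecourse(df["time_s"].to_numpy(float), df["signal"].to_numpy(float))


def write_timecourse(tc: RoiTimecourse, path) -> None:
    pd.DataFrame({"time_s": tc.times, "signal": tc.values}).to_csv(
        path, sep="\t", index=False
    )


def read_paradigm(path) -> Paradigm:
    with open(path) as fh:
        d = json.load(fh)
    for key in ("variant", "tr_s", "blocks", "trials"):
        if key not in d:
            raise ValueError(f"{path}: paradigm JSON missing key {key!r}")
    blocks = [GasBlock(b["label"], b["start_s"], b["end_s"]) for b in d["blocks"]]
    trials = [
        Trial(t["onset_s"], t["duration_s"], t["off_end_s"], t.get("usable", True))
        for t in d["trials"]
    ]
    return Paradigm(blocks=blocks, trials=trials, variant=d["variant"], tr=d["tr_s"])


def write_paradigm(paradigm: Paradigm, path) -> None:
    d = {
        "variant": paradigm.variant,
        "tr_s": paradigm.tr,
        "blocks": [
            {"label": b.label, "start_s": b.start, "end_s": b.end}
            for b in paradigm.blocks
        ],
        "trials": [
            {
                "onset_s": t.onset,
                "duration_s": t.duration,
                "off_end_s": t.off_end,
                "usable": t.usable,
            }
            for t in paradigm.trials
        ],
    }
    with open(path, "w") as fh:
        json.dump(d, fh, indent=2)


def read_volume(path):
    """Read a 4-D NIfTI; returns (data, affine). Rejects non-4-D images."""
    import nibabel as nib

    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D volume, got {img.ndim}-D")
    return np.asanyarray(img.dataobj, dtype=float), img.affine


def read_mask(path):
    import nibabel as nib

    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D mask, got {img.ndim}-D")
    return np.asanyarray(img.dataobj) > 0, img.affine


def write_map(data: np.ndarray, affine: np.ndarray, path) -> None:
    import nibabel as nib

    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


@dataclass
class RunConfig:
    """End-to-end run description for `run_calibration`.

    Exactly one of `q0_assumed` / `q0_measured` drives the q_h scale:
    `q0_measured` (e.g. from the phase-ratio estimator) replaces the
    literature OEF. TE/TR in seconds; `qc_threshold` in mm Hg.
    """

    bold_path: str
    endtidal_path: str
    paradigm_path: str
    te: float = 0.025
    q0_assumed: Optional[float] = 0.4
    q0_measured: Optional[float] = None
    qc_threshold: float = 1.0
    rcbf: Optional[float] = None
    constants: GasConstants = field(default_factory=GasConstants)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.te <= 0:
            raise ValueError("te must be positive")
        if (self.q0_assumed is None) == (self.q0_measured is None):
            raise ValueError("exactly one of q0_assumed / q0_measured must be set")

    @property
    def q0(self) -> float:
        return self.q0_measured if self.q0_measured is not None else self.q0_assumed


def run_calibration(config: RunConfig) -> dict:
    """Full pipeline: gas -> QC -> conditioning -> two-line fit -> Fick.

    Returns a JSON-serialisable bundle with the calibration fit, QC
    decisions, the per-block q_h values, the optional CMRO2 result, and
    full provenance (config, constants, software version).
    """
    trace = read_endtidal(config.endtidal_path)
    paradigm = read_paradigm(config.paradigm_path)
    tc = read_timecourse(config.bold_path)

    contrasts = hyperoxia_contrast(trace, paradigm, config.q0, config.constants)
    keep = petco2_trial_qc(trace, paradigm, config.qc_threshold)
    tc = normalise_to_baseline(detrend_linear(tc, paradigm), paradigm)
    summaries = trial_summaries(tc, paradigm, keep=keep)
    qh_by_block = [c.q_h for c in contrasts]
    fit = fit_calibration(
        points_from_summaries(summaries, qh_by_block, config.te), config.te
    )

    bundle = {
        "software": {"name": "calbold", "version": __version__},
        "config": {
            "bold_path": str(config.bold_path),
            "endtidal_path": str(config.endtidal_path),
            "paradigm_path": str(config.paradigm_path),
            "te_s": config.te,
            "q0": {"value": config.q0, "mode": "measured" if config.q0_measured is not None else "assumed"},
            "qc_threshold_mmHg": config.qc_threshold,
            "seed": config.seed,
            "constants": asdict(config.constants),
        },
        "qc": {
            "kept_trials": [int(i) for i in np.flatnonzero(keep)],
            "discarded_trials": [int(i) for i in np.flatnonzero(~keep)],
        },
        "gas": {
            "qh_by_block": qh_by_block,
            "dqh_by_block": [c.dq_h for c in contrasts],
            "pao2_by_block_mmHg": [c.pao2 for c in contrasts],
        },
        "fit": fit.to_dict(),
    }
    if config.rcbf is not None:
        bundle["cmro2"] = fick_rcmro2(fit.q_act, config.rcbf).to_dict()
    return bundle
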