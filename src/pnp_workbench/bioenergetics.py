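"""Mitochondrial stress-test (Seahorse) trace summarization.

Decomposes an oxygen-consumption-rate (OCR) trace recorded across the
standard sequential injections — oligomycin (ATP-synthase block), FCCP
(uncoupling), rotenone + antimycin A (complex I/III block) — into the kit's
respiration parameters, and computes acute-injection percent changes of OCR
and of the extracellular acidification rate (ECAR, a glycolysis proxy).

Parameter identities (all in OCR units):

    non_mitochondrial = mean OCR of the final (rotenone+antimycin) phase
    basal             = baseline-phase mean  - non_mitochondrial
    proton_leak       = post-oligomycin mean - non_mitochondrial
    atp_linked        = basal - proton_leak
    maximal           = post-FCCP maximum measurement - non_mitochondrial
    spare_capacity    = maximal - basal
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "OCRTrace",
    "MitoParams",
    "phase_means",
    "mito_params",
    "acute_change",
    "read_trace_csv",
    "MITOSTRESS_LABELS",
]

#: Canonical injection sequence of the MitoStress layout.
MITOSTRESS_LABELS = ("oligomycin", "FCCP", "rotenone+antimycin")


@dataclass
class OCRTrace:
    """Time-ordered OCR (and optional ECAR) measurements with injections.

    Timepoints are minutes, strictly increasing; every injection time must
    fall inside the measured range and each inter-injection phase must keep
    at least one measurement (two for a valid trace per the instrument
    convention).
    """

    timepoints: np.ndarray
    ocr: np.ndarray
    injections: list[tuple[str, float]]
    ecar: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.ocr = np.asarray(self.ocr, dtype=float)
        if self.ecar is not None:
            self.ecar = np.asarray(self.ecar, dtype=float)
            if self.ecar.size != self.timepoints.size:
                raise ValueError("ecar and timepoints length mismatch")
        if self.ocr.size != self.timepoints.size:
            raise ValueError("ocr and timepoints length mismatch")
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        times = [t for _, t in self.injections]
        if any(t <= self.timepoints[0] or t >= self.timepoints[-1] for t in times):
            raise ValueError("every injection time must lie inside the measured range")
        if sorted(times) != times:
            raise ValueError("injections must be time-ordered")

    @property
    def phase_labels(self) -> list[str]:
        return ["baseline"] + [label for label, _ in self.injections]

    def phase_slices(self) -> list[np.ndarray]:
        """Boolean masks per phase: baseline, then strictly after each injection."""
        bounds = [self.timepoints[0] - 1.0] + [t for _, t in self.injections]
        bounds.append(self.timepoints[-1] + 1.0)
        masks = []
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            masks.append((self.timepoints > lo) & (self.timepoints < hi))
        return masks


@dataclass(frozen=True)
class MitoParams:
    """Respiration parameters of the MitoStress decomposition (OCR units)."""

    basal: float
    atp_linked: float
    proton_leak: float
    maximal: float
    spare_capacity: float
    non_mitochondrial: float

    def __post_init__(self) -> None:
        vals = (self.basal, self.atp_linked, self.proton_leak,
                self.maximal, self.spare_capacity, self.non_mitochondrial)
        if not all(np.isfinite(vals)):
            raise ValueError("MitoParams must be finite")

    def as_dict(self) -> dict[str, float]:
        return {
            "basal": self.basal,
            "atp_linked": self.atp_linked,
            "proton_leak": self.proton_leak,
            "maximal": self.maximal,
            "spare_capacity": self.spare_capacity,
            "non_mitochondrial": self.non_mitochondrial,
        }


def phase_means(trace: OCRTrace) -> pd.DataFrame:
    """Mean OCR (and ECAR) per phase, phases delimited by injection times."""
    rows = []
    for label, mask in zip(trace.phase_labels, trace.phase_slices()):
        if mask.sum() < 1:
            raise ValueError(f"phase {label!r} has no measurements")
        row = {"phase": label, "n": int(mask.sum()), "ocr_mean": float(trace.ocr[mask].mean())}
        if trace.ecar is not None:
            row["ecar_mean"] = float(trace.ecar[mask].mean())
        rows.append(row)
    return pd.DataFrame(rows).set_index("phase")


def mito_params(trace: OCRTrace) -> MitoParams:
    """MitoStress respiration parameters from a four-phase trace."""
    labels = trace.phase_labels
    required = ["baseline", *MITOSTRESS_LABELS]
    missing = [r for r in required if r not in labels]
    if missing:
        raise ValueError(f"trace is missing required phases {missing}; expected {required}")
    means = phase_means(trace)
    masks = dict(zip(labels, trace.phase_slices()))
    non_mito = float(means.loc["rotenone+antimycin", "ocr_mean"])
    basal = float(means.loc["baseline", "ocr_mean"]) - non_mito
    proton_leak = float(means.loc["oligomycin", "ocr_mean"]) - non_mito
    maximal = float(trace.ocr[masks["FCCP"]].max()) - non_mito
    return MitoParams(
        basal=basal,
        atp_linked=basal - proton_leak,
        proton_leak=proton_leak,
        maximal=maximal,
        spare_capacity=maximal - basal,
        non_mitochondrial=non_mito,
    )


def acute_change(trace: OCRTrace, injection_label: str) -> dict[str, float]:
    """Percent change of OCR (and ECAR) across one injection.

    100 x (post-phase mean - pre-phase mean) / pre-phase mean, computed
    separately for each measured quantity.
    """
    labels = trace.phase_labels
    if injection_label not in labels[1:]:
        raise ValueError(f"no injection labeled {injection_label!r}; have {labels[1:]}")
    k = labels.index(injection_label)
    masks = trace.phase_slices()
    pre, post = masks[k - 1], masks[k]
    if pre.sum() < 1 or post.sum() < 1:
        raise ValueError(f"injection {injection_label!r} lacks measurements on one side")
    out = {}
    for name, series in (("ocr", trace.ocr), ("ecar", trace.ecar)):
        if series is None:
            continue
        pre_mean = float(series[pre].mean())
        if pre_mean == 0:
            raise ValueError(f"undefined percent change: pre-injection {name} mean is zero")
        out[name] = 100.0 * (float(series[post].mean()) - pre_mean) / pre_mean
    return out


def read_trace_csv(
    trace_path: str | Path, injections_path: str | Path | None = None
) -> OCRTrace:
    """Read a trace CSV (time_min, well_id, group, ocr[, ecar]) plus an
    injections JSON ([{label, time_min}, ...]).

    Replicate wells are aggregated by mean per timepoint before analysis.
    """
    df = pd.read_csv(trace_path)
    for col in ("time_min", "ocr"):
        if col not in df.columns:
            raise ValueError(f"trace CSV is missing column {col!r}")
    agg = {"ocr": "mean"}
    if "ecar" in df.columns:
        agg["ecar"] = "mean"
    per_t = df.groupby("time_min", sort=True).agg(agg).reset_index()
    injections: list[tuple[str, float]] = []
    if injections_path is not None:
        spec = json.loads(Path(injections_path).read_text())
        injections = [(str(e["label"]), float(e["time_min"])) for e in spec]
    return OCRTrace(
        timepoints=per_t["time_min"].to_numpy(),
        ocr=per_t["ocr"].to_numpy(),
        ecar=per_t["ecar"].to_numpy() if "ecar" in per_t.columns else None,
        injections=injections,
    )


def write_trace_csv(trace: OCRTrace, trace_path: str | Path,
                    injections_path: str | Path | None = None) -> None:
    """Write a trace (single aggregated well) and optionally its injections."""
    df = pd.DataFrame({"time_min": trace.timepoints, "well_id": "A1", "group": "g1",
                       "ocr": trace.ocr})
    if trace.ecar is not None:
        df["ecar"] = trace.ecar
    df.to_csv(trace_path, index=False)
    if injections_path is not None:
        Path(injections_path).write_text(
            json.dumps([{"label": l, "time_min": t} for l, t in trace.injections], indent=1)
        )
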