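"""Mitochondrial stress-test parameters from oxygen-consumption traces.

A Seahorse-style stress test records oxygen consumption rate (OCR) in
four phases: baseline, after oligomycin (ATP-synthase inhibitor), after
FCCP (uncoupler) and after rotenone/antimycin (complex I/III inhibitors,
leaving only non-mitochondrial respiration).  With phase summaries
S_b, S_o, S_f, S_r the six canonical parameters are

    non-mitochondrial   = S_r
    basal mitochondrial = S_b - S_r
    ATP-linked          = S_b - S_o
    proton leak         = S_o - S_r
    maximal             = S_f - S_r
    spare capacity      = S_f - S_b

so that basal = ATP-linked + proton leak holds by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

__all__ = ["PHASES", "OCRTrace", "StressTestParams", "stress_test_params",
           "simulate_trace", "StressTest", "StressTestResults"]

PHASES = ("baseline", "oligomycin", "FCCP", "rotenone_antimycin")


@dataclass
class OCRTrace:
    """OCR time series with an injection-phase label per measurement."""

    time_min: np.ndarray
    ocr_pmol_min: np.ndarray
    phase: list[str]
    protein_mg: float | None = None
    well: str = ""

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.ocr_pmol_min = np.asarray(self.ocr_pmol_min, dtype=float)
        if not (len(self.time_min) == len(self.ocr_pmol_min) == len(self.phase)):
            raise ValueError("time, OCR and phase must have equal length")
        unknown = set(self.phase) - set(PHASES)
        if unknown:
            raise ValueError(f"unknown phase label(s): {sorted(unknown)}")
        # phases must appear in canonical order
        seen = [p for i, p in enumerate(self.phase)
                if i == 0 or p != self.phase[i - 1]]
        expected = [p for p in PHASES if p in set(self.phase)]
        if seen != expected:
            raise ValueError(f"phases out of canonical order: {seen}")


@dataclass
class StressTestParams:
    """The six stress-test parameters, pmol O2/min (per mg if normalised)."""

    non_mitochondrial: float
    basal_mitochondrial: float
    atp_linked: float
    proton_leak: float
    maximal: float
    spare_capacity: float
    per_mg_protein: bool = False

    def as_series(self) -> pd.Series:
        return pd.Series({f.name: getattr(self, f.name) for f in fields(self)
                          if f.name != "per_mg_protein"})


def stress_test_params(trace: OCRTrace, summarizer: str = "mean",
                       per_protein: bool = False) -> StressTestParams:
    """Derive the stress-test parameters from a labelled OCR trace.

    ``summarizer`` is "mean" (average of each phase's measurements, the
    default with three measurements per phase) or "last" (final
    measurement of each phase, a common alternative convention).
    Negative derived values, possible under noise, are clipped to zero
    with a warning.
    """
    missing = [p for p in PHASES if p not in trace.phase]
    if missing:
        raise ValueError(f"missing phase(s): {missing}")
    if summarizer not in ("mean", "last"):
        raise ValueError(f"unknown summarizer {summarizer!r}")
    s = {}
    for p in PHASES:
        vals = trace.ocr_pmol_min[[i for i, q in enumerate(trace.phase) if q == p]]
        s[p] = float(vals.mean() if summarizer == "mean" else vals[-1])
    s_b, s_o, s_f, s_r = (s[p] for p in PHASES)
    raw = {
        "non_mitochondrial": s_r,
        "basal_mitochondrial": s_b - s_r,
        "atp_linked": s_b - s_o,
        "proton_leak": s_o - s_r,
        "maximal": s_f - s_r,
        "spare_capacity": s_f - s_b,
    }
    clipped = {k for k, v in raw.items() if v < 0}
    if clipped:
        warnings.warn(f"negative derived OCR parameter(s) clipped to 0: "
                      f"{sorted(clipped)}", stacklevel=2)
        raw = {k: max(v, 0.0) for k, v in raw.items()}
    if per_protein:
        if not trace.protein_mg or trace.protein_mg <= 0:
            raise ValueError("per-protein normalisation needs protein_mg > 0")
        raw = {k: v / trace.protein_mg for k, v in raw.items()}
    return StressTestParams(**raw, per_mg_protein=per_protein)


def simulate_trace(params: StressTestParams, noise_sd: float = 0.0,
                   seed: int | np.random.Generator = 0,
                   points_per_phase: int = 3, dt_min: float = 10.0,
                   protein_mg: float | None = None, well: str = "") -> OCRTrace:
    """Piecewise-constant OCR trace implied by stress-test parameters.

    Phase levels are reconstructed from the parameter identities
    (baseline = basal + non-mito, oligomycin = leak + non-mito, FCCP =
    maximal + non-mito, rotenone/antimycin = non-mito) plus Gaussian
    noise; at zero noise the trace round-trips exactly through
    :func:`stress_test_params`.
    """
    for f in ("non_mitochondrial", "basal_mitochondrial", "atp_linked",
              "proton_leak", "maximal", "spare_capacity"):
        if getattr(params, f) < 0:
            raise ValueError(f"{f} must be non-negative")
    rng = np.random.default_rng(seed)
    levels = {
        "baseline": params.non_mitochondrial + params.basal_mitochondrial,
        "oligomycin": params.non_mitochondrial + params.proton_leak,
        "FCCP": params.non_mitochondrial + params.maximal,
        "rotenone_antimycin": params.non_mitochondrial,
    }
    times, ocr, phase = [], [], []
    t = 0.0
    for p in PHASES:
        for _ in range(points_per_phase):
            times.append(t)
            ocr.append(levels[p] + rng.normal(0.0, noise_sd))
            phase.append(p)
            t += dt_min
    return OCRTrace(np.array(times), np.array(ocr), phase,
                    protein_mg=protein_mg, well=well)


class StressTest:
    """Stress-test model over one or many wells (statsmodels-style)."""

    def __init__(self, traces: list[OCRTrace] | OCRTrace,
                 summarizer: str = "mean", per_protein: bool = False):
        self.traces = [traces] if isinstance(traces, OCRTrace) else list(traces)
        self.summarizer = summarizer
        self.per_protein = per_protein

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "StressTest":
        """Build from a long table (well, time_min, ocr_pmol_min, phase)."""
        traces = []
        for well, sub in df.groupby("well", sort=True):
            sub = sub.sort_values("time_min")
            protein = (float(sub["protein_mg"].iloc[0])
                       if "protein_mg" in sub else None)
            traces.append(OCRTrace(sub["time_min"].to_numpy(),
                                   sub["ocr_pmol_min"].to_numpy(),
                                   list(sub["phase"]), protein_mg=protein,
                                   well=str(well)))
        return cls(traces, **kwargs)

    def fit(self) -> "StressTestResults":
        rows = {}
        for tr in self.traces:
            p = stress_test_params(tr, summarizer=self.summarizer,
                                   per_protein=self.per_protein)
            rows[tr.well or f"well{len(rows)}"] = p.as_series()
        return StressTestResults(self, pd.DataFrame(rows).T)


class StressTestResults:
    def __init__(self, model: StressTest, table: pd.DataFrame):
        self.model = model
        self.params = table

    def summary(self) -> str:
        unit = "pmol O2/min/mg" if self.model.per_protein else "pmol O2/min"
        desc = self.params.agg(["mean", "std"]).T
        return (f"Mitochondrial stress test ({len(self.params)} wells, {unit})\n"
                + desc.to_string(float_format=lambda v: f"{v:.4g}"))
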