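"""Sliding-window genome scan and the power-evaluation harness.

Each window of an observed chromosome is summarised, standardised with the
training parameters, and assigned a posterior probability of the MMC model
by rejection ABC.  A window is called sweep-like when that probability
exceeds the nearest-rank 99th percentile of the same probability computed
on matched neutral simulations.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .engine import HaplotypeMatrix
from .model_choice import TrainingSet, rejection_model_choice
from .params import WindowSpec
from .sumstats import window_stats

__all__ = [
    "ScanResult",
    "PowerReport",
    "make_windows",
    "scan_chromosome",
    "call_sweeps",
    "evaluate_power",
]


@dataclasses.dataclass
class ScanResult:
    """Per-window MMC posteriors for one chromosome (ordered by start)."""
    windows: list[WindowSpec]
    p_mmc: np.ndarray
    threshold: float | None = None
    calls: np.ndarray | None = None
    meta: dict = dataclasses.field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "start": [w.start for w in self.windows],
            "end": [w.end for w in self.windows],
            "p_mmc": self.p_mmc,
        })
        if self.calls is not None:
            df["call"] = np.where(self.calls, "sweep-like", "neutral")
        return df

    def write_bed(self, path, chrom: str = "chr1") -> None:
        df = self.to_frame()
        with open(path, "w") as fh:
            for k, v in self.meta.items():
                fh.write(f"# {k}={v}\n")
            for _, r in df.iterrows():
                call = r.get("call", ".")
                fh.write(f"{chrom}\t{int(r.start)}\t{int(r.end)}\t"
                         f"{r.p_mmc:.6g}\t{call}\n")

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for k, v in self.meta.items():
                fh.write(f"# {k}={v}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)


@dataclasses.dataclass
class PowerReport:
    """Sweep-detection power over replicate scans.

    A sweep replicate counts as detected when at least one window whose span
    contains the sweep position is called sweep-like.  FPR is the fraction
    of all neutral windows called sweep-like (per-window convention).
    """
    tpr: float
    fpr: float | None
    n_replicates: int
    target_region: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(self)])


def make_windows(L: int, size: int, step: int) -> list[WindowSpec]:
    """Windows [k·step, k·step+size) while the end fits within L."""
    if size > L:
        raise ValueError(f"window size {size} > chromosome length {L}")
    if step > size:
        raise ValueError(f"step {step} > size {size}")
    out = []
    start = 0
    while start + size <= L:
        out.append(WindowSpec(start, start + size))
        start += step
    return out


def scan_chromosome(m: HaplotypeMatrix, ts: TrainingSet,
                    tolerance: float = 0.10,
                    size: int | None = None, step: int | None = None,
                    windows: list[WindowSpec] | None = None) -> ScanResult:
    """Per-window MMC posterior along one chromosome."""
    if windows is None:
        if size is None:
            raise ValueError("give either windows or size/step")
        windows = make_windows(m.span[1] - m.span[0], size,
                               step if step is not None else size)
    p = np.empty(len(windows))
    for i, w in enumerate(windows):
        vec = window_stats(m, w)
        p[i] = rejection_model_choice(vec, ts, tolerance).p_mmc
    return ScanResult(windows=list(windows), p_mmc=p)


def call_sweeps(scan: ScanResult, threshold: float) -> ScanResult:
    """Flag windows whose p_mmc exceeds the neutral threshold."""
    scan.threshold = float(threshold)
    scan.calls = scan.p_mmc > threshold
    return scan


def evaluate_power(replicates: list[ScanResult], sweep_position: int,
                   neutral_replicates: list[ScanResult] | None = None
                   ) -> PowerReport:
    """TPR over sweep replicates; per-window FPR over neutral replicates.

    Every ScanResult must already have calls (see :func:`call_sweeps`).
    """
    detected = 0
    for sc in replicates:
        if sc.calls is None:
            raise ValueError("call_sweeps before evaluate_power")
        hit = any(c and w.start <= sweep_position < w.end
                  for w, c in zip(sc.windows, sc.calls))
        detected += bool(hit)
    tpr = detected / len(replicates) if replicates else np.nan
    fpr = None
    if neutral_replicates:
        calls = np.concatenate([sc.calls.astype(bool)
                                for sc in neutral_replicates])
        fpr = float(calls.mean())
    return PowerReport(
        tpr=float(tpr), fpr=fpr, n_replicates=len(replicates),
        target_region="windows whose span contains the sweep position")
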