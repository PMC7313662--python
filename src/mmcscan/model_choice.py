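"""Rejection-ABC model choice between the Kingman and MMC models.

Training vectors are the 11 window summary statistics computed on simulated
training regions.  The pipeline is: impute per-statistic degeneracies with
the most extreme observed training value (zero-variation windows are an MMC
hallmark and must stay classifiable), greedily prune statistics whose
absolute Pearson correlation with an already-kept statistic exceeds 0.8
(fixed iteration order = STAT_NAMES order), centre and scale the survivors,
and classify a target by the model-label fraction among the
round(tolerance·R) nearest training rows in Euclidean distance.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib

import numpy as np
import pandas as pd

from .engine import simulate_training_replicate
from .params import DemographyModel, PsiModel, SimulationParams
from .sumstats import STAT_NAMES

__all__ = [
    "TrainingSet",
    "ModelPosterior",
    "CVReport",
    "prune_correlated",
    "standardize",
    "rejection_model_choice",
    "loo_cv",
    "neutral_threshold",
    "build_training_set",
]

KINGMAN, MMC = 0, 1
_LABEL_NAMES = {KINGMAN: "kingman", MMC: "mmc"}


@dataclasses.dataclass
class ModelPosterior:
    p_kingman: float
    p_mmc: float
    n_accepted: int
    tolerance: float


@dataclasses.dataclass
class CVReport:
    """Leave-one-out confusion counts; rows = true model, cols = called."""
    confusion: np.ndarray          # 2x2, [true][called]
    n_folds: int

    @property
    def misclassification(self) -> dict:
        out = {}
        for lab, name in _LABEL_NAMES.items():
            tot = self.confusion[lab].sum()
            out[name] = float(self.confusion[lab, 1 - lab] / tot) if tot else np.nan
        return out


def impute_degenerate(stats: np.ndarray, fill: np.ndarray | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Replace NaN entries column-wise with the most extreme (minimum)
    observed finite value; returns (filled stats, per-column fill values).

    Zero-variation windows sit in the low-diversity tail of every statistic
    that is defined for them (S=0, π=0), so the minimum is used as the
    sentinel for the statistics that become undefined.
    """
    x = np.array(stats, dtype=np.float64)
    if fill is None:
        with np.errstate(all="ignore"):
            fill = np.nanmin(x, axis=0)
        fill = np.where(np.isfinite(fill), fill, 0.0)
    nan_r, nan_c = np.nonzero(np.isnan(x))
    x[nan_r, nan_c] = fill[nan_c]
    return x, fill


def prune_correlated(stats: np.ndarray, threshold: float = 0.8) -> np.ndarray:
    """Greedy pruning in fixed column order.

    Iterates columns left to right; a column is dropped when its absolute
    Pearson correlation with any already-kept column exceeds ``threshold``.
    Rows containing NaN (degenerate windows) are excluded from the
    correlation estimates.  Constant columns are dropped (their correlation
    is undefined and they carry no signal).
    """
    x = np.asarray(stats, dtype=np.float64)
    complete = ~np.isnan(x).any(axis=1)
    if complete.sum() < 2:
        raise ValueError("need >= 2 non-degenerate rows to estimate correlations")
    xc = x[complete]
    sd = xc.std(axis=0)
    kept: list[int] = []
    for j in range(x.shape[1]):
        if sd[j] == 0:
            continue
        ok = True
        for i in kept:
            r = np.corrcoef(xc[:, i], xc[:, j])[0, 1]
            if abs(r) > threshold:
                ok = False
                break
        if ok:
            kept.append(j)
    if not kept:
        raise ValueError("all columns pruned")
    return np.array(kept, dtype=np.int64)


def standardize(stats: np.ndarray, center: np.ndarray | None = None,
                scale: np.ndarray | None = None
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(x − center)/scale per column; training computes center=mean and
    scale=sd, targets reuse the training parameters."""
    x = np.asarray(stats, dtype=np.float64)
    if center is None:
        center = x.mean(axis=0)
    if scale is None:
        scale = x.std(axis=0)
    if np.any(scale == 0):
        raise ValueError("zero-variance column; prune before standardizing")
    return (x - center) / scale, center, scale


@dataclasses.dataclass
class TrainingSet:
    """Summary-statistic training matrix with model labels.

    ``stats`` holds the raw (unstandardized, possibly NaN) vectors;
    ``kept_columns``, ``center``, ``scale`` and ``fill`` are fitted on the
    pooled training data and reused for every target window.
    """

    stats: np.ndarray
    labels: np.ndarray
    psi_values: np.ndarray
    stat_names: list[str] = dataclasses.field(
        default_factory=lambda: list(STAT_NAMES))
    kept_columns: np.ndarray | None = None
    center: np.ndarray | None = None
    scale: np.ndarray | None = None
    fill: np.ndarray | None = None
    meta: dict = dataclasses.field(default_factory=dict)

    def fit(self, threshold: float = 0.8) -> "TrainingSet":
        filled, self.fill = impute_degenerate(self.stats)
        self.kept_columns = prune_correlated(self.stats, threshold)
        z, self.center, self.scale = standardize(filled[:, self.kept_columns])
        self._z = z
        return self

    @property
    def standardized(self) -> np.ndarray:
        if self.kept_columns is None:
            raise ValueError("call fit() first")
        if not hasattr(self, "_z"):
            filled, _ = impute_degenerate(self.stats, self.fill)
            self._z, _, _ = standardize(filled[:, self.kept_columns],
                                        self.center, self.scale)
        return self._z

    def transform(self, targets: np.ndarray) -> np.ndarray:
        """Impute + restrict + standardize target vectors with the fitted
        training parameters."""
        t = np.atleast_2d(np.asarray(targets, dtype=np.float64))
        filled, _ = impute_degenerate(t, self.fill)
        z, _, _ = standardize(filled[:, self.kept_columns],
                              self.center, self.scale)
        return z

    # ---- serialization (TSV + JSON sidecar) -------------------------------

    def save(self, path: str | pathlib.Path) -> None:
        path = pathlib.Path(path)
        df = pd.DataFrame(self.stats, columns=self.stat_names)
        df["label"] = [_LABEL_NAMES[int(l)] for l in self.labels]
        df["psi"] = self.psi_values
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        side = {
            "stat_names": self.stat_names,
            "kept_columns": None if self.kept_columns is None
            else self.kept_columns.tolist(),
            "center": None if self.center is None else self.center.tolist(),
            "scale": None if self.scale is None else self.scale.tolist(),
            "fill": None if self.fill is None else self.fill.tolist(),
            "meta": self.meta,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(side, indent=1))

    @classmethod
    def load(cls, path: str | pathlib.Path) -> "TrainingSet":
        path = pathlib.Path(path)
        df = pd.read_csv(path, sep="\t")
        side = json.loads(
            path.with_suffix(path.suffix + ".json").read_text())
        names = side["stat_names"]
        inv = {v: k for k, v in _LABEL_NAMES.items()}
        ts = cls(
            stats=df[names].to_numpy(np.float64),
            labels=np.array([inv[l] for l in df["label"]], dtype=np.int8),
            psi_values=df["psi"].to_numpy(np.float64),
            stat_names=names,
            meta=side.get("meta", {}),
        )
        for key in ("kept_columns", "center", "scale", "fill"):
            val = side.get(key)
            if val is not None:
                setattr(ts, key, np.asarray(val))
        if ts.kept_columns is not None:
            ts.kept_columns = ts.kept_columns.astype(np.int64)
        return ts


def rejection_model_choice(target: np.ndarray, ts: TrainingSet,
                           tolerance: float = 0.10) -> ModelPosterior:
    """Posterior model probabilities by the rejection sampler.

    Accepts the round(tolerance·R) nearest training rows in Euclidean
    distance on the standardized kept statistics; rows tied with the
    boundary distance are all included.  p_mmc is the accepted MMC fraction.
    """
    z = ts.standardized
    t = ts.transform(target)[0]
    d = np.sqrt(((z - t) ** 2).sum(axis=1))
    R = z.shape[0]
    k = max(1, int(round(tolerance * R)))
    order = np.argsort(d, kind="stable")
    boundary = d[order[k - 1]]
    accepted = np.flatnonzero(d <= boundary)
    p_mmc = float((ts.labels[accepted] == MMC).mean())
    return ModelPosterior(p_kingman=1.0 - p_mmc, p_mmc=p_mmc,
                          n_accepted=int(accepted.size), tolerance=tolerance)


def loo_cv(ts: TrainingSet, tolerance: float = 0.10,
           n_folds: int = 1000, seed: int = 0) -> CVReport:
    """Leave-one-out cross-validation of the model classifier.

    Each held-out replicate (uniform subsample of ``n_folds``) is classified
    against the remaining rows by argmax posterior; exact posterior ties are
    counted as misclassified.
    """
    z = ts.standardized
    R = z.shape[0]
    n_folds = min(n_folds, R)
    rng = np.random.default_rng(seed)
    folds = rng.choice(R, size=n_folds, replace=False) if n_folds < R \
        else np.arange(R)
    k = max(1, int(round(tolerance * (R - 1))))
    confusion = np.zeros((2, 2), dtype=np.int64)
    labels = ts.labels
    for i in folds:
        d = np.sqrt(((z - z[i]) ** 2).sum(axis=1))
        d[i] = np.inf
        order = np.argsort(d, kind="stable")
        boundary = d[order[k - 1]]
        accepted = np.flatnonzero(d <= boundary)
        p_mmc = float((labels[accepted] == MMC).mean())
        true = int(labels[i])
        if p_mmc == 0.5:
            called = 1 - true       # tie -> recorded as misclassified
        else:
            called = MMC if p_mmc > 0.5 else KINGMAN
        confusion[true, called] += 1
    return CVReport(confusion=confusion, n_folds=n_folds)


def neutral_threshold(neutral_pmmc_values, level: float = 0.99) -> float:
    """Nearest-rank empirical percentile of neutral p_mmc values.

    The threshold is the smallest value v such that at least ``level`` of
    the neutral probabilities are <= v (nearest-rank definition; e.g. 100
    values 0.00..0.99 at level 0.99 give 0.98).
    """
    v = np.sort(np.asarray(neutral_pmmc_values, dtype=np.float64))
    if v.size < 100:
        raise ValueError(f"need >= 100 neutral probabilities, got {v.size}")
    if not (0 < level <= 1):
        raise ValueError("level must be in (0, 1]")
    rank = int(np.ceil(level * v.size))
    return float(v[rank - 1])


def build_training_set(params: SimulationParams, demog: DemographyModel,
                       psi_prior: PsiModel, n_per_model: int,
                       seed: int = 0, fit: bool = True,
                       progress: bool = False) -> TrainingSet:
    """Simulate n_per_model Kingman + n_per_model MMC training replicates
    under one demography and fit the ABC preprocessing."""
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(2 * n_per_model, np.uint32)
    stats = np.empty((2 * n_per_model, len(STAT_NAMES)))
    labels = np.empty(2 * n_per_model, dtype=np.int8)
    psis = np.full(2 * n_per_model, np.nan)
    it = range(2 * n_per_model)
    if progress:
        from tqdm import tqdm  # pragma: no cover
        it = tqdm(it, desc="training")
    for i in it:
        model = "kingman" if i < n_per_model else "mmc"
        vec, psi = simulate_training_replicate(
            model, demog, params, psi_prior, seed=int(seeds[i]))
        stats[i] = vec
        labels[i] = KINGMAN if model == "kingman" else MMC
        if psi is not None:
            psis[i] = psi
    ts = TrainingSet(stats=stats, labels=labels, psi_values=psis,
                     meta={"n_per_model": n_per_model, "seed": seed,
                           "demography": dataclasses.asdict(demog),
                           "params": dataclasses.asdict(params),
                           "psi_prior": dataclasses.asdict(psi_prior)})
    if fit:
        ts.fit()
    return ts
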