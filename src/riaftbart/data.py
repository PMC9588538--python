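"""Clustered multi-treatment survival data: container, validation, I/O, Kaplan-Meier.

The data model is one row per subject: an observed follow-up time ``y`` (months),
an event indicator ``delta`` (1 = failure observed, 0 = right-censored), a
categorical treatment label with J >= 2 arms, a cluster identifier (e.g. the
treating institution) with K >= 2 levels, and a block of pre-treatment
covariates.  Categorical covariates are one-hot expanded (reference level
dropped); missing values are rejected, not imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter


class ValidationError(ValueError):
    """Raised when input data violate the survival-data contract."""


class ConfigurationError(ValueError):
    """Raised for bad column maps / missing columns."""


@dataclass
class StepSurvivalCurve:
    """Right-continuous step survival function.

    ``times`` are the strictly increasing event times; ``surv[i]`` is the
    survival probability at ``times[i]`` (just after the drop).  S(0) = 1 is
    implicit and not stored.
    """

    times: np.ndarray
    surv: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.surv = np.asarray(self.surv, dtype=float)
        if self.times.ndim != 1 or self.surv.shape != self.times.shape:
            raise ValidationError("times and surv must be 1-d arrays of equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")
        if self.surv.size and (self.surv[0] > 1.0 + 1e-12 or np.any(np.diff(self.surv) > 1e-12)):
            raise ValidationError("surv must start <= 1 and be non-increasing")

    def __call__(self, t: np.ndarray) -> np.ndarray:
        """Evaluate S(t) by step interpolation (S(t)=1 before the first event)."""
        t = np.asarray(t, dtype=float)
        if self.times.size == 0:
            return np.ones_like(t)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.surv[np.clip(idx, 0, None)], 1.0)
        return out


@dataclass
class ClusteredSurvivalData:
    """Validated clustered survival data.

    Attributes
    ----------
    y : (N,) float array of observed times in months, all > 0.
    delta : (N,) int array, 1 = event, 0 = right-censored.
    a : (N,) array of treatment labels (J >= 2 distinct values).
    cluster : (N,) int array of cluster indices re-coded 1..K (sorted original
        labels); the original labels are kept in ``cluster_labels``.
    x : (N, p) DataFrame of numeric covariates (categoricals already one-hot
        expanded with the reference level dropped).
    """

    y: np.ndarray
    delta: np.ndarray
    a: np.ndarray
    cluster: np.ndarray
    x: pd.DataFrame
    cluster_labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.delta = np.asarray(self.delta)
        self.a = np.asarray(self.a)
        self.cluster = np.asarray(self.cluster)
        if not isinstance(self.x, pd.DataFrame):
            self.x = pd.DataFrame(np.asarray(self.x, dtype=float))
            self.x.columns = [f"x{j + 1}" for j in range(self.x.shape[1])]
        n = self.y.shape[0]
        for name, arr in (("delta", self.delta), ("a", self.a), ("cluster", self.cluster)):
            if len(arr) != n:
                raise ValidationError(f"{name} has length {len(arr)}, expected {n}")
        if len(self.x) != n:
            raise ValidationError(f"x has {len(self.x)} rows, expected {n}")

        bad = np.flatnonzero(~np.isfinite(self.y) | (self.y <= 0))
        if bad.size:
            raise ValidationError(f"y must be finite and > 0; offending rows: {bad.tolist()}")
        d = np.asarray(self.delta, dtype=float)
        bad = np.flatnonzero(~np.isin(d, (0.0, 1.0)))
        if bad.size:
            raise ValidationError(f"delta must be 0 or 1; offending rows: {bad.tolist()}")
        self.delta = d.astype(int)
        if pd.isna(pd.Series(self.a)).any() or pd.isna(pd.Series(self.cluster)).any():
            raise ValidationError("missing treatment or cluster labels")
        if self.x.isna().any().any():
            rows = np.flatnonzero(self.x.isna().any(axis=1).to_numpy())
            raise ValidationError(f"missing covariate values; offending rows: {rows.tolist()}")

        # re-index clusters 1..K deterministically by sorted original label
        orig = pd.unique(pd.Series(self.cluster))
        orig_sorted = np.sort(np.asarray(orig))
        if not self.cluster_labels:
            self.cluster_labels = {int(i + 1): lab for i, lab in enumerate(orig_sorted)}
        lab_to_idx = {lab: i + 1 for i, lab in enumerate(orig_sorted)}
        self.cluster = np.asarray([lab_to_idx[c] for c in self.cluster], dtype=int)

        if len(self.treatments) < 2:
            raise ValidationError("need at least 2 treatment arms")
        if self.n_clusters < 2:
            raise ValidationError("need at least 2 clusters")

    # -- basic shape accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def n_clusters(self) -> int:
        return int(self.cluster.max())

    @property
    def treatments(self) -> np.ndarray:
        """Sorted distinct treatment labels a_1 < ... < a_J."""
        return np.sort(pd.unique(pd.Series(self.a)))

    @property
    def n_treatments(self) -> int:
        return len(self.treatments)

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.cluster, minlength=self.n_clusters + 1)[1:]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.y, "event": self.delta, "treatment": self.a,
                           "cluster": [self.cluster_labels[int(c)] for c in self.cluster]})
        return pd.concat([df, self.x.reset_index(drop=True)], axis=1)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def replace_times(self, y: np.ndarray) -> "ClusteredSurvivalData":
        """Copy with new observed times (used by the sensitivity correction)."""
        return ClusteredSurvivalData(
            y=np.asarray(y, float), delta=self.delta.copy(), a=self.a.copy(),
            cluster=np.asarray([self.cluster_labels[int(c)] for c in self.cluster]),
            x=self.x.copy(), cluster_labels=dict(self.cluster_labels))


DEFAULT_COLUMN_MAP = {"time": "time", "event": "event", "treatment": "treatment",
                      "cluster": "cluster"}


def from_dataframe(df: pd.DataFrame,
                   time: str = "time", event: str = "event",
                   treatment: str = "treatment", cluster: str = "cluster",
                   covariates: Sequence[str] | None = None) -> ClusteredSurvivalData:
    """Build a validated :class:`ClusteredSurvivalData` from a tidy DataFrame.

    Categorical / string covariates are expanded to indicator columns with the
    first (sorted) level dropped as reference.
    """
    for col in (time, event, treatment, cluster):
        if col not in df.columns:
            raise ConfigurationError(f"column '{col}' not found in input")
    if covariates is None:
        covariates = [c for c in df.columns if c not in (time, event, treatment, cluster)]
    else:
        missing = [c for c in covariates if c not in df.columns]
        if missing:
            raise ConfigurationError(f"covariate columns not found: {missing}")
    xdf = df[list(covariates)].copy()
    cat_cols = [c for c in xdf.columns
                if xdf[c].dtype == object or isinstance(xdf[c].dtype, pd.CategoricalDtype)]
    if cat_cols:
        xdf = pd.get_dummies(xdf, columns=cat_cols, drop_first=True, dtype=float)
    xdf = xdf.astype(float)
    return ClusteredSurvivalData(
        y=df[time].to_numpy(), delta=df[event].to_numpy(), a=df[treatment].to_numpy(),
        cluster=df[cluster].to_numpy(), x=xdf.reset_index(drop=True))


def load_clustered_survival(path, column_map: Mapping[str, str] | None = None,
                            covariates: Sequence[str] | None = None,
                            sep: str | None = None) -> ClusteredSurvivalData:
    """Load a CSV/TSV file into a validated :class:`ClusteredSurvivalData`.

    ``column_map`` maps the roles ``time``, ``event``, ``treatment``,
    ``cluster`` to column names in the file; unlisted columns (or the explicit
    ``covariates`` list) become the covariate block.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    return from_dataframe(df, time=cmap["time"], event=cmap["event"],
                          treatment=cmap["treatment"], cluster=cmap["cluster"],
                          covariates=covariates)


def kaplan_meier(y: np.ndarray, delta: np.ndarray) -> StepSurvivalCurve:
    """Product-limit (Kaplan-Meier) estimator of the survival function.

    Ties between event times are handled by a single simultaneous
    multiplication at the tied time.  Returns the curve evaluated at the
    distinct event times only.
    """
    y = np.asarray(y, dtype=float)
    delta = np.asarray(delta, dtype=int)
    if y.size == 0:
        raise ValidationError("empty input")
    if y.shape != delta.shape:
        raise ValidationError("y and delta must have the same length")
    if np.any(y <= 0):
        raise ValidationError("all times must be > 0")
    km = KaplanMeierFitter()
    km.fit(y, event_observed=delta)
    event_times = np.unique(y[delta == 1])
    if event_times.size == 0:
        return StepSurvivalCurve(times=np.array([]), surv=np.array([]))
    surv = km.survival_function_at_times(event_times).to_numpy()
    return StepSurvivalCurve(times=event_times, surv=surv)
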