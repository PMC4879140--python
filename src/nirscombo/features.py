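"""Epoch segmentation and the six per-epoch signal features.

Each contiguous task or rest block, per channel and per chromophore, is one
epoch — and one classification sample.  With the default paradigm (initial
rest + 5 × task/rest) and 16 channels this yields 80 task and 96 rest samples
per subject per chromophore.

Six time-domain features are computed per epoch, with population (1/N)
moments exactly as conventionally printed:

- signal mean            M        = (1/N) Σ Xᵢ
- signal variance        var(X)   = Σ (X − μ)² / N
- signal skewness        skew(X)  = E[((X − μ)/σ)³]
- signal kurtosis        kurt(X)  = E[((X − μ)/σ)⁴]   (non-excess; normal → 3)
- signal peak            max(X)   (signed maximum, both chromophores)
- signal slope           least-squares line fit against time in seconds (μM/s)

Feature columns are min-max rescaled to [0, 1]:  x′ = (x − min x)/(max x − min x),
by default per subject × chromophore over all epochs; a stored scaling record
allows fitting on training folds only (the leakage-safe mode).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mbll import HemoSeries

__all__ = [
    "FEATURE_NAMES",
    "Epoch",
    "MinMaxScaling",
    "epochize",
    "feat_mean",
    "feat_variance",
    "feat_skewness",
    "feat_kurtosis",
    "feat_peak",
    "feat_slope",
    "compute_features",
    "feature_table",
    "rescale_minmax",
]

logger = logging.getLogger("nirscombo.features")

#: Canonical feature order used everywhere (combo enumeration, tables).
FEATURE_NAMES = ("mean", "slope", "variance", "peak", "skewness", "kurtosis")

PROVENANCE_COLUMNS = ("subject", "channel", "block", "label", "chromophore")


class DegenerateEpochError(ValueError):
    """Raised when an epoch has zero variance and a moment ratio is undefined."""


@dataclass
class Epoch:
    """One task or rest segment of one channel of one chromophore."""

    subject_id: int
    channel_index: int
    label: str  # "task" | "rest"
    start: int  # half-open sample range [start, end)
    end: int
    chromophore: str  # "HbO" | "HbR"
    data: np.ndarray
    t: np.ndarray  # seconds

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        if self.end <= self.start:
            raise ValueError("epoch sample range must be non-empty (end > start)")
        if self.data.size != self.end - self.start or self.t.size != self.data.size:
            raise ValueError("epoch data/time length must equal end - start")
        if self.label not in ("task", "rest"):
            raise ValueError(f"label must be 'task' or 'rest', got {self.label!r}")


def _runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Contiguous (value, start, end) runs of a label vector."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label vector")
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [labels.size]])
    return [(int(labels[s]), int(s), int(e)) for s, e in zip(starts, ends)]


def epochize(
    x: HemoSeries,
    labels: np.ndarray,
    subject_id: int = 0,
    chromophores: tuple[str, ...] = ("HbO", "HbR"),
    drop_initial_rest: bool = False,
) -> list[Epoch]:
    """Cut a concentration series into per-block, per-channel, per-chromophore epochs.

    ``drop_initial_rest`` skips a leading rest block (the baseline period),
    which balances the classes at one rest block per task block.
    """
    labels = np.asarray(labels)
    if labels.size != x.n_samples:
        raise ValueError(
            f"label vector ({labels.size}) misaligned with series ({x.n_samples} samples)"
        )
    t = np.arange(x.n_samples) / x.fs
    epochs = []
    runs = _runs(labels)
    if drop_initial_rest and runs and runs[0][0] == 0:
        runs = runs[1:]
    for value, start, end in runs:
        name = "task" if value else "rest"
        for chrom in chromophores:
            arr = x.chromophore(chrom)
            for c in range(x.n_channels):
                epochs.append(
                    Epoch(
                        subject_id=subject_id,
                        channel_index=c,
                        label=name,
                        start=start,
                        end=end,
                        chromophore=chrom,
                        data=arr[start:end, c],
                        t=t[start:end],
                    )
                )
    return epochs


def _data(e) -> np.ndarray:
    x = e.data if isinstance(e, Epoch) else np.asarray(e, dtype=float)
    if x.size == 0:
        raise ValueError("empty epoch")
    return x


def feat_mean(e) -> float:
    """Epoch mean M = (1/N) Σ Xᵢ."""
    return float(np.mean(_data(e)))


def feat_variance(e) -> float:
    """Population variance Σ(X − μ)²/N (divide by N, not N−1)."""
    return float(np.var(_data(e)))


def _std_moment(x: np.ndarray, k: int) -> float:
    mu = x.mean()
    sigma = x.std()
    if sigma == 0:
        raise DegenerateEpochError("zero standard deviation: standardized moment undefined")
    return float(np.mean(((x - mu) / sigma) ** k))


def feat_skewness(e) -> float:
    """Population skewness E[((X − μ)/σ)³]."""
    return _std_moment(_data(e), 3)


def feat_kurtosis(e) -> float:
    """Population non-excess kurtosis E[((X − μ)/σ)⁴] (normal samples ≈ 3)."""
    return _std_moment(_data(e), 4)


def feat_peak(e, absolute: bool = False) -> float:
    """Signed maximum of the epoch (for HbR this is the least-negative value).

    ``absolute=True`` returns the largest magnitude instead; the default
    applies one plain maximum to both chromophores.
    """
    x = _data(e)
    if absolute:
        return float(np.max(np.abs(x)))
    return float(np.max(x))


def feat_slope(e, t: np.ndarray | None = None) -> float:
    """Least-squares slope of the epoch against time in seconds (μM/s)."""
    x = _data(e)
    if x.size < 2:
        raise ValueError("slope needs at least 2 samples")
    if t is None:
        if not isinstance(e, Epoch):
            raise ValueError("time vector required when data is a bare array")
        t = e.t
    t = np.asarray(t, dtype=float)
    return float(np.polyfit(t, x, 1)[0])


_FEATURE_FUNCS = {
    "mean": feat_mean,
    "slope": feat_slope,
    "variance": feat_variance,
    "peak": feat_peak,
    "skewness": feat_skewness,
    "kurtosis": feat_kurtosis,
}


def compute_features(e: Epoch) -> dict[str, float]:
    """All six features of one epoch, in canonical order."""
    return {name: _FEATURE_FUNCS[name](e) for name in FEATURE_NAMES}


def feature_table(
    epochs: list[Epoch],
    on_degenerate: str = "error",
) -> pd.DataFrame:
    """Assemble the epoch × feature table with provenance columns.

    ``on_degenerate``: "error" raises on a zero-variance epoch; "drop" skips
    it with a logged warning (batch mode).
    """
    if on_degenerate not in ("error", "drop"):
        raise ValueError("on_degenerate must be 'error' or 'drop'")
    rows = []
    for e in epochs:
        try:
            feats = compute_features(e)
        except DegenerateEpochError:
            if on_degenerate == "error":
                raise
            logger.warning(
                "dropping degenerate epoch (subject %s, channel %s, %s %s)",
                e.subject_id, e.channel_index, e.chromophore, e.label,
            )
            continue
        rows.append(
            {
                "subject": e.subject_id,
                "channel": e.channel_index,
                "block": e.start,
                "label": e.label,
                "chromophore": e.chromophore,
                **feats,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class MinMaxScaling:
    """Per-column min/max record; lets training-fold parameters apply to test folds."""

    mins: pd.Series
    maxs: pd.Series

    @classmethod
    def fit(cls, df: pd.DataFrame, columns=FEATURE_NAMES) -> "MinMaxScaling":
        cols = list(columns)
        mins = df[cols].min()
        maxs = df[cols].max()
        constant = [c for c in cols if maxs[c] <= mins[c]]
        if constant:
            raise ValueError(f"constant feature column(s), cannot min-max scale: {constant}")
        return cls(mins=mins, maxs=maxs)

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        cols = list(self.mins.index)
        out[cols] = (df[cols] - self.mins) / (self.maxs - self.mins)
        return out


def rescale_minmax(
    df: pd.DataFrame,
    columns=FEATURE_NAMES,
    by: tuple[str, ...] | None = ("subject", "chromophore"),
) -> tuple[pd.DataFrame, dict]:
    """Rescale feature columns to [0, 1], by default within subject × chromophore.

    Returns the rescaled table and a dict of scaling records keyed by group.
    """
    cols = [c for c in columns if c in df.columns]
    if not cols:
        raise ValueError("no feature columns to rescale")
    records: dict = {}
    if by:
        keys = [k for k in by if k in df.columns]
        parts = []
        for key, group in df.groupby(list(keys), sort=True):
            scaling = MinMaxScaling.fit(group, cols)
            records[key] = scaling
            parts.append(scaling.transform(group))
        out = pd.concat(parts).sort_index()
    else:
        scaling = MinMaxScaling.fit(df, cols)
        records[()] = scaling
        out = scaling.transform(df)
    return out, records


def write_feature_tsv(path, df: pd.DataFrame, scaling: dict | None = None) -> None:
    """Feature table to TSV plus an optional sidecar JSON of scaling parameters."""
    import json
    from pathlib import Path

    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    if scaling is not None:
        sidecar = {
            str(key): {
                "min": {k: float(v) for k, v in rec.mins.items()},
                "max": {k: float(v) for k, v in rec.maxs.items()},
            }
            for key, rec in scaling.items()
        }
        path.with_suffix(".scaling.json").write_text(json.dumps(sidecar, indent=1))
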