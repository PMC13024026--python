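"""Evaluation statistics for brain-age models.

Three suites, matching how lifespan brain-age models are judged in practice:

* accuracy on cross-sectional scans — MAE, signed mean error (ME), Pearson r,
  R^2, per-decade-bin MAE and its maximum (mMAE, worst age range);
* longitudinal consistency — the error of the *predicted change* between a
  baseline and follow-up scan against the true elapsed time (MdE, MAdE and
  the binned maximum mMAdE);
* test-retest reproducibility — within-subject SD of repeated predictions,
  the mean and SD of the retest difference, and ICC(3,1) (two-way mixed
  effects, consistency definition, single measurement).

Small occupied bins are reported but excluded from the binned maxima, since
a 2-subject bin can inflate the worst-case error arbitrarily.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class PredictionSet:
    """Paired (true age, predicted age) values, one entry per scan."""

    scan_id: np.ndarray
    y_true: np.ndarray
    y_pred: np.ndarray
    subject_id: np.ndarray | None = None

    def __post_init__(self):
        self.scan_id = np.asarray(self.scan_id, dtype=object)
        self.y_true = np.asarray(self.y_true, dtype=float)
        self.y_pred = np.asarray(self.y_pred, dtype=float)
        if self.subject_id is not None:
            self.subject_id = np.asarray(self.subject_id, dtype=object)
        if len(self.y_true) < 1:
            raise ValueError("PredictionSet needs at least one entry")
        if not (np.all(np.isfinite(self.y_true)) and np.all(np.isfinite(self.y_pred))):
            raise ValueError("ages and predictions must be finite")

    @property
    def n(self) -> int:
        return len(self.y_true)

    def to_frame(self) -> pd.DataFrame:
        d = {"scan_id": self.scan_id, "age": self.y_true, "predicted_age": self.y_pred}
        if self.subject_id is not None:
            d["subject_id"] = self.subject_id
        return pd.DataFrame(d)

    def to_csv(self, path):
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PredictionSet":
        df = pd.read_csv(path)
        return cls(df["scan_id"].to_numpy(), df["age"].to_numpy(),
                   df["predicted_age"].to_numpy(),
                   df["subject_id"].to_numpy() if "subject_id" in df else None)


@dataclass
class PairSet:
    """Two scans per subject: baseline/follow-up or test/retest predictions."""

    subject_id: np.ndarray
    y1: np.ndarray
    yhat1: np.ndarray
    y2: np.ndarray
    yhat2: np.ndarray

    def __post_init__(self):
        self.subject_id = np.asarray(self.subject_id, dtype=object)
        for name in ("y1", "yhat1", "y2", "yhat2"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if len(self.subject_id) < 1:
            raise ValueError("PairSet needs at least one paired subject")

    @property
    def m(self) -> int:
        return len(self.subject_id)

    @property
    def delta_true(self) -> np.ndarray:
        return self.y2 - self.y1

    @property
    def delta_pred(self) -> np.ndarray:
        return self.yhat2 - self.yhat1

    @property
    def change_error(self) -> np.ndarray:
        return self.delta_pred - self.delta_true

    @classmethod
    def from_predictions(cls, preds: PredictionSet, first_ids, second_ids) -> "PairSet":
        """Pair scans by subject given the ids of first- and second-session scans."""
        if preds.subject_id is None:
            raise ValueError("pairing requires subject ids on the predictions")
        by_scan = {s: i for i, s in enumerate(preds.scan_id)}
        first = {}
        for s in first_ids:
            first[preds.subject_id[by_scan[s]]] = by_scan[s]
        rows = []
        seen = set()
        for s in second_ids:
            i2 = by_scan[s]
            subj = preds.subject_id[i2]
            if subj not in first:
                raise ValueError(f"subject {subj!r} has a second scan but no first scan")
            i1 = first.pop(subj)
            seen.add(subj)
            rows.append((subj, preds.y_true[i1], preds.y_pred[i1],
                         preds.y_true[i2], preds.y_pred[i2]))
        if first:
            missing = sorted(map(str, first))
            raise ValueError(f"unpaired subjects (missing second scan): {missing}")
        arr = list(zip(*rows))
        return cls(np.array(arr[0], dtype=object), *map(np.array, arr[1:]))


@dataclass
class AgeBinning:
    """Left-closed, right-open age bins; default decades 0-100."""

    edges: np.ndarray = field(default_factory=lambda: np.arange(0.0, 101.0, 10.0))
    min_bin_n: int = 3

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=float)
        if not np.all(np.diff(self.edges) > 0):
            raise ValueError("bin edges must be strictly increasing")
        if self.min_bin_n < 1:
            raise ValueError("min_bin_n must be >= 1")

    def assign(self, ages: np.ndarray) -> np.ndarray:
        ages = np.asarray(ages, dtype=float)
        bad = (ages < self.edges[0]) | (ages >= self.edges[-1])
        if np.any(bad):
            raise ValueError(
                f"ages outside binning range [{self.edges[0]}, {self.edges[-1]}): "
                f"{ages[bad][:5].tolist()}")
        return np.searchsorted(self.edges, ages, side="right") - 1

    @property
    def k(self) -> int:
        return len(self.edges) - 1


# ---------------------------------------------------------------------------
# accuracy
# ---------------------------------------------------------------------------

def accuracy_metrics(preds: PredictionSet) -> dict:
    y, yh = preds.y_true, preds.y_pred
    out = {"n": preds.n,
           "mae": float(np.mean(np.abs(yh - y))),
           "me": float(np.mean(yh - y)),
           "r": None, "r2": None, "flags": []}
    if preds.n < 2:
        out["flags"].append("r/r2 undefined: fewer than 2 samples")
        return out
    sy = y - y.mean()
    syh = yh - yh.mean()
    den = math.sqrt(float(sy @ sy) * float(syh @ syh))
    if float(sy @ sy) == 0.0:
        out["flags"].append("r/r2 undefined: zero variance in true ages")
        return out
    if den == 0.0:
        out["flags"].append("r undefined: zero variance in predictions")
    else:
        out["r"] = float((sy @ syh) / den)
    out["r2"] = float(1.0 - ((yh - y) @ (yh - y)) / (sy @ sy))
    return out


def _binned_table(values: np.ndarray, bins: np.ndarray, binning: AgeBinning,
                  col: str) -> pd.DataFrame:
    rows = []
    for k in range(binning.k):
        mask = bins == k
        n_k = int(mask.sum())
        rows.append({
            "bin_low": binning.edges[k], "bin_high": binning.edges[k + 1],
            "n": n_k,
            col: float(np.mean(values[mask])) if n_k else np.nan,
            "excluded": bool(n_k and n_k < binning.min_bin_n),
        })
    return pd.DataFrame(rows)


def _binned_max(table: pd.DataFrame, col: str):
    ok = table[(table["n"] >= 1) & ~table["excluded"]]
    if len(ok) == 0:
        return None, ["binned maximum undefined: no eligible bin"]
    return float(ok[col].max()), []


def binned_mae(preds: PredictionSet, binning: AgeBinning | None = None):
    """Per-bin MAE table and the maximum over eligible bins (mMAE)."""
    binning = binning or AgeBinning()
    bins = binning.assign(preds.y_true)
    table = _binned_table(np.abs(preds.y_pred - preds.y_true), bins, binning, "mae")
    mmae, flags = _binned_max(table, "mae")
    return table, mmae, flags


# ---------------------------------------------------------------------------
# longitudinal consistency
# ---------------------------------------------------------------------------

def longitudinal_metrics(pairs: PairSet, binning: AgeBinning | None = None) -> dict:
    """Change-error statistics; bins are taken on the baseline chronological age."""
    binning = binning or AgeBinning()
    delta = pairs.change_error
    bins = binning.assign(pairs.y1)
    table = _binned_table(np.abs(delta), bins, binning, "made")
    mmade, flags = _binned_max(table, "made")
    return {"m": pairs.m,
            "mde": float(np.mean(delta)),
            "made": float(np.mean(np.abs(delta))),
            "mmade": mmade,
            "table": table,
            "flags": flags}


# ---------------------------------------------------------------------------
# test-retest reproducibility
# ---------------------------------------------------------------------------

def icc_3_1(matrix: np.ndarray) -> float:
    """ICC(3,1): two-way mixed effects, consistency, single measurement.

    matrix is (subjects x repeated measurements) with no missing cells.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D subjects x measurements matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError(f"need >= 2 subjects and >= 2 measurements, got {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("missing or non-finite cells are not supported")
    gm = x.mean()
    ss_subject = k * np.sum((x.mean(axis=1) - gm) ** 2)
    ss_measure = n * np.sum((x.mean(axis=0) - gm) ** 2)
    ss_total = np.sum((x - gm) ** 2)
    ss_error = ss_total - ss_subject - ss_measure
    ms_subject = ss_subject / (n - 1)
    ms_error = ss_error / ((n - 1) * (k - 1))
    denom = ms_subject + (k - 1) * ms_error
    if denom == 0.0:
        raise ZeroDivisionError("ICC undefined: no between- or within-subject variance")
    return float((ms_subject - ms_error) / denom)


def retest_metrics(pairs: PairSet) -> dict:
    """Within-subject SD, retest difference stats and ICC(3,1).

    The SD of two values uses the sample (n-1) form, i.e. |d| / sqrt(2).
    """
    d = pairs.yhat1 - pairs.yhat2
    sigma_i = np.abs(d) / math.sqrt(2.0)
    out = {"m": pairs.m,
           "sigma_scan": float(np.mean(sigma_i)),
           "mu_d": float(np.mean(d)),
           "sigma_d": float(np.std(d, ddof=1)) if pairs.m > 1 else None,
           "icc": None, "ms_subject": None, "ms_error": None, "flags": []}
    if pairs.m < 2:
        out["flags"].append("sigma_d/ICC undefined: fewer than 2 paired subjects")
        return out
    mat = np.column_stack([pairs.yhat1, pairs.yhat2])
    n, k = mat.shape
    gm = mat.mean()
    ss_subject = k * np.sum((mat.mean(axis=1) - gm) ** 2)
    ss_measure = n * np.sum((mat.mean(axis=0) - gm) ** 2)
    ss_error = np.sum((mat - gm) ** 2) - ss_subject - ss_measure
    out["ms_subject"] = float(ss_subject / (n - 1))
    out["ms_error"] = float(ss_error / ((n - 1) * (k - 1)))
    try:
        out["icc"] = icc_3_1(mat)
    except ZeroDivisionError:
        out["flags"].append("ICC undefined: all predictions identical")
    return out


# ---------------------------------------------------------------------------
# consolidated report
# ---------------------------------------------------------------------------

@dataclass
class MetricReport:
    accuracy: dict | None = None
    longitudinal: dict | None = None
    retest: dict | None = None

    def to_dict(self) -> dict:
        def clean(d):
            if d is None:
                return None
            d = dict(d)
            if isinstance(d.get("table"), pd.DataFrame):
                d["table"] = d["table"].to_dict(orient="records")
            return d
        return {"accuracy": clean(self.accuracy),
                "longitudinal": clean(self.longitudinal),
                "retest": clean(self.retest)}

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2, sort_keys=True, allow_nan=True)
        if path is not None:
            Path(path).parent.mkdir(parents=True, exist_ok=True)
            Path(path).write_text(s)
        return s

    def summary(self) -> str:
        lines = []
        if self.accuracy:
            a = self.accuracy
            lines.append(f"accuracy      n={a['n']}  MAE={a['mae']:.3f}  ME={a['me']:+.3f}"
                         + (f"  r={a['r']:.4f}" if a.get("r") is not None else "")
                         + (f"  R2={a['r2']:.4f}" if a.get("r2") is not None else "")
                         + (f"  mMAE={a['mmae']:.3f}" if a.get("mmae") is not None else ""))
        if self.longitudinal:
            g = self.longitudinal
            mm = f"  mMAdE={g['mmade']:.3f}" if g.get("mmade") is not None else ""
            lines.append(f"longitudinal  m={g['m']}  MdE={g['mde']:+.3f}  MAdE={g['made']:.3f}{mm}")
        if self.retest:
            t = self.retest
            icc = f"  ICC={t['icc']:.4f}" if t.get("icc") is not None else "  ICC=undefined"
            sd = f"  sd(d)={t['sigma_d']:.3f}" if t.get("sigma_d") is not None else ""
            lines.append(f"retest        m={t['m']}  sd(scan)={t['sigma_scan']:.3f}"
                         f"  mean(d)={t['mu_d']:+.3f}{sd}{icc}")
        return "\n".join(lines)


def evaluate_accuracy(preds: PredictionSet, binning: AgeBinning | None = None) -> dict:
    out = accuracy_metrics(preds)
    table, mmae, flags = binned_mae(preds, binning)
    out["mmae"] = mmae
    out["table"] = table
    out["flags"] = out["flags"] + flags
    return out
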