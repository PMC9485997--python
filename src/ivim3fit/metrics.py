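"""Quantitative evaluation of IVIM fits.

Three kinds of summaries:

* **RMSE against simulation ground truth** — the per-parameter
  root-mean-square error of a fitting method on simulated curves, reported
  on native parameter scales (mm²/s for decay constants, dimensionless for
  fractions), the criterion used to benchmark neural against least-squares
  fitting at each noise level.
* **Parameter-map SNR** — mean divided by sample standard deviation of a
  fitted parameter within a homogeneous ROI, a precision proxy for map
  quality.
* **Method/model comparison** — paired per-subject (or per-replicate)
  differences with Wilcoxon signed-rank and paired-t statistics, and
  Spearman rank correlation against ordinal clinical grades.  All test
  statistics are delegated to scipy.stats.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import ValidationError

__all__ = [
    "rmse",
    "normalised_rmse",
    "rmse_table",
    "map_snr",
    "map_snr_table",
    "compare_methods",
    "correlate_with_grades",
]


def _param_dict(p) -> dict[str, np.ndarray]:
    if hasattr(p, "as_dict"):
        p = p.as_dict()
    return {k: np.asarray(v, dtype=float) for k, v in p.items()}


def rmse(pred, truth, parameters: Optional[Sequence[str]] = None) -> dict[str, float]:
    """Per-parameter root-mean-square error sqrt(mean((pred - truth)²)).

    ``pred`` and ``truth`` may be parameter containers or mappings of equal
    length arrays; only parameters present in both are compared unless an
    explicit list is given.
    """
    pred_d, truth_d = _param_dict(pred), _param_dict(truth)
    if parameters is None:
        parameters = [k for k in pred_d if k in truth_d]
        if not parameters:
            raise ValidationError("no common parameters to compare")
    out = {}
    for name in parameters:
        p, t = np.ravel(pred_d[name]), np.ravel(truth_d[name])
        if p.shape != t.shape:
            raise ValidationError(f"length mismatch for {name}")
        out[name] = float(np.sqrt(np.mean((p - t) ** 2)))
    return out


def normalised_rmse(pred, truth, parameters: Optional[Sequence[str]] = None) -> dict[str, float]:
    """RMSE divided by the truth mean per parameter, for cross-parameter aggregation."""
    pred_d, truth_d = _param_dict(pred), _param_dict(truth)
    raw = rmse(pred_d, truth_d, parameters)
    out = {}
    for name, v in raw.items():
        denom = float(np.mean(np.abs(truth_d[name])))
        out[name] = v / denom if denom > 0 else np.inf
    return out


def rmse_table(entries: Mapping[tuple[str, float], Mapping[str, float]]) -> pd.DataFrame:
    """Assemble {(method, snr_level) -> {param -> rmse}} into a table."""
    idx = pd.MultiIndex.from_tuples(entries.keys(), names=["method", "snr_level"])
    table = pd.DataFrame(list(entries.values()), index=idx)
    if (table.to_numpy() < 0).any():
        raise ValidationError("RMSE entries must be non-negative")
    return table.sort_index()


def map_snr(param_map, roi=None, ddof: int = 1) -> float:
    """Mean/SD of a parameter map inside an ROI (sample SD convention).

    Returns NaN (flagged undefined) when the ROI has zero variance.
    """
    values = np.asarray(param_map, dtype=float)
    if roi is not None:
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != values.shape:
            raise ValidationError("ROI shape does not match map shape")
        values = values[roi]
    values = values.ravel()
    if values.size < 2:
        raise ValidationError("ROI must select at least 2 voxels")
    sd = float(values.std(ddof=ddof))
    if sd == 0:
        return np.nan
    return float(values.mean()) / sd


def map_snr_table(
    maps_per_subject: Mapping[str, Mapping[str, np.ndarray]],
    rois: Mapping[str, np.ndarray],
) -> pd.DataFrame:
    """Per-subject rows of per-parameter map SNR within each subject's ROI."""
    rows = {}
    for subject, maps in maps_per_subject.items():
        roi = rois[subject]
        rows[subject] = {name: map_snr(m, roi) for name, m in maps.items()}
    return pd.DataFrame.from_dict(rows, orient="index")


def _paired_tests(a: np.ndarray, b: np.ndarray) -> dict[str, float]:
    diff = a - b
    out = {
        "mean_diff": float(diff.mean()),
        "direction": int(np.sign(diff.mean())),
        "n": int(diff.size),
    }
    if np.allclose(diff, 0):
        out.update(wilcoxon_stat=0.0, wilcoxon_p=1.0, t_stat=0.0, t_p=1.0)
        return out
    try:
        w = stats.wilcoxon(a, b)
        out["wilcoxon_stat"], out["wilcoxon_p"] = float(w.statistic), float(w.pvalue)
    except ValueError:
        out["wilcoxon_stat"], out["wilcoxon_p"] = np.nan, np.nan
    t = stats.ttest_rel(a, b)
    out["t_stat"], out["t_p"] = float(t.statistic), float(t.pvalue)
    return out


def compare_methods(per_method: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Paired comparison of >= 2 methods evaluated on identical subjects.

    ``per_method`` maps a method name to a subjects x quantities frame (e.g.
    ROI means, map SNRs or adjusted R² per subject).  Every pair of methods
    is compared per quantity with a Wilcoxon signed-rank and a paired t
    test; a positive direction means the first method of the pair is larger.
    """
    if len(per_method) < 2:
        raise ValidationError("need at least two methods to compare")
    methods = list(per_method)
    ref = per_method[methods[0]]
    for name, frame in per_method.items():
        if not frame.index.equals(ref.index):
            raise ValidationError(f"subject set of {name!r} does not match")
    rows = []
    for m_a, m_b in combinations(methods, 2):
        fa, fb = per_method[m_a], per_method[m_b]
        for quantity in ref.columns:
            if quantity not in fa.columns or quantity not in fb.columns:
                continue
            res = _paired_tests(fa[quantity].to_numpy(float), fb[quantity].to_numpy(float))
            rows.append({"method_a": m_a, "method_b": m_b, "quantity": quantity, **res})
    return pd.DataFrame(rows)


def correlate_with_grades(param_summaries, grades) -> pd.DataFrame:
    """Spearman rank correlation of per-subject parameter values vs ordinal grades.

    Intended for user-supplied clinical tables (e.g. fibrosis or disease
    activity grades); returns one row per parameter with the tie-corrected
    coefficient and its p-value.
    """
    if isinstance(param_summaries, pd.DataFrame):
        params = {c: param_summaries[c].to_numpy(float) for c in param_summaries.columns}
    else:
        params = {k: np.asarray(v, dtype=float) for k, v in param_summaries.items()}
    grades = np.asarray(grades, dtype=float)
    if grades.size < 5:
        raise ValidationError("need at least 5 subjects")
    if np.all(grades == grades[0]):
        raise ValidationError("grades are constant; rank correlation undefined")
    rows = []
    for name, values in params.items():
        if values.size != grades.size:
            raise ValidationError(f"length mismatch for {name}")
        r = stats.spearmanr(values, grades)
        rows.append(
            {"parameter": name, "rho": float(r.statistic), "p": float(r.pvalue)}
        )
    return pd.DataFrame(rows).set_index("parameter")
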