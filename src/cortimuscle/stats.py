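"""Group-level statistics for coupling vectors.

Grand averages of coupling values across task-related vs non-task rows, a
paired Wilcoxon signed-rank comparison between the two conditions, and a
channel-to-value export for topographic maps.

The Wilcoxon implementation excludes zero differences, uses mid-ranks for
ties, and reports a two-sided p-value from the exact permutation
distribution of the rank sum when n <= 25 (dynamic programming over doubled
ranks, valid with ties) or from the normal approximation with tie and
continuity corrections otherwise.  Z is signed by the rank sum of positive
differences (W+), so swapping the paired columns flips its sign.

Pairing unit: by default one pair per subject x EEG channel (trials and
task-related/non-task sEMG channels averaged first); pairs at different EEG
channels of one subject share trials and are therefore dependent -- use
``unit="subject"`` (averaging channels as well) when independence of pairs
matters, e.g. for calibration studies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

from .features import predictor_columns

__all__ = [
    "PairedSample",
    "WilcoxonResult",
    "wilcoxon_signed_rank",
    "paired_from_table",
    "grand_average",
    "topo_export",
]


@dataclass
class PairedSample:
    task_related: np.ndarray
    non_task: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.task_related, dtype=float)
        b = np.asarray(self.non_task, dtype=float)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("paired samples must be equal-length 1-D arrays")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise ValueError("paired samples must be finite")
        self.task_related, self.non_task = a, b


@dataclass
class WilcoxonResult:
    z: float
    p: float
    w_plus: float
    w_minus: float
    n_used: int              # nonzero differences
    median_task: float
    median_non_task: float
    exact: bool
    degenerate: bool = False  # all differences zero


def _exact_sf_with_ties(ranks2: np.ndarray) -> np.ndarray:
    """Distribution of 2*W+ over all sign assignments (counts array).

    ``ranks2`` are doubled mid-ranks (integers).  Returns counts c[s] of
    assignments with 2*W+ = s, s = 0..sum(ranks2).
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        new = counts.copy()
        new[r:] += counts[: total + 1 - r]
        counts = new
    return counts


def wilcoxon_signed_rank(sample: PairedSample,
                         exact_threshold: int = 25) -> WilcoxonResult:
    """Paired two-sided Wilcoxon signed-rank test (see module docstring)."""
    d = sample.task_related - sample.non_task
    med_t = float(np.median(sample.task_related))
    med_n = float(np.median(sample.non_task))
    d = d[d != 0.0]  # zero-difference exclusion
    n = d.size
    if n == 0:
        return WilcoxonResult(z=0.0, p=1.0, w_plus=0.0, w_minus=0.0,
                              n_used=0, median_task=med_t,
                              median_non_task=med_n, exact=True,
                              degenerate=True)
    ranks = _st.rankdata(np.abs(d))  # mid-ranks for ties
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    sigma = np.sqrt(sigma2) if sigma2 > 0 else 0.0
    if sigma > 0:
        cc = 0.5 if abs(w_plus - mu) >= 0.5 else 0.0  # continuity, toward mean
        z = (w_plus - mu - np.sign(w_plus - mu) * cc) / sigma
    else:
        z = 0.0
    if n <= exact_threshold:
        ranks2 = np.rint(2 * ranks).astype(int)
        counts = _exact_sf_with_ties(ranks2)
        total = counts.sum()
        s_obs = int(round(2 * w_plus))
        lower = counts[: s_obs + 1].sum() / total
        upper = counts[s_obs:].sum() / total
        p = float(min(1.0, 2.0 * min(lower, upper)))
        exact = True
    else:
        p = float(2.0 * _st.norm.sf(abs(z)))
        exact = False
    return WilcoxonResult(z=float(z), p=p, w_plus=w_plus, w_minus=w_minus,
                          n_used=n, median_task=med_t, median_non_task=med_n,
                          exact=exact)


def paired_from_table(table: pd.DataFrame,
                      unit: str = "subject_channel") -> PairedSample:
    """Build the paired task-related / non-task sample from a feature table.

    Per subject, rows with label 1 and label 0 are averaged (over trials and
    sEMG channels) into per-EEG-channel vectors.  ``unit="subject_channel"``
    pairs every (subject, channel); ``unit="subject"`` averages channels so
    pairs are independent across units.
    """
    if unit not in ("subject_channel", "subject"):
        raise ValueError(f"unknown pairing unit {unit!r}")
    cols = predictor_columns(table)
    task_vals, non_vals = [], []
    for _, g in table.groupby("subject"):
        t = g.loc[g["label"] == 1, cols]
        nt = g.loc[g["label"] == 0, cols]
        if t.empty or nt.empty:
            raise ValueError("a subject lacks one of the two conditions")
        tv = t.mean(axis=0).to_numpy()
        nv = nt.mean(axis=0).to_numpy()
        if unit == "subject":
            tv, nv = np.array([tv.mean()]), np.array([nv.mean()])
        task_vals.append(tv)
        non_vals.append(nv)
    return PairedSample(np.concatenate(task_vals), np.concatenate(non_vals))


def grand_average(table: pd.DataFrame) -> pd.DataFrame:
    """Per-EEG-channel mean, SD and median for each label group."""
    cols = predictor_columns(table)
    out = []
    for label, g in table.groupby("label"):
        if g.empty:
            raise ValueError(f"empty group for label {label}")
        vals = g[cols]
        out.append(pd.DataFrame({
            "channel": cols, "label": label,
            "mean": vals.mean(axis=0).to_numpy(),
            "sd": vals.std(axis=0, ddof=0).to_numpy(),
            "median": vals.median(axis=0).to_numpy()}))
    if not out:
        raise ValueError("empty feature table")
    return pd.concat(out, ignore_index=True)


def topo_export(values: Mapping[str, Sequence[float]],
                labels: Sequence[str]) -> pd.DataFrame:
    """Channel -> value table for topographic rendering.

    ``values`` maps a condition name (e.g. "task_related") to one value per
    channel.  Normalized columns are provided under both conventions: the
    condition's own maximum (``norm_own``) and the maximum shared across all
    conditions (``norm_shared``).
    """
    labels = list(labels)
    arrays = {}
    for cond, v in values.items():
        v = np.asarray(v, dtype=float)
        if v.shape != (len(labels),):
            raise ValueError(
                f"condition {cond!r} has {v.size} values for "
                f"{len(labels)} channel labels")
        arrays[cond] = v
    shared_max = max((np.abs(v).max() for v in arrays.values()), default=0.0)
    rows = []
    for cond, v in arrays.items():
        own = np.abs(v).max()
        rows.append(pd.DataFrame({
            "condition": cond, "channel": labels, "value": v,
            "norm_own": v / own if own > 0 else np.ones_like(v),
            "norm_shared": v / shared_max if shared_max > 0 else v}))
    return pd.concat(rows, ignore_index=True)
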