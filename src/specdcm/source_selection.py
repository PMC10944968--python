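"""Data-driven selection of one source per region of interest.

Candidate sources within each predefined ROI are ranked by a massive
univariate one-way ANOVA over baseline-corrected time-frequency power, with
trial type (high accuracy / low accuracy / swap) as the factor: each
(source, time window, frequency bin) cell yields an F statistic, the
uncorrected F values are summed over time and frequency per source, and the
source with the highest collapsed F within the ROI is selected.  Bilateral
ROIs (e.g. a midline region) are selected once across both hemispheres;
others separately for contra- and ipsilateral candidate sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["baseline_correct", "tf_anova", "collapse_f", "select_sources"]

#: canonical time-frequency grid: 31 windows of 0.5 s in 0.05 s steps,
#: 2-100 Hz in 2 Hz steps
N_TIME_WINDOWS = 31
N_FREQ_BINS = 50


def baseline_correct(power: np.ndarray, baseline_power: np.ndarray) -> np.ndarray:
    """Relative-change baseline correction: (power - baseline) / baseline.

    ``power`` has trials on the first axis; ``baseline_power`` is per-trial
    baseline power that is averaged over trials before the correction, so
    the same reference is subtracted from every trial.  Must be strictly
    positive.
    """
    power = np.asarray(power, dtype=float)
    baseline = np.asarray(baseline_power, dtype=float).mean(axis=0)
    if np.any(baseline <= 0):
        raise ValueError("baseline power must be strictly positive")
    return (power - baseline) / baseline


def tf_anova(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """One-way fixed-effects ANOVA F per cell, trials as observations.

    ``values`` is (n_trials, ...) — any trailing shape of time-frequency
    (and source) cells; ``labels`` assigns each trial to a group.  Returns
    the F statistic with (k - 1, N - k) degrees of freedom per cell.
    Every group must contribute at least 2 trials.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    k = groups.size
    if k < 2:
        raise ValueError("need at least two trial types")
    n_total = values.shape[0]
    grand = values.mean(axis=0)
    ss_between = np.zeros(values.shape[1:])
    ss_within = np.zeros(values.shape[1:])
    for g in groups:
        sel = labels == g
        n_g = int(sel.sum())
        if n_g < 2:
            raise ValueError(f"trial type {g!r} has fewer than 2 trials")
        sub = values[sel]
        mean_g = sub.mean(axis=0)
        ss_between += n_g * (mean_g - grand) ** 2
        ss_within += ((sub - mean_g) ** 2).sum(axis=0)
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (n_total - k)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ms_between / ms_within
    return np.where(ms_within == 0, np.where(ms_between == 0, 0.0, np.inf), f)


def collapse_f(f_map: np.ndarray) -> np.ndarray:
    """Sum uncorrected F statistics over all time-frequency cells.

    ``f_map`` is (..., n_time, n_freq) with leading source axes; the sum is
    over the two trailing axes and is invariant to any permutation of
    cells.
    """
    return np.asarray(f_map, dtype=float).sum(axis=(-2, -1))


def select_sources(
    f_maps: np.ndarray,
    rois: dict[str, np.ndarray],
    bilateral_rois: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Pick the source with the highest collapsed F within each ROI.

    Parameters
    ----------
    f_maps : array (n_sources, n_time, n_freq)
        Per-source ANOVA F maps.
    rois : mapping ROI name -> candidate source indices.  For lateralized
        ROIs provide separate ``name_contra`` / ``name_ipsi`` entries;
        names listed in ``bilateral_rois`` are selected once over their
        full candidate set.
    Ties are broken deterministically by the lowest source index.
    """
    collapsed = collapse_f(f_maps)
    rows = []
    for name, candidates in rois.items():
        candidates = np.sort(np.asarray(candidates, dtype=int))
        if candidates.size == 0:
            raise ValueError(f"ROI {name!r} has no candidate sources")
        scores = collapsed[candidates]
        # argmax returns the first maximum; sorted candidates make the tie
        # rule "lowest source index"
        best = candidates[int(np.argmax(scores))]
        rows.append(
            {
                "roi": name,
                "bilateral": name in bilateral_rois,
                "source": int(best),
                "collapsed_f": float(collapsed[best]),
            }
        )
    return pd.DataFrame(rows)
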