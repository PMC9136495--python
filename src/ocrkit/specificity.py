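"""Shannon-entropy stage-specificity calling.

A feature (gene or peak) is stage-specific when its activity concentrates
in one time point. Concentration is measured by the Shannon entropy (bits)
of the feature's stage-mean CPM profile normalized to a probability vector:
0 bits means fully concentrated, log2(S) bits means uniform over S stages.
Candidates below an entropy threshold (1.6 for genes, 1.8 for peaks by
default) must additionally be clearly "on" at their top stage and not
broadly active elsewhere; both activity filters operate on the stage-level
Z profile and are configurable.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .normalize import StageMatrix

logger = logging.getLogger(__name__)

GENE_ENTROPY_THRESHOLD = 1.6
PEAK_ENTROPY_THRESHOLD = 1.8


def shannon_entropy(stage_means: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Entropy in bits of each row of a nonnegative stage-mean matrix.

    Rows are normalized to p_i = x_i / sum(x); H = -sum p_i log2 p_i with
    the convention 0*log(0) = 0. All-zero rows yield NaN (undefined).
    """
    arr = np.asarray(stage_means, dtype=float)
    single = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if arr.shape[1] < 2:
        raise ValueError("entropy requires at least 2 stages")
    if (arr < 0).any():
        raise ValueError("negative stage means")
    totals = arr.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = arr / totals
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    h = -terms.sum(axis=1)
    h[totals.ravel() == 0] = np.nan
    return h[0] if single else h


def call_stage_specific(
    stages: StageMatrix,
    entropy_threshold: float,
    z_high: float = 1.0,
    z_active: float = 0.0,
    max_additional_active: int = 2,
) -> pd.DataFrame:
    """Call each feature stage-specific or not, with a reject reason.

    A feature is specific to its argmax stage iff, in order:

    1. entropy < ``entropy_threshold``            (reject_reason "entropy")
    2. stage Z at the argmax stage > ``z_high``   (reject_reason "max_activity")
    3. at most ``max_additional_active`` OTHER stages have
       stage Z > ``z_active``                     (reject_reason "spread")

    Features with undefined entropy (all stage means zero) are excluded from
    the result, with a logged count. Returns a DataFrame indexed by feature
    with columns: specific (bool), stage, entropy, reject_reason.
    """
    mean_cpm = stages.mean_cpm.to_numpy(dtype=float)
    z = stages.z.to_numpy(dtype=float)
    if mean_cpm.shape != z.shape:
        raise ValueError("mean_cpm and z shapes differ")
    stage_labels = np.asarray(list(stages.mean_cpm.columns))
    h = shannon_entropy(mean_cpm)
    defined = ~np.isnan(h)
    if (~defined).any():
        logger.info("excluding %d all-zero feature(s) with undefined entropy", int((~defined).sum()))

    argmax = mean_cpm.argmax(axis=1)
    rows = np.arange(len(mean_cpm))
    z_at_max = z[rows, argmax]
    other_active = (z > z_active).sum(axis=1) - (z_at_max > z_active).astype(int)

    specific = np.zeros(len(mean_cpm), dtype=bool)
    reason = np.full(len(mean_cpm), "", dtype=object)
    ok_entropy = h < entropy_threshold
    ok_max = z_at_max > z_high
    ok_spread = other_active <= max_additional_active
    specific[defined] = (ok_entropy & ok_max & ok_spread)[defined]
    reason[~ok_entropy] = "entropy"
    reason[ok_entropy & ~ok_max] = "max_activity"
    reason[ok_entropy & ok_max & ~ok_spread] = "spread"
    reason[specific] = ""

    out = pd.DataFrame(
        {
            "specific": specific,
            "stage": np.where(specific, stage_labels[argmax], None),
            "entropy": h,
            "reject_reason": np.where(specific, None, reason),
        },
        index=stages.mean_cpm.index,
    )
    return out.loc[defined]
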