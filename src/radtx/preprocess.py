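"""Transcript filters and control-normalization.

Background correction of array intensities proceeds in two steps: a
detection filter removing transcripts with too many non-assessable reads,
and an intensity filter removing transcripts whose mean intensity sits at
the chip's background-noise level. Surviving transcripts are normalized to
the arithmetic mean of the control-arm samples, gene by gene, yielding
fold changes (log2 by default).
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import ExpressionMatrix, FoldChangeMatrix

logger = logging.getLogger(__name__)

__all__ = ["filter_detection", "filter_intensity", "normalize_to_control"]


def filter_detection(
    matrix: ExpressionMatrix, max_missing_frac: float = 0.30
) -> ExpressionMatrix:
    """Drop genes with ``max_missing_frac`` or more non-assessable reads.

    Retention is strict: a gene is kept only if its missing fraction is
    strictly below the threshold, so at the default 0.30 a gene missing in
    exactly 30% of samples is excluded. Gene order and the sample set are
    preserved.
    """
    if not 0 <= max_missing_frac <= 1:
        raise ValueError("max_missing_frac must lie in [0, 1]")
    if matrix.n_genes == 0 or matrix.n_samples == 0:
        raise ValueError("empty expression matrix")
    frac = matrix.missing_mask.mean(axis=1)
    keep = frac < max_missing_frac
    logger.info("detection filter: %d of %d genes retained", int(keep.sum()), matrix.n_genes)
    return ExpressionMatrix(matrix.values.loc[keep], matrix.arms)


def filter_intensity(matrix: ExpressionMatrix, min_mean: float = 100.0) -> ExpressionMatrix:
    """Keep genes whose mean intensity over assessable reads is >= ``min_mean``.

    The boundary is inclusive (a constant gene at exactly ``min_mean`` is
    retained). Genes with every entry missing have no defined mean and are
    excluded with a log message.
    """
    if matrix.n_genes == 0 or matrix.n_samples == 0:
        raise ValueError("empty expression matrix")
    means = matrix.values.mean(axis=1, skipna=True)
    all_missing = matrix.missing_mask.all(axis=1)
    if all_missing.any():
        logger.warning(
            "%d genes with all entries missing excluded (mean undefined)",
            int(all_missing.sum()),
        )
    keep = (means >= min_mean) & ~all_missing
    logger.info("intensity filter: %d of %d genes retained", int(keep.sum()), matrix.n_genes)
    return ExpressionMatrix(matrix.values.loc[keep], matrix.arms)


def normalize_to_control(
    matrix: ExpressionMatrix, control_arm: str, log2: bool = True
) -> FoldChangeMatrix:
    """Divide each gene by its arithmetic mean over control samples.

    Missing entries stay missing. Genes whose control mean is undefined,
    zero or negative cannot be normalized and are excluded with a log
    message. With ``log2=True`` (default) the ratios are log2-transformed so
    up- and down-regulation are symmetric around 0.
    """
    control_samples = matrix.samples_in_arm(control_arm)
    if not control_samples:
        raise ValueError(f"control arm {control_arm!r} has no samples")
    ctrl_mean = matrix.values[control_samples].mean(axis=1, skipna=True)
    bad = ~(ctrl_mean > 0)
    if bad.any():
        logger.warning(
            "%d genes with non-positive or undefined control mean excluded",
            int(bad.sum()),
        )
    values = matrix.values.loc[~bad].div(ctrl_mean.loc[~bad], axis=0)
    if log2:
        values = np.log2(values)
    return FoldChangeMatrix(values, matrix.arms, log2=log2, control_arm=control_arm)
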