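"""Quantile normalization across arrays and linear scaling to a target median.

Replicate arrays of one strain are normalized together for RNA-level tracks;
treatment (mutant) plus matched control (wild-type) arrays are normalized
together for differential tracks.  Each array's PM and MM values are
concatenated into one vector before normalization, so PM and MM share the
normalization map (joint handling; a flag separates them).  After
normalization the group is linearly scaled so that the pooled PM and MM
median equals the target (100 by default) — effectively normalizing to total
RNA, since the pooled signal is dominated by non-specific hybridization.
"""

from __future__ import annotations

import numpy as np

from .genome_io import IntensitySet

DEFAULT_TARGET_MEDIAN = 100.0

__all__ = ["quantile_normalize", "scale_to_median", "normalize_group"]


def _quantile_normalize_matrix(mat: np.ndarray) -> np.ndarray:
    """Quantile-normalize rows of ``mat`` (arrays x values).

    Each value becomes the mean of the arrays' order statistics at its rank;
    ties within an array receive the mean of the tied ranks' targets, so the
    result is deterministic and permutation-equivariant.
    """
    target = np.sort(mat, axis=1).mean(axis=0)
    out = np.empty_like(mat, dtype=float)
    # prefix sums give O(1) means of target over a tied rank range
    csum = np.concatenate([[0.0], np.cumsum(target)])
    for j in range(mat.shape[0]):
        order = np.argsort(mat[j], kind="stable")
        sorted_vals = mat[j][order]
        assigned = np.empty(len(sorted_vals))
        i = 0
        n = len(sorted_vals)
        while i < n:
            k = i + 1
            while k < n and sorted_vals[k] == sorted_vals[i]:
                k += 1
            assigned[i:k] = (csum[k] - csum[i]) / (k - i)
            i = k
        out[j][order] = assigned
    return out


def quantile_normalize(
    intensities: IntensitySet,
    group: list[str] | None = None,
    joint_pm_mm: bool = True,
) -> IntensitySet:
    """Quantile-normalize the named group of arrays (default: all arrays).

    With ``joint_pm_mm`` (default) each array's PM and MM vectors are
    concatenated before normalization; otherwise PM and MM are normalized
    as separate value sets.  Arrays outside the group are left untouched.
    Afterwards the sorted value multisets of the group's arrays are identical.
    """
    labels = group if group is not None else intensities.labels
    if len(labels) < 2:
        raise ValueError("quantile normalization requires a group of >= 2 arrays")
    idx = intensities.array_indices(labels)
    out = intensities.copy()
    if joint_pm_mm:
        stacked = np.hstack([intensities.pm[idx], intensities.mm[idx]])
        normed = _quantile_normalize_matrix(stacked)
        n = intensities.pm.shape[1]
        out.pm[idx] = normed[:, :n]
        out.mm[idx] = normed[:, n:]
    else:
        out.pm[idx] = _quantile_normalize_matrix(intensities.pm[idx])
        out.mm[idx] = _quantile_normalize_matrix(intensities.mm[idx])
    return out


def scale_to_median(
    intensities: IntensitySet,
    target: float = DEFAULT_TARGET_MEDIAN,
    group: list[str] | None = None,
) -> IntensitySet:
    """Linearly scale the group so the pooled PM+MM median equals ``target``."""
    if target <= 0:
        raise ValueError("target median must be positive")
    labels = group if group is not None else intensities.labels
    idx = intensities.array_indices(labels)
    pooled = np.concatenate(
        [intensities.pm[idx].ravel(), intensities.mm[idx].ravel()]
    )
    med = float(np.median(pooled))
    if med <= 0:
        raise ValueError("pooled median is zero; cannot scale")
    factor = target / med
    out = intensities.copy()
    out.pm[idx] = intensities.pm[idx] * factor
    out.mm[idx] = intensities.mm[idx] * factor
    return out


def normalize_group(
    intensities: IntensitySet,
    group: list[str] | None = None,
    target: float = DEFAULT_TARGET_MEDIAN,
    joint_pm_mm: bool = True,
) -> IntensitySet:
    """Quantile normalization followed by median scaling, on one group."""
    out = quantile_normalize(intensities, group=group, joint_pm_mm=joint_pm_mm)
    return scale_to_median(out, target=target, group=group)
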